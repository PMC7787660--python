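"""Planar registration between the optical and synchrotron frames.

Both instruments record positions relative to three labelled reference
corners of the silicon-nitride frame. Three matched non-collinear points
determine a planar affine transform exactly (6 unknowns, 6 equations);
shear in the fitted transform absorbs stage-axis non-orthogonality, and a
negative determinant flags a mirrored view (the two instruments look at
opposite faces of the membrane).

Coordinate convention: physical nm, origin at the top-left pixel centre,
x rightward (columns), y downward (rows); pixel (i, j) centre is at
(x, y) = (j·px, i·px).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "FIDUCIAL_LABELS",
    "FiducialFrame",
    "AffineTransform2D",
    "fit_affine_from_fiducials",
    "map_point",
    "refine_by_correlation",
    "resample_to_frame",
    "DegenerateGeometryError",
    "CannotRefineError",
]

FIDUCIAL_LABELS = ("ref1", "ref2", "ref3")


class DegenerateGeometryError(ValueError):
    """Fiducials are (near-)collinear: no unique affine transform."""


class CannotRefineError(RuntimeError):
    """Correlation refinement impossible (e.g. zero-variance image)."""


def _triangle_area(points: np.ndarray) -> float:
    a, b, c = points
    u, v = b - a, c - a
    return 0.5 * abs(u[0] * v[1] - u[1] * v[0])


@dataclass
class FiducialFrame:
    """Three labelled reference points (nm) defining one instrument frame."""

    frame_id: str
    points: dict[str, tuple[float, float]]
    min_area_nm2: float = 1e-6

    def __post_init__(self) -> None:
        if set(self.points) != set(FIDUCIAL_LABELS):
            raise ValueError(f"fiducial labels must be exactly {FIDUCIAL_LABELS}")
        self.points = {k: (float(v[0]), float(v[1])) for k, v in self.points.items()}
        if _triangle_area(self.as_array()) <= self.min_area_nm2:
            raise DegenerateGeometryError(
                f"fiducials of frame {self.frame_id!r} are (near-)collinear "
                f"(triangle area <= {self.min_area_nm2} nm^2)"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.points[k] for k in FIDUCIAL_LABELS], dtype=float)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(k, *self.points[k]) for k in FIDUCIAL_LABELS],
            columns=["label", "x_nm", "y_nm"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, frame_id: str | None = None) -> "FiducialFrame":
        df = pd.read_csv(path)
        pts = {r.label: (r.x_nm, r.y_nm) for r in df.itertuples()}
        return cls(frame_id=frame_id or Path(path).stem, points=pts)


@dataclass(frozen=True, eq=False)
class AffineTransform2D:
    """p' = A·p + b with A a 2×2 linear part and b a 2-vector offset (nm)."""

    matrix: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float).reshape(2, 2))
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float).reshape(2))
        if abs(self.determinant) <= 1e-12:
            raise ValueError("transform is not invertible (|det| <= 1e-12)")

    # --- algebra ----------------------------------------------------------
    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.matrix))

    @property
    def is_mirror(self) -> bool:
        """True when the transform includes a reflection (det < 0)."""
        return self.determinant < 0

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix.T + self.offset
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return AffineTransform2D(
            self.matrix @ other.matrix, self.matrix @ other.offset + self.offset
        )

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform2D(inv, -inv @ self.offset)

    # --- constructors -------------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "AffineTransform2D":
        return cls(np.eye(2), np.array([dx, dy], dtype=float))

    @classmethod
    def similarity(
        cls,
        scale: float = 1.0,
        rotation_deg: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
        mirror: bool = False,
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform2D":
        """Similarity transform about ``center``; mirror flips y before rotating."""
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        lin = scale * rot
        if mirror:
            lin = lin @ np.diag([1.0, -1.0])
        c = np.asarray(center, dtype=float)
        offset = c - lin @ c + np.asarray(translation, dtype=float)
        return cls(lin, offset)

    # --- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        m = np.column_stack([self.matrix, self.offset])  # 2x3, row-major
        payload = json.dumps({"matrix_2x3_row_major": m.ravel().tolist(), "units": "nm"}, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, src: str | Path) -> "AffineTransform2D":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        m = np.asarray(json.loads(text)["matrix_2x3_row_major"], dtype=float).reshape(2, 3)
        return cls(m[:, :2], m[:, 2])


def fit_affine_from_fiducials(src: FiducialFrame, dst: FiducialFrame) -> AffineTransform2D:
    """Exact interpolating affine from three matched reference points.

    Three non-collinear point pairs determine the six affine parameters
    exactly; the residual on the fiducials is at numerical precision.
    """
    if set(src.points) != set(dst.points):
        raise ValueError("fiducial label sets differ between frames")
    p = src.as_array()
    q = dst.as_array()
    design = np.column_stack([p, np.ones(3)])  # 3x3
    if abs(np.linalg.det(design)) < 1e-9:
        raise DegenerateGeometryError("source fiducials are collinear")
    sol = np.linalg.solve(design, q)  # columns: [a1 a2; b1 b2; c1 c2]
    matrix = sol[:2].T
    offset = sol[2]
    return AffineTransform2D(matrix, offset)


def map_point(t: AffineTransform2D, point) -> np.ndarray:
    """Apply the transform to one point or an (N, 2) array of points."""
    return t.apply(point)


@dataclass
class RefineResult:
    transform: AffineTransform2D
    shift_px: tuple[float, float]  # (dx, dy), moving → fixed
    peak_correlation: float


def _masked_pearson(a: np.ndarray, b: np.ndarray) -> float:
    sel = np.isfinite(a) & np.isfinite(b)
    if sel.sum() < 3:
        return -np.inf
    a, b = a[sel], b[sel]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return -np.inf
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def refine_by_correlation(
    fixed: np.ndarray,
    moving: np.ndarray,
    init: AffineTransform2D | None = None,
    search_radius_px: int = 5,
    pixel_size_nm: float = 1.0,
    subpixel: bool = False,
) -> RefineResult:
    """Translation-only refinement by normalized cross-correlation.

    Both images must already live on a common grid (``moving`` resampled
    through ``init``). The integer-pixel shift maximizing the masked
    Pearson correlation within ``search_radius_px`` is composed (in nm)
    with ``init``; with ``subpixel`` a parabolic fit around the peak gives
    ~0.1-pixel resolution.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    for name, img in (("fixed", fixed), ("moving", moving)):
        vals = img[np.isfinite(img)]
        if vals.size < 9 or vals.std() == 0:
            raise CannotRefineError(f"{name} image is flat or empty; cannot refine")

    r = int(search_radius_px)
    corr = np.full((2 * r + 1, 2 * r + 1), -np.inf)
    for i, dy in enumerate(range(-r, r + 1)):
        for j, dx in enumerate(range(-r, r + 1)):
            shifted = np.full_like(moving, np.nan)
            ys = slice(max(0, dy), moving.shape[0] + min(0, dy))
            xs = slice(max(0, dx), moving.shape[1] + min(0, dx))
            ys_src = slice(max(0, -dy), moving.shape[0] + min(0, -dy))
            xs_src = slice(max(0, -dx), moving.shape[1] + min(0, -dx))
            shifted[ys, xs] = moving[ys_src, xs_src]
            corr[i, j] = _masked_pearson(fixed, shifted)

    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    peak = corr[iy, ix]
    dy, dx = float(iy - r), float(ix - r)

    if subpixel:
        for axis, idx in (("y", iy), ("x", ix)):
            if 0 < idx < 2 * r:
                c = corr[idx - 1: idx + 2, ix] if axis == "y" else corr[iy, idx - 1: idx + 2]
                if np.all(np.isfinite(c)):
                    denom = c[0] - 2 * c[1] + c[2]
                    if denom < 0:
                        frac = 0.5 * (c[0] - c[2]) / denom
                        if axis == "y":
                            dy += float(np.clip(frac, -0.5, 0.5))
                        else:
                            dx += float(np.clip(frac, -0.5, 0.5))

    shift_t = AffineTransform2D.translation(dx * pixel_size_nm, dy * pixel_size_nm)
    base = init if init is not None else AffineTransform2D.identity()
    return RefineResult(
        transform=shift_t.compose(base), shift_px=(dx, dy), peak_correlation=float(peak)
    )


def resample_to_frame(
    data: np.ndarray,
    transform: AffineTransform2D,
    src_pixel_size_nm: float,
    out_shape: tuple[int, int],
    out_pixel_size_nm: float | None = None,
    order: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``data`` (source frame) onto the destination frame grid.

    ``transform`` maps source-frame coordinates (nm) to destination-frame
    coordinates. Inverse mapping with bilinear interpolation; destination
    pixels mapping outside the source are flagged in the returned
    ``missing`` mask (NaN in the data), never zero-filled.
    """
    data = np.asarray(data, dtype=float)
    out_pixel_size_nm = out_pixel_size_nm or src_pixel_size_nm
    inv = transform.inverse()
    ny, nx = out_shape
    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
    dst_xy = np.stack([jj.ravel() * out_pixel_size_nm, ii.ravel() * out_pixel_size_nm], axis=1)
    src_xy = inv.apply(dst_xy)
    rows = src_xy[:, 1] / src_pixel_size_nm
    cols = src_xy[:, 0] / src_pixel_size_nm
    out = ndimage.map_coordinates(
        data, np.array([rows, cols]), order=order, mode="constant", cval=np.nan
    ).reshape(out_shape)
    missing = ~np.isfinite(out)
    if missing.all():
        raise ValueError("empty overlap: every destination pixel maps outside the source")
    return out, missing
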