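"""Background masking, masked Pearson colocalization, and line profiles.

Background pixels are identified by kappa-sigma clipping (iterate: compute
mean and SD over the current background set, drop pixels above
mean + k·SD) unless an explicit background region is given. The foreground
threshold is the background mean plus k (default 3) standard deviations of
the background pixel values. Pearson correlation between two channels is
computed only over foreground pixels (union of the per-channel masks by
default), so the coefficient reflects signal covariation rather than the
shared empty background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "BackgroundStats",
    "ColocResult",
    "estimate_background",
    "foreground_mask",
    "masked_pearson",
    "line_profile",
]


@dataclass
class BackgroundStats:
    mean: float
    sd: float
    k: float
    threshold: float
    n_background: int
    iterations: int
    converged: bool


def _finite(values: np.ndarray) -> np.ndarray:
    return values[np.isfinite(values)]


def estimate_background(
    data: np.ndarray,
    k: float = 3.0,
    background_roi: np.ndarray | None = None,
    max_iter: int = 50,
) -> BackgroundStats:
    """Estimate background level and spread of a map.

    With ``background_roi`` (boolean mask) the statistics come from that
    region directly. Otherwise kappa-sigma clipping is run from the full
    pixel set; a constant image converges immediately with sd 0. Failure to
    converge within ``max_iter`` returns the last iterate with
    ``converged=False``.
    """
    data = np.asarray(data, dtype=float)
    if background_roi is not None:
        vals = _finite(data[np.asarray(background_roi, dtype=bool)])
        if vals.size < 2:
            raise ValueError("background ROI must contain >= 2 finite pixels")
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        return BackgroundStats(mean, sd, k, mean + k * sd, int(vals.size), 0, True)

    vals = _finite(data)
    if vals.size < 16:
        raise ValueError("need >= 16 non-missing pixels to estimate background")
    current = vals
    converged = False
    mean = sd = 0.0
    iterations = 0
    for iterations in range(1, max_iter + 1):
        mean, sd = float(current.mean()), float(current.std(ddof=1)) if current.size > 1 else 0.0
        kept = current[current <= mean + k * sd]
        if kept.size == current.size:
            converged = True
            break
        if kept.size < 2:  # clipping collapsed; keep last sane iterate
            break
        current = kept
    if not converged:
        warnings.warn("kappa-sigma clipping did not converge; returning last iterate")
    return BackgroundStats(mean, sd, k, mean + k * sd, int(current.size), iterations, converged)


def foreground_mask(data: np.ndarray, bg: BackgroundStats) -> np.ndarray:
    """Pixels strictly above the background threshold (missing excluded)."""
    data = np.asarray(data, dtype=float)
    return np.isfinite(data) & (data > bg.threshold)


@dataclass
class ColocResult:
    channel_a: str
    channel_b: str
    pearson_r: float
    n_pixels: int
    policy: str


def masked_pearson(
    map_a: np.ndarray,
    map_b: np.ndarray,
    policy: str = "union",
    k: float = 3.0,
    names: tuple[str, str] = ("A", "B"),
    bg_a: BackgroundStats | None = None,
    bg_b: BackgroundStats | None = None,
) -> ColocResult:
    """Pearson correlation between two channels over foreground pixels.

    ``policy`` selects the pixel set: union (default) or intersection of
    the per-channel foreground masks.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel grids differ in shape")
    if policy not in ("union", "intersection"):
        raise ValueError("policy must be 'union' or 'intersection'")
    bg_a = bg_a or estimate_background(a, k=k)
    bg_b = bg_b or estimate_background(b, k=k)
    ma = foreground_mask(a, bg_a)
    mb = foreground_mask(b, bg_b)
    sel = (ma | mb) if policy == "union" else (ma & mb)
    sel &= np.isfinite(a) & np.isfinite(b)
    n = int(sel.sum())
    if n < 3:
        raise ValueError(f"only {n} pixels pass the {policy} mask; >= 3 required")
    va, vb = a[sel], b[sel]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero variance in a channel over the mask; correlation undefined")
    r = float(stats.pearsonr(va, vb).statistic)
    return ColocResult(names[0], names[1], r, n, policy)


def line_profile(
    maps,
    polyline_nm,
    pixel_size_nm: float,
    width_nm: float = 0.0,
    normalize: bool = False,
    step_nm: float | None = None,
):
    """Sample one or more maps along a polyline (nm coordinates).

    Samples every ``step_nm`` (default: one pixel) of arc length, averaging
    perpendicular to the local direction over ``width_nm``. With
    ``normalize`` each profile is mapped to (p − min)/(max − min); a
    constant profile normalizes to all zeros with a warning.

    Returns ``(distances_nm, profiles)`` where profiles is a list matching
    the input maps (a single array input yields a one-element list).
    """
    single = isinstance(maps, np.ndarray)
    maps = [maps] if single else list(maps)
    pts = np.asarray(polyline_nm, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline needs at least two (x, y) vertices")
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seg_len.sum())
    if total <= 0:
        raise ValueError("degenerate (zero-length) polyline")

    step = step_nm or pixel_size_nm
    distances = np.arange(0.0, total + 0.5 * step, step)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    centers, normals = [], []
    for d in distances:
        i = min(np.searchsorted(cum, d, side="right") - 1, len(seg) - 1)
        frac = (d - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
        p = pts[i] + frac * seg[i]
        t = seg[i] / seg_len[i]
        centers.append(p)
        normals.append(np.array([-t[1], t[0]]))
    centers = np.asarray(centers)
    normals = np.asarray(normals)

    if width_nm > 0:
        offs = np.arange(-width_nm / 2, width_nm / 2 + 0.5 * pixel_size_nm, pixel_size_nm)
    else:
        offs = np.array([0.0])

    profiles = []
    for m in maps:
        m = np.asarray(m, dtype=float)
        acc = np.zeros(len(centers))
        cnt = np.zeros(len(centers))
        for o in offs:
            xy = centers + o * normals
            rows = xy[:, 1] / pixel_size_nm
            cols = xy[:, 0] / pixel_size_nm
            vals = ndimage.map_coordinates(
                m, np.array([rows, cols]), order=1, mode="constant", cval=np.nan
            )
            ok = np.isfinite(vals)
            acc[ok] += vals[ok]
            cnt[ok] += 1
        with np.errstate(invalid="ignore"):
            prof = acc / np.where(cnt > 0, cnt, np.nan)
        if normalize:
            lo, hi = np.nanmin(prof), np.nanmax(prof)
            if hi > lo:
                prof = (prof - lo) / (hi - lo)
            else:
                warnings.warn("constant profile: normalization undefined, returning zeros")
                prof = np.zeros_like(prof)
        profiles.append(prof)
    return distances, profiles
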