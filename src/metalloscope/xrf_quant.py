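"""Unit conversions and detection limits for quantified XRF element maps.

Quantified synchrotron X-ray fluorescence maps arrive as areal mass density
(ng/mm² per pixel). This module converts between areal density, per-pixel
mass, and atom counts, and computes the IUPAC limit of detection
LOD = m_b + k·σ_b from replicate blank measurements.

All internal arithmetic is carried at full precision in g/nm²; rounding to
two significant figures happens only at report time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MOLAR_MASS_G_PER_MOL",
    "AVOGADRO",
    "ElementMap",
    "LODEntry",
    "areal_density_to_atoms",
    "atoms_to_areal_density",
    "pixel_mass",
    "atoms_per_pixel",
    "compute_lod",
    "lod_per_pixel",
    "lod_report",
    "round_sig",
]

#: IUPAC 2021 standard atomic weights (g/mol) for the supported elements.
MOLAR_MASS_G_PER_MOL: dict[str, float] = {
    "P": 30.974,
    "S": 32.06,
    "K": 39.098,
    "Ca": 40.078,
    "Fe": 55.845,
    "Cu": 63.546,
    "Zn": 65.38,
}

AVOGADRO = 6.02214076e23  # atoms/mol (exact, SI 2019)

#: 1 ng/mm² expressed in g/nm²  (1e-9 g / 1e12 nm²)
_NG_MM2_TO_G_NM2 = 1e-21


class UnknownElementError(ValueError):
    pass


def _molar_mass(element: str) -> float:
    try:
        return MOLAR_MASS_G_PER_MOL[element]
    except KeyError:
        raise UnknownElementError(
            f"unknown element {element!r}; supported: "
            + ", ".join(sorted(MOLAR_MASS_G_PER_MOL))
        ) from None


@dataclass
class ElementMap:
    """A 2-D areal mass density map (ng/mm²) for one element.

    ``missing`` marks pixels with no data (e.g. outside the resampled field
    of view); they propagate as NaN through conversions and are excluded
    from statistics downstream.
    """

    element: str
    data: np.ndarray
    pixel_size_nm: float
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        _molar_mass(self.element)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ElementMap data must be 2-D")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.data.shape:
                raise ValueError("missing mask shape mismatch")
        valid = self.valid_data
        if np.any(valid[np.isfinite(valid)] < 0):
            raise ValueError("areal densities must be >= 0 where not missing")

    @property
    def valid_data(self) -> np.ndarray:
        """Data with missing pixels replaced by NaN."""
        if self.missing is None:
            return self.data
        out = self.data.copy()
        out[self.missing] = np.nan
        return out

    # --- I/O -------------------------------------------------------------
    def write_tiff(self, path: str | Path) -> None:
        import tifffile

        path = Path(path)
        tifffile.imwrite(path, self.valid_data.astype(np.float32))
        sidecar = {
            "element": self.element,
            "pixel_size_nm": self.pixel_size_nm,
            "units": "ng/mm^2",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read_tiff(cls, path: str | Path) -> "ElementMap":
        import tifffile

        path = Path(path)
        data = np.asarray(tifffile.imread(path), dtype=float)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        missing = ~np.isfinite(data)
        data = np.where(missing, 0.0, data)
        return cls(
            element=meta["element"],
            data=data,
            pixel_size_nm=float(meta["pixel_size_nm"]),
            missing=missing if missing.any() else None,
        )


def areal_density_to_atoms(density_ng_mm2, element: str | None = None):
    """Convert areal mass density (ng/mm²) to atomic density (atoms/nm²).

    atoms/nm² = density · 1e-21 (g/nm² per ng/mm²) · N_A / M.
    Accepts scalars, arrays, or an :class:`ElementMap` (NaN at missing
    pixels propagates).
    """
    if isinstance(density_ng_mm2, ElementMap):
        return areal_density_to_atoms(density_ng_mm2.valid_data, density_ng_mm2.element)
    if element is None:
        raise TypeError("element symbol required unless passing an ElementMap")
    m = _molar_mass(element)
    return np.asarray(density_ng_mm2, dtype=float) * _NG_MM2_TO_G_NM2 * AVOGADRO / m


def atoms_to_areal_density(atoms_nm2, element: str):
    """Inverse of :func:`areal_density_to_atoms` (atoms/nm² → ng/mm²)."""
    m = _molar_mass(element)
    return np.asarray(atoms_nm2, dtype=float) * m / (AVOGADRO * _NG_MM2_TO_G_NM2)


def pixel_mass(density_ng_mm2, pixel_size_nm: float):
    """Element mass in grams contained in one pixel.

    mass = density[ng/mm²] · 1e-21 · pixel_size_nm² grams.
    """
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be > 0")
    return np.asarray(density_ng_mm2, dtype=float) * 1e-21 * pixel_size_nm**2


def atoms_per_pixel(density_ng_mm2, pixel_size_nm: float, element: str):
    """Number of atoms of ``element`` in one pixel."""
    return areal_density_to_atoms(density_ng_mm2, element) * pixel_size_nm**2


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report-time convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass
class LODEntry:
    """IUPAC detection limit for one element from blank replicates."""

    element: str
    blank_mean_ng_mm2: float
    blank_sd_ng_mm2: float
    k: float
    n_blanks: int
    lod_areal_ng_mm2: float = field(init=False)

    def __post_init__(self) -> None:
        self.lod_areal_ng_mm2 = self.blank_mean_ng_mm2 + self.k * self.blank_sd_ng_mm2


def compute_lod(blanks: Iterable[float], element: str = "Zn", k: float = 3.0) -> LODEntry:
    """LOD = mean(blanks) + k · sd(blanks) with the sample (n−1) deviation.

    Requires at least two blank measurements (σ is otherwise undefined).
    """
    values = np.asarray(list(blanks), dtype=float)
    if values.size < 2:
        raise ValueError("at least 2 blank measurements required to estimate sigma")
    return LODEntry(
        element=element,
        blank_mean_ng_mm2=float(values.mean()),
        blank_sd_ng_mm2=float(values.std(ddof=1)),
        k=float(k),
        n_blanks=int(values.size),
    )


def lod_per_pixel(
    lod_areal_ng_mm2: float, pixel_size_nm: float, element: str
) -> dict[str, float]:
    """Express an areal LOD as per-pixel mass (g) and atom count.

    Atoms are reported both at full precision and rounded to 2 significant
    figures (the convention of published per-pixel detection-limit tables).
    """
    mass_g = float(pixel_mass(lod_areal_ng_mm2, pixel_size_nm))
    atoms = float(atoms_per_pixel(lod_areal_ng_mm2, pixel_size_nm, element))
    return {
        "element": element,
        "pixel_size_nm": pixel_size_nm,
        "mass_g": mass_g,
        "mass_g_2sf": round_sig(mass_g, 2),
        "atoms": atoms,
        "atoms_2sf": round_sig(atoms, 2),
    }


def lod_report(
    blank_table: Mapping[str, Iterable[float]] | pd.DataFrame,
    k: float = 3.0,
    pixel_size_nm: float = 40.0,
) -> pd.DataFrame:
    """Per-element LOD table from a blanks table (one column per element)."""
    if isinstance(blank_table, pd.DataFrame):
        blank_table = {c: blank_table[c].to_numpy() for c in blank_table.columns}
    rows = []
    for element, blanks in blank_table.items():
        entry = compute_lod(blanks, element=element, k=k)
        per_px = lod_per_pixel(entry.lod_areal_ng_mm2, pixel_size_nm, element)
        rows.append(
            {
                "element": element,
                "n_blanks": entry.n_blanks,
                "blank_mean_ng_mm2": entry.blank_mean_ng_mm2,
                "blank_sd_ng_mm2": entry.blank_sd_ng_mm2,
                "k": entry.k,
                "lod_ng_mm2": entry.lod_areal_ng_mm2,
                "lod_pixel_mass_g": per_px["mass_g"],
                "lod_pixel_mass_g_2sf": per_px["mass_g_2sf"],
                "lod_pixel_atoms": per_px["atoms"],
                "lod_pixel_atoms_2sf": per_px["atoms_2sf"],
            }
        )
    return pd.DataFrame(rows).set_index("element")
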