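"""Metal-to-protein stoichiometry from element maps and sequence composition.

The atomic ratio between two elements (e.g. S/Zn) is measured as the ratio
of background-corrected mean atomic densities over regions of interest
centred on the structure of interest, aggregated as mean ± SD over ROIs.
Dividing an S/metal ratio by the protein's sulfur content (one atom per
methionine or cysteine residue, counted from sequence) converts it to a
protein-molecules-per-metal stoichiometry. Note this is a colocalization
stoichiometry; it does not by itself prove direct chemical binding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .colocalization import BackgroundStats, estimate_background

__all__ = [
    "RectROI",
    "StoichiometrySummary",
    "sulfur_atoms_per_molecule",
    "sulfur_atoms_from_fasta",
    "roi_atomic_ratio",
    "compute_roi_ratios",
    "summarize_ratios",
    "molecules_per_metal",
]

logger = logging.getLogger(__name__)

_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}  # X allowed, contributes no sulfur


def sulfur_atoms_per_molecule(sequences: str | Iterable[str]) -> int:
    """Count sulfur atoms in a protein from its chain sequence(s).

    One sulfur atom per methionine (M) and per cysteine (C), summed over all
    chains of the molecule (e.g. the two chains of a tubulin-αβ dimer).
    Unknown residues 'X' contribute zero; any other letter is rejected with
    its position.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    total = 0
    for chain_idx, seq in enumerate(sequences):
        seq = seq.strip().upper()
        for pos, aa in enumerate(seq):
            if aa not in _AMINO_ACIDS:
                raise ValueError(
                    f"illegal amino-acid character {aa!r} at chain {chain_idx + 1}, "
                    f"position {pos + 1}"
                )
        total += seq.count("M") + seq.count("C")
    return total


def sulfur_atoms_from_fasta(path: str | Path) -> int:
    """Sulfur count summed over all records of a FASTA file."""
    from Bio import SeqIO

    seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return sulfur_atoms_per_molecule(seqs)


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangular ROI in physical nm coordinates."""

    label: str
    x_nm: float
    y_nm: float
    w_nm: float
    h_nm: float

    def to_mask(self, shape: tuple[int, int], pixel_size_nm: float) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        c0 = int(round(self.x_nm / pixel_size_nm))
        r0 = int(round(self.y_nm / pixel_size_nm))
        c1 = int(round((self.x_nm + self.w_nm) / pixel_size_nm))
        r1 = int(round((self.y_nm + self.h_nm) / pixel_size_nm))
        mask[max(r0, 0): r1, max(c0, 0): c1] = True
        return mask


def _roi_mask(roi, shape: tuple[int, int], pixel_size_nm: float) -> np.ndarray:
    if isinstance(roi, RectROI):
        mask = roi.to_mask(shape, pixel_size_nm)
    else:
        mask = np.asarray(roi, dtype=bool)
        if mask.shape != shape:
            raise ValueError("ROI mask shape does not match the maps")
    if mask.sum() < 4:
        raise ValueError("each ROI must contain at least 4 pixels")
    return mask


def roi_atomic_ratio(
    numerator: np.ndarray,
    denominator: np.ndarray,
    roi,
    pixel_size_nm: float = 40.0,
    background_correction: bool = True,
    numerator_bg: BackgroundStats | None = None,
    denominator_bg: BackgroundStats | None = None,
) -> float | None:
    """Ratio of mean atomic densities over one ROI.

    With background correction (default on) each channel's blank level —
    the kappa-sigma background mean of the full map unless supplied — is
    subtracted before taking the ratio, so off-structure signal does not
    bias the stoichiometry. An ROI whose corrected denominator is not
    positive is excluded (returns None, reason logged).
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape:
        raise ValueError("numerator and denominator maps differ in shape")
    mask = _roi_mask(roi, num.shape, pixel_size_nm)
    sel = mask & np.isfinite(num) & np.isfinite(den)
    if sel.sum() < 4:
        logger.info("ROI excluded: fewer than 4 valid pixels")
        return None
    n_blank = d_blank = 0.0
    if background_correction:
        n_blank = (numerator_bg or estimate_background(num)).mean
        d_blank = (denominator_bg or estimate_background(den)).mean
    num_mean = float(num[sel].mean()) - n_blank
    den_mean = float(den[sel].mean()) - d_blank
    if den_mean <= 0:
        logger.info("ROI excluded: corrected denominator mean %.3g <= 0", den_mean)
        return None
    return num_mean / den_mean


def compute_roi_ratios(
    numerator: np.ndarray,
    denominator: np.ndarray,
    rois: Sequence,
    pixel_size_nm: float = 40.0,
    background_correction: bool = True,
) -> tuple[list[float], int]:
    """Per-ROI ratios over a set of ROIs; returns (ratios, n_excluded).

    Background levels are estimated once per map and shared across ROIs.
    """
    nbg = estimate_background(np.asarray(numerator, dtype=float)) if background_correction else None
    dbg = (
        estimate_background(np.asarray(denominator, dtype=float)) if background_correction else None
    )
    ratios: list[float] = []
    excluded = 0
    for roi in rois:
        r = roi_atomic_ratio(
            numerator,
            denominator,
            roi,
            pixel_size_nm=pixel_size_nm,
            background_correction=background_correction,
            numerator_bg=nbg,
            denominator_bg=dbg,
        )
        if r is None:
            excluded += 1
        else:
            ratios.append(r)
    return ratios, excluded


def summarize_ratios(ratios: Iterable[float]) -> tuple[float, float, int]:
    """Aggregate per-ROI ratios as (mean, sample SD, n); needs n >= 2."""
    vals = np.asarray(list(ratios), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 ratios to summarize (SD undefined)")
    return float(vals.mean()), float(vals.std(ddof=1)), int(vals.size)


@dataclass
class StoichiometrySummary:
    """Aggregate elemental ratio and its protein-molecule conversion."""

    numerator_element: str
    denominator_element: str
    ratios: list[float]
    n_excluded: int
    s_per_molecule: int | None = None
    ratio_mean: float = field(init=False)
    ratio_sd: float = field(init=False)
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.ratio_mean, self.ratio_sd, self.n = summarize_ratios(self.ratios)

    def molecules_per_metal(self) -> dict[str, float]:
        if self.s_per_molecule is None:
            raise ValueError("s_per_molecule not set")
        return molecules_per_metal(self.ratio_mean, self.ratio_sd, self.s_per_molecule)


def molecules_per_metal(
    ratio_mean: float, ratio_sd: float, s_per_molecule: int
) -> dict[str, float]:
    """Convert an S/metal atomic ratio to protein molecules per metal atom.

    The divisor is a known constant of the protein sequence, so both mean
    and SD scale by 1/s_per_molecule. Values are reported at full precision
    and rounded to one decimal (the customary reporting precision).
    """
    if s_per_molecule < 1:
        raise ValueError("s_per_molecule must be >= 1")
    mean = ratio_mean / s_per_molecule
    sd = ratio_sd / s_per_molecule
    return {
        "mean": mean,
        "sd": sd,
        "mean_1dp": round(mean, 1),
        "sd_1dp": round(sd, 1),
    }
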