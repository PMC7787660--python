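"""Quantitative fluorescence group comparison for chelation experiments.

Per image: segment signal by mode-thresholding the intensity histogram
(threshold = lower edge of the bin just above the modal bin), exclude the
soma so only dendritic areas contribute, and take the mean foreground
intensity (counts/pixel). Per-image means are normalized to the median of
the matching control group (per biological replicate when replicate ids
are present) and compared across groups with a fixed decision tree:

* assumption checks at alpha 0.05 — Shapiro-Wilk normality per group,
  Bartlett homogeneity of variances across groups;
* two groups: Student t-test when both assumptions hold, otherwise
  Mann-Whitney U;
* three or more groups: one-way ANOVA with Tukey HSD pairwise when both
  hold, otherwise Kruskal-Wallis followed — only when the omnibus p is
  below ``alpha_gate`` (default 0.01) — by Dunn's rank test with Holm
  adjustment.

The report records the exact path taken, so the decision is auditable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "mode_threshold",
    "measure_image",
    "MeasureResult",
    "normalize_to_control",
    "dunn_test",
    "compare_groups",
    "GroupComparisonReport",
]


def mode_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Histogram-mode segmentation threshold.

    Builds ``n_bins`` equal-width bins over [min, max]; the threshold is
    the lower edge of the bin immediately above the modal bin (the dominant
    background mode), ties on the modal count broken toward the lowest bin.
    A constant image returns that constant with a warning (empty
    foreground).
    """
    vals = np.asarray(image, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("image has no finite pixels")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        warnings.warn("constant image: threshold equals the constant, foreground empty")
        return lo
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    mode_idx = int(np.argmax(counts))  # argmax takes the first (lowest) on ties
    return float(edges[min(mode_idx + 1, n_bins)])


@dataclass
class MeasureResult:
    mean_intensity: float  # NaN when the image is excluded
    n_pixels: int
    excluded: bool
    reason: str | None = None


def measure_image(
    image: np.ndarray, threshold: float, soma_mask: np.ndarray | None = None
) -> MeasureResult:
    """Mean intensity (counts/pixel) over segmented, soma-excluded pixels."""
    img = np.asarray(image, dtype=float)
    sel = np.isfinite(img) & (img > threshold)
    if soma_mask is not None:
        soma = np.asarray(soma_mask, dtype=bool)
        if soma.shape != img.shape:
            raise ValueError("soma mask shape mismatch")
        sel &= ~soma
    n = int(sel.sum())
    if n == 0:
        return MeasureResult(np.nan, 0, True, "empty foreground after threshold/soma exclusion")
    return MeasureResult(float(img[sel].mean()), n, False)


def normalize_to_control(
    df: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    replicate_col: str | None = None,
    control_label: str = "control",
) -> pd.Series:
    """Divide every value by the control-group median.

    With a replicate column, each replicate experiment is normalized by its
    own control median, making replicates comparable despite day-to-day
    intensity scale changes.
    """
    def _norm(sub: pd.DataFrame) -> pd.Series:
        ctrl = sub.loc[sub[group_col] == control_label, value_col]
        if ctrl.empty:
            raise ValueError("control group is empty; cannot normalize")
        med = float(ctrl.median())
        if med == 0:
            raise ValueError("control median is zero; cannot normalize")
        return sub[value_col] / med

    if replicate_col is None:
        return _norm(df)
    out = pd.Series(index=df.index, dtype=float)
    for _, sub in df.groupby(replicate_col):
        out.loc[sub.index] = _norm(sub)
    return out


def dunn_test(groups: dict[str, np.ndarray], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise rank test after a Kruskal-Wallis omnibus.

    z_ij = (mean rank_i − mean rank_j) / sqrt((N(N+1)/12 − T)·(1/n_i + 1/n_j))
    with tie correction T = Σ(t³ − t) / (12(N − 1)); two-sided normal
    p-values, Holm-adjusted by default.
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    ranks = stats.rankdata(pooled)
    sizes = {g: len(groups[g]) for g in names}
    n_total = len(pooled)
    mean_ranks, start = {}, 0
    for g in names:
        mean_ranks[g] = ranks[start: start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_raw"].to_numpy(), method=adjust)[1]
    out["adjustment"] = adjust
    return out


@dataclass
class GroupComparisonReport:
    groups: dict[str, int]  # group -> n
    normality_p: dict[str, float]
    variance_homogeneity_p: float
    assumptions_met: bool
    assumption_alpha: float
    omnibus_test: str
    omnibus_p: float
    alpha_gate: float
    pairwise: pd.DataFrame | None
    decision_path: list[str] = field(default_factory=list)


def compare_groups(
    values_by_group: dict[str, np.ndarray],
    alpha_gate: float = 0.01,
    assumption_alpha: float = 0.05,
) -> GroupComparisonReport:
    """Run the group-comparison decision tree on normalized intensities."""
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    groups = {g: v[np.isfinite(v)] for g, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has n={len(v)} < 3")

    path: list[str] = []
    normality_p = {}
    for g, v in groups.items():
        if np.ptp(v) == 0:  # shapiro undefined on constant data; clearly non-normal fit
            normality_p[g] = 0.0
        else:
            normality_p[g] = float(stats.shapiro(v).pvalue)
    normal = all(p > assumption_alpha for p in normality_p.values())
    path.append(f"shapiro-wilk per group at alpha={assumption_alpha}: "
                + ("pass" if normal else "fail"))
    if all(np.ptp(v) > 0 for v in groups.values()):
        bartlett_p = float(stats.bartlett(*groups.values()).pvalue)
    else:
        bartlett_p = 1.0
    homogeneous = bartlett_p > assumption_alpha
    path.append(f"bartlett at alpha={assumption_alpha}: " + ("pass" if homogeneous else "fail"))
    assumptions_met = normal and homogeneous

    names = list(groups)
    pairwise = None
    if len(groups) == 2:
        a, b = (groups[n] for n in names)
        if assumptions_met:
            omnibus = "t-test"
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        else:
            omnibus = "mann-whitney"
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        path.append(f"two groups -> {omnibus}")
    else:
        if assumptions_met:
            omnibus = "anova"
            p = float(stats.f_oneway(*groups.values()).pvalue)
            path.append("assumptions met -> one-way ANOVA + Tukey HSD")
            res = stats.tukey_hsd(*groups.values())
            rows = []
            for i, j in itertools.combinations(range(len(names)), 2):
                rows.append(
                    {
                        "group_a": names[i],
                        "group_b": names[j],
                        "p_raw": float(res.pvalue[i, j]),
                        "p_adjusted": float(res.pvalue[i, j]),
                        "adjustment": "tukey",
                    }
                )
            pairwise = pd.DataFrame(rows)
        else:
            omnibus = "kruskal-wallis"
            p = float(stats.kruskal(*groups.values()).pvalue)
            path.append("assumptions not met -> Kruskal-Wallis")
            if p < alpha_gate:
                path.append(f"omnibus p={p:.3g} < {alpha_gate} -> Dunn pairwise, Holm adjustment")
                pairwise = dunn_test(groups, adjust="holm")
            else:
                path.append(f"omnibus p={p:.3g} >= {alpha_gate} -> no pairwise tests")

    return GroupComparisonReport(
        groups={g: len(v) for g, v in groups.items()},
        normality_p=normality_p,
        variance_homogeneity_p=bartlett_p,
        assumptions_met=assumptions_met,
        assumption_alpha=assumption_alpha,
        omnibus_test=omnibus,
        omnibus_p=p,
        alpha_gate=alpha_gate,
        pairwise=pairwise,
        decision_path=path,
    )
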