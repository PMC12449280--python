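"""Paired nonparametric statistics for preprocessing-variant comparisons.

The analysis layer mirrors common practice in segmentation studies:
Shapiro-Wilk normality assessment (reported descriptively), two-sided
Wilcoxon signed-rank tests between preprocessing variants on paired
per-case DSC values, Spearman rank correlation between lesion volume
and DSC, and Benjamini-Hochberg (step-up FDR) adjustment of all
p-values emitted in one report.

scipy.stats provides the test engines; statsmodels provides the BH
step-up.  The wrappers pin down the conventions used throughout the
package: zero differences are dropped before ranking, the exact null
distribution is used for n <= 25 pairs (after dropping zeros) and a
normal approximation with continuity correction above, and a fully
degenerate comparison (all differences zero) is reported as p = 1 with
a flag rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedComparison",
    "CorrelationResult",
    "shapiro_wilk",
    "wilcoxon_signed_rank",
    "spearman",
    "bh_adjust",
    "compare_variants",
]

EXACT_WILCOXON_MAX_N = 25


@dataclass
class PairedComparison:
    """One row of a pairwise variant-comparison report."""

    label: str
    sequence: str
    n_pairs: int
    statistic: float
    p_raw: float
    p_adjusted: float = float("nan")
    normality_p: float = float("nan")
    degenerate: bool = False


@dataclass
class CorrelationResult:
    """Spearman rank correlation with its two-sided p-value."""

    rho: float
    p: float
    n: int
    degenerate: bool = False


def shapiro_wilk(x: Sequence[float]) -> float:
    """Shapiro-Wilk normality p-value (descriptive use only).

    A constant sample has no defined test statistic; it is reported as
    non-normal with p = 0.0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got {x.size}")
    if x.size > 5000:
        raise ValueError(f"Shapiro-Wilk supports n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        return 0.0
    return float(sps.shapiro(x).pvalue)


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking.  With n <= 25 non-zero
    differences the exact null distribution is used; above that, the
    normal approximation with continuity correction.  Returns
    ``(statistic, p, degenerate)`` where ``degenerate`` marks the
    all-differences-zero case (reported as p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("paired samples must be equal-length 1-D arrays with n >= 1")
    diff = a - b
    nz = diff[diff != 0]
    if nz.size == 0:
        return float("nan"), 1.0, True
    method = "exact" if nz.size <= EXACT_WILCOXON_MAX_N else "approx"
    res = sps.wilcoxon(nz, method=method, correction=True, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), False


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties, two-sided p).

    A constant sample leaves the correlation undefined; the result is
    flagged degenerate with rho = NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("spearman needs two equal-length 1-D samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(rho=float("nan"), p=float("nan"), n=int(x.size),
                                 degenerate=True)
    res = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), p=float(res.pvalue), n=int(x.size))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adjusted_(i) = min over j >= i of (m * p_(j) / j) over the ascending
    order statistics, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _comparison_units(frame: pd.DataFrame, level: str, tumor_class: str) -> pd.DataFrame:
    """Per (case, sequence, variant) comparison unit: class-mean or tumor DSC."""
    defined = frame.dropna(subset=["dsc"])
    if level == "mean_per_case":
        units = (defined.groupby(["case_id", "sequence", "variant"])["dsc"]
                 .mean().reset_index())
    elif level == "tumor":
        units = defined[defined["class_name"] == tumor_class][
            ["case_id", "sequence", "variant", "dsc"]].copy()
    else:
        raise ValueError(f"level must be 'mean_per_case' or 'tumor', got {level!r}")
    return units


def compare_variants(
    table,
    pairs: Sequence[tuple[str, str]],
    *,
    level: str = "mean_per_case",
    tumor_class: str = "tumor",
    sequences: Sequence[str] | None = None,
) -> list[PairedComparison]:
    """Paired Wilcoxon tests between preprocessing variants, BH-adjusted.

    For every requested ``(variant_a, variant_b)`` pair and every
    sequence, the per-case comparison unit (mean DSC across classes, or
    the tumor-class DSC) is formed and a two-sided Wilcoxon signed-rank
    test run on the paired values.  All comparisons emitted in one call
    form a single BH family.  Shapiro-Wilk p on the paired differences
    is attached descriptively.
    """
    frame = table.to_frame() if hasattr(table, "to_frame") else table
    units = _comparison_units(frame, level, tumor_class)
    if sequences is None:
        sequences = sorted(units["sequence"].unique())
    comparisons: list[PairedComparison] = []
    for sequence in sequences:
        sub = units[units["sequence"] == sequence]
        by_variant = {v: g.set_index("case_id")["dsc"] for v, g in sub.groupby("variant")}
        for va, vb in pairs:
            if va not in by_variant or vb not in by_variant:
                continue
            sa, sb = by_variant[va], by_variant[vb]
            common = sorted(set(sa.index) & set(sb.index))
            missing = sorted(set(sa.index) ^ set(sb.index))
            if missing:
                raise ValueError(
                    f"unmatched cases for {va} vs {vb} ({sequence}): {missing}"
                )
            if not common:
                continue
            a = sa.loc[common].to_numpy()
            b = sb.loc[common].to_numpy()
            stat, p, degenerate = wilcoxon_signed_rank(a, b)
            norm_p = shapiro_wilk(a - b) if len(common) >= 3 and np.ptp(a - b) > 0 else float("nan")
            comparisons.append(PairedComparison(
                label=f"{va} vs {vb}", sequence=sequence, n_pairs=len(common),
                statistic=stat, p_raw=p, normality_p=norm_p, degenerate=degenerate,
            ))
    if comparisons:
        adjusted = bh_adjust([c.p_raw for c in comparisons])
        for c, adj in zip(comparisons, adjusted):
            c.p_adjusted = float(adj)
    return comparisons


def comparisons_frame(comparisons: Sequence[PairedComparison]) -> pd.DataFrame:
    """Tabular (CSV-ready) view of a comparison report."""
    return pd.DataFrame([asdict(c) for c in comparisons])
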