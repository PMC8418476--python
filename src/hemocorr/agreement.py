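"""Bland-Altman agreement between corrected and baseline NSE.

Agreement is summarized on the percent scale: for each pair the difference
``corrected - baseline`` is expressed as a percentage of the pair mean
(classical Bland-Altman ratio plot) or of the baseline value.  The 95%
limits of agreement are ``mean ± 1.96·SD`` of those percent differences, and
a correction is acceptable when both limits lie inside a total allowable
bias band (±20% here, derived from the assay's intermediate precision).
Independence of the differences from the degree of hemolysis is checked by
Spearman rank correlation against HI.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "AgreementResult",
    "bland_altman_percent",
    "loa_from_moments",
    "diff_vs_hi_independence",
    "acceptability",
    "compare_group_locations",
    "compare_paired_locations",
    "plot_bland_altman",
]

Z_95 = 1.96  # conventional multiplier for 95% limits of agreement


@dataclass(frozen=True)
class AgreementResult:
    """Percent-difference Bland-Altman summary.

    ``loa_lower_pct`` / ``loa_upper_pct`` are ``mean ± z·SD``; Spearman
    fields are populated by :func:`diff_vs_hi_independence`.
    """

    mean_diff_pct: float
    sd_diff_pct: float
    loa_lower_pct: float
    loa_upper_pct: float
    n_pairs: int
    denominator: str = "mean"
    spearman_r_vs_hi: Optional[float] = None
    spearman_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("agreement needs >= 2 pairs")


def percent_differences(
    baseline: Sequence[float],
    corrected: Sequence[float],
    denominator: Literal["mean", "baseline"] = "mean",
) -> np.ndarray:
    """Per-pair percent difference ``100·(corrected − baseline)/denominator``."""
    b = np.asarray(baseline, dtype=float)
    c = np.asarray(corrected, dtype=float)
    if b.shape != c.shape or b.ndim != 1:
        raise ValueError("baseline and corrected must be 1-d arrays of equal length")
    if denominator == "mean":
        denom = (b + c) / 2.0
    elif denominator == "baseline":
        denom = b
    else:
        raise ValueError(f"denominator must be 'mean' or 'baseline', got {denominator!r}")
    if np.any(denom == 0):
        raise ZeroDivisionError("zero denominator in percent difference")
    return 100.0 * (c - b) / denom


def bland_altman_percent(
    baseline: Sequence[float],
    corrected: Sequence[float],
    denominator: Literal["mean", "baseline"] = "mean",
    z: float = Z_95,
) -> AgreementResult:
    """Bland-Altman summary of corrected vs baseline on the percent scale.

    Uses the sample (n−1) standard deviation; limits of agreement are
    ``mean ± z·SD``.
    """
    b = np.asarray(baseline, dtype=float)
    c = np.asarray(corrected, dtype=float)
    if b.size < 2:
        raise ValueError("agreement needs >= 2 pairs")
    if np.any(b <= 0) or np.any(c <= 0):
        raise ValueError("all values must be positive for percent differences")
    d = percent_differences(b, c, denominator)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = loa_from_moments(mean, sd, z)
    return AgreementResult(
        mean_diff_pct=mean,
        sd_diff_pct=sd,
        loa_lower_pct=lo,
        loa_upper_pct=hi,
        n_pairs=int(b.size),
        denominator=denominator,
    )


def loa_from_moments(mean_pct: float, sd_pct: float, z: float = Z_95) -> Tuple[float, float]:
    """Limits of agreement ``(mean − z·SD, mean + z·SD)`` from summary moments."""
    if sd_pct < 0:
        raise ValueError("sd must be >= 0")
    return mean_pct - z * sd_pct, mean_pct + z * sd_pct


def diff_vs_hi_independence(
    diff_pct: Sequence[float], hi: Sequence[float]
) -> Tuple[float, float]:
    """Spearman rank correlation of percent differences against HI.

    A correction that fully removes the hemolysis effect leaves differences
    uncorrelated with the degree of hemolysis (rho near 0, large p).
    """
    d = np.asarray(diff_pct, dtype=float)
    h = np.asarray(hi, dtype=float)
    if d.shape != h.shape or d.size < 3:
        raise ValueError("need >= 3 equal-length observations")
    if np.ptp(d) == 0 or np.ptp(h) == 0:
        raise ValueError("constant input vector; rank correlation undefined")
    res = stats.spearmanr(d, h)
    return float(res.statistic), float(res.pvalue)


def with_independence(
    result: AgreementResult,
    diff_pct: Sequence[float],
    hi: Sequence[float],
) -> AgreementResult:
    """Return a copy of ``result`` with the Spearman fields filled in."""
    rho, p = diff_vs_hi_independence(diff_pct, hi)
    return replace(result, spearman_r_vs_hi=rho, spearman_p=p)


def acceptability(result: AgreementResult, bias_limit: float = 20.0) -> bool:
    """True iff both limits of agreement lie within ±``bias_limit`` percent.

    Boundary inclusive: limits exactly at ±bias_limit pass.
    """
    if bias_limit <= 0:
        raise ValueError("bias_limit must be positive")
    return result.loa_lower_pct >= -bias_limit and result.loa_upper_pct <= bias_limit


def compare_group_locations(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two groups' locations.

    Returns ``(U, p)``; used to check that hemolyzed specimens sit higher
    than baselines while corrected values do not differ from them.
    """
    res = stats.mannwhitneyu(np.asarray(a, float), np.asarray(b, float),
                             alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def compare_paired_locations(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon signed-rank comparison of paired measurements.

    The self-control validation design measures the same specimen before and
    after hemolysis, so the paired signed-rank test is the appropriate (and
    far more powerful) location comparison; :func:`compare_group_locations`
    remains for unpaired groups.
    """
    res = stats.wilcoxon(np.asarray(a, float), np.asarray(b, float),
                         alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def plot_bland_altman(
    baseline: Sequence[float],
    corrected: Sequence[float],
    denominator: Literal["mean", "baseline"] = "mean",
    ax=None,
):
    """Percent-difference Bland-Altman plot (requires matplotlib)."""
    import matplotlib.pyplot as plt

    b = np.asarray(baseline, float)
    c = np.asarray(corrected, float)
    res = bland_altman_percent(b, c, denominator)
    d = percent_differences(b, c, denominator)
    avg = (b + c) / 2.0
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(avg, d, s=14, alpha=0.7)
    for y, style in ((res.mean_diff_pct, "-"), (res.loa_lower_pct, "--"),
                     (res.loa_upper_pct, "--")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel("pair average NSE (μg/L)")
    ax.set_ylabel(f"difference (% of {denominator})")
    return ax
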