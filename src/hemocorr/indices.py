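"""Hemolysis-index (HI) quantification, reference intervals and specimen classification.

The hemolysis index is a semi-quantitative measure of cell-free hemoglobin in
serum, computed on clinical chemistry analyzers from the bichromatic absorbance
difference at 570 nm and 600 nm (the oxyhemoglobin band minus a turbidity
reference).  One HI unit corresponds to 10 mg/L free hemoglobin, and
instruments report HI as an integer in the range 1-1000.

This module covers the pre-analytical quality side of the pipeline:

* :func:`compute_hi` - absorbance pair to integer HI,
* :func:`hb_from_hi` - HI to free-hemoglobin concentration,
* :func:`estimate_reference_interval` - nonparametric (CLSI-style) reference
  intervals via rank interpolation,
* :func:`classify_specimen` - hemolyzed / not-hemolyzed flag at a cutoff,
* :func:`visual_miss_fraction` - how often visual inspection misses
  HI-positive specimens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    BelowQuantificationError,
    InvalidSpectrumError,
    ValidationError,
)

__all__ = [
    "AbsorbancePair",
    "HemolysisIndex",
    "ReferenceInterval",
    "DEFAULT_HI_CALIBRATION_K",
    "DEFAULT_HI_CUTOFF",
    "HI_RANGE_MAX",
    "HB_MG_PER_L_PER_HI",
    "compute_hi",
    "hb_from_hi",
    "estimate_reference_interval",
    "classify_specimen",
    "visual_miss_fraction",
    "read_hi_table",
]

#: mg/L free hemoglobin represented by one HI unit.
HB_MG_PER_L_PER_HI = 10.0

#: Upper end of the instrument's reportable HI range.
HI_RANGE_MAX = 1000

#: Hemolyzed / not-hemolyzed cutoff: the upper limit of the HI reference
#: interval in healthy serum.  "Abnormal" is strictly above this value.
DEFAULT_HI_CUTOFF = 5

#: Default absorbance-difference -> HI conversion factor (HI units per AU).
#: The optical calibration of commercial serum-index kits is proprietary; the
#: default is chosen so that absorbances synthesized from a target
#: free-hemoglobin concentration round-trip through compute_hi / hb_from_hi
#: (Hb of 10 mg/L, i.e. HI 1, maps to an absorbance difference of 0.01 AU).
DEFAULT_HI_CALIBRATION_K = 100.0


@dataclass(frozen=True)
class AbsorbancePair:
    """Paired serum absorbance readings, in absorbance units (AU).

    Parameters
    ----------
    a570 : float
        Absorbance at 570 nm (oxyhemoglobin peak shoulder).
    a600 : float
        Absorbance at 600 nm (reference wavelength).
    """

    a570: float
    a600: float

    def __post_init__(self) -> None:
        for name in ("a570", "a600"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")

    @property
    def difference(self) -> float:
        """Bichromatic difference A570 - A600 (AU)."""
        return self.a570 - self.a600


@dataclass(frozen=True)
class HemolysisIndex:
    """Integer hemolysis index as reported by the instrument.

    ``value`` is dimensionless; one unit corresponds to 10 mg/L free
    hemoglobin.  Readings below the quantification range (HI < 1) are stored
    as 0 with ``censored_low`` set.
    """

    value: int
    censored_low: bool = False

    def __post_init__(self) -> None:
        if self.censored_low:
            if self.value != 0:
                raise ValueError("censored_low readings are stored as value 0")
        elif not 1 <= self.value <= HI_RANGE_MAX:
            raise ValueError(
                f"HI value {self.value} outside instrument range [1, {HI_RANGE_MAX}]"
            )


@dataclass(frozen=True)
class ReferenceInterval:
    """A nonparametric reference interval.

    Attributes
    ----------
    lower, upper : float
        Interval bounds in analyte units.
    percentile_spec : str
        Human-readable coverage description, e.g. ``"one-sided 95%"``.
    n : int
        Number of reference subjects used.
    method : str
        Rank-estimator descriptor.
    """

    lower: float
    upper: float
    percentile_spec: str
    n: int
    method: str = "rank r = p*(n+1), linear interpolation"

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _round_half_away(x: float) -> int:
    """Round half away from zero (reproducible integer HI reporting)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def compute_hi(
    pair: AbsorbancePair,
    k: float = DEFAULT_HI_CALIBRATION_K,
    *,
    epsilon: float = 0.005,
    range_max: int = HI_RANGE_MAX,
) -> HemolysisIndex:
    """Convert an absorbance pair to an integer hemolysis index.

    HI = round(k * (A570 - A600)), clamped to the instrument range
    [1, ``range_max``]; values below 1 are reported as below-range
    (``censored_low``).

    Parameters
    ----------
    pair : AbsorbancePair
        Serum absorbance readings.
    k : float
        Calibration factor (HI units per AU), ``k > 0``.
    epsilon : float
        Tolerated negative absorbance difference (AU) before the spectrum is
        considered invalid; small negative differences from photometric noise
        are clipped to zero.
    range_max : int
        Upper clamp of the reportable range.

    Raises
    ------
    InvalidSpectrumError
        If A600 exceeds A570 by more than ``epsilon``.
    """
    if k <= 0:
        raise ValueError(f"calibration factor k must be positive, got {k!r}")
    diff = pair.difference
    if diff < -epsilon:
        raise InvalidSpectrumError(
            f"A600 exceeds A570 by {-diff:.4f} AU (> epsilon {epsilon}); "
            "not a hemoglobin-like spectrum"
        )
    value = _round_half_away(k * max(diff, 0.0))
    if value < 1:
        return HemolysisIndex(0, censored_low=True)
    return HemolysisIndex(min(value, range_max))


def hb_from_hi(hi: HemolysisIndex) -> float:
    """Free-hemoglobin concentration (mg/L) equivalent to an HI reading.

    Exactly ``10 * value`` by the instrument convention 1 HI = 10 mg/L Hb.

    Raises
    ------
    BelowQuantificationError
        For below-range (censored) readings, which carry no quantitative
        hemoglobin equivalent.
    """
    if hi.censored_low:
        raise BelowQuantificationError(
            "HI below quantification range; no hemoglobin equivalent"
        )
    return HB_MG_PER_L_PER_HI * hi.value


def _rank_percentile(sorted_values: np.ndarray, p: float) -> float:
    # CLSI-style nonparametric estimate: rank r = p*(n+1), linear
    # interpolation between order statistics, clamped to [1, n].
    n = sorted_values.size
    r = p * (n + 1)
    r = min(max(r, 1.0), float(n))
    lo = int(math.floor(r))
    hi = min(lo + 1, n)
    frac = r - lo
    return float(sorted_values[lo - 1] * (1 - frac) + sorted_values[hi - 1] * frac)


def estimate_reference_interval(
    values: Sequence[float],
    coverage: float = 0.95,
    sided: Literal["one", "two"] = "two",
) -> ReferenceInterval:
    """Nonparametric reference interval by rank interpolation.

    Follows the CLSI-recommended nonparametric approach: order statistics with
    rank ``r = p * (n + 1)`` and linear interpolation.  For ``sided="one"``
    the interval is ``[0, upper percentile]`` - appropriate for analytes such
    as the hemolysis index where only an upper limit is clinically meaningful.
    For ``sided="two"`` the central ``coverage`` fraction is returned.

    Parameters
    ----------
    values : sequence of float
        Reference-population measurements; ``n >= 20`` required (CLSI
        recommends at least 120; smaller n is allowed but imprecise).
    coverage : float
        Coverage fraction in (0, 1); 0.95 gives the conventional 95% interval.
    sided : {"one", "two"}
        One-sided upper limit or central two-sided interval.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot estimate a reference interval from no data")
    if not np.all(np.isfinite(arr)):
        raise ValueError("reference values must be finite")
    if not 0 < coverage < 1:
        raise ValueError(f"coverage must lie in (0, 1), got {coverage!r}")
    if arr.size < 20:
        raise ValueError(
            f"n={arr.size} is too small for a nonparametric reference interval "
            "(need >= 20)"
        )
    arr.sort()
    n = int(arr.size)
    if sided == "one":
        upper = _rank_percentile(arr, coverage)
        return ReferenceInterval(
            lower=0.0,
            upper=upper,
            percentile_spec=f"one-sided {coverage:.0%} upper limit",
            n=n,
        )
    if sided == "two":
        alpha = (1.0 - coverage) / 2.0
        lower = _rank_percentile(arr, alpha)
        upper = _rank_percentile(arr, 1.0 - alpha)
        return ReferenceInterval(
            lower=lower,
            upper=upper,
            percentile_spec=f"central {coverage:.0%}",
            n=n,
        )
    raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")


def classify_specimen(hi: HemolysisIndex, cutoff: float = DEFAULT_HI_CUTOFF) -> bool:
    """True iff the specimen counts as hemolyzed: HI strictly above ``cutoff``.

    The boundary is excluded: a specimen at exactly the reference upper limit
    is still within the reference interval.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    return hi.value > cutoff


def visual_miss_fraction(
    visual_flags: Sequence[bool], hi_flags: Sequence[bool]
) -> float:
    """Fraction of HI-positive specimens not flagged by visual inspection.

    Parameters
    ----------
    visual_flags : sequence of bool
        True where a technician judged the specimen hemolyzed by eye.
    hi_flags : sequence of bool
        True where the HI test flags the specimen (must contain >= 1 True).
    """
    if len(visual_flags) != len(hi_flags):
        raise ValueError(
            f"length mismatch: {len(visual_flags)} visual vs {len(hi_flags)} HI flags"
        )
    vis = np.asarray(visual_flags, dtype=bool)
    hif = np.asarray(hi_flags, dtype=bool)
    n_pos = int(hif.sum())
    if n_pos == 0:
        raise ValueError("no HI-positive specimens; miss fraction undefined")
    missed = int((hif & ~vis).sum())
    return missed / n_pos


_ABS_COLUMNS = ["specimen_id", "a570", "a600"]
_HI_COLUMNS = ["specimen_id", "hi"]


def read_hi_table(path, k: float = DEFAULT_HI_CALIBRATION_K) -> pd.DataFrame:
    """Read a specimen HI table from CSV.

    Accepts either ``specimen_id,a570,a600`` (absorbances are converted with
    :func:`compute_hi`) or ``specimen_id,hi`` (pre-computed indices).  Returns
    a DataFrame with columns ``specimen_id, hi, censored_low``.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str})
    cols = list(df.columns)
    if cols == _ABS_COLUMNS:
        his = [
            compute_hi(AbsorbancePair(float(r.a570), float(r.a600)), k=k)
            for r in df.itertuples()
        ]
    elif cols == _HI_COLUMNS:
        his = []
        for raw in df["hi"]:
            v = int(raw)
            his.append(
                HemolysisIndex(0, censored_low=True) if v < 1 else HemolysisIndex(v)
            )
    else:
        raise ValidationError(
            f"unexpected header {cols}; expected {_ABS_COLUMNS} or {_HI_COLUMNS}"
        )
    return pd.DataFrame(
        {
            "specimen_id": df["specimen_id"],
            "hi": [h.value for h in his],
            "censored_low": [h.censored_low for h in his],
        }
    )
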