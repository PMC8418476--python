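"""Synthetic cohorts: healthy controls, the RBC-lysate spiking experiment, and
an intentional-hemolysis validation cohort.

The study design being emulated deposits no data, so every downstream module
is exercised on synthetic specimens with known ground truth:

* :func:`make_healthy_cohort` - healthy-control HI and NSE distributions used
  to establish reference intervals (HI median 2, 95th percentile 5; NSE
  median 8.5 μg/L, 95th percentile 11.8 μg/L).
* :func:`simulate_spiking_experiment` - the 23-pool x 11-aliquot spike-recovery
  design: serial halving dilutions of a red-cell lysate added to serum pools
  at a 1:10 volume ratio, from which the increment line is re-derived.
* :func:`make_validation_cohort` - paired baseline / intentionally-hemolyzed
  specimens with patient-specific NSE/HI ratios, for Bland-Altman validation
  of the correction.

Every generator is deterministic given a seed, and with all noise CVs set to
zero the observed fields equal the hidden truth fields exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .correction import NSE_ASSAY_CEILING, NSE_ASSAY_FLOOR, RbcRatio
from .exceptions import AssayRangeError

__all__ = [
    "SpikingDesign",
    "NoiseModel",
    "SyntheticCohort",
    "make_lysate_series",
    "simulate_spiking_experiment",
    "make_validation_cohort",
    "make_healthy_cohort",
    "default_pool_baselines",
]

#: Canonical cohort CSV column order.
COHORT_COLUMNS = [
    "record_id",
    "patient_id",
    "role",
    "nse_meas",
    "hi_meas",
    "true_nse",
    "true_hi",
    "true_r",
]


def make_lysate_series(start_hi: float, n_levels: int) -> list[float]:
    """Serial halving dilution series of lysate HI concentrations.

    Each level is half the previous, rounded to 2 decimals, e.g.
    ``make_lysate_series(6000, 10)`` -> 6000, 3000, ..., 11.72.
    """
    if start_hi <= 0:
        raise ValueError("start_hi must be positive")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    return [round(start_hi / 2**i, 2) for i in range(n_levels)]


@dataclass(frozen=True)
class SpikingDesign:
    """Layout of the in-silico spike-recovery experiment.

    23 serum pools x 11 aliquots each: 10 aliquots receive serial halving
    dilutions of a red-cell lysate at ``spike_ratio`` (1 volume lysate to 10
    volumes serum), the 11th receives saline and serves as the pool's
    baseline.  Three low-NSE pools use the alternate, slightly lower series.
    """

    n_pools: int = 23
    aliquots_per_pool: int = 11
    lysate_hi_series: Tuple[float, ...] = tuple(make_lysate_series(6000, 10))
    alt_lysate_hi_series: Tuple[float, ...] = tuple(make_lysate_series(5000, 10))
    n_alt_pools: int = 3
    spike_ratio: Tuple[int, int] = (1, 10)  # lysate : serum volumes
    donor_r: RbcRatio = field(default_factory=lambda: RbcRatio(0.31))
    baseline_hi: float = 2.0  # healthy-median serum HI of the pools

    def __post_init__(self) -> None:
        for series in (self.lysate_hi_series, self.alt_lysate_hi_series):
            arr = np.asarray(series)
            if not np.all(np.diff(arr) < 0):
                raise ValueError("lysate HI series must be strictly decreasing")
            # halving within rounding slack
            if not np.allclose(arr[1:], arr[:-1] / 2, rtol=0.01):
                raise ValueError("lysate HI series must halve at each step")
        if self.aliquots_per_pool != len(self.lysate_hi_series) + 1:
            raise ValueError("aliquots_per_pool must equal len(series) + 1")
        if self.n_alt_pools > self.n_pools:
            raise ValueError("n_alt_pools cannot exceed n_pools")

    @property
    def spike_fraction(self) -> float:
        """Volume fraction contributed by the lysate (1/11 for 1:10)."""
        a, b = self.spike_ratio
        return a / (a + b)

    @property
    def serum_fraction(self) -> float:
        a, b = self.spike_ratio
        return b / (a + b)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise, CV-parameterized.

    ``hi_cv_repeat`` / ``nse_cv_repeat`` apply within a single run (paired
    same-day designs); ``hi_cv_intermediate`` / ``nse_cv`` are the across-day
    (intermediate-precision) figures.  All noise factors have mean 1, so zero
    CV reproduces the truth exactly.
    """

    hi_cv_repeat: float = 0.02
    hi_cv_intermediate: float = 0.05
    nse_cv: float = 0.10  # intermediate precision bound of the NSE assay
    nse_cv_repeat: float = 0.02  # within-run repeatability (ECLIA-class)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hi_cv_repeat", "hi_cv_intermediate", "nse_cv", "nse_cv_repeat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def zero(cls, seed: int = 0) -> "NoiseModel":
        """Noise-free model (all CVs 0); observations equal truth."""
        return cls(0.0, 0.0, 0.0, 0.0, seed)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noise_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 lognormal multipliers with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass
class SyntheticCohort:
    """A generated cohort: observed measurements plus hidden truth columns."""

    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SyntheticCohort":
        return cls(pd.read_csv(path, dtype={"record_id": str, "patient_id": str}))

    def paired(self) -> pd.DataFrame:
        """Wide per-patient view of a baseline/hemolyzed paired cohort.

        Columns: ``patient_id, baseline_nse, hemolyzed_nse, hemolyzed_hi,
        true_r``.  Only defined for cohorts holding exactly one baseline and
        one hemolyzed record per patient.
        """
        base = self.frame[self.frame["role"] == "baseline"].set_index("patient_id")
        hem = self.frame[self.frame["role"] == "hemolyzed"].set_index("patient_id")
        if len(base) != len(hem) or not base.index.equals(hem.index):
            raise ValueError("cohort is not a clean baseline/hemolyzed pairing")
        return pd.DataFrame(
            {
                "patient_id": base.index,
                "baseline_nse": base["nse_meas"].to_numpy(),
                "hemolyzed_nse": hem["nse_meas"].to_numpy(),
                "hemolyzed_hi": hem["hi_meas"].to_numpy(),
                "true_r": hem["true_r"].to_numpy(),
            }
        )


def default_pool_baselines(
    n_pools: int = 23,
    low: float = 8.4,
    high: float = 370.0,
) -> np.ndarray:
    """Baseline NSE concentrations of the serum pools, low to high.

    The study's actual pool values are unpublished; defaults span the spiked
    range log-uniformly (deterministic log-spacing, not draws) so that low
    and high NSE pools are equally represented.
    """
    return np.geomspace(low, high, n_pools)


def simulate_spiking_experiment(
    design: SpikingDesign | None = None,
    pool_baseline_nse: Optional[Sequence[float]] = None,
    noise: NoiseModel | None = None,
) -> SyntheticCohort:
    """Run the in-silico spike-recovery experiment.

    For each pool, the saline aliquot keeps the pool's serum diluted by the
    spiking ratio; each spiked aliquot mixes lysate and serum at that ratio:

    * ``HI_true  = lysate_hi * spike_fraction + baseline_hi``
    * ``NSE_true = baseline_nse * serum_fraction + donor_r * lysate_hi * spike_fraction``

    (the lysate's NSE content is its HI times the donor's NSE/HI ratio).
    Observations multiply truth by lognormal noise; HI is then rounded to the
    integer granularity instruments report.  All 253 = 23 x 11 aliquots are
    measured within one day, so within-run repeatability CVs apply to both
    analytes; cross-day simulations would use the intermediate CVs instead.
    """
    design = design or SpikingDesign()
    noise = noise or NoiseModel()
    if pool_baseline_nse is None:
        pool_baseline_nse = default_pool_baselines(design.n_pools)
    base = np.asarray(pool_baseline_nse, dtype=float)
    if base.size != design.n_pools:
        raise ValueError(
            f"need {design.n_pools} pool baselines, got {base.size}"
        )
    if np.any(base < NSE_ASSAY_FLOOR) or np.any(base > NSE_ASSAY_CEILING):
        raise AssayRangeError(
            "pool baseline NSE outside assay measurable range "
            f"[{NSE_ASSAY_FLOOR}, {NSE_ASSAY_CEILING}] μg/L"
        )
    rng = noise.rng()

    # the lowest-NSE pools use the alternate series (indices in sorted order)
    order = np.argsort(base)
    alt_pools = set(order[: design.n_alt_pools].tolist())

    rows = []
    for p in range(design.n_pools):
        series = (
            design.alt_lysate_hi_series if p in alt_pools else design.lysate_hi_series
        )
        pool_id = f"pool{p + 1:02d}"
        # aliquot 0: saline baseline
        lysate_levels = [0.0] + list(series)
        for a, lys in enumerate(lysate_levels):
            hi_true = lys * design.spike_fraction + design.baseline_hi
            nse_true = (
                base[p] * design.serum_fraction
                + design.donor_r.r * lys * design.spike_fraction
            )
            rows.append(
                {
                    "record_id": f"{pool_id}-a{a:02d}",
                    "patient_id": pool_id,
                    "role": "baseline" if a == 0 else "spiked",
                    "true_nse": nse_true,
                    "true_hi": hi_true,
                    "true_r": design.donor_r.r,
                }
            )
    df = pd.DataFrame(rows)
    n = len(df)
    hi_obs = df["true_hi"].to_numpy() * _noise_factors(rng, noise.hi_cv_repeat, n)
    nse_obs = df["true_nse"].to_numpy() * _noise_factors(rng, noise.nse_cv_repeat, n)
    df["hi_meas"] = np.maximum(np.floor(hi_obs + 0.5), 0).astype(int)
    df["nse_meas"] = nse_obs
    return SyntheticCohort(df[COHORT_COLUMNS].copy())


def make_validation_cohort(
    n: int = 47,
    r_range: Tuple[float, float] = (0.091, 0.467),
    hi_range: Tuple[float, float] = (6.0, 314.0),
    baseline_nse_range: Tuple[float, float] = (6.94, 366.1),
    noise: NoiseModel | None = None,
    offset_range: Tuple[float, float] = (0.0, 2.0),
    r_loc: float = 0.31,
    r_scale: float = 0.05,
) -> SyntheticCohort:
    """Paired baseline / intentionally-hemolyzed specimens.

    Each pseudo-patient carries a personal NSE/HI ratio R (clipped normal
    around 0.31, reflecting the tight interquartile spread of observed
    patient ratios) and is measured twice in the same run: once pristine,
    once after in-vitro hemolysis that raises HI to a lognormal draw clipped
    to ``hi_range``.  The hemolyzed truth is

        ``NSE_hemolyzed = NSE_baseline + R * ΔHI + offset * R``

    where the small uniform ``offset`` (μg/L per unit R) emulates the
    positive intercept seen in spike-recovery data (release of NSE not fully
    indexed by hemoglobin).  Baseline NSE and hemolyzed HI are right-skewed
    lognormals calibrated to the quartiles observed in the validated patient
    group (baseline NSE quartiles ≈ 10/50/100 μg/L; hemolyzed HI quartiles
    ≈ 15/36/69), clipped to the stated ranges.  Both members of a pair are
    measured in the same run, so within-run repeatability CVs apply.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    noise = noise or NoiseModel()
    rng = noise.rng()

    # quartile-matched lognormal scales: sigma = ln(Q3/Q1) / (2 * 0.6745)
    nse_mu, nse_sigma = math.log(50.46), math.log(99.87 / 10.32) / (2 * 0.6745)
    hi_mu, hi_sigma = math.log(36.0), math.log(69.0 / 15.0) / (2 * 0.6745)

    r_true = np.clip(rng.normal(r_loc, r_scale, n), *r_range)
    base_nse = np.clip(rng.lognormal(nse_mu, nse_sigma, n), *baseline_nse_range)
    base_hi = np.minimum(np.floor(rng.lognormal(math.log(2), 0.557, n) + 0.5), 5.0)
    hem_hi = np.clip(rng.lognormal(hi_mu, hi_sigma, n), *hi_range)
    offset = rng.uniform(*offset_range, n)

    hem_nse = base_nse + r_true * (hem_hi - base_hi) + offset * r_true

    def observe(nse_true, hi_true):
        nse = nse_true * _noise_factors(rng, noise.nse_cv_repeat, n)
        hi = hi_true * _noise_factors(rng, noise.hi_cv_repeat, n)
        return nse, np.maximum(np.floor(hi + 0.5), 0).astype(int)

    b_nse_obs, b_hi_obs = observe(base_nse, base_hi)
    h_nse_obs, h_hi_obs = observe(hem_nse, hem_hi)

    rows = []
    for i in range(n):
        pid = f"pt{i + 1:03d}"
        rows.append(
            {
                "record_id": f"{pid}-base",
                "patient_id": pid,
                "role": "baseline",
                "nse_meas": b_nse_obs[i],
                "hi_meas": b_hi_obs[i],
                "true_nse": base_nse[i],
                "true_hi": base_hi[i],
                "true_r": r_true[i],
            }
        )
        rows.append(
            {
                "record_id": f"{pid}-hem",
                "patient_id": pid,
                "role": "hemolyzed",
                "nse_meas": h_nse_obs[i],
                "hi_meas": h_hi_obs[i],
                "true_nse": hem_nse[i],
                "true_hi": hem_hi[i],
                "true_r": r_true[i],
            }
        )
    return SyntheticCohort(pd.DataFrame(rows, columns=COHORT_COLUMNS))


def make_healthy_cohort(
    n: int = 200,
    hi_dist_params: Tuple[float, float] = (math.log(2.0), 0.557),
    nse_dist_params: Tuple[float, float] = (math.log(8.5), 0.199),
    seed: int = 0,
) -> SyntheticCohort:
    """Healthy-control cohort for reference-interval work.

    HI is a right-skewed lognormal (``(mu, sigma)`` on the log scale)
    discretized to the integer granularity of instrument reports; defaults
    put the median at 2 and the 95th percentile at 5.  NSE is lognormal with
    default median 8.5 μg/L and 95th percentile 11.8 μg/L.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    hi_mu, hi_sigma = hi_dist_params
    nse_mu, nse_sigma = nse_dist_params
    hi_true = rng.lognormal(hi_mu, hi_sigma, n)
    nse_true = rng.lognormal(nse_mu, nse_sigma, n)
    hi_obs = np.maximum(np.floor(hi_true + 0.5), 0).astype(int)
    rows = {
        "record_id": [f"hc{i + 1:03d}" for i in range(n)],
        "patient_id": [f"hc{i + 1:03d}" for i in range(n)],
        "role": "baseline",
        "nse_meas": nse_true,
        "hi_meas": hi_obs,
        "true_nse": nse_true,
        "true_hi": hi_true,
        "true_r": np.nan,
    }
    return SyntheticCohort(pd.DataFrame(rows, columns=COHORT_COLUMNS))
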