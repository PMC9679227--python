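"""Corrected somatic mutation rates per base pair per year.

The point estimate applies the false-positive and sensitivity corrections to
the mean per-sample mutation count over the diploid genome and the elapsed
propagation time:

    rate = mean_count * (1 - fp_rate) / (years * ploidy * genome_size * sensitivity)

Division is by the detection sensitivity (the fraction of spiked-in mutations
the pipeline recovers), which inflates the count for missed mutations.
Confidence intervals come from a nonparametric percentile bootstrap over the
per-sample counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._util import SomacloneError, substream


@dataclass
class RateInputs:
    mean_count: float
    years: float
    genome_size: float
    ploidy_factor: float = 2.0
    fp_rate: float = 0.0
    sensitivity: float = 1.0

    def validate(self) -> None:
        if self.years <= 0:
            raise SomacloneError("years must be positive")
        if not 0.0 <= self.fp_rate < 1.0:
            raise SomacloneError("fp_rate must lie in [0, 1)")
        if not 0.0 < self.sensitivity <= 1.0:
            raise SomacloneError("sensitivity must lie in (0, 1]")
        if self.genome_size <= 0 or self.ploidy_factor <= 0:
            raise SomacloneError("genome_size and ploidy_factor must be positive")


@dataclass
class RateEstimate:
    rate: float
    ci_low: float
    ci_high: float
    method: str

    def validate(self) -> None:
        if not self.ci_low <= self.rate <= self.ci_high:
            raise SomacloneError("confidence interval does not bracket the estimate")


def point_rate(
    mean_count: float,
    years: float,
    genome_size: float,
    ploidy_factor: float = 2.0,
    fp_rate: float = 0.0,
    sensitivity: float = 1.0,
) -> float:
    """Corrected per-bp-per-year mutation rate.

    >>> round(point_rate(312.5, 67, 4.08e8, fp_rate=0.032, sensitivity=0.596), 11)
    9.28e-09
    """
    inputs = RateInputs(mean_count, years, genome_size, ploidy_factor, fp_rate, sensitivity)
    inputs.validate()
    return (
        mean_count
        * (1.0 - fp_rate)
        / (years * ploidy_factor * genome_size * sensitivity)
    )


def bootstrap_ci(
    per_sample_counts,
    inputs: RateInputs,
    reps: int = 1000,
    seed: int = 0,
) -> RateEstimate:
    """Percentile bootstrap (2.5/97.5) over samples of the corrected rate."""
    counts = np.asarray(per_sample_counts, dtype=float)
    if counts.size < 2:
        raise SomacloneError("bootstrap requires at least 2 samples")
    if reps < 100:
        warnings.warn("bootstrap with reps < 100 yields unstable intervals")
    inputs.validate()
    rng = substream(seed, "bootstrap")

    def rate_of(mean_count: float) -> float:
        return (
            mean_count
            * (1.0 - inputs.fp_rate)
            / (inputs.years * inputs.ploidy_factor * inputs.genome_size * inputs.sensitivity)
        )

    draws = rng.integers(0, counts.size, size=(reps, counts.size))
    boot = np.array([rate_of(counts[row].mean()) for row in draws])
    point = rate_of(counts.mean())
    lo, hi = np.percentile(boot, [2.5, 97.5])
    est = RateEstimate(
        rate=point,
        ci_low=float(min(lo, point)),
        ci_high=float(max(hi, point)),
        method="percentile-bootstrap",
    )
    est.validate()
    return est


def rate_ratio(rate_a: float, rate_b: float) -> float:
    """Fold difference between two rates.

    >>> round(rate_ratio(9.24e-9, 1.99e-9), 2)
    4.64
    """
    if rate_b == 0:
        raise SomacloneError("denominator rate is zero")
    return rate_a / rate_b


def per_sample_counts(calls, samples) -> dict[str, int]:
    """Somatic calls carried by each sample (a shared call counts for every carrier)."""
    counts = {s: 0 for s in samples}
    if len(calls) == 0:
        return counts
    for carriers in calls["carriers"]:
        for s in str(carriers).split(","):
            if s in counts:
                counts[s] += 1
    return counts
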