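"""False-positive and false-negative calibration of the calling pipeline.

The false-positive rate comes from triplicate re-sequencing: variant sites
seen in all three replicates of a sample count as true, anything else in the
union counts as erroneously called, and the rate is the erroneous fraction of
the pooled candidate union. Sensitivity comes from spike-ins: synthetic point
substitutions dropped across the genome, counted callable when more than 3
covered reads support them, and counted detected when they additionally pass
the strand test. The reported ``sensitivity`` — detected callable spike-ins
over all spike-ins — is the figure historically labelled a "false-negative
rate" in mutation-accumulation studies; both names expose the same number.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import SomacloneError, substream
from .calling import strand_filter
from .model import ReferenceModel
from .simulate import SimConfig


@dataclass
class ErrorRates:
    """FP/FN calibration summary consumed by the rate estimator."""

    fp_rate: float | None = None
    n_candidates: int | None = None
    n_erroneous: int | None = None
    sensitivity: float | None = None
    n_spikein: int | None = None
    n_callable: int | None = None
    n_filtered_callable: int | None = None

    @property
    def false_negative_rate(self) -> float | None:
        """Alias: the published convention reports sensitivity under this name."""
        return self.sensitivity

    def validate(self) -> None:
        for name in ("fp_rate", "sensitivity"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise SomacloneError(f"{name} outside [0, 1]")
        if (
            self.n_erroneous is not None
            and self.n_candidates is not None
            and self.n_erroneous > self.n_candidates
        ):
            raise SomacloneError("n_erroneous exceeds n_candidates")

    def merged(self, other: "ErrorRates") -> "ErrorRates":
        data = asdict(self)
        for k, v in asdict(other).items():
            if v is not None:
                data[k] = v
        return ErrorRates(**data)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ErrorRates":
        with open(path) as fh:
            return cls(**json.load(fh))


def estimate_fp(
    replicate_calls: Mapping[str, Sequence[Iterable[str]]],
) -> tuple[ErrorRates, dict[str, dict[str, float]]]:
    """Triplicate-concordance false-positive rate.

    ``replicate_calls`` maps sample -> at least three call-site collections
    from independent re-sequencing runs. Per sample, candidates are the union
    and true calls the intersection across replicates; the pooled rate divides
    pooled non-concordant candidates by the pooled union. Invariant to
    replicate ordering.
    """
    per_sample: dict[str, dict[str, float]] = {}
    total_union = 0
    total_err = 0
    for sample, reps in replicate_calls.items():
        sets = [set(r) for r in reps]
        if len(sets) < 3:
            raise SomacloneError(
                f"sample {sample}: {len(sets)} replicate call sets; need at least 3"
            )
        union = set().union(*sets)
        inter = set.intersection(*sets)
        err = len(union) - len(inter)
        per_sample[sample] = {
            "n_candidates": len(union),
            "n_erroneous": err,
            "fp_rate": err / len(union) if union else 0.0,
        }
        total_union += len(union)
        total_err += err
    rates = ErrorRates(
        fp_rate=total_err / total_union if total_union else 0.0,
        n_candidates=total_union,
        n_erroneous=total_err,
    )
    rates.validate()
    return rates, per_sample


def spike_in_sensitivity(
    ref: ReferenceModel,
    config: SimConfig,
    n: int = 1000,
    zygosity: str = "hom",
    seed: int | None = None,
) -> ErrorRates:
    """Detection sensitivity from synthetic substitutions at the read level.

    ``n`` point substitutions are dropped uniformly over the accessible genome
    and given read support under the generator's depth/strand model (depth is
    position-independent under that model, so only the read draws matter). ``zygosity`` sets the simulated variant
    allele fraction: ``"hom"`` (1 - seq_error) mirrors the published protocol
    of homozygous derived spike-ins; ``"het"`` (0.5) matches the allele
    fraction of genuine clonal somatic mutations and is what the pipeline's
    own rate correction uses. A spike-in is callable when its covered-read
    count exceeds 3 and filtered when it then fails the two-strand bias test;
    sensitivity = (callable - filtered) / n.
    """
    if n < 100:
        warnings.warn("spike-in n < 100 gives an unstable sensitivity estimate")
    if zygosity not in ("hom", "het"):
        raise SomacloneError("zygosity must be 'hom' or 'het'")
    rng = substream(seed if seed is not None else config.seed, "spikein")

    vaf = 0.5 if zygosity == "het" else 1.0 - config.seq_error
    dp = rng.poisson(config.mean_depth, size=n)
    alt = rng.binomial(dp, vaf)
    p_strand = np.clip(rng.normal(0.5, config.strand_imbalance_sd, size=n), 0.05, 0.95)
    fwd = rng.binomial(alt, p_strand)
    rev = alt - fwd

    callable_mask = alt > 3
    filtered = np.array(
        [
            callable_mask[i] and not strand_filter((int(fwd[i]), int(rev[i])))
            for i in range(n)
        ]
    )
    n_callable = int(callable_mask.sum())
    n_filtered = int(filtered.sum())
    rates = ErrorRates(
        sensitivity=(n_callable - n_filtered) / n,
        n_spikein=n,
        n_callable=n_callable,
        n_filtered_callable=n_filtered,
    )
    rates.validate()
    return rates


def sensitivity_statistic(n_spikein: int, n_callable: int, n_filtered_callable: int) -> float:
    """(callable - filtered) / spiked, e.g. (604 - 8) / 1000 = 0.596."""
    if not 0 <= n_filtered_callable <= n_callable <= n_spikein:
        raise SomacloneError("require 0 <= filtered <= callable <= spiked")
    return (n_callable - n_filtered_callable) / n_spikein
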