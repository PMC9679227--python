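"""Consensus deleteriousness calls and outgroup allele-frequency selection classes.

A nonsynonymous mutation is deleterious by consensus when all three effect
predictors agree: SIFT <= 0.05, PROVEAN < -2.5 and PolyPhen > 0.5 (operators
exactly as printed by the predictors' conventions; any missing score makes the
call unscorable). Selection classes come from outgroup allele frequencies at
the mutated site: a derived allele already above 95% frequency in the
outgroup population marks positive selection, an ancestral allele above 95%
marks purifying selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import SomacloneError, percent


@dataclass
class EffectScores:
    sift: float | None = None
    provean: float | None = None
    polyphen: float | None = None

    def validate(self) -> None:
        if self.sift is not None and not (math.isnan(self.sift) or 0.0 <= self.sift <= 1.0):
            raise SomacloneError("SIFT score outside [0, 1]")
        if self.polyphen is not None and not (
            math.isnan(self.polyphen) or 0.0 <= self.polyphen <= 1.0
        ):
            raise SomacloneError("PolyPhen score outside [0, 1]")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def deleterious_consensus(scores: EffectScores) -> str:
    """'deleterious' iff sift <= 0.05 AND provean < -2.5 AND polyphen > 0.5.

    >>> deleterious_consensus(EffectScores(0.05, -2.6, 0.6))
    'deleterious'
    >>> deleterious_consensus(EffectScores(0.01, -2.5, 0.9))  # strict '<'
    'tolerated'
    """
    scores.validate()
    if _missing(scores.sift) or _missing(scores.provean) or _missing(scores.polyphen):
        return "unscorable"
    if scores.sift <= 0.05 and scores.provean < -2.5 and scores.polyphen > 0.5:
        return "deleterious"
    return "tolerated"


def score_table_consensus(scores: pd.DataFrame) -> pd.Series:
    """Vectorized consensus over a score table (columns sift/provean/polyphen)."""
    out = []
    for _, row in scores.iterrows():
        out.append(
            deleterious_consensus(
                EffectScores(
                    sift=row.get("sift"), provean=row.get("provean"), polyphen=row.get("polyphen")
                )
            )
        )
    return pd.Series(out, index=scores.index, name="consensus")


def deleterious_pattern_report(
    deleterious_calls: pd.DataFrame, total_somatic_snvs: int
) -> dict:
    """Sharing and zygosity pattern of the consensus-deleterious set.

    Reports per-sample counts, how many are shared by two or more samples,
    how many reached a homozygous carrier state, and the consensus fraction of
    all somatic SNVs as a percentage (two decimals, half away from zero).
    """
    per_sample: dict[str, int] = {}
    n_shared = 0
    n_hom = 0
    for _, row in deleterious_calls.iterrows():
        carriers = [s for s in str(row["carriers"]).split(",") if s]
        if len(carriers) >= 2:
            n_shared += 1
        if "carrier_gt" in row and row["carrier_gt"] == 2:
            n_hom += 1
        for s in carriers:
            per_sample[s] = per_sample.get(s, 0) + 1
    n = len(deleterious_calls)
    return {
        "n_deleterious": n,
        "per_sample": dict(sorted(per_sample.items())),
        "n_shared": n_shared,
        "n_homozygous": n_hom,
        "all_sample_specific": n_shared == 0,
        "all_heterozygous": n_hom == 0,
        "consensus_fraction_pct": percent(n, total_somatic_snvs, 2)
        if total_somatic_snvs
        else 0.0,
    }


@dataclass
class SelectionCall:
    pre_af: float
    post_af: float
    selection_class: str

    def validate(self) -> None:
        if self.pre_af + self.post_af > 1.0 + 1e-9:
            raise SomacloneError("pre- and post-mutation allele frequencies exceed 1")


def classify_selection(
    pre_af: float | None, post_af: float | None, af_threshold: float = 0.95
) -> SelectionCall:
    """Classify one mutation from outgroup pre/post-mutation allele frequencies.

    Strictly above ``af_threshold`` derived (post-mutation) frequency means
    the new allele is essentially fixed in the outgroup: positive selection.
    Strictly above-threshold ancestral (pre-mutation) frequency: purifying.
    Anything else (including a site absent from the outgroup) is unclassified.
    """
    if pre_af is None or post_af is None or np.isnan(pre_af) or np.isnan(post_af):
        return SelectionCall(np.nan, np.nan, "unclassified")
    call = SelectionCall(pre_af, post_af, "unclassified")
    call.validate()
    if post_af > af_threshold:
        call.selection_class = "positive"
    elif pre_af > af_threshold:
        call.selection_class = "purifying"
    return call


def outgroup_allele_frequency(genotype_codes: np.ndarray) -> float:
    """Alternate-allele frequency from diploid genotype codes (-1 missing)."""
    g = np.asarray(genotype_codes)
    valid = g >= 0
    if valid.sum() == 0:
        return float("nan")
    return float(g[valid].sum() / (2.0 * valid.sum()))


def derived_allele_burden(
    derived_calls: pd.DataFrame,
    n_samples: int,
    maf_min: float = 0.1,
    ingroup_af: pd.Series | None = None,
) -> dict:
    """Zygosity burden of derived mutations among the clonal samples.

    ``fixed`` means derived frequency 1 among the clone-mates. The minor-
    allele-frequency floor (ingroup frequencies by default) applies only
    here, not to the selection classification.
    """
    calls = derived_calls
    if ingroup_af is not None:
        maf = np.minimum(ingroup_af, 1.0 - ingroup_af)
        calls = calls[maf.to_numpy() >= maf_min]
    n = len(calls)
    if n == 0:
        return {"n": 0, "het_fraction": float("nan"), "fixed_fraction": float("nan")}
    het = int((calls["carrier_gt"] == 1).sum()) if "carrier_gt" in calls else 0
    fixed = int((calls["n_carriers"] == n_samples).sum()) if "n_carriers" in calls else 0
    return {"n": n, "het_fraction": het / n, "fixed_fraction": fixed / n}
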