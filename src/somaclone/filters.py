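"""Hard-filter cascade and site-level post-filters for the raw variant set.

SNPs are removed when ANY of the GATK-style predicates fires (OR semantics,
strict comparisons, matching the printed operators):

    FS > 60 | MQ < 40 | MQRankSum < -12.5 | QD < 2 | ReadPosRankSum < -8 | SOR > 3

and indels under ``QD < 2.0 | FS > 200.0 | ReadPosRankSum < -20.0``. A missing
annotation makes that one rule non-evaluable for the site (it cannot fire).

Post-filters then (i) mask genotypes with depth outside [mean/3, 3*mean] of
the per-sample mean, (ii) remove SNPs at or within 5 bp of an indel, (iii)
mask genotypes with GQ < 10 and (iv) remove sites whose genotype missingness,
computed after masking, exceeds 25%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SiteTable

logger = logging.getLogger(__name__)

# (INFO field, comparison, threshold); "gt" removes when value > thr, "lt" when <
SNP_HARD_RULES = [
    ("FS", "gt", 60.0),
    ("MQ", "lt", 40.0),
    ("MQRankSum", "lt", -12.5),
    ("QD", "lt", 2.0),
    ("ReadPosRankSum", "lt", -8.0),
    ("SOR", "gt", 3.0),
]
INDEL_HARD_RULES = [
    ("QD", "lt", 2.0),
    ("FS", "gt", 200.0),
    ("ReadPosRankSum", "lt", -20.0),
]


@dataclass
class FilterConfig:
    snp_hard: list = field(default_factory=lambda: list(SNP_HARD_RULES))
    indel_hard: list = field(default_factory=lambda: list(INDEL_HARD_RULES))
    depth_hi_mult: float = 3.0
    depth_lo_mult: float = 1.0 / 3.0
    indel_prox_bp: int = 5
    gq_min: int = 10
    site_missing_max: float = 0.25

    def validate(self) -> None:
        if not self.depth_lo_mult < self.depth_hi_mult:
            raise ValueError("depth_lo_mult must be below depth_hi_mult")


def _rule_fires(values: np.ndarray, op: str, threshold: float) -> np.ndarray:
    """Strict predicate; NaN (annotation absent / non-numeric) never fires."""
    with np.errstate(invalid="ignore"):
        if op == "gt":
            return values > threshold
        return values < threshold


def apply_hard_filters(
    sites: SiteTable, config: FilterConfig | None = None
) -> tuple[SiteTable, dict[str, int]]:
    """Remove sites failing any hard-filter predicate; report per-rule counts.

    Returns the retained table and a dict of how many sites each rule fired on
    (a site can fire several rules) plus ``removed``/``retained`` totals.
    """
    config = config or FilterConfig()
    config.validate()
    v = sites.variants
    is_indel = v["is_indel"].to_numpy()
    remove = np.zeros(len(v), dtype=bool)
    counts: dict[str, int] = {}
    for kind, rules, mask in (
        ("snp", config.snp_hard, ~is_indel),
        ("indel", config.indel_hard, is_indel),
    ):
        for fld, op, thr in rules:
            if fld not in v.columns:
                logger.warning("INFO field %s absent; rule skipped", fld)
                continue
            values = pd.to_numeric(v[fld], errors="coerce").to_numpy(dtype=float)
            bad = ~np.isfinite(values) & mask
            if bad.any():
                logger.warning(
                    "%d %s sites have non-numeric %s; rule skipped there",
                    int(bad.sum()), kind, fld,
                )
            fires = _rule_fires(values, op, thr) & mask
            counts[f"{kind}:{fld}"] = int(fires.sum())
            remove |= fires
    counts["removed"] = int(remove.sum())
    counts["retained"] = int((~remove).sum())
    assert counts["removed"] + counts["retained"] == len(v)
    return sites.subset(~remove), counts


def indel_span(ref: str, alt: str, pos: int) -> tuple[int, int]:
    """Closed 1-based [start, end] footprint of an indel: pos .. pos+max(len)-1."""
    return pos, pos + max(len(ref), len(alt)) - 1


def apply_site_postfilters(
    sites: SiteTable, config: FilterConfig | None = None
) -> tuple[SiteTable, pd.DataFrame]:
    """Depth/GQ genotype masking, indel-proximity removal, missingness removal.

    Depth bounds use each sample's mean depth over the (hard-filtered) input.
    GQ and depth violations mask the genotype rather than dropping the site;
    missingness is then computed over the masked matrix. Returns the retained
    table (with masks applied) and a per-removed-site ledger (key, rule).
    """
    config = config or FilterConfig()
    config.validate()
    out = sites.copy()
    v = out.variants
    n, s = out.gt.shape

    mean_depth = out.dp.mean(axis=0) if n else np.zeros(s)
    with np.errstate(invalid="ignore"):
        depth_bad = (out.dp > config.depth_hi_mult * mean_depth) | (
            out.dp < config.depth_lo_mult * mean_depth
        )
    gq_bad = out.gq < config.gq_min
    mask = (depth_bad | gq_bad) & (out.gt >= 0)
    out.gt[mask] = -1

    # SNPs at or within indel_prox_bp of any indel footprint
    is_indel = v["is_indel"].to_numpy()
    prox = np.zeros(n, dtype=bool)
    for chrom, sub in v.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        snp_sel = idx[~is_indel[idx]]
        ind_sel = idx[is_indel[idx]]
        if len(ind_sel) == 0 or len(snp_sel) == 0:
            continue
        spans = [
            indel_span(v.at[i, "ref"], v.at[i, "alt"], int(v.at[i, "pos"]))
            for i in ind_sel
        ]
        starts = np.array([a - config.indel_prox_bp for a, _ in spans])
        ends = np.array([b + config.indel_prox_bp for _, b in spans])
        order = np.argsort(starts)
        starts, ends = starts[order], np.maximum.accumulate(ends[order])
        pos = v["pos"].to_numpy()[snp_sel]
        j = np.searchsorted(starts, pos, side="right") - 1
        inside = (j >= 0) & (pos <= ends[np.clip(j, 0, None)])
        prox[snp_sel[inside]] = True

    missing_frac = (out.gt < 0).mean(axis=1) if s else np.ones(n)
    all_missing = (out.gt < 0).all(axis=1)
    miss_bad = missing_frac > config.site_missing_max

    remove = prox | miss_bad | all_missing
    reasons = np.where(prox, "indel-proximity", np.where(all_missing, "missing", "missingness"))
    ledger = pd.DataFrame(
        {"key": out.keys().to_numpy()[remove], "rule": reasons[remove]}
    )
    return out.subset(~remove), ledger
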