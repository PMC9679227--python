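"""Somatic mutation identification among clonal samples.

A site is a somatic candidate when the non-missing genotypes of the clone-mates
disagree. The clone-founder genotype is taken as the majority genotype (ties
broken toward the homozygous-ancestral state when outgroup genotypes are
supplied, otherwise toward the lexicographically smaller genotype), and the
carriers are the samples departing from it. Strand-resolved read evidence
gates each carrier: an allele *gained* relative to the founder must be seen on
both strands with a forward/reverse bias ratio below 2; an allele *lost* must
leave zero residual reads at a depth high enough to rule out sampling dropout
of one haplotype (binomial dropout probability 2^-depth below 1e-6, i.e. at
least 20 reads). Sites inside population-recurrent structural variants are
masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GT_HET, SiteTable, annotation_of_positions

TRANSITIONS = ["hom→het", "het→hom", "hom→hom-alt"]

#: minimum carrier depth for loss-of-allele (het→hom) evidence: the chance of
#: one haplotype contributing zero of d reads is 2^-d, kept below 1e-6
LOSS_DEPTH_MIN = 20


@dataclass(frozen=True)
class StrandCounts:
    fwd_alt: int
    rev_alt: int


def strand_filter(counts: StrandCounts | tuple[int, int] | None) -> bool:
    """Both-strand support with bias ratio strictly below 2.

    >>> strand_filter((3, 2))
    True
    >>> strand_filter((4, 2))   # ratio exactly 2 fails
    False
    """
    if counts is None:
        return False
    fwd, rev = (counts.fwd_alt, counts.rev_alt) if isinstance(counts, StrandCounts) else counts
    if fwd < 1 or rev < 1:
        return False
    return max(fwd, rev) / min(fwd, rev) < 2.0


def _transition(founder: int, carrier: int) -> str:
    if founder in (0, 2) and carrier == GT_HET:
        return "hom→het"
    if founder == GT_HET and carrier in (0, 2):
        return "het→hom"
    return "hom→hom-alt"


def _founder_genotype(gts: np.ndarray, ancestral_gt: int | None) -> int:
    """Majority genotype over non-missing samples; ties broken as documented."""
    valid = gts[gts >= 0]
    counts = np.bincount(valid, minlength=3)
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if len(tied) > 1 and ancestral_gt is not None and ancestral_gt in tied:
        return int(ancestral_gt)
    return int(tied[0])


def call_somatic(
    sites: SiteTable,
    annotations: pd.DataFrame | None = None,
    ancestral_gt: np.ndarray | None = None,
    require_support: bool = True,
) -> pd.DataFrame:
    """Call somatic mutations from genotype heterogeneity among clone-mates.

    Parameters
    ----------
    sites
        Filtered biallelic site table of the clonal samples.
    annotations
        Optional BED-like feature frame; each call gets exactly one label.
    ancestral_gt
        Optional per-site ancestral genotype code used only to break founder
        ties toward the homozygous-ancestral state.
    require_support
        Gate carriers on read evidence: gained non-reference alleles need the
        two-strand test, lost alleles need zero residual reads. (Strand counts
        are tracked for the alternate allele; reference-allele residuals use
        ``dp - alt``.) Indel carriers are exempt from the strand-ratio test.

    Returns one row per retained somatic call with carriers, zygosity
    transition (classified against the founder from the modal carrier
    genotype), shared flag and annotation class.
    """
    v = sites.variants
    gt = sites.gt
    alt_total = sites.alt_total()
    samples = np.array(sites.samples)
    rows = []
    for i in range(sites.n_sites):
        g = gt[i]
        valid = g >= 0
        if valid.sum() == 0:
            continue
        vals = np.unique(g[valid])
        if len(vals) < 2:
            continue
        anc = int(ancestral_gt[i]) if ancestral_gt is not None else None
        founder = _founder_genotype(g, anc)
        carrier_idx = np.flatnonzero(valid & (g != founder))
        if require_support:
            kept = []
            founder_has_alt = founder >= 1
            founder_has_ref = founder <= 1
            for j in carrier_idx:
                cg = int(g[j])
                has_alt, has_ref = cg >= 1, cg <= 1
                ok = True
                if has_alt and not founder_has_alt and not v["is_indel"].iat[i]:
                    ok = strand_filter((int(sites.alt_fwd[i, j]), int(sites.alt_rev[i, j])))
                if founder_has_alt and not has_alt:
                    ok = ok and alt_total[i, j] == 0 and sites.dp[i, j] >= LOSS_DEPTH_MIN
                if founder_has_ref and not has_ref:
                    ok = ok and (sites.dp[i, j] - alt_total[i, j]) == 0 and sites.dp[i, j] >= LOSS_DEPTH_MIN
                if ok:
                    kept.append(j)
            carrier_idx = np.array(kept, dtype=int)
        if len(carrier_idx) == 0:
            continue
        carrier_gts = g[carrier_idx]
        modal = np.bincount(carrier_gts, minlength=3).argmax()
        rows.append(
            {
                "chrom": v["chrom"].iat[i],
                "pos": int(v["pos"].iat[i]),
                "ref": v["ref"].iat[i],
                "alt": v["alt"].iat[i],
                "var_type": "indel" if v["is_indel"].iat[i] else "SNV",
                "carriers": ",".join(samples[carrier_idx]),
                "n_carriers": len(carrier_idx),
                "shared": len(carrier_idx) >= 2,
                "founder_gt": founder,
                "carrier_gt": int(modal),
                "transition": _transition(founder, int(modal)),
            }
        )
    calls = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "var_type", "carriers", "n_carriers",
            "shared", "founder_gt", "carrier_gt", "transition",
        ],
    )
    if annotations is not None and len(calls):
        calls["annotation"] = annotation_of_positions(
            annotations, calls["chrom"].tolist(), calls["pos"].to_numpy() - 1
        )
    elif len(calls):
        calls["annotation"] = "unannotated"
    else:
        calls["annotation"] = pd.Series(dtype=object)
    return calls


def sample_variant_sites(
    sites: SiteTable, sample: str, founder_gt: np.ndarray, require_support: bool = True
) -> set[str]:
    """Candidate variant-site keys where one sample departs from the founder.

    Used for replicate concordance: a candidate needs a confident genotype and
    allele support (zero residual reads for lost alleles), but deliberately
    not the strand-ratio test — replicate comparison measures call stability,
    and layering a stochastic read-level filter on top would conflate sampling
    noise with erroneous calls.
    """
    j = sites.samples.index(sample)
    g = sites.gt[:, j]
    alt_total = sites.alt_total()[:, j]
    ref_resid = sites.dp[:, j] - alt_total
    differs = (g >= 0) & (founder_gt >= 0) & (g != founder_gt)
    if require_support:
        dp = sites.dp[:, j]
        lost_alt = (founder_gt >= 1) & (g == 0)
        lost_ref = (founder_gt <= 1) & (g == 2)
        gained_alt = (founder_gt == 0) & (g >= 1)
        ok = np.ones_like(differs)
        ok[lost_alt & ((alt_total > 0) | (dp < LOSS_DEPTH_MIN))] = False
        ok[lost_ref & ((ref_resid > 0) | (dp < LOSS_DEPTH_MIN))] = False
        ok[gained_alt & (alt_total < 1)] = False
        differs &= ok
    keys = sites.keys().to_numpy()
    return set(keys[differs])


def majority_genotypes(sites: SiteTable) -> np.ndarray:
    """Per-site majority (founder) genotype code over non-missing samples."""
    out = np.zeros(sites.n_sites, dtype=np.int8)
    for i in range(sites.n_sites):
        g = sites.gt[i]
        valid = g[g >= 0]
        out[i] = np.bincount(valid, minlength=3).argmax() if len(valid) else -1
    return out


# ---------------------------------------------------------------------------
# structural-variant masking


def sv_mask(
    calls: pd.DataFrame,
    sv_sets: dict[str, pd.DataFrame],
    n_samples: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove calls inside structural variants recurrent in most samples.

    ``sv_sets`` maps sample -> BED-like frame (chrom, start, end[, type]).
    Per sample and type the intervals are merged; a genomic region becomes a
    mask only when supported by strictly more than ``n_samples / 2`` samples.
    Calls overlapping a mask (closed containment at boundary bases) are
    dropped. Returns (retained calls, mask intervals).
    """
    if not sv_sets or calls.empty:
        return calls.copy(), pd.DataFrame(columns=["chrom", "start", "end"])

    events = []
    for sample, df in sv_sets.items():
        if df is None or df.empty:
            continue
        df = df.copy()
        if "type" not in df.columns:
            df["type"] = "SV"
        for (chrom, svtype), sub in df.groupby(["chrom", "type"]):
            merged = _merge_intervals(sub[["start", "end"]].to_numpy())
            for a, b in merged:
                events.append((chrom, svtype, sample, a, b))
    if not events:
        return calls.copy(), pd.DataFrame(columns=["chrom", "start", "end"])

    ev = pd.DataFrame(events, columns=["chrom", "type", "sample", "start", "end"])
    masks = []
    for (chrom, svtype), sub in ev.groupby(["chrom", "type"]):
        edges = np.unique(np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy()]))
        for a, b in zip(edges[:-1], edges[1:]):
            support = ((sub["start"] <= a) & (sub["end"] >= b)).groupby(
                sub["sample"]
            ).any().sum()
            if support > n_samples / 2.0:
                masks.append((chrom, int(a), int(b)))
    if not masks:
        return calls.copy(), pd.DataFrame(columns=["chrom", "start", "end"])
    mask_df = pd.DataFrame(masks, columns=["chrom", "start", "end"])
    mask_df = (
        mask_df.groupby("chrom", group_keys=False)
        .apply(lambda g: pd.DataFrame(_merge_intervals(g[["start", "end"]].to_numpy()),
                                      columns=["start", "end"]).assign(chrom=g.name),
               include_groups=False)
        .reset_index(drop=True)[["chrom", "start", "end"]]
    )

    keep = np.ones(len(calls), dtype=bool)
    for chrom, sub in mask_df.groupby("chrom"):
        sel = calls["chrom"] == chrom
        if not sel.any():
            continue
        pos0 = calls.loc[sel, "pos"].to_numpy() - 1
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        j = np.searchsorted(starts, pos0, side="right") - 1
        inside = (j >= 0) & (pos0 < ends[np.clip(j, 0, None)])
        keep[np.flatnonzero(sel)[inside]] = False
    return calls[keep].reset_index(drop=True), mask_df


def _merge_intervals(arr: np.ndarray) -> list[tuple[int, int]]:
    if len(arr) == 0:
        return []
    arr = arr[np.argsort(arr[:, 0])]
    merged = [tuple(arr[0])]
    for a, b in arr[1:]:
        la, lb = merged[-1]
        if a <= lb:
            merged[-1] = (la, max(lb, b))
        else:
            merged.append((a, b))
    return [(int(a), int(b)) for a, b in merged]


# ---------------------------------------------------------------------------
# indel candidate filter


def indel_somatic_filter(
    sites: SiteTable, min_reads: int = 5, max_missing: float = 0.10
) -> SiteTable:
    """Indel candidate QC: genotypes with mapped reads below ``min_reads`` are
    treated as missing and sites with strictly more than ``max_missing``
    missingness are dropped. Non-indel sites pass through untouched."""
    out = sites.copy()
    is_indel = out.variants["is_indel"].to_numpy()
    low = (out.dp < min_reads) & is_indel[:, None]
    out.gt[low & (out.gt >= 0)] = -1
    miss = (out.gt < 0).mean(axis=1)
    drop = is_indel & (miss > max_missing)
    return out.subset(~drop)
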