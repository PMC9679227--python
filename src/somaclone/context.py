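"""Genomic context of somatic mutations: heterozygosity versus distance to the
nearest mutation (with a random-site control), annotation-partition chi-square
tests, and the recombination-window regression.

The heterozygosity profile reports, per distance bin, both the per-bp density
of heterozygous genotypes and per-bp nucleotide diversity (pi, mean pairwise
difference), since the two statistics are used interchangeably in this
literature. Bin denominators are exact base-pair counts obtained from merged
call-centred intervals, so overlapping flanks are not double counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import SomacloneError, substream
from .model import GT_HET, ReferenceModel, SiteTable


@dataclass
class ContextConfig:
    flank_bp: int = 1200
    n_random_sites: int = 1000
    window_bp: int = 50_000
    n_groups: int = 7
    distance_bins: list[int] = field(
        default_factory=lambda: [0, 100, 200, 400, 600, 800, 1000, 1200]
    )

    def validate(self) -> None:
        if self.flank_bp <= 0:
            raise SomacloneError("flank_bp must be positive")
        if self.n_groups < 2:
            raise SomacloneError("n_groups must be at least 2")
        edges = self.distance_bins
        if any(b <= a for a, b in zip(edges[:-1], edges[1:])) or edges[-1] > self.flank_bp:
            raise SomacloneError("distance_bins must increase and stay within flank_bp")


def _merged_interval_length(points: np.ndarray, radius: int, length: int) -> int:
    """Total bp within ``radius`` of any point, on a chromosome of ``length``."""
    if len(points) == 0 or radius < 0:
        return 0
    starts = np.maximum(points - radius, 0)
    ends = np.minimum(points + radius + 1, length)
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    total, cur_s, cur_e = 0, starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    total += cur_e - cur_s
    return int(total)


def _profile_for_anchors(
    anchors: dict[str, np.ndarray],
    sites: SiteTable,
    ref: ReferenceModel,
    config: ContextConfig,
    stratum: str,
) -> list[dict]:
    """Het density / pi per distance bin around a set of anchor positions (0-based)."""
    edges = config.distance_bins
    n_bins = len(edges) - 1
    het_counts = np.zeros(n_bins)
    pi_sums = np.zeros(n_bins)
    bp = np.zeros(n_bins)

    v = sites.variants
    n_samples = sites.n_samples
    for chrom, codes in ref.chroms.items():
        pts = anchors.get(chrom, np.empty(0, dtype=int))
        if len(pts) == 0:
            continue
        pts = np.sort(pts)
        for b in range(n_bins):
            lo, hi = edges[b], edges[b + 1]
            outer = _merged_interval_length(pts, hi - 1, len(codes))
            inner = _merged_interval_length(pts, lo - 1, len(codes)) if lo > 0 else 0
            bp[b] += outer - inner

        sel = (v["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        site_pos0 = v["pos"].to_numpy()[sel] - 1
        j = np.searchsorted(pts, site_pos0)
        left = np.abs(site_pos0 - pts[np.clip(j - 1, 0, len(pts) - 1)])
        right = np.abs(pts[np.clip(j, 0, len(pts) - 1)] - site_pos0)
        dist = np.minimum(left, right)
        gt = sites.gt[sel]
        for b in range(n_bins):
            lo, hi = edges[b], edges[b + 1]
            in_bin = (dist >= lo) & (dist < hi)
            if not in_bin.any():
                continue
            g = gt[in_bin]
            valid = g >= 0
            het_counts[b] += (g == GT_HET).sum()
            # per-site pi from sample allele frequencies
            n_val = valid.sum(axis=1)
            alt_alleles = np.where(g > 0, g, 0).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = alt_alleles / (2.0 * n_val)
                denom = 2.0 * n_val - 1
                pi = np.where(n_val > 0, 2.0 * p * (1 - p) * (2.0 * n_val) / denom, 0.0)
            pi_sums[b] += np.nansum(pi)

    rows = []
    for b in range(n_bins):
        if bp[b] == 0:
            rows.append(
                {
                    "stratum": stratum,
                    "bin_lo": edges[b],
                    "bin_hi": edges[b + 1],
                    "bp": 0,
                    "het_per_bp": np.nan,
                    "pi_per_bp": np.nan,
                }
            )
        else:
            rows.append(
                {
                    "stratum": stratum,
                    "bin_lo": edges[b],
                    "bin_hi": edges[b + 1],
                    "bp": int(bp[b]),
                    "het_per_bp": het_counts[b] / (bp[b] * n_samples),
                    "pi_per_bp": pi_sums[b] / bp[b],
                }
            )
    return rows


def het_vs_distance(
    calls: pd.DataFrame,
    sites: SiteTable,
    ref: ReferenceModel,
    config: ContextConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Heterozygosity profile by distance to the nearest somatic call.

    Returns one row per (stratum, distance bin) with per-bp heterozygous
    genotype density and per-bp nucleotide diversity. Strata are 'all', each
    annotation class present among the calls, and a 'control' built from
    ``n_random_sites`` uniform positions. Bins with no covered base pairs are
    reported as missing (NaN), not zero.
    """
    config = config or ContextConfig()
    config.validate()
    if calls.empty:
        raise SomacloneError("no somatic calls supplied")
    rows: list[dict] = []

    def anchors_of(sub: pd.DataFrame) -> dict[str, np.ndarray]:
        return {
            chrom: g["pos"].to_numpy() - 1 for chrom, g in sub.groupby("chrom")
        }

    rows += _profile_for_anchors(anchors_of(calls), sites, ref, config, "all")
    if "annotation" in calls:
        for ann, sub in calls.groupby("annotation"):
            rows += _profile_for_anchors(anchors_of(sub), sites, ref, config, str(ann))

    rng = substream(seed, "het-control")
    lengths = {c: len(codes) for c, codes in ref.chroms.items()}
    total = sum(lengths.values())
    control: dict[str, list[int]] = {c: [] for c in lengths}
    names = list(lengths)
    probs = np.array([lengths[c] / total for c in names])
    chosen = rng.choice(len(names), size=config.n_random_sites, p=probs)
    for ci in chosen:
        c = names[ci]
        control[c].append(int(rng.integers(0, lengths[c])))
    rows += _profile_for_anchors(
        {c: np.array(p, dtype=int) for c, p in control.items()},
        sites,
        ref,
        config,
        "control",
    )
    return pd.DataFrame(rows)


def annotation_chisq(
    observed: dict[str, int], expected_fractions: dict[str, float]
) -> pd.DataFrame:
    """Yates-corrected chi-square (df=1) per annotation class.

    Each class is tested in-class vs not-in-class against its expected genomic
    fraction: chi2 = sum((|O - E| - 0.5)^2 / E) over the two cells.
    """
    total = sum(observed.values())
    if total == 0:
        raise SomacloneError("no observed counts")
    if abs(sum(expected_fractions.values()) - 1.0) > 1e-6:
        raise SomacloneError("expected fractions must sum to 1")
    rows = []
    for cls, frac in expected_fractions.items():
        o_in = observed.get(cls, 0)
        o_out = total - o_in
        e_in = frac * total
        e_out = total - e_in
        if e_in == 0 or e_out == 0:
            chi2, p = np.nan, np.nan
        else:
            chi2 = (max(abs(o_in - e_in) - 0.5, 0.0)) ** 2 / e_in + (
                max(abs(o_out - e_out) - 0.5, 0.0)
            ) ** 2 / e_out
            p = float(stats.chi2.sf(chi2, df=1))
        rows.append(
            {
                "annotation": cls,
                "observed": o_in,
                "expected": e_in,
                "chi2_yates": chi2,
                "pvalue": p,
            }
        )
    return pd.DataFrame(rows)


def recomb_regression(
    calls: pd.DataFrame,
    recomb_windows: pd.DataFrame,
    config: ContextConfig | None = None,
    mode: str = "count",
) -> dict:
    """Group windows by somatic-SNP count and regress mean rho on the group.

    Windows (chrom, start, end, rho) tile the genome at ``window_bp``. The
    default grouping is by exact somatic count 0..n_groups-2 with the top
    class pooled (count >= n_groups-1); ``mode='quantile'`` groups by count
    quantiles instead. Ordinary least squares of per-group mean rho on the
    group index with a two-sided p on the slope; skipped (with a warning)
    when fewer than two groups are populated.
    """
    config = config or ContextConfig()
    config.validate()
    win = recomb_windows.copy()
    counts = np.zeros(len(win), dtype=int)
    for chrom, sub in calls.groupby("chrom"):
        sel = (win["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts = win.loc[sel, "start"].to_numpy()
        ends = win.loc[sel, "end"].to_numpy()
        pos0 = sub["pos"].to_numpy() - 1
        j = np.searchsorted(starts, pos0, side="right") - 1
        ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, None)])
        idx = np.flatnonzero(sel)[j[ok]]
        np.add.at(counts, idx, 1)
    win["somatic_count"] = counts

    if mode == "quantile":
        try:
            win["group"] = pd.qcut(
                win["somatic_count"].rank(method="first"),
                config.n_groups,
                labels=False,
            )
        except ValueError:
            win["group"] = 0
    else:
        win["group"] = np.minimum(win["somatic_count"], config.n_groups - 1)

    grouped = (
        win.groupby("group")["rho"].agg(["mean", "count"]).reset_index()
        .rename(columns={"mean": "mean_rho", "count": "n_windows"})
    )
    result = {"groups": grouped, "windows": win}
    if len(grouped) < 2:
        warnings.warn("fewer than 2 populated somatic-count groups; regression skipped")
        result.update(slope=None, intercept=None, pvalue=None, skipped=True)
        return result
    fit = stats.linregress(grouped["group"], grouped["mean_rho"])
    result.update(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pvalue=float(fit.pvalue),
        rvalue=float(fit.rvalue),
        skipped=False,
    )
    return result
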