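"""Synthetic clonal-lineage data generator.

Emulates the study design the downstream pipeline expects: a diploid genome
with elevated background heterozygosity, a cutting-propagation pedigree,
Poisson mutation accumulation per branch with cytosine-context-biased rates,
Poisson sequencing depth with binomial allele sampling, strand-count noise,
and independent triplicate re-sequencing of a subset of samples. Every stage
is driven by one run seed; sub-streams are derived per component so partial
re-runs are reproducible.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from itertools import zip_longest

import numpy as np
import pandas as pd
from Bio import Phylo

from ._seqcontext import CONTEXT_NAMES, classify_contexts
from ._util import BASES, SomacloneError, substream
from .model import (
    GT_HET,
    GT_HOMREF,
    INFO_FIELDS,
    PedigreeNode,
    PedigreeTruth,
    PhasedGenotypes,
    ReferenceModel,
    SiteTable,
)

#: 11-sample cutting pedigree over 67 years used as the default study design:
#: one four-leaf cluster propagated from a common parent plus smaller clusters,
#: all root-to-tip path lengths equal to the elapsed 67 years.
DEFAULT_PEDIGREE = (
    "((pay01:47,pay08:47,pay09:47,pay10:47):20,"
    "(pay03:50,pay06:50):17,"
    "(pay02:55,pay04:55,pay11:55):12,"
    "pay05:67,pay07:67):0;"
)


@dataclass
class SimConfig:
    """Parameters of one simulated clonal-lineage dataset.

    Rates are per base pair per year on the diploid genome (so the expected
    SNV count on a branch is ``snv_rate * years * 2 * genome_length``).
    ``context_multipliers`` are *relative* weights shaping where mutations
    land (CpG/CHG/CHH/nonC); the genome-wide mean rate stays ``snv_rate``.
    ``het_density`` is expected founder heterozygous sites per kb.
    """

    genome_length: int = 408_000_000
    n_chromosomes: int = 19
    gc_content: float = 0.35
    het_density: float = 8.0
    annotation_fractions: tuple[float, float, float] = (0.05, 0.10, 0.85)
    pedigree_newick: str = DEFAULT_PEDIGREE
    snv_rate: float = 9.24e-9
    indel_rate: float = 1.77e-9
    context_multipliers: dict[str, float] = field(
        default_factory=lambda: {"CpG": 2.5, "CHG": 1.5, "CHH": 1.0, "nonC": 1.0}
    )
    mean_depth: float = 25.0
    seq_error: float = 0.005
    strand_imbalance_sd: float = 0.05
    n_replicate_samples: int = 5
    seed: int = 0
    # plumbing beyond the core design
    phase_block_bp: int = 500_000
    n_outgroup_samples: int = 10
    outgroup_ancestral_match: float = 0.95
    deleterious_fraction: float = 0.3
    recomb_window_bp: int = 50_000

    def validate(self) -> None:
        if self.genome_length < 1000:
            raise SomacloneError(
                "genome_length < 1 kb: sequence contexts undefined at this scale"
            )
        if abs(sum(self.annotation_fractions) - 1.0) > 1e-9:
            raise SomacloneError("annotation_fractions must sum to 1")
        for name in ("snv_rate", "indel_rate", "het_density", "mean_depth", "seq_error"):
            if getattr(self, name) < 0:
                raise SomacloneError(f"{name} must be non-negative")
        if not 0 < self.gc_content < 1:
            raise SomacloneError("gc_content must lie in (0, 1)")
        if any(v < 0 for v in self.context_multipliers.values()):
            raise SomacloneError("context multipliers must be non-negative")


# ---------------------------------------------------------------------------
# pedigree parsing


def parse_pedigree(newick: str) -> dict[str, PedigreeNode]:
    """Parse a newick topology with branch lengths in years into named nodes."""
    tree = Phylo.read(_io.StringIO(newick), "newick")
    nodes: dict[str, PedigreeNode] = {}
    counter = [0]

    def visit(clade, parent: str | None) -> str:
        name = clade.name
        if name is None:
            name = f"node{counter[0]}"
            counter[0] += 1
        years = float(clade.branch_length or 0.0)
        nodes[name] = PedigreeNode(name=name, parent=parent, years=years)
        if parent is not None:
            nodes[parent].children.append(name)
        for child in clade.clades:
            visit(child, name)
        return name

    root = visit(tree.root, None)
    if not any(not n.children for n in nodes.values()):
        raise SomacloneError("pedigree has no leaves")
    nodes[root].parent = None
    return nodes


def _root_name(nodes: dict[str, PedigreeNode]) -> str:
    return next(n for n, node in nodes.items() if node.parent is None)


# ---------------------------------------------------------------------------
# genome


def _chrom_lengths(config: SimConfig) -> dict[str, int]:
    base = config.genome_length // config.n_chromosomes
    lengths = {}
    rem = config.genome_length - base * config.n_chromosomes
    for i in range(config.n_chromosomes):
        lengths[f"chr{i + 1}"] = base + (1 if i < rem else 0)
    return lengths


def _tile_annotations(chrom: str, length: int, fractions, period: int = 20_000) -> list:
    """Interleave exon/intron/intergenic segments so per-feature totals are exact."""
    feats = ["exon", "intron", "intergenic"]
    targets = [int(round(f * length)) for f in fractions]
    targets[2] = length - targets[0] - targets[1]
    seg_sizes = [max(1, int(round(f * period))) for f in fractions]
    queues = []
    for f, total, seg in zip(feats, targets, seg_sizes):
        n_full, last = divmod(total, seg)
        q = [(f, seg)] * n_full + ([(f, last)] if last else [])
        queues.append(q)
    rows, pos = [], 0
    for f, seg in (x for tup in zip_longest(*queues) for x in tup if x is not None):
        rows.append((chrom, pos, pos + seg, f))
        pos += seg
    assert pos == length
    return rows


def simulate_genome(config: SimConfig) -> ReferenceModel:
    """Random diploid reference: sequence, annotation tiling, founder het map."""
    config.validate()
    rng = substream(config.seed, "genome")
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    chroms: dict[str, np.ndarray] = {}
    ann_rows: list = []
    for chrom, length in _chrom_lengths(config).items():
        chroms[chrom] = rng.choice(4, size=length, p=p).astype(np.uint8)
        ann_rows.extend(
            _tile_annotations(chrom, length, config.annotation_fractions)
        )
    annotations = pd.DataFrame(ann_rows, columns=["chrom", "start", "end", "feature"])

    n_het = int(round(config.het_density * config.genome_length / 1000.0))
    offsets, names = _genome_offsets(chroms)
    gpos = rng.choice(config.genome_length, size=min(n_het, config.genome_length), replace=False)
    gpos.sort()
    chrom_idx = np.searchsorted(offsets, gpos, side="right") - 1
    pos0 = gpos - offsets[chrom_idx]
    refs = np.array(
        [chroms[names[c]][p] for c, p in zip(chrom_idx, pos0)], dtype=np.uint8
    )
    alts = (refs + rng.integers(1, 4, size=refs.size)) % 4
    het_sites = pd.DataFrame(
        {
            "chrom": [names[c] for c in chrom_idx],
            "pos0": pos0,
            "ref": [BASES[r] for r in refs],
            "alt": [BASES[a] for a in alts],
            "hap": rng.integers(0, 2, size=refs.size),
        }
    )
    realized_gc = float(
        np.mean([np.isin(c, (1, 2)).mean() for c in chroms.values()])
    )
    return ReferenceModel(
        chroms=chroms, annotations=annotations, het_sites=het_sites, gc_content=realized_gc
    )


def _genome_offsets(chroms: dict[str, np.ndarray]):
    names = list(chroms)
    lengths = np.array([len(chroms[n]) for n in names])
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    return offsets, names


# ---------------------------------------------------------------------------
# mutations


def expected_branch_snvs(config: SimConfig, years: float) -> float:
    """Poisson mean for SNVs on a branch: rate * years * diploid factor * genome size."""
    return config.snv_rate * years * 2.0 * config.genome_length


def simulate_mutations(ref: ReferenceModel, config: SimConfig) -> PedigreeTruth:
    """Drop Poisson mutation counts on each pedigree branch and place them.

    SNV placement is uniform over the diploid genome then thinned by the
    relative context multiplier (rejection sampling), so positions follow the
    per-site context weights while the branch total stays Poisson with mean
    ``snv_rate * years * 2 * genome_length``. Positions already occupied by a
    founder heterozygous site or an earlier mutation are redrawn and counted.
    """
    config.validate()
    rng = substream(config.seed, "mutations")
    nodes = parse_pedigree(config.pedigree_newick)
    root = _root_name(nodes)

    offsets, names = _genome_offsets(ref.chroms)
    occupied: set[int] = set()
    for chrom, sub in ref.het_sites.groupby("chrom"):
        off = offsets[names.index(chrom)]
        occupied.update((sub["pos0"].to_numpy() + off).tolist())

    mult = np.array([config.context_multipliers.get(c, 1.0) for c in CONTEXT_NAMES])
    m_max = mult.max() if mult.max() > 0 else 1.0

    rows = []
    mut_id = 0
    collisions = 0
    L = config.genome_length
    for name, node in nodes.items():
        if node.parent is None:
            continue
        n_snv = rng.poisson(expected_branch_snvs(config, node.years))
        n_indel = rng.poisson(config.indel_rate * node.years * 2.0 * L)
        placed = 0
        while placed < n_snv:
            g = int(rng.integers(2, L - 2))
            if g in occupied:
                collisions += 1
                continue
            ci = int(np.searchsorted(offsets, g, side="right") - 1)
            chrom = names[ci]
            pos0 = g - int(offsets[ci])
            if pos0 < 2 or pos0 > len(ref.chroms[chrom]) - 3:
                continue
            ctx = int(classify_contexts(ref.chroms[chrom], np.array([pos0]))[0])
            if rng.random() >= mult[ctx] / m_max:
                continue
            refb = BASES[ref.chroms[chrom][pos0]]
            altb = BASES[(ref.chroms[chrom][pos0] + int(rng.integers(1, 4))) % 4]
            rows.append(
                (mut_id, name, chrom, pos0, refb, altb, int(rng.integers(0, 2)), "SNV")
            )
            occupied.add(g)
            mut_id += 1
            placed += 1
        placed = 0
        while placed < n_indel:
            g = int(rng.integers(2, L - 12))
            if g in occupied:
                collisions += 1
                continue
            ci = int(np.searchsorted(offsets, g, side="right") - 1)
            chrom = names[ci]
            pos0 = g - int(offsets[ci])
            if pos0 < 2 or pos0 > len(ref.chroms[chrom]) - 13:
                continue
            ilen = min(int(rng.geometric(0.5)), 10)
            anchor = BASES[ref.chroms[chrom][pos0]]
            if rng.random() < 0.5:  # insertion
                ins = "".join(BASES[i] for i in rng.integers(0, 4, size=ilen))
                refb, altb = anchor, anchor + ins
            else:  # deletion
                tail = "".join(
                    BASES[b] for b in ref.chroms[chrom][pos0 + 1 : pos0 + 1 + ilen]
                )
                refb, altb = anchor + tail, anchor
            rows.append(
                (mut_id, name, chrom, pos0, refb, altb, int(rng.integers(0, 2)), "indel")
            )
            occupied.add(g)
            mut_id += 1
            placed += 1

    mutations = pd.DataFrame(
        rows,
        columns=["mut_id", "branch", "chrom", "pos0", "ref", "alt", "hap", "var_type"],
    )
    return PedigreeTruth(
        nodes=nodes, root=root, mutations=mutations, n_position_collisions=collisions
    )


# ---------------------------------------------------------------------------
# read-level site table


def _call_genotypes(alt: np.ndarray, dp: np.ndarray, seq_error: float):
    """Binomial-likelihood genotyper; returns (gt codes, GQ)."""
    e = max(seq_error / 3.0, 1e-4)
    vafs = np.array([e, 0.5, 1.0 - e])
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.stack(
            [alt * np.log(v) + (dp - alt) * np.log(1.0 - v) for v in vafs], axis=-1
        )
    order = np.argsort(ll, axis=-1)
    gt = order[..., -1].astype(np.int8)
    best = np.take_along_axis(ll, order[..., -1:], axis=-1)[..., 0]
    second = np.take_along_axis(ll, order[..., -2:-1], axis=-1)[..., 0]
    gq = np.clip(np.round(4.342944819 * (best - second)), 0, 99).astype(np.int32)
    gt[dp == 0] = -1
    gq[dp == 0] = 0
    return gt, gq


def _draw_info(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Site-level alignment annotations drawn from mostly-passing null distributions."""
    return pd.DataFrame(
        {
            "FS": rng.exponential(10.0, n),
            "MQ": 60.0 - rng.exponential(3.0, n),
            "MQRankSum": rng.normal(0.0, 3.5, n),
            "QD": rng.gamma(6.0, 4.0, n),
            "ReadPosRankSum": rng.normal(0.0, 2.8, n),
            "SOR": rng.exponential(0.55, n),
        }
    )


def _truth_variants(truth: PedigreeTruth, ref: ReferenceModel) -> tuple[pd.DataFrame, np.ndarray]:
    """Merged variant frame (germline het + somatic) and truth genotype matrix."""
    leaves = truth.leaves
    germ = ref.het_sites.copy()
    germ["pos"] = germ["pos0"] + 1
    germ["is_indel"] = False
    germ["origin"] = "germline"
    germ["mut_id"] = -1

    som = truth.mutations.copy()
    som["pos"] = som["pos0"] + 1
    som["is_indel"] = som["var_type"] == "indel"
    som["origin"] = "somatic"
    som["hap"] = som["hap"].astype(int)

    variants = pd.concat(
        [
            germ[["chrom", "pos", "ref", "alt", "is_indel", "origin", "mut_id", "hap"]],
            som[["chrom", "pos", "ref", "alt", "is_indel", "origin", "mut_id", "hap"]],
        ],
        ignore_index=True,
    )
    variants = variants.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    carriers = truth.carriers()
    gt_truth = np.zeros((len(variants), len(leaves)), dtype=np.int8)
    is_germ = (variants["origin"] == "germline").to_numpy()
    gt_truth[is_germ, :] = GT_HET
    mut_ids = variants["mut_id"].to_numpy()
    for i in np.flatnonzero(~is_germ):
        for j, leaf in enumerate(leaves):
            if leaf in carriers[int(mut_ids[i])]:
                gt_truth[i, j] = GT_HET
    return variants, gt_truth


def _sample_reads(
    gt_truth: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> SiteTable | tuple:
    """Draw depth, alt reads and strand split conditional on truth genotypes."""
    shape = gt_truth.shape
    dp = rng.poisson(config.mean_depth, size=shape).astype(np.int32)
    vaf = np.where(
        gt_truth == GT_HET,
        0.5,
        np.where(gt_truth == GT_HOMREF, config.seq_error / 3.0, 1.0 - config.seq_error),
    )
    alt = rng.binomial(dp, vaf).astype(np.int32)
    p_strand = np.clip(
        rng.normal(0.5, config.strand_imbalance_sd, size=shape), 0.05, 0.95
    )
    fwd = rng.binomial(alt, p_strand).astype(np.int32)
    rev = alt - fwd
    gt, gq = _call_genotypes(alt, dp, config.seq_error)
    return gt, dp, gq, fwd, rev


def simulate_site_table(
    truth: PedigreeTruth, ref: ReferenceModel, config: SimConfig
) -> tuple[SiteTable, dict[str, list[SiteTable]]]:
    """Sequence the clonal samples (and triplicate re-runs of a subset).

    Returns the main multi-sample table plus, for the first
    ``n_replicate_samples`` leaves, three independently re-drawn single-sample
    tables conditioned on the same germline and somatic truth. Site-level INFO
    annotations are shared between the main table and replicates (they describe
    the locus, not the read draw).
    """
    config.validate()
    rng = substream(config.seed, "reads")
    leaves = truth.leaves
    variants, gt_truth = _truth_variants(truth, ref)
    info = _draw_info(len(variants), substream(config.seed, "info"))
    var_out = variants[["chrom", "pos", "ref", "alt", "is_indel"]].copy()
    for col in INFO_FIELDS:
        var_out[col] = info[col].to_numpy()

    gt, dp, gq, fwd, rev = _sample_reads(gt_truth, config, rng)
    table = SiteTable(
        samples=list(leaves), variants=var_out, gt=gt, dp=dp, gq=gq, alt_fwd=fwd, alt_rev=rev
    )

    replicates: dict[str, list[SiteTable]] = {}
    for j, sample in enumerate(leaves[: config.n_replicate_samples]):
        reps = []
        for r in range(3):
            rrng = substream(config.seed, f"replicate:{sample}:{r}")
            g, d, q, f, v = _sample_reads(gt_truth[:, [j]], config, rrng)
            reps.append(
                SiteTable(
                    samples=[sample], variants=var_out, gt=g, dp=d, gq=q, alt_fwd=f, alt_rev=v
                )
            )
        replicates[sample] = reps
    return table, replicates


def simulate_phased_genotypes(
    truth: PedigreeTruth, ref: ReferenceModel, config: SimConfig
) -> PhasedGenotypes:
    """Truth-derived phased genotypes in phase blocks of ``phase_block_bp``.

    Haplotype labels are flipped at random per (sample, chromosome, block), as
    a read-based phaser would produce: only within-block co-occurrence is
    meaningful, never the absolute label.
    """
    rng = substream(config.seed, "phasing")
    leaves = truth.leaves
    variants, gt_truth = _truth_variants(truth, ref)
    n, s = gt_truth.shape
    hap = np.zeros((n, s, 2), dtype=np.int8)
    pos0 = variants["pos"].to_numpy() - 1
    hap_of_alt = variants["hap"].to_numpy()
    is_het = gt_truth == GT_HET
    for k in range(2):
        hap[:, :, k] = np.where(is_het & (hap_of_alt[:, None] == k), 1, 0)

    block = (pos0 // config.phase_block_bp).astype(np.int64)
    chrom_codes = pd.factorize(variants["chrom"])[0]
    block_key = chrom_codes * 1_000_000 + block
    ps = np.tile((block * config.phase_block_bp + 1).astype(np.int32)[:, None], (1, s))

    for j in range(s):
        for key in np.unique(block_key):
            if rng.random() < 0.5:
                sel = block_key == key
                hap[sel, j, :] = hap[sel, j, ::-1]
    return PhasedGenotypes(
        samples=list(leaves),
        variants=variants[["chrom", "pos", "ref", "alt"]].copy(),
        hap=hap,
        ps=ps,
    )


def truth_calls(truth: PedigreeTruth) -> pd.DataFrame:
    """Ground-truth mutations in the somatic-call frame layout.

    Gives downstream analyses (spectrum, pedigree, haplotype test) a perfect
    call set so their behaviour can be checked independently of caller noise.
    """
    carriers = truth.carriers()
    m = truth.mutations
    rows = []
    for _, row in m.iterrows():
        carr = sorted(carriers[int(row["mut_id"])])
        rows.append(
            {
                "chrom": row["chrom"],
                "pos": int(row["pos0"]) + 1,
                "ref": row["ref"],
                "alt": row["alt"],
                "var_type": row["var_type"],
                "carriers": ",".join(carr),
                "n_carriers": len(carr),
                "shared": len(carr) >= 2,
                "mut_id": int(row["mut_id"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "var_type", "carriers",
                 "n_carriers", "shared", "mut_id"],
    )


# ---------------------------------------------------------------------------
# outgroups, effect scores, recombination windows


def simulate_outgroups(
    truth: PedigreeTruth, ref: ReferenceModel, config: SimConfig
) -> pd.DataFrame:
    """Outgroup population genotypes at every candidate site, two species.

    At somatic sites the founder (reference) allele is ancestral; with
    probability ``outgroup_ancestral_match`` both outgroup species are fixed
    for it, otherwise the site segregates at a uniform frequency (standing
    variation predating the clone). Germline heterozygous sites segregate.
    Returns a frame with per-species consensus genotype codes and derived/
    ancestral allele frequencies.
    """
    rng = substream(config.seed, "outgroups")
    variants, _ = _truth_variants(truth, ref)
    n = len(variants)
    is_germ = (variants["origin"] == "germline").to_numpy()
    rows = {}
    for species in ("outgroupA", "outgroupB"):
        af_alt = np.where(
            is_germ,
            rng.beta(0.8, 0.8, size=n),
            np.where(
                rng.random(n) < config.outgroup_ancestral_match,
                0.0,
                rng.random(n),
            ),
        )
        counts = rng.binomial(2 * config.n_outgroup_samples, af_alt)
        af_hat = counts / (2.0 * config.n_outgroup_samples)
        gt = np.where(af_hat == 0.0, 0, np.where(af_hat == 1.0, 2, 1)).astype(np.int8)
        rows[f"{species}_gt"] = gt
        rows[f"{species}_af_alt"] = af_hat
    out = variants[["chrom", "pos", "ref", "alt"]].copy()
    for k, v in rows.items():
        out[k] = v
    return out


def simulate_effect_scores(
    truth: PedigreeTruth, ref: ReferenceModel, config: SimConfig
) -> pd.DataFrame:
    """SIFT/PROVEAN/PolyPhen-style score table for exonic somatic SNVs.

    A ``deleterious_fraction`` of exonic SNVs draws scores in the damaging
    ranges of all three predictors; the rest draw tolerated scores. Scores are
    synthetic stand-ins for predictor output consumed by the selection module.
    """
    from .model import annotation_of_positions

    rng = substream(config.seed, "scores")
    snvs = truth.mutations[truth.mutations["var_type"] == "SNV"]
    ann = annotation_of_positions(
        ref.annotations, snvs["chrom"].tolist(), snvs["pos0"].to_numpy()
    )
    exonic = snvs[np.asarray(ann) == "exon"]
    n = len(exonic)
    damaging = rng.random(n) < config.deleterious_fraction
    sift = np.where(damaging, rng.uniform(0.0, 0.05, n), rng.uniform(0.06, 1.0, n))
    provean = np.where(damaging, rng.uniform(-8.0, -2.6, n), rng.uniform(-2.4, 2.0, n))
    polyphen = np.where(damaging, rng.uniform(0.51, 1.0, n), rng.uniform(0.0, 0.5, n))
    return pd.DataFrame(
        {
            "chrom": exonic["chrom"].to_numpy(),
            "pos": exonic["pos0"].to_numpy() + 1,
            "ref": exonic["ref"].to_numpy(),
            "alt": exonic["alt"].to_numpy(),
            "sift": sift,
            "provean": provean,
            "polyphen": polyphen,
        }
    )


def simulate_recomb_windows(ref: ReferenceModel, config: SimConfig) -> pd.DataFrame:
    """Null per-window population recombination rates (independent of mutations)."""
    rng = substream(config.seed, "recomb")
    rows = []
    for chrom, codes in ref.chroms.items():
        length = len(codes)
        starts = np.arange(0, length, config.recomb_window_bp)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + config.recomb_window_bp, length))))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["rho"] = rng.lognormal(mean=1.0, sigma=0.5, size=len(df))
    return df


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimResult:
    """Everything one simulated study produces, with ground truth attached."""

    config: SimConfig
    ref: ReferenceModel
    truth: PedigreeTruth
    sites: SiteTable
    replicates: dict[str, list[SiteTable]]
    phased: PhasedGenotypes
    outgroups: pd.DataFrame
    effect_scores: pd.DataFrame
    recomb_windows: pd.DataFrame


def simulate_all(config: SimConfig) -> SimResult:
    """Run the full generator: genome, pedigree mutations, reads, side tables."""
    config.validate()
    ref = simulate_genome(config)
    truth = simulate_mutations(ref, config)
    sites, replicates = simulate_site_table(truth, ref, config)
    phased = simulate_phased_genotypes(truth, ref, config)
    outgroups = simulate_outgroups(truth, ref, config)
    scores = simulate_effect_scores(truth, ref, config)
    recomb = simulate_recomb_windows(ref, config)
    return SimResult(
        config=config,
        ref=ref,
        truth=truth,
        sites=sites,
        replicates=replicates,
        phased=phased,
        outgroups=outgroups,
        effect_scores=scores,
        recomb_windows=recomb,
    )
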