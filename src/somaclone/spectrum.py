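"""Mutation spectrum, Ti/Tv, content-corrected AT bias and context enrichment.

Point mutations are strand-collapsed onto the six pyrimidine-rooted classes
(C→A, C→G, C→T, T→A, T→C, T→G); a purine-rooted change counts as its
complement (G→A ≡ C→T). Cytosine methylation contexts (CpG, CHG, CHH with
H = A, C or T) are evaluated on both strands. Context enrichment compares the
per-site mutation rate of each cytosine class against the non-cytosine
baseline with an exact binomial test, Benjamini–Hochberg corrected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._seqcontext import CONTEXT_NAMES, classify_contexts, genome_context_counts
from ._util import BASES, SomacloneError
from .model import ReferenceModel

PYRIMIDINE_CLASSES = ["C→A", "C→G", "C→T", "T→A", "T→C", "T→G"]
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
TRANSITIONS_6 = {"C→T", "T→C"}


class SpectrumTable:
    """Counts by mutation class and sequence context with genomic normalizers."""

    def __init__(
        self,
        class6: pd.Series,
        class12: pd.Series,
        dinuc_counts: pd.Series,
        trinuc_counts: pd.DataFrame,
        genome_background: dict,
        n_edge_excluded: int = 0,
    ):
        self.class6 = class6
        self.class12 = class12
        self.dinuc_counts = dinuc_counts
        self.trinuc_counts = trinuc_counts
        self.genome_background = genome_background
        self.n_edge_excluded = n_edge_excluded
        if int(class6.sum()) != int(class12.sum()):
            raise SomacloneError("collapsed and uncollapsed class totals disagree")

    @property
    def total(self) -> int:
        return int(self.class6.sum())

    def percentages(self, decimals: int = 1) -> pd.Series:
        from ._util import percent

        tot = self.total
        return self.class6.map(lambda c: percent(c, tot, decimals) if tot else 0.0)


def collapse_class(ref: str, alt: str) -> str:
    """Strand-collapsed 6-class label for a substitution."""
    if ref in "GA":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}→{alt}"


def _genome_composition(ref: ReferenceModel) -> dict:
    base_counts = np.zeros(4, dtype=np.int64)
    dinuc = np.zeros(16, dtype=np.int64)
    trinuc = np.zeros(64, dtype=np.int64)
    for codes in ref.chroms.values():
        base_counts += np.bincount(codes, minlength=4)
        if len(codes) > 1:
            dinuc += np.bincount(4 * codes[:-1].astype(int) + codes[1:], minlength=16)
        if len(codes) > 2:
            trinuc += np.bincount(
                16 * codes[:-2].astype(int) + 4 * codes[1:-1].astype(int) + codes[2:],
                minlength=64,
            )
    total = base_counts.sum()
    return {
        "base_counts": dict(zip(BASES, base_counts.tolist())),
        "base_freq": dict(zip(BASES, (base_counts / total).tolist())),
        "gc_bases": int(base_counts[1] + base_counts[2]),
        "at_bases": int(base_counts[0] + base_counts[3]),
        "dinuc_counts": {
            BASES[i // 4] + BASES[i % 4]: int(c) for i, c in enumerate(dinuc)
        },
        "trinuc_counts": {
            BASES[i // 16] + BASES[(i // 4) % 4] + BASES[i % 4]: int(c)
            for i, c in enumerate(trinuc)
        },
        "context_counts": genome_context_counts(ref.chroms),
    }


def classify_spectrum(calls: pd.DataFrame, ref: ReferenceModel) -> SpectrumTable:
    """Tabulate SNV calls into 6/12 classes plus di- and trinucleotide contexts.

    Raises when a call's reference base disagrees with the reference sequence
    (coordinate drift). Trinucleotide contexts count the mutation at the
    first, second and third triplet position; dinucleotides count the left and
    right neighbor pair of each mutation. Sites too close to a chromosome end
    for a full window are excluded from context counts (but not from classes).
    """
    snvs = calls[calls["var_type"] == "SNV"] if "var_type" in calls else calls
    class12 = pd.Series(0, index=[f"{r}→{a}" for r in BASES for a in BASES if a != r])
    class6 = pd.Series(0, index=PYRIMIDINE_CLASSES)
    dinuc = {}
    trinuc_rows: dict[tuple[int, str], int] = {}
    n_edge = 0
    for _, row in snvs.iterrows():
        codes = ref.chroms[row["chrom"]]
        p = int(row["pos"]) - 1
        refb, altb = row["ref"], row["alt"]
        if BASES[codes[p]] != refb:
            raise SomacloneError(
                f"{row['chrom']}:{row['pos']}: call ref {refb} mismatches reference "
                f"{BASES[codes[p]]} (coordinate drift?)"
            )
        class12[f"{refb}→{altb}"] += 1
        class6[collapse_class(refb, altb)] += 1
        if 2 <= p <= len(codes) - 3:
            seq = "".join(BASES[c] for c in codes[p - 2 : p + 3])
            for tripos, triplet in ((1, seq[2:5]), (2, seq[1:4]), (3, seq[0:3])):
                trinuc_rows[(tripos, triplet)] = trinuc_rows.get((tripos, triplet), 0) + 1
            for pair in (seq[1:3], seq[2:4]):
                dinuc[pair] = dinuc.get(pair, 0) + 1
        else:
            n_edge += 1
    trinuc = pd.DataFrame(
        [(p, t, c) for (p, t), c in sorted(trinuc_rows.items())],
        columns=["triplet_position", "triplet", "count"],
    )
    return SpectrumTable(
        class6=class6,
        class12=class12,
        dinuc_counts=pd.Series(dinuc, dtype=int).sort_index(),
        trinuc_counts=trinuc,
        genome_background=_genome_composition(ref),
        n_edge_excluded=n_edge,
    )


def titv(table: SpectrumTable) -> float:
    """Transition/transversion ratio from the collapsed spectrum."""
    ti = sum(table.class6[c] for c in TRANSITIONS_6)
    tv = sum(table.class6[c] for c in PYRIMIDINE_CLASSES if c not in TRANSITIONS_6)
    if tv == 0:
        raise SomacloneError("Ti/Tv undefined: zero transversions")
    return ti / tv


def at_bias(table: SpectrumTable) -> float:
    """Per-base fold excess of G/C→A/T changes over A/T→G/C.

    Each direction's count is normalized by the genomic base content of its
    source class before taking the ratio.
    """
    gc_to_at = int(table.class6["C→T"] + table.class6["C→A"])
    at_to_gc = int(table.class6["T→C"] + table.class6["T→G"])
    bg = table.genome_background
    if at_to_gc == 0:
        raise SomacloneError("AT bias undefined: zero A/T→G/C mutations")
    return (gc_to_at / bg["gc_bases"]) / (at_to_gc / bg["at_bases"])


def context_enrichment(
    calls: pd.DataFrame, ref: ReferenceModel, fdr: float = 0.05
) -> pd.DataFrame:
    """Per-context mutation rate against the non-cytosine baseline.

    For each cytosine context c, rate(c) = mutated sites in c / genomic sites
    in c; ``enrichment`` divides by the non-C baseline rate (the class whose
    sites carry no methylation-linked elevation), and ``enrichment_vs_mean``
    divides by the genome-wide mean rate. Significance is an exact two-sided
    binomial test of the context's share of mutations against its share of
    (context + baseline) genomic sites, BH-corrected across contexts.
    """
    snvs = calls[calls["var_type"] == "SNV"] if "var_type" in calls else calls
    genome_counts = genome_context_counts(ref.chroms)
    mut_counts = dict.fromkeys(CONTEXT_NAMES, 0)
    n_excluded = 0
    for _, row in snvs.iterrows():
        codes = ref.chroms[row["chrom"]]
        p = int(row["pos"]) - 1
        if p < 2 or p > len(codes) - 3:
            n_excluded += 1
            continue
        label = CONTEXT_NAMES[int(classify_contexts(codes, np.array([p]))[0])]
        mut_counts[label] += 1

    total_mut = sum(mut_counts.values())
    total_sites = sum(genome_counts.values())
    mean_rate = total_mut / total_sites if total_sites else 0.0
    base_rate = (
        mut_counts["nonC"] / genome_counts["nonC"] if genome_counts["nonC"] else np.nan
    )

    rows = []
    for ctx in CONTEXT_NAMES:
        n_sites = genome_counts[ctx]
        n_mut = mut_counts[ctx]
        rate = n_mut / n_sites if n_sites else np.nan
        if ctx == "nonC" or n_sites == 0 or mut_counts["nonC"] + n_mut == 0:
            p_val = np.nan
        else:
            trials = n_mut + mut_counts["nonC"]
            p_null = n_sites / (n_sites + genome_counts["nonC"])
            p_val = stats.binomtest(n_mut, trials, p_null, alternative="two-sided").pvalue
        rows.append(
            {
                "context": ctx,
                "n_sites": n_sites,
                "n_mutations": n_mut,
                "rate": rate,
                "enrichment": rate / base_rate if base_rate else np.nan,
                "enrichment_vs_mean": rate / mean_rate if mean_rate else np.nan,
                "pvalue": p_val,
            }
        )
    df = pd.DataFrame(rows)
    tested = df["pvalue"].notna()
    qvals = np.full(len(df), np.nan)
    if tested.any():
        qvals[tested.to_numpy()] = stats.false_discovery_control(
            df.loc[tested, "pvalue"].to_numpy(), method="bh"
        )
    df["qvalue"] = qvals
    df["significant"] = df["qvalue"] < fdr
    df.attrs["n_edge_excluded"] = n_excluded
    return df


def trinucleotide_enrichment(table: SpectrumTable) -> pd.DataFrame:
    """Per-triplet mutation rate vs the genomic frequency of that triplet.

    Counts with the mutation at triplet position 1, 2 and 3 are each
    normalized by the genomic occurrences of the triplet (per-triplet
    background correction)."""
    bg = table.genome_background["trinuc_counts"]
    rows = []
    for _, row in table.trinuc_counts.iterrows():
        n_bg = bg.get(row["triplet"], 0)
        rows.append(
            {
                "triplet_position": row["triplet_position"],
                "triplet": row["triplet"],
                "count": row["count"],
                "genome_count": n_bg,
                "rate": row["count"] / n_bg if n_bg else np.nan,
            }
        )
    return pd.DataFrame(rows)


def flanking_composition(
    calls: pd.DataFrame, ref: ReferenceModel, max_dist: int
) -> pd.DataFrame:
    """A/T and C/G base proportions by distance from each mutation.

    For every distance d in [1, max_dist] both flanking bases (pos-d, pos+d)
    contribute; genome-wide AT/GC fractions are attached as baselines.
    """
    if max_dist < 1:
        raise SomacloneError("max_dist must be at least 1")
    snvs = calls[calls["var_type"] == "SNV"] if "var_type" in calls else calls
    at = np.zeros(max_dist, dtype=np.int64)
    gc = np.zeros(max_dist, dtype=np.int64)
    for chrom, sub in snvs.groupby("chrom"):
        codes = ref.chroms[chrom]
        pos0 = sub["pos"].to_numpy() - 1
        for d in range(1, max_dist + 1):
            for side in (pos0 - d, pos0 + d):
                ok = (side >= 0) & (side < len(codes))
                b = codes[side[ok]]
                gc[d - 1] += int(np.isin(b, (1, 2)).sum())
                at[d - 1] += int(np.isin(b, (0, 3)).sum())
    total = at + gc
    bg = _genome_composition(ref)
    genome_total = bg["gc_bases"] + bg["at_bases"]
    with np.errstate(invalid="ignore"):
        df = pd.DataFrame(
            {
                "distance": np.arange(1, max_dist + 1),
                "at_fraction": np.where(total > 0, at / np.maximum(total, 1), np.nan),
                "gc_fraction": np.where(total > 0, gc / np.maximum(total, 1), np.nan),
            }
        )
    df.attrs["genome_at_fraction"] = bg["at_bases"] / genome_total
    df.attrs["genome_gc_fraction"] = bg["gc_bases"] / genome_total
    return df
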