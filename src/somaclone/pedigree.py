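"""Derived-mutation polarization, sharing matrix, pedigree reconstruction and
the shared-mutation haplotype identity test.

Clonally propagated individuals inherit every mutation their parent plant
carried before the cutting was taken, so shared derived mutations define
nested clades and a greedy perfect-phylogeny pass recovers the cutting
pedigree. If a shared mutation truly predates the cut it must also sit on the
same haplotype in every carrier, which the phase-based identity test checks
against an already-phased genotype set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import SomacloneError, percent
from .model import PhasedGenotypes


# ---------------------------------------------------------------------------
# polarization


def polarize_derived(
    calls: pd.DataFrame,
    outgroup_a_gt: np.ndarray,
    outgroup_b_gt: np.ndarray,
) -> pd.DataFrame:
    """Assign ancestral/derived states from two outgroup genotypes per call.

    A call is polarizable only when both outgroups are homozygous for the same
    allele of the site; that allele is ancestral and the other is derived.
    Heterozygous or missing outgroup genotypes leave the call unpolarizable
    (flagged, excluded from derived-mutation analyses).
    """
    out = calls.copy()
    a = np.asarray(outgroup_a_gt)
    b = np.asarray(outgroup_b_gt)
    if len(a) != len(out) or len(b) != len(out):
        raise SomacloneError("outgroup genotype arrays must align with calls")
    polarizable = (a == b) & np.isin(a, (0, 2))
    ancestral = np.where(a == 0, out["ref"], out["alt"])
    derived = np.where(a == 0, out["alt"], out["ref"])
    out["polarizable"] = polarizable
    out["ancestral"] = np.where(polarizable, ancestral, None)
    out["derived"] = np.where(polarizable, derived, None)
    return out


# ---------------------------------------------------------------------------
# sharing matrix and pedigree


def sharing_matrix(calls: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Mutation x sample presence/absence matrix (index = call row order)."""
    mat = pd.DataFrame(False, index=calls.index, columns=samples)
    for idx, carriers in calls["carriers"].items():
        for s in str(carriers).split(","):
            if s in mat.columns:
                mat.at[idx, s] = True
    return mat


def pair_shared_counts(matrix: pd.DataFrame) -> pd.DataFrame:
    """Symmetric per-pair shared-mutation counts."""
    m = matrix.to_numpy().astype(int)
    shared = m.T @ m
    return pd.DataFrame(shared, index=matrix.columns, columns=matrix.columns)


@dataclass
class CladeNode:
    clade: frozenset
    parent: "CladeNode | None" = None
    children: list = field(default_factory=list)
    mutations: list = field(default_factory=list)

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)


@dataclass
class PedigreeTree:
    root: CladeNode
    homoplasy: list

    def nodes(self) -> list[CladeNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def leaf_mutation_counts(self) -> dict[str, int]:
        counts = {}

        def walk(node: CladeNode, acc: int) -> None:
            acc += node.n_mutations
            if not node.children and len(node.clade) == 1:
                counts[next(iter(node.clade))] = acc
            for c in node.children:
                walk(c, acc)

        walk(self.root, 0)
        return counts

    def branch_table(self) -> pd.DataFrame:
        rows = [
            {
                "clade": ",".join(sorted(n.clade)),
                "n_samples": len(n.clade),
                "n_mutations": n.n_mutations,
            }
            for n in self.nodes()
        ]
        return pd.DataFrame(rows).sort_values(
            ["n_samples", "clade"], ascending=[False, True]
        ).reset_index(drop=True)

    def newick(self) -> str:
        def fmt(node: CladeNode) -> str:
            if not node.children:
                label = next(iter(node.clade)) if len(node.clade) == 1 else "|".join(sorted(node.clade))
                return f"{label}:{node.n_mutations}"
            inner = ",".join(fmt(c) for c in sorted(node.children, key=lambda c: sorted(c.clade)))
            return f"({inner}):{node.n_mutations}"

        return fmt(self.root) + ";"


def build_pedigree(matrix: pd.DataFrame) -> PedigreeTree:
    """Greedy perfect-phylogeny reconstruction from a sharing matrix.

    Carrier sets are placed largest-first (ties in genomic/row order); a set is
    accepted when it nests with every clade placed so far (subset, superset or
    disjoint). Mutations whose carrier sets conflict with the accepted clade
    structure are reported as homoplasy and left unplaced. With no sharing the
    result is a star over the samples.
    """
    samples = list(matrix.columns)
    if len(samples) < 2:
        raise SomacloneError("pedigree reconstruction needs at least 2 samples")
    groups: dict[frozenset, list] = {}
    order: list[frozenset] = []
    for mut_id, row in matrix.iterrows():
        carriers = frozenset(matrix.columns[row.to_numpy().astype(bool)])
        if not carriers:
            continue
        if carriers not in groups:
            groups[carriers] = []
            order.append(carriers)
        groups[carriers].append(mut_id)

    all_set = frozenset(samples)
    accepted: dict[frozenset, list] = {all_set: []}
    homoplasy: list = []
    for carriers in sorted(order, key=lambda c: (-len(c), order.index(c))):
        muts = groups[carriers]
        if carriers == all_set:
            accepted[all_set].extend(muts)
            continue
        ok = all(
            carriers <= t or t <= carriers or not (carriers & t) for t in accepted
        )
        if ok:
            accepted.setdefault(carriers, []).extend(muts)
        else:
            homoplasy.extend(muts)
    for s in samples:  # every sample is a leaf even without private mutations
        accepted.setdefault(frozenset([s]), [])

    nodes = {c: CladeNode(clade=c, mutations=m) for c, m in accepted.items()}
    for clade, node in nodes.items():
        if clade == all_set:
            continue
        supersets = [c for c in nodes if clade < c]
        parent = min(supersets, key=len)
        node.parent = nodes[parent]
        nodes[parent].children.append(node)
    return PedigreeTree(root=nodes[all_set], homoplasy=homoplasy)


# ---------------------------------------------------------------------------
# haplotype identity test


def haplotype_identity_test(
    shared_calls: pd.DataFrame, phased: PhasedGenotypes
) -> pd.DataFrame:
    """Classify each shared call as same-haplotype / different / unphased.

    For every carrier the somatic allele is located on one haplotype of its
    phase block; the nearest heterozygous neighbor site that is phased in the
    same block for *all* carriers anchors the comparison. The call is
    same-haplotype when every carrier sees the same neighbor allele in phase
    with the somatic allele, different when orientations disagree, and
    unphased when no informative anchored neighbor exists. Single-carrier
    calls with an anchored neighbor are reported as 'phased' (cross-carrier
    identity needs at least two carriers).
    """
    v = phased.variants
    keys = v["chrom"].astype(str) + ":" + v["pos"].astype(str)
    key_to_idx = {k: i for i, k in enumerate(keys)}
    sample_to_col = {s: j for j, s in enumerate(phased.samples)}
    results = []
    for _, call in shared_calls.iterrows():
        carriers = [s for s in str(call["carriers"]).split(",") if s in sample_to_col]
        key = f"{call['chrom']}:{call['pos']}"
        idx = key_to_idx.get(key)
        status, neighbor = "unphased", None
        if idx is not None and len(carriers) >= 1:
            cols = [sample_to_col[s] for s in carriers]
            som_hap = {}
            phase_sets = {}
            for s, j in zip(carriers, cols):
                h = phased.hap[idx, j]
                ps = phased.ps[idx, j]
                if ps < 0 or set(h.tolist()) != {0, 1}:
                    som_hap = None
                    break
                som_hap[s] = int(np.flatnonzero(h == 1)[0])
                phase_sets[s] = int(ps)
            if som_hap is not None:
                status, neighbor = _scan_neighbors(
                    phased, idx, carriers, cols, som_hap, phase_sets, call["chrom"]
                )
                if len(carriers) == 1 and status == "same-haplotype":
                    status = "phased"  # co-phasing across carriers needs >= 2
        results.append(
            {
                "chrom": call["chrom"],
                "pos": call["pos"],
                "carriers": call["carriers"],
                "status": status,
                "neighbor_pos": neighbor,
            }
        )
    return pd.DataFrame(results)


def _scan_neighbors(phased, idx, carriers, cols, som_hap, phase_sets, chrom):
    """Nearest neighbor het site phased with the call in every carrier."""
    v = phased.variants
    same_chrom = np.flatnonzero((v["chrom"] == chrom).to_numpy())
    pos = v["pos"].to_numpy()
    order = same_chrom[np.argsort(np.abs(pos[same_chrom] - pos[idx]), kind="stable")]
    for q in order:
        if q == idx:
            continue
        orients = []
        informative = True
        for s, j in zip(carriers, cols):
            h = phased.hap[q, j]
            if (
                phased.ps[q, j] != phase_sets[s]
                or set(h.tolist()) != {0, 1}
            ):
                informative = False
                break
            orients.append(int(h[som_hap[s]]))
        if informative:
            if len(set(orients)) == 1:
                return "same-haplotype", int(pos[q])
            return "different", int(pos[q])
    return "unphased", None


# ---------------------------------------------------------------------------
# summaries


def sharing_summary(
    calls: pd.DataFrame, phase_status: pd.Series | None = None
) -> dict:
    """Counts of total / shared / sample-specific calls plus phased fractions.

    Fractions are percentages rounded to one decimal, half away from zero.
    """
    total = len(calls)
    shared = int(calls["shared"].sum()) if total else 0
    summary = {
        "total": total,
        "shared": shared,
        "sample_specific": total - shared,
        "pct_shared": percent(shared, total) if total else 0.0,
    }
    if phase_status is not None and total:
        phased_mask = phase_status.isin(["same-haplotype", "different", "phased"])
        summary["n_phased"] = int(phased_mask.sum())
        summary["pct_phased"] = percent(summary["n_phased"], total)
        summary["n_same_haplotype"] = int((phase_status == "same-haplotype").sum())
        summary["n_different"] = int((phase_status == "different").sum())
    elif phase_status is not None:
        summary.update(n_phased=0, pct_phased=0.0, n_same_haplotype=0, n_different=0)
    return summary
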