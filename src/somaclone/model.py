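"""In-memory containers shared across pipeline stages.

Coordinates are 0-based half-open internally; VCF emission/consumption converts
to 1-based. Genotypes at biallelic sites are coded on a single int8 axis:
-1 missing, 0 hom-ref, 1 het, 2 hom-alt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import decode_seq

INFO_FIELDS = ["FS", "MQ", "MQRankSum", "QD", "ReadPosRankSum", "SOR"]

GT_MISSING = -1
GT_HOMREF = 0
GT_HET = 1
GT_HOMALT = 2


@dataclass
class SiteTable:
    """Per-site, per-sample genotype matrix with depth, quality and strand counts.

    ``variants`` holds one row per biallelic site: chrom, pos (1-based), ref,
    alt, is_indel and the GATK-style INFO annotations used by the hard filters.
    Arrays are (n_sites, n_samples): ``gt`` genotype codes, ``dp`` total depth,
    ``gq`` genotype quality, ``alt_fwd``/``alt_rev`` strand-resolved read counts
    supporting the alternate allele.
    """

    samples: list[str]
    variants: pd.DataFrame
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    alt_fwd: np.ndarray
    alt_rev: np.ndarray
    n_multiallelic_excluded: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def keys(self) -> pd.Series:
        v = self.variants
        return (
            v["chrom"].astype(str)
            + ":"
            + v["pos"].astype(str)
            + ":"
            + v["ref"]
            + ":"
            + v["alt"]
        )

    def subset(self, mask: np.ndarray) -> "SiteTable":
        """New table restricted to sites where ``mask`` is True (order kept)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SiteTable(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            gt=self.gt[idx].copy(),
            dp=self.dp[idx].copy(),
            gq=self.gq[idx].copy(),
            alt_fwd=self.alt_fwd[idx].copy(),
            alt_rev=self.alt_rev[idx].copy(),
            n_multiallelic_excluded=self.n_multiallelic_excluded,
        )

    def copy(self) -> "SiteTable":
        return self.subset(np.ones(self.n_sites, dtype=bool))

    def alt_total(self) -> np.ndarray:
        return self.alt_fwd + self.alt_rev


@dataclass
class PhasedGenotypes:
    """Phased biallelic genotypes with phase-set identifiers.

    ``hap`` is (n_sites, n_samples, 2) with allele codes 0 (ref) / 1 (alt) /
    -1 (missing); ``ps`` is (n_sites, n_samples) phase-set ids, -1 when the
    genotype is unphased. Haplotype labels are arbitrary per (sample, phase
    set): only co-occurrence within a phase set is meaningful.
    """

    samples: list[str]
    variants: pd.DataFrame  # chrom, pos (1-based), ref, alt
    hap: np.ndarray
    ps: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.variants)


@dataclass
class ReferenceModel:
    """Simulated reference: sequences, annotation intervals and background het map.

    ``chroms`` maps name -> uint8 code array (0..3 = ACGT). ``annotations`` is
    a BED-like frame (chrom, start, end, feature; 0-based half-open) tiling the
    genome. ``het_sites`` lists founder heterozygous sites (chrom, pos0, ref,
    alt, hap) where ``hap`` is the founder haplotype carrying the alternate.
    """

    chroms: dict[str, np.ndarray]
    annotations: pd.DataFrame
    het_sites: pd.DataFrame
    gc_content: float

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chroms)

    @property
    def genome_length(self) -> int:
        return sum(len(c) for c in self.chroms.values())

    def sequence(self, chrom: str) -> str:
        return decode_seq(self.chroms[chrom])


@dataclass
class PedigreeNode:
    name: str
    parent: str | None
    children: list[str] = field(default_factory=list)
    years: float = 0.0  # branch length above this node


@dataclass
class PedigreeTruth:
    """Simulated cutting pedigree with per-branch mutation assignments.

    ``mutations`` has one row per event: mut_id, branch (node name whose
    subtending branch carries it), chrom, pos0, ref, alt, hap (haplotype of
    origin, 0/1), var_type ('SNV'/'indel'). A leaf inherits every mutation on
    the branches of its root path.
    """

    nodes: dict[str, PedigreeNode]
    root: str
    mutations: pd.DataFrame
    n_position_collisions: int = 0

    @property
    def leaves(self) -> list[str]:
        return [n for n, node in self.nodes.items() if not node.children]

    def root_path(self, leaf: str) -> list[str]:
        path = []
        cur: str | None = leaf
        while cur is not None:
            path.append(cur)
            cur = self.nodes[cur].parent
        return path

    def leaf_assignments(self) -> dict[str, np.ndarray]:
        """Leaf -> array of mut_ids inherited along its root path."""
        out = {}
        branch_col = self.mutations["branch"].to_numpy()
        ids = self.mutations["mut_id"].to_numpy()
        for leaf in self.leaves:
            on_path = np.isin(branch_col, self.root_path(leaf))
            out[leaf] = ids[on_path]
        return out

    def carriers(self) -> dict[int, frozenset[str]]:
        """mut_id -> set of leaves carrying the mutation."""
        assign = self.leaf_assignments()
        out: dict[int, set[str]] = {int(i): set() for i in self.mutations["mut_id"]}
        for leaf, ids in assign.items():
            for i in ids:
                out[int(i)].add(leaf)
        return {k: frozenset(v) for k, v in out.items()}


def annotation_of_positions(
    annotations: pd.DataFrame, chroms: Sequence[str], pos0: Sequence[int]
) -> np.ndarray:
    """Feature label for each (chrom, 0-based pos), from non-overlapping tiling intervals."""
    chroms = np.asarray(chroms)
    pos0 = np.asarray(pos0)
    out = np.full(len(pos0), "intergenic", dtype=object)
    for chrom, sub in annotations.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        feats = sub["feature"].to_numpy()
        idx = np.searchsorted(starts, pos0[sel], side="right") - 1
        ok = (idx >= 0) & (pos0[sel] < ends[np.clip(idx, 0, None)])
        lab = np.full(sel.sum(), "intergenic", dtype=object)
        lab[ok] = feats[idx[ok]]
        out[sel] = lab
    return out
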