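"""Polarization, perfect-phylogeny reconstruction and the haplotype test."""

import numpy as np
import pandas as pd
import pytest

from somaclone import (
    PhasedGenotypes,
    build_pedigree,
    haplotype_identity_test,
    pair_shared_counts,
    polarize_derived,
    sharing_matrix,
    sharing_summary,
)
from somaclone._util import SomacloneError


def _calls(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "carriers"])
    df["n_carriers"] = df["carriers"].str.split(",").str.len()
    df["shared"] = df["n_carriers"] >= 2
    df["var_type"] = "SNV"
    return df


class TestPolarize:
    def test_both_outgroups_homref_derived_is_alt(self):
        calls = _calls([("chr1", 100, "A", "G", "s1")])
        out = polarize_derived(calls, np.array([0]), np.array([0]))
        assert out["polarizable"].iloc[0]
        assert out["ancestral"].iloc[0] == "A" and out["derived"].iloc[0] == "G"

    def test_both_outgroups_homalt_derived_is_ref(self):
        calls = _calls([("chr1", 100, "A", "G", "s1")])
        out = polarize_derived(calls, np.array([2]), np.array([2]))
        assert out["derived"].iloc[0] == "A"

    @pytest.mark.parametrize("a,b", [(0, 2), (1, 1), (0, 1), (-1, 0)])
    def test_disagreeing_or_het_or_missing_unpolarizable(self, a, b):
        calls = _calls([("chr1", 100, "A", "G", "s1")])
        out = polarize_derived(calls, np.array([a]), np.array([b]))
        assert not out["polarizable"].iloc[0]
        assert out["derived"].iloc[0] is None


class TestBuildPedigree:
    def test_no_sharing_star_topology(self):
        calls = _calls(
            [("chr1", 10, "A", "G", "A"), ("chr1", 20, "A", "G", "B"), ("chr1", 30, "A", "G", "C")]
        )
        tree = build_pedigree(sharing_matrix(calls, ["A", "B", "C"]))
        assert len(tree.root.children) == 3
        assert all(len(c.clade) == 1 for c in tree.root.children)
        assert not tree.homoplasy

    def test_nested_clades_recovered(self):
        rows = []
        pos = 10
        for carriers, n in [("A,B,C,D", 3), ("A,B", 4), ("C,D", 2), ("A", 1), ("D", 2)]:
            for _ in range(n):
                rows.append(("chr1", pos, "A", "G", carriers))
                pos += 10
        calls = _calls(rows)
        tree = build_pedigree(sharing_matrix(calls, list("ABCD")))
        clades = {",".join(sorted(n.clade)): n.n_mutations for n in tree.nodes()}
        assert clades["A,B"] == 4 and clades["C,D"] == 2
        assert clades["A,B,C,D"] == 3
        assert tree.leaf_mutation_counts()["A"] == 3 + 4 + 1
        assert tree.leaf_mutation_counts()["D"] == 3 + 2 + 2

    def test_conflicting_carrier_sets_reported_as_homoplasy(self):
        calls = _calls(
            [("chr1", 10, "A", "G", "A,B"), ("chr1", 20, "A", "G", "B,C")]
        )
        tree = build_pedigree(sharing_matrix(calls, list("ABC")))
        assert len(tree.homoplasy) == 1

    def test_order_invariance_for_compatible_matrices(self):
        rows = []
        pos = 10
        for carriers in ["A,B", "A,B,C,D", "C,D", "A", "B", "C", "D", "A,B", "C,D"]:
            rows.append(("chr1", pos, "A", "G", carriers))
            pos += 10
        calls = _calls(rows)
        base = build_pedigree(sharing_matrix(calls, list("ABCD"))).branch_table()
        rng = np.random.default_rng(3)
        for _ in range(5):
            perm = calls.sample(frac=1.0, random_state=int(rng.integers(1e6))).reset_index(drop=True)
            got = build_pedigree(sharing_matrix(perm, list("ABCD"))).branch_table()
            pd.testing.assert_frame_equal(base, got)

    def test_single_sample_rejected(self):
        calls = _calls([("chr1", 10, "A", "G", "A")])
        with pytest.raises(SomacloneError):
            build_pedigree(sharing_matrix(calls, ["A"]))

    def test_pair_counts_symmetric(self):
        calls = _calls([("chr1", 10, "A", "G", "A,B"), ("chr1", 20, "A", "G", "B,C")])
        counts = pair_shared_counts(sharing_matrix(calls, list("ABC")))
        assert counts.at["A", "B"] == counts.at["B", "A"] == 1


def _phased(positions, hap_matrix, ps_matrix, samples=("s1", "s2")):
    """hap_matrix: list over sites of list over samples of (h0, h1)."""
    variants = pd.DataFrame(
        {"chrom": "chr1", "pos": positions, "ref": "A", "alt": "G"}
    )
    return PhasedGenotypes(
        samples=list(samples),
        variants=variants,
        hap=np.array(hap_matrix, dtype=np.int8),
        ps=np.array(ps_matrix, dtype=np.int32),
    )


class TestHaplotypeIdentity:
    def test_same_orientation_in_both_carriers(self):
        # somatic at pos 100 on hap carrying the neighbor's alt in both samples
        phased = _phased(
            [100, 150],
            [
                [(1, 0), (0, 1)],  # somatic allele on h0 (s1) / h1 (s2)
                [(1, 0), (0, 1)],  # neighbor alt co-phased the same way
            ],
            [[1, 1], [1, 1]],
        )
        calls = _calls([("chr1", 100, "A", "G", "s1,s2")])
        res = haplotype_identity_test(calls, phased)
        assert res["status"].iloc[0] == "same-haplotype"
        assert res["neighbor_pos"].iloc[0] == 150

    def test_opposite_orientation_is_different(self):
        phased = _phased(
            [100, 150],
            [
                [(1, 0), (0, 1)],
                [(1, 0), (1, 0)],  # neighbor alt on the opposite phase in s2
            ],
            [[1, 1], [1, 1]],
        )
        calls = _calls([("chr1", 100, "A", "G", "s1,s2")])
        res = haplotype_identity_test(calls, phased)
        assert res["status"].iloc[0] == "different"

    def test_no_het_neighbor_in_block_is_unphased(self):
        phased = _phased(
            [100, 150],
            [
                [(1, 0), (0, 1)],
                [(1, 1), (1, 1)],  # neighbor homozygous: uninformative
            ],
            [[1, 1], [1, 1]],
        )
        calls = _calls([("chr1", 100, "A", "G", "s1,s2")])
        res = haplotype_identity_test(calls, phased)
        assert res["status"].iloc[0] == "unphased"

    def test_carriers_in_different_phase_blocks_unphased(self):
        phased = _phased(
            [100, 150],
            [
                [(1, 0), (0, 1)],
                [(1, 0), (0, 1)],
            ],
            [[1, 1], [1, 2]],  # s2's neighbor sits in another phase set
        )
        calls = _calls([("chr1", 100, "A", "G", "s1,s2")])
        res = haplotype_identity_test(calls, phased)
        assert res["status"].iloc[0] == "unphased"

    def test_nearest_informative_neighbor_wins(self):
        phased = _phased(
            [100, 120, 400],
            [
                [(1, 0), (0, 1)],
                [(1, 0), (0, 1)],  # near neighbor agrees
                [(1, 0), (1, 0)],  # far neighbor would disagree
            ],
            [[1, 1], [1, 1], [1, 1]],
        )
        calls = _calls([("chr1", 100, "A", "G", "s1,s2")])
        res = haplotype_identity_test(calls, phased)
        assert res["status"].iloc[0] == "same-haplotype"
        assert res["neighbor_pos"].iloc[0] == 120


class TestSharingSummary:
    def test_counts_and_percentages(self):
        rows = [("chr1", 10 * i, "A", "G", "s1,s2" if i < 3 else "s1") for i in range(10)]
        calls = _calls(rows)
        summary = sharing_summary(calls)
        assert summary["total"] == 10
        assert summary["shared"] == 3
        assert summary["sample_specific"] == 7
        assert summary["pct_shared"] == 30.0

    def test_phased_fraction_rounding(self):
        calls = _calls([("chr1", 10 * i, "A", "G", "s1") for i in range(7)])
        status = pd.Series(
            ["phased", "phased", "phased", "same-haplotype", "unphased", "unphased", "unphased"]
        )
        summary = sharing_summary(calls, status)
        assert summary["n_phased"] == 4
        assert summary["pct_phased"] == 57.1  # 4/7 = 57.14...

    def test_empty_input(self):
        calls = _calls([])
        summary = sharing_summary(calls, pd.Series(dtype=object))
        assert summary["total"] == 0 and summary["pct_shared"] == 0.0
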