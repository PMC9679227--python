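"""Somatic caller: strand gating, founder/transition logic, SV masking, indel QC."""

import numpy as np
import pandas as pd
import pytest

from somaclone import (
    call_somatic,
    indel_somatic_filter,
    strand_filter,
    sv_mask,
)
from somaclone.calling import TRANSITIONS, StrandCounts
from somaclone.simulate import (
    SimConfig,
    simulate_genome,
    simulate_mutations,
    simulate_site_table,
    truth_calls,
)

from conftest import make_table


class TestStrandFilter:
    @pytest.mark.parametrize(
        "fwd,rev,passes",
        [
            (3, 2, True),    # ratio 1.5
            (4, 2, False),   # ratio exactly 2 is not < 2
            (5, 0, False),   # single-strand support
            (0, 5, False),
            (1, 1, True),
            (7, 4, True),
        ],
    )
    def test_bias_rule(self, fwd, rev, passes):
        assert strand_filter(StrandCounts(fwd, rev)) is passes
        assert strand_filter((fwd, rev)) is passes

    def test_missing_counts_fail(self):
        assert strand_filter(None) is False


class TestCallSomatic:
    def test_uniform_genotypes_not_somatic(self):
        table = make_table([[1, 1, 1, 1], [0, 0, 0, 0]])
        assert call_somatic(table).empty

    def test_single_carrier_hom_to_het(self):
        table = make_table([[0, 0, 1, 0]])
        calls = call_somatic(table)
        assert len(calls) == 1
        row = calls.iloc[0]
        assert row["carriers"] == "s3"
        assert row["transition"] == "hom→het"
        assert not row["shared"]

    def test_two_carriers_shared(self):
        table = make_table([[1, 1, 0, 0, 0]])
        calls = call_somatic(table)
        assert calls.iloc[0]["shared"]
        assert calls.iloc[0]["carriers"] == "s1,s2"

    def test_het_to_hom_requires_zero_residual_reads(self):
        # carrier called 0/0 at a majority-het site: residual alt reads veto it
        gt = np.array([[0, 1, 1, 1]], dtype=np.int8)
        table = make_table(gt.tolist())
        table.alt_fwd[0, 0] = 1  # one stray alt read in the would-be carrier
        table.alt_rev[0, 0] = 0
        assert call_somatic(table).empty
        table.alt_fwd[0, 0] = 0
        calls = call_somatic(table)
        assert calls.iloc[0]["transition"] == "het→hom"

    def test_gained_allele_needs_both_strands(self):
        table = make_table([[0, 0, 1, 0]])
        i = 0
        j = 2
        table.alt_rev[i, j] = 0  # all alt reads on one strand
        assert call_somatic(table).empty
        assert len(call_somatic(table, require_support=False)) == 1

    def test_transition_classes_partition_calls(self):
        table = make_table([[0, 0, 0, 1], [1, 1, 1, 0], [2, 2, 2, 1], [0, 0, 0, 2]])
        calls = call_somatic(table)
        assert len(calls) == 4
        assert calls["transition"].isin(TRANSITIONS).all()
        assert calls["transition"].value_counts().sum() == len(calls)

    def test_annotation_partition(self):
        ann = pd.DataFrame(
            [("chr1", 0, 105, "exon"), ("chr1", 105, 125, "intron"),
             ("chr1", 125, 1000, "intergenic")],
            columns=["chrom", "start", "end", "feature"],
        )
        table = make_table([[0, 1]] * 3, pos=[100, 110, 130])
        calls = call_somatic(table, annotations=ann)
        assert list(calls["annotation"]) == ["exon", "intron", "intergenic"]

    def test_perfect_data_recovers_truth_exactly(self):
        """With no sequencing error and deep coverage, recall is 1 and there
        are no false calls."""
        cfg = SimConfig(
            genome_length=300_000, n_chromosomes=1, het_density=2.0,
            pedigree_newick="((A:30,B:30):37,C:67,D:67):0;",
            snv_rate=3e-7, indel_rate=0.0, seq_error=0.0, mean_depth=120.0,
            strand_imbalance_sd=0.0, n_replicate_samples=0, seed=17,
        )
        ref = simulate_genome(cfg)
        truth = simulate_mutations(ref, cfg)
        sites, _ = simulate_site_table(truth, ref, cfg)
        calls = call_somatic(sites)
        expected = truth_calls(truth)
        got = set(zip(calls["chrom"], calls["pos"], calls["carriers"]))
        want = set(zip(expected["chrom"], expected["pos"], expected["carriers"]))
        assert got == want


class TestSvMask:
    def _calls(self, positions):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": positions,
                "ref": "A",
                "alt": "G",
                "var_type": "SNV",
                "carriers": "s1",
                "n_carriers": 1,
                "shared": False,
            }
        )

    def test_majority_support_is_strict(self):
        iv = pd.DataFrame([("chr1", 100, 200)], columns=["chrom", "start", "end"])
        calls = self._calls([150])
        six = {f"s{i}": iv for i in range(6)}
        five = {f"s{i}": iv for i in range(5)}
        masked, _ = sv_mask(calls, six, n_samples=11)
        assert masked.empty  # 6/11 > half: mask active
        kept, _ = sv_mask(calls, five, n_samples=11)
        assert len(kept) == 1  # 5/11 is not more than half

    def test_boundary_base_is_masked(self):
        iv = pd.DataFrame([("chr1", 100, 200)], columns=["chrom", "start", "end"])
        svs = {f"s{i}": iv for i in range(3)}
        calls = self._calls([101, 200, 201])  # 1-based: first and last covered base, then outside
        kept, _ = sv_mask(calls, svs, n_samples=3)
        assert list(kept["pos"]) == [201]

    def test_no_sv_input_is_identity(self):
        calls = self._calls([10, 20])
        kept, masks = sv_mask(calls, {}, n_samples=4)
        pd.testing.assert_frame_equal(kept, calls)
        assert masks.empty


class TestIndelFilter:
    @pytest.mark.parametrize("reads,kept", [(4, False), (5, True)])
    def test_read_count_boundary(self, reads, kept):
        table = make_table(
            [[1]], refs=["AT"], alts=["A"], is_indel=True, dp=np.array([[reads]])
        )
        out = indel_somatic_filter(table)
        assert (out.n_sites == 1) == kept

    def test_missing_rate_boundary_is_strict(self):
        # 10 samples, exactly 10% missing is retained
        gt = [[1] * 9 + [-1]]
        table = make_table(gt, refs=["AT"], alts=["A"], is_indel=True)
        assert indel_somatic_filter(table).n_sites == 1
        gt = [[1] * 8 + [-1, -1]]
        table = make_table(gt, refs=["AT"], alts=["A"], is_indel=True)
        assert indel_somatic_filter(table).n_sites == 0

    def test_empty_input(self):
        table = make_table([[1, 1]], is_indel=False)
        out = indel_somatic_filter(table)
        assert out.n_sites == 1  # SNVs pass through untouched
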