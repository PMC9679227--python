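"""Spectrum classification, Ti/Tv, AT bias, methylation contexts, flanks."""

import numpy as np
import pandas as pd
import pytest

from somaclone import (
    SpectrumTable,
    at_bias,
    classify_spectrum,
    collapse_class,
    context_enrichment,
    flanking_composition,
    titv,
    trinucleotide_enrichment,
)
from somaclone._seqcontext import CONTEXT_NAMES, classify_contexts
from somaclone._util import SomacloneError, encode_seq

from conftest import make_ref


def _calls(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "var_type"])


class TestClassification:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("G", "A", "C→T"), ("C", "T", "C→T"), ("A", "C", "T→G"), ("T", "A", "T→A")],
    )
    def test_purine_changes_collapse_to_pyrimidine(self, ref, alt, expected):
        assert collapse_class(ref, alt) == expected

    def test_counts_and_contexts_on_toy_sequence(self):
        ref = make_ref("AACGTACGTT")
        calls = _calls([("chr1", 4, "G", "A", "SNV"), ("chr1", 5, "T", "C", "SNV")])
        table = classify_spectrum(calls, ref)
        assert table.total == 2
        assert table.class6["C→T"] == 1 and table.class6["T→C"] == 1
        # each interior SNV contributes its left and right dinucleotide
        assert int(table.dinuc_counts.sum()) == 4
        assert len(table.trinuc_counts) > 0

    def test_reference_mismatch_raises(self):
        ref = make_ref("AACGTACGTT")
        calls = _calls([("chr1", 4, "T", "A", "SNV")])  # reference base there is G
        with pytest.raises(SomacloneError, match="drift"):
            classify_spectrum(calls, ref)

    def test_empty_calls_all_zero(self):
        table = classify_spectrum(_calls([]), make_ref("ACGTACGTAC"))
        assert table.total == 0
        assert (table.class6 == 0).all()

    def test_complement_invariance(self):
        """Reverse-complementing the genome and the calls leaves the collapsed
        spectrum unchanged."""
        seq = "AACGTTGACCGTAGGCTAAC"
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))
        calls = _calls(
            [("chr1", 4, "G", "A", "SNV"), ("chr1", 8, "A", "C", "SNV"),
             ("chr1", 15, "G", "T", "SNV")]
        )
        rc_calls = _calls(
            [
                ("chr1", len(seq) - int(r["pos"]) + 1, comp[r["ref"]], comp[r["alt"]], "SNV")
                for _, r in calls.iterrows()
            ]
        )
        t1 = classify_spectrum(calls, make_ref(seq))
        t2 = classify_spectrum(rc_calls, make_ref(rc))
        pd.testing.assert_series_equal(t1.class6, t2.class6)


class TestRatios:
    def _table(self, class6_counts):
        class6 = pd.Series(class6_counts)
        class12 = pd.Series(0, index=[f"{r}→{a}" for r in "ACGT" for a in "ACGT" if r != a])
        class12["C→T"] = class6.get("C→T", 0)
        class12["C→A"] = class6.get("C→A", 0)
        class12["C→G"] = class6.get("C→G", 0)
        class12["T→A"] = class6.get("T→A", 0)
        class12["T→C"] = class6.get("T→C", 0)
        class12["T→G"] = class6.get("T→G", 0)
        return SpectrumTable(
            class6=class6.reindex(["C→A", "C→G", "C→T", "T→A", "T→C", "T→G"], fill_value=0),
            class12=class12,
            dinuc_counts=pd.Series(dtype=int),
            trinuc_counts=pd.DataFrame(columns=["triplet_position", "triplet", "count"]),
            genome_background={"gc_bases": 400, "at_bases": 600},
        )

    def test_titv_balanced(self):
        table = self._table({"C→T": 1, "T→C": 1, "C→A": 1, "T→G": 1})
        assert titv(table) == 1.0

    def test_titv_matches_printed_form(self):
        table = self._table({"C→T": 100, "T→C": 64, "C→A": 40, "C→G": 20, "T→A": 25, "T→G": 15})
        assert titv(table) == pytest.approx(1.64)

    def test_titv_undefined_without_transversions(self):
        with pytest.raises(SomacloneError):
            titv(self._table({"C→T": 5}))

    def test_at_bias_toy_genome(self):
        # GC fraction 0.4: (20/400) / (5/600) = 6.0
        table = self._table({"C→T": 12, "C→A": 8, "T→C": 3, "T→G": 2})
        assert at_bias(table) == pytest.approx(6.0)

    def test_at_bias_equal_per_base_rates(self):
        table = self._table({"C→T": 4, "T→C": 6})  # 4/400 == 6/600
        assert at_bias(table) == pytest.approx(1.0)

    def test_at_bias_undefined_without_reverse_direction(self):
        with pytest.raises(SomacloneError):
            at_bias(self._table({"C→T": 5}))


class TestContexts:
    def test_context_definitions(self):
        codes = encode_seq("ACGACTACA")
        # C at index 1 followed by G -> CpG; C at index 4 in C,T,A -> CHH;
        # C at index 6 in C,A,? ... index 6 is A? spell: A C G A C T A C A
        labels = [CONTEXT_NAMES[i] for i in classify_contexts(codes, np.array([1, 4, 7]))]
        assert labels[0] == "CpG"
        assert labels[1] == "CHH"

    def test_g_sites_use_minus_strand_context(self):
        # C G at indices 1,2: the G is a CpG site seen from the minus strand
        codes = encode_seq("ACGTT")
        assert CONTEXT_NAMES[int(classify_contexts(codes, np.array([2]))[0])] == "CpG"

    def test_chg_symmetry(self):
        codes = encode_seq("ACTGA")  # C at 1: C,T,G -> CHG; G at 3: minus-strand CHG
        assert CONTEXT_NAMES[int(classify_contexts(codes, np.array([1]))[0])] == "CHG"
        assert CONTEXT_NAMES[int(classify_contexts(codes, np.array([3]))[0])] == "CHG"

    def test_neutral_mutations_show_no_enrichment(self):
        from somaclone.simulate import SimConfig, simulate_genome, simulate_mutations, truth_calls

        cfg = SimConfig(
            genome_length=1_000_000, n_chromosomes=1, het_density=0.0,
            pedigree_newick="(A:67):0;", snv_rate=8e-6, indel_rate=0.0,
            context_multipliers={"CpG": 1.0, "CHG": 1.0, "CHH": 1.0, "nonC": 1.0},
            n_replicate_samples=0, seed=31,
        )
        ref = simulate_genome(cfg)
        truth = simulate_mutations(ref, cfg)
        enr = context_enrichment(truth_calls(truth), ref)
        tested = enr[enr["context"] != "nonC"]
        assert not tested["significant"].any()
        # ~1000 mutations, ~65 in the rarest class: 4 binomial SEs is ~0.5
        assert tested["enrichment"].between(0.55, 1.45).all()

    def test_trinucleotide_rates_are_background_corrected(self):
        ref = make_ref("ACGTACGTACGTACGT")
        calls = _calls([("chr1", 5, "A", "G", "SNV")])
        table = classify_spectrum(calls, ref)
        tri = trinucleotide_enrichment(table)
        assert (tri["genome_count"] > 0).all()
        assert np.isfinite(tri["rate"]).all()


class TestFlanking:
    def test_uniform_mutations_flat_profile(self):
        from somaclone.simulate import SimConfig, simulate_genome, simulate_mutations, truth_calls

        cfg = SimConfig(
            genome_length=500_000, n_chromosomes=1, gc_content=0.5, het_density=0.0,
            pedigree_newick="(A:67):0;", snv_rate=1e-6, indel_rate=0.0,
            context_multipliers={"CpG": 1.0, "CHG": 1.0, "CHH": 1.0, "nonC": 1.0},
            n_replicate_samples=0, seed=37,
        )
        ref = simulate_genome(cfg)
        truth = simulate_mutations(ref, cfg)
        prof = flanking_composition(truth_calls(truth), ref, max_dist=10)
        assert prof["gc_fraction"].between(0.45, 0.55).all()
        assert prof.attrs["genome_gc_fraction"] == pytest.approx(0.5, abs=0.01)

    def test_zero_max_dist_rejected(self):
        with pytest.raises(SomacloneError):
            flanking_composition(_calls([]), make_ref("ACGTACGT"), max_dist=0)
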