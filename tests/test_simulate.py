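"""Generator behaviour: genome composition, Poisson accumulation, read model,
determinism and the clonal-inheritance invariants of the simulated truth."""

import numpy as np
import pandas as pd
import pytest

from somaclone import (
    SimConfig,
    expected_branch_snvs,
    simulate_genome,
    simulate_mutations,
    simulate_site_table,
)
from somaclone._util import SomacloneError
from somaclone.simulate import truth_calls


def _cfg(**kw):
    base = dict(
        genome_length=200_000,
        n_chromosomes=1,
        het_density=1.0,
        pedigree_newick="(A:67,B:67):0;",
        snv_rate=1e-7,
        indel_rate=0.0,
        n_replicate_samples=0,
        seed=5,
    )
    base.update(kw)
    return SimConfig(**base)


class TestGenome:
    def test_gc_content_matches_target(self):
        ref = simulate_genome(_cfg(genome_length=1_000_000, gc_content=0.5))
        assert 0.497 <= ref.gc_content <= 0.503

    def test_zero_het_density_gives_no_background_sites(self):
        ref = simulate_genome(_cfg(het_density=0.0))
        assert len(ref.het_sites) == 0

    def test_annotation_fractions_are_exact(self):
        ref = simulate_genome(
            _cfg(genome_length=1_000_000, annotation_fractions=(0.1, 0.3, 0.6))
        )
        spans = ref.annotations.assign(bp=lambda d: d.end - d.start).groupby("feature")["bp"].sum()
        assert abs(spans["exon"] - 100_000) <= 2
        assert abs(spans["intron"] - 300_000) <= 2
        assert spans.sum() == 1_000_000

    def test_annotation_intervals_tile_without_overlap(self):
        ref = simulate_genome(_cfg())
        for _, sub in ref.annotations.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()
            assert sub["start"].iloc[0] == 0

    def test_short_genome_rejected(self):
        with pytest.raises(SomacloneError, match="1 kb"):
            simulate_genome(_cfg(genome_length=500))

    def test_bad_fractions_rejected(self):
        with pytest.raises(SomacloneError, match="sum to 1"):
            simulate_genome(_cfg(annotation_fractions=(0.5, 0.5, 0.5)))


class TestMutations:
    def test_expected_count_matches_study_scale(self):
        # rate 1e-8 over 67 years on a 408 Mb diploid genome
        mean = expected_branch_snvs(
            SimConfig(snv_rate=1e-8, genome_length=408_000_000), 67.0
        )
        assert mean == pytest.approx(546.72, rel=1e-9)

    def test_branch_count_is_poisson_at_stated_mean(self):
        # same rate-per-bp-year at 1/10 scale; one draw within 3 sigma
        cfg = _cfg(
            genome_length=40_800_000, n_chromosomes=4, snv_rate=1e-8,
            het_density=0.0, pedigree_newick="(A:67):0;", seed=42,
        )
        ref = simulate_genome(cfg)
        truth = simulate_mutations(ref, cfg)
        mean = 1e-8 * 67 * 2 * 40_800_000
        assert abs(len(truth.mutations) - mean) <= 3 * np.sqrt(mean)

    def test_zero_rate_zero_mutations(self):
        cfg = _cfg(snv_rate=0.0, indel_rate=0.0)
        ref = simulate_genome(cfg)
        truth = simulate_mutations(ref, cfg)
        assert len(truth.mutations) == 0

    def test_star_pedigree_stem_mutations_shared_by_all(self):
        cfg = _cfg(
            pedigree_newick="((A:10,B:10,C:10,D:10):57):0;",
            snv_rate=5e-7,
        )
        ref = simulate_genome(cfg)
        truth = simulate_mutations(ref, cfg)
        stem = [n for n in truth.nodes.values() if n.children and n.parent is not None]
        assert len(stem) == 1
        stem_ids = set(
            truth.mutations.loc[truth.mutations["branch"] == stem[0].name, "mut_id"]
        )
        assert stem_ids, "stem branch must carry mutations at this rate"
        assign = truth.leaf_assignments()
        for leaf in "ABCD":
            assert stem_ids <= set(assign[leaf])

    def test_positions_unique_within_lineage(self):
        cfg = _cfg(snv_rate=1e-6)
        ref = simulate_genome(cfg)
        truth = simulate_mutations(ref, cfg)
        keys = truth.mutations[["chrom", "pos0"]].apply(tuple, axis=1)
        assert keys.is_unique

    def test_shared_mutation_single_branch_single_haplotype(self):
        """A mutation carried by several leaves lives on one ancestral branch
        and one haplotype — the clonal-inheritance invariant."""
        cfg = _cfg(pedigree_newick="((A:30,B:30):37,C:67):0;", snv_rate=5e-7)
        ref = simulate_genome(cfg)
        truth = simulate_mutations(ref, cfg)
        carriers = truth.carriers()
        m = truth.mutations.set_index("mut_id")
        for mid, carr in carriers.items():
            assert len(carr) >= 1
            if len(carr) >= 2:
                branch = m.at[mid, "branch"]
                # the branch must be ancestral to every carrier
                for leaf in carr:
                    assert branch in truth.root_path(leaf)
                assert m.at[mid, "hap"] in (0, 1)


class TestReads:
    def test_no_alt_reads_without_error_at_homref_sites(self):
        cfg = _cfg(seq_error=0.0, mean_depth=100.0, snv_rate=2e-7)
        ref = simulate_genome(cfg)
        truth = simulate_mutations(ref, cfg)
        sites, _ = simulate_site_table(truth, ref, cfg)
        calls = truth_calls(truth)
        for _, row in calls.iterrows():
            i = sites.variants.index[
                (sites.variants["chrom"] == row["chrom"])
                & (sites.variants["pos"] == row["pos"])
            ][0]
            carr = set(row["carriers"].split(","))
            for j, s in enumerate(sites.samples):
                if s not in carr:
                    assert sites.alt_total()[i, j] == 0

    def test_het_alt_fraction_concentrates_near_half(self):
        cfg = _cfg(mean_depth=40.0, het_density=5.0, snv_rate=0.0)
        ref = simulate_genome(cfg)
        truth = simulate_mutations(ref, cfg)
        sites, _ = simulate_site_table(truth, ref, cfg)
        frac = sites.alt_total() / np.maximum(sites.dp, 1)
        inside = (frac >= 0.30) & (frac <= 0.70)
        assert inside.mean() >= 0.95

    def test_same_seed_identical_tables(self):
        cfg = _cfg(n_replicate_samples=1)
        ref = simulate_genome(cfg)
        truth = simulate_mutations(ref, cfg)
        a, ra = simulate_site_table(truth, ref, cfg)
        b, rb = simulate_site_table(truth, ref, cfg)
        assert np.array_equal(a.gt, b.gt)
        assert np.array_equal(a.dp, b.dp)
        assert np.array_equal(a.alt_fwd, b.alt_fwd)
        pd.testing.assert_frame_equal(a.variants, b.variants)
        assert np.array_equal(ra["A"][0].gt, rb["A"][0].gt)

    def test_replicates_share_truth_but_not_reads(self):
        cfg = _cfg(n_replicate_samples=1, het_density=4.0)
        ref = simulate_genome(cfg)
        truth = simulate_mutations(ref, cfg)
        _, reps = simulate_site_table(truth, ref, cfg)
        r1, r2 = reps["A"][0], reps["A"][1]
        assert not np.array_equal(r1.dp, r2.dp)
        # called genotypes agree at nearly all sites (same underlying truth)
        both = (r1.gt >= 0) & (r2.gt >= 0)
        assert (r1.gt[both] == r2.gt[both]).mean() > 0.99


def test_neutral_context_spectrum_is_uniform():
    """With all context multipliers 1 on a 50% GC genome the six collapsed
    mutation classes are uniform within multinomial sampling error."""
    from somaclone import classify_spectrum

    cfg = _cfg(
        genome_length=2_000_000, gc_content=0.5, het_density=0.0,
        snv_rate=1.5e-6, pedigree_newick="(A:67):0;",
        context_multipliers={"CpG": 1.0, "CHG": 1.0, "CHH": 1.0, "nonC": 1.0},
        seed=13,
    )
    ref = simulate_genome(cfg)
    truth = simulate_mutations(ref, cfg)
    table = classify_spectrum(truth_calls(truth), ref)
    counts = table.class6.to_numpy()
    from scipy import stats

    p = stats.chisquare(counts).pvalue
    assert p > 1e-3, f"spectrum not uniform: {table.class6.to_dict()} (p={p:.2g})"
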