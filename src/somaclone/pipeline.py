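"""Stage orchestration: simulate -> filter -> call -> errors -> rate, with the
spectrum/context/pedigree/selection analyses branching off the somatic calls.

``run_pipeline`` is file-based: each stage reads the standard-format artifacts
its predecessors wrote (so the exchange formats are exercised end to end) and
every output is recorded in a provenance log with input checksums and
parameters. ``recover_rate`` is the in-memory equivalent of the
calibration+estimation path, used for simulation studies where file round
trips would only add time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import PipelineError, percent
from . import io as sio
from .calling import call_somatic, indel_somatic_filter, majority_genotypes, sample_variant_sites, sv_mask
from .context import ContextConfig, het_vs_distance, recomb_regression
from .errors import ErrorRates, estimate_fp, spike_in_sensitivity
from .filters import FilterConfig, apply_hard_filters, apply_site_postfilters
from .model import SiteTable
from .pedigree import (
    build_pedigree,
    haplotype_identity_test,
    pair_shared_counts,
    polarize_derived,
    sharing_matrix,
    sharing_summary,
)
from .rates import RateInputs, bootstrap_ci, per_sample_counts, point_rate
from .selection import (
    classify_selection,
    deleterious_pattern_report,
    score_table_consensus,
)
from .simulate import SimConfig, parse_pedigree, simulate_all
from .spectrum import at_bias, classify_spectrum, context_enrichment, flanking_composition, titv

logger = logging.getLogger(__name__)

ALL_STAGES = [
    "simulate", "filter", "call", "errors", "rate",
    "spectrum", "context", "pedigree", "selection",
]
STAGE_DEPS = {
    "filter": ["simulate"],
    "call": ["filter"],
    "errors": ["simulate", "call"],
    "rate": ["call", "errors"],
    "spectrum": ["call", "simulate"],
    "context": ["call", "filter", "simulate"],
    "pedigree": ["call", "simulate"],
    "selection": ["call", "simulate"],
}


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    context: ContextConfig = field(default_factory=ContextConfig)
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in ALL_STAGES})
    years: float | None = None  # elapsed propagation years; default from pedigree
    rounding_decimals: int = 1

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_kwargs = raw.pop("sim", {})
        if "annotation_fractions" in sim_kwargs:
            sim_kwargs["annotation_fractions"] = tuple(sim_kwargs["annotation_fractions"])
        sim = SimConfig(**sim_kwargs)
        stages = {s: True for s in ALL_STAGES}
        stages.update(raw.pop("stages", {}))
        cfg = cls(
            outdir=raw.pop("outdir", "somaclone-out"),
            seed=raw.pop("seed", 0),
            sim=sim,
            stages=stages,
            years=raw.pop("years", None),
        )
        cfg.sim.seed = cfg.seed
        return cfg


def pedigree_years(newick: str) -> float:
    """Mean root-to-leaf path length (years) of the propagation pedigree."""
    nodes = parse_pedigree(newick)
    leaves = [n for n, node in nodes.items() if not node.children]
    spans = []
    for leaf in leaves:
        total, cur = 0.0, leaf
        while cur is not None:
            total += nodes[cur].years
            cur = nodes[cur].parent
        spans.append(total)
    return float(np.mean(spans))


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Holds per-stage artifact paths and the provenance record."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.artifacts: dict[str, Path] = {}
        self.provenance: dict = {"seed": config.seed, "stages": {}}

    def path(self, name: str) -> Path:
        return self.outdir / name

    def record(self, stage: str, inputs: list[Path], outputs: list[Path], params: dict):
        self.provenance["stages"][stage] = {
            "inputs": {p.name: _md5(p) for p in inputs if p.exists()},
            "outputs": [p.name for p in outputs],
            "params": params,
        }
        for p in outputs:
            self.artifacts[p.name] = p

    def require(self, stage: str) -> None:
        for dep in STAGE_DEPS.get(stage, []):
            if not self.config.stages.get(dep, False):
                raise PipelineError(
                    f"stage '{stage}' requires stage '{dep}' which is toggled off"
                )

    def write_provenance(self) -> None:
        with open(self.path("provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> PipelineRun:
    """Execute the enabled stages in dependency order."""
    run = PipelineRun(config)
    config.sim.seed = config.seed
    state: dict = {}

    if config.stages.get("simulate", False):
        _stage_simulate(run, state)
    for stage in ["filter", "call", "errors", "rate", "spectrum", "context", "pedigree", "selection"]:
        if config.stages.get(stage, False):
            run.require(stage)
            globals()[f"_stage_{stage}"](run, state)
    run.write_provenance()
    return run


def _stage_simulate(run: PipelineRun, state: dict) -> None:
    sim = simulate_all(run.config.sim)
    state["sim"] = sim
    p = run.path
    sio.write_fasta(sim.ref.chroms, p("reference.fa"))
    sio.write_bed(sim.ref.annotations, p("annotation.bed"))
    sio.write_vcf(sim.sites, p("sites.vcf"))
    sio.write_tsv(sio.strand_counts_frame(sim.sites), p("strand_counts.tsv"))
    truth = sim.truth.mutations.copy()
    truth["pos"] = truth["pos0"] + 1
    sio.write_tsv(truth.drop(columns=["pos0"]), p("truth_mutations.tsv"))
    sio.write_newick(run.config.sim.pedigree_newick, p("pedigree_truth.nwk"))
    sio.write_phased_vcf(sim.phased, p("phased.vcf"))
    sio.write_tsv(sim.outgroups, p("outgroups.tsv"))
    sio.write_tsv(sim.effect_scores, p("effect_scores.tsv"))
    sio.write_tsv(sim.recomb_windows, p("recomb_windows.tsv"))
    rep_paths = []
    for sample, reps in sim.replicates.items():
        for r, table in enumerate(reps, start=1):
            rp = p(f"replicate_{sample}_{r}.vcf")
            sio.write_vcf(table, rp)
            rep_paths.append(rp)
    outputs = [
        p(n)
        for n in (
            "reference.fa", "annotation.bed", "sites.vcf", "strand_counts.tsv",
            "truth_mutations.tsv", "pedigree_truth.nwk", "phased.vcf",
            "outgroups.tsv", "effect_scores.tsv", "recomb_windows.tsv",
        )
    ] + rep_paths
    run.record("simulate", [], outputs, {"seed": run.config.seed})


def _stage_filter(run: PipelineRun, state: dict) -> None:
    p = run.path
    table = sio.read_vcf(p("sites.vcf"))
    table = sio.attach_strand_counts(table, sio.read_tsv(p("strand_counts.tsv")))
    hard, counts = apply_hard_filters(table, run.config.filters)
    post, ledger = apply_site_postfilters(hard, run.config.filters)
    post = indel_somatic_filter(post)
    state["filtered"] = post
    sio.write_vcf(post, p("filtered.vcf"))
    sio.write_tsv(ledger, p("removal_ledger.tsv"))
    with open(p("removal_counts.json"), "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
    run.record(
        "filter",
        [p("sites.vcf"), p("strand_counts.tsv")],
        [p("filtered.vcf"), p("removal_ledger.tsv"), p("removal_counts.json")],
        {"gq_min": run.config.filters.gq_min},
    )


def _stage_call(run: PipelineRun, state: dict) -> None:
    p = run.path
    table = sio.read_vcf(p("filtered.vcf"))
    table = sio.attach_strand_counts(table, sio.read_tsv(p("strand_counts.tsv")))
    state["filtered"] = table
    annotations = sio.read_bed(p("annotation.bed"))
    calls = call_somatic(table, annotations=annotations)
    sv_path = p("sv_intervals.bed")
    if sv_path.exists():
        sv = sio.read_bed(sv_path, feature_col=True).rename(columns={"feature": "sample"})
        calls, _ = sv_mask(
            calls,
            {s: g[["chrom", "start", "end"]] for s, g in sv.groupby("sample")},
            table.n_samples,
        )
    state["calls"] = calls
    sio.write_tsv(calls, p("somatic_calls.tsv"))
    keys = set(
        calls["chrom"].astype(str) + ":" + calls["pos"].astype(str)
    )
    vkeys = table.variants["chrom"].astype(str) + ":" + table.variants["pos"].astype(str)
    sio.write_vcf(table.subset(vkeys.isin(keys).to_numpy()), p("somatic.vcf"))
    run.record(
        "call",
        [p("filtered.vcf"), p("annotation.bed")],
        [p("somatic_calls.tsv"), p("somatic.vcf")],
        {},
    )


def _stage_errors(run: PipelineRun, state: dict) -> None:
    p = run.path
    sim = state["sim"]
    table = state.get("filtered") or sio.read_vcf(p("filtered.vcf"))
    founder = majority_genotypes(table)
    # map founder genotypes onto the replicate variant grid via site keys
    replicate_calls = {}
    for sample in sim.replicates:
        sets = []
        for r in range(1, 4):
            rep = sio.read_vcf(p(f"replicate_{sample}_{r}.vcf"))
            rep_f, _ = apply_hard_filters(rep)
            rep_f, _ = apply_site_postfilters(rep_f)
            rep_founder = _align_founder(table, rep_f, founder)
            sets.append(sample_variant_sites(rep_f, sample, rep_founder))
        replicate_calls[sample] = sets
    fp_rates, per_sample = estimate_fp(replicate_calls)
    fn_rates = spike_in_sensitivity(
        sim.ref, run.config.sim, n=1000, zygosity="het", seed=run.config.seed
    )
    rates = fp_rates.merged(fn_rates)
    rates.to_json(p("errors.json"))
    with open(p("errors_per_sample.json"), "w") as fh:
        json.dump(per_sample, fh, indent=2, sort_keys=True)
    state["errors"] = rates
    run.record(
        "errors",
        [p("filtered.vcf")],
        [p("errors.json"), p("errors_per_sample.json")],
        {"spikein_n": 1000, "zygosity": "het"},
    )


def _align_founder(table: SiteTable, rep: SiteTable, founder: np.ndarray) -> np.ndarray:
    main_keys = {k: i for i, k in enumerate(table.keys())}
    out = np.full(rep.n_sites, -1, dtype=np.int8)
    for i, k in enumerate(rep.keys()):
        j = main_keys.get(k)
        if j is not None:
            out[i] = founder[j]
    return out


def _stage_rate(run: PipelineRun, state: dict) -> None:
    p = run.path
    calls = state.get("calls")
    if calls is None:
        calls = sio.read_tsv(p("somatic_calls.tsv"))
    rates: ErrorRates = state.get("errors") or ErrorRates.from_json(p("errors.json"))
    samples = state["filtered"].samples
    years = run.config.years or pedigree_years(run.config.sim.pedigree_newick)
    genome = run.config.sim.genome_length
    result = {}
    for var_type in ("SNV", "indel"):
        sub = calls[calls["var_type"] == var_type]
        counts = per_sample_counts(sub, samples)
        values = list(counts.values())
        mean_count = float(np.mean(values)) if values else 0.0
        inputs = RateInputs(
            mean_count=mean_count,
            years=years,
            genome_size=genome,
            fp_rate=rates.fp_rate or 0.0,
            sensitivity=rates.sensitivity or 1.0,
        )
        rate = point_rate(
            mean_count, years, genome,
            fp_rate=inputs.fp_rate, sensitivity=inputs.sensitivity,
        )
        entry = {
            "rate_per_bp_per_year": rate,
            "mean_count": mean_count,
            "per_sample_counts": counts,
            "years": years,
            "genome_size": genome,
            "fp_rate": inputs.fp_rate,
            "sensitivity": inputs.sensitivity,
        }
        if len(values) >= 2 and mean_count > 0:
            est = bootstrap_ci(values, inputs, reps=1000, seed=run.config.seed)
            entry["ci_low"], entry["ci_high"] = est.ci_low, est.ci_high
        result[var_type] = entry
    with open(p("rate.json"), "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    state["rate"] = result
    run.record(
        "rate", [p("somatic_calls.tsv"), p("errors.json")], [p("rate.json")],
        {"years": years, "genome_size": genome},
    )


def _stage_spectrum(run: PipelineRun, state: dict) -> None:
    p = run.path
    calls = state.get("calls")
    if calls is None:
        calls = sio.read_tsv(p("somatic_calls.tsv"))
    ref = state["sim"].ref
    table = classify_spectrum(calls, ref)
    summary = {
        "total_snvs": table.total,
        "class6": table.class6.to_dict(),
        "class6_pct": table.percentages(run.config.rounding_decimals).to_dict(),
    }
    try:
        summary["titv"] = titv(table)
        summary["at_bias"] = at_bias(table)
    except Exception as exc:
        summary["titv_error"] = str(exc)
    enr = context_enrichment(calls, ref)
    flank = flanking_composition(calls, ref, max_dist=20) if table.total else None
    sio.write_tsv(
        table.class6.rename("count").rename_axis("class").reset_index(), p("spectrum_classes.tsv")
    )
    sio.write_tsv(enr, p("context_enrichment.tsv"))
    if flank is not None:
        sio.write_tsv(flank, p("flanking_composition.tsv"))
    with open(p("spectrum_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    run.record(
        "spectrum", [p("somatic_calls.tsv"), p("reference.fa")],
        [p("spectrum_classes.tsv"), p("context_enrichment.tsv"), p("spectrum_summary.json")],
        {},
    )


def _stage_context(run: PipelineRun, state: dict) -> None:
    p = run.path
    calls = state.get("calls")
    if calls is None:
        calls = sio.read_tsv(p("somatic_calls.tsv"))
    sim = state["sim"]
    cfg = run.config.context
    outputs = []
    if len(calls):
        profile = het_vs_distance(
            calls, state["filtered"], sim.ref, cfg, seed=run.config.seed
        )
        sio.write_tsv(profile, p("het_profile.tsv"))
        outputs.append(p("het_profile.tsv"))
    recomb = recomb_regression(calls, sio.read_tsv(p("recomb_windows.tsv")), cfg)
    with open(p("recomb_regression.json"), "w") as fh:
        json.dump(
            {k: v for k, v in recomb.items() if k not in ("groups", "windows")},
            fh, indent=2, sort_keys=True,
        )
    sio.write_tsv(recomb["groups"], p("recomb_groups.tsv"))
    outputs += [p("recomb_regression.json"), p("recomb_groups.tsv")]
    run.record(
        "context", [p("somatic_calls.tsv"), p("recomb_windows.tsv")], outputs, {},
    )


def _stage_pedigree(run: PipelineRun, state: dict) -> None:
    p = run.path
    calls = state.get("calls")
    if calls is None:
        calls = sio.read_tsv(p("somatic_calls.tsv"))
    out = sio.read_tsv(p("outgroups.tsv"))
    merged = calls.merge(
        out, on=["chrom", "pos", "ref", "alt"], how="left", validate="many_to_one"
    )
    a = merged["outgroupA_gt"].fillna(-1).to_numpy()
    b = merged["outgroupB_gt"].fillna(-1).to_numpy()
    derived = polarize_derived(calls, a, b)
    derived_only = derived[derived["polarizable"]].reset_index(drop=True)
    sio.write_tsv(derived, p("derived_calls.tsv"))

    phased = sio.read_phased_vcf(p("phased.vcf"))
    shared = derived_only[derived_only["shared"]]
    hap = haplotype_identity_test(shared, phased)
    sio.write_tsv(hap, p("haplotype_status.tsv"))
    status_all = haplotype_identity_test(derived_only, phased)

    samples = state["filtered"].samples
    matrix = sharing_matrix(derived_only, samples)
    tree = build_pedigree(matrix)
    sio.write_newick(tree.newick(), p("pedigree.nwk"))
    sio.write_tsv(tree.branch_table(), p("pedigree_branches.tsv"))
    sio.write_nexus_distances(pair_shared_counts(matrix), p("splits.nex"))

    summary = sharing_summary(derived_only, status_all["status"])
    summary["n_homoplasy"] = len(tree.homoplasy)
    with open(p("sharing_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    run.record(
        "pedigree",
        [p("somatic_calls.tsv"), p("outgroups.tsv"), p("phased.vcf")],
        [p("derived_calls.tsv"), p("haplotype_status.tsv"), p("pedigree.nwk"),
         p("pedigree_branches.tsv"), p("splits.nex"), p("sharing_summary.json")],
        {},
    )


def _stage_selection(run: PipelineRun, state: dict) -> None:
    p = run.path
    calls = state.get("calls")
    if calls is None:
        calls = sio.read_tsv(p("somatic_calls.tsv"))
    scores = sio.read_tsv(p("effect_scores.tsv"))
    merged = calls.merge(scores, on=["chrom", "pos", "ref", "alt"], how="inner")
    merged["consensus"] = score_table_consensus(merged)
    deleterious = merged[merged["consensus"] == "deleterious"]
    total_snvs = int((calls["var_type"] == "SNV").sum())
    report = deleterious_pattern_report(deleterious, total_snvs)

    out = sio.read_tsv(p("outgroups.tsv"))
    sel = calls.merge(out, on=["chrom", "pos", "ref", "alt"], how="left")
    classes = []
    for _, row in sel.iterrows():
        post = row.get("outgroupA_af_alt")
        if post is None or (isinstance(post, float) and np.isnan(post)):
            classes.append("unclassified")
        else:
            pre = 1.0 - post  # reference allele is pre-mutation at somatic sites
            classes.append(classify_selection(pre, post).selection_class)
    sel_out = calls.copy()
    sel_out["selection_class"] = classes
    sio.write_tsv(sel_out, p("selection_calls.tsv"))
    summary = {
        "deleterious": report,
        "selection_class_counts": pd.Series(classes).value_counts().to_dict(),
    }
    with open(p("selection_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    run.record(
        "selection",
        [p("somatic_calls.tsv"), p("effect_scores.tsv"), p("outgroups.tsv")],
        [p("selection_calls.tsv"), p("selection_summary.json")],
        {},
    )


# ---------------------------------------------------------------------------
# in-memory calibration + estimation path for simulation studies


def recover_rate(config: SimConfig, spikein_n: int = 1000) -> dict:
    """Simulate one study and push it through calibration and rate estimation.

    Runs the generator, the filter cascade, the somatic caller, triplicate
    false-positive estimation, heterozygous spike-in sensitivity, and the
    corrected rate formula — all in memory. Returns the corrected and
    uncorrected estimates alongside the generator's true rate.
    """
    from .simulate import simulate_genome, simulate_mutations, simulate_site_table

    ref = simulate_genome(config)
    truth = simulate_mutations(ref, config)
    sites, replicates = simulate_site_table(truth, ref, config)

    hard, _ = apply_hard_filters(sites)
    post, _ = apply_site_postfilters(hard)
    post = indel_somatic_filter(post)
    calls = call_somatic(post, annotations=ref.annotations)
    snv_calls = calls[calls["var_type"] == "SNV"]

    founder = majority_genotypes(sites)
    # replicates go through the same filter cascade as the main call set, so
    # low-depth/low-GQ genotypes are masked before concordance is assessed
    replicate_calls = {}
    for sample, reps in replicates.items():
        sets = []
        for rep in reps:
            rep_f, _ = apply_hard_filters(rep)
            rep_f, _ = apply_site_postfilters(rep_f)
            rep_founder = _align_founder(sites, rep_f, founder)
            sets.append(sample_variant_sites(rep_f, sample, rep_founder))
        replicate_calls[sample] = sets
    fp, _ = estimate_fp(replicate_calls)
    fn = spike_in_sensitivity(ref, config, n=spikein_n, zygosity="het", seed=config.seed)

    samples = sites.samples
    counts = per_sample_counts(snv_calls, samples)
    mean_count = float(np.mean(list(counts.values())))
    years = pedigree_years(config.pedigree_newick)
    corrected = point_rate(
        mean_count, years, config.genome_length,
        fp_rate=fp.fp_rate or 0.0, sensitivity=fn.sensitivity or 1.0,
    )
    raw = point_rate(mean_count, years, config.genome_length)
    truth_counts = {leaf: len(ids) for leaf, ids in truth.leaf_assignments().items()}
    return {
        "rate_corrected": corrected,
        "rate_uncorrected": raw,
        "true_rate": config.snv_rate,
        "mean_count_called": mean_count,
        "mean_count_truth_snv": float(
            np.mean(
                [
                    (truth.mutations.loc[
                        truth.mutations["mut_id"].isin(ids), "var_type"
                    ] == "SNV").sum()
                    for ids in truth.leaf_assignments().values()
                ]
            )
        ),
        "fp_rate": fp.fp_rate,
        "sensitivity": fn.sensitivity,
        "years": years,
        "n_calls": len(snv_calls),
    }
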