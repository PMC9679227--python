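"""Shared fixtures: hand-built site tables and a small simulated study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from somaclone import SimConfig, SiteTable, simulate_all
from somaclone._util import encode_seq
from somaclone.model import INFO_FIELDS, ReferenceModel


def make_table(
    genotypes: list[list[int]],
    samples: list[str] | None = None,
    pos: list[int] | None = None,
    ref: str = "A",
    alt: str = "G",
    is_indel: bool | list[bool] = False,
    dp: int | np.ndarray = 30,
    gq: int | np.ndarray = 99,
    info: dict | None = None,
    chrom: str = "chr1",
    refs: list[str] | None = None,
    alts: list[str] | None = None,
) -> SiteTable:
    """Build a SiteTable from a per-site genotype matrix with sane read support.

    Heterozygous genotypes get an even strand split of half the depth; hom-alt
    gets full depth on the alternate; hom-ref gets none.
    """
    gt = np.array(genotypes, dtype=np.int8)
    n, s = gt.shape
    samples = samples or [f"s{i + 1}" for i in range(s)]
    pos = pos or list(range(100, 100 + 10 * n, 10))
    if isinstance(is_indel, bool):
        is_indel = [is_indel] * n
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "pos": pos,
            "ref": refs or [ref] * n,
            "alt": alts or [alt] * n,
            "is_indel": is_indel,
        }
    )
    defaults = {"FS": 1.0, "MQ": 60.0, "MQRankSum": 0.0, "QD": 20.0,
                "ReadPosRankSum": 0.0, "SOR": 0.5}
    defaults.update(info or {})
    for fld in INFO_FIELDS:
        v = defaults[fld]
        variants[fld] = v if np.ndim(v) else [v] * n
    dp_arr = np.full((n, s), dp, dtype=np.int32) if np.ndim(dp) == 0 else np.asarray(dp, dtype=np.int32)
    gq_arr = np.full((n, s), gq, dtype=np.int32) if np.ndim(gq) == 0 else np.asarray(gq, dtype=np.int32)
    alt_total = np.where(gt == 1, dp_arr // 2, np.where(gt == 2, dp_arr, 0))
    fwd = alt_total // 2
    rev = alt_total - fwd
    return SiteTable(
        samples=samples, variants=variants, gt=gt.copy(), dp=dp_arr, gq=gq_arr,
        alt_fwd=fwd.astype(np.int32), alt_rev=rev.astype(np.int32),
    )


def make_ref(seq: str, chrom: str = "chr1") -> ReferenceModel:
    """Single-chromosome reference with one intergenic annotation interval."""
    codes = encode_seq(seq)
    ann = pd.DataFrame(
        [(chrom, 0, len(seq), "intergenic")], columns=["chrom", "start", "end", "feature"]
    )
    het = pd.DataFrame(columns=["chrom", "pos0", "ref", "alt", "hap"])
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    return ReferenceModel(chroms={chrom: codes}, annotations=ann, het_sites=het, gc_content=gc)


@pytest.fixture(scope="session")
def small_sim():
    """A 500 kb four-sample study with dense truth for end-to-end checks."""
    config = SimConfig(
        genome_length=500_000,
        n_chromosomes=2,
        het_density=4.0,
        pedigree_newick="((A:30,B:30):37,C:67,D:67):0;",
        snv_rate=5e-7,
        indel_rate=1e-7,
        n_replicate_samples=2,
        phase_block_bp=100_000,
        seed=7,
    )
    return simulate_all(config)
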