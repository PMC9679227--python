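"""Standard-format I/O: FASTA, VCF (plain and phased), BED, TSVs, newick, NEXUS.

VCF coordinates are 1-based and BED 0-based half-open on disk; both are
converted to the internal convention on read. Round trips are lossless for
every field the pipeline uses (GT/DP/GQ/AD, the six INFO annotations, strand
counts travel in a separate TSV).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import ParseError, decode_seq, encode_seq
from .model import INFO_FIELDS, PhasedGenotypes, SiteTable

# ---------------------------------------------------------------------------
# FASTA


def write_fasta(chroms: dict[str, np.ndarray], path) -> None:
    records = [
        SeqRecord(Seq(decode_seq(codes)), id=name, description="")
        for name, codes in chroms.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, np.ndarray]:
    chroms = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        chroms[rec.id] = encode_seq(str(rec.seq))
    if not chroms:
        raise ParseError(f"{path}: no FASTA records found")
    return chroms


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(samples, contigs: dict[str, int] | None, phased: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in (contigs or {"unknown": 2**29}).items():
        header.add_line(f"##contig=<ID={name},length={length}>")
    for fld in INFO_FIELDS:
        header.add_line(
            f'##INFO=<ID={fld},Number=1,Type=Float,Description="{fld} site annotation">'
        )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">'
    )
    if phased:
        header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(table: SiteTable, path, contigs: dict[str, int] | None = None) -> None:
    """Emit the site table as an uncompressed multi-sample VCF."""
    if contigs is None:
        contigs = {
            c: int(sub["pos"].max()) + 100
            for c, sub in table.variants.groupby("chrom", sort=False)
        }
    header = _vcf_header(table.samples, contigs, phased=False)
    alt_total = table.alt_total()
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        v = table.variants
        for i in range(table.n_sites):
            rec = vf.new_record(
                contig=v["chrom"].iat[i],
                start=int(v["pos"].iat[i]) - 1,
                alleles=(v["ref"].iat[i], v["alt"].iat[i]),
            )
            for fld in INFO_FIELDS:
                if fld in v.columns and np.isfinite(v[fld].iat[i]):
                    rec.info[fld] = float(v[fld].iat[i])
            for j, s in enumerate(table.samples):
                g = int(table.gt[i, j])
                rec.samples[s]["GT"] = (
                    (None, None) if g < 0 else ((0, 0), (0, 1), (1, 1))[g]
                )
                dp = int(table.dp[i, j])
                rec.samples[s]["DP"] = dp
                rec.samples[s]["GQ"] = int(table.gq[i, j])
                rec.samples[s]["AD"] = (dp - int(alt_total[i, j]), int(alt_total[i, j]))
            vf.write(rec)


def _validate_vcf_columns(path) -> None:
    """Cheap structural pass: every data line must carry the header's columns."""
    n_expected = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                n_expected = len(line.rstrip("\n").split("\t"))
                continue
            if not line.strip():
                continue
            n = len(line.rstrip("\n").split("\t"))
            if n_expected is None:
                raise ParseError(f"{path}: line {lineno}: data before #CHROM header")
            if n != n_expected:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_expected} columns, found {n}"
                    " (truncated or malformed record)"
                )
    if n_expected is None:
        raise ParseError(f"{path}: no #CHROM header line")


def read_vcf(path) -> SiteTable:
    """Parse a multi-sample VCF into a SiteTable; multiallelic records are
    excluded and counted on ``n_multiallelic_excluded``."""
    _validate_vcf_columns(path)
    rows = []
    gts, dps, gqs, fwds, revs = [], [], [], [], []
    n_multi = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            row = {
                "chrom": rec.contig,
                "pos": rec.pos,
                "ref": ref,
                "alt": alt,
                "is_indel": len(ref) != len(alt),
            }
            for fld in INFO_FIELDS:
                row[fld] = float(rec.info[fld]) if fld in rec.info else np.nan
            rows.append(row)
            gt_row, dp_row, gq_row, ad_row = [], [], [], []
            for s in samples:
                smp = rec.samples[s]
                alleles = smp.get("GT", (None, None))
                if alleles is None or any(a is None for a in alleles):
                    gt_row.append(-1)
                else:
                    gt_row.append(int(sum(alleles)))
                dp_row.append(int(smp.get("DP") or 0))
                gq_row.append(int(smp.get("GQ") or 0))
                ad = smp.get("AD")
                ad_row.append(int(ad[1]) if ad is not None and len(ad) > 1 and ad[1] is not None else 0)
            gts.append(gt_row)
            dps.append(dp_row)
            gqs.append(gq_row)
            fwds.append(ad_row)  # strand split travels in the side TSV
            revs.append([0] * len(samples))
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "is_indel"] + INFO_FIELDS
    )
    n = len(variants)
    shape = (n, len(samples))
    table = SiteTable(
        samples=samples,
        variants=variants,
        gt=np.array(gts, dtype=np.int8).reshape(shape),
        dp=np.array(dps, dtype=np.int32).reshape(shape),
        gq=np.array(gqs, dtype=np.int32).reshape(shape),
        alt_fwd=np.array(fwds, dtype=np.int32).reshape(shape),
        alt_rev=np.array(revs, dtype=np.int32).reshape(shape),
        n_multiallelic_excluded=n_multi,
    )
    return table


def attach_strand_counts(table: SiteTable, strand: pd.DataFrame) -> SiteTable:
    """Overwrite a table's alt strand counts from a strand-count TSV frame."""
    out = table.copy()
    out.alt_fwd[:] = 0
    out.alt_rev[:] = 0
    key_to_idx = {
        (c, p): i
        for i, (c, p) in enumerate(zip(out.variants["chrom"], out.variants["pos"]))
    }
    col = {s: j for j, s in enumerate(out.samples)}
    for _, row in strand.iterrows():
        i = key_to_idx.get((row["chrom"], row["pos"]))
        j = col.get(row["sample"])
        if i is not None and j is not None:
            out.alt_fwd[i, j] = row["fwd_reads"]
            out.alt_rev[i, j] = row["rev_reads"]
    return out


def write_phased_vcf(phased: PhasedGenotypes, path) -> None:
    contigs = {
        c: int(sub["pos"].max()) + 100
        for c, sub in phased.variants.groupby("chrom", sort=False)
    }
    header = _vcf_header(phased.samples, contigs, phased=True)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        v = phased.variants
        for i in range(phased.n_sites):
            rec = vf.new_record(
                contig=v["chrom"].iat[i],
                start=int(v["pos"].iat[i]) - 1,
                alleles=(v["ref"].iat[i], v["alt"].iat[i]),
            )
            for j, s in enumerate(phased.samples):
                h = phased.hap[i, j]
                ps = int(phased.ps[i, j])
                if h[0] < 0:
                    rec.samples[s]["GT"] = (None, None)
                else:
                    rec.samples[s]["GT"] = (int(h[0]), int(h[1]))
                    rec.samples[s].phased = ps >= 0
                    if ps >= 0:
                        rec.samples[s]["PS"] = ps
            vf.write(rec)


def read_phased_vcf(path) -> PhasedGenotypes:
    _validate_vcf_columns(path)
    rows, haps, pss = [], [], []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            rows.append(
                {"chrom": rec.contig, "pos": rec.pos, "ref": rec.ref, "alt": rec.alts[0]}
            )
            h_row, ps_row = [], []
            for s in samples:
                smp = rec.samples[s]
                alleles = smp.get("GT", (None, None))
                if alleles is None or any(a is None for a in alleles):
                    h_row.append((-1, -1))
                    ps_row.append(-1)
                else:
                    h_row.append((int(alleles[0]), int(alleles[1])))
                    ps_row.append(int(smp.get("PS") or -1) if smp.phased else -1)
            haps.append(h_row)
            pss.append(ps_row)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return PhasedGenotypes(
        samples=samples,
        variants=variants,
        hap=np.array(haps, dtype=np.int8).reshape(len(rows), len(samples), 2),
        ps=np.array(pss, dtype=np.int32).reshape(len(rows), len(samples)),
    )


# ---------------------------------------------------------------------------
# BED / TSV


def write_bed(df: pd.DataFrame, path, columns=("chrom", "start", "end", "feature")) -> None:
    df[list(columns)].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, feature_col: bool = True) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + (["feature"] if feature_col else [])
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#")
    except Exception as exc:  # pragma: no cover - malformed separators etc.
        raise ParseError(f"{path}: {exc}") from exc
    if df[["start", "end"]].isna().any().any():
        bad = int(df[["start", "end"]].isna().any(axis=1).idxmax()) + 1
        raise ParseError(f"{path}: line {bad}: missing interval bounds")
    return df


def strand_counts_frame(table: SiteTable) -> pd.DataFrame:
    """Long-format strand-count rows (chrom, pos, sample, allele, fwd, rev)."""
    v = table.variants
    rows = []
    for j, s in enumerate(table.samples):
        rows.append(
            pd.DataFrame(
                {
                    "chrom": v["chrom"],
                    "pos": v["pos"],
                    "sample": s,
                    "allele": v["alt"],
                    "fwd_reads": table.alt_fwd[:, j],
                    "rev_reads": table.alt_rev[:, j],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


# ---------------------------------------------------------------------------
# trees


def write_newick(newick: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip() + "\n")


def write_nexus_distances(pair_counts: pd.DataFrame, path) -> None:
    """NEXUS taxa + distances blocks from pairwise shared-mutation counts.

    The distance between two samples is the count of mutations private to
    either (total carried by each minus twice the shared count), the additive
    distance a splits network tool expects from clonal sharing data.
    """
    taxa = list(pair_counts.columns)
    shared = pair_counts.to_numpy()
    own = np.diag(shared)
    dist = own[:, None] + own[None, :] - 2 * shared
    np.fill_diagonal(dist, 0)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(taxa)};\n  TAXLABELS\n")
        for t in taxa:
            fh.write(f"    {t}\n")
        fh.write("  ;\nEND;\n\nBEGIN DISTANCES;\n")
        fh.write("  FORMAT TRIANGLE=BOTH DIAGONAL LABELS=LEFT;\n  MATRIX\n")
        for i, t in enumerate(taxa):
            row = " ".join(str(int(x)) for x in dist[i])
            fh.write(f"    {t} {row}\n")
        fh.write("  ;\nEND;\n")
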