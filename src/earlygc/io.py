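"""Standard-format readers and writers (FASTA, GFF3/TSV gene models, VCF).

VCF v4.2 is the single variant interchange format: one file per
tumor/normal pair, FORMAT fields DP/AD/ADF/ADR for both samples, and INFO
fields KNOWN (population-database flag), VS (variant score), CQ (call
quality), BC (barcode read pairs), MBQ (minimum base quality). The tumor
sample column is named after the sample id; the second column is NORMAL.
Multi-allelic records are rejected with instructions to split them.
Internally all coordinates are 0-based half-open; VCF/GFF3 I/O converts
from their 1-based conventions at the boundary.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import AnnotationError, GeneModel, ReferenceGenome
from .filters import (
    EXOME_CRITERIA,
    TARGETED_CRITERIA,
    FilterReport,
    VariantCall,
    infer_var_class,
)
from .simulate import TRUTH_COLUMNS


class IOFormatError(ValueError):
    """Malformed or unsupported input file content."""


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(ref: ReferenceGenome, path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(ref.seq(c)), id=c, description="") for c in ref.chroms]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> ReferenceGenome:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise IOFormatError(f"no sequences found in {path}")
    return ReferenceGenome(seqs)


# ---------------------------------------------------------------------------
# gene models (GFF3 with gene/CDS features, or simplified TSV)

GENE_TSV_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def write_genes_gff3(
    genes: Sequence[GeneModel], path: str | os.PathLike,
    ref: ReferenceGenome | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if ref is not None:
            for chrom in ref.chroms:
                fh.write(f"##sequence-region {chrom} 1 {ref.length(chrom)}\n")
        for gene in genes:
            start, end = gene.span
            fh.write(
                f"{gene.chrom}\tearlygc\tgene\t{start + 1}\t{end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            # phase: bases to skip before the first full codon, in
            # translation order (descending intervals for minus strand)
            order = gene.intervals if gene.strand == "+" else gene.intervals[::-1]
            cum = 0
            phases = {}
            for s, e in order:
                phases[(s, e)] = (3 - cum % 3) % 3
                cum += e - s
            for k, (s, e) in enumerate(gene.intervals, 1):
                fh.write(
                    f"{gene.chrom}\tearlygc\tCDS\t{s + 1}\t{e}\t.\t{gene.strand}\t"
                    f"{phases[(s, e)]}\tID={gene.gene_id}.cds{k};Parent={gene.gene_id}\n"
                )


def read_genes_gff3(path: str | os.PathLike) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        cds = sorted(db.children(feat, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            raise IOFormatError(f"gene {feat.id} has no CDS features")
        try:
            genes.append(
                GeneModel(
                    gene_id=feat.id,
                    chrom=feat.seqid,
                    strand=feat.strand,
                    intervals=tuple((c.start - 1, c.end) for c in cds),
                )
            )
        except AnnotationError as exc:
            raise IOFormatError(str(exc)) from exc
    return sorted(genes, key=lambda g: g.gene_id)


def write_genes_tsv(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """One row per CDS interval: gene_id, chrom, start, end (1-based
    inclusive, matching GFF3), strand."""
    rows = [
        dict(gene_id=g.gene_id, chrom=g.chrom, start=s + 1, end=e, strand=g.strand)
        for g in genes
        for s, e in g.intervals
    ]
    pd.DataFrame(rows, columns=GENE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genes_tsv(path: str | os.PathLike) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise IOFormatError(f"gene TSV missing columns: {sorted(missing)}")
    genes = []
    for gene_id, group in df.groupby("gene_id", sort=True):
        chroms = group["chrom"].unique()
        strands = group["strand"].unique()
        if len(chroms) != 1 or len(strands) != 1:
            raise IOFormatError(f"gene {gene_id}: inconsistent chrom/strand rows")
        intervals = tuple(
            sorted((int(r.start) - 1, int(r.end)) for r in group.itertuples())
        )
        try:
            genes.append(
                GeneModel(gene_id=str(gene_id), chrom=str(chroms[0]),
                          strand=str(strands[0]), intervals=intervals)
            )
        except AnnotationError as exc:
            raise IOFormatError(str(exc)) from exc
    return genes


def read_genes(
    path: str | os.PathLike, ref: ReferenceGenome | None = None
) -> list[GeneModel]:
    """Read gene models from GFF3 (.gff/.gff3) or simplified TSV.

    If a reference is supplied, models are validated against its bounds.
    """
    suffix = Path(path).suffix.lower()
    genes = read_genes_gff3(path) if suffix in (".gff", ".gff3") else read_genes_tsv(path)
    if ref is not None:
        for gene in genes:
            try:
                gene.validate_against(ref)
            except AnnotationError as exc:
                raise IOFormatError(str(exc)) from exc
    return genes


# ---------------------------------------------------------------------------
# VCF

_INFO_FIELDS = [
    ("KNOWN", "0", "Flag", "Listed in dbSNP 137, HapMap, or 1000 Genomes"),
    ("VS", "1", "Float", "Variant score"),
    ("CQ", "1", "Float", "Variant call quality"),
    ("BC", "1", "Integer", "Read pairs per barcode supporting the variant"),
    ("MBQ", "1", "Integer", "Minimum base quality over variant-supporting reads"),
]

_FORMAT_FIELDS = [
    ("DP", "1", "Integer", "Read depth"),
    ("AD", "R", "Integer", "Allelic depths (ref, alt)"),
    ("ADF", "R", "Integer", "Allelic depths on the forward strand (ref, alt)"),
    ("ADR", "R", "Integer", "Allelic depths on the reverse strand (ref, alt)"),
]


def _vcf_header(ref: ReferenceGenome, sample_id: str, filters: dict[str, str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in ref.chroms:
        header.contigs.add(chrom, length=ref.length(chrom))
    for fid, number, ftype, desc in _INFO_FIELDS:
        header.info.add(fid, number, ftype, desc)
    for fid, number, ftype, desc in _FORMAT_FIELDS:
        header.formats.add(fid, number, ftype, desc)
    for code, desc in filters.items():
        header.filters.add(code, None, None, desc)
    header.add_sample(sample_id)
    header.add_sample("NORMAL")
    return header


def _even_split(total: int) -> tuple[int, int]:
    return total - total // 2, total // 2


def write_vcf(
    calls: Sequence[VariantCall],
    path: str | os.PathLike,
    ref: ReferenceGenome,
    sample_id: str,
    filter_codes: dict[int, Sequence[str]] | None = None,
) -> None:
    """Write one tumor/normal pair's calls as uncompressed VCF v4.2.

    ``filter_codes`` optionally maps a call's index in ``calls`` to the
    criterion codes to place in FILTER; unmapped records get PASS.
    Reference-supporting read strand counts are not modelled and are split
    evenly between strands.
    """
    header = _vcf_header(ref, sample_id, {**EXOME_CRITERIA, **TARGETED_CRITERIA})
    ordered = sorted(
        range(len(calls)), key=lambda i: (calls[i].chrom, calls[i].pos, calls[i].alt)
    )
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in ordered:
            call = calls[i]
            rec = vcf.new_record(
                contig=call.chrom, start=call.pos - 1,
                alleles=(call.ref, call.alt),
            )
            if call.known_variant:
                rec.info["KNOWN"] = True
            if call.variant_score is not None:
                rec.info["VS"] = call.variant_score
            if call.call_quality is not None:
                rec.info["CQ"] = call.call_quality
            if call.barcode_pairs is not None:
                rec.info["BC"] = call.barcode_pairs
            if call.base_quality_min is not None:
                rec.info["MBQ"] = call.base_quality_min
            tumor_ref = call.tumor_depth - call.tumor_alt
            trf, trr = _even_split(tumor_ref)
            tumor = rec.samples[sample_id]
            tumor["DP"] = call.tumor_depth
            tumor["AD"] = (tumor_ref, call.tumor_alt)
            tumor["ADF"] = (trf, call.alt_forward)
            tumor["ADR"] = (trr, call.alt_reverse)
            normal_ref = call.normal_depth - call.normal_alt
            nrf, nrr = _even_split(normal_ref)
            naf, nar = _even_split(call.normal_alt)
            normal = rec.samples["NORMAL"]
            normal["DP"] = call.normal_depth
            normal["AD"] = (normal_ref, call.normal_alt)
            normal["ADF"] = (nrf, naf)
            normal["ADR"] = (nrr, nar)
            if filter_codes and i in filter_codes:
                for code in filter_codes[i]:
                    rec.filter.add(code)
            else:
                rec.filter.add("PASS")
            vcf.write(rec)


def read_vcf(path: str | os.PathLike, sample_id: str | None = None) -> list[VariantCall]:
    """Read one tumor/normal pair's calls from VCF.

    The tumor sample id defaults to the first sample column name.
    """
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 2:
            raise IOFormatError(
                f"{path}: expected a tumor/normal sample pair, found {samples}"
            )
        tumor_name = sample_id or samples[0]
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise IOFormatError(
                    f"{path}: multi-allelic record at {rec.chrom}:{rec.pos}; "
                    "split multi-allelic sites into one record per alternate "
                    "allele before loading"
                )
            tumor = rec.samples[samples[0]]
            normal = rec.samples[samples[1]]
            for fname in ("DP", "AD", "ADF", "ADR"):
                if tumor.get(fname) is None or normal.get(fname) is None:
                    raise IOFormatError(
                        f"{path}: FORMAT field {fname} missing at "
                        f"{rec.chrom}:{rec.pos}"
                    )
            alt = rec.alts[0]
            calls.append(
                VariantCall(
                    sample_id=tumor_name,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    var_class=infer_var_class(rec.ref, alt),
                    tumor_depth=tumor["DP"],
                    tumor_alt=tumor["AD"][1],
                    normal_depth=normal["DP"],
                    normal_alt=normal["AD"][1],
                    alt_forward=tumor["ADF"][1],
                    alt_reverse=tumor["ADR"][1],
                    known_variant="KNOWN" in rec.info,
                    variant_score=(
                        # VCF floats are single precision; canonicalize
                        float(f"{float(rec.info['VS']):.6g}")
                        if "VS" in rec.info else None
                    ),
                    base_quality_min=(
                        int(rec.info["MBQ"]) if "MBQ" in rec.info else None
                    ),
                    call_quality=(
                        float(f"{float(rec.info['CQ']):.6g}")
                        if "CQ" in rec.info else None
                    ),
                    barcode_pairs=int(rec.info["BC"]) if "BC" in rec.info else None,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# tables


def write_truth_table(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise IOFormatError(f"truth table missing columns: {sorted(missing)}")
    return df


def write_rejections_tsv(report: FilterReport, path: str | os.PathLike) -> None:
    """Sidecar TSV listing every rejected record and its violated criteria."""
    rows = [
        dict(sample_id=c.sample_id, chrom=c.chrom, pos=c.pos, ref=c.ref, alt=c.alt,
             criteria=",".join(codes))
        for c, codes in report.rejected
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "criteria"]
    ).to_csv(path, sep="\t", index=False)


def write_msi_tsv(results, path: str | os.PathLike) -> None:
    from .msi import BETHESDA_MARKERS

    rows = []
    for r in results:
        row = {"sample_id": r.sample_id}
        row.update({m: int(f) for m, f in zip(BETHESDA_MARKERS, r.flags)})
        row["unstable_fraction"] = r.unstable_fraction
        row["msi_class"] = r.msi_class
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_msi_flags(path: str | os.PathLike) -> list[tuple[str, tuple[bool, ...]]]:
    from .msi import BETHESDA_MARKERS

    df = pd.read_csv(path, sep="\t")
    missing = ({"sample_id"} | set(BETHESDA_MARKERS)) - set(df.columns)
    if missing:
        raise IOFormatError(f"MSI table missing columns: {sorted(missing)}")
    return [
        (str(r["sample_id"]), tuple(bool(r[m]) for m in BETHESDA_MARKERS))
        for _, r in df.iterrows()
    ]


def read_4col(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["CHROM", "POS", "REF", "ALT"]:
        raise IOFormatError(f"{path}: expected columns CHROM, POS, REF, ALT")
    return df
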