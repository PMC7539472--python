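"""Readers and writers for mutation catalogs (VCF 4.2, MAF) and BED annotation.

Internally all indels are held in MAF-style allele representation (``-`` for
the absent allele, see :class:`~mutsim.classification.MutationRecord`); VCF
anchored-base indels are converted on read and regenerated on write, so both
formats round-trip up to representation normalization.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .classification import MutationRecord
from .genome import ReferenceGenome, RegionMask

logger = logging.getLogger(__name__)

MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Variant_Type",
    "Reference_Allele",
    "Tumor_Seq_Allele1",
    "Tumor_Seq_Allele2",
    "Tumor_Sample_Barcode",
]
_VTYPE_TO_MAF = {"SBS": "SNP", "DBS": "DNP", "INS": "INS", "DEL": "DEL"}
_MAF_TO_VTYPE = {v: k for k, v in _VTYPE_TO_MAF.items()}


def harmonize_chrom(chrom: str, genome: ReferenceGenome | None) -> str:
    """Match a chromosome name to the genome's 'chr'-prefix convention."""
    if genome is None or chrom in genome.names:
        return chrom
    alt = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
    if alt in genome.names:
        return alt
    return chrom


def _minimal_representation(pos: int, ref: str, alt: str):
    """Reduce a VCF (pos, ref, alt) to minimal MAF-style alleles.

    Returns (pos, ref, alt, vtype) with our 1-based conventions, or raises
    ValueError for representations we do not model (MNPs longer than 2).
    """
    i = 0
    while i < min(len(ref), len(alt)) and ref[i] == alt[i]:
        i += 1
    r, a = ref[i:], alt[i:]
    j = 0
    while j < min(len(r), len(a)) and r[len(r) - 1 - j] == a[len(a) - 1 - j]:
        j += 1
    if j:
        r, a = r[: len(r) - j], a[: len(a) - j]
    p = pos + i
    if r and a:
        if len(r) != len(a):
            raise ValueError(f"complex variant {ref}>{alt}")
        if len(r) == 1:
            return p, r, a, "SBS"
        if len(r) == 2:
            return p, r, a, "DBS"
        raise ValueError(f"MNP longer than 2 bp: {ref}>{alt}")
    if r:
        return p, r, "-", "DEL"
    return p - 1, "-", a, "INS"


def _check_ref(rec: MutationRecord, genome: ReferenceGenome | None) -> bool:
    if genome is None or rec.ref == "-":
        return True
    if rec.chrom not in genome.names:
        return False
    start = rec.pos - 1
    return genome.slice(rec.chrom, start, start + len(rec.ref)) == rec.ref


def read_vcf(path, genome: ReferenceGenome | None = None) -> dict[str, list[MutationRecord]]:
    """Read a VCF into per-sample records; multi-allelic rows are split.

    Sample identity comes from genotype columns carrying the alt; a VCF
    without sample columns maps everything to the filename stem.
    """
    path = Path(path)
    out: dict[str, list[MutationRecord]] = {}
    rejected = 0
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        default_sample = path.stem
        for row in vf:
            chrom = harmonize_chrom(row.chrom, genome)
            for ai, alt in enumerate(row.alts or (), start=1):
                if alt is None or set(alt) - set("ACGTN"):
                    rejected += 1
                    continue
                try:
                    p, r, a, vtype = _minimal_representation(row.pos, row.ref.upper(), alt.upper())
                except ValueError as exc:
                    logger.debug("rejected %s:%s: %s", chrom, row.pos, exc)
                    rejected += 1
                    continue
                if vcf_samples:
                    carriers = [
                        s
                        for s in vcf_samples
                        if ai in (row.samples[s].get("GT") or ())
                    ]
                else:
                    carriers = [default_sample]
                for sample in carriers:
                    rec = MutationRecord(sample, chrom, p, r, a, vtype)
                    if not _check_ref(rec, genome):
                        logger.debug("reference mismatch at %s:%s", chrom, p)
                        rejected += 1
                        continue
                    out.setdefault(sample, []).append(rec)
    if rejected:
        logger.warning("%s: %d record(s) rejected", path.name, rejected)
    return out


def read_maf(path, genome: ReferenceGenome | None = None) -> dict[str, list[MutationRecord]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"Chromosome", "Start_Position", "Reference_Allele", "Tumor_Seq_Allele2",
                "Variant_Type", "Tumor_Sample_Barcode"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MAF is missing columns: {sorted(missing)}")
    out: dict[str, list[MutationRecord]] = {}
    rejected = 0
    for row in df.itertuples(index=False):
        vtype = _MAF_TO_VTYPE.get(row.Variant_Type)
        if vtype is None:
            rejected += 1
            continue
        chrom = harmonize_chrom(str(row.Chromosome), genome)
        pos = int(row.Start_Position)
        ref, alt = row.Reference_Allele, row.Tumor_Seq_Allele2
        try:
            rec = MutationRecord(str(row.Tumor_Sample_Barcode), chrom, pos, ref, alt, vtype)
        except ValueError:
            rejected += 1
            continue
        if not _check_ref(rec, genome):
            rejected += 1
            continue
        out.setdefault(rec.sample, []).append(rec)
    if rejected:
        logger.warning("%s: %d record(s) rejected", Path(path).name, rejected)
    return out


def read_catalog(path, format: str | None = None, genome: ReferenceGenome | None = None):
    """Read a VCF or MAF catalog into ``{sample: [MutationRecord, ...]}``."""
    if format is None:
        suffix = Path(path).suffix.lower()
        format = "MAF" if suffix == ".maf" else "VCF"
    if format.upper() == "VCF":
        return read_vcf(path, genome)
    if format.upper() == "MAF":
        return read_maf(path, genome)
    raise ValueError(f"unknown catalog format {format!r}")


def _sort_records(records: Sequence[MutationRecord], genome: ReferenceGenome | None):
    if genome is not None:
        order = {c: i for i, c in enumerate(genome.names)}
        return sorted(records, key=lambda r: (order.get(r.chrom, len(order)), r.chrom, r.pos))
    return sorted(records, key=lambda r: (r.chrom, r.pos))


def write_vcf(records, path, genome: ReferenceGenome) -> None:
    """Write a single-sample VCF 4.2 file (anchored-base indel encoding)."""
    records = list(records)
    samples = {r.sample for r in records}
    if len(samples) > 1:
        raise ValueError("write_vcf writes one sample per file; split the catalog")
    sample = samples.pop() if samples else "SAMPLE"
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={n},length={genome.length(n)}>" for n in genome.names]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for rec in _sort_records(records, genome):
        if rec.vtype in ("SBS", "DBS"):
            pos, ref, alt = rec.pos, rec.ref, rec.alt
        elif rec.vtype == "DEL":
            if rec.pos < 2:
                raise ValueError("cannot anchor a deletion at the chromosome start")
            anchor = genome.base(rec.chrom, rec.pos - 2)
            pos, ref, alt = rec.pos - 1, anchor + rec.ref, anchor
        else:  # INS
            if rec.pos < 1:
                raise ValueError("cannot anchor an insertion before the chromosome start")
            anchor = genome.base(rec.chrom, rec.pos - 1)
            pos, ref, alt = rec.pos, anchor, anchor + rec.alt
        lines.append(
            f"{rec.chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t0/1"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_maf(records, path, genome: ReferenceGenome | None = None) -> None:
    rows = []
    for rec in _sort_records(list(records), genome):
        if rec.vtype == "INS":
            start, end = rec.pos, rec.pos + 1
        elif rec.vtype == "DEL":
            start, end = rec.pos, rec.pos + len(rec.ref) - 1
        else:
            start, end = rec.pos, rec.pos + len(rec.ref) - 1
        rows.append(
            {
                "Hugo_Symbol": ".",
                "Chromosome": rec.chrom,
                "Start_Position": start,
                "End_Position": end,
                "Variant_Type": _VTYPE_TO_MAF[rec.vtype],
                "Reference_Allele": rec.ref,
                "Tumor_Seq_Allele1": rec.ref,
                "Tumor_Seq_Allele2": rec.alt,
                "Tumor_Sample_Barcode": rec.sample,
            }
        )
    pd.DataFrame(rows, columns=MAF_COLUMNS).to_csv(path, sep="\t", index=False)


def write_catalog(records, path, format: str = "VCF", genome: ReferenceGenome | None = None):
    """Write records to VCF (needs the genome for indel anchors) or MAF."""
    if format.upper() == "VCF":
        if genome is None:
            raise ValueError("writing VCF requires the reference genome")
        write_vcf(records, path, genome)
    elif format.upper() == "MAF":
        write_maf(records, path, genome)
    else:
        raise ValueError(f"unknown catalog format {format!r}")


# -- BED ------------------------------------------------------------------


def _bed_rows(path) -> Iterable[list[str]]:
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        yield line.split("\t")


def read_genes_bed(path) -> list[tuple[str, int, int, str]]:
    """Gene intervals from BED6 (name in col 4, strand in col 6)."""
    out = []
    for f in _bed_rows(path):
        if len(f) < 6:
            raise ValueError("gene BED needs 6 columns (strand in column 6)")
        out.append((f[0], int(f[1]), int(f[2]), f[5]))
    return out


def read_regions_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Plain interval BED (e.g. exome targets) as {chrom: [(start, end)]}."""
    out: dict[str, list[tuple[int, int]]] = {}
    for f in _bed_rows(path):
        out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return out


def read_mask_bed(path, exhaustive: bool = False) -> RegionMask:
    """Probability mask from BED with a numeric weight in column 4."""
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    for f in _bed_rows(path):
        if len(f) < 4:
            raise ValueError("mask BED needs a weight in column 4")
        intervals.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
    return RegionMask(intervals, exhaustive=exhaustive)


def write_genes_bed(genes, path) -> None:
    lines = [f"{c}\t{s}\t{e}\tgene{i}\t0\t{st}" for i, (c, s, e, st) in enumerate(genes)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
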