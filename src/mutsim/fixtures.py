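"""Synthetic genomes, annotations and catalogs with known channel composition.

Everything here is generated programmatically and deterministically from a
seed, so the whole toolchain — context indexing, classification, simulation
and the null analyses — runs and is testable without any reference-genome
download. Default genomes are 2 chromosomes x 50 kb of iid bases at 41% GC
(roughly the human average), large enough that every trinucleotide context
occurs thousands of times.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np

from .classification import get_scheme
from .genome import (
    ReferenceGenome,
    RegionMask,
    TranscriptionMap,
    build_context_index,
    build_transcription_map,
)
from .simulator import (
    SimulationOptions,
    ChannelPlacer,
    allocate_counts,
    default_context_width,
    place_mutations,
)


@dataclasses.dataclass
class FixtureSpec:
    """Parameters of a synthetic genome/catalog fixture."""

    chrom_lengths: tuple[int, ...] = (50_000, 50_000)
    gc_content: float = 0.41
    gene_fraction: float = 0.4
    gene_length: int = 4_000
    n_mutations: int = 1_000
    spectrum: str = "uniform"  # uniform | two_channel | strand_biased
    strand_bias: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        if any(length < 1 for length in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")


def make_genome(spec: FixtureSpec, fasta_path=None) -> ReferenceGenome:
    """Random iid-base genome at the requested GC; optionally written as FASTA."""
    rng = np.random.default_rng(spec.seed)
    at, gc = (1 - spec.gc_content) / 2, spec.gc_content / 2
    chroms = []
    for i, length in enumerate(spec.chrom_lengths):
        bases = rng.choice(list("ACGT"), size=length, p=[at, gc, gc, at])
        chroms.append((f"chr{i + 1}", "".join(bases)))
    genome = ReferenceGenome.from_sequences(chroms)
    if fasta_path is not None:
        write_fasta(genome, fasta_path)
    return genome


def write_fasta(genome: ReferenceGenome, path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chromosomes:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def make_genes(spec: FixtureSpec, genome: ReferenceGenome) -> list[tuple[str, int, int, str]]:
    """Deterministic gene layout: alternating-strand genes at ~gene_fraction
    cover, plus one antisense overlap per chromosome so bi-directionally
    transcribed regions exist."""
    out: list[tuple[str, int, int, str]] = []
    step = max(int(spec.gene_length / max(spec.gene_fraction, 1e-9)), spec.gene_length + 1)
    for chrom in genome.names:
        length = genome.length(chrom)
        start, i = 200, 0
        first = None
        while start + spec.gene_length < length:
            strand = "+" if i % 2 == 0 else "-"
            gene = (chrom, start, start + spec.gene_length, strand)
            out.append(gene)
            if first is None:
                first = gene
            i += 1
            start += step
        if first is not None:
            mid = (first[1] + first[2]) // 2
            out.append((chrom, mid, first[2], "-" if first[3] == "+" else "+"))
    return out


def _preset_weights(spec: FixtureSpec, scheme, abundance: np.ndarray) -> np.ndarray:
    labels = scheme.labels
    w = np.zeros(len(labels))
    if spec.spectrum == "uniform":
        # uniform over channels with enough sites that placement cannot
        # exhaust them on a small fixture genome; indel channels need more
        # headroom because their candidate sites can mutually overlap
        w[abundance >= (25 if scheme.kind == "ID" else 5)] = 1.0
    elif spec.spectrum == "two_channel":
        if np.count_nonzero(abundance > 0) < 2:
            raise ValueError("fewer than two channels have eligible sites")
        # the two most site-rich channels, so placement cannot exhaust them
        first, second = np.argsort(abundance)[::-1][:2]
        w[int(first)], w[int(second)] = 0.7, 0.3
    elif spec.spectrum == "strand_biased":
        if not scheme.strand_aware:
            raise ValueError("strand_biased preset needs a strand-aware scheme")
        for i, lab in enumerate(labels):
            if lab.startswith("T:"):
                w[i] = spec.strand_bias
            elif lab.startswith("U:"):
                w[i] = 1.0
    else:
        raise ValueError(f"unknown spectrum preset {spec.spectrum!r}")
    w[abundance <= 0] = 0.0
    if w.sum() <= 0:
        raise ValueError("preset leaves no channel with eligible sites")
    return w


def make_catalog(
    genome: ReferenceGenome,
    spec: FixtureSpec,
    scheme="SBS96",
    tmap: Optional[TranscriptionMap] = None,
    mask: Optional[RegionMask] = None,
    sample: str = "fixture",
) -> tuple[list, np.ndarray]:
    """Place ``spec.n_mutations`` mutations consistent with a preset spectrum.

    Returns the records and the exact per-channel spectrum they realize; a
    rebuilt matrix of the catalog equals this spectrum by construction.
    """
    scheme = get_scheme(scheme)
    if scheme.strand_aware and tmap is None:
        tmap = build_transcription_map(genome, make_genes(spec, genome))
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(9,)))
    index = build_context_index(genome, default_context_width(scheme), tmap=tmap, mask=mask)
    opts = SimulationOptions(scheme=scheme, seed=spec.seed)
    placer = ChannelPlacer(index, scheme, tmap)
    abundance = np.array(
        [sum(placer.abundance(c, ci) for c in index.names) for ci in range(scheme.n_channels)]
    )
    w = _preset_weights(spec, scheme, abundance)
    counts = rng.multinomial(spec.n_mutations, w / w.sum())
    alloc = allocate_counts(counts, placer, opts, rng)
    catalog = place_mutations(alloc, placer, opts, rng, sample=sample)
    return catalog.records, counts


def emit_fixture_set(spec: FixtureSpec, out_dir, scheme="SBS96") -> dict[str, Path]:
    """Write a self-contained fixture directory: FASTA, BEDs, VCF, spectrum TSV."""
    from . import catalog_io
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scheme = get_scheme(scheme)
    genome = make_genome(spec, out_dir / "genome.fa")
    genes = make_genes(spec, genome)
    catalog_io.write_genes_bed(genes, out_dir / "genes.bed")
    tmap = build_transcription_map(genome, genes)
    # exome targets: the gene intervals; mask: downweight the second half of chr1
    with open(out_dir / "targets.bed", "w") as fh:
        for c, s, e, _ in genes:
            fh.write(f"{c}\t{s}\t{e}\n")
    half = genome.length(genome.names[0]) // 2
    with open(out_dir / "mask.bed", "w") as fh:
        fh.write(f"{genome.names[0]}\t{half}\t{genome.length(genome.names[0])}\t0.1\n")
    records, spectrum = make_catalog(genome, spec, scheme, tmap=tmap)
    catalog_io.write_catalog(records, out_dir / "catalog.vcf", "VCF", genome)
    pd.DataFrame(
        {"MutationType": list(scheme.labels), "fixture": spectrum}
    ).to_csv(out_dir / "true_spectrum.tsv", sep="\t", index=False)
    return {
        "fasta": out_dir / "genome.fa",
        "genes": out_dir / "genes.bed",
        "targets": out_dir / "targets.bed",
        "mask": out_dir / "mask.bed",
        "vcf": out_dir / "catalog.vcf",
        "spectrum": out_dir / "true_spectrum.tsv",
    }
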