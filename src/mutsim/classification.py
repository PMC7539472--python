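"""Mutational-channel classification schemes and catalog matrices.

Supported schemes and channel counts:

========  ========  =========================================================
name      channels  meaning
========  ========  =========================================================
SBS6      6         mutated pyrimidine base pair (C>A ... T>G)
SBS24     24        SBS6 x transcription category (T/U/B/N prefix)
SBS96     96        +/-1 bp context, e.g. ``A[C>T]G``
SBS384    384       SBS96 x transcription category, e.g. ``T:A[C>T]G``
SBS1536   1536      +/-2 bp context, e.g. ``AA[C>T]GG``
SBS6144   6144      SBS1536 x transcription category
SBS24576  24576     +/-3 bp context
DBS78     78        doublet substitutions, revcomp-collapsed, e.g. ``CC>TT``
ID83      83        indels by length, repeat/homopolymer and microhomology
ID415     415       ID83 x 5 transcription categories (T/U/B/N/Q)
========  ========  =========================================================

Substitution channels are pyrimidine-collapsed: a record whose reference base
is a purine is reverse-complemented (context reversed and complemented)
before labelling. Transcription categories are assigned relative to the
strand carrying the pyrimidine of the mutated pair: T = pyrimidine on the
transcribed (template) strand, U = untranscribed, B = bi-directionally
transcribed region, N = intergenic. Indel labels read ``length:kind:subtype:n``
where for deletions of one base ``n`` is the total homopolymer run length in
the reference (1..5, 6 = 6+), for insertions the number of pre-existing
copies (0..4, 5 = 5+), for longer repeat-mediated indels the analogous repeat
unit counts, and for microhomology deletions (``M``) the homology length.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from functools import lru_cache
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .genome import (
    CAT_LETTERS,
    DBS_REF_SET,
    PYRIMIDINES,
    RAW_BOTH,
    RAW_NONE,
    RAW_PLUS,
    ContextIndex,
    ReferenceGenome,
    TranscriptionMap,
    effective_category,
    revcomp,
)

logger = logging.getLogger(__name__)

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
ID_CATEGORIES = "TUBNQ"  # Q: indel spans a transcription-category boundary


class UnclassifiableError(ValueError):
    """Raised when a record cannot be assigned a channel under a scheme."""


@dataclasses.dataclass(frozen=True)
class MutationRecord:
    """One somatic variant in MAF-style allele representation.

    ``pos`` is 1-based. SBS/DBS: position of the (first) substituted base.
    DEL: position of the first deleted base, ``ref`` the deleted sequence,
    ``alt`` ``"-"``. INS: position of the base immediately 5' of the
    insertion, ``ref`` ``"-"``, ``alt`` the inserted sequence.
    """

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str  # SBS | DBS | INS | DEL

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if self.vtype == "SBS" and not (len(self.ref) == len(self.alt) == 1):
            raise ValueError("SBS requires single-base alleles")
        if self.vtype == "DBS" and not (len(self.ref) == len(self.alt) == 2):
            raise ValueError("DBS requires two-base alleles")
        if self.vtype == "DEL" and self.alt != "-":
            raise ValueError("DEL requires alt '-'")
        if self.vtype == "INS" and self.ref != "-":
            raise ValueError("INS requires ref '-'")


@dataclasses.dataclass(frozen=True)
class Scheme:
    """A mutational-channel classification scheme."""

    name: str
    kind: str  # SBS | DBS | ID
    flank: int  # bp of context each side (SBS only)
    strand_aware: bool
    labels: tuple[str, ...]

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def label_index(self) -> dict[str, int]:
        return _label_index(self.name)

    def __str__(self) -> str:  # pragma: no cover
        return self.name


@lru_cache(maxsize=None)
def _label_index(name: str) -> dict[str, int]:
    return {lab: i for i, lab in enumerate(enumerate_channels(name).labels)}


def _sbs_labels(flank: int) -> list[str]:
    flanks = ["".join(p) for p in itertools.product("ACGT", repeat=flank)]
    out = []
    for sub in SUBSTITUTIONS:
        for left in flanks:
            for right in flanks:
                if flank == 0:
                    out.append(sub)
                else:
                    out.append(f"{left}[{sub}]{right}")
    return out


def _dbs_labels() -> list[str]:
    # canonical alts per COSMIC DBS-78 reference doublet
    alts = {
        "AC": "CA CG CT GA GG GT TA TG TT",
        "AT": "CA CC CG GA GC TA",
        "CC": "AA AG AT GA GG GT TA TG TT",
        "CG": "AT GC GT TA TC TT",
        "CT": "AA AC AG GA GC GG TA TC TG",
        "GC": "AA AG AT CA CG TA",
        "TA": "AT CG CT GC GG GT",
        "TC": "AA AG AT CA CG CT GA GG GT",
        "TG": "AA AC AT CA CC CT GA GC GT",
        "TT": "AA AC AG CA CC CG GA GC GG",
    }
    return [f"{ref}>{alt}" for ref in DBS_REF_SET for alt in alts[ref].split()]


def _id_labels() -> list[str]:
    out = []
    for base in "CT":
        out += [f"1:Del:{base}:{n}" for n in range(1, 7)]
    for base in "CT":
        out += [f"1:Ins:{base}:{n}" for n in range(0, 6)]
    for length in (2, 3, 4, 5):
        out += [f"{length}:Del:R:{n}" for n in range(1, 7)]
    for length in (2, 3, 4, 5):
        out += [f"{length}:Ins:R:{n}" for n in range(0, 6)]
    for length in (2, 3, 4, 5):
        out += [f"{length}:Del:M:{h}" for h in range(1, min(length - 1, 5) + 1 if length < 5 else 6)]
    return out


_SCHEME_DEFS = {
    "SBS6": ("SBS", 0, False),
    "SBS24": ("SBS", 0, True),
    "SBS96": ("SBS", 1, False),
    "SBS384": ("SBS", 1, True),
    "SBS1536": ("SBS", 2, False),
    "SBS6144": ("SBS", 2, True),
    "SBS24576": ("SBS", 3, False),
    "DBS78": ("DBS", 0, False),
    "ID83": ("ID", 0, False),
    "ID415": ("ID", 0, True),
}


@lru_cache(maxsize=None)
def enumerate_channels(scheme_name: str) -> Scheme:
    """Return the named scheme with its canonically ordered channel labels."""
    if scheme_name not in _SCHEME_DEFS:
        raise ValueError(f"unknown scheme {scheme_name!r}")
    kind, flank, strand_aware = _SCHEME_DEFS[scheme_name]
    if kind == "SBS":
        base = _sbs_labels(flank)
        labels = [f"{c}:{lab}" for c in "TUBN" for lab in base] if strand_aware else base
    elif kind == "DBS":
        labels = _dbs_labels()
    else:
        base = _id_labels()
        labels = [f"{c}:{lab}" for c in ID_CATEGORIES for lab in base] if strand_aware else base
    return Scheme(scheme_name, kind, flank, strand_aware, tuple(labels))


def get_scheme(scheme) -> Scheme:
    return scheme if isinstance(scheme, Scheme) else enumerate_channels(scheme)


# -- label parsing -------------------------------------------------------


def parse_sbs_label(label: str) -> tuple[Optional[str], str, str, str]:
    """Split an SBS label into (category, left flank, ref>alt core, right flank)."""
    cat = None
    if len(label) > 1 and label[1] == ":":
        cat, label = label[0], label[2:]
    if "[" in label:
        left, rest = label.split("[")
        core, right = rest.split("]")
    else:
        left = right = ""
        core = label
    return cat, left, core, right


def sbs_channel_context(label: str) -> tuple[Optional[str], str, str]:
    """Placement key of an SBS channel: (category, k-mer context, alt base)."""
    cat, left, core, right = parse_sbs_label(label)
    ref, alt = core.split(">")
    return cat, left + ref + right, alt


def format_sbs_label(
    left: str, ref: str, alt: str, right: str, category: Optional[str] = None
) -> str:
    core = f"{ref}>{alt}"
    lab = f"{left}[{core}]{right}" if left or right else core
    return f"{category}:{lab}" if category else lab


# -- classification ------------------------------------------------------


def classify_sbs(
    rec: MutationRecord,
    genome: ReferenceGenome | ContextIndex,
    scheme,
    tmap: TranscriptionMap | None = None,
) -> str:
    """Channel label of a single base substitution under an SBS scheme."""
    scheme = get_scheme(scheme)
    if scheme.kind != "SBS" or rec.vtype != "SBS":
        raise UnclassifiableError(f"{rec.vtype} record under {scheme.name}")
    pos0 = rec.pos - 1
    chrom_seq = _chrom_seq(genome, rec.chrom)
    h = scheme.flank
    if pos0 - h < 0 or pos0 + h + 1 > len(chrom_seq):
        raise UnclassifiableError("context window off chromosome end")
    window = chrom_seq[pos0 - h : pos0 + h + 1]
    if window[h] != rec.ref:
        raise UnclassifiableError(
            f"reference mismatch at {rec.chrom}:{rec.pos}: genome {window[h]}, record {rec.ref}"
        )
    if "N" in window:
        raise UnclassifiableError("context window contains N")
    pyr = rec.ref in PYRIMIDINES
    if pyr:
        left, ref, alt, right = window[:h], rec.ref, rec.alt, window[h + 1 :]
    else:
        rc = revcomp(window)
        left, ref, alt, right = rc[:h], rc[h], _COMP[rec.alt], rc[h + 1 :]
    cat = None
    if scheme.strand_aware:
        if tmap is None:
            raise ValueError(f"{scheme.name} requires a transcription map")
        raw = int(tmap.raw[rec.chrom][pos0])
        cat = CAT_LETTERS[effective_category(raw, pyr)]
    return format_sbs_label(left, ref, alt, right, cat)


@lru_cache(maxsize=None)
def _dbs_label_set() -> frozenset:
    return frozenset(enumerate_channels("DBS78").labels)


def canonical_dbs(ref: str, alt: str) -> str:
    """Canonical DBS-78 label of a doublet substitution (revcomp-collapsed)."""
    if len(ref) != 2 or len(alt) != 2:
        raise UnclassifiableError("DBS requires two-base alleles")
    if ref[0] == alt[0] or ref[1] == alt[1]:
        raise UnclassifiableError(f"{ref}>{alt} shares a base with its reference")
    label = f"{ref}>{alt}"
    if label in _dbs_label_set():
        return label
    label = f"{revcomp(ref)}>{revcomp(alt)}"
    if label not in _dbs_label_set():
        raise UnclassifiableError(f"{ref}>{alt} is not a valid doublet substitution")
    return label


def classify_dbs(rec: MutationRecord, genome: ReferenceGenome | ContextIndex) -> str:
    """Channel label of a doublet base substitution under DBS-78."""
    if rec.vtype != "DBS":
        raise UnclassifiableError(f"{rec.vtype} record under DBS78")
    pos0 = rec.pos - 1
    chrom_seq = _chrom_seq(genome, rec.chrom)
    if chrom_seq[pos0 : pos0 + 2] != rec.ref:
        raise UnclassifiableError(
            f"reference mismatch at {rec.chrom}:{rec.pos}: genome "
            f"{chrom_seq[pos0:pos0 + 2]}, record {rec.ref}"
        )
    return canonical_dbs(rec.ref, rec.alt)


def _homopolymer_run(seq: str, pos: int, base: str) -> int:
    """Length of the maximal run of ``base`` containing/adjacent to ``pos``."""
    n = 0
    i = pos
    while i >= 0 and seq[i] == base:
        n += 1
        i -= 1
    i = pos + 1
    while i < len(seq) and seq[i] == base:
        n += 1
        i += 1
    return n


def _count_unit_copies(seq: str, right_start: int, left_end: int, unit: str) -> int:
    """Adjacent copies of ``unit`` 3' of ``right_start`` and 5' of ``left_end``."""
    d = len(unit)
    n = 0
    i = right_start
    while seq[i : i + d] == unit:
        n += 1
        i += d
    i = left_end - d
    while i >= 0 and seq[i : i + d] == unit:
        n += 1
        i -= d
    return n


def indel_label(seq: str, vtype: str, p0: int, unit: str) -> str:
    """Strandless ID-83 label of a left-aligned indel on a sequence string.

    ``p0`` is the 0-based offset of the first deleted base (DEL) or of the
    position the inserted sequence would occupy (INS); ``unit`` the
    deleted/inserted sequence.
    """
    if not unit or "-" in unit:
        raise UnclassifiableError("empty indel allele")
    if "N" in unit:
        raise UnclassifiableError("indel allele contains N")
    if vtype == "DEL":
        if seq[p0 : p0 + len(unit)] != unit:
            raise UnclassifiableError(f"reference mismatch for deletion at offset {p0}")
        if p0 > 0 and seq[p0 - 1] == unit[-1]:
            raise UnclassifiableError("deletion is not left-aligned")
        start_after = p0 + len(unit)
    else:
        if p0 > 0 and seq[p0 - 1] == unit[-1]:
            raise UnclassifiableError("insertion is not left-aligned")
        start_after = p0
    d = len(unit)
    if d == 1:
        base = unit
        letter = base if base in PYRIMIDINES else _COMP[base]
        if vtype == "DEL":
            run = _homopolymer_run(seq, p0, base)
            return f"1:Del:{letter}:{min(run, 6)}"
        run = 0
        i = p0
        while i < len(seq) and seq[i] == base:
            run += 1
            i += 1
        return f"1:Ins:{letter}:{min(run, 5)}"
    if vtype == "DEL":
        copies = _count_unit_copies(seq, start_after, p0, unit)
        total = copies + 1  # include the deleted copy itself
        if total == 1:
            hom = 0
            for i in range(d - 1):
                if start_after + i < len(seq) and seq[start_after + i] == unit[i]:
                    hom += 1
                else:
                    break
            if hom > 0:
                return f"{min(d, 5)}:Del:M:{min(hom, 5)}"
            return f"{min(d, 5)}:Del:R:1"
        return f"{min(d, 5)}:Del:R:{min(total, 6)}"
    copies = _count_unit_copies(seq, p0, p0, unit)
    return f"{min(d, 5)}:Ins:R:{min(copies, 5)}"


def indel_category(raw_arr, footprint: tuple[int, int], unit: str) -> str:
    """Transcription category letter of an indel from gene-strand codes.

    Spanning a category boundary yields the boundary category Q. One-base
    indels orient by the pyrimidine of the indel base pair; longer indels
    have no pyrimidine anchor and use the reference strand (the coding,
    i.e. untranscribed, strand of a + gene).
    """
    raws = {int(raw_arr[p]) for p in range(*footprint)}
    if len(raws) > 1:
        return "Q"
    raw = raws.pop()
    if raw == RAW_NONE:
        return "N"
    if raw == RAW_BOTH:
        return "B"
    if len(unit) == 1:
        return CAT_LETTERS[effective_category(raw, unit in PYRIMIDINES)]
    return "U" if raw == RAW_PLUS else "T"


def indel_footprint(vtype: str, p0: int, unit: str, seq_len: int) -> tuple[int, int]:
    if vtype == "DEL":
        return (p0, p0 + len(unit))
    return (max(p0 - 1, 0), min(p0 + 1, seq_len))


def classify_indel(
    rec: MutationRecord,
    genome: ReferenceGenome | ContextIndex,
    tmap: TranscriptionMap | None = None,
    scheme="ID83",
) -> str:
    """Channel label of a left-aligned minimal indel under ID-83 / ID-415."""
    scheme = get_scheme(scheme)
    if scheme.kind != "ID" or rec.vtype not in ("INS", "DEL"):
        raise UnclassifiableError(f"{rec.vtype} record under {scheme.name}")
    seq = _chrom_seq(genome, rec.chrom)
    unit = rec.ref if rec.vtype == "DEL" else rec.alt
    p0 = rec.pos - 1 if rec.vtype == "DEL" else rec.pos
    label = indel_label(seq, rec.vtype, p0, unit)
    if not scheme.strand_aware:
        return label
    if tmap is None:
        raise ValueError(f"{scheme.name} requires a transcription map")
    cat = indel_category(tmap.raw[rec.chrom], indel_footprint(rec.vtype, p0, unit, len(seq)), unit)
    return f"{cat}:{label}"


def _chrom_seq(genome: ReferenceGenome | ContextIndex, chrom: str) -> str:
    if chrom not in getattr(genome, "names", ()):
        raise UnclassifiableError(f"unknown chromosome {chrom}")
    if isinstance(genome, ReferenceGenome):
        # immutable: decode each chromosome once
        cache = genome.__dict__.setdefault("_seq_cache", {})
        if chrom not in cache:
            cache[chrom] = genome.sequence(chrom)
        return cache[chrom]
    return genome.sequence(chrom)


def classify(rec: MutationRecord, genome, scheme, tmap=None) -> str:
    """Dispatch a record to the classifier matching the scheme kind."""
    scheme = get_scheme(scheme)
    if scheme.kind == "SBS":
        return classify_sbs(rec, genome, scheme, tmap)
    if scheme.kind == "DBS":
        return classify_dbs(rec, genome)
    return classify_indel(rec, genome, tmap, scheme)


# -- matrices ------------------------------------------------------------


@dataclasses.dataclass
class MutationalMatrix:
    """Channels x samples count matrix for one classification scheme."""

    scheme: Scheme
    df: pd.DataFrame  # index: channel labels, columns: samples
    n_excluded: int = 0

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    def column(self, sample: str) -> np.ndarray:
        return self.df[sample].to_numpy()

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "MutationType", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, scheme) -> "MutationalMatrix":
        scheme = get_scheme(scheme)
        df = pd.read_csv(path, sep="\t").set_index("MutationType")
        df = df.reindex(list(scheme.labels), fill_value=0).astype(int)
        return cls(scheme, df)


def build_matrix(
    catalog: Iterable[MutationRecord],
    genome,
    scheme,
    tmap: TranscriptionMap | None = None,
    by_chromosome: bool = False,
):
    """Classify a catalog into a channels x samples matrix.

    Records incompatible with the scheme or unclassifiable (N in window,
    window off a chromosome end) are excluded and tallied. With
    ``by_chromosome`` a dict of per-chromosome matrices is returned, for
    simulations that preserve each chromosome's burden and pattern.
    """
    scheme = get_scheme(scheme)
    counts: dict = {}
    samples: list[str] = []
    excluded = 0
    for rec in catalog:
        try:
            label = classify(rec, genome, scheme, tmap)
        except UnclassifiableError as exc:
            logger.debug("excluded record %s:%s: %s", rec.chrom, rec.pos, exc)
            excluded += 1
            continue
        if rec.sample not in samples:
            samples.append(rec.sample)
        key = (rec.chrom, label, rec.sample) if by_chromosome else (label, rec.sample)
        counts[key] = counts.get(key, 0) + 1
    if excluded:
        logger.warning("%d records excluded as unclassifiable under %s", excluded, scheme.name)
    if not by_chromosome:
        df = pd.DataFrame(0, index=list(scheme.labels), columns=samples, dtype=int)
        for (label, sample), n in counts.items():
            df.loc[label, sample] = n
        return MutationalMatrix(scheme, df, excluded)
    chroms = sorted({c for c, _, _ in counts})
    out = {}
    for chrom in chroms:
        df = pd.DataFrame(0, index=list(scheme.labels), columns=samples, dtype=int)
        for (c, label, sample), n in counts.items():
            if c == chrom:
                df.loc[label, sample] = n
        out[chrom] = MutationalMatrix(scheme, df, excluded)
    return out


@lru_cache(maxsize=None)
def _collapse_map(source_name: str, target_name: str) -> tuple[str, ...]:
    """Per-source-channel target labels; raises if target is not a coarsening."""
    source = enumerate_channels(source_name)
    target = enumerate_channels(target_name)
    if source.kind != target.kind:
        raise ValueError(f"{target_name} is not a coarsening of {source_name}")
    if source.kind == "SBS":
        if target.flank > source.flank or (target.strand_aware and not source.strand_aware):
            raise ValueError(f"{target_name} is not a coarsening of {source_name}")
        trim = source.flank - target.flank
        out = []
        for lab in source.labels:
            cat, left, core, right = parse_sbs_label(lab)
            left = left[trim:] if trim else left
            right = right[: len(right) - trim] if trim else right
            out.append(
                format_sbs_label(left, *core.split(">"), right, cat if target.strand_aware else None)
            )
        return tuple(out)
    if source.kind == "ID":
        if target.strand_aware and not source.strand_aware:
            raise ValueError(f"{target_name} is not a coarsening of {source_name}")
        if source.strand_aware and not target.strand_aware:
            return tuple(lab.split(":", 1)[1] for lab in source.labels)
        return source.labels
    return source.labels  # DBS78 -> DBS78


def collapse_matrix(m: MutationalMatrix, target) -> MutationalMatrix:
    """Sum a matrix down a many-to-one channel map onto a coarser scheme."""
    target = get_scheme(target)
    mapping = _collapse_map(m.scheme.name, target.name)
    grouped = m.df.groupby(list(mapping), sort=False).sum()
    grouped = grouped.reindex(list(target.labels), fill_value=0).astype(int)
    grouped.index.name = m.df.index.name
    return MutationalMatrix(target, grouped, m.n_excluded)
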