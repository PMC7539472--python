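"""Reference genomes, transcription/region annotation and k-mer context indexes.

The simulator needs to know, for every eligible genomic position, which
strand-collapsed sequence context it carries, which transcriptional category
it falls in, and what its relative placement weight is.  All of that is held
in :class:`ContextIndex`, a per-chromosome set of numpy arrays that can be
queried for counts, sampled from, and incrementally edited when mutations are
simulated as dependent (sequence-updating) events.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

# base encoding: A=0 C=1 G=2 T=3 N=4; complement(b) = 3-b for b<4
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASE = "ACGTN"
PYRIMIDINES = frozenset("CT")

# transcription categories, raw (gene-strand) frame
RAW_NONE, RAW_PLUS, RAW_MINUS, RAW_BOTH = 0, 1, 2, 3
# effective categories, pyrimidine frame (these are the label letters)
CAT_LETTERS = "NTUB"
CAT_N, CAT_T, CAT_U, CAT_B = 0, 1, 2, 3

# canonical reference doublets of the DBS-78 classification
DBS_REF_SET = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as a uint8 array (A=0,C=1,G=2,T=3,N=4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    if (out == 255).any():
        bad = chr(arr[out == 255][0])
        raise ValueError(f"non-IUPAC character in sequence: {bad!r}")
    return out


_DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    return _DECODE_LUT[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


@dataclasses.dataclass
class ReferenceGenome:
    """Ordered named chromosomes with uppercase ACGTN sequences."""

    names: list[str]
    codes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names")
        for name in self.names:
            if self.codes[name].size == 0:
                raise ValueError(f"empty sequence for chromosome {name}")

    @classmethod
    def from_sequences(cls, chromosomes: Iterable[tuple[str, str]]) -> "ReferenceGenome":
        names, codes = [], {}
        for name, seq in chromosomes:
            names.append(name)
            codes[name] = encode(seq.upper())
        return cls(names, codes)

    @property
    def chromosomes(self) -> list[tuple[str, str]]:
        return [(n, self.sequence(n)) for n in self.names]

    def sequence(self, name: str) -> str:
        return decode(self.codes[name])

    def length(self, name: str) -> int:
        return int(self.codes[name].size)

    @property
    def total_length(self) -> int:
        return sum(self.codes[n].size for n in self.names)

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 0-based position."""
        return _BASE[self.codes[chrom][pos]]

    def slice(self, chrom: str, start: int, end: int) -> str:
        return decode(self.codes[chrom][start:end])


def load_genome(fasta_path) -> ReferenceGenome:
    """Load a FASTA file, preserving record order and uppercasing sequences."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return ReferenceGenome.from_sequences((r.id, str(r.seq)) for r in records)


@dataclasses.dataclass
class TranscriptionMap:
    """Per-position transcription categories derived from gene intervals.

    Internally stores the gene-strand frame (none/+/-/both); the pyrimidine
    frame T/U flip is applied by classification and by the context index.
    """

    raw: dict[str, np.ndarray]  # uint8, RAW_* codes

    def category(self, chrom: str, pos: int) -> str:
        """Category letter at a position, for a pyrimidine on the + strand."""
        return CAT_LETTERS[effective_category(int(self.raw[chrom][pos]), True)]


def effective_category(raw_code: int, pyrimidine_on_plus: bool) -> int:
    """Map a gene-strand category to the pyrimidine-frame category letter code.

    A gene on the + strand is transcribed from the - strand, so a pyrimidine
    on + lies on the untranscribed strand (U); the reverse-complement
    representation flips T and U.
    """
    if raw_code == RAW_NONE:
        return CAT_N
    if raw_code == RAW_BOTH:
        return CAT_B
    if raw_code == RAW_PLUS:
        return CAT_U if pyrimidine_on_plus else CAT_T
    return CAT_T if pyrimidine_on_plus else CAT_U


def build_transcription_map(
    genome: ReferenceGenome, genes: Iterable[tuple[str, int, int, str]]
) -> TranscriptionMap:
    """Build per-position categories from (chrom, start, end, strand) intervals.

    Intervals are 0-based half-open. Positions covered by genes on both
    strands are bi-directional; single-strand cover keeps the gene strand.
    """
    plus = {n: np.zeros(genome.length(n), dtype=bool) for n in genome.names}
    minus = {n: np.zeros(genome.length(n), dtype=bool) for n in genome.names}
    for chrom, start, end, strand in genes:
        if chrom not in plus:
            raise ValueError(f"gene on unknown chromosome {chrom}")
        if not (0 <= start < end <= genome.length(chrom)):
            raise ValueError(f"gene interval out of bounds: {chrom}:{start}-{end}")
        if strand not in "+-":
            raise ValueError(f"invalid strand {strand!r}")
        (plus if strand == "+" else minus)[chrom][start:end] = True
    raw = {}
    for n in genome.names:
        arr = np.zeros(genome.length(n), dtype=np.uint8)
        arr[plus[n]] = RAW_PLUS
        arr[minus[n]] = RAW_MINUS
        arr[plus[n] & minus[n]] = RAW_BOTH
        raw[n] = arr
    return TranscriptionMap(raw)


@dataclasses.dataclass
class RegionMask:
    """Interval weights scaling the local opportunity for simulated mutations.

    Weight 0 removes sites from the samplable set. Positions outside the
    listed intervals default to weight 1.0 unless the mask is declared
    exhaustive (then 0.0). Later intervals override earlier ones.
    """

    intervals: dict[str, list[tuple[int, int, float]]]
    exhaustive: bool = False

    def weights(self, genome: ReferenceGenome, chrom: str) -> np.ndarray:
        w = np.full(genome.length(chrom), 0.0 if self.exhaustive else 1.0)
        for start, end, weight in self.intervals.get(chrom, []):
            if weight < 0:
                raise ValueError("mask weights must be nonnegative")
            if not (0 <= start < end <= genome.length(chrom)):
                raise ValueError(f"mask interval out of bounds: {chrom}:{start}-{end}")
            w[start:end] = weight
        return w


def _doublet_canon_lut() -> np.ndarray:
    """16-entry lookup: doublet id -> id of its canonical DBS reference."""
    lut = np.zeros(16, dtype=np.int32)
    canon_ids = {_CODE[d[0]] * 4 + _CODE[d[1]] for d in DBS_REF_SET}
    for a in range(4):
        for b in range(4):
            i = a * 4 + b
            rc = (3 - b) * 4 + (3 - a)
            lut[i] = i if i in canon_ids else rc
    return lut


_DBS_CANON = _doublet_canon_lut()


class ContextIndex:
    """Strand-collapsed k-mer context counts and samplable site sets.

    For odd ``k`` each position with a complete N-free window centred on it
    carries the pyrimidine-collapsed k-mer id of that window; for ``k == 2``
    each left-base position carries the canonical DBS reference-doublet id.
    Per-position arrays also hold the effective transcription category and the
    mask weight, so eligible sites of a (context, category) can be enumerated,
    weighted, and sampled. ``apply_sequence_edit`` keeps everything consistent
    under point edits for dependent-event simulation.
    """

    def __init__(
        self,
        genome: ReferenceGenome,
        k: int,
        tmap: TranscriptionMap | None = None,
        mask: RegionMask | None = None,
        exome: dict[str, Sequence[tuple[int, int]]] | None = None,
    ):
        if k not in (1, 2, 3, 5, 7):
            raise ValueError(f"unsupported context width k={k}")
        self.k = k
        self.h = (k - 1) // 2 if k % 2 == 1 else 0
        self.genome = genome
        self.tmap = tmap
        self.names = list(genome.names)
        self.codes: dict[str, np.ndarray] = {n: genome.codes[n].copy() for n in self.names}
        self.rawcat: dict[str, np.ndarray] = {}
        self.weight: dict[str, np.ndarray] = {}
        self.in_scope: dict[str, np.ndarray] = {}
        self.ctx: dict[str, np.ndarray] = {}
        self.effcat: dict[str, np.ndarray] = {}
        self._cache: dict = {}
        self._powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        if exome is not None:
            for chrom in exome:
                if chrom not in self.codes:
                    raise ValueError(f"exome target on unknown chromosome {chrom}")
        for n in self.names:
            L = genome.length(n)
            self.rawcat[n] = (
                tmap.raw[n].copy() if tmap is not None else np.zeros(L, dtype=np.uint8)
            )
            self.weight[n] = (
                mask.weights(genome, n) if mask is not None else np.ones(L)
            )
            scope = np.zeros(L, dtype=bool) if exome is not None else np.ones(L, dtype=bool)
            if exome is not None:
                for start, end in exome.get(n, []):
                    if not (0 <= start < end <= L):
                        raise ValueError(f"exome interval out of bounds: {n}:{start}-{end}")
                    scope[start:end] = True
            self.in_scope[n] = scope
            self._rebuild_chrom(n)
        n_eligible = sum(int((self.ctx[n] >= 0).sum()) for n in self.names)
        if n_eligible == 0:
            raise ValueError(f"no complete N-free window of width {k} in the genome")
        if mask is not None:
            total = sum(
                float(self.weight[n][(self.ctx[n] >= 0)].sum()) for n in self.names
            )
            if total <= 0:
                raise ValueError("mask leaves no position with positive weight")

    # -- construction ---------------------------------------------------

    def _rebuild_chrom(self, chrom: str) -> None:
        c = self.codes[chrom]
        L = c.size
        k, h = self.k, self.h
        ctx = np.full(L, -1, dtype=np.int32)
        eff = np.zeros(L, dtype=np.uint8)
        if L >= k:
            win = np.lib.stride_tricks.sliding_window_view(c, k)
            valid = (win < 4).all(axis=1)
            fwd = (win.astype(np.int64) * self._powers).sum(axis=1)
            comp = 3 - win[:, ::-1].astype(np.int64)
            rc = (comp * self._powers).sum(axis=1)
            if k == 2:
                collapsed = np.where(valid, _DBS_CANON[np.where(valid, fwd, 0)], -1)
                ctx[: L - 1] = collapsed
                raw = self.rawcat[chrom][: L - 1]
                eff[: L - 1] = np.where(raw == RAW_BOTH, CAT_B, np.where(raw == 0, CAT_N, raw))
                ctx[: L - 1][~self.in_scope[chrom][: L - 1]] = -1
            else:
                center = c[h : L - h]
                pyr = (center == 1) | (center == 3)
                collapsed = np.where(pyr, fwd, rc)
                ctx[h : L - h] = np.where(valid, collapsed, -1)
                raw = self.rawcat[chrom][h : L - h]
                eff_slice = np.empty(raw.size, dtype=np.uint8)
                eff_slice[raw == RAW_NONE] = CAT_N
                eff_slice[raw == RAW_BOTH] = CAT_B
                single = (raw == RAW_PLUS) | (raw == RAW_MINUS)
                # + gene & pyrimidine center -> U; flips with strand/purine
                is_u = (raw == RAW_PLUS) == pyr
                eff_slice[single & is_u] = CAT_U
                eff_slice[single & ~is_u] = CAT_T
                eff[h : L - h] = eff_slice
                ctx[h : L - h][~self.in_scope[chrom][h : L - h]] = -1
        self.ctx[chrom] = ctx
        self.effcat[chrom] = eff
        self._cache.clear()

    # -- queries --------------------------------------------------------

    def context_id(self, context: str) -> int:
        if len(context) != self.k:
            raise ValueError(f"context {context!r} has wrong width for k={self.k}")
        return int(sum(_CODE[b] * p for b, p in zip(context, self._powers)))

    def context_str(self, ctx_id: int) -> str:
        out = []
        for p in self._powers:
            out.append(_BASE[(ctx_id // p) % 4])
        return "".join(out)

    def counts(self, chrom: str | None = None, by_category: bool = False) -> dict:
        """Raw (mask-independent) context counts.

        Keys are context strings, or (context, category letter) tuples when
        ``by_category`` is true; restricted to one chromosome when given.
        """
        chroms = [chrom] if chrom is not None else self.names
        out: dict = {}
        n_ctx = 4**self.k
        for n in chroms:
            ctx = self.ctx[n]
            sel = ctx >= 0
            if by_category:
                combo = ctx[sel] * 4 + self.effcat[n][sel]
                bc = np.bincount(combo, minlength=n_ctx * 4)
                for flat in np.flatnonzero(bc):
                    key = (self.context_str(flat // 4), CAT_LETTERS[flat % 4])
                    out[key] = out.get(key, 0) + int(bc[flat])
            else:
                bc = np.bincount(ctx[sel], minlength=n_ctx)
                for cid in np.flatnonzero(bc):
                    key = self.context_str(int(cid))
                    out[key] = out.get(key, 0) + int(bc[cid])
        return out

    def eligible_sites(
        self, chrom: str, context: str | int, category: int | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Positions (and mask weights) carrying a context, optionally a category.

        Only sites with positive weight are returned; positions are 0-based
        window centres (left base for doublets).
        """
        cid = self.context_id(context) if isinstance(context, str) else context
        key = (chrom, cid, category)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        sel = (self.ctx[chrom] == cid) & (self.weight[chrom] > 0)
        if category is not None:
            sel &= self.effcat[chrom] == category
        pos = np.flatnonzero(sel)
        w = self.weight[chrom][pos]
        self._cache[key] = (pos, w)
        return pos, w

    def abundance(self, chrom: str, context: str | int, category: int | None = None) -> float:
        """Mask-weighted abundance of a (context, category) on one chromosome."""
        _, w = self.eligible_sites(chrom, context, category)
        return float(w.sum())

    def sequence(self, chrom: str) -> str:
        """Current (possibly edited) sequence of a chromosome."""
        return decode(self.codes[chrom])

    def base(self, chrom: str, pos: int) -> str:
        return _BASE[self.codes[chrom][pos]]

    def copy(self) -> "ContextIndex":
        new = object.__new__(ContextIndex)
        new.__dict__.update(
            k=self.k,
            h=self.h,
            genome=self.genome,
            tmap=self.tmap,
            names=list(self.names),
            codes={n: a.copy() for n, a in self.codes.items()},
            rawcat=self.rawcat,
            weight=self.weight,
            in_scope=self.in_scope,
            ctx={n: a.copy() for n, a in self.ctx.items()},
            effcat={n: a.copy() for n, a in self.effcat.items()},
            _cache={},
            _powers=self._powers,
        )
        return new

    # -- editing --------------------------------------------------------

    def _recompute_window(self, chrom: str, center: int) -> None:
        c = self.codes[chrom]
        L = c.size
        k, h = self.k, self.h
        if k == 2:
            lo, hi = center, center + 2
            if lo < 0 or hi > L:
                return
            pair = c[lo:hi]
            if (pair >= 4).any() or not self.in_scope[chrom][center]:
                self.ctx[chrom][center] = -1
                return
            fwd = int(pair[0]) * 4 + int(pair[1])
            self.ctx[chrom][center] = _DBS_CANON[fwd]
            return
        lo, hi = center - h, center + h + 1
        if lo < 0 or hi > L:
            return
        win = c[lo:hi]
        if (win >= 4).any() or not self.in_scope[chrom][center]:
            self.ctx[chrom][center] = -1
            self.effcat[chrom][center] = CAT_N
            return
        fwd = int((win.astype(np.int64) * self._powers).sum())
        pyr = c[center] in (1, 3)
        if pyr:
            cid = fwd
        else:
            comp = 3 - win[::-1].astype(np.int64)
            cid = int((comp * self._powers).sum())
        self.ctx[chrom][center] = cid
        self.effcat[chrom][center] = effective_category(int(self.rawcat[chrom][center]), pyr)


def apply_sequence_edit(
    index: ContextIndex, chrom: str, pos: int, ref: str, alt: str
) -> ContextIndex:
    """Apply a single-base substitution to the index's sequence state.

    Every k-window overlapping ``pos`` is re-derived, so context counts and
    samplable sites stay equal to a fresh rebuild on the edited sequence.
    """
    code = index.codes[chrom]
    if _BASE[code[pos]] != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: genome has {_BASE[code[pos]]}, record says {ref}"
        )
    if ref == alt:
        raise ValueError("ref and alt are identical")
    code[pos] = _CODE[alt]
    if index.k == 2:
        centers = range(pos - 1, pos + 1)
    else:
        centers = range(pos - index.h, pos + index.h + 1)
    for c in centers:
        if 0 <= c < code.size:
            index._recompute_window(chrom, c)
    index._cache.clear()
    return index


def build_context_index(
    genome: ReferenceGenome,
    k: int,
    tmap: TranscriptionMap | None = None,
    mask: RegionMask | None = None,
    exome: dict[str, Sequence[tuple[int, int]]] | None = None,
) -> ContextIndex:
    """Count and index strand-collapsed k-mer contexts across a genome."""
    return ContextIndex(genome, k, tmap=tmap, mask=mask, exome=exome)
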