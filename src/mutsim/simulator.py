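"""Monte Carlo engine: turn an observed channel spectrum into random catalogs.

The engine preserves a sample's mutational pattern at the chosen
classification resolution: each channel's count is (optionally Poisson
perturbed, then) split across chromosomes in proportion to the mask-weighted
abundance of the channel's sequence context, and every mutation is placed
uniformly (weight-proportionally) over the currently eligible sites of that
context and transcription category. With updating (dependent events) enabled,
each placed substitution edits the working copy of the genome so subsequent
draws see the updated channel rates.
"""

from __future__ import annotations

import dataclasses
import hashlib
from collections import defaultdict
from typing import Iterator, Optional

import numpy as np

from .classification import (
    MutationalMatrix,
    MutationRecord,
    Scheme,
    get_scheme,
    indel_category,
    indel_label,
    sbs_channel_context,
)
from .genome import (
    CAT_LETTERS,
    ContextIndex,
    ReferenceGenome,
    RegionMask,
    TranscriptionMap,
    apply_sequence_edit,
    build_context_index,
    revcomp,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
SEX_CHROMOSOMES_MALE_ONLY = ("chrY", "Y")


class SiteExhaustionError(RuntimeError):
    """No remaining eligible site for a demanded channel."""


@dataclasses.dataclass
class SimulationOptions:
    """Options of one simulation run; defaults give the proportional model."""

    scheme: str | Scheme = "SBS96"
    iterations: int = 1
    seed: int = 0
    updating: bool = False
    per_chromosome: bool = False
    gender: str = "female"
    exome: bool = False
    poisson_noise: bool = False
    mask: Optional[RegionMask] = None
    output_format: str = "VCF"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.gender not in ("female", "male"):
            raise ValueError("gender must be 'female' or 'male'")
        if self.output_format not in ("VCF", "MAF"):
            raise ValueError("output_format must be VCF or MAF")

    def digest(self) -> str:
        fields = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "mask"
        }
        fields["scheme"] = get_scheme(fields["scheme"]).name
        payload = repr(sorted(fields.items()))
        return hashlib.md5(payload.encode()).hexdigest()[:12]


@dataclasses.dataclass(frozen=True)
class Provenance:
    sample: str
    iteration: int
    seed: int
    options_digest: str


@dataclasses.dataclass
class SimulatedCatalog:
    records: list[MutationRecord]
    provenance: Provenance

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def plan_counts(spectrum: np.ndarray, opts: SimulationOptions, rng) -> np.ndarray:
    """Target per-channel counts: the observed spectrum, or a Poisson draw
    around it when noise is enabled (a channel observed 0 times stays 0)."""
    spectrum = np.asarray(spectrum)
    if (spectrum < 0).any():
        raise ValueError("spectrum counts must be nonnegative")
    if not opts.poisson_noise:
        return spectrum.copy()
    return rng.poisson(spectrum)


def _female(opts: SimulationOptions) -> frozenset:
    return frozenset(SEX_CHROMOSOMES_MALE_ONLY) if opts.gender == "female" else frozenset()


class ChannelPlacer:
    """Per-run placement state: parsed channels and cached site lookups."""

    def __init__(self, index: ContextIndex, scheme: Scheme, tmap: TranscriptionMap | None):
        self.index = index
        self.scheme = scheme
        self.tmap = tmap
        self.channels: list = [self._parse(label) for label in scheme.labels]
        self._cum: dict = {}
        self._id_sites_cache: dict = {}
        self._seq_cache: dict = {}

    def _parse(self, label: str):
        if self.scheme.kind == "SBS":
            cat, ctx, alt = sbs_channel_context(label)
            cid = self.index.context_id(ctx)
            cat_code = CAT_LETTERS.index(cat) if cat is not None else None
            return ("SBS", cid, cat_code, ctx[len(ctx) // 2], alt)
        if self.scheme.kind == "DBS":
            ref, alt = label.split(">")
            return ("DBS", self.index.context_id(ref), None, ref, alt)
        return ("ID", label)

    def seq(self, chrom: str) -> str:
        if chrom not in self._seq_cache:
            self._seq_cache[chrom] = self.index.sequence(chrom)
        return self._seq_cache[chrom]

    def invalidate(self, chrom: str) -> None:
        self._cum.clear()
        self._seq_cache.pop(chrom, None)

    # -- abundances -----------------------------------------------------

    def abundance(self, chrom: str, ci: int) -> float:
        info = self.channels[ci]
        if info[0] in ("SBS", "DBS"):
            return self.index.abundance(chrom, info[1], info[2])
        _, w, _ = self._id_sites(chrom, info[1])
        return float(w.sum()) if w.size else 0.0

    # -- substitution site sampling -------------------------------------

    def _cum_sites(self, chrom: str, cid: int, cat):
        key = (chrom, cid, cat)
        hit = self._cum.get(key)
        if hit is None:
            pos, w = self.index.eligible_sites(chrom, cid, cat)
            hit = (pos, np.cumsum(w))
            self._cum[key] = hit
        return hit

    def draw_subst_site(self, chrom: str, cid: int, cat, rng) -> int:
        pos, cumw = self._cum_sites(chrom, cid, cat)
        if pos.size == 0 or cumw[-1] <= 0:
            raise SiteExhaustionError(f"no eligible site on {chrom}")
        i = int(np.searchsorted(cumw, rng.random() * cumw[-1], side="right"))
        return int(pos[min(i, pos.size - 1)])

    # -- indel sites -----------------------------------------------------

    def _id_channel_parts(self, label: str):
        if self.scheme.strand_aware:
            cat, rest = label.split(":", 1)
        else:
            cat, rest = None, label
        length_s, kind, subtype, n_s = rest.split(":")
        return cat, rest, kind, subtype, int(length_s), int(n_s)

    def _id_sites(self, chrom: str, label: str):
        """Candidate (positions, weights, templates) for one indel channel.

        Templates are (ref, alt) allele pairs; ``alt is None`` marks channels
        whose inserted sequence is drawn at placement time (zero-copy
        insertions). Every stored candidate classifies back to the channel.
        """
        key = (chrom, label)
        hit = self._id_sites_cache.get(key)
        if hit is not None:
            return hit
        cat, rest, kind, subtype, length, n = self._id_channel_parts(label)
        seq = self.seq(chrom)
        L = len(seq)
        d = 1 if subtype in "CT" else length
        if subtype == "M" and length == 5 and n == 5:
            d = 6  # homology 5 requires a deletion longer than 5 bp
        weight = self.index.weight[chrom]
        scope = self.index.in_scope[chrom]
        raw = self.index.rawcat[chrom]
        positions, weights, templates = [], [], []
        for p in range(1, L - d):
            if weight[p] <= 0 or not scope[p]:
                continue
            if kind == "Del":
                unit = seq[p : p + d]
                if "N" in unit or seq[p - 1] == unit[-1]:
                    continue
                try:
                    if indel_label(seq, "DEL", p, unit) != rest:
                        continue
                except ValueError:
                    continue
                if cat is not None and indel_category(raw, (p, p + d), unit) != cat:
                    continue
                positions.append(p)
                weights.append(weight[p])
                templates.append((unit, "-"))
            elif d == 1:
                alts = []
                for b in (subtype, _COMP[subtype]):
                    try:
                        if indel_label(seq, "INS", p, b) != rest:
                            continue
                    except ValueError:
                        continue
                    if cat is not None and indel_category(raw, (p - 1, p + 1), b) != cat:
                        continue
                    alts.append(b)
                if alts:
                    positions.append(p)
                    weights.append(weight[p])
                    templates.append(("-", tuple(alts)))
            else:
                if n >= 1:
                    unit = seq[p : p + d]
                    if "N" in unit:
                        continue
                    try:
                        if indel_label(seq, "INS", p, unit) != rest:
                            continue
                    except ValueError:
                        continue
                    if cat is not None and indel_category(raw, (p - 1, p + 1), unit) != cat:
                        continue
                    positions.append(p)
                    weights.append(weight[p])
                    templates.append(("-", unit))
                else:
                    if "N" in seq[p - 1 : p + d]:
                        continue
                    if cat is not None and indel_category(raw, (p - 1, p + 1), "NN") != cat:
                        continue
                    positions.append(p)
                    weights.append(weight[p])
                    templates.append(("-", None))
        hit = (np.asarray(positions), np.asarray(weights, dtype=float), templates)
        self._id_sites_cache[key] = hit
        return hit

    def draw_id_site(self, chrom: str, label: str, rng, occupied) -> MutationRecord | None:
        positions, weights, templates = self._id_sites(chrom, label)
        if positions.size == 0:
            raise SiteExhaustionError(f"no eligible site for {label} on {chrom}")
        cumw = np.cumsum(weights)
        _, rest, kind, subtype, length, n = self._id_channel_parts(label)
        seq = self.seq(chrom)
        for _ in range(200):
            i = int(np.searchsorted(cumw, rng.random() * cumw[-1], side="right"))
            i = min(i, positions.size - 1)
            p = int(positions[i])
            ref, alt = templates[i]
            if kind == "Del":
                fp = range(p, p + len(ref))
            else:
                fp = range(max(p - 1, 0), p + 1)
            if any(q in occupied for q in fp):
                continue
            if alt is None:  # zero-copy multi-base insertion: draw the unit
                alt = self._draw_insertion_unit(seq, p, length, rest, rng)
                if alt is None:
                    continue
            elif isinstance(alt, tuple):
                alt = alt[int(rng.integers(len(alt)))]
            occupied.update(fp)
            if kind == "Del":
                return MutationRecord("", chrom, p + 1, ref, "-", "DEL")
            return MutationRecord("", chrom, p, "-", alt, "INS")
        # weighted redraws kept colliding; fall back to scanning the
        # remaining sites in random order for a free one
        for i in rng.permutation(positions.size):
            p = int(positions[i])
            ref, alt = templates[i]
            fp = range(p, p + len(ref)) if kind == "Del" else range(max(p - 1, 0), p + 1)
            if any(q in occupied for q in fp):
                continue
            if alt is None:
                alt = self._draw_insertion_unit(seq, p, length, rest, rng)
                if alt is None:
                    continue
            elif isinstance(alt, tuple):
                alt = alt[int(rng.integers(len(alt)))]
            occupied.update(fp)
            if kind == "Del":
                return MutationRecord("", chrom, p + 1, ref, "-", "DEL")
            return MutationRecord("", chrom, p, "-", alt, "INS")
        raise SiteExhaustionError(f"no remaining eligible site for {label} on {chrom}")

    @staticmethod
    def _draw_insertion_unit(seq: str, p: int, d: int, rest: str, rng) -> str | None:
        for _ in range(64):
            unit = "".join("ACGT"[b] for b in rng.integers(0, 4, size=d))
            try:
                if indel_label(seq, "INS", p, unit) == rest:
                    return unit
            except ValueError:
                continue
        return None


def allocate_counts(
    counts: np.ndarray,
    placer: ChannelPlacer,
    opts: SimulationOptions,
    rng,
) -> dict[str, np.ndarray]:
    """Split per-channel counts over chromosomes by a multinomial draw with
    probabilities proportional to each chromosome's weighted context
    abundance. Per-channel totals are conserved exactly."""
    index = placer.index
    skip = _female(opts)
    chroms = [c for c in index.names if c not in skip]
    out = {c: np.zeros(len(counts), dtype=int) for c in chroms}
    for ci, n in enumerate(counts):
        n = int(n)
        if n == 0:
            continue
        ab = np.array([placer.abundance(c, ci) for c in chroms])
        if ab.sum() <= 0:
            label = placer.scheme.labels[ci]
            raise SiteExhaustionError(f"channel {label} has no eligible site genome-wide")
        split = rng.multinomial(n, ab / ab.sum())
        for c, m in zip(chroms, split):
            out[c][ci] = m
    return out


def place_mutations(
    chrom_counts: dict[str, np.ndarray],
    placer: ChannelPlacer,
    opts: SimulationOptions,
    rng,
    sample: str = "",
    iteration: int = 0,
) -> SimulatedCatalog:
    """Place allocated counts onto chromosomes; one catalog, sorted."""
    index = placer.index
    scheme = placer.scheme
    records: list[MutationRecord] = []
    occupied: dict[str, set] = defaultdict(set)
    for chrom in index.names:
        counts = chrom_counts.get(chrom)
        if counts is None:
            continue
        for ci in np.flatnonzero(counts):
            info = placer.channels[ci]
            n = int(counts[ci])
            if info[0] == "ID":
                for _ in range(n):
                    rec = placer.draw_id_site(chrom, info[1], rng, occupied[chrom])
                    records.append(dataclasses.replace(rec, sample=sample))
                continue
            _, cid, cat, ref, alt = info
            pos_all, _ = index.eligible_sites(chrom, cid, cat)
            if pos_all.size < n:
                raise SiteExhaustionError(
                    f"channel {scheme.labels[ci]} needs {n} sites on {chrom}, "
                    f"only {pos_all.size} eligible"
                )
            placed = 0
            attempts = 0
            width = 1 if info[0] == "SBS" else 2
            while placed < n:
                attempts += 1
                if attempts > 200 * n + 1000:
                    raise SiteExhaustionError(
                        f"could not place {scheme.labels[ci]} on {chrom} (collisions)"
                    )
                p = placer.draw_subst_site(chrom, cid, cat, rng)
                fp = range(p, p + width)
                if any(q in occupied[chrom] for q in fp):
                    continue
                occupied[chrom].update(fp)
                if info[0] == "SBS":
                    fwd = index.base(chrom, p) == ref
                    r, a = (ref, alt) if fwd else (_COMP[ref], _COMP[alt])
                    records.append(MutationRecord(sample, chrom, p + 1, r, a, "SBS"))
                    if opts.updating:
                        apply_sequence_edit(index, chrom, p, r, a)
                        placer.invalidate(chrom)
                else:
                    site_ref = index.base(chrom, p) + index.base(chrom, p + 1)
                    fwd = site_ref == ref
                    a = alt if fwd else revcomp(alt)
                    records.append(MutationRecord(sample, chrom, p + 1, site_ref, a, "DBS"))
                    if opts.updating:
                        apply_sequence_edit(index, chrom, p, site_ref[0], a[0])
                        apply_sequence_edit(index, chrom, p + 1, site_ref[1], a[1])
                        placer.invalidate(chrom)
                placed += 1
    order = {c: i for i, c in enumerate(index.names)}
    records.sort(key=lambda r: (order[r.chrom], r.pos))
    return SimulatedCatalog(
        records, Provenance(sample, iteration, opts.seed, opts.digest())
    )


def _iteration_rng(seed: int, sample_index: int, iteration: int):
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(sample_index, iteration))
    )


def default_context_width(scheme: Scheme) -> int:
    if scheme.kind == "SBS":
        return 2 * scheme.flank + 1
    return 2 if scheme.kind == "DBS" else 1


def simulate(
    matrix: MutationalMatrix | dict[str, MutationalMatrix],
    genome: ReferenceGenome,
    opts: SimulationOptions,
    tmap: TranscriptionMap | None = None,
    index: ContextIndex | None = None,
    exome: dict | None = None,
) -> Iterator[SimulatedCatalog]:
    """Simulate every sample of a catalog matrix for the requested iterations.

    Yields one :class:`SimulatedCatalog` per (sample, iteration), each drawn
    from an independent RNG stream derived from ``(seed, sample, iteration)``.
    In per-chromosome mode ``matrix`` must be a dict of per-chromosome
    matrices (see ``build_matrix(by_chromosome=True)``) and each chromosome's
    spectrum is reproduced exactly on that chromosome.
    """
    scheme = get_scheme(opts.scheme)
    per_chrom = opts.per_chromosome
    if per_chrom != isinstance(matrix, dict):
        raise ValueError("per_chromosome mode requires per-chromosome matrices (and vice versa)")
    if scheme.strand_aware and tmap is None:
        raise ValueError(f"{scheme.name} requires a transcription map")
    if opts.updating and scheme.kind == "ID":
        raise ValueError("updating (dependent-event) mode supports substitution schemes only")
    if opts.exome and exome is None and index is None:
        raise ValueError("exome mode requires target intervals")
    if index is None:
        index = build_context_index(
            genome,
            default_context_width(scheme),
            tmap=tmap,
            mask=opts.mask,
            exome=exome if opts.exome else None,
        )
    some = next(iter(matrix.values())) if per_chrom else matrix
    if some.scheme.name != scheme.name:
        raise ValueError(f"matrix scheme {some.scheme.name} != options scheme {scheme.name}")
    samples = some.samples
    base_placer = ChannelPlacer(index, scheme, tmap)
    for si, sample in enumerate(samples):
        for it in range(opts.iterations):
            rng = _iteration_rng(opts.seed, si, it)
            if opts.updating:
                placer = ChannelPlacer(index.copy(), scheme, tmap)
            else:
                placer = base_placer
            if per_chrom:
                chrom_counts = {
                    chrom: plan_counts(m.column(sample), opts, rng)
                    for chrom, m in matrix.items()
                }
            else:
                counts = plan_counts(matrix.column(sample), opts, rng)
                chrom_counts = allocate_counts(counts, placer, opts, rng)
            yield place_mutations(chrom_counts, placer, opts, rng, sample, it)
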