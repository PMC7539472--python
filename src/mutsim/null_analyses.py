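"""Null-hypothesis analyses built on simulated catalogs.

Three questions are supported:

* how many doublet base substitutions (DBSs) would arise purely from two
  independent single base substitutions landing on adjacent positions, and is
  the observed DBS count enriched over that null (z-test, BH-corrected);
* whether simulating at a coarse resolution reproduces the mutational
  pattern seen at a finer sequence context (cosine similarity against a 0.85
  identity threshold);
* how similar two random nonnegative spectra are by chance (the cosine
  null: mean ~0.75 for iid uniform entries, exceedance of 0.85 below 1e-6).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classification import (
    MutationRecord,
    build_matrix,
    canonical_dbs,
    enumerate_channels,
    get_scheme,
)

logger = logging.getLogger(__name__)

COSINE_IDENTITY_THRESHOLD = 0.85


@dataclasses.dataclass
class DbsNullResult:
    """Observed-vs-simulated adjacent-DBS comparison for one sample."""

    sample: str
    real_dbs: int
    sim_mean: float
    sim_sd: float
    fold_increase: float
    z: float
    p: float
    q: float | None = None


@dataclasses.dataclass
class SimilarityResult:
    """Cosine of real vs simulated spectra at an extended evaluation context."""

    sample: str
    eval_scheme: str
    iteration: int
    cosine: float
    passes: bool
    included: bool


def count_adjacent_pairs(
    catalog: Iterable[MutationRecord],
) -> tuple[int, pd.Series]:
    """Count pairs of SBSs at consecutive genomic positions.

    The catalog must be position-sorted within chromosomes. A run of m
    consecutive SBSs contributes floor(m/2) non-overlapping pairs, paired
    left to right; each pair is classified into DBS-78 from the two
    single-base alts. Returns the pair count and the DBS-78 spectrum.
    """
    scheme = enumerate_channels("DBS78")
    spectrum = pd.Series(0, index=list(scheme.labels))
    records = [r for r in catalog if r.vtype == "SBS"]
    count = 0
    i = 0
    while i < len(records) - 1:
        a, b = records[i], records[i + 1]
        if a.chrom == b.chrom and b.pos == a.pos + 1:
            count += 1
            label = canonical_dbs(a.ref + b.ref, a.alt + b.alt)
            spectrum[label] += 1
            i += 2  # non-overlapping: a run of three yields one pair
        else:
            i += 1
    return count, spectrum


def dbs_null_test(real_dbs: int, sim_counts: Sequence[int], sample: str = "") -> DbsNullResult:
    """One-sided upper-tail z-test of the observed DBS count against the
    simulated adjacent-pair distribution (population sd over iterations)."""
    if len(sim_counts) == 0:
        raise ValueError("empty simulation list")
    sim = np.asarray(sim_counts, dtype=float)
    mean = float(sim.mean())
    sd = float(sim.std())  # population convention (divide by N)
    fold = real_dbs / mean if mean > 0 else math.inf if real_dbs > 0 else 0.0
    if sd == 0:
        logger.warning("degenerate simulated sd=0 for sample %r", sample)
        z = math.inf if real_dbs > mean else (-math.inf if real_dbs < mean else 0.0)
        p = 0.0 if real_dbs > mean else (1.0 if real_dbs < mean else 0.5)
    else:
        z = (real_dbs - mean) / sd
        p = float(stats.norm.sf(z))
    return DbsNullResult(sample, real_dbs, mean, sd, fold, z, p)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in the original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def dbs_null_analysis(
    real_dbs: dict[str, int], sim_pair_counts: dict[str, Sequence[int]]
) -> list[DbsNullResult]:
    """Run the z-test per sample and BH-correct across samples."""
    results = [
        dbs_null_test(real_dbs[s], sim_pair_counts[s], sample=s) for s in real_dbs
    ]
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = q
    return results


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def extended_context_similarity(
    real_catalog: Iterable[MutationRecord],
    simulated_catalogs: Iterable,
    sim_scheme,
    eval_scheme,
    genome,
    tmap=None,
    threshold: float = COSINE_IDENTITY_THRESHOLD,
) -> list[SimilarityResult]:
    """Compare real vs simulated spectra at a finer evaluation resolution.

    Builds the eval-scheme spectrum of the real catalog and of each simulated
    catalog and reports per-iteration cosines. A sample is flagged excluded
    (``included=False``) when its catalog is too sparse for the evaluation
    resolution: fewer than 2 mutations per channel on average, i.e. total
    mutations < 2 x n_channels.
    """
    sim_scheme = get_scheme(sim_scheme)
    eval_scheme = get_scheme(eval_scheme)
    if eval_scheme.kind != sim_scheme.kind:
        raise ValueError("evaluation scheme must refine the simulation scheme")
    if eval_scheme.kind == "SBS" and eval_scheme.flank < sim_scheme.flank:
        raise ValueError(
            f"{eval_scheme.name} is coarser than the simulation scheme {sim_scheme.name}"
        )
    real = list(real_catalog)
    sample = real[0].sample if real else ""
    real_m = build_matrix(real, genome, eval_scheme, tmap)
    real_vec = real_m.df.iloc[:, 0].to_numpy() if real_m.samples else np.zeros(eval_scheme.n_channels)
    included = len(real) >= 2 * eval_scheme.n_channels
    out = []
    for it, cat in enumerate(simulated_catalogs):
        recs = list(cat)
        m = build_matrix(recs, genome, eval_scheme, tmap)
        vec = m.df.iloc[:, 0].to_numpy() if m.samples else np.zeros(eval_scheme.n_channels)
        c = cosine_similarity(real_vec, vec)
        out.append(
            SimilarityResult(sample, eval_scheme.name, it, c, c >= threshold, included)
        )
    return out


@dataclasses.dataclass
class RandomVectorNull:
    """Empirical cosine null for random nonnegative channel vectors."""

    n_vectors: int
    n_channels: int
    n_pairs: int
    mean_cosine: float
    exceedance: float  # fraction of pairs with cosine >= threshold
    threshold: float = COSINE_IDENTITY_THRESHOLD


def random_vector_null(
    n_vectors: int,
    n_channels: int,
    rng,
    threshold: float = COSINE_IDENTITY_THRESHOLD,
    max_pairs: int | None = None,
) -> RandomVectorNull:
    """Pairwise cosine similarity among random nonnegative vectors.

    Vectors have iid uniform [0, 1] entries. All distinct pairs are compared
    with a blocked matrix product; if ``max_pairs`` is given and the number
    of distinct pairs exceeds it, that many uniformly sampled pairs are used
    instead. As dimension grows the mean tends to E[x]^2 / E[x^2] = 0.75.
    """
    if n_vectors < 2:
        raise ValueError("need at least two vectors")
    u = rng.random((n_vectors, n_channels)).astype(np.float32)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    total_pairs = n_vectors * (n_vectors - 1) // 2
    if max_pairs is not None and total_pairs > max_pairs:
        acc = 0.0
        n_exceed = 0
        done = 0
        chunk = 50_000
        while done < max_pairs:
            m = min(chunk, max_pairs - done)
            i = rng.integers(0, n_vectors, size=m)
            j = rng.integers(0, n_vectors - 1, size=m)
            j = np.where(j >= i, j + 1, j)  # uniform over ordered distinct pairs
            c = np.einsum("ij,ij->i", u[i], u[j])
            acc += float(c.sum(dtype=np.float64))
            n_exceed += int((c >= threshold).sum())
            done += m
        return RandomVectorNull(
            n_vectors, n_channels, max_pairs, acc / max_pairs, n_exceed / max_pairs, threshold
        )
    acc = 0.0
    n_exceed = 0
    block = max(1, 2**22 // max(n_vectors, 1))
    cols = np.arange(n_vectors)
    for r0 in range(0, n_vectors, block):
        r1 = min(r0 + block, n_vectors)
        s = u[r0:r1] @ u.T
        mask = cols[None, :] > np.arange(r0, r1)[:, None]
        acc += float(s.sum(dtype=np.float64, where=mask))
        n_exceed += int(((s >= threshold) & mask).sum())
    return RandomVectorNull(
        n_vectors, n_channels, total_pairs, acc / total_pairs, n_exceed / total_pairs, threshold
    )
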