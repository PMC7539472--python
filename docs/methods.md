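# Methods

## Model

`mutsim` treats a sample's mutational catalog as a draw from a channel-level
background model. The observed catalog is classified into the channels of a
chosen scheme (SBS-6/24/96/384/1536/6144/24576, DBS-78, ID-83/415), and a
simulated catalog is generated in three stages per sample and iteration:

1. **Plan.** The target count of each channel is the observed count, or an
   independent Poisson draw with that mean when Poisson noise is enabled
   (applied once per iteration, before allocation). A channel observed zero
   times therefore stays zero.
2. **Allocate.** Each channel's count is split across chromosomes by a
   multinomial draw with probabilities proportional to the chromosome's
   mask-weighted abundance of the channel's sequence context (and strand
   category for strand-aware schemes). Per-channel totals are conserved
   exactly by construction. In per-chromosome mode the input is already a
   per-chromosome spectrum and allocation is the identity. For female
   samples chrY carries zero abundance.
3. **Place.** Each mutation is placed at a site drawn with probability
   proportional to its mask weight among the currently eligible sites of its
   (context, category). A site already mutated in the same iteration is
   rejected and redrawn. The emitted ref/alt follow the reference strand at
   the site: a pyrimidine-collapsed channel materializes as its reverse
   complement wherever the reference shows the purine representation — no
   coin is tossed, the sequence decides.

Mutations are independent events by default ("with replacement"). With
`updating` enabled, each placed substitution edits the working copy of the
genome, and every k-mer window overlapping the edited base is re-derived, so
later draws see the updated channel rates ("without replacement"). Because a
position can be mutated at most once per iteration, emitted reference
alleles always match the original genome; only the *context rates* evolve.

## Context index

The index stores, per chromosome, a per-position array of strand-collapsed
k-mer ids (k = 1, 3, 5, 7 for SBS schemes, 2 for doublets), the effective
transcription category, and the mask weight. Collapse maps each window onto
the representation whose central base is a pyrimidine (for doublets, onto a
fixed canonical reference-doublet set), so the index of a genome equals the
index of its reverse complement. Any window containing N, truncated by a
chromosome end, or outside the exome targets (in exome mode) is ineligible.
Raw counts ignore mask weights; the samplable site set and the abundances
used for chromosome allocation are weight-adjusted, and weight-0 sites are
removed from the samplable set entirely — a mask therefore shifts both
*where* mutations land and *how many* land per chromosome.

## Classification conventions

- Substitutions are pyrimidine-collapsed; labels follow the COSMIC-style
  grammar `A[C>T]G`, with a `T:`/`U:`/`B:`/`N:` prefix for strand-aware
  schemes. The category is assigned relative to the strand carrying the
  pyrimidine of the mutated pair: a pyrimidine on the coding strand of a
  `+` gene is untranscribed (U); the reverse-complement representation flips
  T and U.
- DBS-78 uses the canonical COSMIC reference doublets (AC, AT, CC, CG, CT,
  GC, TA, TC, TG, TT) with reverse-complement collapse; validity requires
  both positions to change.
- Indel labels read `length:kind:subtype:n`. For 1-bp deletions `n` is the
  total homopolymer run length in the reference (1–5, 6 = 6+); for 1-bp
  insertions the number of pre-existing copies (0–4, 5 = 5+); longer
  repeat-mediated indels count repeat units analogously; deletions at
  non-repetitive sites with flanking sequence identity are microhomology
  (`M`) channels with `n` the homology length. Indels must be left-aligned
  and minimal. ID-415's fifth category `Q` marks indels whose footprint
  spans a transcription-category boundary. Multi-base indels have no
  pyrimidine anchor; their T/U assignment uses the reference strand (the
  coding strand of a `+` gene is untranscribed).

## Null analyses

- **Adjacent doublets.** SBSs at consecutive positions are counted as
  non-overlapping pairs left to right, so a run of m consecutive SBSs
  yields ⌊m/2⌋ pairs; each pair is classified into DBS-78 from the two
  alts. The per-sample test is a one-sided upper-tail z-test of the
  observed DBS count against the simulated pair-count distribution, with
  the population standard deviation (divide by N) across iterations;
  degenerate sd = 0 maps to p = 0/0.5/1 by the sign of the difference, with
  a logged warning. Fold increase is observed / simulated mean.
  Benjamini–Hochberg correction across samples goes through
  `statsmodels.stats.multitest`.
- **Extended-context similarity.** Real and simulated catalogs are both
  classified at a finer evaluation scheme and compared per iteration by
  cosine similarity; 0.85 is the identity threshold. Samples with fewer
  than 2 mutations per evaluation channel on average (total < 2 ×
  n_channels) are flagged as too sparse; the flag is reported rather than
  silently dropping the sample.
- **Random-vector null.** Vectors have iid uniform [0, 1] entries; as the
  dimension grows, the expected pairwise cosine tends to
  E[x]² / E[x²] = 0.75. All distinct pairs are compared via a blocked
  matrix product in float32 (sums accumulated in float64); when a
  `max_pairs` budget is set and exceeded, uniformly sampled ordered pairs
  are used instead and the pair count is reported.

## Numerical and design choices

- **RNG.** numpy's PCG64. Each (sample, iteration) gets an independent
  stream via `SeedSequence(seed, spawn_key=(sample_index, iteration))`, so
  runs are reproducible and iterations independent.
- **Coordinates.** Internally 0-based half-open; all emitted VCF/MAF
  positions 1-based. Indels are held MAF-style (`-` for the absent allele)
  and converted to VCF anchored-base representation on write.
- **Collisions.** Within an iteration a site (footprint, for multi-base
  events) is mutated at most once; collisions are redrawn, with a
  deterministic scan of the remaining sites before declaring exhaustion.
  Exhaustion on tiny genomes is a hard error naming the channel and
  chromosome, never a silent undercount.
- **Updating mode** is limited to substitution schemes: an applied indel
  would shift all downstream coordinates and invalidate the emitted
  positions. Updating bookkeeping re-derives *all* windows overlapping an
  edit, not only the central one, so incremental counts always equal a
  fresh recount of the edited sequence (tested against that oracle).
- **Insertion materialization.** Repeat-extending insertions copy the
  adjacent unit from the reference. Zero-copy insertions have no sequence
  constraint at the site, so the inserted unit is drawn from the RNG and
  rejection-checked to classify back to the demanded channel.
- **Chromosome allocation** is multinomial (exact conservation per channel
  comes from the multinomial itself); largest-remainder rounding would also
  conserve totals but makes iterations less exchangeable.

## Synthetic fixtures

The fixture generator emulates just enough structure to exercise every code
path: iid bases at a requested GC content (default 41%, roughly the human
average; default 2 chromosomes × 50 kb, large enough that every
trinucleotide context occurs thousands of times), a deterministic
alternating-strand gene layout with one antisense overlap per chromosome so
bi-directional regions exist, and catalogs drawn from preset spectra
(uniform over sufficiently abundant channels; two-channel-concentrated;
strand-biased at a configurable T:U ratio). The uniform preset excludes
channels with fewer than 5 eligible sites (25 for indel channels, whose
candidate sites can mutually overlap) so that placement cannot exhaust a
channel by construction.

What the fixtures deliberately do not emulate: real chromosome-scale
composition, chromatin or replication-timing covariates of mutation rate,
sequencing artifacts, and clonal structure. Passing tests therefore
demonstrate the correctness of the bookkeeping (classification,
conservation, distributional behavior of placement) — not that any
particular biological background model is adequate for a given cohort.

## Problem sizes

Tests and the acceptance script run at fixture scale: genomes of 6–100 kb,
catalogs of 10²–10³·⁵ mutations, 1–1000 iterations, and the full
10,000-vector × 1536-channel cosine null (~5×10⁷ pairs). These sizes were
chosen so the whole suite completes in seconds while every estimate quoted
above is still well inside its sampling tolerance.

## Known limitations

- Exome mode restricts by the window's central position; a context window
  may straddle a target boundary.
- Sample sex only removes chrY for female samples; it does not halve male
  chrX opportunity (ploidy is outside the channel-rate model).
- MNPs longer than 2 bp and complex substitutions are rejected on read with
  a tally, not modeled.
- The germline use case is supported only insofar as a germline VCF can be
  simulated like any other catalog; no population allele-frequency model is
  included.
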