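"""Monte Carlo engine: planning, allocation, placement, full simulation."""

import numpy as np
import pytest
from scipy import stats

from mutsim import (
    ChannelPlacer,
    FixtureSpec,
    ReferenceGenome,
    RegionMask,
    SimulationOptions,
    SiteExhaustionError,
    allocate_counts,
    build_context_index,
    build_matrix,
    collapse_matrix,
    enumerate_channels,
    make_catalog,
    make_genome,
    place_mutations,
    plan_counts,
    simulate,
)


def genome_of(*seqs):
    return ReferenceGenome.from_sequences((f"chr{i+1}", s) for i, s in enumerate(seqs))


def rng_of(seed=0):
    return np.random.default_rng(seed)


class TestPlanCounts:
    def test_identity_without_noise(self):
        s = np.array([3, 0, 7])
        out = plan_counts(s, SimulationOptions(), rng_of())
        assert (out == s).all()

    def test_poisson_zero_stays_zero(self):
        s = np.zeros(50, dtype=int)
        out = plan_counts(s, SimulationOptions(poisson_noise=True), rng_of())
        assert (out == 0).all()

    def test_poisson_mean_matches_observed_count(self):
        # 10,000 independent draws around an observed count of 100
        s = np.full(10_000, 100)
        out = plan_counts(s, SimulationOptions(poisson_noise=True), rng_of(1))
        se = np.sqrt(100 / 10_000)
        assert abs(out.mean() - 100) < 3 * se


class TestAllocateCounts:
    def _placer(self, genome, scheme="SBS6"):
        scheme = enumerate_channels(scheme)
        index = build_context_index(genome, 1)
        return ChannelPlacer(index, scheme, None), scheme

    def test_single_chromosome_gets_everything(self):
        placer, scheme = self._placer(genome_of("ACGTACGT" * 10))
        counts = np.zeros(6, dtype=int)
        counts[scheme.labels.index("C>T")] = 12
        out = allocate_counts(counts, placer, SimulationOptions(scheme="SBS6"), rng_of())
        assert out["chr1"][scheme.labels.index("C>T")] == 12

    def test_multinomial_split_matches_abundance(self):
        # chr1 has 30 C/G positions, chr2 has 70: expect a 30/70 split
        g = genome_of("AC" * 30 + "AT" * 20, "AG" * 70)
        placer, scheme = self._placer(g)
        ci = scheme.labels.index("C>T")
        counts = np.zeros(6, dtype=int)
        counts[ci] = 10
        opts = SimulationOptions(scheme="SBS6")
        totals = np.zeros(2)
        n_draws = 2_000
        rng = rng_of(3)
        for _ in range(n_draws):
            out = allocate_counts(counts, placer, opts, rng)
            totals += [out["chr1"][ci], out["chr2"][ci]]
            assert out["chr1"][ci] + out["chr2"][ci] == 10
        p = 0.3
        se = np.sqrt(10 * p * (1 - p) / n_draws)
        assert abs(totals[0] / n_draws - 10 * p) < 3 * se

    def test_female_excludes_chrY(self):
        g = ReferenceGenome.from_sequences([("chr1", "ACGT" * 20), ("chrY", "ACGT" * 20)])
        index = build_context_index(g, 1)
        scheme = enumerate_channels("SBS6")
        placer = ChannelPlacer(index, scheme, None)
        counts = np.zeros(6, dtype=int)
        counts[scheme.labels.index("C>T")] = 50
        out_f = allocate_counts(counts, placer, SimulationOptions(scheme="SBS6"), rng_of(1))
        assert "chrY" not in out_f
        out_m = allocate_counts(
            counts, placer, SimulationOptions(scheme="SBS6", gender="male"), rng_of(1)
        )
        assert out_m["chrY"].sum() > 0

    def test_absent_context_raises(self):
        placer, scheme = self._placer(genome_of("ATATATAT"))
        counts = np.zeros(6, dtype=int)
        counts[scheme.labels.index("C>T")] = 1
        with pytest.raises(SiteExhaustionError):
            allocate_counts(counts, placer, SimulationOptions(scheme="SBS6"), rng_of())


class TestPlacement:
    def test_forced_single_site(self):
        g = genome_of("AAAACAAAA")  # exactly one ACA context site
        scheme = enumerate_channels("SBS96")
        index = build_context_index(g, 3)
        placer = ChannelPlacer(index, scheme, None)
        counts = np.zeros(96, dtype=int)
        counts[scheme.labels.index("A[C>T]A")] = 1
        cat = place_mutations({"chr1": counts}, placer, SimulationOptions(), rng_of())
        (rec,) = cat.records
        assert (rec.chrom, rec.pos, rec.ref, rec.alt) == ("chr1", 5, "C", "T")

    def test_purine_site_emits_reverse_complement(self):
        g = genome_of("AAATGTAAA")  # TGT in pyrimidine frame is ACA
        scheme = enumerate_channels("SBS96")
        index = build_context_index(g, 3)
        placer = ChannelPlacer(index, scheme, None)
        counts = np.zeros(96, dtype=int)
        counts[scheme.labels.index("A[C>T]A")] = 1
        cat = place_mutations({"chr1": counts}, placer, SimulationOptions(), rng_of())
        (rec,) = cat.records
        assert (rec.ref, rec.alt) == ("G", "A")

    def test_occupancy_uniform_over_equal_sites(self):
        # 4 equally weighted eligible ACA sites; 10,000 independent placements
        g = genome_of("AAACAAACAAACAAACAAA")
        scheme = enumerate_channels("SBS96")
        index = build_context_index(g, 3)
        placer = ChannelPlacer(index, scheme, None)
        sites, _ = index.eligible_sites("chr1", "ACA")
        assert sites.size == 4
        counts = np.zeros(96, dtype=int)
        counts[scheme.labels.index("A[C>T]G")] = 0
        counts[scheme.labels.index("A[C>T]A")] = 1
        rng = rng_of(17)
        occupancy = {int(p): 0 for p in sites}
        for _ in range(10_000):
            cat = place_mutations({"chr1": counts}, placer, SimulationOptions(), rng)
            occupancy[cat.records[0].pos - 1] += 1
        chi2 = stats.chisquare(list(occupancy.values()))
        assert chi2.pvalue > 0.01

    def test_mask_weights_shift_occupancy(self):
        g = genome_of("AAACAAACAAA")  # two ACA sites at 3 and 7
        mask = RegionMask({"chr1": [(0, 5, 9.0)]})  # site 3 weighted 9x
        scheme = enumerate_channels("SBS96")
        index = build_context_index(g, 3, mask=mask)
        placer = ChannelPlacer(index, scheme, None)
        counts = np.zeros(96, dtype=int)
        counts[scheme.labels.index("A[C>T]A")] = 1
        rng = rng_of(23)
        hits = {3: 0, 7: 0}
        for _ in range(2_000):
            cat = place_mutations({"chr1": counts}, placer, SimulationOptions(), rng)
            hits[cat.records[0].pos - 1] += 1
        assert stats.binomtest(hits[3], 2_000, 0.9).pvalue > 0.01


class TestSimulate:
    def test_empty_sample_yields_empty_catalog(self, medium_genome):
        m = build_matrix([], medium_genome, "SBS96")
        m.df["empty"] = 0
        cats = list(simulate(m, medium_genome, SimulationOptions(scheme="SBS96")))
        assert len(cats) == 1 and len(cats[0].records) == 0

    @pytest.mark.parametrize("scheme", ["SBS96", "DBS78", "ID83"])
    def test_pattern_conservation(self, scheme, small_genome, small_spec):
        recs, spectrum = make_catalog(small_genome, small_spec, scheme)
        m = build_matrix(recs, small_genome, scheme)
        opts = SimulationOptions(scheme=scheme, iterations=2, seed=11)
        for cat in simulate(m, small_genome, opts):
            rebuilt = build_matrix(cat.records, small_genome, scheme)
            assert (rebuilt.column("fixture") == spectrum).all()

    def test_conservation_propagates_to_coarsenings(
        self, medium_genome, medium_spec, medium_tmap
    ):
        recs, spectrum = make_catalog(
            medium_genome, medium_spec, "SBS384", tmap=medium_tmap
        )
        m = build_matrix(recs, medium_genome, "SBS384", medium_tmap)
        opts = SimulationOptions(scheme="SBS384", iterations=1, seed=2)
        (cat,) = simulate(m, medium_genome, opts, tmap=medium_tmap)
        rebuilt = build_matrix(cat.records, medium_genome, "SBS384", medium_tmap)
        assert (rebuilt.column("fixture") == spectrum).all()
        for coarse in ("SBS96", "SBS24", "SBS6"):
            a = collapse_matrix(rebuilt, coarse).df.values
            b = collapse_matrix(m, coarse).df.values
            assert (a == b).all()

    def test_reference_validity(self, medium_genome, medium_spec):
        recs, _ = make_catalog(medium_genome, medium_spec, "SBS96")
        m = build_matrix(recs, medium_genome, "SBS96")
        (cat,) = simulate(m, medium_genome, SimulationOptions(scheme="SBS96", seed=9))
        for rec in cat.records:
            assert medium_genome.base(rec.chrom, rec.pos - 1) == rec.ref

    def test_per_chromosome_exact(self, medium_genome, medium_spec):
        recs, _ = make_catalog(medium_genome, medium_spec, "SBS96")
        mats = build_matrix(recs, medium_genome, "SBS96", by_chromosome=True)
        opts = SimulationOptions(scheme="SBS96", per_chromosome=True, seed=5)
        (cat,) = simulate(mats, medium_genome, opts)
        rebuilt = build_matrix(cat.records, medium_genome, "SBS96", by_chromosome=True)
        for chrom, m in mats.items():
            assert (rebuilt[chrom].column("fixture") == m.column("fixture")).all()

    def test_exome_containment(self, medium_genome, medium_spec):
        recs, _ = make_catalog(medium_genome, medium_spec, "SBS96")
        m = build_matrix(recs, medium_genome, "SBS96")
        exome = {"chr1": [(2_000, 15_000)], "chr2": [(500, 9_000)]}
        opts = SimulationOptions(scheme="SBS96", exome=True, seed=5)
        (cat,) = simulate(m, medium_genome, opts, exome=exome)
        assert len(cat.records) == len(recs)
        for rec in cat.records:
            assert any(s <= rec.pos - 1 < e for s, e in exome[rec.chrom])

    def test_same_seed_identical_different_iterations_differ(
        self, medium_genome, medium_spec
    ):
        recs, _ = make_catalog(medium_genome, medium_spec, "SBS96")
        m = build_matrix(recs, medium_genome, "SBS96")
        opts = SimulationOptions(scheme="SBS96", iterations=2, seed=42)
        a = [c.records for c in simulate(m, medium_genome, opts)]
        b = [c.records for c in simulate(m, medium_genome, opts)]
        assert a == b
        assert a[0] != a[1]

    def test_updating_counts_match_fresh_recount(self, small_genome, small_spec):
        from mutsim import apply_sequence_edit

        recs, _ = make_catalog(small_genome, small_spec, "SBS96")
        m = build_matrix(recs, small_genome, "SBS96")
        opts = SimulationOptions(scheme="SBS96", seed=1, updating=True)
        (cat,) = simulate(m, small_genome, opts)
        index = build_context_index(small_genome, 3)
        for rec in cat.records:
            apply_sequence_edit(index, rec.chrom, rec.pos - 1, rec.ref, rec.alt)
        edited = ReferenceGenome.from_sequences(
            [(n, index.sequence(n)) for n in index.names]
        )
        fresh = build_context_index(edited, 3)
        assert index.counts(by_category=True) == fresh.counts(by_category=True)

    def test_updating_rejected_for_indel_schemes(self, small_genome, small_spec):
        recs, _ = make_catalog(small_genome, small_spec, "ID83")
        m = build_matrix(recs, small_genome, "ID83")
        opts = SimulationOptions(scheme="ID83", updating=True)
        with pytest.raises(ValueError):
            next(simulate(m, small_genome, opts))

    def test_poisson_noise_perturbs_totals(self, medium_genome, medium_spec):
        recs, spectrum = make_catalog(medium_genome, medium_spec, "SBS96")
        m = build_matrix(recs, medium_genome, "SBS96")
        opts = SimulationOptions(scheme="SBS96", iterations=5, seed=8, poisson_noise=True)
        totals = [len(c.records) for c in simulate(m, medium_genome, opts)]
        assert len(set(totals)) > 1  # noise actually applied
        assert abs(np.mean(totals) - spectrum.sum()) < 5 * np.sqrt(spectrum.sum())

    def test_scheme_mismatch_rejected(self, medium_genome, medium_spec):
        recs, _ = make_catalog(medium_genome, medium_spec, "SBS96")
        m = build_matrix(recs, medium_genome, "SBS96")
        with pytest.raises(ValueError):
            next(simulate(m, medium_genome, SimulationOptions(scheme="SBS6")))
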