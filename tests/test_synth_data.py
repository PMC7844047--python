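from __future__ import annotations

import numpy as np
import pytest

from cggcat.genotype_io import exclude_uncovered_loci, read_str_vcf
from cggcat.population_stats import summarize_callset
from cggcat.repeat_catalog import build_catalog, canonical_motif_frames
from cggcat.synth_data import (
    GUARD_BP,
    ConfigurationError,
    PlantedLocus,
    SimulationConfig,
    TruthRecord,
    apply_censoring,
    emit_vcf,
    generate_genome,
    plant_random_loci,
    simulate_population,
    write_fasta,
)


def _toy_truth(units_list, spacing=100):
    truth = []
    pos = 0
    for i, u in enumerate(units_list):
        truth.append(
            TruthRecord(
                locus_id=f"chr1_{pos + 1}", chrom="chr1", start=pos, end=pos + 3 * u,
                motif="CGG", units=u, n_interruptions=0, central_units=u,
                expected_polymorphism_rate=0.0,
            )
        )
        pos += 3 * u + spacing
    return truth


class TestGenerateGenome:
    def test_round_trip_equals_truth(self, small_genome_bundle, cgg_class):
        _, genome, truth = small_genome_bundle
        loci = build_catalog(genome, cgg_class)
        assert [(l.chrom, l.start, l.end) for l in loci] == [
            (t.chrom, t.start, t.end) for t in truth
        ]

    def test_zero_planted_loci(self, cgg_class):
        config = SimulationConfig(seed=1, genome_length=20_000)
        genome, truth = generate_genome(config)
        assert truth == []
        assert build_catalog(genome, cgg_class) == []

    def test_seed_determinism(self):
        config = SimulationConfig(
            seed=9, genome_length=5_000, planted_loci=[PlantedLocus("chr1", 500, "CGG", 6)]
        )
        g1, t1 = generate_genome(config)
        g2, t2 = generate_genome(config)
        assert g1 == g2 and t1 == t2

    def test_interruptions_planted_verbatim(self):
        p = PlantedLocus("chr1", 500, "CGG", 10, interruptions=(10,))
        config = SimulationConfig(seed=2, genome_length=5_000, planted_loci=[p])
        genome, _ = generate_genome(config)
        seq = genome["chr1"][500 : 500 + 30]
        assert seq[10] == "T"
        assert seq[:10] == ("CGG" * 4)[:10]

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_genome(
                SimulationConfig(
                    seed=0, genome_length=100,
                    planted_loci=[PlantedLocus("chr1", 10, "CGG", 50)],
                )
            )

    def test_overlapping_loci_rejected(self):
        config = SimulationConfig(
            seed=0, genome_length=5_000,
            planted_loci=[
                PlantedLocus("chr1", 500, "CGG", 10),
                PlantedLocus("chr1", 520, "CGG", 10),
            ],
        )
        with pytest.raises(ConfigurationError):
            generate_genome(config)

    def test_guard_flanks_are_at(self):
        config = SimulationConfig(
            seed=4, genome_length=5_000, planted_loci=[PlantedLocus("chr1", 500, "CGG", 6)]
        )
        genome, _ = generate_genome(config)
        seq = genome["chr1"]
        assert set(seq[500 - GUARD_BP : 500]) <= {"A", "T"}
        assert set(seq[518 : 518 + GUARD_BP]) <= {"A", "T"}

    def test_fasta_output_is_readable(self, small_genome_bundle, tmp_path):
        from cggcat.repeat_catalog import read_fasta

        _, genome, _ = small_genome_bundle
        path = tmp_path / "g.fa"
        write_fasta(genome, path)
        assert read_fasta(path) == genome


class TestPlantRandomLoci:
    def test_spacing_and_bounds(self):
        rng = np.random.default_rng(0)
        loci = plant_random_loci(rng, 50, 200_000, min_spacing=50)
        prev_end = None
        for p in sorted(loci, key=lambda p: p.position):
            if prev_end is not None:
                assert p.position - prev_end >= 50
            prev_end = p.end
        assert all(p.units >= 4 for p in loci)

    def test_interruptions_only_in_long_repeats(self):
        rng = np.random.default_rng(1)
        loci = plant_random_loci(rng, 100, 500_000, interrupted_fraction=0.5)
        for p in loci:
            if p.interruptions:
                assert p.units >= 8
                # interior, pairwise >= 2 units apart
                units_idx = [off // 3 for off in p.interruptions]
                assert all(1 <= u <= p.units - 2 for u in units_idx)
                for x, y in zip(units_idx, units_idx[1:]):
                    assert abs(y - x) >= 2

    def test_infeasible_packing(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ConfigurationError):
            plant_random_loci(rng, 100, 5_000)


class TestSimulatePopulation:
    def test_zero_instability_is_uniform(self):
        truth = _toy_truth([5, 10, 20])
        config = SimulationConfig(seed=0, n_samples=20, instability_floor=0.0, instability_slope=0.0)
        table = simulate_population(truth, config)
        for t in truth:
            sub = table[table["locus_id"] == t.locus_id]
            assert (sub["a1"] == t.central_units).all()
            assert (sub["a2"] == t.central_units).all()

    def test_alleles_truncated_at_one(self):
        truth = _toy_truth([4] * 10)
        config = SimulationConfig(
            seed=3, n_samples=50, instability_floor=1.0, instability_slope=0.0, step_geom_p=0.1
        )
        table = simulate_population(truth, config)
        assert (table[["a1", "a2"]] >= 1).all().all()

    def test_geometric_tail_exceeds_fifty(self):
        truth = _toy_truth([4] * 30)
        config = SimulationConfig(
            seed=4, n_samples=100, instability_floor=1.0, instability_slope=0.0, step_geom_p=0.05
        )
        table = simulate_population(truth, config)
        assert table[["a1", "a2"]].to_numpy().max() > 50

    def test_polymorphic_fraction_increases_with_units(self):
        rng_units = list(range(4, 61, 2)) * 8
        truth = _toy_truth(rng_units)
        config = SimulationConfig(
            seed=5, n_samples=200, instability_floor=0.0, instability_slope=0.0002
        )
        table = simulate_population(truth, config)
        by_units: dict[int, list[bool]] = {}
        for t in truth:
            sub = table[table["locus_id"] == t.locus_id]
            poly = bool(
                (sub["a1"] != t.central_units).any() or (sub["a2"] != t.central_units).any()
            )
            by_units.setdefault(t.central_units, []).append(poly)
        # expected per-allele rate p = slope * units; per-locus poly prob
        # 1 - (1-p)^(2n); check the empirical fraction tracks it loosely in
        # wide bins (binomial noise at 8 loci per unit value is large)
        lows = [v for u, vs in by_units.items() if u <= 20 for v in vs]
        highs = [v for u, vs in by_units.items() if u >= 44 for v in vs]
        assert np.mean(highs) > np.mean(lows)

    def test_determinism(self):
        truth = _toy_truth([5, 9])
        config = SimulationConfig(seed=6, n_samples=10)
        assert simulate_population(truth, config).equals(simulate_population(truth, config))


class TestCensoring:
    @pytest.mark.parametrize(
        "true_units,cap,expected",
        [
            (70, 50, 50),
            (40, 50, 40),
            (50, 50, 50),
            (151, 50, 151),  # far past the cap: fully in-read repeats
            (70, None, 70),
        ],
    )
    def test_apply_censoring(self, true_units, cap, expected):
        assert apply_censoring(true_units, cap) == expected

    def test_emitted_vcf_censored(self, tmp_path):
        truth = _toy_truth([40])
        config = SimulationConfig(
            seed=8, n_samples=30, instability_floor=1.0, instability_slope=0.0,
            step_geom_p=0.02, censor_cap=50,
        )
        table = simulate_population(truth, config)
        assert (table[["a1", "a2"]].to_numpy() > 50).any()  # some true alleles past cap
        path = emit_vcf(table, truth, config, tmp_path / "c.vcf")
        cs = read_str_vcf(path)
        reported = np.array(cs.alleles_at(truth[0].locus_id))
        assert not ((reported > 50) & (reported < 150)).any()

    def test_auto_cap_derives_from_read_length(self):
        config = SimulationConfig(seed=0, censor_cap="auto", read_length=150)
        assert config.effective_censor_cap == 50
        assert SimulationConfig(seed=0).effective_censor_cap is None

    def test_no_cap_reports_truth(self, tmp_path):
        truth = _toy_truth([40])
        config = SimulationConfig(
            seed=8, n_samples=30, instability_floor=1.0, instability_slope=0.0,
            step_geom_p=0.02, censor_cap=None,
        )
        table = simulate_population(truth, config)
        path = emit_vcf(table, truth, config, tmp_path / "c.vcf")
        cs = read_str_vcf(path)
        for row in table.itertuples():
            assert cs.get(row.sample, row.locus_id).allele_units == tuple(
                sorted((row.a1, row.a2))
            )


class TestEmitVcf:
    def test_missing_rate_zero_full_call_rate(self, tmp_path):
        from cggcat.genotype_io import allele_call_rate

        truth = _toy_truth([5, 9, 14])
        config = SimulationConfig(seed=9, n_samples=20, missing_rate=0.0)
        table = simulate_population(truth, config)
        cs = read_str_vcf(emit_vcf(table, truth, config, tmp_path / "c.vcf"))
        assert allele_call_rate(cs) == 1.0

    def test_missing_rate_produces_no_calls(self, tmp_path):
        from cggcat.genotype_io import allele_call_rate

        truth = _toy_truth([5, 9, 14])
        config = SimulationConfig(seed=9, n_samples=40, missing_rate=0.2)
        table = simulate_population(truth, config)
        cs = read_str_vcf(emit_vcf(table, truth, config, tmp_path / "c.vcf"))
        assert allele_call_rate(cs) < 1.0

    def test_evidence_patterns_drive_exclusion(self, tmp_path):
        truth = _toy_truth([5, 9, 14])
        ids = [t.locus_id for t in truth]
        config = SimulationConfig(
            seed=10, n_samples=5,
            zero_coverage_loci=[ids[0]], flanking_only_loci=[ids[1]],
        )
        table = simulate_population(truth, config)
        cs = read_str_vcf(emit_vcf(table, truth, config, tmp_path / "c.vcf"))
        kept, excluded = exclude_uncovered_loci(cs)
        assert kept == [ids[2]]
        assert sorted(excluded) == sorted(
            [(ids[0], "no_coverage"), (ids[1], "flanking_only")]
        )

    def test_bad_dialect_rejected(self, tmp_path):
        truth = _toy_truth([5])
        config = SimulationConfig(seed=0, n_samples=2)
        table = simulate_population(truth, config)
        with pytest.raises(ValueError):
            emit_vcf(table, truth, config, tmp_path / "c.vcf", dialect="nope")


class TestFullRoundTrip:
    def test_medians_recover_planted_centrals(self, cohort_bundle, tmp_path):
        config, genome, truth, table = cohort_bundle
        path = emit_vcf(table, truth, config, tmp_path / "cohort.vcf")
        cs = read_str_vcf(path)
        summaries, _ = summarize_callset(cs)
        recovered = sum(
            1 for t in truth if summaries[t.locus_id].median_units == t.central_units
        )
        assert recovered >= 0.99 * len(truth)
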