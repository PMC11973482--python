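"""Forward simulator: Poisson occupancy, bottleneck choice, mutation input,
selection thinning, treatment variance structure, and determinism."""

import math

import numpy as np
import pytest

from liquidma import (DFE, DilutionDesign, FailedTransfer, SimulationConfig,
                      harmonic_mean_popsize, simulate_dilution_bottleneck,
                      simulate_experiment, simulate_transfer)
from liquidma.mutio import BPS_CLASSES
from liquidma.selection import compare_treatments, cv
from liquidma.simulate import inoculate_row, simulate_growth_curves


class TestDilutionBottleneck:
    def test_poisson_occupancy_at_half_turbidity(self, rng):
        # lambda = ln 2 makes exactly half of wells turbid: 1 - e^-ln2 = 0.5
        lam = math.log(2)
        n = 200_000
        counts = inoculate_row(lam, n, rng)
        turbid_fraction = (counts >= 1).mean()
        se = math.sqrt(0.5 * 0.5 / n)
        assert abs(turbid_fraction - 0.5) < 3 * se

    def test_rare_event_limit_single_founder(self, rng):
        # as lambda -> 0 a turbid well almost surely holds exactly one cell
        design = DilutionDesign(rows=((1e-4, 100_000),))
        founders = []
        for _ in range(200):
            try:
                f, _, _ = simulate_dilution_bottleneck(design, 1.0, rng)
                founders.append(f)
            except FailedTransfer:
                pass
        assert founders, "expected some turbid wells at 1e5 wells per attempt"
        assert np.mean(np.array(founders) == 1) >= 0.999 - 3 * math.sqrt(
            1e-4 / len(founders))

    def test_lowest_dilution_row_and_leftmost_well_chosen(self):
        # seeded so the outcome is known: verify the chosen well is the
        # leftmost turbid well of the last row containing any turbid well
        design = DilutionDesign(rows=((0.9, 8), (0.2, 8), (0.02, 8)))
        for seed in range(50):
            rng = np.random.default_rng(seed)
            state = rng.bit_generator.state
            founder, row, well = simulate_dilution_bottleneck(design, 1.0, rng)
            rng2 = np.random.default_rng(seed)
            rng2.bit_generator.state = state
            counts = [inoculate_row(lam, w, rng2) for lam, w in design.rows]
            turbid_rows = [i for i, c in enumerate(counts) if (c >= 1).any()]
            assert row == turbid_rows[-1]
            assert well == int(np.flatnonzero(counts[row] >= 1)[0])
            assert founder == counts[row][well] >= 1

    def test_founder_distribution_matches_analytic_conditional(self, rng):
        # brute-force MC at 1e5 replicates vs the closed-form mixture:
        # P(row r chosen) = (1 - e^-lam_r w) * prod_{r'>r} e^-lam_r' w,
        # founder | row ~ Poisson(lam_r) truncated to >= 1
        design = DilutionDesign(rows=((0.9, 8), (0.2, 8), (0.02, 8)))
        reps = 100_000
        observed = np.zeros(8, dtype=float)
        fails = 0
        for _ in range(reps):
            try:
                f, _, _ = simulate_dilution_bottleneck(design, 1.0, rng)
                if f < len(observed):
                    observed[f] += 1
            except FailedTransfer:
                fails += 1
        observed /= reps

        lams = [lam for lam, _ in design.rows]
        wells = [w for _, w in design.rows]
        p_clear = [math.exp(-l * w) for l, w in zip(lams, wells)]
        expected = np.zeros(8)
        p_fail = np.prod(p_clear)
        for r, lam in enumerate(lams):
            p_row = (1 - p_clear[r]) * np.prod(p_clear[r + 1:])
            trunc = 1 - math.exp(-lam)
            for k in range(1, 8):
                expected[k] += p_row * (math.exp(-lam) * lam ** k /
                                        math.factorial(k)) / trunc
        assert abs(fails / reps - p_fail) < 3 * math.sqrt(p_fail / reps) + 1e-4
        for k in range(1, 8):
            se = math.sqrt(max(expected[k], 1e-9) / reps)
            assert abs(observed[k] - expected[k]) < 4 * se + 1e-4

    def test_all_wells_clear_raises_failed_transfer(self):
        design = DilutionDesign(rows=((1e-9, 2),))
        with pytest.raises(FailedTransfer):
            simulate_dilution_bottleneck(design, 1.0, np.random.default_rng(0))

    def test_lambdas_must_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            DilutionDesign(rows=((0.5, 8), (0.9, 8)))


class TestSimulateTransfer:
    def test_neutral_mean_mutation_count_matches_analytic(self):
        # mu * L * G * T = 2.8e-8 * 4.6e6 * 29.9 * 20 = 77.02 expected BPS
        config = SimulationConfig(dfe=DFE.neutral(), mu_indel=0.0,
                                  lines=1, transfers=20)
        totals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(config.transfers):
                out = simulate_transfer(config, 1.0, rng)
                count += sum(not m.is_indel for m in out.mutations)
            totals.append(count)
        mean = np.mean(totals)
        sem = np.std(totals, ddof=1) / math.sqrt(len(totals))
        assert abs(mean - 77.02) < 3 * sem

    def test_zero_rate_zero_mutations(self):
        config = SimulationConfig(mu_bps=0.0, mu_indel=0.0)
        for seed in range(20):
            out = simulate_transfer(config, 1.0, np.random.default_rng(seed))
            assert out.mutations == ()

    def test_lethal_mutations_never_transmitted(self):
        config = SimulationConfig(dfe=DFE(lethal_fraction=1.0), mu_bps=5e-7)
        for seed in range(20):
            out = simulate_transfer(config, 1.0, np.random.default_rng(seed))
            assert out.mutations == ()
            assert out.n_final > 1  # census is not affected by lineage lethals

    def test_generations_are_log2_census_per_founder(self):
        config = SimulationConfig(dfe=DFE.neutral())
        out = simulate_transfer(config, 1.0, np.random.default_rng(1),
                                founder_count=4)
        assert out.generations == pytest.approx(math.log2(out.n_final / 4))

    def test_purifying_dfe_thins_transmission(self):
        strong = DFE(deleterious_mean_effect=0.2)
        cfg_neutral = SimulationConfig(dfe=DFE.neutral(), mu_bps=5e-7, mu_indel=0.0)
        cfg_purify = SimulationConfig(dfe=strong, mu_bps=5e-7, mu_indel=0.0)
        n_neutral = n_purify = 0
        for seed in range(100):
            n_neutral += len(simulate_transfer(
                cfg_neutral, 1.0, np.random.default_rng(seed)).mutations)
            n_purify += len(simulate_transfer(
                cfg_purify, 1.0, np.random.default_rng(10_000 + seed)).mutations)
        assert n_purify < n_neutral


class TestSimulateExperiment:
    def test_byte_identical_outputs_for_fixed_seed(self, tmp_path):
        for sub in ("a", "b"):
            config = SimulationConfig(lines=2, transfers=2, seed=123)
            simulate_experiment(config).write(tmp_path / sub)
        for name in ("mutations.tsv", "cfu.tsv", "curves.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_single_class_spectrum_emits_only_that_class(self):
        config = SimulationConfig(spectrum=(1.0, 0, 0, 0, 0, 0),
                                  lines=2, transfers=5, seed=7, mu_indel=0.0)
        result = simulate_experiment(config, growth_curves=False)
        assert (result.mutations["bps_class"] == "A:T->G:C").all()

    def test_plate_census_more_variable_than_liquid(self):
        # treatment-specific CV: plate colonies vary far more than liquid
        # wells; rank test on per-line CVs over 16 lines x 20 transfers
        liquid = simulate_experiment(
            SimulationConfig(treatment="liquid", seed=5), growth_curves=False)
        plate = simulate_experiment(
            SimulationConfig(treatment="plate", seed=6), growth_curves=False)
        cv_liquid = [cv(g["cfu_per_ml"].to_numpy())
                     for _, g in liquid.cfu.groupby("line_id")]
        cv_plate = [cv(g["cfu_per_ml"].to_numpy())
                    for _, g in plate.cfu.groupby("line_id")]
        _, p = compare_treatments(cv_liquid, cv_plate, test="mann_whitney")
        assert p < 0.01
        assert np.median(cv_plate) > np.median(cv_liquid)

    def test_every_mutation_traces_to_one_line_and_transfer(self):
        config = SimulationConfig(lines=4, transfers=6, seed=9)
        result = simulate_experiment(config, growth_curves=False)
        total_from_histories = sum(len(h.mutations) for h in result.histories)
        assert len(result.mutations) == total_from_histories
        for h in result.histories:
            assert len(h.generations) == config.transfers
            assert all(f >= 1 for f in h.founder_counts)
            assert all(1 <= m.transfer <= config.transfers for m in h.mutations)
            assert all(1 <= m.position <= config.genome_length for m in h.mutations)

    def test_genome_backed_positions_carry_real_ref_bases(self):
        from liquidma import synthesize_genome
        genome, annotation = synthesize_genome(20_000, coding_fraction=0.5, seed=2)
        config = SimulationConfig(genome=genome, annotation=annotation,
                                  mu_bps=5e-6, mu_indel=0.0, lines=2,
                                  transfers=3, seed=4)
        result = simulate_experiment(config, growth_curves=False)
        assert len(result.mutations) > 0
        for row in result.mutations.itertuples(index=False):
            assert genome.base(int(row.position)) == row.ref

    def test_purifying_dfe_lowers_intragenic_share_below_null(self):
        # directional property: under purifying selection the realized
        # intragenic fraction of transmitted mutations drops below the
        # coding-site fraction of the genome
        from liquidma import annotate_mutations, count_site_classes, synthesize_genome
        genome, annotation = synthesize_genome(30_000, coding_fraction=0.7, seed=8)
        table = count_site_classes(genome, annotation)
        base = dict(genome=genome, annotation=annotation, mu_bps=2e-5,
                    mu_indel=0.0, lines=8, transfers=10)
        neutral = simulate_experiment(
            SimulationConfig(dfe=DFE.neutral(), seed=21, **base),
            growth_curves=False)
        purify = simulate_experiment(
            SimulationConfig(dfe=DFE(lethal_fraction=0.2,
                                     deleterious_mean_effect=0.15), seed=22, **base),
            growth_curves=False)

        def intragenic_fraction(result):
            recs = annotate_mutations(result.mutation_records(), genome, annotation)
            return np.mean([r.genic == "intragenic" for r in recs])

        null_fraction = table.coding_sites / table.genome_length
        assert intragenic_fraction(neutral) == pytest.approx(null_fraction, abs=0.05)
        assert intragenic_fraction(purify) < null_fraction


class TestGrowthCurveGeneration:
    def test_batches_contain_ancestor_replicates(self, rng):
        curves = simulate_growth_curves({"L01": 0.9, "L02": 0.95, "L03": 1.0},
                                        rng=rng)
        for batch, group in curves.groupby("batch"):
            assert "ANC" in set(group["sample_id"])

    def test_low_fitness_line_grows_slower(self, rng):
        from liquidma.growth import frame_to_curves, growth_metrics
        curves = frame_to_curves(simulate_growth_curves(
            {"SLOW": 0.5, "FAST": 1.0}, rng=rng, noise_sd=0.001))
        metrics = growth_metrics(curves)
        mean_slope = metrics.groupby("sample_id")["max_slope"].mean()
        assert mean_slope["SLOW"] < mean_slope["FAST"]


class TestHarmonicMeanPopsize:
    def test_full_day_of_doubling(self):
        # 27 doublings: harmonic mean census ~= 14, far above the bottleneck of 1
        assert round(harmonic_mean_popsize(27)) == 14

    def test_single_generation(self):
        assert harmonic_mean_popsize(1) == pytest.approx(2 / 1.5)

    def test_asymptotic_form(self):
        g = 40
        assert harmonic_mean_popsize(g) == pytest.approx((g + 1) / 2, rel=1e-6)

    def test_requires_at_least_one_generation(self):
        with pytest.raises(ValueError):
            harmonic_mean_popsize(0)
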