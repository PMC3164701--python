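"""Codon-order indices, working-point inference and related analyses."""

import itertools

import numpy as np
import pytest

from riboflow.analysis import (
    dpco,
    dtco,
    empirical_spearman_p,
    fit_loglog_abundance_regressor,
    fold_change,
    gene_working_point,
    global_working_point,
    jackknife_site_size,
    rfm_rate,
    translation_cost,
)
from riboflow.codon_rates import CodonTimeTable, Transcript, site_rates
from riboflow.io import generate_fixture_transcripts


@pytest.fixture
def table():
    return CodonTimeTable.from_times({"FFF": 1.0, "MMM": 2.0, "SSS": 4.0})


@pytest.fixture
def mixed_transcript():
    return Transcript("mix", ("FFF", "FFF", "SSS", "MMM", "SSS", "FFF"))


class TestDTCO:
    def test_homogeneous_transcript_has_zero_order_dependence(self, table):
        tr = Transcript("g", ("MMM",) * 8)
        rep = dtco(tr, table, C=2, lam=0.5, seed=1)
        assert rep.dtco == pytest.approx(0.0, abs=1e-9)

    def test_sampled_matches_full_enumeration(self, table, mixed_transcript):
        """Shuffle-sampled spread vs. exhaustive enumeration of all orders."""
        C, lam = 2, 0.5
        cache = {}
        rates = []
        for perm in itertools.permutations(mixed_transcript.codons):
            if perm not in cache:
                cache[perm] = rfm_rate(Transcript("p", perm), table, C, lam)
            rates.append(cache[perm])
        r0 = rfm_rate(mixed_transcript, table, C, lam)
        exact = 100.0 * np.std(rates, ddof=0) / r0
        rep = dtco(mixed_transcript, table, C, lam, n_perm=300, seed=2)
        assert rep.dtco == pytest.approx(exact, rel=0.2)

    def test_reproducible_with_fixed_seed(self, table, mixed_transcript):
        a = dtco(mixed_transcript, table, 2, 0.5, seed=9)
        b = dtco(mixed_transcript, table, 2, 0.5, seed=9)
        assert a.dtco == b.dtco
        assert np.array_equal(a.permuted_rates, b.permuted_rates)

    def test_saturated_lambda_is_still_finite(self, table, mixed_transcript):
        rep = dtco(mixed_transcript, table, 2, 50.0, seed=3)
        assert np.isfinite(rep.dtco) and rep.dtco >= 0

    def test_permutations_preserve_codon_content(self, table, mixed_transcript):
        """Order shuffles leave any content-only index untouched."""
        from riboflow.predictors import gene_tai

        rng = np.random.default_rng(0)
        codons = list(mixed_transcript.codons)
        base = gene_tai(mixed_transcript, table)
        for _ in range(5):
            rng.shuffle(codons)
            assert gene_tai(Transcript("p", tuple(codons)), table) == pytest.approx(base)


class TestLogLogRegressor:
    def test_exact_power_law(self):
        rates = np.array([0.5, 1.0, 2.0, 4.0])
        slope, intercept = fit_loglog_abundance_regressor(rates, rates**2)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_abundance_flat_line(self):
        slope, _ = fit_loglog_abundance_regressor([1, 2, 3, 4], [5, 5, 5, 5])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_recovery_under_lognormal_noise(self):
        rng = np.random.default_rng(8)
        rates = np.exp(rng.uniform(-2, 1, size=200))
        ab = np.exp(1.5 * np.log(rates) + 0.7 + rng.normal(0, 0.1, size=200))
        slope, intercept = fit_loglog_abundance_regressor(rates, ab)
        assert slope == pytest.approx(1.5, rel=0.05)
        assert intercept == pytest.approx(0.7, abs=0.05)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_loglog_abundance_regressor([1, 2, -1], [1, 2, 3])


class TestDPCO:
    def test_identity_regressor_reduces_to_rate_ratio(self, table, mixed_transcript):
        rep = dtco(mixed_transcript, table, 2, 0.5, seed=4)
        val = dpco(mixed_transcript, (1.0, 0.0), table, 2, 0.5, seed=4)
        assert val == pytest.approx(rep.dtco, rel=1e-9)

    def test_homogeneous_transcript_zero(self, table):
        tr = Transcript("g", ("SSS",) * 6)
        assert dpco(tr, (1.3, 0.2), table, 2, 0.5, seed=1) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_steeper_regressor_amplifies_spread(self, table, mixed_transcript):
        v1 = dpco(mixed_transcript, (1.0, 0.0), table, 2, 0.5, seed=5)
        v2 = dpco(mixed_transcript, (2.0, 0.0), table, 2, 0.5, seed=5)
        assert v2 > v1


class TestWorkingPoint:
    def test_single_site_closed_form(self):
        # R = lam/(lam+1), capacity 1: Q=93 -> lam = 0.93/0.07
        lam = gene_working_point(np.array([1.0]), 93.0)
        assert lam == pytest.approx(0.93 / 0.07, rel=1e-4)

    def test_half_capacity_single_site(self):
        assert gene_working_point(np.array([1.0]), 50.0) == pytest.approx(1.0, rel=1e-4)

    def test_monotone_in_q(self):
        rates = np.array([0.8, 1.2, 0.6])
        lams = [gene_working_point(rates, q) for q in (30, 60, 90)]
        assert lams[0] < lams[1] < lams[2]

    def test_unreachable_q_rejected(self):
        with pytest.raises(ValueError):
            gene_working_point(np.array([1.0]), 100.0)

    def test_solve_at_working_point_recovers_q(self):
        from riboflow.rfm_core import (
            RFMInstance,
            elongation_capacity,
            solve_steady_state_algebraic,
        )

        rates = np.array([1.5, 0.7, 1.1, 0.9])
        q = 80.0
        lam = gene_working_point(rates, q)
        cap, _ = elongation_capacity(rates)
        R = solve_steady_state_algebraic(RFMInstance(lam, rates)).rate
        assert R / cap == pytest.approx(q / 100.0, rel=1e-3)

    def test_global_working_point_recovers_planted_lambda(self):
        transcripts, _, table = generate_fixture_transcripts(
            30, 100, 20, (1.0, 10.0), seed=5
        )
        gene_rates = [site_rates(tr, 10, table) for tr in transcripts]
        lam_true = float(np.median([gene_working_point(r, 60.0) for r in gene_rates]))
        from riboflow.rfm_core import RFMInstance, solve_steady_state_algebraic

        rng = np.random.default_rng(6)
        R_true = np.array(
            [solve_steady_state_algebraic(RFMInstance(lam_true, r)).rate for r in gene_rates]
        )
        abundance = np.exp(2.0 * np.log(R_true) + rng.normal(0, 0.02, size=len(R_true)))
        grid = np.geomspace(lam_true / 30, lam_true * 30, 9)
        wp = global_working_point(gene_rates, abundance, grid)
        i_star = int(np.argmin(np.abs(np.log(wp.lam_grid) - np.log(wp.lam_star))))
        i_true = int(np.argmin(np.abs(np.log(grid) - np.log(lam_true))))
        assert abs(i_star - i_true) <= 1
        assert 0 < wp.q_percent <= 100.0

    def test_single_grid_point(self):
        transcripts, _, table = generate_fixture_transcripts(
            10, 40, 10, (1.0, 5.0), seed=2
        )
        gene_rates = [site_rates(tr, 10, table) for tr in transcripts]
        rng = np.random.default_rng(1)
        wp = global_working_point(gene_rates, rng.uniform(1, 2, 10), np.array([0.05]))
        assert wp.lam_star == 0.05

    def test_constant_abundance_rejected(self):
        transcripts, _, table = generate_fixture_transcripts(
            10, 40, 10, (1.0, 5.0), seed=2
        )
        gene_rates = [site_rates(tr, 10, table) for tr in transcripts]
        with pytest.raises(ValueError):
            global_working_point(gene_rates, np.ones(10), np.array([0.05]))


class TestTranslationCost:
    @pytest.mark.parametrize(
        "rate,density,expected",
        [(0.000162, 0.42, 0.000386), (0.000125, 0.36, 0.000347)],
    )
    def test_proteins_per_time_per_ribosome(self, rate, density, expected):
        assert translation_cost(rate, density) == pytest.approx(expected, rel=5e-3)

    def test_equal_rate_and_density(self):
        assert translation_cost(0.3, 0.3) == pytest.approx(1.0)

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            translation_cost(0.1, 0.0)


class TestFoldChange:
    def test_identity_variant(self, table, mixed_transcript):
        fc = fold_change(mixed_transcript, mixed_transcript, table, C=2)
        assert fc == pytest.approx(1.0)

    def test_initiation_limited_regime_insensitive_to_speed(self, table):
        native = Transcript("n", ("SSS",) * 12)
        variant = Transcript("v", ("MMM",) * 12)  # all dwell times halved
        grid = np.linspace(1e-4, 1e-3, 11)  # lambda far below site rates
        fc = fold_change(native, variant, table, C=3, lam_grid=grid)
        assert fc == pytest.approx(1.0, rel=0.01)

    def test_saturated_regime_tracks_capacity_ratio(self, table):
        native = Transcript("n", ("SSS",) * 12)
        variant = Transcript("v", ("MMM",) * 12)
        grid = np.linspace(50.0, 100.0, 5)  # deep saturation
        fc = fold_change(native, variant, table, C=3, lam_grid=grid)
        assert fc == pytest.approx(2.0, rel=0.02)


class TestEmpiricalSpearman:
    def test_perfect_correlation_has_zero_p(self):
        x = np.arange(10.0)
        rho, p = empirical_spearman_p(x, x, n_perm=100, seed=0)
        assert rho == pytest.approx(1.0)
        assert p == 0.0

    def test_null_p_is_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for k in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            ps.append(empirical_spearman_p(x, y, n_perm=60, seed=k)[1])
        assert 0.2 < np.median(ps) < 0.8

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            empirical_spearman_p([1, 2, 3], [1, 2, 3], n_perm=0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            empirical_spearman_p([1, 2, 3], [1, 2])


class TestJackknife:
    def test_single_candidate_always_selected(self, table):
        transcripts, _, tab = generate_fixture_transcripts(12, 40, 10, (1, 5), seed=3)
        rng = np.random.default_rng(0)
        counts = jackknife_site_size(
            transcripts, rng.uniform(1, 2, 12), tab, [10], lam=0.05, reps=17, seed=1
        )
        assert counts == {10: 17}

    def test_counts_sum_to_reps(self):
        transcripts, _, tab = generate_fixture_transcripts(15, 60, 15, (1, 8), seed=4)
        rng = np.random.default_rng(1)
        counts = jackknife_site_size(
            transcripts, rng.uniform(1, 2, 15), tab, [5, 10, 20], lam=0.05,
            reps=25, seed=2,
        )
        assert sum(counts.values()) == 25

    def test_constant_abundance_rejected(self):
        transcripts, _, tab = generate_fixture_transcripts(10, 40, 10, (1, 5), seed=5)
        with pytest.raises(ValueError):
            jackknife_site_size(
                transcripts, np.ones(10), tab, [5, 10], lam=0.05, reps=5, seed=0
            )
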