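import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.constants import Avogadro

from beadpoisson import (
    BeadDose,
    OccupancyHistogram,
    expected_mu,
    fit_occupancy_fractions,
    fit_truncated_poisson,
    ligand_density,
    poisson_pmf,
    sse,
    truncated_occupancy,
)


class TestPoissonPmf:
    def test_single_bead_probability_at_unit_rate(self):
        # the 37% single-occupancy ceiling of random encapsulation
        assert poisson_pmf(1, 1.0) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_zero_rate_is_point_mass_at_zero(self):
        assert poisson_pmf(0, 0.0) == 1.0
        assert poisson_pmf(3, 0.0) == 0.0

    def test_matches_factorial_free_recurrence(self):
        # f(k) = f(k-1) * mu / k, seeded at f(0) = exp(-mu)
        mu = 0.41
        f = math.exp(-mu)
        for k in range(1, 12):
            f *= mu / k
            assert poisson_pmf(k, mu) == pytest.approx(f, rel=1e-12)
        assert poisson_pmf(2, mu) == pytest.approx(0.0557798, abs=1e-6)

    @pytest.mark.parametrize("mu", [0.1, 0.41, 1.0, 5.0, 20.0])
    def test_normalisation(self, mu):
        k = np.arange(0, 201)
        assert abs(poisson_pmf(k, mu).sum() - 1.0) < 1e-12

    def test_single_bead_probability_maximised_at_mu_one(self):
        grid = np.linspace(0.01, 5, 2000)
        vals = [poisson_pmf(1, m) for m in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(1.0, abs=5e-3)
        assert max(vals) <= math.exp(-1) + 1e-12

    @pytest.mark.parametrize("k,mu", [(-1, 1.0), (1.5, 1.0), (1, -0.1)])
    def test_domain_errors(self, k, mu):
        with pytest.raises(ValueError):
            poisson_pmf(k, mu)


class TestTruncatedOccupancy:
    def test_values_at_the_abil_fitted_rate(self):
        # conditioning on bead-bearing droplets at mu = 0.41
        assert truncated_occupancy(1, 0.41) == pytest.approx(0.8089692, abs=1e-6)
        assert truncated_occupancy(2, 0.41) == pytest.approx(0.1658387, abs=1e-6)

    def test_normalisation_over_k(self):
        k = np.arange(1, 51)
        assert abs(truncated_occupancy(k, 0.41).sum() - 1.0) < 1e-12

    def test_single_bead_fraction_strictly_decreasing_in_mu(self):
        mus = np.linspace(0.01, 10, 500)
        vals = [truncated_occupancy(1, m) for m in mus]
        assert np.all(np.diff(vals) < 0)

    def test_undefined_at_zero_rate(self):
        with pytest.raises(ValueError):
            truncated_occupancy(1, 0.0)
        with pytest.raises(ValueError):
            truncated_occupancy(0, 0.41)


class TestSse:
    def test_identical_vectors(self):
        assert sse([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_hand_arithmetic(self):
        assert sse([0.8, 0.2], [0.7, 0.3]) == pytest.approx(0.02, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sse([0.5], [0.25, 0.25])

    def test_fit_result_sse_recomputable(self):
        fit = fit_truncated_poisson(OccupancyHistogram({1: 81, 2: 17, 3: 2}))
        assert fit.sse == pytest.approx(sse(fit.observed, fit.model_fractions()), abs=1e-12)


class TestOccupancyHistogram:
    def test_truncated_rejects_zero_entry(self):
        with pytest.raises(ValueError):
            OccupancyHistogram({0: 5, 1: 10})

    def test_from_bead_counts_drops_empties_when_truncated(self):
        h = OccupancyHistogram.from_bead_counts([0, 0, 1, 1, 2])
        assert h.counts == {1: 2, 2: 1}
        assert h.n_total == 3

    def test_fractions_cover_contiguous_support(self):
        h = OccupancyHistogram({1: 8, 3: 2})
        assert list(h.support()) == [1, 2, 3]
        assert h.fractions() == pytest.approx([0.8, 0.0, 0.2])


class TestFit:
    def test_self_consistency_on_exact_model(self):
        support = np.arange(1, 51)
        fractions = truncated_occupancy(support, 0.5)
        fit = fit_occupancy_fractions(support, fractions)
        assert fit.mu == pytest.approx(0.5, abs=1e-6)
        assert fit.sse <= 1e-12

    def test_matches_grid_search_oracle(self):
        hist = OccupancyHistogram({1: 81, 2: 17, 3: 2})
        fit = fit_truncated_poisson(hist)
        grid = np.arange(0.001, 3, 1e-4)
        obs, sup = hist.fractions(), hist.support()
        sses = [sse(obs, truncated_occupancy(sup, m)) for m in grid]
        assert fit.mu == pytest.approx(grid[int(np.argmin(sses))], abs=1e-4)
        assert 0.35 < fit.mu < 0.47  # the ~0.41 region

    def test_all_mass_at_one_bead_pins_rate_at_lower_bound(self):
        with pytest.warns(RuntimeWarning):
            fit = fit_occupancy_fractions([1], [1.0])
        assert fit.at_lower_bound

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(scale=st.floats(0.01, 1000.0))
    def test_invariant_to_rescaling_counts(self, scale):
        base = fit_truncated_poisson(OccupancyHistogram({1: 81, 2: 17, 3: 2}))
        scaled = fit_truncated_poisson(
            OccupancyHistogram({1: 81 * scale, 2: 17 * scale, 3: 2 * scale})
        )
        assert scaled.mu == pytest.approx(base.mu, rel=1e-9)

    @pytest.mark.parametrize("mu_true", [0.1, 0.41, 0.45, 1.0])
    def test_parameter_recovery_from_exact_model_draws(self, mu_true):
        # draw >=1e4 droplets from the exact truncated model, refit
        rng = np.random.default_rng(int(mu_true * 1000))
        support = np.arange(1, 31)
        probs = truncated_occupancy(support, mu_true)
        counts = rng.multinomial(20_000, probs / probs.sum())
        hist = OccupancyHistogram({int(k): int(n) for k, n in zip(support, counts) if n > 0})
        fit = fit_truncated_poisson(hist)
        assert abs(fit.mu - mu_true) < 0.02

    def test_mle_option_agrees_with_sse_on_exact_data(self):
        support = np.arange(1, 41)
        counts = np.round(truncated_occupancy(support, 0.8) * 1e7)
        hist = OccupancyHistogram(
            {int(k): float(n) for k, n in zip(support, counts) if n > 0}
        )
        assert fit_truncated_poisson(hist, method="mle").mu == pytest.approx(0.8, abs=1e-3)


class TestExpectedMu:
    def test_abil_condition(self):
        assert expected_mu(BeadDose(1e7, 100.0), 3.6) == pytest.approx(0.36, rel=1e-12)

    def test_fluosurf_condition(self):
        mu = expected_mu(BeadDose(1e7, 200.0), 8.9)
        assert mu == pytest.approx(0.445, rel=1e-12)
        assert round(mu, 2) == 0.45

    def test_vanishing_droplet_limit(self):
        assert expected_mu(BeadDose(1e7, 100.0), 0.0) == 0.0

    def test_invalid_dose_rejected(self):
        with pytest.raises(ValueError):
            BeadDose(0, 100.0)
        with pytest.raises(ValueError):
            BeadDose(1e7, -1.0)


class TestLigandDensity:
    def test_peptide_coupling_arithmetic(self):
        # 9.2 ul x 9 uM over 5e7 beads ~ 1e6 molecules per bead
        d = ligand_density(9.2, 9.0, 5e7)
        assert d == pytest.approx(9.97e5, rel=1e-3)

    def test_zero_concentration(self):
        assert ligand_density(1.0, 0.0, 1e6) == 0.0

    def test_avogadro_identity(self):
        # 1 ul x 1 uM = 1e-12 mol = N_A * 1e-12 molecules
        assert ligand_density(1.0, 1.0, Avogadro * 1e-12) == pytest.approx(1.0, rel=1e-12)

    def test_zero_beads_rejected(self):
        with pytest.raises(ValueError):
            ligand_density(1.0, 1.0, 0)
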