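import math

import numpy as np
import pytest

from beadpoisson import (
    BeadDose,
    VolumeBinnedMixture,
    VolumeBinning,
    bin_droplet_volumes,
    build_mixture,
    load_beads,
    mixture_occupancy,
    poisson_pmf,
    truncated_mixture_occupancy,
    truncated_occupancy,
)


class TestBinning:
    def test_hand_binning(self):
        b = bin_droplet_volumes([1.0, 1.0, 3.0], 2.0)
        assert b.bin_counts.tolist() == [2, 1]
        assert b.representative_volume_pl.tolist() == [1.0, 3.0]
        assert b.bin_edges.tolist() == [0.0, 2.0, 4.0]

    def test_half_open_convention_on_edges(self):
        b = bin_droplet_volumes([2.0], 2.0)
        assert b.bin_edges.tolist() == [2.0, 4.0]
        assert b.bin_counts.tolist() == [1]

    def test_counts_conserved_on_lognormal_sample(self):
        rng = np.random.default_rng(1)
        v = rng.lognormal(math.log(3.6), 0.8, 10_000)
        b = bin_droplet_volumes(v, 2.0)
        assert b.n_binned == 10_000

    def test_interior_empty_bins_kept(self):
        b = bin_droplet_volumes([1.0, 9.0], 2.0)
        assert b.bin_counts.tolist() == [1, 0, 0, 0, 1]

    def test_within_bin_mean_representative(self):
        b = bin_droplet_volumes([0.5, 1.5, 3.0], 2.0, representative="mean")
        assert b.representative_volume_pl[0] == pytest.approx(1.0)
        assert b.representative_volume_pl[1] == pytest.approx(3.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bin_droplet_volumes([], 2.0)


class TestBuildMixture:
    def test_single_bin_degenerates_to_one_poisson(self):
        b = bin_droplet_volumes([3.0, 3.5], 2.0)
        mix = build_mixture(b, BeadDose(1e7, 100.0))
        assert mix.weights.tolist() == [1.0]

    def test_volume_share_arithmetic_two_bins(self):
        b = VolumeBinning(
            bin_edges=np.array([0.0, 2.0, 4.0]),
            bin_counts=np.array([100, 100]),
            representative_volume_pl=np.array([1.0, 3.0]),
        )
        mix = build_mixture(b, BeadDose(1e7, 100.0))
        assert mix.weights == pytest.approx([0.25, 0.75])

    def test_count_weighting_alternative(self):
        b = VolumeBinning(
            bin_edges=np.array([0.0, 2.0, 4.0]),
            bin_counts=np.array([100, 100]),
            representative_volume_pl=np.array([1.0, 3.0]),
        )
        mix = build_mixture(b, BeadDose(1e7, 100.0), weighting="droplet_count")
        assert mix.weights == pytest.approx([0.5, 0.5])

    def test_rates_proportional_to_representative_volume(self):
        rng = np.random.default_rng(2)
        b = bin_droplet_volumes(rng.lognormal(1.0, 0.6, 5000), 2.0)
        dose = BeadDose(1e7, 100.0)
        mix = build_mixture(b, dose)
        ratios = mix.rates / b.representative_volume_pl
        assert ratios == pytest.approx(np.full_like(ratios, dose.concentration_per_pl))


class TestMixtureOccupancy:
    def test_one_component_reduces_to_poisson(self):
        mix = VolumeBinnedMixture(weights=np.array([1.0]), rates=np.array([0.41]))
        assert mixture_occupancy(mix, 1) == pytest.approx(poisson_pmf(1, 0.41), rel=1e-12)

    def test_two_component_hand_evaluation(self):
        mix = VolumeBinnedMixture(weights=np.array([0.5, 0.5]), rates=np.array([0.2, 0.8]))
        expect = 0.5 * math.exp(-0.2) + 0.5 * math.exp(-0.8)
        assert mixture_occupancy(mix, 0) == pytest.approx(expect, rel=1e-9)
        assert mixture_occupancy(mix, 0) == pytest.approx(0.634030, abs=1e-5)

    def test_normalisation_for_random_mixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            w = rng.dirichlet(np.ones(6))
            mix = VolumeBinnedMixture(weights=w, rates=rng.uniform(0.05, 4.0, 6))
            assert abs(mixture_occupancy(mix, np.arange(0, 101)).sum() - 1.0) < 1e-12

    def test_mean_bead_count_identity(self):
        # law of total expectation: sum_k k M(k) = sum_i w_i mu_i
        rng = np.random.default_rng(4)
        w = rng.dirichlet(np.ones(5))
        mix = VolumeBinnedMixture(weights=w, rates=rng.uniform(0.1, 3.0, 5))
        k = np.arange(0, 200)
        assert np.sum(k * mixture_occupancy(mix, k)) == pytest.approx(mix.mean_rate, abs=1e-10)


class TestTruncatedMixture:
    def test_one_component_matches_truncated_occupancy(self):
        mix = VolumeBinnedMixture(weights=np.array([1.0]), rates=np.array([0.41]))
        k = np.arange(1, 10)
        assert truncated_mixture_occupancy(mix, k) == pytest.approx(
            truncated_occupancy(k, 0.41), rel=1e-12
        )

    def test_all_zero_rates_rejected(self):
        mix = VolumeBinnedMixture(weights=np.array([1.0]), rates=np.array([0.0]))
        with pytest.raises(ValueError):
            truncated_mixture_occupancy(mix, 1)

    def test_polydisperse_mixture_is_overdispersed(self):
        # large droplets raise P(k>=2 | k>=1) above a mean-matched single Poisson
        mix = VolumeBinnedMixture(weights=np.array([0.5, 0.5]), rates=np.array([0.2, 0.8]))
        mu = mix.mean_rate
        p_multi_mix = 1.0 - truncated_mixture_occupancy(mix, 1)
        p_multi_single = 1.0 - truncated_occupancy(1, mu)
        assert p_multi_mix > p_multi_single

    def test_monte_carlo_agreement_with_simulated_loading(self):
        # 1e5 droplets drawn from the binned volume distribution, beads placed
        # volume-proportionally; per-droplet occupancy must match the
        # count-weighted mixture, volume-weighted occupancy the default
        # (aqueous-volume-share) mixture, each within 3 SE per k
        rng = np.random.default_rng(7)
        raw = rng.lognormal(math.log(3.6) - 0.32, 0.8, 100_000)
        binning = bin_droplet_volumes(raw, 2.0)
        vols = np.repeat(binning.representative_volume_pl, binning.bin_counts)
        n_beads = int(round(0.1 * vols.sum()))
        dose = BeadDose(n_beads, vols.sum() / 1e6)
        counts = load_beads(vols, np.ones(n_beads, int), rng)
        bc = counts[counts >= 1]
        sup = np.arange(1, bc.max() + 1)

        emp = np.bincount(bc, minlength=bc.max() + 1)[1:] / bc.size
        model = truncated_mixture_occupancy(build_mixture(binning, dose, "droplet_count"), sup)
        se = np.sqrt(model * (1 - model) / bc.size)
        mask = model * bc.size >= 5
        assert np.all(np.abs(emp - model)[mask] <= 3 * se[mask])

        vbc = vols[counts >= 1]
        wemp = np.array([vbc[bc == k].sum() for k in sup]) / vbc.sum()
        wmodel = truncated_mixture_occupancy(build_mixture(binning, dose), sup)
        n_eff = vbc.sum() ** 2 / np.sum(vbc**2)
        wse = np.sqrt(wmodel * (1 - wmodel) / n_eff)
        wmask = wmodel * n_eff >= 5
        assert np.all(np.abs(wemp - wmodel)[wmask] <= 3 * wse[wmask])

    def test_consistent_under_bin_refinement(self):
        # halving the bin width on a smooth volume distribution barely moves
        # the truncated occupancy (below the companion MC noise floor)
        rng = np.random.default_rng(8)
        v = rng.lognormal(math.log(3.6) - 0.32, 0.8, 50_000)
        dose = BeadDose(int(0.1 * v.sum()), v.sum() / 1e6)
        k = np.arange(1, 8)
        coarse = truncated_mixture_occupancy(build_mixture(bin_droplet_volumes(v, 2.0), dose), k)
        fine = truncated_mixture_occupancy(build_mixture(bin_droplet_volumes(v, 0.5), dose), k)
        assert np.max(np.abs(coarse - fine)) < 0.005
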