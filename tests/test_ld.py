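"""r^2, decay curves, four-gamete detection, rho fit, Marey map."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chlamypop import ld
from chlamypop.simulate import simulate_panel

from conftest import make_matrix, neutral_config


def _r2_from_haplotype_table(a, b):
    """Independent oracle: haplotype counts -> D^2 / (pA qA pB qB)."""
    n = len(a)
    pAB = sum(1 for x, y in zip(a, b) if x == 1 and y == 1) / n
    pA = sum(a) / n
    pB = sum(b) / n
    D = pAB - pA * pB
    return D * D / (pA * (1 - pA) * pB * (1 - pB))


class TestRSquared:
    def test_two_gametes_perfect_ld(self):
        assert ld.r_squared([1, 1, 0, 0], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_four_equal_gametes_no_ld(self):
        assert ld.r_squared([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_three_gamete_example(self):
        # gametes AB, AB, Ab, aB: D = 1/2 - 3/4*3/4 = -1/16; r^2 = 1/9
        assert ld.r_squared([1, 1, 1, 0], [1, 1, 0, 1]) == pytest.approx(1 / 9)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ld.r_squared([1, 1, 1], [0, 1, 0])

    def test_missing_calls_dropped_pairwise(self):
        value = ld.r_squared([1, 1, 0, 0, -1], [1, 1, 0, 0, 1])
        assert value == pytest.approx(1.0)

    def test_exhaustive_haplotype_oracle_up_to_six_strains(self):
        """Every polymorphic pair of call vectors for n = 2..6."""
        checked = 0
        for n in range(2, 7):
            for a in itertools.product((0, 1), repeat=n):
                if len(set(a)) < 2:
                    continue
                for b in itertools.product((0, 1), repeat=n):
                    if len(set(b)) < 2:
                        continue
                    expected = _r2_from_haplotype_table(a, b)
                    assert ld.r_squared(np.array(a), np.array(b)) == \
                        pytest.approx(expected)
                    checked += 1
        assert checked > 3000


class TestLdDecay:
    def test_single_pair_single_bin(self):
        calls = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=np.int8)
        matrix = make_matrix(calls, positions=[1000, 11_000])
        curve = ld.ld_decay(matrix, bin_width=25_000)
        populated = curve[curve["n_pairs"] > 0]
        assert len(populated) == 1
        assert populated["mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_doubling_bin_width_preserves_pair_total(self, two_group_panel):
        matrix = two_group_panel.matrix
        narrow = ld.ld_decay(matrix, bin_width=5_000)
        wide = ld.ld_decay(matrix, bin_width=10_000)
        assert narrow["n_pairs"].sum() == wide["n_pairs"].sum()

    def test_decay_with_recombination(self):
        panel = simulate_panel(neutral_config([150_000], rho=5e-4, seed=23))
        curve = ld.ld_decay(panel.matrix, bin_width=25_000)
        populated = curve[curve["n_pairs"] > 10]
        assert populated["mean_r2"].iloc[0] > populated["mean_r2"].iloc[-1]

    def test_per_chromosome_scope(self, two_group_panel):
        curves = ld.ld_decay(two_group_panel.matrix, bin_width=25_000,
                             scope="chromosome")
        assert set(curves["scope"]) == set(
            two_group_panel.matrix.chromosome_order())


class TestFourGametes:
    def test_pair_with_all_four_gametes_counted(self):
        calls = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        assert ld.four_gamete_pairs(make_matrix(calls))["total"] == 1

    def test_three_gamete_pair_not_counted(self):
        calls = np.array([[0, 0], [0, 1], [1, 1], [1, 1]], dtype=np.int8)
        assert ld.four_gamete_pairs(make_matrix(calls))["total"] == 0

    def test_inter_chromosomal_pairs_ignored(self):
        calls = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        matrix = make_matrix(calls, positions=[5, 5],
                             chromosomes=["chr01", "chr02"])
        assert ld.four_gamete_pairs(matrix)["total"] == 0

    def test_matches_pairwise_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        calls = rng.integers(0, 2, size=(8, 40)).astype(np.int8)
        matrix = make_matrix(calls)
        expected = 0
        for i in range(40):
            for j in range(i + 1, 40):
                gametes = {(int(a), int(b))
                           for a, b in zip(calls[:, i], calls[:, j])}
                expected += len(gametes) == 4
        assert ld.four_gamete_pairs(matrix)["total"] == expected


class TestRhoEstimation:
    def test_no_recombination_estimates_near_boundary(self):
        panel = simulate_panel(neutral_config([100_000], rho=0.0, seed=2))
        estimate = ld.estimate_rho(panel.matrix, "chr01")
        assert estimate.rho_per_base < 1e-5

    def test_flat_curve_model_limit(self):
        # constant r^2 with no decay: the model limit is rho -> 0
        calls = np.tile(np.array([[0], [0], [1], [1]], dtype=np.int8), 20)
        matrix = make_matrix(calls, positions=np.arange(20) * 3_000 + 1)
        estimate = ld.estimate_rho(matrix, "chr01", bin_width=5_000)
        assert estimate.rho_per_base == 0.0

    def test_too_few_bins_rejected(self):
        calls = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        matrix = make_matrix(calls, positions=[10, 20])
        with pytest.raises(ValueError, match="bins"):
            ld.estimate_rho(matrix, "chr01", bin_width=1_000)

    def test_genome_rho_averages_chromosomes(self):
        panel = simulate_panel(neutral_config([80_000] * 2, rho=3e-4,
                                              seed=29))
        rho, estimates = ld.genome_rho(panel.matrix)
        assert rho == pytest.approx(
            np.mean([e.rho_per_base for e in estimates]))
        assert len(estimates) == 2


class TestOutcrossing:
    def test_zero_rho_zero_generations(self):
        assert ld.outcrossing_generations(0.0, 1e-7).generations == 0.0

    def test_unit_case(self):
        assert ld.outcrossing_generations(2e-7, 1e-7).generations == \
            pytest.approx(1.0)

    def test_linear_in_rho_inverse_in_r(self):
        base = ld.outcrossing_generations(2e-4, 1e-7).generations
        assert ld.outcrossing_generations(4e-4, 1e-7).generations == \
            pytest.approx(2 * base)
        assert ld.outcrossing_generations(2e-4, 2e-7).generations == \
            pytest.approx(base / 2)

    def test_nonpositive_map_rate_rejected(self):
        with pytest.raises(ValueError):
            ld.outcrossing_generations(1e-4, 0.0)


class TestMareyFit:
    def _logistic(self, x, lower, upper, midpoint, slope):
        return lower + (upper - lower) / (1 + np.exp(-slope * (x - midpoint)))

    def test_noiseless_logistic_recovered(self):
        x = np.linspace(0, 4e6, 25)
        truth = dict(lower=2.0, upper=95.0, midpoint=1.8e6, slope=2.4e-6)
        markers = pd.DataFrame({"bp": x, "cM": self._logistic(x, **truth)})
        fit = ld.marey_fit(markers, chromosome="chr01")
        assert fit.lower == pytest.approx(truth["lower"], rel=1e-4)
        assert fit.upper == pytest.approx(truth["upper"], rel=1e-4)
        assert fit.midpoint == pytest.approx(truth["midpoint"], rel=1e-4)
        assert fit.slope == pytest.approx(truth["slope"], rel=1e-4)

    def test_derivative_at_midpoint(self):
        x = np.linspace(0, 4e6, 25)
        markers = pd.DataFrame({
            "bp": x, "cM": self._logistic(x, 0.0, 80.0, 2e6, 2e-6)})
        fit = ld.marey_fit(markers)
        # (upper - lower) * slope / 4 per base, reported per kb
        expected = 80.0 * 2e-6 / 4 * 1_000
        assert fit.local_rate_cm_per_kb(fit.midpoint) == pytest.approx(
            expected, rel=1e-3)

    def test_linear_region_fit_stays_in_range(self):
        rng = np.random.default_rng(6)
        x = np.linspace(1e5, 9e5, 12)
        cm = 10 + 3e-5 * x + rng.normal(0, 0.3, size=x.size)
        fit = ld.marey_fit(pd.DataFrame({"bp": x, "cM": cm}))
        predicted = fit.predict(x)
        assert predicted.min() >= cm.min() - 2
        assert predicted.max() <= cm.max() + 2
        assert (np.diff(fit.predict(np.linspace(0, 1e6, 200))) >= 0).all()

    def test_too_few_markers_rejected(self):
        markers = pd.DataFrame({"bp": [1, 2, 3, 4], "cM": [0, 1, 2, 3]})
        with pytest.raises(ValueError, match="five markers"):
            ld.marey_fit(markers)


class TestLdMatrix:
    def test_grid_symmetric_with_unit_diagonal(self, two_group_panel):
        pos, grid = ld.ld_matrix(two_group_panel.matrix, "chr01")
        assert np.allclose(grid, grid.T)
        assert np.allclose(np.diag(grid), 1.0)
        assert pos.size == grid.shape[0]

    def test_planted_high_ld_block_detected(self):
        rng = np.random.default_rng(41)
        calls = rng.integers(0, 2, size=(8, 30)).astype(np.int8)
        haplotype = rng.integers(0, 2, size=8).astype(np.int8)
        calls[:, 10:18] = haplotype[:, None]  # eight perfectly linked sites
        matrix = make_matrix(calls, positions=np.arange(30) * 500 + 1)
        _, _, blocks = ld.ld_matrix(matrix, "chr01", block_threshold=0.95)
        spans = [(s, e) for s, e in blocks]
        assert any(s <= 10 * 500 + 1 and e >= 17 * 500 + 1 for s, e in spans)
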