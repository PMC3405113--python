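"""Diversity estimators against closed forms and brute-force oracles."""

import itertools

import numpy as np
import pytest

from chlamypop import diversity
from chlamypop.datatypes import MISSING
from chlamypop.simulate import simulate_panel

from conftest import make_matrix, neutral_config


class TestWatterson:
    def test_no_segregating_sites_gives_zero(self):
        assert diversity.watterson_theta(0, 12, 1000) == 0.0

    def test_pair_closed_form(self):
        assert diversity.watterson_theta(1, 2, 1) == 1.0  # a_2 = 1

    def test_four_sample_example(self):
        # a_4 = 1 + 1/2 + 1/3 = 1.8333...; 3/(a_4*100)
        assert diversity.watterson_theta(3, 4, 100) == pytest.approx(
            0.016364, abs=5e-7)

    def test_undefined_without_length(self):
        assert np.isnan(diversity.watterson_theta(3, 4, 0))

    def test_rejects_single_sequence(self):
        with pytest.raises(ValueError):
            diversity.watterson_theta(1, 1, 100)


class TestPiTheta:
    def test_identical_haplotypes(self):
        matrix = make_matrix(np.zeros((2, 5)))
        assert diversity.pi_theta(matrix, 100) == 0.0

    def test_single_pair_fraction(self):
        calls = np.zeros((2, 5), dtype=np.int8)
        calls[1, :] = 1  # differ at all 5 sites of 100 bases
        assert diversity.pi_theta(make_matrix(calls), 100) == 0.05

    def test_three_sample_enumeration(self):
        # calls (0,0,1): pairs differ (0,1,1) -> mean 2/3 over L=1
        matrix = make_matrix(np.array([[0], [0], [1]]))
        assert diversity.pi_theta(matrix, 1) == pytest.approx(2 / 3)

    def test_strict_mode_drops_sites_with_missing(self):
        calls = np.array([[0, 0], [1, MISSING], [1, 1]], dtype=np.int8)
        # only site 1 is complete: diffs (1, 1, 0) -> 2/3 over L=10
        assert diversity.pi_theta(make_matrix(calls), 10) == pytest.approx(
            2 / 3 / 10)

    def test_pairwise_mode_uses_per_pair_lengths(self):
        calls = np.array([[0, 0], [1, MISSING]], dtype=np.int8)
        # L=10 total, 2 SNP columns; the pair is co-called at 1 SNP
        # -> L_12 = 10 - 2 + 1 = 9, d_12 = 1
        value = diversity.pi_theta(make_matrix(calls), 10, mode="pairwise")
        assert value == pytest.approx(1 / 9)

    def test_oracle_brute_force_hamming(self):
        """theta_pi equals the mean pairwise Hamming distance per base."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = rng.integers(2, 8)
            s = rng.integers(1, 30)
            calls = rng.integers(0, 2, size=(n, s)).astype(np.int8)
            L = int(s + rng.integers(0, 50))
            expected = np.mean([
                (calls[i] != calls[j]).sum() / L
                for i, j in itertools.combinations(range(n), 2)])
            assert diversity.pi_theta(make_matrix(calls), L) == pytest.approx(
                expected)


@pytest.fixture(scope="module")
def panel():
    return simulate_panel(neutral_config([50_000, 50_000], rho=2e-4, seed=13))


class TestClassAndWindows:
    def test_class_S_partitions_total(self, two_group_panel):
        panel = two_group_panel
        table = diversity.class_diversity(panel.matrix, panel.annotation,
                                          panel.mask)
        classes = table[table["site_class"] != "all"]
        total = table[table["site_class"] == "all"].iloc[0]
        assert classes["S"].sum() == total["S"]
        assert classes["L"].sum() == total["L"]

    def test_whole_chromosome_window_equals_chromosome_estimate(self, panel):
        chrom = "chr01"
        idx = panel.matrix.sites_on(chrom)
        sub = panel.matrix.take_sites(idx)
        L = panel.mask.n_callable(chrom)
        est = diversity.diversity_estimate(sub, L)
        windows = diversity.windowed_diversity(panel.matrix, panel.mask,
                                               window_size=10**9)
        row = windows[windows["chromosome"] == chrom].iloc[0]
        assert row["S"] == est.S
        assert row["theta_w"] == pytest.approx(est.theta_w_per_base)
        assert row["theta_pi"] == pytest.approx(est.theta_pi_per_base)

    def test_length_weighted_window_mean_equals_global(self, panel):
        windows = diversity.windowed_diversity(panel.matrix, panel.mask,
                                               window_size=7_500)
        ok = windows["L"] > 0
        weighted = (windows.loc[ok, "theta_w"]
                    * windows.loc[ok, "L"]).sum() / windows.loc[ok, "L"].sum()
        est = diversity.diversity_estimate(panel.matrix,
                                           panel.mask.n_callable())
        assert weighted == pytest.approx(est.theta_w_per_base)

    def test_exclude_intergenic_drops_both_s_and_l(self, two_group_panel):
        panel = two_group_panel
        full = diversity.windowed_diversity(panel.matrix, panel.mask,
                                            window_size=25_000)
        genic = diversity.windowed_diversity(
            panel.matrix, panel.mask, window_size=25_000,
            exclude_intergenic=True, annotation=panel.annotation)
        assert (genic["S"] <= full["S"]).all()
        assert (genic["L"] < full["L"]).all()

    def test_moving_average_is_trailing_ten_windows(self, panel):
        windows = diversity.windowed_diversity(panel.matrix, panel.mask,
                                               window_size=2_000)
        chrom = windows[windows["chromosome"] == "chr01"]
        th = chrom["theta_w"].to_numpy()
        ma = chrom["theta_w_ma10"].to_numpy()
        assert ma[0] == pytest.approx(th[0])
        k = 14
        assert ma[k] == pytest.approx(np.mean(th[k - 9:k + 1]))


class TestChromosomeContrast:
    def test_hand_computed_example(self):
        windows = _windows_frame({"chrA": [1, 2, 3], "chrB": [4, 5, 6]})
        result = diversity.chromosome_contrast(windows, "chrA")
        assert result["F"] == pytest.approx(13.5)
        assert (result["df1"], result["df2"]) == (1, 4)

    def test_identical_groups_give_zero(self):
        windows = _windows_frame({"chrA": [2, 3, 4], "chrB": [3, 2, 4]})
        result = diversity.chromosome_contrast(windows, "chrA")
        assert result["F"] == pytest.approx(0.0)

    def test_zero_within_variance_flags_infinity(self):
        windows = _windows_frame({"chrA": [1, 1], "chrB": [2, 2]})
        assert diversity.chromosome_contrast(windows, "chrA")["F"] == np.inf

    def test_textbook_oracle_on_random_inputs(self):
        """F = MS_between / MS_within, written out longhand."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(size=rng.integers(2, 12))
            grand = np.concatenate([a, b]).mean()
            ssb = len(a) * (a.mean() - grand) ** 2 \
                + len(b) * (b.mean() - grand) ** 2
            ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            expected = (ssb / 1) / (ssw / (len(a) + len(b) - 2))
            windows = _windows_frame({"chrA": a, "chrB": b})
            result = diversity.chromosome_contrast(windows, "chrA")
            assert result["F"] == pytest.approx(expected)

    def test_needs_two_windows_per_group(self):
        windows = _windows_frame({"chrA": [1], "chrB": [2, 3]})
        with pytest.raises(ValueError):
            diversity.chromosome_contrast(windows, "chrA")


class TestSpearman:
    def test_perfectly_monotone(self):
        result = diversity.spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert result["rho"] == pytest.approx(1.0)

    def test_hand_computed_rank_example(self):
        # d = (ranks differences) gives sum d^2 = 6 -> 1 - 36/24 = -0.5
        result = diversity.spearman_correlation([1, 2, 3], [3, 1, 2])
        assert result["rho"] == pytest.approx(-0.5)

    def test_reversal_negates_rho(self):
        x = [3, 1, 4, 1, 5, 9, 2, 6]
        y = [2, 7, 1, 8, 2, 8, 1, 8]
        forward = diversity.spearman_correlation(x, y)["rho"]
        backward = diversity.spearman_correlation(x, [-v for v in y])["rho"]
        assert forward == pytest.approx(-backward)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            result = diversity.spearman_correlation([1, 1, 1], [1, 2, 3])
        assert np.isnan(result["rho"])


def _windows_frame(values_by_chrom):
    import pandas as pd
    rows = []
    for chrom, values in values_by_chrom.items():
        for k, v in enumerate(values):
            rows.append({"chromosome": chrom, "start": 1 + k, "end": 2 + k,
                         "theta_w": float(v)})
    return pd.DataFrame(rows)
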