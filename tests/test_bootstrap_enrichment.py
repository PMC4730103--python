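"""The enrichment statistic, its bootstrap null, and multiple-testing correction."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ewce
from ewce import EwceError
from conftest import enumeration_pvalues


class TestSummedSpecificity:
    def test_exclusive_marker_and_additivity(self, dyadic_spec):
        lone = pd.DataFrame(
            [[1.0, 0.0], [0.0, 1.0]], index=["ma", "mb"], columns=["A", "B"]
        )
        spec = ewce.SpecificityMatrix(values=lone, level="subtype")
        g = ewce.summed_specificity(["ma"], spec)
        assert g["A"] == 1.0 and g["B"] == 0.0
        g2 = ewce.summed_specificity(["ma", "mb"], spec)
        assert g2["A"] == 1.0 and g2["B"] == 1.0

    def test_matches_per_column_hand_sum(self, dyadic_spec):
        genes = ["g1", "g3", "g5", "g6", "g2"]
        gamma = ewce.summed_specificity(genes, dyadic_spec)
        for col in dyadic_spec.groups:
            hand = sum(dyadic_spec.values.at[g, col] for g in genes)
            assert gamma[col] == pytest.approx(hand, abs=1e-12)

    def test_unknown_gene_named_in_error(self, dyadic_spec):
        with pytest.raises(EwceError, match="nope"):
            ewce.summed_specificity(["g1", "nope"], dyadic_spec)


class TestUncontrolledSampling:
    def test_full_background_draw_is_forced(self, dyadic_spec):
        bg = ewce.BackgroundSet(genes=list(dyadic_spec.genes))
        null = ewce.sample_random_lists(bg, dyadic_spec, n=6, reps=50, seed=0)
        total = dyadic_spec.values.sum(axis=0).to_numpy()
        np.testing.assert_allclose(null.values, np.tile(total, (50, 1)))

    def test_single_gene_uniformity(self):
        values = pd.DataFrame(
            [[1.0, 0.0], [0.0, 1.0]], index=["x", "y"], columns=["A", "B"]
        )
        spec = ewce.SpecificityMatrix(values=values, level="subtype")
        bg = ewce.BackgroundSet(genes=["x", "y"])
        null = ewce.sample_random_lists(bg, spec, n=1, reps=4000, seed=1)
        share_x = (null.values[:, 0] == 1.0).mean()
        assert abs(share_x - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_pair_frequencies_uniform_over_enumeration(self, dyadic_spec):
        """chi-square on the C(6,2)=15 pairs, identified via dyadic gamma values."""
        bg = ewce.BackgroundSet(genes=list(dyadic_spec.genes))
        reps = 30000
        null = ewce.sample_random_lists(bg, dyadic_spec, n=2, reps=reps, seed=2)
        pair_gammas = {}
        for pair in combinations(dyadic_spec.genes, 2):
            key = tuple(
                np.round(dyadic_spec.values.loc[list(pair)].sum(axis=0), 12)
            )
            pair_gammas[key] = pair
        assert len(pair_gammas) == 15  # dyadic rows make every pair distinguishable
        observed = pd.Series(
            [tuple(np.round(row, 12)) for row in null.values]
        ).value_counts()
        assert set(observed.index) <= set(pair_gammas)
        chi2 = (((observed - reps / 15) ** 2) / (reps / 15)).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=14)

    def test_oversized_list_is_rejected(self, dyadic_spec):
        bg = ewce.BackgroundSet(genes=list(dyadic_spec.genes))
        with pytest.raises(EwceError, match="cannot draw"):
            ewce.sample_random_lists(bg, dyadic_spec, n=7, reps=10, seed=0)


class TestControlledSampling:
    def _spec_two_blocks(self):
        # block-1 genes specific to A with distinct dyadic weights, block-2 to B
        values = pd.DataFrame(
            [
                [0.50, 0.50, 0.0],
                [0.25, 0.75, 0.0],
                [0.125, 0.875, 0.0],
                [0.0, 0.50, 0.50],
                [0.0, 0.75, 0.25],
                [0.0, 0.875, 0.125],
            ],
            index=[f"g{i}" for i in range(1, 7)],
            columns=["A", "mid", "B"],
        )
        return ewce.SpecificityMatrix(values=values, level="subtype")

    def _grid(self, cells):
        members = {}
        for g, cell in cells.items():
            members.setdefault(cell, []).append(g)
        return ewce.DecileGrid(
            length_boundaries=np.array([1.0]),
            gc_boundaries=np.array([]),
            cell_assignment=cells,
            members=members,
        )

    def test_singleton_cells_force_the_target_list(self, dyadic_spec):
        cells = {g: (i + 1, 1) for i, g in enumerate(dyadic_spec.genes)}
        grid = self._grid(cells)
        target = ["g2", "g5"]
        null = ewce.sample_controlled_lists(target, grid, dyadic_spec, reps=64, seed=3)
        gamma = ewce.summed_specificity(target, dyadic_spec)
        np.testing.assert_allclose(null.values, np.tile(gamma.to_numpy(), (64, 1)))
        res = ewce.bootstrap_test(gamma, null)
        assert (res.table["p"] == 1.0).all()

    def test_one_cell_grid_equals_uncontrolled_from_cell(self, dyadic_spec):
        cells = {g: (1, 1) for g in dyadic_spec.genes}
        grid = self._grid(cells)
        null = ewce.sample_controlled_lists(
            ["g1", "g2"], grid, dyadic_spec, reps=20000, seed=4
        )
        # every replicate must be one of the 15 distinct unordered pairs
        pair_keys = {
            tuple(np.round(dyadic_spec.values.loc[list(p)].sum(axis=0), 12))
            for p in combinations(dyadic_spec.genes, 2)
        }
        seen = {tuple(np.round(row, 12)) for row in null.values}
        assert seen <= pair_keys
        assert len(seen) == 15    # all pairs occur at 20k replicates

    def test_positions_stay_in_their_cells(self):
        spec = self._spec_two_blocks()
        cells = {g: ((1, 1) if i < 3 else (2, 1)) for i, g in enumerate(spec.genes)}
        grid = self._grid(cells)
        null = ewce.sample_controlled_lists(["g1", "g4"], grid, spec, reps=5000, seed=5)
        # membership oracle: gamma(A) only from block 1, gamma(B) only from block 2
        a_vals = {0.5, 0.25, 0.125}
        assert set(np.round(null.values[:, 0], 12)) <= a_vals
        assert set(np.round(null.values[:, 2], 12)) <= a_vals
        # both positions always contribute exactly one gene from each block
        assert (null.values[:, 0] > 0).all() and (null.values[:, 2] > 0).all()

    def test_empty_cell_is_an_error_naming_the_gene(self, dyadic_spec):
        grid = self._grid({"g1": (1, 1)})
        with pytest.raises(EwceError, match="g2"):
            ewce.sample_controlled_lists(["g1", "g2"], grid, dyadic_spec, reps=5, seed=0)

    def test_infeasible_uniqueness_falls_back_to_duplicates(self, dyadic_spec, caplog):
        cells = {"g1": (1, 1)}
        grid = self._grid(cells)
        with caplog.at_level("WARNING", logger="ewce"):
            null = ewce.sample_controlled_lists(
                ["g1", "g1"], grid, dyadic_spec, reps=10, seed=6
            )
        assert "duplicates" in caplog.text
        np.testing.assert_allclose(
            null.values, 2 * np.tile(dyadic_spec.values.loc["g1"].to_numpy(), (10, 1))
        )


class TestBootstrapTest:
    def test_extreme_target_and_centering(self):
        null = ewce.BootstrapSampleMatrix(
            values=np.array([[0.1], [0.2], [0.3], [0.4]]),
            groups=["A"], n_replicates=4, list_length=1, mode="uncontrolled",
        )
        above = ewce.bootstrap_test(pd.Series({"A": 0.9}), null)
        assert above.table.at["A", "p"] == pytest.approx(1 / 5)
        centred = ewce.bootstrap_test(pd.Series({"A": 0.25}), null)
        assert centred.table.at["A", "fold"] == pytest.approx(1.0)
        assert centred.table.at["A", "z"] == pytest.approx(0.0)

    def test_enumeration_oracle_small_background(self, dyadic_spec):
        bg = ewce.BackgroundSet(genes=list(dyadic_spec.genes))
        target = ["g1", "g4"]
        exact = enumeration_pvalues(dyadic_spec, bg.genes, target)
        null = ewce.sample_random_lists(bg, dyadic_spec, n=2, reps=20000, seed=7)
        res = ewce.bootstrap_test(
            ewce.summed_specificity(target, dyadic_spec), null, continuity=False
        )
        for group in dyadic_spec.groups:
            p, q = res.table.at[group, "p"], exact[group]
            se = np.sqrt(q * (1 - q) / 20000)
            assert abs(p - q) <= max(3 * se, 1e-12)

    def test_zero_sd_gives_nan_z_but_valid_p_fold(self):
        null = ewce.BootstrapSampleMatrix(
            values=np.full((10, 1), 0.5),
            groups=["A"], n_replicates=10, list_length=1, mode="uncontrolled",
        )
        res = ewce.bootstrap_test(pd.Series({"A": 0.5}), null)
        assert np.isnan(res.table.at["A", "z"])
        assert res.table.at["A", "p"] == 1.0
        assert res.table.at["A", "fold"] == pytest.approx(1.0)

    def test_full_background_target_has_fold_near_one(self, sim_reference):
        spec = sim_reference["subtype_spec"]
        bg = sim_reference["background"]
        res = ewce.bootstrap_enrichment(
            list(bg.genes), spec, bg, reps=200, seed=8, correction=None
        )
        np.testing.assert_allclose(res.table["fold"].to_numpy(), 1.0, rtol=1e-9)

    def test_seed_determinism_bit_identical(self, sim_reference):
        spec = sim_reference["subtype_spec"]
        bg = sim_reference["background"]
        a = ewce.sample_random_lists(bg, spec, n=15, reps=500, seed=99)
        b = ewce.sample_random_lists(bg, spec, n=15, reps=500, seed=99)
        assert np.array_equal(a.values, b.values)
        c = ewce.sample_random_lists(bg, spec, n=15, reps=500, seed=100)
        assert not np.array_equal(a.values, c.values)


class TestCorrection:
    def test_bonferroni_multiplication(self):
        assert ewce.correct_pvalues([0.01] * 5, "bonferroni") == pytest.approx(
            [0.05] * 5
        )

    def test_single_test_unchanged(self):
        for method in ("bonferroni", "bh"):
            assert ewce.correct_pvalues([0.013], method) == pytest.approx([0.013])

    def test_bh_step_up_hand_computation(self):
        # p=(0.01,0.02,0.03,0.04), m=4: adjusted_i = min_j>=i (m/j * p_j)
        # raw m/j*p: (0.04, 0.04, 0.04, 0.04) -> all 0.04
        out = ewce.correct_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_empty_and_invalid(self):
        assert list(ewce.correct_pvalues([], "bh")) == []
        with pytest.raises(EwceError):
            ewce.correct_pvalues([0.0, 0.5], "bonferroni")


def test_planted_markers_reach_small_p(sim_reference):
    """A pure marker list of the planted group is detected with tiny p."""
    truth = sim_reference["truth"]
    spec = sim_reference["subtype_spec"]
    bg = sim_reference["background"]
    target = ewce.simulate_gene_list(truth, "S3", n=20, purity=1.0, seed=12)
    res = ewce.bootstrap_enrichment(target, spec, bg, reps=2000, seed=13)
    assert res.table.at["S3", "p"] == pytest.approx(1 / 2001)
    assert res.table.at["S3", "p"] == res.table["p"].min()
    assert res.table.at["S3", "fold"] > 1.5
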