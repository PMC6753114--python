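"""Shapley attributions, position profiles, contrasts and composition."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from guidehf import (
    attribute,
    attribute_positions,
    homopolymer_contribution,
    log_odds_composition,
    position_profile,
    variant_contrast,
)
from guidehf.interpret import AttributionMatrix

from conftest import random_spacer


def exhaustive_shapley(f, x, background):
    """Brute-force Shapley values by coalition enumeration.

    Value of a coalition S: E over background rows of f with features in S
    taken from x and the rest from the background row.
    """
    d = len(x)
    bg = np.atleast_2d(background)

    def value(subset):
        rows = np.repeat(bg.copy(), 1, axis=0)
        rows[:, list(subset)] = x[list(subset)]
        return float(np.mean(f(rows)))

    phi = np.zeros(d)
    for j in range(d):
        others = [k for k in range(d) if k != j]
        for r in range(d):
            for subset in itertools.combinations(others, r):
                w = math.factorial(r) * math.factorial(d - r - 1) / math.factorial(d)
                phi[j] += w * (value(subset + (j,)) - value(subset))
    return phi


class TestExactLinear:
    def test_closed_form(self, rng):
        from sklearn.linear_model import LinearRegression

        X = rng.normal(size=(50, 4))
        w = np.array([1.0, -2.0, 0.5, 0.0])
        y = X @ w + 3.0
        est = LinearRegression().fit(X, y)
        bg = rng.normal(size=(20, 4))
        attr = attribute(est, X[:5], bg, explainer="exact_linear")
        expected = (X[:5] - bg.mean(axis=0)) * w
        np.testing.assert_allclose(attr.values, expected, atol=1e-8)
        np.testing.assert_allclose(attr.local_accuracy_error(), 0, atol=1e-8)

    def test_single_feature_attribution_is_pred_minus_base(self, rng):
        from sklearn.linear_model import LinearRegression

        X = rng.normal(size=(30, 1))
        est = LinearRegression().fit(X, 2 * X[:, 0] + 1)
        bg = rng.normal(size=(10, 1))
        attr = attribute(est, X[:3], bg, explainer="exact_linear")
        np.testing.assert_allclose(
            attr.values[:, 0], attr.predictions - attr.base, atol=1e-8
        )


class TestTreeExplainer:
    def test_local_accuracy_through_xgboost(self, rng):
        from xgboost import XGBRegressor

        X = rng.normal(size=(200, 5))
        y = X[:, 0] * 2 + (X[:, 1] > 0) * 1.5 + rng.normal(0, 0.1, 200)
        est = XGBRegressor(n_estimators=30, max_depth=3, random_state=0).fit(X, y)
        attr = attribute(est, X[:10], X, explainer="tree")
        assert attr.local_accuracy_error().max() < 1e-4
        imp = attr.mean_abs()
        assert imp["f0"] > imp["f4"]

    def test_requires_tree_model(self, rng):
        from sklearn.linear_model import LinearRegression

        est = LinearRegression().fit(rng.normal(size=(10, 2)), rng.normal(size=10))
        with pytest.raises(TypeError):
            attribute(est, np.zeros((1, 2)), np.zeros((2, 2)), explainer="tree")


class TestSamplingShapley:
    def test_matches_exhaustive_enumeration_three_features(self, rng):
        f = lambda X: X[:, 0] * X[:, 1] + 2 * X[:, 2] + 0.5 * (X[:, 0] > 0)
        X = rng.normal(size=(4, 3))
        bg = np.zeros((1, 3))
        attr = attribute(f, X, bg, explainer="sampling", n_permutations=200, seed=0)
        for i in range(4):
            expected = exhaustive_shapley(f, X[i], bg)
            np.testing.assert_allclose(attr.values[i], expected, atol=0.02)

    def test_converges_with_budget_at_eight_features(self, rng):
        w = rng.normal(size=8)
        f = lambda X: X @ w + np.prod(X[:, :2], axis=1)
        X = rng.normal(size=(2, 8))
        bg = rng.normal(size=(4, 8))
        attr = attribute(f, X, bg, explainer="sampling", n_permutations=400, seed=1)
        for i in range(2):
            expected = exhaustive_shapley(f, X[i], bg)
            np.testing.assert_allclose(attr.values[i], expected, atol=0.05)

    def test_local_accuracy_exact_by_construction(self, rng):
        f = lambda X: np.tanh(X).sum(axis=1)
        X = rng.normal(size=(6, 5))
        bg = rng.normal(size=(3, 5))
        attr = attribute(f, X, bg, explainer="sampling", n_permutations=5, seed=2)
        np.testing.assert_allclose(attr.local_accuracy_error(), 0, atol=1e-10)

    def test_unknown_explainer(self):
        with pytest.raises(ValueError):
            attribute(lambda X: X.sum(1), np.zeros((1, 2)), np.zeros((1, 2)), explainer="deep")


def analytic_model(bonus_nt="G", bonus_pos=19, weight=0.2):
    def f(spacers):
        return np.array([0.5 + weight * (s[bonus_pos] == bonus_nt) for s in spacers])

    return f


class TestPositionalAttribution:
    def test_planted_g20_lights_up_position_20(self, rng):
        f = analytic_model()
        spacers = [random_spacer(rng) for _ in range(60)]
        bg = [random_spacer(rng) for _ in range(8)]
        attr = attribute_positions(f, spacers, bg, n_permutations=8, seed=0)
        np.testing.assert_allclose(attr.local_accuracy_error(), 0, atol=1e-12)
        prof = position_profile(attr, spacers)
        mean_g20, z_g20, sig = prof.cell("G", 20)
        assert z_g20 > 1
        assert sig
        assert mean_g20 > 0


class TestPositionProfile:
    def _uniform_attr(self, spacers, values):
        return AttributionMatrix(
            values, 0.0, tuple(f"pos_{i}" for i in range(1, 21)), values.sum(axis=1)
        )

    def test_all_zero_attributions_are_degenerate(self, rng):
        spacers = [random_spacer(rng) for _ in range(10)]
        prof = position_profile(self._uniform_attr(spacers, np.zeros((10, 20))), spacers)
        assert prof.degenerate
        assert not prof.significant.any()
        assert np.isnan(prof.z).all()

    def test_z_matrix_standardized(self, rng):
        spacers = [random_spacer(rng) for _ in range(200)]
        values = rng.normal(size=(200, 20))
        prof = position_profile(self._uniform_attr(spacers, values), spacers)
        cells = prof.z[~prof.missing]
        assert cells.mean() == pytest.approx(0.0, abs=1e-12)
        assert cells.std() == pytest.approx(1.0, abs=1e-12)

    def test_empty_cells_flagged_missing(self):
        spacers = ["A" * 20] * 5  # only A carriers anywhere
        values = np.ones((5, 20))
        prof = position_profile(self._uniform_attr(spacers, values), spacers)
        assert prof.missing[:, 1:].all()  # C/G/T cells everywhere missing
        assert not prof.missing[:, 0].any()


class TestVariantContrast:
    def _profile(self, rng, weight, seed):
        f = analytic_model(bonus_pos=17, weight=weight)  # G_18
        local = np.random.default_rng(seed)
        spacers = [random_spacer(local) for _ in range(60)]
        bg = [random_spacer(local) for _ in range(8)]
        attr = attribute_positions(f, spacers, bg, n_permutations=8, seed=0)
        return position_profile(attr, spacers)

    def test_identical_profiles_contrast_to_zero(self, rng):
        p = self._profile(rng, 0.3, seed=1)
        dz, sig = variant_contrast(p, p)
        assert np.nanmax(np.abs(dz)) == 0
        assert not sig.any()

    def test_opposite_planted_effects_flagged(self, rng):
        p_pos = self._profile(rng, 0.3, seed=1)
        p_neg = self._profile(rng, -0.3, seed=1)
        dz, sig = variant_contrast(p_neg, p_pos)
        k = "ACGT".index("G")
        assert sig[17, k]
        assert dz[17, k] < -1

    def test_antisymmetry(self, rng):
        a = self._profile(rng, 0.3, seed=2)
        b = self._profile(rng, 0.1, seed=3)
        dab, _ = variant_contrast(a, b)
        dba, _ = variant_contrast(b, a)
        np.testing.assert_allclose(dab, -dba, atol=1e-12)

    def test_shape_mismatch(self, rng):
        import dataclasses

        p = self._profile(rng, 0.3, seed=4)
        q = dataclasses.replace(p, z=p.z[:10])
        with pytest.raises(ValueError):
            variant_contrast(q, p)


class TestHomopolymer:
    def _attr(self, spacers, values):
        return AttributionMatrix(
            np.asarray(values, float),
            0.0,
            tuple(f"pos_{i}" for i in range(1, 21)),
            np.asarray(values, float).sum(axis=1),
        )

    def test_absent_motif_gives_all_nan(self, rng):
        spacers = ["ACGT" * 5] * 4
        out = homopolymer_contribution(self._attr(spacers, np.ones((4, 20))), spacers, "TTTT")
        assert list(out) == list(range(1, 18))
        assert all(np.isnan(v) for v in out.values())

    def test_single_guide_summed_window(self):
        spacer = "ACGT" + "GGGG" + "ACGTACGTACGT"  # GGGG at spacer positions 5-8
        values = np.zeros((1, 20))
        values[0, 4:8] = 0.1
        out = homopolymer_contribution(self._attr([spacer], values), [spacer], "GGGG")
        assert out[5] == pytest.approx(0.4)

    def test_encoded_coordinates_shift_labels(self):
        spacer = "GGGG" + "ACGTACGTACGTACGT"
        values = np.ones((1, 20))
        out = homopolymer_contribution(
            self._attr([spacer], values), [spacer], "GGGG", positions="encoded"
        )
        assert min(out) == 2
        assert max(out) == 18

    def test_planted_penalty_shows_negative_means(self, rng):
        spacers, values = [], []
        for _ in range(30):
            s = random_spacer(rng)
            start = int(rng.integers(0, 17))
            s = s[:start] + "TTTT" + s[start + 4 :]
            row = rng.normal(0, 0.01, 20)
            row[start : start + 4] -= 0.2
            spacers.append(s)
            values.append(row)
        out = homopolymer_contribution(self._attr(spacers, values), spacers, "TTTT")
        observed = [v for v in out.values() if not np.isnan(v)]
        assert np.mean(observed) < -0.5


class TestLogOdds:
    def test_identical_composition_gives_zero(self):
        spacers = ["ACGT" * 5] * 8
        lo = log_odds_composition(np.linspace(0, 1, 8), spacers)
        assert np.abs(lo.to_numpy()).max() == 0

    def test_worked_g20_example(self):
        top = ["A" * 19 + "G"] * 4
        bottom = ["A" * 19 + "T"] * 4
        spacers = bottom + top
        acts = [0.1] * 4 + [0.9] * 4
        lo = log_odds_composition(acts, spacers, quantile=0.5)
        assert lo.loc[20, "G"] == pytest.approx(math.log(9), abs=1e-12)

    def test_swapping_groups_negates(self, rng):
        spacers = [random_spacer(rng) for _ in range(40)]
        acts = rng.random(40)
        lo = log_odds_composition(acts, spacers)
        swapped = log_odds_composition(1 - acts, spacers)
        np.testing.assert_allclose(lo.to_numpy(), -swapped.to_numpy(), atol=1e-12)

    def test_monotone_transform_invariance(self, rng):
        spacers = [random_spacer(rng) for _ in range(40)]
        acts = rng.random(40)
        a = log_odds_composition(acts, spacers)
        b = log_odds_composition(np.exp(3 * acts), spacers)
        pd.testing.assert_frame_equal(a, b)

    def test_input_validation(self, rng):
        spacers = [random_spacer(rng) for _ in range(10)]
        with pytest.raises(ValueError, match="quantile"):
            log_odds_composition(rng.random(10), spacers, quantile=0.7)
        with pytest.raises(ValueError, match="8"):
            log_odds_composition([0.5] * 5, spacers[:5])
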