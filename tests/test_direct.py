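"""Pairwise REML meta-analysis: effect computation and tau^2 estimation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mtcsim.direct import (
    NonInformativeStudyError,
    StudyEffect,
    effects_from_tables,
    reml_pool,
    restricted_loglik,
    table_to_effect,
)
import pandas as pd


def _grid_argmax(y, v, lo=0.0, hi=2.0):
    """Independent oracle: dense grid search over the restricted likelihood,
    refined to 1e-6 resolution around the coarse optimum."""
    y, v = np.asarray(y), np.asarray(v)
    grid = np.arange(lo, hi, 1e-4)
    ll = [restricted_loglik(t, y, v) for t in grid]
    best = grid[int(np.argmax(ll))]
    fine = np.arange(max(lo, best - 2e-4), best + 2e-4, 1e-6)
    ll = [restricted_loglik(t, y, v) for t in fine]
    return float(fine[int(np.argmax(ll))])


class TestTableToEffect:
    def test_symmetric_table(self):
        e = table_to_effect(10, 20, 10, 20)
        assert e.y == pytest.approx(0.0)
        assert e.v == pytest.approx(0.4)

    def test_hand_computed_or_three(self):
        e = table_to_effect(20, 40, 10, 40)
        assert e.y == pytest.approx(np.log(3.0), abs=1e-12)
        assert e.v == pytest.approx(1 / 20 + 1 / 20 + 1 / 10 + 1 / 30)

    def test_zero_cell_corrects_all_four_cells(self):
        e = table_to_effect(0, 10, 5, 10, correction=0.5)
        cells = np.array([0.5, 10.5, 5.5, 5.5])
        assert e.y == pytest.approx(np.log(cells[0] * cells[3] / (cells[1] * cells[2])))
        assert e.v == pytest.approx(np.sum(1.0 / cells))

    def test_double_zero_is_non_informative(self):
        with pytest.raises(NonInformativeStudyError):
            table_to_effect(0, 10, 0, 12)
        with pytest.raises(NonInformativeStudyError):
            table_to_effect(10, 10, 12, 12)

    def test_batch_conversion_warns_and_skips(self):
        df = pd.DataFrame(
            {"study": ["a", "b"], "r1": [5, 0], "n1": [10, 10],
             "r2": [4, 0], "n2": [10, 10]}
        )
        with pytest.warns(UserWarning, match="excluded"):
            effects = effects_from_tables(df)
        assert len(effects) == 1


class TestRemlPool:
    def test_single_study_is_degenerate(self):
        res = reml_pool([StudyEffect(0.4, 0.09)])
        assert res.log_or == pytest.approx(0.4)
        assert res.se == pytest.approx(0.3)
        assert res.tau2 == 0.0
        assert res.k_studies == 1

    def test_identical_effects_give_zero_heterogeneity(self):
        effects = [StudyEffect(0.25, v) for v in (0.04, 0.09, 0.02)]
        res = reml_pool(effects)
        assert res.tau2 == pytest.approx(0.0, abs=1e-10)
        assert res.log_or == pytest.approx(0.25)

    def test_ci_and_or_are_consistent_transforms(self):
        effects = [StudyEffect(y, 0.05) for y in (-0.2, 0.1, 0.5, 0.3)]
        res = reml_pool(effects)
        assert res.odds_ratio == pytest.approx(np.exp(res.log_or))
        assert res.ci_low == pytest.approx(np.exp(res.log_or - 1.959963985 * res.se))
        assert res.ci_high == pytest.approx(np.exp(res.log_or + 1.959963985 * res.se))
        assert res.z == pytest.approx(res.log_or / res.se)

    @pytest.mark.parametrize("seed", range(12))
    def test_reml_matches_grid_search_oracle(self, seed):
        """Fisher-scoring tau^2 equals a dense grid-search maximizer of the
        restricted likelihood on random small instances."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 11))
        v = rng.uniform(0.01, 0.3, size=k)
        tau = rng.choice([0.0, 0.05, 0.2])
        y = rng.normal(0.3, np.sqrt(v + tau**2))
        res = reml_pool([StudyEffect(yi, vi) for yi, vi in zip(y, v)])
        oracle = _grid_argmax(y, v)
        assert res.tau2 == pytest.approx(oracle, abs=1e-4)

    def test_parameter_recovery_at_large_k(self):
        rng = np.random.default_rng(2024)
        theta, tau2 = 0.3, 0.04
        v = rng.uniform(0.02, 0.08, size=400)
        y = rng.normal(theta, np.sqrt(v + tau2))
        res = reml_pool([StudyEffect(yi, vi) for yi, vi in zip(y, v)])
        assert res.log_or == pytest.approx(theta, abs=0.05)
        assert res.tau2 == pytest.approx(tau2, abs=0.02)

    def test_homogeneous_limit_equals_fixed_effect_pooling(self):
        rng = np.random.default_rng(5)
        v = np.full(30, 1e-4)  # tiny variances, y nearly identical
        y = rng.normal(0.2, 1e-3, size=30)
        res = reml_pool([StudyEffect(yi, vi) for yi, vi in zip(y, v)])
        w = 1.0 / (v + res.tau2)
        assert res.log_or == pytest.approx(np.sum(w * y) / np.sum(w))
        assert res.tau2 < 1e-5

    @given(
        st.lists(
            st.tuples(
                st.floats(-2.0, 2.0),
                st.floats(0.01, 0.5),
            ),
            min_size=1,
            max_size=10,
        )
    )
    def test_pooled_estimate_lies_within_effect_range(self, pairs):
        effects = [StudyEffect(y, v) for y, v in pairs]
        res = reml_pool(effects)
        ys = [e.y for e in effects]
        assert min(ys) - 1e-9 <= res.log_or <= max(ys) + 1e-9
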