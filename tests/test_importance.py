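"""Permutation importance, stabilisation, F1 weighting, aggregation, consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest

from prrtkit.bench import f1
from prrtkit.cohort import CohortError
from prrtkit.importance import (
    FIRanking,
    aggregate_fi,
    consensus,
    correlation_filter,
    model_weights,
    permutation_importance,
    select_top,
    stabilize_pi,
)


class _ConstantModel:
    def predict(self, X):
        return np.zeros(len(X), dtype=int)


class _LookupModel:
    """Predicts the (integer) value of one column — an identity lookup."""

    def __init__(self, col: int):
        self.col = col

    def predict(self, X):
        return np.asarray(X)[:, self.col].astype(int)


class TestPermutationImportance:
    def test_constant_predictor_scores_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, 20)
        pi = permutation_importance(_ConstantModel(), X, y, [0], n_perm=10, seed=0)
        assert pi == 0.0

    def test_constant_column_warns_and_scores_zero(self):
        X = np.column_stack([np.ones(10), np.arange(10)])
        y = np.array([0, 1] * 5)
        with pytest.warns(UserWarning, match="constant"):
            pi = permutation_importance(_LookupModel(1), X, y, [0], n_perm=5, seed=0)
        assert pi == 0.0

    def test_label_copy_feature_matches_exhaustive_enumeration(self):
        # feature = exact copy of a balanced binary label of size 4; the
        # expected permuted F1 is enumerable over all 4! column permutations
        y = np.array([0, 1, 0, 1])
        X = np.column_stack([y.astype(float), np.zeros(4)])
        expected_mean = np.mean(
            [f1(y, y[list(p)]) for p in itertools.permutations(range(4))]
        )
        oracle_pi = 1.0 - expected_mean
        pi = permutation_importance(
            _LookupModel(0), X, y, [0], n_perm=4000, seed=1
        )
        assert pi == pytest.approx(oracle_pi, abs=0.03)
        assert oracle_pi == pytest.approx(0.5)  # frozen from the enumeration

    def test_noise_feature_within_monte_carlo_band(self):
        # a feature the model ignores entirely: PI exactly 0 by construction;
        # a feature with tiny influence: PI within the permutation noise band
        rng = np.random.default_rng(3)
        n = 60
        y = rng.integers(0, 2, n)
        X = np.column_stack([y + rng.normal(0, 0.1, n), rng.normal(size=n)])
        model = _LookupModel(0)

        class _Round:
            def predict(self, Z):
                return (np.asarray(Z)[:, 0] > 0.5).astype(int)

        # replicate PI of the pure-noise column over independent seeds
        pis = [
            permutation_importance(_Round(), X, y, [1], n_perm=50, seed=s)
            for s in range(10)
        ]
        assert max(abs(p) for p in pis) <= 3 * (np.std(pis) + 1e-12) + 1e-9


class TestStabilize:
    @pytest.mark.parametrize(
        "pis, expected",
        [([-0.2], 0.2), ([0.1, -0.1], 0.1), ([0.3, 0.1, 0.2], pytest.approx(0.2))],
    )
    def test_mean_absolute_pi(self, pis, expected):
        table = pd.DataFrame(
            {
                "config_id": "m",
                "split": range(len(pis)),
                "feature": "f",
                "pi": pis,
            }
        )
        out = stabilize_pi(table)
        assert out.loc[0, "stabilized_pi"] == expected

    def test_missing_columns_rejected(self):
        with pytest.raises(CohortError):
            stabilize_pi(pd.DataFrame({"pi": [1.0]}))


class TestModelWeights:
    def test_equal_f1_gives_unit_weights(self):
        w = model_weights(pd.Series({"a": 0.8, "b": 0.8, "c": 0.8}))
        assert np.allclose(w, 1.0)

    def test_worked_pair(self):
        w = model_weights(pd.Series({"a": 0.5, "b": 1.0}))
        assert w["a"] == pytest.approx(2 / 3)
        assert w["b"] == pytest.approx(4 / 3)

    def test_weights_average_to_one(self):
        rng = np.random.default_rng(0)
        w = model_weights(pd.Series(rng.uniform(0.1, 0.9, 12)))
        assert w.mean() == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(CohortError):
            model_weights(pd.Series({"a": 0.0, "b": 0.0}))


def _stab(values: dict[str, dict[str, float]]) -> pd.DataFrame:
    rows = [
        {"config_id": cid, "feature": f, "stabilized_pi": v}
        for cid, feats in values.items()
        for f, v in feats.items()
    ]
    return pd.DataFrame(rows)


class TestAggregateFI:
    def test_single_config_preserves_order(self):
        stab = _stab({"m": {"a": 0.3, "b": 0.1, "c": 0.2}})
        ranking = aggregate_fi(stab, pd.Series({"m": 1.0}))
        assert ranking.table["feature"].tolist() == ["a", "c", "b"]
        assert ranking.table["fi"].iloc[0] == 1.0  # max-normalised

    def test_equal_weights_average_vectors(self):
        stab = _stab({"m1": {"a": 0.4, "b": 0.0}, "m2": {"a": 0.0, "b": 0.2}})
        ranking = aggregate_fi(stab, pd.Series({"m1": 1.0, "m2": 1.0}))
        t = ranking.table.set_index("feature")
        assert t.loc["a", "fi"] == pytest.approx(1.0)
        assert t.loc["b", "fi"] == pytest.approx(0.1 / 0.2)

    def test_scale_equivariance_of_ranking(self):
        stab = _stab({"m": {"a": 0.31, "b": 0.13, "c": 0.22, "d": 0.05}})
        base = aggregate_fi(stab, pd.Series({"m": 1.0})).table["feature"].tolist()
        scaled = stab.assign(stabilized_pi=stab["stabilized_pi"] * 17.0)
        again = aggregate_fi(scaled, pd.Series({"m": 1.0})).table["feature"].tolist()
        assert base == again

    def test_weight_monotonicity(self):
        # raising one config's F1 never lowers that config's influence
        stab = _stab({"m1": {"a": 0.5, "b": 0.0}, "m2": {"a": 0.0, "b": 0.5}})
        fi_a = []
        for f1_m1 in (0.4, 0.6, 0.8):
            w = model_weights(pd.Series({"m1": f1_m1, "m2": 0.5}))
            t = aggregate_fi(stab, w).table.set_index("feature")
            # un-normalised ratio of a vs b tracks m1's relative weight
            fi_a.append(t.loc["a", "fi"] / max(t.loc["b", "fi"], 1e-12))
        assert fi_a == sorted(fi_a)

    def test_partial_coverage_uses_covering_configs_only(self):
        stab = _stab({"m1": {"a": 0.4}, "m2": {"a": 0.2, "b": 0.2}})
        ranking = aggregate_fi(stab, pd.Series({"m1": 1.0, "m2": 1.0}))
        t = ranking.table.set_index("feature")
        assert t.loc["a", "coverage"] == 2
        assert t.loc["b", "coverage"] == 1
        assert t.loc["a", "fi"] == pytest.approx(1.0)  # (0.4+0.2)/2 = 0.3 -> max
        assert t.loc["b", "fi"] == pytest.approx(0.2 / 0.3)

    def test_ties_break_lexicographically(self):
        stab = _stab({"m": {"zeta": 0.2, "alpha": 0.2, "mid": 0.2}})
        ranking = aggregate_fi(stab, pd.Series({"m": 1.0}))
        assert ranking.table["feature"].tolist() == ["alpha", "mid", "zeta"]


class TestSelectTop:
    @pytest.mark.parametrize(
        "n, fraction, expected", [(40, 0.10, 4), (104, 0.10, 11), (7, 1.0, 7)]
    )
    def test_ceiling_rule(self, n, fraction, expected):
        stab = _stab({"m": {f"f{i:03d}": 1.0 - i * 1e-3 for i in range(n)}})
        ranking = aggregate_fi(stab, pd.Series({"m": 1.0}))
        assert len(select_top(ranking, fraction)) == expected

    def test_empty_ranking_rejected(self):
        with pytest.raises(CohortError):
            select_top(FIRanking("lesion", pd.DataFrame(columns=["feature", "rank"])))


class TestConsensus:
    def _ranking(self, level, fis, selected):
        table = pd.DataFrame(
            {
                "feature": list(fis),
                "fi": list(fis.values()),
                "coverage": 1,
            }
        ).sort_values("fi", ascending=False).reset_index(drop=True)
        table["rank"] = range(1, len(table) + 1)
        table["selected"] = table["feature"].isin(selected)
        return FIRanking(level, table)

    def test_identical_selections_intersect_fully(self):
        l = self._ranking("lesion", {"a": 1.0, "b": 0.5}, {"a", "b"})
        p = self._ranking("patient", {"a": 0.8, "b": 1.0}, {"a", "b"})
        out = consensus(l, p)
        assert set(out["feature"]) == {"a", "b"}
        assert out["feature"].tolist() == ["a", "b"]  # by mean fi: 0.9 vs 0.75

    def test_disjoint_selections_yield_empty(self):
        l = self._ranking("lesion", {"a": 1.0, "b": 0.5}, {"a"})
        p = self._ranking("patient", {"a": 0.8, "b": 1.0}, {"b"})
        assert len(consensus(l, p)) == 0

    def test_feature_selected_at_one_level_only_is_excluded(self):
        l = self._ranking("lesion", {"planted": 1.0, "noise": 0.9}, {"planted", "noise"})
        p = self._ranking("patient", {"planted": 1.0, "noise": 0.1}, {"planted"})
        out = consensus(l, p)
        assert out["feature"].tolist() == ["planted"]


class TestCorrelationFilter:
    def test_zero_pi_feature_dropped_and_strong_retained(self):
        table = pd.DataFrame(
            {
                "config_id": ["m"] * 4,
                "split": [0, 1, 0, 1],
                "feature": ["dead", "dead", "live", "live"],
                "pi": [0.0, 0.0, 0.2, 0.3],
            }
        )
        retained, _ = correlation_filter(table, None, eps=1e-6)
        assert retained == ["live"]

    def test_eps_zero_disables_filter(self):
        table = pd.DataFrame(
            {"config_id": "m", "split": [0, 0], "feature": ["a", "b"], "pi": [0.0, 0.1]}
        )
        retained, _ = correlation_filter(table, None, eps=0.0)
        assert retained == ["a", "b"]

    def test_all_dropped_raises_with_hint(self):
        table = pd.DataFrame(
            {"config_id": "m", "split": [0], "feature": ["a"], "pi": [0.0]}
        )
        with pytest.raises(CohortError, match="eps"):
            correlation_filter(table, None, eps=1e-6)

    def test_triangle_artifact_is_lower_triangular(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        table = pd.DataFrame(
            {
                "config_id": "m",
                "split": 0,
                "feature": ["a", "b", "c"],
                "pi": [0.1, 0.2, 0.3],
            }
        )
        _, tri = correlation_filter(table, frame, eps=1e-6)
        upper = np.triu(tri.to_numpy(), k=1)
        assert np.allclose(upper, 0.0)
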