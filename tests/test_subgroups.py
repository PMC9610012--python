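import numpy as np
import pandas as pd
import pytest

from volleymine.subgroups import (
    discover,
    effect_label,
    enumerate_conditions,
    false_discovery_probability,
    subgroup_analysis,
    subgroup_effect_size,
    swap_randomized_null,
    z_quality,
)


def make_matrix(X, y, action="attack", feature_names=None):
    """Wrap raw arrays into the feature-matrix layout the search expects."""
    X = np.asarray(X, dtype=float)
    names = feature_names or [f"F{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    n = len(df)
    df.insert(0, "player_id", [f"P{i}" for i in range(n)])
    df.insert(1, "match_id", "M01")
    df.insert(2, "match_date", pd.Timestamp("2018-06-01"))
    df.insert(3, "action_type", action)
    df["n_actions"] = 1
    df["target"] = np.asarray(y, dtype=float)
    return df


def brute_force_search(X, y, min_frac=0.10, max_frac=0.90):
    """Independent scorer: loop over every (feature, operator, threshold)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    mean_all, sd_all = y.mean(), y.std(ddof=1)
    out = []
    for j in range(X.shape[1]):
        v = X[:, j]
        for thr in np.unique(v[~np.isnan(v)]):
            for op in ("<=", ">="):
                mask = (v <= thr) if op == "<=" else (v >= thr)
                mask &= ~np.isnan(v)
                size = int(mask.sum())
                if not (min_frac * n <= size <= max_frac * n) or size == 0:
                    continue
                z = (y[mask].mean() - mean_all) * np.sqrt(size) / sd_all
                out.append((j, op, float(thr), size, z))
    return out


class TestZQuality:
    def test_whole_dataset_scores_zero(self):
        y = [1.0, 2.0, 5.0, 9.0]
        assert z_quality(y, y) == pytest.approx(0.0)

    def test_hand_computed_golden(self):
        # all = {0,0,10,10}: mean 5, sd ~5.7735; S = {10,10}
        assert z_quality([10, 10], [0, 0, 10, 10]) == pytest.approx(
            5 * np.sqrt(2) / np.std([0, 0, 10, 10], ddof=1))
        assert z_quality([10, 10], [0, 0, 10, 10]) == pytest.approx(1.2247, abs=1e-4)

    def test_scales_with_sqrt_subgroup_size(self):
        all_t = [0.0, 0, 0, 10, 10, 10, 5, 5]
        z1 = z_quality([10, 10], all_t)
        z2 = z_quality([10, 10, 10, 10], all_t)
        assert z2 == pytest.approx(np.sqrt(2) * z1)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            z_quality([], [1, 2, 3])
        with pytest.raises(ValueError):
            z_quality([3], [3, 3, 3])


class TestEffectSize:
    def test_identical_groups_negligible(self):
        d, lo, hi, label = subgroup_effect_size([1, 2, 3], [1, 2, 3])
        assert d == pytest.approx(0.0)
        assert label == "negligible"
        assert lo < 0 < hi

    def test_zero_pooled_sd_undefined(self):
        d, *_, label = subgroup_effect_size([2, 2], [0, 0])
        assert np.isnan(d) and label == "undefined"

    def test_one_pooled_sd_shift_is_large(self, rng):
        a = rng.normal(0, 1, 4000)
        b = rng.normal(1, 1, 4000)
        d, lo, hi, label = subgroup_effect_size(b, a)
        assert d == pytest.approx(1.0, abs=0.08)
        assert label == "large"
        assert lo < d < hi

    @pytest.mark.parametrize("d,expected", [(0.1, "negligible"), (0.3, "small"),
                                            (0.65, "medium"), (1.2, "large")])
    def test_labels_follow_thresholds(self, d, expected):
        assert effect_label(d) == expected


class TestFalseDiscoveryProbability:
    def test_add_one_bound_case(self):
        null = np.linspace(0.5, 3.0, 1000)
        assert false_discovery_probability(5.0, null) == pytest.approx(1 / 1001)

    def test_observed_below_all_nulls(self):
        assert false_discovery_probability(0.1, np.ones(100) * 2) == 1.0

    def test_boundary_at_95th_percentile(self):
        null = np.arange(1, 101, dtype=float)
        # 5 maxima >= 96 -> p = 6/101
        assert false_discovery_probability(96.0, null) == pytest.approx(6 / 101)


class TestEnumeration:
    def test_constant_feature_yields_no_candidates(self):
        m = make_matrix(np.ones((20, 1)), np.arange(20))
        assert len(enumerate_conditions(m, "attack")) == 0

    def test_size_window_enforced(self):
        # feature with values 1,2,3 on 30 rows (10 each): only subgroup
        # sizes 10 and 20 are admissible (30 rows would be 100%)
        v = np.repeat([1.0, 2.0, 3.0], 10)
        m = make_matrix(v[:, None], np.arange(30))
        cand = enumerate_conditions(m, "attack")
        assert set(cand["size"]) == {10, 20}

    def test_min_size_one_for_ten_rows(self):
        m = make_matrix(np.arange(10)[:, None].astype(float), np.arange(10))
        cand = enumerate_conditions(m, "attack")
        assert cand["size"].min() == 1
        assert cand["size"].max() == 9


class TestDiscover:
    def test_matches_brute_force_oracle(self, rng):
        for trial in range(5):
            n = int(rng.integers(12, 50))
            k = int(rng.integers(1, 6))
            X = np.round(rng.normal(0, 1, (n, k)), 1)
            y = rng.normal(5, 2, n)
            m = make_matrix(X, y)
            res = discover(m, "attack")
            oracle = brute_force_search(X, y)
            # best |z| per (feature, operator) must agree exactly
            best = {}
            for j, op, thr, size, z in oracle:
                key = (f"F{j}", op)
                if key not in best or abs(z) > abs(best[key][1]):
                    best[key] = (thr, z, size)
            assert len(res) == len(best)
            for r in res.itertuples():
                thr, z, size = best[(r.feature, r.operator)]
                assert r.quality == pytest.approx(z, rel=1e-9)
                assert r.size == size
            # and the global ranking starts at the overall best |z|
            assert abs(res["quality"].iloc[0]) == pytest.approx(
                max(abs(z) for _, _, _, _, z in oracle), rel=1e-9)

    def test_duplicate_feature_columns_score_identically(self, rng):
        v = rng.normal(0, 1, 30)
        m = make_matrix(np.column_stack([v, v]), rng.normal(0, 1, 30),
                        feature_names=["orig", "copy"])
        res = discover(m, "attack")
        by_feat = res.set_index(["feature", "operator"])["quality"]
        for op in ("<=", ">="):
            assert by_feat["orig", op] == pytest.approx(by_feat["copy", op])

    def test_sign_convention_flips_with_target(self, rng):
        X = rng.normal(0, 1, (40, 3))
        y = rng.normal(0, 1, 40)
        r1 = discover(make_matrix(X, y), "attack")
        r2 = discover(make_matrix(X, -y), "attack")
        merged = r1.merge(r2, on=["feature", "operator", "threshold"], suffixes=("_pos", "_neg"))
        assert len(merged) == len(r1)
        np.testing.assert_allclose(merged["quality_pos"], -merged["quality_neg"], rtol=1e-9)

    def test_positive_quality_means_above_average(self, rng):
        X = rng.normal(0, 1, (60, 2))
        y = X[:, 0] * 2 + rng.normal(0, 0.5, 60)
        res = discover(make_matrix(X, y), "attack")
        top = res.iloc[0]
        assert (top["subgroup_mean"] > y.mean()) == (top["quality"] > 0)


class TestSwapNull:
    def test_single_run(self, rng):
        m = make_matrix(rng.normal(0, 1, (30, 3)), rng.normal(0, 1, 30))
        null = swap_randomized_null(m, "attack", n_runs=1, seed=0)
        assert null.shape == (1,) and null[0] > 0

    def test_fixed_seed_reproducible(self, rng):
        m = make_matrix(rng.normal(0, 1, (30, 3)), rng.normal(0, 1, 30))
        a = swap_randomized_null(m, "attack", n_runs=25, seed=42)
        b = swap_randomized_null(m, "attack", n_runs=25, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_maxima_strictly_positive(self, rng):
        m = make_matrix(rng.normal(0, 1, (40, 4)), rng.normal(0, 1, 40))
        null = swap_randomized_null(m, "attack", n_runs=50, seed=1)
        assert (null > 0).all()

    def test_null_max_at_least_observed_under_permutation_symmetry(self, rng):
        # the observed best |z| should land inside the null's support range
        m = make_matrix(rng.normal(0, 1, (40, 4)), rng.normal(0, 1, 40))
        obs = abs(discover(m, "attack")["quality"].iloc[0])
        null = swap_randomized_null(m, "attack", n_runs=200, seed=3)
        assert null.min() < obs < null.max() * 1.5


class TestAnalysis:
    def test_analysis_attaches_fd_and_effect(self, rng):
        m = make_matrix(rng.normal(0, 1, (40, 4)), rng.normal(5, 1, 40))
        res = subgroup_analysis(m, "attack", n_runs=60, seed=0, top_k=5)
        assert {"fd_probability", "significant", "cohens_d", "effect"} <= set(res.columns)
        assert res["fd_probability"].between(0, 1).all()
        assert (res["significant"] == (res["fd_probability"] < 0.05)).all()

    def test_strong_signal_is_significant(self, rng):
        # one feature perfectly splits the target far beyond any null
        v = np.repeat([0.0, 1.0], 25)
        y = np.concatenate([rng.normal(0, 0.3, 25), rng.normal(5, 0.3, 25)])
        X = np.column_stack([v, rng.normal(0, 1, 50)])
        res = subgroup_analysis(make_matrix(X, y), "attack", n_runs=199, seed=0)
        top = res.iloc[0]
        assert top["feature"] == "F0" and top["significant"]
        assert top["effect"] == "large"
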