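"""FAMD identities, mixed association measures, hotspot rule search."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA

from logfeat.association import (
    association_matrix,
    correlation_ratio,
    cramers_v,
    famd,
    hotspot_rules,
)


@pytest.fixture(scope="module")
def mixed_df():
    rng = np.random.default_rng(10)
    n = 150
    return pd.DataFrame(
        {
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
            "c1": rng.choice(["a", "b", "c"], n),
            "c2": rng.choice(["u", "v"], n),
        }
    )


class TestFAMD:
    def test_eigenvalue_sum_equals_total_inertia(self, mixed_df):
        res = famd(mixed_df)
        # 2 continuous + (3-1) + (2-1) = 5
        assert res.total_inertia == pytest.approx(5.0, abs=1e-9)
        assert res.eigenvalues.sum() == pytest.approx(res.total_inertia, abs=1e-9)

    def test_eigenvalues_nonincreasing_nonnegative(self, mixed_df):
        eig = famd(mixed_df).eigenvalues
        assert (eig >= -1e-12).all()
        assert (np.diff(eig) <= 1e-12).all()

    def test_contrib_sums_to_100_per_dimension(self, mixed_df):
        res = famd(mixed_df)
        assert np.allclose(res.contrib.sum(axis=0), 100.0)

    def test_cos2_in_unit_interval_and_bounded_sum(self, mixed_df):
        res = famd(mixed_df)
        assert ((res.cos2 >= -1e-12) & (res.cos2 <= 1 + 1e-9)).all().all()
        assert (res.cos2.sum(axis=1) <= 1 + 1e-9).all()

    def test_all_continuous_matches_pca(self):
        """On purely continuous input FAMD is PCA of the correlation
        matrix: identical coordinates up to sign, within 1e-8."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 4)) @ rng.normal(size=(4, 4))
        df = pd.DataFrame(X, columns=list("abcd"))
        res = famd(df)
        Z = (X - X.mean(0)) / X.std(0, ddof=0)
        pca = PCA(n_components=4).fit(Z)
        scores = pca.transform(Z)
        eig_pca = (pca.singular_values_**2) / len(X)
        assert np.allclose(res.eigenvalues[:4], eig_pca, atol=1e-8)
        for k in range(4):
            a, b = res.row_coords.iloc[:, k].to_numpy(), scores[:, k]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_duplicated_continuous_columns_coincide(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=60)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=60)})
        res = famd(df)
        # the shared axis carries both columns: coordinates coincide
        assert np.allclose(
            res.column_coords.loc["a"], res.column_coords.loc["b"], atol=1e-8
        )
        assert res.eigenvalues[0] >= 2.0 - 1e-9  # their shared variance

    def test_constant_variable_dropped_with_record(self, mixed_df):
        df = mixed_df.copy()
        df["const"] = 1.0
        res = famd(df)
        assert "const" in res.dropped

    def test_fewer_than_two_variables_rejected(self):
        with pytest.raises(ValueError, match="two variables"):
            famd(pd.DataFrame({"a": [1.0, 2.0]}))


class TestAssociationMatrix:
    def test_diagonal_and_ranges(self, mixed_df):
        mat = association_matrix(mixed_df)
        assert np.allclose(np.diag(mat), 1.0)
        cats = ["c1", "c2"]
        assert ((mat.loc[cats, cats] >= 0) & (mat.loc[cats, cats] <= 1)).all().all()
        assert mat.loc["x1", "x2"] >= -1 and mat.loc["x1", "x2"] <= 1

    def test_symmetry(self, mixed_df):
        mat = association_matrix(mixed_df)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)

    def test_identical_continuous_gives_pearson_one(self):
        x = np.arange(20, dtype=float)
        mat = association_matrix(pd.DataFrame({"a": x, "b": x}))
        assert mat.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_categoricals_low_v(self):
        rng = np.random.default_rng(99)
        n = 2000
        df = pd.DataFrame(
            {"x": rng.choice(["p", "q", "r"], n), "y": rng.choice(["s", "t"], n)}
        )
        assert cramers_v(df["x"], df["y"]) < 0.1

    def test_deterministic_category_perfect_eta(self):
        cats = ["a"] * 10 + ["b"] * 10
        vals = [0.0] * 10 + [5.0] * 10
        assert correlation_ratio(cats, vals) == pytest.approx(1.0)

    def test_all_missing_column_errors(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="entirely missing"):
            association_matrix(df)

    def test_threshold_screen(self, mixed_df):
        mat = association_matrix(mixed_df, threshold=0.6)
        screen = mat.attrs["screen"]
        assert bool(screen.loc["x1", "x1"])


class TestHotspot:
    @staticmethod
    def _planted(n=600, seed=13):
        """F1=a AND F2=b makes class 'hot' with high confidence."""
        rng = np.random.default_rng(seed)
        f1 = rng.choice(["a", "x"], n)
        f2 = rng.choice(["b", "y"], n)
        noise = rng.choice(["m", "n"], n)
        hot = (f1 == "a") & (f2 == "b") & (rng.random(n) < 0.95)
        cold_flip = (~((f1 == "a") & (f2 == "b"))) & (rng.random(n) < 0.05)
        target = np.where(hot | cold_flip, "hot", "cold")
        return pd.DataFrame(
            {"F1": f1, "F2": f2, "noise": noise, "target": target}
        )

    def test_planted_rule_recovered_at_depth_two(self):
        df = self._planted()
        rules = hotspot_rules(df, "target", "hot", min_support=0.3, max_depth=2)
        best = max(rules, key=lambda r: r.confidence)
        assert set(v for v, _ in best.conditions) == {"F1", "F2"}
        assert dict(best.conditions) == {"F1": "a", "F2": "b"}
        assert best.confidence > 0.9

    def test_children_strictly_improve_confidence(self):
        df = self._planted()
        rules = hotspot_rules(df, "target", "hot")
        by_cond = {r.conditions: r for r in rules}
        for r in rules:
            if r.conditions:
                parent = by_cond[r.conditions[:-1]]
                assert r.confidence > parent.confidence

    def test_min_support_one_returns_only_root(self):
        df = self._planted()
        rules = hotspot_rules(df, "target", "hot", min_support=1.0)
        assert len(rules) == 1 and rules[0].conditions == ()

    def test_uniform_noise_gains_little_over_root(self):
        rng = np.random.default_rng(55)
        n = 1500
        df = pd.DataFrame(
            {
                "F1": rng.choice(["a", "b"], n),
                "F2": rng.choice(["c", "d"], n),
                "target": rng.choice(["hot", "cold"], n),
            }
        )
        rules = hotspot_rules(df, "target", "hot", min_support=0.3)
        root_conf = rules[0].confidence
        assert all(r.confidence - root_conf <= 0.1 for r in rules)

    def test_absent_target_class_errors(self):
        df = self._planted()
        with pytest.raises(ValueError, match="absent"):
            hotspot_rules(df, "target", "nope")

    def test_bad_min_support_rejected(self):
        df = self._planted()
        with pytest.raises(ValueError, match="min_support"):
            hotspot_rules(df, "target", "hot", min_support=0)
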