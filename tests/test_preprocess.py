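import math

import numpy as np
import pandas as pd
import pytest

import oracles
from hsvr_qsar.preprocess import (
    Autoscaler,
    DescriptorFilter,
    chemical_space_stats,
    kennard_stone_split,
    similarity_check,
)
from hsvr_qsar.preprocess import EmptyFeatureSpaceError


def named_frame(cols: dict) -> pd.DataFrame:
    n = len(next(iter(cols.values())))
    return pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])


class TestDescriptorFilter:
    def test_duplicate_column_keeps_exactly_one(self):
        X = named_frame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [4.0, 1, 3, 2]})
        filt = DescriptorFilter().fit(X)
        kept = filt.surviving_
        assert ("a" in kept) != ("b" in kept)
        assert "c" in kept
        assert len(filt.report_.dropped_intercorrelated) == 1

    def test_constant_column_dropped_as_low_variance(self):
        X = named_frame({"a": [5.0, 5, 5, 5], "b": [1.0, 2, 3, 4]})
        filt = DescriptorFilter().fit(X)
        assert filt.surviving_ == ["b"]
        assert filt.report_.dropped_low_variance == ["a"]

    def test_missing_values_drop_descriptor(self):
        X = named_frame({"a": [1.0, np.nan, 3, 4], "b": [1.0, 2, 3, 4]})
        filt = DescriptorFilter().fit(X)
        assert filt.report_.dropped_missing == ["a"]

    def test_keep_rule_prefers_response_correlated_member(self, rng):
        """Of an intercorrelated pair, the descriptor more correlated
        with the response survives."""
        base = rng.normal(size=60)
        d2 = base + 0.05 * rng.normal(size=60)          # tracks the response
        d1 = d2 + 0.08 * rng.normal(size=60)            # noisier copy of d2
        X = named_frame(
            {
                "d1": d1,
                "d2": d2,
                "u1": rng.normal(size=60),
                "u2": rng.normal(size=60),
                "u3": rng.normal(size=60),
            }
        )
        y = base
        r2_pair = np.corrcoef(d1, d2)[0, 1] ** 2
        assert r2_pair > 0.8
        # the keep rule compares |corr(d, y)| directly
        assert abs(np.corrcoef(d2, y)[0, 1]) > abs(np.corrcoef(d1, y)[0, 1])
        filt = DescriptorFilter().fit(X, y)
        assert "d2" in filt.surviving_ and "d1" not in filt.surviving_

    def test_idempotent(self, small_dataset):
        X, y = small_dataset
        first = DescriptorFilter().fit(X, y)
        Xf = first.transform(X)
        second = DescriptorFilter().fit(Xf, y)
        assert second.surviving_ == first.surviving_
        assert not second.report_.dropped_intercorrelated

    def test_all_removed_raises(self):
        X = named_frame({"a": [1.0, 1, 1], "b": [2.0, 2, 2]})
        with pytest.raises(EmptyFeatureSpaceError):
            DescriptorFilter().fit(X)

    def test_report_partitions_names(self, small_dataset):
        X, y = small_dataset
        filt = DescriptorFilter().fit(X, y)
        rep = filt.report_
        dropped = (
            set(rep.dropped_missing)
            | set(rep.dropped_low_variance)
            | {d for _, d, _ in rep.dropped_intercorrelated}
        )
        assert dropped | set(rep.surviving) == set(X.columns)
        assert not dropped & set(rep.surviving)


class TestAutoscaler:
    def test_simple_column(self):
        X = named_frame({"a": [1.0, 2.0, 3.0]})
        out = Autoscaler().fit(X).transform(X)
        assert np.allclose(out["a"], [-1.0, 0.0, 1.0])

    def test_hand_computed_column(self):
        vals = [2.0, 4, 4, 4, 5, 5, 7, 9]
        X = named_frame({"a": vals})
        sd = math.sqrt(sum((v - 5.0) ** 2 for v in vals) / 7)
        expected = [(v - 5.0) / sd for v in vals]
        out = Autoscaler().fit(X).transform(X)
        assert np.allclose(out["a"], expected)

    def test_training_columns_become_standard(self, small_dataset):
        X, _ = small_dataset
        out = Autoscaler().fit(X).transform(X)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_invertible(self, small_dataset):
        X, _ = small_dataset
        sc = Autoscaler().fit(X)
        back = sc.inverse_transform(sc.transform(X))
        assert np.allclose(back.to_numpy(), X.to_numpy(), atol=1e-10)

    def test_unseen_name_rejected(self, small_dataset):
        X, _ = small_dataset
        sc = Autoscaler().fit(X)
        bad = X.rename(columns={X.columns[0]: "mystery"})
        with pytest.raises(KeyError):
            sc.transform(bad)

    def test_zero_variance_rejected(self):
        X = named_frame({"a": [3.0, 3.0, 3.0]})
        with pytest.raises(ValueError):
            Autoscaler().fit(X)


class TestKennardStone:
    def test_one_dimensional_worked_example(self):
        X = named_frame({"x": [0.0, 1.0, 2.0, 4.0, 10.0]})
        X.index = ["p0", "p1", "p2", "p4", "p10"]
        part = kennard_stone_split(X, train_fraction=0.8)
        assert part.selection_order == ["p0", "p10", "p4", "p2"]
        assert part.test_ids == ["p1"]

    def test_63_samples_split_50_13(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(63, 5)), index=[f"m{i}" for i in range(63)])
        X.columns = [f"d{j}" for j in range(5)]
        part = kennard_stone_split(X, train_fraction=0.8)
        assert len(part.train_ids) == 50
        assert len(part.test_ids) == 13

    def test_two_points_full_fraction(self):
        X = named_frame({"x": [0.0, 1.0]})
        part = kennard_stone_split(X, train_fraction=1.0)
        assert sorted(part.train_ids) == ["s0", "s1"]
        assert part.test_ids == []

    def test_deterministic(self, small_dataset):
        X, _ = small_dataset
        Xn = Autoscaler().fit(X).transform(X)
        p1 = kennard_stone_split(Xn, 0.8)
        p2 = kennard_stone_split(Xn, 0.8)
        assert p1.selection_order == p2.selection_order
        assert p1.train_ids == p2.train_ids

    def test_greedy_matches_exhaustive_oracle(self, rng):
        """Every pick maximizes the minimum distance to the selected
        set, verified against a brute-force implementation on small
        instances."""
        for _ in range(20):
            n = int(rng.integers(4, 13))
            d = int(rng.integers(1, 4))
            pts = rng.normal(size=(n, d))
            X = pd.DataFrame(pts, index=[f"q{i}" for i in range(n)])
            X.columns = [f"d{j}" for j in range(d)]
            n_train = int(np.floor(0.8 * n + 0.5))
            part = kennard_stone_split(X, 0.8)
            expected = oracles.kennard_stone_order([tuple(p) for p in pts], n_train)
            assert part.selection_order == [f"q{i}" for i in expected]


class TestChemicalSpace:
    def test_collinear_points_load_on_one_component(self):
        t = np.linspace(0, 1, 10)
        X = pd.DataFrame({"x": t, "y": 2 * t, "z": -t}, index=[f"s{i}" for i in range(10)])
        stats = chemical_space_stats(X, n_components=3)
        assert stats["explained_variance_ratio"][0] == pytest.approx(1.0)

    def test_unit_square_geometry(self):
        X = pd.DataFrame(
            {"x": [0.0, 1.0, 0.0, 1.0], "y": [0.0, 0.0, 1.0, 1.0]},
            index=list("abcd"),
        )
        stats = chemical_space_stats(X, n_components=2)
        assert stats["nn_distance_mean"] == pytest.approx(1.0)
        assert stats["max_distance"] == pytest.approx(math.sqrt(2.0))

    def test_matches_pairwise_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 5)), index=[f"s{i}" for i in range(20)])
        X.columns = [f"d{j}" for j in range(5)]
        stats = chemical_space_stats(X)
        pts = X.to_numpy()
        dists = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(dists, np.inf)
        nn = dists.min(axis=1)
        assert stats["nn_distance_mean"] == pytest.approx(nn.mean())
        assert stats["max_distance"] == pytest.approx(dists[np.isfinite(dists)].max())

    def test_component_truncation_warns(self):
        X = pd.DataFrame(
            {"x": [0.0, 1.0, 2.0], "y": [1.0, 0.0, 2.0]}, index=list("abc")
        )
        with pytest.warns(UserWarning):
            chemical_space_stats(X, n_components=5)


class TestSimilarityCheck:
    def test_identical_tables_fully_overlap(self, small_dataset):
        X, y = small_dataset
        rep = similarity_check(X, X, y, y)
        assert all(v["overlap"] == pytest.approx(1.0) for v in rep.values())

    def test_disjoint_ranges_have_zero_overlap(self):
        tr = pd.DataFrame({"a": [0.0, 1.0]}, index=["x", "y"])
        te = pd.DataFrame({"a": [5.0, 6.0]}, index=["u", "v"])
        rep = similarity_check(tr, te)
        assert rep["a"]["overlap"] == 0.0

    def test_overlap_matches_interval_arithmetic(self, small_dataset):
        X, y = small_dataset
        tr, te = X.iloc[:60], X.iloc[60:]
        rep = similarity_check(tr, te)
        for name in X.columns:
            a, b = tr[name], te[name]
            inter = max(0.0, min(a.max(), b.max()) - max(a.min(), b.min()))
            union = max(a.max(), b.max()) - min(a.min(), b.min())
            assert rep[name]["overlap"] == pytest.approx(inter / union)
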