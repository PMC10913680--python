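"""Cross-validation folds, error metrics, selection rules, the repair loop
and the tuning procedures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import holomix as hx
from holomix import selection as S
from conftest import make_dataset, two_class_block, three_block_planted


class TestStratifiedFolds:
    def test_balanced_assignment(self):
        labels = np.repeat(["a", "b", "c", "d"], 3)
        assign = hx.stratified_folds(labels, folds=3, repeats=2, seed=1)
        for r in range(2):
            for f in range(3):
                fold_labels = labels[assign[r] == f]
                assert sorted(fold_labels) == ["a", "b", "c", "d"]

    def test_deterministic_given_seed(self):
        labels = np.repeat(["a", "b"], 6)
        a1 = hx.stratified_folds(labels, 3, repeats=4, seed=9)
        a2 = hx.stratified_folds(labels, 3, repeats=4, seed=9)
        np.testing.assert_array_equal(a1, a2)
        a3 = hx.stratified_folds(labels, 3, repeats=4, seed=10)
        assert not np.array_equal(a1, a3)

    def test_folds_exceeding_class_size_rejected(self):
        labels = np.repeat(["a", "b"], 3)
        with pytest.raises(hx.ValidationError, match="folds"):
            hx.stratified_folds(labels, folds=4)


class TestBer:
    def test_forced_arithmetic(self):
        true = np.array(["A"] * 4 + ["B"] * 2, dtype=object)
        pred = true.copy()
        pred[0] = "B"   # one error among 4 A's
        pred[4] = "A"   # one error among 2 B's
        assert hx.ber(true, pred) == pytest.approx((0.25 + 0.5) / 2)

    def test_extremes(self):
        t = np.array(["A", "A", "B", "B"], dtype=object)
        assert hx.ber(t, t) == 0.0
        flipped = np.array(["B", "B", "A", "A"], dtype=object)
        assert hx.ber(t, flipped) == 1.0

    @given(st.lists(st.sampled_from(["x", "y"]), min_size=4, max_size=30))
    @settings(max_examples=50, derandomize=True)
    def test_balanced_classes_reduce_to_plain_error_rate(self, half):
        true = np.array(half + half, dtype=object)          # balanced by design
        rng = np.random.default_rng(len(half))
        pred = np.array([rng.choice(["x", "y"]) for _ in true], dtype=object)
        if len(set(true.tolist())) < 2:
            return
        nx = (true == "x").sum()
        if nx != len(true) - nx:
            return
        assert hx.ber(true, pred) == pytest.approx(float((true != pred).mean()))

    def test_absent_class_rejected(self):
        with pytest.raises(hx.ValidationError):
            hx.ber(np.array(["A", "A"], dtype=object),
                   np.array(["A", "B"], dtype=object))


class TestSelectionRules:
    @pytest.mark.parametrize("shares,expected", [
        ([0.85, 0.10, 0.05], 1),
        ([0.5, 0.25, 0.15, 0.1], 3),
    ])
    def test_variance_rule_examples(self, shares, expected):
        model = hx.fit_pca(np.random.default_rng(0).normal(size=(6, 4)), ncomp=3)
        model.explained_variance = np.array(shares)
        assert hx.select_ncomp_variance(model) == expected

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8))
    @settings(max_examples=100, derandomize=True)
    def test_variance_rule_matches_brute_force(self, raw):
        shares = np.array(raw) / np.sum(raw)
        model = hx.fit_pca(np.random.default_rng(0).normal(size=(6, 4)), ncomp=3)
        model.explained_variance = shares
        brute = next(h for h in range(1, len(shares) + 1)
                     if shares[:h].sum() >= 0.80 - 1e-12)
        assert hx.select_ncomp_variance(model) == brute

    @pytest.mark.parametrize("q2,expected", [
        ([0.3, 0.12, 0.01], 2),
        ([0.5], 1),
        ([-0.2, 0.0], 1),          # fallback
    ])
    def test_q2_rule_examples(self, q2, expected):
        assert hx.select_ncomp_q2(q2) == expected

    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=8))
    @settings(max_examples=100, derandomize=True)
    def test_q2_rule_matches_brute_force(self, q2):
        brute = max([h + 1 for h, v in enumerate(q2) if v > 0.0975], default=1)
        assert hx.select_ncomp_q2(q2) == brute

    @pytest.mark.parametrize("x,expected", [(0.87, 0.8), (0.90, 0.9),
                                            (0.999, 0.9), (0.0, 0.0), (1.0, 1.0)])
    def test_floor_tenth_examples(self, x, expected):
        assert hx.floor_tenth(x) == pytest.approx(expected)

    @given(st.floats(0, 1))
    @settings(max_examples=100, derandomize=True)
    def test_floor_tenth_matches_brute_force(self, x):
        brute = max(k / 10 for k in range(11) if k / 10 <= x + 1e-12)
        assert hx.floor_tenth(x) == pytest.approx(brute)


class TestUniqueness:
    @pytest.mark.parametrize("col,expected", [
        ([1.0, 2.0, 3.0, 4.0], 100.0),
        ([5.0, 5.0, 5.0, 5.0], 25.0),
        ([1.0, 1.0, 2.0, 2.0], 50.0),
    ])
    def test_examples(self, col, expected):
        assert hx.uniqueness_percent(col) == pytest.approx(expected)


class TestQ2:
    def test_noiseless_linear_response_gives_q2_near_one(self):
        # Y proportional to the leading principal score of X: that score is
        # the fixed point of the PLS weight equation, so one dense component
        # predicts Y exactly and Q2 of component 1 approaches 1.
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 5))
        from holomix import models as M
        Xs, *_ = M.center_scale(X)
        t1 = Xs @ np.linalg.svd(Xs)[2][0]
        Y = np.outer(t1, [1.0, -0.5])
        q2 = hx.q2_scores(X, Y, ncomp=1, folds=5, repeats=2, seed=0)
        assert q2[0] > 0.9

    def test_independent_noise_stays_below_threshold(self):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(12, 5))
            Y = rng.normal(size=(12, 4))
            vals.append(hx.q2_scores(X, Y, ncomp=1, folds=3, repeats=1,
                                     seed=seed)[0])
        assert np.mean(vals) < 0.0975

    def test_finite_and_bounded_by_one(self):
        rng = np.random.default_rng(5)
        q2 = hx.q2_scores(rng.normal(size=(12, 6)), rng.normal(size=(12, 3)),
                          ncomp=3, folds=3, repeats=2, seed=2)
        assert np.all(np.isfinite(q2)) and np.all(q2 <= 1.0)


class TestNzvRepair:
    def _failing_task(self, fail_until_removed):
        def task(dss):
            for name, ds in dss.items():
                for bad in fail_until_removed.get(name, []):
                    if bad in ds.feature_ids:
                        raise hx.TunableFailure("nzv", datasets=[name])
            return {n: d.n_features for n, d in dss.items()}
        return task

    def test_constant_column_removed_first(self):
        ds = make_dataset(n=6, p=5, name="X")
        ds.values["f3"] = 7.0  # constant -> uniqueness 1/6
        task = self._failing_task({"X": ["f3"]})
        result, log = hx.nzv_repair(task, {"X": ds})
        assert result["X"] == 4
        assert log[0]["removed_feature_ids"] == ["f3"]
        assert log[0]["uniqueness_percent"] == pytest.approx(100 / 6)

    def test_global_minimum_decides_the_dataset(self):
        X = make_dataset(n=4, p=3, name="X")
        X.values["f1"] = [1.0, 1.0, 2.0, 2.0]   # 50 %
        Y = make_dataset(n=4, p=3, seed=1, name="Y")
        Y.values["f2"] = [3.0, 3.0, 3.0, 4.0]   # 50 %... make X lower:
        X.values["f1"] = [1.0, 1.0, 1.0, 2.0]   # 50 %
        X.values["f2"] = [5.0, 5.0, 5.0, 5.0]   # 25 % -> global minimum in X
        calls = {"n": 0}

        def task(dss):
            calls["n"] += 1
            if calls["n"] == 1:
                raise hx.TunableFailure("nzv", datasets=["X", "Y"])
            return True

        _, log = hx.nzv_repair(task, {"X": X, "Y": Y})
        assert log[0]["dataset"] == "X"
        assert log[0]["removed_feature_ids"] == ["f2"]

    def test_perpetual_failure_aborts_with_log(self):
        ds = make_dataset(n=5, p=4, name="X")

        def task(dss):
            raise hx.TunableFailure("always", datasets=["X"])

        with pytest.raises(hx.RepairAborted) as exc:
            hx.nzv_repair(task, {"X": ds})
        assert len(exc.value.repair_log) >= 1

    def test_feature_counts_strictly_decrease(self):
        # distinct uniqueness per column so each iteration removes exactly one
        ds = make_dataset(n=6, p=6, name="X")
        for j, reps in enumerate(range(6)):
            col = np.arange(6, dtype=float)
            col[:reps] = -1.0  # j repeated values -> decreasing uniqueness
            ds.values[f"f{j + 1}"] = col

        def task(dss):
            if dss["X"].n_features > 3:
                raise hx.TunableFailure("nzv", datasets=["X"])
            return dss["X"].n_features

        result, log = hx.nzv_repair(task, {"X": ds})
        assert result == 3
        counts = [6] + [6 - i - 1 for i in range(len(log))]
        assert all(a > b for a, b in zip(counts, counts[1:]))
        # lowest uniqueness removed first
        assert log[0]["removed_feature_ids"] == ["f6"]

    def test_non_tunable_errors_propagate(self):
        def task(dss):
            raise ValueError("bug")
        with pytest.raises(ValueError):
            hx.nzv_repair(task, {"X": make_dataset(name="X")})


class TestTuneSplsda:
    def test_singleton_grid_returns_it(self):
        ds, labels, _ = two_class_block(seed=0, p=20, n_informative=4)
        res = hx.tune_splsda(ds, labels, ncomp_max=2, grid=[20],
                             folds=3, repeats=2, seed=0)
        assert res.selected_keep[ds.name] == [20, 20]

    def test_planted_features_recovered_with_low_ber(self):
        hits, bers = [], []
        for seed in range(5):
            ds, labels, truth = two_class_block(seed=seed)
            res = hx.tune_splsda(ds, labels, ncomp_max=1, grid=[3, 5, 8],
                                 folds=3, repeats=3, seed=seed)
            model = hx.fit_splsda(ds, labels, ncomp=1, keep=[5])
            sel = set(model.blocks[ds.name].selected_features(1))
            hits.append(len(sel & set(truth)) / len(truth))
            key = (1, res.selected_keep[ds.name][0])
            bers.append(res.criterion_surface[key])
        assert np.mean(hits) >= 0.8
        assert np.mean(bers) <= 0.1

    def test_surface_is_deterministic(self):
        ds, labels, _ = two_class_block(seed=1, p=20, n_informative=4)
        r1 = hx.tune_splsda(ds, labels, 1, grid=[2, 4], folds=3, repeats=2, seed=5)
        r2 = hx.tune_splsda(ds, labels, 1, grid=[2, 4], folds=3, repeats=2, seed=5)
        assert r1.criterion_surface == r2.criterion_surface
        assert r1.selected_keep == r2.selected_keep


class TestTuneSplsKeep:
    def test_singleton_grids_selected(self):
        rng = np.random.default_rng(2)
        X = make_dataset(n=12, p=8, seed=1, name="X")
        Y = make_dataset(n=12, p=6, seed=2, name="Y")
        res = hx.tune_spls_keep(X, Y, ncomp=1, gridX=[4], gridY=[3],
                                folds=3, repeats=2, seed=0)
        assert res.selected_keep == {"X": [4], "Y": [3]}

    def test_planted_pair_inside_selected_support(self):
        rng = np.random.default_rng(8)
        n = 30  # large enough that chance correlations stay well below rho
        z = rng.normal(size=n)
        Xv = rng.normal(size=(n, 10)); Yv = rng.normal(size=(n, 8))
        Xv[:, 2] = z + 0.1 * rng.normal(size=n)
        Yv[:, 6] = z + 0.1 * rng.normal(size=n)
        X = hx.OmicsDataset("X", pd.DataFrame(
            Xv, index=[f"s{i}" for i in range(n)],
            columns=[f"x{j}" for j in range(10)]))
        Y = hx.OmicsDataset("Y", pd.DataFrame(
            Yv, index=X.sample_ids, columns=[f"y{j}" for j in range(8)]))
        res = hx.tune_spls_keep(X, Y, ncomp=1, gridX=[1, 3], gridY=[1, 3],
                                folds=3, repeats=2, seed=1)
        model = hx.fit_spls(X, Y, ncomp=1,
                            keepX=res.selected_keep["X"],
                            keepY=res.selected_keep["Y"])
        assert "x2" in model.blocks["X"].selected_features()
        assert "y6" in model.blocks["Y"].selected_features()


class TestTuneSpcaKeep:
    def test_singleton_grid_selected(self):
        ds = make_dataset(n=10, p=8, seed=4, name="pc")
        res = hx.tune_spca_keep(ds, ncomp=2, grid=[3], folds=3, repeats=2,
                                seed=0)
        assert res.selected_keep["pc"] == [3, 3]
        assert res.criterion == "score_correlation"

    def test_selected_support_aligns_with_planted_axis(self):
        """Whatever sparsity the CV score-correlation criterion picks, the
        component-1 support tracks the planted axis: a small keep selects
        only planted features (high precision), a large keep covers them
        all (high recall)."""
        for seed in (0, 1, 2, 6):
            ds, _, truth = two_class_block(seed=seed)
            res = hx.tune_spca_keep(ds, ncomp=1, grid=[2, 5, 10], folds=3,
                                    repeats=2, seed=seed)
            model = hx.fit_spca(ds, ncomp=1, keep=res.selected_keep[ds.name])
            sel = set(model.blocks[ds.name].selected_features(1))
            planted = set(truth)
            precision = len(sel & planted) / len(sel)
            recall = len(sel & planted) / len(planted)
            assert max(precision, recall) >= 0.8, (seed, precision, recall)


class TestDesignMatrix:
    def test_identical_blocks_correlate_perfectly(self):
        ds = make_dataset(n=10, p=6, seed=3, name="a")
        twin = hx.OmicsDataset("b", ds.values.copy())
        design = hx.data_driven_design({"a": ds, "b": twin})
        assert design.raw_minimum == pytest.approx(1.0, abs=1e-9)
        assert design.values[0, 1] == pytest.approx(1.0)

    def test_minimum_over_pairs_fills_matrix(self):
        blocks, labels, _ = three_block_planted(seed=2)
        design = hx.data_driven_design(blocks)
        off = design.values[~np.eye(3, dtype=bool)]
        assert len(set(np.round(off, 12))) == 1
        assert design.values[0, 1] == hx.floor_tenth(design.raw_minimum)

    def test_validation(self):
        with pytest.raises(hx.ValidationError):
            hx.DesignMatrix(["a", "b"], np.array([[0.0, 1.2], [1.2, 0.0]]))
        with pytest.raises(hx.ValidationError):
            hx.DesignMatrix(["a", "b"], np.array([[0.0, 0.5], [0.4, 0.0]]))


class TestTuneDiablo:
    def test_singleton_grids_returned(self):
        blocks, labels, _ = three_block_planted(seed=1)
        res = hx.tune_diablo(blocks, labels, ncomp_max=1,
                             grids={n: [4] for n in blocks},
                             folds=3, repeats=1, seed=0, design=None)
        for n in blocks:
            assert res.selected_keep[n][:res.selected_ncomp] == [4]

    def test_planted_recovery_and_ber(self):
        hits, bers = [], []
        for seed in range(3):
            blocks, labels, truth = three_block_planted(seed=seed)
            design = hx.DesignMatrix.uniform(list(blocks), 0.5)
            res = hx.tune_diablo(blocks, labels, ncomp_max=2,
                                 grids={n: [2, 4, 8] for n in blocks},
                                 folds=3, repeats=2, seed=seed, design=design)
            model = hx.fit_diablo(blocks, labels, ncomp=res.selected_ncomp,
                                  design=design,
                                  keep={n: [4] * res.selected_ncomp
                                        for n in blocks})
            assert res.selected_ncomp >= 1
            rec = []
            for n in blocks:
                sel = set(model.blocks[n].selected_features())
                rec.append(len(sel & set(truth[n])) / len(truth[n]))
            hits.append(np.mean(rec))
            # CV BER of the sparse model at the matched grid point
            bers.append(S.cv_ber_diablo(
                blocks, labels, {n: [4] * res.selected_ncomp for n in blocks},
                res.selected_ncomp, design, folds=3, repeats=2, seed=seed))
        assert np.mean(hits) >= 0.8
        assert np.mean(bers) <= 0.1


class TestReduceDataset:
    def test_full_keep_is_identity(self):
        ds, labels, _ = two_class_block(seed=0, p=15, n_informative=3)
        model = hx.fit_splsda(ds, labels, ncomp=1, keep=[15])
        red = hx.reduce_dataset(ds, model)
        assert red.feature_ids == ds.feature_ids

    def test_union_over_components_preserves_order(self):
        ds, labels, _ = two_class_block(seed=1, p=15, n_informative=3)
        model = hx.fit_splsda(ds, labels, ncomp=2, keep=[2, 2])
        red = hx.reduce_dataset(ds, model)
        expect = model.blocks[ds.name].selected_features(2)
        assert red.feature_ids == [f for f in ds.feature_ids if f in set(expect)]
        assert 2 <= red.n_features <= 4
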