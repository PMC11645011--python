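"""Reference interpolation, BP categories, splits, training, size budget."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scalebp.errors import BudgetError, CalibrationError, ScalebpError
from scalebp.model import (
    FEATURE_COLUMNS,
    GBTHyperparams,
    REPORTED_CATEGORY_COUNTS,
    categorize_bp,
    cross_validate,
    estimate_size,
    interpolate_reference,
    max_trees_under_budget,
    stratified_split,
    train,
)
from scalebp.session import CuffReading


def synthetic_rows(n=2000, noise_sd=2.0, seed=0):
    """Monotone PTT -> BP rows spanning all four categories."""
    rng = np.random.default_rng(seed)
    sbp = rng.uniform(95.0, 165.0, n)
    dbp = sbp - rng.uniform(30.0, 45.0, n)
    ptt = 50.0 + 12000.0 / sbp + rng.normal(0, 1.0, n)
    df = pd.DataFrame({
        "ptt_free": ptt,
        "ptt_sys": ptt / 120.0,
        "ptt_dia": ptt / 80.0,
        "ref_sbp": sbp + rng.normal(0, noise_sd, n),
        "ref_dbp": dbp + rng.normal(0, noise_sd, n),
        "subject_id": "syn",
        "segment_start": np.arange(n) * 512,
    })
    df["category"] = [categorize_bp(s, d)
                      for s, d in zip(df.ref_sbp, df.ref_dbp)]
    return df


class TestInterpolateReference:
    def test_midpoint(self):
        cuff = [CuffReading(0, 140, 90), CuffReading(60, 120, 80)]
        sbp, dbp = interpolate_reference(cuff, [30.0])
        assert sbp[0] == 130.0 and dbp[0] == 85.0

    def test_at_reading_time_exact(self):
        cuff = [CuffReading(0, 140, 90), CuffReading(60, 120, 80)]
        sbp, dbp = interpolate_reference(cuff, [60.0])
        assert sbp[0] == 120.0 and dbp[0] == 80.0

    def test_outside_span_clamped(self):
        cuff = [CuffReading(10, 140, 90), CuffReading(60, 120, 80)]
        sbp, _ = interpolate_reference(cuff, [0.0, 99.0])
        assert sbp.tolist() == [140.0, 120.0]

    def test_single_reading_rejected(self):
        with pytest.raises(CalibrationError):
            interpolate_reference([CuffReading(0, 120, 80)], [1.0])


class TestCategorize:
    @pytest.mark.parametrize("sbp,dbp,expect", [
        (118, 78, "normal"),
        (125, 75, "prehypertension"),
        (141, 70, "stage2"),
        (135, 70, "stage1"),
        (124, 82, "stage1"),      # DBP pulls an SBP-pre hypertensive row up
        (140, 70, "stage2"),      # boundary closure at exactly 140
        (110, 90, "stage2"),      # boundary closure at exactly 90
        (139, 89, "stage1"),
        (119.9, 79.9, "normal"),
    ])
    def test_examples(self, sbp, dbp, expect):
        assert categorize_bp(sbp, dbp) == expect

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(sbp=st.floats(60, 250, allow_nan=False),
           dbp=st.floats(30, 150, allow_nan=False))
    def test_total_function(self, sbp, dbp):
        assert categorize_bp(sbp, dbp) in (
            "normal", "prehypertension", "stage1", "stage2")


class TestStratifiedSplit:
    def test_ten_rows_gives_8_2(self):
        df = synthetic_rows(200, seed=1)
        sub = df[df.category == df.category.iloc[0]].head(10)
        tr, te = stratified_split(sub, seed=0)
        assert len(tr) == 8 and len(te) == 2

    def test_reported_category_sizes_give_expected_test_counts(self):
        # round(0.2 n) per category for the original recordings' category sizes
        sizes = REPORTED_CATEGORY_COUNTS
        expected = {"normal": 119, "prehypertension": 36,
                    "stage1": 118, "stage2": 179}
        rows = []
        for cat, n in sizes.items():
            for _ in range(n):
                rows.append({"category": cat})
        df = pd.DataFrame(rows)
        tr, te = stratified_split(df, seed=3)
        got = te.category.value_counts().to_dict()
        assert got == expected

    def test_partition_and_reproducibility(self):
        df = synthetic_rows(500, seed=2)
        tr1, te1 = stratified_split(df, seed=9)
        tr2, te2 = stratified_split(df, seed=9)
        assert set(tr1.index) | set(te1.index) == set(df.index)
        assert set(tr1.index) & set(te1.index) == set()
        assert tr1.index.tolist() == tr2.index.tolist()
        for cat in df.category.unique():
            n = (df.category == cat).sum()
            n_te = (te1.category == cat).sum()
            assert abs(n_te - 0.2 * n) <= 0.5 + 1e-9


class TestTrain:
    def test_constant_target_predicts_constant(self):
        df = synthetic_rows(50, seed=3)
        with pytest.warns(UserWarning, match="zero-variance"):
            m = train(df, np.full(50, 97.0), GBTHyperparams(n_estimators=5))
        pred = m.predict(df[FEATURE_COLUMNS].to_numpy()[:10])
        assert np.allclose(pred, 97.0, atol=1e-6)

    def test_single_stump_two_values(self):
        df = synthetic_rows(200, seed=4)
        hp = GBTHyperparams(n_estimators=1, max_depth=1)
        m = train(df, df.ref_sbp.to_numpy(), hp)
        assert len(m.trees) == 1 and m.max_depth_actual() <= 1
        pred = m.predict(df[FEATURE_COLUMNS].to_numpy())
        assert len(np.unique(np.round(pred, 9))) <= 2

    def test_monotone_synthetic_recovery(self):
        df = synthetic_rows(2000, noise_sd=2.0, seed=5)
        tr, te = stratified_split(df, seed=5)
        m = train(tr, tr.ref_sbp.to_numpy(), GBTHyperparams(), seed=5)
        pred = m.predict(te[FEATURE_COLUMNS].to_numpy())
        from scalebp.metrics import pcc
        assert pcc(te.ref_sbp.to_numpy(), pred) >= 0.9

    def test_hyperparams_honored(self):
        df = synthetic_rows(300, seed=6)
        hp = GBTHyperparams(n_estimators=7, max_depth=3)
        m = train(df, df.ref_sbp.to_numpy(), hp)
        assert len(m.trees) == 7
        assert m.max_depth_actual() <= 3

    def test_prediction_is_base_plus_leaf_sum(self, rng):
        # audit: scalar tree walk vs the vectorized predict
        df = synthetic_rows(300, seed=7)
        m = train(df, df.ref_sbp.to_numpy(), GBTHyperparams(n_estimators=10))

        def walk(node, x):
            while "value" not in node:
                node = (node["left"] if x[node["feature"]] < node["threshold"]
                        else node["right"])
            return node["value"]

        X = rng.normal(150, 30, size=(100, 3))
        expect = np.array([m.base_score + sum(walk(t, x) for t in m.trees)
                           for x in X])
        assert np.allclose(m.predict(X), expect, rtol=0, atol=1e-9)

    def test_matches_booster_predictions(self):
        import xgboost as xgb
        df = synthetic_rows(400, seed=8)
        X = df[FEATURE_COLUMNS].to_numpy()
        y = df.ref_sbp.to_numpy()
        hp = GBTHyperparams(n_estimators=20)
        m = train(df, y, hp, seed=0)
        booster = xgb.train({
            "objective": "reg:squarederror", "eta": hp.learning_rate,
            "max_depth": hp.max_depth, "base_score": float(np.mean(y)),
            "seed": 0, "nthread": 1, "tree_method": "exact", "lambda": 1.0,
        }, xgb.DMatrix(X, label=y), num_boost_round=hp.n_estimators)
        # evaluate off the training grid: training rows sit exactly on split
        # thresholds, where float32 (booster) and float64 (IR) comparisons
        # can legitimately route differently
        rng = np.random.default_rng(1)
        Xq = X + rng.normal(0, 0.01, X.shape)
        ours = m.predict(Xq)
        theirs = booster.predict(xgb.DMatrix(Xq))
        assert np.max(np.abs(ours - theirs) / np.abs(theirs)) < 1e-4

    def test_serialization_round_trip(self):
        from scalebp.model import GBTModel
        df = synthetic_rows(100, seed=9)
        m = train(df, df.ref_sbp.to_numpy(), GBTHyperparams(n_estimators=3))
        m2 = GBTModel.from_json(m.to_json())
        X = df[FEATURE_COLUMNS].to_numpy()
        assert np.array_equal(m.predict(X), m2.predict(X))


class TestCrossValidate:
    def test_linear_data_perfect_folds(self):
        # the feature takes repeated discrete values, so tree leaves can
        # represent the linear map exactly once boosting has converged
        rng = np.random.default_rng(0)
        n = 400
        ptt = rng.choice(np.linspace(100, 250, 20), n)
        df = pd.DataFrame({
            "ptt_free": ptt, "ptt_sys": ptt / 120, "ptt_dia": ptt / 80,
            "ref_sbp": 2.0 * ptt - 50.0, "ref_dbp": 2.0 * ptt - 50.0,
            "category": np.where(np.arange(n) % 2 == 0, "normal", "stage2"),
        })
        hp = GBTHyperparams(learning_rate=0.3, max_depth=6, n_estimators=200)
        out = cross_validate(df, "sbp", hp, k=3)
        assert all(p > 1 - 1e-6 for p in out["pcc_folds"])

    def test_same_seed_same_folds(self):
        df = synthetic_rows(300, seed=11)
        a = cross_validate(df, "sbp", GBTHyperparams(n_estimators=5), seed=4)
        b = cross_validate(df, "sbp", GBTHyperparams(n_estimators=5), seed=4)
        assert a["pcc_folds"] == b["pcc_folds"]

    def test_row_order_invariant(self):
        df = synthetic_rows(300, seed=12)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = cross_validate(df, "dbp", GBTHyperparams(n_estimators=5), seed=4)
        b = cross_validate(shuffled, "dbp", GBTHyperparams(n_estimators=5), seed=4)
        assert a["pcc_mean"] == pytest.approx(b["pcc_mean"], abs=0.05)

    def test_pure_noise_near_zero_pcc(self):
        rng = np.random.default_rng(3)
        df = synthetic_rows(2000, seed=13)
        df["ref_sbp"] = rng.normal(130, 10, len(df))  # decouple the target
        out = cross_validate(df, "sbp", GBTHyperparams(n_estimators=20), seed=1)
        assert abs(out["pcc_mean"]) < 0.1


class TestSizeAndBudget:
    def test_empty_ensemble_base_cost(self):
        from scalebp.model import BASE_COST_BYTES, GBTModel
        m = GBTModel("sbp", [], 100.0, GBTHyperparams())
        assert estimate_size(m) == BASE_COST_BYTES

    def test_single_stump_cost(self):
        from scalebp.model import BASE_COST_BYTES, GBTModel
        stump = {"feature": 0, "threshold": 1.0,
                 "left": {"value": 1.0}, "right": {"value": 2.0}}
        m = GBTModel("sbp", [stump], 100.0, GBTHyperparams())
        # one internal record (4 quantities) + 2 leaves, 4 bytes each
        assert estimate_size(m) == BASE_COST_BYTES + 24

    def test_size_monotone_in_trees(self):
        df = synthetic_rows(400, seed=14)
        sizes = []
        for n in (10, 20, 30, 40, 50):
            m = train(df, df.ref_sbp.to_numpy(),
                      GBTHyperparams(n_estimators=n), seed=0)
            sizes.append(estimate_size(m))
        assert all(a < b for a, b in zip(sizes, sizes[1:]))

    def test_budget_selection_boundary(self):
        df = synthetic_rows(300, seed=15)
        candidates = (5, 10, 15)
        sel_all = max_trees_under_budget(
            df, GBTHyperparams(), budget_bytes=10**9,
            candidates=candidates, cv_folds=2, seed=0)
        assert sel_all.chosen_n_estimators == 15
        table = sel_all.table.set_index("n_estimators")
        # budget between the 10- and 15-tree totals picks exactly 10
        mid = int((table.loc[10, "total_size_bytes"]
                   + table.loc[15, "total_size_bytes"]) // 2)
        sel_mid = max_trees_under_budget(
            df, GBTHyperparams(), budget_bytes=mid,
            candidates=candidates, cv_folds=2, seed=0)
        assert sel_mid.chosen_n_estimators == 10

    def test_budget_too_small_raises(self):
        df = synthetic_rows(300, seed=16)
        with pytest.raises(BudgetError):
            max_trees_under_budget(df, GBTHyperparams(), budget_bytes=10,
                                   candidates=(5,), cv_folds=2, seed=0)
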