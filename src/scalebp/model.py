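"""Blood-pressure regression: feature table, splits, boosted trees, budget.

The model maps three per-segment features — calibration-free mean PTT and
the calibration-based PTT_SYS / PTT_DIA ratios — to SBP or DBP.  Reference
pressures are linearly interpolated between the per-minute cuff readings and
averaged over the beats of a segment; rows are categorized on the IEEE
cuffless-device scale (normal / prehypertension / stage 1 / stage 2) and all
splits are stratified by that category (4:1 train:test, or k-fold CV).

Training uses gradient-boosted regression trees (squared error) via xgboost
with the reference deployment's hyperparameters (learning rate 0.0497,
depth 12, 100 trees)
as defaults.  The fitted booster is parsed into the package's own tree IR —
a nested dict per tree with ``feature``/``threshold``/``left``/``right``
internal nodes and ``value`` leaves — which backs prediction, the flash-size
estimate, and the embedded-source exporter.  A prediction is the base score
plus one leaf value per tree.

The flash-size estimate charges 4 bytes per stored quantity (an internal
node stores a feature id, a threshold and two branch references; a leaf
stores one value) plus a small fixed base.  It is a monotone, order-of-
magnitude estimate of the exported source's footprint, not any compiler's
output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from . import metrics
from .errors import BudgetError, CalibrationError, ScalebpError
from .session import CuffReading

FEATURE_COLUMNS = ["ptt_free", "ptt_sys", "ptt_dia"]
CATEGORIES = ["normal", "prehypertension", "stage1", "stage2"]

#: Per-category sample counts of the original scale recordings this
#: package reimplements
#: (normal, prehypertension, stage 1, stage 2) — used for bookkeeping checks.
REPORTED_CATEGORY_COUNTS = {
    "normal": 597, "prehypertension": 182, "stage1": 590, "stage2": 893,
}


def interpolate_reference(
    cuff: Sequence[CuffReading], beat_times: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat reference BP by piecewise-linear interpolation of cuff readings.

    SBP and DBP are interpolated independently; beat times outside the
    reading span are clamped to the nearest reading.
    """
    if len(cuff) < 2:
        raise CalibrationError("need at least 2 cuff readings to interpolate")
    t = np.asarray([r.t for r in cuff])
    beat_times = np.asarray(beat_times, dtype=float)
    sbp = np.interp(beat_times, t, [r.sbp for r in cuff])
    dbp = np.interp(beat_times, t, [r.dbp for r in cuff])
    return sbp, dbp


def categorize_bp(sbp: float, dbp: float) -> str:
    """IEEE-scale BP category, evaluated stage2 -> stage1 -> pre -> normal.

    Boundary closure: stage 2 at SBP >= 140 or DBP >= 90; stage 1 at SBP
    130-139 or DBP 80-89; prehypertension at SBP 120-129 with DBP < 80.
    Every positive input lands in exactly one category.
    """
    if sbp >= 140 or dbp >= 90:
        return "stage2"
    if 130 <= sbp or 80 <= dbp:
        return "stage1"
    if 120 <= sbp:
        return "prehypertension"
    return "normal"


def stratified_split(
    rows: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category 4:1 split: round(test_fraction * n) rows to test.

    Sampling is without replacement under the seed; empty categories are
    skipped with a warning.  Train and test are disjoint and exhaustive.
    """
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    for cat in CATEGORIES:
        idx = rows.index[rows["category"] == cat].to_numpy()
        if len(idx) == 0:
            warnings.warn(f"category {cat!r} empty; skipped in stratification")
            continue
        n_test = int(round(test_fraction * len(idx)))
        test_idx.append(rng.choice(idx, size=n_test, replace=False))
    test_all = np.concatenate(test_idx) if test_idx else np.array([], dtype=int)
    mask = rows.index.isin(test_all)
    return rows.loc[~mask].copy(), rows.loc[mask].copy()


@dataclass(frozen=True)
class GBTHyperparams:
    learning_rate: float = 0.0497
    max_depth: int = 12
    n_estimators: int = 100

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_depth < 1 or self.n_estimators < 1:
            raise ScalebpError(f"invalid hyperparameters {self}")


def _parse_xgb_node(node: dict) -> dict:
    if "leaf" in node:
        return {"value": float(node["leaf"])}
    feature = int(str(node["split"]).lstrip("f"))
    yes, no = node["yes"], node["no"]
    kids = {c["nodeid"]: c for c in node["children"]}
    return {
        "feature": feature,
        "threshold": float(node["split_condition"]),
        "left": _parse_xgb_node(kids[yes]),   # feature < threshold
        "right": _parse_xgb_node(kids[no]),   # ties and >= go right
    }


@dataclass
class GBTModel:
    """Boosted regression ensemble in the package's own tree IR."""

    target: str                      # "sbp" | "dbp"
    trees: list[dict]
    base_score: float
    hyperparams: GBTHyperparams
    n_features: int = 3

    def predict(self, X: np.ndarray) -> np.ndarray:
        """base_score + sum of one leaf per tree, vectorized over rows."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.full(len(X), self.base_score)
        for tree in self.trees:
            out += _eval_tree(tree, X)
        return out

    def node_count(self) -> int:
        return sum(_count_nodes(t) for t in self.trees)

    def max_depth_actual(self) -> int:
        return max((_depth(t) for t in self.trees), default=0)

    def to_json(self) -> str:
        return json.dumps({
            "target": self.target, "base_score": self.base_score,
            "n_features": self.n_features,
            "hyperparams": vars(self.hyperparams), "trees": self.trees,
        })

    @classmethod
    def from_json(cls, text: str) -> "GBTModel":
        d = json.loads(text)
        return cls(target=d["target"], trees=d["trees"],
                   base_score=d["base_score"],
                   hyperparams=GBTHyperparams(**d["hyperparams"]),
                   n_features=d.get("n_features", 3))


def _eval_tree(node: dict, X: np.ndarray) -> np.ndarray:
    if "value" in node:
        return np.full(len(X), node["value"])
    out = np.empty(len(X))
    mask = X[:, node["feature"]] < node["threshold"]
    if mask.any():
        out[mask] = _eval_tree(node["left"], X[mask])
    if (~mask).any():
        out[~mask] = _eval_tree(node["right"], X[~mask])
    return out


def _count_nodes(node: dict) -> int:
    if "value" in node:
        return 1
    return 1 + _count_nodes(node["left"]) + _count_nodes(node["right"])


def _depth(node: dict) -> int:
    if "value" in node:
        return 0
    return 1 + max(_depth(node["left"]), _depth(node["right"]))


def train(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    hp: GBTHyperparams = GBTHyperparams(),
    seed: int = 0,
    target: str = "sbp",
) -> GBTModel:
    """Fit a squared-error boosted ensemble honoring ``hp`` exactly.

    base_score is the training-target mean; the booster's trees are parsed
    into the package IR.  Deterministic for a fixed seed on one thread.
    """
    if isinstance(X, pd.DataFrame):
        X = X[FEATURE_COLUMNS].to_numpy()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) < 10:
        raise ScalebpError(f"need at least 10 training rows, got {len(X)}")
    base = float(np.mean(y))
    if np.var(y) == 0:
        warnings.warn("degenerate zero-variance target; model predicts the constant")
    dtrain = xgb.DMatrix(X, label=y,
                         feature_names=[f"f{i}" for i in range(X.shape[1])])
    params = {
        "objective": "reg:squarederror",
        "eta": hp.learning_rate,
        "max_depth": hp.max_depth,
        "base_score": base,
        "seed": seed,
        "nthread": 1,
        "tree_method": "exact",
        "lambda": 1.0,
    }
    booster = xgb.train(params, dtrain, num_boost_round=hp.n_estimators)
    dump = booster.get_dump(dump_format="json")
    trees = [_parse_xgb_node(json.loads(t)) for t in dump]
    return GBTModel(target=target, trees=trees, base_score=base,
                    hyperparams=hp, n_features=X.shape[1])


def cross_validate(
    rows: pd.DataFrame,
    target: str,
    hp: GBTHyperparams = GBTHyperparams(),
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Category-stratified k-fold CV; per-fold PCC and MAE, mean +/- sd.

    A fold whose predictions have zero variance gets a missing (NaN) PCC.
    """
    if k < 2 or len(rows) < k:
        raise ScalebpError(f"need k >= 2 and at least k rows, got k={k}, n={len(rows)}")
    ycol = {"sbp": "ref_sbp", "dbp": "ref_dbp"}[target]
    X = rows[FEATURE_COLUMNS].to_numpy()
    y = rows[ycol].to_numpy()
    cats = rows["category"].to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pccs, maes = [], []
    for tr, te in skf.split(X, cats):
        model = train(X[tr], y[tr], hp, seed=seed, target=target)
        pred = model.predict(X[te])
        try:
            pccs.append(metrics.pcc(y[te], pred))
        except ScalebpError:
            pccs.append(float("nan"))
        maes.append(metrics.mae(y[te], pred)[0])
    pccs_a, maes_a = np.asarray(pccs), np.asarray(maes)
    return {
        "pcc_folds": pccs, "mae_folds": maes,
        "pcc_mean": float(np.nanmean(pccs_a)),
        "pcc_sd": float(np.nanstd(pccs_a, ddof=1)),
        "mae_mean": float(np.mean(maes_a)),
        "mae_sd": float(np.std(maes_a, ddof=1)),
    }


BYTES_PER_QUANTITY = 4
INTERNAL_NODE_QUANTITIES = 4   # feature id, threshold, two branch references
LEAF_QUANTITIES = 1
BASE_COST_BYTES = 8            # base score + tree count


def estimate_size(model: GBTModel) -> int:
    """Flash-footprint estimate of the exported model, in bytes."""
    total = BASE_COST_BYTES
    for tree in model.trees:
        n_total = _count_nodes(tree)
        n_leaves = _count_leaves(tree)
        n_internal = n_total - n_leaves
        total += BYTES_PER_QUANTITY * (
            INTERNAL_NODE_QUANTITIES * n_internal + LEAF_QUANTITIES * n_leaves)
    return total


def _count_leaves(node: dict) -> int:
    if "value" in node:
        return 1
    return _count_leaves(node["left"]) + _count_leaves(node["right"])


@dataclass
class BudgetSelection:
    """Outcome of the tree-count search under a joint flash budget."""

    chosen_n_estimators: int
    budget_bytes: int
    table: pd.DataFrame  # per candidate: sizes, CV PCC and MAE for both targets
    sbp_model: GBTModel
    dbp_model: GBTModel


def max_trees_under_budget(
    rows: pd.DataFrame,
    hp: GBTHyperparams = GBTHyperparams(),
    budget_bytes: int = 1_000_000,
    candidates: Sequence[int] = (50, 60, 70, 80, 90, 100),
    seed: int = 0,
    cv_folds: int = 5,
) -> BudgetSelection:
    """Largest candidate tree count whose SBP + DBP models jointly fit flash.

    Mirrors the embedded workflow: evaluate candidates by stratified CV
    (PCC and MAE per candidate), estimate both models' flash sizes, and keep
    the largest candidate that fits the budget (default 1 MB, the target
    board's flash).  Raises :class:`BudgetError` when none fits.
    """
    records = []
    fitted: dict[int, tuple[GBTModel, GBTModel]] = {}
    for n in sorted(candidates):
        hp_n = GBTHyperparams(hp.learning_rate, hp.max_depth, int(n))
        sbp_m = train(rows, rows["ref_sbp"].to_numpy(), hp_n, seed, "sbp")
        dbp_m = train(rows, rows["ref_dbp"].to_numpy(), hp_n, seed, "dbp")
        fitted[int(n)] = (sbp_m, dbp_m)
        records.append({
            "n_estimators": int(n),
            "sbp_size_bytes": estimate_size(sbp_m),
            "dbp_size_bytes": estimate_size(dbp_m),
        })
    table = pd.DataFrame.from_records(records)
    table["total_size_bytes"] = table["sbp_size_bytes"] + table["dbp_size_bytes"]
    fits = table[table["total_size_bytes"] <= budget_bytes]
    if fits.empty:
        smallest = int(table["total_size_bytes"].min())
        raise BudgetError(
            f"no candidate fits {budget_bytes} bytes; smallest is {smallest}")
    for rec in records:
        hp_n = GBTHyperparams(hp.learning_rate, hp.max_depth, rec["n_estimators"])
        cv_s = cross_validate(rows, "sbp", hp_n, cv_folds, seed)
        cv_d = cross_validate(rows, "dbp", hp_n, cv_folds, seed)
        rec.update({
            "sbp_pcc": cv_s["pcc_mean"], "sbp_pcc_sd": cv_s["pcc_sd"],
            "dbp_pcc": cv_d["pcc_mean"], "dbp_pcc_sd": cv_d["pcc_sd"],
            "sbp_mae": cv_s["mae_mean"], "sbp_mae_sd": cv_s["mae_sd"],
            "dbp_mae": cv_d["mae_mean"], "dbp_mae_sd": cv_d["mae_sd"],
        })
    table = pd.DataFrame.from_records(records)
    table["total_size_bytes"] = table["sbp_size_bytes"] + table["dbp_size_bytes"]
    chosen = int(fits["n_estimators"].max())
    sbp_m, dbp_m = fitted[chosen]
    return BudgetSelection(chosen_n_estimators=chosen, budget_bytes=budget_bytes,
                           table=table, sbp_model=sbp_m, dbp_model=dbp_m)


def build_feature_table(
    records: Sequence[dict],
) -> pd.DataFrame:
    """Assemble labeled feature rows from per-segment extraction records.

    Each record needs ``ptt_free``/``ptt_sys``/``ptt_dia``, the absolute beat
    times of the segment, the session's cuff readings, subject id and
    segment start.  The segment reference BP is the mean of the per-beat
    interpolated references; the category follows from that reference.
    """
    rows = []
    for rec in records:
        sbp_b, dbp_b = interpolate_reference(rec["cuff_readings"],
                                             rec["beat_times"])
        ref_sbp = float(np.mean(sbp_b))
        ref_dbp = float(np.mean(dbp_b))
        rows.append({
            "ptt_free": rec["ptt_free"], "ptt_sys": rec["ptt_sys"],
            "ptt_dia": rec["ptt_dia"], "ref_sbp": ref_sbp, "ref_dbp": ref_dbp,
            "category": categorize_bp(ref_sbp, ref_dbp),
            "subject_id": rec["subject_id"],
            "segment_start": rec["segment_start"],
        })
    return pd.DataFrame(rows)
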