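"""Reusable simulation experiments exercising the whole pipeline.

These drivers generate synthetic sessions with known ground truth, push them
through the real extraction / modeling / export code paths, and measure how
well each stage recovers what the generator buried in the signals.  They
back both the acceptance tests and the reproduction script, so the numbers
those report are always recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import model as bp_model
from .fiducials import DEFAULT_PARAMS, ExtractionParams, extract_features
from .filters import segment_session
from .model import GBTHyperparams, GBTModel, build_feature_table, stratified_split, train
from .session import BiosignalSession
from .simulate import CohortSubject, SimulationConfig, make_cohort, simulate_session


def extract_session_records(
    session: BiosignalSession,
    params: ExtractionParams = DEFAULT_PARAMS,
    window: int = 1024,
    hop: int = 512,
) -> list[dict]:
    """Per-segment extraction over a whole session (quality-passing only).

    Each record carries the three features, the absolute beat sample indices
    and times, and the session's cuff readings — everything needed to label
    the row against interpolated reference BP.
    """
    records = []
    for seg in segment_session(session, window, hop):
        feats = extract_features(seg, session.calibration, params)
        if not feats.quality_ok:
            continue
        beat_idx = feats.beat_indices + seg.start_index
        records.append({
            "ptt_free": feats.ptt_free,
            "ptt_sys": feats.ptt_sys,
            "ptt_dia": feats.ptt_dia,
            "ptt_per_beat": feats.ptt_ms,
            "n_beats": feats.n_beats,
            "beat_times": beat_idx / session.fs,
            "beat_indices": beat_idx,
            "cuff_readings": session.cuff_readings,
            "subject_id": session.subject_id,
            "segment_start": seg.start_index,
        })
    return records


def ptt_recovery(
    n_sessions: int = 50,
    noise_sd: float = 0.0,
    tol_samples: int = 1,
    seed: int = 0,
    duration_s: float = 20.0,
    params: ExtractionParams = DEFAULT_PARAMS,
) -> dict:
    """Fraction of ground-truth beats whose PTT is recovered within tolerance.

    Sessions have constant heart rate drawn from 60-90 BPM and constant BP
    with the PTT offset tuned so the true PTT is uniform in 120-220 ms.
    Beats are matched to ground truth by nearest dIPG-peak index; a truth
    beat counts as recovered when some detected beat lies within half a
    cycle of it and its PTT errs by at most ``tol_samples`` samples.  Beats
    whose wavelets touch the session edges are excluded (interior beats).
    """
    rng = np.random.default_rng(seed)
    n_recovered = 0
    n_truth = 0
    fs = 500.0
    for _ in range(n_sessions):
        hr = float(rng.uniform(60.0, 90.0))
        ptt_target = float(rng.uniform(120.0, 220.0))
        cfg = SimulationConfig(
            duration_s=duration_s, fs=fs, hr_start=hr, hr_end=hr, hrv_sd=1.0,
            ptt_a_ms=ptt_target - 12000.0 / 120.0, ptt_b=12000.0,
            bp_start=(120.0 + 1e-6, 80.0), bp_end=(120.0, 80.0),
            noise_sd=noise_sd, drift_amp=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        session, truth = simulate_session(cfg)
        recs = extract_session_records(session, params)
        pairs_idx, pairs_ptt = [], []
        for seg_rec in recs:
            for bi, pt in zip(seg_rec["beat_indices"], seg_rec["ptt_per_beat"]):
                pairs_idx.append(bi)
                pairs_ptt.append(pt)
        pairs_idx = np.asarray(pairs_idx)
        pairs_ptt = np.asarray(pairs_ptt)

        cycle = 60.0 / hr * fs
        interior = (truth.j_wave_idx > cycle) & (
            truth.dipg_peak_idx < session.n_samples - cycle)
        for dp_true, ptt_true in zip(truth.dipg_peak_idx[interior],
                                     truth.true_ptt_ms[interior]):
            n_truth += 1
            if len(pairs_idx) == 0:
                continue
            near = np.abs(pairs_idx - dp_true) <= cycle / 2
            if not near.any():
                continue
            err_samples = np.abs(pairs_ptt[near] - ptt_true) * fs / 1000.0
            if np.min(err_samples) <= tol_samples + 1e-9:
                n_recovered += 1
    return {
        "fraction_recovered": n_recovered / n_truth if n_truth else 0.0,
        "n_truth_beats": n_truth,
        "n_recovered": n_recovered,
    }


def cohort_feature_table(
    cohort: list[CohortSubject],
    params: ExtractionParams = DEFAULT_PARAMS,
    label_noise_sd: float = 0.0,
    noise_seed: int = 0,
) -> pd.DataFrame:
    """Pooled labeled feature table for a cohort, via the real pipeline.

    ``label_noise_sd`` perturbs the cuff readings (mmHg) before the
    reference interpolation, emulating cuff measurement error without
    touching the signals, so noise sweeps can reuse one extraction pass.
    """
    rng = np.random.default_rng(noise_seed)
    records = []
    for subject in cohort:
        for sess in subject.sessions:
            recs = extract_session_records(sess, params)
            if label_noise_sd > 0:
                noisy = [
                    replace_cuff(r, rng, label_noise_sd) for r in recs
                ]
                records.extend(noisy)
            else:
                records.extend(recs)
    return build_feature_table(records)


def replace_cuff(rec: dict, rng: np.random.Generator, sd: float) -> dict:
    """Perturb a record's cuff readings with Gaussian noise (mmHg).

    DBP is clamped below SBP by at least 5 mmHg so a large noise draw cannot
    produce an unphysiological (inverted pulse pressure) reading.
    """
    from .session import CuffReading

    noisy = []
    for c in rec["cuff_readings"]:
        sbp = c.sbp + float(rng.normal(0, sd))
        dbp = c.dbp + float(rng.normal(0, sd))
        dbp = min(dbp, sbp - 5.0)
        noisy.append(CuffReading(t=c.t, sbp=sbp, dbp=dbp))
    out = dict(rec)
    out["cuff_readings"] = noisy
    return out


def cohort_experiment(
    n_subjects: int = 20,
    label_noise_sd: float = 2.0,
    seed: int = 0,
    duration_s: float = 120.0,
    repetitions: int = 2,
    hp: GBTHyperparams = GBTHyperparams(),
) -> dict:
    """End-to-end recovery: simulate, extract, split 4:1, train, evaluate.

    Returns held-out PCC and MAE for SBP and DBP plus the fitted models and
    the test table (reused by the export degradation check).
    """
    template = SimulationConfig(duration_s=duration_s, cuff_interval_s=60.0,
                                cuff_noise_sd=0.0)
    cohort = make_cohort(n_subjects, template, seed=seed,
                         repetitions=repetitions, rest_duration_s=60.0)
    table = cohort_feature_table(cohort, label_noise_sd=label_noise_sd,
                                 noise_seed=seed + 1)
    train_df, test_df = stratified_split(table, seed=seed)
    out = {"n_rows": len(table), "n_train": len(train_df), "n_test": len(test_df)}
    models = {}
    for target, col in (("sbp", "ref_sbp"), ("dbp", "ref_dbp")):
        m = train(train_df, train_df[col].to_numpy(), hp, seed=seed, target=target)
        pred = m.predict(test_df[bp_model.FEATURE_COLUMNS].to_numpy())
        from . import metrics
        rep = metrics.evaluate(test_df[col].to_numpy(), pred)
        out[f"{target}_pcc"] = rep.pcc
        out[f"{target}_mae"] = rep.mae
        out[f"{target}_me"] = rep.me
        models[target] = m
    out["models"] = models
    out["test_table"] = test_df
    out["train_table"] = train_df
    out["feature_table"] = table
    return out


def label_noise_sweep(
    sigmas=(8.0, 4.0, 2.0, 1.0),
    n_subjects: int = 20,
    seed: int = 0,
    duration_s: float = 120.0,
    repetitions: int = 2,
    hp: GBTHyperparams = GBTHyperparams(),
) -> dict:
    """Test-set MAE as a function of cuff label noise, one extraction pass."""
    template = SimulationConfig(duration_s=duration_s, cuff_noise_sd=0.0)
    cohort = make_cohort(n_subjects, template, seed=seed,
                         repetitions=repetitions, rest_duration_s=60.0)
    base_records = []
    for subject in cohort:
        for sess in subject.sessions:
            base_records.extend(extract_session_records(sess))
    out = {}
    for sigma in sigmas:
        rng = np.random.default_rng(seed + 1)
        recs = [replace_cuff(r, rng, sigma) for r in base_records] \
            if sigma > 0 else base_records
        table = build_feature_table(recs)
        train_df, test_df = stratified_split(table, seed=seed)
        sig_out = {}
        for target, col in (("sbp", "ref_sbp"), ("dbp", "ref_dbp")):
            m = train(train_df, train_df[col].to_numpy(), hp, seed=seed,
                      target=target)
            pred = m.predict(test_df[bp_model.FEATURE_COLUMNS].to_numpy())
            from . import metrics
            sig_out[f"{target}_mae"] = metrics.mae(
                test_df[col].to_numpy(), pred)[0]
        out[sigma] = sig_out
    return out


def random_model(rng: np.random.Generator, n_trees: int | None = None,
                 max_depth: int = 12, n_features: int = 3) -> GBTModel:
    """A random ensemble in the package tree IR (for equivalence testing)."""

    def grow(depth: int) -> dict:
        if depth >= max_depth or rng.random() < 0.35:
            return {"value": float(rng.normal(0, 2.0))}
        return {
            "feature": int(rng.integers(0, n_features)),
            "threshold": float(rng.normal(0, 1.5)),
            "left": grow(depth + 1),
            "right": grow(depth + 1),
        }

    if n_trees is None:
        n_trees = int(rng.integers(1, 101))
    trees = [grow(0) for _ in range(n_trees)]
    return GBTModel(target="sbp", trees=trees, base_score=float(rng.normal(100, 10)),
                    hyperparams=GBTHyperparams(n_estimators=n_trees),
                    n_features=n_features)


def export_equivalence(n_models: int = 50, n_inputs: int = 1000,
                       seed: int = 0) -> dict:
    """Max relative error between native prediction and interpreted export."""
    from .export import export_embedded_source, interpret_exported

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_models):
        m = random_model(rng)
        X = rng.normal(0, 2.0, size=(n_inputs, 3))
        native = m.predict(X)
        interp = interpret_exported(export_embedded_source(m, "double"), X)
        rel = np.max(np.abs(native - interp) / np.maximum(np.abs(native), 1e-12))
        worst = max(worst, float(rel))
    return {"max_relative_error": worst, "n_models": n_models,
            "n_inputs": n_inputs}
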