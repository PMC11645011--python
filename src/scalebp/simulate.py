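"""Synthetic BCG/IPG session generator with per-beat ground truth.

The generator emulates the measurement protocol this package targets: a subject
stands on a weight-fat scale after treadmill exercise while blood pressure
decays exponentially back toward its resting value and a cuff samples it
once per minute.  Every quantity the pipeline is supposed to recover is
known exactly:

* beat times follow an inhomogeneous rhythm (heart rate interpolating
  ``hr_start`` -> ``hr_end`` with Gaussian beat-to-beat jitter);
* SBP/DBP decay exponentially from ``bp_start`` to ``bp_end`` with time
  constant ``bp_decay_tau``;
* each beat's PTT follows the inverse coupling PTT = a + b / SBP (a soft
  Moens-Korteweg-style relation), rounded to a whole sample so the
  ground-truth identity true_ptt = (dipg_peak - j_wave) * 1000 / fs holds
  exactly;
* the BCG channel is a Gaussian-windowed 8 Hz cosine wavelet whose maximum
  (the J-wave) sits exactly on the beat sample; the IPG channel is a raised
  cosine of width 0.35 cycle positioned so the discrete first difference
  peaks exactly PTT after the J-wave;
* white noise (as a fraction of the unit pulse amplitude) and a sinusoidal
  baseline drift are added to both channels; cuff readings are sampled from
  the true trajectories (exact unless ``cuff_noise_sd`` > 0).

The waveforms are stand-ins with correct fiducial structure, not
morphologically faithful recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ConfigError
from .session import BiosignalSession, Calibration, CuffReading


@dataclass(frozen=True)
class SimulationConfig:
    """Study-protocol parameters of one simulated session."""

    duration_s: float = 360.0          # post-exercise stand: six minutes
    fs: float = 500.0
    hr_start: float = 100.0            # BPM, elevated right after exercise
    hr_end: float = 75.0               # BPM, recovering
    hrv_sd: float = 2.0                # BPM beat-to-beat jitter
    ptt_a_ms: float = 50.0             # PTT = a + b / SBP
    ptt_b: float = 12000.0             # ms * mmHg (PTT ~ 150 ms at SBP 120)
    bp_start: tuple[float, float] = (145.0, 90.0)   # (SBP, DBP) post-exercise
    bp_end: tuple[float, float] = (120.0, 80.0)     # resting values
    bp_decay_tau_s: float = 120.0      # recovery time constant
    noise_sd: float = 0.05             # fraction of unit pulse amplitude
    drift_amp: float = 0.2             # amplitude units
    drift_freq_hz: float = 0.25        # respiration-like baseline sway
    cuff_interval_s: float = 60.0      # cuff cadence during the stand
    cuff_noise_sd: float = 0.0         # mmHg; label noise when > 0
    seed: int = 0

    def __post_init__(self) -> None:
        for hr in (self.hr_start, self.hr_end):
            if not 40.0 <= hr <= 220.0:
                raise ConfigError(f"heart rate {hr} BPM outside [40, 220]")
        for sbp, dbp in (self.bp_start, self.bp_end):
            if not sbp > dbp > 0:
                raise ConfigError(f"unphysiological BP pair {sbp}/{dbp}")
        if self.bp_decay_tau_s <= 0:
            raise ConfigError("bp_decay_tau_s must be positive")


@dataclass
class GroundTruth:
    """Everything the pipeline should recover, exact to the sample."""

    beat_times: np.ndarray      # s
    true_ptt_ms: np.ndarray     # per beat
    true_sbp: np.ndarray        # mmHg, trajectory at each beat
    true_dbp: np.ndarray
    j_wave_idx: np.ndarray      # sample index of each BCG J-wave
    dipg_peak_idx: np.ndarray   # sample index of each dIPG peak
    sbp_at: Callable[[np.ndarray], np.ndarray] = None
    dbp_at: Callable[[np.ndarray], np.ndarray] = None


def _bp_trajectory(cfg: SimulationConfig):
    s0, d0 = cfg.bp_start
    s1, d1 = cfg.bp_end

    def sbp_at(t):
        return s1 + (s0 - s1) * np.exp(-np.asarray(t, float) / cfg.bp_decay_tau_s)

    def dbp_at(t):
        return d1 + (d0 - d1) * np.exp(-np.asarray(t, float) / cfg.bp_decay_tau_s)

    return sbp_at, dbp_at


def simulate_session(cfg: SimulationConfig,
                     phase: str = "post_exercise") -> tuple[BiosignalSession, GroundTruth]:
    """Generate one session and its ground truth, deterministic under seed."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(cfg.duration_s * fs))
    sbp_at, dbp_at = _bp_trajectory(cfg)

    # beat schedule
    beat_times: list[float] = []
    intervals: list[float] = []
    t = 0.5  # leave room for the first wavelet
    margin = 0.6  # keep the last pulse fully inside the record
    while t < cfg.duration_s - margin:
        frac = t / cfg.duration_s
        hr = cfg.hr_start + (cfg.hr_end - cfg.hr_start) * frac
        hr_jit = hr + rng.normal(0.0, cfg.hrv_sd)
        hr_jit = float(np.clip(hr_jit, 40.0, 220.0))
        beat_times.append(t)
        iv = 60.0 / hr_jit
        intervals.append(iv)
        t += iv
    if not beat_times:
        raise ConfigError("session too short to hold a single beat")
    bt = np.asarray(beat_times)
    iv = np.asarray(intervals)

    bcg = np.zeros(n)
    ipg = np.zeros(n)
    sigma = 0.05 * fs  # 25-sample Gaussian envelope for the BCG wavelet
    half = int(3 * sigma)

    j_idx = np.rint(bt * fs).astype(int)
    sbp_b = sbp_at(bt)
    dbp_b = dbp_at(bt)
    ptt_ms_exact = cfg.ptt_a_ms + cfg.ptt_b / sbp_b
    ptt_samples = np.rint(ptt_ms_exact * fs / 1000.0).astype(int)
    dipg_idx = j_idx + ptt_samples

    cycle_samples = np.rint(iv * fs).astype(int)
    min_width = np.min(0.35 * cycle_samples)
    if min_width < 8:
        raise ConfigError("heart rate too high for the pulse width; beats overlap")

    for j, dp, cyc in zip(j_idx, dipg_idx, cycle_samples):
        # BCG wavelet: strict max exactly at the beat sample
        k = np.arange(max(0, j - half), min(n, j + half + 1))
        bcg[k] += np.exp(-((k - j) ** 2) / (2 * sigma**2)) * np.cos(
            2 * np.pi * 8.0 * (k - j) / fs)
        # IPG raised cosine: steepest ascent of the *discrete* difference at dp.
        # The backward difference d[t] peaks at the continuous max slope + 0.5,
        # so center the quarter-width point at dp - 0.5.
        w = 0.35 * cyc
        t0 = (dp - 0.5) - w / 4.0
        kk = np.arange(int(np.ceil(t0)), min(n, int(np.floor(t0 + w)) + 1))
        kk = kk[kk >= 0]
        ipg[kk] += 0.5 * (1.0 - np.cos(2 * np.pi * (kk - t0) / w))

    if cfg.noise_sd > 0:
        bcg += rng.normal(0.0, cfg.noise_sd, n)
        ipg += rng.normal(0.0, cfg.noise_sd, n)
    if cfg.drift_amp > 0:
        tt = np.arange(n) / fs
        drift = cfg.drift_amp * np.sin(2 * np.pi * cfg.drift_freq_hz * tt)
        bcg += drift
        ipg += cfg.drift_amp * np.sin(2 * np.pi * cfg.drift_freq_hz * tt + 1.0)

    cuff_t = np.arange(0.0, cfg.duration_s + 1e-9, cfg.cuff_interval_s)
    cuff_t = cuff_t[cuff_t <= n / fs]
    cuffs = []
    for ct in cuff_t:
        s = float(sbp_at(ct))
        d = float(dbp_at(ct))
        if cfg.cuff_noise_sd > 0:
            s += float(rng.normal(0.0, cfg.cuff_noise_sd))
            d += float(rng.normal(0.0, cfg.cuff_noise_sd))
            d = min(d, s - 5.0)  # keep the pulse pressure physiological
        cuffs.append(CuffReading(t=float(ct), sbp=s, dbp=d))

    session = BiosignalSession(
        subject_id=f"sim-{cfg.seed}", phase=phase, fs=fs, bcg=bcg, ipg=ipg,
        cuff_readings=cuffs,
        calibration=Calibration(sbp_rest=cfg.bp_end[0], dbp_rest=cfg.bp_end[1]),
    )
    truth = GroundTruth(
        beat_times=bt, true_ptt_ms=ptt_samples * 1000.0 / fs,
        true_sbp=sbp_b, true_dbp=dbp_b,
        j_wave_idx=j_idx, dipg_peak_idx=dipg_idx,
        sbp_at=sbp_at, dbp_at=dbp_at,
    )
    return session, truth


@dataclass
class CohortSubject:
    """One simulated subject: a resting calibration session plus labeled stands."""

    subject_id: str
    rest_session: BiosignalSession
    rest_truth: GroundTruth
    sessions: list[BiosignalSession]
    truths: list[GroundTruth]
    calibration: Calibration


def make_cohort(
    n_subjects: int,
    template: SimulationConfig | None = None,
    seed: int = 0,
    repetitions: int = 4,
    rest_duration_s: float = 60.0,
) -> list[CohortSubject]:
    """Simulate a cohort spanning the four blood-pressure categories.

    Per subject: resting SBP ~ U[100, 160] and DBP ~ U[60, 100] mmHg (DBP
    capped below SBP - 25), the PTT coupling coefficient ``b`` jittered
    +/-10%, one rest session (providing the calibration pair) and
    ``repetitions`` post-exercise sessions boosted +25/+10 mmHg, honoring the
    >20 mmHg exercise-boost protocol.
    """
    if n_subjects < 1:
        raise ConfigError("need at least one subject")
    template = template or SimulationConfig()
    rng = np.random.default_rng(seed)
    cohort: list[CohortSubject] = []
    for s in range(n_subjects):
        sbp_rest = float(rng.uniform(100.0, 160.0))
        dbp_rest = float(rng.uniform(60.0, min(100.0, sbp_rest - 25.0)))
        b = template.ptt_b * float(rng.uniform(0.9, 1.1))
        sub_seed = int(rng.integers(0, 2**31 - 1))

        rest_cfg = replace(
            template, duration_s=rest_duration_s, hr_start=template.hr_end,
            hr_end=template.hr_end, ptt_b=b,
            bp_start=(sbp_rest + 1e-6, dbp_rest),  # constant BP at rest
            bp_end=(sbp_rest, dbp_rest), seed=sub_seed,
        )
        rest_session, rest_truth = simulate_session(rest_cfg, phase="rest")
        # calibration = the (possibly noisy) first rest cuff reading
        first = rest_session.cuff_readings[0]
        cal = Calibration(sbp_rest=first.sbp, dbp_rest=first.dbp)
        rest_session.calibration = cal

        sessions, truths = [], []
        for r in range(repetitions):
            cfg = replace(
                template, ptt_b=b,
                bp_start=(sbp_rest + 25.0, dbp_rest + 10.0),
                bp_end=(sbp_rest, dbp_rest),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            sess, truth = simulate_session(cfg, phase="post_exercise")
            sess.subject_id = f"subj-{s:02d}"
            sess.calibration = cal
            sessions.append(sess)
            truths.append(truth)
        cohort.append(CohortSubject(
            subject_id=f"subj-{s:02d}", rest_session=rest_session,
            rest_truth=rest_truth, sessions=sessions, truths=truths,
            calibration=cal))
    return cohort
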