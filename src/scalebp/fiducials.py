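"""Beat-to-beat fiducial detection and pulse-transit-time extraction.

The algorithm locates, per 2 s analysis segment, three families of fiducial
points and derives one pulse transit time (PTT) per cardiac cycle:

1. **IPG peaks (IPG_P).**  Candidates come from zero crossings of the first
   difference of IPG (dIPG).  A detection threshold is formed from the mean
   of the three largest candidate amplitudes (scaled by ``beta``); surviving
   candidates are verified as the strict local maximum within +/-25 samples.
   The mean interval between verified peaks (``Cycle_Average``) then gates a
   minimum-separation pass (0.7 x Cycle_Average, larger amplitude wins) that
   yields the "truth" IPG peaks.
2. **dIPG foot and peak.**  Foot candidates come from zero crossings of the
   second difference (ddIPG), verified as strict minima of dIPG within
   +/-20 samples.  From each truth IPG peak the nearest verified foot within
   0.7 x Cycle_Average forward is the truth dIPG foot; searching backward
   from that foot, the first local maximum of dIPG is the dIPG peak — the
   steepest-upstroke point of the pulse, the distal timing reference.
3. **BCG J-waves (BCG_P).**  Candidates are zero crossings of the first
   difference of BCG; the largest-amplitude candidate between consecutive
   dIPG peaks (one cycle back for the first beat) is the J-wave, the
   proximal timing reference.

PTT(i) = (dIPG_P(i) - BCG_P(i)) * 1000 / fs, in milliseconds.  The
calibration-free feature is the mean PTT of the segment; dividing it by the
subject's resting SBP and DBP gives the two calibration-based features
PTT_SYS and PTT_DIA.

Discrete-sampling details: a zero crossing of a backward difference lands
one sample after the underlying extremum, so every candidate is first
relocated to the extremum of its verification window before the strict
verification test; and because a first difference of wideband noise is noisy
enough to drown the pulse upstroke, both channels are pre-smoothed with a
symmetric (zero-phase) FIR low pass, which delays neither channel and so
leaves PTT unbiased.  Smoothing cutoffs and all search windows are
parameters of :class:`ExtractionParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal as _sig

from .errors import QualityError, ScalebpError
from .filters import Segment
from .session import Calibration


@dataclass(frozen=True)
class ExtractionParams:
    """Tunable parameters of the fiducial pipeline (units in comments)."""

    beta: float = 0.5                 # threshold scale on mean of top-3 peaks
    peak_half_window: int = 25        # samples; IPG-peak verification window
    foot_half_window: int = 20        # samples; dIPG-foot verification window
    separation_factor: float = 0.7    # fraction of Cycle_Average
    min_candidates: int = 2           # peaks needed to form a threshold
    ptt_bounds_ms: tuple[float, float] = (50.0, 400.0)  # plausibility gate
    smooth: bool = True               # symmetric FIR pre-smoothing
    ipg_smooth_hz: float = 5.0        # IPG smoothing cutoff
    bcg_smooth_hz: float = 20.0       # BCG smoothing cutoff
    smooth_taps: int = 101            # FIR length (odd => integer center)
    foot_search: Literal["forward", "backward"] = "forward"
    peak_search: Literal["backward", "forward"] = "backward"


DEFAULT_PARAMS = ExtractionParams()


@dataclass
class FiducialSet:
    """All detected fiducials of one segment, including diagnostics."""

    ipg_peaks: np.ndarray        # truth IPG_P (sample indices)
    threshold: float             # scaled mean of top-3 candidate amplitudes
    cycle_average: float         # samples
    dipg_foots: np.ndarray       # truth dIPG_F, paired per beat
    dipg_peaks: np.ndarray       # dIPG_P, paired per beat
    bcg_peaks: np.ndarray        # BCG_P (J-waves), paired per beat
    # stage diagnostics
    t_ipg_peak: np.ndarray = field(default_factory=lambda: np.array([], int))
    v_ipg_peak: np.ndarray = field(default_factory=lambda: np.array([], int))
    v_dipg_foot: np.ndarray = field(default_factory=lambda: np.array([], int))

    def as_dict(self) -> dict:
        return {
            "ipg_peaks": self.ipg_peaks.tolist(),
            "threshold": self.threshold,
            "cycle_average": self.cycle_average,
            "dipg_foots": self.dipg_foots.tolist(),
            "dipg_peaks": self.dipg_peaks.tolist(),
            "bcg_peaks": self.bcg_peaks.tolist(),
            "t_ipg_peak": self.t_ipg_peak.tolist(),
            "v_ipg_peak": self.v_ipg_peak.tolist(),
            "v_dipg_foot": self.v_dipg_foot.tolist(),
        }


@dataclass
class PTTFeatures:
    """Per-segment features: one calibration-free and two calibration-based."""

    ptt_free: float | None       # ms, mean of the per-beat PTTs
    ptt_sys: float | None        # ms/mmHg, ptt_free / resting SBP
    ptt_dia: float | None        # ms/mmHg, ptt_free / resting DBP
    n_beats: int
    quality_ok: bool
    ptt_ms: np.ndarray = field(default_factory=lambda: np.array([]))
    fiducials: FiducialSet | None = None
    beat_indices: np.ndarray = field(default_factory=lambda: np.array([], int))


def differentiate(x: Sequence[float]) -> np.ndarray:
    """First backward difference, d[0] = 0, same length as the input."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ScalebpError("differentiate requires at least 2 samples")
    d = np.empty_like(x)
    d[0] = 0.0
    d[1:] = x[1:] - x[:-1]
    return d


def zero_cross_extrema(d: Sequence[float], polarity: Literal["peak", "foot"]) -> np.ndarray:
    """Zero-crossing candidates of a derivative sequence.

    ``peak``: crossings from > 0 to <= 0 (maxima of the integrated signal);
    ``foot``: crossings from < 0 to >= 0 (minima).  The index reported is the
    first sample after the crossing.
    """
    d = np.asarray(d, dtype=float)
    if polarity == "peak":
        mask = (d[:-1] > 0) & (d[1:] <= 0)
    elif polarity == "foot":
        mask = (d[:-1] < 0) & (d[1:] >= 0)
    else:
        raise ScalebpError(f"unknown polarity {polarity!r}")
    return np.nonzero(mask)[0] + 1


def peak_threshold(amplitudes: Sequence[float], beta: float = 0.5,
                   min_candidates: int = 2) -> float:
    """Detection threshold: ``beta`` x mean of the largest candidate peaks.

    The mean is taken over the three largest amplitudes (or all of them when
    only two are present — a 2 s window at 60 BPM holds just two full
    cycles).  Fewer than ``min_candidates`` candidates marks the segment as
    too poor to threshold.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if len(amps) < min_candidates:
        raise QualityError(
            f"only {len(amps)} peak candidates; need >= {min_candidates}")
    top = np.sort(amps)[-3:]
    return float(beta * np.mean(top))


def verify_extremum(x: Sequence[float], idx: int, half_window: int,
                    mode: Literal["max", "min"] = "max") -> int | None:
    """Accept ``idx`` iff it is the strict extremum of its +/-half_window span.

    On a plateau of equal extrema the earliest index is the extremum; later
    plateau members are rejected.  Returns the index, or None on rejection.
    """
    x = np.asarray(x, dtype=float)
    if not 0 <= idx < len(x):
        raise ScalebpError(f"candidate index {idx} out of bounds")
    lo = max(0, idx - half_window)
    hi = min(len(x), idx + half_window + 1)
    win = x[lo:hi]
    if mode == "min":
        win = -win
    best = int(np.argmax(win)) + lo  # argmax takes the earliest on ties
    return idx if best == idx else None


def relocate_candidates(x: Sequence[float], candidates: Sequence[int],
                        half_window: int, mode: Literal["max", "min"] = "max"
                        ) -> np.ndarray:
    """Move each candidate to the extremum of its window; dedupe and sort.

    Zero-crossing candidates of a backward difference sit one sample past the
    true extremum (and jitter further under noise); relocation makes the
    subsequent strict verification meaningful.
    """
    x = np.asarray(x, dtype=float)
    sgn = -1.0 if mode == "min" else 1.0
    out = []
    for idx in candidates:
        lo = max(0, int(idx) - half_window)
        hi = min(len(x), int(idx) + half_window + 1)
        out.append(int(np.argmax(sgn * x[lo:hi])) + lo)
    return np.unique(np.asarray(out, dtype=int))


def cycle_average(peaks: Sequence[int]) -> float:
    """Mean interval (samples) between successive verified IPG peaks."""
    peaks = np.asarray(peaks)
    if len(peaks) < 2:
        raise QualityError("cycle average needs at least 2 verified peaks")
    return float(np.mean(np.diff(peaks)))


def truth_ipg_peaks(peaks: Sequence[int], amplitudes: Sequence[float],
                    cyc: float, separation_factor: float = 0.7) -> np.ndarray:
    """Minimum-separation pass: gaps >= separation_factor * Cycle_Average.

    Scanning in time order, a peak closer than the gap to the previously
    accepted one displaces it only if its amplitude is larger.
    """
    if cyc <= 0:
        raise ScalebpError("cycle average must be positive")
    peaks = np.asarray(peaks, dtype=int)
    amps = np.asarray(amplitudes, dtype=float)
    min_gap = separation_factor * cyc
    kept: list[int] = []
    for p, a in zip(peaks, amps):
        if kept and p - kept[-1] < min_gap:
            prev_amp = amps[np.searchsorted(peaks, kept[-1])]
            if a > prev_amp:
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    return np.asarray(kept, dtype=int)


def _first_local_max_backward(d: np.ndarray, start: int, stop: int) -> int | None:
    """First local maximum of ``d`` scanning backward from ``start`` to ``stop``."""
    for j in range(start, max(stop, 1) - 1, -1):
        if j <= 0 or j >= len(d) - 1:
            continue
        if d[j] > d[j - 1] and d[j] >= d[j + 1]:
            return j
    return None


def _first_local_max_forward(d: np.ndarray, start: int, stop: int) -> int | None:
    for j in range(start, min(stop, len(d) - 1)):
        if j <= 0:
            continue
        if d[j] > d[j - 1] and d[j] >= d[j + 1]:
            return j
    return None


def locate_dipg_fiducials(
    dipg: np.ndarray,
    foots: Sequence[int],
    truth_peaks: Sequence[int],
    cyc: float,
    separation_factor: float = 0.7,
    foot_search: str = "forward",
    peak_search: str = "backward",
) -> tuple[np.ndarray, np.ndarray]:
    """Pair each truth IPG peak with its dIPG foot and dIPG peak.

    Forward foot search: the nearest verified foot within
    (IPG_P, IPG_P + separation_factor * cyc].  Backward peak search: from the
    foot toward earlier samples, the first local maximum of dIPG (falling
    back to the window argmax when the scan finds none).  Beats without a
    foot in range are dropped.  The reversed directions are available for
    sensitivity checks via ``foot_search`` / ``peak_search``.
    """
    dipg = np.asarray(dipg, dtype=float)
    foots = np.asarray(foots, dtype=int)
    span = int(round(separation_factor * cyc))
    out_f: list[int] = []
    out_p: list[int] = []
    for pk in truth_peaks:
        if foot_search == "forward":
            in_range = foots[(foots > pk) & (foots <= pk + span)]
            foot = int(in_range[0]) if len(in_range) else None
        else:
            in_range = foots[(foots < pk) & (foots >= pk - span)]
            foot = int(in_range[-1]) if len(in_range) else None
        if foot is None:
            continue  # beat dropped
        if peak_search == "backward":
            lo = max(0, foot - span)
            dp = _first_local_max_backward(dipg, foot - 1, lo)
            if dp is None:
                win = dipg[lo:foot]
                dp = int(np.argmax(win)) + lo if len(win) else None
        else:
            hi = min(len(dipg), foot + span)
            dp = _first_local_max_forward(dipg, foot + 1, hi)
            if dp is None:
                win = dipg[foot + 1: hi]
                dp = int(np.argmax(win)) + foot + 1 if len(win) else None
        if dp is None:
            continue
        if out_p and dp <= out_p[-1]:
            continue  # keep dIPG peaks strictly increasing
        out_f.append(foot)
        out_p.append(int(dp))
    return np.asarray(out_f, dtype=int), np.asarray(out_p, dtype=int)


def locate_bcg_peaks(
    bcg: np.ndarray,
    dbcg: np.ndarray,
    dipg_peaks: Sequence[int],
    cyc: float,
    relocate_half_window: int = 25,
) -> tuple[np.ndarray, np.ndarray]:
    """J-wave per beat: largest BCG candidate between consecutive dIPG peaks.

    Candidates are relocated zero crossings of dBCG.  The first beat, having
    no preceding dIPG peak, searches one Cycle_Average back — and is dropped
    when that window extends before the segment start, because its J-wave
    may lie outside the observable span.  Beats without any candidate in
    their window are dropped together with their dIPG peak.  Returns
    (bcg_peaks, kept_dipg_peaks), equal length, bcg < dipg pairwise.
    """
    bcg = np.asarray(bcg, dtype=float)
    dipg_peaks = np.asarray(dipg_peaks, dtype=int)
    cands = relocate_candidates(
        bcg, zero_cross_extrema(dbcg, "peak"), relocate_half_window, "max")
    out_b: list[int] = []
    out_d: list[int] = []
    for i, dp in enumerate(dipg_peaks):
        if i == 0:
            lo = dp - int(round(cyc))
            if lo < 0:
                continue  # J-wave window not observable in this segment
        else:
            lo = int(dipg_peaks[i - 1])
        in_win = cands[(cands > lo) & (cands < dp)]
        if len(in_win) == 0:
            continue
        best = int(in_win[np.argmax(bcg[in_win])])
        out_b.append(best)
        out_d.append(int(dp))
    return np.asarray(out_b, dtype=int), np.asarray(out_d, dtype=int)


def compute_ptt(dipg_peaks: Sequence[int], bcg_peaks: Sequence[int],
                fs: float) -> np.ndarray:
    """Per-beat PTT in ms: (dIPG_P - BCG_P) x 1000 / fs."""
    dp = np.asarray(dipg_peaks, dtype=int)
    bp = np.asarray(bcg_peaks, dtype=int)
    if dp.shape != bp.shape:
        raise ScalebpError("fiducial lists must have equal length")
    if np.any(bp >= dp):
        raise ScalebpError("BCG peak must precede its dIPG peak")
    return (dp - bp) * 1000.0 / fs


def _smooth(x: np.ndarray, cutoff_hz: float, fs: float, taps: int) -> np.ndarray:
    """Zero-phase FIR low pass (odd length, applied centered)."""
    taps = min(taps if taps % 2 == 1 else taps + 1, 2 * (len(x) // 2) - 1)
    if taps < 3:
        return x
    h = _sig.firwin(taps, cutoff_hz, fs=fs)
    return np.convolve(x, h, mode="same")


def detect_fiducials(bcg: np.ndarray, ipg: np.ndarray, fs: float,
                     params: ExtractionParams = DEFAULT_PARAMS) -> FiducialSet:
    """Run the full three-part fiducial pipeline on one segment.

    Raises :class:`QualityError` when no usable beats survive.
    """
    bcg = np.asarray(bcg, dtype=float)
    ipg = np.asarray(ipg, dtype=float)
    if params.smooth:
        ipg_s = _smooth(ipg, params.ipg_smooth_hz, fs, params.smooth_taps)
        bcg_s = _smooth(bcg, params.bcg_smooth_hz, fs, params.smooth_taps)
    else:
        ipg_s, bcg_s = ipg, bcg
    dipg = differentiate(ipg_s)
    ddipg = differentiate(dipg)
    dbcg = differentiate(bcg_s)

    # part 1: IPG peaks
    cands = relocate_candidates(ipg_s, zero_cross_extrema(dipg, "peak"),
                                params.peak_half_window, "max")
    if len(cands) < params.min_candidates:
        raise QualityError("too few IPG peak candidates")
    thr = peak_threshold(ipg_s[cands], params.beta, params.min_candidates)
    t_ipg = cands[ipg_s[cands] > thr]
    v_ipg = np.asarray(
        [c for c in t_ipg
         if verify_extremum(ipg_s, int(c), params.peak_half_window, "max") is not None],
        dtype=int)
    cyc = cycle_average(v_ipg)
    truth = truth_ipg_peaks(v_ipg, ipg_s[v_ipg], cyc, params.separation_factor)

    # part 2: dIPG foot and peak
    foot_cands = relocate_candidates(dipg, zero_cross_extrema(ddipg, "foot"),
                                     params.foot_half_window, "min")
    v_foot = np.asarray(
        [c for c in foot_cands
         if verify_extremum(dipg, int(c), params.foot_half_window, "min") is not None],
        dtype=int)
    foots, dpeaks = locate_dipg_fiducials(
        dipg, v_foot, truth, cyc, params.separation_factor,
        params.foot_search, params.peak_search)

    # part 3: BCG J-waves
    bpeaks, dpeaks_kept = locate_bcg_peaks(bcg_s, dbcg, dpeaks, cyc,
                                           params.peak_half_window)
    keep = np.isin(dpeaks, dpeaks_kept)
    return FiducialSet(
        ipg_peaks=truth, threshold=thr, cycle_average=cyc,
        dipg_foots=foots[keep], dipg_peaks=dpeaks_kept, bcg_peaks=bpeaks,
        t_ipg_peak=t_ipg, v_ipg_peak=v_ipg, v_dipg_foot=v_foot)


def extract_features(segment: Segment, calibration: Calibration | None = None,
                     params: ExtractionParams = DEFAULT_PARAMS) -> PTTFeatures:
    """Fiducial pipeline + PTT features for one segment.

    Quality failures are reported in the result (``quality_ok=False``), not
    raised: a segment passes when it yields at least one beat and every PTT
    lies inside the plausibility bounds (default 50-400 ms), the automatic
    stand-in for manual good-quality selection.
    """
    try:
        fid = detect_fiducials(segment.bcg, segment.ipg, segment.fs, params)
        ptt = compute_ptt(fid.dipg_peaks, fid.bcg_peaks, segment.fs)
    except (QualityError, ScalebpError):
        return PTTFeatures(ptt_free=None, ptt_sys=None, ptt_dia=None,
                           n_beats=0, quality_ok=False)
    lo, hi = params.ptt_bounds_ms
    ok = len(ptt) >= 1 and bool(np.all((ptt >= lo) & (ptt <= hi)))
    ptt_free = float(np.mean(ptt)) if len(ptt) else None
    ptt_sys = ptt_dia = None
    if ptt_free is not None and calibration is not None:
        ptt_sys = ptt_free / calibration.sbp_rest
        ptt_dia = ptt_free / calibration.dbp_rest
    return PTTFeatures(ptt_free=ptt_free, ptt_sys=ptt_sys, ptt_dia=ptt_dia,
                       n_beats=len(ptt), quality_ok=ok, ptt_ms=ptt,
                       fiducials=fid, beat_indices=fid.dipg_peaks)


def max_beats_per_segment(window: int = 1024, fs: float = 500.0,
                          hr_max_bpm: float = 200.0) -> int:
    """Upper bound on complete cardiac cycles (hence PTT values) per segment.

    A 1024-sample window at 500 Hz spans 2.048 s; at 200 BPM a cycle lasts
    0.3 s, so at most floor(2.048 / 0.3) = 6 complete cycles fit.
    """
    return int((window / fs) // (60.0 / hr_max_bpm))
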