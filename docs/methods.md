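# Methods

This note records the models, algorithmic choices and numerical conventions
behind `scalebp`, and what the synthetic experiments do and do not show.

## Signal model and session I/O

A session is a pair of equal-length channels sampled at a constant rate
(default 500 Hz): BCG in arbitrary strain-gauge units, IPG in arbitrary
impedance units, plus cuff readings (time, SBP, DBP) and an optional
resting calibration pair. The text format is CSV (`time,bcg,ipg`) with a
JSON sidecar for everything that is not a sample; floats are written at
`repr` precision and parsed with round-trip conversion, so write→read is
bit-exact.

The byte-stream codec emulates the device's UART input path. The published
facts are a 12-bit ADC and a 2000 bytes/s aggregate rate at 500 Hz; the
framing dialect is this package's own fixed choice: per sample time, BCG
then IPG, each a 12-bit code right-aligned in a 16-bit little-endian word.
The affine code mapping uses the per-channel min/max of the session (stored
in the sidecar), so decoding is deterministic and the round trip is exact
to within half a quantization step. A constant channel maps to mid-scale
with a ±1-unit span rather than a degenerate zero-width range.

## Filters

Two coefficient sources are provided:

* **printed** — the four published transfer functions verbatim. These are
  rounded to 2–3 significant digits; the BCG high-pass denominator
  `1 − 1.99 z⁻¹ + 0.99 z⁻²` factors as (1 − z⁻¹)(1 − 0.99 z⁻¹), i.e. a pole
  exactly on the unit circle, and the BCG low-pass denominator also has a
  pole marginally outside. Applying them logs a stability warning and
  proceeds (useful for fidelity experiments only). The text calls the BCG
  high pass fourth-order although the printed equation is a biquad; an
  optional flag cascades the biquad twice, but the default applies the
  equation as printed, once.
* **designed** (default) — Butterworth (BCG: 0.5 Hz HP, 20 Hz LP, order 4)
  and Chebyshev-I (IPG: 0.3 Hz HP order 2, 10 Hz LP order 4) redesigned at
  double precision for the session's rate via `scipy.signal`. The Chebyshev
  passband ripple is unstated upstream; the package default is 0.5 dB,
  configurable.

Filtering is causal with zero initial state — the target system runs in
real time — and the streaming class carries the direct-form state across
chunks, so chunked and one-pass filtering agree bit-for-bit. `single`
precision casts coefficients, input and state to float32 to emulate the
microcontroller; the published observation that edge filter coefficients
differ from their double-precision designs is reproduced this way.

## Fiducial detection and PTT

The per-segment algorithm follows the three-part peak/foot/J-wave scheme
described in the README. Conventions that the source description leaves
open, fixed here:

* **Derivative** = first backward difference, `d[0] = 0`.
* **Zero-crossing indices** land one sample after the underlying extremum
  (and jitter under noise), so every candidate is first *relocated* to the
  extremum of its verification window (±25 samples for IPG peaks and BCG
  candidates, ±20 for dIPG foots) and then strictly verified there: the
  candidate must be the unique window extremum, earliest index winning
  ties.
* **Threshold** = β × mean of the three largest candidate amplitudes, with
  β = 0.5 by default: against the unscaled top-3 mean nearly every true
  peak would fail (they *are* the top-3), so β < 1 is required for the rule
  to act as a floor rather than a ceiling; β = 1 reproduces the literal
  rule. A 2.048 s window at 60 BPM holds only two full cycles, so the
  top-3 mean degrades to a top-2 mean when only two candidates exist;
  fewer than two rejects the segment.
* **Truth IPG peaks**: scanning in time order, a peak closer than
  0.7 × Cycle_Average to the previously accepted one survives only if its
  amplitude is larger (the survivor replaces the earlier peak).
* **Search directions**: the dIPG foot is the nearest verified foot within
  0.7 × Cycle_Average *after* the IPG peak; the dIPG peak is the first
  local maximum scanning *backward* from that foot (window argmax as
  fallback). Both directions are switchable for sensitivity checks, since
  pulse physiology (steepest upstroke before the peak) motivates but does
  not prove this reading.
* **First-beat J-wave window** is one Cycle_Average back from the first
  dIPG peak; if that window starts before the segment, the beat is dropped
  — its J-wave may be unobservable, and pairing it with whatever candidate
  happens to lie inside produces physically impossible transit times.
* **PTT unit**: milliseconds, (dIPG_P − BCG_P) × 1000 / fs.
* **Normalization**: PTT_SYS = PTT/SBP_rest and PTT_DIA = PTT/DBP_rest
  (division; "normalized by" could also mean multiplication or an affine
  map — the choice is isolated in one place).
* **Quality gate**: a segment passes when it yields ≥ 1 beat and every PTT
  lies in [50, 400] ms. This automatic plausibility gate stands in for the
  manual good-quality selection used on the original recordings; it is not
  a reimplementation of that manual judgment.

**Noise conditioning.** The backward difference of wideband noise easily
drowns the IPG upstroke (the pulse is wide and its peak slope small), so
both channels are pre-smoothed inside the extraction stage with a
*symmetric* FIR low pass (default 101 taps; 5 Hz for IPG, 20 Hz for BCG).
Symmetric (zero-phase) smoothing delays neither channel, so PTT — a
cross-channel difference — is unbiased; this is deliberately separate from
the causal preprocessing filters, whose differing group delays would bias
PTT by a few samples. The causal bank remains the default front end of the
full pipeline (its bias is constant-like and absorbed by the regression);
ground-truth recovery experiments run the extraction stage directly.

## Reference labels, categories, splits

Per-beat reference BP is linearly interpolated between cuff readings (SBP
and DBP independently; beat times outside the cuff span are clamped to the
nearest reading); the segment label is the mean over its beats. Categories
follow the four-level scale (normal / prehypertension / stage 1 / stage 2)
evaluated in descending order, closing the boundary gaps of the written
definition: stage 2 at SBP ≥ 140 or DBP ≥ 90, stage 1 at SBP 130–139 or
DBP 80–89 (so 124/82 is stage 1 via its DBP), prehypertension at SBP
120–129, else normal — a total function. Splits are per-category:
round(0.2 n) rows to test, sampled without replacement under a named seed;
cross-validation uses category-stratified folds.

## Regression model and size budget

The regressor is a squared-error gradient-boosted tree ensemble fitted by
xgboost with the reference deployment's defaults (learning rate 0.0497,
max depth 12, 100
trees), base score = training-target mean, single-threaded exact tree
construction for determinism. The fitted booster is parsed into the
package's own tree IR (internal node = feature, threshold, left, right;
leaf = value; `feature < threshold` goes left, ties right), which is the
single source of truth for prediction, size estimation and export — a
prediction is the base score plus one leaf per tree.

The flash-size estimate charges 4 bytes per stored quantity: an internal
node stores 4 quantities (feature id, threshold, two branch references), a
leaf one, plus an 8-byte base. It is monotone in tree count and
order-of-magnitude consistent with a compiled footprint, with no claim of
matching any toolchain's bytes. Budget selection evaluates a candidate
tree-count grid (default 50–100), requires the SBP + DBP models to fit the
budget jointly (default 1 MB, the target board's flash) and keeps the
largest candidate that fits, reporting per-candidate CV PCC/MAE alongside
the sizes.

## Embedded export and interpreter

The exporter emits one pure C function of the three features built only
from literals, comparisons, `?:` conditionals and addition — the minimal
dialect any embedded toolchain accepts. Emission is deterministic. In
`single` mode thresholds and leaves are rounded to float32 at emission and
the interpreter runs float32 comparisons and accumulation; in `double`
mode interpretation reproduces native predictions exactly (identical
arithmetic in identical order). The interpreter is a tokenizer plus
recursive-descent parser for exactly this dialect; a parse failure
indicates an emitter bug, not bad input. No compiler is invoked anywhere.

## Metrics

PCC, ME ± SD and MAE ± SD with sample (n−1) standard deviations taken over
the per-sample errors; MAE ≥ |ME| always, with equality iff all errors
share one sign. The "± SD" on reported MAEs can alternatively mean the
spread across CV folds; the CV report returns fold means and SDs
separately so both readings are available. The BHS helper grades on the
standard cumulative thresholds (≥ 60/85/95% of absolute errors within
5/10/15 mmHg for grade A, etc.), which come from the BHS protocol, not
from this package's experiments.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *protocol* and the *timing structure* of real
sessions, not waveform morphology:

* beat times from an inhomogeneous rhythm (heart rate interpolating start
  → end, Gaussian beat-to-beat jitter, default 2 BPM);
* SBP/DBP decaying exponentially from a post-exercise boost (+25/+10 mmHg,
  honoring the > 20 mmHg exercise criterion) toward rest with time
  constant τ (default 120 s — a plausible placeholder; no quantitative
  recovery constant is published for this protocol);
* PTT = a + b/SBP per beat (a = 50 ms, b = 12 000 ms·mmHg gives ≈ 150 ms at
  120 mmHg) — a soft Moens–Korteweg-style inverse coupling, rounded to a
  whole sample so the ground-truth identity
  `true_ptt = (dipg_peak − j_wave) × 1000 / fs` holds exactly;
* BCG = Gaussian-windowed 8 Hz cosine with its maximum (the J-wave)
  exactly on the beat sample; IPG = raised cosine of width 0.35 cycle
  positioned so the *discrete* first difference peaks exactly PTT after
  the J-wave (a half-sample offset in the continuous placement makes the
  backward difference land on the integer target);
* white noise as a fraction of unit pulse amplitude (default 5%),
  sinusoidal baseline drift (default 0.2 units at 0.25 Hz), cuff readings
  exactly on the true trajectories unless cuff noise is configured (noisy
  DBP is clamped 5 mmHg below SBP to keep readings physiological).

Cohorts draw resting SBP ~ U[100, 160] and DBP ~ U[60, min(100, SBP−25)]
mmHg per subject — wide enough to populate all four categories — and
jitter the coupling coefficient b by ±10% between subjects; each subject
contributes one rest session (whose first cuff reading is the calibration)
and a number of post-exercise sessions.

Passing tests on this generator therefore show that the pipeline recovers
fiducials, transit times and pressures *when the assumed fiducial
structure holds and the PTT–BP coupling is the assumed monotone law*. They
do not show robustness to real BCG/IPG morphology, motion artifact,
arrhythmia, electrode contact variation, or subjects whose PTT–BP
relationship drifts between calibration and measurement.

## Experiment sizes and numerical conventions

The bundled experiments use desk-scale problem sizes chosen as the
package's own defaults: ground-truth recovery uses 100 sessions of 20 s at
constant heart rates in 60–90 BPM and true PTT in 120–220 ms (50 clean at
±1 sample, 50 at 10% noise at ±2 samples); the end-to-end cohort uses 20
subjects × 2 post-exercise stands of 120 s with 2 mmHg cuff noise, and the
label-noise sweep retrains on one extraction pass at σ ∈ {8, 4, 2, 1}
mmHg; export equivalence uses 50 random ensembles (≤ 100 trees, depth
≤ 12) × 1000 inputs at a 1e-9 relative tolerance. Seeds parameterize every
random source; identical seeds reproduce identical sessions, splits, fits
and artifacts (single-threaded xgboost, exact tree method).

Known limitations: the causal filter bank biases PTT by a few samples
(channel-dependent group delay), visible as a small mean PTT offset when
the full pipeline is used for recovery experiments; fiducial detection
assumes one dominant upstroke per cycle and will merge beats above ~200
BPM; the size estimate is intentionally crude; and the interpreter, while
exact, is an emulator — on-target numerics can differ where a compiler
contracts floating-point operations.
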