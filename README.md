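# scalebp

Cuffless blood-pressure estimation from the signals of an instrumented
bodily weight-fat scale.

When a person stands on a scale fitted with strain gauges and foot
electrodes, two signals are available without any cuff: the
**ballistocardiogram** (BCG, the body's recoil from each cardiac ejection)
and the **impedance plethysmogram** (IPG, the blood-volume pulse seen in the
body's electrical impedance). The delay between the BCG **J-wave** and the
main peak of the differentiated IPG of the same beat is a **pulse transit
time** (PTT), and by the Moens–Korteweg relation PTT falls as blood pressure
rises. `scalebp` implements the complete measurement chain that turns these
two signals into systolic/diastolic pressure (SBP/DBP) estimates, sized to
run on a flash-budgeted microcontroller:

1. **Session I/O** — `time,bcg,ipg` CSV with a JSON sidecar, or a simulated
   12-bit ADC byte stream (2 channels × 2 bytes × 500 Hz = 2000 bytes/s).
2. **Preprocessing** — streaming (causal, state-carrying) IIR filters, from
   published coefficients or redesigned Butterworth/Chebyshev-I specs;
   1024-sample windows with 512-sample overlap.
3. **PTT extraction** — a three-part fiducial algorithm: IPG peaks by
   zero crossings of dIPG with a top-3-amplitude threshold and ±25-sample
   verification; dIPG foot/peak via ddIPG zero crossings, ±20-sample
   verification and a 0.7 × mean-cycle search gate; BCG J-waves as the
   largest BCG candidate between consecutive dIPG peaks. Per segment this
   yields the calibration-free mean PTT and, divided by the subject's
   resting SBP/DBP, the calibration-based features PTT_SYS and PTT_DIA.
4. **BP regression** — gradient-boosted trees (squared error; defaults:
   learning rate 0.0497, depth 12, 100 trees) on the three features, with
   cuff references linearly interpolated per beat, four-category BP
   stratification (normal / prehypertension / stage 1 / stage 2), 4:1
   splits and 5-fold CV, and a flash-size estimate that selects the largest
   tree count fitting a 1 MB budget.
5. **Edge export** — transpiles a trained ensemble into one dependency-free
   C function of nested conditionals, verified against the native model by
   a built-in parser/interpreter, including 32-bit precision emulation.
6. **Synthetic data** — a session simulator with exact per-beat ground
   truth (beat times, J-wave and dIPG-peak sample indices, true PTT, true
   BP trajectories), emulating the post-exercise protocol: BP boosted
   +25/+10 mmHg decaying exponentially to rest, cuff sampled once a minute.

Evaluation uses the Pearson correlation coefficient (ρ), mean error
ME = mean(ŷ−y) ± SD and mean absolute error MAE = mean(|ŷ−y|) ± SD, plus an
optional British Hypertension Society grade.

## Worked example

```bash
python examples/train_and_evaluate.py
```

simulates 10 subjects (a resting calibration stand plus two post-exercise
stands each), extracts features through the real pipeline, labels them with
interpolated cuff references carrying 2 mmHg noise, and trains/evaluates
both models:

```
feature rows: 2320 (train 1857, test 463)
categories: {'stage2': 1356, 'stage1': 632, 'prehypertension': 256, 'normal': 76}
SBP: PCC 0.994, ME +0.14 +/- 2.11 mmHg, MAE 1.66 +/- 1.31 mmHg  (n=463)
DBP: PCC 0.978, ME +0.00 +/- 1.80 mmHg, MAE 1.41 +/- 1.12 mmHg  (n=463)
```

PCC near 1 with MAE just above the 2 mmHg label-noise floor means the PTT
features carry the blood-pressure signal end to end on this synthetic
cohort (see `docs/methods.md` for what the simulator does and does not
emulate). The other examples cover simulation + PTT recovery
(`simulate_and_extract.py`), streaming filters (`filter_signals.py`) and
embedded export under a flash budget (`export_for_embedded.py`).

A thin CLI wraps the same library calls:

```bash
scalebp simulate --duration 120 --seed 1 --out session.csv
scalebp extract-ptt session.csv --no-filter
scalebp pipeline session.csv --seed 1 --out-dir artifacts/
```

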