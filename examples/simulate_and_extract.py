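"""Simulate a post-exercise session and extract beat-to-beat PTT.

Builds a two-minute synthetic recording (BP decaying 145/90 -> 120/80,
5% amplitude noise), runs the fiducial pipeline on every 2.048 s segment,
and compares the extracted pulse transit times with the generator's ground
truth.
"""

import numpy as np

from scalebp.experiments import extract_session_records
from scalebp.simulate import SimulationConfig, simulate_session

cfg = SimulationConfig(duration_s=120.0, noise_sd=0.05, seed=3)
session, truth = simulate_session(cfg)
print(f"session: {session.n_samples} samples at {session.fs:.0f} Hz, "
      f"{len(truth.beat_times)} beats, {len(session.cuff_readings)} cuff readings")

records = extract_session_records(session)
print(f"quality-passing segments: {len(records)}")

# match each detected beat to the nearest ground-truth beat
det_idx = np.concatenate([r["beat_indices"] for r in records])
det_ptt = np.concatenate([r["ptt_per_beat"] for r in records])
true_ptt = np.array([
    truth.true_ptt_ms[np.argmin(np.abs(truth.dipg_peak_idx - i))]
    for i in det_idx
])
err = det_ptt - true_ptt
print(f"beats detected: {len(det_idx)}")
print(f"PTT error: mean {np.mean(err):+.2f} ms, "
      f"95th percentile |err| {np.percentile(np.abs(err), 95):.2f} ms")
print("(a 2 ms error is one sample at 500 Hz; the fiducial pipeline should "
      "stay within +/-2 samples on most beats at this noise level)")
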