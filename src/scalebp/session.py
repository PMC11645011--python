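"""Session data model and I/O for two-channel BCG/IPG recordings.

A recording session holds the ballistocardiogram (BCG) and impedance
plethysmogram (IPG) channels sampled at a constant rate (500 Hz by default),
the per-minute cuff blood-pressure readings taken during the session, and the
subject's resting-state calibration pair.

Two on-disk representations are supported:

* a CSV text file with columns ``time,bcg,ipg`` plus a JSON metadata sidecar
  (``<name>.meta.json``) carrying cuff readings, calibration and the ADC
  mapping, and
* a simulated fixed-rate byte stream of 12-bit ADC frames, matching the
  UART input path of the embedded device (2 channels x 2 bytes per sample,
  value right-aligned little-endian, BCG then IPG; 2000 bytes/s at 500 Hz).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FramingError, ParseError, RangeError, StructuralError

ADC_MAX = 4095  # 12-bit full scale
BYTES_PER_FRAME = 4  # 2 channels x 2 bytes


@dataclass(frozen=True)
class CuffReading:
    """One oscillometric cuff measurement, ``t`` seconds from session start."""

    t: float
    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if not (self.sbp > self.dbp > 0):
            raise StructuralError(
                f"cuff reading requires sbp > dbp > 0, got {self.sbp}/{self.dbp}"
            )


@dataclass(frozen=True)
class Calibration:
    """Resting-state blood pressure used to normalize PTT per subject."""

    sbp_rest: float
    dbp_rest: float

    def __post_init__(self) -> None:
        if not (self.sbp_rest > self.dbp_rest > 0):
            raise StructuralError(
                "calibration requires sbp_rest > dbp_rest > 0, "
                f"got {self.sbp_rest}/{self.dbp_rest}"
            )


@dataclass
class BiosignalSession:
    """A two-channel recording with cuff references and optional calibration."""

    subject_id: str
    phase: str  # "rest" | "post_exercise"
    fs: float
    bcg: np.ndarray
    ipg: np.ndarray
    cuff_readings: list[CuffReading] = field(default_factory=list)
    calibration: Calibration | None = None

    def __post_init__(self) -> None:
        self.bcg = np.asarray(self.bcg, dtype=float)
        self.ipg = np.asarray(self.ipg, dtype=float)
        if self.phase not in ("rest", "post_exercise"):
            raise StructuralError(f"unknown phase {self.phase!r}")
        if self.fs <= 0:
            raise StructuralError(f"sampling rate must be positive, got {self.fs}")
        if self.bcg.shape != self.ipg.shape or self.bcg.ndim != 1:
            raise StructuralError(
                f"channel length mismatch: bcg {self.bcg.shape}, ipg {self.ipg.shape}"
            )
        times = [r.t for r in self.cuff_readings]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise StructuralError("cuff readings must be strictly increasing in time")
        horizon = len(self.bcg) / self.fs
        if any(t < 0 or t > horizon for t in times):
            raise StructuralError("cuff reading time outside the recording span")

    @property
    def n_samples(self) -> int:
        return len(self.bcg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class AdcMapping:
    """Per-channel affine mapping between amplitude units and 12-bit codes."""

    bcg_lo: float
    bcg_hi: float
    ipg_lo: float
    ipg_hi: float

    @classmethod
    def from_session(cls, session: BiosignalSession) -> "AdcMapping":
        def bounds(x: np.ndarray) -> tuple[float, float]:
            if len(x) == 0:
                return 0.0, 1.0
            lo, hi = float(np.min(x)), float(np.max(x))
            if lo == hi:  # constant channel: center it on the mid-code
                lo, hi = lo - 1.0, hi + 1.0
            return lo, hi

        blo, bhi = bounds(session.bcg)
        ilo, ihi = bounds(session.ipg)
        return cls(blo, bhi, ilo, ihi)

    @classmethod
    def identity(cls) -> "AdcMapping":
        """Raw-code mapping: amplitudes are the ADC codes themselves."""
        return cls(0.0, float(ADC_MAX), 0.0, float(ADC_MAX))

    def to_dict(self) -> dict:
        return {
            "bcg_lo": self.bcg_lo,
            "bcg_hi": self.bcg_hi,
            "ipg_lo": self.ipg_lo,
            "ipg_hi": self.ipg_hi,
        }


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def write_session(session: BiosignalSession, path: str | Path) -> None:
    """Write a session as ``time,bcg,ipg`` CSV plus a JSON metadata sidecar.

    Floats are written with ``repr`` precision so the round trip through
    :func:`read_session` is bit-exact.
    """
    path = Path(path)
    t = np.arange(session.n_samples) / session.fs
    with open(path, "w") as fh:
        fh.write("time,bcg,ipg\n")
        for ti, b, i in zip(t.tolist(), session.bcg.tolist(), session.ipg.tolist()):
            fh.write(f"{ti!r},{b!r},{i!r}\n")
    meta = {
        "subject_id": session.subject_id,
        "phase": session.phase,
        "fs": session.fs,
        "cuff_readings": [
            {"t": r.t, "sbp": r.sbp, "dbp": r.dbp} for r in session.cuff_readings
        ],
        "calibration": (
            {
                "sbp_rest": session.calibration.sbp_rest,
                "dbp_rest": session.calibration.dbp_rest,
            }
            if session.calibration
            else None
        ),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_session(path: str | Path) -> BiosignalSession:
    """Read a session written by :func:`write_session`.

    The sampling rate is inferred from the median time step and the file is
    rejected if any step deviates more than 1% from it (non-constant rate).
    A missing value in either channel is a structural error; a non-numeric
    token is a parse error naming the offending line.
    """
    path = Path(path)
    try:
        # round_trip parsing so write -> read is bit-exact at full precision
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("time", "bcg", "ipg"):
        if col not in df.columns:
            raise StructuralError(f"{path}: missing column {col!r}")
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header row, one for 0-based indexing
            line = int(bad.idxmax()) + 2
            raise ParseError(f"{path}: non-numeric {col!r} value at line {line}")
        if numeric.isna().any():
            line = int(numeric.isna().idxmax()) + 2
            raise StructuralError(f"{path}: missing {col!r} value at line {line}")
        df[col] = numeric

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    if len(df) >= 2:
        dt = np.diff(df["time"].to_numpy())
        med = float(np.median(dt))
        if med <= 0:
            raise StructuralError(f"{path}: non-increasing time column")
        if np.any(np.abs(dt - med) > 0.01 * med):
            raise StructuralError(f"{path}: sampling rate deviates >1% from constant")
        fs = 1.0 / med
    else:
        fs = float(meta.get("fs", 500.0))

    cuffs = [CuffReading(**r) for r in meta.get("cuff_readings", [])]
    cal = Calibration(**meta["calibration"]) if meta.get("calibration") else None
    return BiosignalSession(
        subject_id=str(meta.get("subject_id", path.stem)),
        phase=meta.get("phase", "rest"),
        fs=float(meta.get("fs", fs)),
        bcg=df["bcg"].to_numpy(),
        ipg=df["ipg"].to_numpy(),
        cuff_readings=cuffs,
        calibration=cal,
    )


def _to_codes(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    codes = np.rint((np.asarray(x, dtype=float) - lo) / (hi - lo) * ADC_MAX)
    if np.any(codes < 0) or np.any(codes > ADC_MAX):
        raise RangeError("sample outside the 12-bit ADC range after mapping")
    return codes.astype(np.uint16)


def encode_stream(
    session: BiosignalSession, mapping: AdcMapping | None = None
) -> bytes:
    """Encode a session as the device's 12-bit frame stream.

    Each sample time emits one 4-byte frame: BCG then IPG, each a 12-bit code
    right-aligned in a 16-bit little-endian word. At 500 Hz this is the
    2000 bytes/s stream rate of the emulated UART link.
    """
    if mapping is None:
        mapping = AdcMapping.from_session(session)
    bcg = _to_codes(session.bcg, mapping.bcg_lo, mapping.bcg_hi)
    ipg = _to_codes(session.ipg, mapping.ipg_lo, mapping.ipg_hi)
    frames = np.empty(2 * len(bcg), dtype="<u2")
    frames[0::2] = bcg
    frames[1::2] = ipg
    return frames.tobytes()


def decode_stream(
    data: bytes, fs: float = 500.0, mapping: AdcMapping | None = None
) -> BiosignalSession:
    """Decode a 12-bit frame stream back into a session.

    Without a mapping the amplitudes are the raw ADC codes (0..4095); with the
    encoder's mapping the original amplitudes are recovered to within half a
    quantization step.
    """
    if len(data) % BYTES_PER_FRAME != 0:
        raise FramingError(
            f"stream length {len(data)} is not a whole number of 4-byte frames"
        )
    codes = np.frombuffer(data, dtype="<u2").astype(float)
    if np.any(codes > ADC_MAX):
        raise RangeError("stream contains codes above 12-bit full scale")
    if mapping is None:
        mapping = AdcMapping.identity()
    bcg = mapping.bcg_lo + codes[0::2] / ADC_MAX * (mapping.bcg_hi - mapping.bcg_lo)
    ipg = mapping.ipg_lo + codes[1::2] / ADC_MAX * (mapping.ipg_hi - mapping.ipg_lo)
    return BiosignalSession(
        subject_id="stream", phase="rest", fs=fs, bcg=bcg, ipg=ipg
    )


def write_stream(session: BiosignalSession, path: str | Path) -> AdcMapping:
    """Write the binary stream plus a sidecar with the ADC mapping and fs."""
    path = Path(path)
    mapping = AdcMapping.from_session(session)
    path.write_bytes(encode_stream(session, mapping))
    _sidecar_path(path).write_text(
        json.dumps({"fs": session.fs, "adc": mapping.to_dict()}, indent=1)
    )
    return mapping


def read_stream(path: str | Path) -> BiosignalSession:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    mapping = AdcMapping(**meta["adc"])
    return decode_stream(path.read_bytes(), fs=float(meta["fs"]), mapping=mapping)
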