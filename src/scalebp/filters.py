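"""Streaming IIR filtering and fixed-window segmentation.

The embedded front end filters each channel with recursive (IIR) filters
before fiducial detection.  Two coefficient sources are provided:

``printed``
    The transfer-function coefficients exactly as published for the four
    filter stages (BCG high/low pass, IPG high/low pass).  These are rounded
    to two or three significant digits, which places the BCG high-pass
    denominator's pole on the unit circle (1 - 1.99 + 0.99 = 0 at z = 1), so
    applying them logs a marginal-stability warning.

``designed``
    Coefficients redesigned at double precision from the stated family /
    order / cutoff at fs = 500 Hz (Butterworth for BCG, Chebyshev type I for
    IPG).  This is the default source for the pipeline.

Filtering is causal (zero initial state, no forward-backward pass) because
the target system runs in real time; :class:`StreamingIIR` carries the filter
state across chunks so chunked and whole-signal application agree bit-for-bit.
A ``single`` precision mode rounds coefficients, input and state to 32-bit
floats to emulate the microcontroller's arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy import signal

from .errors import ConfigError
from .session import BiosignalSession

Precision = Literal["double", "single"]

#: Published recursive-filter coefficients (b, a), a[0] = 1.
PRINTED_COEFFICIENTS: dict[str, tuple[list[float], list[float]]] = {
    # BCG high pass, 0.5 Hz cutoff (printed as a biquad)
    "bcg_hp": ([0.98, -1.97, 0.98], [1.0, -1.99, 0.99]),
    # BCG low pass, 4th-order Butterworth, 20 Hz cutoff
    "bcg_lp": (
        [1.14e-5, 4.56e-5, 6.84e-5, 4.56e-5, 1.14e-5],
        [1.0, -3.75, 5.31, -3.35, 0.79],
    ),
    # IPG high pass, Chebyshev, 0.3 Hz cutoff
    "ipg_hp": (
        [0.99, -3.96, 5.95, -3.96, 0.99],
        [1.0, -3.98, 5.95, -3.95, 0.98],
    ),
    # IPG low pass, 4th-order Chebyshev, 10 Hz cutoff
    "ipg_lp": (
        [1.83e-4, 7.32e-4, 1.1e-3, 7.32e-4, 1.83e-4],
        [1.0, -3.34, 4.23, -2.4, 0.51],
    ),
}

#: Text-level design specs for the same four stages (family, order, cutoff, kind).
DESIGN_SPECS: dict[str, dict] = {
    "bcg_hp": {"family": "butterworth", "order": 4, "cutoff_hz": 0.5, "kind": "highpass"},
    "bcg_lp": {"family": "butterworth", "order": 4, "cutoff_hz": 20.0, "kind": "lowpass"},
    "ipg_hp": {"family": "chebyshev-I", "order": 2, "cutoff_hz": 0.3, "kind": "highpass"},
    "ipg_lp": {"family": "chebyshev-I", "order": 4, "cutoff_hz": 10.0, "kind": "lowpass"},
}


@dataclass
class IIRCoefficients:
    """Rational transfer function H(z) = B(z)/A(z) with a0 = 1."""

    b: np.ndarray
    a: np.ndarray
    label: str = "custom"
    design: dict | None = None

    def __post_init__(self) -> None:
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if self.a[0] != 1.0:
            raise ConfigError(f"a[0] must be 1, got {self.a[0]}")

    def is_stable(self, tol: float = 1e-9) -> bool:
        """True when every pole lies strictly inside the unit circle."""
        if len(self.a) == 1:
            return True
        return bool(np.all(np.abs(np.roots(self.a)) < 1.0 - tol))


def printed_filter(label: str, cascade_to_text_order: bool = False) -> IIRCoefficients:
    """Return the published coefficients for one of the four filter stages.

    ``cascade_to_text_order`` applies the BCG high-pass biquad twice in
    cascade (the accompanying text calls that stage fourth order although the
    printed equation is second order); the default uses the equation as
    printed, once.
    """
    if label not in PRINTED_COEFFICIENTS:
        raise KeyError(f"unknown printed filter {label!r}; "
                       f"choose from {sorted(PRINTED_COEFFICIENTS)}")
    b, a = PRINTED_COEFFICIENTS[label]
    if cascade_to_text_order and label == "bcg_hp":
        b = np.convolve(b, b)
        a = np.convolve(a, a)
    return IIRCoefficients(b=np.array(b), a=np.array(a), label=label,
                           design={"source": "printed"})


def design_filter(
    family: str,
    order: int,
    cutoff_hz: float,
    fs_hz: float = 500.0,
    kind: str = "lowpass",
    ripple_db: float = 0.5,
    label: str = "custom",
) -> IIRCoefficients:
    """Design Butterworth or Chebyshev-I coefficients at double precision.

    ``ripple_db`` only applies to the Chebyshev family (the source text does
    not state a ripple; 0.5 dB is the package default).
    """
    if not 0 < cutoff_hz < fs_hz / 2:
        raise ConfigError(
            f"cutoff {cutoff_hz} Hz outside (0, {fs_hz / 2}) at fs={fs_hz}"
        )
    if kind not in ("lowpass", "highpass"):
        raise ConfigError(f"unsupported filter kind {kind!r}")
    if family == "butterworth":
        b, a = signal.butter(order, cutoff_hz, btype=kind, fs=fs_hz)
    elif family == "chebyshev-I":
        b, a = signal.cheby1(order, ripple_db, cutoff_hz, btype=kind, fs=fs_hz)
    else:
        raise ConfigError(f"unknown filter family {family!r}")
    return IIRCoefficients(
        b=b, a=a, label=label,
        design={"family": family, "order": order, "cutoff_hz": cutoff_hz,
                "fs_hz": fs_hz, "kind": kind, "source": "designed"},
    )


def designed_filter(label: str, fs_hz: float = 500.0) -> IIRCoefficients:
    """Redesign one of the four named stages from its text-level spec."""
    if label not in DESIGN_SPECS:
        raise KeyError(f"unknown filter label {label!r}")
    spec = DESIGN_SPECS[label]
    return design_filter(spec["family"], spec["order"], spec["cutoff_hz"],
                         fs_hz=fs_hz, kind=spec["kind"], label=label)


def filter_bank(source: str = "designed", fs_hz: float = 500.0) -> dict[str, IIRCoefficients]:
    """The four-stage bank keyed by label, from either coefficient source."""
    if source == "printed":
        return {lab: printed_filter(lab) for lab in PRINTED_COEFFICIENTS}
    if source == "designed":
        return {lab: designed_filter(lab, fs_hz) for lab in DESIGN_SPECS}
    raise ConfigError(f"unknown filter source {source!r}")


class StreamingIIR:
    """Recursive filter with carried state for chunkwise (real-time) use.

    y[n] = sum_k b[k] x[n-k] - sum_{k>=1} a[k] y[n-k], zero initial state.
    Processing a signal in chunks of any sizes produces bit-identical output
    to a single pass, because the direct-form state is carried across calls.
    """

    def __init__(self, coeffs: IIRCoefficients, precision: Precision = "double"):
        if precision not in ("double", "single"):
            raise ConfigError(f"unknown precision {precision!r}")
        self.precision = precision
        dtype = np.float64 if precision == "double" else np.float32
        self.b = coeffs.b.astype(dtype)
        self.a = coeffs.a.astype(dtype)
        self.coeffs = coeffs
        if not coeffs.is_stable():
            warnings.warn(
                f"filter {coeffs.label!r} has a pole on or outside the unit "
                "circle; output may drift", stacklevel=2)
        n_state = max(len(self.b), len(self.a)) - 1
        self._zi = np.zeros(n_state, dtype=dtype)

    def process(self, chunk: np.ndarray) -> np.ndarray:
        chunk = np.asarray(chunk, dtype=self.b.dtype)
        if len(chunk) == 0:
            return chunk.copy()
        if not np.all(np.isfinite(chunk)):
            raise ValueError("non-finite sample in filter input")
        y, self._zi = signal.lfilter(self.b, self.a, chunk, zi=self._zi)
        return y


def apply_iir(
    coeffs: IIRCoefficients,
    x: np.ndarray,
    precision: Precision = "double",
) -> np.ndarray:
    """Filter a whole signal causally from zero initial state."""
    return StreamingIIR(coeffs, precision).process(np.asarray(x, dtype=float))


def segment_signal(
    x: np.ndarray, window: int = 1024, hop: int = 512
) -> list[np.ndarray]:
    """Slice a signal into fixed windows at offsets 0, hop, 2*hop, ...

    The trailing partial window is discarded; an input shorter than one
    window yields an empty list.  The default 1024-point window with
    512-point overlap gives 2.048 s segments at 500 Hz.
    """
    if window <= 0 or not 0 < hop <= window:
        raise ConfigError(f"invalid segmentation window={window} hop={hop}")
    x = np.asarray(x)
    n = len(x)
    if n < window:
        return []
    count = (n - window) // hop + 1
    return [x[i * hop: i * hop + window] for i in range(count)]


@dataclass
class Segment:
    """One analysis window of both channels, with its position in the session."""

    bcg: np.ndarray
    ipg: np.ndarray
    start_index: int
    fs: float


def segment_session(
    session: BiosignalSession, window: int = 1024, hop: int = 512
) -> list[Segment]:
    """Segment both channels of a session jointly."""
    bs = segment_signal(session.bcg, window, hop)
    is_ = segment_signal(session.ipg, window, hop)
    return [
        Segment(bcg=b, ipg=i, start_index=k * hop, fs=session.fs)
        for k, (b, i) in enumerate(zip(bs, is_))
    ]


def filter_session(
    session: BiosignalSession,
    source: str = "designed",
    precision: Precision = "double",
) -> BiosignalSession:
    """Apply the two-stage (high-pass then low-pass) bank to both channels."""
    bank = filter_bank(source, session.fs)
    bcg = apply_iir(bank["bcg_lp"], apply_iir(bank["bcg_hp"], session.bcg, precision), precision)
    ipg = apply_iir(bank["ipg_lp"], apply_iir(bank["ipg_hp"], session.ipg, precision), precision)
    return BiosignalSession(
        subject_id=session.subject_id, phase=session.phase, fs=session.fs,
        bcg=bcg, ipg=ipg, cuff_readings=list(session.cuff_readings),
        calibration=session.calibration,
    )
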