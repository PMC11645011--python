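"""Evaluation metrics for blood-pressure estimates.

Three quantities summarize agreement between target (cuff-referenced) and
estimated pressures: the Pearson correlation coefficient (PCC), the mean
error ME = mean(y - x), and the mean absolute error MAE = mean(|y - x|).
ME and MAE are reported as mean +/- sample standard deviation of the
per-sample (absolute) errors, with (n-1) normalization.

An optional helper grades an estimator on the British Hypertension Society
scale from the cumulative fractions of absolute errors within 5, 10 and
15 mmHg; those thresholds come from the BHS protocol itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ScalebpError


def _check_pair(x, y, min_n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ScalebpError(f"metric inputs must be equal-length 1-D, got {x.shape} vs {y.shape}")
    if len(x) < min_n:
        raise ScalebpError(f"metric requires at least {min_n} samples, got {len(x)}")
    return x, y


def pcc(x, y) -> float:
    """Pearson correlation between targets ``x`` and estimates ``y``."""
    x, y = _check_pair(x, y, min_n=2)
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        raise ScalebpError("correlation undefined: an input has zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def me(x, y) -> tuple[float, float]:
    """Mean signed error (y - x) and its sample standard deviation."""
    x, y = _check_pair(x, y)
    err = y - x
    sd = float(np.std(err, ddof=1)) if len(err) > 1 else 0.0
    return float(np.mean(err)), sd


def mae(x, y) -> tuple[float, float]:
    """Mean absolute error |y - x| and its sample standard deviation."""
    x, y = _check_pair(x, y)
    err = np.abs(y - x)
    sd = float(np.std(err, ddof=1)) if len(err) > 1 else 0.0
    return float(np.mean(err)), sd


@dataclass(frozen=True)
class EvalReport:
    """PCC / ME / MAE summary for one target (SBP or DBP)."""

    pcc: float
    me: float
    me_sd: float
    mae: float
    mae_sd: float
    n: int

    def as_dict(self) -> dict:
        return {
            "pcc": self.pcc, "me": self.me, "me_sd": self.me_sd,
            "mae": self.mae, "mae_sd": self.mae_sd, "n": self.n,
        }


def evaluate(x, y) -> EvalReport:
    """Full report for one target/estimate pair."""
    m, m_sd = me(x, y)
    a, a_sd = mae(x, y)
    return EvalReport(pcc=pcc(x, y), me=m, me_sd=m_sd, mae=a, mae_sd=a_sd,
                      n=len(np.asarray(x)))


#: BHS cumulative-error thresholds: fractions within 5/10/15 mmHg per grade.
BHS_GRADES = {
    "A": (0.60, 0.85, 0.95),
    "B": (0.50, 0.75, 0.90),
    "C": (0.40, 0.65, 0.85),
}


def bhs_grade(x, y) -> str:
    """BHS grade (A/B/C/D) from cumulative absolute-error percentages."""
    x, y = _check_pair(x, y)
    err = np.abs(y - x)
    frac = tuple(float(np.mean(err <= t)) for t in (5.0, 10.0, 15.0))
    for grade, needs in BHS_GRADES.items():
        if all(f >= need for f, need in zip(frac, needs)):
            return grade
    return "D"
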