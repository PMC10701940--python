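"""Figures of merit for calibration and validation.

Per analyte: RMSEC/RMSEP, percentage recoveries with mean and RSD,
the predicted-vs-actual regression line, and detection/quantitation limits
LOD = 3.3 (s/S) and LOQ = 10 (s/S), where S is the slope of the
predicted-vs-actual line and s a residual standard deviation about it.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy import stats as sps

__all__ = [
    "RegressionMerit",
    "AnalyteMerit",
    "MeritReport",
    "rmse",
    "recovery_stats",
    "predicted_vs_actual",
    "lod_loq",
    "merit_report",
]


def rmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """Root mean square error, dividing by n (no df correction).

    Used with calibration rows for RMSEC and validation rows for RMSEP.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be equal-length non-empty vectors")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def recovery_stats(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Per-sample recovery% (100 * pred/truth), mean%, and RSD%.

    RSD uses the sample standard deviation (n - 1 denominator).
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if np.any(truth <= 0):
        raise ValueError("recovery undefined for non-positive true concentrations")
    rec = 100.0 * pred / truth
    mean = float(np.mean(rec))
    rsd = float(100.0 * np.std(rec, ddof=1) / mean) if rec.size > 1 else 0.0
    return rec, mean, rsd


@dataclasses.dataclass(frozen=True)
class RegressionMerit:
    """Predicted-vs-actual straight line: pred = intercept + slope * actual."""

    slope: float
    intercept: float
    r: float
    residual_sd: float  # sd of residuals about the line, n-2 denominator


def predicted_vs_actual(pred: np.ndarray, truth: np.ndarray) -> RegressionMerit:
    """Ordinary least-squares line of predicted on actual concentrations."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.size < 3:
        raise ValueError("need at least 3 points for the merit regression")
    res = sps.linregress(truth, pred)
    resid = pred - (res.intercept + res.slope * truth)
    s = float(np.sqrt(np.sum(resid**2) / (pred.size - 2)))
    return RegressionMerit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        residual_sd=s,
    )


def lod_loq(merit: RegressionMerit) -> tuple[float, float]:
    """LOD = 3.3 s/S and LOQ = 10 s/S from the merit regression."""
    if merit.slope == 0:
        raise ValueError("LOD/LOQ undefined for zero calibration slope")
    s_over_S = merit.residual_sd / merit.slope
    return 3.3 * s_over_S, 10.0 * s_over_S


@dataclasses.dataclass(frozen=True)
class AnalyteMerit:
    analyte: str
    rmsec: float
    rmsep: float
    recoveries: tuple[float, ...]  # validation samples, %
    mean_recovery: float
    rsd: float
    regression: RegressionMerit
    lod: float
    loq: float


@dataclasses.dataclass(frozen=True)
class MeritReport:
    analytes: tuple[AnalyteMerit, ...]

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    **{
                        k: v
                        for k, v in dataclasses.asdict(a).items()
                        if k != "regression"
                    },
                    "regression": dataclasses.asdict(a.regression),
                }
                for a in self.analytes
            ]
        )

    @classmethod
    def from_json(cls, text: str) -> "MeritReport":
        rows = json.loads(text)
        return cls(
            analytes=tuple(
                AnalyteMerit(
                    analyte=r["analyte"],
                    rmsec=r["rmsec"],
                    rmsep=r["rmsep"],
                    recoveries=tuple(r["recoveries"]),
                    mean_recovery=r["mean_recovery"],
                    rsd=r["rsd"],
                    regression=RegressionMerit(**r["regression"]),
                    lod=r["lod"],
                    loq=r["loq"],
                )
                for r in rows
            )
        )

    def to_text(self) -> str:
        """Two-decimal tabular rendering of the main merit figures."""
        lines = [
            f"{'analyte':<8}{'RMSEC':>8}{'RMSEP':>8}{'mean%':>9}{'RSD%':>7}"
            f"{'slope':>9}{'r':>9}{'LOD':>8}{'LOQ':>8}"
        ]
        for a in self.analytes:
            lines.append(
                f"{a.analyte:<8}{a.rmsec:>8.2f}{a.rmsep:>8.2f}"
                f"{a.mean_recovery:>9.2f}{a.rsd:>7.2f}{a.regression.slope:>9.4f}"
                f"{a.regression.r:>9.4f}{a.lod:>8.2f}{a.loq:>8.2f}"
            )
        return "\n".join(lines)


def merit_report(
    analytes,
    Y_cal_true: np.ndarray,
    Y_cal_pred: np.ndarray,
    Y_val_true: np.ndarray,
    Y_val_pred: np.ndarray,
) -> MeritReport:
    """Assemble the full per-analyte merit report for one calibration model."""
    out = []
    for k, name in enumerate(analytes):
        reg = predicted_vs_actual(Y_cal_pred[:, k], Y_cal_true[:, k])
        lod, loq = lod_loq(reg)
        rec, mean, rsd = recovery_stats(Y_val_pred[:, k], Y_val_true[:, k])
        out.append(
            AnalyteMerit(
                analyte=str(name),
                rmsec=rmse(Y_cal_pred[:, k], Y_cal_true[:, k]),
                rmsep=rmse(Y_val_pred[:, k], Y_val_true[:, k]),
                recoveries=tuple(float(r) for r in rec),
                mean_recovery=mean,
                rsd=rsd,
                regression=reg,
                lod=lod,
                loq=loq,
            )
        )
    return MeritReport(analytes=tuple(out))
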