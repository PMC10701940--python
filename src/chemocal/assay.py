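"""Dosage-form assay arithmetic: dilutions, standard spiking, label claim.

The tablet assay dissolves powdered tablets to a stock (nominally
5000.00 ug/mL paracetamol, 100.00 ug/mL hyoscine butylbromide), dilutes
2.5 -> 100 mL to a working solution (125.00 / 2.50 ug/mL) and again
1 -> 25 mL to the measured solution (5.00 / 0.10 ug/mL).  Because
0.10 ug/mL hyoscine sits far below the calibrated 16-24 ug/mL range, the
measured solution is spiked with 16.00 ug/mL of hyoscine standard; the
spike is subtracted from the predicted value before computing the label
claim percentage.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .design import ANALYTES

__all__ = [
    "DilutionStep",
    "AssayPlan",
    "DEFAULT_ASSAY_PLAN",
    "dilute",
    "dilution_chain",
    "apply_spike_and_predict",
    "label_claim_percent",
]

HYO_INDEX = ANALYTES.index("HYO")


@dataclasses.dataclass(frozen=True)
class DilutionStep:
    """Transfer ``taken_volume`` mL into a ``final_volume`` mL flask."""

    taken_volume: float
    final_volume: float

    def __post_init__(self) -> None:
        if not (0 < self.taken_volume <= self.final_volume):
            raise ValueError(
                f"need 0 < taken ({self.taken_volume}) <= final ({self.final_volume})"
            )

    @property
    def factor(self) -> float:
        return self.taken_volume / self.final_volume


def dilute(concentration: float, step: DilutionStep) -> float:
    """c_out = c_in * taken/final (ug/mL)."""
    return concentration * step.factor


def dilution_chain(concentration: float, steps: Sequence[DilutionStep]) -> float:
    """Compose dilutions: the overall factor is the product of step factors."""
    for step in steps:
        concentration = dilute(concentration, step)
    return concentration


@dataclasses.dataclass(frozen=True)
class AssayPlan:
    """Nominal amounts, stock concentrations, dilution chain and HYO spike."""

    label_claim_mg: dict = dataclasses.field(
        default_factory=lambda: {"PAR": 500.0, "HYO": 10.0}
    )
    stock_ug_per_ml: dict = dataclasses.field(
        default_factory=lambda: {"PAR": 5000.0, "HYO": 100.0}
    )
    chain: tuple[DilutionStep, ...] = (
        DilutionStep(2.5, 100.0),
        DilutionStep(1.0, 25.0),
    )
    spike_hyo_ug_per_ml: float = 16.0

    def __post_init__(self) -> None:
        if self.spike_hyo_ug_per_ml < 0:
            raise ValueError("spike must be >= 0")
        if any(v <= 0 for v in self.stock_ug_per_ml.values()):
            raise ValueError("stock concentrations must be > 0")

    def nominal_final(self, analyte: str) -> float:
        """Nominal concentration in the measured flask, before spiking."""
        return dilution_chain(self.stock_ug_per_ml[analyte], self.chain)


DEFAULT_ASSAY_PLAN = AssayPlan()


def apply_spike_and_predict(
    model,
    sample_spectrum: np.ndarray,
    spike_conc: float,
    *,
    negative_tolerance: float = 0.05,
) -> np.ndarray:
    """Predict all six analytes, then subtract the HYO spike.

    ``model`` is any fitted calibration model with a ``predict`` method.
    Raises if the spike-corrected HYO concentration is meaningfully
    negative, which flags failed spike accounting.
    """
    if spike_conc < 0:
        raise ValueError("spike concentration must be >= 0")
    pred = np.asarray(model.predict(sample_spectrum), dtype=float).reshape(-1)
    if pred.size != len(ANALYTES):
        raise ValueError(f"model must predict {len(ANALYTES)} analytes")
    corrected = pred.copy()
    corrected[HYO_INDEX] -= spike_conc
    if corrected[HYO_INDEX] < -negative_tolerance:
        raise ValueError(
            f"spike accounting failed: corrected HYO = {corrected[HYO_INDEX]:.4f} "
            f"ug/mL is below -{negative_tolerance}"
        )
    return corrected


def label_claim_percent(found: float, nominal: float) -> float:
    """100 * found/nominal, the percentage of the declared content found."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be > 0")
    return 100.0 * found / nominal
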