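"""Multilevel multifactor calibration design.

Builds the five-level, six-factor, 25-run concentration design used to
calibrate the six-component system (paracetamol, hyoscine butylbromide and
the four toxic impurities p-nitrophenol, p-chloroacetanilide, tropic acid
and p-aminophenol).  The design has a centre-point first run followed by 24
runs generated by cyclically rotating a single length-24 level sequence, so
that every factor column contains each coded level in {-2..+2} exactly five
times.  Coded levels map affinely to concentrations in ug/mL.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "FactorSpec",
    "DEFAULT_FACTORS",
    "DESIGN_GENERATOR",
    "DEFAULT_VALIDATION_IDS",
    "CodedDesign",
    "ConcentrationDesign",
    "build_coded_design",
    "to_concentrations",
    "split_sets",
    "reference_design",
    "write_design_csv",
    "read_design_csv",
]

#: Analyte column order used throughout the package.
ANALYTES: tuple[str, ...] = ("PAR", "HYO", "PNP", "PCA", "TRO", "PAP")

N_RUNS = 25
N_FACTORS = 6
LEVELS = (-2, -1, 0, 1, 2)

#: The length-24 cyclic difference column of the published design, decoded
#: from the printed concentration table.  Run 1 is the all-centre point;
#: run i (i >= 2) of factor k equals ``DESIGN_GENERATOR[(i - 2 + k - 1) % 24]``.
DESIGN_GENERATOR: tuple[int, ...] = (
    0, -2, -2, 2, -1, 2, 0, -1, -1, 1, 2, 1,
    0, 2, 2, -2, 1, -2, 0, 1, 1, -1, -2, -1,
)

#: 1-based run numbers of the published validation (cross-validation) set.
DEFAULT_VALIDATION_IDS: frozenset[int] = frozenset({5, 8, 10, 11, 14, 15, 17, 22})


@dataclasses.dataclass(frozen=True)
class FactorSpec:
    """Affine map from coded level to concentration for one analyte.

    ``conc = center + level * step`` (ug/mL).  ``center - 2 * step`` must stay
    strictly positive so every design concentration is positive.
    """

    name: str
    center: float
    step: float

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"{self.name}: step must be > 0, got {self.step}")
        if self.center - 2 * self.step <= 0:
            raise ValueError(
                f"{self.name}: center - 2*step = {self.center - 2 * self.step} "
                "must be strictly positive"
            )

    def concentration(self, level: int) -> float:
        return self.center + level * self.step


#: Published factor ranges: PAR 4-8, HYO 16-24, PNP 1-5, PCA 0.4-0.8,
#: TRO 4-12, PAP 2-6 ug/mL, i.e. (center, step) per factor.
DEFAULT_FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("PAR", 6.0, 1.0),
    FactorSpec("HYO", 20.0, 2.0),
    FactorSpec("PNP", 3.0, 1.0),
    FactorSpec("PCA", 0.6, 0.1),
    FactorSpec("TRO", 8.0, 2.0),
    FactorSpec("PAP", 4.0, 1.0),
)


@dataclasses.dataclass(frozen=True)
class CodedDesign:
    """25 x 6 matrix of coded levels plus the generator it was built from."""

    levels: np.ndarray
    generator: tuple[int, ...]

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=int)
        if lv.shape != (N_RUNS, N_FACTORS):
            raise ValueError(f"levels must be {N_RUNS}x{N_FACTORS}, got {lv.shape}")
        object.__setattr__(self, "levels", lv)


@dataclasses.dataclass(frozen=True)
class ConcentrationDesign:
    """Concentration matrix (ug/mL) with its calibration/validation split.

    Run ids are 1-based to match the printed mixture numbers.
    """

    concentrations: np.ndarray
    calibration_ids: frozenset[int]
    validation_ids: frozenset[int]
    analytes: tuple[str, ...] = ANALYTES

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        n = conc.shape[0]
        cal, val = set(self.calibration_ids), set(self.validation_ids)
        if cal & val:
            raise ValueError("calibration and validation ids overlap")
        if cal | val != set(range(1, n + 1)):
            raise ValueError("calibration and validation ids must partition runs")
        object.__setattr__(self, "calibration_ids", frozenset(cal))
        object.__setattr__(self, "validation_ids", frozenset(val))

    @property
    def n_runs(self) -> int:
        return self.concentrations.shape[0]

    def rows(self, ids: Iterable[int]) -> np.ndarray:
        idx = np.array(sorted(ids), dtype=int) - 1
        return self.concentrations[idx]

    @property
    def calibration(self) -> np.ndarray:
        """Calibration-set concentrations in run order (17 x 6 by default)."""
        return self.rows(self.calibration_ids)

    @property
    def validation(self) -> np.ndarray:
        """Validation-set concentrations in run order (8 x 6 by default)."""
        return self.rows(self.validation_ids)


def _check_generator(generator: Sequence[int], permissive: bool) -> tuple[int, ...]:
    gen = tuple(int(g) for g in generator)
    if len(gen) != N_RUNS - 1:
        raise ValueError(f"generator must have length {N_RUNS - 1}, got {len(gen)}")
    if any(g not in LEVELS for g in gen):
        raise ValueError("generator entries must lie in {-2,-1,0,1,2}")
    if not permissive:
        counts = {lv: gen.count(lv) for lv in LEVELS}
        # With the centre-point first run each column then holds every level
        # exactly five times.
        expected = {-2: 5, -1: 5, 0: 4, 1: 5, 2: 5}
        if counts != expected:
            raise ValueError(
                f"unbalanced generator: level counts {counts}, expected {expected} "
                "(pass permissive=True to bypass)"
            )
    return gen


def build_coded_design(
    generator: Sequence[int] = DESIGN_GENERATOR, *, permissive: bool = False
) -> CodedDesign:
    """Build the 25-run coded design from a length-24 cyclic generator.

    Run 1 is the all-zero centre point; for runs 2-25 factor column ``k``
    equals the generator cyclically rotated by ``k - 1`` positions.  Set
    ``permissive=True`` to skip the level-balance check (e.g. for degenerate
    test designs).
    """
    gen = _check_generator(generator, permissive)
    levels = np.zeros((N_RUNS, N_FACTORS), dtype=int)
    for i in range(2, N_RUNS + 1):
        for k in range(1, N_FACTORS + 1):
            levels[i - 1, k - 1] = gen[(i - 2 + k - 1) % (N_RUNS - 1)]
    return CodedDesign(levels=levels, generator=gen)


def to_concentrations(
    coded: CodedDesign,
    factors: Sequence[FactorSpec] = DEFAULT_FACTORS,
    validation_ids: Iterable[int] = DEFAULT_VALIDATION_IDS,
) -> ConcentrationDesign:
    """Map coded levels to concentrations (ug/mL), rounded to 2 decimals.

    Factor order must match the analyte column order PAR, HYO, PNP, PCA,
    TRO, PAP.  Raises if any resulting concentration is not positive.
    """
    if len(factors) != N_FACTORS:
        raise ValueError(f"expected {N_FACTORS} factors, got {len(factors)}")
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    conc = centers + coded.levels * steps
    # Stored at 2 dp, matching how the design is printed and pipetted.
    conc = np.round(conc, 2)
    if np.any(conc <= 0):
        bad = np.argwhere(conc <= 0)[0]
        raise ValueError(
            f"non-positive concentration at run {bad[0] + 1}, "
            f"factor {factors[bad[1]].name}"
        )
    return ConcentrationDesign(
        concentrations=conc,
        calibration_ids=frozenset(range(1, N_RUNS + 1)) - frozenset(validation_ids),
        validation_ids=frozenset(validation_ids),
    )


def split_sets(
    design: ConcentrationDesign,
    validation_ids: Iterable[int] | None = None,
    *,
    seed: int | None = None,
    n_validation: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (calibration, validation) concentration matrices.

    Either pass an explicit id set, or a ``seed`` to draw ``n_validation``
    runs at random (reproducibly).  With neither, the design's stored split
    is used — by default the published 17/8 partition.
    """
    n = design.n_runs
    if validation_ids is not None and seed is not None:
        raise ValueError("pass either validation_ids or seed, not both")
    if validation_ids is not None:
        ids = [int(i) for i in validation_ids]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate validation ids")
        if any(i < 1 or i > n for i in ids):
            raise ValueError(f"validation ids must lie in 1..{n}")
        val = frozenset(ids)
    elif seed is not None:
        rng = np.random.default_rng(seed)
        val = frozenset(rng.choice(n, size=n_validation, replace=False) + 1)
    else:
        val = design.validation_ids
    cal = frozenset(range(1, n + 1)) - val
    return design.rows(cal), design.rows(val)


def reference_design() -> ConcentrationDesign:
    """The published 25-mixture design with its 17/8 calibration split."""
    return to_concentrations(build_coded_design())


# ---------------------------------------------------------------------------
# CSV interface: header mix_no,PAR,HYO,PNP,PCA,TRO,PAP,set  (set in {cal,val})

def write_design_csv(design: ConcentrationDesign, path) -> None:
    df = pd.DataFrame(design.concentrations, columns=list(design.analytes))
    df.insert(0, "mix_no", np.arange(1, design.n_runs + 1))
    df["set"] = ["val" if i in design.validation_ids else "cal" for i in df["mix_no"]]
    for col in design.analytes:
        df[col] = df[col].map(lambda x: f"{x:.2f}")
    df.to_csv(path, index=False)


def read_design_csv(path) -> ConcentrationDesign:
    df = pd.read_csv(path)
    required = {"mix_no", "set", *ANALYTES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design CSV missing columns: {sorted(missing)}")
    df = df.sort_values("mix_no")
    val = frozenset(int(i) for i in df.loc[df["set"] == "val", "mix_no"])
    cal = frozenset(int(i) for i in df.loc[df["set"] == "cal", "mix_no"])
    return ConcentrationDesign(
        concentrations=df[list(ANALYTES)].to_numpy(dtype=float),
        calibration_ids=cal,
        validation_ids=val,
    )
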