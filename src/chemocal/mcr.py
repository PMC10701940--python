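"""Multivariate curve resolution by alternating least squares (MCR-ALS).

Factorizes an absorbance matrix ``A`` (samples x wavelengths) into
non-negative concentration profiles ``C`` and spectral profiles ``S`` so
that ``A = C @ S.T + E``.  The pieces:

* :func:`fnnls` — fast non-negativity-constrained least squares (active-set
  method working on the normal-equation cross-products), the per-row /
  per-column solver inside constrained ALS.
* :func:`simplisma_init` — purest-variable selection (SIMPLISMA) providing
  the initial spectral estimate from the data alone.
* :func:`run_mcr_als` — the alternating optimization with lack-of-fit /
  explained-variance diagnostics and a relative-lof convergence rule
  (default threshold 0.1%).
* :func:`quantify_from_profiles` — pseudo-univariate calibration of the
  resolved concentration profiles against known calibration concentrations,
  which turns the curve resolution into a quantitative model.

The bilinear factorization is only defined up to permutation and positive
scaling of paired (C, S) columns; spectral columns are renormalized to unit
Euclidean norm after every iteration, and quantitation aligns components to
analytes by correlation, so results are invariant to both ambiguities.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

__all__ = [
    "McrConfig",
    "McrDecomposition",
    "SimplismaResult",
    "ComponentCollapseWarning",
    "fnnls",
    "simplisma_init",
    "run_mcr_als",
    "quantify_from_profiles",
    "McrQuantification",
]


class ComponentCollapseWarning(UserWarning):
    """A resolved concentration or spectral profile became identically zero."""


def fnnls(Z: np.ndarray, b: np.ndarray, tol: float | None = None) -> np.ndarray:
    """Solve ``min ||Z x - b||^2  s.t. x >= 0`` (fast NNLS, Bro & de Jong).

    Operates on the cross-products ``Z'Z`` and ``Z'b``, which is what makes
    it fast when called repeatedly with the same ``Z`` shape inside ALS.
    The solution satisfies the KKT conditions: ``x >= 0``, gradient
    ``w = Z'b - Z'Z x <= tol`` on the zero set and ``|w| <= tol`` on the
    positive set.
    """
    Z = np.asarray(Z, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(Z)) and np.all(np.isfinite(b))):
        raise ValueError("fnnls requires finite inputs")
    return _fnnls_gram(Z.T @ Z, Z.T @ b, tol)


def _fnnls_gram(ZtZ: np.ndarray, Ztb: np.ndarray, tol: float | None = None) -> np.ndarray:
    """fnnls core operating on precomputed cross-products."""
    n = ZtZ.shape[0]
    if tol is None:
        tol = 10 * np.finfo(float).eps * np.linalg.norm(ZtZ, 1) * max(n, 1)
    x = np.zeros(n)
    passive = np.zeros(n, dtype=bool)
    w = Ztb - ZtZ @ x
    max_outer = 30 * n
    for _ in range(max_outer):
        if passive.all() or np.all(w[~passive] <= tol):
            break
        j = int(np.argmax(np.where(~passive, w, -np.inf)))
        passive[j] = True
        while True:
            s = np.zeros(n)
            idx = np.where(passive)[0]
            s[idx] = np.linalg.lstsq(ZtZ[np.ix_(idx, idx)], Ztb[idx], rcond=None)[0]
            if np.all(s[idx] > tol):
                x = s
                break
            # step toward s until the first passive variable hits zero
            neg = idx[s[idx] <= tol]
            alpha = np.min(x[neg] / (x[neg] - s[neg]))
            x = x + alpha * (s - x)
            passive &= x > tol
            x[~passive] = 0.0
        w = Ztb - ZtZ @ x
    return x


def _nnls_columns(Z: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise fnnls: solve min ||Z X - B|| with X >= 0, B has many columns.

    Solves the unconstrained normal equations for all columns at once and
    reruns fnnls only on columns whose solution goes negative, which is what
    keeps the ALS inner loops fast.
    """
    ZtZ = Z.T @ Z
    ZtB = Z.T @ B
    try:
        X = np.linalg.solve(ZtZ, ZtB)
    except np.linalg.LinAlgError:
        X = np.linalg.lstsq(ZtZ, ZtB, rcond=None)[0]
    bad = np.where(X.min(axis=0) < 0)[0]
    for j in bad:
        X[:, j] = _fnnls_gram(ZtZ, ZtB[:, j])
    return X


# ---------------------------------------------------------------------------
# SIMPLISMA

@dataclasses.dataclass(frozen=True)
class SimplismaResult:
    """Purest-variable selection output.

    ``S0`` is the initial spectral estimate (wavelengths x components),
    ``wavelength_indices`` the selected purest grid indices in selection
    order, and ``purity`` the first-pass purity value of every variable.
    """

    S0: np.ndarray
    wavelength_indices: tuple[int, ...]
    purity: np.ndarray


def simplisma_init(
    A: np.ndarray, n_components: int, noise_allowance_percent: float = 5.0
) -> SimplismaResult:
    """SIMPLISMA initial estimate of the spectral profiles.

    Variables are wavelengths (columns of ``A``).  The purity of variable j
    is ``p_j = sigma_j / (mu_j + alpha)`` with ``alpha`` the noise allowance
    (a percentage of the largest column mean); successive selections are
    orthogonalized with the determinant-based weight computed from the
    correlation-around-the-origin matrix of the length-scaled variables.
    The concentration directions at the purest wavelengths then give the
    spectral estimate by non-negative least squares.
    """
    A = np.asarray(A, dtype=float)
    n_samples, n_vars = A.shape
    if n_components < 1 or n_components > min(n_samples, n_vars):
        raise ValueError(f"n_components must lie in 1..{min(n_samples, n_vars)}")
    mu = A.mean(axis=0)
    sigma = A.std(axis=0)  # population sd, standard in SIMPLISMA
    if np.max(mu) <= 0 and np.max(sigma) <= 0:
        raise ValueError("degenerate all-zero matrix")
    alpha = (noise_allowance_percent / 100.0) * np.max(mu)
    base_purity = sigma / (mu + alpha)
    if np.max(sigma) == 0:
        raise ValueError("constant matrix: zero purity everywhere")
    # length-scaled variables for the determinant weights
    lam = np.sqrt(mu**2 + (sigma + alpha) ** 2)
    Y = A / lam
    COO = (Y.T @ Y) / n_samples
    selected: list[int] = []
    for _ in range(n_components):
        weights = np.empty(n_vars)
        for j in range(n_vars):
            idx = [j] + selected
            weights[j] = np.linalg.det(COO[np.ix_(idx, idx)])
        purity = base_purity * weights
        purity[selected] = -np.inf
        selected.append(int(np.argmax(purity)))
    # Concentration directions at the purest wavelengths -> spectra by NNLS.
    C0 = A[:, selected]
    S0 = _nnls_columns(C0, A).T  # wavelengths x components
    return SimplismaResult(
        S0=S0, wavelength_indices=tuple(selected), purity=base_purity
    )


# ---------------------------------------------------------------------------
# ALS

@dataclasses.dataclass(frozen=True)
class McrConfig:
    """ALS settings: component count, constraint toggles, stopping rule."""

    n_components: int = 6
    nonneg_C: bool = True
    nonneg_S: bool = True
    convergence_tol: float = 0.001  # relative lof change (0.001 = 0.1%)
    max_iterations: int = 200

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")


@dataclasses.dataclass(frozen=True)
class McrDecomposition:
    """Resolved bilinear factorization ``A = C @ S.T + E`` with diagnostics.

    ``lof_percent = 100 * sqrt(sum(E^2) / sum(A^2))`` and
    ``r2_percent = 100 * (1 - sum(E^2)/sum(A^2))``, so the two always obey
    ``r2 = 100 - lof^2 / 100``.
    """

    C: np.ndarray
    S: np.ndarray
    E: np.ndarray
    lof_percent: float
    r2_percent: float
    n_iterations: int
    converged: bool
    collapsed: bool = False


def _lof(A: np.ndarray, C: np.ndarray, S: np.ndarray) -> float:
    E = A - C @ S.T
    return 100.0 * np.sqrt(np.sum(E**2) / np.sum(A**2))


def run_mcr_als(
    A: np.ndarray, S0: np.ndarray, config: McrConfig | None = None
) -> McrDecomposition:
    """Alternating least squares from an initial spectral estimate.

    Each iteration solves C given S, then S given C (non-negatively via
    fnnls when the corresponding constraint is on), renormalizes the
    spectral columns to unit Euclidean norm (moving the scale into C), and
    stops when the relative lack-of-fit change drops below the threshold,
    the fit is exact, or ``max_iterations`` is reached.
    """
    if config is None:
        config = McrConfig(n_components=np.asarray(S0).shape[1])
    A = np.asarray(A, dtype=float)
    S = np.asarray(S0, dtype=float).copy()
    if S.shape != (A.shape[1], config.n_components):
        raise ValueError(
            f"S0 must be {A.shape[1]} x {config.n_components}, got {S.shape}"
        )
    lof_prev = np.inf
    converged = False
    it = 0
    C = np.zeros((A.shape[0], config.n_components))
    for it in range(1, config.max_iterations + 1):
        if config.nonneg_C:
            C = _nnls_columns(S, A.T).T
        else:
            C = np.linalg.lstsq(S, A.T, rcond=None)[0].T
        if config.nonneg_S:
            S = _nnls_columns(C, A).T
        else:
            S = np.linalg.lstsq(C, A, rcond=None)[0].T
        norms = np.linalg.norm(S, axis=0)
        ok = norms > 0
        S[:, ok] /= norms[ok]
        C[:, ok] *= norms[ok]
        lof = _lof(A, C, S)
        if lof <= 1e-10:
            converged = True
            break
        if np.isfinite(lof_prev) and lof_prev > 0:
            if abs(lof - lof_prev) / lof_prev < config.convergence_tol:
                converged = True
                break
        lof_prev = lof
    E = A - C @ S.T
    ss_res, ss_tot = np.sum(E**2), np.sum(A**2)
    lof = 100.0 * np.sqrt(ss_res / ss_tot)
    r2 = 100.0 * (1.0 - ss_res / ss_tot)
    collapsed = bool(np.any(np.all(C == 0, axis=0)) or np.any(np.all(S == 0, axis=0)))
    if collapsed:
        warnings.warn(
            "MCR-ALS component collapse: at least one resolved profile is "
            "identically zero",
            ComponentCollapseWarning,
            stacklevel=2,
        )
    return McrDecomposition(
        C=C, S=S, E=E, lof_percent=lof, r2_percent=r2,
        n_iterations=it, converged=converged, collapsed=collapsed,
    )


# ---------------------------------------------------------------------------
# Quantitation from resolved profiles

@dataclasses.dataclass(frozen=True)
class McrQuantification:
    """Per-analyte straight lines fitted to resolved profiles + predictions.

    ``assignment[k]`` is the resolved-component index matched to analyte k;
    ``slopes``/``intercepts`` parametrize resolved-vs-known lines on the
    calibration rows; ``predictions`` are inverted concentrations for the
    non-calibration rows (in row order of ``unknown_rows``).
    """

    assignment: tuple[int, ...]
    slopes: np.ndarray
    intercepts: np.ndarray
    predictions: np.ndarray
    unknown_rows: tuple[int, ...]


def quantify_from_profiles(
    decomp: McrDecomposition,
    cal_rows: Sequence[int],
    Y_cal: np.ndarray,
) -> McrQuantification:
    """Quantify unknowns from an augmented-matrix decomposition.

    ``cal_rows`` are the 0-based row indices of the calibration samples in
    the matrix the decomposition was computed on; all other rows are treated
    as unknowns.  Components are aligned to analytes by the maximum absolute
    correlation between resolved concentration columns (calibration rows)
    and the known concentrations; an ambiguous alignment (two analytes
    claiming one component) raises.
    """
    Y_cal = np.asarray(Y_cal, dtype=float)
    cal_rows = [int(i) for i in cal_rows]
    C_cal = decomp.C[cal_rows]
    n_analytes = Y_cal.shape[1]
    if C_cal.shape[0] != Y_cal.shape[0]:
        raise ValueError("cal_rows and Y_cal row counts differ")
    corr = np.zeros((n_analytes, decomp.C.shape[1]))
    for k in range(n_analytes):
        for c in range(decomp.C.shape[1]):
            sd_y = np.std(Y_cal[:, k])
            sd_c = np.std(C_cal[:, c])
            if sd_y == 0 or sd_c == 0:
                corr[k, c] = 0.0
            else:
                corr[k, c] = np.corrcoef(Y_cal[:, k], C_cal[:, c])[0, 1]
    assignment = tuple(int(np.argmax(np.abs(corr[k]))) for k in range(n_analytes))
    if len(set(assignment)) != n_analytes:
        raise ValueError(
            f"ambiguous component-analyte alignment: assignment {assignment} "
            "maps two analytes to one resolved component"
        )
    unknown_rows = tuple(
        i for i in range(decomp.C.shape[0]) if i not in set(cal_rows)
    )
    slopes = np.empty(n_analytes)
    intercepts = np.empty(n_analytes)
    preds = np.empty((len(unknown_rows), n_analytes))
    for k, c in enumerate(assignment):
        y = Y_cal[:, k]
        x = C_cal[:, c]
        # resolved response vs known concentration: resolved = a + b * known
        b, a = np.polyfit(y, x, 1)
        if b == 0:
            raise ValueError(f"zero calibration slope for analyte column {k}")
        slopes[k], intercepts[k] = b, a
        preds[:, k] = (decomp.C[list(unknown_rows), c] - a) / b
    return McrQuantification(
        assignment=assignment,
        slopes=slopes,
        intercepts=intercepts,
        predictions=preds,
        unknown_rows=unknown_rows,
    )
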