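"""Direct multivariate calibration: PCR, PLS2 and a linear feed-forward net.

All three models map a 361-point absorbance spectrum to the six analyte
concentrations.  Spectra and concentrations are mean-centered at fit time
and the centering state is stored with the model, so prediction is always
``(x - x_mean) @ B + y_mean``.  The latent-variable count for PCR/PLS is
chosen by leave-one-out cross-validation (pooled RMSECV over all analytes).

The network mirrors the classical 361-6-6 feed-forward topology with linear
("purelin") transfer functions in both layers; since the composed map is
affine its optimum coincides with multiresponse ordinary least squares,
which makes the net a useful consistency check on the latent-variable
models.  It is trained by full-batch gradient descent on the mean squared
error from a small seeded random initialization.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

__all__ = [
    "CenteringState",
    "LatentModel",
    "AnnModel",
    "LvSelection",
    "fit_pcr",
    "fit_pls",
    "select_lv",
    "fit_ann",
    "save_model",
    "load_model",
]


@dataclasses.dataclass(frozen=True)
class CenteringState:
    """Column means removed from X and Y at fit time."""

    x_mean: np.ndarray
    y_mean: np.ndarray


def _center(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, CenteringState]:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    state = CenteringState(x_mean=X.mean(axis=0), y_mean=Y.mean(axis=0))
    return X - state.x_mean, Y - state.y_mean, state


@dataclasses.dataclass(frozen=True)
class LatentModel:
    """Fitted PCR or PLS model: prediction = (x - x_mean) @ B + y_mean."""

    kind: str  # "pcr" | "pls"
    n_lv: int
    B: np.ndarray  # n_wavelengths x n_analytes
    centering: CenteringState

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.centering.x_mean) @ self.B + self.centering.y_mean


@dataclasses.dataclass(frozen=True)
class AnnModel:
    """Linear-linear feed-forward network (input -> hidden -> output)."""

    W1: np.ndarray  # n_wavelengths x n_hidden
    b1: np.ndarray
    W2: np.ndarray  # n_hidden x n_outputs
    b2: np.ndarray
    centering: CenteringState
    epochs: int
    mse_history: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xc = X - self.centering.x_mean
        # purelin-purelin: both layers affine, composition is affine.
        return (Xc @ self.W1 + self.b1) @ self.W2 + self.b2 + self.centering.y_mean


@dataclasses.dataclass(frozen=True)
class LvSelection:
    """Leave-one-out RMSECV per candidate latent-variable count."""

    rmsecv: np.ndarray  # pooled over analytes, index h-1 -> h LVs
    per_analyte: np.ndarray  # max_lv x n_analytes
    chosen_lv: int


def _check_lv(n_cal: int, n_lv: int, rank: int) -> None:
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if n_lv > n_cal - 1:
        raise ValueError(f"n_lv={n_lv} needs at least {n_lv + 1} calibration samples")
    if n_lv > rank:
        raise ValueError(f"n_lv={n_lv} exceeds rank {rank} of the centered data")


def fit_pcr(X_cal: np.ndarray, Y_cal: np.ndarray, n_lv: int) -> LatentModel:
    """Principal component regression with ``n_lv`` components.

    Y is regressed on the scores of the first ``n_lv`` principal components
    of the centered spectra (components ordered by decreasing singular
    value).
    """
    Xc, Yc, state = _center(X_cal, Y_cal)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(Xc.shape) * np.finfo(float).eps)) if s.size else 0
    _check_lv(Xc.shape[0], n_lv, rank)
    # B = V_r diag(1/s_r) U_r' Yc  (regression of Yc on scores T = U_r S_r)
    B = Vt[:n_lv].T @ ((U[:, :n_lv].T @ Yc) / s[:n_lv, None])
    return LatentModel(kind="pcr", n_lv=n_lv, B=B, centering=state)


def fit_pls(
    X_cal: np.ndarray,
    Y_cal: np.ndarray,
    n_lv: int,
    *,
    max_inner_iter: int = 500,
    inner_tol: float = 1e-12,
) -> LatentModel:
    """NIPALS PLS2: one joint model for all six responses.

    Raises ``RuntimeError`` if a NIPALS inner loop fails to converge within
    ``max_inner_iter`` iterations.
    """
    Xc, Yc, state = _center(X_cal, Y_cal)
    rank = np.linalg.matrix_rank(Xc)
    _check_lv(Xc.shape[0], n_lv, rank)
    n, p = Xc.shape
    m = Yc.shape[1]
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((m, n_lv))
    Xd, Yd = Xc.copy(), Yc.copy()
    for a in range(n_lv):
        # start u from the Y column with the largest variance
        u = Yd[:, np.argmax(np.var(Yd, axis=0))].copy()
        if np.allclose(u, 0):
            u = Yd[:, 0] + 1e-12
        t_old = None
        for it in range(max_inner_iter):
            w = Xd.T @ u
            w /= np.linalg.norm(w)
            t = Xd @ w
            q = Yd.T @ t / (t @ t)
            u = Yd @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) <= inner_tol * np.linalg.norm(t):
                break
            t_old = t
        else:
            raise RuntimeError(
                f"NIPALS inner loop for component {a + 1} did not converge "
                f"within {max_inner_iter} iterations (last |t| change above "
                f"{inner_tol} relative); inspect the data for degeneracy"
            )
        p_vec = Xd.T @ t / (t @ t)
        W[:, a], P[:, a], Q[:, a] = w, p_vec, q
        Xd -= np.outer(t, p_vec)
        Yd -= np.outer(t, q)
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return LatentModel(kind="pls", n_lv=n_lv, B=B, centering=state)


_FITTERS = {"pcr": fit_pcr, "pls": fit_pls}


def select_lv(
    X_cal: np.ndarray, Y_cal: np.ndarray, max_lv: int, kind: str = "pls"
) -> LvSelection:
    """Leave-one-out cross-validation over 1..max_lv latent variables.

    RMSECV pools the squared prediction errors of all analytes
    (``sqrt(sum_err2 / (n * m))``); per-analyte curves are also returned.
    The chosen count is the smallest h attaining the minimum pooled RMSECV.
    """
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    X = np.asarray(X_cal, dtype=float)
    Y = np.asarray(Y_cal, dtype=float)
    n, m = Y.shape
    if max_lv > n - 2:
        raise ValueError(f"max_lv={max_lv} too large for {n} calibration samples")
    fit = _FITTERS[kind]
    sq = np.zeros((max_lv, m))
    feasible = np.ones(max_lv, dtype=bool)
    for i in range(n):
        keep = np.arange(n) != i
        for h in range(1, max_lv + 1):
            if not feasible[h - 1]:
                continue
            try:
                model = fit(X[keep], Y[keep], h)
            except ValueError:
                # h exceeds the rank of this fold (e.g. noise-free data):
                # the candidate is not fittable
                feasible[h - 1] = False
                continue
            err = model.predict(X[i]) - Y[i]
            sq[h - 1] += err.ravel() ** 2
    per_analyte = np.sqrt(sq / n)
    pooled = np.sqrt(sq.sum(axis=1) / (n * m))
    per_analyte[~feasible] = np.inf
    pooled[~feasible] = np.inf
    chosen = int(np.argmin(pooled)) + 1  # argmin returns the first minimum
    return LvSelection(rmsecv=pooled, per_analyte=per_analyte, chosen_lv=chosen)


def fit_ann(
    X_cal: np.ndarray,
    Y_cal: np.ndarray,
    n_hidden: int = 6,
    epochs: int = 100,
    learning_rate: float = 0.5,
    seed: int = 0,
    adaptive: bool = True,
) -> AnnModel:
    """Train the linear-linear feed-forward net by full-batch gradient descent.

    Weights start from seeded Normal(0, 0.01) values; inputs and targets are
    mean-centered during training (the stored centering restores original
    units at prediction).  By default the step size backtracks (halves)
    whenever a step would increase the loss, so training is monotone and
    robust to the initial learning rate; with ``adaptive=False`` the rate is
    fixed and divergence raises an error advising a smaller rate.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    Xc, Yc, state = _center(X_cal, Y_cal)
    n, p = Xc.shape
    m = Yc.shape[1]
    rng = np.random.default_rng(seed)
    params = [
        rng.normal(0.0, 0.01, size=(p, n_hidden)),   # W1
        np.zeros(n_hidden),                           # b1
        rng.normal(0.0, 0.01, size=(n_hidden, m)),    # W2
        np.zeros(m),                                  # b2
    ]

    def forward(prm):
        W1, b1, W2, b2 = prm
        H = Xc @ W1 + b1
        R = H @ W2 + b2 - Yc
        return H, R, float(np.mean(R**2))

    lr = learning_rate
    history = np.empty(epochs)
    for epoch in range(epochs):
        H, R, mse = forward(params)
        if not np.isfinite(mse) or mse > 1e12:
            raise FloatingPointError(
                f"ANN training diverged at epoch {epoch + 1} "
                f"(MSE={mse:.3g}); reduce learning_rate (current {lr})"
            )
        history[epoch] = mse
        G = 2.0 * R / (n * m)
        GH = G @ params[2].T
        grads = [Xc.T @ GH, GH.sum(axis=0), H.T @ G, G.sum(axis=0)]
        stalled = False
        while True:
            trial = [p_ - lr * g_ for p_, g_ in zip(params, grads)]
            if not adaptive:
                params = trial
                break
            new_mse = forward(trial)[2]
            if np.isfinite(new_mse) and new_mse <= mse:
                params = trial
                lr *= 1.2  # recover step size after a successful move
                break
            lr *= 0.5
            if lr < 1e-14:
                # no descent step exists at machine precision: converged
                stalled = True
                break
        if stalled:
            history[epoch:] = mse
            break
    W1, b1, W2, b2 = params
    return AnnModel(
        W1=W1, b1=b1, W2=W2, b2=b2, centering=state, epochs=epochs, mse_history=history
    )


# ---------------------------------------------------------------------------
# JSON persistence

def save_model(model: LatentModel | AnnModel, path) -> None:
    if isinstance(model, LatentModel):
        payload = {
            "kind": model.kind,
            "n_lv": model.n_lv,
            "B": model.B.tolist(),
            "x_mean": model.centering.x_mean.tolist(),
            "y_mean": model.centering.y_mean.tolist(),
        }
    else:
        payload = {
            "kind": "ann",
            "W1": model.W1.tolist(),
            "b1": model.b1.tolist(),
            "W2": model.W2.tolist(),
            "b2": model.b2.tolist(),
            "x_mean": model.centering.x_mean.tolist(),
            "y_mean": model.centering.y_mean.tolist(),
            "epochs": model.epochs,
            "mse_history": model.mse_history.tolist(),
        }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> LatentModel | AnnModel:
    with open(path) as fh:
        payload = json.load(fh)
    centering = CenteringState(
        x_mean=np.array(payload["x_mean"]), y_mean=np.array(payload["y_mean"])
    )
    if payload["kind"] in ("pcr", "pls"):
        return LatentModel(
            kind=payload["kind"],
            n_lv=int(payload["n_lv"]),
            B=np.array(payload["B"]),
            centering=centering,
        )
    return AnnModel(
        W1=np.array(payload["W1"]),
        b1=np.array(payload["b1"]),
        W2=np.array(payload["W2"]),
        b2=np.array(payload["b2"]),
        centering=centering,
        epochs=int(payload["epochs"]),
        mse_history=np.array(payload["mse_history"]),
    )
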