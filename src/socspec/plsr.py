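"""Partial least-squares regression (univariate response, NIPALS).

Mean-centering only, no variance scaling — the usual choice for
absorbance spectra, where the informative signal sits in band depths of
comparable magnitude.  For a univariate response the NIPALS inner loop
converges in a single pass per component, so each component reduces to
four matrix-vector products: weight w = X'y, score t = Xw/|w|, loadings
p = X't/t't and q = y't/t't, followed by deflation of X (and y).

The number of latent variables is chosen by internal leave-one-out
cross-validation with the minimum-RMSE criterion, ties broken towards
fewer components.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

_W_TOL = 1e-12


@dataclass
class PLSRModel:
    x_mean: np.ndarray  # (p,)
    y_mean: float
    weights: np.ndarray  # (p, a)
    x_loadings: np.ndarray  # (p, a)
    y_loadings: np.ndarray  # (a,)
    coef: np.ndarray  # (p,) regression vector on centered data
    n_latent: int
    n_train: int
    scores: np.ndarray  # (n, a) training scores (orthogonal columns)

    def save(self, path) -> None:
        """Write the model as a flat JSON artifact for audit."""
        payload = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "n_latent": self.n_latent,
            "n_train": self.n_train,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "PLSRModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            n_latent=int(d["n_latent"]),
            n_train=int(d["n_train"]),
            scores=np.empty((0, int(d["n_latent"]))),  # training scores not archived
        )


def _nipals_path(Xc: np.ndarray, yc: np.ndarray, n_latent: int):
    """Extract up to ``n_latent`` components from centered data.

    Returns (W, P, q, T) truncated to the number of components actually
    extracted: the loop stops early once the covariance of the deflated
    X with the response residual vanishes (exact fit or exhausted rank),
    at which point further components cannot change predictions.
    """
    X = Xc.copy()
    y = yc.copy()
    n, p = X.shape
    W = np.empty((p, n_latent))
    P = np.empty((p, n_latent))
    q = np.empty(n_latent)
    T = np.empty((n, n_latent))
    scale = max(np.linalg.norm(X.T @ y), 1.0)
    done = 0
    for a in range(n_latent):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= _W_TOL * scale:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= _W_TOL:
            break
        pl = X.T @ t / tt
        qa = float(y @ t) / tt
        X -= np.outer(t, pl)
        y = y - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pl, qa, t
        done = a + 1
    if done == 0:
        raise ValueError("cannot extract any component: X'y is zero")
    return W[:, :done], P[:, :done], q[:done], T[:, :done]


def _coef_from_path(W: np.ndarray, P: np.ndarray, q: np.ndarray, n_latent: int) -> np.ndarray:
    Wa = W[:, :n_latent]
    Pa = P[:, :n_latent]
    return Wa @ np.linalg.solve(Pa.T @ Wa, q[:n_latent])


def max_components(n: int, p: int) -> int:
    """Upper bound on extractable components for n training samples."""
    return min(n - 1, p)


def fit_plsr(X: np.ndarray, y: np.ndarray, n_latent: int) -> PLSRModel:
    """Fit univariate-response PLSR with ``n_latent`` components."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with one response per row")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two training samples")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in training data")
    if np.std(y) == 0:
        raise ValueError("zero-variance response")
    if not (1 <= n_latent <= max_components(n, p)):
        raise ValueError(
            f"n_latent={n_latent} outside [1, {max_components(n, p)}] for n={n}, p={p}"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T = _nipals_path(X - x_mean, y - y_mean, n_latent)
    n_used = W.shape[1]  # may be < n_latent when the fit is exact early
    coef = _coef_from_path(W, P, q, n_used)
    return PLSRModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        n_latent=n_used,
        n_train=n,
        scores=T,
    )


def predict(model: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    """Predict responses: yhat = y_mean + (X_new - x_mean) @ coef."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"{X_new.shape[1]} variables but model was trained with {model.x_mean.size}"
        )
    return model.y_mean + (X_new - model.x_mean) @ model.coef


def select_n_latent_loo(
    X: np.ndarray, y: np.ndarray, max_latent: int
) -> tuple[int, np.ndarray]:
    """Choose the number of latent variables by leave-one-out CV.

    For each candidate count a = 1..max_latent the RMSE over all n
    held-out predictions is computed; returns the smallest count
    attaining the minimum RMSE together with the full RMSE curve.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("leave-one-out selection needs n >= 3")
    bound = max_components(n - 1, p)
    if not (1 <= max_latent <= bound):
        raise ValueError(f"max_latent={max_latent} outside [1, {bound}] for LOO on n={n}")
    sq_err = np.zeros(max_latent)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        x_mean = Xtr.mean(axis=0)
        y_mean = ytr.mean()
        W, P, q, _ = _nipals_path(Xtr - x_mean, ytr - y_mean, max_latent)
        n_avail = W.shape[1]
        xc = X[i] - x_mean
        for a in range(1, max_latent + 1):
            pred = y_mean + xc @ _coef_from_path(W, P, q, min(a, n_avail))
            sq_err[a - 1] += (pred - y[i]) ** 2
    rmse = np.sqrt(sq_err / n)
    chosen = int(np.argmin(rmse)) + 1  # argmin returns the first (smallest) minimiser
    return chosen, rmse
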