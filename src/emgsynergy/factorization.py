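"""Muscle-synergy factorisation: NMF, PCA, ICA and FA under one contract.

Every method decomposes an L×N activation matrix x into synergy weights W
(L×K) and excitation primitives H (K×N) so that x ≈ W·H (+ per-muscle offset
for the centring methods), minimising the Frobenius reconstruction error
under method-specific constraints:

* **NMF** — Lee–Seung multiplicative updates for the Euclidean objective
  ‖x − WH‖²_F with W, H ≥ 0; non-convex, so several random restarts are run
  and the best kept.  The objective is non-increasing at every iteration.
* **PCA** — singular value decomposition of the row-centred matrix; the
  optimal rank-K approximation (Eckart–Young), primitives mutually
  orthogonal.
* **ICA** — whitening to K dimensions followed by a symmetric fixed-point
  iteration maximising |kurtosis| of the projections (the classic
  fourth-moment FastICA contrast); the orthogonal unmixing rotation is kept
  as the mixing matrix.  Reconstruction goes back through the de-whitening
  transform, which is folded into W so x̂ = W·H + offset holds uniformly.
* **FA** — principal-axis factoring of the muscle covariance matrix:
  loadings are top-K eigenvectors scaled by √eigenvalue, factor scores by
  the regression method; no rotation, no iterative communality refinement.

Shared conventions: centring methods store the removed per-muscle mean in
``offset``; each primitive's sign is flipped so its skewness is non-negative
(activation bursts are right-skewed, and ECDF comparison downstream is not
sign-invariant); finally every H row is rescaled to peak (max |·|) 1 with
the compensating scale folded into the corresponding W column, which leaves
the reconstruction unchanged.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

from .preprocessing import ActivationMatrix

__all__ = [
    "SynergyDecomposition",
    "fit_nmf",
    "fit_pca",
    "fit_ica",
    "fit_fa",
    "fit_method",
    "reconstruct",
    "reconstruction_error_stats",
    "kaiser_criterion_k",
    "METHODS",
]

METHODS = ("NMF", "PCA", "ICA", "FA")

_EPS = 1e-12


@dataclasses.dataclass
class SynergyDecomposition:
    """Result of factorising an activation matrix.

    ``x_hat`` is the reconstruction W·H (+ offset); ``mixing`` stores the
    K×K orthogonal unmixing rotation for ICA; ``meta`` carries per-method
    diagnostics (iterations, objective history, convergence flag, seed).
    """

    W: np.ndarray
    H: np.ndarray
    method: str
    K: int
    x_hat: np.ndarray
    offset: np.ndarray | None = None
    mixing: np.ndarray | None = None
    meta: dict = dataclasses.field(default_factory=dict)


def _as_array(x: ActivationMatrix | np.ndarray) -> np.ndarray:
    if isinstance(x, ActivationMatrix):
        return x.x
    return np.asarray(x, dtype=float)


def _check_K(K: int, L: int) -> None:
    if not 1 <= K <= L:
        raise ValueError(f"K must be in [1, {L}], got {K}")


def _fix_signs(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each primitive so its skewness is >= 0.

    Ties (symmetric primitives) are broken by making the largest-magnitude
    loading of the corresponding W column positive.
    """
    W = W.copy()
    H = H.copy()
    for k in range(H.shape[0]):
        s = stats.skew(H[k])
        if abs(s) < 1e-12:
            idx = np.argmax(np.abs(W[:, k]))
            s = np.sign(W[idx, k])
        if s < 0:
            H[k] = -H[k]
            W[:, k] = -W[:, k]
    return W, H


def _normalise_primitive_scale(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rescale each H row to peak 1, folding the scale into W (x̂ invariant)."""
    W = W.copy()
    H = H.copy()
    for k in range(H.shape[0]):
        peak = np.max(np.abs(H[k]))
        if peak > 0:
            H[k] /= peak
            W[:, k] *= peak
    return W, H


def _finalise(
    W: np.ndarray,
    H: np.ndarray,
    method: str,
    offset: np.ndarray | None,
    mixing: np.ndarray | None,
    meta: dict,
    fix_signs: bool = True,
) -> SynergyDecomposition:
    if fix_signs:
        W, H = _fix_signs(W, H)
    W, H = _normalise_primitive_scale(W, H)
    x_hat = W @ H
    if offset is not None:
        x_hat = x_hat + offset
    return SynergyDecomposition(
        W=W, H=H, method=method, K=H.shape[0], x_hat=x_hat,
        offset=offset, mixing=mixing, meta=meta,
    )


# ---------------------------------------------------------------------------
# NMF


def fit_nmf(
    x: ActivationMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
    restarts: int = 10,
) -> SynergyDecomposition:
    """Non-negative matrix factorisation by Lee–Seung multiplicative updates.

    Minimises ‖x − WH‖²_F subject to W, H ≥ 0.  Runs ``restarts`` random
    initialisations (uniform in (0, 1] scaled by √(mean(x)/K)) and returns
    the one with the lowest final objective.  ``tol`` is the relative change
    of the objective between iterations used for early stopping.
    """
    X = _as_array(x)
    if np.any(X < 0):
        raise ValueError("NMF requires a non-negative input matrix")
    L = X.shape[0]
    _check_K(K, L)

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), _EPS) / K)
    best: tuple[float, np.ndarray, np.ndarray, list[float], int] | None = None

    for _ in range(max(1, restarts)):
        W = scale * (1.0 - rng.random((L, K)))  # uniform in (0, 1]
        H = scale * (1.0 - rng.random((K, X.shape[1])))
        history: list[float] = [float(np.linalg.norm(X - W @ H) ** 2)]
        for it in range(max_iter):
            H *= (W.T @ X) / (W.T @ W @ H + _EPS)
            W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
            obj = float(np.linalg.norm(X - W @ H) ** 2)
            history.append(obj)
            prev = history[-2]
            if prev - obj <= tol * max(prev, _EPS):
                break
        if best is None or history[-1] < best[0]:
            best = (history[-1], W, H, history, len(history) - 1)

    assert best is not None
    obj, W, H, history, iters = best
    meta = {
        "seed": seed,
        "iterations": iters,
        "final_objective": obj,
        "objective_history": history,
        "restarts": restarts,
        "converged": iters < max_iter,
    }
    # NMF factors are non-negative: sign fixing is a no-op, skip it
    return _finalise(W, H, "NMF", None, None, meta, fix_signs=False)


# ---------------------------------------------------------------------------
# PCA


def fit_pca(x: ActivationMatrix | np.ndarray, K: int) -> SynergyDecomposition:
    """Principal component analysis via SVD of the row-centred matrix."""
    X = _as_array(x)
    L = X.shape[0]
    _check_K(K, L)
    offset = X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(X - offset, full_matrices=False)
    W = U[:, :K] * s[:K]
    H = Vt[:K]
    meta = {"singular_values": s.tolist()}
    return _finalise(W, H, "PCA", offset, None, meta)


# ---------------------------------------------------------------------------
# ICA


def _sym_decorrelate(B: np.ndarray) -> np.ndarray:
    """Symmetric decorrelation: B ← (B Bᵀ)^(−1/2) B."""
    vals, vecs = np.linalg.eigh(B @ B.T)
    vals = np.clip(vals, _EPS, None)
    return (vecs / np.sqrt(vals)) @ vecs.T @ B


def fit_ica(
    x: ActivationMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    contrast: str = "kurtosis",
) -> SynergyDecomposition:
    """Independent component analysis with a kurtosis (fourth-moment) contrast.

    Centres and whitens the data to K dimensions, then runs the symmetric
    fixed-point iteration for the chosen contrast (``kurtosis`` default,
    ``logcosh`` optional).  On non-convergence a warning is emitted and the
    best-effort result is returned with ``meta['converged'] = False``.
    """
    X = _as_array(x)
    L, N = X.shape
    _check_K(K, L)
    if contrast not in ("kurtosis", "logcosh"):
        raise ValueError("contrast must be 'kurtosis' or 'logcosh'")

    offset = X.mean(axis=1, keepdims=True)
    Xc = X - offset
    # PCA whitening to K dimensions
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    s = np.clip(s, np.sqrt(_EPS), None)
    d = s[:K] / np.sqrt(N)
    whiten = (U[:, :K] / d).T            # K x L
    dewhiten = U[:, :K] * d              # L x K
    Z = whiten @ Xc                      # K x N, unit covariance

    rng = np.random.default_rng(seed)
    B = _sym_decorrelate(rng.standard_normal((K, K)))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Y = B @ Z
        if contrast == "kurtosis":
            # w ← E[z (wᵀz)³] − 3 w   (fixed point of the fourth moment)
            B_new = (Y**3) @ Z.T / N - 3.0 * B
        else:
            g = np.tanh(Y)
            B_new = g @ Z.T / N - np.mean(1.0 - g**2, axis=1, keepdims=True) * B
        B_new = _sym_decorrelate(B_new)
        delta = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", B_new, B)) - 1.0)))
        B = B_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"ICA did not converge in {max_iter} iterations (delta above tol); "
            "returning best-effort result",
            RuntimeWarning,
        )

    H = B @ Z
    W = dewhiten @ B.T
    meta = {"seed": seed, "iterations": it, "converged": converged, "contrast": contrast}
    return _finalise(W, H, "ICA", offset, B.T, meta)


# ---------------------------------------------------------------------------
# FA


def fit_fa(x: ActivationMatrix | np.ndarray, K: int) -> SynergyDecomposition:
    """Principal-axis factor analysis on the muscle covariance matrix.

    Loadings are the top-K eigenvectors of the covariance matrix scaled by
    √eigenvalue; factor scores follow the regression method
    H = Λᵀ C⁻¹ (x − mean).  Eigenvalues are floored at 1e-12 so singular
    covariance matrices (exactly low-rank data) are handled.
    """
    X = _as_array(x)
    L, N = X.shape
    _check_K(K, L)
    offset = X.mean(axis=1, keepdims=True)
    Xc = X - offset
    C = (Xc @ Xc.T) / (N - 1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], _EPS, None)
    vecs = vecs[:, order]
    loadings = vecs[:, :K] * np.sqrt(vals[:K])
    # regression scores through the (pseudo-)inverse of the covariance
    C_inv = (vecs / vals) @ vecs.T
    H = loadings.T @ C_inv @ Xc
    meta = {"eigenvalues": vals.tolist()}
    return _finalise(loadings, H, "FA", offset, None, meta)


def kaiser_criterion_k(x: ActivationMatrix | np.ndarray) -> int:
    """Number of significant factors by the eigenvalue-greater-than-1 rule.

    Computed on standardised data (correlation matrix of the muscle rows),
    the conventional reading of the Kaiser criterion.
    """
    X = _as_array(x)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd
    R = (Z @ Z.T) / (X.shape[1] - 1)
    vals = np.linalg.eigvalsh(R)
    return int(np.sum(vals > 1.0))


# ---------------------------------------------------------------------------
# common

_FITTERS = {
    "NMF": lambda x, K, seed, **kw: fit_nmf(x, K, seed=seed, **kw),
    "PCA": lambda x, K, seed, **kw: fit_pca(x, K),
    "ICA": lambda x, K, seed, **kw: fit_ica(x, K, seed=seed, **kw),
    "FA": lambda x, K, seed, **kw: fit_fa(x, K),
}


def fit_method(
    x: ActivationMatrix | np.ndarray,
    method: str,
    K: int,
    seed: int = 0,
    **kwargs,
) -> SynergyDecomposition:
    """Dispatch to the requested factorisation method (one of METHODS)."""
    method = method.upper()
    if method not in _FITTERS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return _FITTERS[method](x, K, seed, **kwargs)


def reconstruct(dec: SynergyDecomposition) -> np.ndarray:
    """Rebuild x̂ = W·H (+ offset).  Pure and idempotent."""
    if dec.W.shape[1] != dec.H.shape[0]:
        raise ValueError("inconsistent decomposition shapes")
    x_hat = dec.W @ dec.H
    if dec.offset is not None:
        x_hat = x_hat + dec.offset
    return x_hat


def reconstruction_error_stats(
    x: ActivationMatrix | np.ndarray, dec: SynergyDecomposition
) -> dict[str, float]:
    """MSE of the reconstruction with its variance decomposition diagnostic.

    Returns mean squared error, the variance of x̂ and the residual variance
    σ²ₑ; for a well-behaved decomposition MSE ≈ var(x̂') + σ²ₑ where x̂' is
    the reconstruction error-free part — reported as raw numbers so callers
    can inspect the decomposition quality.
    """
    X = _as_array(x)
    x_hat = dec.x_hat
    if X.shape != x_hat.shape:
        raise ValueError("x and reconstruction shapes disagree")
    resid = X - x_hat
    return {
        "mse": float(np.mean(resid**2)),
        "var_xhat": float(np.var(x_hat)),
        "var_e": float(np.var(resid)),
    }
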