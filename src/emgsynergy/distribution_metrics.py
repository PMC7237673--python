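"""Probability-distribution comparison of activations and primitives.

The question these metrics answer: does a factorisation method produce
excitation primitives whose amplitude distribution looks like the muscle
activation patterns it was fitted to?  A method whose primitives share the
activations' distribution can, with scalar non-negative weights, reproduce
the activations' distributional shape — a complementary criterion to plain
reconstruction accuracy.

Machinery:

* moment summaries (Fisher excess kurtosis, skewness) of pooled samples;
* a Gaussian PDF model for plotting distribution shapes on a common grid;
* empirical cumulative distribution functions with mass 1/n per observation;
* the two-sample Kolmogorov–Smirnov statistic D = sup|F₁ − F₂| evaluated
  over the pooled jump points, with the asymptotic p-value at effective
  sample size n₁n₂/(n₁+n₂);
* `compare_primitives_to_activations`, which computes D for every
  (muscle, primitive) pair, reduces to the per-primitive worst case D_k and
  the overall maximum dissimilarity D_max, and reports the *occurrence of
  agreement*: the percentage of pairs where the KS test fails to reject
  distributional equality at level alpha.

Because two-sample KS is not invariant to rescaling one sample only, each
primitive is min–max normalised to [0, 1] before comparison (activations
already live there); pass ``primitive_prep='raw'`` for a sensitivity check.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import special, stats

from .factorization import SynergyDecomposition
from .preprocessing import ActivationMatrix

__all__ = [
    "DistributionSummary",
    "EcdfSample",
    "KsComparison",
    "summarise_distribution",
    "gaussian_pdf_model",
    "ecdf",
    "ks_two_sample",
    "compare_primitives_to_activations",
]


@dataclasses.dataclass(frozen=True)
class DistributionSummary:
    """Pooled-sample moments: excess kurtosis, skewness, mean, sd, n."""

    excess_kurtosis: float
    skewness: float
    mu: float
    sigma: float
    n: int


def summarise_distribution(sample: np.ndarray) -> DistributionSummary:
    """Fisher excess kurtosis and skewness with population-moment estimators."""
    a = np.ravel(np.asarray(sample, dtype=float))
    if a.size < 4:
        raise ValueError("need at least 4 observations for kurtosis")
    return DistributionSummary(
        excess_kurtosis=float(stats.kurtosis(a, fisher=True, bias=True)),
        skewness=float(stats.skew(a, bias=True)),
        mu=float(a.mean()),
        sigma=float(a.std(ddof=0)),
        n=int(a.size),
    )


def gaussian_pdf_model(summary: DistributionSummary, grid: np.ndarray) -> np.ndarray:
    """Gaussian density with the summary's mean and sd, evaluated on grid."""
    if summary.sigma <= 0:
        raise ValueError("sigma must be positive")
    return stats.norm.pdf(np.asarray(grid, dtype=float), loc=summary.mu, scale=summary.sigma)


class EcdfSample:
    """A sample with its right-continuous empirical CDF (mass 1/n each)."""

    def __init__(self, values: np.ndarray):
        values = np.ravel(np.asarray(values, dtype=float))
        if values.size == 0:
            raise ValueError("empty sample")
        self.values = np.sort(values)
        self.n = values.size

    def evaluate(self, t) -> np.ndarray | float:
        """Fraction of observations <= t (vectorised)."""
        t = np.asarray(t, dtype=float)
        out = np.searchsorted(self.values, t, side="right") / self.n
        return out if out.ndim else float(out)

    __call__ = evaluate


def ecdf(sample: np.ndarray) -> EcdfSample:
    """Build the standard empirical cumulative distribution function."""
    return EcdfSample(sample)


def _as_ecdf(x) -> EcdfSample:
    return x if isinstance(x, EcdfSample) else EcdfSample(x)


def ks_two_sample(a, b) -> dict[str, float]:
    """Two-sample KS statistic and asymptotic p-value.

    D is the supremum of |F_a − F_b|; since both ECDFs are right-continuous
    step functions jumping only at sample points, the supremum is attained at
    a pooled jump point evaluated from the right, where one-sided limits are
    covered by also evaluating each ECDF just below each jump (handled
    implicitly because every jump point of either sample is in the pooled
    set).  p = Q_KS(√(n_eff)·D) with n_eff = n_a·n_b/(n_a+n_b).
    """
    Fa, Fb = _as_ecdf(a), _as_ecdf(b)
    pooled = np.concatenate([Fa.values, Fb.values])
    D = float(np.max(np.abs(Fa.evaluate(pooled) - Fb.evaluate(pooled))))
    n_eff = Fa.n * Fb.n / (Fa.n + Fb.n)
    p = float(special.kolmogorov(np.sqrt(n_eff) * D))
    return {"D": D, "p": min(1.0, p)}


@dataclasses.dataclass
class KsComparison:
    """All-pairs KS comparison of muscles (rows) against primitives (cols).

    ``D_k`` is the worst-case dissimilarity of primitive k over all muscles,
    ``D_max`` the maximum of D_k, and ``agreement_pct`` the percentage of the
    L×K pairs whose KS test fails to reject equality at level alpha.
    """

    D_lk: np.ndarray
    p_lk: np.ndarray
    D_k: np.ndarray
    D_max: float
    agreement_pct: float
    alpha: float


def _prepare_primitive(h: np.ndarray, mode: str) -> np.ndarray:
    if mode == "raw":
        return h
    if mode == "minmax":
        lo, hi = h.min(), h.max()
        if hi - lo <= 0:
            return np.zeros_like(h)
        return (h - lo) / (hi - lo)
    raise ValueError("primitive_prep must be 'minmax' or 'raw'")


def compare_primitives_to_activations(
    x: ActivationMatrix | np.ndarray,
    dec: SynergyDecomposition,
    alpha: float = 0.05,
    primitive_prep: str = "minmax",
    reduction: str = "max",
) -> KsComparison:
    """KS-compare every primitive's ECDF with every muscle activation's ECDF.

    ``reduction`` controls how D_k summarises over muscles: ``max`` (the
    worst-case convention) or ``min`` (best-matching muscle, exploratory).
    """
    X = x.x if isinstance(x, ActivationMatrix) else np.asarray(x, dtype=float)
    L = X.shape[0]
    K = dec.H.shape[0]
    if K >= L:
        raise ValueError("number of synergies must be less than number of muscles")
    if reduction not in ("max", "min"):
        raise ValueError("reduction must be 'max' or 'min'")

    muscle_ecdfs = [EcdfSample(X[l]) for l in range(L)]
    D_lk = np.empty((L, K))
    p_lk = np.empty((L, K))
    for k in range(K):
        h = _prepare_primitive(dec.H[k], primitive_prep)
        Fh = EcdfSample(h)
        for l in range(L):
            r = ks_two_sample(muscle_ecdfs[l], Fh)
            D_lk[l, k] = r["D"]
            p_lk[l, k] = r["p"]

    reduce_fn = np.max if reduction == "max" else np.min
    D_k = reduce_fn(D_lk, axis=0)
    agreement_pct = 100.0 * float(np.mean(p_lk >= alpha))
    return KsComparison(
        D_lk=D_lk,
        p_lk=p_lk,
        D_k=D_k,
        D_max=float(np.max(D_k)),
        agreement_pct=agreement_pct,
        alpha=alpha,
    )
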