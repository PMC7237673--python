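"""VAF, synergy-number selection, method scoring and group statistics.

VAF (variance accounted for) is the global, uncentred form

    VAF = 1 − Σ(x − x̂)² / Σx²

summed over every entry of the L×N matrix — the usual synergy-literature
convention.  For centring methods the reconstruction includes the re-added
per-muscle mean, so VAF is always measured against the original x.

The number of synergies K is the smallest value in the candidate range for
which *every* factorisation method exceeds the VAF threshold (85% default).

`score_dataset` produces one record per trial × method: VAF plus the two
distribution metrics (occurrence of agreement, maximum dissimilarity) from
:mod:`.distribution_metrics`.  `group_comparison` runs a one-way
repeated-measures ANOVA across methods (subjects as the repeated factor,
trials averaged to subject means first) with Bonferroni-corrected paired
t-tests, per condition.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .distribution_metrics import compare_primitives_to_activations
from .factorization import METHODS, fit_method
from .preprocessing import ActivationMatrix

__all__ = [
    "MethodScore",
    "vaf",
    "select_num_synergies",
    "score_dataset",
    "scores_to_frame",
    "group_comparison",
    "matched_cosine_similarity",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class MethodScore:
    """Per-trial, per-method evaluation record."""

    method: str
    condition: str
    subject: str
    trial_id: str
    vaf: float
    agreement_pct: float
    d_max: float
    K: int


def matched_cosine_similarity(W_est: np.ndarray, W_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Align estimated synergy weights to ground truth and score the match.

    Factorisations are identified only up to permutation (and scale, already
    normalised away upstream), so columns of ``W_est`` are assigned to columns
    of ``W_true`` by maximising total cosine similarity (Hungarian algorithm).
    Returns ``(perm, cosines)`` where ``perm[j]`` is the estimated column
    matched to true column j and ``cosines[j]`` the corresponding cosine.
    """
    from scipy.optimize import linear_sum_assignment

    W_est = np.asarray(W_est, dtype=float)
    W_true = np.asarray(W_true, dtype=float)
    if W_est.shape != W_true.shape:
        raise ValueError("weight matrices must have identical shapes")

    def _unit(M):
        norms = np.linalg.norm(M, axis=0, keepdims=True)
        norms[norms == 0] = 1.0
        return M / norms

    sim = _unit(W_true).T @ _unit(W_est)  # K x K cosine matrix
    rows, cols = linear_sum_assignment(-sim)
    return cols, sim[rows, cols]


def vaf(x: ActivationMatrix | np.ndarray, x_hat: np.ndarray) -> float:
    """Global uncentred variance accounted for of a reconstruction."""
    X = x.x if isinstance(x, ActivationMatrix) else np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if X.shape != x_hat.shape:
        raise ValueError("x and x_hat shapes disagree")
    denom = float(np.sum(X**2))
    if denom == 0:
        raise ValueError("VAF undefined for an all-zero activation matrix")
    return 1.0 - float(np.sum((X - x_hat) ** 2)) / denom


def select_num_synergies(
    x: ActivationMatrix | np.ndarray,
    methods: tuple[str, ...] = METHODS,
    K_range: range = range(2, 7),
    threshold: float = 0.85,
    seed: int = 0,
) -> int:
    """Smallest K for which all methods reconstruct with VAF above threshold.

    Returns the range maximum (with a warning) if the threshold is never
    reached by every method simultaneously.
    """
    if not methods:
        raise ValueError("methods set must be non-empty")
    ks = list(K_range)
    for K in ks:
        if all(vaf(x, fit_method(x, m, K, seed=seed).x_hat) > threshold for m in methods):
            return K
    warnings.warn(
        f"no K in {ks} reached VAF > {threshold:.2f} for all methods; returning {ks[-1]}",
        RuntimeWarning,
    )
    return ks[-1]


def score_dataset(
    trials: list[ActivationMatrix],
    methods: tuple[str, ...] = METHODS,
    K: int = 3,
    seeds: list[int] | None = None,
    conditions: list[str] | None = None,
    subjects: list[str] | None = None,
    trial_ids: list[str] | None = None,
    alpha: float = 0.05,
) -> list[MethodScore]:
    """Fit every method to every trial and score VAF + distribution metrics.

    Per-trial fit failures are logged and skipped rather than aborting the
    whole run.  Deterministic given ``seeds`` (one per trial).
    """
    n = len(trials)
    seeds = seeds if seeds is not None else list(range(n))
    conditions = conditions if conditions is not None else ["unknown"] * n
    subjects = subjects if subjects is not None else ["s01"] * n
    trial_ids = trial_ids if trial_ids is not None else [f"t{i:03d}" for i in range(n)]

    scores: list[MethodScore] = []
    for i, trial in enumerate(trials):
        for method in methods:
            try:
                dec = fit_method(trial, method, K, seed=seeds[i])
                comparison = compare_primitives_to_activations(trial, dec, alpha=alpha)
                scores.append(
                    MethodScore(
                        method=method,
                        condition=conditions[i],
                        subject=subjects[i],
                        trial_id=trial_ids[i],
                        vaf=vaf(trial, dec.x_hat),
                        agreement_pct=comparison.agreement_pct,
                        d_max=comparison.D_max,
                        K=K,
                    )
                )
            except Exception:  # pragma: no cover - defensive path
                logger.exception("scoring failed for trial %s method %s; skipped",
                                 trial_ids[i], method)
    return scores


def scores_to_frame(scores: list[MethodScore]) -> pd.DataFrame:
    """Long-format DataFrame of MethodScore records."""
    return pd.DataFrame([dataclasses.asdict(s) for s in scores])


def _rm_anova(wide: pd.DataFrame) -> dict:
    """Classical one-way repeated-measures ANOVA (subjects × methods)."""
    from statsmodels.stats.anova import AnovaRM

    long = wide.reset_index().melt(id_vars="subject", var_name="method", value_name="y")
    res = AnovaRM(long, depvar="y", subject="subject", within=["method"]).fit()
    row = res.anova_table.iloc[0]
    return {
        "F": float(row["F Value"]),
        "df_num": float(row["Num DF"]),
        "df_den": float(row["Den DF"]),
        "p": float(row["Pr > F"]),
    }


def group_comparison(
    scores: list[MethodScore] | pd.DataFrame,
    metric: str = "vaf",
) -> dict[str, dict]:
    """RM-ANOVA across methods per condition with Bonferroni pairwise tests.

    Trials are first averaged to subject means (subjects, not trials, are
    the repeated units).  Requires a balanced design: every subject must
    contribute to every method within a condition.
    """
    if metric not in ("vaf", "agreement_pct", "d_max"):
        raise ValueError("metric must be one of vaf, agreement_pct, d_max")
    df = scores if isinstance(scores, pd.DataFrame) else scores_to_frame(scores)
    if df["method"].nunique() < 2:
        raise ValueError("need at least 2 methods for a group comparison")

    out: dict[str, dict] = {}
    for condition, sub in df.groupby("condition"):
        means = sub.groupby(["subject", "method"])[metric].mean().unstack("method")
        if means.isna().any().any():
            raise ValueError(
                f"unbalanced design in condition {condition!r}: every subject must "
                "have scores for every method"
            )
        if len(means) < 2:
            raise ValueError("need at least 2 subjects for a repeated-measures ANOVA")
        means.index.name = "subject"
        # degenerate case: no variation between methods at all -> no effect,
        # reported as F = 0, p = 1 rather than the 0/0 the F ratio would give
        degenerate = bool(np.allclose(means.to_numpy(), means.to_numpy()[:, [0]]))
        if degenerate:
            result = {"F": 0.0, "df_num": float(len(means.columns) - 1),
                      "df_den": float((len(means.columns) - 1) * (len(means) - 1)),
                      "p": 1.0}
        else:
            result = _rm_anova(means)

        pairs = list(itertools.combinations(sorted(means.columns), 2))
        m = len(pairs)
        pairwise = {}
        for a, b in pairs:
            diff = means[a] - means[b]
            if np.allclose(diff, 0.0):
                t, p_raw = 0.0, 1.0
            else:
                t, p_raw = stats.ttest_rel(means[a], means[b])
            pairwise[f"{a}_vs_{b}"] = {
                "t": float(t),
                "p_raw": float(p_raw),
                "p_bonferroni": float(min(1.0, m * p_raw)),
            }
        result["pairwise"] = pairwise
        result["n_subjects"] = int(len(means))
        out[str(condition)] = result
    return out
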