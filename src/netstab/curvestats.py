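"""Decisions between stability-curve sets.

Three tools:

* :func:`auc` / :func:`rank_by_auc` — trapezoidal area under the replicate-
  mean curve; lower area = more robust clustering, so methods are ranked
  ascending.
* :func:`gp_bayes_factor` — model comparison on the paired replicate
  differences d(level, replicate): a zero-mean squared-exponential GP plus
  white noise (structured) against zero-mean white noise alone.  The Bayes
  factor exp(LML1 - LML0) > 100 is read as strong evidence the two curve
  processes differ.
* :func:`interval_wise_test` — a permutation test on the squared difference
  of group means, aggregated over every contiguous interval of levels; the
  adjusted p-value of a level is the maximum p over all intervals containing
  it, which controls the interval-wise error rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ValidationError
from .engine import CurveSet, RobustnessResult
from .rng import RandomState

__all__ = [
    "auc",
    "rank_by_auc",
    "gp_bayes_factor",
    "interval_wise_test",
    "GPTestResult",
    "IWTResult",
]

#: Bayes-factor interpretation thresholds (reported, never auto-acted upon).
BF_THRESHOLDS = {"strong": 100.0, "substantial": 3.0}


def auc(levels, curve) -> float:
    """Trapezoidal integral of ``curve`` over the level axis."""
    levels = np.asarray(levels, dtype=float)
    curve = np.asarray(curve, dtype=float)
    if levels.ndim != 1 or curve.shape != levels.shape:
        raise DomainError(
            f"levels and curve must be equal-length 1-D arrays, "
            f"got {levels.shape} and {curve.shape}"
        )
    if len(levels) < 2:
        raise DomainError("need at least two levels to integrate")
    if np.any(np.diff(levels) <= 0):
        raise DomainError("levels must be strictly increasing")
    return float(np.trapezoid(curve, levels))


def rank_by_auc(result: RobustnessResult) -> list[tuple[str, float]]:
    """Methods of a result ordered by ascending AUC of the mean observed curve.

    Ties break lexicographically by method spec string.
    """
    entries = []
    for spec in result.methods():
        cs = result.curve(spec, "observed")
        entries.append((spec, auc(cs.levels, cs.mean_curve())))
    return sorted(entries, key=lambda t: (t[1], t[0]))


def _check_pair(a: CurveSet, b: CurveSet) -> None:
    if a.levels != b.levels:
        raise DomainError("curve sets are on different perturbation grids")
    if a.measure != b.measure:
        raise DomainError("curve sets use different stability measures")


@dataclass
class GPTestResult:
    """Outcome of the GP marginal-likelihood model comparison."""

    lml_structured: float
    lml_noise: float
    log_bayes_factor: float
    bayes_factor: float
    verdict: str  # "strong" | "substantial" | "none"
    thresholds: dict = field(default_factory=lambda: dict(BF_THRESHOLDS))

    def to_dict(self) -> dict:
        return {
            "lml_structured": self.lml_structured,
            "lml_noise": self.lml_noise,
            "log_bayes_factor": self.log_bayes_factor,
            "bayes_factor": self.bayes_factor if np.isfinite(self.bayes_factor)
            else None,
            "verdict": self.verdict,
            "thresholds": self.thresholds,
        }


def gp_bayes_factor(
    a: CurveSet,
    b: CurveSet,
    restarts: int = 5,
    rng: RandomState = RandomState(0),
) -> GPTestResult:
    """Bayes factor for "the two curve processes differ".

    Forms paired differences d = a.values - b.values (requires equal
    replicate counts), then compares marginal likelihoods of

    * M1: zero-mean GP with squared-exponential kernel + white noise,
      hyperparameters optimized with ``restarts`` optimizer starts
      (lengthscale bounded to [grid step, grid span], noise floor 1e-6);
    * M0: zero-mean white noise, whose maximum LML is closed-form.

    Swapping ``a`` and ``b`` negates d and leaves both (zero-mean) marginal
    likelihoods — hence the Bayes factor — unchanged.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

    _check_pair(a, b)
    if a.replicates != b.replicates:
        raise DomainError(
            "paired GP test needs equal replicate counts "
            f"({a.replicates} vs {b.replicates})"
        )
    if restarts < 1:
        raise DomainError("restarts must be a positive integer")
    levels = np.asarray(a.levels)
    d = (a.values - b.values).ravel()
    x = np.repeat(levels, a.replicates).reshape(-1, 1)

    n = d.size
    noise_floor = 1e-6
    s2 = max(float(np.mean(d**2)), noise_floor)
    lml_noise = -0.5 * n * np.log(2 * np.pi * s2) - 0.5 * float(np.sum(d**2)) / s2

    step = float(np.min(np.diff(levels))) if len(levels) > 1 else 0.05
    span = float(levels[-1] - levels[0]) if len(levels) > 1 else 1.0
    kernel = ConstantKernel(1.0, (1e-10, 1e4)) * RBF(
        length_scale=max(span / 3.0, step), length_scale_bounds=(step, max(span, step * 1.001))
    ) + WhiteKernel(noise_level=max(s2, noise_floor), noise_level_bounds=(noise_floor, 1e4))
    gp = GaussianProcessRegressor(
        kernel=kernel,
        n_restarts_optimizer=restarts - 1,
        normalize_y=False,
        random_state=rng.integer(2**31 - 1),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            gp.fit(x, d)
        except Exception as exc:  # optimizer failure after all restarts
            raise ValidationError(
                f"GP optimization failed for the structured model: {exc}"
            ) from exc
    lml_structured = float(gp.log_marginal_likelihood_value_)

    log_bf = lml_structured - lml_noise
    with np.errstate(over="ignore"):
        bf = float(np.exp(log_bf))
    if bf > BF_THRESHOLDS["strong"]:
        verdict = "strong"
    elif bf > BF_THRESHOLDS["substantial"]:
        verdict = "substantial"
    else:
        verdict = "none"
    return GPTestResult(lml_structured, lml_noise, float(log_bf), bf, verdict)


@dataclass
class IWTResult:
    """Interval-wise permutation test output: one adjusted p per level."""

    levels: tuple[float, ...]
    p_adjusted: np.ndarray
    p_pointwise: np.ndarray
    n_perm: int
    intervals: list[tuple[int, int]]
    interval_stats: np.ndarray
    interval_p: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "levels": list(self.levels),
            "p_adjusted": self.p_adjusted.tolist(),
            "p_pointwise": self.p_pointwise.tolist(),
            "n_perm": self.n_perm,
            "intervals": [list(t) for t in self.intervals],
            "interval_stats": self.interval_stats.tolist(),
            "interval_p": self.interval_p.tolist(),
            "warnings": list(self.warnings),
        }

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"level": self.levels, "p_adj": self.p_adjusted}
        ).to_csv(path, index=False)


def _interval_sums(t: np.ndarray) -> np.ndarray:
    """Sums of T over every contiguous interval, for T of shape (..., L).

    Returns shape (..., L*(L+1)/2) in the order (start, end) with start<=end,
    start-major.
    """
    L = t.shape[-1]
    cs = np.concatenate(
        [np.zeros(t.shape[:-1] + (1,)), np.cumsum(t, axis=-1)], axis=-1
    )
    cols = []
    for i in range(L):
        for j in range(i, L):
            cols.append(cs[..., j + 1] - cs[..., i])
    return np.stack(cols, axis=-1)


def interval_wise_test(
    a: CurveSet,
    b: CurveSet,
    n_perm: int = 1000,
    rng: RandomState = RandomState(0),
) -> IWTResult:
    """Permutation test for a functional difference between two curve sets.

    Each replicate curve is a functional observation.  The pointwise
    statistic is the squared difference of group means; interval statistics
    sum it over every contiguous level interval.  The null distribution comes
    from ``n_perm`` random reassignments of whole curves to the two groups,
    and the adjusted p-value at a level is the maximum interval p-value over
    all intervals containing that level.
    """
    _check_pair(a, b)
    if a.replicates < 2 or b.replicates < 2:
        raise DomainError("each curve set needs at least 2 replicates")
    if n_perm < 1:
        raise DomainError("n_perm must be a positive integer")
    warn_list = []
    if n_perm < 100:
        warn_list.append(
            f"n_perm={n_perm} is small; p-value resolution is only {1/(n_perm+1):.3g}"
        )

    curves_a = a.values.T  # (Ra, L)
    curves_b = b.values.T
    ra = curves_a.shape[0]
    pooled = np.vstack([curves_a, curves_b])
    n_tot, L = pooled.shape

    obs_t = (curves_a.mean(axis=0) - curves_b.mean(axis=0)) ** 2
    obs_int = _interval_sums(obs_t)

    gen = rng.generator
    # Permute a canonically ordered pool so the null draw is exactly
    # invariant to how replicates are labeled within each group.
    pool = pooled[np.lexsort(pooled.T[::-1])]
    order = np.argsort(gen.random((n_perm, n_tot)), axis=1)
    ga = pool[order[:, :ra]]  # (n_perm, Ra, L)
    gb = pool[order[:, ra:]]
    perm_t = (ga.mean(axis=1) - gb.mean(axis=1)) ** 2
    perm_int = _interval_sums(perm_t)  # (n_perm, n_intervals)

    exceed = (perm_int >= obs_int[None, :] - 1e-15).sum(axis=0)
    interval_p = (1.0 + exceed) / (1.0 + n_perm)

    intervals = [(i, j) for i in range(L) for j in range(i, L)]
    p_adj = np.zeros(L)
    p_point = np.zeros(L)
    for idx, (i, j) in enumerate(intervals):
        if i == j:
            p_point[i] = interval_p[idx]
    for li in range(L):
        containing = [idx for idx, (i, j) in enumerate(intervals) if i <= li <= j]
        p_adj[li] = interval_p[containing].max()

    return IWTResult(
        a.levels, p_adj, p_point, int(n_perm), intervals, obs_int, interval_p,
        warn_list,
    )
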