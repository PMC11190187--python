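"""Group-level inference: paired sign-flip permutation tests with Holm
correction, cluster-based permutation over time, and Bayesian population
prevalence.

All permutation tests enumerate the full 2^n sign-flip null exhaustively
whenever 2^n does not exceed the requested permutation count (for eleven
subjects, 2^11 = 2048, so the default is exhaustive); otherwise random
sign flips are drawn and the add-one p-value convention guarantees a
valid, strictly positive p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PermTestResult",
    "ClusterResult",
    "PrevalenceResult",
    "paired_permutation_test",
    "holm_adjust",
    "cluster_permutation_test",
    "prevalence_estimate",
]


@dataclass
class PermTestResult:
    observed: float
    p: float
    n_permutations: int
    exhaustive: bool
    side: str


@dataclass
class ClusterResult:
    """Temporal clusters with their mass and permutation p-values."""

    clusters: list  # of dicts {start, end, t_start, t_end, mass, p}
    threshold: float
    n_permutations: int
    exhaustive: bool
    t_obs: np.ndarray = field(repr=False, default=None)


@dataclass
class PrevalenceResult:
    k: int
    n: int
    alpha: float
    map: float
    hpdi: tuple


def _sign_matrix(n: int, n_perm: int, rng: np.random.Generator):
    """All 2^n sign patterns when feasible, else random draws."""
    if 2**n <= n_perm:
        bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        return 2.0 * bits - 1.0, True
    return rng.choice([-1.0, 1.0], size=(n_perm, n)), False


def paired_permutation_test(
    a,
    b=0.5,
    n_perm: int = 2048,
    side: str = "greater",
    rng: np.random.Generator | int | None = None,
) -> PermTestResult:
    """Paired permutation test on per-subject values.

    The statistic is the mean paired difference mean(a - b); the null is
    built by random sign flips of the differences (exhaustive enumeration
    of all 2^n patterns when 2^n <= n_perm).  ``b`` may be a vector of
    paired values or a scalar reference such as the 0.5 chance level.
    """
    a = np.asarray(a, dtype=float)
    b_arr = np.broadcast_to(np.asarray(b, dtype=float), a.shape)
    if a.ndim != 1 or a.size < 2:
        raise ValueError("need a 1-D sample of at least 2 paired values")
    d = a - b_arr
    n = d.size
    obs = float(d.mean())

    rng = np.random.default_rng(rng)
    signs, exhaustive = _sign_matrix(n, n_perm, rng)
    null = signs @ d / n

    if side == "greater":
        hits = null >= obs - 1e-12
    elif side == "less":
        hits = null <= obs + 1e-12
    elif side == "two-sided":
        hits = np.abs(null) >= abs(obs) - 1e-12
    else:
        raise ValueError(f"unknown side {side!r}")

    if exhaustive:
        p = float(hits.mean())
        n_draws = signs.shape[0]
    else:
        n_draws = n_perm
        p = float((1 + hits.sum()) / (1 + n_perm))
    return PermTestResult(observed=obs, p=p, n_permutations=n_draws, exhaustive=exhaustive, side=side)


def holm_adjust(pvals) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def _t_onesample(d: np.ndarray) -> np.ndarray:
    """Pointwise one-sample t vs 0 over subjects (axis 0); zero-variance
    timepoints give t = 0 with a warning."""
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    bad = sd == 0
    if bad.any():
        warnings.warn("zero-variance timepoints: t set to 0", RuntimeWarning)
        sd = np.where(bad, np.inf, sd)
    return m / (sd / np.sqrt(n))


def _clusters_from_t(t: np.ndarray, threshold: float, side: str):
    """Maximal runs of adjacent supra-threshold timepoints with their mass."""
    if side == "greater":
        supra = t > threshold
        signed = t
    elif side == "less":
        supra = t < -threshold
        signed = -t
    else:  # two-sided: positive and negative runs separately, mass = |sum t|
        supra = np.abs(t) > threshold
        signed = np.abs(t)

    out = []
    i, T = 0, t.size
    while i < T:
        if supra[i]:
            j = i
            while j + 1 < T and supra[j + 1] and (
                side != "two-sided" or np.sign(t[j + 1]) == np.sign(t[i])
            ):
                j += 1
            out.append((i, j, float(signed[i : j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return out


def _max_cluster_mass(t: np.ndarray, threshold: float, side: str) -> float:
    cl = _clusters_from_t(t, threshold, side)
    return max((m for _, _, m in cl), default=0.0)


def cluster_permutation_test(
    series,
    n_perm: int = 2048,
    cluster_alpha: float = 0.05,
    side: str = "greater",
    times=None,
    threshold: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test on subject x time series.

    Pointwise one-sample t statistics against zero are thresholded at the
    two-sided ``cluster_alpha`` t quantile (df = n - 1); clusters are
    maximal runs of adjacent supra-threshold timepoints with mass = sum
    of t.  The null distribution is the maximum cluster mass over
    sign-flip permutations of whole subjects, exhaustive when 2^n does
    not exceed ``n_perm``.
    """
    d = np.asarray(series, dtype=float)
    if d.ndim != 2 or d.shape[0] < 2 or d.shape[1] < 1:
        raise ValueError("series must be subjects x timepoints with >= 2 subjects")
    n, T = d.shape
    if threshold is None:
        threshold = float(sps.t.ppf(1.0 - cluster_alpha / 2.0, df=n - 1))

    t_obs = _t_onesample(d)
    clusters = _clusters_from_t(t_obs, threshold, side)

    rng = np.random.default_rng(rng)
    signs, exhaustive = _sign_matrix(n, n_perm, rng)
    n_draws = signs.shape[0]

    # sign flips leave per-subject squares unchanged: reuse sum of squares
    ss = (d**2).sum(axis=0)
    null_max = np.empty(n_draws)
    sqrt_n = np.sqrt(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n_draws):
            m = signs[i] @ d / n
            var = (ss - n * m**2) / (n - 1)
            sd = np.sqrt(np.maximum(var, 0.0))
            t_null = np.divide(m, sd / sqrt_n, out=np.zeros(T), where=sd > 0)
            null_max[i] = _max_cluster_mass(t_null, threshold, side)

    results = []
    for start, end, mass in clusters:
        if exhaustive:
            p = float((null_max >= mass - 1e-12).mean())
        else:
            p = float((1 + (null_max >= mass - 1e-12).sum()) / (1 + n_draws))
        entry = {"start": start, "end": end, "mass": mass, "p": p}
        if times is not None:
            entry["t_start"] = float(np.asarray(times)[start])
            entry["t_end"] = float(np.asarray(times)[end])
        results.append(entry)
    return ClusterResult(
        clusters=results,
        threshold=threshold,
        n_permutations=n_draws,
        exhaustive=exhaustive,
        t_obs=t_obs,
    )


def prevalence_estimate(k: int, n: int, alpha: float = 0.05, ci: float = 0.95) -> PrevalenceResult:
    """Bayesian lower-bound population prevalence from a subject count.

    Each subject shows a significant effect with probability
    theta = alpha + gamma * (1 - alpha), where gamma is the population
    prevalence of true effects and alpha the within-subject false-positive
    level.  With a uniform prior, the posterior on theta after observing
    k significant subjects of n is Beta(k + 1, n - k + 1).  The MAP of
    gamma is max(0, (k/n - alpha) / (1 - alpha)); the HPD interval is
    found numerically on the theta posterior and mapped through
    gamma = (theta - alpha) / (1 - alpha), truncated to [0, 1].
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    post = sps.beta(k + 1, n - k + 1)

    gamma_map = max(0.0, (k / n - alpha) / (1.0 - alpha))

    # shortest interval containing `ci` posterior mass (posterior is unimodal)
    tail = 1.0 - ci

    def width(lo_mass: float) -> float:
        return post.ppf(lo_mass + ci) - post.ppf(lo_mass)

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(width, bounds=(0.0, tail), method="bounded")
    cands = [0.0, tail, float(res.x)]
    lo_mass = min(cands, key=width)
    theta_lo, theta_hi = post.ppf(lo_mass), post.ppf(lo_mass + ci)

    to_gamma = lambda th: min(1.0, max(0.0, (th - alpha) / (1.0 - alpha)))
    lo, hi = to_gamma(theta_lo), to_gamma(theta_hi)
    lo = min(lo, gamma_map)
    hi = max(hi, gamma_map)
    return PrevalenceResult(k=k, n=n, alpha=alpha, map=gamma_map, hpdi=(lo, hi))
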