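"""Study statistics: Spearman correlation (exact permutation p at small n),
partial Spearman with a covariate, one-tailed t contrasts, and normality
diagnostics (Monte-Carlo Lilliefors, bias-corrected skewness).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as ss

__all__ = [
    "StatResult",
    "spearman",
    "partial_spearman",
    "paired_t_one_tailed",
    "lilliefors_null",
    "distribution_diagnostics",
    "top_bottom_contrast",
]

EXACT_PERMUTATION_MAX_N = 10


class DegenerateTestError(ValueError):
    """The requested statistic is undefined on the given data."""


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p: float
    tails: str  # {"one", "two"}
    method: str
    df: float | None = None
    n: int | None = None


def _ranks(x: np.ndarray) -> np.ndarray:
    return ss.rankdata(x, method="average")


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise DegenerateTestError("constant input vector")
    return float((rx * ry).sum() / denom)


def _exact_null(rx: np.ndarray, ry: np.ndarray, chunk: int = 200_000) -> np.ndarray:
    """Rank correlations of rx against every permutation of ry."""
    n = len(rx)
    rxc = rx - rx.mean()
    denom = np.sqrt((rxc**2).sum() * ((ry - ry.mean()) ** 2).sum())
    if denom == 0:
        raise DegenerateTestError("constant input vector")
    out = []
    it = itertools.permutations(ry - ry.mean())
    while True:
        block = np.array(list(itertools.islice(it, chunk)))
        if block.size == 0:
            break
        out.append(block @ rxc / denom)
    return np.concatenate(out)


def spearman(x, y, tails: str = "two", alternative: str = "greater") -> StatResult:
    """Spearman rank correlation with average ranks for ties.

    The p-value is exact (full permutation enumeration) for n <= 10 and
    uses the usual t approximation (df = n - 2) otherwise.  For one-tailed
    tests ``alternative`` gives the hypothesised direction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    n = len(x)
    rx, ry = _ranks(x), _ranks(y)
    rho = _rank_corr(rx, ry)

    if n <= EXACT_PERMUTATION_MAX_N:
        rho_null = _exact_null(rx, ry)
        if tails == "two":
            p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
        elif alternative == "greater":
            p = float(np.mean(rho_null >= rho - 1e-12))
        else:
            p = float(np.mean(rho_null <= rho + 1e-12))
        method = "spearman-exact"
        df = None
    else:
        df = n - 2
        if abs(rho) >= 1.0:
            p_two = 0.0
        else:
            t = rho * np.sqrt(df / (1.0 - rho**2))
            p_two = 2.0 * ss.t.sf(abs(t), df)
        if tails == "two":
            p = p_two
        else:
            p_one = p_two / 2.0
            in_direction = (rho >= 0) if alternative == "greater" else (rho <= 0)
            p = p_one if in_direction else 1.0 - p_one
        method = "spearman-t"
    return StatResult(statistic=rho, p=min(p, 1.0), tails=tails, method=method, df=df, n=n)


def partial_spearman(x, y, covariate, tails: str = "two") -> StatResult:
    """Spearman correlation of x and y after removing a covariate.

    Both variables are ranked, linearly regressed on the ranked covariate,
    and the residuals are rank-correlated.  A constant covariate cannot be
    regressed out; the plain Spearman is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if not (len(x) == len(y) == len(c)) or len(x) < 4:
        raise ValueError("need three equal-length vectors, n >= 4")
    if np.ptp(c) == 0:
        warnings.warn("constant covariate; falling back to plain Spearman")
        res = spearman(x, y, tails=tails)
        return StatResult(res.statistic, res.p, res.tails, "partial-spearman-fallback", res.df, res.n)

    rc = _ranks(c)
    design = np.column_stack([np.ones(len(rc)), rc])
    res_x = _ranks(x) - design @ np.linalg.lstsq(design, _ranks(x), rcond=None)[0]
    res_y = _ranks(y) - design @ np.linalg.lstsq(design, _ranks(y), rcond=None)[0]
    # a variable fully explained by the covariate leaves numerical dust as
    # residuals; its partial association is zero, not the dust's rank noise
    tiny = 1e-8 * len(x)
    if res_x.std() < tiny or res_y.std() < tiny:
        return StatResult(0.0, 1.0, tails, "partial-spearman", None, len(x))
    res = spearman(res_x, res_y, tails=tails)
    return StatResult(res.statistic, res.p, res.tails, "partial-spearman", res.df, res.n)


def paired_t_one_tailed(a, b, direction: str = "greater") -> StatResult:
    """One-tailed paired t-test on a - b (df = n - 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need two equal-length vectors, n >= 2")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:  # identical vectors: no evidence either way
            return StatResult(0.0, 0.5, "one", "paired-t", df=len(a) - 1, n=len(a))
        raise DegenerateTestError("zero variance of paired differences")
    t, p = ss.ttest_rel(a, b, alternative=direction)
    return StatResult(statistic=float(t), p=float(p), tails="one",
                      method="paired-t", df=len(a) - 1, n=len(a))


def _lilliefors_stat(x: np.ndarray) -> float:
    """Two-sided KS distance between the ECDF and a normal CDF with the
    sample's own mean and (ddof=1) SD."""
    n = len(x)
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = ss.norm.cdf(z)
    d_plus = np.max(np.arange(1, n + 1) / n - cdf)
    d_minus = np.max(cdf - np.arange(0, n) / n)
    return float(max(d_plus, d_minus))


def lilliefors_null(n: int, n_mc: int = 10000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors statistic at sample
    size ``n`` (normal draws, statistic recomputed with estimated moments).
    Reusable across tests at the same n."""
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_mc, n))
    return np.array([_lilliefors_stat(row) for row in draws])


def distribution_diagnostics(
    x, n_mc: int = 10000, seed: int = 0, null: np.ndarray | None = None
) -> dict:
    """Normality diagnostics: Lilliefors test (Monte-Carlo p) and
    bias-corrected sample skewness.

    The p-value is ``(1 + #{null >= observed}) / (1 + n_mc)`` over seeded
    normal null draws; a precomputed ``null`` (from
    :func:`lilliefors_null`) may be supplied.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("need n >= 5")
    if np.ptp(x) == 0:
        raise DegenerateTestError("zero variance")
    stat = _lilliefors_stat(x)
    if null is None:
        null = lilliefors_null(len(x), n_mc=n_mc, seed=seed)
    p = float((1 + np.sum(null >= stat)) / (1 + len(null)))
    return {
        "lilliefors_stat": stat,
        "lilliefors_p": p,
        "skewness": float(ss.skew(x, bias=False)),
        "n": len(x),
    }


def top_bottom_contrast(vs, tri, ids=None, k: int = 10) -> StatResult:
    """One-tailed two-sample t of TRI between the k highest- and k
    lowest-VS subjects (df = 2k - 2).

    Ties straddling the k-th rank break deterministically by subject id.
    """
    vs = np.asarray(vs, dtype=float)
    tri = np.asarray(tri, dtype=float)
    n = len(vs)
    if len(tri) != n:
        raise ValueError("vs and tri length mismatch")
    if n < 2 * k:
        raise ValueError("need at least 2k subjects")
    ids = np.arange(n) if ids is None else np.asarray(ids)
    order = np.lexsort((ids, vs))  # ascending vs, ties by id
    bottom = order[:k]
    top = order[-k:]
    if np.ptp(np.concatenate([tri[top], tri[bottom]])) == 0:
        return StatResult(0.0, 0.5, "one", "top-bottom-t", df=2 * k - 2, n=2 * k)
    t, p = ss.ttest_ind(tri[top], tri[bottom], alternative="greater")
    return StatResult(float(t), float(p), "one", "top-bottom-t", df=2 * k - 2, n=2 * k)
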