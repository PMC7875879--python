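"""Null distributions for score-based parameter-instability statistics.

Under parameter homogeneity each column of the decorrelated cumulative score
process converges to an independent standard Brownian bridge, so the null
distribution of every statistic is a functional of ``q`` independent bridges.
Analytic tails are used where they exist:

* ``DM`` — the supremum of ``|bridge|`` follows the Kolmogorov distribution;
  the maximum over ``q`` independent bridges has CDF ``K(x)**q``.
* ``WDM`` — the bridge inspected at the ``m - 1`` ordinal level boundaries is
  multivariate normal; the rectangle probability gives the exact tail.
* weighted categorical ``LM`` — chi-square with ``q (m - 1)`` degrees of
  freedom.

The remaining functionals (``CvM``, ``maxLM``, ``maxLM_O``, ``maxLR``, and
the printed differenced categorical ``LM``) are simulated: Brownian bridges on
a 1,000-point grid (or the exact finite-dimensional Gaussian for binned
statistics), 20,000 replicates, fixed internal seed, cached per configuration
within the process.  Simulated p-values report a Monte Carlo standard error
and are truncated to ``[1 / (reps + 1), 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PValue",
    "dm_pvalue",
    "cvm_pvalue",
    "suplm_pvalue",
    "wdm_pvalue",
    "maxlm_ordinal_pvalue",
    "lm_printed_pvalue",
    "lm_weighted_pvalue",
    "critical_value_table",
    "clear_cache",
]

_TABLE_SEED = 186525  # fixed: asymptotic tables are not user randomness
_GRID = 1000
_REPS = 20000
_CACHE: dict[tuple, np.ndarray] = {}


@dataclass
class PValue:
    p: float
    method: str  # "analytic" | "simulated"
    mc_se: float = 0.0


def clear_cache() -> None:
    _CACHE.clear()


def _null_sample(key: tuple, builder) -> np.ndarray:
    if key not in _CACHE:
        _CACHE[key] = np.sort(builder())
    return _CACHE[key]


def _simulated_p(stat: float, null: np.ndarray) -> PValue:
    reps = null.size
    exceed = reps - np.searchsorted(null, stat, side="right")
    p = max(exceed / reps, 1.0 / (reps + 1.0))
    se = float(np.sqrt(p * (1.0 - p) / reps))
    return PValue(p=float(min(p, 1.0)), method="simulated", mc_se=se)


def _bridges(rng: np.random.Generator, nrep: int, q: int, grid: int) -> np.ndarray:
    """nrep x grid x q Brownian bridges at t = 1/grid .. 1 (last row zero)."""
    inc = rng.standard_normal((nrep, grid, q)) / np.sqrt(grid)
    w = np.cumsum(inc, axis=1)
    t = (np.arange(1, grid + 1) / grid)[None, :, None]
    return w - t * w[:, -1:, :]


def _sim_functional(q: int, fn, *, grid: int = _GRID, reps: int = _REPS,
                    batch: int = 2000) -> np.ndarray:
    rng = np.random.default_rng(_TABLE_SEED)
    out = np.empty(reps)
    pos = 0
    while pos < reps:
        nb = min(batch, reps - pos)
        out[pos:pos + nb] = fn(_bridges(rng, nb, q, grid))
        pos += nb
    return out


# -- continuous-covariate statistics ----------------------------------------


def dm_pvalue(stat: float, q: int) -> PValue:
    """Double-maximum statistic: Kolmogorov tail for q independent bridges."""
    if stat <= 0:
        return PValue(1.0, "analytic")
    return PValue(float(1.0 - stats.kstwobign.cdf(stat) ** q), "analytic")


def cvm_pvalue(stat: float, q: int, *, grid: int = _GRID, reps: int = _REPS) -> PValue:
    def fn(b):
        return np.einsum("rgk->r", b ** 2) / b.shape[1]

    null = _null_sample(("cvm", q, grid, reps),
                        lambda: _sim_functional(q, fn, grid=grid, reps=reps))
    return _simulated_p(stat, null)


def suplm_null(q: int, trim: tuple[float, float], *, grid: int = _GRID,
               reps: int = _REPS) -> np.ndarray:
    lo, hi = round(float(trim[0]), 3), round(float(trim[1]), 3)

    def fn(b):
        g = b.shape[1]
        t = np.arange(1, g + 1) / g
        keep = (t >= lo) & (t <= hi) & (t < 1.0)
        tt = t[keep]
        ssq = np.einsum("rgk->rg", b[:, keep, :] ** 2)
        return (ssq / (tt * (1.0 - tt))[None, :]).max(axis=1)

    return _null_sample(("suplm", q, lo, hi, grid, reps),
                        lambda: _sim_functional(q, fn, grid=grid, reps=reps))


def suplm_pvalue(stat: float, q: int, trim: tuple[float, float]) -> PValue:
    return _simulated_p(stat, suplm_null(q, trim))


# -- binned statistics (ordinal / categorical covariates) --------------------


def _bridge_cov(props: np.ndarray) -> np.ndarray:
    """Covariance of the bridge at cumulative proportions ``props``."""
    t = np.asarray(props, dtype=float)
    return np.minimum.outer(t, t) - np.outer(t, t)


def _binned_bridge_draws(props: np.ndarray, q: int, reps: int) -> np.ndarray:
    """reps x (len props) x q exact draws of the bridge at the boundaries."""
    C = _bridge_cov(props)
    w, V = np.linalg.eigh(C)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(_TABLE_SEED + 1)
    z = rng.standard_normal((reps, q, len(props)))
    return np.einsum("rqj,kj->rkq", z, root)


def maxlm_ordinal_pvalue(stat: float, q: int, props, *, reps: int = 50000) -> PValue:
    key = ("maxlmo", q, tuple(np.round(props, 4)), reps)

    def build():
        t = np.asarray(props, dtype=float)
        draws = _binned_bridge_draws(t, q, reps)
        ssq = np.einsum("rkq->rk", draws ** 2)
        return (ssq / (t * (1.0 - t))[None, :]).max(axis=1)

    return _simulated_p(stat, _null_sample(key, build))


def wdm_pvalue(stat: float, q: int, props, *, max_analytic_dim: int = 25) -> PValue:
    """Weighted double maximum: exact MVN rectangle at the level boundaries."""
    t = np.asarray(props, dtype=float)
    if stat <= 0:
        return PValue(1.0, "analytic")
    if len(t) == 1:
        p1 = 2.0 * stats.norm.sf(stat)
        return PValue(float(1.0 - (1.0 - p1) ** q), "analytic")
    if len(t) <= max_analytic_dim:
        C = _bridge_cov(t)
        s = np.sqrt(np.diag(C))
        R = C / np.outer(s, s)
        rect = stats.multivariate_normal(mean=np.zeros(len(t)), cov=R,
                                         allow_singular=True).cdf(
            np.full(len(t), stat), lower_limit=np.full(len(t), -stat))
        rect = min(max(float(rect), 0.0), 1.0)
        return PValue(float(1.0 - rect ** q), "analytic")
    key = ("wdm", q, tuple(np.round(t, 4)))

    def build():
        draws = _binned_bridge_draws(t, q, 50000)
        scale = np.sqrt(t * (1.0 - t))
        return (np.abs(draws).max(axis=2) / scale[None, :]).max(axis=1)

    return _simulated_p(stat, _null_sample(key, build))


def _lm_printed_weights(props_per_level: np.ndarray) -> np.ndarray:
    """Eigenvalues of the differenced multinomial-bridge covariance.

    The printed categorical statistic sums squared consecutive differences of
    the per-level score sums; its null is the Gaussian quadratic form with
    these weights (times independent chi-square_q variates).
    """
    pi = np.asarray(props_per_level, dtype=float)
    m = pi.size
    C = np.diag(pi) - np.outer(pi, pi)
    M = np.eye(m) - np.diag(np.ones(m - 1), -1)
    w = np.linalg.eigvalsh(M @ C @ M.T)
    return np.clip(w, 0.0, None)


def lm_printed_pvalue(stat: float, q: int, props_per_level, *,
                      reps: int = 200000) -> PValue:
    lam = _lm_printed_weights(props_per_level)
    lam = lam[lam > 1e-12]
    key = ("lmprint", q, tuple(np.round(lam, 6)), reps)

    def build():
        rng = np.random.default_rng(_TABLE_SEED + 2)
        chis = rng.chisquare(q, size=(reps, lam.size))
        return chis @ lam

    return _simulated_p(stat, _null_sample(key, build))


def lm_weighted_pvalue(stat: float, q: int, m: int) -> PValue:
    """Undifferenced weighted categorical LM: chi-square with q(m-1) df."""
    return PValue(float(stats.chi2.sf(stat, q * (m - 1))), "analytic")


# -- table export ------------------------------------------------------------


def critical_value_table(configs, quantiles=(0.90, 0.95, 0.99)) -> "pd.DataFrame":
    """Tabulate simulated critical values.

    ``configs`` is an iterable of dicts with keys ``statistic`` ("CvM" |
    "maxLM"), ``q`` and, for maxLM, ``trim``.  Returns a tidy table including
    the generating seed; regenerable via the CLI ``make-critical-values``.
    """
    import pandas as pd

    rows = []
    for cfg in configs:
        kind = cfg["statistic"]
        q = int(cfg["q"])
        if kind == "CvM":
            def fn(b):
                return np.einsum("rgk->r", b ** 2) / b.shape[1]
            null = _null_sample(("cvm", q, _GRID, _REPS), lambda: _sim_functional(q, fn))
            trim = ""
        elif kind == "maxLM":
            trim = tuple(cfg.get("trim", (0.1, 0.9)))
            null = suplm_null(q, trim)
        else:
            raise ValueError(f"no simulated table for statistic {kind!r}")
        for qu in quantiles:
            rows.append({"statistic": kind, "q": q, "trim": str(trim),
                         "quantile": qu, "value": float(np.quantile(null, qu)),
                         "reps": null.size, "seed": _TABLE_SEED})
    return pd.DataFrame(rows)
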