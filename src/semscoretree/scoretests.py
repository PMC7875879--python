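"""Score-based parameter-instability tests on cumulative score processes.

The case-wise scores of a fitted model are sorted by a covariate, decorrelated
with the symmetric inverse square root of the per-observation information, and
cumulated:

    CSP(s) = n^{-1/2} I^{-1/2} sum_{h<=s} score_h .

Under parameter homogeneity each of the ``q`` columns behaves like an
independent Brownian bridge, and functionals of the process yield tests that
are sensitive to different heterogeneity patterns: ``DM`` (double maximum),
``CvM`` (Cramér–von Mises), and ``maxLM`` (maximum Lagrange multiplier with a
variance-stabilizing scaling and trimmed boundaries) for continuous
covariates; ``WDM`` and ``maxLM_O`` on cumulative level bins for ordinal
covariates; and the per-level ``LM`` statistic for categorical covariates.

Omitting the outer maximum pairs every admissible cut with a partial
statistic, which is also how cut points are localized after a covariate has
been selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from . import nulldist
from .nulldist import PValue

__all__ = [
    "ScoreProcess",
    "BinnedProcess",
    "ScoreTestResult",
    "inverse_sqrt",
    "cumulative_score_process",
    "bin_scores",
    "dm_statistic",
    "cvm_statistic",
    "maxlm_statistic",
    "wdm_statistic",
    "maxlm_ordinal_statistic",
    "lm_categorical_statistic",
    "score_pvalue",
    "locate_cutpoint_score",
]

DEFAULT_TRIM = (0.15, 0.85)


def inverse_sqrt(info: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root of a positive definite matrix."""
    info = np.asarray(info, dtype=float)
    w, V = linalg.eigh(info)
    if w.min() <= 1e-12 * max(w.max(), 1.0):
        bad = np.nonzero(w <= 1e-12 * max(w.max(), 1.0))[0]
        raise np.linalg.LinAlgError(
            f"information matrix is singular (eigenvector(s) {bad.tolist()})")
    return (V / np.sqrt(w)) @ V.T


@dataclass
class ScoreProcess:
    """Decorrelated cumulative score process induced by a covariate ordering."""

    csp: np.ndarray  # N x q
    order: np.ndarray  # permutation of case indices (covariate-sorted)
    sorted_values: np.ndarray  # covariate values in sorted order
    boundaries: np.ndarray | None = None  # admissible s between distinct values (None: all)

    @property
    def n(self) -> int:
        return self.csp.shape[0]

    @property
    def q(self) -> int:
        return self.csp.shape[1]

    def select_columns(self, cols) -> "ScoreProcess":
        return ScoreProcess(csp=self.csp[:, list(cols)], order=self.order,
                            sorted_values=self.sorted_values,
                            boundaries=self.boundaries)


@dataclass
class BinnedProcess:
    """Per-level score sums for ordinal / categorical covariates.

    ``bsp`` holds the scaled per-level sums (m x q), ``cbsp`` their cumulative
    sums over the first m - 1 levels, ``counts`` the per-level case counts.
    """

    bsp: np.ndarray  # m x q
    cbsp: np.ndarray  # (m-1) x q
    counts: np.ndarray  # m per-level counts
    levels: tuple  # level values in order

    @property
    def m(self) -> int:
        return len(self.counts)

    @property
    def q(self) -> int:
        return self.bsp.shape[1]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def cumulative_counts(self) -> np.ndarray:
        return np.cumsum(self.counts)[:-1]

    def select_columns(self, cols) -> "BinnedProcess":
        return BinnedProcess(bsp=self.bsp[:, list(cols)],
                             cbsp=self.cbsp[:, list(cols)],
                             counts=self.counts, levels=self.levels)


@dataclass
class ScoreTestResult:
    kind: str
    statistic: float
    partial: np.ndarray  # per admissible position / level boundary
    positions: np.ndarray  # s values (counts left of the boundary)
    trim: tuple[float, float] | None = None
    pvalue: PValue | None = None
    extra: dict = field(default_factory=dict)


def cumulative_score_process(scores: np.ndarray, info: np.ndarray,
                             covariate_values: np.ndarray) -> ScoreProcess:
    """Build the decorrelated cumulative score process.

    Cases are stably sorted by the covariate; runs of tied values are recorded
    so that cut points never separate tied cases.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    x = np.asarray(covariate_values)
    order = np.argsort(x, kind="stable")
    isq = inverse_sqrt(info)
    csp = np.cumsum(scores[order], axis=0) @ isq.T / np.sqrt(n)
    xs = x[order]
    boundaries = np.nonzero(xs[:-1] != xs[1:])[0] + 1  # 1-based counts
    return ScoreProcess(csp=csp, order=order, sorted_values=xs,
                        boundaries=boundaries)


def bin_scores(scores: np.ndarray, covariate_values: np.ndarray,
               levels, info: np.ndarray) -> BinnedProcess:
    """Sum decorrelated, n^{-1/2}-scaled scores within covariate levels.

    Empty levels are dropped (ordinal neighbours absorb them implicitly since
    only occupied boundaries remain).
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    isq = inverse_sqrt(info)
    dec = scores @ isq.T / np.sqrt(n)
    x = np.asarray(covariate_values)
    sums, counts, kept = [], [], []
    for lev in levels:
        mask = x == lev
        c = int(mask.sum())
        if c == 0:
            continue
        kept.append(lev)
        counts.append(c)
        sums.append(dec[mask].sum(axis=0))
    bsp = np.vstack(sums)
    cbsp = np.cumsum(bsp, axis=0)[:-1]
    return BinnedProcess(bsp=bsp, cbsp=cbsp, counts=np.asarray(counts),
                         levels=tuple(kept))


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def dm_statistic(sp: ScoreProcess) -> ScoreTestResult:
    """Double maximum: max over positions and parameters of |CSP|."""
    partial = np.abs(sp.csp).max(axis=1)
    return ScoreTestResult(kind="DM", statistic=float(partial.max()),
                           partial=partial, positions=np.arange(1, sp.n + 1))


def cvm_statistic(sp: ScoreProcess) -> ScoreTestResult:
    """Cramér–von Mises: mean over positions of the summed squared process."""
    persum = (sp.csp ** 2).sum(axis=1)
    return ScoreTestResult(kind="CvM", statistic=float(persum.sum() / sp.n),
                           partial=persum, positions=np.arange(1, sp.n + 1))


def _maxlm_partials(sp: ScoreProcess, trim: tuple[float, float],
                    min_side: int = 0) -> tuple[np.ndarray, np.ndarray]:
    n = sp.n
    lo = max(int(np.ceil(trim[0] * n)), 1, min_side)
    hi = min(int(np.floor(trim[1] * n)), n - 1, n - min_side)
    s = np.arange(lo, hi + 1)
    if sp.boundaries is not None:
        s = np.intersect1d(s, sp.boundaries)
    if s.size == 0:
        return np.array([]), np.array([], dtype=int)
    frac = s / n
    ssq = (sp.csp[s - 1] ** 2).sum(axis=1)
    return ssq / (frac * (1.0 - frac)), s


def maxlm_statistic(sp: ScoreProcess, trim: tuple[float, float] = DEFAULT_TRIM,
                    min_side: int = 0) -> ScoreTestResult:
    """Maximum LM: trimmed maximum of the variance-stabilized squared process."""
    if not 0.0 < trim[0] < trim[1] < 1.0:
        raise ValueError(f"trim fractions must satisfy 0 < lo < hi < 1, got {trim}")
    partial, s = _maxlm_partials(sp, trim, min_side)
    stat = float(partial.max()) if partial.size else 0.0
    return ScoreTestResult(kind="maxLM", statistic=stat, partial=partial,
                           positions=s, trim=trim)


def _binned_scale(bp: BinnedProcess) -> np.ndarray:
    frac = bp.cumulative_counts / bp.n
    return frac * (1.0 - frac)


def wdm_statistic(bp: BinnedProcess) -> ScoreTestResult:
    """Weighted double maximum over the first m - 1 cumulative level bins."""
    scale = np.sqrt(_binned_scale(bp))
    partial = np.abs(bp.cbsp).max(axis=1) / scale
    return ScoreTestResult(kind="WDM", statistic=float(partial.max()),
                           partial=partial, positions=bp.cumulative_counts)


def maxlm_ordinal_statistic(bp: BinnedProcess) -> ScoreTestResult:
    """Maximum LM at the m - 1 ordinal level boundaries."""
    partial = (bp.cbsp ** 2).sum(axis=1) / _binned_scale(bp)
    return ScoreTestResult(kind="maxLM_O", statistic=float(partial.max()),
                           partial=partial, positions=bp.cumulative_counts)


def lm_categorical_statistic(bp: BinnedProcess, variant: str = "printed") -> ScoreTestResult:
    """Categorical LM statistic.

    ``printed``: sum of squared consecutive differences of the per-level sums
    (with the zeroth sum set to zero); depends on the level order by
    construction.  ``weighted``: the order-invariant sum of squared per-level
    sums weighted by inverse level proportions, whose null is chi-square with
    q(m-1) degrees of freedom.
    """
    if variant == "printed":
        diffs = np.diff(np.vstack([np.zeros(bp.q), bp.bsp]), axis=0)
        partial = (diffs ** 2).sum(axis=1)
        stat = float(partial.sum())
    elif variant == "weighted":
        frac = bp.counts / bp.n
        partial = (bp.bsp ** 2).sum(axis=1) / frac
        stat = float(partial.sum())
    else:
        raise ValueError(f"unknown LM variant {variant!r}")
    return ScoreTestResult(kind="LM", statistic=stat, partial=partial,
                           positions=np.arange(1, bp.m + 1),
                           extra={"variant": variant,
                                  "props": tuple(bp.counts / bp.n),
                                  "m": bp.m})


# ---------------------------------------------------------------------------
# p-values and cut-point localization
# ---------------------------------------------------------------------------


def score_pvalue(result: ScoreTestResult, q: int, *, n: int | None = None,
                 props=None) -> PValue:
    """Attach the null-distribution p-value for a computed statistic.

    ``q`` is the effective number of (focus) parameters; ``props`` are the
    cumulative level proportions for binned statistics.
    """
    kind = result.kind
    if kind == "DM":
        pv = nulldist.dm_pvalue(result.statistic, q)
    elif kind == "CvM":
        pv = nulldist.cvm_pvalue(result.statistic, q)
    elif kind == "maxLM":
        pv = nulldist.suplm_pvalue(result.statistic, q, result.trim or DEFAULT_TRIM)
    elif kind == "WDM":
        pv = nulldist.wdm_pvalue(result.statistic, q, props)
    elif kind == "maxLM_O":
        pv = nulldist.maxlm_ordinal_pvalue(result.statistic, q, props)
    elif kind == "LM":
        if result.extra.get("variant") == "weighted":
            pv = nulldist.lm_weighted_pvalue(result.statistic, q, result.extra["m"])
        else:
            pv = nulldist.lm_printed_pvalue(result.statistic, q,
                                            result.extra["props"])
    else:
        raise ValueError(f"unknown statistic kind {kind!r}")
    result.pvalue = pv
    return pv


def locate_cutpoint_score(sp_or_bp, trim: tuple[float, float] = DEFAULT_TRIM,
                          min_side: int = 0):
    """Locate the cut after the position maximizing the maxLM-type partials.

    Continuous: returns the midpoint between the adjacent distinct covariate
    values; ordinal: the boundary after the selected level.  Ties resolve to
    the earliest admissible boundary.
    """
    if isinstance(sp_or_bp, ScoreProcess):
        partial, s = _maxlm_partials(sp_or_bp, trim, min_side)
        if partial.size == 0:
            return None
        best = int(s[int(np.argmax(partial))])
        xs = sp_or_bp.sorted_values
        return 0.5 * (float(xs[best - 1]) + float(xs[best]))
    bp: BinnedProcess = sp_or_bp
    partial = (bp.cbsp ** 2).sum(axis=1) / _binned_scale(bp)
    best = int(np.argmax(partial))
    return bp.levels[best]
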