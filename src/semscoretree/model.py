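"""Mean- and covariance-structure models estimated by normal-theory maximum likelihood.

A template model maps a free-parameter vector ``theta`` (length ``q``) to a
model-implied mean vector ``mu(theta)`` (length ``p``, optional) and covariance
matrix ``Sigma(theta)`` (``p x p``).  Templates are specified through labelled
pattern matrices in the factor-analytic form

    Sigma(theta) = Lambda Phi Lambda' + Theta,      mu(theta) = nu + Lambda alpha,

where pattern entries are either numeric constants (fixed) or string labels
(free parameters; repeated labels impose equality).  Estimation minimizes the
maximum likelihood discrepancy

    F_ML = (ybar - mu)' Sigma^{-1} (ybar - mu) + tr(S Sigma^{-1})
           - ln det(S Sigma^{-1}) - p,

with ``S`` the maximum likelihood (divide-by-n) sample covariance, so that
``n * F_ML`` and ``-2 log L`` differ by a theta-independent constant and the
same estimates maximize the summed case-wise normal log-likelihood.

Fitted models expose the ingredients of score-based parameter-instability
tests: case-wise log-likelihoods, the ``N x q`` score matrix (case-wise
gradients of the log-likelihood at the estimates, which sum to zero), and a
per-observation information estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "EstimationError",
    "TemplateModel",
    "Covariate",
    "Dataset",
    "FittedModel",
    "ml_moments",
    "evaluate_fml",
    "fit_ml",
    "fit_ml_moments",
    "casewise_scores",
    "information_estimate",
    "lr_statistic",
]

_LN_2PI = float(np.log(2.0 * np.pi))


class EstimationError(RuntimeError):
    """Raised when a model cannot be estimated on the given sample."""


def ml_moments(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean and maximum likelihood (divide-by-n) covariance of ``Y``."""
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    ybar = Y.mean(axis=0)
    D = Y - ybar
    S = D.T @ D / n
    return ybar, S


def _sym(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a + a.T)


# ---------------------------------------------------------------------------
# Template specification
# ---------------------------------------------------------------------------


def _as_pattern(pat, shape) -> np.ndarray:
    arr = np.empty(shape, dtype=object)
    pat = np.asarray(pat, dtype=object).reshape(shape)
    arr[...] = pat
    return arr


@dataclass
class TemplateModel:
    """Parametric template: free parameters mapped to implied moments.

    Built from labelled pattern matrices (see module docstring).  ``nu`` /
    ``alpha`` may be ``None``, in which case the model has no mean structure
    and the mean vector is treated as saturated (fixed at the sample mean of
    whatever sample the model is evaluated on); mean parameters then carry no
    scores.
    """

    lam: np.ndarray  # p x r pattern
    phi: np.ndarray  # r x r symmetric pattern
    theta: np.ndarray  # p x p symmetric pattern (residual covariance)
    nu: np.ndarray | None = None  # p intercept pattern
    alpha: np.ndarray | None = None  # r latent-mean pattern
    start_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    name: str = "custom"

    def __post_init__(self):
        self.lam = _as_pattern(self.lam, np.shape(self.lam))
        p, r = self.lam.shape
        self.phi = _as_pattern(self.phi, (r, r))
        self.theta = _as_pattern(self.theta, (p, p))
        if self.nu is not None:
            self.nu = _as_pattern(self.nu, (p,))
        if self.alpha is not None:
            self.alpha = _as_pattern(self.alpha, (r,))
        self.p = p
        self.r = r
        self._index_parameters()

    # -- parameter bookkeeping ---------------------------------------------
    def _index_parameters(self) -> None:
        names: list[str] = []
        variance_only: dict[str, bool] = {}

        def scan(pat, diag_pd=False):
            if pat is None or pat.size == 0:
                return
            it = np.nditer(pat, flags=["multi_index", "refs_ok"])
            for v in it:
                lab = v.item()
                if isinstance(lab, str):
                    idx = it.multi_index
                    on_diag = diag_pd and len(idx) == 2 and idx[0] == idx[1]
                    if lab not in variance_only:
                        names.append(lab)
                        variance_only[lab] = on_diag
                    else:
                        variance_only[lab] = variance_only[lab] and on_diag

        scan(self.alpha)
        scan(self.nu)
        scan(self.lam)
        scan(self.phi, diag_pd=True)
        scan(self.theta, diag_pd=True)
        self.parameter_names: tuple[str, ...] = tuple(names)
        self.q = len(names)
        self.transforms: tuple[str, ...] = tuple(
            "log" if variance_only[n] else "identity" for n in names
        )
        self._pos = {n: i for i, n in enumerate(names)}

        def build(pat, shape):
            if pat is None:
                return None, None
            fixed = np.zeros(shape, dtype=float)
            deriv = [np.zeros(shape) for _ in range(self.q)]
            if pat.size == 0:
                return fixed, (np.stack(deriv) if self.q else np.zeros((0,) + shape))
            it = np.nditer(pat, flags=["multi_index", "refs_ok"])
            for v in it:
                lab = v.item()
                if isinstance(lab, str):
                    deriv[self._pos[lab]][it.multi_index] = 1.0
                else:
                    fixed[it.multi_index] = float(lab)
            return fixed, np.stack(deriv) if self.q else np.zeros((0,) + shape)

        p, r = self.p, self.r
        self._lam0, self._dlam = build(self.lam, (p, r))
        self._phi0, self._dphi = build(_sym_pattern(self.phi), (r, r))
        self._th0, self._dth = build(_sym_pattern(self.theta), (p, p))
        self._nu0, self._dnu = build(self.nu, (p,))
        self._al0, self._dal = build(self.alpha, (r,))
        # with all loadings fixed both moment maps are affine in theta:
        # precompute the closed form (hot path for growth-curve scans)
        self._affine = not self._dlam.any()
        if self._affine:
            L = self._lam0
            self._cov_const = _sym(L @ self._phi0 @ L.T + self._th0)
            self._cov_lin = np.stack([
                _sym(L @ self._dphi[j] @ L.T + self._dth[j])
                for j in range(self.q)]) if self.q else np.zeros((0, p, p))
            if self.nu is not None:
                self._mean_const = self._nu0 + L @ self._al0
                self._mean_lin = np.stack([
                    self._dnu[j] + L @ self._dal[j] for j in range(self.q)
                ]) if self.q else np.zeros((0, p))

    @property
    def has_mean_structure(self) -> bool:
        return self.nu is not None

    # -- implied moments ----------------------------------------------------
    def _matrices(self, theta: np.ndarray):
        theta = np.asarray(theta, dtype=float)
        L = self._lam0 + np.tensordot(theta, self._dlam, axes=1)
        P = self._phi0 + np.tensordot(theta, self._dphi, axes=1)
        T = self._th0 + np.tensordot(theta, self._dth, axes=1)
        return L, P, T

    def implied_cov(self, theta: np.ndarray) -> np.ndarray:
        if self._affine:
            if self.q == 0:
                return self._cov_const
            flat = self._cov_lin.reshape(self.q, -1).T @ np.asarray(theta, float)
            return self._cov_const + flat.reshape(self.p, self.p)
        L, P, T = self._matrices(theta)
        return _sym(L @ P @ L.T + T)

    def implied_mean(self, theta: np.ndarray) -> np.ndarray | None:
        if not self.has_mean_structure:
            return None
        theta = np.asarray(theta, dtype=float)
        if self._affine:
            return self._mean_const + self._mean_lin.T @ theta
        nu = self._nu0 + np.tensordot(theta, self._dnu, axes=1)
        al = self._al0 + np.tensordot(theta, self._dal, axes=1)
        L, _, _ = self._matrices(theta)
        return nu + L @ al

    def implied_cov_deriv(self, theta: np.ndarray) -> np.ndarray:
        """Stack of q matrices dSigma/dtheta_j at ``theta``.

        Constant (cached) when the template has no free loadings.
        """
        if self._affine:
            return self._cov_lin
        return self._cov_deriv_at(theta)

    def _cov_deriv_at(self, theta: np.ndarray) -> np.ndarray:
        L, P, _ = self._matrices(theta)
        PLt = P @ L.T
        out = np.empty((self.q, self.p, self.p))
        for j in range(self.q):
            dL = self._dlam[j]
            a = dL @ PLt
            out[j] = _sym(a + a.T + L @ self._dphi[j] @ L.T + self._dth[j])
        return out

    def implied_mean_deriv(self, theta: np.ndarray) -> np.ndarray | None:
        if not self.has_mean_structure:
            return None
        if self._affine:
            return self._mean_lin
        theta = np.asarray(theta, dtype=float)
        L, _, _ = self._matrices(theta)
        al = self._al0 + np.tensordot(theta, self._dal, axes=1)
        out = np.empty((self.q, self.p))
        for j in range(self.q):
            out[j] = self._dnu[j] + self._dlam[j] @ al + L @ self._dal[j]
        return out

    # -- constraints --------------------------------------------------------
    def constrain(self, values: Mapping[str, float]) -> "TemplateModel":
        """Return a template with the named parameters fixed at ``values``."""
        unknown = set(values) - set(self.parameter_names)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")

        def sub(pat):
            if pat is None:
                return None
            out = pat.copy()
            it = np.nditer(out, flags=["multi_index", "refs_ok"])
            for v in it:
                lab = v.item()
                if isinstance(lab, str) and lab in values:
                    out[it.multi_index] = float(values[lab])
            return out

        tm = TemplateModel(
            lam=sub(self.lam), phi=sub(self.phi), theta=sub(self.theta),
            nu=sub(self.nu), alpha=sub(self.alpha), name=self.name,
        )
        outer = self

        def start(ybar, S):
            full = outer.start_values(ybar, S)
            keep = [i for i, nm in enumerate(outer.parameter_names) if nm not in values]
            return full[keep]

        tm.start_fn = start
        return tm

    # -- start values -------------------------------------------------------
    def start_values(self, ybar: np.ndarray, S: np.ndarray) -> np.ndarray:
        if self.start_fn is not None:
            return np.asarray(self.start_fn(ybar, S), dtype=float)
        return self._default_start(ybar, S)

    def _default_start(self, ybar: np.ndarray, S: np.ndarray) -> np.ndarray:
        start = np.zeros(self.q)
        sdiag = np.clip(np.diag(S), 1e-3, None)
        for i, nm in enumerate(self.parameter_names):
            if self.transforms[i] == "log":
                # a variance: residual variances start at half the observed
                # variance of their row, latent variances at one
                rows = np.nonzero(self._dth[i].diagonal())[0]
                start[i] = 0.5 * sdiag[rows].mean() if rows.size else 1.0
            elif self._dlam[i].any():
                rows = np.nonzero(self._dlam[i].any(axis=1))[0]
                start[i] = 0.7 * np.sqrt(sdiag[rows].mean())
            elif self._dnu is not None and self._dnu[i].any():
                rows = np.nonzero(self._dnu[i])[0]
                start[i] = ybar[rows].mean()
            elif self._dal is not None and self._dal[i].any():
                start[i] = 0.0
        return start

    # -- factories ----------------------------------------------------------
    @classmethod
    def lgcm(cls, ages: Sequence[float] = (6.0, 7.0, 9.0, 11.0)) -> "TemplateModel":
        """Linear latent growth curve model with fixed occasion loadings.

        Four observed occasions by default; six free parameters: mean and
        variance of the random intercept ``f_I``, mean and variance of the
        random slope ``f_S``, their covariance, and one residual variance
        shared across occasions.
        """
        p = len(ages)
        lam = [[1.0, float(a)] for a in ages]
        phi = [["var_i", "cov_is"], ["cov_is", "var_s"]]
        theta = np.full((p, p), 0.0, dtype=object)
        for j in range(p):
            theta[j, j] = "resid"
        tm = cls(
            lam=lam, phi=phi, theta=theta,
            nu=[0.0] * p, alpha=["mean_i", "mean_s"], name="lgcm",
        )
        basis = np.asarray(lam, dtype=float)

        def start(ybar, S):
            al, *_ = np.linalg.lstsq(basis, ybar, rcond=None)
            # affine method of moments for the covariance part
            dmats = [tm._dphi_sigma(k) for k in range(3)]
            resid_mat = np.eye(p)
            X = np.column_stack([m[np.triu_indices(p)] for m in dmats]
                                + [resid_mat[np.triu_indices(p)]])
            y = S[np.triu_indices(p)]
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            vi, c, vs, rv = coef
            floor = 0.02 * float(np.diag(S).mean())
            # parameter order: mean_i, mean_s, var_i, cov_is, var_s, resid
            return np.array([al[0], al[1], max(vi, floor), c,
                             max(vs, 0.5 * floor), max(rv, floor)])

        tm.start_fn = start
        return tm

    def _dphi_sigma(self, k: int) -> np.ndarray:
        """Sigma-derivative of the k-th free Phi entry (helper for starts)."""
        L = self._lam0
        names = ["var_i", "cov_is", "var_s"]
        j = self._pos[names[k]]
        return L @ self._dphi[j] @ L.T

    @classmethod
    def cfa_two_factor(cls) -> "TemplateModel":
        """Two correlated factors, three indicators each, no mean structure.

        Factor variances fixed to one for identification; the latent
        covariance ``phi``, six loadings and six residual variances are free
        (q = 13).
        """
        lam = np.zeros((6, 2), dtype=object)
        for j in range(3):
            lam[j, 0] = f"lam{j + 1}"
            lam[j + 3, 1] = f"lam{j + 4}"
        phi = [[1.0, "phi"], ["phi", 1.0]]
        theta = np.zeros((6, 6), dtype=object)
        for j in range(6):
            theta[j, j] = f"res{j + 1}"
        tm = cls(lam=lam, phi=phi, theta=theta, name="cfa2f")

        def start(ybar, S):
            sd = np.sqrt(np.clip(np.diag(S), 1e-3, None))
            lams = np.empty(6)
            for b, idx in enumerate(((0, 1, 2), (3, 4, 5))):
                a, bb, c = idx
                denom = S[bb, c] if abs(S[bb, c]) > 1e-3 else 1e-3
                l0 = np.sqrt(np.clip(abs(S[a, bb] * S[a, c] / denom),
                                     0.04 * S[a, a], 0.96 * S[a, a]))
                lams[a] = l0
                lams[bb] = np.clip(S[a, bb] / l0, 0.2 * sd[bb], 0.95 * sd[bb])
                lams[c] = np.clip(S[a, c] / l0, 0.2 * sd[c], 0.95 * sd[c])
            cross = S[:3, 3:] / np.outer(lams[:3], lams[3:])
            phi0 = float(np.clip(cross.mean(), -0.9, 0.9))
            res = np.clip(np.diag(S) - lams ** 2, 0.05 * np.diag(S), None)
            return np.concatenate([lams[:3], lams[3:], [phi0], res])

        tm.start_fn = start
        return tm

    @classmethod
    def univariate_mean(cls, sigma2: float = 1.0) -> "TemplateModel":
        """Univariate normal with free mean and fixed variance (q = 1)."""
        tm = cls(lam=np.zeros((1, 0), dtype=object), phi=np.zeros((0, 0), dtype=object),
                 theta=[[float(sigma2)]], nu=["mu"], alpha=np.zeros(0, dtype=object),
                 name="univariate_mean")
        tm.start_fn = lambda ybar, S: np.array([float(ybar[0])])
        return tm

    @classmethod
    def saturated(cls, p: int) -> "TemplateModel":
        """Free mean vector and free covariance matrix (q = p + p(p+1)/2)."""
        theta = np.empty((p, p), dtype=object)
        for a in range(p):
            for b in range(a, p):
                theta[a, b] = theta[b, a] = f"s{a + 1}{b + 1}"
        nu = [f"m{a + 1}" for a in range(p)]
        tm = cls(lam=np.zeros((p, 0), dtype=object), phi=np.zeros((0, 0), dtype=object),
                 theta=theta, nu=nu, alpha=np.zeros(0, dtype=object), name="saturated")

        def start(ybar, S):
            vals = list(ybar)
            for a in range(p):
                for b in range(a, p):
                    vals.append(S[a, b])
            return np.array(vals)

        tm.start_fn = start
        return tm


def _sym_pattern(pat: np.ndarray) -> np.ndarray:
    out = pat.copy()
    n = out.shape[0]
    for a in range(n):
        for b in range(a + 1, n):
            if out[a, b] is None or (isinstance(out[a, b], float) and out[a, b] == 0.0):
                if isinstance(out[b, a], str) or (isinstance(out[b, a], (int, float)) and out[b, a] != 0):
                    out[a, b] = out[b, a]
            out[b, a] = out[a, b]
    return out


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------


@dataclass
class Covariate:
    name: str
    values: np.ndarray
    kind: str  # continuous | ordinal | categorical
    levels: tuple | None = None  # explicit order for ordinal / label set

    def __post_init__(self):
        if self.kind not in ("continuous", "ordinal", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        self.values = np.asarray(self.values)
        if self.kind == "ordinal" and self.levels is None:
            self.levels = tuple(np.unique(self.values))
        if self.kind == "categorical" and self.levels is None:
            self.levels = tuple(pd.unique(self.values))


@dataclass
class Dataset:
    """Complete-case outcome matrix plus typed covariates."""

    Y: np.ndarray
    covariates: dict[str, Covariate] = field(default_factory=dict)

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("Y must be two-dimensional")
        if not np.isfinite(self.Y).all():
            raise ValueError("outcome matrix contains missing or non-finite values")
        for cov in self.covariates.values():
            if len(cov.values) != self.n:
                raise ValueError(f"covariate {cov.name!r} length mismatch")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcomes: Sequence[str],
                       covariates: Mapping[str, object] | None = None) -> "Dataset":
        """Build from a rectangular table.

        ``covariates`` maps column names to a kind string or a dict
        ``{"type": ..., "levels": [...]}``.
        """
        Y = df.loc[:, list(outcomes)].to_numpy(dtype=float)
        covs: dict[str, Covariate] = {}
        for name, spec in (covariates or {}).items():
            if isinstance(spec, str):
                kind, levels = spec, None
            else:
                kind = spec["type"]
                levels = tuple(spec["levels"]) if "levels" in spec else None
            covs[name] = Covariate(name, df[name].to_numpy(), kind, levels)
        return cls(Y=Y, covariates=covs)

    def subset(self, idx: np.ndarray) -> "Dataset":
        covs = {k: Covariate(c.name, c.values[idx], c.kind, c.levels)
                for k, c in self.covariates.items()}
        return Dataset(Y=self.Y[idx], covariates=covs)


# ---------------------------------------------------------------------------
# Discrepancy function and fitting
# ---------------------------------------------------------------------------


def evaluate_fml(model: TemplateModel, ybar: np.ndarray, S: np.ndarray,
                 theta: np.ndarray) -> float:
    """Maximum likelihood discrepancy between sample and implied moments.

    Returns ``inf`` (never raises) when the implied covariance is singular.
    """
    Sigma = model.implied_cov(theta)
    mu = model.implied_mean(theta)
    d = np.zeros(model.p) if mu is None else np.asarray(ybar, float) - mu
    try:
        c, low = linalg.cho_factor(Sigma, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return float("inf")
    logdet_sigma = 2.0 * np.log(np.diag(c)).sum()
    Sinv = linalg.cho_solve((c, low), np.eye(model.p), check_finite=False)
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        return float("inf")
    val = (d @ Sinv @ d + np.trace(S @ Sinv)
           - (logdet_s - logdet_sigma) - model.p)
    return float(val)


def _fml_grad(model: TemplateModel, ybar, S, theta):
    """(F, grad_F) on the natural scale; (inf, zeros) if Sigma not PD."""
    Sigma = model.implied_cov(theta)
    mu = model.implied_mean(theta)
    d = np.zeros(model.p) if mu is None else ybar - mu
    try:
        c, low = linalg.cho_factor(Sigma, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return float("inf"), np.zeros(model.q)
    logdet_sigma = 2.0 * np.log(np.diag(c)).sum()
    Sinv = linalg.cho_solve((c, low), np.eye(model.p), check_finite=False)
    sign, logdet_s = np.linalg.slogdet(S)
    if sign <= 0:
        raise EstimationError("sample covariance is singular")
    Sid = Sinv @ d
    F = float(d @ Sid + np.trace(S @ Sinv) - (logdet_s - logdet_sigma) - model.p)
    dSig = model.implied_cov_deriv(theta)
    W = Sinv - Sinv @ S @ Sinv - np.outer(Sid, Sid)
    grad = np.einsum("jab,ab->j", dSig, W)
    dmu = model.implied_mean_deriv(theta)
    if dmu is not None:
        grad -= 2.0 * dmu @ Sid
    return F, grad


def _to_natural(model: TemplateModel, x: np.ndarray) -> np.ndarray:
    th = x.copy()
    for i, tr in enumerate(model.transforms):
        if tr == "log":
            th[i] = np.exp(np.clip(x[i], -40.0, 40.0))
    return th


def _to_working(model: TemplateModel, theta: np.ndarray) -> np.ndarray:
    x = np.asarray(theta, dtype=float).copy()
    for i, tr in enumerate(model.transforms):
        if tr == "log":
            x[i] = np.log(np.clip(theta[i], 1e-10, None))
    return x


@dataclass
class FittedModel:
    """Maximum likelihood fit of a template on one sample."""

    model: TemplateModel
    theta: np.ndarray
    fml: float
    n: int
    ybar: np.ndarray
    S: np.ndarray
    converged: bool
    n_iter: int
    grad_norm: float
    message: str = ""
    Y: np.ndarray | None = None
    _scores: np.ndarray | None = field(default=None, repr=False)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return self.model.parameter_names

    @property
    def minus2_loglik(self) -> float:
        """-2 log L evaluated from the sample moments."""
        Sigma = self.model.implied_cov(self.theta)
        mu = self.model.implied_mean(self.theta)
        d = np.zeros(self.model.p) if mu is None else self.ybar - mu
        sign, logdet = np.linalg.slogdet(Sigma)
        Sinv = np.linalg.inv(Sigma)
        return float(self.n * (self.model.p * _LN_2PI + logdet
                               + np.trace(self.S @ Sinv) + d @ Sinv @ d))

    def casewise_loglik(self, Y: np.ndarray | None = None) -> np.ndarray:
        Y = self.Y if Y is None else np.asarray(Y, dtype=float)
        if Y is None:
            raise ValueError("no case-level data attached to this fit")
        Sigma = self.model.implied_cov(self.theta)
        mu = self.model.implied_mean(self.theta)
        center = Y.mean(axis=0) if mu is None else mu
        D = Y - center
        Sinv = np.linalg.inv(Sigma)
        sign, logdet = np.linalg.slogdet(Sigma)
        quad = np.einsum("na,ab,nb->n", D, Sinv, D)
        return -0.5 * (self.model.p * _LN_2PI + logdet + quad)

    def scores(self, Y: np.ndarray | None = None) -> np.ndarray:
        if Y is None and self._scores is not None:
            return self._scores
        Y = self.Y if Y is None else np.asarray(Y, dtype=float)
        if Y is None:
            raise ValueError("no case-level data attached to this fit")
        sc = casewise_scores(self.model, self.theta, Y)
        if Y is self.Y:
            self._scores = sc
        return sc

    def information(self, method: str = "opg") -> np.ndarray:
        return information_estimate(self.scores(), method=method,
                                    model=self.model, theta=self.theta)


def _fisher_scoring(model: TemplateModel, ybar, S, theta0, *, gtol=1e-8,
                    maxiter=50):
    """Newton-type minimization of F_ML with the expected-information Hessian.

    Fast path for warm-started group fits; returns None when scoring leaves
    the admissible region (non-PD covariance, non-positive variance) so the
    caller can fall back to the transformed quasi-Newton path.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    log_idx = [i for i, t in enumerate(model.transforms) if t == "log"]
    F, g = _fml_grad(model, ybar, S, theta)
    if not np.isfinite(F):
        return None
    # Hessian frozen at the warm start: linear convergence, cheap iterations
    info = information_estimate(None, "expected", model=model, theta=theta)
    try:
        H = np.linalg.inv(2.0 * info + 1e-10 * np.eye(model.q))
    except np.linalg.LinAlgError:
        return None
    for _ in range(maxiter):
        if np.max(np.abs(g)) <= gtol * (1.0 + abs(F)):
            return theta, F, g
        step = H @ g
        lam = 1.0
        for _ in range(12):
            cand = theta - lam * step
            if log_idx and np.any(cand[log_idx] <= 0.0):
                lam *= 0.5
                continue
            Fc, gc = _fml_grad(model, ybar, S, cand)
            if np.isfinite(Fc) and Fc <= F + 1e-12:
                theta, F, g = cand, Fc, gc
                break
            lam *= 0.5
        else:
            return None
    if np.max(np.abs(g)) <= 1e-6 * (1.0 + abs(F)):
        return theta, F, g
    return None


def fit_ml_moments(model: TemplateModel, ybar: np.ndarray, S: np.ndarray, n: int,
                   start: np.ndarray | None = None, *, gtol: float = 1e-7,
                   maxiter: int = 500, n_restarts: int = 3,
                   fast: bool = False) -> FittedModel:
    """Fit a template to sample moments by minimizing ``F_ML``.

    Variance parameters are optimized on the log scale internally so the
    implied covariance stays positive definite; estimates are reported on the
    natural scale.  On non-convergence the start is perturbed deterministically
    up to ``n_restarts`` times and the best point found is returned flagged.
    """
    ybar = np.asarray(ybar, dtype=float)
    S = _sym(np.asarray(S, dtype=float))
    theta0 = model.start_values(ybar, S) if start is None else np.asarray(start, float)

    if fast and start is not None:
        scored = _fisher_scoring(model, ybar, S, theta0)
        if scored is not None:
            theta_hat, F, g = scored
            return FittedModel(model=model, theta=theta_hat, fml=float(F),
                               n=int(n), ybar=ybar, S=S, converged=True,
                               n_iter=0, grad_norm=float(np.max(np.abs(g))))

    def objective(x):
        th = _to_natural(model, x)
        F, g = _fml_grad(model, ybar, S, th)
        if not np.isfinite(F):
            return 1e12, np.zeros_like(x)
        for i, tr in enumerate(model.transforms):
            if tr == "log":
                g[i] *= th[i]
        return F, g

    best = None
    rng = np.random.default_rng(0)
    x0 = _to_working(model, theta0)
    for attempt in range(n_restarts + 1):
        res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                                options={"maxiter": maxiter, "gtol": gtol,
                                         "ftol": 1e-12})
        gn = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        ok = bool(np.isfinite(res.fun)) and (res.success or gn <= 1e-5 * (1.0 + abs(res.fun)))
        cand = (res, gn, ok)
        if best is None or res.fun < best[0].fun:
            best = cand
        if ok:
            best = cand
            break
        x0 = _to_working(model, theta0) + 0.2 * rng.standard_normal(model.q)
    res, gn, ok = best
    theta_hat = _to_natural(model, res.x)
    return FittedModel(model=model, theta=theta_hat, fml=float(res.fun), n=int(n),
                       ybar=ybar, S=S, converged=ok, n_iter=int(res.nit),
                       grad_norm=gn, message=str(res.message))


def fit_ml(model: TemplateModel, data: Dataset | np.ndarray,
           start: np.ndarray | None = None, *, min_n: int | None = None,
           **kwargs) -> FittedModel:
    """Fit a template to case-level data; see :func:`fit_ml_moments`."""
    Y = data.Y if isinstance(data, Dataset) else np.asarray(data, dtype=float)
    n = Y.shape[0]
    floor = max(model.p + 1, min_n if min_n is not None else 0)
    if n < floor:
        raise EstimationError(f"sample of {n} below the minimum of {floor}")
    ybar, S = ml_moments(Y)
    fit = fit_ml_moments(model, ybar, S, n, start=start, **kwargs)
    fit.Y = Y
    return fit


def casewise_scores(model: TemplateModel, theta: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """N x q matrix of case-wise log-likelihood gradients at ``theta``.

    For models without a mean structure the cases are centered at the sample
    mean of ``Y`` (the saturated mean plays the role of a nuisance parameter
    and contributes no scores).
    """
    Y = np.asarray(Y, dtype=float)
    Sigma = model.implied_cov(theta)
    mu = model.implied_mean(theta)
    center = Y.mean(axis=0) if mu is None else mu
    D = Y - center
    Sinv = np.linalg.inv(Sigma)
    U = D @ Sinv
    dSig = model.implied_cov_deriv(theta)
    const = -0.5 * np.einsum("ab,jba->j", Sinv, dSig)
    quad = 0.5 * np.einsum("na,jab,nb->nj", U, dSig, U)
    sc = const[None, :] + quad
    dmu = model.implied_mean_deriv(theta)
    if dmu is not None:
        sc += U @ dmu.T
    return sc


def information_estimate(scores: np.ndarray, method: str = "opg", *,
                         model: TemplateModel | None = None,
                         theta: np.ndarray | None = None) -> np.ndarray:
    """Per-observation Fisher information estimate.

    ``opg`` is the average outer product of the score rows; ``expected`` is the
    analytic expected information (requires ``model`` and ``theta``).
    """
    if method == "opg":
        scores = np.asarray(scores, dtype=float)
        return scores.T @ scores / scores.shape[0]
    if method == "expected":
        if model is None or theta is None:
            raise ValueError("expected information needs model and theta")
        Sigma = model.implied_cov(theta)
        Sinv = np.linalg.inv(Sigma)
        dSig = model.implied_cov_deriv(theta)
        A = np.einsum("ab,jbc->jac", Sinv, dSig)
        info = 0.5 * np.einsum("jab,kba->jk", A, A)
        dmu = model.implied_mean_deriv(theta)
        if dmu is not None:
            info += dmu @ Sinv @ dmu.T
        return _sym(info)
    raise ValueError(f"unknown information method {method!r}")


def lr_statistic(full_fit: FittedModel, group_fits: Sequence[FittedModel]) -> tuple[float, int]:
    """Likelihood ratio between a single-group fit and the multigroup fit.

    ``-2 (logL_full - logL_sub)`` with ``(J - 1) q`` degrees of freedom; the
    group subsamples must partition the full sample and share the template.
    Equivalently ``sum_j n_j (F[ybar_j, S_j, theta_full] - F[ybar_j, S_j,
    theta_j])`` with ML moments.
    """
    if any(not g.converged for g in group_fits) or not full_fit.converged:
        raise EstimationError("likelihood ratio unavailable: a fit did not converge")
    model = full_fit.model
    lr = 0.0
    for g in group_fits:
        f_at_full = evaluate_fml(model, g.ybar, g.S, full_fit.theta)
        lr += g.n * (f_at_full - g.fml)
    df = (len(group_fits) - 1) * model.q
    return float(lr), int(df)
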