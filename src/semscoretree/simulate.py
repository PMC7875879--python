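"""Synthetic populations and Monte Carlo harness for tree split selection.

Two data-generating populations are built in:

* a four-occasion linear latent growth curve model (LGCM) with occasion
  loadings fixed at the ages 6, 7, 9, 11 — intercept mean 5.389, intercept
  variance 25.137, slope variance 2.808, intercept–slope covariance 0.745,
  with group-2 overrides for either the growth means ("fixed effects") or the
  three random-effect parameters; the slope mean (2.0) and residual variance
  (10.0) are reconstructions chosen to keep the implied trajectories on the
  scale of the original Wechsler application and are fully configurable;
* a two-factor confirmatory factor model (CFA), three indicators per factor,
  unit factor variances, all loadings 0.837 (each factor accounts for 70% of
  indicator variance, residuals 1 - 0.837^2), no mean structure; group
  differences either in the latent covariance (0 vs 0.471) or in the first
  loading (0.837 vs 0.640 with covariance 0.471 in both groups).

Outcome data are drawn from the exact model-implied multivariate normal
moments.  An informative covariate encodes group membership deterministically
through its quantile threshold (central, 1/3- or 1/6-type cuts, optionally
mirrored for counterbalancing); noise covariates are independent of the
groups.  Covariates are continuous standard normal, ordinal with six
equally occupied levels, or balanced dichotomous.

The experiment runners score a replication as a rejection when the root node
splits, which is exactly the tree-level event counted in the type-I error and
rejection-rate summaries (a tree with more than one node).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .model import Covariate, Dataset, FittedModel, TemplateModel, fit_ml
from .tree import SEMTree, TreeOptions, evaluate_covariate, select_covariate
from .tree import adjusted_rand_index

__all__ = [
    "LGCMParams",
    "CFAParams",
    "ExperimentSummary",
    "generate_model_data",
    "generate_covariate",
    "generate_two_group_sample",
    "run_null_experiment",
    "run_power_experiment",
    "run_cfa_rejection_experiment",
    "introductory_example",
]


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------


@dataclass
class LGCMParams:
    mean_i: float = 5.389
    mean_s: float = 2.0  # reconstruction; not printed in the source application
    var_i: float = 25.137
    var_s: float = 2.808
    cov_is: float = 0.745
    resid: float = 10.0  # reconstruction
    ages: tuple[float, ...] = (6.0, 7.0, 9.0, 11.0)

    def implied_moments(self) -> tuple[np.ndarray, np.ndarray]:
        L = np.column_stack([np.ones(len(self.ages)), np.asarray(self.ages)])
        psi = np.array([[self.var_i, self.cov_is], [self.cov_is, self.var_s]])
        mu = L @ np.array([self.mean_i, self.mean_s])
        Sigma = L @ psi @ L.T + self.resid * np.eye(len(self.ages))
        return mu, Sigma

    def template(self) -> TemplateModel:
        return TemplateModel.lgcm(self.ages)

    def group2_fixed_effects(self, which: str = "intercept") -> "LGCMParams":
        """Growth-mean difference; which growth mean differs is a switch."""
        if which == "intercept":
            return replace(self, mean_i=5.695)
        return replace(self, mean_s=self.mean_s + (5.695 - 5.389))

    def group2_random_effects(self) -> "LGCMParams":
        return replace(self, var_i=38.023, var_s=4.247, cov_is=1.127)


@dataclass
class CFAParams:
    loadings: tuple[float, ...] = (0.837,) * 6
    phi: float = 0.0
    residuals: tuple[float, ...] | None = None  # default 1 - loading^2

    def __post_init__(self):
        if self.residuals is None:
            self.residuals = tuple(1.0 - l ** 2 for l in self.loadings)

    def implied_moments(self) -> tuple[np.ndarray, np.ndarray]:
        lam = np.zeros((6, 2))
        lam[:3, 0] = self.loadings[:3]
        lam[3:, 1] = self.loadings[3:]
        phi = np.array([[1.0, self.phi], [self.phi, 1.0]])
        Sigma = lam @ phi @ lam.T + np.diag(self.residuals)
        return np.zeros(6), Sigma

    def template(self) -> TemplateModel:
        return TemplateModel.cfa_two_factor()

    def with_phi(self, phi: float) -> "CFAParams":
        return replace(self, phi=phi)

    def with_loading(self, value: float, indicator: int = 0) -> "CFAParams":
        """Override one loading; residual variances keep their base values
        (the loading is the only group difference)."""
        lo = list(self.loadings)
        lo[indicator] = value
        return replace(self, loadings=tuple(lo), residuals=self.residuals)


def generate_model_data(params, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` multivariate normal cases from the model-implied moments."""
    mu, Sigma = params.implied_moments()
    try:
        return rng.multivariate_normal(mu, Sigma, size=n, method="cholesky")
    except np.linalg.LinAlgError:  # degenerate (singular) populations
        return rng.multivariate_normal(mu, Sigma, size=n, method="svd")


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------


def generate_covariate(kind: str, n: int, rng: np.random.Generator,
                       name: str = "x") -> Covariate:
    """An uninformative (noise) covariate of the given kind."""
    if kind == "continuous":
        return Covariate(name, rng.standard_normal(n), "continuous")
    if kind == "ordinal":
        if n % 6:
            raise ValueError("ordinal covariates need n divisible by 6")
        vals = rng.permutation(np.repeat(np.arange(1, 7), n // 6))
        return Covariate(name, vals, "ordinal", levels=tuple(range(1, 7)))
    if kind == "dichotomous":
        vals = rng.permutation(np.repeat([0, 1], [n - n // 2, n // 2]))
        return Covariate(name, vals, "categorical", levels=(0, 1))
    raise ValueError(f"unknown covariate kind {kind!r}")


def _informative_covariate(kind: str, n1: int, n2: int, flip: bool,
                           rng: np.random.Generator, name: str = "z",
                           ) -> tuple[Covariate, np.ndarray]:
    """Covariate whose quantile threshold encodes the group label exactly.

    Returns the covariate and a boolean vector marking group-2 membership.
    ``flip`` mirrors the cut (counterbalancing of non-central cut points).
    """
    n = n1 + n2
    if kind == "continuous":
        x = rng.standard_normal(n)
        ranks = np.argsort(np.argsort(x))
        g2 = ranks >= n1 if not flip else ranks < n2
        return Covariate(name, x, "continuous"), g2
    if kind == "ordinal":
        if n % 6 or n1 % (n // 6):
            raise ValueError("ordinal cut must fall on a level boundary")
        vals = rng.permutation(np.repeat(np.arange(1, 7), n // 6))
        boundary = 6 * n1 // n
        g2 = vals > boundary if not flip else vals <= 6 - boundary
        return Covariate(name, vals, "ordinal", levels=tuple(range(1, 7))), g2
    if kind == "dichotomous":
        vals = rng.permutation(np.repeat([0, 1], [n1, n2]))
        g2 = vals == 1
        return Covariate(name, vals, "categorical", levels=(0, 1)), g2
    raise ValueError(f"unknown covariate kind {kind!r}")


def generate_two_group_sample(group1_params, group2_params, n1: int, n2: int,
                              covariate_kind: str = "continuous",
                              noise_kinds: tuple[str, ...] = (),
                              flip: bool = False, *,
                              rng: np.random.Generator,
                              ) -> tuple[Dataset, np.ndarray]:
    """Two-population sample with one informative and optional noise covariates.

    Returns the dataset and the true group-2 indicator.
    """
    cov, g2 = _informative_covariate(covariate_kind, n1, n2, flip, rng)
    n = n1 + n2
    p = group1_params.implied_moments()[0].size
    Y = np.empty((n, p))
    Y[~g2] = generate_model_data(group1_params, int((~g2).sum()), rng)
    Y[g2] = generate_model_data(group2_params, int(g2.sum()), rng)
    covs = {cov.name: cov}
    for i, kind in enumerate(noise_kinds):
        nz = generate_covariate(kind, n, rng, name=f"noise{i + 1}")
        covs[nz.name] = nz
    return Dataset(Y=Y, covariates=covs), g2


# ---------------------------------------------------------------------------
# Experiment summaries
# ---------------------------------------------------------------------------


@dataclass
class ExperimentSummary:
    """Per-condition Monte Carlo rates with binomial uncertainty bands."""

    rates: dict[str, float]
    reps: int
    seed: int
    extras: dict = field(default_factory=dict)

    def mc_se(self, key: str) -> float:
        r = self.rates[key]
        return float(np.sqrt(r * (1.0 - r) / self.reps))


def _root_rejects(evaluations, alpha: float, bonferroni: bool) -> bool:
    best, p_adj = select_covariate(
        evaluations, TreeOptions(alpha=alpha,
                                 bonferroni_across_covariates=bonferroni))
    return best is not None and p_adj < alpha


# ---------------------------------------------------------------------------
# Simulation I: type-I error under homogeneity
# ---------------------------------------------------------------------------


def run_null_experiment(*, reps: int = 2000, n: int = 504,
                        statistics: tuple[str, ...] = ("CvM", "maxLM"),
                        noise_kinds: tuple[str, ...] = ("continuous",),
                        params: LGCMParams | None = None,
                        alpha: float = 0.05, trim: float = 0.15,
                        seed: int = 0) -> ExperimentSummary:
    """False-split rate of score-guided trees on homogeneous growth data.

    All requested statistics are evaluated on the same fitted replications;
    a replication counts as a type-I error when the root splits (a tree with
    more than one node).
    """
    params = params or LGCMParams()
    template = params.template()
    rng = np.random.default_rng(seed)
    hits = {s: 0 for s in statistics}
    used = 0
    opts = {s: _stat_options(s, alpha=alpha, trim=trim) for s in statistics}
    for _ in range(reps):
        Y = generate_model_data(params, n, rng)
        covs = [generate_covariate(k, n, rng, name=f"noise{i + 1}")
                for i, k in enumerate(noise_kinds)]
        fit = fit_ml(template, Y)
        if not fit.converged:
            continue
        used += 1
        for s in statistics:
            evals = [evaluate_covariate(fit, Y, c, opts[s]) for c in covs]
            if _root_rejects(evals, alpha, bonferroni=True):
                hits[s] += 1
    rates = {s: hits[s] / used for s in statistics}
    return ExperimentSummary(rates=rates, reps=used, seed=seed)


def _stat_options(statistic: str, *, alpha: float, trim: float,
                  focus: tuple[str, ...] = ()) -> TreeOptions:
    kw = dict(method="score", alpha=alpha, trim=trim, focus_parameters=focus)
    if statistic in ("DM", "CvM", "maxLM"):
        kw["stat_continuous"] = statistic
    elif statistic in ("WDM", "maxLM_O"):
        kw["stat_ordinal"] = statistic
    elif statistic != "LM":
        raise ValueError(f"unknown statistic {statistic!r}")
    return TreeOptions(**kw)


# ---------------------------------------------------------------------------
# Simulation II: power, cut points, group recovery
# ---------------------------------------------------------------------------


def run_power_experiment(*, reps: int = 500, n: int = 504,
                         difference: str = "random_effects",
                         covariate_kind: str = "dichotomous",
                         noise_kinds: tuple[str, ...] = (),
                         cut: str = "central", counterbalance: bool = True,
                         method: str = "score", statistic: str = "maxLM",
                         alpha: float = 0.05, trim: float = 0.15,
                         seed: int = 0, max_depth: int | None = None,
                         ) -> ExperimentSummary:
    """Two-group growth-curve design: power, cut precision, group recovery.

    Power counts trees that select the informative covariate at any level;
    cut-point bias/SD/RMSE use trees whose initial split is on the informative
    covariate; the adjusted Rand index compares leaves with the true grouping
    (0 for an unsplit tree).
    """
    g1 = LGCMParams()
    g2 = (g1.group2_random_effects() if difference == "random_effects"
          else g1.group2_fixed_effects())
    fractions = {"central": 0.5, "third": 1.0 / 3.0, "sixth": 1.0 / 6.0}
    frac = fractions[cut]
    template = g1.template()
    rng = np.random.default_rng(seed)
    power_hits = 0
    cut_errors: list[float] = []
    aris: list[float] = []
    used = 0
    for r in range(reps):
        flip = counterbalance and bool(r % 2)
        n1 = int(round(frac * n))
        data, g2_mask = generate_two_group_sample(
            g1, g2, n1, n - n1, covariate_kind, noise_kinds, flip, rng=rng)
        model = SEMTree(template, data)
        kw = dict(method=method, alpha=alpha, trim=trim, seed=seed + r,
                  max_depth=max_depth)
        if method == "score":
            kw.update(stat_continuous=statistic if statistic in ("DM", "CvM", "maxLM")
                      else "maxLM",
                      stat_ordinal=statistic if statistic in ("WDM", "maxLM_O")
                      else "maxLM_O")
        try:
            res = model.fit(**kw)
        except Exception:
            continue
        used += 1
        split_covs = [nd.split["covariate"] for nd in res.nodes if nd.split]
        if "z" in split_covs:
            power_hits += 1
        root_split = res.root.split
        if root_split and root_split["covariate"] == "z":
            true_cut = _true_cut(covariate_kind, n1 if not flip else n - n1, n)
            if true_cut is not None:
                cut_errors.append(float(root_split["boundary"]) - true_cut)
        truth = g2_mask.astype(int)
        aris.append(adjusted_rand_index(res.partition(), truth))
    errs = np.asarray(cut_errors)
    rates = {"power": power_hits / used if used else np.nan}
    extras = {
        "cut_bias": float(errs.mean()) if errs.size else np.nan,
        "cut_sd": float(errs.std(ddof=0)) if errs.size else np.nan,
        "cut_rmse": float(np.sqrt((errs ** 2).mean())) if errs.size else np.nan,
        "ari_mean": float(np.mean(aris)) if aris else np.nan,
        "cut_errors": errs,
    }
    return ExperimentSummary(rates=rates, reps=used, seed=seed, extras=extras)


def _true_cut(kind: str, n1: int, n: int) -> float | None:
    if kind == "continuous":
        return float(stats.norm.ppf(n1 / n))
    if kind == "ordinal":
        return 6 * n1 / n + 0.5  # boundary between levels b and b+1
    return None


# ---------------------------------------------------------------------------
# Simulations III & IV: focus parameters and global equality constraints
# ---------------------------------------------------------------------------

MEASUREMENT_PARAMETERS = tuple(f"lam{i}" for i in range(1, 7)) + tuple(
    f"res{i}" for i in range(1, 7))
F2_MEASUREMENT = ("lam4", "lam5", "lam6", "res4", "res5", "res6")


def constrained_root_fit(fit: FittedModel, constraints: tuple[str, ...]) -> FittedModel:
    """Root-node fit of the template with parameters fixed at full-sample values.

    At the root the constrained optimum coincides with the unconstrained one
    (the fixed values are the full-sample estimates), so the constrained fit
    is the restriction of ``fit`` — asserted against an explicit refit in the
    test suite.
    """
    tmpl = fit.model
    values = {nm: float(fit.theta[tmpl.parameter_names.index(nm)])
              for nm in constraints}
    sub = tmpl.constrain(values)
    keep = [i for i, nm in enumerate(tmpl.parameter_names) if nm not in values]
    return FittedModel(model=sub, theta=fit.theta[keep], fml=fit.fml, n=fit.n,
                       ybar=fit.ybar, S=fit.S, converged=fit.converged,
                       n_iter=fit.n_iter, grad_norm=fit.grad_norm, Y=fit.Y)


def run_cfa_rejection_experiment(*, reps: int = 1000, n_per_group: int = 250,
                                 group_difference: str = "phi",
                                 scenarios: tuple[str, ...] = ("none",),
                                 alpha: float = 0.05, trim: float = 0.15,
                                 statistic: str = "maxLM",
                                 seed: int = 0) -> ExperimentSummary:
    """Rejection (root-split) rates of score-guided trees on two-group CFA data.

    ``group_difference``: "phi" (latent covariance 0 vs 0.471, loadings
    homogeneous) or "lambda" (first loading 0.837 vs 0.640, covariance 0.471
    in both groups).  Scenarios: "none", "focus_measurement", "focus_phi",
    "constrain_phi", "constrain_f2", "constrain_lambda".  All scenarios of a
    replication share the same data and root fit.
    """
    base = CFAParams()
    if group_difference == "phi":
        g1, g2 = base.with_phi(0.0), base.with_phi(0.471)
    elif group_difference == "lambda":
        g1 = base.with_phi(0.471)
        g2 = g1.with_loading(0.640, indicator=0)
    else:
        raise ValueError(f"unknown group difference {group_difference!r}")
    template = base.template()
    rng = np.random.default_rng(seed)
    scenario_opts = {
        "none": ("focus", ()),
        "focus_measurement": ("focus", MEASUREMENT_PARAMETERS),
        "focus_phi": ("focus", ("phi",)),
        "constrain_phi": ("constrain", ("phi",)),
        "constrain_f2": ("constrain", F2_MEASUREMENT),
        "constrain_lambda": ("constrain", ("lam1",)),
    }
    hits = {s: 0 for s in scenarios}
    used = 0
    for _ in range(reps):
        data, _g2 = generate_two_group_sample(g1, g2, n_per_group, n_per_group,
                                              "continuous", rng=rng)
        fit = fit_ml(template, data.Y)
        if not fit.converged:
            continue
        used += 1
        cov = data.covariates["z"]
        for s in scenarios:
            mode, names = scenario_opts[s]
            if mode == "focus":
                opts = _stat_options(statistic, alpha=alpha, trim=trim, focus=names)
                ev = evaluate_covariate(fit, data.Y, cov, opts)
            else:
                cfit = constrained_root_fit(fit, names)
                opts = _stat_options(statistic, alpha=alpha, trim=trim)
                ev = evaluate_covariate(cfit, data.Y, cov, opts)
            if ev.available and ev.pvalue < alpha:
                hits[s] += 1
    rates = {s: hits[s] / used for s in scenarios}
    return ExperimentSummary(rates=rates, reps=used, seed=seed,
                             extras={"group_difference": group_difference})


# ---------------------------------------------------------------------------
# Worked example: single-factor ability model with an age and a site effect
# ---------------------------------------------------------------------------


def introductory_example(seed: int = 0, n: int = 600,
                         ) -> tuple[TemplateModel, Dataset]:
    """Three ability tests, one latent factor; loadings differ by age and site.

    Individuals older than 45 have a smaller first loading (0.6 vs 0.8) and,
    if tested at site 2, all loadings lowered by another 0.1; gender is noise.
    """
    rng = np.random.default_rng(seed)
    half = n // 2
    age = np.concatenate([rng.uniform(20.0, 45.0, half),
                          rng.uniform(45.0, 70.0, n - half)])
    site = rng.permutation(np.repeat([1, 2], [n - n // 2, n // 2]))
    gender = rng.permutation(np.repeat([0, 1], [n - n // 2, n // 2]))
    perm = rng.permutation(n)
    age, site, gender = age[perm], site[perm], gender[perm]
    Y = np.empty((n, 3))
    for i in range(n):
        lam = np.array([0.8, 0.8, 0.8])
        if age[i] > 45.0:
            lam[0] = 0.6
            if site[i] == 2:
                lam -= 0.1
        res = 1.0 - lam ** 2
        f = rng.standard_normal()
        Y[i] = lam * f + rng.standard_normal(3) * np.sqrt(res)
    lam_pat = np.array([["l1"], ["l2"], ["l3"]], dtype=object)
    theta_pat = np.zeros((3, 3), dtype=object)
    for j in range(3):
        theta_pat[j, j] = f"e{j + 1}"
    template = TemplateModel(lam=lam_pat, phi=[[1.0]], theta=theta_pat,
                             name="cfa1f")
    data = Dataset(Y=Y, covariates={
        "age": Covariate("age", age, "continuous"),
        "site": Covariate("site", site, "categorical", levels=(1, 2)),
        "gender": Covariate("gender", gender, "categorical", levels=(0, 1)),
    })
    return template, data
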