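"""Cumulative score processes, the six instability statistics, p-values,
and cut-point localization — each statistic checked exactly against a
brute-force double-loop evaluation of its defining formula."""

import numpy as np
import pytest
from scipy import stats

from semscoretree import (TemplateModel, bin_scores, cumulative_score_process,
                          cvm_statistic, dm_statistic, fit_ml,
                          lm_categorical_statistic, locate_cutpoint_score,
                          maxlm_ordinal_statistic, maxlm_statistic,
                          score_pvalue, wdm_statistic)
from semscoretree.scoretests import ScoreProcess, BinnedProcess, inverse_sqrt
from semscoretree import nulldist


# ---------------------------------------------------------------------------
# brute-force oracles (independent double-loop evaluations)
# ---------------------------------------------------------------------------


def brute_csp(scores, info, x):
    n, q = scores.shape
    w, V = np.linalg.eigh(info)
    isq = V @ np.diag(1.0 / np.sqrt(w)) @ V.T
    order = np.argsort(x, kind="stable")
    out = np.zeros((n, q))
    for s in range(1, n + 1):
        acc = np.zeros(q)
        for h in range(s):
            acc += scores[order[h]]
        out[s - 1] = isq @ acc / np.sqrt(n)
    return out


def brute_dm(csp):
    best = 0.0
    for s in range(csp.shape[0]):
        for k in range(csp.shape[1]):
            best = max(best, abs(csp[s, k]))
    return best


def brute_cvm(csp):
    total = 0.0
    for s in range(csp.shape[0]):
        for k in range(csp.shape[1]):
            total += csp[s, k] ** 2
    return total / csp.shape[0]


def brute_maxlm(csp, lo_s, hi_s):
    n = csp.shape[0]
    best = 0.0
    for s in range(lo_s, hi_s + 1):
        f = s / n
        best = max(best, (csp[s - 1] ** 2).sum() / (f * (1 - f)))
    return best


def brute_wdm(cbsp, nl, n):
    best = 0.0
    for l in range(cbsp.shape[0]):
        f = nl[l] / n
        for k in range(cbsp.shape[1]):
            best = max(best, abs(cbsp[l, k]) / np.sqrt(f * (1 - f)))
    return best


def brute_maxlm_o(cbsp, nl, n):
    best = 0.0
    for l in range(cbsp.shape[0]):
        f = nl[l] / n
        best = max(best, (cbsp[l] ** 2).sum() / (f * (1 - f)))
    return best


def brute_lm_printed(bsp):
    m, q = bsp.shape
    prev = np.zeros(q)
    total = 0.0
    for l in range(m):
        for k in range(q):
            total += (bsp[l, k] - prev[k]) ** 2
        prev = bsp[l]
    return total


# ---------------------------------------------------------------------------
# process construction
# ---------------------------------------------------------------------------


def test_csp_simplest_case():
    """Scores (-1, +1), unit information: CSP = (-1/sqrt(2), 0)."""
    sp = cumulative_score_process(np.array([[-1.0], [1.0]]), np.array([[1.0]]),
                                  np.array([0.0, 1.0]))
    assert sp.csp.ravel() == pytest.approx([-1.0 / np.sqrt(2.0), 0.0])


def test_csp_terminal_row_is_zero(lgcm_fit):
    rng = np.random.default_rng(0)
    x = rng.standard_normal(lgcm_fit.n)
    sp = cumulative_score_process(lgcm_fit.scores(), lgcm_fit.information("opg"), x)
    # bounded by optimizer tolerance: the score sums vanish to ~1e-6 * N
    assert np.abs(sp.csp[-1]).max() < 1e-5


def test_csp_rows_are_cumulative_and_match_bruteforce():
    rng = np.random.default_rng(1)
    scores = rng.standard_normal((12, 2))
    scores -= scores.mean(axis=0)
    info = np.cov(scores.T, bias=True) + 0.5 * np.eye(2)
    x = rng.standard_normal(12)
    sp = cumulative_score_process(scores, info, x)
    assert np.allclose(sp.csp, brute_csp(scores, info, x), atol=1e-10)


def test_decorrelation_exact_with_opg(lgcm_fit):
    """OPG-decorrelated score increments have exactly identity covariance."""
    sc = lgcm_fit.scores()
    isq = inverse_sqrt(lgcm_fit.information("opg"))
    dec = sc @ isq.T
    assert np.allclose(dec.T @ dec / sc.shape[0], np.eye(sc.shape[1]), atol=1e-8)


def test_two_regime_scores_peak_at_boundary():
    """A single change point produces one extreme of the cumulative process
    at the regime boundary."""
    n, c = 200, 0.5
    rng = np.random.default_rng(2)
    scores = rng.standard_normal((n, 1)) * 0.3
    scores[:100] -= c
    scores[100:] += c
    scores -= scores.mean(axis=0)
    x = np.arange(n, dtype=float)
    sp = cumulative_score_process(scores, np.array([[scores.var()]]), x)
    assert abs(int(np.argmin(sp.csp[:, 0])) + 1 - 100) <= 3


def test_bin_scores_equal_occupancy_counts(lgcm_fit):
    rng = np.random.default_rng(3)
    levels = tuple(range(1, 7))
    x = rng.permutation(np.repeat(levels, 504 // 6))
    bp = bin_scores(lgcm_fit.scores(), x, levels, lgcm_fit.information("opg"))
    assert bp.cumulative_counts.tolist() == [84, 168, 252, 336, 420]
    assert bp.counts.sum() == 504


def test_binned_process_matches_csp_at_level_boundaries(lgcm_fit):
    """CBSP rows are the CSP evaluated at cumulative level boundaries."""
    rng = np.random.default_rng(4)
    levels = tuple(range(1, 7))
    x = rng.permutation(np.repeat(levels, 504 // 6))
    info = lgcm_fit.information("opg")
    bp = bin_scores(lgcm_fit.scores(), x, levels, info)
    sp = cumulative_score_process(lgcm_fit.scores(), info, x)
    assert np.allclose(bp.cbsp, sp.csp[bp.cumulative_counts - 1], atol=1e-10)
    # last level's sum closes the telescoping to zero (optimizer tolerance)
    assert np.abs(bp.cbsp[-1] + bp.bsp[-1]).max() < 1e-5


# ---------------------------------------------------------------------------
# statistics vs their printed formulas
# ---------------------------------------------------------------------------


def _random_process(rng, n, q):
    csp = rng.standard_normal((n, q))
    return ScoreProcess(csp=csp, order=np.arange(n),
                        sorted_values=np.arange(n, dtype=float))


@pytest.mark.parametrize("seed", range(8))
def test_continuous_statistics_equal_bruteforce(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 20))
    q = int(rng.integers(1, 4))
    sp = _random_process(rng, n, q)
    assert dm_statistic(sp).statistic == pytest.approx(brute_dm(sp.csp))
    assert cvm_statistic(sp).statistic == pytest.approx(brute_cvm(sp.csp))
    trim = (0.2, 0.8)
    lo, hi = int(np.ceil(0.2 * n)), int(np.floor(0.8 * n))
    got = maxlm_statistic(sp, trim).statistic
    assert got == pytest.approx(brute_maxlm(sp.csp, max(lo, 1), min(hi, n - 1)))


@pytest.mark.parametrize("seed", range(8))
def test_binned_statistics_equal_bruteforce(seed):
    rng = np.random.default_rng(100 + seed)
    m = int(rng.integers(2, 6))
    q = int(rng.integers(1, 4))
    counts = rng.integers(2, 10, size=m)
    bsp = rng.standard_normal((m, q))
    bsp[-1] = -bsp[:-1].sum(axis=0)  # enforce score-sum zero
    bp = BinnedProcess(bsp=bsp, cbsp=np.cumsum(bsp, axis=0)[:-1],
                       counts=counts, levels=tuple(range(m)))
    nl, n = bp.cumulative_counts, bp.n
    assert wdm_statistic(bp).statistic == pytest.approx(brute_wdm(bp.cbsp, nl, n))
    assert maxlm_ordinal_statistic(bp).statistic == pytest.approx(
        brute_maxlm_o(bp.cbsp, nl, n))
    assert lm_categorical_statistic(bp).statistic == pytest.approx(
        brute_lm_printed(bsp))


def test_statistic_worked_examples():
    sp = ScoreProcess(csp=np.array([[0.5], [-1.2], [0.3], [0.0]]),
                      order=np.arange(4), sorted_values=np.arange(4.0))
    assert dm_statistic(sp).statistic == pytest.approx(1.2)
    sp3 = ScoreProcess(csp=np.array([[0.5], [-1.2], [0.3]]),
                       order=np.arange(3), sorted_values=np.arange(3.0))
    assert cvm_statistic(sp3).statistic == pytest.approx((0.25 + 1.44 + 0.09) / 3)
    # doubling the process quadruples CvM
    sp3b = ScoreProcess(csp=2 * sp3.csp, order=np.arange(3),
                        sorted_values=np.arange(3.0))
    assert cvm_statistic(sp3b).statistic == pytest.approx(4 * cvm_statistic(sp3).statistic)
    spm = ScoreProcess(csp=np.array([[0.3], [0.8], [0.3], [0.0]]),
                       order=np.arange(4), sorted_values=np.arange(4.0))
    res = maxlm_statistic(spm, (0.25, 0.75))
    assert res.statistic == pytest.approx(2.56)
    assert res.positions[int(np.argmax(res.partial))] == 2
    # zero process -> all statistics zero
    spz = ScoreProcess(csp=np.zeros((5, 2)), order=np.arange(5),
                       sorted_values=np.arange(5.0))
    assert dm_statistic(spz).statistic == 0.0
    assert cvm_statistic(spz).statistic == 0.0
    assert maxlm_statistic(spz, (0.2, 0.8)).statistic == 0.0


def test_wdm_and_lm_worked_examples():
    bp = BinnedProcess(bsp=np.array([[0.6], [-0.6]]),
                       cbsp=np.array([[0.6]]), counts=np.array([5, 5]),
                       levels=(0, 1))
    assert wdm_statistic(bp).statistic == pytest.approx(0.6 / 0.5)
    a = 0.7
    bp2 = BinnedProcess(bsp=np.array([[a], [-a]]), cbsp=np.array([[a]]),
                        counts=np.array([5, 5]), levels=(0, 1))
    assert lm_categorical_statistic(bp2).statistic == pytest.approx(5 * a ** 2)
    # the printed differencing depends on the level order (regression pin)
    bp_rev = BinnedProcess(bsp=np.array([[-a], [a], [0.0]]),
                           cbsp=np.array([[-a], [0.0]]),
                           counts=np.array([3, 3, 3]), levels=(0, 1, 2))
    bp_fwd = BinnedProcess(bsp=np.array([[a], [0.0], [-a]]),
                           cbsp=np.array([[a], [a]]),
                           counts=np.array([3, 3, 3]), levels=(0, 1, 2))
    assert (lm_categorical_statistic(bp_rev).statistic
            != lm_categorical_statistic(bp_fwd).statistic)
    # the weighted variant is order-invariant
    assert lm_categorical_statistic(bp_rev, "weighted").statistic == pytest.approx(
        lm_categorical_statistic(bp_fwd, "weighted").statistic)


# ---------------------------------------------------------------------------
# p-values
# ---------------------------------------------------------------------------


def test_dm_pvalue_matches_kolmogorov():
    res = nulldist.dm_pvalue(1.358, q=1)
    assert res.method == "analytic"
    assert res.p == pytest.approx(0.050, abs=2e-3)
    assert nulldist.dm_pvalue(0.0, q=3).p == 1.0


def test_lm_weighted_pvalue_is_chisquare_tail():
    assert nulldist.lm_weighted_pvalue(stats.chi2.ppf(0.95, 1), q=1, m=2).p == \
        pytest.approx(0.05)


def test_lm_printed_null_weights_balanced_dichotomous():
    """Balanced m=2: the printed LM statistic is 1.25 * chi-square_q."""
    lam = nulldist._lm_printed_weights(np.array([0.5, 0.5]))
    lam = np.sort(lam[lam > 1e-12])
    assert lam == pytest.approx([1.25])
    pv = nulldist.lm_printed_pvalue(1.25 * stats.chi2.ppf(0.95, 2), q=2,
                                    props_per_level=[0.5, 0.5])
    assert pv.p == pytest.approx(0.05, abs=5e-3)


def test_zero_statistics_give_maximal_p(lgcm_fit):
    assert nulldist.cvm_pvalue(0.0, q=2).p == pytest.approx(1.0)
    assert nulldist.suplm_pvalue(0.0, q=2, trim=(0.15, 0.85)).p == pytest.approx(1.0)
    assert nulldist.wdm_pvalue(0.0, q=2, props=[0.5]).p == 1.0


def test_wdm_analytic_pvalue_matches_simulation():
    """The MVN-rectangle tail agrees with brute simulation of the binned
    bridge at the inspection points."""
    props = np.array([1 / 3, 2 / 3])
    stat = 2.2
    analytic = nulldist.wdm_pvalue(stat, q=2, props=props)
    assert analytic.method == "analytic"
    draws = nulldist._binned_bridge_draws(props, q=2, reps=40000)
    scale = np.sqrt(props * (1 - props))
    sim = (np.abs(draws).max(axis=2) / scale[None, :]).max(axis=1)
    p_sim = (sim > stat).mean()
    assert analytic.p == pytest.approx(p_sim, abs=0.01)


def test_simulated_pvalue_reports_mc_uncertainty():
    pv = nulldist.cvm_pvalue(1.0, q=1)
    assert pv.method == "simulated"
    assert 0.0 < pv.mc_se < 0.02
    assert pv.p >= 1.0 / 20001


# ---------------------------------------------------------------------------
# cut-point localization
# ---------------------------------------------------------------------------


def test_locate_cut_at_unique_extreme():
    csp = np.zeros((10, 1))
    csp[4, 0] = 3.0  # extreme at s=5
    x = np.arange(10.0)
    sp = ScoreProcess(csp=csp, order=np.arange(10), sorted_values=x,
                      boundaries=np.arange(1, 10))
    cut = locate_cutpoint_score(sp, trim=(0.1, 0.9))
    assert cut == pytest.approx(0.5 * (x[4] + x[5]))


def test_locate_cut_tie_breaks_to_earliest():
    csp = np.ones((10, 1))
    x = np.arange(10.0)
    sp = ScoreProcess(csp=csp, order=np.arange(10), sorted_values=x,
                      boundaries=np.arange(1, 10))
    cut = locate_cutpoint_score(sp, trim=(0.3, 0.7))
    assert cut == pytest.approx(0.5 * (x[2] + x[3]))  # earliest admissible s=3


def test_locate_cut_never_splits_ties():
    scores = np.array([[1.0], [2.0], [-4.0], [0.5], [0.5]])
    x = np.array([0.0, 1.0, 1.0, 1.0, 2.0])
    sp = cumulative_score_process(scores, np.array([[1.0]]), x)
    assert set(sp.boundaries.tolist()) == {1, 4}
    cut = locate_cutpoint_score(sp, trim=(0.01, 0.99))
    assert cut in (0.5, 1.5)


def test_locate_cut_dichotomous_single_boundary():
    bp = BinnedProcess(bsp=np.array([[0.4], [-0.4]]), cbsp=np.array([[0.4]]),
                       counts=np.array([6, 4]), levels=("a", "b"))
    assert locate_cutpoint_score(bp) == "a"


def test_cutpoint_recovery_central_break():
    """Synthetic single-break scores: located cut concentrates near the true
    median break of the covariate."""
    rng = np.random.default_rng(9)
    errs = []
    for _ in range(40):
        n = 400
        x = rng.standard_normal(n)
        med = np.median(x)
        scores = rng.standard_normal((n, 1)) * 0.8
        scores[x > med] += 0.8
        scores -= scores.mean(axis=0)
        sp = cumulative_score_process(scores, np.array([[scores.var()]]), x)
        errs.append(locate_cutpoint_score(sp, trim=(0.15, 0.85)) - med)
    assert abs(np.mean(errs)) < 0.1


# ---------------------------------------------------------------------------
# distributional properties
# ---------------------------------------------------------------------------


def test_dm_monotone_in_break_size():
    """A larger single-parameter break never lowers the median DM."""
    rng = np.random.default_rng(10)
    medians = []
    for c in (0.0, 0.15, 0.4):
        vals = []
        for _ in range(200):
            n = 100
            sc = rng.standard_normal((n, 1))
            sc[n // 2:] += c
            sc -= sc.mean(axis=0)
            sp = cumulative_score_process(sc, np.array([[sc.var()]]),
                                          np.arange(n, dtype=float))
            vals.append(dm_statistic(sp).statistic)
        medians.append(np.median(vals))
    assert medians[0] <= medians[1] <= medians[2]


def test_maxlm_agrees_with_maxlr_oracle():
    """One-parameter mean model, N=2,000: the maxLM statistic tracks the
    closed-form maximally selected LR (they are asymptotically equivalent)."""
    rng = np.random.default_rng(12)
    tm = TemplateModel.univariate_mean(1.0)
    n = 2000
    lm_vals, lr_vals = [], []
    for _ in range(200):
        y = rng.standard_normal((n, 1))
        y[:n // 2] -= 0.05
        y[n // 2:] += 0.05
        x = np.arange(n, dtype=float)
        fit = fit_ml(tm, y)
        sp = cumulative_score_process(fit.scores(), fit.information("opg"), x)
        lm_vals.append(maxlm_statistic(sp, (0.15, 0.85)).statistic)
        # closed-form sup-LR oracle with known unit variance
        ybar = y.mean()
        cum = np.cumsum(y.ravel() - ybar)
        s = np.arange(int(np.ceil(0.15 * n)), int(np.floor(0.85 * n)) + 1)
        lr_vals.append((cum[s - 1] ** 2 * n / (s * (n - s))).max())
    rho = stats.spearmanr(lm_vals, lr_vals).statistic
    assert rho >= 0.95
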