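"""Tree growth, covariate selection, partitioning, rendering, ARI."""

import json

import numpy as np
import pytest

from semscoretree import (Covariate, Dataset, SEMTree, SEMTreeResults,
                          SplitEvaluation, TemplateModel, TreeOptions,
                          adjusted_rand_index, fit_ml, select_covariate)
from semscoretree.simulate import (CFAParams, constrained_root_fit,
                                   generate_two_group_sample,
                                   introductory_example)
from semscoretree.tree import evaluate_covariate, route_cases


def _eval(cov, p, available=True):
    return SplitEvaluation(covariate=cov, kind="continuous", method="score",
                           available=available, pvalue=p)


def test_select_covariate_bonferroni_arithmetic():
    opts = TreeOptions(alpha=0.05)
    best, p_adj = select_covariate([_eval("a", 0.03)], opts)
    assert best.covariate == "a" and p_adj == pytest.approx(0.03)
    evs = [_eval("a", 0.5), _eval("b", 0.02), _eval("c", 0.9)]
    best, p_adj = select_covariate(evs, opts)
    assert best.covariate == "b" and p_adj == pytest.approx(0.06)
    assert p_adj >= opts.alpha  # -> no split
    best, p_adj = select_covariate([_eval("a", 1.0, available=False)], opts)
    assert best is None and p_adj is None
    # unavailable covariates do not enter the Bonferroni count
    evs = [_eval("a", 0.02), _eval("b", 1.0, available=False)]
    _, p_adj = select_covariate(evs, opts)
    assert p_adj == pytest.approx(0.02)


def test_select_covariate_tie_breaks_by_declaration_order():
    evs = [_eval("first", 0.01), _eval("second", 0.01)]
    best, _ = select_covariate(evs, TreeOptions())
    assert best.covariate == "first"


def test_options_validation():
    with pytest.raises(ValueError):
        TreeOptions(alpha=1.5)
    with pytest.raises(ValueError):
        TreeOptions(focus_parameters=("a",), equality_constraints=("a", "b"))
    with pytest.raises(ValueError):
        TreeOptions(stat_continuous="WDM")
    with pytest.raises(ValueError):
        TreeOptions(method="bogus")


def test_max_depth_zero_gives_root_only():
    template, data = introductory_example(seed=1)
    res = SEMTree(template, data).fit(max_depth=0, seed=1)
    assert res.n_nodes == 1
    assert len(set(res.partition())) == 1


@pytest.fixture(scope="module")
def intro_tree():
    template, data = introductory_example(seed=4)
    res = SEMTree(template, data).fit(seed=4)
    return res


def test_partition_property(intro_tree):
    """Leaves are disjoint and exhaust the sample."""
    leaves = intro_tree.leaves
    all_idx = np.concatenate([leaf.indices for leaf in leaves])
    assert len(all_idx) == intro_tree.model.data.n
    assert len(np.unique(all_idx)) == len(all_idx)
    labels = intro_tree.partition()
    for leaf in leaves:
        assert set(labels[leaf.indices]) == {leaf.node_id}
    for node in intro_tree.nodes:
        if node.children:
            l, r = node.children
            assert set(l.indices).isdisjoint(r.indices)
            assert set(l.indices) | set(r.indices) == set(node.indices)
            assert min(l.n, r.n) >= intro_tree.options.min_leaf_n
            assert node.split["p_adjusted"] < intro_tree.options.alpha


def test_trees_are_deterministic():
    template, data = introductory_example(seed=4)
    r1 = SEMTree(template, data).fit(seed=4)
    r2 = SEMTree(template, data).fit(seed=4)
    assert r1.render("text") == r2.render("text")
    assert json.dumps(r1.to_dict(), sort_keys=True) == \
        json.dumps(r2.to_dict(), sort_keys=True)


def test_intro_example_recovers_age_split_not_gender():
    """Age (true first-order effect) is the modal root split; the noise
    covariate gender is never selected at the root."""
    root_covs = []
    for seed in range(6):
        template, data = introductory_example(seed=seed)
        res = SEMTree(template, data).fit(seed=seed)
        if res.root.split:
            root_covs.append(res.root.split["covariate"])
    assert root_covs.count("age") >= len(root_covs) // 2 + 1
    assert "gender" not in root_covs


def test_routing_boundary_goes_left(intro_tree):
    assert intro_tree.root.split is not None
    split = intro_tree.root.split
    d = intro_tree.to_dict()
    import pandas as pd
    row = {"age": 30.0, "site": 1, "gender": 0}
    if split["kind"] == "continuous":
        cut = split["boundary"]
        left_row = dict(row, **{split["covariate"]: cut})
        right_row = dict(row, **{split["covariate"]: cut + 1e-6})
    else:
        levels = intro_tree.model.data.covariates[split["covariate"]].levels
        inside = sorted(split["boundary"])[0]
        outside = next(l for l in levels if l not in split["boundary"])
        left_row = dict(row, **{split["covariate"]: inside})
        right_row = dict(row, **{split["covariate"]: outside})
    df = pd.DataFrame([left_row, right_row])
    labels = route_cases(d, df)
    left_ids = {n["id"] for n in _collect(d["tree"]["children"][0])}
    assert labels[0] in left_ids
    assert labels[1] not in left_ids


def _collect(node):
    out = [node]
    for c in node.get("children", []):
        out.extend(_collect(c))
    return out


def test_json_round_trip(intro_tree):
    text = intro_tree.render("json")
    parsed = SEMTreeResults.parse(text)
    assert parsed == intro_tree.to_dict()


def test_dot_has_nodes_minus_one_edges(intro_tree):
    dot = intro_tree.render("dot")
    assert dot.count("->") == intro_tree.n_nodes - 1


def test_adjusted_rand_index_examples():
    assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == pytest.approx(1.0)
    assert adjusted_rand_index([0, 0, 0, 0], [1, 1, 2, 2]) == pytest.approx(0.0)
    assert adjusted_rand_index([1, 1, 2], [1, 2, 2]) == pytest.approx(-0.5)


def test_summary_mentions_structure(intro_tree):
    text = intro_tree.summary()
    assert "Method: score" in text
    assert "Node" in text
    pars = intro_tree.leaf_parameters()
    assert set(pars.columns) == {"node", "n", "parameter", "estimate", "se"}
    assert (pars["se"].dropna() > 0).all()


def test_constrained_root_shortcut_matches_explicit_refit():
    """Fixing a parameter at its full-sample estimate and refitting gives the
    same root evaluation as restricting the unconstrained fit."""
    rng = np.random.default_rng(30)
    g = CFAParams(phi=0.3)
    data, _ = generate_two_group_sample(g, g, 100, 100, "continuous", rng=rng)
    tm = TemplateModel.cfa_two_factor()
    fit = fit_ml(tm, data.Y)
    shortcut = constrained_root_fit(fit, ("phi",))
    phi_hat = float(fit.theta[tm.parameter_names.index("phi")])
    explicit = fit_ml(tm.constrain({"phi": phi_hat}), data.Y)
    assert np.allclose(shortcut.theta, explicit.theta, atol=5e-4)
    opts = TreeOptions(method="score")
    cov = data.covariates["z"]
    e1 = evaluate_covariate(shortcut, data.Y, cov, opts)
    e2 = evaluate_covariate(explicit, data.Y, cov, opts)
    assert e1.statistic == pytest.approx(e2.statistic, rel=1e-3)
    assert e1.pvalue == pytest.approx(e2.pvalue, abs=2e-3)


def test_grow_with_equality_constraints_fixes_parameter():
    rng = np.random.default_rng(31)
    g1, g2 = CFAParams(phi=0.0), CFAParams(phi=0.471)
    data, _ = generate_two_group_sample(g1, g2, 150, 150, "continuous", rng=rng)
    tm = TemplateModel.cfa_two_factor()
    res = SEMTree(tm, data).fit(equality_constraints=("phi",), seed=31,
                                max_depth=1)
    assert "phi" not in res.root.fit.parameter_names
    assert "phi" in getattr(res.root, "constraints", {})
    for node in res.nodes:
        assert node.fit.model.q == tm.q - 1


def test_focus_parameters_change_effective_dimension():
    rng = np.random.default_rng(32)
    g = CFAParams(phi=0.3)
    data, _ = generate_two_group_sample(g, g, 120, 120, "continuous", rng=rng)
    tm = TemplateModel.cfa_two_factor()
    fit = fit_ml(tm, data.Y)
    cov = data.covariates["z"]
    full = evaluate_covariate(fit, data.Y, cov, TreeOptions(method="score"))
    foc = evaluate_covariate(fit, data.Y, cov,
                             TreeOptions(method="score", focus_parameters=("phi",)))
    assert foc.statistic <= full.statistic + 1e-9
    assert foc.available and full.available


def test_lr_methods_agree_on_dichotomous_single_candidate():
    """With one candidate cut, score LM, naive and maxLR are all available
    and produce p-values in [0, 1]."""
    rng = np.random.default_rng(33)
    g = CFAParams(phi=0.3)
    data, _ = generate_two_group_sample(g, g, 80, 80, "dichotomous", rng=rng)
    tm = TemplateModel.cfa_two_factor()
    fit = fit_ml(tm, data.Y)
    cov = data.covariates["z"]
    for method in ("score", "naive", "maxLR"):
        ev = evaluate_covariate(fit, data.Y, cov,
                                TreeOptions(method=method, min_fit_n=20, seed=1))
        assert ev.available
        assert 0.0 <= ev.pvalue <= 1.0
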