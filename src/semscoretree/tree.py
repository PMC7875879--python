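"""Recursive partitioning of structural equation models over covariates.

:class:`SEMTree` is the model object: a template mean/covariance-structure
model plus a data set with typed covariates.  Its :meth:`SEMTree.fit` grows
the tree — at every node the template is fitted by maximum likelihood, each
covariate is evaluated for parameter instability (score-based or
likelihood-ratio-based), the covariate with the smallest (Bonferroni adjusted)
p-value is selected, and the node is split at the located cut point until no
covariate is significant or a stopping rule fires.  The returned
:class:`SEMTreeResults` carries the node structure, per-leaf estimates with
standard errors, the induced sample partition, and rendering helpers.

Focus parameters restrict split evaluation to a declared parameter subset
(score tests select the corresponding columns of the fully decorrelated
process); global equality constraints estimate a parameter once at the root
and fix it in every submodel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import lrtests, scoretests
from .model import (Covariate, Dataset, EstimationError, FittedModel,
                    TemplateModel, fit_ml)

__all__ = [
    "TreeOptions",
    "TreeNode",
    "SplitEvaluation",
    "SEMTree",
    "SEMTreeResults",
    "evaluate_covariate",
    "select_covariate",
    "grow_tree",
    "adjusted_rand_index",
]

_SCORE_STATS = {
    "continuous": ("DM", "CvM", "maxLM"),
    "ordinal": ("WDM", "maxLM_O"),
    "categorical": ("LM",),
}


@dataclass
class TreeOptions:
    """Growth options; defaults follow common structural-change practice."""

    method: str = "score"  # score | naive | fair | maxLR
    alpha: float = 0.05
    bonferroni_across_covariates: bool = True
    trim: float = 0.15
    min_fit_n: int = 20
    min_leaf_n: int = 20
    max_depth: int | None = None
    stat_continuous: str = "maxLM"
    stat_ordinal: str = "maxLM_O"
    stat_categorical: str = "LM"
    lm_variant: str = "printed"
    focus_parameters: tuple[str, ...] = ()
    equality_constraints: tuple[str, ...] = ()
    information: str = "expected"  # decorrelation; "opg" available
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.trim < 0.5:
            raise ValueError("trim must lie in (0, 0.5)")
        self.focus_parameters = tuple(self.focus_parameters)
        self.equality_constraints = tuple(self.equality_constraints)
        overlap = set(self.focus_parameters) & set(self.equality_constraints)
        if overlap:
            raise ValueError(f"focus and constrained parameters overlap: {sorted(overlap)}")
        if self.method not in ("score", "naive", "fair", "maxLR"):
            raise ValueError(f"unknown method {self.method!r}")
        for stat, kind in ((self.stat_continuous, "continuous"),
                           (self.stat_ordinal, "ordinal"),
                           (self.stat_categorical, "categorical")):
            if stat not in _SCORE_STATS[kind]:
                raise ValueError(f"unknown {kind} statistic {stat!r}")


@dataclass
class SplitEvaluation:
    covariate: str
    kind: str
    method: str
    available: bool
    statistic: float | None = None
    pvalue: float | None = None
    pvalue_method: str = ""
    cut: object = None
    detail: object = None
    reason: str = ""


@dataclass
class TreeNode:
    node_id: int
    depth: int
    indices: np.ndarray
    fit: FittedModel | None
    split: dict | None = None  # covariate, kind, boundary, statistic, p, p_adjusted
    children: tuple["TreeNode", "TreeNode"] | None = None
    evaluations: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def n(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# Split evaluation
# ---------------------------------------------------------------------------


def _focus_indices(template: TemplateModel, focus: Sequence[str]) -> list[int]:
    missing = [f for f in focus if f not in template.parameter_names]
    if missing:
        raise ValueError(f"focus parameters not in the template: {missing}")
    return [template.parameter_names.index(f) for f in focus]


def _score_eval(fit: FittedModel, covariate: Covariate, options: TreeOptions,
                min_side: int) -> SplitEvaluation:
    scores = fit.scores()
    try:
        info = fit.information(options.information)
        if covariate.kind == "continuous":
            sp = scoretests.cumulative_score_process(scores, info, covariate.values)
        else:
            levels = covariate.levels or tuple(np.unique(covariate.values))
            bp = scoretests.bin_scores(scores, covariate.values, levels, info)
    except np.linalg.LinAlgError as err:
        return SplitEvaluation(covariate.name, covariate.kind, "score",
                               available=False, reason=str(err))
    focus = options.focus_parameters
    cols = _focus_indices(fit.model, focus) if focus else list(range(fit.model.q))
    q_eff = len(cols)

    if covariate.kind == "continuous":
        spf = sp.select_columns(cols)
        stat_name = options.stat_continuous
        trim = (options.trim, 1.0 - options.trim)
        if stat_name == "DM":
            res = scoretests.dm_statistic(spf)
        elif stat_name == "CvM":
            res = scoretests.cvm_statistic(spf)
        else:
            res = scoretests.maxlm_statistic(spf, trim, min_side=min_side)
        if res.partial.size == 0:
            return SplitEvaluation(covariate.name, covariate.kind, "score",
                                   available=False, reason="no admissible cut point")
        pv = scoretests.score_pvalue(res, q_eff)
        cut = scoretests.locate_cutpoint_score(spf, trim, min_side=min_side)
        return SplitEvaluation(covariate.name, covariate.kind, "score", True,
                               res.statistic, pv.p, pv.method, cut, res)

    if bp.m < 2:
        return SplitEvaluation(covariate.name, covariate.kind, "score",
                               available=False, reason="single occupied level")
    bpf = bp.select_columns(cols)
    props = bp.cumulative_counts / bp.n
    if covariate.kind == "ordinal":
        stat_name = options.stat_ordinal
        res = (scoretests.wdm_statistic(bpf) if stat_name == "WDM"
               else scoretests.maxlm_ordinal_statistic(bpf))
        pv = scoretests.score_pvalue(res, q_eff, props=props)
        cut = scoretests.locate_cutpoint_score(bpf)
        return SplitEvaluation(covariate.name, covariate.kind, "score", True,
                               res.statistic, pv.p, pv.method, cut, res)
    res = scoretests.lm_categorical_statistic(bpf, variant=options.lm_variant)
    pv = scoretests.score_pvalue(res, q_eff)
    frac = bp.counts / bp.n
    contrib = (bpf.bsp ** 2).sum(axis=1) / frac
    cut = frozenset([bp.levels[int(np.argmax(contrib))]])
    return SplitEvaluation(covariate.name, covariate.kind, "score", True,
                           res.statistic, pv.p, pv.method, cut, res)


def _lr_eval(fit: FittedModel, Y: np.ndarray, covariate: Covariate,
             options: TreeOptions, rng: np.random.Generator) -> SplitEvaluation:
    model = fit.model
    if options.focus_parameters:
        fixed = {nm: float(fit.theta[i]) for i, nm in enumerate(model.parameter_names)
                 if nm not in options.focus_parameters}
        model = model.constrain(fixed)  # experimental focus-LR comparison
        start = np.asarray([fit.theta[fit.model.parameter_names.index(nm)]
                            for nm in model.parameter_names])
    else:
        start = fit.theta
    min_fit = max(options.min_fit_n, options.min_leaf_n, model.p + 1)
    cands = lrtests.enumerate_candidates(covariate, trim=options.trim,
                                         min_fit_n=min_fit)
    if options.method == "fair":
        result = lrtests.fair_test(model, Y, covariate, rng, trim=options.trim,
                                   min_fit_n=min_fit)
    elif not cands:
        result = None
    elif options.method == "naive":
        result = lrtests.naive_test(model, Y, cands, start)
    else:
        result = lrtests.maxlr_test(model, Y, cands, start)
    if result is None or result.selected is None:
        return SplitEvaluation(covariate.name, covariate.kind, options.method,
                               available=False, reason="no admissible or convergent candidate")
    return SplitEvaluation(covariate.name, covariate.kind, options.method, True,
                           result.statistic, result.pvalue, "chi2/supLM",
                           result.selected.boundary, result)


def evaluate_covariate(fit: FittedModel, Y: np.ndarray, covariate: Covariate,
                       options: TreeOptions,
                       rng: np.random.Generator | None = None) -> SplitEvaluation:
    """Evaluate one covariate at one node; dispatches on method and kind."""
    min_side = max(options.min_leaf_n, options.min_fit_n)
    if options.method == "score":
        return _score_eval(fit, covariate, options, min_side)
    if rng is None:
        rng = np.random.default_rng(options.seed)
    return _lr_eval(fit, Y, covariate, options, rng)


def select_covariate(evaluations: Sequence[SplitEvaluation],
                     options: TreeOptions) -> tuple[SplitEvaluation | None, float | None]:
    """Smallest p-value wins; Bonferroni across available covariates.

    Ties resolve to covariate declaration order.  Returns the winning
    evaluation and its adjusted p-value, or ``(None, None)``.
    """
    avail = [e for e in evaluations if e.available and e.pvalue is not None]
    if not avail:
        return None, None
    best = min(avail, key=lambda e: e.pvalue)
    p_adj = best.pvalue * len(avail) if options.bonferroni_across_covariates else best.pvalue
    return best, min(1.0, p_adj)


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------


def _route_left(covariate: Covariate, split: dict, values: np.ndarray) -> np.ndarray:
    kind, boundary = split["kind"], split["boundary"]
    if kind == "continuous":
        return values <= boundary
    if kind == "ordinal":
        levels = list(covariate.levels)
        ranks = np.asarray([levels.index(v) for v in values])
        return ranks <= levels.index(boundary)
    return np.isin(values, list(boundary))


def grow_tree(template: TemplateModel, data: Dataset, options: TreeOptions) -> TreeNode:
    """Grow a tree from the root sample; raises if the root fit fails."""
    constrained = template
    constraint_values: dict[str, float] = {}
    if options.equality_constraints:
        root_fit = fit_ml(template, data.Y, min_n=options.min_fit_n)
        if not root_fit.converged:
            raise EstimationError("root fit for equality constraints did not converge")
        constraint_values = {nm: float(root_fit.theta[template.parameter_names.index(nm)])
                             for nm in options.equality_constraints}
        constrained = template.constrain(constraint_values)

    counter = [0]
    seed_root = np.random.SeedSequence(options.seed if options.seed is not None else 0)

    def node_rng(node_id: int, cov_idx: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=seed_root.entropy,
                                   spawn_key=(node_id, cov_idx)))

    def build(indices: np.ndarray, depth: int) -> TreeNode:
        node_id = counter[0]
        counter[0] += 1
        sub = data.subset(indices)
        try:
            fit = fit_ml(constrained, sub.Y, min_n=options.min_fit_n)
        except EstimationError:
            fit = None
        node = TreeNode(node_id=node_id, depth=depth, indices=indices, fit=fit)
        if fit is None or not fit.converged:
            if depth == 0:
                raise EstimationError("root model estimation failed")
            return node
        if options.max_depth is not None and depth >= options.max_depth:
            return node
        if node.n < 2 * max(options.min_leaf_n, options.min_fit_n):
            return node
        evals = []
        for ci, cov in enumerate(sub.covariates.values()):
            evals.append(evaluate_covariate(fit, sub.Y, cov, options,
                                            rng=node_rng(node_id, ci)))
        node.evaluations = evals
        best, p_adj = select_covariate(evals, options)
        if best is None or p_adj >= options.alpha:
            return node
        cov = sub.covariates[best.covariate]
        split = {"covariate": best.covariate, "kind": best.kind,
                 "boundary": best.cut, "statistic": best.statistic,
                 "p": best.pvalue, "p_adjusted": p_adj, "method": best.method}
        left_mask = _route_left(cov, split, cov.values)
        n_left = int(left_mask.sum())
        if min(n_left, node.n - n_left) < options.min_leaf_n:
            return node
        left = build(indices[left_mask], depth + 1)
        right = build(indices[~left_mask], depth + 1)
        if (left.fit is None or not left.fit.converged
                or right.fit is None or not right.fit.converged):
            counter[0] = node_id + 1  # rejected split: discard daughters
            return TreeNode(node_id=node_id, depth=depth, indices=indices,
                            fit=fit, evaluations=evals)
        node.split = split
        node.children = (left, right)
        return node

    root = build(np.arange(data.n), 0)
    root.constraints = constraint_values  # type: ignore[attr-defined]
    return root


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class SEMTree:
    """A template structural equation model paired with partitioning data.

    Parameters
    ----------
    template : TemplateModel
        The model fitted in every node; only its free parameters may vary
        across groups and drive split decisions.
    data : Dataset
        Outcomes (complete continuous cases) and typed covariates.
    """

    def __init__(self, template: TemplateModel, data: Dataset):
        self.template = template
        self.data = data
        if data.p != template.p:
            raise ValueError(f"template implies {template.p} outcomes, data has {data.p}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, template: TemplateModel,
                       outcomes: Sequence[str], covariates=None) -> "SEMTree":
        return cls(template, Dataset.from_dataframe(df, outcomes, covariates))

    def fit(self, **options) -> "SEMTreeResults":
        opts = options.pop("options", None) or TreeOptions(**options)
        root = grow_tree(self.template, self.data, opts)
        return SEMTreeResults(self, root, opts)


class SEMTreeResults:
    """A grown tree: node structure, per-leaf estimates, partition, rendering."""

    def __init__(self, model: SEMTree, root: TreeNode, options: TreeOptions):
        self.model = model
        self.root = root
        self.options = options

    # -- structure ----------------------------------------------------------
    @property
    def nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def rec(node):
            out.append(node)
            if node.children:
                rec(node.children[0])
                rec(node.children[1])

        rec(self.root)
        return out

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    # -- partitioning -------------------------------------------------------
    def partition(self, data: Dataset | None = None) -> np.ndarray:
        """Leaf label per case (training data by default, or new data)."""
        ds = data if data is not None else self.model.data
        labels = np.empty(ds.n, dtype=int)

        def rec(node, idx):
            if node.is_leaf:
                labels[idx] = node.node_id
                return
            cov = ds.covariates[node.split["covariate"]]
            left = _route_left(cov, node.split, cov.values[idx])
            rec(node.children[0], idx[left])
            rec(node.children[1], idx[~left])

        rec(self.root, np.arange(ds.n))
        return labels

    # -- estimates ----------------------------------------------------------
    def leaf_parameters(self) -> pd.DataFrame:
        """Per-leaf estimates with standard errors from the information."""
        rows = []
        for leaf in self.leaves:
            fit = leaf.fit
            se = np.full(len(fit.parameter_names), np.nan)
            try:
                cov = np.linalg.inv(fit.n * fit.information(self.options.information))
                se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            except np.linalg.LinAlgError:
                pass
            for name, est, s in zip(fit.parameter_names, fit.theta, se):
                rows.append({"node": leaf.node_id, "n": leaf.n,
                             "parameter": name, "estimate": est, "se": s})
        return pd.DataFrame(rows)

    # -- rendering ----------------------------------------------------------
    def summary(self) -> str:
        opt = self.options
        lines = [
            "Structural equation model tree",
            "=" * 62,
            f"Template: {self.model.template.name}  "
            f"(p={self.model.template.p}, q={self.model.template.q})",
            f"Method: {opt.method}  alpha={opt.alpha}  trim={opt.trim}  "
            f"N={self.model.data.n}",
        ]
        if opt.focus_parameters:
            lines.append(f"Focus parameters: {', '.join(opt.focus_parameters)}")
        if opt.equality_constraints:
            cons = getattr(self.root, "constraints", {})
            lines.append("Constrained: " + ", ".join(
                f"{k}={v:.4g}" for k, v in cons.items()))
        lines.append("-" * 62)
        lines.append(self.render("text"))
        lines.append("-" * 62)
        leafpar = self.leaf_parameters()
        for node_id, grp in leafpar.groupby("node"):
            terms = ", ".join(f"{r.parameter}={r.estimate:.3f} ({r.se:.3f})"
                              for r in grp.itertuples())
            lines.append(f"Node {node_id}: {terms}")
        return "\n".join(lines)

    def render(self, fmt: str = "text") -> str:
        if fmt == "text":
            out = []

            def rec(node, indent):
                pad = "  " * indent
                if node.is_leaf:
                    out.append(f"{pad}[{node.node_id}] leaf n={node.n}")
                else:
                    s = node.split
                    b = s["boundary"]
                    b = sorted(b) if isinstance(b, frozenset) else f"{b:.4g}"
                    out.append(f"{pad}[{node.node_id}] n={node.n} split "
                               f"{s['covariate']} <= {b} "
                               f"(stat={s['statistic']:.4g}, p={s['p']:.4g}, "
                               f"adj={s['p_adjusted']:.4g})")
                    rec(node.children[0], indent + 1)
                    rec(node.children[1], indent + 1)

            rec(self.root, 0)
            return "\n".join(out)
        if fmt == "json":
            return json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if fmt == "dot":
            lines = ["digraph semtree {"]
            for node in self.nodes:
                if node.is_leaf:
                    lines.append(f'  n{node.node_id} [label="#{node.node_id}\\nn={node.n}"];')
                else:
                    s = node.split
                    lines.append(f'  n{node.node_id} [label="#{node.node_id}\\n'
                                 f'{s["covariate"]}\\np={s["p"]:.3g}"];')
                    for child in node.children:
                        lines.append(f"  n{node.node_id} -> n{child.node_id};")
            lines.append("}")
            return "\n".join(lines)
        raise ValueError(f"unknown format {fmt!r}")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        def ser(node):
            d = {"id": node.node_id, "depth": node.depth, "n": node.n,
                 "estimates": {k: float(v) for k, v in
                               zip(node.fit.parameter_names, node.fit.theta)}
                 if node.fit is not None else None}
            if node.split:
                s = dict(node.split)
                if isinstance(s["boundary"], frozenset):
                    s["boundary"] = sorted(s["boundary"])
                else:
                    s["boundary"] = float(s["boundary"]) if isinstance(
                        s["boundary"], (int, float, np.floating)) else s["boundary"]
                d["split"] = {k: (float(v) if isinstance(v, (np.floating, float)) else v)
                              for k, v in s.items()}
                d["children"] = [ser(c) for c in node.children]
            return d

        import hashlib

        opts = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.options).items()}
        cov_meta = {name: {"type": c.kind,
                           "levels": None if c.levels is None else
                           [_plain(v) for v in c.levels]}
                    for name, c in self.model.data.covariates.items()}
        return {"schema_version": 1,
                "version": __version__(),
                "template": self.model.template.name,
                "options": opts,
                "config_hash": hashlib.md5(
                    json.dumps(opts, sort_keys=True).encode()).hexdigest(),
                "covariates": cov_meta,
                "seed": self.options.seed,
                "tree": ser(self.root)}

    @staticmethod
    def parse(text: str) -> dict:
        return json.loads(text)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions."""
    return float(adjusted_rand_score(labels_a, labels_b))


def _plain(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def __version__() -> str:
    from . import __version__ as v
    return v


def route_cases(tree_dict: dict, df: pd.DataFrame) -> np.ndarray:
    """Route new cases through a serialized tree; returns leaf node ids.

    Cases at a continuous cut boundary go left ("<= cut"); ordinal splits
    compare level order, categorical splits test membership in the stored
    left-level set.
    """
    cov_meta = tree_dict["covariates"]
    labels = np.empty(len(df), dtype=int)

    def rec(node, idx):
        if "split" not in node:
            labels[idx] = node["id"]
            return
        s = node["split"]
        meta = cov_meta[s["covariate"]]
        vals = df[s["covariate"]].to_numpy()[idx]
        if s["kind"] == "continuous":
            left = vals <= s["boundary"]
        elif s["kind"] == "ordinal":
            levels = list(meta["levels"])
            left = np.asarray([levels.index(v) for v in vals]) <= levels.index(
                s["boundary"])
        else:
            left = np.isin(vals, list(s["boundary"]))
        rec(node["children"][0], idx[left])
        rec(node["children"][1], idx[~left])

    rec(tree_dict["tree"], np.arange(len(df)))
    return labels
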