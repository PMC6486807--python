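"""Ancestral-state reconstruction and phylogenetic correlation machinery.

* Mk model: 2-state symmetric continuous-time Markov chain ("unordered and
  equally weighted"), single rate fitted by maximum likelihood per tree via
  Felsenstein pruning; marginal ancestral states at every node from the
  standard up/down (re-rooting) pass with a flat (0.5, 0.5) root prior.
* Multi-tree summaries: clades matched by tip bipartition across a tree
  sample; per clade the presence fraction, mean marginal state
  probabilities, and the fraction of trees in which the most-probable state
  changes along the subtending branch.
* Pearson correlation and Felsenstein's phylogenetically independent
  contrasts (PIC), with through-origin correlation of two contrast sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import optimize, stats

__all__ = [
    "MkFit",
    "ContrastSet",
    "mk_fit",
    "summarize_asr_over_trees",
    "pearson",
    "pic_contrasts",
    "pic_correlation",
]

STATES = ("IR", "DR")  # encoded 0, 1


@dataclass
class MkFit:
    rate: float
    logL: float
    node_marginals: dict  # node key (frozenset of tip labels) -> (p_IR, p_DR)
    notes: tuple = ()


@dataclass
class ContrastSet:
    contrasts: list  # (node key, standardized contrast value)
    notes: tuple = ()

    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.contrasts])


def _p_change(rate: float, b: float) -> float:
    return 0.5 * (1.0 - np.exp(-2.0 * rate * b))


def _check_tree(tree: dendropy.Tree, char: dict) -> None:
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = tips - set(char)
    if missing:
        raise ValueError(f"tips without states: {sorted(missing)}")
    bad = set(char) & tips and {
        s for t, s in char.items() if t in tips and s not in STATES
    }
    if bad:
        raise ValueError(f"unknown states: {sorted(bad)}")


def _clade_key(node) -> frozenset:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def _pruning_loglik(tree: dendropy.Tree, char: dict, rate: float) -> float:
    partial = _postorder_partials(tree, char, rate)
    root = tree.seed_node
    return float(np.log(0.5 * partial[root].sum()))


def _postorder_partials(tree, char, rate):
    partial = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            v = np.zeros(2)
            v[STATES.index(char[node.taxon.label])] = 1.0
            partial[node] = v
        else:
            v = np.ones(2)
            for child in node.child_nodes():
                pc = _p_change(rate, child.edge.length or 0.0)
                P = np.array([[1 - pc, pc], [pc, 1 - pc]])
                v = v * (P @ partial[child])
            partial[node] = v
    return partial


def mk_fit(tree: dendropy.Tree, char: dict) -> MkFit:
    """ML single-rate Mk fit with marginal ancestral states at every node.

    Marginals are computed by the up/down algorithm: for each node, the
    outside (rootward) partial is propagated down and combined with the
    inside (pruning) partial; with the symmetric model and flat root prior
    this equals re-rooting at each node.
    """
    _check_tree(tree, char)
    tip_states = {char[leaf.taxon.label] for leaf in tree.leaf_node_iter()}
    total_bl = sum(e.length or 0.0 for e in tree.preorder_edge_iter())
    if total_bl <= 0:
        raise ValueError("tree has no positive branch lengths")

    notes = []
    if len(tip_states) == 1:
        rate = 0.0
        notes.append("monomorphic tips: boundary fit at rate 0")
        logL = 0.0
    else:
        res = optimize.minimize_scalar(
            lambda lr: -_pruning_loglik(tree, char, np.exp(lr)),
            bounds=(np.log(1e-8), np.log(1e4)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        rate = float(np.exp(res.x))
        logL = float(-res.fun)

    inside = _postorder_partials(tree, char, rate)
    outside = {tree.seed_node: np.array([0.5, 0.5])}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = node.parent_node
        sib_product = np.ones(2)
        for sib in parent.child_nodes():
            if sib is node:
                continue
            pc = _p_change(rate, sib.edge.length or 0.0)
            P = np.array([[1 - pc, pc], [pc, 1 - pc]])
            sib_product = sib_product * (P @ inside[sib])
        at_parent = outside[parent] * sib_product
        pc = _p_change(rate, node.edge.length or 0.0)
        P = np.array([[1 - pc, pc], [pc, 1 - pc]])
        outside[node] = P.T @ at_parent

    marginals = {}
    for node in tree.preorder_node_iter():
        joint = inside[node] * outside[node]
        total = joint.sum()
        if total <= 0:
            joint = np.array([0.5, 0.5])
            total = 1.0
        marginals[_clade_key(node)] = tuple(joint / total)
    if len(tip_states) == 1:
        logL = float(np.log(0.5))
    return MkFit(rate=rate, logL=logL, node_marginals=marginals, notes=tuple(notes))


def summarize_asr_over_trees(trees: list, char: dict) -> dict:
    """Per-clade ancestral-state summary across a sample of trees.

    Returns {clade (frozenset of tips): {"presence": fraction of trees with
    the clade, "mean_marginal": (p_IR, p_DR) averaged where present,
    "change_fraction": fraction of trees, among those containing the clade,
    in which the most-probable state differs between the clade's node and
    its parent}}.
    """
    if not trees:
        raise ValueError("empty tree sample")
    tip_sets = {frozenset(l.taxon.label for l in t.leaf_node_iter()) for t in trees}
    if len(tip_sets) != 1:
        raise ValueError("trees do not share a tip set")

    acc: dict = {}
    n_trees = len(trees)
    for tree in trees:
        fit = mk_fit(tree, char)
        parent_of = {}
        for node in tree.preorder_node_iter():
            key = _clade_key(node)
            parent_of[key] = (
                _clade_key(node.parent_node) if node.parent_node else None
            )
        for key, marg in fit.node_marginals.items():
            entry = acc.setdefault(
                key, {"count": 0, "marg": np.zeros(2), "changes": 0}
            )
            entry["count"] += 1
            entry["marg"] += np.array(marg)
            pkey = parent_of[key]
            if pkey is not None:
                pm = fit.node_marginals[pkey]
                if int(np.argmax(marg)) != int(np.argmax(pm)):
                    entry["changes"] += 1
    out = {}
    for key, entry in acc.items():
        out[key] = {
            "presence": entry["count"] / n_trees,
            "mean_marginal": tuple(entry["marg"] / entry["count"]),
            "change_fraction": entry["changes"] / entry["count"],
        }
    return out


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-test p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pic_contrasts(tree: dendropy.Tree, values: dict) -> ContrastSet:
    """Felsenstein's phylogenetically independent contrasts.

    At each internal node of the (strictly binary) tree the standardized
    contrast is (x1 - x2) / sqrt(v1 + v2); the node's ancestral value is the
    precision-weighted average and its parent branch is lengthened by
    v1*v2/(v1+v2). Polytomies and zero-variance cherries are errors.
    """
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    missing = set(tips) - set(values)
    if missing:
        raise ValueError(f"tips without values: {sorted(missing)}")

    node_val = {}
    node_var = {}
    contrasts = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node_val[node] = float(values[node.taxon.label])
            node_var[node] = float(node.edge.length or 0.0)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError("tree must be strictly binary for PIC")
        c1, c2 = children
        v1, v2 = node_var[c1], node_var[c2]
        if v1 + v2 <= 0:
            raise ValueError("zero-length cherry: contrast variance is 0")
        contrast = (node_val[c1] - node_val[c2]) / np.sqrt(v1 + v2)
        contrasts.append((_clade_key(node), float(contrast)))
        node_val[node] = (node_val[c1] / v1 + node_val[c2] / v2) / (1 / v1 + 1 / v2) if v1 > 0 and v2 > 0 else (
            node_val[c1] if v1 == 0 else node_val[c2]
        )
        extra = v1 * v2 / (v1 + v2)
        node_var[node] = float((node.edge.length or 0.0) + extra)
    return ContrastSet(contrasts=contrasts)


def pic_correlation(tree: dendropy.Tree, x: dict, y: dict) -> tuple[float, float]:
    """Through-origin correlation of the PIC sets of two tip variables.

    r = sum(cx*cy) / sqrt(sum(cx^2) sum(cy^2)); two-sided p from
    t = r*sqrt((k-1)/(1-r^2)) with k-1 degrees of freedom (k contrasts).
    """
    cx = pic_contrasts(tree, x).values()
    cy = pic_contrasts(tree, y).values()
    sxx, syy, sxy = float(cx @ cx), float(cy @ cy), float(cx @ cy)
    if sxx <= 0 or syy <= 0:
        raise ValueError("degenerate contrasts")
    r = sxy / np.sqrt(sxx * syy)
    k = cx.size
    df = k - 1
    if df < 1:
        raise ValueError("need at least 2 contrasts")
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(r), float(p)
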