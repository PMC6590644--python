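"""Tree-size selection by cross-validation with the c*SE rule.

A grown tree is reduced to a nested family of subtrees (fixed-effect trees:
weakest-link cost-complexity pruning on the FE-weighted node sums of
squares, the CART standard; random-effects trees: prefixes of the recorded
split order, the natural nested family of a sequential algorithm).  Ten-fold
cross-validation estimates a prediction error per candidate size, and the
c*SE rule picks the smallest size whose error is within c standard errors of
the minimum.  c = 1 is the classical one-standard-error rule; c = 0 picks
the error minimum.  Larger c means more pruning, which is the mechanism that
controls the Type I error of the final significance test.

Recommended defaults (encoded in :func:`recommended_c`): for FE trees c = 1
when K < 80 and c = 0.5 otherwise; for RE trees c = 1 when K < 120 and
c = 0.5 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import EffectSizeSet, SubgroupPartition
from .kernels import (
    SubgroupFit,
    fe_partition_fit,
    pooled_dl_tau2,
    re_partition_fit,
    subgroup_ci,
)
from .tree import DEFAULT_MIN_NODE_SIZE, MetaTree, grow_fe, grow_re

__all__ = [
    "CVCurve",
    "MetaCartResult",
    "nested_sequence",
    "cv_curve",
    "select_c_se",
    "recommended_c",
    "fit_metacart",
    "fit_metacart_path",
]


@dataclass
class CVCurve:
    """Cross-validation error per candidate tree size."""

    sizes: np.ndarray      # number of terminal nodes, strictly increasing
    errors: np.ndarray     # mean per-study weighted squared error
    ses: np.ndarray        # standard error of the mean contribution
    seed: int | None = None

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        self.errors = np.asarray(self.errors, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        if len(self.sizes) == 0 or self.sizes[0] != 1:
            raise ValueError("size family must start at 1")
        if np.any(np.diff(self.sizes) <= 0):
            raise ValueError("sizes must be strictly increasing")


def nested_sequence(tree: MetaTree):
    """Nested subtree family, ascending by size.

    Returns a list of (n_leaves, kept-internal-node frozenset) pairs,
    starting at the root-only tree of size 1.
    """
    if tree.model == "RE":
        return [(s + 1, tree.kept_for_prefix(s))
                for s in range(len(tree.split_order) + 1)]
    return _weakest_link_family(tree)


def _weakest_link_family(tree: MetaTree):
    """CART cost-complexity family on FE-weighted node sums of squares."""
    return [(s, k) for s, k, _ in _weakest_link_family_alphas(tree)]


def _weakest_link_family_alphas(tree: MetaTree):
    """Weakest-link family with critical complexity values.

    Repeatedly collapses the internal node(s) with the smallest
    per-terminal impurity reduction g(t) = (Q_t - sum of leaf Q under t)
    / (leaves under t - 1); all weakest links are collapsed together.
    Returns (size, kept, alpha) ascending by size, where ``alpha`` is the
    complexity at which the subtree becomes optimal (0 for the full tree).
    """
    kept = {n.id for n in tree.nodes if not n.is_leaf}
    family = [(tree.n_leaves(frozenset(kept)), frozenset(kept), 0.0)]
    while kept:
        stats = {}
        for t in kept:
            leaf_q = 0.0
            n_leaf = 0
            stack = [tree.nodes[t].left, tree.nodes[t].right]
            while stack:
                nid = stack.pop()
                if nid in kept:
                    stack.append(tree.nodes[nid].left)
                    stack.append(tree.nodes[nid].right)
                else:
                    leaf_q += tree.nodes[nid].q
                    n_leaf += 1
            stats[t] = (tree.nodes[t].q - leaf_q) / max(n_leaf - 1, 1)
        gmin = min(stats.values())
        to_prune = {t for t, g in stats.items() if g <= gmin + 1e-12}
        # collapsing a node removes every kept node in its subtree
        removed = set()
        for t in to_prune:
            stack = [t]
            while stack:
                nid = stack.pop()
                if nid in kept:
                    removed.add(nid)
                    stack.append(tree.nodes[nid].left)
                    stack.append(tree.nodes[nid].right)
        kept -= removed
        family.append((tree.n_leaves(frozenset(kept)), frozenset(kept),
                       float(gmin)))
    family.sort(key=lambda x: x[0])
    # drop duplicates (can arise when the last collapse reaches the root)
    dedup = []
    for size, kept_set, alpha in family:
        if not dedup or size != dedup[-1][0]:
            dedup.append((size, kept_set, alpha))
    return dedup


def _chain_family_alphas(tree: MetaTree):
    """Cost-complexity family of a sequential (RE) tree.

    The nested candidates of a sequential tree are the prefixes of its
    split order.  The cost-complexity-optimal prefixes are those on the
    lower convex minorant of the training impurity (FE-weighted leaf Q)
    against tree size; each carries the critical complexity at which it
    becomes optimal, exactly mirroring the weakest-link family of a
    recursive tree.  Returns (size, kept, alpha) ascending by size.
    """
    R = [tree.root.q]
    for nid in tree.split_order:
        n = tree.nodes[nid]
        R.append(R[-1] - (n.q - tree.nodes[n.left].q - tree.nodes[n.right].q))
    T = len(R) - 1
    hull = [0]
    for j in range(1, T + 1):
        while len(hull) >= 2:
            s1, s2 = hull[-2], hull[-1]
            slope_prev = (R[s1] - R[s2]) / (s2 - s1)
            slope_new = (R[s2] - R[j]) / (j - s2)
            if slope_new >= slope_prev - 1e-12:
                hull.pop()
            else:
                break
        hull.append(j)
    out = []
    for k, s in enumerate(hull):
        if k + 1 < len(hull):
            nxt = hull[k + 1]
            alpha = (R[s] - R[nxt]) / (nxt - s)
        else:
            alpha = 0.0
        out.append((s + 1, tree.kept_for_prefix(s), float(max(alpha, 0.0))))
    return out


def _leaf_predictions(data_tr: EffectSizeSet, tree: MetaTree, kept, model: str):
    """Per-leaf predicted effect and the training tau^2 for one subtree."""
    leaves = tree.leaf_ids(kept)
    if model == "FE":
        return {nid: tree.nodes[nid].d_plus for nid in leaves}, 0.0
    part = tree.partition(kept)
    tau2 = pooled_dl_tau2(data_tr, part)
    w = 1.0 / (data_tr.var + tau2)
    preds = {}
    for j, nid in enumerate(leaves):
        mem = tree.nodes[nid].members
        preds[nid] = float(np.sum(w[mem] * data_tr.d[mem]) / np.sum(w[mem]))
    return preds, tau2


def cv_curve(data: EffectSizeSet, model: str = "FE", folds: int = 10,
             seed: int | None = 0, min_node_size: int = DEFAULT_MIN_NODE_SIZE,
             grown: MetaTree | None = None) -> CVCurve:
    """K-fold cross-validation error over the main tree's candidate sizes.

    The validation error of a study is its weight times the squared
    deviation of its observed effect from the training-tree node summary it
    is routed to.  FE trees use the FE weight 1/var; RE trees use the
    marginal training RE weight 1/(var + tau^2_0), where tau^2_0 is the DL
    estimate on the training set *without* subgrouping — a per-fold
    constant, so that candidate sizes are compared on a common scale (a
    per-size tau^2 would shrink the apparent error of small trees, whose
    larger residual heterogeneity deflates their own weights).  RE node
    summaries are still the per-size RE weighted means.  Per size, the
    curve reports the mean contribution and the standard error of that
    mean.  Deterministic given ``seed`` (fold assignment is the only
    randomness).
    """
    if model not in ("FE", "RE"):
        raise ValueError("model must be 'FE' or 'RE'")
    grow = grow_fe if model == "FE" else grow_re
    if grown is None:
        grown = grow(data, min_node_size)
    fam_fn = (_weakest_link_family_alphas if model == "FE"
              else _chain_family_alphas)
    fam_alpha = fam_fn(grown)
    family = [(s, k) for s, k, _ in fam_alpha]
    alphas = [a for _, _, a in fam_alpha]
    # rpart-style complexity targets: each candidate subtree is optimal on
    # the interval [alpha_i, alpha_{i-1}); folds are evaluated at the
    # interval's geometric mean (root at +inf, full tree at 0)
    targets = [np.inf]
    for i in range(1, len(alphas)):
        targets.append(float(np.sqrt(alphas[i] * alphas[i - 1])))
    sizes = np.array([s for s, _ in family], dtype=np.int64)

    K = data.K
    folds = min(folds, K)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(K)
    fold_of = np.empty(K, dtype=np.int64)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        fold_of[chunk] = f

    codes, _, _, _ = data.encoded()
    contrib = np.zeros((K, len(sizes)))
    for f in range(folds):
        val_idx = np.flatnonzero(fold_of == f)
        tr_idx = np.flatnonzero(fold_of != f)
        data_tr = data.subset(tr_idx)
        if model == "RE":
            root_part = SubgroupPartition(
                assignment=np.zeros(len(tr_idx), dtype=np.int64), J=1)
            tau2_marg = pooled_dl_tau2(data_tr, root_part)
        else:
            tau2_marg = 0.0
        ftree = grow(data_tr, min_node_size)
        ffam_alpha = fam_fn(ftree)
        ffam = [(s, k) for s, k, _ in ffam_alpha]
        falphas = np.array([a for _, _, a in ffam_alpha])
        entry_cache = {}
        for si, s in enumerate(sizes):
            # fold subtree that is cost-complexity optimal at the
            # candidate's complexity target (smallest size on ties)
            ok = np.flatnonzero(falphas <= targets[si])
            fi = int(ok[0]) if len(ok) else len(ffam) - 1
            if fi not in entry_cache:
                kept = ffam[fi][1]
                preds, tau2 = _leaf_predictions(data_tr, ftree, kept, model)
                entry_cache[fi] = (kept, preds, tau2)
            kept, preds, tau2 = entry_cache[fi]
            for k in val_idx:
                leaf = ftree.route(codes[k], kept)
                resid = data.d[k] - preds[leaf]
                contrib[k, si] = resid * resid / (data.var[k] + tau2_marg)
    errors = contrib.mean(axis=0)
    ses = contrib.std(axis=0, ddof=1) / np.sqrt(K) if K > 1 else np.zeros(len(sizes))
    return CVCurve(sizes=sizes, errors=errors, ses=ses, seed=seed)


def select_c_se(curve: CVCurve, c: float) -> int:
    """Smallest size with error <= min(error) + c * SE(argmin).

    With c = 0 this is the error minimum (the smallest such size on ties);
    the selection is non-increasing in c.
    """
    if c < 0:
        raise ValueError("c must be >= 0")
    imin = int(np.argmin(curve.errors))
    threshold = curve.errors[imin] + c * curve.ses[imin]
    ok = np.flatnonzero(curve.errors <= threshold)
    return int(curve.sizes[ok[0]])


def recommended_c(model: str, K: int) -> float:
    """Pruning parameter recommended for Type I error control <= 0.05."""
    if model == "FE":
        return 1.0 if K < 80 else 0.5
    return 1.0 if K < 120 else 0.5


@dataclass
class MetaCartResult:
    """A pruned meta-analytic tree with its subgroup meta-analysis."""

    model: str
    tree: MetaTree
    kept: frozenset
    size: int
    c: float
    curve: CVCurve
    fit: SubgroupFit
    alpha: float = 0.05
    seed: int | None = None

    @property
    def is_trivial(self) -> bool:
        """True when pruning removed every split (no moderator effect)."""
        return self.size == 1

    @property
    def pvalue(self) -> float | None:
        return self.fit.pvalue

    @property
    def significant(self) -> bool:
        """Nontrivial tree with a significant between-subgroups Q test."""
        return (not self.is_trivial and self.fit.pvalue is not None
                and self.fit.pvalue < self.alpha)

    @property
    def moderators_used(self) -> set:
        return self.tree.moderators_used(self.kept) if self.size > 1 else set()

    @property
    def leaf_ids(self) -> list:
        return self.tree.leaf_ids(self.kept)

    def ci(self, level: float = 0.95) -> np.ndarray:
        return subgroup_ci(self.fit, level)


def _final_fit(data, tree, kept, model) -> SubgroupFit:
    part = tree.partition(kept)
    if model == "FE":
        return fe_partition_fit(data, part)
    return re_partition_fit(data, part)


def fit_metacart(data: EffectSizeSet, model: str = "RE", c: float | None = None,
                 folds: int = 10, seed: int | None = 0, alpha: float = 0.05,
                 min_node_size: int = DEFAULT_MIN_NODE_SIZE) -> MetaCartResult:
    """Grow, cross-validate, prune and test a meta-analytic tree.

    ``c=None`` applies the recommended K-dependent pruning rule.  A size-1
    result is a "trivial tree": no moderator effect detected, and no
    between-subgroups test is available (``pvalue`` is None).
    """
    return fit_metacart_path(data, model, [c], folds, seed, alpha,
                             min_node_size)[0]


def fit_metacart_path(data: EffectSizeSet, model: str, cs, folds: int = 10,
                      seed: int | None = 0, alpha: float = 0.05,
                      min_node_size: int = DEFAULT_MIN_NODE_SIZE):
    """Fit once, select for several pruning parameters.

    Growth and cross-validation are shared; one :class:`MetaCartResult` is
    returned per entry of ``cs`` (None entries use the recommended rule).
    """
    if model not in ("FE", "RE"):
        raise ValueError("model must be 'FE' or 'RE'")
    grow = grow_fe if model == "FE" else grow_re
    grown = grow(data, min_node_size)
    family = nested_sequence(grown)
    if len(family) == 1:
        # nothing to prune (e.g. a single study): trivial tree, no test
        curve = CVCurve(sizes=[1], errors=[0.0], ses=[0.0], seed=seed)
    else:
        curve = cv_curve(data, model, folds, seed, min_node_size, grown=grown)
    size_to_kept = dict(family)
    results = []
    for c in cs:
        c_eff = recommended_c(model, data.K) if c is None else float(c)
        size = select_c_se(curve, c_eff)
        kept = size_to_kept[size]
        fit = _final_fit(data, grown, kept, model)
        results.append(MetaCartResult(
            model=model, tree=grown, kept=kept, size=size, c=c_eff,
            curve=curve, fit=fit, alpha=alpha, seed=seed,
        ))
    return results
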