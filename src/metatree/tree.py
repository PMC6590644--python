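"""Meta-analytic regression tree growth.

Two growth algorithms share the node/tree machinery here:

* **Fixed-effect (FE) growth** is classical recursive partitioning with
  FE-weighted impurity: at every node the split minimising the sum of the
  two children's within-Q is chosen, which is identical to the split
  maximising the local two-child between-subgroups Q_B.  Each node's best
  split depends only on the node, so the grown tree is order-invariant; the
  recorded split order is best-first (largest local Q_B gain first).

* **Random-effects (RE) growth** is sequential, not recursive: at every
  step, every terminal node is a candidate parent, every admissible rule in
  it is scored by the *whole-tree* between-subgroups Q*_B after re-pooling
  the DerSimonian-Laird residual heterogeneity for the candidate partition,
  and the globally best (parent, rule) is split.  The split order therefore
  matters and defines the nested subtree family used in pruning.

Both grow maximally (zero-gain splits permitted; pruning removes them) and
stop when no terminal node can be split with both children at or above the
minimum node size (default 2 studies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _fast
from .data import EffectSizeSet, SubgroupPartition
from .kernels import fe_summary, within_q_fe, re_partition_fit

__all__ = [
    "SplitRule",
    "Node",
    "MetaTree",
    "candidate_splits",
    "best_split_fe",
    "grow_fe",
    "score_split_re",
    "best_split_re",
    "grow_re",
]

DEFAULT_MIN_NODE_SIZE = 2


@dataclass(frozen=True)
class SplitRule:
    """A binary split of a node on one moderator.

    ``threshold`` rules (binary / ordinal / continuous moderators) send
    studies with encoded value <= threshold left.  ``subset`` rules
    (nominal moderators) send studies whose level code is in
    ``left_codes`` left.  ``observed_codes`` records the level codes seen
    in the training node (used to route unseen levels of later data), and
    the decoded ``left_values`` make rules human-readable.
    """

    mod: int
    col: str
    kind: str                      # "threshold" | "subset"
    threshold: float = np.nan
    left_codes: tuple = ()
    observed_codes: tuple = ()
    left_values: tuple = ()

    def goes_left(self, code: float) -> bool:
        if self.kind == "threshold":
            return code <= self.threshold
        return int(code) in self.left_codes


@dataclass
class Node:
    """One tree node; ``members`` indexes rows of the training data."""

    id: int
    parent: int | None
    members: np.ndarray
    d_plus: float
    q: float
    depth: int
    rule: SplitRule | None = None
    left: int | None = None
    right: int | None = None
    split_gain: float = np.nan     # local Q_B of the split made at this node

    @property
    def is_leaf(self) -> bool:
        return self.rule is None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class MetaTree:
    """A grown meta-analytic regression tree.

    ``split_order`` lists internal node ids in the order the splits were
    made; for RE trees this order defines the nested pruning family and
    ``re_path[s]`` records the pooled tau^2 and whole-tree Q*_B after the
    (s+1)-th split.
    """

    model: str
    min_size: int
    nodes: list = field(default_factory=list)
    split_order: list = field(default_factory=list)
    re_path: list = field(default_factory=list)

    # -- structure helpers -------------------------------------------------
    @property
    def root(self) -> Node:
        return self.nodes[0]

    def n_leaves(self, kept=None) -> int:
        return len(self.leaf_ids(kept))

    def kept_for_prefix(self, n_splits: int) -> frozenset:
        """Internal-node set for a prefix of the split order."""
        return frozenset(self.split_order[:n_splits])

    def leaf_ids(self, kept=None) -> list:
        """Terminal node ids of the (possibly pruned) tree.

        ``kept`` is the set of internal node ids retained; ``None`` means
        the full tree.  Leaves are returned in left-to-right order.
        """
        if kept is None:
            kept = frozenset(n.id for n in self.nodes if not n.is_leaf)
        out = []

        def walk(nid):
            node = self.nodes[nid]
            if node.id in kept and node.rule is not None:
                walk(node.left)
                walk(node.right)
            else:
                out.append(nid)

        walk(0)
        return out

    def partition(self, kept=None) -> SubgroupPartition:
        """Training-data partition induced by the (pruned) tree."""
        leaves = self.leaf_ids(kept)
        assignment = np.empty(self.root.size, dtype=np.int64)
        for j, nid in enumerate(leaves):
            assignment[self.nodes[nid].members] = j
        return SubgroupPartition(assignment=assignment, J=len(leaves))

    def moderators_used(self, kept=None) -> set:
        """Distinct moderator column names split on in the (pruned) tree."""
        if kept is None:
            kept = frozenset(n.id for n in self.nodes if not n.is_leaf)
        return {self.nodes[nid].rule.col for nid in kept}

    def route(self, code_row, kept=None) -> int:
        """Leaf id a study with encoded moderator row ``code_row`` lands in.

        A nominal level unseen in the training node is routed to the child
        with more training studies (ties go left).
        """
        if kept is None:
            kept = frozenset(n.id for n in self.nodes if not n.is_leaf)
        nid = 0
        while True:
            node = self.nodes[nid]
            if node.id not in kept or node.rule is None:
                return nid
            rule = node.rule
            code = code_row[rule.mod]
            if rule.kind == "subset" and int(code) not in rule.observed_codes:
                left_n = self.nodes[node.left].size
                right_n = self.nodes[node.right].size
                nid = node.left if left_n >= right_n else node.right
            elif rule.goes_left(code):
                nid = node.left
            else:
                nid = node.right


# ---------------------------------------------------------------------------
# candidate enumeration (public, pure Python; the kernels repeat this order)
# ---------------------------------------------------------------------------

def candidate_splits(data: EffectSizeSet, members, mod: int) -> list:
    """All admissible rules for one moderator within one node.

    Continuous/ordinal: midpoints between consecutive distinct observed
    values; binary: the single dichotomy; nominal with L observed levels:
    all 2^(L-1) - 1 proper bipartitions.  A constant moderator yields an
    empty list.  Rules are returned in the canonical (deterministic) order
    used for tie-breaking: thresholds ascending, subset bitmasks ascending.
    """
    codes, type_codes, n_levels, level_maps = data.encoded()
    members = np.asarray(members)
    col = data.X.columns[mod]
    vals = codes[members, mod]
    rules = []
    if type_codes[mod] == 0:
        uniq = np.unique(vals)
        for lo, hi in zip(uniq[:-1], uniq[1:]):
            thr = 0.5 * (lo + hi)
            levels = level_maps.get(col)
            left_vals = tuple(
                levels[int(u)] for u in uniq if u <= thr
            ) if levels is not None else tuple(u for u in uniq if u <= thr)
            rules.append(SplitRule(
                mod=mod, col=col, kind="threshold", threshold=thr,
                observed_codes=tuple(int(u) for u in uniq) if levels else (),
                left_values=left_vals,
            ))
    else:
        obs = sorted(int(u) for u in np.unique(vals))
        if len(obs) >= 2:
            l0 = obs[0]
            obs_mask = 0
            for lv in obs:
                obs_mask |= 1 << lv
            levels = level_maps[col]
            for mask in range(1, 1 << int(n_levels[mod])):
                if mask & ~obs_mask or not (mask >> l0) & 1 or mask == obs_mask:
                    continue
                left = tuple(lv for lv in obs if (mask >> lv) & 1)
                rules.append(SplitRule(
                    mod=mod, col=col, kind="subset",
                    left_codes=left, observed_codes=tuple(obs),
                    left_values=tuple(levels[lv] for lv in left),
                ))
    return rules


def _rule_from_kernel(data, members, mod, thr, mask):
    """Decode a kernel result into a SplitRule."""
    codes, type_codes, n_levels, level_maps = data.encoded()
    members = np.asarray(members)
    col = data.X.columns[mod]
    vals = codes[members, mod]
    uniq = np.unique(vals)
    levels = level_maps.get(col)
    if type_codes[mod] == 0:
        left_vals = tuple(
            levels[int(u)] if levels is not None else float(u)
            for u in uniq if u <= thr
        )
        return SplitRule(
            mod=mod, col=col, kind="threshold", threshold=float(thr),
            observed_codes=tuple(int(u) for u in uniq) if levels else (),
            left_values=left_vals,
        )
    obs = tuple(int(u) for u in uniq)
    left = tuple(lv for lv in obs if (mask >> lv) & 1)
    return SplitRule(
        mod=mod, col=col, kind="subset", left_codes=left,
        observed_codes=obs, left_values=tuple(levels[lv] for lv in left),
    )


def _apply_rule(codes, members, rule: SplitRule):
    vals = codes[members, rule.mod]
    if rule.kind == "threshold":
        mask_left = vals <= rule.threshold
    else:
        mask_left = np.isin(vals.astype(np.int64), rule.left_codes)
    return members[mask_left], members[~mask_left]


# ---------------------------------------------------------------------------
# fixed-effect growth
# ---------------------------------------------------------------------------

def best_split_fe(data: EffectSizeSet, members, min_size: int = DEFAULT_MIN_NODE_SIZE):
    """Best FE split of a node, or None.

    Returns (rule, gain) where gain is the local two-child Q_B — identical
    to the reduction Q_parent - (Q_left + Q_right).
    """
    members = np.asarray(members, dtype=np.int64)
    if len(members) < 2 * min_size:
        return None
    codes, type_codes, n_levels, _ = data.encoded()
    mod, thr, mask, score = _fast.fe_best_split(
        data.d, data.var, codes, type_codes, n_levels, members, min_size)
    if mod == _fast.NO_SPLIT:
        return None
    w = 1.0 / data.var[members]
    s0 = w.sum()
    s1 = (w * data.d[members]).sum()
    gain = max(float(score - s1 * s1 / s0), 0.0)
    rule = _rule_from_kernel(data, members, mod, thr, mask)
    return rule, gain


def grow_fe(data: EffectSizeSet, min_node_size: int = DEFAULT_MIN_NODE_SIZE) -> MetaTree:
    """Grow a maximal FE tree (recursive partitioning, best-first order)."""
    codes, _, _, _ = data.encoded()
    tree = MetaTree(model="FE", min_size=min_node_size)
    all_members = np.arange(data.K, dtype=np.int64)
    root = Node(
        id=0, parent=None, members=all_members,
        d_plus=fe_summary(data.d, data.var),
        q=within_q_fe(data.d, data.var), depth=0,
    )
    tree.nodes.append(root)
    # frontier of splittable leaves with their cached best splits
    pending = {}
    cand = best_split_fe(data, all_members, min_node_size)
    if cand is not None:
        pending[0] = cand
    while pending:
        # best-first: largest local gain, ties to the oldest node
        nid = min(pending, key=lambda i: (-pending[i][1], i))
        rule, gain = pending.pop(nid)
        node = tree.nodes[nid]
        left_m, right_m = _apply_rule(codes, node.members, rule)
        for side_members in (left_m, right_m):
            child = Node(
                id=len(tree.nodes), parent=nid, members=side_members,
                d_plus=fe_summary(data.d[side_members], data.var[side_members]),
                q=within_q_fe(data.d[side_members], data.var[side_members]),
                depth=node.depth + 1,
            )
            tree.nodes.append(child)
            if node.left is None:
                node.left = child.id
            else:
                node.right = child.id
            c = best_split_fe(data, side_members, min_node_size)
            if c is not None:
                pending[child.id] = c
        node.rule = rule
        node.split_gain = gain
        tree.split_order.append(nid)
    return tree


# ---------------------------------------------------------------------------
# random-effects growth
# ---------------------------------------------------------------------------

def score_split_re(data: EffectSizeSet, tree: MetaTree, parent_id: int,
                   rule: SplitRule) -> float:
    """Whole-tree Q*_B if ``parent_id`` were split by ``rule`` (reference path).

    Forms the partition given by the tree's current terminal nodes with the
    parent replaced by the two children, re-pools tau^2, and returns the RE
    between-subgroups Q*.  Side-effect free; used as the slow reference
    implementation for the JIT step kernel.
    """
    codes, _, _, _ = data.encoded()
    parent = tree.nodes[parent_id]
    if not parent.is_leaf:
        raise ValueError("parent is not a terminal node")
    left_m, right_m = _apply_rule(codes, parent.members, rule)
    if min(len(left_m), len(right_m)) < tree.min_size:
        raise ValueError("rule violates the minimum node size")
    leaves = [nid for nid in tree.leaf_ids() if nid != parent_id]
    assignment = np.empty(data.K, dtype=np.int64)
    for j, nid in enumerate(leaves):
        assignment[tree.nodes[nid].members] = j
    assignment[left_m] = len(leaves)
    assignment[right_m] = len(leaves) + 1
    part = SubgroupPartition(assignment=assignment, J=len(leaves) + 2)
    return re_partition_fit(data, part).q_between


def best_split_re(data: EffectSizeSet, tree: MetaTree):
    """Globally best next RE split over all terminal nodes (reference path).

    Substep 1 finds, per candidate parent, the rule maximising the
    whole-tree Q*_B; substep 2 compares parents.  Pure Python; enumerates
    every (parent, moderator, rule) triple via :func:`score_split_re`.
    Returns (parent_id, rule, qb_star) or None.
    """
    best = None
    for pid in tree.leaf_ids():
        parent = tree.nodes[pid]
        if parent.size < 2 * tree.min_size:
            continue
        for mod in range(data.M):
            for rule in candidate_splits(data, parent.members, mod):
                codes, _, _, _ = data.encoded()
                left_m, right_m = _apply_rule(codes, parent.members, rule)
                if min(len(left_m), len(right_m)) < tree.min_size:
                    continue
                qb = score_split_re(data, tree, pid, rule)
                if best is None or qb > best[2]:
                    best = (pid, rule, qb)
    return best


def _node_dl_stats(d, var, members):
    """FE within-Q, DL C component, and size of one node."""
    w = 1.0 / var[members]
    s0 = w.sum()
    s1 = (w * d[members]).sum()
    s2 = (w * d[members] ** 2).sum()
    q = max(float(s2 - s1 * s1 / s0), 0.0)
    c = float(s0 - (w * w).sum() / s0)
    return q, c, len(members)


def grow_re(data: EffectSizeSet, min_node_size: int = DEFAULT_MIN_NODE_SIZE) -> MetaTree:
    """Grow a maximal RE tree by sequential partitioning.

    Each accepted split maximises the whole-tree Q*_B over every scored
    candidate at that step; the per-step pooled tau^2 and Q*_B are recorded
    in ``tree.re_path``.
    """
    codes, type_codes, n_levels, _ = data.encoded()
    d, var = data.d, data.var
    tree = MetaTree(model="RE", min_size=min_node_size)
    all_members = np.arange(data.K, dtype=np.int64)
    root = Node(
        id=0, parent=None, members=all_members,
        d_plus=fe_summary(d, var), q=within_q_fe(d, var), depth=0,
    )
    tree.nodes.append(root)

    assign = np.zeros(data.K, dtype=np.int64)
    slots = [0]                      # terminal node id per slot
    q0, c0, n0 = _node_dl_stats(d, var, all_members)
    node_q = [q0]
    node_c = [c0]
    node_n = [float(n0)]

    while True:
        n_terminal = len(slots)
        parent_slot, mod, thr, mask, tau2, qb = _fast.re_best_step(
            d, var, codes, type_codes, n_levels, assign, n_terminal,
            np.asarray(node_q), np.asarray(node_c), np.asarray(node_n),
            min_node_size,
        )
        if parent_slot == _fast.NO_SPLIT:
            break
        pid = slots[parent_slot]
        parent = tree.nodes[pid]
        rule = _rule_from_kernel(data, parent.members, mod, thr, mask)
        left_m, right_m = _apply_rule(codes, parent.members, rule)
        left = Node(
            id=len(tree.nodes), parent=pid, members=left_m,
            d_plus=fe_summary(d[left_m], var[left_m]),
            q=within_q_fe(d[left_m], var[left_m]), depth=parent.depth + 1,
        )
        tree.nodes.append(left)
        right = Node(
            id=len(tree.nodes), parent=pid, members=right_m,
            d_plus=fe_summary(d[right_m], var[right_m]),
            q=within_q_fe(d[right_m], var[right_m]), depth=parent.depth + 1,
        )
        tree.nodes.append(right)
        parent.rule = rule
        parent.left = left.id
        parent.right = right.id
        parent.split_gain = max(float(qb), 0.0)
        tree.split_order.append(pid)
        tree.re_path.append({"tau2": float(tau2), "qb_star": max(float(qb), 0.0)})

        # left child takes the parent's slot; right child appends
        slots[parent_slot] = left.id
        slots.append(right.id)
        assign[right_m] = n_terminal
        ql, cl, nl = _node_dl_stats(d, var, left_m)
        qr, cr, nr = _node_dl_stats(d, var, right_m)
        node_q[parent_slot] = ql
        node_c[parent_slot] = cl
        node_n[parent_slot] = float(nl)
        node_q.append(qr)
        node_c.append(cr)
        node_n.append(float(nr))
    return tree
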