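"""Tree growth: candidate enumeration, exhaustive oracles, determinism."""

import numpy as np
import pandas as pd
import pytest

from metatree import (
    EffectSizeSet,
    SimDesign,
    SubgroupPartition,
    best_split_fe,
    best_split_re,
    candidate_splits,
    fe_partition_fit,
    gen_dataset,
    grow_fe,
    grow_re,
    re_partition_fit,
    score_split_re,
)
from metatree.tree import MetaTree, Node, _apply_rule
from metatree.kernels import fe_summary, within_q_fe


def _exhaustive_best_fe(data, members, min_size=2):
    """Brute-force oracle: minimum child Q-sum over every (moderator, rule)."""
    best = None
    members = np.asarray(members)
    codes, _, _, _ = data.encoded()
    for mod in range(data.M):
        for rule in candidate_splits(data, members, mod):
            lm, rm = _apply_rule(codes, members, rule)
            if min(len(lm), len(rm)) < min_size:
                continue
            qsum = (within_q_fe(data.d[lm], data.var[lm])
                    + within_q_fe(data.d[rm], data.var[rm]))
            if best is None or qsum < best[1] - 1e-12:
                best = (rule, qsum)
    return best


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

def test_binary_single_rule(toy4):
    rules = candidate_splits(toy4, np.arange(4), 0)
    assert len(rules) == 1
    assert rules[0].kind == "threshold"


def test_nominal_three_bipartitions():
    data = EffectSizeSet(
        d=[0.1, 0.2, 0.3, 0.4, 0.5, 0.6], var=[0.04] * 6,
        X=pd.DataFrame({"g": ["A", "B", "C", "A", "B", "C"]}),
        types={"g": "nominal"})
    rules = candidate_splits(data, np.arange(6), 0)
    assert len(rules) == 3
    lefts = {frozenset(r.left_values) for r in rules}
    assert lefts == {frozenset({"A"}), frozenset({"A", "B"}),
                     frozenset({"A", "C"})}


def test_continuous_rule_count_matches_distinct_values():
    rng = np.random.default_rng(0)
    x = np.round(rng.normal(size=30), 1)
    data = EffectSizeSet(d=rng.normal(size=30), var=np.full(30, 0.05),
                         X=pd.DataFrame({"x": x}), types={"x": "continuous"})
    rules = candidate_splits(data, np.arange(30), 0)
    assert len(rules) == len(np.unique(x)) - 1


def test_constant_moderator_no_rules():
    data = EffectSizeSet(d=[0.1, 0.2, 0.3], var=[0.04] * 3,
                         X=pd.DataFrame({"x": [1, 1, 1]}),
                         types={"x": "binary"})
    assert candidate_splits(data, np.arange(3), 0) == []


# ---------------------------------------------------------------------------
# FE splitting
# ---------------------------------------------------------------------------

def test_best_split_fe_toy(toy4):
    rule, gain = best_split_fe(toy4, np.arange(4))
    assert rule.col == "x1"
    assert gain == pytest.approx(6.25)


@pytest.mark.parametrize("mtype", ["binary", "nominal", "ordinal", "continuous"])
@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_best_split_fe_matches_exhaustive_oracle(mtype, seed):
    """The kernel's split equals brute-force enumeration on K<=12, M<=3."""
    from conftest import random_dataset
    data, _ = random_dataset(seed, K=12, M=3, mtype=mtype)
    members = np.arange(data.K)
    got = best_split_fe(data, members)
    want = _exhaustive_best_fe(data, members)
    assert (got is None) == (want is None)
    if got is None:
        return
    rule, gain = got
    codes, _, _, _ = data.encoded()
    lm, rm = _apply_rule(codes, members, rule)
    qsum = (within_q_fe(data.d[lm], data.var[lm])
            + within_q_fe(data.d[rm], data.var[rm]))
    assert qsum == pytest.approx(want[1], abs=1e-8)
    # duality: the local two-child Q_B equals the impurity reduction
    q_parent = within_q_fe(data.d, data.var)
    part = SubgroupPartition((codes[:, rule.mod] > rule.threshold).astype(int)
                             if rule.kind == "threshold" else
                             (~np.isin(codes[:, rule.mod].astype(int),
                                       rule.left_codes)).astype(int), 2)
    qb = fe_partition_fit(data, part).q_between
    assert qb == pytest.approx(q_parent - qsum, abs=1e-8)
    assert gain == pytest.approx(qb, abs=1e-8)


def test_grow_fe_deterministic():
    from conftest import random_dataset
    data, _ = random_dataset(7, K=30, M=3, mtype="continuous")
    t1, t2 = grow_fe(data), grow_fe(data)
    assert t1.split_order == t2.split_order
    assert all(a.rule == b.rule for a, b in zip(t1.nodes, t2.nodes))


def test_grow_fe_recovers_noiseless_interaction():
    """Data generated exactly from a two-way interaction: the first two
    splits isolate the two true moderators."""
    rng = np.random.default_rng(1)
    K = 40
    x1 = rng.integers(0, 2, K)
    x2 = rng.integers(0, 2, K)
    noise = rng.integers(0, 2, K)
    d = np.where((x1 == 1) & (x2 == 1), 0.8, 0.0) + rng.normal(0, 0.01, K)
    data = EffectSizeSet(d=d, var=np.full(K, 0.04),
                         X=pd.DataFrame({"x1": x1, "x2": x2, "x3": noise}),
                         types={c: "binary" for c in ("x1", "x2", "x3")})
    tree = grow_fe(data)
    first_two = {tree.nodes[nid].rule.col for nid in tree.split_order[:2]}
    assert first_two == {"x1", "x2"}


def test_grow_respects_min_node_size():
    from conftest import random_dataset
    data, _ = random_dataset(3, K=20, M=2, mtype="continuous")
    for grow in (grow_fe, grow_re):
        tree = grow(data, min_node_size=3)
        for nid in tree.leaf_ids():
            assert tree.nodes[nid].size >= 3
        for n in tree.nodes:
            if not n.is_leaf:
                assert tree.nodes[n.left].size >= 3
                assert tree.nodes[n.right].size >= 3


def test_children_partition_parent():
    from conftest import random_dataset
    data, _ = random_dataset(11, K=20, M=3, mtype="nominal")
    tree = grow_fe(data)
    for n in tree.nodes:
        if n.is_leaf:
            continue
        lm = tree.nodes[n.left].members
        rm = tree.nodes[n.right].members
        assert np.array_equal(np.sort(np.concatenate([lm, rm])),
                              np.sort(n.members))


# ---------------------------------------------------------------------------
# RE sequential growth
# ---------------------------------------------------------------------------

def _single_node_tree(data):
    tree = MetaTree(model="RE", min_size=2)
    m = np.arange(data.K, dtype=np.int64)
    tree.nodes.append(Node(id=0, parent=None, members=m,
                           d_plus=fe_summary(data.d, data.var),
                           q=within_q_fe(data.d, data.var), depth=0))
    return tree


def test_score_split_re_single_node_reduces_to_partition_fit():
    from conftest import random_dataset
    data, _ = random_dataset(5, K=12, M=2, mtype="binary")
    tree = _single_node_tree(data)
    rule = candidate_splits(data, np.arange(data.K), 0)[0]
    codes, _, _, _ = data.encoded()
    lm, rm = _apply_rule(codes, np.arange(data.K), rule)
    part = SubgroupPartition(np.isin(np.arange(data.K), rm).astype(int), 2)
    assert score_split_re(data, tree, 0, rule) == pytest.approx(
        re_partition_fit(data, part).q_between)


@pytest.mark.parametrize("mtype", ["binary", "nominal", "ordinal", "continuous"])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_grow_re_matches_stepwise_reference(mtype, seed):
    """Every accepted split's Q*_B equals the maximum over the brute-force
    enumeration of (parent, moderator, rule) triples at that step."""
    from conftest import random_dataset
    data, _ = random_dataset(seed + 20, K=12, M=3, mtype=mtype)
    fast = grow_re(data)
    ref = _single_node_tree(data)
    codes, _, _, _ = data.encoded()
    for step, rec in zip(range(len(fast.split_order)), fast.re_path):
        best = best_split_re(data, ref)
        assert best is not None
        pid, rule, qb = best
        assert qb == pytest.approx(rec["qb_star"], abs=1e-7)
        parent = ref.nodes[pid]
        lm, rm = _apply_rule(codes, parent.members, rule)
        for sm in (lm, rm):
            ch = Node(id=len(ref.nodes), parent=pid, members=sm,
                      d_plus=fe_summary(data.d[sm], data.var[sm]),
                      q=within_q_fe(data.d[sm], data.var[sm]),
                      depth=parent.depth + 1)
            ref.nodes.append(ch)
            if parent.left is None:
                parent.left = ch.id
            else:
                parent.right = ch.id
        parent.rule = rule
        ref.split_order.append(pid)
    assert best_split_re(data, ref) is None


def test_grow_re_refit_consistency():
    """After each split, re-fitting the terminal partition reproduces the
    recorded whole-tree tau^2 and Q*_B."""
    from conftest import random_dataset
    data, _ = random_dataset(9, K=20, M=3, mtype="ordinal")
    tree = grow_re(data)
    assert len(tree.re_path) == len(tree.split_order)
    for s, rec in enumerate(tree.re_path):
        kept = tree.kept_for_prefix(s + 1)
        fit = re_partition_fit(data, tree.partition(kept))
        assert fit.q_between == pytest.approx(rec["qb_star"], abs=1e-7)
        assert fit.tau2 == pytest.approx(rec["tau2"], abs=1e-9)


def test_re_equals_fe_tree_when_tau2_zero_throughout():
    """Nearly homogeneous within-group effects keep the DL estimate at 0 at
    every step, making the sequential tree identical to the FE tree."""
    rng = np.random.default_rng(8)
    K = 16
    x1 = np.repeat([0, 1], 8)
    x2 = np.tile([0, 1], 8)
    d = 0.5 * x1 + 0.001 * rng.standard_normal(K)
    data = EffectSizeSet(d=d, var=np.full(K, 0.04),
                         X=pd.DataFrame({"x1": x1, "x2": x2}),
                         types={"x1": "binary", "x2": "binary"})
    fe = grow_fe(data)
    re = grow_re(data)
    assert all(step["tau2"] == 0.0 for step in re.re_path)
    assert len(fe.nodes) == len(re.nodes)
    fe_rules = sorted((n.id, n.rule.col, n.rule.threshold)
                      for n in fe.nodes if not n.is_leaf)
    re_rules = sorted((n.id, n.rule.col, n.rule.threshold)
                      for n in re.nodes if not n.is_leaf)
    # same set of nodes and rules; FE order is best-first on local gain,
    # RE order on global Q*_B, which coincide when tau2 = 0
    assert fe_rules == re_rules


def test_route_matches_training_membership():
    from conftest import random_dataset
    data, _ = random_dataset(13, K=25, M=3, mtype="nominal")
    tree = grow_fe(data)
    codes, _, _, _ = data.encoded()
    for k in range(data.K):
        leaf = tree.route(codes[k])
        assert k in tree.nodes[leaf].members
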