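"""Monte-Carlo evaluation harness.

Runs design cells of the synthetic-data generator through the tree fitter
and scores three success criteria per replication:

1. *Type I error* (null model A): a pruned tree with at least one split and
   a significant between-subgroups Q at alpha.
2. *Power* (models B-E): same indicator, i.e. any nontrivial significant
   tree regardless of which moderators it uses.
3. *Recovery*: the pruned tree's set of distinct splitting moderators
   equals the true moderator set exactly (no misses, no spurious picks).
   By default no significance requirement is attached (a switch adds one).

A weighted meta-regression with the true structure pre-specified serves as
the idealized comparator for recovery, and the single "medium" design cell
supports subgroup-estimate bias and 95%-CI coverage bookkeeping over
exactly-recovered two-split trees.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import EffectSizeSet
from .prune import MetaCartResult, fit_metacart_path, recommended_c
from .simulate import (
    DESIGN_LEVELS,
    SimDesign,
    TrueModel,
    _effective_side,
    gen_dataset,
)

__all__ = [
    "CellOutcome",
    "evaluate_criteria",
    "meta_regression",
    "metareg_recovery",
    "match_canonical_c",
    "run_cell",
    "sample_design_cells",
    "table2",
    "table3",
    "table4",
    "reproduce_tables",
]

log = logging.getLogger("metatree")


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------

def evaluate_criteria(result: MetaCartResult, truth: TrueModel,
                      require_significance: bool = False):
    """Indicator triple (criterion1, criterion2, criterion3).

    Criteria 1 and 2 are the same indicator read under the null (model A)
    and the alternative respectively: a nontrivial pruned tree whose
    between-subgroups Q test is significant.  Criterion 3 compares the set
    of moderators the pruned tree splits on with the true set; with
    ``require_significance`` the tree must also test significant.
    """
    signif = int(result.significant)
    used = result.moderators_used
    recovered = int(
        result.size > 1
        and used == set(truth.true_mods)
        and (not require_significance or result.significant)
    )
    return signif, signif, recovered


# ---------------------------------------------------------------------------
# meta-regression comparator
# ---------------------------------------------------------------------------

def _true_terms(truth: TrueModel, X: pd.DataFrame):
    """Indicator regressors encoding the true subgroup structure."""
    e = [_effective_side(X[c], truth.mtype).astype(float)
         for c in truth.true_mods]
    m = truth.model
    if m == "B":
        return [e[0]]
    if m == "C":
        return [e[0] * e[1]]
    if m == "D":
        return [e[0] * e[1], (1.0 - e[0]) * e[2]]
    if m == "E":
        return [e[0] * e[1] * e[2]]
    raise ValueError("meta-regression comparison needs a nontrivial model (B-E)")


def meta_regression(d, var, Z, model: str = "FE"):
    """Weighted meta-regression with meta-analytic (z-based) inference.

    ``Z`` is the design matrix including the intercept.  FE: weights 1/var,
    coefficient covariance (Z' W Z)^-1.  RE: DerSimonian-Laird residual
    tau^2 from the FE fit, tau^2 = max(0, (Q_E - (K - p)) / tr(P)) with
    P = W - W Z (Z'WZ)^-1 Z' W, then weights 1/(var + tau^2).  Returns
    (beta, se, pvalues, tau2).
    """
    d = np.asarray(d, dtype=float)
    var = np.asarray(var, dtype=float)
    Z = np.asarray(Z, dtype=float)
    K, p = Z.shape

    def _wls(w):
        Xw = Z * w[:, None]
        A = Z.T @ Xw
        cov = np.linalg.inv(A)
        beta = cov @ (Xw.T @ d)
        return beta, cov

    w = 1.0 / var
    beta, cov = _wls(w)
    tau2 = 0.0
    if model == "RE":
        resid = d - Z @ beta
        qe = float(np.sum(w * resid * resid))
        Xw = Z * w[:, None]
        P_trace = float(np.sum(w) - np.trace(np.linalg.inv(Z.T @ Xw) @ (Xw.T @ Xw)))
        tau2 = max(0.0, (qe - (K - p)) / P_trace)
        beta, cov = _wls(1.0 / (var + tau2))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvalues = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, pvalues, tau2


def metareg_recovery(data: EffectSizeSet, truth: TrueModel,
                     assumption: str = "FE", alpha: float = 0.05) -> int:
    """1 iff every true structural term is significant in meta-regression.

    The true effective-subgroup predicates are encoded as indicator
    regressors (intercept plus one term per interaction branch), the
    idealized analysis a researcher could run if the structure were known.
    A singular design (e.g. a predicate with no studies on one side) counts
    as a failed recovery, with a warning.
    """
    terms = _true_terms(truth, data.X)
    Z = np.column_stack([np.ones(data.K)] + terms)
    try:
        _, _, pvalues, _ = meta_regression(data.d, data.var, Z, assumption)
    except np.linalg.LinAlgError:
        warnings.warn("singular meta-regression design; recovery scored 0",
                      RuntimeWarning, stacklevel=2)
        return 0
    return int(np.all(pvalues[1:] < alpha))


# ---------------------------------------------------------------------------
# canonical two-split tree matching (subgroup-estimate bookkeeping)
# ---------------------------------------------------------------------------

def match_canonical_c(result: MetaCartResult, data: EffectSizeSet,
                      truth: TrueModel):
    """Match a pruned tree against the canonical two-way interaction shape.

    The canonical shape splits the root on the first true moderator,
    then splits the first moderator's effective side on the second true
    moderator, giving three subgroups: (1) x1 ineffective, (2) x1 effective
    but x2 ineffective, (3) both effective (true mean delta_I).  Trees that
    pick the same subgroups with the reversed split order are *not*
    matched, so subgroup summaries stay comparable across replications.

    Returns (means, ci) arrays ordered subgroup 1..3, or None.
    """
    if truth.model != "C" or result.size != 3:
        return None
    tree = result.tree
    kept = result.kept
    if 0 not in kept or len(kept) != 2:
        return None
    child_id = next(nid for nid in kept if nid != 0)
    child = tree.nodes[child_id]
    if child.parent != 0:
        return None
    if tree.root.rule.col != truth.true_mods[0]:
        return None
    if child.rule.col != truth.true_mods[1]:
        return None
    e1 = _effective_side(data.X[truth.true_mods[0]], truth.mtype)
    e2 = _effective_side(data.X[truth.true_mods[1]], truth.mtype)
    targets = [
        frozenset(np.flatnonzero(~e1).tolist()),
        frozenset(np.flatnonzero(e1 & ~e2).tolist()),
        frozenset(np.flatnonzero(e1 & e2).tolist()),
    ]
    leaves = result.leaf_ids
    leaf_sets = {nid: frozenset(tree.nodes[nid].members.tolist())
                 for nid in leaves}
    order = []
    for tgt in targets:
        hit = [nid for nid, s in leaf_sets.items() if s == tgt]
        if len(hit) != 1:
            return None
        order.append(hit[0])
    idx = [leaves.index(nid) for nid in order]
    ci = result.ci(0.95)
    return result.fit.means[idx], ci[idx]


# ---------------------------------------------------------------------------
# cell runner
# ---------------------------------------------------------------------------

@dataclass
class CellOutcome:
    """Monte-Carlo proportions for one design cell and pruning parameter."""

    design: SimDesign
    model: str                     # FE | RE
    c: float
    reps: int
    p_signif: float                # criteria 1/2 proportion
    p_recovery: float              # criterion 3 proportion
    p_metareg: float | None = None
    n_matched: int = 0             # canonical trees found (model C only)
    subgroup_means: np.ndarray | None = None
    subgroup_sds: np.ndarray | None = None
    coverage: np.ndarray | None = None
    failures: int = 0

    @property
    def se_signif(self) -> float:
        return float(np.sqrt(self.p_signif * (1 - self.p_signif) / self.reps))

    @property
    def se_recovery(self) -> float:
        return float(np.sqrt(self.p_recovery * (1 - self.p_recovery) / self.reps))


def _rep_seeds(base_seed: int, rep: int):
    """Independent child seeds for one replication (order-independent)."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(rep,))
    s_data, s_cv = ss.spawn(2)
    cv_seed = int(s_cv.generate_state(1)[0] % (2 ** 31))
    return s_data, cv_seed


def run_cell(design: SimDesign, model: str, reps: int, base_seed: int,
             cs=(None,), alpha: float = 0.05, folds: int = 10,
             coverage: bool = False, metareg: bool = False):
    """Run one design cell; returns one :class:`CellOutcome` per ``cs`` entry.

    Each replication draws a dataset from its own child seed, fits the tree
    once and prunes it at every requested c (None = recommended rule).
    Replication failures are logged and counted, never fatal.  Optional
    bookkeeping: meta-regression recovery, and subgroup means/CI coverage
    over canonically matched model-C trees.
    """
    n_c = len(cs)
    signif = np.zeros(n_c)
    recov = np.zeros(n_c)
    mreg = 0.0
    n_match = np.zeros(n_c, dtype=int)
    mean_sum = np.zeros((n_c, 3))
    mean_sq = np.zeros((n_c, 3))
    cover = np.zeros((n_c, 3))
    failures = 0
    for r in range(reps):
        s_data, cv_seed = _rep_seeds(base_seed, r)
        try:
            data, truth = gen_dataset(design, s_data)
            results = fit_metacart_path(data, model, cs, folds=folds,
                                        seed=cv_seed, alpha=alpha)
        except Exception:
            log.exception("replication %d of cell %s failed", r, design)
            failures += 1
            continue
        for i, res in enumerate(results):
            c1, c2, c3 = evaluate_criteria(res, truth)
            signif[i] += c1
            recov[i] += c3
            if coverage:
                m = match_canonical_c(res, data, truth)
                if m is not None:
                    means, ci = m
                    true_vals = np.array([0.0, 0.0, truth.deltaI])
                    n_match[i] += 1
                    mean_sum[i] += means
                    mean_sq[i] += means ** 2
                    cover[i] += ((ci[:, 0] <= true_vals)
                                 & (true_vals <= ci[:, 1]))
        if metareg and design.model != "A":
            mreg += metareg_recovery(data, truth, model, alpha)
    done = max(reps - failures, 1)
    out = []
    for i, c in enumerate(cs):
        c_eff = recommended_c(model, design.K) if c is None else float(c)
        kw = {}
        if coverage and n_match[i] > 0:
            mu = mean_sum[i] / n_match[i]
            var = mean_sq[i] / n_match[i] - mu ** 2
            kw = dict(
                n_matched=int(n_match[i]),
                subgroup_means=mu,
                subgroup_sds=np.sqrt(np.maximum(var, 0.0)),
                coverage=cover[i] / n_match[i],
            )
        out.append(CellOutcome(
            design=design, model=model, c=c_eff, reps=done,
            p_signif=signif[i] / done, p_recovery=recov[i] / done,
            p_metareg=(mreg / done) if metareg and design.model != "A" else None,
            failures=failures, **kw,
        ))
    return out


# ---------------------------------------------------------------------------
# design sampling and table reproduction
# ---------------------------------------------------------------------------

def sample_design_cells(n_cells: int, factors: dict, rng: np.random.Generator,
                        fixed: dict | None = None):
    """Balanced random sample of factorial cells.

    Each factor's levels are repeated to length ``n_cells`` and shuffled
    independently, so every marginal is (near-)exactly balanced while level
    combinations vary.  ``fixed`` entries are constant across cells.
    """
    cols = {}
    for name, levels in factors.items():
        reps = -(-n_cells // len(levels))
        arr = np.array((list(levels) * reps)[:n_cells], dtype=object)
        rng.shuffle(arr)
        cols[name] = arr
    cells = []
    for i in range(n_cells):
        kw = {name: cols[name][i] for name in cols}
        if fixed:
            kw.update(fixed)
        cells.append(kw)
    return cells


_NON_K_FACTORS = {
    "mtype": DESIGN_LEVELS["mtype"],
    "correlated": DESIGN_LEVELS["correlated"],
    "M": DESIGN_LEVELS["M"],
    "nbar": DESIGN_LEVELS["nbar"],
    "tau2": DESIGN_LEVELS["tau2"],
}


def table2(models=("FE", "RE"), Ks=(40, 80, 120), cs=(0.5, 1.0),
           n_cells: int = 24, reps: int = 100, base_seed: int = 0) -> pd.DataFrame:
    """Type I error of the tree fitter under the null (model A).

    For each (model, K) a balanced sample of the non-K design factors is
    run; the table reports the mean rejection proportion per pruning
    parameter, with the between-cell SD and the Monte-Carlo SE of the mean.
    """
    rows = []
    for model in models:
        for K in Ks:
            rng = np.random.default_rng(base_seed + 7919 * K)
            cells = sample_design_cells(n_cells, _NON_K_FACTORS, rng,
                                        fixed={"K": int(K), "model": "A",
                                               "deltaI": 0.5})
            props = {c: [] for c in cs}
            for ci_, kw in enumerate(cells):
                design = SimDesign(**{k: _cast(k, v) for k, v in kw.items()})
                outs = run_cell(design, model, reps,
                                base_seed + 104729 * K + ci_, cs=cs)
                for out in outs:
                    props[out.c].append(out.p_signif)
            for c in cs:
                p = np.asarray(props[c])
                rows.append({
                    "model": model, "K": K, "c": c,
                    "type1": p.mean(),
                    "between_cell_sd": p.std(ddof=1),
                    "mc_se": float(np.sqrt(p.mean() * (1 - p.mean())
                                           / (len(p) * reps))),
                    "n_cells": len(p), "reps_per_cell": reps,
                })
    return pd.DataFrame(rows)


def _cast(key, val):
    casts = {"K": int, "M": int, "nbar": float, "tau2": float,
             "deltaI": float, "correlated": bool, "mtype": str, "model": str}
    return casts[key](val)


def table3(models=("FE",), tree_models=("B",), n_cells: int = 24,
           reps: int = 50, base_seed: int = 0) -> pd.DataFrame:
    """Recovery of the tree fitter vs. true-structure meta-regression.

    Balanced sample over the full design (including K and delta_I); the
    tree uses the recommended K-dependent pruning rule; the meta-regression
    comparator gets the true structure pre-specified.
    """
    factors = dict(_NON_K_FACTORS)
    factors["K"] = DESIGN_LEVELS["K"]
    factors["deltaI"] = DESIGN_LEVELS["deltaI"]
    rows = []
    for model in models:
        for tm in tree_models:
            rng = np.random.default_rng(base_seed + sum(ord(ch) for ch in tm))
            cells = sample_design_cells(n_cells, factors, rng,
                                        fixed={"model": tm})
            rec_tree, rec_reg = [], []
            for ci_, kw in enumerate(cells):
                design = SimDesign(**{k: _cast(k, v) for k, v in kw.items()})
                out = run_cell(design, model, reps, base_seed + 13 * ci_ + 1,
                               cs=(None,), metareg=True)[0]
                rec_tree.append(out.p_recovery)
                rec_reg.append(out.p_metareg)
            rt, rr = np.asarray(rec_tree), np.asarray(rec_reg)
            rows.append({
                "model": model, "tree": tm,
                "metacart": rt.mean(), "metacart_sd": rt.std(ddof=1),
                "metareg": rr.mean(), "metareg_sd": rr.std(ddof=1),
                "difference": rt.mean() - rr.mean(),
                "n_cells": len(cells), "reps_per_cell": reps,
            })
    return pd.DataFrame(rows)


#: the single "medium" design cell used for subgroup-estimate bookkeeping
MEDIUM_CELL = SimDesign(K=80, nbar=80.0, tau2=0.025, deltaI=0.5, M=10,
                        mtype="ordinal", correlated=True, model="C")


def table4(models=("FE", "RE"), reps: int = 1000, base_seed: int = 0) -> pd.DataFrame:
    """Subgroup-estimate bias and 95%-CI coverage in retrieved trees.

    Runs the medium design cell, keeps replications whose pruned tree
    matches the canonical two-way interaction shape exactly, and reports
    per-subgroup averaged estimates and CI coverage (true means 0, 0, 0.5).
    """
    rows = []
    for model in models:
        out = run_cell(MEDIUM_CELL, model, reps, base_seed, cs=(None,),
                       coverage=True)[0]
        for j in range(3):
            truth_val = [0.0, 0.0, MEDIUM_CELL.deltaI][j]
            rows.append({
                "model": model, "subgroup": j + 1, "true": truth_val,
                "estimate": None if out.subgroup_means is None
                else out.subgroup_means[j],
                "estimate_sd": None if out.subgroup_sds is None
                else out.subgroup_sds[j],
                "coverage": None if out.coverage is None else out.coverage[j],
                "n_matched": out.n_matched, "reps": out.reps,
            })
    return pd.DataFrame(rows)


def reproduce_tables(config: dict, base_seed: int = 0) -> dict:
    """Drive scaled table reproductions from a configuration mapping.

    ``config`` maps table names ("table2", "table3", "table4") to keyword
    dictionaries for the corresponding functions; returns name -> DataFrame.
    An empty config yields an empty dict.
    """
    runners = {"table2": table2, "table3": table3, "table4": table4}
    out = {}
    for name, kwargs in config.items():
        if name not in runners:
            raise ValueError(f"unknown table {name!r}")
        kwargs = dict(kwargs or {})
        kwargs.setdefault("base_seed", base_seed)
        out[name] = runners[name](**kwargs)
    return out
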