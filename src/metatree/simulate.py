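"""Synthetic meta-analytic data generator.

Emulates a Monte-Carlo design for studying moderator-detection methods:
five true tree structures of increasing complexity (A: no moderator effect;
B: one main effect; C: one two-way interaction; D: two two-way
interactions; E: one three-way interaction), four moderator types (binary,
nominal, ordinal, continuous), independent or correlated moderators, and
standardized-mean-difference effect sizes sampled through a noncentral
t-distribution.

Moderators are derived from latent multivariate normals: continuous columns
are N(20, 10^2) rounded to one decimal; binary columns dichotomize the
latent variable at its mean; three-level nominal/ordinal columns cut at the
1/3 and 2/3 population quantiles (nominal interval labels A/B/C are
randomly permuted per column, ordinal levels keep the interval order).

The "effective" side of a moderator is the side away from its lowest
category: binary -> level 1, ordinal -> levels {2, 3}, nominal -> labels
{B, C}, continuous -> value > 20 (the population mean).  Ineffective
subgroups have true mean 0; effective subgroups have mean delta_I.  True
per-study effects add N(0, sigma_tau^2) residual heterogeneity; observed
effects follow the two-group equal-allocation SMD sampling model with n
subjects *per arm*: t ~ noncentral-t(df = 2n-2, ncp = delta * sqrt(n/2)),
d = t * sqrt(2/n) (times the Hedges small-sample factor by default), with
sampling variance 2/n + d^2/(4n).

The per-arm reading of the average sample size and the ordinal/nominal
effective sides are calibrated against two closed-form fingerprints of the
reference results: the fixed-effect undercoverage 2*Phi(1.96*sqrt(v/(v +
tau^2))) - 1 = 0.834 at v = 2/80, tau^2 = 0.025, and the between-
replication SDs of the three subgroup estimates, which imply subgroup
sizes near 27/14/38 out of K = 80 (only a 2/3 effective side produces
them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import EffectSizeSet

__all__ = [
    "SimDesign",
    "TrueModel",
    "TRUE_MODELS",
    "gen_correlation",
    "gen_moderators",
    "true_subgroup_means",
    "sample_study_sizes",
    "sample_effects",
    "gen_dataset",
]

#: factorial levels of the reference design
DESIGN_LEVELS = {
    "K": (40, 80, 120),
    "nbar": (40, 80, 160),
    "tau2": (0.0, 0.025, 0.05),
    "deltaI": (0.3, 0.4, 0.5, 0.8),
    "M": (5, 10, 20),
    "mtype": ("binary", "nominal", "ordinal", "continuous"),
    "correlated": (False, True),
}

#: number of true moderators per tree model
_N_TRUE = {"A": 0, "B": 1, "C": 2, "D": 3, "E": 3}


@dataclass(frozen=True)
class SimDesign:
    """One cell of the factorial simulation design."""

    K: int = 80
    nbar: float = 80.0
    tau2: float = 0.025
    deltaI: float = 0.5
    M: int = 10
    mtype: str = "ordinal"
    correlated: bool = False
    model: str = "C"

    def __post_init__(self):
        if self.K < 4:
            raise ValueError("K must be >= 4")
        if self.tau2 < 0 or self.deltaI < 0:
            raise ValueError("tau2 and deltaI must be nonnegative")
        if self.mtype not in DESIGN_LEVELS["mtype"]:
            raise ValueError(f"unknown moderator type {self.mtype!r}")
        if self.model not in _N_TRUE:
            raise ValueError(f"unknown tree model {self.model!r}")
        if self.M < _N_TRUE[self.model]:
            raise ValueError("M smaller than the model's number of true moderators")


@dataclass(frozen=True)
class TrueModel:
    """Ground truth: which moderators act, and where the effect sits."""

    model: str
    true_mods: tuple          # column names of the true moderators
    mtype: str
    deltaI: float

    def effective(self, X: pd.DataFrame) -> np.ndarray:
        """Boolean vector: does each study fall in an effective subgroup."""
        e = {c: _effective_side(X[c], self.mtype) for c in self.true_mods}
        m = self.model
        if m == "A":
            return np.zeros(len(X), dtype=bool)
        if m == "B":
            return e[self.true_mods[0]]
        if m == "C":
            return e[self.true_mods[0]] & e[self.true_mods[1]]
        if m == "D":
            e1, e2, e3 = (e[c] for c in self.true_mods)
            return (e1 & e2) | (~e1 & e3)
        # E: three-way interaction
        e1, e2, e3 = (e[c] for c in self.true_mods)
        return e1 & e2 & e3

    def delta(self, X: pd.DataFrame) -> np.ndarray:
        """Per-study true subgroup mean (0 or deltaI)."""
        return np.where(self.effective(X), self.deltaI, 0.0)


def _effective_side(col: pd.Series, mtype: str) -> np.ndarray:
    if mtype == "binary":
        return col.to_numpy() == 1
    if mtype == "ordinal":
        return col.to_numpy() >= 2
    if mtype == "nominal":
        return col.to_numpy() != "A"
    return col.to_numpy(dtype=float) > 20.0


def TRUE_MODELS(model: str, M: int, mtype: str, deltaI: float) -> TrueModel:
    """Construct the ground truth for one tree model; x1.. are true."""
    n_true = _N_TRUE[model]
    return TrueModel(
        model=model,
        true_mods=tuple(f"x{i + 1}" for i in range(n_true)),
        mtype=mtype,
        deltaI=deltaI,
    )


def gen_correlation(M: int, rng: np.random.Generator) -> np.ndarray:
    """A positive-definite correlation matrix with entries in (-0.4, 0.4).

    A one-factor structure R = ll' + diag(1 - l^2) with loadings drawn
    uniformly on (-sqrt(0.4), sqrt(0.4)); PD by construction with
    off-diagonal magnitudes below 0.4, the range observed in real
    moderator data.
    """
    lam = rng.uniform(-np.sqrt(0.4), np.sqrt(0.4), size=M)
    R = np.outer(lam, lam)
    np.fill_diagonal(R, 1.0)
    return R


def gen_moderators(design: SimDesign, rng: np.random.Generator):
    """Moderator matrix for one dataset.

    Returns (X, types, ordinal_levels) ready for :class:`EffectSizeSet`.
    """
    K, M = design.K, design.M
    if design.correlated:
        R = gen_correlation(M, rng)
        L = np.linalg.cholesky(R)
        Z = rng.standard_normal((K, M)) @ L.T
    else:
        Z = rng.standard_normal((K, M))
    cols = {}
    types = {}
    ordinal_levels = {}
    lo, hi = stats.norm.ppf(1 / 3), stats.norm.ppf(2 / 3)
    for j in range(M):
        name = f"x{j + 1}"
        z = Z[:, j]
        if design.mtype == "continuous":
            cols[name] = np.round(20.0 + 10.0 * z, 1)
        elif design.mtype == "binary":
            cols[name] = (z > 0).astype(np.int64)
        elif design.mtype == "ordinal":
            cols[name] = 1 + (z > lo).astype(np.int64) + (z > hi).astype(np.int64)
            ordinal_levels[name] = [1, 2, 3]
        else:  # nominal: random A/B/C labelling of the three intervals
            interval = (z > lo).astype(np.int64) + (z > hi).astype(np.int64)
            labels = rng.permutation(np.array(["A", "B", "C"]))
            cols[name] = labels[interval]
        types[name] = design.mtype
    return pd.DataFrame(cols), types, ordinal_levels


def true_subgroup_means(model: TrueModel, X: pd.DataFrame, deltaI=None) -> np.ndarray:
    """Per-study true mean effect (0 in ineffective subgroups, delta_I else)."""
    for c in model.true_mods:
        if c not in X.columns:
            raise ValueError(f"true moderator {c!r} missing from X")
    if deltaI is None:
        return model.delta(X)
    return np.where(model.effective(X), deltaI, 0.0)


def sample_study_sizes(K: int, nbar: float, rng: np.random.Generator) -> np.ndarray:
    """Per-arm sample sizes n_k ~ N(nbar, (nbar/3)^2).

    Each study compares two arms of n_k subjects (total 2 n_k).  Rounded to
    the nearest integer and clamped below at 5 (10 subjects in total) so
    the noncentral-t sampling is well defined.
    """
    if nbar < 10:
        raise ValueError("nbar must be >= 10")
    n = np.round(rng.normal(nbar, nbar / 3.0, size=K))
    return np.maximum(n, 5).astype(np.int64)


def sample_effects(delta: np.ndarray, tau2: float, n: np.ndarray,
                   rng: np.random.Generator, hedges: bool = True):
    """Observed SMDs and sampling variances for true subgroup means.

    True study effects delta_k ~ N(Delta_k, tau2); with two arms of n
    subjects each the t-statistic is noncentral-t(df = 2n - 2,
    ncp = delta_k sqrt(n/2)) and the observed d is t sqrt(2/n), multiplied
    by the Hedges small-sample factor 1 - 3/(4 df - 1) when ``hedges`` (the
    default).  Sampling variance: 2/n + d^2/(4n).
    """
    delta = np.asarray(delta, dtype=float)
    n = np.asarray(n)
    true_delta = delta if tau2 == 0 else rng.normal(delta, np.sqrt(tau2))
    df = 2 * n - 2
    ncp = true_delta * np.sqrt(n / 2.0)
    t = stats.nct.rvs(df=df, nc=ncp, random_state=rng)
    d = t * np.sqrt(2.0 / n)
    if hedges:
        d = d * (1.0 - 3.0 / (4.0 * df - 1.0))
    var = 2.0 / n + d * d / (4.0 * n)
    return d, var


def gen_dataset(design: SimDesign, seed, hedges: bool = True):
    """One synthetic meta-analytic dataset plus its ground truth.

    Deterministic given ``seed``; returns (EffectSizeSet, TrueModel).
    """
    rng = np.random.default_rng(seed)
    X, types, ordinal_levels = gen_moderators(design, rng)
    truth = TRUE_MODELS(design.model, design.M, design.mtype, design.deltaI)
    delta = truth.delta(X)
    n = sample_study_sizes(design.K, design.nbar, rng)
    d, var = sample_effects(delta, design.tau2, n, rng, hedges=hedges)
    data = EffectSizeSet(d=d, var=var, X=X, types=types,
                         ordinal_levels=ordinal_levels)
    return data, truth
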