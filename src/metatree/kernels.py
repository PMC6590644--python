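"""Subgroup meta-analysis arithmetic.

Fixed-effect (FE) and random-effects (RE) machinery for a meta-analysis
partitioned into subgroups: inverse-variance weighted summaries, the
within/between/total Q-statistics, the pooled DerSimonian-Laird estimate of
residual heterogeneity, the chi-square significance test of a subgrouping,
and Wald confidence intervals for subgroup summary effects.

Under the FE model the observed effect of study k is d_k = delta + eps_k with
sampling variance var_k, and the weighted sums of squares decompose as
Q_T = sum_j Q_j + Q_B.  Under the RE model used here -- fixed effect across
subgroups, random effects within -- a single residual-heterogeneity variance
tau^2 is pooled across subgroups by the DerSimonian-Laird moment estimator
and all RE quantities (d*_j+, Q*_j, Q*_T, Q*_B = Q*_T - sum Q*_j) use the
weights 1/(var_k + tau^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import EffectSizeSet, SubgroupPartition

__all__ = [
    "SubgroupFit",
    "fe_summary",
    "within_q_fe",
    "fe_partition_fit",
    "pooled_dl_tau2",
    "re_partition_fit",
    "qb_test",
    "subgroup_ci",
]


@dataclass
class SubgroupFit:
    """Summary of a subgroup meta-analysis of one partition.

    ``model`` is "FE" or "RE".  For FE fits ``tau2`` is exactly 0 and the
    starred RE quantities coincide with their FE counterparts.
    """

    model: str
    J: int
    sizes: np.ndarray          # studies per subgroup
    means: np.ndarray          # d_j+ (FE) or d*_j+ (RE)
    q_within: np.ndarray       # Q_j or Q*_j
    q_between: float           # Q_B or Q*_B
    q_total: float             # Q_T or Q*_T
    grand_mean: float          # d_++ or d*_++
    tau2: float                # pooled residual heterogeneity (0 for FE)
    df: int                    # J - 1
    pvalue: float | None       # chi-square test of Q_B; None when J == 1
    weight_sums: np.ndarray    # per-subgroup sum of (FE or RE) weights

    def ci(self, level: float = 0.95) -> np.ndarray:
        """Per-subgroup Wald confidence intervals, shape (J, 2)."""
        return subgroup_ci(self, level)


def _check_dv(d, var):
    d = np.asarray(d, dtype=float)
    var = np.asarray(var, dtype=float)
    if d.size == 0:
        raise ValueError("empty effect-size vector")
    if d.shape != var.shape:
        raise ValueError("d and var must have the same shape")
    if np.any(var <= 0):
        raise ValueError("sampling variances must be strictly positive")
    return d, var


def fe_summary(d, var) -> float:
    """Fixed-effect summary effect: inverse-variance weighted mean.

    This equals the weighted node mean used as the prediction of a
    fixed-effect meta-analytic regression tree node.
    """
    d, var = _check_dv(d, var)
    w = 1.0 / var
    return float(np.sum(w * d) / np.sum(w))


def within_q_fe(d, var) -> float:
    """Within-group heterogeneity Q = sum_k (d_k - d_+)^2 / var_k.

    Identical to the FE-weighted within-node sum of squares (the tree
    impurity), and zero iff all effect sizes are equal.
    """
    d, var = _check_dv(d, var)
    w = 1.0 / var
    mean = np.sum(w * d) / np.sum(w)
    return float(np.sum(w * (d - mean) ** 2))


def _group_sums(d, w, assignment, J):
    """Per-subgroup sums of w, w*d, w*d^2 (vectorised)."""
    s0 = np.bincount(assignment, weights=w, minlength=J)
    s1 = np.bincount(assignment, weights=w * d, minlength=J)
    s2 = np.bincount(assignment, weights=w * d * d, minlength=J)
    return s0, s1, s2


def fe_partition_fit(data: EffectSizeSet, part: SubgroupPartition) -> SubgroupFit:
    """Fixed-effect subgroup meta-analysis of a partition.

    Returns per-subgroup Q_j, the between-subgroups Q_B, the total Q_T and
    the grand weighted mean d_++; the identity Q_T = sum Q_j + Q_B holds to
    numerical tolerance.
    """
    a = part.assignment
    if len(a) != data.K:
        raise ValueError("partition does not match dataset")
    w = data.w_fe
    s0, s1, s2 = _group_sums(data.d, w, a, part.J)
    means = s1 / s0
    q_within = s2 - s1 * s1 / s0
    q_within = np.maximum(q_within, 0.0)  # guard tiny negative roundoff
    tot0, tot1, tot2 = s0.sum(), s1.sum(), s2.sum()
    grand = tot1 / tot0
    q_total = max(tot2 - tot1 * tot1 / tot0, 0.0)
    q_between = float(np.sum(s0 * (means - grand) ** 2))
    sizes = np.bincount(a, minlength=part.J)
    pval = qb_test(q_between, part.J) if part.J >= 2 else None
    return SubgroupFit(
        model="FE", J=part.J, sizes=sizes, means=means, q_within=q_within,
        q_between=q_between, q_total=float(q_total), grand_mean=float(grand),
        tau2=0.0, df=part.J - 1, pvalue=pval, weight_sums=s0,
    )


def pooled_dl_tau2(data: EffectSizeSet, part: SubgroupPartition) -> float:
    """Pooled DerSimonian-Laird residual heterogeneity across subgroups.

    tau^2 = max(0, (sum_j Q_j - sum_j (K_j - 1)) / sum_j C_j) with FE weights
    w, where C_j = sum w - (sum w^2)/(sum w) within subgroup j.  Truncated at
    zero.  A partition of all-singleton subgroups carries no information
    about heterogeneity (every C_j = 0): returns 0 with a warning so that
    tree growth down to minimum node size never aborts.
    """
    a = part.assignment
    w = data.w_fe
    s0, s1, s2 = _group_sums(data.d, w, a, part.J)
    q_within = np.maximum(s2 - s1 * s1 / s0, 0.0)
    sizes = np.bincount(a, minlength=part.J)
    w2sum = np.bincount(a, weights=w * w, minlength=part.J)
    c = s0 - w2sum / s0
    denom = float(c.sum())
    if denom <= 0.0:
        warnings.warn(
            "all subgroups are singletons; residual heterogeneity is not "
            "estimable and is set to 0", RuntimeWarning, stacklevel=2,
        )
        return 0.0
    num = float(q_within.sum() - (sizes - 1).sum())
    return max(0.0, num / denom)


def re_partition_fit(data: EffectSizeSet, part: SubgroupPartition) -> SubgroupFit:
    """Random-effects subgroup meta-analysis with pooled DL heterogeneity.

    Estimates tau^2 by :func:`pooled_dl_tau2`, then computes all starred
    quantities with weights 1/(var + tau^2).  When the DL estimate is 0 the
    result coincides exactly with :func:`fe_partition_fit` (up to the model
    tag and tau2 field).
    """
    tau2 = pooled_dl_tau2(data, part)
    a = part.assignment
    w = 1.0 / (data.var + tau2)
    s0, s1, s2 = _group_sums(data.d, w, a, part.J)
    means = s1 / s0
    q_within = np.maximum(s2 - s1 * s1 / s0, 0.0)
    tot0, tot1, tot2 = s0.sum(), s1.sum(), s2.sum()
    grand = tot1 / tot0
    q_total = max(tot2 - tot1 * tot1 / tot0, 0.0)
    # Q*_T - sum Q*_j equals the direct between-group sum of squares; the
    # direct form is used so a tau2 = 0 fit matches the FE fit bit-for-bit
    q_between = float(np.sum(s0 * (means - grand) ** 2))
    sizes = np.bincount(a, minlength=part.J)
    pval = qb_test(q_between, part.J) if part.J >= 2 else None
    return SubgroupFit(
        model="RE", J=part.J, sizes=sizes, means=means, q_within=q_within,
        q_between=q_between, q_total=float(q_total), grand_mean=float(grand),
        tau2=float(tau2), df=part.J - 1, pvalue=pval, weight_sums=s0,
    )


def qb_test(q_between: float, J: int) -> float:
    """Upper-tail chi-square p-value of the between-subgroups Q-statistic.

    Reference distribution chi^2 with J - 1 degrees of freedom.
    """
    if J < 2:
        raise ValueError("the between-subgroups test requires J >= 2")
    if q_between < 0:
        raise ValueError("Q_B must be nonnegative")
    return float(stats.chi2.sf(q_between, J - 1))


def subgroup_ci(fit: SubgroupFit, level: float = 0.95) -> np.ndarray:
    """Normal-theory Wald intervals d_j+ +/- z * sqrt(1 / sum of weights).

    FE fits use FE weights; RE fits use RE weights with the pooled tau^2
    (so RE intervals are never narrower than FE ones on the same data).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(1.0 / fit.weight_sums)
    return np.column_stack([fit.means - half, fit.means + half])
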