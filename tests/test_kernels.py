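"""Subgroup meta-analysis arithmetic: hand values, invariants, oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metatree import (
    EffectSizeSet,
    SubgroupPartition,
    fe_partition_fit,
    fe_summary,
    pooled_dl_tau2,
    qb_test,
    re_partition_fit,
    subgroup_ci,
    within_q_fe,
)
from conftest import one_group


@pytest.mark.parametrize("d, var, expected", [
    ([0.5], [0.1], 0.5),                      # single study
    ([0.0, 1.0], [0.04, 0.04], 0.5),          # symmetric equal weights
    ([0.2, 0.5, 0.8], [0.04] * 3, 0.5),       # hand-evaluated weighted mean
    ([0.0, 1.0], [0.01, 0.04], 0.2),          # unequal weights: (100*0+25*1)/125
])
def test_fe_summary(d, var, expected):
    assert fe_summary(d, var) == pytest.approx(expected)


@pytest.mark.parametrize("d, var, expected", [
    ([0.5], [0.1], 0.0),
    ([0.0, 1.0], [0.04, 0.04], 12.5),
    ([0.2, 0.5, 0.8], [0.04] * 3, 4.5),
])
def test_within_q(d, var, expected):
    assert within_q_fe(d, var) == pytest.approx(expected)


@pytest.mark.parametrize("bad", [([], []), ([0.1], [0.0]), ([0.1], [-1.0])])
def test_input_validation(bad):
    with pytest.raises(ValueError):
        fe_summary(*bad)


def test_fe_partition_decomposition(toy4):
    part = SubgroupPartition([0, 0, 1, 1], 2)
    fit = fe_partition_fit(toy4, part)
    assert fit.q_between == pytest.approx(6.25)
    assert fit.q_within.sum() == pytest.approx(0.25)
    assert fit.q_total == pytest.approx(6.5)
    assert fit.grand_mean == pytest.approx(0.4)
    assert fit.pvalue == pytest.approx(0.012419, abs=1e-5)


def test_single_group_has_zero_qb(toy4):
    fit = fe_partition_fit(toy4, one_group(toy4))
    assert fit.q_between == pytest.approx(0.0)
    assert fit.q_total == pytest.approx(fit.q_within[0])
    assert fit.pvalue is None


def test_constant_effects_zero_q():
    data = EffectSizeSet(d=[0.3] * 4, var=[0.05] * 4,
                         X=pd.DataFrame({"x": [0, 1, 0, 1]}),
                         types={"x": "binary"})
    fit = fe_partition_fit(data, SubgroupPartition([0, 1, 0, 1], 2))
    assert fit.q_between == pytest.approx(0.0, abs=1e-12)
    assert fit.q_total == pytest.approx(0.0, abs=1e-12)


def test_dl_tau2_hand_value(pair):
    # Q = 12.5, df = 1, C = 50 - (2*625)/50 = 25 -> (12.5-1)/25 = 0.46
    assert pooled_dl_tau2(pair, one_group(pair)) == pytest.approx(0.46)


def test_dl_tau2_truncation():
    data = EffectSizeSet(d=[0.50, 0.51], var=[0.04, 0.04],
                         X=pd.DataFrame({"x": [0, 1]}), types={"x": "binary"})
    assert pooled_dl_tau2(data, one_group(data)) == 0.0


def test_dl_tau2_all_singletons_warns(toy4):
    part = SubgroupPartition([0, 1, 2, 3], 4)
    with pytest.warns(RuntimeWarning):
        assert pooled_dl_tau2(toy4, part) == 0.0


def test_re_fit_hand_values(pair):
    fit = re_partition_fit(pair, one_group(pair))
    assert fit.tau2 == pytest.approx(0.46)
    assert fit.weight_sums[0] == pytest.approx(4.0)     # w* = 2 each
    assert fit.means[0] == pytest.approx(0.5)
    assert fit.q_within[0] == pytest.approx(1.0)


def test_re_equals_fe_when_tau2_zero():
    # heterogeneity below expectation -> DL truncates to 0 -> identical fits
    data = EffectSizeSet(d=[0.30, 0.31, 0.70, 0.71], var=[0.04] * 4,
                         X=pd.DataFrame({"x": [0, 0, 1, 1]}),
                         types={"x": "binary"})
    part = SubgroupPartition([0, 0, 1, 1], 2)
    fe = fe_partition_fit(data, part)
    re = re_partition_fit(data, part)
    assert re.tau2 == 0.0
    assert np.array_equal(re.means, fe.means)
    assert re.q_between == fe.q_between
    assert re.q_total == fe.q_total


@pytest.mark.parametrize("qb, J, expected", [
    (0.0, 2, 1.0),
    (6.25, 2, 0.012419),
    (40.59, 3, None),  # large interaction: p < 0.001
])
def test_qb_test(qb, J, expected):
    p = qb_test(qb, J)
    if expected is None:
        assert p < 0.001
    else:
        assert p == pytest.approx(expected, abs=1e-5)


def test_qb_test_requires_two_groups():
    with pytest.raises(ValueError):
        qb_test(1.0, 1)


def test_ci_closed_form(pair):
    fit = fe_partition_fit(pair, one_group(pair))
    lo, hi = subgroup_ci(fit, 0.95)[0]
    half = 1.959964 * np.sqrt(1.0 / 50.0)
    assert lo == pytest.approx(0.5 - half, abs=1e-5)
    assert hi == pytest.approx(0.5 + half, abs=1e-5)


def test_re_ci_wider_when_heterogeneous(pair):
    part = one_group(pair)
    fe = fe_partition_fit(pair, part)
    re = re_partition_fit(pair, part)
    w_fe = np.diff(subgroup_ci(fe, 0.95))[0]
    w_re = np.diff(subgroup_ci(re, 0.95))[0]
    assert re.tau2 > 0
    assert w_re > w_fe


def test_ci_level_validation(pair):
    fit = fe_partition_fit(pair, one_group(pair))
    with pytest.raises(ValueError):
        subgroup_ci(fit, 1.5)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

@settings(max_examples=50, deadline=None)
@given(st.integers(0, 10 ** 6), st.integers(5, 25), st.integers(1, 4))
def test_q_additivity_random_partitions(seed, K, J):
    """Q_T = sum_j Q_j + Q_B for arbitrary partitions (FE), and the RE
    analogue holds by construction."""
    rng = np.random.default_rng(seed)
    d = rng.normal(0.3, 0.5, K)
    var = rng.uniform(0.01, 0.3, K)
    assignment = rng.integers(0, J, K)
    _, assignment = np.unique(assignment, return_inverse=True)
    part = SubgroupPartition(assignment, int(assignment.max()) + 1)
    data = EffectSizeSet(d=d, var=var,
                         X=pd.DataFrame({"x": np.zeros(K)}),
                         types={"x": "continuous"})
    fe = fe_partition_fit(data, part)
    assert fe.q_total == pytest.approx(fe.q_within.sum() + fe.q_between,
                                       rel=1e-8, abs=1e-10)
    re = re_partition_fit(data, part)
    assert re.tau2 >= 0.0
    assert re.q_total == pytest.approx(re.q_within.sum() + re.q_between,
                                       rel=1e-8, abs=1e-10)


def test_null_chi2_calibration():
    """Under homogeneity, Q_T ~ chi2(K-1): empirical rejection at the 0.05
    critical value stays within 3 Monte-Carlo SEs."""
    rng = np.random.default_rng(42)
    K, reps = 12, 4000
    var = rng.uniform(0.02, 0.2, size=(reps, K))
    d = 0.4 + rng.standard_normal((reps, K)) * np.sqrt(var)
    w = 1.0 / var
    mean = (w * d).sum(axis=1) / w.sum(axis=1)
    qt = (w * (d - mean[:, None]) ** 2).sum(axis=1)
    from scipy import stats as ss
    reject = (qt > ss.chi2.ppf(0.95, K - 1)).mean()
    tol = 3 * np.sqrt(0.05 * 0.95 / reps)
    assert abs(reject - 0.05) < tol


def test_dl_tau2_matches_metafor(tmp_path):
    """Pooled DL heterogeneity and within-Q agree with metafor's rma
    (a categorical-moderator DL fit is algebraically the pooled estimator)."""
    import subprocess
    rng = np.random.default_rng(3)
    K = 16
    d = rng.normal(0.3, 0.4, K)
    var = rng.uniform(0.02, 0.2, K)
    g = np.array([0] * 6 + [1] * 5 + [2] * 5)
    data = EffectSizeSet(d=d, var=var, X=pd.DataFrame({"g": g}),
                         types={"g": "nominal"})
    part = SubgroupPartition(g, 3)
    tau2 = pooled_dl_tau2(data, part)
    fit = re_partition_fit(data, part)

    df = pd.DataFrame({"yi": d, "vi": var, "g": g})
    csv = tmp_path / "dat.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "oracle.R"
    script.write_text(
        'dat <- read.csv("%s")\n'
        'suppressMessages(library(metafor))\n'
        'fit <- rma(yi, vi, mods=~factor(g)-1, data=dat, method="DL")\n'
        'cat(fit$tau2, fit$QE, sep="\\n")\n' % csv
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, check=True)
    tau2_r, qe_r = map(float, out.stdout.split())
    assert tau2 == pytest.approx(tau2_r, rel=1e-6)
    # metafor's QE is the FE-weight residual Q = sum of within-subgroup Q_j
    assert fe_partition_fit(data, part).q_within.sum() == pytest.approx(
        qe_r, rel=1e-6)
    assert fit.tau2 == tau2
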