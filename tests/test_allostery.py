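import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dmsallo.allostery import (
    DISRUPTING,
    ENHANCING,
    NOT_SIGNIFICANT,
    allosteric_effect,
    classify,
    heatmap_matrix,
    sgof,
    welch_test,
    welch_test_matrix,
)
from dmsallo.fitness import MEASURED, NO_DATA, NULL_DATA


def test_effect_examples():
    d, f = allosteric_effect([-0.05, -0.05, -0.05], [-0.10, -0.10, -0.10])
    assert d == pytest.approx(0.05)
    assert f == pytest.approx(math.exp(0.05))
    d0, f0 = allosteric_effect([0.1, 0.2], [0.1, 0.2])
    assert d0 == 0.0 and f0 == 1.0
    d_nan, _ = allosteric_effect([0.1], [0.1, 0.2])  # insufficient replicates
    assert math.isnan(d_nan)


def test_welch_against_closed_form_and_scipy():
    a = np.array([0.0, 0.01, -0.01])
    b = np.array([0.5, 0.51, 0.49])
    p = welch_test(a, b)
    # independent closed-form Welch computation
    sa, sb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / 2 + sb**2 / 2)
    p_manual = 2 * stats.t.sf(abs(t), df)
    assert p == pytest.approx(p_manual, rel=1e-9)
    assert p < 0.001
    assert p == pytest.approx(
        stats.ttest_ind(a, b, equal_var=False).pvalue, rel=1e-12
    )


def test_welch_degenerate_conventions():
    assert welch_test([0.1, 0.1, 0.1], [0.1, 0.1, 0.1]) == 1.0
    assert welch_test([0.1, 0.1, 0.1], [0.2, 0.2, 0.2]) == 0.0
    assert math.isnan(welch_test([0.1], [0.2, 0.3]))


def test_welch_matrix_matches_scalar(rng):
    lit = rng.normal(0, 0.02, (40, 3))
    dark = rng.normal(0.01, 0.03, (40, 3))
    p_vec = welch_test_matrix(lit, dark)
    p_scalar = np.array([welch_test(lit[i], dark[i]) for i in range(40)])
    assert np.allclose(p_vec, p_scalar, rtol=1e-10)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-0.2, 0.2), min_size=3, max_size=3),
    st.lists(st.floats(-0.2, 0.2), min_size=3, max_size=3),
)
def test_antisymmetry_under_condition_swap(lit, dark):
    d1, _ = allosteric_effect(lit, dark)
    d2, _ = allosteric_effect(dark, lit)
    assert d1 == pytest.approx(-d2, abs=1e-15)
    assert welch_test(lit, dark) == pytest.approx(welch_test(dark, lit), rel=1e-12)


def _sgof_oracle(p_values, alpha=0.05, gamma=0.05):
    """Independent brute-force SGoF: count successive binomial tail tests."""
    p = sorted(p_values)
    n = len(p)
    r = sum(1 for x in p if x <= gamma)
    k = 0
    while r > 0:
        # exact one-sided binomial tail P(X >= r) by direct summation
        tail = sum(
            math.comb(n, i) * gamma**i * (1 - gamma) ** (n - i) for i in range(r, n + 1)
        )
        if tail > alpha:
            break
        k += 1
        r -= 1
    if k:
        k = sum(1 for x in p if x <= p[k - 1])  # all-or-none at tied boundary
    return k


def test_sgof_all_large_pvalues():
    res = sgof(np.full(200, 0.5))
    assert res.n_significant == 0 and res.p_star == 0.0


def test_sgof_strong_signal_matches_enumeration_oracle():
    p = np.concatenate([np.full(50, 1e-6), np.full(50, 0.9)])
    res = sgof(p)
    assert res.n_significant == _sgof_oracle(p) == 50
    assert res.p_star == pytest.approx(1e-6)


def test_sgof_moderate_signal_matches_enumeration_oracle(rng):
    p = np.concatenate([rng.uniform(0, 0.01, 30), rng.uniform(0, 1, 170)])
    res = sgof(p)
    assert res.n_significant == _sgof_oracle(p)
    declared = np.sort(p)[: res.n_significant]
    assert (declared <= res.p_star).all()  # declared set = smallest p-values


def test_sgof_adding_p_of_one_never_adds_discoveries(rng):
    p = rng.uniform(0, 0.2, 100)
    base = sgof(p).n_significant
    extended = sgof(np.append(p, 1.0)).n_significant
    assert extended <= base


def test_sgof_empty_and_invalid():
    assert sgof(np.array([])).n_significant == 0
    with pytest.raises(ValueError):
        sgof(np.array([-0.1, 0.5]))


def _growth_frame(rows):
    frame = pd.DataFrame(rows).set_index("variant")
    frame["status"] = MEASURED
    return frame


def test_classification_signs_and_summary():
    # 200 null variants plus strong effects of both signs; the SGoF
    # meta-test needs an excess of small p-values across the family
    rows = []
    rng = np.random.default_rng(5)
    for i in range(200):
        lit = rng.normal(-0.05, 0.005, 3)
        dark = rng.normal(-0.05, 0.005, 3)
        rows.append(dict(variant=f"A{i+1}C", lit_1=lit[0], lit_2=lit[1], lit_3=lit[2],
                         dark_1=dark[0], dark_2=dark[1], dark_3=dark[2],
                         lit_mean=lit.mean(), dark_mean=dark.mean()))
    strong = [("E154R", +0.05), ("W22H", -0.05)]
    for j in range(20):
        strong.append((f"G{j + 30}A", +0.05 if j % 2 else -0.05))
    for name, delta in strong:
        dark = rng.normal(-0.05, 0.001, 3)
        lit = dark + delta + rng.normal(0, 0.0005, 3)
        rows.append(dict(variant=name, lit_1=lit[0], lit_2=lit[1], lit_3=lit[2],
                         dark_1=dark[0], dark_2=dark[1], dark_3=dark[2],
                         lit_mean=lit.mean(), dark_mean=dark.mean()))
    records, summary = classify(_growth_frame(rows))
    declared = records[records["class"].isin([ENHANCING, DISRUPTING])]
    true_names = {name for name, _ in strong}
    assert len(declared) >= 10
    assert set(declared.index) <= true_names  # no false discoveries here
    assert (declared.loc[declared["class"] == ENHANCING, "delta"] > 0).all()
    assert (declared.loc[declared["class"] == DISRUPTING, "delta"] < 0).all()
    assert summary["n_enhancing"] >= 1 and summary["n_disrupting"] >= 1
    # declared set is exactly the smallest p-values
    assert declared["p_value"].max() <= records.loc[
        ~records.index.isin(declared.index), "p_value"
    ].min()
    assert (
        summary["n_enhancing"] + summary["n_disrupting"] + summary["n_not_significant"]
        == summary["n_tested"]
    )


def test_raw_mode_uses_fixed_threshold():
    rows = [dict(variant="M1A", lit_1=0.0, lit_2=0.001, lit_3=-0.001,
                 dark_1=-0.02, dark_2=-0.019, dark_3=-0.021,
                 lit_mean=0.0, dark_mean=-0.02)]
    records, summary = classify(_growth_frame(rows), mode="raw", raw_threshold=0.05)
    assert summary["threshold"] == 0.05
    assert records.loc["M1A", "class"] == ENHANCING


def test_heatmap_matrix_codes():
    wt = "MI"
    growth = pd.DataFrame(
        {"status": [MEASURED, NULL_DATA, NO_DATA]},
        index=["M1A", "M1C", "I2A"],
    )
    records = pd.DataFrame({"delta": [0.03]}, index=["M1A"])
    mat = heatmap_matrix(growth, records, wt)
    assert mat.loc[1, "A"] == pytest.approx(0.03)
    assert mat.loc[1, "C"] == -999.0
    assert mat.loc[2, "A"] == -1000.0
    assert math.isnan(mat.loc[1, "M"])  # wild-type identity cell
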