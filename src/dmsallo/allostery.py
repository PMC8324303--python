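"""Allosteric-effect statistics with Welch tests and SGoF control.

The allosteric effect of a mutation is the difference between its mean
lit and mean dark relative growth rates,

    delta = mean(rgr_lit) - mean(rgr_dark),

whose exponential ``exp(delta)`` approximates the fold change in the
lit/dark velocity ratio of the mutant relative to the unmutated
construct (growth rate is log-linear in enzyme velocity in the regime
of the assay).  Significance is assessed per mutation by Welch's
unequal-variance t-test on the replicate growth rates, and the family
of tests is controlled with the binomial Sequential Goodness of Fit
(SGoF) procedure, which declares the k smallest p-values significant
based on a one-sided binomial meta-test of how many p-values fall below
the initial threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ENHANCING = "enhancing"
DISRUPTING = "disrupting"
NOT_SIGNIFICANT = "not_significant"
EXCLUDED = "excluded"


def allosteric_effect(
    lit_rgrs: np.ndarray, dark_rgrs: np.ndarray
) -> tuple[float, float]:
    """Return ``(delta, exp(delta))`` for one mutation.

    Requires at least two finite replicate measurements per condition;
    otherwise both values are NaN (the mutation is excluded).
    """
    lit = np.asarray(lit_rgrs, dtype=float)
    dark = np.asarray(dark_rgrs, dtype=float)
    lit = lit[np.isfinite(lit)]
    dark = dark[np.isfinite(dark)]
    if len(lit) < 2 or len(dark) < 2:
        return math.nan, math.nan
    delta = float(np.mean(lit) - np.mean(dark))
    return delta, math.exp(delta)


def welch_test(lit_rgrs: np.ndarray, dark_rgrs: np.ndarray) -> float:
    """Two-sided Welch unequal-variance t-test p-value.

    Degenerate samples follow a documented convention: if both groups
    have zero variance the p-value is 1 for equal means and 0 for
    unequal means (the statistic diverges).
    """
    a = np.asarray(lit_rgrs, dtype=float)
    b = np.asarray(dark_rgrs, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return math.nan
    if np.all(a == a[0]) and np.all(b == b[0]):
        return 1.0 if a[0] == b[0] else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def welch_test_matrix(lit: np.ndarray, dark: np.ndarray) -> np.ndarray:
    """Vectorized Welch test over rows of two (n, k) replicate arrays."""
    lit = np.asarray(lit, dtype=float)
    dark = np.asarray(dark, dtype=float)
    na, nb = lit.shape[1], dark.shape[1]
    ma, mb = lit.mean(axis=1), dark.mean(axis=1)
    va, vb = lit.var(axis=1, ddof=1), dark.var(axis=1, ddof=1)
    sa, sb = va / na, vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = np.all(lit == lit[:, :1], axis=1) & np.all(dark == dark[:, :1], axis=1)
    p[degenerate] = np.where(lit[degenerate, 0] == dark[degenerate, 0], 1.0, 0.0)
    return p


@dataclass(frozen=True)
class SGoFResult:
    n_tests: int
    n_below_gamma: int
    n_significant: int
    p_star: float  # largest p-value declared significant (0 if none)
    alpha: float
    gamma: float

    def is_significant(self, p: np.ndarray) -> np.ndarray:
        if self.n_significant == 0:
            return np.zeros(np.shape(p), dtype=bool)
        return np.asarray(p) <= self.p_star


def sgof(p_values: np.ndarray, alpha: float = 0.05, gamma: float = 0.05) -> SGoFResult:
    """Binomial (exact) Sequential Goodness of Fit multiple testing.

    Let R be the number of p-values at or below ``gamma``.  While the
    one-sided exact binomial meta-test P(X >= R') with
    X ~ Binomial(n, gamma) is significant at ``alpha`` and R' > 0, one
    more of the smallest p-values is declared significant and R' is
    decremented.  Ties with the largest declared p-value are declared
    together (deterministic, inclusion-favouring), so the declared set
    is always the set of smallest p-values.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size and (p[0] < 0 or p[-1] > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return SGoFResult(0, 0, 0, 0.0, alpha, gamma)
    r = int(np.sum(p <= gamma))
    n_sig = 0
    r_current = r
    while r_current > 0 and stats.binom.sf(r_current - 1, n, gamma) <= alpha:
        n_sig += 1
        r_current -= 1
    if n_sig == 0:
        return SGoFResult(n, r, 0, 0.0, alpha, gamma)
    p_star = float(p[n_sig - 1])
    # ties at the boundary are declared together
    n_sig = int(np.sum(p <= p_star))
    return SGoFResult(n, r, n_sig, p_star, alpha, gamma)


def classify(
    growth: pd.DataFrame,
    alpha: float = 0.05,
    gamma: float = 0.05,
    mode: str = "sgof",
    raw_threshold: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Allostery classification for low-growth-filtered growth records.

    ``growth`` is the table from ``fitness.estimate_growth_rates`` after
    ``apply_low_growth_filter`` (replicate columns ``lit_1..k`` /
    ``dark_1..k``).  Returns a per-variant record table with columns
    ``delta``, ``fold``, ``p_value``, ``class`` plus a summary dict.

    ``mode='sgof'`` uses the SGoF-adjusted threshold; ``mode='raw'`` is
    the relaxed sensitivity analysis at ``raw_threshold``.
    """
    lit_cols = sorted(c for c in growth.columns if c.startswith("lit_") and c[4:].isdigit())
    dark_cols = sorted(c for c in growth.columns if c.startswith("dark_") and c[5:].isdigit())
    records = []
    for variant, row in growth.iterrows():
        lit = row[lit_cols].to_numpy(dtype=float)
        dark = row[dark_cols].to_numpy(dtype=float)
        delta, fold = allosteric_effect(lit, dark)
        p = welch_test(lit, dark)
        records.append(
            {"variant": variant, "delta": delta, "fold": fold, "p_value": p}
        )
    frame = pd.DataFrame(records).set_index("variant")

    valid = frame["p_value"].notna()
    pvals = frame.loc[valid, "p_value"].to_numpy()
    if mode == "sgof":
        result = sgof(pvals, alpha=alpha, gamma=gamma)
        threshold = result.p_star if result.n_significant else -1.0
    elif mode == "raw":
        result = None
        threshold = raw_threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")

    cls = pd.Series(EXCLUDED, index=frame.index, dtype=object)
    sig = valid & (frame["p_value"] <= threshold)
    cls[valid & ~sig] = NOT_SIGNIFICANT
    cls[sig & (frame["delta"] > 0)] = ENHANCING
    cls[sig & (frame["delta"] < 0)] = DISRUPTING
    frame["class"] = cls

    summary = {
        "n_tested": int(valid.sum()),
        "n_enhancing": int((cls == ENHANCING).sum()),
        "n_disrupting": int((cls == DISRUPTING).sum()),
        "n_not_significant": int((cls == NOT_SIGNIFICANT).sum()),
        "n_excluded": int((cls == EXCLUDED).sum()),
        "threshold": float(threshold),
        "mode": mode,
    }
    if result is not None:
        summary["sgof_n_below_gamma"] = result.n_below_gamma
    return frame, summary


def heatmap_matrix(
    growth: pd.DataFrame,
    records: pd.DataFrame,
    wt_protein: str,
) -> pd.DataFrame:
    """Positions x residues matrix of allosteric effects for plotting.

    Cells hold delta for measured variants; NaN for wild-type identity;
    -999 for null-data and -1000 for no-data variants, mirroring the
    source-data sentinel conventions.
    """
    from .fitness import NO_DATA, NULL_DATA, SENTINEL_NO_DATA, SENTINEL_NULL
    from .genetics import AA20
    from .library import VariantID

    n_pos = len(wt_protein)
    mat = pd.DataFrame(
        np.nan, index=range(1, n_pos + 1), columns=list(AA20), dtype=float
    )
    for variant, row in growth.iterrows():
        v = VariantID.from_name(str(variant))
        if row["status"] == NO_DATA:
            mat.loc[v.position, v.mut] = SENTINEL_NO_DATA
        elif row["status"] == NULL_DATA:
            mat.loc[v.position, v.mut] = SENTINEL_NULL
    for variant, row in records.iterrows():
        v = VariantID.from_name(str(variant))
        mat.loc[v.position, v.mut] = row["delta"]
    return mat
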