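"""Relative growth rates from allele-frequency trajectories.

For variant *a* with counts ``N_a`` and reference counts ``N_WT`` the
log-normalized frequency at time *t* is

    f_a(t) = ln(N_a / N_WT)_t - ln(N_a / N_WT)_{t=0}

so f_a(0) = 0 by construction.  The slope of an ordinary least-squares
fit of f_a against time is the relative growth rate (rgr, h^-1): the
difference between the variant's exponential growth rate and the
reference allele's.  A variant enters the fit for a replicate only if
it has more than 50 reads at t = 0 there; timepoints where either count
is zero are dropped (the log is undefined), and at least three usable
timepoints are required for a slope.

Variants are classified per the source-data conventions of the assay:

- ``no_data``  - absent or ineligible at t = 0 in one or more replicates
  (exported with the -1000 sentinel);
- ``null_data`` - eligible at t = 0 but depleted before three usable
  timepoints in some replicate (exported with -999);
- ``measured`` - a slope in every replicate of both conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CONDITIONS, REFERENCE

MEASURED = "measured"
NULL_DATA = "null_data"
NO_DATA = "no_data"

SENTINEL_NULL = -999.0
SENTINEL_NO_DATA = -1000.0

#: Strict read-support threshold at t = 0 for a usable trajectory.
MIN_T0_READS = 50

#: Empirical growth-rate viability cutoff: the relative growth rate of a
#: catalytically crippled active-site control; variants at or below it
#: in either condition are treated as (near-)inactive and excluded from
#: allostery analysis.
LOW_GROWTH_CUTOFF = -0.13


@dataclass(frozen=True)
class FrequencyTrajectory:
    variant: str
    condition: str
    replicate: int
    times_h: np.ndarray
    f: np.ndarray
    eligible: bool  # > MIN_T0_READS mutant reads at t = 0

    @property
    def n_points(self) -> int:
        return len(self.times_h)


def normalize_frequencies(
    counts: pd.DataFrame,
    reference: str = REFERENCE,
    min_t0_reads: int = MIN_T0_READS,
) -> list[FrequencyTrajectory]:
    """Build log-normalized frequency trajectories from a count table.

    ``counts`` is the long-format table produced by the simulator or
    the counting stage: columns ``condition, replicate, timepoint_h,
    variant, count`` with the reference allele present in every sample.
    """
    trajectories: list[FrequencyTrajectory] = []
    for (condition, replicate), group in counts.groupby(
        ["condition", "replicate"], sort=True
    ):
        pivot = group.pivot_table(
            index="variant", columns="timepoint_h", values="count", fill_value=0
        ).sort_index(axis=1)
        times = pivot.columns.to_numpy(dtype=float)
        if times[0] != 0:
            raise ValueError(
                f"replicate {condition}/{replicate} is missing the t=0 sample"
            )
        if reference not in pivot.index:
            raise ValueError(f"reference allele {reference!r} absent from counts")
        ref = pivot.loc[reference].to_numpy(dtype=float)
        if ref[0] <= 0:
            raise ValueError("reference count at t=0 must be positive")
        for variant, row in pivot.iterrows():
            if variant == reference:
                continue
            n = row.to_numpy(dtype=float)
            eligible = n[0] > min_t0_reads
            usable = (n > 0) & (ref > 0)
            t_use = times[usable]
            logratio = np.log(n[usable] / ref[usable])
            f = logratio - logratio[0] if usable[0] else np.array([])
            if not usable[0]:
                t_use = np.array([])
            trajectories.append(
                FrequencyTrajectory(
                    variant=str(variant),
                    condition=str(condition),
                    replicate=int(replicate),
                    times_h=t_use,
                    f=f,
                    eligible=bool(eligible and usable[0]),
                )
            )
    return trajectories


def fit_growth_rate(trajectory: FrequencyTrajectory) -> tuple[float, float, int]:
    """OLS slope (with intercept) of f against time.

    Returns ``(slope, stderr, n_points)``; fewer than three usable
    timepoints yields ``(nan, nan, n)``, the null-data signal.
    """
    n = trajectory.n_points
    if n < 3:
        return math.nan, math.nan, n
    res = stats.linregress(trajectory.times_h, trajectory.f)
    stderr = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    return float(res.slope), stderr, n


def classify_status(replicate_trajectories: list[FrequencyTrajectory]) -> str:
    """Status of one variant from its trajectories across all vials."""
    if any(not t.eligible for t in replicate_trajectories):
        return NO_DATA
    if any(t.n_points < 3 for t in replicate_trajectories):
        return NULL_DATA
    return MEASURED


def estimate_growth_rates(
    counts: pd.DataFrame,
    reference: str = REFERENCE,
    min_t0_reads: int = MIN_T0_READS,
    expected_variants: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variant growth-rate table across conditions and replicates.

    Returns a DataFrame indexed by variant with columns ``lit_1..k``,
    ``lit_mean``, ``lit_sd``, ``dark_1..k``, ``dark_mean``, ``dark_sd``
    and ``status``.  Variants listed in ``expected_variants`` but absent
    from the counts are included as ``no_data`` rows, so the three
    status categories partition the designed library.
    """
    trajectories = normalize_frequencies(counts, reference, min_t0_reads)
    by_variant: dict[str, list[FrequencyTrajectory]] = {}
    for t in trajectories:
        by_variant.setdefault(t.variant, []).append(t)

    n_reps = max((t.replicate for t in trajectories), default=0)
    rows = {}
    variants = list(by_variant)
    if expected_variants is not None:
        variants = list(expected_variants)
    for variant in variants:
        trajs = by_variant.get(variant, [])
        expected = len(CONDITIONS) * n_reps
        if len(trajs) < expected:
            status = NO_DATA  # absent from at least one sample at t = 0
        else:
            status = classify_status(trajs)
        row: dict[str, float | str] = {"status": status}
        for condition in CONDITIONS:
            slopes = []
            for rep in range(1, n_reps + 1):
                traj = next(
                    (
                        t
                        for t in trajs
                        if t.condition == condition and t.replicate == rep
                    ),
                    None,
                )
                slope = math.nan
                if status == MEASURED and traj is not None:
                    slope, _, _ = fit_growth_rate(traj)
                row[f"{condition}_{rep}"] = slope
                slopes.append(slope)
            arr = np.asarray(slopes, dtype=float)
            row[f"{condition}_mean"] = float(np.mean(arr)) if status == MEASURED else math.nan
            row[f"{condition}_sd"] = (
                float(np.std(arr, ddof=1)) if status == MEASURED and len(arr) > 1 else math.nan
            )
        rows[variant] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "variant"
    return frame


def apply_low_growth_filter(
    growth: pd.DataFrame, cutoff: float = LOW_GROWTH_CUTOFF
) -> tuple[pd.DataFrame, pd.Index]:
    """Drop near-inactive variants before allostery analysis.

    A variant is excluded when its status is not ``measured`` or its
    mean relative growth rate is at or below ``cutoff`` in either
    condition ("at or below": the boundary itself is excluded).
    Returns ``(retained, excluded_index)``.
    """
    measured = growth["status"] == MEASURED
    viable = (growth["lit_mean"] > cutoff) & (growth["dark_mean"] > cutoff)
    keep = measured & viable
    return growth[keep], growth.index[~keep]
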