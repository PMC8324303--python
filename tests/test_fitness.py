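import math

import numpy as np
import pandas as pd
import pytest

from dmsallo.fitness import (
    LOW_GROWTH_CUTOFF,
    MEASURED,
    NO_DATA,
    NULL_DATA,
    FrequencyTrajectory,
    apply_low_growth_filter,
    classify_status,
    estimate_growth_rates,
    fit_growth_rate,
    normalize_frequencies,
)

TIMES = [0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0]


def counts_frame(variant_counts, wt_counts, condition="dark", replicate=1):
    """Build a long count table for one replicate from per-time lists."""
    rows = []
    for t, wt in zip(TIMES[: len(wt_counts)], wt_counts):
        rows.append((condition, replicate, t, "WT", wt))
    for name, series in variant_counts.items():
        for t, n in zip(TIMES[: len(series)], series):
            rows.append((condition, replicate, t, name, n))
    return pd.DataFrame(
        rows, columns=["condition", "replicate", "timepoint_h", "variant", "count"]
    )


def test_constant_ratio_gives_zero_frequencies_and_slope():
    counts = counts_frame({"M1A": [200] * 7}, [1000] * 7)
    (traj,) = normalize_frequencies(counts)
    assert np.allclose(traj.f, 0.0)
    slope, stderr, n = fit_growth_rate(traj)
    assert slope == 0.0 and stderr == 0.0 and n == 7


def test_doubling_ratio_gives_ln2():
    counts = counts_frame({"M1A": [100, 200]}, [1000, 1000])
    (traj,) = normalize_frequencies(counts)
    assert traj.f[1] == pytest.approx(math.log(2.0))


def test_t0_read_threshold_is_strict():
    counts = counts_frame({"M1A": [50] * 7, "M1C": [51] * 7}, [1000] * 7)
    trajs = {t.variant: t for t in normalize_frequencies(counts)}
    assert not trajs["M1A"].eligible
    assert trajs["M1C"].eligible


def test_exact_line_recovers_slope():
    t = np.array(TIMES)
    traj = FrequencyTrajectory("M1A", "dark", 1, t, -0.1 * t, True)
    slope, stderr, n = fit_growth_rate(traj)
    assert slope == pytest.approx(-0.1, abs=1e-12)
    assert stderr == pytest.approx(0.0, abs=1e-12)


def test_two_timepoints_signal_null_data():
    traj = FrequencyTrajectory("M1A", "dark", 1, np.array([0.0, 4.0]),
                               np.array([0.0, -0.4]), True)
    slope, stderr, n = fit_growth_rate(traj)
    assert math.isnan(slope) and n == 2


def test_status_classification():
    full = FrequencyTrajectory("v", "dark", 1, np.array(TIMES), np.zeros(7), True)
    short = FrequencyTrajectory("v", "dark", 2, np.array([0.0, 4.0]),
                                np.zeros(2), True)
    absent = FrequencyTrajectory("v", "lit", 1, np.array([]), np.array([]), False)
    assert classify_status([full, full]) == MEASURED
    assert classify_status([full, short]) == NULL_DATA
    assert classify_status([full, absent]) == NO_DATA  # missing at t=0 anywhere


def test_missing_t0_sample_is_fatal():
    counts = counts_frame({"M1A": [100] * 7}, [1000] * 7)
    with pytest.raises(ValueError, match="t=0"):
        normalize_frequencies(counts[counts.timepoint_h > 0])


def test_variant_tracking_reference_has_zero_rate():
    # a variant whose counts are exactly proportional to the reference
    counts = counts_frame({"M1A": [300, 270, 240, 210, 180, 150, 120]},
                          [1000, 900, 800, 700, 600, 500, 400])
    (traj,) = normalize_frequencies(counts)
    slope, _, _ = fit_growth_rate(traj)
    assert slope == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "lit_mean,dark_mean,kept",
    [(0.0, 0.0, True), (0.0, -0.14, False), (0.0, -0.13, False), (-0.131, 0.0, False)],
)
def test_low_growth_filter_boundary(lit_mean, dark_mean, kept):
    growth = pd.DataFrame(
        {
            "lit_mean": [lit_mean],
            "dark_mean": [dark_mean],
            "status": [MEASURED],
        },
        index=["M1A"],
    )
    retained, excluded = apply_low_growth_filter(growth, LOW_GROWTH_CUTOFF)
    assert ("M1A" in retained.index) is kept


def test_non_measured_records_always_excluded():
    growth = pd.DataFrame(
        {
            "lit_mean": [0.0, 0.0],
            "dark_mean": [0.0, 0.0],
            "status": [NULL_DATA, NO_DATA],
        },
        index=["M1A", "M1C"],
    )
    retained, excluded = apply_low_growth_filter(growth)
    assert retained.empty and len(excluded) == 2


def test_categories_partition_designed_library(small_growth):
    truth, growth = small_growth
    assert len(growth) == len(truth.frame) == 570
    n = growth["status"].value_counts()
    assert n.get(MEASURED, 0) + n.get(NULL_DATA, 0) + n.get(NO_DATA, 0) == 570
    # dropouts (x0 == 0) are classified as missing at t = 0
    dropped = truth.frame.index[truth.frame["x0"] == 0]
    assert (growth.loc[dropped, "status"] == NO_DATA).all()


def test_parameter_recovery_on_shared_simulation(small_growth):
    truth, growth = small_growth
    measured = growth[growth["status"] == MEASURED]
    joined = measured.join(truth.frame)
    err = joined["dark_mean"] - joined["rgr_dark"]
    assert np.sqrt((err**2).mean()) < 0.02  # depth 2e5; tighter at 1e6
    r = np.corrcoef(joined["dark_1"], joined["dark_2"])[0, 1]
    assert r > 0.9
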