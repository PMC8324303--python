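"""Steady-state Michaelis-Menten kinetics and allosteric fold changes.

Initial velocities come from the depletion of NADPH followed by
absorbance at 340 nm (extinction coefficient 13.2 mM^-1 cm^-1); the
Michaelis-Menten model

    v = kcat * [S] / (Km + [S])

is fitted by nonlinear least squares with enzyme concentration
normalized to one.  Allostery is reported as the ratio of lit to dark
velocity evaluated at a reference substrate concentration (25 uM
dihydrofolate, the physiological level in wild-type E. coli), and
multi-mutant expectations combine single-mutant folds log-additively
relative to the unmutated construct.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: NADPH extinction coefficient at 340 nm, mM^-1 cm^-1.
NADPH_EXTINCTION = 13.2

#: Physiological dihydrofolate concentration in wild-type E. coli (uM).
PHYSIOLOGICAL_DHF_UM = 25.0


def initial_velocity(
    times_s: np.ndarray,
    a340: np.ndarray,
    extinction: float = NADPH_EXTINCTION,
    path_cm: float = 1.0,
    window_s: float = 15.0,
) -> float:
    """Initial velocity (uM/s) from an absorbance trace.

    The slope of A340 over the first ``window_s`` seconds, converted by
    Beer-Lambert with the extinction coefficient in mM^-1 cm^-1 (hence
    the factor 1000 to uM).  NADPH is consumed, so the absorbance falls;
    a flat or rising trace yields velocity 0 with a warning.
    """
    t = np.asarray(times_s, dtype=float)
    a = np.asarray(a340, dtype=float)
    m = t <= window_s
    if m.sum() < 2:
        raise ValueError("trace does not cover the initial-rate window")
    slope = stats.linregress(t[m], a[m]).slope
    if slope >= 0:
        warnings.warn("non-decreasing A340 trace; returning velocity 0")
        return 0.0
    return -slope / (extinction * path_cm) * 1000.0


@dataclass(frozen=True)
class KineticsFit:
    """Fitted Michaelis-Menten parameters for one condition."""

    kcat: float  # s^-1 (enzyme concentration normalized to 1)
    km: float  # uM
    kcat_se: float
    km_se: float
    condition: str = ""
    construct: str = ""

    def velocity(self, s_um: float | np.ndarray) -> float | np.ndarray:
        s = np.asarray(s_um, dtype=float)
        v = self.kcat * s / (self.km + s)
        return float(v) if np.isscalar(s_um) else v


def fit_mm(
    s_um: np.ndarray,
    v: np.ndarray,
    condition: str = "",
    construct: str = "",
) -> KineticsFit:
    """Nonlinear least-squares Michaelis-Menten fit.

    Parameterized in (log kcat, log Km) so positivity is enforced
    without bounds.  Initial guesses: kcat = 1.1 * max(v), Km =
    substrate concentration at half-maximal velocity by interpolation.
    Standard errors come from the Jacobian at the optimum.
    """
    s = np.asarray(s_um, dtype=float)
    vv = np.asarray(v, dtype=float)
    if len(np.unique(s[s > 0])) < 5:
        raise ValueError("need at least 5 distinct non-zero substrate concentrations")
    vmax0 = float(vv.max()) * 1.1
    if vmax0 <= 0:
        raise ValueError("all velocities are non-positive")
    order = np.argsort(s)
    km0 = float(np.interp(vmax0 / 2.2, vv[order], s[order]))
    km0 = max(km0, 1e-6)

    def model(theta: np.ndarray) -> np.ndarray:
        kcat, km = np.exp(theta)
        return kcat * s / (km + s)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return model(theta) - vv

    res = optimize.least_squares(
        residuals, x0=np.log([vmax0, km0]), method="lm", xtol=1e-15, ftol=1e-15
    )
    if not res.success:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {res.message}")
    kcat, km = np.exp(res.x)
    # covariance of log-parameters from J^T J; delta-method to linear scale
    dof = max(len(vv) - 2, 1)
    s_sq = float(2 * res.cost) / dof
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * s_sq
        kcat_se = float(kcat * math.sqrt(max(cov[0, 0], 0.0)))
        km_se = float(km * math.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        kcat_se = km_se = math.nan
    return KineticsFit(float(kcat), float(km), kcat_se, km_se, condition, construct)


def fit_dataset(data: pd.DataFrame) -> dict[tuple[str, str], KineticsFit]:
    """Fit every (construct, condition) group of a velocity table.

    ``data`` columns: ``construct``, ``condition``, ``S_uM``,
    ``v_uM_per_s`` (replicates pooled into one fit per group).
    """
    fits = {}
    for (construct, condition), grp in data.groupby(["construct", "condition"]):
        fits[(construct, condition)] = fit_mm(
            grp["S_uM"].to_numpy(),
            grp["v_uM_per_s"].to_numpy(),
            condition=str(condition),
            construct=str(construct),
        )
    return fits


def allosteric_fold(
    lit_fit: KineticsFit,
    dark_fit: KineticsFit,
    s_ref_um: float = PHYSIOLOGICAL_DHF_UM,
) -> dict[str, float]:
    """Lit/dark fold change of velocity at the reference substrate.

    Also reports the kcat and Km ratios.  When Km is light-insensitive
    the fold equals the kcat ratio at any substrate concentration.
    """
    v_dark = dark_fit.velocity(s_ref_um)
    if v_dark == 0:
        raise ZeroDivisionError("dark velocity is zero at the reference substrate")
    return {
        "fold": float(lit_fit.velocity(s_ref_um) / v_dark),
        "kcat_ratio": lit_fit.kcat / dark_fit.kcat,
        "km_ratio": lit_fit.km / dark_fit.km,
        "s_ref_um": float(s_ref_um),
    }


def log_additive_expectation(
    single_folds: list[float], baseline_fold: float
) -> float:
    """Expected combined fold of a multi-mutant from its singles.

    Additive in log space relative to the unmutated construct:

        expected = baseline * prod(single_i / baseline)

    so a single equal to baseline contributes nothing.
    """
    if baseline_fold <= 0 or any(f <= 0 for f in single_folds):
        raise ValueError("folds must be positive")
    log_expected = math.log(baseline_fold) + sum(
        math.log(f) - math.log(baseline_fold) for f in single_folds
    )
    return math.exp(log_expected)
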