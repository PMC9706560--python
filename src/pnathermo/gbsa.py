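"""Post-processing of MM-GBSA binding-energy tables.

MM-GBSA end-point estimates from simulation are consumed here as data
(sequence, mean over replicates, standard error); the module never evaluates
generalized Born energies.  It provides:

* the standard-state correction referencing a simulated binding free energy
  to 1 M concentration (an RT ln-volume shift against V0 = 1661 A^3);
* an ordinary-least-squares linear calibration of computed against
  experimental values, ``chi_exp = a * chi_com + b``;
* benchmark error metrics (mean absolute difference, mean relative error,
  R^2) between a reference and a prediction;
* propagation of an affine calibration into a fitted nearest-neighbor
  parameter set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .nn_model import NnParameterSet

logger = logging.getLogger(__name__)

#: Standard-state volume per molecule at 1 M, cubic angstroms.
V_STANDARD_A3 = 1661.0

_R_KCAL = 1.987204e-3  # kcal K-1 mol-1


@dataclass(frozen=True)
class StandardStateContext:
    """Simulation-box volume and temperature for the 1 M reference shift."""

    v_box: float  # A^3
    temperature: float = 298.0  # K
    v_standard: float = V_STANDARD_A3

    def __post_init__(self) -> None:
        if self.v_box <= 0 or self.v_standard <= 0:
            raise ValueError("volumes must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class LinearCalibration:
    """Fitted line chi_exp = a * chi_com + b with diagnostics."""

    slope: float
    intercept: float
    r_squared: float
    slope_se: float = float("nan")
    intercept_se: float = float("nan")
    residuals: np.ndarray | None = None


@dataclass(frozen=True)
class BenchmarkReport:
    """Agreement metrics between reference and predicted values."""

    mean_absolute_difference: float
    mean_relative_error_percent: float
    r_squared: float
    residuals: np.ndarray


def standard_state_correction(ctx: StandardStateContext) -> float:
    """Additive shift (kcal mol-1) referencing a binding dG to 1 M.

    ``dG_ss = -R T ln(V0 / V_box)``: a box larger than the standard-state
    volume dilutes the strands relative to 1 M, making the corrected binding
    free energy more positive.  Zero when V_box equals V0.
    """
    return -_R_KCAL * ctx.temperature * math.log(ctx.v_standard / ctx.v_box)


def fit_calibration(
    experimental: np.ndarray | list[float],
    computed: np.ndarray | list[float],
) -> LinearCalibration:
    """OLS of experimental on computed values: slope a, intercept b, R^2."""
    y = np.asarray(experimental, dtype=float)
    x = np.asarray(computed, dtype=float)
    if y.shape != x.shape:
        raise ValueError("experimental and computed lengths differ")
    if y.size < 3:
        raise ValueError("need at least 3 pairs to calibrate")
    if np.ptp(x) == 0:
        raise ValueError("computed values have zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    b, a = res.params
    b_se, a_se = res.bse
    return LinearCalibration(
        slope=float(a),
        intercept=float(b),
        r_squared=float(res.rsquared),
        slope_se=float(a_se),
        intercept_se=float(b_se),
        residuals=np.asarray(res.resid),
    )


def apply_calibration(
    values: np.ndarray | list[float] | float, cal: LinearCalibration
):
    """Elementwise a * value + b."""
    if np.isscalar(values):
        return cal.slope * values + cal.intercept
    return cal.slope * np.asarray(values, dtype=float) + cal.intercept


def benchmark(
    reference: np.ndarray | list[float],
    predicted: np.ndarray | list[float],
) -> BenchmarkReport:
    """Mean absolute difference, mean relative error (%), and R^2.

    Entries with a zero reference value have an undefined relative error and
    are excluded from the relative-error mean with a warning.
    """
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if ref.shape != pred.shape or ref.size == 0:
        raise ValueError("reference and predicted must be equal, non-empty")
    resid = ref - pred
    mad = float(np.mean(np.abs(resid)))
    nonzero = ref != 0
    if not nonzero.all():
        logger.warning(
            "%d zero reference value(s) excluded from the relative error",
            int((~nonzero).sum()),
        )
    if nonzero.any():
        mre = float(
            np.mean(100.0 * np.abs(resid[nonzero]) / np.abs(ref[nonzero]))
        )
    else:
        mre = float("nan")
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return BenchmarkReport(
        mean_absolute_difference=mad,
        mean_relative_error_percent=mre,
        r_squared=r2,
        residuals=resid,
    )


def propagate_calibration(
    params: NnParameterSet, cal: LinearCalibration
) -> NnParameterSet:
    """Carry an affine calibration of the observations into the fitted terms.

    Least squares is linear in the observations, so fitting on calibrated
    data ``a*chi + b`` is the same as scaling every stack and terminal-G.C
    term by ``a`` and mapping the initiation term to ``a*init + b`` (the
    intercept rides on the per-duplex constant column).  Standard errors
    scale by ``|a|``; the intercept SE adds to the initiation term.

    The result is flagged ``calibrated``: the intercept can be dominated by
    systematic computational error rather than a physical initiation energy,
    and dG = dH - T dS consistency across separately calibrated observables
    is not guaranteed.
    """
    a, b = cal.slope, cal.intercept
    stacks = {
        label: (a * v, abs(a) * se) for label, (v, se) in params.stack_terms.items()
    }
    init_v, init_se = params.init_term
    init_se_new = math.sqrt(
        (abs(a) * init_se) ** 2
        + (0.0 if math.isnan(cal.intercept_se) else cal.intercept_se) ** 2
    )
    tgc_v, tgc_se = params.terminal_gc_term
    cov = None
    if params.covariance is not None:
        cov = a * a * params.covariance
    return NnParameterSet(
        stack_terms=stacks,
        init_term=(a * init_v + b, init_se_new),
        terminal_gc_term=(a * tgc_v, abs(a) * tgc_se),
        observable_kind=params.observable_kind,
        p_values=dict(params.p_values),
        covariance=cov,
        calibrated=True,
    )
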