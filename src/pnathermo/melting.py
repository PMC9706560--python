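"""Two-state UV-melting analysis and van't Hoff thermodynamics.

A hyperchromic absorbance-vs-temperature curve at 260 nm is min-max
normalized into an alpha curve (alpha = duplexed fraction, 1 = all duplex).
Under the two-state assumption the equilibrium constant follows from alpha
and the total strand concentration C_T; regressing ln K on 1/T (the linear
van't Hoff form) yields the standard binding enthalpy and entropy, assumed
temperature-independent, and dG = dH - T dS at a reference temperature.

Units follow the field's tables: enthalpies and free energies in
kcal mol-1, entropies in cal K-1 mol-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Gas constant, cal K-1 mol-1.
R_CAL = 1.987204

#: Default alpha window for the van't Hoff regression (the tails diverge).
DEFAULT_ALPHA_WINDOW = (0.15, 0.85)


@dataclass(frozen=True)
class MeltingCurve:
    """Absorbance (260 nm) vs temperature with sample metadata."""

    temperatures: np.ndarray  # K, strictly increasing
    absorbances: np.ndarray
    strand_concentration: float  # C_T, mol/L total strands
    self_complementary: bool

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if t.size != a.size:
            raise ValueError("temperature and absorbance lengths differ")
        if t.size < 4:
            raise ValueError("need at least 4 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.strand_concentration <= 0:
            raise ValueError("strand concentration must be positive")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "absorbances", a)


@dataclass(frozen=True)
class AlphaCurve:
    """Duplexed fraction alpha(T); alpha = 1 means all double helices."""

    temperatures: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
            raise ValueError("alpha values must lie in [0, 1]")
        object.__setattr__(
            self, "temperatures", np.asarray(self.temperatures, dtype=float)
        )
        object.__setattr__(self, "alpha", np.clip(a, 0.0, 1.0))


@dataclass(frozen=True)
class ThermoResult:
    """van't Hoff outputs: dH, dS, dG(T_ref), Tm, and fit diagnostics."""

    dH: float  # kcal/mol, signed
    dH_se: float
    dS: float  # cal/K/mol, signed
    dS_se: float
    dG: float  # kcal/mol at reference_temperature
    dG_se: float
    reference_temperature: float
    Tm: float | None
    r_squared: float
    n_points: int


def normalize_to_alpha(curve: MeltingCurve) -> AlphaCurve:
    """Min-max normalize absorbance into the duplexed fraction.

    ``alpha(T) = (A_max - A(T)) / (A_max - A_min)``: single strands are
    hyperchromic at 260 nm, so absorbance rises on melting and alpha falls.
    """
    a = curve.absorbances
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        raise ValueError("flat absorbance curve cannot be normalized")
    return AlphaCurve(curve.temperatures, (hi - a) / (hi - lo))


def melting_temperature(alpha_curve: AlphaCurve) -> float:
    """Temperature of the first downward crossing of alpha = 0.5.

    Linearly interpolates between the bracketing points; an exact grid hit
    returns the grid temperature.
    """
    t = alpha_curve.temperatures
    a = alpha_curve.alpha
    for i in range(len(a)):
        if a[i] == 0.5:
            return float(t[i])
        if i > 0 and a[i - 1] > 0.5 > a[i]:
            frac = (a[i - 1] - 0.5) / (a[i - 1] - a[i])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    raise ValueError(
        "alpha never crosses 0.5 downward "
        f"(observed range [{a.min():.3f}, {a.max():.3f}])"
    )


def equilibrium_constant(
    alpha: float, c_total: float, self_complementary: bool
) -> float:
    """Two-state duplex formation constant from the duplexed fraction.

    Self-complementary (2A = A2):      K = alpha / (2 (1-alpha)^2 C_T)
    Non-self-complementary (A + B = AB,
    equal strand concentrations):      K = 2 alpha / ((1-alpha)^2 C_T)

    At alpha = 0.5 the self-complementary form gives exactly K = 1/C_T.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be strictly inside (0, 1), got {alpha}")
    if c_total <= 0:
        raise ValueError("strand concentration must be positive")
    if self_complementary:
        return alpha / (2.0 * (1.0 - alpha) ** 2 * c_total)
    return 2.0 * alpha / ((1.0 - alpha) ** 2 * c_total)


def gibbs(
    dH: float,
    dS: float,
    temperature: float,
    dH_se: float = 0.0,
    dS_se: float = 0.0,
) -> tuple[float, float]:
    """dG = dH - T dS/1000 (kcal mol-1), with independent-error propagation."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    dG = dH - temperature * dS / 1000.0
    se = math.sqrt(dH_se**2 + (temperature * dS_se / 1000.0) ** 2)
    return dG, se


def vant_hoff_fit(
    alpha_curve: AlphaCurve,
    c_total: float,
    self_complementary: bool,
    alpha_window: tuple[float, float] = DEFAULT_ALPHA_WINDOW,
    reference_temperature: float = 298.0,
) -> ThermoResult:
    """Linear van't Hoff regression of ln K on 1/T.

    Points with alpha inside ``alpha_window`` enter an ordinary least-squares
    fit ``ln K = -dH/(R T) + dS/R``, so dH = -R * slope (converted to kcal)
    and dS = R * intercept.  Standard errors come from the regression
    covariance.  Tm (alpha = 0.5 crossing) is attached when it exists.
    """
    lo, hi = alpha_window
    mask = (alpha_curve.alpha > lo) & (alpha_curve.alpha < hi)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 points with alpha in ({lo}, {hi}); got {int(mask.sum())}"
        )
    t = alpha_curve.temperatures[mask]
    a = alpha_curve.alpha[mask]
    ln_k = np.log(
        [equilibrium_constant(ai, c_total, self_complementary) for ai in a]
    )
    inv_t = 1.0 / t
    fit = stats.linregress(inv_t, ln_k)

    dH = -R_CAL * fit.slope / 1000.0  # kcal/mol
    dH_se = R_CAL * fit.stderr / 1000.0
    dS = R_CAL * fit.intercept  # cal/K/mol
    dS_se = R_CAL * fit.intercept_stderr
    dG, dG_se = gibbs(dH, dS, reference_temperature, dH_se, dS_se)
    try:
        tm = melting_temperature(alpha_curve)
    except ValueError:
        tm = None
    return ThermoResult(
        dH=dH,
        dH_se=dH_se,
        dS=dS,
        dS_se=dS_se,
        dG=dG,
        dG_se=dG_se,
        reference_temperature=reference_temperature,
        Tm=tm,
        r_squared=float(fit.rvalue**2),
        n_points=int(mask.sum()),
    )


def analyze_melting_curve(
    curve: MeltingCurve,
    alpha_window: tuple[float, float] = DEFAULT_ALPHA_WINDOW,
    reference_temperature: float = 298.0,
) -> ThermoResult:
    """Convenience: normalize, then run the van't Hoff fit."""
    return vant_hoff_fit(
        normalize_to_alpha(curve),
        curve.strand_concentration,
        curve.self_complementary,
        alpha_window=alpha_window,
        reference_temperature=reference_temperature,
    )
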