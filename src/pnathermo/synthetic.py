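"""Synthetic inputs emulating the pipeline's upstream data sources.

Real inputs to the analysis are lab or simulation products: MM-GBSA
binding-enthalpy tables over ~49 homoduplexes (triplicate means with
standard errors), hyperchromic UV-melting curves sampled at 2 K steps, and
per-frame Watson-Crick bond counts from 100 ns trajectories.  The
generators here emulate each of those at the same scales so every analysis
stage can be exercised end to end, deterministically under a seed:

* random PNA sequences (lengths 6-18, optional self-complementarity);
* replicate observations drawn around exact nearest-neighbor predictions
  from a ground-truth parameter set (default: the packaged reference set);
* two-state melting curves solved from the equilibrium constant;
* two-state Markov bond trajectories with class-specific open/close rates.

What the generators do *not* emulate: sequence-correlated systematic error
in MM-GBSA, sloping instrument baselines beyond a linear term, or any
non-Markovian structure in bond kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn_model
from .melting import R_CAL, MeltingCurve
from .hbonds import MAX_BONDS, HbondSeries, PairSpec
from .nn_model import NnParameterSet, ObservationSet
from .sequences import PnaSequence, describe_duplex

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the real data scales: 49 homoduplexes of lengths 6-18,
    triplicate observations with ~1 kcal/mol replicate noise, micromolar
    strands melted on a 2 K grid, and faster-opening terminal base pairs.
    """

    seed: int = 0
    n_sequences: int = 49
    length_min: int = 6
    length_max: int = 18
    gc_fraction: float = 0.5
    self_complementary_fraction: float = 0.1
    noise_sd_enthalpy: float = 1.0  # kcal/mol per replicate
    length_proportional_noise: bool = False
    n_replicates: int = 3
    melting_noise_sd: float = 0.005  # absorbance units
    # mean open/close rates per ns, keyed by pair class
    hbond_rates: dict = field(
        default_factory=lambda: {
            "terminal": (2.0, 20.0),
            "internal": (0.3, 30.0),
        }
    )

    def __post_init__(self) -> None:
        if not (2 <= self.length_min <= self.length_max):
            raise ValueError("need 2 <= length_min <= length_max")
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if not 0 <= self.self_complementary_fraction <= 1:
            raise ValueError("self_complementary_fraction must lie in [0, 1]")
        if self.noise_sd_enthalpy < 0 or self.melting_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def generate_sequences(cfg: GeneratorConfig) -> list[PnaSequence]:
    """Random PNA sequences at the configured lengths and GC content.

    Self-complementary sequences are built by construction: a random
    even-length half followed by its own antiparallel complement.  If the
    length range admits no even length, requesting self-complementary
    sequences is an error.
    """
    rng = np.random.default_rng(cfg.seed)
    even_lengths = [
        n for n in range(cfg.length_min, cfg.length_max + 1) if n % 2 == 0
    ]
    if cfg.self_complementary_fraction > 0 and not even_lengths:
        raise ValueError(
            "self-complementary sequences need an even length, but the "
            f"range {cfg.length_min}-{cfg.length_max} contains none"
        )
    out: list[PnaSequence] = []
    for _ in range(cfg.n_sequences):
        self_comp = rng.random() < cfg.self_complementary_fraction
        if self_comp:
            length = int(rng.choice(even_lengths))
            half = _random_bases(rng, length // 2, cfg.gc_fraction)
            comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
            other = "".join(comp[b] for b in reversed(half))
            out.append(PnaSequence(half + other))
        else:
            length = int(rng.integers(cfg.length_min, cfg.length_max + 1))
            out.append(PnaSequence(_random_bases(rng, length, cfg.gc_fraction)))
    return out


def generate_observations(
    sequences: list[PnaSequence],
    truth: NnParameterSet | None = None,
    cfg: GeneratorConfig | None = None,
) -> ObservationSet:
    """Triplicate-mean observations around exact nearest-neighbor values.

    Each sequence's true binding enthalpy is the nearest-neighbor prediction
    under ``truth`` (default: the packaged reference parameters); replicates
    are drawn N(true, sd^2) and reported as (mean, standard error of the
    mean).  Zero noise gives exact values with zero SEs.
    """
    cfg = cfg or GeneratorConfig()
    truth = truth or nn_model.reference_parameters()
    rng = np.random.default_rng(cfg.seed + 1)
    entries = []
    for seq in sequences:
        desc = describe_duplex(seq)
        mu, _ = nn_model.predict(desc, truth)
        sd = cfg.noise_sd_enthalpy
        if cfg.length_proportional_noise:
            sd *= len(seq) / cfg.length_min
        if sd == 0:
            entries.append((desc, mu, 0.0))
            continue
        reps = rng.normal(mu, sd, size=cfg.n_replicates)
        se = (
            float(reps.std(ddof=1) / np.sqrt(cfg.n_replicates))
            if cfg.n_replicates > 1
            else sd
        )
        entries.append((desc, float(reps.mean()), se))
    return ObservationSet(tuple(entries), observable_kind=truth.observable_kind)


def solve_alpha(k_eq: float, c_total: float, self_complementary: bool) -> float:
    """Duplexed fraction from the two-state equilibrium constant.

    Inverts the concentration relations used by the melting analysis
    (self-complementary: K = a/(2(1-a)^2 C_T); otherwise K = 2a/((1-a)^2 C_T)),
    taking the physical root in [0, 1].
    """
    if self_complementary:
        x = 2.0 * k_eq * c_total  # a = x(1-a)^2
        if x == 0:
            return 0.0
        disc = (2 * x + 1) ** 2 - 4 * x * x
        return float((2 * x + 1 - np.sqrt(disc)) / (2 * x))
    x = k_eq * c_total / 2.0  # a = x(1-a)^2 with K = 2a/((1-a)^2 C_T)
    if x == 0:
        return 0.0
    disc = (2 * x + 1) ** 2 - 4 * x * x
    return float((2 * x + 1 - np.sqrt(disc)) / (2 * x))


def analytic_tm_self_complementary(
    dH: float, dS: float, c_total: float
) -> float:
    """Temperature (K) where a self-complementary duplex is half melted.

    At alpha = 0.5 the equilibrium constant equals 1/C_T, so
    Tm = 1000*dH / (dS + R ln C_T) with dH in kcal/mol, dS in cal/K/mol.
    """
    return 1000.0 * dH / (dS + R_CAL * np.log(c_total))


def generate_melting_curve(
    dH: float,
    dS: float,
    c_total: float,
    self_complementary: bool,
    temperatures: np.ndarray | None = None,
    noise_sd: float = 0.0,
    baseline_slopes: tuple[float, float] = (0.0, 0.0),
    a_duplex: float = 0.5,
    a_single: float = 1.0,
    seed: int = 0,
) -> MeltingCurve:
    """Two-state melting curve from (dH, dS) on a temperature grid.

    K(T) = exp(dS/R - 1000*dH/(R T)) is inverted to alpha(T), then mapped to
    absorbance A = A_ss - (A_ss - A_ds) * alpha (single strands hyperchromic)
    with optional linear baselines (slopes per K for the duplex and
    single-strand states) and Gaussian absorbance noise.  Default grid:
    274-372 K at 2 K steps, emulating water-bath sampling.
    """
    if dH >= 0:
        raise ValueError("need dH < 0 for a melting transition")
    if temperatures is None:
        temperatures = np.arange(274.0, 373.0, 2.0)
    t = np.asarray(temperatures, dtype=float)
    ln_k = dS / R_CAL - 1000.0 * dH / (R_CAL * t)
    alpha = np.array(
        [solve_alpha(np.exp(lk), c_total, self_complementary) for lk in ln_k]
    )
    m_ds, m_ss = baseline_slopes
    t0 = t[0]
    a_ds = a_duplex + m_ds * (t - t0)
    a_ss = a_single + m_ss * (t - t0)
    absorbance = a_ss - (a_ss - a_ds) * alpha
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, noise_sd, size=t.size)
    return MeltingCurve(
        temperatures=t,
        absorbances=absorbance,
        strand_concentration=c_total,
        self_complementary=self_complementary,
    )


def generate_hbond_series(
    pairs: list[PairSpec],
    rates: dict | None = None,
    duration: float = 100.0,
    dt: float = 0.01,
    seed: int = 0,
) -> HbondSeries:
    """Two-state Markov bond trajectories, one chain per Watson-Crick bond.

    Each bond of each pair flips between bonded and broken with per-step
    probabilities ``1 - exp(-rate * dt)`` from its class's (open, close)
    rates in 1/ns.  Bonds start bonded; the pair's per-frame count is the
    number of currently bonded bonds.
    """
    rates = rates or GeneratorConfig().hbond_rates
    if dt <= 0 or duration <= 0:
        raise ValueError("duration and dt must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / dt))
    counts = np.zeros((n_frames, len(pairs)), dtype=int)
    for j, p in enumerate(pairs):
        k_open, k_close = rates[p.pair_class]
        if k_open < 0 or k_close < 0:
            raise ValueError("rates must be non-negative")
        p_open = 1.0 - np.exp(-k_open * dt)
        p_close = 1.0 - np.exp(-k_close * dt)
        n_bonds = MAX_BONDS[p.pair_type]
        bonded = np.ones(n_bonds, dtype=bool)
        u = rng.random((n_frames, n_bonds))
        for f in range(n_frames):
            flip = np.where(bonded, u[f] < p_open, u[f] < p_close)
            bonded = bonded ^ flip
            counts[f, j] = int(bonded.sum())
    times = dt * np.arange(1, n_frames + 1)
    return HbondSeries(times=times, counts=counts, pairs=tuple(pairs))
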