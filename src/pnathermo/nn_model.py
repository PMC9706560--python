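"""Nearest-neighbor decomposition of PNA homoduplex binding thermodynamics.

The binding enthalpy (or entropy, or free energy) of a homoduplex is modeled
as a sum over its overlapping stacks plus a helix-initiation term plus a
terminal-G.C term that enters only when both terminal base pairs are G.C::

    dChi = sum_i j_i * ddChi_i  +  dChi_init  +  B * dChi_T.GC

with j_i the occurrence count of the i-th canonical stack and B the 0/1
terminal-G.C indicator.  Stacking the per-duplex counts row-wise gives a
design matrix S; the 12 unknown terms are estimated by linear least squares,
optionally weighted by the reciprocal standard error of each observation.

All quantities are stored *signed* (binding enthalpies negative, i.e.
stabilizing); published tables print magnitudes (-dH), which are converted at
I/O boundaries only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .sequences import CANONICAL_STACKS, STACK_WC_HBONDS, DuplexDescriptor

logger = logging.getLogger(__name__)

#: Fixed column / term order of the design matrix and parameter vector.
TERM_ORDER: tuple[str, ...] = CANONICAL_STACKS + ("Init", "T.GC")

N_TERMS = len(TERM_ORDER)  # 12

#: C2-symmetry entropy decrement for self-complementary duplexes,
#: cal K-1 mol-1 (the duplex loses a rotational degree of freedom on binding).
SYMMETRY_ENTROPY_DECREMENT = 1.4

ObservableKind = Literal["enthalpy", "entropy", "free_energy"]


@dataclass(frozen=True)
class ObservationSet:
    """Per-duplex observed binding quantities with standard errors.

    ``entries`` holds ``(descriptor, value, se)`` triples; values are signed
    (negative = stabilizing) and share one ``observable_kind``.
    """

    entries: tuple[tuple[DuplexDescriptor, float, float], ...]
    observable_kind: ObservableKind = "enthalpy"

    def __post_init__(self) -> None:
        for _, _, se in self.entries:
            if se < 0:
                raise ValueError("standard errors must be non-negative")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v, _ in self.entries], dtype=float)

    @property
    def standard_errors(self) -> np.ndarray:
        return np.array([s for _, _, s in self.entries], dtype=float)

    @property
    def descriptors(self) -> list[DuplexDescriptor]:
        return [d for d, _, _ in self.entries]


@dataclass
class NnParameterSet:
    """The 12 fitted nearest-neighbor terms with standard errors.

    ``stack_terms`` maps the 10 canonical stack labels to ``(value, se)``;
    ``init_term`` and ``terminal_gc_term`` are ``(value, se)`` pairs.  Values
    are signed.  ``covariance`` (term order :data:`TERM_ORDER`) is kept when
    the set comes from a fit, for exact error propagation.
    """

    stack_terms: dict[str, tuple[float, float]]
    init_term: tuple[float, float]
    terminal_gc_term: tuple[float, float]
    observable_kind: ObservableKind = "enthalpy"
    p_values: dict[str, float] = field(default_factory=dict)
    covariance: np.ndarray | None = None
    calibrated: bool = False

    def __post_init__(self) -> None:
        missing = set(CANONICAL_STACKS) - set(self.stack_terms)
        if missing:
            raise ValueError(f"missing stack terms: {sorted(missing)}")
        for _, se in list(self.stack_terms.values()) + [
            self.init_term,
            self.terminal_gc_term,
        ]:
            if se < 0:
                raise ValueError("standard errors must be non-negative")

    def term(self, name: str) -> tuple[float, float]:
        if name == "Init":
            return self.init_term
        if name == "T.GC":
            return self.terminal_gc_term
        return self.stack_terms[name]

    @property
    def vector(self) -> np.ndarray:
        """Signed term values in :data:`TERM_ORDER`."""
        return np.array([self.term(t)[0] for t in TERM_ORDER])

    @property
    def se_vector(self) -> np.ndarray:
        return np.array([self.term(t)[1] for t in TERM_ORDER])


def build_design_matrix(duplexes: Sequence[DuplexDescriptor]) -> np.ndarray:
    """N x 12 occurrence-count matrix in :data:`TERM_ORDER` column order.

    The initiation column is identically one; the terminal-G.C column is the
    0/1 indicator B (1 only when both terminal pairs are G.C).
    """
    if len(duplexes) == 0:
        raise ValueError("need at least one duplex")
    rows = np.zeros((len(duplexes), N_TERMS))
    for r, d in enumerate(duplexes):
        for label, count in d.stack_counts.items():
            rows[r, TERM_ORDER.index(label)] = count
        rows[r, TERM_ORDER.index("Init")] = 1.0
        rows[r, TERM_ORDER.index("T.GC")] = d.terminal_gc_indicator
    return rows


def _check_rank(design: np.ndarray) -> None:
    u, s, vt = np.linalg.svd(design, full_matrices=False)
    tol = 1e-10 * s[0]
    deficient = s < tol
    if deficient.any():
        bad_cols: set[str] = set()
        for row in vt[deficient]:
            for j in np.flatnonzero(np.abs(row) > 1e-6):
                bad_cols.add(TERM_ORDER[j])
        raise ValueError(
            "design matrix is rank deficient; unidentifiable term(s): "
            + ", ".join(sorted(bad_cols))
        )


def fit_nn(
    obs: ObservationSet,
    weighting: Literal["reciprocal_se", "unweighted"] = "reciprocal_se",
    se_floor: float | None = None,
) -> NnParameterSet:
    """Estimate the 12 nearest-neighbor terms by (weighted) least squares.

    With ``reciprocal_se`` weighting each residual is scaled by 1/se, i.e.
    the regression minimizes ``||diag(1/se) (chi - S eps)||^2``.  Standard
    errors of zero cannot be inverted; they are clamped up to ``se_floor``
    (default: the smallest strictly positive SE in the set) with a warning.

    Parameters standard errors come from the weighted normal-equations
    covariance; p-values are two-sided t-tests on N - 12 degrees of freedom.
    """
    n = len(obs)
    if n < N_TERMS:
        raise ValueError(f"need at least {N_TERMS} observations, got {n}")
    design = build_design_matrix(obs.descriptors)
    y = obs.values

    if weighting == "unweighted":
        weights = np.ones(n)
    elif weighting == "reciprocal_se":
        se = obs.standard_errors.copy()
        positive = se[se > 0]
        if se_floor is None:
            if positive.size == 0:
                logger.warning(
                    "all standard errors are zero; falling back to "
                    "unweighted least squares"
                )
                se = np.ones(n)
            else:
                se_floor = float(positive.min())
        if se_floor is not None and (se < se_floor).any():
            n_clamped = int((se < se_floor).sum())
            logger.warning(
                "%d standard error(s) below the floor %.4g clamped",
                n_clamped,
                se_floor,
            )
            se = np.maximum(se, se_floor)
        weights = 1.0 / se**2  # WLS minimizes sum w_i r_i^2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    _check_rank(design * np.sqrt(weights)[:, None])

    model = sm.WLS(y, design, weights=weights)
    res = model.fit()

    params = dict(zip(TERM_ORDER, res.params))
    ses = dict(zip(TERM_ORDER, res.bse))
    pvals = dict(zip(TERM_ORDER, res.pvalues))
    return NnParameterSet(
        stack_terms={s: (params[s], ses[s]) for s in CANONICAL_STACKS},
        init_term=(params["Init"], ses["Init"]),
        terminal_gc_term=(params["T.GC"], ses["T.GC"]),
        observable_kind=obs.observable_kind,
        p_values=pvals,
        covariance=np.asarray(res.cov_params()),
    )


def predict(
    duplex: DuplexDescriptor,
    params: NnParameterSet,
    use_covariance: bool = False,
) -> tuple[float, float]:
    """Nearest-neighbor prediction (signed) with propagated standard error.

    By default term errors are treated as independent, so the prediction SE
    is ``sqrt(sum (j_i se_i)^2)``; with ``use_covariance=True`` and a fitted
    parameter set, the full covariance gives exact propagation ``x' C x``.
    """
    x = build_design_matrix([duplex])[0]
    value = float(x @ params.vector)
    if use_covariance:
        if params.covariance is None:
            raise ValueError("parameter set carries no covariance matrix")
        var = float(x @ params.covariance @ x)
    else:
        var = float(np.sum((x * params.se_vector) ** 2))
    return value, math.sqrt(var)


def apply_symmetry_correction(
    predicted_entropy: float, self_complementary: bool
) -> float:
    """C2-symmetry correction for self-complementary duplexes.

    The binding entropy (cal K-1 mol-1, signed) of a self-complementary
    duplex is made more negative by 1.4 cal K-1 mol-1: the duplex's two-fold
    rotational symmetry removes a degree of freedom on binding.  Applies to
    entropy predictions only, never to the enthalpy fit.
    """
    if self_complementary:
        return predicted_entropy - SYMMETRY_ENTROPY_DECREMENT
    return predicted_entropy


def group_stack_summary(params: NnParameterSet) -> dict[int, float]:
    """Unweighted mean stack magnitude per Watson-Crick bond-count class.

    Returns ``{4: m4, 5: m5, 6: m6}`` where each value is the arithmetic mean
    of ``-value`` (magnitude) over the stacks with that many Watson-Crick
    hydrogen bonds.
    """
    groups: dict[int, list[float]] = {4: [], 5: [], 6: []}
    for label, (value, _) in params.stack_terms.items():
        groups[STACK_WC_HBONDS[label]].append(-value)
    return {k: float(np.mean(v)) for k, v in groups.items()}


# ---------------------------------------------------------------------------
# Parameter-set I/O (Table-style CSV: term, value, se, p_value; values are
# printed as magnitudes, stored signed internally)

def write_parameters(params: NnParameterSet, path: str | Path) -> None:
    rows = []
    for t in TERM_ORDER:
        value, se = params.term(t)
        rows.append(
            {
                "term": t,
                "value": -value,  # magnitude at the file boundary
                "se": se,
                "p_value": params.p_values.get(t, float("nan")),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_parameters(
    path: str | Path, observable_kind: ObservableKind = "enthalpy"
) -> NnParameterSet:
    df = pd.read_csv(path)
    required = {"term", "value", "se"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"parameter CSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    by_term = {str(r.term): r for r in df.itertuples()}
    missing = set(TERM_ORDER) - set(by_term)
    if missing:
        raise ValueError(f"parameter CSV missing term(s): {sorted(missing)}")

    def pair(t: str) -> tuple[float, float]:
        r = by_term[t]
        return -float(r.value), float(r.se)

    pvals = {}
    if "p_value" in df.columns:
        pvals = {
            str(r.term): float(r.p_value)
            for r in df.itertuples()
            if not pd.isna(r.p_value)
        }
    return NnParameterSet(
        stack_terms={s: pair(s) for s in CANONICAL_STACKS},
        init_term=pair("Init"),
        terminal_gc_term=pair("T.GC"),
        observable_kind=observable_kind,
        p_values=pvals,
    )


def reference_parameters() -> NnParameterSet:
    """The packaged PNA nearest-neighbor binding-enthalpy parameter set.

    Fitted from MM-GBSA binding enthalpies of 49 PNA homoduplexes; every
    term was significant at p < 1e-5.  Values print as magnitudes (-dH,
    kcal mol-1) in the packaged CSV and load signed.
    """
    with resources.as_file(
        resources.files("pnathermo.data") / "nn_enthalpy_pna.csv"
    ) as p:
        return read_parameters(p)
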