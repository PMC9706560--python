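"""Watson-Crick hydrogen-bond detection and melting-event statistics.

A base pair is monitored through its Watson-Crick donor/hydrogen/acceptor
triplets (two for A.T, three for G.C).  A bond counts as formed when the
donor-acceptor distance is below 0.325 nm and the hydrogen-donor-acceptor
angle is below 30 degrees (both strict).  Per-frame bonded counts per pair
form an :class:`HbondSeries`; a *melting event* is a maximal uninterrupted
run of frames in which at least one of the pair's bonds is broken
(count < max_bonds).  Event durations feed occurrence-per-nanosecond curves
and total-melting-time summaries, and per-pair bonded fractions aggregate
into terminal/internal x AT/GC group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

#: Geometric Watson-Crick hydrogen-bond criteria.
DIST_CUTOFF_NM = 0.325
ANGLE_CUTOFF_DEG = 30.0

#: Canonical Watson-Crick bond counts per pair type.
MAX_BONDS = {"AT": 2, "GC": 3}

PairClass = Literal["terminal", "internal"]
PairType = Literal["AT", "GC"]


@dataclass(frozen=True)
class WcTriplet:
    """Donor, hydrogen, acceptor coordinates (nm) of one Watson-Crick bond."""

    donor: np.ndarray
    hydrogen: np.ndarray
    acceptor: np.ndarray
    base_pair_index: int = 0

    def __post_init__(self) -> None:
        for name in ("donor", "hydrogen", "acceptor"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 3-vector")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class PairSpec:
    """Identity of a monitored base pair."""

    index: int
    pair_type: PairType
    pair_class: PairClass

    @property
    def max_bonds(self) -> int:
        return MAX_BONDS[self.pair_type]


@dataclass(frozen=True)
class HbondSeries:
    """Bonded-bond counts per frame for a set of monitored base pairs.

    ``counts`` has shape (n_frames, n_pairs); frame times are uniform with
    spacing ``dt`` (ns).
    """

    times: np.ndarray  # ns
    counts: np.ndarray  # (n_frames, n_pairs) integers
    pairs: tuple[PairSpec, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != t.size:
            raise ValueError("counts must be (n_frames, n_pairs)")
        if c.shape[1] != len(self.pairs):
            raise ValueError("counts column count must match pairs")
        if t.size < 2 or not np.all(np.diff(t) > 0):
            raise ValueError("need >= 2 strictly increasing frame times")
        for j, p in enumerate(self.pairs):
            col = c[:, j]
            if col.min() < 0 or col.max() > p.max_bonds:
                raise ValueError(
                    f"pair {p.index}: counts must lie in [0, {p.max_bonds}]"
                )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", c)

    @property
    def dt(self) -> float:
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("frame spacing is not uniform")
        return float(steps[0])

    @property
    def duration(self) -> float:
        """Total observed time (n_frames * dt), ns."""
        return self.dt * self.times.size


@dataclass(frozen=True)
class MeltingEvent:
    """A maximal uninterrupted interval with >= 1 broken Watson-Crick bond."""

    base_pair_index: int
    start_time: float  # ns
    duration: float  # ns
    censored: bool = False  # touches the start or end of the series


def detect_hbond(
    triplet: WcTriplet,
    dist_cutoff: float = DIST_CUTOFF_NM,
    angle_cutoff: float = ANGLE_CUTOFF_DEG,
    angle_vertex: Literal["donor", "hydrogen"] = "donor",
) -> bool:
    """Geometric Watson-Crick hydrogen-bond test (strict inequalities).

    The angle is measured at the donor between the donor->hydrogen and
    donor->acceptor vectors; ``angle_vertex="hydrogen"`` instead uses the
    donor-hydrogen-acceptor angle's deviation from linearity (the angle
    between hydrogen->donor and hydrogen->acceptor, taken from 180 degrees).
    """
    da = triplet.acceptor - triplet.donor
    dh = triplet.hydrogen - triplet.donor
    dist = float(np.linalg.norm(da))
    if np.linalg.norm(dh) == 0 or dist == 0:
        raise ValueError("coincident atoms give an undefined angle")
    if dist >= dist_cutoff:
        return False
    if angle_vertex == "donor":
        cosang = float(da @ dh / (dist * np.linalg.norm(dh)))
        angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    else:
        hd = triplet.donor - triplet.hydrogen
        ha = triplet.acceptor - triplet.hydrogen
        cosang = float(
            hd @ ha / (np.linalg.norm(hd) * np.linalg.norm(ha))
        )
        angle = 180.0 - math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    return angle < angle_cutoff


def counts_from_triplets(
    frames: Sequence[Sequence[WcTriplet]],
    pairs: Sequence[PairSpec],
    dt: float,
    **detect_kwargs,
) -> HbondSeries:
    """Build an :class:`HbondSeries` by applying :func:`detect_hbond` per frame."""
    index_of = {p.index: j for j, p in enumerate(pairs)}
    counts = np.zeros((len(frames), len(pairs)), dtype=int)
    for f, triplets in enumerate(frames):
        for trip in triplets:
            if detect_hbond(trip, **detect_kwargs):
                counts[f, index_of[trip.base_pair_index]] += 1
    times = dt * np.arange(1, len(frames) + 1)
    return HbondSeries(times=times, counts=counts, pairs=tuple(pairs))


def percent_bonded(
    series: HbondSeries,
) -> dict[tuple[PairClass, PairType], tuple[float, float]]:
    """Mean +/- SD (%) of the normalized bonded fraction per pair group.

    Each pair's fraction is the time-mean of ``count / max_bonds``; the
    fractions are then averaged (and their SD taken) across the pairs in
    each (pair_class, pair_type) group and expressed as percentages.  SD is
    0 for single-pair groups.
    """
    fractions: dict[tuple[PairClass, PairType], list[float]] = {}
    for j, p in enumerate(series.pairs):
        frac = float(series.counts[:, j].mean()) / p.max_bonds
        fractions.setdefault((p.pair_class, p.pair_type), []).append(frac)
    return {
        key: (100.0 * float(np.mean(v)), 100.0 * float(np.std(v, ddof=0)))
        for key, v in fractions.items()
    }


def find_melting_events(series: HbondSeries) -> list[MeltingEvent]:
    """Segment each pair's series into maximal broken-bond runs.

    A frame belongs to an event when its count is below the pair's
    ``max_bonds``; duration is (run length) * dt.  Runs touching either
    series boundary are included and flagged censored.
    """
    dt = series.dt
    n = series.times.size
    events: list[MeltingEvent] = []
    for j, p in enumerate(series.pairs):
        broken = series.counts[:, j] < p.max_bonds
        i = 0
        while i < n:
            if broken[i]:
                start = i
                while i < n and broken[i]:
                    i += 1
                events.append(
                    MeltingEvent(
                        base_pair_index=p.index,
                        start_time=float(series.times[start]),
                        duration=dt * (i - start),
                        censored=(start == 0 or i == n),
                    )
                )
            else:
                i += 1
    return events


def event_occurrence_curve(
    events: Sequence[MeltingEvent],
    total_time: float,
    thresholds: Sequence[float],
) -> np.ndarray:
    """Occurrences per ns of events at least as long as each threshold.

    ``curve[k] = #{events with duration >= thresholds[k]} / total_time``;
    non-increasing in the threshold by construction.
    """
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    durations = np.array([e.duration for e in events], dtype=float)
    return np.array(
        [float((durations >= tau).sum()) / total_time for tau in thresholds]
    )


def total_melting_time(events: Sequence[MeltingEvent]) -> dict[int, float]:
    """Summed event duration (ns) per base pair."""
    totals: dict[int, float] = {}
    for e in events:
        totals[e.base_pair_index] = totals.get(e.base_pair_index, 0.0) + e.duration
    return totals
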