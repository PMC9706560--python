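"""File-format dialects, pipeline configuration, and orchestration.

Tables at file boundaries follow the printed-table convention: binding
quantities are stored as magnitudes in columns named for the observable
(``neg_dH_kcal``, ``neg_dS_cal``, ``neg_dG_kcal``) and are converted to
signed values (negative = stabilizing) on read.  Parsing is fail-fast with
line context; warnings never silently alter data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn_model
from .gbsa import benchmark
from .hbonds import HbondSeries, PairSpec
from .melting import MeltingCurve
from .nn_model import NnParameterSet, ObservationSet, ObservableKind
from .sequences import describe_duplex, validate_sequence

logger = logging.getLogger(__name__)

#: Magnitude-convention observable columns at file boundaries.
OBSERVABLE_COLUMNS: dict[str, ObservableKind] = {
    "neg_dH_kcal": "enthalpy",
    "neg_dS_cal": "entropy",
    "neg_dG_kcal": "free_energy",
}


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end analysis settings; round-trips losslessly through JSON."""

    reference_temperature: float = 298.0
    weighting: str = "reciprocal_se"
    alpha_window: tuple[float, float] = (0.15, 0.85)
    se_floor: float | None = None
    output_precision: int = 2
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        raw["alpha_window"] = tuple(raw["alpha_window"])
        return cls(**raw)

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def read_observations(path: str | Path) -> ObservationSet:
    """Read a (sequence, magnitude, se) table into a signed ObservationSet.

    Exactly one observable column from :data:`OBSERVABLE_COLUMNS` must be
    present alongside ``sequence`` and ``se``.  Duplicate sequences and
    non-numeric values are errors reported with their CSV line numbers.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no observation rows")
    obs_cols = [c for c in df.columns if c in OBSERVABLE_COLUMNS]
    if len(obs_cols) != 1:
        raise ValueError(
            f"{path}: expected exactly one observable column among "
            f"{sorted(OBSERVABLE_COLUMNS)}, found {obs_cols or list(df.columns)}"
        )
    col = obs_cols[0]
    if "sequence" not in df.columns or "se" not in df.columns:
        raise ValueError(f"{path}: need columns 'sequence', '{col}', 'se'")

    bad = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            float(row[col]), float(row["se"])
        except (TypeError, ValueError):
            bad.append(line)
    if bad:
        raise ValueError(f"{path}: non-numeric values on line(s) {bad}")
    dupes = df["sequence"][df["sequence"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate sequence(s) {dupes}")

    entries = []
    for _, row in df.iterrows():
        desc = describe_duplex(validate_sequence(str(row["sequence"])))
        entries.append((desc, -float(row[col]), float(row["se"])))
    return ObservationSet(tuple(entries), observable_kind=OBSERVABLE_COLUMNS[col])


def write_observations(obs: ObservationSet, path: str | Path) -> None:
    col = {v: k for k, v in OBSERVABLE_COLUMNS.items()}[obs.observable_kind]
    pd.DataFrame(
        {
            "sequence": [str(d.sequence) for d in obs.descriptors],
            col: -obs.values,
            "se": obs.standard_errors,
        }
    ).to_csv(path, index=False)


def read_melting_curve(path: str | Path) -> MeltingCurve:
    """Read a melting-curve CSV with ``# key = value`` metadata comments.

    Required metadata: ``c_total`` (mol/L) and ``self_complementary``
    (true/false); data columns are ``temperature_K, absorbance``.
    """
    meta: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    data_lines = []
    for ln in lines:
        if ln.lstrip().startswith("#"):
            body = ln.lstrip()[1:]
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
        elif ln.strip():
            data_lines.append(ln)
    if "c_total" not in meta or "self_complementary" not in meta:
        raise ValueError(
            f"{path}: header comments must define c_total and self_complementary"
        )
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(data_lines)))
    if not {"temperature_K", "absorbance"}.issubset(df.columns):
        raise ValueError(f"{path}: need columns temperature_K, absorbance")
    return MeltingCurve(
        temperatures=df["temperature_K"].to_numpy(float),
        absorbances=df["absorbance"].to_numpy(float),
        strand_concentration=float(meta["c_total"]),
        self_complementary=meta["self_complementary"].lower()
        in ("true", "1", "yes"),
    )


def write_melting_curve(curve: MeltingCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# c_total = {curve.strand_concentration!r}\n")
        fh.write(f"# self_complementary = {str(curve.self_complementary).lower()}\n")
        pd.DataFrame(
            {
                "temperature_K": curve.temperatures,
                "absorbance": curve.absorbances,
            }
        ).to_csv(fh, index=False)


def read_hbond_series(path: str | Path) -> HbondSeries:
    """Read per-frame bonded counts: ``time_ns`` plus ``pair_<i>_<AT|GC>_<class>``."""
    df = pd.read_csv(path)
    if "time_ns" not in df.columns:
        raise ValueError(f"{path}: need a time_ns column")
    pairs = []
    cols = []
    for c in df.columns:
        if c == "time_ns":
            continue
        parts = c.split("_")
        if len(parts) != 4 or parts[0] != "pair":
            raise ValueError(
                f"{path}: column {c!r} is not pair_<index>_<AT|GC>_<class>"
            )
        pairs.append(
            PairSpec(index=int(parts[1]), pair_type=parts[2], pair_class=parts[3])
        )
        cols.append(c)
    return HbondSeries(
        times=df["time_ns"].to_numpy(float),
        counts=df[cols].to_numpy(int),
        pairs=tuple(pairs),
    )


def write_hbond_series(series: HbondSeries, path: str | Path) -> None:
    data = {"time_ns": series.times}
    for j, p in enumerate(series.pairs):
        data[f"pair_{p.index}_{p.pair_type}_{p.pair_class}"] = series.counts[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def predictions_table(
    sequences: list[str],
    params: NnParameterSet,
    experimental: ObservationSet | None = None,
    precision: int = 2,
) -> pd.DataFrame:
    """Per-sequence prediction table in the printed-table layout.

    Columns: sequence, predicted magnitude; when experimental observations
    are supplied, also the experimental magnitude, absolute difference, and
    percent difference.
    """
    rows = []
    exp_by_seq = {}
    if experimental is not None:
        exp_by_seq = {
            str(d.sequence): v for d, v, _ in experimental.entries
        }
    for s in sequences:
        desc = describe_duplex(validate_sequence(s))
        value, se = nn_model.predict(desc, params)
        row = {"sequence": str(desc.sequence), "neg_dH_nn": -value, "se": se}
        if str(desc.sequence) in exp_by_seq:
            exp = -exp_by_seq[str(desc.sequence)]
            row["neg_dH_exp"] = exp
            row["abs_diff"] = abs(exp - (-value))
            row["pct_diff"] = 100.0 * abs(exp - (-value)) / abs(exp)
        rows.append(row)
    return pd.DataFrame(rows).round(precision)


def run_pipeline(
    config: PipelineConfig,
    observations: ObservationSet,
    benchmark_observations: ObservationSet,
    out_dir: str | Path | None = None,
) -> dict:
    """Fit, predict, and benchmark end to end.

    Fits the nearest-neighbor model on ``observations``, predicts the
    sequences of ``benchmark_observations``, and compares against their
    experimental values.  Returns a report dict (parameters, prediction
    table, benchmark metrics); when ``out_dir`` is given, writes
    ``params.csv``, ``predictions.csv``, and ``benchmark.json`` there.
    """
    logger.info(
        "pipeline start: seed=%d config=%s version=%s",
        config.seed,
        config.digest,
        _version(),
    )
    params = nn_model.fit_nn(
        observations, weighting=config.weighting, se_floor=config.se_floor
    )
    seqs = [str(d.sequence) for d in benchmark_observations.descriptors]
    table = predictions_table(
        seqs, params, benchmark_observations, precision=config.output_precision
    )
    report = benchmark(
        table["neg_dH_exp"].to_numpy(), table["neg_dH_nn"].to_numpy()
    )
    metrics = {
        "mean_absolute_difference": report.mean_absolute_difference,
        "mean_relative_error_percent": report.mean_relative_error_percent,
        "r_squared": report.r_squared,
        "seed": config.seed,
        "config_digest": config.digest,
        "version": _version(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nn_model.write_parameters(params, out / "params.csv")
        table.to_csv(out / "predictions.csv", index=False)
        (out / "benchmark.json").write_text(json.dumps(metrics, indent=2))
    return {"params": params, "predictions": table, "benchmark": metrics}


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("pnathermo")
    except PackageNotFoundError:
        return "unknown"
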