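"""Canonical file formats: gradient/work TSV tables and JSON reports.

The TSV dialects are defined by this package (engine-agnostic), with
'#'-prefixed metadata lines, tab separation and snake_case headers:

* gradient table: columns ``lambda, replica, time_ps, dhdl_kcal_mol``
* work table: columns ``direction, replica, work_kcal_mol`` plus metadata
  lines ``#trans_len_fwd_ps=`` and ``#trans_len_rev_ps=``
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, is_dataclass
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    EnsembleGradients,
    FreeEnergyEstimate,
    GradientSeries,
    LambdaSchedule,
    WorkRecord,
    WorkSet,
)
from .exceptions import FormatError, ScheduleMismatchError, ValidationError

GRADIENT_COLUMNS = ["lambda", "replica", "time_ps", "dhdl_kcal_mol"]
WORK_COLUMNS = ["direction", "replica", "work_kcal_mol"]


def _read_tsv(path: str, required: list[str]) -> tuple[pd.DataFrame, dict[str, str]]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            stripped = line[1:].strip()
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                meta[k.strip()] = v.strip()
        else:
            body.append(line)
    if not body:
        raise FormatError(f"{path}: no header line found")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), sep="\t")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df, meta


def read_gradient_table(
    path: str, leg: str, schedule: LambdaSchedule
) -> EnsembleGradients:
    """Read a canonical gradient TSV into a rectangular :class:`EnsembleGradients`.

    Every λ value in the file must match a schedule window within 1e-9;
    a missing (λ, replica) cell raises a completeness error.
    """
    df, _ = _read_tsv(path, GRADIENT_COLUMNS)
    series = []
    for (lam, rep), grp in df.groupby(["lambda", "replica"], sort=True):
        try:
            schedule.index_of(float(lam))
        except ValidationError as exc:
            raise ScheduleMismatchError(
                f"{path}: λ={lam} does not match schedule {schedule.name!r}"
            ) from exc
        grp = grp.sort_values("time_ps")
        series.append(
            GradientSeries(
                replica_id=int(rep),
                lam=float(lam),
                samples=tuple(grp["dhdl_kcal_mol"].astype(float)),
                times=tuple(grp["time_ps"].astype(float)),
            )
        )
    return EnsembleGradients(leg=leg, schedule=schedule, series=tuple(series))


def write_gradient_table(data: EnsembleGradients, path: str) -> None:
    """Write an :class:`EnsembleGradients` to the canonical gradient TSV."""
    rows = []
    for s in sorted(data.series, key=lambda s: (s.lam, s.replica_id)):
        times = s.times if s.times is not None else tuple(
            2.0 * (i + 1) for i in range(len(s.samples))
        )
        for t, v in zip(times, s.samples):
            rows.append((s.lam, s.replica_id, t, v))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#leg={data.leg}\n#schedule={data.schedule.name}\n")
        fh.write("\t".join(GRADIENT_COLUMNS) + "\n")
        for lam, rep, t, v in rows:
            fh.write(f"{lam:.17g}\t{rep}\t{t:.17g}\t{v:.17g}\n")


def read_work_table(path: str) -> WorkSet:
    """Read a canonical work TSV into a :class:`WorkSet`.

    Direction tokens must be exactly ``forward`` or ``reverse``.  A file
    with records in only one direction is accepted but flagged
    unidirectional in downstream estimates.
    """
    df, meta = _read_tsv(path, WORK_COLUMNS)
    records = []
    for r in df.itertuples():
        direction = str(r.direction)
        if direction not in ("forward", "reverse"):
            raise FormatError(
                f"{path}: direction token {direction!r} not in {{'forward', 'reverse'}}"
            )
        records.append(
            WorkRecord(
                direction=direction,
                replica_id=int(r.replica),
                work=float(r.work_kcal_mol),
            )
        )
    return WorkSet(
        records=tuple(records),
        transition_length_fwd=float(meta.get("trans_len_fwd_ps", 0.0)),
        transition_length_rev=float(meta.get("trans_len_rev_ps", 0.0)),
    )


def write_work_table(ws: WorkSet, path: str) -> None:
    """Write a :class:`WorkSet` to the canonical work TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#trans_len_fwd_ps={ws.transition_length_fwd:.17g}\n")
        fh.write(f"#trans_len_rev_ps={ws.transition_length_rev:.17g}\n")
        fh.write("\t".join(WORK_COLUMNS) + "\n")
        for r in ws.records:
            fh.write(f"{r.direction}\t{r.replica_id}\t{r.work:.17g}\n")


BENCHMARK_COLUMNS = ["complex_id", "system_id", "dg_pred", "dg_pred_err", "dg_exp"]


def read_benchmark_table(path: str):
    """Read a benchmark TSV (complex_id, system_id, dg_pred, dg_pred_err, dg_exp)."""
    from .core import BenchmarkTable

    df, _ = _read_tsv(path, BENCHMARK_COLUMNS)
    return BenchmarkTable.from_frame(df)


def write_benchmark_table(tbl, path: str) -> None:
    """Write a :class:`BenchmarkTable` to the canonical benchmark TSV."""
    tbl.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, FreeEnergyEstimate):
        return obj.to_dict()
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def _check_finite(obj: Any, path: str = "") -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_finite(v, f"{path}.{k}" if path else str(k))
    elif isinstance(obj, list):
        for i, v in enumerate(obj):
            _check_finite(v, f"{path}[{i}]")
    elif isinstance(obj, float) and not math.isfinite(obj):
        raise ValidationError(f"non-finite value at {path!r} in report bundle")


def write_report(results: Any, path: str) -> None:
    """Serialize an estimate/diagnostic bundle to structured JSON.

    The report embeds the package version; non-finite numbers anywhere in
    the bundle are rejected.
    """
    payload = {"abfekit_version": __version__, "results": _jsonify(results)}
    _check_finite(payload["results"])
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
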