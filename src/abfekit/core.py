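"""Domain types for ensemble alchemical absolute binding free energy analysis.

Units are uniform across the package: energies in kcal/mol, times in ps
(replica lengths in ns where noted), temperatures in kelvin.  Replica
identifiers are 1-based integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import CompletenessError, DegenerateInputError, ValidationError

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_MOL_K = 0.0019872041

#: Legs of the double-decoupling cycle that are sampled by simulation.
LEGS = ("complex_alchemical", "complex_restraints", "ligand_alchemical")


@dataclass(frozen=True)
class ThermoContext:
    """Thermodynamic state of the analysis (temperature only).

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.  Default 300 K, the production
        temperature of the protocols this package post-processes.
    """

    temperature: float = 300.0

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValidationError("temperature must be positive (kelvin)")

    @property
    def kT(self) -> float:
        """Thermal energy k_B·T in kcal/mol (≈0.5962 at 300 K)."""
        return KB_KCAL_MOL_K * self.temperature


@dataclass(frozen=True)
class LambdaSchedule:
    """An ordered set of alchemical coupling values λ ∈ [0, 1].

    ``values`` must be strictly increasing, start at 0.0 and end at 1.0.
    """

    name: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise ValidationError("schedule needs at least two λ-windows")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValidationError("λ values must be strictly increasing")
        if vals[0] != 0.0 or vals[-1] != 1.0:
            raise ValidationError("schedule must span λ = 0.0 ... 1.0")

    def __len__(self) -> int:
        return len(self.values)

    def index_of(self, lam: float, tol: float = 1e-9) -> int:
        """Index of the window matching ``lam`` within ``tol``."""
        arr = np.asarray(self.values)
        i = int(np.argmin(np.abs(arr - lam)))
        if abs(arr[i] - lam) > tol:
            raise ValidationError(f"λ={lam!r} not in schedule {self.name!r}")
        return i


@dataclass(frozen=True)
class GradientSeries:
    """∂H/∂λ samples of one replica at one λ-window.

    ``times`` (ps), when present, must be strictly increasing and aligned
    with ``samples``.
    """

    replica_id: int
    lam: float
    samples: tuple[float, ...]
    times: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.replica_id < 1:
            raise ValidationError("replica_id must be >= 1")
        samples = tuple(float(s) for s in self.samples)
        object.__setattr__(self, "samples", samples)
        if len(samples) == 0:
            raise ValidationError("samples must be non-empty")
        if self.times is not None:
            times = tuple(float(t) for t in self.times)
            object.__setattr__(self, "times", times)
            if len(times) != len(samples):
                raise ValidationError("times and samples lengths differ")
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValidationError("times must be strictly increasing")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.samples, dtype=float)


@dataclass(frozen=True)
class EnsembleGradients:
    """Replica-resolved ∂H/∂λ samples over a full λ-schedule of one leg.

    The (λ, replica) grid must be rectangular: every replica present at
    every λ-window of the schedule.
    """

    leg: str
    schedule: LambdaSchedule
    series: tuple[GradientSeries, ...]

    def __post_init__(self) -> None:
        if self.leg not in LEGS:
            raise ValidationError(f"unknown leg {self.leg!r}; expected one of {LEGS}")
        series = tuple(self.series)
        object.__setattr__(self, "series", series)
        lams = set()
        replicas = set()
        seen = set()
        for s in series:
            i = self.schedule.index_of(s.lam)
            key = (i, s.replica_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate series for λ-index {i}, replica {s.replica_id}"
                )
            seen.add(key)
            lams.add(i)
            replicas.add(s.replica_id)
        missing = [
            (self.schedule.values[i], r)
            for i in range(len(self.schedule))
            for r in sorted(replicas)
            if (i, r) not in seen
        ]
        if lams != set(range(len(self.schedule))) or missing:
            raise CompletenessError(
                "non-rectangular (λ, replica) grid; missing cells: "
                + ", ".join(f"(λ={l}, replica={r})" for l, r in missing[:20])
            )
        if not replicas:
            raise ValidationError("no gradient series supplied")

    @property
    def replica_ids(self) -> tuple[int, ...]:
        return tuple(sorted({s.replica_id for s in self.series}))

    @property
    def n_replicas(self) -> int:
        return len(self.replica_ids)

    def at_lambda(self, lam: float) -> tuple[GradientSeries, ...]:
        """All replica series at one λ-window, sorted by replica id."""
        i = self.schedule.index_of(lam)
        out = [s for s in self.series if self.schedule.index_of(s.lam) == i]
        return tuple(sorted(out, key=lambda s: s.replica_id))


@dataclass(frozen=True)
class WorkRecord:
    """A single nonequilibrium work value (kcal/mol).

    ``direction`` is ``"forward"`` for 0→1 transitions and ``"reverse"`` for
    1→0 transitions; ``replica_id`` tags the end-state equilibrium replica
    the transition started from.
    """

    direction: str
    replica_id: int
    work: float

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse"):
            raise ValidationError(
                f"direction must be 'forward' or 'reverse', got {self.direction!r}"
            )
        object.__setattr__(self, "work", float(self.work))


@dataclass(frozen=True)
class WorkSet:
    """Forward and reverse nonequilibrium work samples of one transformation."""

    records: tuple[WorkRecord, ...]
    transition_length_fwd: float = 0.0  # ps
    transition_length_rev: float = 0.0  # ps

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    def works(self, direction: str) -> np.ndarray:
        return np.asarray(
            [r.work for r in self.records if r.direction == direction], dtype=float
        )

    def replica_ids(self, direction: str) -> tuple[int, ...]:
        return tuple(
            sorted({r.replica_id for r in self.records if r.direction == direction})
        )

    def for_replica(self, replica_id: int, direction: str) -> np.ndarray:
        return np.asarray(
            [
                r.work
                for r in self.records
                if r.direction == direction and r.replica_id == replica_id
            ],
            dtype=float,
        )

    @property
    def n_forward(self) -> int:
        return sum(1 for r in self.records if r.direction == "forward")

    @property
    def n_reverse(self) -> int:
        return sum(1 for r in self.records if r.direction == "reverse")

    @property
    def bidirectional(self) -> bool:
        return self.n_forward > 0 and self.n_reverse > 0


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A ΔG value (kcal/mol) with its standard error and provenance."""

    value: float
    stderr: float
    method: str
    n_replicas: int = 1
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValidationError("ΔG value must be finite")
        if not math.isfinite(self.stderr) or self.stderr < 0:
            raise ValidationError("stderr must be finite and >= 0")
        if self.n_replicas < 1:
            raise ValidationError("n_replicas must be >= 1")
        object.__setattr__(self, "meta", dict(self.meta))

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "stderr": self.stderr,
            "method": self.method,
            "n_replicas": self.n_replicas,
            "meta": dict(self.meta),
        }


def _as_estimate(x: "FreeEnergyEstimate | float", method: str = "FIXED") -> FreeEnergyEstimate:
    if isinstance(x, FreeEnergyEstimate):
        return x
    return FreeEnergyEstimate(value=float(x), stderr=0.0, method=method)


@dataclass(frozen=True)
class CycleComponents:
    """The five ΔG terms of the double-decoupling cycle.

    Components may be :class:`FreeEnergyEstimate` objects or plain numbers
    (treated as exact).  ``dG_conf_prot`` may be 0, in which case the
    assembled estimate is flagged ``unadjusted``.
    """

    dG_alch_com: FreeEnergyEstimate
    dG_restr_com: FreeEnergyEstimate
    dG_alch_lig: FreeEnergyEstimate
    dG_restr_lig: FreeEnergyEstimate
    dG_conf_prot: FreeEnergyEstimate

    def __post_init__(self) -> None:
        for name in (
            "dG_alch_com",
            "dG_restr_com",
            "dG_alch_lig",
            "dG_restr_lig",
            "dG_conf_prot",
        ):
            object.__setattr__(self, name, _as_estimate(getattr(self, name)))


@dataclass(frozen=True)
class LegSpec:
    """Protocol parameters of one thermodynamic leg."""

    ensemble_size: int
    replica_length_ns: float
    n_lambda: int | None = None  # EQ only
    trns_per_rep: int | None = None  # NEQ only
    trans_len_fwd_ps: float | None = None  # NEQ only
    trans_len_rev_ps: float | None = None  # NEQ only

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValidationError("ensemble_size must be >= 1")
        if not (self.replica_length_ns > 0):
            raise ValidationError("replica_length_ns must be > 0")
        for name in ("n_lambda", "trns_per_rep"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("trans_len_fwd_ps", "trans_len_rev_ps"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise ValidationError(f"{name} must be > 0")


@dataclass(frozen=True)
class ProtocolSpec:
    """All tunable parameters of one ABFE protocol (both legs)."""

    method: str  # "EQ" | "NEQ"
    complex: LegSpec
    ligand: LegSpec
    neq_restraint_leg_equals_complex: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("EQ", "NEQ"):
            raise ValidationError("method must be 'EQ' or 'NEQ'")
        for leg_name in ("complex", "ligand"):
            leg: LegSpec = getattr(self, leg_name)
            if self.method == "EQ" and leg.n_lambda is None:
                raise ValidationError(f"EQ protocol requires n_lambda on {leg_name} leg")
            if self.method == "NEQ":
                if (
                    leg.trns_per_rep is None
                    or leg.trans_len_fwd_ps is None
                    or leg.trans_len_rev_ps is None
                ):
                    raise ValidationError(
                        f"NEQ protocol requires transition parameters on {leg_name} leg"
                    )

    def to_dict(self) -> dict:
        def leg_dict(leg: LegSpec) -> dict:
            return {k: v for k, v in vars(leg).items()}

        return {
            "method": self.method,
            "complex": leg_dict(self.complex),
            "ligand": leg_dict(self.ligand),
            "neq_restraint_leg_equals_complex": self.neq_restraint_leg_equals_complex,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProtocolSpec":
        return cls(
            method=d["method"],
            complex=LegSpec(**d["complex"]),
            ligand=LegSpec(**d["ligand"]),
            neq_restraint_leg_equals_complex=bool(
                d.get("neq_restraint_leg_equals_complex", True)
            ),
        )


@dataclass(frozen=True)
class BenchmarkRow:
    """Predicted vs experimental ΔG of one ligand–protein complex."""

    complex_id: str
    system_id: str
    dG_pred: float
    dG_pred_err: float
    dG_exp: float

    def __post_init__(self) -> None:
        if self.dG_pred_err < 0:
            raise ValidationError("dG_pred_err must be >= 0")


@dataclass(frozen=True)
class BenchmarkTable:
    """Benchmark of predicted against experimental binding free energies."""

    rows: tuple[BenchmarkRow, ...]

    def __post_init__(self) -> None:
        rows = tuple(self.rows)
        object.__setattr__(self, "rows", rows)
        ids = [r.complex_id for r in rows]
        if len(set(ids)) != len(ids):
            raise ValidationError("complex_id values must be unique")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def systems(self) -> tuple[str, ...]:
        return tuple(sorted({r.system_id for r in self.rows}))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "complex_id": [r.complex_id for r in self.rows],
                "system_id": [r.system_id for r in self.rows],
                "dg_pred": [r.dG_pred for r in self.rows],
                "dg_pred_err": [r.dG_pred_err for r in self.rows],
                "dg_exp": [r.dG_exp for r in self.rows],
            }
        )

    @classmethod
    def from_frame(cls, df) -> "BenchmarkTable":
        rows = tuple(
            BenchmarkRow(
                complex_id=str(r.complex_id),
                system_id=str(r.system_id),
                dG_pred=float(r.dg_pred),
                dG_pred_err=float(r.dg_pred_err),
                dG_exp=float(r.dg_exp),
            )
            for r in df.itertuples()
        )
        return cls(rows=rows)


def require_min_samples(values: Sequence[float], n: int, what: str) -> np.ndarray:
    """Validate a sample list and return it as a float array."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < n:
        raise DegenerateInputError(f"{what} requires at least {n} values")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{what} contains non-finite values")
    return arr
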