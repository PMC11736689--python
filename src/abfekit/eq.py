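"""Equilibrium (thermodynamic integration) free-energy estimation.

ΔG = ∫₀¹ ⟨∂H/∂λ⟩ dλ, with the angular brackets denoting ensemble averaging
over independent replicas.  Per-λ uncertainty comes from a bootstrap of the
energy derivatives followed by ensemble averaging; the per-window standard
errors are propagated through the trapezoid quadrature weights treating
λ-windows as independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import EnsembleGradients, FreeEnergyEstimate, GradientSeries, LambdaSchedule
from .exceptions import DegenerateInputError, ValidationError

#: The three λ-schedules used by the protocols this package post-processes.
_SCHEDULES: dict[str, tuple[float, ...]] = {
    # 13 windows for ligand (de)coupling in water and in the protein
    "coupling13": (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    # 15 windows when coupling and restraint release are performed together
    "combined15": (
        0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99, 1.0,
    ),
    # 12 windows for separate removal of Boresch restraints (ascending order)
    "restraints12": (0.0, 0.01, 0.025, 0.05, 0.075, 0.1, 0.15, 0.2, 0.3, 0.5, 0.75, 1.0),
}

#: λ below which ligand electrostatics remain fully extinguished.
ELEC_ONSET = 0.45


def builtin_schedule(name: str) -> LambdaSchedule:
    """Return one of the built-in λ-schedules.

    ``coupling13`` — ligand (de)coupling; ``combined15`` — simultaneous
    coupling and restraint release; ``restraints12`` — separate restraint
    removal (stored ascending).
    """
    try:
        values = _SCHEDULES[name]
    except KeyError:
        raise ValidationError(
            f"unknown schedule {name!r}; choose from {sorted(_SCHEDULES)}"
        ) from None
    return LambdaSchedule(name=name, values=values)


def coupling_weights(lam: float, leg: str = "coupling"):
    """Coupling weights (w_vdw, w_elec, w_restr) at one λ.

    Van der Waals interactions are switched linearly over the full λ range;
    electrostatics stay off up to λ = 0.45 and then grow linearly to 1.
    On the combined leg the Boresch restraint strength decays as 1 − λ;
    on the pure coupling leg no restraint weight applies (returned as None).
    """
    if not (0.0 <= lam <= 1.0):
        raise ValidationError(f"λ must be in [0, 1], got {lam}")
    if leg not in ("coupling", "combined"):
        raise ValidationError(f"leg must be 'coupling' or 'combined', got {leg!r}")
    w_vdw = float(lam)
    w_elec = 0.0 if lam <= ELEC_ONSET else (lam - ELEC_ONSET) / (1.0 - ELEC_ONSET)
    w_restr = 1.0 - lam if leg == "combined" else None
    return w_vdw, w_elec, w_restr


@dataclass(frozen=True)
class LambdaMeanProfile:
    """Per-λ ensemble-averaged ⟨∂H/∂λ⟩ with standard errors (kcal/mol)."""

    schedule: LambdaSchedule
    means: tuple[float, ...]
    stderrs: tuple[float, ...]

    def __post_init__(self) -> None:
        means = tuple(float(m) for m in self.means)
        stderrs = tuple(float(s) for s in self.stderrs)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "stderrs", stderrs)
        if len(means) != len(self.schedule) or len(stderrs) != len(self.schedule):
            raise ValidationError("profile lengths must match the schedule")
        if any(s < 0 for s in stderrs):
            raise ValidationError("stderrs must be >= 0")


def bootstrap_lambda_mean(
    series: Sequence[GradientSeries], n_boot: int = 1000, seed=None
) -> tuple[float, float]:
    """Bootstrap the ensemble-averaged ⟨∂H/∂λ⟩ at a single λ-window.

    Each bootstrap iteration resamples every replica's gradient samples with
    replacement, forms replica means, and ensemble-averages them over
    replicas.  Returns (mean of bootstrap means, SD of bootstrap means).

    When all replicas carry the same number of samples (the usual case),
    one resampling index matrix is shared across replicas, which makes the
    result exactly invariant to replica relabelling; otherwise each replica
    gets its own stream, consumed in sorted replica-id order.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    ordered = sorted(series, key=lambda s: s.replica_id)
    if not ordered:
        raise DegenerateInputError("need at least one replica")
    for s in ordered:
        if len(s.samples) < 2:
            raise DegenerateInputError(
                f"replica {s.replica_id} has a single sample; bootstrap undefined"
            )
    rng = np.random.default_rng(seed)
    counts = {len(s.samples) for s in ordered}
    if len(counts) == 1:
        n = counts.pop()
        data = np.stack([s.array for s in ordered])  # (R, n)
        idx = rng.integers(0, n, size=(n_boot, n))
        # (R, n_boot): replica means over the shared resampled time indices.
        # Rows are sorted before averaging so the summation order (and hence
        # the result, bit for bit) is independent of replica labelling.
        replica_means = data[:, idx].mean(axis=2)
        boot = np.sort(replica_means, axis=0).mean(axis=0)
    else:
        per_replica = []
        for s in ordered:
            arr = s.array
            idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
            per_replica.append(arr[idx].mean(axis=1))
        boot = np.stack(per_replica).mean(axis=0)
    return float(boot.mean()), float(boot.std())


def trapezoid_weights(lambdas: np.ndarray) -> np.ndarray:
    """Quadrature weights of the composite trapezoid rule on a λ grid."""
    lam = np.asarray(lambdas, dtype=float)
    w = np.empty_like(lam)
    w[0] = (lam[1] - lam[0]) / 2.0
    w[-1] = (lam[-1] - lam[-2]) / 2.0
    w[1:-1] = (lam[2:] - lam[:-2]) / 2.0
    return w


def ti_integrate(profile: LambdaMeanProfile) -> FreeEnergyEstimate:
    """Trapezoidal quadrature of a ⟨∂H/∂λ⟩ profile with error propagation.

    stderr = sqrt(Σ_k w_k² σ_k²) with trapezoid weights w_k, treating
    λ-windows as statistically independent.
    """
    lam = np.asarray(profile.schedule.values, dtype=float)
    means = np.asarray(profile.means, dtype=float)
    stderrs = np.asarray(profile.stderrs, dtype=float)
    if not np.all(np.isfinite(means)):
        raise ValidationError("non-finite per-λ mean in profile")
    value = float(np.trapezoid(means, x=lam))
    w = trapezoid_weights(lam)
    stderr = float(np.sqrt(np.sum(w**2 * stderrs**2)))
    return FreeEnergyEstimate(
        value=value,
        stderr=stderr,
        method="TI",
        n_replicas=1,
        meta={"n_lambda": int(lam.size)},
    )


def eq_free_energy(
    data: EnsembleGradients, n_boot: int = 1000, seed: int = 2024
) -> FreeEnergyEstimate:
    """Ensemble-TI free energy of one alchemical leg.

    Thin wrapper over :class:`abfekit.estimators.ThermodynamicIntegration`:
    bootstraps the ensemble average at every λ-window, then integrates the
    profile.  Deterministic for a given seed.
    """
    from .estimators import ThermodynamicIntegration

    return ThermodynamicIntegration(n_boot=n_boot, random_state=seed).fit(data).estimate_


def running_average_by_ensemble_size(per_replica_dG: Sequence[float]) -> np.ndarray:
    """Cumulative means of per-replica ΔG values, ordered by ensemble size.

    Element k is the mean of the first k values — the estimate one would
    report with an ensemble of size k.
    """
    arr = np.asarray(per_replica_dG, dtype=float)
    if arr.size == 0:
        raise ValidationError("per-replica ΔG list must be non-empty")
    return np.cumsum(arr) / np.arange(1, arr.size + 1)
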