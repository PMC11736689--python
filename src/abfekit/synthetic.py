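"""Synthetic data with analytic ground truth for estimator validation.

The stand-in for an alchemical leg is a one-dimensional harmonic oscillator
whose stiffness interpolates linearly between end states,
k(λ) = (1−λ)k0 + λk1, so that ∂H/∂λ = ½(k1−k0)x² and the exact free-energy
difference is ΔG = (kT/2)·ln(k1/k0).  This is the simplest system in which
thermodynamic integration, free-energy perturbation, Jarzynski and Crooks
estimates all have closed forms.  Work samples can be drawn either from
the Gaussian fluctuation-theorem-consistent family or from genuine
out-of-equilibrium overdamped (Ornstein–Uhlenbeck) switching dynamics.

Every generator is bit-reproducible for a fixed seed; replica streams are
split with ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import math

import numpy as np

from .core import (
    EnsembleGradients,
    GradientSeries,
    LambdaSchedule,
    ThermoContext,
    WorkRecord,
    WorkSet,
)
from .exceptions import ValidationError


class HarmonicModel:
    """Harmonic alchemical toy system with end-state stiffnesses k0, k1."""

    def __init__(self, k0: float, k1: float, kT: float):
        if not (k0 > 0 and k1 > 0):
            raise ValidationError("spring constants must be positive")
        if not (kT > 0):
            raise ValidationError("kT must be positive")
        self.k0 = float(k0)
        self.k1 = float(k1)
        self.kT = float(kT)

    def stiffness(self, lam: float) -> float:
        return (1.0 - lam) * self.k0 + lam * self.k1

    def hamiltonian(self, lam: float, x) -> np.ndarray:
        return 0.5 * self.stiffness(lam) * np.square(x)

    def dhdl(self, x) -> np.ndarray:
        return 0.5 * (self.k1 - self.k0) * np.square(x)

    @property
    def dG_true(self) -> float:
        """Exact ΔG = (kT/2)·ln(k1/k0)."""
        return 0.5 * self.kT * math.log(self.k1 / self.k0)

    def mean_dhdl(self, lam: float) -> float:
        """Analytic ⟨∂H/∂λ⟩ = ½(k1−k0)·kT/k(λ)."""
        return 0.5 * (self.k1 - self.k0) * self.kT / self.stiffness(lam)


def harmonic_ti_ensemble(
    m: HarmonicModel,
    schedule: LambdaSchedule,
    ensemble_size: int,
    n_samples: int,
    seed: int,
    leg: str = "ligand_alchemical",
) -> tuple[EnsembleGradients, float]:
    """Replica-resolved equilibrium ∂H/∂λ samples at every λ-window.

    At each (λ, replica) cell, positions are drawn from the exact Boltzmann
    distribution x ~ N(0, kT/k(λ)) on a replica-specific stream, and the
    gradient ½(k1−k0)x² is emitted.  Returns the ensemble and the exact ΔG.
    """
    if ensemble_size < 1 or n_samples < 1:
        raise ValidationError("ensemble_size and n_samples must be >= 1")
    children = np.random.SeedSequence(seed).spawn(ensemble_size)
    series = []
    for r, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        for lam in schedule.values:
            sd = math.sqrt(m.kT / m.stiffness(lam))
            x = rng.normal(0.0, sd, size=n_samples)
            series.append(
                GradientSeries(
                    replica_id=r,
                    lam=lam,
                    samples=tuple(m.dhdl(x)),
                    times=tuple(2.0 * (i + 1) for i in range(n_samples)),
                )
            )
    data = EnsembleGradients(leg=leg, schedule=schedule, series=tuple(series))
    return data, m.dG_true


def gaussian_work_set(
    dG: float,
    sigma: float,
    n_fwd: int,
    n_rev: int,
    n_replicas: int,
    ctx: ThermoContext | None = None,
    seed: int = 0,
) -> WorkSet:
    """Gaussian work samples exactly consistent with the Crooks relation.

    Forward works ~ N(dG + σ²/2kT, σ²), reverse works ~ N(−dG + σ²/2kT, σ²):
    the mean dissipated work σ²/2kT is the same in both directions, so the
    pair satisfies the fluctuation theorem in distribution.  Records are
    tagged evenly across ``n_replicas`` replica ids.
    """
    ctx = ctx or ThermoContext()
    if not (sigma > 0):
        raise ValidationError("sigma must be positive")
    if n_fwd % n_replicas or n_rev % n_replicas:
        raise ValidationError("work counts must be divisible by n_replicas")
    kT = ctx.kT
    diss = sigma**2 / (2.0 * kT)
    rng = np.random.default_rng(seed)
    wf = rng.normal(dG + diss, sigma, size=n_fwd)
    wr = rng.normal(-dG + diss, sigma, size=n_rev)
    records = []
    for i, w in enumerate(wf):
        records.append(
            WorkRecord(direction="forward", replica_id=1 + i % n_replicas, work=w)
        )
    for i, w in enumerate(wr):
        records.append(
            WorkRecord(direction="reverse", replica_id=1 + i % n_replicas, work=w)
        )
    return WorkSet(records=tuple(records))


def ou_switching_work(
    m: HarmonicModel,
    n_steps: int,
    dt: float,
    relax_time: float,
    n_transitions: int,
    direction: str = "forward",
    seed: int = 0,
) -> np.ndarray:
    """Work samples from overdamped switching of the harmonic system.

    Each transition starts from the exact equilibrium of its initial end
    state and propagates x with exact Ornstein–Uhlenbeck updates in the
    instantaneous potential while λ is switched linearly over ``n_steps``;
    the work accumulates as Σ [H(λ_{i+1}, x_i) − H(λ_i, x_i)].  The
    friction is chosen so that the λ=0 potential relaxes on ``relax_time``
    (ps); slower switching dissipates less.  Stored work follows the
    transition's own direction, so reverse works average to −ΔG plus
    dissipation.
    """
    if n_steps < 1:
        raise ValidationError("n_steps must be >= 1")
    if not (dt > 0 and relax_time > 0):
        raise ValidationError("dt and relax_time must be positive")
    if direction not in ("forward", "reverse"):
        raise ValidationError("direction must be 'forward' or 'reverse'")
    rng = np.random.default_rng(seed)
    lams = np.linspace(0.0, 1.0, n_steps + 1)
    if direction == "reverse":
        lams = lams[::-1]
    gamma = relax_time * m.k0  # friction: τ(λ) = γ/k(λ), τ(0) = relax_time
    k_init = m.stiffness(lams[0])
    x = rng.normal(0.0, math.sqrt(m.kT / k_init), size=n_transitions)
    work = np.zeros(n_transitions)
    for lam_a, lam_b in zip(lams[:-1], lams[1:]):
        work += m.hamiltonian(lam_b, x) - m.hamiltonian(lam_a, x)
        k = m.stiffness(lam_b)
        a = math.exp(-k * dt / gamma)
        noise_sd = math.sqrt(m.kT / k * (1.0 - a * a))
        x = a * x + rng.normal(0.0, noise_sd, size=n_transitions)
    return work


def ou_switching_work_set(
    m: HarmonicModel,
    n_steps: int,
    dt: float,
    relax_time: float,
    n_transitions: int,
    n_replicas: int = 1,
    seed: int = 0,
) -> WorkSet:
    """Bidirectional :class:`WorkSet` from OU switching, tagged by replica."""
    if n_transitions % n_replicas:
        raise ValidationError("n_transitions must be divisible by n_replicas")
    ss = np.random.SeedSequence(seed).spawn(2)
    records = []
    for direction, child in zip(("forward", "reverse"), ss):
        works = ou_switching_work(
            m, n_steps, dt, relax_time, n_transitions, direction, child
        )
        for i, w in enumerate(works):
            records.append(
                WorkRecord(direction=direction, replica_id=1 + i % n_replicas, work=w)
            )
    return WorkSet(
        records=tuple(records),
        transition_length_fwd=n_steps * dt,
        transition_length_rev=n_steps * dt,
    )


def inject_extremes(
    ws: WorkSet, count: int, magnitude: float = 1500.0, seed: int = 0
) -> WorkSet:
    """Append ``count`` extreme forward work records (work ≥ ``magnitude``).

    Emulates the occasional extreme forward work values seen when coupling
    a ligand in the protein environment.  ``magnitude`` must exceed the
    1000 kcal/mol filter cutoff so that filtering removes exactly the
    injected records.
    """
    if magnitude < 1001.0:
        raise ValidationError("magnitude must be >= 1001 kcal/mol")
    if count < 0 or count > ws.n_forward:
        raise ValidationError("count must be between 0 and the forward record count")
    if count == 0:
        return ws
    rng = np.random.default_rng(seed)
    ids = ws.replica_ids("forward") or (1,)
    extremes = tuple(
        WorkRecord(
            direction="forward",
            replica_id=int(rng.choice(ids)),
            work=float(magnitude + 100.0 * rng.random()),
        )
        for _ in range(count)
    )
    return WorkSet(
        records=ws.records + extremes,
        transition_length_fwd=ws.transition_length_fwd,
        transition_length_rev=ws.transition_length_rev,
    )


def skewed_dg_ensemble(
    mu: float, scale: float, alpha: float, n: int, seed: int = 0
) -> np.ndarray:
    """Skew-normal ΔG ensemble for non-normality diagnostics.

    The analytic skewness for shape parameter α is
    ((4−π)/2)·(δ√(2/π))³ / (1−2δ²/π)^{3/2} with δ = α/√(1+α²).
    """
    if not (scale > 0):
        raise ValidationError("scale must be positive")
    if n < 4:
        raise ValidationError("n must be >= 4")
    from scipy.stats import skewnorm

    rng = np.random.default_rng(seed)
    return skewnorm.rvs(alpha, loc=mu, scale=scale, size=n, random_state=rng)


def skewnorm_skewness(alpha: float) -> float:
    """Closed-form skewness of the skew-normal distribution."""
    delta = alpha / math.sqrt(1.0 + alpha**2)
    num = (4.0 - math.pi) / 2.0 * (delta * math.sqrt(2.0 / math.pi)) ** 3
    den = (1.0 - 2.0 * delta**2 / math.pi) ** 1.5
    return num / den
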