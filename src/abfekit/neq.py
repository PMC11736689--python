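"""Nonequilibrium free-energy estimation from work distributions.

Work values are obtained by integrating ∂H/∂λ over fast alchemical
transitions.  The bidirectional estimate solves the Bennett/Crooks
maximum-likelihood self-consistency equation; the unidirectional estimate
is the Jarzynski exponential average.  Stored work is the work done on the
system along its own transition direction, so the fluctuation-theorem
pairing compares forward works W_f against negated reverse works −W_r.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .core import (
    FreeEnergyEstimate,
    GradientSeries,
    ThermoContext,
    WorkRecord,
    WorkSet,
)
from .exceptions import (
    ConvergenceError,
    DegenerateInputError,
    FormatError,
    ValidationError,
)

#: Work values above this magnitude (kcal/mol) are discarded before estimation.
EXTREME_WORK_CUTOFF = 1000.0


def integrate_work(series: GradientSeries, lambda_path: Sequence[float]) -> float:
    """Work of one transition: trapezoidal ∫ (∂H/∂λ) dλ along the λ(t) path.

    The path must be strictly monotone, 0→1 (forward) or 1→0 (reverse);
    the sign of the returned work follows the path direction.
    """
    lam = np.asarray(lambda_path, dtype=float)
    dhdl = series.array
    if lam.size != dhdl.size:
        raise FormatError(
            f"λ-path length {lam.size} does not match {dhdl.size} gradient samples"
        )
    d = np.diff(lam)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValidationError("λ-path must be strictly monotone")
    return float(np.trapezoid(dhdl, x=lam))


def filter_extreme_work(
    ws: WorkSet, cutoff: float = EXTREME_WORK_CUTOFF
) -> tuple[WorkSet, int, int]:
    """Drop work records above ``cutoff`` (kcal/mol); idempotent.

    Extreme forward work values occur occasionally when the ligand is
    coupled in the protein environment and degrade both accuracy and
    precision if retained.  Returns (filtered set, removed forward count,
    removed reverse count).
    """
    if not (cutoff > 0):
        raise ValidationError("cutoff must be positive")
    kept, removed_fwd, removed_rev = [], 0, 0
    for r in ws.records:
        if r.work > cutoff:
            if r.direction == "forward":
                removed_fwd += 1
            else:
                removed_rev += 1
        else:
            kept.append(r)
    filtered = WorkSet(
        records=tuple(kept),
        transition_length_fwd=ws.transition_length_fwd,
        transition_length_rev=ws.transition_length_rev,
    )
    for direction, before, after in (
        ("forward", ws.n_forward, filtered.n_forward),
        ("reverse", ws.n_reverse, filtered.n_reverse),
    ):
        if before > 0 and after == 0:
            raise DegenerateInputError(
                f"filtering removed every {direction} work value"
            )
    return filtered, removed_fwd, removed_rev


def _bar_objective(dg: float, wf: np.ndarray, wr: np.ndarray, kT: float) -> float:
    """Bennett self-consistency residual (monotone increasing in dg)."""
    M = np.log(wf.size / wr.size)
    fwd = expit(-(M + (wf - dg) / kT))
    rev = expit(-(-M + (wr + dg) / kT))
    return float(fwd.sum() - rev.sum())


def solve_bar(
    wf: np.ndarray,
    wr: np.ndarray,
    kT: float,
    tol: float = 1e-8,
    bracket: float = 1e4,
) -> float:
    """Root of the Bennett/Crooks maximum-likelihood equation (kcal/mol)."""
    lo, hi = -bracket, bracket
    flo = _bar_objective(lo, wf, wr, kT)
    fhi = _bar_objective(hi, wf, wr, kT)
    # the objective is monotone increasing in dg; a strict sign change is
    # required — a flat zero at a bracket end means the two distributions
    # are so far apart that no sample constrains the estimate
    if not (flo < 0.0 < fhi):
        raise ConvergenceError(
            "no bracketing root for the maximum-likelihood equation within "
            f"±{bracket} kcal/mol; check work-distribution overlap"
        )
    dg = float(brentq(_bar_objective, lo, hi, args=(wf, wr, kT), xtol=tol))
    # guard against a flat zero plateau between far-separated distributions:
    # if every sample's likelihood weight underflows at the solution, the
    # root is uninformative
    M = np.log(wf.size / wr.size)
    x = M + (np.concatenate([wf, -wr]) - dg) / kT
    if float(np.max(expit(x) * expit(-x))) == 0.0:
        raise ConvergenceError(
            "work distributions do not overlap; maximum-likelihood estimate "
            "is unconstrained"
        )
    return dg


def bar_analytic_stderr(
    wf: np.ndarray, wr: np.ndarray, dg: float, kT: float
) -> float:
    """Asymptotic standard error of the maximum-likelihood estimate.

    Bennett's variance expression evaluated at the solution, over the
    combined sample of forward works and negated reverse works.
    """
    nf, nr = wf.size, wr.size
    n = nf + nr
    M = np.log(nf / nr)
    u = np.concatenate([wf, -wr]) / kT
    x = M + u - dg / kT
    # 1/(2+2cosh x), computed stably via the logistic function
    ksi = expit(x) * expit(-x)
    mean_ksi = float(ksi.mean())
    var = (1.0 / mean_ksi - (n / nf + n / nr)) / n
    return kT * float(np.sqrt(max(var, 0.0)))


def bar_mle(ws: WorkSet, ctx: ThermoContext | None = None) -> FreeEnergyEstimate:
    """Bidirectional maximum-likelihood (Crooks/BAR) ΔG from a work set.

    Thin wrapper over :class:`abfekit.estimators.CrooksBAR` with the
    analytic (asymptotic) standard error.
    """
    from .estimators import CrooksBAR

    ctx = ctx or ThermoContext()
    est = CrooksBAR(temperature=ctx.temperature, uncertainty="analytic").fit(ws)
    return est.estimate_


def jarzynski(
    works: Sequence[float], ctx: ThermoContext | None = None
) -> FreeEnergyEstimate:
    """Unidirectional Jarzynski estimate ΔG = −kT·ln⟨exp(−W/kT)⟩.

    Computed with log-sum-exp stabilization.  Forward works estimate the
    +ΔG of the forward process; the estimator is biased at finite sample
    size and never exceeds the mean work.
    """
    from .estimators import JarzynskiEstimator

    ctx = ctx or ThermoContext()
    est = JarzynskiEstimator(temperature=ctx.temperature).fit(np.asarray(works, float))
    return est.estimate_


def jarzynski_value(works: np.ndarray, kT: float) -> float:
    """Log-sum-exp core of the Jarzynski estimator."""
    w = np.asarray(works, dtype=float)
    if w.size == 0:
        raise DegenerateInputError("need at least one work value")
    if not np.all(np.isfinite(w)):
        raise ValidationError("work values must be finite")
    return float(-kT * (logsumexp(-w / kT) - np.log(w.size)))


def neq_free_energy(ws: WorkSet, ctx: ThermoContext | None = None) -> FreeEnergyEstimate:
    """Pooled Crooks/BAR ΔG with between-replica uncertainty.

    The value pools all work records; the standard error is the sample
    SD/√R of the R per-replica maximum-likelihood estimates, each replica
    using only the works tagged with its id in both directions.
    """
    from .estimators import CrooksBAR

    ctx = ctx or ThermoContext()
    est = CrooksBAR(temperature=ctx.temperature, uncertainty="replica").fit(ws)
    return est.estimate_
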