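"""scikit-learn-style free-energy estimators.

Each estimator follows the sklearn contract: hyperparameters in
``__init__`` (exposed through ``get_params``/``set_params``), a ``fit``
method taking the data container, and fitted attributes with a trailing
underscore.  The module-level functions in :mod:`abfekit.eq` and
:mod:`abfekit.neq` are thin wrappers over these classes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .core import (
    EnsembleGradients,
    FreeEnergyEstimate,
    ThermoContext,
    WorkSet,
)
from .eq import LambdaMeanProfile, bootstrap_lambda_mean, ti_integrate
from .exceptions import DegenerateInputError, ValidationError
from .neq import bar_analytic_stderr, jarzynski_value, solve_bar


class ThermodynamicIntegration(BaseEstimator):
    """Ensemble-TI estimator: bootstrap per λ-window, trapezoid quadrature.

    Parameters
    ----------
    n_boot : int, default=1000
        Bootstrap iterations per λ-window (minimum 100).
    random_state : int, default=2024
        Seed of the bootstrap stream; one child stream is spawned per
        λ-window so the estimate is reproducible bit-for-bit.

    Attributes
    ----------
    dg_ : float
        Estimated ΔG of the leg, kcal/mol.
    stderr_ : float
        Standard error propagated through the quadrature weights.
    profile_ : LambdaMeanProfile
        Bootstrapped per-λ ensemble means and standard errors.
    n_replicas_ : int
        Ensemble size of the input data.
    estimate_ : FreeEnergyEstimate
        Full result object with method tag ``TI``.
    """

    def __init__(self, n_boot: int = 1000, random_state: int = 2024):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X: EnsembleGradients, y=None) -> "ThermodynamicIntegration":
        if not isinstance(X, EnsembleGradients):
            raise ValidationError("ThermodynamicIntegration.fit expects EnsembleGradients")
        schedule = X.schedule
        children = np.random.SeedSequence(self.random_state).spawn(len(schedule))
        means, stderrs = [], []
        for k, lam in enumerate(schedule.values):
            m, s = bootstrap_lambda_mean(
                X.at_lambda(lam), n_boot=self.n_boot, seed=children[k]
            )
            means.append(m)
            stderrs.append(s)
        self.profile_ = LambdaMeanProfile(
            schedule=schedule, means=tuple(means), stderrs=tuple(stderrs)
        )
        base = ti_integrate(self.profile_)
        self.n_replicas_ = X.n_replicas
        self.dg_ = base.value
        self.stderr_ = base.stderr
        self.estimate_ = FreeEnergyEstimate(
            value=base.value,
            stderr=base.stderr,
            method="TI",
            n_replicas=X.n_replicas,
            meta={
                "leg": X.leg,
                "schedule": schedule.name,
                "n_boot": int(self.n_boot),
                "seed": int(self.random_state),
            },
        )
        return self


class CrooksBAR(BaseEstimator):
    """Bidirectional maximum-likelihood (Crooks/BAR) estimator.

    Solves the Bennett self-consistency equation by bracketed root finding.
    The uncertainty is either the asymptotic maximum-likelihood standard
    error (``uncertainty="analytic"``) or the standard error across
    per-replica subestimates (``uncertainty="replica"``), each replica's
    ΔG obtained from the works tagged with its id in both directions.

    Parameters
    ----------
    temperature : float, default=300.0
        Temperature in kelvin.
    uncertainty : {"analytic", "replica"}, default="analytic"
    tol : float, default=1e-8
        Root-finding tolerance, kcal/mol.
    bracket : float, default=1e4
        Half-width of the root bracket, kcal/mol.
    """

    def __init__(
        self,
        temperature: float = 300.0,
        uncertainty: str = "analytic",
        tol: float = 1e-8,
        bracket: float = 1e4,
    ):
        self.temperature = temperature
        self.uncertainty = uncertainty
        self.tol = tol
        self.bracket = bracket

    def fit(self, X: WorkSet, y=None) -> "CrooksBAR":
        if not isinstance(X, WorkSet):
            raise ValidationError("CrooksBAR.fit expects a WorkSet")
        if self.uncertainty not in ("analytic", "replica"):
            raise ValidationError("uncertainty must be 'analytic' or 'replica'")
        kT = ThermoContext(self.temperature).kT
        wf = X.works("forward")
        wr = X.works("reverse")
        if wf.size < 2 or wr.size < 2:
            raise DegenerateInputError(
                "need at least 2 work values in each direction for BAR"
            )
        dg = solve_bar(wf, wr, kT, tol=self.tol, bracket=self.bracket)
        meta: dict[str, object] = {
            "n_forward": int(wf.size),
            "n_reverse": int(wr.size),
            "temperature_K": float(self.temperature),
            "uncertainty": self.uncertainty,
            "per_replica_pairing": "bidirectional MLE per equal replica index",
        }
        if self.uncertainty == "replica":
            ids_f = X.replica_ids("forward")
            ids_r = X.replica_ids("reverse")
            if set(ids_f) != set(ids_r):
                raise ValidationError(
                    "replica id sets differ between directions; per-replica "
                    "uncertainty requires matched ids"
                )
            bad = [
                rid
                for rid in ids_f
                if X.for_replica(rid, "forward").size < 2
                or X.for_replica(rid, "reverse").size < 2
            ]
            if bad:
                raise DegenerateInputError(
                    f"replicas with < 2 works in a direction: {bad}"
                )
            per_rep = np.array(
                [
                    solve_bar(
                        X.for_replica(rid, "forward"),
                        X.for_replica(rid, "reverse"),
                        kT,
                        tol=self.tol,
                        bracket=self.bracket,
                    )
                    for rid in ids_f
                ]
            )
            R = per_rep.size
            stderr = float(per_rep.std(ddof=1) / np.sqrt(R)) if R > 1 else 0.0
            self.per_replica_dg_ = per_rep
            self.n_replicas_ = R
            meta["per_replica_dg"] = [float(v) for v in per_rep]
        else:
            stderr = bar_analytic_stderr(wf, wr, dg, kT)
            self.n_replicas_ = 1
        self.dg_ = dg
        self.stderr_ = stderr
        self.estimate_ = FreeEnergyEstimate(
            value=dg,
            stderr=stderr,
            method="BAR_MLE",
            n_replicas=self.n_replicas_,
            meta=meta,
        )
        return self


class JarzynskiEstimator(BaseEstimator):
    """Unidirectional exponential-average estimator.

    ΔG = −kT·ln⟨exp(−W/kT)⟩ over one direction's works, computed with
    log-sum-exp stabilization.  Biased at finite sample size; bounded
    above by the mean work (Jensen's inequality).
    """

    def __init__(self, temperature: float = 300.0):
        self.temperature = temperature

    def fit(self, X, y=None) -> "JarzynskiEstimator":
        kT = ThermoContext(self.temperature).kT
        w = np.asarray(X, dtype=float).ravel()
        self.dg_ = jarzynski_value(w, kT)
        self.stderr_ = 0.0
        self.n_samples_ = int(w.size)
        self.estimate_ = FreeEnergyEstimate(
            value=self.dg_,
            stderr=0.0,
            method="JARZYNSKI",
            n_replicas=1,
            meta={"n_works": int(w.size), "temperature_K": float(self.temperature)},
        )
        return self
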