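"""Protocol cost model and reliability-driven parameter escalation.

Costs count aggregate simulation time per ABFE prediction.  An equilibrium
leg costs n_λ × ensemble × replica-length; a nonequilibrium leg costs the
two end-state equilibrium ensembles plus all fast transitions.  Escalation
adjusts one parameter at a time, in a set order, until both reliability
criteria (standard error and, for NEQ, distance) pass or all caps are hit.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

from .core import LegSpec, ProtocolSpec
from .exceptions import ValidationError


@dataclass(frozen=True)
class CostBreakdown:
    """Per-leg aggregate simulation time (ns) and the overall total (μs)."""

    complex_alchemical_ns: float
    complex_restraints_ns: float
    ligand_alchemical_ns: float

    @property
    def overall_us(self) -> float:
        return (
            self.complex_alchemical_ns
            + self.complex_restraints_ns
            + self.ligand_alchemical_ns
        ) / 1000.0

    def to_dict(self) -> dict:
        return {
            "complex_alchemical_ns": self.complex_alchemical_ns,
            "complex_restraints_ns": self.complex_restraints_ns,
            "ligand_alchemical_ns": self.ligand_alchemical_ns,
            "overall_us": self.overall_us,
        }


def _leg_cost_ns(leg: LegSpec, method: str) -> float:
    if method == "EQ":
        return leg.n_lambda * leg.ensemble_size * leg.replica_length_ns
    # NEQ: two end-state equilibrium ensembles plus the fast transitions
    eq_part = 2.0 * leg.ensemble_size * leg.replica_length_ns
    n_trans = leg.trns_per_rep * leg.ensemble_size
    trans_part = n_trans * (leg.trans_len_fwd_ps + leg.trans_len_rev_ps) / 1000.0
    return eq_part + trans_part


def protocol_cost(spec: ProtocolSpec) -> CostBreakdown:
    """Aggregate simulation cost of one ABFE prediction under ``spec``.

    With the combined coupling+restraint-release leg, an EQ protocol has no
    separate restraint-leg cost; an NEQ protocol's restraint leg is costed
    equal to the complex leg when ``neq_restraint_leg_equals_complex``.
    """
    complex_ns = _leg_cost_ns(spec.complex, spec.method)
    ligand_ns = _leg_cost_ns(spec.ligand, spec.method)
    if spec.method == "NEQ" and spec.neq_restraint_leg_equals_complex:
        restr_ns = complex_ns
    else:
        restr_ns = 0.0
    return CostBreakdown(
        complex_alchemical_ns=complex_ns,
        complex_restraints_ns=restr_ns,
        ligand_alchemical_ns=ligand_ns,
    )


def recommended_protocol(profile: str = "standard", method: str = "EQ") -> ProtocolSpec:
    """Recommended protocol parameters.

    ``standard``: ensemble 10 (complex) / 5 (ligand), 10 ns replicas, 50
    transitions per replica (every 200 ps), 800 ps forward / 400 ps reverse
    transitions for the complex and 400 ps for the ligand leg.
    ``minimum``: ensembles 5/5, 5 ns replicas, 25 transitions per replica,
    same transition lengths.  EQ λ-counts: 15 (combined complex leg), 13
    (ligand leg).
    """
    if profile not in ("standard", "minimum"):
        raise ValidationError(f"unknown profile {profile!r}")
    if method not in ("EQ", "NEQ"):
        raise ValidationError(f"unknown method {method!r}")
    ens_com = 10 if profile == "standard" else 5
    ens_lig = 5
    rep_len = 10.0 if profile == "standard" else 5.0
    if method == "EQ":
        return ProtocolSpec(
            method="EQ",
            complex=LegSpec(ensemble_size=ens_com, replica_length_ns=rep_len, n_lambda=15),
            ligand=LegSpec(ensemble_size=ens_lig, replica_length_ns=rep_len, n_lambda=13),
        )
    trns = 50 if profile == "standard" else 25
    return ProtocolSpec(
        method="NEQ",
        complex=LegSpec(
            ensemble_size=ens_com,
            replica_length_ns=rep_len,
            trns_per_rep=trns,
            trans_len_fwd_ps=800.0,
            trans_len_rev_ps=400.0,
        ),
        ligand=LegSpec(
            ensemble_size=ens_lig,
            replica_length_ns=rep_len,
            trns_per_rep=trns,
            trans_len_fwd_ps=400.0,
            trans_len_rev_ps=400.0,
        ),
        neq_restraint_leg_equals_complex=True,
    )


#: Default escalation ladders; the order is fixed, the intermediate step
#: values are package choices (only the caps are externally prescribed).
DEFAULT_ESCALATION = {
    "trns_per_rep_steps": (50, 75, 100),
    "trans_len_fwd_steps_ps": (800.0, 1000.0, 2000.0),
    "trans_len_rev_floor_ps": 400.0,
    "ensemble_increment": 5,
    "ensemble_cap": 100,
    "replica_length_factor": 2.0,
    "replica_length_cap_ns": 100.0,
}


@dataclass
class EscalationState:
    """Mutable record of a reliability-driven escalation run."""

    spec: ProtocolSpec
    step_history: list[tuple[str, float, float]] = field(default_factory=list)
    complete: bool = False
    exhausted: bool = False
    note: str = ""
    config: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_ESCALATION))

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "step_history": [list(h) for h in self.step_history],
            "complete": self.complete,
            "exhausted": self.exhausted,
            "note": self.note,
            "config": {
                k: list(v) if isinstance(v, tuple) else v for k, v in self.config.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EscalationState":
        cfg = copy.deepcopy(DEFAULT_ESCALATION)
        for k, v in d.get("config", {}).items():
            cfg[k] = tuple(v) if isinstance(v, list) else v
        return cls(
            spec=ProtocolSpec.from_dict(d["spec"]),
            step_history=[tuple(h) for h in d.get("step_history", [])],
            complete=bool(d.get("complete", False)),
            exhausted=bool(d.get("exhausted", False)),
            note=str(d.get("note", "")),
            config=cfg,
        )


def _next_in_ladder(current: float, steps: tuple) -> float | None:
    for s in steps:
        if s > current:
            return s
    return None


def escalation_step(state: EscalationState, flags: dict) -> EscalationState:
    """Advance one escalation step given the reliability flags.

    If both criteria pass the state is marked complete.  Otherwise, one
    parameter of the complex leg is raised: for NEQ, transitions per
    replica (to 100), then transition length (to 2 ns forward, reverse at
    half with a 400 ps floor), then ensemble size (+5 to 100), then replica
    length (×2 to 100 ns); for EQ, ensemble size then replica length.  When
    every cap is reached the state is marked exhausted — some systems may
    require breaching even these maxima.
    """
    if state.exhausted or state.complete:
        raise ValidationError("escalation state is already terminal")
    precision_ok = bool(flags.get("precision_ok", False))
    overlap_ok = flags.get("overlap_ok", None)
    if precision_ok and (overlap_ok is None or overlap_ok):
        out = copy.deepcopy(state)
        out.complete = True
        return out

    out = copy.deepcopy(state)
    spec = out.spec
    leg = spec.complex
    cfg = out.config

    def bump(param: str, old, new) -> None:
        out.spec = replace(spec, complex=replace(leg, **{param: new}))
        out.step_history.append((param, float(old), float(new)))

    if spec.method == "NEQ":
        nxt = _next_in_ladder(leg.trns_per_rep, cfg["trns_per_rep_steps"])
        if nxt is not None:
            bump("trns_per_rep", leg.trns_per_rep, int(nxt))
            return out
        nxt = _next_in_ladder(leg.trans_len_fwd_ps, cfg["trans_len_fwd_steps_ps"])
        if nxt is not None:
            new_rev = max(nxt / 2.0, cfg["trans_len_rev_floor_ps"])
            out.spec = replace(
                spec,
                complex=replace(leg, trans_len_fwd_ps=nxt, trans_len_rev_ps=new_rev),
            )
            out.step_history.append(("trans_len_fwd_ps", leg.trans_len_fwd_ps, nxt))
            return out
    if leg.ensemble_size < cfg["ensemble_cap"]:
        new = min(leg.ensemble_size + cfg["ensemble_increment"], cfg["ensemble_cap"])
        bump("ensemble_size", leg.ensemble_size, new)
        return out
    if leg.replica_length_ns < cfg["replica_length_cap_ns"]:
        new = min(
            leg.replica_length_ns * cfg["replica_length_factor"],
            cfg["replica_length_cap_ns"],
        )
        bump("replica_length_ns", leg.replica_length_ns, new)
        return out
    out.exhausted = True
    out.note = (
        "all escalation caps reached; some systems may need to breach "
        "even these maximum values"
    )
    return out
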