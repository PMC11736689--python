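"""Cycle assembly, Boresch restraint term, adjustment, accuracy metrics."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from abfekit.core import (
    BenchmarkRow,
    BenchmarkTable,
    CycleComponents,
    FreeEnergyEstimate,
    ThermoContext,
)
from abfekit.cycle import (
    BoreschParams,
    accuracy_metrics,
    assemble_cycle,
    boresch_restraint_dg,
    conf_correction,
)
from abfekit.exceptions import DegenerateInputError, ValidationError


def restraint_quadrature_oracle(p: BoreschParams, kT: float) -> float:
    """Independent oracle: the restrained configurational integral evaluated
    by direct quadrature (the 6-D integral factorizes over coordinates)."""

    def z_r():
        return quad(
            lambda r: r * r * math.exp(-0.5 * p.Kr * (r - p.r0) ** 2 / kT),
            0.0,
            p.r0 + 20.0,
        )[0]

    def z_theta(K, th0):
        return quad(
            lambda t: math.sin(t) * math.exp(-0.5 * K * (t - th0) ** 2 / kT),
            0.0,
            math.pi,
        )[0]

    def z_phi(K):
        return quad(lambda f: math.exp(-0.5 * K * f * f / kT), -math.pi, math.pi)[0]

    z = (
        z_r()
        * z_theta(p.KthetaA, p.thetaA0)
        * z_theta(p.KthetaB, p.thetaB0)
        * z_phi(p.KphiA)
        * z_phi(p.KphiB)
        * z_phi(p.KphiC)
    )
    return -kT * math.log(8.0 * math.pi**2 * p.V0 / z)


TYPICAL = dict(
    r0=5.0,
    thetaA0=math.pi / 2,
    thetaB0=math.pi / 2,
    Kr=10.0,
    KthetaA=10.0,
    KthetaB=10.0,
    KphiA=10.0,
    KphiB=10.0,
    KphiC=10.0,
)


class TestBoreschRestraint:
    def test_matches_quadrature_oracle_in_stiff_regime(self, ctx300):
        p = BoreschParams(**TYPICAL)
        closed = boresch_restraint_dg(p, ctx300).value
        oracle = restraint_quadrature_oracle(p, ctx300.kT)
        assert closed == pytest.approx(oracle, abs=0.05)

    def test_doubling_v0_shifts_by_minus_kT_ln2(self, ctx300):
        p1 = BoreschParams(**TYPICAL)
        p2 = BoreschParams(**TYPICAL, V0=2 * 1660.0)
        shift = boresch_restraint_dg(p2, ctx300).value - boresch_restraint_dg(p1, ctx300).value
        assert shift == pytest.approx(-ctx300.kT * math.log(2.0), abs=1e-12)

    def test_scaling_all_constants_by_four(self, ctx300):
        p1 = BoreschParams(**TYPICAL)
        scaled = {k: (4 * v if k.startswith("K") else v) for k, v in TYPICAL.items()}
        p2 = BoreschParams(**scaled)
        shift = boresch_restraint_dg(p2, ctx300).value - boresch_restraint_dg(p1, ctx300).value
        assert shift == pytest.approx(-3.0 * ctx300.kT * math.log(4.0), abs=1e-12)

    @pytest.mark.parametrize(
        "name", ["Kr", "KthetaA", "KthetaB", "KphiA", "KphiB", "KphiC"]
    )
    def test_stiffer_restraints_lower_dG(self, name, ctx300):
        base = boresch_restraint_dg(BoreschParams(**TYPICAL), ctx300).value
        stiffer = boresch_restraint_dg(
            BoreschParams(**{**TYPICAL, name: TYPICAL[name] * 3.0}), ctx300
        ).value
        assert stiffer < base

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValidationError):
            BoreschParams(**{**TYPICAL, "thetaA0": math.pi})
        with pytest.raises(ValidationError):
            BoreschParams(**{**TYPICAL, "Kr": 0.0})


def _components(vals, errs=(0, 0, 0, 0, 0)):
    names = ["dG_alch_com", "dG_restr_com", "dG_alch_lig", "dG_restr_lig", "dG_conf_prot"]
    return CycleComponents(
        **{
            n: FreeEnergyEstimate(value=v, stderr=e, method="TI")
            for n, v, e in zip(names, vals, errs)
        }
    )


class TestAssembleCycle:
    def test_all_zero_components(self):
        assert assemble_cycle(_components([0, 0, 0, 0, 0])).value == 0.0

    def test_sign_convention(self):
        est = assemble_cycle(_components([-40.0, 2.0, -30.0, -5.0, 1.0]))
        # −40 − 2 + 30 − 5 + 1
        assert est.value == pytest.approx(-16.0)
        assert est.method == "SUM"

    def test_stderr_adds_in_quadrature(self):
        est = assemble_cycle(_components([0, 0, 0, 0, 0], errs=(0.3, 0.1, 0.2, 0, 0)))
        assert est.stderr == pytest.approx(math.sqrt(0.09 + 0.01 + 0.04), abs=1e-12)

    def test_linearity_under_component_scaling(self):
        a = assemble_cycle(_components([-40.0, 2.0, -30.0, -5.0, 1.0])).value
        b = assemble_cycle(_components([-80.0, 4.0, -60.0, -10.0, 2.0])).value
        assert b == pytest.approx(2 * a)

    def test_unadjusted_flag(self):
        est = assemble_cycle(_components([1.0, 0, 0, 0, 0.0]))
        assert est.meta["unadjusted"] is True


def _table(rows):
    return BenchmarkTable(
        rows=tuple(
            BenchmarkRow(
                complex_id=f"c{i}",
                system_id=s,
                dG_pred=p,
                dG_pred_err=e,
                dG_exp=x,
            )
            for i, (s, p, e, x) in enumerate(rows)
        )
    )


class TestConfCorrection:
    def test_two_point_system(self):
        tbl = _table([("A", -5.0, 0.1, -6.0), ("A", -7.0, 0.1, -8.0)])
        per_system, adjusted, skipped = conf_correction(tbl)
        assert per_system == {"A": pytest.approx(1.0)}
        assert [r.dG_pred for r in adjusted.rows] == [pytest.approx(-6.0), pytest.approx(-8.0)]
        assert skipped == ()

    def test_exact_predictions_unchanged(self):
        tbl = _table([("A", -5.0, 0.1, -5.0), ("A", -7.0, 0.1, -7.0)])
        per_system, adjusted, _ = conf_correction(tbl)
        assert per_system["A"] == pytest.approx(0.0)
        assert [r.dG_pred for r in adjusted.rows] == [r.dG_pred for r in tbl.rows]

    def test_translation_invariance_of_adjusted_values(self):
        rows = [("A", -5.0, 0.1, -6.0), ("A", -7.0, 0.1, -9.0), ("A", -3.0, 0.1, -4.5)]
        shifted = [(s, p + 2.5, e, x) for s, p, e, x in rows]
        per1, adj1, _ = conf_correction(_table(rows))
        per2, adj2, _ = conf_correction(_table(shifted))
        assert per2["A"] == pytest.approx(per1["A"] + 2.5)
        for r1, r2 in zip(adj1.rows, adj2.rows):
            assert r2.dG_pred == pytest.approx(r1.dG_pred)

    def test_zeroes_per_system_mean_signed_error(self):
        rng = np.random.default_rng(0)
        rows = [
            (sys_id, float(rng.normal(-8, 2)), 0.2, float(rng.normal(-8, 2)))
            for sys_id in ("A", "B", "C")
            for _ in range(7)
        ]
        _, adjusted, _ = conf_correction(_table(rows))
        df = adjusted.to_frame()
        for _, grp in df.groupby("system_id"):
            assert abs((grp.dg_pred - grp.dg_exp).mean()) < 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        rows = [
            ("A", float(rng.normal()), 0.1, float(rng.normal())) for _ in range(6)
        ]
        _, adjusted, _ = conf_correction(_table(rows))
        per2, _, _ = conf_correction(adjusted)
        assert per2["A"] == pytest.approx(0.0, abs=1e-12)

    def test_small_system_skipped(self):
        tbl = _table([("A", -5.0, 0.1, -6.0), ("A", -7.0, 0.1, -8.0), ("B", -4.0, 0.1, -5.0)])
        per_system, adjusted, skipped = conf_correction(tbl)
        assert "B" not in per_system and skipped == ("B",)
        (b_row,) = [r for r in adjusted.rows if r.system_id == "B"]
        assert b_row.dG_pred == -4.0


class TestAccuracyMetrics:
    def test_perfect_predictions(self):
        tbl = _table([("A", v, 0.1, v) for v in (-8.0, -6.5, -5.0, -3.2)])
        rep = accuracy_metrics(tbl, n_boot=200, seed=0)
        assert rep.mue == 0.0 and rep.rmse == 0.0
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.spearman_rho == pytest.approx(1.0)

    def test_rmse_at_least_mue_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(3, 12))
            tbl = _table(
                [
                    ("A", float(rng.normal(-7, 2)), 0.2, float(rng.normal(-7, 2)))
                    for _ in range(n)
                ]
            )
            rep = accuracy_metrics(tbl, n_boot=100, seed=1)
            assert rep.rmse >= rep.mue - 1e-12

    def test_error_bar_threshold_fractions(self):
        tbl = _table(
            [("A", -5.0, e, -5.5) for e in (0.4, 0.6, 1.2)]
        )
        rep = accuracy_metrics(tbl, n_boot=100, seed=0, thresholds=(0.5, 1.0))
        assert rep.frac_stderr_gt["0.5"] == pytest.approx(200.0 / 3.0, abs=0.01)
        assert rep.frac_stderr_gt["1"] == pytest.approx(100.0 / 3.0, abs=0.01)

    def test_pearson_affine_and_spearman_monotone_invariance(self):
        rng = np.random.default_rng(4)
        preds = rng.normal(-7, 2, size=15)
        exps = preds + rng.normal(0, 1, size=15)
        tbl = _table([("A", float(p), 0.1, float(x)) for p, x in zip(preds, exps)])
        rep = accuracy_metrics(tbl, n_boot=100, seed=0)
        affine = _table(
            [("A", float(2.0 * p + 3.0), 0.1, float(x)) for p, x in zip(preds, exps)]
        )
        rep_affine = accuracy_metrics(affine, n_boot=100, seed=0)
        assert rep_affine.pearson_r == pytest.approx(rep.pearson_r, abs=1e-10)
        monotone = _table(
            [("A", float(np.exp(p / 4.0)), 0.1, float(x)) for p, x in zip(preds, exps)]
        )
        rep_mono = accuracy_metrics(monotone, n_boot=100, seed=0)
        assert rep_mono.spearman_rho == pytest.approx(rep.spearman_rho, abs=1e-10)

    def test_too_few_rows_rejected(self):
        tbl = _table([("A", -5.0, 0.1, -5.0), ("A", -6.0, 0.1, -6.0)])
        with pytest.raises(DegenerateInputError):
            accuracy_metrics(tbl, n_boot=100, seed=0)
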