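"""Equilibrium (TI) estimation: schedules, bootstrap, quadrature, recovery."""

import numpy as np
import pytest

from abfekit.core import EnsembleGradients, GradientSeries, LambdaSchedule
from abfekit.eq import (
    LambdaMeanProfile,
    bootstrap_lambda_mean,
    builtin_schedule,
    coupling_weights,
    eq_free_energy,
    running_average_by_ensemble_size,
    ti_integrate,
)
from abfekit.estimators import ThermodynamicIntegration
from abfekit.exceptions import DegenerateInputError, ValidationError
from abfekit.synthetic import HarmonicModel, harmonic_ti_ensemble


class TestSchedules:
    @pytest.mark.parametrize(
        "name,length,contains",
        [
            ("coupling13", 13, (0.01, 0.9)),
            ("combined15", 15, (0.95, 0.99)),
            ("restraints12", 12, (0.075, 0.025)),
        ],
    )
    def test_builtin_lengths_and_members(self, name, length, contains):
        s = builtin_schedule(name)
        assert len(s) == length
        assert s.values[0] == 0.0 and s.values[-1] == 1.0
        for v in contains:
            assert v in s.values

    def test_unknown_name_rejected(self):
        with pytest.raises(ValidationError):
            builtin_schedule("coupling99")


class TestCouplingWeights:
    @pytest.mark.parametrize(
        "lam,leg,expected",
        [
            (0.45, "coupling", (0.45, 0.0, None)),
            (1.0, "combined", (1.0, 1.0, 0.0)),
            (0.725, "combined", (0.725, 0.5, 0.275)),
            (0.0, "coupling", (0.0, 0.0, None)),
        ],
    )
    def test_weights(self, lam, leg, expected):
        w_vdw, w_elec, w_restr = coupling_weights(lam, leg)
        assert w_vdw == pytest.approx(expected[0])
        assert w_elec == pytest.approx(expected[1])
        if expected[2] is None:
            assert w_restr is None
        else:
            assert w_restr == pytest.approx(expected[2])

    def test_lambda_outside_domain_rejected(self):
        with pytest.raises(ValidationError):
            coupling_weights(1.2)


def _series(rep, samples, lam=0.5):
    return GradientSeries(replica_id=rep, lam=lam, samples=tuple(samples))


class TestBootstrapLambdaMean:
    def test_constant_replicas_give_zero_stderr(self):
        series = [_series(1, [2.5] * 10), _series(2, [2.5] * 10)]
        mean, stderr = bootstrap_lambda_mean(series, n_boot=200, seed=0)
        assert mean == pytest.approx(2.5)
        assert stderr == 0.0

    def test_ensemble_average_of_two_replicas(self):
        rng = np.random.default_rng(1)
        series = [
            _series(1, 1.0 + 0.01 * rng.normal(size=500)),
            _series(2, 3.0 + 0.01 * rng.normal(size=500)),
        ]
        mean, _ = bootstrap_lambda_mean(series, n_boot=500, seed=0)
        assert mean == pytest.approx(2.0, abs=0.01)

    def test_stderr_tracks_analytic_s_over_sqrt_n(self):
        rng = np.random.default_rng(2)
        series = [_series(1, rng.normal(size=400))]
        _, stderr = bootstrap_lambda_mean(series, n_boot=2000, seed=3)
        assert stderr == pytest.approx(1.0 / 20.0, rel=0.3)

    def test_single_sample_replica_rejected(self):
        with pytest.raises(DegenerateInputError):
            bootstrap_lambda_mean([_series(1, [1.0])], n_boot=200, seed=0)

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_lambda_mean([_series(1, [1.0, 2.0])], n_boot=50, seed=0)


class TestTiIntegrate:
    def _profile(self, lams, means, stderrs):
        return LambdaMeanProfile(
            schedule=LambdaSchedule("s", tuple(lams)),
            means=tuple(means),
            stderrs=tuple(stderrs),
        )

    def test_trapezoid_exact_for_linear_means(self):
        est = ti_integrate(self._profile([0, 0.5, 1], [0, 1, 2], [0, 0, 0]))
        assert est.value == pytest.approx(1.0, abs=1e-12)
        assert est.stderr == 0.0

    def test_stderr_propagation_weights(self):
        est = ti_integrate(self._profile([0, 0.5, 1], [0, 0, 0], [1, 1, 1]))
        assert est.value == 0.0
        assert est.stderr == pytest.approx(np.sqrt(0.25**2 + 0.5**2 + 0.25**2))
        assert est.stderr == pytest.approx(0.6124, abs=1e-4)

    def test_affine_means_integrate_exactly(self):
        # trapezoid is exact whenever the integrand is affine in λ
        lams = np.array([0.0, 0.1, 0.35, 0.6, 1.0])
        means = 3.0 * lams - 1.25
        est = ti_integrate(self._profile(lams, means, np.zeros_like(lams)))
        assert est.value == pytest.approx(3.0 / 2.0 - 1.25, abs=1e-12)

    def test_nonfinite_mean_rejected(self):
        with pytest.raises(ValidationError):
            ti_integrate(self._profile([0, 1], [0, np.inf], [0, 0]))


class TestEqFreeEnergy:
    KT = 0.59616123

    def _harmonic(self, seed, ensemble=4, n=100):
        m = HarmonicModel(1.0, 4.0, self.KT)
        return harmonic_ti_ensemble(m, builtin_schedule("coupling13"), ensemble, n, seed)

    def test_recovers_harmonic_closed_form(self):
        data, dg_true = self._harmonic(seed=11, ensemble=10, n=200)
        est = eq_free_energy(data, n_boot=500, seed=11)
        assert dg_true == pytest.approx(0.5 * self.KT * np.log(4.0))
        assert abs(est.value - dg_true) <= 3 * est.stderr
        assert est.method == "TI"
        assert est.n_replicas == 10

    def test_all_zero_gradients_give_zero(self):
        sched = builtin_schedule("coupling13")
        series = [
            GradientSeries(replica_id=r, lam=lam, samples=(0.0,) * 5)
            for lam in sched.values
            for r in (1, 2)
        ]
        data = EnsembleGradients(leg="ligand_alchemical", schedule=sched, series=series)
        est = eq_free_energy(data, n_boot=200, seed=0)
        assert est.value == 0.0 and est.stderr == 0.0

    def test_deterministic_for_fixed_seed(self):
        data, _ = self._harmonic(seed=5)
        a = eq_free_energy(data, n_boot=200, seed=42)
        b = eq_free_energy(data, n_boot=200, seed=42)
        assert a.value == b.value and a.stderr == b.stderr

    def test_invariant_under_replica_relabelling(self):
        data, _ = self._harmonic(seed=6)
        # swap replica ids 1 <-> 4 (same series content, permuted labels)
        perm = {1: 4, 4: 1, 2: 2, 3: 3}
        relabeled = EnsembleGradients(
            leg=data.leg,
            schedule=data.schedule,
            series=tuple(
                GradientSeries(
                    replica_id=perm[s.replica_id],
                    lam=s.lam,
                    samples=s.samples,
                    times=s.times,
                )
                for s in data.series
            ),
        )
        a = eq_free_energy(data, n_boot=200, seed=9)
        b = eq_free_energy(relabeled, n_boot=200, seed=9)
        assert a.value == b.value and a.stderr == b.stderr

    def test_stderr_shrinks_with_more_samples(self):
        m = HarmonicModel(1.0, 4.0, self.KT)
        sched = builtin_schedule("coupling13")
        data_small, _ = harmonic_ti_ensemble(m, sched, 5, 40, seed=3)
        data_large, _ = harmonic_ti_ensemble(m, sched, 5, 400, seed=3)
        se_small = eq_free_energy(data_small, n_boot=400, seed=1).stderr
        se_large = eq_free_energy(data_large, n_boot=400, seed=1).stderr
        assert se_large < se_small

    def test_sklearn_estimator_contract(self):
        data, _ = self._harmonic(seed=2)
        ti = ThermodynamicIntegration(n_boot=200, random_state=7)
        assert ti.get_params() == {"n_boot": 200, "random_state": 7}
        fitted = ti.fit(data)
        assert fitted is ti
        assert hasattr(ti, "dg_") and hasattr(ti, "stderr_") and hasattr(ti, "profile_")
        ti.set_params(n_boot=300)
        assert ti.n_boot == 300


class TestRunningAverage:
    def test_cumulative_means(self):
        np.testing.assert_allclose(
            running_average_by_ensemble_size([1, 2, 3]), [1.0, 1.5, 2.0]
        )

    def test_constant_input_is_fixed_point(self):
        np.testing.assert_allclose(
            running_average_by_ensemble_size([2.0] * 5), [2.0] * 5
        )

    def test_last_element_is_full_mean(self):
        vals = [0.3, -1.2, 4.5, 2.2]
        out = running_average_by_ensemble_size(vals)
        assert out[-1] == pytest.approx(np.mean(vals))
        assert len(out) == len(vals)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            running_average_by_ensemble_size([])
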