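"""Simplex L2 fits: recovery, determinism, frozen-parameter contracts."""
import numpy as np
import pandas as pd
import pytest

from yeastcons.fitting import (
    FitResult,
    IdentifiabilityError,
    MeasurementTable,
    _predict_model1,
    _rk4_tensor_model1,
    fit_hill_dose_response,
    fit_model,
    fit_per_replicate,
    refit_output_stage,
)
from yeastcons.kinetics import (
    Model1Params,
    Transfer,
    dose_response,
    steady_state_model1,
    timecourse_tensor_model1,
)
from yeastcons.library import StrainSpec
from yeastcons.species import Signal
from yeastcons.synth import NoiseModel, generate_sensor_dataset

TRUTH = Model1Params(d1=1.0, V=1.0, K=276.5, n=1.0, d2=0.5, k3=37.5, c0=15.0, d3=0.3)
FREE = ("d1", "K", "n", "d2", "k3", "c0", "d3")  # V absorbed into k3
# init keeps the processor-faster-than-reporter rate ordering: the linear
# x2 -> x3 cascade is symmetric under a d2/d3 exchange, so an inverted init
# funnels the simplex into the label-swapped optimum
INIT = TRUTH.replace(d1=1.5, K=170.0, n=1.4, d2=0.8, k3=60.0, c0=8.0, d3=0.2)
INIT_KN = TRUTH.replace(K=170.0, n=1.4)  # for fits freezing everything else


@pytest.fixture(scope="module")
def noiseless_table():
    ds = generate_sensor_dataset(
        TRUTH, "repressing", noise=NoiseModel(cv=0.0, replicate_count=1, seed=0))
    return ds.table


def test_fast_predictor_matches_stiff_solver(library):
    doses = np.array([0.0, 1.0, 10.0, 100.0, 1000.0, 5000.0])
    times = np.array([0.5, 1.0, 3.0, 8.0, 12.0])
    for sid in ("IAA_rep_GFP", "bE_act_GFP", "aF_act_GFP"):
        s = library[sid]
        fast = _rk4_tensor_model1(s.params, s.transfer[0], doses, times)
        slow = timecourse_tensor_model1(s.params, s.transfer[0], doses, times)
        np.testing.assert_allclose(fast, slow, rtol=2e-4)


def test_noise_free_recovery_within_one_percent(noiseless_table):
    fit = fit_model(INIT, "repressing", noiseless_table, free=FREE,
                    seed=0, n_restarts=2, max_evals=3000)
    for k in FREE:
        assert getattr(fit.params, k) == pytest.approx(getattr(TRUTH, k), rel=1e-2), k


def test_loss_never_worse_than_init_and_deterministic(noiseless_table):
    a = fit_model(INIT, "repressing", noiseless_table, free=("K", "n"),
                  seed=3, n_restarts=3, max_evals=400)
    b = fit_model(INIT, "repressing", noiseless_table, free=("K", "n"),
                  seed=3, n_restarts=3, max_evals=400)
    init_loss = np.sqrt(np.sum(
        (_predict_model1(INIT, "repressing", noiseless_table)
         - noiseless_table.data["value"].to_numpy()) ** 2))
    assert a.loss <= init_loss
    assert a.params == b.params and a.loss == b.loss  # bit-identical per seed


def test_frozen_parameters_untouched(noiseless_table):
    fit = fit_model(INIT, "repressing", noiseless_table, free=("K", "n"),
                    seed=0, n_restarts=2, max_evals=300)
    for k in set(Model1Params.NAMES) - {"K", "n"}:
        assert getattr(fit.params, k) == getattr(INIT, k)


def test_constant_data_raises_identifiability_error():
    rows = [{"time": t, "dose_auxin": d, "value": 5.0, "replicate": 1}
            for t in (1.0, 2.0, 4.0) for d in (0.0, 10.0, 100.0)]
    table = MeasurementTable(pd.DataFrame(rows))
    with pytest.raises(IdentifiabilityError):
        fit_model(INIT, "repressing", table)


def test_insufficient_design_rejected():
    rows = [{"time": 1.0, "dose_auxin": 0.0, "value": 1.0, "replicate": 1},
            {"time": 2.0, "dose_auxin": 0.0, "value": 2.0, "replicate": 1}]
    with pytest.raises(IdentifiabilityError):
        fit_model(INIT, "repressing", MeasurementTable(pd.DataFrame(rows)))


class TestPerReplicate:
    def test_identical_replicates_have_zero_sd(self):
        ds = generate_sensor_dataset(
            TRUTH, "repressing", noise=NoiseModel(cv=0.0, replicate_count=3, seed=0))
        prf = fit_per_replicate(INIT_KN, "repressing", ds.table, free=("K", "n"),
                                seed=0, n_restarts=2, max_evals=300)
        assert all(sd == pytest.approx(0.0, abs=1e-12) for sd in prf.sd.values())
        assert len({f.params.K for f in prf.fits}) == 1  # bit-identical fits
        assert prf.mean["K"] == pytest.approx(prf.averaged.params.K, rel=5e-3)

    def test_noisy_replicates_spread_and_recover(self):
        ds = generate_sensor_dataset(
            TRUTH, "repressing", noise=NoiseModel(cv=0.05, replicate_count=3, seed=11))
        prf = fit_per_replicate(INIT_KN, "repressing", ds.table, free=("K", "n"),
                                seed=0, n_restarts=2, max_evals=600)
        assert prf.sd["n"] > 0
        assert prf.mean["K"] == pytest.approx(TRUTH.K, rel=0.10)
        assert prf.mean["n"] == pytest.approx(TRUTH.n, rel=0.10)

    def test_single_replicate_rejected(self):
        ds = generate_sensor_dataset(
            TRUTH, "repressing", noise=NoiseModel(cv=0.0, replicate_count=1, seed=0))
        with pytest.raises(ValueError, match="replicates"):
            fit_per_replicate(INIT, "repressing", ds.table)


class TestRefitOutputStage:
    def _cascade_table(self, library, sensor, sender, doses, clearance):
        from yeastcons.synth import generate_cascade_dataset
        ds = generate_cascade_dataset(
            [sender], sensor, Signal.ALPHA_FACTOR, doses,
            times=(2.0, 5.0, 8.0, 12.0),
            noise=NoiseModel(cv=0.0, replicate_count=1, seed=0),
            clearance=clearance)
        return ds.tables["cascade"]

    def test_recovers_altered_output_stage(self, library, iaa_sensor):
        sender = library["aF_act_IAA"]
        # generating truth uses a rescaled output stage and clearance
        true_k3, true_c0, true_d3 = 60.0, 4.0, 0.45
        altered = StrainSpec(
            id=sender.id, inputs=sender.inputs, transfer=sender.transfer,
            output=sender.output, role=sender.role, feedback=sender.feedback,
            params=sender.params.replace(k3=true_k3, c0=true_c0))
        table = self._cascade_table(library, iaa_sensor, altered,
                                    [0.0, 5.0, 50.0, 500.0], true_d3)
        fit = refit_output_stage(sender, iaa_sensor, table, seed=0,
                                 n_restarts=3, max_evals=250)
        assert fit.free == ("k3", "c0", "d3")
        assert fit.params.k3 == pytest.approx(true_k3, rel=0.05)
        assert fit.params.c0 == pytest.approx(true_c0, rel=0.05)
        assert fit.params.d3 == pytest.approx(true_d3, rel=0.05)
        # everything except the output stage stays exactly frozen
        for k in ("d1", "V", "K", "n", "d2"):
            assert getattr(fit.params, k) == getattr(sender.params, k)

    def test_validation_split_reported(self, library, iaa_sensor):
        sender = library["aF_act_IAA"]
        fit_tab = self._cascade_table(library, iaa_sensor, sender,
                                      [0.0, 10.0, 100.0, 1000.0], 0.3)
        val_tab = self._cascade_table(library, iaa_sensor, sender,
                                      [2.0, 30.0, 300.0, 3000.0], 0.3)
        fit = refit_output_stage(sender, iaa_sensor, fit_tab, seed=0,
                                 n_restarts=2, max_evals=120, validation=val_tab)
        assert fit.validation_loss >= 0.0


class TestHillDoseResponse:
    def test_exact_recovery(self):
        doses = np.geomspace(0.1, 1000, 12)
        doses = np.concatenate([[0.0], doses])
        y = 5.0 + 95.0 * (doses / 10.0) ** 1.3 / (1 + (doses / 10.0) ** 1.3)
        fit = fit_hill_dose_response(doses, y)
        assert fit.ec50 == pytest.approx(10.0, rel=5e-3)
        assert fit.n == pytest.approx(1.3, rel=5e-3)
        assert fit.fold_change == pytest.approx(100.0 / 5.0, rel=1e-2)

    def test_recovers_configured_sensor_cooperativity(self, library):
        """Steady-state curve of the beta-estradiol repressive sensor yields
        its configured Hill coefficient (2.2)."""
        s = library["bE_rep_GFP"]
        doses = np.concatenate([[0.0], np.geomspace(0.01, 100, 14)])
        dr = dose_response(s.params, "repressing", doses, read_time=300.0)
        fit = fit_hill_dose_response(dr)
        assert fit.mode is Transfer.REPRESSING
        assert fit.n == pytest.approx(2.2, rel=0.05)
        assert fit.ec50 == pytest.approx(0.5, rel=0.05)

    def test_double_repression_feedback_boosts_effective_cooperativity(self, library):
        """Auxin repressing its own attenuator (GH3.3) thresholds the signal
        seen by the sensor: the fitted effective Hill coefficient exceeds the
        bare sensor's."""
        from yeastcons.composition import compose, consortium_endpoint
        sensor = library["IAA_rep_GFP"]
        fb = library["IAA_rep_GH3"]  # auxin represses its own attenuator
        doses = np.concatenate([[0.0], np.geomspace(5.0, 10000.0, 11)])
        bare = []
        with_fb = []
        for d in doses:
            bare.append(steady_state_model1(sensor.params, "repressing", d))
            model = compose([(fb, 1.0)], sensor)
            tc = consortium_endpoint(model, {Signal.AUXIN: d}, t_end=10.0)
            with_fb.append(tc.endpoint(model.sensor_label))
        n_bare = fit_hill_dose_response(doses, np.array(bare)).n
        n_fb = fit_hill_dose_response(doses, np.array(with_fb)).n
        assert n_fb > n_bare

    def test_too_few_doses_rejected(self):
        with pytest.raises(IdentifiabilityError):
            fit_hill_dose_response([0, 1, 10, 100], [1, 2, 3, 4])

    def test_flat_curve_rejected(self):
        doses = np.concatenate([[0.0], np.geomspace(0.1, 100, 8)])
        with pytest.raises(IdentifiabilityError):
            fit_hill_dose_response(doses, np.full(doses.size, 7.0))
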