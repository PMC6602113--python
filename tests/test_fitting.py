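"""RMSD, the two experimental calibrations, and the repeated global fit."""

import numpy as np
import pytest

from opfkin import (
    ExperimentSet,
    RateConstants,
    Trace,
    calibrate_diffusion,
    calibrate_ero1_dtt,
    fit_parameters,
    rmsd,
)
from opfkin.fitting import fit_report_table
from opfkin.synth import (
    NoiseSpec,
    dtt_assay_conditions,
    generate_titration_series,
    generate_trace,
    recovery_conditions,
)


def make_trace(t, o2):
    return Trace(t=np.asarray(t, float), o2=np.asarray(o2, float))


class TestRmsd:
    def test_identical_traces(self):
        tr = make_trace([0, 1, 2], [258, 257, 256])
        assert rmsd(tr, tr) == 0.0

    def test_constant_offset(self):
        a = make_trace([0, 1, 2], [258, 257, 256])
        b = make_trace([0, 1, 2], [255, 254, 253])
        assert rmsd(a, b) == pytest.approx(3.0)

    def test_two_point_hand_value(self):
        a = make_trace([0, 1], [10.0, 10.0])
        b = make_trace([0, 1], [11.0, 13.0])
        assert rmsd(a, b) == pytest.approx(np.sqrt(5.0), rel=1e-12)

    def test_grid_mismatch_rejected(self):
        a = make_trace([0, 1, 2], [1, 2, 3])
        b = make_trace([0, 1.5, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="grid"):
            rmsd(a, b)


class TestCalibrateDiffusion:
    def test_noise_free_recovery_recovered_exactly(self):
        t = np.arange(0.0, 1801.0)
        o2 = 258.0 * (1.0 - np.exp(-0.01 * t))
        kdiff, o2_sat, diag = calibrate_diffusion(make_trace(t, o2))
        assert kdiff == pytest.approx(0.01, rel=1e-6)
        assert o2_sat == pytest.approx(258.0, rel=1e-6)
        assert diag["rmsd"] < 1e-6

    def test_simulated_recovery_trace_round_trip(self):
        k_true = RateConstants(kdiff=0.004, o2_sat=250.0)
        trace = generate_trace(k_true, recovery_conditions(duration=1500.0),
                               NoiseSpec(sd=0.0))
        kdiff, o2_sat, _ = calibrate_diffusion(trace)
        assert kdiff == pytest.approx(0.004, rel=1e-6)
        assert o2_sat == pytest.approx(250.0, rel=1e-6)

    def test_flat_trace_rejected(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(ValueError, match="no recovery signal"):
            calibrate_diffusion(make_trace(t, np.full_like(t, 258.0)))

    def test_noisy_recovery_within_five_percent(self):
        """Monte-Carlo: sd 1 μM electrode noise leaves kdiff within 5%."""
        t = np.arange(0.0, 1201.0)
        clean = 258.0 * (1.0 - np.exp(-0.01 * t))
        worst = 0.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            kdiff, _, _ = calibrate_diffusion(make_trace(t, clean + rng.normal(0, 1.0, t.size)))
            worst = max(worst, abs(kdiff - 0.01) / 0.01)
        assert worst < 0.05


class TestCalibrateEro1Dtt:
    def test_noise_free_parameter_recovery(self):
        k_true = RateConstants(k1=0.015, kdtt=2.0e-4)
        series = generate_titration_series(
            k_true, "dtt_scan", NoiseSpec(sd=0.0), duration=400.0, sample_interval=2.0
        )
        k1, kdtt, diag = calibrate_ero1_dtt(series)
        assert k1 == pytest.approx(0.015, rel=0.01)
        assert kdtt == pytest.approx(2.0e-4, rel=0.01)
        assert diag["rmsd"] < 0.05

    def test_zero_dtt_series_rejected(self):
        series = generate_titration_series(
            RateConstants(), "dtt_scan", NoiseSpec(sd=0.0), grid=(0.0,),
            duration=200.0, sample_interval=5.0,
        )
        with pytest.raises(ValueError, match="no signal"):
            calibrate_ero1_dtt(series)

    def test_experiments_with_pdi_rejected(self):
        series = generate_titration_series(
            RateConstants(), "pdi_scan", NoiseSpec(sd=0.0), grid=(5.0,),
            duration=200.0, sample_interval=5.0,
        )
        with pytest.raises(ValueError, match="Pdi1p"):
            calibrate_ero1_dtt(series)


@pytest.fixture(scope="module")
def tiny_series():
    """Short noise-free coupled-assay series for fast fitting tests."""
    return generate_titration_series(
        RateConstants(), "pdi_scan", NoiseSpec(sd=0.0), grid=(2.5, 10.0),
        duration=400.0, sample_interval=4.0,
    )


@pytest.fixture(scope="module")
def tiny_ensemble(tiny_series):
    return fit_parameters(
        tiny_series, n_repeats=2, seed=11, maxiter=8, popsize=6, rtol=1e-6, atol=1e-8
    )


class TestFitParameters:
    def test_same_seed_bit_identical(self, tiny_series, tiny_ensemble):
        again = fit_parameters(
            tiny_series, n_repeats=2, seed=11, maxiter=8, popsize=6, rtol=1e-6, atol=1e-8
        )
        for a, b in zip(tiny_ensemble.results, again.results):
            assert a.constants.to_dict() == b.constants.to_dict()
            assert a.per_experiment_rmsd == b.per_experiment_rmsd
            assert a.objective == b.objective

    def test_fixed_constants_unchanged(self, tiny_ensemble):
        template = RateConstants()
        for res in tiny_ensemble.results:
            for name in template.fixed:
                assert getattr(res.constants, name) == getattr(template, name)

    def test_rank_order_ascending_and_best_objective(self, tiny_ensemble):
        avg = [r.avg_rmsd for r in tiny_ensemble.results]
        assert avg == sorted(avg)
        assert tiny_ensemble.best.objective == min(r.objective for r in tiny_ensemble.results)
        for res in tiny_ensemble.results:
            assert res.avg_rmsd == pytest.approx(np.mean(res.per_experiment_rmsd))

    def test_report_table_shape(self, tiny_ensemble):
        df = fit_report_table(tiny_ensemble)
        assert list(df["rank"]) == [1, 2]
        assert "avg_rmsd_uM" in df.columns and "kox" in df.columns
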