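import numpy as np
import pytest

from sqifc import correction as corr
from sqifc import psd
from sqifc.circuits import resistor
from sqifc.correction import CalibrationTable, StageError
from sqifc.psd import ExcitationConfig

from conftest import random_rc_tree


def corrected_complex(frame):
    mag = frame["z_mag_ohm"].to_numpy(float)
    ph = np.radians(frame["z_phase_deg"].to_numpy(float))
    return mag * np.exp(1j * ph)


class TestCalibration:
    def test_identity_on_parasitic_free_chain(self, excitation):
        sweep = psd.sweep_eis(excitation, resistor(10e3), 1e5, 1e7, 10, channels=(1,))
        table = corr.build_calibration([(10e3, sweep)], excitation)
        assert np.allclose(table.factors, 1.0, rtol=1e-12)

    def test_removes_known_single_pole(self):
        # calibrate on 10 kΩ with a known roll-off, apply to a 1 kΩ sweep;
        # oracle = the parasitic-free simulation of the same 1 kΩ resistor
        lossy = ExcitationConfig(bandwidth_hz=5e6)
        clean = ExcitationConfig()
        ref = psd.sweep_eis(lossy, resistor(10e3), 1e5, 1e7, 10, channels=(1,))
        table = corr.build_calibration([(10e3, ref)], lossy)
        target = psd.sweep_eis(lossy, resistor(1e3), 1e5, 1e7, 10, channels=(1,))
        calibrated = corr.apply_calibration(target, table)
        oracle = psd.sweep_eis(clean, resistor(1e3), 1e5, 1e7, 10, channels=(1,))
        assert np.allclose(calibrated["re_v"], oracle["re_v"], rtol=5e-3)
        assert np.allclose(calibrated["im_v"], oracle["im_v"], atol=5e-3 * oracle["re_v"].abs().max())

    def test_factors_independent_of_reference_value(self):
        lossy = ExcitationConfig(bandwidth_hz=5e6)
        t10k = corr.build_calibration(
            [(10e3, psd.sweep_eis(lossy, resistor(10e3), 1e5, 1e7, 10, channels=(1,)))], lossy
        )
        t1k = corr.build_calibration(
            [(1e3, psd.sweep_eis(lossy, resistor(1e3), 1e5, 1e7, 10, channels=(1,)))], lossy
        )
        assert np.allclose(t10k.factors, t1k.factors, rtol=1e-6)

    def test_grid_mismatch_rejected(self, excitation):
        a = psd.sweep_eis(excitation, resistor(1e3), 1e5, 1e7, 10, channels=(1,))
        b = psd.sweep_eis(excitation, resistor(1e3), 1e5, 1e7, 12, channels=(1,))
        with pytest.raises(ValueError, match="grid"):
            corr.build_calibration([(1e3, a), (1e3, b)], excitation)

    def test_table_json_round_trip(self, excitation):
        sweep = psd.sweep_eis(excitation, resistor(10e3), 1e5, 1e7, 6, channels=(1,))
        table = corr.build_calibration([(10e3, sweep)], excitation)
        again = CalibrationTable.from_json(table.to_json())
        assert np.allclose(again.frequencies, table.frequencies)
        assert np.allclose(again.factors, table.factors)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            CalibrationTable(np.array([1e3, 1e3]), np.array([1 + 0j, 1 + 0j]))
        with pytest.raises(ValueError):
            CalibrationTable(np.array([1e3, 1e4]), np.array([1 + 0j, 0j]))


class TestReconstructPolar:
    def test_pure_real_reading_means_zero_phase(self, excitation):
        _, theta = corr.reconstruct_polar(0.01, 0.0, excitation)
        assert theta == 0.0

    def test_equal_components_give_minus_45_degrees(self, excitation):
        _, theta = corr.reconstruct_polar(0.01, 0.01, excitation)
        assert np.degrees(theta) == pytest.approx(-45.0)

    def test_round_trip_single_harmonic_resistor(self):
        # with only the fundamental the chain is the pure-sine case and the
        # reconstruction inverts it exactly
        cfg = ExcitationConfig(n_harmonics=1, f0=2e5)
        reading = psd.psd_dc_analytic(cfg, [4.2e3])
        mag, theta = corr.reconstruct_polar(reading.re_v, reading.im_v, cfg)
        assert mag == pytest.approx(4.2e3, rel=1e-12)
        assert theta == 0.0

    def test_zero_vector_rejected(self, excitation):
        with pytest.raises(ValueError):
            corr.reconstruct_polar(0.0, 0.0, excitation)


class TestSquareToSine:
    def test_requires_calibrated_stage(self, excitation, validation_circuit):
        raw = psd.sweep_eis(excitation, validation_circuit, 2e4, 1.2e7, 10, channels=(1,))
        with pytest.raises(StageError):
            corr.square_to_sine(raw, excitation)

    def test_flat_resistor_recovered_everywhere(self, excitation):
        sweep = psd.sweep_eis(excitation, resistor(8.2e3), 2e4, 1.2e7, 25, channels=(1,))
        cal = corr.identity_calibration(sweep["frequency_hz"].to_numpy())
        out = corr.square_to_sine(corr.apply_calibration(sweep, cal), excitation)
        assert np.allclose(out["z_mag_ohm"], 8.2e3, rtol=5e-3)
        assert np.allclose(out["z_phase_deg"], 0.0, atol=0.05)

    def test_validation_circuit_within_3_percent_in_band(self, excitation, validation_circuit):
        sweep = psd.sweep_eis(excitation, validation_circuit, 2e4, 1.2e7, 25, channels=(1,))
        cal = corr.build_calibration(
            [(10e3, psd.sweep_eis(excitation, resistor(10e3), 2e4, 1.2e7, 25, channels=(1,)))],
            excitation,
        )
        out = corr.square_to_sine(corr.apply_calibration(sweep, cal), excitation)
        f = out["frequency_hz"].to_numpy()
        band = (f >= 1e5) & (f <= 1e7)
        z_true = validation_circuit.impedance(f)
        mag_err = np.abs(out["z_mag_ohm"].to_numpy() - np.abs(z_true)) / np.abs(z_true)
        phase_err = np.abs(
            out["z_phase_deg"].to_numpy() - np.degrees(np.angle(z_true))
        ) / np.max(np.abs(np.degrees(np.angle(z_true))[band]))
        assert mag_err[band].max() < 0.03
        assert phase_err[band].max() < 0.03

    def test_topmost_frequency_no_subtraction_full_residual(self, excitation, validation_circuit):
        sweep = psd.sweep_eis(excitation, validation_circuit, 2e4, 1.2e7, 10, channels=(1,))
        cal = corr.identity_calibration(sweep["frequency_hz"].to_numpy())
        calibrated = corr.apply_calibration(sweep, cal)
        out = corr.square_to_sine(calibrated, excitation, assume_flat_above_grid=False)
        top = out.loc[out["frequency_hz"].idxmax()]
        top_cal = calibrated.loc[calibrated["frequency_hz"].idxmax()]
        # no harmonic reading available: nothing subtracted, E flags everything
        assert top["re_v"] == pytest.approx(top_cal["re_v"], rel=1e-12)
        assert top["im_v"] == pytest.approx(top_cal["im_v"], rel=1e-12)
        assert top["residual_flag"] == pytest.approx(1.0)
        bottom = out.loc[out["frequency_hz"].idxmin()]
        assert bottom["residual_flag"] == 0.0

    def test_round_trip_random_circuits_in_grid(self, excitation):
        # excitation restricted to grid-supported harmonics: the correction
        # must invert the forward chain wherever every harmonic is measurable
        rng = np.random.default_rng(99)
        for _ in range(5):
            model = random_rc_tree(rng)
            sweep = psd.sweep_eis(
                excitation, model, 2e4, 1.2e7, 25, channels=(1,), max_harmonic_hz=1.2e7
            )
            cal = corr.identity_calibration(sweep["frequency_hz"].to_numpy())
            out = corr.square_to_sine(
                corr.apply_calibration(sweep, cal), excitation, assume_flat_above_grid=False
            )
            f = out["frequency_hz"].to_numpy()
            in_grid = f * 11 <= 1.2e7 * (1 + 1e-9)
            err = np.abs(corrected_complex(out) - model.impedance(f)) / np.abs(
                model.impedance(f)
            )
            assert err[in_grid].max() < 5e-3
            resid = out["residual_flag"].to_numpy()
            assert np.all(resid[in_grid] == 0.0)
            assert np.all(resid[~in_grid] > 0.0)

    def test_recursive_no_worse_than_literal(self, excitation):
        from sqifc.circuits import validation_circuit, validation_circuit_alt

        for model in (validation_circuit(), validation_circuit_alt()):
            sweep = psd.sweep_eis(excitation, model, 2e4, 1.2e7, 25, channels=(1,))
            cal = corr.identity_calibration(sweep["frequency_hz"].to_numpy())
            calibrated = corr.apply_calibration(sweep, cal)
            errs = {}
            for mode in ("literal", "recursive"):
                out = corr.square_to_sine(calibrated, excitation, mode=mode)
                f = out["frequency_hz"].to_numpy()
                z = model.impedance(f)
                errs[mode] = np.max(np.abs(corrected_complex(out) - z) / np.abs(z))
            assert errs["recursive"] <= errs["literal"]

    def test_invariant_under_global_gain_rescaling(self, validation_circuit):
        # K_psd, Rf and V0 cancel between forward chain and reconstruction
        base = ExcitationConfig()
        scaled = ExcitationConfig(v0=0.2, rf=47e3, k_psd=psd.K_PSD_PRINTED)
        outs = []
        for cfg in (base, scaled):
            sweep = psd.sweep_eis(cfg, validation_circuit, 2e4, 1.2e7, 15, channels=(1,))
            cal = corr.identity_calibration(sweep["frequency_hz"].to_numpy())
            outs.append(corr.square_to_sine(corr.apply_calibration(sweep, cal), cfg))
        assert np.allclose(outs[0]["z_mag_ohm"], outs[1]["z_mag_ohm"], rtol=1e-10)
        assert np.allclose(outs[0]["z_phase_deg"], outs[1]["z_phase_deg"], atol=1e-8)
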