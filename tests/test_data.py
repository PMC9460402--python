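"""Readers, writers and container invariants."""

import json
import math

import numpy as np
import pandas as pd
import pytest

import rheomwd as rm
from rheomwd.data import GridSpec, RunConfig, ValidationError


def _write_freq_csv(tmp_path, name="sweep.csv", rows=None, meta=None):
    rows = rows if rows is not None else [
        (0.1, 120.0, 300.0), (1.0, 400.0, 500.0), (10.0, 800.0, 450.0),
        (100.0, 950.0, 300.0), (1000.0, 990.0, 150.0)]
    df = pd.DataFrame(rows, columns=["omega_rad_per_s", "g_prime_pa",
                                     "g_double_prime_pa"])
    path = tmp_path / name
    df.to_csv(path, index=False)
    meta = meta if meta is not None else {
        "temperature_c": 23.0, "mode": "CS", "amplitude": 300.0,
        "gap_mm": 0.5, "sample_id": "collagen_4pct"}
    (tmp_path / (path.stem + ".meta.json")).write_text(json.dumps(meta))
    return path


class TestReadSweep:
    def test_frequency_sweep_with_sidecar(self, tmp_path):
        sweep = rm.read_sweep(_write_freq_csv(tmp_path), "frequency")
        assert len(sweep) == 5
        assert sweep.temperature == 23.0
        assert sweep.mode is rm.SweepMode.CS
        assert sweep.amplitude == 300.0
        assert sweep.gap == 0.5
        assert sweep.sample_id == "collagen_4pct"

    def test_descending_rows_are_reordered(self, tmp_path):
        rows = [(10.0, 800.0, 450.0), (1.0, 400.0, 500.0), (0.1, 120.0, 300.0)]
        sweep = rm.read_sweep(_write_freq_csv(tmp_path, rows=rows), "frequency")
        assert np.all(np.diff(sweep.omega) > 0)
        assert sweep.g_prime[0] == 120.0

    def test_negative_modulus_names_row(self, tmp_path):
        rows = [(0.1, 120.0, 300.0), (1.0, -1.0, 500.0), (10.0, 800.0, 450.0)]
        with pytest.raises(ValidationError, match="g_prime.*row 1"):
            rm.read_sweep(_write_freq_csv(tmp_path, rows=rows), "frequency")

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"omega_rad_per_s": [1, 2, 3],
                      "g_prime_pa": [1, 2, 3]}).to_csv(path, index=False)
        with pytest.raises(ValidationError, match="missing column"):
            rm.read_sweep(path, "frequency")

    def test_non_numeric_cell_names_position(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("omega_rad_per_s,g_prime_pa,g_double_prime_pa\n"
                        "0.1,abc,3\n1,2,3\n10,4,5\n")
        with pytest.raises(ValidationError, match="g_prime_pa.*row 0"):
            rm.read_sweep(path, "frequency")

    def test_too_few_rows(self, tmp_path):
        path = tmp_path / "tiny.csv"
        path.write_text("omega_rad_per_s,g_prime_pa,g_double_prime_pa\n1,2,3\n")
        with pytest.raises(ValidationError, match="fewer than 3"):
            rm.read_sweep(path, "frequency")

    def test_hz_conversion(self, tmp_path):
        rows = [(1.0, 10.0, 20.0), (2.0, 30.0, 40.0), (4.0, 50.0, 60.0)]
        meta = {"temperature_c": 23.0, "mode": "CS", "frequency_unit": "Hz"}
        path = _write_freq_csv(tmp_path, rows=rows, meta=meta)
        sweep = rm.read_sweep(path, "frequency")
        assert sweep.omega == pytest.approx([2 * math.pi, 4 * math.pi,
                                             8 * math.pi])


class TestContainers:
    def test_omega_must_be_positive_increasing(self):
        with pytest.raises(ValidationError):
            rm.FrequencySweep(temperature=23.0, omega=[1.0, 1.0, 2.0],
                              g_prime=[1, 1, 1], g_double_prime=[1, 1, 1])
        with pytest.raises(ValidationError):
            rm.FrequencySweep(temperature=23.0, omega=[-1.0, 1.0, 2.0],
                              g_prime=[1, 1, 1], g_double_prime=[1, 1, 1])

    def test_temperature_must_be_finite(self):
        with pytest.raises(ValidationError):
            rm.FrequencySweep(temperature=math.inf, omega=[1.0, 2.0, 3.0],
                              g_prime=[1, 1, 1], g_double_prime=[1, 1, 1])

    def test_grid_spec_validation(self):
        with pytest.raises(ValidationError):
            GridSpec(minimum=1.0, maximum=0.1)
        grid = GridSpec(1e-2, 1e2, 5).build()
        assert grid[0] == pytest.approx(1e-2) and grid[-1] == pytest.approx(1e2)


class TestRoundTrips:
    def test_distribution_round_trip(self, tmp_path, lognormal_truth):
        path = tmp_path / "mwd.csv"
        rm.write_result(lognormal_truth, path)
        back = rm.read_result(path, "distribution")
        np.testing.assert_allclose(back.w, lognormal_truth.w, rtol=1e-12)
        np.testing.assert_allclose(back.mass_grid, lognormal_truth.mass_grid,
                                   rtol=1e-12)
        summary = json.loads((tmp_path / "mwd.summary.json").read_text())
        assert summary["pdi"] == pytest.approx(lognormal_truth.pdi, rel=1e-12)

    def test_spectrum_round_trip(self, tmp_path):
        spec = rm.ContinuousSpectrum(lambda_grid=np.logspace(-2, 2, 41),
                                     H=np.linspace(1.0, 500.0, 41))
        path = tmp_path / "spec.csv"
        rm.write_result(spec, path)
        back = rm.read_result(path, "spectrum")
        np.testing.assert_allclose(back.H, spec.H, rtol=1e-12)

    def test_master_curve_round_trip(self, tmp_path):
        mc = rm.MasterCurve(reference_temperature=28.0,
                            omega=np.logspace(-1, 1, 9),
                            g_prime=np.linspace(10, 90, 9),
                            g_double_prime=np.linspace(20, 60, 9),
                            source_temperature_per_point=np.full(9, 28.0))
        path = tmp_path / "master.csv"
        rm.write_result(mc, path)
        back = rm.read_result(path, "master_curve")
        np.testing.assert_allclose(back.g_prime, mc.g_prime, rtol=1e-12)

    def test_nan_payload_rejected(self, tmp_path):
        curve = rm.RelaxationCurve(time=[1.0, 2.0], modulus=[1.0, 0.5])
        curve.modulus[1] = math.nan
        with pytest.raises(ValidationError, match="non-finite"):
            rm.write_result(curve, tmp_path / "bad.csv")

    def test_sweep_round_trip(self, tmp_path):
        sweep = rm.TemperatureSweep(temperature=[23.0, 30.0, 40.0],
                                    viscosity=[100.0, 80.0, 10.0],
                                    tan_delta=[0.3, 0.8, 1.2])
        rm.write_sweep(sweep, tmp_path / "t.csv")
        back = rm.read_sweep(tmp_path / "t.csv", "temperature")
        np.testing.assert_allclose(back.viscosity, sweep.viscosity, rtol=1e-12)

    def test_runconfig_round_trip(self, tmp_path):
        cfg = RunConfig(lve_tolerance=0.04, seed=7,
                        reptation={"g_n": 1000.0, "me": 5e4})
        cfg.to_json(tmp_path / "cfg.json")
        back = RunConfig.from_json(tmp_path / "cfg.json")
        assert back.lve_tolerance == 0.04
        assert back.reptation["me"] == 5e4
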