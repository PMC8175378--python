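"""Folding of response functions with spectra; tables and reductions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import braindose as bd
from braindose.dose_engine import UnitModeError


def _constant_rf(grid, height, e_lo, e_hi):
    return bd.make_synthetic_brf(
        "flat", {"e_lo": e_lo, "e_hi": e_hi, "height": height}, grid)


def _flat_spectrum(grid, f0, mode=bd.FLUENCE):
    return bd.ParticleSpectrum(bd.get_species("H"), grid,
                               np.full(grid.n_bins, f0), mode)


class TestFold:
    def test_constant_window_analytic_value(self):
        """rf = c on [E1,E2], F = F0 everywhere -> dose ~ c*F0*(E2-E1)."""
        grid = bd.EnergyGrid.default(n_bins=2048)
        c, f0, e1, e2 = 0.02, 3.0e4, 50.0, 400.0
        rf = _constant_rf(grid, c, e1, e2)
        res = bd.fold(rf, _flat_spectrum(grid, f0))
        assert res.unit == "uGy"
        # window edges land mid-bin, so allow ~ one bin width of slack
        assert res.value == pytest.approx(c * f0 * (e2 - e1), rel=1e-2)

    def test_zero_spectrum_gives_zero(self, head, grid):
        rf = bd.generate_brf(head, bd.ShieldConfig(0.2), "H", grid)
        assert bd.fold(rf, _flat_spectrum(grid, 0.0)).value == 0.0

    def test_agrees_with_refined_riemann_oracle(self, grid):
        """Trapezoid fold vs. 100x-finer Riemann sum, smooth product."""
        def rf_func(e):
            return 1e-2 * np.exp(-0.5 * np.log(e / 80.0) ** 2)

        def spec_func(e):
            return 1e5 * (e / 30.0) ** -2.5

        rf = bd.ResponseFunction("head", bd.ShieldConfig(0),
                                 bd.get_species("H"), grid,
                                 rf_func(grid.centers), "synthetic")
        spec = bd.ParticleSpectrum(bd.get_species("H"), grid,
                                   spec_func(grid.centers), bd.FLUENCE)
        value = bd.fold(rf, spec).value
        fine = np.geomspace(grid.centers[0], grid.centers[-1],
                            grid.n_bins * 100)
        mids = np.sqrt(fine[:-1] * fine[1:])
        oracle = float(np.sum(rf_func(mids) * spec_func(mids)
                              * np.diff(fine)))
        assert value == pytest.approx(oracle, rel=1e-3)

    def test_grid_refinement_convergence(self):
        """Halving bin widths moves the fold by < 0.5% on smooth input."""
        values = []
        for n in (128, 256):
            grid = bd.EnergyGrid.default(n_bins=n)
            rf = bd.ResponseFunction(
                "head", bd.ShieldConfig(0), bd.get_species("H"), grid,
                1e-2 * np.exp(-0.5 * np.log(grid.centers / 100.0) ** 2),
                "synthetic")
            spec = bd.sep_spectrum(bd.SEPShape(i0=1e5, gamma=3.0), grid)
            values.append(bd.fold(rf, spec).value)
        assert abs(values[1] - values[0]) / values[1] < 5e-3

    @given(a=st.floats(min_value=0.1, max_value=10.0),
           b=st.floats(min_value=0.1, max_value=10.0))
    def test_linearity_in_spectrum_and_response(self, a, b):
        grid = bd.EnergyGrid.default(n_bins=32)
        rng = np.random.default_rng(11)
        rf_vals = rng.uniform(0, 1e-2, grid.n_bins)
        sp_vals = rng.uniform(0, 1e4, grid.n_bins)
        h = bd.get_species("H")
        rf = bd.ResponseFunction("head", bd.ShieldConfig(0), h, grid,
                                 rf_vals, "synthetic")
        rf_a = bd.ResponseFunction("head", bd.ShieldConfig(0), h, grid,
                                   a * rf_vals, "synthetic")
        sp = bd.ParticleSpectrum(h, grid, sp_vals, bd.FLUENCE)
        base = bd.fold(rf, sp).value
        assert bd.fold(rf_a, sp).value == pytest.approx(a * base, rel=1e-12)
        assert bd.fold(rf, sp.scaled(b)).value == pytest.approx(
            b * base, rel=1e-12)

    def test_species_mismatch_rejected(self, head, grid):
        rf = bd.generate_brf(head, bd.ShieldConfig(0), "He", grid)
        with pytest.raises(UnitModeError, match="species"):
            bd.fold(rf, _flat_spectrum(grid, 1.0))

    def test_flux_mode_yields_rate_unit(self, head, grid):
        rf = bd.generate_brf(head, bd.ShieldConfig(0), "H", grid)
        assert bd.fold(rf, _flat_spectrum(grid, 1.0, bd.FLUX)).unit == "uGy/s"


@pytest.fixture(scope="module")
def rfs(head, grid):
    return {s: bd.generate_brf(head, bd.ShieldConfig(0), s, grid)
            for s in ("H", "He", "C", "N", "Fe")}


@pytest.fixture(scope="module")
def scenarios(head, grid):
    return {s: bd.generate_brf(head, bd.STANDARD_SHIELDS[s], "H", grid)
            for s in ("none", "2mm", "2cm", "10cm")}


class TestGCRDoseRate:
    def test_total_is_sum_of_species(self, rfs, grid):
        res = bd.gcr_dose_rate(rfs, bd.GCRParams(phi=500), grid)
        per = res.provenance["per_species_uGy_day"]
        assert res.unit == "uGy/day"
        assert res.value == pytest.approx(sum(per.values()), rel=1e-12)

    def test_rate_decreases_with_phi(self, rfs, grid):
        lo = bd.gcr_dose_rate(rfs, bd.GCRParams(phi=300), grid).value
        hi = bd.gcr_dose_rate(rfs, bd.GCRParams(phi=1200), grid).value
        assert hi < lo

    def test_missing_species_rejected(self, rfs, grid):
        partial = {k: v for k, v in rfs.items() if k != "Fe"}
        with pytest.raises(UnitModeError, match="Fe"):
            bd.gcr_dose_rate(partial, bd.GCRParams(), grid)


class TestSEPEventDose:
    def test_flux_mode_rejected(self, head, grid):
        rf = bd.generate_brf(head, bd.ShieldConfig(0.2), "H", grid)
        with pytest.raises(UnitModeError, match="fluence"):
            bd.sep_event_dose(rf, _flat_spectrum(grid, 1.0, bd.FLUX))

    def test_unit_conversion_matches_fold(self, head, grid, ensemble):
        rf = bd.generate_brf(head, bd.ShieldConfig(0.2), "H", grid)
        ev = ensemble[0]
        assert bd.sep_event_dose(rf, ev).value == pytest.approx(
            bd.fold(rf, ev).value * 1e-4, rel=1e-12)

    def test_doubling_fluence_doubles_dose(self, head, grid, ensemble):
        rf = bd.generate_brf(head, bd.ShieldConfig(0.2), "H", grid)
        ev = ensemble[3]
        assert bd.sep_event_dose(rf, ev.scaled(2.0)).value == pytest.approx(
            2.0 * bd.sep_event_dose(rf, ev).value, rel=1e-12)

    def test_delta_response_picks_out_fluence(self, grid, ensemble):
        """Unit-area delta rf at E_R -> dose = fluence(E_R) x 1e-4 cGy."""
        delta = bd.make_synthetic_brf("delta", {"e_r": 100.0, "area": 1.0},
                                      grid)
        idx = int(np.argmax(delta.values > 0))
        ev = ensemble[5]
        dose = bd.sep_event_dose(delta, ev).value
        # trapezoid weight of a single-bin delta on the log grid
        e = grid.centers
        w = delta.values[idx] * e[idx] * (np.log(e[idx + 1])
                                          - np.log(e[idx - 1])) / 2.0
        assert dose == pytest.approx(w * ev.values[idx] * 1e-4, rel=1e-9)


class TestDoseTable:
    def test_single_cell_equals_direct_dose(self, scenarios, ensemble):
        ev = {"e0": ensemble[0]}
        table = bd.dose_table(ev, {"2mm": scenarios["2mm"]})
        direct = bd.sep_event_dose(scenarios["2mm"], ensemble[0]).value
        assert table.doses.loc["e0", "2mm"] == pytest.approx(direct)

    def test_doses_fall_with_shield_depth(self, scenarios, ensemble):
        events = {f"e{i}": ev for i, ev in enumerate(ensemble)}
        table = bd.dose_table(events, scenarios)
        d = table.doses[["none", "2mm", "2cm", "10cm"]].to_numpy()
        assert np.all(np.diff(d, axis=1) <= 0)

    def test_empty_event_list_gives_empty_table(self, scenarios):
        table = bd.dose_table({}, scenarios)
        assert table.doses.shape == (0, len(scenarios))

    def test_csv_roundtrip(self, scenarios, ensemble, tmp_path):
        events = {f"e{i}": ev for i, ev in enumerate(ensemble[:5])}
        table = bd.dose_table(events, scenarios)
        path = tmp_path / "table.csv"
        table.to_csv(path)
        back = bd.EventDoseTable.from_csv(path)
        assert back.unit == "cGy"
        pd.testing.assert_frame_equal(back.doses, table.doses)


class TestReductionStats:
    def test_identical_scenarios_give_zero(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]},
                          index=["e1", "e2"])
        fr, mean = bd.reduction_stats(bd.EventDoseTable(df), "a", "b")
        assert np.allclose(fr, 0.0) and mean == 0.0

    def test_zero_baseline_excluded_with_warning(self, caplog):
        df = pd.DataFrame({"a": [0.0, 10.0], "b": [0.0, 2.0]},
                          index=["e1", "e2"])
        with caplog.at_level("WARNING"):
            fr, mean = bd.reduction_stats(bd.EventDoseTable(df), "a", "b")
        assert list(fr.index) == ["e2"]
        assert mean == pytest.approx(80.0)
        assert any("zero baseline" in r.message for r in caplog.records)

    def test_unknown_scenario_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0]}, index=list("xyz"))
        with pytest.raises(KeyError):
            bd.reduction_stats(bd.EventDoseTable(df), "a", "missing")
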