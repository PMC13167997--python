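"""Parameter sweeps, zero-error roots, and the ERR lookup table."""

import numpy as np
import pytest

from dualgat import (
    CorneaGeometry,
    CorneaMechanics,
    EyeState,
    SweepSpec,
    err_lookup_table,
    goldmann_error,
    run_sweep,
    slope_vs_modulus,
    zero_error_curvature,
    zero_error_modulus,
    zero_error_thickness,
)
from dualgat.sweeps import (
    write_lookup_csv,
    zero_curvature_closed_form,
    zero_modulus_closed_form,
    zero_thickness_closed_form,
)


class TestZeroErrorRoots:
    """At the reference cornea the tonometer reads true; each printed
    reference value is the root of ERR in its own variable."""

    def test_thickness_root(self, reference_mech):
        h_star = zero_error_thickness(reference_mech, a=7.15)
        assert h_star == pytest.approx(0.536, rel=5e-3)
        assert h_star == pytest.approx(
            zero_thickness_closed_form(reference_mech, 7.15), rel=1e-9
        )

    def test_curvature_root(self, reference_mech):
        a_star = zero_error_curvature(reference_mech, h=0.536)
        assert a_star == pytest.approx(7.15, rel=5e-3)
        assert a_star == pytest.approx(
            zero_curvature_closed_form(reference_mech, 0.536), rel=1e-9
        )

    def test_modulus_root(self):
        e_star = zero_error_modulus(h=0.536, a=7.15)
        assert e_star == pytest.approx(0.16, rel=5e-3)
        assert e_star == pytest.approx(
            zero_modulus_closed_form(0.536, 7.15), rel=1e-9
        )

    def test_roots_are_mutually_consistent(self):
        """Inserting any two printed reference values yields the third."""
        h_star = zero_error_thickness(CorneaMechanics(0.16), a=7.15)
        a_star = zero_error_curvature(CorneaMechanics(0.16), h=h_star)
        e_star = zero_error_modulus(h=h_star, a=a_star)
        assert e_star == pytest.approx(0.16, rel=1e-9)

    def test_residual_at_root(self, reference_mech):
        h_star = zero_error_thickness(reference_mech, a=7.15)
        geom = CorneaGeometry.from_mid_surface(7.15, h_star)
        assert abs(goldmann_error(reference_mech, geom)) < 1e-9

    def test_bracket_expansion(self, reference_mech):
        """A bracket that misses the root initially still converges."""
        h_star = zero_error_thickness(reference_mech, a=7.15, bracket=(0.6, 0.7))
        assert h_star == pytest.approx(0.536, rel=5e-3)

    @pytest.mark.filterwarnings("ignore::dualgat.ThinShellWarning")
    def test_no_root_raises(self):
        with pytest.raises(ValueError, match="no sign change"):
            # E=0 makes ERR identically -p3; no thickness can zero it
            zero_error_thickness(CorneaMechanics(1e-12), a=7.15)


class TestRunSweep:
    def _spec(self, parameter, grid, reference_eye):
        return SweepSpec(parameter=parameter, grid=np.asarray(grid),
                         fixed=reference_eye)

    def test_thickness_sweep_monotone_and_zero_at_reference(self, reference_eye):
        spec = self._spec("thickness", np.arange(0.45, 0.66, 0.01), reference_eye)
        res = run_sweep(spec)
        err = res.table["err_mmhg"].to_numpy()
        assert np.all(np.diff(err) > 0)
        # the grid point nearest 0.536 mm has |ERR| below one 0.01 mm step of slope
        assert np.abs(err).min() < 0.08

    def test_curvature_sweep_monotone_decreasing(self, reference_eye):
        spec = self._spec("curvature", np.arange(6.5, 8.01, 0.05), reference_eye)
        err = run_sweep(spec).table["err_mmhg"].to_numpy()
        assert np.all(np.diff(err) < 0)

    def test_err_column_identity(self, reference_eye):
        spec = self._spec("modulus", np.arange(0.10, 0.36, 0.01), reference_eye)
        table = run_sweep(spec).table
        assert np.allclose(
            table["err_mmhg"], table["iopg0_mmhg"] - table["iopt_mmhg"], atol=1e-12
        )

    def test_iopt_grid_and_metadata(self, reference_eye):
        spec = SweepSpec(
            parameter="thickness",
            grid=np.array([0.50, 0.55]),
            fixed=reference_eye,
            iopt_grid=np.array([10.0, 20.0, 30.0]),
        )
        res = run_sweep(spec)
        assert len(res.table) == 6
        assert res.metadata["nu"] == 0.485
        assert res.metadata["parameter"] == "thickness"

    def test_invalid_spec(self, reference_eye):
        with pytest.raises(ValueError):
            SweepSpec(parameter="thickness", grid=np.array([0.6, 0.5]),
                      fixed=reference_eye)
        with pytest.raises(ValueError):
            SweepSpec(parameter="hue", grid=np.array([0.5]), fixed=reference_eye)


class TestLookupTable:
    def test_reference_cell_is_zero(self):
        table = err_lookup_table(h_grid=[0.536], a_grid=[7.15], e_grid=[0.16])
        assert len(table) == 1
        assert table["err_mmhg"].iloc[0] == pytest.approx(0.0, abs=1e-3)

    def test_monotone_along_each_axis(self):
        table = err_lookup_table()
        for col, sign in (("h_mm", 1), ("e_mpa", 1), ("a_mm", -1)):
            others = [c for c in ("h_mm", "a_mm", "e_mpa") if c != col]
            for _, group in table.groupby(others):
                diffs = np.diff(group.sort_values(col)["err_mmhg"].to_numpy())
                assert np.all(sign * diffs > 0)

    def test_physiologic_range_magnitude(self):
        """|ERR| over the physiologic grid is of the same order as the
        0.5-7 mmHg deviations the model predicts clinically."""
        table = err_lookup_table(
            h_grid=np.arange(0.45, 0.651, 0.01),
            a_grid=np.arange(6.5, 8.01, 0.05),
            e_grid=np.arange(0.10, 0.351, 0.01),
        )
        lo, hi = table["err_mmhg"].min(), table["err_mmhg"].max()
        assert -4.0 < lo < 0.0
        assert 5.0 < hi < 15.0

    def test_grid_order_irrelevant(self):
        t1 = err_lookup_table(h_grid=[0.5, 0.6], a_grid=[7.0, 7.5], e_grid=[0.2])
        t2 = err_lookup_table(h_grid=[0.6, 0.5], a_grid=[7.5, 7.0], e_grid=[0.2])
        s1 = set(map(tuple, np.round(t1.to_numpy(), 9)))
        s2 = set(map(tuple, np.round(t2.to_numpy(), 9)))
        assert s1 == s2

    def test_geometry_guard(self):
        with pytest.raises(ValueError):
            err_lookup_table(a_grid=[1.7])

    def test_csv_export_rounds_err_only(self, tmp_path):
        import pandas as pd

        table = err_lookup_table(h_grid=[0.536], a_grid=[7.15], e_grid=[0.16])
        path = tmp_path / "lookup.csv"
        write_lookup_csv(table, path)
        back = pd.read_csv(path)
        assert back["err_mmhg"].iloc[0] == pytest.approx(0.0, abs=5e-3)
        assert back["h_mm"].iloc[0] == 0.536


class TestSlopes:
    def test_analytic_slope_value(self, reference_geom):
        slopes = slope_vs_modulus([0.16, 0.32], reference_geom)
        # at the reference cornea the thickness slope is ~4.0 mmHg / 0.536 mm
        assert slopes[0] == pytest.approx(7.4618, abs=1e-3)
        assert slopes[1] / slopes[0] == pytest.approx(2.0, rel=1e-12)

    def test_matches_numerical_sweep_slope(self, reference_geom, reference_eye):
        spec = SweepSpec(
            parameter="thickness",
            grid=np.array([0.50, 0.60]),
            fixed=reference_eye,
        )
        table = run_sweep(spec).table
        num = (table["iopg0_mmhg"].iloc[1] - table["iopg0_mmhg"].iloc[0]) / 0.10
        assert num == pytest.approx(
            float(slope_vs_modulus([0.16, 0.32], reference_geom)[0]), rel=1e-6
        )

    def test_needs_two_values(self, reference_geom):
        with pytest.raises(ValueError):
            slope_vs_modulus([0.16], reference_geom)
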