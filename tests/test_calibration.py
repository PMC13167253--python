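import json

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from cacalib import (
    EQ1_COEFFS,
    CalibrationCurve,
    CTVolume,
    HUCalibrator,
    HUPairTable,
    Protocol,
    apply_calibration,
    default_phantom_spec,
    eq1_forward,
    fit_calibration,
    invert_curve,
    make_phantom_volume,
)
from cacalib.calibration import (
    CalibrationError,
    build_pair_table,
    measure_insert_hu,
)


def pair_table(x, y):
    return HUPairTable(pd.DataFrame({
        "variant": "T", "insert": [f"i{k}" for k in range(len(x))],
        "ldct_hu": x, "csct_hu": y,
    }))


def identity_curve(domain=(-2000.0, 2000.0)):
    return CalibrationCurve(order=1, coeffs=(1.0, 0.0), domain=domain,
                            sse=0.0, r2=1.0)


class TestFitSelection:
    def test_identity_pairs_reproduce_line(self):
        x = np.linspace(-500, 1000, 20)
        curve, diag = fit_calibration(pair_table(x, x))
        assert curve.order == 1  # ties toward lower order
        assert curve.sse == pytest.approx(0.0, abs=1e-12)
        assert curve.r2 == pytest.approx(1.0)
        np.testing.assert_allclose(curve.coeffs, (1.0, 0.0), atol=1e-9)

    def test_cubic_coefficients_recovered(self):
        x = np.linspace(-1000, 1500, 50)
        curve, diag = fit_calibration(pair_table(x, eq1_forward(x)))
        assert curve.order == 3
        np.testing.assert_allclose(curve.coeffs, EQ1_COEFFS, rtol=1e-6)
        sse = diag.set_index("order")["sse"]
        assert sse[3] < sse[2] < sse[1]

    def test_collinear_points_exclude_underdetermined_order(self):
        x = np.array([0.0, 100.0, 200.0])
        curve, diag = fit_calibration(pair_table(x, 2 * x + 1))
        assert not diag.set_index("order").loc[3, "condition_ok"]
        assert curve.order == 1
        assert curve.sse == pytest.approx(0.0, abs=1e-12)

    def test_degree_k_generators_recovered(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(-800, 1200, 30))
        for k, coeffs in [(1, (1.2, -5.0)), (2, (1e-4, 0.9, 3.0)),
                          (3, (2e-7, -1e-4, 1.1, -8.0))]:
            curve, _ = fit_calibration(pair_table(x, np.polyval(coeffs, x)))
            assert curve.order == k
            np.testing.assert_allclose(curve.coeffs, coeffs, rtol=1e-6)

    def test_sse_non_increasing_in_order(self):
        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(-500, 1500, 40))
        y = eq1_forward(x) + rng.normal(0, 20, x.size)
        _, diag = fit_calibration(pair_table(x, y))
        ok = diag[diag["condition_ok"]].set_index("order")["sse"]
        assert (ok.diff().dropna() <= 1e-9).all()

    def test_too_few_points(self):
        with pytest.raises(CalibrationError):
            fit_calibration(pair_table([1.0], [1.0]))

    def test_duplicate_rows_rejected(self):
        df = pd.DataFrame({
            "variant": ["A", "A"], "insert": ["x", "x"],
            "ldct_hu": [1.0, 2.0], "csct_hu": [1.0, 2.0],
        })
        with pytest.raises(CalibrationError):
            HUPairTable(df)

    def test_order_override(self):
        x = np.linspace(-1000, 1500, 50)
        curve, _ = fit_calibration(pair_table(x, eq1_forward(x)), order=2)
        assert curve.order == 2

    def test_raw_basis_matches_scaled_fit(self):
        x = np.linspace(-1000, 1500, 50)
        est = HUCalibrator().fit(x, eq1_forward(x))
        grid = np.linspace(-1000, 1500, 333)
        np.testing.assert_allclose(
            np.polyval(est.coeffs_, grid), est.predict(grid), rtol=1e-9
        )

    def test_sklearn_estimator_protocol(self):
        est = HUCalibrator(candidate_orders=(1, 2), max_order=2)
        assert est.get_params()["max_order"] == 2
        cloned = clone(est)
        x = np.linspace(0, 100, 10)
        cloned.fit(x, 2 * x + 1.0)
        assert cloned.order_ == 1
        assert cloned.score(x, 2 * x + 1.0) == pytest.approx(1.0)


class TestApplyCalibration:
    def make_ldct(self, values):
        return CTVolume(np.asarray(values, dtype=float).reshape(1, 1, -1),
                        (1.0, 1.0), 3.0, protocol=Protocol.LDCT)

    def eq1_curve(self):
        x = np.linspace(-1000, 1500, 50)
        curve, _ = fit_calibration(pair_table(x, eq1_forward(x)))
        return curve

    def test_known_values(self):
        out = apply_calibration(self.make_ldct([0.0, 130.0]), self.eq1_curve())
        assert out.voxels[0, 0, 0] == pytest.approx(-12.97, abs=1e-9)
        assert out.voxels[0, 0, 1] == pytest.approx(162.3986987, abs=1e-6)

    def test_identity_curve_changes_only_protocol(self):
        v = self.make_ldct([-100.0, 0.0, 500.0])
        out = apply_calibration(v, identity_curve())
        np.testing.assert_array_equal(out.voxels, v.voxels)
        assert out.protocol is Protocol.CLDCT
        assert v.protocol is Protocol.LDCT  # input untouched

    def test_geometry_preserved(self):
        v = CTVolume(np.zeros((2, 3, 4)), (0.6, 0.7), 3.0,
                     protocol=Protocol.LDCT)
        out = apply_calibration(v, identity_curve())
        assert out.shape == v.shape
        assert out.pixel_spacing == v.pixel_spacing
        assert out.slice_thickness == v.slice_thickness

    @pytest.mark.parametrize("protocol", [Protocol.CSCT, Protocol.CLDCT,
                                          Protocol.TRUTH])
    def test_non_ldct_refused(self, protocol):
        v = CTVolume(np.zeros((1, 2, 2)), (1.0, 1.0), 3.0, protocol=protocol)
        with pytest.raises(ValueError):
            apply_calibration(v, identity_curve())

    def test_bad_condition_refused_unless_forced(self):
        curve = identity_curve()
        curve.condition_ok = False
        v = self.make_ldct([0.0])
        with pytest.raises(CalibrationError):
            apply_calibration(v, curve)
        out = apply_calibration(v, curve, force=True)
        assert out.protocol is Protocol.CLDCT

    def test_transform_volume_matches_apply(self):
        x = np.linspace(-1000, 1500, 50)
        est = HUCalibrator().fit(x, eq1_forward(x))
        v = self.make_ldct([-200.0, 40.0, 800.0])
        np.testing.assert_array_equal(
            est.transform_volume(v).voxels,
            apply_calibration(v, est.curve_).voxels,
        )


class TestInvertCurve:
    def test_constant_term_inverts_to_zero(self):
        x = np.linspace(-1000, 1500, 50)
        curve, _ = fit_calibration(pair_table(x, eq1_forward(x)))
        assert abs(invert_curve(curve, -12.97)) < 1e-5

    def test_identity(self):
        assert invert_curve(identity_curve(), 400.0) == pytest.approx(400.0, abs=1e-6)

    def test_round_trip(self):
        x = np.linspace(-1000, 1500, 50)
        curve, _ = fit_calibration(pair_table(x, eq1_forward(x)))
        rng = np.random.default_rng(1)
        hu = rng.uniform(-1000, 1500, 100)
        np.testing.assert_allclose(curve(invert_curve(curve, hu)), hu, atol=1e-5)

    def test_no_bracket(self):
        with pytest.raises(CalibrationError):
            invert_curve(identity_curve(), 1e7)


class TestRoiMeasurement:
    def test_roi_shrinks_with_warning(self, caplog, noiseless_transfer):
        from cacalib.phantoms import InsertSpec, PhantomSpec

        spec = PhantomSpec(
            variant="X", body_axes=(100.0, 100.0), body_hu=30.0,
            inserts=(InsertSpec("small", (0.0, 0.0), 5.0, 500.0),),
        )
        vol = make_phantom_volume(spec, Protocol.CSCT, noiseless_transfer,
                                  seed=0, matrix=128, fov_mm=128.0, n_slices=3)
        with caplog.at_level("WARNING", logger="cacalib.calibration"):
            table = measure_insert_hu(vol, spec)
        assert "shrinking" in caplog.text
        assert table["mean_hu"].iloc[0] == 500.0

    def test_insert_outside_volume_errors(self, noiseless_transfer):
        from cacalib.phantoms import InsertSpec, PhantomSpec
        from cacalib.volume import GeometryError

        spec = default_phantom_spec("ED4")  # 320 mm wide
        vol = make_phantom_volume(default_phantom_spec("ED1"), Protocol.CSCT,
                                  noiseless_transfer, seed=0, matrix=64,
                                  fov_mm=100.0, n_slices=3)
        with pytest.raises(GeometryError):
            measure_insert_hu(vol, spec)


class TestPhantomFitRecoversTransfer:
    def test_noiseless_phantom_calibration_within_half_hu(self, noiseless_transfer):
        """Curve fitted from noiseless phantom ROI pairs maps LDCT back to
        the CSCT-energy truth within 0.5 HU across [-1000, 1500]."""
        ldct_rows, csct_rows = [], []
        for variant in ("ED1", "ED4"):
            spec = default_phantom_spec(variant)
            kw = {"matrix": 256, "n_slices": 3}
            csct_rows.append(measure_insert_hu(
                make_phantom_volume(spec, Protocol.CSCT, noiseless_transfer,
                                    seed=0, **kw), spec))
            ldct_rows.append(measure_insert_hu(
                make_phantom_volume(spec, Protocol.LDCT, noiseless_transfer,
                                    seed=0, **kw), spec))
        pairs = build_pair_table(pd.concat(ldct_rows, ignore_index=True),
                                 pd.concat(csct_rows, ignore_index=True))
        curve, _ = fit_calibration(pairs)
        assert curve.order == 3
        truth = np.arange(-1000.0, 1500.5, 0.5)
        ldct = noiseless_transfer.inverse(truth)
        np.testing.assert_allclose(curve(ldct), truth, atol=0.5)


class TestCurveSerialization:
    def test_json_round_trip(self, tmp_path):
        x = np.linspace(-1000, 1500, 50)
        curve, _ = fit_calibration(pair_table(x, eq1_forward(x)))
        p = tmp_path / "curve.json"
        curve.to_json(p)
        back = CalibrationCurve.from_json(p)
        assert back.order == curve.order
        assert back.coeffs == curve.coeffs
        assert back.r2 == curve.r2
        payload = json.loads(p.read_text())
        assert payload["coeffs_highest_first"][0] == pytest.approx(3.871e-7, rel=1e-6)

    def test_non_monotone_curve_warns(self):
        with pytest.warns(UserWarning, match="not strictly increasing"):
            CalibrationCurve(order=2, coeffs=(1.0, 0.0, 0.0),
                             domain=(-100.0, 100.0), sse=0.0, r2=1.0)
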