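import numpy as np
import pandas as pd
import pytest
from skimage import measure

from cacalib import (
    CohortParams,
    Protocol,
    default_phantom_spec,
    make_cohort,
    make_patient,
    make_phantom_volume,
    score_scan,
)
from cacalib.calibration import measure_insert_hu
from cacalib.phantoms import InsertSpec, PhantomSpec, TransferModel


def small_phantom_kwargs():
    return {"matrix": 128, "n_slices": 3}


class TestPhantomRasterization:
    def test_noiseless_csct_roi_exact(self, noiseless_transfer):
        spec = default_phantom_spec("ED1")
        vol = make_phantom_volume(spec, Protocol.CSCT, noiseless_transfer,
                                  seed=0, **small_phantom_kwargs())
        table = measure_insert_hu(vol, spec)
        nominal = {ins.name: ins.csct_hu for ins in spec.inserts}
        for _, row in table.iterrows():
            assert row["mean_hu"] == nominal[row["insert"]]

    def test_identity_transfer_ldct_equals_csct(self, identity_transfer):
        spec = default_phantom_spec("ED2")
        kw = small_phantom_kwargs()
        csct = make_phantom_volume(spec, Protocol.CSCT, identity_transfer,
                                   seed=0, fov_mm=320.0, **kw)
        ldct = make_phantom_volume(spec, Protocol.LDCT, identity_transfer,
                                   seed=0, fov_mm=320.0, **kw)
        np.testing.assert_allclose(ldct.voxels, csct.voxels, atol=1e-9)

    def test_spectral_shift_maps_constant_term_to_zero(self, noiseless_transfer):
        # an insert at the cubic's value-at-zero appears at 0 HU on LDCT
        spec = PhantomSpec(
            variant="X", body_axes=(100.0, 100.0), body_hu=30.0,
            inserts=(InsertSpec("probe", (0.0, 0.0), 15.0, -12.97),),
        )
        ldct = make_phantom_volume(spec, Protocol.LDCT, noiseless_transfer,
                                   seed=0, fov_mm=128.0, **small_phantom_kwargs())
        table = measure_insert_hu(ldct, spec)
        assert table["mean_hu"].iloc[0] == pytest.approx(0.0, abs=1e-5)

    def test_air_background_not_mapped(self, noiseless_transfer):
        spec = default_phantom_spec("ED1")
        ldct = make_phantom_volume(spec, Protocol.LDCT, noiseless_transfer,
                                   seed=0, **small_phantom_kwargs())
        assert ldct.voxels[0, 0, 0] == -1000.0

    def test_noise_roi_standard_error(self):
        # ROI of ~1000 voxels at SD 15: |mean - nominal| < 4 HU is > 5 SEs
        transfer = TransferModel(noise_sd_csct=15.0, noise_sd_ldct=15.0)
        spec = default_phantom_spec("ED1")
        vol = make_phantom_volume(spec, Protocol.CSCT, transfer, seed=42,
                                  matrix=256, n_slices=3)
        table = measure_insert_hu(vol, spec)
        nominal = {ins.name: ins.csct_hu for ins in spec.inserts}
        for _, row in table.iterrows():
            assert abs(row["mean_hu"] - nominal[row["insert"]]) < 4.0

    def test_truth_protocol_rejected(self, noiseless_transfer):
        with pytest.raises(ValueError):
            make_phantom_volume(default_phantom_spec("ED1"), Protocol.TRUTH,
                                noiseless_transfer)


class TestMakePatient:
    def test_seeded_determinism(self, noiseless_transfer):
        params = CohortParams(n_patients=1, seed=0)
        a = make_patient(params, noiseless_transfer, patient_seed=99)
        b = make_patient(params, noiseless_transfer, patient_seed=99)
        for x, y in zip(a[:3], b[:3]):
            np.testing.assert_array_equal(x.voxels, y.voxels)
        np.testing.assert_array_equal(a[3].labels, b[3].labels)
        assert a[4]["lesions"] == b[4]["lesions"]

    def test_identity_noiseless_protocols_identical(self, identity_transfer):
        params = CohortParams(n_patients=1, seed=0, motion_sigma_mm=0.0)
        _, csct, ldct, _, _ = make_patient(params, identity_transfer, 7)
        # equal up to the numeric inverter's 1e-6 HU bisection tolerance
        np.testing.assert_allclose(csct.voxels, ldct.voxels, atol=1e-6)

    def test_no_lesions_scores_zero(self, noiseless_transfer):
        params = CohortParams(n_patients=1, seed=0, lesions_per_artery=0.0)
        _, csct, _, mask, meta = make_patient(params, noiseless_transfer, 3)
        assert meta["truth_lesion_count"] == 0
        report = score_scan(csct, mask)
        assert report.total_agatston == 0.0
        assert report.total_volume_mm3 == 0.0

    def test_truth_components_match_recorded_count(self, noiseless_transfer):
        params = CohortParams(n_patients=1, seed=0, lesions_per_artery=1.5)
        truth, _, _, _, meta = make_patient(params, noiseless_transfer, 11)
        n_components = int(measure.label(truth.voxels >= 130.0,
                                         connectivity=3).max())
        assert n_components == meta["truth_lesion_count"]
        assert meta["truth_lesion_count"] > 0

    def test_lesion_peaks_within_range(self, noiseless_transfer):
        params = CohortParams(n_patients=1, seed=0)
        truth, _, _, mask, meta = make_patient(params, noiseless_transfer, 5)
        lo, hi = params.lesion_peak_hu_range
        for lesion in meta["lesions"]:
            assert lo <= lesion["peak_hu"] <= hi
        # lesions live inside artery labels
        assert (mask.labels[truth.voxels >= 130.0] > 0).all()

    def test_motion_changes_only_lesion_slices(self, noiseless_transfer):
        params0 = CohortParams(n_patients=1, seed=0, motion_sigma_mm=0.0)
        params1 = CohortParams(n_patients=1, seed=0, motion_sigma_mm=2.0)
        truth, _, ldct0, _, _ = make_patient(params0, noiseless_transfer, 21)
        _, _, ldct1, _, _ = make_patient(params1, noiseless_transfer, 21)
        lesion_slices = (truth.voxels >= 130.0).any(axis=(1, 2))
        clean = ~lesion_slices
        np.testing.assert_array_equal(ldct0.voxels[clean], ldct1.voxels[clean])
        assert not np.array_equal(ldct0.voxels[lesion_slices],
                                  ldct1.voxels[lesion_slices])

    @pytest.mark.parametrize("bad_kwargs", [
        {"lesion_peak_hu_range": (100.0, 800.0)},
        {"lesion_radius_range": (2.0, 2.0)},
        {"motion_sigma_mm": -1.0},
    ])
    def test_invalid_params_rejected(self, bad_kwargs):
        with pytest.raises(ValueError):
            CohortParams(**bad_kwargs)


class TestMakeCohort:
    def test_manifest_and_files(self, tmp_path, noiseless_transfer):
        params = CohortParams(n_patients=5, seed=1)
        manifest = make_cohort(params, noiseless_transfer, tmp_path)
        assert len(manifest) == 5
        assert list(manifest.columns[:6]) == [
            "patient_id", "subgroup", "csct_path", "ldct_path", "mask_path",
            "truth_path",
        ]
        for col in ("csct_path", "ldct_path", "truth_path", "mask_path"):
            for p in manifest[col]:
                assert (tmp_path / p).exists() or __import__("pathlib").Path(p).exists()
        assert (tmp_path / "manifest.csv").exists()

    def test_same_seed_reproduces(self, tmp_path, noiseless_transfer):
        params = CohortParams(n_patients=3, seed=5)
        m1 = make_cohort(params, noiseless_transfer, tmp_path / "a")
        m2 = make_cohort(params, noiseless_transfer, tmp_path / "b")
        pd.testing.assert_frame_equal(
            m1.drop(columns=[c for c in m1.columns if c.endswith("_path")]),
            m2.drop(columns=[c for c in m2.columns if c.endswith("_path")]),
        )
        a = np.asarray(__import__("nibabel").load(m1["csct_path"][0]).dataobj)
        b = np.asarray(__import__("nibabel").load(m2["csct_path"][0]).dataobj)
        np.testing.assert_array_equal(a, b)

    def test_different_seeds_differ(self, tmp_path, noiseless_transfer):
        m1 = make_cohort(CohortParams(n_patients=3, seed=1), noiseless_transfer,
                         tmp_path / "a")
        m2 = make_cohort(CohortParams(n_patients=3, seed=2), noiseless_transfer,
                         tmp_path / "b")
        assert (
            m1["truth_lesion_count"].tolist() != m2["truth_lesion_count"].tolist()
            or m1["truth_total_volume_mm3"].tolist()
            != m2["truth_total_volume_mm3"].tolist()
        )
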