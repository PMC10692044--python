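"""Phantom generator: geometry, determinism, observer simulation, splits."""

import numpy as np
import pandas as pd
import pytest

from crlmvol.ct_io import MaskVolume
from crlmvol.metrics import confusion_counts, dice_from_counts
from crlmvol.phantoms import (
    CohortManifest,
    GenerationError,
    PhantomSpec,
    generate_cohort,
    generate_phantom,
    perturb_mask,
    split_cohort,
)
from crlmvol.volumetry import total_tumor_volume

TINY = dict(grid_shape=(32, 32, 16), spacing_mm=(2.0, 2.0, 2.5))


class TestSpecValidation:
    def test_hyperdense_lesions_rejected(self):
        with pytest.raises(ValueError, match="hypodense"):
            PhantomSpec(lesion_hu_mean=120.0, liver_hu_mean=110.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(grid_shape=(0, 10, 10)),
            dict(spacing_mm=(1, -1, 1)),
            dict(n_lesions_range=(3, 1)),
            dict(lesion_radius_range_mm=(0.0, 5.0)),
            dict(noise_sd_hu=-1.0),
        ],
    )
    def test_invalid_ranges(self, kwargs):
        with pytest.raises(ValueError):
            PhantomSpec(**kwargs)


class TestGeneratePhantom:
    def test_no_lesions_requested(self):
        spec = PhantomSpec(n_lesions_range=(0, 0), seed=1, **TINY)
        _, _, tumor, truth = generate_phantom(spec, "s1", "p1")
        assert tumor.labels.sum() == 0
        assert truth.true_ttv_cm3 == 0.0

    def test_seeded_determinism_bitwise(self):
        spec = PhantomSpec(seed=5, **TINY)
        a = generate_phantom(spec, "s1", "p1")
        b = generate_phantom(spec, "s1", "p1")
        np.testing.assert_array_equal(a[0].voxels, b[0].voxels)
        np.testing.assert_array_equal(a[2].labels, b[2].labels)
        c = generate_phantom(spec, "s2", "p1")  # different scan differs
        assert (a[0].voxels != c[0].voxels).any()

    def test_tumor_inside_liver(self):
        for seed in (0, 1, 2, 3):
            spec = PhantomSpec(seed=seed, **TINY)
            _, liver, tumor, _ = generate_phantom(spec, f"s{seed}", "p")
            assert not np.any(tumor.labels & ~liver.labels)

    def test_liver_is_single_connected_component(self):
        from scipy import ndimage

        spec = PhantomSpec(seed=2, **TINY)
        _, liver, _, _ = generate_phantom(spec, "s", "p")
        _, n = ndimage.label(liver.labels)
        assert n == 1

    def test_liver_hu_mean_within_noise_bound(self):
        # blur disabled: boundary partial-volume mixing would bias the mean
        spec = PhantomSpec(seed=3, blur_sigma_mm=0.0, n_lesions_range=(0, 0), **TINY)
        ct, liver, _, _ = generate_phantom(spec, "s", "p")
        inside = ct.voxels[liver.labels.astype(bool)]
        sd_vox = np.hypot(spec.liver_hu_sd, spec.noise_sd_hu)
        bound = 3 * sd_vox / np.sqrt(inside.size)
        assert abs(inside.mean() - spec.liver_hu_mean) < bound

    def test_truth_ttv_matches_volumetry_exactly(self):
        spec = PhantomSpec(seed=4, **TINY)
        _, _, tumor, truth = generate_phantom(spec, "s", "p")
        assert truth.true_ttv_cm3 == total_tumor_volume(tumor).ttv_cm3

    def test_sphere_volume_within_surface_voxel_bound(self):
        r = 6.2  # mm
        spec = PhantomSpec(
            grid_shape=(32, 32, 32),
            spacing_mm=(1.0, 1.0, 1.0),
            n_lesions_range=(1, 1),
            lesion_radius_range_mm=(r, r),
            seed=6,
        )
        _, _, tumor, truth = generate_phantom(spec, "s", "p")
        analytic = 4 / 3 * np.pi * r**3 / 1000.0  # ≈ 0.998 cm³
        # voxels whose center lies within half a voxel diagonal of the
        # sphere surface bound the discretization error
        half_diag = np.sqrt(3) / 2
        shell = ((r - half_diag) ** 3, (r + half_diag) ** 3)
        shell_cm3 = 4 / 3 * np.pi * (shell[1] - shell[0]) / 1000.0
        assert abs(truth.true_ttv_cm3 - analytic) < shell_cm3
        assert truth.true_ttv_cm3 == pytest.approx(analytic, rel=0.15)

    def test_oversized_lesion_fails_generation(self):
        spec = PhantomSpec(
            grid_shape=(16, 16, 8),
            spacing_mm=(1.0, 1.0, 1.0),
            lesion_radius_range_mm=(50.0, 60.0),
            seed=0,
        )
        with pytest.raises(GenerationError):
            generate_phantom(spec, "s", "p", max_retries=20)


class TestPerturbMask:
    @staticmethod
    def _ball_mask(shape=(24, 24, 12), spacing=(2, 2, 2.5), radius=14.0):
        grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij")
        center = [n * s / 2 for n, s in zip(shape, spacing)]
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        return MaskVolume("m", (d2 <= radius**2).astype(np.uint8), spacing)

    def test_zero_magnitude_is_identity(self):
        m = self._ball_mask()
        out = perturb_mask(m, 0.0, seed=0)
        np.testing.assert_array_equal(out.labels, m.labels)

    def test_empty_mask_stays_empty(self):
        m = MaskVolume("m", np.zeros((8, 8, 8), dtype=np.uint8), (1, 1, 1))
        out = perturb_mask(m, 5.0, seed=0)
        assert out.labels.sum() == 0

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            perturb_mask(self._ball_mask(), -1.0, seed=0)

    def test_deterministic_given_seed(self):
        m = self._ball_mask()
        a = perturb_mask(m, 2.0, seed=3)
        b = perturb_mask(m, 2.0, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_dsc_decreases_with_magnitude_on_average(self):
        m = self._ball_mask()

        def mean_dsc(mag):
            vals = []
            for seed in range(20):
                p = perturb_mask(m, mag, seed=seed)
                vals.append(dice_from_counts(confusion_counts(m, p)))
            return float(np.mean(vals))

        assert mean_dsc(1.0) > mean_dsc(3.0)


class TestSplitCohort:
    @staticmethod
    def _entries(n_patients, scans_per_patient=1):
        rows = []
        for p in range(n_patients):
            for s in range(scans_per_patient):
                rows.append({"patient_id": f"p{p}", "scan_id": f"p{p}_s{s}"})
        return pd.DataFrame(rows)

    def test_largest_remainder_sizes(self):
        manifest = split_cohort(self._entries(10), (0.728, 0.065, 0.206), seed=0)
        counts = manifest.frame["partition"].value_counts()
        assert (counts["train"], counts["validation"], counts["test"]) == (7, 1, 2)

    def test_patient_scans_stay_together(self):
        manifest = split_cohort(self._entries(6, scans_per_patient=3), (0.5, 0.25, 0.25), seed=1)
        per_patient = manifest.frame.groupby("patient_id")["partition"].nunique()
        assert (per_patient == 1).all()

    def test_degenerate_all_train(self):
        manifest = split_cohort(self._entries(5), (1.0, 0.0, 0.0), seed=0)
        assert (manifest.frame["partition"] == "train").all()

    def test_fewer_patients_than_partitions(self):
        with pytest.raises(ValueError, match="partitions"):
            split_cohort(self._entries(2), (0.5, 0.25, 0.25), seed=0)

    def test_bad_fractions(self):
        with pytest.raises(ValueError, match="fractions"):
            split_cohort(self._entries(5), (0.7, 0.2, 0.2), seed=0)

    def test_deterministic_given_seed(self):
        a = split_cohort(self._entries(12), (0.6, 0.2, 0.2), seed=9)
        b = split_cohort(self._entries(12), (0.6, 0.2, 0.2), seed=9)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_manifest_rejects_leaky_assignment(self):
        df = pd.DataFrame(
            [
                {"patient_id": "p0", "scan_id": "a", "partition": "train"},
                {"patient_id": "p0", "scan_id": "b", "partition": "test"},
            ]
        )
        with pytest.raises(ValueError, match="multiple partitions"):
            CohortManifest(df)


class TestCohortReproducibility:
    def test_same_master_seed_reproduces_everything(self):
        spec = PhantomSpec(seed=13, **TINY)
        m1, d1 = generate_cohort(spec, n_patients=4)
        m2, d2 = generate_cohort(spec, n_patients=4)
        pd.testing.assert_frame_equal(m1.frame, m2.frame)
        for sid in d1:
            np.testing.assert_array_equal(d1[sid][0].voxels, d2[sid][0].voxels)
            np.testing.assert_array_equal(d1[sid][2].labels, d2[sid][2].labels)
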