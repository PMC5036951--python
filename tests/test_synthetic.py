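import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hippoflat.synthetic import (
    DEFAULT_TARGET_R,
    CohortSpec,
    PhantomSpec,
    SpecValidationError,
    generate_cohort_table,
    generate_phantom,
    generate_subject_volumes,
)
from hippoflat.volume_io import (
    LABEL_CSF,
    LABEL_GM,
    LABEL_WM,
    SUBREGION_CODES,
    SUBREGION_NAMES,
)

ISO = (0.4, 0.4, 0.4)


class TestPhantomSpecValidation:
    def test_invalid_shape_named(self):
        with pytest.raises(SpecValidationError, match="shape_kind"):
            generate_phantom(PhantomSpec(shape_kind="sphere"))

    def test_too_thin_sheet_named(self):
        spec = PhantomSpec("flat_slab", 0.5, ISO, (24, 30, 30), 1)
        with pytest.raises(SpecValidationError, match="sheet_thickness_mm"):
            generate_phantom(spec)

    def test_too_small_grid_named(self):
        spec = PhantomSpec("flat_slab", 4.0, ISO, (10, 30, 30), 1)
        with pytest.raises(SpecValidationError, match="grid_dims"):
            generate_phantom(spec)

    def test_band_count_range(self):
        with pytest.raises(SpecValidationError, match="n_subregion_bands"):
            generate_phantom(PhantomSpec(n_subregion_bands=8))


class TestPhantomGeometry:
    def test_slab_is_five_voxels_with_wm_below_csf_above(self):
        spec = PhantomSpec("flat_slab", 2.0, ISO, (24, 30, 30), 1, 0.0, 0)
        vol, gt = generate_phantom(spec)
        # central column: WM then exactly 5 GM voxels then CSF
        col = vol.labels[:, 15, 15]
        gm_idx = np.flatnonzero((col == LABEL_GM) | (col >= 10))
        assert len(gm_idx) == 5
        assert col[gm_idx[0] - 1] == LABEL_WM
        assert col[gm_idx[-1] + 1] == LABEL_CSF
        assert np.unique(gt[gt > 0]) == pytest.approx([2.0])

    def test_shell_ground_truth_uniform(self):
        spec = PhantomSpec("cylindrical_shell", 2.0, ISO, (48, 48, 16), 1, 0.0, 0)
        vol, gt = generate_phantom(spec)
        assert np.unique(gt[gt > 0]) == pytest.approx([2.0])
        gm = vol.gm_mask()
        assert (gt[gm] > 0).all()

    def test_c_sheet_has_seven_bands_in_order(self, c_sheet_phantom):
        vol, _ = c_sheet_phantom
        present = sorted(set(np.unique(vol.labels)) - {0, 1, 2, 3})
        assert present == list(SUBREGION_CODES)
        # band order follows angle: mean angular position increases with code
        c = (np.array(vol.labels.shape[:2]) - 1) / 2
        angles = []
        for code in SUBREGION_CODES:
            idx = np.argwhere(vol.labels == code)[:, :2]
            a = np.arctan2(idx[:, 1] - c[1], idx[:, 0] - c[0])
            angles.append(np.median(a))
        assert angles == sorted(angles)

    def test_label_noise_flips_requested_fraction(self):
        spec = PhantomSpec("flat_slab", 2.0, ISO, (24, 40, 40), 4, 0.2, 9)
        vol, _ = generate_phantom(spec)
        clean, _ = generate_phantom(
            PhantomSpec("flat_slab", 2.0, ISO, (24, 40, 40), 4, 0.0, 9))
        banded = np.isin(clean.labels, SUBREGION_CODES)
        flipped = (vol.labels != clean.labels) & banded
        assert flipped.sum() == pytest.approx(0.2 * banded.sum(), rel=0.01)

    def test_deterministic_for_fixed_seed(self):
        spec = PhantomSpec("folded_c_sheet", 2.0, ISO, (40, 40, 20), 7, 0.1, 3)
        v1, g1 = generate_phantom(spec)
        v2, g2 = generate_phantom(spec)
        np.testing.assert_array_equal(v1.labels, v2.labels)
        np.testing.assert_array_equal(g1, g2)


class TestCohortGeneration:
    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 2 ** 31 - 1))
    def test_exact_categorical_marginals_every_seed(self, seed):
        cohort = generate_cohort_table(CohortSpec(seed=seed))
        assert len(cohort) == 58
        groups = cohort["education_group"].value_counts()
        assert groups["lower"] == 32 and groups["higher"] == 26
        assert (cohort["gender"] == "female").sum() == 27
        assert cohort["family_history"].sum() == 22
        assert (~cohort["mri_available"]).sum() == 4
        geno = cohort.groupby(["apoe_genotype", "education_group"], observed=True).size()
        assert geno[("2/3", "lower")] == 2 and geno[("2/3", "higher")] == 1
        assert geno[("3/3", "lower")] == 12 and geno[("3/3", "higher")] == 6
        assert geno[("3/4", "lower")] == 13 and geno[("3/4", "higher")] == 14
        assert geno[("4/4", "lower")] == 5 and geno[("4/4", "higher")] == 5

    def test_education_within_range_and_groups_consistent(self, default_cohort):
        c = default_cohort
        assert c["education_years"].between(9, 21).all()
        mean = c["education_years"].mean()
        lower = c[c["education_group"] == "lower"]["education_years"]
        higher = c[c["education_group"] == "higher"]["education_years"]
        assert (lower < mean).all() and (higher >= mean).all()

    def test_zero_slopes_zero_noise_gives_base_thickness(self):
        spec = CohortSpec(
            education_slope_by_risklevel_and_subregion={
                rl: {n: 0.0 for n in SUBREGION_NAMES}
                for rl in ("low", "intermediate", "high")},
            residual_sd_mm=1e-12,
            seed=5,
        )
        cohort = generate_cohort_table(spec)
        for name in SUBREGION_NAMES:
            base = spec.base_thickness_mm_by_subregion[name]
            np.testing.assert_allclose(cohort[f"thick_{name}"], base, atol=1e-9)

    def test_risk_levels_follow_genotype_and_fh(self, default_cohort):
        from hippoflat.cohort_stats import assign_risk_level

        for _, row in default_cohort.iterrows():
            assert row["risk_level"] == assign_risk_level(
                row["apoe_genotype"], row["family_history"])

    def test_infeasible_counts_rejected(self):
        with pytest.raises(SpecValidationError, match="apoe_genotype_counts"):
            CohortSpec(apoe_genotype_counts={"3/3": (32, 25)}).validate()
        with pytest.raises(SpecValidationError, match="female_counts"):
            CohortSpec(female_counts=(40, 9)).validate()

    def test_nonzero_low_risk_slopes_rejected(self):
        slopes = {rl: {n: 0.0 for n in SUBREGION_NAMES}
                  for rl in ("low", "intermediate", "high")}
        slopes["low"]["CA1"] = 0.05
        with pytest.raises(SpecValidationError, match="low-risk"):
            CohortSpec(education_slope_by_risklevel_and_subregion=slopes).validate()


class TestSubjectVolumes:
    def test_default_cohort_emits_54_volumes(self, default_cohort):
        spec = PhantomSpec("flat_slab", 2.5, (0.5, 0.5, 0.5), (28, 44, 24), 7, 0.0, 2)
        vols = generate_subject_volumes(default_cohort, spec)
        assert len(vols) == 54

    def test_band_thickness_matches_subject(self, default_cohort):
        spec = PhantomSpec("flat_slab", 2.5, (0.25, 0.25, 0.5), (40, 60, 24), 7, 0.0, 2)
        one = default_cohort[default_cohort["mri_available"]].head(1)
        vols = generate_subject_volumes(one, spec)
        sid, (vol, gt) = next(iter(vols.items()))
        row = one.iloc[0]
        for code, name in zip(SUBREGION_CODES, SUBREGION_NAMES):
            sel = vol.labels == code
            want = float(row[f"thick_{name}"])
            got = float(np.unique(gt[sel])[0])
            assert got == pytest.approx(want, abs=0.25)  # one voxel rounding

    def test_byte_identical_on_rerun(self, default_cohort):
        spec = PhantomSpec("flat_slab", 2.5, (0.5, 0.5, 0.5), (28, 44, 24), 7, 0.0, 2)
        head = default_cohort[default_cohort["mri_available"]].head(2)
        v1 = generate_subject_volumes(head, spec)
        v2 = generate_subject_volumes(head, spec)
        for sid in v1:
            np.testing.assert_array_equal(v1[sid][0].labels, v2[sid][0].labels)

    def test_too_thin_subject_rejected(self, default_cohort):
        spec = PhantomSpec("flat_slab", 2.5, (1.3, 1.3, 1.3), (24, 44, 24), 7, 0.0, 2)
        with pytest.raises(SpecValidationError, match="sheet_thickness_mm"):
            generate_subject_volumes(default_cohort, spec)
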