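"""Synthetic subject and paired-cohort generation."""

import numpy as np
import pytest

from cmr_remodel.phantom import (CohortEffects, LesionSpec, PhantomError,
                                 PhantomParams, generate_paired_cohort,
                                 generate_subject, ground_truth_from_params,
                                 solve_post_contrast_myo_t1, write_subject)
from cmr_remodel.tissue import ecv_from_t1


class TestPhantomParams:
    def test_endo_exceeding_epi_rejected(self):
        with pytest.raises(PhantomError):
            PhantomParams(n_slices=3, endo_radius=(30, 30, 30),
                          epi_radius=(25, 35, 35))

    def test_post_contrast_above_native_rejected(self):
        with pytest.raises(PhantomError):
            PhantomParams(t1_myo_post=1400.0)

    def test_lesion_outside_slices_rejected(self):
        with pytest.raises(PhantomError):
            PhantomParams(lesion_spec=[LesionSpec(99, 250, 30, 0.5)])

    def test_invalid_hematocrit_rejected(self):
        with pytest.raises(PhantomError):
            PhantomParams(hematocrit=1.2)

    def test_levels_split_in_thirds(self):
        p = PhantomParams(n_slices=9)
        assert p.slice_levels == ["basal"] * 3 + ["mid"] * 3 + ["apical"] * 3


class TestGroundTruth:
    def test_ecv_hand_arithmetic(self):
        p = PhantomParams(noise_sd=0.0, t1_myo_native=1300, t1_myo_post=600,
                          t1_blood_native=1900, t1_blood_post=400,
                          hematocrit=0.40)
        assert p.true_ecv() == pytest.approx(0.2728, abs=5e-5)

    def test_volumes_match_analytic_annuli(self):
        p = PhantomParams(n_slices=3, endo_radius=(25, 25, 25),
                          epi_radius=(35, 35, 35), noise_sd=0.0)
        t = ground_truth_from_params(p)
        assert t.true_edv == pytest.approx(3 * np.pi * 625 * 8 / 1000)
        assert t.true_myo_volume_ed == pytest.approx(
            3 * np.pi * (1225 - 625) * 8 / 1000)
        assert t.true_mass == pytest.approx(t.true_myo_volume_ed * 1.05)

    def test_no_lesions_zero_lge_and_clean_image(self):
        p = PhantomParams(noise_sd=0.0, seed=5)
        b = generate_subject(p)
        assert b.truth.true_lge_volume == 0.0
        # no band voxel exceeds remote mean + 6 sd when noise-free
        from cmr_remodel.pipeline import quantify_subject
        m = quantify_subject(b)
        assert m.lge_volume_ml == 0.0
        assert m.lge_mass_g == 0.0

    def test_solve_post_contrast_t1_round_trips_ecv(self):
        t1mp = solve_post_contrast_myo_t1(0.30, 0.42, 1320, 1880, 440)
        assert ecv_from_t1(1320, t1mp, 1880, 440, 0.42) == pytest.approx(
            0.30, rel=1e-12)


class TestGenerateSubject:
    def test_seed_determinism_bitwise(self):
        p1 = PhantomParams(seed=77, lesion_spec=[LesionSpec(1, 250, 30, 0.5)])
        p2 = PhantomParams(seed=77, lesion_spec=[LesionSpec(1, 250, 30, 0.5)])
        a, b = generate_subject(p1), generate_subject(p2)
        assert (a.images.t1_native == b.images.t1_native).all()
        assert (a.images.lge == b.images.lge).all()
        assert (a.masks.labels_ed == b.masks.labels_ed).all()

    def test_different_seed_differs(self):
        a = generate_subject(PhantomParams(seed=1))
        b = generate_subject(PhantomParams(seed=2))
        assert not (a.images.t1_native == b.images.t1_native).all()

    def test_serialization_byte_identical(self, tmp_path):
        p = PhantomParams(seed=9, lesion_spec=[LesionSpec(0, 260, 20, 0.5)])
        d1 = write_subject(generate_subject(p), tmp_path / "a")
        d2 = write_subject(generate_subject(p), tmp_path / "b")
        for f in sorted(x.name for x in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_masks_delineate_generating_geometry(self):
        p = PhantomParams(noise_sd=0.0, seed=3)
        b = generate_subject(p)
        g = p.grid_size
        c = (g - 1) / 2.0
        ii, jj = np.indices((g, g))
        r = np.hypot(ii - c, jj - c)
        for k in (0, p.n_slices - 1):
            cavity = b.masks.labels_ed[..., k] == 1
            assert (cavity == (r < p.endo_radius[k])).all()

    def test_lesion_overlapping_reference_roi_rejected(self):
        p = PhantomParams(noise_sd=0.0, seed=3)
        # reference ROI lives at sweep 95-145 deg in the free wall
        p.lesion_spec = [LesionSpec(1, 100.0, 30.0, 0.8)]
        with pytest.raises(PhantomError, match="reference ROI"):
            generate_subject(p)

    def test_rician_noise_changes_distribution(self):
        a = generate_subject(PhantomParams(seed=4, rician=False))
        b = generate_subject(PhantomParams(seed=4, rician=True))
        assert not np.allclose(a.images.lge, b.images.lge)


class TestPairedCohort:
    def test_realized_lvmi_change_near_configured_mean(self):
        eff = CohortEffects(n_subjects=43, seed=20)
        _, rec = generate_paired_cohort(eff, render=False)
        se = 8.4 / np.sqrt(43)
        assert rec["delta_lvmi_gen"].mean() == pytest.approx(-19.8,
                                                             abs=2 * se)

    def test_large_cohort_iecv_mean(self):
        eff = CohortEffects(n_subjects=200, seed=21)
        _, rec = generate_paired_cohort(eff, render=False)
        se = 2.6 / np.sqrt(200)
        assert rec["delta_iecv_gen"].mean() == pytest.approx(-4.4,
                                                             abs=2 * se)

    def test_null_effects_give_identical_truth(self):
        eff = CohortEffects(
            n_subjects=4, seed=22,
            delta_lvmi=(0.0, 0.0), delta_iecv=(0.0, 0.0),
            delta_icv=(0.0, 0.0), delta_ef_points=(0.0, 0.0))
        pairs, rec = generate_paired_cohort(eff, render=False)
        for pre, post in pairs:
            assert post.truth.true_lvmi == pytest.approx(pre.truth.true_lvmi)
            assert post.truth.true_iecv == pytest.approx(pre.truth.true_iecv)
            assert post.truth.true_ecv == pytest.approx(pre.truth.true_ecv)

    def test_moment_convergence_at_n1000(self):
        eff = CohortEffects(n_subjects=1000, seed=23)
        _, rec = generate_paired_cohort(eff, render=False)
        n = 1000
        for col, (mu, sd) in [("delta_lvmi_gen", (-19.8, 8.4)),
                              ("delta_iecv_gen", (-4.4, 2.6)),
                              ("delta_icv_gen", (-16.6, 6.6)),
                              ("delta_ef_gen", (-2.6, 3.1))]:
            se_mean = sd / np.sqrt(n)
            se_sd = sd / np.sqrt(2 * n)
            assert rec[col].mean() == pytest.approx(mu, abs=3 * se_mean), col
            assert rec[col].std(ddof=1) == pytest.approx(sd, abs=3 * se_sd), col

    def test_truth_deltas_match_recorded_draws(self):
        eff = CohortEffects(n_subjects=6, seed=24)
        pairs, rec = generate_paired_cohort(eff, render=False)
        for (pre, post), (_, row) in zip(pairs, rec.iterrows()):
            assert post.truth.true_lvmi - pre.truth.true_lvmi == \
                pytest.approx(row["delta_lvmi_gen"], abs=1e-9)
            assert post.truth.true_iecv - pre.truth.true_iecv == \
                pytest.approx(row["delta_iecv_gen"], abs=1e-9)
            assert post.truth.true_icv - pre.truth.true_icv == \
                pytest.approx(row["delta_icv_gen"], abs=1e-9)

    def test_inconsistent_change_sds_rejected(self):
        eff = CohortEffects(n_subjects=4, seed=25,
                            delta_lvmi=(-19.8, 1.0))  # sd too small
        with pytest.raises(PhantomError, match="inconsistent change sds"):
            generate_paired_cohort(eff, render=False)

    def test_cohort_determinism(self):
        eff = CohortEffects(n_subjects=5, seed=26)
        _, r1 = generate_paired_cohort(eff, render=False)
        _, r2 = generate_paired_cohort(eff, render=False)
        assert r1.equals(r2)
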