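"""PET phantom generator: kinetics, geometry, cohorts, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taupet.petquant import extract_tac, washout_metrics
from taupet.synthetic.kinetics import KineticParams
from taupet.synthetic.phantom import (
    REFERENCE_VOLUMES_MM3,
    CohortSpec,
    PhantomSpec,
    adjacent_shell_mask,
    build_atlas,
    generate_cohort,
    generate_pet_phantom,
    tracer_profile,
)


class TestKinetics:
    @pytest.mark.parametrize(
        "targets",
        [((10.0, 0.57), (60.0, 0.11)), ((10.0, 0.72), (60.0, 0.26))],
    )
    def test_calibration_hits_washout_targets_exactly(self, targets):
        kp = KineticParams.from_washout_targets(2.5, 1.0, targets)
        for t, frac in targets:
            assert kp.fraction_of_peak(t) == pytest.approx(frac, abs=1e-12)

    def test_infeasible_targets_raise(self):
        # decays faster than any single exponential through the first point
        with pytest.raises(ValueError, match="single exponential"):
            KineticParams.from_washout_targets(2.5, 1.0, ((10.0, 0.9), (60.0, 0.01)))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        t=st.floats(0.0, 200.0),
        peak_time=st.floats(0.5, 10.0),
        f=st.floats(0.0, 1.0),
        kf=st.floats(0.01, 0.5),
        ks_frac=st.floats(0.0, 1.0),
    )
    def test_curve_nonnegative_and_fraction_bounded(self, t, peak_time, f, kf, ks_frac):
        kp = KineticParams(peak_time, 2.0, f, kf, kf * ks_frac)
        assert kp.curve(t) >= 0.0
        if t >= peak_time:
            assert 0.0 <= kp.fraction_of_peak(t) <= 1.0

    def test_scaled_preserves_shape(self):
        kp = KineticParams(2.5, 1.0, 0.5, 0.1, 0.01)
        t = np.linspace(0, 60, 50)
        np.testing.assert_allclose(kp.scaled(1.3).curve(t), 1.3 * kp.curve(t), rtol=1e-12)


class TestAtlas:
    def test_volumes_within_20_percent_of_reference(self, default_atlas):
        vols = default_atlas.volumes_mm3()
        for name, ref in REFERENCE_VOLUMES_MM3.items():
            assert abs(vols[name] - ref) / ref < 0.20, name

    def test_volume_consistency_with_voxel_count(self, default_atlas):
        mask = default_atlas.mask("brainstem")
        assert default_atlas.volume_mm3("brainstem") == pytest.approx(
            mask.sum() * default_atlas.voxel_volume_mm3
        )

    def test_whole_brain_is_union_of_brain_labels(self, default_atlas):
        wb = default_atlas.mask("whole_brain")
        parts = ["brainstem", "striatum_septum", "cerebellum", "brain_rest"]
        union = np.zeros_like(wb)
        for p in parts:
            union |= default_atlas.mask(p)
        assert np.array_equal(wb, union)


class TestPhantom:
    def test_noise_free_voxels_match_analytic_curves(self, noise_free_phantom):
        img, atlas, truth = noise_free_phantom
        spec_regions = tracer_profile("t807")
        for name, kin in spec_regions.items():
            mask = atlas.mask(name)
            expect = kin.curve(img.frame_mid_min)
            voxel_tacs = img.data[mask]
            np.testing.assert_allclose(
                voxel_tacs, np.broadcast_to(expect, voxel_tacs.shape), rtol=1e-12, atol=1e-14
            )

    def test_truth_table_matches_curves(self, noise_free_phantom):
        _, _, truth = noise_free_phantom
        sub = truth[truth.region == "brainstem"]
        kin = tracer_profile("t807")["brainstem"]
        np.testing.assert_allclose(
            sub.activity.to_numpy(), kin.curve(sub.frame_mid_min.to_numpy()), rtol=1e-12
        )

    def test_proportional_brainstem_construction(self):
        regions = tracer_profile("t807")
        regions = {**regions, "brainstem": regions["striatum_septum"].scaled(1.3)}
        spec = PhantomSpec(regions=regions, psf_sigma_mm=0.0, noise_sd_frac=0.0)
        img, atlas, _ = generate_pet_phantom(spec)
        bst = img.data[atlas.mask("brainstem")]
        strio = img.data[atlas.mask("striatum_septum")]
        np.testing.assert_allclose(
            bst, np.broadcast_to(1.3 * strio[0], bst.shape), rtol=1e-12
        )

    @pytest.mark.parametrize(
        "tracer, fractions", [("t807", (72.0, 26.0)), ("thk5117", (57.0, 11.0))]
    )
    def test_whole_brain_washout_matches_configured_fractions(self, tracer, fractions):
        spec = PhantomSpec.default(tracer, psf_sigma_mm=0.0, noise_sd_frac=0.0)
        img, atlas, _ = generate_pet_phantom(spec)
        wb = extract_tac(img, atlas, "whole_brain")
        got = washout_metrics(wb, [10.0, 60.0])
        np.testing.assert_allclose(got, fractions, atol=1.0)

    def test_seeded_determinism_bit_identical(self):
        spec = PhantomSpec.default("thk5117", grid_shape=(16, 20, 16), voxel_size_mm=(1.0,) * 3)
        img1, _, _ = generate_pet_phantom(spec)
        img2, _, _ = generate_pet_phantom(spec)
        assert np.array_equal(img1.data, img2.data)

    def test_different_seed_changes_noise(self):
        import dataclasses

        spec = PhantomSpec.default("t807", grid_shape=(16, 20, 16), voxel_size_mm=(1.0,) * 3)
        img1, _, _ = generate_pet_phantom(spec)
        img2, _, _ = generate_pet_phantom(dataclasses.replace(spec, seed=spec.seed + 1))
        assert not np.array_equal(img1.data, img2.data)

    def test_spill_in_grows_with_psf(self, default_atlas):
        shell = adjacent_shell_mask(default_atlas, "petrous_bone", 0.5)
        late = []
        for sigma in (0.0, 0.2, 0.4):
            spec = PhantomSpec.default("t807", psf_sigma_mm=sigma, noise_sd_frac=0.0)
            img, _, _ = generate_pet_phantom(spec)
            late.append(img.data[shell][:, -1].mean())
        assert late[0] < late[1] < late[2]

    def test_empty_frame_schedule_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            PhantomSpec(regions=tracer_profile("t807"), frame_schedule=())

    def test_nonpositive_voxel_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            PhantomSpec(regions=tracer_profile("t807"), voxel_size_mm=(0.25, 0.0, 0.25))


class TestCohort:
    def test_zero_effect_zero_cv_groups_identical_noise_free(self):
        spec = PhantomSpec.default("t807", psf_sigma_mm=0.0, noise_sd_frac=0.0,
                                   grid_shape=(16, 20, 16), voxel_size_mm=(1.0,) * 3)
        scans = generate_cohort(CohortSpec(1, 1, 0.0, 0.0, seed=0), spec)
        tg = next(s for s in scans if s.genotype == "TG")
        wt = next(s for s in scans if s.genotype == "WT")
        np.testing.assert_array_equal(tg.image.data, wt.image.data)

    def test_tg_brainstem_scaled_by_effect(self):
        spec = PhantomSpec.default("t807", psf_sigma_mm=0.0, noise_sd_frac=0.0)
        atlas = build_atlas(spec.grid_shape, spec.voxel_size_mm)
        scans = generate_cohort(CohortSpec(1, 1, 0.14, 0.0, seed=0), spec, atlas=atlas)
        tg = next(s for s in scans if s.genotype == "TG")
        wt = next(s for s in scans if s.genotype == "WT")
        bst = atlas.mask("brainstem")
        np.testing.assert_allclose(tg.image.data[bst], 1.14 * wt.image.data[bst], rtol=1e-12)
        other = atlas.mask("striatum_septum")
        np.testing.assert_array_equal(tg.image.data[other], wt.image.data[other])

    def test_animal_factors_persist_across_sessions(self):
        spec = PhantomSpec.default("t807", grid_shape=(16, 20, 16), voxel_size_mm=(1.0,) * 3)
        c = CohortSpec(2, 2, 0.1, 0.05, seed=7)
        s0 = generate_cohort(c, spec, session=0)
        s1 = generate_cohort(c, spec, session=1)
        for a, b in zip(s0, s1):
            assert a.animal_id == b.animal_id
            assert a.region_factors == b.region_factors
            # but the noise realization differs between sessions
            assert not np.array_equal(a.image.data, b.image.data)

    def test_invalid_group_sizes_rejected(self):
        with pytest.raises(ValueError, match="n_tg"):
            CohortSpec(0, 7)

    def test_mean_one_factors(self):
        spec = PhantomSpec.default("t807", grid_shape=(8, 10, 8), voxel_size_mm=(2.0,) * 3)
        scans = generate_cohort(CohortSpec(60, 60, 0.0, 0.10, seed=1), spec)
        factors = np.array([list(s.region_factors.values()) for s in scans])
        assert factors.mean() == pytest.approx(1.0, abs=0.01)
        assert factors.std() == pytest.approx(0.10, abs=0.02)
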