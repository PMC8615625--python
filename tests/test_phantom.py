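import numpy as np
import pandas as pd
import pytest

import vesselfoci as vf


class TestArmConfig:
    def test_rate_model(self):
        arm = vf.ArmConfig("a", lambda_ext=2.0, lambda_emitter=10.0, tau_um=50.0)
        assert arm.mean_foci(0.0) == pytest.approx(12.0)
        assert arm.mean_foci(50.0) == pytest.approx(2 + 10 / np.e)
        assert float(arm.mean_foci(1e6)) == pytest.approx(2.0)

    @pytest.mark.parametrize("kwargs", [
        dict(lambda_ext=-1), dict(lambda_emitter=-0.1), dict(tau_um=0.0),
        dict(area_scale=0.0), dict(frac_pos_marker=1.5),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            vf.ArmConfig("a", **kwargs)


class TestGenerateSection:
    def test_null_arm_has_zero_true_foci(self, small_geometry):
        arm = vf.ArmConfig("null", lambda_ext=0.0, lambda_emitter=0.0)
        sec = vf.generate_section(arm, small_geometry, seed=5, render=False)
        assert (sec.truth["n_foci"] == 0).all()
        assert len(sec.truth_foci) == 0

    def test_flat_profile_in_long_decay_limit(self):
        # tau -> infinity: mean foci independent of distance
        arm = vf.ArmConfig("flat", lambda_ext=0.0, lambda_emitter=6.0, tau_um=1e9)
        geom = vf.SectionGeometry(shape=(512, 512), n_nuclei=45)
        tabs = [vf.generate_section(arm, geom, seed=s, render=False).truth
                for s in range(8)]
        truth = pd.concat(tabs)
        near = truth[truth.distance_um < 40]["n_foci"].mean()
        far = truth[truth.distance_um > 80]["n_foci"].mean()
        assert near == pytest.approx(6.0, rel=0.15)
        assert far == pytest.approx(6.0, rel=0.15)

    def test_decaying_profile_orders_categories(self):
        arm = vf.ArmConfig("em", lambda_ext=2.0, lambda_emitter=10.0, tau_um=50.0)
        geom = vf.SectionGeometry(shape=(768, 768), n_nuclei=60)
        tabs = [vf.generate_section(arm, geom, seed=s, render=False).truth
                for s in range(6)]
        truth = pd.concat(tabs)
        by_cat = truth.groupby("category")["n_foci"].mean()
        assert by_cat["<50 µm"] > by_cat["50–100 µm"] > by_cat[">100 µm"]

    def test_fixed_seed_is_bit_reproducible(self, small_geometry):
        arm = vf.ArmConfig("a", lambda_ext=3.0)
        s1 = vf.generate_section(arm, small_geometry, seed=9)
        s2 = vf.generate_section(arm, small_geometry, seed=9)
        np.testing.assert_array_equal(s1.gamma_h2ax.voxels, s2.gamma_h2ax.voxels)
        np.testing.assert_array_equal(s1.labels, s2.labels)
        pd.testing.assert_frame_equal(s1.truth, s2.truth)

    def test_truth_consistent_with_rendered_masks(self, rendered_section):
        sec = rendered_section
        # nuclei count and label mask agree
        assert sec.truth["nucleus_id"].nunique() == len(sec.truth)
        assert set(np.unique(sec.labels)) - {0} == set(sec.truth["nucleus_id"])
        # areas recorded from painted pixels
        for _, row in sec.truth.head(5).iterrows():
            painted = (sec.labels == row.nucleus_id).sum()
            assert row.area_um2 == pytest.approx(
                painted * sec.geometry.pixel_size ** 2)
        # every planted focus sits inside its nucleus label
        for _, f in sec.truth_foci.iterrows():
            assert sec.labels[int(f.y_px), int(f.x_px)] == f.nucleus_id

    def test_microenvironment_structure(self, rendered_section):
        sec = rendered_section
        from scipy import ndimage
        dist_um = ndimage.distance_transform_edt(
            ~sec.vessel.pixels) * sec.geometry.pixel_size
        # pimonidazole stays negative within 50 µm of the perfused vessel
        assert not sec.pimo.pixels[dist_um <= 50.0].any()
        # and appears beyond it
        assert sec.pimo.pixels[dist_um > 60.0].mean() > 0.3
        # BrdU-positive cells are present near the vessel
        lab, n = ndimage.label(sec.brdu.pixels & (dist_um <= 50.0))
        assert n >= 10

    def test_eligibility_of_generated_roi(self, rendered_section):
        flags = vf.check_roi_eligibility(rendered_section.vessel,
                                         rendered_section.pimo,
                                         rendered_section.brdu)
        assert flags.eligible

    def test_area_scale_enlarges_nuclei(self):
        geom = vf.SectionGeometry(shape=(512, 512), n_nuclei=25)
        base = vf.generate_section(vf.ArmConfig("c"), geom, seed=3, render=False)
        big = vf.generate_section(vf.ArmConfig("e", area_scale=1.4), geom,
                                  seed=3, render=False)
        assert big.truth.area_um2.mean() > 1.2 * base.truth.area_um2.mean()

    def test_infeasible_packing_raises(self):
        geom = vf.SectionGeometry(shape=(128, 128), n_nuclei=200)
        with pytest.raises(ValueError, match="without overlap|no room"):
            vf.generate_section(vf.ArmConfig("a"), geom, seed=0, render=False)


class TestGenerateExperiment:
    def test_bookkeeping_arms_tumors_rois(self):
        arms = [vf.ArmConfig(f"arm{i}") for i in range(3)]
        geom = vf.SectionGeometry(shape=(320, 320), n_nuclei=10)
        packets, truth = vf.generate_experiment(
            arms, n_tumors_per_arm=2, n_rois=2, seed=1, geometry=geom,
            render=False)
        assert len(packets) == 3 * 2 * 2
        assert truth.groupby(["tumor_id", "roi_id"]).ngroups == 12
        assert set(truth["arm_id"]) == {"arm0", "arm1", "arm2"}

    def test_zero_tumor_variance_shares_rates(self):
        arms = [vf.ArmConfig("a", lambda_ext=5.0)]
        geom = vf.SectionGeometry(shape=(320, 320), n_nuclei=12)
        packets, _ = vf.generate_experiment(arms, n_tumors_per_arm=3, n_rois=1,
                                            seed=2, geometry=geom,
                                            sigma_tumor=0.0, render=False)
        rates = {p["section"].arm.lambda_ext for p in packets}
        assert rates == {5.0}

    def test_tumor_random_effect_varies_rates(self):
        arms = [vf.ArmConfig("a", lambda_ext=5.0)]
        geom = vf.SectionGeometry(shape=(320, 320), n_nuclei=12)
        packets, _ = vf.generate_experiment(arms, n_tumors_per_arm=3, n_rois=1,
                                            seed=2, geometry=geom,
                                            sigma_tumor=0.5, render=False)
        rates = {round(p["section"].arm.lambda_ext, 6) for p in packets}
        assert len(rates) == 3


class TestSimulateFociCounts:
    def test_counts_follow_the_decay_model(self):
        arm = vf.ArmConfig("a", lambda_ext=2.0, lambda_emitter=10.0, tau_um=50.0)
        df = vf.simulate_foci_counts(arm, n_nuclei=30_000, seed=4)
        near = df[df.distance_um < 20]
        far = df[df.distance_um > 200]
        assert near["n_foci"].mean() == pytest.approx(
            arm.mean_foci(near.distance_um).mean(), rel=0.05)
        assert far["n_foci"].mean() == pytest.approx(
            arm.mean_foci(far.distance_um).mean(), rel=0.05)
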