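import numpy as np
import pandas as pd
import pytest

from radiocell import foci_imaging as fi
from radiocell import synthetic_data as sd


class TestMaxProject:
    def test_single_plane_identity(self):
        img = np.random.default_rng(0).random((1, 32, 32))
        assert np.array_equal(fi.max_project(img), img[0])

    def test_disjoint_spots_union(self):
        a = np.zeros((16, 16))
        b = np.zeros((16, 16))
        a[2, 2] = 5.0
        b[10, 10] = 7.0
        proj = fi.max_project(np.stack([a, b]))
        assert proj[2, 2] == 5.0 and proj[10, 10] == 7.0

    def test_projection_matches_analytic_envelope(self):
        nuc, dam, _, _ = sd.gen_foci_images(
            seed=4, n_nuclei=5, image_shape=(400, 400), noise=False
        )
        # noiseless planes are scaled copies; the max recovers the envelope
        assert np.allclose(fi.max_project(nuc), nuc.max(axis=0))
        assert np.allclose(fi.max_project(dam), dam.max(axis=0))

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            fi.max_project(np.zeros((0, 8, 8)))


class TestStackIO:
    def test_tiff_round_trip(self, tmp_path):
        _, dam, _, _ = sd.gen_foci_images(seed=21, n_nuclei=2,
                                          image_shape=(200, 200))
        path = tmp_path / "stack.tif"
        fi.write_stack(path, dam)
        back = fi.read_stack(path)
        assert back.shape == dam.shape
        assert np.allclose(back, dam.astype(np.float32))

    def test_single_page_read_as_one_plane(self, tmp_path):
        path = tmp_path / "plane.tif"
        fi.write_stack(path, np.ones((16, 16)))
        assert fi.read_stack(path).shape == (1, 16, 16)


class TestSegmentNuclei:
    def test_nonoverlapping_ellipses_all_found_with_good_iou(self):
        nuc, _, truth, _ = sd.gen_foci_images(seed=0, n_nuclei=25)
        rois = fi.segment_nuclei(fi.max_project(nuc))
        assert len(rois) == len(truth)
        yy, xx = np.mgrid[0 : nuc.shape[1], 0 : nuc.shape[2]]
        for _, row in truth.iterrows():
            dy, dx = yy - row.center_y, xx - row.center_x
            u = dy * np.cos(row.theta_rad) + dx * np.sin(row.theta_rad)
            v = -dy * np.sin(row.theta_rad) + dx * np.cos(row.theta_rad)
            true_mask = (u / row.axis_a_px) ** 2 + (v / row.axis_b_px) ** 2 <= 1
            ious = [
                (r.mask & true_mask).sum() / (r.mask | true_mask).sum()
                for r in rois
            ]
            assert max(ious) >= 0.8

    def test_blank_image_warns_empty(self):
        with pytest.warns(UserWarning):
            assert fi.segment_nuclei(np.zeros((64, 64))) == []

    def test_touching_ellipses_split_by_watershed(self):
        yy, xx = np.mgrid[0:200, 0:200]
        img = np.zeros((200, 200))
        # two ellipses with centres 1.2 minor-axes apart (overlapping)
        for cy in (80.0, 122.0):
            mask = ((yy - cy) / 35.0) ** 2 + ((xx - 100.0) / 45.0) ** 2 <= 1
            img[mask] = 500.0
        rois = fi.segment_nuclei(img, peak_min_distance_px=15)
        assert len(rois) == 2


class TestCountFoci:
    def test_uniform_signal_gives_zero(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:50, 10:50] = True
        roi = fi.NucleusROI(label=1, mask=mask, area_px=int(mask.sum()))
        assert fi.count_foci(roi, np.full((64, 64), 7.0)) == 0

    def test_twelve_foci_recovered_within_one(self):
        hits = 0
        for seed in range(6):
            nuc, dam, truth, _ = sd.gen_foci_images(
                seed=200 + seed, n_nuclei=1, mean_foci=12, sd_foci=0.0,
                focus_snr=5.0, image_shape=(256, 256),
            )
            rois = fi.segment_nuclei(fi.max_project(nuc))
            count = fi.count_foci(rois[0], fi.max_project(dam))
            hits += abs(count - truth.true_foci[0]) <= 1
        assert hits >= 5

    def test_affine_intensity_invariance(self):
        nuc, dam, _, _ = sd.gen_foci_images(seed=9, n_nuclei=3,
                                            image_shape=(400, 400))
        rois = fi.segment_nuclei(fi.max_project(nuc))
        dam2d = fi.max_project(dam)
        for roi in rois:
            assert fi.count_foci(roi, dam2d) == fi.count_foci(
                roi, 3.5 * dam2d + 100.0
            )

    def test_adding_a_bright_focus_never_decreases_count(self):
        nuc, dam, _, _ = sd.gen_foci_images(seed=13, n_nuclei=1, mean_foci=5,
                                            sd_foci=0.0, image_shape=(256, 256))
        rois = fi.segment_nuclei(fi.max_project(nuc))
        dam2d = fi.max_project(dam)
        before = fi.count_foci(rois[0], dam2d)
        ys, xs = np.nonzero(rois[0].mask)
        cy, cx = int(ys.mean()), int(xs.mean())
        yy, xx = np.mgrid[0 : dam2d.shape[0], 0 : dam2d.shape[1]]
        spot = 500.0 * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 1.2**2)
        )
        after = fi.count_foci(rois[0], dam2d + spot)
        assert after >= before

    def test_recovery_slope_across_generated_means(self):
        generated, detected = [], []
        for i, mean in enumerate((3, 8, 14, 20, 25)):
            nuc, dam, truth, _ = sd.gen_foci_images(
                seed=50 + i, n_nuclei=10, mean_foci=mean,
                sd_foci=np.sqrt(mean),
            )
            rois = fi.segment_nuclei(fi.max_project(nuc))
            dam2d = fi.max_project(dam)
            generated.append(truth.true_foci.mean())
            detected.append(np.mean([fi.count_foci(r, dam2d) for r in rois]))
        slope = np.polyfit(generated, detected, 1)[0]
        assert 0.85 <= slope <= 1.1


class TestTimecourse:
    @pytest.fixture()
    def per_nucleus(self):
        rng = np.random.default_rng(0)
        rows = []
        for cond, mean in (("untreated", 4.0), ("treated", 8.0)):
            for _ in range(120):
                rows.append(
                    {
                        "condition": cond,
                        "timepoint_h": 0.0,
                        "foci_count": rng.poisson(mean),
                    }
                )
        return pd.DataFrame(rows)

    def test_twofold_increase_recovered(self, per_nucleus):
        out = fi.focus_timecourse(per_nucleus)
        treated = out[out.condition == "treated"].iloc[0]
        assert treated.fold_change_vs_untreated == pytest.approx(2.0, rel=0.2)

    def test_sem_is_sd_over_sqrt_n(self, per_nucleus):
        out = fi.focus_timecourse(per_nucleus)
        row = out.iloc[0]
        grp = per_nucleus[
            (per_nucleus.condition == row.condition)
            & (per_nucleus.timepoint_h == row.timepoint_h)
        ]["foci_count"]
        assert row["sem"] == pytest.approx(grp.std(ddof=1) / np.sqrt(len(grp)))

    def test_single_condition_has_no_fold_change(self):
        df = pd.DataFrame(
            {"condition": ["treated"] * 5, "timepoint_h": [0.0] * 5,
             "foci_count": [3, 4, 5, 6, 7]}
        )
        out = fi.focus_timecourse(df)
        assert "fold_change_vs_untreated" not in out.columns
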