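"""Seeded watershed, PIV displacement, seed propagation and tracking."""

import numpy as np
import pytest

from edgepulse import segmentation as seg
from edgepulse import synthetic
from edgepulse.core import ImageStack


def _seedset(seeds, frame=0):
    return seg.SeedSet(frame=frame, seeds=seeds)


class TestSeededWatershed:
    def test_uniform_image_single_seed_fills_frame(self):
        img = np.full((40, 40), 5.0)
        res = seg.seeded_watershed(img, _seedset([(1, 20.0, 20.0)]))
        assert np.all(res.labels == 1)

    def test_two_squares_split_by_bright_ridge(self):
        # two 10×10 µm squares at 0.2 µm/px separated by a bright ridge
        px = 0.2
        img = np.zeros((50, 101))
        img[:, 50] = 100.0
        res = seg.seeded_watershed(img, _seedset([(1, 25.0, 25.0), (2, 75.0, 25.0)]))
        for cid in (1, 2):
            area = (res.labels == cid).sum() * px * px
            assert abs(area - 100.0) / 100.0 < 0.05

    def test_labels_partition_every_pixel(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(60, 60))
        res = seg.seeded_watershed(img, _seedset([(1, 10.0, 10.0), (2, 50.0, 50.0)]))
        assert set(np.unique(res.labels)) == {1, 2}

    def test_seeds_in_one_basin_are_flagged(self):
        img = np.full((40, 40), 5.0)
        res = seg.seeded_watershed(img, _seedset([(1, 10.0, 20.0), (2, 30.0, 20.0)]))
        assert any("share" in w for w in res.warnings)

    def test_regions_contain_their_seeds(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(60, 60)).cumsum(axis=0)
        seeds = [(1, 10.0, 10.0), (2, 45.0, 40.0)]
        res = seg.seeded_watershed(img, _seedset(seeds))
        for cid, x, y in seeds:
            assert res.labels[int(y), int(x)] == cid

    def test_out_of_bounds_seed_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            seg.seeded_watershed(np.zeros((10, 10)), _seedset([(1, 50.0, 5.0)]))

    def test_noiseless_movie_iou_against_ground_truth(
        self, noiseless_tissue, noiseless_movie, first_frame_seeds
    ):
        tissue, _ = noiseless_tissue
        stack, gt = noiseless_movie
        res = seg.seeded_watershed(stack.frame(0), first_frame_seeds)
        for cid in tissue.cell_ids:
            a = res.labels == cid
            b = gt[0] == cid
            iou = (a & b).sum() / (a | b).sum()
            assert iou >= 0.9


class TestPivDisplacement:
    def _textured(self, shape=(96, 96), seed=0):
        rng = np.random.default_rng(seed)
        img = rng.normal(size=shape).cumsum(axis=0).cumsum(axis=1)
        return img - img.mean()

    def test_identical_frames_give_zero_field(self):
        img = self._textured()
        f = seg.piv_displacement(img, img)
        # parabolic subpixel refinement can leave sub-0.1-px residuals
        assert np.allclose(f.dx, 0.0, atol=0.1) and np.allclose(f.dy, 0.0, atol=0.1)
        assert f.confidence.max() > 0.99

    def test_integer_shift_recovered_at_all_confident_points(self):
        """Brute-force oracle: a (2, 1) px roll must be found everywhere the
        window content supports a confident match."""
        img = self._textured(seed=2)
        shifted = np.roll(np.roll(img, 2, axis=1), 1, axis=0)
        f = seg.piv_displacement(img, shifted)
        confident = f.confidence > seg.CONFIDENT_NCC
        # interior points are unaffected by roll wrap-around
        inner = np.zeros_like(confident)
        inner[1:-1, 1:-1] = True
        sel = confident & inner
        assert sel.sum() > 0
        assert np.allclose(f.dx[sel], 2.0, atol=0.2)
        assert np.allclose(f.dy[sel], 1.0, atol=0.2)

    def test_pure_noise_pair_has_low_confidence(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(96, 96))
        b = rng.normal(size=(96, 96))
        f = seg.piv_displacement(a, b)
        assert f.confidence.mean() < seg.CONFIDENT_NCC

    def test_flat_window_reports_zero_with_zero_confidence(self):
        a = np.zeros((64, 64))
        b = np.zeros((64, 64))
        f = seg.piv_displacement(a, b)
        assert np.all(f.dx == 0) and np.all(f.confidence == 0)

    def test_window_minimum_enforced(self):
        with pytest.raises(ValueError):
            seg.piv_displacement(np.zeros((32, 32)), np.zeros((32, 32)), window=4)


class TestPropagateSeeds:
    def test_zero_field_keeps_seeds(self):
        labels = np.ones((40, 40), dtype=int)
        field = seg.PivField(
            xs=np.array([20]), ys=np.array([20]),
            dx=np.zeros((1, 1)), dy=np.zeros((1, 1)), confidence=np.ones((1, 1)),
        )
        out, lost = seg.propagate_seeds(labels, _seedset([(1, 15.0, 22.0)]), field)
        assert out.seeds == [(1, 15.0, 22.0)] and not lost
        assert out.frame == 1

    def test_uniform_field_translates_seeds(self):
        labels = np.ones((40, 40), dtype=int)
        field = seg.PivField(
            xs=np.array([20]), ys=np.array([20]),
            dx=np.full((1, 1), 2.0), dy=np.full((1, 1), 1.0), confidence=np.ones((1, 1)),
        )
        out, _ = seg.propagate_seeds(labels, _seedset([(1, 15.0, 22.0)]), field)
        assert out.seeds == [(1, 17.0, 23.0)]

    def test_seed_leaving_image_marks_cell_lost(self):
        labels = np.ones((40, 40), dtype=int)
        field = seg.PivField(
            xs=np.array([20]), ys=np.array([20]),
            dx=np.full((1, 1), 100.0), dy=np.zeros((1, 1)), confidence=np.ones((1, 1)),
        )
        out, lost = seg.propagate_seeds(labels, _seedset([(1, 35.0, 22.0)]), field)
        assert lost == [1] and not out.seeds

    def test_drifting_movie_keeps_seeds_inside_cells(self):
        cfg = synthetic.SyntheticTissueConfig(
            n_frames=8, dt=10.0, drift_um_per_frame=(0.3, 0.15), seed=2
        )
        tissue, _ = synthetic.generate_oscillating_tissue(cfg)
        stack, gt = synthetic.generate_membrane_movie(tissue, snr=np.inf, seed=2)
        seeds = [(cid, *(tissue.polygons[cid][0].mean(axis=0) / stack.pixel_size))
                 for cid in tissue.cell_ids]
        seeds = _seedset([(c, float(x), float(y)) for c, x, y in seeds])
        inside = total = 0
        for f in range(stack.n_frames - 1):
            field = seg.piv_displacement(stack.frame(f), stack.frame(f + 1))
            seeds, lost = seg.propagate_seeds(gt[f], seeds, field)
            assert not lost
            for cid, x, y in seeds.seeds:
                total += 1
                inside += gt[f + 1][int(round(y)), int(round(x))] == cid
        assert inside / total >= 0.95


class TestTrackTissue:
    def test_single_frame_stack_equals_plain_watershed(
        self, noiseless_movie, first_frame_seeds, noiseless_tissue
    ):
        stack, _ = noiseless_movie
        tissue, _ = noiseless_tissue
        one = ImageStack(
            data=stack.data[:1], pixel_size=stack.pixel_size, dt=stack.dt,
            channel_names=stack.channel_names,
        )
        tracks, labels = seg.track_tissue(one, first_frame_seeds)
        ws = seg.seeded_watershed(stack.frame(0), first_frame_seeds)
        for tr in tracks:
            ws_area = (ws.labels == tr.cell_id).sum() * stack.pixel_size**2
            assert tr.areas[0] == pytest.approx(ws_area, rel=0.05)

    def test_noiseless_tracking_recovers_areas_and_dynamics(
        self, noiseless_tissue, noiseless_movie, first_frame_seeds
    ):
        tissue, truth = noiseless_tissue
        stack, _ = noiseless_movie
        tracks, _ = seg.track_tissue(stack, first_frame_seeds)
        assert len(tracks) == 4
        for tr in tracks:
            true_areas = truth.areas_true[tr.cell_id]
            rel_err = np.abs(tr.areas - true_areas) / true_areas
            assert np.nanmax(rel_err) < 0.05
            # oscillation dynamics are preserved
            r = np.corrcoef(tr.areas, true_areas)[0, 1]
            assert r > 0.9

    def test_translation_equivariance(self, noiseless_tissue):
        tissue, _ = noiseless_tissue
        import dataclasses as dc

        stack, _ = synthetic.generate_membrane_movie(tissue, snr=np.inf, seed=0)
        shift_px = 8
        shifted_data = np.roll(stack.data, shift_px, axis=-1)  # x shift
        shifted = ImageStack(
            data=shifted_data, pixel_size=stack.pixel_size, dt=stack.dt,
            channel_names=stack.channel_names,
        )
        seeds = [(0, 2.0, 2.0)] + [
            (cid, *(tissue.polygons[cid][0].mean(axis=0) / stack.pixel_size))
            for cid in tissue.cell_ids
        ]
        base = _seedset([(c, float(x), float(y)) for c, x, y in seeds])
        moved = _seedset(
            [(c, float(x) + (shift_px if c != 0 else 0), float(y)) for c, x, y in seeds]
        )
        one = ImageStack(data=stack.data[:1], pixel_size=stack.pixel_size, dt=stack.dt,
                         channel_names=stack.channel_names)
        one_shift = ImageStack(data=shifted.data[:1], pixel_size=stack.pixel_size, dt=stack.dt,
                               channel_names=stack.channel_names)
        t1, _ = seg.track_tissue(one, base)
        t2, _ = seg.track_tissue(one_shift, moved)
        for a, b in zip(t1, t2):
            assert b.areas[0] == pytest.approx(a.areas[0], rel=0.02)
            da = b.polygons[0].mean(axis=0) - a.polygons[0].mean(axis=0)
            assert da[0] == pytest.approx(shift_px * stack.pixel_size, abs=0.1)
            assert da[1] == pytest.approx(0.0, abs=0.1)

    def test_all_cells_lost_raises(self):
        stack = ImageStack(
            data=np.zeros((2, 1, 1, 32, 32)), pixel_size=0.1, dt=10.0,
        )
        with pytest.raises(ValueError, match="no cells"):
            seg.track_tissue(stack, _seedset([(0, 5.0, 5.0)]))
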