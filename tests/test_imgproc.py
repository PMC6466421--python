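import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import helicount as hc
from helicount.imgproc import PipelineParams
from helicount.synthgen import CD3
from tests.conftest import make_plan
from tests.oracles import brute_bernsen, brute_rolling_ball_subtract

small_frames = arrays(
    dtype=np.uint8,
    shape=st.tuples(st.integers(12, 24), st.integers(12, 24)),
    elements=st.integers(0, 255),
)


class TestRollingBall:
    @pytest.mark.parametrize("level", [0, 37, 200, 255])
    def test_constant_frame_maps_to_zero(self, level):
        frame = np.full((20, 30), level, dtype=np.uint8)
        assert (hc.rolling_ball_subtract(frame, 4) == 0).all()

    def test_single_pixel_spike_preserved(self):
        frame = np.zeros((15, 15), dtype=np.uint8)
        frame[7, 7] = 180
        out = hc.rolling_ball_subtract(frame, 3)
        assert out[7, 7] == 180
        assert out.sum() == 180

    def test_oversized_ball_rejected(self):
        with pytest.raises(ValueError, match="exceeds frame"):
            hc.rolling_ball_subtract(np.zeros((10, 10), dtype=np.uint8), 6)

    @given(frame=small_frames, radius=st.integers(1, 5))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, frame, radius):
        expected = brute_rolling_ball_subtract(frame, radius)
        assert (hc.rolling_ball_subtract(frame, radius) == expected).all()

    @given(frame=small_frames, radius=st.integers(1, 5))
    @settings(max_examples=40, deadline=None)
    def test_anti_extensive(self, frame, radius):
        out = hc.rolling_ball_subtract(frame, radius)
        assert (out.astype(int) <= frame.astype(int)).all()


class TestBernsen:
    def test_uniform_dim_frame_is_background(self):
        frame = np.full((16, 16), 50, dtype=np.uint8)
        assert not hc.bernsen_threshold(frame, 3, 15, 128).any()

    def test_uniform_bright_frame_is_foreground(self):
        frame = np.full((16, 16), 200, dtype=np.uint8)
        assert hc.bernsen_threshold(frame, 3, 15, 128).all()

    @given(
        frame=small_frames,
        radius=st.integers(1, 4),
        contrast=st.integers(5, 60),
        midgray=st.integers(50, 200),
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, frame, radius, contrast, midgray):
        expected = brute_bernsen(frame, radius, contrast, midgray)
        got = hc.bernsen_threshold(frame, radius, contrast, midgray)
        assert (got == expected).all()

    @given(
        frame=arrays(
            dtype=np.uint8,
            shape=st.tuples(st.integers(12, 20), st.integers(12, 20)),
            elements=st.integers(60, 160),
        ),
        shift=st.integers(1, 40),
    )
    @settings(max_examples=40, deadline=None)
    def test_shift_invariant_where_contrast_met(self, frame, shift):
        """Adding a constant moves local midpoints equally, so the decision
        is unchanged wherever the contrast criterion holds."""
        from scipy import ndimage as ndi

        radius, contrast = 3, 20
        yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        fp = yy**2 + xx**2 <= radius**2
        local_max = ndi.maximum_filter(frame, footprint=fp, mode="nearest")
        local_min = ndi.minimum_filter(frame, footprint=fp, mode="nearest")
        met = (local_max.astype(int) - local_min.astype(int)) >= contrast
        a = hc.bernsen_threshold(frame, radius, contrast, 128)
        b = hc.bernsen_threshold(frame + shift, radius, contrast, 128)
        assert (a[met] == b[met]).all()


class TestFindParticles:
    def test_empty_mask(self):
        mask = np.zeros((10, 10), dtype=bool)
        assert hc.find_particles(mask, params=PipelineParams(min_area=1, max_area=99)) == []

    def test_two_separated_squares(self):
        mask = np.zeros((12, 20), dtype=bool)
        mask[2:5, 2:5] = True
        mask[6:9, 10:13] = True
        ps = hc.find_particles(mask, params=PipelineParams(min_area=1, max_area=99))
        assert len(ps) == 2
        assert sorted(p.area for p in ps) == [9, 9]
        first = min(ps, key=lambda p: p.centroid_x)
        assert (first.centroid_x, first.centroid_y) == (3.0, 3.0)

    @pytest.mark.parametrize("connectivity,expected", [(8, 1), (4, 2)])
    def test_diagonal_touch_depends_on_connectivity(self, connectivity, expected):
        mask = np.zeros((6, 6), dtype=bool)
        mask[2, 2] = mask[3, 3] = True
        params = PipelineParams(min_area=1, max_area=99, connectivity=connectivity)
        assert len(hc.find_particles(mask, params=params)) == expected

    def test_area_filter(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[1, 1] = True  # area 1: below min
        mask[4:10, 4:10] = True  # area 36: above max
        params = PipelineParams(min_area=2, max_area=20)
        assert hc.find_particles(mask, params=params) == []

    def test_count_invariant_under_translation_and_rotation(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((40, 40), dtype=bool)
        for _ in range(6):
            y, x = rng.integers(5, 30, 2)
            mask[y : y + 3, x : x + 3] = True
        params = PipelineParams(min_area=1, max_area=400)
        n = len(hc.find_particles(mask, params=params))
        assert len(hc.find_particles(np.roll(mask, (3, 4), (0, 1)), params=params)) == n
        assert len(hc.find_particles(np.rot90(mask), params=params)) == n

    def test_mean_intensity_from_source(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:4, 2:4] = True
        source = np.zeros((8, 8), dtype=np.uint8)
        source[2:4, 2:4] = [[10, 20], [30, 40]]
        (p,) = hc.find_particles(mask, source, PipelineParams(min_area=1, max_area=99))
        assert p.mean_intensity == pytest.approx(25.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            hc.find_particles(np.zeros((5, 5), dtype=bool), np.zeros((6, 6)))


class TestProcessFrame:
    def test_constant_frame_yields_no_particles(self):
        frame = np.full((60, 60), 120, dtype=np.uint8)
        _, particles = hc.process_frame(frame, PipelineParams(ball_radius=5, bernsen_radius=3))
        assert particles == []

    def test_five_separated_cells_recovered_exactly(self, channel):
        plan = make_plan(1)
        pop, noise = hc.exact_recovery_conditions()
        rng = np.random.default_rng(1)
        recs = [
            hc.GroundTruthRecord(0, x, y, False, 60.0, 0.0)
            for x, y in [(80, 60), (200, 100), (450, 300), (520, 430), (120, 400)]
        ]
        frame = hc.render_frame(recs, CD3, plan, pop, noise, seed=rng)
        _, particles = hc.process_frame(frame, PipelineParams.for_plan(plan))
        assert len(particles) == 5

    def test_blank_noisy_scan_counts_no_cells(self, channel):
        """An empty channel with full shot/read noise yields zero counted
        cells over a 50-pair blank scan.  Per-channel false particles are
        bounded to rare two-tail shot-noise events (a high spike and a
        dark pixel sharing one threshold window); colocalization across
        the two independently-noisy channels suppresses them entirely."""
        plan = make_plan(50)
        pop = hc.PopulationSpec(cd3_concentration=0.0)
        params = PipelineParams.for_plan(plan)
        ds = hc.generate_scan(19, pop, hc.NoiseSpec(), plan, channel)
        res = hc.run_scan(ds, params)
        assert res.n_colocalized == 0
        assert res.n_cd4_channel + res.n_cd3_channel <= 2  # ~2.5e-3/frame tail events


class TestPipelineParams:
    def test_for_plan_rescales_to_grid(self):
        full = hc.AcquisitionPlan()
        params_full = PipelineParams.for_plan(full)
        assert params_full.ball_radius == 50
        assert params_full.bernsen_radius == 15
        down = full.downscaled(4)
        params_down = PipelineParams.for_plan(down)
        assert params_down.ball_radius == pytest.approx(50 / 4, abs=1)
        assert params_down.min_area < params_full.min_area

    @pytest.mark.parametrize(
        "kw",
        [
            dict(ball_radius=0),
            dict(min_area=0),
            dict(min_area=10, max_area=5),
            dict(connectivity=6),
        ],
    )
    def test_validation(self, kw):
        with pytest.raises(ValueError):
            PipelineParams(**kw)
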