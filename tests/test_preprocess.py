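import numpy as np
import pytest

from wfgica.preprocess import (
    DffMovie,
    RawMovie,
    common_mask,
    compute_dff,
    concatenate_states,
    downsample,
    highpass,
    register,
)
from wfgica.states import STATES, Segment, validate_segments


def _movie(frames, fps=10.0, bregma=(10.0, 32.0), lamb=(50.0, 32.0), **kw):
    return RawMovie(frames=np.asarray(frames, np.float32), fps=fps,
                    bregma=bregma, lambda_=lamb, **kw)


def _sine_dff(freq, fps=10.0, dur=120.0, n_pix=3):
    t = np.arange(int(dur * fps)) / fps
    data = np.tile(np.sin(2 * np.pi * freq * t)[:, None], (1, n_pix)).astype(np.float32)
    mask = np.zeros((1, n_pix), bool)
    mask[0] = True
    return DffMovie(data=data, mask=mask, fps=fps,
                    segments=[Segment("iso2.0", 0, len(t))], f0=np.ones(n_pix))


class TestSegments:
    def test_segments_must_be_ordered_deepest_to_awake(self):
        with pytest.raises(ValueError, match="order"):
            validate_segments([Segment("awake", 0, 10), Segment("iso2.0", 10, 20)])

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            validate_segments([Segment("iso2.0", 0, 10), Segment("iso1.75", 5, 20)])


class TestRegister:
    def test_identity_when_landmarks_match_reference(self, rng):
        frames = rng.random((5, 32, 32)).astype(np.float32)
        m = _movie(frames, bregma=(8.0, 16.0), lamb=(26.0, 16.0))
        out = register(m, (8.0, 16.0), (26.0, 16.0))
        assert np.array_equal(out.frames, frames)

    def test_translation_recovered_exactly_on_interior(self, rng):
        frames = rng.random((3, 40, 40)).astype(np.float32)
        # landmarks sit 3 rows below the reference: content must shift up
        m = _movie(frames, bregma=(11.0, 20.0), lamb=(33.0, 20.0))
        out = register(m, (8.0, 20.0), (30.0, 20.0))
        assert np.allclose(out.frames[:, :-3, :], frames[:, 3:, :], atol=1e-5)
        assert out.bregma == (8.0, 20.0)

    def test_rotation_scale_roundtrip(self, rng):
        """Register a rotated/scaled session and check landmark agreement."""
        frames = rng.random((2, 48, 48)).astype(np.float32)
        m = _movie(frames, bregma=(10.0, 25.0), lamb=(40.0, 28.0))
        out = register(m, (9.0, 24.0), (41.0, 24.0))
        assert out.bregma == (9.0, 24.0) and out.lambda_ == (41.0, 24.0)
        assert out.frames.shape == frames.shape

    def test_coincident_landmarks_raise(self, rng):
        m = _movie(rng.random((2, 16, 16)), bregma=(5.0, 8.0), lamb=(5.0, 8.0))
        with pytest.raises(ValueError, match="degenerate"):
            register(m, (4.0, 8.0), (12.0, 8.0))


class TestDownsample:
    def test_factor_one_is_identity(self, rng):
        m = _movie(rng.random((4, 16, 16)))
        assert downsample(m, 1) is m

    def test_constant_block_mean(self):
        m = _movie(np.full((2, 4, 4), 7.0))
        out = downsample(m, 4)
        assert out.frames.shape == (2, 1, 1)
        assert np.allclose(out.frames, 7.0)

    def test_checkerboard_averages_to_half(self):
        board = np.indices((8, 8)).sum(axis=0) % 2
        m = _movie(board[None].astype(np.float32))
        out = downsample(m, 2)
        assert np.allclose(out.frames, 0.5)

    def test_nondivisible_dims_cropped_and_landmarks_scaled(self, rng):
        m = _movie(rng.random((2, 17, 18)), bregma=(8.0, 8.0), lamb=(14.0, 8.0))
        out = downsample(m, 4)
        assert out.frames.shape == (2, 4, 4)
        assert out.bregma == (2.0, 2.0)

    def test_rejects_nonpositive_factor(self, rng):
        with pytest.raises(ValueError):
            downsample(_movie(rng.random((1, 8, 8))), 0)


class TestCommonMask:
    def test_identical_regions_returned(self):
        v = np.zeros((8, 8), bool)
        v[2:6, 2:6] = True
        assert np.array_equal(common_mask([v, v.copy()]), v)

    def test_half_planes_intersect_in_strip(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[:5] = True
        b[3:] = True
        out = common_mask([a, b])
        want = np.zeros((8, 8), bool)
        want[3:5] = True
        assert np.array_equal(out, want)

    def test_disjoint_regions_raise(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0] = True
        b[3] = True
        with pytest.raises(ValueError, match="empty"):
            common_mask([a, b])


class TestComputeDff:
    def test_constant_movie_gives_zeros(self):
        m = _movie(np.full((10, 6, 6), 250.0))
        mask = np.ones((6, 6), bool)
        assert np.allclose(compute_dff(m, mask).data, 0.0)

    def test_ten_percent_step(self):
        frames = np.full((100, 2, 2), 100.0)
        frames[50] = 110.0
        m = _movie(frames)
        dff = compute_dff(m, np.ones((2, 2), bool))
        f0 = 100.0 + 10.0 / 100
        assert np.allclose(dff.data[50], 100 * (110 - f0) / f0, atol=1e-4)

    def test_matches_direct_formula_on_random_movie(self, rng):
        frames = (rng.random((30, 8, 8)) * 50 + 100).astype(np.float32)
        mask = rng.random((8, 8)) > 0.4
        dff = compute_dff(_movie(frames), mask)
        flat = frames[:, mask]
        f0 = flat.mean(axis=0)
        assert np.allclose(dff.data, 100 * (flat - f0) / f0, atol=1e-4)

    def test_nonpositive_baseline_rejected(self):
        frames = np.zeros((5, 4, 4), np.float32)
        with pytest.raises(ValueError, match="baseline"):
            compute_dff(_movie(frames), np.ones((4, 4), bool))


class TestHighpass:
    def test_constant_input_rejected_to_zero(self):
        d = _sine_dff(0.0)
        d.data[:] = 5.0
        out = highpass(d, 0.1)
        assert np.max(np.abs(out.data)) < 1e-6 * 5.0 + 1e-9

    def test_passband_gain_near_unity_at_1hz(self):
        out = highpass(_sine_dff(1.0), 0.1)
        trim = slice(100, -100)
        amp = np.sqrt(2) * np.sqrt(np.mean(out.data[trim, 0] ** 2))
        assert 0.95 <= amp <= 1.05

    def test_stopband_attenuates_very_slow_oscillation(self):
        out = highpass(_sine_dff(0.01, dur=400.0), 0.1)
        trim = slice(200, -200)
        amp = np.sqrt(2) * np.sqrt(np.mean(out.data[trim, 0] ** 2))
        assert amp < 0.1

    def test_zero_mean_invariant_after_filtering(self):
        out = highpass(_sine_dff(0.3), 0.1)
        sd = out.data.std(axis=0)
        assert np.all(np.abs(out.data.mean(axis=0)) < 1e-6 * sd)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            highpass(_sine_dff(1.0, fps=10.0), 5.0)


class TestConcatenateStates:
    def _state_movie(self, state, n, n_pix=4, fps=10.0, seed=0):
        rng = np.random.default_rng(seed)
        mask = np.zeros((2, 2), bool)
        mask.ravel()[:n_pix] = True
        return DffMovie(data=rng.random((n, n_pix)).astype(np.float32), mask=mask,
                        fps=fps, segments=[Segment(state, 0, n)], f0=np.ones(n_pix))

    def test_single_state_identity(self):
        m = self._state_movie("iso2.0", 30)
        out = concatenate_states([m])
        assert np.array_equal(out.data, m.data)
        assert out.segments == [Segment("iso2.0", 0, 30)]

    def test_two_states_lengths_and_boundaries(self):
        a = self._state_movie("iso2.0", 20, seed=1)
        b = self._state_movie("iso1.75", 35, seed=2)
        out = concatenate_states([a, b])
        assert out.n_frames == 55
        assert out.segments == [Segment("iso2.0", 0, 20), Segment("iso1.75", 20, 55)]

    def test_six_state_roundtrip_is_bit_exact(self):
        movies = [self._state_movie(s, 10 + i, seed=i) for i, s in enumerate(STATES)]
        out = concatenate_states(movies)
        for m, seg in zip(movies, out.segments):
            assert np.array_equal(out.data[seg.start:seg.end], m.data)

    def test_mask_mismatch_rejected(self):
        a = self._state_movie("iso2.0", 10)
        b = self._state_movie("iso1.75", 10)
        b.mask = ~b.mask
        b.data = b.data[:, : b.mask.sum()]
        with pytest.raises(ValueError):
            concatenate_states([a, b])


class TestPipelineProperties:
    def test_preprocessing_chain_is_deterministic(self, rng):
        frames = (rng.random((50, 24, 24)) * 40 + 200).astype(np.float32)
        seg = [Segment("iso2.0", 0, 25), Segment("awake", 25, 50)]

        def run():
            m = _movie(frames.copy(), bregma=(6.0, 12.0), lamb=(19.0, 12.0),
                       segments=list(seg))
            m = downsample(m, 2)
            m = register(m, (3.5, 6.0), (10.0, 6.0))
            mask = np.zeros((12, 12), bool)
            mask[3:10, 3:10] = True  # interior, clear of warped-in borders
            d = compute_dff(m, mask)
            return highpass(d, 0.1).data

        assert np.array_equal(run(), run())

    def test_highpass_removes_drift_and_restores_truth_correlation(self):
        """With slow drift in the forward model, filtering brings pixel traces
        closer to the drift-free ground truth than the unfiltered dF/F."""
        from wfgica.synthetic import DriftParams, SimulationConfig, simulate_study

        cfg = SimulationConfig(
            n_subjects=1, sessions_per_subject=1, height=40, width=40,
            fps=10.0, dur_per_state=60.0, landmark_jitter=0, vessel_amp=0.0,
            noise_sd=0.5, drift=DriftParams(sin_amp=0.05, sin_freq=0.02, linear_amp=0.03),
            calibrate=False,
        )
        raws, truth = simulate_study(cfg, seed=4)
        raw = raws[0]
        mask = truth.atlas.mask
        dff = compute_dff(raw, mask)
        filt = highpass(dff, 0.1)
        flat_maps = truth.maps.reshape(truth.maps.shape[0], -1)[:, mask.ravel()]
        signal = (truth.timecourses[raw.session_id].T @ flat_maps)
        signal -= signal.mean(axis=0)
        px = np.argsort(flat_maps.max(axis=0))[-20:]  # strongest-signal pixels

        def mean_corr(data):
            cs = [np.corrcoef(data[:, p], signal[:, p])[0, 1] for p in px]
            return float(np.mean(cs))

        assert mean_corr(filt.data) > mean_corr(dff.data)
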