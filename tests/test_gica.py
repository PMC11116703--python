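import numpy as np
import pytest

from wfgica.gica import (
    GroupDataset,
    back_reconstruct,
    default_l1,
    fit_group_ica,
    icasso,
    reduce_group,
    reduce_session,
    run_ica,
    select_order,
)
from wfgica.preprocess import DffMovie
from wfgica.states import Segment


def _dff(data, fps=10.0, session_id="s"):
    data = np.asarray(data, np.float64)
    t, p = data.shape
    mask = np.zeros((1, p), bool)
    mask[0] = True
    return DffMovie(data=data, mask=mask, fps=fps, f0=np.ones(p),
                    segments=[Segment("iso2.0", 0, t)], session_id=session_id)


def _sparse_sources(n_src, p, rng):
    """Disjoint boxcar maps: super-Gaussian over pixels, mutually independent."""
    maps = np.zeros((n_src, p))
    width = p // n_src
    for k in range(n_src):
        maps[k, k * width : k * width + max(width // 8, 2)] = 1.0
    return maps


class TestReduction:
    def test_full_rank_reduction_is_lossless(self, rng):
        tc = rng.standard_normal((3, 200))
        maps = rng.standard_normal((3, 50))
        x = tc.T @ maps
        red = reduce_session(_dff(x), 3)
        recon = red.u @ red.scaled
        assert np.linalg.norm(recon - x) < 1e-8 * np.linalg.norm(x)

    def test_equal_variance_signals_split_retained_variance(self):
        t = np.arange(400)
        s1 = np.sqrt(2) * np.sin(2 * np.pi * t / 50)
        s2 = np.sqrt(2) * np.cos(2 * np.pi * t / 50)
        m1 = np.zeros(40)
        m2 = np.zeros(40)
        m1[:20] = 1.0
        m2[20:] = 1.0
        x = np.outer(s1, m1) + np.outer(s2, m2)
        red = reduce_session(_dff(x), 1)
        total = np.linalg.norm(x) ** 2
        kept = float(red.s[0] ** 2)
        assert kept / total == pytest.approx(0.5, abs=0.02)

    def test_whitening_contract_identity_covariance(self, rng):
        x = rng.standard_normal((120, 60))
        red = reduce_session(_dff(x), 10)
        cov = red.whitened @ red.whitened.T / red.whitened.shape[1]
        assert np.max(np.abs(cov - np.eye(10))) < 1e-6

    def test_group_stage_whitening_contract(self, rng):
        reds = [reduce_session(_dff(rng.standard_normal((80, 50))), 6) for _ in range(3)]
        model = reduce_group(reds, 5, 50)
        cov = model.group_white @ model.group_white.T / 50
        assert np.max(np.abs(cov - np.eye(5))) < 1e-6

    def test_rank_deficit_rejected(self, rng):
        tc = rng.standard_normal((2, 100))
        maps = rng.standard_normal((2, 30))
        with pytest.raises(ValueError, match="rank"):
            reduce_session(_dff(tc.T @ maps), 5)

    def test_default_l1_headroom(self):
        assert default_l1(8) == 12
        assert default_l1(8, cap=10) == 10


class TestRunIca:
    def _whitened_mixture(self, rng, n_src=3, p=3000, t=300):
        maps = _sparse_sources(n_src, p, rng)
        tc = rng.standard_normal((t, n_src))
        x = tc @ maps  # (T, P): each frame mixes the spatial sources
        red = reduce_session(_dff(x), n_src)
        return red.whitened, maps

    def test_recovers_super_gaussian_sources(self, rng):
        white, maps = self._whitened_mixture(rng)
        comps = run_ica(white, seed=0)
        from wfgica.annotate import match_components

        m = match_components(maps, comps.maps)
        assert np.all(m.abs_r > 0.95)

    def test_pixel_permutation_equivariance(self, rng):
        white, _ = self._whitened_mixture(rng)
        perm = rng.permutation(white.shape[1])
        a = run_ica(white, seed=3).maps
        b = run_ica(white[:, perm], seed=3).maps
        assert np.allclose(a[:, perm], b, atol=1e-8)

    def test_same_seed_reproduces_exactly(self, rng):
        white, _ = self._whitened_mixture(rng)
        a = run_ica(white, seed=11)
        b = run_ica(white, seed=11)
        assert np.array_equal(a.maps, b.maps)

    def test_maps_are_zscored_with_positive_peak(self, rng):
        white, _ = self._whitened_mixture(rng)
        comps = run_ica(white, seed=0)
        assert np.allclose(comps.maps.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(comps.maps.std(axis=1), 1.0, atol=1e-9)
        for row in comps.maps:
            assert row[np.argmax(np.abs(row))] > 0


class TestIcasso:
    def test_well_separated_sources_give_high_stability(self, rng):
        maps = _sparse_sources(4, 4000, rng)
        tc = rng.standard_normal((4, 300))
        x = tc.T @ maps + 0.01 * rng.standard_normal((300, 4000))
        red = reduce_session(_dff(x), 6)
        res, comps = icasso(red.scaled, 4, n_runs=5, seed=0)
        assert np.all(res.stability > 0.95)
        from wfgica.annotate import match_components

        assert np.all(match_components(maps, comps.maps).abs_r > 0.95)

    def test_single_run_rejected(self, rng):
        red = reduce_session(_dff(rng.standard_normal((50, 30))), 4)
        with pytest.raises(ValueError):
            icasso(red.scaled, 3, n_runs=1)

    def test_randinit_runs_cluster_one_estimate_per_run(self, rng):
        maps = _sparse_sources(3, 2000, rng)
        tc = rng.standard_normal((3, 200))
        x = tc.T @ maps
        red = reduce_session(_dff(x), 3)
        res, _ = icasso(red.scaled, 3, n_runs=2, mode="randinit", seed=0)
        for c in range(3):
            idx = np.flatnonzero(res.labels == c)
            runs = idx // 3
            assert sorted(runs) == [0, 1]  # one estimate from each run
            a, b = res.estimates[idx]
            assert abs(np.corrcoef(a, b)[0, 1]) > 0.999


class TestBackReconstruction:
    def test_single_session_collapses_to_group_maps(self, rng):
        maps = _sparse_sources(3, 1500, rng)
        tc = rng.standard_normal((3, 250))
        x = tc.T @ maps
        ds = GroupDataset([_dff(x, session_id="only")])
        fit = fit_group_ica(ds, 3, l1=3, n_runs=0, seed=0)
        back = fit.back.maps["only"]
        # raw back-reconstructed maps equal the group raw maps
        assert np.allclose(back, fit.components.raw_maps, atol=1e-6)

    def test_sign_flip_propagates_to_timecourses(self, rng):
        maps = _sparse_sources(3, 1500, rng)
        tc = rng.standard_normal((3, 250))
        ds = GroupDataset([_dff(tc.T @ maps, session_id="a"),
                           _dff(rng.standard_normal((3, 250)).T @ maps, session_id="b")])
        fit = fit_group_ica(ds, 3, l1=3, n_runs=0, seed=0)  # rank-3 sessions
        comps = fit.components
        flipped = type(comps)(maps=comps.maps.copy(), raw_maps=comps.raw_maps.copy(),
                              mixing=comps.mixing.copy())
        flipped.raw_maps[1] *= -1
        flipped.mixing[:, 1] *= -1
        back2 = back_reconstruct(fit.model, flipped, ds)
        for sid in ("a", "b"):
            assert np.allclose(back2.timecourses[sid][1],
                               -fit.back.timecourses[sid][1], atol=1e-9)
            assert np.allclose(back2.timecourses[sid][0],
                               fit.back.timecourses[sid][0], atol=1e-9)

    def test_reduction_chain_projection_is_idempotent(self, rng):
        reds = [reduce_session(_dff(rng.standard_normal((100, 60))), 8) for _ in range(2)]
        model = reduce_group(reds, 6, 60)
        w, d = model.group_whitening(), model.group_dewhitening()
        stacked = np.concatenate([r.scaled for r in reds], axis=0)
        once = d @ (w @ stacked)
        twice = d @ (w @ once)
        assert np.max(np.abs(once - twice)) < 1e-6

    def test_noiseless_study_timecourse_recovery(self):
        """At the true order on clean data, back-reconstructed session time
        courses match the (band-limited) ground truth."""
        from wfgica.pipeline import RunConfig, run_study
        from wfgica.synthetic import DriftParams, highpass_timecourses
        from wfgica.annotate import match_components

        cfg = RunConfig(seed=6, k=8, simulate=dict(
            fps=10.0, dur_per_state=60.0, height=40, width=40,
            noise_sd=1e-4, vessel_amp=0.0, landmark_jitter=0,
            drift=DriftParams(sin_amp=0.0, linear_amp=0.0)))
        result, truth = run_study(cfg)
        m = match_components(truth.maps[:, result.mask], result.fit.components.maps)
        pairs = {a: b for a, b, _ in m.pairs}
        for sid in list(truth.timecourses)[:3]:
            tc_true = highpass_timecourses(truth.timecourses[sid], 10.0)
            tc_rec = result.fit.back.timecourses[sid]
            for a, b in pairs.items():
                assert abs(np.corrcoef(tc_true[a], tc_rec[b])[0, 1]) > 0.95


class TestOrderSelection:
    def test_single_candidate_returned_with_warning(self, rng):
        ds = GroupDataset([_dff(rng.standard_normal((60, 40)))])
        with pytest.warns(UserWarning):
            sel = select_order(ds, [5])
        assert sel.best_k == 5

    def test_r_index_curve_finite_and_positive(self, rng):
        maps = _sparse_sources(4, 1200, rng)
        sessions = [
            _dff(rng.standard_normal((4, 150)).T @ maps
                 + 0.05 * rng.standard_normal((150, 1200)), session_id=f"s{i}")
            for i in range(2)
        ]
        sel = select_order(GroupDataset(sessions), [2, 4, 6], n_runs=4, seed=0)
        for v in sel.r_index.values():
            assert np.isfinite(v) and v >= 0


class TestModelOrderRobustness:
    def test_headline_statistics_stable_across_model_order(self):
        """The retrosplenial occurrence and co-occurrence contrasts survive
        moderate over/under-specification of the component count."""
        from wfgica.pipeline import RunConfig, run_study
        from wfgica.states import STATES

        # one-below-truth merges the bilateral pair into a single
        # retrosplenial IC: the occurrence contrast must survive that too
        for k in (7, 8, 10, 12):
            cfg = RunConfig(seed=13, k=k, simulate=dict(
                fps=10.0, dur_per_state=120.0, height=40, width=40))
            result, _ = run_study(cfg)
            retro = result.occurrence[result.occurrence.group == "Retrosplenial"]
            piv = retro.pivot_table(index="subject", columns="state", values="rel",
                                    sort=False).mean(axis=0)
            assert piv["iso2.0"] > piv["awake"], f"occurrence contrast lost at K={k}"
            gt = result.group_tables.get("Retrosplenial")
            if gt is not None and {"iso2.0", "awake"} <= set(gt.columns):
                z = gt.mean(axis=0)
                assert z["iso2.0"] > z["awake"], f"coupling contrast lost at K={k}"
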