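"""Particle filter: initialization, culling, observation fusion,
retrospective inference."""

import math

import numpy as np
import pytest

from idioloc import arena as ar
from idioloc import metrics as me
from idioloc import motion as mo
from idioloc import pfilter as pf


def make_cfg(arena, n=500, boundary="crossing", em=None, **kw):
    return pf.FilterConfig(map_arena=arena, n_particles=n,
                           boundary_mode=boundary,
                           error_model=em or mo.ErrorModel(sigma_theta=0.0,
                                                           sigma_step=0.0),
                           **kw)


def zero_noise_stream(traj):
    em = mo.ErrorModel(sigma_theta=0.0, sigma_step=0.0)
    return mo.corrupt(traj, em, seed=0)


class TestInitEnsemble:
    def test_oriented_is_a_delta_at_truth(self, kite):
        cfg = make_cfg(kite)
        ens = pf.init_ensemble(cfg, "oriented", true_pose=(3.0, 4.0, 1.0),
                               rng=0)
        assert me.place_stability_index(ens, (3.0, 4.0), kite) == 1.0
        assert np.all(ens.theta == 1.0)

    def test_disoriented_is_chance_with_uniform_headings(self, kite):
        cfg = make_cfg(kite, n=10_000)
        ens = pf.init_ensemble(cfg, "disoriented", rng=1)
        ip = np.mean([me.place_stability_index(ens, p, kite)
                      for p in kite.sample_uniform(20, np.random.default_rng(2))])
        assert ip == pytest.approx(0.5, abs=0.02)
        # uniform headings: circular variance of particle headings near 1
        assert me.circular_variance(ens.theta) == pytest.approx(1.0, abs=0.03)
        assert not pf.estimate_pose(ens).heading_defined

    def test_lineage_initialized(self, kite):
        cfg = make_cfg(kite, track_lineage=True)
        ens = pf.init_ensemble(cfg, "disoriented", rng=1)
        np.testing.assert_array_equal(ens.lineage_xy, ens.xy)

    def test_min_particles_enforced(self, kite):
        with pytest.raises(ValueError):
            make_cfg(kite, n=50)


class TestStep:
    def test_zero_noise_tracks_truth_exactly(self, kite, motion_cfg):
        traj = mo.generate_trajectory(kite, motion_cfg, duration=60, seed=3)
        stream = zero_noise_stream(traj)
        cfg = make_cfg(kite, n=200)
        ens = pf.run_filter(stream, cfg, init_mode="oriented",
                            true_pose0=(traj.xy[0, 0], traj.xy[0, 1],
                                        traj.theta[0]), rng=4)
        est = pf.estimate_pose(ens)
        np.testing.assert_allclose([est.x, est.y], traj.xy[-1], atol=1e-8)
        assert mo.wrap_diff(est.theta, traj.theta[-1]) == pytest.approx(0.0,
                                                                        abs=1e-8)

    def test_particles_always_inside_and_uncrossed(self, kite, motion_cfg,
                                                   calibrated):
        traj = mo.generate_trajectory(kite, motion_cfg, duration=60, seed=5)
        stream = mo.corrupt(traj, calibrated, seed=6)
        cfg = make_cfg(kite, em=calibrated)
        checked = []

        def cb(i, ens):
            if i % 20 == 0:
                checked.append(kite.geometry.contains_points(ens.xy).all())

        pf.run_filter(stream, cfg, init_mode="disoriented", rng=7, callback=cb)
        assert checked and all(checked)

    def test_culling_matches_exhaustive_enumeration(self, kite):
        # toy configuration: 2 positions x 20 directions = 40 hypotheses
        # tracked without noise over 3 large steps near the acute corner;
        # the filter's surviving pose set must equal brute-force enumeration
        starts = np.array([[-40.0, 0.0], [20.0, 10.0]])
        dirs = np.arange(20) * (2 * np.pi / 20)
        poses = [(p, th) for p in starts for th in dirs]
        dthetas = [0.6, -0.9, 0.4]
        steps = [30.0, 30.0, 20.0]
        true0 = (starts[0], dirs[0])  # heading +x from the acute corner

        # oracle: propagate each hypothesis independently, cull on crossing
        def propagate(p, th):
            p = p.copy()
            alive = True
            for dth, L in zip(dthetas, steps):
                th = th + dth
                q = p + L * np.array([math.cos(th), math.sin(th)])
                if ar.segment_crosses(kite, p, q):
                    alive = False
                    break
                p = q
            return alive, p, th

        oracle = {}
        for p, th in poses:
            alive, pe, the = propagate(np.asarray(p), th)
            if alive:
                oracle[(round(pe[0], 6), round(pe[1], 6))] = the
        # filter: 120 particles = each hypothesis three times
        n = 120
        xy = np.repeat(np.array([p for p, _ in poses]), 3, axis=0)
        th = np.repeat(np.array([t for _, t in poses]), 3)
        ens = pf.ParticleEnsemble(xy=xy, theta=th,
                                  weights=np.full(n, 1.0 / n))
        cfg = make_cfg(kite, n=n)
        t = 0.0
        for dth, L in zip(dthetas, steps):
            t += 0.5
            d = mo.DisplacementEstimate(t=t, step_hat=L, dtheta_hat=dth)
            ens = pf.step(ens, d, cfg, rng=8)
        survivors = {(round(x, 6), round(y, 6)) for x, y in ens.xy}
        assert survivors == set(oracle.keys())
        assert len(survivors) < 40  # culling really happened
        # the true hypothesis survives
        alive, pe, _ = propagate(np.asarray(true0[0]), true0[1])
        assert alive and (round(pe[0], 6), round(pe[1], 6)) in survivors

    def test_crossing_vs_endpoint_on_barrier(self, circle_barrier):
        # particles straddling the barrier: culled under the crossing
        # model, kept under the discrete-endpoint model
        b = circle_barrier.barriers[0]
        mid = (b[0] + b[1]) / 2.0
        normal = np.array([-(b[1] - b[0])[1], (b[1] - b[0])[0]])
        normal /= np.linalg.norm(normal)
        n = 100
        xy = np.tile(mid + 3.0 * normal, (n, 1))
        heading = math.atan2(-normal[1], -normal[0])
        ens = pf.ParticleEnsemble(xy=xy, theta=np.full(n, heading),
                                  weights=np.full(n, 1.0 / n))
        d = mo.DisplacementEstimate(t=0.5, step_hat=6.0, dtheta_hat=0.0)
        out_cross = pf.step(ens.copy(), d, make_cfg(circle_barrier), rng=9)
        out_end = pf.step(ens.copy(), d,
                          make_cfg(circle_barrier, boundary="discrete_endpoint"),
                          rng=9)
        assert out_cross.n_reinits == 1      # everyone crossed: total cull
        assert out_end.n_reinits == 0        # endpoints valid: no cull
        np.testing.assert_allclose(out_end.xy, xy + 6.0 * -normal, atol=1e-9)

    def test_total_cull_reinitializes_uniformly(self, kite):
        cfg = make_cfg(kite, n=300)
        ens = pf.init_ensemble(cfg, "oriented", true_pose=(0.0, 0.0, 0.0),
                               rng=1)
        d = mo.DisplacementEstimate(t=0.5, step_hat=500.0, dtheta_hat=0.0)
        out = pf.step(ens, d, cfg, rng=2)
        assert out.n == 300
        assert out.n_reinits == 1
        assert kite.geometry.contains_points(out.xy).all()

    def test_boundary_none_variance_grows(self, kite, motion_cfg, calibrated):
        traj = mo.generate_trajectory(kite, motion_cfg, duration=600, seed=10)
        stream = mo.corrupt(traj, calibrated, seed=11)
        cfg = make_cfg(kite, boundary="none", em=calibrated)
        spread = []

        def cb(i, ens):
            if i % 120 == 119:  # once a minute
                spread.append(ens.xy.var(axis=0).sum())

        pf.run_filter(stream, cfg, init_mode="oriented",
                      true_pose0=(traj.xy[0, 0], traj.xy[0, 1], traj.theta[0]),
                      rng=12, callback=cb)
        # unbounded growth up to sampling noise of the ensemble variance
        from scipy.stats import spearmanr

        assert spearmanr(np.arange(len(spread)), spread).statistic > 0.9
        assert spread[-1] > 5.0 * spread[0]

    def test_deterministic_given_seed(self, kite, motion_cfg, calibrated):
        traj = mo.generate_trajectory(kite, motion_cfg, duration=30, seed=13)
        stream = mo.corrupt(traj, calibrated, seed=14)
        cfg = make_cfg(kite, em=calibrated)
        a = pf.run_filter(stream, cfg, init_mode="disoriented", rng=15)
        b = pf.run_filter(stream, cfg, init_mode="disoriented", rng=15)
        np.testing.assert_array_equal(a.xy, b.xy)
        np.testing.assert_array_equal(a.theta, b.theta)


class TestApplyCompass:
    def test_sharpens_uniform_headings(self, kite):
        cfg = make_cfg(kite, n=2000)
        ens = pf.init_ensemble(cfg, "disoriented", rng=1)
        v_before = me.circular_variance(ens.theta)
        out = pf.apply_compass(ens, obs=0.0, sd=math.radians(15.0), rng=2)
        assert me.circular_variance(out.theta) < v_before - 0.3
        assert out.n == ens.n

    def test_concentrated_ensemble_unchanged_in_distribution(self, kite):
        n = 1000
        ens = pf.ParticleEnsemble(xy=np.zeros((n, 2)),
                                  theta=np.full(n, 1.0),
                                  weights=np.full(n, 1.0 / n))
        out = pf.apply_compass(ens, obs=1.0, sd=0.2, rng=3)
        np.testing.assert_allclose(out.theta, 1.0)

    def test_sd_validation(self, kite):
        cfg = make_cfg(kite)
        ens = pf.init_ensemble(cfg, "disoriented", rng=1)
        with pytest.raises(ValueError):
            pf.apply_compass(ens, 0.0, sd=0.0)


class TestApplyContact:
    def test_contact_keeps_wall_particles(self, circle):
        n = 400
        rng = np.random.default_rng(4)
        wall = 37.5 * np.stack([np.cos(rng.uniform(0, 2 * np.pi, n // 2)),
                                np.sin(rng.uniform(0, 2 * np.pi, n // 2))], 1)
        centre = rng.normal(0, 3, size=(n // 2, 2))
        xy = np.concatenate([wall, centre])
        ens = pf.ParticleEnsemble(xy=xy, theta=np.zeros(n),
                                  weights=np.full(n, 1.0 / n))
        cfg = make_cfg(circle)
        out = pf.apply_contact(ens, True, cfg, tol=2.0, rng=5)
        d = circle.geometry.distance_to_boundary(out.xy)
        assert (d <= 2.0).all()
        out2 = pf.apply_contact(ens, False, cfg, tol=2.0, rng=6)
        assert (circle.geometry.distance_to_boundary(out2.xy) > 2.0).all()

    def test_all_at_centre_contact_triggers_reinit(self, circle):
        n = 200
        ens = pf.ParticleEnsemble(xy=np.zeros((n, 2)), theta=np.zeros(n),
                                  weights=np.full(n, 1.0 / n))
        out = pf.apply_contact(ens, True, make_cfg(circle, n=n), tol=1.0,
                               rng=7)
        assert out.n_reinits == 1
        assert out.n == n


class TestEstimatePose:
    def test_delta(self):
        ens = pf.ParticleEnsemble(xy=np.tile([1.0, 2.0], (5, 1)),
                                  theta=np.full(5, 0.7),
                                  weights=np.full(5, 0.2))
        est = pf.estimate_pose(ens)
        assert (est.x, est.y) == (1.0, 2.0)
        assert est.theta == pytest.approx(0.7)
        assert est.heading_defined

    def test_symmetric_clusters_average_to_centre(self):
        xy = np.array([[10.0, 0.0]] * 50 + [[-10.0, 0.0]] * 50)
        ens = pf.ParticleEnsemble(xy=xy, theta=np.zeros(100),
                                  weights=np.full(100, 0.01))
        est = pf.estimate_pose(ens)
        assert (est.x, est.y) == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_uniform_headings_flagged_undefined(self, rng):
        n = 20_000
        ens = pf.ParticleEnsemble(xy=np.zeros((n, 2)),
                                  theta=np.linspace(0, 2 * np.pi, n,
                                                    endpoint=False),
                                  weights=np.full(n, 1.0 / n))
        est = pf.estimate_pose(ens)
        assert est.heading_resultant < 1e-3
        assert not est.heading_defined


class TestReverseReplay:
    def test_zero_noise_recovers_start_exactly(self, kite, motion_cfg):
        traj = mo.generate_trajectory(kite, motion_cfg, duration=60, seed=20)
        stream = zero_noise_stream(traj)
        cfg = make_cfg(kite, n=200)
        final = pf.run_filter(stream, cfg, init_mode="oriented",
                              true_pose0=(traj.xy[0, 0], traj.xy[0, 1],
                                          traj.theta[0]), rng=21)
        ens0 = pf.reverse_replay(stream, final, cfg, rng=22)
        est = pf.estimate_pose(ens0)
        np.testing.assert_allclose([est.x, est.y], traj.xy[0], atol=1e-6)

    def test_replay_improves_time_zero_estimate(self, kite, motion_cfg,
                                                calibrated):
        # disoriented 2-minute trials: at time 0 the real-time estimate is
        # chance (0.5); the replayed estimate must beat it
        vals = []
        for s in range(8):
            rng = np.random.default_rng(100 + s)
            traj = mo.generate_trajectory(kite, motion_cfg, duration=120,
                                          seed=rng)
            stream = mo.corrupt(traj, calibrated, seed=rng)
            cfg = make_cfg(kite, n=1000, em=calibrated)
            final = pf.run_filter(stream, cfg, init_mode="disoriented",
                                  rng=rng)
            ens0 = pf.reverse_replay(stream, final, cfg, rng=rng)
            vals.append(me.place_stability_index(ens0, traj.xy[0], kite))
        assert np.median(vals) > 0.5

    def test_replay_of_replay_preserves_final_quality(self, kite, motion_cfg,
                                                      calibrated):
        rng = np.random.default_rng(200)
        traj = mo.generate_trajectory(kite, motion_cfg, duration=120,
                                      seed=rng)
        stream = mo.corrupt(traj, calibrated, seed=rng)
        cfg = make_cfg(kite, n=1000, em=calibrated)
        final = pf.run_filter(stream, cfg, init_mode="disoriented", rng=rng)
        ip_final = me.place_stability_index(final, traj.xy[-1], kite)
        ens0 = pf.reverse_replay(stream, final, cfg, rng=rng)
        # play the same stream forward again from the replayed start
        ens = ens0
        for i in range(len(stream)):
            ens = pf.step(ens, stream[i], cfg, rng=rng)
        ip_again = me.place_stability_index(ens, traj.xy[-1], kite)
        assert ip_again >= ip_final - 0.15  # sampling tolerance


class TestBackwardInferenceOnline:
    def test_oriented_start_is_exact_and_constant(self, kite, motion_cfg,
                                                  calibrated):
        traj = mo.generate_trajectory(kite, motion_cfg, duration=30, seed=30)
        stream = mo.corrupt(traj, calibrated, seed=31)
        cfg = make_cfg(kite, n=300, em=calibrated)
        times, snaps = pf.backward_inference_online(
            stream, cfg, init_mode="oriented",
            true_pose0=(traj.xy[0, 0], traj.xy[0, 1], traj.theta[0]), rng=32)
        for ens in snaps:
            np.testing.assert_allclose(
                ens.xy, np.broadcast_to(traj.xy[0], ens.xy.shape))

    def test_time_zero_snapshot_equals_init(self, kite, calibrated,
                                            motion_cfg):
        traj = mo.generate_trajectory(kite, motion_cfg, duration=10, seed=33)
        stream = mo.corrupt(traj, calibrated, seed=34)
        cfg = make_cfg(kite, n=300, em=calibrated, track_lineage=True)
        ens_init = pf.init_ensemble(cfg, "disoriented", rng=35)
        np.testing.assert_array_equal(ens_init.lineage_xy, ens_init.xy)

    def test_initial_pose_estimate_improves_over_time(self, kite, motion_cfg,
                                                      calibrated):
        early, late = [], []
        for s in range(6):
            rng = np.random.default_rng(300 + s)
            traj = mo.generate_trajectory(kite, motion_cfg, duration=120,
                                          seed=rng)
            stream = mo.corrupt(traj, calibrated, seed=rng)
            cfg = make_cfg(kite, n=1000, em=calibrated)
            times, snaps = pf.backward_inference_online(
                stream, cfg, init_mode="disoriented", rng=rng,
                record_every=40)
            ips = [me.place_stability_index(e, traj.xy[0], kite)
                   for e in snaps]
            early.append(np.mean(ips[:2]))
            late.append(np.mean(ips[-2:]))
        assert np.median(late) > np.median(early)
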