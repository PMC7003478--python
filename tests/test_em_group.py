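"""Groupwise EM: initialization, group steps, transform updates, baselines."""

import numpy as np
import pytest

from parcelbundle import phantom
from parcelbundle.em_group import (
    GroupConfig,
    GroupModel,
    group_e_step,
    initialize_group,
    run_group_em,
    subject_centroids,
    update_common_centroids,
    update_transforms,
)
from parcelbundle.em_single import EMConfig, MembershipMatrix, run_em
from parcelbundle.fiber_core import FiberSet, fiber_distance, orient_points
from parcelbundle.parcellation import build_distance_fields
from parcelbundle.spatial_transforms import RigidTransform, identity_transform, warp_points


@pytest.fixture(scope="module")
def group_phantom():
    return phantom.make_group(
        S=3, warp_magnitude=1.5, seed=4, grid=44, L=8, K=6,
        n_per_bundle=15, roi_radius=2.5,
    )


@pytest.fixture(scope="module")
def group_dist(group_phantom):
    return build_distance_fields(group_phantom.parcellation)


def one_bundle_membership(values, orientations=None):
    J = len(values)
    values = np.asarray(values, dtype=float)[:, None]
    return MembershipMatrix(
        keys=[(1, 2)],
        values=values,
        orientations=(
            np.zeros((J, 1), dtype=bool) if orientations is None else orientations
        ),
        log_liks=np.zeros((J, 1)),
        gated=np.zeros((J, 1), dtype=bool),
        unassigned=np.zeros(J, dtype=bool),
        log_evidence=np.zeros(J),
    )


class TestInitializeGroup:
    def test_identical_aligned_subjects_give_identity_and_single_init(
        self, small_phantom, small_dist
    ):
        cfg = GroupConfig()
        fs = small_phantom.fiber_set
        model, assigns, Xs = initialize_group([fs, fs], small_dist, cfg)
        for T in model.transforms:
            assert np.allclose(T.rotation, np.eye(3), atol=1e-6)
            assert np.allclose(T.translation, 0.0, atol=1e-6)
        from parcelbundle.em_single import initialize_model

        single_model, single_assign = initialize_model(fs, small_dist, EMConfig())
        assert assigns[0] == single_assign
        for k in single_model.centroids:
            assert np.allclose(model.centroids[k], single_model.centroids[k], atol=1e-6)

    def test_rigid_displacement_of_one_subject_recovered(self, small_phantom, small_dist):
        cfg = GroupConfig()
        fs = small_phantom.fiber_set
        shift = np.array([2.0, -1.5, 1.0])
        moved = FiberSet.from_arrays([f.points + shift for f in fs.fibers])
        model, _, _ = initialize_group([fs, fs, fs, moved], small_dist, cfg)
        T = model.transforms[3]
        # native -> common should undo the displacement
        pts = np.array([f.points[0] for f in moved.fibers[:20]])
        back = warp_points(T, pts)
        assert np.linalg.norm(back - (pts - shift), axis=1).mean() < 0.3

    def test_empty_subject_named_in_error(self, small_phantom, small_dist):
        fs = small_phantom.fiber_set
        empty = FiberSet([], subject_id="sub-bad")
        with pytest.raises(ValueError, match="sub-bad"):
            initialize_group([fs, empty], small_dist, GroupConfig())


class TestGroupSteps:
    def test_single_subject_reduces_to_single_e_step(self, small_phantom, small_dist):
        cfg = GroupConfig()
        from parcelbundle.em_single import e_step, initialize_model

        fs = small_phantom.fiber_set.resampled(cfg.m)
        X = fs.to_array()
        model, _ = initialize_model(fs, small_dist, cfg)
        group = GroupModel(dict(model.centroids), [identity_transform()],
                           cfg.sigma_bundle, cfg.sigma_roi)
        membs, _ = group_e_step([X], group, small_dist, cfg)
        single = e_step(X, model, small_dist, cfg)
        assert np.allclose(membs[0].values, single.values)

    def test_symmetric_subjects_have_identical_memberships(
        self, small_phantom, small_dist
    ):
        cfg = GroupConfig()
        X = small_phantom.fiber_set.resampled(cfg.m).to_array()
        from parcelbundle.em_single import initialize_model

        model, _ = initialize_model(small_phantom.fiber_set, small_dist, cfg)
        group = GroupModel(dict(model.centroids),
                           [identity_transform(), identity_transform()],
                           cfg.sigma_bundle, cfg.sigma_roi)
        membs, _ = group_e_step([X, X], group, small_dist, cfg)
        assert np.allclose(membs[0].values, membs[1].values)

    def test_common_centroid_update_matches_brute_force(self, rng):
        cfg = GroupConfig(m=8)
        X1 = rng.normal(size=(4, 8, 3))
        X2 = rng.normal(size=(3, 8, 3))
        w1, w2 = rng.random(4), rng.random(3)
        m1, m2 = one_bundle_membership(w1), one_bundle_membership(w2)
        cents = update_common_centroids([X1, X2], [m1, m2], cfg)
        expected = (
            np.einsum("j,jmp->mp", w1, X1) + np.einsum("j,jmp->mp", w2, X2)
        ) / (w1.sum() + w2.sum())
        assert np.allclose(cents[(1, 2)], expected)

    def test_mirror_offset_subjects_average_to_midline(self, rng):
        cfg = GroupConfig(m=8)
        mid = np.cumsum(rng.normal(size=(8, 3)), axis=0)
        d = np.array([0, 0, 1.0])
        cents = update_common_centroids(
            [(mid + d)[None], (mid - d)[None]],
            [one_bundle_membership([1.0]), one_bundle_membership([1.0])],
            cfg,
        )
        assert np.allclose(cents[(1, 2)], mid)

    def test_subject_centroids_with_unit_membership_are_plain_means(self, rng):
        cfg = GroupConfig(m=8)
        X = rng.normal(size=(5, 8, 3))
        memb = one_bundle_membership(np.ones(5))
        cents = subject_centroids([X], [memb], cfg)
        curve, mass = cents[0][(1, 2)]
        assert np.allclose(curve, X.mean(axis=0))
        assert mass == 5.0


class TestUpdateTransforms:
    def test_equal_centroids_give_near_identity_residual(self, rng):
        cfg = GroupConfig(tps_lambda=0.0)
        curves = {(1, 2): np.cumsum(rng.normal(size=(20, 3)), axis=0),
                  (2, 3): np.cumsum(rng.normal(size=(20, 3)), axis=0) + 5,
                  (1, 3): np.cumsum(rng.normal(size=(20, 3)), axis=0) - 5}
        subj = {0: {k: (v, 10.0) for k, v in curves.items()}}
        transforms = update_transforms(subj, curves, cfg)
        for k, v in curves.items():
            assert np.allclose(warp_points(transforms[0], v), v, atol=1e-6)

    def test_known_smooth_warp_recovered_at_held_out_points(self, rng):
        from parcelbundle.spatial_transforms import fit_tps

        axis = np.linspace(0, 40, 3)
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        ctrl = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        disp = rng.normal(size=ctrl.shape)
        disp *= 2.0 / np.linalg.norm(disp, axis=1, keepdims=True)
        truth = fit_tps(ctrl, ctrl + disp, lam=0.0)  # native -> common

        common = {}
        subj = {0: {}}
        for i in range(14):
            a = rng.uniform(5, 35, 3)
            b = rng.uniform(5, 35, 3)
            native = np.linspace(a, b, 20)
            key = (1, i + 2)
            subj[0][key] = (native, 10.0)
            common[key] = warp_points(truth, native)
        cfg = GroupConfig(tps_lambda=0.0)
        transforms = update_transforms(subj, common, cfg)
        held_out = rng.uniform(8, 32, size=(100, 3))
        err = warp_points(transforms[0], held_out) - warp_points(truth, held_out)
        rms = np.sqrt((err**2).sum(axis=1).mean())
        assert rms <= 0.2

    def test_downsampling_uses_every_third_index(self, rng):
        assert list(np.arange(0, 20, 3)) == [0, 3, 6, 9, 12, 15, 18]

    def test_too_few_correspondences_keep_previous_transform(self, rng):
        cfg = GroupConfig()
        prev = [identity_transform()]
        with pytest.warns(UserWarning):
            out = update_transforms({0: {}}, {}, cfg, previous=prev)
        assert out[0] is prev[0]


class TestRunGroupEM:
    def test_s1_reduces_to_single_subject_assignment(self, small_phantom, small_dist):
        cfg = GroupConfig()
        res_g = run_group_em([small_phantom.fiber_set], small_dist, cfg, method="group")
        res_s = run_em(small_phantom.fiber_set, small_dist, EMConfig())
        agree = np.mean(
            [a == b for a, b in zip(res_g.assignments[0], res_s.assignment)]
        )
        assert agree >= 0.99

    def test_zero_misregistration_all_methods_agree(self, small_phantom, small_dist):
        cfg = GroupConfig()
        fs = small_phantom.fiber_set
        results = {
            m: run_group_em([fs, fs], small_dist, cfg, method=m)
            for m in ("group", "independent", "posthoc_tps", "pooled")
        }
        ref = results["group"].assignments[0]
        for m, res in results.items():
            assert res.assignments[0] == ref, m
            assert res.assignments[1] == ref, m

    def test_objective_trace_non_decreasing_without_gating(self, group_phantom, group_dist):
        cfg = GroupConfig(
            gate_multiplier=np.inf, tps_lambda=0.0,
            group_change_threshold=0, group_max_iterations=6,
        )
        res = run_group_em(group_phantom.fiber_sets, group_dist, cfg, method="group")
        ll = [t["log_likelihood"] for t in res.trace]
        assert np.all(np.diff(ll) >= -1e-6 * abs(ll[0]))

    def test_transform_update_reduces_weighted_alignment_residual(
        self, group_phantom, group_dist
    ):
        cfg = GroupConfig(tps_lambda=0.0)
        res = run_group_em(group_phantom.fiber_sets, group_dist, cfg, method="group")
        common = res.model.centroids
        for s, cents in res.subject_centroids.items():
            before = after = 0.0
            for k, (curve, mass) in cents.items():
                if k not in common:
                    continue
                before += mass * ((curve - common[k]) ** 2).sum()
                warped = warp_points(res.model.transforms[s], curve)
                after += mass * ((warped - common[k]) ** 2).sum()
            assert after <= before + 1e-6

    def test_group_beats_independent_on_misregistered_phantom(
        self, group_phantom, group_dist
    ):
        from parcelbundle.metrics import group_report

        cfg = GroupConfig()
        rep_g = group_report(run_group_em(group_phantom.fiber_sets, group_dist, cfg, "group"))
        rep_i = group_report(
            run_group_em(group_phantom.fiber_sets, group_dist, cfg, "independent")
        )
        assert rep_g.gmiv < rep_i.gmiv
        assert rep_g.mbcd < rep_i.mbcd

    def test_unknown_method_rejected(self, small_phantom, small_dist):
        with pytest.raises(ValueError):
            run_group_em([small_phantom.fiber_set], small_dist, GroupConfig(), "bogus")
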