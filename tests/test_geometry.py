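"""Trajectory measurements: superposition, angles, RMSF, axes, hinges, PCA."""

import numpy as np
import pytest

from riboswivel.geometry import (
    axis_displacement_profile, com_distance_series,
    helix_axis, kabsch_superpose, locate_hinges, measure_body_rotation,
    measure_swivel_tilt, pair_distance_series, pca_motion, rmsf,
)
from riboswivel.linalg import rotation_about_axis, swing_twist
from riboswivel.synthetic import (
    DumbbellSpec, make_hinge_dumbbell, make_kinked_duplex, make_mini_duplex,
    make_swivel_trajectory, refdef_from_truth,
)


# --- rigid superposition ---------------------------------------------------

def test_kabsch_identity_and_rotation_recovery():
    rng = np.random.default_rng(0)
    P = rng.normal(0, 3, (20, 3))
    R0, t0, rmsd = kabsch_superpose(P, P)
    np.testing.assert_allclose(R0, np.eye(3), atol=1e-10)
    assert rmsd == pytest.approx(0.0, abs=1e-10)
    Rz = rotation_about_axis(np.array([0.0, 0.0, 1.0]), np.radians(30))
    R, t, rmsd = kabsch_superpose(P, P @ Rz.T)
    angle = np.degrees(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1)))
    assert angle == pytest.approx(30.0, abs=1e-6)
    assert np.linalg.det(R) == pytest.approx(1.0)


def test_kabsch_noisy_rmsd_scale():
    rng = np.random.default_rng(1)
    P = rng.normal(0, 5, (50, 3))
    sigma = 0.1
    Q = P + rng.normal(0, sigma, P.shape)
    _, _, rmsd = kabsch_superpose(P, Q)
    # per-atom residual ~ sqrt(3) sigma, slightly reduced by the fitted
    # 6 rigid degrees of freedom
    assert rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.2)


def test_kabsch_rejects_degenerate_input():
    line = np.stack([np.array([i, 0.0, 0.0]) for i in range(5)])
    with pytest.raises(ValueError):
        kabsch_superpose(line, line)
    with pytest.raises(ValueError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


# --- swivel / tilt ---------------------------------------------------------

def test_reference_frame_measures_zero(dumbbell):
    start, _, truth = dumbbell
    refdef = refdef_from_truth(start, truth)
    sw, ti = measure_swivel_tilt(start.coords, refdef)
    assert sw == pytest.approx(0.0, abs=1e-9)
    assert ti == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("swivel, tilt", [(16.0, 0.0), (22.6, 5.0), (-8.0, 2.0)])
def test_planted_rotation_recovery(swivel, tilt):
    start, endpoint, truth = make_hinge_dumbbell(
        DumbbellSpec(swivel_deg=swivel, tilt_deg=tilt, seed=3))
    refdef = refdef_from_truth(start, truth)
    sw, ti = measure_swivel_tilt(endpoint.coords, refdef)
    assert sw == pytest.approx(swivel, abs=0.2)
    assert ti == pytest.approx(abs(tilt), abs=0.2)


def test_swing_twist_composition_closes():
    rng = np.random.default_rng(4)
    n = np.array([0.0, 0.0, 1.0])
    for _ in range(10):
        a = rng.uniform(-0.6, 0.6)
        b = rng.uniform(0.0, 0.3)
        axis_in_plane = np.array([np.cos(rng.uniform(0, 2 * np.pi)),
                                  np.sin(rng.uniform(0, 2 * np.pi)), 0.0])
        R = rotation_about_axis(axis_in_plane, b) @ rotation_about_axis(n, a)
        twist, swing = swing_twist(R, n)
        assert twist == pytest.approx(a, abs=1e-9)
        assert swing == pytest.approx(b, abs=1e-9)


def test_angle_measurements_invariant_under_global_rigid_motion(dumbbell):
    start, endpoint, truth = dumbbell
    refdef = refdef_from_truth(start, truth)
    R = rotation_about_axis(np.array([2.0, 1.0, -1.0]), 0.9)
    t = np.array([25.0, -11.0, 4.0])
    sw0, ti0 = measure_swivel_tilt(endpoint.coords, refdef)
    sw1, ti1 = measure_swivel_tilt(endpoint.coords @ R.T + t, refdef)
    assert sw1 == pytest.approx(sw0, abs=0.1)
    assert ti1 == pytest.approx(ti0, abs=0.1)
    br0 = measure_body_rotation(start.coords, refdef)
    br1 = measure_body_rotation(start.coords @ R.T + t, refdef)
    assert br0 == pytest.approx(0.0, abs=1e-9)
    assert br1 == pytest.approx(0.0, abs=0.1)


def test_body_rotation_recovery(dumbbell):
    start, _, truth = dumbbell
    refdef = refdef_from_truth(start, truth)
    # rotate the whole structure about an axis orthogonal to the plane
    # normal, but keep the "body core" (alignment reference) fixed: the
    # plane normal then rotates by the planted angle
    normal = np.array(truth["axis"])
    ortho = np.array(truth["tilt_axis"])
    R = rotation_about_axis(ortho, np.radians(8.0))
    frame = start.coords.copy()
    head = np.array(truth["head_core"], dtype=int)
    frame[head] = frame[head] @ R.T
    assert measure_body_rotation(frame, refdef) == pytest.approx(8.0, abs=0.1)


# --- RMSF ------------------------------------------------------------------

def test_rmsf_static_and_alternating():
    base = np.random.default_rng(0).normal(0, 4, (10, 3))
    static = np.repeat(base[None], 6, axis=0)
    prof = rmsf(static, np.arange(10), np.arange(10))
    np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)
    # one atom alternating +-d along x around the mean -> rmsf exactly d
    d = 0.75
    frames = np.repeat(base[None], 6, axis=0)
    frames[::2, 9, 0] += d
    frames[1::2, 9, 0] -= d
    prof = rmsf(frames, np.array([9]), np.arange(9))  # align on the static atoms
    assert prof.rmsf[0] == pytest.approx(d, rel=1e-6)


def test_rmsf_scales_linearly_with_noise():
    rng = np.random.default_rng(5)
    base = rng.normal(0, 5, (30, 3))
    def noisy(sigma, seed):
        r = np.random.default_rng(seed)
        return base[None] + r.normal(0, sigma, (300, 30, 3))
    p1 = rmsf(noisy(0.1, 1), np.arange(30), np.arange(30))
    p2 = rmsf(noisy(0.2, 1), np.arange(30), np.arange(30))
    ratio = np.median(p2.rmsf) / np.median(p1.rmsf)
    assert ratio == pytest.approx(2.0, rel=0.1)


def test_rmsf_time_reversal_invariance(dumbbell):
    start, _, truth = dumbbell
    sched = np.stack([np.linspace(0, 20, 12), np.zeros(12)], axis=1)
    traj = make_swivel_trajectory(start, truth, sched, noise_sigma=0.05, seed=2)
    sel = np.array(truth["hinge_atoms"], dtype=int)
    asel = np.array(truth["body_core"], dtype=int)
    ref = traj.frames[0]
    fwd = rmsf(traj.frames, sel, asel, reference=ref)
    rev = rmsf(traj.frames[::-1], sel, asel, reference=ref)
    np.testing.assert_allclose(fwd.rmsf, rev.rmsf, atol=1e-10)


def test_rmsf_requires_two_frames():
    with pytest.raises(ValueError):
        rmsf(np.zeros((1, 5, 3)), np.arange(5), np.arange(5))


# --- distances -------------------------------------------------------------

def test_pair_and_com_distances():
    frames = np.zeros((3, 4, 3))
    frames[:, 1] = [3.0, 4.0, 0.0]
    frames[:, 2] = [10.0, 0.0, 0.0]
    frames[:, 3] = [10.0, 2.0, 0.0]
    np.testing.assert_allclose(pair_distance_series(frames, 0, 1), 5.0)
    # two single-atom selections reduce to the pair distance
    np.testing.assert_allclose(
        com_distance_series(frames, np.array([0]), np.array([1])),
        pair_distance_series(frames, 0, 1))
    # hand-computed centers of mass: {0,1} -> (1.5, 2, 0); {2,3} -> (10, 1, 0)
    expect = np.linalg.norm(np.array([1.5, 2.0, 0.0]) - np.array([10.0, 1.0, 0.0]))
    np.testing.assert_allclose(
        com_distance_series(frames, np.array([0, 1]), np.array([2, 3])), expect)
    with pytest.raises(ValueError):
        com_distance_series(frames, np.array([], dtype=int), np.array([1]))


# --- helical axis ----------------------------------------------------------

def test_ideal_duplex_axis_is_the_z_axis(duplex):
    prof = helix_axis(duplex, [("A", 1, 12)])
    assert len(prof.points) > 2
    assert np.abs(prof.points[:, :2]).max() < 0.5


def test_helix_axis_equivariance(duplex):
    R = rotation_about_axis(np.array([1.0, 1.0, 0.0]), 0.8)
    t = np.array([3.0, -2.0, 7.0])
    moved = duplex.with_coords(duplex.coords @ R.T + t)
    p0 = helix_axis(duplex, [("A", 1, 12)]).points
    p1 = helix_axis(moved, [("A", 1, 12)]).points
    np.testing.assert_allclose(p1, p0 @ R.T + t, atol=0.1)


def test_kinked_duplex_axis_changes_direction_once():
    kinked = make_kinked_duplex(10, bend_deg=30.0)
    prof = helix_axis(kinked, [("A", 1, 10), ("A", 11, 20)])
    seg = np.diff(prof.points, axis=0)
    seg = seg / np.linalg.norm(seg, axis=1)[:, None]
    turn = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", seg[:-1], seg[1:]), -1, 1)))
    # one direction change at the junction: the large turns form a single
    # contiguous cluster there, and the total turn matches the bend
    big = np.flatnonzero(turn > 10.0)
    assert len(big) >= 1
    assert big.max() - big.min() <= 1          # contiguous
    n_arm_points = len(prof.points) // 2
    assert abs(big.mean() - (n_arm_points - 1)) <= 1.5
    assert turn[big].sum() == pytest.approx(30.0, abs=5.0)


def test_helix_axis_requires_enough_residues(duplex):
    with pytest.raises(ValueError, match="need"):
        helix_axis(duplex, [("A", 1, 3)])


# --- displacement profiles & hinges ---------------------------------------

def test_displacement_profile_of_identical_states_is_zero(duplex):
    pos, disp = axis_displacement_profile(duplex, duplex, [("A", 1, 12)])
    np.testing.assert_allclose(disp, 0.0, atol=1e-10)


def test_rigid_head_displacement_localizes(dumbbell):
    # head displaced, body fixed: head-attributed positions move, body's do not
    straight = make_mini_duplex(20)
    kinked = make_kinked_duplex(10, bend_deg=30.0)
    arm1 = np.array([i for i, a in enumerate(straight.atoms)
                     if a.chain_id == "A" and a.res_seq <= 10])
    pos, disp = axis_displacement_profile(
        straight, kinked, [("A", 1, 10), ("A", 11, 20)], align_selection=arm1)
    n1 = np.sum(pos <= 10)
    assert disp[:n1].max() < 0.3
    assert disp[n1:].max() > 3.0


def test_locate_hinges_v_and_two_basin_profiles():
    v = np.abs(np.arange(21) - 10).astype(float)
    assert locate_hinges(v) == [10]
    two = np.minimum(np.abs(np.arange(31) - 8), np.abs(np.arange(31) - 22)).astype(float)
    assert locate_hinges(two) == [8, 22]
    assert locate_hinges(np.ones(12)) == []


def test_locate_hinges_noisy_junction_recovery():
    straight = make_mini_duplex(20)
    kinked = make_kinked_duplex(10, bend_deg=30.0)
    arm1 = np.array([i for i, a in enumerate(straight.atoms)
                     if a.chain_id == "A" and a.res_seq <= 10])
    pos, disp = axis_displacement_profile(
        straight, kinked, [("A", 1, 10), ("A", 11, 20)], align_selection=arm1)
    junction = (np.sum(pos <= 10) - 1) + 0.5
    rng = np.random.default_rng(9)
    hits = 0
    for _ in range(20):
        noisy = disp + rng.normal(0, 0.05 * (disp.max() - disp.min()), len(disp))
        found = locate_hinges(noisy)
        if found and min(abs(f - junction) for f in found) <= 2:
            hits += 1
    assert hits >= 18


# --- PCA -------------------------------------------------------------------

def test_pca_single_direction_dominates():
    rng = np.random.default_rng(3)
    base = rng.normal(0, 5, (6, 3))
    frames = np.repeat(base[None], 200, axis=0)
    frames[:, 5, 0] += rng.normal(0, 1.0, 200)  # one atom moves along x only
    evals, modes, proj = pca_motion(frames, np.array([5]), np.arange(5))
    assert evals[0] / evals.sum() > 0.99


def test_pca_trace_identity_and_anisotropy():
    rng = np.random.default_rng(12)
    base = rng.normal(0, 5, (5, 3))
    frames = np.repeat(base[None], 3000, axis=0)
    s1, s2 = 3.0, 1.0
    frames[:, 4, 0] += rng.normal(0, s1, 3000)
    frames[:, 4, 1] += rng.normal(0, s2, 3000)
    evals, modes, proj = pca_motion(frames, np.array([4]), np.arange(4))
    X = frames[:, 4, :] - frames[:, 4, :].mean(axis=0)
    total_var = (X ** 2).mean(axis=0).sum()
    assert evals.sum() == pytest.approx(total_var, rel=1e-6)
    assert evals[0] / evals[1] == pytest.approx((s1 / s2) ** 2, rel=0.15)


def test_pca_needs_three_frames():
    with pytest.raises(ValueError):
        pca_motion(np.zeros((2, 4, 3)), np.arange(4))
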