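import numpy as np
import pytest

from fiducialign import (
    FiducialSpec,
    LandmarkSet,
    RigidTransform,
    align_by_fiducial,
    compose,
    icp,
    invert,
    kabsch,
    make_cross_marker,
    make_sphere_marker,
    simulate_scan,
)
from fiducialign.errors import (
    DegenerateConfigurationError,
    InvalidParameterError,
    RegistrationFailureError,
)
from fiducialign.scan_sim import ScanConfig


def rot_z(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


def rot_x(deg):
    a = np.radians(deg)
    return np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])


def random_rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.normal(size=3) * 5


class TestRigidTransform:
    def test_rejects_non_rotation(self):
        with pytest.raises(InvalidParameterError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))
        with pytest.raises(InvalidParameterError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))  # reflection

    def test_group_axioms(self, rng):
        r1, t1 = random_rigid(rng)
        r2, t2 = random_rigid(rng)
        r3, t3 = random_rigid(rng)
        A, B, C = RigidTransform(r1, t1), RigidTransform(r2, t2), RigidTransform(r3, t3)
        ident = RigidTransform.identity()
        assert np.allclose(compose(A, invert(A)).matrix(), np.eye(4), atol=1e-12)
        assert np.array_equal(compose(ident, A).matrix(), A.matrix())
        assert np.allclose(
            compose(compose(A, B), C).matrix(), compose(A, compose(B, C)).matrix(), atol=1e-12
        )

    def test_compose_order(self):
        # compose(T1, T2) applies T2 first
        T1 = RigidTransform(np.eye(3), [1, 0, 0])
        T2 = RigidTransform(rot_z(90), [0, 0, 0])
        p = np.array([[1.0, 0.0, 0.0]])
        assert np.allclose(compose(T1, T2).apply(p), [[1.0, 1.0, 0.0]], atol=1e-12)

    def test_matrix_roundtrip(self, rng):
        r, t = random_rigid(rng)
        T = RigidTransform(r, t)
        assert np.allclose(RigidTransform.from_matrix(T.matrix()).matrix(), T.matrix())


class TestKabsch:
    def test_identity_case(self, rng):
        pts = rng.normal(size=(6, 3)) * 10
        T = kabsch(pts, pts)
        assert np.allclose(T.matrix(), np.eye(4), atol=1e-12)

    def test_known_pose_recovery(self, rng):
        src = rng.normal(size=(8, 3)) * 15
        rot = rot_z(30)
        t = np.array([5.0, -2.0, 1.0])
        T = kabsch(src, src @ rot.T + t)
        assert np.abs(T.rotation - rot).max() < 1e-9
        assert np.abs(T.translation - t).max() < 1e-9

    def test_degenerate_configurations(self):
        with pytest.raises(DegenerateConfigurationError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.stack([np.arange(5.0)] * 3, axis=1)  # collinear
        with pytest.raises(DegenerateConfigurationError):
            kabsch(line, line)

    def test_count_mismatch(self, rng):
        with pytest.raises(DegenerateConfigurationError):
            kabsch(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))

    def test_no_reflection_on_mirrored_data(self, rng):
        src = rng.normal(size=(10, 3))
        dst = src * np.array([1, 1, -1])  # mirrored
        T = kabsch(src, dst)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_optimality_vs_noisy_random_search(self, rng):
        src = rng.normal(size=(10, 3)) * 10
        dst = src @ rot_z(20).T + np.array([1, 2, 3]) + rng.normal(0, 0.05, size=(10, 3))
        T = kabsch(src, dst)
        best = np.sqrt(np.mean(np.sum((T.apply(src) - dst) ** 2, axis=1)))
        for _ in range(1000):
            r, t = random_rigid(rng)
            rmsd = np.sqrt(np.mean(np.sum((src @ r.T + t - dst) ** 2, axis=1)))
            assert best <= rmsd + 1e-12

    def test_random_grid_oracle_never_beats_kabsch(self, rng):
        """Vectorized million-sample random rigid search on noiseless n=4 data."""
        src = rng.normal(size=(4, 3)) * 8
        rot = rot_x(35) @ rot_z(-10)
        dst = src @ rot.T + np.array([2.0, -1.0, 4.0])
        T = kabsch(src, dst)
        best = np.sqrt(np.mean(np.sum((T.apply(src) - dst) ** 2, axis=1)))
        assert best < 1e-9
        n = 1_000_000
        q = rng.normal(size=(n, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        w, x, y, z = q.T
        rots = np.empty((n, 3, 3))
        rots[:, 0, 0] = 1 - 2 * (y * y + z * z)
        rots[:, 0, 1] = 2 * (x * y - w * z)
        rots[:, 0, 2] = 2 * (x * z + w * y)
        rots[:, 1, 0] = 2 * (x * y + w * z)
        rots[:, 1, 1] = 1 - 2 * (x * x + z * z)
        rots[:, 1, 2] = 2 * (y * z - w * x)
        rots[:, 2, 0] = 2 * (x * z - w * y)
        rots[:, 2, 1] = 2 * (y * z + w * x)
        rots[:, 2, 2] = 1 - 2 * (x * x + y * y)
        ts = rng.uniform(-6, 6, size=(n, 3))
        moved = np.einsum("nij,kj->nki", rots, src) + ts[:, None, :]
        rmsd = np.sqrt(np.mean(np.sum((moved - dst) ** 2, axis=2), axis=1))
        assert rmsd.min() >= best - 1e-12


class TestICP:
    def test_already_aligned(self, sphere_marker):
        r = icp(sphere_marker, sphere_marker)
        assert r.converged
        assert r.iterations <= 2
        assert r.final_rms < 1e-9

    def test_monotone_descent_trace(self, cross_marker, rng):
        cfg = ScanConfig(noise_sigma=0.05, sample_spacing=0.6, smoothing_iters=0, seed=5)
        scan = simulate_scan(cross_marker, cfg)
        init = RigidTransform(rot_z(4), [0.5, -0.5, 0.3])
        moved = init.apply_mesh(scan)
        r = icp(moved, cross_marker, max_iterations=40)
        trace = r.rms_trace
        assert len(trace) >= 2
        for k in range(1, len(trace)):
            assert trace[k] <= trace[k - 1] + 1e-12

    def test_sphere_translation_recovery(self):
        """Sphere pose is rotationally ambiguous; translation and rms are not."""
        cfg = ScanConfig(noise_sigma=0.05, sample_spacing=0.6, smoothing_iters=0, seed=7)
        sphere = make_sphere_marker(10.0, 3)
        scan = simulate_scan(sphere, cfg)
        true = RigidTransform(rot_z(5), [2.0, 0.0, 0.0])
        moved = true.apply_mesh(scan)
        r = icp(moved, sphere, max_iterations=60, reject_distance_mm=5.0)
        # recovered translation maps the sphere centre back within 0.2 mm
        centre_err = np.linalg.norm(r.transform.apply(true.apply([[0, 0, 0]])) - [[0, 0, 0]])
        assert centre_err < 0.2
        assert r.final_rms <= 1.5 * cfg.noise_sigma

    def test_cross_full_pose_recovery(self, cross_marker):
        """5 deg + 2 mm perturbation on the cross: full 6-DOF recovery."""
        cfg = ScanConfig(noise_sigma=0.05, sample_spacing=0.6, smoothing_iters=0, seed=11)
        scan = simulate_scan(cross_marker, cfg)
        true = RigidTransform(rot_x(5), [2.0, 0.0, 0.5])
        moved = true.apply_mesh(scan)
        r = icp(moved, cross_marker, max_iterations=80, reject_distance_mm=5.0)
        residual = compose(r.transform, true)
        assert residual.rotation_angle_deg() < 0.5
        assert np.linalg.norm(residual.translation) < 0.2
        assert r.final_rms <= 1.5 * cfg.noise_sigma

    def test_vertex_permutation_invariance(self, cross_marker):
        cfg = ScanConfig(noise_sigma=0.02, sample_spacing=0.8, smoothing_iters=0, seed=3)
        scan = simulate_scan(cross_marker, cfg)
        perm = np.random.default_rng(1).permutation(scan.n_vertices)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        shuffled = type(scan)(scan.vertices[perm], inv[scan.faces], scan.name)
        r1 = icp(scan, cross_marker, max_points=None)
        r2 = icp(shuffled, cross_marker, max_points=None)
        assert abs(r1.final_rms - r2.final_rms) <= 2e-6

    def test_failure_on_distant_target(self, cross_marker):
        far = cross_marker.translated([500.0, 0.0, 0.0])
        with pytest.raises(RegistrationFailureError):
            icp(far, cross_marker, reject_distance_mm=1.0)


class TestAlignByFiducial:
    def landmarks(self):
        return LandmarkSet(
            np.array([[10, 0, 3], [-10, 0, 3], [0, 10, 3], [0, -10, 3], [0, 0, 3]], dtype=float)
        )

    def test_identity_on_identical_scans(self, cross_marker):
        lm = self.landmarks()
        r = align_by_fiducial(cross_marker, cross_marker, lm, lm, region_radius_mm=25.0)
        assert np.allclose(r.transform.matrix(), np.eye(4), atol=1e-9)

    def test_two_landmarks_rejected(self, cross_marker):
        lm2 = LandmarkSet(np.array([[1.0, 0, 0], [0, 1.0, 0]]))
        with pytest.raises(DegenerateConfigurationError):
            align_by_fiducial(cross_marker, cross_marker, lm2, lm2)

    def test_two_noisy_copies_bound(self, cross_marker):
        """Aligning two independent noisy scans lands near the noise floor."""
        lm = self.landmarks()
        sigma = 0.05
        rng = np.random.default_rng(42)
        failures = 0
        for seed in range(3):
            cfg_a = ScanConfig(noise_sigma=sigma, sample_spacing=0.6, seed=seed * 2)
            cfg_b = ScanConfig(noise_sigma=sigma, sample_spacing=0.6, seed=seed * 2 + 1)
            a = simulate_scan(cross_marker, cfg_a)
            b = simulate_scan(cross_marker, cfg_b)
            jit = lambda p: p + rng.normal(0, 0.05, size=p.shape)
            r = align_by_fiducial(
                a, b, LandmarkSet(jit(lm.points)), LandmarkSet(jit(lm.points)),
                region_radius_mm=25.0, max_iterations=30, tolerance_mm=1e-4,
            )
            if r.final_rms > 2 * sigma:
                failures += 1
        assert failures == 0


class TestLandmarkIO:
    def test_file_roundtrip(self, tmp_path, rng):
        lm = LandmarkSet(rng.normal(size=(4, 3)) * 10, ["a", "b", "c", "d"])
        p = tmp_path / "lm.pts"
        lm.write(p)
        back = LandmarkSet.read(p)
        assert back.labels == lm.labels
        assert np.allclose(back.points, lm.points, atol=1e-6)

    def test_malformed_line(self, tmp_path):
        p = tmp_path / "bad.pts"
        p.write_text("a 1 2\n")
        with pytest.raises(InvalidParameterError):
            LandmarkSet.read(p)
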