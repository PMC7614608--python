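"""Pose-pair geometry: Euler conventions, C2 resolution, pair descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from globulegeom.pose_geometry import (
    Pose,
    crosslink_distances,
    CrosslinkSet,
    contact_frequency,
    embed_pairs,
    euler_from_matrix,
    extract_pairs,
    matrix_from_euler,
    pair_geometry,
    resolve_symmetry,
)
from globulegeom.synthetic_scenes import generate_contact_pairs


# -- independent oracle: hand-rolled single-axis rotations ------------------

def rot_x(deg):
    a = np.deg2rad(deg)
    return np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]])


def rot_y(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]])


def rot_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


class TestEuler:
    @pytest.mark.parametrize(
        "R, expected",
        [
            (np.eye(3), (0, 0, 0)),
            (rot_z(90), (0, 0, 90)),
            (rot_x(30), (30, 0, 0)),
            (rot_y(-45), (0, -45, 0)),
        ],
    )
    def test_single_axis_cases(self, R, expected):
        assert np.allclose(euler_from_matrix(R), expected, atol=1e-9)

    def test_numeric_composition_oracle(self):
        # compose intrinsic X->Y->Z by explicit matrix product, then invert
        R = rot_x(10) @ rot_y(20) @ rot_z(30)
        assert np.allclose(euler_from_matrix(R), (10, 20, 30), atol=1e-6)

    def test_gimbal_lock_convention(self):
        # at rotY = 90 the decomposition is degenerate: rotZ is zeroed and
        # rotX carries the full in-plane angle
        R = rot_x(50) @ rot_y(90) @ rot_z(25)
        rx, ry, rz = euler_from_matrix(R)
        assert rz == 0.0
        assert ry == pytest.approx(90.0, abs=1e-8)
        assert np.allclose(matrix_from_euler((rx, ry, rz)), R, atol=1e-8)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_random_rotations(self, seed):
        R = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
        assert np.allclose(matrix_from_euler(euler_from_matrix(R)), R, atol=1e-8)

    def test_euler_ranges(self, rng):
        for _ in range(100):
            rx, ry, rz = euler_from_matrix(Rotation.random(rng=rng).as_matrix())
            assert -180 < rx <= 180 and -90 <= ry <= 90 and -180 < rz <= 180

    def test_rejects_non_orthonormal(self):
        with pytest.raises(ValueError):
            euler_from_matrix(np.eye(3) * 1.1)
        with pytest.raises(ValueError):
            euler_from_matrix(np.diag([1.0, 1.0, -1.0]))  # reflection


def brute_force_canonical(pose_a, pose_b, model):
    """Oracle: enumerate all symmetry-composed pose variants and keep the
    relative rotation whose matched first markers are closest in space."""
    s1 = model.atom(model.symmetry_pair[0])
    best, best_d = None, np.inf
    for alpha in (0, 1):
        for beta in (0, 1):
            ra = pose_a.rotation @ np.linalg.matrix_power(model.symmetry_op, alpha)
            rb = pose_b.rotation @ np.linalg.matrix_power(model.symmetry_op, beta)
            m_a = ra @ s1 + pose_a.center
            m_b = rb @ s1 + pose_b.center
            d = np.linalg.norm(m_a - m_b)
            if d < best_d - 1e-12:
                best_d, best = d, ra.T @ rb
    return best


def random_pose(rng, spread=500.0, pid=0):
    return Pose(
        rotation=Rotation.random(rng=rng).as_matrix(),
        center=rng.uniform(-spread, spread, 3),
        particle_id=pid,
    )


class TestSymmetryResolution:
    def test_c2_composed_pose_gives_identity(self, model, rng):
        # pose B places the complex identically to pose A (C2-composed,
        # small shift): the canonical relative rotation must be identity
        pose_a = random_pose(rng)
        pose_b = Pose(
            rotation=pose_a.rotation @ model.symmetry_op,
            center=pose_a.center + np.array([10.0, 0, 0]),
            particle_id=0,
        )
        r_rel, swapped = resolve_symmetry(pose_a, pose_b, model)
        assert np.allclose(r_rel, np.eye(3), atol=1e-10)
        assert swapped

    def test_matches_brute_force(self, model, rng):
        for _ in range(50):
            a, b = random_pose(rng), random_pose(rng)
            r_rel, _ = resolve_symmetry(a, b, model)
            assert np.allclose(r_rel, brute_force_canonical(a, b, model), atol=1e-12)

    def test_exact_tie_returns_identity_assignment(self, model):
        # identical poses: both assignments give equal marker distances
        pose = Pose(rotation=np.eye(3), center=np.zeros(3))
        r_rel, swapped = resolve_symmetry(pose, pose, model)
        assert not swapped
        assert np.allclose(r_rel, np.eye(3))

    def test_symmetry_idempotence(self, model, rng):
        # replacing either pose by its C2 equivalent leaves the canonical
        # representative unchanged
        for _ in range(20):
            a, b = random_pose(rng), random_pose(rng)
            base, _ = resolve_symmetry(a, b, model)
            a2 = Pose(rotation=a.rotation @ model.symmetry_op, center=a.center)
            b2 = Pose(rotation=b.rotation @ model.symmetry_op, center=b.center)
            for aa, bb in ((a2, b), (a, b2), (a2, b2)):
                alt, _ = resolve_symmetry(aa, bb, model)
                assert np.allclose(alt, base, atol=1e-9)

    def test_antisymmetry(self, model, rng):
        for _ in range(20):
            a, b = random_pose(rng), random_pose(rng)
            r_ab, _ = resolve_symmetry(a, b, model)
            r_ba, _ = resolve_symmetry(b, a, model)
            assert np.allclose(r_ba, r_ab.T, atol=1e-6)


class TestPairGeometry:
    def test_translated_identity_pair(self, model):
        a = Pose(rotation=np.eye(3), center=np.zeros(3))
        b = Pose(rotation=np.eye(3), center=np.array([100.0, 0, 0]))
        pg = pair_geometry(a, b, model)
        # center marker sits at the model origin, so centers are 100 apart
        assert pg.distance_center == pytest.approx(100.0)
        assert np.allclose(pg.euler, (0, 0, 0), atol=1e-9)
        assert pg.theta == pytest.approx(90.0)   # +X direction
        assert pg.phi == pytest.approx(0.0)

    def test_rigid_motion_invariance(self, model, rng):
        a, b = random_pose(rng), random_pose(rng)
        ref = pair_geometry(a, b, model)
        G = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-1000, 1000, 3)
        a2 = Pose(rotation=G @ a.rotation, center=G @ a.center + t)
        b2 = Pose(rotation=G @ b.rotation, center=G @ b.center + t)
        moved = pair_geometry(a2, b2, model)
        assert moved.distance_center == pytest.approx(ref.distance_center, abs=1e-6)
        assert moved.distance_closest == pytest.approx(ref.distance_closest, abs=1e-6)
        assert np.allclose(moved.euler, ref.euler, atol=1e-6)
        assert moved.theta == pytest.approx(ref.theta, abs=1e-6)
        assert moved.phi == pytest.approx(ref.phi, abs=1e-6)
        assert moved.contact == ref.contact

    def test_closest_distance_matches_exhaustive_scan(self, model, rng):
        for _ in range(50):
            a, b = random_pose(rng, spread=300.0), random_pose(rng, spread=300.0)
            pg = pair_geometry(a, b, model)
            pa, pb = a.place(model.coords), b.place(model.coords)
            brute = min(
                np.linalg.norm(pa[i] - pb[j])
                for i in range(len(pa))
                for j in range(len(pb))
            )
            assert pg.distance_closest == pytest.approx(brute, abs=1e-9)
            assert pg.contact == (brute <= 10.0)
            assert pg.distance_center >= pg.distance_closest >= 0

    def test_degenerate_pair_warns(self, model):
        pose = Pose(rotation=np.eye(3), center=np.zeros(3))
        with pytest.warns(UserWarning, match="degenerate"):
            pg = pair_geometry(pose, pose, model)
        assert pg.phi == 0.0 and pg.theta == 0.0


class TestExtractPairs:
    def test_three_poses_one_particle(self, model, rng):
        poses = [random_pose(rng, pid=0) for _ in range(3)]
        assert len(extract_pairs(poses, [0, 0, 0], model, dedup_cutoff=1.0)) == 3

    def test_cross_particle_pairs_excluded(self, model, rng):
        poses = [random_pose(rng, pid=0), random_pose(rng, pid=1)]
        assert extract_pairs(poses, [0, 1], model) == []

    def test_duplicates_collapsed_first_kept(self, model, rng):
        base = random_pose(rng, pid=0)
        dup = Pose(rotation=Rotation.random(rng=rng).as_matrix(),
                   center=base.center + [30.0, 0, 0], particle_id=0)
        far1 = Pose(rotation=np.eye(3), center=base.center + 400.0, particle_id=0)
        far2 = Pose(rotation=np.eye(3), center=base.center - 400.0, particle_id=0)
        poses = [base, dup, far1, far2]
        pairs = extract_pairs(poses, [0] * 4, model, dedup_cutoff=100.0)
        # dup removed -> C(3,2)=3 pairs, and index 1 never appears
        assert len(pairs) == 3
        used = {p.index_a for p in pairs} | {p.index_b for p in pairs}
        assert used == {0, 2, 3}

    def test_empty_input(self, model):
        assert extract_pairs([], [], model) == []

    def test_assignment_must_cover_poses(self, model, rng):
        with pytest.raises(ValueError):
            extract_pairs([random_pose(rng)], [], model)


class TestContactFrequency:
    def test_far_pairs_have_zero_frequency(self, model):
        a = Pose(rotation=np.eye(3), center=np.zeros(3))
        b = Pose(rotation=np.eye(3), center=np.array([5000.0, 0, 0]))
        freq, frac = contact_frequency([(a, b)], model)
        assert frac == 0.0 and (freq == 0).all()

    def test_coincident_pairs_have_unit_frequency(self, model):
        pose = Pose(rotation=np.eye(3), center=np.zeros(3))
        freq, frac = contact_frequency([(pose, pose)] * 3, model)
        assert frac == 1.0 and (freq == 1).all()

    def test_generated_contact_fraction_closure(self, model):
        pairs, flags = generate_contact_pairs(model, 120, 0.2, cutoff=10.0, seed=5)
        _, frac = contact_frequency(pairs, model, cutoff=10.0)
        assert frac == pytest.approx(flags.mean(), abs=1e-12)

    def test_invalid_cutoff(self, model):
        with pytest.raises(ValueError):
            contact_frequency([], model, cutoff=-1.0)


class TestEmbedding:
    @staticmethod
    def two_cluster_table(n_per=60, seed=0):
        rng = np.random.default_rng(seed)
        a = np.column_stack([
            rng.normal(10, 2, n_per), rng.normal(0, 2, n_per),
            rng.normal(0, 2, n_per), rng.normal(200, 5, n_per),
        ])
        b = np.column_stack([
            rng.normal(150, 2, n_per), rng.normal(60, 2, n_per),
            rng.normal(-120, 2, n_per), rng.normal(500, 5, n_per),
        ])
        return np.vstack([a, b]), np.r_[np.zeros(n_per), np.ones(n_per)]

    def test_deterministic_and_shaped(self):
        X, _ = self.two_cluster_table()
        c1 = embed_pairs(X, perplexity=20, seed=3)
        c2 = embed_pairs(X, perplexity=20, seed=3)
        assert c1.shape == (len(X), 2)
        assert np.array_equal(c1, c2)

    def test_separated_clusters_stay_separated(self):
        from sklearn.metrics import silhouette_score

        X, labels = self.two_cluster_table()
        coords = embed_pairs(X, perplexity=20, seed=0)
        assert silhouette_score(coords, labels) > 0.5

    def test_too_few_rows_error_names_minimum(self):
        with pytest.raises(ValueError, match="90"):
            embed_pairs(np.zeros((10, 4)), perplexity=30)


class TestCrosslinkDistances:
    def test_basic_distances(self):
        coords = {("A", 1): np.zeros(3), ("A", 2): np.array([3.0, 4.0, 0.0])}
        links = CrosslinkSet(pairs=[("A", 1, "A", 1), ("A", 1, "A", 2)])
        out, counts, edges = crosslink_distances(links, coords, cutoff=30.0)
        assert out.distances[0] == 0.0 and out.satisfied[0]
        assert out.distances[1] == pytest.approx(5.0)   # 3-4-5 triangle
        assert counts[1] == 1   # 5 A falls in the 5-10 bin
        assert out.n_unmapped == 0

    def test_missing_residue_tallied_not_dropped(self):
        coords = {("A", 1): np.zeros(3)}
        links = CrosslinkSet(pairs=[("A", 1, "B", 99), ("A", 1, "A", 1)])
        out, _, _ = crosslink_distances(links, coords)
        assert out.n_unmapped == 1
        assert len(out.pairs) == 2
        assert np.isnan(out.distances[0])
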