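"""Coordination counting, distances, superposed RMSD, Daura clustering, RMSF."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lanthakit.trajectory import (
    Frame,
    Trajectory,
    com_distance,
    coordination_count,
    coordination_fractions,
    daura_cluster,
    min_distance,
    rmsd_superposed,
    rmsf,
)


def make_frame(waters, ion=(0.0, 0.0, 0.0)):
    return Frame(groups={"ion": np.array([ion]), "water": np.asarray(waters, float).reshape(-1, 3)})


def random_rotation(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestCoordinationCount:
    def test_no_waters(self):
        frame = Frame(groups={"ion": np.zeros((1, 3)), "water": np.empty((0, 3))})
        assert coordination_count(frame) == 0

    def test_distance_arithmetic(self):
        frame = make_frame([[3.0, 0, 0], [3.5, 0, 0]])
        assert coordination_count(frame) == 1

    def test_boundary_inclusive(self):
        frame = make_frame([[3.4, 0, 0]])
        assert coordination_count(frame) == 1

    def test_multiple_ion_points_rejected(self):
        frame = Frame(groups={"ion": np.zeros((2, 3)), "water": np.empty((0, 3))})
        with pytest.raises(ValueError, match="exactly one"):
            coordination_count(frame)

    def test_missing_group_rejected(self):
        frame = Frame(groups={"ion": np.zeros((1, 3))})
        with pytest.raises(KeyError):
            coordination_count(frame)


class TestCoordinationFractions:
    def test_all_singly_coordinated(self):
        frames = [make_frame([[2.0, 0, 0], [6.0, 0, 0]]) for _ in range(10)]
        frac = coordination_fractions(Trajectory(frames))
        assert frac["1"] == 1.0 and frac["0"] == 0.0 and frac["2"] == 0.0
        assert frac[">=1"] == 1.0

    def test_reorder_invariance(self):
        frames = [make_frame([[2.0, 0, 0]]), make_frame([[6.0, 0, 0]]),
                  make_frame([[2.0, 0, 0]])]
        a = coordination_fractions(Trajectory(frames))
        b = coordination_fractions(Trajectory(frames[::-1]))
        assert a == b


class TestComDistance:
    def test_identical_groups(self):
        pts = np.random.default_rng(0).normal(size=(4, 3))
        frame = Frame(groups={"a": pts, "b": pts.copy()})
        assert com_distance(frame, "a", "b") == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        frame = Frame(groups={
            "a": np.zeros((2, 3)),
            "b": np.array([[10.0, 0, 0], [12.0, 0, 0]]),
        })
        assert com_distance(frame, "a", "b") == pytest.approx(11.0)

    def test_mass_weighting(self):
        frame = Frame(
            groups={"a": np.zeros((1, 3)),
                    "b": np.array([[10.0, 0, 0], [20.0, 0, 0]])},
            masses={"b": np.array([3.0, 1.0])},
        )
        assert com_distance(frame, "a", "b") == pytest.approx(12.5)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(4, 3)) + 8.0
        shift = np.array([3.0, -2.0, 7.0])
        f1 = Frame(groups={"a": a, "b": b})
        f2 = Frame(groups={"a": a + shift, "b": b + shift})
        assert com_distance(f1, "a", "b") == pytest.approx(com_distance(f2, "a", "b"))


class TestMinDistance:
    def test_shared_point_zero(self):
        a = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        b = np.array([[5.0, 0, 0], [9.0, 0, 0]])
        assert min_distance(Frame(groups={"a": a, "b": b}), "a", "b") == 0.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(20, 3)), rng.normal(size=(20, 3)) + 2.0
        frame = Frame(groups={"a": a, "b": b})
        oracle = min(np.linalg.norm(p - q) for p in a for q in b)
        assert min_distance(frame, "a", "b") == pytest.approx(oracle, rel=1e-12)

    def test_triangle_bound_against_com(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(10, 3)), rng.normal(size=(10, 3)) + 15.0
        frame = Frame(groups={"a": a, "b": b})
        rg = lambda x: np.sqrt(((x - x.mean(0)) ** 2).sum(1).max())
        assert min_distance(frame, "a", "b") <= com_distance(frame, "a", "b") + rg(a) + rg(b)


class TestRmsdSuperposed:
    def test_identical_sets_zero(self):
        pts = np.random.default_rng(2).normal(size=(6, 3))
        assert rmsd_superposed(pts, pts) == pytest.approx(0.0, abs=1e-12)

    @given(seed=st.integers(0, 50))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_rigid_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 3)) * 4.0
        rot = random_rotation(rng)
        moved = pts @ rot.T + rng.normal(size=3) * 10.0
        assert rmsd_superposed(pts, moved) == pytest.approx(0.0, abs=1e-9)

    def test_against_numeric_rotation_search(self):
        """Numeric search over rotations (coarse grid + local polish) is an
        independent oracle for the closed-form optimal superposition."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        a = rng.normal(size=(4, 3)) * 2.0
        b = a + rng.normal(size=(4, 3)) * 0.5
        closed = rmsd_superposed(a, b)
        ac = a - a.mean(0)
        bc = b - b.mean(0)

        def objective(euler):
            rot = Rotation.from_euler("xyz", euler).as_matrix()
            return np.sqrt(((ac @ rot.T - bc) ** 2).sum() / 4)

        angles = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        best_euler = min(itertools.product(angles, angles, angles), key=objective)
        best = minimize(objective, best_euler, method="Nelder-Mead",
                        options={"xatol": 1e-8, "fatol": 1e-12}).fun
        assert closed <= best + 1e-9  # closed form is never beaten
        assert abs(best - closed) < 1e-3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmsd_superposed(np.zeros((4, 3)), np.zeros((5, 3)))


def brute_force_daura(items, cutoff):
    """Independent greedy enumeration oracle for small item counts."""
    n = len(items)
    rmsd = np.array([[rmsd_superposed(items[i], items[j]) for j in range(n)] for i in range(n)])
    remaining = list(range(n))
    clusters = []
    while remaining:
        best_center, best_members = None, []
        for i in remaining:
            members = [j for j in remaining if rmsd[i, j] <= cutoff]
            if len(members) > len(best_members):
                best_center, best_members = i, members
        clusters.append((best_center, sorted(best_members)))
        remaining = [j for j in remaining if j not in best_members]
    return clusters


class TestDauraCluster:
    def test_single_item(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        res = daura_cluster([pts])
        assert res.n_clusters == 1 and res.centroids[0] == 0

    def test_two_planted_groups(self):
        from lanthakit.synthetic import GeneratorSpec, gen_conformer_set

        items, labels = gen_conformer_set(
            k_clusters=2, per_cluster=3, intra_spread=0.3, inter_sep=8.0,
            spec=GeneratorSpec(seed=5),
        )
        res = daura_cluster(items, cutoff=1.7)
        assert res.n_clusters == 2
        # members agree with planted labels up to cluster relabelling
        for cid in res.centroids:
            member_labels = {labels[i] for i in res.members(cid)}
            assert len(member_labels) == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        items = [rng.normal(size=(5, 3)) * rng.uniform(0.5, 2.0) for _ in range(8)]
        cutoff = 1.7
        res = daura_cluster(items, cutoff)
        oracle = brute_force_daura(items, cutoff)
        assert res.n_clusters == len(oracle)
        for cid, (center, members) in enumerate(oracle):
            assert res.centroids[cid] == center
            assert res.members(cid) == members

    def test_partition_property(self):
        rng = np.random.default_rng(9)
        items = [rng.normal(size=(6, 3)) for _ in range(12)]
        res = daura_cluster(items, cutoff=2.5)
        sizes = sum(len(res.members(cid)) for cid in res.centroids)
        assert sizes == 12
        assert sorted(res.assignment) == list(range(12))
        for cid, center in res.centroids.items():
            assert res.assignment[center] == cid


class TestRmsf:
    def test_static_trajectory_zero(self):
        pts = np.random.default_rng(4).normal(size=(6, 3))
        traj = Trajectory([Frame(groups={"a": pts.copy()}) for _ in range(5)])
        assert rmsf(traj, "a") == pytest.approx(np.zeros(6), abs=1e-12)

    def test_oscillating_atom_amplitude(self):
        base = np.random.default_rng(5).normal(size=(5, 3)) * 3.0
        frames = []
        for sign in (1.0, -1.0) * 10:
            coords = base.copy()
            coords[0, 0] += sign * 0.8
            frames.append(Frame(groups={"a": coords}))
        values = rmsf(Trajectory(frames), "a", superpose=False)
        assert values[0] == pytest.approx(0.8, rel=1e-9)
        assert values[1:] == pytest.approx(np.zeros(4), abs=1e-12)

    def test_global_rigid_transform_invariance(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(7, 3)) * 2.0
        frames_a, frames_b = [], []
        rot = random_rotation(rng)
        shift = np.array([5.0, -3.0, 1.0])
        for _ in range(8):
            coords = base + rng.normal(scale=0.1, size=base.shape)
            frames_a.append(Frame(groups={"a": coords}))
            frames_b.append(Frame(groups={"a": coords @ rot.T + shift}))
        a = rmsf(Trajectory(frames_a), "a")
        b = rmsf(Trajectory(frames_b), "a")
        assert a == pytest.approx(b, abs=1e-9)

    def test_single_frame_rejected(self):
        traj = Trajectory([Frame(groups={"a": np.zeros((3, 3))})])
        with pytest.raises(ValueError):
            rmsf(traj, "a")
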