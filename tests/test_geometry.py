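import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from spinscape.geometry import (
    RigidTransform,
    clash_exclusion_mask,
    count_clashes,
    count_clashes_batch,
    site_rmsd,
    superpose,
)


def _grid_rmsd_oracle(mobile, target, step_deg=5.0):
    """Brute-force minimum rmsd over a rotation grid (translation removed)."""
    mob = mobile - mobile.mean(axis=0)
    tgt = target - target.mean(axis=0)
    angles = np.deg2rad(np.arange(0, 360, step_deg))
    polar = np.deg2rad(np.arange(0, 181, step_deg))
    best = np.inf
    for a in angles:
        for b in polar:
            rots = Rotation.from_euler(
                "zyz", np.column_stack([np.full_like(angles, a),
                                        np.full_like(angles, b), angles])
            )
            moved = np.einsum("rij,nj->rni", rots.as_matrix(), mob)
            rmsd = np.sqrt(np.mean(np.sum((moved - tgt) ** 2, axis=-1), axis=-1))
            best = min(best, rmsd.min())
    return best


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(5, 3))
        tf, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation(self, rng):
        pts = rng.normal(size=(4, 3))
        tf, rmsd = superpose(pts, pts + np.array([5.0, 0.0, 0.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(tf.apply(pts), pts + [5, 0, 0], atol=1e-9)

    def test_matches_rotation_grid_oracle(self, rng):
        mobile = rng.normal(size=(4, 3))
        target = rng.normal(size=(4, 3))
        _, rmsd = superpose(mobile, target)
        oracle = _grid_rmsd_oracle(mobile, target)
        assert rmsd <= oracle + 1e-9  # Kabsch is optimal
        assert abs(rmsd - oracle) < 1e-2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_to_joint_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(size=(5, 3))
        target = rng.normal(size=(5, 3))
        _, rmsd0 = superpose(mobile, target)
        rot = Rotation.random(rng=np.random.default_rng(seed + 1)).as_matrix()
        shift = rng.normal(size=3)
        _, rmsd1 = superpose(mobile @ rot.T + shift, target @ rot.T + shift)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-8)


class TestSiteRmsd:
    def test_identical_is_zero(self, rng):
        pts = rng.normal(size=(4, 3))
        assert site_rmsd(pts, pts) == 0.0

    def test_uniform_displacement(self, rng):
        pts = rng.normal(size=(4, 3))
        shifted = pts + np.array([0.0, 0.0, 2.0])
        assert site_rmsd(shifted, pts) == pytest.approx(2.0)

    def test_matches_direct_formula(self, rng):
        a = rng.normal(size=(4, 3))
        b = a + rng.normal(scale=0.5, size=(4, 3))
        expected = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
        assert site_rmsd(a, b) == pytest.approx(expected, abs=1e-12)

    def test_no_refitting_happens(self):
        # a pure rotation about the centroid must NOT give zero
        pts = np.array([[1.0, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]])
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        assert site_rmsd(pts @ rot.T, pts) > 0.5

    def test_wrong_length(self):
        with pytest.raises(ValueError):
            site_rmsd(np.zeros((3, 3)), np.zeros((3, 3)))


class TestCountClashes:
    def test_far_apart_is_zero(self):
        label = np.array([[100.0, 0, 0]])
        protein = np.array([[0.0, 0, 0]])
        assert count_clashes(label, protein, cutoff=3.4) == 0

    def test_single_pair_below_cutoff(self):
        label = np.array([[0.0, 0, 0]])
        protein = np.array([[3.3, 0, 0]])
        assert count_clashes(label, protein, cutoff=3.4) == 1
        assert count_clashes(label, protein, cutoff=3.0) == 0

    def test_strictly_less_than_cutoff(self):
        label = np.array([[0.0, 0, 0]])
        protein = np.array([[3.4, 0, 0]])
        assert count_clashes(label, protein, cutoff=3.4) == 0

    def test_empty_inputs(self):
        assert count_clashes(np.zeros((0, 3)), np.zeros((5, 3)), 3.4) == 0
        assert count_clashes(np.zeros((2, 3)), np.zeros((0, 3)), 3.4) == 0

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            count_clashes(np.zeros((1, 3)), np.zeros((1, 3)), 0.0)

    def test_exclusions_removed_from_count(self):
        label = np.array([[0.0, 0, 0]])
        protein = np.array([[1.0, 0, 0], [2.0, 0, 0]])
        assert count_clashes(label, protein, 3.4) == 2
        assert count_clashes(label, protein, 3.4, exclusions=[0]) == 1

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_tree_equals_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        label = rng.uniform(0, 10, size=(rng.integers(1, 20), 3))
        protein = rng.uniform(0, 10, size=(rng.integers(1, 80), 3))
        cutoff = float(rng.uniform(0.5, 5.0))
        naive = sum(
            1
            for la in label
            for pa in protein
            if np.linalg.norm(la - pa) < cutoff
        )
        assert count_clashes(label, protein, cutoff) == naive
        batch = count_clashes_batch(label[None, :, :], protein, cutoff)
        assert batch[0] == naive


def test_clash_exclusion_mask_covers_site_and_neighbour_backbone(helix):
    mask = clash_exclusion_mask(helix, ["A:6"])
    excluded = {
        (helix.atoms[i].residue_id[1], helix.atoms[i].name)
        for i in np.flatnonzero(mask)
    }
    assert {(6, n) for n in ("N", "CA", "C", "O", "CB")} <= excluded
    for neighbour in (5, 7):
        assert {(neighbour, n) for n in ("N", "CA", "C", "O")} <= excluded
        assert (neighbour, "CB") not in excluded


def test_rigid_transform_validates_rotation():
    with pytest.raises(ValueError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))  # improper
    tf = RigidTransform.identity()
    pts = np.arange(12.0).reshape(4, 3)
    np.testing.assert_array_equal(tf.apply(pts), pts)
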