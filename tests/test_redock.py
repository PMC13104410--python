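"""In-place RMSD, symmetry correction, success rates, report assembly."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dockperm import (
    RedockingValidation,
    average_rmsd,
    best_pose,
    gen_translated_poses,
    heavy_atom_view,
    inplace_rmsd,
    round_half_up,
    success_rate,
    top_pose_index,
    top_pose_rmsd,
)
from dockperm.pose_io import PoseValidationError

from conftest import toy_conformer


def brute_force_symmetry_rmsd(ref, pose):
    """Oracle: minimise over *all* element- and bond-preserving permutations."""
    ref_h, pose_h = heavy_atom_view(ref), heavy_atom_view(pose)
    a, b = ref_h.coords, pose_h.coords
    elements = ref_h.elements
    bonds = {frozenset((i, j)): order for i, j, order in ref_h.bonds}
    best = np.inf
    for perm in itertools.permutations(range(len(a))):
        if any(elements[perm[i]] != elements[i] for i in range(len(a))):
            continue
        mapped = {
            frozenset((perm[i], perm[j])): order
            for (i, j), order in ((tuple(k), v) for k, v in bonds.items())
        }
        if mapped != bonds:
            continue
        d = np.sqrt(np.mean(np.sum((a[list(perm)] - b) ** 2, axis=1)))
        best = min(best, d)
    return float(best)


def para_ring():
    """Planar para-disubstituted 6-ring: flipping about the axis is an automorphism."""
    # ring carbons at hexagon vertices, substituents N (top) and O (bottom)
    ring = [
        (0.0, 1.4, 0.0), (1.21, 0.7, 0.0), (1.21, -0.7, 0.0),
        (0.0, -1.4, 0.0), (-1.21, -0.7, 0.0), (-1.21, 0.7, 0.0),
    ]
    coords = ring + [(0.0, 2.8, 0.0), (0.0, -2.8, 0.0)]
    elements = ["C"] * 6 + ["N", "O"]
    bonds = [(i, (i + 1) % 6, 1.5) for i in range(6)] + [(0, 6, 1.0), (3, 7, 1.0)]
    return toy_conformer(elements, coords, bonds, name="para")


class TestInplaceRmsd:
    def test_identity_is_zero(self, reference_ligand):
        assert inplace_rmsd(reference_ligand, reference_ligand) == 0.0

    def test_rigid_translation_gives_vector_norm(self, reference_ligand):
        ps = gen_translated_poses(reference_ligand, [3.0], seed=0)
        assert inplace_rmsd(reference_ligand, ps.poses[0]) == pytest.approx(3.0)

    def test_symmetric_flip_recovered_only_with_symmetry(self):
        ref = para_ring()
        # flip 180° about the N...O axis (y axis): x -> -x, z -> -z
        flipped = toy_conformer(
            ref.elements,
            [(-x, y, -z) for x, y, z in ref.coords],
            ref.bonds,
            name="flipped",
        )
        assert inplace_rmsd(ref, flipped, symmetry=False) > 1.0
        assert inplace_rmsd(ref, flipped, symmetry=True) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_matches_brute_force_oracle(self):
        ref = para_ring()
        rng = np.random.default_rng(5)
        jittered = toy_conformer(
            ref.elements,
            np.asarray(ref.coords) + rng.normal(0, 0.3, (len(ref), 3)),
            ref.bonds,
        )
        assert inplace_rmsd(ref, jittered, symmetry=True) == pytest.approx(
            brute_force_symmetry_rmsd(ref, jittered)
        )

    def test_symmetry_never_exceeds_identity(self, reference_ligand):
        ps = gen_translated_poses(reference_ligand, [1.0, 2.5], seed=3, mode="jitter")
        for pose in ps.poses:
            assert inplace_rmsd(reference_ligand, pose, symmetry=True) <= inplace_rmsd(
                reference_ligand, pose, symmetry=False
            ) + 1e-12

    def test_invariant_under_common_rigid_shift(self, reference_ligand):
        ps = gen_translated_poses(reference_ligand, [2.0], seed=9)
        pose = ps.poses[0]
        shift = np.array([5.0, -3.0, 1.0])
        ref2 = toy_conformer(
            reference_ligand.elements,
            np.asarray(reference_ligand.coords) + shift,
            reference_ligand.bonds,
        )
        pose2 = toy_conformer(pose.elements, np.asarray(pose.coords) + shift, pose.bonds)
        assert inplace_rmsd(ref2, pose2) == pytest.approx(
            inplace_rmsd(reference_ligand, pose)
        )

    def test_atom_count_mismatch_errors(self, reference_ligand, water):
        with pytest.raises(PoseValidationError):
            inplace_rmsd(reference_ligand, water)


class TestPoseSelection:
    def test_best_pose_examples(self):
        assert best_pose([3.3, 0.8, 2.0]) == (0.8, 2)
        assert best_pose([1.0, 1.0]) == (1.0, 1)  # tie -> lowest rank

    def test_best_pose_matches_exhaustive_scan(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 12, size=100)
        value, rank_ = best_pose(vals)
        expected = min(range(100), key=lambda i: vals[i])
        assert (value, rank_) == (vals[expected], expected + 1)

    def test_top_pose_orientation(self, water):
        from dockperm.pose_io import PoseSet

        ps = PoseSet(
            reference=water,
            poses=[water, water, water],
            scores={"f": [5.0, 9.0, 1.0]},
        )
        rmsds = [3.0, 0.8, 2.0]
        assert top_pose_rmsd(ps, "f", "higher", rmsds=rmsds) == (0.8, 2)
        assert top_pose_rmsd(ps, "f", "lower", rmsds=rmsds) == (2.0, 3)

    def test_top_pose_index_matches_sort_oracle(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=100)
        assert top_pose_index(scores) == int(np.argsort(-scores, kind="stable")[0])


class TestSuccessRate:
    @pytest.mark.parametrize(
        "rmsds, expected",
        [
            ([1.16, 1.65, 1.02], 100),
            ([8.82, 4.66, 2.54], 0),
            ([2.0, 2.0, 2.0], 0),  # strict inequality at the boundary
            ([1.9, 2.1, 0.5], 67),
        ],
    )
    def test_strict_cutoff_rule(self, rmsds, expected):
        assert success_rate(rmsds).rounded == expected

    @given(
        st.lists(st.floats(0.0, 15.0), min_size=1, max_size=12),
        st.floats(0.1, 5.0),
        st.floats(0.0, 5.0),
    )
    def test_monotone_in_cutoff(self, rmsds, cutoff, bump):
        low = success_rate(rmsds, cutoff)
        high = success_rate(rmsds, cutoff + bump)
        assert high.n_success >= low.n_success

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            success_rate([])


class TestAverageRmsd:
    @pytest.mark.parametrize(
        "rmsds, expected",
        [
            ([8.68, 7.99, 1.87], 6.2),
            ([1.16, 1.65, 1.02], 1.3),
            ([4.0], 4.0),
        ],
    )
    def test_one_decimal_reporting(self, rmsds, expected):
        assert round_half_up(average_rmsd(rmsds), 1) == expected

    @given(st.lists(st.floats(0.0, 20.0), min_size=1, max_size=10))
    def test_mean_within_range(self, rmsds):
        m = average_rmsd(rmsds)
        assert min(rmsds) - 1e-9 <= m <= max(rmsds) + 1e-9


class TestRedockReport:
    def test_pooled_overall_success_rate(self, reference_ligand):
        # 2/3 under each algorithm pools to 4/6 = 67%
        def pose_set(lig, targets):
            ps = gen_translated_poses(reference_ligand, targets, seed=hash(lig) % 1000,
                                      ligand_id=lig)
            ps.scores["f"] = list(range(len(targets), 0, -1))  # top pose = pose 1
            return ps

        sets_a = [pose_set(l, [t]) for l, t in zip("abc", [1.0, 1.5, 3.0])]
        sets_b = [pose_set(l, [t]) for l, t in zip("abc", [0.5, 2.5, 1.9])]
        res = RedockingValidation(
            {("S", "algo1"): sets_a, ("S", "algo2"): sets_b}
        ).fit()
        overall = res.overall_success_rates("S")
        assert overall["f"].n_success == 4
        assert overall["f"].n_total == 6
        assert overall["f"].rounded == 67

    def test_inconsistent_ligand_sets_rejected(self, reference_ligand):
        ps1 = gen_translated_poses(reference_ligand, [1.0], seed=0, ligand_id="x")
        ps2 = gen_translated_poses(reference_ligand, [1.0], seed=1, ligand_id="y")
        for ps in (ps1, ps2):
            ps.scores["f"] = [1.0]
        with pytest.raises(ValueError, match="inconsistent"):
            RedockingValidation({("S", "a1"): [ps1], ("S", "a2"): [ps2]}).fit()

    def test_single_ligand_single_function_table(self, reference_ligand):
        ps = gen_translated_poses(reference_ligand, [0.9], seed=0, ligand_id="x")
        ps.scores["f"] = [1.0]
        frame = RedockingValidation({("S", "a"): [ps]}).fit().summary()
        assert frame.loc[("S", "a", "Success rate (%)"), "f"] == 100
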