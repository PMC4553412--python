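"""Rotation-maximized gray-matter cube similarity and network assembly."""

import numpy as np
import pandas as pd
import pytest

import tremornet as tn
from tremornet.morpho_similarity import GmPatchSet, cube_orientations


def _oracle_orientations(cube, include_reflections=True):
    """Independent enumeration of cube isometries via repeated rot90.

    Generates the 24 proper rotations by composing quarter turns
    breadth-first until closure, then adds a mirror image of each when
    reflections are requested.
    """
    seen = {}
    frontier = [np.array(cube)]
    seen[cube.tobytes()] = np.array(cube)
    while frontier:
        nxt = []
        for c in frontier:
            for axes in ((0, 1), (0, 2), (1, 2)):
                r = np.rot90(c, 1, axes)
                if r.tobytes() not in seen:
                    seen[r.tobytes()] = r
                    nxt.append(r)
        frontier = nxt
    rots = list(seen.values())
    if include_reflections:
        out = list(rots)
        for r in rots:
            out.append(np.flip(r, axis=0))
        return out
    return rots


def _pearson(a, b):
    a, b = a.ravel().astype(float), b.ravel().astype(float)
    a -= a.mean()
    b -= b.mean()
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestOrientations:
    def test_group_sizes(self):
        assert len(cube_orientations(True)) == 48
        assert len(cube_orientations(False)) == 24

    def test_oracle_enumeration_has_expected_orbit_size(self, rng):
        cube = rng.standard_normal((3, 3, 3))  # generic cube: full orbit
        assert len(_oracle_orientations(cube, False)) == 24
        assert len({c.tobytes() for c in _oracle_orientations(cube, True)}) == 48


class TestCubeSimilarity:
    def test_rotated_copy_recovers_unit_similarity(self, rng):
        a = rng.standard_normal((3, 3, 3))
        b = np.rot90(a, 1, (0, 1))
        assert tn.cube_similarity(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_orientation_oracle(self, rng):
        for trial in range(10):
            a = rng.standard_normal((3, 3, 3))
            b = -a if trial == 0 else rng.standard_normal((3, 3, 3))
            for refl in (True, False):
                oracle = max(_pearson(r, b) for r in _oracle_orientations(a, refl))
                assert tn.cube_similarity(a, b, refl) == pytest.approx(oracle, abs=1e-10)

    def test_max_statistic_inflates_null_similarity(self, rng):
        # the max over 48 correlated draws sits well above zero even for
        # independent cubes; Monte-Carlo reference on 1000 pairs
        sims = [
            tn.cube_similarity(rng.standard_normal((3, 3, 3)), rng.standard_normal((3, 3, 3)))
            for _ in range(1000)
        ]
        assert 0.15 < float(np.mean(sims)) < 0.6

    def test_symmetry_is_exact(self, rng):
        for _ in range(20):
            a = rng.standard_normal((3, 3, 3))
            b = rng.standard_normal((3, 3, 3))
            assert tn.cube_similarity(a, b) == tn.cube_similarity(b, a)

    def test_pearson_invariance_to_offset_and_scale(self, rng):
        a = rng.standard_normal((3, 3, 3))
        b = rng.standard_normal((3, 3, 3))
        ref = tn.cube_similarity(a, b)
        assert tn.cube_similarity(2.5 * a + 7.0, b) == pytest.approx(ref, abs=1e-12)
        assert tn.cube_similarity(a, 0.3 * b - 1.0) == pytest.approx(ref, abs=1e-12)

    def test_more_orientations_never_decrease_similarity(self, rng):
        for _ in range(20):
            a = rng.standard_normal((3, 3, 3))
            b = rng.standard_normal((3, 3, 3))
            assert tn.cube_similarity(a, b, True) >= tn.cube_similarity(a, b, False) - 1e-12

    def test_flat_patch_yields_missing(self, rng):
        assert np.isnan(tn.cube_similarity(np.full((3, 3, 3), 2.0), rng.standard_normal((3, 3, 3))))


class TestExtractPatches:
    def test_centered_cube_indexing(self):
        vol = np.arange(1000, dtype=float).reshape(10, 10, 10)
        table = pd.DataFrame({"node_id": ["a"], "x": [5.0], "y": [5.0], "z": [5.0]})
        patches = tn.extract_patches(vol, table, cube_edge=3)
        np.testing.assert_array_equal(patches[0], vol[4:7, 4:7, 4:7])

    def test_single_voxel_cube(self):
        vol = np.arange(27, dtype=float).reshape(3, 3, 3)
        table = pd.DataFrame({"node_id": ["a"], "x": [1.0], "y": [2.0], "z": [0.0]})
        patches = tn.extract_patches(vol, table, cube_edge=1)
        assert patches[0].item() == vol[1, 2, 0]

    def test_boundary_cube_clamped_with_warning(self):
        vol = np.zeros((6, 6, 6))
        table = pd.DataFrame({"node_id": ["a"], "x": [0.0], "y": [0.0], "z": [0.0]})
        with pytest.warns(UserWarning, match="clamped"):
            patches = tn.extract_patches(vol, table, cube_edge=3)
        assert patches.shape == (1, 3, 3, 3)

    def test_centroid_outside_volume_is_an_error(self):
        vol = np.zeros((6, 6, 6))
        table = pd.DataFrame({"node_id": ["bad"], "x": [60.0], "y": [0.0], "z": [0.0]})
        with pytest.raises(ValueError, match="bad"):
            tn.extract_patches(vol, table, cube_edge=3)

    def test_world_to_voxel_through_affine(self):
        vol = np.arange(1000, dtype=float).reshape(10, 10, 10)
        affine = np.diag([3.0, 3.0, 3.0, 1.0])  # 3 mm voxels
        table = pd.DataFrame({"node_id": ["a"], "x": [15.0], "y": [15.0], "z": [15.0]})
        patches = tn.extract_patches(vol, table, cube_edge=3, affine=affine)
        np.testing.assert_array_equal(patches[0], vol[4:7, 4:7, 4:7])


class TestMorphoNetwork:
    def _patch_set(self, patches):
        patches = np.asarray(patches, float)[None]
        return GmPatchSet(
            subject_ids=("s0",),
            node_ids=tuple(f"n{i}" for i in range(patches.shape[1])),
            patches=patches,
            cube_edge=patches.shape[2],
        )

    def test_identical_cubes_give_unit_edges(self, rng):
        cube = rng.uniform(0, 1, (3, 3, 3))
        mats, _ = tn.build_morpho_network(self._patch_set([cube, cube, cube]))
        w = mats[0].weights
        iu = np.triu_indices(3, 1)
        assert np.allclose(w[iu], 1.0)

    def test_negative_similarity_zeroed(self, rng):
        # a radial pattern is invariant under every cube isometry, so its
        # negation is anticorrelated in all 48 orientations: max similarity -1
        idx = np.indices((3, 3, 3)) - 1
        radial = np.sqrt((idx**2).sum(axis=0))
        assert tn.cube_similarity(radial, -radial) == pytest.approx(-1.0, abs=1e-12)
        third = rng.uniform(0, 1, (3, 3, 3))
        mats, _ = tn.build_morpho_network(
            self._patch_set([radial, radial.max() - radial, third])
        )
        assert mats[0].weights[0, 1] == 0.0

    def test_zero_variance_nodes_reported_and_masked(self, rng):
        flat = np.full((3, 3, 3), 0.5)
        live1 = rng.uniform(0, 1, (3, 3, 3))
        live2 = rng.uniform(0, 1, (3, 3, 3))
        mats, report = tn.build_morpho_network(self._patch_set([live1, flat, live2]))
        assert report.excluded["s0"] == ("n1",)
        assert np.isnan(mats[0].weights[0, 1]) and np.isnan(mats[0].weights[1, 2])
        assert np.isfinite(mats[0].weights[0, 2])

    def test_majority_excluded_aborts(self):
        flat = np.full((3, 3, 3), 0.5)
        live = np.arange(27, dtype=float).reshape(3, 3, 3)
        with pytest.raises(ValueError, match="zero-variance"):
            tn.build_morpho_network(self._patch_set([flat, flat, live]))

    def test_exclusion_fraction_matches_configured_rate(self, small_cohort):
        _, report = tn.build_morpho_network(small_cohort.patches)
        expected = round(small_cohort.config.zero_variance_fraction * 24) / 24
        assert report.global_fraction == pytest.approx(expected)
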