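"""Single-subject gray-matter morphological networks.

Edges measure the similarity of local gray-matter (GM) patterns between
region centroids: each node is represented by a small cube of GM values
around its centroid, and the edge weight between two nodes is the
maximum Pearson correlation of their cubes over the cube isometry group
(24 proper rotations, optionally extended with reflections to 48).
Negative similarities are zeroed — only positive GM covariance is
interpreted as morphological connectivity — and binarization is left to
the shared sparsity grid so functional and morphological networks are
thresholded on equal footing.

Nodes whose cube has zero variance (flat GM, e.g. fully outside tissue)
cannot be correlated and are excluded; the exclusion report keeps track
of them per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .wavelet_fc import ConnectivityMatrix

__all__ = [
    "GmPatchSet",
    "NodeExclusionReport",
    "cube_orientations",
    "extract_patches",
    "cube_similarity",
    "build_morpho_network",
]


@dataclass(frozen=True)
class GmPatchSet:
    """Per-subject, per-node cubes of gray-matter values.

    ``patches`` has shape ``(n_subjects, n_nodes, e, e, e)`` with ``e`` the
    (odd) cube edge in voxels.  Values are non-negative GM
    concentrations/volumes.
    """

    subject_ids: tuple[str, ...]
    node_ids: tuple[str, ...]
    patches: np.ndarray
    cube_edge: int

    def __post_init__(self) -> None:
        e = self.cube_edge
        if e % 2 != 1 or e < 1:
            raise ValueError("cube_edge must be odd and >= 1")
        expected = (len(self.subject_ids), len(self.node_ids), e, e, e)
        if self.patches.shape != expected:
            raise ValueError(f"patches shape {self.patches.shape} != {expected}")
        if np.nanmin(self.patches) < 0:
            raise ValueError("gray-matter values must be non-negative")


@dataclass(frozen=True)
class NodeExclusionReport:
    """Zero-variance nodes removed from each subject's morphological network."""

    excluded: dict[str, tuple[str, ...]]
    global_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.global_fraction <= 1.0:
            raise ValueError("global_fraction must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subject_id": sid, "node_id": nid}
            for sid, nodes in self.excluded.items()
            for nid in nodes
        ]
        return pd.DataFrame(rows, columns=["subject_id", "node_id"])


def cube_orientations(include_reflections: bool = True) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """The cube isometry group as (axis permutation, sign flips) pairs.

    48 orthogonal transforms of a cubic array: 6 axis permutations x 8 sign
    patterns.  The 24 with positive determinant are the proper rotations;
    ``include_reflections=False`` restricts to those.
    """
    from itertools import permutations, product

    perm_sign = []
    for perm in permutations(range(3)):
        # determinant sign of the permutation matrix
        perm_det = 1 if perm in ((0, 1, 2), (1, 2, 0), (2, 0, 1)) else -1
        for signs in product((1, -1), repeat=3):
            det = perm_det * signs[0] * signs[1] * signs[2]
            if include_reflections or det == 1:
                perm_sign.append((perm, signs))
    return perm_sign


def _orient(cube: np.ndarray, perm: tuple[int, ...], signs: tuple[int, ...]) -> np.ndarray:
    out = np.transpose(cube, perm)
    for ax, s in enumerate(signs):
        if s < 0:
            out = np.flip(out, axis=ax)
    return out


def _standardize(v: np.ndarray) -> np.ndarray | None:
    """Center and scale a flattened patch so a dot product is a Pearson r.

    A flat patch (zero variance; detected exactly via peak-to-peak, which
    is immune to the float noise a mean subtraction leaves behind) has no
    correlation defined and yields None.
    """
    v = v.astype(float).ravel()
    if v.max() == v.min():
        return None
    v = v - v.mean()
    return v / np.linalg.norm(v)


def cube_similarity(
    patch_a: np.ndarray,
    patch_b: np.ndarray,
    include_reflections: bool = True,
) -> float:
    """Rotation-maximized Pearson similarity between two GM cubes.

    Maximum over the cube isometry group of corr(orient(a), b).  Because the
    group is closed under inversion, orienting ``a`` against fixed ``b`` and
    vice versa give the same maximum in exact arithmetic; to make the
    symmetry bit-exact under float round-off, both directions are evaluated
    and the larger kept.  Returns NaN when either patch has zero variance.
    """
    if patch_a.shape != patch_b.shape:
        raise ValueError("patches must share a shape")
    a0 = _standardize(patch_a)
    b0 = _standardize(patch_b)
    if a0 is None or b0 is None:
        return float("nan")
    shape = patch_a.shape
    best = -1.0
    for perm, signs in cube_orientations(include_reflections):
        ra = _orient(a0.reshape(shape), perm, signs).ravel()
        rb = _orient(b0.reshape(shape), perm, signs).ravel()
        best = max(best, float(ra @ b0), float(rb @ a0))
    return min(best, 1.0)


def extract_patches(
    gm_volume: "nib.spatialimages.SpatialImage | np.ndarray",
    node_table: pd.DataFrame,
    cube_edge: int = 3,
    affine: np.ndarray | None = None,
) -> np.ndarray:
    """Cut one cube per node out of a gray-matter volume.

    ``node_table`` needs columns ``node_id, x, y, z`` with world-mm
    coordinates (mapped to 0-based voxel indices through the volume's
    affine) or, for a bare array with no affine, voxel indices directly.
    Cubes whose extent would cross the volume boundary are clamped inward
    with a warning; centroids falling outside the volume are an error.

    Returns an array of shape ``(n_nodes, e, e, e)``.
    """
    if cube_edge % 2 != 1 or cube_edge < 1:
        raise ValueError("cube_edge must be odd and >= 1")
    if isinstance(gm_volume, np.ndarray):
        vol = gm_volume
        aff = affine if affine is not None else np.eye(4)
    else:
        vol = np.asanyarray(gm_volume.dataobj, dtype=float)
        aff = gm_volume.affine
    world = node_table[["x", "y", "z"]].to_numpy(dtype=float)
    ijk1 = np.linalg.inv(aff) @ np.column_stack([world, np.ones(len(world))]).T
    centers = np.round(ijk1[:3].T).astype(int)
    shape = np.array(vol.shape[:3])
    outside = (centers < 0).any(axis=1) | (centers >= shape).any(axis=1)
    if outside.any():
        bad = node_table["node_id"].to_numpy()[outside]
        raise ValueError(f"node centroids outside volume: {list(bad)}")
    half = cube_edge // 2
    lo = centers - half
    clamped = np.clip(lo, 0, shape - cube_edge)
    if (clamped != lo).any():
        n_cl = int((clamped != lo).any(axis=1).sum())
        warnings.warn(f"{n_cl} node cube(s) clamped inside the volume boundary")
    patches = np.empty((len(centers), cube_edge, cube_edge, cube_edge), dtype=float)
    for k, (i, j, l) in enumerate(clamped):
        patches[k] = vol[i : i + cube_edge, j : j + cube_edge, l : l + cube_edge]
    return patches


def build_morpho_network(
    patch_set: GmPatchSet,
    include_reflections: bool = True,
) -> tuple[list[ConnectivityMatrix], NodeExclusionReport]:
    """All-pairs rotation-maximized similarity, positivity-filtered.

    Per subject: compute the cube similarity for every node pair, zero
    negative values (positive-similarity rule), and carry zero-variance
    nodes as NaN rows/columns.  Binarization is delegated to the sparsity
    grid in the graph-metrics stage.  More than half the nodes excluded is
    treated as a broken input and aborts.
    """
    n_subj, n_nodes = patch_set.patches.shape[:2]
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    orients = cube_orientations(include_reflections)
    matrices: list[ConnectivityMatrix] = []
    excluded: dict[str, tuple[str, ...]] = {}
    n_excl_total = 0
    for s, sid in enumerate(patch_set.subject_ids):
        cubes = patch_set.patches[s]
        flat = cubes.reshape(n_nodes, -1).astype(float)
        # flat cubes detected via peak-to-peak (exact), not float variance
        dead = np.flatnonzero(flat.max(axis=1) == flat.min(axis=1))
        flat = flat - flat.mean(axis=1, keepdims=True)
        nrm = np.linalg.norm(flat, axis=1)
        nrm[dead] = 0.0
        excluded[sid] = tuple(patch_set.node_ids[i] for i in dead)
        n_excl_total += dead.size
        if dead.size > n_nodes / 2:
            raise ValueError(
                f"subject {sid}: {dead.size}/{n_nodes} nodes have zero-variance "
                "gray-matter cubes; input looks degenerate"
            )
        safe = nrm.copy()
        safe[dead] = 1.0
        z = flat / safe[:, None]
        zc = z.reshape(cubes.shape)
        # orientation permutes voxels, so standardization commutes with it:
        # standardize once, orient the standardized cubes, running max of
        # orient(a) . b over the group
        sim = np.full((n_nodes, n_nodes), -1.0)
        for perm, signs in orients:
            za = np.transpose(zc, (0,) + tuple(p + 1 for p in perm))
            for ax, sgn in enumerate(signs):
                if sgn < 0:
                    za = np.flip(za, axis=ax + 1)
            np.maximum(sim, za.reshape(n_nodes, -1) @ z.T, out=sim)
        sim = np.minimum(sim, 1.0)
        sim = np.maximum(sim, sim.T)  # guard symmetry against round-off
        sim[sim < 0] = 0.0  # only positive similarity survives
        sim[dead, :] = np.nan
        sim[:, dead] = np.nan
        np.fill_diagonal(sim, np.nan)
        matrices.append(
            ConnectivityMatrix(
                subject_id=sid,
                weights=sim,
                node_ids=patch_set.node_ids,
                modality="morphological",
                scale=None,
            )
        )
    report = NodeExclusionReport(
        excluded=excluded, global_fraction=n_excl_total / (n_subj * n_nodes)
    )
    return matrices, report
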