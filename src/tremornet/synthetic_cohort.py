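"""Synthetic two-group cohorts with planted, recoverable structure.

The generator emulates a resting-state case/control study — by default
16 patients and 20 controls, 264 network nodes, 180 timepoints at
TR = 2 s (175 after the usual discard of 5) — and plants effects that
every downstream stage can be scored against:

* **Topology.** Each group's ROI time series are zero-mean Gaussian
  noise colored by a block (modular) correlation matrix: ``intra_module_r``
  within modules, ``inter_module_r`` between.  The group difference is a
  single knob, ``topology_gap``: patients' intra-module coupling is
  reduced by that amount, which lowers their thresholded networks' local
  efficiency — the direction of the headline clinical finding this design
  mirrors.
* **Morphology.** Per node, a gray-matter cube drawn as a module-level
  archetype pattern plus node- and subject-level noise, so nodes of the
  same module are morphologically similar.  A configurable fraction of
  nodes receives flat (zero-variance) cubes to exercise the exclusion
  rule.
* **Clinic.** Tremor/UPDRS/duration scores are exact linear functions of
  measured nodal efficiency on a small set of "clinical nodes" plus
  Gaussian noise, so screened regression has a known coefficient vector
  (signs included) to recover.

Everything is driven by one integer seed; identical configurations give
bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .morpho_similarity import GmPatchSet
from .timeseries_prep import RoiTimeSeriesPanel, write_panel_tsv

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "Cohort",
    "plant_block_covariance",
    "generate_timeseries",
    "generate_gm_patches",
    "generate_clinical",
    "generate_cohort",
    "write_cohort",
    "assemble_gm_volume",
]

#: scale factors applied to the planted weight vector per clinical score
_CLINICAL_SCALES = {"tremor": 1.0, "updrs": 2.5, "duration": -0.8}


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the emulated study: 16 patients (group A) vs 20
    controls (group B), 264 nodes in 8 modules, 180 timepoints at
    TR = 2 s, and a modest reduction of patients' intra-module coupling.
    """

    n_group_a: int = 16
    n_group_b: int = 20
    n_nodes: int = 264
    n_timepoints: int = 180
    tr_seconds: float = 2.0
    n_modules: int = 8
    intra_module_r: float = 0.35
    inter_module_r: float = 0.08
    topology_gap: float = 0.12
    ar1_phi: float = 0.0
    cube_edge: int = 3
    n_clinical_nodes: int = 5
    clinical_beta: tuple[float, ...] = (40.0, -30.0, 35.0, -25.0, 30.0)
    clinical_noise_sd: float = 0.5
    relative_clinical_noise: bool = True
    zero_variance_fraction: float = 0.0001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes % self.n_modules != 0:
            raise ValueError("n_nodes must be divisible by n_modules")
        if not 0 <= self.inter_module_r < self.intra_module_r < 1:
            raise ValueError("need 0 <= inter_module_r < intra_module_r < 1")
        if self.intra_module_r - self.topology_gap < self.inter_module_r:
            raise ValueError("topology_gap drives patient intra-coupling below inter")
        if self.cube_edge % 2 != 1 or self.cube_edge < 3:
            raise ValueError("cube_edge must be odd and >= 3")
        if self.tr_seconds <= 0 or self.clinical_noise_sd < 0:
            raise ValueError("tr_seconds must be > 0 and clinical_noise_sd >= 0")
        if len(self.clinical_beta) != self.n_clinical_nodes:
            raise ValueError("clinical_beta length must equal n_clinical_nodes")
        if not 0 <= self.zero_variance_fraction < 0.5:
            raise ValueError("zero_variance_fraction must lie in [0, 0.5)")
        if not -1 < self.ar1_phi < 1:
            raise ValueError("ar1_phi must lie in (-1, 1)")


@dataclass(frozen=True)
class SyntheticTruth:
    """The planted parameters downstream recovery is judged against."""

    target_covariance_a: np.ndarray
    target_covariance_b: np.ndarray
    planted_clinical_weights: np.ndarray  # length n_nodes, nonzero on clinical nodes
    clinical_nodes: tuple[int, ...]
    module_of_node: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        for c in (self.target_covariance_a, self.target_covariance_b):
            if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
                raise ValueError("covariances must be symmetric with unit diagonal")
        if not np.all(np.isfinite(self.planted_clinical_weights)):
            raise ValueError("planted weights must be finite")


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    truth: SyntheticTruth
    panel: RoiTimeSeriesPanel
    patches: GmPatchSet
    table: pd.DataFrame  # subject_id, group, age, gender (+ clinical, NaN until filled)


def plant_block_covariance(
    n_nodes: int, n_modules: int, intra_r: float, inter_r: float
) -> np.ndarray:
    """Block correlation matrix: ``intra_r`` within modules, ``inter_r`` between.

    Repaired to the positive-semidefinite cone by clipping negative
    eigenvalues at zero and rescaling back to unit diagonal; parameters for
    which the repair moves entries materially are rejected.
    """
    if not 0 <= inter_r < 1 or not 0 <= intra_r < 1:
        raise ValueError("correlations must lie in [0, 1)")
    if n_modules > 1 and inter_r > intra_r:
        raise ValueError("inter_r must not exceed intra_r")
    if n_nodes % n_modules != 0:
        raise ValueError("n_nodes must be divisible by n_modules")
    module = np.repeat(np.arange(n_modules), n_nodes // n_modules)
    C = np.where(module[:, None] == module[None, :], intra_r, inter_r)
    np.fill_diagonal(C, 1.0)
    lam = np.linalg.eigvalsh(C)
    if lam[0] < -1e-10:
        lam_c, V = np.linalg.eigh(C)
        C = V @ np.diag(np.maximum(lam_c, 0.0)) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        C = (C + C.T) / 2
        if np.linalg.eigvalsh(C)[0] < -1e-8:
            raise ValueError(
                f"block parameters (intra={intra_r}, inter={inter_r}) are not "
                "repairable to a positive-semidefinite correlation matrix"
            )
    return C


def _module_assignment(config: CohortConfig) -> np.ndarray:
    return np.repeat(np.arange(config.n_modules), config.n_nodes // config.n_modules)


def make_truth(config: CohortConfig) -> SyntheticTruth:
    """Derive the planted ground truth implied by a configuration."""
    cov_b = plant_block_covariance(
        config.n_nodes, config.n_modules, config.intra_module_r, config.inter_module_r
    )
    cov_a = plant_block_covariance(
        config.n_nodes,
        config.n_modules,
        config.intra_module_r - config.topology_gap,
        config.inter_module_r,
    )
    module = _module_assignment(config)
    # clinical nodes spread evenly across the node range (hence modules)
    nodes = tuple(
        int(i) for i in np.linspace(0, config.n_nodes, config.n_clinical_nodes, endpoint=False)
    )
    weights = np.zeros(config.n_nodes)
    weights[list(nodes)] = config.clinical_beta
    return SyntheticTruth(
        target_covariance_a=cov_a,
        target_covariance_b=cov_b,
        planted_clinical_weights=weights,
        clinical_nodes=nodes,
        module_of_node=module,
        seed=config.seed,
    )


def _coloring_matrix(cov: np.ndarray) -> np.ndarray:
    lam, V = np.linalg.eigh(cov)
    return V @ np.diag(np.sqrt(np.maximum(lam, 0.0))) @ V.T


def generate_timeseries(
    truth: SyntheticTruth,
    n_subjects_a: int,
    n_subjects_b: int,
    n_timepoints: int,
    tr_seconds: float = 2.0,
    ar1_phi: float = 0.0,
    seed: int = 0,
) -> RoiTimeSeriesPanel:
    """Gaussian ROI series colored by each group's target covariance.

    White (or, with ``ar1_phi``, AR(1)-autocorrelated) noise is multiplied
    by the symmetric matrix square root of the group covariance, so the
    empirical inter-node correlation converges to the target as timepoints
    grow; the flat spectrum of white noise means every wavelet scale
    inherits the full correlation structure.
    """
    rng = np.random.default_rng(seed)
    n_nodes = truth.target_covariance_a.shape[0]
    roots = {
        "A": _coloring_matrix(truth.target_covariance_a),
        "B": _coloring_matrix(truth.target_covariance_b),
    }
    ids, mats = [], []
    for grp, n_subj in (("A", n_subjects_a), ("B", n_subjects_b)):
        for s in range(n_subj):
            z = rng.standard_normal((n_timepoints, n_nodes))
            if ar1_phi != 0.0:
                for t in range(1, n_timepoints):
                    z[t] += ar1_phi * z[t - 1]
                z *= np.sqrt(1 - ar1_phi**2)
            ids.append(f"sub-{grp}{s + 1:02d}")
            mats.append(z @ roots[grp].T)
    return RoiTimeSeriesPanel(
        subject_ids=tuple(ids),
        data=tuple(mats),
        node_ids=tuple(f"n{i:03d}" for i in range(n_nodes)),
        tr_seconds=tr_seconds,
    )


def generate_gm_patches(
    truth: SyntheticTruth,
    subject_ids: tuple[str, ...],
    cube_edge: int = 3,
    noise_sd: float = 0.25,
    node_jitter_sd: float = 0.10,
    zero_variance_fraction: float = 0.0,
    seed: int = 0,
) -> GmPatchSet:
    """Gray-matter cubes: module archetype + node pattern + subject noise.

    Nodes in one module share an archetype, so their rotation-maximized
    similarity is high; nodes of different modules are near-independent.
    The last ``round(fraction * n_nodes)`` nodes of each subject are
    replaced by flat cubes (zero variance) to exercise the exclusion rule.
    Values are clipped at 0 (GM concentrations are non-negative).
    """
    rng = np.random.default_rng(seed)
    n_nodes = len(truth.module_of_node)
    n_modules = int(truth.module_of_node.max()) + 1
    e = cube_edge
    archetypes = rng.uniform(0.2, 0.8, size=(n_modules, e, e, e))
    node_jitter = node_jitter_sd * rng.standard_normal((n_nodes, e, e, e))
    base = archetypes[truth.module_of_node] + node_jitter
    n_flat = int(round(zero_variance_fraction * n_nodes))
    patches = np.empty((len(subject_ids), n_nodes, e, e, e))
    for s in range(len(subject_ids)):
        patches[s] = np.clip(base + noise_sd * rng.standard_normal(base.shape), 0.0, None)
        if n_flat:
            patches[s, n_nodes - n_flat :] = 0.4  # flat cube: zero variance
    return GmPatchSet(
        subject_ids=tuple(subject_ids),
        node_ids=tuple(f"n{i:03d}" for i in range(n_nodes)),
        patches=patches,
        cube_edge=e,
    )


def generate_clinical(
    truth: SyntheticTruth,
    nodal_efficiency_per_subject: np.ndarray,
    subject_ids: tuple[str, ...],
    noise_sd: float = 0.5,
    relative_noise: bool = True,
    seed: int = 0,
    beta: np.ndarray | None = None,
) -> pd.DataFrame:
    """Clinical scores as planted linear functions of nodal efficiency.

    ``score = scale_score * sum_i beta_i e_i + eps``, with ``eps ~ N(0, sd)``
    (no intercept, so a one-hot weight vector at zero noise returns that
    node's efficiency verbatim).  With ``relative_noise`` the sd is
    ``noise_sd * std(linear predictor)``, so the default 0.5 plants a
    population R² of 1/(1 + 0.5²) = 0.8; ``noise_sd = 0`` gives exactly
    linear (noiseless) scores.  Tremor, UPDRS and duration use fixed
    multiples of the same weight vector (duration with flipped sign).
    """
    rng = np.random.default_rng(seed)
    E = np.atleast_2d(np.asarray(nodal_efficiency_per_subject, float))
    w = truth.planted_clinical_weights if beta is None else np.asarray(beta, float)
    lin = E @ w
    sd_signal = lin.std()
    sd = noise_sd * sd_signal if relative_noise and sd_signal > 0 else noise_sd
    out = {"subject_id": list(subject_ids)}
    for score, scale in _CLINICAL_SCALES.items():
        out[score] = scale * lin + sd * abs(scale) * rng.standard_normal(len(lin))
    return pd.DataFrame(out)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Full cohort: time series, GM patches, demographics, planted truth.

    Clinical columns are left NaN: the planted scores are functions of
    *measured* nodal efficiency, so the pipeline fills them after the
    graph-metrics stage (`generate_clinical`).
    """
    truth = make_truth(config)
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    panel = generate_timeseries(
        truth,
        config.n_group_a,
        config.n_group_b,
        config.n_timepoints,
        config.tr_seconds,
        config.ar1_phi,
        seed=int(seeds[0]),
    )
    patches = generate_gm_patches(
        truth,
        panel.subject_ids,
        config.cube_edge,
        zero_variance_fraction=config.zero_variance_fraction,
        seed=int(seeds[1]),
    )
    demo_rng = np.random.default_rng(int(seeds[2]))
    n = panel.n_subjects
    table = pd.DataFrame(
        {
            "subject_id": list(panel.subject_ids),
            "group": ["A"] * config.n_group_a + ["B"] * config.n_group_b,
            "age": np.clip(demo_rng.normal(60.0, 10.0, n).round(1), 37.0, 81.0),
            "gender": demo_rng.integers(0, 2, n),  # independent of group
            "tremor": np.nan,
            "updrs": np.nan,
            "duration": np.nan,
        }
    )
    return Cohort(config=config, truth=truth, panel=panel, patches=patches, table=table)


def assemble_gm_volume(
    patches: np.ndarray, spacing: int = 2, voxel_mm: float = 3.0
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Lay one subject's node cubes out on a 3-D grid inside one volume.

    Returns ``(volume, node_table, affine)`` suitable for the real
    patch-extraction path (`morpho_similarity.extract_patches`): cube k
    sits at grid position (i, j, l) with ``spacing`` empty voxels between
    cubes, and the node table holds world-mm centroids under the scaled
    affine.
    """
    n_nodes, e = patches.shape[0], patches.shape[1]
    side = int(np.ceil(n_nodes ** (1 / 3)))
    pitch = e + spacing
    vol = np.zeros((side * pitch + spacing,) * 3)
    rows = []
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    for k in range(n_nodes):
        i, rem = divmod(k, side * side)
        j, l = divmod(rem, side)
        o = np.array([i, j, l]) * pitch + spacing
        vol[o[0] : o[0] + e, o[1] : o[1] + e, o[2] : o[2] + e] = patches[k]
        center = o + e // 2
        rows.append(
            {
                "node_id": f"n{k:03d}",
                "x": center[0] * voxel_mm,
                "y": center[1] * voxel_mm,
                "z": center[2] * voxel_mm,
                "label": f"node {k}",
            }
        )
    return vol, pd.DataFrame(rows), affine


def write_cohort(cohort: Cohort, directory: str | Path, nifti: bool = False) -> Path:
    """Serialize a cohort: per-subject series TSVs, cohort table TSV,
    patch container (.npz), truth JSON; optionally tiny NIfTI GM volumes
    plus a node-centroid TSV.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_panel_tsv(cohort.panel, directory / "timeseries")
    cohort.table.to_csv(directory / "cohort.tsv", sep="\t", index=False)
    np.savez_compressed(
        directory / "gm_patches.npz",
        patches=cohort.patches.patches,
        subject_ids=np.array(cohort.patches.subject_ids),
        node_ids=np.array(cohort.patches.node_ids),
        cube_edge=cohort.patches.cube_edge,
    )
    truth = {
        "seed": cohort.truth.seed,
        "clinical_nodes": list(cohort.truth.clinical_nodes),
        "planted_clinical_weights": cohort.truth.planted_clinical_weights.tolist(),
        "module_of_node": cohort.truth.module_of_node.tolist(),
        "config": asdict(cohort.config),
    }
    (directory / "truth.json").write_text(json.dumps(truth, indent=1))
    if nifti:
        import nibabel as nib

        nifti_dir = directory / "nifti"
        nifti_dir.mkdir(exist_ok=True)
        for s, sid in enumerate(cohort.patches.subject_ids):
            vol, node_table, affine = assemble_gm_volume(cohort.patches.patches[s])
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), nifti_dir / f"{sid}_gm.nii")
            if s == 0:
                node_table.to_csv(directory / "node_centroids.tsv", sep="\t", index=False)
    return directory
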