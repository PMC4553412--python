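import numpy as np
import pandas as pd
import pytest

import tremornet as tn
from tremornet.synthetic_cohort import make_truth


class TestBlockCovariance:
    def test_independence_case_is_identity(self):
        C = tn.plant_block_covariance(4, 2, 0.0, 0.0)
        assert np.array_equal(C, np.eye(4))

    def test_single_block_fills_off_diagonals(self):
        C = tn.plant_block_covariance(4, 1, 0.6, 0.0)
        expected = np.full((4, 4), 0.6)
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(C, expected)

    def test_study_scale_matrix_is_psd(self):
        C = tn.plant_block_covariance(264, 8, 0.5, 0.1)
        assert np.linalg.eigvalsh(C)[0] >= -1e-10
        assert np.allclose(np.diag(C), 1.0)

    @pytest.mark.parametrize("intra,inter", [(0.5, 0.6), (1.2, 0.1), (-0.1, 0.0)])
    def test_invalid_parameters_rejected(self, intra, inter):
        with pytest.raises(ValueError):
            tn.plant_block_covariance(8, 2, intra, inter)


class TestTimeseries:
    def test_identity_covariance_gives_near_zero_correlations(self):
        cfg = tn.CohortConfig(
            n_group_a=1, n_group_b=0, n_nodes=8, n_modules=8,
            intra_module_r=0.01, inter_module_r=0.0, topology_gap=0.0,
            n_timepoints=5000, n_clinical_nodes=1, clinical_beta=(1.0,),
        )
        truth = make_truth(cfg)
        # overwrite with exact identity for the independence check
        truth = tn.SyntheticTruth(
            target_covariance_a=np.eye(8), target_covariance_b=np.eye(8),
            planted_clinical_weights=truth.planted_clinical_weights,
            clinical_nodes=truth.clinical_nodes,
            module_of_node=truth.module_of_node, seed=0,
        )
        panel = tn.generate_timeseries(truth, 1, 0, 5000, seed=1)
        r = np.corrcoef(panel.data[0], rowvar=False)
        off = np.abs(r[np.triu_indices(8, 1)])
        assert off.mean() < 0.1

    def test_planted_block_correlation_recovered(self):
        cfg = tn.CohortConfig(
            n_group_a=0, n_group_b=1, n_nodes=8, n_modules=2,
            intra_module_r=0.6, inter_module_r=0.0, topology_gap=0.0,
            n_timepoints=5000, n_clinical_nodes=2, clinical_beta=(1.0, -1.0),
        )
        truth = make_truth(cfg)
        panel = tn.generate_timeseries(truth, 0, 1, 5000, seed=3)
        r = np.corrcoef(panel.data[0], rowvar=False)
        within = r[np.ix_(range(4), range(4))][np.triu_indices(4, 1)]
        assert np.all(np.abs(within - 0.6) < 0.05)

    def test_same_seed_is_bit_identical(self):
        cfg = tn.CohortConfig(n_group_a=2, n_group_b=2, n_nodes=16, n_modules=4,
                              n_timepoints=50, seed=9)
        a = tn.generate_cohort(cfg)
        b = tn.generate_cohort(cfg)
        for ma, mb in zip(a.panel.data, b.panel.data):
            assert np.array_equal(ma, mb)
        assert np.array_equal(a.patches.patches, b.patches.patches)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestGmPatches:
    def test_shared_archetype_without_noise_gives_unit_similarity(self):
        cfg = tn.CohortConfig(n_group_a=1, n_group_b=1, n_nodes=8, n_modules=2,
                              n_timepoints=50)
        truth = make_truth(cfg)
        ps = tn.generate_gm_patches(
            truth, ("s1",), cube_edge=3, noise_sd=0.0, node_jitter_sd=0.0, seed=0
        )
        # nodes 0 and 1 share module 0's archetype exactly
        sim = tn.cube_similarity(ps.patches[0, 0], ps.patches[0, 1])
        assert sim == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_count_is_exact(self):
        cfg = tn.CohortConfig(n_group_a=1, n_group_b=0, n_nodes=100, n_modules=4,
                              n_timepoints=50)
        truth = make_truth(cfg)
        ps = tn.generate_gm_patches(truth, ("s1",), zero_variance_fraction=0.01, seed=0)
        _, report = tn.build_morpho_network(ps)
        assert len(report.excluded["s1"]) == round(0.01 * 100)
        assert report.global_fraction == pytest.approx(0.01)

    def test_independent_archetypes_low_mean_similarity(self, rng):
        # different modules, large noise: mean max-rotation similarity stays
        # well below the within-module value (max-statistic inflation keeps
        # it above zero; see the morphological-network tests)
        cfg = tn.CohortConfig(n_group_a=1, n_group_b=0, n_nodes=16, n_modules=16,
                              intra_module_r=0.2, inter_module_r=0.0,
                              n_timepoints=50)
        truth = make_truth(cfg)
        ps = tn.generate_gm_patches(truth, ("s1",), noise_sd=1.5, seed=1)
        sims = [
            tn.cube_similarity(ps.patches[0, i], ps.patches[0, j])
            for i in range(8) for j in range(i + 1, 8)
        ]
        assert np.mean(sims) < 0.55


class TestClinical:
    def _efficiencies(self, rng, n_subj, n_nodes):
        return rng.uniform(0.1, 0.5, size=(n_subj, n_nodes))

    def test_one_hot_noiseless_score_equals_nodal_efficiency(self, rng, small_cohort):
        E = self._efficiencies(rng, 5, 24)
        beta = np.zeros(24)
        beta[3] = 1.0
        clin = tn.generate_clinical(
            small_cohort.truth, E, tuple("abcde"), noise_sd=0.0, seed=0, beta=beta
        )
        assert np.allclose(clin["tremor"].to_numpy(), E[:, 3])

    def test_noiseless_fit_on_true_predictors_is_exact(self, rng, small_cohort):
        truth = small_cohort.truth
        E = self._efficiencies(rng, 10, 24)
        clin = tn.generate_clinical(truth, E, tuple(f"s{i}" for i in range(10)),
                                    noise_sd=0.0, seed=0)
        rep = tn.fit_mlrm(E[:, list(truth.clinical_nodes)], clin["tremor"].to_numpy())
        assert rep.r_squared == pytest.approx(1.0, abs=1e-10)
        planted = truth.planted_clinical_weights[list(truth.clinical_nodes)]
        assert np.allclose(rep.coefficients, planted, atol=1e-7)

    def test_relative_noise_targets_population_r2(self, rng, small_cohort):
        # sd = 0.5 * signal sd -> population R^2 = 0.8; recovered R^2 on the
        # true predictor set should concentrate in [0.6, 0.95] at n = 16
        truth = small_cohort.truth
        r2 = []
        for s in range(100):
            E = self._efficiencies(rng, 16, 24)
            clin = tn.generate_clinical(truth, E, tuple(f"s{i}" for i in range(16)),
                                        noise_sd=0.5, relative_noise=True, seed=s)
            rep = tn.fit_mlrm(E[:, list(truth.clinical_nodes)], clin["tremor"].to_numpy())
            r2.append(rep.r_squared)
        assert 0.6 <= np.median(r2) <= 0.95


def test_topology_gap_monotonically_widens_local_efficiency_difference():
    """A larger planted intra-module coupling gap must widen the expected
    group difference in AUC local efficiency (patients below controls)."""
    diffs = {0.05: [], 0.25: []}
    for gap in diffs:
        for seed in range(20):
            cfg = tn.CohortConfig(
                n_group_a=4, n_group_b=4, n_nodes=40, n_modules=4,
                n_timepoints=128, topology_gap=gap, seed=seed,
            )
            co = tn.generate_cohort(cfg)
            panel = tn.preprocess(co.panel, n_discard=3)
            mats = tn.wavelet_correlation(tn.modwt_decompose(panel, levels=2), 2)
            grid = tn.default_sparsity_grid(0.05, 0.35, 0.1)
            auc = [tn.efficiency_profile(m, grid).auc_e_loc for m in mats]
            diffs[gap].append(np.mean(auc[4:]) - np.mean(auc[:4]))  # B - A
    assert np.mean(diffs[0.25]) > np.mean(diffs[0.05]) > 0


def test_cohort_serialization_round_trip(tmp_path, small_cohort):
    out = tn.write_cohort(small_cohort, tmp_path / "cohort")
    assert (out / "cohort.tsv").exists()
    assert (out / "truth.json").exists()
    from tremornet.timeseries_prep import read_panel_tsv

    paths = sorted((out / "timeseries").glob("*.tsv"))
    panel = read_panel_tsv(paths, tr_seconds=2.0)
    assert panel.n_subjects == small_cohort.panel.n_subjects
    sid = panel.subject_ids[0]
    np.testing.assert_allclose(
        panel.matrix(sid), small_cohort.panel.matrix(sid), rtol=1e-9
    )


def test_nifti_materialization_exercises_extraction_path(tmp_path, small_cohort):
    import nibabel as nib

    vol, node_table, affine = tn.assemble_gm_volume(small_cohort.patches.patches[0])
    img = nib.Nifti1Image(vol.astype(np.float32), affine)
    extracted = tn.extract_patches(img, node_table, cube_edge=3)
    np.testing.assert_allclose(extracted, small_cohort.patches.patches[0], rtol=1e-6)
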