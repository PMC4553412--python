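"""End-to-end orchestration: synthesize -> prep -> networks -> metrics
-> group inference -> classification -> regression, from one config.

`RunConfig` consolidates every tunable (cohort design, wavelet settings,
sparsity grid, null-ensemble and permutation sizes, screening
thresholds) and derives one named seed per stochastic stage from the
master seed, so a rerun with the same config reproduces every output.
`run_pipeline` returns the in-memory `RunResult` and can additionally
write a run directory (TSV/JSON artifacts plus a human-readable
markdown report regenerable with `make_report`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .discriminant import ClassifierReport, loocv_classify, permutation_significance
from .graph_metrics import (
    EfficiencyProfile,
    default_sparsity_grid,
    efficiency_profile,
    is_small_world,
    profiles_to_frame,
)
from .group_inference import (
    partial_correlation,
    permutation_test,
    permutation_test_matrix,
    false_positive_correction,
)
from .morpho_similarity import build_morpho_network
from .regression_link import (
    RegressionReport,
    cross_modal_link,
    screened_regression,
)
from .synthetic_cohort import Cohort, CohortConfig, generate_clinical, generate_cohort, write_cohort
from .timeseries_prep import preprocess
from .wavelet_fc import modwt_decompose, wavelet_correlation

__all__ = ["RunConfig", "RunResult", "run_pipeline", "make_report"]

log = logging.getLogger("tremornet")

_STAGES = ("synth", "prep", "fc", "morph", "metrics", "stats", "classify", "regress")


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of one full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    # preprocessing
    n_discard: int = 5
    apply_bandpass: bool = True
    f_lo: float = 0.01
    f_hi: float = 0.1
    # wavelet
    wavelet_name: str = "sym4"
    wavelet_levels: int = 4
    wavelet_boundary: str = "periodic"
    analysis_scale: int = 2  # scale whose networks feed inference/MVPA
    # morphology
    include_reflections: bool = True
    # sparsity grid / nulls
    sparsity_lo: float = 0.02
    sparsity_hi: float = 0.40
    sparsity_step: float = 0.02
    n_null: int = 100
    null_sparsity_stride: int = 1
    small_world_tol: float = 0.1
    # inference / MVPA / regression
    n_perm_group: int = 10_000
    n_perm_select: int = 1000
    n_perm_mvpa: int = 100
    feature_p: float = 0.01
    screening_p: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.sparsity_lo < self.sparsity_hi < 1:
            raise ValueError("need 0 < sparsity_lo < sparsity_hi < 1")
        if self.sparsity_step <= 0:
            raise ValueError("sparsity_step must be positive")
        if not 1 <= self.analysis_scale <= self.wavelet_levels:
            raise ValueError("analysis_scale must lie within the decomposition levels")
        if min(self.n_null, self.n_perm_group, self.n_perm_select, self.n_perm_mvpa) < 1:
            raise ValueError("permutation/null counts must be >= 1")
        if not (0 < self.feature_p <= 1 and 0 < self.screening_p <= 1):
            raise ValueError("screening thresholds must lie in (0, 1]")
        if self.null_sparsity_stride < 1:
            raise ValueError("null_sparsity_stride must be >= 1")

    def sparsity_grid(self) -> np.ndarray:
        return default_sparsity_grid(self.sparsity_lo, self.sparsity_hi, self.sparsity_step)

    def stage_seeds(self) -> dict[str, int]:
        """One named, reproducible sub-seed per stochastic stage."""
        state = np.random.SeedSequence(self.seed).generate_state(len(_STAGES))
        return {name: int(s % (2**31 - 1)) for name, s in zip(_STAGES, state)}

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def reduced(cls, seed: int = 0, **overrides: Any) -> "RunConfig":
        """Desk-scale validation configuration.

        Keeps the full cohort design and sparsity grid but shrinks the
        stochastic ensembles (8 nulls at every 4th sparsity, 1000 group
        permutations, 300 screening permutations) so a complete run fits in
        a few minutes on one CPU.  Headline settings (10,000 permutations,
        100 nulls at every sparsity) remain the defaults of `RunConfig`.
        """
        kw: dict[str, Any] = dict(
            n_null=8,
            null_sparsity_stride=4,
            n_perm_group=1000,
            n_perm_select=300,
            n_perm_mvpa=100,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        cohort_kwargs = raw.pop("cohort", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"cohort"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(cohort=CohortConfig(**cohort_kwargs), **raw)


@dataclass
class RunResult:
    """Everything one pipeline run computed, in memory."""

    config: RunConfig
    cohort: Cohort
    profiles: dict[tuple[str, int | None], list[EfficiencyProfile]]
    small_world: pd.DataFrame
    global_stats: pd.DataFrame
    nodal_stats: pd.DataFrame
    clinical_correlation: dict[str, Any]
    classifier: ClassifierReport
    classifier_morpho: ClassifierReport | None
    regressions: dict[str, RegressionReport]
    cross_modal: dict[str, RegressionReport]
    manifest: dict[str, Any]


def _group_masks(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    g = table["group"].to_numpy()
    return g == "A", g == "B"


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute every stage in dependency order; optionally write a run dir."""
    t0 = time.time()
    seeds = config.stage_seeds()
    timings: dict[str, float] = {}

    def tick(stage: str) -> None:
        timings[stage] = round(time.time() - t0 - sum(timings.values()), 2)
        log.info("stage %-8s done in %.1fs", stage, timings[stage])

    # -- synth ------------------------------------------------------------
    cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["synth"])
    cohort = generate_cohort(cohort_cfg)
    tick("synth")

    # -- prep -------------------------------------------------------------
    panel = preprocess(
        cohort.panel,
        n_discard=config.n_discard,
        apply_bandpass=config.apply_bandpass,
        f_lo=config.f_lo,
        f_hi=config.f_hi,
    )
    tick("prep")

    # -- functional networks ----------------------------------------------
    scales = modwt_decompose(
        panel, config.wavelet_name, config.wavelet_levels, config.wavelet_boundary
    )
    fc = {j: wavelet_correlation(scales, j) for j in range(1, config.wavelet_levels + 1)}
    tick("fc")

    # -- morphological networks -------------------------------------------
    morpho, exclusion = build_morpho_network(cohort.patches, config.include_reflections)
    tick("morph")

    # -- metrics ----------------------------------------------------------
    grid = config.sparsity_grid()
    rng = np.random.default_rng(seeds["metrics"])
    profiles: dict[tuple[str, int | None], list[EfficiencyProfile]] = {}
    for j, mats in fc.items():
        with_null = j == config.analysis_scale
        profiles[("functional", j)] = [
            efficiency_profile(
                m,
                grid,
                n_null=config.n_null if with_null else 0,
                null_sparsity_stride=config.null_sparsity_stride,
                seed=int(rng.integers(2**31 - 1)),
            )
            for m in mats
        ]
    profiles[("morphological", None)] = [
        efficiency_profile(
            m,
            grid,
            n_null=config.n_null,
            null_sparsity_stride=config.null_sparsity_stride,
            seed=int(rng.integers(2**31 - 1)),
        )
        for m in morpho
    ]
    tick("metrics")

    # -- clinical scores (functions of measured nodal efficiency) ---------
    key = ("functional", config.analysis_scale)
    auc_nodal_loc = np.vstack([p.auc_nodal_loc for p in profiles[key]])
    auc_nodal_glob = np.vstack([p.auc_nodal_glob for p in profiles[key]])
    mask_a, mask_b = _group_masks(cohort.table)
    clin = generate_clinical(
        cohort.truth,
        auc_nodal_loc[mask_a],
        tuple(np.array(cohort.panel.subject_ids)[mask_a]),
        noise_sd=cohort_cfg.clinical_noise_sd,
        relative_noise=cohort_cfg.relative_clinical_noise,
        seed=seeds["synth"] + 1,
    )
    table = cohort.table.drop(columns=["tremor", "updrs", "duration"]).merge(
        clin, on="subject_id", how="left"
    )
    cohort = dataclasses.replace(cohort, table=table)

    # -- group inference ---------------------------------------------------
    covars = table[["age", "gender"]].to_numpy(float)
    group = mask_a.astype(int)
    stat_rows = []
    sw_rows = []
    for (modality, scale), profs in profiles.items():
        auc_g = np.array([p.auc_e_glob for p in profs])
        auc_l = np.array([p.auc_e_loc for p in profs])
        for metric, vals in (("auc_e_glob", auc_g), ("auc_e_loc", auc_l)):
            gc = permutation_test(
                vals[mask_a],
                vals[mask_b],
                covariates=np.vstack([covars[mask_a], covars[mask_b]]),
                n_perm=config.n_perm_group,
                seed=seeds["stats"],
                metric=f"{modality}/{scale}/{metric}",
            )
            stat_rows.append(
                {
                    "modality": modality,
                    "scale": scale,
                    "metric": metric,
                    "diff_a_minus_b": gc.observed_difference,
                    "t": gc.t_statistic,
                    "p": gc.p_value,
                    "direction": gc.direction,
                }
            )
        norm = np.array([p.mean_normalized() for p in profs])  # (n_subj, 2): glob, loc
        if np.isfinite(norm).any():
            for gname, mask in (("A", mask_a), ("B", mask_b)):
                med_g = float(np.nanmedian(norm[mask, 0]))
                med_l = float(np.nanmedian(norm[mask, 1]))
                sw_rows.append(
                    {
                        "modality": modality,
                        "scale": scale,
                        "group": gname,
                        "normalized_e_glob": med_g,
                        "normalized_e_loc": med_l,
                        "small_world": is_small_world(med_l, med_g, config.small_world_tol),
                    }
                )
    global_stats = pd.DataFrame(stat_rows)
    small_world = pd.DataFrame(sw_rows)

    # nodal maps at the analysis scale, 1/N-corrected
    nodal_rows = []
    for name, feats in (("nodal_loc", auc_nodal_loc), ("nodal_glob", auc_nodal_glob)):
        t, p, diff = permutation_test_matrix(
            feats, group, covars, n_perm=min(config.n_perm_group, 2000), seed=seeds["stats"] + 1
        )
        mask_sig = false_positive_correction(p, cohort.panel.n_nodes)
        for i, nid in enumerate(cohort.panel.node_ids):
            if mask_sig[i] or p[i] < 0.05:  # keep the interesting rows only
                nodal_rows.append(
                    {
                        "metric": name,
                        "node_id": nid,
                        "t": t[i],
                        "p": p[i],
                        "diff_a_minus_b": diff[i],
                        "corrected_significant": bool(mask_sig[i]),
                    }
                )
    nodal_stats = pd.DataFrame(
        nodal_rows,
        columns=["metric", "node_id", "t", "p", "diff_a_minus_b", "corrected_significant"],
    )

    # clinical association: tremor vs local-efficiency AUC in patients
    patients = table[mask_a]
    auc_l_scale = np.array([p.auc_e_loc for p in profiles[key]])[mask_a]
    clinical_correlation: dict[str, Any] = {
        "pair": "tremor ~ functional auc_e_loc (age/gender partialled)"
    }
    if int(mask_a.sum()) >= 6:  # partial correlation needs n >= k + 4
        pc = partial_correlation(
            auc_l_scale,
            patients["tremor"].to_numpy(float),
            patients[["age", "gender"]].to_numpy(float),
        )
        clinical_correlation.update(r=pc.r, p=pc.p_value, n=pc.n)
    else:
        log.warning("too few patients for the clinical partial correlation")
        clinical_correlation.update(r=float("nan"), p=float("nan"), n=int(mask_a.sum()))
    tick("stats")

    # -- MVPA ---------------------------------------------------------------
    report = loocv_classify(
        auc_nodal_loc,
        group,
        p_thresh=config.feature_p,
        n_perm_select=config.n_perm_select,
        seed=seeds["classify"],
    )
    report = permutation_significance(
        auc_nodal_loc,
        group,
        n_perm=config.n_perm_mvpa,
        p_thresh=config.feature_p,
        n_perm_select=config.n_perm_select,
        seed=seeds["classify"] + 1,
        report=report,
    )
    morpho_profiles = profiles[("morphological", None)]
    morpho_nodal_loc = np.vstack([p.auc_nodal_loc for p in morpho_profiles])
    classifier_morpho = loocv_classify(
        morpho_nodal_loc,
        group,
        p_thresh=config.feature_p,
        n_perm_select=config.n_perm_select,
        seed=seeds["classify"] + 2,
    )
    tick("classify")

    # -- regressions ---------------------------------------------------------
    node_ids = tuple(cohort.panel.node_ids)
    regressions = {}
    for score in ("tremor", "updrs", "duration"):
        regressions[score] = screened_regression(
            auc_nodal_loc[mask_a],
            patients[score].to_numpy(float),
            p_thresh=config.screening_p,
            predictor_ids=node_ids,
            response_name=score,
        )
    f_summary = np.array([p.auc_e_loc for p in profiles[key]])
    m_summary = np.array([p.auc_e_loc for p in morpho_profiles])
    cross_modal = {
        "morpho_to_functional": cross_modal_link(
            f_summary, morpho_nodal_loc, "morpho_to_functional", config.screening_p, node_ids=node_ids
        ),
        "functional_to_morpho": cross_modal_link(
            f_summary,
            morpho_nodal_loc,
            "functional_to_morpho",
            config.screening_p,
            functional_nodal=auc_nodal_loc,
            morpho_summary=m_summary,
            node_ids=node_ids,
        ),
    }
    tick("regress")

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "n_subjects": cohort.panel.n_subjects,
        "n_nodes": cohort.panel.n_nodes,
        "exclusion_fraction": exclusion.global_fraction,
        "version": __import__("tremornet").__version__,
    }
    # wall times are logged separately: the manifest itself stays
    # byte-reproducible across reruns of an identical config
    log.info("stage wall times: %s", timings)
    result = RunResult(
        config=config,
        cohort=cohort,
        profiles=profiles,
        small_world=small_world,
        global_stats=global_stats,
        nodal_stats=nodal_stats,
        clinical_correlation=clinical_correlation,
        classifier=report,
        classifier_morpho=classifier_morpho,
        regressions=regressions,
        cross_modal=cross_modal,
        manifest=manifest,
    )
    if out_dir is not None:
        write_run_dir(result, out_dir)
    return result


def _report_dict(result: RunResult) -> dict[str, Any]:
    def reg(r: RegressionReport) -> dict[str, Any]:
        return {
            "response": r.response,
            "predictors": list(r.predictor_ids),
            "coefficients": r.coefficients.tolist(),
            "r_squared": r.r_squared,
            "f_pvalue": r.f_pvalue,
            "n": r.n,
            "no_model": r.no_model,
        }

    c = result.classifier
    return {
        "manifest": result.manifest,
        "small_world": result.small_world.to_dict(orient="records"),
        "global_stats": result.global_stats.to_dict(orient="records"),
        "nodal_stats": result.nodal_stats.to_dict(orient="records"),
        "clinical_correlation": result.clinical_correlation,
        "classifier": {
            "features": "functional nodal local-efficiency AUC",
            "accuracy": c.accuracy,
            "sensitivity": c.sensitivity,
            "specificity": c.specificity,
            "z_score": c.z_score,
            "null_accuracies": None
            if c.null_accuracies is None
            else c.null_accuracies.tolist(),
        },
        "classifier_morpho": None
        if result.classifier_morpho is None
        else {
            "features": "morphological nodal local-efficiency AUC",
            "accuracy": result.classifier_morpho.accuracy,
            "sensitivity": result.classifier_morpho.sensitivity,
            "specificity": result.classifier_morpho.specificity,
        },
        "regressions": {k: reg(v) for k, v in result.regressions.items()},
        "cross_modal": {k: reg(v) for k, v in result.cross_modal.items()},
        "truth": {
            "clinical_nodes": list(result.cohort.truth.clinical_nodes),
            "planted_clinical_weights": [
                float(result.cohort.truth.planted_clinical_weights[i])
                for i in result.cohort.truth.clinical_nodes
            ],
            "topology_gap": result.config.cohort.topology_gap,
        },
    }


def write_run_dir(result: RunResult, out_dir: str | Path) -> Path:
    """Persist cohort, metric tables, stats and the consolidated report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(result.cohort, out / "cohort")
    all_profiles = [p for profs in result.profiles.values() for p in profs]
    profiles_to_frame(all_profiles).to_csv(out / "efficiency_curves.tsv", sep="\t", index=False)
    auc_rows = [
        {
            "subject_id": p.subject_id,
            "modality": p.modality,
            "scale": p.scale,
            "auc_e_glob": p.auc_e_glob,
            "auc_e_loc": p.auc_e_loc,
        }
        for p in all_profiles
    ]
    pd.DataFrame(auc_rows).to_csv(out / "auc_summary.tsv", sep="\t", index=False)
    result.global_stats.to_csv(out / "group_stats.tsv", sep="\t", index=False)
    result.nodal_stats.to_csv(out / "nodal_stats.tsv", sep="\t", index=False)
    result.small_world.to_csv(out / "small_world.tsv", sep="\t", index=False)
    (out / "results.json").write_text(json.dumps(_report_dict(result), indent=1, default=float))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1, default=str))
    (out / "report.md").write_text(render_report(_report_dict(result)))
    return out


def render_report(rd: dict[str, Any]) -> str:
    """Markdown summary of one run's results (truth comparison included)."""
    lines = ["# tremornet run report", ""]
    man = rd.get("manifest", {})
    lines += [
        f"- config hash: `{man.get('config_hash', 'absent')}`",
        f"- subjects: {man.get('n_subjects', '?')}, nodes: {man.get('n_nodes', '?')}",
        "",
    ]
    if rd.get("small_world"):
        lines += ["## Small-world flags", "",
                  "| modality | scale | group | norm E_glob | norm E_loc | small-world |",
                  "|---|---|---|---|---|---|"]
        for r in rd["small_world"]:
            lines.append(
                f"| {r['modality']} | {r['scale']} | {r['group']} | "
                f"{r['normalized_e_glob']:.3f} | {r['normalized_e_loc']:.3f} | {r['small_world']} |"
            )
        lines.append("")
    else:
        lines += ["## Small-world flags", "", "_absent_", ""]
    if rd.get("global_stats"):
        lines += ["## Group differences (covariate-adjusted permutation)", "",
                  "| modality | scale | metric | diff (A-B) | p |", "|---|---|---|---|---|"]
        for r in rd["global_stats"]:
            lines.append(
                f"| {r['modality']} | {r['scale']} | {r['metric']} | "
                f"{r['diff_a_minus_b']:.4g} | {r['p']:.4g} |"
            )
        lines.append("")
    if rd.get("clinical_correlation"):
        cc = rd["clinical_correlation"]
        lines += ["## Clinical partial correlation", "",
                  f"{cc['pair']}: r = {cc['r']:.3f}, p = {cc['p']:.3g} (n = {cc['n']})", ""]
    if rd.get("classifier"):
        c = rd["classifier"]
        z = c.get("z_score")
        lines += ["## Classification (screened MLDA, LOOCV)", "",
                  f"- {c['features']}: accuracy {c['accuracy']:.2f}, "
                  f"sensitivity {c['sensitivity']:.2f}, specificity {c['specificity']:.2f}"
                  + (f", z = {z:.2f}" if z is not None else "")]
        if rd.get("classifier_morpho"):
            m = rd["classifier_morpho"]
            lines.append(
                f"- {m['features']}: accuracy {m['accuracy']:.2f}, "
                f"sensitivity {m['sensitivity']:.2f}, specificity {m['specificity']:.2f}"
            )
        lines.append("")
    else:
        lines += ["## Classification", "", "_absent_", ""]
    if rd.get("regressions"):
        lines += ["## Clinical regressions (screened MLRM)", ""]
        for name, r in rd["regressions"].items():
            if r["no_model"]:
                lines.append(f"- {name}: no predictor survived screening")
            else:
                lines.append(
                    f"- {name}: R^2 = {r['r_squared']:.3f}, F p = {r['f_pvalue']:.3g}, "
                    f"{len(r['predictors'])} predictor(s)"
                )
        lines.append("")
    if rd.get("cross_modal"):
        lines += ["## Cross-modal association", ""]
        for name, r in rd["cross_modal"].items():
            lines.append(
                f"- {name}: R^2 = {r['r_squared']:.3f} "
                f"({len(r['predictors'])} screened predictor(s))"
            )
        lines.append("")
    if rd.get("truth"):
        t = rd["truth"]
        lines += ["## Planted truth vs. detection", "",
                  f"- planted intra-module coupling gap: {t['topology_gap']}",
                  f"- clinical nodes (planted): {t['clinical_nodes']}",
                  f"- planted weights: {t['planted_clinical_weights']}"]
        regs = rd.get("regressions", {})
        if "tremor" in regs and not regs["tremor"]["no_model"]:
            lines.append(f"- tremor model predictors found: {regs['tremor']['predictors']}")
        lines.append("")
    return "\n".join(lines)


def make_report(run_dir: str | Path) -> str:
    """Regenerate the markdown report from a persisted run directory."""
    run_dir = Path(run_dir)
    results = run_dir / "results.json"
    if not results.exists():
        if not (run_dir / "manifest.json").exists():
            raise FileNotFoundError(f"no manifest.json in {run_dir}")
        rd: dict[str, Any] = {"manifest": json.loads((run_dir / "manifest.json").read_text())}
    else:
        rd = json.loads(results.read_text())
    text = render_report(rd)
    (run_dir / "report.md").write_text(text)
    return text
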