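"""End-to-end study replica: simulate -> deconvolute -> group -> diff ->
annotate -> quantify -> compose -> report.

All stage outputs land as files under the configured output directory
(feature lists, area tables, differential results, annotations,
concentrations, formulas as CSV; deconvolved spectra as MSP; the report as
JSON); raw scan data stays in memory unless ``write_mzml`` is set. A fixed
seed makes the whole run deterministic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import crb, differential, quantify, scorecard, sensory
from .gradients import HILIC, REFERENCE_GRADIENT, RPLC, default_gradients
from .simulate import (
    NEGATIVE,
    POSITIVE,
    AcquisitionConfig,
    export_library_and_standards,
    make_compound_panel,
    make_study_design,
    simulate_dia_acquisition,
    simulate_sensory_scores,
    variable_swath_windows,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One config drives the whole replica; thresholds default to the standard
    screening values (FC > 2, p < 0.05, ME < 10 ppm, DP > 0.4, RT <= 0.1 min)."""

    seed: int = 0
    outdir: str = "crbdia_out"
    # synthetic study
    n_compounds: int = 200
    coelution_fraction: float = 0.05
    group_sizes: dict = field(default_factory=lambda: {"T": 24, "N1": 5, "N2": 24, "N3": 4})
    modes: tuple = (POSITIVE, NEGATIVE)
    columns: tuple = (RPLC, HILIC)
    library_coverage: float = 0.7
    isomer_decoys: int = 5
    noise_sd: float = 1.0
    # deconvolution
    tol_ppm: float = 10.0
    min_gradients: int = 7
    rt_tol: float = 0.05
    min_behavior_corr: float = 0.99
    rt_window: float = 0.2
    # differential filter
    fc_min: float = 2.0
    p_max: float = 0.05
    # annotation
    me_max_ppm: float = 10.0
    dp_min: float = 0.4
    rt_max: float = 0.1
    frag_tol: float = 0.025
    # grouping
    iqr_k: float = 1.5
    n_subgroups: int = 3
    # stages
    run_quantification: bool = True
    write_mzml: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.modes = tuple(cfg.modes)
        cfg.columns = tuple(cfg.columns)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages on the four (mode x column) datasets; returns the
    report dict (also written to ``<outdir>/report.json``)."""
    t_start = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()}}

    # --- stage 1: simulate -------------------------------------------------
    stage = "simulate"
    try:
        compounds, pairs = make_compound_panel(
            config.n_compounds, config.seed, coelution_fraction=config.coelution_fraction
        )
        design, roles = make_study_design(
            compounds, config.seed + 1, group_sizes=dict(config.group_sizes)
        )
        gradients = {c: default_gradients(c) for c in config.columns}
        prec_mzs = np.array([c.precursor_mz(c.modes[0]) for c in compounds])
        acq = AcquisitionConfig(
            swath_windows=variable_swath_windows(prec_mzs), seed=config.seed + 2
        )
        bundle = simulate_dia_acquisition(
            design, compounds, gradients, acq,
            modes=config.modes, columns=config.columns,
            coeluting_pairs=pairs,
        )
        scores = simulate_sensory_scores(design, noise_sd=config.noise_sd, seed=config.seed + 3)
        rt_g5 = pd.DataFrame(
            {col: bundle.truth.rt[col][REFERENCE_GRADIENT] for col in config.columns}
        )
        library_specs, standards = export_library_and_standards(
            compounds, config.library_coverage, config.isomer_decoys, config.seed + 4,
            rt_g5=rt_g5,
            msp_path=out / "library.msp", standards_path=out / "standards.csv",
        )
        library = ann.records_from_matchms(library_specs)
        scores.to_csv(out / "sensory_scores.csv", index=False)
        design.concentrations.to_csv(out / "true_concentrations_ppm.csv")
        if config.write_mzml:
            from .runio import write_mzml

            mzml_dir = out / "mzml"
            mzml_dir.mkdir(exist_ok=True)
            for run in list(bundle.qc_runs.values()) + list(bundle.sample_runs.values()):
                write_mzml(run, mzml_dir / f"{run.run_id}.mzML")
    except Exception:
        log.exception("stage %s failed", stage)
        raise

    # --- stage 2: sensory grouping ----------------------------------------
    stage = "grouping"
    flagged = sensory.flag_outlier_scores(scores, k=config.iqr_k)
    profiles = sensory.sample_sensory_profile(flagged)
    tobacco_ids = design.group_members("T")
    assignment = sensory.classify_samples(
        profiles, tobacco_ids, n_subgroups=config.n_subgroups, seed=config.seed
    )
    groups = assignment.assignments
    flagged.to_csv(out / "sensory_scores_flagged.csv", index=False)
    profiles.to_csv(out / "sensory_profiles.csv")
    sensory.group_sensory_profile(profiles, groups).to_csv(out / "radar_profiles.csv")
    pd.concat([assignment.pc_scores, groups], axis=1).to_csv(out / "pca_groups.csv")
    ari = scorecard.adjusted_rand_index(groups, design.groups)
    report["grouping"] = {
        "flag_fraction": float(flagged["outlier_flag"].mean()),
        "explained_variance_pc12": float(assignment.explained_variance_ratio[:2].sum()),
        "ari_vs_design": ari,
    }

    n1 = list(groups.index[groups == "N1"])
    n2t = list(groups.index[groups.isin(["N2", "T"])])
    n3 = list(groups.index[groups == "N3"])

    # --- stages 3-6 per dataset -------------------------------------------
    datasets = bundle.datasets()
    per_dataset: dict[str, dict] = {}
    all_best_annotations: list[ann.AnnotationResult] = []
    feature_index: dict[str, crb.IonFeature] = {}
    area_tables: dict[tuple[str, str], pd.DataFrame] = {}
    matched_all: dict[str, str] = {}

    for mode, col in datasets:
        key = f"{mode}-{col}"
        stage = f"deconvolution[{key}]"
        qc = {g: r for (m, c, g), r in bundle.qc_runs.items() if (m, c) == (mode, col)}
        features = crb.deconvolve_dataset(
            qc, config.tol_ppm, config.min_gradients, config.rt_tol,
            config.min_behavior_corr,
        )
        for f in features:
            feature_index[f.feature_id] = f
        gradient_ids = sorted(qc)
        crb.features_to_frame(features, gradient_ids).to_csv(
            out / f"features_{key}.csv", index=False
        )
        _write_spectra_msp(features, out / f"spectra_{key}.msp", mode)

        stage = f"targeted[{key}]"
        sample_runs = {
            s: bundle.sample_runs.get((mode, col, s)) for s in design.sample_ids
        }
        areas = crb.targeted_peak_areas(
            sample_runs, features, config.tol_ppm, config.rt_window
        )
        area_tables[(mode, col)] = areas
        areas.to_csv(out / f"areas_{key}.csv")

        stage = f"differential[{key}]"
        res_n1 = differential.select_differential_features(
            areas, n1, n2t, config.fc_min, config.p_max, label_a="N1"
        ) if len(n1) >= 2 else []
        res_n2t = differential.select_differential_features(
            areas, n2t, n3, config.fc_min, config.p_max, label_a="N2&T"
        ) if len(n3) >= 2 else []
        frame_n1 = differential.results_to_frame(res_n1)
        frame_n2t = differential.results_to_frame(res_n2t)
        frame_n1.to_csv(out / f"diff_N1_vs_N2T_{key}.csv", index=False)
        frame_n2t.to_csv(out / f"diff_N2T_vs_N3_{key}.csv", index=False)
        selected_ids = set(frame_n1[frame_n1["selected"]]["feature_id"]) | set(
            frame_n2t[frame_n2t["selected"]]["feature_id"]
        )
        selected = [f for f in features if f.feature_id in selected_ids]

        qc_g5 = bundle.qc_runs[(mode, col, REFERENCE_GRADIENT)]
        if selected:
            times, aic, scatter = differential.build_aic(selected, qc_g5, config.tol_ppm)
            pd.DataFrame({"time_min": times, "intensity": aic}).to_csv(
                out / f"aic_{key}.csv", index=False
            )
            scatter.to_csv(out / f"feature_map_{key}.csv", index=False)

        stage = f"annotation[{key}]"
        std_rt = standards.set_index(["name", "column_mode"])["rt_g5"]
        best_per_feature = []
        for f in selected:
            cands = ann.annotate_level2(
                f, library, config.me_max_ppm, config.dp_min, config.frag_tol
            )
            if not cands:
                continue
            best = cands[0]
            rt_std = std_rt.get((best.name, col))
            best = ann.confirm_level1(
                best, f.rt_reference, None if rt_std is None else float(rt_std), config.rt_max
            )
            best_per_feature.append(best)
        all_best_annotations.extend(best_per_feature)
        if best_per_feature:
            ann.annotations_to_frame(best_per_feature).to_csv(
                out / f"annotations_{key}.csv", index=False
            )

        matched = scorecard.match_features_to_truth(
            features, bundle.truth, mode, col, config.tol_ppm
        )
        matched_all.update(matched)
        frag_score = scorecard.fragment_assignment_score(features, matched, bundle)
        per_dataset[key] = {
            "n_features": len(features),
            "n_diff_N1": int(frame_n1["selected"].sum()) if len(frame_n1) else 0,
            "n_diff_N2T": int(frame_n2t["selected"].sum()) if len(frame_n2t) else 0,
            "n_level2": len(best_per_feature),
            "n_level1": sum(a.level == 1 for a in best_per_feature),
            "n_isomer_flagged": sum(a.isomer_flag for a in best_per_feature),
            "fragment_precision": frag_score.precision,
            "fragment_recall": frag_score.recall,
        }
    report["datasets"] = per_dataset

    # --- stage 7: quantification ------------------------------------------
    if config.run_quantification:
        stage = "quantification"
        validated = [
            a for a in all_best_annotations if a.level == 1 and not a.isomer_flag
        ]
        conc_rows = {}
        if validated:
            qc_conc = design.concentrations.mean(axis=1)
            spike = qc_conc.clip(lower=1e-3)
            spiked_design = _spiked_design(design, {a.name: float(spike.get(a.name, 1.0)) for a in validated})
            spiked_bundle = simulate_dia_acquisition(
                spiked_design, compounds, gradients, acq,
                modes=config.modes, columns=config.columns, simulate_qc=False,
            )
            for a in validated:
                f = feature_index[a.feature_id]
                key = (f.mode, f.column_mode)
                unspiked_row = area_tables[key].loc[a.feature_id]
                spiked_runs = {
                    s: spiked_bundle.sample_runs.get((f.mode, f.column_mode, s))
                    for s in design.sample_ids
                }
                spiked_row = crb.targeted_peak_areas(
                    spiked_runs, [f], config.tol_ppm, config.rt_window
                ).loc[a.feature_id]
                est = quantify.quantify_table(
                    unspiked_row.to_frame().T.rename(index={a.feature_id: a.name}),
                    spiked_row.to_frame().T.rename(index={a.feature_id: a.name}),
                    pd.Series({a.name: float(spike.get(a.name, 1.0))}),
                )
                conc_rows[a.name] = est.loc[a.name]
        conc_table = pd.DataFrame(conc_rows).T
        if len(conc_table):
            conc_table.to_csv(out / "concentrations_ppm.csv")
            group_means = quantify.group_mean_concentrations(conc_table, groups)
            group_means.to_csv(out / "group_concentrations_ppm.csv")
            quant_err = scorecard.quantification_error(conc_table, design.concentrations)
        else:
            group_means = pd.DataFrame()
            quant_err = {"median_rel_error": float("nan"), "p90_rel_error": float("nan"), "n": 0}
        report["quantification"] = {
            "n_validated": len(conc_rows),
            **quant_err,
        }

        stage = "formulas"
        if len(conc_table) and "N1" in group_means.columns:
            entries = [
                (name, 1, float(group_means.loc[name, "N1"]))
                for name in conc_table.index
                if group_means.loc[name, "N1"] > 0
            ]
            if len(entries) >= 4:
                majors = [n for n, _l, _c in sorted(entries, key=lambda e: -e[2])[:3]]
                recipes = [
                    quantify.compose_formula(entries, "all_validated", name="Formula 1"),
                    quantify.compose_formula(entries, "majors", majors, name="Formula 2"),
                    quantify.compose_formula(entries, "minors", majors, name="Formula 3"),
                ]
                rows = [
                    (r.name, r.subset_rule, n, c)
                    for r in recipes for n, c in r.components
                ]
                pd.DataFrame(rows, columns=["formula", "rule", "compound", "ppm"]).to_csv(
                    out / "formulas.csv", index=False
                )
                report["formulas"] = {r.name: len(r.components) for r in recipes}

    # --- report ------------------------------------------------------------
    counts = scorecard.pool_study_counts(
        {k: v["n_diff_N1"] + v["n_diff_N2T"] for k, v in per_dataset.items()},
        {k: v["n_level2"] for k, v in per_dataset.items()},
        {k: v["n_level1"] for k, v in per_dataset.items()},
    )
    report["pooled_counts"] = counts
    report["elapsed_seconds"] = round(time.time() - t_start, 1)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def _spiked_design(design, spike: dict[str, float]):
    from .simulate import StudyDesign

    conc = design.concentrations.copy()
    for name, amount in spike.items():
        if name in conc.index:
            conc.loc[name] = conc.loc[name] + amount
    return StudyDesign(
        samples=list(design.samples), concentrations=conc, assessors=design.assessors,
        metric_ranges=dict(design.metric_ranges),
    )


def _write_spectra_msp(features, path, mode):
    from matchms import Spectrum

    from .runio import write_msp

    specs = []
    for f in features:
        if not f.ms2_spectrum:
            continue
        arr = np.array(f.ms2_spectrum, float)
        specs.append(
            Spectrum(
                mz=arr[:, 0], intensities=arr[:, 1],
                metadata={
                    "compound_name": f.feature_id,
                    "precursor_mz": round(f.mz, 6),
                    "ionmode": mode,
                    "retention_time": round(f.rt_reference, 4),
                },
            )
        )
    if specs:
        write_msp(specs, path)
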