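"""Scoring of pipeline outputs against generator ground truth.

Every quantity the synthetic study plants (precursors, fragment assignments,
group-enriched compounds, concentrations) can be recovered from the pipeline
output and compared; this module computes those precision/recall/error
numbers for reports and validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crb import IonFeature
from .gradients import REFERENCE_GRADIENT
from .simulate import DatasetBundle, GroundTruth


def match_features_to_truth(
    features: list[IonFeature],
    truth: GroundTruth,
    mode: str,
    column_mode: str,
    tol_ppm: float = 10.0,
    rt_tol: float = 0.1,
) -> dict[str, str]:
    """feature_id -> ground-truth compound name, by precursor m/z + G5 RT."""
    ref_rt = truth.rt[column_mode][REFERENCE_GRADIENT]
    matched: dict[str, str] = {}
    for f in features:
        best = None
        for name, (m, mz) in truth.precursor_mz.items():
            if m != mode:
                continue
            if abs(f.mz - mz) > mz * tol_ppm * 1e-6:
                continue
            rt = ref_rt.get(name, np.nan)
            if not np.isfinite(rt) or abs(f.rt_reference - rt) > rt_tol:
                continue
            d = abs(f.mz - mz) / mz + abs(f.rt_reference - rt)
            if best is None or d < best[0]:
                best = (d, name)
        if best is not None:
            matched[f.feature_id] = best[1]
    return matched


@dataclass
class FragmentScore:
    precision: float
    recall: float
    n_assigned: int
    n_true: int


def fragment_assignment_score(
    features: list[IonFeature],
    matched: dict[str, str],
    bundle: DatasetBundle,
    frag_tol: float = 0.025,
    detect_margin: float = 1.5,
) -> FragmentScore:
    """Precision/recall of CRB fragment assignment versus the planted truth.

    The recall denominator counts *recoverable* fragments only: template
    fragments whose QC apex intensity clears the peak-detection threshold
    with a margin (smoothing and intensity noise shave marginal apexes), and
    that lie inside the MS2 acquisition range.
    """
    cfg = bundle.config
    min_height = 1000.0
    qc_conc = bundle.design.concentrations.mean(axis=1)
    tp = fp = fn = 0
    n_assigned = 0
    for f in features:
        name = matched.get(f.feature_id)
        if name is None or f.ms2_spectrum is None:
            continue
        apex = cfg.response_factor * float(qc_conc[name])
        true_frags = [
            mz for mz, rel in bundle.truth.fragments[name]
            if rel * apex >= detect_margin * min_height
            and cfg.ms2_range[0] <= mz <= cfg.ms2_range[1]
        ]
        assigned = [mz for mz, _i in f.ms2_spectrum]
        n_assigned += len(assigned)
        hit = np.zeros(len(true_frags), bool)
        for amz in assigned:
            ds = [abs(amz - tmz) for tmz in true_frags]
            if ds and min(ds) <= frag_tol:
                hit[int(np.argmin(ds))] = True
                tp += 1
            else:
                fp += 1
        fn += int((~hit).sum())
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return FragmentScore(precision, recall, n_assigned, tp + fn)


def coelution_splitting_score(
    features: list[IonFeature],
    matched: dict[str, str],
    bundle: DatasetBundle,
    frag_tol: float = 0.025,
) -> dict[str, float]:
    """How cleanly planted G5 co-elution pairs are split.

    For every planted pair with both members recovered, count fragments of
    one member assigned to the other (cross-assignments). Returns the
    fraction of pairs with zero cross-assignments ("clean_fraction") — the
    quantity that collapses when all nine gradients are identical and
    retention behaviour carries no information beyond co-elution.
    """
    by_name = {name: fid for fid, name in matched.items()}
    feat = {f.feature_id: f for f in features}
    n_pairs = 0
    clean = 0
    crossed = 0
    for a, b in bundle.truth.coeluting_pairs:
        fa, fb = by_name.get(a), by_name.get(b)
        if fa is None or fb is None:
            continue
        n_pairs += 1
        cross = 0
        for fid, own, other in ((fa, a, b), (fb, b, a)):
            spec = feat[fid].ms2_spectrum or []
            own_frags = [mz for mz, _r in bundle.truth.fragments[own]]
            other_frags = [mz for mz, _r in bundle.truth.fragments[other]]
            for amz, _i in spec:
                d_other = min((abs(amz - m) for m in other_frags), default=np.inf)
                d_own = min((abs(amz - m) for m in own_frags), default=np.inf)
                if d_other <= frag_tol < d_own or (d_other <= frag_tol and d_other < d_own):
                    cross += 1
        crossed += cross
        if cross == 0:
            clean += 1
    return {
        "n_pairs_recovered": n_pairs,
        "clean_fraction": clean / n_pairs if n_pairs else float("nan"),
        "cross_assigned_fragments": crossed,
    }


def differential_recovery(
    results_frame: pd.DataFrame,
    matched: dict[str, str],
    planted_roles: pd.Series,
    contrast_role: str,
) -> dict[str, float]:
    """Sensitivity/precision of the differential filter versus planted roles.

    ``contrast_role`` is the generator's label for compounds enriched in the
    tested direction ("N1" or "N2T").
    """
    sel = results_frame[results_frame["selected"]]
    tested_names = {fid: matched.get(fid) for fid in results_frame["feature_id"]}
    truth_pos = {fid for fid, n in tested_names.items() if n is not None and planted_roles.get(n) == contrast_role}
    picked = set(sel["feature_id"])
    tp = len(picked & truth_pos)
    sens = tp / len(truth_pos) if truth_pos else float("nan")
    prec = tp / len(picked) if picked else float("nan")
    return {"sensitivity": sens, "precision": prec, "n_planted": len(truth_pos), "n_selected": len(picked)}


def quantification_error(
    estimated: pd.DataFrame, truth_ppm: pd.DataFrame
) -> dict[str, float]:
    """Median and 90th-percentile absolute relative error of recovered ppm."""
    errs = []
    for name in estimated.index:
        if name not in truth_ppm.index:
            continue
        for sid in estimated.columns:
            est = estimated.loc[name, sid]
            true = truth_ppm.loc[name, sid]
            if np.isfinite(est) and true > 0:
                errs.append(abs(est - true) / true)
    if not errs:
        return {"median_rel_error": float("nan"), "p90_rel_error": float("nan"), "n": 0}
    return {
        "median_rel_error": float(np.median(errs)),
        "p90_rel_error": float(np.quantile(errs, 0.9)),
        "n": len(errs),
    }


def adjusted_rand_index(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """ARI between two labelings over their shared samples."""
    from sklearn.metrics import adjusted_rand_score

    shared = labels_a.index.intersection(labels_b.index)
    return float(adjusted_rand_score(labels_a[shared], labels_b[shared]))


def pool_study_counts(
    differential_counts: dict[str, int],
    annotation_counts: dict[str, int],
    validated_counts: dict[str, int],
) -> dict[str, float]:
    """Pooled headline counts across contrasts, as reported in study summaries.

    Returns the total differential-feature count, total putative (level-2)
    annotation count, total standard-confirmed (level-1) count, and the
    validation rate = confirmed / putative as a percentage (1 decimal).
    """
    n_diff = sum(differential_counts.values())
    n_annot = sum(annotation_counts.values())
    n_valid = sum(validated_counts.values())
    rate = round(100.0 * n_valid / n_annot, 1) if n_annot else float("nan")
    return {
        "differential_total": n_diff,
        "annotated_total": n_annot,
        "validated_total": n_valid,
        "validation_rate_percent": rate,
    }
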