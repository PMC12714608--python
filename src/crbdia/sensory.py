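"""Sensory-panel screening, profiling, and PCA-based sample grouping.

Panel scores arrive in long format (sample_id, assessor_id, metric, score).
Outliers are screened per (sample, metric) cell across assessors with the
Tukey-fence IQR rule, per-sample profiles are assessor means, and samples are
grouped by PCA of the standardised profiles followed by k-means on the first
two principal components of the non-tobacco samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)

SCORE_COLUMNS = ["sample_id", "assessor_id", "metric", "score"]


def tukey_hinges(values: np.ndarray) -> tuple[float, float]:
    """Lower and upper hinge (Tukey's fourths) of ``values``.

    The data are split at the median; with an odd count the median joins both
    halves. Each hinge is the median of its half.
    """
    v = np.sort(np.asarray(values, float))
    n = len(v)
    half = (n + 1) // 2
    lower = v[:half]
    upper = v[n - half:]
    return float(np.median(lower)), float(np.median(upper))


def flag_outlier_scores(table: pd.DataFrame, k: float = 1.5) -> pd.DataFrame:
    """Annotate scores outside the Tukey fences with ``outlier_flag``.

    Within each (sample, metric) cell across assessors, scores outside
    [Q1 - k*IQR, Q3 + k*IQR] (hinge-based quartiles) are flagged. Cells with
    fewer than 4 scores are left unflagged (logged). Data are never deleted —
    the flag is an annotation column.
    """
    out = table.copy()
    out["outlier_flag"] = False
    for (sid, metric), idx in out.groupby(["sample_id", "metric"]).groups.items():
        scores = out.loc[idx, "score"].to_numpy(float)
        if len(scores) < 4:
            log.info("cell (%s, %s) has %d scores; outlier screen skipped", sid, metric, len(scores))
            continue
        q1, q3 = tukey_hinges(scores)
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        out.loc[idx, "outlier_flag"] = (scores < lo) | (scores > hi)
    return out


def sample_sensory_profile(
    table: pd.DataFrame, exclude_flagged: bool = True
) -> pd.DataFrame:
    """Per-sample mean score per metric (sample x metric).

    Flagged scores are excluded from the mean by default; if every score of a
    cell is flagged the cell is left missing (NaN).
    """
    t = table
    if exclude_flagged and "outlier_flag" in t.columns:
        t = t[~t["outlier_flag"]]
    return t.pivot_table(index="sample_id", columns="metric", values="score", aggfunc="mean")


def group_sensory_profile(profiles: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-group mean profile (radar-chart table); NaN cells are skipped."""
    return profiles.groupby(groups.reindex(profiles.index)).mean()


@dataclass
class GroupAssignment:
    """PCA + k-means grouping of samples by sensory profile."""

    assignments: pd.Series              # sample_id -> group label
    pc_scores: pd.DataFrame             # sample x PC
    loadings: pd.DataFrame              # metric x PC
    explained_variance_ratio: np.ndarray
    degenerate: bool = False


def classify_samples(
    profiles: pd.DataFrame,
    tobacco_ids: list[str],
    n_subgroups: int = 3,
    seed: int = 0,
    *,
    advantage_metrics: tuple[str, str] = ("astringency", "nasal_moistening"),
) -> GroupAssignment:
    """Group samples: tobacco keeps label T; natural samples get N1/N2/N3.

    Metrics are centred and unit-scaled, decomposed by PCA (SVD), and the
    natural samples are partitioned by k-means (50 restarts, fixed seed) on
    the first two PC scores. Labelling rule: the subgroup whose centroid is
    nearest the tobacco centroid is N2 ("closely aligned with tobacco"), the
    one with the highest mean astringency + nasal moistening is N1
    (advantageous sensory profile), the remainder N3 (and N4... for larger
    k, by descending advantage score).
    """
    profiles = profiles.sort_index()
    variances = profiles.var(axis=0, ddof=0)
    keep = variances > 0
    if not keep.any():
        # fully degenerate input: keep the (constant) metrics, centre only
        keep[:] = True
    elif not keep.all():
        dropped = list(profiles.columns[~keep])
        warnings.warn(f"zero-variance metrics dropped before scaling: {dropped}")
    x = profiles.loc[:, keep]
    if x.shape[1] < 2:
        raise ValueError("need at least 2 informative metrics")
    std = x.std(ddof=0).replace(0.0, 1.0)
    z = (x - x.mean()) / std
    pca = PCA(svd_solver="full", random_state=seed)
    with np.errstate(invalid="ignore", divide="ignore"):  # all-constant input
        scores = pca.fit_transform(z.to_numpy())
    pc_cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    pc_scores = pd.DataFrame(scores, index=profiles.index, columns=pc_cols)
    loadings = pd.DataFrame(pca.components_.T, index=x.columns, columns=pc_cols)

    natural = [s for s in profiles.index if s not in set(tobacco_ids)]
    if len(natural) < n_subgroups:
        raise ValueError("fewer natural samples than requested subgroups")
    nat_xy = pc_scores.loc[natural, pc_cols[: min(2, len(pc_cols))]].to_numpy()

    assignments = pd.Series("T", index=profiles.index, name="group")
    degenerate = False
    if np.allclose(nat_xy.std(axis=0), 0.0):
        log.error("all natural profiles identical: k-means degenerate, single subgroup returned")
        degenerate = True
        labels = np.zeros(len(natural), dtype=int)
        n_clusters = 1
    else:
        km = KMeans(n_clusters=n_subgroups, n_init=50, random_state=seed)
        labels = km.fit_predict(nat_xy)
        n_clusters = n_subgroups

    used_cols = pc_cols[: nat_xy.shape[1]]
    t_centroid = pc_scores.loc[list(tobacco_ids), used_cols].to_numpy().mean(axis=0)
    centroids = np.array([nat_xy[labels == c].mean(axis=0) for c in range(n_clusters)])
    dist_t = np.linalg.norm(centroids - t_centroid, axis=1)
    advantage = np.array([
        profiles.loc[np.array(natural)[labels == c], list(advantage_metrics)].to_numpy().mean()
        for c in range(n_clusters)
    ])

    names = {}
    order_remaining = set(range(n_clusters))
    n2 = int(np.argmin(dist_t))
    names[n2] = "N2"
    order_remaining.discard(n2)
    if order_remaining:
        n1 = max(order_remaining, key=lambda c: advantage[c])
        names[n1] = "N1"
        order_remaining.discard(n1)
    for j, c in enumerate(sorted(order_remaining, key=lambda c: -advantage[c]), start=3):
        names[c] = f"N{j}"
    for sid, lab in zip(natural, labels):
        assignments[sid] = names[lab]
    return GroupAssignment(
        assignments=assignments,
        pc_scores=pc_scores,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        degenerate=degenerate,
    )
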