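"""Abundant-ion-feature (AIF) selection between sensory groups.

A feature is *enriched* in group A versus group B when its mean peak area is
more than ``fc_min``-fold higher (strict) and Welch's unequal-variance t-test
gives p below ``p_max``. No multiple-testing correction is applied — the
selection is deliberately liberal, mirroring common practice for exploratory
untargeted screens; treat the selected set as candidates, not discoveries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crb import IonFeature
from .peaks import extract_xic
from .runio import Run

DEFAULT_FC_MIN = 2.0
DEFAULT_P_MAX = 0.05


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns ``(t, df, p)`` with the Satterthwaite degrees of freedom and the
    two-sided p-value. Degenerate convention: when both variances vanish, df
    is clamped to 1 and the statistic is 0 (p = 1) for equal means or
    +/- infinity (p = 0) for unequal means.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 values")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        if mx == my:
            return 0.0, 1.0, 1.0
        t = np.inf if mx > my else -np.inf
        return float(t), 1.0, 0.0
    t = (mx - my) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    df = max(df, 1.0)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass(frozen=True)
class DifferentialResult:
    """Per-feature contrast statistics with volcano coordinates."""

    feature_id: str
    fold_change: float          # mean_A / mean_B (epsilon-protected)
    p_value: float
    t_stat: float
    df: float
    enriched_in: str | None     # group A label when selected, else None
    selected: bool

    @property
    def log2_fc(self) -> float:
        return float(np.log2(self.fold_change))

    @property
    def neg_log10_p(self) -> float:
        with np.errstate(divide="ignore"):
            return float(-np.log10(self.p_value)) if self.p_value > 0 else np.inf


def select_differential_features(
    table: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    fc_min: float = DEFAULT_FC_MIN,
    p_max: float = DEFAULT_P_MAX,
    *,
    label_a: str = "A",
    log_transform: bool = False,
) -> list[DifferentialResult]:
    """Test every feature for enrichment in ``group_a`` over ``group_b``.

    ``table`` is features x samples (peak areas; NaN = missing run, excluded
    from the test; 0 = genuinely undetected, included). Zero group means are
    replaced by epsilon = half the smallest positive area in the table, which
    keeps fold changes finite without inventing an intensity scale. The t-test
    runs on raw areas by default; ``log_transform`` applies log1p first.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    positives = table.to_numpy()
    positives = positives[np.isfinite(positives) & (positives > 0)]
    eps = 0.5 * positives.min() if positives.size else 1.0

    results = []
    for fid, row in table.iterrows():
        xa = row[group_a].dropna().to_numpy(float)
        xb = row[group_b].dropna().to_numpy(float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"feature {fid}: group with fewer than 2 usable values")
        mean_a, mean_b = xa.mean(), xb.mean()
        fc = (mean_a if mean_a > 0 else eps) / (mean_b if mean_b > 0 else eps)
        tx, ty = (np.log1p(xa), np.log1p(xb)) if log_transform else (xa, xb)
        t, df, p = welch_t_test(tx, ty)
        selected = fc > fc_min and p < p_max
        results.append(
            DifferentialResult(
                feature_id=str(fid),
                fold_change=float(fc),
                p_value=p,
                t_stat=t,
                df=df,
                enriched_in=label_a if selected else None,
                selected=selected,
            )
        )
    return results


def results_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "fold_change": [r.fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "t_stat": [r.t_stat for r in results],
            "df": [r.df for r in results],
            "log2_fc": [r.log2_fc for r in results],
            "neg_log10_p": [r.neg_log10_p for r in results],
            "enriched_in": [r.enriched_in for r in results],
            "selected": [r.selected for r in results],
        }
    )


def build_aic(
    features: list[IonFeature],
    qc_run: Run,
    tol_ppm: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Accumulated ion chromatogram: pointwise sum of the members' XICs.

    Returns ``(times, aic, scatter)`` where ``scatter`` is the (m/z, RT, apex
    intensity) table for feature-map plots; the apex intensity is the XIC
    maximum within +/- 0.2 min of the feature's reference RT.
    """
    times = qc_run.ms1.times
    aic = np.zeros(len(times))
    rows = []
    for f in features:
        xic = extract_xic(qc_run.ms1, f.mz, tol_ppm)
        aic += xic
        near = np.abs(times - f.rt_reference) <= 0.2
        apex = float(xic[near].max()) if near.any() else float(xic.max() if len(xic) else 0.0)
        rows.append((f.feature_id, f.mz, f.rt_reference, apex))
    scatter = pd.DataFrame(rows, columns=["feature_id", "mz", "rt", "apex_intensity"])
    return times, aic, scatter


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]
    unmatched_a: list[str]
    unmatched_b: list[str]

    @property
    def overlap(self) -> int:
        return len(self.pairs)


def match_feature_lists(
    list_a: list[IonFeature],
    list_b: list[IonFeature],
    tol_ppm: float = 10.0,
    rt_tol: float = 0.2,
) -> MatchResult:
    """Greedy nearest-m/z pairing of two feature lists (e.g. two deconvolution
    tools run on the same dataset); each feature is matched at most once."""
    cands = []
    for i, a in enumerate(list_a):
        for j, b in enumerate(list_b):
            dmz = abs(a.mz - b.mz)
            if dmz <= a.mz * tol_ppm * 1e-6 and abs(a.rt_reference - b.rt_reference) <= rt_tol:
                cands.append((dmz, i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _d, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((list_a[i].feature_id, list_b[j].feature_id))
    return MatchResult(
        pairs=pairs,
        unmatched_a=[f.feature_id for i, f in enumerate(list_a) if i not in used_a],
        unmatched_b=[f.feature_id for j, f in enumerate(list_b) if j not in used_b],
    )
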