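"""Cross-gradient precursor linking and retention-behaviour MS2 deconvolution.

The deconvolution principle: a QC pool is acquired under nine different LC
gradients, so every real analyte traces out a characteristic *retention
behaviour* — its vector of retention times across the gradient family. A DIA
fragment belongs to a precursor only if its retention behaviour follows the
precursor's: it must co-elute with the precursor in every gradient where both
are seen, and the two RT vectors must be strongly correlated. Co-elution under
a single gradient is easily coincidental; co-elution under nine independent
programs essentially is not, which is what separates this approach from
single-run peak-shape matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gradients import REFERENCE_GRADIENT
from .peaks import ChromPeak, detect_chrom_peaks, detect_peaks_in_series, extract_xic
from .runio import Run

log = logging.getLogger(__name__)

DEFAULT_MIN_GRADIENTS = 7
DEFAULT_RT_TOL = 0.05          # minutes, per-gradient co-elution gate
DEFAULT_MIN_BEHAVIOR_CORR = 0.99
DEFAULT_TOL_PPM = 10.0
MAX_FRAGMENT_EXCESS = 0.02     # Da above precursor m/z


@dataclass
class IonFeature:
    """A deconvolved precursor: m/z, retention behaviour, MS2 spectrum."""

    feature_id: str
    mode: str
    column_mode: str
    mz: float
    rt_vector: dict[str, float]              # gradient id -> RT (missing allowed)
    rt_reference: float                      # RT under the reference gradient
    support: int
    ms2_spectrum: list[tuple[float, float]] | None = None
    heights: dict[str, float] = field(default_factory=dict)
    areas: dict[str, float] = field(default_factory=dict)

    def rt_array(self, gradient_ids: list[str]) -> np.ndarray:
        return np.array([self.rt_vector.get(g, np.nan) for g in gradient_ids])


def link_precursors_across_gradients(
    per_gradient_peaks: dict[str, list[ChromPeak]],
    tol_ppm: float = DEFAULT_TOL_PPM,
    min_gradients: int = DEFAULT_MIN_GRADIENTS,
    *,
    reference: str = REFERENCE_GRADIENT,
    mode: str = "unknown",
    column_mode: str = "unknown",
    id_prefix: str = "F",
    require_reference: bool = True,
) -> list[IonFeature]:
    """Assemble per-gradient MS1 peaks into cross-gradient ion features.

    Peaks are clustered by m/z (gap > tol_ppm splits clusters). Within a
    cluster, isomers are resolved by within-gradient elution rank: when a
    gradient offers several peaks of the same m/z, the i-th earliest peak in
    every gradient is assigned to the i-th feature — elution *order* is far
    more stable across gradient programs than absolute RT, so rank-consistent
    assignment minimises the spread of gradient-normalised RT ranks. Features
    with support below ``min_gradients`` or (by default) without a detection
    under the reference gradient are rejected.
    """
    flat: list[tuple[float, str, ChromPeak]] = [
        (p.mz, gid, p) for gid, peaks in per_gradient_peaks.items() for p in peaks
    ]
    if not flat:
        return []
    flat.sort(key=lambda x: x[0])
    mzs = np.array([x[0] for x in flat])
    gaps = np.diff(mzs) > mzs[:-1] * tol_ppm * 1e-6
    bounds = np.concatenate(([0], np.flatnonzero(gaps) + 1, [len(mzs)]))

    features: list[IonFeature] = []
    counter = 0
    for s, e in zip(bounds[:-1], bounds[1:]):
        cluster = flat[s:e]
        by_gradient: dict[str, list[ChromPeak]] = {}
        for _mz, gid, p in cluster:
            by_gradient.setdefault(gid, []).append(p)
        for peaks in by_gradient.values():
            peaks.sort(key=lambda p: p.rt_apex)
        n_feats = max(len(v) for v in by_gradient.values())
        for rank in range(n_feats):
            members = {
                gid: peaks[rank] for gid, peaks in by_gradient.items() if len(peaks) > rank
            }
            support = len(members)
            if support < min_gradients:
                continue
            if require_reference and reference not in members:
                log.debug(
                    "cluster at m/z %.4f rank %d rejected: no %s detection",
                    cluster[0][0], rank, reference,
                )
                continue
            weights = np.array([p.height for p in members.values()])
            mz = float(np.average([p.mz for p in members.values()], weights=weights))
            ref_rt = members[reference].rt_apex if reference in members else float(
                np.median([p.rt_apex for p in members.values()])
            )
            counter += 1
            features.append(
                IonFeature(
                    feature_id=f"{id_prefix}{counter:05d}",
                    mode=mode,
                    column_mode=column_mode,
                    mz=mz,
                    rt_vector={gid: p.rt_apex for gid, p in members.items()},
                    rt_reference=float(ref_rt),
                    support=support,
                    heights={gid: p.height for gid, p in members.items()},
                    areas={gid: p.area for gid, p in members.items()},
                )
            )
    features.sort(key=lambda f: (f.mz, f.rt_reference))
    for i, f in enumerate(features, start=1):
        f.feature_id = f"{id_prefix}{i:05d}"
    return features


def behavior_correlation(
    rt_a: dict[str, float], rt_b: dict[str, float], min_spread: float = 0.0
) -> tuple[float, int]:
    """Pearson correlation of two RT vectors over their shared gradients.

    Returns ``(corr, n_shared)``; corr is NaN when either vector's retention
    spread does not exceed ``min_spread`` (minutes). A spread at or below the
    co-elution tolerance carries no behaviour information — the vector is
    jitter around a constant, which is exactly the situation when all
    gradients are identical — so correlating it would compare noise with
    noise.
    """
    shared = sorted(set(rt_a) & set(rt_b))
    n = len(shared)
    if n < 2:
        return float("nan"), n
    a = np.array([rt_a[g] for g in shared])
    b = np.array([rt_b[g] for g in shared])
    if a.std() <= max(min_spread, 1e-9) or b.std() <= max(min_spread, 1e-9):
        return float("nan"), n
    return float(np.corrcoef(a, b)[0, 1]), n


def crb_deconvolve_ms2(
    feature: IonFeature,
    fragment_features: list[IonFeature],
    rt_tol: float = DEFAULT_RT_TOL,
    min_behavior_corr: float = DEFAULT_MIN_BEHAVIOR_CORR,
    *,
    min_shared: int = 4,
    reference: str = REFERENCE_GRADIENT,
) -> IonFeature:
    """Assign fragment candidates to ``feature`` by retention behaviour.

    A candidate (a fragment ion linked across gradients within the feature's
    SWATH window) is assigned iff

    * its m/z does not exceed the precursor m/z + 0.02 Da,
    * it co-elutes with the precursor within ``rt_tol`` in *every* gradient
      where both are detected,
    * the Pearson correlation of the two RT vectors over their shared
      gradients (at least ``min_shared``) reaches ``min_behavior_corr``.

    When the correlation is undefined because the RT vectors are constant
    (nine copies of one gradient), the correlation gate is waived and only
    the co-elution gate applies — the method then degrades, by construction,
    to single-run co-elution grouping.

    Returns a copy of the feature with ``ms2_spectrum`` set (fragment
    intensities read under the reference gradient, sorted by m/z).
    """
    spectrum: list[tuple[float, float]] = []
    for frag in fragment_features:
        if frag.mz > feature.mz + MAX_FRAGMENT_EXCESS:
            continue
        shared = sorted(set(frag.rt_vector) & set(feature.rt_vector))
        if len(shared) < min_shared:
            log.debug(
                "fragment m/z %.4f for %s skipped: only %d shared gradients",
                frag.mz, feature.feature_id, len(shared),
            )
            continue
        dts = [abs(frag.rt_vector[g] - feature.rt_vector[g]) for g in shared]
        if max(dts) > rt_tol:
            continue
        corr, _n = behavior_correlation(frag.rt_vector, feature.rt_vector, min_spread=rt_tol)
        if not np.isnan(corr) and corr < min_behavior_corr:
            continue
        intensity = frag.heights.get(reference)
        if intensity is None:
            continue
        spectrum.append((frag.mz, float(intensity)))
    spectrum.sort()
    return replace(feature, ms2_spectrum=spectrum)


def deconvolve_dataset(
    qc_runs: dict[str, Run],
    tol_ppm: float = DEFAULT_TOL_PPM,
    min_gradients: int = DEFAULT_MIN_GRADIENTS,
    rt_tol: float = DEFAULT_RT_TOL,
    min_behavior_corr: float = DEFAULT_MIN_BEHAVIOR_CORR,
    *,
    reference: str = REFERENCE_GRADIENT,
    min_fragment_gradients: int = 4,
    peak_kwargs: dict | None = None,
) -> list[IonFeature]:
    """Full CRB deconvolution of one (mode, column) dataset.

    ``qc_runs`` maps gradient id -> QC run. MS1 peaks are detected per
    gradient and linked into precursor features; MS2 peaks are detected per
    SWATH window per gradient, linked into fragment candidates, and assigned
    to each precursor of the corresponding window by retention behaviour.
    """
    peak_kwargs = peak_kwargs or {}
    any_run = next(iter(qc_runs.values()))
    mode, column = any_run.mode, any_run.column_mode
    windows = any_run.swath_windows

    ms1_peaks = {
        gid: detect_peaks_in_series(run.ms1, tol_ppm=tol_ppm, **peak_kwargs)
        for gid, run in qc_runs.items()
    }
    features = link_precursors_across_gradients(
        ms1_peaks, tol_ppm, min_gradients,
        reference=reference, mode=mode, column_mode=column,
        id_prefix=f"{'P' if mode == 'positive' else 'N'}{column[0]}",
    )

    frag_features_per_window: dict[int, list[IonFeature]] = {}
    for w in range(len(windows)):
        ms2_peaks = {
            gid: detect_peaks_in_series(run.ms2[w], tol_ppm=tol_ppm, **peak_kwargs)
            for gid, run in qc_runs.items()
            if w in run.ms2
        }
        frag_features_per_window[w] = link_precursors_across_gradients(
            ms2_peaks, tol_ppm, min_fragment_gradients,
            reference=reference, mode=mode, column_mode=column, id_prefix="frag",
        )

    out = []
    for f in features:
        w = _window_of(f.mz, windows)
        frags = frag_features_per_window.get(w, []) if w is not None else []
        out.append(
            crb_deconvolve_ms2(
                f, frags, rt_tol, min_behavior_corr,
                min_shared=min_fragment_gradients, reference=reference,
            )
        )
    return out


def _window_of(mz: float, windows: list[tuple[float, float]]) -> int | None:
    hits = [
        (abs(mz - (lo + hi) / 2), i) for i, (lo, hi) in enumerate(windows) if lo <= mz <= hi
    ]
    return min(hits)[1] if hits else None


def targeted_peak_areas(
    sample_runs: dict[str, Run | None],
    features: list[IonFeature],
    tol_ppm: float = DEFAULT_TOL_PPM,
    rt_window: float = 0.2,
    *,
    peak_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Targeted re-search of deconvolved features in single-gradient runs.

    For every (feature, sample) pair the MS1 XIC at the feature m/z is peak-
    picked and the largest peak whose apex falls within ``rt_reference +/-
    rt_window`` is integrated. Undetected-in-window is 0 (a real absence that
    enters statistics); a missing run (``None``) yields NaN cells, which are
    excluded from statistics downstream.
    """
    peak_kwargs = peak_kwargs or {}
    table = pd.DataFrame(
        0.0, index=[f.feature_id for f in features], columns=list(sample_runs)
    )
    for sid, run in sample_runs.items():
        if run is None:
            table[sid] = np.nan
            continue
        for f in features:
            trace = extract_xic(run.ms1, f.mz, tol_ppm)
            peaks = detect_chrom_peaks(trace, run.ms1.times, mz=f.mz, **peak_kwargs)
            inside = [
                p for p in peaks if abs(p.rt_apex - f.rt_reference) <= rt_window
            ]
            if inside:
                best = max(inside, key=lambda p: p.height)
                table.loc[f.feature_id, sid] = best.area
    return table


# ---------------------------------------------------------------------------
# feature list I/O
# ---------------------------------------------------------------------------

def features_to_frame(features: list[IonFeature], gradient_ids: list[str]) -> pd.DataFrame:
    rows = []
    for f in features:
        row = {
            "feature_id": f.feature_id,
            "mode": f.mode,
            "column_mode": f.column_mode,
            "mz": f.mz,
            "rt_reference": f.rt_reference,
            "support": f.support,
        }
        for g in gradient_ids:
            row[f"rt_{g}"] = f.rt_vector.get(g, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def features_from_frame(frame: pd.DataFrame) -> list[IonFeature]:
    gradient_ids = [c[3:] for c in frame.columns if c.startswith("rt_") and c != "rt_reference"]
    out = []
    for _, r in frame.iterrows():
        rt_vector = {
            g: float(r[f"rt_{g}"]) for g in gradient_ids if np.isfinite(r[f"rt_{g}"])
        }
        out.append(
            IonFeature(
                feature_id=str(r["feature_id"]),
                mode=str(r["mode"]),
                column_mode=str(r["column_mode"]),
                mz=float(r["mz"]),
                rt_vector=rt_vector,
                rt_reference=float(r["rt_reference"]),
                support=int(r["support"]),
            )
        )
    return out
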