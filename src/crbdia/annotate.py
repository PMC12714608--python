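"""Spectral-library annotation and standard-based confirmation.

Level 2 (putative): the deconvolved MS2 spectrum matches a library record of
the same ion mode with precursor mass error below 10 ppm and spectral dot
product above 0.4. Level 1 (confirmed): additionally, the feature's retention
time agrees with the chemical standard within 0.1 min under the same gradient
and column. A spectral match whose standard RT is off by more than 0.5 min is
reported as an isomer of the library compound, not an identification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .crb import IonFeature

log = logging.getLogger(__name__)

DEFAULT_FRAG_TOL = 0.025   # Da, MS2 centroid tolerance
DEFAULT_ME_MAX_PPM = 10.0
DEFAULT_DP_MIN = 0.4
DEFAULT_RT_MAX = 0.1       # minutes, level-1 gate
ISOMER_RT_MIN = 0.5        # minutes, RT discrepancy that flags an isomer


@dataclass(frozen=True)
class LibraryRecord:
    name: str
    precursor_mz: float
    mode: str
    spectrum: tuple[tuple[float, float], ...]
    class_label: str = "unclassified"
    rt_standard: float | None = None
    decoy_of: str | None = None

    def __post_init__(self) -> None:
        if not self.spectrum:
            raise ValueError("library spectrum must be non-empty")


def records_from_matchms(spectra) -> list[LibraryRecord]:
    """Convert matchms ``Spectrum`` objects (e.g. from MSP) to records."""
    out = []
    for s in spectra:
        meta = s.metadata
        out.append(
            LibraryRecord(
                name=meta.get("compound_name", "unknown"),
                precursor_mz=float(meta["precursor_mz"]),
                mode=meta.get("ionmode", "unknown"),
                spectrum=tuple(zip(s.peaks.mz.tolist(), s.peaks.intensities.tolist())),
                class_label=meta.get("chemical_class", "unclassified"),
                rt_standard=float(meta["retention_time"]) if "retention_time" in meta else None,
                decoy_of=meta.get("decoy_of"),
            )
        )
    return out


@dataclass(frozen=True)
class AnnotationResult:
    feature_id: str
    name: str
    dot_product: float
    mass_error_ppm: float
    level: int                      # 2 = spectral match, 1 = standard-confirmed
    class_label: str = "unclassified"
    rt_delta: float | None = None
    isomer_flag: bool = False
    unverifiable: bool = False
    decoy_of: str | None = None


def _greedy_pairs(
    mz_a: np.ndarray, mz_b: np.ndarray, frag_tol: float
) -> list[tuple[int, int]]:
    """Deterministic greedy peak pairing by ascending m/z gap."""
    cands = []
    for i, ma in enumerate(mz_a):
        for j, mb in enumerate(mz_b):
            d = abs(ma - mb)
            if d <= frag_tol:
                cands.append((d, i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _d, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def spectral_dot_product(
    spec_a, spec_b, frag_tol: float = DEFAULT_FRAG_TOL, weighting: str = "none"
) -> float:
    """Cosine similarity of two fragment spectra after greedy peak pairing.

    Peaks are paired within ``frag_tol`` Da by ascending m/z gap; the cosine
    is taken over the union of peaks, unpaired peaks contributing zero to the
    other spectrum. Bounded in [0, 1], symmetric, and invariant to uniform
    intensity scaling of either spectrum.

    ``weighting``: "none" (plain cosine on intensities, default), "sqrt"
    (square-root intensities), or "mz" (intensity x m/z weights).
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    a = np.asarray(list(spec_a), float)
    b = np.asarray(list(spec_b), float)
    if a.size == 0 or b.size == 0:
        raise ValueError("spectra must be non-empty")
    if weighting == "sqrt":
        a = np.column_stack([a[:, 0], np.sqrt(a[:, 1])])
        b = np.column_stack([b[:, 0], np.sqrt(b[:, 1])])
    elif weighting == "mz":
        a = np.column_stack([a[:, 0], a[:, 0] * a[:, 1]])
        b = np.column_stack([b[:, 0], b[:, 0] * b[:, 1]])
    elif weighting != "none":
        raise ValueError(f"unknown weighting {weighting!r}")
    pairs = _greedy_pairs(a[:, 0], b[:, 0], frag_tol)
    num = sum(a[i, 1] * b[j, 1] for i, j in pairs)
    denom = np.linalg.norm(a[:, 1]) * np.linalg.norm(b[:, 1])
    if denom == 0:
        return 0.0
    return float(num / denom)


def annotate_level2(
    feature: IonFeature,
    library: list[LibraryRecord],
    me_max_ppm: float = DEFAULT_ME_MAX_PPM,
    dp_min: float = DEFAULT_DP_MIN,
    frag_tol: float = DEFAULT_FRAG_TOL,
) -> list[AnnotationResult]:
    """Rank library matches of a deconvolved feature.

    Candidates are same-mode records with |precursor mass error| strictly
    below ``me_max_ppm``; those with dot product strictly above ``dp_min``
    are returned ranked by dot product (ties by smaller mass error).
    """
    if not feature.ms2_spectrum:
        log.info("feature %s has no deconvolved MS2 spectrum; no candidates", feature.feature_id)
        return []
    results = []
    for rec in library:
        if rec.mode != feature.mode:
            continue
        me = (feature.mz - rec.precursor_mz) / rec.precursor_mz * 1e6
        if abs(me) >= me_max_ppm:
            continue
        dp = spectral_dot_product(feature.ms2_spectrum, rec.spectrum, frag_tol)
        if dp <= dp_min:
            continue
        results.append(
            AnnotationResult(
                feature_id=feature.feature_id,
                name=rec.name,
                dot_product=dp,
                mass_error_ppm=float(me),
                level=2,
                class_label=rec.class_label,
                decoy_of=rec.decoy_of,
            )
        )
    results.sort(key=lambda r: (-r.dot_product, abs(r.mass_error_ppm)))
    return results


def confirm_level1(
    annotation: AnnotationResult,
    feature_rt: float,
    standard_rt: float | None,
    rt_max: float = DEFAULT_RT_MAX,
) -> AnnotationResult:
    """Upgrade a level-2 annotation to level 1 on standard RT agreement.

    Level 1 requires |feature RT - standard RT| <= ``rt_max`` min under the
    same gradient/column. A discrepancy above 0.5 min marks the feature as an
    isomer of the library compound. Missing standard RT leaves the annotation
    unverifiable.
    """
    if standard_rt is None or not np.isfinite(standard_rt):
        return replace(annotation, unverifiable=True)
    delta = float(feature_rt - standard_rt)
    level1 = abs(delta) <= rt_max
    return replace(
        annotation,
        level=1 if level1 else 2,
        rt_delta=delta,
        isomer_flag=abs(delta) > ISOMER_RT_MIN,
    )


def summarize_classes(
    annotations: list[AnnotationResult], intensities: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-class annotation counts, proportions, and accumulated intensity.

    ``intensities`` is the features x samples area table; each annotation
    contributes its feature's mean area to its class total.
    """
    rows: dict[str, dict[str, float]] = {}
    for a in annotations:
        r = rows.setdefault(a.class_label, {"count": 0, "summed_intensity": 0.0})
        r["count"] += 1
        if intensities is not None and a.feature_id in intensities.index:
            r["summed_intensity"] += float(np.nanmean(intensities.loc[a.feature_id].to_numpy(float)))
    out = pd.DataFrame.from_dict(rows, orient="index").rename_axis("class_label")
    if len(out):
        out["proportion"] = out["count"] / out["count"].sum()
        out = out.sort_values("count", ascending=False)
    return out


def annotations_to_frame(annotations: list[AnnotationResult]) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in annotations])
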