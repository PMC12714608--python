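"""Spectral dot product (vs a brute-force cosine oracle), annotation gates,
standard confirmation, and class summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from crbdia.annotate import (
    AnnotationResult,
    LibraryRecord,
    annotate_level2,
    confirm_level1,
    records_from_matchms,
    spectral_dot_product,
    summarize_classes,
)
from crbdia.crb import IonFeature


def brute_force_cosine(spec_a, spec_b, frag_tol=0.025):
    """Independent oracle: exhaustive pair enumeration, then the same greedy
    acceptance by ascending gap, cosine over the union vector."""
    a = [tuple(p) for p in spec_a]
    b = [tuple(p) for p in spec_b]
    cands = sorted(
        (abs(ma - mb), i, j)
        for i, (ma, _ia) in enumerate(a)
        for j, (mb, _ib) in enumerate(b)
        if abs(ma - mb) <= frag_tol
    )
    ua, ub, num = set(), set(), 0.0
    for _d, i, j in cands:
        if i in ua or j in ub:
            continue
        ua.add(i)
        ub.add(j)
        num += a[i][1] * b[j][1]
    na = np.sqrt(sum(x * x for _m, x in a))
    nb = np.sqrt(sum(x * x for _m, x in b))
    return num / (na * nb) if na * nb else 0.0


def random_spectrum(rng, n=None):
    n = n or rng.integers(3, 20)
    mz = np.sort(rng.uniform(50, 800, n))
    inten = rng.uniform(0.01, 1.0, n)
    return list(zip(mz.tolist(), inten.tolist()))


class TestDotProduct:
    def test_identical_spectra_give_one(self):
        s = [(100.0, 3.0), (150.0, 4.0), (210.5, 1.0)]
        assert spectral_dot_product(s, s) == pytest.approx(1.0)

    def test_no_shared_peaks_give_zero(self):
        assert spectral_dot_product([(100.0, 1.0)], [(200.0, 1.0)]) == 0.0

    def test_hand_computed_cosine(self):
        a = [(100.0, 3.0), (150.0, 4.0)]
        b = [(100.0, 4.0), (150.0, 3.0)]
        assert spectral_dot_product(a, b) == pytest.approx(24.0 / 25.0)

    def test_matches_brute_force_oracle_on_100_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b = random_spectrum(rng), random_spectrum(rng)
            assert spectral_dot_product(a, b) == pytest.approx(
                brute_force_cosine(a, b), abs=1e-12
            )

    @given(st.integers(0, 10_000), st.floats(0.1, 100.0))
    def test_symmetric_bounded_and_scale_invariant(self, seed, scale):
        rng = np.random.default_rng(seed)
        a, b = random_spectrum(rng), random_spectrum(rng)
        dp = spectral_dot_product(a, b)
        assert 0.0 <= dp <= 1.0 + 1e-12
        assert dp == pytest.approx(spectral_dot_product(b, a), abs=1e-12)
        scaled = [(m, i * scale) for m, i in a]
        assert dp == pytest.approx(spectral_dot_product(scaled, b), rel=1e-9)

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            spectral_dot_product([], [(100.0, 1.0)])

    def test_weighting_variants_self_similarity_and_ordering(self):
        a = [(100.0, 0.04), (400.0, 1.0)]
        b = [(100.0, 1.0), (400.0, 0.04)]
        for w in ("none", "sqrt", "mz"):
            assert spectral_dot_product(a, a, weighting=w) == pytest.approx(1.0)
        # sqrt weighting compresses intensity disparity, raising the score
        assert spectral_dot_product(a, b, weighting="sqrt") > spectral_dot_product(a, b)
        with pytest.raises(ValueError, match="weighting"):
            spectral_dot_product(a, b, weighting="cube")


def mk_feature(mz=300.0, spectrum=None, rt=5.0, mode="positive"):
    return IonFeature(
        feature_id="F1", mode=mode, column_mode="RPLC", mz=mz,
        rt_vector={"G5": rt}, rt_reference=rt, support=9,
        ms2_spectrum=spectrum,
    )


def mk_record(name="cmpd", mz=300.0, spectrum=None, mode="positive", **kw):
    return LibraryRecord(
        name=name, precursor_mz=mz, mode=mode,
        spectrum=tuple(spectrum or [(120.0, 1.0), (180.0, 0.5)]), **kw
    )


class TestLevel2:
    spec = [(120.0, 1.0), (180.0, 0.5), (250.0, 0.2)]

    def test_matching_record_ranks_first(self):
        feature = mk_feature(spectrum=[(m, i * 1e5) for m, i in self.spec])
        library = [
            mk_record("right", 300.0, self.spec),
            mk_record("wrong", 300.0, [(90.0, 1.0), (110.0, 0.8)]),
        ]
        res = annotate_level2(feature, library)
        assert res and res[0].name == "right"
        assert res[0].dot_product >= 0.99
        assert res[0].level == 2

    def test_mass_error_gate_strict(self):
        feature = mk_feature(mz=300.0 * (1 + 12e-6), spectrum=self.spec)
        assert annotate_level2(feature, [mk_record(mz=300.0, spectrum=self.spec)]) == []

    def test_dot_product_gate(self):
        # one shared peak out of many: DP well below 0.4
        feature = mk_feature(spectrum=[(120.0, 1.0), (60.0, 1.0), (70.0, 1.0), (80.0, 1.0)])
        rec = mk_record(spectrum=[(120.0, 0.2), (200.0, 1.0), (220.0, 1.0)])
        assert annotate_level2(feature, [rec]) == []

    def test_wrong_ion_mode_excluded(self):
        feature = mk_feature(spectrum=self.spec, mode="negative")
        assert annotate_level2(feature, [mk_record(spectrum=self.spec)]) == []

    def test_feature_without_spectrum_yields_nothing(self):
        assert annotate_level2(mk_feature(spectrum=None), [mk_record()]) == []


class TestLevel1:
    base = AnnotationResult(
        feature_id="F1", name="cmpd", dot_product=0.9, mass_error_ppm=2.0, level=2
    )

    @pytest.mark.parametrize("delta,level", [(0.0, 1), (0.05, 1), (-0.1, 1), (0.2, 2)])
    def test_rt_agreement_gate(self, delta, level):
        res = confirm_level1(self.base, feature_rt=5.0 + delta, standard_rt=5.0)
        assert res.level == level
        assert res.rt_delta == pytest.approx(delta)

    def test_isomer_decoy_flagged_never_level1(self):
        res = confirm_level1(self.base, feature_rt=5.6, standard_rt=5.0)
        assert res.level == 2 and res.isomer_flag

    def test_missing_standard_is_unverifiable(self):
        res = confirm_level1(self.base, feature_rt=5.0, standard_rt=None)
        assert res.level == 2 and res.unverifiable


class TestClassSummary:
    def make(self, classes):
        return [
            AnnotationResult(
                feature_id=f"F{i}", name=f"c{i}", dot_product=0.9,
                mass_error_ppm=1.0, level=2, class_label=cls,
            )
            for i, cls in enumerate(classes)
        ]

    def test_single_class_has_proportion_one(self):
        out = summarize_classes(self.make(["acid"] * 4))
        assert len(out) == 1
        assert out.loc["acid", "proportion"] == 1.0

    def test_counts_conserved_and_fourteen_classes_kept(self):
        classes = [f"class_{i % 14}" for i in range(40)]
        out = summarize_classes(self.make(classes))
        assert len(out) == 14
        assert out["count"].sum() == 40
        assert out["proportion"].sum() == pytest.approx(1.0)

    def test_intensities_accumulated_per_class(self):
        table = pd.DataFrame({"s1": [10.0, 30.0]}, index=["F0", "F1"])
        out = summarize_classes(self.make(["acid", "acid"]), table)
        assert out.loc["acid", "summed_intensity"] == 40.0


def test_msp_round_trip_preserves_records(tmp_path):
    from matchms import Spectrum

    from crbdia.runio import read_msp, write_msp

    spec = Spectrum(
        mz=np.array([100.0, 150.0]), intensities=np.array([0.5, 1.0]),
        metadata={"compound_name": "x", "precursor_mz": 300.1,
                  "ionmode": "positive", "chemical_class": "acid",
                  "retention_time": 5.25},
    )
    path = tmp_path / "lib.msp"
    write_msp([spec], path)
    (rec,) = records_from_matchms(read_msp(path))
    assert rec.name == "x"
    assert rec.precursor_mz == pytest.approx(300.1)
    assert rec.rt_standard == pytest.approx(5.25)
    assert rec.spectrum == ((100.0, 0.5), (150.0, 1.0))
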