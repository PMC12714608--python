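"""Cross-gradient linking, retention-behaviour fragment assignment, and
targeted re-search, scored against the generator's planted truth."""

import numpy as np
import pytest

from crbdia import crb, scorecard
from crbdia.crb import IonFeature, crb_deconvolve_ms2, link_precursors_across_gradients
from crbdia.gradients import RPLC, GradientProgram, default_gradients
from crbdia.peaks import ChromPeak
from crbdia.runio import ScanSeries
from crbdia.simulate import (
    AcquisitionConfig,
    make_compound_panel,
    make_study_design,
    simulate_dia_acquisition,
    variable_swath_windows,
)

GIDS = [f"G{i}" for i in range(1, 10)]


def peak(mz, rt, height=5000.0, area=1000.0):
    return ChromPeak(mz=mz, rt_apex=rt, rt_bounds=(rt - 0.1, rt + 0.1), area=area, height=height)


def feature(mz, rts, heights=None, fid="F1"):
    return IonFeature(
        feature_id=fid, mode="positive", column_mode=RPLC, mz=mz,
        rt_vector=dict(rts), rt_reference=rts.get("G5", 0.0),
        support=len(rts), heights=heights or {g: 1000.0 for g in rts},
    )


class TestLinking:
    def test_singleton_present_in_all_gradients(self):
        rts = {g: 5.0 + 0.5 * i for i, g in enumerate(GIDS)}
        per_gradient = {g: [peak(300.0, rt)] for g, rt in rts.items()}
        feats = link_precursors_across_gradients(per_gradient, 10.0, 7)
        assert len(feats) == 1
        f = feats[0]
        assert f.support == 9
        assert f.rt_vector == pytest.approx(rts)
        assert f.rt_reference == rts["G5"]

    def test_support_below_threshold_discarded(self):
        per_gradient = {g: [peak(300.0, 5.0)] for g in GIDS[:5]}
        assert link_precursors_across_gradients(per_gradient, 10.0, 7) == []

    def test_cluster_without_reference_detection_rejected(self):
        per_gradient = {g: [peak(300.0, 5.0)] for g in GIDS if g != "G5"}
        assert link_precursors_across_gradients(per_gradient, 10.0, 7) == []

    def test_crossing_isomers_resolved_by_elution_rank(self):
        """Two same-m/z isomers whose order crosses in one gradient: rank
        assignment recovers each truth RT vector in >= 8 of 9 entries."""
        rt_a = {g: 4.0 + 0.6 * i for i, g in enumerate(GIDS)}
        rt_b = {g: 5.0 + 0.7 * i for i, g in enumerate(GIDS)}
        rt_a["G9"], rt_b["G9"] = rt_b["G9"], rt_a["G9"]  # cross once
        per_gradient = {g: [peak(300.0, rt_a[g]), peak(300.0, rt_b[g])] for g in GIDS}
        feats = link_precursors_across_gradients(per_gradient, 10.0, 7)
        assert len(feats) == 2
        for truth in (rt_a, rt_b):
            hits = max(
                sum(abs(f.rt_vector[g] - truth[g]) < 1e-9 for g in GIDS) for f in feats
            )
            assert hits >= 8


class TestFragmentAssignment:
    def test_identical_behaviour_assigned_with_unit_correlation(self):
        rts = {g: 5.0 + 0.5 * i for i, g in enumerate(GIDS)}
        prec = feature(400.0, rts)
        frag = feature(150.0, rts, fid="frag")
        out = crb_deconvolve_ms2(prec, [frag])
        assert out.ms2_spectrum == [(150.0, 1000.0)]
        corr, n = crb.behavior_correlation(prec.rt_vector, frag.rt_vector)
        assert n == 9 and corr == pytest.approx(1.0)

    def test_fragment_above_precursor_mass_never_assigned(self):
        rts = {g: 5.0 + 0.5 * i for i, g in enumerate(GIDS)}
        out = crb_deconvolve_ms2(feature(400.0, rts), [feature(400.03, rts, fid="frag")])
        assert out.ms2_spectrum == []

    def test_fewer_than_four_shared_gradients_unassessable(self):
        rts_p = {g: 5.0 + 0.5 * i for i, g in enumerate(GIDS)}
        rts_f = {g: rts_p[g] for g in ("G4", "G5", "G6")}
        out = crb_deconvolve_ms2(feature(400.0, rts_p), [feature(150.0, rts_f, fid="frag")])
        assert out.ms2_spectrum == []

    def test_coelution_in_one_gradient_only_is_rejected(self):
        rts_p = {g: 5.0 + 0.5 * i for i, g in enumerate(GIDS)}
        rts_f = {g: rts_p[g] + (0.0 if g == "G5" else 0.5) for g in GIDS}
        out = crb_deconvolve_ms2(feature(400.0, rts_p), [feature(150.0, rts_f, fid="frag")])
        assert out.ms2_spectrum == []

    def test_constant_rt_vectors_fall_back_to_coelution(self):
        """Nine identical gradients: correlation undefined, co-elution alone
        decides (the degenerate negative control)."""
        rts = {g: 5.0 for g in GIDS}
        out = crb_deconvolve_ms2(feature(400.0, rts), [feature(150.0, dict(rts), fid="frag")])
        assert out.ms2_spectrum == [(150.0, 1000.0)]


class TestOnSyntheticStudy:
    def test_deconvolution_recovers_planted_compounds(self, small_bundle):
        qc = {g: r for (m, c, g), r in small_bundle.qc_runs.items() if m == "positive"}
        feats = crb.deconvolve_dataset(qc)
        matched = scorecard.match_features_to_truth(
            feats, small_bundle.truth, "positive", RPLC
        )
        n_pos = sum(
            1 for name, (m, _mz) in small_bundle.truth.precursor_mz.items() if m == "positive"
        )
        assert len(matched) >= 0.9 * n_pos
        score = scorecard.fragment_assignment_score(feats, matched, small_bundle)
        assert score.precision >= 0.9
        assert score.recall >= 0.9
        # every RT-vector entry lies within its gradient's run duration
        durations = {g.id: g.run_end for g in small_bundle.gradients[RPLC]}
        for f in feats:
            for gid, rt in f.rt_vector.items():
                assert 0.0 < rt <= durations[gid]

    def test_output_invariant_to_scan_order_and_gradient_labels(self, small_bundle):
        qc = {g: r for (m, c, g), r in small_bundle.qc_runs.items() if m == "positive"}
        feats_ref = crb.deconvolve_dataset(qc)

        def shuffle(series, rng):
            order = rng.permutation(len(series.mz))
            return ScanSeries(series.times, series.scan_index[order],
                              series.mz[order], series.intensity[order])

        rng = np.random.default_rng(0)
        qc_shuffled = {}
        for gid, run in qc.items():
            import copy

            r2 = copy.copy(run)
            r2.ms1 = shuffle(run.ms1, rng)
            r2.ms2 = {w: shuffle(s, rng) for w, s in run.ms2.items()}
            qc_shuffled[gid] = r2
        feats_shuf = crb.deconvolve_dataset(qc_shuffled)
        assert len(feats_shuf) == len(feats_ref)
        for a, b in zip(feats_ref, feats_shuf):
            assert a.mz == pytest.approx(b.mz)
            assert a.rt_vector == pytest.approx(b.rt_vector)
            assert a.ms2_spectrum == pytest.approx(b.ms2_spectrum)

    def test_planted_coelution_pairs_are_split(self, small_bundle):
        qc = {g: r for (m, c, g), r in small_bundle.qc_runs.items() if m == "positive"}
        feats = crb.deconvolve_dataset(qc)
        matched = scorecard.match_features_to_truth(
            feats, small_bundle.truth, "positive", RPLC
        )
        split = scorecard.coelution_splitting_score(feats, matched, small_bundle)
        if split["n_pairs_recovered"]:
            assert split["clean_fraction"] == 1.0


class TestDegenerateControl:
    def test_single_gradient_nine_times_collapses_to_coelution(
        self, short_gradients, noise_free_config
    ):
        """With nine copies of one gradient, retention behaviour carries no
        information: fragments of co-eluting precursors are cross-assigned."""
        g5 = short_gradients[RPLC][4]
        degenerate = {
            RPLC: [
                GradientProgram(gid, RPLC, g5.breakpoints, g5.dead_time) for gid in GIDS
            ]
        }
        compounds, pairs = make_compound_panel(
            20, seed=21, coelution_fraction=0.4, gradients=short_gradients
        )
        design, _ = make_study_design(compounds, seed=22)
        prec = np.array([c.precursor_mz(c.modes[0]) for c in compounds])
        acq = noise_free_config(variable_swath_windows(prec), seed=23)

        results = {}
        for label, grads in (("distinct", short_gradients), ("degenerate", degenerate)):
            bundle = simulate_dia_acquisition(
                design, compounds, grads, acq, columns=(RPLC,),
                simulate_samples=False, coeluting_pairs=pairs,
            )
            feats, matched, split = {}, {}, {"n_pairs_recovered": 0}
            agg = {"clean": [], "pairs": 0, "crossed": 0}
            for mode in ("positive", "negative"):
                qc = {g: r for (m, c, g), r in bundle.qc_runs.items() if m == mode}
                if not qc:
                    continue
                fs = crb.deconvolve_dataset(qc)
                mt = scorecard.match_features_to_truth(fs, bundle.truth, mode, RPLC)
                sp = scorecard.coelution_splitting_score(fs, mt, bundle)
                agg["pairs"] += sp["n_pairs_recovered"]
                agg["crossed"] += sp["cross_assigned_fragments"]
            results[label] = agg
        assert results["distinct"]["pairs"] >= 2
        assert results["distinct"]["crossed"] == 0
        assert results["degenerate"]["crossed"] > 0


class TestTargetedSearch:
    def test_area_matches_truth_absence_is_zero_and_window_enforced(self, small_bundle):
        qc = {g: r for (m, c, g), r in small_bundle.qc_runs.items() if m == "positive"}
        feats = crb.deconvolve_dataset(qc)
        matched = scorecard.match_features_to_truth(
            feats, small_bundle.truth, "positive", RPLC
        )
        sid = small_bundle.design.sample_ids[0]
        runs = {sid: small_bundle.sample_runs[("positive", RPLC, sid)]}
        table = crb.targeted_peak_areas(runs, feats, rt_window=0.2)
        checked = 0
        for f in feats:
            name = matched.get(f.feature_id)
            if name is None:
                continue
            true_area = small_bundle.truth.areas.loc[name, sid]
            got = table.loc[f.feature_id, sid]
            if true_area > 5e4:  # well above detection limit
                assert got == pytest.approx(true_area, rel=0.1)
                checked += 1
        assert checked >= 5

        # a feature whose window lies far from any signal integrates to zero
        ghost = feature(feats[0].mz, {"G5": feats[0].rt_reference + 3.0}, fid="ghost")
        ghost_table = crb.targeted_peak_areas(runs, [ghost], rt_window=0.2)
        assert ghost_table.loc["ghost", sid] == 0.0

    def test_missing_run_is_nan_not_zero(self, small_bundle):
        qc = {g: r for (m, c, g), r in small_bundle.qc_runs.items() if m == "positive"}
        feats = crb.deconvolve_dataset(qc)[:3]
        table = crb.targeted_peak_areas({"gone": None}, feats)
        assert table["gone"].isna().all()
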