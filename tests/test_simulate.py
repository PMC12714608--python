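"""Synthetic study generator: acquisition scheme, conservation, sensory panel,
library export, and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from crbdia.gradients import RPLC, default_gradients
from crbdia.peaks import extract_xic
from crbdia.runio import read_mzml, write_mzml
from crbdia.simulate import (
    AcquisitionConfig,
    DEFAULT_BASELINES,
    METRIC_RANGES,
    METRICS,
    export_library_and_standards,
    fixed_swath_windows,
    make_compound_panel,
    make_study_design,
    simulate_dia_acquisition,
    simulate_sensory_scores,
    variable_swath_windows,
)


def test_duty_cycle_is_ms1_plus_twelve_ms2_dwells():
    acq = AcquisitionConfig(swath_windows=fixed_swath_windows())
    assert acq.n_windows == 12
    assert acq.cycle_time == pytest.approx(0.150 + 12 * 0.050)


def test_swath_windows_cover_range_and_overlap_bounded():
    mzs = np.random.default_rng(0).uniform(100, 900, 500)
    windows = variable_swath_windows(mzs)
    acq = AcquisitionConfig(swath_windows=windows)  # validates invariants
    assert windows[0][0] <= 70.0 and windows[-1][1] >= 1200.0
    for (l0, h0), (l1, h1) in zip(windows, windows[1:]):
        assert l1 <= h0 and h0 - l1 <= 1.0


def test_window_gap_rejected():
    with pytest.raises(ValueError, match="gap"):
        AcquisitionConfig(swath_windows=[(70.0, 400.0), (500.0, 1200.0)])


@pytest.fixture(scope="module")
def one_compound_bundle(short_gradients, noise_free_config):
    compounds, _ = make_compound_panel(1, seed=5, coelution_fraction=0.0,
                                       gradients=short_gradients)
    design, _ = make_study_design(compounds, seed=6, sample_cv=0.0)
    acq = noise_free_config(fixed_swath_windows())
    bundle = simulate_dia_acquisition(
        design, compounds, short_gradients, acq, columns=(RPLC,),
        modes=(compounds[0].modes[0],),
    )
    return compounds[0], bundle


class TestNoiseFreeLimit:
    def test_xic_is_single_gaussian_at_true_rt(self, one_compound_bundle):
        c, bundle = one_compound_bundle
        run = bundle.qc_runs[(c.modes[0], RPLC, "G5")]
        trace = extract_xic(run.ms1, c.precursor_mz(c.modes[0]), 10.0)
        apex_rt = run.ms1.times[np.argmax(trace)]
        true_rt = bundle.truth.rt[(RPLC, "G5")][c.name]
        assert apex_rt == pytest.approx(true_rt, abs=0.02)
        # Gaussian shape: log-intensity is quadratic in time around the apex
        nz = trace > 0
        lo = np.log(trace[nz])
        coef = np.polyfit(run.ms1.times[nz], lo, 2)
        assert coef[0] < 0

    def test_qc_area_equals_mean_sample_area(self, one_compound_bundle):
        """Equal-volume pooling: noise-free QC area = mean per-sample area (<1%)."""
        c, bundle = one_compound_bundle
        mode = c.modes[0]
        run_qc = bundle.qc_runs[(mode, RPLC, "G5")]
        mz = c.precursor_mz(mode)
        qc_area = np.trapezoid(extract_xic(run_qc.ms1, mz), run_qc.ms1.times)
        sample_areas = []
        for sid in bundle.design.sample_ids:
            r = bundle.sample_runs[(mode, RPLC, sid)]
            sample_areas.append(np.trapezoid(extract_xic(r.ms1, mz), r.ms1.times))
        assert qc_area == pytest.approx(np.mean(sample_areas), rel=0.01)


def test_unfragmented_precursor_recorded_not_dropped(short_gradients, noise_free_config):
    compounds, _ = make_compound_panel(5, seed=7, coelution_fraction=0.0,
                                       gradients=short_gradients)
    design, _ = make_study_design(compounds, seed=8)
    # acquisition limited to 400 Da: heavier precursors are unfragmented
    acq = noise_free_config([(70.0, 400.0)], ms1_range=(70.0, 400.0))
    bundle = simulate_dia_acquisition(
        design, compounds, short_gradients, acq, columns=(RPLC,), simulate_samples=False
    )
    heavy = [c.name for c in compounds if c.precursor_mz(c.modes[0]) > 400.0]
    assert heavy and set(heavy) <= bundle.truth.unfragmented


def test_emg_tailing_shifts_apex_but_stays_detectable(short_gradients, noise_free_config):
    compounds, _ = make_compound_panel(1, seed=5, coelution_fraction=0.0,
                                       gradients=short_gradients)
    design, _ = make_study_design(compounds, seed=6, sample_cv=0.0)
    acq = noise_free_config(fixed_swath_windows(), emg_tau_min=0.08)
    c = compounds[0]
    bundle = simulate_dia_acquisition(
        design, compounds, short_gradients, acq, columns=(RPLC,),
        modes=(c.modes[0],), simulate_samples=False,
    )
    run = bundle.qc_runs[(c.modes[0], RPLC, "G5")]
    from crbdia.peaks import detect_chrom_peaks

    trace = extract_xic(run.ms1, c.precursor_mz(c.modes[0]), 10.0)
    peaks = detect_chrom_peaks(trace, run.ms1.times)
    assert len(peaks) == 1
    true_rt = bundle.truth.rt[(RPLC, "G5")][c.name]
    assert peaks[0].rt_apex >= true_rt - 0.02          # mode sits after the Gaussian centre
    assert peaks[0].rt_bounds[1] - peaks[0].rt_apex > peaks[0].rt_apex - peaks[0].rt_bounds[0]


def test_seeded_simulation_is_bit_reproducible(short_gradients):
    compounds, _ = make_compound_panel(5, seed=1, gradients=short_gradients)
    design, _ = make_study_design(compounds, seed=2)
    prec = np.array([c.precursor_mz(c.modes[0]) for c in compounds])
    acq = AcquisitionConfig(swath_windows=variable_swath_windows(prec), seed=42)
    runs = []
    for _ in range(2):
        b = simulate_dia_acquisition(
            design, compounds, short_gradients, acq, columns=(RPLC,),
            simulate_samples=False,
        )
        runs.append(b.qc_runs[(compounds[0].modes[0], RPLC, "G3")])
    a, b = runs
    assert np.array_equal(a.ms1.mz, b.ms1.mz)
    assert np.array_equal(a.ms1.intensity, b.ms1.intensity)
    assert all(np.array_equal(a.ms2[w].mz, b.ms2[w].mz) for w in a.ms2)


def test_mzml_round_trip_preserves_scans_and_peaks(small_bundle, tmp_path):
    run = next(iter(small_bundle.qc_runs.values()))
    path = tmp_path / "run.mzML"
    write_mzml(run, path)
    back = read_mzml(path)
    assert back.ms1.n_scans == run.ms1.n_scans
    assert np.allclose(np.sort(back.ms1.mz), np.sort(run.ms1.mz))
    assert np.allclose(np.sort(back.ms1.intensity), np.sort(run.ms1.intensity))
    assert set(back.ms2) == set(run.ms2)
    for w in run.ms2:
        assert back.ms2[w].n_scans == run.ms2[w].n_scans
        assert np.allclose(np.sort(back.ms2[w].mz), np.sort(run.ms2[w].mz))


class TestSensoryScores:
    def test_zero_noise_zero_bias_returns_baselines(self, small_bundle):
        scores = simulate_sensory_scores(
            small_bundle.design, noise_sd=0.0, assessor_bias_sd=0.0, seed=0
        )
        groups = small_bundle.design.groups
        for (sid, metric), grp in scores.groupby(["sample_id", "metric"]):
            assert (grp["score"] == DEFAULT_BASELINES[groups[sid]][metric]).all()

    def test_scores_respect_metric_ranges(self, small_bundle):
        scores = simulate_sensory_scores(small_bundle.design, noise_sd=30.0, seed=3)
        for metric in METRICS:
            lo, hi = METRIC_RANGES[metric]
            vals = scores.loc[scores["metric"] == metric, "score"]
            assert vals.between(lo, hi).all()

    def test_negative_noise_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            simulate_sensory_scores(small_bundle.design, noise_sd=-1.0)

    def test_planted_effect_recovered_in_expectation(self, small_bundle):
        """+6 points planted on N1 astringency, noise_sd = 1: the N1-minus-N2
        mean over 200 replicates recovers 6 within 0.5."""
        design = small_bundle.design
        flat = {g: dict.fromkeys(METRICS, 30.0) for g in ("T", "N1", "N2", "N3")}
        effects = {"N1": {"astringency": 6.0}}
        diffs = []
        n1 = design.group_members("N1")
        n2 = design.group_members("N2")
        for rep in range(200):
            s = simulate_sensory_scores(
                design, noise_sd=1.0, seed=1000 + rep, baselines=flat,
                group_effects=effects,
            )
            astr = s[s["metric"] == "astringency"].set_index("sample_id")["score"]
            diffs.append(
                astr.loc[astr.index.isin(n1)].mean() - astr.loc[astr.index.isin(n2)].mean()
            )
        assert np.mean(diffs) == pytest.approx(6.0, abs=0.5)


class TestLibraryExport:
    def test_full_coverage_no_decoys_is_one_record_each(self, small_panel):
        compounds, _ = small_panel
        records, _std = export_library_and_standards(compounds, 1.0, 0, seed=0)
        assert len(records) == len(compounds)
        names = {r.metadata["compound_name"] for r in records}
        assert names == {c.name for c in compounds}

    def test_partial_coverage_is_exact_and_reproducible(self, short_gradients):
        compounds, _ = make_compound_panel(100, seed=3, coelution_fraction=0.0,
                                           gradients=short_gradients)
        r1, _ = export_library_and_standards(compounds, 0.3, 0, seed=9)
        r2, _ = export_library_and_standards(compounds, 0.3, 0, seed=9)
        assert len(r1) == 30
        assert [a.metadata["compound_name"] for a in r1] == [
            b.metadata["compound_name"] for b in r2
        ]

    def test_decoy_rt_offset_exceeds_half_minute(self, small_panel, small_bundle):
        compounds, _ = small_panel
        rt_g5 = pd.DataFrame({RPLC: small_bundle.truth.rt[RPLC]["G5"]})
        records, std = export_library_and_standards(
            compounds, 1.0, 5, seed=4, rt_g5=rt_g5
        )
        decoys = [r for r in records if "decoy_of" in r.metadata]
        assert len(decoys) == 5
        for d in decoys:
            parent_rt = float(rt_g5.loc[d.metadata["decoy_of"], RPLC])
            assert abs(float(d.metadata["retention_time"]) - parent_rt) >= 0.5

    def test_too_many_decoys_rejected(self, small_panel):
        compounds, _ = small_panel
        with pytest.raises(ValueError):
            export_library_and_standards(compounds, 1.0, len(compounds) + 1, seed=0)
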