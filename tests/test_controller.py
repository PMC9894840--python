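"""Decision engine: calibration, scheduling, trigger chain, close-out."""

import numpy as np
import pytest

from targetms import controller as C
from targetms.assay import Assay, AssayTarget
from targetms.config import AcquisitionConfig
from targetms.quant import QuantEvent
from targetms.sim import ScanRecord, ScanRequest


def make_scan(mz, intensity, scan_type="OT_MS2", noise=1.0, target=None):
    mz = np.asarray(mz, dtype=float)
    order = np.argsort(mz)
    return ScanRecord(
        request=ScanRequest(type=scan_type, time=0.0, center_mz=500.0,
                            width_mz=0.7, max_it_ms=100.0, target_key=target),
        realized_it_ms=100.0,
        peaks_mz=mz[order],
        peaks_int=np.asarray(intensity, dtype=float)[order],
        reporters=None,
        noise_est=noise,
        duration_s=0.2,
    )


def make_target(key="AAAAAAGK/2", protein="P1", bin_=10,
                frag_mz=(300.0, 350.0, 400.0, 450.0, 500.0, 550.0, 600.0, 650.0),
                frag_int=(8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0)):
    return AssayTarget(key=key, protein=protein, bin=bin_, precursor_mz=500.0,
                       frag_mz=frag_mz, frag_int=frag_int)


def make_assay(targets):
    goals = {}
    for t in targets:
        goals[t.protein] = goals.get(t.protein, 0) + 1
    return Assay(targets=list(targets), config_snapshot={}, protein_goals=goals)


class TestCalibration:
    def test_median_robust_to_outlier(self, config):
        state = C.CalibrationState(c=9.0, last_update_t=0.0)
        state = C.calibrate_elution_point(state, [10, 11, 11, 12, 40], 15.0, config)
        assert state.c == 11.0

    def test_empty_episode_extrapolates_at_default_rate(self, config):
        state = C.CalibrationState(c=11.0, last_update_t=0.0)
        state = C.calibrate_elution_point(state, [], 15.0, config)
        assert state.c == pytest.approx(11.0 + 15.0 / config.bin_width_s)

    def test_estimate_is_monotone(self, config):
        state = C.CalibrationState(c=11.0, last_update_t=0.0,
                                   last_accept=(0.0, 11.0))
        state = C.calibrate_elution_point(state, [9, 9, 9], 15.0, config)
        assert state.c == 11.0

    def test_rate_from_last_two_accepted_episodes(self, config):
        state = C.CalibrationState()
        state = C.calibrate_elution_point(state, [10], 0.0, config)
        state = C.calibrate_elution_point(state, [13], 30.0, config)
        assert state.rate == pytest.approx(0.1)


class TestScheduling:
    def test_window_selection(self, config):
        targets = [make_target(key=f"T{b}/2", bin_=b) for b in (16, 17, 23, 24)]
        assay = make_assay(targets)
        state = C.CalibrationState(c=20.0)
        got = {t.bin for t in C.schedule_prm_targets(assay, state, config)}
        assert got == {17, 23}

    def test_closed_out_excluded(self, config):
        t = make_target(bin_=20)
        assay = make_assay([t])
        assay.peptide_closed[t.key] = True
        state = C.CalibrationState(c=20.0)
        assert C.schedule_prm_targets(assay, state, config) == []

    def test_uncalibrated_schedules_nothing(self, config):
        assay = make_assay([make_target()])
        assert C.schedule_prm_targets(assay, C.CalibrationState(), config) == []


class TestPrmMatch:
    def test_six_matched_triggers_five_does_not(self, config):
        target = make_target()
        six = make_scan(target.frag_mz[:6], [10] * 6, "IT_PRM", target=target.key)
        five = make_scan(target.frag_mz[:5], [10] * 5, "IT_PRM", target=target.key)
        assert C.evaluate_prm_match(six, target, config) == (6, True)
        assert C.evaluate_prm_match(five, target, config) == (5, False)

    def test_empty_scan_no_trigger(self, config):
        target = make_target()
        empty = make_scan([], [], "IT_PRM", target=target.key)
        assert C.evaluate_prm_match(empty, target, config) == (0, False)

    def test_scan_target_mismatch_rejected(self, config):
        target = make_target()
        scan = make_scan([300.0], [1.0], "IT_PRM", target="OTHER/2")
        with pytest.raises(ValueError):
            C.evaluate_prm_match(scan, target, config)


class TestIdentification:
    def test_exact_reproduction_scores_cosine_one(self, config):
        target = make_target()
        scan = make_scan(target.frag_mz, target.frag_int)
        cosine, coverage, ok = C.evaluate_identification(
            scan, target.frag_mz, target.frag_int, config
        )
        assert round(cosine, 2) == 1.00
        assert coverage == 1.0
        assert ok

    def test_cosine_at_threshold_fails_strictly(self):
        # strict inequality: a spectrum whose cosine exactly equals the
        # configured threshold must NOT pass
        lib_mz, lib_int = [300.0, 400.0], [3.0, 4.0]
        scan = make_scan(lib_mz, [4.0, 3.0])  # cosine = 24/25 = 0.96 exactly
        base = AcquisitionConfig()
        cosine, coverage, _ = C.evaluate_identification(scan, lib_mz, lib_int, base)
        assert cosine == pytest.approx(0.96) and coverage == 1.0
        at = AcquisitionConfig(cosine_min=cosine)
        _, _, ok = C.evaluate_identification(scan, lib_mz, lib_int, at)
        assert not ok
        below = AcquisitionConfig(cosine_min=cosine - 1e-9)
        _, _, ok2 = C.evaluate_identification(scan, lib_mz, lib_int, below)
        assert ok2

    def test_low_coverage_fails_despite_high_cosine(self, config):
        # three high-abundance library fragments, only one present
        lib_mz = [300.0, 400.0, 500.0]
        lib_int = [1.0, 0.8, 0.6]
        scan = make_scan([300.0], [1.0])
        cosine, coverage, ok = C.evaluate_identification(scan, lib_mz, lib_int, config)
        assert coverage == pytest.approx(1 / 3)
        assert not ok

    def test_empty_library_entry_rejected(self, config):
        with pytest.raises(ValueError):
            C.evaluate_identification(make_scan([300.0], [1.0]), [], [], config)


class TestSpsSelection:
    def test_clean_spectrum_caps_at_ten(self, config):
        mz = [300.0 + 20 * i for i in range(12)]
        intensity = [100.0 - i for i in range(12)]
        scan = make_scan(mz, intensity)
        notches, purities, _ = C.select_sps_ions(scan, mz, intensity, config)
        assert len(notches) == 10
        assert all(p == 1.0 for p in purities)

    def test_equal_intensity_contaminant_excludes_ion(self, config):
        # foreign peak of equal intensity inside the 1 Da notch: purity 0.5
        scan = make_scan([300.0, 300.5, 400.0], [50.0, 50.0, 40.0])
        notches, purities, _ = C.select_sps_ions(
            scan, [300.0, 400.0], [1.0, 0.8], config
        )
        assert [round(n[0]) for n in notches] == [400]

    def test_zero_pure_candidates_aborts(self, config):
        scan = make_scan([300.0, 300.5], [50.0, 50.0])
        notches, _, _ = C.select_sps_ions(scan, [300.0], [1.0], config)
        assert notches == []


class TestCloseOut:
    def event(self, key="AAAAAAGK/2", protein="P1"):
        return QuantEvent(key=key, protein=protein, scan_index=0, time_s=1.0,
                          sn=(10.0,) * 11, purity=0.9, matched_fragments=8)

    def test_peptide_closes_and_protein_counts(self, config):
        t1, t2 = make_target(), make_target(key="CCCCCCGK/2")
        assay = make_assay([t1, t2])
        C.update_close_out(assay, self.event(key=t1.key), config)
        assert assay.peptide_closed[t1.key]
        assert not assay.protein_closed("P1")  # goal 2, one quantified
        C.update_close_out(assay, self.event(key=t2.key), config)
        assert assay.protein_closed("P1")

    def test_double_close_is_idempotent(self, config):
        t1 = make_target()
        assay = make_assay([t1])
        C.update_close_out(assay, self.event(key=t1.key), config)
        C.update_close_out(assay, self.event(key=t1.key), config)
        assert assay.protein_quantified_count["P1"] == 1

    def test_unknown_peptide_rejected(self, config):
        assay = make_assay([make_target()])
        with pytest.raises(KeyError):
            C.update_close_out(assay, self.event(key="NOPE/2"), config)


class TestRealtimeSearch:
    def _index(self, lib):
        return C.SearchIndex.from_library(lib)

    def test_planted_peptide_identified_and_decoy_rejected(self, config):
        from targetms.sim import library_from_scenario, make_proteome_scenario

        sc = make_proteome_scenario(n_proteins=20, peptides_per_protein=1, seed=9)
        lib = library_from_scenario(sc)
        index = self._index(lib)
        entry = sorted(lib.spectral.values(), key=lambda e: e.key)[0]
        scan = make_scan(entry.peaks_mz, entry.peaks_int, "CALIB_MS2")
        key, score, reason = C.realtime_search(scan, entry.precursor_mz, index, config)
        assert key == entry.key
        assert score >= config.score_min
        # a spectrum matching nothing is not identified
        junk = make_scan([111.0, 222.0], [5.0, 5.0], "CALIB_MS2")
        key2, _, _ = C.realtime_search(junk, entry.precursor_mz, index, config)
        assert key2 is None

    def test_short_peptides_rejected(self, config):
        from targetms.libraries import build_library_bundle
        from test_libraries import make_psm

        psm = make_psm(seq="AAAGK", peaks=tuple((300.0 + i, 5.0) for i in range(8)))
        lib = build_library_bundle([psm], label_scheme="TMT11")
        index = self._index(lib)
        entry = lib.spectral["AAAGK/2"]
        scan = make_scan(entry.peaks_mz, entry.peaks_int, "CALIB_MS2")
        prec = index.candidates[0].precursor_mz
        key, _, reason = C.realtime_search(scan, prec, index, config)
        assert key is None and reason == "length"


@pytest.fixture(scope="module")
def small_run(config):
    from targetms.sim import library_from_scenario, make_proteome_scenario
    from targetms.workflows import assay_from_proteins

    sc = make_proteome_scenario(
        n_proteins=40, peptides_per_protein=1, abundance_log10_sigma=0.8,
        gradient_s=600.0, seed=21,
    )
    lib = library_from_scenario(sc)
    proteins = sorted({a.protein for a in sc.analytes})[:15]
    assay = assay_from_proteins(proteins, lib, config=config)
    log, events = C.run_targeted(sc, assay, lib, config, seed=21)
    return sc, lib, assay, log, events


class TestRunLoops:
    def test_trigger_chain_enforced(self, small_run, config):
        _, _, _, log, _ = small_run
        for d in log.decisions:
            if d.stage == "quantified":
                assert d.prm_scan is not None and d.otms2_scan is not None
                assert d.prm_scan < d.otms2_scan < d.ms3_scan
                assert log.scans[d.prm_scan].type == "IT_PRM"
                assert log.scans[d.otms2_scan].type == "OT_MS2"
                assert log.scans[d.ms3_scan].type == "SPS_MS3"
        ms3_refs = {d.ms3_scan for d in log.decisions if d.ms3_scan is not None}
        for i, s in enumerate(log.scans):
            if s.type == "SPS_MS3":
                assert i in ms3_refs

    def test_window_discipline(self, small_run, config):
        """No IT-PRM is issued for a target outside the +/-3-bin window."""
        sc, lib, assay, log, _ = small_run
        trace = log.calib_trace
        target_bin = {t.key: t.bin for t in assay.targets}
        for s in log.scans:
            if s.type != "IT_PRM":
                continue
            c_at = [e["c"] for e in trace if e["t"] <= s.time and e["c"] is not None]
            assert c_at, "PRM before first calibration"
            center = round(c_at[-1])
            assert abs(target_bin[s.request.target_key] - center) <= (
                config.window_halfwidth_bins
            )

    def test_quantified_targets_close_out(self, small_run):
        sc, lib, assay, log, events = small_run
        from targetms.workflows import quantified_keys

        for key in quantified_keys(events, sc.label_scheme):
            assert assay.peptide_closed[key]

    def test_empty_assay_rejected(self, small_run, config):
        sc, lib, assay, _, _ = small_run
        empty = Assay(targets=[], config_snapshot={}, protein_goals={})
        with pytest.raises(ValueError):
            C.run_targeted(sc, empty, lib, config)

    def test_scheme_mismatch_rejected(self, small_run, config):
        sc, lib, assay, _, _ = small_run
        import dataclasses

        bad = dataclasses.replace(sc, label_scheme="TMT11",
                                  analytes=[], _arrays={})
        with pytest.raises(ValueError, match="scheme"):
            C.run_targeted(bad, assay, lib, config)

    def test_identical_inputs_identical_log_hash(self, config):
        from targetms.sim import library_from_scenario, make_proteome_scenario
        from targetms.workflows import assay_from_proteins

        sc = make_proteome_scenario(n_proteins=10, peptides_per_protein=1,
                                    gradient_s=300.0, seed=31)
        lib = library_from_scenario(sc)
        proteins = sorted({a.protein for a in sc.analytes})[:5]
        hashes = []
        for _ in range(2):
            assay = assay_from_proteins(proteins, lib, config=config)
            log, _ = C.run_targeted(sc, assay, lib, config, seed=31)
            hashes.append(log.log_hash())
        assert hashes[0] == hashes[1]


class TestDdaBaseline:
    def test_dynamic_exclusion_prevents_reselection(self, config):
        from targetms.sim import library_from_scenario, make_proteome_scenario

        sc = make_proteome_scenario(n_proteins=20, peptides_per_protein=1,
                                    gradient_s=600.0, seed=41)
        lib = library_from_scenario(sc)
        log, _ = C.run_dda_baseline(sc, lib, config, seed=41)
        selections: dict[float, list[float]] = {}
        for s in log.scans:
            if s.type != "CALIB_MS2":
                continue
            mz = s.request.center_mz
            times = [
                t for prev_mz, ts in selections.items()
                if abs(prev_mz - mz) <= mz * config.dyn_exclusion_ppm * 1e-6
                for t in ts
            ]
            if times:
                assert s.time - max(times) >= config.dyn_exclusion_s
            selections.setdefault(mz, []).append(s.time)

    def test_undetectable_analyte_never_selected(self, config):
        from targetms.sim import library_from_scenario

        from test_sim import toy_analyte, toy_scenario

        weak = toy_analyte(key="AAAAAAGK/2", coeff=1e-3, apex=100.0)
        strong = toy_analyte(key="CCCCCCGR/2", prec=700.0, coeff=1e5, apex=100.0)
        sc = toy_scenario([weak, strong], gradient_s=200.0)
        lib = library_from_scenario(sc)
        log, _ = C.run_dda_baseline(sc, lib, config, seed=1)
        centers = [s.request.center_mz for s in log.scans if s.type == "CALIB_MS2"]
        assert all(abs(c - 600.0) > 1.0 for c in centers)


def test_capacity_every_in_window_target_is_monitored(config):
    """A dense assay of abundant targets: every open target whose bin enters
    the calibrated window during the run receives at least one PRM."""
    from targetms.sim import library_from_scenario, make_proteome_scenario
    from targetms.workflows import assay_from_proteins

    sc = make_proteome_scenario(
        n_proteins=100, peptides_per_protein=2, abundance_log10_sigma=0.3,
        gradient_s=900.0, seed=51,
    )
    lib = library_from_scenario(sc)
    proteins = sorted({a.protein for a in sc.analytes})
    assay = assay_from_proteins(proteins, lib, k=2, config=config)
    log, _ = C.run_targeted(sc, assay, lib, config, seed=51)
    centers = [round(e["c"]) for e in log.calib_trace if e["c"] is not None]
    visited = {
        t.key
        for t in assay.targets
        if any(abs(t.bin - c) <= config.window_halfwidth_bins for c in centers)
    }
    prm_targets = {s.request.target_key for s in log.scans if s.type == "IT_PRM"}
    assert visited <= prm_targets
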