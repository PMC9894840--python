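"""The real-time acquisition decision engine.

Targeted mode alternates two activities across the gradient. Every 15 s a
*calibration episode* fragments the top MS1 peaks, identifies them with a
fast library search, and maps the identifications to elution-library bins;
the running elution point ``c`` is the monotone running median of accepted
episode bins, extrapolated at the library's bin rate when an episode comes
back empty. Between episodes the controller cycles rapid ion-trap PRM scans
over every open target whose library bin lies within +/-3 bins of ``c``.
A PRM matching >= 6 monitored fragments promotes a 900-ms Orbitrap MS2;
cosine > 0.9 against the library spectrum plus > 60% coverage of its
high-abundance fragments confirms identity; pure fragments (>= 0.75 of the
ion current in their 1-Da notch) become SPS ions for a 2000-ms MS3 whose
reporter region is the quantification readout. Quantified peptides close
out and are never rescheduled, including across injections sharing an assay.

A conventional top-N DDA baseline with real-time search gating (dynamic
exclusion 120 s at +/-7 ppm, 250-ms MS3 fills) is provided for sensitivity
comparisons on identical scenarios.

The real-time scorer is a normalized matched-fragment count standing in for
a cross-correlation search engine, with the published acceptance gates
mapped onto it (|ppm| < 10, length >= 7, score >= 0.5, margin to the
runner-up >= 0.10, best match not a reversed-sequence decoy). It sits behind
:class:`SearchIndex` and is swappable.
"""

from __future__ import annotations

import hashlib
import statistics
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace

import numpy as np

from . import chem
from .assay import Assay, AssayTarget
from .config import AcquisitionConfig
from .libraries import LibraryBundle
from .quant import QuantEvent, extract_reporters, EVENT_PURITY_MIN, SUMMED_SN_MIN
from .sim import SampleScenario, ScanRecord, ScanRequest, VirtualInstrument

MAX_SCORED_FRAGMENTS = 20

STAGES = ("none", "prm_matched", "id_confirmed", "quantified")


@dataclass(frozen=True)
class TriggerDecision:
    """Outcome of one targeted attempt on one peptide."""

    target_key: str
    stage: str
    matched_fragments: int = 0
    cosine: float = 0.0
    coverage: float = 0.0
    n_notches: int = 0
    prm_scan: int | None = None
    otms2_scan: int | None = None
    ms3_scan: int | None = None
    reason: str = ""


@dataclass
class AcquisitionLog:
    mode: str
    config_hash: str
    scans: list[ScanRecord] = field(default_factory=list)
    decisions: list[TriggerDecision] = field(default_factory=list)
    calib_trace: list[dict] = field(default_factory=list)
    closeout_events: list[dict] = field(default_factory=list)

    def add_scan(self, record: ScanRecord) -> int:
        self.scans.append(record)
        return len(self.scans) - 1

    def log_hash(self) -> str:
        h = hashlib.sha1()
        for s in self.scans:
            h.update(
                f"{s.type}|{s.time:.4f}|{s.realized_it_ms:.4f}|"
                f"{len(s.peaks_mz)}|{float(np.sum(s.peaks_int)):.4f}\n".encode()
            )
        for d in self.decisions:
            h.update(f"{d.target_key}|{d.stage}|{d.matched_fragments}\n".encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Real-time library search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Candidate:
    key: str
    precursor_mz: float
    frag_mz: np.ndarray
    n_frag: int
    decoy: bool
    sequence: str


class SearchIndex:
    """Precursor-indexed target + reversed-decoy candidates for the
    simplified real-time scorer."""

    def __init__(self, candidates: list[_Candidate]):
        self.candidates = sorted(candidates, key=lambda c: c.precursor_mz)
        self._mz = [c.precursor_mz for c in self.candidates]

    @classmethod
    def from_library(cls, lib: LibraryBundle) -> "SearchIndex":
        cands: list[_Candidate] = []
        for entry in lib.spectral.values():
            order = np.argsort(entry.peaks_int)[::-1][:MAX_SCORED_FRAGMENTS]
            fmz = np.sort(np.asarray(entry.peaks_mz)[order])
            prec = entry.precursor_mz
            if prec is None:
                pep = chem.apply_label_scheme(
                    entry.sequence, lib.label_scheme, charge=entry.charge
                )
                prec = chem.precursor_mz(chem.peptide_neutral_mass(pep), entry.charge)
            cands.append(
                _Candidate(entry.key, prec, fmz, len(fmz), False, entry.sequence)
            )
            # reversed-sequence decoy: same precursor mass, shuffled backbone
            rev_seq = entry.sequence[:-1][::-1] + entry.sequence[-1]
            rev_pep = chem.apply_label_scheme(
                rev_seq, lib.label_scheme, charge=entry.charge
            )
            rev_mz = np.sort(
                np.array([mz for _, mz in chem.fragment_ladder(rev_pep)])
            )[:MAX_SCORED_FRAGMENTS]
            cands.append(
                _Candidate(
                    f"rev_{entry.key}", prec, rev_mz, len(rev_mz), True, rev_seq
                )
            )
        return cls(cands)

    def window(self, mz: float, ppm: float) -> list[_Candidate]:
        half = mz * ppm * 1e-6
        lo = bisect_left(self._mz, mz - half)
        hi = bisect_right(self._mz, mz + half)
        return self.candidates[lo:hi]


def _match_count(sorted_scan_mz: np.ndarray, frag_mz: np.ndarray, tol: float) -> int:
    if len(sorted_scan_mz) == 0 or len(frag_mz) == 0:
        return 0
    pos = np.searchsorted(sorted_scan_mz, frag_mz)
    left = np.clip(pos - 1, 0, len(sorted_scan_mz) - 1)
    right = np.clip(pos, 0, len(sorted_scan_mz) - 1)
    d = np.minimum(
        np.abs(sorted_scan_mz[left] - frag_mz), np.abs(sorted_scan_mz[right] - frag_mz)
    )
    return int((d <= tol).sum())


def realtime_search(
    scan: ScanRecord,
    observed_precursor_mz: float,
    index: SearchIndex,
    config: AcquisitionConfig,
) -> tuple[str | None, float, str]:
    """Score candidates within the precursor search window; apply the
    acceptance gates. Returns (accepted key or None, best score, reason)."""
    cands = index.window(observed_precursor_mz, config.precursor_search_ppm)
    if not cands:
        return None, 0.0, "no candidates"
    scan_mz = scan.peaks_mz  # instrument emits sorted m/z
    scored = sorted(
        (
            (
                _match_count(scan_mz, c.frag_mz, config.it_frag_tol_da) / c.n_frag
                if c.n_frag
                else 0.0,
                c.key,
                c,
            )
            for c in cands
        ),
        key=lambda t: (-t[0], t[1]),
    )
    best_score, _, best = scored[0]
    runner = scored[1][0] if len(scored) > 1 else 0.0
    if best.decoy:
        return None, best_score, "decoy top match"
    ppm = abs(observed_precursor_mz - best.precursor_mz) / best.precursor_mz * 1e6
    if ppm >= config.ppm_max:
        return None, best_score, "ppm"
    if len(best.sequence) < config.min_peptide_length:
        return None, best_score, "length"
    if best_score < config.score_min:
        return None, best_score, "score"
    if best_score - runner < config.delta_score_min:
        return None, best_score, "delta"
    return best.key, best_score, "accepted"


# ---------------------------------------------------------------------------
# Elution calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationState:
    """Monotone elution-point estimate ``c`` (in bins) plus a bins/s rate."""

    c: float | None = None
    rate: float | None = None
    last_update_t: float | None = None
    last_accept: tuple[float, float] | None = None  # (t, c) of last accepted


def calibrate_elution_point(
    state: CalibrationState,
    episode_bins: list[int],
    now: float,
    config: AcquisitionConfig,
) -> CalibrationState:
    """Median of the episode's bins, floored at the previous estimate; empty
    episodes extrapolate at the estimated (default 1 bin per bin-width) rate."""
    default_rate = 1.0 / config.bin_width_s
    if episode_bins:
        m = float(statistics.median(episode_bins))
        c_new = m if state.c is None else max(state.c, m)
        rate = state.rate
        if state.last_accept is not None:
            t0, c0 = state.last_accept
            if now > t0 and c_new > c0:
                rate = (c_new - c0) / (now - t0)
        return CalibrationState(
            c=c_new, rate=rate, last_update_t=now, last_accept=(now, c_new)
        )
    if state.c is None:
        return replace(state, last_update_t=now)
    dt = now - (state.last_update_t if state.last_update_t is not None else now)
    rate = state.rate if state.rate is not None else default_rate
    return replace(state, c=state.c + rate * dt, last_update_t=now)


def run_calibration_episode(
    instrument: VirtualInstrument,
    ms1: ScanRecord,
    index: SearchIndex,
    lib: LibraryBundle,
    config: AcquisitionConfig,
) -> tuple[list[tuple[str, int]], list[ScanRecord]]:
    """Fragment the top-N MS1 peaks, search each fast MS2, and map accepted
    identifications to elution-library bins."""
    accepted: list[tuple[str, int]] = []
    scans: list[ScanRecord] = []
    if len(ms1.peaks_mz) == 0:
        return accepted, scans
    order = np.argsort(ms1.peaks_int)[::-1][: config.calib_topn]
    for j in order:
        center = float(ms1.peaks_mz[j])
        scan = instrument.execute(
            ScanRequest(
                type="CALIB_MS2",
                time=instrument.clock,
                center_mz=center,
                width_mz=config.isolation_width_da,
                max_it_ms=config.max_it_calib_ms2_ms,
            )
        )
        scans.append(scan)
        key, _, _ = realtime_search(scan, center, index, config)
        if key is not None and key in lib.elution:
            accepted.append((key, lib.elution[key].bin))
    return accepted, scans


# ---------------------------------------------------------------------------
# Targeting primitives
# ---------------------------------------------------------------------------

def schedule_prm_targets(
    assay: Assay, state: CalibrationState, config: AcquisitionConfig
) -> list[AssayTarget]:
    """Open targets within +/- window_halfwidth bins of round(c), in
    deterministic (bin, key) order."""
    if state.c is None:
        return []
    center = round(state.c)
    hw = config.window_halfwidth_bins
    return [
        t
        for t in sorted(assay.targets, key=lambda t: (t.bin, t.key))
        if abs(t.bin - center) <= hw and assay.is_open(t)
    ]


def evaluate_prm_match(
    scan: ScanRecord, target: AssayTarget, config: AcquisitionConfig
) -> tuple[int, bool]:
    """Count monitored fragments present in the ion-trap PRM within the
    coarse tolerance; trigger at >= min_prm_fragments."""
    if scan.request.target_key is not None and scan.request.target_key != target.key:
        raise ValueError("PRM scan/target mismatch")
    matched = _match_count(
        scan.peaks_mz, np.asarray(target.frag_mz), config.it_frag_tol_da
    )
    return matched, matched >= config.min_prm_fragments


def _project_onto_library(
    scan: ScanRecord, frag_mz: np.ndarray, tol_ppm: float
) -> np.ndarray:
    """Experimental intensity at each library fragment position within a ppm
    tolerance (0 when unmatched); multiple peaks in tolerance take the max."""
    exp = np.zeros(len(frag_mz))
    if len(scan.peaks_mz) == 0:
        return exp
    for i, mz in enumerate(frag_mz):
        half = mz * tol_ppm * 1e-6
        lo = np.searchsorted(scan.peaks_mz, mz - half)
        hi = np.searchsorted(scan.peaks_mz, mz + half, side="right")
        if hi > lo:
            exp[i] = float(scan.peaks_int[lo:hi].max())
    return exp


def evaluate_identification(
    scan: ScanRecord,
    frag_mz,
    frag_int,
    config: AcquisitionConfig,
) -> tuple[float, float, bool]:
    """Cosine of the experimental spectrum projected onto the library peak
    positions, plus coverage of the library's high-abundance fragments.

    Passes only when cosine > cosine_min AND coverage > coverage_min, both
    strict.
    """
    frag_mz = np.asarray(frag_mz, dtype=float)
    frag_int = np.asarray(frag_int, dtype=float)
    if len(frag_mz) == 0:
        raise ValueError("empty library entry")
    exp = _project_onto_library(scan, frag_mz, config.ot_frag_tol_ppm)
    ne, nl = np.linalg.norm(exp), np.linalg.norm(frag_int)
    cosine = float(exp @ frag_int / (ne * nl)) if ne > 0 and nl > 0 else 0.0
    hi = frag_int > config.rel_abundance_cut * frag_int.max()
    coverage = float((exp[hi] > 0).sum() / hi.sum()) if hi.any() else 0.0
    passed = cosine > config.cosine_min and coverage > config.coverage_min
    return cosine, coverage, passed


def select_sps_ions(
    scan: ScanRecord,
    frag_mz,
    frag_int,
    config: AcquisitionConfig,
    tol_da: float | None = None,
) -> tuple[list[tuple[float, float]], list[float], list[float]]:
    """Pick up to sps_max matched library fragments whose share of the ion
    current inside their notch (half-width 1 Da) meets the per-ion purity
    threshold. Returns (notches, purities, intensities of kept ions)."""
    frag_mz = np.asarray(frag_mz, dtype=float)
    candidates: list[tuple[float, float, float]] = []  # (exp_int, exp_mz, purity)
    for mz in frag_mz:
        if tol_da is not None:
            half = tol_da
        else:
            half = mz * config.ot_frag_tol_ppm * 1e-6
        lo = np.searchsorted(scan.peaks_mz, mz - half)
        hi = np.searchsorted(scan.peaks_mz, mz + half, side="right")
        if hi <= lo:
            continue
        j = lo + int(np.argmax(scan.peaks_int[lo:hi]))
        exp_mz = float(scan.peaks_mz[j])
        exp_int = float(scan.peaks_int[j])
        nlo = np.searchsorted(scan.peaks_mz, exp_mz - config.sps_notch_halfwidth_da)
        nhi = np.searchsorted(
            scan.peaks_mz, exp_mz + config.sps_notch_halfwidth_da, side="right"
        )
        total = float(scan.peaks_int[nlo:nhi].sum())
        purity = exp_int / total if total > 0 else 0.0
        candidates.append((exp_int, exp_mz, purity))
    candidates.sort(key=lambda t: -t[0])
    notches, purities, intensities = [], [], []
    for exp_int, exp_mz, purity in candidates:
        if purity >= config.sps_ion_purity_min:
            notches.append((exp_mz, config.sps_notch_halfwidth_da))
            purities.append(purity)
            intensities.append(exp_int)
            if len(notches) >= config.sps_max:
                break
    return notches, purities, intensities


def update_close_out(
    assay: Assay, event: QuantEvent, config: AcquisitionConfig
) -> None:
    """Mark the event's peptide closed; close its protein once the
    quantified-peptide count reaches the protein's goal. Monotone: flags are
    never unset."""
    if event.key not in assay.peptide_closed:
        raise KeyError(f"unknown assay peptide {event.key}")
    if not assay.peptide_closed[event.key]:
        assay.peptide_closed[event.key] = True
        assay.protein_quantified_count[event.protein] = (
            assay.protein_quantified_count.get(event.protein, 0) + 1
        )


# ---------------------------------------------------------------------------
# Run loops
# ---------------------------------------------------------------------------

def _event_passes_quant_filters(event: QuantEvent, scheme: str) -> bool:
    return (
        event.summed_sn > SUMMED_SN_MIN[scheme]
        and event.purity > EVENT_PURITY_MIN
    )


def run_targeted(
    scenario: SampleScenario,
    assay: Assay,
    library: LibraryBundle,
    config: AcquisitionConfig | None = None,
    seed: int | None = None,
) -> tuple[AcquisitionLog, list[QuantEvent]]:
    """Execute one targeted injection of the scenario against the assay.

    Returns the full acquisition log (every scan, decision, calibration
    update, and close-out event) and the raw quantification events; close-out
    state persists on the assay across calls.
    """
    config = config or AcquisitionConfig()
    if not assay.targets:
        raise ValueError("empty assay")
    if scenario.label_scheme != library.label_scheme:
        raise ValueError(
            f"scenario scheme {scenario.label_scheme} != library "
            f"{library.label_scheme}"
        )
    seed = config.seed if seed is None else seed
    inst = VirtualInstrument(
        scenario,
        seed=seed,
        ms1_min_intensity=config.ms1_min_intensity,
        ms2_min_intensity=config.ms2_min_intensity,
        agc_ms1=config.agc_ms1,
        agc_ms2=config.agc_ms2,
        agc_ms3=config.agc_ms3,
    )
    index = SearchIndex.from_library(library)
    state = CalibrationState()
    log = AcquisitionLog(mode="targeted", config_hash=config.config_hash)
    events: list[QuantEvent] = []
    reporter_mz = scenario.reporter_mz

    # targets sorted by bin for fast window queries
    targets = sorted(assay.targets, key=lambda t: (t.bin, t.key))
    bins = [t.bin for t in targets]
    prm_due = {t.key: 0.0 for t in targets}
    protein_of = {t.key: t.protein for t in targets}

    next_calib = 0.0
    while inst.clock < scenario.gradient_s:
        if inst.clock >= next_calib:
            ms1 = inst.execute(
                ScanRequest(type="MS1", time=inst.clock, max_it_ms=config.max_it_ms1_ms)
            )
            log.add_scan(ms1)
            accepted, scans = run_calibration_episode(inst, ms1, index, library, config)
            for s in scans:
                log.add_scan(s)
            state = calibrate_elution_point(
                state, [b for _, b in accepted], inst.clock, config
            )
            log.calib_trace.append(
                {
                    "t": inst.clock,
                    "c": state.c,
                    "episode_bins": [b for _, b in accepted],
                    "n_ids": len(accepted),
                }
            )
            next_calib += config.calib_period_s
            continue

        in_window: list[AssayTarget] = []
        if state.c is not None:
            center = round(state.c)
            lo = bisect_left(bins, center - config.window_halfwidth_bins)
            hi = bisect_right(bins, center + config.window_halfwidth_bins)
            in_window = [t for t in targets[lo:hi] if assay.is_open(t)]
        due = [t for t in in_window if prm_due[t.key] <= inst.clock]
        if not due:
            horizon = [next_calib]
            horizon.extend(prm_due[t.key] for t in in_window)
            inst.clock = max(inst.clock + 0.02, min(horizon))
            continue

        # serve the longest-waiting due target (round-robin under equal revisit)
        target = min(due, key=lambda t: (prm_due[t.key], t.bin, t.key))
        prm_due[target.key] = inst.clock + config.prm_revisit_s
        prm = inst.execute(
            ScanRequest(
                type="IT_PRM",
                time=inst.clock,
                center_mz=target.precursor_mz,
                width_mz=config.isolation_width_da,
                max_it_ms=config.max_it_itprm_ms,
                target_key=target.key,
            )
        )
        prm_idx = log.add_scan(prm)
        matched, trig = evaluate_prm_match(prm, target, config)
        if not trig:
            log.decisions.append(
                TriggerDecision(target.key, "none", matched, prm_scan=prm_idx)
            )
            continue
        ot = inst.execute(
            ScanRequest(
                type="OT_MS2",
                time=inst.clock,
                center_mz=target.precursor_mz,
                width_mz=config.isolation_width_da,
                max_it_ms=config.max_it_otms2_ms,
                target_key=target.key,
            )
        )
        ot_idx = log.add_scan(ot)
        cosine, coverage, ok = evaluate_identification(
            ot, target.frag_mz, target.frag_int, config
        )
        if not ok:
            log.decisions.append(
                TriggerDecision(
                    target.key,
                    "prm_matched",
                    matched,
                    cosine,
                    coverage,
                    prm_scan=prm_idx,
                    otms2_scan=ot_idx,
                )
            )
            continue
        notches, purities, intensities = select_sps_ions(
            ot, target.frag_mz, target.frag_int, config
        )
        if not notches:
            log.decisions.append(
                TriggerDecision(
                    target.key,
                    "id_confirmed",
                    matched,
                    cosine,
                    coverage,
                    prm_scan=prm_idx,
                    otms2_scan=ot_idx,
                    reason="no pure SPS ions",
                )
            )
            continue
        ms3 = inst.execute(
            ScanRequest(
                type="SPS_MS3",
                time=inst.clock,
                center_mz=target.precursor_mz,
                width_mz=config.isolation_width_da,
                notches=tuple(notches),
                max_it_ms=config.max_it_ms3_ms,
                target_key=target.key,
            )
        )
        ms3_idx = log.add_scan(ms3)
        _, sn = extract_reporters(ms3, reporter_mz)
        wsum = sum(intensities)
        purity = float(
            sum(p * w for p, w in zip(purities, intensities)) / wsum
        ) if wsum > 0 else 0.0
        event = QuantEvent(
            key=target.key,
            protein=protein_of[target.key],
            scan_index=ms3_idx,
            time_s=ms3.time,
            sn=tuple(sn),
            purity=purity,
            matched_fragments=matched,
        )
        events.append(event)
        log.decisions.append(
            TriggerDecision(
                target.key,
                "quantified",
                matched,
                cosine,
                coverage,
                n_notches=len(notches),
                prm_scan=prm_idx,
                otms2_scan=ot_idx,
                ms3_scan=ms3_idx,
            )
        )
        if _event_passes_quant_filters(event, scenario.label_scheme):
            update_close_out(assay, event, config)
            log.closeout_events.append(
                {"t": inst.clock, "key": target.key, "protein": target.protein}
            )
    return log, events


def run_dda_baseline(
    scenario: SampleScenario,
    library: LibraryBundle,
    config: AcquisitionConfig | None = None,
    seed: int | None = None,
) -> tuple[AcquisitionLog, list[QuantEvent]]:
    """Top-N data-dependent acquisition with real-time-search-gated SPS-MS3.

    Precursors are taken from each MS1 by descending intensity under dynamic
    exclusion (120 s, +/-7 ppm); accepted identifications get an SPS-MS3 with
    the short (250 ms) fill of conventional real-time-search methods.
    """
    config = config or AcquisitionConfig()
    seed = config.seed if seed is None else seed
    inst = VirtualInstrument(
        scenario,
        seed=seed,
        ms1_min_intensity=config.ms1_min_intensity,
        ms2_min_intensity=config.ms2_min_intensity,
        agc_ms1=config.agc_ms1,
        agc_ms2=config.agc_ms2,
        agc_ms3=config.agc_ms3,
    )
    index = SearchIndex.from_library(library)
    log = AcquisitionLog(mode="dda", config_hash=config.config_hash)
    events: list[QuantEvent] = []
    reporter_mz = scenario.reporter_mz
    excl_mz: list[float] = []
    excl_until: list[float] = []

    def excluded(mz: float, now: float) -> bool:
        if not excl_mz:
            return False
        arr = np.asarray(excl_mz)
        until = np.asarray(excl_until)
        return bool(
            ((np.abs(arr - mz) <= mz * config.dyn_exclusion_ppm * 1e-6)
             & (until > now)).any()
        )

    while inst.clock < scenario.gradient_s:
        cycle_start = inst.clock
        ms1 = inst.execute(
            ScanRequest(type="MS1", time=inst.clock, max_it_ms=config.max_it_ms1_ms)
        )
        log.add_scan(ms1)
        order = np.argsort(ms1.peaks_int)[::-1]
        selected = 0
        for j in order:
            if selected >= config.rts_topn:
                break
            if inst.clock - cycle_start >= config.rts_cycle_s:
                break
            center = float(ms1.peaks_mz[j])
            if excluded(center, inst.clock):
                continue
            ms2 = inst.execute(
                ScanRequest(
                    type="CALIB_MS2",
                    time=inst.clock,
                    center_mz=center,
                    width_mz=config.isolation_width_da,
                    max_it_ms=config.max_it_calib_ms2_ms,
                )
            )
            ms2_idx = log.add_scan(ms2)
            excl_mz.append(center)
            excl_until.append(inst.clock + config.dyn_exclusion_s)
            selected += 1
            key, score, _ = realtime_search(ms2, center, index, config)
            if key is None:
                continue
            entry = library.spectral[key]
            notches, purities, intensities = select_sps_ions(
                ms2,
                entry.peaks_mz,
                entry.peaks_int,
                config,
                tol_da=config.it_frag_tol_da,
            )
            if not notches:
                continue
            ms3 = inst.execute(
                ScanRequest(
                    type="SPS_MS3",
                    time=inst.clock,
                    center_mz=center,
                    width_mz=config.isolation_width_da,
                    notches=tuple(notches[: config.sps_max]),
                    max_it_ms=config.rts_ms3_max_it_ms,
                    target_key=key,
                )
            )
            ms3_idx = log.add_scan(ms3)
            _, sn = extract_reporters(ms3, reporter_mz)
            wsum = sum(intensities)
            purity = float(
                sum(p * w for p, w in zip(purities, intensities)) / wsum
            ) if wsum > 0 else 0.0
            matched = int(round(score * min(len(entry.peaks_mz), MAX_SCORED_FRAGMENTS)))
            events.append(
                QuantEvent(
                    key=key,
                    protein=entry.proteins[0] if entry.proteins else "",
                    scan_index=ms3_idx,
                    time_s=ms3.time,
                    sn=tuple(sn),
                    purity=purity,
                    matched_fragments=matched,
                )
            )
            log.decisions.append(
                TriggerDecision(
                    key,
                    "quantified",
                    matched,
                    otms2_scan=ms2_idx,
                    ms3_scan=ms3_idx,
                )
            )
        # prune stale exclusion entries occasionally
        if len(excl_mz) > 4096:
            keep = [i for i, u in enumerate(excl_until) if u > inst.clock]
            excl_mz = [excl_mz[i] for i in keep]
            excl_until = [excl_until[i] for i in keep]
    return log, events
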