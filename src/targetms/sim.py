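"""Discrete-event virtual LC-MS/MS instrument and multiplexed sample.

The sample is a set of analytes, each a labeled tryptic peptide with a
per-channel abundance vector, a Gaussian elution peak (apex, sigma), and a
flux coefficient converting abundance to ion flux (counts/s) at the source.
The instrument answers scan requests against this ground truth:

* ``MS1`` — one peak per eluting analyte at its precursor m/z.
* ``PRESCAN`` — total incoming flux in a window, for AGC bookkeeping.
* ``CALIB_MS2`` / ``IT_PRM`` — fast ion-trap fragment scans (coarse mass
  accuracy, 0.1 Da jitter) of everything co-isolated in the precursor window.
* ``OT_MS2`` — the same at Orbitrap accuracy (3 ppm jitter).
* ``SPS_MS3`` — several fragment notches are co-isolated and the reporter
  region is read out per channel; co-isolated foreign fragments contribute
  their own channel profile, which is how isobaric interference arises.

Ion accumulation follows a simple AGC model: fill time =
min(max injection, AGC target / incoming flux), so weak signals integrate up
to the cap and reporter intensities are linear in fill below it. Counting
(Poisson) noise is optional; mass jitter is part of the analyzer model and is
always drawn from the seeded generator, so identical request streams
reproduce bit-identical records.

Every peak carries a hidden attribution map (analyte -> fraction of the
peak's ion current). The acquisition controller never reads it; tests and
oracles do.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import chem

# -- reporter ion m/z tables (standard published values) --------------------

TMT11_CHANNELS = (
    "126", "127N", "127C", "128N", "128C", "129N",
    "129C", "130N", "130C", "131N", "131C",
)
TMT11_REPORTER_MZ = (
    126.127726, 127.124761, 127.131081, 128.128116, 128.134436, 129.131471,
    129.137790, 130.134825, 130.141145, 131.138180, 131.144500,
)
TMTPRO16_CHANNELS = TMT11_CHANNELS + (
    "132N", "132C", "133N", "133C", "134N",
)
TMTPRO16_REPORTER_MZ = TMT11_REPORTER_MZ + (
    132.141535, 132.147855, 133.144890, 133.151210, 134.148245,
)

REPORTER_TABLES = {
    "TMT11": dict(zip(TMT11_CHANNELS, TMT11_REPORTER_MZ)),
    "TMTpro16": dict(zip(TMTPRO16_CHANNELS, TMTPRO16_REPORTER_MZ)),
}

PLEX_SIZE = {"TMT11": 11, "TMTpro16": 16}

#: Analyzer mass-accuracy model: ion trap absolute sd (Da), Orbitrap ppm sd.
IT_MZ_SD_DA = 0.1
OT_MZ_PPM_SD = 3.0

#: Fixed per-scan overheads (s), excluding injection time.
SCAN_OVERHEAD_S = {
    "MS1": 0.06,
    "PRESCAN": 0.01,
    "CALIB_MS2": 0.03,
    "IT_PRM": 0.03,
    "OT_MS2": 0.12,
    "SPS_MS3": 0.15,
}

_ELUTION_CUTOFF_SIGMA = 6.0


@dataclass(frozen=True)
class Analyte:
    """Ground-truth description of one peptide species in the sample."""

    key: str
    sequence: str
    charge: int
    protein: str
    channel_abundance: tuple[float, ...]
    apex_s: float
    sigma_s: float
    flux_coeff: float
    frag_mz: tuple[float, ...]
    frag_rel: tuple[float, ...]  # relative fragment yields, sum == 1
    precursor_mz: float
    cv: str = "CV0"
    role: str = "background"  # spike | background | interferer

    def __post_init__(self):
        if self.sigma_s <= 0:
            raise ValueError("peak sigma must be > 0")
        if any(a < 0 for a in self.channel_abundance):
            raise ValueError("channel abundances must be >= 0")

    @property
    def total_abundance(self) -> float:
        return float(sum(self.channel_abundance))


def elution_intensity(analyte: Analyte, t: float) -> float:
    """Instantaneous ion flux (counts/s) of an analyte at time ``t``."""
    z = (t - analyte.apex_s) / analyte.sigma_s
    if abs(z) > _ELUTION_CUTOFF_SIGMA:
        return 0.0
    return analyte.flux_coeff * analyte.total_abundance * math.exp(-0.5 * z * z)


@dataclass
class SampleScenario:
    """A virtual multiplexed sample plus its noise model."""

    analytes: list[Analyte]
    label_scheme: str
    gradient_s: float
    counting_noise: bool = True
    mass_jitter: bool = True
    noise_floor: float = 1.0
    channel_mode: str = "reporter"  # or "abstract" for unit tests
    seed: int = 0
    _arrays: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.label_scheme not in PLEX_SIZE:
            raise ValueError(f"unknown label scheme {self.label_scheme!r}")
        plex = PLEX_SIZE[self.label_scheme]
        for a in self.analytes:
            if len(a.channel_abundance) != plex:
                raise ValueError(
                    f"{a.key}: abundance vector length {len(a.channel_abundance)}"
                    f" != plex {plex}"
                )
            if not (0.0 <= a.apex_s <= self.gradient_s):
                raise ValueError(f"{a.key}: apex outside the gradient")

    @property
    def plex(self) -> int:
        return PLEX_SIZE[self.label_scheme]

    @property
    def reporter_mz(self) -> np.ndarray:
        if self.channel_mode == "abstract":
            return 100.0 + np.arange(self.plex, dtype=float)
        return np.array(
            [REPORTER_TABLES[self.label_scheme][c] for c in self.channel_labels]
        )

    @property
    def channel_labels(self) -> tuple[str, ...]:
        if self.channel_mode == "abstract":
            return tuple(f"ch{i}" for i in range(self.plex))
        return (TMT11_CHANNELS if self.label_scheme == "TMT11" else TMTPRO16_CHANNELS)

    def arrays(self) -> dict:
        """Vectorized ground truth, computed once."""
        if not self._arrays:
            A = self.analytes
            abund = np.array([a.channel_abundance for a in A], dtype=float)
            tot = abund.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                chanfrac = np.where(tot[:, None] > 0, abund / tot[:, None], 0.0)
            self._arrays = {
                "prec_mz": np.array([a.precursor_mz for a in A]),
                "apex": np.array([a.apex_s for a in A]),
                "sigma": np.array([a.sigma_s for a in A]),
                "coeff": np.array([a.flux_coeff for a in A]),
                "tot_abund": tot,
                "chanfrac": chanfrac,
                "cv": np.array([a.cv for a in A]),
            }
        return self._arrays

    def flux_at(self, t: float) -> np.ndarray:
        arr = self.arrays()
        z = (t - arr["apex"]) / arr["sigma"]
        out = np.zeros(len(self.analytes))
        mask = np.abs(z) <= _ELUTION_CUTOFF_SIGMA
        out[mask] = (
            arr["coeff"][mask] * arr["tot_abund"][mask] * np.exp(-0.5 * z[mask] ** 2)
        )
        return out

    # -- persistence ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "label_scheme": self.label_scheme,
                "gradient_s": self.gradient_s,
                "counting_noise": self.counting_noise,
                "mass_jitter": self.mass_jitter,
                "noise_floor": self.noise_floor,
                "channel_mode": self.channel_mode,
                "seed": self.seed,
                "analytes": [
                    {
                        "key": a.key,
                        "sequence": a.sequence,
                        "charge": a.charge,
                        "protein": a.protein,
                        "channel_abundance": list(a.channel_abundance),
                        "apex_s": a.apex_s,
                        "sigma_s": a.sigma_s,
                        "flux_coeff": a.flux_coeff,
                        "frag_mz": list(a.frag_mz),
                        "frag_rel": list(a.frag_rel),
                        "precursor_mz": a.precursor_mz,
                        "cv": a.cv,
                        "role": a.role,
                    }
                    for a in self.analytes
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SampleScenario":
        d = json.loads(text)
        return cls(
            analytes=[
                Analyte(
                    key=a["key"],
                    sequence=a["sequence"],
                    charge=a["charge"],
                    protein=a["protein"],
                    channel_abundance=tuple(a["channel_abundance"]),
                    apex_s=a["apex_s"],
                    sigma_s=a["sigma_s"],
                    flux_coeff=a["flux_coeff"],
                    frag_mz=tuple(a["frag_mz"]),
                    frag_rel=tuple(a["frag_rel"]),
                    precursor_mz=a["precursor_mz"],
                    cv=a["cv"],
                    role=a["role"],
                )
                for a in d["analytes"]
            ],
            label_scheme=d["label_scheme"],
            gradient_s=d["gradient_s"],
            counting_noise=d["counting_noise"],
            mass_jitter=d.get("mass_jitter", True),
            noise_floor=d["noise_floor"],
            channel_mode=d.get("channel_mode", "reporter"),
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# Scenario generators
# ---------------------------------------------------------------------------

_SEQ_ALPHABET = "ADEFGHILNPQSTVWY"  # internal residues; K/R reserved for C-term


def _random_peptide(rng: np.random.Generator, used: set[str]) -> tuple[str, int]:
    while True:
        n = int(rng.integers(7, 16))
        seq = "".join(rng.choice(list(_SEQ_ALPHABET), size=n)) + str(
            rng.choice(["K", "R"])
        )
        if seq not in used:
            used.add(seq)
            charge = int(rng.choice([2, 3], p=[0.7, 0.3]))
            return seq, charge


def _make_analyte(
    rng: np.random.Generator,
    used: set[str],
    scheme: str,
    channel_abundance: np.ndarray,
    apex_s: float,
    protein: str,
    role: str,
    sigma_s: float = 8.0,
    flux_coeff: float = 2e4,
) -> Analyte:
    seq, charge = _random_peptide(rng, used)
    pep = chem.apply_label_scheme(seq, scheme, charge=charge)
    prec = chem.precursor_mz(chem.peptide_neutral_mass(pep), charge)
    ladder = chem.fragment_ladder(pep)
    mzs = np.array([mz for _, mz in ladder])
    # lognormal fragment yields: a few dominant ions, a long tail
    rel = rng.lognormal(mean=0.0, sigma=1.0, size=len(mzs))
    rel /= rel.sum()
    coeff = flux_coeff * 10 ** rng.normal(0.0, 0.25)
    return Analyte(
        key=f"{seq}/{charge}",
        sequence=seq,
        charge=charge,
        protein=protein,
        channel_abundance=tuple(channel_abundance),
        apex_s=apex_s,
        sigma_s=sigma_s * float(10 ** rng.normal(0.0, 0.05)),
        flux_coeff=coeff,
        frag_mz=tuple(mzs),
        frag_rel=tuple(rel),
        precursor_mz=prec,
        role=role,
    )


def make_adh1_scenario(
    n_spike_peptides: int = 12,
    design_ratios: Sequence[float] = (1.0, 2.0, 4.0),
    replicates: int = 3,
    dilution_factor: float = 1.0,
    background_size: int = 150,
    gradient_s: float = 1200.0,
    spike_level: float = 0.5,
    counting_noise: bool = False,
    seed: int = 0,
) -> SampleScenario:
    """Protein-standard spike-in sample in a constant whole-proteome background.

    The spike peptides follow the given ratio groups (default 1:2:4 in
    triplicate) across the middle channels of an 11-plex, with the first and
    last channels left blank to measure baseline interference. Background
    peptides are mixed 1:1 across all channels. ``dilution_factor`` scales
    spike abundances down by 1/factor, emulating a serial dilution.
    """
    plex = PLEX_SIZE["TMT11"]
    n_signal = len(design_ratios) * replicates
    if n_signal + 2 > plex + 1:  # 2 blanks flank the signal channels
        raise ValueError("design longer than plex")
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    spike_vec = np.zeros(plex)
    start = (plex - n_signal) // 2
    for g, ratio in enumerate(design_ratios):
        for r in range(replicates):
            spike_vec[start + g * replicates + r] = ratio * spike_level
    spike_vec /= dilution_factor
    analytes = []
    for i in range(n_spike_peptides):
        apex = gradient_s * float(rng.uniform(0.08, 0.92))
        analytes.append(
            _make_analyte(rng, used, "TMT11", spike_vec, apex, "ADH1_SPIKE", "spike")
        )
    for i in range(background_size):
        level = float(10 ** rng.normal(0.0, 0.5))
        vec = np.full(plex, level)
        apex = gradient_s * float(rng.uniform(0.02, 0.98))
        analytes.append(
            _make_analyte(
                rng, used, "TMT11", vec, apex, f"BG{i:04d}", "background"
            )
        )
    return SampleScenario(
        analytes=analytes,
        label_scheme="TMT11",
        gradient_s=gradient_s,
        counting_noise=counting_noise,
        seed=seed,
    )


def make_proteome_scenario(
    n_proteins: int,
    peptides_per_protein: int = 2,
    abundance_log10_sigma: float = 1.2,
    label_scheme: str = "TMTpro16",
    channel_design: Sequence[float] | None = None,
    gradient_s: float = 1800.0,
    counting_noise: bool = True,
    seed: int = 0,
) -> SampleScenario:
    """Whole-proteome-like sample with log-normal protein abundances.

    Protein abundances span several orders of magnitude (log10 sd default
    1.2, the shape of deep proteome iBAQ distributions); peptide flux is the
    protein abundance times a per-peptide yield factor. Channels follow
    ``channel_design`` (default 1:1).
    """
    if n_proteins < 0 or peptides_per_protein < 0:
        raise ValueError("sizes must be >= 0")
    plex = PLEX_SIZE[label_scheme]
    design = np.ones(plex) if channel_design is None else np.asarray(
        channel_design, dtype=float
    )
    if len(design) != plex:
        raise ValueError("channel design length != plex")
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    analytes = []
    for p in range(n_proteins):
        protein = f"P{p:04d}"
        abundance = float(10 ** rng.normal(0.0, abundance_log10_sigma))
        for _ in range(peptides_per_protein):
            yield_factor = float(10 ** rng.normal(0.0, 0.3))
            vec = design * abundance * yield_factor
            apex = gradient_s * float(rng.uniform(0.02, 0.98))
            analytes.append(
                _make_analyte(rng, used, label_scheme, vec, apex, protein, "background")
            )
    return SampleScenario(
        analytes=analytes,
        label_scheme=label_scheme,
        gradient_s=gradient_s,
        counting_noise=counting_noise,
        seed=seed,
    )


def warp_gradient(scenario: SampleScenario, exponent: float = 1.15) -> SampleScenario:
    """Monotone nonlinear warp of all elution apexes, t' = L * (t/L)**exponent.

    Models a changed LC gradient: elution *order* is preserved while absolute
    times shift, which is exactly the regime real-time calibration must absorb.
    """
    L = scenario.gradient_s
    warped = [
        replace(a, apex_s=L * (a.apex_s / L) ** exponent) for a in scenario.analytes
    ]
    return replace(scenario, analytes=warped, _arrays={})


def unwarp_time(t: float, gradient_s: float, exponent: float = 1.15) -> float:
    """Inverse of the gradient warp: the original-run time whose analytes
    elute at warped-run time ``t``."""
    return gradient_s * (t / gradient_s) ** (1.0 / exponent)


# ---------------------------------------------------------------------------
# Scan requests / records
# ---------------------------------------------------------------------------

SCAN_TYPES = ("MS1", "PRESCAN", "CALIB_MS2", "IT_PRM", "OT_MS2", "SPS_MS3")


@dataclass(frozen=True)
class ScanRequest:
    type: str
    time: float
    center_mz: float | None = None
    width_mz: float | None = None
    notches: tuple[tuple[float, float], ...] = ()  # (center, halfwidth) each
    max_it_ms: float = 50.0
    cv: str = "CV0"
    target_key: str | None = None  # echo only; never consulted by the sample


@dataclass
class ScanRecord:
    request: ScanRequest
    realized_it_ms: float
    peaks_mz: np.ndarray
    peaks_int: np.ndarray
    reporters: np.ndarray | None
    noise_est: float
    duration_s: float
    #: hidden ground-truth attribution; per-peak list of {analyte_key: frac}
    #: for MS1/MS2, a single {analyte_key: frac} map for SPS_MS3.
    attribution: list | dict | None = None

    @property
    def type(self) -> str:
        return self.request.type

    @property
    def time(self) -> float:
        return self.request.time


class VirtualInstrument:
    """Executes scan requests against a scenario, advancing an internal clock."""

    def __init__(self, scenario: SampleScenario, seed: int = 0,
                 ms1_min_intensity: float = 50.0, ms2_min_intensity: float = 2.0,
                 agc_ms1: float = 2e5, agc_ms2: float = 5e4, agc_ms3: float = 1e5):
        self.scenario = scenario
        self.rng = np.random.default_rng(seed)
        self.clock = 0.0
        self.ms1_min_intensity = ms1_min_intensity
        self.ms2_min_intensity = ms2_min_intensity
        self.agc = {"MS1": agc_ms1, "MS2": agc_ms2, "MS3": agc_ms3}

    # -- helpers -------------------------------------------------------
    def _jitter(self, mz: np.ndarray, analyzer: str) -> np.ndarray:
        if not self.scenario.mass_jitter or len(mz) == 0:
            return mz
        if analyzer == "it":
            return mz + self.rng.normal(0.0, IT_MZ_SD_DA, size=len(mz))
        return mz * (1.0 + self.rng.normal(0.0, OT_MZ_PPM_SD * 1e-6, size=len(mz)))

    def _counts(self, expected: np.ndarray) -> np.ndarray:
        if self.scenario.counting_noise:
            return self.rng.poisson(np.maximum(expected, 0.0)).astype(float)
        return expected

    def _eluting_mask(self, t: float, cv: str) -> np.ndarray:
        arr = self.scenario.arrays()
        flux = self.scenario.flux_at(t)
        return (flux > 0) & (arr["cv"] == cv), flux

    # -- main entry ----------------------------------------------------
    def execute(self, request: ScanRequest) -> ScanRecord:
        if request.type not in SCAN_TYPES:
            raise ValueError(f"unknown scan type {request.type!r}")
        if request.time < self.clock - 1e-9:
            raise ValueError(
                f"scan requested in the past: {request.time:.3f} < {self.clock:.3f}"
            )
        self.clock = max(self.clock, request.time)
        handler = {
            "MS1": self._do_ms1,
            "PRESCAN": self._do_prescan,
            "CALIB_MS2": self._do_ms2,
            "IT_PRM": self._do_ms2,
            "OT_MS2": self._do_ms2,
            "SPS_MS3": self._do_ms3,
        }[request.type]
        record = handler(request)
        record.duration_s = SCAN_OVERHEAD_S[request.type] + record.realized_it_ms / 1e3
        self.clock += record.duration_s
        return record

    # -- scan handlers -------------------------------------------------
    def _do_ms1(self, req: ScanRequest) -> ScanRecord:
        t = self.clock
        mask, flux = self._eluting_mask(t, req.cv)
        total = float(flux[mask].sum())
        fill_s = min(req.max_it_ms / 1e3, self.agc["MS1"] / total) if total > 0 else (
            req.max_it_ms / 1e3
        )
        arr = self.scenario.arrays()
        idx = np.flatnonzero(mask)
        expected = flux[idx] * fill_s
        counts = self._counts(expected)
        keep = counts >= self.ms1_min_intensity
        idx, counts = idx[keep], counts[keep]
        mz = self._jitter(arr["prec_mz"][idx], "ot")
        order = np.argsort(mz)
        attribution = [
            {self.scenario.analytes[i].key: 1.0} for i in idx[order]
        ]
        return ScanRecord(
            request=req,
            realized_it_ms=fill_s * 1e3,
            peaks_mz=mz[order],
            peaks_int=counts[order],
            reporters=None,
            noise_est=max(self.scenario.noise_floor, 1.0),
            duration_s=0.0,
            attribution=attribution,
        )

    def _do_prescan(self, req: ScanRequest) -> ScanRecord:
        t = self.clock
        mask, flux = self._eluting_mask(t, req.cv)
        if req.center_mz is not None and req.width_mz is not None:
            arr = self.scenario.arrays()
            mask = mask & (
                np.abs(arr["prec_mz"] - req.center_mz) <= req.width_mz / 2
            )
        total = float(flux[mask].sum())
        return ScanRecord(
            request=req,
            realized_it_ms=req.max_it_ms,
            peaks_mz=np.array([req.center_mz or 0.0]),
            peaks_int=np.array([total]),
            reporters=None,
            noise_est=max(self.scenario.noise_floor, 1.0),
            duration_s=0.0,
            attribution=[{}],
        )

    def _isolated(self, t: float, req: ScanRequest) -> tuple[np.ndarray, np.ndarray]:
        if req.center_mz is None or req.width_mz is None:
            raise ValueError(f"{req.type} requires an isolation window")
        mask, flux = self._eluting_mask(t, req.cv)
        arr = self.scenario.arrays()
        mask = mask & (np.abs(arr["prec_mz"] - req.center_mz) <= req.width_mz / 2)
        return np.flatnonzero(mask), flux

    def _do_ms2(self, req: ScanRequest) -> ScanRecord:
        analyzer = "ot" if req.type == "OT_MS2" else "it"
        idx, flux = self._isolated(self.clock, req)
        total = float(flux[idx].sum())
        fill_s = min(req.max_it_ms / 1e3, self.agc["MS2"] / total) if total > 0 else (
            req.max_it_ms / 1e3
        )
        mz_parts, int_parts, attr = [], [], []
        for i in idx:
            a = self.scenario.analytes[i]
            expected = flux[i] * np.asarray(a.frag_rel) * fill_s
            counts = self._counts(expected)
            keep = counts >= self.ms2_min_intensity
            if not keep.any():
                continue
            mz_parts.append(np.asarray(a.frag_mz)[keep])
            int_parts.append(counts[keep])
            attr.extend({a.key: 1.0} for _ in range(int(keep.sum())))
        if mz_parts:
            mz = self._jitter(np.concatenate(mz_parts), analyzer)
            inten = np.concatenate(int_parts)
            order = np.argsort(mz)
            mz, inten = mz[order], inten[order]
            attr = [attr[j] for j in order]
        else:
            mz = np.array([])
            inten = np.array([])
            attr = []
        return ScanRecord(
            request=req,
            realized_it_ms=fill_s * 1e3,
            peaks_mz=mz,
            peaks_int=inten,
            reporters=None,
            noise_est=max(self.scenario.noise_floor, 1.0),
            duration_s=0.0,
            attribution=attr,
        )

    def _do_ms3(self, req: ScanRequest) -> ScanRecord:
        if not req.notches:
            raise ValueError("SPS_MS3 requires a non-empty notch list")
        idx, flux = self._isolated(self.clock, req)
        arr = self.scenario.arrays()
        # flux of each co-isolated analyte entering the notches
        influx = {}
        for i in idx:
            a = self.scenario.analytes[i]
            fmz = np.asarray(a.frag_mz)
            captured = np.zeros(len(fmz), dtype=bool)
            for center, hw in req.notches:
                captured |= np.abs(fmz - center) <= hw
            share = float(np.asarray(a.frag_rel)[captured].sum())
            if share > 0:
                influx[i] = flux[i] * share
        total = sum(influx.values())
        fill_s = min(req.max_it_ms / 1e3, self.agc["MS3"] / total) if total > 0 else (
            req.max_it_ms / 1e3
        )
        plex = self.scenario.plex
        expected = np.zeros(plex)
        for i, fin in influx.items():
            expected += fin * arr["chanfrac"][i] * fill_s
        reporters = self._counts(expected)
        noise_est = max(self.scenario.noise_floor, 1.0)
        rep_mz = self.scenario.reporter_mz.copy()
        if self.scenario.mass_jitter:
            rep_mz = rep_mz + self.rng.normal(0.0, 0.0008, size=plex)
        nz = reporters > 0
        attribution = (
            {self.scenario.analytes[i].key: fin / total for i, fin in influx.items()}
            if total > 0
            else {}
        )
        return ScanRecord(
            request=req,
            realized_it_ms=fill_s * 1e3,
            peaks_mz=rep_mz[nz],
            peaks_int=reporters[nz],
            reporters=reporters,
            noise_est=noise_est,
            duration_s=0.0,
            attribution=attribution,
        )


# ---------------------------------------------------------------------------
# Ground-truth-derived library (the in-silico analog of a prior library run)
# ---------------------------------------------------------------------------

def library_from_scenario(
    scenario: SampleScenario,
    bin_width_s: float = 30.0,
    roles: Sequence[str] = ("spike", "background"),
) -> "LibraryBundle":
    """Build the paired spectral/elution library a previous deep run of this
    sample would have produced: per analyte, its fragment pattern as the
    spectrum and floor(apex / bin width) as the elution bin."""
    from .libraries import (  # local import to avoid a cycle
        ElutionLibraryEntry,
        LibraryBundle,
        SpectralLibraryEntry,
    )

    spectral, elution = {}, {}
    for a in scenario.analytes:
        if a.role not in roles:
            continue
        intensities = tuple(1e4 * r for r in a.frag_rel)
        spectral[a.key] = SpectralLibraryEntry(
            key=a.key,
            peaks_mz=a.frag_mz,
            peaks_int=intensities,
            proteins=(a.protein,),
            best_score=3.0 + math.log10(a.total_abundance + 1e-12),
            fraction="sim",
            id_time_s=a.apex_s,
            precursor_mz=a.precursor_mz,
        )
        elution[a.key] = ElutionLibraryEntry(
            key=a.key,
            bin=int(a.apex_s // bin_width_s),
            raw_id_time_s=a.apex_s,
        )
    return LibraryBundle(
        spectral=spectral,
        elution=elution,
        bin_width_s=bin_width_s,
        label_scheme=scenario.label_scheme,
        meta={"run": "simulated-library-run"},
    )
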