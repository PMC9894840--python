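"""Acquisition configuration.

All decision thresholds of the real-time controller live here, with the
published operating point as defaults: 30-s elution bins, a +/-3-bin targeting
window, a calibration episode every 15 s fragmenting the top 6 MS1 peaks,
>=6 matched fragments to promote an ion-trap PRM, cosine > 0.9 plus > 60%
coverage of high-abundance library fragments to confirm identity, up to 10
SPS ions above a 0.75 per-ion purity, and ultra-long fills (900 ms OT-MS2,
2000 ms SPS-MS3). The DDA baseline uses 120-s dynamic exclusion at +/-7 ppm
and a 250-ms MS3 fill.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass


@dataclass(frozen=True)
class AcquisitionConfig:
    # Elution calibration / targeting geometry
    bin_width_s: float = 30.0
    window_halfwidth_bins: int = 3
    calib_period_s: float = 15.0
    calib_topn: int = 6
    # Trigger chain thresholds
    min_prm_fragments: int = 6
    cosine_min: float = 0.9
    coverage_min: float = 0.6
    rel_abundance_cut: float = 0.5
    sps_max: int = 10
    sps_ion_purity_min: float = 0.75
    sps_notch_halfwidth_da: float = 1.0
    # Injection-time caps (ms) and AGC targets (charges)
    max_it_ms1_ms: float = 50.0
    max_it_itprm_ms: float = 200.0
    max_it_otms2_ms: float = 900.0
    max_it_ms3_ms: float = 2000.0
    max_it_calib_ms2_ms: float = 35.0
    rts_ms3_max_it_ms: float = 250.0
    agc_ms1: float = 2e5
    agc_ms2: float = 5e4
    agc_ms3: float = 1e5
    # Matching tolerances
    it_frag_tol_da: float = 0.4
    ot_frag_tol_ppm: float = 10.0
    precursor_search_ppm: float = 50.0
    isolation_width_da: float = 0.7
    # Real-time search acceptance filters
    ppm_max: float = 10.0
    min_peptide_length: int = 7
    score_min: float = 0.5
    delta_score_min: float = 0.10
    # DDA baseline
    dyn_exclusion_s: float = 120.0
    dyn_exclusion_ppm: float = 7.0
    rts_topn: int = 10
    rts_cycle_s: float = 1.2
    # Scheduling / instrument realism
    prm_revisit_s: float = 1.0
    ms1_min_intensity: float = 50.0
    ms2_min_intensity: float = 2.0
    # Close-out: peptides needed to close a protein; None = all assay peptides
    protein_closeout_goal: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.bin_width_s <= 0:
            raise ValueError("bin_width_s must be > 0")
        if self.window_halfwidth_bins < 0:
            raise ValueError("window_halfwidth_bins must be >= 0")
        for name in ("cosine_min", "coverage_min", "rel_abundance_cut",
                     "sps_ion_purity_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_prm_fragments < 1 or self.sps_max < 1:
            raise ValueError("fragment/SPS counts must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        """Short stable hash stamped into run logs and quant provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_toml(cls, path: str) -> "AcquisitionConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))
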