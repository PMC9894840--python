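"""Spectral and elution library construction from PSM tables.

A spectral library keeps, per unique (sequence, variable mods, charge) key,
the fragment spectrum of the single best-scoring PSM. An elution library maps
the same key to an elution-order bin: the best PSM's identification time
divided by a fixed bin width (30 s by default). Identification times are
recorded as-is, without retention-time alignment between fractions; relative
elution order, not absolute time, is what the acquisition controller consumes.

Ties in score are broken by earlier identification time, then lexicographic
key, so library builds are fully deterministic. Decoy PSMs (accession prefix
``rev_``) never enter a library; a helper chooses a plain score threshold
that keeps the decoy fraction at or below a target FDR.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

DECOY_PREFIX = "rev_"

REQUIRED_PSM_COLUMNS = (
    "peptide",
    "mods",
    "charge",
    "score",
    "id_time_s",
    "fraction",
    "proteins",
    "spectrum",
)


@dataclass(frozen=True)
class PsmRecord:
    """One row of an upstream search result."""

    sequence: str
    mods: str  # variable-mod signature, e.g. "oxidation@3"; "" if none
    charge: int
    score: float
    id_time_s: float
    fraction: str
    proteins: tuple[str, ...]
    decoy: bool
    ppm_error: float
    peaks_mz: tuple[float, ...]
    peaks_int: tuple[float, ...]

    def __post_init__(self):
        if self.id_time_s < 0:
            raise ValueError("id_time_s must be >= 0")
        if not math.isfinite(self.score):
            raise ValueError("score must be finite")
        if any(i < 0 for i in self.peaks_int):
            raise ValueError("peak intensities must be >= 0")

    @property
    def key(self) -> str:
        base = f"{self.sequence}/{self.charge}"
        return base + (f"/{self.mods}" if self.mods else "")


@dataclass(frozen=True)
class SpectralLibraryEntry:
    key: str
    peaks_mz: tuple[float, ...]
    peaks_int: tuple[float, ...]
    proteins: tuple[str, ...]
    best_score: float
    fraction: str
    id_time_s: float
    precursor_mz: float | None = None

    def __post_init__(self):
        if not self.peaks_mz:
            raise ValueError(f"library entry {self.key} has no peaks")
        if len(self.peaks_mz) != len(self.peaks_int):
            raise ValueError("peak m/z and intensity lengths differ")

    @property
    def base_peak_intensity(self) -> float:
        return max(self.peaks_int)

    @property
    def sequence(self) -> str:
        return self.key.split("/", 1)[0]

    @property
    def charge(self) -> int:
        return int(self.key.split("/")[1])


@dataclass(frozen=True)
class ElutionLibraryEntry:
    key: str
    bin: int
    raw_id_time_s: float


@dataclass
class LibraryBundle:
    """Paired spectral + elution libraries with identical key sets."""

    spectral: dict[str, SpectralLibraryEntry]
    elution: dict[str, ElutionLibraryEntry]
    bin_width_s: float
    label_scheme: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.bin_width_s <= 0:
            raise ValueError("bin_width_s must be > 0")
        extra = set(self.elution) - set(self.spectral)
        if extra:
            raise ValueError(f"elution keys missing from spectral library: {sorted(extra)[:3]}")

    def __len__(self) -> int:
        return len(self.spectral)

    def keys(self):
        return self.spectral.keys()

    # -- persistence ---------------------------------------------------
    def to_json(self) -> str:
        entries = []
        for key in sorted(self.spectral):
            s = self.spectral[key]
            e = self.elution.get(key)
            entries.append(
                {
                    "key": key,
                    "peaks": [[round(m, 6), round(i, 6)] for m, i in zip(s.peaks_mz, s.peaks_int)],
                    "proteins": list(s.proteins),
                    "score": s.best_score,
                    "fraction": s.fraction,
                    "id_time_s": s.id_time_s,
                    "precursor_mz": s.precursor_mz,
                    "bin": e.bin if e else None,
                }
            )
        return json.dumps(
            {
                "version": 1,
                "bin_width_s": self.bin_width_s,
                "label_scheme": self.label_scheme,
                "meta": self.meta,
                "entries": entries,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "LibraryBundle":
        d = json.loads(text)
        spectral, elution = {}, {}
        for ent in d["entries"]:
            key = ent["key"]
            mz, it = zip(*ent["peaks"])
            spectral[key] = SpectralLibraryEntry(
                key=key,
                peaks_mz=tuple(mz),
                peaks_int=tuple(it),
                proteins=tuple(ent["proteins"]),
                best_score=ent["score"],
                fraction=ent["fraction"],
                id_time_s=ent["id_time_s"],
                precursor_mz=ent.get("precursor_mz"),
            )
            if ent["bin"] is not None:
                elution[key] = ElutionLibraryEntry(
                    key=key,
                    bin=ent["bin"],
                    raw_id_time_s=ent["id_time_s"],
                )
        return cls(spectral, elution, d["bin_width_s"], d["label_scheme"], d.get("meta", {}))

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str) -> "LibraryBundle":
        with open(path) as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# PSM table adapter
# ---------------------------------------------------------------------------

def _parse_spectrum(text: str) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Parse 'mz:intensity;mz:intensity;...'."""
    mzs, ints = [], []
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        m, i = part.split(":")
        mzs.append(float(m))
        ints.append(float(i))
    return tuple(mzs), tuple(ints)


def format_spectrum(mz: Sequence[float], intensity: Sequence[float]) -> str:
    return ";".join(f"{m:.5f}:{i:.4f}" for m, i in zip(mz, intensity))


def read_psm_table(source) -> list[PsmRecord]:
    """Read a TSV of PSMs (one row per match) into records.

    Decoy status is derived from the accession convention: any protein whose
    accession starts with ``rev_`` marks the PSM as a decoy. Unparsable rows
    raise with the offending 0-based row index.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table missing required columns: {missing}")
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            proteins = tuple(p for p in str(row.proteins).split(";") if p)
            mzs, ints = _parse_spectrum(row.spectrum)
            records.append(
                PsmRecord(
                    sequence=row.peptide,
                    mods=row.mods,
                    charge=int(row.charge),
                    score=float(row.score),
                    id_time_s=float(row.id_time_s),
                    fraction=row.fraction,
                    proteins=proteins,
                    decoy=any(p.startswith(DECOY_PREFIX) for p in proteins),
                    ppm_error=float(getattr(row, "ppm_error", 0.0) or 0.0),
                    peaks_mz=mzs,
                    peaks_int=ints,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"unparsable PSM row {idx}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# Library builders
# ---------------------------------------------------------------------------

def _best_psm_per_key(psms: Iterable[PsmRecord]) -> dict[str, PsmRecord]:
    """Deterministic best PSM per key: score desc, id_time asc, key asc."""
    ranked = sorted(psms, key=lambda p: (-p.score, p.id_time_s, p.key))
    best: dict[str, PsmRecord] = {}
    for p in ranked:
        best.setdefault(p.key, p)
    return best


def build_spectral_library(psms: Iterable[PsmRecord]) -> dict[str, SpectralLibraryEntry]:
    """One entry per unique key from the maximum-score non-decoy PSM."""
    targets = [p for p in psms if not p.decoy]
    for p in targets:
        if not p.peaks_mz:
            raise ValueError(f"PSM for {p.key} lacks a spectrum")
    return {
        key: SpectralLibraryEntry(
            key=key,
            peaks_mz=p.peaks_mz,
            peaks_int=p.peaks_int,
            proteins=p.proteins,
            best_score=p.score,
            fraction=p.fraction,
            id_time_s=p.id_time_s,
        )
        for key, p in _best_psm_per_key(targets).items()
    }


def build_elution_library(
    psms: Iterable[PsmRecord], bin_width_s: float = 30.0
) -> dict[str, ElutionLibraryEntry]:
    """Bin = floor(best PSM id_time / bin width), per unique non-decoy key."""
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be > 0")
    best = _best_psm_per_key(p for p in psms if not p.decoy)
    return {
        key: ElutionLibraryEntry(
            key=key,
            bin=int(p.id_time_s // bin_width_s),
            raw_id_time_s=p.id_time_s,
        )
        for key, p in best.items()
    }


def build_library_bundle(
    psms: Sequence[PsmRecord],
    bin_width_s: float = 30.0,
    label_scheme: str = "TMTpro16",
    meta: dict | None = None,
) -> LibraryBundle:
    return LibraryBundle(
        spectral=build_spectral_library(psms),
        elution=build_elution_library(psms, bin_width_s),
        bin_width_s=bin_width_s,
        label_scheme=label_scheme,
        meta=meta or {},
    )


def merge_libraries(a: LibraryBundle, b: LibraryBundle) -> LibraryBundle:
    """Key union; on conflict the entry pair with the higher best-PSM score
    wins (spectral and elution entries move together)."""
    if a.bin_width_s != b.bin_width_s:
        raise ValueError("cannot merge libraries with different bin widths")
    if a.label_scheme != b.label_scheme:
        raise ValueError("cannot merge libraries with different label schemes")
    spectral = dict(a.spectral)
    elution = dict(a.elution)
    for key, entry in b.spectral.items():
        if key not in spectral or entry.best_score > spectral[key].best_score:
            spectral[key] = entry
            if key in b.elution:
                elution[key] = b.elution[key]
            else:
                elution.pop(key, None)
    meta = {"merged_from": [a.meta.get("run", "a"), b.meta.get("run", "b")]}
    return LibraryBundle(spectral, elution, a.bin_width_s, a.label_scheme, meta)


def score_threshold_for_fdr(
    psms: Sequence[PsmRecord], max_decoy_fraction: float = 0.01
) -> float:
    """Smallest score cut such that decoys / total <= ``max_decoy_fraction``
    among PSMs at or above the cut. Full FDR modeling is assumed upstream;
    this is a plain target-decoy threshold.
    """
    if not psms:
        return float("inf")
    order = sorted(psms, key=lambda p: -p.score)
    decoys = 0
    best_cut = float("inf")
    for i, p in enumerate(order, start=1):
        decoys += p.decoy
        if decoys / i <= max_decoy_fraction:
            best_cut = p.score
    return best_cut
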