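"""Post-acquisition reporter-ion quantification.

Reporter signal is extracted from each SPS-MS3 scan within a 0.003 Da
tolerance and expressed as signal-to-noise (SN). Events are filtered on
summed SN (> 100 for TMT11, > 160 for TMTpro16) and SPS isolation purity
(> 0.7, strict). Per peptide, at most the top three events by matched
fragment count are kept and summed channel-wise; matrices are then column
normalized to equalize channel loading, blank-channel interference is
subtracted for spike-in designs, and peptides roll up to proteins by summing
over protein-unique peptides.

The summed-SN filter is applied before top-3 selection; the order is a
package choice, documented in the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AcquisitionConfig
from .sim import REPORTER_TABLES, ScanRecord

REPORTER_TOL_DA = 0.003

SUMMED_SN_MIN = {"TMT11": 100.0, "TMTpro16": 160.0}
EVENT_PURITY_MIN = 0.7


@dataclass(frozen=True)
class QuantEvent:
    """Reporter readout of one SPS-MS3 scan for one peptide target."""

    key: str
    protein: str
    scan_index: int
    time_s: float
    sn: tuple[float, ...]
    purity: float
    matched_fragments: int

    def __post_init__(self):
        if any(x < 0 for x in self.sn):
            raise ValueError("SN values must be >= 0")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must lie in [0, 1]")

    @property
    def summed_sn(self) -> float:
        return float(sum(self.sn))


def extract_reporters(
    ms3: ScanRecord,
    channel_mz: Mapping[str, float] | Sequence[float],
    tol: float = REPORTER_TOL_DA,
) -> tuple[np.ndarray, np.ndarray]:
    """Per channel, the nearest peak within ``tol`` of the reporter m/z
    (else 0); returns (intensity, SN) arrays."""
    if ms3.type != "SPS_MS3":
        raise ValueError("reporter extraction requires an SPS_MS3 scan")
    mzs = (
        np.array(list(channel_mz.values()))
        if isinstance(channel_mz, Mapping)
        else np.asarray(channel_mz, dtype=float)
    )
    intensity = np.zeros(len(mzs))
    if len(ms3.peaks_mz):
        for c, target in enumerate(mzs):
            d = np.abs(ms3.peaks_mz - target)
            j = int(np.argmin(d))
            if d[j] <= tol:
                intensity[c] = ms3.peaks_int[j]
    sn = intensity / max(ms3.noise_est, 1e-12)
    return intensity, sn


def filter_quant_events(
    events: Iterable[QuantEvent],
    scheme: str,
    config: AcquisitionConfig | None = None,
) -> list[QuantEvent]:
    """Keep events with summed SN above the scheme threshold and isolation
    purity > 0.7; both comparisons strict."""
    if scheme not in SUMMED_SN_MIN:
        raise ValueError(f"unknown label scheme {scheme!r}")
    sn_min = SUMMED_SN_MIN[scheme]
    return [
        e for e in events if e.summed_sn > sn_min and e.purity > EVENT_PURITY_MIN
    ]


def aggregate_peptide_events(
    events: Sequence[QuantEvent],
) -> dict[str, np.ndarray]:
    """Per peptide, sum the channel SN vectors of at most the top three
    events ranked by matched fragment count (ties to higher summed SN, then
    earlier scan index for determinism)."""
    by_key: dict[str, list[QuantEvent]] = {}
    for e in events:
        by_key.setdefault(e.key, []).append(e)
    out: dict[str, np.ndarray] = {}
    for key, evs in by_key.items():
        ranked = sorted(
            evs, key=lambda e: (-e.matched_fragments, -e.summed_sn, e.scan_index)
        )[:3]
        out[key] = np.sum([np.asarray(e.sn) for e in ranked], axis=0)
    return out


def events_to_matrix(
    events: Sequence[QuantEvent], channel_labels: Sequence[str]
) -> pd.DataFrame:
    """Filtered events -> peptide x channel SN matrix (rows sorted by key)."""
    agg = aggregate_peptide_events(events)
    df = pd.DataFrame.from_dict(agg, orient="index", columns=list(channel_labels))
    return df.sort_index()


def normalize_columns(
    matrix: pd.DataFrame, reference_rows: Sequence[str] | None = None
) -> pd.DataFrame:
    """Scale each column so column sums equalize at the mean original sum.

    With ``reference_rows``, scaling factors come from those rows only
    (e.g. 1:1 loading-control peptides) and are applied to the whole matrix;
    this keeps deliberate ratio designs in the other rows intact.
    """
    ref = matrix if reference_rows is None else matrix.loc[list(reference_rows)]
    sums = ref.sum(axis=0)
    if (sums <= 0).any():
        bad = list(sums.index[sums <= 0])
        raise ValueError(f"zero-sum column(s): {bad}")
    factors = sums.mean() / sums
    out = matrix * factors
    out.attrs = dict(matrix.attrs)
    out.attrs["normalized"] = True
    return out


def subtract_blank_interference(
    matrix: pd.DataFrame, blank_channels: Sequence[str]
) -> pd.DataFrame:
    """Per row, subtract the mean of the blank channels from every non-blank
    channel, flooring at zero. Blank columns are retained for reporting but
    carry no meaning downstream."""
    blanks = list(blank_channels)
    if not blanks:
        raise ValueError("no blank channels designated")
    missing = [b for b in blanks if b not in matrix.columns]
    if missing:
        raise ValueError(f"blank channels not in matrix: {missing}")
    baseline = matrix[blanks].mean(axis=1)
    out = matrix.copy()
    signal_cols = [c for c in matrix.columns if c not in blanks]
    out[signal_cols] = (matrix[signal_cols].sub(baseline, axis=0)).clip(lower=0.0)
    out.attrs = dict(matrix.attrs)
    out.attrs["blank_subtracted"] = True
    return out


def rollup_proteins(
    peptide_matrix: pd.DataFrame, peptide_to_proteins: Mapping[str, Sequence[str]]
) -> tuple[pd.DataFrame, list[str]]:
    """Channel-wise sum over protein-unique peptides; peptides shared by
    several proteins contribute to none and are returned in the shared list."""
    unmapped = [k for k in peptide_matrix.index if k not in peptide_to_proteins]
    if unmapped:
        raise ValueError(f"unmapped peptide(s): {unmapped[:3]}")
    shared: list[str] = []
    rows: dict[str, np.ndarray] = {}
    for key in peptide_matrix.index:
        prots = list(peptide_to_proteins[key])
        if len(prots) != 1:
            shared.append(key)
            continue
        prot = prots[0]
        vec = peptide_matrix.loc[key].to_numpy(dtype=float)
        rows[prot] = rows.get(prot, 0.0) + vec
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(peptide_matrix.columns)
    ).sort_index()
    return out, shared


def summarize(
    matrix: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per row: group means and CVs, fold changes between consecutive named
    groups and vs. the first group, and a two-sided two-sample t-test between
    the last and first group."""
    names = list(groups)
    cols = {f"mean_{g}": matrix[list(ch)].mean(axis=1) for g, ch in groups.items()}
    for g, ch in groups.items():
        if len(ch) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 channels")
        sub = matrix[list(ch)]
        cols[f"cv_{g}"] = sub.std(axis=1, ddof=1) / sub.mean(axis=1).replace(0, np.nan)
    base = names[0]
    for g in names[1:]:
        cols[f"ratio_{g}_vs_{base}"] = cols[f"mean_{g}"] / cols[f"mean_{base}"].replace(
            0, np.nan
        )
    with warnings.catch_warnings():
        # zero-variance groups (noise-free replicates) are legitimate input;
        # the t statistic is nan there and downstream code must handle it
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(
            matrix[list(groups[names[-1]])],
            matrix[list(groups[base])],
            axis=1,
        )
    cols[f"t_{names[-1]}_vs_{base}"] = pd.Series(t, index=matrix.index)
    cols[f"p_{names[-1]}_vs_{base}"] = pd.Series(p, index=matrix.index)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def write_quant_events(events: Sequence[QuantEvent], path: str,
                       channel_labels: Sequence[str]) -> None:
    df = pd.DataFrame(
        {
            "key": [e.key for e in events],
            "protein": [e.protein for e in events],
            "scan_index": [e.scan_index for e in events],
            "time_s": [e.time_s for e in events],
            "purity": [e.purity for e in events],
            "matched_fragments": [e.matched_fragments for e in events],
            **{
                f"sn_{c}": [e.sn[i] for e in events]
                for i, c in enumerate(channel_labels)
            },
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_quant_events(path: str) -> list[QuantEvent]:
    df = pd.read_csv(path, sep="\t")
    sn_cols = [c for c in df.columns if c.startswith("sn_")]
    return [
        QuantEvent(
            key=row["key"],
            protein=row["protein"],
            scan_index=int(row["scan_index"]),
            time_s=float(row["time_s"]),
            sn=tuple(float(row[c]) for c in sn_cols),
            purity=float(row["purity"]),
            matched_fragments=int(row["matched_fragments"]),
        )
        for _, row in df.iterrows()
    ]


def write_matrix(matrix: pd.DataFrame, path: str, config_hash: str = "",
                 blanks: Sequence[str] = ()) -> None:
    """Matrix TSV with '#'-prefixed provenance header lines."""
    with open(path, "w") as fh:
        fh.write(f"#config_hash\t{config_hash}\n")
        fh.write(f"#normalized\t{bool(matrix.attrs.get('normalized'))}\n")
        fh.write(f"#blanks\t{','.join(blanks)}\n")
        matrix.to_csv(fh, sep="\t", index_label="row")


def read_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="row")
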