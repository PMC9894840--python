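"""Turn a protein target list plus a library bundle into an executable assay.

Per protein, up to ``k`` peptides (default 3) are selected from the library,
ranked by best-PSM score, then base-peak intensity, then key. Each selected
peptide becomes an :class:`AssayTarget` carrying its elution bin, precursor
m/z, and the top library fragments to monitor. Peptides with too few library
fragments to support PRM detection are skipped with a warning; proteins with
no library peptides are flagged untargetable rather than erroring.

Close-out state lives on the :class:`Assay` and persists across injections:
once a peptide is quantified it is never rescheduled, and a protein closes
when its quantified-peptide count reaches its goal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chem
from .config import AcquisitionConfig
from .libraries import LibraryBundle, SpectralLibraryEntry

#: Cap on monitored fragments per peptide; ion-trap PRM matching needs a
#: bounded set.
MAX_MONITORED_FRAGMENTS = 20


@dataclass
class TargetList:
    proteins: list[str]
    pinned_peptides: dict[str, list[str]] = field(default_factory=dict)
    k: int = 3

    def __post_init__(self):
        if not self.proteins:
            raise ValueError("empty target list")


def load_target_list(source, k: int = 3) -> TargetList:
    """Read a target CSV with a ``protein`` column and optional ``peptide``
    and ``charge`` columns; duplicates are collapsed with a warning."""
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if "protein" not in df.columns:
        raise ValueError("target list must have a 'protein' column")
    if len(df) == 0:
        raise ValueError("empty target list")
    proteins: list[str] = []
    pinned: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        prot = row["protein"].strip()
        if not prot:
            continue
        if prot in proteins:
            warnings.warn(f"duplicate target protein {prot!r} collapsed")
        else:
            proteins.append(prot)
        pep = row.get("peptide", "").strip() if "peptide" in df.columns else ""
        if pep:
            charge = row.get("charge", "").strip() if "charge" in df.columns else ""
            key = f"{pep}/{charge}" if charge else pep
            pinned.setdefault(prot, []).append(key)
    if not proteins:
        raise ValueError("empty target list")
    return TargetList(proteins=proteins, pinned_peptides=pinned, k=k)


@dataclass(frozen=True)
class AssayTarget:
    key: str
    protein: str
    bin: int
    precursor_mz: float
    frag_mz: tuple[float, ...]
    frag_int: tuple[float, ...]
    cv: str = "CV0"

    @property
    def sequence(self) -> str:
        return self.key.split("/", 1)[0]

    @property
    def charge(self) -> int:
        return int(self.key.split("/")[1])


@dataclass
class Assay:
    """Targets plus persistent close-out state for a targeting campaign."""

    targets: list[AssayTarget]
    config_snapshot: dict
    protein_goals: dict[str, int]
    untargetable: list[str] = field(default_factory=list)
    warnings_: list[str] = field(default_factory=list)
    peptide_closed: dict[str, bool] = field(default_factory=dict)
    protein_quantified_count: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for t in self.targets:
            self.peptide_closed.setdefault(t.key, False)
        for prot in self.protein_goals:
            self.protein_quantified_count.setdefault(prot, 0)

    @property
    def keys(self) -> set[str]:
        return {t.key for t in self.targets}

    def protein_closed(self, protein: str) -> bool:
        return self.protein_quantified_count.get(protein, 0) >= self.protein_goals.get(
            protein, 1
        )

    def is_open(self, target: AssayTarget) -> bool:
        return not self.peptide_closed[target.key] and not self.protein_closed(
            target.protein
        )

    def open_targets(self) -> list[AssayTarget]:
        return [t for t in self.targets if self.is_open(t)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_snapshot": self.config_snapshot,
                "protein_goals": self.protein_goals,
                "untargetable": self.untargetable,
                "warnings": self.warnings_,
                "peptide_closed": self.peptide_closed,
                "protein_quantified_count": self.protein_quantified_count,
                "targets": [
                    {
                        "key": t.key,
                        "protein": t.protein,
                        "bin": t.bin,
                        "precursor_mz": t.precursor_mz,
                        "frag_mz": list(t.frag_mz),
                        "frag_int": list(t.frag_int),
                        "cv": t.cv,
                    }
                    for t in self.targets
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "Assay":
        d = json.loads(text)
        return cls(
            targets=[
                AssayTarget(
                    key=t["key"],
                    protein=t["protein"],
                    bin=t["bin"],
                    precursor_mz=t["precursor_mz"],
                    frag_mz=tuple(t["frag_mz"]),
                    frag_int=tuple(t["frag_int"]),
                    cv=t.get("cv", "CV0"),
                )
                for t in d["targets"]
            ],
            config_snapshot=d["config_snapshot"],
            protein_goals=d["protein_goals"],
            untargetable=d.get("untargetable", []),
            warnings_=d.get("warnings", []),
            peptide_closed=d.get("peptide_closed", {}),
            protein_quantified_count=d.get("protein_quantified_count", {}),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str) -> "Assay":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _entry_rank(entry: SpectralLibraryEntry):
    return (-entry.best_score, -entry.base_peak_intensity, entry.key)


def rank_and_select_peptides(
    targets: TargetList, lib: LibraryBundle
) -> tuple[dict[str, list[str]], list[str]]:
    """Per protein, up to ``k`` library peptide keys; proteins absent from
    the library are returned in the untargetable list."""
    by_protein: dict[str, list[SpectralLibraryEntry]] = {}
    for entry in lib.spectral.values():
        if entry.key not in lib.elution:
            continue
        for prot in entry.proteins:
            by_protein.setdefault(prot, []).append(entry)
    selections: dict[str, list[str]] = {}
    untargetable: list[str] = []
    for prot in targets.proteins:
        pinned = targets.pinned_peptides.get(prot, [])
        candidates = sorted(by_protein.get(prot, []), key=_entry_rank)
        keys: list[str] = []
        for pin in pinned:
            match = [e.key for e in candidates if e.key == pin or e.sequence == pin]
            keys.extend(k for k in match if k not in keys)
        for e in candidates:
            if len(keys) >= targets.k:
                break
            if e.key not in keys:
                keys.append(e.key)
        if keys:
            selections[prot] = keys[: targets.k]
        else:
            untargetable.append(prot)
    return selections, untargetable


def build_assay(
    targets: TargetList,
    lib: LibraryBundle,
    config: AcquisitionConfig | None = None,
) -> Assay:
    """Assemble assay targets with bins, precursor m/z, and monitored
    fragments; raises only if *every* protein is untargetable."""
    config = config or AcquisitionConfig()
    selections, untargetable = rank_and_select_peptides(targets, lib)
    assay_targets: list[AssayTarget] = []
    warns: list[str] = []
    goals: dict[str, int] = {}
    for prot, keys in selections.items():
        kept: list[AssayTarget] = []
        for key in keys:
            entry = lib.spectral[key]
            if len(entry.peaks_mz) < config.min_prm_fragments:
                warns.append(
                    f"{key} skipped: {len(entry.peaks_mz)} library fragments "
                    f"< {config.min_prm_fragments}"
                )
                continue
            order = np.argsort(entry.peaks_int)[::-1][:MAX_MONITORED_FRAGMENTS]
            order = np.sort(order)  # keep m/z order among the kept top peaks
            prec = entry.precursor_mz
            if prec is None:
                pep = chem.apply_label_scheme(
                    entry.sequence, lib.label_scheme, charge=entry.charge
                )
                prec = chem.precursor_mz(chem.peptide_neutral_mass(pep), entry.charge)
            kept.append(
                AssayTarget(
                    key=key,
                    protein=prot,
                    bin=lib.elution[key].bin,
                    precursor_mz=prec,
                    frag_mz=tuple(entry.peaks_mz[i] for i in order),
                    frag_int=tuple(entry.peaks_int[i] for i in order),
                )
            )
        if kept:
            assay_targets.extend(kept)
            goal = config.protein_closeout_goal
            goals[prot] = len(kept) if goal is None else min(goal, len(kept))
        else:
            untargetable.append(prot)
    if not assay_targets:
        raise ValueError("no targetable proteins: assay would be empty")
    assay_targets.sort(key=lambda t: (t.bin, t.key))
    return Assay(
        targets=assay_targets,
        config_snapshot=config.to_dict(),
        protein_goals=goals,
        untargetable=sorted(set(untargetable)),
        warnings_=warns,
    )
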