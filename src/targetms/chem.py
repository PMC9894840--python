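"""Peptide and fragment mass arithmetic for isobarically labeled tryptic peptides.

Monoisotopic residue masses come from :mod:`pyteomics` (standard IUPAC atomic
masses); the proton and water constants are the values conventionally used in
proteome search engines. The modification table covers the labeling chemistry
used throughout the package: TMT 11-plex (+229.1629 Da) or TMTpro 16-plex
(+304.2071 Da) amine labels on the peptide N-terminus and every lysine side
chain, static carbamidomethylation of cysteine (+57.0215 Da), and up to three
variable methionine oxidations (+15.9949 Da).

Only singly charged b/y ladders are produced by default; higher fragment
charges are available but the ion-trap monitoring scans in the controller
match 1+ fragments only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from pyteomics import mass as _pmass

PROTON_MASS = 1.007276
WATER_MASS = 18.010565

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Monoisotopic residue (not free amino acid) masses, Da.
RESIDUE_MASSES: dict[str, float] = {
    aa: float(_pmass.std_aa_mass[aa]) for aa in CANONICAL_RESIDUES
}

#: Sentinel site for peptide N-terminal modifications.
NTERM = "nterm"


@dataclass(frozen=True)
class Modification:
    """A named mass delta with a site rule.

    ``sites`` holds the residue letters the modification may attach to;
    ``nterm_ok`` allows attachment to the peptide N-terminus. ``static``
    modifications are applied unconditionally by the label scheme;
    ``max_count`` bounds variable occurrences per peptide.
    """

    name: str
    delta: float
    sites: frozenset[str]
    nterm_ok: bool = False
    static: bool = True
    max_count: int | None = None

    def allows(self, site: int | str, sequence: str) -> bool:
        if site == NTERM:
            return self.nterm_ok
        if not isinstance(site, int) or not (0 <= site < len(sequence)):
            return False
        return sequence[site] in self.sites


class ModificationTable:
    """Registry of known modifications, serializable as JSON."""

    def __init__(self, mods: Iterable[Modification] = ()):
        self._mods: dict[str, Modification] = {}
        for m in mods:
            self.add(m)

    def add(self, mod: Modification) -> None:
        self._mods[mod.name] = mod

    def __getitem__(self, name: str) -> Modification:
        try:
            return self._mods[name]
        except KeyError:
            raise KeyError(f"unknown modification: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._mods

    def names(self) -> list[str]:
        return sorted(self._mods)

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "name": m.name,
                    "delta": m.delta,
                    "sites": sorted(m.sites),
                    "nterm_ok": m.nterm_ok,
                    "static": m.static,
                    "max_count": m.max_count,
                }
                for m in self._mods.values()
            ],
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModificationTable":
        return cls(
            Modification(
                name=d["name"],
                delta=d["delta"],
                sites=frozenset(d["sites"]),
                nterm_ok=d["nterm_ok"],
                static=d["static"],
                max_count=d.get("max_count"),
            )
            for d in json.loads(text)
        )


def default_modification_table() -> ModificationTable:
    return ModificationTable(
        [
            Modification("TMT11", 229.1629, frozenset("K"), nterm_ok=True),
            Modification("TMTpro16", 304.2071, frozenset("K"), nterm_ok=True),
            Modification("carbamidomethyl", 57.0215, frozenset("C")),
            Modification(
                "oxidation", 15.9949, frozenset("M"), static=False, max_count=3
            ),
        ]
    )


DEFAULT_MODIFICATIONS = default_modification_table()

#: Label scheme name -> (label modification name, reporter plex size).
LABEL_SCHEMES = {"TMT11": ("TMT11", 11), "TMTpro16": ("TMTpro16", 16)}


@dataclass(frozen=True)
class ModifiedPeptide:
    """A (possibly labeled) peptide with charge and explicit modifications.

    ``modifications`` is a tuple of ``(site, name)`` pairs where ``site`` is a
    0-based residue index or :data:`NTERM`. A lysine at position 0 under an
    active label scheme carries two labels: one N-terminal, one side-chain.
    """

    sequence: str
    charge: int
    modifications: tuple[tuple[int | str, str], ...] = ()

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        for aa in self.sequence:
            if aa not in RESIDUE_MASSES:
                raise ValueError(f"unknown residue letter: {aa!r}")

    @property
    def key(self) -> str:
        """Stable string key: sequence/charge[/sorted-mod-signature]."""
        var = sorted(
            f"{name}@{site}"
            for site, name in self.modifications
            if name == "oxidation"
        )
        base = f"{self.sequence}/{self.charge}"
        return base + ("/" + ",".join(var) if var else "")


def peptide_neutral_mass(
    peptide: ModifiedPeptide, table: ModificationTable | None = None
) -> float:
    """Monoisotopic neutral mass: residue sum + water + modification deltas."""
    table = table or DEFAULT_MODIFICATIONS
    total = WATER_MASS + sum(RESIDUE_MASSES[aa] for aa in peptide.sequence)
    for site, name in peptide.modifications:
        mod = table[name]
        if not mod.allows(site, peptide.sequence):
            raise ValueError(
                f"modification {name!r} not allowed at site {site!r} "
                f"of {peptide.sequence}"
            )
        total += mod.delta
    return total


def precursor_mz(neutral_mass: float, charge: int) -> float:
    """(M + z * proton) / z."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def apply_label_scheme(
    sequence: str,
    scheme: str,
    charge: int = 2,
    variable_mods: Sequence[tuple[int | str, str]] = (),
    table: ModificationTable | None = None,
) -> ModifiedPeptide:
    """Attach the static modifications of an isobaric label scheme.

    One label on the N-terminus, one on every lysine side chain, and
    carbamidomethyl on every cysteine; ``variable_mods`` are appended after
    validation against the table's site rules and ``max_count``.
    """
    table = table or DEFAULT_MODIFICATIONS
    if scheme not in LABEL_SCHEMES:
        raise ValueError(f"unknown label scheme: {scheme!r}")
    label_name, _ = LABEL_SCHEMES[scheme]
    mods: list[tuple[int | str, str]] = [(NTERM, label_name)]
    for i, aa in enumerate(sequence):
        if aa == "K":
            mods.append((i, label_name))
        elif aa == "C":
            mods.append((i, "carbamidomethyl"))
    counts: dict[str, int] = {}
    for site, name in variable_mods:
        mod = table[name]
        if not mod.allows(site, sequence):
            raise ValueError(
                f"variable modification {name!r} invalid at {site!r} of {sequence}"
            )
        counts[name] = counts.get(name, 0) + 1
        if mod.max_count is not None and counts[name] > mod.max_count:
            raise ValueError(f"more than {mod.max_count} {name!r} modifications")
        mods.append((site, name))
    return ModifiedPeptide(sequence, charge, tuple(mods))


def fragment_ladder(
    peptide: ModifiedPeptide,
    ion_types: Iterable[str] = ("b", "y"),
    frag_charges: Iterable[int] = (1,),
    table: ModificationTable | None = None,
) -> list[tuple[str, float]]:
    """b/y fragment m/z ladder with modification deltas placed on the
    fragment that contains the modified site.

    N-terminal modifications travel with b ions; a modification at residue
    index ``i`` is carried by ``b_j`` for ``j > i`` and by ``y_j`` for
    ``j >= n - i``. Returns ``(label, mz)`` pairs, e.g. ``("b2+1", 356.1)``;
    a length-1 peptide yields an empty ladder.
    """
    table = table or DEFAULT_MODIFICATIONS
    for t in ion_types:
        if t not in ("b", "y"):
            raise ValueError(f"unknown ion type: {t!r}")
    n = len(peptide.sequence)
    if n < 2:
        return []
    # Per-position mass including site modifications; N-term delta separate.
    pos_mass = [RESIDUE_MASSES[aa] for aa in peptide.sequence]
    nterm_delta = 0.0
    for site, name in peptide.modifications:
        delta = table[name].delta
        if site == NTERM:
            nterm_delta += delta
        else:
            pos_mass[site] += delta

    ladder: list[tuple[str, float]] = []
    if "b" in ion_types:
        acc = nterm_delta
        for i in range(n - 1):
            acc += pos_mass[i]
            for z in frag_charges:
                ladder.append((f"b{i + 1}+{z}", (acc + z * PROTON_MASS) / z))
    if "y" in ion_types:
        acc = WATER_MASS
        for j in range(n - 1):
            acc += pos_mass[n - 1 - j]
            for z in frag_charges:
                ladder.append((f"y{j + 1}+{z}", (acc + z * PROTON_MASS) / z))
    return ladder
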