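"""Monoisotopic mass arithmetic for peptides, fragment ions, and neutral losses.

Everything downstream (fragment enumeration, annotation, the synthetic
generator) rests on the arithmetic here: residue masses, molecular formulas,
charge-state m/z, and the halved neutral-loss shifts characteristic of
doubly charged precursors.

Masses are monoisotopic throughout; adducts other than protons are out of
scope.  The proton mass is fixed at 1.007276 Da.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "parse_formula",
    "formula_mass",
    "Residue",
    "ResidueTable",
    "NeutralLoss",
    "default_losses",
    "PeptideSequence",
    "IonKind",
    "IonSpec",
    "peptide_mass",
    "neutral_fragment_mass",
    "ion_mz",
    "delta_mz",
    "CAR_TAT1",
    "T_CAR_T",
    "TAT1_CAR",
]

#: Mass of a proton in Da (charge carrier for all ions considered here).
PROTON_MASS = 1.007276

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def parse_formula(text: str) -> dict[str, int]:
    """Parse a molecular formula string like ``"C72H133N37O17"`` into an
    element -> count map.  An empty string is the empty formula."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        if not m.group(0):
            break
        elem = m.group(1)
        n = int(m.group(2) or 1)
        if n < 0:
            raise ValueError(f"negative count for element {elem!r}")
        counts[elem] = counts.get(elem, 0) + n
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return counts


def formula_mass(formula: Mapping[str, int] | str) -> float:
    """Monoisotopic mass of a molecular formula (element -> count map or
    formula string).  Raises ``KeyError`` naming any unknown element."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    total = 0.0
    for elem, n in formula.items():
        if n < 0:
            raise ValueError(f"negative count for element {elem!r}")
        try:
            atomic = _pmass.nist_mass[elem][0][0]
        except KeyError:
            raise KeyError(f"unknown element symbol {elem!r}") from None
        total += n * atomic
    return total


#: Monoisotopic mass of water, the terminal group completing a peptide/y ion.
WATER_MASS = formula_mass("H2O")


@dataclass(frozen=True)
class Residue:
    """One residue entry: code, monoisotopic residue mass, and formula."""

    code: str
    mass: float
    formula: str

    def __post_init__(self) -> None:
        fm = formula_mass(self.formula)
        if abs(fm - self.mass) > 1e-6:
            raise ValueError(
                f"residue {self.code!r}: mass {self.mass} does not match "
                f"formula {self.formula} ({fm:.6f})"
            )


def _composition_to_formula(comp: Mapping[str, int]) -> str:
    return "".join(
        f"{el}{n}" for el, n in sorted(comp.items()) if n
    )


class ResidueTable:
    """Registry of residue codes -> (monoisotopic mass, elemental formula).

    The default table holds the 20 standard amino acids plus β-alanine
    (code ``"bA"``, composition C3H5NO) — a non-proteinogenic residue that
    is mass-identical to alanine, which is exactly why sequence position and
    not composition must differentiate the isomers studied here.
    """

    def __init__(self, residues: Iterable[Residue]):
        self.entries: dict[str, Residue] = {}
        for r in residues:
            if r.code in self.entries:
                raise ValueError(f"duplicate residue code {r.code!r}")
            self.entries[r.code] = r

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __getitem__(self, code: str) -> Residue:
        try:
            return self.entries[code]
        except KeyError:
            raise KeyError(f"unknown residue code {code!r}") from None

    def mass(self, code: str) -> float:
        return self[code].mass

    @classmethod
    def default(cls) -> "ResidueTable":
        residues = []
        for aa in _STANDARD_AA:
            comp = _pmass.std_aa_comp[aa]
            formula = _composition_to_formula(comp)
            residues.append(Residue(aa, formula_mass(formula), formula))
        residues.append(Residue("bA", formula_mass("C3H5NO"), "C3H5NO"))
        return cls(residues)

    # -- serialisation so users can extend the table ----------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("code\tmass\tformula\n")
            for r in self.entries.values():
                fh.write(f"{r.code}\t{r.mass:.6f}\t{r.formula}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueTable":
        residues = []
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            if header != ["code", "mass", "formula"]:
                raise ValueError(f"bad residue table header: {header}")
            for line in fh:
                if not line.strip():
                    continue
                code, mass_s, formula = line.rstrip("\n").split("\t")
                residues.append(Residue(code, float(mass_s), formula))
        return cls(residues)


@dataclass(frozen=True, order=True)
class NeutralLoss:
    """A neutral molecule shed by an ion during CID.

    ``mass`` may be a printed literature value; it is validated against the
    formula within 1e-4 Da.  On a z-charged ion the m/z shift is −mass/z.
    """

    name: str
    formula: str
    mass: float

    def __post_init__(self) -> None:
        fm = formula_mass(self.formula)
        if abs(fm - self.mass) > 1e-4:
            raise ValueError(
                f"neutral loss {self.name!r}: mass {self.mass} does not match "
                f"formula {self.formula} ({fm:.6f})"
            )


def default_losses() -> dict[str, NeutralLoss]:
    """The arginine-dominated neutral-loss catalogue: ammonia and water from
    anywhere, carbodiimide and guanidine from arginine side-chain termini."""
    losses = [
        NeutralLoss("ammonia", "NH3", 17.0265),
        NeutralLoss("water", "H2O", 18.0105),
        NeutralLoss("carbodiimide", "CH2N2", 42.0218),
        NeutralLoss("guanidine", "CH5N3", 59.0483),
    ]
    return {l.name: l for l in losses}


@dataclass(frozen=True)
class PeptideSequence:
    """An ordered residue-code sequence with a label."""

    residues: tuple[str, ...]
    id: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("peptide sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)

    @classmethod
    def parse(
        cls,
        text: str,
        id: str = "",
        table: "ResidueTable | None" = None,
    ) -> "PeptideSequence":
        """Parse a sequence string with single-letter codes and hyphen- or
        bracket-delimited multi-character tokens, e.g. ``"GRKKRRQRRRPS-bA-H"``
        or ``"GRKKRRQ[bA]HRRRPS"``."""
        table = table if table is not None else ResidueTable.default()
        codes: list[str] = []
        # bracket tokens are atomic; hyphens only separate
        chunks: list[str] = []
        for part in text.split("-"):
            i = 0
            while i < len(part):
                if part[i] == "[":
                    j = part.index("]", i)
                    chunks.append("\x00" + part[i + 1 : j])  # atomic marker
                    i = j + 1
                else:
                    j = part.find("[", i)
                    j = len(part) if j < 0 else j
                    chunks.append(part[i:j])
                    i = j
        by_len = sorted(table.entries, key=len, reverse=True)
        pos = 0
        for chunk in chunks:
            if chunk.startswith("\x00"):
                code = chunk[1:]
                if code not in table:
                    raise KeyError(
                        f"unknown residue code {code!r} at position {pos}"
                    )
                codes.append(code)
                pos += 1
                continue
            i = 0
            while i < len(chunk):
                for code in by_len:
                    if chunk.startswith(code, i):
                        codes.append(code)
                        i += len(code)
                        pos += 1
                        break
                else:
                    raise KeyError(
                        f"unresolvable residue code starting at {chunk[i:]!r} "
                        f"(residue position {pos})"
                    )
        return cls(tuple(codes), id=id)

    def __str__(self) -> str:
        return "-".join(self.residues)


class IonKind(str, Enum):
    PRECURSOR = "precursor"
    B = "b"
    Y = "y"
    INTERNAL_B = "internal_b"
    SCRAMBLED_B = "scrambled_b"


#: ion kinds whose neutral mass includes the C-terminal water
_WATER_KINDS = frozenset({IonKind.PRECURSOR, IonKind.Y})


@dataclass(frozen=True)
class IonSpec:
    """A theoretical ion: kind, residue content (ordered), charge, and a
    multiset of neutral losses.  ``provenance`` records how a scrambled or
    internal ion was produced and never participates in equality."""

    kind: IonKind
    residues: tuple[str, ...]
    charge: int
    losses: tuple[NeutralLoss, ...] = ()
    provenance: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if not self.residues:
            raise ValueError("residue content must be non-empty")
        object.__setattr__(self, "losses", tuple(sorted(self.losses)))

    def with_losses(self, *extra: NeutralLoss) -> "IonSpec":
        return IonSpec(
            self.kind,
            self.residues,
            self.charge,
            self.losses + tuple(extra),
            provenance=self.provenance,
        )

    @property
    def composition(self) -> tuple[str, ...]:
        """Sorted residue multiset (mass-determining part of the content)."""
        return tuple(sorted(self.residues))

    def dedup_key(self):
        return (
            self.kind,
            self.composition,
            self.charge,
            tuple(l.name for l in self.losses),
        )


def peptide_mass(seq: PeptideSequence, table: ResidueTable | None = None) -> float:
    """Neutral monoisotopic peptide mass: Σ residue masses + H2O."""
    table = table if table is not None else ResidueTable.default()
    total = WATER_MASS
    for i, code in enumerate(seq.residues):
        if code not in table:
            raise KeyError(f"unknown residue code {code!r} at position {i}")
        total += table.mass(code)
    return total


def neutral_fragment_mass(ion: IonSpec, table: ResidueTable | None = None) -> float:
    """Neutral mass of the fragment before losses: Σ residues for b-type
    (including internal and scrambled), plus H2O for y ions and the intact
    precursor."""
    table = table if table is not None else ResidueTable.default()
    total = sum(table.mass(c) for c in ion.residues)
    if ion.kind in _WATER_KINDS:
        total += WATER_MASS
    return total


def ion_mz(ion: IonSpec, table: ResidueTable | None = None) -> float:
    """m/z of an ion: (neutral fragment mass − Σ loss masses + z·m_p)/z."""
    table = table if table is not None else ResidueTable.default()
    neutral = neutral_fragment_mass(ion, table)
    loss_total = sum(l.mass for l in ion.losses)
    if loss_total >= neutral:
        raise ValueError(
            f"losses ({loss_total:.4f} Da) exceed fragment mass "
            f"({neutral:.4f} Da): non-physical ion"
        )
    return (neutral - loss_total + ion.charge * PROTON_MASS) / ion.charge


def delta_mz(loss: NeutralLoss, charge: int) -> float:
    """Signed m/z shift of a neutral loss on a z-charged ion: −mass/z.

    On doubly charged precursors loss masses appear halved — e.g. ammonia
    shifts a 2+ ion by −8.51 Th, water by −9.01 Th, a 0.5 Th difference that
    itself betrays the charge state.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return -loss.mass / charge


# Canonical study sequences: carnosine (βAla-His) grafted onto the
# arginine-rich TAT1 peptide GRKKRRQRRRPS at N-terminal, central, and
# C-terminal positions.  All three are isomers (C72H133N37O17).
CAR_TAT1 = PeptideSequence.parse("bA-HGRKKRRQRRRPS", id="Car-TAT1")
T_CAR_T = PeptideSequence.parse("GRKKRRQ-bA-H-RRRPS", id="T-Car-T")
TAT1_CAR = PeptideSequence.parse("GRKKRRQRRRPS-bA-H", id="TAT1-Car")
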