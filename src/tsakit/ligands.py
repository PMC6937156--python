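"""N-sulfamoyl amino-acid ligand catalog and formula-weight utility.

The four transition-state analogs share a common core whose heavy atoms are
numbered C13 (alpha carbon), C14/O15/O16 (terminal carboxylate), N17
(sulfamoylated nitrogen), S18 (tetrahedral sulfur), N19 (free sulfamide
nitrogen) and O20/O21 (sulfonyl oxygens).  Side-chain atom names are
provisional (the deposited het codes are mapped via ``name_map`` in a
config if they differ).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import UnknownElementError

# Standard atomic weights (g/mol), 3 decimals where the standard value has
# them.  Sulfur uses 32.065 (the pre-2009 standard), which is the value the
# 2-decimal formula weights of the source compounds round-trip against.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "P": 30.974,
    "S": 32.065,
    "Cl": 35.453,
    "K": 39.098,
    "Ca": 40.078,
    "Zn": 65.38,
    "Se": 78.971,
    "Br": 79.904,
    "I": 126.904,
}

SULFAMOYL_ATOMS = frozenset({"S18", "N17", "N19", "O20", "O21"})
CARBOXYLATE_ATOMS = frozenset({"C14", "O15", "O16"})
CALPHA_ATOMS = frozenset({"C13"})

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation formula string like ``"C5H10N2O6S"``."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = match.end()
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def molecular_weight(formula: dict[str, int] | str) -> float:
    """Formula weight in g/mol (2-decimal report precision downstream)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    total = 0.0
    for element, count in formula.items():
        if element not in ATOMIC_WEIGHTS:
            raise UnknownElementError(f"no atomic weight for element {element!r}")
        if not (isinstance(count, int) and count > 0):
            raise ValueError(f"count for {element} must be a positive integer")
        total += count * ATOMIC_WEIGHTS[element]
    return total


@dataclass(frozen=True)
class LigandDefinition:
    """Atom nomenclature and elemental composition of one analog."""

    code: str  # SGlu | SLeu | SArg | SPhe
    parent_residue: str
    formula: dict[str, int]
    mw: float
    side_chain_atoms: tuple[str, ...]
    formula_derived: bool = False  # True when not printed in the source data
    sulfamoyl_atoms: frozenset = field(default=SULFAMOYL_ATOMS)
    carboxylate_atoms: frozenset = field(default=CARBOXYLATE_ATOMS)
    calpha: frozenset = field(default=CALPHA_ATOMS)

    def __post_init__(self) -> None:
        recomputed = molecular_weight(self.formula)
        if abs(recomputed - self.mw) > 0.01:
            raise ValueError(
                f"{self.code}: mw {self.mw} inconsistent with formula "
                f"({recomputed:.4f})"
            )
        named = [self.sulfamoyl_atoms, self.carboxylate_atoms, self.calpha,
                 frozenset(self.side_chain_atoms)]
        total = sum(len(s) for s in named)
        if len(frozenset().union(*named)) != total:
            raise ValueError(f"{self.code}: atom-name sets overlap")


def ligand_catalog() -> list[LigandDefinition]:
    """The four N-sulfamoyl analogs, in decreasing-K_I order of their parent.

    SGlu's formula (and its 226.21 g/mol weight) is as printed for the free
    acid; the other three are derived from parent amino acid + sulfamoyl
    substitution and flagged accordingly.
    """
    return [
        LigandDefinition(
            code="SGlu", parent_residue="GLU",
            formula=parse_formula("C5H10N2O6S"), mw=226.21,
            side_chain_atoms=("C10", "C11", "C12", "O22", "O23"),
        ),
        LigandDefinition(
            code="SArg", parent_residue="ARG",
            formula=parse_formula("C6H15N5O4S"), mw=253.28,
            side_chain_atoms=("C9", "C10", "C11", "C12", "N22", "N23", "N24"),
            formula_derived=True,
        ),
        LigandDefinition(
            code="SPhe", parent_residue="PHE",
            formula=parse_formula("C9H12N2O4S"), mw=244.27,
            side_chain_atoms=("C6", "C7", "C8", "C9", "C10", "C11", "C12"),
            formula_derived=True,
        ),
        LigandDefinition(
            code="SLeu", parent_residue="LEU",
            formula=parse_formula("C6H14N2O4S"), mw=210.25,
            side_chain_atoms=("C9", "C10", "C11", "C12"),
            formula_derived=True,
        ),
    ]
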