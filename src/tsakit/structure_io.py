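"""Coordinate-file reading, unambiguous atom addressing and tabular output.

Parsing of PDB / mmCIF files is delegated to :mod:`biotite`; this module
converts the parsed arrays into a flat, altloc-aware record model and adds
the addressing and formatting contracts the downstream geometry stages rely
on.  PDB writing is done directly (fixed-column formatting) so that altloc
identifiers and occupancies survive a round trip.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import (
    AmbiguousAtomError,
    EmptyStructureError,
    LigandIdentificationError,
    MissingAtomError,
    ParseError,
)
from .ligands import ATOMIC_WEIGHTS

_WATER_RES_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class AtomRecord:
    """One ATOM/HETATM record with altloc kept explicit."""

    serial: int
    name: str
    alt_loc: str  # single character or ""
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str  # insertion code or ""
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0
    element: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")

    @property
    def element_known(self) -> bool:
        return self.element.capitalize() in ATOMIC_WEIGHTS

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.res_name.upper() in _WATER_RES_NAMES

    def address(self) -> tuple[str, int, str, str]:
        """(chain, res_seq, i_code, name) — unique after altloc resolution."""
        return (self.chain_id, self.res_seq, self.i_code, self.name)


class AltlocPolicy(Enum):
    HIGHEST_OCCUPANCY = "highest_occupancy"
    FIRST = "first"
    EXPLICIT = "explicit"


@dataclass
class AtomQuery:
    """Specification resolving to exactly one atom (or a defined error)."""

    name: str
    chain_id: Optional[str] = None
    res_seq: Optional[int] = None
    res_name: Optional[str] = None
    i_code: str = ""
    ligand: bool = False  # resolve inside the single polyatomic hetero group
    altloc_policy: AltlocPolicy = AltlocPolicy.HIGHEST_OCCUPANCY
    altloc_char: str = ""  # used with AltlocPolicy.EXPLICIT

    def __str__(self) -> str:  # for error messages
        where = "ligand" if self.ligand else f"{self.res_name or '*'} {self.chain_id or '*'}/{self.res_seq}"
        return f"{where}:{self.name}"


@dataclass
class Structure:
    """Ordered atom list plus optional crystal metadata."""

    label: str
    atoms: list[AtomRecord]
    cell: Optional[tuple[float, float, float, float, float, float]] = None
    space_group: Optional[str] = None

    def __len__(self) -> int:
        return len(self.atoms)

    # ---- default selections (hydrogens always excluded) -----------------
    def protein_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hetero and not a.is_hydrogen]

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def calpha_atoms(self, policy: AltlocPolicy = AltlocPolicy.HIGHEST_OCCUPANCY) -> list[AtomRecord]:
        """Protein C-alpha atoms, altloc-resolved (element C excludes Ca2+ ions)."""
        cas = [
            a
            for a in self.protein_atoms()
            if a.name == "CA" and a.element.upper() in ("C", "")
        ]
        return _resolve_altlocs(cas, policy)

    def ligand_atoms(self, res_name: Optional[str] = None) -> list[AtomRecord]:
        """Atoms of the unique non-water hetero group with >= 3 atoms.

        Monoatomic hetero species (Zn2+, Ca2+, halides) and small buffer
        ions never qualify; if several polyatomic groups remain, the het
        code must be given explicitly.
        """
        groups: dict[tuple[str, int, str, str], list[AtomRecord]] = {}
        for a in self.atoms:
            if not a.is_hetero or a.is_water or a.is_hydrogen:
                continue
            key = (a.chain_id, a.res_seq, a.i_code, a.res_name)
            groups.setdefault(key, []).append(a)
        candidates = {k: v for k, v in groups.items() if len(v) >= 3}
        if res_name is not None:
            candidates = {k: v for k, v in candidates.items() if k[3] == res_name}
        if not candidates:
            raise LigandIdentificationError(
                f"{self.label}: no polyatomic non-water hetero group"
                + (f" with res_name {res_name}" if res_name else "")
            )
        if len(candidates) > 1:
            names = sorted({k[3] for k in candidates})
            raise LigandIdentificationError(
                f"{self.label}: multiple candidate ligand groups {names}; "
                "specify res_name explicitly"
            )
        (_, atoms), = candidates.items()
        return atoms

    def metal_atoms(self, element: str = "ZN") -> list[AtomRecord]:
        """Monoatomic metal records matched by element symbol, res_name fallback."""
        sym = element.upper()
        hits = [a for a in self.atoms if a.is_hetero and a.element.upper() == sym]
        if not hits:
            hits = [a for a in self.atoms if a.is_hetero and a.res_name.upper() == sym]
        return hits


def _resolve_altlocs(atoms: Sequence[AtomRecord], policy: AltlocPolicy,
                     altloc_char: str = "") -> list[AtomRecord]:
    """Collapse altloc copies: one record per (chain, res, icode, name)."""
    by_addr: dict[tuple, list[AtomRecord]] = {}
    order: list[tuple] = []
    for a in atoms:
        addr = a.address()
        if addr not in by_addr:
            order.append(addr)
        by_addr.setdefault(addr, []).append(a)
    out = []
    for addr in order:
        copies = by_addr[addr]
        out.append(_pick_altloc(copies, policy, altloc_char))
    return out


def _pick_altloc(copies: Sequence[AtomRecord], policy: AltlocPolicy,
                 altloc_char: str = "") -> AtomRecord:
    if len(copies) == 1:
        return copies[0]
    if policy is AltlocPolicy.FIRST:
        return copies[0]
    if policy is AltlocPolicy.EXPLICIT:
        for a in copies:
            if a.alt_loc == altloc_char:
                return a
        raise MissingAtomError(
            f"no altloc '{altloc_char}' among {[a.alt_loc for a in copies]}"
        )
    # highest occupancy; ties broken by lexicographically smallest altloc
    return min(copies, key=lambda a: (-a.occupancy, a.alt_loc))


def resolve_atom(structure: Structure, query: AtomQuery) -> AtomRecord:
    """Return the unique atom matching *query* (after altloc policy)."""
    if len(structure) == 0:
        raise EmptyStructureError(f"{structure.label}: structure has no atoms")
    if query.ligand:
        pool: Iterable[AtomRecord] = structure.ligand_atoms(query.res_name)
    else:
        pool = structure.atoms
        if query.res_name is not None:
            pool = [a for a in pool if a.res_name == query.res_name]
    hits = [a for a in pool if a.name == query.name]
    if not query.ligand:
        if query.chain_id is not None:
            hits = [a for a in hits if a.chain_id == query.chain_id]
        if query.res_seq is not None:
            hits = [a for a in hits if a.res_seq == query.res_seq]
        hits = [a for a in hits if a.i_code == query.i_code]
    if not hits:
        raise MissingAtomError(f"{structure.label}: no atom matches {query}")
    addresses = {a.address() for a in hits}
    if len(addresses) > 1:
        raise AmbiguousAtomError(
            f"{structure.label}: query {query} matches {len(addresses)} distinct atoms"
        )
    return _pick_altloc(hits, query.altloc_policy, query.altloc_char)


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------

def read_structure(path: str | Path, dialect: Optional[str] = None,
                   label: Optional[str] = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    ``dialect`` is ``"pdb"`` or ``"mmcif"``; when omitted it is inferred
    from the file suffix.  All ATOM/HETATM records are captured, including
    every altloc copy; waters, metals and hydrogens are retained (default
    selections exclude hydrogens later).
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = "mmcif" if suffix in (".cif", ".mmcif") else "pdb"
    if dialect not in ("pdb", "mmcif"):
        raise ValueError(f"unknown dialect {dialect!r}")

    cell = None
    space_group = None
    try:
        if dialect == "pdb":
            from biotite.structure.io.pdb import PDBFile

            pdb_file = PDBFile.read(str(path))
            arr = pdb_file.get_structure(
                model=1, altloc="all",
                extra_fields=["atom_id", "b_factor", "occupancy"],
            )
            cell, space_group = _parse_cryst1(pdb_file.lines)
        else:
            from biotite.structure.io.pdbx import CIFFile
            from biotite.structure.io.pdbx import get_structure as _cif_get

            cif = CIFFile.read(str(path))
            arr = _cif_get(
                cif, model=1, altloc="all",
                extra_fields=["atom_id", "b_factor", "occupancy"],
            )
            cell, space_group = _cif_cell(cif)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        if dialect == "pdb":
            try:
                text = path.read_text(errors="replace")
            except OSError:
                text = ""
            if not any(line.startswith(("ATOM", "HETATM"))
                       for line in text.splitlines()):
                raise EmptyStructureError(f"{path}: no atoms found") from exc
        raise ParseError(f"cannot parse {path} as {dialect}: {exc}") from exc

    if arr.array_length() == 0:
        raise EmptyStructureError(f"{path}: no atoms found")

    altloc_ids = (
        arr.get_annotation("altloc_id")
        if "altloc_id" in arr.get_annotation_categories()
        else [""] * arr.array_length()
    )
    atoms = []
    for i in range(arr.array_length()):
        alt = str(altloc_ids[i]).strip()
        if alt == ".":
            alt = ""
        atoms.append(
            AtomRecord(
                serial=int(arr.atom_id[i]),
                name=str(arr.atom_name[i]),
                alt_loc=alt,
                res_name=str(arr.res_name[i]),
                chain_id=str(arr.chain_id[i]),
                res_seq=int(arr.res_id[i]),
                i_code=str(arr.ins_code[i]).strip(),
                position=arr.coord[i],
                occupancy=float(arr.occupancy[i]),
                b_factor=float(arr.b_factor[i]),
                element=str(arr.element[i]),
                is_hetero=bool(arr.hetero[i]),
            )
        )
    return Structure(label=label or path.stem, atoms=atoms, cell=cell,
                     space_group=space_group)


def _parse_cryst1(lines: Sequence[str]):
    for line in lines:
        if line.startswith("CRYST1"):
            try:
                cell = tuple(
                    float(line[start:stop])
                    for start, stop in ((6, 15), (15, 24), (24, 33),
                                        (33, 40), (40, 47), (47, 54))
                )
                sg = line[55:66].strip() or None
                return cell, sg
            except ValueError:
                return None, None
    return None, None


def _cif_cell(cif):
    try:
        block = cif.block
        cell_cat = block.get("cell")
        if cell_cat is None:
            return None, None
        cell = tuple(
            float(cell_cat[k].as_item())
            for k in ("length_a", "length_b", "length_c",
                      "angle_alpha", "angle_beta", "angle_gamma")
        )
        sym = block.get("symmetry")
        sg = sym["space_group_name_H-M"].as_item() if sym is not None else None
        return cell, sg
    except Exception:  # noqa: BLE001 - metadata is optional
        return None, None


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------

def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-column PDB; preserves serials, altlocs and occupancies."""
    lines = []
    if structure.cell is not None:
        a, b, c, al, be, ga = structure.cell
        sg = structure.space_group or "P 1"
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} {sg:<11s}"
        )
    for atom in structure.atoms:
        record = "HETATM" if atom.is_hetero else "ATOM  "
        name = atom.name
        # element-aligned name field: 1/2-char element symbols start col 13/14
        if len(name) < 4 and len(atom.element) < 2:
            name = " " + name
        x, y, z = atom.position
        lines.append(
            f"{record}{atom.serial:>5d} {name:<4s}{atom.alt_loc or ' ':1s}"
            f"{atom.res_name:<3s} {atom.chain_id:1s}{atom.res_seq:>4d}"
            f"{atom.i_code or ' ':1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          "
            f"{atom.element.upper():>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the convention used for all printed distances)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def format_distance(value: float) -> str:
    return f"{round_half_up(value, 2):.2f}"


def format_kinetic(value: float) -> str:
    """Scientific notation, 3 significant digits."""
    if value == 0:
        return "0.00e+00"
    return f"{value:.2e}"


def write_table(rows: Sequence, path: str | Path, row_type=None) -> None:
    """Write homogeneous dataclass rows as TSV with a header line.

    Float fields tagged ``metadata={"fmt": "distance"}`` render with exactly
    2 decimals (half-up); fields tagged ``"kinetic"`` render in scientific
    notation with 3 significant digits.  An empty row list writes a
    header-only file (``row_type`` supplies the header then).
    """
    path = Path(path)
    if not rows:
        if row_type is None:
            raise ValueError("empty row list needs an explicit row_type for the header")
        header = "\t".join(f.name for f in dataclasses.fields(row_type))
        path.write_text(header + "\n")
        return
    first = rows[0]
    if not dataclasses.is_dataclass(first):
        raise TypeError("write_table expects dataclass rows")
    row_type = type(first)
    if any(type(r) is not row_type for r in rows):
        raise TypeError("rows must be homogeneous")
    fields = dataclasses.fields(row_type)
    lines = ["\t".join(f.name for f in fields)]
    for row in rows:
        cells = []
        for f in fields:
            v = getattr(row, f.name)
            fmt = f.metadata.get("fmt") if f.metadata else None
            if fmt == "distance":
                cells.append(format_distance(v))
            elif fmt == "kinetic":
                cells.append(format_kinetic(v))
            elif isinstance(v, float):
                cells.append(repr(v))
            else:
                cells.append(str(v))
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def read_table(path: str | Path, row_type):
    """Inverse of :func:`write_table` for a known dataclass row type."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    fields = {f.name: f for f in dataclasses.fields(row_type)}
    if set(header) != set(fields):
        raise ParseError(f"{path}: header {header} does not match {sorted(fields)}")
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        values = line.split("\t")
        kwargs = {}
        for name, raw in zip(header, values):
            ftype = fields[name].type
            if ftype in ("float", float):
                kwargs[name] = float(raw)
            elif ftype in ("int", int):
                kwargs[name] = int(raw)
            else:
                kwargs[name] = raw
        rows.append(row_type(**kwargs))
    return rows


# Row types shared with the geometry module -------------------------------

@dataclass
class DistanceRow:
    """One printed line of the catalytic-subsite distance table."""

    ligand_atom: str
    partner: str
    distance: float = field(metadata={"fmt": "distance"})


@dataclass
class DisplacementRow:
    """Displacement of one labelled atom between two superposed complexes."""

    label: str
    displacement: float = field(metadata={"fmt": "distance"})
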