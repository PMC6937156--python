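"""Rigid C-alpha superposition and active-site distance/displacement tables.

The superposition is the classic SVD solution of the orthogonal Procrustes
problem with the proper-rotation (determinant +1) correction; it is applied
to ALL alpha-carbons shared by residue number between the two complexes,
with no outlier trimming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateGeometryError, InsufficientPairsError, MissingAtomError
from .structure_io import (
    AltlocPolicy,
    AtomQuery,
    DisplacementRow,
    DistanceRow,
    Structure,
    resolve_atom,
)

logger = logging.getLogger(__name__)


@dataclass
class RigidTransform:
    """Proper rotation + translation: x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3, translation a 3-vector")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self @ other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_pairs: int
    paired_residues: list[tuple[str, int]] = field(default_factory=list)


def atom_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two positions (Angstrom)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("positions must be finite")
    return float(np.linalg.norm(a - b))


def pair_calpha(
    ref: Structure, mobile: Structure,
    policy: AltlocPolicy = AltlocPolicy.HIGHEST_OCCUPANCY,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Ordered coordinate pairs for every residue with a C-alpha in BOTH.

    Pairing key is (chain, res_seq, i_code); residue-name mismatches at a
    shared number are tolerated (and logged), matching the shared-numbering
    convention of isomorphous complexes.
    """
    ref_ca = {a.address()[:3]: a for a in ref.calpha_atoms(policy)}
    mob_ca = {a.address()[:3]: a for a in mobile.calpha_atoms(policy)}
    shared = [k for k in ref_ca if k in mob_ca]
    if len(shared) < 3:
        raise InsufficientPairsError(
            f"only {len(shared)} shared C-alpha between {ref.label} and {mobile.label}"
        )
    for key in shared:
        if ref_ca[key].res_name != mob_ca[key].res_name:
            logger.warning(
                "residue name mismatch at %s: %s vs %s",
                key, ref_ca[key].res_name, mob_ca[key].res_name,
            )
    ref_xyz = np.array([ref_ca[k].position for k in shared])
    mob_xyz = np.array([mob_ca[k].position for k in shared])
    residues = [(k[0], k[1]) for k in shared]
    return ref_xyz, mob_xyz, residues


def kabsch_superpose(
    ref_coords: np.ndarray, mobile_coords: np.ndarray,
    paired_residues: Optional[list[tuple[str, int]]] = None,
) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation (mobile -> ref)."""
    ref = np.asarray(ref_coords, dtype=float)
    mob = np.asarray(mobile_coords, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate lists must be matching (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise InsufficientPairsError(f"need >= 3 pairs, got {n}")

    ref_centroid = ref.mean(axis=0)
    mob_centroid = mob.mean(axis=0)
    ref_c = ref - ref_centroid
    mob_c = mob - mob_centroid

    # collinear/coincident point sets leave the rotation underdetermined
    for name, pts in (("reference", ref_c), ("mobile", mob_c)):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise DegenerateGeometryError(f"{name} points are collinear or coincident")

    cov = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = ref_centroid - rotation @ mob_centroid
    transform = RigidTransform(rotation, translation)

    deviations = ref - transform.apply(mob)
    rmsd = float(np.sqrt((deviations**2).sum() / n))
    return SuperpositionResult(
        transform=transform, rmsd=rmsd, n_pairs=n,
        paired_residues=list(paired_residues) if paired_residues else [],
    )


def superpose_structures(
    ref: Structure, mobile: Structure,
    policy: AltlocPolicy = AltlocPolicy.HIGHEST_OCCUPANCY,
) -> SuperpositionResult:
    """All-shared-C-alpha superposition of *mobile* onto *ref*."""
    ref_xyz, mob_xyz, residues = pair_calpha(ref, mobile, policy)
    return kabsch_superpose(ref_xyz, mob_xyz, residues)


# --------------------------------------------------------------------------
# Default atom-label sets
# --------------------------------------------------------------------------

#: displacement-table rows: nine ligand core atoms, Tyr255 OH and the
#: Glu277 carboxylate
DEFAULT_DISPLACEMENT_LABELS: list[tuple[str, AtomQuery]] = [
    ("S18", AtomQuery(name="S18", ligand=True)),
    ("N17", AtomQuery(name="N17", ligand=True)),
    ("N19", AtomQuery(name="N19", ligand=True)),
    ("O20", AtomQuery(name="O20", ligand=True)),
    ("O21", AtomQuery(name="O21", ligand=True)),
    ("C14", AtomQuery(name="C14", ligand=True)),
    ("O16", AtomQuery(name="O16", ligand=True)),
    ("O15", AtomQuery(name="O15", ligand=True)),
    ("C13", AtomQuery(name="C13", ligand=True)),
    ("Tyr 255, OH", AtomQuery(name="OH", res_seq=255, res_name="TYR")),
    ("Glu277, CD", AtomQuery(name="CD", res_seq=277, res_name="GLU")),
    ("Glu277, OE1", AtomQuery(name="OE1", res_seq=277, res_name="GLU")),
    ("Glu277, OE2", AtomQuery(name="OE2", res_seq=277, res_name="GLU")),
]

#: the 16 catalytic-subsite distance rows: (ligand atom, partner label, query)
DEFAULT_DISTANCE_PAIRS: list[tuple[str, str, AtomQuery]] = [
    ("O16", "ARG 129[NH2]", AtomQuery(name="NH2", res_seq=129, res_name="ARG")),
    ("O15", "ARG 129[NH2]", AtomQuery(name="NH2", res_seq=129, res_name="ARG")),
    ("O21", "ARG 129[NH1]", AtomQuery(name="NH1", res_seq=129, res_name="ARG")),
    ("O21", "ARG 129[NH2]", AtomQuery(name="NH2", res_seq=129, res_name="ARG")),
    ("O15", "ASN 146[ND2]", AtomQuery(name="ND2", res_seq=146, res_name="ASN")),
    ("O15", "ARG 147[NH1]", AtomQuery(name="NH1", res_seq=147, res_name="ARG")),
    ("O16", "ARG 147[NH2]", AtomQuery(name="NH2", res_seq=147, res_name="ARG")),
    ("N19", "THR 205[O]", AtomQuery(name="O", res_seq=205, res_name="THR")),
    ("N17", "TYR 255[OH]", AtomQuery(name="OH", res_seq=255, res_name="TYR")),
    ("O16", "TYR 255[OH]", AtomQuery(name="OH", res_seq=255, res_name="TYR")),
    ("N19", "GLU 277[OE1]", AtomQuery(name="OE1", res_seq=277, res_name="GLU")),
    ("N17", "GLU 277[OE2]", AtomQuery(name="OE2", res_seq=277, res_name="GLU")),
    ("O20", "GLU 277[OE1]", AtomQuery(name="OE1", res_seq=277, res_name="GLU")),
    ("S18", "Zn2+", AtomQuery(name="ZN", res_name="ZN")),
    ("O20", "Zn2+", AtomQuery(name="ZN", res_name="ZN")),
    ("O21", "Zn2+", AtomQuery(name="ZN", res_name="ZN")),
]


def displacement_table(
    ref: Structure, mobile: Structure,
    atom_labels: Optional[Sequence[tuple[str, AtomQuery]]] = None,
    superposition: Optional[SuperpositionResult] = None,
) -> list[DisplacementRow]:
    """Per-atom displacements between two complexes in the common C-alpha frame."""
    if superposition is None:
        superposition = superpose_structures(ref, mobile)
    labels = atom_labels if atom_labels is not None else DEFAULT_DISPLACEMENT_LABELS
    rows = []
    for label, query in labels:
        try:
            atom_ref = resolve_atom(ref, query)
        except MissingAtomError as exc:
            raise MissingAtomError(f"[{label}] in reference {ref.label}: {exc}") from exc
        try:
            atom_mob = resolve_atom(mobile, query)
        except MissingAtomError as exc:
            raise MissingAtomError(f"[{label}] in mobile {mobile.label}: {exc}") from exc
        moved = superposition.transform.apply(atom_mob.position)
        rows.append(DisplacementRow(label=label,
                                    displacement=atom_distance(atom_ref.position, moved)))
    return rows


def distance_table(
    structure: Structure,
    pair_spec: Optional[Sequence[tuple[str, str, AtomQuery]]] = None,
) -> list[DistanceRow]:
    """Ligand-to-subsite Euclidean distances within one complex."""
    pairs = pair_spec if pair_spec is not None else DEFAULT_DISTANCE_PAIRS
    rows = []
    for ligand_atom, partner_label, partner_query in pairs:
        try:
            lig = resolve_atom(structure, AtomQuery(name=ligand_atom, ligand=True))
            partner = resolve_atom(structure, partner_query)
        except MissingAtomError as exc:
            raise MissingAtomError(
                f"row ({ligand_atom}, {partner_label}): {exc}"
            ) from exc
        rows.append(DistanceRow(
            ligand_atom=ligand_atom, partner=partner_label,
            distance=atom_distance(lig.position, partner.position),
        ))
    return rows
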