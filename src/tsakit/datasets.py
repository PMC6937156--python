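"""Access to the deposited crystal-structure inputs (PDB 6GO2, 6SN6).

The coordinate files are not redistributed with the package; place them
(as plain-text ``.pdb``) either in the package data directory
``tsakit/data/structures/`` or in a directory named by the environment
variable ``TSAKIT_STRUCTURE_DIR``.  ``fetch_structures`` downloads them
from RCSB when network access is available.
"""

from __future__ import annotations

import os
import urllib.request
from importlib import resources
from pathlib import Path
from typing import Optional

from .structure_io import Structure, read_structure

#: deposited accessions: CPT+SLeu and CPT+SGlu complexes
ACCESSIONS = {"6GO2": "SLeu", "6SN6": "SGlu"}

_RCSB_URL = "https://files.rcsb.org/download/{accession}.pdb"


def structure_dir() -> Path:
    env = os.environ.get("TSAKIT_STRUCTURE_DIR")
    if env:
        return Path(env)
    return Path(resources.files("tsakit.data") / "structures")


def deposited_structure_path(accession: str) -> Path:
    """Path to a local copy of the deposited entry; FileNotFoundError if absent."""
    accession = accession.upper()
    for directory in (structure_dir(),
                      Path(resources.files("tsakit.data") / "structures")):
        for suffix in (".pdb", ".ent", ".cif"):
            candidate = directory / f"{accession}{suffix}"
            if candidate.exists():
                return candidate
            candidate = directory / f"{accession.lower()}{suffix}"
            if candidate.exists():
                return candidate
    raise FileNotFoundError(
        f"no local copy of {accession}; run `tsakit fetch` (needs network) or "
        f"place {accession}.pdb under {structure_dir()} "
        "(or set TSAKIT_STRUCTURE_DIR)"
    )


def have_deposited_structures() -> bool:
    try:
        for accession in ACCESSIONS:
            deposited_structure_path(accession)
        return True
    except FileNotFoundError:
        return False


def load_deposited(accession: str) -> Structure:
    path = deposited_structure_path(accession)
    return read_structure(path, label=accession.upper())


def fetch_structures(dest: Optional[Path] = None, timeout: float = 60.0) -> list[Path]:
    """Download the deposited entries from RCSB (network required)."""
    dest = Path(dest) if dest is not None else structure_dir()
    dest.mkdir(parents=True, exist_ok=True)
    paths = []
    for accession in ACCESSIONS:
        target = dest / f"{accession}.pdb"
        if not target.exists():
            url = _RCSB_URL.format(accession=accession)
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                target.write_bytes(resp.read())
        paths.append(target)
    return paths
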