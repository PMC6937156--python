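"""Join per-ligand geometry and kinetics; quantify the geometry–affinity link.

With only four ligands, correlations are descriptive ordering statistics —
no p-values are attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import JoinError, UndefinedCorrelationError
from .structure_io import DistanceRow, format_distance, format_kinetic

LIGAND_ORDER = ("SGlu", "SArg", "SPhe", "SLeu")


@dataclass
class LigandRecord:
    """One ligand's affinity, efficiency and key active-site gaps."""

    code: str
    K_I: float  # M
    kcat_over_KM: float  # 1/(M s)
    zn_s_gap: float  # Angstrom, Zn...S18
    hbond_glu277: float  # Angstrom, N17...Glu277 OE2
    hbond_tyr255: float  # Angstrom, carboxylate O...Tyr255 OH

    @property
    def assoc_const(self) -> float:
        return 1.0 / self.K_I


@dataclass
class CorrelationSummary:
    spearman_rho: float
    pearson_log: float
    n: int


def _data_path(name: str) -> Path:
    return Path(resources.files("tsakit.data") / name)


def load_distance_fixture() -> dict[str, list[DistanceRow]]:
    """Packaged catalytic-subsite distance table, one row list per ligand."""
    df = pd.read_csv(_data_path("table3_distances.tsv"), sep="\t")
    out: dict[str, list[DistanceRow]] = {code: [] for code in LIGAND_ORDER}
    for _, row in df.iterrows():
        for code in LIGAND_ORDER:
            ligand_atom = row["ligand_atom"]
            note = row.get("note")
            if code == "SLeu" and isinstance(note, str) and "O15" in note:
                ligand_atom = "O15"
            out[code].append(DistanceRow(
                ligand_atom=ligand_atom, partner=row["partner"],
                distance=float(row[code]),
            ))
    return out


def load_kinetics_fixture() -> pd.DataFrame:
    """Packaged inhibition/efficiency table (K_I in M, kcat/KM in 1/(M s))."""
    return pd.read_csv(_data_path("table4_kinetics.tsv"), sep="\t")


def _find_distance(rows: Sequence[DistanceRow], partner_contains: str,
                   ligand_atoms: Sequence[str]) -> float:
    for row in rows:
        if partner_contains in row.partner and row.ligand_atom in ligand_atoms:
            return row.distance
    raise JoinError(
        f"no distance row with partner ~{partner_contains!r} "
        f"and ligand atom in {list(ligand_atoms)}"
    )


def assemble_ligand_table(
    geometry: Mapping[str, Sequence[DistanceRow]],
    kinetics: pd.DataFrame,
) -> list[LigandRecord]:
    """One record per ligand; raises :class:`JoinError` on one-sided ligands."""
    kin_codes = set(kinetics["ligand"])
    geo_codes = set(geometry)
    if kin_codes != geo_codes:
        raise JoinError(
            f"ligands only in kinetics: {sorted(kin_codes - geo_codes)}; "
            f"only in geometry: {sorted(geo_codes - kin_codes)}"
        )
    if not geo_codes:
        raise JoinError("empty inputs")
    records = []
    for _, kin in kinetics.iterrows():
        code = kin["ligand"]
        rows = geometry[code]
        records.append(LigandRecord(
            code=code,
            K_I=float(kin["K_I_M"]),
            kcat_over_KM=float(kin["kcat_over_KM"]),
            zn_s_gap=_find_distance(rows, "Zn", ["S18"]),
            hbond_glu277=_find_distance(rows, "GLU 277[OE2]", ["N17"]),
            hbond_tyr255=_find_distance(rows, "TYR 255[OH]", ["O15", "O16"]),
        ))
    order = {c: i for i, c in enumerate(LIGAND_ORDER)}
    records.sort(key=lambda r: order.get(r.code, len(order)))
    return records


def _average_ranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties assigned the average of their positions."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Rank correlation (average ranks for ties), in [-1, 1]."""
    if len(xs) != len(ys):
        raise ValueError("inputs must have equal length")
    if len(xs) < 3:
        raise UndefinedCorrelationError(f"need n >= 3, got {len(xs)}")
    rx = _average_ranks(xs)
    ry = _average_ranks(ys)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError("zero variance in ranks")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def pearson_log(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Pearson correlation of log10-transformed (positive) quantities."""
    x = np.log10(np.asarray(xs, dtype=float))
    y = np.log10(np.asarray(ys, dtype=float))
    if len(x) < 3:
        raise UndefinedCorrelationError(f"need n >= 3, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def summarize(records: Sequence[LigandRecord]) -> CorrelationSummary:
    assoc = [r.assoc_const for r in records]
    gaps = [r.zn_s_gap for r in records]
    return CorrelationSummary(
        spearman_rho=spearman(assoc, gaps),
        pearson_log=pearson_log(assoc, [g for g in gaps]),
        n=len(records),
    )


def report(records: Sequence[LigandRecord], out: str | Path,
           plot: Optional[str | Path] = None) -> None:
    """TSV report with a correlation footer and an optional dual-axis plot."""
    if not records:
        raise ValueError("need at least one record")
    lines = ["code\tK_I_M\tassoc_const_per_M\tkcat_over_KM_per_M_s\t"
             "zn_s_gap_A\thbond_glu277_A\thbond_tyr255_A"]
    for r in records:
        lines.append("\t".join([
            r.code, format_kinetic(r.K_I), format_kinetic(r.assoc_const),
            format_kinetic(r.kcat_over_KM), format_distance(r.zn_s_gap),
            format_distance(r.hbond_glu277), format_distance(r.hbond_tyr255),
        ]))
    try:
        summary = summarize(records)
        lines.append(f"# spearman(assoc_const, zn_s_gap) = {summary.spearman_rho:.3f}")
        lines.append(f"# pearson(log10 assoc_const, log10 zn_s_gap) = "
                     f"{summary.pearson_log:.3f}")
        lines.append(f"# n = {summary.n}")
    except UndefinedCorrelationError as exc:
        lines.append(f"# correlation not computable: {exc}")
    Path(out).write_text("\n".join(lines) + "\n")
    if plot is not None:
        _plot(records, plot)


def _plot(records: Sequence[LigandRecord], path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = sorted(records, key=lambda r: r.zn_s_gap)
    gaps = [r.zn_s_gap for r in ordered]
    fig, ax1 = plt.subplots(figsize=(5, 4))
    ax1.semilogy(gaps, [r.assoc_const for r in ordered], "D-", color="tab:blue",
                 label="association constant 1/K_I")
    ax1.set_xlabel("Zn–S gap (Å)")
    ax1.set_ylabel("1/K_I (M$^{-1}$)", color="tab:blue")
    ax2 = ax1.twinx()
    ax2.semilogy(gaps, [r.kcat_over_KM for r in ordered], "s--", color="tab:red",
                 label="kcat/KM")
    ax2.set_ylabel("k$_{cat}$/K$_M$ (M$^{-1}$s$^{-1}$)", color="tab:red")
    for r in ordered:
        ax1.annotate(r.code, (r.zn_s_gap, r.assoc_const),
                     textcoords="offset points", xytext=(4, 4), fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
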