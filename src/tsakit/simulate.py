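"""Seeded generators for every input the analysis stages consume.

All randomness flows through ``numpy.random.default_rng`` (PCG64), so a
given config reproduces bit-identical outputs across runs and releases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .geometry import RigidTransform
from .kinetics import MMParams, ProgressCurve, closed_form_progress
from .structure_io import AtomRecord, Structure


@dataclass
class SimulationConfig:
    """Bundle of truth parameters for a reproducible simulation run."""

    seed: int = 0
    noise_sd: float = 0.0
    times: Optional[np.ndarray] = None
    params: Optional[MMParams] = None
    K_I: Optional[float] = None
    inhibitor_levels: tuple[float, ...] = ()
    s0: Optional[float] = None
    n_atoms: int = 100
    jitter_sd: float = 0.0
    transform: Optional[RigidTransform] = None


def simulate_progress_curve(params: MMParams, K_I: Optional[float], I: float,
                            s0: float, times: Sequence[float],
                            noise_sd: float = 0.0, seed: int = 0,
                            rel_noise: float = 0.0) -> ProgressCurve:
    """Competitive-inhibition progress curve with Gaussian absorbance noise.

    The noiseless trajectory follows the integrated Michaelis–Menten law
    with K_M scaled by (1 + I/K_I).  Noise is Gaussian on the concentration
    scale (a spectrophotometric readout) with per-point standard deviation
    ``noise_sd + rel_noise * s(t)`` — a constant floor plus an optional
    signal-proportional part — and the result is clipped to (0, s0].
    """
    times = np.asarray(times, dtype=float)
    if I > 0 and (K_I is None or K_I <= 0):
        raise ValueError("positive inhibitor concentration needs a positive K_I")
    scale = 1.0 + (I / K_I if I > 0 else 0.0)
    s = np.asarray(closed_form_progress(s0, params.Vmax, params.KM, times,
                                        KM_scale=scale), dtype=float)
    if noise_sd > 0 or rel_noise > 0:
        rng = np.random.default_rng(seed)
        sd = noise_sd + rel_noise * s
        s = s + rng.normal(0.0, 1.0, size=s.shape) * sd
    s = np.clip(s, 1e-12 * s0, s0)
    return ProgressCurve(
        s0=s0, inhibitor_conc=I, times=times, substrate=s,
        meta={"true_Vmax": params.Vmax, "true_KM": params.KM,
              "true_K_I": K_I, "noise_sd": noise_sd, "rel_noise": rel_noise,
              "seed": seed},
    )


def time_to_conversion(params: MMParams, s0: float, fraction: float,
                       KM_scale: float = 1.0) -> float:
    """Time at which a noiseless curve reaches the given fractional conversion."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    s = s0 * (1.0 - fraction)
    return (params.KM * KM_scale * np.log(s0 / s) + (s0 - s)) / params.Vmax


def simulate_inhibition_series(params: MMParams, K_I: float,
                               inhibitor_levels: Sequence[float], s0: float,
                               times: Optional[Sequence[float]] = None,
                               noise_sd: float = 0.0, seed: int = 0,
                               rel_noise: float = 0.0, n_times: int = 40,
                               max_conversion: float = 0.95
                               ) -> list[ProgressCurve]:
    """One curve per inhibitor level, with per-curve derived seeds.

    When ``times`` is omitted, each curve gets its own uniform grid from 0
    to the time of ``max_conversion`` conversion (inhibited curves run
    longer), mirroring how a progress-curve experiment is actually timed.
    """
    seeds = np.random.SeedSequence(seed).spawn(len(inhibitor_levels))
    curves = []
    for level, child in zip(inhibitor_levels, seeds):
        if times is None:
            scale = 1.0 + (level / K_I if level > 0 else 0.0)
            t_end = time_to_conversion(params, s0, max_conversion, scale)
            grid = np.linspace(0.0, t_end, n_times)
        else:
            grid = np.asarray(times, dtype=float)
        curves.append(simulate_progress_curve(
            params, K_I, level, s0, grid, noise_sd,
            seed=int(child.generate_state(1)[0]), rel_noise=rel_noise,
        ))
    return curves


def simulate_initial_rates(params: MMParams, substrate_concs: Sequence[float],
                           rel_noise: float = 0.0, seed: int = 0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Michaelis–Menten initial rates with multiplicative Gaussian noise."""
    s = np.asarray(substrate_concs, dtype=float)
    if np.any(s <= 0):
        raise ValueError("substrate concentrations must be positive")
    v = params.rate(s)
    if rel_noise > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + rng.normal(0.0, rel_noise, size=v.shape))
        v = np.clip(v, 0.0, None)
    return s, v


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def random_transform(rng: np.random.Generator,
                     translation_scale: float = 10.0) -> RigidTransform:
    return RigidTransform(random_rotation(rng),
                          rng.normal(0.0, translation_scale, size=3))


def _cloud_structure(n_atoms: int, rng: np.random.Generator,
                     label: str = "cloud") -> Structure:
    coords = rng.normal(0.0, 10.0, size=(n_atoms, 3))
    atoms = [
        AtomRecord(serial=i + 1, name="CA", alt_loc="", res_name="GLY",
                   chain_id="A", res_seq=i + 1, i_code="",
                   position=coords[i], occupancy=1.0, b_factor=0.0,
                   element="C", is_hetero=False)
        for i in range(n_atoms)
    ]
    return Structure(label=label, atoms=atoms)


def make_structure_pair(template: Union[Structure, int],
                        transform: RigidTransform, jitter_sd: float = 0.0,
                        seed: int = 0) -> tuple[Structure, Structure]:
    """(reference, mobile) pair related by *transform* plus per-atom jitter.

    Jitter (isotropic Gaussian, sd per coordinate) is applied to the mobile
    copy only, mimicking two independently refined models of one frame.
    """
    rng = np.random.default_rng(seed)
    if isinstance(template, int):
        if template < 3:
            raise ValueError("need at least 3 atoms")
        ref = _cloud_structure(template, rng)
    else:
        ref = template
    mobile_atoms = []
    for atom in ref.atoms:
        pos = transform.apply(atom.position)
        if jitter_sd > 0:
            pos = pos + rng.normal(0.0, jitter_sd, size=3)
        mobile_atoms.append(AtomRecord(
            serial=atom.serial, name=atom.name, alt_loc=atom.alt_loc,
            res_name=atom.res_name, chain_id=atom.chain_id,
            res_seq=atom.res_seq, i_code=atom.i_code, position=pos,
            occupancy=atom.occupancy, b_factor=atom.b_factor,
            element=atom.element, is_hetero=atom.is_hetero,
        ))
    mobile = Structure(label=f"{ref.label}-moved", atoms=mobile_atoms,
                       cell=ref.cell, space_group=ref.space_group)
    return ref, mobile


#: residue spec: (chain_id, res_seq, res_name, is_hetero)
ResidueSpec = tuple[str, int, str, bool]


def make_toy_complex(spec: Sequence[tuple[str, ResidueSpec, Sequence[float]]],
                     label: str = "toy") -> Structure:
    """Minimal complex from (atom name, residue spec, position) triples.

    Element symbols are inferred from the leading letters of the atom name
    (two-letter attempt first, so ``ZN`` maps to zinc).
    """
    from .ligands import ATOMIC_WEIGHTS

    atoms = []
    seen = set()
    for i, (name, (chain, res_seq, res_name, hetero), pos) in enumerate(spec):
        address = (chain, res_seq, "", name)
        if address in seen:
            raise ValueError(f"duplicate atom address {address}")
        seen.add(address)
        element = name[0].upper()
        # hetero species may use two-letter symbols (ZN, CA, NA, ...)
        if hetero and name[:2].capitalize() in ATOMIC_WEIGHTS:
            element = name[:2].capitalize().upper()
        atoms.append(AtomRecord(
            serial=i + 1, name=name, alt_loc="", res_name=res_name,
            chain_id=chain, res_seq=res_seq, i_code="",
            position=np.asarray(pos, dtype=float), occupancy=1.0,
            b_factor=0.0, element=element, is_hetero=hetero,
        ))
    return Structure(label=label, atoms=atoms)
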