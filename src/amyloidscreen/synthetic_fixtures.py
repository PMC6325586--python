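"""Parametric CA-only structure generators with known ground-truth labels.

Three families cover the decision boundaries of the screen:

* :func:`make_cross_beta` — a stack of planar zig-zag extended strands at
  the canonical cross-beta inter-sheet spacing (4.8 A between neighbouring
  chains, 3.8 A CA-CA step, ~3.4 A rise along the strand axis).  Noise-free
  stacks with at least two chains are always positive.
* :func:`make_helix_bundle` — parallel ideal alpha-helices (1.5 A rise,
  100 deg per residue, ~2.3 A radius).  Neighbouring helices keep a
  near-constant mutual distance, so they satisfy the parallelism rule, but
  every pseudo-bond angle sits near 90 deg and the curvature rule rejects
  them: always negative.
* :func:`make_barrel` — one single chain threading extended strands around a
  cylinder: self-parallel geometry that must stay negative purely because the
  screen demands distinct chains.

All geometry constants are textbook values chosen so that noise-free fixtures
sit far from every rule boundary; they carry no claim of physical realism
(no side chains, no hydrogen bonds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import ChainTrace, ResiduePoint, StructureRecord

__all__ = ["FibrilSpec", "make_cross_beta", "make_helix_bundle", "make_barrel"]

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


@dataclass(frozen=True)
class FibrilSpec:
    """Parameters of a synthetic cross-beta stack.

    ``rise`` is the per-residue advance along the strand axis, ``strand_step``
    the CA-CA distance (together they fix the zig-zag amplitude and hence a
    vertex angle of ~127 deg), ``stack_spacing`` the distance between
    neighbouring chains, ``twist_deg`` a per-chain rotation about the stacking
    axis, and ``noise_sd`` the standard deviation of isotropic Gaussian
    coordinate noise.
    """

    n_chains: int = 2
    n_residues: int = 14
    rise: float = 3.4
    strand_step: float = 3.8
    stack_spacing: float = 4.8
    twist_deg: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.n_residues < 3:
            raise ValueError("n_residues must be >= 3")
        if min(self.rise, self.strand_step, self.stack_spacing) <= 0:
            raise ValueError("all lengths must be positive")
        if self.strand_step <= self.rise:
            raise ValueError("strand_step must exceed rise (zig-zag amplitude)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _record(entry_id: str, chain_coords: list[np.ndarray]) -> StructureRecord:
    if len(chain_coords) > len(_CHAIN_IDS):
        raise ValueError("too many chains for the PDB chain alphabet")
    chains = []
    for cid, xyz in zip(_CHAIN_IDS, chain_coords):
        chains.append(
            ChainTrace(
                chain_id=cid,
                residues=tuple(
                    ResiduePoint(cid, i, str(i + 1), tuple(map(float, p)))
                    for i, p in enumerate(xyz)
                ),
            )
        )
    return StructureRecord(entry_id=entry_id, chains=chains)


def _zigzag_strand(n_residues: int, rise: float, step: float) -> np.ndarray:
    """Planar zig-zag along x with CA-CA distance *step* and x-advance *rise*."""
    amp = math.sqrt(step * step - rise * rise) / 2.0
    x = np.arange(n_residues) * rise
    y = amp * np.where(np.arange(n_residues) % 2 == 0, 1.0, -1.0)
    return np.column_stack([x, y, np.zeros(n_residues)])


def make_cross_beta(spec: FibrilSpec) -> StructureRecord:
    """A stack of parallel zig-zag strands; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    base = _zigzag_strand(spec.n_residues, spec.rise, spec.strand_step)
    center = base.mean(axis=0)
    coords = []
    for k in range(spec.n_chains):
        xyz = base.copy()
        if spec.twist_deg:
            ang = math.radians(spec.twist_deg * k)
            c, s = math.cos(ang), math.sin(ang)
            rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            xyz = (xyz - center) @ rot.T + center
        xyz[:, 2] += k * spec.stack_spacing
        if spec.noise_sd > 0:
            xyz = xyz + rng.normal(0.0, spec.noise_sd, xyz.shape)
        coords.append(xyz)
    return _record("crossbeta", coords)


def make_helix_bundle(
    n_chains: int = 2,
    n_residues: int = 20,
    radius: float = 2.3,
    rise_per_res: float = 1.5,
    seed: int = 0,
    bundle_spacing: float = 10.0,
    noise_sd: float = 0.0,
) -> StructureRecord:
    """Parallel ideal alpha-helices, ``bundle_spacing`` A apart, same phase."""
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if n_residues < 4:
        raise ValueError("n_residues must be >= 4")
    if radius <= 0 or rise_per_res <= 0 or bundle_spacing <= 0:
        raise ValueError("all lengths must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_residues)
    phase = np.radians(100.0) * t  # ~3.6 residues per turn
    helix = np.column_stack(
        [radius * np.cos(phase), radius * np.sin(phase), rise_per_res * t]
    )
    coords = []
    for k in range(n_chains):
        xyz = helix.copy()
        xyz[:, 0] += k * bundle_spacing
        if noise_sd > 0:
            xyz = xyz + rng.normal(0.0, noise_sd, xyz.shape)
        coords.append(xyz)
    return _record("helixbundle", coords)


def make_barrel(
    n_strands: int = 8,
    n_res_per_strand: int = 10,
    radius: float | None = None,
    as_chains: bool = False,
) -> StructureRecord:
    """Extended strands on a cylinder, threaded into a SINGLE chain.

    Strands run alternately up and down the cylinder axis and are joined by
    short interpolated turns, so the one chain is parallel to itself — the
    geometry of a beta-barrel.  With ``as_chains=True`` the turns are dropped
    and every strand becomes its own chain, which demonstrates that only the
    distinct-chain requirement (not geometry) keeps barrels out of the list.
    """
    if n_strands < 4:
        raise ValueError("n_strands must be >= 4")
    if n_res_per_strand < 3:
        raise ValueError("n_res_per_strand must be >= 3")
    if radius is None:
        # neighbouring strands ~4.8 A apart on the cylinder
        radius = 4.8 / (2.0 * math.sin(math.pi / n_strands))
    step = 3.4  # rise per residue along the strand axis
    amp = math.sqrt(3.8**2 - step**2) / 2.0
    strands: list[np.ndarray] = []
    for k in range(n_strands):
        ang = 2.0 * math.pi * k / n_strands
        cx, cy = radius * math.cos(ang), radius * math.sin(ang)
        # radial zig-zag keeps the strand locally extended
        wobble = amp * np.where(np.arange(n_res_per_strand) % 2 == 0, 1.0, -1.0)
        z = np.arange(n_res_per_strand) * step
        if k % 2 == 1:
            z = z[::-1]  # antiparallel threading, as in a real barrel
        xyz = np.column_stack(
            [
                cx + wobble * math.cos(ang),
                cy + wobble * math.sin(ang),
                z,
            ]
        )
        strands.append(xyz)
    if as_chains:
        return _record("barrelchains", strands)
    points: list[np.ndarray] = []
    for k, strand in enumerate(strands):
        points.extend(strand)
        if k + 1 < n_strands:
            a, b = strand[-1], strands[k + 1][0]
            for f in (1.0 / 3.0, 2.0 / 3.0):  # two turn residues, gaps < 4.5 A
                mid = a + f * (b - a)
                mid = mid + np.array([0.0, 0.0, 1.0])
                points.append(mid)
    return _record("barrel", [np.array(points)])
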