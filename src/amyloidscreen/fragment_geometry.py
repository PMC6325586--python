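"""Distance profiles, maximal low-variance windows, and pseudo-bond angles.

These are the geometric primitives of the screen.  For an ordered chain pair
(A, B) the *distance profile* holds, for every CA atom of A, the distance to
the nearest CA of B.  Where two chains run parallel — as the strands of a
cross-beta stack do, at ~4.8 A spacing — the profile is nearly constant, so a
low standard deviation over a contiguous window is the signature of
parallelism (rule a).  The *pseudo-bond angle* at a CA vertex, formed with its
two sequence neighbours, separates extended strands (~127 deg) from helices
(~90 deg); its fragment average is the curvature filter (rule b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import ChainTrace

__all__ = [
    "DistanceProfile",
    "Fragment",
    "RuleParams",
    "distance_profile",
    "pseudo_bond_angle",
    "pseudo_dihedral",
    "mean_fragment_angle",
    "maximal_windows",
]


@dataclass(frozen=True)
class RuleParams:
    """Numeric thresholds of the three screening rules.

    Defaults are the published operating point: fragments are runs of
    inter-chain nearest-CA distances with standard deviation at most
    ``sigma_max`` and every distance inside ``[d_min, d_max]`` (rule a), whose
    mean pseudo-bond angle lies in ``[theta_min, theta_max]`` (rule b), and
    which span at least ``len(chain) / length_ratio_divisor`` residues
    (rule c).  All intervals are closed.

    ``sample_std`` switches the standard deviation from the population form
    (divide by n, the default) to the sample form (n - 1) for sensitivity
    analysis.  ``min_fragment_residues`` is a floor of 3 so rule b always has
    at least one interior vertex to average.
    """

    sigma_max: float = 1.5
    d_min: float = 2.0
    d_max: float = 15.0
    theta_min: float = 110.0
    theta_max: float = 180.0
    length_ratio_divisor: float = 7.0
    min_fragment_residues: int = 3
    sample_std: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.d_min < self.d_max:
            raise ValueError("require 0 < d_min < d_max")
        if not 0 <= self.theta_min <= self.theta_max <= 180:
            raise ValueError("require 0 <= theta_min <= theta_max <= 180")
        if self.sigma_max <= 0:
            raise ValueError("sigma_max must be positive")
        if self.length_ratio_divisor < 1:
            raise ValueError("length_ratio_divisor must be >= 1")
        if self.min_fragment_residues < 3:
            raise ValueError("min_fragment_residues must be >= 3")

    @property
    def ddof(self) -> int:
        return 1 if self.sample_std else 0


@dataclass(frozen=True)
class DistanceProfile:
    """Per-residue minimum cross-chain CA distances for an ordered chain pair."""

    source_chain_id: str
    target_chain_id: str
    dmin: np.ndarray  # shape (len(source),), aligned to source seq_index

    def __post_init__(self) -> None:
        d = np.asarray(self.dmin, dtype=float)
        object.__setattr__(self, "dmin", d)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("dmin must be a non-empty 1-d array")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("dmin values must be finite and non-negative")

    def __len__(self) -> int:
        return int(self.dmin.size)


@dataclass(frozen=True)
class Fragment:
    """A contiguous source-chain window that passed all three rules.

    ``start``/``end`` are inclusive seq_index positions in the deposited
    source chain; ``sigma``, ``d_lo``/``d_hi`` summarise the window's slice of
    the distance profile and ``mean_theta`` is its average pseudo-bond angle.
    """

    source_chain_id: str
    target_chain_id: str
    start: int
    end: int
    sigma: float
    d_lo: float
    d_hi: float
    mean_theta: float

    def __post_init__(self) -> None:
        if self.end - self.start + 1 < 3:
            raise ValueError("Fragment must span at least 3 residues")

    def __len__(self) -> int:
        return self.end - self.start + 1


def distance_profile(source: ChainTrace, target: ChainTrace) -> DistanceProfile:
    """Minimum distance from every CA of *source* to the nearest CA of *target*."""
    if source.chain_id == target.chain_id:
        raise ValueError("distance profile requires two distinct chains")
    d = cdist(source.coords(), target.coords()).min(axis=1)
    return DistanceProfile(source.chain_id, target.chain_id, d)


def pseudo_bond_angle(p, q, r) -> float:
    """Angle (degrees, in [0, 180]) at vertex *q* between rays q->p and q->r."""
    p, q, r = (np.asarray(v, dtype=float) for v in (p, q, r))
    u, w = p - q, r - q
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0 or nw == 0:
        raise ValueError("pseudo-bond angle undefined for coincident points")
    cosang = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def pseudo_dihedral(p, q, r, s) -> float:
    """Torsion angle (degrees, in (-180, 180]) of four consecutive CA atoms."""
    p, q, r, s = (np.asarray(v, dtype=float) for v in (p, q, r, s))
    b1, b2, b3 = q - p, r - q, s - r
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2))))


def mean_fragment_angle(chain: ChainTrace, start: int, end: int) -> float:
    """Mean pseudo-bond angle over the interior vertices of chain[start..end].

    *start* and *end* are inclusive seq_index positions; both neighbours of
    every averaged vertex lie inside the fragment, so a fragment must span at
    least 3 residues.
    """
    if end - start + 1 < 3:
        raise ValueError("fragment must span at least 3 residues")
    off = chain.start_index
    xyz = chain.coords()
    i0, i1 = start - off, end - off
    if i0 < 0 or i1 >= len(xyz):
        raise IndexError("fragment outside chain")
    angles = [
        pseudo_bond_angle(xyz[i - 1], xyz[i], xyz[i + 1]) for i in range(i0 + 1, i1)
    ]
    return float(np.mean(angles))


def _window_sigma(prefix: np.ndarray, prefix_sq: np.ndarray, s: int, e: int, ddof: int) -> float:
    n = e - s + 1
    if n - ddof <= 0:
        return 0.0
    total = prefix[e + 1] - prefix[s]
    total_sq = prefix_sq[e + 1] - prefix_sq[s]
    var = (total_sq - total * total / n) / (n - ddof)
    return float(np.sqrt(max(var, 0.0)))


def maximal_windows(profile: DistanceProfile, params: RuleParams) -> list[tuple[int, int]]:
    """All inclusion-maximal windows of the profile satisfying rule (a).

    A window ``[s, e]`` (0-based, inclusive, length >=
    ``params.min_fragment_residues``) qualifies when every distance in it lies
    in ``[d_min, d_max]`` and the standard deviation of its distances is at
    most ``sigma_max``.  A qualifying window is returned iff no strict
    superwindow also qualifies under (i)+(ii).  The deviation constraint is
    not monotone under extension, so maximal windows may overlap; all are
    kept, sorted by start.

    Implementation: with prefix sums the deviation of any window is O(1), so
    all qualifying windows are scanned in O(n^2).  For each start ``s`` only
    the longest qualifying window ``(s, E_s)`` can be maximal (any shorter one
    is contained in it), and ``(s, E_s)`` is dominated exactly when some
    earlier start reaches at least as far right, i.e. ``max_{s' < s} E_{s'} >=
    E_s``; a prefix-maximum scan finishes the filter.
    """
    d = profile.dmin
    n = d.size
    k = params.min_fragment_residues
    inbound = (d >= params.d_min) & (d <= params.d_max)
    prefix = np.concatenate(([0.0], np.cumsum(d)))
    prefix_sq = np.concatenate(([0.0], np.cumsum(d * d)))
    # longest in-bounds run starting at each position
    run_end = np.full(n, -1, dtype=int)
    e = -1
    for s in range(n - 1, -1, -1):
        if inbound[s]:
            if e < s:
                e = s
            while e + 1 < n and inbound[e + 1]:
                e += 1
            run_end[s] = e
        else:
            e = -1

    best_end = np.full(n, -1, dtype=int)
    for s in range(n):
        if run_end[s] < s + k - 1:
            continue
        for e in range(run_end[s], s + k - 2, -1):
            if _window_sigma(prefix, prefix_sq, s, e, params.ddof) <= params.sigma_max:
                best_end[s] = e
                break

    windows: list[tuple[int, int]] = []
    reach = -1  # max best_end over earlier starts
    for s in range(n):
        if best_end[s] > reach:
            windows.append((int(s), int(best_end[s])))
        reach = max(reach, int(best_end[s]))
    return windows
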