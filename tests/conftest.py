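"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from amyloidscreen import FibrilSpec, RuleParams, make_cross_beta, make_helix_bundle


def brute_force_windows(d, params: RuleParams) -> list[tuple[int, int]]:
    """O(n^3) enumeration oracle for rule (a) maximal windows.

    Tests every window directly with numpy and filters the non-maximal ones
    by pairwise containment; independent of the prefix-sum implementation.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    valid = []
    for s in range(n):
        for e in range(s + params.min_fragment_residues - 1, n):
            w = d[s : e + 1]
            if (
                w.min() >= params.d_min
                and w.max() <= params.d_max
                and np.std(w, ddof=params.ddof) <= params.sigma_max
            ):
                valid.append((s, e))
    return sorted(
        (s, e)
        for (s, e) in valid
        if not any(
            s2 <= s and e <= e2 and (s2, e2) != (s, e) for (s2, e2) in valid
        )
    )


def random_profile(rng: np.random.Generator) -> np.ndarray:
    """A random distance profile mixing in-bound, out-of-bound and flat runs."""
    n = int(rng.integers(1, 51))
    kind = rng.integers(0, 3)
    if kind == 0:
        d = rng.uniform(0.0, 20.0, n)
    elif kind == 1:
        d = rng.uniform(3.0, 8.0, n)  # mostly in-bounds, sigma borderline
    else:
        d = np.full(n, rng.uniform(2.0, 15.0)) + rng.normal(0.0, 1.0, n)
    return np.abs(d)


def random_rotation(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A random proper rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-50.0, 50.0, 3)
    return rot, shift


def transform_record(record, rot: np.ndarray, shift: np.ndarray):
    """Apply one rigid-body transform to every chain of a record."""
    from dataclasses import replace

    from amyloidscreen import ChainTrace, ResiduePoint, StructureRecord

    chains = []
    for chain in record.chains:
        xyz = chain.coords() @ rot.T + shift
        chains.append(
            replace(
                chain,
                residues=tuple(
                    replace(r, xyz=tuple(map(float, p)))
                    for r, p in zip(chain.residues, xyz)
                ),
            )
        )
    return StructureRecord(record.entry_id, chains, record.sheet_annotation)


@pytest.fixture
def cross_beta_2x14():
    """Noise-free 2-chain, 14-residue cross-beta stack."""
    return make_cross_beta(FibrilSpec(n_chains=2, n_residues=14))


@pytest.fixture
def helix_bundle_2x20():
    """Two parallel ideal alpha-helices, 20 residues each."""
    return make_helix_bundle(n_chains=2, n_residues=20)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
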