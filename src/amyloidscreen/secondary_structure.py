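"""Decide which chains count as beta-sheet chains before pairwise screening.

A chain pair is only screened when both chains are "identified as
beta-sheets".  Deposited structures disagree about how much help they give
here: crystallographic entries usually carry SHEET / struct_sheet_range
annotation, while many solid-state NMR amyloid depositions carry none.  Three
strategies are therefore offered, selected by :class:`SheetCallConfig.mode`:

``annotation``
    Trust the deposited strand ranges; a residue is extended iff its author
    number falls inside one.
``geometric``
    A CA-only fallback in the spirit of P-SEA: an interior residue is
    extended iff its pseudo-bond angle lies in ``theta_range`` (default
    100-155 deg, the extended-strand band; helices sit near 90 deg) and the
    four-CA pseudo-dihedral starting at its predecessor has absolute value of
    at least 90 deg (strands are near +/-180 deg, helices near +50 deg).
    Terminal residues inherit the flag of the nearest interior residue so
    short amyloid peptides are not penalised at their ends.
``annotation_then_geometric`` (default)
    Annotation when present, geometric otherwise.
``none``
    Every chain qualifies; rules (a)-(c) carry the full burden.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fragment_geometry import pseudo_bond_angle, pseudo_dihedral
from .structure_io import ChainTrace, StructureRecord

__all__ = [
    "SheetCallConfig",
    "NoAnnotationError",
    "residue_extended_flags",
    "is_sheet_chain",
]


class NoAnnotationError(LookupError):
    """Annotation mode was requested but the record carries no sheet records."""


@dataclass(frozen=True)
class SheetCallConfig:
    """How chains qualify as beta-sheet chains.

    ``min_extended_fraction`` is deliberately permissive (0.25): this triage
    only pre-filters chain pairs, and rule (c) independently demands that the
    parallel fragment cover at least 1/7 of the chain.
    """

    mode: str = "annotation_then_geometric"
    min_extended_fraction: float = 0.25
    theta_range: tuple[float, float] = (100.0, 155.0)
    min_abs_dihedral: float = 90.0

    def __post_init__(self) -> None:
        if self.mode not in ("annotation", "geometric", "annotation_then_geometric", "none"):
            raise ValueError(f"unknown sheet-call mode {self.mode!r}")
        if not 0 <= self.min_extended_fraction <= 1:
            raise ValueError("min_extended_fraction must lie in [0, 1]")
        lo, hi = self.theta_range
        if not 0 <= lo <= hi <= 180:
            raise ValueError("theta_range must lie within [0, 180]")


def _annotation_flags(chain: ChainTrace, record: StructureRecord) -> list[bool]:
    if record is None or record.sheet_annotation is None:
        raise NoAnnotationError(
            f"no SHEET/struct_sheet_range annotation for chain {chain.chain_id}"
        )
    ranges = [r for r in record.sheet_annotation if r.chain_id == chain.chain_id]
    flags = []
    for res in chain.residues:
        num = res.auth_seq_id.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz")
        try:
            n = int(num)
        except ValueError:
            flags.append(False)
            continue
        flags.append(any(n in r for r in ranges))
    return flags


def _geometric_flags(chain: ChainTrace, config: SheetCallConfig) -> list[bool]:
    n = len(chain)
    if n < 3:
        return [False] * n
    xyz = chain.coords()
    lo, hi = config.theta_range
    flags: list[bool | None] = [None] * n
    for i in range(1, n - 1):
        theta = pseudo_bond_angle(xyz[i - 1], xyz[i], xyz[i + 1])
        ok = lo <= theta <= hi
        if ok and i + 2 < n:
            tau = pseudo_dihedral(xyz[i - 1], xyz[i], xyz[i + 1], xyz[i + 2])
            ok = abs(tau) >= config.min_abs_dihedral
        elif ok and i >= 2:
            tau = pseudo_dihedral(xyz[i - 2], xyz[i - 1], xyz[i], xyz[i + 1])
            ok = abs(tau) >= config.min_abs_dihedral
        flags[i] = ok
    flags[0] = flags[1]
    flags[-1] = flags[-2]
    return [bool(f) for f in flags]


def residue_extended_flags(
    chain: ChainTrace,
    config: SheetCallConfig,
    record: StructureRecord | None = None,
) -> list[bool]:
    """One extended/not-extended flag per residue of *chain*.

    *record* supplies the sheet annotation for the annotation modes; the
    geometric mode needs only the chain itself.
    """
    if config.mode == "none":
        return [True] * len(chain)
    if config.mode == "annotation":
        return _annotation_flags(chain, record)
    if config.mode == "geometric":
        return _geometric_flags(chain, config)
    # annotation_then_geometric
    try:
        return _annotation_flags(chain, record)
    except NoAnnotationError:
        return _geometric_flags(chain, config)


def is_sheet_chain(
    chain: ChainTrace,
    config: SheetCallConfig,
    record: StructureRecord | None = None,
) -> bool:
    """True iff the fraction of extended residues reaches the configured floor."""
    if config.mode == "none":
        return True
    flags = residue_extended_flags(chain, config, record)
    return sum(flags) / len(flags) >= config.min_extended_fraction
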