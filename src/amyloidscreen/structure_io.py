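"""Read PDB/mmCIF files into a minimal C-alpha chain model, and write it back out.

The screening rules operate on nothing but the ordered C-alpha trace of each
polypeptide chain, so this module deliberately discards everything else:
side chains, ligands, waters, nucleic acids, anisotropic records.  gemmi does
the actual format parsing (both PDB and mmCIF, including ``SHEET`` /
``_struct_sheet_range`` annotations); this module reduces its output to the
:class:`StructureRecord` data model that the rest of the package consumes.

Conventions applied while reading:

* only the FIRST model of a multi-model (NMR) file is used;
* only ``ATOM`` records of standard amino acids contribute C-alpha points
  (modified residues can be admitted through ``extra_residues``);
* for alternate locations of a CA atom, the highest-occupancy one wins,
  ties broken by file order;
* chains left with zero CA atoms are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "ResiduePoint",
    "ChainTrace",
    "StructureRecord",
    "SheetRange",
    "StructureParseError",
    "EmptyStructureError",
    "STANDARD_AMINO_ACIDS",
    "DEFAULT_MAX_GAP",
    "read_structure",
    "split_on_breaks",
    "write_structure",
]

#: Three-letter codes of the 20 canonical amino acids.
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Chain-break threshold (A).  Trans CA-CA is ~3.8 A; anything above this is a
#: gap in the deposited density, not a peptide bond.
DEFAULT_MAX_GAP = 4.5

_PDB_CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


class StructureParseError(ValueError):
    """The file could not be parsed in the requested format."""


class EmptyStructureError(ValueError):
    """The file parsed but contains no protein chain with a CA atom."""


@dataclass(frozen=True)
class ResiduePoint:
    """One residue reduced to its C-alpha position.

    Parameters
    ----------
    chain_id
        Label of the parent chain.
    seq_index
        Ordinal position within the chain trace.  0-based and consecutive for
        freshly read chains; segments produced by :func:`split_on_breaks` keep
        the parent chain's indices so downstream reports refer to positions in
        the deposited chain.
    auth_seq_id
        Author residue number plus insertion code, exactly as read.
    xyz
        Cartesian coordinates in Angstrom.
    """

    chain_id: str
    seq_index: int
    auth_seq_id: str
    xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.xyz) != 3 or not all(math.isfinite(c) for c in self.xyz):
            raise ValueError(f"xyz must be 3 finite components, got {self.xyz!r}")


@dataclass(frozen=True)
class ChainTrace:
    """Ordered C-alpha trace of one polypeptide chain (or break segment)."""

    chain_id: str
    residues: tuple[ResiduePoint, ...]
    source_model: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("ChainTrace requires at least one residue")
        idx = [r.seq_index for r in self.residues]
        if idx != list(range(idx[0], idx[0] + len(idx))):
            raise ValueError("seq_index values must be consecutive")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def start_index(self) -> int:
        return self.residues[0].seq_index

    def coords(self) -> np.ndarray:
        """(n, 3) float array of CA coordinates."""
        return np.array([r.xyz for r in self.residues], dtype=float)


@dataclass(frozen=True)
class SheetRange:
    """One strand interval from a SHEET / struct_sheet_range record."""

    chain_id: str
    start_seq: int
    end_seq: int

    def __contains__(self, auth_num: int) -> bool:
        lo, hi = sorted((self.start_seq, self.end_seq))
        return lo <= auth_num <= hi


@dataclass
class StructureRecord:
    """A structure file reduced to CA traces plus optional sheet annotation."""

    entry_id: str
    chains: list[ChainTrace]
    sheet_annotation: frozenset[SheetRange] | None = None

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids in {self.entry_id}: {ids}")

    def chain(self, chain_id: str) -> ChainTrace:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


def _detect_format(path: Path, format: str) -> gemmi.CoorFormat:
    if format == "pdb":
        return gemmi.CoorFormat.Pdb
    if format == "mmcif":
        return gemmi.CoorFormat.Mmcif
    if format == "auto":
        return gemmi.CoorFormat.Detect
    raise ValueError(f"unknown format {format!r}; expected pdb, mmcif or auto")


def _pick_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy CA of a residue; ties resolved by file order."""
    best = None
    for atom in residue:
        if atom.name != "CA" or atom.element.name != "C":
            continue
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def _sheet_annotation(st: gemmi.Structure) -> frozenset[SheetRange] | None:
    ranges = set()
    for sheet in st.sheets:
        for strand in sheet.strands:
            ranges.add(
                SheetRange(
                    chain_id=strand.start.chain_name,
                    start_seq=strand.start.res_id.seqid.num,
                    end_seq=strand.end.res_id.seqid.num,
                )
            )
    return frozenset(ranges) if ranges else None


def read_structure(
    path: str | Path,
    format: str = "auto",
    extra_residues: Iterable[str] = (),
) -> StructureRecord:
    """Read one structure file into a :class:`StructureRecord`.

    Parameters
    ----------
    path
        PDB or mmCIF file.
    format
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (detect from extension/content).
    extra_residues
        Additional residue names (e.g. ``"MSE"``) admitted into traces on top
        of the 20 standard amino acids.

    Raises
    ------
    StructureParseError
        The file does not parse in the requested format.
    EmptyStructureError
        No chain contributes a single CA atom.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=_detect_format(path, format))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")

    allowed = STANDARD_AMINO_ACIDS | set(extra_residues)
    model = st[0]  # first model only (NMR entries deposit near-identical models)
    chains: list[ChainTrace] = []
    for chain in model:
        points: list[ResiduePoint] = []
        for residue in chain:
            if residue.name not in allowed:
                continue
            if residue.het_flag == "H" and residue.name not in extra_residues:
                continue
            atom = _pick_ca(residue)
            if atom is None:
                continue
            icode = residue.seqid.icode.strip()
            points.append(
                ResiduePoint(
                    chain_id=chain.name,
                    seq_index=len(points),
                    auth_seq_id=f"{residue.seqid.num}{icode}",
                    xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                )
            )
        if points:
            chains.append(
                ChainTrace(
                    chain_id=chain.name,
                    residues=tuple(points),
                    source_model=model.num if hasattr(model, "num") else 1,
                )
            )
    if not chains:
        raise EmptyStructureError(f"{path}: no protein chain with CA atoms")
    return StructureRecord(
        entry_id=path.name.split(".")[0],
        chains=chains,
        sheet_annotation=_sheet_annotation(st),
    )


def split_on_breaks(chain: ChainTrace, max_gap: float = DEFAULT_MAX_GAP) -> list[ChainTrace]:
    """Split a trace wherever consecutive CA atoms are further apart than *max_gap*.

    The outputs partition the input (order preserved, lengths sum to the input
    length) and keep the parent chain's ``seq_index`` values.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    xyz = chain.coords()
    if len(xyz) == 1:
        return [chain]
    gaps = np.linalg.norm(np.diff(xyz, axis=0), axis=1) > max_gap
    segments: list[ChainTrace] = []
    start = 0
    for i, broken in enumerate(gaps):
        if broken:
            segments.append(replace(chain, residues=chain.residues[start : i + 1]))
            start = i + 1
    segments.append(replace(chain, residues=chain.residues[start:]))
    return segments


def write_structure(record: StructureRecord, path: str | Path) -> None:
    """Write a record as a CA-only PDB file (residue type ALA).

    The output round-trips through :func:`read_structure` to an equal record
    (coordinates to the 3-decimal precision of the PDB fixed-width format).
    Chain ids must be single characters from the PDB chain alphabet, which
    caps the record at 62 chains.
    """
    if not record.chains:
        raise ValueError("cannot write a record with no chains")
    if len(record.chains) > len(_PDB_CHAIN_ALPHABET):
        raise ValueError(
            f"{len(record.chains)} chains exceed the {len(_PDB_CHAIN_ALPHABET)}-letter "
            "PDB chain-id alphabet"
        )
    for chain in record.chains:
        if len(chain.chain_id) != 1:
            raise ValueError(
                f"chain id {chain.chain_id!r} is not a single PDB chain character"
            )
    lines = []
    serial = 0
    for chain in record.chains:
        for res in chain.residues:
            serial += 1
            num = res.auth_seq_id if res.auth_seq_id else str(res.seq_index + 1)
            icode = " "
            if num and num[-1].isalpha():
                num, icode = num[:-1], num[-1]
            x, y, z = res.xyz
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA {chain.chain_id}{int(num):4d}{icode}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append(f"TER   {serial + 1:5d}      ALA {chain.chain_id}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
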