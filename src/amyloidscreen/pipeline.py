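"""Batch screening: scan many files, emit the amyloid list, TSV and manifest.

``scan`` is a pure function of its inputs and parameters — re-running it on
the same files yields byte-identical outputs apart from the manifest
timestamp — so any scheduler can wrap it to keep a list current as new
entries appear.  A parse failure of one input never aborts the batch; the
entry is recorded with outcome ``parse_error`` and screening continues.

``fetch`` (network) downloads entries from the RCSB archive by accession,
mmCIF preferred, into a local cache; it is idempotent on cache hits.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
import sys
import time
import urllib.error
import urllib.request
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .classifier import ScreenResult, screen_structure
from .fragment_geometry import RuleParams
from .secondary_structure import SheetCallConfig
from .structure_io import (
    EmptyStructureError,
    StructureParseError,
    read_structure,
)

__all__ = ["RunManifest", "scan", "fetch", "FRAGMENT_TSV_HEADER"]

_PDB_ID_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")
_RCSB_URL = "https://files.rcsb.org/download/{id}.cif"

FRAGMENT_TSV_HEADER = (
    "entry_id\tsource_chain\ttarget_chain\tstart_auth\tend_auth\tlength"
    "\tsigma\td_lo\td_hi\tmean_theta"
)


@dataclass
class RunManifest:
    """Reproducibility record of one batch run."""

    params: RuleParams
    sheet_config: SheetCallConfig
    inputs: list[str]
    timestamp: str
    tool_version: str
    outcomes: dict[str, str] = field(default_factory=dict)  # entry -> outcome

    def to_json(self) -> str:
        doc = {
            "tool_version": self.tool_version,
            "timestamp": self.timestamp,
            "params": asdict(self.params),
            "sheet_config": asdict(self.sheet_config),
            "inputs": self.inputs,
            "outcomes": self.outcomes,
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def _fragment_rows(result: ScreenResult, record) -> list[str]:
    rows = []
    for f in result.fragments:
        chain = record.chain(f.source_chain_id)
        off = chain.start_index
        start_auth = chain.residues[f.start - off].auth_seq_id
        end_auth = chain.residues[f.end - off].auth_seq_id
        rows.append(
            f"{result.entry_id}\t{f.source_chain_id}\t{f.target_chain_id}"
            f"\t{start_auth}\t{end_auth}\t{len(f)}"
            f"\t{f.sigma:.4f}\t{f.d_lo:.3f}\t{f.d_hi:.3f}\t{f.mean_theta:.2f}"
        )
    return rows


def scan(
    inputs: list[str | Path],
    params: RuleParams | None = None,
    sheet_config: SheetCallConfig | None = None,
    out_dir: str | Path = ".",
    log=sys.stderr,
) -> RunManifest:
    """Screen every input file and write the aggregate results.

    Writes ``amyloid_list.txt`` (sorted positive entry ids, one per line),
    ``fragments.tsv`` (one row per passing fragment) and ``manifest.json``
    into *out_dir*.
    """
    if not inputs:
        raise ValueError("no inputs to scan")
    params = params or RuleParams()
    sheet_config = sheet_config or SheetCallConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = RunManifest(
        params=params,
        sheet_config=sheet_config,
        inputs=[str(p) for p in inputs],
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        tool_version=__version__,
    )
    positives: list[str] = []
    tsv_rows: list[str] = []
    for path in inputs:
        path = Path(path)
        t0 = time.perf_counter()
        try:
            record = read_structure(path)
        except (StructureParseError, EmptyStructureError, FileNotFoundError) as exc:
            manifest.outcomes[path.name.split(".")[0]] = "parse_error"
            if log:
                print(f"[scan] {path.name}: parse_error ({exc})", file=log)
            continue
        result = screen_structure(record, params, sheet_config)
        manifest.outcomes[result.entry_id] = "positive" if result.verdict else "negative"
        if result.verdict:
            positives.append(result.entry_id)
            tsv_rows.extend(_fragment_rows(result, record))
        (out_dir / f"{result.entry_id}.json").write_text(result.to_json() + "\n")
        if log:
            elapsed = time.perf_counter() - t0
            print(
                f"[scan] {result.entry_id}: verdict={result.verdict} "
                f"n_fragments={len(result.fragments)} elapsed={elapsed:.2f}s",
                file=log,
            )
    (out_dir / "amyloid_list.txt").write_text(
        "".join(f"{e}\n" for e in sorted(positives))
    )
    (out_dir / "fragments.tsv").write_text(
        "\n".join([FRAGMENT_TSV_HEADER] + tsv_rows) + "\n"
    )
    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def fetch(
    accessions: list[str],
    cache_dir: str | Path,
    timeout: float = 30.0,
    log=sys.stderr,
) -> list[Path]:
    """Download entries by PDB accession into *cache_dir* (mmCIF format).

    Idempotent: accessions already cached are not re-downloaded.  Invalid
    accession patterns raise before any network activity; download failures
    are recorded per id and do not abort the batch.
    """
    for acc in accessions:
        if not _PDB_ID_RE.match(acc):
            raise ValueError(f"{acc!r} is not a valid 4-character PDB accession")
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for acc in accessions:
        dest = cache_dir / f"{acc.upper()}.cif"
        if dest.exists():
            paths.append(dest)
            continue
        url = _RCSB_URL.format(id=acc.upper())
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                dest.write_bytes(resp.read())
            paths.append(dest)
        except (urllib.error.URLError, OSError) as exc:
            if log:
                print(f"[fetch] {acc}: failed ({exc})", file=log)
    return paths
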