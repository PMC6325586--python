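"""Combine the three geometric rules over all ordered chain pairs.

A structure is called amyloid-like iff some ordered pair (A, B) of distinct,
sheet-qualifying chains carries a fragment F of A that

(a) keeps a near-constant distance to B: every nearest-CA distance in F lies
    in [d_min, d_max] and their standard deviation is at most sigma_max;
(b) is nearly straight: the pseudo-bond angles of consecutive CA triples,
    averaged over F, lie in [theta_min, theta_max]; and
(c) is long enough relative to its chain: len(F) >= len(A) / divisor, with
    len(A) counted over the residues of the deposited chain that have a CA.

Single-chain entries are negative by construction — amyloid fibrils are
aggregates of distinct, near-parallel chains, which is also what keeps
beta-barrels (self-parallel strands of one chain) out of the list.

The distance profile is directional, so both (A, B) and (B, A) are screened;
either direction suffices and each surviving window is reported separately.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .fragment_geometry import (
    DistanceProfile,
    Fragment,
    RuleParams,
    distance_profile,
    maximal_windows,
    mean_fragment_angle,
)
from .secondary_structure import SheetCallConfig, is_sheet_chain
from .structure_io import (
    DEFAULT_MAX_GAP,
    ChainTrace,
    StructureRecord,
    split_on_breaks,
)

__all__ = ["PairDiagnostics", "ScreenResult", "screen_pair", "screen_structure"]


@dataclass
class PairDiagnostics:
    """Per-ordered-pair rejection tallies.

    ``failed_a`` counts break-segments that produced no rule-(a) window at
    all; ``failed_b`` / ``failed_c`` count rule-(a) windows rejected by the
    angle and length rules (a window failing both is counted in both).
    """

    failed_a: int = 0
    failed_b: int = 0
    failed_c: int = 0


@dataclass
class ScreenResult:
    """Verdict for one structure with all passing fragments and diagnostics."""

    entry_id: str
    verdict: bool
    fragments: list[Fragment]
    n_chains: int
    n_sheet_chains: int
    rejects: dict[str, PairDiagnostics] = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "entry_id": self.entry_id,
            "verdict": self.verdict,
            "n_chains": self.n_chains,
            "n_sheet_chains": self.n_sheet_chains,
            "fragments": [asdict(f) for f in self.fragments],
            "rejects": {k: asdict(v) for k, v in self.rejects.items()},
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def screen_pair(
    source: ChainTrace,
    target: ChainTrace,
    params: RuleParams,
    max_gap: float = DEFAULT_MAX_GAP,
    diagnostics: PairDiagnostics | None = None,
) -> list[Fragment]:
    """Fragments of *source* that pass rules (a)-(c) against *target*.

    The source chain is split at physical breaks (CA-CA gaps above *max_gap*)
    so neither the deviation of rule (a) nor the angle average of rule (b)
    spans missing density; rule (c) is nevertheless measured against the full
    deposited chain length.
    """
    if source.chain_id == target.chain_id:
        raise ValueError("screen_pair requires two distinct chains")
    diag = diagnostics if diagnostics is not None else PairDiagnostics()
    min_len_c = len(source) / params.length_ratio_divisor
    profile = distance_profile(source, target)
    fragments: list[Fragment] = []
    for segment in split_on_breaks(source, max_gap):
        if len(segment) < params.min_fragment_residues:
            diag.failed_a += 1
            continue
        off = segment.start_index - source.start_index
        sub = DistanceProfile(
            profile.source_chain_id,
            profile.target_chain_id,
            profile.dmin[off : off + len(segment)],
        )
        windows = maximal_windows(sub, params)
        if not windows:
            diag.failed_a += 1
            continue
        for s, e in windows:
            start = segment.start_index + s
            end = segment.start_index + e
            theta = mean_fragment_angle(source, start, end)
            ok_b = params.theta_min <= theta <= params.theta_max
            ok_c = (e - s + 1) >= min_len_c
            if not ok_b:
                diag.failed_b += 1
            if not ok_c:
                diag.failed_c += 1
            if ok_b and ok_c:
                window = sub.dmin[s : e + 1]
                fragments.append(
                    Fragment(
                        source_chain_id=source.chain_id,
                        target_chain_id=target.chain_id,
                        start=start,
                        end=end,
                        sigma=float(np.std(window, ddof=params.ddof)),
                        d_lo=float(window.min()),
                        d_hi=float(window.max()),
                        mean_theta=theta,
                    )
                )
    return fragments


def screen_structure(
    record: StructureRecord,
    params: RuleParams | None = None,
    sheet_config: SheetCallConfig | None = None,
    max_gap: float = DEFAULT_MAX_GAP,
) -> ScreenResult:
    """Screen one structure over all ordered pairs of sheet-qualifying chains."""
    params = params or RuleParams()
    sheet_config = sheet_config or SheetCallConfig()
    n_chains = len(record.chains)
    if n_chains < 2:
        return ScreenResult(record.entry_id, False, [], n_chains, 0, {})
    sheet_chains = [
        c for c in record.chains if is_sheet_chain(c, sheet_config, record)
    ]
    fragments: list[Fragment] = []
    rejects: dict[str, PairDiagnostics] = {}
    for source in sheet_chains:
        for target in sheet_chains:
            if source.chain_id == target.chain_id:
                continue
            diag = PairDiagnostics()
            fragments.extend(
                screen_pair(source, target, params, max_gap, diagnostics=diag)
            )
            rejects[f"{source.chain_id}->{target.chain_id}"] = diag
    return ScreenResult(
        entry_id=record.entry_id,
        verdict=bool(fragments),
        fragments=fragments,
        n_chains=n_chains,
        n_sheet_chains=len(sheet_chains),
        rejects=rejects,
    )
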