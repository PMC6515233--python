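"""Per-column conservation of a protein alignment.

Sequence-logo-style profiling: each column's residue distribution over the
non-gap entries, its Shannon information content in bits relative to a
uniform 20-residue background (log2 20 - H), and extraction of maximal
runs of high-information, low-gap columns as conserved blocks.  Gaps are
excluded from the distribution rather than treated as a 21st symbol, the
usual logo convention; no small-sample correction is applied by default.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .seqio import AlignedSet, GAP

MAX_BITS = math.log2(20)


@dataclass(frozen=True)
class ColumnProfile:
    column: int  # 1-based
    counts: dict  # residue -> count over non-gap entries
    gap_fraction: float
    information_bits: float
    consensus_residue: str  # '-' for gap-only columns
    gap_only: bool


def column_profiles(alignment: AlignedSet) -> list[ColumnProfile]:
    n_seqs = len(alignment.records)
    profiles = []
    for col in range(alignment.length):
        residues = [s[col] for _, s in alignment.records]
        counts = Counter(r for r in residues if r != GAP)
        n_gap = n_seqs - sum(counts.values())
        if not counts:
            profiles.append(
                ColumnProfile(col + 1, {}, 1.0, 0.0, GAP, gap_only=True)
            )
            continue
        total = sum(counts.values())
        entropy = -sum(
            (c / total) * math.log2(c / total) for c in counts.values()
        )
        bits = max(0.0, MAX_BITS - entropy)
        # consensus: most common residue, alphabetical tie-break
        consensus = min(counts, key=lambda r: (-counts[r], r))
        profiles.append(
            ColumnProfile(
                column=col + 1,
                counts=dict(counts),
                gap_fraction=n_gap / n_seqs,
                information_bits=bits,
                consensus_residue=consensus,
                gap_only=False,
            )
        )
    return profiles


def find_conserved_blocks(
    profiles: Sequence[ColumnProfile],
    min_bits: float = 3.0,
    min_len: int = 4,
    max_gapfrac: float = 0.2,
) -> list[tuple[int, int, str]]:
    """Maximal runs of >= min_len columns that all pass both thresholds.

    Returns (start_col, end_col, consensus) with 1-based inclusive columns.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")

    def passes(p: ColumnProfile) -> bool:
        return (
            not p.gap_only
            and p.information_bits >= min_bits
            and p.gap_fraction <= max_gapfrac
        )

    blocks = []
    run_start = None
    for i, p in enumerate(profiles):
        if passes(p):
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if i - run_start >= min_len:
                blocks.append((run_start, i - 1))
            run_start = None
    if run_start is not None and len(profiles) - run_start >= min_len:
        blocks.append((run_start, len(profiles) - 1))
    return [
        (
            profiles[a].column,
            profiles[b].column,
            "".join(profiles[k].consensus_residue for k in range(a, b + 1)),
        )
        for a, b in blocks
    ]


def profiles_table(profiles: Sequence[ColumnProfile]) -> str:
    lines = ["column\tgap_fraction\tinformation_bits\tconsensus"]
    for p in profiles:
        lines.append(
            f"{p.column}\t{p.gap_fraction:.4f}\t{p.information_bits:.4f}\t"
            f"{p.consensus_residue}"
        )
    return "\n".join(lines) + "\n"


def text_logo(profiles: Sequence[ColumnProfile], width: int = 60) -> str:
    """A minimal text-art logo: consensus letters scaled by information."""
    rows = []
    for chunk_start in range(0, len(profiles), width):
        chunk = profiles[chunk_start : chunk_start + width]
        scale = []
        for level in (4, 3, 2, 1):
            scale.append(
                "".join(
                    p.consensus_residue if p.information_bits >= level else " "
                    for p in chunk
                )
            )
        scale.append("".join(p.consensus_residue for p in chunk))
        rows.append("\n".join(scale))
    return ("\n" + "-" * width + "\n").join(rows)
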