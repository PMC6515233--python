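"""Group-II diagnostic cysteine motifs.

One phylogenetic group of plant PAPs carries two invariant cysteine-
containing segments, GGECGV and YERTC, plus a further conserved cysteine
downstream of YERTC; these cysteines are implicated in the inter-subunit
disulfide bridge of the homodimeric high-molecular-mass forms.  In the
yellow-lupin PPD1 structure the YERTC cysteine is C484 and its partner is
C491, so the downstream offset defaults to 7 (six intervening residues).
Matching is exact — the segments are invariant, no degeneracy.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

from .motif_scan import BlockProfile
from .seqio import AlignedSet, ProteinRecord

GGECGV = "GGECGV"
YERTC = "YERTC"
DEFAULT_CYS_OFFSET = 7  # C491 - C484
DEFAULT_GHXH_WINDOW = 15


def find_exact(sequence: str, motif: str) -> list[int]:
    """All 1-based start positions of exact (possibly overlapping) matches."""
    hits = []
    start = 0
    while True:
        i = sequence.find(motif, start)
        if i < 0:
            return hits
        hits.append(i + 1)
        start = i + 1


@dataclass(frozen=True)
class YertcContext:
    start: int  # 1-based start of the YERTC match
    cys_position: int  # position of the motif's own C (start + 4)
    downstream_cys: bool
    downstream_position: int | None  # where the partner C sits if present
    near_ghxh: bool
    ghxh_distance: int | None  # |slot-5 start - motif end|, if slot 5 found


@dataclass(frozen=True)
class CysMotifReport:
    protein_id: str
    ggecgv_hits: tuple
    yertc_hits: tuple  # of YertcContext
    group2_flag: bool

    def __post_init__(self) -> None:
        expected = bool(self.ggecgv_hits) and bool(self.yertc_hits)
        if self.group2_flag != expected:
            raise ValueError("group2_flag inconsistent with motif hits")


def scan_cys_motifs(
    protein: ProteinRecord,
    profile: BlockProfile | None = None,
    cys_offset: int = DEFAULT_CYS_OFFSET,
    ghxh_window: int = DEFAULT_GHXH_WINDOW,
) -> CysMotifReport:
    if profile is not None and profile.protein_id != protein.id:
        raise ValueError(
            f"profile is for {profile.protein_id!r}, protein is {protein.id!r}"
        )
    seq = protein.sequence
    gge = tuple(find_exact(seq, GGECGV))
    slot5 = profile.hits[4] if profile is not None else None
    contexts = []
    for p in find_exact(seq, YERTC):
        cys_pos = p + 4
        partner = cys_pos + cys_offset
        has_partner = partner <= len(seq) and seq[partner - 1] == "C"
        motif_end = p + len(YERTC) - 1
        dist = abs(slot5.start - motif_end) if slot5 is not None else None
        contexts.append(
            YertcContext(
                start=p,
                cys_position=cys_pos,
                downstream_cys=has_partner,
                downstream_position=partner if has_partner else None,
                near_ghxh=dist is not None and dist <= ghxh_window,
                ghxh_distance=dist,
            )
        )
    return CysMotifReport(
        protein_id=protein.id,
        ggecgv_hits=gge,
        yertc_hits=tuple(contexts),
        group2_flag=bool(gge) and bool(contexts),
    )


@dataclass(frozen=True)
class PositionSummary:
    """Per-motif location distribution, in sequence and alignment coordinates."""

    sequence_positions: dict  # motif -> sorted list of 1-based positions
    alignment_columns: dict | None  # motif -> sorted list of columns, if aligned
    median: dict  # motif -> median sequence position (None if no hits)
    spread: dict  # motif -> (min, max) or None


def _to_alignment_column(gapped: str, seq_pos: int) -> int:
    """Map a 1-based ungapped position to its 1-based alignment column."""
    seen = 0
    for col, c in enumerate(gapped, start=1):
        if c != "-":
            seen += 1
            if seen == seq_pos:
                return col
    raise ValueError(f"position {seq_pos} beyond ungapped length")


def motif_position_summary(
    reports: Iterable[CysMotifReport],
    alignment: AlignedSet | None = None,
) -> PositionSummary:
    reports = list(reports)
    if alignment is not None:
        aligned_ids = set(alignment.ids)
        for r in reports:
            if r.protein_id not in aligned_ids:
                raise ValueError(f"{r.protein_id!r} not in the alignment")
    seq_pos: dict[str, list[int]] = {GGECGV: [], YERTC: []}
    aln_pos: dict[str, list[int]] | None = (
        {GGECGV: [], YERTC: []} if alignment is not None else None
    )
    for r in reports:
        hits = {GGECGV: list(r.ggecgv_hits), YERTC: [c.start for c in r.yertc_hits]}
        for motif, positions in hits.items():
            seq_pos[motif].extend(positions)
            if aln_pos is not None:
                gapped = alignment.sequence(r.protein_id)
                aln_pos[motif].extend(
                    _to_alignment_column(gapped, p) for p in positions
                )
    median = {
        m: (statistics.median(v) if v else None) for m, v in seq_pos.items()
    }
    spread = {m: ((min(v), max(v)) if v else None) for m, v in seq_pos.items()}
    return PositionSummary(
        sequence_positions={m: sorted(v) for m, v in seq_pos.items()},
        alignment_columns=(
            {m: sorted(v) for m, v in aln_pos.items()} if aln_pos is not None else None
        ),
        median=median,
        spread=spread,
    )


def report_table(reports: Sequence[CysMotifReport]) -> str:
    """TSV: protein_id, motif, position, downstream_cys, dist_to_GHXH, group2."""
    lines = ["protein_id\tmotif\tposition\tdownstream_cys\tdist_to_GHXH\tgroup2_flag"]
    for r in reports:
        for p in r.ggecgv_hits:
            lines.append(f"{r.protein_id}\t{GGECGV}\t{p}\t\t\t{r.group2_flag}")
        for c in r.yertc_hits:
            dist = "" if c.ghxh_distance is None else str(c.ghxh_distance)
            lines.append(
                f"{r.protein_id}\t{YERTC}\t{c.start}\t{c.downstream_cys}\t"
                f"{dist}\t{r.group2_flag}"
            )
    return "\n".join(lines) + "\n"
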