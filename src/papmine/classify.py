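"""Turn block profiles into PAP candidate calls.

A candidate is called active when at least ``min_blocks`` (default 4) of
the five consensus blocks are found in order; proteins lacking three or
more blocks are treated as inactive relatives.  Size classes follow the
low/high molecular-mass split of the family: LMM proteins (catalytic
domain only) are shorter than 400 residues, HMM proteins carry an extra
N-terminal domain.

Two readings of "complete" are reported side by side: ``complete_blocks``
(all five slots filled, tolerated substitutions allowed — the reading
under which 16 of the 19 curated tea-plant PAPs are complete) and
``complete_metals`` (all seven metal-binding anchors present with their
strict consensus residue, so an F-for-Y block 2 disqualifies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.SeqUtils import molecular_weight as _bio_mw

from .motif_scan import BlockProfile

LMM_MAX_AA = 400  # proteins below this are low-molecular-mass PAPs


@dataclass(frozen=True)
class PapCandidate:
    protein_id: str
    n_blocks: int
    complete_blocks: bool
    complete_metals: bool
    missing_slots: tuple
    size_class: str  # "LMM" | "HMM"
    active_call: bool
    length_aa: int
    mw_kda: float | None = None

    def __post_init__(self) -> None:
        if self.complete_metals and not self.complete_blocks:
            raise ValueError("complete_metals implies complete_blocks")


@dataclass(frozen=True)
class SummaryCounts:
    n_total: int
    n_active: int
    n_all5_blocks: int
    n_missing_slot1: int
    n_noncanonical_slot2: int
    n_lmm: int


def classify_candidate(
    profile: BlockProfile,
    length_aa: int,
    min_blocks: int = 4,
    mw_kda: float | None = None,
) -> PapCandidate:
    if not 1 <= min_blocks <= 5:
        raise ValueError(f"min_blocks must be in 1..5, got {min_blocks}")
    if length_aa < 1:
        raise ValueError("length_aa must be >= 1")
    complete_blocks = profile.n_blocks == 5
    complete_metals = complete_blocks and all(
        all(h.anchors_ok) for h in profile.hits
    )
    return PapCandidate(
        protein_id=profile.protein_id,
        n_blocks=profile.n_blocks,
        complete_blocks=complete_blocks,
        complete_metals=complete_metals,
        missing_slots=tuple(profile.missing_slots),
        size_class="LMM" if length_aa < LMM_MAX_AA else "HMM",
        active_call=profile.n_blocks >= min_blocks,
        length_aa=length_aa,
        mw_kda=mw_kda,
    )


def summarize_candidates(
    candidates: Iterable[PapCandidate],
    profiles: Iterable[BlockProfile] | None = None,
) -> SummaryCounts:
    """Family-level totals.

    ``n_noncanonical_slot2`` needs the underlying profiles (to see the slot-2
    anchor flags); when they are not supplied it falls back to counting
    candidates whose blocks are complete but whose metals are not, which on
    block-table-derived constructs is the same set (F-for-Y is the only
    tolerated anchor substitution).
    """
    cands = list(candidates)
    if profiles is not None:
        by_id = {p.protein_id: p for p in profiles}
        n_nc2 = 0
        for c in cands:
            p = by_id.get(c.protein_id)
            hit = p.hits[1] if p is not None else None
            if hit is not None and not all(hit.anchors_ok):
                n_nc2 += 1
    else:
        n_nc2 = sum(1 for c in cands if c.complete_blocks and not c.complete_metals)
    return SummaryCounts(
        n_total=len(cands),
        n_active=sum(1 for c in cands if c.active_call),
        n_all5_blocks=sum(1 for c in cands if c.complete_blocks),
        n_missing_slot1=sum(1 for c in cands if c.missing_slots == (1,)),
        n_noncanonical_slot2=n_nc2,
        n_lmm=sum(1 for c in cands if c.size_class == "LMM"),
    )


def molecular_weight(sequence: str) -> float:
    """Average (not monoisotopic) protein mass in kDa, one water included.

    Rejects X: an unknown residue has no defined mass here.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if "X" in sequence:
        raise ValueError("sequence contains X; mass undefined")
    return _bio_mw(sequence, seq_type="protein", monoisotopic=False) / 1000.0


def candidate_table(
    candidates: Sequence[PapCandidate],
) -> str:
    """Render candidates as the documented TSV."""
    header = (
        "protein_id\tlength_aa\tmw_kda\tn_blocks\tmissing_slots\t"
        "complete_blocks\tcomplete_metals\tsize_class\tactive_call"
    )
    lines = [header]
    for c in candidates:
        mw = f"{c.mw_kda:.1f}" if c.mw_kda is not None else ""
        missing = ",".join(str(s) for s in c.missing_slots)
        lines.append(
            f"{c.protein_id}\t{c.length_aa}\t{mw}\t{c.n_blocks}\t{missing}\t"
            f"{c.complete_blocks}\t{c.complete_metals}\t{c.size_class}\t{c.active_call}"
        )
    return "\n".join(lines) + "\n"
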