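"""Detection of the five PAP consensus blocks in a protein sequence.

Plant purple acid phosphatases carry five short active-site segments,
conventionally written GDXG / GDXXY / GNH(D/E) / VXXH / GHXH, whose seven
bold residues (D, D, Y, N, H, H, H) coordinate the binuclear Fe(III)-M(II)
center.  The scanner finds every occurrence of each block pattern and then
chooses the ordered, non-overlapping assignment of at most one hit per slot
that maximizes the number of filled slots, subject to spacing bounds
between consecutive chosen blocks.

The per-position residue sets are the minimal degeneracy closure over the
curated tea-plant block table: slot 1 admits A at position 1 and H at
position 4, slot 2 admits F at its final (tyrosine) position, and slot 4's
first three positions are unconstrained.  Matches that use one of these
tolerated substitutions are flagged non-canonical; the strict consensus is
recoverable by filtering on that flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seqio import ProteinRecord

#: expected metal-coordinating residues, in block/slot order
METAL_RESIDUES = ("D", "D", "Y", "N", "H", "H", "H")

_ALL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class BlockPattern:
    """Per-slot position-specific residue sets with metal-binding anchors."""

    slot: int
    allowed: tuple  # per-position frozenset of residues
    canonical: tuple  # per-position frozenset (strict consensus subset)
    anchor_offsets: tuple  # 0-based offsets of metal-binding positions

    def __post_init__(self) -> None:
        if not 1 <= self.slot <= 5:
            raise ValueError(f"slot must be 1..5, got {self.slot}")
        if len(self.allowed) != len(self.canonical):
            raise ValueError("allowed/canonical length mismatch")

    @property
    def length(self) -> int:
        return len(self.allowed)

    def matches(self, peptide: str) -> bool:
        return len(peptide) == self.length and all(
            c in s for c, s in zip(peptide, self.allowed)
        )

    def is_canonical(self, peptide: str) -> bool:
        return all(c in s for c, s in zip(peptide, self.canonical))

    def find_all(self, sequence: str) -> list[int]:
        """1-based start positions of every occurrence."""
        n, m = len(sequence), self.length
        return [
            i + 1
            for i in range(n - m + 1)
            if all(sequence[i + j] in self.allowed[j] for j in range(m))
        ]


@dataclass(frozen=True)
class BlockHit:
    slot: int
    start: int  # 1-based
    matched: str
    anchors_ok: tuple  # per-anchor: residue is the strict consensus one
    canonical: bool  # no tolerated substitution anywhere in the hit

    @property
    def end(self) -> int:
        return self.start + len(self.matched) - 1


@dataclass(frozen=True)
class BlockProfile:
    protein_id: str
    hits: tuple  # 5 entries, BlockHit or None, indexed by slot-1
    n_blocks: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "n_blocks", sum(1 for h in self.hits if h is not None)
        )

    @property
    def missing_slots(self) -> list[int]:
        return [s for s in range(1, 6) if self.hits[s - 1] is None]

    @property
    def metal_residues(self) -> tuple:
        """The seven anchor residues in slot order; '-' where absent."""
        pats = default_patterns()
        out = []
        for pat in pats:
            hit = self.hits[pat.slot - 1]
            for off in pat.anchor_offsets:
                out.append(hit.matched[off] if hit is not None else "-")
        return tuple(out)


@dataclass(frozen=True)
class SpacingConfig:
    """Bounds on the residue gap between consecutive chosen blocks."""

    min_gap: int = 5
    max_gap: int = 400

    def __post_init__(self) -> None:
        if self.min_gap < 0 or self.max_gap < self.min_gap:
            raise ValueError("need 0 <= min_gap <= max_gap")


def _sets(*strings: str) -> tuple:
    return tuple(frozenset(s) for s in strings)


def default_patterns() -> list[BlockPattern]:
    """The five consensus-block patterns with their degeneracy closure.

    Anchors: slot 1 D@2; slot 2 D@2 and Y@5 (F tolerated, non-canonical);
    slot 3 N@2; slot 4 H@4; slot 5 H@2 and H@4.
    """
    X = "ACDEFGHIKLMNPQRSTVWY"
    return [
        BlockPattern(1, _sets("GA", "D", X, "GH"), _sets("G", "D", X, "G"), (1,)),
        BlockPattern(2, _sets("G", "D", X, X, "YF"), _sets("G", "D", X, X, "Y"), (1, 4)),
        BlockPattern(3, _sets("G", "N", "H", "DE"), _sets("G", "N", "H", "DE"), (1,)),
        BlockPattern(4, _sets(X, X, X, "H"), _sets("V", X, X, "H"), (3,)),
        BlockPattern(5, _sets("G", "H", X, "H"), _sets("G", "H", X, "H"), (1, 3)),
    ]


def patterns_to_config(patterns: Sequence[BlockPattern]) -> str:
    """Serialize a pattern set to the documented per-slot text config."""
    lines = []
    for p in patterns:
        for i, (allowed, canon) in enumerate(zip(p.allowed, p.canonical), start=1):
            anchor = "*" if (i - 1) in p.anchor_offsets else ""
            lines.append(
                f"slot{p.slot}\tpos{i}{anchor}\t"
                f"{''.join(sorted(allowed))}\t{''.join(sorted(canon))}"
            )
    return "\n".join(lines) + "\n"


def patterns_from_config(text: str) -> list[BlockPattern]:
    by_slot: dict[int, list[tuple[frozenset, frozenset, bool]]] = {}
    for line in text.strip().split("\n"):
        slot_s, pos_s, allowed, canon = line.split("\t")
        slot = int(slot_s.replace("slot", ""))
        anchor = pos_s.endswith("*")
        by_slot.setdefault(slot, []).append(
            (frozenset(allowed), frozenset(canon), anchor)
        )
    pats = []
    for slot in sorted(by_slot):
        rows = by_slot[slot]
        pats.append(
            BlockPattern(
                slot,
                tuple(a for a, _, _ in rows),
                tuple(c for _, c, _ in rows),
                tuple(i for i, (_, _, anc) in enumerate(rows) if anc),
            )
        )
    return pats


def _make_hit(pattern: BlockPattern, start: int, sequence: str) -> BlockHit:
    matched = sequence[start - 1 : start - 1 + pattern.length]
    anchors_ok = tuple(
        matched[off] in pattern.canonical[off] for off in pattern.anchor_offsets
    )
    return BlockHit(
        slot=pattern.slot,
        start=start,
        matched=matched,
        anchors_ok=anchors_ok,
        canonical=pattern.is_canonical(matched),
    )


def _assignment_key(hits: Sequence[BlockHit]) -> tuple:
    """Ordering key (to minimize): fewer blocks last, then canonical count,
    total span, leftmost starts."""
    n = len(hits)
    n_canon = sum(1 for h in hits if h.canonical)
    span = (hits[-1].end - hits[0].start) if hits else 0
    starts = tuple(h.start for h in hits)
    return (-n, -n_canon, span, starts)


def _compatible(prev: BlockHit, nxt: BlockHit, spacing: SpacingConfig) -> bool:
    gap = nxt.start - prev.end - 1
    return spacing.min_gap <= gap <= spacing.max_gap


def scan_blocks(
    protein: ProteinRecord,
    patterns: Sequence[BlockPattern] | None = None,
    spacing: SpacingConfig | None = None,
) -> BlockProfile:
    """Choose the best ordered assignment of block hits for one protein.

    Among all combinations of at most one occurrence per slot with strictly
    increasing, non-overlapping positions and inter-block gaps within the
    spacing bounds, returns the one maximizing the number of filled slots;
    ties broken by more canonical hits, then smallest total span, then
    leftmost starts.  Branch-and-bound over slots keeps this fast even when
    a weak pattern (slot 4 constrains only its final histidine) has many
    occurrences.
    """
    patterns = list(patterns) if patterns is not None else default_patterns()
    spacing = spacing or SpacingConfig()
    seq = protein.sequence

    occ: list[list[BlockHit]] = []
    for pat in sorted(patterns, key=lambda p: p.slot):
        occ.append([_make_hit(pat, s, seq) for s in pat.find_all(seq)])

    best: list[BlockHit] | None = None
    best_key: tuple | None = None

    def search(slot_idx: int, chosen: list[BlockHit]) -> None:
        nonlocal best, best_key
        if slot_idx == len(occ):
            key = _assignment_key(chosen)
            if best_key is None or key < best_key:
                best, best_key = list(chosen), key
            return
        # bound: even taking every remaining slot cannot beat the best count
        if best_key is not None:
            max_possible = len(chosen) + (len(occ) - slot_idx)
            if -max_possible > best_key[0]:
                return
        for hit in occ[slot_idx]:
            if chosen and not _compatible(chosen[-1], hit, spacing):
                continue
            chosen.append(hit)
            search(slot_idx + 1, chosen)
            chosen.pop()
        search(slot_idx + 1, chosen)  # skip this slot

    search(0, [])
    hits: list[BlockHit | None] = [None] * 5
    for h in best or []:
        hits[h.slot - 1] = h
    return BlockProfile(protein_id=protein.id, hits=tuple(hits))


def scan_proteome(
    records: Iterable[ProteinRecord],
    patterns: Sequence[BlockPattern] | None = None,
    spacing: SpacingConfig | None = None,
    progress_every: int = 1000,
    log=None,
) -> list[BlockProfile]:
    """Scan a whole proteome; one profile per record, order preserved."""
    records = list(records)
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate protein ids: {dupes}")
    profiles = []
    for k, rec in enumerate(records, start=1):
        try:
            profiles.append(scan_blocks(rec, patterns, spacing))
        except Exception as exc:
            raise RuntimeError(f"scan failed on record {rec.id!r}") from exc
        if log is not None and k % progress_every == 0:
            log(f"scanned {k}/{len(records)} proteins")
    return profiles
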