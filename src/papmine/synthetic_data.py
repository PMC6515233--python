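"""Ground-truth-labeled synthetic inputs for every pipeline stage.

Four generators, each a pure function of its parameters and a seed:

* ``generate_proteome`` — proteins carrying chosen consensus blocks in slot
  order joined by neutral linkers, plus decoys with at most a couple of
  blocks, emulating the structure of a screened candidate pool (complete,
  partial and inactive architectures).  Linkers are drawn uniformly over
  the 18 residues excluding D and H: every block pattern requires a D or an
  H, so a linker can never spawn an accidental block match on its own;
  boundary windows are rejection-checked as well.
* ``evolve_sequences`` — sites evolved independently down a given tree
  under the 20-state Jukes-Cantor process (along a branch of length b,
  measured in expected substitutions per site, each site resamples
  uniformly over the alphabet with probability 1 - exp(-b*20/19)), so the
  Poisson-corrected distance is a consistent estimator of path length and
  tree-recovery tests have a mathematically grounded truth.
* ``simulate_counts`` — negative-binomial count matrices with planted
  fold changes for the DEG decision-rule suite.
* ``simulate_reads`` — read alignments drawn from a known isoform mixture
  (constitutive / 5'-limited intron retention / exon skipping) over a
  multi-exon gene model, split at the chosen isoform's junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .motif_scan import BlockPattern, SpacingConfig, default_patterns
from .seqio import (
    BlockTableRow,
    CountMatrix,
    GeneModel,
    ProteinRecord,
    ReadAlignment,
    load_reference_block_table,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: linker alphabet: no D or H (every block pattern needs one, so no match can
#: lie wholly inside a linker), no Y or F (a slot-2 window anchored in a
#: planted block must not borrow its terminal Y/F from the linker), and no V
#: (a slot-4 window starting in the linker must stay non-canonical so the
#: planted assignment always wins the canonical-count tie-break)
LINKER_AA = "".join(c for c in AA20 if c not in "DHYFV")
#: residues used at unconstrained block positions in random block strings;
#: chosen so one slot's random string cannot contain another slot's pattern
SAFE_X = "ILMSTQRKEW"
_MAX_LINKER_RETRIES = 1000


# ---------------------------------------------------------------------------
# Planted-motif proteome


@dataclass(frozen=True)
class PlantedProtein:
    protein_id: str
    slots: tuple  # planted slot numbers, increasing
    block_strings: tuple  # one per planted slot
    positions: tuple = ()  # 1-based starts, filled in by the generator


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """What to plant: which proteins, which slots, which block strings."""

    proteins: tuple  # of PlantedProtein (positions ignored on input)
    n_decoys: int = 0
    decoy_max_blocks: int = 2
    linker_length_range: tuple = (30, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.linker_length_range
        if not 1 <= lo <= hi:
            raise ValueError("linker_length_range must satisfy 1 <= lo <= hi")
        if not 0 <= self.decoy_max_blocks <= 2:
            raise ValueError("decoy_max_blocks must be 0..2")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")


def spec_from_reference_table(
    rows: Sequence[BlockTableRow] | None = None,
    n_decoys: int = 10,
    seed: int = 0,
) -> SyntheticProteomeSpec:
    """Plant each curated row's printed block strings in slot order."""
    rows = list(rows) if rows is not None else load_reference_block_table()
    proteins = []
    for row in rows:
        slots = tuple(s for s in range(1, 6) if row.block_strings[s - 1])
        strings = tuple(row.block_strings[s - 1] for s in slots)
        proteins.append(
            PlantedProtein(protein_id=row.name, slots=slots, block_strings=strings)
        )
    return SyntheticProteomeSpec(
        proteins=tuple(proteins), n_decoys=n_decoys, seed=seed
    )


def random_block_string(
    pattern: BlockPattern, rng: np.random.Generator
) -> str:
    """A random canonical peptide for a pattern; unconstrained positions are
    drawn from SAFE_X so the string cannot double as another slot's match."""
    out = []
    for i in range(pattern.length):
        canon = sorted(pattern.canonical[i])
        pool = SAFE_X if len(canon) == 20 else "".join(canon)
        out.append(pool[rng.integers(len(pool))])
    return "".join(out)


def _linker(
    length: int,
    rng: np.random.Generator,
    left_ctx: str,
    right_ctx: str,
    patterns: Sequence[BlockPattern],
) -> str:
    """A neutral linker spawning no accidental in-linker pattern occurrence.

    The linker alphabet makes a match wholly inside the linker impossible
    (every pattern requires a D or an H); the rejection loop is kept as a
    guard should a caller supply custom patterns without that property.
    """
    for _ in range(_MAX_LINKER_RETRIES):
        linker = "".join(
            LINKER_AA[i] for i in rng.integers(len(LINKER_AA), size=length)
        )
        probe = left_ctx + linker + right_ctx
        ok = True
        for pat in patterns:
            for start in pat.find_all(probe):
                end = start + pat.length - 1
                wholly_in_linker = (
                    start > len(left_ctx) and end <= len(left_ctx) + length
                )
                if wholly_in_linker:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return linker
    raise RuntimeError(f"could not sample a clean linker of length {length}")


def generate_proteome(
    spec: SyntheticProteomeSpec,
    patterns: Sequence[BlockPattern] | None = None,
    spacing: SpacingConfig | None = None,
) -> tuple[list[ProteinRecord], list[PlantedProtein]]:
    """Assemble planted proteins and decoys; returns (records, truth_table).

    Decoy k is named ``decoy<k>`` and carries 0..decoy_max_blocks random
    canonical block strings in increasing slot order, so at the default
    active threshold of 4 blocks no decoy can be called active.
    """
    patterns = list(patterns) if patterns is not None else default_patterns()
    spacing = spacing or SpacingConfig()
    by_slot = {p.slot: p for p in patterns}
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.linker_length_range
    if lo < spacing.min_gap:
        raise ValueError(
            f"linker length {lo} below the spacing lower bound {spacing.min_gap}"
        )
    if hi > spacing.max_gap:
        raise ValueError(
            f"linker length {hi} above the spacing upper bound {spacing.max_gap}"
        )

    planted: list[PlantedProtein] = list(spec.proteins)
    for k in range(spec.n_decoys):
        n_blocks = int(rng.integers(0, spec.decoy_max_blocks + 1))
        slots = tuple(sorted(int(s) + 1 for s in rng.choice(5, size=n_blocks, replace=False)))
        strings = tuple(random_block_string(by_slot[s], rng) for s in slots)
        planted.append(
            PlantedProtein(
                protein_id=f"decoy{k + 1}", slots=slots, block_strings=strings
            )
        )

    records: list[ProteinRecord] = []
    truth: list[PlantedProtein] = []
    for prot in planted:
        for slot, s in zip(prot.slots, prot.block_strings):
            if not by_slot[slot].matches(s):
                raise ValueError(
                    f"{prot.protein_id}: {s!r} does not fit slot {slot}"
                )
        pieces: list[str] = []
        positions: list[int] = []
        pos = 0
        prev_block = ""
        blocks = list(zip(prot.slots, prot.block_strings))
        for slot, block in blocks:
            length = int(rng.integers(lo, hi + 1))
            link = _linker(length, rng, prev_block, block, patterns)
            pieces.append(link)
            pos += length
            positions.append(pos + 1)
            pieces.append(block)
            pos += len(block)
            prev_block = block
        tail = int(rng.integers(lo, hi + 1))
        pieces.append(_linker(tail, rng, prev_block, "", patterns))
        records.append(
            ProteinRecord(id=prot.protein_id, sequence="".join(pieces))
        )
        truth.append(
            PlantedProtein(
                protein_id=prot.protein_id,
                slots=prot.slots,
                block_strings=prot.block_strings,
                positions=tuple(positions),
            )
        )
    return records, truth


def truth_table_tsv(truth: Sequence[PlantedProtein]) -> str:
    lines = ["protein_id\tslots\tblocks\tpositions"]
    for t in truth:
        lines.append(
            f"{t.protein_id}\t"
            + ",".join(str(s) for s in t.slots)
            + "\t"
            + ",".join(t.block_strings)
            + "\t"
            + ",".join(str(p) for p in t.positions)
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Sequence evolution on a tree (20-state Jukes-Cantor)


def evolve_sequences(
    tree, root_length: int, seed: int = 0
):
    """Evolve ``root_length`` sites down a PhyloTree; returns an AlignedSet.

    Root sequence uniform over the 20 residues; along a branch of length b
    (expected substitutions per site) each site independently resamples a
    uniform residue with probability 1 - exp(-b * 20/19), the 20-state
    Jukes-Cantor chain.  No indels, so the leaves are already aligned.
    """
    from .seqio import AlignedSet  # local to avoid cycles at import time

    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(AA20.encode(), dtype=np.uint8)
    root_states = rng.integers(0, 20, size=root_length)

    leaf_seqs: dict[str, str] = {}

    def descend(node, states: np.ndarray) -> None:
        for child in node.child_nodes():
            b = child.edge.length or 0.0
            p_sub = 1.0 - np.exp(-b * 20.0 / 19.0)
            child_states = states.copy()
            if p_sub > 0:
                # equivalent JC formulation: with prob 1-exp(-b*20/19) a site
                # resamples uniformly over all 20 states (so the chance of a
                # visible change is (19/20)(1-exp(-b*20/19)), and branches
                # compose exactly as a Markov chain)
                hit = rng.random(root_length) < p_sub
                n_hit = int(hit.sum())
                if n_hit:
                    child_states[hit] = rng.integers(0, 20, size=n_hit)
            if child.is_leaf():
                leaf_seqs[child.taxon.label] = (
                    alphabet[child_states].tobytes().decode()
                )
            else:
                descend(child, child_states)

    dtree = tree.tree if hasattr(tree, "tree") else tree
    descend(dtree.seed_node, root_states)
    if dtree.seed_node.is_leaf():
        raise ValueError("tree root must be internal")
    return AlignedSet(
        records=tuple(sorted(leaf_seqs.items()))
    )


# ---------------------------------------------------------------------------
# Negative-binomial count matrices


@dataclass(frozen=True)
class CountTruth:
    up_genes: tuple
    down_genes: tuple
    log2_fc: float


def simulate_counts(
    n_genes: int,
    n_up: int,
    n_down: int,
    fc: float = 8.0,
    dispersion: float = 0.05,
    depth: float = 1e6,
    n_reps: int = 3,
    seed: int = 0,
) -> tuple[CountMatrix, CountTruth]:
    """Two-condition NB counts with planted symmetric fold changes.

    Baseline per-gene means are log-uniform over [10, 1000], scaled so each
    library's expected depth is ``depth``; condition B multiplies up-genes
    by fc and down-genes by 1/fc.  Gene lengths uniform in [500, 5000] bp.
    """
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down must not exceed n_genes")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if fc <= 0:
        raise ValueError("fc must be > 0")
    rng = np.random.default_rng(seed)
    base = 10.0 ** rng.uniform(1, 3, size=n_genes)
    lengths = rng.integers(500, 5001, size=n_genes)

    gene_ids = tuple(f"g{i + 1}" for i in range(n_genes))
    idx = rng.permutation(n_genes)
    up = np.sort(idx[:n_up])
    down = np.sort(idx[n_up : n_up + n_down])
    mult_b = np.ones(n_genes)
    mult_b[up] *= fc
    mult_b[down] /= fc

    def draw(means: np.ndarray) -> np.ndarray:
        scaled = means * (depth / means.sum())
        r = 1.0 / dispersion
        p = r / (r + scaled)
        return rng.negative_binomial(r, p, size=n_genes)

    sample_ids = tuple(
        [f"A{r + 1}" for r in range(n_reps)] + [f"B{r + 1}" for r in range(n_reps)]
    )
    cols = [draw(base) for _ in range(n_reps)] + [
        draw(base * mult_b) for _ in range(n_reps)
    ]
    counts = tuple(
        tuple(int(cols[s][g]) for s in range(2 * n_reps)) for g in range(n_genes)
    )
    truth = CountTruth(
        up_genes=tuple(gene_ids[i] for i in up),
        down_genes=tuple(gene_ids[i] for i in down),
        log2_fc=float(np.log2(fc)),
    )
    return (
        CountMatrix(gene_ids, sample_ids, counts, tuple(int(x) for x in lengths)),
        truth,
    )


# ---------------------------------------------------------------------------
# Deterministic nine-exon splicing worked example


def splice_worked_example(
    n_es: int = 12,
    n_ir: int = 15,
    n_canonical_per_junction: int = 4,
    read_len: int = 50,
) -> tuple[GeneModel, list[ReadAlignment]]:
    """A deterministic nine-exon gene with planted splicing evidence.

    The gene has nine 200-bp exons separated by 300-bp introns.  Planted
    reads: ``n_es`` split reads whose junction joins the end of exon 6 to
    the start of exon 8 (exon-7 skipping), ``n_ir`` contiguous reads
    extending from the 3' end of exon 7 into the first ~40 bp of intron 7
    (5'-confined intron retention), and ``n_canonical_per_junction`` split
    reads across every adjacent exon junction (constitutive support).
    """
    exons = tuple((1 + i * 500, 200 + i * 500) for i in range(9))
    model = GeneModel("gene_AS", "scaffold1", "+", exons)
    reads: list[ReadAlignment] = []
    e6_end = exons[5][1]
    e8_start = exons[7][0]
    for i in range(n_es):
        left = 10 + (i % (read_len - 20))  # bases on the donor side
        reads.append(
            ReadAlignment(
                f"es{i + 1}",
                model.chrom,
                (
                    (e6_end - left + 1, e6_end),
                    (e8_start, e8_start + (read_len - left) - 1),
                ),
            )
        )
    e7_end = exons[6][1]
    for j in range(n_ir):
        into_intron = 10 + j  # 10..(9 + n_ir) bases past the exon boundary
        start = e7_end - (read_len - into_intron) + 1
        reads.append(
            ReadAlignment(
                f"ir{j + 1}", model.chrom, ((start, start + read_len - 1),)
            )
        )
    for k in range(len(exons) - 1):
        el_end = exons[k][1]
        er_start = exons[k + 1][0]
        for c in range(n_canonical_per_junction):
            left = 15 + 5 * c
            reads.append(
                ReadAlignment(
                    f"can{k + 1}_{c + 1}",
                    model.chrom,
                    (
                        (el_end - left + 1, el_end),
                        (er_start, er_start + (read_len - left) - 1),
                    ),
                )
            )
    return model, reads


# ---------------------------------------------------------------------------
# Read simulation over a gene model


@dataclass(frozen=True)
class IsoformMix:
    """Fractions of reads from each transcript form (must sum to 1)."""

    constitutive: float = 1.0
    ir: float = 0.0
    ir_intron: int = 1  # which intron is retained (1-based)
    ir_fraction: float = 0.5  # how much of the intron's 5' end is retained
    es: float = 0.0
    es_pair: tuple = (1, 3)  # (donor exon, acceptor exon), non-adjacent

    def __post_init__(self) -> None:
        total = self.constitutive + self.ir + self.es
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mix fractions must sum to 1, got {total}")
        if self.es and self.es_pair[1] <= self.es_pair[0] + 1:
            raise ValueError("es_pair must skip at least one exon")
        if not 0 < self.ir_fraction <= 1:
            raise ValueError("ir_fraction must be in (0, 1]")


def _isoform_segments(model: GeneModel, mix: IsoformMix, which: str):
    """Genomic segments (1-based inclusive) of one transcript form."""
    exons = list(model.exons)
    if which == "constitutive":
        return exons
    if which == "ir":
        istart, iend = model.introns[mix.ir_intron - 1]
        ilen = iend - istart + 1
        keep = max(1, int(round(ilen * mix.ir_fraction)))
        if model.strand == "+":
            retained = (istart, istart + keep - 1)
        else:
            retained = (iend - keep + 1, iend)
        segs = exons[: mix.ir_intron] + [retained] + exons[mix.ir_intron :]
        # merge the retained piece with its neighbour exon when contiguous
        merged: list[tuple[int, int]] = []
        for s, e in sorted(segs):
            if merged and s == merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        return merged
    if which == "es":
        donor, acceptor = mix.es_pair
        return exons[:donor] + exons[acceptor - 1 :]
    raise ValueError(which)


def simulate_reads(
    model: GeneModel,
    mix: IsoformMix,
    n_reads: int = 500,
    read_len: int = 50,
    seed: int = 0,
) -> tuple[list[ReadAlignment], list[str]]:
    """Uniformly placed reads from a known isoform mixture.

    Each read picks an isoform by the mix fractions, a uniform start on the
    transcript, and is split into genomic segments at that isoform's
    junctions.  Returns (reads, per-read isoform labels).
    """
    import warnings as _warnings

    shortest_exon = min(e - s + 1 for s, e in model.exons)
    if read_len > shortest_exon:
        _warnings.warn(
            f"read_len {read_len} exceeds the shortest exon ({shortest_exon} bp); "
            "junction reads may span more than two segments",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    forms = []
    probs = []
    for name, p in (("constitutive", mix.constitutive), ("ir", mix.ir), ("es", mix.es)):
        if p > 0:
            forms.append(name)
            probs.append(p)
    seg_cache = {f: _isoform_segments(model, mix, f) for f in forms}

    reads: list[ReadAlignment] = []
    labels: list[str] = []
    for k in range(n_reads):
        form = forms[rng.choice(len(forms), p=np.asarray(probs) / sum(probs))]
        segs = seg_cache[form]
        tx_len = sum(e - s + 1 for s, e in segs)
        if read_len > tx_len:
            raise ValueError("read_len longer than the transcript")
        start = int(rng.integers(0, tx_len - read_len + 1))
        remaining = read_len
        offset = start
        out_segs: list[tuple[int, int]] = []
        for s, e in segs:
            seg_len = e - s + 1
            if offset >= seg_len:
                offset -= seg_len
                continue
            take = min(remaining, seg_len - offset)
            out_segs.append((s + offset, s + offset + take - 1))
            remaining -= take
            offset = 0
            if remaining == 0:
                break
        reads.append(
            ReadAlignment(
                read_id=f"read{k + 1}", chrom=model.chrom, segments=tuple(out_segs)
            )
        )
        labels.append(form)
    return reads, labels
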