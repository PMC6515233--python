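"""Readers and writers for the external formats the pipeline touches.

Protein FASTA (plain and aligned), gene models (GFF3 exon features or
BED12), Newick trees, TSV count matrices, TSV read-alignment tables, and
the curated tea-plant PAP consensus-block reference table that anchors the
classification examples.

Coordinate conventions: protein positions are 1-based; genomic intervals
are stored 1-based inclusive.  BED input (0-based half-open) is converted
at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
#: letters tolerated on input but folded to X (ambiguity / rare residues)
NONCANONICAL_AA = set("BZUOJ")
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedSet:
    """An externally produced multiple alignment (gap character '-')."""

    records: tuple  # of (id, gapped sequence) pairs, order preserved
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise FormatError("alignment needs at least 2 sequences")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise FormatError(f"unequal alignment lengths: {sorted(lengths)}")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate ids in alignment")
        object.__setattr__(self, "length", lengths.pop())

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def sequence(self, rec_id: str) -> str:
        for i, s in self.records:
            if i == rec_id:
                return s
        raise KeyError(rec_id)

    def gap_only_columns(self) -> list[int]:
        """1-based columns where every sequence has a gap."""
        out = []
        for c in range(self.length):
            if all(s[c] == GAP for _, s in self.records):
                out.append(c + 1)
        return out


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered set of exons; introns are the gaps between."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple  # of (start, end), 1-based inclusive, sorted, non-overlapping

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise FormatError(f"gene {self.gene_id} has no exons")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise FormatError(f"exon {s}-{e} inverted in {self.gene_id}")
            if prev_end is not None and s <= prev_end:
                raise FormatError(f"overlapping/unsorted exons in {self.gene_id}")
            prev_end = e

    @property
    def introns(self) -> list[tuple[int, int]]:
        """1-based inclusive intron intervals between consecutive exons."""
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    chrom: str
    segments: tuple  # of (start, end), 1-based inclusive, sorted

    def __post_init__(self) -> None:
        if not self.segments:
            raise FormatError(f"read {self.read_id} has no segments")
        prev_end = None
        for s, e in self.segments:
            if s > e:
                raise FormatError(f"segment {s}-{e} inverted in {self.read_id}")
            if prev_end is not None and s <= prev_end:
                raise FormatError(f"overlapping segments in {self.read_id}")
            prev_end = e

    @property
    def is_split(self) -> bool:
        return len(self.segments) >= 2

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """(last base of left segment, first base of right segment) pairs."""
        return [
            (self.segments[i][1], self.segments[i + 1][0])
            for i in range(len(self.segments) - 1)
        ]


@dataclass(frozen=True)
class CountMatrix:
    gene_ids: tuple
    sample_ids: tuple
    counts: tuple  # rows = genes, columns = samples, non-negative ints
    gene_lengths: tuple  # bp, one per gene

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.gene_ids):
            raise FormatError("count rows do not match gene ids")
        if len(self.gene_lengths) != len(self.gene_ids):
            raise FormatError("gene_lengths must cover every gene")
        for row in self.counts:
            if len(row) != len(self.sample_ids):
                raise FormatError("count row width does not match sample ids")
            if any(c < 0 for c in row):
                raise FormatError("negative count")
        if any(l <= 0 for l in self.gene_lengths):
            raise FormatError("gene lengths must be positive")


@dataclass(frozen=True)
class BlockTableRow:
    """One curated PAP: its five consensus-block strings (empty = absent)."""

    gene_id: str
    name: str
    block_strings: tuple  # 5 entries, '' where the block is absent
    domains: tuple

    SLOT_LENGTHS = (4, 5, 4, 4, 4)

    def __post_init__(self) -> None:
        if len(self.block_strings) != 5:
            raise FormatError(f"{self.name}: need 5 block slots")
        for slot, s in enumerate(self.block_strings, start=1):
            if s and len(s) != self.SLOT_LENGTHS[slot - 1]:
                raise FormatError(
                    f"{self.name}: slot {slot} string {s!r} has wrong length"
                )


# ---------------------------------------------------------------------------
# FASTA


def sanitize_sequence(seq: str, rec_id: str = "?") -> str:
    """Upper-case, strip one terminal '*', fold rare letters to X."""
    s = seq.upper().strip()
    if s.endswith("*"):
        s = s[:-1]
    folded = set(s) & NONCANONICAL_AA
    if folded:
        warnings.warn(
            f"record {rec_id!r}: non-canonical residues {sorted(folded)} mapped to X",
            stacklevel=2,
        )
        s = "".join("X" if c in NONCANONICAL_AA else c for c in s)
    return s


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=sanitize_sequence(str(rec.seq), rec.id),
                description=rec.description[len(rec.id):].strip(),
            )
        )
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    bio = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    _BioSeqIO.write(bio, str(path), "fasta")


def read_aligned_fasta(path: str | Path) -> AlignedSet:
    pairs = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        pairs.append((rec.id, str(rec.seq).upper()))
    if not pairs:
        raise FormatError(f"no FASTA records in {path}")
    return AlignedSet(records=tuple(pairs))


def write_aligned_fasta(alignment: AlignedSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in alignment.records:
            fh.write(f">{rec_id}\n{seq}\n")


# ---------------------------------------------------------------------------
# Gene models


def _read_bed12(path: str | Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{ln}: BED12 needs 12 fields")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{ln}: blockCount mismatch")
            # 0-based half-open -> 1-based inclusive
            exons = tuple(
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            models.append(GeneModel(name, chrom, strand, exons))
    return models


def _read_gff3(path: str | Path) -> list[GeneModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{ln}: GFF3 needs 9 fields")
            chrom, _, ftype, start, end, _, strand, _, attrs = f
            if ftype.lower() != "exon":
                continue
            parent = None
            for kv in attrs.split(";"):
                kv = kv.strip()
                if kv.startswith("Parent="):
                    parent = kv[len("Parent="):]
            if parent is None:
                raise FormatError(f"{path}:{ln}: exon without Parent attribute")
            if parent not in exons:
                exons[parent] = []
                meta[parent] = (chrom, strand)
                order.append(parent)
            exons[parent].append((int(start), int(end)))
    models = []
    for gid in order:
        chrom, strand = meta[gid]
        models.append(GeneModel(gid, chrom, strand, tuple(sorted(exons[gid]))))
    return models


def read_gene_models(path: str | Path, dialect: str) -> list[GeneModel]:
    if dialect == "bed12":
        return _read_bed12(path)
    if dialect == "gff3":
        return _read_gff3(path)
    raise FormatError(f"unknown gene-model dialect {dialect!r}")


def write_bed12(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start0 = m.exons[0][0] - 1
            end0 = m.exons[-1][1]
            sizes = ",".join(str(e - s + 1) for s, e in m.exons)
            starts = ",".join(str(s - 1 - start0) for s, _ in m.exons)
            fh.write(
                "\t".join(
                    [
                        m.chrom, str(start0), str(end0), m.gene_id, "0",
                        m.strand, str(start0), str(end0), "0",
                        str(len(m.exons)), sizes, starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Read-alignment TSV: read_id <tab> chrom <tab> "start-end;start-end"


def read_alignment_table(path: str | Path) -> list[ReadAlignment]:
    reads = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 3:
                raise FormatError(f"{path}:{ln}: need read_id, chrom, segments")
            segs = []
            for part in f[2].split(";"):
                s, _, e = part.partition("-")
                segs.append((int(s), int(e)))
            reads.append(ReadAlignment(f[0], f[1], tuple(segs)))
    return reads


def write_alignment_table(reads: Iterable[ReadAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            segs = ";".join(f"{s}-{e}" for s, e in r.segments)
            fh.write(f"{r.read_id}\t{r.chrom}\t{segs}\n")


# ---------------------------------------------------------------------------
# Count matrix TSV: header = gene_id, length_bp, <samples...>


def read_count_matrix(path: str | Path) -> CountMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "gene_id" or header[1] != "length_bp":
            raise FormatError(
                f"{path}: header must start 'gene_id\\tlength_bp\\t<samples>'"
            )
        samples = tuple(header[2:])
        gene_ids, lengths, rows = [], [], []
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(header):
                raise FormatError(f"{path}:{ln}: column count mismatch")
            gene_ids.append(f[0])
            lengths.append(int(f[1]))
            rows.append(tuple(int(x) for x in f[2:]))
    return CountMatrix(tuple(gene_ids), samples, tuple(rows), tuple(lengths))


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlength_bp\t" + "\t".join(cm.sample_ids) + "\n")
        for gid, length, row in zip(cm.gene_ids, cm.gene_lengths, cm.counts):
            fh.write(f"{gid}\t{length}\t" + "\t".join(str(c) for c in row) + "\n")


# ---------------------------------------------------------------------------
# Newick (dendropy-backed)


def read_newick(path: str | Path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"malformed Newick in {path}: {exc}") from exc


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6g",
    )


# ---------------------------------------------------------------------------
# Curated reference block table


def load_reference_block_table() -> list[BlockTableRow]:
    """The 19 curated tea-plant PAPs and their printed consensus-block strings.

    Ships with the package as a versioned TSV; this is the worked example that
    grounds the scanner's degeneracy sets and the classification counts
    (19 active, 16 with all five blocks, 3 lacking only the first block).
    """
    text = (
        resources.files("papmine").joinpath("data/tea_pap_blocks.tsv").read_text()
    )
    lines = text.strip().split("\n")
    rows = []
    for line in lines[1:]:
        f = line.split("\t")
        rows.append(
            BlockTableRow(
                gene_id=f[0],
                name=f[1],
                block_strings=tuple(f[2:7]),
                domains=tuple(f[7].split(";")) if len(f) > 7 and f[7] else (),
            )
        )
    if len(rows) != 19:
        raise FormatError(f"reference block table must have 19 rows, got {len(rows)}")
    return rows
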