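"""Junction-read evidence for alternative splicing over one gene model.

Two event kinds are called from mapped-read coordinates alone:

* exon skipping (ES): split reads whose junction joins the donor end of
  exon i to the acceptor start of exon j with j > i + 1, matched exactly
  (the inputs are aligner-derived coordinates, so the default tolerance
  is 0 bp and configurable for noisier pipelines);
* intron retention (IR): contiguous (non-split) reads overlapping an
  intron's interior by at least ``min_ir_bases``; the call records which
  fraction of the intron the supporting reads cover and whether that
  coverage is confined to the intron's 5' half, the pattern seen when a
  retained intron is only partially transcribed or processed.

Events need ``min_support`` reads (default 3).  Transcript-form counting
is deliberately conservative: one form per supported event plus the
constitutive form; stacked multi-event isoforms are not inferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import GeneModel, ReadAlignment


@dataclass(frozen=True)
class IrDetail:
    covered_fraction: float  # of intron bases covered by supporting reads
    five_prime_biased: bool  # covered bases confined to the 5' half


@dataclass(frozen=True)
class AsEvent:
    gene_id: str
    kind: str  # "intron_retention" | "exon_skipping"
    target: tuple  # (intron_index,) for IR; (donor_exon, acceptor_exon) for ES
    support: int
    detail: IrDetail | None = None

    def __post_init__(self) -> None:
        if self.kind == "exon_skipping":
            donor, acceptor = self.target
            if acceptor <= donor + 1:
                raise ValueError("exon-skipping pair must be non-adjacent")
        elif self.kind != "intron_retention":
            raise ValueError(f"unknown event kind {self.kind!r}")


def call_as_events(
    model: GeneModel,
    reads: Iterable[ReadAlignment],
    min_support: int = 3,
    min_ir_bases: int = 10,
    junction_tolerance: int = 0,
    log=None,
) -> list[AsEvent]:
    """Call IR and ES events supported by >= min_support reads."""
    introns = model.introns
    exons = model.exons
    span_start, span_end = model.span
    n_outside = 0

    es_support: dict[tuple[int, int], int] = {}
    ir_support = [0] * len(introns)
    ir_covered = [set() for _ in introns]  # covered intron offsets (0-based)

    for read in reads:
        if read.chrom != model.chrom:
            n_outside += 1
            continue
        if read.segments[-1][1] < span_start or read.segments[0][0] > span_end:
            n_outside += 1
            continue
        if read.is_split:
            for jl, jr in read.junctions:
                for i in range(len(exons)):
                    for j in range(i + 2, len(exons)):
                        if (
                            abs(jl - exons[i][1]) <= junction_tolerance
                            and abs(jr - exons[j][0]) <= junction_tolerance
                        ):
                            es_support[(i + 1, j + 1)] = (
                                es_support.get((i + 1, j + 1), 0) + 1
                            )
        else:
            (rs, re) = read.segments[0]
            for k, (istart, iend) in enumerate(introns):
                ov_start = max(rs, istart)
                ov_end = min(re, iend)
                overlap = ov_end - ov_start + 1
                if overlap >= min_ir_bases:
                    ir_support[k] += 1
                    ir_covered[k].update(
                        range(ov_start - istart, ov_end - istart + 1)
                    )
    if log is not None and n_outside:
        log(f"{n_outside} reads outside the {model.gene_id} span were ignored")

    events: list[AsEvent] = []
    for k, (istart, iend) in enumerate(introns):
        if ir_support[k] < min_support:
            continue
        ilen = iend - istart + 1
        covered = ir_covered[k]
        # the 5' half depends on strand: genomic-left for '+', right for '-'
        half = ilen / 2
        if model.strand == "+":
            biased = all(off < half for off in covered)
        else:
            biased = all(off >= ilen - half for off in covered)
        events.append(
            AsEvent(
                gene_id=model.gene_id,
                kind="intron_retention",
                target=(k + 1,),
                support=ir_support[k],
                detail=IrDetail(
                    covered_fraction=len(covered) / ilen,
                    five_prime_biased=biased,
                ),
            )
        )
    for (donor, acceptor), support in sorted(es_support.items()):
        if support < min_support:
            continue
        events.append(
            AsEvent(
                gene_id=model.gene_id,
                kind="exon_skipping",
                target=(donor, acceptor),
                support=support,
            )
        )
    return events


@dataclass(frozen=True)
class TranscriptFormSet:
    gene_id: str
    forms: frozenset  # of labels; "constitutive" plus one per event
    n_forms: int

    def __post_init__(self) -> None:
        if self.n_forms != len(self.forms):
            raise ValueError("n_forms must equal |forms|")


def enumerate_forms(model: GeneModel, events: Sequence[AsEvent]) -> TranscriptFormSet:
    """Constitutive form plus one labeled form per supported event."""
    labels = {"constitutive"}
    for ev in events:
        if ev.gene_id != model.gene_id:
            raise ValueError(
                f"event for {ev.gene_id!r} mixed into {model.gene_id!r}"
            )
        if ev.kind == "intron_retention":
            labels.add(f"IR_intron{ev.target[0]}")
        else:
            labels.add(f"ES_exon{ev.target[0]}-exon{ev.target[1]}")
    return TranscriptFormSet(
        gene_id=model.gene_id, forms=frozenset(labels), n_forms=len(labels)
    )


def events_table(events: Sequence[AsEvent]) -> str:
    lines = ["gene_id\tkind\ttarget\tsupport\tdetail"]
    for ev in events:
        if ev.kind == "intron_retention":
            target = f"intron{ev.target[0]}"
            detail = (
                f"covered={ev.detail.covered_fraction:.3f};"
                f"5prime_biased={ev.detail.five_prime_biased}"
            )
        else:
            target = f"exon{ev.target[0]}-exon{ev.target[1]}"
            detail = ""
        lines.append(f"{ev.gene_id}\t{ev.kind}\t{target}\t{ev.support}\t{detail}")
    return "\n".join(lines) + "\n"
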