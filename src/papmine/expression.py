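"""FPKM quantification, a simple two-condition DEG test, expression bins.

FPKM = counts * 1e9 / (gene length in bp * library size), with library
size taken as each sample's total counted fragments.  Differential calls
reproduce the decision rule adjusted p < 0.05 AND fold change > 2
(|log2 FC| > 1); the per-gene p-value comes from a documented simple
test — Welch's t on log2(FPKM + 1) by default, or a method-of-moments
negative-binomial Wald test — since a full shrinkage-based RNA-seq model
is deliberately out of scope.  Benjamini-Hochberg controls the FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .seqio import CountMatrix

DEG_ADJ_P = 0.05
DEG_ABS_LOG2_FC = 1.0  # fold change > 2
PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class ExpressionTable:
    gene_ids: tuple
    sample_ids: tuple
    fpkm: np.ndarray  # genes x samples

    def value(self, gene_id: str, sample_id: str) -> float:
        return float(
            self.fpkm[self.gene_ids.index(gene_id), self.sample_ids.index(sample_id)]
        )

    def to_tsv(self) -> str:
        lines = ["gene_id\t" + "\t".join(self.sample_ids)]
        for g, row in zip(self.gene_ids, self.fpkm):
            lines.append(g + "\t" + "\t".join(f"{v:.4f}" for v in row))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class DegRecord:
    gene_id: str
    log2_fc: float
    p_value: float
    adj_p: float
    is_deg: bool
    direction: str  # up | down | none

    def __post_init__(self) -> None:
        expected = self.adj_p < DEG_ADJ_P and abs(self.log2_fc) > DEG_ABS_LOG2_FC
        if self.is_deg != expected:
            raise ValueError("is_deg inconsistent with the decision rule")
        if self.is_deg:
            want = "up" if self.log2_fc > 0 else "down"
            if self.direction != want:
                raise ValueError("direction inconsistent with log2_fc sign")
        elif self.direction != "none":
            raise ValueError("non-DEG records have direction 'none'")


def fpkm(counts: CountMatrix) -> ExpressionTable:
    mat = np.asarray(counts.counts, dtype=float)
    lengths = np.asarray(counts.gene_lengths, dtype=float)
    libsize = mat.sum(axis=0)
    if np.any(libsize <= 0):
        empty = [s for s, t in zip(counts.sample_ids, libsize) if t <= 0]
        raise ValueError(f"samples with zero total counts: {empty}")
    vals = mat * 1e9 / (lengths[:, None] * libsize[None, :])
    return ExpressionTable(
        gene_ids=tuple(counts.gene_ids),
        sample_ids=tuple(counts.sample_ids),
        fpkm=vals,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch_log_p(a: np.ndarray, b: np.ndarray) -> float:
    la = np.log2(a + PSEUDOCOUNT)
    lb = np.log2(b + PSEUDOCOUNT)
    if np.var(la) == 0 and np.var(lb) == 0:
        return 1.0 if np.mean(la) == np.mean(lb) else 0.0
    return float(_stats.ttest_ind(la, lb, equal_var=False).pvalue)


def _nb_moments_p(a: np.ndarray, b: np.ndarray) -> float:
    """Method-of-moments negative-binomial Wald test on raw counts.

    Per group, dispersion is estimated as max(0, (s^2 - m)/m^2); the Wald
    statistic compares log means with delta-method variances
    var(log m) ~= (1/m + phi)/n.
    """

    def logmean_var(x: np.ndarray) -> tuple[float, float]:
        m = float(np.mean(x))
        if m <= 0:
            m = 0.5  # continuity floor for all-zero groups
        s2 = float(np.var(x, ddof=1))
        phi = max(0.0, (s2 - m) / (m * m))
        return math.log(m), (1.0 / m + phi) / len(x)

    la, va = logmean_var(a)
    lb, vb = logmean_var(b)
    z = (lb - la) / math.sqrt(va + vb) if (va + vb) > 0 else 0.0
    return float(2 * _stats.norm.sf(abs(z)))


def call_degs(
    counts: CountMatrix,
    groups: Mapping[str, str],
    test: str = "welch_log",
    alpha: float = DEG_ADJ_P,
    min_abs_log2_fc: float = DEG_ABS_LOG2_FC,
) -> list[DegRecord]:
    """Two-condition differential-expression calls under the FC/FDR rule.

    ``groups`` maps sample id -> condition name (exactly two conditions,
    each with >= 2 replicates).  log2 fold change (second condition over
    first, conditions sorted by name) uses mean FPKM with a pseudo-count;
    the p-value uses the chosen per-gene test on the indicated scale.
    """
    conditions = sorted(set(groups.values()))
    if len(conditions) != 2:
        raise ValueError(f"need exactly 2 conditions, got {conditions}")
    cond_a, cond_b = conditions
    idx_a = [i for i, s in enumerate(counts.sample_ids) if groups.get(s) == cond_a]
    idx_b = [i for i, s in enumerate(counts.sample_ids) if groups.get(s) == cond_b]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each condition needs at least 2 replicates")
    if test not in ("welch_log", "nb_moments"):
        raise ValueError(f"unknown test {test!r}")

    expr = fpkm(counts)
    raw = np.asarray(counts.counts, dtype=float)
    p_values = []
    fold_changes = []
    for g in range(len(counts.gene_ids)):
        fa = expr.fpkm[g, idx_a]
        fb = expr.fpkm[g, idx_b]
        fold_changes.append(
            math.log2(np.mean(fb) + PSEUDOCOUNT) - math.log2(np.mean(fa) + PSEUDOCOUNT)
        )
        if test == "welch_log":
            p_values.append(_welch_log_p(fa, fb))
        else:
            p_values.append(_nb_moments_p(raw[g, idx_a], raw[g, idx_b]))
    adj = bh_adjust(p_values)

    records = []
    for g, gid in enumerate(counts.gene_ids):
        lfc = fold_changes[g]
        is_deg = adj[g] < alpha and abs(lfc) > min_abs_log2_fc
        records.append(
            DegRecord(
                gene_id=gid,
                log2_fc=lfc,
                p_value=float(p_values[g]),
                adj_p=float(adj[g]),
                is_deg=bool(is_deg),
                direction=("up" if lfc > 0 else "down") if is_deg else "none",
            )
        )
    return records


#: left-closed expression bins used to describe the tissue profiles
DEFAULT_BIN_THRESHOLDS = (1.0, 20.0, 50.0)
BIN_LABELS = ("silent", "low", "moderate", "high")


def bin_expression(
    values: Mapping[str, float] | Sequence[tuple[str, float]],
    thresholds: Sequence[float] = DEFAULT_BIN_THRESHOLDS,
) -> dict:
    """Bin per-gene FPKM: silent < t0 <= low < t1 <= moderate < t2 <= high."""
    ts = list(thresholds)
    if ts != sorted(ts) or len(set(ts)) != len(ts):
        raise ValueError("thresholds must be strictly increasing")
    if len(ts) != 3:
        raise ValueError("exactly 3 thresholds define the 4 bins")
    items = values.items() if isinstance(values, Mapping) else values
    out = {}
    for gene_id, v in items:
        if v < ts[0]:
            out[gene_id] = BIN_LABELS[0]
        elif v < ts[1]:
            out[gene_id] = BIN_LABELS[1]
        elif v < ts[2]:
            out[gene_id] = BIN_LABELS[2]
        else:
            out[gene_id] = BIN_LABELS[3]
    return out


def deg_table(records: Sequence[DegRecord]) -> str:
    lines = ["gene_id\tlog2_fc\tp_value\tadj_p\tis_deg\tdirection"]
    for r in records:
        lines.append(
            f"{r.gene_id}\t{r.log2_fc:.4f}\t{r.p_value:.6g}\t{r.adj_p:.6g}\t"
            f"{r.is_deg}\t{r.direction}"
        )
    return "\n".join(lines) + "\n"


def read_design_table(path) -> dict:
    """Two-column sample -> condition TSV."""
    groups = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sample, _, cond = line.partition("\t")
            groups[sample] = cond
    return groups
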