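# Methods

## Consensus-block model of PAP candidacy

A candidate purple acid phosphatase is identified structurally, by the five
short active-site segments written `GDXG / GDXXY / GNH(D/E) / VXXH / GHXH`,
whose anchors D, D, Y, N, H, H, H coordinate the binuclear metal center. Each
slot is modeled as a position-specific residue-set pattern of fixed length
(4, 5, 4, 4, 4). Two residue sets are kept per position: the *allowed* set —
the minimal closure over the curated tea-plant block table (slot 1 admits A
at position 1 and H at position 4, as in the observed `ADMH`; slot 2 admits F
at its tyrosine position; slot 4 constrains only its terminal H, since
curated cells begin with V, A or F) — and the *canonical* set, the strict
consensus. A hit records whether each anchor carries its canonical residue
and whether the whole match is canonical, so strictness is a reporting
dimension, not a lost distinction. The published block literature is itself
ambiguous about block 1 (`GDXG` vs `DXG`); we encode the table-backed
degenerate form and flag non-canonical matches rather than guess.

### Ordered assignment

A protein may contain many pattern occurrences; the scanner selects at most
one per slot such that chosen hits are strictly ordered, non-overlapping, and
separated by gaps within spacing bounds (default 5–400 residues; the
literature gives none, and these bounds accept every curated architecture
while excluding biologically absurd ones). Among feasible assignments the
scanner maximizes, in order: number of filled slots; number of canonical
hits; smallest total span; leftmost starts. The search is branch-and-bound
over slots and is verified against an exhaustive enumeration oracle in the
test suite. Classification thresholds follow the family convention: active =
≥4 blocks (proteins lacking three or more are inactive relatives), LMM =
<400 aa. "Complete" is reported two ways, because the curated family counts
F-for-Y proteins among its 16 complete members: `complete_blocks` (all five
slots filled) and `complete_metals` (all seven anchors canonical).

## Group-II cysteine motifs

`GGECGV` and `YERTC` are invariant in the group-II clade, so matching is
exact substring search (verified against a naive O(nm) oracle). The partner
cysteine "six residues downstream" of the YERTC cysteine is encoded as
offset 7, because the reference residue numbering (C484 → C491 in lupin
PPD1) implies six *intervening* residues; the offset is configurable.
Adjacency to the `GHXH` block uses a 15-residue window — "adjacent" is
unquantified in the literature, and the window is configurable. Motif
positions are summarized in both ungapped-sequence and alignment-column
coordinates, since reported positions (≈370, ≈480) do not state which
convention they use.

## Conservation profiles

Per alignment column, information content = log₂20 − H of the residue
distribution over non-gap entries (gaps excluded rather than treated as a
21st symbol, the usual logo convention; no small-sample correction by
default). Conserved blocks are maximal runs of ≥`min_len` columns with
information ≥`min_bits` and gap fraction ≤`max_gapfrac`.

## Phylogeny

Distances: p = mismatches / comparable sites with pairwise deletion
(columns where either sequence has `-` or `X` are excluded; unknown residues
carry no substitution signal), Poisson-corrected d = −ln(1 − p). Saturated
pairs (p ≥ 1) are flagged with an infinite sentinel and must be resolved by
the user before tree building. Trees: Saitou–Nei neighbor joining with
Q-matrix ties broken by the lexicographically smallest cluster-id pair, so
identical inputs give identical trees; negative branch-length estimates are
clamped to zero with the raw value retained as an annotation. NJ is exact on
additive matrices, which the suite verifies to 1e-9 on random tree-derived
matrices. Bootstrap: columns resampled with replacement under a caller seed;
support = percentage of non-degenerate replicates containing each internal
bipartition of the full-data tree; degenerate replicates are dropped and
counted (warning above 10%). Gamma rate variation and empirical substitution
matrices are deliberately not implemented — the method modeled here is plain
Poisson correction. Group assignment labels each query by the smallest side
of any tree edge that contains it together with a unanimous set of
user-supplied anchors; conflicting minimal sides yield "unresolved".

## Expression

FPKM = counts × 10⁹ / (gene length bp × library size), with library size =
total counted fragments per sample (total *mapped* fragments is not
recoverable from a count matrix; documented choice). DEG rule: BH-adjusted
p < 0.05 AND |log₂FC| > 1, log₂FC from mean FPKM with pseudo-count 1.

The per-gene test is a documented simple stand-in for a full shrinkage
model, with two options:

* `welch_log` (default): Welch's t on log₂(FPKM+1). With three replicates
  per condition this test has 2–4 degrees of freedom, which makes it
  deliberately conservative — across twenty 2000-gene null simulations it
  produced zero false calls — but also limits its power after BH correction
  (an 8-fold change needs p ≈ 1.5·10⁻³ to survive at these ranks, which
  2–4 df rarely deliver). It is the right default when false positives are
  the dominant concern.
* `nb_moments`: a method-of-moments negative-binomial Wald test on raw
  counts (per-group dispersion φ = max(0, (s²−m)/m²), delta-method variance
  (1/m + φ)/n on the log mean). Its normal reference is slightly
  anti-conservative at n=3 (≈1 false call per 2000-gene null simulation,
  which the fold-change filter largely absorbs) but detects planted 8-fold
  changes at dispersion 0.05 with power ≈ 1.

The acceptance suite exercises each option on its corresponding property:
false-call control with the shipped default, planted-effect power with the
count-based test. Expression bins are left-closed: silent <1, low [1,20),
moderate [20,50), high ≥50 FPKM.

## Splicing evidence

Exon skipping: split reads whose junction coincides exactly (tolerance 0 bp
by default — inputs are aligner coordinates, not raw reads; configurable)
with the donor end of exon i and acceptor start of exon j, j > i+1. Intron
retention: contiguous reads overlapping an intron interior by ≥10 bases; the
call records the covered fraction and whether coverage is confined to the
intron's 5' half (strand-aware), the signature of a partially
transcribed/processed retained intron. Events require ≥3 supporting reads;
the threshold is a documented default, not an inferred one — published
descriptions ("considerable reads") do not quantify it. Transcript forms
are counted conservatively as {constitutive} ∪ {one per event}; stacking of
multiple events into single isoforms is not inferred. Percent-spliced-in
statistics and replicate-level differential splicing are out of scope.

## Synthetic data: what it emulates, and what it does not

* **Proteome generator.** Planted proteins concatenate chosen block strings
  in slot order with neutral linkers (default 30 residues, matching the
  spacing bounds); decoys carry ≤2 blocks, so the planted/decoy split is the
  ground truth for the active call. Linkers are drawn uniformly over the 15
  residues excluding D, H, Y, F and V: D/H exclusion makes an accidental
  in-linker block match impossible (every pattern requires one of them), and
  the Y/F/V exclusions remove boundary windows that could tie with a planted
  assignment under the scanner's ranking. A rejection-sampling guard (1000
  retries, then error) remains for custom pattern sets. Real proteomes, of
  course, have homologous domain context rather than uniform linkers; the
  generator validates the scanner's combinatorics, not its behaviour on
  remote homologs.
* **Evolution.** The 20-state Jukes–Cantor chain (uniform resampling with
  probability 1 − e^(−b·20/19) per branch) makes the Poisson-corrected
  distance a consistent estimator of path length; the estimator's small
  downward bias at deeper divergences (E[p] = (19/20)(1 − e^(−20t/19))) is
  well inside the 3-standard-error recovery band at the test scale (2000
  sites, path lengths ≤ ~0.6). No indels, no site-rate variation, no
  exchangeability structure — sufficient for validating the distance/NJ
  machinery, not a realistic protein evolution model.
* **Counts.** Negative-binomial with log-uniform baseline means (10–1000),
  common dispersion, planted symmetric fold changes, gene lengths uniform in
  500–5000 bp, library depth 10⁶. No size-factor heterogeneity or
  gene-specific dispersion trends.
* **Reads.** Uniform placement along a chosen isoform, split exactly at its
  junctions; no sequencing error or alignment noise, which is why exact
  junction matching recovers planted events with zero false positives by
  construction.

Every generator is a pure function of (parameters, seed); identical seeds
give byte-identical outputs.

## Problem sizes used by the test and acceptance suites

Worked examples run on the 19-row curated table + 10 decoys and a 9-exon
gene model; tree recovery uses an 8-leaf binary tree (branch lengths
0.05–0.15), 2000 sites, 20 seeds; DEG suites use 2000 genes with 3 vs 3
replicates and 30+30 planted changes. These sizes exercise every code path
and estimator margin the package claims while keeping the full suite in the
tens of seconds.

## Known limitations

External steps are consumed, not computed: BLAST-based candidate retrieval,
multiple sequence alignment, read mapping and counting, signal-peptide and
glycosylation prediction, GO enrichment. The activity call rests on the
block-count rule alone (the literature's additional "complete
metallophosphatase domain" criterion has no reproducible published
definition). pI is not computed; molecular weight uses average residue
masses and rejects sequences containing X.
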