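# Methods

This note documents the models, statistical procedures, and design choices
behind `clonotrack`, in the order the pipeline applies them.

## Bulk repertoire model and cleaning

A bulk TCRβ repertoire is a table of unique rearrangements with read
counts (AIRR Rearrangement TSV: `junction`, `v_call`, `j_call`,
`duplicate_count`, `productive`; the older `cdr3`/`consensus_count`
headers are accepted because tool outputs vary). Cleaning follows the
standard rules for genomic-DNA TCRβ amplicon data: non-productive
rearrangements and sequences with fewer than two reads are discarded
(comparisons are strict: a 2-read sequence is kept). A *clone* is a unique
CDR3β nucleotide sequence; rearrangements sharing a junction are collapsed
with counts summed and the V/J calls of the largest constituent retained.
Clone frequencies are computed over the post-filter read total. The
pipeline fixes the order filter → collapse; filtering after collapsing
would apply the read threshold to summed counts and retain clones whose
individual rearrangements were each below threshold.

Ranking ties (equal read counts) are broken by lexicographic CDR3β order,
so top-k selection is reproducible across runs and input row orders. This
tie-break is our convention; any deterministic rule would do.

## Clonality and overlap statistics

- *Clonal expansion* (single cell): a clonotype spanning ≥ 2 cells.
  Summaries report proportions over clonotypes and over cells, since a few
  large clones can dominate cells while being a minority of clonotypes.
- *Dominance*: cumulative frequency share of the top-n clones under the
  deterministic rank order; non-decreasing in n and exactly 1 at n equal
  to the clone count.
- *Overlap* between two collapsed repertoires: exact CDR3β nucleotide
  match, optionally also requiring V-gene agreement with alleles collapsed
  (`TRBV9-1*01` ≡ `TRBV9-1*02`). Reports the shared clone set (symmetric),
  per-repertoire normalised clone fractions, and per-repertoire frequency
  mass of the shared clones — clone-count and read-frequency views answer
  different questions, so both are always reported.
- *Subset share of top clones*: the frequency mass, within a blood subset,
  of the top-k tissue clones; the statistic that distinguishes a
  tissue-connected subset (PD-1⁺CXCR5⁻) from a control subset (PD-1⁻).

## Tracking

The top-K (default 100) tissue clones are matched into single-cell TCR
data by exact CDR3β nucleotide identity — the conservative clonal-identity
criterion, consistent with the bulk clone definition; an amino-acid mode
exists for cross-platform inputs, and V-gene agreement can be required. A
matched clone's cells vote for their transcriptional clusters; the clone
is affiliated to the majority cluster. Vote ties are flagged `ambiguous`
and resolved toward the cluster with more cells overall, then the smaller
label. The per-cluster aggregate counts only clones with ≥ 1 matched cell.
Analyses are strictly per donor; clones are never pooled across donors
because public clones would confound the tissue-blood link.

## Single-cell QC, normalisation, markers, modules

**QC.** Cells are removed if mitochondrial UMI fraction > 10%, detected
genes < 400, ERCC UMI fraction > 25%, ERCC quantification accuracy < 0.7,
or ribosomal-protein UMI fraction < 5%. Boundary cells are kept (the rules
are strict inequalities on the removal side). Metrics missing from the
metadata are computed from gene-name prefixes (`MT-`, `RPS`/`RPL`,
`ERCC-`); ERCC accuracy is the Pearson correlation between log1p observed
spike-in counts and log1p input molarities and requires the molarity
vector — a rule whose metric cannot be obtained is skipped with a warning.
Per-rule removal counts are logged so every "n of N" statement is
auditable.

**Normalisation.** Per-cell depth scaling to a target sum of 10,000
followed by natural-log log1p. Raw counts are kept in a layer. Zero-depth
cells are removed with a warning.

**Markers.** One-vs-rest per group. Genes must be detected in ≥ 25% of
cells in the group or the rest (min.pct) and have |avg_log₂FC| ≥ 0.25.
avg_log₂FC = log₂((mean(expm1(x_in)) + 1)/(mean(expm1(x_out)) + 1)) on the
log-normalised matrix; this formula is stated because published analyses
rarely print theirs, and ours is documented rather than claimed identical
to any other implementation. Surviving genes get a two-sided
Mann–Whitney/Wilcoxon rank-sum test (tie-corrected normal approximation,
vectorised across genes), BH adjustment within group, and a cutoff of
adjusted p < 0.01. Groups with fewer than 3 cells are skipped with a
warning.

**Modules.** A reactivity module is the top 50 genes of a group by
avg_log₂FC, restricted to up-regulated markers (a signature is the program
a population expresses, not what it lacks; without this restriction a
module short of 50 positive genes would be padded with down-regulated
genes that invert the score elsewhere). Ties break lexicographically.
Fewer than 50 eligible genes yields a shorter module with a warning.

**Module score.** Genes are ranked by mean normalised expression and cut
into 25 equal-occupancy bins; for each module gene, up to 100 control
genes are sampled (seeded, without replacement) from its bin, pooled into
a control set. Score = mean(module genes) − mean(control set). The bin
count and control count are the de-facto defaults of this scoring scheme,
made explicit and configurable; the seed is always explicit. Degenerate
cases behave sensibly: a constant matrix scores exactly 0, and if the
control set coincides with the module the score is identically 0.

**Comparisons.** Across clusters: global Kruskal–Wallis plus all pairwise
two-sided rank-sum tests with BH adjustment (clusters under 2 cells are
excluded with a warning). Two groups (e.g. tetramer⁺ vs tetramer⁻):
two-sided Mann–Whitney with the median difference as the effect summary;
exact p-values at small sample sizes. Top-percentile highlighting returns
all cells at or above the (100−pct) percentile, ties included — with all
scores equal, every cell is returned.

## Enrichment frequency

F = n/N with N = reference count in the saved fraction divided by the
saved fraction (default 1/10), scaled per million. F is scale-invariant in
the counts. The Clopper–Pearson interval treats n as binomial out of N;
`level=0` degenerates to the point estimate. The companion simulator
models the randomness the estimator faces — binomial sampling of the
saved counting aliquot and binomial capture of specific cells, with
capture efficiency an explicit parameter defaulting to 1 (complete
capture). Under that model the estimator is unbiased up to the negligible
Jensen term of 1/N̂. Physically removing the aliquot before enrichment
would shrink the numerator by (1 − saved fraction); users modelling that
variant can set `capture_efficiency = 0.9`. Detection thresholds are
user-set, never hard-coded. Background subtraction from unstimulated
control wells is accepted as an optional pre-subtracted input rather than
formalised.

## Synthetic-data generator

The generator's defaults are the study conditions the test-suite validates
under; they are chosen once and not tuned.

- **Tissue clone sizes:** truncated Zipf over ranks with exponent 1.2 on
  5000 clones (a log-normal law is available via config). The exponent is
  a free parameter, not an estimate of any patient's liver: the true
  intrahepatic clone-size law is unknown, and 1.2 was chosen to reproduce
  the qualitative regime in which the top 100 clones hold a majority
  (here ≈ 77%) of reads. Reads are multinomial at depth 10⁶, so total
  depth is conserved exactly and unobserved clones simply get zero reads.
- **CDR3β sequences:** random in-frame sequences of 27–54 nt with
  conserved flanks (Cys-Ala-Ser at the V side, Phe-Gly at the J side) and
  stop-free interiors; uniqueness by rejection. No V(D)J recombination or
  sequencing-error model — clonal identity is the only property the
  analysis uses.
- **Blood subsets:** each top-100 tissue clone enters the PD-1⁺ subset
  with probability 0.10 and the PD-1⁻ subset with probability 0.02
  (independent Bernoulli draws), alongside 1000 novel clones per subset.
  Shared clones carry identical CDR3β and V call across compartments, so
  the exact-match key works by construction. Every emitted blood clone is
  guaranteed ≥ 2 reads (2 reads seeded per clone, the remaining depth
  multinomial) so the standard min-count filter cannot silently delete a
  planted shared clone; depth is still conserved exactly.
- **Single cells:** 2000 cells, 2000 genes (including small MT-/RPS/RPL
  families so QC is exercised; ERCC spike-ins are not emulated and the
  ERCC rules skip), 6 clusters with uniform occupancy. UMI counts are
  negative binomial (dispersion θ = 2) around per-cluster mean profiles
  with mean library size 5000. Each reactivity group is anchored to one
  cluster — auto-reactivity to cluster `c2` — and the group's 50 planted
  signature genes are shifted by log₂FC = 1 in that cluster; unanchored
  clusters get their own 20 planted marker genes. Anchoring makes the
  reactivity label a function of cluster at generation time: this is the
  desk-scale simplification of having a separate labelled (stimulated)
  dataset, and it means a single generated dataset serves both module
  derivation and transfer. 90% of cells carry a TCR; cells of shared
  tissue clones are placed in the autoreactive cluster with probability
  0.8 (configurable; 1.0 makes the placement deterministic).
- **RNG:** one stream per sub-generator, spawned from the master seed, so
  adding a generator never perturbs the others; everything is
  byte-reproducible under a fixed seed.

**What passing tests show — and don't.** The generator reproduces the
*statistical skeleton* the analysis assumes: heavy-tailed clone sizes,
differential subset sharing, NB counts with planted effects, and exact
clone identity across compartments. It does not emulate V(D)J biology,
sequencing error, batch effects, doublets, ambient RNA, or continuous/
overlapping transcriptional states. Success on synthetic data therefore
validates the correctness and calibration of the machinery, not its
robustness to every artefact of real data.

## Numerical choices and degenerate inputs

- Frequencies sum to 1 within 1e-9 of rounding; all rank orders are
  deterministic under the count-then-lexicographic rule.
- Rank-sum p-values use the tie-corrected normal approximation for
  vectorised marker testing (appropriate at the tested group sizes) and
  exact enumeration automatically at small n in two-group contrasts.
- Empty inputs return empty summaries (expansion of zero clonotypes),
  raise typed errors where the quantity is undefined (zero reference
  count in F = n/N, empty module intersection), or warn and degrade
  (empty AIRR file → empty repertoire; k beyond the repertoire → whole
  repertoire).
- The top-percentile rule uses linear-interpolation percentiles with
  ties-at-the-cut included.

## Problem sizes used in validation

The automated checks run at the generator's default scale (5000 tissue
clones at depth 10⁶; 2000 cells × 2000 genes; 100–200 replicates for
calibration and recovery statistics; 1000 Monte-Carlo repetitions for the
frequency estimator) — sizes at which every statistical property under
test is comfortably identified while the whole suite stays desk-scale.

## Known limitations

- The β-chain bridges bulk and single-cell data by necessity; paired-αβ
  identity is available only within single-cell data, so cross-compartment
  matches could in principle merge distinct αβ clones sharing a β chain.
- Majority-vote cluster affiliation is our convention for multi-cluster
  clones; clones spanning clusters are flagged `ambiguous` rather than
  split.
- Cluster labels are consumed as input; clustering, integration, and
  embedding are out of scope.
- The marker fold-change formula and normalisation target are documented
  choices, not claims of bit-identity with any third-party tool.
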