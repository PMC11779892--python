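# clonotrack

Cross-compartment T-cell clonotype tracking and reactivity-signature
transfer for paired bulk TCRβ / single-cell datasets.

## The problem

In autoimmune liver disease, rare circulating autoreactive CD4 T cells are
suspected to be the blood-borne counterparts of clonally expanded T cells in
the inflamed liver. Two kinds of evidence link them:

1. **Clonal identity.** Bulk TCRβ sequencing of a liver biopsy yields a clone
   table (one clone per unique CDR3β nucleotide sequence). The most abundant
   tissue clones can be searched for, by exact CDR3β match, in single-cell
   TCR data from sorted circulating memory CD4 subsets (e.g. PD-1⁺CXCR5⁻ vs
   PD-1⁻ cells). Which transcriptional cluster those matched cells occupy
   tells you the circulating phenotype of dominant intrahepatic clones.
2. **Transcriptional identity.** Antigen-reactivity gene signatures derived
   from peptide-stimulated, labelled cells (one-vs-rest Wilcoxon rank-sum
   markers, top 50 genes by avg_log₂FC) can be transferred to unstimulated
   cells as *module scores* — mean normalised expression of the signature
   genes minus that of expression-matched control genes — and compared
   across clusters or between tetramer⁺/tetramer⁻ cells.

`clonotrack` implements this full analysis as a reusable, tested pipeline:
AIRR repertoire I/O and cleaning, clonal-expansion and dominance statistics,
cross-repertoire overlap, top-clone tracking with majority-vote cluster
affiliation, signature derivation/scoring/testing, and the magnetic-
enrichment frequency estimator F = n/N used to quantify antigen-specific
cells per million CD4. Because patient data are controlled-access, the
package ships a synthetic-data generator that emulates the statistical
structure of the real inputs (truncated-Zipf tissue clone sizes, subset-
specific clone sharing, negative-binomial UMI counts with planted
signatures) with complete ground truth, so the whole analysis can be run
and validated at desk scale.

## Key statistics

- **Clone definition (bulk):** each unique CDR3β nucleotide sequence;
  non-productive rearrangements and sequences with < 2 reads are discarded.
- **Clonal expansion (single cell):** a clonotype observed in ≥ 2 cells.
- **Dominance:** cumulative frequency share of the top-n clones,
  `top_n_cumulative_share`.
- **Module score:** s(c) = mean_{g∈M} x_{cg} − mean_{g∈C} x_{cg}, with
  controls C drawn per module gene from 25 average-expression bins
  (100 controls per gene, seeded).
- **Marker test:** two-sided one-vs-rest Wilcoxon rank-sum on
  log-normalised expression, prefiltered at min.pct = 0.25 and
  |avg_log₂FC| ≥ 0.25, Benjamini–Hochberg adjusted, kept at adjusted
  p < 0.01.
- **Score comparisons:** Kruskal–Wallis across clusters with BH-adjusted
  pairwise rank-sum tests; unpaired Mann–Whitney for two-group contrasts.
- **Enrichment frequency:** F = n/N where N = (reference count in the
  saved 1/10 fraction) × 10, with an exact Clopper–Pearson interval.

## Worked example

```python
import clonotrack as ct
from clonotrack import signatures as sig
from clonotrack.repertoire import collapse_to_clones, filter_repertoire
from clonotrack.tracking import track

study = ct.simulate_study(ct.SimConfig(seed=42))
liver = collapse_to_clones(filter_repertoire(study.tissue))
print(f"liver clones after filtering: {len(liver)}")
print(f"top-100 cumulative share: {ct.top_n_cumulative_share(liver, 100):.3f}")

pd1pos = collapse_to_clones(filter_repertoire(study.blood_pd1pos))
ov = ct.repertoire_overlap(liver, pd1pos)
print(f"clones shared liver/PD-1+: {ov.n_shared} "
      f"({100 * ov.frac_of_b:.1f}% of the PD-1+ subset)")

cts = ct.clonotypes_from_table(study.sc_clonotypes, key="beta")
res = track(liver, cts, study.adata.obs["cluster"].to_dict(), k=100)
print(f"top-100 liver clones found in circulating cells: {res.n_tracked_found}")
print(f"cluster affiliation of tracked clones: {res.aggregate}")

ad = sig.normalize_log(sig.qc_filter_cells(study.adata))
labelled = ad[ad.obs["reactivity"] != "unlabeled"].copy()
markers = sig.find_markers(labelled, "reactivity")
module = sig.build_reactivity_module(markers, "auto-reactivity", top_n=50)
scores = sig.module_score(ad, module, seed=42)
report = sig.compare_cluster_scores(scores, ad.obs["cluster"])
print(report.per_cluster.round(3).to_string(index=False))
print(f"Kruskal-Wallis p = {report.kruskal_p:.3g}")
```

Output:

```
liver clones after filtering: 4999
top-100 cumulative share: 0.770
clones shared liver/PD-1+: 12 (1.2% of the PD-1+ subset)
top-100 liver clones found in circulating cells: 12
cluster affiliation of tracked clones: {'c2': 12}
cluster   n   mean  median
     c0 318 -0.182  -0.183
     c1 343 -0.158  -0.153
     c2 377  0.258   0.252
     c3 309 -0.157  -0.156
     c4 324 -0.160  -0.164
     c5 328 -0.155  -0.156
Kruskal-Wallis p = 2.12e-195
```

Reading: the simulated liver is strongly oligoclonal (top 100 clones hold
77% of reads); 12 of its top-100 clones are found among circulating PD-1⁺
cells; all 12 tracked clones are affiliated to cluster c2 — which is also
the cluster with the highest auto-reactivity module score. The tracking and
signature-transfer routes agree on the identity of the circulating
counterpart of the dominant tissue clones, which is exactly the property
the pipeline is built to detect.

A command-line interface mirrors the library
(`clonotrack simulate | filter | clonality | overlap | track |
signatures | score | freq | run-all`); `clonotrack run-all --outdir out
--seed 0` executes the whole pipeline and writes a machine-readable
`run_report.json`.

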