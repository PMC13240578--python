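# Methods

`cloneshare` analyses paired single-cell expression and antigen-receptor
(TCR/BCR) data sampled from three anatomical compartments — lung
interstitial tissue, bronchoalveolar lavage fluid (BALF, sampling the
airway/alveolar lumen) and peripheral blood (PBMC) — and asks how expanded
lymphocyte clones are shared across those compartments.

## Clonotype identity

A clonotype is the set of cells carrying identical rearranged receptor
chains. Per barcode, only productive chains contribute; when a locus yields
more than two productive contigs (presumptive doublet chains) the two with
the highest UMI support are kept. The default key (`NT_VJ`) is the sorted
set of (chain, V gene, J gene, CDR3 nucleotide) tuples, matching the 10x
vendor definition; amino-acid (`AA_VJ`) and vendor-id (`RAW_ID`) keys are
selectable because published analyses are frequently ambiguous on this
point. Clone ids are prefixed with the subject id, so clones can never span
subjects: public-clone analysis is intentionally out of scope, and the
subject scoping is what makes pooled and per-subject index computations
coincide (see below). Barcodes carrying both TCR and BCR chains are dropped
as doublets. For BCR, the isotype is the constant gene of the highest-UMI
productive heavy chain.

## QC and normalization

Cells are removed when the mitochondrial read fraction exceeds 10% or fewer
than 200 genes are detected. Both bounds are strict: a cell at exactly 10%
or exactly 200 genes is kept. This is the literal reading of the usual
"over 10% / less than 200" phrasing; the thresholds are configurable
(`QcThresholds`). Normalization is library-size scaling to 10^4 counts per
cell followed by log1p; it matches `scanpy`'s
`normalize_total` + `log1p` (cross-checked in tests). Cells with zero total
counts get all-zero normalized values and a logged warning rather than an
error, since they are expected to have been QC-removed already.

Signature scores are the per-cell mean of normalized expression over the
genes of the set that are present in the matrix (absent genes dropped with
a logged count; an empty intersection is an error). The MHC-I-style score
is shipped as a configurable signature with no default gene list claimed:
the original gene set is not public.

Differential expression uses the two-sided Wilcoxon rank-sum test per gene
on normalized values (Welch's t-test selectable), log-fold change as the
difference of group means on the ln scale, and Benjamini–Hochberg FDR
control within each contrast. Genes constant across both groups get p = 1
and LFC = 0 by convention. Composition statistics operate on per-subject
proportion vectors (n always refers to subjects), Wilcoxon across groups
with BH over cell types, and Pearson correlation for pairs of types.

## Sharing patterns

Expanded clones (total size within subject ≥ `min_size`, default 2, pooled
over compartments — cross-compartment sharing cannot be judged per
compartment) are classified by occupancy: presence in a compartment means
≥ `min_cells` cells there (default 1). The mapping is a total function on
the 8 occupancy states:

| lung | PBMC | BALF | label |
|------|------|------|-------|
| ✓ | ✗ | ✓ | P1A (interstitium→airway, activated) |
| ✓ | ✗ | ✗ | P1B (lung-restricted, resting resident) |
| ✓ | ✓ | ✗ | P2 (blood↔interstitium, circulating effector) |
| all four remaining non-empty states | | | OTHER |
| ✗ | ✗ | ✗ | UNCLASSIFIED |

The empty state can only arise when `min_cells` > 1 erases every
compartment; it is treated as "not classifiable" rather than OTHER, which
keeps the invariant that every classified clone occupies at least one
compartment. A rule-based classifier was chosen over heatmap clustering
because it is total, auditable and reproducible; the original assignment
may have been partly data-driven, and this difference is deliberate.
Classification is per clone — cells inherit their clone's label, and
receptor-negative cells are UNCLASSIFIED.

## Entropy indices

All indices use natural logarithms and the convention 0·ln 0 = 0.

* **Expansion** of a stratum with clone-frequency vector *p* over *N*
  clones: `1 − H(p)/ln N` (one minus Pielou evenness). A single clone is a
  degenerate stratum: the index is defined as 1 if that clone has ≥ 2
  cells, 0 for a lone singleton. Values within 1e-12 of the boundaries are
  snapped to 0/1 to absorb floating error on exactly-even inputs.
* **Migration**: for clone *i* with distribution *q_i* over the considered
  compartments, the index is Σ w_i · H(q_i) with w_i the clone's share of
  the stratum's cells. Pairwise calls restrict counts to the two
  compartments (so deleting the third compartment's cells cannot change
  the result) and drop clones absent from both. Normalized variants divide
  by ln k (k compartments considered); with a single category the raw
  value is identically 0 and the normalized value is defined as 0.
* **Transition**: the same machinery with phenotype-cluster distributions.

Aggregation across subjects computes each subject's index first and then
takes the mean weighted by the subject's stratum cell count, which
prevents large subjects from dominating through pooled pseudo-clones.
Because clone ids are subject-scoped, this equals the single pooled
computation; both are implemented and compared in tests to document the
equivalence (it would break if clone ids could collide across subjects).
Both normalized and raw variants are emitted since published index plots
rarely state their scale.

## Reference scoring with fine-tuning

Pattern-labelled cells are aggregated into pseudo-bulk profiles by
per-gene median of normalized expression (median for robustness; mean
selectable). Patterns with fewer than 10 labelled cells are dropped. For
each ordered pattern pair (A, B) the markers are the `genes_per_pair`
(default 50) genes with the largest strictly positive profile difference
A − B; a constant gene can never be selected. A query cell is scored by
Spearman correlation (ties mid-ranked) against each profile over the union
of pairwise markers; fewer than 20 evaluation genes is an error; a
zero-variance vector scores 0. Fine-tuning retains patterns within
`margin` (default 0.05) of the top score, re-scores on the surviving
patterns' pairwise markers only, and repeats until one pattern remains or
the retained set stops shrinking. At a stall a strictly highest raw score
wins; an exact tie (e.g. two identical profiles) yields AMBIGUOUS with the
tied labels logged. `margin` and `genes_per_pair` are documented defaults,
not published values.

## Synthetic cohorts

The generator emits exactly the file dialects the readers accept, plus a
ground-truth JSON. Defaults describe a pneumonia-like cohort: 5 subjects ×
200 clones; 60% of clones expanded with sizes 1 + Geometric(p = 0.3)
(minimum 2, mean ≈ 4.3); pattern mix (0.5, 0.2, 0.3, 0) over
(P1A, P1B, P2, OTHER); compartment allocation by Dirichlet-multinomial
over each pattern's allowed compartments (P1A lung+BALF, P1B lung,
P2 lung+PBMC, OTHER unrestricted; concentration 4 per compartment).
Because a sharing pattern is *defined by* occupancy, the default
(`ensure_occupancy=True`) seats one cell in each allowed compartment
before allocating the remainder stochastically; setting it to False gives
the fully stochastic variant in which small clones can miss a compartment
and genuinely belong to a different observable pattern.

Expression is negative binomial (dispersion θ = 10, baseline mean 0.5 per
gene) with multiplicative 2^effect shifts: canonical markers (resident
ITGAE/CXCR6/CXCR3, cytotoxic GZMB/GNLY, cycling MKI67 for P1A; ITGAE/CXCR6
for P1B; circulating CX3CR1/FGFBP2/KLRG1 for P2; all at log2 effect 2)
plus 30 pattern-specific program genes per pattern at the same effect —
real transcriptional programs span dozens of co-regulated genes, and the
correlation-based scorer requires ≥ 20 evaluation genes, which the nine
canonical markers alone cannot supply — plus 100 flat background genes.
QC covariates are drawn independently of the simulated panel
(mitochondrial fraction ~ Beta(2, 38), detected genes ~ round
Normal(2500, 400)), emulating whole-transcriptome detection; this is why
the `n_genes` covariate does not equal the panel's nonzero count.

What a green test does **not** establish: the generator has no batch
effects, no ambient RNA or doublet contamination, no compartment-specific
library-size differences, no isotype switching within clones, and its
programs are cleanly block-structured rather than correlated continua —
recovery results on it bound implementation correctness, not performance
on real cohorts.

## Numerical and degenerate-input choices

* Probability vectors are validated to sum to 1 within 1e-9.
* Loop-oracle comparisons for the indices hold to 1e-12.
* Duplicate gene symbols on read are disambiguated ".1", ".2", … in file
  order.
* Marker ties in reference building break deterministically by gene name;
  chain ties in clonotype collapse break by (UMI desc, CDR3, V, J).
* All randomness flows from one `numpy` Generator seeded per run;
  identical seeds give byte-identical output files.

## Known limitations

Batch integration, embedding, clustering and cell-type annotation are out
of scope: cluster labels arrive as input. Expansion judged on pooled
compartments means a clone expanded only by virtue of appearing once in
each of three compartments counts as expanded with `min_size` ≤ 3.
Covariate regression during scaling is not implemented. The classifier
reproduces the published occupancy table, not any unpublished clustering
that may have produced it.
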