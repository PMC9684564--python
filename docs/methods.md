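# Methods

## Interactor classification

`baitcall` classifies protein groups from a MaxQuant-style table into
candidate bait interactors per condition by presence/absence, not by
quantitative enrichment. The sequence is fixed: (1) q-value filter,
(2) decoy/contaminant removal, (3) binarization, (4) per-condition rules.

* **q-value threshold** (`q_max`, default 0.01, strict `<`). The q-value is
  the minimal FDR at which the identification is accepted; the comparison
  is strict, so a record sitting exactly on the threshold is excluded.
* **Decoys and contaminants** are dropped *before* binarization, so a decoy
  detected in a control sample can never mask a genuine protein through the
  control subtraction.
* **Presence** means raw intensity > 0. MaxQuant writes 0 for "not
  detected"; whether a nonzero intensity came from an MS/MS identification
  or a match-between-runs transfer is not visible in the protein-group
  table, so intensity positivity is the documented proxy for
  "identified in this sample".
* **Control rule** (`ANY_CONTROL_REPLICATE` default): a protein detected in
  any IgG-control replicate of a condition is removed from that condition's
  candidates. The stricter `ALL_CONTROL_REPLICATES` variant (remove only
  when detected in every control replicate) is selectable because
  control-side summaries are often tabulated that way. Subtraction is
  always per-condition, never pooled across conditions.
* **Replicate rule** (`min_bait_replicates="all"` default): candidates must
  be detected in every bait replicate of the condition; an integer k
  relaxes this to ≥ k. The bait protein passes through the same rules with
  no special-casing.

Two monotonicity properties follow directly and are property-tested:
lowering `q_max` never enlarges a candidate set, and relaxing the replicate
rule from "all" to k < n never shrinks it.

## Identifier namespace

Cross-table matching uses the **leading accession** of each protein group
(the first entry of the majority-accession cell). Gene names are carried
as reporting attributes and fall back to the leading accession when empty.
The alternative — matching on gene symbols — is left to the caller, who
can supply gene-level lists to the comparison and enrichment stages; no
identifier-mapping service is built in.

## Set algebra

`compare_conditions` partitions the union of per-condition sets by exact
membership signature into all 2ⁿ−1 Venn regions (zero-count regions are
reported too, for a deterministic output shape). `unique_to(G)` is
intersection(G) minus union(complement). When the complement of G is a
single condition, the identity

  intersection(G) = common_all ⊎ unique_to(G)

is exact; `consistency_check` verifies it and reports the discrepancy set
otherwise. The bait identifier is an ordinary member and is included in
all counts by default; `drop_bait` removes it everywhere when bait-free
counts are wanted. Reference-list comparisons (`overlap_stats`) report the
intersection count, percentage of each side and Jaccard index; an empty
side is flagged degenerate rather than raising.

## Overrepresentation testing

`fisher_overrepresentation(k, n, K, N)` is the one-sided upper tail of the
hypergeometric distribution, evaluated through scipy's log-space survival
function and cross-checked in the tests against exact rational enumeration
for every admissible configuration with N ≤ 40. Only overrepresentation is
tested. Annotation terms are flat sets (no GO-DAG propagation). The
background is always caller-supplied; query genes outside it are dropped
with a logged count, and the package never silently substitutes the query
union for the background. Correction is Benjamini–Hochberg by default
(Bonferroni and none selectable) applied within each ontology category
separately, since the top-N ranking is also per category; ties in p are
broken by term id for determinism.

## Replicate QC

Correlations are Pearson, computed on log2 intensities over
pairwise-complete observations. Zeros are treated as missing with **no
pseudocount**: log2(0) is undefined, and imputing a floor value would
manufacture correlation between samples that merely share absences. Pairs
sharing fewer than 3 proteins are reported as undefined together with
their count. The QC report summarizes the minimum within-condition
bait-pair and control-pair r and flags bait pairs below the threshold
(default 0.93, the conventional concordance bar for this design).

## Synthetic data generator

The generator emulates the motivating study design: 4 conditions (one
normal, three cancer cell lines), bait IP and IgG control in triplicate.
Planted classes: 1 bait, 38 common interactors, 18 cancer-group
interactors, 60 background binders, 5 contaminants, 5 decoys (all
overridable; `n_common=38`/`n_unique=18` mirror the reference tables'
scale). Mechanics and defaults:

* **Detection** is an independent Bernoulli event per (protein, sample).
  True interactors appear in bait samples of their conditions with
  `p_det_true` (default 0.9 — realistic AP-MS per-replicate dropout) and
  never in controls; background binders appear condition-agnostically with
  `p_det_bg_bait` = 0.6 in bait samples and `p_det_bg_ctrl` = 0.9 in
  controls (bead/antibody stickiness is most visible where no specific
  complex competes). Independence across replicates makes the all-of-n
  rule's recall exactly `p_det_trueⁿ` (`expected_recall`), and the
  background false-positive rate under the any-control rule
  `p_det_bg_bait³ · (1 − p_det_bg_ctrl)³`; both laws are verified by
  simulation in the tests.
* **Intensities** for detected events are log-normal:
  log2 I = μ + protein effect + sample effect + residual, with μ = 25 (a
  typical MaxQuant log2 intensity scale), σ_protein = 3.0 (protein
  abundances spanning several orders of magnitude, as in real MS),
  σ_sample = 0.25 (shared per-sample loading/efficiency shifts) and
  σ_noise = 0.4 in bait samples. Control samples use a larger residual
  (σ_noise_control = 1.2) because nonspecific carryover is poorly
  reproducible; this yields bait-replicate Pearson r ≈
  σ_p²/(σ_p² + σ_noise²) ≈ 0.98 and visibly lower control-replicate r,
  matching the qualitative QC signature of real data. Undetected cells are
  written as intensity 0, the parser's missing-data convention.
* **q-values** for planted real classes are uniform below `q_true_max`
  (0.005); contaminant/decoy rows draw above `q_junk_min` (0.05), so the
  quality filter and the flags are each sufficient to remove them.
* **Determinism**: one `numpy` generator seeded from `SimParams.seed`
  drives all draws in a fixed iteration order, so a seed reproduces the
  output table byte-for-byte.

What the generator does **not** model: peptide-level inference, shared
peptides between groups, correlated dropout (available conceptually but
not default — detection independence is what makes the closed forms
exact), condition-specific background abundance shifts, and
intensity-dependent detection (low-abundance proteins dropping out more
often). Passing recovery tests therefore demonstrates the correctness of
the classification logic under the stated model, not the biological
fidelity of any particular real dataset.

## Packaged reference tables

Two tables from the motivating Kpnβ1 IP-MS study are shipped as TSV: the
common-core interactor table (39 accession rows including the bait; the
study's narrative rounds this set to 38) and the 18-protein cancer-unique
table. They are transcribed verbatim from the printed tables — the
row-count discrepancy with the narrative is preserved, not silently
corrected — and serve as fixed inputs for the set-algebra examples and
acceptance computations. The study's per-cell-line candidate lists and the
external database exports (BioGRID, BioPlex, STRING) are not included, so
their pairwise overlap counts are not recomputed anywhere.

## Problem sizes

The default simulated experiment is 127 protein groups × 24 samples;
recovery-law checks aggregate 12–20 such experiments (hundreds to
thousands of Bernoulli measurements, giving Monte-Carlo standard errors
below 0.01 on recall estimates). The Fisher oracle sweep enumerates all
~260,000 admissible (N, K, n, k) configurations with N ≤ 40. These sizes
were chosen so every law is measured with comfortable statistical margin
while the whole suite runs in well under a minute per module.
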