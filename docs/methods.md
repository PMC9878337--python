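# Methods

## Model and assumptions

`rade` quantifies a compound's net transcriptomic effect on a cancer by
crossing two differential comparisons. E1 compares cancer tissue with
matched normal tissue and labels each gene +1 / −1 / 0 by strict
thresholds on a signed-ratio fold-change (±2) and a raw p-value (0.001).
E2 compares a compound-treated cell line with its DMSO vehicle control
and computes, per gene, `FC = (T − D) / max(|D|, floor)`. The method
assumes gene identifiers are directly comparable across the two
experiments (exact string match; no symbol aliasing or orthology
mapping) and is otherwise scale-agnostic in the expression units of T
and D, because the denominator uses |D|.

A gene is **reversed** when the compound pushes it in the direction
opposite to its disease change beyond the reversal threshold, and
**adverse** when the compound pushes it strongly (beyond the adverse
threshold) in the disease direction, or strongly perturbs a gene the
disease leaves unchanged. Reversed and adverse are provably disjoint: a
reversal requires an opposite-direction FC on a signature gene, an
adverse call a same-direction (or neutral-gene) FC beyond a strictly
larger threshold.

The condition-level score is `RADE = (#Ad/#Re) · (#Mu/#Re)` with #Mu the
disease-signature size; lower is better. The score deliberately scales
with signature size: the second factor measures how much of the disease
signature the compound leaves uncorrected. RADE values are therefore
comparable across compounds against one signature, not across cancers.
Transcriptomic "adverse" here is a safety proxy and is not a clinical
adverse-reaction prediction.

Patients are mapped to cell lines by mutated-gene-set overlap,
`Match_k(s) = |DE(s) ∩ Mucl(k)| / |Mucl(k)|`, normalised by the cell
line's set so a sample that recapitulates the whole line scores 1
regardless of how many extra private mutations it carries.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `fc_threshold` | 2 | signed ratio | E1 label cut (strict) |
| `p_threshold` | 0.001 | probability | E1 label cut (strict, raw p) |
| `reversal_threshold` | 2 | signed ratio | E2 cut for a reversal |
| `adverse_threshold` | 15 | signed ratio | E2 cut for an adverse call |
| `floor` | 0.1 | expression units | minimum fold-change denominator |
| `adverse_mode` | `symmetric` | — | see below |
| `alpha` | 0.05 | probability | enrichment significance on FDR q |
| `min_group_total` | 10 | raw counts | prefilter: group total in both groups |
| `cohort_min_score` | 0 | match score | optional floor for mutation-match cohorts |

Configuration validation rejects `adverse_threshold <=
reversal_threshold`, under which the taxonomy degenerates.

## Design choices where the design was open

* **Prefilter granularity.** "Low counts in a sample group" is read as
  the *group-wise total* raw count < 10, the common bulk-RNA-seq
  prefilter convention; per-sample and per-group-mean readings were
  rejected as non-deterministic across cohort sizes. Boundary (=10) is
  retained.
* **Fold-change scale.** DE tables usually arrive as log2 fold-changes;
  the reader converts log2FC x to a signed ratio (2^x for x ≥ 0,
  −2^(−x) for x < 0) so the ±2 cut applies uniformly. A `log2fc` column
  is always converted; a plain `fc` column is converted only under the
  default `fc_scale: log2`.
* **Adverse branches.** The formal taxonomy omits the (E1 = 0,
  FC₂ < −15) case that its prose symmetrically implies. The default
  `symmetric` mode includes it; `strict_paper` reproduces the formal
  branch list literally. Both are first-class and tested.
* **Adverse threshold vs prose.** The prose labels E2 at ±2 while the
  formal adverse branches require |FC₂| > 15; the formal definition
  wins. The prose reading is available by setting
  `adverse_threshold: 2`... which the validator then rejects as
  degenerate at the default reversal threshold — by design, since the
  two calls would overlap in no longer provably disjoint ways; choose
  `reversal_threshold` below it if you really want that regime.
* **Zero-adverse convention.** #Ad = 0 yields score 0 with status
  `zero_adverse` unconditionally, even when #Re = 0 too. #Re = 0 with
  #Ad > 0 yields no finite score (`undefined_no_reversal`) and ranks
  last.
* **Ranking tie-breaks.** Equal scores (including the zero-adverse
  ties at 0) break by larger #Re, then lexicographic condition key, so
  ranking is a deterministic total order. Conditions (dose/duration) of
  one compound are ranked independently; no cross-condition
  aggregation is performed, and replicates within a condition are
  mean-collapsed before the fold-change (logged).
* **"High matching score" cohorts.** The mutation-match cohort is
  operationalised as argmax assignment (with the lexicographic tie
  rule), plus an optional minimum-score floor (default 0). Samples with
  empty mutation sets score 0 everywhere and are flagged (`tied`)
  rather than dropped, so argmax cohorts partition the samples.
* **Enrichment universe.** The default universe is the shared
  analyzable transcriptome — genes present in both the signature and
  the perturbation profile — not the whole genome. Reversed and
  adverse sets are enriched separately. Significance uses BH-FDR q at
  0.05; raw-p thresholding is a flag. No pathway content is bundled
  (licensing and version drift); collections are user-supplied GMT.

## Synthetic data: what a green test establishes

The generators emit small worlds with planted truth. The tissue
generator produces negative-binomial counts (variance μ + φμ², default
φ = 0.1, base means log-normal around 100) for exercising the
prefilter, and a DE table whose signal genes carry their *exact*
planted fold-change (default ±4) with p ~ 10^−U(4,8) and whose null
genes carry |fc| near 1 with uniform p. Real DE tables carry estimation
noise in fc; this one intentionally does not, so signature recovery is
deterministic. The perturbation generator plants exact E2 fold-changes
(±3 opposite-direction for reversed genes, +16 on neutral genes for
adverse ones, on a uniform 5–15 control baseline) plus optional additive
Gaussian noise on the treated channel — a stand-in chosen to stress the
thresholds, not a model of L1000 assay noise. The mutation generator
gives cell lines disjoint gene sets and samples 80% subsets of their
assigned line plus private genes. None of the generators model
transcriptome covariance, batch effects, dose–response shape, or
variant-level mutation structure; green tests establish the arithmetic
and the planted-truth recovery, not performance on real cohorts.

Defaults: 2,000 genes, 50 up + 50 down signature genes, 20 + 20
samples, three compounds at reversal fractions 0.8/0.5/0.2 with equal
adverse fractions (0.05 of neutral genes), noise off. All generators
are byte-identical under a fixed seed.

## Numerical choices

* Strict inequalities at every threshold (a gene exactly at ±2 or at
  p = 0.001 is unlabelled; FC₂ exactly ±15 is not adverse).
* The hypergeometric tail is computed through the survival function in
  log space (scipy), exact to ~1e-15 against enumeration for N ≤ 12;
  BH-FDR goes through statsmodels and matches the textbook step-up to
  1e-12 on random vectors.
* Fold-changes are exact IEEE arithmetic; no result clipping. The floor
  applies only to the denominator.
* Tabular floats are written with 6 significant digits; set outputs are
  sorted lexicographically for diff-stability. Round-tripping a
  perturbation file through the writers preserves classifications (the
  planted margins exceed the 1e-5 relative rounding).

## Known limitations

* Gene identity is exact-string; cross-platform ID harmonisation must
  happen upstream.
* No dose–response modelling: each (dose, duration) condition is scored
  independently, and comparing RADE across conditions of one compound
  is left to the user.
* The score is undefined (not merely large) for compounds with adverse
  hits and zero reversals; downstream consumers must handle the
  sentinel.
* Enrichment treats pathways as flat sets; no topology, no
  redundancy correction beyond BH.
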