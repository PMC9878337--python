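# rade

**Reversed and Adverse Drug Effect (RADE) scoring for connectivity-map-style
drug screening.**

Drug-repurposing screens often rank compounds by how well their induced
expression changes *reverse* a disease signature, and ignore what else the
compound does to the transcriptome. `rade` scores both sides: it rewards
compounds that push cancer-associated genes back toward normal and penalises
compounds that push genes — disease-associated or not — strongly in a harmful
direction. It is aimed at computational drug-discovery researchers working
with tumor-vs-normal differential expression (e.g. TCGA-style cohorts),
compound perturbation profiles (CMap/LINCS-style treated-vs-DMSO expression),
and mutation profiles (CCLE/TCGA-style gene-level calls).

## The method

Two differential comparisons are labelled gene by gene:

* **E1** (cancer vs normal tissue): gene *g* is labelled +1 if FC > 2 and
  p < 0.001, −1 if FC < −2 and p < 0.001, else 0. The non-zero genes form the
  disease signature **Mu**. Genes with raw-count totals below 10 in either
  sample group are prefiltered out.
* **E2** (compound-treated vs DMSO-treated cell line): per gene,
  `FC_j = (T_j − D_j) / max(|D_j|, 0.1)`, where the 0.1 floor prevents
  division blow-up for weakly expressed controls.

Crossing the two yields, per (compound, cell line, dose, duration) condition:

* **reversed** genes **Re**: E1 = +1 and FC₂ < −2, or E1 = −1 and FC₂ > 2;
* **adverse** genes **Ad**: FC₂ beyond ±15 in the disease direction, or a
  strong (|FC₂| > 15) hit on a gene the disease leaves unchanged.

The compound's score is

```
RADE = (#Ad / #Re) · (#Mu / #Re)
```

— harm per unit of correction, times the fraction of the disease signature
left uncorrected. **Lower is better.** A compound with no adverse genes
scores exactly 0; one with adverse genes but no reversals has no finite
score and ranks last. Tumor samples are mapped to cell lines by
`Match_k(s) = |DE(s) ∩ Mucl(k)| / |Mucl(k)|` over mutated-gene sets, and
reversed/adverse sets are interpreted through hypergeometric pathway
enrichment (Benjamini–Hochberg FDR, q < 0.05) and pairwise drug-combination
set comparison.

## Worked example

Everything runs on synthetic fixtures with planted ground truth — no
downloads. Three compounds are planted that reverse 80%, 50% and 20% of a
100-gene disease signature while strongly perturbing the same number of
neutral genes:

```sh
$ rade simulate --outdir fixture --seed 7
$ rade signature --de fixture/de_table.tsv --out signature.tsv
signature genes: 100/2000
$ rade classify --signature signature.tsv --perturbations fixture/perturbations.tsv --outdir effects
cpd_A|CL1|10 uM|24 h: reversed=80 adverse=95
cpd_B|CL1|10 uM|24 h: reversed=50 adverse=95
cpd_C|CL1|10 uM|24 h: reversed=20 adverse=95
$ rade score --effects effects/effects_cpd_A.tsv --signature signature.tsv
rade=1.48438 status=defined n_reversed=80 n_adverse=95 n_signature=100
$ rade score --effects effects/effects_cpd_C.tsv --signature signature.tsv
rade=23.75 status=defined n_reversed=20 n_adverse=95 n_signature=100
```

cpd_A reverses 80 of the 100 signature genes at the cost of 95 adverse
genes: RADE = (95/80)·(100/80) ≈ 1.48. cpd_C buys the same harm with only
20 reversals and scores 16× worse. Equal harm, better correction, lower
(better) score — exactly the ordering the statistic is built to expose.
The same stages are available as library functions
(`rade.label_tissue_genes`, `rade.classify_effects`, `rade.rade_score`,
`rade.rank_compounds`, …) and as one `rade run --config config.yaml`
pipeline; `rade match`, `rade cohort`, `rade enrich` and `rade combo` cover
patient matching, cohort selection, pathway enrichment and combination
comparison.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

simulates a 2,000-gene cohort with a 500-gene planted signature, plants a
compound that reverses 100 signature genes with no adverse hits, runs the
full signature → fold-change → classification → scoring path, and writes
the RADE score the package returns for that compound as JSON.

See `docs/methods.md` for model assumptions, parameter defaults and known
limitations.
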