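# psapred

Case-case GWAS meta-analysis and calibrated subtype risk prediction on
multi-cohort genotype dosage data, exercised end-to-end on a bundled
synthetic cohort simulator.

The pipeline distinguishes two subtypes of a common disease (labelled
`PSA` vs. `PSC`, with shared controls) through:

1. **synthdata** — multi-cohort case-control simulator: shared and
   subtype-specific risk loci, one strong MHC-like locus, population
   structure, per-marker imputation quality, optional case-only cohort.
2. **assoc** — marker QC (MAF / call rate / exact HWE) and per-cohort
   logistic Wald association with covariates and conditioning markers;
   genomic-control λ.
3. **meta** — fixed-effects inverse-variance meta-analysis (METAL-style
   summary interchange), plus the indirect case-case χ² statistic
   `(β_A − β_C)² / (V_A + V_C − 2ρ√(V_A V_C))` with conservative ρ = 0.
4. **select** — stepwise conditional indirect meta-analysis feature
   selection with a cross-validated median-AUROC plateau stopping rule
   (gain < 0.2% three blocks in a row, 200-marker budget).
5. **classify** — train/test design (10% hold-out at a 3:7 subtype ratio,
   balanced training), classifier registry (ridge logistic, LDA, shrinkage
   DA, random forest, gradient boosting, elastic net), repeated CV, AUROC
   and top-k% precision/recall/specificity.
6. **risk** — Bayes/KDE calibration of classifier scores into posterior
   subtype probabilities under configurable prior prevalences, calibration
   curves, and risk assessment for unknown-subtype samples.
7. **ensemble** — tenfold ensemble with per-fold conditional selection and
   mean-rank combination; leave-one-cohort-out evaluation.
8. **enrich** — overlap of markers with regulatory-element BED intervals
   by significance bin, relative to the baseline bin, with optional MHC
   exclusion.

## Test

```sh
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py` (oracle equivalence,
type-I-error calibration, planted-signal recovery, pipeline
discrimination, calibration, ensemble behaviour); the full run takes a few
minutes on one CPU.

## CLI

The `psapred` entry point chains the stages on files
(VCF v4.2 with `DS` dosages + tab-separated phenotype tables):

```sh
psapred simulate --config cfg.yaml --out data/
psapred qc       --vcf data/cohort0.vcf --out data/cohort0.qc.vcf
psapred assoc    --vcf data/cohort0.vcf --pheno data/cohort0.pheno.tsv \
                 --case PSA --covariates subpop --out c0.psa.tsv
psapred meta     --results c0.psa.tsv --results c1.psa.tsv \
                 --names cohort0,cohort1 --out psa.meta
psapred indirect --psa psa.meta --psc psc.meta --rho 0 --out indirect.tsv
psapred select   --config cfg.yaml --out path.tsv
psapred train    --config cfg.yaml --out run/
psapred evaluate --scores run/test_scores.tsv --top-k 5,10,20 --out metrics.tsv
psapred calibrate --cv-scores run/cv_scores.tsv --apply-to run/test_scores.tsv \
                  --out posteriors.tsv
psapred assess   --posteriors posteriors.tsv --out high_risk.tsv
psapred ensemble --config cfg.yaml --out combined.tsv
psapred loco     --config cfg.yaml --out loco.tsv
psapred enrich   --indirect indirect.tsv --bed cells.bed --out enrich.tsv
```

Every command writes a `*.runlog.json` with parameters, seeds, and
filter counts. A single master seed in the config makes full runs
reproducible bit-for-bit.

Configuration is YAML:

```yaml
seed: 3
cohorts:
  - {name: cohort0, vcf: data/cohort0.vcf, pheno: data/cohort0.pheno.tsv,
     contains_psc: true}
params:
  simulate: {n_cohorts: 2, n_control: 500, n_psa: 500, n_psc: 500,
             n_markers: 200, seed: 3}
  select: {max_markers: 200, p_pool_max: 0.05, covariate_names: [subpop]}
  train: {model_name: logistic_ridge,
          select_params: {max_markers: 60}}
```

## Conventions

- Dosages in `[0, 2]`; VCF coordinates 1-based; BED intervals 0-based
  half-open (converted on read).
- Classifier scores are oriented so larger = more `PSA`-like.
- The extended MHC window is chr6:25–34 Mb.
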