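# mirwoi

A reusable pipeline for classifying the endometrial window of implantation
(WOI) from miRNA panel-qPCR Cq profiles. Given per-replicate Cq tables from a
167-miRNA panel (plus endogenous and spike-in controls), the pipeline:

1. averages replicate profiles per patient,
2. quantile-normalizes the Cq values (training-fitted reference, replayed on
   held-out profiles),
3. removes miRNAs missing in more than 10% of profiles,
4. imputes remaining non-amplified cells with the global maximum normalized Cq,
5. standardizes features (zero mean, unit sample variance) and applies PCA,
6. fits an elastic-net-penalized linear score against the ordinal encoding
   108 h → −1, 120 h → 0, 144 h → +1, with 10-fold cross-validation over
   (α, λ, PCA variance target),
7. calls the endometrial state from the score: > +1 → 144 h, < −1 → 108 h,
   otherwise 120 h.

**Penalty convention:** the objective is
`RSS + λ·(α‖β‖₂² + (1−α)‖β‖₁)` — α weights the *squared* (ridge) term, the
reverse of the usual glmnet convention. α = 1 is pure ridge, α = 0 pure lasso.

Also included: three-class evaluation (confusion matrix with rows = predicted,
one-vs-rest SEN/SPE/PPV/NPV, macro averages, concordance-by-pIF), a
differential-expression screen (inclusive |log2FC| ≥ 0.585 and p ≤ 0.05, with
a Shapiro–Wilk gate choosing pooled vs Welch t-tests), and a synthetic cohort
generator so everything is testable without any external dataset.

## CLI

```sh
# synthesize a cohort (Cq table, roles, metadata, ground truth)
mirwoi simulate --out-dir sim/ --seed 1 --effect-size 2.0

# train on labelled patients; writes model.json + cv_report.json
mirwoi train --cq sim/cq.tsv --roles sim/roles.tsv \
             --metadata sim/metadata.tsv --out-dir model/ --seed 1

# score new profiles
mirwoi predict --model model/model.json --cq sim/cq.tsv \
               --roles sim/roles.tsv --out predictions.tsv

# confusion matrix + metrics against metadata labels
mirwoi evaluate --predictions predictions.tsv --metadata sim/metadata.tsv \
                --out metrics.json

# differential-expression screen (120h vs 108h, 120h vs 144h)
mirwoi de --cq sim/cq.tsv --roles sim/roles.tsv \
          --metadata sim/metadata.tsv --out de.tsv
```

`--config config.yaml` overrides option defaults on any subcommand. Cq tables
are delimited wide tables (rows = assays, columns = profiles); empty cells,
`NA`, or Cq ≥ 40 (configurable ceiling) mean no amplification. Profile columns
named `<patient>-r<k>` group replicates by patient.

## Layout

- `src/mirwoi/data.py` — Cq/metadata I/O, replicate averaging, control QC,
  train/test splitting
- `src/mirwoi/preprocess.py` — quantile normalization, amplification filter,
  imputation, scaler, PCA, frozen parameter store
- `src/mirwoi/enet.py` — coordinate-descent elastic net, score thresholds,
  cross-validation, trained-model serialization
- `src/mirwoi/evaluate.py` — three-class metrics and concordance
- `src/mirwoi/de.py` — differential-expression screen
- `src/mirwoi/simulate.py` — synthetic cohort generator
- `src/mirwoi/cli.py` — command-line interface
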