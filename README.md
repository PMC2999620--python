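# seropanel

Multi-site serum proteomic case-control biomarker panel discovery, built as a
tested, reusable pipeline:

- **KS marker screening** — two-sample Kolmogorov–Smirnov distance per
  analyte, asymptotic p-values, Benjamini–Hochberg q-values, up/down
  direction from median log differences (`seropanel.ks`).
- **Log-normal marginal fitting** — Gauss–Newton least squares between the
  empirical CDF and a normal CDF in log concentration, with a moment
  fallback and a heavy-tail robustness utility (`seropanel.lognormal`).
- **Naive Bayes classification** — diagonal multivariate-normal classifier
  over log concentrations with an adjustable class prior; sensitivity,
  specificity, pairwise-concordance AUC, Wilson intervals
  (`seropanel.classifier`).
- **Greedy beam search** — forward search over marker panels maximizing
  sensitivity + specificity, with configurable beam width, plateau stopping,
  and marker-frequency accounting (`seropanel.search`).
- **Six-analysis biomarker selection** — two control populations x three KS
  criteria (per-site / combined / both), beam search per analysis,
  frequency gating, union with provenance (`seropanel.selection`).
- **Criteria-gated training** — class-stratified 10-fold cross-validation
  with per-fold refits, an ordered pre-specified criteria cascade, final
  panel choice, model freezing with content hashes, and structurally
  enforced blinded verification (`seropanel.pipeline`).
- **Preanalytical site audit** — mean between-site within-class KS vs.
  disease KS per analyte, with >= 0.4 flagging and display ordering
  (`seropanel.preanalytical`).
- **Synthetic cohort generator** — multi-site case/control matrices with
  log-normal marginals, planted disease markers (location shifts in log
  space), and disjoint planted site-handling artifacts, calibrated against
  the closed form `KS = 2*Phi(delta/2) - 1` (`seropanel.synthetic`).

## Command line

All stages are exposed via the `seropanel` entry point:

```sh
seropanel synthesize --config cfg.yaml --out-matrix m.tsv --out-annot a.tsv --seed 1
seropanel screen     --matrix m.tsv --annot a.tsv --out screen.tsv
seropanel fit        --matrix m.tsv --annot a.tsv --out models.tsv
seropanel select     --matrix m.tsv --annot a.tsv --out selection.json
seropanel search     --matrix m.tsv --annot a.tsv --candidates ids.txt --out panels.tsv
seropanel train      --matrix m.tsv --annot a.tsv --selection selection.json --out model.json
seropanel classify   --model model.json --matrix m.tsv --out scores.tsv
seropanel verify     --model model.json --matrix m.tsv --barcodes bc.tsv --key key.tsv --out verification.json
seropanel audit-sites --matrix m.tsv --annot a.tsv --threshold 0.4 --out audit.tsv
seropanel run        --config run.yaml
```

`run` executes the full flow (split -> screen -> select -> search ->
cross-validate -> gate -> freeze -> blinded verification) into a run
directory with a manifest of content hashes; reruns with the same config are
byte-identical. Exit codes: 0 success, 2 validation error, 3 stage failure.

An end-to-end `run.yaml` looks like:

```yaml
out_dir: runs/demo
synthesis: {study_mimic: true}
verification_fraction: 0.25
seeds: {split: 1, cv: 2, search: 3, synthesis: 4}
selection: {ks_threshold: 0.3, frequency_threshold: 10, score_threshold: 1.7}
beam: {beam_width: 1000, max_panel_size: 10}
prior_case: 0.5
```

## File formats

Plain TSV throughout: the matrix has a header row of analyte ids and a
leading `sample_id` column with strictly positive RFU values; annotations
use the fixed header `sample_id class_label site control_subtype stage
histology age sex smoking_status pack_years gold_grade barcode` with `NA`
for unknowns; the blinding key is `barcode`/`class_label`. Floats are
written with `repr` so write/read round trips are bit-stable.

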