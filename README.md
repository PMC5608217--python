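# frmt

Ensemble feature ranking for two-class protein-expression matrices.
Ten filter feature-selection criteria — Welch t-test, Wilcoxon rank-sum,
and eight greedy information-theoretic selectors (MIM, MIFS, mRMR, JMI,
DISR, CMIM, ICAP, CIFE) — are fused into a single stable ranking with
the TOPSIS multi-criteria decision procedure (features are the
alternatives, the selection methods the criteria).  The package also
ships the matching evaluation protocol: repeated stratified k-fold
cross-validation over a pluggable classifier roster, scored by MCC and
rank-based AUC, with winning-frequency and best-method analyses, plus a
synthetic-data generator for RPPA-like cohorts with planted signal.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the heavier simulation-backed
properties (≈6 min on one CPU); everything else runs in seconds.
Brute-force reference implementations live in `tests/oracles.py`.

## Command line

```bash
# generate a synthetic two-class cohort (class counts of a named preset
# or fully custom) with planted discriminative features
frmt simulate --preset READ --n-redundant 8 --seed 1 --output cohort.csv

# fused ranking (or any single criterion via --method)
frmt rank --input cohort.csv --label-column stage --positive-label 1 \
     --method frmt --top-k 10 --output ranking.tsv

# repeated stratified CV across classifiers / selectors / subset sizes
frmt evaluate --input cohort.csv --label-column stage --positive-label 1 \
     --folds 10 --repeats 30 --subset-sizes 5,10,15,20 \
     --output-dir eval_out
```

Every flag can be preset from a flat YAML file via `--config`
(command-line values win), and every run writes a JSON provenance
sidecar.  Rankings are TSV (`rank`, `feature_name`, `score`) with a JSON
sidecar that makes `read_ranking` a lossless inverse of `write_ranking`.

## Library

```python
from frmt import SyntheticConfig, generate, frmt_rank, cross_validate

data, truth = generate(SyntheticConfig(
    n_early=100, n_advanced=100, n_features=115,
    n_informative=8, effect_size=1.5, seed=0))
ranking = frmt_rank(data)           # scores = TOPSIS closeness H
mcc, auc = cross_validate(data, "frmt", 10, "nb", n_folds=10, n_repeats=30)
```

Labels are encoded `+1` (positive / early stage) and `-1` (negative /
advanced stage) everywhere; MCC's TP counts positive-class hits.

## Notes on defaults

- Information-theoretic criteria see equal-frequency discretized values
  (10 bins by default, `--bins`); the t-test and rank-sum criteria use
  the continuous values directly.
- The TOPSIS decision matrix is built from the methods' native scores
  (`score_mode="raw"`); a rank-transformed variant
  (`score_mode="rank"`, entries `m − r + 1`) is available on
  `build_decision_matrix` / `frmt_rank`.
- The classifier roster is svm, rf, dt, lda, nb, fl (a minimal Gaussian
  fuzzy-inference classifier) and knn, consumed through a small
  fit/predict/decision-scores adapter.
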