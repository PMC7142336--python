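# hmmdbp

Prediction of DNA-binding proteins (DBPs) from evolutionary profiles.
DBPs — transcription factors, polymerase components, repair and
remodelling enzymes — are routinely identified from sequence alone by
binary classifiers, and profile HMMs built from multiple alignments carry
more evolutionary signal than raw sequence. `hmmdbp` implements that
approach end to end for people who have HH-suite `.hhm` profiles (or just
want to study the method's statistical machinery):

1. **Profile decoding** — an `.hhm` file stores match-emission scores
   `x = −1000·log₂ p`; the 20 emission columns are decoded back to
   probabilities with `f(x) = 2^(−x/1000)`, giving an `L × 20` matrix
   `h` with entries in `[0, 1]`.
2. **Feature extraction** — each protein becomes a fixed-length vector
   fusing three families:
   - AAC (amino-acid composition): `h̄_j = (1/L) Σᵢ h_{i,j}`, 20 features;
   - ACT (auto-covariance): `A_{j,g} = (1/(L−g)) Σᵢ (h_{i,j}−h̄_j)(h_{i+g,j}−h̄_j)`
     for lags `g = 1..G`, 20·G features;
   - CCT (cross-covariance): the same lagged product between distinct
     columns `j ≠ k` (ordered pairs), 380·G features.

   With all three families, the descriptor has `20 + 400·G` dimensions —
   2020 at the default `G = 5`.
3. **Feature selection** — features are ranked by boosted-tree importance
   (XGBoost total gain by default; random-forest impurity decrease as an
   alternative) and the top K (default 270) are retained.
4. **Classification** — an SVM with RBF kernel, `C` and `γ` tuned over
   `2^−10 … 2^10` by grid search with stratified cross-validation on the
   training data; a random forest is available for comparison runs.
5. **Evaluation** — stratified 10-fold CV, jackknife (leave-one-out) CV
   and independent train/test protocols, reporting SN, SP, ACC, MCC and
   AUC from pooled held-out predictions, plus ROC curves.

A synthetic-data module generates labeled `.hhm` profiles with planted,
tunable class signal in each feature channel (column mean shifts → AAC,
lag-1 autocorrelation → ACT, lagged cross-column coupling → CCT), so the
entire pipeline is testable without any sequence database or HHblits run.

## Worked example

```python
from hmmdbp import (SyntheticSpec, FeatureSpec, EvalSettings, make_dataset,
                    rank_features, evaluate_cv)

spec = SyntheticSpec(n_pos=100, n_neg=100, length_range=(50, 200),
                     effect_size=0.8, seed=42)
ds = make_dataset(spec, FeatureSpec(max_lag=5))
print(f"{ds.n_samples} proteins x {ds.n_features} features")

ranking = rank_features(ds, "xgboost", seed=42)
print("top 5 features:", ranking.top_names(5))

base, _ = evaluate_cv(ds, "tenfold", EvalSettings(), seed=42)
print("before selection:", base)

settings = EvalSettings(select_method="xgboost", select_k=270,
                        grid_search=True, grid_step=2, grid_folds=5)
report, _ = evaluate_cv(ds, "tenfold", settings, seed=42)
print("after selection: ", report)
```

prints

```
200 proteins x 2020 features
top 5 features: ['CCT[D,I,1]', 'ACT[H,1]', 'ACT[C,1]', 'ACT[Y,2]', 'AAC[P]']
before selection: [tenfold] ACC=0.7100 SN=0.6300 SP=0.7900 MCC=0.4255 AUC=0.7977 (TP=63 FP=21 TN=79 FN=37)
after selection:  [tenfold] ACC=0.9700 SN=0.9800 SP=0.9600 MCC=0.9402 AUC=0.9980 (TP=98 FP=4 TN=96 FN=2)
```

The top-ranked features are precisely the planted signal channels of this
synthetic dataset: `CCT[D,I,1]` is the coupled column pair, `ACT[C,1]` and
`ACT[H,1]` the autocorrelated columns, `AAC[P]` a mean-shifted column.
Pruning the 2020-dimensional descriptor to its 270 most important
components lifts pooled 10-fold accuracy from 0.71 to 0.97 — feature
selection removing noise dimensions is the method's central effect.

## Command line

Every stage is also a subcommand of the `hmmdbp` console script:

```sh
hmmdbp simulate --n-pos 100 --n-neg 100 --effect-size 1.5 --seed 1 --out fix/
hmmdbp featurize --profiles fix/ --labels fix/labels.tsv -g 5 --out features.tsv
hmmdbp rank --table features.tsv --out ranking.tsv
hmmdbp select --table features.tsv --ranking ranking.tsv -k 270 --out top.tsv
hmmdbp evaluate --table top.tsv --protocol tenfold --out eval/
hmmdbp pipeline --config run.yaml          # the whole chain, one config echo
hmmdbp sweep-g --profiles fix/ --labels fix/labels.tsv --g-max 10 --out gsweep/
hmmdbp sweep-k --profiles fix/ --labels fix/labels.tsv --out ksweep/
hmmdbp compare-features --profiles fix/ --labels fix/labels.tsv --out cmp/
```

`pipeline` writes the feature table, ranking, model metrics, ROC points
and a `config.yaml` echo (all effective settings + version) into the
output directory, so a run is reproducible from its artifacts alone.

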