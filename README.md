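# mineinjury

Predictive modelling of mining accident outcomes and days away from work
(DAFW) from structured injury records and free-text accident narratives.

Mining remains one of the most hazardous occupations, and agencies such as
the US Mine Safety and Health Administration (MSHA) collect large accident
registries combining *fixed-field entries* (occupation, nature of injury,
injured body part, accident/shift times, experience, …) with a short
free-text *narrative* of each accident. This package implements, as a
tested and reusable pipeline, an analysis that asks two questions of such
data: do the narratives carry enough information to predict the degree of
injury (a nine-class outcome), and can either input predict the number of
days away from work? It is aimed at occupational-safety researchers and
epidemiologists who want to run the full method — or any stage of it — on
their own injury registries or on fully synthetic data.

Because the real registry cannot be redistributed, the package ships a
first-class synthetic generator that emulates the structure of such data
(nine-class outcome imbalance, high-cardinality categoricals, short
signal-bearing narratives, a right-skewed non-negative DAFW outcome), so
every stage is testable end to end without any download.

## The method

**Target-statistics encoding.** High-cardinality categorical predictors
are replaced by smoothed per-class conditional probabilities. For category
$X_i$ and outcome class $Y_j$,

$$S_i(Y_j) = \lambda(n_i)\,\frac{n_{iY}}{n_i} + \bigl(1-\lambda(n_i)\bigr)\,\frac{n_Y}{n_{TR}},
\qquad \lambda(n) = \frac{n}{n+m},$$

where $n_i$ counts training rows with category $X_i$, $n_{iY}$ those also
in class $Y_j$, $n_Y$ the class total, $n_{TR}$ the training-set size, and
$m>0$ a smoothing constant. Rare categories shrink toward the class prior;
unseen categories map to it exactly ($\lambda(0)=0$). Since the $k$
per-class probabilities sum to one, only $k-1$ derived columns are kept.

**Narrative vectors.** Narratives are lowercased, punctuation-stripped,
stop-word-filtered and Porter-stemmed, then a word2vec model (CBOW with
negative sampling, 300 components by default) is trained on the training
narratives. A narrative's vector is the TF-IDF-weighted average of its
word vectors, with TF = term count / narrative length and
IDF = ln(corpus size / document frequency).

**Class-conditional augmentation.** To counter class imbalance, one
word2vec model is trained per outcome class; in each minority-class
training narrative, six randomly chosen words are each replaced by their
top three cosine neighbours in the class's own embedding, producing
exactly 18 synthetic narratives per eligible narrative (narratives shorter
than six words are left untouched). Held-out data is never augmented.

**Models and evaluation.** Logistic regression, a Gini decision tree, a
30-tree random forest, and a two-hidden-layer ReLU network (learning rate
0.001, dropout 0.3; softmax output for classification, softplus output for
regression so predicted DAFW is never negative) are trained on a
stratified 70/30 split and scored with support-weighted F1 / accuracy
(classification) or MSE / RMSE (regression). Feature importance for the
fixed-field network is leave-one-feature-out: the network is fully
retrained once per original variable (a target-encoded categorical's
derived columns are removed together) and importance is the drop in
held-out weighted F1.

## Worked example

The numbered scripts under `analysis/` run the studies at desk scale and
write their tables under `results/`. For example:

```bash
$ python analysis/02_outcome_models.py
...
mean weighted F1 — narrative RF 0.859 vs best fixed-field model 0.390 (majority baseline 0.336)

$ python analysis/04_dafw_models.py
...
mean RMSE — fixed-field ANN 9.55, fixed-field RF 9.61, narrative ANN 12.13,
narrative RF 12.63 (DAFW sd 12.05)

$ python analysis/03_augmentation.py
...
minority-class F1 improved in 5/5 seeds (mean 0.122 -> 0.629)
```

Read: when the outcome signal is planted only in the narratives, the
narrative-trained random forest reaches weighted F1 0.86 while every
fixed-field model stays near the majority baseline (0.34–0.39); when DAFW
is driven by shift timing and experience — information absent from the
narratives — the fixed-field regressors achieve the lower RMSE (9.6 vs
12.1–12.6, against an outcome standard deviation of 12.0); and augmenting
a 5% minority class raises its F1 from 0.12 to 0.63 on average. The
feature-importance script ranks the planted dominant variable
(nature of injury, ΔF1 ≈ 0.39) first, with null features within ±0.006.

The same pipeline is scriptable via the `mineinjury` CLI
(`generate`, `preprocess`, `encode`, `vectorize`, `augment`, `run-all`)
or the `ExperimentConfig` / `run_experiment` API.

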