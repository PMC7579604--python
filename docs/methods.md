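# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
studies do and do not demonstrate.

## Record model and filtering

A record holds eight categorical predictors (subunit, classification,
accident type, occupation, activity, injury source, nature of injury,
injured body part), a coal/metal flag (0 = coal, 1 = metal), accident and
shift-start clock times in minutes since midnight, three experience
variables in decimal years, a free-text narrative, a nine-class
degree-of-injury outcome, and a non-negative integer days-away-from-work
(DAFW) count that may be missing.

Cleaning removes rows with any empty retained field and rows whose outcome
describes non-employees, itemizing both counts. Missing DAFW is *not* a
cleaning matter: it is an outcome, filtered only when the DAFW task is
selected (which also drops zero-day rows). Task selection for the
fixed-field outcome task drops classes holding less than 1% of rows; the
threshold is computed on the full pre-split dataset, and an explicit
`keep_classes` override exists because the exact class set used on the
real registry is ambiguous (by the registry's class mix, five classes
exceed 1%, yet three-class analyses are also reported for it; the package
implements the rule, not a guess at the discrepancy).

The hours-into-shift feature is ((accident − shift start) mod 1440)/60,
so overnight shifts wrap through midnight; both raw time variables are
retained alongside it, since replacing them degrades the models.

## Narrative normalization

Tokenization lowercases and splits on non-alphanumerics; stop words come
from a fixed list shipped with the package (so results cannot drift with
third-party library versions); each remaining token is stemmed with a full
implementation of the classic Porter algorithm. Normalization is
idempotent on the synthetic vocabulary (verified by test); genuine English
has rare words whose stem re-stems differently, which is why the
idempotence property is asserted on the generator's vocabulary rather than
universally.

## Target-statistics encoding

S_i(Y_j) = λ(n_i)·n_iY/n_i + (1 − λ(n_i))·n_Y/n_TR with λ(n) = n/(n+m).
Per category the class probabilities sum to one, so k−1 derived columns
are kept; the dropped class defaults to the last in sorted label order
(configurable — any choice is information-equivalent). The smoothing
constant m is not fixed by the method's source; the default is m = 10
(λ = 1/2 at ten observations, a mild shrinkage for the cardinalities at
hand) and every encoder property holds for any m > 0. The encoder is
fitted on the training split only; whether the original analysis did so is
unstated, and the leakage-safe choice is made here. Unseen categories
receive the prior, the λ(0) = 0 limit of the same formula.

## Word embeddings and narrative vectors

The word2vec trainer is a compact numpy implementation: CBOW by default
(skip-gram available), negative sampling with five noise words drawn from
the unigram^0.75 distribution, fixed context window (default 5), fixed
learning rate 0.025, mini-batched updates, float32, single-threaded and
fully seeded — identical parameters and seed give bit-identical vectors.
The source analysis fixes only the dimension (300); window, epochs,
min_count and architecture are unstated there, and the defaults here
(window 5, 20 epochs, min_count 1, CBOW) are documented as this package's
own choices, all config-exposed.

TF = term count / narrative length; IDF = ln(n_docs / doc_freq) with no
smoothing, exactly as stated — a term in every narrative gets weight zero.
The narrative vector sums tfidf(term)·vec(term) over distinct in-vocabulary
terms (TF already carries the term's multiplicity) and divides by the
number of in-vocabulary token positions; out-of-vocabulary tokens are
skipped and excluded from the divisor, and a narrative with no
in-vocabulary token yields a flagged zero vector.

## Augmentation

One embedding per outcome class, trained only on that class's training
narratives. Per narrative, six distinct in-vocabulary positions are chosen
uniformly at random (positions whose token the class model lacks are
skipped and redrawn; if fewer than six are eligible, all are used);
each chosen position is substituted by each of the top three cosine
neighbours of its token (self excluded, ties broken lexicographically for
determinism), giving 6 × 3 = 18 variants per eligible narrative, each at
Hamming distance one from the original. Narratives under six tokens pass
through untouched. Synthetic rows keep their source label and a
provenance tag; augmentation refuses rows tagged as held-out. The
after-augmentation counts of the real registry are not integer multiples
of 19× the before-counts, so the original per-class intensity is
unrecoverable; an optional per-class cap stands in for it.

## Models

Logistic regression (multinomial, L2, lbfgs, standardized inputs),
decision tree (Gini / squared error) and random forest (30 trees) are
scikit-learn estimators configured here, single-threaded and seeded. The
ANN is the package's own numpy MLP: two ReLU hidden layers (default
widths 128 and 64 — unstated in the method's source and config-exposed),
inverted dropout 0.3, Adam at learning rate 0.001, 50 epochs with batch
size 64 and no early stopping (determinism), softmax/cross-entropy output
for classification and softplus/MSE for regression. Inputs are
standardized internally; for regression the softplus output is scaled by
the training-target standard deviation, which preserves the non-negativity
guarantee while keeping optimisation on O(1) quantities. No class
weighting is applied on imbalanced tasks — augmentation is the pipeline's
imbalance remedy.

## Evaluation

Stratified 70/30 split with largest-remainder rounding, so the overall
training size is exactly round(0.7·n) and every class is within ±1 of its
proportional share; seeded and deterministic. Confusion matrices are
rows-actual/columns-predicted. Precision and recall use the
denominator-zero ⇒ 0 convention. Weighted F1 averages per-class F1 by
support. RMSE = √MSE by construction. For the DAFW experiment the split is
stratified on the degree-of-injury class of the remaining lost-time rows.

## Leave-one-feature-out importance

The fixed-field ANN is retrained once per original variable on the
identical train/test partition, removing all derived columns of a
target-encoded categorical together; importance is baseline minus ablated
*test-set* weighted F1 (train-set F1 would reward overfitting; the source
is silent on which was used). Deltas may be negative; no sum rule holds.

## Synthetic data generator

The generator defines the study conditions. Defaults: the nine-class
outcome mix follows the real registry's observed imbalance (35.3% days
away only, 30.8% no lost time, …, 0.37% fatality); categorical
cardinalities mirror the registry (occupation 198, injury source 127,
activity 98, …); narratives of 8–20 tokens are drawn Zipf-like from a
fixed 200-token background vocabulary, and with probability q = 0.9 a
record carries 1–3 tokens from a 10-token signal vocabulary unique to its
class (disjoint across classes and from the background, all tokens
stop-word-free and Porter-stable so normalization preserves them); DAFW
for lost-time classes is log-normal (multiplicative noise, σ = 1 —
matching the right skew of real lost-time distributions) around a median
of 6 days times a geometric 0.5×–2× effect ladder over nature-of-injury,
body-part and occupation levels, times exp(0.06·hours − 0.02·job
experience); 20% of accidents occur ≥ 8 h into the shift so the hours
feature has spread; small rates of blanked fields (1%), missing DAFW (2%)
and non-employee rows (0.5%) exercise the cleaning rules. Fixed-field
class signal is off by default (signal lives only in narratives); the
importance study switches it on for one field to create a dominant
feature.

What the generator does *not* emulate: real narrative grammar and shared
vocabulary across classes (class vocabularies are disjoint by
construction, making the text task easier than reality), correlated
categorical fields, registry coding noise, temporal drift. Passing the
directional studies therefore shows the pipeline recovers signal it is
pointed at and ranks inputs correctly — not that real-data effect sizes
are reproduced.

## Study designs and problem sizes

The multi-seed studies (`mineinjury.studies`) use n = 5000 (outcome and
DAFW comparisons, 10 seeds), n = 3000 (augmentation benefit, 10 seeds;
importance calibration, 5 seeds), with 50-component, 5-epoch embeddings —
the comparisons concern relative performance, for which embedding capacity
beyond this adds nothing — while the 300-component default is exercised on
a 1000-narrative corpus. The DAFW study flattens the category-effect
ladder and strengthens the hours/experience coefficients (0.15 and −0.05,
σ = 0.5) so lost days depend *only* on fixed-field information, which is
the contrast that study is designed to measure. The augmentation study
uses a 5% minority (fatality) between two equal majority classes.

## Known limitations

* The word2vec trainer is designed for corpora of 10³–10⁵ short
  documents; it makes no attempt at the throughput of native
  implementations.
* Target-statistics encoding is fitted once on the training split; no
  cross-fold variant is provided.
* The <1% class-filter ambiguity on the real registry (three vs five
  retained classes) is surfaced as configuration rather than resolved.
* For DAFW regression the categorical encoder uses the degree-of-injury
  class as its target; category effects on the *magnitude* of DAFW are
  therefore invisible to the fixed-field features unless they also shift
  the class mix.
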