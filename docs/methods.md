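# Methods

This note documents the models and procedures implemented in `pepmine`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data experiments do and do not demonstrate.

## The record template

One experimental data entry couples a short peptide system to an observed
self-assembly outcome. Nine categorical features describe the system and
protocol — peptide sequence (2–3 residues over the 20 standard amino
acids), N-terminal / C-terminal / side-chain (non-terminal) modifications,
system category (single peptide, conjugate, or mixture), conjugate partner,
thermal process (none/heating/cooling), topology (linear/cyclic), and the
solution (solvent plus zero or more solutes). Four numerical features carry
the conditions: solvent volume ratio (fraction in [0,1]), peptide
concentration (mg/ml, > 0), pH ([0,14]), and temperature (°C). The outcome
is one of eight phases: no-assembly, hydrogel, fiber, tube, sphere,
particle, ribbon, vesicle. Records validate on construction (pydantic);
the conjugate category and a non-trivial conjugate partner imply each
other; missing numerics serialize as the literal `nan` token.

Controlled vocabularies are derived from data and sorted lexicographically,
so encodings are reproducible regardless of record order.

## Curation rules

Reported conditions rarely arrive as single standardized numbers. The
curation module applies fixed conventions:

* **Range expansion.** A condition reported as a range yields six entries
  at `linspace(low, high, 6)` — deterministic even spacing including both
  endpoints rather than random draws, since random sampling would neither
  be reproducible nor guarantee coverage of the range.
* **Critical-value bracketing.** A reported phase-transition value *c*
  yields four entries: 0.8c and 0.9c labelled with the phase below the
  transition, 1.1c and 1.2c with the phase above. Values scale linearly
  with *c* by construction.
* **Concentration standardization.** Molar units convert to mg/ml through
  the peptide molecular weight, computed from an average residue-mass table
  as Σ(residue masses) + 18.02 (one water for the free termini);
  modifications are ignored unless an extra mass is supplied. Weight
  percent assumes the solution density (water, 1000 mg/ml, by default).
* **Missing temperature** defaults to room temperature, 25 °C.
* **Missing pH** goes through a pluggable resolver whose default only
  resolves the unambiguous case — pure water with no solutes → 7.0 —
  and otherwise leaves pH missing. Estimating the pH of mixed organic
  solvents from composition has no generally agreed formula, so it is
  deliberately left to user-supplied resolvers.

Numeric features are min-max normalized to [0,1] at the encoding boundary,
not inside records: a normalized concentration of 0 would violate the
record invariant `concentration > 0`, and keeping records in raw units
preserves their physical meaning. Normalization is monotone and exactly
invertible when the feature has spread; zero-spread features map to 0 with
a warning.

## Encoding

Records become fixed-length vectors: each categorical feature contributes a
one-hot block per the schema vocabulary, numerics contribute one dimension
each. Two features are multi-element. The sequence uses three positional
slots (tripeptide length) over the amino-acid vocabulary plus an explicit
"absent" category that dipeptides use in slot 3, keeping one schema for
both lengths. The solution uses a one-hot solvent block plus a multi-hot
solute block, since a record may carry several solutes. Missing numerics
are imputed with the feature's normalized median over the encoded set (the
medians are recorded on the matrix so training-set medians can be reused at
test time). The feature-group map records the contiguous dimension span of
each of the 13 named features; its spans are disjoint and cover every
dimension, which is what makes grouped attribution conservation exact.

## Classification protocol

* **Splits.** 60/15/25 train/validation/test. Rounding convention:
  `train = round(0.60 n)`, `val = round(0.15 n)`, test takes the remainder —
  on n = 1012 this gives a 607-record train set, and splitting 75
  publications gives 45/11/19 papers. The publication-grouped mode splits
  source publications, not records, so the test set comes entirely from
  unseen studies; leakage is structurally zero.
* **SMOTE.** Minority phases are oversampled by interpolating between
  same-class nearest neighbors: each synthetic row is `x + u·(x_nn − x)`,
  `u ~ U(0,1)`, neighbors found with `k = 5` (reduced to class size − 1
  when needed). The default strategy balances every class up to the
  majority count and is overridable with per-class targets, because
  published post-oversampling set sizes do not always correspond to full
  balancing and the exact targets are a user decision. Originals are never
  modified, and only the training partition is ever oversampled.
* **Model selection.** Four classic families — random forest, multilayer
  perceptron, Gaussian process, k-nearest-neighbors — each with a
  three-axis hyperparameter grid searched exhaustively under stratified
  five-fold cross-validation; the full selection table is returned next to
  the refitted best model so the argmax can be audited.
* **Metrics.** Precision, recall, F1 and the 8×8 confusion matrix. The
  averaging mode is an open choice in this kind of study; the default is
  weighted (class-frequency) averaging with macro reported alongside, and
  the mode is stamped into every result object. The chance level for
  comparison is the uniform-guess accuracy 1/8 = 0.125.
* **Interpretability.** Shapley values of `predict_proba` are estimated by
  permutation sampling with a background set: feature dimensions are
  revealed in random order on top of a background row, and a dimension's
  attribution is its mean marginal change in class probability. The
  estimator is exactly efficient per sampled permutation (the telescoping
  sum equals f(x) − f(background)). Per-dimension attributions are summed
  over each feature's span, so one-hot categorical features get a single
  grouped importance; grouping conserves attribution mass to machine
  precision. Default 16 permutations; the estimator is seeded and
  deterministic.

## Literature-mining pipeline

Documents arrive as plain text (a PDF-to-text converter is injectable but
not bundled). The experimental section is located by heading patterns —
Materials/Methods/Experimental section/Experimental details, singular or
plural, case-insensitive, tolerant of numbering prefixes, matched on their
own line — and closed by the next section's heading (Results and
Discussion, Conclusions, References, Acknowledgements, ...). With no start
heading the complete document is kept; with no end heading the text runs to
the end. Paragraphs (split on blank lines) survive iff they contain a
mining keyword (case-insensitive substring) and are at least 100 characters
long; within survivors, lines under 9 characters — typical PDF-extraction
debris like figure labels — are dropped. The abstract is prepended, and if
the assembled text exceeds the token budget (default 4096) the body is
trimmed from both ends, keeping the middle: introductions and conclusions
carry the least experimental detail. The abstract is protected and only
tail-truncated, with a warning, if it alone exceeds the budget.

The default keyword vocabulary ships the reconstructable core (the seven
phase names, "assembl", and the condition terms concentration / pH /
temperature / solvent / peptide) and is user-extensible; enlarging it can
only grow the kept-paragraph set. The tokenizer is a pluggable registry
entry; the default is a deterministic whitespace tokenizer whose id is
recorded in every manifest, because published token counts depend on the
counting model's proprietary tokenizer and are not reproducible exactly.

## Extraction and its evaluation

Extraction backends satisfy a minimal contract — text in, a list of flat
field→string maps out — so a hosted language model can be adapted without
touching the rest of the pipeline. The shipped reference backend is
rule-based: it segments text on `Sample N:` anchors (grouping a sample's
condition sentences and its result sentences by number), captures each
field with a dedicated pattern, and reports `nan` for anything not found,
never inventing values. It is deterministic, which makes it the instrument
for measuring the harness ceiling. Coercion of raw strings into the schema
is total: units are parsed and standardized to mg/ml, spelling variants map
through an alias table (nanofiber→fiber, nanotube→tube, gel→hydrogel, ...),
and unmappable values become missing and are logged — no out-of-vocabulary
category can reach downstream storage. An export utility writes one
prompt/completion pair per publication (aggregating all of its entries)
for users who want to fine-tune their own extractor; the training itself is
out of scope.

Scoring pairs each predicted entry with a same-publication ground-truth
entry: exact unique (sequence, phase) matches pair directly; otherwise the
remaining truth entry with the most agreement over the other 11 features
wins, ties broken by lowest index, each truth entry consumed at most once
(one-to-one matching prevents a single lucky prediction from absorbing many
truth rows). Categorical accuracy is the exact-match fraction per feature —
the composite solution feature counts only when solvent and all solutes
match — and the summary accuracy is the unweighted mean over the nine
features. Numeric MAE is computed per feature in raw units over pairs where
both sides carry values; `nan` extractions are excluded and tallied. With
zero pairs, accuracies are undefined (None), not zero.

## Synthetic data: what it emulates and what it does not

The dataset generator reproduces the structural features of a curated
experimental corpus: mixed categorical/numerical features, strong class
imbalance (default priors 0.30 no-assembly, 0.24 hydrogel, 0.16 fiber,
0.08 tube, 0.08 sphere, 0.06 particle, 0.04 ribbon, 0.04 vesicle —
configurable), and multiple records per source publication (75 publications
by default, each guaranteed at least one record). Under the `rule`
mechanism the phase is a stated deterministic decision list over
interpretable clauses (concentration below 1 mg/ml → no assembly; FF motif
in water → hydrogel, or fiber at ≥ 5 mg/ml; cyclic → tube; DMSO with acidic
pH → sphere, else particle; Fmoc N-terminus → ribbon; otherwise vesicle),
sampled constructively so the drawn phase frequencies follow the priors.
`noisy` flips labels with probability ε; `shuffled` permutes them.

The chance-level control uses a uniform class prior: with shuffled labels
and an imbalanced prior, a classifier legitimately scores the majority
frequency rather than 1/8, so the comparison against the 0.125 chance level
is only meaningful when all eight classes are equiprobable.

The document generator renders each publication's records into a templated
paper: abstract, condition sentences (one `Sample i` paragraph per record),
result sentences stating phases, keyword-free distractor paragraphs
(asserted keyword-free at import), and sub-threshold noise lines. The
`sectioned` template carries explicit headings, so preprocessing cuts at
"Results and Discussion" and the extractor never sees the phase statements
— reproducing the sparse-information challenge of real papers, where the
evaluation's fallback matcher must pair entries on conditions alone. The
`headingless` template keeps the whole text, making all 14 fields
recoverable. Numbers are generated pre-rounded (concentration/solvent
ratio to 2 decimals, pH/temperature to 1) so that text formatting is
lossless and the noiseless round trip is an exact-recovery ceiling check.

What passing these tests shows: the record/encoding/classification wiring
is correct, the protocol recovers learnable structure and does not
hallucinate structure in noise, the preprocessing filters behave exactly as
specified, and the extraction-evaluation harness is exact at its ceiling.
What it does not show: performance on real publications — real prose is
not templated, real extraction requires a stronger backend than the
reference rules, and real curated data carries labelling noise, correlated
features, and vocabulary drift that the generator does not emulate.

## Numerical choices and degenerate inputs

Problem sizes in the default test and reproduction runs: 1000-record
synthetic datasets across 75 publications for classifier checks, 60-record
/ 6-publication corpora for mining round trips, 10 explained records × 25
background rows × 6 permutations for attribution checks, 10^5 draws for
the Monte Carlo baseline. All stochastic stages fan a single run-level
seed out to split/oversample/model/attribution seeds. Ties in grid search
resolve to scikit-learn's first-best; vocabulary order is lexicographic;
an all-zero one-hot block decodes to "unknown" (None); empty record lists
are errors for vocabulary building and splitting, while an empty
prediction set scores as undefined rather than zero. Classes with a single
training instance cannot be SMOTE-interpolated and are skipped with a log
message (or raise under strict mode).

## Known limitations

* The reference extraction backend is template-oriented; on free prose it
  will under-extract (by design it never invents values). It measures the
  harness, not the state of the art.
* pH resolution from solution composition is intentionally minimal.
* The whitespace tokenizer undercounts relative to subword tokenizers, so
  token budgets are conservative in characters per token.
* Grouped attribution uses sampled permutations; per-dimension values carry
  Monte Carlo error (conservation is exact regardless). Increase
  `n_permutations` for publication-grade importance rankings.
* Modified termini do not alter the molecular weight used in concentration
  conversion unless an explicit extra mass is supplied.
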