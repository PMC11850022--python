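# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package, in the order a user meets
them.

## Stimulus logic

Stimuli are five-dimensional binary vectors; bit `1` on a dimension is the
feature value typical of category A (in the letter tasks, the feature
containing a T). Training/transfer designs place the perfectly diagnostic
criterion attribute (CA) on a configurable dimension: category A is the
all-ones prototype plus the four vectors with one family-resemblance (FR)
dimension flipped; category B items are the complements; transfer items flip
the CA bit. This is the minimal construction satisfying the design's stated
properties — CA classifies 10/10 training items, each FR bit 8/10, and every
transfer item differs from its source in exactly the CA position. The exact
composition of the original five stimulus sets is published only as figures,
so this construction is an inference, asserted by tests rather than assumed.

Task rules: family resemblance is the ≥3-of-5 majority (defined only for five
dimensions; other sizes raise rather than silently generalize), odd/even is
the parity of the bit count, unidimensional tasks read one probed dimension
(the top fin by default, the dimension of median rated salience). The 20-item
control set is balanced 10/10 under both the majority and the parity rule, so
neither task can be shortcut by a response bias.

## The synthetic cohort generator

Each participant draws, once:

- a **believed mapping** per dimension — correct with probability
  `learn_prob[d]`, otherwise reversed with probability `rho_rev` (default
  0.25) or ambiguous. Reversed mappings are a real phenomenon in this
  paradigm (participants scoring 0% on a dimension's feature probes);
  ambiguous dimensions respond at chance on probes and abstain from
  categorization votes.
- a **probe fidelity** `q_d`: single-feature probes are answered correctly
  with probability `q_d` under a correct mapping, `1 − q_d` under a reversed
  one, 0.5 under an ambiguous one. Fidelity exists because measured
  per-dimension accuracies in this kind of study are not trichotomous — group
  means run 67–91% with only 2–4 of 5 dimensions at 100% — and because a
  latent accuracy threshold is only identifiable when measured accuracies
  fall on both sides of it.
- a **strategy set** `U`: either drawn explicitly (its size from a mix, the
  set being CA plus random FR dimensions), derived by the step gate
  `a_d ≥ θ` from the participant's own realized all-features accuracies
  (`strategy_mode="gated"`), or all five dimensions
  (`strategy_mode="all"`). In the all-dimensions mode the believed mappings
  are always directional (`rho_rev = 1`): using a dimension presupposes
  *some* association, possibly the wrong one.

Responses are the majority vote of `U` under the believed mappings (ties and
empty sets resolve at chance), mixed with a lapse probability `g`. Training
repeats blocks of the 10 training stimuli (preceded by an observation
sub-block in the variants that include observation learning) until two blocks
reach ≥90%, up to `max_training_blocks` (default 25); non-convergence is
flagged, never dropped. Then 3 transfer blocks × 10 stimuli and 3
all-features blocks × 10 feature probes follow. The all-features probes are
*simulated* before the training loop (the gated strategy set needs them) but
emitted in chronological phase order; everything is driven by one
per-participant seed stream, so datasets are byte-reproducible.

Response times are multiplicative-lognormal around the process mean
(`RT = μ · exp(N(0, σ²))`, σ = 0.3 by default): positive, right-skewed, with
no distributional claim from the source paradigm. The process means:

| mode | whole stimulus | single feature probe |
|---|---|---|
| COMBINATION | `rt_base + |U|·(t_fix + t_recall·recall?)` | `rt_base + t_fix + t_recall·recall?` |
| DIFFERENTIATION | `rt_base + t_fix + t_recall·recall? + t_diff·1[|U|<5]` | same |

`recall?` is 1 for tasks whose answer requires learned feature–category
associations (training, transfer, category counting, unidimensional category
judgement) and 0 for letter tasks, where the answer is printed on the
stimulus. Default ranges (`rt_base` 0.5–1.0 s, `t_fix` 0.25–0.35 s,
`t_recall` 0.35–0.45 s, `t_diff` 0.8–1.2 s; control-task variants `rt_base`
0.4–0.6, `t_fix` 0.4–0.5, `t_recall` 0.25–0.35) put simulated means on the
1–10 s scale of observed group RTs; they are configuration, not claims.

Strategy-mix defaults are theory-mode dependent, because the two theories
predict different strategy ecologies: under COMBINATION, unidimensional
categorization is modal and overall similarity rare
({1: .45, 2: .2, 3: .15, 4: .1, 5: .1}); under DIFFERENTIATION, holistic
processing is primitive and overall-similarity strategies are modal
({1: .25, 2: .1, 3: .1, 4: .1, 5: .45}), as the triad-task literature
motivating that theory reports.

Two simulated raters independently return the participant's true `|U|`,
perturbed by ±1 with probability 0.2 (clipped to 1..5) or replaced by the
incomprehensible token with probability 0.07. These rates reproduce the
observed scale of inter-rater statistics in this paradigm (≈63% identical
ratings, κ ≈ 0.5, mean absolute difference ≈ 0.3, ≈13% of participants with
at least one incomprehensible marking).

What the generator does **not** emulate: learning dynamics within training
(knowledge is static per participant), eye movements, within-participant
strategy switching, the visual/color properties of the stimuli (a color-cue
variant is represented purely as elevated learning probabilities for
non-strategy dimensions), and rater idiosyncrasies beyond symmetric noise.
Passing tests therefore show that the *analysis pipeline* behaves correctly
on data with the assumed structure — not that real behavior has that
structure.

## The step-function model

For one participant, the all-features test yields per-dimension accuracy
`a_d ∈ {0, 1/6, …, 1}` (6 probes per dimension) and a modal believed mapping
(correct / reversed / ambiguous on an exact split). The model predicts
`P(respond A) = g/2 + (1 − g) · core`, where `core` is 1, 0.5 or 0 as the
majority vote of the eligible dimensions falls to A, ties, or B. Eligibility
defines the variants: **GATED_FR** uses `{d : a_d ≥ θ}` (equality counts as
used — with θ on the attainable-accuracy grid, ≥ vs > is pure convention,
fixed for determinism); **UNGATED** uses all dimensions; **CA_ONLY** only the
criterial one.

Inference is exact on a grid: θ over the attainable accuracies
{0, 1/6, …, 1} and `g` over 21 equispaced points on [0, 0.5] (lapse above 0.5
mimics response reversal, which the reversed mappings already capture), with
a uniform prior over grid points. The posterior is the normalized likelihood;
the evidence is the log prior-weighted mean likelihood, which charges an
automatic Occam penalty to variants whose prior mass covers poorly fitting
regions. Grid inference was chosen over MCMC because two bounded parameters
on small grids make the evidence exact at grid resolution and every fit
deterministic. A predicted probability of exactly zero for an observed
response yields a −∞ log likelihood sentinel, never an exception; the
posterior then ignores that grid point. Cohort-level comparison sums
per-participant log evidence (no hierarchical pooling) and reports pairwise
log Bayes factors; exact ties are reported, not silently broken.

### Identifiability of the threshold

θ is constrained only at the realized accuracy values of that participant's
dimensions: all thresholds between two adjacent realized `a_d` values induce
the same eligible set, and — with only 10 distinct transfer stimuli —
different eligible sets can even induce identical majority labels (e.g. a
participant using dimensions {2, 3, 5} with correct mappings labels every
transfer item exactly as the full five-dimension majority does). Such
participants carry a flat θ posterior whose mean sits mid-grid; this is the
correct Bayesian answer, not a failure of the fit. The recovery study in the
test suite therefore runs at conditions where accuracies span the threshold
region (learning probability 0.8, probe fidelity uniform on 0.75–0.98),
which yields informative posteriors for most multidimensional participants
while keeping the number of perfectly learned dimensions (≈1.8 of 5 on
average) in the observed range.

## Statistics

Spearman ρ is the Pearson correlation of mid-ranks (scipy's tie handling),
with a two-sided t-approximation p on n−2 df by default — standard practice
at n ≈ 36–46 — and an exact-style permutation alternative (add-one rule,
explicit seed) since the original analysis does not state its method.
Standardized simple regression reports β (= Pearson r), t, R², adjusted R².
Cohen's κ is unweighted over the categories actually observed, treating each
rating value and the incomprehensible token as distinct nominal categories;
incomprehensible pairs count for κ and percent-identical but are excluded
from the mean absolute difference. The one-way ANOVA uses the standard sum-of-
squares decomposition with η² = SS_between/SS_total; Tukey(-Kramer) adjusted
p-values come from the studentized-range distribution on N−k df, and Cohen's
d uses the pairwise pooled SD. Degenerate inputs (constant vectors, all-equal
raters, zero variance, undersized groups) raise typed errors rather than
returning NaN; the pipeline records such a statistic as undefined instead of
aborting the run.

## Pipeline

`run_pipeline` either simulates a cohort or loads the tidy CSVs, then calls
the same module-level operations a user would call directly — the report has
no private code paths, which a test asserts. Reports carry a provenance block
(SHA-256 of the canonical config JSON excluding the output directory, the
master seed, the package version); identical configs reproduce reports
byte-for-byte. Stage failures abort with the stage name and remove partial
outputs.

Control-task simulations emit only the analyzed trials (feature-*testing*
trials, 10 per block in multidimensional conditions and 2 in unidimensional
ones, plus the 20-trial task-training and task-test blocks); the two
familiarization screens per feature-training block produce no behavioral
measurements and are not represented.

## Known limitations

- The step model takes the step literally: no soft (sigmoidal) gate, no
  hierarchical population prior, no RT likelihood (RTs are analyzed
  descriptively).
- Per-dimension accuracy is the model's knowledge summary; per-feature
  asymmetries within a dimension are not represented.
- The θ grid's resolution is bounded by the 6-probe design; thresholds are
  only ever recovered to the containing grid cell.
- Simulation sizes in tests and the acceptance script (cohorts of 40–54,
  20–100 replicate cohorts per question) were chosen to give stable rates at
  interactive runtimes; all are configuration.
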