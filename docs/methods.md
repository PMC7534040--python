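# Methods

This note documents the models and procedures implemented in `semcoh`,
the defaults chosen where the method left the design open, and what the
synthetic-data experiments do and do not establish.

## Semantic space

The space is classical LSA. Documents are tokenized (lowercase,
punctuation stripped, numerals kept, contraction clitics split on a fixed
suffix table: *n't, 'll, 're, 've, 'm, 's, 'd*). The term–document count
matrix receives log-entropy weighting — local weight `log(1 + tf)`, global
weight `1 − H_t/log n`, where `H_t` is the entropy of the term's
distribution over documents — the historically standard choice for LSA.
Truncated SVD retains the top `d` components; word vectors are rows of
`U·Σ`. The `U`-only convention is available
(`scale_by_singular_values=False`) because cosine structure differs
between the two; `U·Σ` is the default since it weights dimensions by the
variance they explain. Default `d = 100` for synthetic corpora;
configurable, with `d ≤ min(|V|, n_docs)` enforced.

The per-dimension sign indeterminacy of the SVD is resolved by forcing
the largest-magnitude entry of each left singular vector positive, so
repeated builds are bit-identical. `scipy.sparse.linalg.svds` is started
from a fixed vector for the same reason.

Passage vectors are unweighted sums of word vectors (equivalent to means
under cosine). Out-of-vocabulary tokens contribute nothing but are
counted: windows are defined over *transcribed words*, not
vector-bearing words, so function words absent from the corpus still
occupy window positions. A passage with no in-vocabulary token is
flagged empty and is excluded from cosines; undefined values propagate
as missing, never as zero.

## Transcript editing

Transcripts arrive with inline span annotations — `<fs>` false starts and
aborted utterances, `<rep>` immediate perseverations, `<com>` comments
about the task or the speaker's own word-finding — reflecting human
editing judgments; no automatic disfluency detection is attempted. Spans
may not nest or overlap; parse errors carry line numbers. Non-lexical
fillers are simply absent from transcripts. Removed fractions are exact
rationals (`fractions.Fraction`); any rounding happens in reports.
Removal percentages are available per response and pooled per group
(whether the original analysis pooled or averaged is unspecified, so
both are reported).

## Coherence

Windows are 20 tokens (configurable), advancing one token at a time; a
response with `n` clean tokens yields `n − 19` windows, computed via a
cumulative sum over token vectors (O(n) instead of O(n·w)); an
independent per-slice oracle in the test suite confirms equivalence to
1e-10.

GC compares each window to the prompt's composite vector: the mean of
unit-normalized whole-response vectors of control speakers.
Normalizing before averaging stops long responses from dominating
(whether the original averaged raw or normalized vectors is unstated).
When a control speaker is scored, their own response is left out of the
composite to avoid self-similarity bias; patients are scored against the
all-controls composite.

LC compares each window to the *disjoint* predecessor — the 20 tokens
immediately before the window's start — rather than the step-1
predecessor, which would share 19 of 20 tokens and pin LC near 1
regardless of content. The overlapping reading is available behind
`lc_style="overlapping"`. Consequently GC needs ≥ 20 clean tokens and LC
needs ≥ 40; shorter responses are excluded from the affected measure
with a logged reason.

Cosines are reported raw; small negative values are possible in SVD
space and are not clamped (the familiar 0–1 description of the scale is
treated as describing typical values). Per-response GC/LC are means over
windows; participant values are unweighted means over their eligible
responses; group summaries are unweighted means and sample SDs over
participants.

## Lexical-semantic markers and PCA

Seven markers per response: mean frequency (log scale), semantic
diversity, concreteness, age of acquisition, and phonemic length of the
nouns produced, each averaged token-wise over noun tokens found in the
norms table (misses are counted, not imputed); type:token ratio and
% closed-class words over all clean tokens. Norm lookup is
case-insensitive on the exact surface form — no lemmatization, to avoid
a hidden tagger/lemmatizer dependence; POS tags come from the norms
table (or any upstream tagger). The closed-class lexicon ships with the
package and is configurable. Markers are computed per response and
averaged per participant (a pooled option exists; the original's choice
is unstated).

The nine participant-level measures (7 markers + GC + LC) are z-scored
and reduced by PCA on the correlation matrix. `k = 4` factors are
retained (fixed by design, not chosen by parallel analysis), varimax
rotation is applied, each factor's sign is set so its largest-|loading|
measure loads positively, factors are ordered by explained variance, and
scores are least-squares regressions of the standardized data on the
loadings (mean zero by construction). These conventions make repeated
runs exactly reproducible; rotation and scoring method were open choices.

## Statistics

**Group comparison (GC/LC).** Response-level values are modelled with
fixed effects {intercept, group (dummy, control reference — the estimate
is the patient-minus-control gap), mean-centred response length} and
random effects {participant intercept, prompt intercept, by-prompt group
slope}, fitted by REML. The implementation is self-contained: the
residual variance is profiled out of the REML criterion, the variance
ratios are optimized by L-BFGS-B from several starts, and the group
effect is tested by a t-test with Satterthwaite denominator df computed
from finite-difference gradients of the contrast variance and the
observed information of the REML criterion. On a fixture dataset the
estimates, SEs, Satterthwaite df and p-values agree with lme4/lmerTest
to at least four significant figures (an R oracle test in the suite).
Singular fits descend a declared ladder — drop the by-prompt slope, then
the prompt intercept — and every simplification is recorded in the
result. Variance components stuck at the zero boundary are treated as
known zeros in the df computation, and df is clamped to `(0, N − p]`.

**Single-case tests.** The group model is refitted on the controls plus
one patient, testing the case indicator (two-sided, α = 0.05); this is
the mixed-model extension of the classical modified t-test (which is
included as `crawford_howell` for cross-checking). The by-prompt slope
is omitted by default: with a single case it is not identifiable apart
from the residual. Monte-Carlo calibration at the study's size
(12 controls × 6 prompts; participant SD 0.06, prompt SD 0.03, residual
SD 0.08) gives a false-positive rate statistically indistinguishable
from 5% over 500 null simulations, and detection above 80% for a case
shifted by 3× the SD of a control speaker's response values
(√(0.06² + 0.08²)).

**Accuracy model.** Trial-level correctness is modelled with a logistic
mixed model: 2×2×2 factorial fixed effects (group × task × control
demand), sum-coded ±0.5 with the alphabetically second level positive;
random intercepts for participants and items plus within-unit slopes
(participant: task, demand; item: group), dropped as a block if the fit
fails. Fitting is Laplace-approximate ML: penalized IRLS profiles the
fixed effects and modes at fixed variance parameters, Nelder-Mead
optimizes the log-SDs, and a final BFGS pass re-optimizes the fixed
effects on the Laplace objective (this matches glmer's Laplace fit to
~1e-3 on a fixture). Each fixed effect is assessed by a likelihood-ratio
test against the model without it. Complete separation (a constant
outcome overall or within a design cell) is reported with the offending
cell rather than fitted.

Two-sided tests at α = 0.05 throughout; no multiple-comparison
correction is applied. Correlations are Pearson r with the two-sided
t-transform p, pairwise-complete, requiring ≥ 3 pairs.

## Synthetic data

The generator produces every pipeline input with planted ground truth.

*Topics.* Twenty topics on a ring, each owning a disjoint 200-word core
vocabulary; a topic's word distribution also draws on its neighbours'
cores out to ring distance 3 with per-side masses 0.26 / 0.11 / 0.05.
This makes ring-adjacent topics semantically close in the trained space
(cosine ≈ 0.9 between adjacent topic centroids) and distant topics
unrelated — the geometry needed for gradual drift to be locally smooth.
Within-block word weights are Dirichlet draws fixed per block, so every
topic sees a shared block identically.

*Responses.* A response starts on the prompt topic. At every 20-token
boundary, with probability δ, a smooth speaker begins a linear mixture
ramp (default 200 tokens) toward a ring neighbour — finishing a ramp
before drifting again — while an abrupt speaker jumps instantly to a
uniformly random topic. During a ramp, topic membership of successive
tokens follows a deterministic error-diffusion blend of the two topics
rather than independent Bernoulli draws, so the drifting mixture adds no
artificial window-composition noise on top of the drift itself.
Function words (closed-class, out-of-vocabulary for the space) are
interleaved at a configurable rate (study default ≈ 0.35 with
between-speaker variation), diluting windows the way real transcribed
speech does. Ground-truth topic trajectories are returned with every
response.

*Study.* The default study is 12 controls × 6 prompts (δ = 0.05,
≈ 135 words, 60 s) and 7 patients × 5–6 prompts with drift severities
spread over 0.25–0.8, faster transitions (80 tokens), similar word
counts but much slower speech, 9% of tokens annotated for removal
(controls: 1.6%). Impairment is induced entirely through drift and
length — vectors are never edited post hoc. Norms are linear
combinations of four latent factors plus noise mapped to plausible
scales; accuracy trials follow the factorial logistic model with
patients' ability offsets tied to their drift severity, so
semantic-control performance and coherence covary across patients as
they should.

*What the generator does not emulate:* natural lexical statistics
(Zipfian frequencies, polysemy), syntax and morphology, real
psycholinguistic norm distributions, prosody or timing, and individual
lexical-retrieval failure patterns. Passing tests therefore establish
that the measures and models behave correctly under the stated
generative assumptions — monotone GC decline in drift rate, the
GC-impaired/LC-spared dissociation for smooth drift, nominal error
rates, unbiased effect recovery — not that any particular clinical
population will show a given effect size.

## Simulation conditions used in tests

Problem sizes were chosen so the whole suite runs in a few minutes on
one CPU: drift experiments use 200 responses per condition (length 120
for the monotonicity sweep; length 280 and δ = 0.2 for the dissociation
check, where "LC within sampling error" is operationalized as a Welch
|t| below the 99% two-sided bound of 2.576 and "GC reduced" as t > 2);
calibration uses 500 null single-case simulations and 200
recovery/power simulations at the study's size; PCA recovery uses
n = 200 with noise SD 0.1. Simulation seeds are fixed in the tests and
recorded in acceptance output for reproducibility.

## Known limitations

- The LSA space quality depends entirely on the background corpus; the
  synthetic corpus yields much higher absolute coherence values than a
  space trained on natural text, so only contrasts, not absolute
  values, transfer across spaces.
- The disjoint-window LC is one of several defensible readings of
  "previous window"; the overlapping variant is provided but produces
  near-ceiling values by construction.
- Satterthwaite df relies on finite-difference derivatives; with
  variance components very near but not at the boundary the df can be
  sensitive to the step size (relative step 1e-4).
- The GLMM's Laplace approximation shares the known small-cluster bias
  of all Laplace-based logistic mixed models; no adaptive quadrature is
  implemented.
- Single-case inference assumes the case's residual variance matches
  the controls'; a genuinely more variable patient inflates the
  estimated deficit's significance.
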