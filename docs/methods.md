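# Methods

This note documents the models and procedures implemented in `ndchealth`,
the choices made where the design was genuinely open, and what the synthetic
test corpora do and do not establish about behaviour on real documents.

## Preprocessing

Text is ASCII-folded, lowercased, and split into sentences by a rule-based
splitter on terminal punctuation with an abbreviation exception list
(deterministic and dependency-light by design). Intra-word hyphens and
apostrophes are collapsed ("co-benefits" → "cobenefits") before tokens are
extracted as alphabetic strings, so hyphenation variants match a single
lexicon entry. The filtered token stream drops a fixed, versioned English
stopword list shipped with the package (reproducibility over any external
default; replaceable via `PreprocessConfig`) and tokens shorter than two
characters; numbers and punctuation are removed by construction. Bigrams are
formed from adjacent surviving tokens within a sentence and joined with an
underscore (`kyoto_protocol` style). Processing is English-centric and
documents are analysed as-is, with no language detection or translation.

Document-feature matrices default to a minimum document frequency of 2 for
the topic-model vocabulary (noise control) and 1 for keyness
(completeness).

## The engagement rubric

Candidate references are sentences containing at least one core health term
(multiword terms match as contiguous phrases on unfiltered sentence tokens,
so "save lives" survives stopword handling). Each candidate receives exactly
one category — sentence-level unitisation keeps counts well defined. Cue
lexicons, one per (group, level), drive the assignment with a fixed
precedence: trade-off > co-benefit > adaptation > mitigation > impact >
background. Rarer, more informative readings would otherwise be swallowed by
generic impact vocabulary, which is why precedence runs from rare to common.
Within a group the most specific level whose cue matches wins; the
"detailed" adaptation level additionally requires plan-operational
vocabulary (monitoring, early warning, surveillance, strengthening, ...) in
the same sentence, operationalising "detailed information and plans". A
candidate matching no cue falls back to impact/general — the minimal bare
mention, entry score 1.

Entry scores are 1 (general impact, background), 2 (general adaptation,
mitigation link, general co-benefit, trade-off) or 3 (specific impact,
specific/detailed adaptation, specific co-benefit). The published rubric
table prints no entry for a specific-but-not-detailed adaptation reference;
this implementation aligns it with the other "specific" categories at 3.
Aggregation uses the rule

    HES = 0 if no reference, else min(5, max entry + #groups − 1),

a breadth-bonus reading of "amended on the basis of more specific or
detailed references": it reproduces the anchor behaviours (a single general
mention scores 1; detailed multi-domain engagement scores 4–5) while keeping
the score a deterministic function of the category set. Scoring is
deterministic and monotone — adding a reference can never lower a score —
and both properties are enforced by tests.

The shipped lexicons are explicit, editable stand-ins developed against the
category definitions; the rubric is an automated coder and is not expected
to reproduce human coders' judgments verbatim on real NDCs.

## Keyword-assisted topic model

The model is LDA with four keyword topics (health, economics, energy,
agriculture) and two residual topics, K = 6. A token in keyword topic k is
drawn from a keyword-restricted distribution φ̃ₖ with probability πₖ
(switch prior Beta(γ₁, γ₂)) or from the regular distribution φₖ. All
distributions are integrated out and the sampler sweeps per-token (topic,
switch) assignments; the collapsed conditionals multiply the document-topic
predictive (n_dk + α), the switch predictive, and the appropriate word
predictive. Posterior summaries are means over every 5th post-burn-in sweep
(thinning reduces autocorrelation at negligible cost).

Defaults: α = 0.1, β = 0.01, β̃ = 0.1, γ = (1, 1), 1500 sweeps with 500
burn-in, all configuration-exposed. α is fixed rather than sampled (the
simplest faithful variant). Keywords shared between topics are a hard error,
keeping the φ̃ supports disjoint and attribution unambiguous. Keywords
absent from the vocabulary are dropped with a warning; a topic losing all
its keywords is a hard error naming the topic.

Initialisation anchors every keyword occurrence to its keyword topic with
the switch on; all other tokens start at uniform-random topics. Without the
anchor the keyword channel can die out in the first sweeps (π collapses
toward 0) and topic labels are then permutable — with it, labels are pinned
from sweep one. Uniform variates are drawn outside the numba-compiled
kernel, so fits are bitwise-reproducible given the seed regardless of the
compilation path.

The collapsed joint log-likelihood is tracked every sweep for convergence
monitoring; on a one-token corpus it equals the closed form −log V, and in
the unkeyed limit the sampler is standard collapsed-Gibbs LDA, verified
against brute-force enumeration of all K^N assignments on a 7-token corpus
(posterior-mean θ agreement within 0.02).

HTP is read directly off θ for the topic labelled "health".

## Keyness

For each bigram, a 2×2 table of (feature count, all-other-token count) by
group yields Pearson's χ² without continuity correction (the common
text-analysis default) and Dunning's G² (the corpus-linguistics standard),
with the 0·ln 0 = 0 convention for empty cells. Direction records the group
with the higher relative frequency; ranking defaults to χ² with
lexicographic tie-breaks. Both statistics are computed so either ranking is
available; no significance thresholds or multiplicity corrections are
applied, since the output is a ranked list. The default contrast is HES 0–1
(target) versus HES 2–5 (reference); rare bigrams are not trimmed by
default.

## Regression

The three models are logistic (any mention), OLS (HES) and OLS (HTP) on
eight country covariates after listwise deletion. OLS uses the sandwich
covariance with the HC1 small-sample factor n/(n−k); HC0/HC2/HC3 and
classical are switchable, and coefficients are invariant to that choice.
The logistic model reports conventional ML (observed-information) standard
errors — the robust-error phrasing is read as attaching to the OLS models —
with HC1 available behind a flag. Confidence intervals are 95% Wald on the
coefficient scale; fit statistics are R² and McFadden's pseudo-R²
(1 − ll_model/ll_null). Perfect separation and rank-deficient designs are
hard errors with diagnostics. The health-term-count sensitivity outcome is
fitted by OLS on the raw count, with a log1p transform config-gated.
Estimation is delegated to statsmodels; this module contributes the fixed
covariate set, the deletion step and the reporting surface.

## Synthetic data

The generators define the study conditions used throughout the tests.

*Topic corpora*: 200 documents of ~150 tokens (Poisson) over a 500-word
vocabulary, θ ~ Dir(0.1), six topics with block-structured word
distributions (block mass 0.9) and switch probability 0.3; keywords are
eight words per keyword topic. Under these conditions the sampler recovers
health-topic proportions with MAE < 0.05.

*Scored corpora*: 185 documents mixing neutral filler (a 500-word
pseudo-word lexicon disjoint from every rubric and stopword term, so filler
can never trigger a reference), theme sentences carrying non-health topic
keywords, and template health sentences assembled from the cue lexicons.
Category plants follow the observed mix (73% of documents mention health;
general adaptation is the most common reference type, specific co-benefits
and trade-offs rare). Because templates are built from the lexicons, planted
categories — and hence HES and term counts — are exactly recoverable, which
the end-to-end pipeline test asserts without tolerance. A hard-mode
paraphrase flag is reserved for robustness experiments and is not part of
the recoverability guarantee.

*Covariates*: 185 countries with world-scale magnitudes (log population
~N(16, 2), log GDP per capita ~N(8.5, 1.2), 20% small-island states, PM2.5
~N(27, 17) truncated). True coefficients default to the fitted point
estimates of the three country-level models; intercepts, which the source
table does not print, were chosen once to give realistic base rates
(any-mention ≈ 0.73, mean HES ≈ 2, mean HTP ≈ 0.1). Default missingness
(rate 0.054 on the democracy score) leaves ≈175 complete countries, the
listwise sample size of the study design. A heteroscedastic option scales
the noise SD by the absolute standardised PM2.5 value (with a 0.1 floor to
keep variances positive), the design used to validate HC1 against the
empirical sampling SD.

What passing these tests shows: the sampler, statistics and rubric
arithmetic are correct under the stated generative assumptions. What they do
not show: rubric agreement with human coders on natural prose, behaviour on
non-English documents, or topic-model adequacy for real NDC vocabulary —
the synthetic corpora have cleanly separated vocabularies and
lexicon-faithful phrasing by construction.

## Numerical and procedural choices

- One global seed expands into per-stage substreams keyed by stage name
  (CRC-derived SeedSequence), so adding a stage never shifts another
  stage's randomness.
- The parameter-recovery gate compares every refitted coefficient at
  n = 5000 against its 99.9% Wald interval: with 27 coefficients across the
  three models, per-coefficient 95% intervals would fail jointly about a
  quarter of the time by chance alone; 99.9% keeps the family-wise false
  alarm under ~3% while still detecting any real bias at that sample size.
- Gibbs categorical draws guard against floating-point overshoot by falling
  back to the last positive-probability slot.
- Keyness returns exact zeros (not NaN) for degenerate 2×2 margins.
- Empty-after-filtering documents are excluded from feature matrices with a
  warning rather than an error; empty corpora, empty groups, single-class
  outcomes and rank-deficient designs are hard errors.
- Problem sizes in the test suite (e.g. 30–60 documents for sampler
  invariants, 200 for recovery, 200 replicates for the HC1 check) were
  chosen as the smallest sizes at which the checked asymptotics are
  expected to hold cleanly.

## Known limitations

- The rubric is cue-driven: sarcasm, negation ("no impact on health") and
  cross-sentence references are out of reach; one category per sentence.
- Aggregation depends only on the set of categories present, not on
  reference counts beyond presence.
- The keyATM variant implemented is the base model: no covariate or dynamic
  extensions, no sampling of α, no model selection over K.
- The keyness module reports ranked statistics without inferential
  machinery.
- Real replication data (the deposited NDC corpus and covariate table) are
  not bundled; the pipeline accepts them through the same corpus/covariate
  interfaces when available.
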