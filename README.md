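# ndchealth

Measuring how countries engage with public health in their national climate
pledges.

Nationally determined contributions (NDCs) are the pledges countries submit
under the Paris Agreement, outlining mitigation and adaptation plans. They
are also the main global policy instrument for protecting population health
as temperatures rise — yet the attention given to health in them varies
enormously. `ndchealth` is a reusable, tested pipeline for quantifying that
engagement in any corpus of policy documents, and for asking which country
characteristics explain it. It is aimed at researchers in global health
policy and climate politics who work with document corpora and country-level
covariates.

## What it computes

**Health engagement score (HES, 0–5).** A rubric classifies every sentence
containing a core health term into one of ten categories — combinations of a
thematic group (impact, adaptation, mitigation, co-benefit, trade-off,
background) and a specificity level (general, specific, detailed) — each
carrying an entry score *e(c) ∈ {1, 2, 3}*. A document with reference
categories *C* and thematic groups *G(C)* scores

```
HES = min(5, max_{c∈C} e(c) + |G(C)| − 1),     HES = 0 if C = ∅
```

so any mention scores at least 1 and deep, multi-domain engagement
saturates at 5.

**Health topic proportion (HTP, 0–1).** A keyword-assisted topic model
(keyATM) — latent Dirichlet allocation with four keyword-seeded topics
(health, economics, energy, agriculture) plus two residual topics — is fit
by collapsed Gibbs sampling. Tokens in keyword topic *k* are drawn from a
keyword-restricted distribution φ̃ₖ with probability πₖ and from the
regular distribution φₖ otherwise, with priors θ_d ~ Dir(α), φₖ ~ Dir(β),
φ̃ₖ ~ Dir(β̃), πₖ ~ Beta(γ₁, γ₂). HTP is the posterior-mean θ mass a
document places on the health topic.

**Keyness.** Bigrams distinguishing low-engagement (HES 0–1) from
higher-engagement (HES 2–5) documents, ranked by the 2×2 Pearson χ²
(no continuity correction) and Dunning's log-likelihood ratio G².

**Country-level regressions.** Logistic regression of any-mention, and OLS
with heteroscedasticity-robust (HC1) standard errors for HES and HTP, on
log population, a small-island-developing-state indicator, log GDP per
capita, democracy score, health expenditure (% GDP), coal rents (% GDP),
population-weighted temperature change, and PM2.5 exposure, after listwise
deletion.

A synthetic-data module generates corpora with planted references (known
HES), corpora drawn from the topic model's generative process (known θ),
and covariate tables simulated at known coefficients, so the whole pipeline
is testable end to end without any external data.

## Worked example

```python
from ndchealth import Document, tokenize, HealthLexicon, score_document

lex = HealthLexicon.default()
text = ("Minimize climate-related health risks through: strengthening integrated "
        "risk monitoring and early warning systems and response for climate "
        "sensitive diseases. Renewable energy measures will also benefit health.")
scores, refs = score_document(tokenize(Document(doc_id="BTN", text=text)), lex)
print(scores.any_mention, scores.hes, scores.health_term_count)
for r in refs:
    print(f"  sentence {r.sentence_index}: {r.category} (entry {r.entry_score})")
```

prints

```
True 4 3
  sentence 0: adaptation/detailed (entry 3)
  sentence 1: mitigation/general (entry 2)
```

The first sentence is a detailed health-adaptation plan (entry score 3); the
second links mitigation to health (entry 2). Two thematic groups are
engaged, so HES = min(5, 3 + 1) = 4, and three core health terms occur.

Fitting the topic model on a synthetic corpus with known proportions:

```python
from ndchealth import build_dfm, KeyATMSpec, KeywordTopicModel
from ndchealth.synthetic import SyntheticCorpusSpec, gen_topic_corpus

docs, true_theta, keywords = gen_topic_corpus(SyntheticCorpusSpec(n_docs=200), seed=1)
dfm = build_dfm([tokenize(d) for d in docs], ngram_order=1, min_doc_frequency=2)
fit = KeywordTopicModel(dfm, KeyATMSpec(keyword_topics=keywords)).fit(seed=1)
print(fit.summary())
```

```
Keyword-assisted topic model (collapsed Gibbs)
==============================================
documents: 200   vocabulary: 500
topics: 6 (4 keyword + 2 residual)
iterations: 1500 (burn-in 500, thin 5), seed 1
final log-likelihood: -149163.3

topic      mean θ   π (keyword share)   keyword mass
health        0.136      0.366             0.381
economics     0.156      0.305             0.339
energy        0.175      0.349             0.350
agriculture   0.220      0.341             0.342
residual_1    0.133        -                 -
residual_2    0.180        -                 -
```

On this corpus the recovered health-topic proportions (`fit.htp("health")`)
have a mean absolute error of 0.014 against the generating truth.

## Command line

```bash
ndch simulate --out bundle --seed 1 --n-docs 185   # synthetic corpus + covariates
ndch pipeline --config cfg.yaml --seed 1           # corpus → scores → topics → keyness → regression
ndch score|topics|keyness|regress --config cfg.yaml  # individual stages
```

All stages write flat CSVs plus a manifest with input hashes, the seed and
versions; deterministic stages reproduce bitwise, stochastic ones given the
seed.

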