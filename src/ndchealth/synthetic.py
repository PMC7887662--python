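"""Synthetic corpora and covariate tables with known ground truth.

Three generators make every pipeline stage testable offline:

* :func:`gen_topic_corpus` — documents drawn from the keyword-assisted
  topic-model generative process (topic-blocked word distributions, a
  keyword/regular switch for keyword topics) with the true document-topic
  proportions returned.
* :func:`gen_scored_corpus` — documents assembled from neutral filler plus
  template health sentences of known rubric category, so the planted
  engagement scores are exactly recoverable; optional planted differential
  bigrams for keyness contrasts.
* :func:`gen_covariates` — country covariate tables with outcomes simulated
  at stated true coefficients under logistic and linear links, with optional
  heteroscedastic noise and missingness.

Every generator is a pure function of its spec and seed. The filler
vocabulary is a 500-word synthetic lexicon of pronounceable pseudo-words,
disjoint by construction from all health terms, cue terms and stopwords, so
no filler token can trigger the rubric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import Document, default_stopwords
from .health_scoring import ENTRY_SCORES, VALID_CATEGORIES, HealthLexicon

__all__ = [
    "SyntheticCorpusSpec",
    "SyntheticScoredCorpusSpec",
    "SyntheticCovariateSpec",
    "background_vocabulary",
    "category_templates",
    "gen_topic_corpus",
    "gen_scored_corpus",
    "gen_covariates",
    "true_hes",
]

# ---------------------------------------------------------------------------
# background vocabulary

def background_vocabulary(size: int = 500) -> list[str]:
    """Deterministic pseudo-word lexicon, disjoint from rubric vocabulary."""
    syllables = [c + v for c in "bdfgklmnprstvz" for v in "aeiou"]
    taboo = set(default_stopwords())
    lex = HealthLexicon.default()
    for term in lex.core_terms:
        taboo.update(term)
    for terms in lex.cues.values():
        for t in terms:
            taboo.update(t)
    words: list[str] = []
    for a, b, c in itertools.product(syllables, repeat=3):
        w = a + b + c
        if w not in taboo:
            words.append(w)
        if len(words) == size:
            return words
    raise RuntimeError("could not build background vocabulary")  # pragma: no cover


# ---------------------------------------------------------------------------
# topic-model corpus

@dataclass
class SyntheticCorpusSpec:
    """Generative settings for the topic-model corpus.

    Defaults are the desk-scale study conditions: 200 documents of ~150
    tokens over a 500-word vocabulary, four keyword topics plus two residual
    topics, document proportions drawn from a symmetric Dirichlet(0.1), and
    keyword-topic tokens routed through the keyword distribution with
    probability 0.3.
    """

    n_docs: int = 200
    doc_length_mean: float = 150.0
    vocab_size: int = 500
    keyword_topic_labels: tuple[str, ...] = ("health", "economics", "energy", "agriculture")
    n_residual_topics: int = 2
    n_keywords_per_topic: int = 8
    theta_alpha: float = 0.1
    true_theta: np.ndarray | None = None
    pi_true: float = 0.3
    block_mass: float = 0.9

    @property
    def n_topics(self) -> int:
        return len(self.keyword_topic_labels) + self.n_residual_topics

    @property
    def topic_labels(self) -> list[str]:
        return list(self.keyword_topic_labels) + [
            f"residual_{i + 1}" for i in range(self.n_residual_topics)
        ]


def gen_topic_corpus(
    spec: SyntheticCorpusSpec, seed: int = 0
) -> tuple[list[Document], pd.DataFrame, dict[str, list[str]]]:
    """Draw documents from the keyword topic model's generative process.

    Returns (documents, true theta frame, keyword lists). Each topic owns a
    block of the vocabulary carrying ``block_mass`` of its word distribution;
    keywords are the first words of each keyword topic's block.
    """
    rng = np.random.default_rng(seed)
    K = spec.n_topics
    V = spec.vocab_size

    def b26(j: int) -> str:  # alphabetic ids survive number stripping
        s = ""
        for _ in range(3):
            s = chr(ord("a") + j % 26) + s
            j //= 26
        return s

    vocab = [f"w{b26(j)}" for j in range(V)]

    # block-structured word distributions
    block = V // K
    phi = np.full((K, V), (1.0 - spec.block_mass) / V)
    for k in range(K):
        lo, hi = k * block, (k + 1) * block if k < K - 1 else V
        inner = rng.dirichlet(np.ones(hi - lo))
        phi[k, lo:hi] += spec.block_mass * inner
    phi /= phi.sum(axis=1, keepdims=True)

    keywords: dict[str, list[str]] = {}
    phi_tilde = np.zeros((len(spec.keyword_topic_labels), V))
    for k, label in enumerate(spec.keyword_topic_labels):
        ids = np.arange(k * block, k * block + spec.n_keywords_per_topic)
        keywords[label] = [vocab[j] for j in ids]
        phi_tilde[k, ids] = 1.0 / len(ids)

    if spec.true_theta is not None:
        theta = np.asarray(spec.true_theta, dtype=float)
        if theta.shape != (spec.n_docs, K):
            raise ValueError("true_theta must have shape (n_docs, n_topics)")
    else:
        theta = rng.dirichlet(np.full(K, spec.theta_alpha), size=spec.n_docs)

    docs: list[Document] = []
    for d in range(spec.n_docs):
        n = max(int(rng.poisson(spec.doc_length_mean)), 10)
        zs = rng.choice(K, size=n, p=theta[d])
        words: list[str] = []
        for z in zs:
            if z < len(spec.keyword_topic_labels) and rng.random() < spec.pi_true:
                w = rng.choice(V, p=phi_tilde[z])
            else:
                w = rng.choice(V, p=phi[z])
            words.append(vocab[w])
        docs.append(Document(doc_id=f"D{d:04d}", text=" ".join(words)))

    theta_df = pd.DataFrame(
        theta, index=[d.doc_id for d in docs], columns=spec.topic_labels
    )
    return docs, theta_df, keywords


# ---------------------------------------------------------------------------
# scored corpus

#: Template sentences per category, assembled from the shipped cue lexicons
#: plus neutral words only, so the rubric recovers the planted category
#: exactly. core_term_count is the hand-counted number of core-term
#: occurrences per template (used for planted term-count truth).
_TEMPLATES: dict[tuple[str, str], tuple[str, int]] = {
    ("impact", "general"): ("The effects of climate change on health are noted here.", 1),
    ("impact", "specific"): ("The impacts of climate change on health include malaria and deaths.", 2),
    ("adaptation", "general"): ("The national adaptation plan includes the health sector.", 1),
    ("adaptation", "specific"): ("Adaptation measures will address the spread of malaria affecting health.", 2),
    ("adaptation", "detailed"): ("Adaptation includes strengthening surveillance and early warning systems for health.", 1),
    ("mitigation", "general"): ("Renewable energy measures will also benefit health.", 1),
    ("co_benefit", "general"): ("Clean cooking programmes bring co-benefits for health.", 1),
    ("co_benefit", "specific"): ("Clean cooking brings co-benefits for health and will save lives.", 2),
    ("trade_off", "general"): ("Limited fiscal space constrains spending on health and climate action.", 1),
    ("background", "general"): ("The country faces development challenges including poverty and poor health.", 1),
}


def category_templates() -> dict[tuple[str, str], str]:
    """The template sentence for each of the ten rubric categories."""
    return {k: v[0] for k, v in _TEMPLATES.items()}


def true_hes(categories: Sequence[tuple[str, str]]) -> int:
    """Ground-truth HES for a planted category set: max entry score plus one
    per additional thematic group, capped at 5 (0 when nothing is planted)."""
    if not categories:
        return 0
    max_entry = max(ENTRY_SCORES[c] for c in categories)
    groups = {g for g, _ in categories}
    return min(5, max_entry + len(groups) - 1)


@dataclass
class SyntheticScoredCorpusSpec:
    """Settings for corpora with planted health references.

    ``category_rates`` are the per-document probabilities that a mentioning
    document contains each category, patterned on the observed category mix
    (general adaptation the most common reference, specific co-benefits and
    trade-offs rare); ``any_mention_rate`` matches the observed 73% share of
    documents referring to health at all. ``planted_references`` overrides
    the random draw with an explicit per-document category list.
    ``planted_keyness`` injects (bigram, group, per-doc occurrences) plants,
    with group "target" = planted HES 0–1 and "reference" = HES 2–5.
    """

    n_docs: int = 185
    n_filler_sentences: int = 12
    n_theme_sentences: int = 6
    filler_sentence_length: int = 9
    any_mention_rate: float = 0.73
    category_rates: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("impact", "general"): 0.50,
            ("impact", "specific"): 0.30,
            ("adaptation", "general"): 0.46,
            ("adaptation", "specific"): 0.20,
            ("adaptation", "detailed"): 0.22,
            ("mitigation", "general"): 0.15,
            ("co_benefit", "general"): 0.18,
            ("co_benefit", "specific"): 0.08,
            ("trade_off", "general"): 0.08,
            ("background", "general"): 0.20,
        }
    )
    planted_references: Sequence[Sequence[tuple[str, str]]] | None = None
    planted_keyness: Sequence[tuple[str, str, int]] = ()

    def __post_init__(self) -> None:
        for cat in self.category_rates:
            if cat not in ENTRY_SCORES:
                raise ValueError(f"unknown category in category_rates: {cat}")
        if self.planted_references is not None:
            for cats in self.planted_references:
                for cat in cats:
                    if tuple(cat) not in ENTRY_SCORES:
                        raise ValueError(f"unknown planted category: {cat}")
            if len(self.planted_references) != self.n_docs:
                raise ValueError("planted_references must list one entry per document")
        for _, group, rate in self.planted_keyness:
            if group not in ("target", "reference"):
                raise ValueError("keyness plant group must be 'target' or 'reference'")
            if rate < 0:
                raise ValueError("keyness plant rate must be >= 0")


def gen_scored_corpus(
    spec: SyntheticScoredCorpusSpec, seed: int = 0
) -> tuple[list[Document], pd.DataFrame]:
    """Generate documents with planted health references.

    Returns (documents, truth frame) where the truth frame holds one row per
    document: ``doc_id, hes, any_mention, health_term_count`` plus one
    boolean column per category.
    """
    from .topic_model import load_keywords

    rng = np.random.default_rng(seed)
    vocab = background_vocabulary()
    # non-health theme vocabulary keeps the topic-model stage runnable on
    # these corpora; theme sentences carry no core health term, so they can
    # never register as health references
    themes = {k: v for k, v in load_keywords().items() if k != "health"}
    theme_labels = sorted(themes)
    docs: list[Document] = []
    rows = []
    for d in range(spec.n_docs):
        if spec.planted_references is not None:
            cats = [tuple(c) for c in spec.planted_references[d]]
        else:
            cats = []
            if rng.random() < spec.any_mention_rate:
                for cat, rate in spec.category_rates.items():
                    if rng.random() < min(rate / spec.any_mention_rate, 1.0):
                        cats.append(cat)
                if not cats:
                    cats = [("impact", "general")]  # a mentioning doc mentions something

        sentences = []
        for _ in range(spec.n_filler_sentences):
            words = rng.choice(len(vocab), size=spec.filler_sentence_length)
            sentences.append(" ".join(vocab[w] for w in words).capitalize() + ".")
        for _ in range(spec.n_theme_sentences):
            theme = theme_labels[rng.integers(len(theme_labels))]
            kws = rng.choice(themes[theme], size=2, replace=False)
            filler = [vocab[w] for w in rng.choice(len(vocab), size=4)]
            words = [kws[0], *filler[:2], kws[1], *filler[2:]]
            sentences.append(" ".join(words).capitalize() + ".")
        for cat in cats:
            sentences.append(_TEMPLATES[cat][0])

        hes = true_hes(cats)
        group = "target" if hes <= 1 else "reference"
        for feature, plant_group, rate in spec.planted_keyness:
            if plant_group == group and rate > 0:
                a, _, b = feature.partition("_")
                sentences.extend(f"{a.capitalize()} {b}." for _ in range(rate))

        order = rng.permutation(len(sentences))
        doc_id = f"D{d:04d}"
        docs.append(Document(doc_id=doc_id, text=" ".join(sentences[i] for i in order)))

        row: dict[str, object] = {
            "doc_id": doc_id,
            "hes": hes,
            "any_mention": hes >= 1,
            "health_term_count": sum(_TEMPLATES[c][1] for c in cats),
        }
        for cat in VALID_CATEGORIES:
            row[f"{cat[0]}/{cat[1]}"] = cat in cats
        rows.append(row)
    return docs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# covariate tables

#: Default true coefficients: the point estimates of the three fitted
#: country-level models (logistic any-mention, OLS HES, OLS HTP), with
#: intercepts chosen to give realistic base rates (any-mention ~0.73,
#: mean HES ~2, mean HTP ~0.1) under the default covariate distributions.
DEFAULT_TRUE_BETA: dict[str, dict[str, float]] = {
    "any_mention": {
        "const": -0.5, "log_population": 0.2, "sids": 3.6,
        "log_gdp_per_capita": -0.5, "democracy": -0.1,
        "health_expenditure_pct_gdp": -0.1, "coal_rents_pct_gdp": -0.1,
        "temp_change_weighted": 0.7, "pm25_exposure": 0.1,
    },
    "hes": {
        "const": 4.7, "log_population": 0.05, "sids": 0.9,
        "log_gdp_per_capita": -0.5, "democracy": 0.01,
        "health_expenditure_pct_gdp": -0.02, "coal_rents_pct_gdp": -0.5,
        "temp_change_weighted": 0.6, "pm25_exposure": 0.01,
    },
    "htp": {
        "const": 0.28, "log_population": -0.002, "sids": 0.1,
        "log_gdp_per_capita": -0.02, "democracy": -0.002,
        "health_expenditure_pct_gdp": -0.003, "coal_rents_pct_gdp": 0.01,
        "temp_change_weighted": 0.03, "pm25_exposure": 0.001,
    },
}


@dataclass
class SyntheticCovariateSpec:
    """Country covariates and outcomes simulated at known coefficients.

    Covariate distributions approximate world-scale magnitudes (log
    population around e^16 ≈ 9M people, log GDP per capita around e^8.5 ≈
    $4900, ~20% small-island states, PM2.5 around 27 µg/m³). The default
    missingness (rate 0.054 on the democracy score) leaves ~175 of 185
    countries complete, the listwise analysis sample of the study design.
    """

    n_countries: int = 185
    true_beta: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRUE_BETA.items()}
    )
    sids_prevalence: float = 0.2
    hes_noise_sd: float = 1.2
    htp_noise_sd: float = 0.05
    noise_model: str = "gaussian"  # "gaussian" | "heteroscedastic"
    heteroscedastic_col: str = "pm25_exposure"
    missing_rate: float = 0.054
    missing_columns: tuple[str, ...] = ("democracy",)

    def __post_init__(self) -> None:
        if not 0 <= self.sids_prevalence <= 1:
            raise ValueError("sids_prevalence must lie in [0, 1]")
        if self.hes_noise_sd <= 0 or self.htp_noise_sd <= 0:
            raise ValueError("noise SDs must be > 0")
        if self.noise_model not in ("gaussian", "heteroscedastic"):
            raise ValueError("noise_model must be 'gaussian' or 'heteroscedastic'")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


def _iso3_codes(n: int) -> list[str]:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    codes = ("".join(t) for t in itertools.product(letters, repeat=3))
    return list(itertools.islice(codes, n))


def gen_covariates(
    spec: SyntheticCovariateSpec, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Simulate a covariate table plus outcomes at the spec's coefficients.

    Returns (table, truth). The table has NaNs where missingness applies;
    ``truth`` carries the true betas, the complete (pre-missingness) table
    and the latent linear predictors.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_countries
    cov = pd.DataFrame(
        {
            "iso3": _iso3_codes(n),
            "log_population": rng.normal(16.0, 2.0, n),
            "sids": (rng.random(n) < spec.sids_prevalence).astype(int),
            "log_gdp_per_capita": rng.normal(8.5, 1.2, n),
            "democracy": np.clip(rng.normal(5.0, 3.0, n), 0, 10),
            "health_expenditure_pct_gdp": np.clip(rng.normal(6.5, 2.7, n), 0.5, None),
            "coal_rents_pct_gdp": rng.exponential(0.3, n),
            "temp_change_weighted": rng.normal(0.5, 0.3, n),
            "pm25_exposure": np.clip(rng.normal(27.0, 17.0, n), 3.0, None),
        }
    )

    def linpred(model: str) -> np.ndarray:
        beta = spec.true_beta[model]
        eta = np.full(n, float(beta.get("const", 0.0)))
        for col, b in beta.items():
            if col != "const":
                eta += float(b) * cov[col].to_numpy()
        return eta

    eta_any = linpred("any_mention")
    p_any = 1.0 / (1.0 + np.exp(-eta_any))
    any_mention = (rng.random(n) < p_any).astype(int)

    if spec.noise_model == "heteroscedastic":
        x = cov[spec.heteroscedastic_col].to_numpy()
        z = (x - x.mean()) / x.std()
        scale = np.abs(z) + 0.1  # floor keeps every variance positive
    else:
        scale = np.ones(n)
    eta_hes = linpred("hes")
    hes = eta_hes + rng.normal(0.0, spec.hes_noise_sd, n) * scale
    eta_htp = linpred("htp")
    htp = np.clip(eta_htp + rng.normal(0.0, spec.htp_noise_sd, n) * scale, 0.0, 1.0)

    table = cov.copy()
    table["any_mention"] = any_mention
    table["hes"] = hes
    table["htp"] = htp

    complete = table.copy()
    for col in spec.missing_columns:
        mask = rng.random(n) < spec.missing_rate
        table.loc[mask, col] = np.nan

    truth = {
        "true_beta": {k: dict(v) for k, v in spec.true_beta.items()},
        "complete": complete,
        "linear_predictors": {"any_mention": eta_any, "hes": eta_hes, "htp": eta_htp},
        "p_any_mention": p_any,
    }
    return table, truth
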