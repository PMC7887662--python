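"""Keyword-assisted topic model (keyATM) fitted by collapsed Gibbs sampling.

The model is latent Dirichlet allocation augmented with keyword topics: a
small set of topics (here health, economics, energy, agriculture by default)
each seeded with a keyword list. A token assigned to keyword topic ``k`` is
drawn either from a keyword-restricted distribution φ̃_k (with topic-specific
probability π_k) or from the topic's regular distribution φ_k. The priors are

    θ_d ~ Dirichlet(α),  φ_k ~ Dirichlet(β),  φ̃_k ~ Dirichlet(β̃),
    π_k ~ Beta(γ₁, γ₂),

all integrated out in the sampler, which sweeps the per-token topic
assignment and keyword/regular switch. With no keyword topics the model
reduces exactly to collapsed-Gibbs LDA.

The health topic proportion (HTP) of a document is its posterior-mean θ mass
on the health topic — the package's breadth measure of health engagement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._gibbs import sweep
from .corpus_io import DocumentFeatureMatrix

__all__ = [
    "KeyATMSpec",
    "KeywordTopicModel",
    "KeywordTopicResults",
    "HtpResult",
    "fit_keyatm",
    "compute_htp",
    "topic_histogram",
    "load_keywords",
]


def load_keywords(path=None) -> dict[str, list[str]]:
    """Topic keyword lists from a YAML file (shipped defaults when ``path``
    is None): a mapping of topic label -> term list."""
    import yaml
    from importlib import resources
    from pathlib import Path

    if path is None:
        text = resources.files("ndchealth.data").joinpath("topic_keywords.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    payload = yaml.safe_load(text)
    if not isinstance(payload, dict) or not payload:
        raise ValueError("keyword file must map topic labels to term lists")
    return {str(k): [str(w) for w in v] for k, v in payload.items()}


@dataclass
class KeyATMSpec:
    """Hyperparameters and sampler settings.

    ``keyword_topics`` maps topic label -> keyword list (order fixes topic
    indices); ``n_residual_topics`` unkeyed topics absorb remaining content.
    Concentrations: ``alpha`` (document-topic), ``beta`` (regular word),
    ``beta_tilde`` (keyword word), ``gamma`` (Beta prior on the switch).
    """

    keyword_topics: Mapping[str, Sequence[str]] = field(default_factory=dict)
    n_residual_topics: int = 2
    alpha: float = 0.1
    beta: float = 0.01
    beta_tilde: float = 0.1
    gamma: tuple[float, float] = (1.0, 1.0)
    n_iterations: int = 1500
    n_burnin: int = 500
    thin: int = 5

    def __post_init__(self) -> None:
        if self.n_residual_topics < 0:
            raise ValueError("n_residual_topics must be >= 0")
        if self.n_topics == 0:
            raise ValueError("model needs at least one topic")
        for label, words in self.keyword_topics.items():
            if not list(words):
                raise ValueError(f"keyword topic {label!r} has an empty keyword list")
        flat = [w for ws in self.keyword_topics.values() for w in ws]
        if len(flat) != len(set(flat)):
            dupes = sorted({w for w in flat if flat.count(w) > 1})
            raise ValueError(f"keywords shared between topics are not allowed: {dupes}")
        for name in ("alpha", "beta", "beta_tilde"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.gamma[0] <= 0 or self.gamma[1] <= 0:
            raise ValueError("gamma shapes must be > 0")
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be >= 1")
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ValueError("n_burnin must lie in [0, n_iterations)")

    @property
    def n_topics(self) -> int:
        return len(self.keyword_topics) + self.n_residual_topics

    @property
    def topic_labels(self) -> list[str]:
        return list(self.keyword_topics) + [
            f"residual_{i + 1}" for i in range(self.n_residual_topics)
        ]


@dataclass(frozen=True)
class HtpResult:
    doc_id: str
    htp: float


class KeywordTopicModel:
    """Model object binding a unigram DFM to a :class:`KeyATMSpec`.

    ``fit(seed)`` runs the collapsed Gibbs sampler and returns a
    :class:`KeywordTopicResults`.
    """

    def __init__(self, dfm: DocumentFeatureMatrix, spec: KeyATMSpec | None = None):
        if len(dfm.features) == 0:
            raise ValueError("empty vocabulary")
        self.dfm = dfm
        self.spec = spec or KeyATMSpec()
        self.vocab = list(dfm.features)
        self._vindex = {w: j for j, w in enumerate(self.vocab)}

        # resolve keywords against the vocabulary
        self.keyword_ids: list[np.ndarray] = []
        for label, words in self.spec.keyword_topics.items():
            present = [w for w in words if w in self._vindex]
            absent = sorted(set(words) - set(present))
            if not present:
                raise ValueError(
                    f"no keyword of topic {label!r} occurs in the vocabulary"
                )
            if absent:
                warnings.warn(
                    f"dropping absent keywords for topic {label!r}: {absent}",
                    stacklevel=2,
                )
            self.keyword_ids.append(
                np.array(sorted(self._vindex[w] for w in present), dtype=np.int64)
            )

    def fit(self, seed: int = 0) -> "KeywordTopicResults":
        spec = self.spec
        K = spec.n_topics
        K_kw = len(spec.keyword_topics)
        V = len(self.vocab)
        counts = self.dfm.counts
        D = counts.shape[0]

        # token-level representation
        doc_of = np.repeat(
            np.arange(D, dtype=np.int64), counts.sum(axis=1)
        )
        word_of = np.concatenate(
            [np.repeat(np.arange(V, dtype=np.int64), counts[d]) for d in range(D)]
        )
        N = doc_of.shape[0]
        if N == 0:
            raise ValueError("corpus contains no tokens")

        is_kw = np.zeros((max(K_kw, 1), V), dtype=np.bool_)
        n_keywords = np.zeros(max(K_kw, 1), dtype=np.float64)
        for k, ids in enumerate(self.keyword_ids):
            is_kw[k, ids] = True
            n_keywords[k] = len(ids)

        # anchored initialization: keyword tokens start in their keyword
        # topic with the switch on, which pins topic labels from sweep one
        rng = np.random.default_rng(seed)
        z = rng.integers(0, K, size=N).astype(np.int64)
        s = np.zeros(N, dtype=np.int64)
        for k in range(K_kw):
            anchored = is_kw[k, word_of]
            z[anchored] = k
            s[anchored] = 1

        n_dk = np.zeros((D, K), dtype=np.float64)
        n_kw_ = np.zeros((K, V), dtype=np.float64)
        n_k = np.zeros(K, dtype=np.float64)
        m_kw = np.zeros((K, V), dtype=np.float64)
        m_k = np.zeros(K, dtype=np.float64)
        np.add.at(n_dk, (doc_of, z), 1.0)
        reg = s == 0
        np.add.at(n_kw_, (z[reg], word_of[reg]), 1.0)
        np.add.at(n_k, z[reg], 1.0)
        np.add.at(m_kw, (z[~reg], word_of[~reg]), 1.0)
        np.add.at(m_k, z[~reg], 1.0)

        nd = counts.sum(axis=1).astype(np.float64)
        theta_acc = np.zeros((D, K))
        phi_acc = np.zeros((K, V))
        phi_t_acc = np.zeros((max(K_kw, 1), V))
        pi_acc = np.zeros(max(K_kw, 1))
        n_samples = 0
        ll_trace = np.empty(spec.n_iterations)

        g1, g2 = spec.gamma
        for it in range(spec.n_iterations):
            u = rng.random(N)
            sweep(
                doc_of, word_of, z, s,
                n_dk, n_kw_, n_k, m_kw, m_k,
                is_kw, n_keywords,
                spec.alpha, spec.beta, spec.beta_tilde, g1, g2,
                K_kw, u,
            )
            ll_trace[it] = self._log_likelihood(
                n_dk, n_kw_, n_k, m_kw, m_k, n_keywords, nd, K_kw
            )
            if it >= spec.n_burnin and (it - spec.n_burnin) % spec.thin == 0:
                n_samples += 1
                theta_acc += (n_dk + spec.alpha) / (nd[:, None] + K * spec.alpha)
                phi_acc += (n_kw_ + spec.beta) / (n_k[:, None] + V * spec.beta)
                for k in range(K_kw):
                    denom = m_k[k] + n_keywords[k] * spec.beta_tilde
                    row = np.where(is_kw[k], m_kw[k] + spec.beta_tilde, 0.0)
                    phi_t_acc[k] += row / denom
                    pi_acc[k] += (m_k[k] + g1) / (m_k[k] + n_k[k] + g1 + g2)

        theta = theta_acc / n_samples
        phi = phi_acc / n_samples
        phi_tilde = phi_t_acc[:K_kw] / n_samples if K_kw else np.zeros((0, V))
        pi = pi_acc[:K_kw] / n_samples if K_kw else np.zeros(0)

        return KeywordTopicResults(
            model=self,
            theta=pd.DataFrame(theta, index=self.dfm.doc_ids, columns=spec.topic_labels),
            phi=pd.DataFrame(phi, index=spec.topic_labels, columns=self.vocab),
            phi_tilde=pd.DataFrame(
                phi_tilde, index=spec.topic_labels[:K_kw], columns=self.vocab
            ),
            pi=pd.Series(pi, index=spec.topic_labels[:K_kw], name="pi"),
            log_likelihood_trace=ll_trace,
            assignments=z.copy(),
            switches=s.copy(),
            seed=seed,
        )

    def _log_likelihood(self, n_dk, n_kw_, n_k, m_kw, m_k, n_keywords, nd, K_kw) -> float:
        """Collapsed joint log p(w, z, s) under the integrated-out priors."""
        spec = self.spec
        K = spec.n_topics
        V = len(self.vocab)
        a, b, bt = spec.alpha, spec.beta, spec.beta_tilde
        g1, g2 = spec.gamma
        ll = float(
            np.sum(gammaln(K * a) - gammaln(nd + K * a))
            + np.sum(gammaln(n_dk + a) - gammaln(a))
        )
        ll += float(
            np.sum(gammaln(V * b) - gammaln(n_k + V * b))
            + np.sum(gammaln(n_kw_ + b) - gammaln(b))
        )
        for k in range(K_kw):
            ids = self.keyword_ids[k]
            L = n_keywords[k]
            ll += float(
                gammaln(L * bt) - gammaln(m_k[k] + L * bt)
                + np.sum(gammaln(m_kw[k, ids] + bt) - gammaln(bt))
            )
            tot = m_k[k] + n_k[k]
            ll += float(
                gammaln(g1 + g2) - gammaln(tot + g1 + g2)
                + gammaln(m_k[k] + g1) - gammaln(g1)
                + gammaln(n_k[k] + g2) - gammaln(g2)
            )
        return ll


@dataclass
class KeywordTopicResults:
    """Posterior summaries of a fitted keyword topic model."""

    model: KeywordTopicModel
    theta: pd.DataFrame            # D x K document-topic proportions
    phi: pd.DataFrame              # K x V regular word distributions
    phi_tilde: pd.DataFrame        # keyword topics x V, supported on keywords
    pi: pd.Series                  # per keyword topic switch probability
    log_likelihood_trace: np.ndarray
    assignments: np.ndarray        # final-sweep token topic assignments
    switches: np.ndarray
    seed: int

    @property
    def topic_labels(self) -> list[str]:
        return list(self.theta.columns)

    def htp(self, health_label: str = "health") -> pd.Series:
        """Health topic proportion per document: θ[d, health]."""
        if health_label not in self.theta.columns:
            raise KeyError(f"no topic labelled {health_label!r} in the fit")
        return self.theta[health_label].rename("htp")

    def word_distribution(self, label: str) -> pd.Series:
        """Blended p(w | topic): π φ̃ + (1-π) φ for keyword topics, φ otherwise."""
        if label not in self.theta.columns:
            raise KeyError(f"unknown topic {label!r}")
        if label in self.phi_tilde.index:
            p = float(self.pi[label])
            return p * self.phi_tilde.loc[label] + (1 - p) * self.phi.loc[label]
        return self.phi.loc[label]

    def keyword_mass(self, label: str) -> float:
        """Probability mass the blended topic distribution puts on its keywords."""
        k = self.topic_labels.index(label)
        ids = self.model.keyword_ids[k]
        return float(self.word_distribution(label).iloc[ids].sum())

    def top_words(self, n: int = 20) -> pd.DataFrame:
        """Top-``n`` words per topic by blended probability."""
        cols = {}
        for label in self.topic_labels:
            dist = self.word_distribution(label)
            cols[label] = dist.sort_values(ascending=False).head(n).index.tolist()
        return pd.DataFrame(cols)

    def topic_histogram(self, bin_width: float = 0.1) -> pd.DataFrame:
        return topic_histogram(self, bin_width)

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Keyword-assisted topic model (collapsed Gibbs)",
            "=" * 46,
            f"documents: {self.theta.shape[0]}   vocabulary: {self.phi.shape[1]}",
            f"topics: {spec.n_topics} ({len(spec.keyword_topics)} keyword + "
            f"{spec.n_residual_topics} residual)",
            f"iterations: {spec.n_iterations} (burn-in {spec.n_burnin}, "
            f"thin {spec.thin}), seed {self.seed}",
            f"final log-likelihood: {self.log_likelihood_trace[-1]:.1f}",
            "",
            "topic      mean θ   π (keyword share)   keyword mass",
        ]
        for label in self.topic_labels:
            mean_t = self.theta[label].mean()
            if label in self.phi_tilde.index:
                pi = f"{self.pi[label]:.3f}"
                km = f"{self.keyword_mass(label):.3f}"
            else:
                pi = km = "  -  "
            lines.append(f"{label:<12} {mean_t:6.3f}   {pi:>8}          {km:>8}")
        return "\n".join(lines)


def fit_keyatm(
    dfm: DocumentFeatureMatrix, spec: KeyATMSpec, seed: int = 0
) -> KeywordTopicResults:
    """Fit the keyword-assisted topic model on a unigram DFM."""
    return KeywordTopicModel(dfm, spec).fit(seed=seed)


def compute_htp(
    fit: KeywordTopicResults, health_label: str = "health"
) -> list[HtpResult]:
    """One :class:`HtpResult` per document, read off θ."""
    series = fit.htp(health_label)
    return [HtpResult(doc_id=str(d), htp=float(v)) for d, v in series.items()]


def topic_histogram(fit: KeywordTopicResults, bin_width: float = 0.1) -> pd.DataFrame:
    """Binned document counts of topic proportions (counts sum to D per topic)."""
    if not 0 < bin_width <= 1:
        raise ValueError("bin_width must lie in (0, 1]")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    out = {}
    for label in fit.topic_labels:
        counts, _ = np.histogram(fit.theta[label].to_numpy(), bins=edges)
        out[label] = counts
    return pd.DataFrame(out, index=pd.Index(edges[:-1].round(10), name="bin_left"))
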