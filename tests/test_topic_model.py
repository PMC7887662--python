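"""Keyword-assisted topic model: sampler correctness and invariants."""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln, logsumexp

from ndchealth.corpus_io import DocumentFeatureMatrix, build_dfm, tokenize
from ndchealth.synthetic import SyntheticCorpusSpec, gen_topic_corpus
from ndchealth.topic_model import (
    KeyATMSpec,
    KeywordTopicModel,
    compute_htp,
    fit_keyatm,
    load_keywords,
    topic_histogram,
)


def _tokenize_all(docs):
    return [tokenize(d) for d in docs]


def lda_enumeration_posterior_theta(dfm, alpha, beta, K):
    """Exact LDA posterior mean of θ by enumerating all K^N token assignments.

    Independent oracle: evaluates the collapsed joint p(w, z) in closed form
    (ratios of gamma functions from the Dirichlet-multinomial marginals) for
    every assignment and averages θ̂(z) under the exact posterior.
    """
    counts = dfm.counts
    D, V = counts.shape
    doc_of = np.repeat(np.arange(D), counts.sum(axis=1))
    word_of = np.concatenate([np.repeat(np.arange(V), counts[d]) for d in range(D)])
    N = len(doc_of)
    nd = counts.sum(axis=1)

    log_ws = []
    theta_hats = []
    for z in itertools.product(range(K), repeat=N):
        z = np.asarray(z)
        n_dk = np.zeros((D, K))
        n_kw = np.zeros((K, V))
        np.add.at(n_dk, (doc_of, z), 1)
        np.add.at(n_kw, (z, word_of), 1)
        n_k = n_kw.sum(axis=1)
        lj = (
            np.sum(gammaln(K * alpha) - gammaln(nd + K * alpha))
            + np.sum(gammaln(n_dk + alpha) - gammaln(alpha))
            + np.sum(gammaln(V * beta) - gammaln(n_k + V * beta))
            + np.sum(gammaln(n_kw + beta) - gammaln(beta))
        )
        log_ws.append(lj)
        theta_hats.append((n_dk + alpha) / (nd[:, None] + K * alpha))
    log_ws = np.asarray(log_ws)
    w = np.exp(log_ws - logsumexp(log_ws))
    return np.tensordot(w, np.asarray(theta_hats), axes=1)


class TestSpecValidation:
    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError, match="n_iterations"):
            KeyATMSpec(n_iterations=0)

    def test_duplicate_keywords_across_topics_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            KeyATMSpec(keyword_topics={"a": ["x"], "b": ["x"]})

    def test_empty_keyword_list_rejected(self):
        with pytest.raises(ValueError, match="empty keyword list"):
            KeyATMSpec(keyword_topics={"a": []})

    def test_burnin_must_precede_end(self):
        with pytest.raises(ValueError, match="n_burnin"):
            KeyATMSpec(n_iterations=100, n_burnin=100)

    def test_all_keywords_absent_names_the_topic(self, make_tokenized):
        dfm = build_dfm([make_tokenized("solar wind", "A")], 1)
        spec = KeyATMSpec(keyword_topics={"health": ["malaria"]}, n_residual_topics=1)
        with pytest.raises(ValueError, match="health"):
            KeywordTopicModel(dfm, spec)

    def test_absent_keywords_dropped_with_warning(self, make_tokenized):
        dfm = build_dfm([make_tokenized("health solar", "A")], 1)
        spec = KeyATMSpec(keyword_topics={"health": ["health", "malaria"]},
                          n_residual_topics=1)
        with pytest.warns(UserWarning, match="malaria"):
            KeywordTopicModel(dfm, spec)


class TestDegenerateCases:
    def test_single_document_single_topic_theta_is_one(self, make_tokenized):
        dfm = build_dfm([make_tokenized("solar wind solar", "A")], 1)
        spec = KeyATMSpec(n_residual_topics=1, n_iterations=20, n_burnin=5)
        fit = KeywordTopicModel(dfm, spec).fit(seed=0)
        assert fit.theta.to_numpy().ravel() == pytest.approx([1.0])

    def test_single_token_log_likelihood_closed_form(self):
        # one token over a 3-word vocabulary, K=1: collapsed p(w) = 1/V
        dfm = DocumentFeatureMatrix(["A"], ["a", "b", "c"], np.array([[1, 0, 0]]))
        spec = KeyATMSpec(n_residual_topics=1, n_iterations=5, n_burnin=1)
        fit = KeywordTopicModel(dfm, spec).fit(seed=0)
        assert fit.log_likelihood_trace == pytest.approx(np.log(1 / 3))

    def test_matches_brute_force_enumeration_lda(self):
        # 7 tokens, V=3, K=2: 128 assignments enumerated exactly
        dfm = DocumentFeatureMatrix(
            ["A", "B"], ["a", "b", "c"], np.array([[2, 1, 0], [1, 0, 3]])
        )
        alpha, beta, K = 0.5, 0.5, 2
        exact = lda_enumeration_posterior_theta(dfm, alpha, beta, K)
        spec = KeyATMSpec(
            keyword_topics={}, n_residual_topics=K, alpha=alpha, beta=beta,
            n_iterations=6000, n_burnin=1000, thin=1,
        )
        fit = KeywordTopicModel(dfm, spec).fit(seed=123)
        assert np.abs(fit.theta.to_numpy() - exact).max() < 0.02


class TestFitInvariants:
    @pytest.fixture(scope="class")
    def small_fit(self):
        docs, theta, kw = gen_topic_corpus(
            SyntheticCorpusSpec(n_docs=30, doc_length_mean=60, vocab_size=120),
            seed=5,
        )
        dfm = build_dfm(_tokenize_all(docs), 1, min_doc_frequency=1)
        spec = KeyATMSpec(keyword_topics=kw, n_iterations=150, n_burnin=50)
        return KeywordTopicModel(dfm, spec).fit(seed=9)

    def test_theta_rows_are_simplices(self, small_fit):
        assert small_fit.theta.to_numpy().sum(axis=1) == pytest.approx(1.0)
        assert (small_fit.theta.to_numpy() >= 0).all()

    def test_phi_rows_are_simplices(self, small_fit):
        assert small_fit.phi.to_numpy().sum(axis=1) == pytest.approx(1.0)

    def test_phi_tilde_supported_on_keywords_only(self, small_fit):
        for k, label in enumerate(small_fit.phi_tilde.index):
            row = small_fit.phi_tilde.loc[label].to_numpy()
            ids = small_fit.model.keyword_ids[k]
            mask = np.zeros(len(row), dtype=bool)
            mask[ids] = True
            assert row[~mask] == pytest.approx(0.0)
            assert row.sum() == pytest.approx(1.0)

    def test_pi_in_unit_interval(self, small_fit):
        assert ((small_fit.pi >= 0) & (small_fit.pi <= 1)).all()

    def test_likelihood_trace_improves(self, small_fit):
        trace = small_fit.log_likelihood_trace
        assert trace[-50:].mean() > trace[:10].mean()

    def test_summary_mentions_topics(self, small_fit):
        text = small_fit.summary()
        assert "health" in text and "residual_1" in text


class TestDeterminismAndSeparation:
    def test_identical_seed_identical_fit(self):
        docs, _, kw = gen_topic_corpus(
            SyntheticCorpusSpec(n_docs=15, doc_length_mean=40, vocab_size=90), seed=2
        )
        dfm = build_dfm(_tokenize_all(docs), 1)
        spec = KeyATMSpec(keyword_topics=kw, n_iterations=80, n_burnin=20)
        f1 = KeywordTopicModel(dfm, spec).fit(seed=77)
        f2 = KeywordTopicModel(dfm, spec).fit(seed=77)
        assert (f1.assignments == f2.assignments).all()
        assert np.array_equal(f1.log_likelihood_trace, f2.log_likelihood_trace)
        assert f1.theta.equals(f2.theta)

    def test_well_separated_topics_recovered(self):
        # two disjoint vocabularies, documents drawn from one topic each
        rng = np.random.default_rng(3)
        vocab_a = [f"aa{c}" for c in "bcdfghjklm"]
        vocab_b = [f"bb{c}" for c in "bcdfghjklm"]
        rows, ids, truth = [], [], []
        for i in range(60):
            topic = i % 2
            words = rng.choice(vocab_a if topic == 0 else vocab_b, size=40)
            rows.append(" ".join(words))
            ids.append(f"D{i:03d}")
            truth.append(topic)
        from ndchealth.corpus_io import Document

        dfm = build_dfm(
            [tokenize(Document(i, t)) for i, t in zip(ids, rows)], 1
        )
        spec = KeyATMSpec(
            keyword_topics={"alpha": vocab_a[:3], "beta": vocab_b[:3]},
            n_residual_topics=0, n_iterations=200, n_burnin=50,
        )
        fit = KeywordTopicModel(dfm, spec).fit(seed=4)
        dominant = fit.theta.to_numpy().argmax(axis=1)
        agreement = (dominant == np.array(truth)).mean()
        assert agreement >= 0.95


class TestKeywordEffect:
    def test_keyword_channel_concentrates_mass(self):
        """The defining keyATM property: seeding keywords gives the keyed
        topic more mass on its keywords than any topic of an unkeyed LDA."""
        docs, _, kw = gen_topic_corpus(
            SyntheticCorpusSpec(
                n_docs=60, doc_length_mean=80, vocab_size=180,
                keyword_topic_labels=("health",), n_residual_topics=2,
            ),
            seed=8,
        )
        dfm = build_dfm(_tokenize_all(docs), 1)
        keyed = KeywordTopicModel(
            dfm, KeyATMSpec(keyword_topics=kw, n_residual_topics=2,
                            n_iterations=200, n_burnin=50)
        ).fit(seed=21)
        plain = KeywordTopicModel(
            dfm, KeyATMSpec(keyword_topics={}, n_residual_topics=3,
                            n_iterations=200, n_burnin=50)
        ).fit(seed=21)
        kw_ids = keyed.model.keyword_ids[0]
        lda_best = max(
            plain.phi.iloc[k].iloc[kw_ids].sum() for k in range(3)
        )
        assert keyed.keyword_mass("health") > lda_best


class TestHtpAndHistogram:
    def _fit(self):
        docs, theta, kw = gen_topic_corpus(
            SyntheticCorpusSpec(n_docs=25, doc_length_mean=50, vocab_size=120), seed=6
        )
        dfm = build_dfm(_tokenize_all(docs), 1)
        spec = KeyATMSpec(keyword_topics=kw, n_iterations=100, n_burnin=30)
        return fit_keyatm(dfm, spec, seed=2)

    def test_htp_reads_theta_directly(self):
        fit = self._fit()
        results = compute_htp(fit, "health")
        assert len(results) == 25
        for r in results:
            assert r.htp == pytest.approx(float(fit.theta.loc[r.doc_id, "health"]))
            assert 0 <= r.htp <= 1

    def test_unknown_label_is_an_error(self):
        fit = self._fit()
        with pytest.raises(KeyError, match="nosuch"):
            fit.htp("nosuch")

    def test_histogram_counts_conserve_documents(self):
        fit = self._fit()
        hist = topic_histogram(fit, 0.1)
        assert (hist.sum(axis=0) == 25).all()

    def test_histogram_low_mass_lands_in_first_bin(self):
        theta = pd.DataFrame(
            {"health": np.linspace(0.01, 0.09, 10), "residual_1": 0.5},
        )

        class FakeFit:
            topic_labels = ["health", "residual_1"]

        fake = FakeFit()
        fake.theta = theta
        hist = topic_histogram(fake, 0.1)
        assert hist["health"].iloc[0] == 10

    def test_invalid_bin_width(self):
        fit = self._fit()
        with pytest.raises(ValueError, match="bin_width"):
            topic_histogram(fit, 0.0)


def test_default_keyword_lists_load_and_are_disjoint():
    kw = load_keywords()
    assert set(kw) == {"health", "economics", "energy", "agriculture"}
    flat = [w for ws in kw.values() for w in ws]
    assert len(flat) == len(set(flat))
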