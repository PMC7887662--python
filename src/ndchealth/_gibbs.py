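"""Collapsed Gibbs sweep for the keyword-assisted topic model.

One sweep resamples every token's topic assignment ``z`` and, for tokens in
keyword topics, the keyword/regular switch ``s``, with the document-topic,
topic-word and switch probabilities integrated out. The kernel is
JIT-compiled with numba when available; the identical pure-Python function is
used otherwise. Uniform variates are drawn outside the kernel, so results
are bitwise-identical across the two paths given the same seed.
"""

from __future__ import annotations

import numpy as np


def _sweep_py(
    doc_of, word_of, z, s,
    n_dk, n_kw, n_k, m_kw, m_k,
    is_kw, n_keywords,
    alpha, beta, beta_tilde, gamma1, gamma2,
    n_keyword_topics, u,
):
    N = doc_of.shape[0]
    K = n_k.shape[0]
    V = n_kw.shape[1]
    probs = np.empty(2 * K)
    for i in range(N):
        d = doc_of[i]
        w = word_of[i]
        zi = z[i]
        n_dk[d, zi] -= 1
        if s[i] == 1:
            m_kw[zi, w] -= 1
            m_k[zi] -= 1
        else:
            n_kw[zi, w] -= 1
            n_k[zi] -= 1

        total = 0.0
        last_pos = 0
        for k in range(K):
            a = n_dk[d, k] + alpha
            if k < n_keyword_topics:
                t0 = n_k[k]
                t1 = m_k[k]
                denom = t0 + t1 + gamma1 + gamma2
                p0 = a * (t0 + gamma2) / denom * (n_kw[k, w] + beta) / (t0 + V * beta)
                if is_kw[k, w]:
                    p1 = (
                        a * (t1 + gamma1) / denom
                        * (m_kw[k, w] + beta_tilde)
                        / (t1 + n_keywords[k] * beta_tilde)
                    )
                else:
                    p1 = 0.0
            else:
                p0 = a * (n_kw[k, w] + beta) / (n_k[k] + V * beta)
                p1 = 0.0
            probs[2 * k] = p0
            probs[2 * k + 1] = p1
            if p0 > 0.0:
                last_pos = 2 * k
            if p1 > 0.0:
                last_pos = 2 * k + 1
            total += p0 + p1

        r = u[i] * total
        acc = 0.0
        pick = last_pos  # guard against r > total from rounding
        for j in range(2 * K):
            acc += probs[j]
            if r <= acc:
                pick = j
                break
        k_new = pick // 2
        s_new = pick % 2
        z[i] = k_new
        s[i] = s_new
        n_dk[d, k_new] += 1
        if s_new == 1:
            m_kw[k_new, w] += 1
            m_k[k_new] += 1
        else:
            n_kw[k_new, w] += 1
            n_k[k_new] += 1


try:  # pragma: no cover - exercised implicitly by the fit tests
    from numba import njit

    sweep = njit(cache=True)(_sweep_py)
except ImportError:  # pragma: no cover
    sweep = _sweep_py
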