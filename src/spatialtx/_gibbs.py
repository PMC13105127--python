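"""Collapsed Gibbs sampling kernels for LDA, JIT-compiled with numba.

Single-threaded on purpose: determinism under a fixed seed is a contract.
Token arrays are flat per-occurrence (document id, word id) pairs.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_fit(doc, word, n_docs, n_words, n_topics, alpha, beta, n_iter, burnin, seed):
    """Run collapsed Gibbs; return topic-count accumulators over post-burnin sweeps.

    Returns (acc_doc_topic, acc_word_topic, n_samples) where the accumulators
    sum the count matrices over the ``n_iter - burnin`` retained sweeps.
    """
    np.random.seed(seed)
    n_tokens = doc.shape[0]
    z = np.empty(n_tokens, dtype=np.int64)
    ndk = np.zeros((n_docs, n_topics), dtype=np.int64)
    nwk = np.zeros((n_words, n_topics), dtype=np.int64)
    nk = np.zeros(n_topics, dtype=np.int64)
    for t in range(n_tokens):
        k = np.random.randint(0, n_topics)
        z[t] = k
        ndk[doc[t], k] += 1
        nwk[word[t], k] += 1
        nk[k] += 1

    acc_ndk = np.zeros((n_docs, n_topics), dtype=np.float64)
    acc_nwk = np.zeros((n_words, n_topics), dtype=np.float64)
    n_samples = 0
    p = np.empty(n_topics, dtype=np.float64)
    wbeta = n_words * beta
    for it in range(n_iter):
        for t in range(n_tokens):
            d = doc[t]
            w = word[t]
            k = z[t]
            ndk[d, k] -= 1
            nwk[w, k] -= 1
            nk[k] -= 1
            total = 0.0
            for kk in range(n_topics):
                p[kk] = (ndk[d, kk] + alpha) * (nwk[w, kk] + beta) / (nk[kk] + wbeta)
                total += p[kk]
            u = np.random.random() * total
            cum = 0.0
            knew = n_topics - 1
            for kk in range(n_topics):
                cum += p[kk]
                if u < cum:
                    knew = kk
                    break
            z[t] = knew
            ndk[d, knew] += 1
            nwk[w, knew] += 1
            nk[knew] += 1
        if it >= burnin:
            acc_ndk += ndk
            acc_nwk += nwk
            n_samples += 1
    return acc_ndk, acc_nwk, n_samples


@njit(cache=True)
def gibbs_fold_in(doc, word, n_docs, phi, alpha, n_iter, burnin, seed):
    """Sample topic assignments for held-out documents with phi fixed.

    ``phi`` is the fitted (n_words, n_topics) word-topic matrix.  Returns the
    accumulated document-topic counts over post-burnin sweeps and the sample
    count, from which a held-out theta can be estimated.
    """
    np.random.seed(seed)
    n_topics = phi.shape[1]
    n_tokens = doc.shape[0]
    z = np.empty(n_tokens, dtype=np.int64)
    ndk = np.zeros((n_docs, n_topics), dtype=np.int64)
    for t in range(n_tokens):
        k = np.random.randint(0, n_topics)
        z[t] = k
        ndk[doc[t], k] += 1

    acc = np.zeros((n_docs, n_topics), dtype=np.float64)
    n_samples = 0
    p = np.empty(n_topics, dtype=np.float64)
    for it in range(n_iter):
        for t in range(n_tokens):
            d = doc[t]
            w = word[t]
            k = z[t]
            ndk[d, k] -= 1
            total = 0.0
            for kk in range(n_topics):
                p[kk] = (ndk[d, kk] + alpha) * phi[w, kk]
                total += p[kk]
            u = np.random.random() * total
            cum = 0.0
            knew = n_topics - 1
            for kk in range(n_topics):
                cum += p[kk]
                if u < cum:
                    knew = kk
                    break
            z[t] = knew
            ndk[d, knew] += 1
        if it >= burnin:
            acc += ndk
            n_samples += 1
    return acc, n_samples
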