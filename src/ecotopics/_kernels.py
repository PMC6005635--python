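"""Numba kernels for the collapsed Gibbs sweeps.

The kernels operate on flat token arrays sorted by sample: tokens of sample
``d`` occupy ``start[d]:start[d+1]``.  They mutate the count matrices and
assignment arrays in place and draw all randomness from numba's own stream,
seeded explicitly at entry, so a sweep is a pure function of (state, seed).
The Python-level single-token operations in :mod:`ecotopics.corrlda`
implement the identical conditionals and are cross-checked against these
kernels in the test-suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_sweeps(
    n_sweeps,
    seed,
    seq_start,
    seq_genus,
    seq_topic,
    word_start,
    word_type,
    word_topic,
    Nzd,
    Nzw,
    Nz,
    Mzd,
    Mzt,
    Mz,
    alpha,
    beta,
    gamma,
    accum_seq,
    accum_word,
    burn_in,
    accumulate,
):
    """Run ``n_sweeps`` collapsed Gibbs sweeps in place.

    Within each sample all sequence tokens are resampled first, then all
    word tokens.  When ``accumulate`` is true, per-token topic draws after
    ``burn_in`` sweeps are tallied into ``accum_seq`` / ``accum_word``.
    """
    np.random.seed(seed)
    D = seq_start.shape[0] - 1
    K = alpha.shape[0]
    V = Nzw.shape[1]
    S = Mzt.shape[1]
    p = np.empty(K, dtype=np.float64)
    for sweep in range(n_sweeps):
        for d in range(D):
            # -- sequence tokens -------------------------------------------
            for i in range(seq_start[d], seq_start[d + 1]):
                w = seq_genus[i]
                old = seq_topic[i]
                Nzd[old, d] -= 1
                Nzw[old, w] -= 1
                Nz[old] -= 1
                if Nzd[old, d] == 0 and Mzd[old, d] > 0:
                    # removing the token would orphan this topic's words:
                    # the conditional is a point mass on the old topic
                    Nzd[old, d] += 1
                    Nzw[old, w] += 1
                    Nz[old] += 1
                    continue
                maxlp = -1.0e300
                for k in range(K):
                    lp = (
                        np.log(Nzd[k, d] + alpha[k])
                        + np.log(Nzw[k, w] + beta)
                        - np.log(Nz[k] + beta * V)
                    )
                    m = Mzd[k, d]
                    if m > 0:
                        # coupling with the sample's word topics:
                        # Mzd > 0 implies Nzd > 0 here (invariant)
                        lp += m * (np.log(Nzd[k, d] + 1.0) - np.log(Nzd[k, d]))
                    p[k] = lp
                    if lp > maxlp:
                        maxlp = lp
                tot = 0.0
                for k in range(K):
                    p[k] = np.exp(p[k] - maxlp)
                    tot += p[k]
                u = np.random.random() * tot
                acc = 0.0
                new = K - 1
                for k in range(K):
                    acc += p[k]
                    if u <= acc:
                        new = k
                        break
                seq_topic[i] = new
                Nzd[new, d] += 1
                Nzw[new, w] += 1
                Nz[new] += 1
            # -- word tokens -----------------------------------------------
            for j in range(word_start[d], word_start[d + 1]):
                t = word_type[j]
                old = word_topic[j]
                Mzd[old, d] -= 1
                Mzt[old, t] -= 1
                Mz[old] -= 1
                tot = 0.0
                for k in range(K):
                    pk = Nzd[k, d] * (Mzt[k, t] + gamma) / (Mz[k] + gamma * S)
                    p[k] = pk
                    tot += pk
                u = np.random.random() * tot
                acc = 0.0
                new = K - 1
                for k in range(K):
                    acc += p[k]
                    if u <= acc:
                        new = k
                        break
                word_topic[j] = new
                Mzd[new, d] += 1
                Mzt[new, t] += 1
                Mz[new] += 1
        if accumulate and sweep >= burn_in:
            for i in range(seq_topic.shape[0]):
                accum_seq[i, seq_topic[i]] += 1
            for j in range(word_topic.shape[0]):
                accum_word[j, word_topic[j]] += 1


@njit(cache=True)
def predict_chain(
    seed,
    n_iters,
    genus_tokens,
    phi,
    alpha,
    record_mask,
    theta_records,
):
    """One Gibbs chain over a new sample's sequence tokens, phi/alpha frozen.

    Topics are initialized uniformly at random; at every iteration flagged in
    ``record_mask`` the smoothed topic-count vector ``N_k + alpha_k`` is
    written to the next row of ``theta_records`` (caller normalizes).
    """
    np.random.seed(seed)
    K = alpha.shape[0]
    N = genus_tokens.shape[0]
    z = np.empty(N, dtype=np.int64)
    Nk = np.zeros(K, dtype=np.int64)
    p = np.empty(K, dtype=np.float64)
    for i in range(N):
        zi = np.random.randint(0, K)
        z[i] = zi
        Nk[zi] += 1
    rec = 0
    for it in range(n_iters):
        for i in range(N):
            w = genus_tokens[i]
            old = z[i]
            Nk[old] -= 1
            tot = 0.0
            for k in range(K):
                pk = phi[k, w] * (Nk[k] + alpha[k])
                p[k] = pk
                tot += pk
            if tot <= 0.0:
                Nk[old] += 1
                continue
            u = np.random.random() * tot
            acc = 0.0
            new = K - 1
            for k in range(K):
                acc += p[k]
                if u <= acc:
                    new = k
                    break
            z[i] = new
            Nk[new] += 1
        if record_mask[it]:
            for k in range(K):
                theta_records[rec, k] = Nk[k] + alpha[k]
            rec += 1
    return rec
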