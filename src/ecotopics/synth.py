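"""Synthetic paired corpora drawn from the model's own generative process.

Ground truth is retained so that recovery can be scored after resolving
label switching.  Also hosts the brute-force enumeration oracle used to
validate the collapsed Gibbs sampler on tiny instances.

Generative process, per sample d:
    theta_d ~ Dirichlet(alpha);  phi_z ~ Dirichlet(beta * 1_V);
    psi_z ~ Dirichlet(gamma * 1_S);
    z_dn ~ Mult(theta_d);  w_dn ~ Mult(phi_{z_dn});
    c_dm ~ Mult({N_zd / N_d});  t_dm ~ Mult(psi_{c_dm}).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .corpus import PairedCorpus
from .corrlda import Hyperparameters

__all__ = [
    "GroundTruth",
    "generate_corpus",
    "default_regime",
    "exact_posterior_small",
    "match_topics",
]

ENUMERATION_LIMIT = 2 ** 18


@dataclass
class GroundTruth:
    """The latent parameters a synthetic corpus was generated from."""

    theta_true: np.ndarray  # D x K
    phi_true: np.ndarray  # K x V
    psi_true: np.ndarray  # K x S
    hyper: Hyperparameters
    seed: int

    def validate(self) -> None:
        for mat in (self.theta_true, self.phi_true, self.psi_true):
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("ground-truth rows must be stochastic")


# purely alphabetic synthetic words (no trailing 's') survive the same text
# cleaning applied to real descriptions and queries
_LETTERS = "abcdefghijklmnopqrtuvwxy"


def _word_name(index: int) -> str:
    hi, lo = divmod(index, len(_LETTERS))
    return f"word{_LETTERS[hi]}{_LETTERS[lo]}"


def _draw_parameters(K: int, V: int, S: int, alpha: np.ndarray, beta: float,
                     gamma: float, D: int, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    theta = rng.dirichlet(alpha, size=D)
    phi = rng.dirichlet(np.full(V, beta), size=K)
    psi = rng.dirichlet(np.full(S, gamma), size=K)
    return theta, phi, psi


def generate_corpus(
    K: int,
    D: int,
    V: int,
    S: int,
    alpha: float | np.ndarray,
    beta: float,
    gamma: float,
    N_d: int | np.ndarray,
    M_d: int | np.ndarray,
    seed: int,
    ground_truth: GroundTruth | None = None,
    max_retries: int = 50,
) -> tuple[PairedCorpus, GroundTruth]:
    """Draw a paired corpus with known parameters.

    ``alpha`` may be a scalar (symmetric) or a length-K vector; ``N_d`` and
    ``M_d`` a scalar or per-sample vector.  Parameter and token draws use
    separate seed streams, so passing an existing ``ground_truth`` redraws
    tokens under the same theta/phi/psi.  In rare draws a vocabulary item
    receives no token anywhere; the token stage is then retried with the
    next derived seed so that the corpus invariants hold.
    """
    alpha_vec = np.full(K, float(alpha)) if np.isscalar(alpha) else np.asarray(alpha, float)
    hyper = Hyperparameters(alpha_vec, float(beta), float(gamma))
    Nd = np.full(D, N_d, dtype=np.int64) if np.isscalar(N_d) else np.asarray(N_d, np.int64)
    Md = np.full(D, M_d, dtype=np.int64) if np.isscalar(M_d) else np.asarray(M_d, np.int64)
    if (Nd < 1).any() or (Md < 1).any():
        raise ValueError("every sample needs N_d >= 1 and M_d >= 1")

    param_ss, token_ss = np.random.SeedSequence(seed).spawn(2)
    param_streams = param_ss.spawn(max_retries)
    token_streams = token_ss.spawn(max_retries)
    for attempt in range(max_retries):
        # sparse parameter draws can starve a vocabulary item outright, so a
        # failed attempt redraws parameters too (unless the caller pinned them)
        if ground_truth is None:
            theta, phi, psi = _draw_parameters(
                K, V, S, alpha_vec, beta, gamma, D,
                np.random.default_rng(param_streams[attempt]),
            )
            truth = GroundTruth(theta, phi, psi, hyper, int(seed))
        else:
            truth = ground_truth
            theta, phi, psi = truth.theta_true, truth.phi_true, truth.psi_true
        rng = np.random.default_rng(token_streams[attempt])
        genus_counts = np.zeros((D, V), dtype=np.int64)
        word_counts = np.zeros((D, S), dtype=np.int64)
        for d in range(D):
            z = rng.choice(K, size=Nd[d], p=theta[d])
            nzd = np.bincount(z, minlength=K)
            for k in np.nonzero(nzd)[0]:
                genus_counts[d] += rng.multinomial(nzd[k], phi[k])
            c = rng.choice(K, size=Md[d], p=nzd / Nd[d])
            mzd = np.bincount(c, minlength=K)
            for k in np.nonzero(mzd)[0]:
                word_counts[d] += rng.multinomial(mzd[k], psi[k])
        if (genus_counts.sum(axis=0) > 0).all() and (word_counts.sum(axis=0) > 0).all():
            corpus = PairedCorpus(
                sample_ids=[f"synth{d:05d}" for d in range(D)],
                genus_vocab=[f"Genus{v:04d}" for v in range(V)],
                word_vocab=[_word_name(s) for s in range(S)],
                genus_counts=genus_counts,
                word_counts=word_counts,
                metadata={"generator_seed": int(seed), "token_attempt": attempt},
            )
            return corpus, truth
    raise RuntimeError(
        "could not populate every vocabulary item; increase token counts or V/S"
    )


def default_regime(seed: int = 0) -> tuple[PairedCorpus, GroundTruth]:
    """The standard recovery regime: K=5, D=300, V=40, S=25, N_d=150,
    M_d=15, sparse phi/psi (concentration 0.1) and alpha = 1/K — small
    enough to train in minutes yet separated enough to be identifiable."""
    return generate_corpus(
        K=5, D=300, V=40, S=25, alpha=1.0 / 5, beta=0.1, gamma=0.1,
        N_d=150, M_d=15, seed=seed,
    )


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

def exact_posterior_small(
    corpus: PairedCorpus,
    hyper: Hyperparameters,
    limit: int = ENUMERATION_LIMIT,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact per-token posterior marginals by exhaustive enumeration.

    Enumerates every joint assignment (Z, C), weights it by the collapsed
    joint probability and marginalizes.  Returns (sequence-token marginals,
    word-token marginals, log normalizing constant).  Joint assignments
    whose word topics lack sequence support have probability zero.
    """
    K = hyper.K
    seq_tokens = [
        (d, v)
        for d in range(corpus.D)
        for v in range(corpus.V)
        for _ in range(corpus.genus_counts[d, v])
    ]
    word_tokens = [
        (d, s)
        for d in range(corpus.D)
        for s in range(corpus.S)
        for _ in range(corpus.word_counts[d, s])
    ]
    n_seq, n_word = len(seq_tokens), len(word_tokens)
    n_total = n_seq + n_word
    if K ** n_total > limit:
        raise ValueError(f"instance too large to enumerate: K^{n_total} > {limit}")

    Nd = corpus.N_d
    asum = float(hyper.alpha.sum())
    max_tok = n_total + 1
    lg_alpha = np.array([[math.lgamma(i + a) for i in range(max_tok)] for a in hyper.alpha])
    lg_asum = np.array([math.lgamma(i + asum) for i in range(max_tok)])
    lg_beta = np.array([math.lgamma(i + hyper.beta) for i in range(max_tok)])
    lg_betaV = np.array([math.lgamma(i + hyper.beta * corpus.V) for i in range(max_tok)])
    lg_gamma = np.array([math.lgamma(i + hyper.gamma) for i in range(max_tok)])
    lg_gammaS = np.array([math.lgamma(i + hyper.gamma * corpus.S) for i in range(max_tok)])

    log_weights = []
    assignments = []
    for joint in itertools.product(range(K), repeat=n_total):
        Z, C = joint[:n_seq], joint[n_seq:]
        Nzd = np.zeros((K, corpus.D), dtype=np.int64)
        Nzw = np.zeros((K, corpus.V), dtype=np.int64)
        for (d, v), z in zip(seq_tokens, Z):
            Nzd[z, d] += 1
            Nzw[z, v] += 1
        Mzd = np.zeros((K, corpus.D), dtype=np.int64)
        Mzt = np.zeros((K, corpus.S), dtype=np.int64)
        for (d, s), c in zip(word_tokens, C):
            Mzd[c, d] += 1
            Mzt[c, s] += 1
        if ((Mzd > 0) & (Nzd == 0)).any():
            continue
        lp = 0.0
        for k in range(K):
            for d in range(corpus.D):
                lp += lg_alpha[k][Nzd[k, d]] - lg_alpha[k][0]
        for d in range(corpus.D):
            lp -= lg_asum[Nd[d]] - lg_asum[0]
        Nz = Nzd.sum(axis=1)
        Mz = Mzd.sum(axis=1)
        for k in range(K):
            lp += lg_beta[Nzw[k]].sum() - corpus.V * lg_beta[0]
            lp -= lg_betaV[Nz[k]] - lg_betaV[0]
            lp += lg_gamma[Mzt[k]].sum() - corpus.S * lg_gamma[0]
            lp -= lg_gammaS[Mz[k]] - lg_gammaS[0]
        mask = Mzd > 0
        lp += (Mzd[mask] * np.log(Nzd[mask])).sum()
        Md = Mzd.sum(axis=0)
        lp -= (Md * np.log(np.maximum(Nd, 1))).sum()
        log_weights.append(lp)
        assignments.append(joint)

    log_w = np.array(log_weights)
    log_norm = float(np.logaddexp.reduce(log_w))
    weights = np.exp(log_w - log_norm)
    seq_marg = np.zeros((n_seq, K))
    word_marg = np.zeros((n_word, K))
    for weight, joint in zip(weights, assignments):
        for i in range(n_seq):
            seq_marg[i, joint[i]] += weight
        for j in range(n_word):
            word_marg[j, joint[n_seq + j]] += weight
    return seq_marg, word_marg, log_norm


def match_topics(true_phi: np.ndarray, est_phi: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Resolve label switching by optimal assignment on total variation.

    Returns ``(perm, tv)`` where ``est_phi[perm[k]]`` is the estimate matched
    to true topic ``k`` and ``tv[k]`` the corresponding total-variation
    distance; the assignment minimizes the summed TV (Hungarian algorithm).
    """
    true_phi = np.asarray(true_phi)
    est_phi = np.asarray(est_phi)
    if true_phi.shape != est_phi.shape:
        raise ValueError("true and estimated distributions must share shape")
    cost = 0.5 * np.abs(true_phi[:, None, :] - est_phi[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(true_phi.shape[0], dtype=np.int64)
    perm[rows] = cols
    return perm, cost[rows, perm[rows]]
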