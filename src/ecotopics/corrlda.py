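"""Correspondence-LDA trained by collapsed Gibbs sampling.

The model couples two modalities observed for every sample: sequence tokens
(genus assignments of individual 16S reads) and word tokens (the cleaned
description text).  Each sample ``d`` carries topic proportions ``theta_d``
with an asymmetric Dirichlet(alpha) prior; each topic ``z`` carries a genus
distribution ``phi_z`` (symmetric Dirichlet(beta)) and a word distribution
``psi_z`` (symmetric Dirichlet(gamma)).  Sequence tokens draw topics from
``theta_d``; word tokens draw topics from the *empirical* sequence-topic
frequencies ``N_zd / N_d`` of their own sample, which ties descriptions to
the observed community rather than to the latent mixture.

With theta, phi and psi integrated out, the joint factorizes as

    P(W, T, Z, C | alpha, beta, gamma)
        = P(Z | alpha) P(W | Z, beta) P(C | Z) P(T | C, gamma)

and inference reduces to Gibbs sampling the token-level assignments Z and C.
Hyperparameters are re-estimated each sweep by Minka's fixed-point method.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import digamma, gammaln

from . import _kernels
from .corpus import PairedCorpus

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

__all__ = [
    "Hyperparameters",
    "GibbsState",
    "CorrLDAModel",
    "initialize_state",
    "log_prob_Z",
    "log_prob_W_given_Z",
    "log_prob_C_given_Z",
    "log_prob_T_given_C",
    "joint_log_prob",
    "sequence_conditional",
    "word_conditional",
    "sample_sequence_topic",
    "sample_word_topic",
    "update_hyperparameters",
    "gibbs_sweep",
    "gibbs_marginals",
    "train",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hyperparameters:
    """Dirichlet concentrations: asymmetric alpha over topics, scalar beta
    (genus distributions) and gamma (word distributions)."""

    alpha: np.ndarray
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=np.float64))
        if self.alpha.ndim != 1 or self.alpha.size < 1:
            raise ValueError("alpha must be a non-empty vector")
        if (self.alpha <= 0).any() or self.beta <= 0 or self.gamma <= 0:
            raise ValueError("all Dirichlet concentrations must be > 0")

    @property
    def K(self) -> int:
        return int(self.alpha.size)

    @classmethod
    def default(cls, K: int, alpha0: float | None = None,
                beta: float = 0.1, gamma: float = 0.1) -> "Hyperparameters":
        # 50/K is the usual starting point for LDA-family samplers
        if alpha0 is None:
            alpha0 = 50.0 / K
        return cls(np.full(K, alpha0), beta, gamma)


@dataclass
class GibbsState:
    """Token-level topic assignments plus their sufficient statistics.

    Tokens are stored flat, sample-major: sequence tokens of sample ``d``
    live at ``seq_start[d]:seq_start[d+1]`` (genus ids in ``seq_genus``,
    assignments in ``seq_topic``), word tokens likewise.  Count matrices are
    derivable from the assignments; :meth:`validate` recounts and checks the
    support invariant (a topic carrying words in a sample must also carry at
    least one sequence there).
    """

    seq_start: np.ndarray  # D+1
    seq_genus: np.ndarray
    seq_topic: np.ndarray
    word_start: np.ndarray  # D+1
    word_type: np.ndarray
    word_topic: np.ndarray
    Nzd: np.ndarray  # K x D
    Nzw: np.ndarray  # K x V
    Nz: np.ndarray  # K
    Mzd: np.ndarray  # K x D
    Mzt: np.ndarray  # K x S
    Mz: np.ndarray  # K
    rng_seed: int = 0

    @property
    def D(self) -> int:
        return self.seq_start.size - 1

    @property
    def K(self) -> int:
        return self.Nzd.shape[0]

    @property
    def V(self) -> int:
        return self.Nzw.shape[1]

    @property
    def S(self) -> int:
        return self.Mzt.shape[1]

    @property
    def N_d(self) -> np.ndarray:
        return np.diff(self.seq_start).astype(np.int64)

    @property
    def M_d(self) -> np.ndarray:
        return np.diff(self.word_start).astype(np.int64)

    def recount(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Recompute (Nzd, Nzw, Mzd, Mzt) from the raw assignments."""
        K, D, V, S = self.K, self.D, self.V, self.S
        Nzd = np.zeros((K, D), dtype=np.int64)
        Nzw = np.zeros((K, V), dtype=np.int64)
        Mzd = np.zeros((K, D), dtype=np.int64)
        Mzt = np.zeros((K, S), dtype=np.int64)
        for d in range(D):
            sl = slice(self.seq_start[d], self.seq_start[d + 1])
            np.add.at(Nzd[:, d], self.seq_topic[sl], 1)
            np.add.at(Nzw, (self.seq_topic[sl], self.seq_genus[sl]), 1)
            wl = slice(self.word_start[d], self.word_start[d + 1])
            np.add.at(Mzd[:, d], self.word_topic[wl], 1)
            np.add.at(Mzt, (self.word_topic[wl], self.word_type[wl]), 1)
        return Nzd, Nzw, Mzd, Mzt

    def validate(self) -> None:
        Nzd, Nzw, Mzd, Mzt = self.recount()
        if not (
            np.array_equal(Nzd, self.Nzd)
            and np.array_equal(Nzw, self.Nzw)
            and np.array_equal(Mzd, self.Mzd)
            and np.array_equal(Mzt, self.Mzt)
            and np.array_equal(Nzd.sum(axis=1), self.Nz)
            and np.array_equal(Mzd.sum(axis=1), self.Mz)
        ):
            raise ValueError("count matrices inconsistent with assignments")
        if ((self.Mzd > 0) & (self.Nzd == 0)).any():
            raise ValueError("support invariant violated: words on a topic with no sequences")


@dataclass
class CorrLDAModel:
    """Point estimates and metadata of a trained model."""

    hyper: Hyperparameters
    theta: np.ndarray  # D x K
    phi: np.ndarray  # K x V
    psi: np.ndarray  # K x S
    genus_vocab: list[str]
    word_vocab: list[str]
    sample_ids: list[str]
    metadata: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.hyper.K

    def validate(self) -> None:
        for name, mat in (("theta", self.theta), ("phi", self.phi), ("psi", self.psi)):
            if (mat <= 0).any():
                raise ValueError(f"{name} has non-positive entries")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows do not sum to 1")


# ---------------------------------------------------------------------------
# state construction
# ---------------------------------------------------------------------------

def _expand_tokens(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand a D x W count matrix into flat (start, type) token arrays."""
    D = counts.shape[0]
    per_doc = counts.sum(axis=1)
    start = np.zeros(D + 1, dtype=np.int64)
    np.cumsum(per_doc, out=start[1:])
    types = np.empty(int(per_doc.sum()), dtype=np.int64)
    for d in range(D):
        row = counts[d]
        nz = np.nonzero(row)[0]
        types[start[d]:start[d + 1]] = np.repeat(nz, row[nz])
    return start, types


def initialize_state(corpus: PairedCorpus, hyper: Hyperparameters, seed: int) -> GibbsState:
    """Random-topic initialization.

    Sequence assignments are uniform over topics; word assignments are then
    drawn from each sample's resulting sequence-topic frequencies, so the
    support invariant holds from the start.
    """
    if corpus.D == 0:
        raise ValueError("cannot initialize on an empty corpus")
    K = hyper.K
    rng = np.random.default_rng(seed)
    seq_start, seq_genus = _expand_tokens(corpus.genus_counts)
    word_start, word_type = _expand_tokens(corpus.word_counts)
    seq_topic = rng.integers(0, K, size=seq_genus.size, dtype=np.int64)
    word_topic = np.empty(word_type.size, dtype=np.int64)
    for d in range(corpus.D):
        sl = slice(seq_start[d], seq_start[d + 1])
        freq = np.bincount(seq_topic[sl], minlength=K) / (seq_start[d + 1] - seq_start[d])
        wl = slice(word_start[d], word_start[d + 1])
        word_topic[wl] = rng.choice(K, size=word_start[d + 1] - word_start[d], p=freq)
    state = GibbsState(
        seq_start=seq_start,
        seq_genus=seq_genus,
        seq_topic=seq_topic,
        word_start=word_start,
        word_type=word_type,
        word_topic=word_topic,
        Nzd=np.zeros((K, corpus.D), dtype=np.int64),
        Nzw=np.zeros((K, corpus.V), dtype=np.int64),
        Nz=np.zeros(K, dtype=np.int64),
        Mzd=np.zeros((K, corpus.D), dtype=np.int64),
        Mzt=np.zeros((K, corpus.S), dtype=np.int64),
        Mz=np.zeros(K, dtype=np.int64),
        rng_seed=int(seed),
    )
    state.Nzd, state.Nzw, state.Mzd, state.Mzt = state.recount()
    state.Nz = state.Nzd.sum(axis=1)
    state.Mz = state.Mzd.sum(axis=1)
    return state


# ---------------------------------------------------------------------------
# collapsed likelihood terms
# ---------------------------------------------------------------------------

def log_prob_Z_from_counts(Nzd: np.ndarray, alpha: np.ndarray) -> float:
    """log P(Z | alpha): Dirichlet-multinomial over per-sample topic counts."""
    if (np.asarray(alpha) <= 0).any():
        raise ValueError("alpha must be positive")
    Nd = Nzd.sum(axis=0)
    D = Nzd.shape[1]
    asum = alpha.sum()
    return float(
        D * (gammaln(asum) - gammaln(alpha).sum())
        + gammaln(Nzd + alpha[:, None]).sum()
        - gammaln(Nd + asum).sum()
    )


def _symmetric_dm_term(counts_zw: np.ndarray, conc: float) -> float:
    """Collapsed symmetric Dirichlet-multinomial term, pooled over topics."""
    if conc <= 0:
        raise ValueError("concentration must be positive")
    K, W = counts_zw.shape
    totals = counts_zw.sum(axis=1)
    return float(
        K * (gammaln(conc * W) - W * gammaln(conc))
        + gammaln(counts_zw + conc).sum()
        - gammaln(totals + conc * W).sum()
    )


def log_prob_C_from_counts(Mzd: np.ndarray, Nzd: np.ndarray) -> float:
    """log P(C | Z) = sum_dz M_zd log(N_zd / N_d); -inf when unsupported."""
    if ((Mzd > 0) & (Nzd == 0)).any():
        raise ValueError("support invariant violated: M_zd > 0 with N_zd = 0")
    Nd = Nzd.sum(axis=0)
    Md = Mzd.sum(axis=0)
    mask = Mzd > 0
    out = float((Mzd[mask] * np.log(Nzd[mask])).sum())
    out -= float((Md[Md > 0] * np.log(Nd[Md > 0])).sum())
    return out


def log_prob_Z(state: GibbsState, hyper: Hyperparameters) -> float:
    return log_prob_Z_from_counts(state.Nzd, hyper.alpha)


def log_prob_W_given_Z(state: GibbsState, hyper: Hyperparameters) -> float:
    return _symmetric_dm_term(state.Nzw, hyper.beta)


def log_prob_C_given_Z(state: GibbsState) -> float:
    return log_prob_C_from_counts(state.Mzd, state.Nzd)


def log_prob_T_given_C(state: GibbsState, hyper: Hyperparameters) -> float:
    return _symmetric_dm_term(state.Mzt, hyper.gamma)


def joint_log_prob(state: GibbsState, hyper: Hyperparameters) -> float:
    """Collapsed log P(W, T, Z, C | alpha, beta, gamma)."""
    return (
        log_prob_Z(state, hyper)
        + log_prob_W_given_Z(state, hyper)
        + log_prob_C_given_Z(state)
        + log_prob_T_given_C(state, hyper)
    )


# ---------------------------------------------------------------------------
# single-token conditionals (reference implementations)
# ---------------------------------------------------------------------------

def sequence_conditional(state: GibbsState, d: int, n: int,
                         hyper: Hyperparameters) -> np.ndarray:
    """Full conditional P(z_dn = k | rest), the token itself removed.

    Includes the exact coupling factor prod_z (N_zd + [z=k])^{M_zd} from the
    sample's word assignments.  If removing the token would leave its old
    topic with words but no sequences, the conditional is a point mass there.
    """
    i = state.seq_start[d] + n
    if not state.seq_start[d] <= i < state.seq_start[d + 1]:
        raise IndexError(f"sample {d} has no sequence token {n}")
    K, V = state.K, state.V
    w = state.seq_genus[i]
    old = state.seq_topic[i]
    nzd = state.Nzd[:, d].astype(np.float64).copy()
    nzw = state.Nzw[:, w].astype(np.float64).copy()
    nz = state.Nz.astype(np.float64).copy()
    nzd[old] -= 1
    nzw[old] -= 1
    nz[old] -= 1
    if nzd[old] == 0 and state.Mzd[old, d] > 0:
        out = np.zeros(K)
        out[old] = 1.0
        return out
    logp = (
        np.log(nzd + hyper.alpha)
        + np.log(nzw + hyper.beta)
        - np.log(nz + hyper.beta * V)
    )
    m = state.Mzd[:, d].astype(np.float64)
    active = m > 0  # invariant: nzd > 0 wherever m > 0 (old handled above)
    logp[active] += m[active] * (np.log(nzd[active] + 1.0) - np.log(nzd[active]))
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def word_conditional(state: GibbsState, d: int, m: int,
                     hyper: Hyperparameters) -> np.ndarray:
    """Full conditional P(c_dm = k | rest) with the token removed:
    proportional to N_kd * (M_kt + gamma) / (M_k + gamma S)."""
    j = state.word_start[d] + m
    if not state.word_start[d] <= j < state.word_start[d + 1]:
        raise IndexError(f"sample {d} has no word token {m}")
    if state.seq_start[d + 1] == state.seq_start[d]:
        raise ValueError(f"sample {d} has no sequence tokens")
    t = state.word_type[j]
    old = state.word_topic[j]
    mzt = state.Mzt[:, t].astype(np.float64).copy()
    mz = state.Mz.astype(np.float64).copy()
    mzt[old] -= 1
    mz[old] -= 1
    p = state.Nzd[:, d] * (mzt + hyper.gamma) / (mz + hyper.gamma * state.S)
    return p / p.sum()


def _apply_seq_assignment(state: GibbsState, i: int, new: int) -> None:
    d = int(np.searchsorted(state.seq_start, i, side="right")) - 1
    w = state.seq_genus[i]
    old = state.seq_topic[i]
    state.Nzd[old, d] -= 1
    state.Nzw[old, w] -= 1
    state.Nz[old] -= 1
    state.seq_topic[i] = new
    state.Nzd[new, d] += 1
    state.Nzw[new, w] += 1
    state.Nz[new] += 1


def sample_sequence_topic(state: GibbsState, d: int, n: int,
                          hyper: Hyperparameters, rng: np.random.Generator) -> int:
    """Resample one sequence token from its full conditional; updates counts."""
    p = sequence_conditional(state, d, n, hyper)
    new = int(rng.choice(state.K, p=p))
    _apply_seq_assignment(state, state.seq_start[d] + n, new)
    return new


def sample_word_topic(state: GibbsState, d: int, m: int,
                      hyper: Hyperparameters, rng: np.random.Generator) -> int:
    """Resample one word token from its full conditional; updates counts."""
    p = word_conditional(state, d, m, hyper)
    new = int(rng.choice(state.K, p=p))
    j = state.word_start[d] + m
    t = state.word_type[j]
    old = state.word_topic[j]
    state.Mzd[old, d] -= 1
    state.Mzt[old, t] -= 1
    state.Mz[old] -= 1
    state.word_topic[j] = new
    state.Mzd[new, d] += 1
    state.Mzt[new, t] += 1
    state.Mz[new] += 1
    return new


# ---------------------------------------------------------------------------
# hyperparameter fixed point
# ---------------------------------------------------------------------------

def update_hyperparameters(state: GibbsState, hyper: Hyperparameters,
                           floor: float = 1e-8) -> Hyperparameters:
    """One Minka fixed-point step for alpha (per component), beta, gamma.

    alpha_k <- alpha_k * sum_d [psi(N_kd + alpha_k) - psi(alpha_k)]
                       / sum_d [psi(N_d + A) - psi(A)],  A = sum alpha;
    beta and gamma take the analogous pooled symmetric updates.  Components
    are floored at a small positive constant; a non-finite result raises.
    """
    alpha = hyper.alpha
    Nd = state.N_d
    asum = alpha.sum()
    denom = (digamma(Nd + asum) - digamma(asum)).sum()
    if denom > 0:
        num = (digamma(state.Nzd + alpha[:, None]) - digamma(alpha)[:, None]).sum(axis=1)
        alpha = np.maximum(alpha * num / denom, floor)
    beta = _symmetric_update(state.Nzw, state.Nz, hyper.beta, floor)
    gamma = _symmetric_update(state.Mzt, state.Mz, hyper.gamma, floor)
    if not (np.isfinite(alpha).all() and np.isfinite(beta) and np.isfinite(gamma)):
        raise FloatingPointError("hyperparameter update diverged")
    return Hyperparameters(alpha, beta, gamma)


def _symmetric_update(counts_zw: np.ndarray, totals_z: np.ndarray,
                      conc: float, floor: float) -> float:
    W = counts_zw.shape[1]
    denom = W * (digamma(totals_z + conc * W) - digamma(conc * W)).sum()
    if denom <= 0:
        return conc
    num = (digamma(counts_zw + conc) - digamma(conc)).sum()
    return max(conc * num / denom, floor)


# ---------------------------------------------------------------------------
# sweeps and training
# ---------------------------------------------------------------------------

_NO_ACCUM = np.zeros((0, 1), dtype=np.int64)


def gibbs_sweep(state: GibbsState, hyper: Hyperparameters, seed: int,
                update_hyper: bool = True) -> tuple[Hyperparameters, float]:
    """One full sweep (sequences then words per sample), optional
    hyperparameter step, returning the new hyperparameters and the collapsed
    joint log-likelihood."""
    _kernels.gibbs_sweeps(
        1, np.uint32(seed & 0x7FFFFFFF),
        state.seq_start, state.seq_genus, state.seq_topic,
        state.word_start, state.word_type, state.word_topic,
        state.Nzd, state.Nzw, state.Nz, state.Mzd, state.Mzt, state.Mz,
        hyper.alpha, hyper.beta, hyper.gamma,
        _NO_ACCUM, _NO_ACCUM, 0, False,
    )
    if update_hyper:
        hyper = update_hyperparameters(state, hyper)
    return hyper, joint_log_prob(state, hyper)


def gibbs_marginals(state: GibbsState, hyper: Hyperparameters, n_sweeps: int,
                    burn_in: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Empirical per-token marginal assignment frequencies from a long run
    with fixed hyperparameters (for comparison against exact enumeration)."""
    accum_seq = np.zeros((state.seq_topic.size, state.K), dtype=np.int64)
    accum_word = np.zeros((state.word_topic.size, state.K), dtype=np.int64)
    _kernels.gibbs_sweeps(
        n_sweeps, np.uint32(seed & 0x7FFFFFFF),
        state.seq_start, state.seq_genus, state.seq_topic,
        state.word_start, state.word_type, state.word_topic,
        state.Nzd, state.Nzw, state.Nz, state.Mzd, state.Mzt, state.Mz,
        hyper.alpha, hyper.beta, hyper.gamma,
        accum_seq, accum_word, burn_in, True,
    )
    kept = n_sweeps - burn_in
    return accum_seq / kept, accum_word / kept


def point_estimates(state: GibbsState, hyper: Hyperparameters
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed point estimates (theta, phi, psi) from one state."""
    theta = (state.Nzd.T + hyper.alpha) / (state.N_d[:, None] + hyper.alpha.sum())
    phi = (state.Nzw + hyper.beta) / (state.Nz[:, None] + hyper.beta * state.V)
    psi = (state.Mzt + hyper.gamma) / (state.Mz[:, None] + hyper.gamma * state.S)
    return theta, phi, psi


def train(
    corpus: PairedCorpus,
    K: int = 80,
    iterations: int = 1000,
    seed: int = 0,
    hyper: Hyperparameters | None = None,
    update_hyper: bool = True,
    average_last: int = 1,
) -> CorrLDAModel:
    """Train a Correspondence-LDA model.

    ``average_last > 1`` averages the point estimates of the final
    ``average_last`` states (within one chain topic labels are stable, so no
    relabeling is needed); the default uses the final state only.
    Deterministic given ``seed``.
    """
    if K < 1 or iterations < 1:
        raise ValueError("need K >= 1 and iterations >= 1")
    if hyper is None:
        hyper = Hyperparameters.default(K)
    if hyper.K != K:
        raise ValueError("hyper.K does not match K")
    state = initialize_state(corpus, hyper, seed)
    sweep_seeds = np.random.SeedSequence(seed).generate_state(iterations, dtype=np.uint32)
    history = []
    tail: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for it in range(iterations):
        hyper, ll = gibbs_sweep(state, hyper, int(sweep_seeds[it]), update_hyper)
        history.append((it, ll, float(hyper.alpha.sum()), hyper.beta, hyper.gamma))
        if iterations - it <= average_last:
            tail.append(point_estimates(state, hyper))
    if average_last > 1:
        theta = np.mean([t for t, _, _ in tail], axis=0)
        phi = np.mean([p for _, p, _ in tail], axis=0)
        psi = np.mean([q for _, _, q in tail], axis=0)
    else:
        theta, phi, psi = tail[-1]
    model = CorrLDAModel(
        hyper=hyper,
        theta=theta,
        phi=phi,
        psi=psi,
        genus_vocab=list(corpus.genus_vocab),
        word_vocab=list(corpus.word_vocab),
        sample_ids=list(corpus.sample_ids),
        metadata={
            "iterations": iterations,
            "seed": int(seed),
            "K": K,
            "update_hyper": update_hyper,
            "final_log_likelihood": history[-1][1],
            "history": history,
        },
    )
    model.validate()
    return model


def training_log_frame(model: CorrLDAModel):
    """Per-sweep log-likelihood and hyperparameter trajectory as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        model.metadata.get("history", []),
        columns=["sweep", "joint_log_likelihood", "alpha_sum", "beta", "gamma"],
    )


# ---------------------------------------------------------------------------
# model archive
# ---------------------------------------------------------------------------

def save_model(model: CorrLDAModel, path: str | Path) -> None:
    payload = {
        "format": "ecotopics-model",
        "version": MODEL_FORMAT_VERSION,
        "alpha": model.hyper.alpha.tolist(),
        "beta": model.hyper.beta,
        "gamma": model.hyper.gamma,
        "theta": model.theta.tolist(),
        "phi": model.phi.tolist(),
        "psi": model.psi.tolist(),
        "genus_vocab": model.genus_vocab,
        "word_vocab": model.word_vocab,
        "sample_ids": model.sample_ids,
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> CorrLDAModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: corrupt or truncated model archive") from exc
    if payload.get("format") != "ecotopics-model":
        raise ValueError(f"{path}: not a model archive")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported archive version {payload.get('version')}")
    meta = payload.get("metadata", {})
    if "history" in meta:
        meta["history"] = [tuple(row) for row in meta["history"]]
    return CorrLDAModel(
        hyper=Hyperparameters(np.array(payload["alpha"]), payload["beta"], payload["gamma"]),
        theta=np.array(payload["theta"]),
        phi=np.array(payload["phi"]),
        psi=np.array(payload["psi"]),
        genus_vocab=list(payload["genus_vocab"]),
        word_vocab=list(payload["word_vocab"]),
        sample_ids=list(payload["sample_ids"]),
        metadata=meta,
    )
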