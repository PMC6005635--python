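"""Topic-mixture prediction for new samples from genus counts alone.

A trained model's genus distributions phi act as fixed source communities
(in the spirit of Bayesian source tracking): a new sample's sequence tokens
are Gibbs-sampled with phi and alpha frozen,

    P(z_dn = k | rest)  ∝  phi_{k,w} * (N_kd\\dn + alpha_k) / (N_d\\dn + sum alpha),

and the topic mixture is the posterior mean of the smoothed topic counts.
Multi-chain runs provide a per-topic standard deviation, a goodness-of-fit
signal: a sample the model explains well is stable across chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .corpus import RawProfile, filter_and_subsample
from .corrlda import CorrLDAModel

logger = logging.getLogger(__name__)

__all__ = ["TopicMixture", "predict_topics", "predict_with_stability"]


@dataclass
class TopicMixture:
    """Predicted topic proportions for one sample."""

    proportions: np.ndarray  # length K, sums to 1
    sd: np.ndarray | None = None  # per-topic, present iff chains > 1
    n_tokens_used: int = 0
    chains: int = 1
    oov_mass: float = 0.0  # fraction of input tokens dropped as out-of-vocabulary

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=np.float64)
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if (self.sd is not None) != (self.chains > 1):
            raise ValueError("sd must be present exactly when chains > 1")
        if self.sd is not None and (np.asarray(self.sd) < 0).any():
            raise ValueError("sd must be non-negative")


def _prepare_tokens(model: CorrLDAModel, profile: RawProfile,
                    min_total: int, max_total: int, seed: int
                    ) -> tuple[np.ndarray, float]:
    """Depth-filter the profile and expand in-vocabulary genus tokens."""
    filtered = filter_and_subsample(profile, min_total=min_total,
                                    max_total=max_total, seed=seed)
    if filtered is None:
        raise ValueError(
            f"sample {profile.sample_id!r} has fewer than {min_total} assigned sequences"
        )
    index = {g: j for j, g in enumerate(model.genus_vocab)}
    total = filtered.total
    kept: list[int] = []
    dropped = 0
    for genus in sorted(filtered.counts):
        count = filtered.counts[genus]
        if genus in index:
            kept.extend([index[genus]] * count)
        else:
            dropped += count
    if dropped:
        logger.warning(
            "sample %s: %d/%d tokens belong to genera outside the model vocabulary",
            profile.sample_id, dropped, total,
        )
    if not kept:
        raise ValueError(
            f"sample {profile.sample_id!r}: no genus overlaps the model vocabulary"
        )
    return np.array(kept, dtype=np.int64), dropped / total


def _run_chain(tokens: np.ndarray, model: CorrLDAModel, iterations: int,
               record_mask: np.ndarray, seed: int) -> np.ndarray:
    n_rec = int(record_mask.sum())
    records = np.empty((n_rec, model.K), dtype=np.float64)
    _kernels.predict_chain(
        np.uint32(seed & 0x7FFFFFFF), iterations, tokens,
        model.phi, model.hyper.alpha, record_mask, records,
    )
    return records / records.sum(axis=1, keepdims=True)


def predict_topics(
    model: CorrLDAModel,
    new_profile: RawProfile,
    iterations: int = 200,
    burn_in: int | None = None,
    seed: int = 0,
    min_total: int = 1000,
    max_total: int = 10000,
) -> TopicMixture:
    """Posterior-mean topic mixture of a new sample, model frozen.

    The depth filter applied to training samples (discard below
    ``min_total``, subsample above ``max_total``) is applied to the new
    sample first.  ``burn_in`` defaults to ``iterations // 2``; proportions
    average the smoothed topic-count estimate over post-burn-in states.
    """
    if burn_in is None:
        burn_in = iterations // 2
    if not 0 <= burn_in < iterations:
        raise ValueError("need 0 <= burn_in < iterations")
    tokens, oov = _prepare_tokens(model, new_profile, min_total, max_total, seed)
    mask = np.zeros(iterations, dtype=np.bool_)
    mask[burn_in:] = True
    thetas = _run_chain(tokens, model, iterations, mask, seed)
    return TopicMixture(
        proportions=thetas.mean(axis=0),
        n_tokens_used=int(tokens.size),
        chains=1,
        oov_mass=oov,
    )


def predict_with_stability(
    model: CorrLDAModel,
    new_profile: RawProfile,
    chains: int = 100,
    draws_per_chain: int = 1,
    iterations: int = 200,
    burn_in: int | None = None,
    seed: int = 0,
    min_total: int = 1000,
    max_total: int = 10000,
) -> TopicMixture:
    """Multi-chain prediction with a per-topic stability estimate.

    Each independent chain contributes the mean of ``draws_per_chain``
    states evenly spaced after burn-in (one draw per chain reproduces the
    draw-and-average protocol of the published stability analysis).  The
    result averages the chain estimates; with more than one chain the
    across-chain standard deviation is attached.
    """
    if chains < 1 or draws_per_chain < 1:
        raise ValueError("need chains >= 1 and draws_per_chain >= 1")
    if burn_in is None:
        burn_in = iterations // 2
    if not 0 <= burn_in < iterations:
        raise ValueError("need 0 <= burn_in < iterations")
    tokens, oov = _prepare_tokens(model, new_profile, min_total, max_total, seed)
    post = iterations - burn_in
    draws = min(draws_per_chain, post)
    mask = np.zeros(iterations, dtype=np.bool_)
    # evenly spaced recording points, always including the final state
    positions = burn_in + np.unique(
        np.round(np.linspace(post - 1, 0, draws)).astype(np.int64)
    )
    mask[positions] = True
    chain_seeds = np.random.SeedSequence(seed).generate_state(chains, dtype=np.uint32)
    estimates = np.empty((chains, model.K))
    for c in range(chains):
        thetas = _run_chain(tokens, model, iterations, mask, int(chain_seeds[c]))
        estimates[c] = thetas.mean(axis=0)
    proportions = estimates.mean(axis=0)
    proportions = proportions / proportions.sum()
    return TopicMixture(
        proportions=proportions,
        sd=estimates.std(axis=0, ddof=0) if chains > 1 else None,
        n_tokens_used=int(tokens.size),
        chains=chains,
        oov_mass=oov,
    )
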