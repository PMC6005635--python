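"""Model evaluation: held-out perplexity, topic divergence, environment labels.

Perplexity follows the document-completion protocol: half of each test
sample's sequence tokens estimate its topic mixture (fold-in, model frozen),
the other half is scored, and

    perplexity = exp( - sum_d sum_held-out log sum_z theta_dz phi_z,w / n_held-out ).

Lower is better; the curve over the number of topics K guides model choice.
Perplexity is computed over genus tokens only; test descriptions play no
part in fold-in.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import PairedCorpus
from .corrlda import CorrLDAModel, train
from .predict import _run_chain

logger = logging.getLogger(__name__)

__all__ = [
    "PerplexityReport",
    "heldout_perplexity",
    "select_K",
    "topic_divergence",
    "environment_topics",
    "EnvironmentAssociation",
    "load_word_groups",
    "default_word_groups",
]


@dataclass
class PerplexityReport:
    K: int
    perplexities: list[float]
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.perplexities):
            raise ValueError("perplexity must be positive")
        self.mean = float(np.mean(self.perplexities))
        self.sd = float(np.std(self.perplexities))


def _test_tokens(model: CorrLDAModel, corpus: PairedCorpus) -> list[np.ndarray]:
    """Per-sample genus-token arrays indexed into the model vocabulary."""
    index = {g: j for j, g in enumerate(model.genus_vocab)}
    col_map = np.array([index.get(g, -1) for g in corpus.genus_vocab])
    dropped = int(corpus.genus_counts[:, col_map < 0].sum())
    if dropped:
        logger.warning(
            "%d test tokens belong to genera outside the model vocabulary", dropped
        )
    out = []
    for d in range(corpus.D):
        row = corpus.genus_counts[d]
        keep = (row > 0) & (col_map >= 0)
        out.append(np.repeat(col_map[keep], row[keep]))
    return out


def heldout_perplexity(
    model: CorrLDAModel,
    test_corpus: PairedCorpus,
    fold_fraction: float = 0.5,
    seed: int = 0,
    fold_in_iterations: int = 200,
) -> float:
    """Document-completion perplexity of the model on held-out samples.

    Each test sample's sequence tokens are split uniformly at random into an
    observed fraction (``fold_fraction``) and a held-out remainder; the
    observed part is folded in by a single Gibbs chain (phi and alpha
    frozen, posterior mean after 50% burn-in) and the held-out tokens are
    scored under theta-hat @ phi.  Normalized by held-out token count.
    """
    if not 0.0 < fold_fraction < 1.0:
        raise ValueError("fold_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    burn_in = fold_in_iterations // 2
    mask = np.zeros(fold_in_iterations, dtype=np.bool_)
    mask[burn_in:] = True
    total_ll = 0.0
    n_heldout = 0
    chain_seeds = np.random.SeedSequence(seed).generate_state(
        test_corpus.D, dtype=np.uint32
    )
    for d, tokens in enumerate(_test_tokens(model, test_corpus)):
        n = tokens.size
        n_obs = int(round(fold_fraction * n))
        if n_obs < 1 or n_obs >= n:
            logger.warning("test sample %d too small to split; skipped", d)
            continue
        perm = rng.permutation(n)
        observed, heldout = tokens[perm[:n_obs]], tokens[perm[n_obs:]]
        thetas = _run_chain(observed, model, fold_in_iterations, mask,
                            int(chain_seeds[d]))
        theta_hat = thetas.mean(axis=0)
        probs = theta_hat @ model.phi[:, heldout]
        total_ll += float(np.log(probs).sum())
        n_heldout += heldout.size
    if n_heldout == 0:
        raise ValueError("no held-out tokens; test corpus unusable")
    return float(np.exp(-total_ll / n_heldout))


def select_K(
    train_corpus: PairedCorpus,
    test_corpus: PairedCorpus,
    K_grid: list[int],
    chains: int = 5,
    iterations: int = 200,
    seed: int = 0,
    fold_fraction: float = 0.5,
    fold_in_iterations: int = 200,
    update_hyper: bool = True,
) -> list[PerplexityReport]:
    """Mean +/- sd held-out perplexity per candidate K over independent chains."""
    if not K_grid:
        raise ValueError("K_grid must be non-empty")
    reports = []
    chain_seeds = np.random.SeedSequence(seed).generate_state(
        len(K_grid) * chains, dtype=np.uint32
    )
    i = 0
    for K in K_grid:
        perps = []
        for _ in range(chains):
            s = int(chain_seeds[i])
            i += 1
            model = train(train_corpus, K=K, iterations=iterations, seed=s,
                          update_hyper=update_hyper)
            perps.append(
                heldout_perplexity(model, test_corpus, fold_fraction, s,
                                   fold_in_iterations)
            )
        reports.append(PerplexityReport(K=K, perplexities=perps))
    return reports


def topic_divergence(model: CorrLDAModel, space: str = "genus") -> np.ndarray:
    """Pairwise Jensen-Shannon divergence between topic distributions.

    Base-2 logarithms, so disjoint supports score 1.0 (maximum divergence);
    the matrix is symmetric with a zero diagonal.  ``space`` selects the
    genus distributions phi or the word distributions psi.
    """
    if space == "genus":
        rows = model.phi
    elif space == "word":
        rows = model.psi
    else:
        raise ValueError("space must be 'genus' or 'word'")
    K = rows.shape[0]

    def h(p: np.ndarray) -> float:
        nz = p > 0
        return float(-(p[nz] * np.log2(p[nz])).sum())

    out = np.zeros((K, K))
    ent = [h(rows[k]) for k in range(K)]
    for a in range(K):
        for b in range(a + 1, K):
            m = 0.5 * (rows[a] + rows[b])
            jsd = h(m) - 0.5 * (ent[a] + ent[b])
            out[a, b] = out[b, a] = min(max(jsd, 0.0), 1.0)
    return out


@dataclass
class EnvironmentAssociation:
    """Which topics generate an environment's marker words, and how much of
    each sample those topics explain."""

    topics: dict[str, list[int]]
    sample_fractions: pd.DataFrame  # samples x environments, sum of theta
    dominant_counts: dict[str, int]  # samples with fraction > 0.5


def load_word_groups(path: str | Path) -> dict[str, list[str]]:
    """Read environment word groups from a two-column TSV
    (environment name, space-separated marker words)."""
    groups = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, _, words = line.partition("\t")
        groups[name] = words.split()
    return groups


def default_word_groups() -> dict[str, list[str]]:
    """The packaged default marker-word groups (gut, oral, skin, vagina,
    ocean, freshwater, soil, hot spring)."""
    ref = importlib.resources.files("ecotopics") / "data" / "environment_words.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_word_groups(path)


def environment_topics(
    model: CorrLDAModel,
    word_groups: dict[str, list[str]] | None = None,
    threshold: float = 0.05,
) -> EnvironmentAssociation:
    """Label topics by the environments whose marker words they generate.

    Topic z is associated with an environment when the summed probability of
    the environment's marker words under psi_z exceeds ``threshold`` (5% by
    default).  Per sample, the summed theta over an environment's topics is
    reported, along with the number of samples where it exceeds one half.
    """
    if word_groups is None:
        word_groups = default_word_groups()
    word_idx = {w: j for j, w in enumerate(model.word_vocab)}
    topics: dict[str, list[int]] = {}
    fractions = {}
    dominant = {}
    for env, words in word_groups.items():
        if not words:
            raise ValueError(f"environment {env!r} has an empty word group")
        cols = [word_idx[w] for w in words if w in word_idx]
        missing = [w for w in words if w not in word_idx]
        if missing:
            logger.warning("environment %s: words not in vocabulary: %s",
                           env, ", ".join(missing))
        if cols:
            mass = model.psi[:, cols].sum(axis=1)
            assoc = np.nonzero(mass > threshold)[0].tolist()
        else:
            assoc = []
        topics[env] = assoc
        frac = model.theta[:, assoc].sum(axis=1) if assoc else np.zeros(model.theta.shape[0])
        fractions[env] = frac
        dominant[env] = int((frac > 0.5).sum())
    frame = pd.DataFrame(fractions, index=model.sample_ids)
    return EnvironmentAssociation(topics=topics, sample_fractions=frame,
                                  dominant_counts=dominant)
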