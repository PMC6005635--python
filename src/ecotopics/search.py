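"""Query-likelihood semantic search over modelled samples.

A free-text query is cleaned exactly like the training descriptions; words
outside the model vocabulary are discarded.  A sample's score is the
probability that its topic mixture generates every remaining query word,

    Score(d) = prod_n sum_z psi_{z, q_n} theta_{d, z},

accumulated in log space (an 8-word query easily reaches the 1e-6 scale).
When a query names a taxon, the score can additionally be scaled by that
taxon's relative abundance in each sample — for ranks above genus, by the
summed abundance of the descendant genera from a user-supplied lineage
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import RawDocument, TextCleanConfig, preprocess_text
from .corrlda import CorrLDAModel

logger = logging.getLogger(__name__)

__all__ = [
    "Query",
    "SearchResult",
    "preprocess_query",
    "score_samples",
    "taxon_scaled_score",
    "load_lineage",
]


@dataclass
class Query:
    raw_text: str
    valid_terms: list[str]
    taxon_terms: list[str] = field(default_factory=list)


@dataclass
class SearchResult:
    """Samples ranked by descending score; ties broken by sample id."""

    ranking: list[tuple[str, float]]

    def top(self, n: int) -> list[tuple[str, float]]:
        return self.ranking[:n]


def load_lineage(path: str | Path) -> pd.DataFrame:
    """Read a lineage table: TSV rows of (genus, rank, ancestor_name)."""
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["genus", "rank", "ancestor_name"], dtype=str)
    return frame


def preprocess_query(text: str, model: CorrLDAModel,
                     config: TextCleanConfig | None = None,
                     lineage: pd.DataFrame | None = None) -> Query:
    """Clean a query and intersect it with the model's vocabularies.

    Word terms outside the model's word vocabulary are discarded (logged);
    tokens matching a genus name — or an ancestor taxon from the lineage
    table — case-insensitively are collected as taxon terms.  A query
    yielding neither word nor taxon terms is an error.
    """
    config = config or TextCleanConfig()
    bag = preprocess_text(RawDocument("query", text), config)
    vocab = set(model.word_vocab)
    valid, discarded = [], []
    for word, count in sorted(bag.items()):
        if word in vocab:
            valid.extend([word] * count)
        else:
            discarded.append(word)
    if discarded:
        logger.info("query words outside the vocabulary discarded: %s",
                    ", ".join(discarded))
    taxa_lower = {g.lower(): g for g in model.genus_vocab}
    if lineage is not None:
        for name in lineage["ancestor_name"].unique():
            taxa_lower.setdefault(name.lower(), name)
    taxon_terms = []
    for raw in text.split():
        token = raw.strip(".,;:!?()[]\"'").lower()
        if token in taxa_lower:
            taxon_terms.append(taxa_lower[token])
    if not valid and not taxon_terms:
        raise ValueError("no usable query terms")
    return Query(raw_text=text, valid_terms=valid, taxon_terms=taxon_terms)


def _log_scores(model: CorrLDAModel, terms: list[str]) -> np.ndarray:
    word_idx = {w: j for j, w in enumerate(model.word_vocab)}
    # canonical term order makes the score exactly order-invariant
    cols = sorted(word_idx[t] for t in terms)
    per_term = model.theta @ model.psi[:, cols]  # D x N
    return np.log(per_term).sum(axis=1)


def _ranked(sample_ids: list[str], scores: np.ndarray) -> SearchResult:
    order = sorted(range(len(sample_ids)), key=lambda d: (-scores[d], sample_ids[d]))
    return SearchResult([(sample_ids[d], float(scores[d])) for d in order])


def score_samples(model: CorrLDAModel, query: Query) -> SearchResult:
    """Rank all samples by the query-likelihood score."""
    if not query.valid_terms:
        raise ValueError("query has no valid word terms")
    scores = np.exp(_log_scores(model, query.valid_terms))
    return _ranked(model.sample_ids, scores)


def _descendant_columns(model: CorrLDAModel, taxon: str,
                        lineage: pd.DataFrame | None) -> list[int]:
    genus_idx = {g.lower(): j for j, g in enumerate(model.genus_vocab)}
    if taxon.lower() in genus_idx:
        return [genus_idx[taxon.lower()]]
    if lineage is not None:
        hits = lineage[lineage["ancestor_name"].str.lower() == taxon.lower()]
        cols = [genus_idx[g.lower()] for g in hits["genus"] if g.lower() in genus_idx]
        if cols:
            return cols
    raise ValueError(f"taxon {taxon!r} not resolvable against the genus vocabulary"
                     " or lineage table")


def taxon_scaled_score(
    model: CorrLDAModel,
    query: Query,
    abundances: np.ndarray | pd.DataFrame,
    lineage: pd.DataFrame | None = None,
) -> SearchResult:
    """Query-likelihood score scaled by taxon abundance.

    ``abundances`` holds per-sample relative genus abundances over the model
    genus vocabulary (rows sum to 1).  For each taxon term, a sample's score
    is multiplied by the taxon's relative abundance there — the summed
    abundance of descendant genera when the term is above genus rank — so
    samples lacking the taxon score exactly zero.
    """
    if isinstance(abundances, pd.DataFrame):
        abundances = abundances.reindex(index=model.sample_ids,
                                        columns=model.genus_vocab).to_numpy()
    abundances = np.asarray(abundances, dtype=np.float64)
    if abundances.shape != (len(model.sample_ids), len(model.genus_vocab)):
        raise ValueError("abundance matrix must be samples x genus vocabulary")
    if not np.allclose(abundances.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("abundance rows must sum to 1")
    if query.valid_terms:
        scores = np.exp(_log_scores(model, query.valid_terms))
    else:
        scores = np.ones(len(model.sample_ids))
    for taxon in query.taxon_terms:
        cols = _descendant_columns(model, taxon, lineage)
        scores = scores * abundances[:, cols].sum(axis=1)
    return _ranked(model.sample_ids, scores)
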