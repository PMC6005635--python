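"""Build paired (genus counts, description words) corpora.

This module turns two raw inputs — genus-level taxonomic count tables and
free-text sample descriptions — into a :class:`PairedCorpus`: two aligned
count matrices over fixed, lexicographically sorted vocabularies.  The
cleaning and filtering rules mirror standard practice for metadata-driven
microbiome corpora:

* samples with fewer than 1,000 genus-assigned sequences are discarded and
  samples with more than 10,000 are uniformly subsampled to 10,000;
* description text is lowercased, lemmatized and stripped of stop words,
  tokens containing non-alphabetic characters, tokens that look like
  nucleotide strings (A/T/C/G making up >= 70% of the length), and a
  user-supplied list of generic words;
* vocabulary words occurring fewer than 20 times in total, in more than 30%
  of the samples, or (when study labels are known) in only a single study
  are removed;
* only samples retaining both modalities survive.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

logger = logging.getLogger(__name__)

CORPUS_FORMAT_VERSION = 1

__all__ = [
    "RawProfile",
    "RawDocument",
    "TextCleanConfig",
    "PairedCorpus",
    "load_taxon_table",
    "load_documents",
    "filter_and_subsample",
    "preprocess_text",
    "build_vocabulary",
    "assemble_corpus",
    "subset_corpus",
    "save_corpus",
    "load_corpus",
    "default_lemmatizer",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawProfile:
    """Genus-level sequence counts for one sample."""

    sample_id: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for genus, count in self.counts.items():
            if not genus:
                raise ValueError(f"empty genus name in sample {self.sample_id!r}")
            if count < 0:
                raise ValueError(
                    f"negative count {count} for genus {genus!r} in sample {self.sample_id!r}"
                )

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class RawDocument:
    """Free-text description attached to one sample."""

    sample_id: str
    text: str


_IRREGULAR_PLURALS = {
    "feces": "feces",
    "species": "species",
    "genera": "genus",
    "bacteria": "bacterium",
    "archaea": "archaeon",
    "fungi": "fungus",
    "flora": "flora",
    "microbiota": "microbiota",
    "data": "data",
    "media": "medium",
    "larvae": "larva",
    "algae": "alga",
    "children": "child",
    "teeth": "tooth",
    "mice": "mouse",
    "men": "man",
    "women": "woman",
}


def default_lemmatizer(word: str) -> str:
    """Reduce common English inflections to a base form.

    A light rule-based lemmatizer: irregular forms from a small domain
    dictionary, then plural-suffix rules.  It is deliberately conservative —
    a token it does not recognise is returned unchanged.  Any callable
    ``str -> str`` may be supplied instead via :class:`TextCleanConfig`.
    """
    if word in _IRREGULAR_PLURALS:
        return _IRREGULAR_PLURALS[word]
    if len(word) > 3 and word.endswith("ies"):
        return word[:-3] + "y"
    if len(word) > 4 and word.endswith(("ches", "shes", "sses", "xes", "zes")):
        return word[:-2]
    if len(word) > 3 and word.endswith("s") and not word.endswith(("ss", "us", "is")):
        return word[:-1]
    return word


@dataclass
class TextCleanConfig:
    """Knobs for description-text cleaning and vocabulary filtering."""

    stopword_list: frozenset[str] = frozenset(ENGLISH_STOP_WORDS)
    general_word_list: frozenset[str] = frozenset()
    atcg_fraction_threshold: float = 0.7
    min_word_count: int = 20
    max_word_sample_fraction: float = 0.3
    study_of_sample: Mapping[str, str] | None = None
    lemmatizer: Callable[[str], str] = default_lemmatizer

    def __post_init__(self) -> None:
        if not 0.0 <= self.atcg_fraction_threshold <= 1.0:
            raise ValueError("atcg_fraction_threshold must lie in [0, 1]")
        if not 0.0 <= self.max_word_sample_fraction <= 1.0:
            raise ValueError("max_word_sample_fraction must lie in [0, 1]")
        if self.min_word_count < 0:
            raise ValueError("min_word_count must be non-negative")
        self.stopword_list = frozenset(w.lower() for w in self.stopword_list)
        self.general_word_list = frozenset(w.lower() for w in self.general_word_list)


@dataclass
class PairedCorpus:
    """Aligned genus-count and word-count matrices over fixed vocabularies.

    Row ``d`` of ``genus_counts`` sums to ``N_d`` (sequence tokens) and row
    ``d`` of ``word_counts`` sums to ``M_d`` (description tokens); every
    retained sample has at least one token in each modality.
    """

    sample_ids: list[str]
    genus_vocab: list[str]
    word_vocab: list[str]
    genus_counts: np.ndarray  # D x V, int64
    word_counts: np.ndarray  # D x S, int64
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genus_counts = np.asarray(self.genus_counts, dtype=np.int64)
        self.word_counts = np.asarray(self.word_counts, dtype=np.int64)
        self.validate()

    @property
    def D(self) -> int:
        return len(self.sample_ids)

    @property
    def V(self) -> int:
        return len(self.genus_vocab)

    @property
    def S(self) -> int:
        return len(self.word_vocab)

    @property
    def N_d(self) -> np.ndarray:
        return self.genus_counts.sum(axis=1)

    @property
    def M_d(self) -> np.ndarray:
        return self.word_counts.sum(axis=1)

    def validate(self) -> None:
        D, V, S = self.D, self.V, self.S
        if self.genus_counts.shape != (D, V):
            raise ValueError(f"genus_counts shape {self.genus_counts.shape} != ({D}, {V})")
        if self.word_counts.shape != (D, S):
            raise ValueError(f"word_counts shape {self.word_counts.shape} != ({D}, {S})")
        if len(set(self.genus_vocab)) != V or len(set(self.word_vocab)) != S:
            raise ValueError("vocabularies must be duplicate-free")
        if (self.genus_counts < 0).any() or (self.word_counts < 0).any():
            raise ValueError("counts must be non-negative")
        if D:
            if (self.N_d < 1).any() or (self.M_d < 1).any():
                raise ValueError("every sample needs >=1 token in both modalities")
            if (self.genus_counts.sum(axis=0) == 0).any():
                raise ValueError("all-zero genus vocabulary column")
            if (self.word_counts.sum(axis=0) == 0).any():
                raise ValueError("all-zero word vocabulary column")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairedCorpus):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.genus_vocab == other.genus_vocab
            and self.word_vocab == other.word_vocab
            and np.array_equal(self.genus_counts, other.genus_counts)
            and np.array_equal(self.word_counts, other.word_counts)
        )


# ---------------------------------------------------------------------------
# input readers
# ---------------------------------------------------------------------------

def load_taxon_table(path: str | Path, dialect: str = "long") -> list[RawProfile]:
    """Read a genus-level count table.

    ``dialect`` selects the layout: ``"long"`` is a headerless three-column
    TSV of (sample_id, genus, count); ``"wide"`` a TSV matrix with samples as
    rows and genera as columns (first column holds sample ids); ``"biom"`` a
    BIOM table (observations are genera).  Duplicate (sample, genus) rows are
    summed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long":
        return _load_long(path)
    if dialect == "wide":
        return _load_wide(path)
    if dialect == "biom":
        return _load_biom(path)
    raise ValueError(f"unknown taxon-table dialect {dialect!r}")


def _load_long(path: Path) -> list[RawProfile]:
    acc: dict[str, Counter] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
            sid, genus, raw = parts
            try:
                count = int(raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: count {raw!r} is not an integer") from exc
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative count {count}")
            acc.setdefault(sid, Counter())[genus] += count
    if not acc:
        logger.warning("taxon table %s is empty", path)
    return [RawProfile(sid, dict(cnt)) for sid, cnt in acc.items()]


def _load_wide(path: Path) -> list[RawProfile]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if (frame.values < 0).any():
        raise ValueError(f"{path}: negative count in wide table")
    profiles = []
    for sid, row in frame.iterrows():
        counts = {g: int(c) for g, c in row.items() if c > 0}
        profiles.append(RawProfile(str(sid), counts))
    return profiles


def _load_biom(path: Path) -> list[RawProfile]:
    try:
        import biom
    except ImportError as exc:  # pragma: no cover - biom ships with scikit-bio here
        raise ImportError("BIOM input requires the 'biom-format' package") from exc
    table = biom.load_table(str(path))
    profiles = []
    for sid in table.ids("sample"):
        vec = table.data(sid, axis="sample", dense=True)
        counts = {
            str(genus): int(v)
            for genus, v in zip(table.ids("observation"), vec)
            if v > 0
        }
        profiles.append(RawProfile(str(sid), counts))
    return profiles


def load_documents(path: str | Path, fmt: str = "tsv") -> list[RawDocument]:
    """Read per-sample description documents (``tsv`` or ``jsonl``)."""
    path = Path(path)
    docs: list[RawDocument] = []
    if fmt == "tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                sid, _, text = line.partition("\t")
                if not sid:
                    raise ValueError(f"{path}:{lineno}: missing sample id")
                docs.append(RawDocument(sid, text))
    elif fmt == "jsonl":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                rec = json.loads(line)
                docs.append(RawDocument(str(rec["sample_id"]), str(rec["text"])))
    else:
        raise ValueError(f"unknown document format {fmt!r}")
    return docs


# ---------------------------------------------------------------------------
# filtering & cleaning
# ---------------------------------------------------------------------------

def filter_and_subsample(
    profile: RawProfile,
    min_total: int = 1000,
    max_total: int = 10000,
    seed: int = 0,
) -> RawProfile | None:
    """Apply the sequence-depth filter: discard below, subsample above.

    Samples with fewer than ``min_total`` genus-assigned sequences return
    ``None``; samples above ``max_total`` are subsampled to exactly
    ``max_total`` sequences, uniformly without replacement from the token
    multiset (multivariate hypergeometric), deterministic given ``seed``.
    """
    if min_total <= 0 or max_total <= 0 or min_total > max_total:
        raise ValueError("need 0 < min_total <= max_total")
    total = profile.total
    if total < min_total:
        return None
    if total <= max_total:
        return profile
    genera = sorted(profile.counts)
    counts = np.array([profile.counts[g] for g in genera], dtype=np.int64)
    rng = np.random.default_rng(seed)
    kept = rng.multivariate_hypergeometric(counts, max_total)
    return RawProfile(
        profile.sample_id,
        {g: int(k) for g, k in zip(genera, kept) if k > 0},
    )


_ALPHA_RE = re.compile(r"^[a-z]+$")
_TOKEN_RE = re.compile(r"\S+")
# sentence punctuation is shed from token edges; interior symbols (hyphens,
# digits) still disqualify the token under the non-alphabetic rule
_EDGE_PUNCT = ".,;:!?\"'()[]{}<>"


def _atcg_fraction(word: str) -> float:
    return sum(ch in "atcg" for ch in word) / len(word)


def preprocess_text(doc: RawDocument, config: TextCleanConfig) -> dict[str, int]:
    """Clean one document into a bag of words.

    Tokens are lowercased and lemmatized; stop words, tokens with any
    non-alphabetic character, nucleotide-like tokens (A/T/C/G fraction at or
    above the configured threshold) and configured generic words are dropped.
    An empty result is legal.
    """
    counts: Counter = Counter()
    for match in _TOKEN_RE.finditer(doc.text.lower()):
        token = match.group().strip(_EDGE_PUNCT)
        if not token:
            continue
        if not _ALPHA_RE.fullmatch(token):
            continue
        if _atcg_fraction(token) >= config.atcg_fraction_threshold:
            continue
        if token in config.stopword_list:
            continue
        lemma = config.lemmatizer(token)
        if lemma in config.stopword_list or lemma in config.general_word_list:
            continue
        counts[lemma] += 1
    return dict(counts)


def build_vocabulary(
    docs: Mapping[str, Mapping[str, int]],
    config: TextCleanConfig,
) -> tuple[list[str], dict[str, dict[str, int]]]:
    """Apply corpus-wide word filters and fix the word vocabulary.

    Removes words with total count below ``min_word_count``, words present in
    more than ``max_word_sample_fraction`` of the documents, and — when
    ``study_of_sample`` is provided — words confined to a single study.
    Returns the surviving vocabulary (sorted) and the documents restricted
    to it.  Documents left empty stay in the mapping (as empty bags) so the
    filter is idempotent; :func:`assemble_corpus` drops them.
    """
    if not docs:
        raise ValueError("build_vocabulary needs at least one document")
    total: Counter = Counter()
    doc_freq: Counter = Counter()
    studies: dict[str, set[str]] = {}
    n_docs = len(docs)
    for sid, bag in docs.items():
        for word, count in bag.items():
            total[word] += count
            doc_freq[word] += 1
            if config.study_of_sample is not None:
                studies.setdefault(word, set()).add(
                    config.study_of_sample.get(sid, sid)
                )
    if config.study_of_sample is None:
        logger.warning("no study labels supplied; single-study word rule skipped")

    def keep(word: str) -> bool:
        if total[word] < config.min_word_count:
            return False
        if doc_freq[word] / n_docs > config.max_word_sample_fraction:
            return False
        if config.study_of_sample is not None and len(studies[word]) < 2:
            return False
        return True

    vocab = sorted(w for w in total if keep(w))
    if not vocab:
        raise ValueError("no word survived the vocabulary filters")
    keep_set = set(vocab)
    filtered = {
        sid: {w: c for w, c in bag.items() if w in keep_set}
        for sid, bag in docs.items()
    }
    return vocab, filtered


def assemble_corpus(
    profiles: Iterable[RawProfile],
    documents: Mapping[str, Mapping[str, int]],
    word_vocab: Sequence[str] | None = None,
    metadata: dict | None = None,
) -> PairedCorpus:
    """Intersect modalities and assemble the paired count matrices.

    Only samples with non-empty counts on both sides are retained.  The genus
    vocabulary is the sorted union of genera observed in retained samples;
    the word vocabulary defaults to the sorted union of words in the retained
    documents (pass the output of :func:`build_vocabulary` to pin it).
    """
    prof_by_id = {p.sample_id: p for p in profiles if p.total > 0}
    doc_ids = {sid for sid, bag in documents.items() if bag}
    shared = sorted(prof_by_id.keys() & doc_ids)
    if not shared:
        raise ValueError("no sample carries both a genus profile and a document")

    genus_vocab = sorted({g for sid in shared for g in prof_by_id[sid].counts})
    if word_vocab is None:
        word_vocab = sorted({w for sid in shared for w in documents[sid]})
    else:
        word_vocab = list(word_vocab)

    genus_idx = {g: j for j, g in enumerate(genus_vocab)}
    word_idx = {w: j for j, w in enumerate(word_vocab)}
    D = len(shared)
    genus_counts = np.zeros((D, len(genus_vocab)), dtype=np.int64)
    word_counts = np.zeros((D, len(word_vocab)), dtype=np.int64)
    for d, sid in enumerate(shared):
        for g, c in prof_by_id[sid].counts.items():
            genus_counts[d, genus_idx[g]] = c
        for w, c in documents[sid].items():
            if w in word_idx:
                word_counts[d, word_idx[w]] = c
    # a pinned vocabulary can zero out a document entirely; drop such samples
    keep = word_counts.sum(axis=1) > 0
    if not keep.all():
        shared = [s for s, k in zip(shared, keep) if k]
        genus_counts = genus_counts[keep]
        word_counts = word_counts[keep]
        used = genus_counts.sum(axis=0) > 0
        genus_vocab = [g for g, u in zip(genus_vocab, used) if u]
        genus_counts = genus_counts[:, used]
    used_w = word_counts.sum(axis=0) > 0
    if not used_w.all():
        word_vocab = [w for w, u in zip(word_vocab, used_w) if u]
        word_counts = word_counts[:, used_w]
    return PairedCorpus(
        sample_ids=shared,
        genus_vocab=genus_vocab,
        word_vocab=list(word_vocab),
        genus_counts=genus_counts,
        word_counts=word_counts,
        metadata=metadata or {},
    )


def subset_corpus(corpus: PairedCorpus, indices: Sequence[int]) -> PairedCorpus:
    """Restrict a corpus to a subset of samples.

    Vocabulary items unused by the subset are trimmed so the invariants
    hold; downstream evaluation aligns vocabularies by name, so a subset
    remains comparable with models trained on the full corpus.
    """
    indices = list(indices)
    if not indices:
        raise ValueError("subset needs at least one sample")
    genus_counts = corpus.genus_counts[indices]
    word_counts = corpus.word_counts[indices]
    used_g = genus_counts.sum(axis=0) > 0
    used_w = word_counts.sum(axis=0) > 0
    return PairedCorpus(
        sample_ids=[corpus.sample_ids[i] for i in indices],
        genus_vocab=[g for g, u in zip(corpus.genus_vocab, used_g) if u],
        word_vocab=[w for w, u in zip(corpus.word_vocab, used_w) if u],
        genus_counts=genus_counts[:, used_g],
        word_counts=word_counts[:, used_w],
        metadata=dict(corpus.metadata),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _sparse_triplets(matrix: np.ndarray) -> list[list[int]]:
    rows, cols = np.nonzero(matrix)
    return [[int(r), int(c), int(matrix[r, c])] for r, c in zip(rows, cols)]


def _dense(triplets: list, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=np.int64)
    for r, c, v in triplets:
        out[r, c] = v
    return out


def save_corpus(corpus: PairedCorpus, path: str | Path) -> None:
    """Write a corpus to a versioned JSON archive."""
    payload = {
        "format": "ecotopics-corpus",
        "version": CORPUS_FORMAT_VERSION,
        "sample_ids": corpus.sample_ids,
        "genus_vocab": corpus.genus_vocab,
        "word_vocab": corpus.word_vocab,
        "genus_counts": _sparse_triplets(corpus.genus_counts),
        "word_counts": _sparse_triplets(corpus.word_counts),
        "metadata": corpus.metadata,
    }
    Path(path).write_text(json.dumps(payload))


def load_corpus(path: str | Path) -> PairedCorpus:
    """Read a corpus archive written by :func:`save_corpus`."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: corrupt or truncated corpus archive") from exc
    if payload.get("format") != "ecotopics-corpus":
        raise ValueError(f"{path}: not a corpus archive")
    if payload.get("version") != CORPUS_FORMAT_VERSION:
        raise ValueError(
            f"{path}: archive version {payload.get('version')} != {CORPUS_FORMAT_VERSION}"
        )
    D = len(payload["sample_ids"])
    return PairedCorpus(
        sample_ids=list(payload["sample_ids"]),
        genus_vocab=list(payload["genus_vocab"]),
        word_vocab=list(payload["word_vocab"]),
        genus_counts=_dense(payload["genus_counts"], (D, len(payload["genus_vocab"]))),
        word_counts=_dense(payload["word_counts"], (D, len(payload["word_vocab"]))),
        metadata=payload.get("metadata", {}),
    )
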