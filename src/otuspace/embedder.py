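"""Skip-gram embeddings of walk corpora.

OTU and sample tokens from the metapath walks are embedded into one
shared vector space with skip-gram + negative sampling (the word2vec
objective applied to walk sentences; because the walks already enforce
the O-S-O metapath, the heterogeneous walk + skip-gram scheme reduces to
this).  The trainer is a single-threaded compiled loop, deterministic
for a fixed corpus and seed.

Defaults follow the embedding configuration used throughout the
pipeline: 128 dimensions, window 7, 5 negative samples, min_count 1 (so
ultra-rare OTUs present in one or two samples still receive vectors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .hetnet import OTU, SAMPLE
from .walker import WalkCorpus, token_type

__all__ = ["EmbeddingSpace", "train_embeddings", "nearest_neighbors",
           "write_word2vec", "read_word2vec"]

_TABLE_SIZE = 1 << 20
_NOISE_POWER = 0.75  # word2vec unigram smoothing exponent


@dataclass
class EmbeddingSpace:
    """Namespaced node token -> d-dimensional vector, both node types."""

    tokens: list[str]
    vectors: np.ndarray  # (V, d) float32
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.vectors.shape[0] != len(self.tokens):
            raise ValueError("one vector per token required")
        self._index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __getitem__(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self._index[token]]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary") from None

    def subset_matrix(self, node_type: str) -> tuple[list[str], np.ndarray]:
        """(tokens, matrix) restricted to one node type."""
        idx = [i for i, t in enumerate(self.tokens) if token_type(t) == node_type]
        return [self.tokens[i] for i in idx], self.vectors[idx]


@njit(cache=True)
def _sgns_kernel(
    flat, offsets, syn0, syn1, table, table_is_sample, type_aware,
    window, negative, epochs, alpha0, seed,
):  # pragma: no cover - compiled
    np.random.seed(seed)
    d = syn0.shape[1]
    total = epochs * flat.size
    processed = 0
    min_alpha = alpha0 * 1e-4
    tsize = table.size
    for _ep in range(epochs):
        for s in range(offsets.size - 1):
            start = offsets[s]
            end = offsets[s + 1]
            for pos in range(start, end):
                center = flat[pos]
                alpha = alpha0 * (1.0 - processed / (total + 1.0))
                if alpha < min_alpha:
                    alpha = min_alpha
                processed += 1
                b = np.random.randint(1, window + 1)
                lo = pos - b
                if lo < start:
                    lo = start
                hi = pos + b
                if hi > end - 1:
                    hi = end - 1
                for p2 in range(lo, hi + 1):
                    if p2 == pos:
                        continue
                    context = flat[p2]
                    neu1e = np.zeros(d, dtype=np.float32)
                    for n in range(negative + 1):
                        if n == 0:
                            target = context
                            label = np.float32(1.0)
                        else:
                            # draw until the negative matches the context's
                            # node type (type-aware mode) and differs from it
                            target = table[np.random.randint(0, tsize)]
                            if type_aware:
                                want = table_is_sample[context]
                                tries = 0
                                while table_is_sample[target] != want and tries < 32:
                                    target = table[np.random.randint(0, tsize)]
                                    tries += 1
                            if target == context:
                                continue
                            label = np.float32(0.0)
                        f = np.float32(0.0)
                        for k in range(d):
                            f += syn0[center, k] * syn1[target, k]
                        if f > 6.0:
                            g = (label - 1.0) * alpha
                        elif f < -6.0:
                            g = label * alpha
                        else:
                            g = (label - 1.0 / (1.0 + np.exp(-f))) * alpha
                        gf = np.float32(g)
                        for k in range(d):
                            neu1e[k] += gf * syn1[target, k]
                        for k in range(d):
                            syn1[target, k] += gf * syn0[center, k]
                    for k in range(d):
                        syn0[center, k] += neu1e[k]


def _build_vocab(corpus: WalkCorpus, min_count: int) -> tuple[list[str], np.ndarray]:
    freq: dict[str, int] = {}
    for sent in corpus.sentences():
        for tok in sent:
            freq[tok] = freq.get(tok, 0) + 1
    items = [(t, c) for t, c in freq.items() if c >= min_count]
    items.sort(key=lambda tc: (-tc[1], tc[0]))
    tokens = [t for t, _ in items]
    counts = np.array([c for _, c in items], dtype=np.float64)
    return tokens, counts


def _unigram_table(counts: np.ndarray) -> np.ndarray:
    p = counts ** _NOISE_POWER
    p /= p.sum()
    bounds = np.floor(np.cumsum(p) * _TABLE_SIZE).astype(np.int64)
    table = np.zeros(_TABLE_SIZE, dtype=np.int32)
    prev = 0
    for i, b in enumerate(bounds):
        table[prev:b] = i
        prev = b
    table[prev:] = len(counts) - 1
    return table


def train_embeddings(
    corpus: WalkCorpus,
    d: int = 128,
    window: int = 7,
    negative: int = 5,
    min_count: int = 1,
    epochs: int = 5,
    alpha: float = 0.025,
    seed: int = 0,
    type_aware_negatives: bool = False,
) -> EmbeddingSpace:
    """Train skip-gram-with-negative-sampling vectors on the walk corpus.

    ``type_aware_negatives`` restricts negative draws to the node type of
    the positive context token; the default draws negatives from the full
    smoothed unigram distribution.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    tokens, counts = _build_vocab(corpus, min_count)
    if not tokens:
        raise ValueError("no token reaches min_count")
    index = {t: i for i, t in enumerate(tokens)}
    sents = [
        np.array([index[t] for t in sent if t in index], dtype=np.int32)
        for sent in corpus.sentences()
    ]
    flat = np.concatenate([s for s in sents if s.size]) if sents else np.empty(0, np.int32)
    lens = np.array([s.size for s in sents if s.size], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)]).astype(np.int64)
    table = _unigram_table(counts)
    is_sample = np.array([token_type(t) == SAMPLE for t in tokens], dtype=np.bool_)

    rng = np.random.default_rng(seed)
    syn0 = ((rng.random((len(tokens), d), dtype=np.float32) - 0.5) / d).astype(np.float32)
    syn1 = np.zeros((len(tokens), d), dtype=np.float32)
    _sgns_kernel(
        flat, offsets, syn0, syn1, table, is_sample, type_aware_negatives,
        window, negative, epochs, np.float64(alpha), seed % (2**31 - 1),
    )
    meta = dict(d=d, window=window, negative=negative, min_count=min_count,
                epochs=epochs, alpha=alpha, seed=seed,
                type_aware_negatives=type_aware_negatives)
    return EmbeddingSpace(tokens, syn0, meta)


def aligned_matrix(
    space: EmbeddingSpace,
    ids: list[str],
    node_type: str,
    normalize: bool = True,
) -> np.ndarray:
    """Vectors for the given raw ids, in order, as a dense matrix.

    With ``normalize`` (default) rows are scaled to unit length before
    use: skip-gram vector norms track corpus frequency rather than
    community composition, so distance analyses downstream (nearest
    neighbours, local aggregation) read the direction, not the norm.
    """
    prefix = "O:" if node_type == OTU else "S:"
    mat = np.stack([space[prefix + i] for i in ids]).astype(np.float64)
    if normalize:
        mat /= np.linalg.norm(mat, axis=1, keepdims=True) + 1e-12
    return mat


def nearest_neighbors(
    space: EmbeddingSpace, token: str, k: int, node_type: str = "any"
) -> list[tuple[str, float]]:
    """Top-k cosine neighbours of ``token``, excluding the query itself.

    ``node_type`` in {"OTU", "SAMPLE", "any"} filters candidates before
    ranking.
    """
    q = space[token]
    if node_type == "any":
        cand_tokens, mat = space.tokens, space.vectors
    elif node_type in (OTU, SAMPLE):
        cand_tokens, mat = space.subset_matrix(node_type)
    else:
        raise ValueError(f"unknown node_type {node_type!r}")
    if k <= 0:
        return []
    qn = q / (np.linalg.norm(q) + 1e-12)
    norms = np.linalg.norm(mat, axis=1) + 1e-12
    sims = (mat @ qn) / norms
    order = np.argsort(-sims)
    out = []
    for i in order:
        if cand_tokens[i] == token:
            continue
        out.append((cand_tokens[i], float(sims[i])))
        if len(out) == k:
            break
    return out


def write_word2vec(space: EmbeddingSpace, path: str | Path) -> None:
    """word2vec text format: header ``V d`` then one token + floats per line."""
    with open(path, "w") as fh:
        fh.write(f"{len(space.tokens)} {space.d}\n")
        for t, vec in zip(space.tokens, space.vectors):
            fh.write(t + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")


def read_word2vec(path: str | Path) -> EmbeddingSpace:
    with open(path) as fh:
        header = fh.readline().split()
        v, d = int(header[0]), int(header[1])
        tokens, vecs = [], np.empty((v, d), dtype=np.float32)
        for i in range(v):
            parts = fh.readline().split()
            tokens.append(parts[0])
            vecs[i] = np.array(parts[1:], dtype=np.float32)
    return EmbeddingSpace(tokens, vecs)
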