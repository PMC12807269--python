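"""Weighted OTU-Sample-OTU metapath random walks.

The walker starts at an OTU node and alternates between the two node
types; bipartiteness of the network enforces the metapath, so the only
bias needed is the edge-weight-proportional choice of the next node:

    p(v | u) = w(u, v) / sum_{x in Nb(u)} w(u, x)

One walk of ``n_cycles`` O-S-O cycles visits 1 + 2 * n_cycles nodes.
Tokens are namespaced ("O:<id>" / "S:<id>") so that an OTU and a sample
sharing a raw identifier stay distinct in the corpus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hetnet import OTU, SAMPLE, HetNet

__all__ = ["Walk", "WalkCorpus", "transition_probs", "sample_walk", "generate_corpus",
           "write_corpus", "read_corpus"]

logger = logging.getLogger(__name__)


def otu_token(otu_id: str) -> str:
    return f"O:{otu_id}"


def sample_token(sample_id: str) -> str:
    return f"S:{sample_id}"


def token_type(token: str) -> str:
    return OTU if token.startswith("O:") else SAMPLE


@dataclass
class Walk:
    """One metapath walk as an ordered list of namespaced tokens."""

    tokens: list[str]

    def __post_init__(self) -> None:
        types = [token_type(t) for t in self.tokens]
        if types and types[0] != OTU:
            raise ValueError("walk must start at an OTU node")
        for a, b in zip(types, types[1:]):
            if a == b:
                raise ValueError("walk types must strictly alternate")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class WalkCorpus:
    walks: list[Walk]
    walks_per_otu: int
    n_cycles: int
    seed: int | None = None

    def sentences(self) -> list[list[str]]:
        return [w.tokens for w in self.walks]

    def __len__(self) -> int:
        return len(self.walks)


class _CumWeights:
    """Per-node cumulative edge weights for O(log deg) weighted sampling."""

    def __init__(self, net: HetNet) -> None:
        self.net = net
        csr, csc = net.weights, net.weights.tocsc()
        self.s_indices, self.s_indptr = csr.indices, csr.indptr
        self.s_cum = np.cumsum(csr.data)
        self.o_indices, self.o_indptr = csc.indices, csc.indptr
        self.o_cum = np.cumsum(csc.data)

    def step(self, node_type: str, idx: int, rng: np.random.Generator) -> int | None:
        if node_type == SAMPLE:
            lo, hi = self.s_indptr[idx], self.s_indptr[idx + 1]
            indices, cum = self.s_indices, self.s_cum
        else:
            lo, hi = self.o_indptr[idx], self.o_indptr[idx + 1]
            indices, cum = self.o_indices, self.o_cum
        if hi == lo:
            return None
        base = cum[lo - 1] if lo > 0 else 0.0
        total = cum[hi - 1] - base
        u = rng.random() * total
        k = np.searchsorted(cum[lo:hi] - base, u, side="right")
        k = min(k, hi - lo - 1)
        return int(indices[lo + k])


def transition_probs(net: HetNet, node_type: str, idx: int) -> tuple[np.ndarray, np.ndarray]:
    """Weight-proportional next-step distribution over a node's neighbours.

    Returns ``(neighbor_indices, probabilities)``; the indices refer to the
    opposite node type.  An isolated node has no distribution.
    """
    nbrs, w = (
        net.sample_neighbors(idx) if node_type == SAMPLE else net.otu_neighbors(idx)
    )
    if len(nbrs) == 0:
        raise ValueError(f"isolated {node_type} node index {idx}")
    return nbrs, w / w.sum()


def sample_walk(
    net: HetNet,
    start_otu: int | str,
    n_cycles: int,
    rng: np.random.Generator,
    _cum: _CumWeights | None = None,
) -> Walk:
    """One weighted walk of ``n_cycles`` O-S-O cycles from an OTU node.

    Truncates early (with a log record) only if a dead-end node is hit,
    which cannot happen on a prevalence-filtered network.
    """
    if isinstance(start_otu, str):
        start_otu = net.otu_ids.index(start_otu)
    cum = _cum or _CumWeights(net)
    if net.degree(OTU, start_otu) == 0:
        raise ValueError(f"start OTU index {start_otu} has no neighbors")
    tokens = [otu_token(net.otu_ids[start_otu])]
    node_type, idx = OTU, start_otu
    for _ in range(2 * n_cycles):
        nxt = cum.step(node_type, idx, rng)
        if nxt is None:
            logger.info("walk truncated at dead-end %s %d", node_type, idx)
            break
        node_type = SAMPLE if node_type == OTU else OTU
        idx = nxt
        tokens.append(
            sample_token(net.sample_ids[idx]) if node_type == SAMPLE
            else otu_token(net.otu_ids[idx])
        )
    return Walk(tokens)


def generate_corpus(
    net: HetNet,
    walks_per_otu: int = 100,
    n_cycles: int = 100,
    seed: int = 0,
) -> WalkCorpus:
    """``walks_per_otu`` walks from every non-isolated OTU node.

    Each walk draws from its own deterministic substream (spawned from
    ``seed``), so the corpus is reproducible regardless of generation
    order.
    """
    cum = _CumWeights(net)
    starts = [j for j in range(net.n_otus) if net.degree(OTU, j) > 0]
    children = np.random.SeedSequence(seed).spawn(len(starts) * walks_per_otu)
    walks: list[Walk] = []
    k = 0
    for j in starts:
        for _ in range(walks_per_otu):
            rng = np.random.default_rng(children[k])
            walks.append(sample_walk(net, j, n_cycles, rng, _cum=cum))
            k += 1
    return WalkCorpus(walks, walks_per_otu, n_cycles, seed)


def write_corpus(corpus: WalkCorpus, path: str | Path) -> None:
    """One walk per line, whitespace-separated namespaced tokens."""
    with open(path, "w") as fh:
        for walk in corpus.walks:
            fh.write(" ".join(walk.tokens) + "\n")


def read_corpus(path: str | Path) -> WalkCorpus:
    walks = []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if toks:
                walks.append(Walk(toks))
    n_cycles = (len(walks[0]) - 1) // 2 if walks else 0
    return WalkCorpus(walks, walks_per_otu=0, n_cycles=n_cycles)
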