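"""Weighted sample-OTU heterogeneous network construction.

Each OTU's log10 relative abundances (over the samples where it occurs)
are standardised to z-scores, and the z-score is mapped onto an edge
weight in [1, 7]:

    w = 7                      if  log10 r - mu >=  3 sigma
    w = (log10 r - mu)/sigma + 4   if strictly between +-3 sigma
    w = 1                      if  log10 r - mu <= -3 sigma
    w = 0                      if  r = 0  (no edge stored)

so an OTU sitting exactly at its own mean gets the midpoint weight 4, and
the weight reflects how enriched or depleted the OTU is in that sample
relative to its behaviour across the cohort, rather than its raw
abundance (which spans orders of magnitude between dominant and rare
taxa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .otu_io import RelAbundanceTable

__all__ = [
    "OtuLogStats",
    "HetNet",
    "otu_log_stats",
    "edge_weight",
    "build_network",
    "write_edge_list",
    "read_edge_list",
]

OTU = "OTU"
SAMPLE = "SAMPLE"


@dataclass
class OtuLogStats:
    """Per-OTU mean/sd of log10 relative abundance over nonzero samples.

    ``sigma`` is the population standard deviation (1/n_j inside the
    root) by default; ``ddof=1`` at computation time gives the sample
    form.
    """

    otu_ids: list[str]
    mu: np.ndarray
    sigma: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        if (self.n < 1).any():
            raise ValueError("every OTU must occur in at least one sample")
        if (self.sigma < 0).any():
            raise ValueError("negative sigma")


def otu_log_stats(rel: RelAbundanceTable, ddof: int = 0) -> OtuLogStats:
    """Mean and standard deviation of log10 r_ij over nonzero entries only."""
    csc = rel.rel.tocsc()
    n_otus = len(rel.otu_ids)
    mu = np.zeros(n_otus)
    sigma = np.zeros(n_otus)
    n = np.zeros(n_otus, dtype=np.int64)
    for j in range(n_otus):
        vals = csc.data[csc.indptr[j] : csc.indptr[j + 1]]
        vals = vals[vals > 0]
        if vals.size == 0:
            raise ValueError(f"OTU {rel.otu_ids[j]!r} occurs in no sample")
        logs = np.log10(vals)
        n[j] = logs.size
        mu[j] = logs.mean()
        sigma[j] = logs.std(ddof=ddof) if logs.size > ddof else 0.0
    return OtuLogStats(list(rel.otu_ids), mu, sigma, n)


def edge_weight(r_ij: float, mu_j: float, sigma_j: float) -> float:
    """Clamped z-score edge weight; 0 for an absent OTU, else in [1, 7].

    A zero-variance OTU (constant abundance, or present in one sample)
    shows no deviation from its own mean, so every presence maps to the
    z=0 weight 4.
    """
    if sigma_j < 0:
        raise ValueError("sigma must be non-negative")
    if r_ij == 0:
        return 0.0
    if r_ij < 0:
        raise ValueError("negative relative abundance")
    dev = np.log10(r_ij) - mu_j
    if sigma_j == 0:
        return 4.0
    if dev >= 3 * sigma_j:
        return 7.0
    if dev <= -3 * sigma_j:
        return 1.0
    return dev / sigma_j + 4.0


def _edge_weights_vec(logr: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Vectorised weight for nonzero entries given their log10 abundance."""
    dev = logr - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(sigma > 0, dev / np.where(sigma > 0, sigma, 1.0) + 4.0, 4.0)
    w = np.where((sigma > 0) & (dev >= 3 * sigma), 7.0, w)
    w = np.where((sigma > 0) & (dev <= -3 * sigma), 1.0, w)
    return w


@dataclass
class HetNet:
    """Weighted bipartite sample-OTU graph backed by a sparse matrix.

    ``weights`` holds w_ij for sample i, OTU j; structural zeros are
    absent OTUs (no edge).  All stored weights lie in [1, 7].
    """

    sample_ids: list[str]
    otu_ids: list[str]
    weights: sp.csr_matrix

    def __post_init__(self) -> None:
        self.weights = sp.csr_matrix(self.weights)
        self.weights.eliminate_zeros()
        if self.weights.nnz:
            lo, hi = self.weights.data.min(), self.weights.data.max()
            if lo < 1.0 or hi > 7.0:
                raise ValueError(f"edge weight outside [1, 7]: range ({lo}, {hi})")
        self._csc = self.weights.tocsc()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_edges(self) -> int:
        return self.weights.nnz

    def sample_neighbors(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(OTU indices, weights) adjacent to sample ``i``."""
        sl = slice(self.weights.indptr[i], self.weights.indptr[i + 1])
        return self.weights.indices[sl], self.weights.data[sl]

    def otu_neighbors(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """(sample indices, weights) adjacent to OTU ``j``."""
        sl = slice(self._csc.indptr[j], self._csc.indptr[j + 1])
        return self._csc.indices[sl], self._csc.data[sl]

    def degree(self, node_type: str, idx: int) -> int:
        nbrs, _ = (
            self.sample_neighbors(idx) if node_type == SAMPLE else self.otu_neighbors(idx)
        )
        return len(nbrs)


def build_network(rel: RelAbundanceTable, ddof: int = 0) -> HetNet:
    """One weighted edge per nonzero relative abundance.

    Isolated sample nodes (no OTUs after filtering) are kept with a
    warning so the node universe matches the table.
    """
    stats = otu_log_stats(rel, ddof=ddof)
    coo = rel.rel.tocoo()
    keep = coo.data > 0
    rows, cols, vals = coo.row[keep], coo.col[keep], coo.data[keep]
    w = _edge_weights_vec(np.log10(vals), stats.mu[cols], stats.sigma[cols])
    weights = sp.csr_matrix(
        (w, (rows, cols)), shape=(len(rel.sample_ids), len(rel.otu_ids))
    )
    deg = np.asarray((weights > 0).sum(axis=1)).ravel()
    if (deg == 0).any():
        isolated = [s for s, d in zip(rel.sample_ids, deg) if d == 0]
        warnings.warn(
            f"{len(isolated)} isolated sample node(s) kept: {isolated[:3]}",
            stacklevel=2,
        )
    return HetNet(list(rel.sample_ids), list(rel.otu_ids), weights)


def write_edge_list(net: HetNet, path: str | Path) -> None:
    """TSV edge list: sample_id, otu_id, weight to 6 decimal places."""
    coo = net.weights.tocoo()
    with open(path, "w") as fh:
        fh.write("sample_id\totu_id\tweight\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{net.sample_ids[i]}\t{net.otu_ids[j]}\t{w:.6f}\n")


def read_edge_list(path: str | Path) -> HetNet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "otu_id": str})
    sample_ids = sorted(df["sample_id"].unique())
    otu_ids = sorted(df["otu_id"].unique())
    si = {s: i for i, s in enumerate(sample_ids)}
    oi = {o: j for j, o in enumerate(otu_ids)}
    rows = df["sample_id"].map(si).to_numpy()
    cols = df["otu_id"].map(oi).to_numpy()
    weights = sp.csr_matrix(
        (df["weight"].to_numpy(), (rows, cols)), shape=(len(sample_ids), len(otu_ids))
    )
    return HetNet(sample_ids, otu_ids, weights)
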