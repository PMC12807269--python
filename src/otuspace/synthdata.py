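"""Synthetic microbiome communities with known ground truth.

The generator emulates the shape of a large 16S gut survey: a very
sparse count matrix, heavy-tailed OTU prevalence with a sizeable
ultra-rare class (OTUs planted in just one or two samples), log-normal
within-sample abundances, and fixed-depth multinomial read sampling.
Community structure comes from guilds: each OTU belongs to one guild,
each sample mixes guilds with Dirichlet weights, and an OTU's presence
probability and abundance both rise with its guild's weight in the
sample.  Categorical attributes are either *planted* (a threshold on
the weight of one informative guild, hence correlated with community
structure) or *null* (independent of everything), giving ground truth
for aggregation and classification tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .otu_io import OtuTable, SampleMetadata

__all__ = ["AttributeSpec", "SynthConfig", "GroundTruth", "generate",
           "fixture_small", "classification_task"]


@dataclass
class AttributeSpec:
    name: str
    kind: str = "null"  # "planted" | "null"
    n_levels: int = 2  # null attributes only
    threshold: float = 0.5  # planted: guild-weight cut for "Yes"
    guild: int = 0  # planted: informative guild
    na_frac: float = 0.0  # fraction of cells blanked to "NA"

    def __post_init__(self) -> None:
        if self.kind not in ("planted", "null"):
            raise ValueError(f"unknown attribute kind {self.kind!r}")


@dataclass
class SynthConfig:
    n_samples: int = 100
    n_otus: int = 500
    n_guilds: int = 3
    #: scalar (symmetric) or one concentration per guild
    dirichlet_alpha: float | tuple[float, ...] = 0.3
    #: optional distinct community state: a ``marker_fraction`` minority of
    #: samples draws guild weights from ``marker_alpha`` instead (e.g. a
    #: disease-state or enterotype-like subpopulation dominated by one
    #: guild); planted attributes thresholded on that guild then mark a
    #: coherent, locally aggregated group of samples
    marker_fraction: float | None = None
    marker_alpha: tuple[float, ...] | None = None
    base_log10_mean: float = -3.0
    base_log10_sd: float = 0.8
    rare_log10_mean: float = -2.5
    rare_log10_sd: float = 0.5
    guild_boost: float = 2.0
    noise_sd: float = 0.5
    ultra_rare_frac: float = 0.5
    presence_strength: float = 1.5
    max_presence: float = 0.9
    depth: int = 30_000
    attributes: list[AttributeSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_guilds < 1:
            raise ValueError("need at least one guild")
        if not 0 <= self.ultra_rare_frac <= 1:
            raise ValueError("ultra_rare_frac must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for spec in self.attributes:
            if spec.kind == "planted" and not 0 <= spec.guild < self.n_guilds:
                raise ValueError(f"planted guild {spec.guild} out of range")


@dataclass
class GroundTruth:
    otu_guild: dict[str, int]
    sample_guild_weights: dict[str, list[float]]
    attribute_kind: dict[str, str]
    planted_guild: dict[str, int]
    discriminative_otus: dict[str, list[str]]
    ultra_rare_otus: list[str]

    def weights_matrix(self, sample_ids: list[str]) -> np.ndarray:
        return np.array([self.sample_guild_weights[s] for s in sample_ids])

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def generate(config: SynthConfig) -> tuple[OtuTable, SampleMetadata, GroundTruth]:
    """Draw one synthetic cohort; identical config -> identical output."""
    rng = np.random.default_rng(config.seed)
    ns, no, ng = config.n_samples, config.n_otus, config.n_guilds
    sample_ids = [f"SMP{i:05d}" for i in range(ns)]
    otu_ids = [f"OTU{j:05d}" for j in range(no)]

    guild = rng.integers(0, ng, size=no)
    ultra = rng.random(no) < config.ultra_rare_frac
    alpha = np.broadcast_to(np.asarray(config.dirichlet_alpha, dtype=float), (ng,))
    W = rng.dirichlet(alpha, size=ns)
    if config.marker_fraction:
        carriers = rng.random(ns) < config.marker_fraction
        if carriers.any():
            W[carriers] = rng.dirichlet(
                np.asarray(config.marker_alpha, dtype=float), size=int(carriers.sum())
            )

    base = np.where(
        ultra,
        rng.normal(config.rare_log10_mean, config.rare_log10_sd, size=no),
        rng.normal(config.base_log10_mean, config.base_log10_sd, size=no),
    )

    present = np.zeros((ns, no), dtype=bool)
    common = np.flatnonzero(~ultra)
    if common.size:
        p = np.minimum(
            config.max_presence, config.presence_strength * W[:, guild[common]]
        )
        present[:, common] = rng.random((ns, common.size)) < p
    for j in np.flatnonzero(ultra):
        m = int(rng.integers(1, 3))  # planted in exactly 1 or 2 samples
        present[rng.choice(ns, size=m, replace=False), j] = True

    empty = np.flatnonzero(present.sum(axis=1) == 0)
    if empty.size:
        if common.size == 0:
            raise ValueError("infeasible config: a sample has no present OTU")
        for i in empty:  # guarantee every sample has at least one taxon
            present[i, rng.choice(common)] = True

    log_intensity = (
        base[None, :]
        + config.guild_boost * W[:, guild]
        + rng.normal(0.0, config.noise_sd, size=(ns, no))
    )
    counts = np.zeros((ns, no), dtype=np.int64)
    for i in range(ns):
        idx = np.flatnonzero(present[i])
        intensity = 10.0 ** log_intensity[i, idx]
        counts[i, idx] = rng.multinomial(config.depth, intensity / intensity.sum())

    table = OtuTable(sample_ids, otu_ids, sp.csr_matrix(counts))

    attributes: dict[str, dict[str, str]] = {}
    kind_map: dict[str, str] = {}
    planted_guild: dict[str, int] = {}
    discriminative: dict[str, list[str]] = {}
    for spec in config.attributes:
        kind_map[spec.name] = spec.kind
        if spec.kind == "planted":
            vals = np.where(W[:, spec.guild] > spec.threshold, "Yes", "No")
            planted_guild[spec.name] = spec.guild
            discriminative[spec.name] = [
                otu_ids[j] for j in common if guild[j] == spec.guild
            ]
        else:
            levels = (
                ["Yes", "No"] if spec.n_levels == 2
                else [f"L{k}" for k in range(spec.n_levels)]
            )
            vals = rng.choice(levels, size=ns)
        vals = np.asarray(vals, dtype=object)
        if spec.na_frac > 0:
            vals[rng.random(ns) < spec.na_frac] = "NA"
        attributes[spec.name] = dict(zip(sample_ids, vals))
    meta = SampleMetadata(sample_ids, attributes)

    truth = GroundTruth(
        otu_guild=dict(zip(otu_ids, (int(g) for g in guild))),
        sample_guild_weights={s: [float(x) for x in w] for s, w in zip(sample_ids, W)},
        attribute_kind=kind_map,
        planted_guild=planted_guild,
        discriminative_otus=discriminative,
        ultra_rare_otus=[otu_ids[j] for j in np.flatnonzero(ultra)],
    )
    return table, meta, truth


#: canned fixture conditions shared by the whole test suite
FIXTURE_SEED = 20_240_101


def fixture_small() -> tuple[OtuTable, SampleMetadata, GroundTruth]:
    """Deterministic 60-sample x 300-OTU cohort with 3 guilds.

    An 18% minority of samples carries a marker community state
    (guild 0 dominant, mutually coherent); the planted attribute flags
    exactly that state, so it is locally aggregated by construction.
    The background mixes the other two guilds smoothly (no secondary
    tight clusters).  Three null attributes are independent of
    everything; one carries missing-data cells.
    """
    config = SynthConfig(
        n_samples=60,
        n_otus=300,
        n_guilds=3,
        dirichlet_alpha=(0.2, 2.5, 2.5),
        marker_fraction=0.18,
        marker_alpha=(20.0, 1.5, 1.5),
        attributes=[
            AttributeSpec("PLANTED_GUILD", kind="planted", guild=0, threshold=0.5),
            AttributeSpec("NULL_BINARY", kind="null", n_levels=2),
            AttributeSpec("NULL_TRI", kind="null", n_levels=3),
            AttributeSpec("NULL_SPARSE", kind="null", n_levels=2, na_frac=0.2),
        ],
        seed=FIXTURE_SEED,
    )
    return generate(config)


def classification_task(
    n_samples: int = 400,
    n_otus: int = 500,
    n_informative: int = 5,
    effect: float = 2.0,
    d: int = 64,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Binary task with a few discriminative OTUs among many decoys.

    Returns ``(X, E, y, informative_idx)``: log-scale-style abundance
    features X (n_samples x n_otus), a random embedding matrix E
    (n_otus x d), labels y, and the indices of the informative OTUs,
    which are more prevalent and more abundant in the positive class by
    ``effect`` log-units.
    """
    rng = np.random.default_rng(seed)
    y = (rng.random(n_samples) < 0.5).astype(int)
    X = np.abs(rng.normal(2.0, 1.0, size=(n_samples, n_otus)))
    X *= rng.random((n_samples, n_otus)) < 0.3  # sparse background presence
    informative = rng.choice(n_otus, size=n_informative, replace=False)
    for j in informative:
        present = rng.random(n_samples) < np.where(y == 1, 0.9, 0.1)
        X[:, j] = present * np.abs(rng.normal(2.0 + effect, 0.5, size=n_samples))
    E = rng.normal(0.0, 1.0 / np.sqrt(d), size=(n_otus, d))
    return X, E, y, informative
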