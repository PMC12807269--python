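"""Reading, filtering and normalising OTU tables and sample metadata.

The on-disk dialect is the classic tab-separated OTU table: one row per
OTU, first header cell ``#OTU ID``, one column per sample, integer read
counts, and an optional trailing ``taxonomy`` column.  A BIOM-derived TSV
export (same layout preceded by a ``# Constructed from biom file`` comment
line) is accepted as the ``biom_tsv`` dialect.  In memory everything is
oriented samples x OTUs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "OtuTable",
    "RelAbundanceTable",
    "SampleMetadata",
    "DEFAULT_SYNONYMS",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "filter_dataset",
    "to_relative_abundance",
    "harmonize_metadata",
]

#: Canonical spellings for missing-data and boolean sub-attributes.
DEFAULT_SYNONYMS: dict[str, str] = {
    "Unspecified": "NA",
    "unspecified": "NA",
    "Unknown": "NA",
    "Not sure": "NA",
    "no_data": "NA",
    "nan": "NA",
    "Missing: Not provided": "NA",
    "Not provided": "NA",
    "true": "Yes",
    "false": "No",
}


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclass
class OtuTable:
    """Sparse sample x OTU read-count matrix.

    Parameters
    ----------
    sample_ids, otu_ids
        Unique identifiers for the two axes.
    counts
        Non-negative integer matrix, shape ``(n_samples, n_otus)``.
    taxonomy
        Optional map from OTU id to an opaque taxonomy string.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: sp.csr_matrix
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative read count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def depths(self) -> np.ndarray:
        """Total read count per sample."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def prevalence(self) -> np.ndarray:
        """Number of samples with a nonzero count, per OTU."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()


@dataclass
class RelAbundanceTable:
    """Relative abundances r_ij = counts_ij / depth_i, same axes as OtuTable."""

    sample_ids: list[str]
    otu_ids: list[str]
    rel: sp.csr_matrix
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.rel = sp.csr_matrix(self.rel)
        sums = np.asarray(self.rel.sum(axis=1)).ravel()
        nonempty = sums > 0
        if nonempty.any() and np.abs(sums[nonempty] - 1.0).max() > 1e-9:
            raise ValueError("relative abundances of a sample do not sum to 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)


@dataclass
class SampleMetadata:
    """Categorical sample attributes; cells are sub-attribute strings."""

    sample_ids: list[str]
    attributes: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample")
        known = set(self.sample_ids)
        for attr, cells in self.attributes.items():
            unknown = set(cells) - known
            if unknown:
                raise ValueError(
                    f"attribute {attr!r} refers to unknown sample(s): {sorted(unknown)[:3]}"
                )

    def values(self, attribute: str) -> list[str]:
        """Sub-attribute value for every sample (``"NA"`` where absent)."""
        cells = self.attributes[attribute]
        return [cells.get(s, "NA") for s in self.sample_ids]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(index=pd.Index(self.sample_ids, name="#SampleID"))
        for attr in self.attributes:
            df[attr] = self.values(attr)
        return df


def _read_table_frame(path: str | Path, dialect: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and not line.startswith("#OTU ID"):
                skip += 1
            else:
                break
    if dialect == "classic_tsv" and skip:
        raise ValueError(f"unexpected comment lines in classic_tsv file {path}")
    return pd.read_csv(path, sep="\t", skiprows=skip, header=0, dtype=str)


def read_otu_table(path: str | Path, dialect: str = "classic_tsv") -> OtuTable:
    """Read a classic or BIOM-exported TSV OTU table.

    The on-disk layout is OTUs x samples; the returned table is oriented
    samples x OTUs.  Duplicate ids and non-numeric count cells raise
    ``ValueError``.
    """
    if dialect not in ("classic_tsv", "biom_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_table_frame(path, dialect)
    if df.columns[0] != "#OTU ID":
        raise ValueError(f"first header cell must be '#OTU ID', got {df.columns[0]!r}")
    taxonomy_col = None
    if len(df.columns) > 1 and df.columns[-1].lower() == "taxonomy":
        taxonomy_col = df.columns[-1]
    otu_ids = df["#OTU ID"].astype(str).tolist()
    _check_unique(otu_ids, "OTU")
    sample_cols = [c for c in df.columns[1:] if c != taxonomy_col]
    _check_unique(sample_cols, "sample")
    counts = np.zeros((len(sample_cols), len(otu_ids)), dtype=np.int64)
    for k, col in enumerate(sample_cols):
        try:
            vals = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(
                f"non-numeric count in column {col!r}, OTU {otu_ids[bad]!r}"
            ) from None
        counts[k, :] = np.asarray(vals, dtype=np.float64).round().astype(np.int64)
    taxonomy = None
    if taxonomy_col is not None:
        taxonomy = dict(zip(otu_ids, df[taxonomy_col].astype(str)))
    return OtuTable(sample_cols, otu_ids, sp.csr_matrix(counts), taxonomy)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write the classic TSV dialect (OTU rows, optional taxonomy column)."""
    dense = table.counts.toarray().T  # OTUs x samples on disk
    df = pd.DataFrame(dense, columns=table.sample_ids)
    df.insert(0, "#OTU ID", table.otu_ids)
    if table.taxonomy is not None:
        df["taxonomy"] = [table.taxonomy.get(o, "") for o in table.otu_ids]
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample-metadata TSV with a ``#SampleID`` leading column."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str).fillna("NA")
    if df.columns[0] != "#SampleID":
        raise ValueError(f"first header cell must be '#SampleID', got {df.columns[0]!r}")
    sample_ids = df["#SampleID"].astype(str).tolist()
    attributes = {
        attr: dict(zip(sample_ids, df[attr].astype(str))) for attr in df.columns[1:]
    }
    return SampleMetadata(sample_ids, attributes)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.to_dataframe().to_csv(path, sep="\t")


def filter_dataset(
    table: OtuTable, min_depth: int = 10_000, min_prevalence: int = 2
) -> OtuTable:
    """Depth/prevalence screen: keep samples with total reads strictly above
    ``min_depth``, then OTUs present in at least ``min_prevalence`` of the
    retained samples.  Sample filter runs first so prevalence is counted in
    the retained cohort.  Idempotent for fixed thresholds.
    """
    keep_s = table.depths() > min_depth
    if not keep_s.any():
        raise ValueError(f"no sample has depth > {min_depth}")
    counts = table.counts[keep_s.nonzero()[0], :]
    prev = np.asarray((counts > 0).sum(axis=0)).ravel()
    keep_o = prev >= min_prevalence
    counts = counts[:, keep_o.nonzero()[0]]
    sample_ids = [s for s, k in zip(table.sample_ids, keep_s) if k]
    otu_ids = [o for o, k in zip(table.otu_ids, keep_o) if k]
    taxonomy = None
    if table.taxonomy is not None:
        taxonomy = {o: table.taxonomy[o] for o in otu_ids if o in table.taxonomy}
    return OtuTable(sample_ids, otu_ids, counts, taxonomy)


def to_relative_abundance(table: OtuTable) -> RelAbundanceTable:
    """Divide each sample's counts by its depth.  Zero-depth samples raise."""
    depths = table.depths()
    if (depths == 0).any():
        bad = table.sample_ids[int(np.argmax(depths == 0))]
        raise ValueError(f"sample {bad!r} has zero depth")
    rel = sp.csr_matrix(table.counts, dtype=np.float64)
    rel = sp.diags(1.0 / depths) @ rel
    return RelAbundanceTable(
        list(table.sample_ids), list(table.otu_ids), sp.csr_matrix(rel), table.taxonomy
    )


def harmonize_metadata(
    raw: SampleMetadata, synonym_map: dict[str, str] | None = None
) -> SampleMetadata:
    """Map synonymous sub-attribute spellings onto canonical forms.

    The default map folds the common missing-data spellings into ``"NA"``
    and ``true``/``false`` into ``Yes``/``No``; unmapped values pass through
    unchanged, so the operation is idempotent whenever the map's canonical
    values are fixed points (true for the default).
    """
    smap = DEFAULT_SYNONYMS if synonym_map is None else synonym_map
    for k, v in smap.items():
        if v in smap and smap[v] != v:
            raise ValueError(f"canonical value {v!r} is not a fixed point of the map")
    attributes = {
        attr: {s: smap.get(v, v) for s, v in cells.items()}
        for attr, cells in raw.attributes.items()
    }
    return SampleMetadata(list(raw.sample_ids), attributes)
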