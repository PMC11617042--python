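"""Tabular and graph I/O with identity/shape validation.

The pipeline starts from plain abundance tables: features (taxa or
functional pathways) in rows, samples in columns, tab-separated, UTF-8,
'.' decimal.  Sample alignment between tables and metadata is always by
sample identifier, never by column position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "StudyMetadata",
    "read_abundance_table",
    "read_metadata",
    "write_abundance_table",
    "write_metadata",
    "write_network",
    "read_network",
    "align",
]


class TableIdentityError(ValueError):
    """Duplicate feature or sample identifiers."""


class TableShapeError(ValueError):
    """Table too small to analyse."""


class SampleAlignmentError(KeyError):
    """Table contains samples absent from the metadata."""


@dataclass
class AbundanceTable:
    """Non-negative feature-by-sample abundance matrix.

    ``counts`` holds integer read counts for taxa tables; pathway
    abundance tables may carry non-negative reals.  Feature order is
    preserved as given.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    kind: str = "taxa"

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts, dtype=float)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise TableIdentityError("duplicate feature identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableIdentityError("duplicate sample identifiers")
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise TableShapeError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(self.feature_ids) < 2 or len(self.sample_ids) < 2:
            raise TableShapeError("need at least 2 features and 2 samples")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("non-numeric or non-finite abundance value")
        if np.any(self.counts < 0):
            raise ValueError("negative abundance value")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        """Return a table restricted to ``sample_ids`` (id-based, order as given)."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise SampleAlignmentError(f"unknown samples: {missing}")
        cols = [idx[s] for s in sample_ids]
        return AbundanceTable(
            list(self.feature_ids), list(sample_ids), self.counts[:, cols], self.kind
        )

    def relative_abundance(self, scale: float = 1e6) -> np.ndarray:
        """Per-sample total-sum scaling (CPM when scale=1e6)."""
        totals = self.counts.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("sample with zero total abundance")
        return self.counts / totals * scale


@dataclass
class StudyMetadata:
    """Per-sample design: a two-level group label plus numeric covariates
    and phenotype measurements (e.g. body weight, FITC-dextran intensity,
    ALT, LPS)."""

    sample_ids: list[str]
    group: pd.Series
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    phenotypes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise TableIdentityError("duplicate sample identifiers in metadata")
        self.group = pd.Series(self.group)
        self.group.index = pd.Index(self.sample_ids)
        levels = pd.unique(self.group.astype(str))
        if len(levels) != 2:
            raise ValueError(f"group must have exactly 2 levels, got {list(levels)}")
        counts = self.group.value_counts()
        if counts.min() < 2:
            raise ValueError("both group levels need at least 2 samples")
        for name, df in (("covariates", self.covariates), ("phenotypes", self.phenotypes)):
            df = pd.DataFrame(df)
            if not df.empty:
                df.index = pd.Index(self.sample_ids)
                arr = df.to_numpy()
                if not np.issubdtype(arr.dtype, np.number):
                    raise ValueError(f"non-numeric value in {name}")
            setattr(self, name, df)

    @property
    def group_levels(self) -> list[str]:
        return list(pd.unique(self.group.astype(str)))

    def samples_in_group(self, level: str) -> list[str]:
        return [s for s in self.sample_ids if str(self.group[s]) == str(level)]

    def subset(self, sample_ids: list[str]) -> "StudyMetadata":
        missing = [s for s in sample_ids if s not in set(self.sample_ids)]
        if missing:
            raise SampleAlignmentError(f"samples absent from metadata: {missing}")
        return StudyMetadata(
            list(sample_ids),
            self.group.loc[sample_ids],
            self.covariates.loc[sample_ids] if not self.covariates.empty else pd.DataFrame(),
            self.phenotypes.loc[sample_ids] if not self.phenotypes.empty else pd.DataFrame(),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_abundance_table(path, kind: str = "taxa") -> AbundanceTable:
    """Read a TSV abundance table (first column feature ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    feature_ids = df.iloc[:, 0].astype(str).tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    try:
        counts = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric abundance cell in {path}: {exc}") from exc
    return AbundanceTable(feature_ids, sample_ids, counts, kind=kind)


def write_abundance_table(table: AbundanceTable, path) -> None:
    df = table.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_metadata(
    path,
    group_col: str = "group",
    covariate_cols: list[str] | None = None,
    phenotype_cols: list[str] | None = None,
) -> StudyMetadata:
    """Read per-sample metadata TSV (first column sample_id).

    Numeric columns not named in ``covariate_cols`` default to phenotypes
    unless listed as covariates.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    sample_ids = df.iloc[:, 0].astype(str).tolist()
    df = df.set_index(df.columns[0])
    if group_col not in df.columns:
        raise ValueError(f"metadata lacks group column {group_col!r}")
    numeric_cols = [c for c in df.columns if c != group_col]
    covariate_cols = covariate_cols if covariate_cols is not None else []
    if phenotype_cols is None:
        phenotype_cols = [c for c in numeric_cols if c not in covariate_cols]
    for cols in (covariate_cols, phenotype_cols):
        for c in cols:
            if c not in df.columns:
                raise ValueError(f"metadata lacks column {c!r}")
            vals = pd.to_numeric(df[c], errors="coerce")
            if vals.isna().any():
                raise ValueError(f"non-numeric value in metadata column {c!r}")
            df[c] = vals
    return StudyMetadata(
        sample_ids,
        df[group_col].astype(str),
        df[covariate_cols] if covariate_cols else pd.DataFrame(),
        df[phenotype_cols] if phenotype_cols else pd.DataFrame(),
    )


def write_metadata(metadata: StudyMetadata, path) -> None:
    df = pd.DataFrame({"group": metadata.group.astype(str)})
    for src in (metadata.covariates, metadata.phenotypes):
        for c in src.columns:
            df[c] = src[c]
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def align(table: AbundanceTable, metadata: StudyMetadata) -> tuple[AbundanceTable, StudyMetadata]:
    """Align a table and metadata by sample id.

    Metadata samples missing from the table are dropped with a warning;
    table samples missing from the metadata are a hard error.
    """
    table_samples = set(table.sample_ids)
    meta_samples = set(metadata.sample_ids)
    missing = sorted(table_samples - meta_samples)
    if missing:
        raise SampleAlignmentError(f"table samples absent from metadata: {missing}")
    extra = sorted(meta_samples - table_samples)
    if extra:
        warnings.warn(f"metadata has {len(extra)} samples not in the table; dropped")
    order = list(table.sample_ids)
    return table, metadata.subset(order)


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ("source", "target", "rho", "p", "sign")


def write_network(network, path, format: str = "edgelist") -> None:
    """Write a co-occurrence network as an edge-list TSV or GML.

    Edge attributes (rho, p, sign) round-trip exactly through either
    format; isolated nodes survive GML but not the edge list.
    """
    graph = network if isinstance(network, nx.Graph) else network.graph
    if format == "edgelist":
        rows = [
            {"source": u, "target": v, "rho": d["rho"], "p": d["p"], "sign": d["sign"]}
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "gml":
        nx.write_gml(graph, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "edgelist") -> nx.Graph:
    if format == "edgelist":
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(
                row.source, row.target, rho=float(row.rho), p=float(row.p), sign=int(row.sign)
            )
        return g
    if format == "gml":
        return nx.read_gml(path)
    raise ValueError(f"unknown network format {format!r}")
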