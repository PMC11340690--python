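"""Count tables, sample metadata and taxon lineages: the pipeline's file layer.

All delimited-text formats used throughout the package are plain TSV/CSV with
one header row and one identifier column ("flat" BIOM exports fall in this
dialect).  The canonical in-memory orientation is samples x features
(documents x terms); readers accept either file orientation but never guess —
the caller declares it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SampleMetadata",
    "TaxaTable",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "read_taxa_table",
    "align_tables",
]

RANK_COLUMNS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus")


@dataclass
class CountTable:
    """Samples x features abundance matrix.

    Counts are nonnegative; integers at ingest, fractional downstream (e.g.
    topic abundances).  Identifiers are opaque strings, unique within each
    axis.  Every sample must have a positive total.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValueError(f"duplicate sample identifiers: {dupes}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dupes = _duplicates(self.feature_ids)
            raise ValueError(f"duplicate feature identifiers: {dupes}")
        neg = np.argwhere(self.counts < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}: {self.counts[i, j]}"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite values")
        empty = np.flatnonzero(self.counts.sum(axis=1) <= 0)
        if empty.size:
            names = [self.sample_ids[i] for i in empty]
            raise ValueError(f"samples with zero total reads: {names}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(dtype=float))

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(sample_ids), list(self.feature_ids), self.counts[idx])

    def select_features(self, feature_ids: Sequence[str]) -> "CountTable":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return CountTable(list(self.sample_ids), list(feature_ids), self.counts[:, idx])


@dataclass
class SampleMetadata:
    """Per-sample metadata with a binary group factor (e.g. RRMS vs HC)."""

    sample_ids: list[str]
    group: list[str]
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.group = [str(g) for g in self.group]
        if len(self.sample_ids) != len(self.group):
            raise ValueError("sample_ids and group must have equal length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"duplicate sample identifiers: {_duplicates(self.sample_ids)}")
        if any(g == "" for g in self.group):
            bad = [s for s, g in zip(self.sample_ids, self.group) if g == ""]
            raise ValueError(f"samples with empty group label: {bad}")

    @property
    def levels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(g, None)
        return list(seen)

    def require_binary(self) -> tuple[str, str]:
        """Validate a two-level design with >=2 samples per level; return (reference, case) levels in first-seen order."""
        levels = self.levels
        if len(levels) != 2:
            raise ValueError(f"expected exactly 2 group levels, found {levels}")
        for lev in levels:
            if self.group.count(lev) < 2:
                raise ValueError(f"group level {lev!r} has fewer than 2 samples")
        return levels[0], levels[1]

    def select(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        cov = self.covariates.iloc[idx] if self.covariates is not None else None
        return SampleMetadata(list(sample_ids), [self.group[i] for i in idx], cov)


@dataclass
class TaxaTable:
    """Feature lineages, Kingdom..Genus, as plain strings."""

    feature_ids: list[str]
    ranks: pd.DataFrame  # index = feature_ids, columns subset of RANK_COLUMNS

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        if "Genus" not in self.ranks.columns:
            raise ValueError("taxa table must contain a Genus column")

    def genus_of(self, feature_id: str) -> str:
        return str(self.ranks.loc[feature_id, "Genus"]).strip()


def _duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in ids:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


def _read_delimited(path: str | Path, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return df


def read_count_table(
    path: str | Path,
    orientation: str = "samples-in-rows",
    sep: str | None = None,
) -> CountTable:
    """Read a delimited count table into samples x features orientation.

    ``orientation`` declares the *file* layout ("samples-in-rows" or
    "features-in-rows"); it is never auto-detected.
    """
    if orientation not in ("samples-in-rows", "features-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(path, sep)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(f"non-numeric cell at row {bad!r}, column {col!r} in {path}") from None
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative value at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
        )
    if orientation == "features-in-rows":
        df = pd.DataFrame(values.T, index=df.columns, columns=df.index)
    else:
        df = pd.DataFrame(values, index=df.index, columns=df.columns)
    return CountTable.from_frame(df)


def write_count_table(table: CountTable, path: str | Path, sep: str = "\t") -> None:
    """Write samples-in-rows TSV; integer-valued tables round-trip bit-exactly."""
    df = table.to_frame()
    if np.allclose(table.counts, np.round(table.counts)) and np.abs(table.counts).max() < 2**53:
        df = df.astype(np.int64)
    df.to_csv(path, sep=sep, index_label="sample_id", float_format="%.10g")


def read_metadata(
    path: str | Path,
    group_column: str,
    sep: str | None = None,
) -> SampleMetadata:
    """Read per-sample metadata keyed by the first (identifier) column.

    Samples absent from the companion count table are retained here;
    reconciliation happens in :func:`align_tables`.
    """
    df = _read_delimited(path, sep)
    if group_column not in df.columns:
        raise ValueError(
            f"group column {group_column!r} not found; available columns: {list(df.columns)}"
        )
    group = df[group_column].fillna("").astype(str).str.strip()
    empty = group[group == ""].index.tolist()
    if empty:
        raise ValueError(f"samples with empty group label: {empty}")
    covars = df.drop(columns=[group_column])
    return SampleMetadata(
        list(df.index), list(group), covars if covars.shape[1] else None
    )


def read_taxa_table(path: str | Path, sep: str | None = None) -> TaxaTable:
    df = _read_delimited(path, sep)
    return TaxaTable(list(df.index), df)


def align_tables(
    table: CountTable, meta: SampleMetadata
) -> tuple[CountTable, SampleMetadata, int]:
    """Restrict table and metadata to their shared samples, in table order.

    Returns the aligned pair plus the number of samples dropped (from either
    side) so callers can log attrition.
    """
    meta_set = set(meta.sample_ids)
    shared = [s for s in table.sample_ids if s in meta_set]
    if not shared:
        raise ValueError("count table and metadata share no sample identifiers")
    dropped = (table.n_samples - len(shared)) + (len(meta.sample_ids) - len(shared))
    if dropped == 0 and shared == meta.sample_ids:
        return table, meta, 0
    return table.select_samples(shared), meta.select(shared), dropped
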