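"""Genus aggregation, low-abundance filtering and total-sum scaling.

The preprocessing chain mirrors common practice for 16S genus tables:
aggregate amplicon features to genus, drop genera whose pooled relative
abundance (genus total reads / grand total reads, strict ``<``) falls below a
small cutoff, then rescale each sample to a fixed total (TSS).  Filtering is
applied to each cohort independently; cohorts are never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables_io import CountTable, TaxaTable

__all__ = ["FilterReport", "aggregate_to_genus", "filter_low_abundance", "tss_normalize"]


@dataclass
class FilterReport:
    n_features_before: int
    n_features_after: int
    removed_ids: list[str]
    threshold: float

    def __post_init__(self) -> None:
        if self.n_features_after != self.n_features_before - len(self.removed_ids):
            raise ValueError("inconsistent filter report")

    def to_tsv(self) -> str:
        lines = [
            f"n_features_before\t{self.n_features_before}",
            f"n_features_after\t{self.n_features_after}",
            f"threshold\t{self.threshold!r}",
            f"criterion\tpooled relative abundance < threshold (strict)",
        ]
        lines += [f"removed\t{fid}" for fid in self.removed_ids]
        return "\n".join(lines) + "\n"


def aggregate_to_genus(table: CountTable, taxa: TaxaTable) -> CountTable:
    """Sum feature columns sharing a genus label; read totals are conserved.

    Genus order follows first appearance in the feature list.  Every feature
    must have a lineage row with a non-empty genus.
    """
    known = set(taxa.feature_ids)
    missing = [f for f in table.feature_ids if f not in known]
    if missing:
        raise ValueError(f"features missing from taxa table: {missing}")
    genus_order: list[str] = []
    genus_idx: dict[str, int] = {}
    col_genus = []
    for f in table.feature_ids:
        g = taxa.genus_of(f)
        if not g or g.lower() in ("nan", "na"):
            raise ValueError(f"feature {f!r} has an empty genus rank")
        if g not in genus_idx:
            genus_idx[g] = len(genus_order)
            genus_order.append(g)
        col_genus.append(genus_idx[g])
    out = np.zeros((table.n_samples, len(genus_order)))
    np.add.at(out.T, col_genus, table.counts.T)
    return CountTable(list(table.sample_ids), genus_order, out)


def filter_low_abundance(
    table: CountTable, threshold: float = 1e-5
) -> tuple[CountTable, FilterReport]:
    """Drop features with pooled relative abundance strictly below ``threshold``.

    The pooled relative abundance of a feature is its total reads across all
    samples divided by the grand total.  Samples are untouched.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    totals = table.counts.sum(axis=0)
    grand = totals.sum()
    keep = totals / grand >= threshold
    removed = [f for f, k in zip(table.feature_ids, keep) if not k]
    if not keep.any():
        raise ValueError(
            f"threshold {threshold} removes every feature; input too sparse for this cutoff"
        )
    report = FilterReport(table.n_features, int(keep.sum()), removed, threshold)
    if not removed:
        return table, report
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    out = CountTable(list(table.sample_ids), kept_ids, table.counts[:, keep])
    return out, report


def tss_normalize(table: CountTable, scale: float = 1e6) -> CountTable:
    """Rescale each sample to a fixed total (total-sum scaling).

    Idempotent at fixed scale; ``scale=1`` yields relative abundances.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    sums = table.row_sums()
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise ValueError(f"zero-sum samples cannot be scaled: {[table.sample_ids[i] for i in zero]}")
    values = table.counts * (scale / sums)[:, None]
    return CountTable(list(table.sample_ids), list(table.feature_ids), values)
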