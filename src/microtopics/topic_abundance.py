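"""Assign each sample's reads to topics: gamma times read depth.

The product of the per-document topic probabilities and the sample's total
read count yields a samples x topics abundance table that can re-enter the
pipeline anywhere a count table is accepted (notably differential abundance).
Fractional values are the default; ``rounding="nearest"`` applies
largest-remainder apportionment so each row still sums to the integer depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lda_vem import LdaModel
from .tables_io import CountTable

__all__ = ["TopicAbundanceTable", "assign_reads_to_topics", "largest_remainder_round"]


@dataclass
class TopicAbundanceTable:
    sample_ids: list[str]
    topic_ids: list[str]
    values: np.ndarray  # (D, K), nonnegative
    depths: np.ndarray  # (D,)
    rounding: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("topic abundances must be nonnegative")
        rel = np.abs(self.values.sum(axis=1) - self.depths) / np.maximum(self.depths, 1.0)
        if rel.max(initial=0.0) > 1e-6:
            bad = self.sample_ids[int(np.argmax(rel))]
            raise ValueError(f"row sum deviates from sample depth for {bad}")

    def as_count_table(self) -> CountTable:
        return CountTable(list(self.sample_ids), list(self.topic_ids), self.values)


def largest_remainder_round(row: np.ndarray, total: int) -> np.ndarray:
    """Round nonnegative values to integers preserving their sum.

    Floors every entry, then hands the remaining units to the largest
    fractional remainders (ties broken by lower index, deterministically).
    """
    row = np.asarray(row, dtype=float)
    floors = np.floor(row)
    short = int(round(total - floors.sum()))
    if short < 0:
        raise ValueError("row exceeds its target total")
    out = floors.copy()
    if short:
        remainders = row - floors
        order = np.lexsort((np.arange(row.size), -remainders))
        out[order[:short]] += 1
    return out


def assign_reads_to_topics(
    model: LdaModel,
    table: CountTable,
    rounding: str = "none",
    topic_prefix: str = "",
) -> TopicAbundanceTable:
    """value[d, k] = gamma[d, k] * depth[d], depths being the table row sums.

    Every model document must appear in the table; ``topic_prefix`` labels
    topics with their originating dataset (e.g. ``"exploratory:Topic 4"``) so
    cross-dataset reports stay unambiguous.
    """
    if rounding not in ("none", "nearest"):
        raise ValueError(f"unknown rounding {rounding!r}")
    missing = [d for d in model.doc_ids if d not in set(table.sample_ids)]
    if missing:
        raise ValueError(f"model documents absent from count table: {missing}")
    sub = table.select_samples(model.doc_ids)
    depths = sub.row_sums()
    values = model.gamma * depths[:, None]
    if rounding == "nearest":
        depths = np.round(depths)
        values = np.vstack(
            [largest_remainder_round(v, int(n)) for v, n in zip(values, depths)]
        )
    return TopicAbundanceTable(
        list(model.doc_ids), model.topic_ids(topic_prefix), values, depths, rounding
    )
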