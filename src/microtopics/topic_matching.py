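"""Cross-dataset validation of community types by cosine similarity.

Two cohorts retain different genus sets after filtering, so the topic-term
matrices are first re-expressed over the union vocabulary (absent genera get
probability zero; rows are NOT renormalised — renormalising would inflate
similarity between topics concentrated on shared taxa).  Topic pairs at or
above the cosine threshold form a bipartite match graph whose connected
components are the community types; matching is many-to-many by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .differential import DiffResult
from .lda_vem import LdaModel

__all__ = [
    "SimilarityMatrix",
    "MatchSet",
    "Community",
    "harmonize_vocabularies",
    "cosine_similarity",
    "match_topics",
    "validated_communities",
]


@dataclass
class SimilarityMatrix:
    rows: list[str]  # topic ids of model A
    cols: list[str]  # topic ids of model B
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError("similarity matrix shape mismatch")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("cosine of nonnegative vectors must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.cols)]
        for r, row in zip(self.rows, self.values):
            lines.append(r + "\t" + "\t".join(f"{v:.10g}" for v in row))
        return "\n".join(lines) + "\n"


@dataclass
class MatchSet:
    pairs: list[tuple[str, str, float]]  # (topic A, topic B, cosine)
    threshold: float
    communities: list[set[str]]

    def __post_init__(self) -> None:
        for a, b, c in self.pairs:
            if c < self.threshold:
                raise ValueError(f"pair ({a}, {b}) below threshold: {c}")
        matched = {t for a, b, _ in self.pairs for t in (a, b)}
        in_comm = set().union(*self.communities) if self.communities else set()
        if matched != in_comm:
            raise ValueError("communities must partition the matched topics")

    def to_tsv(self) -> str:
        lines = ["topic_A\ttopic_B\tcosine"]
        for a, b, c in self.pairs:
            lines.append(f"{a}\t{b}\t{c:.10g}")
        return "\n".join(lines) + "\n"


def harmonize_vocabularies(
    beta_A: np.ndarray,
    vocab_A: list[str],
    beta_B: np.ndarray,
    vocab_B: list[str],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Re-express both topic-term matrices over the union vocabulary.

    Terms are ordered: shared-and-A-only terms in A's order, then B-only
    terms in B's order.  Absent terms get probability zero; rows keep their
    original mass (no renormalisation).
    """
    set_A, set_B = set(vocab_A), set(vocab_B)
    if not set_A & set_B:
        raise ValueError("vocabularies are disjoint; nothing to compare")
    union = list(vocab_A) + [t for t in vocab_B if t not in set_A]
    pos = {t: i for i, t in enumerate(union)}
    out_A = np.zeros((beta_A.shape[0], len(union)))
    out_B = np.zeros((beta_B.shape[0], len(union)))
    out_A[:, [pos[t] for t in vocab_A]] = beta_A
    out_B[:, [pos[t] for t in vocab_B]] = beta_B
    return out_A, out_B, union


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (|u| |v|); in [0, 1] for nonnegative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(u @ v / (nu * nv))


def match_topics(
    model_A: LdaModel,
    model_B: LdaModel,
    threshold: float = 0.80,
    prefix_A: str = "A",
    prefix_B: str = "B",
) -> tuple[SimilarityMatrix, MatchSet]:
    """Full K_A x K_B cosine matrix over the harmonised vocabulary; pairs at
    >= threshold (inclusive) retained; communities are connected components
    of the bipartite match graph (many-to-many allowed)."""
    hA, hB, _ = harmonize_vocabularies(model_A.beta, model_A.vocab,
                                       model_B.beta, model_B.vocab)
    nA = np.linalg.norm(hA, axis=1)
    nB = np.linalg.norm(hB, axis=1)
    values = (hA @ hB.T) / np.outer(nA, nB)
    ids_A = model_A.topic_ids(prefix_A)
    ids_B = model_B.topic_ids(prefix_B)
    sim = SimilarityMatrix(ids_A, ids_B, values)
    pairs = [
        (ids_A[i], ids_B[j], float(sim.values[i, j]))
        for i in range(len(ids_A))
        for j in range(len(ids_B))
        if sim.values[i, j] >= threshold
    ]
    graph = nx.Graph()
    graph.add_edges_from((a, b) for a, b, _ in pairs)
    communities = sorted(
        (set(c) for c in nx.connected_components(graph)),
        key=lambda c: sorted(c)[0],
    )
    return sim, MatchSet(pairs, threshold, communities)


@dataclass
class Community:
    """One matched community type with per-topic significance annotations."""

    topics: set[str]
    significant: dict[str, bool]
    direction: dict[str, float]  # sign of the per-topic effect in its own cohort
    validated: bool

    def to_row(self) -> str:
        members = ",".join(sorted(self.topics))
        sig = ",".join(t for t in sorted(self.topics) if self.significant.get(t))
        return f"{members}\t{sig or '-'}\t{int(self.validated)}"


def validated_communities(
    matches: MatchSet,
    diff_A: list[DiffResult],
    diff_B: list[DiffResult],
    rule: str = "both-significant",
) -> list[Community]:
    """Annotate each community with member-topic significance and mark it
    validated.

    ``rule="exploratory-significant"`` validates a community containing any
    significant exploratory (A) topic; ``"both-significant"`` additionally
    requires that topic to be matched to a significant validation (B) topic.
    The second rule's validated set is a subset of the first's.
    """
    if rule not in ("exploratory-significant", "both-significant"):
        raise ValueError(f"unknown rule {rule!r}")
    sig = {r.feature_id: r.significant for r in diff_A + diff_B}
    eff = {r.feature_id: r.effect for r in diff_A + diff_B}
    known = set(sig)
    matched_topics = {t for c in matches.communities for t in c}
    unknown = matched_topics - known
    if unknown:
        raise ValueError(f"topics missing from differential results: {sorted(unknown)}")
    a_side = {a for a, _, _ in matches.pairs}
    out = []
    for comm in matches.communities:
        members_A = comm & a_side
        members_B = comm - a_side
        if rule == "exploratory-significant":
            ok = any(sig[t] for t in members_A)
        else:
            ok = any(
                sig[a] and sig[b]
                for a, b, _ in matches.pairs
                if a in comm and b in comm
            )
        out.append(
            Community(
                topics=set(comm),
                significant={t: sig[t] for t in comm},
                direction={t: float(np.sign(eff[t])) for t in comm},
                validated=bool(ok),
            )
        )
    return out
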