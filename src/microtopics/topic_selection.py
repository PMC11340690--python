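"""Topic-number selection by grid search over K.

Two standard minimisation metrics are computed per candidate K:

* the density metric: mean pairwise cosine similarity among topic-term rows
  (well-separated topics score low; duplicated topics push it toward 1);
* the divergence metric: symmetric KL between the normalised singular-value
  spectrum of the topic-term matrix and the normalised document-length-
  weighted topic mass (the two agree when the factorisation is balanced).

Per-dataset optima are combined by averaging each dataset's per-metric argmin
and rounding to the nearest integer (half away from zero), giving the
pipeline's single K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lda_vem import LdaModel, VemSettings, fit_lda
from .tables_io import CountTable

__all__ = [
    "TuningResult",
    "cao_juan_metric",
    "arun_metric",
    "tune_topic_number",
    "combine_dataset_optima",
]

_KL_FLOOR = 1e-12


@dataclass
class TuningResult:
    grid: list[int]
    cao_juan: list[float]
    arun: list[float]
    settings: VemSettings
    failures: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.grid) == len(self.cao_juan) == len(self.arun)):
            raise ValueError("metric sequences must match the grid length")

    def best_k(self, metric: str) -> int:
        values = {"cao_juan": self.cao_juan, "arun": self.arun}[metric]
        ok = [(v, k) for k, v in zip(self.grid, values) if np.isfinite(v)]
        if not ok:
            raise ValueError(f"no successful fits to minimise {metric}")
        return min(ok)[1]

    @property
    def best_K_per_metric(self) -> dict[str, int]:
        return {m: self.best_k(m) for m in ("cao_juan", "arun")}

    def to_tsv(self) -> str:
        lines = ["K\tcao_juan\tarun"]
        for k, c, a in zip(self.grid, self.cao_juan, self.arun):
            lines.append(f"{k}\t{c:.10g}\t{a:.10g}")
        return "\n".join(lines) + "\n"


def cao_juan_metric(model: LdaModel) -> float:
    """Mean pairwise cosine similarity over all unordered topic pairs of beta.

    In [0, 1] for probability rows; lower means better-separated topics.
    """
    beta = model.beta
    K = beta.shape[0]
    if K < 2:
        raise ValueError("density metric needs at least 2 topics")
    norms = np.linalg.norm(beta, axis=1)
    cos = (beta @ beta.T) / np.outer(norms, norms)
    iu = np.triu_indices(K, k=1)
    return float(cos[iu].mean())


def arun_metric(model: LdaModel, doc_lengths: np.ndarray) -> float:
    """Symmetric KL between the topic-term singular spectrum and the
    document-length-weighted topic mass.

    Both vectors are sorted descending and normalised to sum 1; entries are
    floored at 1e-12 before the logs.  Invariant to rescaling doc_lengths.
    """
    doc_lengths = np.asarray(doc_lengths, dtype=float)
    if doc_lengths.ndim != 1 or doc_lengths.shape[0] != model.n_docs:
        raise ValueError("doc_lengths must be one value per document")
    if np.any(doc_lengths <= 0):
        raise ValueError("doc_lengths must be positive")
    if model.n_topics < 2:
        raise ValueError("divergence metric needs at least 2 topics")
    c1 = np.linalg.svd(model.beta, compute_uv=False)
    c2 = doc_lengths @ model.gamma
    c1 = np.sort(c1)[::-1]
    c2 = np.sort(c2)[::-1]
    c1 = np.maximum(c1 / c1.sum(), _KL_FLOOR)
    c2 = np.maximum(c2 / c2.sum(), _KL_FLOOR)
    return float(np.sum(c1 * np.log(c1 / c2)) + np.sum(c2 * np.log(c2 / c1)))


def tune_topic_number(
    table: CountTable,
    grid: list[int] | range,
    settings: VemSettings | None = None,
) -> TuningResult:
    """Fit one model per candidate K (same seed policy, no restarts) and
    evaluate both metrics.  A failed fit is recorded and excluded from the
    argmin; the grid search continues."""
    settings = settings or VemSettings()
    settings = replace(settings, n_restarts=1)
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    doc_lengths = table.row_sums()
    cao, arun, failures = [], [], {}
    for K in grid:
        try:
            model = fit_lda(table, K, settings)
            cao.append(cao_juan_metric(model))
            arun.append(arun_metric(model, doc_lengths))
        except (ValueError, FloatingPointError) as exc:
            failures[K] = str(exc)
            cao.append(float("nan"))
            arun.append(float("nan"))
    return TuningResult(grid, cao, arun, settings, failures)


def combine_dataset_optima(results: list[TuningResult]) -> int:
    """Average every per-dataset, per-metric best K and round half away
    from zero to the nearest integer; the result is the pipeline's K."""
    if not results:
        raise ValueError("need at least one tuning result")
    best = [k for r in results for k in r.best_K_per_metric.values()]
    mean = float(np.mean(best))
    return int(np.floor(mean + 0.5))
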