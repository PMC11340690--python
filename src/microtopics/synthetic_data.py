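"""Synthetic genus-count cohorts drawn from the LDA generative process.

The generator emulates the statistical structure of paired 16S case-control
cohorts: D samples over V genera, K latent communities (topics), log-normally
uneven sequencing depths, a binary group label, a subset of topics whose
prior prevalence is multiplied in cases, and (for paired cohorts) a subset of
topic-term rows shared verbatim between an exploratory and a validation
dataset.  Every draw is deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .tables_io import CountTable, SampleMetadata

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_dataset", "generate_paired_datasets"]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    Defaults mirror the scale of typical genus-level case-control 16S
    studies: ~60 samples, ~170 genera, a handful of communities, mean depth
    2e4 reads with log-normal spread.  ``effect_size`` multiplies the
    Dirichlet prior mass of ``effect_topics`` in case samples (prevalence
    shift, not content shift); 1.0 means no group effect.
    """

    D: int = 60
    V: int = 170
    K: int = 8
    depth_mean: float = 2e4
    depth_sigma: float = 0.3  # sd of log depth
    alpha0: float = 0.5
    eta0: float = 0.1
    case_fraction: float = 0.5
    effect_topics: tuple[int, ...] = ()
    effect_size: float = 1.0
    shared_topics: tuple[int, ...] = ()
    seed: int = 0
    sample_prefix: str = "S"
    feature_prefix: str = "g"

    def __post_init__(self) -> None:
        if self.D < 2 or self.V < 2 or self.K < 1:
            raise ValueError("need D >= 2, V >= 2, K >= 1")
        if not all(0 <= t < self.K for t in self.effect_topics):
            raise ValueError(f"effect_topics must be in 0..{self.K - 1}")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")


@dataclass
class SyntheticDataset:
    """A generated cohort plus its ground truth (true beta and theta)."""

    table: CountTable
    meta: SampleMetadata
    true_beta: np.ndarray  # (K, V), rows on the simplex
    true_theta: np.ndarray  # (D, K), rows on the simplex
    spec: SyntheticSpec

    def write(self, directory: str | Path, name: str = "synthetic") -> None:
        from .tables_io import write_count_table

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_count_table(self.table, directory / f"{name}_counts.tsv")
        with open(directory / f"{name}_metadata.tsv", "w") as fh:
            fh.write("sample_id\tgroup\n")
            for s, g in zip(self.meta.sample_ids, self.meta.group):
                fh.write(f"{s}\t{g}\n")
        np.savetxt(directory / f"{name}_true_beta.tsv", self.true_beta, delimiter="\t")
        np.savetxt(directory / f"{name}_true_theta.tsv", self.true_theta, delimiter="\t")
        with open(directory / f"{name}_spec.txt", "w") as fh:
            for k, v in vars(self.spec).items():
                fh.write(f"{k}\t{v}\n")


def _draw_depths(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    mu = np.log(spec.depth_mean) - 0.5 * spec.depth_sigma**2
    depths = np.round(rng.lognormal(mu, spec.depth_sigma, size=spec.D))
    return np.maximum(depths, 1).astype(int)


def _draw_counts(
    spec: SyntheticSpec,
    beta: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    n_case = int(round(spec.case_fraction * spec.D))
    groups = ["case"] * n_case + ["control"] * (spec.D - n_case)
    alpha_base = np.full(spec.K, spec.alpha0)
    alpha_case = alpha_base.copy()
    for t in spec.effect_topics:
        alpha_case[t] *= spec.effect_size
    depths = _draw_depths(spec, rng)
    theta = np.empty((spec.D, spec.K))
    counts = np.empty((spec.D, spec.V))
    for d in range(spec.D):
        a = alpha_case if groups[d] == "case" else alpha_base
        theta[d] = rng.dirichlet(a) if spec.K > 1 else np.ones(1)
        p = theta[d] @ beta
        p = p / p.sum()  # guard accumulated rounding for the multinomial draw
        counts[d] = rng.multinomial(depths[d], p)
    return counts, theta, groups


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one cohort: beta_k ~ Dir(eta0), theta_d ~ Dir(alpha_d),
    counts_d ~ Multinomial(depth_d, beta^T theta_d)."""
    rng = np.random.default_rng(spec.seed)
    beta = rng.dirichlet(np.full(spec.V, spec.eta0), size=spec.K)
    counts, theta, groups = _draw_counts(spec, beta, rng)
    sample_ids = [f"{spec.sample_prefix}{d + 1}" for d in range(spec.D)]
    feature_ids = [f"{spec.feature_prefix}{v + 1}" for v in range(spec.V)]
    table = CountTable(sample_ids, feature_ids, counts)
    meta = SampleMetadata(sample_ids, groups)
    return SyntheticDataset(table, meta, beta, theta, spec)


def generate_paired_datasets(
    spec_A: SyntheticSpec,
    spec_B: SyntheticSpec,
    n_shared: int,
    seed: int,
    n_drop_features_B: int = 0,
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Draw an exploratory/validation cohort pair sharing topic content.

    The first ``n_shared`` topic-term rows of cohort B are cohort A's rows
    verbatim, so their cross-dataset cosine on true beta is exactly 1; the
    remaining topics are independent draws.  ``n_drop_features_B`` removes a
    random genus subset from B (rows renormalised) to emulate unequal genus
    retention between cohorts.  Requires equal V before dropping.
    """
    if n_shared > min(spec_A.K, spec_B.K):
        raise ValueError("n_shared exceeds a cohort's topic count")
    if spec_A.V != spec_B.V:
        raise ValueError("paired cohorts must start from the same vocabulary")
    if n_drop_features_B >= spec_B.V:
        raise ValueError("cannot drop the whole vocabulary of cohort B")
    seed_A = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
    seed_B = int(np.random.default_rng(seed + 1).integers(0, 2**31 - 1))
    spec_A = replace(spec_A, seed=seed_A, shared_topics=tuple(range(n_shared)),
                     sample_prefix=spec_A.sample_prefix or "A")
    ds_A = generate_dataset(spec_A)

    spec_B = replace(spec_B, seed=seed_B, shared_topics=tuple(range(n_shared)))
    rng_B = np.random.default_rng(spec_B.seed)
    beta_B = rng_B.dirichlet(np.full(spec_B.V, spec_B.eta0), size=spec_B.K)
    beta_B[:n_shared] = ds_A.true_beta[:n_shared]
    feature_ids = list(ds_A.table.feature_ids)
    if n_drop_features_B:
        drop = rng_B.choice(spec_B.V, size=n_drop_features_B, replace=False)
        keep = np.setdiff1d(np.arange(spec_B.V), drop)
        beta_B = beta_B[:, keep]
        beta_B /= beta_B.sum(axis=1, keepdims=True)
        feature_ids = [feature_ids[i] for i in keep]
        spec_B = replace(spec_B, V=len(keep))
    counts, theta, groups = _draw_counts(spec_B, beta_B, rng_B)
    prefix = spec_B.sample_prefix if spec_B.sample_prefix != spec_A.sample_prefix else "T"
    sample_ids = [f"{prefix}{d + 1}" for d in range(spec_B.D)]
    table = CountTable(sample_ids, feature_ids, counts)
    meta = SampleMetadata(sample_ids, groups)
    ds_B = SyntheticDataset(table, meta, beta_B, theta, spec_B)
    return ds_A, ds_B
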