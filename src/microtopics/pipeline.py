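"""End-to-end two-cohort workflow: preprocess, tune, fit, assign, test,
match, report.

The pipeline runs the same stages on an exploratory cohort (A) and a
validation cohort (B), then validates community types across cohorts.  Every
stage writes its inputs' provenance and outputs as TSV / plain text into the
run directory, and every source of randomness derives from the single
configured seed, so re-running the same configuration reproduces the run
directory byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

from .differential import DiffSettings, linda_test, results_to_tsv
from .lda_vem import LdaModel, VemSettings, fit_lda, save_model
from .preprocess import aggregate_to_genus, filter_low_abundance
from .tables_io import (
    CountTable,
    SampleMetadata,
    align_tables,
    read_count_table,
    read_metadata,
    read_taxa_table,
    write_count_table,
)
from .topic_abundance import assign_reads_to_topics
from .topic_matching import match_topics, validated_communities
from .topic_selection import combine_dataset_optima, tune_topic_number

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Flat configuration of one two-cohort run; all thresholds explicit."""

    table_a: str
    meta_a: str
    table_b: str
    meta_b: str
    out_dir: str
    taxa_a: str | None = None
    taxa_b: str | None = None
    group_column: str = "group"
    orientation: str = "samples-in-rows"
    n_topics: int | None = None  # fixed K skips tuning
    grid_min: int = 2
    grid_max: int = 10
    grid_step: int = 1
    filter_threshold: float = 1e-5
    tss_scale: float = 1e6
    cosine_threshold: float = 0.80
    p_threshold: float = 0.05
    q_threshold: float = 0.25
    rounding: str = "none"
    rule: str = "both-significant"
    max_em_iters: int = 100
    em_tol: float = 1e-4
    seed: int = 0
    label_a: str = "exploratory"
    label_b: str = "validation"

    def validate(self) -> None:
        for name in ("table_a", "meta_a", "table_b", "meta_b"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        for t in (self.cosine_threshold, self.p_threshold, self.q_threshold):
            if not 0 < t <= 1:
                raise ValueError("thresholds must lie in (0, 1]")
        if self.filter_threshold < 0 or self.tss_scale <= 0:
            raise ValueError("filter threshold must be >= 0 and TSS scale > 0")


_BOOL = {"true": True, "false": False, "1": True, "0": False}


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat key=value (or key<TAB>value) text config."""
    raw: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=") if "=" in line else line.partition("\t")
        raw[key.strip()] = value.strip()
    kwargs: dict[str, object] = {}
    for f in fields(RunConfig):
        if f.name not in raw:
            continue
        text = raw.pop(f.name)
        if "None" in f.type and text in ("None", ""):
            kwargs[f.name] = None
        elif f.type in ("int", "int | None"):
            kwargs[f.name] = int(text)
        elif f.type == "float":
            kwargs[f.name] = float(text)
        elif f.type == "bool":
            kwargs[f.name] = _BOOL[text.lower()]
        else:
            kwargs[f.name] = text
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    return RunConfig(**kwargs)  # type: ignore[arg-type]


def _load_cohort(
    cfg: RunConfig, table_path: str, meta_path: str, taxa_path: str | None
) -> tuple[CountTable, SampleMetadata, int]:
    table = read_count_table(table_path, orientation=cfg.orientation)
    meta = read_metadata(meta_path, group_column=cfg.group_column)
    if taxa_path:
        table = aggregate_to_genus(table, read_taxa_table(taxa_path))
    return align_tables(table, meta)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory.

    Stage order per cohort: load (+ optional genus aggregation), align with
    metadata, low-abundance filter, topic-number tuning (skipped when K is
    fixed), LDA fit (cohort B uses seed+1), read-to-topic assignment, and
    topic-level differential abundance; then cross-cohort topic matching and
    the validated-community report.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(msg: str) -> None:
        log.append(msg)

    with open(out / "config_effective.txt", "w") as fh:
        for f in fields(config):
            fh.write(f"{f.name}={getattr(config, f.name)}\n")

    cohorts = {}
    for label, tp, mp, xp in (
        (config.label_a, config.table_a, config.meta_a, config.taxa_a),
        (config.label_b, config.table_b, config.meta_b, config.taxa_b),
    ):
        try:
            table, meta, dropped = _load_cohort(config, tp, mp, xp)
        except Exception as exc:
            _abort(out, log, f"load[{label}]", exc)
        stage(f"load[{label}]: {table.n_samples} samples x {table.n_features} features"
              f" ({dropped} samples dropped at metadata join)")
        try:
            table, report = filter_low_abundance(table, config.filter_threshold)
        except Exception as exc:
            _abort(out, log, f"filter[{label}]", exc)
        (out / f"filter_report_{label}.tsv").write_text(report.to_tsv())
        write_count_table(table, out / f"filtered_{label}.tsv")
        stage(f"filter[{label}]: {report.n_features_before} -> {report.n_features_after} features"
              f" at pooled relative abundance < {config.filter_threshold}")
        cohorts[label] = (table, meta)

    labels = [config.label_a, config.label_b]
    if config.n_topics is None:
        grid = list(range(config.grid_min, config.grid_max + 1, config.grid_step))
        results = []
        for label in labels:
            table, _ = cohorts[label]
            try:
                res = tune_topic_number(
                    table, grid,
                    VemSettings(max_em_iters=config.max_em_iters,
                                em_tol=config.em_tol, seed=config.seed),
                )
            except Exception as exc:
                _abort(out, log, f"tune[{label}]", exc)
            (out / f"tuning_{label}.tsv").write_text(res.to_tsv())
            stage(f"tune[{label}]: best K per metric {res.best_K_per_metric}")
            results.append(res)
        K = combine_dataset_optima(results)
        stage(f"tune: combined K = {K}")
    else:
        K = config.n_topics
        stage(f"tune: skipped, K fixed at {K} by configuration")

    models: dict[str, LdaModel] = {}
    diffs = {}
    diff_settings = DiffSettings(p_threshold=config.p_threshold,
                                 q_threshold=config.q_threshold)
    for offset, label in enumerate(labels):
        table, meta = cohorts[label]
        settings = VemSettings(max_em_iters=config.max_em_iters,
                               em_tol=config.em_tol, seed=config.seed + offset)
        try:
            model = fit_lda(table, K, settings)
        except Exception as exc:
            _abort(out, log, f"fit[{label}]", exc)
        save_model(model, out, name=f"model_{label}")
        stage(f"fit[{label}]: K={K}, seed={settings.seed}, "
              f"{len(model.elbo_trace)} EM iterations, final ELBO {model.elbo_trace[-1]:.6f}")
        models[label] = model

        try:
            topics = assign_reads_to_topics(model, table, rounding=config.rounding,
                                            topic_prefix=label)
        except Exception as exc:
            _abort(out, log, f"assign[{label}]", exc)
        topic_table = topics.as_count_table()
        write_count_table(topic_table, out / f"topic_abundance_{label}.tsv")
        stage(f"assign[{label}]: rounding={config.rounding}")

        try:
            diff = linda_test(topic_table, meta, diff_settings)
        except Exception as exc:
            _abort(out, log, f"test[{label}]", exc)
        (out / f"diff_topics_{label}.tsv").write_text(results_to_tsv(diff))
        n_sig = sum(r.significant for r in diff)
        stage(f"test[{label}]: {n_sig}/{len(diff)} topics significant "
              f"(p<={config.p_threshold}, q<={config.q_threshold})")
        diffs[label] = diff

    try:
        sim, matches = match_topics(models[labels[0]], models[labels[1]],
                                    threshold=config.cosine_threshold,
                                    prefix_A=labels[0], prefix_B=labels[1])
    except Exception as exc:
        _abort(out, log, "match", exc)
    (out / "similarity.tsv").write_text(sim.to_tsv())
    (out / "matches.tsv").write_text(matches.to_tsv())
    stage(f"match: {len(matches.pairs)} pairs at cosine >= {config.cosine_threshold}, "
          f"{len(matches.communities)} communities")

    try:
        communities = validated_communities(matches, diffs[labels[0]],
                                            diffs[labels[1]], rule=config.rule)
    except Exception as exc:
        _abort(out, log, "report", exc)
    with open(out / "communities.tsv", "w") as fh:
        fh.write("members\tsignificant_members\tvalidated\n")
        for c in communities:
            fh.write(c.to_row() + "\n")
    n_val = sum(c.validated for c in communities)
    stage(f"report: {n_val}/{len(communities)} communities validated under rule {config.rule}")

    (out / "log.txt").write_text("\n".join(log) + "\n")
    return out


def _abort(out: Path, log: list[str], stage_name: str, exc: Exception) -> None:
    log.append(f"FAILED at stage {stage_name}: {exc}")
    (out / "log.txt").write_text("\n".join(log) + "\n")
    raise RuntimeError(f"pipeline failed at stage {stage_name}: {exc}") from exc
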