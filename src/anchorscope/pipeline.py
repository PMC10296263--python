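"""End-to-end two-cohort orchestration driven by a flat config file.

The two cohorts are preprocessed and analyzed strictly separately and meet
only at the two cross-cohort steps (correlation mean-ranking and pivot-score
mean-ranking).  Report-table rounding (2 decimals, ties away from zero) is
applied only when writing files; all chained computation stays full
precision.  A JSON manifest (input hashes, config echo, per-stage counts,
seed) makes every run reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import yaml

from . import correlation, draimi, ppi, preprocess, rf
from .errors import AnchorscopeError, ConfigurationError
from .matrix import read_matrix_tsv
from .synth import read_gene_set

log = logging.getLogger("anchorscope")

_REQUIRED_KEYS = ("cohort_a_matrix", "cohort_b_matrix", "anchor", "gene_set", "ppi", "out_dir")
_OPTIONAL_KEYS = {
    "seed": 0,
    "label_a": "cohort_a",
    "label_b": "cohort_b",
    "median_threshold_a": 0.0,
    "threshold_mode_a": preprocess.STRICTLY_GREATER,
    "median_threshold_b": 1.0,
    "threshold_mode_b": preprocess.AT_LEAST,
    "offset": 1.0,
    "log_base": 2.0,
    "rf_mtry": "5,10,15,20,25,30,35,40,45,50",
    "rf_min_node_sizes": "2,3",
    "rf_trees": 101,
    "rf_folds": 10,
    "rf_repeats": 5,
    "ppi_min_score": ppi.DEFAULT_MIN_SCORE,
    "decile_fraction": 0.10,
    "draimi_bootstrap": 100,
    "draimi_top_k": 1000,
}


@dataclass(frozen=True)
class PipelineConfig:
    cohort_a_matrix: str
    cohort_b_matrix: str
    anchor: str
    gene_set: str
    ppi: str
    out_dir: str
    seed: int
    label_a: str
    label_b: str
    preprocess_a: preprocess.PreprocessConfig
    preprocess_b: preprocess.PreprocessConfig
    rf: rf.RFConfig
    ppi_min_score: int
    decile_fraction: float
    draimi_bootstrap: int
    draimi_top_k: int
    echo: dict  # the raw (defaults-filled) key-value mapping, for the manifest


def _int_list(text) -> tuple[int, ...]:
    if isinstance(text, (list, tuple)):
        return tuple(int(v) for v in text)
    return tuple(int(v) for v in str(text).split(",") if str(v).strip())


def validate_config(path) -> PipelineConfig:
    """Load and range-check a flat YAML key-value config; reject unknown keys."""
    with open(path, "rt", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a flat key: value mapping")
    unknown = set(raw) - set(_REQUIRED_KEYS) - set(_OPTIONAL_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    for key in _REQUIRED_KEYS:
        if key not in raw or raw[key] in (None, ""):
            raise ConfigurationError(f"missing required config key: {key!r}")
    merged = {**_OPTIONAL_KEYS, **raw}
    base = os.path.dirname(os.path.abspath(path))

    def respath(p):
        p = str(p)
        return p if os.path.isabs(p) else os.path.join(base, p)

    for key in ("cohort_a_matrix", "cohort_b_matrix", "gene_set", "ppi"):
        merged[key] = respath(merged[key])
        if not os.path.exists(merged[key]):
            raise ConfigurationError(f"{key}: path does not exist: {merged[key]}")
    merged["out_dir"] = respath(merged["out_dir"])
    frac = float(merged["decile_fraction"])
    if not 0.0 < frac <= 0.5:
        raise ConfigurationError(f"decile_fraction must lie in (0, 0.5], got {frac}")
    seed = int(merged["seed"])
    cfg = PipelineConfig(
        cohort_a_matrix=merged["cohort_a_matrix"],
        cohort_b_matrix=merged["cohort_b_matrix"],
        anchor=str(merged["anchor"]),
        gene_set=merged["gene_set"],
        ppi=merged["ppi"],
        out_dir=merged["out_dir"],
        seed=seed,
        label_a=str(merged["label_a"]),
        label_b=str(merged["label_b"]),
        preprocess_a=preprocess.PreprocessConfig(
            median_threshold=float(merged["median_threshold_a"]),
            threshold_mode=str(merged["threshold_mode_a"]),
            offset=float(merged["offset"]),
            log_base=float(merged["log_base"]),
        ),
        preprocess_b=preprocess.PreprocessConfig(
            median_threshold=float(merged["median_threshold_b"]),
            threshold_mode=str(merged["threshold_mode_b"]),
            offset=float(merged["offset"]),
            log_base=float(merged["log_base"]),
        ),
        rf=rf.RFConfig(
            mtry_grid=_int_list(merged["rf_mtry"]),
            min_node_sizes=_int_list(merged["rf_min_node_sizes"]),
            n_trees=int(merged["rf_trees"]),
            cv_folds=int(merged["rf_folds"]),
            cv_repeats=int(merged["rf_repeats"]),
            seed=seed,
        ),
        ppi_min_score=int(merged["ppi_min_score"]),
        decile_fraction=frac,
        draimi_bootstrap=int(merged["draimi_bootstrap"]),
        draimi_top_k=int(merged["draimi_top_k"]),
        echo={k: merged[k] for k in sorted(merged)},
    )
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the four report tables + manifest.

    Any stage failure removes this run's partial outputs and re-raises with
    the stage name attached.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    written: list[str] = []
    stage = "setup"

    def out(name: str) -> str:
        p = os.path.join(config.out_dir, name)
        written.append(p)
        return p

    counts: dict = {}
    try:
        stage = "load"
        gene_set = read_gene_set(config.gene_set)
        graph = ppi.read_edge_list(config.ppi, min_score=config.ppi_min_score)
        cohorts = {}
        for label, mpath, pcfg in (
            (config.label_a, config.cohort_a_matrix, config.preprocess_a),
            (config.label_b, config.cohort_b_matrix, config.preprocess_b),
        ):
            stage = f"preprocess[{label}]"
            raw = read_matrix_tsv(mpath, cohort_label=label)
            cooked = preprocess.preprocess(raw, pcfg)
            if cooked.n_genes == 0:
                raise AnchorscopeError(
                    f"median filter removed every gene in cohort {label!r}"
                )
            counts[f"genes_total_{label}"] = raw.n_genes
            counts[f"genes_after_filter_{label}"] = cooked.n_genes
            counts[f"samples_{label}"] = cooked.n_samples
            log.info("%s: %d/%d genes pass the median filter, %d samples",
                     label, cooked.n_genes, raw.n_genes, cooked.n_samples)
            cohorts[label] = cooked

        stage = "correlation"
        recs = {
            label: correlation.correlate_anchor(m, config.anchor)
            for label, m in cohorts.items()
        }
        merged = correlation.cross_cohort_merge(
            recs[config.label_a], recs[config.label_b]
        )
        counts["correlation_merged_genes"] = len(merged)
        log.info("correlation: %d genes in both cohorts", len(merged))
        correlation.write_correlation_table(
            merged, out("correlation_table.tsv"), config.label_a, config.label_b
        )

        stage = "random_forest"
        tables = {}
        for label, m in cohorts.items():
            summary, records = rf.tune_and_fit(m, config.anchor, config.rf)
            tables[label] = records
            counts[f"rf_best_mtry_{label}"] = summary.best_mtry
            counts[f"rf_best_min_node_size_{label}"] = summary.best_min_node_size
            counts[f"rf_cv_r_squared_{label}"] = summary.cv_r_squared
            counts[f"rf_cv_mae_{label}"] = summary.cv_mae
            log.info("%s: RF best mtry=%d node=%d CV R2=%.3f MAE=%.3f", label,
                     summary.best_mtry, summary.best_min_node_size,
                     summary.cv_r_squared, summary.cv_mae)
            rf.write_importance_table(records, out(f"rf_importance_{label}.tsv"))
        inter40 = rf.intersect_importance(
            tables[config.label_a], tables[config.label_b], 40.0
        )
        inter70 = rf.intersect_importance(
            tables[config.label_a], tables[config.label_b], 70.0
        )
        counts["rf_intersection_gt40"] = len(inter40)
        counts["rf_intersection_gt70"] = len(inter70)
        rf.write_intersection_table(
            inter40, out("rf_intersection.tsv"), config.label_a, config.label_b
        )

        stage = "draimi"
        pivot_scores = {}
        for i, (label, m) in enumerate(cohorts.items()):
            dcfg = draimi.DraimiConfig(
                gene_set=tuple(gene_set),
                decile_fraction=config.decile_fraction,
                n_bootstrap=config.draimi_bootstrap,
                top_k=config.draimi_top_k,
                per_bootstrap_k=config.draimi_top_k,
                seed=config.seed + i,
            )
            top, scores = draimi.run_draimi(m, config.anchor, graph, dcfg)
            pivot_scores[label] = scores
            counts[f"draimi_top_ratios_{label}"] = len(top)
            counts[f"draimi_scored_nodes_{label}"] = len(scores)
            log.info("%s: %d top ratios, %d scored nodes", label, len(top), len(scores))
        rows = draimi.draimi_cross_cohort(
            pivot_scores[config.label_a], pivot_scores[config.label_b]
        )
        counts["draimi_merged_genes"] = len(rows)
        draimi.write_pivot_table(
            rows, out("draimi_scores.tsv"), config.label_a, config.label_b
        )

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "anchor": config.anchor,
            "inputs": {
                p: _sha256(p)
                for p in (
                    config.cohort_a_matrix,
                    config.cohort_b_matrix,
                    config.gene_set,
                    config.ppi,
                )
            },
            "config": _jsonable(config.echo),
            "counts": counts,
            "stages_per_cohort": ["preprocess", "correlation", "random_forest", "draimi"],
            "outputs": [os.path.basename(p) for p in written],
        }
        with open(out("manifest.json"), "wt", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception as exc:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        # keep the error class so the CLI can map it to the right exit code
        kind = type(exc) if isinstance(exc, AnchorscopeError) else AnchorscopeError
        raise kind(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
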