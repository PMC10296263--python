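"""DRAIMI: Differential Ratio Analysis with InterMediary Inference.

The method asks which transcript *ratios* separate samples with high versus
low anchor-gene expression, and which network genes sit between the members
of those ratios.  Concretely:

1. Samples are split into the upper and bottom deciles of anchor expression.
2. For every unordered pair (a, b) in a curated gene set, the per-sample
   log-ratio is the difference of log expressions ``d_s = x_a,s - x_b,s``.
   An absolute Welch two-sample t statistic compares the upper-decile and
   bottom-decile values of ``d``.
3. Consistency is estimated by a within-group bootstrap: group labels and
   sizes are preserved, samples are resampled with replacement inside each
   group, and a pair's consistency is the fraction of replicates in which
   its |t| ranks inside the top ``per_bootstrap_k`` pairs.
4. Pairs are ranked by consistency, then |t|, then pair symbols, and the top
   ``top_k`` ratios are kept.
5. Every network gene g is scored by its *intermediary ratio*: the number of
   top ratios (a, b) with g distinct from both members and directly
   interacting with both, divided by g's total degree in the network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError
from .matrix import LOG, ExpressionMatrix
from .ppi import PPIGraph
from ._util import round_half_away


@dataclass(frozen=True)
class DraimiConfig:
    """Tuning knobs for one DRAIMI run.

    decile_fraction : fraction of samples in each extreme group (0, 0.5].
    gene_set        : symbols eligible for ratio formation (intersected with
                      the matrix; the anchor is excluded unless
                      ``include_anchor``).
    n_bootstrap     : within-group resampling replicates.
    top_k           : ratios kept for pivot scoring.
    per_bootstrap_k : rank cutoff defining a "hit" inside one replicate.
    """

    gene_set: tuple[str, ...] = ()
    decile_fraction: float = 0.10
    n_bootstrap: int = 100
    top_k: int = 1000
    per_bootstrap_k: int = 1000
    include_anchor: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_set", tuple(dict.fromkeys(self.gene_set)))
        if not 0.0 < self.decile_fraction <= 0.5:
            raise ConfigurationError(
                f"decile_fraction must lie in (0, 0.5], got {self.decile_fraction}"
            )
        if self.n_bootstrap < 1 or self.top_k < 1 or self.per_bootstrap_k < 1:
            raise ConfigurationError(
                "n_bootstrap, top_k and per_bootstrap_k must be positive"
            )


@dataclass(frozen=True)
class RatioStat:
    """One gene pair's differential-ratio statistics (pair sorted a < b)."""

    pair: tuple[str, str]
    t_abs: float
    consistency: float
    final_rank: int


@dataclass(frozen=True)
class PivotScore:
    """A network gene's intermediary score: hits among top ratios / degree."""

    gene: str
    hits: int
    degree: int
    intermediary_ratio: float


def split_deciles(
    matrix: ExpressionMatrix, anchor: str, config: DraimiConfig
) -> tuple[list[str], list[str]]:
    """Upper and bottom anchor-expression groups of size floor(f*n), min 1.

    Samples are put on one total order by (anchor value, sample id), so ties
    at either boundary resolve lexicographically and the two groups are
    disjoint by construction.  Returns (upper_ids, lower_ids).
    """
    if matrix.scale_state != LOG:
        raise DataError("split_deciles requires a log-scale matrix")
    values = matrix.gene(anchor)
    samples = matrix.sample_ids
    n = len(samples)
    k = max(1, math.floor(config.decile_fraction * n))
    if 2 * k > n:
        raise DataError(f"cannot form two disjoint groups of {k} from {n} samples")
    warn = n < 2.0 / config.decile_fraction
    order = sorted(range(n), key=lambda i: (values[i], samples[i]))
    lower = order[:k]
    upper = order[-k:][::-1]  # highest first
    if warn:
        matrix.warnings.append(
            f"decile split on only {n} samples gives groups of {k}; "
            "statistics will be unstable"
        )
    return [samples[i] for i in upper], [samples[i] for i in lower]


def _welch_abs_t(
    du: np.ndarray, dl: np.ndarray
) -> np.ndarray:
    """Vectorized |Welch t| across rows (pairs); groups along axis 1.

    Groups of size 1 contribute zero variance; a zero pooled standard error
    yields |t| = 0 when the means agree and +inf when they differ.
    """
    mu, ml = du.shape[1], dl.shape[1]
    mean_u = du.mean(axis=1)
    mean_l = dl.mean(axis=1)
    var_u = du.var(axis=1, ddof=1) if mu > 1 else np.zeros(du.shape[0])
    var_l = dl.var(axis=1, ddof=1) if ml > 1 else np.zeros(dl.shape[0])
    denom = np.sqrt(var_u / mu + var_l / ml)
    diff = np.abs(mean_u - mean_l)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    t[denom == 0.0] = np.where(diff[denom == 0.0] > 0, np.inf, 0.0)
    return t


def ratio_stats(
    matrix: ExpressionMatrix,
    upper_ids: list[str],
    lower_ids: list[str],
    config: DraimiConfig,
    exclude: set[str] | None = None,
) -> list[RatioStat]:
    """Rank every gene pair in the (intersected) gene set by bootstrap consistency.

    Within one bootstrap replicate, top-``per_bootstrap_k`` membership uses
    |t| descending with pair-lexicographic tie-break; the final ranking is
    consistency desc, |t| desc, pair lexicographic.
    """
    if matrix.scale_state != LOG:
        raise DataError("ratio_stats requires a log-scale matrix")
    exclude = exclude or set()
    genes = sorted((set(config.gene_set) & set(matrix.gene_ids)) - exclude)
    if len(genes) < 2:
        raise DataError(
            f"gene set intersected with the matrix leaves {len(genes)} gene(s); "
            "at least 2 are required to form ratios"
        )
    ia, ib = np.triu_indices(len(genes), k=1)
    sub = matrix.data.loc[genes]
    Xu = sub[upper_ids].to_numpy(dtype=float)
    Xl = sub[lower_ids].to_numpy(dtype=float)
    Du = Xu[ia] - Xu[ib]  # pairs x upper samples
    Dl = Xl[ia] - Xl[ib]
    P = Du.shape[0]
    k_hit = min(config.per_bootstrap_k, P)

    t_obs = _welch_abs_t(Du, Dl)

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
    mu, ml = len(upper_ids), len(lower_ids)
    hits = np.zeros(P, dtype=np.int64)
    for _ in range(config.n_bootstrap):
        su = rng.integers(0, mu, size=mu)
        sl = rng.integers(0, ml, size=ml)
        t_b = _welch_abs_t(Du[:, su], Dl[:, sl])
        # stable argsort on -t keeps pair (lexicographic) order among ties
        top = np.argsort(-t_b, kind="stable")[:k_hit]
        hits[top] += 1
    consistency = hits / config.n_bootstrap

    # triu_indices over the sorted gene list enumerates pairs lexicographically,
    # so the row index itself is the pair tie-break key
    order = np.lexsort((np.arange(P), -t_obs, -consistency))
    stats = [
        RatioStat(
            pair=(genes[ia[j]], genes[ib[j]]),
            t_abs=float(t_obs[j]),
            consistency=float(consistency[j]),
            final_rank=rank,
        )
        for rank, j in enumerate(order, start=1)
    ]
    return stats


def select_top_ratios(stats: list[RatioStat], config: DraimiConfig) -> list[RatioStat]:
    """First min(top_k, P) entries by final rank."""
    ordered = sorted(stats, key=lambda s: s.final_rank)
    return ordered[: min(config.top_k, len(ordered))]


def score_pivots(
    top: list[RatioStat], graph: PPIGraph, restrict_degree_to: set[str] | None = None
) -> list[PivotScore]:
    """Intermediary ratios for every connected network node.

    A hit is a top ratio (a, b) with the candidate g distinct from both
    members and adjacent to both.  The denominator is g's degree in the full
    loaded graph by default; pass ``restrict_degree_to`` (e.g. the analyzed
    gene set) to count only neighbors inside that set instead.  Zero-degree
    nodes are excluded (recorded in graph warnings); zero-hit nodes are
    retained with score 0.  Sorted by score desc, hits desc, symbol asc.
    """
    if graph.graph.number_of_nodes() == 0:
        raise DataError("pivot scoring requires a non-empty interaction graph")
    pairs = [s.pair for s in top]
    scores = []
    excluded = 0
    for g in graph.graph.nodes:
        adj = set(graph.graph.neighbors(g))
        degree = len(adj if restrict_degree_to is None else adj & restrict_degree_to)
        if degree == 0:
            excluded += 1
            continue
        h = sum(1 for a, b in pairs if g != a and g != b and a in adj and b in adj)
        scores.append(PivotScore(gene=g, hits=h, degree=degree, intermediary_ratio=h / degree))
    if excluded:
        graph.warnings.append(f"excluded {excluded} zero-degree node(s) from pivot scoring")
    scores.sort(key=lambda s: (-s.intermediary_ratio, -s.hits, s.gene))
    return scores


def run_draimi(
    matrix: ExpressionMatrix, anchor: str, graph: PPIGraph, config: DraimiConfig
) -> tuple[list[RatioStat], list[PivotScore]]:
    """Decile split -> ratio bootstrap -> top-K -> pivot scoring, one cohort."""
    upper, lower = split_deciles(matrix, anchor, config)
    exclude = set() if config.include_anchor else {anchor}
    stats = ratio_stats(matrix, upper, lower, config, exclude=exclude)
    top = select_top_ratios(stats, config)
    return top, score_pivots(top, graph)


def draimi_cross_cohort(
    scores_a: list[PivotScore], scores_b: list[PivotScore]
) -> list[dict]:
    """Inner-join per-cohort pivot scores; mean of the two intermediary ratios.

    Rows are dicts with gene, per-cohort scores/hits/degrees and the full
    precision mean, sorted by mean descending then symbol.
    """
    by_a = {s.gene: s for s in scores_a}
    by_b = {s.gene: s for s in scores_b}
    rows = []
    for g in set(by_a) & set(by_b):
        a, b = by_a[g], by_b[g]
        rows.append(
            {
                "gene": g,
                "score_a": a.intermediary_ratio,
                "score_b": b.intermediary_ratio,
                "mean": (a.intermediary_ratio + b.intermediary_ratio) / 2.0,
                "hits_a": a.hits,
                "degree_a": a.degree,
                "hits_b": b.hits,
                "degree_b": b.degree,
            }
        )
    rows.sort(key=lambda r: (-r["mean"], r["gene"]))
    return rows


def write_pivot_table(rows: list[dict], path, label_a="cohort_a", label_b="cohort_b") -> None:
    """Report TSV shaped like the study's cross-cohort intermediary table."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(
            f"gene\tscore_{label_a}\tscore_{label_b}\tmean"
            f"\thits_{label_a}\tdegree_{label_a}\thits_{label_b}\tdegree_{label_b}\n"
        )
        for r in rows:
            fh.write(
                f"{r['gene']}\t{round_half_away(r['score_a'], 2):.2f}"
                f"\t{round_half_away(r['score_b'], 2):.2f}"
                f"\t{round_half_away(r['mean'], 2):.2f}"
                f"\t{r['hits_a']}\t{r['degree_a']}\t{r['hits_b']}\t{r['degree_b']}\n"
            )
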