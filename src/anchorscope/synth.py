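"""Two-cohort synthetic expression data with known planted structure.

The generator emulates the setting of an anchor-gene monocyte microarray
study: two cohorts of unequal size profiled on the same platform, one anchor
transcript, a handful of genes whose log-scale expression correlates with the
anchor at chosen strengths, gene pairs whose log-ratio differs between the
upper and lower anchor deciles, and network pivot genes wired to both members
of those pairs.  Everything else is independent noise.  Each planted entity
is recorded in a truth table so downstream stages can be scored exactly.

Model
-----
Per gene g a latent standard-normal signal is drawn per sample.  The anchor's
latent signal ``z`` is shared: a planted correlate with target correlation r
uses ``r*z + sqrt(1-r^2)*eps``.  Latents are mapped to the log2 scale as
``mu_g + sigma_g * latent`` with per-gene location/scale drawn once from
configured ranges, then ratio-pair shifts are added to the top-anchor-decile
samples, and finally intensities are produced as ``2**logval - offset``
clipped at zero — the exact inverse of the preprocessing transform, so
planted structure is recovered on the analysis scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrix import INTENSITY, ExpressionMatrix
from .ppi import PPIGraph

_STREAM_COHORT = (0, 1)  # spawn keys for the two cohorts
_STREAM_GRAPH = 2


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic two-cohort study.

    n_samples_per_cohort : sizes of the two cohorts (the study design this
        emulates had ~1202 and ~281 samples; desk-fast defaults are smaller).
    n_genes              : total genes, including anchor and planted symbols.
    anchor_id            : symbol of the anchor gene.
    planted_correlates   : (symbol, target log-scale Pearson r) pairs.
    planted_ratio_pairs  : (gene_a, gene_b, log2-ratio shift) triples; for
        top-anchor-decile samples gene_a is raised and gene_b lowered by
        half the shift each, so the pair's log difference moves by `shift`.
    planted_pivots       : (symbol, indices into planted_ratio_pairs) pairs;
        each pivot is wired to both members of each assigned pair.
    background_edge_prob : probability of each non-planted undirected edge.
    offset               : intensity offset inverted by preprocessing.
    base_mean, base_sd   : uniform ranges for per-gene log2 location/scale.
    seed                 : global seed, expanded into independent substreams
        for cohort 0, cohort 1 and the graph.
    """

    n_samples_per_cohort: tuple[int, int] = (60, 60)
    n_genes: int = 200
    anchor_id: str = "ANCHOR"
    planted_correlates: tuple[tuple[str, float], ...] = ()
    planted_ratio_pairs: tuple[tuple[str, str, float], ...] = ()
    planted_pivots: tuple[tuple[str, tuple[int, ...]], ...] = ()
    background_edge_prob: float = 0.0
    offset: float = 1.0
    base_mean: tuple[float, float] = (4.0, 10.0)
    base_sd: tuple[float, float] = (0.3, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "planted_correlates", tuple((g, float(r)) for g, r in self.planted_correlates)
        )
        object.__setattr__(
            self,
            "planted_ratio_pairs",
            tuple((a, b, float(s)) for a, b, s in self.planted_ratio_pairs),
        )
        object.__setattr__(
            self,
            "planted_pivots",
            tuple((p, tuple(int(i) for i in idx)) for p, idx in self.planted_pivots),
        )
        if any(n <= 0 for n in self.n_samples_per_cohort) or len(self.n_samples_per_cohort) != 2:
            raise ConfigurationError("n_samples_per_cohort must be two positive integers")
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not 0.0 <= self.background_edge_prob <= 1.0:
            raise ConfigurationError("background_edge_prob must lie in [0, 1]")
        if self.offset <= 0:
            raise ConfigurationError("offset must be positive")
        n_pairs = len(self.planted_ratio_pairs)
        for p, idx in self.planted_pivots:
            for i in idx:
                if not 0 <= i < n_pairs:
                    raise ConfigurationError(f"pivot {p!r} references unknown ratio pair {i}")
                a, b, _ = self.planted_ratio_pairs[i]
                if p in (a, b):
                    raise ConfigurationError(f"pivot {p!r} is a member of its own ratio pair {i}")
        # distinctness: anchor, correlates, ratio-pair members and pivots must
        # not reuse symbols (a gene may appear in several ratio pairs though)
        pair_members = list(
            dict.fromkeys(g for pair in self.planted_ratio_pairs for g in pair[:2])
        )
        flat = (
            [self.anchor_id]
            + [g for g, _ in self.planted_correlates]
            + pair_members
            + [p for p, _ in self.planted_pivots]
        )
        if len(flat) != len(set(flat)):
            seen: set[str] = set()
            clash = sorted({g for g in flat if g in seen or seen.add(g)})
            raise ConfigurationError(f"planted gene symbols are not distinct: {clash}")
        if len(flat) > self.n_genes:
            raise ConfigurationError(
                f"{len(flat)} planted symbols exceed n_genes = {self.n_genes}"
            )
        for g, r in self.planted_correlates:
            if not -1.0 <= r <= 1.0:
                raise ConfigurationError(f"target r for {g!r} outside [-1, 1]: {r}")

    @property
    def gene_ids(self) -> list[str]:
        """Gene universe: anchor, planted symbols, then zero-padded fillers."""
        named = dict.fromkeys(
            [self.anchor_id]
            + [g for g, _ in self.planted_correlates]
            + [g for pair in self.planted_ratio_pairs for g in pair[:2]]
            + [p for p, _ in self.planted_pivots]
        )
        width = max(4, len(str(self.n_genes)))
        fillers = (f"G{i:0{width}d}" for i in range(1, 10 * self.n_genes))
        out = list(named)
        for f in fillers:
            if len(out) >= self.n_genes:
                break
            if f not in named:
                out.append(f)
        return out


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed, spawn_key=(stream,))))


def _top_bottom_decile(z: np.ndarray, fraction: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of the top and bottom anchor-decile samples (floor size, min 1)."""
    n = z.size
    k = max(1, int(math.floor(fraction * n)))
    order = np.argsort(z, kind="stable")
    return order[-k:], order[:k]


def generate_cohort(spec: SyntheticSpec, cohort_index: int) -> ExpressionMatrix:
    """Draw one cohort's intensity matrix with all planted structure in place."""
    if cohort_index not in (0, 1):
        raise ConfigurationError("cohort_index must be 0 or 1")
    rng = _rng(spec, _STREAM_COHORT[cohort_index])
    genes = spec.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = spec.n_samples_per_cohort[cohort_index]

    mu = rng.uniform(*spec.base_mean, size=spec.n_genes)
    sigma = rng.uniform(*spec.base_sd, size=spec.n_genes)
    latent = rng.standard_normal((spec.n_genes, n))

    z = latent[gene_pos[spec.anchor_id]]
    for g, r in spec.planted_correlates:
        i = gene_pos[g]
        latent[i] = r * z + math.sqrt(max(0.0, 1.0 - r * r)) * latent[i]

    log_vals = mu[:, None] + sigma[:, None] * latent

    # antisymmetric planting: the pair's log difference shifts by exactly
    # `shift` while pairs sharing only one member shift by half, keeping the
    # planted pair the strongest differential ratio
    top, _bottom = _top_bottom_decile(z)
    for a, b, shift in spec.planted_ratio_pairs:
        log_vals[gene_pos[a], top] += shift / 2.0
        log_vals[gene_pos[b], top] -= shift / 2.0

    intensities = np.clip(np.exp2(log_vals) - spec.offset, 0.0, None)
    sample_ids = [f"C{cohort_index}S{j:05d}" for j in range(1, n + 1)]
    data = pd.DataFrame(intensities, index=genes, columns=sample_ids)
    return ExpressionMatrix(data, cohort_label=f"cohort_{'ab'[cohort_index]}", scale_state=INTENSITY)


def generate_ppi(spec: SyntheticSpec) -> PPIGraph:
    """Build the interaction network: pivot wiring plus Bernoulli background.

    Every gene in the universe appears as a node; planted edges carry score
    999, background edges 900.
    """
    rng = _rng(spec, _STREAM_GRAPH)
    genes = spec.gene_ids
    ppi = PPIGraph()
    ppi.graph.add_nodes_from(genes)
    for p, idx in spec.planted_pivots:
        for i in idx:
            a, b, _ = spec.planted_ratio_pairs[i]
            ppi.add_edge(p, a, 999)
            ppi.add_edge(p, b, 999)
    q = spec.background_edge_prob
    if q > 0:
        g = len(genes)
        draws = rng.random((g, g))
        iu, ju = np.triu_indices(g, k=1)
        for i, j in zip(iu[draws[iu, ju] < q], ju[draws[iu, ju] < q]):
            ppi.add_edge(genes[i], genes[j], 900)
    return ppi


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth tables for one :class:`SyntheticSpec`.

    ``pivots`` records, for each planted pivot, the hit count and degree it
    attains when the top differential ratios are exactly the planted pairs
    and no background edges exist.
    """

    correlates: pd.DataFrame  # gene, r
    ratio_pairs: pd.DataFrame  # gene_a, gene_b, shift (a < b lexicographically)
    pivots: pd.DataFrame  # pivot, hits, degree, intermediary_ratio


def generate_truth(spec: SyntheticSpec) -> SyntheticTruth:
    correlates = pd.DataFrame(
        [(g, r) for g, r in spec.planted_correlates], columns=["gene", "r"]
    )
    pairs = pd.DataFrame(
        [(min(a, b), max(a, b), s) for a, b, s in spec.planted_ratio_pairs],
        columns=["gene_a", "gene_b", "shift"],
    )
    rows = []
    for p, idx in spec.planted_pivots:
        adjacent: set[str] = set()
        for i in idx:
            a, b, _ = spec.planted_ratio_pairs[i]
            adjacent.update((a, b))
        # brute-force hit count over ALL planted pairs, not only assigned ones:
        # shared members can make a pivot adjacent to an unassigned pair too
        hits = sum(
            1
            for a, b, _ in spec.planted_ratio_pairs
            if p not in (a, b) and a in adjacent and b in adjacent
        )
        degree = len(adjacent)
        rows.append((p, hits, degree, hits / degree if degree else float("nan")))
    pivots = pd.DataFrame(rows, columns=["pivot", "hits", "degree", "intermediary_ratio"])
    return SyntheticTruth(correlates=correlates, ratio_pairs=pairs, pivots=pivots)


def immunity_gene_set(spec: SyntheticSpec, extra: int = 0) -> list[str]:
    """Stand-in for a curated immunity gene set: all ratio-pair members plus
    ``extra`` background genes (never the anchor, planted correlates or pivots)."""
    members = list(dict.fromkeys(g for pair in spec.planted_ratio_pairs for g in pair[:2]))
    skip = (
        {spec.anchor_id}
        | set(members)
        | {g for g, _ in spec.planted_correlates}
        | {p for p, _ in spec.planted_pivots}
    )
    for g in spec.gene_ids:
        if extra <= 0:
            break
        if g in skip:
            continue
        members.append(g)
        skip.add(g)
        extra -= 1
    return members


def write_gene_set(symbols, path) -> None:
    """One symbol per line."""
    with open(path, "wt", encoding="utf-8") as fh:
        for s in symbols:
            fh.write(f"{s}\n")


def read_gene_set(path) -> list[str]:
    with open(path, "rt", encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]
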