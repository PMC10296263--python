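"""Transcriptome-wide anchor-gene correlation with FDR and cross-cohort meta-ranking.

Every non-anchor gene is tested for Pearson correlation with the anchor on
the log scale; two-sided p-values come from the exact t transform
``t = r * sqrt((n-2) / (1-r^2))`` with n-2 degrees of freedom, and the
family of all non-anchor genes within one cohort is adjusted with
Benjamini-Hochberg.  Genes quantified in both cohorts are merged by an
inner join, ranked by the arithmetic mean of the two correlation
coefficients (``r_mean``), and reported to two decimals with ties rounded
away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .matrix import LOG, ExpressionMatrix
from ._util import round_half_away


@dataclass(frozen=True)
class CorrelationRecord:
    """One gene's anchor-correlation result within a cohort."""

    gene: str
    r: float
    p: float
    p_fdr: float
    n: int


@dataclass(frozen=True)
class CrossCohortCorrelation:
    """A gene's per-cohort records plus the mean-r meta statistic."""

    gene: str
    record_a: CorrelationRecord
    record_b: CorrelationRecord
    r_mean: float

    @property
    def r_mean_reported(self) -> float:
        return round_half_away(self.r_mean, 2)


def _snap_unit(r):
    """Treat |r| within one part in 1e12 of 1 as exactly +/-1.

    A duplicated row is perfectly collinear with the anchor but accumulated
    float rounding can leave |r| a few ulp short; the exact t transform would
    then return a spuriously finite p.
    """
    return np.where(np.abs(r) >= 1.0 - 1e-12, np.sign(r), r)


def pearson_with_p(x, y, name: str | None = None) -> tuple[float, float]:
    """Pearson r and the two-sided t-distribution p-value.

    ``|r| = 1`` returns p = 0 exactly rather than propagating a division by
    zero.  Zero variance in either vector is an error (naming the gene when
    ``name`` is given).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("pearson_with_p requires two equal-length vectors")
    n = x.size
    if n < 3:
        raise DataError(f"need at least 3 paired observations, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        who = f" for gene {name!r}" if name else ""
        raise DataError(f"correlation undefined{who}: zero variance")
    r = float(np.clip((xc @ yc) / (nx * ny), -1.0, 1.0))
    r = float(_snap_unit(r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, min(p, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values in the original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlate_anchor(matrix: ExpressionMatrix, anchor: str) -> list[CorrelationRecord]:
    """Correlate every non-anchor gene with the anchor; BH-adjust over that family.

    Output is sorted by r descending, ties broken by gene symbol.
    """
    if matrix.scale_state != LOG:
        raise DataError("correlate_anchor requires a log-scale matrix")
    if anchor not in matrix.data.index:
        raise DataError(f"anchor gene {anchor!r} not present in matrix")
    X = matrix.data.to_numpy(dtype=float)
    genes = matrix.gene_ids
    n = matrix.n_samples
    if n < 3:
        raise DataError(f"need at least 3 samples, got {n}")
    a_idx = genes.index(anchor)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", Xc, Xc))
    if norms[a_idx] == 0.0:
        raise DataError(f"correlation undefined for gene {anchor!r}: zero variance")
    dead = np.flatnonzero(norms == 0.0)
    if dead.size:
        raise DataError(f"correlation undefined for gene {genes[dead[0]]!r}: zero variance")
    r = _snap_unit(np.clip(Xc @ Xc[a_idx] / (norms * norms[a_idx]), -1.0, 1.0))
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = np.where(np.abs(r) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    p = np.minimum(p, 1.0)
    keep = [i for i in range(len(genes)) if i != a_idx]
    p_adj = bh_fdr(p[keep])
    records = [
        CorrelationRecord(gene=genes[i], r=float(r[i]), p=float(p[i]), p_fdr=float(q), n=n)
        for i, q in zip(keep, p_adj)
    ]
    records.sort(key=lambda rec: (-rec.r, rec.gene))
    return records


def mean_merge(values_a: dict[str, float], values_b: dict[str, float]) -> list[tuple[str, float, float, float]]:
    """Inner join two per-gene score mappings; rows (gene, a, b, mean), sorted
    by mean descending with gene-symbol tie-break.  Means stay full precision."""
    common = set(values_a) & set(values_b)
    rows = [(g, values_a[g], values_b[g], (values_a[g] + values_b[g]) / 2.0) for g in common]
    rows.sort(key=lambda t: (-t[3], t[0]))
    return rows


def cross_cohort_merge(
    records_a: list[CorrelationRecord], records_b: list[CorrelationRecord]
) -> list[CrossCohortCorrelation]:
    """Merge two cohorts' correlation tables on gene symbol (inner join)."""
    by_a = {rec.gene: rec for rec in records_a}
    by_b = {rec.gene: rec for rec in records_b}
    if len(by_a) != len(records_a) or len(by_b) != len(records_b):
        raise DataError("correlation records must be keyed by unique gene symbols")
    merged = [
        CrossCohortCorrelation(
            gene=g, record_a=by_a[g], record_b=by_b[g], r_mean=(by_a[g].r + by_b[g].r) / 2.0
        )
        for g in set(by_a) & set(by_b)
    ]
    merged.sort(key=lambda m: (-m.r_mean, m.gene))
    return merged


def write_correlation_table(merged: list[CrossCohortCorrelation], path, label_a="cohort_a", label_b="cohort_b") -> None:
    """Report-table TSV: gene, mean r, then per-cohort r and FDR-adjusted p."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(
            f"gene\tr_mean\tr_{label_a}\tp_fdr_{label_a}\tr_{label_b}\tp_fdr_{label_b}\n"
        )
        for m in merged:
            fh.write(
                f"{m.gene}\t{m.r_mean_reported:.2f}"
                f"\t{round_half_away(m.record_a.r, 2):.2f}\t{m.record_a.p_fdr:.3g}"
                f"\t{round_half_away(m.record_b.r, 2):.2f}\t{m.record_b.p_fdr:.3g}\n"
            )
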