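"""Gene-by-sample expression matrices and their tab-delimited on-disk format.

The canonical layout is genes in rows, samples in columns, a header row of
sample identifiers, and the first column holding gene symbols.  Matrices carry
a ``scale_state`` flag (``intensity`` or ``log``) so downstream stages can
refuse to run on the wrong scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, DataFormatError

INTENSITY = "intensity"
LOG = "log"
_SCALE_STATES = (INTENSITY, LOG)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with provenance metadata.

    Parameters
    ----------
    data
        DataFrame indexed by gene symbol with sample identifiers as columns.
    cohort_label
        Free-text cohort name, carried through to report tables.
    scale_state
        ``"intensity"`` (raw, non-negative) or ``"log"`` (after the
        offset + log transform).
    warnings
        Accumulated non-fatal processing notes (e.g. an empty filter result).
    """

    data: pd.DataFrame
    cohort_label: str = ""
    scale_state: str = INTENSITY
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scale_state not in _SCALE_STATES:
            raise DataError(
                f"scale_state must be one of {_SCALE_STATES}, got {self.scale_state!r}"
            )
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicated gene symbols: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            raise DataError("duplicated sample identifiers")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise DataError("expression matrix contains missing or non-finite values")
        if self.scale_state == INTENSITY and values.size and (values < 0).any():
            raise DataError("intensity-scale matrix contains negative values")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def gene(self, symbol: str) -> np.ndarray:
        if symbol not in self.data.index:
            raise DataError(f"gene {symbol!r} not present in matrix")
        return self.data.loc[symbol].to_numpy(dtype=float)


def read_matrix_tsv(path, cohort_label: str = "", scale_state: str = INTENSITY) -> ExpressionMatrix:
    """Read the tab-delimited matrix format (gene symbol column + sample header).

    Ragged rows and duplicated gene symbols are rejected with the offending
    line number.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise DataFormatError("empty matrix file", line=1)
        samples = header.rstrip("\n").split("\t")[1:]
        n_fields = len(samples) + 1
        genes: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_fields:
                raise DataFormatError(
                    f"expected {n_fields} fields, found {len(fields)}", line=lineno
                )
            gene = fields[0]
            if gene in seen:
                raise DataFormatError(f"duplicated gene symbol {gene!r}", line=lineno)
            seen.add(gene)
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise DataFormatError(f"non-numeric value ({exc})", line=lineno) from None
            genes.append(gene)
    data = pd.DataFrame(rows, index=genes, columns=samples, dtype=float)
    return ExpressionMatrix(data, cohort_label=cohort_label, scale_state=scale_state)


def write_matrix_tsv(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix in the canonical tab-delimited layout."""
    out = matrix.data.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")
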