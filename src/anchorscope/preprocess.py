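"""Per-cohort microarray preprocessing: median filtering and offset + log transform.

Two filtering dialects are supported because cohorts often publish different
rules: a "median strictly greater than a threshold" mode (typically used
with threshold 0) and a "median at least a threshold" mode (typically used
with threshold 1).  After filtering, intensities get a positive offset
and are log-transformed; the default offset of 1 with log base 2 maps a zero
intensity to 0 on the log scale, the common microarray convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError
from .matrix import INTENSITY, LOG, ExpressionMatrix

STRICTLY_GREATER = "strictly_greater"
AT_LEAST = "at_least"


@dataclass(frozen=True)
class PreprocessConfig:
    """Median-filter and log-transform settings for one cohort.

    median_threshold : threshold applied to each gene's median intensity.
    threshold_mode   : ``strictly_greater`` or ``at_least``.
    offset           : positive shift added before the log (default 1).
    log_base         : logarithm base, > 1 (default 2).
    """

    median_threshold: float = 0.0
    threshold_mode: str = STRICTLY_GREATER
    offset: float = 1.0
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.threshold_mode not in (STRICTLY_GREATER, AT_LEAST):
            raise ConfigurationError(
                f"threshold_mode must be {STRICTLY_GREATER!r} or {AT_LEAST!r}, "
                f"got {self.threshold_mode!r}"
            )
        if not self.offset > 0:
            raise ConfigurationError(f"offset must be positive, got {self.offset}")
        if not self.log_base > 1:
            raise ConfigurationError(f"log_base must exceed 1, got {self.log_base}")


def filter_by_median(matrix: ExpressionMatrix, config: PreprocessConfig) -> ExpressionMatrix:
    """Keep genes whose per-gene median intensity passes the threshold.

    The median over an even number of samples is the mean of the two central
    order statistics.  Sample set and gene order are preserved.  An empty
    result is returned (with a warning recorded on the matrix) rather than
    raised, so the caller decides how loudly to fail.
    """
    if matrix.scale_state != INTENSITY:
        raise DataError("filter_by_median requires an intensity-scale matrix")
    medians = np.median(matrix.data.to_numpy(), axis=1)
    if config.threshold_mode == STRICTLY_GREATER:
        keep = medians > config.median_threshold
    else:
        keep = medians >= config.median_threshold
    filtered = ExpressionMatrix(
        matrix.data.loc[keep],
        cohort_label=matrix.cohort_label,
        scale_state=INTENSITY,
        warnings=list(matrix.warnings),
    )
    if filtered.n_genes == 0:
        filtered.warnings.append(
            f"median filter (threshold {config.median_threshold}, "
            f"{config.threshold_mode}) removed every gene"
        )
    return filtered


def offset_log_transform(matrix: ExpressionMatrix, config: PreprocessConfig) -> ExpressionMatrix:
    """Apply v -> log_base(v + offset) entry-wise and flip the scale flag."""
    if matrix.scale_state != INTENSITY:
        raise DataError("offset_log_transform requires an intensity-scale matrix")
    values = matrix.data.to_numpy() + config.offset
    if (values <= 0).any():
        g, s = np.argwhere(values <= 0)[0]
        raise DataError(
            f"value + offset is non-positive for gene {matrix.gene_ids[g]!r}, "
            f"sample {matrix.sample_ids[s]!r}"
        )
    logged = np.log(values) / math.log(config.log_base)
    return ExpressionMatrix(
        matrix.data.__class__(logged, index=matrix.data.index, columns=matrix.data.columns),
        cohort_label=matrix.cohort_label,
        scale_state=LOG,
        warnings=list(matrix.warnings),
    )


def preprocess(matrix: ExpressionMatrix, config: PreprocessConfig) -> ExpressionMatrix:
    """Median filter followed by the offset + log transform."""
    return offset_log_transform(filter_by_median(matrix, config), config)
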