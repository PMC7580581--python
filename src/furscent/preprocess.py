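"""Preprocessing of aligned peak tables before distance-based analysis.

Three steps, applied in a fixed order:

1. **Singleton exclusion** — compounds detected in fewer than ``min_samples``
   samples (default 2, i.e. compounds seen in a single sample) are dropped.
   A compound observed once carries no information about group structure and
   is likely an alignment artifact or contaminant.
2. **Relative abundance** — each sample's abundances are scaled to sum to
   100 (percent).  Swab samples differ in total recovered material, so only
   the compositional profile is comparable across samples.
3. **log(x+1)** — natural log of (percent + 1), compressing the dominance of
   the most abundant peaks while mapping absent compounds (0) to 0.

The order matters: filtering before normalization means dropped singletons
do not contribute to the percent denominators.
"""

from __future__ import annotations

import logging

import numpy as np

from .io import AbundanceMatrix, FingerprintError, ValidatedDataset

logger = logging.getLogger("furscent")


def filter_rare_compounds(matrix: AbundanceMatrix, min_samples: int = 2) -> AbundanceMatrix:
    """Drop compounds with nonzero abundance in fewer than ``min_samples`` samples.

    Sample set and retained values are unchanged; only columns are removed.
    """
    if matrix.unit_state != "raw":
        raise FingerprintError(
            f"filter_rare_compounds expects raw abundances, got {matrix.unit_state!r}"
        )
    support = (matrix.values > 0).sum(axis=0)
    keep = support >= min_samples
    if not keep.any():
        raise FingerprintError("empty matrix after filtering rare compounds")
    dropped = [c for c, k in zip(matrix.compound_ids, keep) if not k]
    if dropped:
        logger.info("filter_rare_compounds: dropped %d of %d compounds: %s",
                    len(dropped), matrix.n_compounds, dropped[:10])
    return AbundanceMatrix(matrix.sample_ids,
                           [c for c, k in zip(matrix.compound_ids, keep) if k],
                           matrix.values[:, keep], "raw")


def to_relative_abundance(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each sample's abundances to sum to 100 percent."""
    if matrix.unit_state != "raw":
        raise FingerprintError(
            f"to_relative_abundance expects raw abundances, got {matrix.unit_state!r}"
        )
    totals = matrix.values.sum(axis=1)
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise FingerprintError(
            f"sample {matrix.sample_ids[zero[0]]!r} has zero total abundance"
        )
    return matrix.with_values(100.0 * matrix.values / totals[:, None], "relative_percent")


def log_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Replace every cell x by ln(x+1).  Zeros stay zero."""
    if matrix.unit_state != "relative_percent":
        raise FingerprintError(
            "log_transform expects relative_percent abundances "
            f"(got {matrix.unit_state!r}); refusing a possible double transform"
        )
    return matrix.with_values(np.log1p(matrix.values), "log_relative")


def preprocess_pipeline(dataset: ValidatedDataset, min_samples: int = 2) -> ValidatedDataset:
    """filter_rare_compounds -> to_relative_abundance -> log_transform."""
    matrix = filter_rare_compounds(dataset.matrix, min_samples=min_samples)
    matrix = to_relative_abundance(matrix)
    matrix = log_transform(matrix)
    return ValidatedDataset(matrix, dataset.metadata)
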