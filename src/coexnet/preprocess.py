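"""Sample subsetting and expression-level gene filtering.

Each network in the pipeline is built from one subset of the data: samples
of a single exposure condition, optionally restricted to doses below a
cutoff (e.g. the low-dose arm below 12.5 uM), and the top-N most highly
expressed genes of that subset by rank-mean expression.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import rankdata

from .containers import ExpressionMatrix, SampleMetadata
from .errors import ValidationError

logger = logging.getLogger(__name__)


def subset_condition(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    condition: str,
    max_dose_exclusive: float | None = None,
) -> ExpressionMatrix:
    """Restrict to samples of one condition with dose strictly below a cutoff.

    ``max_dose_exclusive`` is in molar units; ``None`` keeps all doses.
    Sample order of the input matrix is preserved. An empty result is an
    error naming the filter.
    """
    meta.check_condition(condition)
    sub = meta.frame.loc[meta.frame["condition"] == condition]
    wanted = dict(zip(sub["sample_id"].astype(str), sub["dose_molar"].astype(float)))
    keep = []
    for s in expr.sample_ids:
        if s in wanted:
            dose = wanted[s]
            if max_dose_exclusive is None or dose < max_dose_exclusive:
                keep.append(s)
    if not keep:
        raise ValidationError(
            f"no samples left for condition={condition!r}, "
            f"dose < {max_dose_exclusive!r}"
        )
    logger.info(
        "subset %r (dose < %s): %d of %d samples retained",
        condition, max_dose_exclusive, len(keep), expr.n_samples,
    )
    return expr.select_samples(keep)


def rank_mean_filter(expr: ExpressionMatrix, top_n: int) -> ExpressionMatrix:
    """Keep the ``top_n`` most highly expressed genes by rank-mean expression.

    Within each sample, genes are ranked ascending by expression (midranks
    for ties), so higher expression means higher rank; genes are then
    ordered by the mean of those ranks across samples, descending, with a
    lexicographic gene-id tie-break, and the first ``top_n`` are retained.
    Being rank-based, the selection is invariant under any strictly
    monotone per-sample transform of the data.
    """
    if top_n < 2:
        raise ValidationError(f"top_n must be >= 2, got {top_n}")
    values = expr.values
    ranks = np.apply_along_axis(rankdata, 0, values)  # per sample (column)
    mean_rank = ranks.mean(axis=1)
    genes = np.array(expr.gene_ids)
    # descending mean rank, ties by ascending gene id
    order = np.lexsort((genes, -mean_rank))
    kept = genes[order[: min(top_n, len(genes))]].tolist()
    if top_n < len(genes):
        logger.info("rank-mean filter: kept %d of %d genes", len(kept), len(genes))
    return expr.select_genes(kept)
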