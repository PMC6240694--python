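"""Signed weighted co-expression networks and topological overlap.

The network construction follows the standard weighted-network recipe:
pairwise signed Spearman correlation, soft thresholding
``a_ij = ((1 + r_ij)/2)**beta`` with beta = 10 by default, and the
classical topological overlap matrix (TOM)

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),

where ``L_ij = sum_u a_iu a_uj`` over third genes and ``k_i`` is the
connectivity of gene i. ``1 - TOM`` is the clustering dissimilarity.
Consensus networks across conditions are formed by putting each
condition's TOM on a common scale (single-quantile calibration) and
taking the entrywise minimum, so only co-expression present in every
condition survives.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.stats import rankdata

from .containers import (
    AdjacencyMatrix,
    CalibrationRecord,
    CorrelationMatrix,
    ExpressionMatrix,
    TOMMatrix,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Largest gene count handled in a single dense block. Larger inputs are an
#: error: filter harder rather than silently going blockwise.
DEFAULT_MAX_BLOCK_SIZE = 10_000


def spearman_correlation(expr: ExpressionMatrix) -> CorrelationMatrix:
    """Pairwise Spearman correlation: Pearson on per-gene midranks.

    Requires >= 4 complete samples. A gene with zero rank variance
    (constant expression) gets correlation 0 with every other gene
    (logged); the diagonal is exactly 1.
    """
    expr.require_network_ready()
    ranks = np.apply_along_axis(rankdata, 1, expr.values)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0.0
    if constant.any():
        logger.info(
            "spearman: %d constant genes get correlation 0", int(constant.sum())
        )
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(tuple(expr.gene_ids), corr)


def signed_adjacency(cor: CorrelationMatrix, beta: float = 10.0) -> AdjacencyMatrix:
    """Signed soft-thresholded adjacency ``((1 + r)/2)**beta``; diagonal 1."""
    if beta < 1:
        raise ValidationError(f"beta must be >= 1, got {beta}")
    adj = ((1.0 + cor.values) / 2.0) ** beta
    np.clip(adj, 0.0, 1.0, out=adj)
    adj = (adj + adj.T) / 2.0
    np.fill_diagonal(adj, 1.0)
    return AdjacencyMatrix(cor.gene_ids, adj, beta=beta)


def topological_overlap(
    adj: AdjacencyMatrix, max_block_size: int = DEFAULT_MAX_BLOCK_SIZE
) -> TOMMatrix:
    """Topological overlap of a weighted adjacency, computed densely.

    Uses one matrix product for the shared-neighbor term, so it scales to
    the 10,000-gene networks the pipeline targets in a single block.
    """
    n = adj.n_genes
    if n > max_block_size:
        raise ValidationError(
            f"{n} genes exceeds max_block_size={max_block_size}; "
            "apply a stronger expression filter"
        )
    a = adj.values.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # shared[i, j] = sum_u a_iu a_uj, u != i and u != j (diag 0)
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = numer / np.maximum(denom, 1e-12)
    np.clip(tom, 0.0, 1.0, out=tom)
    tom = (tom + tom.T) / 2.0
    np.fill_diagonal(tom, 1.0)
    return TOMMatrix(adj.gene_ids, tom)


def _offdiag(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(values, k=1)
    return values[iu]


def calibrate_toms(
    toms: list[TOMMatrix], quantile: float = 0.95
) -> list[TOMMatrix]:
    """Put TOMs from different conditions on a common scale.

    Each matrix is multiplied by ``s_k = Q_ref / Q_k`` where ``Q_k`` is its
    off-diagonal quantile-``quantile`` value and ``Q_ref`` the median of
    the ``Q_k``; results are clipped to [0, 1] and the scale factors are
    recorded on each output. This single-quantile calibration keeps the
    later entrywise minimum from being dominated by whichever condition
    happens to have globally weaker overlap.
    """
    if len(toms) < 2:
        raise ValidationError("calibration needs >= 2 TOM matrices")
    ref_genes = toms[0].gene_ids
    for t in toms[1:]:
        if t.gene_ids != ref_genes:
            diff = sorted(set(ref_genes) ^ set(t.gene_ids))
            raise ValidationError(
                f"TOM gene sets differ; symmetric difference (first 10): {diff[:10]}"
            )
    qs = np.array([np.quantile(_offdiag(t.values), quantile) for t in toms])
    if np.any(qs <= 0):
        raise ValidationError("degenerate TOM: off-diagonal quantile is 0")
    q_ref = float(np.median(qs))
    scales = q_ref / qs
    out = []
    for t, s in zip(toms, scales):
        values = np.clip(t.values * s, 0.0, 1.0)
        np.fill_diagonal(values, 1.0)
        record = CalibrationRecord(quantile, q_ref, tuple(float(x) for x in scales))
        out.append(TOMMatrix(t.gene_ids, values, calibration=record))
    logger.info("TOM calibration at q=%s: scale factors %s", quantile, scales)
    return out


def consensus_tom(calibrated: list[TOMMatrix]) -> TOMMatrix:
    """Entrywise minimum of calibrated TOMs: structure shared by all inputs."""
    if len(calibrated) < 2:
        raise ValidationError("consensus needs >= 2 TOM matrices")
    ref_genes = calibrated[0].gene_ids
    for t in calibrated[1:]:
        if t.gene_ids != ref_genes:
            raise ValidationError("consensus inputs must share gene order")
    values = np.minimum.reduce([t.values for t in calibrated])
    np.fill_diagonal(values, 1.0)
    return TOMMatrix(
        ref_genes, values, is_consensus=True, calibration=calibrated[0].calibration
    )
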