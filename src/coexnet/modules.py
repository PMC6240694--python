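"""Module detection: clustering, adaptive tree cutting, eigengenes.

Genes are clustered by average linkage on the TOM dissimilarity and the
dendrogram is cut adaptively (a dynamic tree cut): a static cut just
below the top of the tree defines candidate branches, and each branch is
recursively split wherever both sub-branches look like modules on their
own — large enough, internally tight (low "core scatter") and separated
from their sibling by a clear height gap. The deep-split level trades
sensitivity for robustness via the published mapping from level to
(max core scatter, min gap). Genes in no accepted branch stay grey.

Each module is summarized by its eigengene — the first principal
component of the standardized member expression — and genes are scored
by kME, their correlation with each eigengene. Modules whose eigengenes
are highly correlated are merged (merge cut height on 1 - cor), and
misplaced genes can be reassigned to the module whose eigengene they
track significantly better.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from .containers import GREY, EigengeneSet, ExpressionMatrix, ModulePartition
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: deep split level -> (max core scatter, min branch gap), both as fractions
#: of the static cut height. Higher levels split more aggressively.
DEEP_SPLIT_PARAMS: dict[int, tuple[float, float]] = {
    0: (0.64, 0.27),
    1: (0.73, 0.2025),
    2: (0.82, 0.135),
    3: (0.91, 0.0675),
    4: (0.95, 0.0375),
}


def average_linkage(dissim: np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) agglomeration of a square dissimilarity.

    Returns a scipy linkage matrix (n-1 merges of (left, right, height,
    size)). scipy's implementation is deterministic, breaking ties by the
    smallest cluster index.
    """
    d = np.asarray(dissim, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("dissimilarity must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("dissimilarity must be symmetric")
    condensed = squareform(d, checks=False)
    return linkage(condensed, method="average")


@dataclass
class _Tree:
    """Flat arrays describing the dendrogram's internal nodes."""

    n_leaves: int
    heights: np.ndarray          # per internal node
    children: np.ndarray         # (n-1, 2) node ids; leaves are 0..n-1
    leaves: list[list[int]]      # per internal node, member leaf ids
    internal_height_sum: np.ndarray
    internal_count: np.ndarray


def _build_tree(link: np.ndarray, n: int) -> _Tree:
    m = link.shape[0]
    heights = link[:, 2].copy()
    children = link[:, :2].astype(int)
    leaves: list[list[int]] = []
    hsum = np.zeros(m)
    hcount = np.zeros(m, dtype=int)
    for i in range(m):
        node_leaves: list[int] = []
        s, c = 0.0, 0
        for child in children[i]:
            if child < n:
                node_leaves.append(child)
            else:
                j = child - n
                node_leaves.extend(leaves[j])
                s += hsum[j]
                c += hcount[j]
        s += heights[i]
        c += 1
        leaves.append(node_leaves)
        hsum[i] = s
        hcount[i] = c
    return _Tree(n, heights, children, leaves, hsum, hcount)


def dynamic_tree_cut(
    link: np.ndarray,
    deep_split: int = 2,
    min_module_size: int = 30,
    cut_height: float | None = None,
) -> np.ndarray:
    """Cut a dendrogram into modules adaptively.

    Parameters
    ----------
    link:
        scipy linkage matrix over the TOM dissimilarity.
    deep_split:
        0-4; selects (max core scatter, min gap) from
        :data:`DEEP_SPLIT_PARAMS`. Level 2 is the conventional default.
    min_module_size:
        smallest accepted module.
    cut_height:
        static cut defining candidate branches; defaults to 0.99 x the
        maximum merge height.

    Returns
    -------
    Integer labels per leaf: 0 for unassigned (grey), 1..m for modules in
    order of discovery (left to right in the tree).

    Notes
    -----
    A subtree's *core scatter* is the mean of its internal merge heights
    and its *gap* is the drop from the height at which it attaches to its
    sibling down to its own typical internal height (its scatter) — so a
    genuine module attaches well above the level at which its members
    cohere, and stray leaves chaining onto a branch cannot erase its gap.
    Both are judged on the scale of the tree itself: heights are
    normalized relative to the reference height ``h_ref`` (the
    5th-percentile merge height, i.e. the tightest merges observed), so
    the scatter criterion is
    ``scatter <= h_ref + max_core_scatter * (cut_height - h_ref)`` and
    the gap criterion ``gap >= min_gap * (cut_height - h_ref)``. Without
    this baseline, strongly soft-thresholded networks — where even
    within-module dissimilarities sit high in [0, 1] — would never yield
    an acceptable branch. A sub-branch is viable when it meets the size
    floor, its scatter is within bounds and its gap large enough. A
    branch whose two children are both viable is split; a branch with a
    split point anywhere below it is descended (stray leaves chained
    between split points go grey, to be rescued later by kME-based
    cleanup and reassignment); only a branch with no split below is
    accepted whole when its own scatter qualifies, and loose branches
    are descended in search of tight sub-branches, stranding the rest
    as grey.
    """
    if deep_split not in DEEP_SPLIT_PARAMS:
        raise ValidationError(f"deep_split must be in 0..4, got {deep_split}")
    n = link.shape[0] + 1
    labels = np.zeros(n, dtype=int)
    if min_module_size > n:
        warnings.warn(
            f"min_module_size={min_module_size} exceeds gene count {n}; "
            "all genes left unassigned",
            stacklevel=2,
        )
        return labels
    max_scatter, min_gap = DEEP_SPLIT_PARAMS[deep_split]
    tree = _build_tree(link, n)
    h0 = cut_height if cut_height is not None else 0.99 * float(tree.heights.max())
    if h0 <= 0:
        # degenerate: everything merges at height 0 -> one module
        labels[:] = 1 if n >= min_module_size else 0
        return labels
    h_ref = float(np.quantile(tree.heights, 0.05))
    h_ref = min(h_ref, h0)  # guard: explicit cut height below the reference
    span = max(h0 - h_ref, 1e-12)
    max_abs_scatter = h_ref + max_scatter * span
    min_abs_gap = min_gap * span

    def size(node: int) -> int:
        return 1 if node < n else len(tree.leaves[node - n])

    def height(node: int) -> float:
        return 0.0 if node < n else float(tree.heights[node - n])

    def scatter(node: int) -> float:
        if node < n:
            return 0.0
        j = node - n
        return float(tree.internal_height_sum[j] / tree.internal_count[j])

    next_label = [1]

    def accept(node: int) -> None:
        members = [node] if node < n else tree.leaves[node - n]
        labels[members] = next_label[0]
        next_label[0] += 1

    def viable(child: int, parent_height: float) -> bool:
        return (
            size(child) >= min_module_size
            and scatter(child) <= max_abs_scatter
            and (parent_height - scatter(child)) >= min_abs_gap
        )

    # split_below[j]: node n+j or some descendant has two viable children
    split_below = np.zeros(link.shape[0], dtype=bool)
    for j in range(link.shape[0]):
        left, right = tree.children[j]
        here = viable(left, tree.heights[j]) and viable(right, tree.heights[j])
        below = any(
            split_below[c - n] for c in tree.children[j] if c >= n
        )
        split_below[j] = here or below

    def harvest(node: int) -> None:
        if size(node) < min_module_size:
            return  # stays grey
        left, right = tree.children[node - n]
        h = height(node)
        if viable(left, h) and viable(right, h):
            harvest(left)
            harvest(right)
        elif split_below[node - n] or scatter(node) > max_abs_scatter:
            harvest(left)
            harvest(right)
        else:
            accept(node)

    def top(node: int) -> None:
        if node < n:
            return  # lone leaf above the cut -> grey
        if height(node) <= h0:
            harvest(node)
        else:
            left, right = tree.children[node - n]
            top(left)
            top(right)

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 4 * n + 100))
    try:
        top(n + link.shape[0] - 1)  # root node id
    finally:
        sys.setrecursionlimit(old_limit)
    return labels


def partition_from_labels(
    gene_ids: list[str] | tuple[str, ...], labels: np.ndarray
) -> ModulePartition:
    """Turn integer cut labels (0 = grey) into a color-labelled partition."""
    named = tuple(GREY if lab == 0 else f"m{lab}" for lab in labels)
    return ModulePartition(tuple(gene_ids), named).relabel_by_size()


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    return (x - mu) / sd_safe


def module_eigengene(
    expr: ExpressionMatrix, partition: ModulePartition
) -> EigengeneSet:
    """First principal component of each module's standardized expression.

    Member genes are z-scored across samples; the eigengene is the first
    right singular vector of the member x sample matrix, unit norm, with
    its sign chosen so the mean correlation with member profiles is
    non-negative. Variance explained is the first squared singular value
    over the total. A single-gene module's eigengene is that gene's
    normalized z-profile.
    """
    frame = expr.frame
    profiles: dict[str, np.ndarray] = {}
    varexp: dict[str, float] = {}
    for label, genes in partition.modules.items():
        x = _zscore_rows(frame.loc[genes].to_numpy(dtype=float))
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        eig = vt[0]
        total = float((s**2).sum())
        ve = float(s[0] ** 2 / total) if total > 0 else 1.0
        # sign convention: mean member correlation >= 0
        corr_sum = 0.0
        eig_c = eig - eig.mean()
        eig_norm = np.linalg.norm(eig_c)
        for row in x:
            rn = np.linalg.norm(row - row.mean())
            if rn > 0 and eig_norm > 0:
                corr_sum += float((row - row.mean()) @ eig_c) / (rn * eig_norm)
        if corr_sum < 0:
            eig = -eig
        profiles[label] = eig / np.linalg.norm(eig)
        varexp[label] = ve
    return EigengeneSet(tuple(expr.sample_ids), profiles, varexp)


def kme(expr: ExpressionMatrix, eigengenes: EigengeneSet) -> pd.DataFrame:
    """Gene x module matrix of correlations with each eigengene.

    Pearson correlation of the z-scored gene profile with the eigengene
    profile; constant genes get kME 0 (logged).
    """
    x = expr.values
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0.0
    if constant.any():
        logger.info("kME: %d constant genes get kME 0", int(constant.sum()))
    unit = centered / np.where(constant, 1.0, norms)[:, None]
    cols = {}
    for label, prof in eigengenes.profiles.items():
        pc = prof - prof.mean()
        pn = np.linalg.norm(pc)
        if pn == 0:
            cols[label] = np.zeros(expr.n_genes)
            continue
        vals = unit @ (pc / pn)
        vals[constant] = 0.0
        cols[label] = np.clip(vals, -1.0, 1.0)
    return pd.DataFrame(cols, index=expr.gene_ids)


def correlation_p_value(r: np.ndarray | float, n: int) -> np.ndarray | float:
    """Two-sided Student-t p-value for a correlation at n samples."""
    r_arr = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    if df <= 0:
        raise ValidationError(f"correlation test needs >= 3 samples, got {n}")
    with np.errstate(divide="ignore"):
        t_stat = np.abs(r_arr) * np.sqrt(df / np.maximum(1.0 - r_arr**2, 0.0))
    p = np.where(np.isinf(t_stat), 0.0, 2.0 * t_dist.sf(np.where(np.isinf(t_stat), 0.0, t_stat), df))
    return p if p.ndim else float(p)


def trim_low_kme_genes(
    expr: ExpressionMatrix,
    partition: ModulePartition,
    eigengenes: EigengeneSet,
    min_kme_to_stay: float = 0.3,
    min_module_size: int = 1,
) -> ModulePartition:
    """Send genes that barely track their module's eigengene to grey.

    Assigned genes with own-module kME below ``min_kme_to_stay`` become
    grey; a module left smaller than ``min_module_size`` disbands
    entirely. This is the standard cleanup after an adaptive tree cut:
    branches inevitably pick up stray genes that happened to merge
    nearby, and a loose branch of mutually unrelated genes dissolves here
    because none of its members correlate with the branch eigengene.
    """
    kme_table = kme(expr, eigengenes)
    labels = list(partition.labels)
    trimmed = 0
    for idx, (gene, lab) in enumerate(zip(partition.gene_ids, partition.labels)):
        if lab == GREY or lab not in kme_table.columns:
            continue
        if float(kme_table.loc[gene, lab]) < min_kme_to_stay:
            labels[idx] = GREY
            trimmed += 1
    out = ModulePartition(partition.gene_ids, tuple(labels))
    disbanded = [
        lab for lab, genes in out.modules.items() if len(genes) < min_module_size
    ]
    if disbanded:
        labels = [GREY if lab in disbanded else lab for lab in out.labels]
        out = ModulePartition(out.gene_ids, tuple(labels))
    if trimmed or disbanded:
        logger.info(
            "kME trim: %d genes -> grey, %d modules disbanded", trimmed, len(disbanded)
        )
    return out


def merge_close_modules(
    expr: ExpressionMatrix,
    partition: ModulePartition,
    eigengenes: EigengeneSet,
    merge_cut_height: float = 0.25,
) -> tuple[ModulePartition, EigengeneSet]:
    """Union modules whose eigengenes are closer than the merge cut height.

    Eigengenes are clustered by average linkage on 1 - cor(ME_i, ME_j);
    every cluster of modules below ``merge_cut_height`` is unioned and
    eigengenes are recomputed, repeating until a fixed point, so a second
    call is a no-op. Grey never merges.
    """
    current = partition
    eig = eigengenes
    for _ in range(100):
        labels = list(eig.profiles)
        if len(labels) < 2:
            break
        me = np.stack([eig.profiles[lab] for lab in labels])
        me_c = me - me.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(me_c, axis=1)
        norms = np.where(norms == 0.0, 1.0, norms)
        cor = np.clip((me_c / norms[:, None]) @ (me_c / norms[:, None]).T, -1, 1)
        dissim = 1.0 - cor
        np.fill_diagonal(dissim, 0.0)
        link = average_linkage(dissim)
        clusters = fcluster(link, t=merge_cut_height, criterion="distance")
        if len(set(clusters)) == len(labels):
            break  # nothing below the cut height -> fixed point
        sizes = {lab: len(g) for lab, g in current.modules.items()}
        # each cluster keeps the label of its largest constituent module
        mapping: dict[str, str] = {}
        for cl in sorted(set(clusters)):
            members = [lab for lab, c in zip(labels, clusters) if c == cl]
            keep = max(members, key=lambda lab: (sizes[lab], lab))
            for lab in members:
                mapping[lab] = keep
        new_labels = tuple(
            mapping.get(lab, lab) if lab != GREY else GREY for lab in current.labels
        )
        merged = ModulePartition(current.gene_ids, new_labels)
        if merged.modules.keys() == current.modules.keys():
            break
        logger.info(
            "merged %d modules into %d at cut height %s",
            len(labels), len(merged.modules), merge_cut_height,
        )
        current = merged
        eig = module_eigengene(expr, current)
    return current, eig


def reassign_genes(
    expr: ExpressionMatrix,
    partition: ModulePartition,
    eigengenes: EigengeneSet,
    reassign_threshold: float = 0.2,
) -> ModulePartition:
    """Move genes to a module whose eigengene they track significantly better.

    For each assigned gene, correlation p-values (Student t) against its
    own and every other eigengene are compared: the gene moves to module
    m' when ``p_m' < reassign_threshold * p_own`` and its kME there is
    higher; among qualifying modules the one with the highest kME wins.
    A single pass over genes, evaluated against the input eigengenes, so
    the operation terminates trivially; callers recompute eigengenes
    afterwards. A threshold of 0 disables reassignment.
    """
    if reassign_threshold <= 0:
        return partition
    kme_table = kme(expr, eigengenes)
    n = expr.n_samples
    p_table = pd.DataFrame(
        correlation_p_value(kme_table.to_numpy(), n),
        index=kme_table.index,
        columns=kme_table.columns,
    )
    new_labels = list(partition.labels)
    moved = 0
    for idx, (gene, own) in enumerate(zip(partition.gene_ids, partition.labels)):
        if own == GREY or own not in kme_table.columns:
            continue
        p_own = float(p_table.loc[gene, own])
        k_own = float(kme_table.loc[gene, own])
        best_lab, best_k = None, k_own
        for lab in kme_table.columns:
            if lab == own:
                continue
            if (
                float(p_table.loc[gene, lab]) < reassign_threshold * p_own
                and float(kme_table.loc[gene, lab]) > best_k
            ):
                best_lab = lab
                best_k = float(kme_table.loc[gene, lab])
        if best_lab is not None:
            new_labels[idx] = best_lab
            moved += 1
    if moved:
        logger.info("reassigned %d genes to better-fitting modules", moved)
    return ModulePartition(partition.gene_ids, tuple(new_labels))
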