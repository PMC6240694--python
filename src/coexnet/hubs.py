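"""Hub gene identification.

A module hub is a gene with high intramodular membership (top fraction
by own-module kME) that is also highly connected in an external
protein-protein interaction network (top fraction by degree within the
module-induced subgraph). Both criteria are rank-based with a
configurable top fraction; the intersection is returned ranked by kME.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import pandas as pd

from .containers import EdgeList, ModulePartition
from .errors import ValidationError

HUB_COLUMNS = ("module", "gene", "kME", "degree")


def module_degree(
    module_genes: Iterable[str], edges: EdgeList
) -> tuple[dict[str, int], float]:
    """Degrees within the module-induced subgraph and the average degree.

    The average node degree is 2 * E_within / |module|, the quantity PPI
    databases report for a gene set.
    """
    members = set(module_genes)
    degrees = {g: 0 for g in sorted(members)}
    e_within = 0
    for a, b in edges.pairs:
        if a in members and b in members:
            degrees[a] += 1
            degrees[b] += 1
            e_within += 1
    avg = 2.0 * e_within / len(members) if members else 0.0
    return degrees, avg


def _top_fraction(ranked: list[str], fraction: float) -> set[str]:
    k = max(1, math.ceil(fraction * len(ranked)))
    return set(ranked[:k])


def hub_candidates(
    kme: pd.DataFrame,
    partition: ModulePartition,
    degrees: Mapping[str, int],
    top_fraction: float = 0.1,
) -> pd.DataFrame:
    """Per-module hubs: top fraction by kME intersected with top by degree.

    Ranking ties are broken by gene id so shrinking ``top_fraction``
    always yields a subset. Returns a table (module, gene, kME, degree)
    ranked by kME within each module.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValidationError(f"top_fraction must be in (0, 1], got {top_fraction}")
    rows = []
    for label, genes in partition.modules.items():
        if label not in kme.columns:
            raise ValidationError(f"module {label!r} absent from kME matrix")
        by_kme = sorted(genes, key=lambda g: (-float(kme.loc[g, label]), g))
        by_degree = sorted(genes, key=lambda g: (-int(degrees.get(g, 0)), g))
        hubs = _top_fraction(by_kme, top_fraction) & _top_fraction(
            by_degree, top_fraction
        )
        for g in by_kme:
            if g in hubs:
                rows.append(
                    {
                        "module": label,
                        "gene": g,
                        "kME": float(kme.loc[g, label]),
                        "degree": int(degrees.get(g, 0)),
                    }
                )
    return pd.DataFrame(rows, columns=list(HUB_COLUMNS))
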