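"""Gene-set over-representation by Fisher's exact test.

Modules are tested for enrichment of user-supplied gene sets (e.g. TF
target libraries in GMT format) against the universe of analyzed network
genes, using the one-sided (enrichment-only) Fisher exact test — the
hypergeometric upper tail P(X >= overlap) — with Benjamini-Hochberg
adjustment within each module x library family.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetLibrary
from .errors import ValidationError

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = (
    "module", "set_name", "overlap", "module_size", "set_size", "universe", "p", "adj_p",
)


def bh_adjust(pvalues: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = list(pvalues)
    if not p:
        return []
    return list(multipletests(p, method="fdr_bh")[1])


def fisher_enrichment(
    module_genes: Iterable[str],
    library: GeneSetLibrary,
    universe: Iterable[str],
    module_label: str = "module",
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of each library set in a module.

    Sets are intersected with the universe before testing; sets with an
    empty intersection are skipped (logged). The p-value is the
    hypergeometric upper tail P(X >= overlap) for the 2x2 table of
    (overlap, module-only, set-only, rest); BH adjustment is applied over
    the returned family, and rows are ordered by adjusted p then name.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    module = set(module_genes) & universe
    if set(module_genes) - universe:
        extra = sorted(set(module_genes) - universe)
        raise ValidationError(f"module genes outside the universe: {extra[:10]}")
    m_total = len(universe)
    rows = []
    skipped = 0
    for set_name, genes in library.sets.items():
        in_universe = set(genes) & universe
        if not in_universe:
            skipped += 1
            continue
        overlap = len(module & in_universe)
        p = float(hypergeom.sf(overlap - 1, m_total, len(in_universe), len(module)))
        rows.append(
            {
                "module": module_label,
                "set_name": set_name,
                "overlap": overlap,
                "module_size": len(module),
                "set_size": len(in_universe),
                "universe": m_total,
                "p": min(p, 1.0),
            }
        )
    if skipped:
        logger.info(
            "enrichment %s: skipped %d sets with no universe overlap",
            module_label, skipped,
        )
    table = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "adj_p"])
    table["adj_p"] = bh_adjust(table["p"]) if len(table) else []
    table = table.sort_values(["adj_p", "p", "set_name"], kind="stable")
    return table.reset_index(drop=True)


def network_unique_genes(
    significant_modules_a: Mapping[str, Iterable[str]],
    universe_b: Iterable[str],
) -> set[str]:
    """Genes of condition A's significant modules absent from network B.

    ``significant_modules_a`` maps module label -> member genes of the
    modules selected as dose-significant in network A; ``universe_b`` is
    the full analyzed gene set of the comparison network.
    """
    pooled: set[str] = set()
    for genes in significant_modules_a.values():
        pooled.update(genes)
    return pooled - set(universe_b)
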