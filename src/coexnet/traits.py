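"""Module eigengene vs dose statistics.

Each module's eigengene is correlated with the dose trait; significance
comes from the standard Student-t test for a correlation coefficient,

    t = r * sqrt((n - 2) / (1 - r^2)),  p = 2 * P(T_{n-2} >= |t|).

Dose spans many decades (picomolar to micromolar), so the default trait
encoding is the ordinal dose level (1..L over the sorted unique doses),
which is invariant to the dose scale; log10 and linear encodings are
available. The consensus module-trait relationship across conditions is
conservative: the correlation of smallest magnitude when all conditions
agree in sign (with the largest p-value), undefined (NA) otherwise.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import EigengeneSet, SampleMetadata
from .errors import ValidationError
from .modules import correlation_p_value

logger = logging.getLogger(__name__)

TRAIT_TRANSFORMS = ("ordinal", "log10", "linear")


def dose_trait(
    meta: SampleMetadata,
    samples: list[str] | tuple[str, ...],
    transform: str = "ordinal",
) -> np.ndarray:
    """Encode each sample's dose as a numeric trait vector.

    ``ordinal`` maps the sorted unique doses to ranks 1..L; ``log10``
    takes log10(dose), sending zero doses to log10(min positive dose) - 1;
    ``linear`` returns raw molar values.
    """
    doses = meta.doses_for(samples)
    if transform == "ordinal":
        unique = np.unique(doses)
        level = {d: i + 1 for i, d in enumerate(unique)}
        return np.array([float(level[d]) for d in doses])
    if transform == "log10":
        positive = doses[doses > 0]
        if positive.size == 0:
            raise ValidationError("log10 transform impossible: all doses are 0")
        floor = np.log10(positive.min()) - 1.0
        with np.errstate(divide="ignore"):
            out = np.where(doses > 0, np.log10(np.where(doses > 0, doses, 1.0)), floor)
        return out
    if transform == "linear":
        return doses.astype(float)
    raise ValidationError(f"unknown transform {transform!r}; use {TRAIT_TRANSFORMS}")


def eigengene_trait_correlation(
    eigengenes: EigengeneSet,
    trait: np.ndarray,
    condition: str = "",
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate each module eigengene with the trait vector.

    Returns a table with columns module, condition, r, p, n; ``p`` is the
    two-sided Student-t p-value (0 when |r| = 1).
    """
    trait = np.asarray(trait, dtype=float)
    n = len(eigengenes.sample_ids)
    if trait.shape != (n,):
        raise ValidationError(f"trait length {trait.shape} != sample count {n}")
    if n < 4:
        raise ValidationError(f"trait correlation needs >= 4 samples, got {n}")
    if np.std(trait) == 0:
        raise ValidationError("trait has zero variance")
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown method {method!r}")
    tvec = rankdata(trait) if method == "spearman" else trait
    tc = tvec - tvec.mean()
    tn = np.linalg.norm(tc)
    rows = []
    for label, prof in eigengenes.profiles.items():
        pvec = rankdata(prof) if method == "spearman" else prof
        pc = pvec - pvec.mean()
        pn = np.linalg.norm(pc)
        r = float(np.clip(pc @ tc / (pn * tn), -1.0, 1.0)) if pn > 0 else 0.0
        rows.append(
            {
                "module": label,
                "condition": condition,
                "r": r,
                "p": correlation_p_value(r, n),
                "n": n,
            }
        )
    return pd.DataFrame(rows, columns=["module", "condition", "r", "p", "n"])


def select_significant(table: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Rows with p strictly below alpha, sorted by descending correlation."""
    out = table.loc[table["p"] < alpha].copy()
    out = out.sort_values(["r", "module"], ascending=[False, True], kind="stable")
    return out.reset_index(drop=True)


def consensus_trait_relationship(
    per_condition: list[pd.DataFrame],
) -> pd.DataFrame:
    """Summarize per-condition module-trait rows into a consensus table.

    Per module: when every condition's correlation shares one sign, the
    consensus is the correlation of smallest magnitude (sign preserved)
    with the largest of the p-values; on any sign disagreement, or when a
    module is missing from some condition, the consensus is NA (logged).
    """
    if len(per_condition) < 2:
        raise ValidationError("consensus needs >= 2 per-condition tables")
    all_modules = sorted({m for tab in per_condition for m in tab["module"]})
    rows = []
    for module in all_modules:
        rs, ps = [], []
        missing = False
        for tab in per_condition:
            hit = tab.loc[tab["module"] == module]
            if len(hit) != 1:
                missing = True
                break
            rs.append(float(hit["r"].iloc[0]))
            ps.append(float(hit["p"].iloc[0]))
        if missing:
            logger.info("module %s missing from a condition; consensus NA", module)
            rows.append({"module": module, "consensus_r": np.nan, "consensus_p": np.nan})
            continue
        signs = {np.sign(r) for r in rs}
        if len(signs) == 1 and 0.0 not in signs:
            idx = int(np.argmin(np.abs(rs)))
            rows.append(
                {"module": module, "consensus_r": rs[idx], "consensus_p": max(ps)}
            )
        else:
            rows.append({"module": module, "consensus_r": np.nan, "consensus_p": np.nan})
    return pd.DataFrame(rows, columns=["module", "consensus_r", "consensus_p"])
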