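"""Core in-memory containers for the network pipeline.

All containers are thin, validated wrappers around pandas / numpy objects:

* :class:`ExpressionMatrix` — genes x samples normalized expression.
* :class:`SampleMetadata` — per-sample condition and molar dose.
* :class:`GeneSetLibrary` — named gene sets (e.g. TF target libraries).
* :class:`EdgeList` — undirected gene-gene interaction edges.
* :class:`GeneMatrix` and its subclasses — symmetric gene-gene matrices
  (correlation, adjacency, topological overlap) with their invariants.
* :class:`ModulePartition`, :class:`EigengeneSet` — module detection output.

Validation happens at construction; downstream code may assume the
invariants hold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Conventional module color sequence, assigned by decreasing module size.
MODULE_COLORS: tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)

#: Reserved label for genes assigned to no module.
GREY = "grey"


def _check_unique_nonempty(ids: Sequence, what: str) -> None:
    if len(ids) == 0:
        raise ValidationError(f"{what} must be non-empty")
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if list(ids).count(x) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:10]}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized expression, genes in rows, samples in columns.

    Values are unitless normalized intensities; all entries must be finite.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique_nonempty(list(self.frame.index), "gene ids")
        _check_unique_nonempty(list(self.frame.columns), "sample ids")
        values = self.frame.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(values)):
            n_bad = int((~np.isfinite(values)).sum())
            raise ValidationError(
                f"expression matrix contains {n_bad} non-finite values; "
                "impute or drop them before network analysis"
            )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.frame.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self.frame.shape[1]

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.frame.columns]
        if missing:
            raise ValidationError(f"unknown samples: {missing[:10]}")
        return ExpressionMatrix(self.frame.loc[:, list(sample_ids)])

    def select_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.frame.index]
        if missing:
            raise ValidationError(f"unknown genes: {missing[:10]}")
        return ExpressionMatrix(self.frame.loc[list(gene_ids), :])

    def require_network_ready(self) -> None:
        """Network stages need >= 2 genes and >= 4 samples."""
        if self.n_genes < 2 or self.n_samples < 4:
            raise ValidationError(
                f"network operations need >= 2 genes and >= 4 samples, "
                f"got {self.n_genes} x {self.n_samples}"
            )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample condition label and dose in molar units (>= 0)."""

    frame: pd.DataFrame  # columns: sample_id, condition, dose_molar[, replicate]

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "dose_molar"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        _check_unique_nonempty(list(self.frame["sample_id"]), "sample ids")
        doses = self.frame["dose_molar"].to_numpy(dtype=float)
        if not np.all(np.isfinite(doses)) or np.any(doses < 0):
            raise ValidationError("doses must be finite and non-negative (molar)")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame["sample_id"]]

    @property
    def conditions(self) -> list[str]:
        return sorted(self.frame["condition"].unique())

    def dose_of(self, sample_id: str) -> float:
        row = self.frame.loc[self.frame["sample_id"] == sample_id]
        if row.empty:
            raise ValidationError(f"unknown sample {sample_id!r}")
        return float(row["dose_molar"].iloc[0])

    def doses_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = dict(zip(self.frame["sample_id"], self.frame["dose_molar"]))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing[:10]}")
        return np.array([float(lookup[s]) for s in sample_ids])

    def check_condition(self, condition: str, min_dose_levels: int = 3) -> None:
        sub = self.frame.loc[self.frame["condition"] == condition]
        if sub.empty:
            raise ValidationError(f"condition {condition!r} not present in metadata")
        n_levels = sub["dose_molar"].nunique()
        if n_levels < min_dose_levels:
            raise ValidationError(
                f"condition {condition!r} has {n_levels} dose levels; "
                f">= {min_dose_levels} required"
            )


@dataclass(frozen=True)
class GeneSetLibrary:
    """Named gene sets; duplicate ids within a set are collapsed."""

    library_name: str
    sets: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValidationError(f"library {self.library_name!r} has no sets")
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} not deduplicated")

    @staticmethod
    def from_raw(name: str, raw: Mapping[str, Iterable[str]]) -> "GeneSetLibrary":
        sets = {}
        for set_name, genes in raw.items():
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(str(g))
            sets[set_name] = tuple(seen)
        return GeneSetLibrary(name, sets)

    @property
    def gene_space(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EdgeList:
    """Undirected interaction edges; each unordered pair stored once.

    ``scores`` maps the canonical (sorted) pair to an optional confidence
    in [0, 1]; self-loops are rejected.
    """

    scores: Mapping[tuple[str, str], float | None]

    def __post_init__(self) -> None:
        for (a, b), s in self.scores.items():
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            if a > b:
                raise ValidationError(f"edge ({a!r}, {b!r}) not in canonical order")
            if s is not None and not (0.0 <= s <= 1.0):
                raise ValidationError(f"edge score {s} outside [0, 1]")

    @staticmethod
    def from_pairs(
        pairs: Iterable[tuple[str, str]] | Iterable[tuple[str, str, float]],
    ) -> "EdgeList":
        scores: dict[tuple[str, str], float | None] = {}
        dropped = 0
        for item in pairs:
            a, b = str(item[0]), str(item[1])
            s = float(item[2]) if len(item) > 2 and item[2] is not None else None
            if a == b:
                dropped += 1
                continue
            key = (a, b) if a < b else (b, a)
            scores[key] = s
        if dropped:
            logger.info("edge list: dropped %d self-loops", dropped)
        return EdgeList(scores)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self.scores)

    def __len__(self) -> int:
        return len(self.scores)


def _check_symmetric_bounded(
    values: np.ndarray, lo: float, hi: float, what: str, tol: float = 1e-12
) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"{what} must be square")
    if not np.allclose(values, values.T, atol=tol, rtol=0):
        raise ValidationError(f"{what} not symmetric within {tol}")
    if values.min() < lo - 1e-9 or values.max() > hi + 1e-9:
        raise ValidationError(
            f"{what} values outside [{lo}, {hi}]: range "
            f"[{values.min()}, {values.max()}]"
        )
    if not np.allclose(np.diag(values), 1.0, atol=tol):
        raise ValidationError(f"{what} diagonal must be exactly 1")


@dataclass(frozen=True)
class GeneMatrix:
    """Symmetric gene-by-gene matrix with unit diagonal."""

    gene_ids: tuple[str, ...]
    values: np.ndarray

    _lo = -1.0
    _hi = 1.0
    _name = "gene matrix"

    def __post_init__(self) -> None:
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValidationError("gene ids do not match matrix dimension")
        _check_symmetric_bounded(self.values, self._lo, self._hi, self._name)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class CorrelationMatrix(GeneMatrix):
    """Pairwise Spearman correlations in [-1, 1], unit diagonal."""

    _lo = -1.0
    _hi = 1.0
    _name = "correlation matrix"


@dataclass(frozen=True)
class AdjacencyMatrix(GeneMatrix):
    """Signed soft-thresholded adjacency in [0, 1]; records the power beta."""

    beta: float = 1.0
    _lo = 0.0
    _hi = 1.0
    _name = "adjacency matrix"


@dataclass(frozen=True)
class CalibrationRecord:
    """How a set of TOMs was put on a common scale before consensus."""

    quantile: float
    reference_value: float
    scale_factors: tuple[float, ...]


@dataclass(frozen=True)
class TOMMatrix(GeneMatrix):
    """Topological overlap in [0, 1]; 1 - TOM is the clustering dissimilarity."""

    is_consensus: bool = False
    calibration: CalibrationRecord | None = None
    _lo = 0.0
    _hi = 1.0
    _name = "TOM matrix"

    def dissimilarity(self) -> np.ndarray:
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d


@dataclass(frozen=True)
class ModulePartition:
    """gene -> module label; ``grey`` is reserved for unassigned genes.

    Labels other than grey follow the conventional color sequence in
    decreasing order of module size (after :func:`relabel_by_size`).
    """

    gene_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.labels):
            raise ValidationError("one label per gene required")
        _check_unique_nonempty(list(self.gene_ids), "gene ids")

    @property
    def modules(self) -> dict[str, list[str]]:
        """Label -> member genes, grey excluded, insertion order by label rank."""
        out: dict[str, list[str]] = {}
        for g, lab in zip(self.gene_ids, self.labels):
            if lab != GREY:
                out.setdefault(lab, []).append(g)
        return dict(sorted(out.items(), key=lambda kv: (-len(kv[1]), kv[0])))

    @property
    def n_assigned(self) -> int:
        return sum(1 for lab in self.labels if lab != GREY)

    def label_of(self, gene: str) -> str:
        try:
            return self.labels[self.gene_ids.index(gene)]
        except ValueError:
            raise ValidationError(f"gene {gene!r} not in partition") from None

    def relabel_by_size(self) -> "ModulePartition":
        """Rename modules to color labels ordered by decreasing size.

        Ties broken by the lexicographically smallest member gene, so the
        result is deterministic and permutation-equivariant.
        """
        groups: dict[str, list[str]] = {}
        for g, lab in zip(self.gene_ids, self.labels):
            if lab != GREY:
                groups.setdefault(lab, []).append(g)
        ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
        mapping = {GREY: GREY}
        for i, (old, _) in enumerate(ordered):
            if i < len(MODULE_COLORS):
                mapping[old] = MODULE_COLORS[i]
            else:
                mapping[old] = f"module_{i + 1}"
        return ModulePartition(
            self.gene_ids, tuple(mapping[lab] for lab in self.labels)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "module": self.labels})


@dataclass(frozen=True)
class EigengeneSet:
    """Module -> unit-norm first-principal-component sample profile."""

    sample_ids: tuple[str, ...]
    profiles: Mapping[str, np.ndarray]
    variance_explained: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for label, prof in self.profiles.items():
            if prof.shape != (n,):
                raise ValidationError(f"eigengene {label!r} has wrong length")
            norm = float(np.linalg.norm(prof))
            if not np.isclose(norm, 1.0, atol=1e-8):
                raise ValidationError(f"eigengene {label!r} not unit norm ({norm})")
        for label, ve in self.variance_explained.items():
            if not (0.0 < ve <= 1.0 + 1e-12):
                raise ValidationError(
                    f"variance explained for {label!r} outside (0, 1]: {ve}"
                )

    @property
    def module_labels(self) -> list[str]:
        return list(self.profiles)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {label: prof for label, prof in self.profiles.items()},
            index=list(self.sample_ids),
        ).T
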