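"""Synthetic dose-response expression data with planted module structure.

The generator emulates the design of an estrogenicity dose-response
microarray study: one or more exposure conditions, each profiled over a
dose grid spanning picomolar to micromolar concentrations (vehicle
control plus half-log steps by default), with a handful of replicates
per dose. Co-expression modules are planted through a latent
eigengene-like factor per module and condition,

    m(s) = alpha * f(dose_s) + sqrt(1 - alpha^2) * eta_s,

where ``f`` is a standardized dose-response shape (monotonic in the
ordinal dose, a unimodal low-dose bump, or null) and ``eta`` is standard
normal noise, so ``alpha`` is the latent profile's dose correlation.
Member genes load on the factor with strength ``lambda``:

    x_gs = lambda * m(s) + sqrt(1 - lambda^2) * eps_gs + offset_g,

so ``lambda`` is (in expectation) the gene-factor correlation. Background
genes are pure noise around their offsets. The generator also plants TF
target sets (a covered fraction of a module plus decoys) and an
interaction edge list with denser within-module connectivity and one
designated high-degree hub per module, and it emits the ground truth
needed to score recovery.

Everything is drawn from a single seeded generator: identical config and
seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .containers import (
    EdgeList,
    ExpressionMatrix,
    GeneSetLibrary,
    ModulePartition,
    SampleMetadata,
)
from .errors import ValidationError

#: Default dose grid: vehicle control plus 17 half-log steps, 1e-12..1e-4 M.
DEFAULT_DOSES: tuple[float, ...] = (0.0,) + tuple(
    float(1e-12 * 10 ** (0.5 * k)) for k in range(17)
)

BACKGROUND = "background"


@dataclass(frozen=True)
class ConditionSpec:
    """One exposure condition: name, dose grid (molar), replicates per dose."""

    name: str
    dose_levels: tuple[float, ...] = DEFAULT_DOSES
    replicates: int = 2

    def __post_init__(self) -> None:
        if len(set(self.dose_levels)) < 3:
            raise ValidationError("each condition needs >= 3 distinct dose levels")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.dose_levels) * self.replicates


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module.

    ``loading`` is the member-gene loading lambda in [0, 1]; ``dose_effect``
    the latent factor's dose correlation alpha in [-1, 1]; ``shape`` one of
    monotonic / low_dose_peak / null; private modules (``shared`` False)
    are active only in ``condition``.
    """

    size: int
    loading: float = 0.8
    dose_effect: float = 0.7
    shape: str = "monotonic"
    shared: bool = True
    condition: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.loading <= 1.0):
            raise ValidationError(f"loading outside [0, 1]: {self.loading}")
        if not (-1.0 <= self.dose_effect <= 1.0):
            raise ValidationError(f"dose_effect outside [-1, 1]: {self.dose_effect}")
        if self.shape not in ("monotonic", "low_dose_peak", "null"):
            raise ValidationError(f"unknown response shape {self.shape!r}")
        if self.size < 1:
            raise ValidationError("module size must be >= 1")
        if not self.shared and self.condition is None:
            raise ValidationError("private modules must name their condition")


@dataclass(frozen=True)
class TFSetSpec:
    """A planted TF target set: covered fraction of one module plus decoys."""

    target_module: int
    coverage: float = 0.5
    decoy_size: int = 50

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage <= 1.0):
            raise ValidationError(f"coverage outside (0, 1]: {self.coverage}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic study; defaults match the benchmark
    conditions used throughout the test-suite: 5 modules x 100 genes at
    loading 0.8 (three monotonic dose effects of |alpha| = 0.7, one
    low-dose peak, one null), 1500 background genes, and one 36-sample
    condition (18 dose levels x 2 replicates)."""

    seed: int = 0
    conditions: tuple[ConditionSpec, ...] = (ConditionSpec("estrogen"),)
    modules: tuple[ModuleSpec, ...] = (
        ModuleSpec(100, 0.8, 0.7, "monotonic"),
        ModuleSpec(100, 0.8, -0.7, "monotonic"),
        ModuleSpec(100, 0.8, 0.7, "monotonic"),
        ModuleSpec(100, 0.8, 0.5, "low_dose_peak"),
        ModuleSpec(100, 0.8, 0.0, "null"),
    )
    background_genes: int = 1500
    noise_sd: float = 1.0
    tf_sets: tuple[TFSetSpec, ...] = tuple(TFSetSpec(i) for i in range(5))
    edge_within_p: float = 0.15
    edge_between_p: float = 0.002
    offset_mean: float = 7.0
    offset_sd: float = 2.0
    #: added to member-gene expression in conditions where the module is
    #: active; emulates condition-specific induction so private modules
    #: can rank into their own condition's top-N list only. Off by default.
    active_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.background_genes < 0:
            raise ValidationError("background_genes must be >= 0")
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValidationError("condition names must be unique")
        for tf in self.tf_sets:
            if not (0 <= tf.target_module < len(self.modules)):
                raise ValidationError(
                    f"tf set targets unknown module {tf.target_module}"
                )

    @property
    def n_genes(self) -> int:
        return sum(m.size for m in self.modules) + self.background_genes


def two_condition_config(
    seed: int = 0,
    n_shared: int = 2,
    n_private_each: int = 2,
    module_size: int = 100,
    background_genes: int = 1500,
) -> SyntheticConfig:
    """A two-condition design with shared and condition-private modules.

    Shared modules carry the same-sign monotonic dose effect in both
    conditions; each condition additionally owns ``n_private_each``
    private modules that are pure noise in the other condition — the
    setting a consensus analysis is meant to resolve.
    """
    conditions = (ConditionSpec("estrogen"), ConditionSpec("bpa"))
    modules: list[ModuleSpec] = []
    for i in range(n_shared):
        alpha = 0.7 if i % 2 == 0 else -0.7
        modules.append(ModuleSpec(module_size, 0.8, alpha, "monotonic", shared=True))
    for cond in conditions:
        for _ in range(n_private_each):
            modules.append(
                ModuleSpec(
                    module_size, 0.8, 0.7, "monotonic",
                    shared=False, condition=cond.name,
                )
            )
    return SyntheticConfig(
        seed=seed,
        conditions=conditions,
        modules=tuple(modules),
        background_genes=background_genes,
        tf_sets=tuple(TFSetSpec(i) for i in range(len(modules))),
    )


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure emitted alongside the synthetic expression."""

    gene_modules: dict[str, str]          # gene -> module name or "background"
    module_names: tuple[str, ...]
    module_specs: dict[str, ModuleSpec]
    latent_profiles: dict[tuple[str, str], np.ndarray]  # (condition, module)
    tf_set_members: dict[str, tuple[str, ...]]
    hub_genes: dict[str, str]             # module -> designated hub gene
    edges: EdgeList

    def members(self, module: str) -> list[str]:
        return [g for g, m in self.gene_modules.items() if m == module]


@dataclass(frozen=True)
class SyntheticDataset:
    expression: ExpressionMatrix          # genes x all samples, all conditions
    metadata: SampleMetadata
    gene_sets: GeneSetLibrary | None      # None when no TF sets were planted
    edges: EdgeList
    truth: GroundTruth
    config: SyntheticConfig

    def condition_expression(self, condition: str) -> ExpressionMatrix:
        meta = self.metadata.frame
        samples = [
            s for s in self.expression.sample_ids
            if meta.loc[meta["sample_id"] == s, "condition"].iloc[0] == condition
        ]
        return self.expression.select_samples(samples)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _dose_shape(shape: str, doses: np.ndarray) -> np.ndarray:
    """Standardized dose-response profile over the per-sample dose vector."""
    levels = np.unique(doses)
    ordinal = np.searchsorted(levels, doses).astype(float)
    if shape == "monotonic":
        return _standardize(ordinal)
    if shape == "low_dose_peak":
        # unimodal bump centered on a low (nanomolar-range) dose level
        center = max(1.0, 0.25 * (len(levels) - 1))
        width = max(1.0, 0.12 * len(levels))
        return _standardize(np.exp(-0.5 * ((ordinal - center) / width) ** 2))
    return np.zeros_like(ordinal)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one synthetic dataset from the seeded generator."""
    rng = np.random.default_rng(config.seed)
    module_names = tuple(f"planted_{i + 1}" for i in range(len(config.modules)))
    n_genes = config.n_genes
    width = len(str(n_genes))
    gene_ids: list[str] = [f"G{i + 1:0{width}d}" for i in range(n_genes)]

    gene_modules: dict[str, str] = {}
    module_genes: dict[str, list[str]] = {}
    cursor = 0
    for name, spec in zip(module_names, config.modules):
        members = gene_ids[cursor : cursor + spec.size]
        cursor += spec.size
        module_genes[name] = members
        for g in members:
            gene_modules[g] = name
    background = gene_ids[cursor:]
    for g in background:
        gene_modules[g] = BACKGROUND

    offsets = rng.normal(config.offset_mean, config.offset_sd, size=n_genes)
    index_of = {g: i for i, g in enumerate(gene_ids)}

    sample_ids: list[str] = []
    meta_rows = []
    columns: list[np.ndarray] = []
    latent: dict[tuple[str, str], np.ndarray] = {}
    for cond in config.conditions:
        doses = np.repeat(np.array(cond.dose_levels, dtype=float), cond.replicates)
        ids = [
            f"{cond.name}_d{li:02d}_r{ri + 1}"
            for li in range(len(cond.dose_levels))
            for ri in range(cond.replicates)
        ]
        for sid, dose in zip(ids, doses):
            rep = int(sid.rsplit("_r", 1)[1])
            meta_rows.append(
                {"sample_id": sid, "condition": cond.name,
                 "dose_molar": dose, "replicate": rep}
            )
        n_s = len(ids)
        block = np.empty((n_genes, n_s))
        for name, spec in zip(module_names, config.modules):
            active = spec.shared or spec.condition == cond.name
            alpha = spec.dose_effect if (active and spec.shape != "null") else 0.0
            f = _dose_shape(spec.shape, doses) if active else np.zeros(n_s)
            eta = rng.standard_normal(n_s)
            m = alpha * f + np.sqrt(max(0.0, 1.0 - alpha**2)) * eta
            latent[(cond.name, name)] = m
            lam = spec.loading if active else 0.0
            rows = [index_of[g] for g in module_genes[name]]
            eps = rng.normal(0.0, config.noise_sd, size=(len(rows), n_s))
            # first member gene is the designated hub: maximal loading
            lams = np.full(len(rows), lam)
            if lam > 0:
                lams[0] = lam + (1.0 - lam) / 2.0
            block[rows, :] = (
                lams[:, None] * m[None, :]
                + np.sqrt(1.0 - lams**2)[:, None] * eps
            )
            if active and config.active_offset:
                block[rows, :] += config.active_offset
        bg_rows = [index_of[g] for g in background]
        if bg_rows:
            block[bg_rows, :] = rng.normal(
                0.0, config.noise_sd, size=(len(bg_rows), n_s)
            )
        block += offsets[:, None]
        sample_ids.extend(ids)
        columns.append(block)

    values = np.concatenate(columns, axis=1)
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    )
    metadata = SampleMetadata(pd.DataFrame(meta_rows))

    tf_members: dict[str, tuple[str, ...]] = {}
    gene_sets: GeneSetLibrary | None = None
    for i, tf in enumerate(config.tf_sets):
        target = module_names[tf.target_module]
        members = module_genes[target]
        n_cover = int(round(tf.coverage * len(members)))
        if n_cover > len(members):
            raise ValidationError("tf set coverage exceeds module size")
        covered = sorted(rng.choice(members, size=n_cover, replace=False).tolist())
        pool = background if background else gene_ids
        n_decoy = min(tf.decoy_size, len(pool))
        decoys = sorted(rng.choice(pool, size=n_decoy, replace=False).tolist())
        tf_members[f"TF{i + 1}_{target}"] = tuple(dict.fromkeys(covered + decoys))
    if tf_members:
        gene_sets = GeneSetLibrary.from_raw("planted_tf_targets", tf_members)

    pairs: list[tuple[str, str, float]] = []
    hub_genes: dict[str, str] = {}
    for name in module_names:
        members = module_genes[name]
        hub = members[0]
        hub_genes[name] = hub
        n_m = len(members)
        draws = rng.random((n_m, n_m))
        for a in range(n_m):
            for b in range(a + 1, n_m):
                ga, gb = members[a], members[b]
                p = 0.8 if hub in (ga, gb) else config.edge_within_p
                if draws[a, b] < p:
                    pairs.append((ga, gb, 0.9))
    # background / cross-module edges, drawn sparsely by count
    module_of = np.array([gene_modules[g] for g in gene_ids])
    n_pairs_total = n_genes * (n_genes - 1) // 2
    n_bg_edges = rng.binomial(n_pairs_total, config.edge_between_p)
    seen = set()
    attempts = 0
    while len(seen) < n_bg_edges and attempts < 20 * n_bg_edges + 100:
        a, b = rng.integers(0, n_genes, size=2)
        attempts += 1
        if a == b:
            continue
        i, j = (int(a), int(b)) if a < b else (int(b), int(a))
        if (i, j) in seen:
            continue
        if module_of[i] == module_of[j] and module_of[i] != BACKGROUND:
            continue  # within-module edges already drawn at their own rate
        seen.add((i, j))
        pairs.append((gene_ids[i], gene_ids[j], 0.4))
    edges = EdgeList.from_pairs(pairs)

    truth = GroundTruth(
        gene_modules=gene_modules,
        module_names=module_names,
        module_specs=dict(zip(module_names, config.modules)),
        latent_profiles=latent,
        tf_set_members=tf_members,
        hub_genes=hub_genes,
        edges=edges,
    )
    return SyntheticDataset(expression, metadata, gene_sets, edges, truth, config)


@dataclass(frozen=True)
class RecoveryScore:
    ari: float | None
    module_jaccard: dict[str, tuple[str | None, float]]
    sign_agreement: dict[str, bool] | None = None


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def score_recovery(
    partition: ModulePartition,
    truth: GroundTruth,
    trait_table: pd.DataFrame | None = None,
    condition: str | None = None,
) -> RecoveryScore:
    """Score a detected partition against the planted ground truth.

    ARI is computed over genes whose true label is a planted module (an
    all-background truth yields ARI = None). Each planted module is
    matched to the detected module of best Jaccard overlap. When a trait
    table is supplied, sign agreement compares each dose-responsive
    planted module's alpha sign with the detected correlation sign of its
    best-matching module.
    """
    detected = dict(zip(partition.gene_ids, partition.labels))
    missing = [g for g in truth.gene_modules if g not in detected]
    if missing:
        raise ValidationError(f"partition missing genes: {missing[:10]}")
    planted_genes = [g for g, m in truth.gene_modules.items() if m != BACKGROUND]
    if not planted_genes:
        return RecoveryScore(None, {})
    ari = float(
        adjusted_rand_score(
            [truth.gene_modules[g] for g in planted_genes],
            [detected[g] for g in planted_genes],
        )
    )
    modules = partition.modules
    jaccard: dict[str, tuple[str | None, float]] = {}
    for name in truth.module_names:
        true_set = set(truth.members(name))
        best, best_j = None, 0.0
        for label, genes in modules.items():
            j = _jaccard(true_set, set(genes))
            if j > best_j:
                best, best_j = label, j
        jaccard[name] = (best, best_j)

    sign_agreement = None
    if trait_table is not None:
        sign_agreement = {}
        for name in truth.module_names:
            spec = truth.module_specs[name]
            if spec.shape != "monotonic" or spec.dose_effect == 0:
                continue
            if condition is not None and not (
                spec.shared or spec.condition == condition
            ):
                continue
            label, j = jaccard[name]
            if label is None:
                sign_agreement[name] = False
                continue
            hit = trait_table.loc[trait_table["module"] == label]
            if hit.empty:
                sign_agreement[name] = False
                continue
            sign_agreement[name] = bool(
                np.sign(float(hit["r"].iloc[0])) == np.sign(spec.dose_effect)
            )
    return RecoveryScore(ari, jaccard, sign_agreement)
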