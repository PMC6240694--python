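"""Readers and writers for every external format the pipeline touches.

Formats are deliberately plain: tab-separated tables for expression,
metadata, edges and all result tables; GMT for gene-set libraries; one
JSON run report per pipeline run. Expression files are genes-in-rows —
the reader never guesses orientation. Every collapse or exclusion during
loading is logged with counts; nothing is dropped silently.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import TYPE_CHECKING, Any

import numpy as np
import pandas as pd

from .containers import EdgeList, ExpressionMatrix, GeneSetLibrary, SampleMetadata
from .errors import ParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import ConditionResult

logger = logging.getLogger(__name__)


def read_expression(path: str | Path, impute_missing: bool = False) -> ExpressionMatrix:
    """Read a genes-x-samples expression TSV (first column gene id).

    Duplicate gene ids are collapsed by keeping the row with the highest
    mean (logged). Missing values are rejected unless ``impute_missing``
    is set, in which case they are replaced by the gene's mean (logged).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValidationError(f"{path.name}: duplicate sample ids {dupes}")

    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        raw_missing = frame[col].isna() | frame[col].str.strip().eq("")
        bad = converted.isna() & ~raw_missing
        if bad.any():
            row = frame.index[bad.argmax()]
            raise ParseError(
                f"{path.name}: non-numeric value {frame.loc[row, col]!r} "
                f"at gene {row!r}, sample {col!r}"
            )
        numeric[col] = converted

    if numeric.index.duplicated().any():
        means = numeric.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        deduped = numeric.iloc[order]
        n_before = len(deduped)
        deduped = deduped[~deduped.index.duplicated(keep="first")]
        logger.info(
            "%s: collapsed %d duplicate gene rows (kept highest-mean row)",
            path.name, n_before - len(deduped),
        )
        numeric = deduped.loc[[g for g in dict.fromkeys(frame.index)]]

    if numeric.isna().any().any():
        n_missing = int(numeric.isna().sum().sum())
        if not impute_missing:
            raise ValidationError(
                f"{path.name}: {n_missing} missing values; pass "
                "impute_missing=True to mean-impute per gene"
            )
        row_means = numeric.mean(axis=1)
        numeric = numeric.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
        logger.info("%s: mean-imputed %d missing values", path.name, n_missing)

    numeric.index.name = "gene_id"
    return ExpressionMatrix(numeric)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.frame.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata TSV (sample_id, condition, dose_molar[, replicate])."""
    frame = pd.read_csv(Path(path), sep="\t", dtype={"sample_id": str, "condition": str})
    try:
        frame["dose_molar"] = frame["dose_molar"].astype(float)
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{Path(path).name}: bad dose_molar column: {exc}") from exc
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", index=False)


def check_samples_match(expr: ExpressionMatrix, meta: SampleMetadata) -> None:
    """Every analyzed sample must appear exactly once in the metadata."""
    known = set(meta.sample_ids)
    offenders = [s for s in expr.sample_ids if s not in known]
    if offenders:
        raise ValidationError(
            f"samples absent from metadata: {offenders[:10]}"
            + ("..." if len(offenders) > 10 else "")
        )


def read_gmt(path: str | Path, library_name: str | None = None) -> GeneSetLibrary:
    """Read a GMT gene-set library: set_name <TAB> description <TAB> genes..."""
    path = Path(path)
    raw: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: GMT line has {len(fields)} fields, "
                    "need set_name, description, >= 1 gene"
                )
            name = fields[0]
            if name in raw:
                raise ParseError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            raw[name] = [g for g in fields[2:] if g]
    if not raw:
        raise ParseError(f"{path.name}: no sets")
    return GeneSetLibrary.from_raw(library_name or path.stem, raw)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in library.sets.items():
            fh.write("\t".join([name, library.library_name, *genes]) + "\n")


def read_edge_list(path: str | Path) -> EdgeList:
    """Read an undirected edge TSV with header gene_a, gene_b[, score]."""
    frame = pd.read_csv(Path(path), sep="\t", dtype={"gene_a": str, "gene_b": str})
    if not {"gene_a", "gene_b"}.issubset(frame.columns):
        raise ParseError(f"{Path(path).name}: need columns gene_a, gene_b[, score]")
    if "score" in frame.columns:
        triples = list(
            zip(frame["gene_a"], frame["gene_b"], frame["score"].astype(float))
        )
        return EdgeList.from_pairs(triples)
    return EdgeList.from_pairs(list(zip(frame["gene_a"], frame["gene_b"])))


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    rows = []
    for (a, b) in edges.pairs:
        s = edges.scores[(a, b)]
        rows.append({"gene_a": a, "gene_b": b, "score": "" if s is None else s})
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(
        path, sep="\t", index=False
    )


def write_results(result: "ConditionResult", out_dir: str | Path) -> dict[str, Path]:
    """Write all tables of a pipeline run plus the JSON run report.

    Emits: module assignment table (gene, module, own-module kME),
    eigengene table, trait table, significant-module table, enrichment
    table, hub table and ``run_report.json``. Returns name -> path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    assign = result.partition.to_frame()
    if result.kme is not None:
        own = [
            result.kme.loc[g, lab] if lab in result.kme.columns else np.nan
            for g, lab in zip(result.partition.gene_ids, result.partition.labels)
        ]
        assign["kME_own"] = own
    written["modules"] = out / "module_assignments.tsv"
    assign.to_csv(written["modules"], sep="\t", index=False)

    written["eigengenes"] = out / "eigengenes.tsv"
    result.eigengenes.to_frame().to_csv(
        written["eigengenes"], sep="\t", index_label="module"
    )

    if result.kme is not None:
        written["kme"] = out / "kme.tsv"
        result.kme.to_csv(written["kme"], sep="\t", index_label="gene_id")

    for name, table in (
        ("trait_table", result.trait_table),
        ("significant_modules", result.significant),
        ("enrichment", result.enrichment),
        ("hubs", result.hubs),
    ):
        if table is None:
            continue
        written[name] = out / f"{name}.tsv"
        table.to_csv(written[name], sep="\t", index=False)

    written["report"] = out / "run_report.json"
    with open(written["report"], "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")
    return written


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
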