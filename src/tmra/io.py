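"""Readers and writers for every on-disk artifact of the pipeline.

All formats are plain tab-separated text: expression matrix TSV (genes as
rows, samples as columns), labels TSV (sample, class), gene-list text (one
symbol per line), GMT gene sets, regulon tables (tf, target, mode, weight),
SIF network export, MRA result tables and PDS matrices.

Gene identifiers are matched after uppercasing and whitespace-stripping;
no alias resolution is attempted.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import (
    CASE,
    CONTROL,
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    normalize_gene_list,
    normalize_symbol,
)
from .regulons import REGULON_COLUMNS, Interaction, RegulonSet

PathLike = str | os.PathLike


def read_expression(
    matrix_path: PathLike,
    labels_path: PathLike,
    case_class: str = CASE,
    control_class: str = CONTROL,
    log2_transform: bool = False,
) -> ExpressionDataset:
    """Read an expression TSV plus a two-column sample-label TSV.

    The matrix header row holds sample ids; the first column holds gene
    symbols (uppercased on read, row order preserved). The labels file maps
    every sample id to a class token; ``case_class``/``control_class`` name
    the two tokens explicitly. ``log2_transform`` applies log2(x + 1) for
    raw count matrices.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    genes = [normalize_symbol(g) for g in raw.index]
    seen: set[str] = set()
    for g in genes:
        if g in seen:
            raise ValueError(f"duplicate gene row {g!r} in {matrix_path}")
        seen.add(g)
    try:
        values = raw.astype(float)
    except ValueError:
        for j, col in enumerate(raw.columns):
            for i, cell in enumerate(raw[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at gene {genes[i]!r} (row {i + 2}), "
                        f"sample {col!r} (column {j + 2}): {cell!r}"
                    ) from None
        raise
    values.index = pd.Index(genes, name="gene")
    if log2_transform:
        values = np.log2(values + 1.0)

    lab = pd.read_csv(
        labels_path, sep="\t", header=None, names=["sample", "class"], dtype=str
    )
    # tolerate a header row naming the columns
    if lab.iloc[0, 0].strip().lower() in {"sample", "sample_id", "id"}:
        lab = lab.iloc[1:]
    lab["sample"] = lab["sample"].str.strip()
    lab["class"] = lab["class"].str.strip()
    mapping = {case_class: CASE, control_class: CONTROL}
    unknown = set(lab["class"]) - set(mapping)
    if unknown:
        raise ValueError(f"unknown class tokens in labels file: {sorted(unknown)}")
    labels = pd.Series(
        [mapping[c] for c in lab["class"]], index=lab["sample"], name="class"
    )
    missing = set(values.columns) ^ set(labels.index)
    if missing:
        raise ValueError(
            f"samples present in only one of matrix/labels: {sorted(missing)[:5]}"
        )
    return ExpressionDataset(values, labels)


def write_expression(dataset: ExpressionDataset, matrix_path: PathLike,
                     labels_path: PathLike) -> None:
    dataset.values.to_csv(matrix_path, sep="\t", index_label="gene")
    dataset.labels.rename("class").to_csv(
        labels_path, sep="\t", header=False, index_label="sample"
    )


def read_gene_list(path: PathLike) -> list[str]:
    """One gene symbol per line; ordered, deduplication is an error."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    return normalize_gene_list([ln for ln in lines if ln])


def write_gene_list(genes: Iterable[str], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Standard GMT: name TAB description TAB gene TAB gene ...

    Member duplicates within a set are silently collapsed; duplicate set
    names and lines without any member gene are errors.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno} has {len(fields)} fields; need "
                    "name, description and at least one gene"
                )
            name = fields[0].strip()
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} (line {lineno})")
            members: dict[str, None] = {}
            for g in fields[2:]:
                s = normalize_symbol(g)
                if s:
                    members.setdefault(s)
            if not members:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no genes")
            sets[name] = GeneSet(name, fields[1], list(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.genes]) + "\n")


def write_regulon_table(regulons: RegulonSet, path: PathLike) -> None:
    """4-column TSV (tf, target, mode, weight), sorted by tf then target."""
    frame = regulons.to_frame()
    frame["mode"] = [format(v, ".10g") for v in frame["mode"]]
    frame["weight"] = [format(v, ".10g") for v in frame["weight"]]
    frame.to_csv(path, sep="\t", index=False)


def read_regulon_table(path: PathLike) -> RegulonSet:
    frame = pd.read_csv(
        path, sep="\t", dtype={"tf": str, "target": str, "mode": float, "weight": float}
    )
    if list(frame.columns) != REGULON_COLUMNS:
        raise ValueError(
            f"regulon table must have columns {REGULON_COLUMNS}, got "
            f"{list(frame.columns)}"
        )
    if len(frame) == 0:
        return RegulonSet({})
    bad_mode = frame[(frame["mode"] < -1) | (frame["mode"] > 1)]
    if len(bad_mode):
        row = bad_mode.iloc[0]
        raise ValueError(f"mode {row['mode']} of {row.tf}->{row.target} outside [-1, 1]")
    bad_w = frame[(frame["weight"] <= 0) | (frame["weight"] > 1)]
    if len(bad_w):
        row = bad_w.iloc[0]
        raise ValueError(
            f"weight {row['weight']} of {row.tf}->{row.target} outside (0, 1]"
        )
    return RegulonSet.from_frame(frame)


def export_sif(regulons: RegulonSet, path: PathLike) -> None:
    """Cytoscape SIF export: one ``tf <activates|represses> target`` per line.

    The relation is the sign of the mode; an exactly-zero mode is labelled
    ``activates`` (ties are treated as non-repressive).
    """
    frame = regulons.to_frame()
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            rel = "represses" if row.mode < 0 else "activates"
            fh.write(f"{row.tf}\t{rel}\t{row.target}\n")


MRA_COLUMNS = ["regulon", "size", "total_size", "es", "nes", "p_value", "fdr", "rank"]


def write_mra_table(result: pd.DataFrame, path: PathLike) -> None:
    result.to_csv(path, sep="\t", index=False)


def read_mra_table(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(MRA_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"MRA table missing columns {sorted(missing)}")
    return frame


def write_pds_matrix(pds: pd.DataFrame, path: PathLike) -> None:
    """Pathway x sample PDS matrix as TSV."""
    pds.to_csv(path, sep="\t", index_label="pathway")


def read_pds_matrix(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
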