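"""Readers and writers for the pipeline's plain-text formats.

All tabular files are tab-separated with a header row.  Expression
matrices are genes x samples with the gene id in the first column;
gene sets use the standard GMT layout (name, description, then gene
ids); signature directions live in a three-column table because GMT
has no per-gene payload.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import ControlSet, DataError, validate_survival_table
from .signatures import SignatureDefinition

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_controls_tsv", "write_controls_tsv",
    "read_clinical_tsv", "write_clinical_tsv",
    "read_pairs_tsv", "write_pairs_tsv",
    "read_gmt", "write_gmt",
    "read_directions_tsv", "write_directions_tsv",
    "read_signatures", "write_signatures",
    "write_truth_json",
]


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise DataError(f"{path}: duplicate gene ids")
    return df


def write_expression_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep="\t")


def read_controls_tsv(path) -> ControlSet:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "control_class"} <= set(df.columns):
        raise DataError(f"{path}: expected columns gene_id, control_class")
    bad = set(df["control_class"]) - {"positive", "negative", "housekeeping"}
    if bad:
        raise DataError(f"{path}: unknown control classes {sorted(bad)}")
    by = {c: frozenset(df.loc[df["control_class"] == c, "gene_id"])
          for c in ("positive", "negative", "housekeeping")}
    return ControlSet(positive=by["positive"], negative=by["negative"],
                      housekeeping=by["housekeeping"])


def write_controls_tsv(controls: ControlSet, path) -> None:
    rows = [(g, c) for c, ids in (("positive", controls.positive),
                                  ("negative", controls.negative),
                                  ("housekeeping", controls.housekeeping))
            for g in sorted(ids)]
    pd.DataFrame(rows, columns=["gene_id", "control_class"]).to_csv(path, sep="\t", index=False)


def read_clinical_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return validate_survival_table(df)


def write_clinical_tsv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_pairs_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_a", "sample_b", "replicate_type"} <= set(df.columns):
        raise DataError(f"{path}: expected columns sample_a, sample_b, replicate_type")
    return df


def write_pairs_tsv(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict:
    """GMT file -> {name: (description, [genes...])}."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataError(f"{path}: GMT lines need name, description and >=1 gene")
        sets[parts[0]] = (parts[1], parts[2:])
    return sets


def write_gmt(sets: dict, path) -> None:
    lines = [
        "\t".join([name, desc, *genes])
        for name, (desc, genes) in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_directions_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"signature", "gene_id", "direction"} <= set(df.columns):
        raise DataError(f"{path}: expected columns signature, gene_id, direction")
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise DataError(f"{path}: directions must be up/down, got {sorted(bad)}")
    return df


def write_directions_tsv(directions: pd.DataFrame, path) -> None:
    directions.to_csv(path, sep="\t", index=False)


def read_signatures(gmt_path, directions_path) -> list:
    """Combine a GMT file and a direction table into SignatureDefinitions."""
    sets = read_gmt(gmt_path)
    directions = read_directions_tsv(directions_path)
    sigs = []
    for name, (desc, genes) in sets.items():
        sub = directions[directions["signature"] == name]
        dmap = dict(zip(sub["gene_id"], sub["direction"]))
        dmap = {g: d for g, d in dmap.items() if g in set(genes)}
        sigs.append(SignatureDefinition(name=name, genes=tuple(genes),
                                        direction=dmap, source=desc))
    return sigs


def write_signatures(sigs, gmt_path, directions_path) -> None:
    sets = {s.name: (s.source or ".", list(s.genes)) for s in sigs}
    write_gmt(sets, gmt_path)
    rows = [(s.name, g, d) for s in sigs for g, d in s.direction.items()]
    write_directions_tsv(pd.DataFrame(rows, columns=["signature", "gene_id", "direction"]),
                         directions_path)


def write_truth_json(truth, path) -> None:
    payload = {
        "prognostic_gene_ids": sorted(truth.prognostic_gene_ids),
        "true_log_hr": truth.true_log_hr,
        "true_direction": truth.true_direction,
        "batch_assignments": truth.batch_assignments,
        "low_quality_samples": sorted(truth.low_quality_samples),
        "linear_predictor": truth.linear_predictor.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
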