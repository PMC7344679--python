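"""Readers and writers for every tabular artifact the pipeline touches.

CSV/TSV delimiters are sniffed from the header line. Missing intensities
are written as empty cells and parsed back as missing — never as zero.
Networks go to GraphML (via networkx) or a flat edge TSV; ground truth and
model summaries go to JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .annotate import AnnotationResult, annotation_frame
from .tables import (
    CompoundDB,
    FeatureTable,
    SampleMetadata,
    SensoryScores,
    ValidationError,
)

_NA_VALUES = ["", "NA", "NaN", "nan"]


def _sniff_sep(path: str | Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_feature_table(path: str | Path, mode: str = "positive") -> FeatureTable:
    """Read a feature table: columns ``feature_id, mz, rt`` then one column
    per sample. Empty cells and ``NA`` are missing values."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, na_values=_NA_VALUES, keep_default_na=False, dtype={0: str})
    required = ["feature_id", "mz", "rt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"feature table {path} lacks columns: {missing}")
    if df["feature_id"].duplicated().any():
        dupes = df.loc[df["feature_id"].duplicated(), "feature_id"].unique().tolist()
        raise ValidationError(f"duplicated feature_id in {path}: {dupes}")
    df = df.set_index("feature_id")
    sample_cols = [c for c in df.columns if c not in ("mz", "rt")]
    if not sample_cols:
        raise ValidationError(f"feature table {path} has no sample columns")
    intens = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    # entries that fail numeric conversion but were not NA tokens are errors
    raw = df[sample_cols]
    bad = intens.isna() & raw.notna()
    if bad.to_numpy().any():
        rows = intens.index[bad.any(axis=1)].tolist()
        raise ValidationError(f"non-numeric intensity values in features: {rows}")
    features = df[["mz", "rt"]].apply(pd.to_numeric)
    return FeatureTable(features=features, intensities=intens.astype(float), mode=mode)


def write_feature_table(table: FeatureTable, path: str | Path, sep: str = ",") -> None:
    out = pd.concat([table.features[["mz", "rt"]], table.intensities], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path, sep=sep, na_rep="")


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError(f"sample metadata {path} lacks a sample_id column")
    df = df.set_index("sample_id")
    return SampleMetadata(table=df)


def write_sample_metadata(meta: SampleMetadata, path: str | Path, sep: str = ",") -> None:
    out = meta.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)


def read_sensory_scores(path: str | Path) -> SensoryScores:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError(f"sensory score table {path} lacks a sample_id column")
    df = df.set_index("sample_id").apply(pd.to_numeric)
    return SensoryScores(table=df)


def write_sensory_scores(scores: SensoryScores, path: str | Path, sep: str = ",") -> None:
    out = scores.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)


def read_compound_db(path: str | Path) -> CompoundDB:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    if "intrinsic_charge" not in df.columns:
        df["intrinsic_charge"] = 0
    df["intrinsic_charge"] = df["intrinsic_charge"].fillna(0).astype(int)
    return CompoundDB(table=df)


def write_compound_db(db: CompoundDB, path: str | Path, sep: str = ",") -> None:
    db.table.to_csv(path, sep=sep, index=False)


# -- networks ----------------------------------------------------------------

def write_network(net, path: str | Path, format: str = "graphml") -> None:
    """Serialize a BiomarkerNetwork as GraphML or a flat edge TSV.

    The edge TSV has columns attribute, feature_id, vip, mz, rt,
    annotation (empty string when unknown).
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "edge_tsv":
        rows = []
        for attr, fid, data in net.graph.edges(data=True):
            if net.graph.nodes[attr].get("kind") != "attribute":
                attr, fid = fid, attr
            node = net.graph.nodes[fid]
            rows.append(
                (attr, fid, data["weight"], node.get("mz", np.nan),
                 node.get("rt", np.nan), node.get("annotation", ""))
            )
        df = pd.DataFrame(
            rows, columns=["attribute", "feature_id", "vip", "mz", "rt", "annotation"]
        ).sort_values(["attribute", "feature_id"])
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path):
    """Read a GraphML network back into a BiomarkerNetwork."""
    from .network import BiomarkerNetwork

    g = nx.read_graphml(path)
    threshold = g.graph.get("threshold", 0.0)
    return BiomarkerNetwork(graph=g, threshold=float(threshold))


def write_annotations(results: list[AnnotationResult], path: str | Path) -> None:
    annotation_frame(results).to_csv(path, sep="\t", index=False, na_rep="")


# -- JSON helpers ------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
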