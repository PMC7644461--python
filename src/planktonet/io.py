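"""Readers and writers for the pipeline's plain-text formats.

Inputs are CSV (abundance matrix with an ISO-8601 date column and one column
per taxon ID; taxon catalogue; daily fluorescence).  Outputs are TSV edge
lists and classifications, GraphML networks with taxon attributes, CSV
period tables and JSON descriptor/metadata files.  All writers are
byte-stable for fixed inputs so that pipeline runs are reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from planktonet.blooms import Period, PeriodSet
from planktonet.networks import CorrelationNetwork

FLOAT_FORMAT = "%.10g"


def read_abundance_csv(path, taxa: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read an abundance matrix CSV (date column + one column per taxon ID)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a date column and at least one taxon column")
    date_col = df.columns[0]
    try:
        dates = pd.to_datetime(df[date_col], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: cannot parse dates in column {date_col!r}: {exc}") from exc
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate date {dup.date()}")
    try:
        cols = [int(c) for c in df.columns[1:]]
    except ValueError as exc:
        raise ValueError(f"{path}: taxon column headers must be integer IDs: {exc}") from exc
    body = df.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric or missing cell at row {r + 2}, column {df.columns[1 + c]!r}"
        )
    if taxa is not None:
        known = set(int(t) for t in taxa["taxon_id"])
        unknown = [c for c in cols if c not in known]
        if unknown:
            raise ValueError(f"{path}: unknown taxon IDs {unknown}")
    out = pd.DataFrame(numeric.to_numpy(dtype=float), index=pd.DatetimeIndex(dates), columns=cols)
    return out.sort_index()


def write_abundance_csv(m: pd.DataFrame, path) -> None:
    out = m.copy()
    out.insert(0, "date", [d.date().isoformat() for d in m.index])
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_taxa_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"taxon_id", "name", "group", "esd_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: taxon table missing columns {sorted(missing)}")
    df["taxon_id"] = df["taxon_id"].astype(int)
    if df["taxon_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate taxon IDs")
    if (df["esd_um"] <= 0).any():
        raise ValueError(f"{path}: nonpositive ESD")
    return df


def write_taxa_csv(taxa: pd.DataFrame, path) -> None:
    taxa.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_fluorescence_csv(path) -> pd.Series:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need date and value columns")
    dates = pd.to_datetime(df.iloc[:, 0], format="ISO8601")
    s = pd.Series(
        pd.to_numeric(df.iloc[:, 1]).to_numpy(dtype=float),
        index=pd.DatetimeIndex(dates),
        name="fluorescence",
    )
    return s.sort_index()


def write_fluorescence_csv(f: pd.Series, path) -> None:
    pd.DataFrame(
        {"date": [d.date().isoformat() for d in f.index], "fluorescence": f.to_numpy()}
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_periods_csv(p: PeriodSet, path) -> None:
    df = p.to_frame()
    df["start"] = df["start"].dt.date.astype(str)
    df["end"] = df["end"].dt.date.astype(str)
    df.to_csv(path, index=False)


def read_periods_csv(path) -> PeriodSet:
    df = pd.read_csv(path)
    periods = [
        Period(str(r["label"]), pd.Timestamp(r["start"]), pd.Timestamp(r["end"]))
        for _, r in df.iterrows()
    ]
    return PeriodSet(periods, provenance=f"read from {path}")


def network_to_graph(net: CorrelationNetwork, taxa: pd.DataFrame) -> nx.Graph:
    """Materialize a correlation network as a networkx graph with attributes."""
    meta = taxa.set_index("taxon_id")
    g = nx.Graph(period=net.period_label, sign_mode=net.sign_mode, alpha=net.alpha)
    for t in net.nodes:
        if t not in meta.index:
            raise ValueError(f"node {t} missing from taxon table")
        row = meta.loc[t]
        attrs = {"name": str(row["name"]), "group": str(row["group"]), "esd_um": float(row["esd_um"])}
        if "size_class" in meta.columns and not pd.isna(row.get("size_class")):
            attrs["size_class"] = str(row["size_class"])
        g.add_node(int(t), **attrs)
    for _, e in net.edges.iterrows():
        g.add_edge(
            int(e["taxon_a"]), int(e["taxon_b"]),
            rho=float(e["rho"]), p=float(e["p"]), sign=str(e["sign"]),
        )
    return g


def write_network(net: CorrelationNetwork, taxa: pd.DataFrame, path, format: str = "edge_list_tsv") -> None:
    """Write a network as a sorted edge-list TSV or as GraphML."""
    if format == "edge_list_tsv":
        missing = set(net.nodes) - set(int(t) for t in taxa["taxon_id"])
        if missing:
            raise ValueError(f"nodes missing from taxon table: {sorted(missing)}")
        edges = net.edges.sort_values(["taxon_a", "taxon_b"]).reset_index(drop=True)
        edges.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    elif format == "graphml":
        g = network_to_graph(net, taxa)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def write_classification_tsv(cls, path) -> None:
    t = cls.table.copy()
    t["sign_mode"] = cls.sign_mode
    t["grouping"] = cls.grouping
    t.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
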