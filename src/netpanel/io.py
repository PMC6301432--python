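"""File formats: delimited tables, GraphML graph export, results documents.

All tables are UTF-8, comma-delimited, with a fixed documented header
row; readers refuse files whose columns are missing or reordered and
name the offending column. Floats are written with 6 significant
digits; wave indices are 1-based and validated on read. GraphML export
round-trips node and edge attributes (edge kind sets and wave sets are
serialized as comma-joined sorted strings).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from netpanel.simulate import ROSTER_COLUMNS, SimulatedDataset

TABLE_COLUMNS = {
    "respondents": None,  # variable covariate set; checked for required prefix
    "rosters": ROSTER_COLUMNS,
    "matches": ["ego_id", "kind", "nomination_id_earlier", "nomination_id_later",
                "wave_earlier", "wave_later"],
    "attendance": ["ego_id", "wave", "attended"],
}
REQUIRED_RESPONDENT_COLUMNS = ["ego_id", "group"]

_BOOL_COLUMNS = {
    "respondents": ["hiv_positive", "employed", "income_lt_20k", "stably_housed",
                    "ever_jail", "insured", "in_relationship"],
    "rosters": ["is_primary_partner", "alter_exchange_sex",
                "alter_received_payment", "also_confidant"],
    "attendance": ["attended"],
}
_INT_COLUMNS = {
    "respondents": ["n_sex_partners_6mo", "rds_depth"],
    "rosters": ["position"],
    "matches": [],
    "attendance": [],
}
_WAVE_COLUMNS = {
    "rosters": ["wave"],
    "matches": ["wave_earlier", "wave_later"],
    "attendance": ["wave"],
}
_FLOAT_COLUMNS = {"respondents": ["age_years"]}


class FormatError(ValueError):
    """Malformed input file; the message names the file, row and column."""


def _bool_to_str(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    return "true" if bool(v) else "false"


def _str_to_bool(s, table, col, row):
    if s == "" or s is None or (isinstance(s, float) and np.isnan(s)):
        return None
    if s in ("true", "True"):
        return True
    if s in ("false", "False"):
        return False
    raise FormatError(f"{table}[{row}].{col}: expected true/false/empty, got {s!r}")


def write_table(df: pd.DataFrame, path, table: str) -> None:
    out = df.copy()
    for col in _BOOL_COLUMNS.get(table, []):
        if col in out.columns:
            out[col] = out[col].map(_bool_to_str)
    out.to_csv(path, index=False, float_format="%.6g", encoding="utf-8",
               lineterminator="\n")


def read_table(path, table: str) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    expected = TABLE_COLUMNS[table]
    cols = list(df.columns)
    if expected is None:
        for i, col in enumerate(REQUIRED_RESPONDENT_COLUMNS):
            if i >= len(cols) or cols[i] != col:
                raise FormatError(
                    f"{path.name}: column {i} must be {col!r}, found "
                    f"{cols[i] if i < len(cols) else '<missing>'!r}"
                )
    else:
        if cols != expected:
            for i, col in enumerate(expected):
                if i >= len(cols) or cols[i] != col:
                    raise FormatError(
                        f"{path.name}: column {i} must be {col!r}, found "
                        f"{cols[i] if i < len(cols) else '<missing>'!r}"
                    )
            raise FormatError(f"{path.name}: unexpected trailing columns {cols[len(expected):]!r}")
    df = df.replace({"": None})
    for col in _WAVE_COLUMNS.get(table, []):
        waves = []
        for row, s in enumerate(df[col]):
            try:
                w = int(s)
            except (TypeError, ValueError):
                raise FormatError(f"{path.name}[{row}].{col}: wave index {s!r} is not an integer") from None
            if w < 1:
                raise FormatError(f"{path.name}[{row}].{col}: wave index {w} must be >= 1")
            waves.append(w)
        df[col] = waves
    for col in _INT_COLUMNS.get(table, []):
        if col in df.columns:
            df[col] = df[col].map(lambda s: int(float(s)) if s is not None else None)
    for col in _FLOAT_COLUMNS.get(table, []):
        if col in df.columns:
            df[col] = df[col].map(lambda s: float(s) if s is not None else None)
    for col in _BOOL_COLUMNS.get(table, []):
        if col in df.columns:
            df[col] = [
                _str_to_bool(s, path.name, col, row) for row, s in enumerate(df[col])
            ]
    return df


def write_dataset(sim_or_tables, out_dir, include_ground_truth: bool = True) -> dict:
    """Write a dataset's tables to ``out_dir``; returns the file map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(sim_or_tables, SimulatedDataset):
        tables = sim_or_tables.tables()
        truth = sim_or_tables.ground_truth if include_ground_truth else None
    else:
        tables = dict(sim_or_tables)
        truth = None
    paths = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        write_table(df, p, name)
        paths[name] = p
    if truth is not None:
        # synthetic-only: true identities behind each nomination
        p = out_dir / "ground_truth_nominations.csv"
        truth.nomination_members.to_csv(p, index=False, encoding="utf-8",
                                        lineterminator="\n")
        paths["ground_truth_nominations"] = p
        p = out_dir / "ground_truth_persistence.csv"
        truth.persistence.to_csv(p, index=False, encoding="utf-8",
                                 lineterminator="\n")
        paths["ground_truth_persistence"] = p
    return paths


def read_dataset_tables(in_dir) -> dict:
    """Read the four study tables from a directory of CSV files."""
    in_dir = Path(in_dir)
    tables = {}
    for name in ("respondents", "rosters", "matches", "attendance"):
        p = in_dir / f"{name}.csv"
        if not p.exists():
            raise FileNotFoundError(f"missing required table file: {p}")
        tables[name] = read_table(p, name)
    return tables


# ---------------------------------------------------------------------------
# GraphML


def graph_to_graphml(graph: nx.Graph, path) -> None:
    g = nx.Graph()
    for node, data in graph.nodes(data=True):
        g.add_node(node, **{k: ("" if v is None else v) for k, v in data.items()})
    for u, v, data in graph.edges(data=True):
        attrs = dict(data)
        if "kinds" in attrs:
            attrs["kinds"] = ",".join(sorted(attrs["kinds"]))
        if "waves" in attrs:
            attrs["waves"] = ",".join(str(w) for w in sorted(attrs["waves"]))
        g.add_edge(u, v, **attrs)
    nx.write_graphml(g, path, named_key_ids=True)


def graphml_to_graph(path) -> nx.Graph:
    g = nx.read_graphml(path)
    out = nx.Graph()
    for node, data in g.nodes(data=True):
        out.add_node(node, **data)
    for u, v, data in g.edges(data=True):
        attrs = dict(data)
        if "kinds" in attrs:
            attrs["kinds"] = set(attrs["kinds"].split(",")) if attrs["kinds"] else set()
        if "waves" in attrs:
            attrs["waves"] = ({int(w) for w in attrs["waves"].split(",")}
                              if attrs["waves"] else set())
        out.add_edge(u, v, **attrs)
    return out


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [
        {"u": u, "v": v,
         "kinds": ",".join(sorted(d.get("kinds", set()))),
         "waves": ",".join(str(w) for w in sorted(d.get("waves", set())))}
        for u, v, d in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    pd.DataFrame(rows, columns=["u", "v", "kinds", "waves"]).to_csv(
        path, index=False, encoding="utf-8", lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# results documents


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj, key=str)] if isinstance(obj, set) else [_jsonable(v) for v in obj]
    return obj


def write_results_json(document: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(document), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_results_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6g", encoding="utf-8",
              lineterminator="\n")
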