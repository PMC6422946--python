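"""Readers and writers for all tabular and graph artifacts.

Formats are deliberately plain: tab-delimited text for OTU tables,
metadata and measurement series; GraphML or GEXF for networks; CSV for
result tables.  Writers emit a deterministic column order so that a rerun
with the same configuration is byte-identical.
"""

from __future__ import annotations

import re
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import METADATA_COLUMNS, CoNetwork, OtuTable, TreatmentCode

_TREATMENT_RE = re.compile(r"^([A-Za-z])(\d{2})(?:e(\d{2}))?$")

TAXONOMY_COLUMN = "taxonomy"
OTU_ID_COLUMN = "otu_id"


def parse_treatment_code(text: str) -> TreatmentCode:
    """Parse a treatment designation such as ``P35e45`` or ``U45``.

    The leading letter names the soil, the first two digits the
    pre-incubation temperature (degC) and the optional ``e``-suffixed pair
    the incubation temperature after the shift.
    """
    m = _TREATMENT_RE.match(text.strip())
    if m is None:
        raise ValueError(f"unrecognised treatment code: {text!r}")
    soil, pre, inc = m.groups()
    return TreatmentCode(soil=soil, pre_temp=int(pre), inc_temp=None if inc is None else int(inc))


def _check_rectangular(rows: list[list[str]], path: Path) -> None:
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")


def read_otu_table(path: str | Path) -> OtuTable:
    """Read a tab-delimited OTU table.

    Layout: first column OTU id, last column taxonomy lineage, the
    remaining columns integer counts per sample.
    """
    path = Path(path)
    with open(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        raise ValueError(f"{path}: empty file")
    _check_rectangular(rows, path)
    header = rows[0]
    if header[0] != OTU_ID_COLUMN or header[-1] != TAXONOMY_COLUMN:
        raise ValueError(
            f"{path}: expected first column {OTU_ID_COLUMN!r} and last column "
            f"{TAXONOMY_COLUMN!r}, got {header[0]!r} and {header[-1]!r}"
        )
    sample_ids = header[1:-1]
    otu_ids, taxa, counts = [], [], []
    for i, row in enumerate(rows[1:], start=2):
        otu_ids.append(row[0])
        taxa.append(row[-1])
        vals = []
        for j, cell in enumerate(row[1:-1]):
            try:
                v = int(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer count {cell!r} at line {i}, "
                    f"sample {sample_ids[j]!r} (OTU {row[0]!r})"
                ) from None
            vals.append(v)
        counts.append(vals)
    frame = pd.DataFrame(counts, index=pd.Index(otu_ids, name=OTU_ID_COLUMN), columns=sample_ids)
    taxonomy = pd.Series(taxa, index=frame.index, name=TAXONOMY_COLUMN)
    return OtuTable(frame, taxonomy)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    path = Path(path)
    out = table.counts.copy()
    out.insert(len(out.columns), TAXONOMY_COLUMN, table.taxonomy)
    out.index.name = OTU_ID_COLUMN
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "soil": str, "treatment_code": str})
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    md["inc_temp"] = pd.to_numeric(md["inc_temp"], errors="coerce")
    # round-trip check: the stored code must match its parsed fields
    for _, row in md.iterrows():
        code = parse_treatment_code(row["treatment_code"])
        inc = None if pd.isna(row["inc_temp"]) else int(row["inc_temp"])
        if (code.soil, code.pre_temp, code.inc_temp) != (row["soil"], int(row["pre_temp"]), inc):
            raise ValueError(f"{path}: treatment code {row['treatment_code']!r} "
                             f"inconsistent with metadata fields")
    return md.loc[:, list(METADATA_COLUMNS)]


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.loc[:, list(METADATA_COLUMNS)].copy()
    out["inc_temp"] = out["inc_temp"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out["pre_temp"] = out["pre_temp"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_series_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited measurement series (gas, isotope, qPCR, VFA)."""
    with open(Path(path)) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    _check_rectangular(rows, Path(path))
    return pd.read_csv(path, sep="\t")


def write_series_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


_EXPORT_FORMATS = {"graphml", "gexf"}


def export_network(network: CoNetwork | nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a co-occurrence network as GraphML or GEXF.

    Node attributes (taxonomy, domain, module, temperature label, layout
    coordinates) and the rho edge weights are preserved so the file can be
    re-opened in any standard graph viewer.
    """
    fmt = format.lower()
    if fmt not in _EXPORT_FORMATS:
        raise ValueError(f"unsupported network format {format!r}; use one of {sorted(_EXPORT_FORMATS)}")
    graph = network.graph if isinstance(network, CoNetwork) else network
    clean = nx.Graph()
    for node, data in graph.nodes(data=True):
        clean.add_node(node, **{k: _coerce_attr(v) for k, v in data.items()})
    for u, v, data in graph.edges(data=True):
        clean.add_edge(u, v, **{k: _coerce_attr(w) for k, w in data.items()})
    if fmt == "graphml":
        nx.write_graphml(clean, str(path))
    else:
        nx.write_gexf(clean, str(path))


def _coerce_attr(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    fmt = format.lower()
    if fmt not in _EXPORT_FORMATS:
        raise ValueError(f"unsupported network format {format!r}")
    if fmt == "graphml":
        return nx.read_graphml(str(path))
    return nx.read_gexf(str(path))
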