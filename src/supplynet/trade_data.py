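"""Bilateral trade flows: loading, validation, matrix views, graph export.

The long-format flow table (one row per year/exporter/importer) is the raw
input of every downstream stage.  A :class:`TradeNetwork` is a per-year dense
matrix view with the convention **row = exporter, column = importer**, so an
edge ``i -> j`` reads "i supplies j": in-degree counts suppliers, out-degree
counts customers.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyNetworkError, ParameterError

__all__ = [
    "TradeFlowTable",
    "TradeNetwork",
    "CountryIndicatorTable",
    "ValidationReport",
    "clean_flows",
    "load_trade_flows",
    "load_indicators",
    "build_network",
    "binarize",
    "export_graph",
]

#: default column names of the long CSV dialect
FLOW_COLUMNS = {"year": "year", "exporter": "exporter_iso3",
                "importer": "importer_iso3", "value": "value_usd"}
INDICATOR_COLUMNS = {"iso3": "iso3", "year": "year",
                     "gdp": "gdp_usd", "cri": "cri"}

_ISO3_RE = re.compile(r"^[A-Z]{3}$")


@dataclass
class ValidationReport:
    """What happened while cleaning a raw flow table."""

    n_input: int = 0
    n_kept: int = 0
    n_aggregated: int = 0          # duplicate rows merged away
    rejected: list[tuple[str, dict]] = field(default_factory=list)
    flagged_codes: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


@dataclass
class TradeFlowTable:
    """Validated long-format bilateral flows.

    ``frame`` has columns ``year, exporter, importer, value`` with at most one
    row per (year, exporter, importer) and no self-flows or negative values.
    """

    frame: pd.DataFrame
    report: ValidationReport | None = None

    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique().tolist())

    def for_year(self, year: int) -> pd.DataFrame:
        return self.frame[self.frame["year"] == year]

    def total(self, year: int) -> float:
        return float(self.for_year(year)["value"].sum())

    def imports_by_supplier(self, importer: str, year: int) -> pd.Series:
        """USD supplied to ``importer`` in ``year``, indexed by exporter."""
        sub = self.for_year(year)
        sub = sub[sub["importer"] == importer]
        return sub.set_index("exporter")["value"].sort_index()

    def total_imports(self, importer: str, year: int) -> float:
        return float(self.imports_by_supplier(importer, year).sum())

    def importers(self, year: int) -> list[str]:
        return sorted(self.for_year(year)["importer"].unique().tolist())

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.rename(columns={
            "exporter": FLOW_COLUMNS["exporter"],
            "importer": FLOW_COLUMNS["importer"],
            "value": FLOW_COLUMNS["value"]})
        out.to_csv(path, index=False)


@dataclass
class TradeNetwork:
    """Dense per-year matrix view of a flow table.

    ``weights[i, j]`` is the USD flow exported by ``nodes[i]`` to ``nodes[j]``;
    ``binary`` (if present) is the thresholded 0/1 adjacency.
    """

    year: int
    nodes: list[str]
    weights: np.ndarray
    binary: np.ndarray | None = None
    threshold: float | None = None

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, code: str) -> int:
        return self.nodes.index(code)


@dataclass
class CountryIndicatorTable:
    """Per country-year GDP (USD) and epidemic risk index (CRI)."""

    frame: pd.DataFrame  # columns iso3, year, gdp_usd, cri

    def _lookup(self, iso3: str, year: int) -> pd.DataFrame:
        f = self.frame
        return f[(f["iso3"] == iso3) & (f["year"] == year)]

    def gdp(self, iso3: str, year: int) -> float | None:
        row = self._lookup(iso3, year)
        return None if row.empty else float(row["gdp_usd"].iloc[0])

    def cri(self, iso3: str, year: int) -> float | None:
        row = self._lookup(iso3, year)
        return None if row.empty else float(row["cri"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def clean_flows(raw: pd.DataFrame) -> TradeFlowTable:
    """Validate and aggregate a raw ``year/exporter/importer/value`` frame.

    Rejects (and logs) self-flows, negative values and unparseable rows; sums
    duplicates on (year, exporter, importer); flags non-ISO3-looking codes but
    keeps them verbatim.
    """
    report = ValidationReport(n_input=len(raw))
    df = raw.copy()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["year"] = pd.to_numeric(df["year"], errors="coerce")

    bad_num = df["value"].isna() | df["year"].isna()
    for _, row in df[bad_num].iterrows():
        report.rejected.append(("unparseable", row.to_dict()))
    df = df[~bad_num]

    neg = df["value"] < 0
    for _, row in df[neg].iterrows():
        report.rejected.append(("negative_value", row.to_dict()))
    df = df[~neg]

    self_flow = df["exporter"] == df["importer"]
    for _, row in df[self_flow].iterrows():
        report.rejected.append(("self_flow", row.to_dict()))
    df = df[~self_flow]

    df["year"] = df["year"].astype(int)
    n_before = len(df)
    df = (df.groupby(["year", "exporter", "importer"], as_index=False)["value"]
            .sum()
            .sort_values(["year", "exporter", "importer"])
            .reset_index(drop=True))
    report.n_aggregated = n_before - len(df)
    report.n_kept = len(df)

    codes = pd.unique(pd.concat([df["exporter"], df["importer"]]))
    report.flagged_codes = sorted(c for c in codes if not _ISO3_RE.match(str(c)))
    return TradeFlowTable(frame=df, report=report)


def load_trade_flows(path: str | Path,
                     column_map: dict[str, str] | None = None,
                     reporter_side: str | None = None) -> TradeFlowTable:
    """Read a long-format flow CSV and return a validated table.

    ``column_map`` maps the logical names ``year, exporter, importer, value``
    (and optionally ``reporter``) onto CSV header names; defaults to the
    ``year,exporter_iso3,importer_iso3,value_usd`` dialect.  When the file
    carries both importer- and exporter-reported values for the same pair, a
    ``reporter`` column selects which side to keep (``reporter_side``,
    default ``"importer"``).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"flow file not found: {path}")
    cmap = dict(FLOW_COLUMNS)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path)
    needed = {k: cmap[k] for k in ("year", "exporter", "importer", "value")}
    missing = [v for v in needed.values() if v not in raw.columns]
    if missing:
        raise ConfigurationError(f"missing columns in {path}: {missing}")
    if "reporter" in cmap and cmap["reporter"] in raw.columns:
        side = reporter_side or "importer"
        if side not in ("importer", "exporter"):
            raise ConfigurationError(f"reporter_side must be importer/exporter, got {side!r}")
        raw = raw[raw[cmap["reporter"]] == side]
    df = raw.rename(columns={v: k for k, v in needed.items()})
    return clean_flows(df[["year", "exporter", "importer", "value"]])


def load_indicators(path: str | Path,
                    column_map: dict[str, str] | None = None) -> CountryIndicatorTable:
    """Read the per-country indicator CSV (``iso3,year,gdp_usd,cri``)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"indicator file not found: {path}")
    cmap = dict(INDICATOR_COLUMNS)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path)
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise ConfigurationError(f"missing columns in {path}: {missing}")
    df = raw.rename(columns={cmap["iso3"]: "iso3", cmap["year"]: "year",
                             cmap["gdp"]: "gdp_usd", cmap["cri"]: "cri"})
    df["year"] = df["year"].astype(int)
    return CountryIndicatorTable(df[["iso3", "year", "gdp_usd", "cri"]])


def build_network(flows: TradeFlowTable, year: int,
                  countries: list[str] | None = None) -> TradeNetwork:
    """Materialize the dense weighted matrix for one year.

    Node order is the sorted country codes.  With ``countries`` given, the
    matrix is restricted to that set (absent pairs are zero); flows touching
    countries outside the list are dropped.
    """
    sub = flows.for_year(year)
    if sub.empty and countries is None:
        raise EmptyNetworkError(f"no flows for year {year}")
    if countries is not None:
        nodes = sorted(set(countries))
        sub = sub[sub["exporter"].isin(nodes) & sub["importer"].isin(nodes)]
    else:
        nodes = sorted(set(sub["exporter"]) | set(sub["importer"]))
    idx = {c: i for i, c in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for exp_c, imp_c, val in zip(sub["exporter"], sub["importer"], sub["value"]):
        w[idx[exp_c], idx[imp_c]] += val
    np.fill_diagonal(w, 0.0)
    return TradeNetwork(year=year, nodes=nodes, weights=w)


def binarize(net: TradeNetwork, threshold: float) -> TradeNetwork:
    """Threshold the weighted matrix: ``binary[i, j] = 1`` iff weight >= threshold.

    The comparison is inclusive, so a flow exactly at the threshold is an edge.
    """
    if threshold < 0:
        raise ParameterError(f"threshold must be >= 0, got {threshold}")
    if threshold == 0:
        b = (net.weights > 0).astype(np.int8)
    else:
        b = (net.weights >= threshold).astype(np.int8)
    np.fill_diagonal(b, 0)
    return TradeNetwork(year=net.year, nodes=list(net.nodes),
                        weights=net.weights.copy(), binary=b,
                        threshold=float(threshold))


def to_graph(net: TradeNetwork, use_binary: bool | None = None) -> nx.DiGraph:
    """networkx view: edges where binary == 1 (if present) else weight > 0."""
    if use_binary is None:
        use_binary = net.binary is not None
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    mask = (net.binary == 1) if use_binary else (net.weights > 0)
    for i, j in zip(*np.nonzero(mask)):
        g.add_edge(net.nodes[i], net.nodes[j], weight=float(net.weights[i, j]))
    return g


def export_graph(net: TradeNetwork, fmt: str, path: str | Path) -> Path:
    """Write the network as GEXF, GraphML or a ``source,target,weight`` CSV."""
    path = Path(path)
    fmt = fmt.lower()
    g = to_graph(net)
    if fmt == "gexf":
        nx.write_gexf(g, path, version="1.2draft")
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight"])
            for u, v, data in g.edges(data=True):
                writer.writerow([u, v, repr(data["weight"])])
    else:
        raise ConfigurationError(f"unsupported export format: {fmt!r}")
    return path
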