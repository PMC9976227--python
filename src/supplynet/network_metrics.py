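"""Whole-network and per-node metrics on thresholded trade networks.

Covers directed density, in/out degree tables, per-country trade-share tables
with top-k cumulative concentration, and least-squares fitting of a decaying
exponential to the empirical degree distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    DegenerateShareError,
    InsufficientSupportError,
    UndefinedDensityError,
)
from .trade_data import TradeFlowTable, TradeNetwork

__all__ = ["density", "degrees", "trade_shares", "fit_exponential_distribution",
           "ShareTable", "ExpFit", "report_round"]


def report_round(x: float, decimals: int = 2) -> float:
    """Half-up rounding for reported figures (percentages 2dp, density 3dp)."""
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def density(net: TradeNetwork) -> float:
    """Directed density E / (n(n-1)), self-loops excluded.

    Requires the binary adjacency; raises :class:`UndefinedDensityError` for
    n < 2.
    """
    if net.binary is None:
        raise UndefinedDensityError("binarize the network before computing density")
    n = net.n
    if n < 2:
        raise UndefinedDensityError(f"density undefined for n={n}")
    b = net.binary.copy()
    np.fill_diagonal(b, 0)
    e = int(b.sum())
    return e / (n * (n - 1))


def degrees(net: TradeNetwork) -> pd.DataFrame:
    """Per-node degree table from the binary adjacency.

    ``out_degree`` is the row sum (customers supplied at/above threshold),
    ``in_degree`` the column sum (suppliers), ``degree`` their sum so each
    directed edge is counted exactly once per endpoint role.
    """
    if net.binary is None:
        raise UndefinedDensityError("binarize the network before computing degrees")
    b = net.binary
    out_deg = b.sum(axis=1).astype(int)
    in_deg = b.sum(axis=0).astype(int)
    return pd.DataFrame({
        "node": net.nodes,
        "in_degree": in_deg,
        "out_degree": out_deg,
        "degree": in_deg + out_deg,
    }).set_index("node")


@dataclass
class ShareTable:
    """Per-country totals and shares of one year's trade, ranked descending.

    ``frame`` columns: ``flow_total, share, rank, cumulative`` indexed by
    country; shares are fractions of the year's grand total over *all* flows.
    """

    frame: pd.DataFrame
    year: int
    direction: str
    grand_total: float
    top_k: int

    @property
    def cumulative_top_k(self) -> float:
        return self.top_share(self.top_k)

    def top_share(self, k: int) -> float:
        return float(self.frame["share"].iloc[:k].sum())

    def share_of(self, country: str) -> float:
        return float(self.frame.loc[country, "share"])


def trade_shares(flows: TradeFlowTable, year: int, direction: str = "export",
                 top_k: int = 10) -> ShareTable:
    """Country totals by export or import side, as shares of the grand total.

    Rank ties are broken by country code.  Raises
    :class:`DegenerateShareError` when the year's grand total is zero.
    """
    if direction not in ("export", "import"):
        raise DegenerateShareError(f"direction must be export/import, got {direction!r}")
    sub = flows.for_year(year)
    grand = float(sub["value"].sum())
    if grand <= 0:
        raise DegenerateShareError(f"zero grand total for year {year}")
    key = "exporter" if direction == "export" else "importer"
    totals = sub.groupby(key)["value"].sum()
    frame = totals.rename("flow_total").to_frame()
    frame["share"] = frame["flow_total"] / grand
    frame = frame.sort_values(["flow_total", frame.index.name],
                              ascending=[False, True], kind="mergesort")
    frame["rank"] = np.arange(1, len(frame) + 1)
    frame["cumulative"] = frame["share"].cumsum()
    frame.index.name = "country"
    return ShareTable(frame=frame, year=year, direction=direction,
                      grand_total=grand, top_k=top_k)


@dataclass
class ExpFit:
    """Fit of p(k) ~ amplitude * exp(-rate * k) to an empirical degree law."""

    amplitude: float
    rate: float
    rmse: float
    support: np.ndarray  # distinct degrees used
    probabilities: np.ndarray

    def predict(self, k: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-self.rate * np.asarray(k, dtype=float))


def _empirical_distribution(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ks, counts = np.unique(np.asarray(values, dtype=int), return_counts=True)
    return ks.astype(float), counts / counts.sum()


def fit_exponential_distribution(deg: pd.DataFrame, which: str = "degree",
                                 method: str = "raw") -> ExpFit:
    """Least-squares exponential fit to the empirical degree distribution.

    ``which`` selects the ``degree``, ``in_degree``/``in`` or
    ``out_degree``/``out`` column.  ``method="raw"`` (default) fits
    ``a*exp(-b*k)`` directly to the per-degree probabilities, which tolerates
    sparse support; ``method="loglinear"`` fits a line to ``log p(k)``.
    Two distinct degrees give the exact two-point (saturated) solution.
    """
    col = {"degree": "degree", "in": "in_degree", "in_degree": "in_degree",
           "out": "out_degree", "out_degree": "out_degree"}.get(which)
    if col is None:
        raise InsufficientSupportError(f"unknown degree column: {which!r}")
    ks, ps = _empirical_distribution(deg[col].to_numpy())
    if len(ks) < 2:
        raise InsufficientSupportError(
            f"need >= 2 distinct values to fit, got {len(ks)}")
    if len(ks) == 2:
        # saturated: solve a*exp(-b k) through both points exactly
        b = (np.log(ps[0]) - np.log(ps[1])) / (ks[1] - ks[0])
        a = ps[0] * np.exp(b * ks[0])
        return ExpFit(float(a), float(b), 0.0, ks, ps)
    # log-linear solution; used directly or as the raw fit's starting point
    pos = ps > 0
    slope, intercept = np.polyfit(ks[pos], np.log(ps[pos]), 1)
    a0, b0 = float(np.exp(intercept)), float(-slope)
    if method == "loglinear":
        a, b = a0, b0
    elif method == "raw":
        try:
            (a, b), _ = curve_fit(lambda k, a, b: a * np.exp(-b * k),
                                  ks, ps, p0=(max(a0, 1e-9), b0), maxfev=10000)
        except RuntimeError:
            a, b = a0, b0
    else:
        raise InsufficientSupportError(f"unknown fit method: {method!r}")
    resid = ps - a * np.exp(-b * ks)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return ExpFit(float(a), float(b), rmse, ks, ps)
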