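"""External-supply-risk composite for importing countries.

Three per-importer components feed a composite score:

* ``r_edi``  — external dependence: agricultural imports over GDP, shifted
  by +1 (floored at 1 for non-positive ratios);
* ``r_hhi`` — import concentration: sum of squared supplier shares;
* ``r_rici`` — epidemic exposure: import-share-weighted supplier CRI
  (``partner_cri`` mode) or the importer's own CRI (``own_cri`` mode, the
  degenerate literal reading kept for comparison).

``aecsi`` is their sum (raw mode) or the sum of their 1..k interval scores
(graded mode); contribution rates determine a dominant risk type, with
"Compound risks" when no component contributes strictly more than half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import (
    IndicatorError,
    ParameterError,
    UndefinedConcentrationError,
)
from .grading import BreakSet, assign_grades, equal_interval_breaks, jenks_breaks
from .trade_data import CountryIndicatorTable, TradeFlowTable

__all__ = ["edi", "hhi", "rici", "aecsi", "dominant_risk", "risk_pipeline",
           "RiskConfig", "RiskResult"]

DOMINANT_LABELS = ("EDI risk", "HHI risk", "RICI risk", "Compound risks")


def edi(imports: float, gdp: float) -> float:
    """External dependence index: imports/GDP + 1, floored at 1.

    The floor branch (ratio <= 0 -> 1) is unreachable for positive GDP and
    non-negative imports but kept deliberately; it makes the index >= 1 by
    construction.
    """
    if gdp <= 0:
        raise IndicatorError(f"GDP must be positive, got {gdp}")
    if imports < 0:
        raise ParameterError(f"imports must be >= 0, got {imports}")
    e = imports / gdp
    return 1.0 if e <= 0 else e + 1.0


def _supplier_shares(flows: TradeFlowTable, importer: str, year: int) -> pd.Series:
    supplies = flows.imports_by_supplier(importer, year)
    total = supplies.sum()
    if total <= 0:
        raise UndefinedConcentrationError(
            f"{importer} has no positive imports in {year}")
    return supplies / total


def hhi(flows: TradeFlowTable, importer: str, year: int) -> float:
    """Herfindahl-Hirschman import concentration: sum of squared supplier shares."""
    shares = _supplier_shares(flows, importer, year)
    return float((shares ** 2).sum())


def rici(flows: TradeFlowTable, indicators: CountryIndicatorTable,
         importer: str, year: int,
         mode: Literal["partner_cri", "own_cri"] = "partner_cri") -> float:
    """Epidemic-risk exposure of an importer.

    ``partner_cri`` (default): import-share-weighted mean of supplier CRIs.
    ``own_cri``: the importer's own CRI regardless of shares.
    """
    if mode == "own_cri":
        c = indicators.cri(importer, year)
        if c is None:
            raise IndicatorError(f"no CRI for {importer} in {year}",
                                 countries=[importer])
        return float(c)
    if mode != "partner_cri":
        raise ParameterError(f"unknown RICI mode: {mode!r}")
    shares = _supplier_shares(flows, importer, year)
    cris, missing = {}, []
    for supplier in shares.index:
        c = indicators.cri(str(supplier), year)
        if c is None:
            missing.append(str(supplier))
        else:
            cris[supplier] = c
    if missing:
        raise IndicatorError(f"no CRI for suppliers of {importer} in {year}: "
                             f"{missing}", countries=missing)
    values = set(cris.values())
    if len(values) == 1:
        # shares sum to one, so a common CRI c is returned exactly
        return float(values.pop())
    return float(sum(shares[s] * cris[s] for s in shares.index))


def aecsi(r_edi: float, r_hhi: float, r_rici: float,
          mode: Literal["raw", "graded"] = "raw",
          grades: tuple[int, int, int] | None = None,
          ) -> tuple[float, tuple[float, float, float]]:
    """Composite score and per-component contribution rates.

    Raw mode sums the raw component values; graded mode sums their class
    scores (``grades`` required).  Contribution rates are each summand over
    the total and always sum to 1.
    """
    if mode == "graded":
        if grades is None:
            raise ParameterError("graded mode needs the three class scores")
        comps = tuple(float(g) for g in grades)
    elif mode == "raw":
        comps = (float(r_edi), float(r_hhi), float(r_rici))
    else:
        raise ParameterError(f"unknown AECSI mode: {mode!r}")
    if any(c < 0 for c in comps):
        raise ParameterError(f"components must be >= 0, got {comps}")
    total = sum(comps)
    if total <= 0:
        raise ParameterError("contribution rates undefined: all components zero")
    crs = tuple(c / total for c in comps)
    return total, crs  # type: ignore[return-value]


def dominant_risk(cr_edi: float, cr_hhi: float, cr_rici: float) -> str:
    """Dominant-risk label: the unique component with CR strictly above 0.5.

    A rate of exactly 0.5 does not dominate; the label is then
    "Compound risks".
    """
    for cr, label in ((cr_edi, "EDI risk"), (cr_hhi, "HHI risk"),
                      (cr_rici, "RICI risk")):
        if cr > 0.5:
            return label
    return "Compound risks"


@dataclass
class RiskConfig:
    classifier: Literal["jenks", "equal_interval"] = "jenks"
    k: int = 5
    rici_mode: Literal["partner_cri", "own_cri"] = "partner_cri"
    aecsi_mode: Literal["raw", "graded"] = "raw"

    def __post_init__(self) -> None:
        if self.classifier not in ("jenks", "equal_interval"):
            raise ParameterError(f"unknown classifier: {self.classifier!r}")


@dataclass
class RiskResult:
    """Pipeline output: one row per importer plus grading provenance."""

    records: pd.DataFrame
    year: int
    config: RiskConfig
    breaks: dict[str, BreakSet | None] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def _fit_breaks(values: np.ndarray, config: RiskConfig,
                notes: list[str], name: str) -> BreakSet | None:
    """Per-year cross-sectional breaks; None when the cross-section is degenerate."""
    try:
        if config.classifier == "jenks":
            return jenks_breaks(values, config.k)
        return equal_interval_breaks(values, config.k)
    except Exception as exc:  # degenerate cross-section: constant / too few values
        notes.append(f"{name}: classification infeasible ({exc}); all grades set to 1")
        return None


def _grade(values: np.ndarray, breaks: BreakSet | None) -> np.ndarray:
    if breaks is None:
        return np.ones(len(values), dtype=int)
    return assign_grades(values, breaks, warn=False)


def risk_pipeline(flows: TradeFlowTable, indicators: CountryIndicatorTable,
                  year: int, config: RiskConfig | None = None) -> RiskResult:
    """Score every importer of one year and type its dominant risk.

    Grades are fitted on that year's cross-country values (not pooled across
    years).  Per-country failures (missing GDP/CRI, zero imports) are recorded
    and do not abort the remaining countries.
    """
    config = config or RiskConfig()
    failures: dict[str, str] = {}
    notes: list[str] = []
    rows: list[dict] = []
    for importer in flows.importers(year):
        try:
            imports_total = flows.total_imports(importer, year)
            gdp = indicators.gdp(importer, year)
            if gdp is None:
                raise IndicatorError(f"no GDP for {importer} in {year}",
                                     countries=[importer])
            r_e = edi(imports_total, gdp)
            r_h = hhi(flows, importer, year)
            r_r = rici(flows, indicators, importer, year, mode=config.rici_mode)
        except Exception as exc:
            failures[importer] = f"{type(exc).__name__}: {exc}"
            continue
        rows.append({"country": importer, "year": year,
                     "r_edi": r_e, "r_hhi": r_h, "r_rici": r_r})
    records = pd.DataFrame(rows)
    breaks: dict[str, BreakSet | None] = {}
    if not records.empty:
        for name in ("r_edi", "r_hhi", "r_rici"):
            breaks[name] = _fit_breaks(records[name].to_numpy(), config, notes, name)
            records[f"grade_{name.removeprefix('r_')}"] = _grade(
                records[name].to_numpy(), breaks[name])
        totals, crs = [], []
        for _, row in records.iterrows():
            grades = (row["grade_edi"], row["grade_hhi"], row["grade_rici"])
            total, cr = aecsi(row["r_edi"], row["r_hhi"], row["r_rici"],
                              mode=config.aecsi_mode,
                              grades=grades if config.aecsi_mode == "graded" else None)
            totals.append(total)
            crs.append(cr)
        records["aecsi"] = totals
        records[["cr_edi", "cr_hhi", "cr_rici"]] = pd.DataFrame(crs,
                                                                index=records.index)
        breaks["aecsi"] = _fit_breaks(records["aecsi"].to_numpy(), config,
                                      notes, "aecsi")
        records["grade_aecsi"] = _grade(records["aecsi"].to_numpy(),
                                        breaks["aecsi"])
        records["dominant"] = [dominant_risk(e, h, r) for e, h, r in
                               zip(records["cr_edi"], records["cr_hhi"],
                                   records["cr_rici"])]
        records = records.set_index("country")
    return RiskResult(records=records, year=year, config=config,
                      breaks=breaks, failures=failures, notes=notes)
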