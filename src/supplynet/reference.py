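"""Published reference figures for the 88-country Belt-and-Road network.

Bundles the published top-10 exporter/importer rows (USD quantities, printed
percentage shares, partner counts) for 2019 and 2021, the yearly grand totals,
and the published connection counts, so concentration and density figures can
be recomputed without the underlying bilateral extraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trade_data import TradeFlowTable, TradeNetwork, clean_flows

__all__ = ["GRAND_TOTALS", "NODE_COUNT", "EDGE_COUNTS", "TOP10",
           "top10_frame", "reference_flow_table", "reference_binary_network"]

#: grand total agricultural trade (USD) among the 88 sampled countries
GRAND_TOTALS = {2019: 307_384_908_993, 2021: 381_582_788_232}

#: sample size and published >=100M-USD connection counts
NODE_COUNT = 88
EDGE_COUNTS = {2019: 556, 2021: 505}

#: (country, quantity USD, printed share %, partner count) by year/direction
TOP10: dict[tuple[int, str], list[tuple[str, int, float, int]]] = {
    (2019, "export"): [
        ("CHN", 28_388_004_154, 9.24, 34),
        ("IDN", 23_753_536_126, 7.73, 13),
        ("IND", 20_098_378_587, 6.54, 16),
        ("THA", 18_712_887_461, 6.09, 15),
        ("RUS", 17_104_700_703, 5.56, 27),
        ("UKR", 15_917_418_319, 5.18, 7),
        ("ITA", 15_751_194_738, 5.12, 29),
        ("MYS", 14_731_175_035, 4.79, 12),
        ("NZL", 14_702_055_772, 4.78, 6),
        ("POL", 12_968_594_457, 4.22, 15),
    ],
    (2019, "import"): [
        ("CHN", 56_889_520_197, 18.5, 30),
        ("RUS", 18_972_349_720, 6.12, 27),
        ("ITA", 17_691_707_314, 5.76, 34),
        ("KOR", 12_460_848_062, 4.95, 8),
        ("EGY", 12_245_815_698, 3.98, 10),
        ("IND", 12_032_144_998, 3.81, 26),
        ("TUR", 11_703_304_683, 3.81, 23),
        ("SAU", 11_527_055_895, 3.75, 4),
        ("IDN", 9_985_954_133, 3.25, 24),
        ("ARE", 9_655_109_871, 3.14, 7),
    ],
    (2021, "export"): [
        ("IDN", 35_888_649_919, 9.41, 13),
        ("CHN", 28_794_103_903, 7.55, 36),
        ("IND", 26_770_803_485, 7.02, 20),
        ("THA", 23_689_595_579, 6.21, 15),
        ("RUS", 22_983_726_395, 6.02, 28),
        ("MYS", 21_401_527_961, 5.61, 13),
        ("UKR", 20_716_309_523, 5.43, 10),
        ("ITA", 17_911_740_180, 4.69, 31),
        ("NZL", 17_307_137_156, 4.54, 7),
        ("POL", 15_300_714_747, 4.01, 20),
    ],
    (2021, "import"): [
        ("CHN", 78_552_306_715, 20.6, 29),
        ("RUS", 21_190_263_218, 5.56, 30),
        ("ITA", 19_618_077_459, 5.14, 34),
        ("IND", 18_058_426_891, 4.73, 30),
        ("TUR", 15_280_510_267, 4.00, 26),
        ("KOR", 14_746_958_645, 3.86, 9),
        ("SAU", 13_412_083_539, 3.51, 3),
        ("MYS", 12_039_061_430, 3.16, 23),
        ("IDN", 11_266_313_642, 2.95, 27),
        ("ARE", 10_454_229_247, 2.74, 8),
    ],
}

#: published cumulative top-10 shares (%)
CUMULATIVE_TOP10 = {(2019, "export"): 59.25, (2021, "export"): 60.49,
                    (2019, "import"): 53.26, (2021, "import"): 56.25}


def top10_frame(year: int, direction: str) -> pd.DataFrame:
    rows = TOP10[(year, direction)]
    return pd.DataFrame(rows, columns=["country", "quantity_usd",
                                       "printed_share_pct", "partner_count"])


def reference_flow_table(year: int, direction: str,
                         n_residual: int = 20) -> TradeFlowTable:
    """Flow table whose per-country totals reproduce the published top-10 rows.

    Each listed country gets one flow of its published quantity against a
    synthetic counterparty; the remainder of the published grand total is
    spread over ``n_residual`` synthetic countries in chunks small enough to
    stay out of the top 10, so both the shares and the top-10 cumulative
    concentration are recomputable from the table.
    """
    rows = TOP10[(year, direction)]
    total = GRAND_TOTALS[year]
    residual = total - sum(q for _, q, _, _ in rows)
    if residual < 0:
        raise ValueError("top-10 quantities exceed the grand total")
    chunk = residual / n_residual
    records = []
    for i, (country, qty, _, _) in enumerate(rows):
        other = f"Z{i:02d}"
        if direction == "export":
            records.append((year, country, other, qty))
        else:
            records.append((year, other, country, qty))
    for i in range(n_residual):
        a, b = f"R{i:02d}", f"S{i:02d}"
        records.append((year, a, b, chunk))
    frame = pd.DataFrame(records,
                         columns=["year", "exporter", "importer", "value"])
    return clean_flows(frame)


def reference_binary_network(year: int) -> TradeNetwork:
    """An 88-node binary network with exactly the published edge count.

    Edge placement is arbitrary (row-major off-diagonal order): only the node
    and edge counts are meaningful, which is all density depends on.
    """
    n = NODE_COUNT
    e = EDGE_COUNTS[year]
    b = np.zeros((n, n), dtype=np.int8)
    placed = 0
    for i in range(n):
        for j in range(n):
            if i != j and placed < e:
                b[i, j] = 1
                placed += 1
        if placed >= e:
            break
    from .synthetic_world import country_codes
    return TradeNetwork(year=year, nodes=country_codes(n),
                        weights=b.astype(float) * 1e8, binary=b, threshold=1e8)
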