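import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_flows
from supplynet import errors
from supplynet.risk_model import (
    DOMINANT_LABELS,
    RiskConfig,
    aecsi,
    dominant_risk,
    edi,
    hhi,
    rici,
    risk_pipeline,
)
from supplynet.trade_data import CountryIndicatorTable


def indicators_from(rows):
    return CountryIndicatorTable(pd.DataFrame(
        rows, columns=["iso3", "year", "gdp_usd", "cri"]))


class TestEdi:
    def test_direct_formula(self):
        assert edi(1e9, 2e10) == pytest.approx(1.05)

    def test_zero_imports_floor(self):
        assert edi(0.0, 1e10) == 1.0

    def test_result_at_least_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert edi(float(rng.uniform(0, 1e12)),
                       float(rng.uniform(1e8, 1e13))) >= 1.0

    def test_nonpositive_gdp_raises(self):
        for gdp in (0.0, -5.0):
            with pytest.raises(errors.IndicatorError):
                edi(1e9, gdp)

    def test_negative_imports_raise(self):
        with pytest.raises(errors.ParameterError):
            edi(-1.0, 1e10)


class TestHhi:
    def test_single_supplier(self):
        flows = make_flows([(2019, "AAA", "BBB", 5e8)])
        assert hhi(flows, "BBB", 2019) == 1.0

    def test_equal_suppliers(self):
        for k in (2, 4, 10):
            flows = make_flows([(2019, f"S{i:02d}", "IMP", 1.0)
                                for i in range(k)])
            assert hhi(flows, "IMP", 2019) == pytest.approx(1.0 / k)

    def test_hand_evaluated(self):
        flows = make_flows([(2019, "AAA", "IMP", 50.0),
                            (2019, "BBB", "IMP", 30.0),
                            (2019, "CCC", "IMP", 20.0)])
        assert hhi(flows, "IMP", 2019) == pytest.approx(0.38)

    def test_zero_imports_raises(self):
        flows = make_flows([(2019, "AAA", "BBB", 1.0)])
        with pytest.raises(errors.UndefinedConcentrationError):
            hhi(flows, "AAA", 2019)

    def test_bounds(self, world_pre):
        for importer in world_pre.flows.importers(2019)[:20]:
            v = hhi(world_pre.flows, importer, 2019)
            assert 0 < v <= 1


class TestRici:
    def test_all_cri_one(self):
        flows = make_flows([(2019, "AAA", "IMP", 60.0),
                            (2019, "BBB", "IMP", 40.0)])
        ind = indicators_from([("AAA", 2019, 1e10, 1.0),
                               ("BBB", 2019, 1e10, 1.0)])
        assert rici(flows, ind, "IMP", 2019) == 1.0

    def test_hand_evaluated(self):
        flows = make_flows([(2019, "AAA", "IMP", 60.0),
                            (2019, "BBB", "IMP", 40.0)])
        ind = indicators_from([("AAA", 2019, 1e10, 2.0),
                               ("BBB", 2019, 1e10, 5.0)])
        assert rici(flows, ind, "IMP", 2019) == pytest.approx(3.2)

    def test_own_cri_mode_ignores_shares(self):
        flows = make_flows([(2019, "AAA", "IMP", 60.0),
                            (2019, "BBB", "IMP", 40.0)])
        ind = indicators_from([("AAA", 2019, 1e10, 2.0),
                               ("BBB", 2019, 1e10, 5.0),
                               ("IMP", 2019, 1e10, 7.3)])
        assert rici(flows, ind, "IMP", 2019, mode="own_cri") == 7.3

    def test_missing_cri_lists_countries(self):
        flows = make_flows([(2019, "AAA", "IMP", 60.0),
                            (2019, "BBB", "IMP", 40.0)])
        ind = indicators_from([("AAA", 2019, 1e10, 2.0)])
        with pytest.raises(errors.IndicatorError) as exc:
            rici(flows, ind, "IMP", 2019)
        assert exc.value.countries == ["BBB"]

    def test_convexity_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            vals = rng.uniform(1, 100, size=k)
            cris = rng.uniform(1, 150, size=k)
            flows = make_flows([(2019, f"S{i:02d}", "IMP", float(v))
                                for i, v in enumerate(vals)])
            ind = indicators_from([(f"S{i:02d}", 2019, 1e10, float(c))
                                   for i, c in enumerate(cris)])
            r = rici(flows, ind, "IMP", 2019)
            assert cris.min() - 1e-9 <= r <= cris.max() + 1e-9

    def test_common_cri_returned_exactly(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 9, size=7)
        flows = make_flows([(2019, f"S{i:02d}", "IMP", float(v))
                            for i, v in enumerate(vals)])
        ind = indicators_from([(f"S{i:02d}", 2019, 1e10, 37.25)
                               for i in range(7)])
        assert rici(flows, ind, "IMP", 2019) == 37.25


class TestAecsi:
    def test_raw_arithmetic(self):
        total, (ce, ch, cr) = aecsi(1.05, 0.38, 1.0)
        assert total == pytest.approx(2.43)
        assert ce == pytest.approx(1.05 / 2.43)
        assert ch == pytest.approx(0.38 / 2.43)
        assert cr == pytest.approx(1.0 / 2.43)

    def test_symmetry(self):
        total, crs = aecsi(1.0, 1.0, 1.0)
        assert total == 3.0
        assert crs == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_graded_mode(self):
        total, crs = aecsi(0, 0, 0, mode="graded", grades=(2, 3, 5))
        assert total == 10
        assert crs == pytest.approx((0.2, 0.3, 0.5))

    def test_all_zero_components_raise(self):
        with pytest.raises(errors.ParameterError):
            aecsi(0.0, 0.0, 0.0)

    def test_additivity_in_rici(self):
        base, _ = aecsi(1.2, 0.5, 2.0)
        doubled, _ = aecsi(1.2, 0.5, 4.0)
        assert doubled - base == pytest.approx(2.0)

    def test_cr_sum_is_one(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            comps = rng.uniform(0.01, 10, size=3)
            _, crs = aecsi(*comps)
            assert sum(crs) == pytest.approx(1.0, abs=1e-12)


class TestDominantRisk:
    def test_compound_when_no_majority(self):
        assert dominant_risk(0.43, 0.16, 0.41) == "Compound risks"

    def test_rici_dominates(self):
        _, crs = aecsi(1.0, 1.0, 10.0)
        assert crs[2] == pytest.approx(10 / 12)
        assert dominant_risk(*crs) == "RICI risk"

    def test_exact_half_is_compound(self):
        assert dominant_risk(0.5, 0.25, 0.25) == "Compound risks"

    @given(st.floats(0.001, 1), st.floats(0.001, 1), st.floats(0.001, 1))
    @settings(max_examples=300, deadline=None)
    def test_exhaustive_and_exclusive_on_simplex(self, a, b, c):
        total = a + b + c
        crs = (a / total, b / total, c / total)
        label = dominant_risk(*crs)
        assert label in DOMINANT_LABELS
        n_majorities = sum(cr > 0.5 for cr in crs)
        if n_majorities == 0:
            assert label == "Compound risks"
        else:
            assert label != "Compound risks"


class TestRiskPipeline:
    def test_pre_epidemic_world(self, world_pre):
        res = risk_pipeline(world_pre.flows, world_pre.indicators, 2019)
        assert not res.records.empty
        assert (res.records["r_rici"] == 1.0).all()
        assert (res.records["dominant"] != "RICI risk").all()
        crs = res.records[["cr_edi", "cr_hhi", "cr_rici"]].sum(axis=1)
        assert np.allclose(crs, 1.0, atol=1e-12)

    def test_epidemic_shift(self, world_pre, world_epidemic):
        pre = risk_pipeline(world_pre.flows, world_pre.indicators, 2019)
        post = risk_pipeline(world_epidemic.flows, world_epidemic.indicators,
                             2019)
        assert (post.records["aecsi"].mean()
                > 10 * pre.records["aecsi"].mean())
        assert (post.records["dominant"] == "RICI risk").mean() > 0.5

    def test_failure_isolation(self):
        # one importer has no GDP: it is flagged, the rest are scored
        flows = make_flows([(2019, "AAA", "BBB", 5e8),
                            (2019, "AAA", "CCC", 5e8),
                            (2019, "CCC", "BBB", 5e8)])
        ind = indicators_from([("AAA", 2019, 1e10, 1.0),
                               ("CCC", 2019, 1e10, 1.0)])
        res = risk_pipeline(flows, ind, 2019)
        assert "BBB" in res.failures
        assert list(res.records.index) == ["CCC"]

    def test_grades_and_breaks_recorded(self, world_epidemic):
        cfg = RiskConfig(classifier="equal_interval")
        res = risk_pipeline(world_epidemic.flows, world_epidemic.indicators,
                            2019, cfg)
        for name in ("r_edi", "r_hhi", "r_rici", "aecsi"):
            assert res.breaks[name] is not None
            assert res.breaks[name].method == "equal_interval"
        for col in ("grade_edi", "grade_hhi", "grade_rici", "grade_aecsi"):
            assert res.records[col].between(1, 5).all()

    def test_graded_mode_sums_grades(self, world_epidemic):
        cfg = RiskConfig(aecsi_mode="graded")
        res = risk_pipeline(world_epidemic.flows, world_epidemic.indicators,
                            2019, cfg)
        expected = (res.records["grade_edi"] + res.records["grade_hhi"]
                    + res.records["grade_rici"])
        assert (res.records["aecsi"] == expected).all()
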