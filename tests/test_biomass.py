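"""Abundance-to-carbon conversion and the CCF sensitivity sweep."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from picopp import (
    CCFTable,
    GroupCCF,
    StationRecord,
    biomass_from_abundance,
    biomass_station,
    ccf_sensitivity,
)

DIRECT = CCFTable.direct()


class TestBiomassFromAbundance:
    @pytest.mark.parametrize(
        "abundance,ccf,expected",
        [
            (4.8e3, 2590.0, 12.432),  # Euk, early-summer shelf mean -> 12.4
            (1.5e3, 255.0, 0.3825),  # Syn, early-spring shelf mean -> 0.4
            (0.0, 255.0, 0.0),
        ],
    )
    def test_worked_values(self, abundance, ccf, expected):
        assert biomass_from_abundance(abundance, ccf) == pytest.approx(
            expected, abs=1e-12
        )

    @given(
        st.floats(min_value=0, max_value=1e7),
        st.floats(min_value=1.0, max_value=5000.0),
    )
    def test_exact_linearity(self, abundance, ccf):
        base = biomass_from_abundance(abundance, ccf)
        assert base == abundance * ccf * 1e-6
        assert biomass_from_abundance(2 * abundance, ccf) == pytest.approx(
            2 * base, rel=1e-12
        )
        assert biomass_from_abundance(abundance, 2 * ccf) == pytest.approx(
            2 * base, rel=1e-12
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            biomass_from_abundance(-1.0, 255.0)
        with pytest.raises(ValueError):
            biomass_from_abundance(1.0, 0.0)


class TestCCFTable:
    def test_shipped_direct_set(self):
        assert (DIRECT.prochlorococcus.min, DIRECT.prochlorococcus.max) == (16, 53)
        assert DIRECT.synechococcus.average == 255
        assert DIRECT.picoeukaryotes.average == 2590

    def test_shipped_in_situ_set_is_average_only(self):
        t = CCFTable.in_situ()
        for g in ("prochlorococcus", "synechococcus", "picoeukaryotes"):
            ccf = t.group(g)
            assert ccf.min == ccf.max == ccf.average
        assert (t.prochlorococcus.average, t.synechococcus.average,
                t.picoeukaryotes.average) == (60, 154, 1319)

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            GroupCCF(min=100, max=50, average=75)
        with pytest.raises(ValueError):
            GroupCCF(min=0, max=50, average=25)

    def test_level_interpolation_endpoints(self):
        g = DIRECT.picoeukaryotes
        assert g.at_level(0.0) == g.min
        assert g.at_level(1.0) == g.max
        assert g.at_level(0.5) == pytest.approx((g.min + g.max) / 2)


class TestBiomassStation:
    def test_missing_group_contributes_zero_with_flag(self):
        rec = StationRecord(syn_cells_ml=2.2e4, euk_cells_ml=4.8e3)
        est = biomass_station(rec, DIRECT)
        assert est.per_group["prochlorococcus"] == 0.0
        assert est.missing_groups == ("prochlorococcus",)
        assert est.per_group["synechococcus"] == pytest.approx(5.61)
        assert est.per_group["picoeukaryotes"] == pytest.approx(12.432)
        assert est.total == pytest.approx(5.61 + 12.432)

    def test_all_zero_abundances(self):
        rec = StationRecord(pro_cells_ml=0, syn_cells_ml=0, euk_cells_ml=0)
        est = biomass_station(rec, DIRECT)
        assert est.total == 0.0 and not est.missing_groups

    def test_min_max_monotonicity(self):
        rec = StationRecord(pro_cells_ml=1e4, syn_cells_ml=5e3, euk_cells_ml=1e3)
        lo = biomass_station(rec, DIRECT, which="min").total
        mid = biomass_station(rec, DIRECT, which="average").total
        hi = biomass_station(rec, DIRECT, which="max").total
        assert lo <= mid <= hi


@pytest.fixture(scope="module")
def records():
    return [
        StationRecord(sst_c=18.0, chl_mgm3=1.0, pro_cells_ml=1e4,
                      syn_cells_ml=5e3, euk_cells_ml=1e3),
        StationRecord(sst_c=25.0, chl_mgm3=0.8, pro_cells_ml=5e4,
                      syn_cells_ml=2e3, euk_cells_ml=5e2),
        StationRecord(sst_c=10.0, chl_mgm3=2.0, syn_cells_ml=1e4,
                      euk_cells_ml=2e3),
    ]


class TestSensitivity:
    def test_grid_has_eleven_inclusive_levels(self, records):
        res = ccf_sensitivity(records, DIRECT, mode="joint")
        assert len(res.levels) == 11
        assert res.levels[0] == 0.0 and res.levels[-1] == 1.0

    @pytest.mark.parametrize(
        "group,ratio",
        [
            ("picoeukaryotes", 4400 / 800),
            ("prochlorococcus", 53 / 16),
            ("synechococcus", 350 / 170),
        ],
    )
    def test_max_min_ratio_equals_ccf_ratio(self, records, group, ratio):
        # the sweep is linear in CCF, so the spread per group is the pure
        # CCF ratio regardless of the record set
        res = ccf_sensitivity(records, DIRECT, mode="joint")
        assert res.max_min_ratio(group) == pytest.approx(ratio, rel=1e-12)
        assert res.max_min_ratio(group, "median") == pytest.approx(ratio, rel=1e-12)

    def test_summaries_nondecreasing_in_level(self, records):
        res = ccf_sensitivity(records, DIRECT, mode="joint")
        for group in ("prochlorococcus", "synechococcus", "picoeukaryotes", "total"):
            values = res.summary(group, "mean").to_numpy()
            assert np.all(np.diff(values) >= -1e-15)

    def test_single_record_single_group_linear_in_level(self):
        rec = StationRecord(sst_c=20.0, chl_mgm3=1.0, euk_cells_ml=1e3)
        res = ccf_sensitivity([rec], DIRECT, mode="joint")
        pp = res.summary("picoeukaryotes", "mean")
        levels = pp.index.to_numpy() / 100.0
        g = DIRECT.picoeukaryotes
        expected = pp.iloc[0] * (g.min + levels * (g.max - g.min)) / g.min
        np.testing.assert_allclose(pp.to_numpy(), expected, rtol=1e-12)

    def test_per_group_mode_varies_one_group_at_a_time(self, records):
        res = ccf_sensitivity(records, DIRECT, mode="per_group")
        t = res.table
        assert set(t["varied"]) == {
            "prochlorococcus", "synechococcus", "picoeukaryotes"
        }
        # holding Syn at average while varying Euk: Syn PP flat across levels
        syn_while_euk = res.summary(
            "synechococcus", "mean", varied="picoeukaryotes"
        ).to_numpy()
        assert np.ptp(syn_while_euk) == pytest.approx(0.0, abs=1e-15)
        # 3 varied groups x 11 levels x 4 output groups x 4 statistics
        assert len(t) == 3 * 11 * 4 * 4

    def test_empty_record_set_rejected(self):
        with pytest.raises(ValueError):
            ccf_sensitivity([], DIRECT)
        with pytest.raises(ValueError):
            ccf_sensitivity([StationRecord(syn_cells_ml=1.0)], DIRECT)
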