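"""Particulate Cu, the extended-Redfield cell quota and the budget table."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cumob.budget import (
    QuotaModel,
    accumulation_time,
    build_budget_table,
    cell_carbon,
    cell_cu_quota,
    cu_to_c_ratio,
    mob_cu_pool,
    particulate_fraction,
    particulate_profile,
    reported_cu_quota,
    round_sig,
    underestimation_factor,
)
from cumob.datasets import rotsee_budget_inputs
from cumob.errors import ParameterError, UnitError
from cumob.profiles import DepthProfile


class TestParticulateFraction:
    def test_equal_fractions_give_zero(self):
        value, sd, flag = particulate_fraction(10.0, 10.0, 0.1, 0.1)
        assert value == 0.0 and flag == "ok"

    def test_sd_propagation(self):
        value, sd, flag = particulate_fraction(10.0, 7.0, 0.3, 0.4)
        assert value == pytest.approx(3.0)
        assert sd == pytest.approx(0.5, rel=1e-12)  # sqrt(0.09 + 0.16)

    def test_negative_difference_flagged(self):
        value, _, flag = particulate_fraction(7.0, 10.0)
        assert value == -3.0
        assert flag == "negative_particulate"

    @given(
        st.floats(0, 5), st.floats(0, 5),
        st.floats(0, 100), st.floats(0, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_propagated_sd_at_least_max_input_sd(self, s1, s2, t, d):
        _, sd, _ = particulate_fraction(t, d, s1, s2)
        assert sd >= max(s1, s2) - 1e-12

    def test_profile_subtraction_and_unit_mismatch(self):
        z = np.array([1.0, 2.0])
        tot = DepthProfile("Cu", "total", z, [10.0, 5.0], "nM", sds=[0.3, 0.3])
        dis = DepthProfile("Cu", "dissolved", z, [7.0, 6.0], "nM", sds=[0.4, 0.4])
        part = particulate_profile(tot, dis)
        assert part.values.tolist() == [3.0, -1.0]
        assert part.flags.tolist() == ["ok", "negative_particulate"]
        assert part.sds[0] == pytest.approx(0.5)
        dis_um = DepthProfile("Cu", "dissolved", z, [7.0, 6.0], "uM")
        with pytest.raises(UnitError):
            particulate_profile(tot, dis_um)


class TestQuotaChain:
    def test_cell_carbon_defaults(self):
        c = cell_carbon(QuotaModel())
        assert c == pytest.approx(np.pi / 6 * 8 * 6.4e-15, rel=1e-12)
        # one-significant-figure report in pmol
        assert round_sig(c * 1e12, 1) == pytest.approx(0.03)

    def test_cell_carbon_degenerate_and_unit_sphere(self):
        assert cell_carbon(QuotaModel(cell_diameter_um=0.0)) == 0.0
        assert cell_carbon(QuotaModel(cell_diameter_um=1.0)) == pytest.approx(
            3.3510e-15, rel=1e-4
        )

    def test_atom_range_and_mean_quota(self):
        quota, atoms = cell_cu_quota(QuotaModel())
        assert atoms == (2000.0, 60_000.0)
        assert quota == pytest.approx(8.5 * 2500 / 6.02214076e23, rel=1e-12)
        assert quota == pytest.approx(3.529e-20, rel=1e-3)
        assert reported_cu_quota(QuotaModel()) == pytest.approx(4e-20)

    def test_single_atom_cell(self):
        q = QuotaModel(cu_per_pmmo_range=(1, 1), pmmo_per_cell_range=(1, 1))
        quota, atoms = cell_cu_quota(q)
        assert atoms == (1.0, 1.0)
        assert quota == pytest.approx(1.6605e-24, rel=1e-4)

    def test_quota_modes_all_round_to_same_order(self):
        for mode in ("midpoint_product", "atom_midpoint", "geometric_mean"):
            quota, _ = cell_cu_quota(QuotaModel(quota_mode=mode))
            assert 1e-20 < quota < 1e-19

    def test_cu_to_c_power_of_ten(self):
        q = QuotaModel()
        ratio, power = cu_to_c_ratio(cell_cu_quota(q)[0], cell_carbon(q))
        assert ratio == pytest.approx(1.3163e-6, rel=1e-4)
        assert power == pytest.approx(1e-6)

    def test_phytoplankton_like_ratio(self):
        ratio, power = cu_to_c_ratio(1e-16, 1e-10)
        assert power == pytest.approx(1e-6)

    def test_zero_carbon_rejected(self):
        with pytest.raises(ParameterError):
            cu_to_c_ratio(1e-20, 0.0)


class TestPoolsAndTimes:
    def test_mob_pool_examples(self):
        assert mob_cu_pool(0.0, 4e-20) == 0.0
        assert mob_cu_pool(5.5e10, 4e-20) == pytest.approx(2.2, rel=1e-12)
        pool = mob_cu_pool(2.8e9, 4e-20)
        assert pool == pytest.approx(0.112, rel=1e-12)
        assert round_sig(pool, 1) == pytest.approx(0.1)

    def test_accumulation_time_examples(self):
        assert round(accumulation_time(4100.0, 195.0)) == 21
        assert round(accumulation_time(2400.0, 40.0)) == 60
        with pytest.raises(ParameterError):
            accumulation_time(100.0, 0.0)

    @given(k=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_accumulation_time_homogeneity(self, k):
        base = accumulation_time(4100.0, 195.0)
        assert accumulation_time(k * 4100.0, k * 195.0) == pytest.approx(
            base, rel=1e-12
        )

    def test_underestimation_factor(self):
        assert underestimation_factor(5.0, 5.0) == 1.0
        assert underestimation_factor(4100.0, 15.2) == pytest.approx(269.7, abs=0.1)
        assert underestimation_factor(2400.0, 0.112) == pytest.approx(2.14e4, rel=1e-2)
        with pytest.raises(ParameterError):
            underestimation_factor(100.0, 0.0)


class TestBudgetTable:
    def test_published_inputs_reproduce_accumulation_times(self):
        table = build_budget_table(rotsee_budget_inputs())
        assert table["accumulation_time_cu_diss_d_rounded"].tolist() == [21, 39, 6, 6]
        dgt = table["accumulation_time_cu_dgt_d"].to_numpy()
        assert np.allclose(dgt, [4100 / 19, 13100 / 30, 5200 / 20, 60.0])

    def test_stratification_exceedance_flags(self):
        table = build_budget_table(rotsee_budget_inputs()).set_index("campaign")
        dgt_flags = table["accumulation_exceeds_stratification_cu_dgt"]
        # DGT-supply times exceed the elapsed stratification everywhere but
        # the late-season campaign with the strong DGT flux
        assert dgt_flags.tolist() == [True, True, True, False]
        diss_flags = table["accumulation_exceeds_stratification_cu_diss"]
        assert not any(diss_flags)

    def test_missing_flux_yields_partial_row(self):
        from cumob.budget import CampaignBudgetInput

        inp = CampaignBudgetInput(
            id="x", moz_top=7.0, moz_bottom=9.0,
            integrated_mob_cells_m2=1e10,
            measured_cupart_pool_nmol_m2=1000.0,
            cu_diss_flux_nmol_m2_d=100.0,
        )
        row = build_budget_table([inp]).iloc[0]
        assert np.isnan(row["accumulation_time_cu_dgt_d"])
        assert "cu_dgt_flux_nmol_m2_d" in row["missing_inputs"]
        assert row["accumulation_time_cu_diss_d_rounded"] == 10

    def test_synthetic_campaign_budget_matches_ground_truth(
        self, synthetic_campaign
    ):
        from cumob.pipeline import analyze_campaign

        campaign, truth = synthetic_campaign
        analysis = analyze_campaign(campaign)
        table = build_budget_table([analysis.budget_input], use_reported_quota=True)
        row = table.iloc[0]
        assert row["measured_cupart_pool_nmol_m2"] == pytest.approx(
            truth.cupart_pool_nmol_m2, rel=0.05
        )
        assert row["mob_cupart_pool_nmol_m2"] == pytest.approx(
            truth.mob_cu_pool_nmol_m2, rel=0.10
        )
        expected_time = truth.cupart_pool_nmol_m2 / truth.cu_diss_flux_nmol_m2_d
        assert row["accumulation_time_cu_diss_d"] == pytest.approx(
            expected_time, rel=0.10
        )
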