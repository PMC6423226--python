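"""Published campaign summaries bundled as analysis inputs.

The Rotsee field study (a small eutrophic subalpine lake, four campaigns
across the 2013-2015 stratification seasons) reported per-campaign
methane-oxidation-zone bounds, zone-integrated methanotroph cell numbers,
measured particulate-copper pools and diffusive copper supply fluxes. These
published summary values are the inputs to the budget assembly; the raw
depth profiles behind them are not bundled (the synthetic generator emulates
their structure instead).
"""

from __future__ import annotations

from .budget import CampaignBudgetInput

__all__ = ["rotsee_budget_inputs", "ROTSEE_CAMPAIGNS"]

ROTSEE_CAMPAIGNS = ("2013-06", "2013-08", "2014-09", "2015-09")


def rotsee_budget_inputs() -> list[CampaignBudgetInput]:
    """Published per-campaign budget inputs for Rotsee.

    Pools in nmol m^-2, fluxes in nmol m^-2 d^-1, integrated MOB cells in
    cells m^-2; stratification durations are days elapsed since the onset of
    stratification (the lake typically re-stratifies in April).
    """
    prov = {"source": "published campaign summary"}
    return [
        CampaignBudgetInput(
            id="2013-06",
            moz_top=10.5,
            moz_bottom=15.0,
            integrated_relative_mob_pct=6.0,
            integrated_mob_cells_m2=3.8e11,
            measured_cupart_pool_nmol_m2=4100.0,
            cu_dgt_flux_nmol_m2_d=19.0,
            cu_diss_flux_nmol_m2_d=195.0,
            stratification_days=60.0,
            provenance=dict(prov),
        ),
        CampaignBudgetInput(
            id="2013-08",
            moz_top=8.0,
            moz_bottom=11.0,
            integrated_relative_mob_pct=1.4,
            integrated_mob_cells_m2=5.5e10,
            measured_cupart_pool_nmol_m2=13_100.0,
            cu_dgt_flux_nmol_m2_d=30.0,
            cu_diss_flux_nmol_m2_d=336.0,
            stratification_days=120.0,
            provenance=dict(prov),
        ),
        CampaignBudgetInput(
            id="2014-09",
            moz_top=6.0,
            moz_bottom=9.0,
            integrated_relative_mob_pct=1.7,
            integrated_mob_cells_m2=6.6e10,
            measured_cupart_pool_nmol_m2=5200.0,
            cu_dgt_flux_nmol_m2_d=20.0,
            cu_diss_flux_nmol_m2_d=828.0,
            stratification_days=160.0,
            provenance=dict(prov),
        ),
        CampaignBudgetInput(
            id="2015-09",
            moz_top=7.0,
            moz_bottom=8.7,
            integrated_relative_mob_pct=0.9,
            integrated_mob_cells_m2=2.8e9,
            measured_cupart_pool_nmol_m2=2400.0,
            cu_dgt_flux_nmol_m2_d=40.0,
            cu_diss_flux_nmol_m2_d=394.0,
            stratification_days=160.0,
            provenance=dict(prov),
        ),
    ]
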