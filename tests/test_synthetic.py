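"""Synthetic-campaign generator: determinism, noiseless identity, self-consistency."""

import numpy as np
import pytest

from cumob.census import (
    CopyNumberTable,
    census_from_otu_table,
    fit_standard_curve,
    process_qpcr_plate,
)
from cumob.errors import ValidationError
from cumob.synthetic import (
    LakeScenario,
    generate_campaign,
    generate_otu_table,
    generate_qpcr_plate,
)


class TestScenario:
    def test_invalid_moz_rejected(self):
        with pytest.raises(ValidationError):
            LakeScenario(moz_top=9.0, moz_bottom=7.0)
        with pytest.raises(ValidationError):
            LakeScenario(moz_bottom=20.0)

    def test_zone_bounds_are_exact_curve_crossings(self):
        s = LakeScenario()
        # CH4 crosses twice the background exactly at the MOZ top
        assert float(s.ch4(s.moz_top)) == pytest.approx(
            2 * s.epilimnion_ch4_um, rel=1e-9
        )
        # PAR crosses its detection limit exactly at the MOZ bottom
        assert float(s.par(s.moz_bottom)) == pytest.approx(0.1, rel=1e-9)
        # O2 crosses the trace-optode limit exactly at the oxycline
        assert float(s.o2(s.oxycline_depth)) == pytest.approx(0.02, rel=1e-6)


class TestGenerateCampaign:
    def test_noiseless_identity(self):
        s = LakeScenario(seed=1, noise_cv=0.0)
        campaign, _ = generate_campaign(s)
        z = campaign.get("O2").depths
        assert np.allclose(campaign.get("O2").values, s.o2(z))
        assert np.allclose(campaign.get("CH4").values, s.ch4(z))
        assert np.allclose(campaign.get("Cu", "dissolved").values, s.cu_diss(z))
        assert np.allclose(campaign.get("Cu", "total").values, s.cu_total(z))

    def test_same_seed_is_bit_identical(self):
        a, _ = generate_campaign(LakeScenario(seed=9))
        b, _ = generate_campaign(LakeScenario(seed=9))
        for key in a.profiles:
            assert np.array_equal(a.profiles[key].values, b.profiles[key].values)
            assert np.array_equal(a.profiles[key].sds, b.profiles[key].sds)

    def test_different_seeds_differ(self):
        a, _ = generate_campaign(LakeScenario(seed=1))
        b, _ = generate_campaign(LakeScenario(seed=2))
        assert not np.array_equal(
            a.get("Cu", "dissolved").values, b.get("Cu", "dissolved").values
        )

    def test_detection_limit_censoring_applied(self, synthetic_campaign):
        campaign, _ = synthetic_campaign
        o2 = campaign.get("O2")
        deep = o2.depths > 10.0
        assert np.all(o2.flags[deep] == "below_LOD")
        par = campaign.get("PAR")
        assert np.all(par.flags[par.depths > 10.0] == "below_LOD")

    def test_ground_truth_consistent_with_generator(self, default_scenario):
        from cumob.synthetic import ground_truth

        gt = ground_truth(default_scenario)
        # analytic pool equals a fine-grid numerical integral
        z = np.linspace(gt.moz_top, gt.moz_bottom, 20_001)
        num = np.trapezoid(default_scenario.cu_part(z), z) * 1e3
        assert gt.cupart_pool_nmol_m2 == pytest.approx(num, rel=1e-6)
        num_mob = np.trapezoid(default_scenario.mob_cells(z), z) * 1e3
        assert gt.mob_integral_cells_m2 == pytest.approx(num_mob, rel=1e-6)


class TestQpcrPlate:
    def test_noise_free_plate_recovers_curve_exactly(self):
        plate = generate_qpcr_plate(
            {8.0: 1e4}, noise_sd_cp=0.0, poisson_template=False, seed=0
        )
        std = plate[plate.is_standard]
        levels = sorted(std.standard_copies.unique())
        curve = fit_standard_curve(
            levels,
            [std.loc[std.standard_copies == lv, "cp"].to_numpy() for lv in levels],
        )
        assert curve.slope == pytest.approx(-3.3219, rel=1e-9)
        assert curve.intercept == pytest.approx(38.0, rel=1e-9)

    def test_zero_copies_emitted_as_nondetect(self):
        plate = generate_qpcr_plate({5.0: 0.0}, seed=1)
        sample = plate[(~plate.is_standard) & (~plate.is_blank)]
        assert sample.cp.isna().all()
        res = process_qpcr_plate(plate)["pmoA"]
        assert res.iloc[0]["status"] == "not_detected"

    def test_plate_determinism(self):
        a = generate_qpcr_plate({8.0: 1e4}, seed=5)
        b = generate_qpcr_plate({8.0: 1e4}, seed=5)
        assert a.equals(b)

    def test_recovery_fraction_matches_error_model(self):
        """Empirical within-10 % fraction agrees with the closed-form
        prediction from the log-linear Cp error model (triplicate means)."""
        from scipy.stats import norm

        copies = {float(i): 1e4 for i in range(400)}
        plate = generate_qpcr_plate(copies, seed=5)
        res = process_qpcr_plate(plate)["pmoA"]
        ok = res[res.status.isin(["quantified", "estimated_below_LOQ"])]
        frac = np.mean(np.abs(ok.copies_per_reaction - 1e4) / 1e4 <= 0.10)
        slope_mag = 3.3219
        dlo, dhi = slope_mag * -np.log10(0.9), slope_mag * np.log10(1.1)
        sd_mean = 0.15 / np.sqrt(3)
        predicted = norm.cdf(dhi / sd_mean) - norm.cdf(-dlo / sd_mean)
        assert frac == pytest.approx(predicted, abs=0.05)


class TestOtuTable:
    def test_expected_fractions_proportional_to_cells_times_copies(self):
        s = LakeScenario(seed=2)
        otu = generate_otu_table(s, read_depth=None)
        ct = CopyNumberTable()
        col = otu.columns[3]
        depth = float(col)
        counts = otu.groupby("group")[col].sum()
        mob = s.mob_cells(depth)
        weights = {
            "gamma_MOB": s.mob_gamma_fraction * mob * ct["gamma_MOB"],
            "alpha_MOB": (1 - s.mob_gamma_fraction) * mob * ct["alpha_MOB"],
            "verrucomicrobia_excluded": s.verr_cells_l * ct["other"],
            "other": s.other_cells_l * ct["other"],
        }
        total_w = sum(weights.values())
        for g, w in weights.items():
            assert counts[g] / counts.sum() == pytest.approx(w / total_w, rel=1e-9)

    def test_census_round_trip_exact_at_infinite_read_depth(self):
        s = LakeScenario(seed=2)
        otu = generate_otu_table(s, read_depth=None)
        totals = {
            float(col): float(s.sixteen_s_copies(float(col), include_excluded=False))
            for col in otu.columns[3:]
        }
        census = census_from_otu_table(otu, totals)
        gamma = census[census.group == "gamma_MOB"]
        truth = s.mob_gamma_fraction * s.mob_cells(gamma.depth_m.to_numpy())
        assert np.allclose(gamma.cells_per_l.to_numpy(), truth, rtol=1e-9)

    def test_multinomial_sampling_is_unbiased(self):
        """Finite-read-depth census estimates centre on the truth."""
        s = LakeScenario(seed=2)
        depth = float(generate_otu_table(s, read_depth=None).columns[3])
        truth = s.mob_gamma_fraction * s.mob_cells(depth)
        total = float(s.sixteen_s_copies(depth, include_excluded=False))
        estimates = []
        for seed in range(200):
            otu = generate_otu_table(s, read_depth=10_000, seed=seed)
            otu = otu[["otu_id", "taxonomy", "group", f"{depth:g}"]]
            census = census_from_otu_table(otu, {depth: total})
            sel = census[(census.group == "gamma_MOB") & (census.depth_m == depth)]
            estimates.append(float(sel.cells_per_l.iloc[0]))
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(estimates.size)
        assert abs(estimates.mean() - truth) < 4 * se + 1e-9

    def test_single_dominant_group_saturates_read_fraction(self):
        s = LakeScenario(seed=3, mob_peak_cells_l=1e12,
                         mob_background_cells_l=1e12, mob_gamma_fraction=1.0,
                         other_cells_l=1.0, verr_cells_l=1e-6)
        otu = generate_otu_table(s, read_depth=None)
        col = otu.columns[3]
        counts = otu.groupby("group")[col].sum()
        assert counts["gamma_MOB"] / counts.sum() == pytest.approx(1.0, abs=1e-6)
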