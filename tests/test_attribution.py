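"""Attribution tests: ranking, dominance, predictability score, sign
fractions, weighted lags, binned profiles and stratum fractions."""

import numpy as np
import pandas as pd
import pytest

import firelink as fl
from firelink.attribution import attribute_record


def make_links(rows):
    return pd.DataFrame(rows, columns=["source", "lag", "rho"])


class TestLinkFiltering:
    def test_only_links_into_target_kept(self):
        links = pd.DataFrame(
            [
                {"source": "X", "target": "BA", "lag": 1, "rho": 0.5},
                {"source": "BA", "target": "X", "lag": 2, "rho": 0.4},
                {"source": "X", "target": "Y", "lag": 1, "rho": 0.3},
            ]
        )
        out = fl.links_to_ba(links, "BA")
        assert len(out) == 1
        assert out.iloc[0]["source"] == "X"

    def test_empty_graph_gives_empty_table(self):
        assert fl.links_to_ba(pd.DataFrame(), "BA").empty

    def test_multiple_lags_of_same_precursor_kept(self):
        links = pd.DataFrame(
            [
                {"source": "X", "target": "BA", "lag": 1, "rho": 0.5},
                {"source": "X", "target": "BA", "lag": 9, "rho": 0.2},
            ]
        )
        assert len(fl.links_to_ba(links, "BA")) == 2


class TestRanking:
    def test_argmax_abs_rho(self):
        ranked = fl.rank_precursors(
            make_links([("ET0", 1, 0.5), ("SWDI", 60, -0.3)])
        )
        assert ranked.iloc[0]["source"] == "ET0"
        assert ranked.iloc[0]["lag"] == 1

    def test_tie_on_abs_rho_smaller_lag_wins(self):
        ranked = fl.rank_precursors(make_links([("GPP", 4, -0.4), ("VPD", 0, 0.4)]))
        assert ranked.iloc[0]["source"] == "VPD"

    def test_single_row_dominant(self):
        ranked = fl.rank_precursors(make_links([("AAI", 7, -0.2)]))
        assert len(ranked) == 1 and ranked.iloc[0]["source"] == "AAI"

    def test_per_precursor_collapse_to_strongest_lag(self):
        ranked = fl.rank_precursors(
            make_links([("ET0", 9, 0.3), ("ET0", 1, -0.6), ("GPP", 2, 0.4)])
        )
        assert len(ranked) == 2
        et0 = ranked[ranked["source"] == "ET0"].iloc[0]
        assert et0["lag"] == 1 and et0["rho"] == -0.6


class TestDominantGroup:
    def test_grouping_lookup(self):
        g, strengths = fl.dominant_group(make_links([("SWDI", 3, -0.5)]))
        assert g == "bottom-up"
        assert strengths["bottom-up"] == 0.5

    def test_empty_table_maps_to_none(self):
        g, strengths = fl.dominant_group(make_links([]))
        assert g is None
        assert strengths == {"top-down": 0.0, "bottom-up": 0.0}

    def test_cross_group_tie_resolved_by_lag(self):
        g, _ = fl.dominant_group(make_links([("GPP", 4, 0.4), ("VPD", 1, -0.4)]))
        assert g == "top-down"  # VPD wins the tie at the smaller lag


class TestPredictabilityScore:
    def test_sum_of_squares(self):
        assert fl.predictability_score(
            make_links([("ET0", 1, 0.3), ("GPP", 2, -0.4)])
        ) == pytest.approx(0.25)

    def test_empty_is_zero(self):
        assert fl.predictability_score(make_links([])) == 0.0

    def test_upper_bound_ten_precursors(self):
        rows = [(v, 1, 1.0) for v in fl.DEFAULT_GROUPING.mapping]
        assert fl.predictability_score(make_links(rows)) == pytest.approx(10.0)

    def test_invariant_to_order_and_monotone(self, rng):
        rows = [("ET0", 1, 0.3), ("GPP", 2, -0.4), ("Wind", 5, 0.1)]
        s1 = fl.predictability_score(make_links(rows))
        s2 = fl.predictability_score(make_links(rows[::-1]))
        assert s1 == s2
        bigger = [("ET0", 1, 0.5), ("GPP", 2, -0.4), ("Wind", 5, 0.1)]
        assert fl.predictability_score(make_links(bigger)) > s1


class TestWeightedMeanLag:
    def test_single_link(self):
        assert fl.weighted_mean_lag(make_links([("X", 4, 0.2)])) == 4.0

    def test_hand_evaluated_formula(self):
        # (0.4*2 + 0.2*8) / 0.6 = 4.0
        assert fl.weighted_mean_lag(
            make_links([("ET0", 2, 0.4), ("GPP", 8, 0.2)])
        ) == pytest.approx(4.0)

    def test_constant_lags(self):
        assert fl.weighted_mean_lag(
            make_links([("A", 6, 0.9), ("B", 6, 0.1)])
        ) == 6.0

    def test_bounded_by_input_lags(self, rng):
        rows = [(f"P{i}", int(l), float(r)) for i, (l, r) in enumerate(
            zip(rng.integers(0, 100, 8), rng.uniform(-1, 1, 8))
        )]
        wml = fl.weighted_mean_lag(make_links(rows))
        lags = [r[1] for r in rows]
        assert min(lags) <= wml <= max(lags)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fl.weighted_mean_lag(make_links([]))


def _record(eco, rows, area=1.0):
    return attribute_record(make_links(rows), eco, area=area)


class TestSignFractions:
    def test_all_positive(self):
        recs = [_record("e1", [("ET0", 1, 0.5), ("VPD", 2, 0.2)])]
        fr = fl.sign_fractions(recs)
        assert fr["top-down"] == (1.0, 0.0)

    def test_half_half(self):
        recs = [_record("e1", [("ET0", 1, 0.5), ("VPD", 2, -0.2)])]
        fr = fl.sign_fractions(recs)
        assert fr["top-down"] == (0.5, 0.5)

    def test_only_dominant_group_links_counted(self):
        # the ecoregion is top-down dominant; its bottom-up link is not
        # pooled into the bottom-up fractions
        recs = [_record("e1", [("ET0", 1, 0.6), ("GPP", 2, -0.3)])]
        fr = fl.sign_fractions(recs)
        assert fr["top-down"] == (1.0, 0.0)
        assert np.isnan(fr["bottom-up"][0])

    def test_positive_fraction_tends_to_one_with_planted_positive_links(self):
        cfg = fl.PCMCIConfig(tau_max=5, alpha=0.01)
        recs = []
        for seed in range(8):
            spec = fl.ScenarioSpec(
                variables=dict(fl.STANDARD_VARIABLES),
                links=[fl.PlantedLink("ET0", "BA", 1, 0.8)],
                noise_sd=1.0,
                n_weeks=936,
                seed=seed,
            )
            panel, _ = fl.generate_var_panel(spec)
            res = fl.run_pcmci(panel, cfg)
            recs.append(res.attribution())
        fr = fl.sign_fractions(recs)
        assert fr["top-down"][0] > 0.8


class TestGroupMeanLag:
    def test_single_dominant_ecoregion(self):
        recs = [_record("e1", [("ET0", 3, 0.5)])]
        assert fl.group_mean_lag(recs, "top-down") == 3.0

    def test_equal_area_mean(self):
        recs = [
            _record("e1", [("ET0", 2, 0.5)]),
            _record("e2", [("VPD", 6, 0.5)]),
        ]
        assert fl.group_mean_lag(recs, "top-down") == 4.0

    def test_area_weighted_mean(self):
        recs = [
            _record("e1", [("ET0", 0, 0.5)], area=1.0),
            _record("e2", [("VPD", 8, 0.5)], area=3.0),
        ]
        assert fl.group_mean_lag(recs, "top-down") == 6.0

    def test_no_dominant_record_rejected(self):
        recs = [_record("e1", [("ET0", 2, 0.5)])]
        with pytest.raises(ValueError):
            fl.group_mean_lag(recs, "bottom-up")


class TestDominanceRecord:
    def test_none_iff_empty_table(self):
        rec = _record("e1", [])
        assert rec.dominant_group is None and rec.score == 0.0
        rec2 = _record("e2", [("SWDI", 30, -0.7)])
        assert rec2.dominant_group == "bottom-up"
        assert rec2.dominant_precursor == "SWDI"
        assert rec2.dominant_lag == 30

    def test_dominant_has_max_abs_rho(self):
        rec = _record("e1", [("ET0", 1, 0.4), ("SWDI", 9, -0.6), ("GPP", 2, 0.1)])
        top = rec.table["rho"].abs().max()
        dom_rho = rec.table[rec.table["source"] == rec.dominant_precursor]["rho"].abs().max()
        assert dom_rho == top


class TestBinnedProfile:
    def test_counting_fractions(self):
        pixels = pd.DataFrame(
            {
                "cov": [0.1, 0.1, 0.1, 0.1],
                "dominant_group": ["top-down"] * 3 + ["bottom-up"],
            }
        ).rename(columns={"cov": "Tmax"})
        prof = fl.binned_dominance_profile(pixels, "Tmax", n_bins=1)
        assert prof.top_down_fraction[0] == 0.75
        assert prof.bottom_up_fraction[0] == 0.25

    def test_fractions_sum_to_one_where_defined(self, rng):
        n = 500
        pixels = pd.DataFrame(
            {
                "VPD": rng.uniform(0, 10, n),
                "dominant_group": rng.choice(
                    ["top-down", "bottom-up", None], size=n
                ),
            }
        )
        prof = fl.binned_dominance_profile(pixels, "VPD", n_bins=200)
        s = prof.top_down_fraction + prof.bottom_up_fraction
        defined = ~np.isnan(s)
        assert np.allclose(s[defined], 1.0, atol=1e-12)
        assert len(prof.edges) == 201

    def test_empty_bin_flagged_undefined(self):
        pixels = pd.DataFrame(
            {"EVI": [0.0, 10.0], "dominant_group": ["top-down", "top-down"]}
        )
        prof = fl.binned_dominance_profile(pixels, "EVI", n_bins=10)
        assert np.isnan(prof.top_down_fraction[4])

    def test_planted_step_function_recovered(self):
        # dominance switches at covariate 5.0; the profile reproduces
        # the step within one bin
        x = np.linspace(0, 10, 1000)
        pixels = pd.DataFrame(
            {
                "Tmax": x,
                "dominant_group": np.where(x < 5.0, "bottom-up", "top-down"),
            }
        )
        prof = fl.binned_dominance_profile(pixels, "Tmax", n_bins=200)
        centers = 0.5 * (prof.edges[:-1] + prof.edges[1:])
        binw = prof.edges[1] - prof.edges[0]
        defined = ~np.isnan(prof.top_down_fraction)
        below = defined & (centers < 5.0 - binw)
        above = defined & (centers > 5.0 + binw)
        assert (prof.top_down_fraction[below] == 0.0).all()
        assert (prof.top_down_fraction[above] == 1.0).all()


class TestZoneTypeDominance:
    def test_denominator_excludes_undetected(self):
        pixels = pd.DataFrame(
            {
                "climate": ["arid"] * 4,
                "dominant_group": ["top-down", "top-down", "bottom-up", None],
            }
        )
        out = fl.zone_type_dominance(pixels)["climate"]
        row = out.iloc[0]
        assert row["top_down_fraction"] == pytest.approx(2 / 3)
        assert row["bottom_up_fraction"] == pytest.approx(1 / 3)

    def test_all_none_stratum_flagged(self):
        pixels = pd.DataFrame(
            {"vegetation": ["TBE", "TBE"], "dominant_group": [None, None]}
        )
        out = fl.zone_type_dominance(pixels)["vegetation"]
        assert np.isnan(out.iloc[0]["top_down_fraction"])

    def test_pure_stratum(self):
        pixels = pd.DataFrame(
            {"vegetation": ["TNE"] * 3, "dominant_group": ["top-down"] * 3}
        )
        out = fl.zone_type_dominance(pixels)["vegetation"]
        assert out.iloc[0]["top_down_fraction"] == 1.0
        assert out.iloc[0]["bottom_up_fraction"] == 0.0
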