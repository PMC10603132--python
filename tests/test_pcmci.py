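"""Causal-discovery tests: the partial-correlation test against an
independent oracle and closed forms, condition selection, MCI scale
invariance, and graph recovery on planted systems."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import firelink as fl


def oracle_partial_correlation(x, y, Z):
    """Independent brute-force oracle: explicit double OLS regression via
    normal equations, then scipy's Pearson correlation on residuals."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    design = np.column_stack([np.ones(n), *Z]) if len(Z) else np.ones((n, 1))
    gram = design.T @ design
    rx = x - design @ np.linalg.solve(gram, design.T @ x)
    ry = y - design @ np.linalg.solve(gram, design.T @ y)
    return stats.pearsonr(rx, ry).statistic


class TestPartialCorrelation:
    def test_identity_gives_rho_one(self, rng):
        x = rng.normal(size=100)
        res = fl.partial_correlation(x, x)
        assert res.statistic == 1.0

    def test_empty_z_equals_pearson_exactly(self, rng):
        x, y = rng.normal(size=(2, 200))
        res = fl.partial_correlation(x, y)
        r = stats.pearsonr(x, y)
        assert abs(res.statistic - r.statistic) < 1e-12
        assert abs(res.pvalue - r.pvalue) < 1e-10

    def test_trivariate_closed_form_and_oracle(self, rng):
        # known covariance -> closed-form partial correlation from the
        # precision matrix; sample estimate within 3 SE, and bit-level
        # agreement with the double-regression oracle
        cov = np.array([[1.0, 0.6, 0.4], [0.6, 1.0, 0.5], [0.4, 0.5, 1.0]])
        n = 4000
        sample = rng.multivariate_normal(np.zeros(3), cov, size=n)
        x, y, z = sample.T
        prec = np.linalg.inv(cov)
        rho_true = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        res = fl.partial_correlation(x, y, [z])
        se = (1 - rho_true**2) / np.sqrt(n)
        assert abs(res.statistic - rho_true) < 3 * se
        assert abs(res.statistic - oracle_partial_correlation(x, y, [z])) < 1e-10

    def test_oracle_agreement_random_instances(self, rng):
        # spot-check across dimensions here; the 1000-instance sweep is
        # exercised in the acceptance suite
        for _ in range(50):
            n = int(rng.integers(50, 500))
            q = int(rng.integers(0, 6))
            data = rng.normal(size=(n, 2 + q))
            res = fl.partial_correlation(data[:, 0], data[:, 1], list(data[:, 2:].T))
            assert abs(
                res.statistic
                - oracle_partial_correlation(data[:, 0], data[:, 1], list(data[:, 2:].T))
            ) < 1e-10

    def test_listwise_deletion_of_missing_rows(self, rng):
        x, y = rng.normal(size=(2, 120))
        x2 = x.copy()
        x2[:10] = np.nan
        res = fl.partial_correlation(x2, y)
        ref = fl.partial_correlation(x[10:], y[10:])
        assert res.n_eff == 110
        assert abs(res.statistic - ref.statistic) < 1e-12

    def test_collinear_conditioners_warn_but_compute(self, rng):
        x, y, z = rng.normal(size=(3, 100))
        with pytest.warns(UserWarning, match="collinear"):
            res = fl.partial_correlation(x, y, [z, 2 * z])
        ref = fl.partial_correlation(x, y, [z])
        assert abs(res.statistic - ref.statistic) < 1e-10

    def test_degenerate_zero_variance_flagged(self):
        x = np.ones(50)
        y = np.arange(50.0)
        res = fl.partial_correlation(x, y)
        assert res.degenerate and res.pvalue == 1.0

    def test_insufficient_sample_rejected(self, rng):
        with pytest.raises(ValueError, match="insufficient"):
            fl.partial_correlation(
                rng.normal(size=12), rng.normal(size=12), list(rng.normal(size=(3, 12)))
            )


class TestConditionSelection:
    def test_planted_parent_found(self):
        spec = fl.ScenarioSpec(
            variables={"BA": "target", "X": "top-down", "S": "bottom-up"},
            links=[fl.PlantedLink("X", "BA", 2, 0.6)],
            n_weeks=1000,
            seed=0,
        )
        cfg = fl.PCMCIConfig(tau_max=5)
        hits = 0
        for seed in range(20):
            panel, _ = fl.generate_var_panel(
                fl.ScenarioSpec(**{**spec.__dict__, "seed": seed})
            )
            parents = fl.pc_condition_selection(panel, "BA", cfg)
            hits += ("X", 2) in [(v, l) for v, l, _ in parents]
        assert hits >= 19  # >= 95% of replicate seeds

    def test_null_survival_rate_near_pc_alpha_at_q0(self):
        # each candidate survives the unconditional sweep w.p. ~ pc_alpha
        cfg = fl.PCMCIConfig(tau_max=5, q_max=0)
        survived = total = 0
        for seed in range(30):
            panel = fl.generate_null_panel(4, 400, seed)
            parents = fl.pc_condition_selection(panel, panel.variables[0], cfg)
            survived += len(parents)
            total += 4 * 5
        rate = survived / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 4 * se

    def test_chain_indirect_parent_removed_when_mediator_conditions(self):
        # X -> Y -> Z at lags 1, 1: (X, 2) is d-separated from Z given
        # (Y, 1), so the selection for Z keeps the mediator and drops
        # the indirect candidate at large T
        spec = fl.ScenarioSpec(
            variables={"X": "top-down", "Y": "bottom-up", "Z": "target"},
            links=[
                fl.PlantedLink("X", "Y", 1, 0.8),
                fl.PlantedLink("Y", "Z", 1, 0.8),
            ],
            n_weeks=5000,
            seed=42,
        )
        panel, _ = fl.generate_var_panel(spec)
        parents = fl.pc_condition_selection(panel, "Z", fl.PCMCIConfig(tau_max=4))
        pairs = [(v, l) for v, l, _ in parents]
        assert ("Y", 1) in pairs
        assert ("X", 2) not in pairs

    def test_empty_list_is_valid_outcome(self):
        panel = fl.generate_null_panel(3, 300, 99)
        cfg = fl.PCMCIConfig(tau_max=2, pc_alpha=1e-9)
        assert fl.pc_condition_selection(panel, "V0", cfg) == []


class TestMCI:
    def test_scale_invariance_of_rho_matrix(self):
        panel = fl.generate_null_panel(3, 400, 5)
        cfg = fl.PCMCIConfig(tau_max=3)
        parents = {
            v: [(w, l) for w, l, _ in fl.pc_condition_selection(panel, v, cfg)]
            for v in panel.variables
        }
        ds1 = fl.mci_test_all(panel, parents, cfg)
        scaled = panel.copy()
        scaled.data["V1"] = 7.0 * scaled.data["V1"] - 3.0
        ds2 = fl.mci_test_all(scaled, parents, cfg)
        d = np.abs(ds1["rho"].to_numpy() - ds2["rho"].to_numpy())
        assert np.nanmax(d) < 1e-10

    def test_planted_link_is_strongest_into_target(self):
        cfg = fl.PCMCIConfig(tau_max=5)
        hits = 0
        for seed in range(20):
            spec = fl.ScenarioSpec(
                variables={"BA": "target", "X": "top-down", "S": "bottom-up"},
                links=[fl.PlantedLink("X", "BA", 2, 0.6)],
                n_weeks=1000,
                seed=seed,
            )
            panel, _ = fl.generate_var_panel(spec)
            res = fl.run_pcmci(panel, cfg)
            rho = res.audit["rho"].sel(target="BA").to_numpy()
            src = list(res.audit["source"].to_numpy())
            i, tau = np.unravel_index(np.nanargmax(np.abs(rho)), rho.shape)
            hits += (src[i], int(tau)) == ("X", 2)
        assert hits >= 19


class TestRunPCMCI:
    def test_two_link_recovery_with_signs(self):
        cfg = fl.PCMCIConfig(tau_max=70)
        recovered = 0
        for seed in range(10):
            spec = fl.ScenarioSpec(
                variables=dict(fl.STANDARD_VARIABLES),
                links=[
                    fl.PlantedLink("ET0", "BA", 1, 0.7),
                    fl.PlantedLink("SWDI", "BA", 60, 0.4),
                ],
                n_weeks=936,
                seed=seed,
                tau_max=70,
            )
            panel, _ = fl.generate_var_panel(spec)
            res = fl.run_pcmci(panel, cfg)
            links = {
                (r.source, r.target, r.lag): r.rho
                for r in res.links.itertuples()
            }
            got_both = ("ET0", "BA", 1) in links and ("SWDI", "BA", 60) in links
            signs_ok = got_both and links[("ET0", "BA", 1)] > 0 and links[
                ("SWDI", "BA", 60)
            ] > 0
            recovered += got_both and signs_ok
        assert recovered >= 9  # >= 90% of seeds

    def test_null_retained_count_near_alpha_rate(self):
        cfg = fl.PCMCIConfig(tau_max=4)
        n_links = n_tests = 0
        for seed in range(30):
            panel = fl.generate_null_panel(4, 400, seed)
            res = fl.run_pcmci(panel, cfg)
            n_links += len(res.links)
            n_tests += np.isfinite(res.audit["pvalue"].to_numpy()).sum()
        rate = n_links / n_tests
        # retained links exclude some lag-0 entries, so the rate is
        # bounded by ~alpha plus sampling error
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_tests)
        assert rate > 0.01

    def test_degenerate_lag0_two_series(self):
        # tau_max = 0 on two independent series: empty graph w.p. ~ 1 - alpha
        empties = 0
        for seed in range(40):
            panel = fl.generate_null_panel(2, 200, seed)
            res = fl.run_pcmci(panel, fl.PCMCIConfig(tau_max=0, tau_min=0))
            empties += len(res.links) == 0
        assert empties >= 0.95 * 40 * (1 - 0.05) - 5  # loose binomial bound

    def test_determinism_no_internal_randomness(self):
        panel = fl.generate_null_panel(4, 300, 3)
        cfg = fl.PCMCIConfig(tau_max=3)
        r1 = fl.run_pcmci(panel, cfg)
        r2 = fl.run_pcmci(panel, cfg)
        assert r1.links.equals(r2.links)
        assert np.array_equal(
            r1.audit["rho"].to_numpy(), r2.audit["rho"].to_numpy(), equal_nan=True
        )

    def test_retained_links_appear_in_audit_matrices(self):
        spec = fl.ScenarioSpec(
            variables={"BA": "target", "X": "top-down", "S": "bottom-up"},
            links=[fl.PlantedLink("X", "BA", 2, 0.6)],
            n_weeks=800,
            seed=4,
        )
        panel, _ = fl.generate_var_panel(spec)
        res = fl.run_pcmci(panel, fl.PCMCIConfig(tau_max=4))
        for r in res.links.itertuples():
            assert res.audit["rho"].sel(
                source=r.source, target=r.target, lag=r.lag
            ) == r.rho
            assert r.pvalue <= res.config.alpha

    def test_lag0_orientation_rules(self):
        # a strong contemporaneous precursor-target association is kept
        # as precursor -> target only; target -> precursor at lag 0 and
        # precursor-precursor lag 0 links never appear
        spec = fl.ScenarioSpec(
            variables={"BA": "target", "X": "top-down", "S": "bottom-up"},
            links=[
                fl.PlantedLink("X", "BA", 0, 0.7),
                fl.PlantedLink("X", "S", 0, 0.7),
            ],
            n_weeks=800,
            seed=8,
        )
        panel, _ = fl.generate_var_panel(spec)
        res = fl.run_pcmci(panel, fl.PCMCIConfig(tau_max=3))
        lag0 = res.links[res.links["lag"] == 0]
        assert set(lag0["target"]) <= {"BA"}
        assert ("X", "BA", 0) in {
            (r.source, r.target, r.lag) for r in lag0.itertuples()
        }

    def test_model_from_dataframe_and_summary(self, rng):
        df = pd.DataFrame(rng.normal(size=(300, 3)), columns=["BA", "X", "S"])
        model = fl.LaggedCausalModel.from_dataframe(
            df, target="BA", config=fl.PCMCIConfig(tau_max=2)
        )
        res = model.fit()
        text = res.summary()
        assert "tau=[0, 2]" in text and "Retained links" in text

    def test_config_validation(self):
        with pytest.raises(ValueError):
            fl.PCMCIConfig(alpha=0.0)
        with pytest.raises(ValueError):
            fl.PCMCIConfig(tau_min=5, tau_max=3)

    def test_graph_json_roundtrip(self, tmp_path):
        panel = fl.generate_null_panel(3, 300, 2)
        res = fl.run_pcmci(panel, fl.PCMCIConfig(tau_max=2))
        path = tmp_path / "graph.json"
        res.to_json(path)
        import json

        edges = json.loads(path.read_text())
        assert len(edges) == len(res.links)
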