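import numpy as np
import pandas as pd
import pytest

from dielact import regression as rg
from dielact.synthetic_data import GeneratorConfig, generate_covariates, target_responses

FAST = rg.SamplerSettings(n_steps=1500, n_burn=700, min_walkers=60)


def make_records(seed, level_coefficients=None, pattern_coefficients=None,
                 phi_level=100.0, n_per_region=16, **kw):
    cfg = GeneratorConfig(seed=seed, landscapes_per_region=n_per_region,
                          phi_level=phi_level, **kw)
    if level_coefficients is not None:
        cfg.level_coefficients = level_coefficients
    if pattern_coefficients is not None:
        cfg.pattern_coefficients = pattern_coefficients
    rng = np.random.default_rng(seed)
    rec = target_responses(generate_covariates(cfg, rng), cfg, rng)
    rec["n_detections"] = 500
    return rg.standardize_predictors(rec)


class TestFilterLandscapes:
    def test_threshold_boundary(self):
        df = pd.DataFrame({"n_detections": [99, 100, 350], "level": [0.4] * 3})
        kept = rg.filter_landscapes(df)
        assert list(kept["n_detections"]) == [100, 350]

    def test_empty_result_rejected(self):
        df = pd.DataFrame({"n_detections": [5, 20]})
        with pytest.raises(ValueError):
            rg.filter_landscapes(df)


class TestCandidateSets:
    def test_level_set_structure(self):
        models = rg.level_candidate_set()
        assert len(models) == 6
        names = {m.name for m in models}
        assert names == {"buildings", "roads", "twigs", "agriculture",
                         "twigs*agriculture", "deer_density"}

    def test_pattern_set_structure(self):
        models = rg.pattern_candidate_set()
        assert len(models) == 3
        interaction = [m for m in models if "twigs:agriculture" in m.terms]
        assert len(interaction) == 1
        assert set(interaction[0].terms) == {"twigs", "agriculture",
                                             "twigs:agriculture"}


def test_design_matrix_interaction_is_product():
    df = pd.DataFrame({"twigs": [1.0, -1.0], "agriculture": [2.0, 3.0]})
    X, names = rg.design_matrix(df, ("twigs", "agriculture", "twigs:agriculture"))
    assert names == ["intercept", "twigs", "agriculture", "twigs:agriculture"]
    np.testing.assert_allclose(X[:, 3], [2.0, -3.0])


class TestBetaModel:
    def test_parameter_recovery(self):
        rec = make_records(21, level_coefficients={"intercept": -0.3,
                                                   "buildings": 0.5},
                           n_per_region=34)  # ~100 rows
        fit = rg.fit_beta_model(rec, rg.CandidateModel("level", ("buildings",)),
                                settings=FAST, seed=5)
        slope = fit.coefficients.set_index("term").loc["buildings", "estimate"]
        assert slope == pytest.approx(0.5, abs=0.15)

    def test_seeded_determinism(self):
        rec = make_records(22)
        m = rg.CandidateModel("level", ("roads",))
        a = rg.fit_beta_model(rec, m, settings=FAST, seed=9)
        b = rg.fit_beta_model(rec, m, settings=FAST, seed=9)
        pd.testing.assert_frame_equal(a.coefficients, b.coefficients)

    def test_null_slopes_cover_zero(self):
        # With all true slopes at zero, 89% intervals should rarely
        # exclude zero.
        covered = 0
        reps = 8
        for s in range(reps):
            rec = make_records(100 + s, level_coefficients={"intercept": -0.3})
            fit = rg.fit_beta_model(rec, rg.CandidateModel("level", ("twigs",)),
                                    settings=FAST, seed=s)
            row = fit.coefficients.set_index("term").loc["twigs"]
            covered += bool(row["lci"] <= 0 <= row["uci"])
        assert covered >= reps - 2

    def test_levels_outside_unit_interval_rejected(self):
        rec = make_records(23)
        rec.loc[0, "level"] = 1.0
        with pytest.raises(ValueError):
            rg.fit_beta_model(rec, rg.CandidateModel("level", ("twigs",)),
                              settings=FAST, seed=1)


class TestDirichletModel:
    def test_null_fit_matches_empirical_mean(self):
        coefs = {k: {"intercept": v} for k, v in
                 (("morning", -0.4), ("daytime", -0.2), ("evening", -0.4))}
        rec = make_records(31, pattern_coefficients=coefs, n_per_region=34)
        fit = rg.fit_dirichlet_model(rec, rg.CandidateModel("pattern", ("twigs",)),
                                     settings=FAST, seed=3)
        # Posterior intercepts reproduce the empirical mean composition.
        emp = rec[list(rg.CATEGORY_ORDER)].mean().to_numpy()
        b0 = fit.coefficients[fit.coefficients.term == "intercept"]
        eta = np.concatenate([[0.0], b0["estimate"].to_numpy()])
        pred = np.exp(eta) / np.exp(eta).sum()
        np.testing.assert_allclose(pred, emp, atol=0.03)

    def test_interaction_recovery(self):
        rec = make_records(32, n_per_region=34)
        m = rg.CandidateModel("pattern", ("twigs", "agriculture",
                                          "twigs:agriculture"))
        fit = rg.fit_dirichlet_model(rec, m, settings=FAST, seed=4)
        cc = fit.coefficients.set_index(["category", "term"])
        assert cc.loc[("morning", "twigs:agriculture"), "estimate"] == pytest.approx(
            -0.32, abs=0.12)
        assert cc.loc[("daytime", "twigs:agriculture"), "estimate"] == pytest.approx(
            -0.31, abs=0.12)

    def test_zero_composition_component_rejected(self):
        rec = make_records(33)
        rec.loc[0, "night"] = 0.0
        with pytest.raises(ValueError, match="zero"):
            rg.fit_dirichlet_model(rec, rg.CandidateModel("pattern", ("twigs",)),
                                   settings=FAST, seed=1)


class TestModelComparison:
    def test_true_model_dominates_noise(self):
        rec = make_records(41, level_coefficients={"intercept": -0.3,
                                                   "buildings": 0.8},
                           n_per_region=34)
        fits = [
            rg.fit_beta_model(rec, rg.CandidateModel("level", ("buildings",)),
                              settings=FAST, seed=11),
            rg.fit_beta_model(rec, rg.CandidateModel("level", ("deer_density",)),
                              settings=FAST, seed=12),
        ]
        w = rg.loo_weights(fits)
        assert w.sum() == pytest.approx(1.0, abs=1e-6)
        assert w[0] > 0.8
        assert fits[0].evidence_ratio == pytest.approx(1.0)
        assert fits[1].evidence_ratio > 3

    def test_evidence_ratio_published_values(self):
        ratios = rg.evidence_ratios([0.362, 0.243])
        assert ratios[1] == pytest.approx(1.49, abs=0.01)
        ratios = rg.evidence_ratios([0.930, 0.054])
        assert ratios[1] == pytest.approx(17.22, abs=0.01)

    def test_zero_weight_gives_infinite_ratio(self):
        ratios = rg.evidence_ratios([0.9, 0.1, 0.0])
        assert ratios[0] == pytest.approx(0.9 / 0.9)
        assert np.isinf(ratios[2])


def test_credible_interval_mass_by_draw_counting():
    rec = make_records(51)
    fit = rg.fit_beta_model(rec, rg.CandidateModel("level", ("agriculture",)),
                            settings=FAST, seed=6)
    ci = rg.credible_intervals(fit, mass=0.89)
    draws = fit.idata.posterior["b"].values.reshape(-1, 2)
    for j, row in ci.iterrows():
        inside = np.mean((draws[:, j] >= row["lci"]) & (draws[:, j] <= row["uci"]))
        assert inside == pytest.approx(0.89, abs=0.01)
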