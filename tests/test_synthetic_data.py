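import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dielact import pipeline
from dielact.pattern import CATEGORY_ORDER, category_bounds
from dielact.solar_time import TWO_PI
from dielact.synthetic_data import (
    GeneratorConfig,
    _sample_from_density,
    build_density,
    generate_covariates,
    generate_dataset,
    target_responses,
)


class TestGenerateCovariates:
    def test_seeded_reproducibility(self):
        cfg = GeneratorConfig(seed=5)
        a = generate_covariates(cfg, np.random.default_rng(5))
        b = generate_covariates(cfg, np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)

    def test_study_design_counts(self):
        cfg = GeneratorConfig(seed=1, n_regions=3, landscapes_per_region=16)
        df = generate_covariates(cfg, np.random.default_rng(1))
        assert len(df) == 48
        assert df["region_id"].nunique() == 3

    def test_agriculture_spans_reported_gradient(self):
        cfg = GeneratorConfig(seed=2)
        df = generate_covariates(cfg, np.random.default_rng(2))
        # The agricultural gradient brackets 0.13-0.72 km^2 (the -1 SD,
        # mean, +1 SD settings of the study area).
        assert df["agriculture"].min() < 0.13
        assert df["agriculture"].max() > 0.72

    def test_invalid_parameters_rejected(self):
        cfg = GeneratorConfig(seed=1, twigs_shape=-1.0)
        with pytest.raises(ValueError):
            generate_covariates(cfg, np.random.default_rng(1))


class TestTargetResponses:
    def test_null_slopes_scatter_around_intercept(self):
        cfg = GeneratorConfig(seed=3, level_coefficients={"intercept": -0.3})
        rng = np.random.default_rng(3)
        rec = target_responses(generate_covariates(cfg, rng), cfg, rng)
        expected = 1 / (1 + np.exp(0.3))
        assert rec["level"].mean() == pytest.approx(expected, abs=0.05)

    def test_interaction_sign_via_softmax(self):
        # Strong negative morning twigs x agriculture: at high
        # agriculture, more twigs must lower the morning share.
        cfg = GeneratorConfig(seed=4, phi_pattern=1e6, region_sd=0.0)
        cfg.pattern_coefficients = {
            "morning": {"intercept": 0.0, "twigs:agriculture": -1.0},
            "daytime": {"intercept": 0.0},
            "evening": {"intercept": 0.0},
        }
        rng = np.random.default_rng(4)
        rec = target_responses(generate_covariates(cfg, rng), cfg, rng)
        z = rec.copy()
        for c in ("twigs", "agriculture"):
            z[c] = (rec[c] - rec[c].mean()) / rec[c].std(ddof=1)
        high_ag = z[z["agriculture"] > 0.5]
        corr = np.corrcoef(high_ag["twigs"], high_ag["morning"])[0, 1]
        assert corr < 0

    def test_compositions_strictly_positive(self):
        cfg = GeneratorConfig(seed=5)
        rng = np.random.default_rng(5)
        rec = target_responses(generate_covariates(cfg, rng), cfg, rng)
        assert (rec[list(CATEGORY_ORDER)] > 0).all().all()
        np.testing.assert_allclose(rec[list(CATEGORY_ORDER)].sum(axis=1), 1.0)


class TestBuildDensity:
    def test_realized_matches_moderate_target(self, anchors_6_18):
        target = np.array([0.40, 0.18, 0.24, 0.18])
        dens, level, comp = build_density(target, 0.45, anchors_6_18)
        np.testing.assert_allclose(comp, target, atol=0.01)
        assert abs(dens.integral - 1.0) < 1e-3
        assert level == pytest.approx(0.45, abs=0.02)

    def test_night_concentration_puts_peak_in_night(self, anchors_6_18):
        target = np.array([0.7, 0.1, 0.1, 0.1])
        dens, _, _ = build_density(target, 0.3, anchors_6_18)
        night = category_bounds(anchors_6_18)[0]
        peak = dens.grid[np.argmax(dens.values)]
        assert night.contains(peak)

    def test_invalid_targets_rejected(self, anchors_6_18):
        with pytest.raises(ValueError):
            build_density(np.array([0.5, 0.5, 0.2, -0.2]), 0.4, anchors_6_18)
        with pytest.raises(ValueError):
            build_density(np.array([0.25] * 4), 1.5, anchors_6_18)


class TestSimulateDetections:
    def test_seeded_reproducibility(self):
        cfg = GeneratorConfig(seed=7, landscapes_per_region=1,
                              cameras_per_landscape=5)
        a = generate_dataset(cfg).detections
        b = generate_dataset(cfg).detections
        pd.testing.assert_frame_equal(a, b)

    def test_sampling_matches_density(self, anchors_6_18, rng):
        dens, _, _ = build_density(np.array([0.4, 0.2, 0.2, 0.2]), 0.45,
                                   anchors_6_18)
        x = _sample_from_density(dens, 50_000, rng)
        edges = np.linspace(0, TWO_PI, 37)
        observed, _ = np.histogram(x, bins=edges)
        centers = (edges[:-1] + edges[1:]) / 2
        expected = dens(centers)
        expected = expected / expected.sum() * observed.sum()
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01

    def test_mean_detections_per_camera(self):
        cfg = GeneratorConfig(seed=8, landscapes_per_region=4,
                              cameras_per_landscape=20, detections_mean=25.0)
        ds = generate_dataset(cfg)
        per_cam = len(ds.detections) / (12 * 20)
        assert per_cam == pytest.approx(25.0, rel=0.15)

    def test_burst_mode_triplicates_rows(self):
        cfg = GeneratorConfig(seed=9, landscapes_per_region=1,
                              cameras_per_landscape=4, simulate_bursts=True)
        ds = generate_dataset(cfg)
        assert len(ds.detections) % 3 == 0


def test_end_to_end_estimator_recovery():
    """Pipeline estimates recover the realized per-landscape truth.

    All 48 landscapes of the full design at ~750 detections each. The
    generator emits independent encounters here, so the burst
    de-duplication window is disabled; with it on, peak-hour encounters
    are thinned preferentially and levels inflate.
    """
    cfg = GeneratorConfig(seed=77, detections_mean=35.0)
    ds = generate_dataset(cfg)
    assert (ds.covariates["n_detections"] >= 300).all()
    cov = ds.covariates.drop(columns=["level", *CATEGORY_ORDER])
    run_cfg = pipeline.RunConfig(n_boot=50, seed=1, dedup_window_min=0.0)
    recs = pipeline.estimate_landscape_records(ds.detections, cov, run_cfg)
    m = recs.merge(ds.ground_truth, on="landscape_id", suffixes=("", "_truth"))
    assert len(m) == 48
    level_mae = np.abs(m["level"] - m["level_truth"]).mean()
    assert level_mae < 0.05
    for c in CATEGORY_ORDER:
        assert np.abs(m[c] - m[f"{c}_truth"]).mean() < 0.03
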