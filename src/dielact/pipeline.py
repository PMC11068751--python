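"""Config-driven orchestration of the two analyses.

``run_regional`` pools detections per region: anchored circular KDE,
bootstrap activity level, time-of-day composition, and the three Holm
families of Wald comparisons (levels between regions; each fraction
between regions; fractions between categories within each region).

``run_landscape`` estimates level and composition per replicate
landscape, drops landscapes with fewer than ``min_detections``
detections, joins the covariate table, standardizes predictors, fits
the six beta and three Dirichlet candidate models, and reports PSIS-LOO
stacking weights, evidence ratios, and 89% credible intervals.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dielact import activity_kde, comparison_tests, pattern, regression, solar_time
from dielact.pattern import CATEGORY_ORDER
from dielact.solar_time import TWO_PI, SolarAnchors, SolarDay

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline settings; defaults follow standard practice for this analysis."""

    detections: str = "detections.csv"
    covariates: str = "covariates.csv"
    output_dir: str = "results"
    anchoring_scope: str = "region"  # region | landscape | global
    bandwidth_adjust: float = 1.5
    n_boot: int = 1000
    ci: float = 0.95
    min_detections: int = 100
    dedup_window_min: float = 15.0
    utc_offset: float = -5.0
    interval_mass: float = 0.89
    weight_scheme: str = "stacking"
    sampler: regression.SamplerSettings = field(default_factory=regression.SamplerSettings)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sampler = regression.SamplerSettings(**raw.pop("sampler", {}))
        cfg = cls(**raw, sampler=sampler)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_detections(path) -> pd.DataFrame:
    """Read a detection-event CSV and attach circular times and sun times.

    Expected columns: camera_id, landscape_id, region_id, date
    (ISO-8601), time (HH:MM:SS), lat, lon; optional sunrise/sunset
    columns (radians) bypass the solar computation.
    """
    df = pd.read_csv(path, dtype={"camera_id": str, "landscape_id": str,
                                  "region_id": str})
    required = {"camera_id", "landscape_id", "region_id", "date", "time"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"detection table missing columns {sorted(missing)}")
    return df


def _clock_radians(time_strings: pd.Series) -> np.ndarray:
    td = pd.to_timedelta(time_strings)
    return (td.dt.total_seconds().to_numpy() / 86400.0 * TWO_PI) % TWO_PI


def attach_sun_times(df: pd.DataFrame, utc_offset: float) -> pd.DataFrame:
    """Ensure sunrise/sunset columns (radians), computing them if absent."""
    if {"sunrise", "sunset"}.issubset(df.columns):
        return df
    if not {"lat", "lon"}.issubset(df.columns):
        raise ValueError("need either sunrise/sunset or lat/lon columns")
    out = df.copy()
    keys = out[["lat", "lon", "date"]].drop_duplicates()
    sun = {}
    for lat, lon, date in keys.itertuples(index=False):
        day = solar_time.solar_events(lat, lon, _dt.date.fromisoformat(str(date)),
                                      utc_offset)
        sun[(lat, lon, date)] = (day.sunrise, day.sunset)
    vals = out.apply(lambda r: sun[(r["lat"], r["lon"], r["date"])], axis=1)
    out["sunrise"] = [v[0] for v in vals]
    out["sunset"] = [v[1] for v in vals]
    return out


def deduplicate_encounters(df: pd.DataFrame, window_min: float = 15.0) -> pd.DataFrame:
    """Collapse photo bursts: one encounter per camera per rolling window.

    Rows within ``window_min`` minutes of the previous *kept* row of the
    same camera are treated as the same encounter and dropped.
    """
    if window_min <= 0:
        return df
    dt = pd.to_datetime(df["date"].astype(str) + " " + df["time"].astype(str))
    out = df.assign(_dt=dt).sort_values(["camera_id", "_dt"], kind="stable")
    keep = np.ones(len(out), dtype=bool)
    window = pd.Timedelta(minutes=window_min)
    for _, idx in out.groupby("camera_id").indices.items():
        last_kept = None
        times = out["_dt"].to_numpy()[idx]
        for pos, t in zip(idx, times):
            if last_kept is not None and t - last_kept < window:
                keep[pos] = False
            else:
                last_kept = t
    kept = out.loc[keep].drop(columns="_dt").sort_index()
    if len(kept) < len(df):
        logger.info("deduplicate_encounters: %d of %d rows collapsed",
                    len(df) - len(kept), len(df))
    return kept


def anchor_detections(df: pd.DataFrame, scope: str = "region",
                      utc_offset: float = -5.0) -> tuple[pd.DataFrame, dict]:
    """Double-anchor every detection within its anchoring unit.

    Returns the table with an ``anchored`` column plus the per-unit
    :class:`SolarAnchors` used (key ``"global"`` when scope is global).
    """
    df = attach_sun_times(df, utc_offset).reset_index(drop=True)
    df["clock"] = _clock_radians(df["time"])
    if scope == "global":
        df["_unit"] = "global"
    elif scope in ("region", "landscape"):
        df["_unit"] = df[f"{scope}_id"]
    else:
        raise ValueError(f"unknown anchoring scope {scope!r}")

    anchors_by_unit = {}
    anchored = np.empty(len(df))
    for unit, grp in df.groupby("_unit", sort=False):
        days = [
            SolarDay(_dt.date.fromisoformat(str(d)), sr, ss)
            for d, sr, ss in grp[["date", "sunrise", "sunset"]]
            .drop_duplicates().itertuples(index=False)
        ]
        anchors = solar_time.mean_anchors(days)
        anchors_by_unit[unit] = anchors
        # Anchor all rows sharing one camera-day's sun times at once.
        for (d, sr, ss), sub in grp.groupby(["date", "sunrise", "sunset"],
                                            sort=False):
            day = SolarDay(_dt.date.fromisoformat(str(d)), sr, ss)
            anchored[sub.index] = solar_time.double_anchor(
                sub["clock"].to_numpy(), day, anchors)
    df["anchored"] = anchored
    return df.drop(columns="_unit"), anchors_by_unit


def run_regional(detections: pd.DataFrame | str, config: RunConfig,
                 write: bool = True) -> dict:
    """Pooled per-region activity analysis with Wald/Holm comparisons."""
    if isinstance(detections, (str, Path)):
        detections = read_detections(detections)
    detections = deduplicate_encounters(detections, config.dedup_window_min)
    df, anchors_by_region = anchor_detections(detections, scope="region",
                                              utc_offset=config.utc_offset)
    rng = np.random.default_rng(config.seed)

    level_rows, comp_rows = [], []
    units_levels, units_fracs = [], []
    for region, grp in df.groupby("region_id", sort=True):
        if len(grp) < 2:
            logger.warning("region %s has < 2 detections; excluded", region)
            continue
        times = grp["anchored"].to_numpy()
        anchors = anchors_by_region[region]
        cats = pattern.category_bounds(anchors)
        lvl = activity_kde.bootstrap_level(
            times, n_boot=config.n_boot, seed=rng,
            bandwidth_adjust=config.bandwidth_adjust, ci=config.ci)
        comp = pattern.bootstrap_composition(
            times, cats, n_boot=config.n_boot, seed=rng,
            bandwidth_adjust=config.bandwidth_adjust, ci=config.ci)
        level_rows.append({"region_id": region, "n_detections": len(grp),
                           "level": lvl.estimate, "se": lvl.se,
                           "ci_low": lvl.ci_low, "ci_high": lvl.ci_high})
        row = {"region_id": region, "n_detections": len(grp)}
        for c in CATEGORY_ORDER:
            row[c] = comp.fractions[c]
            row[f"{c}_se"] = comp.ses[c]
            row[f"{c}_ci_low"], row[f"{c}_ci_high"] = comp.cis[c]
        comp_rows.append(row)
        units_levels.append({"unit": region, "estimate": lvl.estimate, "se": lvl.se,
                             "family": "levels_between_regions"})
        for c in CATEGORY_ORDER:
            units_fracs.append({"unit": f"{region}:{c}", "estimate": comp.fractions[c],
                                "se": comp.ses[c], "region": region, "category": c})

    levels = pd.DataFrame(level_rows)
    comps = pd.DataFrame(comp_rows)

    comparisons = [comparison_tests.pairwise_comparisons(
        pd.DataFrame(units_levels), family_col="family")]
    fr = pd.DataFrame(units_fracs)
    if not fr.empty and fr["region"].nunique() >= 2:
        fr2 = fr.assign(family="fractions_between_regions")
        comparisons.append(comparison_tests.pairwise_comparisons(
            fr2, family_col="family", pair_col="category"))
        fr3 = fr.assign(family="fractions_between_categories")
        comparisons.append(comparison_tests.pairwise_comparisons(
            fr3, family_col="family", pair_col="region"))
    wald = pd.concat(comparisons, ignore_index=True)

    out = {"levels": levels, "composition": comps, "comparisons": wald,
           "anchors": anchors_by_region}
    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        levels.to_csv(outdir / "regional_levels.csv", index=False)
        comps.to_csv(outdir / "regional_composition.csv", index=False)
        wald.to_csv(outdir / "regional_comparisons.csv", index=False)
        dens_rows = []
        for region, grp in df.groupby("region_id", sort=True):
            if len(grp) < 2:
                continue
            dens = activity_kde.fit_circular_kde(
                grp["anchored"].to_numpy(),
                bandwidth_adjust=config.bandwidth_adjust)
            dens_rows.append(pd.DataFrame({
                "region_id": region, "radians": dens.grid,
                "density": dens.values}))
        pd.concat(dens_rows, ignore_index=True).to_csv(
            outdir / "regional_densities.csv", index=False)
    return out


def estimate_landscape_records(detections: pd.DataFrame, covariates: pd.DataFrame,
                               config: RunConfig) -> pd.DataFrame:
    """Per-landscape level and composition joined with the covariate table."""
    detections = deduplicate_encounters(detections, config.dedup_window_min)
    df, anchors_by_ls = anchor_detections(
        detections, scope="landscape" if config.anchoring_scope != "global" else "global",
        utc_offset=config.utc_offset)
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for ls, grp in df.groupby("landscape_id", sort=True):
        n = len(grp)
        if n < config.min_detections:
            rows.append({"landscape_id": ls, "n_detections": n})
            continue
        times = grp["anchored"].to_numpy()
        anchors = anchors_by_ls.get(ls, anchors_by_ls.get("global"))
        cats = pattern.category_bounds(anchors)
        dens = activity_kde.fit_circular_kde(times, bandwidth_adjust=config.bandwidth_adjust)
        lvl = activity_kde.activity_level(dens)
        comp = pattern.composition(dens, cats)
        row = {"landscape_id": ls, "n_detections": n, "level": lvl.estimate}
        row.update({c: comp.fractions[c] for c in CATEGORY_ORDER})
        rows.append(row)
    est = pd.DataFrame(rows)
    merged = covariates.merge(est, on="landscape_id", how="inner",
                              suffixes=("_true", ""))
    return merged


def run_landscape(detections: pd.DataFrame | str, covariates: pd.DataFrame | str,
                  config: RunConfig, write: bool = True) -> dict:
    """Replicate-landscape regressions: filter, fit, weight, summarize."""
    if isinstance(detections, (str, Path)):
        detections = read_detections(detections)
    if isinstance(covariates, (str, Path)):
        covariates = pd.read_csv(covariates, dtype={"landscape_id": str,
                                                    "region_id": str})
    records = estimate_landscape_records(detections, covariates, config)
    n_input = len(records)
    records = regression.filter_landscapes(records.dropna(subset=["level"]),
                                           config.min_detections)
    logger.info("landscape filter: %d of %d units retained", len(records), n_input)
    records = regression.standardize_predictors(records)

    level_fits, pattern_fits = [], []
    for i, m in enumerate(regression.level_candidate_set()):
        level_fits.append(regression.fit_beta_model(
            records, m, settings=config.sampler, seed=config.seed + 100 + i,
            interval_mass=config.interval_mass))
    for i, m in enumerate(regression.pattern_candidate_set()):
        pattern_fits.append(regression.fit_dirichlet_model(
            records, m, settings=config.sampler, seed=config.seed + 200 + i,
            interval_mass=config.interval_mass))
    regression.loo_weights(level_fits, method=config.weight_scheme)
    regression.loo_weights(pattern_fits, method=config.weight_scheme)

    cmp_rows = []
    for f in level_fits + pattern_fits:
        cmp_rows.append({"response": f.model.response, "hypothesis": f.model.hypothesis,
                         "predictor": f.model.name, "elpd_loo": f.elpd,
                         "weight": f.weight, "evidence_ratio": f.evidence_ratio,
                         "supported": f.evidence_ratio < 3, "converged": f.converged,
                         "rhat_max": f.rhat_max})
    model_table = pd.DataFrame(cmp_rows)

    coef_level = pd.concat(
        [f.coefficients.assign(model=f.model.name) for f in level_fits],
        ignore_index=True)
    coef_pattern = pd.concat(
        [f.coefficients.assign(model=f.model.name) for f in pattern_fits],
        ignore_index=True)

    out = {"records": records, "models": model_table,
           "coefficients_level": coef_level, "coefficients_pattern": coef_pattern,
           "level_fits": level_fits, "pattern_fits": pattern_fits}
    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        records.to_csv(outdir / "landscape_records.csv", index=False)
        model_table.to_csv(outdir / "model_comparison.csv", index=False)
        coef_level.to_csv(outdir / "coefficients_level.csv", index=False)
        coef_pattern.to_csv(outdir / "coefficients_pattern.csv", index=False)
    return out
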