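"""Synthetic camera-trap datasets with known ground truth.

The generator emulates the study design the pipeline targets: replicate
~10-km^2 landscapes nested in a few regions, each holding a grid of
cameras that accumulate deer detections over a two-week winter window.
Landscape covariates (buildings, road length, non-avoided twig density,
agricultural area, deer density) are drawn from plausible right-skewed
laws; each landscape's activity level and four-part diel composition
are then drawn from the same beta/Dirichlet regression structure the
inference module fits, so true coefficients are known.

Detection times are produced in two steps. A smooth circular density
matching the landscape's target composition and level is built as a
four-component von Mises mixture centred on the category midpoints
(weights solved from a linear system; the shared concentration tuned by
bisection so the ratio-to-peak level matches the target). Anchored
times are drawn from that density by inverse-CDF sampling and converted
to clock times by inverting the double-anchoring map for each
camera-day's jittered sunrise/sunset. Ground truth is the *realized*
density's level and composition (dense-grid evaluation), so estimator
tests are insulated from any generator imperfection.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dielact.activity_kde import ActivityDensity, _peak_value, circular_integral
from dielact.pattern import CATEGORY_ORDER, category_bounds, composition
from dielact.solar_time import (
    TWO_PI,
    SolarAnchors,
    SolarDay,
    hours_to_radians,
    inverse_double_anchor,
)

DENSE_GRID = 4096


def _default_level_coefficients() -> dict:
    # Logit scale; intercept gives a mean level near 0.42.
    return {"intercept": -0.32, "buildings": 0.12}


def _default_pattern_coefficients() -> dict:
    # Softmax scale, night as reference; interaction structure of a
    # crepuscular population trading night/evening activity against
    # twig density depending on agricultural land.
    return {
        "morning": {"intercept": -0.45, "twigs": 0.05, "agriculture": 0.07,
                    "twigs:agriculture": -0.32},
        "daytime": {"intercept": -0.25, "twigs": -0.07, "agriculture": 0.19,
                    "twigs:agriculture": -0.31},
        "evening": {"intercept": -0.35, "twigs": -0.01, "agriculture": 0.11,
                    "twigs:agriculture": -0.09},
    }


@dataclass
class GeneratorConfig:
    """Study-design and ground-truth settings for the generator."""

    n_regions: int = 3
    landscapes_per_region: int = 16
    cameras_per_landscape: int = 21
    detections_mean: float = 26.0  # per camera; ~540 per landscape
    detections_dispersion: float = 1.5  # negative-binomial size
    # Covariate laws (landscape scale).
    buildings_logmean: float = 5.0
    buildings_logsd: float = 0.7
    roads_logmean: float = 2.7
    roads_logsd: float = 0.5
    twigs_shape: float = 2.0
    twigs_scale: float = 1.5
    agriculture_low: float = 0.05  # km^2; spans ~0.13-0.72
    agriculture_high: float = 0.80
    deer_logmean: float = 2.0
    deer_logsd: float = 0.75
    # True regression structure.
    level_coefficients: dict = field(default_factory=_default_level_coefficients)
    pattern_coefficients: dict = field(default_factory=_default_pattern_coefficients)
    region_sd: float = 0.10
    phi_level: float = 200.0
    phi_pattern: float = 150.0
    # Diel-density shape and solar geometry.
    kappa_shape: float = 3.0
    anchor_sunrise_h: float = 6.0
    anchor_sunset_h: float = 18.0
    site_jitter_min: float = 20.0  # +/- minutes of camera-site sun-time jitter
    start_date: _dt.date = _dt.date(2021, 2, 25)
    n_days: int = 14
    latitude: float = 40.0
    longitude: float = -86.5
    simulate_bursts: bool = False
    seed: int = 0

    def anchors(self) -> SolarAnchors:
        return SolarAnchors(
            mean_sunrise=float(hours_to_radians(self.anchor_sunrise_h)),
            mean_sunset=float(hours_to_radians(self.anchor_sunset_h)),
        )


@dataclass
class SyntheticDataset:
    """Everything the pipeline reads, plus the generating truth."""

    detections: pd.DataFrame
    covariates: pd.DataFrame  # per-landscape records incl. responses + n_detections
    ground_truth: pd.DataFrame  # per-landscape realized level/composition
    true_coefficients: dict
    anchors: SolarAnchors
    densities: dict  # landscape_id -> ActivityDensity (dense grid)


def generate_covariates(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Landscape covariate table (no responses yet), regions nested."""
    for name in ("buildings_logsd", "roads_logsd", "twigs_shape", "twigs_scale",
                 "deer_logsd", "detections_mean", "detections_dispersion"):
        if getattr(config, name) <= 0:
            raise ValueError(f"config.{name} must be positive")
    n = config.n_regions * config.landscapes_per_region
    rows = []
    for r in range(config.n_regions):
        for j in range(config.landscapes_per_region):
            rows.append({
                "landscape_id": f"L{r + 1}_{j + 1:02d}",
                "region_id": f"R{r + 1}",
                "buildings": float(np.round(rng.lognormal(config.buildings_logmean,
                                                          config.buildings_logsd))),
                "roads": float(rng.lognormal(config.roads_logmean, config.roads_logsd)),
                "twigs": float(rng.gamma(config.twigs_shape, config.twigs_scale)),
                "agriculture": float(rng.uniform(config.agriculture_low,
                                                 config.agriculture_high)),
                "deer_density": float(rng.lognormal(config.deer_logmean,
                                                    config.deer_logsd)),
            })
    assert len(rows) == n
    return pd.DataFrame(rows)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def target_responses(
    records: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-landscape level and composition from the true models."""
    out = records.copy()
    z = {c: _zscore(records[c].to_numpy(float))
         for c in ("buildings", "roads", "twigs", "agriculture", "deer_density")}
    z["twigs:agriculture"] = z["twigs"] * z["agriculture"]

    regions = list(pd.unique(records["region_id"]))
    u_level = rng.normal(0.0, config.region_sd, size=len(regions))
    u_pattern = rng.normal(0.0, config.region_sd, size=(3, len(regions)))
    ridx = records["region_id"].map({r: i for i, r in enumerate(regions)}).to_numpy()

    eta = np.full(len(records), config.level_coefficients.get("intercept", 0.0))
    for term, beta in config.level_coefficients.items():
        if term != "intercept":
            eta += beta * z[term]
    eta += u_level[ridx]
    mu = 1.0 / (1.0 + np.exp(-eta))
    a = mu * config.phi_level
    b = (1.0 - mu) * config.phi_level
    out["level"] = np.clip(rng.beta(a, b), 1e-4, 1.0 - 1e-4)

    eta_k = np.zeros((len(records), 4))  # night, morning, daytime, evening
    for k, cat in enumerate(("morning", "daytime", "evening"), start=1):
        coefs = config.pattern_coefficients[cat]
        e = np.full(len(records), coefs.get("intercept", 0.0))
        for term, beta in coefs.items():
            if term != "intercept":
                e += beta * z[term]
        eta_k[:, k] = e + u_pattern[k - 1, ridx]
    ex = np.exp(eta_k - eta_k.max(axis=1, keepdims=True))
    mu_comp = ex / ex.sum(axis=1, keepdims=True)
    comp = np.vstack([rng.dirichlet(m * config.phi_pattern) for m in mu_comp])
    comp = np.clip(comp, 1e-4, None)
    comp /= comp.sum(axis=1, keepdims=True)
    out[list(CATEGORY_ORDER)] = comp
    return out


def _vm_mixture(grid, centers, kappas, weights):
    from scipy.special import i0e

    d = grid[:, None] - centers[None, :]
    kappas = np.broadcast_to(np.asarray(kappas, float), centers.shape)
    kern = np.exp(kappas * (np.cos(d) - 1.0)) / (TWO_PI * i0e(kappas))
    return kern @ weights


def build_density(
    target_composition,
    target_level: float,
    anchors: SolarAnchors,
    kappa_shape: float = 3.0,
    grid_size: int = DENSE_GRID,
) -> tuple[ActivityDensity, float, np.ndarray]:
    """Circular density matching a target composition and level.

    A four-component von Mises mixture centred on the category midpoints;
    component weights solve the 4x4 linear system equating category
    integrals to the target composition, and the shared concentration is
    tuned by bisection so the realized ratio-to-peak level approaches
    ``target_level``. Returns (density, realized_level,
    realized_composition); the realized values are the ground truth.
    """
    target = np.asarray(target_composition, dtype=float)
    if target.shape != (4,) or np.any(target <= 0) or abs(target.sum() - 1) > 1e-6:
        raise ValueError("target composition must be 4 positive fractions summing to 1")
    if not 0.0 < target_level <= 1.0:
        raise ValueError("target level must be in (0, 1]")
    cats = category_bounds(anchors)  # night, morning, daytime, evening
    centers = np.array([(c.t1 + c.length / 2.0) % TWO_PI for c in cats])
    # Component widths scale with arc length: the crepuscular morning and
    # evening peaks are sharp, night/daytime activity is diffuse. This
    # also keeps the mixture away from exact 4-fold symmetry, which no
    # real diel density has.
    lengths = np.array([c.length for c in cats])
    kappa_scale = lengths.min() / lengths
    grid = np.linspace(0.0, TWO_PI, grid_size, endpoint=False)

    def attempt(kappa):
        """Solve weights at this concentration; None if infeasible."""
        kappas = kappa * kappa_scale
        M = np.empty((4, 4))
        for k, cat in enumerate(cats):
            npts = max(64, int(round(grid_size * cat.length / TWO_PI)))
            x = cat.t1 + np.linspace(0.0, cat.length, npts)
            for l in range(4):
                M[k, l] = np.trapezoid(_vm_mixture(x, centers[l : l + 1],
                                                   kappas[l : l + 1],
                                                   np.ones(1)), x)
        try:
            w = np.linalg.solve(M, target)
        except np.linalg.LinAlgError:
            return None
        if np.any(w <= 0):
            return None
        w = w / w.sum()
        values = _vm_mixture(grid, centers, kappas, w)
        values = values / circular_integral(grid, values)
        level = 1.0 / (TWO_PI * _peak_value(values))
        return w, values, level

    # Level decreases as the mixture sharpens; scan for a bracketing pair.
    kappas = np.geomspace(max(kappa_shape / 8.0, 0.4), kappa_shape * 8.0, 25)
    results = [(k, attempt(k)) for k in kappas]
    feasible = [(k, r) for k, r in results if r is not None]
    if not feasible:
        raise ValueError(
            "no feasible von Mises mixture for this composition; "
            "try a different kappa_shape range"
        )
    lo = hi = None
    for (k1, r1), (k2, r2) in zip(feasible[:-1], feasible[1:]):
        if (r1[2] - target_level) * (r2[2] - target_level) <= 0:
            lo, hi = k1, k2
            break
    if lo is None:
        # Target unreachable within the feasible range: take the closest.
        k_best, r_best = min(feasible, key=lambda kr: abs(kr[1][2] - target_level))
    else:
        f_lo = attempt(lo)[2] - target_level
        for _ in range(40):
            mid = math.sqrt(lo * hi)
            r = attempt(mid)
            if r is None:
                hi = mid
                continue
            if (r[2] - target_level) * f_lo <= 0:
                hi = mid
            else:
                lo, f_lo = mid, r[2] - target_level
        k_best = math.sqrt(lo * hi)
        r_best = attempt(k_best) or attempt(lo)
    w, values, realized_level = r_best
    density = ActivityDensity(grid=grid, values=values, bandwidth=float(k_best), n=1)
    realized_comp = composition(density, cats, n_refine=8 * grid_size).as_array()
    return density, float(realized_level), realized_comp


def _sample_from_density(density: ActivityDensity, size: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws from a gridded circular density."""
    g = np.append(density.grid, TWO_PI)
    v = np.append(density.values, density.values[0])
    cdf = np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) / 2.0 * np.diff(g))])
    cdf /= cdf[-1]
    return np.interp(rng.random(size), cdf, g) % TWO_PI


def simulate_detections(
    densities: dict,
    records: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Camera-level detection events drawn from each landscape's density.

    Per camera the detection count is negative-binomial; anchored times
    are drawn i.i.d. from the landscape density and mapped back to clock
    times through the inverse anchoring map of a randomly assigned
    calendar day whose sunrise/sunset carry site-specific jitter.
    """
    anchors = config.anchors()
    jit_rad = config.site_jitter_min / 60.0 * math.pi / 12.0
    p_nb = config.detections_dispersion / (config.detections_dispersion
                                           + config.detections_mean)
    rows = []
    for rec in records.itertuples(index=False):
        density = densities[rec.landscape_id]
        for cam in range(config.cameras_per_landscape):
            cam_id = f"{rec.landscape_id}_C{cam + 1:02d}"
            lat = config.latitude + rng.uniform(-0.05, 0.05)
            lon = config.longitude + rng.uniform(-0.05, 0.05)
            jitter = rng.uniform(-jit_rad, jit_rad)
            count = rng.negative_binomial(config.detections_dispersion, p_nb)
            if count == 0:
                continue
            anchored = _sample_from_density(density, count, rng)
            day_offsets = rng.integers(0, config.n_days, size=count)
            for t_anch, off in zip(anchored, day_offsets):
                date = config.start_date + _dt.timedelta(days=int(off))
                day = SolarDay(
                    date=date,
                    sunrise=(anchors.mean_sunrise + jitter) % TWO_PI,
                    sunset=(anchors.mean_sunset + jitter) % TWO_PI,
                )
                t_clock = inverse_double_anchor(t_anch, day, anchors)
                seconds = int(round(t_clock / TWO_PI * 86400)) % 86400
                tstr = f"{seconds // 3600:02d}:{seconds % 3600 // 60:02d}:{seconds % 60:02d}"
                base = {
                    "camera_id": cam_id,
                    "landscape_id": rec.landscape_id,
                    "region_id": rec.region_id,
                    "date": date.isoformat(),
                    "time": tstr,
                    "lat": round(lat, 5),
                    "lon": round(lon, 5),
                    "sunrise": round(float(day.sunrise), 6),
                    "sunset": round(float(day.sunset), 6),
                }
                repeats = 3 if config.simulate_bursts else 1
                for _ in range(repeats):
                    rows.append(dict(base))
    return pd.DataFrame(rows)


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Full synthetic dataset: detections + covariates + ground truth."""
    rng = np.random.default_rng(config.seed)
    records = generate_covariates(config, rng)
    records = target_responses(records, config, rng)
    anchors = config.anchors()

    densities = {}
    truth_rows = []
    for rec in records.itertuples(index=False):
        target_comp = np.array([getattr(rec, c) for c in CATEGORY_ORDER])
        density, r_level, r_comp = build_density(
            target_comp, rec.level, anchors, kappa_shape=config.kappa_shape
        )
        densities[rec.landscape_id] = density
        truth_rows.append({
            "landscape_id": rec.landscape_id,
            "region_id": rec.region_id,
            "level": r_level,
            **dict(zip(CATEGORY_ORDER, r_comp)),
        })
    truth = pd.DataFrame(truth_rows)

    detections = simulate_detections(densities, records, config, rng)
    counts = detections.groupby("landscape_id").size()
    if config.simulate_bursts:
        counts = counts // 3
    records["n_detections"] = records["landscape_id"].map(counts).fillna(0).astype(int)

    return SyntheticDataset(
        detections=detections,
        covariates=records,
        ground_truth=truth,
        true_coefficients={
            "level": dict(config.level_coefficients),
            "pattern": {k: dict(v) for k, v in config.pattern_coefficients.items()},
            "region_sd": config.region_sd,
            "phi_level": config.phi_level,
            "phi_pattern": config.phi_pattern,
        },
        anchors=anchors,
        densities=densities,
    )
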