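"""Time-of-day categories and the activity-pattern composition.

The diel circle is tiled by four arcs defined relative to the solar
anchors: morning and evening are the 4-h windows centred on mean
sunrise and mean sunset (2 h either side), daytime is the arc between
them, and night is the complement. The activity pattern is the fraction
of the fitted circular density falling in each arc, obtained by
numerical integration; the four fractions form a composition on the
simplex and sum to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from dielact.activity_kde import ActivityDensity, _kernel_matrix, fit_circular_kde
from dielact.solar_time import TWO_PI, SolarAnchors

CATEGORY_ORDER = ("night", "morning", "daytime", "evening")

#: Half-width of the morning/evening windows: 2 h = pi/6 radians.
HALF_WINDOW = math.pi / 6.0


@dataclass(frozen=True)
class TimeOfDayCategory:
    """A half-open forward arc [t1, t2) of the diel circle."""

    name: str
    t1: float
    t2: float

    @property
    def length(self) -> float:
        """Forward arc length (always positive, <= 2*pi)."""
        return (self.t2 - self.t1) % TWO_PI or TWO_PI

    def contains(self, t) -> np.ndarray:
        """Membership of circular time(s) in the half-open arc."""
        u = (np.asarray(t, dtype=float) - self.t1) % TWO_PI
        return u < self.length


@dataclass(frozen=True)
class PatternComposition:
    """Fractions of total activity in each time-of-day category."""

    fractions: dict
    ses: dict | None = None
    cis: dict | None = None
    n_boot: int = 0

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"fractions sum to {total}, not 1")
        if any(not 0.0 <= v <= 1.0 for v in self.fractions.values()):
            raise ValueError("fractions must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.fractions[k] for k in CATEGORY_ORDER])


def category_bounds(anchors: SolarAnchors) -> list[TimeOfDayCategory]:
    """The four solar-defined categories tiling the diel circle.

    morning = mean sunrise +/- 2 h, evening = mean sunset +/- 2 h,
    daytime between them, night the complement. Raises if day or night
    is shorter than 4 h, in which case the windows would overlap.
    """
    rise, set_ = anchors.mean_sunrise, anchors.mean_sunset
    day_len = (set_ - rise) % TWO_PI
    night_len = TWO_PI - day_len
    if day_len <= 2 * HALF_WINDOW or night_len <= 2 * HALF_WINDOW:
        raise ValueError(
            "anchors closer than 4 h apart: morning and evening windows overlap"
        )
    morning = TimeOfDayCategory("morning", (rise - HALF_WINDOW) % TWO_PI, (rise + HALF_WINDOW) % TWO_PI)
    daytime = TimeOfDayCategory("daytime", morning.t2, (set_ - HALF_WINDOW) % TWO_PI)
    evening = TimeOfDayCategory("evening", daytime.t2, (set_ + HALF_WINDOW) % TWO_PI)
    night = TimeOfDayCategory("night", evening.t2, morning.t1)
    return [night, morning, daytime, evening]


def _check_tiling(categories) -> None:
    total = sum(c.length for c in categories)
    if abs(total - TWO_PI) > 1e-9:
        raise ValueError("categories do not tile the circle")


def composition(
    density: ActivityDensity,
    categories,
    n_refine: int = 2048,
) -> PatternComposition:
    """Fraction of the density in each category by trapezoidal integration.

    The density is interpolated periodically onto >= ``n_refine`` points
    per full circle so that arc boundaries need not coincide with grid
    points; the fractions are renormalized to sum to exactly 1.
    """
    _check_tiling(categories)
    fracs = {}
    for cat in categories:
        npts = max(16, int(round(n_refine * cat.length / TWO_PI)))
        x = cat.t1 + np.linspace(0.0, cat.length, npts)
        y = density(x)
        fracs[cat.name] = float(np.trapezoid(y, x))
    total = sum(fracs.values())
    if total <= 0:
        raise ValueError("density integrates to zero over the categories")
    fracs = {k: v / total for k, v in fracs.items()}
    return PatternComposition(fractions=fracs)


def bootstrap_composition(
    times,
    categories,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    bandwidth_adjust: float = 1.5,
    grid_size: int = 512,
    ci: float = 0.95,
    n_refine: int = 2048,
) -> PatternComposition:
    """Nonparametric bootstrap of the composition (joint per replicate).

    Each replicate resamples the times with replacement, refits the
    density at the full-sample bandwidth and recomputes all four
    fractions together, so the replicate compositions each sum to 1.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    _check_tiling(categories)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.asarray(times, dtype=float) % TWO_PI
    n = times.size

    full = fit_circular_kde(times, bandwidth_adjust=bandwidth_adjust, grid_size=grid_size)
    point = composition(full, categories, n_refine=n_refine)

    # Fixed-bandwidth replicates are weighted averages of the kernel columns,
    # so one kernel matrix serves all bootstrap replicates.
    kmat = _kernel_matrix(full.grid, times, full.bandwidth)  # grid x n
    weights = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot) / n
    dens_mat = weights @ kmat.T  # n_boot x grid

    reps = np.empty((n_boot, len(categories)))
    for j, cat in enumerate(categories):
        npts = max(16, int(round(n_refine * cat.length / TWO_PI)))
        x = (cat.t1 + np.linspace(0.0, cat.length, npts)) % TWO_PI
        y = np.empty((n_boot, npts))
        for b in range(n_boot):
            y[b] = np.interp(x, full.grid, dens_mat[b], period=TWO_PI)
        reps[:, j] = np.trapezoid(y, dx=cat.length / (npts - 1), axis=1)
    reps /= reps.sum(axis=1, keepdims=True)

    alpha = (1.0 - ci) / 2.0
    lo = np.quantile(reps, alpha, axis=0)
    hi = np.quantile(reps, 1.0 - alpha, axis=0)
    ses = {}
    cis = {}
    for j, cat in enumerate(categories):
        est = point.fractions[cat.name]
        ses[cat.name] = float(reps[:, j].std(ddof=1))
        cis[cat.name] = (float(min(lo[j], est)), float(max(hi[j], est)))
    return PatternComposition(fractions=point.fractions, ses=ses, cis=cis, n_boot=n_boot)
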