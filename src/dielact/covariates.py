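"""Food-availability covariates and predictor standardization.

Natural winter food is indexed by the density of "non-avoided" woody
twigs: species consumed at or above the rate expected from their
availability, classified per species by a 1-df Pearson chi-square
goodness-of-fit test of consumed counts against availability
proportions. Twig density within a forest patch is total twigs counted
over total 1-m^2 quadrats surveyed; the survey design places five
quadrats per 50-m transect, with the transect count per patch given by
the smallest NT satisfying A / (2 NT) < NT for patch area A (ha).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class BrowseRecord:
    species: str
    consumed: int
    available: int
    expected: float
    chi2: float
    p_value: float
    classification: str  # "non-avoided" | "avoided"


def twig_density(twig_count: int, n_quadrats: int) -> float:
    """Twigs per m^2: total twigs over total 1-m^2 quadrats surveyed."""
    if n_quadrats < 1:
        raise ValueError("n_quadrats must be >= 1")
    if twig_count < 0:
        raise ValueError("twig_count must be >= 0")
    return twig_count / n_quadrats


def transects_required(area_ha: float) -> int:
    """Smallest positive transect count NT with NT^2 > area/2.

    Equivalent to the allocation inequality A / (2 NT) < NT. Strict:
    area 8 ha needs NT = 3 because 2^2 = 4 is not > 4.
    """
    if area_ha <= 0:
        raise ValueError("patch area must be positive")
    nt = max(1, math.isqrt(int(area_ha // 2)))
    while nt * nt <= area_ha / 2.0:
        nt += 1
    return nt


def classify_selection(consumed: dict, available: dict, alpha: float = 0.05) -> list[BrowseRecord]:
    """Classify twig species as avoided vs non-avoided by browse selection.

    For each species s, a 1-df Pearson goodness-of-fit test compares the
    consumed count of s (vs all other species pooled) against the
    expectation from availability proportions. A species is *avoided*
    when consumption is significantly below expectation (p <= alpha and
    consumed < expected); species consumed at or above the expected rate,
    or not significantly different from it, are *non-avoided*.
    """
    species = sorted(set(consumed) | set(available))
    cons = np.array([consumed.get(s, 0) for s in species], dtype=float)
    avail = np.array([available.get(s, 0) for s in species], dtype=float)
    if cons.sum() <= 0 or avail.sum() <= 0:
        raise ValueError("total consumed and total available must be positive")
    bad = [s for s, c, a in zip(species, cons, avail) if a == 0 and c > 0]
    if bad:
        raise ValueError(f"species with zero availability but nonzero consumption: {bad}")

    total_cons = cons.sum()
    props = avail / avail.sum()
    records = []
    for s, c, p in zip(species, cons, props):
        expected = total_cons * p
        observed = np.array([c, total_cons - c])
        exp_cells = np.array([expected, total_cons - expected])
        if expected in (0.0, total_cons):
            chi2, pval = 0.0, 1.0
        else:
            chi2, pval = stats.chisquare(observed, exp_cells)
        avoided = pval <= alpha and c < expected
        records.append(
            BrowseRecord(
                species=s,
                consumed=int(c),
                available=int(avail[species.index(s)]),
                expected=float(expected),
                chi2=float(chi2),
                p_value=float(max(pval, np.finfo(float).tiny)),
                classification="avoided" if avoided else "non-avoided",
            )
        )
    return records


def landscape_twig_density(patches: pd.DataFrame, area_weighted: bool = True) -> float:
    """Aggregate patch twig densities to a landscape value.

    ``patches`` needs columns ``twig_density`` and ``area_ha``; by
    default patches are weighted by area.
    """
    d = patches["twig_density"].to_numpy(dtype=float)
    if area_weighted:
        w = patches["area_ha"].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise ValueError("patch areas must be positive")
        return float(np.average(d, weights=w))
    return float(d.mean())


def standardize(values) -> np.ndarray:
    """Z-scores: subtract the mean, divide by the sample SD (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("standardize needs >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot standardize")
    return (x - x.mean()) / sd
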