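"""Wald chi-square comparisons with Holm multiplicity adjustment.

Two activity metrics (levels, or composition fractions) with bootstrap
standard errors are compared by

    W = (AL1 - AL2)^2 / (SE(AL1)^2 + SE(AL2)^2),

referred to a chi-square distribution with 1 degree of freedom. All
pairwise comparisons within a family (e.g. activity levels across
regions) are corrected by Holm's step-down procedure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class WaldResult:
    family_id: str
    unit_1: str
    unit_2: str
    estimate_1: float
    estimate_2: float
    se_1: float
    se_2: float
    W: float
    p_raw: float
    p_adj: float


def wald_statistic(a1: float, s1: float, a2: float, s2: float) -> float:
    """Wald statistic for the difference of two estimates with SEs."""
    denom = s1 * s1 + s2 * s2
    if denom <= 0.0:
        raise ValueError("both standard errors are zero; W undefined")
    return (a1 - a2) ** 2 / denom


def chi2_pvalue(w: float) -> float:
    """Upper-tail probability of chi-square(1) at W."""
    if w < 0:
        raise ValueError("Wald statistic must be non-negative")
    # Guard against underflow for extreme W so downstream adjustment
    # keeps p in (0, 1].
    return float(max(stats.chi2.sf(w, df=1), 5e-324))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    The i-th smallest raw p is multiplied by (m - i + 1), running maxima
    enforce monotonicity, and values are capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("holm_adjust requires at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def pairwise_comparisons(
    units: pd.DataFrame,
    family_col: str | None = None,
    pair_col: str | None = None,
) -> pd.DataFrame:
    """All pairwise Wald tests with per-family Holm adjustment.

    Parameters
    ----------
    units
        One row per unit with columns ``unit`` (label), ``estimate``,
        ``se``, and optionally family/pair columns.
    family_col
        Column defining Holm families; each family is adjusted
        separately. ``None`` treats all rows as one family.
    pair_col
        If given, pairs are only formed between rows sharing this
        column's value (e.g. compare regions within each time-of-day
        category) while the Holm correction still spans the family.

    Returns
    -------
    DataFrame with columns family, unit_1, unit_2, est_1, est_2, se_1,
    se_2, W, p_raw, p_holm.
    """
    required = {"unit", "estimate", "se"}
    if not required.issubset(units.columns):
        raise ValueError(f"units table needs columns {sorted(required)}")
    if family_col is None:
        groups = [("all", units)]
    else:
        groups = list(units.groupby(family_col, sort=False))

    rows = []
    for fam, grp in groups:
        if len(grp) < 2:
            warnings.warn(f"family {fam!r} has < 2 units; skipped", stacklevel=2)
            continue
        recs = grp.to_dict("records")
        fam_rows = []
        for r1, r2 in itertools.combinations(recs, 2):
            if pair_col is not None and r1[pair_col] != r2[pair_col]:
                continue
            w = wald_statistic(r1["estimate"], r1["se"], r2["estimate"], r2["se"])
            fam_rows.append(
                {
                    "family": fam,
                    "unit_1": r1["unit"],
                    "unit_2": r2["unit"],
                    "est_1": r1["estimate"],
                    "est_2": r2["estimate"],
                    "se_1": r1["se"],
                    "se_2": r2["se"],
                    "W": w,
                    "p_raw": chi2_pvalue(w),
                }
            )
        if not fam_rows:
            continue
        adj = holm_adjust([r["p_raw"] for r in fam_rows])
        for r, pa in zip(fam_rows, adj):
            r["p_holm"] = float(pa)
        rows.extend(fam_rows)
    return pd.DataFrame(rows)
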