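"""Hierarchical Bayesian regressions of activity level and pattern.

Activity level (a fraction in (0,1)) is modelled by a mixed-effects
beta regression with a logit link,

    level_j ~ Beta(mu_j * phi, (1 - mu_j) * phi)
    logit(mu_j) = b0 + x_j' b + u_region(j),   u_r ~ Normal(0, sigma_u),

and the four-part activity composition by a mixed-effects Dirichlet
regression with a softmax link and night as the reference category,

    y_j ~ Dirichlet(mu_j * phi),  mu_j = softmax(eta_j),
    eta_{j,night} = 0,
    eta_{j,k} = b0_k + x_j' b_k + u_{k,region(j)}   (k = morning,
    daytime, evening),

with Student-t(3, 0, 2.5) priors on intercepts and slopes, a
half-Student-t(3, 0, 2.5) prior on sigma_u, and Gamma(0.01, 0.01) on
the precision phi. Predictors are standardized before fitting;
interaction terms are products of standardized main effects.

Posteriors are sampled with an affine-invariant ensemble MCMC sampler.
Candidate models are compared by PSIS-LOO with stacking weights and
evidence ratios (top weight / model weight); inference on coefficients
uses equal-tailed 89% credible intervals, calling a predictor "strong"
when its interval excludes zero.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

logger = logging.getLogger(__name__)

PREDICTORS = ("buildings", "roads", "twigs", "agriculture", "deer_density")
CATEGORY_ORDER = ("night", "morning", "daytime", "evening")
NONREF_CATEGORIES = ("morning", "daytime", "evening")

# Priors: Student-t(3, 0, 2.5) on coefficients and (half) on sigma_u,
# Gamma(0.01, 0.01) on the precision phi.
_ST_DF = 3.0
_ST_SCALE = 2.5
_PHI_A = 0.01
_PHI_B = 0.01

MIN_DETECTIONS = 100


@dataclass(frozen=True)
class CandidateModel:
    """One entry of a candidate set: a response and its predictor terms."""

    response: str  # "level" | "pattern"
    terms: tuple[str, ...]
    hypothesis: str = ""

    @property
    def name(self) -> str:
        if any(":" in t for t in self.terms):
            return "*".join(t for t in self.terms if ":" not in t)
        return "+".join(self.terms)


def level_candidate_set() -> list[CandidateModel]:
    """Six single-hypothesis models for activity level."""
    return [
        CandidateModel("level", ("buildings",), "anthropogenic development"),
        CandidateModel("level", ("roads",), "anthropogenic development"),
        CandidateModel("level", ("twigs",), "food"),
        CandidateModel("level", ("agriculture",), "food"),
        CandidateModel("level", ("twigs", "agriculture", "twigs:agriculture"), "food"),
        CandidateModel("level", ("deer_density",), "density dependence"),
    ]


def pattern_candidate_set() -> list[CandidateModel]:
    """Three food-hypothesis models for the activity composition."""
    return [
        CandidateModel("pattern", ("twigs",), "food"),
        CandidateModel("pattern", ("agriculture",), "food"),
        CandidateModel("pattern", ("twigs", "agriculture", "twigs:agriculture"), "food"),
    ]


@dataclass
class SamplerSettings:
    """Ensemble-MCMC settings; defaults sized for ~50-row datasets."""

    n_steps: int = 3000
    n_burn: int = 1500
    thin: int = 5
    n_chains: int = 3  # walker groups used as chains for diagnostics
    min_walkers: int = 90
    rhat_threshold: float = 1.01


@dataclass
class FitResult:
    """Posterior summaries and model-comparison bookkeeping for one model."""

    model: CandidateModel
    coefficients: pd.DataFrame  # term [, category], mean, lci, uci, strong
    region_sd: dict
    precision: dict
    idata: az.InferenceData = field(repr=False)
    rhat_max: float = math.nan
    converged: bool = True
    elpd: float = math.nan
    weight: float = math.nan
    evidence_ratio: float = math.nan


def filter_landscapes(records: pd.DataFrame, min_detections: int = MIN_DETECTIONS) -> pd.DataFrame:
    """Drop analysis units with fewer detections than the threshold.

    Units below ``min_detections`` yield imprecise activity estimates
    (coefficient of variation above ~0.10) and are excluded from the
    regressions.
    """
    n = records["n_detections"].to_numpy()
    kept = records.loc[n >= min_detections].reset_index(drop=True)
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("filter_landscapes: dropped %d of %d units (< %d detections)",
                    dropped, len(records), min_detections)
    if kept.empty:
        raise ValueError(f"no landscapes with >= {min_detections} detections")
    return kept


def standardize_predictors(records: pd.DataFrame, columns=PREDICTORS) -> pd.DataFrame:
    """Return a copy with the given columns z-scored (mean 0, sample SD 1)."""
    out = records.copy()
    for c in columns:
        if c in out.columns:
            x = out[c].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValueError(f"predictor {c!r} has zero variance")
            out[c] = (x - x.mean()) / sd
    return out


def design_matrix(records: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with intercept) from standardized predictor columns.

    A term ``"a:b"`` is the elementwise product of the (already
    standardized) columns a and b.
    """
    cols = [np.ones(len(records))]
    names = ["intercept"]
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(records[a].to_numpy(float) * records[b].to_numpy(float))
        else:
            cols.append(records[t].to_numpy(float))
        names.append(t)
    return np.column_stack(cols), names


def _t_logpdf(x, scale=_ST_SCALE, df=_ST_DF):
    z = x / scale
    return -0.5 * (df + 1.0) * np.log1p(z * z / df)  # up to a constant


def _region_index(records: pd.DataFrame) -> tuple[np.ndarray, list]:
    regions = list(pd.unique(records["region_id"]))
    idx = records["region_id"].map({r: i for i, r in enumerate(regions)}).to_numpy()
    return idx, regions


def _run_ensemble(log_prob, ndim, settings, seed, init_center, init_scale=0.05):
    n_walkers = max(settings.min_walkers, 2 * ndim + 2)
    n_walkers += (-n_walkers) % settings.n_chains  # divisible into chain groups
    rng = np.random.RandomState(seed)
    p0 = init_center[None, :] + init_scale * rng.standard_normal((n_walkers, ndim))
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, vectorize=True,
                                    moves=moves)
    state = emcee.State(p0, random_state=np.random.RandomState(seed + 1).get_state())
    sampler.run_mcmc(state, settings.n_steps, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=settings.n_burn, thin=settings.thin)
    # (steps, walkers, dim) -> (chain groups, draws, dim)
    steps, walkers, _ = chain.shape
    per = walkers // settings.n_chains
    chain = chain.transpose(1, 0, 2).reshape(settings.n_chains, per * steps, ndim)
    return chain


def _summaries(draws_2d, names, mass):
    lo, hi = (1.0 - mass) / 2.0, 1.0 - (1.0 - mass) / 2.0
    rows = []
    for j, name in enumerate(names):
        d = draws_2d[:, j]
        l, u = np.quantile(d, [lo, hi])
        rows.append({"term": name, "estimate": float(d.mean()),
                     "lci": float(l), "uci": float(u), "strong": bool(l > 0 or u < 0)})
    return rows


def _check_convergence(posterior: dict, threshold: float):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(az.from_dict(posterior=posterior))
    rmax = float(max(np.nanmax(np.atleast_1d(rhat[v].values)) for v in rhat.data_vars))
    return rmax, rmax < threshold


def fit_beta_model(
    records: pd.DataFrame,
    model: CandidateModel,
    settings: SamplerSettings | None = None,
    seed: int = 0,
    interval_mass: float = 0.89,
) -> FitResult:
    """Fit the hierarchical beta regression for activity level."""
    settings = settings or SamplerSettings()
    if len(records) < 3:
        raise ValueError("need >= 3 records")
    y = records["level"].to_numpy(dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("levels must lie strictly in (0, 1)")
    X, names = design_matrix(records, model.terms)
    ridx, regions = _region_index(records)
    p1, R = X.shape[1], len(regions)
    ndim = p1 + R + 2  # coefs, log sigma_u, u_r, log phi
    logy, log1my = np.log(y), np.log1p(-y)

    def log_prob(theta):
        # Non-centered random intercepts: u_r = sigma_u * z_r, z ~ N(0,1).
        theta = np.atleast_2d(theta)
        b = theta[:, :p1]
        ls = theta[:, p1]
        z = theta[:, p1 + 1 : p1 + 1 + R]
        lp = theta[:, -1]
        bad = (np.abs(ls) > 12) | (lp < -10) | (lp > 14) | (np.abs(b).max(axis=1) > 50)
        ls_ = np.where(bad, 0.0, ls)
        lp_ = np.where(bad, 0.0, lp)
        sigma = np.exp(ls_)
        phi = np.exp(lp_)
        u = sigma[:, None] * z
        eta = b @ X.T + u[:, ridx]
        mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
        a = mu * phi[:, None]
        c = (1.0 - mu) * phi[:, None]
        ll = (len(y) * gammaln(phi) - gammaln(a).sum(axis=1) - gammaln(c).sum(axis=1)
              + ((a - 1.0) * logy).sum(axis=1) + ((c - 1.0) * log1my).sum(axis=1))
        lprior = (_t_logpdf(b).sum(axis=1)
                  + _t_logpdf(sigma) + ls_
                  - 0.5 * (z * z).sum(axis=1)
                  + _PHI_A * lp_ - _PHI_B * phi)
        out = ll + lprior
        return np.where(bad, -np.inf, out)

    init = np.zeros(ndim)
    init[0] = math.log(y.mean() / (1 - y.mean()))
    init[p1] = math.log(0.2)
    init[-1] = math.log(30.0)
    chain = _run_ensemble(log_prob, ndim, settings, seed, init)

    posterior = {
        "b": chain[:, :, :p1],
        "log_sigma_u": chain[:, :, p1],
        "u": np.exp(chain[:, :, p1])[:, :, None] * chain[:, :, p1 + 1 : p1 + 1 + R],
        "log_phi": chain[:, :, -1],
    }
    rmax, ok = _check_convergence(posterior, settings.rhat_threshold)
    if not ok:
        logger.warning("beta model %s: max R-hat %.3f >= %.2f", model.name, rmax,
                       settings.rhat_threshold)

    # Pointwise log-likelihood for PSIS-LOO.
    flat = chain.reshape(-1, ndim)
    b = flat[:, :p1]
    u = np.exp(flat[:, p1])[:, None] * flat[:, p1 + 1 : p1 + 1 + R]
    phi = np.exp(flat[:, -1])
    mu = np.clip(expit(b @ X.T + u[:, ridx]), 1e-12, 1 - 1e-12)
    a = mu * phi[:, None]
    c = (1 - mu) * phi[:, None]
    ll_pw = (gammaln(phi)[:, None] - gammaln(a) - gammaln(c)
             + (a - 1) * logy + (c - 1) * log1my)
    n_ch = chain.shape[0]
    ll_pw = ll_pw.reshape(n_ch, -1, len(y))

    idata = az.from_dict(posterior=posterior, log_likelihood={"level": ll_pw})
    sigma_draws = np.exp(flat[:, p1])
    phi_draws = phi
    coef_rows = _summaries(flat[:, :p1], names, interval_mass)
    return FitResult(
        model=model,
        coefficients=pd.DataFrame(coef_rows),
        region_sd={"mean": float(sigma_draws.mean()),
                   "median": float(np.median(sigma_draws))},
        precision={"mean": float(phi_draws.mean()),
                   "median": float(np.median(phi_draws))},
        idata=idata,
        rhat_max=rmax,
        converged=ok,
    )


def fit_dirichlet_model(
    records: pd.DataFrame,
    model: CandidateModel,
    settings: SamplerSettings | None = None,
    seed: int = 0,
    interval_mass: float = 0.89,
    zero_replacement: float | None = None,
) -> FitResult:
    """Fit the hierarchical Dirichlet regression for the composition.

    Compositions must be strictly positive; pass ``zero_replacement``
    (e.g. 1e-4) to replace zeros and renormalize instead of erroring.
    """
    settings = settings or SamplerSettings()
    Y = records[list(CATEGORY_ORDER)].to_numpy(dtype=float)
    if np.any(Y <= 0):
        if zero_replacement is None:
            raise ValueError(
                "composition has zero components; pass zero_replacement "
                "(e.g. 1e-4) to replace and renormalize"
            )
        Y = np.maximum(Y, zero_replacement)
        Y = Y / Y.sum(axis=1, keepdims=True)
    X, names = design_matrix(records, model.terms)
    ridx, regions = _region_index(records)
    p1, R = X.shape[1], len(regions)
    K = len(NONREF_CATEGORIES)
    ndim = K * p1 + K * R + 2
    logY = np.log(Y)

    def log_prob(theta):
        # Non-centered random intercepts: u = sigma_u * z, z ~ N(0,1).
        theta = np.atleast_2d(theta)
        W = theta.shape[0]
        b = theta[:, : K * p1].reshape(W, K, p1)
        z = theta[:, K * p1 : K * p1 + K * R].reshape(W, K, R)
        ls = theta[:, -2]
        lp = theta[:, -1]
        bad = (np.abs(ls) > 12) | (lp < -10) | (lp > 14) | (np.abs(b).max(axis=(1, 2)) > 50)
        ls_ = np.where(bad, 0.0, ls)
        lp_ = np.where(bad, 0.0, lp)
        sigma = np.exp(ls_)
        phi = np.exp(lp_)
        u = sigma[:, None, None] * z
        eta_k = b @ X.T + u[:, :, ridx]  # (W, K, n)
        eta = np.concatenate([np.zeros((W, 1, eta_k.shape[2])), eta_k], axis=1)
        eta -= eta.max(axis=1, keepdims=True)
        ex = np.exp(eta)
        mu = ex / ex.sum(axis=1, keepdims=True)  # (W, 4, n)
        alpha = np.clip(mu, 1e-12, None) * phi[:, None, None]
        ll = (len(Y) * gammaln(phi)
              - gammaln(alpha).sum(axis=(1, 2))
              + ((alpha - 1.0) * logY.T[None, :, :]).sum(axis=(1, 2)))
        lprior = (_t_logpdf(b).sum(axis=(1, 2))
                  + _t_logpdf(sigma) + ls_
                  - 0.5 * (z * z).sum(axis=(1, 2))
                  + _PHI_A * lp_ - _PHI_B * phi)
        return np.where(bad, -np.inf, ll + lprior)

    init = np.zeros(ndim)
    mean_comp = Y.mean(axis=0)
    init[0 : K * p1 : p1] = np.log(mean_comp[1:] / mean_comp[0])
    init[-2] = math.log(0.2)
    init[-1] = math.log(50.0)
    chain = _run_ensemble(log_prob, ndim, settings, seed, init)

    posterior = {
        "b": chain[:, :, : K * p1].reshape(chain.shape[0], chain.shape[1], K, p1),
        "u": np.exp(chain[:, :, -2])[:, :, None, None]
        * chain[:, :, K * p1 : K * p1 + K * R].reshape(
            chain.shape[0], chain.shape[1], K, R),
        "log_sigma_u": chain[:, :, -2],
        "log_phi": chain[:, :, -1],
    }
    rmax, ok = _check_convergence(posterior, settings.rhat_threshold)
    if not ok:
        logger.warning("dirichlet model %s: max R-hat %.3f >= %.2f", model.name, rmax,
                       settings.rhat_threshold)

    flat = chain.reshape(-1, ndim)
    D = flat.shape[0]
    b = flat[:, : K * p1].reshape(D, K, p1)
    u = np.exp(flat[:, -2])[:, None, None] * flat[:, K * p1 : K * p1 + K * R].reshape(
        D, K, R)
    phi = np.exp(flat[:, -1])
    eta_k = b @ X.T + u[:, :, ridx]
    eta = np.concatenate([np.zeros((D, 1, eta_k.shape[2])), eta_k], axis=1)
    eta -= eta.max(axis=1, keepdims=True)
    ex = np.exp(eta)
    mu = ex / ex.sum(axis=1, keepdims=True)
    alpha = np.clip(mu, 1e-12, None) * phi[:, None, None]
    ll_pw = (gammaln(phi)[:, None]
             - gammaln(alpha).sum(axis=1)
             + ((alpha - 1.0) * logY.T[None, :, :]).sum(axis=1))
    n_ch = chain.shape[0]
    ll_pw = ll_pw.reshape(n_ch, -1, len(Y))

    idata = az.from_dict(posterior=posterior, log_likelihood={"composition": ll_pw})
    coef_rows = []
    for k, cat in enumerate(NONREF_CATEGORIES):
        rows = _summaries(b[:, k, :], names, interval_mass)
        for r in rows:
            r["category"] = cat
        coef_rows.extend(rows)
    sigma_draws = np.exp(flat[:, -2])
    return FitResult(
        model=model,
        coefficients=pd.DataFrame(coef_rows),
        region_sd={"mean": float(sigma_draws.mean()),
                   "median": float(np.median(sigma_draws))},
        precision={"mean": float(phi.mean()), "median": float(np.median(phi))},
        idata=idata,
        rhat_max=rmax,
        converged=ok,
    )


def loo_weights(fits: list[FitResult], method: str = "stacking") -> np.ndarray:
    """PSIS-LOO model weights across a candidate set (stacking default).

    Also fills in each fit's ``elpd``, ``weight`` and ``evidence_ratio``
    in place and returns the weights in the input order.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to weight")
    names = []
    cmp_dict = {}
    for i, f in enumerate(fits):
        nm = f"{i}:{f.model.name}"
        names.append(nm)
        cmp_dict[nm] = f.idata
    arviz_method = {"stacking": "stacking", "pseudo-bma": "BB-pseudo-BMA"}[method]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comp = az.compare(cmp_dict, ic="loo", method=arviz_method)
    weights = np.array([float(comp.loc[nm, "weight"]) for nm in names])
    weights = weights / weights.sum()
    ratios = evidence_ratios(weights)
    for f, nm, w, r in zip(fits, names, weights, ratios):
        f.elpd = float(comp.loc[nm, "elpd_loo"])
        f.weight = float(w)
        f.evidence_ratio = float(r)
        k = comp.loc[nm, "warning"]
        if bool(k):
            logger.warning("model %s: PSIS-LOO Pareto-k diagnostic warning", nm)
    return weights


def evidence_ratios(weights) -> np.ndarray:
    """Top model weight divided by each model's weight (>= 1; inf at 0).

    Models with a ratio < 3 are conventionally considered supported.
    """
    w = np.asarray(weights, dtype=float)
    top = w.max()
    with np.errstate(divide="ignore"):
        return np.where(w > 0, top / w, np.inf)


def credible_intervals(fit: FitResult, mass: float = 0.89) -> pd.DataFrame:
    """Equal-tailed credible intervals for all coefficients of a fit.

    Recomputed at the requested mass from the stored posterior draws;
    ``strong`` flags intervals that exclude zero.
    """
    post = fit.idata.posterior["b"].values  # (chain, draw, ...) coefficient draws
    flat = post.reshape(-1, *post.shape[2:])
    lo, hi = (1 - mass) / 2, 1 - (1 - mass) / 2
    rows = []
    terms = list(fit.coefficients["term"].unique())
    if flat.ndim == 2:  # beta model
        for j, t in enumerate(terms):
            d = flat[:, j]
            l, u = np.quantile(d, [lo, hi])
            rows.append({"term": t, "estimate": float(d.mean()), "lci": float(l),
                         "uci": float(u), "strong": bool(l > 0 or u < 0)})
    else:  # dirichlet: (draws, K, p1)
        for k, cat in enumerate(NONREF_CATEGORIES):
            for j, t in enumerate(terms):
                d = flat[:, k, j]
                l, u = np.quantile(d, [lo, hi])
                rows.append({"category": cat, "term": t, "estimate": float(d.mean()),
                             "lci": float(l), "uci": float(u),
                             "strong": bool(l > 0 or u < 0)})
    return pd.DataFrame(rows)
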