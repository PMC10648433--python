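"""Usual-intake estimation for daily-consumed nutrients.

Short-term 24-h recalls measure a person's long-run ("usual") intake with
large within-person day-to-day noise.  The model here is the amount part of
the NCI approach for non-episodic dietary components:

    g(Y_ij; lambda) = x_ij' beta + u_i + e_ij,
    u_i ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2),

where g is the Box-Cox transform ((y^l - 1)/l, or log y at l = 0), the
covariates are recall sequence (day 1 vs 2), age category, gender, race,
energy, and a weekday (Mon-Thu) indicator, and lambda is selected on a grid
by the profile log-likelihood including the Box-Cox Jacobian term.

A person's usual intake is the back-transformed conditional expectation

    T_i(u) = E_e[ g^{-1}(x_i' beta + u + e) ],

approximated by Gauss-Hermite quadrature.  The population distribution of
usual intake is the survey-weighted distribution of T over persons x
Monte-Carlo draws of u ("pseudo-persons"), from which means, percentiles
and DRI threshold fractions (EAR cut-point, fraction above AI) follow.

The random-intercept ML fit is computed exactly by profiling beta and the
total residual scale out of the likelihood and optimizing the 1-D variance
ratio theta = sigma_u^2 / sigma_e^2; with cluster sizes of 1 or 2 days the
marginal covariance is block diagonal and everything is closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import DRIReference, Person
from .survey import (
    IntervalEstimate,
    SurveyDesign,
    brr_standard_error,
    weighted_mean,
    weighted_quantile,
)

__all__ = [
    "CovariateDesign", "AmountModel", "UsualIntakeDistribution",
    "persondays_frame", "fit_amount_model", "estimate_distribution",
    "threshold_fractions", "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))

AGE_CATEGORY_EDGES = ((4, 8), (9, 13), (14, 18), (19, 30), (31, 50), (51, 70), (71, 200))
RACE_LEVELS = ("hispanic", "nh_white", "nh_black", "other")


def age_category(age: float) -> int:
    years = int(age)  # completed years, as ages are reported in surveys
    for k, (lo, hi) in enumerate(AGE_CATEGORY_EDGES):
        if lo <= years <= hi:
            return k
    raise ValueError(f"age {age} outside covariate bands")


@dataclass
class CovariateDesign:
    """Fixed-effect design: sequence, 7 age categories, gender, race, energy, weekday.

    Energy enters as (kcal - energy_center) / 1000 so the intercept sits at a
    typical diet.  ``include_energy`` is off when the modeled amount is
    energy itself.
    """

    include_energy: bool = True
    energy_center: float = 2000.0

    def column_names(self) -> list[str]:
        cols = ["intercept", "seq_day2"]
        cols += [f"age_{lo}_{hi}" for lo, hi in AGE_CATEGORY_EDGES[1:]]
        cols += ["male"]
        cols += [f"race_{r}" for r in RACE_LEVELS[1:]]
        if self.include_energy:
            cols += ["energy_c"]
        cols += ["weekday"]
        return cols

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        cols = [np.ones(n), (df["day"].to_numpy() == 2).astype(float)]
        acat = df["age_cat"].to_numpy()
        for k in range(1, len(AGE_CATEGORY_EDGES)):
            cols.append((acat == k).astype(float))
        cols.append((df["gender"].to_numpy() == "male").astype(float))
        race = df["race"].to_numpy()
        for r in RACE_LEVELS[1:]:
            cols.append((race == r).astype(float))
        if self.include_energy:
            cols.append((df["energy"].to_numpy() - self.energy_center) / 1000.0)
        cols.append(df["weekday"].to_numpy().astype(float))
        return np.column_stack(cols)


@dataclass
class AmountModel:
    lam: float                      # Box-Cox exponent
    beta: np.ndarray
    sigma_u2: float
    sigma_e2: float
    loglik: float
    converged: bool
    design: CovariateDesign
    column_names: list[str] = field(default_factory=list)
    profile: dict[float, float] = field(default_factory=dict)  # lambda -> loglik


@dataclass
class UsualIntakeDistribution:
    mean: IntervalEstimate
    percentiles: np.ndarray          # shape (99,), percentiles 1..99
    n_pseudo: int
    usual_intakes: np.ndarray        # (n_persons, n_pseudo) pseudo-person T values
    person_ids: list[str]
    design: SurveyDesign

    def __post_init__(self) -> None:
        if np.any(np.diff(self.percentiles) < -1e-9):
            raise ValueError("percentiles must be non-decreasing")


def persondays_frame(persons: Sequence[Person], nutrient: str) -> pd.DataFrame:
    """Long person-day table with the amount of ``nutrient`` plus covariates."""
    rows = []
    for p in persons:
        for d in p.days:
            rows.append({
                "person_id": p.person_id,
                "day": d.day,
                "weekday": bool(d.weekday_indicator),
                "age_cat": age_category(p.age_years),
                "gender": p.gender,
                "race": p.race,
                "energy": d.nutrients.energy,
                "amount": getattr(d.nutrients, nutrient),
            })
    return pd.DataFrame(rows)


def floor_amounts(persondays: pd.DataFrame) -> pd.DataFrame:
    """Replace zero amounts by half the smallest positive amount.

    Substitution clipping can drive a modeled day's intake of a subtracted
    nutrient to exactly zero; the Box-Cox amount model needs strictly
    positive values, so zeros get a continuity floor tied to the observed
    scale of the data.
    """
    df = persondays.copy()
    pos = df.loc[df["amount"] > 0, "amount"]
    if pos.empty:
        raise ValueError("no positive amounts to floor against")
    df.loc[df["amount"] <= 0, "amount"] = 0.5 * float(pos.min())
    return df


def boxcox(y: np.ndarray, lam: float) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox transform requires strictly positive amounts")
    if lam == 0:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def boxcox_inverse(t: np.ndarray, lam: float) -> np.ndarray:
    """Inverse transform; outside the transform's range the intake is 0."""
    t = np.asarray(t, dtype=float)
    if lam == 0:
        return np.exp(np.clip(t, None, 700.0))
    base = lam * t + 1.0
    return np.where(base > 0, np.power(np.clip(base, 0.0, None), 1.0 / lam), 0.0)


def _profile_loglik_theta(
    z: np.ndarray, X: np.ndarray, sizes: np.ndarray, starts: np.ndarray, theta: float
) -> tuple[float, np.ndarray, float]:
    """Exact ML profile at variance ratio theta = sigma_u^2/sigma_e^2.

    With W_i = I + theta J, W_i^{-1} = I - c_i J where c_i = theta/(1+n_i theta):
    GLS beta and sigma_e^2 = RSS_W / N are closed form; returns
    (log-likelihood, beta, sigma_e^2).
    """
    N, p = X.shape
    c = theta / (1.0 + sizes * theta)          # per group

    # group sums of X and z
    gs_X = np.add.reduceat(X, starts, axis=0)  # (G, p)
    gs_z = np.add.reduceat(z, starts)          # (G,)

    A = X.T @ X - (gs_X * c[:, None]).T @ gs_X
    b = X.T @ z - gs_X.T @ (c * gs_z)
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        # rank-deficient designs (e.g. constant covariates on toy fixtures)
        beta = np.linalg.pinv(A, hermitian=True) @ b

    r = z - X @ beta
    gs_r = np.add.reduceat(r, starts)
    rss = float(r @ r - c @ (gs_r ** 2))
    sigma_e2 = rss / N
    logdet = float(np.sum(np.log1p(sizes * theta)))
    ll = -0.5 * N * (np.log(2 * np.pi * sigma_e2) + 1.0) - 0.5 * logdet
    return ll, beta, sigma_e2


def _fit_lambda(
    z: np.ndarray, X: np.ndarray, sizes: np.ndarray, starts: np.ndarray
) -> tuple[float, np.ndarray, float, float, bool]:
    """ML over theta for a fixed transform; returns (ll, beta, su2, se2, ok)."""

    def negll(log_theta: float) -> float:
        return -_profile_loglik_theta(z, X, sizes, starts, np.exp(log_theta))[0]

    res = minimize_scalar(negll, bounds=(-12.0, 5.0), method="bounded",
                          options={"xatol": 1e-6})
    theta = float(np.exp(res.x))
    ll, beta, se2 = _profile_loglik_theta(z, X, sizes, starts, theta)
    # boundary check: a pure-residual model may beat interior theta
    ll0, beta0, se20 = _profile_loglik_theta(z, X, sizes, starts, 1e-14)
    if ll0 >= ll:
        return ll0, beta0, 0.0, se20, True
    return ll, beta, theta * se2, se2, bool(res.success)


def fit_amount_model(
    persondays: pd.DataFrame,
    design: CovariateDesign | None = None,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> AmountModel:
    """Fit the Box-Cox random-intercept amount model by exact ML.

    ``persondays`` must have columns person_id, day, weekday, age_cat,
    gender, race, energy, amount (see :func:`persondays_frame`).  Requires
    at least one person with two recall days — otherwise the within-person
    variance is unidentifiable — and strictly positive amounts.
    """
    design = design or CovariateDesign()
    df = persondays.sort_values(["person_id", "day"], kind="stable").reset_index(drop=True)
    y = df["amount"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("non-positive amounts cannot be Box-Cox transformed")

    codes, _ = pd.factorize(df["person_id"], sort=False)
    sizes = np.bincount(codes).astype(float)
    starts = np.concatenate([[0], np.cumsum(np.bincount(codes))[:-1]])
    if not np.any(sizes >= 2):
        raise ValueError("all persons have a single day; within-person variance "
                         "is unidentifiable")

    X = design.matrix(df)
    log_jac = float(np.sum(np.log(y)))

    best = None
    profile: dict[float, float] = {}
    for lam in lambda_grid:
        z = boxcox(y, float(lam))
        ll, beta, su2, se2, ok = _fit_lambda(z, X, sizes, starts)
        ll_total = ll + (float(lam) - 1.0) * log_jac   # Box-Cox Jacobian
        profile[float(lam)] = ll_total
        if best is None or ll_total > best[0]:
            best = (ll_total, float(lam), beta, su2, se2, ok)

    ll_total, lam, beta, su2, se2, ok = best
    return AmountModel(
        lam=lam, beta=beta, sigma_u2=float(su2), sigma_e2=float(se2),
        loglik=float(ll_total), converged=ok, design=design,
        column_names=design.column_names(), profile=profile,
    )


def _gh_nodes(n: int = 9) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(n)
    return x, w / np.sqrt(np.pi)


def prediction_frame(persons: Sequence[Person], nutrient: str) -> pd.DataFrame:
    """One row per person with covariates fixed at day-1 values (sequence = day 1)."""
    df = persondays_frame(persons, nutrient)
    return df[df["day"] == 1].reset_index(drop=True)


def usual_intake_values(
    model: AmountModel,
    pred: pd.DataFrame,
    n_pseudo: int,
    seed: int,
    n_quad: int = 9,
) -> np.ndarray:
    """(n_persons, n_pseudo) matrix of usual intakes T(x_i, u_ij)."""
    rng = np.random.default_rng(seed)
    X = model.design.matrix(pred)
    lp = X @ model.beta                                    # (n,)
    u = rng.normal(0.0, np.sqrt(model.sigma_u2), size=(len(pred), n_pseudo))
    nodes, wts = _gh_nodes(n_quad)
    e = np.sqrt(2.0 * model.sigma_e2) * nodes              # (q,)
    t = lp[:, None, None] + u[:, :, None] + e[None, None, :]
    return boxcox_inverse(t, model.lam) @ wts              # (n, n_pseudo)


def estimate_distribution(
    model: AmountModel,
    persons: Sequence[Person],
    design: SurveyDesign,
    nutrient: str,
    n_pseudo: int = 100,
    seed: int = 0,
    n_quad: int = 9,
) -> UsualIntakeDistribution:
    """Survey-weighted population distribution of usual intake.

    Monte-Carlo pseudo-persons share their source person's survey weight;
    the mean CI comes from BRR over the replicate weights (the model fit is
    held fixed across replicates; only the weighted aggregation is redone).
    """
    if not model.converged:
        raise RuntimeError("refusing to simulate from an unconverged model")
    persons = list(persons)
    pred = prediction_frame(persons, nutrient)
    sub = design.subset(pred["person_id"].tolist())
    T = usual_intake_values(model, pred, n_pseudo, seed, n_quad)

    person_mean_T = T.mean(axis=1)

    def mean_under(weights: np.ndarray) -> float:
        return weighted_mean(person_mean_T, weights)

    mean_ci = brr_standard_error(mean_under, sub)
    w_rep = np.repeat(sub.base_weights, n_pseudo)
    pct = weighted_quantile(T.ravel(), w_rep, np.arange(1, 100) / 100.0)
    return UsualIntakeDistribution(
        mean=mean_ci, percentiles=pct, n_pseudo=n_pseudo,
        usual_intakes=T, person_ids=pred["person_id"].tolist(), design=sub,
    )


def threshold_fractions(
    dist: UsualIntakeDistribution,
    dri: DRIReference,
    nutrient: str,
    persons: Sequence[Person],
) -> dict[str, IntervalEstimate]:
    """EAR cut-point / AI threshold fractions with BRR CIs.

    EAR: survey-weighted fraction of pseudo-persons with usual intake below
    the threshold; AI: fraction above.  Each person's own age/gender DRI row
    is used.
    """
    by_id = {p.person_id: p for p in persons}
    thresholds = np.empty(len(dist.person_ids))
    kinds = []
    for i, pid in enumerate(dist.person_ids):
        p = by_id[pid]
        value, kind = dri.lookup(nutrient, p.gender, p.age_years)
        thresholds[i] = value
        kinds.append(kind)
    kind = kinds[0]
    below = (dist.usual_intakes < thresholds[:, None]).mean(axis=1)

    out: dict[str, IntervalEstimate] = {}

    def frac_below(weights: np.ndarray) -> float:
        return weighted_mean(below, weights)

    def frac_above(weights: np.ndarray) -> float:
        return weighted_mean(1.0 - below, weights)

    if kind == "EAR":
        out["fraction_below"] = brr_standard_error(frac_below, dist.design)
    elif kind == "AI":
        out["fraction_above"] = brr_standard_error(frac_above, dist.design)
    else:  # limit: report the fraction above the limit
        out["fraction_above"] = brr_standard_error(frac_above, dist.design)
    return out
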