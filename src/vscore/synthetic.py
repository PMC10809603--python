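"""Synthetic place panels and mobile longitudinal cohorts with known truth.

The generator emulates the structure of a city-scale tract panel linked to a
replenished cohort: ~200 census tracts observed over 8 years with skewed,
zero-inflated crime/policing rates and bounded housing/economic proportions;
and ~464 persons contributing 1-17 semiannual visits each, moving between
tracts, with a binary outcome (think viral non-suppression) that declines
over calendar time and depends on both place characteristics and a
person-level random effect.

Generative model
----------------
Each thematic block b (crime rates, housing proportions, economic
proportions) has a tract-level latent factor following a stationary AR(1)
across years with coefficient ``phi``; variables within a block load on the
factor with weight ``sqrt(rho_block)`` so their within-block correlation is
about ``rho_block``. Rate variables are lognormal magnitudes gated by a
Bernoulli zero-inflation with probability ``pi_zero``; proportions are
logit-normal.

The outcome model is ``logit p = alpha_t + f(X_tract,year) + u_person`` with
year intercepts declining linearly on the logit scale, a selectable
vulnerability function f (linear / threshold / interaction, standardized to a
chosen effect size), and ``u_person ~ N(0, sigma_u^2)``. The generator
returns the evaluated truth alongside the cohort so estimator output can be
scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .panel_io import PlacePanel, CohortTable, derive_availability

__all__ = ["PanelParams", "CohortParams", "SyntheticTruth",
           "generate_place_panel", "generate_cohort", "truth_vscore"]


@dataclass(frozen=True)
class PanelParams:
    n_tracts: int = 200
    years: tuple[int, int] = (2009, 2016)       # inclusive calendar range
    n_rate_vars: int = 7
    n_prop_vars: int = 12
    rho_block: float = 0.6
    phi: float = 0.8
    pi_zero: float = 0.3
    missing_years: dict = field(default_factory=dict)  # var -> years to blank
    seed: int = 0

    def __post_init__(self):
        if self.n_tracts < 2:
            raise ValueError("n_tracts must be >= 2")
        if self.years[1] - self.years[0] < 1:
            raise ValueError("need at least 2 years")
        for name, v in [("rho_block", self.rho_block), ("phi", self.phi)]:
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if not (0.0 <= self.pi_zero <= 1.0):
            raise ValueError("pi_zero must be in [0, 1]")
        if self.n_rate_vars < 0 or self.n_prop_vars < 0 \
                or self.n_rate_vars + self.n_prop_vars < 1:
            raise ValueError("need at least one place variable")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass(frozen=True)
class CohortParams:
    n_persons: int = 464
    visit_probs: tuple | None = None    # distribution over 1..17 visits; uniform
    mobility: float = 0.1               # P(tract change between observed years)
    f_type: str = "linear"              # linear | threshold | interaction
    effect_size: float = 1.0            # SD of f across place-by-time cells
    prev_first: float = 0.531           # year-intercept anchor, first year
    prev_last: float = 0.217            # year-intercept anchor, last year
    alpha_shift: tuple | None = None    # extra per-year logit shifts
    sigma_u: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if not (0.0 <= self.mobility <= 1.0):
            raise ValueError("mobility must be in [0, 1]")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")
        if self.f_type not in ("linear", "threshold", "interaction"):
            raise ValueError(f"unknown f_type '{self.f_type}'")
        if self.visit_probs is not None:
            p = np.asarray(self.visit_probs, dtype=float)
            if (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError("visit_probs must be a probability vector")


@dataclass
class SyntheticTruth:
    """Ground truth of the outcome model on the generated grid."""

    cells: pd.DataFrame        # tract_id, year, f, alpha, p_true
    u_person: pd.Series        # person_id -> random effect
    sigma_u: float
    f_type: str


def generate_place_panel(params: PanelParams) -> PlacePanel:
    """Generate a tract × year place panel with block-correlated variables."""
    rng = np.random.default_rng(params.seed)
    years = params.year_list
    T, Y = params.n_tracts, len(years)

    n_hous = max(1, round(params.n_prop_vars * 5 / 12)) if params.n_prop_vars else 0
    n_econ = params.n_prop_vars - n_hous
    names, types, groups, blocks = [], {}, {}, []
    for j in range(params.n_rate_vars):
        names.append(f"crime{j + 1}")
        types[names[-1]] = "rate"
        groups[names[-1]] = "crime"
        blocks.append(0)
    for j in range(n_hous):
        names.append(f"hous{j + 1}")
        types[names[-1]] = "proportion"
        groups[names[-1]] = "housing"
        blocks.append(1)
    for j in range(n_econ):
        names.append(f"econ{j + 1}")
        types[names[-1]] = "proportion"
        groups[names[-1]] = "econ"
        blocks.append(2)

    # block latent factors: stationary AR(1) across years, per tract
    L = np.empty((3, T, Y))
    L[:, :, 0] = rng.standard_normal((3, T))
    innov_sd = np.sqrt(1.0 - params.phi ** 2)
    for t in range(1, Y):
        L[:, :, t] = params.phi * L[:, :, t - 1] \
            + innov_sd * rng.standard_normal((3, T))

    sr = np.sqrt(params.rho_block)
    se = np.sqrt(1.0 - params.rho_block)
    cols = {}
    for j, name in enumerate(names):
        z = sr * L[blocks[j]] + se * rng.standard_normal((T, Y))
        if types[name] == "rate":
            gate = rng.random((T, Y)) >= params.pi_zero
            mu = np.log(4.0 + 3.0 * j)
            cols[name] = gate * np.exp(mu + 0.8 * z)
        else:
            a = logit(min(0.85, 0.10 + 0.04 * j))
            cols[name] = expit(a + 1.0 * z)

    tract_ids = [f"T{i + 1:03d}" for i in range(T)]
    df = pd.DataFrame({
        "tract_id": np.repeat(tract_ids, Y),
        "year": np.tile(years, T),
    })
    for name in names:
        df[name] = cols[name].reshape(-1)

    # inject whole-year availability gaps (e.g. a variable not tracked in 2016)
    for var, gap_years in (params.missing_years or {}).items():
        if var not in names:
            raise ValueError(f"missing_years names unknown variable '{var}'")
        df.loc[df["year"].isin(list(gap_years)), var] = np.nan

    avail = derive_availability(df, names)
    return PlacePanel(df, types, avail, groups)


def _vulnerability_function(panel: PlacePanel, f_type: str,
                            effect_size: float) -> pd.Series:
    """Evaluate f on every cell, standardized to mean 0 / SD ``effect_size``.

    Variables are standardized pooling all years; cells where a variable is
    unavailable contribute 0 for that variable (its pooled mean).
    """
    df = panel.data
    Z = {}
    for v in panel.variables:
        col = df[v].to_numpy(dtype=float)
        mu, sd = np.nanmean(col), np.nanstd(col)
        z = (col - mu) / sd if sd > 0 else np.zeros_like(col)
        Z[v] = np.nan_to_num(z, nan=0.0)

    groups = panel.groups or {}
    prop_vars = [v for v in panel.variables if panel.schema[v] == "proportion"]
    rate_vars = [v for v in panel.variables if panel.schema[v] == "rate"]
    hous_vars = [v for v in panel.variables if groups.get(v) == "housing"] \
        or prop_vars or panel.variables

    if f_type == "linear":
        raw = np.mean([Z[v] for v in panel.variables], axis=0)
    elif f_type == "threshold":
        z = Z[hous_vars[0]]
        raw = (z > np.quantile(z, 0.75)).astype(float)
    else:  # interaction
        z1 = Z[rate_vars[0]] if rate_vars else Z[panel.variables[0]]
        z2 = Z[hous_vars[0]]
        raw = z1 * z2

    sd = raw.std()
    if effect_size == 0.0 or sd == 0.0:
        f = np.zeros(len(df))
    else:
        f = effect_size * (raw - raw.mean()) / sd
    return pd.Series(f, index=df.index)


def _marginal_probability(eta: np.ndarray, sigma_u: float) -> np.ndarray:
    """E_u[expit(eta + u)], u ~ N(0, sigma_u^2), via Gauss-Hermite quadrature."""
    if sigma_u == 0.0:
        return expit(eta)
    nodes, weights = np.polynomial.hermite.hermgauss(41)
    u = np.sqrt(2.0) * sigma_u * nodes
    return expit(eta[:, None] + u[None, :]) @ (weights / np.sqrt(np.pi))


def generate_cohort(panel: PlacePanel,
                    params: CohortParams) -> tuple[CohortTable, SyntheticTruth]:
    """Generate person-visit rows with mobility, plus the evaluated truth."""
    rng = np.random.default_rng(params.seed)
    years = panel.years
    tracts = panel.tracts
    n_years, n_tracts = len(years), len(tracts)
    if n_tracts < 2 and params.mobility > 0:
        raise ValueError("mobility > 0 requires at least 2 tracts")

    # year intercepts: linear decline on the logit scale between the anchors
    a0, a1 = logit(params.prev_first), logit(params.prev_last)
    alpha = np.linspace(a0, a1, n_years) if n_years > 1 else np.array([a0])
    if params.alpha_shift is not None:
        shift = np.asarray(params.alpha_shift, dtype=float)
        if len(shift) != n_years:
            raise ValueError("alpha_shift must have one entry per year")
        alpha = alpha + shift

    f = _vulnerability_function(panel, params.f_type, params.effect_size)
    cell_key = pd.MultiIndex.from_frame(panel.data[["tract_id", "year"]])
    f_lookup = pd.Series(f.to_numpy(), index=cell_key)
    alpha_lookup = dict(zip(years, alpha))

    if params.visit_probs is None:
        visit_support = np.arange(1, 18)
        visit_probs = np.full(17, 1 / 17)
    else:
        visit_support = np.arange(1, len(params.visit_probs) + 1)
        visit_probs = np.asarray(params.visit_probs, dtype=float)

    persons, p_tracts, p_years = [], [], []
    u = rng.normal(0.0, params.sigma_u, params.n_persons)
    for i in range(params.n_persons):
        pid = f"P{i + 1:04d}"
        v = int(rng.choice(visit_support, p=visit_probs))
        span = min(n_years, int(np.ceil(v / 2)))
        start = int(rng.integers(0, n_years - span + 1))
        # two semiannual visits per observed year; overflow stacks on the last
        per_year = np.full(span, 2, dtype=int)
        surplus = 2 * span - v
        if surplus > 0:      # odd visit count: one single-visit year
            per_year[-1] -= 1
        elif surplus < 0:    # span clipped by the study window
            per_year[-1] += -surplus
        tract = tracts[int(rng.integers(0, n_tracts))]
        for s in range(span):
            if s > 0 and rng.random() < params.mobility:
                j = int(rng.integers(0, n_tracts - 1))
                others = [tr for tr in tracts if tr != tract]
                tract = others[j]
            for _ in range(per_year[s]):
                persons.append(pid)
                p_tracts.append(tract)
                p_years.append(years[start + s])

    n_visits = len(persons)
    eta = np.array([alpha_lookup[yr] + f_lookup[(tr, yr)]
                    for tr, yr in zip(p_tracts, p_years)])
    u_by_row = u[[int(p[1:]) - 1 for p in persons]]
    # a single block of uniforms keeps outcome draws maximally coupled across
    # runs that differ only in the linear predictor (same seed, same structure)
    y = (rng.random(n_visits) < expit(eta + u_by_row)).astype(int)

    cohort = CohortTable(pd.DataFrame({
        "person_id": persons,
        "tract_id": p_tracts,
        "year": p_years,
        "outcome": y,
        "weight": 1.0,
    }))

    cells = panel.data[["tract_id", "year"]].copy()
    cells["f"] = f.to_numpy()
    cells["alpha"] = cells["year"].map(alpha_lookup)
    cells["p_true"] = _marginal_probability(
        (cells["alpha"] + cells["f"]).to_numpy(), params.sigma_u)
    truth = SyntheticTruth(
        cells=cells.reset_index(drop=True),
        u_person=pd.Series(u, index=[f"P{i + 1:04d}"
                                     for i in range(params.n_persons)]),
        sigma_u=params.sigma_u,
        f_type=params.f_type,
    )
    return cohort, truth


def truth_vscore(truth: SyntheticTruth):
    """Standardize the true cell probabilities exactly as the estimator does.

    Returns the recovery target: a score table whose year-specific part is the
    within-year standardization of ``p_true`` and whose generic part averages
    the yearly scores per tract and re-standardizes.
    """
    from .pipeline import PredictionGrid, standardize_by_year, generic_score

    grid = PredictionGrid(pd.DataFrame({
        "tract_id": truth.cells["tract_id"],
        "year": truth.cells["year"],
        "prediction": truth.cells["p_true"],
        "provenance": "truth",
    }))
    vtable = standardize_by_year(grid)
    return generic_score(vtable)
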