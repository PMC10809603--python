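"""The V-score estimation pipeline.

Orchestrates the estimation of outcome-oriented place vulnerability scores
from a place panel and a longitudinal cohort:

1. *Downweighting*: within each place-by-time cell, a person's repeat visits
   are downweighted so each person counts at most 1 per cell.
2. *Rough balancing*: each repetition samples at most ``max_years_per_person``
   years per person and one tract per person-year, curbing the influence of
   long-followed individuals while keeping most of the sample.
3. *Connectivity-aware leave-one-tract-out (LOO)*: the prediction for an
   in-sample tract comes from a forest fit after removing that tract's rows
   AND every row (anywhere) of persons ever seen in that tract, so a tract's
   score never touches outcome data connected to it.
4. Tracts with no cohort presence get out-of-sample predictions from one
   forest fit to the full balanced sample.
5. Repetitions are averaged; predicted probabilities are standardized within
   year (mean 0, variance 1) to remove calendar time trends, and a generic
   per-tract score averages the yearly scores.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import forest as cf
from .forest import ForestParams
from .panel_io import PlacePanel, CohortTable, RunConfig, validate_linkage

__all__ = ["ConnectivityMap", "BalancedSample", "PredictionGrid", "VScoreTable",
           "downweight_within_cells", "rough_balance", "build_connectivity",
           "loo_fit_predict", "full_fit_predict", "run_repetitions",
           "proxy_evaluate", "standardize_by_year", "generic_score"]

log = logging.getLogger("vscore")


@dataclass
class ConnectivityMap:
    """Bipartite 'person ever observed in tract' relation, both directions."""

    tract_to_persons: dict
    person_to_tracts: dict

    def persons_of(self, tract) -> set:
        return self.tract_to_persons.get(tract, set())


@dataclass
class BalancedSample:
    """One repetition's rough-balanced subset of the (downweighted) cohort."""

    data: pd.DataFrame
    repetition: int = 0
    seed: int | None = None

    def __len__(self):
        return len(self.data)


@dataclass
class PredictionGrid:
    """Per (tract, year) predicted outcome probability with provenance."""

    data: pd.DataFrame          # tract_id, year, prediction, provenance
    n_repetitions: int = 1


@dataclass
class VScoreTable:
    """Year-specific standardized scores and (optionally) generic scores."""

    by_year: pd.DataFrame               # tract_id, year, vscore, prediction_raw, provenance
    generic: pd.DataFrame | None = None  # tract_id, vscore_generic


# --------------------------------------------------------------------------
# cohort preparation


def downweight_within_cells(cohort: CohortTable) -> CohortTable:
    """Downweight repeat visits so each person counts <= 1 per (tract, year)."""
    df = cohort.data.copy()
    if len(df):
        n = df.groupby(["person_id", "tract_id", "year"])["weight"].transform("size")
        df["weight"] = df["weight"] / n
    return CohortTable(df)


def rough_balance(cohort: CohortTable, max_years: int = 3,
                  seed=None, repetition: int = 0) -> BalancedSample:
    """Sample <= ``max_years`` years per person and one tract per person-year.

    Year choice is uniform without replacement; when a person-year spans
    several tracts, one is drawn with probability proportional to the person's
    total (downweighted) weight in each tract-cell. All of the person's rows
    in the kept (year, tract) cells are retained with their weights.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    df = cohort.data
    keep = np.zeros(len(df), dtype=bool)
    idx_by = df.groupby(["person_id", "year", "tract_id"]).indices
    w = df["weight"].to_numpy()

    person_years: dict = {}
    for (p, yr, tr) in idx_by:
        person_years.setdefault(p, {}).setdefault(yr, []).append(tr)

    for p in sorted(person_years):
        years = sorted(person_years[p])
        k = min(max_years, len(years))
        chosen_years = rng.choice(len(years), size=k, replace=False)
        for yi in sorted(chosen_years):
            yr = years[yi]
            tracts = sorted(person_years[p][yr])
            if len(tracts) == 1:
                tr = tracts[0]
            else:
                cellw = np.array([w[idx_by[(p, yr, t)]].sum() for t in tracts])
                tr = tracts[int(rng.choice(len(tracts), p=cellw / cellw.sum()))]
            keep[idx_by[(p, yr, tr)]] = True

    out = df.loc[keep].reset_index(drop=True)
    return BalancedSample(out, repetition=repetition,
                          seed=None if isinstance(seed, np.random.Generator)
                          else seed)


def build_connectivity(sample) -> ConnectivityMap:
    """Exact transpose mappings tract -> persons and person -> tracts."""
    df = sample.data if hasattr(sample, "data") else sample
    t2p: dict = {}
    p2t: dict = {}
    for p, t in zip(df["person_id"], df["tract_id"]):
        t2p.setdefault(t, set()).add(p)
        p2t.setdefault(p, set()).add(t)
    return ConnectivityMap(t2p, p2t)


# --------------------------------------------------------------------------
# design matrices


def _cell_design(panel: PlacePanel, years=None) -> pd.DataFrame:
    """Covariate matrix per (tract, year) cell: place variables + year."""
    df = panel.data
    if years is not None:
        df = df[df["year"].between(years[0], years[1])]
    X = df[panel.variables].astype(float).copy()
    X["year"] = df["year"].astype(float)
    X.index = pd.MultiIndex.from_frame(df[["tract_id", "year"]])
    return X


def _training_arrays(sample_df: pd.DataFrame, cellX: pd.DataFrame):
    mi = pd.MultiIndex.from_frame(sample_df[["tract_id", "year"]])
    X = cellX.reindex(mi)
    missing_cells = X.index[X.isna().all(axis=1) & ~X.index.isin(cellX.index)]
    if len(missing_cells):
        raise ValueError(f"cohort cells absent from panel: "
                         f"{sorted(set(missing_cells))[:5]}")
    return X.reset_index(drop=True)


def _tract_seed(base_entropy: int, tract) -> int:
    h = zlib.crc32(str(tract).encode("utf-8"))
    return int(np.random.SeedSequence([base_entropy, h]).generate_state(1)[0])


# --------------------------------------------------------------------------
# fitting


def loo_fit_predict(panel: PlacePanel, sample: BalancedSample,
                    conn: ConnectivityMap, tract, params: ForestParams,
                    years=None) -> pd.Series:
    """Leave-one-tract-out predictions for every panel year of ``tract``.

    Training data = balanced sample minus the tract's rows minus all rows of
    persons ever connected to the tract; clusters are the training tracts.
    """
    cellX = _cell_design(panel, years)
    return _loo_predict_prepared(sample.data, cellX, conn, tract, params)


def _loo_predict_prepared(sample_df, cellX, conn, tract,
                          params: ForestParams) -> pd.Series:
    excluded_persons = conn.persons_of(tract)
    mask = (sample_df["tract_id"] != tract) \
        & ~sample_df["person_id"].isin(excluded_persons)
    train = sample_df.loc[mask]
    target = cellX.loc[[tract]] if tract in cellX.index.get_level_values(0) \
        else cellX.iloc[0:0]
    years_out = target.index.get_level_values("year")
    if len(train) == 0:
        warnings.warn(f"empty training set after LOO exclusion for tract "
                      f"{tract}; predictions flagged missing", stacklevel=2)
        return pd.Series(np.nan, index=years_out)
    X = _training_arrays(train, cellX)
    model = cf.fit(X, train["outcome"].to_numpy(), train["weight"].to_numpy(),
                   train["tract_id"].to_numpy(), params)
    preds = cf.predict_oos(model, target)
    return pd.Series(preds, index=years_out)


def full_fit_predict(panel: PlacePanel, sample: BalancedSample,
                     params: ForestParams, years=None, oos_tracts=None):
    """Fit one forest on the full balanced sample; predict out-of-sample tracts.

    ``oos_tracts`` names the tracts to predict for; by default, every panel
    tract absent from the sample. Returns (predictions DataFrame, forest).
    """
    cellX = _cell_design(panel, years)
    sample_df = sample.data
    if oos_tracts is None:
        in_tracts = set(sample_df["tract_id"])
        oos = [t for t in cellX.index.get_level_values(0).unique()
               if t not in in_tracts]
    else:
        oos = list(oos_tracts)
    X = _training_arrays(sample_df, cellX)
    model = cf.fit(X, sample_df["outcome"].to_numpy(),
                   sample_df["weight"].to_numpy(),
                   sample_df["tract_id"].to_numpy(), params)
    if oos:
        target = cellX.loc[oos]
        preds = cf.predict_oos(model, target)
        out = pd.DataFrame({
            "tract_id": target.index.get_level_values(0),
            "year": target.index.get_level_values(1),
            "prediction": preds,
        })
    else:
        out = pd.DataFrame(columns=["tract_id", "year", "prediction"])
    return out, model


# --------------------------------------------------------------------------
# repetitions


def run_repetitions(panel: PlacePanel, cohort: CohortTable,
                    config: RunConfig, collect=None):
    """Run the full multi-repetition procedure.

    Returns ``(PredictionGrid, importance)`` where the grid holds per-cell
    means over repetitions (LOO provenance for tracts present in the cohort,
    full-sample provenance otherwise) and ``importance`` is a DataFrame with
    the mean depth-decayed split importance of the LOO forests (column
    ``loo``) and of the full-sample forest (column ``full``).

    ``collect``, when given, is called after each repetition with a dict
    holding the repetition index, balanced sample and per-repetition grid
    (used by proxy evaluation).
    """
    report = validate_linkage(panel, cohort)
    df = cohort.data
    if report.n_orphans:
        df = df.drop(index=report.orphan_rows)
        log.info("excluded %d orphan cohort rows", report.n_orphans)
    cohort = CohortTable(df.reset_index(drop=True))

    cohort_dw = downweight_within_cells(cohort)
    conn = build_connectivity(cohort_dw)
    cellX = _cell_design(panel, config.years)
    panel_tracts = list(cellX.index.get_level_values(0).unique())
    in_tracts = [t for t in panel_tracts if t in conn.tract_to_persons]

    grids = []
    imp_loo_acc = []
    imp_full_acc = []
    for rep in range(1, config.n_repetitions + 1):
        try:
            sample, grid, imp_full = _collecting_repetition(
                panel, cohort_dw, conn, config, rep, cellX, in_tracts,
                imp_loo_acc)
        except Exception as e:
            raise RuntimeError(f"repetition {rep} failed: {e}") from e
        grids.append(grid.set_index(["tract_id", "year"])["prediction"])
        if imp_full is not None:
            imp_full_acc.append(imp_full)
        log.info("repetition %d/%d: balanced sample %d rows",
                 rep, config.n_repetitions, len(sample))
        if collect is not None:
            collect({"repetition": rep, "sample": sample, "grid": grid})

    allpreds = pd.concat(grids, axis=1)
    mean_pred = allpreds.mean(axis=1)  # NaN-skipping mean over repetitions
    out = mean_pred.rename("prediction").reset_index()
    out["provenance"] = np.where(out["tract_id"].isin(in_tracts),
                                 "LOO", "full-sample")
    grid = PredictionGrid(out, n_repetitions=config.n_repetitions)

    importance = pd.DataFrame({
        "loo": pd.concat(imp_loo_acc, axis=1).mean(axis=1)
        if imp_loo_acc else pd.Series(dtype=float),
        "full": pd.concat(imp_full_acc, axis=1).mean(axis=1)
        if imp_full_acc else pd.Series(dtype=float),
    })
    return grid, importance


def _collecting_repetition(panel, cohort_dw, conn, config, rep, cellX,
                           in_tracts, imp_loo_acc):
    """Like _single_repetition but also accumulates LOO forest importances."""
    rep_entropy = int(np.random.SeedSequence(
        [config.master_seed, rep]).generate_state(1)[0])
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.master_seed, rep, 1]))
    sample = rough_balance(cohort_dw, config.max_years_per_person, rng,
                           repetition=rep)
    sample_df = sample.data

    rows = []
    imps = []
    for tract in in_tracts:
        p = replace(config.forest, seed=_tract_seed(rep_entropy, tract))
        excluded = conn.persons_of(tract)
        mask = (sample_df["tract_id"] != tract) \
            & ~sample_df["person_id"].isin(excluded)
        train = sample_df.loc[mask]
        target = cellX.loc[[tract]]
        if len(train) == 0:
            warnings.warn(f"empty training set after LOO exclusion for tract "
                          f"{tract}; predictions flagged missing", stacklevel=2)
            preds = np.full(len(target), np.nan)
        else:
            X = _training_arrays(train, cellX)
            model = cf.fit(X, train["outcome"].to_numpy(),
                           train["weight"].to_numpy(),
                           train["tract_id"].to_numpy(), p)
            preds = cf.predict_oos(model, target)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                imps.append(cf.importance(model))
        for yr, pr in zip(target.index.get_level_values(1), preds):
            rows.append((tract, yr, pr, "LOO"))
        log.debug("rep %d LOO tract %s: %d training rows", rep, tract,
                  int(mask.sum()))
    if imps:
        imp_loo_acc.append(pd.concat(imps, axis=1).mean(axis=1))

    full_seed = int(np.random.SeedSequence(
        [config.master_seed, rep, 2]).generate_state(1)[0])
    panel_tracts = cellX.index.get_level_values(0).unique()
    oos_tracts = [t for t in panel_tracts if t not in set(in_tracts)]
    oos_preds, full_model = full_fit_predict(
        panel, sample, replace(config.forest, seed=full_seed), config.years,
        oos_tracts=oos_tracts)
    for _, r in oos_preds.iterrows():
        rows.append((r["tract_id"], r["year"], r["prediction"], "full-sample"))
    grid = pd.DataFrame(rows, columns=["tract_id", "year", "prediction",
                                       "provenance"])
    imp_full = cf.importance(full_model)
    return sample, grid, imp_full


# --------------------------------------------------------------------------
# proxy evaluation (adjacent-year fill-in for a variable missing in one year)


def _pipeline_mse(panel, cohort, config) -> float:
    """Weighted Brier score of per-repetition cell predictions against the
    balanced-sample binary outcomes, pooled over repetitions."""
    num = 0.0
    den = 0.0

    def _collect(rec):
        nonlocal num, den
        sample = rec["sample"].data
        lookup = rec["grid"].set_index(["tract_id", "year"])["prediction"]
        mi = pd.MultiIndex.from_frame(sample[["tract_id", "year"]])
        p = lookup.reindex(mi).to_numpy()
        ok = ~np.isnan(p)
        w = sample["weight"].to_numpy()[ok]
        y = sample["outcome"].to_numpy()[ok]
        num += float(np.sum(w * (y - p[ok]) ** 2))
        den += float(np.sum(w))

    run_repetitions(panel, cohort, config, collect=_collect)
    if den == 0:
        raise RuntimeError("no scored observations; cannot compute MSE")
    return num / den


def proxy_evaluate(panel: PlacePanel, cohort: CohortTable, config: RunConfig,
                   variable: str, missing_year: int, source_year: int) -> dict:
    """Evaluate borrowing a variable's adjacent-year values for a missing year.

    Runs the whole pipeline on the base panel and on a panel where
    ``variable``'s ``source_year`` values are copied into ``missing_year``,
    comparing weighted Brier MSE. The proxy is adopted only when it strictly
    improves MSE; ties revert (conservative).
    """
    avail = panel.availability
    if variable not in avail.columns:
        raise ValueError(f"unknown variable '{variable}'")
    if bool(avail.loc[missing_year, variable]):
        raise ValueError(f"variable '{variable}' is available in "
                         f"{missing_year}; nothing to proxy")
    if not bool(avail.loc[source_year, variable]):
        raise ValueError(f"source year {source_year} has no data for "
                         f"'{variable}'")

    proxy = panel.copy()
    src = proxy.data.loc[proxy.data["year"] == source_year,
                         ["tract_id", variable]].set_index("tract_id")[variable]
    tgt_mask = proxy.data["year"] == missing_year
    proxy.data.loc[tgt_mask, variable] = \
        proxy.data.loc[tgt_mask, "tract_id"].map(src).to_numpy()
    proxy.availability.loc[missing_year, variable] = True

    mse_base = _pipeline_mse(panel, cohort, config)
    mse_proxy = _pipeline_mse(proxy, cohort, config)
    decision = "adopt" if mse_proxy < mse_base else "revert"
    return {"mse_base": mse_base, "mse_proxy": mse_proxy, "decision": decision}


# --------------------------------------------------------------------------
# standardization


def standardize_by_year(grid: PredictionGrid) -> VScoreTable:
    """Within-year standardization of predictions to mean 0, variance 1.

    Uses the sample standard deviation (n-1) over all tracts with a
    prediction in the year, LOO and full-sample provenance alike. Removing
    the yearly location/scale removes calendar time trends from the score:
    standardize(a + b*p) == standardize(p) exactly for any a and b > 0.
    """
    df = grid.data.copy()
    df["vscore"] = np.nan
    for yr, g in df.groupby("year"):
        vals = g["prediction"].dropna()
        if len(vals) < 2:
            raise ValueError(f"year {yr} has fewer than 2 tract predictions")
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero variance of predictions in year {yr}; "
                             "standardization undefined")
        df.loc[vals.index, "vscore"] = (vals - vals.mean()) / sd
    df["prediction_raw"] = df["prediction"]
    by_year = df[["tract_id", "year", "vscore", "prediction_raw",
                  "provenance"]].reset_index(drop=True)
    return VScoreTable(by_year=by_year, generic=None)


def generic_score(vtable: VScoreTable) -> VScoreTable:
    """Average each tract's yearly scores and re-standardize across tracts.

    A tract with no yearly score in any year keeps a flagged-missing (NaN)
    generic score; a degenerate table whose cross-year means have zero
    variance yields all-NaN generic scores with a warning.
    """
    means = vtable.by_year.groupby("tract_id")["vscore"].mean()
    valid = means.dropna()
    out = pd.Series(np.nan, index=means.index, name="vscore_generic")
    if len(valid) >= 2:
        sd = valid.std(ddof=1)
        if np.isfinite(sd) and sd > 0:
            out.loc[valid.index] = (valid - valid.mean()) / sd
        else:
            warnings.warn("zero variance of cross-year mean scores; generic "
                          "scores flagged missing", stacklevel=2)
    else:
        warnings.warn("fewer than 2 tracts with scores; generic scores "
                      "flagged missing", stacklevel=2)
    generic = out.rename_axis("tract_id").reset_index()
    return VScoreTable(by_year=vtable.by_year, generic=generic)
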