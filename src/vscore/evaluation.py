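"""Outcome-agnostic D-score baseline and recovery reporting.

The disadvantage score (D-score) is the conventional first-principal-component
summary of standardized place variables: ``D = a0 + a1*X1 + ... + ak*Xk`` with
principal loadings ``a``. It is fitted pooling all years (one loading vector,
so scores are comparable across years) and compared against the
outcome-oriented V-score on synthetic data where the true vulnerability
function is known. The comparison is the package's test of the central
claim motivating outcome-oriented scoring: when the outcome-relevant signal
does not lie along the first principal direction, the V-score recovers it and
the D-score cannot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .panel_io import PlacePanel
from .pipeline import VScoreTable

__all__ = ["DScoreTable", "RecoveryReport", "dscore_pc1", "recovery_report"]


@dataclass
class DScoreTable:
    """(tract, year) first-principal-component scores, centered per year."""

    data: pd.DataFrame          # tract_id, year, dscore
    loadings: pd.Series         # variable -> PC1 loading (oriented)
    explained_variance_ratio: float


@dataclass
class RecoveryReport:
    per_year: dict              # year -> {v_pearson, v_spearman, d_pearson, d_spearman}
    generic: dict               # same keys, on generic scores
    years: list
    lag_corr: list              # year x year Pearson matrix of V-scores
    mean_adjacent_corr: float
    mean_corr_by_lag: dict      # lag -> mean Pearson correlation

    def to_json(self, path=None) -> str:
        doc = json.dumps({
            "per_year": {str(k): v for k, v in self.per_year.items()},
            "generic": self.generic,
            "years": [int(y) for y in self.years],
            "vscore_lag_corr": self.lag_corr,
            "mean_adjacent_corr": self.mean_adjacent_corr,
            "mean_corr_by_lag": {str(k): v
                                 for k, v in self.mean_corr_by_lag.items()},
        }, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc


def dscore_pc1(panel: PlacePanel, deprivation_vars=None) -> DScoreTable:
    """First-principal-component disadvantage score of the place panel.

    Variables are standardized pooling all years; missing entries are
    mean-imputed (zeros after standardization) so the baseline does not
    inherit the forest's missingness handling. The sign is oriented so the
    score correlates positively with the mean of standardized
    deprivation-group variables (proportion variables by default).
    """
    variables = panel.variables
    usable = [v for v in variables
              if panel.data[v].notna().sum() >= 2
              and np.nanstd(panel.data[v].to_numpy(dtype=float)) > 0]
    if len(usable) < 2:
        raise ValueError("need at least 2 usable variables for the D-score")

    Z = np.column_stack([
        np.nan_to_num(
            (panel.data[v].to_numpy(dtype=float)
             - np.nanmean(panel.data[v].to_numpy(dtype=float)))
            / np.nanstd(panel.data[v].to_numpy(dtype=float)), nan=0.0)
        for v in usable])

    pca = PCA(n_components=1)
    scores = pca.fit_transform(Z)[:, 0]
    loadings = pd.Series(pca.components_[0], index=usable)

    if deprivation_vars is None:
        groups = panel.groups or {}
        deprivation_vars = [v for v in usable if groups.get(v) == "econ"] \
            or [v for v in usable if panel.schema[v] == "proportion"] \
            or usable
    dep_idx = [usable.index(v) for v in deprivation_vars if v in usable]
    dep_mean = Z[:, dep_idx].mean(axis=1)
    orient = np.sign(np.corrcoef(scores, dep_mean)[0, 1]) if dep_mean.std() > 0 \
        else 1.0
    if orient == 0:
        orient = 1.0
    scores = orient * scores
    loadings = orient * loadings

    out = panel.data[["tract_id", "year"]].copy()
    out["dscore"] = scores
    # center within year so the baseline is on the same (detrended) footing
    out["dscore"] = out["dscore"] - out.groupby("year")["dscore"].transform("mean")
    return DScoreTable(out.reset_index(drop=True), loadings,
                       float(pca.explained_variance_ratio_[0]))


def _corr_pair(a: pd.Series, b: pd.Series) -> dict:
    df = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(df) < 3:
        raise ValueError("fewer than 3 aligned tracts; correlations undefined")
    x, y = df.iloc[:, 0], df.iloc[:, 1]
    return {"pearson": float(stats.pearsonr(x, y)[0]),
            "spearman": float(stats.spearmanr(x, y)[0])}


def recovery_report(vtable: VScoreTable, dtable: DScoreTable,
                    truth) -> RecoveryReport:
    """Correlations of V- and D-scores with the known truth, plus the V-score
    year-lag correlation structure.

    ``truth`` may be a SyntheticTruth (standardized internally) or an already
    standardized score table.
    """
    from .synthetic import SyntheticTruth, truth_vscore

    tt = truth_vscore(truth) if isinstance(truth, SyntheticTruth) else truth

    v_by = vtable.by_year.set_index(["tract_id", "year"])["vscore"]
    d_by = dtable.data.set_index(["tract_id", "year"])["dscore"]
    t_by = tt.by_year.set_index(["tract_id", "year"])["vscore"]

    years = sorted(vtable.by_year["year"].unique())
    per_year = {}
    for yr in years:
        v = v_by.xs(yr, level="year")
        d = d_by.xs(yr, level="year")
        t = t_by.xs(yr, level="year")
        cv = _corr_pair(v, t)
        cd = _corr_pair(d, t)
        per_year[int(yr)] = {"v_pearson": cv["pearson"],
                             "v_spearman": cv["spearman"],
                             "d_pearson": cd["pearson"],
                             "d_spearman": cd["spearman"]}

    v_gen = vtable.generic.set_index("tract_id")["vscore_generic"] \
        if vtable.generic is not None else v_by.groupby("tract_id").mean()
    t_gen = tt.generic.set_index("tract_id")["vscore_generic"] \
        if tt.generic is not None else t_by.groupby("tract_id").mean()
    d_gen = d_by.groupby("tract_id").mean()
    cv = _corr_pair(v_gen, t_gen)
    cd = _corr_pair(d_gen, t_gen)
    generic = {"v_pearson": cv["pearson"], "v_spearman": cv["spearman"],
               "d_pearson": cd["pearson"], "d_spearman": cd["spearman"]}

    wide = v_by.unstack("year").reindex(columns=years)
    lag_corr = wide.corr().to_numpy()
    by_lag = {}
    n = len(years)
    for lag in range(1, n):
        vals = [lag_corr[i, i + lag] for i in range(n - lag)
                if np.isfinite(lag_corr[i, i + lag])]
        if vals:
            by_lag[lag] = float(np.mean(vals))
    mean_adj = by_lag.get(1, float("nan"))

    return RecoveryReport(per_year=per_year, generic=generic, years=years,
                          lag_corr=[[float(x) for x in row]
                                    for row in lag_corr],
                          mean_adjacent_corr=mean_adj,
                          mean_corr_by_lag=by_lag)
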