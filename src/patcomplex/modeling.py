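"""Statistical models linking image predictors to complexity ratings.

The pipeline mirrors a standard psychophysics analysis: ratings on a
5-point scale are averaged per stimulus; predictors are z-standardised;
all linear models with up to three of the 24 predictors are enumerated
and ranked by explained variance; random-forest regressions with 10-fold
cross-validation approximate the upper bound of achievable prediction
quality; per-participant best two-predictor models quantify individual
differences; and random-slope mixed models test whether participants
weight the structural (symmetry) and quantitative factors differently.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold


class ModelingError(ValueError):
    """Invalid input for a modeling operation."""


# ---------------------------------------------------------------------------
# ratings and standardisation

def aggregate_ratings(ratings: pd.DataFrame) -> pd.Series:
    """Mean rating per stimulus over all non-excluded ratings.

    ``ratings`` is a long table with columns ``participant``, ``stimulus``,
    ``rating`` and optionally a boolean ``excluded`` flag (e.g. repeat
    presentations that must not enter the mean).  Stimuli with no usable
    ratings are absent from the output.
    """
    if len(ratings) == 0:
        raise ModelingError("empty rating table")
    df = ratings
    if "excluded" in df.columns:
        df = df.loc[~df["excluded"].astype(bool)]
    means = df.groupby("stimulus")["rating"].mean()
    means.name = "mean_rating"
    return means


def zstandardize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """z-standardise every column (mean 0, sample SD 1, ddof=1).

    Returns the standardised table and a two-row frame of the means and
    SDs used, for reuse on new data.  Constant columns are rejected.
    """
    means = table.mean()
    sds = table.std(ddof=1)
    constant = sds.index[(sds == 0) | sds.isna()].tolist()
    if constant:
        raise ModelingError(f"cannot standardise constant column(s): {constant}")
    z = (table - means) / sds
    params = pd.DataFrame({"mean": means, "sd": sds}).T
    return z, params


# ---------------------------------------------------------------------------
# ordinary least squares

@dataclass(frozen=True)
class LinearFit:
    """OLS fit summary (intercept first in all parameter arrays)."""

    predictors: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    fvalue: float
    df_model: int
    df_resid: int
    r_squared: float
    r_squared_adj: float
    nobs: int

    def predict(self, X: pd.DataFrame) -> pd.Series:
        yhat = self.params["const"] + (
            X[list(self.predictors)] * self.params[list(self.predictors)]
        ).sum(axis=1)
        yhat.name = "predicted"
        return yhat


def fit_ols(X: pd.DataFrame, y: pd.Series) -> LinearFit:
    """Ordinary least squares of ``y`` on ``X`` with an intercept."""
    X = pd.DataFrame(X)
    if X.isna().any().any() or pd.Series(y).isna().any():
        raise ModelingError("missing values in design or response")
    n, p = X.shape
    if n <= p + 1:
        raise ModelingError(f"need n > p+1 observations (n={n}, p={p})")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.max()
        collinear = worst.index[worst > 1 - 1e-10].tolist() or list(X.columns)
        raise ModelingError(f"rank-deficient design; collinear columns: {collinear}")
    res = sm.OLS(np.asarray(y, dtype=float), design).fit()
    return LinearFit(
        predictors=tuple(X.columns),
        params=pd.Series(res.params, index=design.columns),
        bse=pd.Series(res.bse, index=design.columns),
        tvalues=pd.Series(res.tvalues, index=design.columns),
        pvalues=pd.Series(res.pvalues, index=design.columns),
        fvalue=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        r_squared=float(res.rsquared),
        r_squared_adj=float(res.rsquared_adj),
        nobs=int(res.nobs),
    )


# ---------------------------------------------------------------------------
# exhaustive best-subset selection

@dataclass(frozen=True)
class SubsetModel:
    predictors: tuple[str, ...]
    r_squared: float
    fit: LinearFit


def _subset_r2(Xc: np.ndarray, yc: np.ndarray, tss: float, cols: tuple[int, ...]) -> float:
    # centred design: R^2 = 1 - RSS/TSS without refitting the intercept
    beta, res, *_ = np.linalg.lstsq(Xc[:, cols], yc, rcond=None)
    rss = float(res[0]) if res.size else float(((yc - Xc[:, cols] @ beta) ** 2).sum())
    return 1.0 - rss / tss


def best_subset(
    table: pd.DataFrame, y: pd.Series, k_max: int = 3, top: int = 5
) -> dict[int, list[SubsetModel]]:
    """Enumerate all 1..k_max predictor OLS models, keep the top-5 by R².

    Ties break lexicographically on predictor names; within each size the
    returned list is sorted by R² descending.
    """
    if table.shape[1] > 30:
        raise ModelingError("exhaustive enumeration limited to <= 30 predictors")
    common = table.index.intersection(pd.Series(y).index)
    X = table.loc[common]
    yv = pd.Series(y).loc[common].to_numpy(dtype=float)
    names = list(X.columns)
    Xc = X.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    yc = yv - yv.mean()
    tss = float((yc**2).sum())
    if tss == 0:
        raise ModelingError("constant response")
    out: dict[int, list[SubsetModel]] = {}
    for k in range(1, k_max + 1):
        scored = []
        for combo in itertools.combinations(range(len(names)), k):
            r2 = _subset_r2(Xc, yc, tss, combo)
            scored.append((-r2, tuple(names[i] for i in combo)))
        scored.sort()
        kept = []
        for neg_r2, combo_names in scored[:top]:
            fit = fit_ols(X[list(combo_names)], pd.Series(yv, index=common))
            kept.append(SubsetModel(combo_names, fit.r_squared, fit))
        out[k] = kept
    return out


# ---------------------------------------------------------------------------
# performance metrics

def metrics(pred, obs) -> tuple[float, float, float, float]:
    """(Pearson r, Spearman r_s, RMSE, MAE) of predictions vs observations."""
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.std() == 0 or o.std() == 0:
        raise ModelingError("correlation undefined for constant input")
    r = float(stats.pearsonr(p, o).statistic)
    rs = float(stats.spearmanr(p, o).statistic)
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    mae = float(np.mean(np.abs(p - o)))
    return r, rs, rmse, mae


# ---------------------------------------------------------------------------
# cross-validated random forests

@dataclass(frozen=True)
class CVResult:
    """Pooled out-of-fold predictions and their agreement with the data."""

    predictions: pd.Series
    r: float
    r_s: float
    r_squared: float
    rmse: float
    mae: float
    seed: int
    settings: dict


def rf_cv(
    table: pd.DataFrame,
    predictor_subset: tuple[str, ...],
    y: pd.Series,
    folds: int = 10,
    seed: int = 0,
    n_estimators: int = 500,
) -> CVResult:
    """k-fold cross-validated random-forest regression.

    Defaults mirror the classic regression-forest settings: 500 trees,
    ``max(1, floor(p/3))`` candidate predictors per split, unlimited
    depth.  Each stimulus is predicted exactly once out-of-fold; the
    reported R² is the squared Pearson correlation of the pooled
    out-of-fold predictions with the observed means.
    """
    if len(predictor_subset) == 0:
        raise ModelingError("predictor subset must not be empty")
    missing = [c for c in predictor_subset if c not in table.columns]
    if missing:
        raise ModelingError(f"predictors not in table: {missing}")
    common = table.index.intersection(pd.Series(y).index)
    X = table.loc[common, list(predictor_subset)].to_numpy(dtype=float)
    yv = pd.Series(y).loc[common].to_numpy(dtype=float)
    n = len(common)
    if folds > n:
        raise ModelingError(f"folds={folds} exceeds n={n}")
    max_features = max(1, len(predictor_subset) // 3)
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.generate_state(folds)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % (2**32 - 1))
    oof = np.full(n, np.nan)
    for (train, test), fs in zip(kf.split(X), fold_seeds):
        forest = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features=max_features,
            random_state=int(fs % (2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(X[train], yv[train])
        oof[test] = forest.predict(X[test])
    assert not np.isnan(oof).any()
    r, rs, rmse, mae = metrics(oof, yv)
    return CVResult(
        predictions=pd.Series(oof, index=common, name="oof_prediction"),
        r=r,
        r_s=rs,
        r_squared=r**2,
        rmse=rmse,
        mae=mae,
        seed=seed,
        settings={
            "folds": folds,
            "n_estimators": n_estimators,
            "max_features": max_features,
            "predictors": list(predictor_subset),
        },
    )


# ---------------------------------------------------------------------------
# per-participant models

@dataclass(frozen=True)
class ParticipantModel:
    participant: object
    best_predictors: tuple[str, ...]
    best_r_squared: float
    reference_r_squared: float
    delta_r_squared: float
    n_stimuli: int
    best_fit: LinearFit


@dataclass(frozen=True)
class PerParticipantResult:
    models: list[ParticipantModel]
    predictor_counts: Counter
    model_counts: Counter
    excluded_participants: list
    reference: tuple[str, ...]

    def n_within(self, margin: float = 0.05) -> int:
        """Participants whose optimal model beats the reference by <= margin."""
        return sum(1 for m in self.models if m.delta_r_squared <= margin)


def per_participant_models(
    ratings: pd.DataFrame,
    table: pd.DataFrame,
    reference: tuple[str, str] = ("MS", "RMSGIF"),
    min_stimuli: int = 20,
) -> PerParticipantResult:
    """Exhaustive best two-predictor model for every participant.

    Each participant's own ratings (on the stimuli they actually rated)
    are regressed on every pair of standardised predictors; the winning
    pair, its R², the R² of the reference pair and their difference are
    returned together with corpus-level frequency counts.  Participants
    with constant ratings are flagged and excluded from the counts.
    """
    z, _ = zstandardize(table)
    names = list(z.columns)
    Xall = z.to_numpy(dtype=float)
    df = ratings
    if "excluded" in df.columns:
        df = df.loc[~df["excluded"].astype(bool)]
    models: list[ParticipantModel] = []
    excluded: list = []
    predictor_counts: Counter = Counter()
    model_counts: Counter = Counter()
    ref = tuple(sorted(reference))
    row_of = {s: i for i, s in enumerate(z.index)}
    for participant, grp in df.groupby("participant"):
        grp = grp[grp["stimulus"].isin(row_of)]
        if len(grp) < min_stimuli:
            excluded.append(participant)
            continue
        yv = grp["rating"].to_numpy(dtype=float)
        if yv.std() == 0:
            excluded.append(participant)
            continue
        rows = np.array([row_of[s] for s in grp["stimulus"]])
        Xp = Xall[rows]
        Xc = Xp - Xp.mean(axis=0)
        yc = yv - yv.mean()
        tss = float((yc**2).sum())
        best_combo, best_r2 = None, -np.inf
        for combo in itertools.combinations(range(len(names)), 2):
            r2 = _subset_r2(Xc, yc, tss, combo)
            combo_names = tuple(names[i] for i in combo)
            if r2 > best_r2 + 1e-12 or (
                abs(r2 - best_r2) <= 1e-12 and combo_names < best_combo
            ):
                best_combo, best_r2 = combo_names, r2
        ref_cols = tuple(names.index(c) for c in ref)
        ref_r2 = _subset_r2(Xc, yc, tss, ref_cols)
        Xdf = pd.DataFrame(Xp, columns=names)
        fit = fit_ols(Xdf[list(best_combo)], pd.Series(yv))
        models.append(
            ParticipantModel(
                participant=participant,
                best_predictors=best_combo,
                best_r_squared=best_r2,
                reference_r_squared=ref_r2,
                delta_r_squared=best_r2 - ref_r2,
                n_stimuli=len(grp),
                best_fit=fit,
            )
        )
        predictor_counts.update(best_combo)
        model_counts[tuple(sorted(best_combo))] += 1
    return PerParticipantResult(models, predictor_counts, model_counts, excluded, ref)


# ---------------------------------------------------------------------------
# random-slope mixed models

@dataclass(frozen=True)
class MixedModelFit:
    """One mixed-model fit in the random-effects comparison ladder."""

    name: str
    random_slopes: tuple[str, ...]
    fe_params: pd.Series
    fe_bse: pd.Series
    participant_intercept_var: float
    slope_vars: dict
    stimulus_intercept_var: float
    llf: float
    aic: float
    bic: float
    n_params: int
    converged: bool
    error: str | None = None


@dataclass(frozen=True)
class LmmComparison:
    fits: list[MixedModelFit]
    lrt_pvalues: dict
    aic_ranking: list[str]
    bic_ranking: list[str]


_LMM_LADDER = [
    ("M1", ()),
    ("M2", ("first",)),
    ("M3", ("second",)),
    ("M4", ("first", "second")),
]


def lmm_compare(
    ratings: pd.DataFrame,
    table: pd.DataFrame,
    predictors: tuple[str, str] = ("MS", "RMSGIF"),
) -> LmmComparison:
    """Compare four random-effects structures for the two-factor model.

    M1 has random intercepts only, M2 adds a per-participant slope on the
    first predictor, M3 on the second, and M4 on both.  All models are
    fitted by maximum likelihood so AIC/BIC are comparable, and random
    slopes are tested by likelihood-ratio tests with the p-value halved
    to account for the boundary null of a zero variance.

    The crossed stimulus random intercept is absorbed by centring ratings
    on per-stimulus means before fitting the participant random-effect
    structure (its variance is reported from the spread of the stimulus
    means around the fixed-effect fit); fixed-effect estimates come from
    a companion random-intercept fit on the raw ratings.
    """
    p1, p2 = predictors
    missing = [c for c in predictors if c not in table.columns]
    if missing:
        raise ModelingError(f"predictors not in table: {missing}")
    z, _ = zstandardize(table[list(predictors)])
    df = ratings
    if "excluded" in df.columns:
        df = df.loc[~df["excluded"].astype(bool)]
    df = df[df["stimulus"].isin(z.index)].copy()
    df[p1] = z.loc[df["stimulus"], p1].to_numpy()
    df[p2] = z.loc[df["stimulus"], p2].to_numpy()
    stim_means = df.groupby("stimulus")["rating"].transform("mean")
    df["rating_c"] = df["rating"] - stim_means

    # companion fit on raw ratings for interpretable fixed effects
    exog = sm.add_constant(df[[p1, p2]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = sm.MixedLM(df["rating"], exog, groups=df["participant"]).fit(reml=False)
    fe_params = pd.Series(raw.fe_params, index=exog.columns)
    fe_bse = pd.Series(raw.bse_fe, index=exog.columns)
    stim_resid = df.groupby("stimulus")["rating"].mean() - (
        fe_params["const"] + z[p1] * fe_params[p1] + z[p2] * fe_params[p2]
    )
    stim_var = float(stim_resid.var(ddof=1))

    fits: list[MixedModelFit] = []
    for name, which in _LMM_LADDER:
        cols = []
        if "first" in which:
            cols.append(p1)
        if "second" in which:
            cols.append(p2)
        re_formula = "1" + "".join(f" + {c}" for c in cols)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM.from_formula(
                    f"rating_c ~ {p1} + {p2}",
                    data=df,
                    groups=df["participant"],
                    re_formula=re_formula,
                )
                res = model.fit(reml=False)
            cov_re = pd.DataFrame(res.cov_re)
            slope_vars = {c: float(cov_re.loc[c, c]) for c in cols}
            k = res.df_modelwc
            fits.append(
                MixedModelFit(
                    name=name,
                    random_slopes=tuple(cols),
                    fe_params=fe_params,
                    fe_bse=fe_bse,
                    participant_intercept_var=float(cov_re.iloc[0, 0]),
                    slope_vars=slope_vars,
                    stimulus_intercept_var=stim_var,
                    llf=float(res.llf),
                    aic=float(-2 * res.llf + 2 * k),
                    bic=float(-2 * res.llf + np.log(len(df)) * k),
                    n_params=int(k),
                    converged=bool(res.converged),
                )
            )
        except Exception as exc:  # keep remaining models on failure
            fits.append(
                MixedModelFit(
                    name=name,
                    random_slopes=tuple(cols),
                    fe_params=fe_params,
                    fe_bse=fe_bse,
                    participant_intercept_var=np.nan,
                    slope_vars={},
                    stimulus_intercept_var=stim_var,
                    llf=np.nan,
                    aic=np.nan,
                    bic=np.nan,
                    n_params=0,
                    converged=False,
                    error=str(exc),
                )
            )

    by_name = {f.name: f for f in fits}
    lrt = {}
    for label, alt, null in ((p1, "M2", "M1"), (p2, "M3", "M1")):
        fa, f0 = by_name[alt], by_name[null]
        if np.isnan(fa.llf) or np.isnan(f0.llf):
            lrt[label] = np.nan
            continue
        stat = max(0.0, 2 * (fa.llf - f0.llf))
        dof = max(1, fa.n_params - f0.n_params)
        # halved for the boundary test on a variance component
        lrt[label] = float(stats.chi2.sf(stat, dof) / 2.0)
    ok = [f for f in fits if not np.isnan(f.aic)]
    aic_ranking = [f.name for f in sorted(ok, key=lambda f: f.aic)]
    bic_ranking = [f.name for f in sorted(ok, key=lambda f: f.bic)]
    return LmmComparison(fits, lrt, aic_ranking, bic_ranking)
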