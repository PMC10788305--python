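"""Cohort statistics and sleep-based brain age.

The statistical layer that turns a subject x feature table of sleep
metrics into (i) per-feature age associations with covariate adjustment
and FDR control, (ii) a multivariable linear age-prediction model whose
residual — the *brain age gap*, predicted minus chronological age —
flags atypical development, and (iii) group contrasts and an age-bin
similarity profile.

Modelling conventions:

* covariates: sex as a binary indicator (reference "F"), race one-hot
  with reference level "white";
* outliers: per feature, values beyond 3 SD of the currently unmasked
  distribution are masked, in two rounds;
* feature pruning: greedy in a fixed column order, dropping any feature
  with |r| > 0.9 to an already-retained one (computed on the training
  sample);
* prediction: ordinary least squares of age on features z-scored with
  the training mean/SD plus covariates; 10-fold cross-validation
  reports per-fold R² and MAE; held-out and transfer predictions reuse
  the frozen z-parameters; missing feature values are imputed at the
  training mean;
* multiple testing: Benjamini-Hochberg within each tested family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as spstats
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

SEX_REFERENCE = "F"
RACE_REFERENCE = "white"


# ---------------------------------------------------------------------------
# outlier masking
# ---------------------------------------------------------------------------


def clean_outliers(table: pd.DataFrame, sd: float = 3.0, rounds: int = 2,
                   mode: str = "na_replace") -> pd.DataFrame:
    """Mask per-feature outliers beyond ``sd`` SDs, repeated ``rounds``
    times with statistics recomputed on survivors.

    Both modes mask cells with NaN ("remove" removes the value from all
    per-metric analyses, which for columnwise statistics is the same
    operation); constant features (SD 0) are left untouched.
    """
    if mode not in ("remove", "na_replace"):
        raise ValueError(f"unknown mode {mode!r}")
    out = table.copy()
    for col in out.columns:
        if not pd.api.types.is_numeric_dtype(out[col]):
            continue
        for _ in range(rounds):
            v = out[col]
            mu, sigma = v.mean(), v.std()
            if not np.isfinite(sigma) or sigma == 0:
                break
            mask = (v - mu).abs() > sd * sigma
            if not mask.any():
                break
            out.loc[mask, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# covariate encoding
# ---------------------------------------------------------------------------


def encode_covariates(subjects: pd.DataFrame,
                      include: tuple = ("sex", "race")) -> pd.DataFrame:
    """One-hot / indicator encoding of demographic covariates."""
    cols = {}
    if "sex" in include and "sex" in subjects:
        cols["sex_M"] = (subjects["sex"].astype(str) != SEX_REFERENCE).astype(float)
    if "race" in include and "race" in subjects:
        for level in sorted(subjects["race"].astype(str).unique()):
            if level != RACE_REFERENCE:
                cols[f"race_{level}"] = (subjects["race"].astype(str) == level).astype(float)
    if "ahi" in include and "ahi" in subjects:
        cols["ahi"] = subjects["ahi"].astype(float)
    if "medication" in include and "medication" in subjects:
        cols["medication"] = subjects["medication"].astype(float)
    return pd.DataFrame(cols, index=subjects.index)


# ---------------------------------------------------------------------------
# per-feature age associations
# ---------------------------------------------------------------------------


@dataclass
class AgeAssociation:
    feature: str
    beta: float
    p: float
    pearson_r: float
    quad_beta: float
    delta_aic: float   # AIC(quadratic) - AIC(linear); negative favors quadratic
    delta_bic: float
    fdr_q: float = np.nan
    n: int = 0


def fit_age_associations(features: pd.DataFrame, subjects: pd.DataFrame,
                         covariates: tuple = ("sex", "race"),
                         min_n: int = 20) -> pd.DataFrame:
    """Linear model of each feature on age with covariate adjustment.

    Per feature: feature ~ age + covariates (beta, p for the age term),
    the unadjusted Pearson r with age, and a quadratic comparison
    (adding age²) summarized by AIC/BIC differences.  BH-FDR q-values
    are computed across the tested set.
    """
    cov = encode_covariates(subjects, covariates)
    age = subjects["age"].astype(float)
    base = pd.concat([age.rename("age"), cov], axis=1)
    if np.linalg.matrix_rank(sm.add_constant(base).to_numpy()) < base.shape[1] + 1:
        corr = base.corr().abs()
        np.fill_diagonal(corr.values, 0)
        pairs = corr.stack().sort_values(ascending=False).head(3)
        raise ValueError(f"rank-deficient design; most collinear: {list(pairs.index)}")

    rows = []
    for feat in features.columns:
        y = features[feat].astype(float)
        ok = y.notna() & base.notna().all(axis=1)
        if ok.sum() < min_n:
            continue
        X = sm.add_constant(base[ok])
        fit_lin = sm.OLS(y[ok], X).fit()
        Xq = X.copy()
        Xq["age2"] = X["age"] ** 2
        fit_quad = sm.OLS(y[ok], Xq).fit()
        r, _ = spstats.pearsonr(age[ok], y[ok])
        rows.append(AgeAssociation(
            feature=feat, beta=fit_lin.params["age"],
            p=fit_lin.pvalues["age"], pearson_r=r,
            quad_beta=fit_quad.params["age2"],
            delta_aic=fit_quad.aic - fit_lin.aic,
            delta_bic=fit_quad.bic - fit_lin.bic,
            n=int(ok.sum())))
    df = pd.DataFrame([r.__dict__ for r in rows])
    if len(df):
        df["fdr_q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["fdr_q"] = np.maximum(df["fdr_q"], df["p"])
    return df


# ---------------------------------------------------------------------------
# feature pruning
# ---------------------------------------------------------------------------


def select_features(training: pd.DataFrame, r_threshold: float = 0.9,
                    order: list | None = None) -> list:
    """Greedy correlation pruning in a fixed, documented column order."""
    order = list(order) if order is not None else list(training.columns)
    corr = training[order].corr().abs()
    kept: list = []
    for feat in order:
        if training[feat].std(skipna=True) == 0 or training[feat].isna().all():
            continue
        if any(corr.loc[feat, k] > r_threshold for k in kept
               if np.isfinite(corr.loc[feat, k])):
            continue
        kept.append(feat)
    return kept


# ---------------------------------------------------------------------------
# brain-age model
# ---------------------------------------------------------------------------


@dataclass
class BrainAgeModel:
    features: list
    z_mean: pd.Series
    z_sd: pd.Series
    covariate_cols: list
    coef: np.ndarray
    intercept: float
    cv_r2: tuple = (np.nan, np.nan)    # mean, SD across folds
    cv_mae: tuple = (np.nan, np.nan)

    def design(self, features: pd.DataFrame, subjects: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in features.columns]
        if missing:
            raise ValueError(f"features absent from table: {missing}")
        Z = (features[self.features] - self.z_mean) / self.z_sd
        Z = Z.fillna(0.0)  # training-mean imputation in z-space
        cov = encode_covariates(subjects)
        for c in self.covariate_cols:
            if c not in cov:
                cov[c] = 0.0
        return np.column_stack([Z.to_numpy(), cov[self.covariate_cols].to_numpy()])

    def predict(self, features: pd.DataFrame, subjects: pd.DataFrame) -> "BrainAgeResult":
        X = self.design(features, subjects)
        pred = X @ self.coef + self.intercept
        return BrainAgeResult.from_predictions(
            subjects["age"].to_numpy(float), pred, subjects.index)


@dataclass
class BrainAgeResult:
    predictions: pd.DataFrame   # index subject, columns age, predicted, gap
    r: float
    mae: float
    me: float
    r2: float

    @classmethod
    def from_predictions(cls, age: np.ndarray, pred: np.ndarray, index) -> "BrainAgeResult":
        gap = pred - age
        ss_res = float(np.sum(gap**2))
        ss_tot = float(np.sum((age - age.mean())**2))
        r = float(np.corrcoef(age, pred)[0, 1]) if len(age) > 2 else np.nan
        return cls(
            predictions=pd.DataFrame(
                {"age": age, "predicted": pred, "gap": gap}, index=index),
            r=r, mae=float(np.mean(np.abs(gap))), me=float(np.mean(gap)),
            r2=1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan)


def fit_brain_age(features: pd.DataFrame, subjects: pd.DataFrame,
                  feature_list: list | None = None, n_folds: int = 10,
                  seed: int = 0) -> BrainAgeModel:
    """OLS of age on z-scored features + sex/race covariates.

    z-parameters are the training mean/SD and are frozen into the model
    for held-out prediction; CV reports mean and SD of per-fold R² and
    MAE on the training sample.
    """
    feats = feature_list if feature_list is not None else select_features(features)
    z_mean = features[feats].mean()
    z_sd = features[feats].std().replace(0.0, 1.0)
    cov = encode_covariates(subjects)
    model = BrainAgeModel(
        features=list(feats), z_mean=z_mean, z_sd=z_sd,
        covariate_cols=list(cov.columns),
        coef=np.zeros(len(feats) + cov.shape[1]), intercept=0.0)
    X = model.design(features, subjects)
    y = subjects["age"].to_numpy(float)

    reg = LinearRegression().fit(X, y)
    model.coef = reg.coef_
    model.intercept = float(reg.intercept_)

    if n_folds and n_folds > 1 and len(y) >= 2 * n_folds:
        r2s, maes = [], []
        for tr, te in KFold(n_folds, shuffle=True, random_state=seed).split(X):
            f = LinearRegression().fit(X[tr], y[tr])
            p = f.predict(X[te])
            ss_res = np.sum((y[te] - p) ** 2)
            ss_tot = np.sum((y[te] - y[te].mean()) ** 2)
            r2s.append(1 - ss_res / ss_tot if ss_tot > 0 else np.nan)
            maes.append(np.mean(np.abs(y[te] - p)))
        model.cv_r2 = (float(np.nanmean(r2s)), float(np.nanstd(r2s)))
        model.cv_mae = (float(np.mean(maes)), float(np.std(maes)))
    return model


# ---------------------------------------------------------------------------
# brain-age-gap group analysis
# ---------------------------------------------------------------------------


def gap_group_analysis(features: pd.DataFrame, subjects: pd.DataFrame,
                       pool_group: str = "non-NDD", n_rounds: int = 100,
                       train_frac: float = 0.7, seed: int = 0,
                       r_threshold: float = 0.9) -> pd.DataFrame:
    """Resampled brain-age-gap contrasts between fixed groups and the pool.

    Per round the non-group pool is resplit ``train_frac``/rest, the
    pruning + z-scoring + OLS pipeline is refit on the training part,
    and each fixed group's MAE/ME is compared with the held-out pool by
    two-sample t-tests.  Returns one row per group (plus the held-out
    pool) with mean/min/max of MAE and ME over rounds and median
    p-values (a convention that is anticonservative relative to a
    single pre-registered test).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pool_idx = subjects.index[subjects["group"] == pool_group]
    groups = [g for g in subjects["group"].unique() if g != pool_group]
    if len(pool_idx) < 20:
        raise ValueError("pool too small for resampled splits")

    stats: dict = {g: {"mae": [], "me": [], "p_mae": [], "p_me": [], "n": 0}
                   for g in groups}
    held_stats = {"mae": [], "me": []}
    for _ in range(n_rounds):
        perm = rng.permutation(len(pool_idx))
        n_train = int(round(train_frac * len(pool_idx)))
        tr_idx = pool_idx[perm[:n_train]]
        te_idx = pool_idx[perm[n_train:]]
        feats = select_features(features.loc[tr_idx], r_threshold)
        model = fit_brain_age(features.loc[tr_idx], subjects.loc[tr_idx],
                              feature_list=feats, n_folds=0)
        held = model.predict(features.loc[te_idx], subjects.loc[te_idx])
        held_gap = held.predictions["gap"].to_numpy()
        held_stats["mae"].append(held.mae)
        held_stats["me"].append(held.me)
        for g in groups:
            g_idx = subjects.index[subjects["group"] == g]
            res = model.predict(features.loc[g_idx], subjects.loc[g_idx])
            gap = res.predictions["gap"].to_numpy()
            stats[g]["n"] = len(g_idx)
            stats[g]["mae"].append(res.mae)
            stats[g]["me"].append(res.me)
            stats[g]["p_me"].append(
                spstats.ttest_ind(gap, held_gap, equal_var=False).pvalue)
            stats[g]["p_mae"].append(
                spstats.ttest_ind(np.abs(gap), np.abs(held_gap),
                                  equal_var=False).pvalue)

    rows = [{"group": pool_group + " (held-out)", "n": len(te_idx),
             "mae_mean": np.mean(held_stats["mae"]),
             "mae_min": np.min(held_stats["mae"]),
             "mae_max": np.max(held_stats["mae"]),
             "me_mean": np.mean(held_stats["me"]),
             "me_min": np.min(held_stats["me"]),
             "me_max": np.max(held_stats["me"]),
             "median_p_mae": np.nan, "median_p_me": np.nan}]
    for g in groups:
        s = stats[g]
        rows.append({"group": g, "n": s["n"],
                     "mae_mean": np.mean(s["mae"]), "mae_min": np.min(s["mae"]),
                     "mae_max": np.max(s["mae"]),
                     "me_mean": np.mean(s["me"]), "me_min": np.min(s["me"]),
                     "me_max": np.max(s["me"]),
                     "median_p_mae": np.median(s["p_mae"]),
                     "median_p_me": np.median(s["p_me"])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group-difference models
# ---------------------------------------------------------------------------


def group_difference_models(features: pd.DataFrame, subjects: pd.DataFrame,
                            group: str, reference_group: str = "non-NDD",
                            covariates: tuple = ("sex", "race", "ahi",
                                                 "medication")) -> pd.DataFrame:
    """Standardized group effects and group-by-age interactions.

    Each feature is z-scored over the analysis sample; the model is
    z(feature) ~ group + age + group:age + covariates.  BH-FDR is
    applied separately to the main-effect and interaction families.
    """
    mask = subjects["group"].isin([group, reference_group])
    if not (subjects["group"] == group).any():
        raise ValueError(f"empty group {group!r}")
    sub = subjects[mask]
    feat = features.loc[sub.index]
    g = (sub["group"] == group).astype(float)
    age = sub["age"].astype(float)
    cov = encode_covariates(sub, covariates)
    X0 = pd.concat([g.rename("group"), age.rename("age"),
                    (g * (age - age.mean())).rename("group_x_age"), cov], axis=1)

    rows = []
    for f in feat.columns:
        y = feat[f].astype(float)
        sd = y.std()
        if not np.isfinite(sd) or sd == 0:
            continue
        z = (y - y.mean()) / sd
        ok = z.notna() & X0.notna().all(axis=1)
        if ok.sum() < 20 or g[ok].sum() == 0:
            continue
        fit = sm.OLS(z[ok], sm.add_constant(X0[ok])).fit()
        rows.append({"feature": f,
                     "beta_group": fit.params["group"],
                     "p_group": fit.pvalues["group"],
                     "beta_interaction": fit.params["group_x_age"],
                     "p_interaction": fit.pvalues["group_x_age"],
                     "n": int(ok.sum())})
    df = pd.DataFrame(rows)
    if len(df):
        df["q_group"] = multipletests(df["p_group"], method="fdr_bh")[1]
        df["q_interaction"] = multipletests(df["p_interaction"],
                                            method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# age-bin similarity profile
# ---------------------------------------------------------------------------


def default_age_bins() -> list:
    """(center, width) age bins: 2-y windows at 3..13, 4-y at 16..80."""
    return ([(c, 2.0) for c in (3, 5, 7, 9, 11, 13)]
            + [(c, 4.0) for c in range(16, 84, 4)])


def profile_similarity(group_features: pd.DataFrame,
                       comparison_features: pd.DataFrame,
                       comparison_ages: pd.Series,
                       bins: list | None = None,
                       min_bin_n: int = 10) -> pd.DataFrame:
    """Mean absolute z-profile distance between a group and each age bin.

    Features are z-scored with the comparison sample's mean/SD; per age
    bin, the mean over features of |bin mean - group mean| is reported.
    Bins with fewer than ``min_bin_n`` comparison subjects are omitted.
    """
    bins = bins if bins is not None else default_age_bins()
    shared = [c for c in group_features.columns
              if c in comparison_features.columns]
    if not shared:
        raise ValueError("no shared features")
    mu = comparison_features[shared].mean()
    sd = comparison_features[shared].std().replace(0.0, 1.0)
    zc = (comparison_features[shared] - mu) / sd
    zg = (group_features[shared] - mu) / sd
    group_mean = zg.mean()

    rows = []
    ages = comparison_ages.astype(float)
    for center, width in bins:
        m = (ages >= center - width / 2) & (ages < center + width / 2)
        if m.sum() < min_bin_n:
            continue
        bin_mean = zc[m.to_numpy()].mean()
        rows.append({"bin_center": center, "n": int(m.sum()),
                     "mean_abs_diff": float((bin_mean - group_mean).abs().mean())})
    return pd.DataFrame(rows)
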