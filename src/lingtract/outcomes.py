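"""Relating tract metrics to naming decline.

Conventions used throughout:

* naming change is stored as ``delta = post - pre`` (negative = worse), but
  analyses and reports use the decline magnitude ``pre - post`` so that a
  positive correlation means "larger tract volume, greater decline";
* a decline of >= 4 Graded Naming Test items is clinically significant;
* missing follow-up scores propagate as missing and are excluded pairwise;
* analyses are referenced to the side of surgery (``v_surg_norm``,
  ``tract_li``) rather than to left/right.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from lingtract.exceptions import InputError, ValidationError
from lingtract.io import CohortTable

SIGNIFICANT_DECLINE = 4.0  # GNT items

#: Covariates of the multiple-regression and adjusted mixed models, in the
#: encoded design-column names produced by :func:`_encode_design`.
DEFAULT_COVARIATES = (
    "gnt_pre",
    "age_years",
    "onset_age_years",
    "duration_years",
    "sex_m",
    "education_level",
    "surgery_type_lesionectomy",
    "fmri_li",
)

TIMEPOINTS = ("4mo", "12mo")


def _as_df(cohort: CohortTable | pd.DataFrame) -> pd.DataFrame:
    return cohort.df if isinstance(cohort, CohortTable) else cohort


# --------------------------------------------------------------------------
# Decline scoring
# --------------------------------------------------------------------------


def decline_scores(cohort: CohortTable | pd.DataFrame) -> pd.DataFrame:
    """Per-subject naming change and clinical-significance flags.

    Returns a frame indexed like the cohort with ``delta_4mo``/``delta_12mo``
    (post - pre), ``decline_4mo``/``decline_12mo`` (pre - post) and boolean
    ``significant_4mo``/``significant_12mo`` (decline >= 4); all stay missing
    where the follow-up score is missing.
    """
    df = _as_df(cohort)
    out = pd.DataFrame({"id": df["id"]})
    for tp in TIMEPOINTS:
        post = df[f"gnt_{tp}"]
        out[f"delta_{tp}"] = post - df["gnt_pre"]
        out[f"decline_{tp}"] = df["gnt_pre"] - post
        sig = (df["gnt_pre"] - post) >= SIGNIFICANT_DECLINE
        out[f"significant_{tp}"] = sig.where(post.notna(), other=pd.NA)
    return out


# --------------------------------------------------------------------------
# Correlations
# --------------------------------------------------------------------------


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided t-based p, pairwise-deleting missing.

    Returns (nan, nan) when either vector has zero variance over the
    complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise InputError(f"need >= 3 complete pairs, have {int(ok.sum())}")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent correlations (two-sided)."""
    if n1 < 4 or n2 < 4:
        raise InputError("both samples must have n >= 4")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise InputError("degenerate correlation |r| >= 1")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# --------------------------------------------------------------------------
# Multiple regression and prediction evaluation
# --------------------------------------------------------------------------


def _encode_design(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding of the clinical covariates (binary dummies for
    sex = m and surgery_type = lesionectomy)."""
    enc = df.copy()
    if "sex" in enc:
        enc["sex_m"] = (enc["sex"] == "m").astype(float)
    if "surgery_type" in enc:
        enc["surgery_type_lesionectomy"] = (enc["surgery_type"] == "lesionectomy").astype(float)
    return enc


def _check_rank(X: pd.DataFrame) -> None:
    """Raise naming the collinear columns if the design is rank-deficient."""
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank >= arr.shape[1]:
        return
    # walk the columns; a column (numerically) in the span of its
    # predecessors is reported as collinear
    collinear = []
    basis: list[int] = []
    for j in range(arr.shape[1]):
        cols = basis + [j]
        if np.linalg.matrix_rank(arr[:, cols]) == len(basis):
            collinear.append(X.columns[j])
        else:
            basis.append(j)
    raise ValidationError(f"rank-deficient design; collinear columns: {collinear}")


@dataclass
class RegressionFit:
    """An OLS fit of naming decline on a tract predictor plus covariates."""

    predictor: str
    timepoint: str
    params: pd.Series
    pvalues: pd.Series
    f_stat: float
    df_model: int
    df_resid: int
    f_pvalue: float
    r2: float
    adj_r2: float
    fitted: pd.Series  # fitted decline (pre - post), indexed by subject id
    outcome: pd.Series  # actual decline, same index
    conf_int: pd.DataFrame  # 95% CI per coefficient (columns: lower, upper)
    design: pd.DataFrame = field(repr=False)


def fit_regression(
    cohort: CohortTable | pd.DataFrame,
    predictor: str,
    timepoint: str = "4mo",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> RegressionFit:
    """OLS of decline magnitude (pre - post) on a tract predictor + covariates.

    ``predictor`` is a cohort column (e.g. ``v_surg_norm`` or ``tract_li``);
    the default covariate block is preoperative naming score, age, onset age,
    epilepsy duration, sex, education level, surgery type and fMRI LI.
    Complete cases only; a rank-deficient design raises naming the collinear
    columns.
    """
    if timepoint not in TIMEPOINTS:
        raise InputError(f"timepoint must be one of {TIMEPOINTS}")
    df = _encode_design(_as_df(cohort))
    cols = [predictor, *covariates]
    y = (df["gnt_pre"] - df[f"gnt_{timepoint}"]).astype(float)
    keep = y.notna()
    for c in cols:
        keep &= pd.to_numeric(df[c], errors="coerce").notna()
    n = int(keep.sum())
    if n < len(cols) + 2:
        raise InputError(f"{n} complete cases for {len(cols)} regressors")
    sub = df.loc[keep]
    X = sub[cols].astype(float)
    X = sm.add_constant(X, prepend=True)
    _check_rank(X)
    res = sm.OLS(y[keep].to_numpy(), X.to_numpy()).fit()
    idx = pd.Index(sub["id"], name="id")
    names = list(X.columns)
    return RegressionFit(
        predictor=predictor,
        timepoint=timepoint,
        params=pd.Series(res.params, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        f_stat=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        f_pvalue=float(res.f_pvalue),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        fitted=pd.Series(res.fittedvalues, index=idx),
        outcome=pd.Series(y[keep].to_numpy(), index=idx),
        conf_int=pd.DataFrame(
            res.conf_int(alpha=0.05), index=names, columns=["lower", "upper"]
        ),
        design=X.set_index(idx),
    )


@dataclass(frozen=True)
class PredictionEvaluation:
    """2x2 cross-tabulation of predicted vs actual clinically significant decline."""

    tp: int  # predicted decline, actual decline
    fp: int  # predicted decline, no actual decline
    fn: int  # predicted no decline, actual decline
    tn: int  # predicted no decline, no actual decline

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity_pct(self) -> float:
        """TP / (TP + FN) in percent; missing (nan) with no actual decliners."""
        if self.tp + self.fn == 0:
            return float("nan")
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity_pct(self) -> float:
        if self.tn + self.fp == 0:
            return float("nan")
        return 100.0 * self.tn / (self.tn + self.fp)

    def rounded(self) -> tuple[float, float]:
        """(sensitivity, specificity) rounded to whole percent for reporting."""
        s, p = self.sensitivity_pct, self.specificity_pct
        return (
            float("nan") if np.isnan(s) else round(s),
            float("nan") if np.isnan(p) else round(p),
        )


def contingency(predicted, actual) -> PredictionEvaluation:
    """Cross-tabulate boolean predicted vs actual decline flags."""
    predicted = np.asarray(predicted, dtype=bool)
    actual = np.asarray(actual, dtype=bool)
    if predicted.shape != actual.shape:
        raise InputError("predicted and actual must have equal length")
    return PredictionEvaluation(
        tp=int(np.sum(predicted & actual)),
        fp=int(np.sum(predicted & ~actual)),
        fn=int(np.sum(~predicted & actual)),
        tn=int(np.sum(~predicted & ~actual)),
    )


def evaluate_prediction(
    fit: RegressionFit,
    threshold: float = SIGNIFICANT_DECLINE,
    loo: bool = False,
) -> PredictionEvaluation:
    """Dichotomize a regression fit's predictions against actual decline.

    A subject is predicted to decline when the model's fitted decline
    (pre - post), rounded to the integer score scale of the naming test,
    reaches ``threshold`` (default: the same >= 4-item rule applied to
    actual scores; rounding first avoids a systematic half-point bias when
    continuous predictions are compared with integer score changes).
    ``loo=True`` replaces in-sample fitted values with leave-one-out
    predictions.
    """
    if loo:
        X = fit.design.to_numpy(dtype=float)
        y = fit.outcome.to_numpy(dtype=float)
        preds = np.empty(len(y))
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            beta = np.linalg.lstsq(X[keep], y[keep], rcond=None)[0]
            preds[i] = X[i] @ beta
        fitted = preds
    else:
        fitted = fit.fitted.to_numpy(dtype=float)
    return contingency(
        np.rint(fitted) >= threshold, fit.outcome.to_numpy(dtype=float) >= threshold
    )


# --------------------------------------------------------------------------
# Linear mixed-effects model
# --------------------------------------------------------------------------


def to_long(
    cohort: CohortTable | pd.DataFrame, value_cols: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Long-format decline table: one row per subject x available time point.

    Columns: ``id``, ``decline`` (pre - post), ``time_12mo`` (0/1 indicator)
    plus any carried subject-level ``value_cols``. Missing follow-ups are
    dropped.
    """
    df = _encode_design(_as_df(cohort))
    rows = []
    for tp, flag in (("4mo", 0.0), ("12mo", 1.0)):
        sub = df[df[f"gnt_{tp}"].notna()]
        chunk = pd.DataFrame(
            {
                "id": sub["id"],
                "decline": (sub["gnt_pre"] - sub[f"gnt_{tp}"]).astype(float),
                "time_12mo": flag,
            }
        )
        for c in value_cols:
            chunk[c] = sub[c].to_numpy()
        rows.append(chunk)
    return pd.concat(rows, ignore_index=True)


@dataclass
class MixedModelFit:
    """Random-intercept ML fit of decline on a tract predictor + time point."""

    predictor: str
    fe_params: pd.Series
    random_intercept_var: float
    resid_var: float
    llf: float
    llf_null: float
    chi2: float
    chi2_df: int
    p: float
    marginal_r2: float
    n_obs: int
    n_subjects: int
    used_ols_fallback: bool = False


def _ml_mixed_llf(endog, exog, groups):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, exog, groups=groups)
        res = model.fit(reml=False)
    return res


def fit_mixed_model(
    long_df: pd.DataFrame,
    predictor: str,
    covariates: tuple[str, ...] = (),
) -> MixedModelFit:
    """Fit decline ~ predictor + time point with a per-subject random intercept.

    Fitted by maximum likelihood so the likelihood-ratio chi-squared against
    the nested null model (same terms without the predictor) is valid.
    Marginal R^2 is the fixed-effects share of the modelled variance
    (var(X beta) over var(X beta) + random-intercept variance + residual
    variance). When every subject contributes a single row the model
    degenerates to OLS (with a warning), not an exception.
    """
    needed = ["id", "decline", "time_12mo", predictor, *covariates]
    missing = [c for c in needed if c not in long_df.columns]
    if missing:
        raise InputError(f"long table missing columns {missing}")
    df = long_df.dropna(subset=needed)
    fixed = [predictor, "time_12mo", *covariates]
    X = sm.add_constant(df[fixed].astype(float), prepend=True)
    X0 = X.drop(columns=[predictor])
    y = df["decline"].to_numpy(dtype=float)
    groups = df["id"].to_numpy()
    n_subjects = len(np.unique(groups))

    single_row = n_subjects == len(df)
    if single_row:
        warnings.warn(
            "every subject contributes one row; mixed model degenerates to OLS",
            stacklevel=2,
        )
        full = sm.OLS(y, X.to_numpy()).fit()
        null = sm.OLS(y, X0.to_numpy()).fit()
        re_var = 0.0
        resid_var = float(full.scale)
        fe = pd.Series(full.params, index=list(X.columns))
        llf_full, llf_null = float(full.llf), float(null.llf)
    else:
        full = _ml_mixed_llf(y, X, groups)
        null = _ml_mixed_llf(y, X0, groups)
        re_var = float(np.asarray(full.cov_re)[0, 0])
        resid_var = float(full.scale)
        fe = pd.Series(np.asarray(full.fe_params), index=list(X.columns))
        llf_full, llf_null = float(full.llf), float(null.llf)

    chi2 = max(0.0, 2.0 * (llf_full - llf_null))
    p = float(stats.chi2.sf(chi2, df=1))
    fixed_fit = X.to_numpy(dtype=float) @ fe.to_numpy()
    var_f = float(np.var(fixed_fit))
    marginal_r2 = var_f / (var_f + re_var + resid_var) if (var_f + re_var + resid_var) > 0 else 0.0
    return MixedModelFit(
        predictor=predictor,
        fe_params=fe,
        random_intercept_var=re_var,
        resid_var=resid_var,
        llf=llf_full,
        llf_null=llf_null,
        chi2=chi2,
        chi2_df=1,
        p=p,
        marginal_r2=marginal_r2,
        n_obs=len(df),
        n_subjects=n_subjects,
        used_ols_fallback=single_row,
    )


# --------------------------------------------------------------------------
# Seizure outcome vs naming decline
# --------------------------------------------------------------------------


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table; empty margins give p = 1."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise InputError("expected a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def seizure_outcome_test(
    cohort: CohortTable | pd.DataFrame, timepoint: str = "4mo"
) -> float:
    """Fisher exact test of seizure freedom vs clinically significant decline."""
    df = _as_df(cohort)
    if "seizure_free" not in df.columns:
        raise InputError("cohort lacks a seizure_free column")
    scores = decline_scores(df)
    sig = scores[f"significant_{timepoint}"]
    keep = sig.notna()
    sf = df.loc[keep, "seizure_free"].astype(bool).to_numpy()
    dec = sig[keep].astype(bool).to_numpy()
    table = [
        [int(np.sum(sf & dec)), int(np.sum(sf & ~dec))],
        [int(np.sum(~sf & dec)), int(np.sum(~sf & ~dec))],
    ]
    return fisher_exact_2x2(table)
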