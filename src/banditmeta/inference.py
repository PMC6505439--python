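"""Statistical models for the bandit trial logs.

The three study regressions are exposed as convenience wrappers around a
single hierarchical fitting routine:

* ``decision_confidence_model`` — linear model of decision confidence on
  the carried value and belief-confidence ratings of the chosen and
  unchosen option (plus their value interaction), objective accuracy and
  log RT.
* ``exploration_model`` — logistic model of choosing the lower-rated
  option (exploration) on the belief confidence of the higher-rated
  option, the absolute value difference, and their interaction.
* ``belief_confidence_model`` — linear model of belief confidence on the
  running standard deviation and mean of past outcomes (the ideal-observer
  predictors), log trial number and arm, with the two-way interactions
  among the first three and their three-way interaction.

Linear mixed models are fitted by maximum likelihood with statsmodels'
``MixedLM``; when the requested random structure fails to converge the
fitter falls down a ladder (all slopes -> main-effect slopes -> random
intercept -> per-subject fits pooled by inverse variance) and records
which structure produced the reported estimates. Logistic models use the
two-stage route (per-subject maximum likelihood, random-effects pooling
with a DerSimonian-Laird heterogeneity estimate), since no installed
package fits frequentist random-slope logistic mixed models.

All predictors are z-standardized before fitting, so coefficients are
standardized betas; interaction columns are products of the standardized
main effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelSpec",
    "RegressionResult",
    "StatResult",
    "fit_hierarchical",
    "decision_confidence_model",
    "exploration_model",
    "belief_confidence_model",
    "rating_arm_table",
    "halves_estimation_error",
    "quintile_trend_anova",
    "update_vs_confidence_correlation",
]

STRUCTURE_LADDER = ("full_slopes", "main_slopes", "intercept", "two_stage")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one hierarchical regression.

    ``fixed_terms`` are column names or colon-joined interactions
    (``"a:b"``); interactions are formed as products of the standardized
    main-effect columns.
    """

    outcome: str
    fixed_terms: tuple[str, ...]
    family: str = "linear"  # 'linear' | 'logistic'
    structure: str = "intercept"  # entry point on the random-structure ladder
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.structure not in STRUCTURE_LADDER:
            raise ValueError(f"unknown structure {self.structure!r}")


@dataclass
class RegressionResult:
    """Fixed-effect table, BIC and bookkeeping for one fitted model."""

    model: str
    terms: pd.DataFrame  # columns: term, beta, se, stat, p
    bic: float
    n_obs: int
    n_subjects: int
    converged: bool
    structure: str  # random structure that actually produced the fit
    per_subject: pd.DataFrame | None = None  # per-subject betas (two-stage)

    def beta(self, term: str) -> float:
        row = self.terms[self.terms["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r} in model {self.model!r}")
        return float(row["beta"].iloc[0])

    def se(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "se"])

    def ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        b, s = self.beta(term), self.se(term)
        return b - z * s, b + z * s

    def to_frame(self) -> pd.DataFrame:
        out = self.terms.copy()
        out.insert(0, "model", self.model)
        out["bic"] = self.bic
        out["structure"] = self.structure
        return out


@dataclass
class StatResult:
    """A single test statistic (t, F or r) with df, p and effect size."""

    statistic: float
    df: tuple[float, float]
    p_value: float
    effect_size: float | None = None
    means: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# design-matrix construction


def _build_design(
    data: pd.DataFrame, spec: ModelSpec, subject_col: str
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    base = sorted({c for t in spec.fixed_terms for c in t.split(":")})
    needed = [spec.outcome, *base, subject_col]
    d = data[needed].dropna().reset_index(drop=True)
    if d[spec.outcome].nunique() < 2:
        raise ValueError(f"outcome {spec.outcome!r} is degenerate")
    y = d[spec.outcome].astype(float)
    if spec.standardize and spec.family == "linear":
        y = (y - y.mean()) / y.std(ddof=0)
    X = pd.DataFrame(index=d.index)
    cols = {}
    for c in base:
        v = d[c].astype(float)
        if spec.standardize:
            sd = v.std(ddof=0)
            if sd == 0:
                warnings.warn(f"predictor {c!r} is constant")
                sd = 1.0
            v = (v - v.mean()) / sd
        cols[c] = v
    for term in spec.fixed_terms:
        parts = term.split(":")
        X[term] = np.prod([cols[p] for p in parts], axis=0)
    return X, y, d[subject_col]


def _n_cov_params(re_dim: int) -> int:
    return re_dim * (re_dim + 1) // 2


def _fit_mixedlm(
    X: pd.DataFrame, y: pd.Series, groups: pd.Series, structure: str
) -> tuple[pd.DataFrame, float, bool]:
    exog = sm.add_constant(X, prepend=True)
    if structure == "intercept":
        exog_re = np.ones((len(y), 1))
    else:
        if structure == "full_slopes":
            slope_cols = list(X.columns)
        else:  # main_slopes
            slope_cols = [c for c in X.columns if ":" not in c]
        exog_re = sm.add_constant(X[slope_cols], prepend=True)
    model = sm.MixedLM(y.to_numpy(), exog, groups=groups.to_numpy(),
                       exog_re=np.asarray(exog_re, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False, maxiter=200)
    fe = res.fe_params
    se = res.bse_fe
    if not (res.converged and np.all(np.isfinite(se))):
        raise RuntimeError(f"MixedLM did not converge ({structure})")
    k = len(fe) + _n_cov_params(np.asarray(exog_re).shape[1]) + 1
    bic = -2.0 * res.llf + k * np.log(len(y))
    z = np.asarray(fe) / np.asarray(se)
    p = 2.0 * stats.norm.sf(np.abs(z))
    terms = pd.DataFrame(
        {"term": list(exog.columns), "beta": np.asarray(fe),
         "se": np.asarray(se), "stat": z, "p": p}
    )
    return terms, float(bic), True


def _per_subject_fits(
    X: pd.DataFrame, y: pd.Series, groups: pd.Series, family: str
) -> tuple[pd.DataFrame, float]:
    """Per-subject ML fits; returns the beta table and the summed BIC."""
    rows, bic_total = [], 0.0
    for subject, idx in X.groupby(groups, sort=False).groups.items():
        Xi = sm.add_constant(X.loc[idx], prepend=True, has_constant="add")
        yi = y.loc[idx]
        if len(yi) <= Xi.shape[1] + 1:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if family == "linear":
                    res = sm.OLS(yi, Xi).fit()
                else:
                    if yi.nunique() < 2:
                        continue
                    res = sm.GLM(yi, Xi, family=sm.families.Binomial()).fit(
                        maxiter=200
                    )
        except Exception:
            continue
        se = np.asarray(res.bse)
        beta = np.asarray(res.params)
        if not np.all(np.isfinite(se)) or np.any(se > 1e3):
            continue  # quasi-separation or rank deficiency
        k = Xi.shape[1] + (1 if family == "linear" else 0)
        bic_total += -2.0 * res.llf + k * np.log(len(yi))
        rows.append(
            {"subject": subject, "n": len(yi),
             **{t: b for t, b in zip(Xi.columns, beta)},
             **{f"se_{t}": s for t, s in zip(Xi.columns, se)}}
        )
    return pd.DataFrame(rows), bic_total


def _pool_two_stage(per_subject: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Random-effects (DerSimonian-Laird) pooling of per-subject betas."""
    rows = []
    for t in terms:
        b = per_subject[t].to_numpy(dtype=float)
        v = per_subject[f"se_{t}"].to_numpy(dtype=float) ** 2
        v = np.maximum(v, 1e-12)  # constant predictors give exact-zero SEs
        w = 1.0 / v
        b_fe = np.sum(w * b) / np.sum(w)
        q = np.sum(w * (b - b_fe) ** 2)
        df = len(b) - 1
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        w_re = 1.0 / (v + tau2)
        beta = np.sum(w_re * b) / np.sum(w_re)
        se = np.sqrt(1.0 / np.sum(w_re))
        z = beta / se
        rows.append(
            {"term": t, "beta": beta, "se": se, "stat": z,
             "p": 2.0 * stats.norm.sf(abs(z))}
        )
    return pd.DataFrame(rows)


def fit_hierarchical(
    spec: ModelSpec,
    data: pd.DataFrame,
    subject_col: str = "subject",
    name: str | None = None,
) -> RegressionResult:
    """Fit a hierarchical regression, falling down the structure ladder.

    The requested ``spec.structure`` is tried first; each failure moves one
    rung down (``full_slopes -> main_slopes -> intercept -> two_stage``).
    The returned result records the structure that actually converged and
    always carries the per-subject fit table for downstream per-subject
    analyses.
    """
    X, y, groups = _build_design(data, spec, subject_col)
    n_subjects = groups.nunique()
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for a hierarchical fit")
    per_subject, bic_ps = _per_subject_fits(X, y, groups, spec.family)
    model_name = name or f"{spec.family}:{spec.outcome}"

    start = STRUCTURE_LADDER.index(spec.structure)
    if spec.family == "logistic":
        start = STRUCTURE_LADDER.index("two_stage")
    for structure in STRUCTURE_LADDER[start:]:
        if structure == "two_stage":
            if per_subject.empty or len(per_subject) < 2:
                raise RuntimeError("two-stage fit failed: no usable subjects")
            terms = _pool_two_stage(per_subject, ["const", *X.columns])
            return RegressionResult(
                model=model_name, terms=terms, bic=float(bic_ps),
                n_obs=len(y), n_subjects=n_subjects, converged=True,
                structure="two_stage", per_subject=per_subject,
            )
        try:
            terms, bic, ok = _fit_mixedlm(X, y, groups, structure)
        except Exception:
            continue
        return RegressionResult(
            model=model_name, terms=terms, bic=bic, n_obs=len(y),
            n_subjects=n_subjects, converged=ok, structure=structure,
            per_subject=per_subject,
        )
    raise RuntimeError("hierarchical fit failed at every ladder structure")


# ---------------------------------------------------------------------------
# study regressions


def decision_confidence_model(
    view: pd.DataFrame, structure: str = "intercept"
) -> RegressionResult:
    """Linear model of decision confidence on carried beliefs and controls.

    Expects a choice view (``preprocess.make_choice_view``) with carried
    ratings, ``accuracy`` and ``rt_ms``. RTs are log-transformed before
    standardization.
    """
    d = view.copy()
    d["log_rt"] = np.log(d["rt_ms"])
    spec = ModelSpec(
        outcome="decision_conf",
        fixed_terms=(
            "v_chosen", "v_unchosen", "v_chosen:v_unchosen",
            "c_chosen", "c_unchosen", "accuracy", "log_rt",
        ),
        family="linear",
        structure=structure,
    )
    return fit_hierarchical(spec, d, name="decision_confidence")


def exploration_model(view: pd.DataFrame) -> RegressionResult:
    """Logistic model of exploration on C_high, |DV| and their interaction."""
    spec = ModelSpec(
        outcome="explore",
        fixed_terms=("c_high", "abs_dv", "c_high:abs_dv"),
        family="logistic",
    )
    return fit_hierarchical(spec, view, name="exploration")


def rating_arm_table(log: pd.DataFrame) -> pd.DataFrame:
    """One row per (rating trial, rated arm) with ideal-observer predictors.

    ``sigma_past`` / ``mu_past`` are the running SD and mean of all
    outcomes observed for the rated arm up to and including the current
    trial's reveal (designs that show an outcome on rating trials reveal
    it before the rating is given). Rows with fewer than two past
    outcomes, where the running SD is undefined, are dropped.
    """
    from .preprocess import add_running_outcome_stats

    log = add_running_outcome_stats(log)
    rating = log[log["trial_type"] == "rating"]
    parts = []
    for which in ("primary", "other"):
        if which == "primary":
            sub = rating
            arm = sub["arm"].to_numpy()
            conf, val = sub["belief_conf"], sub["value_rating"]
        else:
            sub = rating[rating["belief_conf_other"].notna()]
            arm = 1 - sub["arm"].to_numpy()
            conf, val = sub["belief_conf_other"], sub["value_rating_other"]
        pick = lambda c0, c1: np.where(arm == 0, sub[c0], sub[c1])  # noqa: E731
        observed = sub["outcome"].notna() & (sub["arm"].to_numpy() == arm)
        # include the current reveal in the running moments where shown
        n0 = pick("run_n_0", "run_n_1").astype(float)
        s_mean = pick("run_mean_0", "run_mean_1")
        s_sd = pick("run_sd_0", "run_sd_1")
        out = sub["outcome"].to_numpy(dtype=float)
        n1 = n0 + observed.to_numpy()
        with np.errstate(invalid="ignore"):
            mean_incl = np.where(
                observed, (np.nan_to_num(s_mean) * n0 + out) / np.maximum(n1, 1),
                s_mean,
            )
            m2_prev = np.nan_to_num(s_sd**2) * np.maximum(n0 - 1, 0)
            m2_incl = np.where(
                observed & (n0 > 0),
                m2_prev + (out - np.nan_to_num(s_mean))
                * (out - mean_incl),
                m2_prev,
            )
            sd_incl = np.where(
                n1 > 1, np.sqrt(np.maximum(m2_incl, 0.0) / np.maximum(n1 - 1, 1)),
                np.nan,
            )
        parts.append(
            pd.DataFrame(
                {
                    "subject": sub["subject"].to_numpy(),
                    "block": sub["block"].to_numpy(),
                    "trial": sub["trial"].to_numpy(),
                    "arm": arm,
                    "value_rating": val.to_numpy(dtype=float),
                    "belief_conf": conf.to_numpy(dtype=float),
                    "mu_past": mean_incl,
                    "sigma_past": sd_incl,
                    "n_past": n1,
                    "log_trial": np.log(sub["trial"].to_numpy(dtype=float)),
                }
            )
        )
    table = pd.concat(parts, ignore_index=True)
    table = table[table["n_past"] >= 2].reset_index(drop=True)
    return table.sort_values(["subject", "block", "trial", "arm"]).reset_index(
        drop=True
    )


def belief_confidence_model(
    rating_table: pd.DataFrame, structure: str = "intercept"
) -> RegressionResult:
    """Ideal-observer regression of belief confidence.

    Input is ``rating_arm_table`` output (or any frame with
    ``belief_conf``, ``sigma_past``, ``mu_past``, ``log_trial``, ``arm``).
    The per-subject ``sigma_past`` betas in ``result.per_subject`` feed the
    metacognition link analysis.
    """
    spec = ModelSpec(
        outcome="belief_conf",
        fixed_terms=(
            "sigma_past", "mu_past", "log_trial", "arm",
            "sigma_past:mu_past", "sigma_past:log_trial", "mu_past:log_trial",
            "sigma_past:mu_past:log_trial",
        ),
        family="linear",
        structure=structure,
    )
    return fit_hierarchical(spec, rating_table, name="belief_confidence")


# ---------------------------------------------------------------------------
# descriptive tests


def halves_estimation_error(log: pd.DataFrame) -> StatResult:
    """Estimation error (|rating - running outcome mean|) by block half.

    The error of each rating is measured against the running mean of the
    outcomes observed for the rated arm so far (including the current
    reveal). Block halves split at the middle trial (middle trial goes to
    the first half for odd lengths); per-subject means are compared with a
    paired t-test.
    """
    table = rating_arm_table(log)
    table = table[table["n_past"] >= 1]
    # only the arm actually shown carries an error vs the observed stream
    table = table.dropna(subset=["mu_past", "value_rating"])
    err = (table["value_rating"] - table["mu_past"]).abs()
    block_len = (
        log.groupby(["subject", "block"])["trial"].max().rename("block_len")
    )
    table = table.join(block_len, on=["subject", "block"])
    half = np.where(
        table["trial"] <= np.ceil(table["block_len"] / 2.0), "first", "second"
    )
    d = pd.DataFrame(
        {"subject": table["subject"], "half": half, "err": err.to_numpy()}
    )
    per = d.groupby(["subject", "half"])["err"].mean().unstack("half")
    per = per.dropna()
    diff = per["first"] - per["second"]
    means = {
        "first_half": float(per["first"].mean()),
        "second_half": float(per["second"].mean()),
    }
    if len(per) < 2 or float(diff.std(ddof=1)) < 1e-9:
        return StatResult(
            statistic=float("nan"), df=(len(per) - 1, 0), p_value=float("nan"),
            means=means, extra={"degenerate": True},
        )
    t, p = stats.ttest_rel(per["first"], per["second"])
    return StatResult(
        statistic=float(t), df=(len(per) - 1, 0), p_value=float(p), means=means
    )


def quintile_trend_anova(
    view: pd.DataFrame, value_col: str, bin_col: str = "conf_bin"
) -> StatResult:
    """Repeated-measures ANOVA across within-subject confidence bins.

    Applies the Greenhouse-Geisser sphericity correction and reports
    partial eta squared, plus the linear polynomial-contrast F across the
    ordered bins in ``extra['linear_F']`` / ``extra['linear_p']``.
    Subjects missing any bin are dropped with a warning.
    """
    cell = (
        view.dropna(subset=[value_col, bin_col])
        .groupby(["subject", bin_col])[value_col]
        .mean()
        .unstack(bin_col)
    )
    complete = cell.dropna()
    if len(complete) < len(cell):
        warnings.warn(
            f"{len(cell) - len(complete)} subject(s) missing a bin; dropped"
        )
    data = complete.to_numpy()
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 bins")
    grand = data.mean()
    subj_means = data.mean(axis=1, keepdims=True)
    cond_means = data.mean(axis=0, keepdims=True)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_err = np.sum((data - subj_means - cond_means + grand) ** 2)
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    f_stat = ms_cond / ms_err if ms_err > 0 else 0.0
    # Greenhouse-Geisser epsilon from the double-centred covariance matrix
    cov = np.cov(data, rowvar=False, ddof=1)
    cc = cov - cov.mean(axis=0, keepdims=True) - cov.mean(axis=1, keepdims=True) \
        + cov.mean()
    eps = float(np.trace(cc) ** 2 / ((k - 1) * np.sum(cc**2)))
    eps = min(max(eps, 1.0 / (k - 1)), 1.0)
    df1, df2 = df_cond * eps, df_err * eps
    p = float(stats.f.sf(f_stat, df1, df2)) if ms_err > 0 else float("nan")
    eta_p2 = float(ss_cond / (ss_cond + ss_err)) if ss_cond + ss_err > 0 else 0.0
    # linear polynomial contrast
    w = np.arange(k, dtype=float) - (k - 1) / 2.0
    scores = data @ w
    t_lin, p_lin = stats.ttest_1samp(scores, 0.0)
    ss_lin = n * np.mean(scores) ** 2 * len(w) / np.sum(w**2)
    return StatResult(
        statistic=float(f_stat),
        df=(float(df1), float(df2)),
        p_value=p,
        effect_size=eta_p2,
        means={int(b): float(m) for b, m in zip(complete.columns, data.mean(0))},
        extra={
            "linear_F": float(t_lin**2),
            "linear_df": (1.0, float(n - 1)),
            "linear_p": float(p_lin),
            "linear_slope_sign": float(np.sign(np.mean(scores))),
            "gg_epsilon": eps,
            "n_subjects": n,
        },
    )


def update_vs_confidence_correlation(log: pd.DataFrame) -> pd.DataFrame:
    """Per-subject correlation of update size with belief-confidence change.

    For consecutive ratings of the same arm within a block, correlates the
    absolute difference between the newly observed outcome and the
    previous value rating of that arm with the change in belief
    confidence. Subjects with fewer than 5 usable pairs are skipped.
    Returns a frame with columns ``subject``, ``r``, ``p``, ``n_pairs``.
    """
    rows = []
    rating = log[log["trial_type"] == "rating"].copy()
    rating = rating.sort_values(["subject", "block", "trial"], kind="stable")
    for subject, grp in rating.groupby("subject", sort=False):
        xs, ys = [], []
        for (_, arm), g in grp.groupby(["block", "arm"], sort=False):
            v = g["value_rating"].to_numpy(dtype=float)
            c = g["belief_conf"].to_numpy(dtype=float)
            o = g["outcome"].to_numpy(dtype=float)
            for i in range(1, len(g)):
                if np.isnan(o[i]) or np.isnan(v[i - 1]) or np.isnan(c[i]):
                    continue
                xs.append(abs(o[i] - v[i - 1]))
                ys.append(c[i] - c[i - 1])
        if len(xs) < 5:
            continue
        if np.std(xs) == 0.0 or np.std(ys) == 0.0:
            continue
        r, p = stats.pearsonr(xs, ys)
        rows.append(
            {"subject": subject, "r": float(r), "p": float(p),
             "n_pairs": len(xs)}
        )
    return pd.DataFrame(rows)
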