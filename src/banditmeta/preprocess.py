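"""Data-preparation rules applied before any statistical modelling.

Covers per-subject reaction-time outlier exclusion, within-subject
z-scoring, carrying the most recent value/confidence ratings of each arm
forward onto subsequent choice trials, exploration and objective-accuracy
labelling, and within-subject quintile binning.

Carried ratings reset at block boundaries because the arm payout
distributions change between blocks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "exclude_rt_outliers",
    "zscore_within_subject",
    "carry_forward",
    "label_exploration",
    "label_objective_accuracy",
    "add_running_outcome_stats",
    "bin_quintiles",
    "make_choice_view",
]


def exclude_rt_outliers(
    log: pd.DataFrame, n_sigma: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop choice trials whose RT is beyond mean +/- ``n_sigma`` SD.

    The rule is applied separately per subject and two-tailed, removing
    both fast lapses and very slow (distracted) responses. Rating trials
    are never excluded. Subjects with fewer than 3 choice trials are
    skipped with a warning. Returns ``(filtered_log, report)`` where the
    report lists per-subject exclusion counts and fractions.
    """
    drop = pd.Series(False, index=log.index)
    rows = []
    for subject, grp in log.groupby("subject", sort=False):
        choice = grp[grp["trial_type"] == "choice"]
        n_choice = len(choice)
        if n_choice < 3:
            warnings.warn(
                f"subject {subject}: fewer than 3 choice trials, skipping "
                "RT exclusion"
            )
            rows.append({"subject": subject, "n_choice": n_choice,
                         "n_excluded": 0, "fraction": 0.0})
            continue
        rt = choice["rt_ms"]
        mean, sd = rt.mean(), rt.std(ddof=1)
        out = (rt - mean).abs() > n_sigma * sd
        drop.loc[choice.index[out]] = True
        rows.append(
            {
                "subject": subject,
                "n_choice": n_choice,
                "n_excluded": int(out.sum()),
                "fraction": float(out.sum() / n_choice),
            }
        )
    return log[~drop].reset_index(drop=True), pd.DataFrame(rows)


def zscore_within_subject(
    values: pd.Series, subjects: pd.Series
) -> pd.Series:
    """Standardize to per-subject mean 0 and population SD 1.

    Missing values propagate. A zero-variance subject yields zeros with a
    warning.
    """
    out = pd.Series(np.nan, index=values.index, dtype=float)
    for subject, idx in values.groupby(subjects, sort=False).groups.items():
        v = values.loc[idx]
        mean = v.mean()
        sd = v.std(ddof=0)
        if not np.isfinite(sd) or sd == 0.0:
            if v.notna().sum() > 0:
                warnings.warn(f"subject {subject}: zero variance in z-score")
            out.loc[idx] = np.where(v.notna(), 0.0, np.nan)
        else:
            out.loc[idx] = (v - mean) / sd
    return out


def _carry_group(grp: pd.DataFrame) -> pd.DataFrame:
    """Carried ratings for one subject-block group (time-ordered)."""
    out = {}
    for arm in (0, 1):
        for what, col, col_other in (
            ("value", "value_rating", "value_rating_other"),
            ("conf", "belief_conf", "belief_conf_other"),
        ):
            is_rating = grp["trial_type"] == "rating"
            s = pd.Series(np.nan, index=grp.index)
            direct = is_rating & (grp["arm"] == arm)
            s[direct] = grp.loc[direct, col]
            if col_other in grp.columns:
                other = (
                    is_rating & (grp["arm"] == 1 - arm)
                    & grp[col_other].notna()
                )
                s[other] = grp.loc[other, col_other]
            # last rating strictly before the current row
            out[f"cf_{what}_{arm}"] = s.ffill().shift(1)
    return pd.DataFrame(out, index=grp.index)


def carry_forward(log: pd.DataFrame) -> pd.DataFrame:
    """Attach each arm's most recent prior rating to every row.

    Adds ``cf_value_0/1`` and ``cf_conf_0/1``: the last value rating and
    belief confidence given for that arm on an earlier trial of the same
    subject and block (both-arm rating rows refresh both slots). Rows
    before any rating of an arm get NaN. Idempotent.
    """
    log = log.drop(columns=[c for c in log.columns if c.startswith("cf_")])
    log = log.sort_values(["subject", "block", "trial"], kind="stable")
    log = log.reset_index(drop=True)
    parts = [
        _carry_group(grp)
        for _, grp in log.groupby(["subject", "block"], sort=False)
    ]
    carried = pd.concat(parts)
    return pd.concat([log, carried], axis=1)


def label_exploration(view: pd.DataFrame) -> pd.DataFrame:
    """Flag choice trials on which the lower-rated arm was chosen.

    ``explore`` is 1 when the chosen arm's carried value rating is strictly
    below the other arm's, 0 when strictly above; ties and rows missing a
    carried rating are unusable (``explore`` NaN).
    """
    view = view.copy()
    chosen = view["arm"].to_numpy()
    v_chosen = np.where(chosen == 0, view["cf_value_0"], view["cf_value_1"])
    v_other = np.where(chosen == 0, view["cf_value_1"], view["cf_value_0"])
    explore = np.where(
        np.isnan(v_chosen) | np.isnan(v_other) | (v_chosen == v_other),
        np.nan,
        (v_chosen < v_other).astype(float),
    )
    explore = np.where(view["trial_type"] == "choice", explore, np.nan)
    view["explore"] = explore
    return view


def add_running_outcome_stats(log: pd.DataFrame) -> pd.DataFrame:
    """Per-arm running mean/SD/count of outcomes observed before each row.

    "Observed" means any trial whose outcome was revealed (rating trials in
    a design that shows outcomes, and all choice trials). Statistics reset
    at block boundaries and exclude the current row's outcome.
    """
    log = log.sort_values(["subject", "block", "trial"], kind="stable")
    log = log.reset_index(drop=True)
    cols = {}
    observed = log["outcome"].notna()
    for arm in (0, 1):
        mask = observed & (log["arm"] == arm)
        x = np.where(mask, log["outcome"].fillna(0.0), 0.0)
        grouped = pd.DataFrame(
            {"x": x, "x2": x**2, "n": mask.astype(float)}, index=log.index
        ).groupby([log["subject"], log["block"]], sort=False)
        csum = grouped.cumsum()
        n = csum["n"] - mask.astype(float)  # exclude current row
        s = csum["x"] - np.where(mask, x, 0.0)
        s2 = csum["x2"] - np.where(mask, x**2, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n > 0, s / n, np.nan)
            var = np.where(
                n > 1, (s2 - s**2 / np.maximum(n, 1)) / (n - 1), np.nan
            )
        cols[f"run_mean_{arm}"] = mean
        cols[f"run_sd_{arm}"] = np.sqrt(np.maximum(var, 0.0))
        cols[f"run_n_{arm}"] = n.astype(int)
    out = log.copy()
    for k, v in cols.items():
        out[k] = v
    return out.reset_index(drop=True)


def label_objective_accuracy(view: pd.DataFrame) -> pd.DataFrame:
    """Flag choice trials on which the objectively better arm was chosen.

    "Objectively better" means the arm with the higher running mean of all
    outcomes observed so far in the block; ties count as correct. Rows on
    which either arm has no prior observation are unusable (NaN).
    """
    if "run_mean_0" not in view.columns:
        view = add_running_outcome_stats(view)
    view = view.copy()
    chosen = view["arm"].to_numpy()
    m_chosen = np.where(chosen == 0, view["run_mean_0"], view["run_mean_1"])
    m_other = np.where(chosen == 0, view["run_mean_1"], view["run_mean_0"])
    acc = np.where(
        np.isnan(m_chosen) | np.isnan(m_other),
        np.nan,
        (m_chosen >= m_other).astype(float),
    )
    acc = np.where(view["trial_type"] == "choice", acc, np.nan)
    view["accuracy"] = acc
    return view


def bin_quintiles(
    values: pd.Series, subjects: pd.Series, n_bins: int = 5
) -> pd.Series:
    """Within-subject quantile bins labelled 1 (lowest) .. ``n_bins``.

    Heavy ties can collapse bins; the result then has fewer distinct
    labels and a warning is issued. Subjects with fewer than ``n_bins``
    usable values get NaN.
    """
    out = pd.Series(np.nan, index=values.index, dtype=float)
    for subject, idx in values.groupby(subjects, sort=False).groups.items():
        v = values.loc[idx]
        if v.notna().sum() < n_bins:
            warnings.warn(f"subject {subject}: fewer than {n_bins} values to bin")
            continue
        binned = pd.qcut(v, n_bins, labels=False, duplicates="drop")
        if binned.dropna().nunique() < n_bins:
            warnings.warn(f"subject {subject}: ties merged confidence bins")
        out.loc[idx] = binned + 1
    return out


def make_choice_view(log: pd.DataFrame) -> pd.DataFrame:
    """Full choice-trial view: carried ratings, labels, derived predictors.

    Returns only choice rows, with columns for the carried value/confidence
    of the chosen, unchosen, higher- and lower-rated arm, ``abs_dv``,
    ``explore`` and ``accuracy``.
    """
    view = carry_forward(log)
    view = add_running_outcome_stats(view)
    view = label_exploration(view)
    view = label_objective_accuracy(view)
    view = view[view["trial_type"] == "choice"].reset_index(drop=True)
    chosen = view["arm"].to_numpy()
    pick = lambda a, b: np.where(chosen == 0, a, b)  # noqa: E731
    view["v_chosen"] = pick(view["cf_value_0"], view["cf_value_1"])
    view["v_unchosen"] = pick(view["cf_value_1"], view["cf_value_0"])
    view["c_chosen"] = pick(view["cf_conf_0"], view["cf_conf_1"])
    view["c_unchosen"] = pick(view["cf_conf_1"], view["cf_conf_0"])
    hi0 = view["cf_value_0"].to_numpy() >= view["cf_value_1"].to_numpy()
    view["v_high"] = np.where(hi0, view["cf_value_0"], view["cf_value_1"])
    view["v_low"] = np.where(hi0, view["cf_value_1"], view["cf_value_0"])
    view["c_high"] = np.where(hi0, view["cf_conf_0"], view["cf_conf_1"])
    view["c_low"] = np.where(hi0, view["cf_conf_1"], view["cf_conf_0"])
    view["abs_dv"] = (view["cf_value_0"] - view["cf_value_1"]).abs()
    return view
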