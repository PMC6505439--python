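"""Type-2 signal-detection metrics: meta-d', M-ratio, and the tracking link.

Choice trials are recast as a 2AFC detection problem: the "stimulus" on a
trial is the objectively better arm (higher running mean of observed
outcomes), the "response" is the chosen arm, and decision confidence is
discretized into within-subject quantile bins. Meta-d' is the type-1
sensitivity that an ideal equal-variance SDT observer would need for its
type-2 (confidence) ROC to match the observed response-conditional
confidence distributions, holding the relative type-1 criterion fixed;
M-ratio = meta-d'/d' indexes metacognitive efficiency. Estimation is
per-subject maximum likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Type2Counts",
    "MetaResult",
    "build_type2_counts",
    "fit_meta_d",
    "subject_metacognition",
    "tracking_vs_efficiency",
]


@dataclass
class Type2Counts:
    """Confidence counts conditional on stimulus and response.

    ``n_s1`` / ``n_s2`` have shape (2, K): row 0 = "respond S1", row 1 =
    "respond S2"; column k = confidence bin k (0 = lowest). ``padded``
    records whether the 1/(2K) zero-cell correction was applied.
    """

    n_bins: int
    n_s1: np.ndarray  # trials with stimulus S1
    n_s2: np.ndarray  # trials with stimulus S2
    padded: bool = False

    @property
    def total(self) -> float:
        return float(self.n_s1.sum() + self.n_s2.sum())


@dataclass
class MetaResult:
    """Per-subject type-1 and type-2 sensitivity summary."""

    d_prime: float
    meta_d: float
    m_ratio: float
    log_m_ratio: float
    criterion: float
    n_bins: int
    padded: bool
    defined: bool  # False when d' <= 0 (M-ratio undefined)


def build_type2_counts(
    accuracy: np.ndarray,
    response: np.ndarray,
    confidence: np.ndarray,
    n_bins: int = 4,
) -> Type2Counts:
    """Cross-classify one subject's trials into type-2 count tables.

    ``response`` codes the chosen side (0/1); the stimulus is recovered
    from ``response`` and ``accuracy`` (correct means response equalled
    stimulus). Confidence is discretized into ``n_bins`` quantile bins;
    if ties leave fewer distinct bins, the bin count is reduced with a
    warning. Cells are padded with 1/(2K) (applied uniformly whenever any
    cell is zero).
    """
    acc = np.asarray(accuracy, dtype=float)
    resp = np.asarray(response, dtype=int)
    conf = np.asarray(confidence, dtype=float)
    keep = np.isfinite(acc) & np.isfinite(conf)
    acc, resp, conf = acc[keep], resp[keep], conf[keep]
    if len(conf) < 2 * n_bins:
        raise ValueError("too few usable trials for type-2 counts")
    binned = pd.qcut(pd.Series(conf), n_bins, labels=False, duplicates="drop")
    if binned.isna().all():  # constant confidence: a single degenerate bin
        binned = pd.Series(np.zeros(len(conf)))
    k = int(binned.max()) + 1
    if k < n_bins:
        warnings.warn(f"confidence ties reduced bins from {n_bins} to {k}")
    stim = np.where(acc == 1.0, resp, 1 - resp)
    tables = np.zeros((2, 2, k))
    for s, r, b in zip(stim, resp, binned.to_numpy()):
        tables[s, r, int(b)] += 1
    padded = bool((tables == 0).any())
    if padded:
        tables = tables + 1.0 / (2.0 * k)
    return Type2Counts(n_bins=k, n_s1=tables[0], n_s2=tables[1], padded=padded)


def _type1_sdt(counts: Type2Counts) -> tuple[float, float]:
    n_s1, n_s2 = counts.n_s1, counts.n_s2
    hr = n_s2[1].sum() / n_s2.sum()  # P(respond S2 | S2)
    far = n_s1[1].sum() / n_s1.sum()  # P(respond S2 | S1)
    d1 = stats.norm.ppf(hr) - stats.norm.ppf(far)
    c1 = -0.5 * (stats.norm.ppf(hr) + stats.norm.ppf(far))
    return float(d1), float(c1)


def _conf_probs(meta_d: float, c_rel: float, t2_lo: np.ndarray,
                t2_hi: np.ndarray) -> np.ndarray:
    """P(conf bin | stim, resp) under the meta-level SDT model.

    Returns shape (2 stim, 2 resp, K). ``t2_lo`` are the type-2 criteria
    below the (scaled) type-1 criterion for "respond S1", ``t2_hi`` those
    above it for "respond S2"; both ordered away from the criterion.
    """
    k = len(t2_lo) + 1
    mus = np.array([-meta_d / 2.0, meta_d / 2.0])
    c_meta = c_rel * meta_d  # scale the relative criterion to meta space
    out = np.empty((2, 2, k))
    lo_edges = np.concatenate([[-np.inf], np.sort(np.r_[t2_lo, c_meta])])
    hi_edges = np.concatenate([np.sort(np.r_[c_meta, t2_hi]), [np.inf]])
    for s, mu in enumerate(mus):
        cdf_lo = stats.norm.cdf(lo_edges, loc=mu)
        p_lo = np.diff(cdf_lo)  # bins below criterion, ascending x
        # respond S1: confidence decreases toward the criterion
        p_resp1 = p_lo[::-1]
        p1 = stats.norm.cdf(c_meta, loc=mu)
        out[s, 0] = p_resp1 / p1 if p1 > 0 else np.full(k, 1.0 / k)
        cdf_hi = stats.norm.cdf(hi_edges, loc=mu)
        p_hi = np.diff(cdf_hi)
        p2 = 1.0 - p1
        out[s, 1] = p_hi / p2 if p2 > 0 else np.full(k, 1.0 / k)
    return np.clip(out, 1e-12, 1.0)


def fit_meta_d(counts: Type2Counts) -> MetaResult:
    """Maximum-likelihood meta-d' for one subject's type-2 counts.

    The type-1 d' and criterion come directly from the marginal response
    rates. The meta-level model keeps the *relative* criterion c/d' fixed
    and fits meta-d' together with the response-conditional type-2
    criteria to the confidence counts. Flagged undefined when d' <= 0.
    """
    d1, c1 = _type1_sdt(counts)
    k = counts.n_bins
    if not np.isfinite(d1) or d1 <= 0:
        return MetaResult(d1, float("nan"), float("nan"), float("nan"),
                          c1, k, counts.padded, defined=False)
    c_rel = c1 / d1
    obs = np.stack([counts.n_s1, counts.n_s2])  # (stim, resp, bin)

    def unpack(x):
        meta_d = x[0]
        c_meta = c_rel * meta_d
        lo = c_meta - np.cumsum(np.exp(x[1:k]))[::-1]
        hi = c_meta + np.cumsum(np.exp(x[k:]))
        return meta_d, lo, hi

    def nll(x):
        meta_d, lo, hi = unpack(x)
        p = _conf_probs(meta_d, c_rel, lo, hi)
        return -float(np.sum(obs * np.log(p)))

    x0 = np.concatenate([[d1], np.full(2 * (k - 1), np.log(0.4))])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-6,
                                         "fatol": 1e-8})
    meta_d = float(res.x[0])
    m_ratio = meta_d / d1
    log_m = float(np.log(m_ratio)) if m_ratio > 0 else float("nan")
    return MetaResult(d1, meta_d, float(m_ratio), log_m, c1, k,
                      counts.padded, defined=True)


def subject_metacognition(
    view: pd.DataFrame, n_bins: int = 4, min_trials: int = 40
) -> pd.DataFrame:
    """Per-subject meta-d' table from a labelled choice view.

    Needs ``accuracy``, ``arm`` and ``decision_conf`` columns (see
    ``preprocess.make_choice_view``). Subjects with fewer than
    ``min_trials`` usable trials are skipped.
    """
    rows = []
    for subject, grp in view.groupby("subject", sort=False):
        usable = grp.dropna(subset=["accuracy", "decision_conf"])
        if len(usable) < min_trials:
            warnings.warn(f"subject {subject}: too few trials for meta-d'")
            continue
        counts = build_type2_counts(
            usable["accuracy"].to_numpy(),
            usable["arm"].to_numpy(),
            usable["decision_conf"].to_numpy(),
            n_bins=n_bins,
        )
        m = fit_meta_d(counts)
        rows.append(
            {"subject": subject, "d_prime": m.d_prime, "meta_d": m.meta_d,
             "m_ratio": m.m_ratio, "log_m_ratio": m.log_m_ratio,
             "n_bins": m.n_bins, "padded": m.padded, "defined": m.defined,
             "n_trials": len(usable)}
        )
    return pd.DataFrame(rows)


def tracking_vs_efficiency(
    beta_sig: pd.DataFrame, meta: pd.DataFrame
) -> "StatResult":
    """Correlate uncertainty-tracking betas with log M-ratio across subjects.

    ``beta_sig`` needs columns ``subject`` and ``beta_sig`` (per-subject
    sensitivity of belief confidence to outcome SD); ``meta`` is the
    ``subject_metacognition`` table. Subjects with undefined M-ratio are
    dropped; fewer than 5 remaining subjects is an error.
    """
    from .inference import StatResult

    merged = beta_sig.merge(meta, on="subject")
    merged = merged[merged["defined"] & np.isfinite(merged["log_m_ratio"])]
    if len(merged) < 5:
        raise ValueError(
            f"only {len(merged)} subjects with defined M-ratio (need >= 5)"
        )
    r, p = stats.pearsonr(merged["beta_sig"], merged["log_m_ratio"])
    return StatResult(
        statistic=float(r), df=(float(len(merged) - 2), 0.0),
        p_value=float(p), means={}, extra={"n_subjects": len(merged)},
    )
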