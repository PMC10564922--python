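"""Negative-binomial Wald differential expression for two-group count data.

Counts for feature i in sample j are modelled as NB with mean
``mu_ij = s_j * m_g(j)`` and variance ``mu + alpha * mu^2``, where ``s_j``
is a median-of-ratios size factor, ``m_g`` is a group mean (log-link GLM
with an intercept and a group covariate) and ``alpha`` is a per-feature
dispersion estimated by Cox-Reid adjusted profile maximum likelihood.
The group coefficient's Wald statistic is referred to a t distribution with
n - 2 degrees of freedom (a small-sample correction of the usual normal
reference) for a two-sided p-value; raw p
(not BH-adjusted) gates significance together with a linear fold-change
threshold, and BH-adjusted p-values are reported alongside.

There is no cross-feature dispersion shrinkage, so results approximate
rather than replicate shrinkage-based NB pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .quantify import CASE, ExpressionMatrix

#: Per-class prefilter: a feature is kept iff its mean raw count across all
#: samples reaches the class threshold.
CLASS_PREFILTER = {"mrna": 5.0, "circ": 2.0, "mirna": 50.0}

_ALPHA_MIN, _ALPHA_MAX = 1e-8, 100.0
# continuity floor: at least half a read (total) per group keeps the Wald
# statistic finite when one group is all-zero
_GROUP_READS_FLOOR = 0.5


@dataclass
class DEConfig:
    prefilter_min_count: float = 2.0
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    pseudocount: float = 0.01
    log2_fc_threshold: bool = False  # gate on |log2 FC| instead of linear FC

    def __post_init__(self) -> None:
        if min(self.prefilter_min_count, self.fc_threshold, self.p_threshold,
               self.pseudocount) <= 0:
            raise ValueError("thresholds must be > 0")

    @classmethod
    def for_class(cls, rna_class: str, **kwargs) -> "DEConfig":
        return cls(prefilter_min_count=CLASS_PREFILTER[rna_class], **kwargs)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Falls back to library-size ratios (with a warning) when no feature is
    nonzero in every sample — common for sparse circRNA matrices.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.size == 0 or not (mat > 0).any():
        raise ValueError("all-zero count matrix")
    all_nonzero = (mat > 0).all(axis=1)
    if all_nonzero.any():
        logs = np.log(mat[all_nonzero])
        log_ref = logs.mean(axis=1, keepdims=True)
        log_factors = np.median(logs - log_ref, axis=0)
    else:
        warnings.warn(
            "no feature observed in every sample; using library-size ratios",
            RuntimeWarning,
            stacklevel=2,
        )
        lib = mat.sum(axis=0)
        if (lib <= 0).any():
            raise ValueError("sample with zero total counts")
        log_factors = np.log(lib)
    log_factors = log_factors - log_factors.mean()  # geometric mean 1
    return pd.Series(np.exp(log_factors), index=counts.columns, name="size_factor")


def _solve_group_mean(y: np.ndarray, s: np.ndarray, alpha: float, floor: float) -> float:
    """MLE of the NB group mean m (mu_j = s_j * m) at fixed dispersion."""
    total = y.sum()
    if total == 0:
        return floor
    if alpha < 1e-12:
        return max(total / s.sum(), floor)
    m = total / s.sum()
    for _ in range(50):
        denom = 1.0 + alpha * s * m
        f = np.sum((y - s * m) / denom)
        fprime = -np.sum(s * (1.0 + alpha * y) / denom**2)
        step = f / fprime
        m_new = m - step
        if m_new <= 0:
            m_new = m / 2.0
        if abs(m_new - m) <= 1e-10 * max(m, 1.0):
            m = m_new
            break
        m = m_new
    return max(m, floor)


def _fit_feature(y: np.ndarray, s: np.ndarray, case_mask: np.ndarray) -> dict:
    """Two-group NB GLM fit for one feature (see module docstring)."""
    groups = (case_mask, ~case_mask)
    floors = [_GROUP_READS_FLOOR / s[g].sum() for g in groups]

    def profile(log_alpha: float) -> float:
        alpha = np.exp(log_alpha)
        nll = 0.0
        cr = 0.0
        for g, floor in zip(groups, floors):
            m = _solve_group_mean(y[g], s[g], alpha, floor)
            mu = s[g] * m
            r = 1.0 / alpha
            nll -= stats.nbinom.logpmf(y[g], r, r / (r + mu)).sum()
            w = np.sum(mu / (1.0 + alpha * mu))
            cr += 0.5 * np.log(w)
        return nll + cr  # minimize negative CR-adjusted loglik

    res = optimize.minimize_scalar(
        profile,
        bounds=(np.log(_ALPHA_MIN), np.log(_ALPHA_MAX)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    alpha = float(np.exp(res.x))
    converged = bool(res.success)

    means, weights = [], []
    for g, floor in zip(groups, floors):
        m = _solve_group_mean(y[g], s[g], alpha, floor)
        mu = s[g] * m
        means.append(m)
        weights.append(np.sum(mu / (1.0 + alpha * mu)))
    m_case, m_ctrl = means
    beta = np.log(m_case / m_ctrl)
    se = np.sqrt(1.0 / weights[0] + 1.0 / weights[1])
    z = beta / se if se > 0 else 0.0
    # t reference with n-2 df: small-sample correction for the Wald statistic
    p = 2.0 * stats.t.sf(abs(z), df=max(len(y) - 2, 1))
    return {
        "base_mean": float(np.mean(y / s)),
        "log2fc": float(beta / np.log(2.0)),
        "wald_statistic": float(z),
        "p_value": float(p) if converged else np.nan,
        "dispersion": alpha,
        "converged": converged,
    }


def prefilter(counts: pd.DataFrame, min_count: float) -> pd.DataFrame:
    """Drop features whose mean raw count across all samples is below threshold."""
    return counts.loc[counts.mean(axis=1) >= min_count]


def nb_wald_test(em: ExpressionMatrix, config: DEConfig) -> pd.DataFrame:
    """Per-feature NB Wald differential expression (case vs control).

    Returns a DataFrame indexed by feature with columns base_mean, log2fc,
    wald_statistic, p_value, adjusted_p, dispersion, status.
    """
    if em.unit != "raw_count":
        raise ValueError("nb_wald_test expects raw counts")
    counts = prefilter(em.values, config.prefilter_min_count)
    if counts.empty:
        raise ValueError("no features pass the prefilter")
    for group in ("case", "control"):
        if len(em.samples_in(group)) < 2:
            raise ValueError(f"need >= 2 samples in group {group!r}")
    sf = size_factors(counts)
    s = sf.to_numpy()
    case_mask = np.array([em.groups[c] == CASE for c in counts.columns])
    rows = [
        _fit_feature(counts.loc[fid].to_numpy(dtype=float), s, case_mask)
        for fid in counts.index
    ]
    de = pd.DataFrame(rows, index=counts.index)
    de.index.name = "feature_id"
    valid = de["p_value"].notna()
    de["adjusted_p"] = np.nan
    if valid.any():
        de.loc[valid, "adjusted_p"] = multipletests(
            de.loc[valid, "p_value"], method="fdr_bh"
        )[1]
    return call_status(de, config)


def call_status(records: pd.DataFrame, config: DEConfig) -> pd.DataFrame:
    """Assign Up / Down / NS per the fold-change + raw-p significance rule."""
    de = records.copy()
    fc = 2.0 ** de["log2fc"]
    if config.log2_fc_threshold:
        up_fc = de["log2fc"] > config.fc_threshold
        down_fc = de["log2fc"] < -config.fc_threshold
    else:
        up_fc = fc > config.fc_threshold
        down_fc = fc < 1.0 / config.fc_threshold
    sig = de["p_value"] < config.p_threshold
    de["status"] = "NS"
    de.loc[up_fc & sig & de["p_value"].notna(), "status"] = "Up"
    de.loc[down_fc & sig & de["p_value"].notna(), "status"] = "Down"
    return de


def status_map(de: pd.DataFrame) -> dict[str, str]:
    return de["status"].to_dict()


def volcano_table(de: pd.DataFrame) -> pd.DataFrame:
    """log2 FC vs -log10 p table with status, for volcano-style plotting."""
    out = de[["log2fc", "p_value", "status"]].copy()
    out["neg_log10_p"] = -np.log10(out["p_value"])
    return out[["log2fc", "neg_log10_p", "status"]]
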