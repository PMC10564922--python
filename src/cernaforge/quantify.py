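"""Back-spliced-junction TPM normalization and group-level comparisons.

circRNA abundance is measured as back-spliced junction (BSJ) reads; the
per-sample normalization is BSJ reads per million total mapped reads
("BSJ-TPM"). Group comparisons cover the global case/control abundance
shift, per-feature log2 fold changes, and group-exclusive expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CASE, CONTROL = "case", "control"


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with sample metadata.

    ``unit`` is tracked through every transform: "raw_count" or "tpm".
    """

    values: pd.DataFrame
    groups: pd.Series
    mapped_totals: pd.Series | None = None
    unit: str = "raw_count"

    def __post_init__(self) -> None:
        samples = list(self.values.columns)
        missing = [s for s in samples if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples missing group labels: {missing}")
        self.groups = self.groups.loc[samples]
        if self.mapped_totals is not None:
            missing = [s for s in samples if s not in self.mapped_totals.index]
            if missing:
                raise ValueError(f"samples missing mapped totals: {missing}")
            self.mapped_totals = self.mapped_totals.loc[samples].astype(float)
            if (self.mapped_totals <= 0).any():
                raise ValueError("mapped_totals must be positive")
        if self.unit not in ("raw_count", "tpm"):
            raise ValueError(f"unknown unit {self.unit!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def subset(self, features) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(features)], self.groups,
                                self.mapped_totals, self.unit)


@dataclass
class GroupShiftResult:
    t_statistic: float
    p_value: float
    direction: str  # case_lower | case_higher | none
    case_means: pd.Series = field(repr=False, default=None)
    control_means: pd.Series = field(repr=False, default=None)


def bsj_tpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize BSJ read counts to reads per million total mapped reads."""
    if counts.unit != "raw_count":
        raise ValueError("bsj_tpm expects a raw-count matrix")
    if counts.mapped_totals is None:
        raise ValueError("mapped_totals required for TPM normalization")
    tpm = counts.values.astype(float).div(counts.mapped_totals, axis=1) * 1e6
    return ExpressionMatrix(tpm, counts.groups, counts.mapped_totals, unit="tpm")


def group_means(em: ExpressionMatrix) -> tuple[pd.Series, pd.Series]:
    case = em.values[em.samples_in(CASE)].mean(axis=1)
    control = em.values[em.samples_in(CONTROL)].mean(axis=1)
    return case, control


def group_shift_test(tpm: ExpressionMatrix, alpha: float = 0.05) -> GroupShiftResult:
    """Test for a global shift between the two groups' abundance profiles.

    Welch's two-sample t-test on log10(mean TPM + 1) of the per-feature
    group averages, mirroring a density-curve comparison of average
    expression per group.
    """
    case_means, control_means = group_means(tpm)
    if len(case_means) < 2:
        raise ValueError("need >= 2 features for a group-shift test")
    if not tpm.samples_in(CASE) or not tpm.samples_in(CONTROL):
        raise ValueError("both groups must be non-empty")
    log_case = np.log10(case_means + 1.0)
    log_control = np.log10(control_means + 1.0)
    t, p = stats.ttest_ind(log_case, log_control, equal_var=False)
    if np.isclose(log_case.mean(), log_control.mean()):
        direction = "none"
    elif log_case.mean() < log_control.mean():
        direction = "case_lower"
    else:
        direction = "case_higher"
    return GroupShiftResult(float(t), float(p), direction, case_means, control_means)


def exclusive_features(counts: ExpressionMatrix, min_reads: int = 2) -> tuple[set[str], set[str]]:
    """Group-exclusive features: supported in one group, all-zero in the other.

    Support uses the consensus rule evaluated within the group: at least
    ``min_reads`` in strictly more than half of that group's samples.
    """
    if counts.unit != "raw_count":
        raise ValueError("exclusive_features expects raw counts")
    out = []
    for own, other in ((CASE, CONTROL), (CONTROL, CASE)):
        own_vals = counts.values[counts.samples_in(own)]
        other_vals = counts.values[counts.samples_in(other)]
        supported = (own_vals >= min_reads).sum(axis=1) > own_vals.shape[1] / 2
        silent = (other_vals == 0).all(axis=1)
        out.append(set(counts.values.index[supported & silent]))
    case_only, control_only = out
    return case_only, control_only


def log2fc(tpm: ExpressionMatrix, pseudocount: float = 0.01) -> pd.Series:
    """Per-feature log2 fold change of group mean expression, case vs control."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    case_means, control_means = group_means(tpm)
    return pd.Series(
        np.log2((case_means + pseudocount) / (control_means + pseudocount)),
        index=tpm.values.index,
        name="log2fc",
    )
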