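"""Perseus-style matrix preprocessing and benchmark statistics.

Covers the downstream analysis path used on collapsed site tables: minimum
valid-value filtering per group, median normalization with downshifted-normal
imputation of missing values, SAM-style s0-moderated testing with permutation
FDR (two-class d-score and multi-class F-type statistic), ROC curves over
d-scores against known regulation labels, and the bias/variance mean-squared
error decomposition used to compare quantification methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

__all__ = [
    "GroupedMatrix", "TestResult", "filter_min_valid", "normalize_and_impute",
    "sam_test", "roc_from_scores", "mse_decomposition",
]


@dataclass
class GroupedMatrix:
    """Feature x sample log2 intensity matrix with a sample -> group map."""

    data: pd.DataFrame
    groups: pd.Series  # index = sample (column of data), value = group label

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        missing = [c for c in self.data.columns if c not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")

    def group_columns(self) -> dict:
        out: dict = {}
        for col in self.data.columns:
            out.setdefault(self.groups[col], []).append(col)
        return out


@dataclass
class TestResult:
    statistic: pd.Series
    q_value: pd.Series
    significant: pd.Series
    s0: float
    fdr: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"statistic": self.statistic, "q_value": self.q_value,
                             "significant": self.significant})


def filter_min_valid(matrix: GroupedMatrix, min_valid: int = 3) -> GroupedMatrix:
    """Keep features with >= min_valid non-missing values in at least one group."""
    cols_by_group = matrix.group_columns()
    largest = max(len(c) for c in cols_by_group.values())
    if min_valid > largest:
        raise ValueError(f"min_valid={min_valid} exceeds largest group size {largest}")
    keep = pd.Series(False, index=matrix.data.index)
    for cols in cols_by_group.values():
        keep |= matrix.data[cols].notna().sum(axis=1) >= min_valid
    return GroupedMatrix(matrix.data.loc[keep].copy(), matrix.groups)


def normalize_and_impute(matrix: pd.DataFrame, width: float = 0.3,
                         downshift: float = 1.8, seed: int | None = None,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Median-subtract each sample, then impute missing values from the lower
    tail of the sample's intensity distribution.

    Imputed draws come from Normal(mean - downshift*sd, width*sd) of the
    sample's valid values, the standard downshifted-normal scheme for
    left-censored proteomics intensities (defaults width 0.3, downshift 1.8).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = matrix.copy().astype(float)
    for col in out.columns:
        valid = out[col].dropna()
        if len(valid) < 2:
            raise ValueError(f"sample {col!r} has fewer than 2 valid values")
        out[col] = out[col] - valid.median()
    for col in out.columns:
        valid = out[col].dropna()
        n_missing = out[col].isna().sum()
        if n_missing == 0:
            continue
        mu = valid.mean() - downshift * valid.std(ddof=1)
        sd = width * valid.std(ddof=1)
        out.loc[out[col].isna(), col] = rng.normal(mu, sd, size=n_missing)
    return out


def _two_class_d(data: np.ndarray, idx1: np.ndarray, idx2: np.ndarray,
                 s0: float) -> np.ndarray:
    x1, x2 = data[:, idx1], data[:, idx2]
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    pooled = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return (m1 - m2) / (pooled + s0)


def _multi_class_stat(data: np.ndarray, group_idx: list[np.ndarray],
                      s0: float) -> np.ndarray:
    k = len(group_idx)
    n_total = sum(len(g) for g in group_idx)
    grand = data.mean(axis=1)
    ss_between = np.zeros(data.shape[0])
    ss_within = np.zeros(data.shape[0])
    for g in group_idx:
        sub = data[:, g]
        m = sub.mean(axis=1)
        ss_between += len(g) * (m - grand) ** 2
        ss_within += ((sub - m[:, None]) ** 2).sum(axis=1)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k)
    return np.sqrt(ms_between) / (np.sqrt(ms_within) + s0)


def sam_test(matrix: GroupedMatrix, design: str = "two-class", s0: float = 0.1,
             n_permutations: int = 250, fdr: float = 0.05,
             seed: int | None = None, zscore: bool = False) -> TestResult:
    """s0-moderated SAM test with permutation-based q-values.

    Two-class design uses the d-score, mean difference over (pooled standard
    error + s0); multi-class uses the analogous F-type statistic,
    sqrt(between-group mean square) over (sqrt(within mean square) + s0).
    q-values at each |statistic| threshold are the ratio of the mean
    permutation exceedance count to the observed count, made monotone.
    """
    data = matrix.data
    if zscore:
        data = data.sub(data.mean(axis=1), axis=0).div(data.std(axis=1, ddof=1), axis=0)
    arr = data.values.astype(float)
    if np.isnan(arr).any():
        raise ValueError("matrix contains missing values; impute first")
    cols = list(data.columns)
    groups_by_label = matrix.group_columns()
    labels = list(groups_by_label)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab, cs in groups_by_label.items():
        if len(cs) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
    if n_permutations < 25:
        warnings.warn("fewer than 25 permutations: q-value resolution is poor")

    col_pos = {c: i for i, c in enumerate(cols)}
    group_idx = [np.array([col_pos[c] for c in groups_by_label[lab]]) for lab in labels]

    if design == "two-class":
        if len(labels) != 2:
            raise ValueError("two-class design requires exactly two groups")
        stat = _two_class_d(arr, group_idx[0], group_idx[1], s0)
    elif design == "multi-class":
        stat = _multi_class_stat(arr, group_idx, s0)
    else:
        raise ValueError(f"unknown design: {design}")

    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in group_idx]
    all_idx = np.concatenate(group_idx)
    perm_stats = np.empty((n_permutations, arr.shape[0]))
    for b in range(n_permutations):
        perm = rng.permutation(all_idx)
        bounds = np.cumsum([0] + sizes)
        pg = [perm[bounds[i]:bounds[i + 1]] for i in range(len(sizes))]
        if design == "two-class":
            perm_stats[b] = _two_class_d(arr, pg[0], pg[1], s0)
        else:
            perm_stats[b] = _multi_class_stat(arr, pg, s0)

    obs_abs = np.abs(stat)
    perm_abs = np.abs(perm_stats).ravel()
    perm_abs.sort()
    order = np.argsort(-obs_abs)
    q = np.empty_like(obs_abs)
    m = len(obs_abs)
    sorted_obs = np.sort(obs_abs)
    for rank, i in enumerate(order):
        t = obs_abs[i]
        observed = m - np.searchsorted(sorted_obs, t, side="left")
        expected = (len(perm_abs) - np.searchsorted(perm_abs, t, side="left")) / n_permutations
        q[i] = min(expected / max(observed, 1), 1.0)
    # enforce monotonicity: larger |stat| never has larger q
    running = np.inf
    for i in np.argsort(-obs_abs):
        running = min(running, q[i])
        q[i] = running

    stat_s = pd.Series(stat, index=data.index, name="statistic")
    q_s = pd.Series(q, index=data.index, name="q_value")
    return TestResult(statistic=stat_s, q_value=q_s,
                      significant=q_s <= fdr, s0=s0, fdr=fdr)


def roc_from_scores(scores, truth_labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR) and trapezoidal AUC thresholding on |score|."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth_labels).astype(bool)
    if truth.all() or (~truth).all():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = _roc_curve(truth, np.abs(scores))
    return fpr, tpr, float(_auc(fpr, tpr))


def mse_decomposition(estimates, truth: float) -> dict[str, float]:
    """Bias/variance decomposition of estimation error against a known truth.

    Returns bias = |mean - truth|, the population variance, the classical
    mse = bias^2 + variance (equal to mean squared error about the truth),
    and the additive 'bias + variance' report used when comparing
    quantification methods on benchmark designs.
    """
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("need at least 2 estimates")
    bias = float(abs(est.mean() - truth))
    variance = float(est.var())  # population variance
    return {"bias": bias, "variance": variance,
            "mse": bias ** 2 + variance,
            "bias_plus_variance": bias + variance}
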