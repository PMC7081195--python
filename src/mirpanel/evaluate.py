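"""Diagnostic performance reporting for index-based models.

ROC/AUC (midrank Mann-Whitney form), confusion metrics at the index >= 0
decision rule (sensitivity, specificity, accuracy, PPV, NPV as percentages
to one decimal, matching the usual diagnostic-table display), subgroup
positive rates across stage and histology partitions, paired pre-/post-
operative comparison, and logistic-regression odds ratios with optional
age/sex/smoking adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .simchip import SampleMeta, metas_to_frame

__all__ = [
    "EvalReport",
    "SubgroupReport",
    "PrePostReport",
    "OrReport",
    "SeparationError",
    "roc_auc",
    "roc_points",
    "confusion_metrics",
    "subgroup_rates",
    "prepost_compare",
    "logistic_or",
]

SUBGROUP_PARTITIONS = ("pstage", "t", "n", "m", "histology")


class SeparationError(RuntimeError):
    """Logistic fit failed because the outcome is (near-)perfectly separated."""


@dataclass
class EvalReport:
    auc: float
    sensitivity: float      # %
    specificity: float      # %
    accuracy: float         # %
    ppv: float              # % (nan when no predicted positives)
    npv: float              # % (nan when no predicted negatives)
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SubgroupReport:
    partition: str
    rates: dict[str, dict]  # level -> {"n": int, "positive_rate": float% | nan}


@dataclass
class PrePostReport:
    n_pairs: int
    pre_mean: float
    pre_se: float
    post_mean: float
    post_se: float
    diff_mean: float  # pre - post
    t_stat: float
    p: float


@dataclass
class OrReport:
    odds_ratio: float
    ci_low: float
    ci_high: float
    adjusted: bool
    coef: float
    se: float


def _as_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OU":
        y = y == "cancer"
    return y.astype(bool)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_auc(indexes, labels) -> float:
    """AUC as the Mann-Whitney probability with midrank tie handling."""
    idx = np.asarray(indexes, dtype=float)
    y = _as_labels(labels)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(idx)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_points(indexes, labels) -> pd.DataFrame:
    """ROC curve points (threshold, fpr, tpr), thresholds descending."""
    idx = np.asarray(indexes, dtype=float)
    y = _as_labels(labels)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-idx, kind="stable")
    idx_s, y_s = idx[order], y[order]
    thresholds, tprs, fprs = [np.inf], [0.0], [0.0]
    tp = fp = 0
    for i in range(len(idx_s)):
        tp += int(y_s[i])
        fp += int(~y_s[i])
        if i + 1 == len(idx_s) or idx_s[i + 1] != idx_s[i]:
            thresholds.append(idx_s[i])
            tprs.append(tp / n1)
            fprs.append(fp / n0)
    return pd.DataFrame({"threshold": thresholds, "fpr": fprs, "tpr": tprs})


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------


def confusion_metrics(indexes, labels, threshold: float = 0.0) -> EvalReport:
    """Threshold metrics with the inclusive rule: index >= threshold is a
    positive (cancer) call.  Percentages are rounded to one decimal."""
    idx = np.asarray(indexes, dtype=float)
    y = _as_labels(labels)
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("both classes must be present")
    pos = idx >= threshold
    tp = int(np.sum(pos & y))
    fp = int(np.sum(pos & ~y))
    tn = int(np.sum(~pos & ~y))
    fn = int(np.sum(~pos & y))

    def pct(num, den):
        return round(100.0 * num / den, 1) if den > 0 else math.nan

    if tp + fp == 0:
        warnings.warn("no predicted positives; PPV undefined (NA)")
    if tn + fn == 0:
        warnings.warn("no predicted negatives; NPV undefined (NA)")
    return EvalReport(
        auc=roc_auc(idx, y),
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        accuracy=pct(tp + tn, len(y)),
        ppv=pct(tp, tp + fp),
        npv=pct(tn, tn + fn),
        tp=tp, fp=fp, tn=tn, fn=fn,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# subgroup positive rates
# ---------------------------------------------------------------------------


def subgroup_rates(
    indexes: Mapping[str, float] | Sequence[float],
    metas: Sequence[SampleMeta] | pd.DataFrame,
    partition: str,
    levels: Sequence[str] | None = None,
    threshold: float = 0.0,
) -> SubgroupReport:
    """Positive rate (index >= threshold, %) per level of a cancer partition.

    ``partition`` is one of pstage / t / n / m / histology.  Only cancer
    samples are considered; empty levels report NaN with a warning.
    """
    if partition not in SUBGROUP_PARTITIONS:
        raise ValueError(f"unknown partition {partition!r}; expected one of {SUBGROUP_PARTITIONS}")
    df = metas_to_frame(metas)
    df = df[df["label"] == "cancer"]
    if isinstance(indexes, Mapping):
        idx = df["sample_id"].map(indexes)
        if idx.isna().any():
            missing = df.loc[idx.isna(), "sample_id"].iloc[0]
            raise ValueError(f"no index for cancer sample {missing}")
        idx = idx.to_numpy(dtype=float)
    else:
        idx = np.asarray(indexes, dtype=float)
        if len(idx) != len(df):
            raise ValueError("indexes do not align with cancer samples")
    values = df[partition]
    if levels is None:
        levels = sorted(values.dropna().unique())
    rates: dict[str, dict] = {}
    for lvl in levels:
        mask = (values == lvl).to_numpy()
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"subgroup {partition}={lvl!r} has no samples; rate NA")
            rates[str(lvl)] = {"n": 0, "positive_rate": math.nan}
        else:
            rate = round(100.0 * float(np.mean(idx[mask] >= threshold)), 1)
            rates[str(lvl)] = {"n": n, "positive_rate": rate}
    return SubgroupReport(partition, rates)


# ---------------------------------------------------------------------------
# pre/post comparison
# ---------------------------------------------------------------------------


def prepost_compare(pre: Mapping[str, float], post: Mapping[str, float]) -> PrePostReport:
    """Paired pre- vs post-operative index comparison (two-sided paired t).

    ``pre`` and ``post`` map pair ids to diagnostic indexes; the key sets
    must coincide.  A zero-variance difference reports p = NaN with a
    warning.
    """
    orphans = sorted(set(pre) ^ set(post))
    if orphans:
        raise ValueError(f"broken pre/post pairing; orphan ids: {orphans}")
    if not pre:
        raise ValueError("no pairs")
    keys = sorted(pre)
    a = np.array([pre[k] for k in keys], dtype=float)
    b = np.array([post[k] for k in keys], dtype=float)
    diff = a - b
    if len(keys) < 2 or np.allclose(np.std(diff, ddof=0), 0.0):
        warnings.warn("degenerate paired comparison (zero-variance differences); p = NA")
        t_stat, p = math.nan, math.nan
        if np.allclose(diff, 0.0):
            t_stat = math.nan
    else:
        t_stat, p = sps.ttest_rel(a, b)
    return PrePostReport(
        n_pairs=len(keys),
        pre_mean=float(np.mean(a)),
        pre_se=float(sps.sem(a)) if len(a) > 1 else math.nan,
        post_mean=float(np.mean(b)),
        post_se=float(sps.sem(b)) if len(b) > 1 else math.nan,
        diff_mean=float(np.mean(diff)),
        t_stat=float(t_stat) if not math.isnan(float(t_stat)) else math.nan,
        p=float(p) if not (isinstance(p, float) and math.isnan(p)) else math.nan,
    )


# ---------------------------------------------------------------------------
# logistic odds ratios
# ---------------------------------------------------------------------------


def logistic_or(
    labels,
    exposure,
    metas: Sequence[SampleMeta] | pd.DataFrame | None = None,
    adjust: Sequence[str] = (),
) -> OrReport:
    """Odds ratio of the outcome per unit of exposure via logistic ML fit.

    ``exposure`` is typically the continuous diagnostic index (default unit)
    or a 0/1 positivity indicator.  ``adjust`` names covariates (age, sex,
    smoking) pulled from ``metas``.  Wald 95% CI.  Perfect or quasi-perfect
    separation raises :class:`SeparationError`.
    """
    y = _as_labels(labels).astype(float)
    x = np.asarray(exposure, dtype=float)
    if len(x) != len(y):
        raise ValueError("exposure and labels must be aligned")
    cols = [x]
    if adjust:
        if metas is None:
            raise ValueError("adjusting covariates requires metas")
        df = metas_to_frame(metas)
        for c in adjust:
            v = df[c]
            if c == "sex":
                cols.append((v == "M").to_numpy(dtype=float))
            elif c == "smoking":
                cols.append((v == "ever").to_numpy(dtype=float))
            else:
                cols.append(v.to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("a covariate is constant; model not identifiable")
    X = sm.add_constant(X)
    if len(y) <= X.shape[1]:
        raise ValueError("more parameters than samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise SeparationError(f"logistic fit failed (separation?): {exc}") from exc
    if not fit.mle_retvals.get("converged", False) or np.any(np.abs(fit.params) > 1e3):
        raise SeparationError("logistic fit diverged: outcome is (near-)perfectly separated")
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    z = sps.norm.ppf(0.975)
    return OrReport(
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        adjusted=bool(adjust),
        coef=coef,
        se=se,
    )
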