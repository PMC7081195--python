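"""Sample exclusion workflow, propensity-score caliper matching, and
cohort comparison statistics.

Exclusion mirrors a typical biobank workflow for a surgical serum series:
low-quality arrays drop out for everyone; cancer samples additionally drop
out for a past history of other cancers, pre-treatment before serum
collection, missing smoking or stage information, or a serum-to-surgery
interval of 180 days or more.  A sample may carry several reasons, so
per-reason counts can sum to more than the number of excluded samples.

Matching is one-to-one greedy nearest-neighbor on the logit of a logistic
propensity score (case status ~ age + sex + smoking), accepting pairs only
within a caliper of 0.2 standard deviations of the logit score — the common
caliper convention.

Cohort summaries use one-way ANOVA for continuous variables and Pearson
chi-square without continuity correction for categorical variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .preprocess import QCResult
from .simchip import SampleMeta, metas_to_frame

__all__ = [
    "ExclusionReport",
    "MatchResult",
    "CohortSummary",
    "MatchingError",
    "apply_exclusions",
    "propensity_match",
    "summarize_cohort",
    "EXCLUSION_REASONS",
]

EXCLUSION_REASONS = (
    "low_quality_array",
    "prior_cancer",
    "missing_info",
    "pretreated",
    "long_interval",
)


class MatchingError(RuntimeError):
    """Propensity matching cannot proceed (e.g. degenerate logistic fit)."""


@dataclass
class ExclusionReport:
    kept_ids: list[str]
    excluded: dict[str, tuple[str, ...]]  # sample_id -> reasons
    reason_counts: dict[str, int]

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]          # (case_id, control_id)
    scores: dict[str, float]              # logit propensity score per sample
    caliper: float
    unmatched_cases: list[str]


@dataclass
class CohortSummary:
    group_col: str
    groups: list[str]
    group_sizes: dict[str, int]
    table: dict[str, dict]  # variable -> {"kind", "stat", "p", per-group stats}

    def p_value(self, variable: str) -> float:
        return self.table[variable]["p"]


def apply_exclusions(
    metas: Sequence[SampleMeta] | pd.DataFrame,
    qc: Sequence[QCResult],
    max_interval_days: int = 180,
) -> ExclusionReport:
    """Apply the sample exclusion workflow; reasons accumulate per sample.

    The interval rule is inclusive: ``interval_days >= max_interval_days``
    excludes.  QC results must cover every cancer sample; a non-cancer
    sample without a QC record is treated as QC-passed.
    """
    df = metas_to_frame(metas)
    qc_by_id = {q.sample_id: q for q in qc}

    excluded: dict[str, tuple[str, ...]] = {}
    kept: list[str] = []
    counts = {r: 0 for r in EXCLUSION_REASONS}

    for _, row in df.iterrows():
        sid = row["sample_id"]
        is_cancer = row["label"] == "cancer"
        q = qc_by_id.get(sid)
        if q is None and is_cancer:
            raise ValueError(f"no QC result for cancer sample {sid}")
        reasons = []
        if q is not None and not q.passed:
            reasons.append("low_quality_array")
        if is_cancer:
            if bool(row.get("prior_cancer")):
                reasons.append("prior_cancer")
            if _missing(row.get("smoking")) or _missing(row.get("pstage")):
                reasons.append("missing_info")
            if bool(row.get("pretreated")):
                reasons.append("pretreated")
            interval = row.get("interval_days")
            if not _missing(interval) and int(interval) >= max_interval_days:
                reasons.append("long_interval")
        if reasons:
            excluded[sid] = tuple(reasons)
            for r in reasons:
                counts[r] += 1
        else:
            kept.append(sid)
    return ExclusionReport(kept, excluded, counts)


def _missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


# ---------------------------------------------------------------------------
# propensity matching
# ---------------------------------------------------------------------------


def _design(df: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = []
    for c in covariates:
        v = df[c]
        if c == "sex":
            cols.append((v == "M").astype(float))
        elif c == "smoking":
            if v.isna().any():
                raise ValueError("smoking covariate incomplete; exclude missing-info samples first")
            cols.append((v == "ever").astype(float))
        else:
            if v.isna().any():
                raise ValueError(f"covariate {c!r} incomplete")
            cols.append(v.astype(float))
    return np.column_stack(cols)


def propensity_match(
    cases: Sequence[SampleMeta] | pd.DataFrame,
    controls: Sequence[SampleMeta] | pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "smoking"),
    caliper_sd_mult: float = 0.2,
) -> MatchResult:
    """One-to-one greedy caliper matching on the logit propensity score.

    Cases are processed in descending score order (ties by id); each takes
    its nearest unmatched control by absolute logit distance, accepted only
    if the distance is within ``caliper_sd_mult`` x sd of all logit scores.
    """
    cases_df = metas_to_frame(cases)
    controls_df = metas_to_frame(controls)
    if len(cases_df) == 0 or len(controls_df) == 0:
        raise ValueError("both cases and controls must be non-empty")

    df = pd.concat([cases_df, controls_df], ignore_index=True)
    y = np.concatenate([np.ones(len(cases_df)), np.zeros(len(controls_df))])
    X = sm.add_constant(_design(df, covariates))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception as exc:  # PerfectSeparationError and numerical failures
            raise MatchingError(
                "degenerate logistic fit (perfect separation?); consider jittering "
                "covariates or exact matching"
            ) from exc
    if not fit.mle_retvals.get("converged", False) or np.any(np.abs(fit.params) > 1e3):
        raise MatchingError(
            "propensity model did not converge (near-perfect separation); consider "
            "jittering covariates or exact matching"
        )
    logit = X @ fit.params
    ids = df["sample_id"].to_numpy()
    scores = dict(zip(ids, logit.astype(float)))
    caliper = caliper_sd_mult * float(np.std(logit, ddof=1))

    case_ids = list(cases_df["sample_id"])
    control_ids = list(controls_df["sample_id"])
    order = sorted(case_ids, key=lambda s: (-scores[s], s))
    available = set(control_ids)
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for cid in order:
        best, best_d = None, np.inf
        for kid in available:
            d = abs(scores[cid] - scores[kid])
            if d < best_d - 1e-15 or (abs(d - best_d) <= 1e-15 and (best is None or kid < best)):
                best, best_d = kid, d
        if best is not None and best_d <= caliper:
            pairs.append((cid, best))
            available.discard(best)
        else:
            unmatched.append(cid)
    return MatchResult(pairs, scores, caliper, unmatched)


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------


def summarize_cohort(
    metas: Sequence[SampleMeta] | pd.DataFrame,
    group_col: str = "label",
    continuous: Sequence[str] = ("age",),
    categorical: Sequence[str] = ("sex", "smoking"),
) -> CohortSummary:
    """Descriptive statistics per group with ANOVA / chi-square p-values.

    Continuous variables report mean +/- SE per group and a one-way ANOVA p;
    categorical variables report counts (% within group) and a Pearson
    chi-square p without continuity correction.  A variable constant across
    the whole cohort yields statistic 0 and p = 1 with a warning.
    """
    df = metas_to_frame(metas)
    groups = sorted(df[group_col].dropna().unique())
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    table: dict[str, dict] = {}

    for var in continuous:
        per = {}
        arrays = []
        for g in groups:
            v = df.loc[df[group_col] == g, var].dropna().astype(float).to_numpy()
            arrays.append(v)
            per[g] = {"mean": float(np.mean(v)), "se": float(sps.sem(v)) if len(v) > 1 else np.nan,
                      "n": int(len(v))}
        if all(np.ptp(a) == 0 for a in arrays) and np.ptp(np.concatenate(arrays)) == 0:
            warnings.warn(f"variable {var!r} is constant; p set to 1")
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.f_oneway(*arrays)
        table[var] = {"kind": "continuous", "stat": float(stat), "p": float(p), "groups": per}

    for var in categorical:
        sub = df[[group_col, var]].dropna()
        ct = pd.crosstab(sub[var], sub[group_col])
        per = {
            g: {
                lvl: {"n": int(ct.loc[lvl, g]),
                      "pct": round(100.0 * ct.loc[lvl, g] / ct[g].sum(), 1)}
                for lvl in ct.index
            }
            for g in ct.columns
        }
        if ct.shape[0] < 2 or ct.shape[1] < 2:
            warnings.warn(f"variable {var!r} is constant; p set to 1")
            stat, p = 0.0, 1.0
        else:
            res = sps.chi2_contingency(ct.to_numpy(), correction=False)
            stat, p = float(res.statistic), float(res.pvalue)
        table[var] = {"kind": "categorical", "stat": stat, "p": p, "groups": per}

    sizes = {g: int((df[group_col] == g).sum()) for g in groups}
    return CohortSummary(group_col, list(groups), sizes, table)


def standardized_mean_difference(
    a: pd.DataFrame, b: pd.DataFrame, covariates: Sequence[str] = ("age", "sex", "smoking")
) -> dict[str, float]:
    """|SMD| per covariate between two groups (binary coding for sex/smoking)."""
    Xa, Xb = _design(a, covariates), _design(b, covariates)
    out = {}
    for j, c in enumerate(covariates):
        va, vb = Xa[:, j], Xb[:, j]
        pooled = np.sqrt((np.var(va, ddof=1) + np.var(vb, ddof=1)) / 2.0)
        out[c] = 0.0 if pooled == 0 else abs(va.mean() - vb.mean()) / pooled
    return out
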