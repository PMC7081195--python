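"""Diagnostic-panel discovery: Fisher linear discriminants, beam search with
leave-one-out cross-validation, and DeLong model selection.

The discriminant for a panel of up to three miRNAs is the classic Fisher
rule ``w = S_pooled^{-1} (mu_cancer - mu_noncancer)`` with the intercept
placed so that the index ``w.x + b`` is zero at the midpoint of the
projected class means; an index >= 0 calls cancer.  Panels are grown by beam
search: all single-miRNA discriminants are scored and the best ``beam_width``
kept; each survivor is extended by every remaining miRNA, rescored, and
truncated again, up to three miRNAs.  Candidates are ranked by LOOCV
accuracy, with apparent AUC and then lexicographic panel id as tie-breaks.

The final panel size is chosen by walking up the size-k champions: advance
from k to k+1 only when DeLong's test for two correlated ROC curves finds
the larger panel's AUC significantly greater — the smallest panel whose
successor brings no significant gain wins.

LOOCV is computed by closed-form leave-one-out downdates of the class means
and pooled scatter, vectorized across candidate panels and held-out samples;
it agrees with an explicit refit loop and keeps the search tractable at
thousands of candidate panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Discriminant",
    "BeamCandidate",
    "BeamState",
    "SelectionResult",
    "fit_fisher_lda",
    "loocv_score",
    "beam_search",
    "delong_test",
    "delong_auc_covariance",
    "select_final_model",
    "apply_model",
]

RIDGE = 1e-8  # relative ridge on the pooled covariance diagonal


@dataclass(frozen=True)
class Discriminant:
    """A linear diagnostic model: index(x) = sum(w_j * x_j) + intercept."""

    mirna_ids: tuple[str, ...]
    weights: tuple[float, ...]
    intercept: float

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.mirna_ids):
            raise ValueError("one weight per miRNA required")
        if not all(math.isfinite(w) for w in self.weights) or not math.isfinite(self.intercept):
            raise ValueError("non-finite discriminant coefficients")

    def index(self, values: Mapping[str, float]) -> float:
        return float(
            sum(w * float(values[m]) for w, m in zip(self.weights, self.mirna_ids))
            + self.intercept
        )

    def to_dict(self) -> dict:
        return {
            "mirna_ids": list(self.mirna_ids),
            "weights": list(self.weights),
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Discriminant":
        return cls(tuple(d["mirna_ids"]), tuple(float(w) for w in d["weights"]), float(d["intercept"]))


@dataclass(frozen=True)
class BeamCandidate:
    panel: tuple[str, ...]
    model: Discriminant
    loocv: float
    auc: float


@dataclass
class BeamState:
    """Per panel size, the ranked surviving candidates."""

    beam_width: int
    levels: dict[int, list[BeamCandidate]]

    def champion(self, size: int) -> BeamCandidate:
        return self.levels[size][0]

    @property
    def max_size(self) -> int:
        return max(self.levels)


@dataclass
class SelectionResult:
    champions: dict[int, BeamCandidate]
    delong_p: dict[tuple[int, int], float]
    aucs: dict[int, float]
    final_size: int

    @property
    def final_model(self) -> Discriminant:
        return self.champions[self.final_size].model


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _as_matrix(values, labels):
    """Coerce (DataFrame | ndarray, labels) to (X, y, column names)."""
    if isinstance(values, pd.DataFrame):
        X = values.to_numpy(dtype=float)
        cols = [str(c) for c in values.columns]
        if isinstance(labels, Mapping):
            y = np.array([labels[s] for s in values.index])
        else:
            y = np.asarray(labels)
    else:
        X = np.asarray(values, dtype=float)
        cols = [str(j) for j in range(X.shape[1])]
        y = np.asarray(labels)
    if y.dtype.kind in "OU":
        y = y == "cancer"
    y = y.astype(bool)
    if len(y) != X.shape[0]:
        raise ValueError("labels do not align with samples")
    return X, y, cols


def _class_stats(X: np.ndarray, y: np.ndarray):
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError(f"each class needs >= 2 samples (got cancer={n1}, non_cancer={n0})")
    m1 = X[y].mean(axis=0)
    m0 = X[~y].mean(axis=0)
    C1 = X[y] - m1
    C0 = X[~y] - m0
    S = C1.T @ C1 + C0.T @ C0
    return n1, n0, m1, m0, S


def _ridged(pooled: np.ndarray) -> np.ndarray:
    k = pooled.shape[-1]
    eps = RIDGE * np.trace(pooled) / k if np.trace(pooled) > 0 else RIDGE
    return pooled + eps * np.eye(k)


def fit_fisher_lda(values, labels, panel: Sequence[str] | None = None) -> Discriminant:
    """Fit a Fisher linear discriminant on the given panel columns.

    Weights are ``S_pooled^{-1} (mu_cancer - mu_noncancer)`` with pooled
    covariance denominator ``n1 + n0 - 2`` and a small relative ridge on the
    diagonal against singularity; the intercept puts index 0 at the midpoint
    of the projected class means, so the cancer class projects to >= 0.
    """
    if isinstance(values, pd.DataFrame) and panel is not None:
        values = values[list(panel)]
    X, y, cols = _as_matrix(values, labels)
    if panel is not None:
        cols = [str(p) for p in panel]
    if X.shape[1] > 3:
        raise ValueError(f"panel size {X.shape[1]} exceeds 3")
    n1, n0, m1, m0, S = _class_stats(X, y)
    pooled = S / (n1 + n0 - 2)
    # ridge only when the pooled covariance is singular/ill-conditioned, so
    # well-posed fits stay exactly affine-equivariant
    try:
        if np.linalg.cond(pooled) > 1e12:
            raise np.linalg.LinAlgError
        w = np.linalg.solve(pooled, m1 - m0)
    except np.linalg.LinAlgError:
        w = np.linalg.solve(_ridged(pooled), m1 - m0)
    if not np.all(np.isfinite(w)):
        w = np.linalg.solve(_ridged(pooled), m1 - m0)
    b = -float(w @ (m1 + m0) / 2.0)
    return Discriminant(tuple(cols), tuple(float(v) for v in w), b)


def apply_model(model: Discriminant, values) -> tuple[np.ndarray, np.ndarray]:
    """Compute diagnostic indexes and calls for one or many samples.

    ``values`` may be a mapping miRNA -> value (one sample), a DataFrame with
    miRNA columns, or an array aligned to the panel.  Returns (indexes,
    calls) where a call is ``"cancer"`` iff index >= 0 (inclusive rule).
    """
    if isinstance(values, Mapping):
        for m in model.mirna_ids:
            if m not in values:
                raise KeyError(f"sample is missing panel miRNA {m!r}")
        idx = np.array([model.index(values)])
    elif isinstance(values, pd.DataFrame):
        missing = [m for m in model.mirna_ids if m not in values.columns]
        if missing:
            raise KeyError(f"matrix is missing panel miRNA {missing[0]!r}")
        X = values[list(model.mirna_ids)].to_numpy(dtype=float)
        idx = X @ np.array(model.weights) + model.intercept
    else:
        X = np.atleast_2d(np.asarray(values, dtype=float))
        if X.shape[1] != len(model.mirna_ids):
            raise ValueError("array width does not match panel size")
        idx = X @ np.array(model.weights) + model.intercept
    calls = np.where(idx >= 0, "cancer", "non_cancer")
    return idx, calls


# ---------------------------------------------------------------------------
# leave-one-out cross-validation (vectorized downdate form)
# ---------------------------------------------------------------------------


def _loocv_batch(X: np.ndarray, y: np.ndarray, panels: np.ndarray, block: int = 4096) -> np.ndarray:
    """LOOCV accuracy for many panels at once.

    ``X`` is (n, M), ``panels`` an integer (P, k) array of column indexes.
    For every held-out sample the class mean and pooled scatter are
    downdated in closed form (rank-1), the Fisher weights re-solved, and the
    held-out sample classified by index >= 0.
    """
    n = X.shape[0]
    P, k = panels.shape
    n1, n0 = int(y.sum()), int((~y).sum())
    if min(n1, n0) < 3:
        raise ValueError("LOOCV needs >= 3 samples per class so every refit keeps >= 2")
    out = np.empty(P)
    r = np.where(y, n1 / (n1 - 1.0), n0 / (n0 - 1.0))  # scatter downdate factor per held-out i

    for s in range(0, P, block):
        pan = panels[s: s + block]
        p = pan.shape[0]
        A = X[:, pan].transpose(1, 0, 2)           # (p, n, k)
        m1 = A[:, y].mean(axis=1)                  # (p, k)
        m0 = A[:, ~y].mean(axis=1)
        C1 = A[:, y] - m1[:, None]
        C0 = A[:, ~y] - m0[:, None]
        S = np.einsum("pik,pil->pkl", C1, C1) + np.einsum("pik,pil->pkl", C0, C0)

        # held-out deviation from its own class mean
        msel = np.where(y[None, :, None], m1[:, None, :], m0[:, None, :])  # (p, n, k)
        U = A - msel
        S_i = S[:, None] - r[None, :, None, None] * np.einsum("pik,pil->pikl", U, U)

        # leave-one-out class means
        m1_i = np.where(
            y[None, :, None], (n1 * m1[:, None, :] - A) / (n1 - 1.0), m1[:, None, :]
        )
        m0_i = np.where(
            ~y[None, :, None], (n0 * m0[:, None, :] - A) / (n0 - 1.0), m0[:, None, :]
        )
        d = m1_i - m0_i
        pooled = S_i / (n - 3.0)
        tr = np.einsum("pikk->pi", pooled)
        eps = RIDGE * np.where(tr > 0, tr, 1.0) / k
        pooled = pooled + eps[..., None, None] * np.eye(k)
        w = np.linalg.solve(pooled, d[..., None])[..., 0]    # (p, n, k)
        score = np.einsum("pik,pik->pi", w, A - (m1_i + m0_i) / 2.0)
        pred = score >= 0.0
        out[s: s + p] = (pred == y[None, :]).mean(axis=1)
    return out


def loocv_score(values, labels, panel: Sequence[str] | None = None) -> float:
    """LOOCV classification accuracy of the Fisher discriminant on a panel."""
    if isinstance(values, pd.DataFrame) and panel is not None:
        values = values[list(panel)]
    X, y, _ = _as_matrix(values, labels)
    if X.shape[0] < 4:
        raise ValueError("LOOCV needs at least 4 samples")
    panels = np.arange(X.shape[1])[None, :]
    return float(_loocv_batch(X, y, panels)[0])


def _fit_batch(X: np.ndarray, y: np.ndarray, panels: np.ndarray):
    """Full-data Fisher fits for many panels: returns (W, b, indexes)."""
    n1, n0, _, _, _ = _class_stats(X[:, :1], y)  # validates class sizes
    A = X[:, panels].transpose(1, 0, 2)          # (P, n, k)
    m1 = A[:, y].mean(axis=1)
    m0 = A[:, ~y].mean(axis=1)
    C1 = A[:, y] - m1[:, None]
    C0 = A[:, ~y] - m0[:, None]
    S = np.einsum("pik,pil->pkl", C1, C1) + np.einsum("pik,pil->pkl", C0, C0)
    pooled = S / (n1 + n0 - 2.0)
    k = panels.shape[1]
    tr = np.einsum("pkk->p", pooled)
    eps = RIDGE * np.where(tr > 0, tr, 1.0) / k
    pooled = pooled + eps[:, None, None] * np.eye(k)
    W = np.linalg.solve(pooled, (m1 - m0)[..., None])[..., 0]   # (P, k)
    b = -np.einsum("pk,pk->p", W, (m1 + m0) / 2.0)
    idx = np.einsum("pnk,pk->pn", A, W) + b[:, None]
    return W, b, idx


def _auc_rows(idx: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Midrank (Mann-Whitney) AUC for each row of index vectors."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = sps.rankdata(idx, axis=1)
    return (ranks[:, y].sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n1 * n0)


# ---------------------------------------------------------------------------
# beam search
# ---------------------------------------------------------------------------


def beam_search(
    values,
    labels,
    max_size: int = 3,
    beam_width: int = 20,
) -> BeamState:
    """Grow 1..max_size-miRNA discriminant panels by beam search.

    Size-1 candidates are all miRNAs; size-(k+1) candidates extend every
    surviving size-k panel by every residual miRNA (deduplicated as sets).
    Ranking: LOOCV accuracy desc, apparent AUC desc, then lexicographic
    panel ids.  The top ``beam_width`` candidates survive at each size.
    """
    if beam_width < 1:
        raise ValueError(f"beam_width must be >= 1, got {beam_width}")
    X, y, cols = _as_matrix(values, labels)
    M = X.shape[1]
    if M < 1:
        raise ValueError("no candidate miRNAs")

    levels: dict[int, list[BeamCandidate]] = {}
    frontier = [(j,) for j in range(M)]
    for size in range(1, max_size + 1):
        if size > 1:
            seen: dict[frozenset, tuple] = {}
            for cand in levels[size - 1]:
                base = tuple(cols.index(m) for m in cand.panel)
                in_base = set(base)
                for j in range(M):
                    if j in in_base:
                        continue
                    key = frozenset(base + (j,))
                    if key not in seen:
                        seen[key] = base + (j,)
            frontier = list(seen.values())
        if not frontier:
            break
        panels = np.array(frontier, dtype=int)
        scores = _loocv_batch(X, y, panels)
        _, _, idx = _fit_batch(X, y, panels)
        aucs = _auc_rows(idx, y)
        order = sorted(
            range(len(frontier)),
            key=lambda i: (-scores[i], -aucs[i], tuple(sorted(cols[j] for j in frontier[i]))),
        )[:beam_width]
        ranked = []
        for i in order:
            panel_ids = tuple(cols[j] for j in frontier[i])
            model = fit_fisher_lda(pd.DataFrame(X[:, list(frontier[i])], columns=panel_ids), y)
            ranked.append(BeamCandidate(panel_ids, model, float(scores[i]), float(aucs[i])))
        levels[size] = ranked
    return BeamState(beam_width, levels)


# ---------------------------------------------------------------------------
# DeLong test for two correlated ROC curves
# ---------------------------------------------------------------------------


def _placements(scores: np.ndarray, y: np.ndarray):
    """Midrank structural components V10 (per case) and V01 (per control)."""
    x = scores[y]
    z = scores[~y]
    m, n = len(x), len(z)
    all_ranks = sps.rankdata(np.concatenate([x, z]))
    v10 = (all_ranks[:m] - sps.rankdata(x)) / n
    v01 = 1.0 - (all_ranks[m:] - sps.rankdata(z)) / m
    return v10, v01


def delong_auc_covariance(scores_a, scores_b, labels):
    """AUCs and the DeLong covariance matrix of (AUC_a, AUC_b)."""
    sa, sb = np.asarray(scores_a, float), np.asarray(scores_b, float)
    y = np.asarray(labels)
    if y.dtype.kind in "OU":
        y = y == "cancer"
    y = y.astype(bool)
    if not (len(sa) == len(sb) == len(y)):
        raise ValueError("index vectors and labels must be aligned")
    m, n = int(y.sum()), int((~y).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    V10 = np.stack([_placements(sa, y)[0], _placements(sb, y)[0]])
    V01 = np.stack([_placements(sa, y)[1], _placements(sb, y)[1]])
    aucs = V10.mean(axis=1)
    S10 = np.cov(V10, ddof=1) if m > 1 else np.zeros((2, 2))
    S01 = np.cov(V01, ddof=1) if n > 1 else np.zeros((2, 2))
    cov = S10 / m + S01 / n
    return float(aucs[0]), float(aucs[1]), cov


def delong_test(index_a, index_b, labels) -> tuple[float, float, float, float]:
    """DeLong's test for two correlated ROC curves.

    Returns (auc_a, auc_b, z, p) with a two-sided normal p-value.  Ties are
    handled by midranks.  Zero variance of the AUC difference yields p = 1
    when the AUCs are equal and raises otherwise.
    """
    auc_a, auc_b, cov = delong_auc_covariance(index_a, index_b, labels)
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 0:
        if np.isclose(auc_a, auc_b):
            return auc_a, auc_b, 0.0, 1.0
        raise ValueError("zero variance of the AUC difference with unequal AUCs")
    z = (auc_a - auc_b) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


# ---------------------------------------------------------------------------
# final model selection
# ---------------------------------------------------------------------------


def select_final_model(beams: BeamState, values, labels, alpha: float = 0.05) -> SelectionResult:
    """Pick the best AUC with the fewest miRNAs via consecutive DeLong tests.

    Starting from the one-miRNA champion, move to the (k+1)-miRNA champion
    only when its AUC is greater *and* DeLong's test rejects equality at
    ``alpha``; stop otherwise.
    """
    X, y, cols = _as_matrix(values, labels)
    df = pd.DataFrame(X, columns=cols)
    champions = {size: beams.champion(size) for size in sorted(beams.levels)}
    idx = {
        size: apply_model(c.model, df)[0] for size, c in champions.items()
    }
    aucs: dict[int, float] = {}
    pvals: dict[tuple[int, int], float] = {}
    sizes = sorted(champions)
    final = sizes[0]
    for k, k1 in zip(sizes, sizes[1:]):
        auc_hi, auc_lo, _, p = delong_test(idx[k1], idx[k], y)
        aucs.setdefault(k, auc_lo)
        aucs[k1] = auc_hi
        pvals[(k, k1)] = p
        if p < alpha and auc_hi > auc_lo:
            final = k1
        else:
            break
    if len(sizes) == 1:
        aucs[sizes[0]] = _auc_rows(idx[sizes[0]][None, :], y)[0]
    return SelectionResult(champions, pvals, aucs, final)
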