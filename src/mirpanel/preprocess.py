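"""Chip-level QC, presence calling, normalization and expression filtering.

The processing chain for serum microarray profiles:

1. **QC** — a chip is discarded when it has more than ``max_flags`` flagged
   spots ("uneven spot images") or a coefficient of variation of the
   negative-control signals greater than ``max_cv`` (either rule suffices).
2. **Presence call** — a miRNA is *present* when its signal strictly exceeds
   the trimmed negative-control mean + 2 SD (top and bottom 5% of negative
   controls removed by signal rank first); present signals then have that
   trimmed mean subtracted as background.
3. **Normalization** — per-sample linear scale factors bring the mean
   background-adjusted signal of three internal-control miRNAs onto the
   cohort-wide reference; values then move to the log2 scale.
4. **Floor** — absent or non-positive adjusted values are replaced with 0.1
   before taking log2 (i.e. log2(0.1) ~= -3.3219).
5. **Expression filter** — keep miRNAs with normalized log2 value > 6
   (signal > 2^6) in strictly more than half of the cancer samples or of the
   non-cancer samples.

geNorm stability ranking of candidate normalizers is provided to verify that
the internal controls behave as stable references in a given cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .simchip import ChipProfile, SampleMeta, frame_to_metas

__all__ = [
    "QCResult",
    "NegCtrlStats",
    "ExpressionMatrix",
    "ChipStructureError",
    "NormalizationError",
    "qc_chip",
    "negctrl_stats",
    "call_presence",
    "normalize_cohort",
    "genorm_stability",
    "filter_expressed",
    "read_chip_tsv",
    "read_chip_dir",
    "read_metadata_csv",
    "read_series_matrix",
    "write_qc_report",
    "FLOOR_LINEAR",
    "FLOOR_LOG2",
]

FLOOR_LINEAR = 0.1
FLOOR_LOG2 = math.log2(FLOOR_LINEAR)


class ChipStructureError(ValueError):
    """A chip is missing probes the pipeline requires."""


class NormalizationError(ValueError):
    """Internal-control normalization cannot proceed."""


@dataclass(frozen=True)
class QCResult:
    sample_id: str
    flag_count: int
    negctrl_cv: float
    passed: bool
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class NegCtrlStats:
    """Trimmed background statistics of the negative-control spots."""

    trimmed_mean: float
    trimmed_sd: float
    n_used: int

    @property
    def presence_threshold(self) -> float:
        return self.trimmed_mean + 2.0 * self.trimmed_sd


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression, samples x miRNAs, with presence mask."""

    samples: list[str]
    mirnas: list[str]
    values: np.ndarray    # (n_samples, n_mirnas) float64, log2 scale
    present: np.ndarray   # bool mask; floored cells are ~present
    factors: np.ndarray   # per-sample linear normalization factor

    def __post_init__(self) -> None:
        n, m = len(self.samples), len(self.mirnas)
        if self.values.shape != (n, m) or self.present.shape != (n, m):
            raise ValueError("ExpressionMatrix dimensions inconsistent")
        if len(self.factors) != n:
            raise ValueError("one normalization factor per sample required")
        if np.any(self.factors <= 0):
            raise ValueError("normalization factors must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.mirnas)

    def column(self, mirna: str) -> np.ndarray:
        try:
            j = self.mirnas.index(mirna)
        except ValueError:
            raise KeyError(f"miRNA {mirna!r} not in matrix") from None
        return self.values[:, j]

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", lineterminator="\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy(dtype=float)
        return cls(
            samples=list(df.index.astype(str)),
            mirnas=list(df.columns.astype(str)),
            values=values,
            present=values > FLOOR_LOG2,
            factors=np.ones(len(df)),
        )


# ---------------------------------------------------------------------------
# QC and presence
# ---------------------------------------------------------------------------


def qc_chip(chip: ChipProfile, max_flags: int = 10, max_cv: float = 0.15) -> QCResult:
    """Chip quality control.

    Fails with ``too_many_flags`` iff the flagged-spot count is strictly
    greater than ``max_flags``, and with ``high_negctrl_cv`` iff the
    coefficient of variation (sample sd / mean) of the *untrimmed*
    negative-control signals is strictly greater than ``max_cv``.
    """
    neg = chip.negctrl_signals
    if neg.size == 0:
        raise ChipStructureError(f"chip {chip.sample_id} has no negative-control probes")
    if neg.size < 2:
        raise ChipStructureError(f"chip {chip.sample_id} has fewer than 2 negative-control probes")
    cv = float(np.std(neg, ddof=1) / np.mean(neg))
    reasons = []
    if chip.flag_count > max_flags:
        reasons.append("too_many_flags")
    if cv > max_cv:
        reasons.append("high_negctrl_cv")
    return QCResult(chip.sample_id, chip.flag_count, cv, not reasons, tuple(reasons))


def negctrl_stats(chip: ChipProfile, trim_frac: float = 0.05) -> NegCtrlStats:
    """Background statistics after removing the top and bottom ``trim_frac``
    of negative-control spots by signal rank (floor(trim_frac*n) per side;
    rank ties broken by probe id for determinism)."""
    neg = chip.negctrl_signals
    ids = chip.negctrl_ids
    if neg.size < 2:
        raise ChipStructureError(f"chip {chip.sample_id} has fewer than 2 negative-control probes")
    order = np.lexsort((ids, neg))
    k = int(np.floor(trim_frac * neg.size))
    kept = neg[order][k: neg.size - k] if k > 0 else neg[order]
    if kept.size < 2:
        raise ValueError(f"chip {chip.sample_id}: trimming removed too many negative controls")
    return NegCtrlStats(float(np.mean(kept)), float(np.std(kept, ddof=1)), int(kept.size))


def call_presence(signal: float, stats: NegCtrlStats) -> tuple[bool, float | None]:
    """Present iff ``signal > trimmed_mean + 2*trimmed_sd`` (strict).

    Present signals are returned background-adjusted (minus the trimmed
    mean); absent signals return ``(False, None)``.
    """
    if signal < 0:
        raise ValueError(f"negative signal {signal}")
    if signal > stats.presence_threshold:
        return True, signal - stats.trimmed_mean
    return False, None


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_cohort(
    chips: Sequence[ChipProfile],
    control_ids: Sequence[str],
    trim_frac: float = 0.05,
    include_controls: bool = False,
) -> ExpressionMatrix:
    """Background-adjust, scale to the internal-control reference, log2.

    Per sample, the scale factor is (cohort-wide mean of the three controls'
    background-adjusted signals) / (this sample's mean of the three); every
    background-adjusted target signal is multiplied by it before log2.
    Absent or non-positive cells take the floor value log2(0.1).

    All chips are assumed to have passed QC.  Raises
    :class:`NormalizationError` naming chip and control if any internal
    control is absent (below background) on any chip.
    """
    if len(chips) == 0:
        raise ValueError("no chips to normalize")
    control_ids = list(control_ids)
    mirnas = list(chips[0].target_ids)
    if include_controls:
        mirnas = mirnas + control_ids

    n, m = len(chips), len(mirnas)
    adjusted = np.full((n, m), np.nan)
    present = np.zeros((n, m), dtype=bool)
    ctrl_means = np.empty(n)

    for i, chip in enumerate(chips):
        if list(chip.target_ids) != list(chips[0].target_ids):
            raise ChipStructureError(f"chip {chip.sample_id}: target probe set differs from cohort")
        stats = negctrl_stats(chip, trim_frac)
        thr = stats.presence_threshold

        ctrl_adj = []
        for cid in control_ids:
            try:
                sig = chip.signal_of(cid)
            except KeyError:
                raise NormalizationError(
                    f"chip {chip.sample_id}: internal control {cid!r} not on chip"
                ) from None
            ok, adj = call_presence(sig, stats)
            if not ok:
                raise NormalizationError(
                    f"chip {chip.sample_id}: internal control {cid!r} is not called present"
                )
            ctrl_adj.append(adj)
        ctrl_means[i] = float(np.mean(ctrl_adj))

        sig = np.concatenate([chip.target_signals, np.array(ctrl_adj) + stats.trimmed_mean]) \
            if include_controls else chip.target_signals
        pres = sig > thr
        adjusted[i] = np.where(pres, sig - stats.trimmed_mean, np.nan)
        present[i] = pres

    reference = float(np.mean(ctrl_means))
    factors = reference / ctrl_means

    scaled = adjusted * factors[:, None]
    floored = ~present | ~(scaled > 0)
    values = np.where(floored, FLOOR_LINEAR, np.where(np.isnan(scaled), FLOOR_LINEAR, scaled))
    values = np.log2(values)
    return ExpressionMatrix(
        samples=[c.sample_id for c in chips],
        mirnas=mirnas,
        values=values,
        present=~floored,
        factors=factors,
    )


def genorm_stability(
    matrix: ExpressionMatrix | pd.DataFrame, candidate_ids: Sequence[str]
) -> list[tuple[str, float]]:
    """Classic geNorm stability M for candidate reference miRNAs.

    For each candidate, M is the mean over all other candidates of the
    standard deviation (across samples) of the pairwise log2 ratio.  Values
    are already log2, so the ratio is a difference.  Returns (id, M) sorted
    by ascending M (most stable first).
    """
    df = matrix.to_frame() if isinstance(matrix, ExpressionMatrix) else matrix
    candidate_ids = list(candidate_ids)
    if len(candidate_ids) < 2:
        raise ValueError("geNorm needs at least two candidates")
    if len(df) < 2:
        raise ValueError("geNorm needs at least two samples")
    V = df[candidate_ids].to_numpy(dtype=float)
    if np.allclose(V, 0.0):
        raise ValueError("geNorm on an all-zero matrix is undefined")
    k = len(candidate_ids)
    M = np.empty(k)
    for j in range(k):
        sds = [np.std(V[:, j] - V[:, l], ddof=1) for l in range(k) if l != j]
        M[j] = float(np.mean(sds))
    order = np.argsort(M, kind="stable")
    return [(candidate_ids[j], float(M[j])) for j in order]


def filter_expressed(
    matrix: ExpressionMatrix | pd.DataFrame,
    labels: Mapping[str, str] | Sequence[str] | pd.Series,
    threshold_log2: float = 6.0,
    frac: float = 0.5,
) -> list[str]:
    """Keep highly expressed miRNAs: normalized log2 value strictly above
    ``threshold_log2`` in strictly more than ``frac`` of the cancer samples
    *or* of the non-cancer samples."""
    df = matrix.to_frame() if isinstance(matrix, ExpressionMatrix) else matrix
    lab = _align_labels(df.index, labels)
    cancer = lab == "cancer"
    if cancer.sum() == 0 or (~cancer).sum() == 0:
        raise ValueError("both cancer and non_cancer samples are required")
    above = df.to_numpy(dtype=float) > threshold_log2
    frac_cancer = above[cancer.to_numpy()].mean(axis=0)
    frac_non = above[(~cancer).to_numpy()].mean(axis=0)
    keep = (frac_cancer > frac) | (frac_non > frac)
    return [mid for mid, k in zip(df.columns, keep) if k]


def _align_labels(index, labels) -> pd.Series:
    if isinstance(labels, Mapping):
        lab = pd.Series({s: labels[s] for s in index})
    elif isinstance(labels, pd.Series):
        lab = labels.reindex(index)
        if lab.isna().any():
            raise ValueError("labels do not cover all samples")
    else:
        labels = list(labels)
        if len(labels) != len(index):
            raise ValueError("labels do not cover all samples")
        lab = pd.Series(labels, index=index)
    return lab


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_chip_tsv(path: str | Path) -> ChipProfile:
    """Read one chip table (``probe_id  probe_type  signal  flagged``)."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"probe_id": str, "probe_type": str},
        float_precision="round_trip",
    )
    expected = ["probe_id", "probe_type", "signal", "flagged"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    flagged = df["flagged"]
    if flagged.dtype != bool:
        flagged = flagged.astype(str).str.lower().isin(("true", "1"))
    return ChipProfile(
        sample_id=path.stem,
        probe_id=df["probe_id"].to_numpy(dtype=object),
        probe_type=df["probe_type"].to_numpy(dtype=object),
        signal=df["signal"].to_numpy(dtype=float),
        flagged=flagged.to_numpy(dtype=bool),
    )


def read_chip_dir(directory: str | Path) -> list[ChipProfile]:
    directory = Path(directory)
    return [read_chip_tsv(p) for p in sorted(directory.glob("*.tsv"))]


def read_metadata_csv(path: str | Path) -> list[SampleMeta]:
    return frame_to_metas(pd.read_csv(Path(path), float_precision="round_trip"))


def read_series_matrix(path: str | Path) -> pd.DataFrame:
    """Parse the data block of a GEO series-matrix TSV.

    Returns probes x samples values from between the
    ``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers,
    with surrounding quotes stripped from identifiers.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise ValueError(f"{path}: series-matrix table markers not found") from None
    block = lines[start + 1: end]
    if not block:
        raise ValueError(f"{path}: empty series-matrix table")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(block)), sep="\t")
    df.columns = [str(c).strip('"') for c in df.columns]
    df = df.set_index(df.columns[0])
    df.index = [str(i).strip('"') for i in df.index]
    return df.astype(float)


def write_qc_report(qcs: Iterable[QCResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": q.sample_id,
                "flag_count": q.flag_count,
                "negctrl_cv": q.negctrl_cv,
                "passed": q.passed,
                "reasons": ";".join(q.reasons),
            }
            for q in qcs
        ]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
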