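"""End-to-end orchestration: raw chips to a selected diagnostic model.

Chains the stages in study order: chip QC, sample exclusion, optional
one-to-one propensity matching of cancer vs non-cancer samples,
internal-control normalization, highly-expressed miRNA filtering, beam
search over 1-3-miRNA Fisher discriminants, and DeLong-based selection of
the final panel size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cohort import ExclusionReport, MatchResult, apply_exclusions, propensity_match
from .discovery import BeamState, SelectionResult, beam_search, select_final_model
from .preprocess import (
    ExpressionMatrix,
    QCResult,
    filter_expressed,
    normalize_cohort,
    qc_chip,
)
from .simchip import ChipProfile, SampleMeta, metas_to_frame

__all__ = ["PipelineResult", "discover_panel"]


@dataclass
class PipelineResult:
    qc: list[QCResult]
    exclusions: ExclusionReport
    match: MatchResult | None
    matrix: ExpressionMatrix
    kept_mirnas: list[str]
    beams: BeamState
    selection: SelectionResult
    labels: pd.Series  # per analyzed sample

    @property
    def final_model(self):
        return self.selection.final_model


def discover_panel(
    chips: Sequence[ChipProfile],
    metas: Sequence[SampleMeta] | pd.DataFrame,
    control_ids: Sequence[str],
    *,
    match: bool = False,
    beam_width: int = 20,
    max_size: int = 3,
    alpha: float = 0.05,
    threshold_log2: float = 6.0,
    frac: float = 0.5,
    max_flags: int = 10,
    max_cv: float = 0.15,
) -> PipelineResult:
    """Run the full discovery pipeline on raw chips plus metadata.

    ``match=True`` inserts one-to-one propensity matching of cancer vs
    non-cancer samples after exclusion — appropriate when carving a
    discovery set out of a larger unbalanced pool.  On an already
    size-balanced cohort a 1:1 pool leaves many cases without an
    in-caliper partner, so matching is off by default.
    """
    meta_df = metas_to_frame(metas).set_index("sample_id", drop=False)
    qcs = [qc_chip(c, max_flags=max_flags, max_cv=max_cv) for c in chips]
    report = apply_exclusions(meta_df, qcs)
    kept = set(report.kept_ids)

    match_result = None
    if match:
        kept_df = meta_df.loc[meta_df["sample_id"].isin(kept)]
        match_result = propensity_match(
            kept_df[kept_df["label"] == "cancer"],
            kept_df[kept_df["label"] == "non_cancer"],
        )
        kept = {s for pair in match_result.pairs for s in pair}

    chips_kept = [c for c in chips if c.sample_id in kept]
    matrix = normalize_cohort(chips_kept, control_ids)
    labels = meta_df.loc[matrix.samples, "label"]

    kept_mirnas = filter_expressed(matrix, labels, threshold_log2=threshold_log2, frac=frac)
    if not kept_mirnas:
        raise ValueError("no miRNAs survive the expression filter")
    values = matrix.to_frame()[kept_mirnas]
    beams = beam_search(values, labels, max_size=max_size, beam_width=beam_width)
    selection = select_final_model(beams, values, labels, alpha=alpha)
    return PipelineResult(qcs, report, match_result, matrix, kept_mirnas, beams, selection, labels)
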