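"""Clinical-score correlations and sex-stratified comparisons.

Spearman rank correlations relate each protein's NPX level to the NIHSS
(neurological deficit, 0-42) or ESRS (recurrence risk, 0-9) score within
the treatment arm.  The default scope pools the arm's baseline and
post-intervention observations into one correlation per protein; the
per-timepoint scope is available because pooling treats repeated measures
of a subject as independent observations — a descriptive convention, not a
statistical endorsement.

Sex comparisons run a per-protein two-sided rank test (Mann-Whitney by
default, Welch t by config) between male and female samples at one
timepoint, with Benjamini-Hochberg correction across the panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import AnalysisConfig, bh_fdr
from .npx_io import Arm, NPXMatrix, Sex, StudyDesign, Timepoint
from .ortho_screen import ScreenSets

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationRecord",
    "SexComparisonRecord",
    "spearman_scores",
    "overlap_with_core",
    "sex_comparison",
]

SCORE_NAMES = ("NIHSS", "ESRS")


@dataclass(frozen=True)
class CorrelationRecord:
    """Spearman association of one protein with one clinical score."""

    protein: str
    score_name: str
    rho: float  # NaN when undefined (constant input or n < 3)
    p: float
    n: int
    significant: bool


@dataclass(frozen=True)
class SexComparisonRecord:
    """Male-vs-female comparison of one protein at one timepoint."""

    protein: str
    timepoint: str
    p: float
    q: float
    significant_after_fdr: bool


def _score_value(sample, score_name: str) -> float | None:
    if score_name == "NIHSS":
        return sample.nihss
    if score_name == "ESRS":
        return sample.esrs
    raise ValueError(f"unknown score {score_name!r}; expected one of {SCORE_NAMES}")


def spearman_scores(
    matrix: NPXMatrix,
    design: StudyDesign,
    score_name: str,
    scope: str = "treatment_pooled",
    alpha: float = 0.05,
) -> list[CorrelationRecord]:
    """Per-protein Spearman rho between NPX and a clinical score.

    ``treatment_pooled`` pools T1 and T2 observations of the treatment arm;
    ``per_timepoint`` returns separate records for T1 and T2 (the record's
    score_name is suffixed with the group label).  Average ranks break ties;
    p comes from the t-approximation on rho with n - 2 df.  Constant protein
    or score vectors, or fewer than 3 usable observations, yield an NA
    record (rho = NaN, significant = False).
    """
    if scope == "treatment_pooled":
        batches = [("", design.group_samples("T1") + design.group_samples("T2"))]
    elif scope == "per_timepoint":
        batches = [("@T1", design.group_samples("T1")), ("@T2", design.group_samples("T2"))]
    else:
        raise ValueError("scope must be 'treatment_pooled' or 'per_timepoint'")

    records: list[CorrelationRecord] = []
    for suffix, sample_ids in batches:
        cols = [matrix.sample_index(s) for s in sample_ids]
        scores = np.array(
            [
                np.nan if (v := _score_value(design.sample_by_id[s], score_name)) is None else float(v)
                for s in sample_ids
            ]
        )
        for i, g in enumerate(matrix.protein_ids):
            x = matrix.values[i, cols]
            ok = ~(matrix.missing_mask[i, cols] | np.isnan(scores))
            xo, yo = x[ok], scores[ok]
            n = int(ok.sum())
            label = score_name + suffix
            if n < 3 or np.all(xo == xo[0]) or np.all(yo == yo[0]):
                if n < 3:
                    logger.info("spearman %s/%s: only %d usable observations", g, label, n)
                records.append(CorrelationRecord(g, label, float("nan"), float("nan"), n, False))
                continue
            rho, p = stats.spearmanr(xo, yo)
            records.append(
                CorrelationRecord(g, label, float(rho), float(p), n, bool(p < alpha))
            )
    return records


def correlations_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [r.protein for r in records],
            "score": [r.score_name for r in records],
            "rho": [r.rho for r in records],
            "p": [r.p for r in records],
            "n": [r.n for r in records],
            "significant": [r.significant for r in records],
        }
    )


def overlap_with_core(
    correlations: list[CorrelationRecord], sets: ScreenSets
) -> tuple[list[str], int]:
    """Score-correlated proteins that also survived the screen.

    Returns the intersection of the significantly correlated proteins with
    the core set, sorted by descending |rho|, plus its count.
    """
    rho_of = {r.protein: abs(r.rho) for r in correlations if r.significant}
    hits = set(rho_of) & sets.core
    ordered = sorted(hits, key=lambda g: (-rho_of[g], g))
    return ordered, len(ordered)


def sex_comparison(
    matrix: NPXMatrix,
    design: StudyDesign,
    timepoint: Timepoint | str = Timepoint.BASELINE,
    config: AnalysisConfig | None = None,
) -> list[SexComparisonRecord]:
    """Per-protein male-vs-female comparison at one timepoint, BH-corrected.

    Both sexes must be represented; proteins with fewer than 2 usable
    observations in either sex get an NA p-value that is ignored by the BH
    step.  significant_after_fdr is q < alpha.
    """
    config = config or AnalysisConfig()
    tp = Timepoint(timepoint) if not isinstance(timepoint, Timepoint) else timepoint
    cols, sexes = [], []
    for j, s in enumerate(matrix.samples):
        if s.timepoint is tp and s.sex in (Sex.MALE, Sex.FEMALE):
            cols.append(j)
            sexes.append(s.sex)
    sexes = np.array([s.value for s in sexes])
    if "male" not in sexes or "female" not in sexes:
        raise ValueError(f"both sexes must be represented at timepoint {tp.value!r}")

    male = np.array(cols)[sexes == "male"]
    female = np.array(cols)[sexes == "female"]
    pvals = []
    for i, g in enumerate(matrix.protein_ids):
        m = matrix.values[i, male][~matrix.missing_mask[i, male]]
        f = matrix.values[i, female][~matrix.missing_mask[i, female]]
        if m.size < 2 or f.size < 2:
            pvals.append(np.nan)
            continue
        if config.sex_test == "welch":
            p = stats.ttest_ind(m, f, equal_var=False).pvalue
        else:
            p = stats.mannwhitneyu(m, f, alternative="two-sided").pvalue
        pvals.append(float(p))
    q = bh_fdr(pvals)
    return [
        SexComparisonRecord(
            protein=g,
            timepoint=tp.value,
            p=pvals[i],
            q=float(q[i]),
            significant_after_fdr=bool(q[i] < config.alpha) if not np.isnan(q[i]) else False,
        )
        for i, g in enumerate(matrix.protein_ids)
    ]


def sex_comparison_frame(records: list[SexComparisonRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [r.protein for r in records],
            "timepoint": [r.timepoint for r in records],
            "p": [r.p for r in records],
            "q": [r.q for r in records],
            "significant_after_fdr": [r.significant_after_fdr for r in records],
        }
    )
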