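"""The six-contrast framework and the triple orthogonal screen.

The trial design yields four cells — treatment baseline (T1), treatment
post (T2), control baseline (C1), control post (C2) — compared along six
axes: four unpaired group contrasts (G1: T2 vs C1, G2: C2 vs T1,
G3: T1 vs C1, G4: T2 vs C2) and two paired longitudinal contrasts within
arm (P1: T2 vs T1, P2: C2 vs C1).  G1 and G2 are descriptive only; the
screen itself rests on G3, G4, P1 and P2.

The screen isolates treatment-specific proteins by set algebra:

* Set 1 — no baseline difference (G3 p > alpha) but a post-intervention
  between-arm difference (G4 p < alpha);
* Set 2 — time-dependent proteins, changing in the control arm (P2);
* Set 3 — treatment-responsive proteins, changing in the treatment arm (P1);
* Set 4 = Set 1 minus Set 2 (strip time-confounded proteins);
* Set 5 = Set 1 intersect Set 3;
* core = Set 3 ∩ Set 4 ∩ Set 5, which reduces algebraically to
  (Set 1 ∩ Set 3) \\ Set 2.

Every membership is decided by the configured rule (p-only or p-and-fold-
change); inequalities are strict on both sides, so p exactly equal to alpha
is neither significant nor baseline-null-eligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexp import (
    AnalysisConfig,
    ContrastResult,
    classify_deps,
    fit_ebayes_prior,
    moderated_test,
    ordinary_stats,
)
from .npx_io import NPXMatrix, StudyDesign
from .synthetic_cohort import SimulationTruth

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastSpec",
    "CONTRASTS",
    "SCREEN_CONTRASTS",
    "ScreenSets",
    "RecoveryReport",
    "run_contrasts",
    "build_screen_sets",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class ContrastSpec:
    """One of the six comparison axes.

    ``group_a`` is the first-named group: a positive effect means higher
    NPX in ``group_a``.  Paired contrasts name the arm whose complete
    subject pairs supply the within-subject differences.
    """

    name: str
    group_a: str
    group_b: str
    paired: bool = False
    arm: str | None = None


CONTRASTS: dict[str, ContrastSpec] = {
    "G1": ContrastSpec("G1", "T2", "C1"),
    "G2": ContrastSpec("G2", "C2", "T1"),
    "G3": ContrastSpec("G3", "T1", "C1"),
    "G4": ContrastSpec("G4", "T2", "C2"),
    "P1": ContrastSpec("P1", "T2", "T1", paired=True, arm="treatment"),
    "P2": ContrastSpec("P2", "C2", "C1", paired=True, arm="control"),
}

#: The contrasts the screen itself consumes (G1/G2 are descriptive only).
SCREEN_CONTRASTS = ("G3", "G4", "P1", "P2")


@dataclass
class ScreenSets:
    """The five screening sets plus the treatment-specific core."""

    set1: set[str]
    set2: set[str]
    set3: set[str]
    set4: set[str]
    set5: set[str]
    core: set[str]
    universe: set[str]
    alpha: float
    membership_rule: str

    def cardinalities(self) -> dict[str, int]:
        return {
            "set1": len(self.set1),
            "set2": len(self.set2),
            "set3": len(self.set3),
            "set4": len(self.set4),
            "set5": len(self.set5),
            "core": len(self.core),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.universe):
            rows.append(
                {
                    "protein": g,
                    "set1": int(g in self.set1),
                    "set2": int(g in self.set2),
                    "set3": int(g in self.set3),
                    "set4": int(g in self.set4),
                    "set5": int(g in self.set5),
                    "core": int(g in self.core),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class RecoveryReport:
    """How well the screen recovered the planted protein classes."""

    sensitivity: float
    specificity: float
    leakage: dict[str, float]
    confusion: dict[str, dict[str, int]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, cells in self.confusion.items():
            rows.append({"class": label, **cells})
        return pd.DataFrame(rows)


def run_contrasts(
    matrix: NPXMatrix, design: StudyDesign, config: AnalysisConfig
) -> dict[str, ContrastResult]:
    """All six moderated contrasts, each with its own shrinkage prior.

    Orientation: positive log2FC means higher in the first-named group —
    T2 for G1/G4/P1, C2 for G2/P2, T1 for G3.
    """
    results: dict[str, ContrastResult] = {}
    for name, spec in CONTRASTS.items():
        stats_in = ordinary_stats(matrix, design, spec)
        prior = fit_ebayes_prior(stats_in)
        result = moderated_test(stats_in, prior, contrast_name=name)
        classify_deps(result, config)
        results[name] = result
    return results


def _significant(result: ContrastResult, config: AnalysisConfig) -> dict[str, bool]:
    """Membership test per protein under the configured rule (strict <)."""
    sig = result.p < config.alpha
    if config.membership_rule == "p_and_fc":
        sig = sig & (np.abs(result.beta_hat) > config.fc_cut)
    sig = np.where(np.isnan(result.p), False, sig)
    return dict(zip(result.protein_ids, map(bool, sig)))


def build_screen_sets(
    results: dict[str, ContrastResult], config: AnalysisConfig
) -> ScreenSets:
    """Apply the triple orthogonal screen to the four constituent contrasts.

    The screening universe is restricted to proteins tested in all of G3,
    G4, P1 and P2; proteins dropped anywhere are excluded and logged.
    """
    missing = [c for c in SCREEN_CONTRASTS if c not in results]
    if missing:
        raise ValueError(f"screen requires contrasts {SCREEN_CONTRASTS}; missing {missing}")

    universe = set(results["G3"].protein_ids)
    for c in SCREEN_CONTRASTS[1:]:
        universe &= set(results[c].protein_ids)
    excluded = set().union(*(results[c].protein_ids for c in SCREEN_CONTRASTS)) - universe
    if excluded:
        logger.info("screen: %d protein(s) excluded for missing contrasts: %s",
                    len(excluded), sorted(excluded))

    sig_g4 = _significant(results["G4"], config)
    sig_p1 = _significant(results["P1"], config)
    sig_p2 = _significant(results["P2"], config)
    p_g3 = dict(zip(results["G3"].protein_ids, results["G3"].p))

    # ties at exactly alpha fail both the p < alpha and the p > alpha test
    ties = [g for g in universe if p_g3[g] == config.alpha]
    if ties:
        logger.warning("screen: G3 p exactly at alpha for %s", sorted(ties))

    set1 = {g for g in universe if (p_g3[g] > config.alpha) and sig_g4[g]}
    set2 = {g for g in universe if sig_p2[g]}
    set3 = {g for g in universe if sig_p1[g]}
    set4 = set1 - set2
    set5 = set1 & set3
    core = set3 & set4 & set5

    return ScreenSets(
        set1=set1, set2=set2, set3=set3, set4=set4, set5=set5, core=core,
        universe=universe, alpha=config.alpha, membership_rule=config.membership_rule,
    )


def evaluate_recovery(sets: ScreenSets, truth: SimulationTruth) -> RecoveryReport:
    """Confusion of the core set against the planted protein classes.

    Sensitivity is the fraction of treatment-specific proteins recovered in
    the core; specificity the fraction of all other proteins kept out;
    leakage rates are reported separately for the time-dependent and mixed
    classes, whose exclusion is the screen's stated purpose.
    """
    if set(truth.protein_ids) != sets.universe:
        extra = sets.universe - set(truth.protein_ids)
        miss = set(truth.protein_ids) - sets.universe
        raise ValueError(
            f"protein universe mismatch between screen and truth "
            f"(screen-only: {sorted(extra)[:5]}, truth-only: {sorted(miss)[:5]})"
        )

    confusion: dict[str, dict[str, int]] = {}
    for label in ("null", "treatment_specific", "time_dependent", "baseline_shifted", "mixed"):
        members = truth.proteins_of_class(label)
        in_core = len(members & sets.core)
        confusion[label] = {"total": len(members), "in_core": in_core, "out_of_core": len(members) - in_core}

    ts = truth.proteins_of_class("treatment_specific")
    non_ts = set(truth.protein_ids) - ts
    sensitivity = len(ts & sets.core) / len(ts) if ts else float("nan")
    specificity = len(non_ts - sets.core) / len(non_ts) if non_ts else float("nan")
    leakage = {}
    for label in ("time_dependent", "mixed", "null", "baseline_shifted"):
        members = truth.proteins_of_class(label)
        leakage[label] = len(members & sets.core) / len(members) if members else float("nan")
    return RecoveryReport(
        sensitivity=sensitivity, specificity=specificity, leakage=leakage, confusion=confusion
    )
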