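"""Random-forest importance ranking of screened proteins.

A bagged ensemble of CART trees classifies the treatment arm's samples by
timepoint (pre vs post by default; arm is available by config) from the NPX
levels of a chosen protein set, and ranks the proteins by the two classic
forest importance measures:

* mean decrease in accuracy — for each tree, the drop in out-of-bag (OOB)
  accuracy when one feature's OOB values are randomly permuted, averaged
  over trees (unscaled);
* mean decrease in Gini — the total Gini impurity reduction attributed to
  splits on the feature, averaged over trees.

The bagging loop is explicit (scikit-learn decision trees underneath) so
that each tree's bootstrap and OOB sample is known and the permutation
importance is computed on genuine OOB predictions, mirroring the classic
forest implementation.  All randomness (bootstraps, split tie-breaks,
permutations) derives from one seed, so identical seeds give identical
rankings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.tree import DecisionTreeClassifier

from .diffexp import AnalysisConfig
from .npx_io import Arm, NPXMatrix, StudyDesign, Timepoint

__all__ = ["ImportanceRecord", "rf_importance", "importance_frame"]


@dataclass(frozen=True)
class ImportanceRecord:
    """Both importance measures and ranks for one protein feature."""

    protein: str
    mean_decrease_accuracy: float
    mean_decrease_gini: float
    rank_mda: int
    rank_gini: int


def _target_labels(design: StudyDesign, sample_ids: list[str], target: str) -> np.ndarray:
    if target == "timepoint":
        return np.array(
            [design.sample_by_id[s].timepoint is Timepoint.POST for s in sample_ids], dtype=int
        )
    if target == "arm":
        return np.array(
            [design.sample_by_id[s].arm is Arm.TREATMENT for s in sample_ids], dtype=int
        )
    raise ValueError("rf_target must be 'timepoint' or 'arm'")


def rf_importance(
    matrix: NPXMatrix,
    design: StudyDesign,
    features: set[str] | list[str],
    config: AnalysisConfig | None = None,
) -> list[ImportanceRecord]:
    """Rank a protein set by OOB permutation and Gini importance.

    By default the classifier separates pre- from post-intervention samples
    of the treatment arm.  Features must exist on the panel; each class
    needs at least 4 samples.  Samples with any missing feature value are
    excluded (the trees have no missing-value handling).
    """
    config = config or AnalysisConfig()
    features = sorted(features)
    missing = [g for g in features if g not in matrix.protein_ids]
    if missing:
        raise ValueError(f"features absent from the panel: {missing}")

    if config.rf_target == "timepoint":
        sample_ids = design.group_samples("T1") + design.group_samples("T2")
    else:
        sample_ids = [s.sample_id for s in matrix.samples]
    y_all = _target_labels(design, sample_ids, config.rf_target)

    rows = [matrix.protein_index(g) for g in features]
    cols = [matrix.sample_index(s) for s in sample_ids]
    X = matrix.values[np.ix_(rows, cols)].T  # samples x features
    usable = ~matrix.missing_mask[np.ix_(rows, cols)].any(axis=0)
    X, y = X[usable], y_all[usable]

    for cls in (0, 1):
        if (y == cls).sum() < 4:
            raise ValueError(
                f"class {cls} has {(y == cls).sum()} samples; need >= 4 per class"
            )

    n, p = X.shape
    n_trees = config.rf_n_trees
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5F0]))

    mda_sum = np.zeros(p)
    gini_sum = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features=config.rf_max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        gini_sum += tree.tree_.compute_feature_importances(normalize=False) * len(boot)
        if oob.size == 0:
            continue
        # one stacked prediction call: baseline OOB block + one permuted
        # block per feature
        blocks = [X[oob]]
        for f in range(p):
            perm = X[oob].copy()
            perm[:, f] = perm[rng.permutation(oob.size), f]
            blocks.append(perm)
        pred = tree.predict(np.vstack(blocks)).reshape(p + 1, oob.size)
        acc = (pred == y[oob]).mean(axis=1)
        mda_sum += acc[0] - acc[1:]

    mda = mda_sum / n_trees
    gini = gini_sum / n_trees
    # rank 1 = most important; ties broken by feature order for stability
    rank_mda = rankdata(-mda, method="ordinal")
    rank_gini = rankdata(-gini, method="ordinal")
    return [
        ImportanceRecord(
            protein=g,
            mean_decrease_accuracy=float(mda[f]),
            mean_decrease_gini=float(gini[f]),
            rank_mda=int(rank_mda[f]),
            rank_gini=int(rank_gini[f]),
        )
        for f, g in enumerate(features)
    ]


def importance_frame(records: list[ImportanceRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "protein": [r.protein for r in records],
            "mean_decrease_accuracy": [r.mean_decrease_accuracy for r in records],
            "mean_decrease_gini": [r.mean_decrease_gini for r in records],
            "rank_mda": [r.rank_mda for r in records],
            "rank_gini": [r.rank_gini for r in records],
        }
    )
    return df.sort_values("rank_mda").reset_index(drop=True)
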