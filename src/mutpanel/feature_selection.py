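"""Gene-panel discovery: random-forest importance ranking with a sequential
backward search (SBS) under 10-fold cross-validation.

The discovery loop fits a random-forest classifier of a binarized survival
outcome on the binary gene matrix, scores mean cross-validated accuracy,
removes the lowest-importance genes according to an adaptive step schedule
(large steps while hundreds of features remain, single-gene steps below 50),
and repeats until one gene is left.  The returned panel is the smallest gene
set attaining the maximal mean CV accuracy along that trace: redundant and
irrelevant features typically depress accuracy, so the trace rises as they
are discarded and falls once informative genes start being removed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold, cross_val_score, cross_validate

from .cohort_io import ClinicalRecord
from .mutation_features import BinaryMutationMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutcomeLabels:
    """Binary outcome per sample, aligned with the mutation matrix."""

    sample_ids: tuple[str, ...]
    labels: tuple[int, ...]
    scheme: str = "event_indicator"

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("sample_ids and labels lengths differ")
        if set(self.labels) - {0, 1}:
            raise ValueError("labels must be binary")

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=list(self.sample_ids), name="label")


@dataclass(frozen=True)
class RfConfig:
    """Random-forest and cross-validation settings for the discovery loop.

    The classifier itself carries no stated hyperparameters in the method it
    implements; the defaults here favour ranking stability on sparse binary
    features: 300 trees, balanced class weights, Gini (impurity) variable
    importance.  ``importance_kind="permutation"`` switches to permutation
    importance on the training data.
    """

    n_trees: int = 100
    importance_kind: str = "impurity"  # or "permutation"
    cv_folds: int = 10
    seed: int = 0
    class_weighting: str = "balanced"  # or "none"
    permutation_repeats: int = 5

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.importance_kind not in ("impurity", "permutation"):
            raise ValueError("importance_kind must be 'impurity' or 'permutation'")
        if self.class_weighting not in ("none", "balanced"):
            raise ValueError("class_weighting must be 'none' or 'balanced'")

    def make_forest(self, seed_offset: int = 0) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            class_weight=None if self.class_weighting == "none" else "balanced",
            random_state=(self.seed + seed_offset) % (2**31),
            n_jobs=1,
        )


@dataclass(frozen=True)
class StepSchedule:
    """Adaptive SBS step sizes as (threshold, step) tiers.

    The step for a feature count ``n`` is the step of the first tier with
    ``n >= threshold``.  The default removes 100 genes per iteration while at
    least 400 remain, then 50, then 20, and one gene at a time once fewer
    than 51 remain.
    """

    tiers: tuple[tuple[int, int], ...] = ((400, 100), (150, 50), (51, 20), (1, 1))

    def __post_init__(self) -> None:
        thresholds = [t for t, _ in self.tiers]
        if thresholds != sorted(thresholds, reverse=True):
            raise ValueError("tier thresholds must be strictly decreasing")
        if len(set(thresholds)) != len(thresholds):
            raise ValueError("tier thresholds must be strictly decreasing")
        if any(s <= 0 for _, s in self.tiers):
            raise ValueError("steps must be positive")
        if thresholds[-1] != 1:
            raise ValueError("last tier must have threshold 1 so the search can finish")

    def step_for(self, n_features: int) -> int:
        for threshold, step in self.tiers:
            if n_features >= threshold:
                # Never step past a single remaining feature.
                return min(step, n_features - 1) if n_features > 1 else 0
        raise ValueError(f"no tier for n_features={n_features}")

    def planned_sizes(self, start: int) -> list[int]:
        """The feature counts the search will visit, starting from ``start``."""
        sizes, n = [], start
        while n >= 1:
            sizes.append(n)
            if n == 1:
                break
            n -= self.step_for(n)
        return sizes

    @classmethod
    def from_list(cls, tiers: Sequence[Sequence[int]]) -> "StepSchedule":
        return cls(tuple((int(t), int(s)) for t, s in tiers))


@dataclass
class SelectionIteration:
    n_features: int
    mean_cv_accuracy: float
    retained_genes: list[str]
    step_size: int


@dataclass
class SelectionTrace:
    """Per-iteration record of the backward search."""

    iterations: list[SelectionIteration] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = [it.n_features for it in self.iterations]
        if any(a <= b for a, b in zip(sizes, sizes[1:])):
            raise ValueError("n_features must be strictly decreasing along the trace")

    def sizes(self) -> list[int]:
        return [it.n_features for it in self.iterations]

    def accuracies(self) -> list[float]:
        return [it.mean_cv_accuracy for it in self.iterations]

    def to_json(self) -> str:
        return json.dumps(
            {"iterations": [asdict(it) for it in self.iterations]},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SelectionTrace":
        data = json.loads(text)
        return cls([SelectionIteration(**it) for it in data["iterations"]])


# ---------------------------------------------------------------------------
# Outcome binarization


def binarize_outcome(
    clinical: Sequence[ClinicalRecord],
    scheme: str = "alive_at_horizon",
    horizon_months: float = 12.0,
) -> OutcomeLabels:
    """Convert survival follow-up to a binary training label.

    Two schemes:

    ``event_indicator``
        label = the event flag (1 = died/progressed during follow-up).
    ``alive_at_horizon`` (default, horizon 12 months)
        label 1 = event observed before the horizon, label 0 = alive at the
        horizon; samples censored before the horizon carry no information
        about it and are excluded (count logged).

    The landmark scheme is the default for discovery because the raw event
    indicator conflates follow-up length with outcome under administrative
    censoring, which can leave a severely imbalanced, nearly uninformative
    label.
    """
    ids: list[str] = []
    labels: list[int] = []
    excluded = 0
    for rec in clinical:
        if scheme == "event_indicator":
            ids.append(rec.sample_id)
            labels.append(int(rec.event))
        elif scheme == "alive_at_horizon":
            if rec.time_months >= horizon_months:
                ids.append(rec.sample_id)
                labels.append(0)  # alive at the landmark
            elif rec.event:
                ids.append(rec.sample_id)
                labels.append(1)  # died before the landmark
            else:
                excluded += 1  # censored before the landmark: uninformative
        else:
            raise ValueError(f"unknown binarization scheme {scheme!r}")
    if excluded:
        logger.info(
            "binarize_outcome(%s, h=%.1f): excluded %d samples censored before the horizon",
            scheme, horizon_months, excluded,
        )
    if len(set(labels)) < 2:
        raise ValueError(
            "outcome binarization produced a single class; a classifier is undefined"
        )
    scheme_tag = scheme if scheme == "event_indicator" else f"alive_at_horizon({horizon_months:g})"
    return OutcomeLabels(tuple(ids), tuple(labels), scheme=scheme_tag)


def _align(
    matrix: BinaryMutationMatrix, labels: OutcomeLabels
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    matrix_samples = set(matrix.sample_ids)
    label_samples = set(labels.sample_ids)
    usable = [s for s in labels.sample_ids if s in matrix_samples]
    missing = label_samples - matrix_samples
    if missing:
        raise ValueError(f"labelled samples absent from the matrix: {sorted(missing)}")
    X = matrix.df.loc[usable].to_numpy(dtype=np.float32)
    y = labels.as_series().loc[usable].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("aligned labels contain a single class")
    return X, y, usable


# ---------------------------------------------------------------------------
# Ranking and backward search


def rank_features(
    matrix: BinaryMutationMatrix, labels: OutcomeLabels, cfg: RfConfig | None = None
) -> pd.Series:
    """Rank genes by random-forest variable importance (descending).

    Returns a Series mapping gene -> importance, sorted descending with the
    gene name as a deterministic tie-break, reproducible under a fixed seed.
    """
    cfg = cfg or RfConfig()
    X, y, _ = _align(matrix, labels)
    forest = cfg.make_forest()
    forest.fit(X, y)
    if cfg.importance_kind == "impurity":
        scores = forest.feature_importances_
    else:
        result = permutation_importance(
            forest, X, y,
            n_repeats=cfg.permutation_repeats,
            random_state=cfg.seed % (2**31),
            n_jobs=1,
        )
        scores = result.importances_mean
    ser = pd.Series(scores, index=matrix.genes, name="importance")
    return ser.sort_values(ascending=False, kind="mergesort").reindex(
        sorted(ser.index, key=lambda g: (-ser[g], g))
    )


def sbs_select(
    matrix: BinaryMutationMatrix,
    labels: OutcomeLabels,
    cfg: RfConfig | None = None,
    schedule: StepSchedule | None = None,
) -> SelectionTrace:
    """Sequential backward search over gene subsets.

    Each iteration fits the forest under stratified cross-validation on the
    current subset, records the mean CV accuracy, re-ranks the subset's genes
    by variable importance averaged over the fold fits (recomputed every
    iteration, never frozen from the first fit), drops the ``step``
    lowest-importance genes per the current schedule tier, and continues
    until a single gene remains.
    """
    cfg = cfg or RfConfig()
    schedule = schedule or StepSchedule()
    if matrix.shape[1] < 2:
        raise ValueError("backward search needs at least 2 genes")
    X_full, y, usable = _align(matrix, labels)
    genes = list(matrix.genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    current = list(genes)
    iterations: list[SelectionIteration] = []

    it = 0
    while True:
        cols = [gene_idx[g] for g in current]
        X = X_full[:, cols]
        folds = min(cfg.cv_folds, int(np.bincount(y).min()))
        if folds < 2:
            raise ValueError("too few samples in the minority class for cross-validation")
        cv = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=(cfg.seed + it) % (2**31)
        )
        fit = cross_validate(
            cfg.make_forest(it), X, y, cv=cv, scoring="accuracy",
            return_estimator=True, n_jobs=1,
        )
        acc = float(np.mean(fit["test_score"]))
        step = schedule.step_for(len(current))
        iterations.append(
            SelectionIteration(
                n_features=len(current),
                mean_cv_accuracy=acc,
                retained_genes=list(current),
                step_size=step,
            )
        )
        if len(current) == 1:
            break
        if cfg.importance_kind == "impurity":
            scores = np.mean(
                [est.feature_importances_ for est in fit["estimator"]], axis=0
            )
        else:
            forest = cfg.make_forest(it)
            forest.fit(X, y)
            scores = permutation_importance(
                forest, X, y,
                n_repeats=cfg.permutation_repeats,
                random_state=(cfg.seed + it) % (2**31),
                n_jobs=1,
            ).importances_mean
        # Lowest-importance genes drop first; name breaks exact ties so the
        # trace is reproducible bit-for-bit.
        order = sorted(range(len(current)), key=lambda i: (scores[i], current[i]))
        doomed = {current[i] for i in order[:step]}
        current = [g for g in current if g not in doomed]
        it += 1
    return SelectionTrace(iterations)


def choose_best_subset(trace: SelectionTrace, tie_tolerance: float = 0.0) -> list[str]:
    """Smallest gene set achieving the maximal mean CV accuracy.

    Among iterations whose accuracy is within ``tie_tolerance`` of the best,
    the one with the fewest genes wins; remaining ties go to the earliest
    iteration.
    """
    if not trace.iterations:
        raise ValueError("empty selection trace")
    best = max(it.mean_cv_accuracy for it in trace.iterations)
    candidates = [
        (it.n_features, i)
        for i, it in enumerate(trace.iterations)
        if it.mean_cv_accuracy >= best - tie_tolerance
    ]
    _, idx = min(candidates)
    return list(trace.iterations[idx].retained_genes)
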