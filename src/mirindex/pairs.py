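"""Pair-ratio index classification.

A model is an ordered list of (up, down) molecule pairs — one member
over-expressed and one under-expressed in the positive group — and the
per-sample index is the product over pairs of the ratio of the up member's
expression to the down member's.  Samples of the positive group score high;
a cutoff on the (log) index separates the groups.  Pairs are selected
greedily by the product of the members' direction confidences, adding pairs
until leave-one-out sensitivity and specificity targets are met or the pair
budget is exhausted.  This is a relative-expression classifier in the
spirit of top-scoring-pairs methods, but ranked by median-confidence
statements rather than rank-inversion scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .confidence import (
    DIRECTION_GREATER,
    DIRECTION_LESS,
    ConfidenceStatement,
    best_confidence,
)

ORIENTATIONS = ("directional", "max-min")


@dataclass(frozen=True)
class MoleculePair:
    """An (up, down) molecule pair with its selection score
    (product of the two members' direction confidences)."""

    up_id: str
    down_id: str
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.up_id == self.down_id:
            raise ValueError("pair members must differ")


@dataclass
class IndexModel:
    """Ordered pair list, classification cutoff and index conventions."""

    pairs: list
    cutoff: float
    orientation: str = "directional"
    epsilon: float = 1e-6
    positive_label: object = None
    warning: bool = False

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise ValueError("index model needs at least one pair")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")


@dataclass
class ClassificationReport:
    """Per-sample indices and predictions with recall summaries."""

    per_sample: pd.DataFrame  # columns: index, predicted, true
    sensitivity: float
    specificity: float
    scheme: str  # "leave-one-out" or "resubstitution"

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def compute_index(sample: pd.Series, model: IndexModel) -> float:
    """Product-of-ratios index for one sample.

    directional: prod over pairs of value(up)/value(down); max-min: prod of
    max/min within each pair.  Non-positive values are replaced by the
    model's epsilon so the index stays finite and positive.
    """
    total = 1.0
    for p in model.pairs:
        for m in (p.up_id, p.down_id):
            if m not in sample.index:
                raise KeyError(f"molecule {m!r} missing from sample")
        up = float(sample[p.up_id])
        down = float(sample[p.down_id])
        up = up if up > 0 else model.epsilon
        down = down if down > 0 else model.epsilon
        if model.orientation == "max-min":
            up, down = max(up, down), min(up, down)
        total *= up / down
    return total


def compute_indices(matrix: pd.DataFrame, model: IndexModel) -> pd.Series:
    """Index per sample for a molecules x samples matrix."""
    missing = [
        m
        for p in model.pairs
        for m in (p.up_id, p.down_id)
        if m not in matrix.index
    ]
    if missing:
        raise KeyError(f"molecules missing from matrix: {sorted(set(missing))}")
    log_idx = np.zeros(matrix.shape[1])
    for p in model.pairs:
        up = matrix.loc[p.up_id].to_numpy(dtype=float)
        down = matrix.loc[p.down_id].to_numpy(dtype=float)
        up = np.where(up > 0, up, model.epsilon)
        down = np.where(down > 0, down, model.epsilon)
        if model.orientation == "max-min":
            up, down = np.maximum(up, down), np.minimum(up, down)
        log_idx += np.log(up) - np.log(down)
    return pd.Series(np.exp(log_idx), index=matrix.columns, name="index")


def _first_label(labels: pd.Series):
    for v in labels:
        return v
    raise ValueError("empty label vector")


def fit_cutoff(indices: Sequence[float], labels: Sequence,
               positive_label=None) -> float:
    """Youden-optimal cutoff at a geometric midpoint.

    Candidate cutoffs are the geometric midpoints between adjacent distinct
    sorted index values; the rule index >= cutoff predicts the positive
    (high-index) group.  The candidate maximizing J = sensitivity +
    specificity - 1 is returned, ties resolved toward the smaller cutoff.
    When ``positive_label`` is not given, the group with the larger median
    log-index is taken as positive (first-appearing label on a tie).
    """
    idx = np.asarray(indices, dtype=float)
    labels = pd.Series(list(labels))
    if (idx <= 0).any():
        raise ValueError("indices must be positive")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"expected 2 groups, got {uniq}")
    if (labels == uniq[0]).sum() == 0 or (labels == uniq[1]).sum() == 0:
        raise ValueError("one group is empty")
    logs = np.log(idx)
    if positive_label is None:
        med = {g: np.median(logs[(labels == g).to_numpy()]) for g in uniq}
        positive_label = max(uniq, key=lambda g: (med[g], -uniq.index(g)))
    pos = (labels == positive_label).to_numpy()
    sorted_logs = np.unique(logs)
    if sorted_logs.size == 1:
        return float(np.exp(sorted_logs[0]))
    mids = (sorted_logs[:-1] + sorted_logs[1:]) / 2.0
    best_j, best_c = -np.inf, None
    for c in mids:  # ascending, so ties keep the smaller cutoff
        pred_pos = logs >= c
        sens = pred_pos[pos].mean()
        spec = (~pred_pos)[~pos].mean()
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_c = j, c
    return float(np.exp(best_c))


def loo_evaluate(
    matrix: pd.DataFrame,
    labels: pd.Series,
    pairs: Sequence[MoleculePair],
    positive_label=None,
    orientation: str = "directional",
    epsilon: float = 1e-6,
) -> ClassificationReport:
    """Leave-one-out evaluation with the pair set fixed.

    Each fold refits the cutoff on the remaining samples' indices and
    classifies the held-out sample (index >= cutoff -> positive group).
    Sensitivity is the recall of the positive group, specificity the recall
    of the other.
    """
    labels = pd.Series(labels, index=matrix.columns) if not isinstance(
        labels, pd.Series
    ) else labels.reindex(matrix.columns)
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"expected 2 groups, got {uniq}")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("leave-one-out needs at least 2 samples per group")
    if positive_label is None:
        positive_label = uniq[0]
    model = IndexModel(list(pairs), cutoff=1.0, orientation=orientation,
                       epsilon=epsilon, positive_label=positive_label)
    indices = compute_indices(matrix, model)
    preds = {}
    negative_label = uniq[1] if positive_label == uniq[0] else uniq[0]
    for s in matrix.columns:
        rest = indices.drop(s)
        cutoff = fit_cutoff(rest, labels.drop(s), positive_label)
        preds[s] = positive_label if indices[s] >= cutoff else negative_label
    per_sample = pd.DataFrame(
        {"index": indices, "predicted": pd.Series(preds), "true": labels}
    )
    pos_mask = labels == positive_label
    sens = float((per_sample.loc[pos_mask, "predicted"] == positive_label).mean())
    spec = float((per_sample.loc[~pos_mask, "predicted"] == negative_label).mean())
    return ClassificationReport(per_sample, sens, spec, "leave-one-out")


def rank_candidate_pairs(
    statements: Sequence[ConfidenceStatement],
    allow_list: Optional[Sequence[str]] = None,
) -> list:
    """All (up, down) combinations of de-flagged opposite-direction molecules,
    ranked by the product of member confidences (ties -> lexicographic ids).

    "up" means higher in the first group (direction first>second).  An
    optional allow-list (e.g. cancer-associated molecules) restricts the
    candidate members.
    """
    allowed = None if allow_list is None else set(allow_list)
    ups = [
        s for s in statements
        if s.de_flag and s.direction == DIRECTION_GREATER
        and (allowed is None or s.molecule in allowed)
    ]
    downs = [
        s for s in statements
        if s.de_flag and s.direction == DIRECTION_LESS
        and (allowed is None or s.molecule in allowed)
    ]
    if not ups or not downs:
        raise ValueError(
            "pair selection needs at least one de-flagged molecule in each direction"
        )
    cands = [
        MoleculePair(u.molecule, d.molecule, u.confidence * d.confidence)
        for u, d in product(ups, downs)
    ]
    cands.sort(key=lambda p: (-p.score, p.up_id, p.down_id))
    return cands


def select_pairs(
    statements: Sequence[ConfidenceStatement],
    matrix: pd.DataFrame,
    labels: pd.Series,
    max_pairs: int = 4,
    min_sensitivity: float = 0.85,
    min_specificity: float = 0.85,
    orientation: str = "directional",
    epsilon: float = 1e-6,
    allow_list: Optional[Sequence[str]] = None,
    positive_label=None,
) -> tuple[IndexModel, ClassificationReport]:
    """Greedy pair selection with a leave-one-out stopping rule.

    Candidates are ranked by the product of member confidences; pairs are
    added one at a time, re-evaluating leave-one-out after each addition,
    and the search stops as soon as both recall targets are met (or the
    pair budget is reached).  If the targets are never met the best prefix
    by Youden's J is returned with the model's warning flag set.  The final
    cutoff is refit on all samples.
    """
    labels = pd.Series(labels, index=matrix.columns) if not isinstance(
        labels, pd.Series
    ) else labels.reindex(matrix.columns)
    if positive_label is None:
        positive_label = _first_label(labels)
    candidates = rank_candidate_pairs(statements, allow_list=allow_list)
    chosen: list = []
    evaluations: list = []
    used: set = set()
    met = False
    for pair in candidates:
        if len(chosen) >= max_pairs:
            break
        # each molecule joins at most one pair (k pairs = 2k distinct
        # molecules), so no single molecule dominates the product index
        if pair.up_id in used or pair.down_id in used:
            continue
        chosen.append(pair)
        used.update((pair.up_id, pair.down_id))
        report = loo_evaluate(
            matrix, labels, chosen, positive_label=positive_label,
            orientation=orientation, epsilon=epsilon,
        )
        evaluations.append((list(chosen), report))
        if (report.sensitivity >= min_sensitivity
                and report.specificity >= min_specificity):
            met = True
            break
    if met:
        final_pairs, final_report = evaluations[-1]
    else:  # best prefix by J; earlier (shorter) prefix wins ties
        final_pairs, final_report = max(
            evaluations, key=lambda e: (e[1].youden_j, -len(e[0]))
        )
    model = IndexModel(final_pairs, cutoff=1.0, orientation=orientation,
                       epsilon=epsilon, positive_label=positive_label,
                       warning=not met)
    indices = compute_indices(matrix, model)
    model.cutoff = fit_cutoff(indices, labels, positive_label)
    return model, final_report


class PairRatioIndexClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-compatible wrapper around the pair-ratio index model.

    ``fit`` takes a samples x molecules matrix (DataFrame, or array with
    generated feature names) and two-group labels.  When ``pairs`` is not
    supplied, direction statements are computed per molecule with the
    order-statistic median-confidence procedure, flagged at ``tau``, and
    pairs are selected greedily as in :func:`select_pairs`.

    Parameters
    ----------
    pairs : list of (up_id, down_id) or MoleculePair, optional
        Fixed pair set; skips selection.
    tau : float
        Confidence threshold for flagging molecules during selection.
    max_pairs, min_sensitivity, min_specificity
        Selection budget and leave-one-out stopping targets.
    orientation : {"directional", "max-min"}
    epsilon : float
        Pseudo-value replacing non-positive expression values.
    positive_label : optional
        The high-index group; defaults to the first label seen in ``y``.

    Attributes
    ----------
    model_ : IndexModel
    pairs_ : list of MoleculePair
    cutoff_ : float
    report_ : ClassificationReport from selection (leave-one-out), or
        resubstitution when pairs were fixed.
    classes_ : ndarray of the two labels.
    """

    def __init__(self, pairs=None, tau=0.90, max_pairs=4,
                 min_sensitivity=0.85, min_specificity=0.85,
                 orientation="directional", epsilon=1e-6,
                 positive_label=None):
        self.pairs = pairs
        self.tau = tau
        self.max_pairs = max_pairs
        self.min_sensitivity = min_sensitivity
        self.min_specificity = min_specificity
        self.orientation = orientation
        self.epsilon = epsilon
        self.positive_label = positive_label

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        cols = getattr(self, "feature_names_in_",
                       [f"m{i}" for i in range(X.shape[1])])
        return pd.DataFrame(X, columns=list(cols))

    def fit(self, X, y):
        frame = self._as_frame(X)
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        y = pd.Series(list(y))
        uniq = list(dict.fromkeys(y))
        if len(uniq) != 2:
            raise ValueError(f"expected exactly 2 classes, got {uniq}")
        self.classes_ = np.asarray(sorted(uniq, key=str))
        positive = self.positive_label if self.positive_label is not None else uniq[0]
        matrix = frame.T  # molecules x samples
        matrix.columns = pd.Index(range(frame.shape[0]))
        labels = pd.Series(y.to_numpy(), index=matrix.columns)
        if self.pairs is not None:
            pairs = [
                p if isinstance(p, MoleculePair) else MoleculePair(p[0], p[1])
                for p in self.pairs
            ]
            model = IndexModel(pairs, cutoff=1.0, orientation=self.orientation,
                               epsilon=self.epsilon, positive_label=positive)
            indices = compute_indices(matrix, model)
            model.cutoff = fit_cutoff(indices, labels, positive)
            neg = uniq[1] if positive == uniq[0] else uniq[0]
            pred = pd.Series(
                np.where(indices >= model.cutoff, positive, neg),
                index=matrix.columns,
            )
            pos_mask = labels == positive
            report = ClassificationReport(
                pd.DataFrame({"index": indices, "predicted": pred, "true": labels}),
                float((pred[pos_mask] == positive).mean()),
                float((pred[~pos_mask] != positive).mean()),
                "resubstitution",
            )
        else:
            g_pos = matrix.loc[:, labels == positive].to_numpy(dtype=float)
            g_neg = matrix.loc[:, labels != positive].to_numpy(dtype=float)
            statements = []
            for r, mol in enumerate(matrix.index):
                # first sample = positive group, so direction first>second
                # means "up in the positive group"
                s = best_confidence(g_pos[r], g_neg[r], molecule=mol)
                s.de_flag = s.confidence >= self.tau
                statements.append(s)
            model, report = select_pairs(
                statements, matrix, labels,
                max_pairs=self.max_pairs,
                min_sensitivity=self.min_sensitivity,
                min_specificity=self.min_specificity,
                orientation=self.orientation, epsilon=self.epsilon,
                positive_label=positive,
            )
        self.model_ = model
        self.pairs_ = model.pairs
        self.cutoff_ = model.cutoff
        self.report_ = report
        self._positive_ = positive
        self._negative_ = uniq[1] if positive == uniq[0] else uniq[0]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        frame = self._as_frame(X)
        matrix = frame.T
        matrix.columns = pd.Index(range(frame.shape[0]))
        indices = compute_indices(matrix, self.model_)
        return np.log(indices.to_numpy()) - np.log(self.cutoff_)

    def predict(self, X):
        score = self.decision_function(X)
        return np.where(score >= 0, self._positive_, self._negative_)
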