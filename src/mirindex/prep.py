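"""Platform-specific preprocessing.

qPCR: detection-limit filtering (a miR is dropped when undetected, CT above
the detection limit, in more than a fixed fraction of samples) and delta-CT
normalization against the median of the endogenous-control assays, reported
on the linear 2^-dCT scale.

Microarray: probe-level low-signal-flag filtering per group, replicate
collapsing to gene level by the mean, and quantile normalization between
samples.

All fraction comparisons are strict ("more than 60%", "more than 30%").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CtMatrix, ExpressionMatrix

DEFAULT_CONTROLS = ("RNU44", "RNU48", "MammU6")


@dataclass(frozen=True)
class DetectionRule:
    """qPCR detection filter: undetected iff CT > detection_limit; a miR is
    excluded when undetected in strictly more than max_undetected_fraction
    of samples."""

    detection_limit: float = 38.0
    max_undetected_fraction: float = 0.60

    def __post_init__(self) -> None:
        if self.detection_limit <= 0:
            raise ValueError("detection_limit must be positive")
        if not (0 <= self.max_undetected_fraction <= 1):
            raise ValueError("max_undetected_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ArrayFilterRule:
    """Probe filter: removed when flagged in strictly more than
    max_flagged_fraction of the samples of at least one group."""

    max_flagged_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not (0 <= self.max_flagged_fraction <= 1):
            raise ValueError("max_flagged_fraction must lie in [0, 1]")


def filter_detected_mirs(
    ct: CtMatrix, rule: DetectionRule = DetectionRule()
) -> tuple[CtMatrix, list]:
    """Drop miRs undetected in more than the allowed fraction of samples.

    CT exactly at the detection limit counts as detected.  Control rows are
    never excluded (they are needed for normalization) but are included in
    the excluded-id report if they fail the rule.  Row order is preserved.
    """
    if ct.values.empty:
        raise ValueError("CT matrix is empty")
    undetected_frac = (ct.values > rule.detection_limit).mean(axis=1)
    failing = set(ct.values.index[undetected_frac > rule.max_undetected_fraction])
    controls = set(ct.control_ids)
    keep = [m for m in ct.values.index if m not in failing or m in controls]
    excluded = [m for m in ct.values.index if m in failing]
    retained = CtMatrix(ct.values.loc[keep], control_ids=list(ct.control_ids))
    return retained, excluded


def delta_ct_normalize(
    ct: CtMatrix, rule: DetectionRule = DetectionRule(),
    groups: Optional[pd.Series] = None,
) -> ExpressionMatrix:
    """Delta-CT normalization to the linear 2^-dCT scale.

    Per sample the reference is the median CT of the *detected* endogenous
    controls; dCT = CT(miR) - reference and expression = 2^-dCT.  Undetected
    entries (CT above the detection limit) are floor-imputed at the limit
    before transformation, a documented least-information choice.
    """
    if not ct.control_ids:
        raise ValueError("delta-CT normalization requires endogenous-control rows")
    ctrl = ct.values.loc[list(ct.control_ids)]
    detected_ctrl = ctrl.where(ctrl <= rule.detection_limit)
    if detected_ctrl.isna().all(axis=0).any():
        bad = list(detected_ctrl.columns[detected_ctrl.isna().all(axis=0)])
        raise ValueError(f"all endogenous controls undetected in sample(s): {bad}")
    reference = detected_ctrl.median(axis=0, skipna=True)

    mirs = ct.values.loc[ct.mir_ids]
    imputed = mirs.clip(upper=rule.detection_limit)
    delta = imputed.sub(reference, axis=1)
    expr = np.power(2.0, -delta)
    if groups is None:
        groups = pd.Series("all", index=expr.columns)
    return ExpressionMatrix(expr, scale="linear", platform="qpcr", groups=groups)


def filter_array_probes(
    probes: pd.DataFrame,
    flags: pd.DataFrame,
    groups: pd.Series,
    rule: ArrayFilterRule = ArrayFilterRule(),
) -> pd.DataFrame:
    """Remove probes flagged as background/low-signal in more than the
    allowed fraction of samples within at least one group."""
    if not probes.index.equals(flags.index) or not probes.columns.equals(flags.columns):
        raise ValueError("flags matrix must be aligned with the probe matrix")
    groups = groups.reindex(probes.columns)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])
        raise ValueError(f"samples without a group label: {missing}")
    drop = pd.Series(False, index=probes.index)
    for g in groups.unique():
        cols = groups[groups == g].index
        frac = flags.loc[:, cols].mean(axis=1)
        drop |= frac > rule.max_flagged_fraction
    return probes.loc[~drop]


def collapse_probe_replicates(
    probes: pd.DataFrame, probe_to_gene: pd.Series
) -> tuple[pd.DataFrame, list]:
    """Collapse probe replicates to gene level by the arithmetic mean.

    ``probe_to_gene`` maps probe id -> gene id and must be single-valued per
    probe.  Genes whose probes were all filtered out upstream are absent
    from the output and returned in the dropped-gene list.
    """
    if probe_to_gene.index.has_duplicates:
        dup = probe_to_gene.index[probe_to_gene.index.duplicated()]
        conflicting = [
            p for p in dup.unique() if probe_to_gene.loc[[p]].nunique() > 1
        ]
        if conflicting:
            raise ValueError(f"probes mapped to conflicting genes: {conflicting}")
        probe_to_gene = probe_to_gene[~probe_to_gene.index.duplicated()]
    unmapped = [p for p in probes.index if p not in probe_to_gene.index]
    if unmapped:
        raise ValueError(f"probes without a gene mapping: {unmapped}")
    gene_of = probe_to_gene.loc[probes.index]
    collapsed = probes.groupby(gene_of.to_numpy()).mean()
    collapsed.index.name = "gene"
    all_genes = pd.unique(probe_to_gene.to_numpy())
    dropped = [g for g in all_genes if g not in collapsed.index]
    # keep first-appearance gene order
    order = [g for g in pd.unique(gene_of.to_numpy())]
    return collapsed.loc[order], dropped


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization between samples.

    Each sample's sorted value vector is replaced by the cross-sample mean
    of order statistics, so all columns share one empirical distribution
    afterwards while within-sample ranks are preserved.
    """
    if matrix.scale != "log2":
        raise ValueError("quantile normalization expects log2-scale input")
    values = matrix.values
    if values.isna().any().any():
        raise ValueError("missing values must be removed before normalization")
    if values.shape[1] < 2:
        warnings.warn("fewer than 2 samples: quantile normalization is a no-op")
        return ExpressionMatrix(values.copy(), matrix.scale, matrix.platform,
                                matrix.groups)
    arr = values.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(arr.shape[0])
    for c in range(arr.shape[1]):
        ranks[order[:, c], c] = rows
    mean_order_stats = np.sort(arr, axis=0).mean(axis=1)
    out = mean_order_stats[ranks]
    return ExpressionMatrix(
        pd.DataFrame(out, index=values.index, columns=values.columns),
        scale=matrix.scale,
        platform=matrix.platform,
        groups=matrix.groups,
    )


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer for between-sample quantile normalization.

    Follows the sklearn convention of samples as rows and features as
    columns: ``fit`` learns the reference distribution (the mean of the
    per-sample sorted feature vectors over the training matrix) and
    ``transform`` maps each sample's within-sample ranks onto it.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D array (samples x features)")
        self.n_features_in_ = X.shape[1]
        # reference = mean of per-sample sorted vectors
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        out = np.empty_like(X)
        for r in range(X.shape[0]):
            order = np.argsort(X[r], kind="stable")
            out[r, order] = self.reference_
        return out
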