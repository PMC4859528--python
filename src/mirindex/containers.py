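"""Shared in-memory containers for expression data.

Matrices are pandas DataFrames with molecules as rows and samples as
columns; group membership is a pandas Series indexed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SCALES = ("linear", "log2")
VALID_PLATFORMS = ("qpcr", "array", "protein", "stroma-array")


def _check_groups(values: pd.DataFrame, groups: pd.Series) -> pd.Series:
    groups = groups.reindex(values.columns)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])
        raise ValueError(f"samples without a group label: {missing}")
    return groups


@dataclass
class ExpressionMatrix:
    """Expression values per (molecule, sample) with platform metadata.

    Parameters
    ----------
    values
        molecules x samples DataFrame.
    scale
        "linear" (strictly positive values) or "log2".
    platform
        one of "qpcr", "array", "protein", "stroma-array".
    groups
        Series mapping sample id -> group label (exactly one per sample).
    """

    values: pd.DataFrame
    scale: str
    platform: str
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}, got {self.scale!r}")
        if self.platform not in VALID_PLATFORMS:
            raise ValueError(
                f"platform must be one of {VALID_PLATFORMS}, got {self.platform!r}"
            )
        if self.values.index.has_duplicates:
            dups = list(self.values.index[self.values.index.duplicated()])
            raise ValueError(f"duplicate molecule ids: {dups}")
        self.groups = _check_groups(self.values, self.groups)
        if self.scale == "linear" and not (self.values.to_numpy() > 0).all():
            raise ValueError("linear-scale expression values must be strictly positive")

    @property
    def group_names(self) -> list:
        seen: list = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def group_columns(self, group) -> pd.DataFrame:
        return self.values.loc[:, self.groups[self.groups == group].index]


@dataclass
class CtMatrix:
    """Raw qPCR cycle-threshold values with designated endogenous controls.

    Lower CT means higher abundance.  ``control_ids`` are the endogenous
    reference assays (defaults elsewhere: RNU44, RNU48, MammU6) and must be
    a subset of the row index.
    """

    values: pd.DataFrame
    control_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if arr.size == 0:
            raise ValueError("CT matrix is empty")
        if not np.isfinite(arr).all() or (arr <= 0).any():
            raise ValueError("CT values must be finite and positive")
        missing = [c for c in self.control_ids if c not in self.values.index]
        if missing:
            raise ValueError(f"control ids not present in matrix: {missing}")

    @property
    def mir_ids(self) -> list:
        return [m for m in self.values.index if m not in set(self.control_ids)]
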