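"""Expression dichotomization and clinicopathological association testing.

Per-molecule expression is dichotomized at the ROC/Youden-optimal cutoff
(AUC via the rank statistic), the over/under labels are crossed with a
dichotomous clinical variable in a 2x2 table, and association is tested
with an uncorrected Pearson chi-square (Fisher's exact test available as an
alternative).  Surrogate luminal A/B subtype assignment follows the
immunohistochemistry thresholds for ER, PR, Ki67 and HER2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DichotomizationRule:
    """ROC-derived cutoff for one molecule: value >= cutoff -> "over"."""

    molecule: str
    cutoff: float
    auc: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


@dataclass
class TestResult:
    method: str  # "pearson-chi2" or "fisher-exact"
    p: float
    statistic: Optional[float] = None
    dof: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError("p-value must lie in (0, 1]")
        if self.statistic is not None and self.statistic < 0:
            raise ValueError("chi-square statistic must be nonnegative")


def _as_2x2(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("table cells must be nonnegative integers")
    return arr


def roc_dichotomize(
    values: Sequence[float], labels: Sequence
) -> tuple[DichotomizationRule, pd.Series]:
    """AUC and Youden-optimal over/under dichotomization.

    The AUC is the rank (Mann-Whitney) statistic with ties counted half,
    oriented so that "over" aligns with the group of higher median
    expression.  The cutoff is the midpoint between adjacent sorted values
    maximizing J for the rule value >= cutoff -> "over"; constant input
    yields AUC 0.5 and a rule flagged degenerate.
    """
    values = pd.Series(values, dtype=float)
    labels = pd.Series(list(labels), index=values.index)
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"expected 2 groups, got {uniq}")
    g1 = values[labels == uniq[0]].to_numpy()
    g2 = values[labels == uniq[1]].to_numpy()
    # orient toward the higher-median group being "over"
    hi, lo = (g1, g2) if np.median(g1) >= np.median(g2) else (g2, g1)
    ranks = stats.rankdata(np.concatenate([hi, lo]))
    r_hi = ranks[: len(hi)].sum()
    auc = (r_hi - len(hi) * (len(hi) + 1) / 2) / (len(hi) * len(lo))

    distinct = np.unique(values.to_numpy())
    if distinct.size == 1:
        rule = DichotomizationRule(values.name or "", float(distinct[0]), 0.5,
                                   degenerate=True)
    else:
        mids = (distinct[:-1] + distinct[1:]) / 2.0
        best_j, best_c = -np.inf, None
        for c in mids:
            sens = (hi >= c).mean()
            spec = (lo < c).mean()
            j = sens + spec - 1.0
            if j > best_j:
                best_j, best_c = j, c
        rule = DichotomizationRule(values.name or "", float(best_c), float(auc))
    status = pd.Series(
        np.where(values >= rule.cutoff, "over", "under"), index=values.index
    )
    return rule, status


def pearson_chi2(table) -> TestResult:
    """Uncorrected Pearson chi-square on a 2x2 table (df = 1).

    No continuity correction is applied.  Zero margins are rejected with a
    pointer to the exact test.
    """
    arr = _as_2x2(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin: use fisher_exact instead")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return TestResult("pearson-chi2", float(p), float(stat), int(dof))


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test (sum of hypergeometric probabilities not
    exceeding that of the observed table, margins fixed)."""
    arr = _as_2x2(table)
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return TestResult("fisher-exact", float(min(p, 1.0)))


def associate(
    status: pd.Series, clinical: pd.Series, method: str = "pearson-chi2"
) -> tuple[pd.DataFrame, TestResult, int]:
    """Cross under/over expression with a dichotomous clinical variable.

    Samples missing the clinical value are dropped (their count is
    returned).  Returns (2x2 table as DataFrame, test result, n_dropped).
    """
    clinical = clinical.reindex(status.index)
    keep = clinical.notna()
    n_dropped = int((~keep).sum())
    status, clinical = status[keep], clinical[keep]
    cats = list(dict.fromkeys(clinical))
    if len(cats) != 2:
        raise ValueError(f"clinical variable must be dichotomous, got {cats}")
    table = pd.crosstab(status, clinical).reindex(
        index=["under", "over"], columns=cats, fill_value=0
    )
    test = pearson_chi2(table) if method == "pearson-chi2" else fisher_exact(table)
    return table, test, n_dropped


def format_p(p: float) -> str:
    """Display rounding: "< 0.001" below 0.0005, else 3 then 2 decimals."""
    if p < 0.0005:
        return "< 0.001"
    r3 = round(p, 3)
    if r3 < 0.1:
        return f"{r3:.3f}"
    return f"{round(p, 2):.2f}"


# ---------------------------------------------------------------------------
# surrogate luminal subtype assignment
# ---------------------------------------------------------------------------

@dataclass
class ClinicalRecord:
    """Immunohistochemistry values needed for surrogate subtyping.

    ER and PR are percent positive nuclei in [0, 100]; Ki67 is percent;
    HER2 score is one of "0", "1+", "2+", "3+" with a FISH result required
    to resolve "2+".
    """

    er_percent: float
    pr_percent: float
    her2_score: str
    ki67_percent: float
    fish_positive: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("er_percent", "pr_percent", "ki67_percent"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if self.her2_score not in ("0", "1+", "2+", "3+"):
            raise ValueError(f"invalid HER2 score {self.her2_score!r}")


class UnresolvedHER2Error(ValueError):
    """HER2 2+ without a FISH result cannot be resolved."""


def assign_luminal_subtype(record: ClinicalRecord) -> str:
    """Surrogate luminal subtype from IHC thresholds.

    ER-positive iff >= 10% stained nuclei; PR-positive iff >= 20%; Ki67
    high iff >= 14%; HER2-positive iff 3+ or (2+ with positive FISH).
    Luminal A: ER+ PR+ HER2- and Ki67 < 14.  Luminal B: ER+ HER2- with
    Ki67 >= 14 and/or PR < 20, or ER+ HER2+ with any Ki67/PR.  ER-negative
    records are "not-luminal".
    """
    if record.her2_score == "2+" and record.fish_positive is None:
        raise UnresolvedHER2Error("HER2 2+ requires a FISH result")
    er_pos = record.er_percent >= 10
    pr_pos = record.pr_percent >= 20
    ki67_high = record.ki67_percent >= 14
    her2_pos = record.her2_score == "3+" or (
        record.her2_score == "2+" and bool(record.fish_positive)
    )
    if not er_pos:
        return "not-luminal"
    if her2_pos:
        return "luminal B"
    if pr_pos and not ki67_high:
        return "luminal A"
    return "luminal B"
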