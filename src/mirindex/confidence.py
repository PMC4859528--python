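"""Distribution-free confidence that one group's median exceeds the other's.

The statistic: for two independent samples A (size n1) and B (size n2),
pick order statistics a_(i) and b_(j) with a_(i) < b_(j).  For continuous
i.i.d. data the events {median_A < a_(i)} and {median_B > b_(j)} have
distribution-free probabilities given by Binomial(n, 1/2) tails:

    P(median_A < a_(i)) = P(B_n1 <= i - 1)
    P(median_B > b_(j)) = P(B_n2 >= j)

Their product is the confidence in the claim median_A < median_B.  The
procedure searches all admissible (i, j) pairs and reports the direction
(either claim) achieving the larger confidence.  No multiple-testing
correction is applied across molecules; the confidence thresholds are the
only gate for calling differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np

from .containers import ExpressionMatrix

DIRECTION_LESS = "first<second"
DIRECTION_GREATER = "first>second"
DIRECTION_NONE = "indeterminate"


@dataclass(frozen=True)
class DEThresholds:
    """Per-platform confidence thresholds for flagging differential expression."""

    tau_mir: float = 0.90
    tau_gene: float = 0.80
    tau_protein: float = 0.80

    def __post_init__(self) -> None:
        for name in ("tau_mir", "tau_gene", "tau_protein"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    def for_platform(self, platform: str) -> float:
        if platform == "qpcr":
            return self.tau_mir
        if platform == "protein":
            return self.tau_protein
        return self.tau_gene


@dataclass
class ConfidenceStatement:
    """Direction claim for one molecule with its confidence and order pair.

    ``direction`` compares the first group to the second; ``order_pair``
    holds the 1-based order indices (i in the claimed-smaller sample,
    j in the claimed-larger one).  ``direction == "indeterminate"`` iff
    ``confidence == 0`` iff ``order_pair is None``.
    """

    molecule: str
    direction: str
    confidence: float
    order_pair: Optional[tuple]
    n1: int
    n2: int
    de_flag: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")
        indet = self.direction == DIRECTION_NONE
        if indet != (self.confidence == 0.0) or indet != (self.order_pair is None):
            raise ValueError(
                "indeterminate direction, zero confidence and absent order pair "
                "must coincide"
            )

    def rendered(self, names: Sequence[str] = ("YA", "MA")) -> str:
        """Render the direction as e.g. ``"YA > MA"``."""
        first, second = names
        if self.direction == DIRECTION_LESS:
            return f"{first} < {second}"
        if self.direction == DIRECTION_GREATER:
            return f"{first} > {second}"
        return "indeterminate"


def binomial_median_tail(n: int, k: int, side: str) -> float:
    """Exact Binomial(n, 1/2) tail probability.

    side="le" returns P(B <= k) = sum_{t=0..k} C(n,t) / 2^n;
    side="ge" returns P(B >= k).  Computed with exact integer binomial
    coefficients, so no floating-point summation error beyond the final
    division.
    """
    if not (0 <= k <= n):
        raise ValueError(f"k must satisfy 0 <= k <= n, got k={k}, n={n}")
    if side == "le":
        total = sum(comb(n, t) for t in range(0, k + 1))
    elif side == "ge":
        total = sum(comb(n, t) for t in range(k, n + 1))
    else:
        raise ValueError(f"side must be 'le' or 'ge', got {side!r}")
    return total / float(2**n)


def _le_tails(n: int) -> np.ndarray:
    """le_tails[i] = P(B_n <= i - 1) for i = 1..n (index 0 unused)."""
    c = np.array([comb(n, t) for t in range(n + 1)], dtype=float)
    cum = np.cumsum(c) / 2.0**n
    out = np.empty(n + 1)
    out[0] = np.nan
    out[1:] = cum[:-1]  # P(B <= i-1)
    return out


def _ge_tails(n: int) -> np.ndarray:
    """ge_tails[j] = P(B_n >= j) for j = 1..n (index 0 unused)."""
    c = np.array([comb(n, t) for t in range(n + 1)], dtype=float)
    rev = np.cumsum(c[::-1])[::-1] / 2.0**n
    out = np.empty(n + 1)
    out[0] = np.nan
    out[1:] = rev[1:]  # P(B >= j)
    return out


def _best_one_direction(a: np.ndarray, b: np.ndarray):
    """Best confidence for the claim median(a) < median(b).

    Admissibility is strict: a_(i) < b_(j).  P(B <= i-1) increases with i
    while P(B >= j) decreases with j, so for each j only the largest
    admissible i matters.

    Returns (confidence, (i, j)) with 1-based order indices, or (0.0, None).
    """
    n1, n2 = len(a), len(b)
    sa = np.sort(a)
    sb = np.sort(b)
    le = _le_tails(n1)
    ge = _ge_tails(n2)
    # for each j: number of a-values strictly below sb[j-1] = largest valid i
    i_max = np.searchsorted(sa, sb, side="left")  # counts a < b_(j)
    best = 0.0
    best_pair = None
    for j in range(1, n2 + 1):
        i = i_max[j - 1]
        if i == 0:
            continue
        conf = le[i] * ge[j]
        if conf > best:
            best = conf
            best_pair = (int(i), j)
    return best, best_pair


def best_confidence(
    sample_a: Sequence[float], sample_b: Sequence[float], molecule: str = ""
) -> ConfidenceStatement:
    """Maximum-confidence direction statement comparing two samples' medians.

    Searches both claims (median_A < median_B and the mirror image) over
    all admissible order-statistic pairs and returns the direction with the
    larger confidence.  If no admissible pair exists in either direction,
    or the two maxima tie exactly, the statement is indeterminate.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    conf_lt, pair_lt = _best_one_direction(a, b)
    conf_gt, pair_gt = _best_one_direction(b, a)
    if conf_lt == conf_gt:
        return ConfidenceStatement(
            molecule, DIRECTION_NONE, 0.0, None, int(a.size), int(b.size)
        )
    if conf_lt > conf_gt:
        return ConfidenceStatement(
            molecule, DIRECTION_LESS, conf_lt, pair_lt, int(a.size), int(b.size)
        )
    # mirrored claim: i indexes the claimed-smaller sample (B), j the larger (A)
    return ConfidenceStatement(
        molecule, DIRECTION_GREATER, conf_gt, pair_gt, int(a.size), int(b.size)
    )


def call_differential(
    matrix: ExpressionMatrix,
    thresholds: DEThresholds = DEThresholds(),
    tau: Optional[float] = None,
) -> list:
    """One confidence statement per molecule, flagged at the platform threshold.

    The matrix must carry exactly two groups; the first group (order of
    appearance in ``matrix.groups``) is the "first" side of each direction.
    ``tau`` overrides the platform-derived threshold when given.
    """
    names = matrix.group_names
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(names)}: {names}")
    if tau is None:
        tau = thresholds.for_platform(matrix.platform)
    g1 = matrix.group_columns(names[0]).to_numpy(dtype=float)
    g2 = matrix.group_columns(names[1]).to_numpy(dtype=float)
    out = []
    for row, molecule in enumerate(matrix.values.index):
        stmt = best_confidence(g1[row], g2[row], molecule=molecule)
        stmt.de_flag = bool(stmt.confidence >= tau)
        out.append(stmt)
    return out


def statements_to_frame(statements: Sequence[ConfidenceStatement],
                        names: Sequence[str] = ("YA", "MA")):
    """Tabulate statements (molecule, statement, confidence, i, j, de_flag)."""
    import pandas as pd

    rows = []
    for s in statements:
        i, j = s.order_pair if s.order_pair is not None else ("", "")
        rows.append(
            {
                "molecule": s.molecule,
                "statement": s.rendered(names),
                "confidence": round(s.confidence, 6),
                "i": i,
                "j": j,
                "de_flag": s.de_flag,
            }
        )
    return pd.DataFrame(rows)
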