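"""Statistical tests used throughout the CCRN analyses.

All comparisons in the pipeline are one-tailed, with the direction fixed in
advance by the scientific claim being tested (e.g. essential proteins enriched
among cooperative hubs, competitive pairs less co-expressed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from Bio import Align

EXACT_WILCOXON_MAX_N = 12  # exact rank enumeration up to this pooled size

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class Direction(str, Enum):
    X_GREATER = "x_greater"
    Y_GREATER = "y_greater"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows = outcome, columns = group."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    direction: str
    n_x: int
    n_y: int


def fisher_exact_one_tailed(
    table: ContingencyTable2x2, alternative: str = "greater"
) -> float:
    """One-tailed Fisher's exact test on a 2x2 table.

    ``alternative='greater'`` asks whether the odds ratio (a d)/(b c) exceeds
    one, i.e. the first-row outcome is enriched in the first-column group.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    _, p = sps.fisher_exact(table.as_array(), alternative=alternative)
    return float(p)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def wilcoxon_rank_sum_one_tailed(
    sample_x: Sequence[float],
    sample_y: Sequence[float],
    alternative: Direction = Direction.X_GREATER,
) -> TestResult:
    """One-tailed Wilcoxon rank-sum (Mann-Whitney) test.

    For pooled sample sizes up to 12 the p-value is exact: every assignment of
    the pooled midranks to the two groups is enumerated.  Larger samples use
    the normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    alternative = Direction(alternative)
    nx_, ny_ = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w_x = float(ranks[:nx_].sum())  # rank sum of sample x

    if nx_ + ny_ <= EXACT_WILCOXON_MAX_N:
        # exact permutation of group labels over the pooled midranks
        total = 0
        extreme = 0
        for idx in combinations(range(nx_ + ny_), nx_):
            total += 1
            w = float(ranks[list(idx)].sum())
            if alternative is Direction.X_GREATER:
                if w >= w_x - 1e-12:
                    extreme += 1
            else:
                if w <= w_x + 1e-12:
                    extreme += 1
        p = extreme / total
        statistic = w_x
    else:
        scipy_alt = "greater" if alternative is Direction.X_GREATER else "less"
        u, p = sps.mannwhitneyu(
            x, y, alternative=scipy_alt, method="asymptotic", use_continuity=True
        )
        statistic = float(u)
        p = float(p)
    return TestResult(
        test_name="wilcoxon_rank_sum_one_tailed",
        statistic=statistic,
        p_value=p,
        direction=alternative.value,
        n_x=nx_,
        n_y=ny_,
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance: correlation undefined")
    return float(sps.pearsonr(x, y)[0])


def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def pairwise_sequence_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over the global alignment of two protein sequences.

    Identity = identical aligned positions / alignment length (gaps included)
    x 100, under match +1 / mismatch -1 / gap open -5 / extend -1 scoring.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    for seq in (seq_a, seq_b):
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-amino-acid symbols: {sorted(bad)}")
    alignment = _identity_aligner().align(seq_a, seq_b)[0]
    matches = 0
    aligned_cols = 0
    prev_a_end = prev_b_end = 0
    length = 0
    first = True
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        if not first:
            length += max(a_start - prev_a_end, b_start - prev_b_end)
        else:
            length += max(a_start, b_start)  # leading gap
            first = False
        for k in range(a_end - a_start):
            if seq_a[a_start + k] == seq_b[b_start + k]:
                matches += 1
        length += a_end - a_start
        prev_a_end, prev_b_end = a_end, b_end
    length += max(len(seq_a) - prev_a_end, len(seq_b) - prev_b_end)  # trailing gap
    if length == 0:
        raise ValueError("degenerate alignment")
    return 100.0 * matches / length


def serialize_results(results: Sequence[TestResult]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "test_name": r.test_name,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "direction": r.direction,
                "n_x": r.n_x,
                "n_y": r.n_y,
            }
            for r in results
        ]
    )
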