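"""Linear-scale group comparisons of rhythm strength and period.

The 24 h-signal strength (proportion of sum of squares at the 24 h Fourier
period) is compared across 3-d subsets with paired two-tailed Wilcoxon
signed-rank tests, grouped into four contrast families (variable x site)
with a Bonferroni correction applied within each family.  Period
("daylength") estimates are compared across groups with Kruskal-Wallis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

FAMILY_LABELS = ("co2_csu", "co2_ambient", "temp_csu", "temp_ambient")


@dataclass
class ContrastFamily:
    """A named family of subset-pair contrasts sharing one Bonferroni divisor."""

    label: str
    pairs: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def all_pairs(cls, label: str, subset_indices: Sequence[int]) -> "ContrastFamily":
        return cls(label=label, pairs=list(combinations(sorted(subset_indices), 2)))

    @property
    def m(self) -> int:
        return len(self.pairs)


def pairwise_wilcoxon(
    strengths: pd.DataFrame, family: ContrastFamily, alpha: float = 0.05
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank tests over a family of subset pairs.

    ``strengths`` is wide-format: one row per hive, one column per subset
    index, entries the per-hive 24 h proportion of sum of squares.  Hives
    missing either member of a pair are dropped pairwise.  Zero differences
    are dropped before ranking (the classic Wilcoxon convention); the exact
    null distribution is used for n <= 25 without ties, the normal
    approximation with continuity correction otherwise.  ``p_bonferroni``
    multiplies the raw p by the family size m, capped at 1.

    Pairs with fewer than 3 nonzero differences are reported as skipped with
    a reason rather than raising.
    """
    rows = []
    for i, j in family.pairs:
        rec: dict = {"family": family.label, "subset_i": i, "subset_j": j}
        if i not in strengths.columns or j not in strengths.columns:
            rec.update(W=np.nan, p_raw=np.nan, p_bonferroni=np.nan,
                       significant=False, n=0, skipped="subset missing")
            rows.append(rec)
            continue
        paired = strengths[[i, j]].dropna()
        d = paired[i].to_numpy() - paired[j].to_numpy()
        d = d[d != 0.0]
        if len(d) < 3:
            rec.update(W=np.nan, p_raw=np.nan, p_bonferroni=np.nan,
                       significant=False, n=len(d),
                       skipped="fewer than 3 nonzero paired differences")
            rows.append(rec)
            continue
        w, p = signed_rank_test(d)
        p_adj = min(1.0, family.m * p)
        rec.update(W=w, p_raw=p, p_bonferroni=p_adj,
                   significant=p_adj < alpha, n=len(d), skipped="")
        rows.append(rec)
    return pd.DataFrame(rows)


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p of the signed-rank statistic under sign symmetry.

    Enumerates the null distribution of W+ = sum of ranks with positive
    sign over all 2^n sign assignments by polynomial convolution.  Average
    ranks from ties are half-integers, so everything is doubled to stay on
    an integer lattice; this keeps the enumeration valid in the presence of
    tied absolute differences (where the classic no-tie tables do not apply).
    """
    scaled = np.round(2.0 * ranks).astype(int)
    total = int(scaled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for s in scaled:
        shifted = np.zeros_like(dist)
        shifted[s:] = dist[: total + 1 - s]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2.0 * w_plus))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def signed_rank_test(d: np.ndarray) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test on nonzero paired differences.

    Zero differences must already be dropped.  Ties get average ranks.  For
    n <= 25 the exact sign-flip null is enumerated (valid with ties); above
    that the normal approximation with continuity and tie correction is
    used.  Returns ``(W, p)`` with W the smaller of the two rank sums, as
    customarily reported.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d == 0.0):
        raise ValidationError("drop zero differences before calling")
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    if n <= 25:
        p = _exact_signed_rank_p(w_plus, ranks)
    else:
        p = float(
            stats.wilcoxon(d, alternative="two-sided", method="approx", correction=True).pvalue
        )
    return w, p


def kruskal_wallis(groups: dict[str, Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal-Wallis H over named groups of period estimates.

    Returns (H, df, p) with the tie-corrected H and a chi-square p on
    ``len(groups) − 1`` degrees of freedom.  All-identical values give
    H = 0, p = 1.
    """
    keys = list(groups)
    if len(keys) < 2:
        raise ValidationError("Kruskal-Wallis needs >= 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in keys]
    for k, arr in zip(keys, arrays):
        if len(arr) < 2:
            raise ValidationError(f"group {k!r} has n < 2")
    df = len(keys) - 1
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0.0:
        return 0.0, df, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), df, float(p)
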