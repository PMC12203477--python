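"""Cross-session comparison of array conditions.

Decoding metrics from the three training conditions (both arrays, medial
only, lateral only) are compared across sessions with a Friedman test
(alpha 0.05); when it is significant, post-hoc pairwise Wilcoxon signed-rank
tests are run for the three condition pairs at the Bonferroni-corrected
threshold 0.05/3 (~0.0167).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CONDITIONS = ("both", "medial", "lateral")
FRIEDMAN_ALPHA = 0.05
N_PAIRWISE = 3
#: Bonferroni-corrected pairwise threshold (0.05 / 3)
PAIRWISE_ALPHA = FRIEDMAN_ALPHA / N_PAIRWISE

#: switch from the exact signed-rank distribution to the normal
#: approximation (with continuity correction) above this sample size
WILCOXON_EXACT_MAX_N = 25


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False


@dataclass
class ConditionComparison:
    task: str
    metric: str
    friedman_stat: float
    friedman_p: float
    pairwise: list[PairwiseResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "task": self.task,
                "metric": self.metric,
                "comparison": "friedman",
                "statistic": self.friedman_stat,
                "p_value": self.friedman_p,
                "significant": self.friedman_p < FRIEDMAN_ALPHA,
            }
        ]
        for pr in self.pairwise:
            rows.append(
                {
                    "task": self.task,
                    "metric": self.metric,
                    "comparison": f"{pr.pair[0]}-{pr.pair[1]}",
                    "statistic": pr.statistic,
                    "p_value": pr.p_value,
                    "significant": pr.significant,
                }
            )
        return pd.DataFrame(rows)


def friedman(table: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Friedman rank test over a sessions x conditions table.

    Uses the chi-square reference distribution.  A table in which every
    session ranks the conditions identically flat (all values equal within
    each row) is degenerate: statistic 0, p 1.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise ValueError("need a 2-D table with >=3 conditions")
    if arr.shape[0] < 3:
        raise ValueError("need >=3 sessions")
    if not np.all(np.isfinite(arr)):
        raise ValueError("table has missing cells")
    if np.all(arr == arr[:, :1]):
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*arr.T)
    return float(stat), float(p)


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> PairwiseResult:
    """Two-sided paired Wilcoxon signed-rank test of x vs y.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 remaining pairs, the normal approximation with continuity
    correction above.  All-zero differences are degenerate (p = 1).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n_nonzero = int(np.sum(d != 0))
    if n_nonzero == 0:
        return PairwiseResult(("x", "y"), 0.0, 1.0, False, degenerate=True)
    method = "exact" if n_nonzero <= WILCOXON_EXACT_MAX_N else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return PairwiseResult(
        ("x", "y"), float(res.statistic), float(res.pvalue),
        res.pvalue < PAIRWISE_ALPHA,
    )


def compare_conditions(
    perf: pd.DataFrame, task: str, metric: str
) -> ConditionComparison:
    """Friedman + gated post-hoc Wilcoxon over the three array conditions.

    ``perf`` is tidy: columns session_seed, task, condition, and the metric.
    Pairwise tests are only run (and reported) when the Friedman test is
    significant at alpha 0.05.
    """
    sub = perf[perf["task"] == task]
    table = sub.pivot(index="session_seed", columns="condition", values=metric)
    table = table[list(CONDITIONS)]
    if table.isna().any().any():
        raise ValueError("incomplete session x condition table")
    stat, p = friedman(table.to_numpy())
    comp = ConditionComparison(task=task, metric=metric, friedman_stat=stat,
                               friedman_p=p)
    if p < FRIEDMAN_ALPHA:
        for a, b in (("both", "medial"), ("both", "lateral"), ("medial", "lateral")):
            pr = wilcoxon_signed_rank(table[a].to_numpy(), table[b].to_numpy())
            pr.pair = (a, b)
            comp.pairwise.append(pr)
    return comp
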