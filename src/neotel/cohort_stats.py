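"""Cohort association statistics.

Two-sided Fisher exact tests on 2x2 tables (the R convention: the p-value
sums the probabilities of all tables, under the hypergeometric null with
fixed margins, that are no more likely than the observed one, with a
relative tolerance of 1e-7 on the probability comparison), two-sided
Wilcoxon rank-sum tests (exact distribution for small tie-free samples,
normal approximation with tie and continuity correction otherwise), and
Spearman rank correlation.

``COHORT_PRESETS`` reconstructs every 2x2 contingency table of the
published screening (n = 720) and relapse/INFORM (n = 40) neuroblastoma
cohorts from the printed group counts (C-Circle positive vs negative
against stage, risk group, sex, MYCN status and histology), so the cohort
associations can be recomputed from the table data alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

_REL_TOL = 1e-7


@dataclass(slots=True, frozen=True)
class TwoByTwo:
    """2x2 contingency table; rows are groups, columns outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_two_sided(t: TwoByTwo) -> tuple[float, float]:
    """Two-sided Fisher exact test; returns (sample odds ratio, p-value).

    p sums hypergeometric probabilities of all tables sharing the margins
    whose probability is <= that of the observed table (relative tolerance
    1e-7). A zero margin forces p = 1. The odds ratio is the sample OR
    (a*d)/(b*c), inf when b*c = 0.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return odds, 1.0
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    mask = pmf <= p_obs * (1.0 + _REL_TOL)
    if mask.all():
        return odds, 1.0
    p = float(pmf[mask].sum())
    return odds, min(p, 1.0)


def wilcoxon_rank_sum_two_sided(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 50
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact-distribution p for tie-free samples of combined size <= 50;
    otherwise the normal approximation with tie correction and continuity
    correction. Two identical multisets give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0
    has_ties = np.unique(combined).size < combined.size
    if not has_ties and combined.size <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def spearman(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Spearman rho: Pearson correlation of mid-ranks; None on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    return float(stats.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# Published cohort presets
# ---------------------------------------------------------------------------
# Each entry: contrast name -> ((CC+ in group, CC+ not in group),
#                               (CC- in group, CC- not in group)).
# Stage contrasts follow the published table layout: stage 1-3 vs stage 4 as
# one 2x2 over staged tumors, and 4S vs all other staged tumors as a second.

COHORT_PRESETS: dict[str, dict[str, TwoByTwo]] = {
    "screening": {
        # 66 C-Circle positive / 654 negative of 720 screened tumors
        "stage_1_3_vs_4": TwoByTwo(25, 41, 391, 180),
        "stage_4s_vs_other": TwoByTwo(0, 66, 83, 571),
        "risk_lr_ir_vs_hr": TwoByTwo(24, 41, 425, 191),
        "sex_male_vs_female": TwoByTwo(39, 27, 358, 296),
        "mycn_amp_vs_normal": TwoByTwo(0, 66, 114, 522),
        "ganglioneuroma_vs_other": TwoByTwo(0, 66, 11, 643),
    },
    "inform": {
        # 19 C-Circle positive / 21 negative of 40 relapse tumors
        "stage_1_3_vs_4": TwoByTwo(4, 14, 0, 20),
        "stage_4s_vs_other": TwoByTwo(1, 18, 1, 20),
        "risk_lr_ir_vs_hr": TwoByTwo(5, 14, 2, 19),
        "sex_male_vs_female": TwoByTwo(13, 6, 19, 2),
        "mycn_amp_vs_normal": TwoByTwo(2, 17, 9, 10),
    },
}

#: Cohort sizes and C-Circle positive counts for the frequency summaries.
COHORT_SIZES = {"screening": (66, 720), "inform": (19, 40)}


def cohort_fisher_tests(cohort: str) -> dict[str, dict[str, float]]:
    """Fisher tests for every preset 2x2 of a cohort.

    Returns ``{contrast: {"odds_ratio": .., "p_value": ..}}``.
    """
    out: dict[str, dict[str, float]] = {}
    for name, table in COHORT_PRESETS[cohort].items():
        odds, p = fisher_exact_two_sided(table)
        out[name] = {"odds_ratio": odds, "p_value": p}
    return out


def positive_fraction(cohort: str) -> float:
    """Fraction of C-Circle positive tumors in a preset cohort."""
    pos, total = COHORT_SIZES[cohort]
    return pos / total
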