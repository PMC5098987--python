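"""Population- and family-level tests on the breeding-design outcomes.

Covers lineage classification (purebred vs hybrid crosses), two-sided Fisher
exact tests on culture survival, Kruskal-Wallis rank tests on settlement and
mortality, the one-way larval-weight model with Tukey HSD comparisons, and
culture-survival summaries.  Alpha is 0.05 throughout; percentages are
reported to one decimal with half-up rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "GroupTestResult",
    "classify_lineage",
    "fisher_exact_two_sided",
    "kruskal_wallis",
    "weight_model_tukey",
    "survival_summary",
    "round_percent",
]


@dataclass
class GroupTestResult:
    statistic: float
    df: int | tuple[int, int]
    p_value: float
    pairwise: dict[tuple[str, str], float] | None = field(default=None)


def round_percent(x: float, decimals: int = 1) -> float:
    """Half-up rounding (so 91.65 -> 91.7, matching hand-reported tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def classify_lineage(dam_pop: str, sire_pop: str) -> str:
    """Purebred when both parents come from the same population, else hybrid."""
    for p in (dam_pop, sire_pop):
        if p not in ("O", "W"):
            raise ValueError(f"unknown population code {p!r}")
    return "purebred" if dam_pop == sire_pop else "hybrid"


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (rows: groups, cols: alive/dead).

    Uses the probability-mass rule: the p value sums hypergeometric
    probabilities of all tables with the observed margins whose probability
    does not exceed that of the observed table.  An empty margin leaves the
    test undefined; p = 1 is returned with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("empty margin: Fisher test undefined, returning p = 1",
                      stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def kruskal_wallis(groups: list) -> GroupTestResult:
    """Kruskal-Wallis H with tie correction; p from chi-square on k-1 df."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    df = len(groups) - 1
    if np.all(flat == flat[0]):
        return GroupTestResult(statistic=0.0, df=df, p_value=1.0)
    h, p = stats.kruskal(*groups)
    return GroupTestResult(statistic=float(h), df=df, p_value=float(p))


def weight_model_tukey(weights, group) -> GroupTestResult:
    """One-way least-squares model of larval weights with Tukey HSD.

    Returns the overall F test (df pair) and all-pairs comparisons adjusted
    family-wise with the single-step studentized-range procedure.  Groups
    with a single observation contribute to the overall fit but are excluded
    from the pairwise comparisons (with a warning).
    """
    w = np.asarray(weights, dtype=float)
    g = np.asarray(group, dtype=object)
    if len(w) != len(g):
        raise ValueError("weights and group must be the same length")
    levels, counts = np.unique(g, return_counts=True)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [w[g == lv] for lv in levels]
    f_stat, p_val = stats.f_oneway(*arrays)
    df = (len(levels) - 1, len(w) - len(levels))

    singletons = set(levels[counts < 2])
    if singletons:
        warnings.warn(
            f"groups with one observation excluded from pairwise: {sorted(singletons)}",
            stacklevel=2,
        )
    keep = ~np.isin(g, list(singletons))
    pairwise: dict[tuple[str, str], float] | None = None
    if len(np.unique(g[keep])) >= 2:
        from itertools import combinations

        res = pairwise_tukeyhsd(w[keep], g[keep])
        pairwise = {
            (str(g1), str(g2)): float(padj)
            for (g1, g2), padj in zip(
                combinations(res.groupsunique, 2), res.pvalues
            )
        }
    return GroupTestResult(
        statistic=float(f_stat), df=df, p_value=float(p_val), pairwise=pairwise
    )


def survival_summary(design, life: pd.DataFrame) -> pd.DataFrame:
    """Per-lineage and per-dam culture-survival proportions.

    A family survives the culture stage only when *all* of its replicates
    survive.  Percentages are reported to one decimal, half-up.
    """
    lineage = design.lineage
    fam = life.groupby("family_id", sort=False).agg(
        dam_id=("dam_id", "first"),
        all_alive=("culture_alive", lambda s: int(s.astype(int).min() == 1)),
    )
    fam["lineage"] = [lineage[f] for f in fam.index]
    rows = []
    for key_col, label in (("lineage", "lineage"), ("dam_id", "dam")):
        for key, sub in fam.groupby(key_col, sort=True):
            n, k = len(sub), int(sub["all_alive"].sum())
            rows.append(
                {
                    "level": label,
                    "group": key,
                    "n_families": n,
                    "n_surviving": k,
                    "percent_surviving": round_percent(100.0 * k / n),
                }
            )
    return pd.DataFrame(rows)
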