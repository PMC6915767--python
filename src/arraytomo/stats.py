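"""Per-animal aggregation and nonparametric group statistics.

The experimental unit is the animal (or human case), never the
individual synapse: per-object tables are first collapsed to one summary
value per animal, and group tests are run on those summaries. Synapse
fractions are small and skewed, so comparisons use the Mann-Whitney U
test (exact for small samples); Mendelian genotype ratios use a
chi-square goodness-of-fit test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["aggregate_per_animal", "mann_whitney_u", "chi_square_gof",
           "chi_square_upper_tail", "MannWhitneyResult", "benjamini_hochberg",
           "EXACT_MAX_N"]

#: largest combined sample size for which the exact U distribution is used
EXACT_MAX_N = 12


def aggregate_per_animal(
    table: pd.DataFrame,
    metric: str,
    statistic: str = "median",
    group_cols: "list[str] | None" = None,
) -> pd.DataFrame:
    """Collapse a per-object table to one value per animal.

    ``table`` must carry an ``animal_id`` column; ``group_cols`` (e.g.
    genotype, treatment, near/far stratum) are carried through. Output
    column is named ``{metric}_{statistic}``.
    """
    if "animal_id" not in table.columns:
        raise ValueError("table must have an animal_id column")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    if table.empty:
        raise ValueError("empty table: no animals to aggregate")
    keys = ["animal_id"] + [c for c in (group_cols or []) if c in table.columns]
    agg = (table.groupby(keys, sort=True)[metric]
           .agg(statistic)
           .reset_index()
           .rename(columns={metric: f"{metric}_{statistic}"}))
    return agg


@dataclass
class MannWhitneyResult:
    U: float
    p: float
    method: str  # "exact" or "asymptotic"

    def __iter__(self):
        return iter((self.U, self.p))


def mann_whitney_u(
    group_a,
    group_b,
    alternative: str = "two-sided",
) -> MannWhitneyResult:
    """Mann-Whitney U test with exact small-sample behaviour.

    U is computed from rank sums with midranks for ties. The p-value is
    exact (full permutation distribution) when the combined sample size
    is at most 12 and there are no ties; otherwise the normal
    approximation with tie and continuity corrections is used. Two
    identical-constant groups give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return MannWhitneyResult(U=a.size * b.size / 2.0, p=1.0, method="degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
        res = sps.mannwhitneyu(a, b, alternative=alternative, method="exact")
    else:
        method = "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative=alternative,
                               method="asymptotic", use_continuity=True)
    return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue),
                             method=method)


def chi_square_gof(observed_counts, expected_proportions) -> tuple[float, int, float]:
    """Chi-square goodness of fit against expected class proportions.

    Returns ``(chi2, df, p)`` with ``chi2 = Σ (O−E)²/E``, ``E = n·p``,
    ``df = k − 1`` and the upper-tail chi-square probability.
    """
    obs = np.asarray(observed_counts, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected must have equal length")
    if np.any(obs < 0):
        raise ValueError("counts must be >= 0")
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("expected proportions must sum to 1")
    expected = obs.sum() * props
    if np.any(expected == 0):
        raise ValueError("an expected count is zero; drop that class")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    p = float(sps.chi2.sf(chi2, df))
    return chi2, df, p


def chi_square_upper_tail(chi2: float, df: int) -> float:
    """Upper-tail chi-square probability P(X² ≥ chi2) at ``df``."""
    if chi2 < 0 or df < 1:
        raise ValueError("need chi2 >= 0 and df >= 1")
    return float(sps.chi2.sf(chi2, df))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; no correction is applied by default)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out
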