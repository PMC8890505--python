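"""Per-region testing of pS6 activation counts across social conditions.

Within one sex, each of the 19 SDMN regions is tested with a tie-corrected
Kruskal-Wallis test across the three social conditions (isolated control,
winner, loser).  Raw p-values are corrected across regions with the
Benjamini-Hochberg step-up procedure, and regions passing the FDR threshold
get Dunn's rank-based pairwise post hoc comparisons (BH-adjusted within
region).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import CONDITIONS, REGIONS

__all__ = ["validate_activation_table", "kruskal_fdr", "dunn_posthoc"]

_PAIRS = tuple(itertools.combinations(CONDITIONS, 2))


def validate_activation_table(
    table: pd.DataFrame, regions: tuple[str, ...] = REGIONS
) -> pd.DataFrame:
    """Check the activation-table contract and return the table.

    Requires columns ``fish_id, sex, condition`` plus one column per
    region, non-negative integer counts, and unique fish ids.
    """
    required = ["fish_id", "sex", "condition", *regions]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"activation table missing columns: {missing}")
    if table["fish_id"].duplicated().any():
        dupes = table.loc[table["fish_id"].duplicated(), "fish_id"].tolist()
        raise ValueError(f"duplicated fish ids: {dupes}")
    counts = table[list(regions)]
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative pS6 counts are not allowed")
    bad_cond = set(table["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
    return table


def _condition_samples(table: pd.DataFrame, sex: str, region: str):
    samples = []
    for condition in CONDITIONS:
        s = table.loc[
            (table["sex"] == sex) & (table["condition"] == condition), region
        ].to_numpy(dtype=float)
        if len(s) < 2:
            raise ValueError(
                f"condition stratum {sex} x {condition} has fewer than 2 fish"
            )
        samples.append(s)
    return samples


def dunn_posthoc(samples: list[np.ndarray]) -> np.ndarray:
    """Dunn's rank-based pairwise comparisons for k groups.

    Returns the symmetric matrix of two-sided unadjusted p-values based on
    the normal approximation of mean-rank differences with tie correction.
    """
    k = len(samples)
    pooled = np.concatenate(samples)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for s in samples:
        mean_ranks.append(ranks[start : start + len(s)].mean())
        start += len(s)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    base_var = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    p = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        se2 = base_var * (1.0 / len(samples[i]) + 1.0 / len(samples[j]))
        if se2 <= 0:  # all observations tied: no evidence of difference
            pij = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(se2)
            pij = 2.0 * stats.norm.sf(abs(z))
        p[i, j] = p[j, i] = pij
    return p


def kruskal_fdr(
    table: pd.DataFrame,
    sex: str,
    alpha: float = 0.05,
    regions: tuple[str, ...] = REGIONS,
) -> pd.DataFrame:
    """Kruskal-Wallis per region with BH-FDR across regions and Dunn post hoc.

    Returns one row per region with the tie-corrected H statistic, the raw
    p-value, the BH-adjusted q-value, and — for regions with q <= alpha —
    BH-adjusted Dunn pairwise p-values between conditions (columns
    ``p_winner_vs_control`` etc.; NaN where the omnibus test was not
    followed up).
    """
    validate_activation_table(table, regions)
    if sex not in set(table["sex"]):
        raise ValueError(f"no rows for sex {sex!r}")

    rows = []
    per_region_samples = {}
    for region in regions:
        samples = _condition_samples(table, sex, region)
        per_region_samples[region] = samples
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:  # all counts equal: H undefined, no signal
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*samples)
        rows.append({"region": region, "H": float(h), "pvalue": float(p)})
    result = pd.DataFrame(rows)
    result["qvalue"] = multipletests(result["pvalue"], method="fdr_bh")[1]

    pair_cols = {(a, b): f"p_{b}_vs_{a}" for a, b in _PAIRS}
    for col in pair_cols.values():
        result[col] = np.nan
    for idx, row in result.iterrows():
        if row["qvalue"] <= alpha:
            p_mat = dunn_posthoc(per_region_samples[row["region"]])
            raw = [p_mat[CONDITIONS.index(a), CONDITIONS.index(b)] for a, b in _PAIRS]
            adj = multipletests(raw, method="fdr_bh")[1]
            for (pair, col), q in zip(pair_cols.items(), adj):
                result.loc[idx, col] = q
    return result
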