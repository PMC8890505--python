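"""Contest-level behavioral statistics.

Per-dyad summaries of scored ethogram events, sex comparisons with a
Shapiro-Wilk normality gate (t-test when both groups look normal, otherwise
Mann-Whitney reported in the rank-sum W convention), principal component
analysis of square-root-transformed display totals, and a distance-based
permutation MANOVA (pseudo-F on Euclidean distances with label shuffling).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .catalog import AGGRESSIVE_BEHAVIORS, BEHAVIORS, SUBMISSIVE_BEHAVIORS

__all__ = [
    "summarize_dyad",
    "summarize_dyads",
    "TwoGroupTestResult",
    "gated_two_group_test",
    "PCAResult",
    "behavior_pca",
    "PermanovaResult",
    "permanova",
    "sex_comparison_table",
]


def _validate_behaviors(labels) -> None:
    unknown = sorted(set(labels) - set(BEHAVIORS))
    if unknown:
        raise ValueError(f"unknown behavior labels: {unknown}")


def summarize_dyad(events: pd.DataFrame, metadata: dict) -> dict:
    """Summarize one dyad's scored events into contest metrics.

    Parameters
    ----------
    events
        Tidy event rows for a single dyad with at least columns
        ``behavior`` and ``t_seconds``.
    metadata
        Must carry ``dyad_id``, ``sex`` and ``resolution_min`` (> 0).

    Returns
    -------
    dict
        ``dyad_id, sex, latency_min, resolution_min``, per-behavior
        ``total_*`` counts and ``freq_*`` per-minute frequencies, plus the
        aggregate ``freq_aggressive`` and ``freq_submissive``.  Latency is
        the time of the first aggressive act from recording start; a dyad
        with no aggressive act has latency NaN (excluded from latency
        tests downstream).
    """
    resolution = float(metadata["resolution_min"])
    if not resolution > 0:
        raise ValueError(
            f"resolution time must be > 0 (dyad {metadata.get('dyad_id')!r})"
        )
    _validate_behaviors(events["behavior"].unique())

    until = events[events["t_seconds"] <= resolution * 60.0]
    totals = until["behavior"].value_counts().to_dict()
    aggressive = until[until["behavior"].isin(AGGRESSIVE_BEHAVIORS)]
    latency = (
        float(aggressive["t_seconds"].min()) / 60.0 if len(aggressive) else np.nan
    )

    row: dict = {
        "dyad_id": metadata["dyad_id"],
        "sex": metadata["sex"],
        "latency_min": latency,
        "resolution_min": resolution,
    }
    for b in BEHAVIORS:
        row[f"total_{b}"] = int(totals.get(b, 0))
        row[f"freq_{b}"] = row[f"total_{b}"] / resolution
    row["freq_aggressive"] = sum(row[f"freq_{b}"] for b in AGGRESSIVE_BEHAVIORS)
    row["freq_submissive"] = sum(row[f"freq_{b}"] for b in SUBMISSIVE_BEHAVIORS)
    return row


def summarize_dyads(events: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Summarize every dyad in an events table.

    ``metadata`` needs one row per dyad with columns
    ``dyad_id, sex, resolution_min``.
    """
    rows = []
    grouped = dict(tuple(events.groupby("dyad_id")))
    empty = events.iloc[0:0]
    for meta in metadata.to_dict("records"):
        dyad_events = grouped.get(meta["dyad_id"], empty)
        rows.append(summarize_dyad(dyad_events, meta))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TwoGroupTestResult:
    """Outcome of the normality-gated two-group comparison."""

    test: str  # "t" or "mann_whitney"
    statistic: float
    pvalue: float
    mean_x: float
    mean_y: float
    se_x: float
    se_y: float
    normal_x: bool
    normal_y: bool
    n_x: int
    n_y: int


def _shapiro_normal(sample: np.ndarray, alpha: float) -> bool:
    if np.ptp(sample) == 0:  # constant sample: W undefined -> fail the gate
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(sample).pvalue > alpha


def gated_two_group_test(
    x, y, alpha_gate: float = 0.05
) -> TwoGroupTestResult:
    """Two-sided two-group comparison with a Shapiro-Wilk normality gate.

    If both samples pass Shapiro-Wilk at ``alpha_gate`` a two-sample t-test
    is used; otherwise a two-sided Mann-Whitney test, whose statistic is
    reported in the rank-sum convention W = U + n_x (n_x + 1) / 2 (the sum
    of ranks of the first sample in the pooled ranking).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs at least 3 non-missing values")

    normal_x = _shapiro_normal(x, alpha_gate)
    normal_y = _shapiro_normal(y, alpha_gate)
    if normal_x and normal_y:
        res = stats.ttest_ind(x, y)
        test, statistic, pvalue = "t", float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0
        test, statistic, pvalue = "mann_whitney", w, float(res.pvalue)
    return TwoGroupTestResult(
        test=test,
        statistic=statistic,
        pvalue=pvalue,
        mean_x=float(np.mean(x)),
        mean_y=float(np.mean(y)),
        se_x=float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan,
        se_y=float(np.std(y, ddof=1) / np.sqrt(len(y))) if len(y) > 1 else np.nan,
        normal_x=normal_x,
        normal_y=normal_y,
        n_x=len(x),
        n_y=len(y),
    )


@dataclass(frozen=True)
class PCAResult:
    """Principal component analysis of behavioral display totals."""

    loadings: pd.DataFrame  # behaviors x components, orthonormal columns
    sdev: np.ndarray  # per-component standard deviation
    proportion: np.ndarray  # proportion of variance, sums to 1
    cumulative: np.ndarray
    scores: np.ndarray  # individuals x components


def behavior_pca(
    totals: pd.DataFrame | np.ndarray,
    *,
    sqrt_transform: bool = True,
    scale: bool = False,
) -> PCAResult:
    """PCA of per-individual behavioral display totals.

    Totals are square-root transformed to correct for the dispersion of
    count data, column-centered, and the sample covariance matrix (ddof=1)
    is eigen-decomposed.  With ``scale=True`` variables are additionally
    standardized to unit variance (correlation-matrix PCA); the covariance
    form is the default.  The sign of each component is fixed so that its
    largest-magnitude loading is positive (first such behavior on ties).
    """
    if isinstance(totals, pd.DataFrame):
        names = list(totals.columns)
        X = totals.to_numpy(dtype=float)
    else:
        X = np.asarray(totals, dtype=float)
        names = [f"var{j}" for j in range(X.shape[1])]
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 individuals and 2 behaviors")
    if (X < 0).any():
        raise ValueError("totals must be non-negative")

    if sqrt_transform:
        X = np.sqrt(X)
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd

    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vec = vec[:, order]
    # Sign convention: dominant loading of each component is positive.
    for j in range(vec.shape[1]):
        lead = np.argmax(np.abs(vec[:, j]))
        if vec[lead, j] < 0:
            vec[:, j] = -vec[:, j]

    total_var = lam.sum()
    proportion = lam / total_var if total_var > 0 else np.zeros_like(lam)
    loadings = pd.DataFrame(
        vec, index=names, columns=[f"PC{j + 1}" for j in range(vec.shape[1])]
    )
    return PCAResult(
        loadings=loadings,
        sdev=np.sqrt(lam),
        proportion=proportion,
        cumulative=np.cumsum(proportion),
        scores=Xc @ vec,
    )


@dataclass(frozen=True)
class PermanovaResult:
    """Distance-based permutation MANOVA result."""

    pseudo_f: float
    pvalue: float
    n_permutations: int
    ss_between: float
    ss_within: float
    ss_total: float


def _ss_partition(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray):
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups:
        mask = labels == g
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub.sum() / (2.0 * mask.sum())
    return ss_total, ss_within


def _pseudo_f(ss_between: float, ss_within: float, a: int, n: int) -> float:
    if ss_within <= 0:
        return 0.0 if ss_between <= 0 else np.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def _distinct_assignments(labels: np.ndarray):
    """All distinct ways to assign the multiset of labels to positions."""
    n = len(labels)
    seen = set()
    for perm in itertools.permutations(range(n)):
        key = tuple(labels[list(perm)])
        if key not in seen:
            seen.add(key)
            yield np.asarray(key)


def permanova(
    data,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Distance-based permutation MANOVA on Euclidean distances.

    The total sum of squares is the sum of all pairwise squared distances
    divided by n; the within-group term sums each group's pairwise squared
    distances divided by the group size.  The pseudo-F statistic
    ``(SS_between / (a-1)) / (SS_within / (n-a))`` is referenced against
    the distribution obtained by shuffling group labels over individuals;
    the p-value uses the add-one correction
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` so it is never
    exactly zero.  Degenerate data with no variance at all report F = 0
    and p = 1.

    With ``exhaustive=True`` every distinct label assignment is evaluated
    once (feasible only for tiny samples) and the p-value is the exact
    fraction of assignments with F >= the observed F (the observed
    assignment is one of them, so p > 0 without any correction).
    """
    X = np.asarray(data, dtype=float)
    labels = np.asarray(groups)
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise ValueError("data must be 2-D with one row per label")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        bad = uniq[counts < 2]
        raise ValueError(f"each group needs >= 2 members (offending: {list(bad)})")

    n, a = X.shape[0], len(uniq)
    d2 = squareform(pdist(X, metric="euclidean")) ** 2
    ss_total, ss_within = _ss_partition(d2, labels, uniq)
    ss_between = ss_total - ss_within
    f_obs = _pseudo_f(ss_between, ss_within, a, n)

    if ss_total <= 0:  # all observations identical: perfectly exchangeable
        return PermanovaResult(0.0, 1.0, n_permutations, 0.0, 0.0, 0.0)

    if exhaustive:
        hits = 0
        total = 0
        for assignment in _distinct_assignments(labels):
            _, ss_w = _ss_partition(d2, assignment, uniq)
            if _pseudo_f(ss_total - ss_w, ss_w, a, n) >= f_obs - 1e-12:
                hits += 1
            total += 1
        pvalue = hits / total
        n_permutations = total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = labels[rng.permutation(n)]
            _, ss_w = _ss_partition(d2, perm, uniq)
            f_perm = _pseudo_f(ss_total - ss_w, ss_w, a, n)
            if f_perm >= f_obs:
                hits += 1
        pvalue = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        pvalue=float(pvalue),
        n_permutations=n_permutations,
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
    )


def sex_comparison_table(
    summaries: pd.DataFrame, alpha_gate: float = 0.05
) -> pd.DataFrame:
    """Run the gated two-group test on every contest metric, F vs M.

    Compares latency, resolution time, per-behavior frequencies and the
    aggressive/submissive aggregates between female and male dyads.
    """
    metrics = (
        ["latency_min", "resolution_min"]
        + [f"freq_{b}" for b in BEHAVIORS]
        + ["freq_aggressive", "freq_submissive"]
    )
    rows = []
    f = summaries[summaries["sex"] == "F"]
    m = summaries[summaries["sex"] == "M"]
    for metric in metrics:
        if metric not in summaries.columns:
            continue
        res = gated_two_group_test(f[metric], m[metric], alpha_gate=alpha_gate)
        rows.append(
            {
                "metric": metric,
                "test": res.test,
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "mean_F": res.mean_x,
                "se_F": res.se_x,
                "mean_M": res.mean_y,
                "se_M": res.se_y,
                "normal_F": res.normal_x,
                "normal_M": res.normal_y,
            }
        )
    return pd.DataFrame(rows)
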