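"""Distributional comparisons of network edge weights.

Edge-weight samples from excitation/inhibition subnetworks are compared
with the two-sided two-sample Kolmogorov-Smirnov test (distribution shape)
and the Mann-Whitney U test (location), together with Cohen's d (pooled
standard deviation) as the effect size.  The balance analysis compares a
treatment's excitation weights against the magnitudes of its inhibition
weights: a positive d means excitation dominates.

Edges sharing a node are not independent; following common practice in
this kind of network comparison the edge weights are nevertheless treated
as plain samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectivity import SignedSubnetworks, TreatmentNetwork

__all__ = [
    "ComparisonResult",
    "cohens_d",
    "effect_size_label",
    "compare_weight_distributions",
    "balance_analysis",
    "edge_weight_sample",
]

# Conventional Cohen bands on |d|: upper bounds for each label.
DEFAULT_EFFECT_BANDS = (
    (0.2, "negligible"),
    (0.5, "small"),
    (0.8, "intermediate"),
    (float("inf"), "large"),
)


def cohens_d(a, b) -> float:
    """Cohen's d with pooled SD; positive when the first sample is larger.

    Returns NaN when either sample has fewer than 2 values or the pooled
    SD is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def effect_size_label(d: float, bands=DEFAULT_EFFECT_BANDS) -> str:
    if np.isnan(d):
        return "undefined"
    for upper, label in bands:
        if abs(d) < upper:
            return label
    return bands[-1][1]


@dataclass(frozen=True)
class ComparisonResult:
    """KS + MWU + Cohen's d battery for two edge-weight samples."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    ks_stat: float
    ks_pvalue: float
    mwu_stat: float
    mwu_pvalue: float
    cohen_d: float
    effect_label: str
    note: str = ""


def compare_weight_distributions(
    a, b, label_a: str = "a", label_b: str = "b", bands=DEFAULT_EFFECT_BANDS
) -> ComparisonResult:
    """Compare two edge-weight samples with KS, MWU and Cohen's d.

    Both tests are two-sided; d is first-minus-second over the pooled SD.
    With a sample of fewer than 2 values d is reported as NaN but the
    tests still run when defined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    ks = stats.ks_2samp(a, b, alternative="two-sided")
    mwu = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    d = cohens_d(a, b)
    return ComparisonResult(
        label_a=label_a,
        label_b=label_b,
        n_a=len(a),
        n_b=len(b),
        ks_stat=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        mwu_stat=float(mwu.statistic),
        mwu_pvalue=float(mwu.pvalue),
        cohen_d=d,
        effect_label=effect_size_label(d, bands),
    )


def edge_weight_sample(network: TreatmentNetwork, sign: str = "all") -> np.ndarray:
    """Nonzero aggregated edge weights of a treatment network.

    ``sign``: ``"all"``, ``"positive"`` (excitation) or ``"negative"``
    (inhibition).
    """
    iu = np.triu_indices(len(network.regions), 1)
    w = network.weights[iu]
    if sign == "positive":
        return w[w > 0]
    if sign == "negative":
        return w[w < 0]
    if sign == "all":
        return w[w != 0]
    raise ValueError(f"unknown sign selector {sign!r}")


def balance_analysis(subnets: SignedSubnetworks) -> ComparisonResult:
    """Excitation-inhibition balance within one treatment network.

    Compares excitation weights against the absolute values of inhibition
    weights (magnitude comparison — otherwise the sign alone separates
    them trivially).  Positive Cohen's d: excitation overcomes inhibition;
    negative: inhibition dominates.  If either side is empty no tests are
    run and the result is flagged ``one-sided network``.
    """
    exc = subnets.excitation["weight"].to_numpy(dtype=float)
    inh = np.abs(subnets.inhibition["weight"].to_numpy(dtype=float))
    label_a = f"{subnets.sex}_{subnets.condition}_excitation"
    label_b = f"{subnets.sex}_{subnets.condition}_inhibition_abs"
    if len(exc) == 0 or len(inh) == 0:
        return ComparisonResult(
            label_a=label_a,
            label_b=label_b,
            n_a=len(exc),
            n_b=len(inh),
            ks_stat=float("nan"),
            ks_pvalue=float("nan"),
            mwu_stat=float("nan"),
            mwu_pvalue=float("nan"),
            cohen_d=float("nan"),
            effect_label="undefined",
            note="one-sided network",
        )
    return compare_weight_distributions(exc, inh, label_a, label_b)
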