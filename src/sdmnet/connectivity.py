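"""Bootstrapped functional-connectivity networks of the SDMN.

For each treatment group (sex x social condition) the pipeline builds many
correlation network instances, one per subsample of the group's fish.  Each
instance is a signed region-by-region correlation matrix, sparsified at a
fixed edge density by keeping the edges with the strongest absolute
weights.  Instances are averaged into a single weighted treatment network,
which is then split into an excitation (positive weight) and an inhibition
(negative weight) subnetwork.

Defaults follow the published pipeline: subsamples of size s = 7, density
threshold rho = 0.23 (39 of the 171 possible edges among 19 regions),
Pearson correlations, and averaging thresholded instances with non-retained
edges contributing zero.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import CONDITIONS, REGIONS, SEXES
from .activation import validate_activation_table

__all__ = [
    "ConnectivityConfig",
    "NetworkInstance",
    "TreatmentNetwork",
    "SignedSubnetworks",
    "enumerate_subsamples",
    "instance_network",
    "aggregate",
    "split_signed",
    "build_treatment_network",
    "build_all_networks",
    "robustness_rank_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConnectivityConfig:
    """Parameters of the bootstrapped network construction.

    Attributes
    ----------
    subsample_size
        Target subsample size s.  When a stratum has n <= s fish, the
        effective size falls back to n - 1 (leave-one-out) unless
        ``strict_s`` is set, in which case the construction errors out.
    density
        Fraction rho of the 171 possible edges retained per instance.
    estimator
        ``"pearson"`` (default) or ``"spearman"``.
    policy
        ``"enumerate_all"`` uses every subsample of the stratum;
        ``"random_m"`` draws ``m`` distinct seeded subsamples.
    aggregation
        ``"mean_with_zeros"`` averages thresholded matrices over all
        instances (non-retained edges count as 0, shrinking unstable edges
        toward zero); ``"mean_over_retaining"`` averages each edge only
        over the instances that retained it.
    rounding
        How the retained-edge count k = rho * E is rounded: ``"round"``
        (banker's rounding), ``"floor"`` or ``"ceil"``.
    """

    subsample_size: int = 7
    density: float = 0.23
    estimator: str = "pearson"
    policy: str = "enumerate_all"
    m: int | None = None
    aggregation: str = "mean_with_zeros"
    rounding: str = "round"
    strict_s: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.subsample_size < 2:
            raise ValueError("subsample_size must be >= 2")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if self.estimator not in ("pearson", "spearman"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.policy not in ("enumerate_all", "random_m"):
            raise ValueError(f"unknown subsample policy {self.policy!r}")
        if self.policy == "random_m" and (self.m is None or self.m < 1):
            raise ValueError("policy 'random_m' requires m >= 1")
        if self.aggregation not in ("mean_with_zeros", "mean_over_retaining"):
            raise ValueError(f"unknown aggregation rule {self.aggregation!r}")
        if self.rounding not in ("round", "floor", "ceil"):
            raise ValueError(f"unknown rounding rule {self.rounding!r}")

    def n_retained(self, n_regions: int) -> int:
        """Number of edges retained per instance for a given node count."""
        n_edges = n_regions * (n_regions - 1) // 2
        target = self.density * n_edges
        if self.rounding == "floor":
            k = math.floor(target)
        elif self.rounding == "ceil":
            k = math.ceil(target)
        else:
            k = round(target)  # round-half-to-even
        return max(1, min(k, n_edges))


@dataclass(frozen=True)
class NetworkInstance:
    """One subsample's thresholded signed correlation network."""

    weights: np.ndarray  # symmetric, zero diagonal, zeros off the mask
    mask: np.ndarray  # boolean retained-edge mask (symmetric)
    regions: tuple[str, ...]
    subsample: tuple = ()

    @property
    def n_retained(self) -> int:
        return int(np.triu(self.mask, 1).sum())


@dataclass(frozen=True)
class TreatmentNetwork:
    """Aggregated signed network for one sex x condition treatment."""

    sex: str
    condition: str
    weights: np.ndarray
    regions: tuple[str, ...]
    n_instances: int

    def edge_list(self) -> pd.DataFrame:
        """Nonzero edges as a tidy (region_i, region_j, weight) table."""
        rows = []
        p = len(self.regions)
        for i in range(p):
            for j in range(i + 1, p):
                w = self.weights[i, j]
                if w != 0:
                    rows.append((self.regions[i], self.regions[j], float(w)))
        return pd.DataFrame(rows, columns=["region_i", "region_j", "weight"])


@dataclass(frozen=True)
class SignedSubnetworks:
    """Sign partition of a treatment network's nonzero edges."""

    sex: str
    condition: str
    excitation: pd.DataFrame  # positive-weight edges
    inhibition: pd.DataFrame  # negative-weight edges


def enumerate_subsamples(
    stratum_ids, config: ConnectivityConfig
) -> list[tuple]:
    """Subsample id-sets for one stratum under the configured policy.

    With ``enumerate_all`` this is every subset of size s_eff in
    lexicographic order over the sorted ids, where s_eff = s when the
    stratum is larger than s and n - 1 (leave-one-out) otherwise.  With
    ``random_m`` it is ``m`` distinct seeded subsets (all of them when m
    exceeds the number available).
    """
    ids = sorted(stratum_ids)
    n = len(ids)
    if n < 3:
        raise ValueError(
            f"stratum of size {n} is too small for correlation networks (need >= 3)"
        )
    s = config.subsample_size
    if n <= s:
        if config.strict_s:
            raise ValueError(
                f"stratum size {n} does not admit subsamples of size {s} "
                "(strict_s is set)"
            )
        s_eff = n - 1
        logger.info(
            "stratum size %d <= s=%d; falling back to leave-one-out s_eff=%d",
            n,
            s,
            s_eff,
        )
    else:
        s_eff = s
    if config.policy == "enumerate_all":
        return list(itertools.combinations(ids, s_eff))
    total = math.comb(n, s_eff)
    m = min(config.m, total)
    rng = np.random.default_rng(config.seed)
    if total <= 10 * m:  # small universe: sample indices into the enumeration
        all_subsets = list(itertools.combinations(ids, s_eff))
        chosen = rng.choice(total, size=m, replace=False)
        return [all_subsets[i] for i in sorted(chosen)]
    subsets: set[tuple] = set()
    while len(subsets) < m:  # rejection sampling; duplicates are rare here
        pick = rng.choice(n, size=s_eff, replace=False)
        subsets.add(tuple(ids[i] for i in sorted(pick)))
    return sorted(subsets)


def _correlation(counts: np.ndarray, estimator: str) -> np.ndarray:
    x = counts.astype(float)
    if estimator == "spearman":
        x = np.apply_along_axis(stats.rankdata, 0, x)
    sd = x.std(axis=0)
    dead = sd == 0
    if dead.any():
        logger.info(
            "zero-variance regions in subsample (correlations set to 0): %s",
            list(np.nonzero(dead)[0]),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    return corr


def instance_network(
    counts: np.ndarray,
    config: ConnectivityConfig,
    regions: tuple[str, ...] = REGIONS,
    subsample: tuple = (),
) -> NetworkInstance:
    """Correlation network of one subsample, density-thresholded.

    The pairwise correlation matrix is computed over the subsample's rows,
    then exactly k = round(rho * E) edges with the largest absolute weight
    are retained (E = number of region pairs); everything else is zeroed.
    Ties at the cutoff are broken by lexicographic (i, j) index order.
    Zero-variance regions get zero correlations and are thereby excluded
    from retention by weight.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] != len(regions):
        raise ValueError(
            f"counts must be 2-D with {len(regions)} region columns, "
            f"got shape {counts.shape}"
        )
    if counts.shape[0] < 3:
        raise ValueError("a subsample needs at least 3 rows for correlation")

    corr = _correlation(counts, config.estimator)
    p = len(regions)
    k = config.n_retained(p)
    iu = np.triu_indices(p, 1)
    order = sorted(
        range(len(iu[0])), key=lambda e: (-abs(corr[iu[0][e], iu[1][e]]), iu[0][e], iu[1][e])
    )
    keep = order[:k]
    mask = np.zeros((p, p), dtype=bool)
    mask[iu[0][keep], iu[1][keep]] = True
    mask |= mask.T
    weights = np.where(mask, corr, 0.0)
    return NetworkInstance(
        weights=weights, mask=mask, regions=tuple(regions), subsample=tuple(subsample)
    )


def aggregate(
    instances: list[NetworkInstance],
    sex: str = "",
    condition: str = "",
    rule: str = "mean_with_zeros",
) -> TreatmentNetwork:
    """Average thresholded instances into one treatment network.

    ``mean_with_zeros`` divides each edge's summed weight by the total
    number of instances; ``mean_over_retaining`` divides by the number of
    instances that retained the edge.
    """
    if not instances:
        raise ValueError("need at least one network instance to aggregate")
    regions = instances[0].regions
    stack = np.stack([inst.weights for inst in instances])
    if rule == "mean_with_zeros":
        weights = stack.mean(axis=0)
    elif rule == "mean_over_retaining":
        retained = np.stack([inst.mask for inst in instances]).sum(axis=0)
        with np.errstate(invalid="ignore"):
            weights = np.where(retained > 0, stack.sum(axis=0) / np.maximum(retained, 1), 0.0)
    else:
        raise ValueError(f"unknown aggregation rule {rule!r}")
    np.fill_diagonal(weights, 0.0)
    return TreatmentNetwork(
        sex=sex,
        condition=condition,
        weights=weights,
        regions=regions,
        n_instances=len(instances),
    )


def split_signed(network: TreatmentNetwork) -> SignedSubnetworks:
    """Partition a treatment network into excitation and inhibition edges."""
    edges = network.edge_list()
    return SignedSubnetworks(
        sex=network.sex,
        condition=network.condition,
        excitation=edges[edges["weight"] > 0].reset_index(drop=True),
        inhibition=edges[edges["weight"] < 0].reset_index(drop=True),
    )


def build_treatment_network(
    table: pd.DataFrame,
    sex: str,
    condition: str,
    config: ConnectivityConfig | None = None,
    regions: tuple[str, ...] = REGIONS,
) -> TreatmentNetwork:
    """Full bootstrap construction for one sex x condition stratum."""
    config = config or ConnectivityConfig()
    validate_activation_table(table, regions)
    stratum = table[(table["sex"] == sex) & (table["condition"] == condition)]
    if stratum.empty:
        raise ValueError(f"no fish in stratum {sex} x {condition}")
    stratum = stratum.set_index("fish_id")
    subsets = enumerate_subsamples(stratum.index, config)
    instances = [
        instance_network(
            stratum.loc[list(subset), list(regions)].to_numpy(),
            config,
            regions,
            subsample=subset,
        )
        for subset in subsets
    ]
    return aggregate(instances, sex=sex, condition=condition, rule=config.aggregation)


def build_all_networks(
    table: pd.DataFrame,
    config: ConnectivityConfig | None = None,
    regions: tuple[str, ...] = REGIONS,
) -> dict[tuple[str, str], TreatmentNetwork]:
    """Treatment networks for every sex x condition present in the table."""
    out = {}
    for sex in SEXES:
        for condition in CONDITIONS:
            stratum = table[(table["sex"] == sex) & (table["condition"] == condition)]
            if stratum.empty:
                continue
            out[(sex, condition)] = build_treatment_network(
                table, sex, condition, config, regions
            )
    return out


def robustness_rank_correlation(
    table: pd.DataFrame,
    sex: str,
    condition: str,
    config: ConnectivityConfig | None = None,
    delta: int = 1,
    regions: tuple[str, ...] = REGIONS,
) -> float:
    """Spearman rank correlation of aggregated edge weights between runs
    at subsample sizes s and s + delta.

    High values indicate that the inferred network is robust to the choice
    of subsample size.
    """
    config = config or ConnectivityConfig()
    net_s = build_treatment_network(table, sex, condition, config, regions)
    config_bigger = replace(config, subsample_size=config.subsample_size + delta)
    net_s2 = build_treatment_network(table, sex, condition, config_bigger, regions)
    iu = np.triu_indices(len(regions), 1)
    rho = stats.spearmanr(net_s.weights[iu], net_s2.weights[iu]).statistic
    return float(rho)
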