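"""Synthetic data generators for contest ethograms and pS6 activation tables.

The raw behavioral and neural data behind this analysis are not public, so
every downstream stage is exercised on synthetic datasets with known ground
truth.  Two generators are provided:

``generate_dyads``
    Emulates staged same-sex dyadic contests.  Per-behavior event totals are
    negative-binomial (overdispersed Poisson) with sex-specific rates;
    latency to first attack and contest resolution time are log-normal
    (positive, right-skewed).  The opponent with more aggressive acts at
    resolution is the winner, ties broken by a coin flip from the dyad's own
    RNG stream.

``generate_activation``
    Emulates per-individual pS6-positive cell counts over the 19 SDMN
    regions.  Marginals are negative binomial; block correlation structure
    (positive or negative) and hub regions are imposed through a Gaussian
    copula, so the generating correlations are recoverable by downstream
    network inference.

Both generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import (
    AGGRESSIVE_BEHAVIORS,
    BEHAVIORS,
    CONDITIONS,
    REGIONS,
    SEXES,
    SUBMISSIVE_BEHAVIORS,
)

__all__ = [
    "BehaviorModel",
    "CorrelationBlock",
    "PlantedHub",
    "ActivationModel",
    "generate_dyads",
    "generate_activation",
]

EVENT_COLUMNS = ("dyad_id", "sex", "fish_id", "behavior", "t_seconds")

# Default per-sex event rates (events / minute).  Chosen to mirror the
# qualitative sex differences reported for zebrafish contests: males bite,
# strike and retreat more; females use antiparallel displays more and
# resolve conflicts faster.  Absolute scales are conventions.
_DEFAULT_RATES: dict[str, dict[str, float]] = {
    "M": {
        "bite": 2.0,
        "antiparallel_display": 1.0,
        "circle": 0.8,
        "chase": 1.5,
        "flee": 1.2,
        "strike": 1.5,
        "retreat": 1.0,
        "freeze": 0.4,
    },
    "F": {
        "bite": 1.2,
        "antiparallel_display": 2.0,
        "circle": 0.8,
        "chase": 1.0,
        "flee": 0.8,
        "strike": 0.6,
        "retreat": 0.5,
        "freeze": 0.4,
    },
}

# Log-normal parameters (mean, sigma of log minutes).  Medians: latency
# ~2 min for both sexes; resolution ~15 min for males, ~9 min for females
# (females resolve conflicts faster).
_DEFAULT_LATENCY = {"M": (np.log(2.0), 0.6), "F": (np.log(2.0), 0.6)}
_DEFAULT_RESOLUTION = {"M": (np.log(15.0), 0.5), "F": (np.log(9.0), 0.5)}


@dataclass(frozen=True)
class BehaviorModel:
    """Generating model for dyadic contest ethograms.

    Parameters
    ----------
    rates
        Per-sex, per-behavior event rates in events/minute over the eight
        ethogram acts.
    latency_params, resolution_params
        Per-sex ``(mu, sigma)`` of the log-normal distributions of latency
        to the first attack and of contest duration after the first attack,
        in log-minutes.  Resolution time is latency plus that duration, so
        it always exceeds latency.
    dispersion
        Negative-binomial shape ``k``; the variance of a count with mean
        ``m`` is ``m + m**2 / k``.  Smaller values mean more overdispersion.
    seed
        Seeds every random draw; identical models and seeds give
        bit-identical outputs.
    """

    rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {s: dict(_DEFAULT_RATES[s]) for s in SEXES}
    )
    latency_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_LATENCY)
    )
    resolution_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RESOLUTION)
    )
    dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for sex in SEXES:
            if sex not in self.rates:
                raise ValueError(f"rates missing for sex {sex!r}")
            for behavior in BEHAVIORS:
                rate = self.rates[sex].get(behavior)
                if rate is None:
                    raise ValueError(
                        f"rate missing for behavior {behavior!r} (sex {sex!r})"
                    )
                if not np.isfinite(rate) or rate < 0:
                    raise ValueError(
                        f"rate for {behavior!r} (sex {sex!r}) must be finite "
                        f"and non-negative, got {rate!r}"
                    )
        if not np.isfinite(self.dispersion) or self.dispersion <= 0:
            raise ValueError("dispersion must be finite and > 0")
        for params in (self.latency_params, self.resolution_params):
            for sex in SEXES:
                mu, sigma = params[sex]
                if not (np.isfinite(mu) and np.isfinite(sigma) and sigma >= 0):
                    raise ValueError("log-normal parameters must be finite, sigma >= 0")


def _nbinom_counts(rng: np.random.Generator, mean: float, k: float, size: int):
    """Negative-binomial counts with the (mean, dispersion-k) parametrization."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=size).astype(np.int64)


def generate_dyads(
    model: BehaviorModel, n_dyads_per_sex: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate dyadic contests and return (events, dyad summaries).

    The events table is tidy with columns
    ``dyad_id, sex, fish_id, behavior, t_seconds``; one row per scored act,
    sorted by dyad then time.  Events run from recording start to conflict
    resolution; the first aggressive act of the dyad occurs exactly at the
    latency.  The summaries table carries per-dyad metadata: latency and
    resolution time in minutes, winner/loser ids, per-behavior totals
    (pooled over both opponents) and frequencies per minute.
    """
    if n_dyads_per_sex < 1:
        raise ValueError("n_dyads_per_sex must be >= 1")

    event_rows: list[tuple] = []
    summary_rows: list[dict] = []
    for sex_idx, sex in enumerate(SEXES):
        lat_mu, lat_sigma = model.latency_params[sex]
        res_mu, res_sigma = model.resolution_params[sex]
        for d in range(n_dyads_per_sex):
            # Independent per-dyad stream: reproducible and insensitive to
            # how many dyads precede it.
            rng = np.random.default_rng([model.seed, sex_idx, d])
            dyad_id = f"{sex}{d:03d}"
            latency_min = float(rng.lognormal(lat_mu, lat_sigma))
            duration_min = float(rng.lognormal(res_mu, res_sigma))
            resolution_min = latency_min + duration_min

            fish_ids = [f"{dyad_id}a", f"{dyad_id}b"]
            counts = {
                fid: {
                    b: int(
                        _nbinom_counts(
                            rng,
                            model.rates[sex][b] * resolution_min,
                            model.dispersion,
                            1,
                        )[0]
                    )
                    for b in BEHAVIORS
                }
                for fid in fish_ids
            }

            # Winner: more aggressive acts at resolution; ties by coin flip.
            aggr = {
                fid: sum(counts[fid][b] for b in AGGRESSIVE_BEHAVIORS)
                for fid in fish_ids
            }
            if aggr[fish_ids[0]] > aggr[fish_ids[1]]:
                winner, loser = fish_ids
            elif aggr[fish_ids[0]] < aggr[fish_ids[1]]:
                loser, winner = fish_ids
            else:
                order = int(rng.integers(2))
                winner, loser = (fish_ids[order], fish_ids[1 - order])

            # Event times: acts occur between first attack and resolution.
            t0 = latency_min * 60.0
            t1 = resolution_min * 60.0
            dyad_events: list[tuple] = []
            for fid in fish_ids:
                for behavior in BEHAVIORS:
                    n = counts[fid][behavior]
                    if n == 0:
                        continue
                    times = rng.uniform(t0, t1, size=n)
                    dyad_events.extend(
                        (dyad_id, sex, fid, behavior, float(t)) for t in times
                    )
            # Anchor the earliest aggressive act exactly at the latency so
            # summaries recover it.
            aggr_idx = [
                i for i, row in enumerate(dyad_events) if row[3] in AGGRESSIVE_BEHAVIORS
            ]
            if aggr_idx:
                first = min(aggr_idx, key=lambda i: dyad_events[i][4])
                r = dyad_events[first]
                dyad_events[first] = (*r[:4], t0)
            dyad_events.sort(key=lambda row: row[4])
            event_rows.extend(dyad_events)

            totals = {
                b: counts[fish_ids[0]][b] + counts[fish_ids[1]][b] for b in BEHAVIORS
            }
            row: dict = {
                "dyad_id": dyad_id,
                "sex": sex,
                "latency_min": latency_min if aggr_idx else np.nan,
                "resolution_min": resolution_min,
                "winner_id": winner,
                "loser_id": loser,
            }
            for b in BEHAVIORS:
                row[f"total_{b}"] = totals[b]
                row[f"freq_{b}"] = totals[b] / resolution_min
            row["freq_aggressive"] = sum(
                row[f"freq_{b}"] for b in AGGRESSIVE_BEHAVIORS
            )
            row["freq_submissive"] = sum(
                row[f"freq_{b}"] for b in SUBMISSIVE_BEHAVIORS
            )
            summary_rows.append(row)

    events = pd.DataFrame(event_rows, columns=list(EVENT_COLUMNS))
    summaries = pd.DataFrame(summary_rows)
    return events, summaries


@dataclass(frozen=True)
class CorrelationBlock:
    """A region subset with a common target pairwise correlation."""

    regions: tuple[str, ...]
    r: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if len(self.regions) < 2:
            raise ValueError("a correlation block needs at least 2 regions")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"target correlation must be in [-1, 1], got {self.r}")


@dataclass(frozen=True)
class PlantedHub:
    """A hub region correlated with each of its spoke regions.

    Implemented as a one-factor structure: corr(hub, spoke) = strength and
    corr(spoke_i, spoke_j) = strength**2, which is positive semi-definite
    by construction for any |strength| <= 1.
    """

    region: str
    spokes: tuple[str, ...]
    strength: float = 0.8

    def __post_init__(self) -> None:
        object.__setattr__(self, "spokes", tuple(self.spokes))
        if self.region in self.spokes:
            raise ValueError("hub region cannot be its own spoke")
        if not self.spokes:
            raise ValueError("a planted hub needs at least one spoke")
        if not -1.0 <= self.strength <= 1.0:
            raise ValueError("hub strength must be in [-1, 1]")


StratumKey = tuple[str, str]  # (sex, condition)


def _as_stratum_map(value, default_keys) -> dict[StratumKey, tuple]:
    """Normalize a global sequence or a per-stratum mapping to a mapping."""
    if value is None:
        return {k: () for k in default_keys}
    if isinstance(value, Mapping):
        out = {k: () for k in default_keys}
        for k, v in value.items():
            out[tuple(k)] = tuple(v)
        return out
    return {k: tuple(value) for k in default_keys}


@dataclass(frozen=True)
class ActivationModel:
    """Generating model for pS6 activation count tables.

    Parameters
    ----------
    group_sizes
        Mapping ``(sex, condition) -> number of fish``.  Defaults to 8 fish
        in each of the 6 strata (group sizes of six to nine per condition
        are typical for this assay).
    baseline_mean
        Mean pS6-positive cell count per region (summed over the five
        scored sections).
    region_means
        Optional per-region mean overrides, globally or per stratum.
    dispersion
        Negative-binomial shape of the count marginals.
    blocks, hubs
        Planted correlation structure, either a sequence applied to every
        stratum or a mapping keyed by ``(sex, condition)``.
    seed
        Seeds all draws; strata use independent child streams.
    """

    group_sizes: Mapping[StratumKey, int] = field(
        default_factory=lambda: {(s, c): 8 for s in SEXES for c in CONDITIONS}
    )
    baseline_mean: float = 40.0
    region_means: Mapping | None = None
    dispersion: float = 8.0
    blocks: Sequence[CorrelationBlock] | Mapping | None = None
    hubs: Sequence[PlantedHub] | Mapping | None = None
    regions: tuple[str, ...] = REGIONS
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        if self.baseline_mean < 0:
            raise ValueError("baseline_mean must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        keys = list(self.group_sizes)
        object.__setattr__(self, "_blocks", _as_stratum_map(self.blocks, keys))
        object.__setattr__(self, "_hubs", _as_stratum_map(self.hubs, keys))
        for key in keys:
            if self.group_sizes[key] < 0:
                raise ValueError(f"negative group size for stratum {key}")
            self.correlation_matrix(key)  # validates PSD at construction

    def stratum_blocks(self, key: StratumKey) -> tuple[CorrelationBlock, ...]:
        return self._blocks[key]  # type: ignore[attr-defined]

    def stratum_hubs(self, key: StratumKey) -> tuple[PlantedHub, ...]:
        return self._hubs[key]  # type: ignore[attr-defined]

    def correlation_matrix(self, key: StratumKey) -> np.ndarray:
        """Target region-region correlation matrix for one stratum.

        Raises
        ------
        ValueError
            If the implied matrix is not positive semi-definite; the message
            names the offending block.
        """
        p = len(self.regions)
        idx = {r: i for i, r in enumerate(self.regions)}
        corr = np.eye(p)
        for block in self.stratum_blocks(key):
            unknown = [r for r in block.regions if r not in idx]
            if unknown:
                raise ValueError(f"block references unknown regions {unknown}")
            for a, b in itertools.combinations(block.regions, 2):
                corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = block.r
            sub = [idx[r] for r in block.regions]
            if np.linalg.eigvalsh(corr[np.ix_(sub, sub)]).min() < -1e-10:
                raise ValueError(
                    f"correlation block {block.regions} with r={block.r} is "
                    "not positive semi-definite (for an equicorrelated block "
                    "of size m, r must be >= -1/(m-1))"
                )
        for hub in self.stratum_hubs(key):
            members = (hub.region, *hub.spokes)
            unknown = [r for r in members if r not in idx]
            if unknown:
                raise ValueError(f"hub references unknown regions {unknown}")
            for spoke in hub.spokes:
                corr[idx[hub.region], idx[spoke]] = hub.strength
                corr[idx[spoke], idx[hub.region]] = hub.strength
            for a, b in itertools.combinations(hub.spokes, 2):
                corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = hub.strength**2
        lam_min = np.linalg.eigvalsh(corr).min()
        if lam_min < -1e-10:
            raise ValueError(
                f"combined planted structure for stratum {key} is not "
                f"positive semi-definite (min eigenvalue {lam_min:.3g}); "
                "overlapping blocks/hubs are likely incompatible"
            )
        return corr

    def stratum_means(self, key: StratumKey) -> np.ndarray:
        means = np.full(len(self.regions), float(self.baseline_mean))
        overrides = self.region_means
        if overrides is not None:
            if any(isinstance(k, tuple) for k in overrides):
                overrides = overrides.get(key, {})
            for region, m in overrides.items():
                means[self.regions.index(region)] = float(m)
        return means


def _copula_counts(
    rng: np.random.Generator,
    n: int,
    means: np.ndarray,
    corr: np.ndarray,
    k: float,
) -> np.ndarray:
    """Correlated negative-binomial counts via a Gaussian copula."""
    p = len(means)
    # Symmetric PSD square root; robust to exactly singular targets.
    lam, vec = np.linalg.eigh(corr)
    root = vec @ np.diag(np.sqrt(np.clip(lam, 0.0, None))) @ vec.T
    z = rng.standard_normal((n, p)) @ root.T
    u = stats.norm.cdf(z)
    # Clip away 0/1 so ppf stays finite.
    u = np.clip(u, 1e-12, 1 - 1e-12)
    counts = np.zeros((n, p), dtype=np.int64)
    for j in range(p):
        m = means[j]
        if m <= 0:
            continue
        counts[:, j] = stats.nbinom.ppf(u[:, j], k, k / (k + m)).astype(np.int64)
    return counts


def generate_activation(model: ActivationModel) -> pd.DataFrame:
    """Generate a pS6 activation table: one row per fish.

    Columns: ``fish_id, sex, condition`` followed by one count column per
    region.  Counts are non-negative integers; within each planted block the
    empirical pairwise correlation converges to the target as the group
    grows; regions outside any block are independent given their means.
    A stratum with group size 0 is simply absent from the table.
    """
    frames = []
    for si, (key, n) in enumerate(sorted(model.group_sizes.items())):
        if n == 0:
            continue
        sex, condition = key
        rng = np.random.default_rng([model.seed, si])
        corr = model.correlation_matrix(key)
        means = model.stratum_means(key)
        counts = _copula_counts(rng, n, means, corr, model.dispersion)
        frame = pd.DataFrame(counts, columns=list(model.regions))
        frame.insert(0, "condition", condition)
        frame.insert(0, "sex", sex)
        frame.insert(0, "fish_id", [f"{sex}_{condition}_{i:03d}" for i in range(n)])
        frames.append(frame)
    if not frames:
        columns = ["fish_id", "sex", "condition", *model.regions]
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True)
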