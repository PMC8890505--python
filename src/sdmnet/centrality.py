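"""Eigencentrality hub analysis of treatment networks.

Node importance is the leading (Perron) eigenvector of the network's
absolute-weight matrix, computed by deterministic power iteration, so
scores are non-negative even for signed networks.  The top-k regions per
treatment are the network's hubs; hub sets are intersected between the
sexes to separate shared from sex-specific hubs.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import TreatmentNetwork

__all__ = ["CentralityRanking", "eigencentrality", "hub_intersection"]


@dataclass(frozen=True)
class CentralityRanking:
    """Per-region eigencentrality scores with a top-k hub set."""

    sex: str
    condition: str
    scores: pd.Series  # indexed by region, unit Euclidean norm, >= 0
    ranking: tuple[str, ...]  # regions from most to least central
    k: int

    @property
    def top(self) -> tuple[str, ...]:
        return self.ranking[: self.k]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "region": self.ranking,
                "score": [self.scores[r] for r in self.ranking],
            }
        )
        out["rank"] = np.arange(1, len(out) + 1)
        out["is_hub"] = out["rank"] <= self.k
        return out


def _power_iteration(
    a: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000
) -> tuple[np.ndarray, float]:
    """Leading eigenpair of a symmetric non-negative matrix.

    Deterministic uniform start vector; converges to the Perron vector for
    a connected non-negative matrix.
    """
    n = a.shape[0]
    x = np.full(n, 1.0 / np.sqrt(n))
    lam = 0.0
    for _ in range(max_iter):
        y = a @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            return x, 0.0
        y /= norm
        if np.max(np.abs(y - x)) < tol:
            return y, float(norm)
        x, lam = y, float(norm)
    return x, lam


def eigencentrality(
    network: TreatmentNetwork,
    k: int = 8,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> CentralityRanking:
    """Eigencentrality ranking on absolute edge weights.

    Weights enter as absolute values so the leading eigenvector is
    non-negative (Perron).  If the nonzero-edge graph is disconnected only
    the component with the largest leading eigenvalue is scored; all other
    regions get 0 (logged via the graph structure, visible as zero
    scores).  The score vector is normalized to unit Euclidean norm;
    ranking ties are broken lexicographically by region name.
    """
    a = np.abs(network.weights)
    regions = network.regions
    if not (a > 0).any():
        raise ValueError("network has no nonzero edge")

    g = nx.from_numpy_array(a)
    best_scores = None
    best_lam = -np.inf
    for component in nx.connected_components(g):
        nodes = sorted(component)
        if len(nodes) == 1:
            continue
        sub = a[np.ix_(nodes, nodes)]
        vec, lam = _power_iteration(sub, tol=tol, max_iter=max_iter)
        if lam > best_lam:
            best_lam = lam
            full = np.zeros(len(regions))
            full[nodes] = np.abs(vec)
            best_scores = full
    assert best_scores is not None
    norm = np.linalg.norm(best_scores)
    scores = pd.Series(best_scores / norm, index=list(regions))
    ranking = tuple(sorted(regions, key=lambda r: (-scores[r], r)))
    return CentralityRanking(
        sex=network.sex,
        condition=network.condition,
        scores=scores,
        ranking=ranking,
        k=k,
    )


def hub_intersection(
    a: CentralityRanking, b: CentralityRanking
) -> tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]:
    """Shared and private hub sets of two rankings at the same k.

    Returns ``(shared, only_a, only_b)`` as sorted tuples, with
    ``len(shared) + len(only_a) == k``.
    """
    if a.k != b.k:
        raise ValueError(f"rankings use different k: {a.k} != {b.k}")
    set_a, set_b = set(a.top), set(b.top)
    return (
        tuple(sorted(set_a & set_b)),
        tuple(sorted(set_a - set_b)),
        tuple(sorted(set_b - set_a)),
    )
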