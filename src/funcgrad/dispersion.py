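"""Network-level summaries in gradient space.

Within-network dispersion measures how tightly a network's nodes cluster
around their centroid (sum of squared Euclidean distances by default);
between-network dispersion is the mean Euclidean distance from a network's
centroid to the centroids of the other networks. The pairwise 7 x 7
centroid-distance matrix decomposes the between-network measure into its
per-pair contributions.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .embedding import GradientEmbedding
from .networks import NETWORKS, validate_network

__all__ = [
    "network_centroid",
    "within_network_dispersion",
    "between_network_dispersion",
    "pairwise_network_dispersion",
    "network_mean_gradient",
    "dispersion_table",
]

AGGREGATORS = ("sum", "mean")


def _coords(emb, dims: int | None) -> np.ndarray:
    coords = emb.coords if isinstance(emb, GradientEmbedding) else np.asarray(emb, dtype=float)
    if dims is not None:
        if dims > coords.shape[1]:
            raise ValueError(f"dims={dims} exceeds the {coords.shape[1]} available gradients")
        coords = coords[:, :dims]
    return coords


def _members(labels: Sequence[str], network: str) -> np.ndarray:
    validate_network(network)
    idx = np.flatnonzero(np.asarray(labels, dtype=object) == network)
    if idx.size == 0:
        raise ValueError(f"network {network} has no member nodes")
    return idx


def network_centroid(emb, labels: Sequence[str], network: str, dims: int | None = 2) -> np.ndarray:
    """Arithmetic mean of member-node coordinates over the first ``dims`` gradients."""
    coords = _coords(emb, dims)
    return coords[_members(labels, network)].mean(axis=0)


def within_network_dispersion(
    emb,
    labels: Sequence[str],
    network: str,
    dims: int | None = 2,
    aggregator: str = "sum",
) -> float:
    """Dispersion of a network's nodes around their centroid.

    Default aggregator is the sum of squared Euclidean distances to the
    centroid (units: squared gradient units); ``aggregator="mean"``
    returns the mean of squares instead.
    """
    if aggregator not in AGGREGATORS:
        raise ValueError(f"aggregator must be one of {AGGREGATORS}")
    coords = _coords(emb, dims)
    member = coords[_members(labels, network)]
    sq = ((member - member.mean(axis=0)) ** 2).sum(axis=1)
    return float(sq.sum() if aggregator == "sum" else sq.mean())


def present_networks(labels: Sequence[str]) -> list[str]:
    """Networks with at least one member node, in canonical order."""
    seen = set(np.asarray(labels, dtype=object))
    return [name for name in NETWORKS if name in seen]


def pairwise_network_dispersion(emb, labels: Sequence[str], dims: int | None = 2) -> np.ndarray:
    """Matrix of Euclidean distances between network centroids.

    7 x 7 in canonical network order when all seven networks have members
    (the standard pipeline); a restricted mode over the present networks is
    supported for testing. Symmetric with zero diagonal.
    """
    names = present_networks(labels)
    if len(names) < 2:
        raise ValueError("need at least two non-empty networks")
    centroids = np.vstack(
        [network_centroid(emb, labels, name, dims) for name in names]
    )
    diff = centroids[:, None, :] - centroids[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def between_network_dispersion(
    emb, labels: Sequence[str], network: str, dims: int | None = 2
) -> float:
    """Mean Euclidean distance from this network's centroid to the
    centroids of all other (present) networks — six in the standard
    seven-network pipeline."""
    validate_network(network)
    names = present_networks(labels)
    if network not in names:
        raise ValueError(f"network {network} has no member nodes")
    pairwise = pairwise_network_dispersion(emb, labels, dims)
    i = names.index(network)
    others = [j for j in range(len(names)) if j != i]
    return float(pairwise[i, others].mean())


def network_mean_gradient(
    emb, labels: Sequence[str], network: str, gradient_index: int
) -> float:
    """Mean score of a network's member nodes on one gradient (1-based index)."""
    coords = _coords(emb, None)
    if not 1 <= gradient_index <= coords.shape[1]:
        raise ValueError(
            f"gradient_index must lie in [1, {coords.shape[1]}], got {gradient_index}"
        )
    return float(coords[_members(labels, network), gradient_index - 1].mean())


def dispersion_table(
    embeddings: Iterable[tuple[Mapping[str, str], "GradientEmbedding | np.ndarray"]],
    labels: Sequence[str],
    dims: int = 2,
    aggregator: str = "sum",
    n_gradient_means: int = 2,
) -> pd.DataFrame:
    """Long-format dispersion summary over scans.

    ``embeddings`` yields (scan labels, embedding) pairs where the labels
    mapping provides ``subject``, ``site``, ``condition`` and ``session``.
    One row per (scan, network, metric) with metrics ``within``,
    ``between``, ``dist:<OTHER>`` (pairwise centroid distances) and
    ``g<k>_mean`` (network-mean gradient scores).
    """
    rows = []
    for meta, emb in embeddings:
        base = {
            "subject": meta.get("subject"),
            "site": meta.get("site"),
            "condition": meta.get("condition"),
            "session": meta.get("session"),
            "dims": dims,
        }
        pairwise = pairwise_network_dispersion(emb, labels, dims)
        for i, name in enumerate(NETWORKS):
            within = within_network_dispersion(emb, labels, name, dims, aggregator)
            others = [j for j in range(len(NETWORKS)) if j != i]
            rows.append({**base, "network": name, "metric": "within", "value": within})
            rows.append(
                {
                    **base,
                    "network": name,
                    "metric": "between",
                    "value": float(pairwise[i, others].mean()),
                }
            )
            for j in others:
                rows.append(
                    {
                        **base,
                        "network": name,
                        "metric": f"dist:{NETWORKS[j]}",
                        "value": float(pairwise[i, j]),
                    }
                )
            for g in range(1, n_gradient_means + 1):
                rows.append(
                    {
                        **base,
                        "network": name,
                        "metric": f"g{g}_mean",
                        "value": network_mean_gradient(emb, labels, name, g),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["subject", "site", "condition", "session", "network", "metric", "dims", "value"],
    )
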