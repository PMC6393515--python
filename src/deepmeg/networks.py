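"""Anatomical network classification and topography clustering.

Selected components are labelled by the anatomy of the SEEG channels they
significantly correlate with: mesial (M) when all structures are
mesial-temporal, lateral (L) when all are lateral neocortical,
mesio-lateral (ML) when both appear, and extended limbic (eL) when any
extra-temporal limbic structure (orbitofrontal cortex, insula, putamen,
thalamus) participates — with the meL flag when an eL network is otherwise
restricted to mesial structures.

Redundancy between the four analysis combinations is quantified by
agglomerative clustering of the component topographies (distance
1 - |Pearson r|, average linkage) and the similarity index
SI = n_clusters / n_components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._utils import format_truncated

MESIAL_STRUCTURES = frozenset(
    {
        "hippocampus",
        "amygdala",
        "internal temporal pole",
        "entorhinal",
        "parahippocampal gyrus",
        "collateral sulcus",
        "fusiform gyrus",
    }
)
LATERAL_STRUCTURES = frozenset(
    {
        "external temporal pole",
        "occipito-temporal sulcus",
        "lateral temporal neocortex",
        "lateral frontal neocortex",
    }
)
EXTENDED_LIMBIC_STRUCTURES = frozenset(
    {"orbitofrontal", "insula", "putamen", "thalamus"}
)


@dataclass(frozen=True)
class NetworkLabel:
    component: int
    network_class: str  # "M" | "L" | "ML" | "eL"
    mel: bool  # extended-limbic network otherwise restricted to mesial regions
    structures: frozenset[str]


@dataclass
class ClusterReport:
    linkage_method: str
    cut_distance: float
    assignments: np.ndarray  # cluster id per component
    n_clusters: int
    n_components: int
    similarity_index: float
    similarity_index_display: str


def classify_network(structures: Iterable[str], component: int = -1) -> NetworkLabel:
    """Classify a component by its significantly correlated structure set.

    A pure function of the (unordered) label set; unknown or empty sets
    are rejected.
    """
    labels = frozenset(structures)
    if not labels:
        raise ValueError("cannot classify an empty structure set")
    known = MESIAL_STRUCTURES | LATERAL_STRUCTURES | EXTENDED_LIMBIC_STRUCTURES | {"other"}
    unknown = labels - known
    if unknown:
        raise ValueError(f"unknown structure labels: {sorted(unknown)}")
    core = labels - {"other"}
    if not core:
        raise ValueError("structure set contains only 'other' labels")
    if core & EXTENDED_LIMBIC_STRUCTURES:
        rest = core - EXTENDED_LIMBIC_STRUCTURES
        mel = rest <= MESIAL_STRUCTURES
        return NetworkLabel(component, "eL", mel, labels)
    has_mesial = bool(core & MESIAL_STRUCTURES)
    has_lateral = bool(core & LATERAL_STRUCTURES)
    if has_mesial and has_lateral:
        return NetworkLabel(component, "ML", False, labels)
    if has_mesial:
        return NetworkLabel(component, "M", False, labels)
    return NetworkLabel(component, "L", False, labels)


def similarity_index(n_clusters: int, n_components: int) -> float:
    """SI = n_clusters / n_components (1/n <= SI <= 1)."""
    if not (1 <= n_clusters <= n_components):
        raise ValueError("need 1 <= n_clusters <= n_components")
    return n_clusters / n_components


def cluster_topographies(
    topographies: np.ndarray,
    cut_distance: float = 0.2,
    method: str = "average",
) -> ClusterReport:
    """Agglomerative clustering of unit-norm topographies.

    Distance is 1 - |Pearson r| between topographies (sign flips are an
    ICA indeterminacy, so anticorrelated maps are identical), average
    linkage, tree cut at ``cut_distance``.
    """
    topo = np.atleast_2d(np.asarray(topographies, dtype=float))
    n = topo.shape[0]
    if n < 2:
        raise ValueError("need at least 2 components to cluster")
    centred = topo - topo.mean(axis=1, keepdims=True)
    sd = centred.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant topography cannot be clustered")
    zs = centred / sd
    corr = np.clip(zs @ zs.T / topo.shape[1], -1.0, 1.0)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = linkage(squareform(dist, checks=False), method=method)
    assignments = fcluster(link, t=cut_distance, criterion="distance")
    n_clusters = int(len(np.unique(assignments)))
    si = similarity_index(n_clusters, n)
    return ClusterReport(
        linkage_method=method,
        cut_distance=cut_distance,
        assignments=assignments,
        n_clusters=n_clusters,
        n_components=n,
        similarity_index=si,
        similarity_index_display=format_truncated(si, 2),
    )
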