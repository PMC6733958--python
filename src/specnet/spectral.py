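"""Spectral decomposition of correlation networks.

The key statistic is the spectral radius: the largest eigenvalue of the
symmetric weighted connection matrix C.  For non-negative C (absolute
weight mode) Perron-Frobenius theory applies: the spectral radius
dominates every eigenvalue in magnitude, has a non-negative eigenvector
(the Perron vector), is simple when the graph is irreducible, and never
increases when an edge is removed.

Per-node scores are spectral-radius-scaled Perron-vector components
(eigenvector centrality, scaled so the top node scores exactly the
spectral radius); their arithmetic mean summarizes the network.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .network import ABSOLUTE, CorrelationNetwork, NetworkError

_SYM_TOL = 1e-10


class SpectralError(ValueError):
    """Raised for matrices the spectral decomposition cannot accept."""


@dataclass
class SpectralSummary:
    """Eigen decomposition of one network's connection matrix."""

    edition_label: str
    group_label: str
    node_labels: tuple[str, ...]
    eigenvalues: np.ndarray          # sorted descending
    spectral_radius: float           # eigenvalues[0]
    principal_eigenvector: np.ndarray  # unit norm, non-negative orientation
    node_eigen_scores: np.ndarray
    mean_node_eigen_score: float
    weighted_degrees: np.ndarray     # row sums of C
    irreducible: bool

    @property
    def spectral_gap(self) -> float:
        """Gap between the two largest eigenvalues (simplicity margin)."""
        if len(self.eigenvalues) < 2:
            return float("inf")
        return float(self.eigenvalues[0] - self.eigenvalues[1])

    def to_dict(self) -> dict:
        return {
            "edition_label": self.edition_label,
            "group_label": self.group_label,
            "node_labels": list(self.node_labels),
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "spectral_radius": float(self.spectral_radius),
            "principal_eigenvector": [float(v) for v in self.principal_eigenvector],
            "node_eigen_scores": [float(v) for v in self.node_eigen_scores],
            "mean_node_eigen_score": float(self.mean_node_eigen_score),
            "weighted_degrees": [float(v) for v in self.weighted_degrees],
            "irreducible": bool(self.irreducible),
        }


def _check_matrix(weights: np.ndarray) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    if np.isnan(weights).any():
        raise SpectralError("connection matrix contains NaN")
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise SpectralError("connection matrix must be square")
    if not np.allclose(weights, weights.T, atol=_SYM_TOL, rtol=0):
        raise SpectralError("connection matrix must be symmetric")
    return weights


def _largest_eigenvalue(weights: np.ndarray) -> float:
    """Fast path used by permutation resampling: SR only, no summary."""
    return float(np.linalg.eigvalsh(weights)[-1])


def eigen_system(network: CorrelationNetwork) -> SpectralSummary:
    """Full symmetric eigen decomposition of the network's connection matrix.

    Eigenvalues are returned in descending order; the principal
    eigenvector has unit Euclidean norm and is oriented so its
    largest-magnitude entry is positive (for non-negative irreducible C
    this is the Perron vector).
    """
    weights = _check_matrix(network.weights)
    if network.weight_mode != ABSOLUTE and (weights < 0).any():
        warnings.warn(
            "signed-mode connection matrix has negative entries; "
            "Perron-Frobenius guarantees (non-negative principal vector, "
            "|eigenvalue| dominance) do not apply",
            UserWarning,
            stacklevel=2,
        )
    values, vectors = np.linalg.eigh(weights)
    order = np.argsort(values)[::-1]
    values = values[order]
    vectors = vectors[:, order]

    principal = vectors[:, 0].copy()
    pivot = int(np.argmax(np.abs(principal)))
    if principal[pivot] < 0:
        principal = -principal

    sr = float(values[0])
    peak = float(principal.max())
    if sr > 0 and peak > 0:
        scores = sr * principal / peak
    else:
        scores = np.zeros_like(principal)

    n = weights.shape[0]
    adjacency = (np.abs(weights) > 0).astype(int)
    n_components, _ = connected_components(adjacency, directed=False)
    irreducible = n_components == 1 and n >= 1

    return SpectralSummary(
        edition_label=network.edition_label,
        group_label=network.group_label,
        node_labels=network.node_labels,
        eigenvalues=values,
        spectral_radius=sr,
        principal_eigenvector=principal,
        node_eigen_scores=scores,
        mean_node_eigen_score=float(scores.mean()) if n else 0.0,
        weighted_degrees=weights.sum(axis=1),
        irreducible=irreducible,
    )


def spectral_radius(network: CorrelationNetwork) -> float:
    """Largest eigenvalue of the weighted connection matrix."""
    return eigen_system(network).spectral_radius


def remove_edge(
    network: CorrelationNetwork, node_a: str, node_b: str
) -> CorrelationNetwork:
    """Copy of the network with the (a, b) link weight zeroed symmetrically.

    Supports monotonicity checks: zeroing an edge never increases the
    spectral radius of a non-negative matrix.
    """
    i = network.index_of(node_a)
    j = network.index_of(node_b)
    if i == j:
        raise NetworkError("self-loops do not exist in a correlation network")
    out = network.copy()
    out.weights[i, j] = out.weights[j, i] = 0.0
    out.signed_weights[i, j] = out.signed_weights[j, i] = 0.0
    return out


def node_eigen_scores(summary: SpectralSummary) -> dict[str, float]:
    """Per-node eigen scores keyed by node label."""
    return {
        label: float(score)
        for label, score in zip(summary.node_labels, summary.node_eigen_scores)
    }


def rank_nodes(summary: SpectralSummary) -> list[tuple[str, float]]:
    """Nodes sorted by eigen score, descending; ties keep node-label order."""
    pairs = list(zip(summary.node_labels, summary.node_eigen_scores))
    return [(label, float(s)) for label, s in sorted(pairs, key=lambda p: -p[1])]


def node_table_frame(summary: SpectralSummary) -> pd.DataFrame:
    """Flat per-node table: eigen score, Perron component, weighted degree."""
    return pd.DataFrame(
        {
            "node": summary.node_labels,
            "eigen_score": summary.node_eigen_scores,
            "perron_component": summary.principal_eigenvector,
            "weighted_degree": summary.weighted_degrees,
        }
    )


def write_summary_json(summary: SpectralSummary, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(summary.to_dict(), indent=2, sort_keys=True))
    return path
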