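"""Weighted complete correlation networks from group variable matrices.

Variables are nodes; every unordered pair gets a link whose weight is the
(absolute, by default) Pearson correlation between the two variables
across the group's athletes.  Links are bidirectional, so the symmetric
connection matrix fully describes the graph and an n-node network counts
n(n-1) directed links.

Pairs involving a zero-variance variable have no defined correlation;
they are kept as weight-0 links (recorded in ``degenerate_pairs``) so
every network in a run shares the same node set and link topology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

ABSOLUTE = "absolute"
SIGNED = "signed"
WEIGHT_MODES = (ABSOLUTE, SIGNED)


class NetworkError(ValueError):
    """Raised for invalid network construction inputs."""


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Product-moment correlation of two equal-length vectors.

    Returns ``None`` (undefined, not an error) when either vector has
    zero variance.  Vectors shorter than 2 or of unequal length are
    errors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise NetworkError("inputs must be 1-D vectors")
    if x.shape != y.shape:
        raise NetworkError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 2:
        raise NetworkError("need at least 2 observations for a correlation")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def link_weight(r: float | None, mode: str = ABSOLUTE) -> float:
    """Map a correlation to a link weight (fraction of 1).

    Absolute mode takes |r|; signed mode keeps r.  An undefined
    correlation becomes a weight-0 link (the pair is tracked separately
    by :func:`build_network`).
    """
    if mode not in WEIGHT_MODES:
        raise NetworkError(f"unknown weight mode {mode!r}; choose from {WEIGHT_MODES}")
    if r is None:
        return 0.0
    if not -1.0 <= r <= 1.0:
        raise NetworkError(f"correlation out of range [-1, 1]: {r}")
    return abs(r) if mode == ABSOLUTE else float(r)


def weight_percent(weight: float) -> float:
    """Render a link weight as a percentage (0.56 -> 56.0).

    Rounded to 12 decimals so decimal weights render exactly.
    """
    return round(100.0 * weight, 12)


@dataclass
class CorrelationNetwork:
    """A complete weighted graph over node variables for one (edition, group)."""

    edition_label: str
    group_label: str
    node_labels: tuple[str, ...]
    weights: np.ndarray
    signed_weights: np.ndarray
    weight_mode: str = ABSOLUTE
    degenerate_pairs: frozenset[tuple[str, str]] = frozenset()

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def index_of(self, label: str) -> int:
        try:
            return self.node_labels.index(label)
        except ValueError:
            raise NetworkError(
                f"unknown node label {label!r}; nodes are {self.node_labels}"
            ) from None

    def edge_weight(self, a: str, b: str) -> float:
        return float(self.weights[self.index_of(a), self.index_of(b)])

    def copy(self) -> "CorrelationNetwork":
        return replace(
            self, weights=self.weights.copy(), signed_weights=self.signed_weights.copy()
        )


def correlation_matrix(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise Pearson correlations of the columns of ``matrix``.

    Returns ``(signed, defined)`` where ``signed[i, j]`` is the
    correlation (0 where undefined) and ``defined[i, j]`` marks pairs for
    which both columns have positive variance.  Diagonal is zero /
    undefined-excluded by the caller's convention of no self-loops.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_obs, n_var = matrix.shape
    ok = matrix.std(axis=0) > 0.0
    signed = np.zeros((n_var, n_var))
    defined = np.outer(ok, ok)
    np.fill_diagonal(defined, False)
    if ok.sum() >= 2:
        sub = np.clip(np.corrcoef(matrix[:, ok], rowvar=False), -1.0, 1.0)
        sub = (sub + sub.T) / 2.0  # force exact symmetry (BLAS LSB noise)
        idx = np.flatnonzero(ok)
        signed[np.ix_(idx, idx)] = sub
    np.fill_diagonal(signed, 0.0)
    return signed, defined


def build_network(
    matrix: np.ndarray,
    node_labels: Sequence[str],
    mode: str = ABSOLUTE,
    *,
    edition_label: str = "",
    group_label: str = "",
) -> CorrelationNetwork:
    """Build the complete correlation network of a group's variable matrix.

    Rows are athletes, columns are the node variables (>= 2 of each).
    All n(n-1)/2 unordered pairs are computed and placed symmetrically.
    """
    if mode not in WEIGHT_MODES:
        raise NetworkError(f"unknown weight mode {mode!r}; choose from {WEIGHT_MODES}")
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise NetworkError("variable matrix must be 2-D (athletes x variables)")
    n_obs, n_var = matrix.shape
    if n_obs < 2:
        raise NetworkError(f"need at least 2 athletes to correlate, got {n_obs}")
    if n_var < 2:
        raise NetworkError(f"need at least 2 variables, got {n_var}")
    node_labels = tuple(node_labels)
    if len(node_labels) != n_var:
        raise NetworkError(
            f"{len(node_labels)} node labels for {n_var} variable columns"
        )
    if np.isnan(matrix).any():
        raise NetworkError("variable matrix contains NaN")

    signed, defined = correlation_matrix(matrix)
    weights = np.abs(signed) if mode == ABSOLUTE else signed.copy()
    weights[~defined] = 0.0
    np.fill_diagonal(weights, 0.0)

    degenerate = frozenset(
        tuple(sorted((node_labels[i], node_labels[j])))
        for i in range(n_var)
        for j in range(i + 1, n_var)
        if not defined[i, j]
    )
    if degenerate:
        warnings.warn(
            f"{edition_label}/{group_label}: {len(degenerate)} link(s) have "
            "undefined correlations (zero-variance variable); kept with weight 0",
            UserWarning,
            stacklevel=2,
        )
    return CorrelationNetwork(
        edition_label=edition_label,
        group_label=group_label,
        node_labels=node_labels,
        weights=weights,
        signed_weights=signed,
        weight_mode=mode,
        degenerate_pairs=degenerate,
    )


def count_links(network: CorrelationNetwork, directed: bool = False) -> int:
    """Number of links in the complete network.

    Links are bidirectional, so the directed count is n(n-1) and the
    undirected count n(n-1)/2.  Degenerate (weight-0) pairs still count
    as links; see ``network.degenerate_pairs`` for how many.
    """
    n = network.n_nodes
    return n * (n - 1) if directed else n * (n - 1) // 2


def out_link_counts(network: CorrelationNetwork) -> dict[str, int]:
    """Directed out-link count per node (n-1 in a complete network)."""
    n = network.n_nodes
    return {label: n - 1 for label in network.node_labels}


def edge_list_frame(network: CorrelationNetwork) -> pd.DataFrame:
    """Edge list with columns node_a, node_b, weight, signed_r, percent."""
    rows = []
    for i in range(network.n_nodes):
        for j in range(i + 1, network.n_nodes):
            w = float(network.weights[i, j])
            rows.append(
                {
                    "node_a": network.node_labels[i],
                    "node_b": network.node_labels[j],
                    "weight": w,
                    "signed_r": float(network.signed_weights[i, j]),
                    "percent": weight_percent(w),
                }
            )
    return pd.DataFrame(rows)


def connection_matrix_frame(network: CorrelationNetwork) -> pd.DataFrame:
    """The connection matrix C with labeled rows and columns."""
    return pd.DataFrame(
        network.weights, index=network.node_labels, columns=network.node_labels
    )


def to_networkx(network: CorrelationNetwork) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(network.node_labels)
    for i in range(network.n_nodes):
        for j in range(i + 1, network.n_nodes):
            graph.add_edge(
                network.node_labels[i],
                network.node_labels[j],
                weight=float(network.weights[i, j]),
                signed_r=float(network.signed_weights[i, j]),
            )
    return graph


def write_graphml(network: CorrelationNetwork, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(to_networkx(network), path)
    return path
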