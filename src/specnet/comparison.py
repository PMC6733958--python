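"""Group-level statistical comparisons for correlation networks.

Two comparison units are supported, kept as separate operations:

* link weights — the 15 upper-triangle weights of a medalist network
  versus those of the matched non-medalist network (per edition);
* spectral radii — the per-edition spectral radius values pooled by
  group across editions.

Both use classical one-way fixed-effects ANOVA followed by Tukey's HSD.
Because the athlete groups are tiny (3 vs 5), a permutation test that
re-partitions athletes and recomputes networks and spectral radii per
shuffle is provided as a distribution-free supplement.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .cohort_io import NODE_VARIABLES, AthleteRecord
from .network import ABSOLUTE, CorrelationNetwork, correlation_matrix
from .spectral import SpectralSummary, _largest_eigenvalue

logger = logging.getLogger(__name__)

LINK_WEIGHTS = "link_weights"
SPECTRAL_RADIUS = "spectral_radius"


class ComparisonError(ValueError):
    """Raised for degenerate or mismatched comparison inputs."""


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    def to_dict(self) -> dict:
        return {"label": self.label, "n": self.n, "mean": self.mean, "sd": self.sd}


@dataclass(frozen=True)
class TukeyPair:
    pair: tuple[str, str]
    mean_diff: float
    q_statistic: float
    adjusted_p: float

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "mean_diff": self.mean_diff,
            "q_statistic": self.q_statistic,
            "adjusted_p": self.adjusted_p,
        }


@dataclass
class ComparisonResult:
    comparison_kind: str
    group_summaries: list[GroupSummary]
    anova_f: float
    anova_p: float
    tukey_pairs: list[TukeyPair]
    larger_group: str | None = None
    per_edition_ordering: dict[str, bool] = field(default_factory=dict)
    permutation_p: float | None = None
    n_permutations: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "comparison_kind": self.comparison_kind,
            "group_summaries": [g.to_dict() for g in self.group_summaries],
            "anova_f": self.anova_f,
            "anova_p": self.anova_p,
            "tukey_pairs": [t.to_dict() for t in self.tukey_pairs],
            "larger_group": self.larger_group,
            "per_edition_ordering": self.per_edition_ordering,
            "permutation_p": self.permutation_p,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def _validate_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ComparisonError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ComparisonError(f"group {i} has n={g.size}; need n >= 2")
    total = sum(g.size for g in arrays)
    if total <= len(arrays):
        raise ComparisonError("total observations must exceed the number of groups")
    return arrays


def _sums_of_squares(arrays: list[np.ndarray]) -> tuple[float, float, int, int]:
    grand = np.concatenate(arrays).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    k = len(arrays)
    n_total = sum(g.size for g in arrays)
    return float(ss_between), float(ss_within), k - 1, n_total - k


def oneway_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA: (F, p).

    ``F = MS_between / MS_within`` on (k-1, N-k) degrees of freedom.
    All-zero within-group variance is degenerate and raises.
    """
    arrays = _validate_groups(groups)
    ss_b, ss_w, df_b, df_w = _sums_of_squares(arrays)
    if ss_w == 0.0:
        raise ComparisonError(
            "within-group variance is zero in every group; F is undefined"
        )
    f_stat = (ss_b / df_b) / (ss_w / df_w)
    p = float(stats.f.sf(f_stat, df_b, df_w))
    return float(f_stat), p


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[TukeyPair]:
    """Tukey's HSD pairwise table after one-way ANOVA.

    The studentized-range statistic for a pair (i, j) is
    ``q = |mean_i - mean_j| / sqrt(MS_within / 2 * (1/n_i + 1/n_j))``
    (Tukey-Kramer for unbalanced groups); adjusted p-values come from the
    studentized range distribution with k groups and N-k df.
    """
    arrays = _validate_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise ComparisonError("one label per group required")
    _, ss_w, _, df_w = _sums_of_squares(arrays)
    if ss_w == 0.0:
        raise ComparisonError(
            "within-group variance is zero in every group; q is undefined"
        )
    ms_w = ss_w / df_w
    k = len(arrays)
    pairs = []
    for i, j in itertools.combinations(range(k), 2):
        gi, gj = arrays[i], arrays[j]
        diff = float(gi.mean() - gj.mean())
        se = math.sqrt(ms_w / 2.0 * (1.0 / gi.size + 1.0 / gj.size))
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_w))
        pairs.append(
            TukeyPair(
                pair=(str(labels[i]), str(labels[j])),
                mean_diff=diff,
                q_statistic=float(q),
                adjusted_p=min(1.0, p),
            )
        )
    return pairs


def _upper_triangle_weights(network: CorrelationNetwork) -> np.ndarray:
    iu = np.triu_indices(network.n_nodes, k=1)
    return network.weights[iu]


def _summaries(labels: Sequence[str], arrays: Sequence[np.ndarray]) -> list[GroupSummary]:
    return [
        GroupSummary(label=str(l), n=int(g.size), mean=float(g.mean()),
                     sd=float(g.std(ddof=1)) if g.size > 1 else 0.0)
        for l, g in zip(labels, arrays)
    ]


def compare_link_weights(
    net_medal: CorrelationNetwork, net_nonmedal: CorrelationNetwork
) -> ComparisonResult:
    """ANOVA + Tukey over the two networks' upper-triangle link weights.

    Perfectly separated constant weights (zero within-group variance but
    different means) are reported as F=inf, p=0 rather than an error;
    fully identical constant networks give F=0, p=1.
    """
    if net_medal.node_labels != net_nonmedal.node_labels:
        raise ComparisonError(
            f"node sets differ: {net_medal.node_labels} vs {net_nonmedal.node_labels}"
        )
    if net_medal.weight_mode != net_nonmedal.weight_mode:
        raise ComparisonError("networks were built in different weight modes")
    w_a = _upper_triangle_weights(net_medal)
    w_b = _upper_triangle_weights(net_nonmedal)
    labels = [net_medal.group_label or "a", net_nonmedal.group_label or "b"]
    summaries = _summaries(labels, [w_a, w_b])
    try:
        f_stat, p = oneway_anova([w_a, w_b])
        pairs = tukey_hsd([w_a, w_b], labels)
    except ComparisonError:
        if np.isclose(w_a.mean(), w_b.mean()):
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
        pairs = [
            TukeyPair(
                pair=(labels[0], labels[1]),
                mean_diff=float(w_a.mean() - w_b.mean()),
                q_statistic=float("inf") if p == 0.0 else 0.0,
                adjusted_p=p,
            )
        ]
    larger = labels[0] if w_a.mean() > w_b.mean() else (
        labels[1] if w_b.mean() > w_a.mean() else None
    )
    return ComparisonResult(
        comparison_kind=LINK_WEIGHTS,
        group_summaries=summaries,
        anova_f=f_stat,
        anova_p=p,
        tukey_pairs=pairs,
        larger_group=larger,
    )


def compare_spectral_radii(summaries: Sequence[SpectralSummary]) -> ComparisonResult:
    """Compare spectral radii pooled by group label across editions.

    Accepts any objects exposing ``edition_label``, ``group_label`` and
    ``spectral_radius``.  Also reports, per edition present in both
    groups, whether the medalist-side spectral radius exceeds the other.
    """
    by_group: dict[str, list[float]] = {}
    by_edition: dict[str, dict[str, float]] = {}
    order: list[str] = []
    for s in summaries:
        if s.group_label not in order:
            order.append(s.group_label)
        by_group.setdefault(s.group_label, []).append(float(s.spectral_radius))
        by_edition.setdefault(s.edition_label, {})[s.group_label] = float(
            s.spectral_radius
        )
    if len(order) < 2:
        raise ComparisonError("need spectral radii from at least 2 group labels")
    for label, values in by_group.items():
        if len(values) < 2:
            raise ComparisonError(
                f"group {label!r} has {len(values)} spectral radius value(s); need >= 2"
            )
    arrays = [np.asarray(by_group[label]) for label in order]
    group_summaries = _summaries(order, arrays)
    ss_b = _sums_of_squares(arrays)[0]
    ss_w = _sums_of_squares(arrays)[1]
    if ss_w == 0.0 and ss_b == 0.0:
        f_stat, p = 0.0, 1.0
        pairs = [
            TukeyPair(pair=(order[0], order[1]), mean_diff=0.0, q_statistic=0.0,
                      adjusted_p=1.0)
        ]
    else:
        f_stat, p = oneway_anova(arrays)
        pairs = tukey_hsd(arrays, order)

    ordering = {
        edition: values[order[0]] > values[order[1]]
        for edition, values in by_edition.items()
        if order[0] in values and order[1] in values
    }
    means = [g.mean for g in group_summaries]
    larger = None
    if means[0] != means[1]:
        larger = order[0] if means[0] > means[1] else order[1]
    return ComparisonResult(
        comparison_kind=SPECTRAL_RADIUS,
        group_summaries=group_summaries,
        anova_f=f_stat,
        anova_p=p,
        tukey_pairs=pairs,
        larger_group=larger,
        per_edition_ordering=ordering,
    )


def _records_matrix(
    records: Sequence[AthleteRecord], variables: Sequence[str]
) -> np.ndarray:
    return np.array(
        [[r.variable(v) for v in variables] for r in records], dtype=float
    )


def _abs_corr_sr(matrix: np.ndarray) -> tuple[float, bool]:
    """Spectral radius of the absolute-correlation network of ``matrix``.

    Returns (SR, any_defined): ``any_defined`` is False when every pair
    is degenerate, i.e. the statistic carries no information.
    """
    signed, defined = correlation_matrix(matrix)
    weights = np.abs(signed)
    weights[~defined] = 0.0
    return _largest_eigenvalue(weights), bool(defined.any())


def permutation_group_test(
    records_a: Sequence[AthleteRecord],
    records_b: Sequence[AthleteRecord],
    statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
    n_permutations: int = 999,
    seed: int = 0,
    variables: Sequence[str] = NODE_VARIABLES,
) -> tuple[float, float]:
    """Two-sided permutation test of a between-group network statistic.

    Athletes are re-partitioned into groups of the original sizes; the
    statistic (default: difference of the two groups' spectral radii,
    networks rebuilt per shuffle in absolute mode) is recomputed each
    time.  Returns ``(p, observed)`` with
    ``p = (1 + #{|stat_perm| >= |stat_obs|}) / (n_permutations + 1)``.
    """
    if n_permutations < 99:
        raise ComparisonError("n_permutations must be at least 99")
    n_a, n_b = len(records_a), len(records_b)
    if n_a + n_b < 5:
        raise ComparisonError("need at least 5 pooled athletes")
    if n_a < 2 or n_b < 2:
        raise ComparisonError("each group needs at least 2 athletes")

    if statistic is None:
        def statistic(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
            sr_a, ok_a = _abs_corr_sr(mat_a)
            sr_b, ok_b = _abs_corr_sr(mat_b)
            if not (ok_a and ok_b):
                raise ComparisonError("all correlations degenerate in a group")
            return sr_a - sr_b

    pooled = _records_matrix(list(records_a) + list(records_b), variables)
    observed = statistic(pooled[:n_a], pooled[n_a:])

    rng = np.random.default_rng(seed)
    extreme = 0
    done = 0
    attempts = 0
    max_attempts = 20 * n_permutations
    while done < n_permutations:
        attempts += 1
        if attempts > max_attempts:
            raise ComparisonError(
                "too many degenerate shuffles; statistic undefined on most partitions"
            )
        perm = rng.permutation(n_a + n_b)
        try:
            value = statistic(pooled[perm[:n_a]], pooled[perm[n_a:]])
        except ComparisonError:
            logger.warning("degenerate shuffle redrawn (attempt %d)", attempts)
            continue
        if abs(value) >= abs(observed) - 1e-12:
            extreme += 1
        done += 1
    p = (1 + extreme) / (n_permutations + 1)
    return float(p), float(observed)
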