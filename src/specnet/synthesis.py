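"""Synthetic finalist cohorts with a tunable latent-factor correlation structure.

Each athlete draws one shared standard-normal factor ``F``; variable ``v``
is generated as ``mu_v + sigma_v * (lambda_v * F + sqrt(1 - lambda_v^2) * eps)``
with independent standard-normal noise ``eps``.  The common loading
``lambda`` is the single knob controlling how strongly the variables
co-vary, so group-level correlation strength (and hence the spectral
radius of the resulting correlation network) rises monotonically with it.

BMI is never sampled: it is recomputed from weight and height, which
builds in the realistic weight-height-BMI dependence the analysis must
tolerate.  Medal counts are rounded to non-negative integers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort_io import MEDALIST, NON_MEDALIST, AthleteRecord, CohortError

#: Variables drawn from the latent-factor model, in generation order.
GENERATED_VARIABLES: tuple[str, ...] = (
    "age",
    "weight",
    "height",
    "olympic_medals",
    "reaction_time",
    "race_time",
)

DEFAULT_MEDALIST_LOADING = 0.85
DEFAULT_NON_MEDALIST_LOADING = 0.45

_DISTANCE_M = 50.0
_EPS_POSITIVE = 1e-6


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, kg/m^2, from weight in kg and height in cm."""
    if weight <= 0 or height <= 0:
        raise ValueError(
            f"weight and height must be positive, got weight={weight}, height={height}"
        )
    return weight / (height / 100.0) ** 2


@dataclass(frozen=True)
class EditionParams:
    """Marginal means/SDs and factor loadings for one (edition, group).

    ``factor_loadings`` maps each generated variable to a loading in
    [0, 1] on the shared latent factor; a common scalar can be supplied
    via :func:`default_edition_params` or :meth:`with_loading`.
    """

    edition_label: str
    group_label: str
    n_athletes: int
    means: dict[str, float]
    sds: dict[str, float]
    factor_loadings: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group_label not in (MEDALIST, NON_MEDALIST):
            raise ValueError(f"unknown group_label {self.group_label!r}")
        if self.n_athletes < 0:
            raise ValueError(f"n_athletes must be non-negative, got {self.n_athletes}")
        missing = set(GENERATED_VARIABLES) - set(self.means)
        if missing:
            raise ValueError(f"means missing variables: {sorted(missing)}")
        for v in GENERATED_VARIABLES:
            sd = self.sds.get(v)
            if sd is None:
                raise ValueError(f"sds missing variable {v!r}")
            if sd < 0:
                raise ValueError(f"sd for {v!r} must be non-negative, got {sd}")
        for v in ("weight", "height"):
            if self.means[v] <= 0:
                raise ValueError(f"mean {v} must be strictly positive")
        for v, lam in self.factor_loadings.items():
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"factor loading for {v!r} must be in [0, 1], got {lam}")

    @property
    def degenerate_variables(self) -> frozenset[str]:
        """Variables whose SD is zero (constant within the group)."""
        return frozenset(v for v in GENERATED_VARIABLES if self.sds[v] == 0.0)

    def loading(self, variable: str) -> float:
        return self.factor_loadings.get(variable, 0.0)

    def with_loading(self, loading: float) -> "EditionParams":
        """Copy of these params with a common loading on every variable."""
        return replace(
            self, factor_loadings={v: loading for v in GENERATED_VARIABLES}
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration: per-edition params plus the master seed.

    A fixed config (including seed) yields bit-identical cohorts.
    """

    editions: tuple[tuple[EditionParams, EditionParams], ...]
    seed: int = 42
    medalist_loading: float = DEFAULT_MEDALIST_LOADING
    non_medalist_loading: float = DEFAULT_NON_MEDALIST_LOADING

    def __post_init__(self) -> None:
        for lam in (self.medalist_loading, self.non_medalist_loading):
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"loadings must be in [0, 1], got {lam}")
        for medal, rest in self.editions:
            if medal.group_label != MEDALIST or rest.group_label != NON_MEDALIST:
                raise ValueError("each edition needs (medalist, non_medalist) params")


# Per-edition marginals: (mean, sd) for each generated variable, split by
# group.  Medalist groups have n=3, non-medalist n=5.
_EDITION_TABLE: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "Sydney 2000": {
        MEDALIST: {
            "age": (22.000, 2.000), "weight": (86.333, 8.444),
            "height": (194.000, 2.667), "olympic_medals": (7.000, 2.000),
            "reaction_time": (0.743, 0.051), "race_time": (21.997, 0.022),
        },
        NON_MEDALIST: {
            "age": (26.200, 2.240), "weight": (88.200, 2.640),
            "height": (196.800, 3.520), "olympic_medals": (1.800, 2.880),
            "reaction_time": (0.824, 0.033), "race_time": (22.298, 0.130),
        },
    },
    "Athens 2004": {
        MEDALIST: {
            "age": (24.667, 2.889), "weight": (89.667, 6.222),
            "height": (195.000, 3.333), "olympic_medals": (4.667, 3.556),
            "reaction_time": (0.673, 0.036), "race_time": (21.963, 0.038),
        },
        NON_MEDALIST: {
            "age": (27.400, 2.160), "weight": (88.400, 3.840),
            "height": (192.000, 4.000), "olympic_medals": (1.600, 2.560),
            "reaction_time": (0.704, 0.053), "race_time": (22.200, 0.092),
        },
    },
    "Beijing 2008": {
        MEDALIST: {
            "age": (22.667, 1.556), "weight": (86.000, 4.000),
            "height": (197.667, 2.889), "olympic_medals": (3.667, 0.444),
            "reaction_time": (0.720, 0.027), "race_time": (21.413, 0.076),
        },
        NON_MEDALIST: {
            "age": (25.600, 2.480), "weight": (84.600, 2.880),
            "height": (190.600, 1.920), "olympic_medals": (1.800, 1.040),
            "reaction_time": (0.686, 0.042), "race_time": (21.660, 0.028),
        },
    },
    "London 2012": {
        MEDALIST: {
            "age": (24.667, 2.444), "weight": (91.333, 7.556),
            "height": (196.333, 1.778), "olympic_medals": (2.667, 1.111),
            "reaction_time": (0.637, 0.016), "race_time": (21.490, 0.100),
        },
        NON_MEDALIST: {
            "age": (28.200, 2.960), "weight": (78.600, 2.720),
            "height": (190.600, 2.320), "olympic_medals": (1.800, 1.040),
            "reaction_time": (0.690, 0.040), "race_time": (21.798, 0.082),
        },
    },
    "Rio 2016": {
        MEDALIST: {
            "age": (29.000, 4.000), "weight": (92.667, 10.444),
            "height": (196.000, 3.333), "olympic_medals": (4.333, 2.444),
            "reaction_time": (0.670, 0.027), "race_time": (21.433, 0.038),
        },
        NON_MEDALIST: {
            "age": (23.800, 1.840), "weight": (86.200, 3.440),
            "height": (190.600, 2.320), "olympic_medals": (0.000, 0.000),
            "reaction_time": (0.648, 0.046), "race_time": (21.816, 0.106),
        },
    },
}

EDITION_LABELS: tuple[str, ...] = tuple(_EDITION_TABLE)

_GROUP_SIZES = {MEDALIST: 3, NON_MEDALIST: 5}


def default_edition_params(
    medalist_loading: float = DEFAULT_MEDALIST_LOADING,
    non_medalist_loading: float = DEFAULT_NON_MEDALIST_LOADING,
) -> list[EditionParams]:
    """The 10 default parameter sets: 5 editions x {medalist, non-medalist}.

    Means and SDs follow the reference per-edition group marginals;
    medalist groups have 3 athletes, non-medalist groups 5.
    """
    out: list[EditionParams] = []
    for edition, groups in _EDITION_TABLE.items():
        for group_label, marginals in groups.items():
            lam = medalist_loading if group_label == MEDALIST else non_medalist_loading
            out.append(
                EditionParams(
                    edition_label=edition,
                    group_label=group_label,
                    n_athletes=_GROUP_SIZES[group_label],
                    means={v: mu for v, (mu, _) in marginals.items()},
                    sds={v: sd for v, (_, sd) in marginals.items()},
                    factor_loadings={v: lam for v in marginals},
                )
            )
    return out


def default_config(
    seed: int = 42,
    medalist_loading: float = DEFAULT_MEDALIST_LOADING,
    non_medalist_loading: float = DEFAULT_NON_MEDALIST_LOADING,
) -> SyntheticConfig:
    """Default 5-edition synthetic configuration."""
    params = default_edition_params(medalist_loading, non_medalist_loading)
    pairs = tuple(
        (params[i], params[i + 1]) for i in range(0, len(params), 2)
    )
    return SyntheticConfig(
        editions=pairs,
        seed=seed,
        medalist_loading=medalist_loading,
        non_medalist_loading=non_medalist_loading,
    )


def generate_cohort(
    params: EditionParams,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    loading_overrides: dict[str, float] | None = None,
    rank_start: int = 1,
) -> list[AthleteRecord]:
    """Draw ``params.n_athletes`` records from the latent-factor model.

    Exactly one of ``seed`` / ``rng`` must drive the randomness; passing a
    generator lets callers chain several groups off one seed stream.
    Ranks are assigned ``rank_start .. rank_start + n - 1`` in draw order
    (the caller decides the group's rank window).
    """
    if rng is None:
        if seed is None:
            raise ValueError("either seed or rng is required")
        rng = np.random.default_rng(seed)
    loadings = {v: params.loading(v) for v in GENERATED_VARIABLES}
    if loading_overrides:
        for v, lam in loading_overrides.items():
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"loading override for {v!r} outside [0, 1]: {lam}")
            loadings[v] = lam

    degenerate = params.degenerate_variables
    if degenerate:
        warnings.warn(
            f"{params.edition_label}/{params.group_label}: zero-SD variable(s) "
            f"{sorted(degenerate)} generated as constants (no correlation signal)",
            UserWarning,
            stacklevel=2,
        )

    n = params.n_athletes
    shared = rng.standard_normal(n)
    columns: dict[str, np.ndarray] = {}
    for v in GENERATED_VARIABLES:
        lam = loadings[v]
        noise = rng.standard_normal(n)
        z = lam * shared + math.sqrt(1.0 - lam * lam) * noise
        columns[v] = params.means[v] + params.sds[v] * z

    columns["olympic_medals"] = np.clip(np.round(columns["olympic_medals"]), 0, None)
    for v in ("weight", "height", "reaction_time", "race_time"):
        if np.any(columns[v] <= 0):
            warnings.warn(
                f"{params.edition_label}/{params.group_label}: sampled non-positive "
                f"{v}; clipped to {_EPS_POSITIVE}",
                UserWarning,
                stacklevel=2,
            )
            columns[v] = np.clip(columns[v], _EPS_POSITIVE, None)

    records = []
    for i in range(n):
        weight = float(columns["weight"][i])
        height = float(columns["height"][i])
        race_time = float(columns["race_time"][i])
        records.append(
            AthleteRecord(
                edition_label=params.edition_label,
                finish_rank=rank_start + i,
                age=float(columns["age"][i]),
                weight=weight,
                height=height,
                bmi=compute_bmi(weight, height),
                olympic_medals=int(columns["olympic_medals"][i]),
                reaction_time=float(columns["reaction_time"][i]),
                race_time=race_time,
                velocity=_DISTANCE_M / race_time,
                degenerate_flags=degenerate,
            )
        )
    return records


def generate_editions(config: SyntheticConfig) -> list[AthleteRecord]:
    """Generate the full multi-edition cohort: 8 finalists per edition.

    Medalist params fill ranks 1-3, non-medalist params ranks 4-8.  A
    single seeded stream drives all draws, so the whole cohort is a pure
    function of the config.
    """
    rng = np.random.default_rng(config.seed)
    records: list[AthleteRecord] = []
    for medal_params, rest_params in config.editions:
        records.extend(generate_cohort(medal_params, rng=rng, rank_start=1))
        records.extend(
            generate_cohort(rest_params, rng=rng, rank_start=medal_params.n_athletes + 1)
        )
    return records
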