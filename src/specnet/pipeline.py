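"""End-to-end orchestration: ingest or synthesize -> split -> networks ->
spectral summaries -> group comparisons -> report files.

A run is a pure function of its config (seed included); writing the same
report twice produces byte-identical JSON.  Any stage failure aborts with
a stage-tagged error and removes partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort_io, comparison, network, spectral, synthesis
from .cohort_io import MEDALIST, NON_MEDALIST, AthleteRecord, GroupTable
from .comparison import ComparisonResult
from .network import ABSOLUTE, CorrelationNetwork
from .spectral import SpectralSummary
from .synthesis import SyntheticConfig

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; the message is prefixed with the stage name."""


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    input_csv: str | None = None
    seed: int = 42
    weight_mode: str = ABSOLUTE
    medalist_loading: float = synthesis.DEFAULT_MEDALIST_LOADING
    non_medalist_loading: float = synthesis.DEFAULT_NON_MEDALIST_LOADING
    n_editions: int = 5
    run_permutation: bool = True
    n_permutations: int = 999

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def synthetic_config(self) -> SyntheticConfig:
        cfg = synthesis.default_config(
            seed=self.seed,
            medalist_loading=self.medalist_loading,
            non_medalist_loading=self.non_medalist_loading,
        )
        if not 1 <= self.n_editions <= len(cfg.editions):
            raise ValueError(
                f"n_editions must be in [1, {len(cfg.editions)}], got {self.n_editions}"
            )
        return dataclasses.replace(cfg, editions=cfg.editions[: self.n_editions])


@dataclass
class EditionResult:
    edition_label: str
    groups: dict[str, GroupTable]
    networks: dict[str, CorrelationNetwork]
    summaries: dict[str, SpectralSummary]
    link_weight_comparison: ComparisonResult
    permutation_p: float | None = None
    permutation_observed: float | None = None


@dataclass
class PipelineReport:
    config_echo: dict
    records: list[AthleteRecord]
    editions: list[EditionResult]
    sr_comparison: ComparisonResult | None
    warnings: list[str] = field(default_factory=list)

    @property
    def network_count(self) -> int:
        return sum(len(e.networks) for e in self.editions)

    @property
    def node_count_total(self) -> int:
        return sum(
            net.n_nodes for e in self.editions for net in e.networks.values()
        )

    @property
    def directed_link_count_total(self) -> int:
        return sum(
            network.count_links(net, directed=True)
            for e in self.editions
            for net in e.networks.values()
        )

    @property
    def sr_table(self) -> list[tuple[str, str, float]]:
        return [
            (e.edition_label, group, float(e.summaries[group].spectral_radius))
            for e in self.editions
            for group in (MEDALIST, NON_MEDALIST)
            if group in e.summaries
        ]

    def to_dict(self) -> dict:
        return {
            "config": self.config_echo,
            "network_count": self.network_count,
            "node_count_total": self.node_count_total,
            "directed_link_count_total": self.directed_link_count_total,
            "n_records": len(self.records),
            "sr_table": [
                {"edition": e, "group": g, "spectral_radius": sr}
                for e, g, sr in self.sr_table
            ],
            "editions": [
                {
                    "edition_label": e.edition_label,
                    "summaries": {
                        g: s.to_dict() for g, s in e.summaries.items()
                    },
                    "link_weight_comparison": e.link_weight_comparison.to_dict(),
                    "permutation_p": e.permutation_p,
                    "permutation_observed": e.permutation_observed,
                    "degenerate_pairs": {
                        g: sorted(map(list, net.degenerate_pairs))
                        for g, net in e.networks.items()
                    },
                }
                for e in self.editions
            ],
            "sr_comparison": (
                self.sr_comparison.to_dict() if self.sr_comparison else None
            ),
            "warnings": self.warnings,
        }


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapper
    return decorate


@_stage("ingest")
def _ingest(config: PipelineConfig) -> list[AthleteRecord]:
    if config.input_csv is not None:
        logger.info("reading cohort from %s", config.input_csv)
        return cohort_io.read_cohort_csv(config.input_csv)
    logger.info(
        "synthesizing %d edition(s), seed=%d", config.n_editions, config.seed
    )
    return synthesis.generate_editions(config.synthetic_config())


@_stage("split")
def _split(records: list[AthleteRecord]) -> dict[str, tuple[GroupTable, GroupTable]]:
    by_edition = cohort_io.group_by_edition(records)
    return {
        label: cohort_io.split_by_medal(eds) for label, eds in by_edition.items()
    }


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full analysis; deterministic given the config."""
    captured: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        records = _ingest(config)
        split = _split(records)

        editions: list[EditionResult] = []
        all_summaries: list[SpectralSummary] = []
        for label, (medal_table, rest_table) in split.items():
            logger.info("building networks for %s", label)
            nets: dict[str, CorrelationNetwork] = {}
            sums: dict[str, SpectralSummary] = {}
            for table in (medal_table, rest_table):
                matrix = _stage("select")(cohort_io.select_node_variables)(table)
                net = _stage("network")(network.build_network)(
                    matrix,
                    table.variables,
                    config.weight_mode,
                    edition_label=label,
                    group_label=table.group_label,
                )
                nets[table.group_label] = net
                sums[table.group_label] = _stage("spectral")(spectral.eigen_system)(net)
            all_summaries.extend(sums.values())

            link_cmp = _stage("compare")(comparison.compare_link_weights)(
                nets[MEDALIST], nets[NON_MEDALIST]
            )
            perm_p = perm_obs = None
            if config.run_permutation:
                perm_p, perm_obs = _stage("compare")(comparison.permutation_group_test)(
                    medal_table.records,
                    rest_table.records,
                    n_permutations=config.n_permutations,
                    seed=config.seed,
                )
            editions.append(
                EditionResult(
                    edition_label=label,
                    groups={MEDALIST: medal_table, NON_MEDALIST: rest_table},
                    networks=nets,
                    summaries=sums,
                    link_weight_comparison=link_cmp,
                    permutation_p=perm_p,
                    permutation_observed=perm_obs,
                )
            )

        sr_cmp = None
        if len(editions) >= 2:
            sr_cmp = _stage("compare")(comparison.compare_spectral_radii)(all_summaries)

    for w in caught:
        captured.append(str(w.message))
        logger.warning("%s", w.message)

    return PipelineReport(
        config_echo=config.to_dict(),
        records=records,
        editions=editions,
        sr_comparison=sr_cmp,
        warnings=captured,
    )


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in text.lower()).strip("_")


def write_report(report: PipelineReport, out_dir: str | Path) -> list[Path]:
    """Write all report artifacts; returns the manifest of created paths.

    On any error the partially written files are removed.
    """
    if not report.editions:
        raise ValueError("report is empty: no editions were analyzed")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []

    def emit(path: Path) -> Path:
        manifest.append(path)
        return path

    try:
        emit(out_dir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True)
        )
        sr_frame = pd.DataFrame(
            report.sr_table, columns=["edition", "group", "spectral_radius"]
        )
        sr_frame.to_csv(emit(out_dir / "sr_table.csv"), index=False)

        comparisons = {
            "per_edition_link_weights": {
                e.edition_label: e.link_weight_comparison.to_dict()
                for e in report.editions
            },
            "spectral_radius": (
                report.sr_comparison.to_dict() if report.sr_comparison else None
            ),
            "permutation": {
                e.edition_label: {
                    "p": e.permutation_p,
                    "observed_sr_difference": e.permutation_observed,
                }
                for e in report.editions
            },
        }
        emit(out_dir / "comparisons.json").write_text(
            json.dumps(comparisons, indent=2, sort_keys=True)
        )

        for e in report.editions:
            for group, net in e.networks.items():
                tag = f"{_slug(e.edition_label)}_{group}"
                network.edge_list_frame(net).to_csv(
                    emit(out_dir / f"edges_{tag}.csv"), index=False
                )
                network.write_graphml(net, emit(out_dir / f"network_{tag}.graphml"))
                network.connection_matrix_frame(net).to_csv(
                    emit(out_dir / f"matrix_{tag}.csv")
                )
                spectral.node_table_frame(e.summaries[group]).to_csv(
                    emit(out_dir / f"node_scores_{tag}.csv"), index=False
                )

        log_lines = [
            f"networks={report.network_count}",
            f"nodes_total={report.node_count_total}",
            f"directed_links_total={report.directed_link_count_total}",
            f"records={len(report.records)}",
        ] + [f"warning: {w}" for w in report.warnings]
        emit(out_dir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    except Exception:
        for path in manifest:
            path.unlink(missing_ok=True)
        raise
    return manifest


def run_and_write(config: PipelineConfig, out_dir: str | Path) -> PipelineReport:
    report = run_pipeline(config)
    write_report(report, out_dir)
    return report
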