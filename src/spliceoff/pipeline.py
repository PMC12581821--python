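"""End-to-end orchestration: scan → filter → consensus → classify → summarize.

The library surface behind the command-line interface.  A
:class:`PipelineConfig` names the inputs (genome, GTF, AON table, per
comparison the rMATS directory and Whippet ``.diff``) and the thresholds; the
run functions return plain objects/DataFrames that the report writers dump as
TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import annotation as ann
from .classify import (
    ClassifiedEvent,
    ClassificationSummary,
    classify,
    find_intended,
    match_sites_to_events,
    replication_overlap,
    summarize,
)
from .errors import ConfigurationError, FormatError
from .events import (
    EVENT_TYPES,
    ConsensusEvent,
    cross_comparison_overlap,
    filter_rmats,
    filter_whippet,
    intersect_tools,
    read_rmats,
    read_whippet,
)
from .scanner import BindingSite, read_aon_table, scan_transcriptome, site_summary

log = logging.getLogger(__name__)


@dataclass
class ComparisonInput:
    """One scrambled-vs-targeting comparison's tool outputs."""

    name: str
    rmats_dir: Path
    whippet_diff: Path
    targeting: str
    scrambled: str
    whippet_group_a: str = "scrambled"  # which Whippet group got the scrambled AON
    rmats_scrambled_group: int = 1


@dataclass
class PipelineParams:
    max_distance: int = 3
    pad: int = 200
    min_reads: int = 10
    fdr_max: float = 0.05
    min_probability: float = 0.90
    min_abs_dpsi: float = 0.10
    intersect_mode: str = "overlap"
    basic_only: bool = False
    intended_rescue: bool = False  # reserved: single-tool intended events

    def validate(self) -> None:
        if self.max_distance < 0:
            raise ConfigurationError("max_distance must be >= 0")
        if self.pad < 0:
            raise ConfigurationError("pad must be >= 0")
        if not (0 < self.fdr_max <= 1 and 0 <= self.min_probability <= 1):
            raise ConfigurationError("significance thresholds out of range")
        if self.intersect_mode not in ("overlap", "exact"):
            raise ConfigurationError(f"bad intersect mode {self.intersect_mode!r}")


@dataclass
class PipelineConfig:
    genome: Path
    gtf: Path
    aon_table: Path
    comparisons: list[ComparisonInput] = field(default_factory=list)
    params: PipelineParams = field(default_factory=PipelineParams)


@dataclass
class ScanResult:
    sites: list[BindingSite]
    summary: pd.DataFrame


@dataclass
class ComparisonResult:
    name: str
    consensus: list[ConsensusEvent]
    classified: list[ClassifiedEvent]
    summary: ClassificationSummary
    intended: Optional[ConsensusEvent]


@dataclass
class ClassificationResult:
    comparisons: dict[str, ComparisonResult]
    overlap: dict[tuple, set[str]]


def load_reference(config: PipelineConfig):
    genome = ann.read_genome(config.genome)
    annotation = ann.read_gtf(config.gtf, basic_only=config.params.basic_only)
    annotation.contig_lengths = ann.contig_lengths(genome)
    annotation.validate()
    records = ann.extract_prespliced(annotation, genome)
    return annotation, records


def run_scan(config: PipelineConfig) -> ScanResult:
    """Predict binding sites for every AON over the pre-spliced database."""
    config.params.validate()
    _, records = load_reference(config)
    aons = read_aon_table(config.aon_table)
    sites = scan_transcriptome(
        aons, records, max_distance=config.params.max_distance
    )
    return ScanResult(sites=sites, summary=site_summary(sites, config.params.max_distance))


def load_comparison_events(
    comp: ComparisonInput, params: PipelineParams
) -> list[ConsensusEvent]:
    """Read, filter and intersect one comparison's rMATS + Whippet outputs."""
    rmats_events = []
    for etype in EVENT_TYPES:
        path = comp.rmats_dir / f"{etype}.MATS.JC.txt"
        if not path.exists():
            raise FormatError(f"comparison {comp.name}: missing {path}")
        rmats_events.extend(
            read_rmats(path, etype, scrambled_group=comp.rmats_scrambled_group)
        )
    rmats_events = filter_rmats(
        rmats_events, min_reads=params.min_reads, fdr_max=params.fdr_max
    )
    whippet_events = read_whippet(
        comp.whippet_diff, a_is_scrambled=(comp.whippet_group_a == "scrambled")
    )
    whippet_events = filter_whippet(
        whippet_events,
        min_probability=params.min_probability,
        min_abs_dpsi=params.min_abs_dpsi,
    )
    return intersect_tools(rmats_events, whippet_events, mode=params.intersect_mode)


def run_classification(config: PipelineConfig, sites: list[BindingSite]) -> ClassificationResult:
    """Classify every comparison's consensus events against binding sites."""
    config.params.validate()
    aons = read_aon_table(config.aon_table)
    aon_by_name = {a.name: a for a in aons}

    consensus_sets: dict[str, list[ConsensusEvent]] = {}
    for comp in config.comparisons:
        consensus_sets[comp.name] = load_comparison_events(comp, config.params)

    overlap = (
        cross_comparison_overlap(consensus_sets)
        if len(consensus_sets) >= 2
        else {}
    )

    results: dict[str, ComparisonResult] = {}
    for comp in config.comparisons:
        events = consensus_sets[comp.name]
        roles = {comp.targeting: "targeting", comp.scrambled: "scrambled"}
        matches = match_sites_to_events(sites, events, roles, pad=config.params.pad)
        targeting_aon = aon_by_name.get(comp.targeting)
        intended = None
        if targeting_aon is not None and targeting_aon.intended_target is not None:
            intended = find_intended(events, targeting_aon)
        classified = classify(
            events, matches, overlap, comp.name, intended, pad=config.params.pad
        )
        results[comp.name] = ComparisonResult(
            name=comp.name,
            consensus=events,
            classified=classified,
            summary=summarize(classified, comp.name),
            intended=intended,
        )
    return ClassificationResult(comparisons=results, overlap=overlap)


def run_replication(
    experiments: dict[str, ClassificationResult], comparison: str
) -> pd.DataFrame:
    """Cross-experiment replication table for one comparison name."""
    per_exp = {}
    for exp_name, res in experiments.items():
        if comparison not in res.comparisons:
            raise ConfigurationError(
                f"experiment {exp_name} lacks comparison {comparison!r}"
            )
        per_exp[exp_name] = res.comparisons[comparison].classified
    return replication_overlap(per_exp)
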