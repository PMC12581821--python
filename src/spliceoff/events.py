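"""Differential-splicing event parsing, filtering and two-tool consensus.

Consumes rMATS junction-count (JC) tables (SE/A5SS/A3SS/RI dialects) and
Whippet ``.diff`` tables, applies read-support and significance filters,
derives a standardized genomic region per event so the two tools become
comparable, and intersects them into consensus events with a mean dPSI and an
exact-coordinate identity key.

dPSI sign convention throughout: ``PSI(scrambled) − PSI(targeting)``, so a
positive dPSI means the targeting AON decreased inclusion (induced a skip).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import FormatError, SpliceoffError

log = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "A5SS", "A3SS", "RI")
WHIPPET_TYPE_MAP = {"CE": "SE", "AD": "A5SS", "AA": "A3SS", "RI": "RI"}

Interval = tuple[int, int]


@dataclass(frozen=True)
class SpliceEvent:
    """One tool-reported differential-splicing event (internal coordinates)."""

    tool: str  # "rmats" | "whippet"
    event_id: str
    event_type: str  # SE | A5SS | A3SS | RI
    gene_id: str
    symbol: str
    contig: str
    strand: str
    primary_interval: Interval  # skipped exon / retained intron / long exon
    flanking_intervals: tuple[Interval, ...]  # 2 for SE/RI, 1 for A5SS/A3SS, 0 for whippet
    short_interval: Optional[Interval] = None  # A5SS/A3SS short variant (rMATS)
    psi_group1: tuple[Optional[float], ...] = ()  # scrambled replicates
    psi_group2: tuple[Optional[float], ...] = ()  # targeting replicates
    dpsi: float = 0.0  # PSI(scrambled) - PSI(targeting)
    significance: float = 1.0  # FDR (rmats) or probability (whippet)
    ijc1: tuple[int, ...] = ()
    sjc1: tuple[int, ...] = ()
    ijc2: tuple[int, ...] = ()
    sjc2: tuple[int, ...] = ()


@dataclass(frozen=True)
class ConsensusEvent:
    """An rMATS/Whippet-matched event with mean dPSI and identity key."""

    event_type: str
    gene_id: str
    symbol: str
    contig: str
    strand: str
    standardized_region: Interval
    rmats_event: SpliceEvent
    whippet_event: SpliceEvent
    mean_dpsi: float
    identity_key: tuple

    @property
    def flanking_intervals(self) -> tuple[Interval, ...]:
        return self.rmats_event.flanking_intervals


def _split_counts(raw: str, what: str, event_id: str) -> tuple[int, ...]:
    parts = str(raw).split(",")
    try:
        return tuple(int(p) for p in parts)
    except ValueError:
        raise FormatError(f"event {event_id}: malformed {what} field {raw!r}") from None


def _split_psi(raw: str) -> tuple[Optional[float], ...]:
    out = []
    for p in str(raw).split(","):
        p = p.strip()
        out.append(None if p in ("NA", "", "nan") else float(p))
    return tuple(out)


_RMATS_COORDS = {
    "SE": ("exonStart_0base", "exonEnd"),
    "A5SS": ("longExonStart_0base", "longExonEnd"),
    "A3SS": ("longExonStart_0base", "longExonEnd"),
    "RI": ("riExonStart_0base", "riExonEnd"),
}


def read_rmats(
    path: str | Path, event_type: str, scrambled_group: int = 1
) -> list[SpliceEvent]:
    """Parse one ``*.MATS.JC.txt`` table into :class:`SpliceEvent` objects.

    *scrambled_group* names the rMATS sample group (1 or 2) that received the
    scrambled AON; dPSI is oriented to PSI(scrambled) − PSI(targeting).
    rMATS ``IncLevelDifference`` is group1 − group2, so it is used as-is when
    group 1 is the scrambled condition and negated otherwise.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event_type {event_type!r}")
    if scrambled_group not in (1, 2):
        raise ValueError("scrambled_group must be 1 or 2")
    df = pd.read_csv(path, sep="\t", dtype=str)
    events: list[SpliceEvent] = []
    cs, ce = _RMATS_COORDS[event_type]
    for _, row in df.iterrows():
        eid = f"{event_type}:{row['ID']}"
        ijc1 = _split_counts(row["IJC_SAMPLE_1"], "IJC_SAMPLE_1", eid)
        sjc1 = _split_counts(row["SJC_SAMPLE_1"], "SJC_SAMPLE_1", eid)
        ijc2 = _split_counts(row["IJC_SAMPLE_2"], "IJC_SAMPLE_2", eid)
        sjc2 = _split_counts(row["SJC_SAMPLE_2"], "SJC_SAMPLE_2", eid)
        if len(ijc1) != len(sjc1) or len(ijc2) != len(sjc2):
            raise FormatError(f"event {eid}: IJC/SJC replicate count mismatch")
        primary = (int(row[cs]), int(row[ce]))
        if event_type in ("SE", "RI"):
            flanks = (
                (int(row["upstreamES"]), int(row["upstreamEE"])),
                (int(row["downstreamES"]), int(row["downstreamEE"])),
            )
            short = None
        else:
            flanks = ((int(row["flankingES"]), int(row["flankingEE"])),)
            short = (int(row["shortES"]), int(row["shortEE"]))
        if event_type == "RI":
            # retained intron proper: between the two flanking exons
            primary = (flanks[0][1], flanks[1][0])
        psi1 = _split_psi(row["IncLevel1"])
        psi2 = _split_psi(row["IncLevel2"])
        inc_diff = float(row["IncLevelDifference"])
        if scrambled_group == 1:
            dpsi = inc_diff
        else:
            dpsi = -inc_diff
            psi1, psi2 = psi2, psi1
            ijc1, sjc1, ijc2, sjc2 = ijc2, sjc2, ijc1, sjc1
        events.append(
            SpliceEvent(
                tool="rmats",
                event_id=eid,
                event_type=event_type,
                gene_id=row["GeneID"],
                symbol=row.get("geneSymbol", row["GeneID"]),
                contig=row["chr"],
                strand=row["strand"],
                primary_interval=primary,
                flanking_intervals=flanks,
                short_interval=short,
                psi_group1=psi1,
                psi_group2=psi2,
                dpsi=dpsi,
                significance=float(row["FDR"]),
                ijc1=ijc1,
                sjc1=sjc1,
                ijc2=ijc2,
                sjc2=sjc2,
            )
        )
    return events


def read_whippet(path: str | Path, a_is_scrambled: bool = True) -> list[SpliceEvent]:
    """Parse a Whippet ``.diff`` table.

    Whippet event codes CE/AD/AA/RI map onto SE/A5SS/A3SS/RI; any other code
    (TS, TE, AF, AL, ...) is outside the four shared types and the row is
    skipped with a logged warning.  ``DeltaPsi`` is Psi_A − Psi_B; the sign is
    flipped when group A is the targeting condition.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    events: list[SpliceEvent] = []
    for idx, row in df.iterrows():
        wtype = row["Type"]
        etype = WHIPPET_TYPE_MAP.get(wtype)
        if etype is None:
            log.warning("whippet %s row %d: skipping event type %r", path, idx, wtype)
            continue
        contig, span = row["Coord"].rsplit(":", 1)
        s, e = span.split("-")
        interval = (int(s) - 1, int(e))  # 1-based inclusive -> half-open
        psi_a, psi_b = float(row["Psi_A"]), float(row["Psi_B"])
        delta = float(row["DeltaPsi"])
        if a_is_scrambled:
            psi1, psi2, dpsi = (psi_a,), (psi_b,), delta
        else:
            psi1, psi2, dpsi = (psi_b,), (psi_a,), -delta
        events.append(
            SpliceEvent(
                tool="whippet",
                event_id=f"{row['Gene']}:{row['Node']}",
                event_type=etype,
                gene_id=row["Gene"],
                symbol=row["Gene"],
                contig=contig,
                strand=row["Strand"],
                primary_interval=interval,
                flanking_intervals=(),
                psi_group1=psi1,
                psi_group2=psi2,
                dpsi=dpsi,
                significance=float(row["Probability"]),
            )
        )
    return events


def filter_rmats(
    events: Sequence[SpliceEvent], min_reads: int = 10, fdr_max: float = 0.05
) -> list[SpliceEvent]:
    """Keep events where EVERY replicate in BOTH groups has IJC+SJC >= min_reads
    and FDR < fdr_max (strict)."""
    out = []
    for ev in events:
        support = [i + s for i, s in zip(ev.ijc1, ev.sjc1)]
        support += [i + s for i, s in zip(ev.ijc2, ev.sjc2)]
        if all(x >= min_reads for x in support) and ev.significance < fdr_max:
            out.append(ev)
    return out


def filter_whippet(
    events: Sequence[SpliceEvent],
    min_probability: float = 0.90,
    min_abs_dpsi: float = 0.10,
) -> list[SpliceEvent]:
    """Keep events with probability >= min_probability and |dPSI| >= min_abs_dpsi."""
    return [
        ev
        for ev in events
        if ev.significance >= min_probability and abs(ev.dpsi) >= min_abs_dpsi
    ]


def standardized_region(event: SpliceEvent) -> Interval:
    """The comparable genomic region of an event, independent of the tool.

    SE → the skipped exon; RI → the retained intron; A5SS/A3SS → the
    alternative segment (set difference between the long and short exon
    variants).  Whippet coordinates already denote this region.
    """
    if event.tool == "whippet":
        return event.primary_interval
    if event.event_type in ("SE", "RI"):
        return event.primary_interval
    long_iv, short_iv = event.primary_interval, event.short_interval
    if short_iv is None:
        raise FormatError(f"event {event.event_id}: missing short exon variant")
    if long_iv == short_iv:
        raise SpliceoffError(f"event {event.event_id}: degenerate A5SS/A3SS (long == short)")
    if long_iv[0] == short_iv[0]:
        return (min(long_iv[1], short_iv[1]), max(long_iv[1], short_iv[1]))
    if long_iv[1] == short_iv[1]:
        return (min(long_iv[0], short_iv[0]), max(long_iv[0], short_iv[0]))
    raise FormatError(
        f"event {event.event_id}: long/short exons share no boundary"
    )


def _regions_match(a: Interval, b: Interval, mode: str) -> bool:
    if mode == "exact":
        return a == b
    return a[0] < b[1] and b[0] < a[1]


def intersect_tools(
    rmats_events: Sequence[SpliceEvent],
    whippet_events: Sequence[SpliceEvent],
    mode: str = "overlap",
) -> list[ConsensusEvent]:
    """Match filtered rMATS and Whippet events of one comparison.

    A match requires the same gene, event type and strand, and standardized
    regions that overlap (default) or are identical (``mode="exact"``).  One
    consensus row is emitted per matched rMATS event; a single Whippet event
    may back several consensus rows (rMATS distinguishes flanking regions,
    Whippet does not).  When several Whippet events match one rMATS event the
    one with the largest region overlap (then closest dPSI, then leftmost) is
    kept.
    """
    if mode not in ("overlap", "exact"):
        raise ValueError(f"unknown intersect mode {mode!r}")
    by_key: dict[tuple, list[tuple[Interval, SpliceEvent]]] = {}
    for wev in whippet_events:
        key = (wev.gene_id, wev.event_type, wev.strand)
        by_key.setdefault(key, []).append((standardized_region(wev), wev))
    consensus: list[ConsensusEvent] = []
    seen_keys: set[tuple] = set()
    for rev in rmats_events:
        region = standardized_region(rev)
        candidates = [
            (wreg, wev)
            for wreg, wev in by_key.get((rev.gene_id, rev.event_type, rev.strand), [])
            if _regions_match(region, wreg, mode)
        ]
        if not candidates:
            continue

        def rank(item: tuple[Interval, SpliceEvent]):
            wreg, wev = item
            overlap = min(region[1], wreg[1]) - max(region[0], wreg[0])
            return (-overlap, abs(rev.dpsi - wev.dpsi), wreg)

        wreg, wev = min(candidates, key=rank)
        identity_key = (
            rev.event_type,
            rev.contig,
            rev.primary_interval,
            rev.flanking_intervals,
            wev.primary_interval,
        )
        if identity_key in seen_keys:
            raise SpliceoffError(f"duplicate identity key {identity_key}")
        seen_keys.add(identity_key)
        consensus.append(
            ConsensusEvent(
                event_type=rev.event_type,
                gene_id=rev.gene_id,
                symbol=rev.symbol,
                contig=rev.contig,
                strand=rev.strand,
                standardized_region=region,
                rmats_event=rev,
                whippet_event=wev,
                mean_dpsi=(rev.dpsi + wev.dpsi) / 2.0,
                identity_key=identity_key,
            )
        )
    consensus.sort(key=lambda c: (c.contig, c.standardized_region, c.event_type))
    return consensus


def cross_comparison_overlap(
    consensus_sets: dict[str, Sequence[ConsensusEvent]],
) -> dict[tuple, set[str]]:
    """Group consensus events across comparisons by exact identity-key equality."""
    if len(consensus_sets) < 2:
        raise ValueError("need at least two comparisons")
    overlap: dict[tuple, set[str]] = {}
    for comparison, events in consensus_sets.items():
        for ev in events:
            overlap.setdefault(ev.identity_key, set()).add(comparison)
    return overlap
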