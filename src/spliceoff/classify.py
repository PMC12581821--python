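"""Linking binding sites to splicing events and classifying off-targets.

A splicing event is called *hybridization-dependent* when (1) a predicted
binding site of the comparison's targeting AON falls inside the event's
linkage window — the flank-to-flank span of the event plus a padding within
which AON binding is assumed able to affect splicing — and (2) the event is
AON-specific, i.e. its identity key appears in exactly one targeting-AON
comparison of the experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import AmbiguityError, SpliceoffError
from .events import ConsensusEvent, standardized_region
from .scanner import AONRecord, BindingSite

log = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass
class ClassifiedEvent:
    """One consensus event with all classification flags set."""

    consensus: ConsensusEvent
    comparison: str
    matched_targeting: bool = False
    matched_scrambled: bool = False
    matching_sites: tuple[BindingSite, ...] = ()
    aon_specific: bool = False
    hybridization_dependent: bool = False
    is_intended: bool = False
    larger_than_intended: Optional[bool] = None  # None: no intended yardstick
    single_flank_note: bool = False


@dataclass
class ClassificationSummary:
    """Per-comparison counts (all / AON-specific), plus per-type totals."""

    comparison: str
    total: int = 0
    specific: int = 0
    matched_scrambled_all: int = 0
    matched_scrambled_specific: int = 0
    matched_targeting_all: int = 0
    matched_targeting_specific: int = 0
    hybridization_dependent: int = 0
    larger_than_intended: int = 0
    by_type: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.specific > self.total:
            raise SpliceoffError("specific count exceeds total")
        for n in (
            self.matched_scrambled_all,
            self.matched_targeting_all,
            self.hybridization_dependent,
        ):
            if n > self.total:
                raise SpliceoffError("matched count exceeds total")
        if sum(self.by_type.values()) != self.total:
            raise SpliceoffError("per-type counts do not sum to total")


def linkage_window(event: ConsensusEvent, pad: int = 200) -> tuple[Interval, bool]:
    """The genomic window within which AON binding could affect the event.

    Spans from the furthest ends of the flanking exons (plus the event region
    itself) extended by *pad* on both sides.  For A5SS/A3SS events only one
    flank is annotated; the window then extends *pad* beyond the event region
    on the unannotated side and the ``single_flank`` flag is returned True.
    The window is clamped at position 0.
    """
    intervals = list(event.flanking_intervals) + [event.standardized_region]
    lo = min(iv[0] for iv in intervals) - pad
    hi = max(iv[1] for iv in intervals) + pad
    if lo < 0:
        log.info("linkage window for %s clamped at 0", event.identity_key)
        lo = 0
    single_flank = len(event.flanking_intervals) < 2
    return (lo, hi), single_flank


def match_sites_to_events(
    sites: Sequence[BindingSite],
    events: Sequence[ConsensusEvent],
    aon_roles: dict[str, str],
    pad: int = 200,
) -> dict[tuple, dict[str, list[BindingSite]]]:
    """Map each event's identity key to the sites matching its linkage window.

    A site matches when the start or end coordinate of its closed genomic
    footprint lies inside the (half-open) window.  Matches are kept separately
    for targeting-AON and scrambled-AON sites, per the roles in *aon_roles*.
    """
    trees: dict[str, IntervalTree] = {}
    windows: dict[tuple, Interval] = {}
    for ev in events:
        (lo, hi), _ = linkage_window(ev, pad)
        windows[ev.identity_key] = (lo, hi)
        trees.setdefault(ev.contig, IntervalTree()).addi(lo, hi, ev.identity_key)
    matches: dict[tuple, dict[str, list[BindingSite]]] = {
        ev.identity_key: {"targeting": [], "scrambled": []} for ev in events
    }
    for site in sites:
        role = aon_roles.get(site.aon_name)
        if role is None:
            continue
        tree = trees.get(site.contig)
        if tree is None:
            continue
        first, last = site.footprint
        hit_keys = {iv.data for iv in tree[first]} | {iv.data for iv in tree[last]}
        for key in sorted(hit_keys, key=repr):
            matches[key][role].append(site)
    return matches


def aon_specificity(
    overlap: dict[tuple, set[str]], comparison: str
) -> dict[tuple, bool]:
    """Per identity key: True iff the key occurs in *comparison* only."""
    known = set().union(*overlap.values()) if overlap else set()
    if comparison not in known:
        raise ValueError(f"comparison {comparison!r} absent from overlap map")
    return {
        key: comps == {comparison}
        for key, comps in overlap.items()
        if comparison in comps
    }


def find_intended(
    events: Sequence[ConsensusEvent], aon: AONRecord
) -> Optional[ConsensusEvent]:
    """The consensus event matching the AON's declared intended target.

    Candidates share the target gene and event type and overlap the declared
    interval when one is given.  No candidate is a legal outcome (logged);
    more than one is an ambiguity error.
    """
    if aon.intended_target is None:
        raise ValueError(f"AON {aon.name} has no intended target descriptor")
    tgt = aon.intended_target
    candidates = []
    for ev in events:
        if ev.gene_id != tgt.gene and ev.symbol != tgt.gene:
            continue
        if ev.event_type != tgt.event_type:
            continue
        if tgt.interval is not None:
            reg = ev.standardized_region
            if not (reg[0] < tgt.interval[1] and tgt.interval[0] < reg[1]):
                continue
        candidates.append(ev)
    if not candidates:
        log.info("no significant intended event found for AON %s", aon.name)
        return None
    if len(candidates) > 1:
        raise AmbiguityError(
            f"AON {aon.name}: {len(candidates)} events match the intended "
            f"target: {[c.identity_key for c in candidates]}"
        )
    return candidates[0]


def classify(
    events: Sequence[ConsensusEvent],
    site_matches: dict[tuple, dict[str, list[BindingSite]]],
    overlap: dict[tuple, set[str]],
    comparison: str,
    intended: Optional[ConsensusEvent],
    pad: int = 200,
) -> list[ClassifiedEvent]:
    """Set all flags for one comparison's consensus events.

    ``hybridization_dependent`` = matched to a targeting-AON site AND
    AON-specific.  ``larger_than_intended`` compares |mean dPSI| against the
    intended event and is None (undefined) when no intended event exists; the
    intended event itself is counted among the targeting-site matches but is
    excluded from the larger-than-intended count.
    """
    specific = aon_specificity(overlap, comparison) if overlap else {}
    intended_key = intended.identity_key if intended is not None else None
    out = []
    for ev in events:
        m = site_matches.get(ev.identity_key, {"targeting": [], "scrambled": []})
        matched_t = bool(m["targeting"])
        matched_s = bool(m["scrambled"])
        is_spec = specific.get(ev.identity_key, True)
        is_intended = ev.identity_key == intended_key
        if intended is None:
            larger: Optional[bool] = None
        elif is_intended:
            larger = False
        else:
            larger = abs(ev.mean_dpsi) > abs(intended.mean_dpsi)
        _, single_flank = linkage_window(ev, pad)
        out.append(
            ClassifiedEvent(
                consensus=ev,
                comparison=comparison,
                matched_targeting=matched_t,
                matched_scrambled=matched_s,
                matching_sites=tuple(m["targeting"] + m["scrambled"]),
                aon_specific=is_spec,
                hybridization_dependent=matched_t and is_spec,
                is_intended=is_intended,
                larger_than_intended=larger,
                single_flank_note=single_flank,
            )
        )
    return out


def summarize(
    classified: Sequence[ClassifiedEvent], comparison: str = ""
) -> ClassificationSummary:
    """Deterministic per-comparison counts in the all/specific report shape."""
    s = ClassificationSummary(comparison=comparison or
                              (classified[0].comparison if classified else ""))
    for ev in classified:
        s.total += 1
        s.by_type[ev.consensus.event_type] = s.by_type.get(ev.consensus.event_type, 0) + 1
        if ev.aon_specific:
            s.specific += 1
        if ev.matched_scrambled:
            s.matched_scrambled_all += 1
            if ev.aon_specific:
                s.matched_scrambled_specific += 1
        if ev.matched_targeting:
            s.matched_targeting_all += 1
            if ev.aon_specific:
                s.matched_targeting_specific += 1
        if ev.hybridization_dependent:
            s.hybridization_dependent += 1
        if ev.larger_than_intended:
            s.larger_than_intended += 1
    s.validate()
    return s


def replication_overlap(
    classified_by_experiment: dict[str, Sequence[ClassifiedEvent]],
) -> pd.DataFrame:
    """Events shared (by identity key) across ALL experiments, with the
    per-experiment mean dPSI side by side."""
    if len(classified_by_experiment) < 2:
        raise ValueError("need at least two experiments")
    names = list(classified_by_experiment)
    per_exp: dict[str, dict[tuple, ClassifiedEvent]] = {
        name: {ev.consensus.identity_key: ev for ev in evs}
        for name, evs in classified_by_experiment.items()
    }
    shared = set(per_exp[names[0]])
    for name in names[1:]:
        shared &= set(per_exp[name])
    rows = []
    for key in sorted(shared, key=repr):
        ev0 = per_exp[names[0]][key].consensus
        row = {
            "gene": ev0.symbol,
            "contig": ev0.contig,
            "region_start": ev0.standardized_region[0],
            "region_end": ev0.standardized_region[1],
            "flanking": ";".join(f"{a}-{b}" for a, b in ev0.flanking_intervals),
            "event_type": ev0.event_type,
        }
        for name in names:
            row[f"dpsi_{name}"] = per_exp[name][key].consensus.mean_dpsi
        rows.append(row)
    cols = [
        "gene", "contig", "region_start", "region_end", "flanking", "event_type",
    ] + [f"dpsi_{n}" for n in names]
    return pd.DataFrame(rows, columns=cols)
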