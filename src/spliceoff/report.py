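"""Plain-TSV and BED report writers.

Every report opens with a single ``#`` comment line recording the package
version, a hash of the run configuration and the seed, so any table can be
traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .classify import ClassifiedEvent, ClassificationSummary
from .events import ConsensusEvent
from .scanner import BindingSite


def config_hash(payload) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_line(cfg_hash: str, seed: Optional[int]) -> str:
    seed_part = "" if seed is None else f" seed={seed}"
    return f"# spliceoff v{__version__} config={cfg_hash}{seed_part}\n"


def _write_df(df: pd.DataFrame, path: Path, cfg_hash: str, seed: Optional[int]) -> None:
    with open(path, "w") as fh:
        fh.write(_header_line(cfg_hash, seed))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_sites_tsv(
    sites: Sequence[BindingSite], path: Path, cfg_hash: str = "-", seed: Optional[int] = None
) -> None:
    rows = [
        {
            "aon": s.aon_name,
            "gene_id": s.gene_id,
            "contig": s.contig,
            "start": s.interval[0],
            "end": s.interval[1],
            "strand": s.strand,
            "distance": s.distance,
            "trace": s.trace,
            "is_intended": int(s.is_intended),
        }
        for s in sites
    ]
    _write_df(pd.DataFrame(rows, columns=[
        "aon", "gene_id", "contig", "start", "end", "strand", "distance",
        "trace", "is_intended",
    ]), path, cfg_hash, seed)


def write_sites_bed(sites: Sequence[BindingSite], path: Path) -> None:
    """BED6: name=aon;distance, score=distance, strand=gene strand."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.contig}\t{s.interval[0]}\t{s.interval[1]}\t"
                f"{s.aon_name};d{s.distance}\t{s.distance}\t{s.strand}\n"
            )


def write_site_summary(
    summary: pd.DataFrame, path: Path, cfg_hash: str = "-", seed: Optional[int] = None
) -> None:
    _write_df(summary, path, cfg_hash, seed)


def consensus_frame(events: Sequence[ConsensusEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        r, w = ev.rmats_event, ev.whippet_event
        rows.append(
            {
                "event_type": ev.event_type,
                "gene_id": ev.gene_id,
                "symbol": ev.symbol,
                "contig": ev.contig,
                "strand": ev.strand,
                "region_start": ev.standardized_region[0],
                "region_end": ev.standardized_region[1],
                "rmats_primary": f"{r.primary_interval[0]}-{r.primary_interval[1]}",
                "rmats_flanks": ";".join(f"{a}-{b}" for a, b in r.flanking_intervals),
                "whippet_coord": f"{w.primary_interval[0]}-{w.primary_interval[1]}",
                "dpsi_rmats": r.dpsi,
                "dpsi_whippet": w.dpsi,
                "mean_dpsi": ev.mean_dpsi,
                "identity_key": repr(ev.identity_key),
            }
        )
    return pd.DataFrame(rows)


def write_consensus_tsv(
    events: Sequence[ConsensusEvent], path: Path, cfg_hash: str = "-",
    seed: Optional[int] = None,
) -> None:
    _write_df(consensus_frame(events), path, cfg_hash, seed)


def classified_frame(classified: Sequence[ClassifiedEvent]) -> pd.DataFrame:
    rows = []
    for ce in classified:
        ev = ce.consensus
        rows.append(
            {
                "comparison": ce.comparison,
                "event_type": ev.event_type,
                "gene_id": ev.gene_id,
                "symbol": ev.symbol,
                "contig": ev.contig,
                "region_start": ev.standardized_region[0],
                "region_end": ev.standardized_region[1],
                "mean_dpsi": ev.mean_dpsi,
                "matched_targeting": int(ce.matched_targeting),
                "matched_scrambled": int(ce.matched_scrambled),
                "aon_specific": int(ce.aon_specific),
                "hybridization_dependent": int(ce.hybridization_dependent),
                "is_intended": int(ce.is_intended),
                "larger_than_intended": (
                    "NA" if ce.larger_than_intended is None
                    else int(ce.larger_than_intended)
                ),
                "single_flank": int(ce.single_flank_note),
                "matching_sites": ";".join(
                    f"{s.aon_name}:{s.contig}:{s.interval[0]}-{s.interval[1]}"
                    for s in ce.matching_sites
                ),
                "identity_key": repr(ev.identity_key),
            }
        )
    return pd.DataFrame(rows)


def write_classified_tsv(
    classified: Sequence[ClassifiedEvent], path: Path, cfg_hash: str = "-",
    seed: Optional[int] = None,
) -> None:
    _write_df(classified_frame(classified), path, cfg_hash, seed)


def summary_frame(summaries: Sequence[ClassificationSummary]) -> pd.DataFrame:
    """Per-comparison classification counts (all / AON-specific layout)."""
    rows = []
    for s in summaries:
        row = {
            "comparison": s.comparison,
            "total_all": s.total,
            "total_specific": s.specific,
            "matched_scrambled_all": s.matched_scrambled_all,
            "matched_scrambled_specific": s.matched_scrambled_specific,
            "matched_targeting_all": s.matched_targeting_all,
            "matched_targeting_specific": s.matched_targeting_specific,
            "hybridization_dependent": s.hybridization_dependent,
            "larger_than_intended": s.larger_than_intended,
        }
        for etype in ("SE", "A5SS", "A3SS", "RI"):
            row[f"n_{etype}"] = s.by_type.get(etype, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_summary_tsv(
    summaries: Sequence[ClassificationSummary], path: Path, cfg_hash: str = "-",
    seed: Optional[int] = None,
) -> None:
    _write_df(summary_frame(summaries), path, cfg_hash, seed)


def write_replication_tsv(
    table: pd.DataFrame, path: Path, cfg_hash: str = "-", seed: Optional[int] = None
) -> None:
    _write_df(table, path, cfg_hash, seed)
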