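"""Approximate binding-site search over pre-spliced gene sequences.

An antisense oligonucleotide (AON) hybridizes to the sense strand of the
pre-mRNA wherever the AON *target sequence* (the reverse complement of the
AON) occurs within a small edit distance.  This module performs an exhaustive
semi-global search — full query against every locus of every gene's
pre-spliced sequence — reporting one deduplicated hit per locus with its
minimal unit-cost Levenshtein distance (substitutions, insertions and
deletions all cost 1).

Two routes compute the per-end-position minimal distances:

* :func:`scan_record` — a vectorized dynamic program (numpy, row-wise with a
  prefix-scan resolution of the in-row dependency), used by the pipeline;
* :func:`brute_force_oracle` — a plain column-by-column dynamic program in
  pure Python, kept deliberately simple as an independent check.

Both share the same locus-refinement and deduplication policy so their hit
sets are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import PresplicedRecord, gene_offset_to_genomic
from .errors import ConfigurationError, FormatError

_RNA_COMPLEMENT = {"A": "T", "U": "A", "G": "C", "C": "G"}
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class TargetDescriptor:
    """Where an AON is designed to act: a gene, an event type, optionally an exon."""

    gene: str
    event_type: str = "SE"
    interval: Optional[tuple[int, int]] = None  # genomic, half-open

    def __str__(self) -> str:
        if self.interval is None:
            return self.event_type
        return f"{self.event_type}:{self.interval[0]}-{self.interval[1]}"


@dataclass(frozen=True)
class AONRecord:
    """One oligonucleotide: name, RNA sequence (5'→3'), role and intended target."""

    name: str
    rna_sequence: str
    role: str  # "targeting" | "scrambled"
    intended_target: Optional[TargetDescriptor] = None

    def __post_init__(self) -> None:
        if self.role not in ("targeting", "scrambled"):
            raise FormatError(f"AON {self.name}: bad role {self.role!r}")
        seq = self.rna_sequence
        if len(seq) < 12:
            raise FormatError(f"AON {self.name}: sequence shorter than 12 nt")
        bad = set(seq) - set("ACGU")
        if bad:
            raise FormatError(f"AON {self.name}: non-RNA characters {sorted(bad)}")


@dataclass(frozen=True)
class Hit:
    """One locus-level hit of a query inside one text (gene-local offsets)."""

    start: int
    end: int
    distance: int
    trace: str  # extended CIGAR: = match, X mismatch, I extra genome base, D missing genome base
    n_indels: int


@dataclass(frozen=True)
class BindingSite:
    """One predicted hybridization locus in genomic coordinates."""

    aon_name: str
    gene_id: str
    contig: str
    interval: tuple[int, int]  # genomic, half-open
    strand: str  # gene strand (the sense strand that was searched)
    distance: int
    trace: str
    is_intended: bool = False

    @property
    def footprint(self) -> tuple[int, int]:
        """Closed genomic endpoints (first base, last base) of the site."""
        return (self.interval[0], self.interval[1] - 1)


def target_sequence(aon: AONRecord) -> str:
    """The DNA sequence an AON hybridizes to: reverse complement, U→T."""
    try:
        comp = [_RNA_COMPLEMENT[c] for c in aon.rna_sequence]
    except KeyError as exc:
        raise FormatError(f"AON {aon.name}: invalid RNA character {exc}") from None
    return "".join(reversed(comp))


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T → 0..3; anything else (N, ambiguity codes) → 4, never matching."""
    out = np.full(len(seq), 4, dtype=np.int8)
    for ch, code in _CODE.items():
        idx = [i for i, c in enumerate(seq) if c == ch]
        if idx:
            out[idx] = code
    return out


def _end_distances(query: str, text: str) -> np.ndarray:
    """min edit distance of the full query against text[..:j], for every j.

    Row-wise DP over the query with the in-row left dependency resolved by a
    prefix-min scan: ``new[j] = j + cummin(cand - j)`` where ``cand`` holds
    the diagonal/vertical candidates.
    """
    q = _encode(query)
    t = _encode(text)
    n = t.size
    idx = np.arange(n + 1, dtype=np.int32)
    row = np.zeros(n + 1, dtype=np.int32)  # D[0][j] = 0: free start in text
    cand = np.empty(n + 1, dtype=np.int32)
    for i in range(1, q.size + 1):
        c = q[i - 1]
        cost = (t != c).astype(np.int32)  # code 4 never equals a query code
        cand[0] = i
        np.minimum(row[:-1] + cost, row[1:] + 1, out=cand[1:])
        row = np.minimum.accumulate(cand - idx) + idx
    return row


def _oracle_end_distances(query: str, text: str) -> list[int]:
    """Same quantity as :func:`_end_distances`, by a plain column-major DP."""
    m = len(query)
    acgt = frozenset("ACGT")
    prev = list(range(m + 1))  # column j=0: must consume i query chars
    ends = [m] + [0] * len(text)
    ends[0] = prev[m]
    for j, tc in enumerate(text, 1):
        tc_ok = tc in acgt
        cur = [0] * (m + 1)  # D[0][j] = 0
        up = 0
        for i in range(1, m + 1):
            cost = 0 if (tc_ok and query[i - 1] == tc) else 1
            val = prev[i - 1] + cost
            if prev[i] + 1 < val:
                val = prev[i] + 1
            if up + 1 < val:
                val = up + 1
            cur[i] = up = val
        ends[j] = cur[m]
        prev = cur
    return ends


def _refine_hit(query: str, text: str, end: int, max_distance: int) -> Hit:
    """Best alignment of the full query ending exactly at *end*.

    Small tuple-cost DP over a bounded window, minimizing lexicographically
    (distance, number of indels, start position) — the stated tie-break.
    """
    m = len(query)
    ws = max(0, end - m - max_distance)
    window = text[ws:end]
    L = len(window)
    acgt = frozenset("ACGT")
    INF = (10**9, 0, 0)
    # cell value: (distance, indels, start column within window)
    prev_row = [(0, 0, j) for j in range(L + 1)]
    back: list[list[int]] = []  # 0 diag, 1 up (gap in genome), 2 left (gap in query)
    for i in range(1, m + 1):
        qc = query[i - 1]
        row = [(prev_row[0][0] + 1, prev_row[0][1] + 1, prev_row[0][2])]
        brow = [1]
        for j in range(1, L + 1):
            tc = window[j - 1]
            cost = 0 if (tc in acgt and qc == tc) else 1
            d0, i0, s0 = prev_row[j - 1]
            diag = (d0 + cost, i0, s0)
            d1, i1, s1 = prev_row[j]
            up = (d1 + 1, i1 + 1, s1)
            d2, i2, s2 = row[j - 1]
            left = (d2 + 1, i2 + 1, s2)
            best, move = diag, 0
            if up < best:
                best, move = up, 1
            if left < best:
                best, move = left, 2
            row.append(best)
            brow.append(move)
        prev_row = row
        back.append(brow)
    dist, n_indels, start_col = prev_row[L]
    # traceback for the trace string
    ops = []
    i, j = m, L
    while i > 0:
        move = back[i - 1][j]
        if move == 0:
            tc = window[j - 1]
            ops.append("=" if (tc in acgt and query[i - 1] == tc) else "X")
            i, j = i - 1, j - 1
        elif move == 1:
            ops.append("D")  # query base with no genome base
            i -= 1
        else:
            ops.append("I")  # genome base not paired to the query
            j -= 1
    trace = "".join(reversed(ops))
    return Hit(ws + start_col, end, dist, trace, n_indels)


def _dedup(hits: list[Hit]) -> list[Hit]:
    """One hit per locus: chain-merge overlapping intervals, keep the
    minimal-(distance, indels, start, end) representative of each cluster."""
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: (h.start, h.end))
    clusters: list[list[Hit]] = [[hits[0]]]
    reach = hits[0].end
    for h in hits[1:]:
        if h.start < reach:
            clusters[-1].append(h)
            reach = max(reach, h.end)
        else:
            clusters.append([h])
            reach = h.end
    return [
        min(cl, key=lambda h: (h.distance, h.n_indels, h.start, h.end))
        for cl in clusters
    ]


def _hits_from_end_distances(
    query: str, text: str, end_d: Sequence[int], max_distance: int
) -> list[Hit]:
    candidates = [
        _refine_hit(query, text, j, max_distance)
        for j in range(len(text) + 1)
        if end_d[j] <= max_distance
    ]
    return sorted(_dedup(candidates), key=lambda h: (h.start, h.end))


def _check_scan_args(query: str, max_distance: int) -> None:
    if not query:
        raise ConfigurationError("empty query")
    if max_distance < 0:
        raise ConfigurationError("max_distance must be >= 0")
    if max_distance >= len(query):
        raise ConfigurationError(
            f"max_distance {max_distance} >= query length {len(query)}"
        )


def scan_record(
    query: str, record: "PresplicedRecord | str", max_distance: int
) -> list[Hit]:
    """All deduplicated loci of *record* within *max_distance* of *query*.

    Semi-global: the full query is aligned against any substring of the text.
    A query longer than the text yields no hits.
    """
    _check_scan_args(query, max_distance)
    text = record if isinstance(record, str) else record.sequence
    if len(query) > len(text):
        return []
    end_d = _end_distances(query, text)
    return _hits_from_end_distances(query, text, end_d, max_distance)


def brute_force_oracle(query: str, text: str, max_distance: int) -> list[Hit]:
    """Independent exhaustive search (plain DP); for tests and verification."""
    _check_scan_args(query, max_distance)
    if len(query) > len(text):
        return []
    end_d = _oracle_end_distances(query, text)
    return _hits_from_end_distances(query, text, end_d, max_distance)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def scan_transcriptome(
    aons: Sequence[AONRecord],
    db: Sequence[PresplicedRecord],
    max_distance: int = 3,
    mark_intended: bool = True,
) -> list[BindingSite]:
    """Scan every AON target sequence against every pre-spliced gene record.

    Local hit offsets are converted to genomic intervals; a site is flagged
    ``is_intended`` when it overlaps the AON's declared intended-target locus
    (the declared interval, or the whole gene when no interval is given).
    """
    if not db:
        raise ConfigurationError("empty pre-spliced database")
    gene_ids = {rec.gene_id for rec in db}
    if mark_intended:
        for aon in aons:
            if aon.role != "targeting":
                continue
            if aon.intended_target is None or aon.intended_target.gene not in gene_ids:
                raise ConfigurationError(
                    f"targeting AON {aon.name} has no resolvable intended target"
                )
    sites: list[BindingSite] = []
    for aon in aons:
        query = target_sequence(aon)
        for rec in db:
            for hit in scan_record(query, rec, max_distance):
                ginterval = gene_offset_to_genomic(rec, (hit.start, hit.end))
                intended = False
                if (
                    mark_intended
                    and aon.intended_target is not None
                    and aon.intended_target.gene == rec.gene_id
                ):
                    locus = aon.intended_target.interval or rec.span
                    intended = _overlaps(ginterval, locus)
                sites.append(
                    BindingSite(
                        aon_name=aon.name,
                        gene_id=rec.gene_id,
                        contig=rec.contig,
                        interval=ginterval,
                        strand=rec.strand,
                        distance=hit.distance,
                        trace=hit.trace,
                        is_intended=intended,
                    )
                )
    sites.sort(key=lambda s: (s.aon_name, s.contig, s.interval))
    return sites


def site_summary(sites: Sequence[BindingSite], max_distance: int = 3) -> pd.DataFrame:
    """Per-AON counts by edit distance plus totals (binding-site report shape)."""
    rows = {}
    for s in sites:
        row = rows.setdefault(
            s.aon_name,
            {f"mismatches_{d}": 0 for d in range(max_distance + 1)}
            | {"total_sites": 0, "genes": set(), "intended_sites": 0},
        )
        row[f"mismatches_{s.distance}"] += 1
        row["total_sites"] += 1
        row["genes"].add(s.gene_id)
        if s.is_intended:
            row["intended_sites"] += 1
    out = []
    for aon in sorted(rows):
        row = rows[aon]
        out.append(
            {"aon": aon}
            | {k: row[k] for k in row if k not in ("genes",)}
            | {"total_genes_involved": len(row["genes"])}
        )
    cols = (
        ["aon"]
        + [f"mismatches_{d}" for d in range(max_distance + 1)]
        + ["total_sites", "total_genes_involved", "intended_sites"]
    )
    return pd.DataFrame(out, columns=cols)


def read_aon_table(path: str | Path) -> list[AONRecord]:
    """Read the AON TSV: columns name, sequence, role, target_gene, target_event.

    ``target_event`` is ``TYPE`` or ``TYPE:start-end`` (0-based half-open
    genomic interval of the intended exon/segment); empty for scrambled AONs.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    required = {"name", "sequence", "role"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"AON table {path}: missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        descriptor = None
        gene = row.get("target_gene", "")
        if gene:
            ev = row.get("target_event", "") or "SE"
            if ":" in ev:
                etype, span = ev.split(":", 1)
                s, e = span.split("-")
                descriptor = TargetDescriptor(gene, etype, (int(s), int(e)))
            else:
                descriptor = TargetDescriptor(gene, ev)
        records.append(
            AONRecord(
                name=row["name"],
                rna_sequence=row["sequence"],
                role=row["role"],
                intended_target=descriptor,
            )
        )
    return records


def write_aon_table(aons: Iterable[AONRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tsequence\trole\ttarget_gene\ttarget_event\n")
        for a in aons:
            gene = a.intended_target.gene if a.intended_target else ""
            ev = str(a.intended_target) if a.intended_target else ""
            fh.write(f"{a.name}\t{a.rna_sequence}\t{a.role}\t{gene}\t{ev}\n")
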