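"""Synthetic study generator: toy genome, planted binding sites, tool outputs.

Generates, deterministically from a seed, everything the pipeline consumes:

* a random multi-exon genome (FASTA + Ensembl-dialect GTF);
* AON binding sites written into the genome at exact edit distances, either
  *linked* (inside the linkage window of a planted splicing event) or
  *unlinked* (in dedicated decoy genes, far from every window).  Each planted
  locus is verified with the brute-force alignment oracle and all accidental
  background matches are scrubbed by point mutation, so the scan result over
  the finished genome is exactly the planted truth;
* rMATS junction-count tables and Whippet ``.diff`` tables whose counts are
  binomial draws around planted group PSIs, with Fisher-exact p-values,
  Benjamini-Hochberg FDR per event-type file, and a seeded-bootstrap stand-in
  for Whippet's posterior probability;
* a JSON truth manifest — the single source of truth for recovery tests.

The junction-count model: with planted inclusion level ψ and the fixed
length-normalization constants IncFormLen=198 / SkipFormLen=99, inclusion
reads are drawn as IJC ~ Binomial(depth, 2ψ/(1+ψ)) and SJC = depth − IJC, so
the length-normalized PSI, (IJC/198) / (IJC/198 + SJC/99), reproduces ψ in
expectation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from . import annotation as ann
from .annotation import (
    GeneModel,
    GenomeAnnotation,
    TranscriptModel,
    extract_prespliced,
    gene_offset_to_genomic,
    genomic_to_gene_offset,
)
from .errors import ConfigurationError, FormatError, GenerationError
from .scanner import (
    AONRecord,
    TargetDescriptor,
    brute_force_oracle,
    scan_record,
    target_sequence,
    write_aon_table,
)

log = logging.getLogger(__name__)

MANIFEST_SCHEMA_VERSION = 2
INC_FORM_LEN = 198
SKIP_FORM_LEN = 99

# oligonucleotide roster used by the default scenario (18-20-mers, one
# scrambled control), matching the published splice-switching designs
DEFAULT_AONS: tuple[tuple[str, str, str], ...] = (
    ("APP-AON", "CUUCUGCAAAGAACACCUUG", "targeting"),
    ("ATXN3-AON", "AUAGGUCCCGCUGCUGCU", "targeting"),
    ("HTT-AON", "GUCCCAUCAUUCAGGUCCAU", "targeting"),
    ("Scrambled-AON", "UCAUUUGCUUCAUACAGG", "scrambled"),
)

DETECTABLE_KINDS = ("intended", "linked", "unlinked", "scr_linked", "shared")

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ScenarioConfig:
    """Everything that defines one synthetic study (before the seed)."""

    aons: tuple[tuple[str, str, str], ...] = DEFAULT_AONS
    # genome shape
    n_decoy_genes: int = 10
    exons_per_gene: tuple[int, int] = (5, 7)
    exon_length: tuple[int, int] = (80, 200)
    intron_length: tuple[int, int] = (250, 450)
    intergenic: tuple[int, int] = (600, 1000)
    n_contigs: int = 2
    # event roster, per targeting-AON comparison
    n_linked: int = 3
    n_unlinked: int = 4
    n_scr_linked: int = 2
    n_shared: int = 5
    n_rmats_only: int = 3
    n_whippet_only: int = 3
    n_null: int = 0
    n_low_coverage: int = 1
    toxic_aon: Optional[str] = "ATXN3-AON"
    toxic_extra_unlinked: int = 8
    # effect sizes (dPSI = PSI(scrambled) - PSI(targeting))
    intended_dpsi: float = 0.40
    intended_scr_psi: float = 0.98
    linked_dpsis: tuple[float, ...] = (0.55, 0.30, 0.20)
    linked_distances: tuple[int, ...] = (2, 3, 3)
    unlinked_dpsis: tuple[float, ...] = (0.55, -0.30, 0.28, 0.25)
    scr_linked_dpsis: tuple[float, ...] = (0.30, -0.25)
    shared_dpsis: tuple[float, ...] = (-0.30, 0.30, -0.20, 0.25, 0.35)
    fp_dpsis: tuple[float, ...] = (0.35, -0.30, 0.28)
    baseline_scr_psi: float = 0.85
    null_psi: float = 0.70
    event_type_cycle: tuple[str, ...] = ("SE", "SE", "A5SS", "A3SS", "RI")
    # sequencing model
    replicates: int = 6
    depth: int = 100
    low_coverage_depth: int = 6
    overdispersion: Optional[float] = None  # beta-binomial rho; None = binomial
    bootstrap_samples: int = 100
    # decoy binding sites per AON, by edit distance
    decoy_sites: dict[int, int] = field(default_factory=lambda: {1: 1, 2: 2, 3: 3})
    pad: int = 200
    max_distance: int = 3

    def targeting_names(self) -> list[str]:
        return [n for n, _, r in self.aons if r == "targeting"]

    def scrambled_name(self) -> str:
        for n, _, r in self.aons:
            if r == "scrambled":
                return n
        raise ConfigurationError("scenario has no scrambled AON")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["decoy_sites"] = {str(k): v for k, v in self.decoy_sites.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown scenario config keys: {sorted(unknown)}")
        d = dict(d)
        if "aons" in d:
            d["aons"] = tuple(tuple(a) for a in d["aons"])
        if "decoy_sites" in d:
            d["decoy_sites"] = {int(k): int(v) for k, v in d["decoy_sites"].items()}
        for key, val in list(d.items()):
            if isinstance(val, list):
                d[key] = tuple(val)
        return cls(**d)


@dataclass
class PlannedEvent:
    event_id: str
    kind: str  # intended | linked | unlinked | scr_linked | shared | rmats_only | whippet_only | null | low_coverage
    event_type: str
    gene_id: str
    symbol: str
    contig: str
    strand: str
    comparisons: tuple[str, ...]
    tools: tuple[str, ...]  # subset of ("rmats", "whippet")
    psi_scr: float
    dpsi: float  # planted PSI(scrambled) - PSI(targeting)
    depth: int
    rmats_primary: tuple[int, int]
    rmats_flanks: tuple[tuple[int, int], ...]
    rmats_short: Optional[tuple[int, int]]
    whippet_interval: tuple[int, int]
    standardized: tuple[int, int]

    @property
    def psi_targ(self) -> float:
        return self.psi_scr - self.dpsi

    @property
    def identity_key(self) -> tuple:
        # the reader reports the retained intron itself as an RI event's
        # primary interval; mirror that so manifest and pipeline keys agree
        primary = self.standardized if self.event_type == "RI" else self.rmats_primary
        return (
            self.event_type,
            self.contig,
            primary,
            self.rmats_flanks,
            self.whippet_interval,
        )


@dataclass
class PlannedSite:
    site_id: str
    aon_name: str
    gene_id: str
    contig: str
    distance: int
    mode: str  # intended | linked | exon_border | unlinked
    genomic_interval: tuple[int, int] = (0, 0)
    local_interval: tuple[int, int] = (0, 0)
    linked_event_id: Optional[str] = None


@dataclass
class TruthManifest:
    """Ground truth of one synthetic study."""

    seed: int
    config: ScenarioConfig
    sites: list[PlannedSite]
    events: list[PlannedEvent]
    comparisons: dict[str, dict]  # name -> {"targeting":..., "scrambled":...}
    schema_version: int = MANIFEST_SCHEMA_VERSION

    def events_in(self, comparison: str, kinds: Sequence[str] = DETECTABLE_KINDS):
        return [
            e
            for e in self.events
            if comparison in e.comparisons
            and e.kind in kinds
            and set(e.tools) == {"rmats", "whippet"}
        ]

    def intended_event(self, comparison: str) -> Optional[PlannedEvent]:
        for e in self.events:
            if e.kind == "intended" and comparison in e.comparisons:
                return e
        return None

    def hybdep_keys(self, comparison: str) -> set[tuple]:
        return {
            e.identity_key
            for e in self.events_in(comparison)
            if e.kind in ("intended", "linked")
        }

    def expected_summary(self, comparison: str) -> dict:
        evs = self.events_in(comparison)
        intended = self.intended_event(comparison)
        by_type: dict[str, int] = {}
        for e in evs:
            by_type[e.event_type] = by_type.get(e.event_type, 0) + 1
        spec = [e for e in evs if e.kind != "shared"]
        return {
            "total": len(evs),
            "specific": len(spec),
            "matched_targeting_all": sum(e.kind in ("intended", "linked") for e in evs),
            "matched_targeting_specific": sum(
                e.kind in ("intended", "linked") for e in spec
            ),
            "matched_scrambled_all": sum(e.kind == "scr_linked" for e in evs),
            "matched_scrambled_specific": sum(e.kind == "scr_linked" for e in spec),
            "hybridization_dependent": sum(
                e.kind in ("intended", "linked") for e in evs
            ),
            "larger_than_intended": 0
            if intended is None
            else sum(
                abs(e.dpsi) > abs(intended.dpsi) for e in evs if e.kind != "intended"
            ),
            "by_type": by_type,
        }


# ---------------------------------------------------------------------------
# genome simulation


def simulate_genome(
    n_genes: int, config: ScenarioConfig, seed_seq: np.random.SeedSequence
) -> tuple[dict[str, str], GenomeAnnotation]:
    """Random multi-exon genes laid out without overlap across contigs."""
    rng = np.random.default_rng(seed_seq)
    per_contig = -(-n_genes // config.n_contigs)  # ceil
    genomes: dict[str, list[str]] = {}
    genes: list[GeneModel] = []
    gi = 0
    for ci in range(config.n_contigs):
        contig = f"chr{ci + 1}"
        pieces: list[str] = []
        cursor = 0
        for _ in range(min(per_contig, n_genes - gi)):
            gap = int(rng.integers(*config.intergenic))
            pieces.append(_random_seq(rng, gap))
            cursor += gap
            n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            exons = []
            start = cursor
            for k in range(n_exons):
                elen = int(rng.integers(*config.exon_length))
                exons.append((cursor, cursor + elen))
                pieces.append(_random_seq(rng, elen))
                cursor += elen
                if k < n_exons - 1:
                    ilen = int(rng.integers(*config.intron_length))
                    pieces.append(_random_seq(rng, ilen))
                    cursor += ilen
            gi += 1
            gene_id = f"G{gi:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            tx = TranscriptModel(f"{gene_id}.t1", tuple(exons), frozenset({"basic"}))
            genes.append(
                GeneModel(gene_id, f"SYM{gi:04d}", contig, strand, (start, cursor), (tx,))
            )
        pieces.append(_random_seq(rng, int(rng.integers(*config.intergenic))))
        genomes[contig] = pieces
    contigs = {c: "".join(p) for c, p in genomes.items()}
    anno = GenomeAnnotation(
        genes=genes, contig_lengths={c: len(s) for c, s in contigs.items()}
    )
    anno.validate()
    return contigs, anno


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# site planting


def _levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _mutate_to_distance(
    seq: str, d: int, rng: np.random.Generator, budget: int = 200
) -> str:
    """A variant of *seq* at exact unit-cost edit distance *d*."""
    bases = "ACGT"
    for _ in range(budget):
        s = list(seq)
        for _ in range(d):
            op = rng.choice(["sub", "ins", "del"], p=[0.7, 0.15, 0.15])
            i = int(rng.integers(0, len(s)))
            if op == "sub":
                s[i] = rng.choice([c for c in bases if c != s[i]])
            elif op == "ins":
                s.insert(i, rng.choice(list(bases)))
            elif len(s) > 1:
                del s[i]
        variant = "".join(s)
        if _levenshtein(seq, variant) == d:
            return variant
    raise GenerationError(f"could not build a distance-{d} variant of {seq!r}")


class _GenomeEditor:
    """Mutable contigs plus an occupied/protected interval registry."""

    def __init__(self, contigs: dict[str, str], anno: GenomeAnnotation):
        self.contigs = {c: bytearray(s, "ascii") for c, s in contigs.items()}
        self.anno = anno
        self.records = {r.gene_id: r for r in extract_prespliced(anno, contigs)}
        self.protected: dict[str, list[tuple[int, int]]] = {}

    def _refresh(self, gene_id: str) -> None:
        g = self.anno.by_id(gene_id)
        contig = self.contigs[g.contig].decode("ascii")
        self.records[gene_id] = extract_prespliced(
            GenomeAnnotation([g], {g.contig: len(contig)}), {g.contig: contig}
        )[0]

    def write_sense(self, gene_id: str, local_start: int, seq: str) -> tuple[int, int]:
        """Write *seq* at a gene-local sense offset; returns the genomic interval."""
        rec = self.records[gene_id]
        gs, ge = gene_offset_to_genomic(rec, (local_start, local_start + len(seq)))
        if rec.strand == "-":
            from Bio.Seq import Seq

            seq = str(Seq(seq).reverse_complement())
        for lo, hi in self.protected.get(rec.contig, []):
            if gs < hi and lo < ge:
                raise GenerationError(
                    f"planted site at {rec.contig}:{gs}-{ge} collides with an "
                    "already-planted locus"
                )
        self.contigs[rec.contig][gs:ge] = seq.encode("ascii")
        self._refresh(gene_id)
        return (gs, ge)

    def protect(self, contig: str, interval: tuple[int, int], margin: int) -> None:
        self.protected.setdefault(contig, []).append(
            (interval[0] - margin, interval[1] + margin)
        )

    def is_protected(self, contig: str, pos: int) -> bool:
        return any(lo <= pos < hi for lo, hi in self.protected.get(contig, []))

    def point_mutate(
        self,
        contig: str,
        pos: int,
        rng: np.random.Generator,
        avoid: str = "",
    ) -> None:
        cur = chr(self.contigs[contig][pos])
        choices = [c for c in "ACGT" if c != cur and c not in avoid]
        self.contigs[contig][pos] = ord(rng.choice(choices))

    def finish(self) -> dict[str, str]:
        return {c: b.decode("ascii") for c, b in self.contigs.items()}


def _verify_planted(
    editor: _GenomeEditor, site: PlannedSite, query: str, max_distance: int
) -> bool:
    """True iff the scan of the site's gene yields this locus at its distance."""
    rec = editor.records[site.gene_id]
    hits = scan_record(query, rec, max_distance)
    for h in hits:
        if (h.start, h.end) == site.local_interval:
            return h.distance == site.distance
    return False


def plant_sites(
    editor: _GenomeEditor,
    aons: Sequence[AONRecord],
    placements: Sequence[tuple[PlannedSite, tuple[int, int]]],
    seed_seq: np.random.SeedSequence,
    max_distance: int = 3,
) -> list[PlannedSite]:
    """Write each planned site into the genome at its exact edit distance.

    *placements* pairs each :class:`PlannedSite` with the gene-local interval
    (lo, hi) within which its start offset is chosen.  Each planted locus is
    re-verified by a scan of its gene; variants are rejection-sampled until
    the realized minimal distance equals the requested one.
    """
    rng = np.random.default_rng(seed_seq)
    targets = {a.name: target_sequence(a) for a in aons}
    planted: list[PlannedSite] = []
    for site, (lo, hi) in placements:
        query = targets[site.aon_name]
        rec = editor.records[site.gene_id]
        ok = False
        for _ in range(80):
            variant = (
                query if site.distance == 0
                else _mutate_to_distance(query, site.distance, rng)
            )
            if hi - len(variant) < lo:
                raise GenerationError(
                    f"site {site.site_id}: placement window {lo}-{hi} too small"
                )
            start = int(rng.integers(lo, hi - len(variant) + 1))
            local_iv = (start, start + len(variant))
            try:
                ginterval = editor.write_sense(site.gene_id, start, variant)
            except GenerationError:
                continue  # collided with an earlier site; try another offset
            site.local_interval = local_iv
            site.genomic_interval = ginterval
            if _verify_planted(editor, site, query, max_distance):
                ok = True
                break
            # undo by overwriting with fresh random sequence and retrying
            editor.write_sense(
                site.gene_id, start, _random_seq(rng, len(variant))
            )
        if not ok:
            raise GenerationError(
                f"site {site.site_id}: could not realize distance {site.distance}"
            )
        editor.protect(rec.contig, site.genomic_interval, max_distance + 2)
        planted.append(site)
    return planted


def scrub_background(
    editor: _GenomeEditor,
    aons: Sequence[AONRecord],
    planted: Sequence[PlannedSite],
    seed_seq: np.random.SeedSequence,
    max_distance: int = 3,
    max_rounds: int = 30,
) -> int:
    """Point-mutate away every accidental (non-planted) approximate match.

    Returns the number of mutations applied.  Planted loci are protected; a
    background hit that cannot be mutated without touching one is a
    generation error (in practice the AON sequences are mutually distant).
    """
    rng = np.random.default_rng(seed_seq)
    targets = {a.name: target_sequence(a) for a in aons}
    planted_by_aon: dict[str, set[tuple[str, tuple[int, int]]]] = {}
    for s in planted:
        planted_by_aon.setdefault(s.aon_name, set()).add((s.gene_id, s.local_interval))
    n_mut = 0
    for _ in range(max_rounds):
        dirty = False
        for aon in aons:
            query = targets[aon.name]
            expected = planted_by_aon.get(aon.name, set())
            for gene_id, rec in sorted(editor.records.items()):
                for hit in scan_record(query, rec, max_distance):
                    if any(
                        g == gene_id and hit.start < iv[1] and iv[0] < hit.end
                        for g, iv in expected
                    ):
                        continue
                    dirty = True
                    # walk the trace to find matched local positions and the
                    # query base aligned to each; mutating a match away from
                    # both bases strictly lowers this alignment's similarity
                    matched: list[tuple[int, str]] = []  # (local text pos, query char)
                    qi, ti = 0, hit.start
                    for op in hit.trace:
                        if op == "=":
                            matched.append((ti, query[qi]))
                        if op in "=XI":
                            ti += 1
                        if op in "=XD":
                            qi += 1
                    mid_local = (hit.start + hit.end) // 2
                    matched.sort(key=lambda m: abs(m[0] - mid_local))
                    for local_pos, qchar in matched:
                        gpos = gene_offset_to_genomic(rec, (local_pos, local_pos + 1))[0]
                        if editor.is_protected(rec.contig, gpos):
                            continue
                        avoid = qchar
                        if rec.strand == "-":
                            avoid = _RC.get(qchar, "")
                        editor.point_mutate(rec.contig, gpos, rng, avoid=avoid)
                        n_mut += 1
                        break
                    else:
                        raise GenerationError(
                            f"background hit in {gene_id} at {hit.start}-{hit.end} "
                            "has no mutable matched position"
                        )
                    editor._refresh(gene_id)
        if not dirty:
            return n_mut
    raise GenerationError("background scrubbing did not converge")


# ---------------------------------------------------------------------------
# splicing-output simulation


def _psi_to_count_p(psi: float) -> float:
    # inverse of the length-normalized PSI with IncFormLen = 2 * SkipFormLen
    return 2.0 * psi / (1.0 + psi)


def _normalized_psi(ijc: float, sjc: float) -> Optional[float]:
    inc = ijc / INC_FORM_LEN
    skip = sjc / SKIP_FORM_LEN
    if inc + skip == 0:
        return None
    return inc / (inc + skip)


def _draw_counts(
    rng: np.random.Generator, psi: float, depth: int, n: int, rho: Optional[float]
) -> np.ndarray:
    p = _psi_to_count_p(psi)
    if rho is None or rho <= 0:
        return rng.binomial(depth, p, size=n)
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    ps = rng.beta(a, b, size=n)
    return rng.binomial(depth, ps)


def simulate_splicing_outputs(
    events: Sequence[PlannedEvent],
    comparison: str,
    outdir: Path,
    config: ScenarioConfig,
    seed_seq: np.random.SeedSequence,
) -> None:
    """Write the rMATS SE/A5SS/A3SS/RI tables and the Whippet ``.diff`` for
    one scrambled-vs-targeting comparison."""
    rng = np.random.default_rng(seed_seq)
    outdir.mkdir(parents=True, exist_ok=True)
    n = config.replicates
    rho = config.overdispersion

    comp_events = sorted(
        (e for e in events if comparison in e.comparisons),
        key=lambda e: (e.event_type, e.contig, e.rmats_primary, e.event_id),
    )

    rmats_rows: dict[str, list[dict]] = {t: [] for t in ("SE", "A5SS", "A3SS", "RI")}
    whippet_rows: list[dict] = []
    node_counter = 0

    for ev in comp_events:
        node_counter += 1
        # --- rMATS side: per-replicate junction counts
        if "rmats" in ev.tools:
            i1 = _draw_counts(rng, ev.psi_scr, ev.depth, n, rho)
            i2 = _draw_counts(rng, ev.psi_targ, ev.depth, n, rho)
            s1, s2 = ev.depth - i1, ev.depth - i2
            psi1 = [_normalized_psi(a, b) for a, b in zip(i1, s1)]
            psi2 = [_normalized_psi(a, b) for a, b in zip(i2, s2)]
            mean1 = float(np.mean([p for p in psi1 if p is not None]))
            mean2 = float(np.mean([p for p in psi2 if p is not None]))
            table = [[int(i1.sum()), int(s1.sum())], [int(i2.sum()), int(s2.sum())]]
            pvalue = float(fisher_exact(table, alternative="two-sided")[1])
            rmats_rows[ev.event_type].append(
                {
                    "event": ev,
                    "ijc1": i1,
                    "sjc1": s1,
                    "ijc2": i2,
                    "sjc2": s2,
                    "psi1": psi1,
                    "psi2": psi2,
                    "inc_diff": mean1 - mean2,
                    "pvalue": pvalue,
                }
            )
        # --- Whippet side: pooled counts, bootstrap probability
        if "whippet" in ev.tools:
            total = ev.depth * n
            ia = int(_draw_counts(rng, ev.psi_scr, total, 1, rho)[0])
            ib = int(_draw_counts(rng, ev.psi_targ, total, 1, rho)[0])
            psi_a = _normalized_psi(ia, total - ia)
            psi_b = _normalized_psi(ib, total - ib)
            delta = psi_a - psi_b
            ref_sign = np.sign(ev.dpsi) if ev.dpsi != 0 else np.sign(delta)
            wins = 0
            for _ in range(config.bootstrap_samples):
                ia_b = rng.binomial(total, ia / total)
                ib_b = rng.binomial(total, ib / total)
                d_b = _normalized_psi(ia_b, total - ia_b) - _normalized_psi(
                    ib_b, total - ib_b
                )
                if d_b != 0 and np.sign(d_b) == ref_sign:
                    wins += 1
            prob = wins / config.bootstrap_samples
            whippet_rows.append(
                {
                    "event": ev,
                    "node": node_counter,
                    "psi_a": psi_a,
                    "psi_b": psi_b,
                    "delta": delta,
                    "prob": prob,
                }
            )

    for etype, rows in rmats_rows.items():
        _write_rmats_file(outdir / f"{etype}.MATS.JC.txt", etype, rows)
    _write_whippet_file(outdir / "whippet.diff", whippet_rows)


_RMATS_HEADER_CORE = [
    "ID", "GeneID", "geneSymbol", "chr", "strand",
]
_RMATS_HEADER_TAIL = [
    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
    "IncFormLen", "SkipFormLen", "PValue", "FDR",
    "IncLevel1", "IncLevel2", "IncLevelDifference",
]
_RMATS_COORD_COLS = {
    "SE": ["exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"],
    "A5SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"],
    "A3SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
             "flankingES", "flankingEE"],
    "RI": ["riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE",
           "downstreamES", "downstreamEE"],
}


def _fmt_psi(values: Sequence[Optional[float]]) -> str:
    return ",".join("NA" if v is None else f"{v:.3f}" for v in values)


def _write_rmats_file(path: Path, etype: str, rows: list[dict]) -> None:
    pvals = [r["pvalue"] for r in rows]
    fdr = multipletests(pvals, method="fdr_bh")[1] if rows else []
    header = _RMATS_HEADER_CORE + _RMATS_COORD_COLS[etype] + _RMATS_HEADER_TAIL
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for idx, r in enumerate(rows):
            ev: PlannedEvent = r["event"]
            if etype == "SE":
                coords = [*ev.rmats_primary, *ev.rmats_flanks[0], *ev.rmats_flanks[1]]
            elif etype in ("A5SS", "A3SS"):
                coords = [*ev.rmats_primary, *ev.rmats_short, *ev.rmats_flanks[0]]
            else:  # RI
                coords = [*ev.rmats_primary, *ev.rmats_flanks[0], *ev.rmats_flanks[1]]
            fields = [
                str(idx), ev.gene_id, ev.symbol, ev.contig, ev.strand,
                *[str(c) for c in coords],
                ",".join(map(str, r["ijc1"])), ",".join(map(str, r["sjc1"])),
                ",".join(map(str, r["ijc2"])), ",".join(map(str, r["sjc2"])),
                str(INC_FORM_LEN), str(SKIP_FORM_LEN),
                f"{r['pvalue']:.6g}", f"{fdr[idx]:.6g}",
                _fmt_psi(r["psi1"]), _fmt_psi(r["psi2"]),
                f"{r['inc_diff']:.3f}",
            ]
            fh.write("\t".join(fields) + "\n")


_WHIPPET_TYPE = {"SE": "CE", "A5SS": "AD", "A3SS": "AA", "RI": "RI"}


def _write_whippet_file(path: Path, rows: list[dict]) -> None:
    header = ["Gene", "Node", "Coord", "Strand", "Type",
              "Psi_A", "Psi_B", "DeltaPsi", "Probability"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            ev: PlannedEvent = r["event"]
            lo, hi = ev.whippet_interval
            fields = [
                ev.gene_id, str(r["node"]),
                f"{ev.contig}:{lo + 1}-{hi}",  # half-open -> 1-based inclusive
                ev.strand, _WHIPPET_TYPE[ev.event_type],
                f"{r['psi_a']:.5f}", f"{r['psi_b']:.5f}",
                f"{r['delta']:.5f}", f"{r['prob']:.3f}",
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# scenario orchestration


def _event_coords(gene: GeneModel, etype: str, k: int = 2) -> dict:
    """Coordinates of one planted event around exon *k* of *gene*."""
    exons = gene.exons
    if len(exons) < k + 2:
        raise GenerationError(f"gene {gene.gene_id} too short for an event at exon {k}")
    up, exon, down = exons[k - 1], exons[k], exons[k + 1]
    if etype == "SE":
        return dict(primary=exon, flanks=(up, down), short=None,
                    whippet=exon, standardized=exon)
    if etype == "A5SS":
        long_iv = (exon[0], exon[1] + 40)
        region = (exon[1], exon[1] + 40)
        return dict(primary=long_iv, flanks=(down,), short=exon,
                    whippet=region, standardized=region)
    if etype == "A3SS":
        long_iv = (exon[0] - 40, exon[1])
        region = (exon[0] - 40, exon[0])
        return dict(primary=long_iv, flanks=(up,), short=exon,
                    whippet=region, standardized=region)
    if etype == "RI":
        ri = (exon[0], down[1])
        intron = (exon[1], down[0])
        return dict(primary=ri, flanks=(exon, down), short=None,
                    whippet=intron, standardized=intron)
    raise ValueError(etype)


@dataclass
class Scenario:
    """A fully planned synthetic study, before file writing."""

    config: ScenarioConfig
    seed: int
    contigs: dict[str, str]
    annotation: GenomeAnnotation
    aons: list[AONRecord]
    manifest: TruthManifest


def build_scenario(config: ScenarioConfig, seed: int) -> Scenario:
    """Plan and generate a complete synthetic study in memory."""
    root = np.random.SeedSequence(seed)
    ss_genome, ss_sites, ss_scrub, ss_events = root.spawn(4)

    targeting = config.targeting_names()
    scrambled = config.scrambled_name()
    comparisons = {t: {"targeting": t, "scrambled": scrambled} for t in targeting}

    # ---- allocate genes: one per event, plus decoys
    per_comp = (
        1  # intended
        + config.n_linked
        + config.n_unlinked
        + config.n_scr_linked
        + config.n_rmats_only
        + config.n_whippet_only
        + config.n_null
        + config.n_low_coverage
    )
    extra = config.toxic_extra_unlinked if config.toxic_aon in targeting else 0
    n_event_genes = per_comp * len(targeting) + extra + config.n_shared
    n_genes = n_event_genes + config.n_decoy_genes
    contigs, anno = simulate_genome(n_genes, config, ss_genome)

    gene_iter = iter(anno.genes)

    def next_gene() -> GeneModel:
        try:
            return next(gene_iter)
        except StopIteration:  # pragma: no cover - arithmetic above prevents it
            raise GenerationError("ran out of genes for the event roster")

    events: list[PlannedEvent] = []
    sites: list[PlannedSite] = []
    placements: list[tuple[PlannedSite, tuple[int, int]]] = []
    type_cycle = config.event_type_cycle
    eid = 0
    sid = 0

    def add_event(kind, etype, gene, comps, tools, psi_scr, dpsi, depth) -> PlannedEvent:
        nonlocal eid
        eid += 1
        if dpsi < 0:
            # inclusion increases under the targeting AON: start from a low
            # scrambled baseline so both group PSIs stay inside [0, 1]
            psi_scr = round(1.0 - psi_scr, 6)
        if not (0.0 <= psi_scr <= 1.0 and 0.0 <= psi_scr - dpsi <= 1.0):
            raise ConfigurationError(
                f"event psi out of range: psi_scr={psi_scr}, dpsi={dpsi}"
            )
        c = _event_coords(gene, etype)
        ev = PlannedEvent(
            event_id=f"E{eid:04d}", kind=kind, event_type=etype,
            gene_id=gene.gene_id, symbol=gene.symbol, contig=gene.contig,
            strand=gene.strand, comparisons=tuple(comps), tools=tuple(tools),
            psi_scr=psi_scr, dpsi=dpsi, depth=depth,
            rmats_primary=c["primary"], rmats_flanks=c["flanks"],
            rmats_short=c["short"], whippet_interval=c["whippet"],
            standardized=c["standardized"],
        )
        events.append(ev)
        return ev

    def add_site(aon, gene, distance, mode, event=None) -> PlannedSite:
        nonlocal sid
        sid += 1
        site = PlannedSite(
            site_id=f"S{sid:04d}", aon_name=aon, gene_id=gene.gene_id,
            contig=gene.contig, distance=distance, mode=mode,
            linked_event_id=event.event_id if event else None,
        )
        sites.append(site)
        return site

    def cyc(vals, i):
        return vals[i % len(vals)]

    both = ("rmats", "whippet")
    qlen = max(len(seq) for _, seq, _ in config.aons)

    # shared background events: identical rows in every comparison
    for i in range(config.n_shared):
        g = next_gene()
        add_event("shared", cyc(type_cycle, i), g, targeting, both,
                  config.baseline_scr_psi, cyc(config.shared_dpsis, i), config.depth)

    for comp in targeting:
        target_gene = next_gene()
        intended = add_event("intended", "SE", target_gene, [comp], both,
                             config.intended_scr_psi, config.intended_dpsi,
                             config.depth)
        # intended binding site straddles the skipped exon's upstream boundary
        site = add_site(comp, target_gene, 0, "intended", intended)
        rec_gene = target_gene
        placements.append(
            (site, _exon_border_window(rec_gene, intended, anno, contigs, qlen))
        )
        for i in range(config.n_linked):
            g = next_gene()
            ev = add_event("linked", "SE", g, [comp], both,
                           config.baseline_scr_psi, cyc(config.linked_dpsis, i),
                           config.depth)
            mode = "exon_border" if i == 0 else "linked"
            site = add_site(comp, g, cyc(config.linked_distances, i), mode, ev)
            if mode == "exon_border":
                window = _exon_border_window(g, ev, anno, contigs, qlen)
            else:
                window = _intron_window(g, ev, anno, contigs, qlen)
            placements.append((site, window))
        n_unl = config.n_unlinked + (extra if comp == config.toxic_aon else 0)
        for i in range(n_unl):
            g = next_gene()
            add_event("unlinked", cyc(type_cycle, i + 1), g, [comp], both,
                      config.baseline_scr_psi, cyc(config.unlinked_dpsis, i),
                      config.depth)
        for i in range(config.n_scr_linked):
            g = next_gene()
            ev = add_event("scr_linked", "SE", g, [comp], both,
                           config.baseline_scr_psi, cyc(config.scr_linked_dpsis, i),
                           config.depth)
            site = add_site(scrambled, g, 3, "linked", ev)
            placements.append((site, _intron_window(g, ev, anno, contigs, qlen)))
        for i in range(config.n_rmats_only):
            g = next_gene()
            add_event("rmats_only", "SE", g, [comp], ("rmats",),
                      config.baseline_scr_psi, cyc(config.fp_dpsis, i), config.depth)
        for i in range(config.n_whippet_only):
            g = next_gene()
            add_event("whippet_only", "SE", g, [comp], ("whippet",),
                      config.baseline_scr_psi, cyc(config.fp_dpsis, i), config.depth)
        for i in range(config.n_null):
            g = next_gene()
            add_event("null", "SE", g, [comp], both,
                      config.null_psi, 0.0, config.depth)
        for i in range(config.n_low_coverage):
            g = next_gene()
            add_event("low_coverage", "SE", g, [comp], ("rmats",),
                      config.baseline_scr_psi, 0.35, config.low_coverage_depth)

    # unlinked decoy sites, far from every linkage window, in decoy genes
    decoy_genes = [next_gene() for _ in range(config.n_decoy_genes)]
    aon_order = [name for name, _, _ in config.aons]
    for d, count in sorted(config.decoy_sites.items()):
        for i in range(count):
            for j, aon_name in enumerate(aon_order):
                g = decoy_genes[(d * 7 + i * len(aon_order) + j) % len(decoy_genes)]
                site = add_site(aon_name, g, d, "unlinked")
                placements.append((site, (0, len_of(g))))

    aons = _aon_records(config, events)

    # ---- edit the genome
    editor = _GenomeEditor(contigs, anno)
    planted = plant_sites(editor, aons, placements, ss_sites, config.max_distance)
    scrub_background(editor, aons, planted, ss_scrub, config.max_distance)
    for site in planted:  # re-verify after scrubbing: scan and oracle agree
        query = target_sequence(next(a for a in aons if a.name == site.aon_name))
        if not _verify_planted(editor, site, query, config.max_distance):
            raise GenerationError(f"site {site.site_id} corrupted by scrubbing")
        rec = editor.records[site.gene_id]
        ctx_lo = max(0, site.local_interval[0] - 2 * config.max_distance)
        ctx_hi = min(len(rec), site.local_interval[1] + 2 * config.max_distance)
        hits = brute_force_oracle(query, rec.sequence[ctx_lo:ctx_hi], config.max_distance)
        if not any(h.distance == site.distance for h in hits):
            raise GenerationError(f"site {site.site_id} fails the oracle check")
    final_contigs = editor.finish()

    manifest = TruthManifest(
        seed=seed, config=config, sites=planted, events=events,
        comparisons=comparisons,
    )
    return Scenario(config, seed, final_contigs, anno, aons, manifest)


def len_of(gene: GeneModel) -> int:
    return gene.span[1] - gene.span[0]


def _exon_border_window(
    gene: GeneModel, ev: PlannedEvent, anno: GenomeAnnotation,
    contigs: dict[str, str], qlen: int,
) -> tuple[int, int]:
    """Gene-local window straddling the event exon's sense-upstream boundary."""
    rec = extract_prespliced(
        GenomeAnnotation([gene], {gene.contig: len(contigs[gene.contig])}),
        {gene.contig: contigs[gene.contig]},
    )[0]
    lo, hi = genomic_to_gene_offset(rec, ev.standardized)
    return (lo - 8, lo - 8 + qlen + 4)


def _intron_window(
    gene: GeneModel, ev: PlannedEvent, anno: GenomeAnnotation,
    contigs: dict[str, str], qlen: int,
) -> tuple[int, int]:
    """Gene-local window in the intron between the upstream flank and the exon."""
    rec = extract_prespliced(
        GenomeAnnotation([gene], {gene.contig: len(contigs[gene.contig])}),
        {gene.contig: contigs[gene.contig]},
    )[0]
    flank_iv = genomic_to_gene_offset(rec, ev.rmats_flanks[0])
    exon_iv = genomic_to_gene_offset(rec, ev.rmats_primary)
    lo = min(flank_iv[1], exon_iv[1], flank_iv[0], exon_iv[0])
    hi = max(flank_iv[0], exon_iv[0], flank_iv[1], exon_iv[1])
    # the intron between the two: tightest gap between the intervals
    gap_lo = min(flank_iv[1], exon_iv[1])
    gap_hi = max(flank_iv[0], exon_iv[0])
    if gap_hi - gap_lo < qlen + 20:
        return (lo, hi)
    return (gap_lo + 8, gap_hi - 8)


def _aon_records(config: ScenarioConfig, events: Sequence[PlannedEvent]) -> list[AONRecord]:
    intended_by_comp = {
        e.comparisons[0]: e for e in events if e.kind == "intended"
    }
    records = []
    for name, seq, role in config.aons:
        descriptor = None
        if role == "targeting" and name in intended_by_comp:
            ev = intended_by_comp[name]
            descriptor = TargetDescriptor(ev.gene_id, "SE", ev.standardized)
        records.append(AONRecord(name, seq, role, descriptor))
    return records


def simulate_scenario(config: ScenarioConfig, seed: int, outdir: str | Path) -> Scenario:
    """Generate the full synthetic file tree under *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = build_scenario(config, seed)
    ann.write_fasta(scenario.contigs, outdir / "genome.fa")
    ann.write_gtf(scenario.annotation, outdir / "annotation.gtf")
    write_aon_table(scenario.aons, outdir / "aons.tsv")

    root = np.random.SeedSequence(seed)
    _, _, _, ss_events = root.spawn(4)
    comp_seeds = ss_events.spawn(len(scenario.manifest.comparisons))
    for (comp, _), ss in zip(sorted(scenario.manifest.comparisons.items()), comp_seeds):
        simulate_splicing_outputs(
            scenario.manifest.events, comp, outdir / "comparisons" / comp,
            config, ss,
        )
    write_manifest(scenario.manifest, outdir / "manifest.json")
    return scenario


# ---------------------------------------------------------------------------
# manifest I/O


def write_manifest(manifest: TruthManifest, path: str | Path) -> None:
    doc = {
        "schema_version": manifest.schema_version,
        "seed": manifest.seed,
        "config": manifest.config.to_dict(),
        "comparisons": manifest.comparisons,
        "sites": [dataclasses.asdict(s) for s in manifest.sites],
        "events": [dataclasses.asdict(e) for e in manifest.events],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _tup(x):
    if isinstance(x, list):
        return tuple(_tup(v) for v in x)
    return x


def read_manifest(path: str | Path) -> TruthManifest:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != MANIFEST_SCHEMA_VERSION:
        raise FormatError(
            f"manifest {path}: schema version {doc.get('schema_version')} != "
            f"{MANIFEST_SCHEMA_VERSION}"
        )
    sites = [
        PlannedSite(**{k: _tup(v) for k, v in s.items()}) for s in doc["sites"]
    ]
    events = [
        PlannedEvent(**{k: _tup(v) for k, v in e.items()}) for e in doc["events"]
    ]
    return TruthManifest(
        seed=doc["seed"],
        config=ScenarioConfig.from_dict(doc["config"]),
        sites=sites,
        events=events,
        comparisons=doc["comparisons"],
    )


# ---------------------------------------------------------------------------
# ready-made scenario variants used by tests and the acceptance analysis


def default_scenario(depth: int = 100, replicates: int = 6) -> ScenarioConfig:
    return ScenarioConfig(depth=depth, replicates=replicates)


def consensus_scenario(
    n_shared_tools: int = 50, n_rmats_only: int = 20, n_whippet_only: int = 20,
    depth: int = 100,
) -> ScenarioConfig:
    """One comparison; events seen by both tools vs tool-specific ones."""
    rng_dpsis = tuple(
        round(x, 2)
        for x in np.linspace(0.25, 0.6, n_shared_tools // 2).tolist()
        + (-np.linspace(0.25, 0.6, n_shared_tools - n_shared_tools // 2)).tolist()
    )
    return ScenarioConfig(
        aons=(DEFAULT_AONS[0], DEFAULT_AONS[3]),
        n_linked=0, n_scr_linked=0, n_shared=0,
        n_unlinked=n_shared_tools - 1,  # +1 intended event
        unlinked_dpsis=rng_dpsis,
        n_rmats_only=n_rmats_only, n_whippet_only=n_whippet_only,
        n_low_coverage=0, toxic_aon=None,
        decoy_sites={}, n_decoy_genes=2,
        event_type_cycle=("SE",),
        depth=depth,
    )


def calibration_scenario(n_events: int = 50, dpsi: float = 0.40, depth: int = 100) -> ScenarioConfig:
    return ScenarioConfig(
        aons=(DEFAULT_AONS[0], DEFAULT_AONS[3]),
        n_linked=0, n_scr_linked=0, n_shared=0,
        n_unlinked=n_events - 1,
        unlinked_dpsis=(dpsi,), intended_dpsi=dpsi,
        baseline_scr_psi=0.95,
        n_rmats_only=0, n_whippet_only=0, n_low_coverage=0,
        toxic_aon=None, decoy_sites={}, n_decoy_genes=2,
        event_type_cycle=("SE",),
        depth=depth,
    )


def null_scenario(n_events: int = 200, depth: int = 100) -> ScenarioConfig:
    return ScenarioConfig(
        aons=(DEFAULT_AONS[0], DEFAULT_AONS[3]),
        n_linked=0, n_scr_linked=0, n_shared=0, n_unlinked=0,
        n_rmats_only=0, n_whippet_only=0, n_low_coverage=0,
        n_null=n_events,
        toxic_aon=None, decoy_sites={}, n_decoy_genes=2,
        event_type_cycle=("SE",),
        depth=depth,
    )


def site_recovery_scenario(total_sites: int = 100) -> ScenarioConfig:
    """Many decoy sites across distances 0-3 (site-recovery stress shape)."""
    per_aon = total_sites // 4  # 4 AONs
    base = per_aon // 4
    rem = per_aon - 3 * base
    return ScenarioConfig(
        n_linked=0, n_scr_linked=0, n_shared=0, n_unlinked=0,
        n_rmats_only=0, n_whippet_only=0, n_low_coverage=0,
        toxic_aon=None,
        decoy_sites={0: base, 1: base, 2: base, 3: rem},
        n_decoy_genes=26,
        event_type_cycle=("SE",),
    )
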