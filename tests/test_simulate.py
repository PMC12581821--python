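"""Synthetic-data generator: determinism, self-consistency, planted truth."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from spliceoff.annotation import extract_prespliced, read_genome, read_gtf
from spliceoff.errors import ConfigurationError, FormatError
from spliceoff.events import EVENT_TYPES, read_rmats, read_whippet
from spliceoff.scanner import AONRecord, brute_force_oracle, target_sequence
from spliceoff.simulate import (
    ScenarioConfig,
    build_scenario,
    calibration_scenario,
    read_manifest,
    simulate_scenario,
    write_manifest,
)

SMALL = ScenarioConfig(
    aons=(
        ("T-AON", "CUUCUGCAAAGAACACCUUG", "targeting"),
        ("S-AON", "UCAUUUGCUUCAUACAGG", "scrambled"),
    ),
    n_linked=1, n_unlinked=2, n_scr_linked=1, n_shared=0,
    n_rmats_only=1, n_whippet_only=1, n_low_coverage=1,
    toxic_aon=None, n_decoy_genes=3,
    decoy_sites={2: 1, 3: 1},
    event_type_cycle=("SE", "A5SS"),
)


def _tree_hashes(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


@pytest.fixture(scope="module")
def small_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("small")
    simulate_scenario(SMALL, 13, out)
    return out


class TestDeterminism:
    def test_same_seed_gives_byte_identical_tree(self, tmp_path, small_dir):
        other = tmp_path / "again"
        simulate_scenario(SMALL, 13, other)
        assert _tree_hashes(other) == _tree_hashes(small_dir)

    def test_different_seed_differs(self, tmp_path, small_dir):
        other = tmp_path / "other"
        simulate_scenario(SMALL, 14, other)
        assert _tree_hashes(other) != _tree_hashes(small_dir)


class TestGenomeAndAnnotation:
    def test_gtf_roundtrips_through_reader(self, small_dir):
        anno = read_gtf(small_dir / "annotation.gtf")
        genome = read_genome(small_dir / "genome.fa")
        anno.contig_lengths = {c: len(s) for c, s in genome.items()}
        anno.validate()  # exons within contigs, transcripts within genes
        manifest = read_manifest(small_dir / "manifest.json")
        assert {g.gene_id for g in anno.genes} >= {
            e.gene_id for e in manifest.events
        }

    def test_introns_can_host_an_aon(self, small_dir):
        anno = read_gtf(small_dir / "annotation.gtf")
        qlen = 20
        for g in anno.genes:
            exons = g.exons
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                assert s2 - e1 >= 2 * qlen


class TestPlantedSites:
    def test_every_site_verified_by_oracle(self, small_dir):
        manifest = read_manifest(small_dir / "manifest.json")
        genome = read_genome(small_dir / "genome.fa")
        anno = read_gtf(small_dir / "annotation.gtf")
        records = {r.gene_id: r for r in extract_prespliced(anno, genome)}
        targets = {
            name: target_sequence(AONRecord(name, seq, role))
            for name, seq, role in manifest.config.aons
        }
        for s in manifest.sites:
            rec = records[s.gene_id]
            ctx_lo = max(0, s.local_interval[0] - 6)
            ctx_hi = min(len(rec), s.local_interval[1] + 6)
            hits = brute_force_oracle(
                targets[s.aon_name], rec.sequence[ctx_lo:ctx_hi], 3
            )
            assert any(h.distance == s.distance for h in hits), s.site_id

    def test_sites_listed_once_and_linked_events_exist(self, small_dir):
        manifest = read_manifest(small_dir / "manifest.json")
        ids = [s.site_id for s in manifest.sites]
        assert len(ids) == len(set(ids))
        event_ids = {e.event_id for e in manifest.events}
        for s in manifest.sites:
            if s.linked_event_id is not None:
                assert s.linked_event_id in event_ids


class TestToolFiles:
    def test_rmats_files_reparse_cleanly(self, small_dir):
        comp = next((small_dir / "comparisons").iterdir())
        total = 0
        for etype in EVENT_TYPES:
            events = read_rmats(comp / f"{etype}.MATS.JC.txt", etype)
            total += len(events)
            for ev in events:
                for psi in ev.psi_group1 + ev.psi_group2:
                    assert psi is None or 0.0 <= psi <= 1.0
                assert -1.0 <= ev.dpsi <= 1.0
        assert total > 0

    def test_whippet_file_reparses_cleanly(self, small_dir, caplog):
        comp = next((small_dir / "comparisons").iterdir())
        events = read_whippet(comp / "whippet.diff")
        assert events
        assert not [r for r in caplog.records if r.levelname == "WARNING"]

    def test_tool_specific_events_in_one_file_only(self, small_dir):
        manifest = read_manifest(small_dir / "manifest.json")
        comp_name = next(iter(manifest.comparisons))
        comp = small_dir / "comparisons" / comp_name
        rmats_genes = set()
        for etype in EVENT_TYPES:
            rmats_genes |= {e.gene_id for e in read_rmats(comp / f"{etype}.MATS.JC.txt", etype)}
        whippet_genes = {e.gene_id for e in read_whippet(comp / "whippet.diff")}
        for ev in manifest.events:
            if comp_name not in ev.comparisons:
                continue
            if ev.kind == "rmats_only":
                assert ev.gene_id in rmats_genes - whippet_genes
            if ev.kind == "whippet_only":
                assert ev.gene_id in whippet_genes - rmats_genes

    def test_intended_scrambled_psi_near_one(self, small_dir):
        manifest = read_manifest(small_dir / "manifest.json")
        comp_name = next(iter(manifest.comparisons))
        intended = manifest.intended_event(comp_name)
        comp = small_dir / "comparisons" / comp_name
        events = read_rmats(comp / "SE.MATS.JC.txt", "SE")
        row = next(e for e in events if e.gene_id == intended.gene_id)
        assert np.mean(row.psi_group1) > 0.9


class TestCountModel:
    def test_estimator_consistency_at_high_depth(self, tmp_path):
        cfg = calibration_scenario(n_events=20, dpsi=0.40, depth=2000)
        out = tmp_path / "deep"
        simulate_scenario(cfg, 5, out)
        manifest = read_manifest(out / "manifest.json")
        comp = next(iter(manifest.comparisons))
        events = read_rmats(out / "comparisons" / comp / "SE.MATS.JC.txt", "SE")
        planted = {e.gene_id: e.dpsi for e in manifest.events
                   if e.kind in ("unlinked", "intended")}
        errs = [abs(ev.dpsi - planted[ev.gene_id]) for ev in events
                if ev.gene_id in planted]
        assert len(errs) == 20
        assert float(np.mean(errs)) <= 0.01

    def test_psi_out_of_range_is_configuration_error(self, tmp_path):
        cfg = ScenarioConfig(
            aons=SMALL.aons, baseline_scr_psi=0.5, unlinked_dpsis=(0.9,),
            n_linked=0, n_scr_linked=0, n_shared=0, n_rmats_only=0,
            n_whippet_only=0, n_low_coverage=0, toxic_aon=None,
            n_decoy_genes=2, decoy_sites={},
        )
        with pytest.raises(ConfigurationError):
            build_scenario(cfg, 3)


class TestManifestIO:
    def test_roundtrip_is_lossless(self, small_dir, tmp_path):
        manifest = read_manifest(small_dir / "manifest.json")
        write_manifest(manifest, tmp_path / "again.json")
        again = read_manifest(tmp_path / "again.json")
        assert again.sites == manifest.sites
        assert again.events == manifest.events
        assert again.config == manifest.config

    def test_schema_version_mismatch_rejected(self, small_dir, tmp_path):
        doc = json.loads((small_dir / "manifest.json").read_text())
        doc["schema_version"] = 999
        bad = tmp_path / "bad.json"
        bad.write_text(json.dumps(doc))
        with pytest.raises(FormatError, match="schema"):
            read_manifest(bad)

    def test_labels_respect_flag_implications(self, small_dir):
        manifest = read_manifest(small_dir / "manifest.json")
        for comp in manifest.comparisons:
            expected = manifest.expected_summary(comp)
            assert expected["hybridization_dependent"] <= expected[
                "matched_targeting_all"
            ]
            assert expected["specific"] <= expected["total"]

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown"):
            ScenarioConfig.from_dict({"not_a_key": 1})
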