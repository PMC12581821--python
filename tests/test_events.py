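"""rMATS/Whippet parsing, filtering, standardized regions, consensus."""

import logging

import numpy as np
import pytest

from spliceoff.errors import FormatError, SpliceoffError
from spliceoff.events import (
    SpliceEvent,
    cross_comparison_overlap,
    filter_rmats,
    filter_whippet,
    intersect_tools,
    read_rmats,
    read_whippet,
    standardized_region,
)

SE_HEADER = (
    "ID\tGeneID\tgeneSymbol\tchr\tstrand\texonStart_0base\texonEnd\t"
    "upstreamES\tupstreamEE\tdownstreamES\tdownstreamEE\t"
    "IJC_SAMPLE_1\tSJC_SAMPLE_1\tIJC_SAMPLE_2\tSJC_SAMPLE_2\t"
    "IncFormLen\tSkipFormLen\tPValue\tFDR\tIncLevel1\tIncLevel2\tIncLevelDifference\n"
)


def se_row(
    ID=0, ijc1="50,48,52", sjc1="2,3,1", ijc2="30,28,31", sjc2="22,20,21",
    fdr="0.001", inc1="0.95,0.90,1.00", inc2="0.60,0.55,0.50", diff="0.400",
):
    return (
        f"{ID}\tGX\tSYMX\tchr1\t+\t5000\t5100\t4000\t4200\t6000\t6150\t"
        f"{ijc1}\t{sjc1}\t{ijc2}\t{sjc2}\t198\t99\t0.0001\t{fdr}\t{inc1}\t{inc2}\t{diff}\n"
    )


WHIPPET_HEADER = "Gene\tNode\tCoord\tStrand\tType\tPsi_A\tPsi_B\tDeltaPsi\tProbability\n"


def make_se(
    tool="rmats", gene="G1", contig="chr1", strand="+", primary=(5000, 5100),
    flanks=((4000, 4200), (6000, 6150)), dpsi=0.4, sig=0.001, etype="SE",
    short=None, event_id="e1",
):
    return SpliceEvent(
        tool=tool, event_id=event_id, event_type=etype, gene_id=gene,
        symbol=gene, contig=contig, strand=strand, primary_interval=primary,
        flanking_intervals=flanks if tool == "rmats" else (),
        short_interval=short, dpsi=dpsi, significance=sig,
    )


class TestReadRmats:
    def test_se_row_fields_and_dpsi(self, tmp_path):
        p = tmp_path / "SE.MATS.JC.txt"
        p.write_text(SE_HEADER + se_row())
        (ev,) = read_rmats(p, "SE")
        assert ev.primary_interval == (5000, 5100)
        assert ev.flanking_intervals == ((4000, 4200), (6000, 6150))
        assert ev.dpsi == pytest.approx(0.400)
        # file value agrees with the replicate-mean difference
        assert np.mean(ev.psi_group1) - np.mean(ev.psi_group2) == pytest.approx(0.40)

    def test_scrambled_group_2_flips_orientation(self, tmp_path):
        p = tmp_path / "SE.MATS.JC.txt"
        p.write_text(SE_HEADER + se_row())
        (ev,) = read_rmats(p, "SE", scrambled_group=2)
        assert ev.dpsi == pytest.approx(-0.400)
        assert ev.psi_group1 == (0.60, 0.55, 0.50)  # group1 is always scrambled

    def test_a5ss_dialect_maps_long_short_flank(self, tmp_path):
        header = SE_HEADER.replace(
            "exonStart_0base\texonEnd\tupstreamES\tupstreamEE\tdownstreamES\tdownstreamEE",
            "longExonStart_0base\tlongExonEnd\tshortES\tshortEE\tflankingES\tflankingEE",
        )
        row = se_row().replace(
            "5000\t5100\t4000\t4200\t6000\t6150", "1000\t1300\t1000\t1200\t2000\t2100"
        )
        p = tmp_path / "A5SS.MATS.JC.txt"
        p.write_text(header + row)
        (ev,) = read_rmats(p, "A5SS")
        assert ev.primary_interval == (1000, 1300)
        assert ev.short_interval == (1000, 1200)
        assert ev.flanking_intervals == ((2000, 2100),)

    def test_malformed_count_field_is_format_error(self, tmp_path):
        p = tmp_path / "SE.MATS.JC.txt"
        p.write_text(SE_HEADER + se_row(ijc1="12,,"))
        with pytest.raises(FormatError, match="IJC"):
            read_rmats(p, "SE")

    def test_replicate_count_mismatch_is_format_error(self, tmp_path):
        p = tmp_path / "SE.MATS.JC.txt"
        p.write_text(SE_HEADER + se_row(ijc1="12,13"))
        with pytest.raises(FormatError, match="mismatch"):
            read_rmats(p, "SE")

    def test_unknown_event_type_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_rmats(tmp_path / "x.txt", "MXE")

    def test_na_psi_preserved_as_missing(self, tmp_path):
        p = tmp_path / "SE.MATS.JC.txt"
        p.write_text(SE_HEADER + se_row(inc1="0.95,NA,1.00"))
        (ev,) = read_rmats(p, "SE")
        assert ev.psi_group1 == (0.95, None, 1.00)


class TestReadWhippet:
    def test_coordinates_and_type_mapping(self, tmp_path):
        p = tmp_path / "w.diff"
        p.write_text(
            WHIPPET_HEADER
            + "G1\t5\tchr1:5001-5100\t+\tCE\t0.95\t0.55\t0.40\t0.99\n"
        )
        (ev,) = read_whippet(p)
        assert ev.event_type == "SE"
        assert ev.primary_interval == (5000, 5100)
        assert ev.dpsi == pytest.approx(0.40)

    def test_unknown_type_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "w.diff"
        p.write_text(
            WHIPPET_HEADER
            + "G1\t5\tchr1:5001-5100\t+\tTS\t0.95\t0.55\t0.40\t0.99\n"
            + "G1\t6\tchr1:7001-7100\t+\tRI\t0.95\t0.55\t0.40\t0.99\n"
        )
        with caplog.at_level(logging.WARNING):
            events = read_whippet(p)
        assert [e.event_type for e in events] == ["RI"]
        assert any("TS" in r.message for r in caplog.records)

    def test_targeting_as_group_a_flips_sign(self, tmp_path):
        p = tmp_path / "w.diff"
        p.write_text(
            WHIPPET_HEADER + "G1\t5\tchr1:5001-5100\t+\tCE\t0.55\t0.95\t-0.40\t0.99\n"
        )
        (ev,) = read_whippet(p, a_is_scrambled=False)
        assert ev.dpsi == pytest.approx(0.40)
        assert ev.psi_group1 == (0.95,)


class TestFilterRmats:
    def test_one_low_replicate_excludes(self, tmp_path):
        p = tmp_path / "SE.MATS.JC.txt"
        p.write_text(SE_HEADER + se_row(ijc1="10,7,12", sjc1="2,2,3"))
        events = read_rmats(p, "SE")
        assert filter_rmats(events) == []  # replicate 2 has 7+2=9 < 10

    def test_fdr_boundary_is_strict(self, tmp_path):
        p = tmp_path / "SE.MATS.JC.txt"
        p.write_text(SE_HEADER + se_row(fdr="0.05"))
        assert filter_rmats(read_rmats(p, "SE")) == []

    def test_hand_enumerated_ten_row_fixture(self, tmp_path):
        # support/FDR combinations with expected pass/fail decided by hand
        rows, expected_kept = [], []
        cases = [
            # (ijc1, sjc1, ijc2, sjc2, fdr, keep?)
            ("50,50,50", "5,5,5", "30,30,30", "20,20,20", "0.001", True),
            ("5,50,50", "4,5,5", "30,30,30", "20,20,20", "0.001", False),  # 9 reads
            ("50,50,50", "5,5,5", "30,30,30", "20,20,20", "0.05", False),  # FDR not < .05
            ("50,50,50", "5,5,5", "30,30,30", "20,20,20", "0.049", True),
            ("6,6,6", "4,4,4", "6,6,6", "4,4,4", "0.01", True),  # exactly 10
            ("6,6,6", "3,4,4", "6,6,6", "4,4,4", "0.01", False),  # one rep 9
            ("50,50,50", "5,5,5", "30,30,3", "20,20,2", "0.001", False),  # grp2 rep 5
            ("100,90,80", "0,0,0", "70,60,50", "30,40,30", "0.0", True),
            ("50,50,50", "5,5,5", "30,30,30", "20,20,20", "1.0", False),
            ("10,10,10", "0,0,0", "10,10,10", "0,0,0", "0.02", True),
        ]
        for i, (i1, s1, i2, s2, fdr, keep) in enumerate(cases):
            rows.append(se_row(ID=i, ijc1=i1, sjc1=s1, ijc2=i2, sjc2=s2, fdr=fdr))
            if keep:
                expected_kept.append(f"SE:{i}")
        p = tmp_path / "SE.MATS.JC.txt"
        p.write_text(SE_HEADER + "".join(rows))
        kept = filter_rmats(read_rmats(p, "SE"))
        assert [e.event_id for e in kept] == expected_kept

    def test_filter_monotone_in_thresholds(self, tmp_path):
        p = tmp_path / "SE.MATS.JC.txt"
        rows = [se_row(ID=i, fdr=str(0.01 * i)) for i in range(8)]
        p.write_text(SE_HEADER + "".join(rows))
        events = read_rmats(p, "SE")
        n_loose = len(filter_rmats(events, min_reads=5, fdr_max=0.10))
        n_mid = len(filter_rmats(events, min_reads=10, fdr_max=0.10))
        n_tight = len(filter_rmats(events, min_reads=10, fdr_max=0.02))
        assert n_loose >= n_mid >= n_tight


class TestFilterWhippet:
    @pytest.mark.parametrize(
        "prob,dpsi,kept",
        [
            (0.97, 0.36, True),   # intended-event regime
            (0.80, 0.36, False),  # below probability cutoff
            (0.99, 0.05, False),  # effect too small
            (0.90, 0.10, True),   # both thresholds inclusive
        ],
    )
    def test_threshold_rules(self, prob, dpsi, kept):
        ev = make_se(tool="whippet", dpsi=dpsi, sig=prob)
        assert (filter_whippet([ev]) == [ev]) is kept


class TestStandardizedRegion:
    def test_se_is_the_skipped_exon(self):
        assert standardized_region(make_se()) == (5000, 5100)

    def test_a5ss_is_the_set_difference(self):
        ev = make_se(etype="A5SS", primary=(1000, 1300), short=(1000, 1200),
                     flanks=((2000, 2100),))
        assert standardized_region(ev) == (1200, 1300)

    def test_a3ss_difference_on_start_side(self):
        ev = make_se(etype="A3SS", primary=(900, 1200), short=(1000, 1200),
                     flanks=((500, 600),))
        assert standardized_region(ev) == (900, 1000)

    def test_degenerate_alt_splice_site_is_error(self):
        ev = make_se(etype="A5SS", primary=(1000, 1200), short=(1000, 1200),
                     flanks=((2000, 2100),))
        with pytest.raises(SpliceoffError):
            standardized_region(ev)

    def test_whippet_coordinate_equals_rmats_region_cross_tool(self):
        r = make_se()
        w = make_se(tool="whippet", primary=(5000, 5100))
        assert standardized_region(r) == standardized_region(w)


class TestIntersectTools:
    def test_mean_dpsi_arithmetic(self):
        r = make_se(dpsi=0.40)
        w = make_se(tool="whippet", dpsi=0.42)
        (c,) = intersect_tools([r], [w])
        assert c.mean_dpsi == pytest.approx(0.41)
        assert min(r.dpsi, w.dpsi) <= c.mean_dpsi <= max(r.dpsi, w.dpsi)

    def test_one_whippet_event_matches_two_rmats_flank_variants(self):
        r1 = make_se(event_id="r1")
        r2 = make_se(event_id="r2", flanks=((3800, 3950), (6000, 6150)))
        w = make_se(tool="whippet")
        out = intersect_tools([r1, r2], [w])
        assert len(out) == 2
        assert len({c.identity_key for c in out}) == 2

    def test_exact_mode_requires_identical_regions(self):
        r = make_se()
        w_off = make_se(tool="whippet", primary=(5001, 5100))
        assert intersect_tools([r], [w_off], mode="exact") == []
        assert len(intersect_tools([r], [w_off], mode="overlap")) == 1

    def test_gene_type_strand_must_agree(self):
        r = make_se()
        assert intersect_tools([r], [make_se(tool="whippet", gene="G2")]) == []
        assert intersect_tools([r], [make_se(tool="whippet", strand="-")]) == []

    def test_consensus_never_exceeds_rmats_count(self):
        rmats = [
            make_se(event_id=f"r{i}", primary=(5000 + 10 * i, 5100 + 10 * i))
            for i in range(3)
        ]
        whippet = [
            make_se(tool="whippet", primary=(5000 + 5 * i, 5100 + 5 * i))
            for i in range(5)
        ]
        assert len(intersect_tools(rmats, whippet)) <= len(rmats)


class TestCrossComparisonOverlap:
    def _consensus(self, dpsi=0.4, primary=(5000, 5100)):
        r = make_se(dpsi=dpsi, primary=primary)
        w = make_se(tool="whippet", dpsi=dpsi, primary=primary)
        return intersect_tools([r], [w])[0]

    def test_grouping_by_key(self):
        a = self._consensus()
        b = self._consensus(primary=(7000, 7100))
        overlap = cross_comparison_overlap(
            {"APP": [a, b], "HTT": [a], "ATXN3": [a]}
        )
        assert overlap[a.identity_key] == {"APP", "HTT", "ATXN3"}
        assert overlap[b.identity_key] == {"APP"}

    def test_requires_two_comparisons(self):
        with pytest.raises(ValueError):
            cross_comparison_overlap({"APP": []})
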