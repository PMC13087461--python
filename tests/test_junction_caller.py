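import numpy as np
import pysam
import pytest
from hypothesis import given, settings, strategies as st

from vectortrace.junction_caller import (
    ChimericSegment,
    SATagError,
    call_junctions,
    call_junctions_from_alignments,
    cigar_intervals,
    classify_sites,
    cluster_sites,
    extract_chimeric_segments,
    parse_sa_tag,
)
from vectortrace.synthetic_data import ErrorModel, simulate_long_reads

from .oracles import single_linkage_clusters, walk_cigar


class TestParseSaTag:
    def test_single_entry_fields(self):
        stubs = parse_sa_tag("chr3,1000,+,500S4500M,60,12;")
        assert stubs == [("chr3", 999, "+", "500S4500M", 60)]

    def test_empty_tag(self):
        assert parse_sa_tag("") == []

    def test_multiple_entries(self):
        stubs = parse_sa_tag("chr1,10,+,5M,60,0;pAAV,20,-,3S2M,40,1;")
        assert len(stubs) == 2
        assert stubs[1] == ("pAAV", 19, "-", "3S2M", 40)

    @pytest.mark.parametrize("bad", [
        "chr3,0,+,4500M,60,12;",      # 1-based pos must be >= 1
        "chr3,10,+,4500M,60;",        # missing field
        "chr3,10,*,4500M,60,12;",     # bad strand
        "chr3,ten,+,4500M,60,12;",    # non-integer
    ])
    def test_malformed_entries_rejected(self, bad):
        with pytest.raises(SATagError):
            parse_sa_tag(bad)


class TestCigarIntervals:
    @pytest.mark.parametrize("cigar,ref_start,strand,read_len,read_iv,ref_iv", [
        ("3000M3000S", 499, "+", 6000, (0, 3000), (499, 3499)),
        ("3000S3000M", 19999, "+", 6000, (3000, 6000), (19999, 22999)),
        ("1000S2000M", 0, "-", 3000, (0, 2000), (0, 2000)),
        ("10S20M5I15M2D10M40S", 100, "+", 100, (10, 60), (100, 147)),
    ])
    def test_known_intervals(self, cigar, ref_start, strand, read_len, read_iv, ref_iv):
        assert cigar_intervals(cigar, ref_start, strand, read_len) == (read_iv, ref_iv)

    def test_inconsistent_read_length_rejected(self):
        with pytest.raises(ValueError, match="query length"):
            cigar_intervals("100M", 0, "+", 150)

    @given(
        st.lists(
            st.tuples(st.sampled_from("MIDSX="), st.integers(1, 50)),
            min_size=1,
            max_size=8,
        ),
        st.sampled_from("+-"),
        st.integers(0, 10_000),
    )
    @settings(max_examples=300, derandomize=True)
    def test_matches_base_walking_oracle(self, ops, strand, ref_start):
        # clips only at the ends; ensure at least one aligned op
        core = [(op, n) for op, n in ops if op != "S"]
        if not any(op in "M=X" for op, _ in core):
            core.append(("M", 7))
        lead = [("S", ops[0][1])] if ops[0][0] == "S" else []
        trail = [("S", ops[-1][1])] if len(ops) > 1 and ops[-1][0] == "S" else []
        full = lead + core + trail
        cigar = "".join(f"{n}{op}" for op, n in full)
        read_len = sum(n for op, n in full if op in "MIS=X")
        assert cigar_intervals(cigar, ref_start, strand, read_len) == walk_cigar(
            cigar, ref_start, strand, read_len
        )


def _make_record(header, name, ref, pos, cigar, seq_len, strand="+", mapq=60, sa=None):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_id = list(header.references).index(ref)
    a.reference_start = pos
    a.mapping_quality = mapq
    a.cigarstring = cigar
    a.flag = 16 if strand == "-" else 0
    a.query_sequence = "A" * seq_len
    if sa:
        a.set_tag("SA", sa)
    return a


@pytest.fixture()
def header():
    return pysam.AlignmentHeader.from_dict(
        {"SQ": [{"SN": "chr13", "LN": 100_000}, {"SN": "pAAV", "LN": 5_000}]}
    )


class TestExtractChimericSegments:
    def test_primary_plus_sa_entries_sorted_by_read_offset(self, header):
        rec = _make_record(header, "r1", "pAAV", 499, "3000M3000S", 6000,
                           sa="chr13,20000,+,3000S3000M,60,0;")
        segs = extract_chimeric_segments(rec)
        assert len(segs) == 2
        assert [s.reference for s in segs] == ["pAAV", "chr13"]
        assert segs[0].read_interval == (0, 3000)
        assert segs[1].read_interval == (3000, 6000)

    def test_no_sa_tag_gives_single_segment(self, header):
        rec = _make_record(header, "r2", "chr13", 100, "500M", 500)
        assert len(extract_chimeric_segments(rec)) == 1

    def test_sa_with_three_entries_gives_four_segments(self, header):
        sa = "chr13,1000,+,100M300S,60,0;chr13,5000,+,100S100M200S,60,0;chr13,9000,+,200S100M100S,60,0;"
        rec = _make_record(header, "r3", "pAAV", 10, "300S100M", 400, sa=sa)
        assert len(extract_chimeric_segments(rec)) == 4

    def test_excessive_read_overlap_skips_read(self, header):
        rec = _make_record(header, "r4", "pAAV", 10, "400M200S", 600,
                           sa="chr13,1000,+,300S300M,60,0;")
        with pytest.warns(UserWarning, match="overlap"):
            assert extract_chimeric_segments(rec) == []


def _seg(ref, ref_iv, read_iv, strand="+", mapq=60):
    return ChimericSegment(
        reference=ref, ref_interval=ref_iv, read_interval=read_iv,
        strand=strand, cigar="", mapq=mapq,
    )


class TestCallJunctions:
    def test_vector_to_host_junction_coordinates(self, scenario):
        segs = [
            _seg("pAAV", (499, 3499), (0, 3000)),
            _seg("chr13", (19999, 22999), (3000, 6000)),
        ]
        events = call_junctions("r1", segs, "pAAV", scenario.vector)
        assert len(events) == 1
        ev = events[0]
        assert (ev.vector_coord, ev.host_chrom, ev.host_coord) == (3499, "chr13", 19999)
        assert ev.orientation == "vector->host"
        assert ev.read_gap == 0

    def test_host_host_pair_yields_nothing(self):
        segs = [_seg("chr13", (0, 100), (0, 100)), _seg("chr3", (0, 100), (100, 200))]
        assert call_junctions("r", segs, "pAAV") == []

    def test_vector_only_read_yields_nothing(self):
        segs = [_seg("pAAV", (0, 2000), (0, 2000))]
        assert call_junctions("r", segs, "pAAV") == []

    @pytest.mark.parametrize("kwargs,expect", [
        (dict(), 1),
        (dict(min_mapq=61), 0),
        (dict(min_segment_len=5000), 0),
        (dict(max_junction_gap=0), 1),
    ])
    def test_quality_filters(self, kwargs, expect):
        segs = [
            _seg("pAAV", (0, 3000), (0, 3000)),
            _seg("chr13", (10_000, 13_000), (3000, 6000)),
        ]
        assert len(call_junctions("r", segs, "pAAV", **kwargs)) == expect

    def test_minus_strand_facing_coordinates(self):
        # host segment aligned on '-' left of the junction faces with its start
        segs = [
            _seg("chr13", (5_000, 8_000), (0, 3000), strand="-"),
            _seg("pAAV", (100, 2100), (3000, 5000), strand="+"),
        ]
        ev = call_junctions("r", segs, "pAAV")[0]
        assert ev.host_coord == 5_000
        assert ev.vector_coord == 100
        assert ev.orientation == "host->vector"


class TestClusterSites:
    def test_merge_within_distance(self):
        events = [
            type("E", (), {"host_chrom": "chr13", "host_coord": c, "read_id": f"r{i}"})()
            for i, c in enumerate([19999, 19999, 19999, 20010])
        ]
        sites = cluster_sites(events, merge_distance=50)
        assert len(sites) == 1
        assert sites[0].representative_coord == 19999
        assert sites[0].support == 4

    def test_separate_beyond_distance(self):
        events = [
            type("E", (), {"host_chrom": "chr1", "host_coord": c, "read_id": f"r{c}"})()
            for c in [100, 500]
        ]
        assert len(cluster_sites(events, merge_distance=50)) == 2

    def test_empty_events(self):
        assert cluster_sites([], merge_distance=50) == []

    @given(st.lists(st.integers(0, 2_000), min_size=1, max_size=40), st.integers(0, 100))
    @settings(max_examples=200, derandomize=True)
    def test_matches_all_pairs_oracle(self, coords, merge):
        events = [
            type("E", (), {"host_chrom": "c", "host_coord": c, "read_id": f"r{i}"})()
            for i, c in enumerate(coords)
        ]
        sites = cluster_sites(events, merge_distance=merge)
        got = sorted(sorted(e.host_coord for e in s.members) for s in sites)
        assert got == single_linkage_clusters(coords, merge)


class TestClassifySites:
    def test_targeted_and_other(self, scenario):
        from vectortrace.junction_caller import IntegrationSite

        cut = scenario.locus.cut_site
        sites = [
            IntegrationSite("chr13", cut, 5, []),
            IntegrationSite("chr3", 40_000, 1, []),
        ]
        df = classify_sites(sites, scenario.locus, predicted_offtargets=[("chr3", 41_000)])
        assert list(df["classification"]) == ["targeted", "other"]
        assert df.loc[1, "nearest_offtarget_distance"] == 1_000

    def test_no_predicted_offtargets(self, scenario):
        from vectortrace.junction_caller import IntegrationSite

        df = classify_sites([IntegrationSite("chr3", 1, 1, [])], scenario.locus)
        assert df["nearest_offtarget_distance"].isna().all()


class TestPipelineInvariants:
    def test_strand_symmetry(self, scenario_two_random, tmp_path):
        """Reverse-complementing every read leaves site coordinates unchanged."""
        scen = scenario_two_random

        def sites_for(flip):
            sim = simulate_long_reads(
                scen.population, scen.genome, scen.vector, scen.locus,
                ErrorModel.perfect(), 250, seed=21, flip=flip,
            )
            sam = tmp_path / f"flip_{flip}.sam"
            sim.write_truth_sam(sam)
            events = call_junctions_from_alignments(sam, scen.vector.name, scen.vector)
            return {
                (s.host_chrom, s.representative_coord)
                for s in cluster_sites(events)
            }

        assert sites_for(False) == sites_for(True)

    def test_episome_reads_do_not_change_sites(self, scenario, tmp_path):
        from vectortrace.synthetic_data import CellPopulationSpec

        scen = scenario
        sim = simulate_long_reads(
            scen.population, scen.genome, scen.vector, scen.locus,
            ErrorModel.perfect(), 200, seed=5,
        )
        base_sam = tmp_path / "base.sam"
        sim.write_truth_sam(base_sam)
        epi = simulate_long_reads(
            CellPopulationSpec(fractions={"WT": 1.0}, episome_copies_per_genome=8.0),
            scen.genome, scen.vector, scen.locus,
            ErrorModel.perfect(), 150, seed=6,
        )
        mixed_sam = tmp_path / "mixed.sam"
        epi_only = [r for r in epi.reads if r.truth.source_label == "episome"]
        epi.reads = epi_only
        epi_sam = tmp_path / "epi.sam"
        epi.write_truth_sam(epi_sam)
        base_lines = base_sam.read_text().splitlines()
        epi_lines = [l for l in epi_sam.read_text().splitlines() if not l.startswith("@")]
        mixed_sam.write_text("\n".join(base_lines + epi_lines) + "\n")

        def site_set(path):
            events = call_junctions_from_alignments(path, scen.vector.name, scen.vector)
            return {(s.host_chrom, s.representative_coord, s.support) for s in cluster_sites(events)}

        assert site_set(base_sam) == site_set(mixed_sam)
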