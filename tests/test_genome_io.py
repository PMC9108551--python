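"""Parsing, validation and exon-projection behaviour of the IO layer."""

import numpy as np
import pandas as pd
import pytest

from meripscore import (
    CoverageTrack,
    FormatError,
    GeneModel,
    SampleDesign,
    Site,
    ValidationError,
    project_to_exons,
    read_bedgraph,
    read_gene_models,
    read_sites,
    write_gene_models,
    write_sites,
)
from meripscore.genome_io import _dense_to_runs, exonic_union


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestBed12:
    def test_single_block_maps_directly(self, tmp_path):
        p = write(tmp_path, "g.bed", "chr1\t100\t200\tgA\t0\t+\t100\t200\t0\t1\t100\t0\n")
        (g,) = read_gene_models(p)
        assert g.exons == ((100, 200),)
        assert g.gene_id == "gA" and g.strand == "+"

    def test_two_blocks_reconstruct_exons(self, tmp_path):
        p = write(tmp_path, "g.bed", "chr1\t0\t150\tgB\t0\t-\t0\t150\t0\t2\t50,50\t0,100\n")
        (g,) = read_gene_models(p)
        assert g.exons == ((0, 50), (100, 150))

    def test_block_count_mismatch_is_parse_error(self, tmp_path):
        p = write(tmp_path, "g.bed", "chr1\t0\t150\tgB\t0\t-\t0\t150\t0\t2\t50\t0\n")
        with pytest.raises(FormatError, match=":1"):
            read_gene_models(p)

    def test_overlapping_blocks_is_validation_error(self, tmp_path):
        p = write(tmp_path, "g.bed", "chr1\t0\t150\tgB\t0\t-\t0\t150\t0\t2\t60,50\t0,40\n")
        with pytest.raises(ValidationError):
            read_gene_models(p)

    def test_roundtrip(self, tmp_path, gene_spliced, gene_simple):
        p = tmp_path / "out.bed"
        write_gene_models([gene_spliced, gene_simple], p)
        back = read_gene_models(p)
        assert [(g.gene_id, g.chrom, g.strand, g.exons) for g in back] == [
            ("gB", "chr1", "+", ((0, 50), (100, 150))),
            ("gA", "chr1", "+", ((100, 200),)),
        ]


class TestSites:
    def test_containment_assignment(self, tmp_path, gene_simple):
        p = write(tmp_path, "s.bed", "chr1\t150\t160\ts1\t0\t.\n")
        (s,) = read_sites(p, [gene_simple])
        assert s.gene_id == "gA"

    def test_max_overlap_wins(self, tmp_path):
        g1 = GeneModel("g1", "chr1", "+", ((100, 200),))
        g2 = GeneModel("g2", "chr1", "+", ((207, 300),))
        # overlap with g1: 10 bp (190..200); with g2: 3 bp (207..210)
        p = write(tmp_path, "s.bed", "chr1\t190\t210\ts1\t0\t.\n")
        (s,) = read_sites(p, [g1, g2])
        assert s.gene_id == "g1"

    def test_tie_breaks_to_lexicographically_smallest(self, tmp_path):
        ga = GeneModel("gZ", "chr1", "+", ((100, 200),))
        gb = GeneModel("gA", "chr1", "-", ((100, 200),))
        p = write(tmp_path, "s.bed", "chr1\t150\t160\ts1\t0\t.\n")
        (s,) = read_sites(p, [ga, gb])
        assert s.gene_id == "gA"

    def test_unassignable_dropped(self, tmp_path, gene_simple, caplog):
        p = write(tmp_path, "s.bed", "chr1\t500\t510\tlost\t0\t.\nchr1\t150\t160\ts1\t0\t.\n")
        with caplog.at_level("INFO"):
            sites = read_sites(p, [gene_simple])
        assert [s.site_id for s in sites] == ["s1"]
        assert "dropped 1" in caplog.text

    def test_zero_length_site_rejected(self, tmp_path, gene_simple):
        p = write(tmp_path, "s.bed", "chr1\t150\t150\ts1\t0\t.\n")
        with pytest.raises(ValidationError):
            read_sites(p, [gene_simple])

    def test_roundtrip_bit_exact(self, tmp_path, gene_simple):
        sites = [Site("s1", "chr1", 150, 160, "gA"), Site("s2", "chr1", 101, 199, "gA")]
        p = tmp_path / "sites.bed"
        write_sites(sites, p)
        first = p.read_bytes()
        back = read_sites(p, [gene_simple])
        assert [(s.site_id, s.chrom, s.start, s.end) for s in back] == [
            (s.site_id, s.chrom, s.start, s.end) for s in sites
        ]
        write_sites(back, p)
        assert p.read_bytes() == first


class TestBedgraph:
    def test_single_record(self, tmp_path, gene_spliced):
        p = write(tmp_path, "t.bg", "chr1\t0\t10\t5.0\n")
        track = read_bedgraph(p, [gene_spliced])
        assert track.lib_total == 50.0
        assert track.depth("chr1", np.arange(0, 12)).tolist() == [5.0] * 10 + [0, 0]

    def test_empty_file(self, tmp_path, gene_spliced):
        p = write(tmp_path, "t.bg", "")
        track = read_bedgraph(p, [gene_spliced])
        assert track.lib_total == 0.0
        assert not track.depth("chr1", np.arange(50)).any()

    def test_overlapping_records_rejected(self, tmp_path, gene_spliced):
        p = write(tmp_path, "t.bg", "chr1\t0\t5\t2\nchr1\t3\t8\t1\n")
        with pytest.raises(ValidationError, match="overlap"):
            read_bedgraph(p, [gene_spliced])

    def test_negative_depth_rejected(self, tmp_path, gene_spliced):
        p = write(tmp_path, "t.bg", "chr1\t0\t5\t-2\n")
        with pytest.raises(ValidationError, match="negative"):
            read_bedgraph(p, [gene_spliced])

    def test_lib_total_counts_only_exonic_bases(self, tmp_path, gene_spliced):
        # record spans the intron [50,100): only exonic bases contribute
        p = write(tmp_path, "t.bg", "chr1\t40\t110\t2\n")
        track = read_bedgraph(p, [gene_spliced])
        assert track.lib_total == 2 * (10 + 10)

    def test_lib_total_matches_recompute(self, tmp_path, gene_spliced):
        p = write(tmp_path, "t.bg", "chr1\t0\t30\t3\nchr1\t120\t140\t1.5\n")
        track = read_bedgraph(p, [gene_spliced])
        assert track.lib_total == pytest.approx(track.recompute_lib_total([gene_spliced]))

    def test_bedgraph_write_read_roundtrip(self, tmp_path, gene_spliced):
        rng = np.random.default_rng(5)
        arr = rng.integers(0, 4, size=150).astype(float)
        track = CoverageTrack.from_dense("s", {"chr1": arr}, genes=[gene_spliced])
        p = tmp_path / "s.bedgraph"
        track.to_bedgraph(p)
        back = read_bedgraph(p, [gene_spliced], "s")
        pos = np.arange(150)
        np.testing.assert_array_equal(back.depth("chr1", pos), arr)
        assert back.lib_total == pytest.approx(track.lib_total)


class TestProjection:
    def test_contained_site(self, gene_simple):
        pos = project_to_exons(Site("s", "chr1", 150, 160, "gA"), gene_simple)
        assert pos.tolist() == list(range(150, 160))

    def test_spliced_site_spans_intron(self, gene_spliced):
        pos = project_to_exons(Site("s", "chr1", 40, 110, "gB"), gene_spliced)
        assert pos.tolist() == list(range(40, 50)) + list(range(100, 110))

    def test_disjoint_site_errors(self, gene_simple):
        with pytest.raises(ValidationError):
            project_to_exons(Site("s", "chr1", 300, 310, "gA"), gene_simple)

    def test_agrees_with_bruteforce_membership(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 1000:
            n_ex = int(rng.integers(1, 5))
            cursor, exons = int(rng.integers(0, 50)), []
            for _ in range(n_ex):
                length = int(rng.integers(1, 40))
                exons.append((cursor, cursor + length))
                cursor += length + int(rng.integers(1, 30))
            gene = GeneModel("g", "chr1", "+", tuple(exons))
            a = int(rng.integers(0, cursor))
            b = a + int(rng.integers(1, 60))
            exonic = set()
            for s, e in exons:
                exonic.update(range(s, e))
            expected = sorted(p for p in range(a, b) if p in exonic)
            site = Site("s", "chr1", a, b, "g")
            if expected:
                assert project_to_exons(site, gene).tolist() == expected
            else:
                with pytest.raises(ValidationError):
                    project_to_exons(site, gene)
            checked += 1


class TestCoverageRepresentation:
    def test_dense_and_runs_identical_depths(self):
        rng = np.random.default_rng(11)
        arr = rng.poisson(2.0, size=400).astype(float)
        dense = CoverageTrack("d")
        dense.add_dense("chr1", arr)
        starts, ends, values = _dense_to_runs(arr)
        runs = CoverageTrack("r")
        runs.add_runs("chr1", starts, ends, values)
        pos = rng.integers(-5, 410, size=300)
        np.testing.assert_array_equal(dense.depth("chr1", pos), runs.depth("chr1", pos))

    def test_exonic_union_merges(self):
        g1 = GeneModel("a", "chr1", "+", ((0, 50), (100, 150)))
        g2 = GeneModel("b", "chr1", "+", ((40, 120),))
        union = exonic_union([g1, g2])
        assert union["chr1"].tolist() == [[0, 150]]


class TestDesign:
    def test_valid_design_pairs(self, design_2x3):
        pairs = design_2x3.pairs()
        assert len(pairs) == 6
        assert pairs[0] == ("PERTURBED", 1, "perturbed_ip_1", "perturbed_input_1")

    def test_missing_input_row_rejected(self):
        df = pd.DataFrame(
            [("a", "IP", "REF", 1), ("b", "IP", "REF", 2), ("c", "INPUT", "REF", 2)],
            columns=["sample_id", "fraction", "condition", "replicate"],
        )
        with pytest.raises(ValidationError, match="replicate 1"):
            SampleDesign(df)

    def test_duplicate_sample_id_rejected(self):
        df = pd.DataFrame(
            [("a", "IP", "REF", 1), ("a", "INPUT", "REF", 1)],
            columns=["sample_id", "fraction", "condition", "replicate"],
        )
        with pytest.raises(ValidationError, match="duplicate"):
            SampleDesign(df)
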