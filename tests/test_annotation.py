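import pytest
from hypothesis import given, settings, strategies as st

from splicesig.annotation import (
    ExonRecord,
    GtfParseError,
    TranscriptModel,
    classify_coding,
    flatten_gene_exons,
    read_bed,
    read_gtf,
    write_bed,
)

from _oracles import flatten_by_sweep


def _tm(tid, gene, exons, strand="+", biotype="protein_coding"):
    return TranscriptModel(tid, gene, "chr1", strand, tuple(exons), biotype)


class TestReadGtf:
    def test_coordinate_conversion_and_grouping(self, gtf_file):
        models = read_gtf(gtf_file)
        by_id = {m.transcript_id: m for m in models}
        assert by_id["gA.1"].exons == ((99, 200), (299, 400))
        assert by_id["gA.1"].gene_id == by_id["gA.2"].gene_id == "gA"
        assert by_id["gB.1"].biotype == "processed_transcript"
        assert by_id["gB.1"].strand == "-"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.gtf"
        p.write_text("")
        assert read_gtf(p) == []

    @pytest.mark.parametrize(
        "line,match",
        [
            ("chr1\texon\t100\t200", "9 tab-separated"),
            (
                'chr1\tx\texon\t300\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";',
                "end 200 < start 300",
            ),
            ("chr1\tx\texon\tab\t200\t.\t+\t.\tgene_id \"g\"; transcript_id \"t\";", "non-integer"),
        ],
    )
    def test_malformed_lines_name_the_line(self, tmp_path, line, match):
        p = tmp_path / "bad.gtf"
        p.write_text(line + "\n")
        with pytest.raises(GtfParseError, match="line 1"):
            read_gtf(p)


class TestFlatten:
    @pytest.mark.parametrize(
        "exon_lists,expected",
        [
            # boundary-union partition of two overlapping transcripts
            ([[(0, 100)], [(50, 150)]], [(0, 50), (50, 100), (100, 150)]),
            # identity when nothing overlaps
            ([[(0, 100), (200, 300)]], [(0, 100), (200, 300)]),
            # nested exons (pinned against the per-base sweep oracle)
            (
                [[(0, 300)], [(100, 200)], [(100, 300)]],
                [(0, 100), (100, 200), (200, 300)],
            ),
        ],
    )
    def test_counting_bins(self, exon_lists, expected):
        assert flatten_by_sweep(exon_lists) == expected  # oracle agrees
        models = [_tm(f"t{i}", "g", exons) for i, exons in enumerate(exon_lists)]
        bins = [(ex.start, ex.end) for ex in flatten_gene_exons(models)]
        assert bins == expected

    def test_empty_input(self):
        assert flatten_gene_exons([]) == []

    def test_bin_ids_numbered_in_genomic_order(self):
        bins = flatten_gene_exons([_tm("t", "g", [(10, 20), (30, 40)])])
        assert [b.exon_id for b in bins] == ["g:E001", "g:E002"]

    def test_genes_flattened_independently(self):
        models = [_tm("t1", "gA", [(0, 100)]), _tm("t2", "gB", [(50, 150)], strand="-")]
        bins = flatten_gene_exons(models)
        assert [(b.gene_id, b.start, b.end) for b in bins] == [
            ("gA", 0, 100),
            ("gB", 50, 150),
        ]

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.lists(
                st.tuples(st.integers(0, 50), st.integers(1, 30)).map(
                    lambda t: (t[0] * 10, t[0] * 10 + t[1])
                ),
                min_size=1,
                max_size=4,
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_flattening_conserves_base_coverage(self, raw_lists):
        # keep only transcript-valid (sorted, disjoint) exon chains
        exon_lists = []
        for exons in raw_lists:
            chain = []
            for s, e in sorted(set(exons)):
                if not chain or s >= chain[-1][1]:
                    chain.append((s, e))
            exon_lists.append(chain)
        models = [_tm(f"t{i}", "g", ex) for i, ex in enumerate(exon_lists)]
        bins = flatten_gene_exons(models)
        covered = {p for ex in exon_lists for s, e in ex for p in range(s, e)}
        bin_bases = [p for b in bins for p in range(b.start, b.end)]
        assert len(bin_bases) == len(set(bin_bases)), "bins overlap"
        assert set(bin_bases) == covered
        assert [(b.start, b.end) for b in bins] == flatten_by_sweep(exon_lists)


class TestClassifyCoding:
    def _exon(self, start, end, eid="g:E001"):
        return ExonRecord(eid, "g", "chr1", "+", start, end)

    def test_single_base_overlap_is_coding(self):
        models = [_tm("t", "gC", [(150, 250)])]
        (out,) = classify_coding([self._exon(100, 200)], models)
        assert out.coding_class == "coding"

    def test_processed_transcript_only_is_non_coding(self):
        models = [_tm("t", "gN", [(100, 200)], biotype="processed_transcript")]
        (out,) = classify_coding([self._exon(100, 200)], models)
        assert out.coding_class == "non_coding"

    def test_half_open_abutment_is_not_overlap(self):
        models = [_tm("t", "gC", [(200, 300)])]
        (out,) = classify_coding([self._exon(100, 200)], models)
        assert out.coding_class == "non_coding"

    def test_idempotent_and_order_independent(self):
        models = [
            _tm("t1", "gC", [(0, 50)]),
            _tm("t2", "gN", [(100, 150)], biotype="nonsense_mediated_decay"),
        ]
        exons = [self._exon(0, 10, "g:E001"), self._exon(100, 120, "g:E002")]
        once = classify_coding(exons, models)
        twice = classify_coding(once, models)
        assert [e.coding_class for e in once] == [e.coding_class for e in twice]
        rev = classify_coding(exons[::-1], models[::-1])
        assert {e.exon_id: e.coding_class for e in rev} == {
            e.exon_id: e.coding_class for e in once
        }


def test_bed_round_trip(tmp_path, gtf_file):
    models = read_gtf(gtf_file)
    exons = flatten_gene_exons(models)
    p = tmp_path / "exons.bed"
    write_bed(exons, p)
    back = read_bed(p)
    assert [(e.exon_id, e.chrom, e.start, e.end, e.strand) for e in back] == [
        (e.exon_id, e.chrom, e.start, e.end, e.strand) for e in exons
    ]
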