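import pytest

from splicesig.annotation import TranscriptModel


def _tm(tid, gene, exons, strand="+", chrom="chr1", biotype="protein_coding"):
    return TranscriptModel(tid, gene, chrom, strand, tuple(exons), biotype)


@pytest.fixture(scope="session")
def toy_mode_genes():
    """Hand-built two-transcript genes, one per event mode, with the expected
    (mode, inclusion_form, exclusion_form) enumerated by hand."""
    return {
        "CE": (
            [
                _tm("tA", "gCE", [(0, 100), (200, 300), (400, 500)]),
                _tm("tB", "gCE", [(0, 100), (400, 500)]),
            ],
            ("CE", ((200, 300),), ((0, 100), (400, 500))),
        ),
        "MCE": (
            [
                _tm("tA", "gMCE", [(0, 100), (200, 300), (400, 500), (600, 700)]),
                _tm("tB", "gMCE", [(0, 100), (600, 700)]),
            ],
            ("MCE", ((200, 300), (400, 500)), ((0, 100), (600, 700))),
        ),
        "A3SS": (
            [
                _tm("tA", "gA3", [(0, 100), (200, 300)]),
                _tm("tB", "gA3", [(0, 100), (170, 300)]),
            ],
            ("A3SS", ((170, 300),), ((200, 300),)),
        ),
        "A5SS": (
            [
                _tm("tA", "gA5", [(0, 100), (200, 300)]),
                _tm("tB", "gA5", [(0, 130), (200, 300)]),
            ],
            ("A5SS", ((0, 130),), ((0, 100),)),
        ),
        "RI": (
            [
                _tm("tA", "gRI", [(0, 100), (200, 300)]),
                _tm("tB", "gRI", [(0, 300)]),
            ],
            ("RI", ((0, 300),), ((0, 100), (200, 300))),
        ),
        "MXE": (
            [
                _tm("tA", "gMXE", [(0, 100), (200, 300), (600, 700)]),
                _tm("tB", "gMXE", [(0, 100), (400, 500), (600, 700)]),
            ],
            ("MXE", ((200, 300),), ((400, 500),)),
        ),
        "AFE": (
            [
                _tm("tA", "gAFE", [(0, 100), (400, 500), (600, 700)]),
                _tm("tB", "gAFE", [(200, 300), (400, 500), (600, 700)]),
            ],
            ("AFE", ((0, 100),), ((200, 300),)),
        ),
        "ALE": (
            [
                _tm("tA", "gALE", [(0, 100), (200, 300)]),
                _tm("tB", "gALE", [(0, 100), (400, 500)]),
            ],
            ("ALE", ((200, 300),), ((400, 500),)),
        ),
    }


@pytest.fixture()
def gtf_file(tmp_path):
    """Small hand-written GTF with two genes (one non-coding transcript)."""
    text = "\n".join(
        [
            "# comment line",
            'chr1\tprotein_coding\texon\t100\t200\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";',
            'chr1\tprotein_coding\texon\t300\t400\t.\t+\t.\tgene_id "gA"; transcript_id "gA.1";',
            'chr1\tprotein_coding\texon\t100\t200\t.\t+\t.\tgene_id "gA"; transcript_id "gA.2";',
            'chr1\tprocessed_transcript\texon\t1000\t1200\t.\t-\t.\tgene_id "gB"; transcript_id "gB.1";',
        ]
    )
    p = tmp_path / "toy.gtf"
    p.write_text(text + "\n")
    return p
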