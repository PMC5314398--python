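"""Transcript models, flattened exon counting bins and coding classification.

Transcript structures are read from Ensembl-dialect GTF. Internally every
coordinate is 0-based half-open; GTF (1-based closed) and BED (0-based
half-open) are converted at the file boundary so that interval arithmetic
uses a single convention throughout the package.

The unit of all downstream exon-level analysis is the *counting bin*: per
gene, the union of all transcript exons is partitioned into maximal
sub-intervals not split by any transcript's exon boundary. A bin is
``coding`` when it overlaps (by at least one base) an exon of any
protein_coding transcript, otherwise ``non_coding``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TranscriptModel",
    "ExonRecord",
    "GtfParseError",
    "read_gtf",
    "flatten_gene_exons",
    "classify_coding",
    "write_bed",
    "read_bed",
]

USAGE_CLASSES = ("up", "down", "unchanged", "untested")
CODING_CLASSES = ("coding", "non_coding")


class GtfParseError(ValueError):
    """Raised when a GTF/BED/bedGraph line cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an ordered chain of exons on one strand.

    ``exons`` are 0-based half-open (start, end) tuples, sorted by start and
    non-overlapping within the transcript. ``biotype`` is the Ensembl
    gene/transcript biotype string (e.g. ``protein_coding``,
    ``processed_transcript``, ``nonsense_mediated_decay``).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ex = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in ex:
            if e <= s:
                raise ValueError(
                    f"exon end must exceed start in {self.transcript_id}: ({s},{e})"
                )
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping exons within transcript {self.transcript_id}"
                )
        object.__setattr__(self, "exons", ex)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Splice junctions as (donor_end, acceptor_start) in genomic order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass
class ExonRecord:
    """One flattened counting bin with gene linkage and class labels."""

    exon_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    coding_class: str | None = None
    usage_class: str = "untested"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"exon {self.exon_id}: end must exceed start")
        if self.usage_class not in USAGE_CLASSES:
            raise ValueError(f"invalid usage_class {self.usage_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(
    path: str | Path,
    attribute_keys: Sequence[str] = ("gene_id", "transcript_id"),
) -> list[TranscriptModel]:
    """Read exon features from an Ensembl-dialect GTF into transcript models.

    Only ``exon`` feature lines are used. 1-based closed GTF coordinates are
    converted to 0-based half-open. The biotype is taken from a
    ``gene_biotype``/``transcript_biotype`` attribute when present, else from
    the source column (Ensembl GTFs up to v75 put the biotype there).

    Raises :class:`GtfParseError` naming the offending line number on a
    malformed line (wrong column count, non-integer or inverted coordinates).
    """
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise GtfParseError(f"line {lineno}: exon end {end1} < start {start1}")
            attr = dict(_ATTR_RE.findall(attrs))
            missing = [k for k in attribute_keys if k not in attr]
            if missing:
                raise GtfParseError(f"line {lineno}: missing attributes {missing}")
            tid = attr["transcript_id"]
            biotype = (
                attr.get("transcript_biotype")
                or attr.get("gene_biotype")
                or source
            )
            rec = exons.setdefault(
                tid,
                {
                    "gene_id": attr["gene_id"],
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": biotype,
                    "exons": [],
                },
            )
            rec["exons"].append((start1 - 1, end1))  # GTF -> half-open
    return [
        TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(rec["exons"]),
            biotype=rec["biotype"],
        )
        for tid, rec in exons.items()
    ]


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def flatten_gene_exons(models: Sequence[TranscriptModel]) -> list[ExonRecord]:
    """Partition each gene's exon union into disjoint counting bins.

    Bin boundaries are the union of all transcript exon start/end positions,
    so no transcript's exon boundary falls inside a bin. Bins are numbered
    5'->3' in genomic coordinate order (``gene:E001`` ...) regardless of
    strand; genes are flattened independently, never merged across gene_ids.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)

    records: list[ExonRecord] = []
    for gene_id in sorted(by_gene):
        group = by_gene[gene_id]
        chroms = {m.chrom for m in group}
        strands = {m.strand for m in group}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"gene {gene_id}: transcripts span chroms/strands")
        chrom, strand = group[0].chrom, group[0].strand
        all_exons = [iv for m in group for iv in m.exons]
        merged = _merge_intervals(all_exons)
        breakpoints = sorted({b for iv in all_exons for b in iv})
        part = 0
        mi = 0
        for lo, hi in zip(breakpoints, breakpoints[1:]):
            # advance to the merged block that could contain [lo, hi)
            while mi < len(merged) and merged[mi][1] <= lo:
                mi += 1
            if mi < len(merged) and merged[mi][0] <= lo and hi <= merged[mi][1]:
                part += 1
                records.append(
                    ExonRecord(
                        exon_id=f"{gene_id}:E{part:03d}",
                        gene_id=gene_id,
                        chrom=chrom,
                        strand=strand,
                        start=lo,
                        end=hi,
                    )
                )
    return records


def classify_coding(
    exons: Sequence[ExonRecord], models: Sequence[TranscriptModel]
) -> list[ExonRecord]:
    """Label each exon ``coding`` or ``non_coding``.

    An exon overlapping (>= 1 base) any exon of any transcript whose biotype
    is ``protein_coding`` is coding; all others — including exons found only
    in processed transcripts or NMD targets, and exons merely abutting a
    coding exon at a half-open boundary — are non_coding. Idempotent and
    independent of input order.
    """
    coding_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in models:
        if m.biotype == "protein_coding":
            coding_by_chrom.setdefault(m.chrom, []).extend(m.exons)
    merged = {c: _merge_intervals(ivs) for c, ivs in coding_by_chrom.items()}
    starts = {c: np.array([s for s, _ in ivs]) for c, ivs in merged.items()}
    ends = {c: np.array([e for _, e in ivs]) for c, ivs in merged.items()}

    out: list[ExonRecord] = []
    for ex in exons:
        label = "non_coding"
        if ex.chrom in merged:
            # rightmost merged interval starting before ex.end overlaps iff it ends after ex.start
            i = int(np.searchsorted(starts[ex.chrom], ex.end, side="left")) - 1
            if i >= 0 and ends[ex.chrom][i] > ex.start:
                label = "coding"
        out.append(replace(ex, coding_class=label))
    return out


def write_bed(exons: Sequence[ExonRecord], path: str | Path) -> None:
    """Write flattened exons as BED6 (name=exon_id, score=0)."""
    with open(path, "w") as fh:
        for ex in exons:
            fh.write(
                f"{ex.chrom}\t{ex.start}\t{ex.end}\t{ex.exon_id}\t0\t{ex.strand}\n"
            )


def read_bed(path: str | Path) -> list[ExonRecord]:
    """Read a BED6 of flattened exons back into records (round-trip of write_bed)."""
    out: list[ExonRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise GtfParseError(f"line {lineno}: BED6 needs 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            gene_id = name.rsplit(":", 1)[0]
            out.append(
                ExonRecord(
                    exon_id=name,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    start=int(start),
                    end=int(end),
                )
            )
    return out
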