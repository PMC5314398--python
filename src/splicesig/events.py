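"""Alternative-splicing event enumeration and PSI inclusion tests.

Eight event modes are enumerated by pairwise comparison of a gene's
transcript models on their shared splice graph:

* **CE** — cassette exon: an internal exon of one form is absent in the
  other, whose junction joins the flanking exons directly.
* **MCE** — multiple cassette exons: >= 2 consecutive exons skipped together
  (supersedes the constituent CEs; longest pattern wins).
* **A5SS / A3SS** — alternative donor / acceptor: an exon shares one
  boundary between forms and shifts the other at an internal splice site;
  donor/acceptor assignment follows the transcribed strand.
* **RI** — retained intron: an intron of one form is fully exonic in the
  other.
* **AFE / ALE** — alternative first / last exon: the transcribed-strand
  first (last) exons differ and do not overlap, while a downstream
  (upstream) exon is shared.
* **MXE** — mutually exclusive exons: two non-overlapping exons share both
  flanking splice sites but never co-occur.

Events are annotation-derived; junction read counts arrive as an external
table (one row per junction id, one column per sample). Inclusion junction
ids use ``chrom:donor-acceptor``; intron-retention support (reads spanning
an unspliced junction) uses ``chrom:start^end``.

The differential test is a two-sided conditional exact test on the
replicate-summed 2x2 [inclusion, exclusion] x [control, knockdown] table,
with PSI = inclusion / (inclusion + exclusion) per condition and
BH adjustment across events (raw-p mode available).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import TranscriptModel
from .usage import ConfigurationError

__all__ = [
    "SpliceEvent",
    "EVENT_MODES",
    "enumerate_events",
    "EventInclusionModel",
    "EventInclusionResults",
    "psi_test",
    "write_events_tsv",
]

EVENT_MODES = ("CE", "A5SS", "A3SS", "RI", "AFE", "ALE", "MCE", "MXE")

Interval = tuple[int, int]


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event: two distinguishable forms of a gene region."""

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    mode: str
    inclusion_form: tuple[Interval, ...]
    exclusion_form: tuple[Interval, ...]
    inclusion_junctions: tuple[str, ...]
    exclusion_junctions: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mode not in EVENT_MODES:
            raise ValueError(f"unknown event mode {self.mode!r}")
        if self.inclusion_form == self.exclusion_form:
            raise ValueError("inclusion and exclusion forms must differ")


def _junc_id(chrom: str, donor: int, acceptor: int) -> str:
    return f"{chrom}:{donor}-{acceptor}"


def _ri_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}^{end}"


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _pair_events(t1: TranscriptModel, t2: TranscriptModel) -> list[dict]:
    """Raw (un-deduplicated) events from one unordered transcript pair."""
    chrom, strand = t1.chrom, t1.strand
    found: list[dict] = []

    for a, b in ((t1, t2), (t2, t1)):
        ea, eb = a.exons, b.exons
        jb = set(b.junctions)

        # --- retained intron: intron of b fully exonic in a -----------------
        for d, acc in b.junctions:
            for s, e in ea:
                if s <= d and acc <= e:
                    left = next(((ls, le) for ls, le in eb if le == d), None)
                    right = next(((rs, re) for rs, re in eb if rs == acc), None)
                    found.append(
                        dict(
                            mode="RI",
                            inclusion_form=((s, e),),
                            exclusion_form=tuple(x for x in (left, right) if x),
                            inc_j=(_ri_id(chrom, d, acc),),
                            exc_j=(_junc_id(chrom, d, acc),),
                        )
                    )

        # --- cassette / multiple cassette: run of exons in a absent in b ----
        i = 1
        while i < len(ea) - 1:
            if any(_overlaps(ea[i], x) for x in eb):
                i += 1
                continue
            j = i
            while j + 1 < len(ea) - 1 and not any(_overlaps(ea[j + 1], x) for x in eb):
                j += 1
            skip_j = (ea[i - 1][1], ea[j + 1][0])
            if skip_j in jb:
                found.append(
                    dict(
                        mode="CE" if i == j else "MCE",
                        inclusion_form=tuple(ea[i : j + 1]),
                        exclusion_form=(ea[i - 1], ea[j + 1]),
                        inc_j=(
                            _junc_id(chrom, ea[i - 1][1], ea[i][0]),
                            _junc_id(chrom, ea[j][1], ea[j + 1][0]),
                        ),
                        exc_j=(_junc_id(chrom, *skip_j),),
                    )
                )
            i = j + 1

    # --- alternative 5'/3' splice sites (one shared boundary) ---------------
    e1, e2 = t1.exons, t2.exons
    for i, x in enumerate(e1):
        for k, y in enumerate(e2):
            if x == y or not _overlaps(x, y):
                continue
            if x[1] == y[1] and x[0] != y[0] and i > 0 and k > 0:
                # start varies at an internal acceptor (genomic); donor on '-'
                mode = "A3SS" if t1.strand == "+" else "A5SS"
                long_t, short_t = (t1, t2) if x[0] < y[0] else (t2, t1)
                lx, sx = min(x, y), max(x, y)
                # retained intron takes precedence: the short form splices an
                # intron that is fully exonic in the long form
                if any(lx[0] <= d and a <= sx[0] for d, a in short_t.junctions
                       if a == sx[0]):
                    continue
                li = long_t.exons.index(lx)
                si = short_t.exons.index(sx)
                found.append(
                    dict(
                        mode=mode,
                        inclusion_form=(lx,),
                        exclusion_form=(sx,),
                        inc_j=(_junc_id(chrom, long_t.exons[li - 1][1], lx[0]),),
                        exc_j=(_junc_id(chrom, short_t.exons[si - 1][1], sx[0]),),
                    )
                )
            elif x[0] == y[0] and x[1] != y[1] and i < len(e1) - 1 and k < len(e2) - 1:
                mode = "A5SS" if t1.strand == "+" else "A3SS"
                long_t, short_t = (t1, t2) if x[1] > y[1] else (t2, t1)
                lx = x if x[1] > y[1] else y
                sx = y if x[1] > y[1] else x
                if any(d == sx[1] and a <= lx[1] for d, a in short_t.junctions):
                    continue
                li = long_t.exons.index(lx)
                si = short_t.exons.index(sx)
                found.append(
                    dict(
                        mode=mode,
                        inclusion_form=(lx,),
                        exclusion_form=(sx,),
                        inc_j=(_junc_id(chrom, lx[1], long_t.exons[li + 1][0]),),
                        exc_j=(_junc_id(chrom, sx[1], short_t.exons[si + 1][0]),),
                    )
                )

    # --- mutually exclusive exons -------------------------------------------
    j1, j2 = set(t1.junctions), set(t2.junctions)
    for i in range(1, len(e1) - 1):
        a = e1[i]
        if any(_overlaps(a, y) for y in e2):
            continue
        for k in range(1, len(e2) - 1):
            b = e2[k]
            if _overlaps(a, b) or any(_overlaps(b, x) for x in e1):
                continue
            pa, na = e1[i - 1][1], e1[i + 1][0]
            pb, nb = e2[k - 1][1], e2[k + 1][0]
            if pa == pb and na == nb:
                first, second = sorted([a, b])
                ft, st = (t1, t2) if first == a else (t2, t1)
                found.append(
                    dict(
                        mode="MXE",
                        inclusion_form=(first,),
                        exclusion_form=(second,),
                        inc_j=(
                            _junc_id(chrom, pa, first[0]),
                            _junc_id(chrom, first[1], na),
                        ),
                        exc_j=(
                            _junc_id(chrom, pa, second[0]),
                            _junc_id(chrom, second[1], na),
                        ),
                    )
                )

    # --- alternative first / last exons (transcribed strand) ----------------
    if len(e1) >= 2 and len(e2) >= 2:
        shared = set(e1) & set(e2)
        # genomically-first exon differs, a shared exon lies downstream
        f1, f2 = e1[0], e2[0]
        if f1 != f2 and not _overlaps(f1, f2) and any(
            s[0] >= max(f1[1], f2[1]) for s in shared
        ):
            mode = "AFE" if strand == "+" else "ALE"
            first, second = sorted([f1, f2])
            ft = t1 if first == f1 else t2
            st = t2 if first == f1 else t1
            found.append(
                dict(
                    mode=mode,
                    inclusion_form=(first,),
                    exclusion_form=(second,),
                    inc_j=(_junc_id(chrom, first[1], ft.exons[1][0]),),
                    exc_j=(_junc_id(chrom, second[1], st.exons[1][0]),),
                )
            )
        # genomically-last exon differs, a shared exon lies upstream
        l1, l2 = e1[-1], e2[-1]
        if l1 != l2 and not _overlaps(l1, l2) and any(
            s[1] <= min(l1[0], l2[0]) for s in shared
        ):
            mode = "ALE" if strand == "+" else "AFE"
            first, second = sorted([l1, l2])
            ft = t1 if first == l1 else t2
            st = t2 if first == l1 else t1
            found.append(
                dict(
                    mode=mode,
                    inclusion_form=(first,),
                    exclusion_form=(second,),
                    inc_j=(_junc_id(chrom, ft.exons[-2][1], first[0]),),
                    exc_j=(_junc_id(chrom, st.exons[-2][1], second[0]),),
                )
            )
    return found


def enumerate_events(models: Sequence[TranscriptModel]) -> list[SpliceEvent]:
    """Enumerate all distinguishable events from annotation transcript models.

    Deterministic and independent of transcript input order; duplicate events
    arising from different transcript pairs are merged; CE events subsumed by
    an MCE spanning the same skipped region are dropped.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)

    events: list[SpliceEvent] = []
    for gene_id in sorted(by_gene):
        group = sorted(by_gene[gene_id], key=lambda m: m.transcript_id)
        raw: dict[tuple, dict] = {}
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if group[i].exons == group[j].exons:
                    continue
                for ev in _pair_events(group[i], group[j]):
                    key = (ev["mode"], ev["inclusion_form"], ev["exclusion_form"])
                    raw.setdefault(key, ev)

        # MCE supersedes constituent CEs with matching flanks
        mce_spans = [
            (ev["inclusion_form"][0][0], ev["inclusion_form"][-1][1])
            for (mode, _, _), ev in raw.items()
            if mode == "MCE"
        ]
        kept = []
        for (mode, inc, exc), ev in raw.items():
            if mode == "CE" and any(
                lo <= inc[0][0] and inc[-1][1] <= hi for lo, hi in mce_spans
            ):
                continue
            kept.append(ev)

        chrom = group[0].chrom
        strand = group[0].strand
        kept.sort(key=lambda ev: (ev["inclusion_form"][0], ev["mode"]))
        for ev in kept:
            lo = ev["inclusion_form"][0][0]
            hi = ev["inclusion_form"][-1][1]
            events.append(
                SpliceEvent(
                    event_id=f"{gene_id}:{ev['mode']}:{lo}-{hi}",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    mode=ev["mode"],
                    inclusion_form=ev["inclusion_form"],
                    exclusion_form=ev["exclusion_form"],
                    inclusion_junctions=tuple(ev["inc_j"]),
                    exclusion_junctions=tuple(ev["exc_j"]),
                )
            )
    events.sort(key=lambda e: (e.chrom, e.inclusion_form[0], e.mode, e.event_id))
    return events


class EventInclusionModel:
    """PSI model: differential inclusion of events from junction counts.

    ``junction_counts`` is indexed by junction id with one column per sample;
    ``design`` maps sample -> {control, knockdown}.
    """

    def __init__(
        self,
        events: Sequence[SpliceEvent],
        junction_counts: pd.DataFrame,
        design: Mapping[str, str],
    ):
        conds = {design.get(s) for s in junction_counts.columns}
        if not {"control", "knockdown"} <= conds:
            raise ConfigurationError("design must contain control and knockdown samples")
        self.events = list(events)
        self.junction_counts = junction_counts
        self.design = dict(design)

    def fit(self, alpha: float = 0.05, adjust: bool = True) -> "EventInclusionResults":
        jc = self.junction_counts
        ctl = [s for s in jc.columns if self.design[s] == "control"]
        kd = [s for s in jc.columns if self.design[s] == "knockdown"]
        rows = []
        for ev in self.events:
            inc = jc.reindex(list(ev.inclusion_junctions)).fillna(0)
            exc = jc.reindex(list(ev.exclusion_junctions)).fillna(0)
            ic, ik = inc[ctl].to_numpy().sum(), inc[kd].to_numpy().sum()
            ec, ek = exc[ctl].to_numpy().sum(), exc[kd].to_numpy().sum()
            rows.append((ev.event_id, ev.gene_id, ev.mode, ic, ec, ik, ek))
        res = pd.DataFrame(
            rows,
            columns=[
                "event_id",
                "gene_id",
                "mode",
                "inc_control",
                "exc_control",
                "inc_knockdown",
                "exc_knockdown",
            ],
        ).set_index("event_id")

        tot_c = res["inc_control"] + res["exc_control"]
        tot_k = res["inc_knockdown"] + res["exc_knockdown"]
        tested = (tot_c > 0) & (tot_k > 0)
        res["psi_control"] = np.where(tot_c > 0, res["inc_control"] / tot_c.replace(0, 1), np.nan)
        res["psi_knockdown"] = np.where(tot_k > 0, res["inc_knockdown"] / tot_k.replace(0, 1), np.nan)
        res["delta_psi"] = res["psi_knockdown"] - res["psi_control"]

        pval = np.full(len(res), np.nan)
        tab = res[["inc_control", "exc_control", "inc_knockdown", "exc_knockdown"]].to_numpy()
        for i in np.flatnonzero(tested.values):
            a, b, c, d = (int(x) for x in tab[i])
            _, pval[i] = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        res["p_value"] = pval
        padj = np.full(len(res), np.nan)
        if tested.any():
            padj[tested.values] = multipletests(pval[tested.values], method="fdr_bh")[1]
        res["p_adjust"] = padj
        crit = res["p_adjust"] if adjust else res["p_value"]
        res["significant"] = (crit < alpha).fillna(False)
        res["tested"] = tested.values
        return EventInclusionResults(res, alpha=alpha, adjust=adjust)


@dataclass
class EventInclusionResults:
    table: pd.DataFrame
    alpha: float
    adjust: bool

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def summary(self) -> str:
        t = self.table
        mode_counts = t.groupby("mode").size().to_dict()
        return "\n".join(
            [
                "Differential event inclusion (PSI, conditional exact test, "
                + ("BH-adjusted)" if self.adjust else "raw p)"),
                f"  events: {len(t)} total, {int(t['tested'].sum())} tested, "
                f"{self.n_significant} significant at alpha={self.alpha}",
                "  by mode: "
                + ", ".join(f"{m}={n}" for m, n in sorted(mode_counts.items())),
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        cols = [
            "gene_id",
            "mode",
            "psi_control",
            "psi_knockdown",
            "delta_psi",
            "p_value",
            "p_adjust",
            "significant",
        ]
        self.table[cols].to_csv(path, sep="\t")


def psi_test(
    events: Sequence[SpliceEvent],
    junction_counts: pd.DataFrame,
    design: Mapping[str, str],
    alpha: float = 0.05,
    adjust: bool = True,
) -> EventInclusionResults:
    """Functional wrapper: fit an :class:`EventInclusionModel` in one call."""
    return EventInclusionModel(events, junction_counts, design).fit(
        alpha=alpha, adjust=adjust
    )


def write_events_tsv(events: Sequence[SpliceEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("event_id\tgene_id\tmode\tstrand\tinclusion_form\texclusion_form\n")
        for ev in events:
            inc = ",".join(f"{s}-{e}" for s, e in ev.inclusion_form)
            exc = ",".join(f"{s}-{e}" for s, e in ev.exclusion_form)
            fh.write(
                f"{ev.event_id}\t{ev.gene_id}\t{ev.mode}\t{ev.strand}\t{inc}\t{exc}\n"
            )
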