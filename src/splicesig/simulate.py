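"""Synthetic annotation, counts, junctions, tracks, gene sets and protein
lists with known ground truth.

The generator emulates the statistical structure the pipeline's analyses
assume: negative-binomial gene totals split multinomially over counting
bins with differential usage planted at known exons; transcript pairs
constructed so every alternative-splicing event mode occurs; junction
counts binomial around a baseline PSI of 0.5 with a planted knockdown
shift; per-marker peak files with class-dependent placement probabilities
over exon bodies plus Poisson background peaks; and gene sets / protein
lists with planted overlap.

Every output draws from its own RNG stream seeded by (master seed, file
label), so adding one output never shifts another; identical config + seed
gives byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import ExonRecord, TranscriptModel, flatten_gene_exons
from .events import SpliceEvent, EVENT_MODES
from .tracks import PeakSet, SignalTrack
from .usage import ConfigurationError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_annotation",
    "simulate_counts",
    "simulate_tracks",
    "simulate_junctions",
    "simulate_gene_sets",
    "simulate_protein_lists",
    "write_simulation",
    "DEFAULT_MARKER_SCENARIO",
]

_STREAMS = {
    "annotation": 1,
    "counts": 2,
    "tracks": 3,
    "junctions": 4,
    "genesets": 5,
    "proteins": 6,
}


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[label]])


# Qualitative marker scenario: DNA hydroxymethylation, promoter-type H3K4me3,
# MeCP2 itself and elongating Pol II enriched over down-regulated (inclusive)
# exon bodies; gene-body H3K36me3 enriched over up-regulated (exclusive)
# exons; DNA methylation depleted over both changed classes.
DEFAULT_MARKER_SCENARIO: dict[str, dict[str, float]] = {
    "MeCP2": {"down": 0.8, "up": 0.1, "unchanged": 0.1},
    "PolII": {"down": 0.8, "up": 0.1, "unchanged": 0.1},
    "5hmC": {"down": 0.8, "up": 0.1, "unchanged": 0.1},
    "H3K4me3": {"down": 0.8, "up": 0.1, "unchanged": 0.1},
    "H3K36me3": {"down": 0.1, "up": 0.8, "unchanged": 0.1},
    "5mC": {"down": 0.05, "up": 0.05, "unchanged": 0.3},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Defaults emulate a bulk RNA-seq experiment in biological triplicate at a
    mean of 2000 reads per gene with NB dispersion 0.1 (variance =
    mean + 0.1 * mean^2), a two-fold planted usage change at 10% + 10% of
    bins, junction tables at mean depth 200 with a planted PSI shift of 0.4,
    and class-specific peak enrichment 0.8 vs 0.1.
    """

    seed: int = 0
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (200, 1000)
    n_replicates: int = 3
    sequencing_depth: float = 2000.0
    nb_dispersion: float = 0.1
    frac_up: float = 0.1
    frac_down: float = 0.1
    usage_effect: float = 1.0
    peak_prob_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"down": 0.8, "up": 0.1, "unchanged": 0.1}
    )
    background_peak_rate: float = 0.5  # peaks per 10 kb
    delta_psi_planted: float = 0.4
    frac_events_changed: float = 0.2
    junction_depth: float = 200.0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise ConfigurationError("frac_up/frac_down must lie in [0, 1]")
        if self.frac_up + self.frac_down >= 1:
            raise ConfigurationError("frac_up + frac_down must be < 1")
        for lo, hi in (self.exons_per_gene, self.exon_length, self.intron_length):
            if lo <= 0 or hi < lo:
                raise ConfigurationError("ranges must be positive and ordered")
        if self.exons_per_gene[0] < 4:
            raise ConfigurationError(
                "need >= 4 exons per gene to host every event mode"
            )
        if self.intron_length[0] < 12:
            raise ConfigurationError(
                "intron budget too small for splice-site shifts (min 12 bp)"
            )
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth serialized alongside simulation outputs."""

    exon_usage_class: dict[str, str] = field(default_factory=dict)
    planted_exons: dict[str, str] = field(default_factory=dict)
    event_delta_psi: dict[str, float] = field(default_factory=dict)
    marker_enriched_class: dict[str, str] = field(default_factory=dict)
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    high_confidence_proteins: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _gene_transcripts(
    gene_id: str,
    chrom: str,
    strand: str,
    mode: str,
    offset: int,
    biotype: str,
    rng: np.random.Generator,
    cfg: SimulationConfig,
) -> tuple[list[TranscriptModel], int]:
    """Build two transcripts of one gene planting exactly one ``mode`` event."""
    lo_e, hi_e = cfg.exon_length
    lo_i, hi_i = cfg.intron_length
    shift = int(min(30, max(3, lo_i // 3)))

    if mode == "MXE":
        # e0 - A - B - e3 with T1 = e0,A,e3 and T2 = e0,B,e3
        lens = rng.integers(lo_e, hi_e + 1, size=4)
        gaps = rng.integers(lo_i, hi_i + 1, size=3)
        pos = offset
        exons = []
        for L, g in zip(lens, list(gaps) + [0]):
            exons.append((pos, pos + int(L)))
            pos += int(L) + int(g)
        e0, A, B, e3 = exons
        t1 = [e0, A, e3]
        t2 = [e0, B, e3]
        end = pos
    else:
        n = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        lens = rng.integers(lo_e, hi_e + 1, size=n)
        gaps = rng.integers(lo_i, hi_i + 1, size=n - 1)
        pos = offset
        exons = []
        for i, L in enumerate(lens):
            exons.append((pos, pos + int(L)))
            pos += int(L) + (int(gaps[i]) if i < n - 1 else 0)
        end = pos
        mid = n // 2
        t1 = list(exons)
        if mode == "CE":
            t2 = exons[:mid] + exons[mid + 1 :]
        elif mode == "MCE":
            t2 = exons[: mid - 1] + exons[mid + 1 :]
        elif mode in ("A5SS", "A3SS"):
            s, e = exons[mid]
            # donor side = exon end on '+', exon start on '-'
            vary_end = (mode == "A5SS") == (strand == "+")
            var = (s, e + shift) if vary_end else (s - shift, e)
            t2 = exons[:mid] + [var] + exons[mid + 1 :]
        elif mode == "RI":
            t2 = exons[:mid] + [(exons[mid][0], exons[mid + 1][1])] + exons[mid + 2 :]
        elif mode in ("AFE", "ALE"):
            alt_len = int(rng.integers(lo_e, hi_e + 1))
            gap = int(rng.integers(lo_i, hi_i + 1))
            # AFE on '+' and ALE on '-' vary the genomically-first exon
            vary_first = (mode == "AFE") == (strand == "+")
            if vary_first:
                s0 = exons[0]
                alt = (s0[0] - gap - alt_len, s0[0] - gap)
                t2 = [alt] + exons[1:]
            else:
                sl = exons[-1]
                alt = (sl[1] + gap, sl[1] + gap + alt_len)
                t2 = exons[:-1] + [alt]
                end = alt[1]
        else:
            raise ValueError(f"unknown mode {mode}")

    models = [
        TranscriptModel(f"{gene_id}.1", gene_id, chrom, strand, tuple(t1), biotype),
        TranscriptModel(f"{gene_id}.2", gene_id, chrom, strand, tuple(t2), biotype),
    ]
    return models, end


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[str, list[TranscriptModel]]:
    """Generate a synthetic genome annotation: (GTF text, transcript models).

    Gene *i* plants event mode ``EVENT_MODES[i % 8]``, alternating strand and
    chromosome; gene loci never overlap. Most genes are protein_coding, every
    fifth is a processed_transcript so coding classification has both
    classes. Deterministic under the config seed.
    """
    rng = _rng(config.seed, "annotation")
    models: list[TranscriptModel] = []
    offsets = {"chr1": 20_000, "chr2": 20_000}
    for i in range(config.n_genes):
        gene_id = f"G{i + 1:04d}"
        chrom = "chr1" if i % 2 == 0 else "chr2"
        strand = "+" if (i // 2) % 2 == 0 else "-"
        mode = EVENT_MODES[i % len(EVENT_MODES)]
        biotype = "processed_transcript" if i % 5 == 4 else "protein_coding"
        group, end = _gene_transcripts(
            gene_id, chrom, strand, mode, offsets[chrom], biotype, rng, config
        )
        models.extend(group)
        offsets[chrom] = end + 10_000

    lines = []
    for m in models:
        for s, e in m.exons:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_biotype "{m.biotype}";'
            )
            lines.append(
                f"{m.chrom}\t{m.biotype}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}"
            )
    return "\n".join(lines) + "\n", models


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts(
    config: SimulationConfig,
    models: Sequence[TranscriptModel],
) -> tuple[pd.DataFrame, dict[str, str], GroundTruth]:
    """NB gene totals split multinomially over counting bins with planted usage.

    Returns (counts DataFrame indexed by exon_id, design sample->condition,
    ground truth). Planted "up" exons have their knockdown within-gene
    proportion multiplied by 2**usage_effect (then renormalized); "down"
    symmetric. Because renormalization shifts every other bin of a planted
    gene slightly in the opposite direction, the ground truth labels each
    exon by its *true* usage-odds change (exactly zero -> unchanged) and
    records the primary planted exons separately in ``planted_exons``.
    """
    rng = _rng(config.seed, "counts")
    exons = flatten_gene_exons(models)
    by_gene: dict[str, list[ExonRecord]] = {}
    for ex in exons:
        by_gene.setdefault(ex.gene_id, []).append(ex)

    eligible = [ex.exon_id for ex in exons if len(by_gene[ex.gene_id]) > 1]
    n_up = int(round(config.frac_up * len(eligible)))
    n_down = int(round(config.frac_down * len(eligible)))
    chosen = rng.choice(len(eligible), size=n_up + n_down, replace=False)
    truth = GroundTruth()
    for j in chosen[:n_up]:
        truth.planted_exons[eligible[j]] = "up"
    for j in chosen[n_up:]:
        truth.planted_exons[eligible[j]] = "down"

    R = config.n_replicates
    samples = [f"control_{r + 1}" for r in range(R)] + [
        f"knockdown_{r + 1}" for r in range(R)
    ]
    design = {s: ("control" if s.startswith("control") else "knockdown") for s in samples}

    rows = {}
    for gene_id in sorted(by_gene):
        bins = by_gene[gene_id]
        lengths = np.array([ex.length for ex in bins], dtype=float)
        base = lengths * rng.uniform(0.5, 1.5, size=len(bins))
        p_ctl = base / base.sum()
        mult = np.array(
            [
                2.0 ** (config.usage_effect if truth.planted_exons.get(ex.exon_id) == "up"
                        else -config.usage_effect if truth.planted_exons.get(ex.exon_id) == "down"
                        else 0.0)
                for ex in bins
            ]
        )
        p_kd = p_ctl * mult
        p_kd = p_kd / p_kd.sum()
        # true per-exon usage change, including renormalization side effects
        with np.errstate(divide="ignore", invalid="ignore"):
            true_lfc = np.log2((p_kd / (1 - p_kd)) / (p_ctl / (1 - p_ctl)))
        for ex, d in zip(bins, true_lfc):
            truth.exon_usage_class[ex.exon_id] = (
                "up" if d > 1e-9 else "down" if d < -1e-9 else "unchanged"
            )
        counts = np.zeros((len(bins), 2 * R), dtype=np.int64)
        for col, s in enumerate(samples):
            p = p_ctl if design[s] == "control" else p_kd
            if config.nb_dispersion > 0:
                r_nb = 1.0 / config.nb_dispersion
                total = rng.negative_binomial(
                    r_nb, r_nb / (r_nb + config.sequencing_depth)
                )
            else:
                total = rng.poisson(config.sequencing_depth)
            counts[:, col] = rng.multinomial(int(total), p)
        for ex, row in zip(bins, counts):
            rows[ex.exon_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    df.index.name = "exon_id"
    return df, design, truth


# ---------------------------------------------------------------------------
# tracks and peaks
# ---------------------------------------------------------------------------

def simulate_tracks(
    config: SimulationConfig,
    exons: Sequence[ExonRecord],
    markers: Mapping[str, Mapping[str, float]] | None = None,
    with_signal: bool = True,
    grid: int = 25,
) -> tuple[dict[str, SignalTrack], dict[str, PeakSet], GroundTruth]:
    """Per-marker peaks with class-dependent exon-body placement plus noise tracks.

    ``markers`` maps marker label -> {usage_class: peak probability}; the
    default is :data:`DEFAULT_MARKER_SCENARIO`. The bedGraph-style signal is
    piecewise constant on a ``grid``-bp lattice: gamma background noise
    (mean 1) plus a constant 6 inside peaks.
    """
    rng = _rng(config.seed, "tracks")
    if markers is None:
        markers = DEFAULT_MARKER_SCENARIO
    truth = GroundTruth()
    extent: dict[str, int] = {}
    for ex in exons:
        extent[ex.chrom] = max(extent.get(ex.chrom, 0), ex.end + 5000)

    peak_sets: dict[str, PeakSet] = {}
    tracks: dict[str, SignalTrack] = {}
    for marker in sorted(markers):
        probs = markers[marker]
        enriched = max(probs, key=lambda c: probs[c])
        truth.marker_enriched_class[marker] = enriched
        peaks: list[tuple[str, int, int, float]] = []
        for ex in exons:
            p = probs.get(ex.usage_class, 0.0)
            if p > 0 and rng.random() < p:
                peaks.append((ex.chrom, ex.start, ex.end, 10.0))
        for chrom, length in sorted(extent.items()):
            n_bg = rng.poisson(config.background_peak_rate * length / 10_000)
            for _ in range(int(n_bg)):
                w = int(rng.integers(150, 400))
                s = int(rng.integers(0, max(1, length - w)))
                peaks.append((chrom, s, s + w, 5.0))
        pset = PeakSet(peaks, source_label=marker)
        peak_sets[marker] = pset
        if with_signal:
            ivs: dict[str, list[tuple[int, int, float]]] = {}
            for chrom, length in sorted(extent.items()):
                n_seg = length // grid + 1
                noise = rng.gamma(4.0, 0.25, size=n_seg)
                occ = pset.occupancy(chrom, 0, n_seg * grid)
                # a grid segment counts as inside a peak when its midpoint is
                mid = np.minimum(np.arange(n_seg) * grid + grid // 2, n_seg * grid - 1)
                vals = noise + 6.0 * occ[mid]
                ivs[chrom] = [
                    (i * grid, (i + 1) * grid, round(float(v), 3))
                    for i, v in enumerate(vals)
                ]
            tracks[marker] = SignalTrack(ivs)
    return tracks, peak_sets, truth


# ---------------------------------------------------------------------------
# junctions
# ---------------------------------------------------------------------------

def simulate_junctions(
    config: SimulationConfig,
    events: Sequence[SpliceEvent],
) -> tuple[pd.DataFrame, dict[str, str], GroundTruth]:
    """Binomial junction counts around baseline PSI 0.5 with planted shifts.

    A fraction ``frac_events_changed`` of events has knockdown PSI shifted by
    ``delta_psi_planted`` (clipped to [0.02, 0.98]). Per replicate the event
    total is Poisson(junction_depth); inclusion reads are recorded on the
    event's first inclusion junction, exclusion reads on its first exclusion
    junction.
    """
    rng = _rng(config.seed, "junctions")
    R = config.n_replicates
    samples = [f"control_{r + 1}" for r in range(R)] + [
        f"knockdown_{r + 1}" for r in range(R)
    ]
    design = {s: ("control" if s.startswith("control") else "knockdown") for s in samples}

    n_changed = int(round(config.frac_events_changed * len(events)))
    changed_idx = set(
        rng.choice(len(events), size=n_changed, replace=False).tolist()
    ) if n_changed else set()

    truth = GroundTruth()
    counts: dict[str, np.ndarray] = {}
    for i, ev in enumerate(events):
        delta = config.delta_psi_planted if i in changed_idx else 0.0
        truth.event_delta_psi[ev.event_id] = float(delta)
        psi_ctl = 0.5
        psi_kd = float(np.clip(0.5 + delta, 0.02, 0.98))
        inc_row = counts.setdefault(
            ev.inclusion_junctions[0], np.zeros(2 * R, dtype=np.int64)
        )
        exc_row = counts.setdefault(
            ev.exclusion_junctions[0], np.zeros(2 * R, dtype=np.int64)
        )
        for col, s in enumerate(samples):
            psi = psi_ctl if design[s] == "control" else psi_kd
            total = rng.poisson(config.junction_depth)
            inc = rng.binomial(total, psi) if total > 0 else 0
            inc_row[col] += inc
            exc_row[col] += total - inc
    df = pd.DataFrame.from_dict(counts, orient="index", columns=samples)
    df.index.name = "junction"
    return df.sort_index(), design, truth


# ---------------------------------------------------------------------------
# gene sets and protein lists
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    config: SimulationConfig,
    models: Sequence[TranscriptModel],
    usage_truth: GroundTruth,
) -> tuple[list, GroundTruth]:
    """GMT-style sets: sets built around genes with planted exons plus random sets."""
    from .enrichment import GeneSet

    rng = _rng(config.seed, "genesets")
    genes = sorted({m.gene_id for m in models})
    down_genes = sorted(
        {e.rsplit(":", 1)[0] for e, c in usage_truth.exon_usage_class.items() if c == "down"}
    )
    up_genes = sorted(
        {e.rsplit(":", 1)[0] for e, c in usage_truth.exon_usage_class.items() if c == "up"}
    )
    truth = GroundTruth()
    sets = []
    for set_id, members in (
        ("PLANTED_DOWN", down_genes),
        ("PLANTED_UP", up_genes),
    ):
        if members:
            noise = rng.choice(genes, size=max(1, len(genes) // 10), replace=False)
            full = sorted(set(members) | set(noise.tolist()))
            sets.append(GeneSet(set_id, f"genes with planted {set_id.lower()} exons", frozenset(full)))
            truth.gene_sets[set_id] = full
    for k in range(3):
        members = sorted(
            rng.choice(genes, size=max(2, len(genes) // 5), replace=False).tolist()
        )
        sets.append(GeneSet(f"RANDOM_{k + 1}", "random gene set", frozenset(members)))
        truth.gene_sets[f"RANDOM_{k + 1}"] = members
    return sets, truth


def simulate_protein_lists(config: SimulationConfig):
    """Three overlapping protein lists with contaminants in the anchor list.

    Returns (ProteinListSet, GroundTruth) where the truth carries the
    expected high-confidence interactor set (anchor minus contaminants,
    restricted to proteins also seen in a support list).
    """
    from .enrichment import ProteinListSet, high_confidence_interactors

    rng = _rng(config.seed, "proteins")
    pool = [f"PROT{i:04d}" for i in range(1, 201)]
    anchor_core = rng.choice(pool, size=40, replace=False).tolist()
    contaminants = ["KRT1", "KRT5", "RPL3", "RPS6"]
    anchor = anchor_core + contaminants
    support_a = rng.choice(anchor_core, size=20, replace=False).tolist() + rng.choice(
        pool, size=60, replace=False
    ).tolist()
    support_b = rng.choice(anchor_core, size=15, replace=False).tolist() + rng.choice(
        pool, size=50, replace=False
    ).tolist() + ["KRT1"]
    lists = ProteinListSet(
        {
            "cell_line": set(anchor),
            "neurons": set(support_a),
            "cortex": set(support_b),
        }
    )
    truth = GroundTruth()
    truth.high_confidence_proteins = sorted(
        high_confidence_interactors(lists, "cell_line", ["neurons", "cortex"])
    )
    return lists, truth


# ---------------------------------------------------------------------------
# full simulation directory
# ---------------------------------------------------------------------------

def write_simulation(
    config: SimulationConfig,
    outdir: str | Path,
    with_signal: bool = True,
) -> GroundTruth:
    """Write a complete synthetic dataset to ``outdir`` and return the merged truth.

    Layout: annotation.gtf, counts.tsv, design.tsv, junctions.tsv,
    tracks/<marker>.bedgraph, peaks/<marker>.bed, genesets.gmt,
    proteins/<label>.txt, ground_truth.json, config.json.
    """
    from .enrichment import write_gmt
    from .events import enumerate_events

    outdir = Path(outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    (outdir / "peaks").mkdir(exist_ok=True)
    (outdir / "proteins").mkdir(exist_ok=True)

    gtf_text, models = simulate_annotation(config)
    (outdir / "annotation.gtf").write_text(gtf_text)

    counts, design, truth = simulate_counts(config, models)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    with open(outdir / "design.tsv", "w") as fh:
        fh.write("sample_id\tcondition\n")
        for s, c in design.items():
            fh.write(f"{s}\t{c}\n")

    events = enumerate_events(models)
    junctions, _, jtruth = simulate_junctions(config, events)
    junctions.to_csv(outdir / "junctions.tsv", sep="\t")
    truth.event_delta_psi = jtruth.event_delta_psi

    exons = flatten_gene_exons(models)
    exons = [
        replace(ex, usage_class=truth.exon_usage_class[ex.exon_id]) for ex in exons
    ]
    tracks, peaks, ttruth = simulate_tracks(config, exons, with_signal=with_signal)
    truth.marker_enriched_class = ttruth.marker_enriched_class
    for marker, pset in peaks.items():
        pset.to_bed(outdir / "peaks" / f"{marker}.bed")
    for marker, track in tracks.items():
        track.to_bedgraph(outdir / "tracks" / f"{marker}.bedgraph")

    sets, gtruth = simulate_gene_sets(config, models, truth)
    write_gmt(sets, outdir / "genesets.gmt")
    truth.gene_sets = gtruth.gene_sets

    plists, ptruth = simulate_protein_lists(config)
    for label, ids in plists.lists.items():
        with open(outdir / "proteins" / f"{label}.txt", "w") as fh:
            fh.write("\n".join(sorted(ids)) + "\n")
    truth.high_confidence_proteins = ptruth.high_confidence_proteins

    truth.to_json(outdir / "ground_truth.json")
    cfg = asdict(config)
    cfg["peak_prob_by_class"] = dict(cfg["peak_prob_by_class"])
    with open(outdir / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=1)
    return truth
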