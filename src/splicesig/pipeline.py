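"""End-to-end orchestration: annotation -> usage -> events -> profiles -> enrichment.

``run_all`` executes the stages in dependency order against a directory of
input files (the layout written by :func:`splicesig.simulate.write_simulation`
or assembled by hand), writes plain-text TSV outputs and a JSON manifest
with input checksums, and skips stages whose inputs are missing (with a
warning) or whose outputs are already up to date.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import classify_coding, flatten_gene_exons, read_gtf, write_bed
from .enrichment import fisher_enrich, read_gmt
from .events import enumerate_events, psi_test, write_events_tsv
from .metaprofile import build_profiles, compare_classes, comparisons_to_frame
from .tracks import read_bed_peaks
from .usage import ExonUsageModel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_all"]

STAGES = ("annotation", "usage", "events", "metaprofile", "enrichment")


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run (all thresholds are the
    analysis defaults: usage alpha 0.05 BH-adjusted, event p 0.05,
    smoothing window 10 bp, minimum gene count 20)."""

    indir: Path
    outdir: Path
    alpha: float = 0.05
    min_gene_count: int = 20
    adjust: bool = True
    window: int = 10
    profile_mode: str | None = None  # None = occupancy for peaks

    def __post_init__(self) -> None:
        self.indir = Path(self.indir)
        self.outdir = Path(self.outdir)


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    started: float = field(default_factory=time.time)
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, status: str, inputs: dict, outputs: list[str], **counts) -> None:
        self.stages.append(
            dict(stage=name, status=status, inputs=inputs, outputs=outputs, counts=counts)
        )
        msg = ", ".join(f"{k}={v}" for k, v in counts.items())
        logger.info("stage %s: %s (%s)", name, status, msg)

    @property
    def completed(self) -> list[str]:
        return [s["stage"] for s in self.stages if s["status"] in ("completed", "cached")]

    def to_json(self, path: str | Path) -> None:
        payload = dict(
            config=self.config,
            version=self.version,
            started=self.started,
            finished=time.time(),
            stages=self.stages,
        )
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_previous(outdir: Path) -> dict[str, dict]:
    mf = outdir / "manifest.json"
    if not mf.exists():
        return {}
    try:
        with open(mf) as fh:
            prev = json.load(fh)
        return {s["stage"]: s for s in prev.get("stages", [])}
    except (json.JSONDecodeError, KeyError):
        return {}


def _cached(prev: dict[str, dict], name: str, inputs: dict, outdir: Path) -> bool:
    s = prev.get(name)
    if not s or s.get("status") not in ("completed", "cached"):
        return False
    if s.get("inputs") != inputs:
        return False
    return all((outdir / Path(o).name).exists() for o in s.get("outputs", []))


def run_all(config: PipelineConfig) -> RunManifest:
    """Run every stage whose inputs exist; returns the manifest.

    Any stage failure propagates (the CLI converts it to a non-zero exit
    naming the stage); absent optional inputs disable dependent stages with
    a logged warning. Re-running with identical inputs reports stages as
    cached.
    """
    indir, outdir = config.indir, config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    prev = _load_previous(outdir)
    manifest = RunManifest(config=dict(vars(config)))

    # --- annotation ---------------------------------------------------------
    gtf = indir / "annotation.gtf"
    if not gtf.exists():
        raise FileNotFoundError(f"stage annotation: missing {gtf}")
    inputs = {"annotation.gtf": _sha256(gtf)}
    models = read_gtf(gtf)
    exons = classify_coding(flatten_gene_exons(models), models)
    if _cached(prev, "annotation", inputs, outdir):
        manifest.record("annotation", "cached", inputs, ["exons.bed"])
    else:
        write_bed(exons, outdir / "exons.bed")
        manifest.record(
            "annotation", "completed", inputs, ["exons.bed"],
            transcripts=len(models), exons=len(exons),
            coding=sum(e.coding_class == "coding" for e in exons),
        )

    # --- exon usage ---------------------------------------------------------
    counts_p, design_p = indir / "counts.tsv", indir / "design.tsv"
    usage_results = None
    if counts_p.exists() and design_p.exists():
        inputs = {"counts.tsv": _sha256(counts_p), "design.tsv": _sha256(design_p)}
        model = ExonUsageModel.from_files(counts_p, design_p, exons)
        usage_results = model.fit(
            alpha=config.alpha, min_gene_count=config.min_gene_count,
            adjust=config.adjust,
        )
        exons = usage_results.classify_exons(exons)
        if _cached(prev, "usage", inputs, outdir):
            manifest.record("usage", "cached", inputs, ["usage.tsv"])
        else:
            usage_results.to_tsv(outdir / "usage.tsv")
            manifest.record(
                "usage", "completed", inputs, ["usage.tsv"],
                tested=usage_results.n_tested,
                up=usage_results.n_up, down=usage_results.n_down,
            )
    else:
        logger.warning("usage stage skipped: counts.tsv/design.tsv not found")
        manifest.record("usage", "skipped", {}, [])

    # --- splice events ------------------------------------------------------
    events = enumerate_events(models)
    junc_p = indir / "junctions.tsv"
    if junc_p.exists() and design_p.exists():
        inputs = {"junctions.tsv": _sha256(junc_p), "design.tsv": _sha256(design_p)}
        jc = pd.read_csv(junc_p, sep="\t", index_col=0)
        design_df = pd.read_csv(design_p, sep="\t")
        design = dict(zip(design_df.iloc[:, 0], design_df.iloc[:, 1]))
        psi = psi_test(events, jc, design, alpha=config.alpha, adjust=config.adjust)
        if _cached(prev, "events", inputs, outdir):
            manifest.record("events", "cached", inputs, ["events.tsv", "psi.tsv"])
        else:
            write_events_tsv(events, outdir / "events.tsv")
            psi.to_tsv(outdir / "psi.tsv")
            manifest.record(
                "events", "completed", inputs, ["events.tsv", "psi.tsv"],
                events=len(events), significant=psi.n_significant,
            )
    else:
        logger.warning("events stage skipped: junctions.tsv not found")
        manifest.record("events", "skipped", {}, [])

    # --- metaprofile --------------------------------------------------------
    peaks_dir = indir / "peaks"
    peak_files = sorted(peaks_dir.glob("*.bed")) if peaks_dir.is_dir() else []
    if peak_files and usage_results is not None:
        inputs = {p.name: _sha256(p) for p in peak_files}
        sources = {p.stem: read_bed_peaks(p, source_label=p.stem) for p in peak_files}
        profiles = build_profiles(
            exons, sources, window=config.window, mode=config.profile_mode
        )
        comps = compare_classes(profiles, region="body")
        if _cached(prev, "metaprofile", inputs, outdir):
            manifest.record("metaprofile", "cached", inputs, ["profiles", "comparisons.tsv"])
        else:
            prof_dir = outdir / "profiles"
            prof_dir.mkdir(exist_ok=True)
            for (marker, cls), prof in profiles.items():
                prof.to_tsv(prof_dir / f"{marker}.{cls}.tsv")
            comparisons_to_frame(comps).to_csv(
                outdir / "comparisons.tsv", sep="\t", index=False
            )
            manifest.record(
                "metaprofile", "completed", inputs, ["profiles", "comparisons.tsv"],
                markers=len(sources), profiles=len(profiles), comparisons=len(comps),
            )
    else:
        logger.warning("metaprofile stage skipped: peaks or usage classes missing")
        manifest.record("metaprofile", "skipped", {}, [])

    # --- enrichment ---------------------------------------------------------
    gmt_p = indir / "genesets.gmt"
    if gmt_p.exists() and usage_results is not None:
        inputs = {"genesets.gmt": _sha256(gmt_p)}
        sets = read_gmt(gmt_p)
        tested = usage_results.table[usage_results.table["usage_class"] != "untested"]
        universe = set(tested["gene_id"])
        sig = tested[tested["usage_class"].isin(["up", "down"])]
        query = set(sig["gene_id"])
        if query:
            enr = fisher_enrich(query, sets, universe, alpha=config.alpha)
            if _cached(prev, "enrichment", inputs, outdir):
                manifest.record("enrichment", "cached", inputs, ["enrichment.tsv"])
            else:
                enr.to_csv(outdir / "enrichment.tsv", sep="\t")
                manifest.record(
                    "enrichment", "completed", inputs, ["enrichment.tsv"],
                    sets=len(sets), query=len(query),
                    significant=int(enr["significant"].sum()),
                )
        else:
            logger.warning("enrichment stage skipped: no significant genes")
            manifest.record("enrichment", "skipped", inputs, [])
    else:
        logger.warning("enrichment stage skipped: genesets.gmt or usage missing")
        manifest.record("enrichment", "skipped", {}, [])

    manifest.to_json(outdir / "manifest.json")
    return manifest
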