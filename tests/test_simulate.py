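from collections import Counter

import numpy as np
import pytest

from splicesig.annotation import flatten_gene_exons, read_gtf
from splicesig.events import EVENT_MODES, enumerate_events
from splicesig.simulate import (
    SimulationConfig,
    GroundTruth,
    simulate_annotation,
    simulate_counts,
    simulate_junctions,
    simulate_tracks,
    write_simulation,
)
from splicesig.tracks import read_bedgraph
from splicesig.usage import ConfigurationError


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(frac_up=0.6, frac_down=0.5),
            dict(exons_per_gene=(2, 3)),
            dict(intron_length=(5, 10)),
            dict(nb_dispersion=-1),
            dict(exon_length=(300, 100)),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)


class TestAnnotation:
    def test_every_mode_planted(self):
        _, models = simulate_annotation(SimulationConfig(seed=2, n_genes=16))
        modes = Counter(e.mode for e in enumerate_events(models))
        assert set(modes) == set(EVENT_MODES)
        assert all(v == 2 for v in modes.values())

    def test_gene_loci_disjoint(self):
        _, models = simulate_annotation(SimulationConfig(seed=2, n_genes=20))
        spans = {}
        for m in models:
            s, e = m.span
            cur = spans.setdefault((m.chrom, m.gene_id), [s, e])
            cur[0], cur[1] = min(cur[0], s), max(cur[1], e)
        for chrom in ("chr1", "chr2"):
            ivs = sorted(v for (c, _), v in spans.items() if c == chrom)
            assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_deterministic_and_round_trips_through_reader(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_genes=10)
        gtf1, models = simulate_annotation(cfg)
        gtf2, _ = simulate_annotation(cfg)
        assert gtf1 == gtf2
        p = tmp_path / "sim.gtf"
        p.write_text(gtf1)
        back = read_gtf(p)
        assert {m.transcript_id: m.exons for m in back} == {
            m.transcript_id: m.exons for m in models
        }


class TestCounts:
    def test_null_config_plants_nothing(self):
        cfg = SimulationConfig(seed=1, n_genes=10, frac_up=0, frac_down=0, usage_effect=0)
        _, models = simulate_annotation(cfg)
        _, _, truth = simulate_counts(cfg, models)
        assert truth.planted_exons == {}
        assert set(truth.exon_usage_class.values()) == {"unchanged"}

    def test_poisson_limit_at_zero_dispersion(self):
        cfg = SimulationConfig(
            seed=3, n_genes=40, nb_dispersion=0.0, frac_up=0, frac_down=0,
        )
        _, models = simulate_annotation(cfg)
        counts, design, _ = simulate_counts(cfg, models)
        gene_tot = counts.groupby(counts.index.str.split(":").str[0]).sum()
        ratios = gene_tot.var(axis=1, ddof=1) / gene_tot.mean(axis=1)
        # variance/mean across replicates near 1 on average for Poisson totals
        assert 0.6 < ratios.mean() < 1.6

    def test_planted_fractions_and_truth_consistency(self):
        cfg = SimulationConfig(seed=4)
        _, models = simulate_annotation(cfg)
        counts, _, truth = simulate_counts(cfg, models)
        n_bins = len(flatten_gene_exons(models))
        n_planted = len(truth.planted_exons)
        assert n_planted == pytest.approx(0.2 * n_bins, abs=2)
        for e, c in truth.planted_exons.items():
            assert truth.exon_usage_class[e] == c
        assert set(counts.index) == set(truth.exon_usage_class)


class TestTracksAndJunctions:
    def test_no_background_no_probability_no_peaks(self):
        cfg = SimulationConfig(seed=6, n_genes=8, background_peak_rate=0.0)
        _, models = simulate_annotation(cfg)
        exons = flatten_gene_exons(models)
        _, peaks, _ = simulate_tracks(
            cfg, exons, markers={"m": {"down": 0.0, "up": 0.0, "unchanged": 0.0}},
            with_signal=False,
        )
        assert len(peaks["m"]) == 0

    def test_zero_depth_junctions_all_untested(self):
        cfg = SimulationConfig(seed=6, n_genes=8, junction_depth=0.0)
        _, models = simulate_annotation(cfg)
        events = enumerate_events(models)
        jc, design, _ = simulate_junctions(cfg, events)
        from splicesig.events import psi_test

        res = psi_test(events, jc, design)
        assert not res.table["tested"].any()

    def test_bedgraph_round_trips_through_reader(self, tmp_path):
        cfg = SimulationConfig(seed=6, n_genes=4)
        _, models = simulate_annotation(cfg)
        exons = flatten_gene_exons(models)
        tracks, _, _ = simulate_tracks(cfg, exons, markers={"m": {"unchanged": 0.3}})
        p = tmp_path / "m.bedgraph"
        tracks["m"].to_bedgraph(p)
        back = read_bedgraph(p)
        for chrom in tracks["m"].chroms:
            a = tracks["m"].coverage(chrom, 0, 2000)
            assert np.allclose(back.coverage(chrom, 0, 2000), a)


def test_write_simulation_is_deterministic_and_complete(tmp_path):
    cfg = SimulationConfig(seed=8, n_genes=12)
    t1 = write_simulation(cfg, tmp_path / "a", with_signal=False)
    t2 = write_simulation(cfg, tmp_path / "b", with_signal=False)
    for name in ["annotation.gtf", "counts.tsv", "junctions.tsv", "genesets.gmt", "ground_truth.json"]:
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
    back = GroundTruth.from_json(tmp_path / "a" / "ground_truth.json")
    assert back.exon_usage_class == t1.exon_usage_class
    assert back.high_confidence_proteins == t1.high_confidence_proteins
    assert (tmp_path / "a" / "peaks").is_dir()
    assert (tmp_path / "a" / "proteins" / "cell_line.txt").exists()
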