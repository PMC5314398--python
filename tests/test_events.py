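import random

import numpy as np
import pandas as pd
import pytest

from splicesig.annotation import TranscriptModel
from splicesig.events import (
    EVENT_MODES,
    enumerate_events,
    psi_test,
)

from _oracles import hypergeom_two_sided


def _tm(tid, gene, exons, strand="+"):
    return TranscriptModel(tid, gene, "chr1", strand, tuple(exons), "protein_coding")


class TestEnumerate:
    @pytest.mark.parametrize("mode", EVENT_MODES)
    def test_each_mode_matches_hand_enumeration(self, toy_mode_genes, mode):
        models, (exp_mode, exp_inc, exp_exc) = toy_mode_genes[mode]
        events = enumerate_events(models)
        assert len(events) == 1
        ev = events[0]
        assert (ev.mode, ev.inclusion_form, ev.exclusion_form) == (
            exp_mode,
            exp_inc,
            exp_exc,
        )

    def test_mce_supersedes_constituent_ces(self, toy_mode_genes):
        models, _ = toy_mode_genes["MCE"]
        events = enumerate_events(models)
        assert [e.mode for e in events] == ["MCE"]

    def test_strand_flip_swaps_donor_acceptor_and_terminal_modes(self):
        # same geometry as the A3SS toy gene, but minus strand -> A5SS
        models = [
            _tm("tA", "g", [(0, 100), (200, 300)], strand="-"),
            _tm("tB", "g", [(0, 100), (170, 300)], strand="-"),
        ]
        assert [e.mode for e in enumerate_events(models)] == ["A5SS"]
        # alternative genomically-first exon on minus strand is an ALE
        models = [
            _tm("tA", "g", [(0, 100), (400, 500), (600, 700)], strand="-"),
            _tm("tB", "g", [(200, 300), (400, 500), (600, 700)], strand="-"),
        ]
        assert [e.mode for e in enumerate_events(models)] == ["ALE"]

    def test_identical_transcripts_yield_no_events(self):
        models = [
            _tm("t1", "g", [(0, 100), (200, 300)]),
            _tm("t2", "g", [(0, 100), (200, 300)]),
        ]
        assert enumerate_events(models) == []

    def test_single_transcript_gene_yields_no_events(self):
        assert enumerate_events([_tm("t1", "g", [(0, 100), (200, 300)])]) == []

    def test_order_invariance_and_determinism(self, toy_mode_genes):
        models = [m for ms, _ in toy_mode_genes.values() for m in ms]
        ref = enumerate_events(models)
        assert len(ref) == len(EVENT_MODES)
        for seed in range(3):
            shuffled = list(models)
            random.Random(seed).shuffle(shuffled)
            assert enumerate_events(shuffled) == ref

    def test_forms_distinguishable_by_junctions(self, toy_mode_genes):
        models = [m for ms, _ in toy_mode_genes.values() for m in ms]
        for ev in enumerate_events(models):
            assert ev.inclusion_junctions
            assert ev.exclusion_junctions
            assert set(ev.inclusion_junctions).isdisjoint(ev.exclusion_junctions)


def _counts(ev, inc_by_sample, exc_by_sample):
    rows = {ev.inclusion_junctions[0]: inc_by_sample, ev.exclusion_junctions[0]: exc_by_sample}
    return pd.DataFrame(rows).T


class TestPsiTest:
    @pytest.fixture()
    def ce_event(self, toy_mode_genes):
        models, _ = toy_mode_genes["CE"]
        return enumerate_events(models)[0]

    DESIGN = {"c1": "control", "k1": "knockdown"}

    def test_balanced_counts_not_significant(self, ce_event):
        jc = _counts(ce_event, {"c1": 50, "k1": 50}, {"c1": 50, "k1": 50})
        res = psi_test([ce_event], jc, self.DESIGN)
        row = res.table.iloc[0]
        assert row.delta_psi == 0.0
        assert not row.significant

    def test_strong_shift_matches_oracle(self, ce_event):
        jc = _counts(ce_event, {"c1": 90, "k1": 10}, {"c1": 10, "k1": 90})
        res = psi_test([ce_event], jc, self.DESIGN)
        row = res.table.iloc[0]
        assert row.psi_control == pytest.approx(0.9)
        assert row.psi_knockdown == pytest.approx(0.1)
        assert row.delta_psi == pytest.approx(-0.8)
        p_oracle = hypergeom_two_sided(90, 10, 10, 90)
        assert p_oracle == pytest.approx(6.699175284224094e-33, rel=1e-12)
        assert row.p_value == pytest.approx(p_oracle, rel=1e-9)
        assert row.significant

    def test_zero_reads_in_a_condition_is_untested(self, ce_event):
        jc = _counts(ce_event, {"c1": 50, "k1": 0}, {"c1": 50, "k1": 0})
        res = psi_test([ce_event], jc, self.DESIGN)
        row = res.table.iloc[0]
        assert not row.tested
        assert np.isnan(row.psi_knockdown)
        assert not row.significant

    def test_label_swap_negates_delta_psi(self, ce_event):
        jc = _counts(ce_event, {"c1": 80, "k1": 30}, {"c1": 20, "k1": 70})
        a = psi_test([ce_event], jc, self.DESIGN).table.iloc[0]
        b = psi_test(
            [ce_event], jc, {"c1": "knockdown", "k1": "control"}
        ).table.iloc[0]
        assert b.delta_psi == pytest.approx(-a.delta_psi)
        assert b.p_value == pytest.approx(a.p_value, rel=1e-12)

    def test_psi_bounds(self, toy_mode_genes):
        models = [m for ms, _ in toy_mode_genes.values() for m in ms]
        events = enumerate_events(models)
        rng = np.random.default_rng(5)
        rows = {}
        for ev in events:
            for j in (ev.inclusion_junctions[0], ev.exclusion_junctions[0]):
                rows[j] = {"c1": int(rng.integers(0, 200)), "k1": int(rng.integers(0, 200))}
        res = psi_test(events, pd.DataFrame(rows).T, self.DESIGN)
        psi = res.table[["psi_control", "psi_knockdown"]].to_numpy()
        ok = np.isnan(psi) | ((psi >= 0) & (psi <= 1))
        assert ok.all()
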