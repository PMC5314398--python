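import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicesig.annotation import ExonRecord
from splicesig.metaprofile import (
    MetaProfile,
    build_profiles,
    compare_classes,
    pool_bins,
    profile_exon,
    smooth,
)
from splicesig.tracks import PeakSet, SignalTrack

from _oracles import moving_average


def _exon(start, end, strand="+", eid="g:E001", cls="untested"):
    return ExonRecord(eid, "g", "chr1", strand, start, end, usage_class=cls)


class TestSmooth:
    def test_constant_fixed_point(self):
        v = np.full(200, 3.7)
        assert np.allclose(smooth(v, 10), 3.7)

    def test_impulse_becomes_plateau(self):
        v = np.zeros(51)
        v[25] = 1.0
        s = smooth(v, 10)  # even window -> 11
        assert np.allclose(s[20:31], 1 / 11)
        assert s.sum() == pytest.approx(1.0)

    def test_linear_ramp_interior_unchanged(self):
        v = np.arange(100, dtype=float)
        s = smooth(v, 11)
        assert np.allclose(s[5:-5], v[5:-5])
        assert np.allclose(s, moving_average(list(v), 11))

    def test_empty_vector(self):
        assert smooth(np.array([]), 5).size == 0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=80),
        st.integers(1, 15),
    )
    def test_matches_direct_convolution_oracle(self, values, window):
        assert np.allclose(smooth(np.array(values), window), moving_average(values, window))


class TestPooling:
    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(3, 997))
    def test_mean_conserved_exactly(self, n):
        rng = np.random.default_rng(n)
        v = rng.random(n)
        pooled = pool_bins(v, 100)
        assert pooled.mean() == pytest.approx(v.mean(), abs=1e-10)
        assert pooled.min() >= v.min() - 1e-12 and pooled.max() <= v.max() + 1e-12


class TestProfileExon:
    def test_peak_over_body_only(self):
        ps = PeakSet([("chr1", 1000, 1157, 1.0)])
        p = profile_exon(_exon(1000, 1157), ps, window=1)
        assert np.allclose(p[100:200], 1.0)
        assert np.allclose(p[:100], 0.0) and np.allclose(p[200:], 0.0)

    def test_no_peaks_all_zero(self):
        p = profile_exon(_exon(1000, 1200), PeakSet([]), window=1)
        assert np.allclose(p, 0.0)

    def test_half_peak_raster(self):
        # exon (1000,1200) +, peak (900,1100): second half of upstream flank
        # and first half of body covered
        ps = PeakSet([("chr1", 900, 1100, 1.0)])
        p = profile_exon(_exon(1000, 1200), ps, window=1)
        assert np.allclose(p[:50], 0.0) and np.allclose(p[50:100], 1.0)
        assert np.allclose(p[100:150], 1.0) and np.allclose(p[150:], 0.0)

    def test_minus_strand_reverses_axis(self):
        ps = PeakSet([("chr1", 900, 1000, 1.0)])  # upstream of a + exon
        plus = profile_exon(_exon(1000, 1100), ps, window=1)
        # same geometry is downstream for a - exon
        minus = profile_exon(_exon(1000, 1100, strand="-"), ps, window=1)
        assert np.allclose(plus, minus[::-1])

    def test_short_exon_rejected(self):
        with pytest.raises(ValueError, match="shorter than 3"):
            profile_exon(_exon(10, 12), PeakSet([]))

    def test_constant_track_flat_profile(self):
        t = SignalTrack({"chr1": [(0, 100000, 2.5)]})
        p = profile_exon(_exon(5000, 5157), t, window=10, mode="signal")
        assert np.allclose(p, 2.5)

    def test_occupancy_bounded(self):
        rng = np.random.default_rng(3)
        peaks = PeakSet(
            [("chr1", int(s), int(s) + int(w), 1.0)
             for s, w in zip(rng.integers(0, 5000, 30), rng.integers(50, 400, 30))]
        )
        p = profile_exon(_exon(2000, 2333), peaks, window=10)
        assert p.min() >= 0.0 and p.max() <= 1.0


class TestBuildAndCompare:
    def _classified(self, n_per_class, length=200, gap=1000):
        exons, pos = [], 10000
        for i in range(3 * n_per_class):
            cls = ("up", "down", "unchanged")[i % 3]
            exons.append(_exon(pos, pos + length, eid=f"g:E{i:03d}", cls=cls))
            pos += length + gap
        return exons

    def test_identical_classes_identical_means(self):
        exons = self._classified(4)
        ps = PeakSet([("chr1", e.start, e.end, 1.0) for e in exons[::2]])
        profiles = build_profiles(exons, {"m": ps})
        same = build_profiles(
            [ex for ex in exons], {"m": ps}
        )
        assert np.allclose(
            profiles[("m", "up")].column_mean, same[("m", "up")].column_mean
        )

    def test_single_exon_class(self):
        exons = [_exon(10000, 10200, eid="g:E001", cls="up")]
        with pytest.warns(UserWarning):  # down/unchanged classes empty
            profiles = build_profiles(exons, {"m": PeakSet([])})
        prof = profiles[("m", "up")]
        assert prof.n_exons == 1
        assert np.allclose(prof.column_mean, prof.matrix[0])

    def test_planted_enrichment_separates_classes(self):
        from splicesig.simulate import SimulationConfig, simulate_tracks

        exons = self._classified(60)
        cfg = SimulationConfig(seed=9)
        _, peaks, _ = simulate_tracks(
            cfg, exons, markers={"m": {"down": 0.8, "up": 0.1, "unchanged": 0.1}},
            with_signal=False,
        )
        profiles = build_profiles(exons, {"m": peaks["m"]})
        down = profiles[("m", "down")].per_exon_summary().mean()
        unch = profiles[("m", "unchanged")].per_exon_summary().mean()
        assert down - unch >= 0.5
        comps = {
            (c.class_a, c.class_b): c for c in compare_classes(profiles, region="body")
        }
        assert comps[("down", "unchanged")].ks_p < 1e-6

    def test_identical_vectors_zero_statistics(self):
        mat = np.tile(np.linspace(0, 1, 300), (5, 1))
        profiles = {
            ("m", "up"): MetaProfile("up", "m", "occupancy", mat, [f"e{i}" for i in range(5)]),
            ("m", "unchanged"): MetaProfile(
                "unchanged", "m", "occupancy", mat.copy(), [f"f{i}" for i in range(5)]
            ),
        }
        (comp,) = compare_classes(profiles, region="body", pairs=[("up", "unchanged")])
        assert comp.ks_stat == 0.0 and comp.t_stat == 0.0

    def test_small_class_skipped(self):
        mat = np.zeros((1, 300))
        profiles = {
            ("m", "up"): MetaProfile("up", "m", "occupancy", mat, ["e"]),
            ("m", "unchanged"): MetaProfile("unchanged", "m", "occupancy", np.zeros((3, 300)), list("abc")),
        }
        with pytest.warns(UserWarning, match="< 2 exons"):
            comps = compare_classes(profiles, pairs=[("up", "unchanged")])
        assert comps == []


def test_strand_reversal_invariance():
    """Mirroring the genome (coordinates and strands flipped) leaves profiles identical."""
    rng = np.random.default_rng(0)
    G = 50000
    vals = rng.random(G // 50)
    fwd = SignalTrack({"chr1": [(s, s + 50, float(v)) for s, v in zip(range(0, G, 50), vals)]})
    starts, ends, v = fwd.intervals("chr1")
    rev = SignalTrack(
        {"chr1": [(G - int(e), G - int(s), float(x)) for s, e, x in zip(starts, ends, v)]}
    )
    for s0, e0, strand in [(20000, 20157, "+"), (31000, 31400, "-")]:
        p_f = profile_exon(_exon(s0, e0, strand=strand), fwd, window=10, mode="signal")
        flipped = "-" if strand == "+" else "+"
        p_r = profile_exon(
            _exon(G - e0, G - s0, strand=flipped), rev, window=10, mode="signal"
        )
        assert np.allclose(p_f, p_r)
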