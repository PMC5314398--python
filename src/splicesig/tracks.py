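"""Genomic signal (bedGraph) and peak (BED) containers, per-base coverage,
and a minimal Poisson sliding-window peak caller.

The peak caller is a convenience stand-in for a full peak-calling tool: it
estimates a single genome-wide background rate from the covered bases of the
track, scores tiling windows with a Poisson upper tail, merges adjacent
significant windows and drops short regions. The pipeline's canonical path
accepts externally generated peak BEDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
from scipy import stats

from .annotation import GtfParseError

__all__ = ["SignalTrack", "PeakSet", "read_bedgraph", "read_bed_peaks", "call_peaks"]


class SignalTrack:
    """Sorted, non-overlapping (start, end, value) intervals per chromosome."""

    def __init__(self, intervals: dict[str, Sequence[tuple[int, int, float]]]):
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            vals = np.array([v for _, _, v in ivs], dtype=float)
            if len(starts):
                if (starts < 0).any() or (ends <= starts).any():
                    raise ValueError(f"{chrom}: invalid interval coordinates")
                if (starts[1:] < ends[:-1]).any():
                    raise ValueError(f"{chrom}: overlapping bedGraph intervals")
                if not np.isfinite(vals).all():
                    raise ValueError(f"{chrom}: non-finite signal values")
            self._chrom[chrom] = (starts, ends, vals)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chrom)

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._chrom[chrom]

    def coverage(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); uncovered bases are 0.

        Bases before position 0 are invalid and must be clipped by the
        caller; an unknown chromosome yields all zeros with a warning.
        """
        if end <= start:
            raise ValueError("coverage requires start < end")
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._chrom:
            warnings.warn(f"chromosome {chrom!r} not in track; returning zeros")
            return out
        starts, ends, vals = self._chrom[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            if b > a:
                out[a:b] = vals[i]
        return out

    def total_mass(self) -> float:
        return float(
            sum(((e - s) * v).sum() for s, e, v in self._chrom.values())
        )

    def covered_bases(self) -> int:
        return int(sum((e - s).sum() for s, e, _ in self._chrom.values()))

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                starts, ends, vals = self._chrom[chrom]
                for s, e, v in zip(starts, ends, vals):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph; ``track``/comment lines are skipped.

    Overlapping intervals, negative coordinates and non-numeric values raise
    a parse error naming the line number.
    """
    ivs: dict[str, list[tuple[int, int, float]]] = {}
    lines: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise GtfParseError(f"line {lineno}: bedGraph needs 4 columns")
            chrom, s, e, v = fields
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-numeric field") from exc
            if start < 0 or end <= start:
                raise GtfParseError(f"line {lineno}: invalid interval {start}-{end}")
            ivs.setdefault(chrom, []).append((start, end, value))
            lines.setdefault(chrom, []).append(lineno)
    # report the first overlapping line rather than a bare container error
    for chrom, chunk in ivs.items():
        order = sorted(range(len(chunk)), key=lambda i: chunk[i][:2])
        for i, j in zip(order, order[1:]):
            if chunk[j][0] < chunk[i][1]:
                raise GtfParseError(
                    f"line {lines[chrom][j]}: interval overlaps a previous one"
                )
    return SignalTrack(ivs)


@dataclass
class PeakSet:
    """Peak intervals (chrom, start, end, score) with a source label."""

    peaks: list[tuple[str, int, int, float]]
    source_label: str = ""
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for chrom, s, e, score in self.peaks:
            if s < 0 or e <= s:
                raise ValueError(f"invalid peak {chrom}:{s}-{e}")
            if not np.isfinite(score):
                raise ValueError("peak scores must be finite")
        self.peaks = sorted(self.peaks)
        idx: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e, _ in self.peaks:
            idx.setdefault(chrom, []).append((s, e))
        merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in idx.items():
            out: list[tuple[int, int]] = []
            for s, e in ivs:
                if out and s <= out[-1][1]:
                    out[-1] = (out[-1][0], max(out[-1][1], e))
                else:
                    out.append((s, e))
            merged[chrom] = (
                np.array([s for s, _ in out], dtype=np.int64),
                np.array([e for _, e in out], dtype=np.int64),
            )
        self._index = merged

    def __len__(self) -> int:
        return len(self.peaks)

    def occupancy(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Binary per-base vector over [start, end): 1 inside any peak."""
        out = np.zeros(end - start, dtype=float)
        if self._index is None or chrom not in self._index:
            return out
        starts, ends = self._index[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(int(starts[i]), start) - start
            b = min(int(ends[i]), end) - start
            if b > a:
                out[a:b] = 1.0
        return out

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, (chrom, s, e, score) in enumerate(self.peaks, start=1):
                name = f"{self.source_label or 'peak'}_{i}"
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score:g}\n")


def read_bed_peaks(path: str | Path, source_label: str = "") -> PeakSet:
    """Read BED3+ peaks; column 5 is the score when present, extra columns ignored."""
    peaks: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GtfParseError(f"line {lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[4]) if len(fields) >= 5 else 0.0
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-numeric field") from exc
            if start < 0 or end <= start:
                raise GtfParseError(f"line {lineno}: invalid interval")
            peaks.append((fields[0], start, end, score))
    return PeakSet(peaks, source_label=source_label)


def _window_sums(track: SignalTrack, chrom: str, window: int) -> tuple[np.ndarray, int]:
    """Integral of the track over tiling windows starting at the first covered base."""
    starts, ends, vals = track.intervals(chrom)
    origin = int(starts[0])
    span = int(ends[-1]) - origin
    n_win = (span + window - 1) // window
    # piecewise-linear cumulative mass F at arbitrary positions
    bp = np.empty(2 * len(starts), dtype=np.int64)
    bp[0::2], bp[1::2] = starts, ends
    mass = np.zeros(2 * len(starts))
    mass[1::2] = (ends - starts) * vals
    cum = np.concatenate([[0.0], np.cumsum(mass)])  # F at each breakpoint

    def F(pos: np.ndarray) -> np.ndarray:
        i = np.searchsorted(bp, pos, side="right")
        base = cum[i]
        # inside an interval (odd index) add the partial mass
        inside = (i % 2) == 1
        res = base.astype(float)
        ii = i[inside] // 2
        res[inside] = cum[i[inside] - 1] + (pos[inside] - starts[ii]) * vals[ii]
        return res

    edges = origin + window * np.arange(n_win + 1, dtype=np.int64)
    edges = np.minimum(edges, int(ends[-1]))
    Fe = F(edges)
    return Fe[1:] - Fe[:-1], origin


def call_peaks(
    track: SignalTrack,
    window: int = 100,
    p_threshold: float = 1e-5,
    min_length: int = 100,
) -> PeakSet:
    """Poisson sliding-window peak calling against a global background rate.

    The background rate lambda is the track's total mass divided by its
    covered bases. Each tiling window's (rounded) signal sum is scored with
    the Poisson upper tail P(X >= k | lambda * window); windows below
    ``p_threshold`` are merged when adjacent, merged regions shorter than
    ``min_length`` are dropped, and the peak score is -log10 of the best
    window p-value. Fractional signal is rounded to integer window counts
    for the Poisson model.
    """
    if window < 10:
        raise ValueError("window must be >= 10 bp")
    covered = track.covered_bases()
    if covered == 0 or track.total_mass() <= 0:
        raise ValueError("empty track")
    lam = track.total_mass() / covered

    peaks: list[tuple[str, int, int, float]] = []
    for chrom in track.chroms:
        sums, origin = _window_sums(track, chrom, window)
        counts = np.rint(sums).astype(np.int64)
        pvals = stats.poisson.sf(counts - 1, lam * window)
        sig = np.flatnonzero(pvals < p_threshold)
        if not len(sig):
            continue
        run_start = sig[0]
        prev = sig[0]
        best = pvals[sig[0]]
        for w in sig[1:]:
            if w == prev + 1:
                best = min(best, pvals[w])
                prev = w
                continue
            _emit(peaks, chrom, origin, window, run_start, prev, best, min_length)
            run_start, prev, best = w, w, pvals[w]
        _emit(peaks, chrom, origin, window, run_start, prev, best, min_length)
    return PeakSet(peaks, source_label="called")


def _emit(peaks, chrom, origin, window, w0, w1, best_p, min_length) -> None:
    start = origin + w0 * window
    end = origin + (w1 + 1) * window
    if end - start >= min_length:
        score = float(-np.log10(max(best_p, 1e-300)))
        peaks.append((chrom, start, end, score))
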