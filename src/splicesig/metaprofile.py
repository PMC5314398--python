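"""Scaled meta-exon profiles of genomic signal around exon classes.

Each exon contributes one 300-bin row: its body rescaled to 100 bins plus an
upstream and a downstream flank, each one exon-length wide and also rescaled
to 100 bins, so the x-axis runs in exon-length units from -1.0 to 2.0 with
0.0 at the exon start and 1.0 at the exon end. Per-base values come either
from binary peak occupancy (1 inside any peak) or from a continuous signal
track; a 10-bp centred sliding-window mean is applied in base space before
rescaling, and minus-strand exons are reversed so bin 0 is always
transcriptionally upstream.

Rescaling uses fractional-base mean pooling: bin *i* of a third of length
*n* averages the bases overlapping [i*n/100, (i+1)*n/100) weighted by
fractional overlap, which conserves the per-base mean of each third exactly.

Class comparisons (up vs unchanged, down vs unchanged, up vs down) apply a
two-sample Kolmogorov-Smirnov test and a Welch t test to per-exon summary
values (mean over a selectable bin region, body by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import ExonRecord
from .tracks import PeakSet, SignalTrack

__all__ = [
    "N_BINS",
    "MetaProfile",
    "ClassComparison",
    "smooth",
    "pool_bins",
    "profile_exon",
    "build_profiles",
    "compare_classes",
    "plot_profiles",
]

logger = logging.getLogger(__name__)

N_BINS = 300
BODY = slice(100, 200)
FLANK_UP = slice(0, 100)
FLANK_DOWN = slice(200, 300)
REGIONS = {"body": BODY, "flank_up": FLANK_UP, "flank_down": FLANK_DOWN, "full": slice(0, 300)}

Source = Union[SignalTrack, PeakSet]


def smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge truncation; output length = input length.

    An even window is incremented to the next odd value (logged) so the
    kernel stays centred. A window of 1 is the identity.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        logger.info("smoothing window %d is even; using %d", window, window + 1)
        window += 1
    if window == 1:
        return values.copy()
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n = len(values)
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def pool_bins(values: np.ndarray, n_bins: int = 100) -> np.ndarray:
    """Mean-pool a per-base vector into ``n_bins`` fractional-overlap bins.

    The mean of the pooled bins equals the per-base mean of the input
    exactly (each base's total weight is 1).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("cannot pool an empty vector")
    csum = np.concatenate([[0.0], np.cumsum(values)])

    def integral(pos: np.ndarray) -> np.ndarray:
        i = np.floor(pos).astype(int)
        i = np.clip(i, 0, n - 1)
        frac = pos - i
        return csum[i] + frac * values[i]

    edges = np.linspace(0.0, float(n), n_bins + 1)
    edges[-1] = float(n)
    ints = np.empty(n_bins + 1)
    ints[:-1] = integral(edges[:-1])
    ints[-1] = csum[-1]
    width = n / n_bins
    return (ints[1:] - ints[:-1]) / width


def _per_base(
    exon: ExonRecord, source: Source, mode: str
) -> tuple[np.ndarray, float]:
    """Raw per-base vector over [start-L, end+L) with chromosome-start clipping."""
    L = exon.length
    lo = exon.start - L
    hi = exon.end + L
    clip = max(0, -lo)
    vec = np.zeros(hi - lo, dtype=float)
    if mode == "occupancy":
        vec[clip:] = source.occupancy(exon.chrom, lo + clip, hi)
    else:
        vec[clip:] = source.coverage(exon.chrom, lo + clip, hi)
    return vec, clip / (hi - lo)


def profile_exon(
    exon: ExonRecord,
    source: Source,
    window: int = 10,
    mode: str | None = None,
) -> np.ndarray:
    """Scaled 300-bin profile (flank, body, flank) of one exon.

    ``mode`` defaults to ``occupancy`` for a :class:`PeakSet` and ``signal``
    for a :class:`SignalTrack`. Exons shorter than 3 bases are untestable
    and raise ValueError (``build_profiles`` excludes them with a warning).
    """
    if exon.length < 3:
        raise ValueError(f"exon {exon.exon_id} shorter than 3 bases")
    if mode is None:
        mode = "occupancy" if isinstance(source, PeakSet) else "signal"
    vec, _clip = _per_base(exon, source, mode)
    vec = smooth(vec, window)
    if exon.strand == "-":
        vec = vec[::-1]
    L = exon.length
    out = np.concatenate(
        [pool_bins(vec[:L]), pool_bins(vec[L : 2 * L]), pool_bins(vec[2 * L :])]
    )
    if mode == "occupancy":
        np.clip(out, 0.0, 1.0, out=out)  # guard cumsum round-off
    return out


@dataclass
class MetaProfile:
    """Profile matrix for one (marker, exon-class) combination."""

    class_label: str
    marker_label: str
    mode: str
    matrix: np.ndarray  # rows = exons, 300 columns
    exon_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != N_BINS:
            raise ValueError(f"profile matrix must have {N_BINS} columns")

    @property
    def n_exons(self) -> int:
        return self.matrix.shape[0]

    @property
    def bin_axis(self) -> np.ndarray:
        """Bin centres in exon-length units: -1.0 at flank start, 1.0 exon end."""
        return -1.0 + (np.arange(N_BINS) + 0.5) * (3.0 / N_BINS)

    @property
    def column_mean(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    @property
    def column_sem(self) -> np.ndarray:
        if self.n_exons < 2:
            return np.zeros(N_BINS)
        return self.matrix.std(axis=0, ddof=1) / np.sqrt(self.n_exons)

    def per_exon_summary(self, region: str = "body") -> np.ndarray:
        return self.matrix[:, REGIONS[region]].mean(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "bin_axis": self.bin_axis,
                "mean": self.column_mean,
                "sem": self.column_sem,
                "n": self.n_exons,
            }
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass
class ClassComparison:
    marker_label: str
    class_a: str
    class_b: str
    region: str
    ks_stat: float
    ks_p: float
    t_stat: float
    t_p: float
    n_a: int
    n_b: int


def build_profiles(
    exons: Sequence[ExonRecord],
    sources: Mapping[str, Source],
    window: int = 10,
    mode: str | None = None,
    classes: Sequence[str] = ("up", "down", "unchanged"),
) -> dict[tuple[str, str], MetaProfile]:
    """Meta-exon profiles per (marker, usage-class); empty classes are omitted.

    ``exons`` must carry ``usage_class`` (from the exon-usage stage or
    simulation ground truth). The ``unchanged`` class is the default
    background for comparisons.
    """
    profiles: dict[tuple[str, str], MetaProfile] = {}
    usable = [ex for ex in exons if ex.length >= 3]
    if len(usable) < len(exons):
        warnings.warn(f"excluded {len(exons) - len(usable)} exons shorter than 3 bp")
    for marker, source in sources.items():
        m = mode or ("occupancy" if isinstance(source, PeakSet) else "signal")
        for cls in classes:
            members = [ex for ex in usable if ex.usage_class == cls]
            if not members:
                warnings.warn(f"class {cls!r} empty for marker {marker!r}; omitted")
                continue
            mat = np.vstack(
                [profile_exon(ex, source, window=window, mode=m) for ex in members]
            )
            profiles[(marker, cls)] = MetaProfile(
                class_label=cls,
                marker_label=marker,
                mode=m,
                matrix=mat,
                exon_ids=[ex.exon_id for ex in members],
            )
    return profiles


DEFAULT_PAIRS = (("up", "unchanged"), ("down", "unchanged"), ("up", "down"))


def compare_classes(
    profiles: Mapping[tuple[str, str], MetaProfile],
    region: str = "body",
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
) -> list[ClassComparison]:
    """KS and Welch t tests on per-exon region means for each class pair."""
    if region not in REGIONS:
        raise ValueError(f"region must be one of {sorted(REGIONS)}")
    out: list[ClassComparison] = []
    markers = sorted({m for m, _ in profiles})
    for marker in markers:
        for a, b in pairs:
            pa, pb = profiles.get((marker, a)), profiles.get((marker, b))
            if pa is None or pb is None:
                continue
            if pa.n_exons < 2 or pb.n_exons < 2:
                warnings.warn(
                    f"skipping {marker} {a} vs {b}: a class has < 2 exons"
                )
                continue
            xa = pa.per_exon_summary(region)
            xb = pb.per_exon_summary(region)
            if np.array_equal(xa, xb):
                ks_stat, ks_p = 0.0, 1.0
                t_stat, t_p = 0.0, 1.0
            else:
                ks_stat, ks_p = stats.ks_2samp(xa, xb)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # zero-variance degenerate pairs
                    t_stat, t_p = stats.ttest_ind(xa, xb, equal_var=False)
                if not np.isfinite(t_stat):
                    t_stat, t_p = 0.0, 1.0
            out.append(
                ClassComparison(
                    marker_label=marker,
                    class_a=a,
                    class_b=b,
                    region=region,
                    ks_stat=float(ks_stat),
                    ks_p=float(ks_p),
                    t_stat=float(t_stat),
                    t_p=float(t_p),
                    n_a=pa.n_exons,
                    n_b=pb.n_exons,
                )
            )
    return out


def comparisons_to_frame(comparisons: Sequence[ClassComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])


def plot_profiles(
    profiles: Mapping[tuple[str, str], MetaProfile],
    path: str | Path,
) -> None:
    """One panel per marker: class mean +/- sem over the 300-bin axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    markers = sorted({m for m, _ in profiles})
    fig, axes = plt.subplots(
        1, max(len(markers), 1), figsize=(4 * max(len(markers), 1), 3), squeeze=False
    )
    colors = {"up": "tab:red", "down": "tab:blue", "unchanged": "0.4", "all": "0.7"}
    for ax, marker in zip(axes[0], markers):
        for (m, cls), prof in profiles.items():
            if m != marker:
                continue
            mu, sem = prof.column_mean, prof.column_sem
            ax.plot(prof.bin_axis, mu, label=cls, color=colors.get(cls))
            ax.fill_between(
                prof.bin_axis, mu - sem, mu + sem, alpha=0.2, color=colors.get(cls)
            )
        for x in (0.0, 1.0):
            ax.axvline(x, color="k", lw=0.5, ls=":")
        ax.set_title(marker)
        ax.set_xlabel("relative position (exon lengths)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
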