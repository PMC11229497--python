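"""Windowed depth-of-coverage karyotyping.

Partial monosomy (heterozygous Mb-scale deletion) shows up as a run of
windows near ratio 0.5; whole-chromosome trisomy as a chromosome-wide shift
to ~1.5.  Segments are called on coarse (200 kb) windows and their
breakpoints refined on fine (10 kb) windows with a two-mean least-squares
step fit, replacing the visual inspection step of a manual read-alignment
review.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

DEFAULT_LOSS_MAX = 0.7
DEFAULT_GAIN_MIN = 1.3
DEFAULT_MIN_WINDOWS = 3
# chromosome-median escalation bands for whole-chromosome calls
TRISOMY_MEDIAN_MIN = 1.35
MONOSOMY_MEDIAN_MAX = 0.65


@dataclass
class DepthProfile:
    """Per-window read counts for one sample at one window size.

    ``windows`` has columns chrom, start, end (1-based inclusive), count and,
    after :func:`normalize_depth`, ratio.  ``reference_level`` is the
    genome-wide median window count over autosome windows (robust against the
    sample's own CNVs on small genomes); it is filled in by normalization.
    """

    sample: str
    window_size: int
    windows: pd.DataFrame
    reference_level: float | None = None

    def chrom_windows(self, chrom: str) -> pd.DataFrame:
        return self.windows[self.windows["chrom"] == chrom]


@dataclass(frozen=True)
class SegmentCall:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    state: str  # "loss" | "gain"
    mean_ratio: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment end before start")
        if self.state not in ("loss", "gain"):
            raise ValueError(f"bad state {self.state!r}")

    @property
    def size_mb(self) -> float:
        return interval_size_mb(self.start, self.end)


@dataclass(frozen=True)
class AneuploidyCall:
    chrom: str
    type: str  # "trisomy" | "monosomy"
    median_ratio: float


def interval_size_mb(start: int, end: int) -> float:
    """Span of an interval in Mb, 2 decimals, rounded half-up.

    Uses the end - start convention of breakpoint coordinates (the two
    breakpoints bracket the event), so e.g. (106843549, 121215358) -> 14.37.
    """
    if end <= start:
        raise ValueError("end must be > start")
    mb = Decimal(end - start) / Decimal(1_000_000)
    return float(mb.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int] | None:
    """Intersection of two same-chromosome intervals, or None when disjoint."""
    start = max(a[0], b[0])
    end = min(a[1], b[1])
    return (start, end) if start < end else None


def normalize_depth(profile: DepthProfile, sex_chroms: tuple[str, ...] = ()) -> DepthProfile:
    """Add a per-window ``ratio`` column: count / genome-wide reference count.

    The reference level is the median of the per-chromosome median counts
    over autosomal windows of full width, which keeps the reference anchored
    at the diploid level even when one chromosome of a small genome is
    entirely trisomic (short terminal windows are excluded from the
    reference but still receive a ratio scaled by their width).  Requires
    >= 10 windows.
    """
    df = profile.windows
    if len(df) < 10:
        raise ValueError("need at least 10 windows to normalize")
    widths = (df["end"] - df["start"] + 1).to_numpy(dtype=float)
    full = widths == widths.max()
    auto = ~df["chrom"].isin(sex_chroms).to_numpy()
    eligible = df.loc[full & auto]
    per_chrom = eligible.groupby("chrom", sort=False)["count"].median()
    ref = float(np.median(per_chrom))
    if ref <= 0:
        raise ValueError("genome-wide reference window count is zero")
    # scale short windows up to full width before dividing
    scaled = df["count"].to_numpy(dtype=float) * (widths.max() / widths)
    out = df.copy()
    out["ratio"] = scaled / ref
    return replace(profile, windows=out, reference_level=ref)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean vector as (start_idx, end_idx) inclusive."""
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def call_segments(
    profile: DepthProfile,
    loss_max: float = DEFAULT_LOSS_MAX,
    gain_min: float = DEFAULT_GAIN_MIN,
    min_windows: int = DEFAULT_MIN_WINDOWS,
) -> tuple[list[SegmentCall], list[AneuploidyCall]]:
    """Call loss/gain segments and whole-chromosome aneuploidies.

    A chromosome whose median ratio sits in the trisomy (>= 1.35) or
    monosomy (<= 0.65) band is escalated to an AneuploidyCall and excluded
    from segment scanning.  On the remaining chromosomes, runs of at least
    ``min_windows`` consecutive windows all below ``loss_max`` (or all above
    ``gain_min``) are merged into segments.
    """
    if "ratio" not in profile.windows.columns:
        raise ValueError("profile must be normalized first (no ratio column)")
    segments: list[SegmentCall] = []
    aneuploidies: list[AneuploidyCall] = []
    for chrom, sub in profile.windows.groupby("chrom", sort=False):
        ratio = sub["ratio"].to_numpy()
        med = float(np.median(ratio))
        if med >= TRISOMY_MEDIAN_MIN:
            aneuploidies.append(AneuploidyCall(chrom, "trisomy", med))
            continue
        if med <= MONOSOMY_MEDIAN_MAX:
            aneuploidies.append(AneuploidyCall(chrom, "monosomy", med))
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for state, mask in (("loss", ratio < loss_max), ("gain", ratio > gain_min)):
            for i0, i1 in _runs(mask):
                if i1 - i0 + 1 < min_windows:
                    continue
                segments.append(
                    SegmentCall(
                        chrom=chrom,
                        start=int(starts[i0]),
                        end=int(ends[i1]),
                        state=state,
                        mean_ratio=float(ratio[i0 : i1 + 1].mean()),
                        n_windows=int(i1 - i0 + 1),
                    )
                )
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments, aneuploidies


def _best_step(values: np.ndarray) -> tuple[int, float]:
    """Least-squares two-mean step fit.

    Returns (split index k, sse) where the step sits between values[k-1] and
    values[k]; k in 1..len-1.  The no-step fit corresponds to k=0 with the
    overall mean.
    """
    n = len(values)
    csum = np.cumsum(values)
    csq = np.cumsum(values**2)
    best_k, best_sse = 0, float(csq[-1] - csum[-1] ** 2 / n)
    for k in range(1, n):
        left = csq[k - 1] - csum[k - 1] ** 2 / k
        right = (csq[-1] - csq[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / (n - k)
        sse = float(left + right)
        if sse < best_sse - 1e-12:
            best_k, best_sse = k, sse
    return best_k, best_sse


def refine_breakpoints(
    segment: SegmentCall,
    fine: DepthProfile,
    flank_windows: int = 40,
    min_flank: int = 5,
) -> SegmentCall:
    """Refine segment boundaries on the fine (10 kb) window profile.

    Each boundary is moved to the maximum-likelihood changepoint of a
    two-mean step fit over fine-window ratios in a window of
    ``flank_windows`` windows either side of the coarse boundary.  If fewer
    than ``min_flank`` fine windows are available on either side, or the
    step fit finds no improvement, the original boundary is kept.
    """
    if "ratio" not in fine.windows.columns:
        raise ValueError("fine profile must be normalized first")
    sub = fine.chrom_windows(segment.chrom)
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    ratio = sub["ratio"].to_numpy()

    def refine_edge(boundary: int, leading: bool) -> int:
        # index of the fine window containing the boundary position
        idx = int(np.searchsorted(ends, boundary))
        lo = max(0, idx - flank_windows)
        hi = min(len(ratio), idx + flank_windows + 1)
        if idx - lo < min_flank or hi - idx < min_flank:
            return boundary  # flank too short; refinement skipped
        k, _ = _best_step(ratio[lo:hi])
        if k == 0:
            return boundary  # constant ratio, keep original
        edge = lo + k  # step between fine windows edge-1 and edge
        return int(starts[edge]) if leading else int(ends[edge - 1])

    return replace(
        segment,
        start=refine_edge(segment.start, leading=True),
        end=refine_edge(segment.end, leading=False),
    )
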