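"""Variable-size sliding-window mapping of locally periodic regions.

A genome-wide scan can miss a periodic arrangement confined to one part of
the chromosome.  This module slides windows of growing size (starting at
10 kbp, multiplied by a growth factor until 95 % of the genome is covered)
along the chromosome and runs a restricted DOM period scan inside every
window holding enough features, testing only periods that fit in the
window.  Windows whose best corrected p-value beats the cutoff become
candidate regions, trimmed to the span of the features that produced the
signal; overlapping candidates whose periods agree within 5 % (the same
tolerance used for "common" periods across regulons) are merged into one
maximal region that keeps the best p-value.

On circular chromosomes windows wrap across the origin; a wrapping region
is split at the origin for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .features import FeatureSet
from .periodicity import (
    batch_periodicity_scores,
    correct_pvalue,
    rayleigh_pvalue,
    scan_multiplicity_factor,
)

__all__ = ["PeriodicRegion", "map_periodic_regions", "merge_regions", "chromogram_table"]

MERGE_REL_TOL = 0.05  # "common period" criterion reused for region merging


@dataclass(frozen=True)
class PeriodicRegion:
    """A genomic interval carrying a locally significant period."""

    start: int  # 1-based, closed
    end: int
    period: float
    p_corrected: float
    n_features: int
    window_size: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region start {self.start} >= end {self.end}")
        if self.period > self.window_size:
            raise ValueError("period exceeds the detecting window size")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _window_sizes(w0: int, growth: float, g: int) -> list[int]:
    cap = int(0.95 * g)
    sizes = []
    w = float(w0)
    while w < cap:
        sizes.append(int(round(w)))
        w *= growth
    sizes.append(cap)
    return sizes


def _frequency_grid(p_min: float, p_max: float, span: float, oversample: float) -> np.ndarray:
    """Periods spaced uniformly in frequency at ``oversample`` times the
    intrinsic resolution 1/span of a window of that size.

    The periodicity score decorrelates over a frequency shift of about
    1/span, so a grid step of 1/(oversample*span) loses essentially no
    power while testing orders of magnitude fewer periods than a fixed-bp
    comb would at large periods.
    """
    df = 1.0 / (oversample * span)
    freqs = np.arange(1.0 / p_max, 1.0 / p_min + df, df)
    return np.clip((1.0 / freqs)[::-1], p_min, p_max)


def _scan_window(
    local_pos: np.ndarray, w: int, p_min: float, oversample: float
) -> tuple[float, float, np.ndarray] | None:
    """Best (period, corrected p, contributor mask) of a window-limited scan.

    The mask marks the features with a positive leave-one-out contribution
    to the periodicity score at the best period — the features actually
    carrying the local pattern; the candidate region is trimmed to their
    span so that a window larger than the periodic segment does not inflate
    the reported interval with unrelated features.
    """
    p_max = float(w)
    if p_min >= p_max:
        return None
    periods = _frequency_grid(p_min, p_max, float(w), oversample)
    n = local_pos.size
    scores = batch_periodicity_scores(local_pos, periods)
    p_raw = rayleigh_pvalue(scores, n, periods, w)
    p_corr = correct_pvalue(p_raw, periods, w, scan_multiplicity_factor(p_min, p_max))
    i = int(np.lexsort((periods, p_corr))[0])  # best p, ties to smaller period
    i = _promote_to_fundamental(periods, p_corr, i)
    z = np.exp(2j * np.pi * local_pos / periods[i])
    total = z.sum()
    contrib = abs(total) ** 2 / n - np.abs(total - z) ** 2 / (n - 1)
    return float(periods[i]), float(p_corr[i]), contrib > 0


MIN_REPETITIONS = 4  # a credible local period must recur at least this often


def _promote_to_fundamental(
    periods: np.ndarray, p_corr: np.ndarray, i: int, decades: float = 2.0
) -> int:
    """Climb from a divisor period to the fundamental lattice spacing.

    A lattice of spacing T scores perfectly at every divisor T/k, and noise
    from unrelated features can hand the window's minimum p-value to a
    divisor instead of T.  While an integer multiple (2x or 3x, within the
    5 % merge tolerance) of the current best period is itself significant to
    within ``decades`` orders of magnitude of the best p-value, move up to
    it; the largest such multiple wins each round.
    """
    while True:
        promoted = None
        for k in (3, 2):
            target = periods[i] * k
            near = np.abs(periods / target - 1.0) <= MERGE_REL_TOL
            if not near.any():
                continue
            j = int(np.nonzero(near)[0][np.argmin(p_corr[near])])
            if p_corr[j] <= max(p_corr[i] * 10.0**decades, 1e-300):
                promoted = j
                break
        if promoted is None or promoted == i:
            return i
        i = promoted


def _periodic_run(contrib_pos: np.ndarray, period: float) -> np.ndarray | None:
    """Largest contiguous periodic run among contributing features.

    Contributors are chained while consecutive gaps stay within two periods;
    the run with the most members wins (ties: wider span, then leftmost).
    A run must occupy at least :data:`MIN_REPETITIONS` distinct repetitions
    of the period — otherwise the "period" is indistinguishable from a
    single clump of features, and no region is reported.
    """
    pos = np.sort(np.asarray(contrib_pos, dtype=float))
    if pos.size < 2:
        return None
    breaks = np.nonzero(np.diff(pos) > 2.0 * period)[0]
    runs = np.split(pos, breaks + 1)
    best = max(runs, key=lambda r: (r.size, r[-1] - r[0], -r[0]))
    cells = np.unique(np.floor((best - best[0]) / period))
    if best.size < MIN_REPETITIONS or cells.size < MIN_REPETITIONS:
        return None
    return best


def map_periodic_regions(
    fs: FeatureSet,
    p_cutoff: float = 0.0005,
    w0: int = 10_000,
    growth: float = 1.5,
    step_frac: float = 0.5,
    min_features: int = 8,
    p_min: float = 5_000.0,
    oversample: float = 8.0,
) -> list[PeriodicRegion]:
    """Map every sub-region of the genome with a significant local period.

    Parameters
    ----------
    p_cutoff
        Corrected p-value a window must beat to seed a region (the mapping
        cutoff; 0.0005 by default, deliberately strict because many windows
        are tested).
    w0, growth, step_frac
        Initial window size (bp), multiplicative growth per round (until
        95 % of the genome is covered), and slide step as a fraction of the
        current window size.
    min_features
        Minimum features inside a window for its scan to be meaningful.
    p_min, oversample
        Lower period bound of the within-window scan (upper bound is always
        the window size) and the frequency oversampling of its period grid
        (see :func:`_frequency_grid`).
    """
    G = fs.genome_length
    if w0 > G:
        raise ValueError(f"initial window {w0} exceeds genome length {G}")
    if not (0.0 < p_cutoff < 1.0):
        raise ValueError(f"p_cutoff must be in (0, 1), got {p_cutoff}")
    if min_features < 4:
        raise ValueError(f"min_features must be >= 4, got {min_features}")
    positions = fs.positions
    candidates: list[PeriodicRegion] = []
    for w in _window_sizes(w0, growth, G):
        stride = max(1, int(round(step_frac * w)))
        last_start = G if fs.circular else max(1, G - w + 1)
        for start in range(1, last_start + 1, stride):
            end = start + w - 1
            if end <= G:
                mask = (positions >= start) & (positions <= end)
                local = positions[mask].astype(float) - start + 1.0
            else:  # circular wrap across the origin
                end_wrapped = end - G
                mask = (positions >= start) | (positions <= end_wrapped)
                local = positions[mask].astype(float)
                local = np.where(local >= start, local - start + 1.0, local + (G - start + 1.0))
            if mask.sum() < min_features:
                continue
            local_sorted = np.sort(local)
            hit = _scan_window(local_sorted, w, p_min, oversample)
            if hit is None:
                continue
            best_p, best_pc, contributing = hit
            if best_pc >= p_cutoff or contributing.sum() < 2:
                continue
            span_local = _periodic_run(local_sorted[contributing], best_p)
            if span_local is None:
                continue
            lo_unrolled = float(span_local.min()) + start - 1
            hi_unrolled = float(span_local.max()) + start - 1
            lo = int((lo_unrolled - 1) % G + 1)
            hi = int((hi_unrolled - 1) % G + 1)
            if hi < lo:  # wraps the origin: keep unrolled coordinates internally
                hi += G
            if hi - lo < 2:
                continue
            g = int(
                np.count_nonzero((positions >= lo) & (positions <= hi))
                if hi <= G
                else np.count_nonzero((positions >= lo) | (positions <= hi - G))
            )
            if g < min_features:
                continue
            candidates.append(PeriodicRegion(lo, hi, best_p, best_pc, g, int(w)))
    merged = merge_regions(candidates, fs)
    return sorted(merged, key=lambda r: (-(r.length), r.start))


def _overlap(a: PeriodicRegion, b: PeriodicRegion) -> bool:
    return a.start <= b.end and b.start <= a.end


def _periods_close(a: PeriodicRegion, b: PeriodicRegion) -> bool:
    return abs(a.period - b.period) / max(a.period, b.period) <= MERGE_REL_TOL


def merge_regions(candidates: list[PeriodicRegion], fs: FeatureSet) -> list[PeriodicRegion]:
    """Merge overlapping candidates with agreeing (<= 5 %) periods.

    Connected-component merging: order-independent and idempotent.  Each
    merged region keeps the best (smallest) corrected p-value and its
    period, spans the union of its members, and recounts its features.
    """
    n = len(candidates)
    if n == 0:
        return []
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _overlap(candidates[i], candidates[j]) and _periods_close(
                candidates[i], candidates[j]
            ):
                parent[find(i)] = find(j)
    groups: dict[int, list[PeriodicRegion]] = {}
    for i, c in enumerate(candidates):
        groups.setdefault(find(i), []).append(c)
    positions = fs.positions
    G = fs.genome_length
    merged = []
    for members in groups.values():
        best = min(members, key=lambda r: (r.p_corrected, r.period))
        start = min(r.start for r in members)
        end = max(r.end for r in members)
        if end <= G:
            g = int(np.count_nonzero((positions >= start) & (positions <= end)))
        else:  # wraps the origin on a circular chromosome
            g = int(
                np.count_nonzero((positions >= start) | (positions <= end - G))
            )
        merged.append(
            PeriodicRegion(start, end, best.period, best.p_corrected, g, best.window_size)
        )
    return merged


def chromogram_table(
    regions: list[PeriodicRegion],
    macrodomain_boundaries: list[int] | None = None,
    genome_length: int | None = None,
) -> pd.DataFrame:
    """Plot-ready chromogram: one region per row, longest region first.

    ``macrodomain_boundaries`` (bp) are user-supplied overlay positions —
    e.g. the E. coli macrodomain borders — validated against the genome
    length when it is given; they are echoed in the table attrs so a
    renderer can draw them as dashed verticals.
    """
    boundaries = list(macrodomain_boundaries or [])
    if genome_length is not None:
        for b in boundaries:
            if not (1 <= b <= genome_length):
                raise ValueError(f"boundary {b} outside [1, {genome_length}]")
    rows = []
    g_len = genome_length or (max((r.end for r in regions), default=0))
    for r in sorted(regions, key=lambda r: (-(r.length), r.start)):
        if genome_length is not None and r.end > genome_length:
            # circular region wrapping the origin: split for display
            rows.append(
                dict(start=r.start, end=genome_length, period=r.period,
                     n_features=r.n_features, p_corrected=r.p_corrected,
                     window_size=r.window_size)
            )
            rows.append(
                dict(start=1, end=r.end - genome_length, period=r.period,
                     n_features=r.n_features, p_corrected=r.p_corrected,
                     window_size=r.window_size)
            )
        else:
            rows.append(
                dict(start=r.start, end=r.end, period=r.period,
                     n_features=r.n_features, p_corrected=r.p_corrected,
                     window_size=r.window_size)
            )
    df = pd.DataFrame(
        rows, columns=["start", "end", "period", "n_features", "p_corrected", "window_size"]
    )
    df.attrs["macrodomain_boundaries"] = boundaries
    return df
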