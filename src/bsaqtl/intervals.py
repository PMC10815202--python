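"""QTL interval calling, per-method merging and multi-method consensus.

A thresholded track yields intervals: maximal runs of consecutive
above-threshold windows, each spanning from the first window's start to the
last window's end (gap tolerance 0 — a single below-threshold or masked
window breaks a run).  Intervals from the four statistics are then
intersected by a position sweep: consensus regions are maximal stretches
where at least ``min_support`` methods' intervals overlap.  For a
full-support region over single intervals this reduces to
``[max of starts, min of ends]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .windows import StatTrack

__all__ = [
    "QtlInterval",
    "ConsensusRegion",
    "call_intervals",
    "intersect_methods",
    "name_regions",
    "evaluate_recovery",
    "RecoveryReport",
]


@dataclass
class QtlInterval:
    """A genomic interval linked to the trait by one statistic (1-based
    inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    peak_value: float
    peak_pos: int
    method: str
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("interval start > end")
        if not self.start <= self.peak_pos <= self.end:
            raise ValueError("peak_pos outside interval")

    def overlaps(self, other: "QtlInterval | ConsensusRegion") -> bool:
        return self.chrom == other.chrom and (
            self.start <= other.end and other.start <= self.end
        )


@dataclass
class ConsensusRegion:
    """A stretch supported by >= min_support methods simultaneously."""

    chrom: str
    start: int
    end: int
    supporting_methods: frozenset[str]
    members: tuple[QtlInterval, ...] = ()
    name: str | None = None

    @property
    def support(self) -> int:
        return len(self.supporting_methods)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome order: Gm02 < Gm05 < Gm20, chr2 < chr10."""
    parts = re.split(r"(\d+)", str(chrom))
    return tuple(int(p) if p.isdigit() else p for p in parts)


def call_intervals(
    track: StatTrack,
    threshold: float | np.ndarray,
    mode: str = "greater",
) -> list[QtlInterval]:
    """Intervals from maximal runs of consecutive significant windows.

    ``mode`` selects the exceedance rule: ``"greater"`` (value > threshold,
    for ED/G), ``"abs_greater"`` (|value| > threshold, for Δ(SNP-index));
    ``"min_q_less"`` (window min_q < threshold, for Fisher q-values).
    ``threshold`` may be a scalar or a per-window array (depth-dependent
    Δ envelopes).  Masked windows are never significant and break runs.
    """
    win = track.windows
    v = win["value"].to_numpy(dtype=float)
    thr = np.broadcast_to(np.asarray(threshold, dtype=float), v.shape)
    if mode == "greater":
        above = v > thr
    elif mode == "abs_greater":
        above = np.abs(v) > thr
    elif mode == "min_q_less":
        if "min_q" not in win:
            raise ValueError("track lacks min_q; smooth() with q_column=")
        above = win["min_q"].to_numpy(dtype=float) < thr
    else:
        raise ValueError(f"unknown mode {mode!r}")
    above &= np.isfinite(v)

    chroms = win["chrom"].to_numpy()
    starts = win["start"].to_numpy()
    ends = win["end"].to_numpy()
    out: list[QtlInterval] = []
    i, n = 0, len(win)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1] and chroms[j + 1] == chroms[i]:
            j += 1
        seg = slice(i, j + 1)
        vals = v[seg]
        peak = int(np.nanargmax(np.abs(vals)))
        out.append(
            QtlInterval(
                chrom=str(chroms[i]),
                start=int(starts[i]),
                end=int(ends[j]),
                peak_value=float(vals[peak]),
                peak_pos=int(starts[seg][peak] + (ends[seg][peak] - starts[seg][peak]) // 2),
                method=track.method,
            )
        )
        i = j + 1
    return _merge_overlapping(out)


def _merge_overlapping(ivs: list[QtlInterval]) -> list[QtlInterval]:
    """Merge bp-overlapping intervals of one method (overlapping windows can
    put two window-runs on overlapping spans); intervals separated by >= 1 bp
    stay separate.  The merged peak is the extremal |peak| of the members."""
    out: list[QtlInterval] = []
    for nxt in sorted(ivs, key=lambda x: (chrom_sort_key(x.chrom), x.start)):
        if out and out[-1].chrom == nxt.chrom and nxt.start <= out[-1].end:
            cur = out[-1]
            if abs(nxt.peak_value) > abs(cur.peak_value):
                cur.peak_value, cur.peak_pos = nxt.peak_value, nxt.peak_pos
            cur.end = max(cur.end, nxt.end)
        else:
            out.append(nxt)
    return out


def _merge_union(intervals: list[QtlInterval]) -> list[tuple[int, int]]:
    """Union coverage of one method's intervals as disjoint (start, end)."""
    ivs = sorted((iv.start, iv.end) for iv in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def intersect_methods(
    intervals_by_method: dict[str, list[QtlInterval]],
    min_support: int | None = None,
) -> list[ConsensusRegion]:
    """Consensus regions where >= ``min_support`` methods' intervals overlap.

    A position sweep over interval endpoints counts, at every base, how many
    methods cover it (a method counts once however many of its intervals
    overlap); maximal runs of bases with support >= min_support become
    :class:`ConsensusRegion` objects.  ``supporting_methods`` (and
    ``members``) record every method/interval overlapping the region.
    Defaults to full support (all methods present in the input).
    """
    methods = list(intervals_by_method)
    if min_support is None:
        min_support = len(methods)
    if min_support > len(methods):
        raise ValueError("min_support exceeds the number of methods")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")

    chroms = sorted(
        {iv.chrom for ivs in intervals_by_method.values() for iv in ivs},
        key=chrom_sort_key,
    )
    regions: list[ConsensusRegion] = []
    for chrom in chroms:
        events: list[tuple[int, int]] = []  # (position, +1/-1), half-open
        for method in methods:
            ivs = [iv for iv in intervals_by_method[method] if iv.chrom == chrom]
            for s, e in _merge_union(ivs):
                events.append((s, +1))
                events.append((e + 1, -1))
        events.sort()
        support = 0
        run_start: int | None = None
        for pos, grp in _grouped(events):
            prev = support
            support += grp
            if prev < min_support <= support:
                run_start = pos
            elif prev >= min_support > support:
                regions.append(_make_region(
                    chrom, run_start, pos - 1, intervals_by_method))
                run_start = None
    return regions


def _grouped(events):
    """Collapse simultaneous events at the same position."""
    i = 0
    while i < len(events):
        pos = events[i][0]
        total = 0
        while i < len(events) and events[i][0] == pos:
            total += events[i][1]
            i += 1
        yield pos, total


def _make_region(chrom, start, end, intervals_by_method) -> ConsensusRegion:
    members = tuple(
        iv
        for ivs in intervals_by_method.values()
        for iv in ivs
        if iv.chrom == chrom and iv.start <= end and start <= iv.end
    )
    return ConsensusRegion(
        chrom=chrom,
        start=int(start),
        end=int(end),
        supporting_methods=frozenset(iv.method for iv in members),
        members=members,
    )


def name_regions(
    regions: list[ConsensusRegion], prefix: str = "qBBN"
) -> list[ConsensusRegion]:
    """Assign qBBN-style names genome-wide: chromosomes in natural order,
    then ascending start.  Returns the regions sorted and named in place."""
    ordered = sorted(regions, key=lambda r: (chrom_sort_key(r.chrom), r.start))
    for i, region in enumerate(ordered, start=1):
        region.name = f"{prefix}{i}"
    return ordered


@dataclass
class RecoveryReport:
    """Aggregate outcome of simulation-recovery replicates."""

    n_replicates: int
    n_hits: int
    mean_width_bp: float
    coverage_rate: float = field(init=False)
    coverage_se: float = field(init=False)

    def __post_init__(self) -> None:
        r = self.n_hits / self.n_replicates if self.n_replicates else float("nan")
        self.coverage_rate = r
        self.coverage_se = (
            float(np.sqrt(r * (1 - r) / self.n_replicates))
            if self.n_replicates
            else float("nan")
        )


def evaluate_recovery(
    replicate_regions: list[list[ConsensusRegion]],
    qtl_positions: list[tuple[str, int]],
) -> RecoveryReport:
    """Fraction of replicates in which any consensus region covers the true
    QTL, plus the mean width of all called regions."""
    if len(replicate_regions) != len(qtl_positions):
        raise ValueError("one QTL position required per replicate")
    hits = 0
    widths = []
    for regions, (chrom, pos) in zip(replicate_regions, qtl_positions):
        if any(r.contains(chrom, pos) for r in regions):
            hits += 1
        widths.extend(r.width for r in regions)
    return RecoveryReport(
        n_replicates=len(replicate_regions),
        n_hits=hits,
        mean_width_bp=float(np.mean(widths)) if widths else float("nan"),
    )
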