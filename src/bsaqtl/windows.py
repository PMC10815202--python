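"""Sliding-window smoothing and per-statistic significance thresholds.

Per-variant statistics are averaged on a sliding-window grid (default 1000 kb
windows advancing in 10 kb steps, matching common BSA-seq practice), and each
statistic gets its own notion of a "99% confidence" threshold:

* Δ(SNP-index): a simulated null confidence envelope as a function of read
  depth (:func:`takagi_ci`), applied two-sidedly to |Δ|;
* ED and G: the genome-wide empirical ``level``-quantile of window values
  (:func:`empirical_threshold`);
* Fisher: per-variant Benjamini–Hochberg q-values; a window is significant
  when its minimum member q falls below ``q < 0.01``.

Windows holding fewer than ``min_snps_per_window`` informative variants are
masked (NaN) rather than zero-filled — an empty window is absence of
evidence, not evidence of no QTL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "make_grid",
    "StatTrack",
    "smooth",
    "takagi_ci",
    "empirical_threshold",
]


def make_grid(
    chrom_lengths: dict[str, int],
    window_size_bp: int = 1_000_000,
    step_bp: int = 10_000,
) -> pd.DataFrame:
    """Sliding-window grid covering each chromosome.

    Window starts are 1, 1+step, 1+2*step, ... for every start not beyond the
    chromosome end; windows are 1-based inclusive and the trailing windows
    are truncated at the chromosome end, so every base is covered and
    interior bases fall in exactly ``window/step`` windows.
    """
    if not (window_size_bp >= step_bp >= 1):
        raise ValueError("need window_size_bp >= step_bp >= 1")
    frames = []
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        starts = np.arange(1, length + 1, step_bp, dtype=np.int64)
        ends = np.minimum(starts + window_size_bp - 1, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(frames, ignore_index=True)


@dataclass
class StatTrack:
    """Windowed values of one statistic on a sliding-window grid.

    ``windows`` holds one row per grid window: chrom, start, end, ``value``
    (mean of member variants' statistic; NaN when masked), ``n_variants``
    (members with a defined statistic) and ``mean_depth``.  Fisher tracks
    additionally carry ``min_q``, the smallest member q-value.
    """

    method: str
    windows: pd.DataFrame
    window_size_bp: int
    step_bp: int

    def unmasked(self) -> pd.DataFrame:
        return self.windows[np.isfinite(self.windows["value"].to_numpy())]


def _window_members(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray):
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="right")
    return lo, hi


def smooth(
    stats: pd.DataFrame,
    grid: pd.DataFrame,
    value_column: str,
    method: str | None = None,
    min_snps_per_window: int = 10,
    depth: np.ndarray | None = None,
    q_column: str | None = None,
) -> StatTrack:
    """Average a per-variant statistic over every grid window.

    ``stats`` must be sorted by (chrom, pos).  Variants whose statistic is
    NaN do not count toward the window mean nor toward the member count.
    ``depth`` (optional, aligned with ``stats``) is averaged per window into
    ``mean_depth`` — used to evaluate depth-dependent Δ(SNP-index)
    envelopes.  ``q_column`` requests a per-window minimum (for Fisher
    q-values).
    """
    if method is None:
        method = value_column
    win = grid.copy()
    n_out = np.zeros(len(win), dtype=np.int64)
    val_out = np.full(len(win), np.nan)
    depth_out = np.full(len(win), np.nan)
    minq_out = np.full(len(win), np.nan)

    for chrom, widx in win.groupby("chrom", sort=False).groups.items():
        widx = np.asarray(widx)
        block = stats[stats["chrom"] == chrom]
        if len(block) == 0:
            continue
        pos = block["pos"].to_numpy()
        v = block[value_column].to_numpy(dtype=float)
        ok = np.isfinite(v)
        csum = np.concatenate([[0.0], np.cumsum(np.where(ok, v, 0.0))])
        ccnt = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
        starts = win.loc[widx, "start"].to_numpy()
        ends = win.loc[widx, "end"].to_numpy()
        lo, hi = _window_members(pos, starts, ends)
        cnt = ccnt[hi] - ccnt[lo]
        with np.errstate(invalid="ignore"):
            mean = np.where(cnt > 0, (csum[hi] - csum[lo]) / np.maximum(cnt, 1), np.nan)
        n_out[widx] = cnt
        val_out[widx] = mean
        if depth is not None:
            d = np.asarray(depth, dtype=float)[stats["chrom"].to_numpy() == chrom]
            cd = np.concatenate([[0.0], np.cumsum(np.where(ok, d, 0.0))])
            depth_out[widx] = np.where(
                cnt > 0, (cd[hi] - cd[lo]) / np.maximum(cnt, 1), np.nan
            )
        if q_column is not None:
            q = block[q_column].to_numpy(dtype=float)
            mins = np.full(len(widx), np.nan)
            for i, (a, b) in enumerate(zip(lo, hi)):
                seg = q[a:b]
                seg = seg[np.isfinite(seg)]
                if seg.size:
                    mins[i] = seg.min()
            minq_out[widx] = mins

    masked = n_out < min_snps_per_window
    val_out[masked] = np.nan
    win["value"] = val_out
    win["n_variants"] = n_out
    if depth is not None:
        win["mean_depth"] = depth_out
    if q_column is not None:
        minq_out[masked] = np.nan
        win["min_q"] = minq_out
    return StatTrack(
        method=method,
        windows=win,
        window_size_bp=int((grid["end"] - grid["start"]).max()) + 1,
        step_bp=int(np.diff(grid["start"].to_numpy()[:2])[0]) if len(grid) > 1 else 1,
    )


def takagi_ci(
    pool_size: int,
    depths,
    level: float = 0.99,
    reps: int = 10_000,
    seed: int = 0,
) -> dict[int, float]:
    """Simulated null confidence envelope for Δ(SNP-index), by depth.

    For each read depth, ``reps`` null F2 sites are simulated: each pool's
    allele count is the sum of ``2*pool_size`` independent fair allele draws
    (an F2 genotype is two independent Bernoulli(1/2) alleles), converted to
    a pool frequency, from which binomial read counts at the given depth are
    drawn for each pool.  The envelope is the ``level`` empirical quantile
    of |Δ(SNP-index)| — a symmetric two-sided band around zero.

    Returns ``{depth: half_width}``.  Even at infinite depth the envelope
    stays away from zero: finite pools leave sampling noise in the pool
    frequencies themselves.
    """
    depths = np.atleast_1d(np.asarray(depths, dtype=int))
    if (depths <= 0).any():
        raise ValueError("depths must be positive")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for a stable 99% quantile")
    if not 0.5 < level < 1.0:
        raise ValueError("level must be in (0.5, 1)")
    rng = np.random.default_rng(seed)
    out: dict[int, float] = {}
    for d in depths:
        freq_h = rng.binomial(2 * pool_size, 0.5, size=reps) / (2.0 * pool_size)
        freq_l = rng.binomial(2 * pool_size, 0.5, size=reps) / (2.0 * pool_size)
        delta = (
            rng.binomial(d, freq_h) / d - rng.binomial(d, freq_l) / d
        )
        out[int(d)] = float(np.quantile(np.abs(delta), level))
    return out


def envelope_for_track(
    track: StatTrack, envelope: dict[int, float]
) -> np.ndarray:
    """Per-window Δ threshold: the envelope interpolated at each window's
    mean depth (extrapolation is clamped to the nearest simulated depth)."""
    if "mean_depth" not in track.windows:
        raise ValueError("track lacks mean_depth; pass depth= to smooth()")
    ds = np.array(sorted(envelope))
    hw = np.array([envelope[d] for d in ds])
    return np.interp(track.windows["mean_depth"].to_numpy(), ds, hw)


def null_window_threshold(
    stat: str,
    pool_size: int,
    mean_depth_h: float,
    mean_depth_l: float,
    n_variants: int,
    level: float = 0.99,
    reps: int = 10_000,
    seed: int = 0,
    ed_power: float = 2.0,
) -> float:
    """Simulated null ``level``-quantile of a window-mean ED or G value.

    Simulates ``reps`` windows of ``n_variants`` independent null F2 sites —
    pool allele counts Binomial(2*pool_size, 1/2), Poisson read depths around
    each pool's mean, binomial reads — computes ED^power or G per site and
    takes the ``level`` quantile of the window means.  Unlike a genome-wide
    empirical quantile this threshold is unaffected by how much of the
    genome carries real signal, which matters on small genomes where a
    single strong QTL occupies more than ``1 - level`` of all windows.
    """
    from . import stats as _stats

    if stat not in ("ed", "g"):
        raise ValueError("stat must be 'ed' or 'g'")
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if mean_depth_h <= 0 or mean_depth_l <= 0:
        raise ValueError("depths must be positive")
    rng = np.random.default_rng(seed)
    shape = (reps, n_variants)
    f_h = rng.binomial(2 * pool_size, 0.5, shape) / (2.0 * pool_size)
    f_l = rng.binomial(2 * pool_size, 0.5, shape) / (2.0 * pool_size)
    d_h = np.maximum(rng.poisson(mean_depth_h, shape), 1)
    d_l = np.maximum(rng.poisson(mean_depth_l, shape), 1)
    alt_h = rng.binomial(d_h, f_h)
    alt_l = rng.binomial(d_l, f_l)
    if stat == "ed":
        _, site = _stats.euclidean_distance(
            (d_h - alt_h).ravel(), alt_h.ravel(),
            (d_l - alt_l).ravel(), alt_l.ravel(), power=ed_power,
        )
    else:
        site = _stats.g_statistic(
            (d_h - alt_h).ravel(), alt_h.ravel(),
            (d_l - alt_l).ravel(), alt_l.ravel(),
        )
    return float(np.quantile(site.reshape(shape).mean(axis=1), level))


def empirical_threshold(
    track: StatTrack, level: float = 0.99, two_sided: bool = False
) -> float:
    """Genome-wide empirical ``level``-quantile of unmasked window values.

    With ``two_sided=True`` the quantile is taken over |value| (for signed
    statistics such as Δ(SNP-index)).  Requires at least 100 unmasked
    windows for the tail quantile to be meaningful.
    """
    if not 0.5 < level < 1.0:
        raise ValueError("level must be in (0.5, 1)")
    vals = track.windows["value"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 100:
        raise ValueError(
            f"only {len(vals)} unmasked windows; need >= 100 for a "
            f"{level:.0%} empirical threshold"
        )
    if two_sided:
        vals = np.abs(vals)
    return float(np.quantile(vals, level))
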