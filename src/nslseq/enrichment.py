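"""ChIP/input enrichment: normalization, log2FC tracks, smoothing,
empirical-FDR thresholds from mirrored negative values, and peak calling.

The significance model follows the noise-mirroring idea: negative log2FC
values are assumed to be experimental noise, so for a candidate cutoff c the
false-discovery rate is estimated as the number of bins at or below -c over
the number of bins at or above +c.  A half-normal fit to the negative tail
is available as an alternative noise model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .io import BinnedTrack, IntervalSet

__all__ = [
    "SizeFactors",
    "ThresholdResult",
    "PeakCall",
    "estimate_size_factors",
    "log2fc_track",
    "smooth_sliding",
    "empirical_fdr_threshold",
    "call_enriched_regions",
    "peaks_to_intervals",
    "peaks_from_intervals",
]


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample median-of-ratios normalization factors (all > 0)."""

    factors: tuple[float, ...]

    def __post_init__(self):
        if any(f <= 0 for f in self.factors):
            raise ValueError("size factors must be positive")

    def __getitem__(self, i: int) -> float:
        return self.factors[i]

    def __len__(self) -> int:
        return len(self.factors)


def estimate_size_factors(counts: np.ndarray) -> SizeFactors:
    """Median-of-ratios size factors over a bins x samples count matrix.

    Per sample: median over bins (restricted to bins whose across-sample
    geometric mean is positive, i.e. all samples non-zero) of
    count / geometric mean.  A single sample gets factor 1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[:, None]
    if counts.shape[1] == 1:
        return SizeFactors((1.0,))
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no bin has positive counts in all samples; use coarser bins"
        )
    logs = np.log(counts[positive])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return SizeFactors(tuple(factors))


def log2fc_track(
    chip: BinnedTrack,
    input_: BinnedTrack,
    sf: SizeFactors | Sequence[float] = (1.0, 1.0),
    pseudocount: float = 1.0,
) -> BinnedTrack:
    """log2((chip/sf_chip + eps) / (input/sf_input + eps)) per bin.

    The pseudocount is applied on the normalized-count scale so its meaning
    does not depend on sequencing depth.
    """
    if not chip.same_layout_as(input_):
        raise ValueError("chip and input tracks have different layouts")
    sfc, sfi = sf[0], sf[1]
    data = {}
    for chrom in chip.data:
        c = chip.data[chrom] / sfc + pseudocount
        i = input_.data[chrom] / sfi + pseudocount
        data[chrom] = np.log2(c / i)
    return BinnedTrack(bin_size=chip.bin_size, data=data, value_kind="log2fc")


def smooth_sliding(track: BinnedTrack, window: int = 400) -> BinnedTrack:
    """Centered moving average over ``window`` bp (multiple of the bin size).

    Chromosome edges are averaged over the available bins only, so a
    constant track is exactly preserved.
    """
    bs = track.bin_size
    if window < bs:
        raise ValueError("window must be >= bin size")
    if window % bs != 0:
        raise ValueError("window must be a multiple of the bin size")
    w = window // bs
    if w == 1:
        return track.map(np.copy)
    left = w // 2
    kernel = np.ones(w)
    data = {}
    for chrom, v in track.data.items():
        num = np.convolve(v, kernel, mode="full")
        den = np.convolve(np.ones_like(v, dtype=float), kernel, mode="full")
        # window for bin i covers bins [i-left, i-left+w); in 'full' output
        # that sum sits at index i - left + w - 1
        idx = np.arange(len(v)) + (w - 1 - left)
        data[chrom] = num[idx] / den[idx]
    return BinnedTrack(bin_size=bs, data=data, value_kind=track.value_kind)


@dataclass
class ThresholdResult:
    """Empirical-FDR threshold c* with the full FDR(c) curve."""

    threshold: float
    fdr_target: float
    grid_step: float
    grid: np.ndarray = field(repr=False)
    fdr_curve: np.ndarray = field(repr=False)
    noise_model: str = "mirror"

    def fdr_at(self, c: float) -> float:
        i = int(np.searchsorted(self.grid, c))
        return float(self.fdr_curve[min(i, len(self.fdr_curve) - 1)])


def empirical_fdr_threshold(
    values: np.ndarray,
    fdr: float = 0.05,
    grid_step: float = 0.01,
    noise_model: Literal["mirror", "halfnormal"] = "mirror",
) -> ThresholdResult:
    """Smallest grid cutoff c* with estimated FDR(c*) <= ``fdr``.

    mirror: FDR(c) = #{v <= -c} / max(1, #{v >= c}).
    halfnormal: sigma fitted to the negative values; the expected number of
    noise exceedances 2 * #neg * (1 - Phi(c/sigma)) replaces the numerator.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0 or not (values > 0).any():
        raise ValueError("values must contain at least one positive entry")
    vmax = np.abs(values).max()
    n_grid = int(np.ceil(vmax / grid_step))
    grid = grid_step * np.arange(1, n_grid + 1)
    pos = np.sort(values[values > 0])
    neg = np.sort(-values[values < 0])  # magnitudes of negatives, ascending
    n_pos_ge = len(pos) - np.searchsorted(pos, grid, side="left")
    if noise_model == "mirror":
        n_noise = len(neg) - np.searchsorted(neg, grid, side="left")
        n_noise = n_noise.astype(float)
    elif noise_model == "halfnormal":
        if len(neg) == 0:
            n_noise = np.zeros_like(grid)
        else:
            sigma = float(np.sqrt(np.mean(neg**2)))
            n_noise = 2.0 * len(neg) * stats.norm.sf(grid / sigma)
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")
    curve = n_noise / np.maximum(1, n_pos_ge)
    ok = np.nonzero(curve <= fdr)[0]
    if ok.size == 0:
        raise ValueError(
            f"no cutoff achieves FDR <= {fdr}; minimum achieved is {curve.min():.4g}"
        )
    i = ok[0]
    return ThresholdResult(
        threshold=float(grid[i]),
        fdr_target=fdr,
        grid_step=grid_step,
        grid=grid,
        fdr_curve=curve,
        noise_model=noise_model,
    )


@dataclass(frozen=True)
class PeakCall:
    """An enriched region with a summit and its 40 bp summit region."""

    chrom: str
    start: int
    end: int
    summit: int
    summit_height: float
    summit_halfwidth: int = 20

    def __post_init__(self):
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie inside the peak interval")

    @property
    def summit_region(self) -> tuple[int, int]:
        return (self.summit - self.summit_halfwidth, self.summit + self.summit_halfwidth)


def _split_summits(values: np.ndarray, valley_frac: float) -> list[int]:
    """Local maxima of a run, merged unless separated by a valley dropping
    below ``valley_frac`` of the lower flanking maximum (subpeak-splitter
    rule)."""
    n = len(values)
    if n == 1:
        return [0]
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1  # plateau
        left_ok = i == 0 or values[i - 1] < values[i]
        right_ok = j == n - 1 or values[j + 1] < values[i]
        if left_ok and right_ok:
            maxima.append((i + j) // 2)
        i = j + 1
    # iteratively merge adjacent maxima whose valley is too shallow
    changed = True
    while changed and len(maxima) > 1:
        changed = False
        for k in range(len(maxima) - 1):
            a, b = maxima[k], maxima[k + 1]
            valley = values[a : b + 1].min()
            lower = min(values[a], values[b])
            if valley >= valley_frac * lower:
                # drop the lower of the two maxima
                drop = k if values[a] <= values[b] else k + 1
                del maxima[drop]
                changed = True
                break
    return maxima


def call_enriched_regions(
    track: BinnedTrack,
    threshold: float | ThresholdResult,
    valley_frac: float = 0.5,
    summit_halfwidth: int = 20,
) -> list[PeakCall]:
    """Maximal runs of bins >= threshold become regions; local maxima within
    a region separated by a valley dropping below ``valley_frac`` of the
    lower flanking maximum become separate summits (regions are split at the
    valley minimum between retained summits)."""
    if isinstance(threshold, ThresholdResult):
        threshold = threshold.threshold
    bs = track.bin_size
    peaks: list[PeakCall] = []
    for chrom, v in track.data.items():
        above = v >= threshold
        if not above.any():
            continue
        run_starts = np.flatnonzero(above & ~np.r_[False, above[:-1]])
        run_ends = np.flatnonzero(above & ~np.r_[above[1:], False]) + 1
        for rs, re in zip(run_starts, run_ends):
            seg = v[rs:re]
            summit_bins = _split_summits(seg, valley_frac)
            # split the region at valley minima between retained summits
            cut_points = [0]
            for a, b in zip(summit_bins[:-1], summit_bins[1:]):
                cut_points.append(a + int(np.argmin(seg[a : b + 1])))
            cut_points.append(len(seg))
            for k, sb in enumerate(summit_bins):
                lo, hi = cut_points[k], cut_points[k + 1]
                summit = (rs + sb) * bs + bs // 2
                peaks.append(
                    PeakCall(
                        chrom=chrom,
                        start=(rs + lo) * bs,
                        end=(rs + hi) * bs,
                        summit=summit,
                        summit_height=float(seg[sb]),
                        summit_halfwidth=summit_halfwidth,
                    )
                )
    return peaks


def peaks_to_intervals(peaks: Sequence[PeakCall]) -> IntervalSet:
    """Export peaks in the MACS-style BED6+ dialect: the score column holds
    the summit height and the name encodes the summit offset from start."""
    return IntervalSet.from_records(
        (
            p.chrom,
            p.start,
            p.end,
            f"peak_{i}|summit={p.summit - p.start}",
            p.summit_height,
            ".",
        )
        for i, p in enumerate(peaks)
    )


def peaks_from_intervals(
    regions: IntervalSet, summit_halfwidth: int = 20
) -> list[PeakCall]:
    """Import externally generated peaks.  The summit offset is taken from a
    ``summit=`` tag in the name column; otherwise the interval midpoint."""
    peaks = []
    for row in regions.frame.itertuples(index=False):
        offset = None
        for part in str(row.name).split("|"):
            if part.startswith("summit="):
                offset = int(part.split("=", 1)[1])
        summit = row.start + (offset if offset is not None else (row.end - row.start) // 2)
        peaks.append(
            PeakCall(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                summit=int(summit),
                summit_height=float(row.score),
                summit_halfwidth=summit_halfwidth,
            )
        )
    return peaks
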