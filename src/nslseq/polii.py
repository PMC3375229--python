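"""Pol II knockdown response: delta tracks, promoter summaries, stalling
indexes under the stringent gene filters, and group comparisons.

Delta Pol II is the bin-wise difference of the knockdown and control log2FC
tracks; negative values mean Pol II loss.  The stalling index of a gene is

    SI = log2( r(TSS) / r(gene body) )

where r is the input-adjusted, size-factor-normalized Pol II read count of
the region divided by its length; the promoter is TSS +/- 200 bp and the
gene body excludes 500 bp after the TSS and 500 bp before the TES.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import BinnedTrack, GeneModel

__all__ = [
    "TestResult",
    "StallingRecord",
    "delta_track",
    "promoter_summary",
    "stalling_index",
    "compare_groups",
    "delta_tertiles",
    "overlapping_gene_ids",
]


def delta_track(kd: BinnedTrack, ctrl: BinnedTrack) -> BinnedTrack:
    """Bin-wise log2FC(knockdown) - log2FC(control)."""
    if not kd.same_layout_as(ctrl):
        raise ValueError("knockdown and control tracks have different layouts")
    data = {c: kd.data[c] - ctrl.data[c] for c in kd.data}
    return BinnedTrack(bin_size=kd.bin_size, data=data, value_kind="delta")


def _window_bins_fully_inside(start: int, end: int, bin_size: int) -> tuple[int, int]:
    """Index range [lo, hi) of bins fully inside [start, end)."""
    lo = -(-start // bin_size)  # ceil
    hi = end // bin_size
    return lo, hi


def promoter_summary(
    track: BinnedTrack,
    genes: Sequence[GeneModel],
    width: int = 400,
    stat: Literal["median", "mean"] = "median",
) -> pd.Series:
    """Per-gene summary over the bins fully inside [tss-width/2, tss+width/2).

    Genes with no fully covered bin get NaN.
    """
    if width % track.bin_size != 0:
        raise ValueError("width must be a multiple of the bin size")
    half = width // 2
    fn = np.median if stat == "median" else np.mean
    out = {}
    for g in genes:
        v = track.data.get(g.chrom)
        if v is None:
            out[g.gene_id] = np.nan
            continue
        lo, hi = _window_bins_fully_inside(g.tss - half, g.tss + half, track.bin_size)
        lo, hi = max(lo, 0), min(hi, len(v))
        out[g.gene_id] = float(fn(v[lo:hi])) if hi > lo else np.nan
    return pd.Series(out, name=f"promoter_{stat}")


def overlapping_gene_ids(genes: Sequence[GeneModel]) -> set[str]:
    """Gene ids overlapping another gene on the same chromosome
    (half-open: touching genes do not overlap)."""
    flagged: set[str] = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: g.start)
        max_end = -1
        prev: GeneModel | None = None
        for g in chrom_genes:
            if g.start < max_end:
                flagged.add(g.gene_id)
                if prev is not None:
                    flagged.add(prev.gene_id)
            if g.end > max_end:
                max_end = g.end
                prev = g
    return flagged


def _region_rate(
    chip: np.ndarray,
    inp: np.ndarray,
    start: int,
    end: int,
    bin_size: int,
    sf_chip: float,
    sf_input: float,
    adjust: str,
    pseudocount: float,
) -> float:
    """Input-adjusted, normalized count density of [start, end), with
    fractional weights for partially covered edge bins."""
    n = len(chip)
    start, end = max(start, 0), min(end, n * bin_size)
    if end <= start:
        return np.nan
    first, last = start // bin_size, (end - 1) // bin_size
    idx = np.arange(first, last + 1)
    bin_lo = idx * bin_size
    bin_hi = bin_lo + bin_size
    frac = (np.minimum(bin_hi, end) - np.maximum(bin_lo, start)) / bin_size
    c = chip[idx] / sf_chip
    i = inp[idx] / sf_input
    if adjust == "subtract":
        adj = np.maximum(c - i, 0.0)
    elif adjust == "ratio":
        adj = c / (i + pseudocount)
    else:
        raise ValueError(f"unknown input adjustment {adjust!r}")
    return float(np.sum(adj * frac) / (end - start))


@dataclass
class StallingRecord:
    gene_id: str
    r_tss: float
    r_body: float
    si: float  # log2(r_tss / r_body); NaN unless filters pass and r > 0
    passed_filters: bool
    reason: str  # "" when passed; else first failing filter


def stalling_index(
    genes: Sequence[GeneModel],
    polii: BinnedTrack,
    input_: BinnedTrack,
    sf: Sequence[float] = (1.0, 1.0),
    threshold: float | None = None,
    fc_track: BinnedTrack | None = None,
    promoter_halfwidth: int = 200,
    body_trim: int = 500,
    min_length: int = 1300,
    adjust: Literal["subtract", "ratio"] = "subtract",
    pseudocount: float = 1.0,
) -> list[StallingRecord]:
    """Stalling indexes with the stringent gene filters applied in order:
    gene overlap, length > ``min_length``, promoter median log2FC >=
    ``threshold`` (evaluated on ``fc_track`` when given, else on a log2FC
    track computed from the count tracks).

    The default input adjustment subtracts the normalized input from the
    normalized ChIP counts (floored at zero); ``adjust="ratio"`` divides
    instead.
    """
    if not polii.same_layout_as(input_):
        raise ValueError("Pol II and input tracks have different layouts")
    overlapping = overlapping_gene_ids(genes)
    prom_median: pd.Series | None = None
    if threshold is not None:
        if fc_track is None:
            from .enrichment import log2fc_track

            fc_track = log2fc_track(polii, input_, sf, pseudocount)
        prom_median = promoter_summary(
            fc_track, genes, width=2 * promoter_halfwidth, stat="median"
        )
    records = []
    for g in genes:
        reason = ""
        if g.gene_id in overlapping:
            reason = "overlap"
        elif g.length <= min_length:
            reason = "length"
        elif prom_median is not None and not (
            np.isfinite(prom_median[g.gene_id])
            and prom_median[g.gene_id] >= threshold
        ):
            reason = "signal"
        chip = polii.data[g.chrom]
        inp = input_.data[g.chrom]
        r_tss = _region_rate(
            chip, inp, g.tss - promoter_halfwidth, g.tss + promoter_halfwidth,
            polii.bin_size, sf[0], sf[1], adjust, pseudocount,
        )
        r_body = _region_rate(
            chip, inp, g.start + body_trim, g.end - body_trim,
            polii.bin_size, sf[0], sf[1], adjust, pseudocount,
        )
        if not reason and not (r_tss > 0 and r_body > 0):
            reason = "zero_rate"
        passed = reason == ""
        si = float(np.log2(r_tss / r_body)) if passed else np.nan
        records.append(
            StallingRecord(
                gene_id=g.gene_id,
                r_tss=r_tss,
                r_body=r_body,
                si=si,
                passed_filters=passed,
                reason=reason,
            )
        )
    return records


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    median_a: float
    median_b: float


def compare_groups(values_a, values_b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null distribution for small tie-free samples (both n <= 25),
    normal approximation with continuity correction otherwise; ties are
    mid-ranked.  Two identical constant groups give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(
            statistic=len(a) * len(b) / 2.0,
            pvalue=1.0,
            n_a=len(a),
            n_b=len(b),
            median_a=float(pooled[0]),
            median_b=float(pooled[0]),
        )
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        n_a=len(a),
        n_b=len(b),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


def delta_tertiles(values: pd.Series) -> pd.Series:
    """Tertile strata of per-gene delta Pol II (type-7 quantile cut points).

    Stratum 1 holds the most severe Pol II loss (lowest values).  The caller
    is expected to pre-filter to genes with delta < 0 and significant
    control promoter signal.
    """
    v = pd.Series(values).dropna()
    if len(v) < 3:
        raise ValueError("need at least 3 genes to form tertiles")
    q1, q2 = np.quantile(v.to_numpy(), [1 / 3, 2 / 3])  # type-7 default
    strata = np.where(v <= q1, 1, np.where(v <= q2, 2, 3))
    return pd.Series(strata, index=v.index, name="stratum")
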