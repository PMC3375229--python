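"""Chromatin context around TSSs: nucleosome occupancy, expression-quartile
stratification, metagene profiles (anchored and scaled-body, with optional
H4 normalization), chromatin-state association, and heatmap matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import PeakCall
from .io import BinnedTrack, GeneModel, IntervalSet, ReadSet, extract_signal

__all__ = [
    "OccupancyRecord",
    "MetaProfile",
    "occupancy_at_tss",
    "quartile_stratify",
    "metaprofile",
    "state_association",
    "heatmap_matrix",
]

MITO_NAMES = {"chrM", "M", "MT", "mitochondrion_genome", "dmel_mitochondrion_genome"}


@dataclass(frozen=True)
class OccupancyRecord:
    gene_id: str
    occ_upstream: int  # reads overlapping the 200 bp window 5' of the TSS
    occ_downstream: int  # reads overlapping the 200 bp window 3' of the TSS


def _overlap_counters(reads: ReadSet):
    """Per chromosome, sorted starts and ends for O(log n) overlap counts."""
    counters = {}
    for chrom, sub in reads.frame.groupby("chrom", sort=False):
        counters[chrom] = (
            np.sort(sub["start"].to_numpy(np.int64)),
            np.sort(sub["end"].to_numpy(np.int64)),
        )
    return counters


def _count_overlapping(counter, a: int, b: int) -> int:
    """Number of reads intersecting [a, b): start < b and end > a."""
    starts, ends = counter
    n = len(starts)
    n_start_ge_b = n - np.searchsorted(starts, b, side="left")
    n_end_le_a = np.searchsorted(ends, a, side="right")
    return int(n - n_start_ge_b - n_end_le_a)


def occupancy_at_tss(
    nuc_reads: ReadSet,
    genes: Sequence[GeneModel],
    width: int = 200,
) -> list[OccupancyRecord]:
    """Sum of overlapping nucleosome reads in the ``width`` bp windows up-
    and downstream of each TSS (any-overlap counting, strand-aware; a read
    spanning the TSS contributes to both sides)."""
    counters = _overlap_counters(nuc_reads)
    records = []
    for g in genes:
        counter = counters.get(g.chrom)
        if counter is None:
            records.append(OccupancyRecord(g.gene_id, 0, 0))
            continue
        t = g.tss
        if g.strand == "+":
            up, down = (t - width, t), (t, t + width)
        else:
            up, down = (t + 1, t + 1 + width), (t + 1 - width, t + 1)
        records.append(
            OccupancyRecord(
                g.gene_id,
                _count_overlapping(counter, *up),
                _count_overlapping(counter, *down),
            )
        )
    return records


def quartile_stratify(expression: pd.Series) -> pd.Series:
    """Expression quartile (1 = lowest) with type-7 cut points; ties go to
    the lower stratum.  Degenerate (non-increasing) cut points are an
    error."""
    v = pd.Series(expression).dropna()
    if len(v) < 4:
        raise ValueError("need at least 4 genes for quartiles")
    cuts = np.quantile(v.to_numpy(float), [0.25, 0.5, 0.75])
    if not (cuts[0] < cuts[1] < cuts[2]):
        raise ValueError(f"degenerate quartile cut points {cuts}")
    strata = 1 + np.sum(v.to_numpy(float)[:, None] > cuts[None, :], axis=1)
    return pd.Series(strata, index=v.index, name="quartile")


@dataclass
class MetaProfile:
    """Across-gene average signal per bin."""

    edges: np.ndarray  # bp relative to anchor, or fractions for scaled mode
    values: np.ndarray
    n_genes: int
    scaled: bool = False


def metaprofile(
    source: BinnedTrack | ReadSet,
    genes: Sequence[GeneModel],
    window: tuple[int, int] = (500, 1000),
    bin_size: int = 25,
    scaled: bool = False,
    n_body_bins: int = 100,
    h4: BinnedTrack | None = None,
    layout=None,
) -> MetaProfile:
    """Metagene profile around the TSS (or over scaled gene bodies).

    * anchored mode: per-gene strand-aware extraction of ``window=(up,
      down)`` in ``bin_size`` bins, then the across-gene mean ignoring
      missing cells.
    * scaled mode: each gene body is linearly interpolated onto
      ``n_body_bins`` fractional bins before averaging.
    * ``h4``: a log2FC track subtracted bin-wise before averaging
      (ratio-of-ratios normalization for histone marks).

    ``source`` may be a read set, in which case it is binned with
    any-overlap counting first (requires ``layout``).
    """
    if isinstance(source, ReadSet):
        from .io import bin_reads

        if layout is None:
            raise ValueError("binning a ReadSet requires a genome layout")
        track = bin_reads(source, layout, bin_size, mode="overlap")
    else:
        track = source
    if h4 is not None:
        if not track.same_layout_as(h4):
            raise ValueError("H4 track layout mismatch")
        track = BinnedTrack(
            bin_size=track.bin_size,
            data={c: track.data[c].astype(float) - h4.data[c] for c in track.data},
            value_kind="log2fc",
        )
    if not genes:
        raise ValueError("no qualifying genes")

    if scaled:
        rows = np.full((len(genes), n_body_bins), np.nan)
        frac = (np.arange(n_body_bins) + 0.5) / n_body_bins
        for i, g in enumerate(genes):
            v = track.data.get(g.chrom)
            if v is None:
                continue
            lo, hi = g.start // track.bin_size, -(-g.end // track.bin_size)
            body = v[lo:hi].astype(float)
            if len(body) == 0:
                continue
            x = np.linspace(0, 1, len(body))
            prof = np.interp(frac, x, body) if len(body) > 1 else np.full(n_body_bins, body[0])
            rows[i] = prof if g.strand == "+" else prof[::-1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            values = np.nanmean(rows, axis=0)
        return MetaProfile(edges=frac, values=values, n_genes=len(genes), scaled=True)

    up, down = window
    rows = np.stack(
        [
            extract_signal(track, g.chrom, g.tss, (up, down), g.strand, bin_size)
            for g in genes
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(rows, axis=0)
    edges = np.arange(-up, down, bin_size)
    return MetaProfile(edges=edges, values=values, n_genes=len(genes))


def state_association(
    points: Sequence[tuple[str, int]] | Sequence[PeakCall],
    states: IntervalSet,
    background: Sequence[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Chromatin-state membership of summit points (2 bp, [pos-1, pos+1))
    or TSS points.

    Returns per-label counts and fractions; when a background point set is
    supplied, adds a two-sided Fisher's exact enrichment p-value and a
    binomial test against the background proportions.  A point overlapping
    two states is assigned to the first by coordinate with a warning.
    """

    def _positions(pts):
        out = []
        for p in pts:
            if isinstance(p, PeakCall):
                out.append((p.chrom, p.summit))
            else:
                out.append((p[0], int(p[1])))
        return out

    by_chrom: dict[str, pd.DataFrame] = {
        str(c): sub.sort_values("start")
        for c, sub in states.frame.groupby("chrom", sort=False)
    }

    def _label_of(chrom: str, pos: int):
        sub = by_chrom.get(chrom)
        if sub is None:
            return None
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        a, b = pos - 1, pos + 1
        hits = np.flatnonzero((starts < b) & (ends > a))
        if len(hits) == 0:
            return None
        if len(hits) > 1:
            warnings.warn(
                f"point {chrom}:{pos} overlaps {len(hits)} states; "
                "assigned to the first by coordinate"
            )
        return sub["name"].iloc[hits[0]]

    def _tally(pts) -> pd.Series:
        labels = [_label_of(c, p) for c, p in _positions(pts)]
        labels = [l for l in labels if l is not None]
        return pd.Series(labels).value_counts()

    counts = _tally(points)
    all_labels = sorted(set(states.frame["name"]))
    counts = counts.reindex(all_labels, fill_value=0)
    total = int(counts.sum())
    out = pd.DataFrame(
        {"count": counts, "fraction": counts / total if total else np.nan}
    )
    if background is not None:
        bg = _tally(background).reindex(all_labels, fill_value=0)
        bg_total = int(bg.sum())
        fisher_p, binom_p = [], []
        for label in all_labels:
            tab = [
                [int(counts[label]), total - int(counts[label])],
                [int(bg[label]), bg_total - int(bg[label])],
            ]
            fisher_p.append(stats.fisher_exact(tab, alternative="two-sided")[1])
            p0 = bg[label] / bg_total if bg_total else np.nan
            if 0 < p0 < 1 and total > 0:
                binom_p.append(
                    stats.binomtest(int(counts[label]), total, p0).pvalue
                )
            else:
                binom_p.append(np.nan)
        out["background_fraction"] = bg / bg_total if bg_total else np.nan
        out["fisher_p"] = fisher_p
        out["binomial_p"] = binom_p
    return out


def heatmap_matrix(
    track: BinnedTrack,
    genes: Sequence[GeneModel],
    window: tuple[int, int] = (500, 1500),
    bin_size: int = 50,
    sort: Literal["cumulative_signal", "genomic_location", "delta"] = "cumulative_signal",
) -> pd.DataFrame:
    """Gene x bin signal matrix for heatmaps (mitochondrial genes excluded).

    ``cumulative_signal`` sorts rows by descending row sum (stable: equal
    sums keep input order); ``delta`` ascending (greatest loss first);
    ``genomic_location`` by (chrom, tss).
    """
    kept = [g for g in genes if g.chrom not in MITO_NAMES]
    up, down = window
    rows = np.stack(
        [
            extract_signal(track, g.chrom, g.tss, (up, down), g.strand, bin_size)
            for g in kept
        ]
    )
    ids = [g.gene_id for g in kept]
    cols = np.arange(-up, down, bin_size)
    df = pd.DataFrame(rows, index=pd.Index(ids, name="gene_id"), columns=cols)
    if sort == "cumulative_signal":
        order = np.argsort(-np.nansum(rows, axis=1), kind="stable")
    elif sort == "delta":
        order = np.argsort(np.nansum(rows, axis=1), kind="stable")
    elif sort == "genomic_location":
        chrom_order = {c: i for i, c in enumerate(dict.fromkeys(g.chrom for g in kept))}
        keys = [(chrom_order[g.chrom], g.tss) for g in kept]
        order = sorted(range(len(kept)), key=lambda i: keys[i])
    else:
        raise ValueError(f"unknown sort {sort!r}")
    return df.iloc[list(order)]


def plot_profile(profiles: dict[str, MetaProfile], path, ylabel: str = "signal"):
    """Optional line-profile plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for name, prof in profiles.items():
        ax.plot(prof.edges, prof.values, label=name)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("position relative to TSS (bp)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
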