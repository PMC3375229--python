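"""NSL target-gene calling: bound-TSS calls from peak summit regions,
multi-protein set algebra (Venn partitions, core set), summit-to-TSS
distance classes and gene-class enrichment statistics.

A TSS is bound by a protein when the 400 bp window around the TSS,
[tss-200, tss+200), intersects the 40 bp summit region [summit-20,
summit+20) of any of that protein's peaks.  Intervals are half-open:
touching windows do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import PeakCall
from .io import GeneModel

__all__ = [
    "BoundTable",
    "call_bound_tss",
    "bound_set_algebra",
    "classify_summit_distance",
    "class_enrichment",
]

DISTANCE_CLASSES = ("proximal", "peripheral", "distal")


@dataclass
class BoundTable:
    """Per-TSS bound flags (one boolean column per protein).

    ``frame`` is indexed by gene_id with per-protein flag columns, an
    ``n_proteins_bound`` column, and the distance class of the nearest
    summit over all proteins.
    """

    frame: pd.DataFrame
    proteins: tuple[str, ...]

    def bound_any(self) -> pd.Series:
        return self.frame[list(self.proteins)].any(axis=1)

    def bound_all(self) -> pd.Series:
        return self.frame[list(self.proteins)].all(axis=1)

    def core_set(self) -> list[str]:
        return list(self.frame.index[self.bound_all()])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


def _summit_positions(peaks: Sequence[PeakCall]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[int]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p.summit)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in by_chrom.items()}


def call_bound_tss(
    genes: Sequence[GeneModel],
    peaks: Mapping[str, Sequence[PeakCall]],
    tss_halfwidth: int = 200,
    summit_halfwidth: int = 20,
) -> BoundTable:
    """Flag each gene's TSS as bound per protein.

    Overlap rule: [tss-h, tss+h) intersects [summit-s, summit+s), i.e.
    |summit - tss| < h + s strictly (half-open edge: a summit exactly
    h + s away does not bind).
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        raise ValueError(f"duplicate gene_ids: {list(dup[dup > 1].index[:5])}")
    reach = tss_halfwidth + summit_halfwidth
    columns: dict[str, np.ndarray] = {}
    for protein, plist in peaks.items():
        summits = _summit_positions(plist)
        flags = np.zeros(len(genes), dtype=bool)
        for i, g in enumerate(genes):
            pos = summits.get(g.chrom)
            if pos is None or len(pos) == 0:
                continue
            # any summit with tss - reach < s < tss + reach
            lo = np.searchsorted(pos, g.tss - reach, side="right")
            hi = np.searchsorted(pos, g.tss + reach, side="left")
            flags[i] = hi > lo
        columns[protein] = flags
    frame = pd.DataFrame(columns, index=pd.Index(ids, name="gene_id"))
    proteins = tuple(peaks)
    frame["n_proteins_bound"] = frame[list(proteins)].sum(axis=1)
    all_peaks = [p for plist in peaks.values() for p in plist]
    if all_peaks:
        dist = classify_summit_distance(all_peaks, genes, per_gene=True)
        frame["distance_class"] = dist.reindex(frame.index)
    else:
        frame["distance_class"] = pd.NA
    return BoundTable(frame=frame, proteins=proteins)


def bound_set_algebra(table: BoundTable) -> dict:
    """Per-protein counts, union and core counts, and the full Venn
    partition over the 2^k - 1 non-empty protein combinations."""
    proteins = table.proteins
    if len(proteins) < 2:
        raise ValueError("set algebra needs at least 2 proteins")
    flags = table.frame[list(proteins)].to_numpy(bool)
    per_protein = {p: int(flags[:, i].sum()) for i, p in enumerate(proteins)}
    union = int(flags.any(axis=1).sum())
    core = table.core_set()
    venn: dict[frozenset, int] = {}
    for r in range(1, len(proteins) + 1):
        for combo in combinations(range(len(proteins)), r):
            members = np.zeros(len(proteins), dtype=bool)
            members[list(combo)] = True
            cell = (flags == members).all(axis=1).sum()
            venn[frozenset(proteins[i] for i in combo)] = int(cell)
    assert sum(venn.values()) == union
    return {
        "per_protein": per_protein,
        "union": union,
        "core": len(core),
        "core_ids": core,
        "venn": venn,
    }


def classify_summit_distance(
    peaks: Sequence[PeakCall],
    genes: Sequence[GeneModel],
    proximal: int = 200,
    peripheral: int = 800,
    per_gene: bool = False,
):
    """Distance class of each summit to the nearest TSS: proximal <= 200 bp,
    peripheral 201-800 bp, distal > 800 bp.

    With ``per_gene=True``, instead returns each gene's class for its
    nearest summit (used for the BoundTable distance column).
    """
    if not genes:
        raise ValueError("gene list must be nonempty")
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}

    def _classify(d: float) -> str:
        if d <= proximal:
            return "proximal"
        if d <= peripheral:
            return "peripheral"
        return "distal"

    if per_gene:
        summit_by_chrom = _summit_positions(peaks)
        out = {}
        for g in genes:
            pos = summit_by_chrom.get(g.chrom)
            if pos is None or len(pos) == 0:
                out[g.gene_id] = pd.NA
                continue
            i = np.searchsorted(pos, g.tss)
            cands = pos[max(i - 1, 0) : i + 1]
            out[g.gene_id] = _classify(np.abs(cands - g.tss).min())
        return pd.Series(out, name="distance_class")

    classes = []
    for p in peaks:
        pos = tss_by_chrom.get(p.chrom)
        if pos is None or len(pos) == 0:
            classes.append("distal")
            continue
        i = np.searchsorted(pos, p.summit)
        cands = pos[max(i - 1, 0) : i + 1]
        classes.append(_classify(np.abs(cands - p.summit).min()))
    return pd.Series(classes, name="distance_class")


@dataclass
class ClassEnrichment:
    """2x2 bound-by-class association for one gene class."""

    gene_class: str
    table: np.ndarray  # [[bound&class, bound&other], [unbound&class, unbound&other]]
    odds_ratio: float
    pvalue: float
    frac_bound_in_class: float  # share of bound genes in this class
    frac_class_bound: float  # share of class genes that are bound


def class_enrichment(
    bound: pd.Series,
    gene_classes: pd.Series,
) -> dict[str, ClassEnrichment]:
    """Fisher's exact association between a bound flag and each gene class.

    ``bound`` and ``gene_classes`` are aligned by gene id; classes must
    partition the genes (no NaN).  Two-sided exact p-values.
    """
    df = pd.DataFrame({"bound": bound, "cls": gene_classes}).dropna()
    if df.empty:
        raise ValueError("no genes with both bound flag and class label")
    out = {}
    for cls in df["cls"].unique():
        in_cls = df["cls"] == cls
        b = df["bound"].astype(bool)
        tab = np.array(
            [
                [int((b & in_cls).sum()), int((b & ~in_cls).sum())],
                [int((~b & in_cls).sum()), int((~b & ~in_cls).sum())],
            ]
        )
        if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
            raise ValueError(f"empty margin for class {cls!r}")
        odds, p = stats.fisher_exact(tab, alternative="two-sided")
        n_bound = tab[0].sum()
        n_cls = tab[:, 0].sum()
        out[str(cls)] = ClassEnrichment(
            gene_class=str(cls),
            table=tab,
            odds_ratio=float(odds),
            pvalue=float(p),
            frac_bound_in_class=tab[0, 0] / n_bound if n_bound else np.nan,
            frac_class_bound=tab[0, 0] / n_cls if n_cls else np.nan,
        )
    return out
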