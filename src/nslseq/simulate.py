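"""Synthetic genome, promoter sequences, ChIP/input/nucleosome reads and
knockdown Pol II with known ground truth.

The generator emulates the signal structure of promoter-centric NSL-complex
ChIP-seq: NSL enrichment concentrated at the TSSs of constitutively
expressed (housekeeping) genes; Pol II with a promoter summit plus gene-body
coverage and a per-gene stalling ratio; knockdown Pol II whose per-gene loss
grows with DRE affinity and shrinks with motif 1 affinity; nucleosome maps
with a nucleosome-free region and phased +1/+2/+3 nucleosomes at bound
promoters; and promoter sequences carrying DRE / motif 1 / E-box versus
TATA / Inr / DPE motifs by gene class.

Everything is deterministic given the seed: each simulation stage draws from
its own child stream of the configured seed, so regenerating any one sample
is reproducible independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    GeneModel,
    GenomeLayout,
    IntervalSet,
    ReadSet,
    write_fasta,
    write_genes_bed12,
)
from .trap import CORE_PROMOTER_CONSENSI, IUPAC, pwm_from_consensus, trap_affinity

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SyntheticGenome",
    "generate_genome",
    "simulate_chip",
    "simulate_knockdown",
    "simulate_nucleosomes",
    "make_state_map",
    "write_dataset",
    "NSL_PROTEINS",
]

NSL_PROTEINS = ("NSL1", "MCRS2", "NSL3", "MBD-R2")

# stable child-stream ids per simulation stage
_STREAMS = {
    "genome": 1,
    "input": 10,
    "NSL1": 11,
    "MCRS2": 12,
    "NSL3": 13,
    "MBD-R2": 14,
    "polII": 15,
    "knockdown": 16,
    "nucleosomes": 17,
    "input2": 18,
    "knockdown_thin": 19,
}

PROMOTER_UP = 400  # promoter sequence spans [-400, +200) around the TSS
PROMOTER_DOWN = 200


@dataclass
class SynthConfig:
    """Stated world of the generator.

    Class fractions, binding probability, summit spread and motif emission
    probabilities mirror the housekeeping-promoter biology being emulated;
    read depths are scaled to desk size (a ~8 Mb toy genome) while keeping
    promoter signal-to-background ratios ChIP-seq-like.
    """

    seed: int
    n_chrom: int = 2
    chrom_length: int = 4_000_000
    n_genes: int = 1000
    class_fractions: dict = field(
        default_factory=lambda: {
            "constitutive": 0.45,
            "active_regulated": 0.30,
            "inactive": 0.25,
        }
    )
    gene_length_range: tuple[int, int] = (1500, 10_000)
    min_gap: int = 1000
    gc_content: float = 0.43
    # per-class motif emission probabilities
    motif_emission: dict = field(
        default_factory=lambda: {
            "constitutive": {"DRE": 0.6, "motif1": 0.4, "Ebox": 0.4},
            "active_regulated": {"TATA": 0.7, "Inr": 0.6, "DPE": 0.3},
            "inactive": {},
        }
    )
    nsl_bind_prob: float = 0.9
    per_protein_dropout: float = 0.05
    chip_summit_sd: float = 80.0
    background_rate: float = 0.02  # reads per bp
    read_length: int = 50
    nsl_intensity_mean: float = 200.0  # reads per bound promoter
    nsl_intensity_shape: float = 4.0
    polii_promoter_mean: float = 200.0
    polii_promoter_shape: float = 4.0
    stalling_log2_mean: float = 1.6
    stalling_log2_sd: float = 0.5
    # knockdown response: f = exp(-softplus(a_dre z_DRE - a_m1 z_M1 + eps))
    response_coefs: tuple[float, float, float] = (1.0, 1.0, 0.25)
    nonbound_thin: float = 0.95
    # nucleosome model
    nuc_background_rate: float = 0.02
    nuc_read_length: int = 150
    nfr_depletion: float = 0.2
    nuc_phase_centers: tuple[int, ...] = (135, 320, 505)
    nuc_phase_sd: float = 30.0
    nuc_reads_per_nucleosome: float = 25.0
    # positioning decays downstream: +1 strongest, as in well-organized arrays
    nuc_phase_decay: float = 0.75
    # expression model (log-normal, class shifted)
    expression_logmean: dict = field(
        default_factory=lambda: {"constitutive": 4.0, "active_regulated": 3.5}
    )
    expression_logsd: dict = field(
        default_factory=lambda: {"constitutive": 0.6, "active_regulated": 0.9}
    )

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        for cls, probs in self.motif_emission.items():
            for motif, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"emission probability {motif}={p} not in [0,1]")
        if not 0 <= self.nsl_bind_prob <= 1:
            raise ValueError("nsl_bind_prob must be in [0,1]")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stage]])


@dataclass
class GroundTruth:
    """The generator's record of what is true: the acceptance surface.

    ``table`` is indexed by gene_id with activity class, expression,
    per-protein true-bound flags, latent ChIP intensities, the stalling
    ratio, promoter DRE/motif-1 affinity scores and (after the knockdown
    simulation) the Pol II response factor f.  ``motifs`` records embedded
    motif instances as (motif, TSS-relative start).
    """

    table: pd.DataFrame
    motifs: dict[str, list[tuple[str, int]]]

    def bound_any(self) -> pd.Series:
        return self.table[[f"bound_{p}" for p in NSL_PROTEINS]].any(axis=1)

    def bound_all(self) -> pd.Series:
        return self.table[[f"bound_{p}" for p in NSL_PROTEINS]].all(axis=1)

    def true_core_set(self) -> list[str]:
        return list(self.table.index[self.bound_all()])

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["motifs"] = [
            ";".join(f"{m}@{pos}" for m, pos in self.motifs.get(g, []))
            for g in df.index
        ]
        df.to_csv(path, sep="\t")


@dataclass
class SyntheticGenome:
    layout: GenomeLayout
    genes: list[GeneModel]
    genome_seqs: dict[str, str]
    promoter_seqs: dict[str, str]  # gene-oriented, TSS at index PROMOTER_UP
    truth: GroundTruth
    config: SynthConfig

    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


def _sample_iupac(rng: np.random.Generator, consensus: str) -> str:
    return "".join(rng.choice(list(IUPAC[sym])) for sym in consensus.upper())


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=probs)


def generate_genome(config: SynthConfig) -> SyntheticGenome:
    """Toy genome with non-overlapping genes (>= ``min_gap`` bp apart),
    class labels, expression values, per-protein true-bound flags, latent
    ChIP intensities and class-specific promoter sequences."""
    rng = config.rng("genome")
    lo, hi = config.gene_length_range
    lengths = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=config.n_genes)
    ).astype(np.int64)

    # spread genes over chromosomes as evenly as possible
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chrom)]
    layout = GenomeLayout({c: config.chrom_length for c in chrom_names})
    per_chrom = np.full(config.n_chrom, config.n_genes // config.n_chrom)
    per_chrom[: config.n_genes % config.n_chrom] += 1

    genes: list[GeneModel] = []
    rows = []
    motifs: dict[str, list[tuple[str, int]]] = {}
    classes = rng.choice(
        list(config.class_fractions),
        size=config.n_genes,
        p=list(config.class_fractions.values()),
    )
    strands = rng.choice(["+", "-"], size=config.n_genes)

    genome = {c: _random_seq(rng, config.chrom_length, config.gc_content)
              for c in chrom_names}
    promoter_seqs: dict[str, str] = {}

    gi = 0
    for ci, chrom in enumerate(chrom_names):
        n_c = int(per_chrom[ci])
        lens_c = lengths[gi : gi + n_c]
        needed = int(lens_c.sum()) + (n_c + 1) * config.min_gap
        if needed > config.chrom_length:
            raise ValueError(
                f"genome too small: chromosome {chrom} needs {needed} bp for "
                f"{n_c} genes but has {config.chrom_length}; increase "
                "chrom_length or reduce n_genes / gene lengths"
            )
        leftover = config.chrom_length - needed
        extras = rng.dirichlet(np.ones(n_c + 1)) * leftover
        cursor = 0
        for k in range(n_c):
            cursor += config.min_gap + int(extras[k])
            start = cursor
            end = start + int(lens_c[k])
            cursor = end
            idx = gi + k
            cls = str(classes[idx])
            strand = str(strands[idx])
            if cls == "inactive":
                expr = 0.0
            else:
                expr = float(
                    np.exp(
                        rng.normal(
                            config.expression_logmean[cls],
                            config.expression_logsd[cls],
                        )
                    )
                )
            gene_id = f"g{idx:05d}"
            gene = GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                activity=cls,
                expression=expr,
            )
            genes.append(gene)

            # promoter sequence: gene-oriented [-400, +200) around the TSS
            prom = _random_seq(rng, PROMOTER_UP + PROMOTER_DOWN, config.gc_content)
            placed: list[tuple[int, int]] = []
            motifs[gene_id] = []
            for motif, p_emit in config.motif_emission.get(cls, {}).items():
                if rng.random() >= p_emit:
                    continue
                consensus = CORE_PROMOTER_CONSENSI[motif]
                w = len(consensus)
                rel = {"TATA": -30, "Inr": -2, "DPE": 28}.get(motif)
                for _attempt in range(20):
                    r = rel if rel is not None else int(rng.integers(-150, -w + 1))
                    a = PROMOTER_UP + r
                    if all(a + w <= s or a >= e for s, e in placed):
                        break
                else:
                    continue
                prom[a : a + w] = np.frombuffer(
                    _sample_iupac(rng, consensus).encode(), dtype="S1"
                )
                placed.append((a, a + w))
                motifs[gene_id].append((motif, r))
            prom_str = prom.tobytes().decode()
            promoter_seqs[gene_id] = prom_str

            # paste promoter into the genome (strand-aware)
            if strand == "+":
                a = gene.tss - PROMOTER_UP
                genome[chrom][a : a + len(prom)] = prom
            else:
                rc = prom_str.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                a = gene.tss - PROMOTER_DOWN + 1
                genome[chrom][a : a + len(prom)] = np.frombuffer(
                    rc.encode(), dtype="S1"
                )

            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "tss": gene.tss,
                    "activity": cls,
                    "expression": expr,
                }
            )
        gi += n_c

    table = pd.DataFrame(rows).set_index("gene_id")

    # true NSL binding: constitutive promoters with high probability, then
    # independent per-protein dropout
    constitutive = (table["activity"] == "constitutive").to_numpy()
    base_bound = constitutive & (rng.random(len(table)) < config.nsl_bind_prob)
    for p in NSL_PROTEINS:
        table[f"bound_{p}"] = base_bound & (
            rng.random(len(table)) >= config.per_protein_dropout
        )

    # latent ChIP intensities
    shape = config.nsl_intensity_shape
    table["nsl_intensity"] = rng.gamma(
        shape, config.nsl_intensity_mean / shape, size=len(table)
    )
    pshape = config.polii_promoter_shape
    table["polii_promoter"] = rng.gamma(
        pshape, config.polii_promoter_mean / pshape, size=len(table)
    )
    table["stalling_ratio"] = 2.0 ** rng.normal(
        config.stalling_log2_mean, config.stalling_log2_sd, size=len(table)
    )
    table["response_f"] = np.nan

    # true promoter affinities for the response motifs ([-200,+200) window)
    dre = pwm_from_consensus("DRE")
    m1 = pwm_from_consensus("motif1")
    a0 = PROMOTER_UP - 200
    b0 = PROMOTER_UP + 200
    table["dre_score"] = [
        trap_affinity(promoter_seqs[g][a0:b0], dre).score for g in table.index
    ]
    table["m1_score"] = [
        trap_affinity(promoter_seqs[g][a0:b0], m1).score for g in table.index
    ]

    genome_seqs = {c: v.tobytes().decode() for c, v in genome.items()}
    truth = GroundTruth(table=table, motifs=motifs)
    return SyntheticGenome(
        layout=layout,
        genes=genes,
        genome_seqs=genome_seqs,
        promoter_seqs=promoter_seqs,
        truth=truth,
        config=config,
    )


def _uniform_reads(rng, chrom, chrom_len, n, read_len) -> pd.DataFrame:
    starts = rng.integers(0, max(chrom_len - read_len, 1), size=n)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + read_len,
            "strand": rng.choice(["+", "-"], size=n),
        }
    )


def _summit_reads(rng, gene: GeneModel, chrom_len, n, sd, read_len) -> pd.DataFrame:
    centers = np.rint(rng.normal(gene.tss, sd, size=n)).astype(np.int64)
    starts = np.clip(centers - read_len // 2, 0, chrom_len - read_len)
    return pd.DataFrame(
        {
            "chrom": gene.chrom,
            "start": starts,
            "end": starts + read_len,
            "strand": rng.choice(["+", "-"], size=n),
        }
    )


def simulate_chip(
    config: SynthConfig,
    genome: SyntheticGenome,
    protein: str,
) -> ReadSet:
    """Simulate one ChIP (or input) sample.

    input: uniform Poisson background.  NSL proteins: background plus
    Gaussian summits (sd ``chip_summit_sd``) at the TSSs of that protein's
    true-bound genes with per-gene Gamma intensities.  polII: background
    plus a promoter summit and uniform gene-body coverage on active genes;
    the promoter:body density ratio is the recorded stalling ratio.
    """
    if protein not in _STREAMS:
        raise ValueError(f"unknown protein kind {protein!r}")
    rng = config.rng(protein)
    layout = genome.layout
    table = genome.truth.table
    frames = []
    for chrom, clen in layout.chrom_lengths.items():
        n_bg = rng.poisson(config.background_rate * clen)
        if n_bg:
            frames.append(_uniform_reads(rng, chrom, clen, n_bg, config.read_length))
    if protein in ("input", "input2"):
        return ReadSet.concat([ReadSet(f) for f in frames]) if frames else ReadSet.empty()

    by_id = genome.genes_by_id()
    if protein in NSL_PROTEINS:
        col = f"bound_{protein}"
        for gene_id in table.index[table[col]]:
            g = by_id[gene_id]
            clen = layout.chrom_lengths[g.chrom]
            n = rng.poisson(table.at[gene_id, "nsl_intensity"])
            if n:
                frames.append(
                    _summit_reads(
                        rng, g, clen, n, config.chip_summit_sd, config.read_length
                    )
                )
    elif protein == "polII":
        active = table.index[table["activity"] != "inactive"]
        for gene_id in active:
            g = by_id[gene_id]
            clen = layout.chrom_lengths[g.chrom]
            promoter_intensity = table.at[gene_id, "polii_promoter"]
            n_prom = rng.poisson(promoter_intensity)
            if n_prom:
                frames.append(
                    _summit_reads(
                        rng, g, clen, n_prom, config.chip_summit_sd, config.read_length
                    )
                )
            body_density = (promoter_intensity / 400.0) / table.at[
                gene_id, "stalling_ratio"
            ]
            n_body = rng.poisson(body_density * g.length)
            if n_body:
                starts = rng.integers(
                    g.start, max(g.end - config.read_length, g.start + 1), size=n_body
                )
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": g.chrom,
                            "start": starts,
                            "end": starts + config.read_length,
                            "strand": rng.choice(["+", "-"], size=n_body),
                        }
                    )
                )
    else:
        raise ValueError(f"unknown protein kind {protein!r}")
    return ReadSet.concat([ReadSet(f) for f in frames]) if frames else ReadSet.empty()


def _softplus(x):
    return np.logaddexp(0.0, x)


def compute_response_factors(config: SynthConfig, genome: SyntheticGenome) -> pd.Series:
    """Per-gene Pol II retention factor f in (0, 1].

    For true-bound genes f = exp(-softplus(a_DRE z_DRE - a_M1 z_M1 + eps))
    with z the promoter DRE / motif 1 affinity scores standardized across
    bound genes; non-bound genes get the small global thinning factor.
    Stored in the ground-truth table (column ``response_f``).
    """
    a_dre, a_m1, noise_sd = config.response_coefs
    if a_dre < 0 or a_m1 < 0 or noise_sd < 0:
        raise ValueError(
            "response coefficients must be nonnegative (sign convention fixed: "
            "DRE increases loss, motif 1 decreases it)"
        )
    rng = config.rng("knockdown")
    table = genome.truth.table
    bound = genome.truth.bound_any()
    f = pd.Series(config.nonbound_thin, index=table.index, name="response_f")

    def _z(col):
        v = table.loc[bound, col].to_numpy(float)
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    z_dre, z_m1 = _z("dre_score"), _z("m1_score")
    eps = rng.normal(0.0, noise_sd, size=int(bound.sum())) if noise_sd > 0 else 0.0
    raw = a_dre * z_dre - a_m1 * z_m1 + eps
    f.loc[bound] = np.exp(-_softplus(raw))
    table["response_f"] = f
    return f


def simulate_knockdown(
    config: SynthConfig,
    genome: SyntheticGenome,
    polii_control: ReadSet,
) -> ReadSet:
    """Thin the control Pol II reads gene by gene.

    Each read is assigned to the gene whose interval (expanded by 400 bp on
    both sides; gaps are >= 1 kb so this is unambiguous) contains its
    midpoint; reads of true-bound genes are kept with probability f, reads
    of other genes with the global ``nonbound_thin`` factor, background
    reads always.  Thinning promoter and body alike preserves the per-gene
    stalling ratio across conditions.
    """
    f = compute_response_factors(config, genome)
    rng = config.rng("knockdown_thin")
    keep_prob_by_gene = f.to_dict()

    # per-chromosome sorted expanded gene intervals
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in genome.layout.chrom_names:
        gs = [g for g in genome.genes if g.chrom == chrom]
        gs.sort(key=lambda g: g.start)
        starts = np.array([g.start - 400 for g in gs])
        ends = np.array([g.end + 400 for g in gs])
        by_chrom[chrom] = (starts, ends, [g.gene_id for g in gs])

    frame = polii_control.frame
    keep = np.ones(len(frame), dtype=bool)
    u = rng.random(len(frame))
    mid = ((frame["start"] + frame["end"]) // 2).to_numpy()
    chroms = frame["chrom"].to_numpy()
    for chrom, (starts, ends, ids) in by_chrom.items():
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        idx = np.searchsorted(starts, mid[sel], side="right") - 1
        inside = (idx >= 0) & (mid[sel] < ends[np.clip(idx, 0, None)])
        probs = np.ones(sel.size)
        gene_idx = idx[inside]
        probs[inside] = [keep_prob_by_gene[ids[j]] for j in gene_idx]
        keep[sel] = u[sel] < probs
    return ReadSet(frame[keep].reset_index(drop=True))


def simulate_nucleosomes(config: SynthConfig, genome: SyntheticGenome) -> ReadSet:
    """MNase-like nucleosome reads.

    Baseline fuzzy occupancy genome-wide; at true-bound promoters the
    region [-200, 0) upstream of the TSS is depleted to ``nfr_depletion``
    of baseline and phased nucleosome read clusters are added at the
    configured downstream dyad positions (+135/+320/+505, sd 30 bp).
    """
    rng = config.rng("nucleosomes")
    layout = genome.layout
    rl = config.nuc_read_length
    frames = []
    for chrom, clen in layout.chrom_lengths.items():
        n = rng.poisson(config.nuc_background_rate * clen)
        if n:
            frames.append(_uniform_reads(rng, chrom, clen, n, rl))
    reads = ReadSet.concat([ReadSet(f) for f in frames]) if frames else ReadSet.empty()

    bound = genome.truth.bound_any()
    bound_genes = [g for g in genome.genes if bound.get(g.gene_id, False)]

    # deplete the NFR: thin baseline reads whose midpoint falls in the
    # gene-oriented [-200, 0) window of a bound promoter
    frame = reads.frame
    mid = ((frame["start"] + frame["end"]) // 2).to_numpy()
    chroms = frame["chrom"].to_numpy()
    keep = np.ones(len(frame), dtype=bool)
    u = rng.random(len(frame))
    for chrom in layout.chrom_names:
        gs = [g for g in bound_genes if g.chrom == chrom]
        if not gs:
            continue
        nfr_lo = np.sort(
            np.array(
                [g.tss - 200 if g.strand == "+" else g.tss + 1 for g in gs]
            )
        )
        sel = np.flatnonzero(chroms == chrom)
        idx = np.searchsorted(nfr_lo, mid[sel], side="right") - 1
        inside = (idx >= 0) & (mid[sel] < nfr_lo[np.clip(idx, 0, None)] + 200)
        thin = inside & (u[sel] >= config.nfr_depletion)
        keep[sel[thin]] = False
    frames = [frame[keep].reset_index(drop=True)]

    # phased nucleosomes downstream of bound TSSs
    for g in bound_genes:
        clen = layout.chrom_lengths[g.chrom]
        sign = 1 if g.strand == "+" else -1
        for k, offset in enumerate(config.nuc_phase_centers):
            n = rng.poisson(config.nuc_reads_per_nucleosome * config.nuc_phase_decay**k)
            if not n:
                continue
            dyads = np.rint(
                rng.normal(g.tss + sign * offset, config.nuc_phase_sd, size=n)
            ).astype(np.int64)
            starts = np.clip(dyads - rl // 2, 0, clen - rl)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": g.chrom,
                        "start": starts,
                        "end": starts + rl,
                        "strand": rng.choice(["+", "-"], size=n),
                    }
                )
            )
    return ReadSet.concat([ReadSet(f) for f in frames])


def make_state_map(
    genome: SyntheticGenome, model: str = "colors"
) -> IntervalSet:
    """Synthetic chromatin-state partition keyed to gene classes.

    colors: bound promoters/bodies 'yellow', active non-bound 'red',
    everything else 'black'.  9-state: bound TSS regions state '1', active
    gene bodies '2', everything else '9'.
    """
    if model == "colors":
        lab_bound, lab_active, lab_bg = "yellow", "red", "black"
    elif model in ("states", "9state"):
        lab_bound, lab_active, lab_bg = "1", "2", "9"
    else:
        raise ValueError(f"unknown state-map model {model!r}")
    bound = genome.truth.bound_any()
    records = []
    for chrom, clen in genome.layout.chrom_lengths.items():
        gs = sorted(
            (g for g in genome.genes if g.chrom == chrom), key=lambda g: g.start
        )
        cursor = 0
        for g in gs:
            lo = max(g.start - 500, 0)
            hi = min(g.end + 500, clen)
            if lo > cursor:
                records.append((chrom, cursor, lo, lab_bg))
            if bound.get(g.gene_id, False):
                label = lab_bound
            elif g.activity != "inactive":
                label = lab_active
            else:
                label = lab_bg
            records.append((chrom, max(lo, cursor), hi, label))
            cursor = hi
        if cursor < clen:
            records.append((chrom, cursor, clen, lab_bg))
    return IntervalSet.from_records(records)


def write_dataset(
    genome: SyntheticGenome,
    outdir,
    reads: dict[str, ReadSet] | None = None,
) -> None:
    """Write the dataset in the plain-text exchange formats consumed by the
    I/O layer: genes.bed12, genome.fa, promoters.fa, expression.tsv,
    ground_truth.tsv, config.yaml and reads_<sample>.bed.gz."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genes_bed12(genome.genes, outdir / "genes.bed12")
    write_fasta(genome.genome_seqs, outdir / "genome.fa")
    write_fasta(genome.promoter_seqs, outdir / "promoters.fa")
    expr = genome.truth.table[["activity", "expression"]]
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    genome.truth.to_tsv(outdir / "ground_truth.tsv")
    cfg = asdict(genome.config)
    cfg["gene_length_range"] = list(cfg["gene_length_range"])
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    for name, rs in (reads or {}).items():
        rs.to_bed(outdir / f"reads_{name}.bed.gz")
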