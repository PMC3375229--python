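"""End-to-end orchestration: simulate (or load) data, build enrichment
tracks, call peaks and bound TSSs, quantify the knockdown response, score
motifs and profile chromatin — collecting every headline statistic in one
machine-readable summary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import chromatin, enrichment, polii, simulate, targets, trap
from .io import BinnedTrack, GenomeLayout, ReadSet, bin_reads
from .simulate import NSL_PROTEINS, SynthConfig, SyntheticGenome

__all__ = ["RunConfig", "AnalysisResult", "run_synthetic_analysis"]


@dataclass
class RunConfig:
    """All analysis parameters; defaults are the canonical settings
    (25 bp bins, 400 bp smoothing window, FDR 0.05, 40 bp summit regions,
    400 bp TSS windows, stalling filters: non-overlapping genes > 1,300 bp
    with 500 bp trims)."""

    seed: int = 1
    bin_size: int = 25
    smooth_window: int = 400
    fdr: float = 0.05
    grid_step: float = 0.01
    pseudocount: float = 1.0
    noise_model: str = "mirror"
    valley_frac: float = 0.5
    summit_halfwidth: int = 20
    tss_halfwidth: int = 200
    min_gene_length: int = 1300
    body_trim: int = 500
    input_adjust: str = "subtract"
    trap_motifs: tuple[str, ...] = tuple(trap.CORE_PROMOTER_CONSENSI)
    synth: SynthConfig | None = None

    def __post_init__(self):
        if self.synth is None:
            self.synth = SynthConfig(seed=self.seed)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class AnalysisResult:
    config: RunConfig
    genome: SyntheticGenome
    thresholds: dict[str, float]
    peaks: dict[str, list]
    bound_table: targets.BoundTable
    set_algebra: dict
    recovery: dict
    fc_tracks: dict[str, BinnedTrack]
    delta_promoter: pd.Series
    ctrl_promoter: pd.Series
    tertiles: pd.Series
    stalling_ctrl: list
    stalling_kd: list
    motif_enrichments: dict[str, trap.MotifEnrichment]
    tertile_assoc: dict[str, dict]
    occupancy: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _fc_pipeline(chip_reads, input_reads, layout, cfg: RunConfig):
    """Counts -> size factors -> log2FC -> 400 bp smoothing -> threshold."""
    chip = bin_reads(chip_reads, layout, cfg.bin_size)
    inp = bin_reads(input_reads, layout, cfg.bin_size)
    counts = np.column_stack([chip.values_concat(), inp.values_concat()])
    sf = enrichment.estimate_size_factors(counts)
    fc = enrichment.log2fc_track(chip, inp, sf, cfg.pseudocount)
    sm = enrichment.smooth_sliding(fc, cfg.smooth_window)
    thr = enrichment.empirical_fdr_threshold(
        sm.values_concat(), cfg.fdr, cfg.grid_step, cfg.noise_model
    )
    return chip, inp, sf, sm, thr


def run_synthetic_analysis(config: RunConfig | None = None) -> AnalysisResult:
    """Run the whole promoter-centric analysis on synthetic data.

    Simulates the genome and all samples from the configured seed, then:
    NSL enrichment tracks and empirical-FDR peak calls for the four NSL
    proteins; bound-TSS table, Venn partition and recovery against ground
    truth; Pol II control/knockdown tracks, delta Pol II, response tertiles
    and stalling indexes; TRAP motif enrichment and tertile association;
    nucleosome occupancy by expression quartile.
    """
    cfg = config or RunConfig()
    genome = simulate.generate_genome(cfg.synth)
    layout = genome.layout
    truth = genome.truth

    # --- NSL binding ------------------------------------------------------
    input_nsl = simulate.simulate_chip(cfg.synth, genome, "input")
    thresholds: dict[str, float] = {}
    peak_calls: dict[str, list] = {}
    fc_tracks: dict[str, BinnedTrack] = {}
    for protein in NSL_PROTEINS:
        reads = simulate.simulate_chip(cfg.synth, genome, protein)
        _, _, _, sm, thr = _fc_pipeline(reads, input_nsl, layout, cfg)
        thresholds[protein] = thr.threshold
        fc_tracks[protein] = sm
        peak_calls[protein] = enrichment.call_enriched_regions(
            sm, thr, cfg.valley_frac, cfg.summit_halfwidth
        )

    bound_table = targets.call_bound_tss(
        genome.genes, peak_calls, cfg.tss_halfwidth, cfg.summit_halfwidth
    )
    algebra = targets.bound_set_algebra(bound_table)

    pred_core = set(bound_table.core_set())
    true_core = set(truth.true_core_set())
    tp = len(pred_core & true_core)
    recovery = {
        "n_predicted_core": len(pred_core),
        "n_true_core": len(true_core),
        "precision": tp / len(pred_core) if pred_core else np.nan,
        "recall": tp / len(true_core) if true_core else np.nan,
    }

    # --- Pol II response --------------------------------------------------
    input_polii = simulate.simulate_chip(cfg.synth, genome, "input2")
    ctrl_reads = simulate.simulate_chip(cfg.synth, genome, "polII")
    kd_reads = simulate.simulate_knockdown(cfg.synth, genome, ctrl_reads)

    ctrl_counts, inp_counts, sf_ctrl, fc_ctrl, thr_ctrl = _fc_pipeline(
        ctrl_reads, input_polii, layout, cfg
    )
    kd_counts, _, sf_kd, fc_kd, thr_kd = _fc_pipeline(
        kd_reads, input_polii, layout, cfg
    )
    thresholds["polII_ctrl"] = thr_ctrl.threshold
    thresholds["polII_kd"] = thr_kd.threshold
    fc_tracks["polII_ctrl"] = fc_ctrl
    fc_tracks["polII_kd"] = fc_kd

    delta = polii.delta_track(fc_kd, fc_ctrl)
    width = 2 * cfg.tss_halfwidth
    delta_prom = polii.promoter_summary(delta, genome.genes, width)
    ctrl_prom = polii.promoter_summary(fc_ctrl, genome.genes, width)

    overlapping = polii.overlapping_gene_ids(genome.genes)
    eligible = [
        g.gene_id
        for g in genome.genes
        if g.gene_id not in overlapping
        and np.isfinite(ctrl_prom[g.gene_id])
        and ctrl_prom[g.gene_id] >= thr_ctrl.threshold
        and delta_prom[g.gene_id] < 0
    ]
    # response tertiles are formed within the bound and non-bound groups
    # separately so both groups populate all three strata
    bound_flags = bound_table.bound_any()
    elig_b = [g for g in eligible if bound_flags[g]]
    elig_n = [g for g in eligible if not bound_flags[g]]
    tertiles = pd.concat(
        [polii.delta_tertiles(delta_prom[ids]) for ids in (elig_b, elig_n) if len(ids) >= 3]
    )

    stalling_ctrl = polii.stalling_index(
        genome.genes, ctrl_counts, inp_counts, sf_ctrl, thr_ctrl.threshold,
        fc_track=fc_ctrl, promoter_halfwidth=cfg.tss_halfwidth,
        body_trim=cfg.body_trim, min_length=cfg.min_gene_length,
        adjust=cfg.input_adjust, pseudocount=cfg.pseudocount,
    )
    stalling_kd = polii.stalling_index(
        genome.genes, kd_counts, inp_counts, sf_kd, thr_kd.threshold,
        fc_track=fc_kd, promoter_halfwidth=cfg.tss_halfwidth,
        body_trim=cfg.body_trim, min_length=cfg.min_gene_length,
        adjust=cfg.input_adjust, pseudocount=cfg.pseudocount,
    )

    # --- TRAP motifs ------------------------------------------------------
    pwms = [trap.pwm_from_consensus(m) for m in cfg.trap_motifs]
    # full promoter window ([-200,+200)): on synthetic data the response
    # motifs are embedded anywhere upstream, so the promoter-wide window is
    # used for both enrichment and tertile association
    scores = trap.score_regions(
        genome.promoter_seqs, pwms, simulate.PROMOTER_UP,
        trap.WindowSpec.enrichment_mode(),
    )
    score_mat = scores.pivot(index="region_id", columns="motif_id", values="score")
    bound_called = bound_table.bound_any()
    expressed = truth.table["activity"] != "inactive"
    motif_enrichments = {}
    for m in cfg.trap_motifs:
        s = score_mat[m]
        grp_b = s[bound_called.reindex(s.index, fill_value=False)]
        grp_n = s[(~bound_called.reindex(s.index, fill_value=False)) & expressed]
        motif_enrichments[m] = trap.motif_enrichment(
            grp_b.dropna(), grp_n.dropna(), motif_id=m
        )

    tertile_assoc = {}
    for m in ("DRE", "motif1", "Ebox", "TATA"):
        tertile_assoc[m] = trap.tertile_density(
            score_mat[m], tertiles, bound_called, motif_id=m
        )

    # --- nucleosomes ------------------------------------------------------
    nuc_reads = simulate.simulate_nucleosomes(cfg.synth, genome)
    occ_records = chromatin.occupancy_at_tss(nuc_reads, genome.genes)
    occupancy = pd.DataFrame(
        [(r.gene_id, r.occ_upstream, r.occ_downstream) for r in occ_records],
        columns=["gene_id", "occ_upstream", "occ_downstream"],
    ).set_index("gene_id")
    expr = truth.table.loc[expressed, "expression"]
    occupancy["quartile"] = chromatin.quartile_stratify(expr).reindex(occupancy.index)
    occupancy["bound"] = bound_called.reindex(occupancy.index, fill_value=False)

    # --- summary ----------------------------------------------------------
    si_ctrl = np.array([r.si for r in stalling_ctrl if r.passed_filters])
    si_kd = np.array([r.si for r in stalling_kd if r.passed_filters])
    si_test = (
        polii.compare_groups(si_ctrl, si_kd)
        if len(si_ctrl) and len(si_kd)
        else None
    )
    b_mask = bound_called.reindex(delta_prom.index, fill_value=False)
    e_mask = expressed.reindex(delta_prom.index, fill_value=False)
    delta_b = delta_prom[b_mask].dropna()
    delta_n = delta_prom[~b_mask & e_mask].dropna()
    delta_test = polii.compare_groups(delta_b, delta_n)
    fvals = truth.table.loc[truth.bound_any(), "response_f"]
    common = delta_prom.reindex(fvals.index).dropna()
    rho = (
        sps.spearmanr(common, np.log(fvals[common.index]))[0]
        if len(common) > 2
        else np.nan
    )

    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_genes": len(genome.genes),
        "thresholds": thresholds,
        "bound_counts": algebra["per_protein"],
        "union_bound": algebra["union"],
        "core_set_size": algebra["core"],
        "recovery": recovery,
        "delta_polii_median_bound": float(delta_b.median()),
        "delta_polii_median_nonbound": float(delta_n.median()),
        "delta_polii_p": delta_test.pvalue,
        "delta_spearman_vs_true_log_f": float(rho),
        "stalling_median_ctrl": float(np.median(si_ctrl)) if len(si_ctrl) else None,
        "stalling_median_kd": float(np.median(si_kd)) if len(si_kd) else None,
        "stalling_p": si_test.pvalue if si_test else None,
        "motif_fold_changes": {
            m: e.fold_change for m, e in motif_enrichments.items()
        },
        "motif_p": {m: e.test.pvalue for m, e in motif_enrichments.items()},
        "nfr_ratio_by_quartile": _nfr_ratios(occupancy),
    }
    return AnalysisResult(
        config=cfg,
        genome=genome,
        thresholds=thresholds,
        peaks=peak_calls,
        bound_table=bound_table,
        set_algebra=algebra,
        recovery=recovery,
        fc_tracks=fc_tracks,
        delta_promoter=delta_prom,
        ctrl_promoter=ctrl_prom,
        tertiles=tertiles,
        stalling_ctrl=stalling_ctrl,
        stalling_kd=stalling_kd,
        motif_enrichments=motif_enrichments,
        tertile_assoc=tertile_assoc,
        occupancy=occupancy,
        summary=summary,
    )


def _nfr_ratios(occupancy: pd.DataFrame) -> dict:
    """Upstream/downstream occupancy ratio of bound genes per expression
    quartile (summed counts)."""
    out = {}
    sub = occupancy[occupancy["bound"] & occupancy["quartile"].notna()]
    for q, grp in sub.groupby("quartile"):
        down = grp["occ_downstream"].sum()
        out[int(q)] = float(grp["occ_upstream"].sum() / down) if down else np.nan
    return out


def write_outputs(result: AnalysisResult, outdir) -> None:
    """Write tables, the summary JSON and a parameter log to a run
    directory; every table carries the config hash in its header."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = result.config.config_hash()

    def _tsv(df: pd.DataFrame, name: str):
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(f"# config_hash={h}\n")
            df.to_csv(fh, sep="\t")

    _tsv(result.bound_table.frame, "bound_table.tsv")
    venn = pd.DataFrame(
        [("+".join(sorted(k)), v) for k, v in result.set_algebra["venn"].items()],
        columns=["proteins", "count"],
    ).set_index("proteins")
    _tsv(venn, "venn_partition.tsv")
    per_gene = pd.DataFrame(
        {
            "delta_promoter": result.delta_promoter,
            "ctrl_promoter": result.ctrl_promoter,
            "stratum": result.tertiles,
        }
    )
    stall = pd.DataFrame(
        [
            (r.gene_id, r.r_tss, r.r_body, r.si, r.reason)
            for r in result.stalling_ctrl
        ],
        columns=["gene_id", "r_tss", "r_body", "si", "filter_reason"],
    ).set_index("gene_id")
    _tsv(per_gene.join(stall, how="left"), "polii_response.tsv")
    _tsv(result.occupancy, "nucleosome_occupancy.tsv")
    enr = pd.DataFrame(
        [
            (m, e.fold_change, e.test.pvalue, e.stars, e.on_affinity_scale)
            for m, e in result.motif_enrichments.items()
        ],
        columns=["motif", "log_median_fold_change", "pvalue", "stars", "affinity_scale"],
    ).set_index("motif")
    _tsv(enr, "motif_enrichment.tsv")
    for protein, plist in result.peaks.items():
        from .io import write_regions
        from .enrichment import peaks_to_intervals

        write_regions(peaks_to_intervals(plist), outdir / f"peaks_{protein}.bed")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
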