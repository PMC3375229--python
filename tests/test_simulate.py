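"""Generator contracts: determinism, class structure, signal construction."""

import numpy as np
import pytest
from scipy import stats

from nslseq.io import bin_reads, read_genes_bed12, read_fasta
from nslseq.simulate import (
    NSL_PROTEINS,
    SynthConfig,
    compute_response_factors,
    generate_genome,
    simulate_chip,
    simulate_knockdown,
    simulate_nucleosomes,
    write_dataset,
)

SMALL = dict(n_genes=150, chrom_length=1_200_000)


class TestGenerateGenome:
    def test_seeded_determinism_byte_identical(self, tmp_path):
        outs = []
        for sub in ("a", "b"):
            cfg = SynthConfig(seed=7, n_genes=100, chrom_length=900_000)
            genome = generate_genome(cfg)
            d = tmp_path / sub
            write_dataset(genome, d)
            outs.append(d)
        for name in ("genes.bed12", "promoters.fa", "ground_truth.tsv", "config.yaml"):
            assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()

    def test_all_constitutive_when_fraction_one(self):
        cfg = SynthConfig(
            seed=3,
            n_genes=50,
            chrom_length=600_000,
            class_fractions={"constitutive": 1.0, "active_regulated": 0.0, "inactive": 0.0},
        )
        genome = generate_genome(cfg)
        assert (genome.truth.table["activity"] == "constitutive").all()

    def test_class_fraction_within_binomial_bound(self):
        cfg = SynthConfig(seed=11)
        genome = generate_genome(cfg)
        n = cfg.n_genes
        frac = (genome.truth.table["activity"] == "constitutive").mean()
        sd = np.sqrt(0.45 * 0.55 / n)
        assert abs(frac - 0.45) <= 3 * sd

    def test_genes_non_overlapping_with_gaps(self, small_genome):
        by_chrom = {}
        for g in small_genome.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs.sort(key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                assert b.start - a.end >= 1000

    def test_too_small_genome_raises_helpful_error(self):
        with pytest.raises(ValueError, match="chrom_length"):
            generate_genome(SynthConfig(seed=1, n_genes=500, chrom_length=400_000))

    def test_promoters_carry_class_motifs(self, small_genome):
        truth = small_genome.truth
        classes = truth.table["activity"]
        for gid, motifs in truth.motifs.items():
            names = {m for m, _ in motifs}
            if classes[gid] == "constitutive":
                assert names <= {"DRE", "motif1", "Ebox"}
            elif classes[gid] == "active_regulated":
                assert names <= {"TATA", "Inr", "DPE"}
            else:
                assert names == set()

    def test_embedded_motif_visible_in_promoter_sequence(self, small_genome):
        # DRE consensus WATCGATW: check the invariant core ATCGAT
        truth = small_genome.truth
        found = 0
        for gid, motifs in truth.motifs.items():
            for m, rel in motifs:
                if m == "DRE":
                    seq = small_genome.promoter_seqs[gid][400 + rel : 400 + rel + 8]
                    assert seq[1:7] == "ATCGAT"
                    found += 1
        assert found > 10

    def test_promoter_matches_genome_sequence(self, small_genome):
        by_id = small_genome.genes_by_id()
        for gid in list(small_genome.promoter_seqs)[:20]:
            g = by_id[gid]
            chrom_seq = small_genome.genome_seqs[g.chrom]
            prom = small_genome.promoter_seqs[gid]
            if g.strand == "+":
                assert chrom_seq[g.tss - 400 : g.tss + 200] == prom
            else:
                rc = prom.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                assert chrom_seq[g.tss - 199 : g.tss + 401] == rc

    def test_bound_genes_are_constitutive(self, small_genome):
        truth = small_genome.truth
        bound = truth.bound_any()
        assert (truth.table.loc[bound, "activity"] == "constitutive").all()


class TestSimulateChip:
    def test_zero_background_and_no_bound_genes_empty(self):
        cfg = SynthConfig(
            seed=5, n_genes=30, chrom_length=400_000,
            background_rate=0.0, nsl_bind_prob=0.0,
        )
        genome = generate_genome(cfg)
        assert len(simulate_chip(cfg, genome, "NSL1")) == 0

    def test_read_count_conserves_rates(self, small_genome):
        cfg = small_genome.config
        reads = simulate_chip(cfg, small_genome, "NSL1")
        truth = small_genome.truth
        expected = (
            cfg.background_rate * cfg.n_chrom * cfg.chrom_length
            + truth.table.loc[truth.table["bound_NSL1"], "nsl_intensity"].sum()
        )
        assert abs(len(reads) - expected) <= 3 * np.sqrt(expected)

    def test_tss_enrichment_of_bound_genes(self, small_genome):
        cfg = small_genome.config
        reads = simulate_chip(cfg, small_genome, "NSL1")
        track = bin_reads(reads, small_genome.layout, 25)
        truth = small_genome.truth
        by_id = small_genome.genes_by_id()
        bg_per_bin = cfg.background_rate * 25
        depths = []
        for gid in truth.table.index[truth.table["bound_NSL1"]]:
            g = by_id[gid]
            lo, hi = (g.tss - 200) // 25, (g.tss + 200) // 25
            depths.append(track.data[g.chrom][lo:hi].mean())
        assert np.mean(depths) > 2 * bg_per_bin

    def test_unknown_protein_kind_is_error(self, small_genome):
        with pytest.raises(ValueError, match="unknown protein"):
            simulate_chip(small_genome.config, small_genome, "H3K4me3")

    def test_input_has_no_promoter_structure(self, small_genome):
        cfg = small_genome.config
        reads = simulate_chip(cfg, small_genome, "input")
        track = bin_reads(reads, small_genome.layout, 25)
        truth = small_genome.truth
        by_id = small_genome.genes_by_id()
        prom, genome_mean = [], track.values_concat().mean()
        for gid in truth.table.index[truth.bound_any()]:
            g = by_id[gid]
            lo, hi = (g.tss - 200) // 25, (g.tss + 200) // 25
            prom.append(track.data[g.chrom][lo:hi].mean())
        assert abs(np.mean(prom) - genome_mean) < 0.3 * genome_mean


class TestKnockdown:
    def test_zero_coefficients_make_flat_response(self):
        cfg = SynthConfig(seed=5, **SMALL, response_coefs=(0.0, 0.0, 0.0))
        genome = generate_genome(cfg)
        f = compute_response_factors(cfg, genome)
        bound = genome.truth.bound_any()
        assert np.allclose(f[bound], 0.5)  # exp(-softplus(0)) = 1/2
        assert np.allclose(f[~bound], cfg.nonbound_thin)

    def test_max_dre_without_motif1_has_smallest_f(self):
        cfg = SynthConfig(seed=5, **SMALL, response_coefs=(1.0, 1.0, 0.0))
        genome = generate_genome(cfg)
        f = compute_response_factors(cfg, genome)
        t = genome.truth.table
        bound = genome.truth.bound_any()
        score = t["dre_score"] - t["m1_score"]  # z-standardization is monotone
        top = score[bound].idxmax()
        assert f[bound].idxmin() == top or np.isclose(f[bound].min(), f[top])

    def test_negative_coefficients_rejected(self):
        cfg = SynthConfig(seed=5, **SMALL, response_coefs=(-1.0, 1.0, 0.1))
        genome = generate_genome(cfg)
        with pytest.raises(ValueError, match="nonnegative"):
            compute_response_factors(cfg, genome)

    def test_f_anticorrelates_with_dre_affinity(self, small_genome):
        cfg = small_genome.config
        f = compute_response_factors(cfg, small_genome)
        truth = small_genome.truth
        bound = truth.bound_any()
        rho = stats.spearmanr(
            f[bound], truth.table.loc[bound, "dre_score"]
        ).statistic
        assert rho < 0

    def test_thinning_reduces_bound_promoter_reads_by_f(self, small_genome):
        cfg = small_genome.config
        ctrl = simulate_chip(cfg, small_genome, "polII")
        kd = simulate_knockdown(cfg, small_genome, ctrl)
        assert len(kd) < len(ctrl)
        truth = small_genome.truth
        by_id = small_genome.genes_by_id()
        t_ctrl = bin_reads(ctrl, small_genome.layout, 25)
        t_kd = bin_reads(kd, small_genome.layout, 25)
        bound_ids = truth.table.index[truth.bound_any()]
        ratios, fs = [], []
        for gid in bound_ids:
            g = by_id[gid]
            lo, hi = (g.tss - 200) // 25, (g.tss + 200) // 25
            c = t_ctrl.data[g.chrom][lo:hi].sum()
            k = t_kd.data[g.chrom][lo:hi].sum()
            if c >= 50:
                ratios.append(k / c)
                fs.append(truth.table.at[gid, "response_f"])
        rho = stats.spearmanr(ratios, fs).statistic
        assert rho > 0.8


class TestNucleosomes:
    def test_nfr_depleted_at_bound_promoters(self, small_genome):
        from nslseq.chromatin import occupancy_at_tss

        cfg = small_genome.config
        reads = simulate_nucleosomes(cfg, small_genome)
        truth = small_genome.truth
        bound = truth.bound_any()
        genes_b = [g for g in small_genome.genes if bound[g.gene_id]]
        recs = occupancy_at_tss(reads, genes_b)
        up = sum(r.occ_upstream for r in recs)
        down = sum(r.occ_downstream for r in recs)
        assert up < 0.5 * down

    def test_depletion_factor_one_is_null(self):
        from nslseq.chromatin import occupancy_at_tss
        from nslseq.polii import compare_groups

        cfg = SynthConfig(seed=9, **SMALL, nfr_depletion=1.0,
                          nuc_reads_per_nucleosome=0.0)
        genome = generate_genome(cfg)
        reads = simulate_nucleosomes(cfg, genome)
        bound = genome.truth.bound_any()
        recs_b = occupancy_at_tss(reads, [g for g in genome.genes if bound[g.gene_id]])
        recs_n = occupancy_at_tss(reads, [g for g in genome.genes if not bound[g.gene_id]])
        res = compare_groups(
            [r.occ_upstream for r in recs_b], [r.occ_upstream for r in recs_n]
        )
        assert res.pvalue > 0.01

    def test_seeded_determinism(self, small_genome):
        cfg = small_genome.config
        a = simulate_nucleosomes(cfg, small_genome)
        b = simulate_nucleosomes(cfg, small_genome)
        assert a.frame.equals(b.frame)


class TestDatasetRoundtrip:
    def test_written_dataset_parses_back(self, tmp_path, small_genome):
        cfg = small_genome.config
        reads = {"input": simulate_chip(cfg, small_genome, "input")}
        write_dataset(small_genome, tmp_path, reads)
        genes = read_genes_bed12(tmp_path / "genes.bed12")
        assert len(genes) == len(small_genome.genes)
        proms = read_fasta(tmp_path / "promoters.fa")
        assert proms == small_genome.promoter_seqs
        from nslseq.io import ReadSet

        back = ReadSet.from_bed(tmp_path / "reads_input.bed.gz")
        assert len(back) == len(reads["input"])
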