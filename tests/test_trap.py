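"""TRAP affinity scoring against exhaustive per-site oracles."""

import numpy as np
import pandas as pd
import pytest

from nslseq.trap import (
    CORE_PROMOTER_CONSENSI,
    PWMModel,
    WindowSpec,
    motif_enrichment,
    pwm_from_consensus,
    read_pwm,
    revcomp,
    score_regions,
    significance_stars,
    sliding_scores,
    tertile_density,
    trap_affinity,
)

BASES = "ACGT"


def brute_force_affinity(seq: str, pwm: PWMModel) -> float:
    """Independent oracle: explicit per-site occupancy sum on both strands."""
    total = 0.0
    for s in (seq.upper(), revcomp(seq)):
        for i in range(len(s) - pwm.width + 1):
            site = s[i : i + pwm.width]
            if "N" in site:
                continue
            e = 0.0
            for j, base in enumerate(site):
                col = pwm.matrix[:, j]
                e += np.log(col.max() / col[BASES.index(base)]) / pwm.lam
            x = pwm.r0 * np.exp(-e)
            total += x / (1.0 + x)
    return total


def random_pwm(rng, width=None, motif_id="m"):
    w = width or int(rng.integers(4, 13))
    m = rng.dirichlet(np.ones(4) * 0.7, size=w).T
    return PWMModel(motif_id=motif_id, matrix=m)


def random_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


class TestTrapAffinity:
    def test_width_one_closed_form(self):
        pwm = PWMModel("w1", np.array([[0.97], [0.01], [0.01], [0.01]]))
        res = trap_affinity("A", pwm)
        # zero-mismatch site on the forward strand plus the T-site on the
        # reverse complement, each with occupancy R0 e^-E / (1 + R0 e^-E)
        r0 = pwm.r0
        e_fwd = 0.0
        col = pwm.matrix[:, 0]
        e_rev = np.log(col.max() / col[3]) / pwm.lam
        expected = r0 / (1 + r0) + (r0 * np.exp(-e_rev)) / (1 + r0 * np.exp(-e_rev))
        assert np.isclose(res.affinity, expected, rtol=1e-12)

    def test_matches_exhaustive_oracle_small(self, rng):
        seq = random_seq(rng, 12)
        pwm = random_pwm(rng, width=4)
        res = trap_affinity(seq, pwm)
        assert np.isclose(res.affinity, brute_force_affinity(seq, pwm), rtol=1e-10)

    def test_oracle_equivalence_many_random_pairs(self, rng):
        for _ in range(50):
            seq = random_seq(rng, int(rng.integers(15, 80)))
            pwm = random_pwm(rng)
            got = trap_affinity(seq, pwm).affinity
            want = brute_force_affinity(seq, pwm)
            assert np.isclose(got, want, rtol=1e-10)

    def test_reverse_complement_symmetry_exact(self, rng):
        for _ in range(20):
            seq = random_seq(rng, 60)
            pwm = random_pwm(rng)
            assert trap_affinity(seq, pwm).affinity == pytest.approx(
                trap_affinity(revcomp(seq), pwm).affinity, rel=1e-12
            )

    def test_appending_bases_never_decreases_affinity(self, rng):
        pwm = random_pwm(rng, width=5)
        seq = random_seq(rng, 30)
        a0 = trap_affinity(seq, pwm).affinity
        a1 = trap_affinity(seq + "G", pwm).affinity
        assert a1 >= a0

    def test_n_positions_skipped(self, rng):
        pwm = random_pwm(rng, width=4)
        assert trap_affinity("NNNN", pwm).affinity == 0.0
        mixed = trap_affinity("ACGTNACGT", pwm).affinity
        left = brute_force_affinity("ACGTNACGT", pwm)
        assert np.isclose(mixed, left, rtol=1e-10)

    def test_too_short_sequence_is_error(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            trap_affinity("AC", random_pwm(rng, width=6))

    def test_renormalization_invariance(self, rng):
        m = rng.dirichlet(np.ones(4), size=6).T
        a = PWMModel("a", m)
        b = PWMModel("b", m * 7.0)  # columns rescaled; normalized on load
        seq = random_seq(rng, 40)
        assert np.isclose(
            trap_affinity(seq, a).affinity, trap_affinity(seq, b).affinity, rtol=1e-12
        )


class TestScoreRegions:
    def test_all_n_window_is_missing(self):
        pwm = pwm_from_consensus("DRE")
        df = score_regions({"r1": "N" * 600}, [pwm], tss_offset=400)
        assert df["score"].isna().all()

    def test_embedded_consensus_beats_shuffled(self, rng):
        pwm = pwm_from_consensus("DRE")
        bg = random_seq(rng, 600)
        embedded = bg[:300] + "AATCGATA" + bg[308:]
        shuffled = bg[:300] + "ATGAATCA" + bg[308:]
        spec = WindowSpec(default=(-200, 200))
        scores = score_regions(
            {"emb": embedded, "shuf": shuffled}, [pwm], 400, spec
        ).set_index("region_id")["score"]
        assert scores["emb"] > scores["shuf"]

    def test_window_outside_sequence_is_missing(self):
        pwm = pwm_from_consensus("Ebox")
        df = score_regions({"r": "ACGT" * 10}, [pwm], tss_offset=5,
                           spec=WindowSpec(default=(-50, 50)))
        assert df["score"].isna().all()

    def test_sliding_maximum_localizes_embedded_motif(self, small_genome):
        """The 40 bp sliding-window maximum falls within 20 bp of the
        embedded DRE for >= 90% of promoters carrying one."""
        pwm = pwm_from_consensus("DRE")
        truth = small_genome.truth
        hits = total = 0
        for gid, motifs in truth.motifs.items():
            dre = [pos for m, pos in motifs if m == "DRE"]
            if not dre:
                continue
            total += 1
            seq = small_genome.promoter_seqs[gid]
            df = sliding_scores(seq, pwm, window=40, step=5)
            best = df.loc[df["affinity"].idxmax()]
            center = (best["window_start"] + best["window_end"]) / 2 - 400
            motif_center = dre[0] + 4
            if abs(center - motif_center) <= 20:
                hits += 1
        assert total > 20
        assert hits / total >= 0.9


class TestMotifEnrichment:
    def test_identical_groups_fold_zero_p_one(self):
        s = pd.Series(np.full(20, 2.0))
        res = motif_enrichment(s, s, "m")
        assert res.fold_change == 0.0
        assert res.test.pvalue == 1.0

    def test_affinity_ratio_arithmetic(self):
        # median scores positive: fold change = ln(med_b / med_n)
        b = pd.Series([2.0, 2.0, 2.0])
        n = pd.Series([1.0, 1.0, 1.0])
        assert np.isclose(motif_enrichment(b, n).fold_change, np.log(2.0))

    def test_nonpositive_median_switches_to_affinity_scale(self):
        b = pd.Series([-1.0, -1.0])
        n = pd.Series([-2.0, -2.0])
        res = motif_enrichment(b, n)
        assert res.on_affinity_scale
        assert np.isclose(res.fold_change, np.log(np.exp(-1) / np.exp(-2)))

    def test_star_coding(self):
        assert significance_stars(1e-5) == "****"
        assert significance_stars(5e-4) == "***"
        assert significance_stars(5e-3) == "**"
        assert significance_stars(0.2) == "*"
        assert significance_stars(0.7) == "n.s."

    def test_synthetic_directions(self, default_run):
        enr = default_run.motif_enrichments
        for motif in ("DRE", "motif1", "Ebox"):
            assert enr[motif].fold_change > 0
            assert enr[motif].test.pvalue < 0.01
        assert enr["TATA"].fold_change < 0


class TestTertileDensity:
    def test_single_gene_strata_summary_is_difference(self):
        scores = pd.Series({"a": 5.0, "b": 3.0, "c": 1.0, "d": 4.0, "e": 2.0, "f": 0.0})
        strata = pd.Series({"a": 1, "b": 2, "c": 3, "d": 1, "e": 2, "f": 3})
        bound = pd.Series({"a": True, "b": True, "c": True,
                           "d": False, "e": False, "f": False})
        res = tertile_density(scores, strata, bound)
        assert res["bound"].summary == 5.0 - 1.0
        assert res["nonbound"].summary == 4.0 - 0.0

    def test_permuted_labels_show_no_association(self, rng):
        n = 300
        scores = pd.Series(rng.normal(size=n), index=range(n))
        strata = pd.Series(rng.integers(1, 4, size=n), index=range(n))
        bound = pd.Series(rng.random(n) < 0.5, index=range(n))
        res = tertile_density(scores, strata, bound)
        for grp in res.values():
            assert abs(grp.summary) < 1.0
            assert grp.test.pvalue > 1e-3

    def test_empty_stratum_is_error(self):
        scores = pd.Series({"a": 1.0, "b": 2.0})
        strata = pd.Series({"a": 1, "b": 2})
        bound = pd.Series({"a": True, "b": True})
        with pytest.raises(ValueError, match="empty stratum"):
            tertile_density(scores, strata, bound)


class TestPWMIO:
    def test_plain_matrix_roundtrip(self, tmp_path, rng):
        m = rng.dirichlet(np.ones(4), size=5).T
        path = tmp_path / "m.pwm"
        path.write_text(
            "\n".join(
                "\t".join(f"{x:.6f}" for x in m[i]) for i in range(4)
            )
        )
        pwm = read_pwm(path, motif_id="x")
        assert pwm.width == 5
        seq = "ACGTACGTAC"
        direct = PWMModel("x", m)
        assert np.isclose(
            trap_affinity(seq, pwm).affinity, trap_affinity(seq, direct).affinity
        )

    def test_jaspar_counts_normalized(self, tmp_path):
        path = tmp_path / "j.pfm"
        path.write_text(
            ">M1\nA [ 10 0 ]\nC [ 0 10 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        )
        pwm = read_pwm(path)
        assert pwm.motif_id == "M1"
        assert np.isclose(pwm.matrix.sum(axis=0), 1.0).all()
        assert pwm.matrix[0, 0] > 0.9

    def test_consensus_pwm_prefers_consensus_base(self):
        pwm = pwm_from_consensus("Ebox")  # CAGCTG
        assert np.argmax(pwm.matrix[:, 0]) == 1  # C
        assert pwm.width == 6
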