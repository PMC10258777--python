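import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from glycomhc.hla_deconv import (CORE, DOWNSTREAM, TRASH, UPSTREAM,
                                 AlleleAssignment, annotate_glyco_positions,
                                 assign_alleles, deconvolve_motifs,
                                 fisher_exact_two_sided, gene_group,
                                 load_rank_table, motif_conservation_test,
                                 relative_glyco_position, summarize_positions)
from glycomhc.synthetic import (generate_motif_peptides, generate_rank_table,
                                make_motif_pwm)


def rank_frame(rows):
    return pd.DataFrame(rows, columns=["peptide", "allele", "rank",
                                       "core_offset"])


class TestAssignAlleles:
    def test_lowest_rank_wins(self):
        table = rank_frame([("AAAAKAAAAKAAA", "DRB1*12:01", 3.2, 1),
                            ("AAAAKAAAAKAAA", "DRB3*02:02", 15.0, 2)])
        [a] = assign_alleles(["AAAAKAAAAKAAA"], table)
        assert a.allele == "DRB1*12:01" and a.core_offset == 1

    def test_all_above_threshold_is_trash(self):
        table = rank_frame([("AAAAKAAAAKAAA", "DRB1*12:01", 25.0, np.nan),
                            ("AAAAKAAAAKAAA", "DRB3*02:02", 40.0, np.nan)])
        [a] = assign_alleles(["AAAAKAAAAKAAA"], table)
        assert a.allele == TRASH

    def test_boundary_rank_inclusive(self):
        table = rank_frame([("AAAAKAAAAKAAA", "DQB1*03:01", 20.0, 0)])
        [a] = assign_alleles(["AAAAKAAAAKAAA"], table)
        assert a.allele == "DQB1*03:01"

    def test_missing_peptide_raises(self):
        table = rank_frame([("AAAAKAAAAKAAA", "DRB1*12:01", 3.0, 0)])
        with pytest.raises(ValueError, match="absent"):
            assign_alleles(["MISSINGPEPTIDE"], table)

    def test_tie_goes_to_lexicographic_first(self):
        table = rank_frame([("AAAAKAAAAKAAA", "DRB9*01:01", 5.0, 0),
                            ("AAAAKAAAAKAAA", "DRB1*01:01", 5.0, 0)])
        [a] = assign_alleles(["AAAAKAAAAKAAA"], table)
        assert a.allele == "DRB1*01:01"

    def test_pure_function(self):
        table = rank_frame([("AAAAKAAAAKAAA", "DRB1*12:01", 3.0, 1)])
        a1 = assign_alleles(["AAAAKAAAAKAAA"], table)
        a2 = assign_alleles(["AAAAKAAAAKAAA"], table)
        assert a1 == a2

    def test_rank_table_validation(self, tmp_path):
        p = tmp_path / "ranks.tsv"
        p.write_text("peptide\tallele\trank\nPEP\tDRB1*01:01\t120\n")
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            load_rank_table(p)


class TestRelativePosition:
    @pytest.mark.parametrize("site,offset,expected_p,expected_cat", [
        (12, 3, 9, DOWNSTREAM),
        (11, 3, 8, CORE),        # the P8 hotspot
        (1, 3, -2, UPSTREAM),
        (3, 3, 0, CORE),
        (0, 0, 0, CORE),
    ])
    def test_examples(self, site, offset, expected_p, expected_cat):
        p, cat = relative_glyco_position(site, offset, peptide_length=25)
        assert (p, cat) == (expected_p, expected_cat)

    def test_site_outside_peptide_rejected(self):
        with pytest.raises(ValueError):
            relative_glyco_position(30, 3, peptide_length=20)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(-5, 5))
    def test_translation_equivariance(self, site, offset, shift):
        p1, _ = relative_glyco_position(site, offset)
        p2, _ = relative_glyco_position(site + abs(shift), offset + abs(shift))
        assert p1 == p2


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact_two_sided([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_hand_enumerated(self):
        # margins (2,2)x(2,2): P(X=2)=1/6, P(X=0)=1/6 -> two-sided 1/3
        assert fisher_exact_two_sided([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided([[1, -1], [0, 2]])

    def test_zero_table(self):
        assert fisher_exact_two_sided([[0, 0], [0, 0]]) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            table = rng.integers(0, 30, size=(2, 2))
            mine = fisher_exact_two_sided(table.tolist())
            ref = fisher_exact(table)[1]
            assert mine == pytest.approx(ref, abs=1e-9)


class TestMotifConservation:
    def _assignments(self, allele_flags):
        return [AlleleAssignment(f"PEPTIDE{i:03d}XXXX", allele, 5.0)
                for i, allele in enumerate(allele_flags)]

    def test_identical_fractions_p_one(self):
        alleles = ["DRB1*01:01"] * 4 + [TRASH] * 4
        assigns = self._assignments(alleles)
        flags = {a.peptide: i % 2 == 0 for i, a in enumerate(assigns)}
        p = motif_conservation_test(assigns, flags)
        assert p["DRB1*01:01"] == pytest.approx(1.0)

    def test_extreme_separation_small_p(self):
        alleles = ["DRB1*01:01"] * 10 + [TRASH] * 10
        assigns = self._assignments(alleles)
        # all glyco in trash, all non-glyco bound
        flags = {a.peptide: a.allele == TRASH for a in assigns}
        p = motif_conservation_test(assigns, flags)
        assert p["DRB1*01:01"] < 0.01

    def test_needs_both_classes(self):
        assigns = self._assignments(["DRB1*01:01"] * 4)
        flags = {a.peptide: True for a in assigns}
        with pytest.raises(ValueError):
            motif_conservation_test(assigns, flags)

    def test_one_test_per_allele(self):
        alleles = ["DRB1*01:01"] * 4 + ["DQB1*02:01"] * 4 + [TRASH] * 4
        assigns = self._assignments(alleles)
        flags = {a.peptide: i % 2 == 0 for i, a in enumerate(assigns)}
        p = motif_conservation_test(assigns, flags)
        assert set(p) == {"DRB1*01:01", "DQB1*02:01"}


class TestGeneGroup:
    @pytest.mark.parametrize("allele,group", [
        ("DRB1*12:01", "DR"), ("DRB3*02:02", "DR"),
        ("DQA1*05:05-DQB1*03:01", "DQ"), ("DPA1*02:01-DPB1*04:01", "DP"),
    ])
    def test_prefixes(self, allele, group):
        assert gene_group(allele) == group

    def test_unparseable_rejected(self):
        with pytest.raises(ValueError):
            gene_group("HLA-A*02:01x")


class TestSummarize:
    def _assign(self, allele, offset, sites, length=20):
        a = AlleleAssignment("A" * length, allele, 2.0, offset)
        annotate_glyco_positions([a], {"A" * length: sites})
        return a

    def test_all_p8_inside(self):
        a = self._assign("DPA1*02:01-DPB1*04:01", 3, [11])
        df = summarize_positions([a])
        assert df.loc[df["group"] == "DP", "fraction_inside"].iloc[0] == 1.0

    def test_fractions_match_counting_oracle(self, rng):
        assigns = []
        inside = outside = 0
        for i in range(60):
            offset = int(rng.integers(0, 8))
            site = int(rng.integers(0, 20))
            pep = "".join(rng.choice(list("ACDEFGHIKL"), 20))
            a = AlleleAssignment(pep, "DRB1*01:01", 2.0, offset)
            annotate_glyco_positions([a], {pep: [site]})
            assigns.append(a)
            if 0 <= site - offset <= 8:
                inside += 1
            else:
                outside += 1
        df = summarize_positions(assigns)
        got = df.loc[df["group"] == "DR"].iloc[0]
        assert got["fraction_inside"] == pytest.approx(inside / (inside + outside))
        assert got["fraction_inside"] + got["fraction_outside"] == pytest.approx(1.0)


class TestDeconvolution:
    def test_planted_motif_recovery(self):
        rng = np.random.default_rng(5)
        pwm = make_motif_pwm(rng)
        truth = generate_motif_peptides({"DRB1*01:01": pwm}, 150, 0, seed=6)
        model = deconvolve_motifs(truth["peptide"].tolist(), k_max=2, runs=5,
                                  seed=7)
        assert model.n_classes == 1
        corr = np.mean([np.corrcoef(model.pwms[0][j], pwm[j])[0, 1]
                        for j in range(9)])
        assert corr > 0.9

    def test_loglik_monotone(self):
        rng = np.random.default_rng(8)
        pwm = make_motif_pwm(rng)
        truth = generate_motif_peptides({"DRB1*01:01": pwm}, 80, 20, seed=9)
        model = deconvolve_motifs(truth["peptide"].tolist(), k_max=1, runs=2,
                                  seed=10)
        assert (np.diff(model.loglik_trace) >= -1e-6).all()

    def test_random_peptides_absorbed_by_background(self):
        rnd = generate_motif_peptides({}, 0, 150, seed=11)
        model = deconvolve_motifs(rnd["peptide"].tolist(), k_max=2, runs=3,
                                  seed=12)
        assert model.responsibilities[:, -1].mean() >= 0.90

    def test_seed_reproducible(self):
        rng = np.random.default_rng(13)
        pwm = make_motif_pwm(rng)
        truth = generate_motif_peptides({"DRB1*01:01": pwm}, 60, 10, seed=14)
        m1 = deconvolve_motifs(truth["peptide"].tolist(), 1, 2, seed=15)
        m2 = deconvolve_motifs(truth["peptide"].tolist(), 1, 2, seed=15)
        np.testing.assert_array_equal(m1.pwms, m2.pwms)
        assert m1.log_likelihood == m2.log_likelihood

    def test_too_few_peptides_rejected(self):
        with pytest.raises(ValueError):
            deconvolve_motifs(["AAAAKAAAAKAAA"] * 10, 1, 1, seed=0)

    def test_short_peptides_excluded(self):
        rng = np.random.default_rng(16)
        pwm = make_motif_pwm(rng)
        truth = generate_motif_peptides({"DRB1*01:01": pwm}, 60, 0, seed=17)
        peptides = truth["peptide"].tolist() + ["SHORTPEP"] * 100
        model = deconvolve_motifs(peptides, 1, 2, min_length=12, seed=18)
        assert model.responsibilities.shape[0] == 60


class TestPlantedAlleleAssignment:
    def test_accuracy_at_least_95_percent(self):
        rng = np.random.default_rng(20)
        motifs = {f"DRB1*{i:02d}:01": make_motif_pwm(np.random.default_rng(30 + i))
                  for i in range(1, 4)}
        truth = generate_motif_peptides(motifs, 80, 40, seed=21)
        ranks = generate_rank_table(truth, sorted(motifs), seed=22)
        assigns = assign_alleles(truth["peptide"].tolist(), ranks)
        expected = [t if t else TRASH for t in truth["true_allele"]]
        acc = np.mean([a.allele == e for a, e in zip(assigns, expected)])
        assert acc >= 0.95
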