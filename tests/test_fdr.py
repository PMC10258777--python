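import itertools
import math

import numpy as np
import pandas as pd
import pytest

from glycomhc.fdr import (FilterOutcome, entrapment_rate, fit_score_mixture,
                          greedy_parsimony, group_specific_filter,
                          peptide_level_filter, pooled_filter,
                          protein_level_filter, sequential_protein_filter,
                          tdc_qvalues)
from glycomhc.synthetic import generate_psm_population


def brute_force_q(scores, decoys):
    """Oracle: enumerate every threshold, then take running minima."""
    scores = np.asarray(scores, float)
    decoys = np.asarray(decoys, bool)
    qs = np.empty(len(scores))
    for i, s in enumerate(scores):
        best = math.inf
        for t in np.unique(scores):
            if t <= s:
                nd = int((decoys & (scores >= t)).sum())
                nt = int((~decoys & (scores >= t)).sum())
                best = min(best, min(1.0, nd / max(1, nt)))
        qs[i] = best
    return qs


class TestTdcQvalues:
    def test_worked_example(self):
        q = tdc_qvalues([10, 9, 8, 7, 9.5, 6], [False, False, False, False,
                                                True, True])
        np.testing.assert_allclose(q[:4], [0.0, 0.25, 0.25, 0.25])

    def test_no_decoys_all_zero(self):
        q = tdc_qvalues([5, 4, 3], [False] * 3)
        assert (q == 0).all()

    def test_all_decoys_above_targets_capped(self):
        q = tdc_qvalues([10, 9, 1], [True, True, False])
        assert q[2] == 1.0

    def test_needs_a_target(self):
        with pytest.raises(ValueError):
            tdc_qvalues([1.0, 2.0], [True, True])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        scores = np.round(rng.normal(5, 2, n), 1)  # rounding forces ties
        decoys = rng.random(n) < 0.4
        if not (~decoys).any():
            decoys[0] = False
        np.testing.assert_allclose(tdc_qvalues(scores, decoys),
                                   brute_force_q(scores, decoys), atol=1e-12)

    def test_monotone_in_score(self, rng):
        scores = rng.normal(5, 2, 500)
        decoys = rng.random(500) < 0.5
        decoys[0] = False
        q = tdc_qvalues(scores, decoys)
        order = np.argsort(-scores)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_equal_scores_share_q(self):
        q = tdc_qvalues([5.0, 5.0, 3.0], [False, False, True])
        assert q[0] == q[1]


def _population(seed=0, n=20_000, asym=30.0):
    return generate_psm_population(n, 0.03, asym, seed=seed)


class TestGroupFilter:
    def test_groups_split_at_cutoff(self):
        df = _population()
        out = group_specific_filter(df, 145.0, 0.01)
        assert (out.table.loc[out.table["delta_mass"] >= 145.0, "group"]
                == "glyco").all()
        assert (out.table.loc[out.table["delta_mass"] < 145.0, "group"]
                == "nonglyco").all()

    def test_delta_203_is_glyco_and_small_delta_nonglyco(self):
        df = pd.DataFrame({"hyperscore": [10.0, 9.0], "is_decoy": [False, False],
                           "delta_mass": [203.08, 0.001]})
        out = group_specific_filter(df)
        assert list(out.table["group"]) == ["glyco", "nonglyco"]

    def test_identical_scores_identical_thresholds(self):
        scores = [10.0, 9.0, 8.0, 2.0]
        decoys = [False, False, False, True]
        df = pd.DataFrame({
            "hyperscore": scores * 2,
            "is_decoy": decoys * 2,
            "delta_mass": [0.0] * 4 + [500.0] * 4,
        })
        out = group_specific_filter(df)
        assert out.thresholds["glyco"] == out.thresholds["nonglyco"]

    def test_empty_group_logged_not_fatal(self, caplog):
        df = pd.DataFrame({"hyperscore": [10.0], "is_decoy": [False],
                           "delta_mass": [0.0]})
        out = group_specific_filter(df)
        assert out.counts["glyco"]["targets"] == 0 if "glyco" in out.counts \
            else True

    def test_thresholds_reproduce_accepted_set(self):
        df = _population(seed=3)
        out = group_specific_filter(df, 145.0, 0.01)
        for group, thr in out.thresholds.items():
            sub = out.table[out.table["group"] == group]
            accepted = set(out.accepted) & set(sub.index)
            by_thr = set(sub.index[(~sub["is_decoy"])
                                   & (sub["hyperscore"] >= thr)])
            assert accepted == by_thr

    def test_refiltering_idempotent(self):
        df = _population(seed=4)
        out1 = group_specific_filter(df, 145.0, 0.01)
        out2 = group_specific_filter(out1.table.drop(columns=["group", "psm_q"]),
                                     145.0, 0.01)
        assert set(out1.accepted) == set(out2.accepted)


class TestCalibrationProperties:
    def test_group_specific_fdr_calibrated(self):
        df = generate_psm_population(100_000, 0.03, 30.0, seed=101)
        out = group_specific_filter(df, 145.0, 0.01)
        acc = out.table.loc[out.accepted]
        glyco = acc[acc["group"] == "glyco"]
        fdp = 1.0 - df.loc[glyco.index, "is_correct"].mean()
        se = math.sqrt(0.01 * 0.99 / len(glyco))
        assert fdp <= 0.01 + 2 * se

    def test_pooled_filtering_inflates_glyco_fdr(self):
        df = generate_psm_population(100_000, 0.03, 30.0, seed=102)
        grp = group_specific_filter(df, 145.0, 0.01)
        pool = pooled_filter(df, 0.01)
        def glyco_fdp(outcome):
            acc = outcome.table.loc[outcome.accepted]
            g = acc[acc["delta_mass"] >= 145.0]
            return 1.0 - df.loc[g.index, "is_correct"].mean()
        assert glyco_fdp(pool) > glyco_fdp(grp)

    def test_symmetric_spaces_agree(self):
        df = generate_psm_population(50_000, 0.5, 1.0, seed=103)
        grp = group_specific_filter(df, 145.0, 0.01)
        pool = pooled_filter(df, 0.01)
        def glyco_fdp(outcome):
            acc = outcome.table.loc[outcome.accepted]
            g = acc[acc["delta_mass"] >= 145.0]
            return 1.0 - df.loc[g.index, "is_correct"].mean()
        assert abs(glyco_fdp(pool) - glyco_fdp(grp)) < 0.01


class TestPeptideFilter:
    def test_best_psm_per_peptide(self):
        df = pd.DataFrame({
            "peptide": ["A", "A", "A", "B"],
            "hyperscore": [5.0, 9.0, 7.0, 6.0],
            "is_decoy": [False] * 4,
            "delta_mass": [0.0] * 4,
        })
        out = peptide_level_filter(df)
        row = out.table[out.table["peptide"] == "A"].iloc[0]
        assert row["hyperscore"] == 9.0
        assert len(out.table) == 2

    def test_single_target_retained(self):
        df = pd.DataFrame({"peptide": ["A"], "hyperscore": [5.0],
                           "is_decoy": [False], "delta_mass": [0.0]})
        out = peptide_level_filter(df)
        assert list(out.table["pep_q"]) == [0.0]
        assert len(out.accepted) == 1

    def test_matches_bruteforce_on_random_psms(self, rng):
        n = 200
        df = pd.DataFrame({
            "peptide": rng.choice([f"P{i}" for i in range(60)], n),
            "hyperscore": np.round(rng.normal(8, 2, n), 2),
            "is_decoy": rng.random(n) < 0.4,
            "delta_mass": np.zeros(n),
        })
        if not (~df["is_decoy"]).any():
            df.loc[0, "is_decoy"] = False
        out = peptide_level_filter(df)
        # oracle: per (peptide, decoy) max score, then brute-force q
        best = df.groupby(["peptide", "is_decoy"])["hyperscore"].max().reset_index()
        oq = brute_force_q(best["hyperscore"].to_numpy(),
                           best["is_decoy"].to_numpy())
        merged = out.table.merge(best, on=["peptide", "is_decoy"],
                                 suffixes=("", "_oracle"))
        assert (merged["hyperscore"] == merged["hyperscore_oracle"]).all()
        got = out.table.sort_values(["peptide", "is_decoy"])["pep_q"].to_numpy()
        want = best.assign(q=oq).sort_values(["peptide", "is_decoy"])["q"].to_numpy()
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestProteinFilter:
    def test_shared_peptides_one_representative(self):
        assignment = greedy_parsimony({"p1": ["A", "B"], "p2": ["A", "B"]})
        assert len(assignment) == 1

    def test_score_monotonicity(self):
        peps = pd.DataFrame({
            "peptide": ["a", "b", "c", "d"],
            "proteins": [("HI",), ("HI",), ("HI",), ("LO",)],
            "is_decoy": [False] * 4,
            "posterior": [0.99, 0.99, 0.99, 0.10],
            "hyperscore": [9.0] * 4,
        })
        out, accepted = protein_level_filter(peps)
        t = out.table.set_index("protein")
        assert t.loc["HI", "score"] > t.loc["LO", "score"]

    @pytest.mark.parametrize("seed", range(25))
    def test_parsimony_matches_minimal_set_cover(self, seed):
        rng = np.random.default_rng(seed)
        n_prot = int(rng.integers(2, 9))
        n_pep = int(rng.integers(2, 12))
        prots = [f"PR{i}" for i in range(n_prot)]
        pep_prots = {}
        for j in range(n_pep):
            k = int(rng.integers(1, n_prot + 1))
            pep_prots[f"pep{j}"] = sorted(rng.choice(prots, size=k, replace=False))
        assignment = greedy_parsimony(pep_prots)
        greedy_size = len(assignment)
        # oracle: exhaustive minimal set cover
        minimal = None
        for r in range(1, n_prot + 1):
            for combo in itertools.combinations(prots, r):
                covered = {p for p, ps in pep_prots.items()
                           if set(ps) & set(combo)}
                if len(covered) == n_pep:
                    minimal = r
                    break
            if minimal is not None:
                break
        # greedy set cover is within the classic ln(n) + 1 factor
        assert minimal <= greedy_size <= minimal * (math.log(n_pep) + 1)
        # and always explains every peptide
        assert sum(len(v) for v in assignment.values()) == n_pep


class TestSequentialFilter:
    def _psms(self):
        return pd.DataFrame({
            "peptide": ["a", "b", "c"],
            "proteins": [("P1",), ("P1", "P2"), ("P3",)],
            "hyperscore": [9.0, 8.0, 7.0],
            "is_decoy": [False] * 3,
        })

    def test_only_failed_protein_removed(self):
        out = sequential_protein_filter(self._psms(), {"P1"})
        assert list(out["peptide"]) == ["a", "b"]

    def test_one_accepted_of_two_kept(self):
        out = sequential_protein_filter(self._psms(), {"P2"})
        assert list(out["peptide"]) == ["b"]

    def test_output_subset_of_input(self):
        df = self._psms()
        out = sequential_protein_filter(df, {"P9"})
        assert set(out.index) <= set(df.index)
        assert len(out) == 0


class TestEntrapment:
    def _final(self):
        return pd.DataFrame({
            "group": ["glyco", "glyco", "glyco", "nonglyco"],
            "proteins": [("H1",), ("E1",), ("H1", "E1"), ("E1",)],
        })

    def test_rates(self):
        species = {"H1": "human", "E1": "weed"}
        rate, offenders = entrapment_rate(self._final(), species, "weed")
        assert rate == pytest.approx(1 / 3)  # mixed provenance not counted
        assert len(offenders) == 1

    def test_all_entrapment(self):
        df = pd.DataFrame({"group": ["glyco"], "proteins": [("E1",)]})
        rate, _ = entrapment_rate(df, {"E1": "weed"}, "weed")
        assert rate == 1.0

    def test_absent_tag_rejected(self):
        with pytest.raises(ValueError):
            entrapment_rate(self._final(), {"H1": "human", "E1": "human"},
                            "weed")

    def test_no_glyco_gives_zero(self):
        df = pd.DataFrame({"group": ["nonglyco"], "proteins": [("E1",)]})
        rate, _ = entrapment_rate(df, {"E1": "weed"}, "weed")
        assert rate == 0.0


class TestMixtureModel:
    def test_posterior_near_half_at_symmetric_point(self, rng):
        t = np.concatenate([rng.normal(10, 1, 2000), rng.normal(5, 1, 2000)])
        d = rng.normal(5, 1, 2000)
        m = fit_score_mixture(t, d)
        assert 0.35 <= float(m.posterior(7.5)) <= 0.65

    def test_posterior_limit_high_score(self, rng):
        t = np.concatenate([rng.normal(10, 1, 1000), rng.normal(5, 1, 1000)])
        d = rng.normal(5, 1, 1000)
        m = fit_score_mixture(t, d)
        assert float(m.posterior(14.0)) > 0.99

    def test_loglik_monotone(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            t = np.concatenate([r.normal(9, 1.5, 400), r.normal(4, 1, 600)])
            d = r.normal(4, 1, 400)
            m = fit_score_mixture(t, d)
            diffs = np.diff(m.loglik_trace)
            assert (diffs >= -1e-6).all()

    def test_posterior_monotone_in_score(self, rng):
        t = np.concatenate([rng.normal(10, 1, 500), rng.normal(5, 1, 500)])
        d = rng.normal(5, 1, 500)
        m = fit_score_mixture(t, d)
        grid = np.linspace(0, 15, 200)
        assert (np.diff(m.posterior(grid)) >= -1e-12).all()

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_score_mixture(np.ones(200), np.ones(200))

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_score_mixture(np.arange(10.0), np.arange(200.0))
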