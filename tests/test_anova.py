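"""ANOVA engine: sequential SS, model selection, permutation P, q-values,
effect sizes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import invscan as iv
from invscan.anova import AnovaEngine, storey_pi0
from invscan.core import InputError

from conftest import make_manual_design


def nested_rss_drops(y, blocks):
    """Oracle: term SS as RSS drops between successively nested lstsq fits."""
    n = len(y)
    X = np.ones((n, 1))
    rss_prev = float(np.sum((y - y.mean()) ** 2))
    drops = []
    for block in blocks:
        X = np.column_stack([X, block])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        drops.append(rss_prev - rss)
        rss_prev = rss
    return drops, rss_prev


class TestDesignCoding:
    def test_default_design_degrees_of_freedom(self):
        design = iv.make_design(iv.SimulationConfig(seed=0))
        coded = iv.build_design(design)
        assert coded.df == {"Sex": 1, "In(2L)t": 1, "In(3R)Mo": 1, "Line": 30}
        assert coded.df_resid == 102

    def test_no_replication_is_an_error(self):
        # two lines, one individual each: no residual df
        ind = pd.DataFrame(
            [("a", "L0", "M"), ("b", "L1", "F")],
            columns=["individual", "line", "sex"],
        )
        kary = pd.DataFrame({"InvX": [0, 1]}, index=pd.Index(["L0", "L1"],
                                                             name="line"))
        with pytest.raises(InputError):
            iv.build_design(iv.StudyDesign(individuals=ind, karyotypes=kary))

    def test_constant_karyotype_drops_term_into_line(self):
        design = make_manual_design(
            6, {"InvA": [], "InvB": [0, 1]}, reps_per_sex=2,
            inversions=("InvA", "InvB"),
        )
        coded = AnovaEngine(design).coded()
        assert "InvA" in coded.dropped
        assert coded.df["InvA"] == 0
        # the df InvA would have used stays in the line block
        assert coded.df["Line"] == 6 - 1 - coded.df["InvB"]

    def test_single_line_class_warns(self):
        design = make_manual_design(5, {"InvX": [0]}, reps_per_sex=2)
        with pytest.warns(UserWarning, match="<2 lines"):
            iv.build_design(design)


class TestFit:
    def test_additive_toy_sequential_ss(self, toy_design):
        # line1=(1,2), line2=(3,4); F/M within each line
        y = pd.Series(
            {"L0_F0": 2.0, "L0_M0": 1.0, "L1_F0": 4.0, "L1_M0": 3.0}
        ).loc[toy_design.individuals["individual"]].to_numpy()
        tab = iv.fit_probe_anova(y, toy_design)
        assert tab.loc["Sex", "SS"] == pytest.approx(1.0)
        assert tab.loc["InvX", "SS"] == pytest.approx(4.0)
        assert tab.loc["Line", "SS"] == pytest.approx(0.0)
        assert tab.loc["Residual", "SS"] == pytest.approx(0.0, abs=1e-12)
        assert tab.loc["InvX", "eta2"] == pytest.approx(0.8)

    def test_pure_sex_response(self, toy_design):
        female = (toy_design.individuals["sex"] == "F").to_numpy(float)
        tab = iv.fit_probe_anova(female, toy_design)
        assert tab.loc["Sex", "eta2"] == pytest.approx(1.0)
        assert tab.drop(index=["Sex"])["SS"].sum() == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("trial", range(10))
    def test_sequential_ss_equals_nested_rss_drops(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n_lines = int(rng.integers(4, 9))
        k = int(rng.integers(1, n_lines - 1))
        design = make_manual_design(
            n_lines, {"InvX": list(rng.choice(n_lines, k, replace=False))},
            reps_per_sex=int(rng.integers(1, 3)),
        )
        engine = AnovaEngine(design)
        coded = engine.coded()
        y = rng.standard_normal(engine.n)
        tab = iv.fit_probe_anova(y, design)
        blocks = [engine.female[:, None],
                  engine.kary_obs[:, 0][engine.ind_line][:, None],
                  engine._line_dummies(engine.kary_obs)]
        drops, rss = nested_rss_drops(y, blocks)
        assert tab.loc["Sex", "SS"] == pytest.approx(drops[0], abs=1e-8)
        assert tab.loc["InvX", "SS"] == pytest.approx(drops[1], abs=1e-8)
        assert tab.loc["Line", "SS"] == pytest.approx(drops[2], abs=1e-8)
        assert tab.loc["Residual", "SS"] == pytest.approx(rss, abs=1e-8)
        # SS conservation and eta^2 summation
        assert tab["SS"].sum() == pytest.approx(np.sum((y - y.mean()) ** 2))
        assert tab["eta2"].sum() == pytest.approx(1.0)


class TestModelSelection:
    def _planted_main_effects(self, seed=11):
        cfg0 = iv.SimulationConfig(genes_per_arm=60, snps_per_arm=5,
                                   n_both_inverted=0, seed=seed)
        genome = iv.make_genome(cfg0)
        planted = [(g.gene_id, inv, 1.5) for g in genome.genes
                   for inv in ("In(2L)t", "In(3R)Mo")]
        cfg = iv.SimulationConfig(genes_per_arm=60, snps_per_arm=5,
                                  n_both_inverted=0, planted_effects=planted,
                                  seed=seed)
        design = iv.make_design(cfg)
        expr, _ = iv.make_expression(design, genome, cfg)
        return expr, design

    def test_main_effects_win_majority_without_interactions(self):
        expr, design = self._planted_main_effects()
        ms = iv.model_selection_scan(expr, design)
        assert ms["majority_model"] == "main"

    def test_empty_interaction_ties_to_simpler_model(self):
        # no doubly-inverted line: the Inv x Inv column is identically zero,
        # its AIC equals the main model's, and the tie goes to fewer terms
        expr, design = self._planted_main_effects()
        ms = iv.model_selection_scan(expr, design)
        aic = ms["aic"]
        inter = "main+In(2L)t:In(3R)Mo"
        assert np.allclose(aic[inter], aic["main"])
        assert not (ms["best_per_probe"] == inter).any()

    def test_planted_interaction_detected(self):
        expr, design = self._planted_main_effects(seed=12)
        vals = expr.values.copy()
        kary3 = design.individual_karyotype("In(3R)Mo")
        female = (design.individuals["sex"] == "F").to_numpy(float)
        vals += np.outer(kary3 * female, np.ones(vals.shape[1]))
        em = iv.ExpressionMatrix(values=vals, probe_map=expr.probe_map)
        ms = iv.model_selection_scan(em, design)
        assert ms["majority_model"] == "main+Sex:In(3R)Mo"

    def test_dropping_a_strong_term_raises_aic(self):
        expr, design = self._planted_main_effects(seed=13)
        ms = iv.model_selection_scan(expr, design)
        # sex effect is planted genome-wide: dropping Sex must cost AIC
        assert (ms["aic"]["main-Sex"] > ms["aic"]["main"]).mean() > 0.9


class TestPermutation:
    def test_extreme_p_values_add_one_mode(self):
        rng = np.random.default_rng(3)
        design = make_manual_design(8, {"InvX": [0, 1, 2]}, reps_per_sex=2)
        n = len(design.individuals)
        k = design.individual_karyotype("InvX")
        # a huge planted effect: observed F should beat every permutation
        strong = 50.0 * k + rng.standard_normal(n) * 0.1
        # and pure noise should not sit above the permutation distribution
        vals = pd.DataFrame({"strong_at": strong},
                            index=design.individuals["individual"])
        em = iv.ExpressionMatrix(
            values=vals, probe_map=pd.Series({"strong_at": "g"})
        )
        B = 99
        out = iv.permutation_scan(em, design, B=B, seed=0, estimator="add_one")
        assert out["p"]["InvX"].iloc[0] == pytest.approx(1.0 / (B + 1))

    def test_null_consistent_observation_has_p_one(self):
        design = make_manual_design(6, {"InvX": [0, 1, 2]}, reps_per_sex=2)
        # constant within karyotype classes: F_obs = 0 <= every permuted F
        k = design.individual_karyotype("InvX")
        line_idx = design.individuals["line"].astype("category").cat.codes
        y = np.asarray(line_idx % 2, dtype=float) * 0.0  # all zero -> constant
        vals = pd.DataFrame(
            {"p_at": np.where(k > 0.5, 0.0, 0.0)
             + np.tile([0.1, -0.1], len(k) // 2)},
            index=design.individuals["individual"],
        )
        em = iv.ExpressionMatrix(values=vals, probe_map=pd.Series({"p_at": "g"}))
        out = iv.permutation_scan(em, design, B=49, seed=1, estimator="add_one")
        # within-line variation only: F_obs is in the bulk, P is large
        assert out["p"]["InvX"].iloc[0] > 0.2

    def test_small_design_matches_exhaustive_enumeration(self):
        # 5 lines, 1 inverted: only 5 distinct label assignments
        rng = np.random.default_rng(8)
        design = make_manual_design(5, {"InvX": [2]}, reps_per_sex=2)
        engine = AnovaEngine(design)
        y = rng.standard_normal(engine.n)
        vals = pd.DataFrame({"y_at": y}, index=design.individuals["individual"])
        em = iv.ExpressionMatrix(values=vals, probe_map=pd.Series({"y_at": "g"}))

        # exhaustive oracle over the 5 assignments
        ss_total = np.sum((y - y.mean()) ** 2)
        fs = []
        for inv_line in range(5):
            kary = np.zeros((5, 1))
            kary[inv_line, 0] = 1.0
            coded = engine.coded(kary)
            F, _ = engine.f_stats(coded, y[:, None], np.array([ss_total]))
            fs.append(F["InvX"][0])
        f_obs = fs[2]
        exact_p = np.mean([f >= f_obs for f in fs])

        B = 2000
        out = iv.permutation_scan(em, design, B=B, seed=5)
        sampled = out["p"]["InvX"].iloc[0]
        mc_se = np.sqrt(exact_p * (1 - exact_p) / B)
        assert abs(sampled - exact_p) < 4 * mc_se + 1e-9

    def test_permutation_preserves_line_structure_and_counts(self):
        design = iv.make_design(iv.SimulationConfig(seed=0))
        engine = AnovaEngine(design)
        rng = np.random.default_rng(0)
        kary = engine.kary_obs.copy()
        for j in range(kary.shape[1]):
            kary[:, j] = kary[rng.permutation(len(engine.lines)), j]
        # inverted-line counts are preserved by construction
        assert kary.sum(axis=0).tolist() == engine.kary_obs.sum(axis=0).tolist()

    def test_small_b_warns_about_floor(self, toy_design):
        vals = pd.DataFrame(
            {"y_at": [1.0, 2.0, 3.0, 4.0]},
            index=toy_design.individuals["individual"],
        )
        em = iv.ExpressionMatrix(values=vals, probe_map=pd.Series({"y_at": "g"}))
        with pytest.warns(UserWarning, match="floor"):
            iv.permutation_scan(em, toy_design, B=5, seed=0)


class TestStorey:
    def test_bh_arithmetic_small_family(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        with pytest.warns(UserWarning, match="pi0"):
            q, pi0 = iv.storey_qvalues(p)
        assert pi0 == 1.0
        assert np.allclose(q, 0.04)

    def test_all_ones_saturate(self):
        p = np.ones(500)
        q, pi0 = iv.storey_qvalues(p)
        assert np.allclose(q, 1.0)

    def test_matches_bh_when_pi0_forced(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(size=80) ** 2
        with pytest.warns(UserWarning):
            q, _ = iv.storey_qvalues(p)  # m<100 -> pi0=1 -> plain BH
        _, q_bh, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_bh)

    def test_pi0_near_one_under_uniform(self):
        rng = np.random.default_rng(7)
        ok = 0
        for _ in range(100):
            pi0 = storey_pi0(rng.uniform(size=10_000))
            ok += 0.9 <= pi0 <= 1.0
        assert ok >= 95

    def test_q_monotone_in_p_and_bounded_below(self):
        rng = np.random.default_rng(4)
        p = np.concatenate([rng.uniform(size=150), rng.uniform(size=50) * 1e-3])
        q, pi0 = iv.storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p * pi0 - 1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            iv.storey_qvalues(np.array([0.0, 0.5]))


class TestEffectSizes:
    def test_eta_squared_toy(self, toy_design):
        y = pd.Series(
            {"L0_F0": 2.0, "L0_M0": 1.0, "L1_F0": 4.0, "L1_M0": 3.0}
        ).loc[toy_design.individuals["individual"]].to_numpy()
        tab = iv.fit_probe_anova(y, toy_design)
        eta = iv.eta_squared(tab)
        assert eta["InvX"] == pytest.approx(0.8)
        assert eta.sum() == pytest.approx(1.0)

    def test_eta_squared_constant_probe_flagged(self, toy_design):
        tab = iv.fit_probe_anova(np.zeros(4), toy_design)
        with pytest.raises(InputError):
            iv.eta_squared(tab)

    @pytest.mark.parametrize(
        "inv,std,expected",
        [
            (([1.0, 2.0, 3.0]), ([1.0, 2.0, 3.0]), 0.0),
            (([2.0, 3.0, 4.0]), ([0.0, 1.0, 2.0]), 2.0),
        ],
    )
    def test_cohens_d_hand_values(self, inv, std, expected):
        assert iv.cohens_d(inv, std) == pytest.approx(expected)

    def test_cohens_d_one_sd_apart(self, rng):
        # two unit-SD groups one unit apart: d -> 1 at large n
        a = rng.standard_normal(200_000) + 1.0
        b = rng.standard_normal(200_000)
        assert iv.cohens_d(a, b) == pytest.approx(1.0, abs=0.02)

    def test_cohens_d_needs_two_per_group(self):
        with pytest.raises(InputError):
            iv.cohens_d([1.0], [0.0, 1.0])

    @pytest.mark.parametrize(
        "d,expected",
        [(0.0, 100.0), (1.0, 61.71), (2.0, 31.73), (-1.0, 61.71)],
    )
    def test_expected_overlap(self, d, expected):
        assert iv.expected_overlap(d) == pytest.approx(expected, abs=0.005)


class TestCallIal:
    def test_boundary_and_empty(self):
        res = pd.DataFrame(
            {
                "q_InvX": [0.04, 0.05, 0.9, np.nan],
                "d_InvX": [1.0, -1.0, 0.5, 0.2],
            },
            index=["a", "b", "c", "e"],
        )
        out = iv.call_ial(res, "InvX", q_threshold=0.05)
        assert list(out.index) == ["a"]  # strict inequality at the threshold
        assert out.loc["a", "direction"] == "up"
        res["q_InvX"] = 1.0
        assert len(iv.call_ial(res, "InvX")) == 0
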