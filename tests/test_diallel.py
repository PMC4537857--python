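"""Fixed-effects diallel model: design, fit, Type III tests, contrasts, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rootbox import diallel as dl
from rootbox import synthetic as syn

from conftest import make_sim_spec


def fit_dataset(spec, trait="Y", drop_rows=None, seed=None):
    data = syn.simulate_diallel_dataset(spec, trait=trait)
    if drop_rows is not None:
        rng = np.random.default_rng(seed)
        drop = rng.choice(len(data), size=int(drop_rows * len(data)), replace=False)
        data = data.drop(index=drop).reset_index(drop=True)
    dspec = dl.DiallelSpec(
        parent_ids=spec.parent_ids,
        check_ids=spec.check_ids,
        env_ids=spec.env_ids,
        reps_per_env=spec.reps_per_env,
    )
    design = dl.build_design(dspec, data)
    return data, design, dl.fit_ols(data, design, trait)


@pytest.fixture(scope="module")
def design12():
    spec = make_sim_spec(n_parents=12, n_checks=6, reps=3)
    data = syn.simulate_diallel_dataset(spec)
    dspec = dl.DiallelSpec(spec.parent_ids, spec.check_ids, spec.env_ids, 3)
    return dspec, data, dl.build_design(dspec, data)


class TestDesignStructure:
    def test_twelve_parents_give_66_crosses(self, design12):
        dspec, _, _ = design12
        assert len(dspec.crosses) == 66
        assert all(a < b for a, b in dspec.crosses)  # unordered, no reciprocals

    def test_free_column_counts(self, design12):
        _, _, design = design12
        assert design.terms["additive"].n_free == 11
        assert design.terms["gca"].n_free == 11
        assert design.terms["sca"].n_free == 54
        total = 11 + 11 + 54
        assert total == 76

    def test_parent_row_coefficients(self, design12):
        dspec, data, design = design12
        r = data.index[(data.entry_class == "parent") & (data.parent1 == "P00")][0]
        t = design.terms["additive"]
        np.testing.assert_allclose(
            t.coef_full[r], [1.0] + [0.0] * 11, atol=0
        )
        assert not design.terms["gca"].coef_full[r].any()
        assert not design.terms["sca"].coef_full[r].any()

    def test_cross_row_coefficients(self, design12):
        dspec, data, design = design12
        sel = (data.entry_class == "F1") & (data.parent1 == "P00") & (data.parent2 == "P01")
        r = data.index[sel][0]
        add = design.terms["additive"].coef_full[r]
        assert add[0] == 0.5 and add[1] == 0.5 and add[2:].sum() == 0
        gca = design.terms["gca"].coef_full[r]
        assert gca[0] == 1.0 and gca[1] == 1.0 and gca[2:].sum() == 0
        sca = design.terms["sca"].coef_full[r]
        assert sca.sum() == 1.0 and sca[0] == 1.0  # (P00,P01) is the first cross

    def test_check_row_has_no_genetic_coefficients(self, design12):
        _, data, design = design12
        r = data.index[data.entry_class == "check"][0]
        for term in ("additive", "gca", "sca"):
            assert not design.terms[term].coef_full[r].any()

    def test_unknown_parent_rejected(self, design12):
        dspec, data, _ = design12
        bad = data.copy()
        bad.loc[bad.index[0], "parent1"] = "NOT_A_LINE"
        with pytest.raises(ValueError, match="unknown parent"):
            dl.build_design(dspec, bad)


class TestFit:
    def test_zero_noise_recovers_every_effect_family(self):
        spec = make_sim_spec(n_parents=6, n_checks=3, reps=2, residual_sd=0.0)
        _, _, fit = fit_dataset(spec)
        np.testing.assert_allclose(
            fit.effects("additive").to_numpy(),
            [spec.additive[p] for p in spec.parent_ids], atol=1e-10,
        )
        np.testing.assert_allclose(
            fit.effects("gca").to_numpy(),
            [spec.gca[p] for p in spec.parent_ids], atol=1e-10,
        )
        np.testing.assert_allclose(
            fit.effects("sca").to_numpy(),
            [spec.sca[c] for c in spec.crosses], atol=1e-10,
        )
        np.testing.assert_allclose(
            fit.effects("env").to_numpy(),
            [spec.env_effects[e] for e in spec.env_ids], atol=1e-10,
        )
        np.testing.assert_allclose(
            fit.effects("checks").to_numpy(),
            [spec.check_effects[c] for c in spec.check_ids], atol=1e-10,
        )

    def test_balanced_zero_noise_class_means_equal_block_means(self):
        spec = make_sim_spec(residual_sd=0.0)
        data, _, fit = fit_dataset(spec)
        ls = dl.class_lsmeans(fit)
        for klass in ("parent", "F1", "check"):
            block = data.loc[data.entry_class == klass, "Y"].mean()
            assert abs(ls[klass] - block) < 1e-10

    def test_unbalanced_estimates_match_normal_equation_oracle(self):
        spec = make_sim_spec(residual_sd=0.2)
        data, design, fit = fit_dataset(spec, drop_rows=0.1, seed=3)
        y = data["Y"].to_numpy(dtype=float)
        X = design.X
        beta_oracle = np.linalg.pinv(X.T @ X) @ X.T @ y
        np.testing.assert_allclose(fit.beta, beta_oracle, atol=1e-8)

    def test_all_missing_trait_rejected(self):
        spec = make_sim_spec()
        data = syn.simulate_diallel_dataset(spec)
        data["Y"] = np.nan
        dspec = dl.DiallelSpec(spec.parent_ids, spec.check_ids, spec.env_ids,
                               spec.reps_per_env)
        design = dl.build_design(dspec, data)
        with pytest.raises(ValueError, match="entirely missing"):
            dl.fit_ols(data, design, "Y")


class TestTypeIII:
    def test_numerator_dfs_for_twelve_parent_diallel(self):
        spec = make_sim_spec(n_parents=12, n_checks=6, reps=3, residual_sd=0.1)
        data, _, fit = fit_dataset(spec)
        tab = dl.type3_anova(fit, data, "Y")
        assert tab.loc["additive", "df"] == 11
        assert tab.loc["sca", "df"] == 54
        assert tab.loc["gca", "df"] == 11
        assert tab.loc["env", "df"] == 1
        assert tab.loc["checks", "df"] == 5
        assert tab.loc["env_additive", "df"] == 11

    def test_shift_invariance_of_f_statistics(self):
        spec = make_sim_spec(residual_sd=0.3)
        data, design, fit = fit_dataset(spec)
        tab = dl.type3_anova(fit, data, "Y")
        shifted = data.copy()
        shifted["Y"] = shifted["Y"] + 100.0
        fit2 = dl.fit_ols(shifted, design, "Y")
        tab2 = dl.type3_anova(fit2, shifted, "Y")
        np.testing.assert_allclose(tab["F"], tab2["F"], rtol=1e-8)

    def test_entry_order_permutation_invariance(self):
        spec = make_sim_spec(residual_sd=0.3)
        data = syn.simulate_diallel_dataset(spec)
        dspec = dl.DiallelSpec(spec.parent_ids, spec.check_ids, spec.env_ids,
                               spec.reps_per_env)
        perm = data.sample(frac=1.0, random_state=5).reset_index(drop=True)
        f1 = dl.fit_ols(data, dl.build_design(dspec, data), "Y")
        f2 = dl.fit_ols(perm, dl.build_design(dspec, perm), "Y")
        pd.testing.assert_series_equal(f1.effects("additive"), f2.effects("additive"))
        t1 = dl.type3_anova(f1, data, "Y")
        t2 = dl.type3_anova(f2, perm, "Y")
        np.testing.assert_allclose(t1["F"], t2["F"], rtol=1e-8)

    def test_null_simulation_f_and_p_calibration(self):
        """Pure-noise data: mean F near 1 and uniform p-values per term."""
        spec0 = make_sim_spec(n_parents=5, n_checks=2, reps=2, heterosis=0.0)
        # strip all true effects: only mu + noise
        base = syn.simulate_diallel_dataset(
            syn.DiallelSimSpec(
                parent_ids=spec0.parent_ids, check_ids=spec0.check_ids,
                env_ids=spec0.env_ids, reps_per_env=2, mu=5.0,
            )
        )
        dspec = dl.DiallelSpec(spec0.parent_ids, spec0.check_ids,
                               spec0.env_ids, 2)
        design = dl.build_design(dspec, base)
        rng = np.random.default_rng(2024)
        pvals = {"additive": [], "sca": [], "env": []}
        fvals = []
        data = base.copy()
        for _ in range(400):
            data["Y"] = 5.0 + rng.normal(0.0, 1.0, len(base))
            fit = dl.fit_ols(data, design, "Y")
            tab = dl.type3_anova(fit, data, "Y", fdr=False)
            for term in pvals:
                pvals[term].append(tab.loc[term, "p"])
            fvals.append(tab.loc["additive", "F"])
        # E[F] = d2/(d2-2) under H0
        d2 = fit.df_resid
        assert abs(np.mean(fvals) - d2 / (d2 - 2)) < 0.2
        for term, ps in pvals.items():
            ks = stats.kstest(ps, "uniform")
            assert ks.pvalue > 0.01, f"{term} p-values not uniform"


class TestContrasts:
    def test_zero_noise_heterosis_exact(self):
        spec = make_sim_spec(heterosis=0.8, residual_sd=0.0)
        _, _, fit = fit_dataset(spec)
        con = dl.estimate_contrasts(fit)
        assert abs(con.loc["heterosis", "estimate"] - 0.8) < 1e-10

    def test_env_difference_is_first_minus_second(self):
        spec = make_sim_spec(residual_sd=0.0)
        _, _, fit = fit_dataset(spec)
        con = dl.estimate_contrasts(fit)
        truth = spec.env_effects["E1"] - spec.env_effects["E2"]
        assert abs(con.loc["env_difference", "estimate"] - truth) < 1e-10

    def test_heterosis_recovery_within_monte_carlo_error(self):
        """200 noisy replicates: mean estimate within 4 SEM of the truth and
        the model SE close to the empirical spread."""
        truth = 0.5
        ests, ses = [], []
        for s in range(200):
            spec = make_sim_spec(n_parents=5, n_checks=2, reps=3,
                                 heterosis=truth, residual_sd=0.4, seed=s)
            _, _, fit = fit_dataset(spec)
            con = dl.estimate_contrasts(fit, fdr=False)
            ests.append(con.loc["heterosis", "estimate"])
            ses.append(con.loc["heterosis", "se"])
        ests = np.asarray(ests)
        sem = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - truth) < 4 * sem
        assert 0.7 < np.mean(ses) / ests.std(ddof=1) < 1.3


class TestAdaptiveFDR:
    @staticmethod
    def oracle(p):
        """Direct transcription of the adaptive step-up: lowest-slope m0,
        then BH with m0, then enforce monotonicity."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        idx = np.argsort(p, kind="stable")
        ps = p[idx]
        slopes = []
        m0 = m
        for i in range(1, m + 1):
            denom = 1.0 - ps[i - 1]
            s = (m + 1 - i) / denom if denom > 0 else np.inf
            if slopes and s > slopes[-1]:
                m0 = min(m, int(np.floor(slopes[-1])) + 1)
                break
            slopes.append(s)
        else:
            m0 = min(m, int(np.floor(slopes[-1])) + 1) if np.isfinite(slopes[-1]) else m
        m0 = max(1, m0)
        q = [ps[i] * m0 / (i + 1) for i in range(m)]
        for i in range(m - 2, -1, -1):
            q[i] = min(q[i], q[i + 1])
        out = np.empty(m)
        out[idx] = np.clip(q, 0, 1)
        return out

    def test_single_p_maps_to_itself(self):
        np.testing.assert_allclose(dl.adjust_fdr(np.array([0.037])), [0.037])

    def test_identical_pvalues_get_identical_q(self):
        q = dl.adjust_fdr(np.full(7, 0.02))
        assert np.unique(q).size == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_direct_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, rng.integers(3, 40))
        np.testing.assert_allclose(dl.adjust_fdr(p), self.oracle(p), atol=1e-12)

    def test_q_monotone_in_p_and_bounded(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0, 1, 50)
        q = dl.adjust_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))

    def test_adaptive_not_larger_than_plain_bh_when_m0_small(self):
        from statsmodels.stats.multitest import multipletests

        # many tiny p-values -> m0 estimate well below m
        p = np.concatenate([np.full(8, 1e-4), [0.2, 0.8]])
        q_adaptive = dl.adjust_fdr(p)
        q_bh = multipletests(p, method="fdr_bh")[1]
        assert np.all(q_adaptive <= q_bh + 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dl.adjust_fdr(np.array([0.1, 1.2]))


class TestRepeatability:
    @staticmethod
    def simulate(var_g, var_ge, var_e, n_geno=30, n_env=2, n_rep=3, seed=0):
        rng = np.random.default_rng(seed)
        g = rng.normal(0, np.sqrt(var_g), n_geno)
        ge = rng.normal(0, np.sqrt(var_ge), (n_geno, n_env))
        rows = []
        for i in range(n_geno):
            for j in range(n_env):
                for r in range(n_rep):
                    rows.append(
                        {"env": f"E{j}", "rep": r + 1, "entry_class": "parent",
                         "parent1": f"G{i:02d}", "parent2": None,
                         "Y": g[i] + ge[i, j] + rng.normal(0, np.sqrt(var_e))}
                    )
        return pd.DataFrame(rows)

    def test_no_noise_gives_one(self):
        data = self.simulate(1.0, 0.0, 0.0)
        data["Y"] = data.groupby("parent1")["Y"].transform("mean")  # kill GE+eps
        assert dl.repeatability(data, "Y", "parent") == pytest.approx(1.0)

    def test_no_genetic_variance_gives_zero_ish(self):
        data = self.simulate(0.0, 0.0, 1.0, seed=4)
        assert dl.repeatability(data, "Y", "parent") < 0.2

    def test_matches_plug_in_formula_on_simulated_components(self):
        var_g, var_ge, var_e, n_env, n_rep = 1.0, 0.4, 0.6, 2, 3
        expected = var_g / (var_g + var_ge / n_env + var_e / (n_env * n_rep))
        vals = [
            dl.repeatability(self.simulate(var_g, var_ge, var_e, n_geno=60, seed=s),
                             "Y", "parent")
            for s in range(8)
        ]
        assert abs(np.mean(vals) - expected) < 0.1

    def test_single_environment_rejected(self):
        data = self.simulate(1.0, 0.0, 1.0)
        data = data[data["env"] == "E0"]
        with pytest.raises(ValueError, match="environment"):
            dl.repeatability(data, "Y", "parent")
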