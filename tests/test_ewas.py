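"""Design encoding, OLS oracle equivalences, and the random-intercept REML fit."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ewaskit.datatypes import ValidationError
from ewaskit.ewas import (
    RandomInterceptREML,
    build_design,
    fit_probe_lmm,
    fit_probe_ols,
    run_cohort_ewas,
)

from conftest import two_cohort_config
from ewaskit.simulate import generate_cohorts, generate_manifest


def _sheet(n, sexes=("F", "M"), chips=2, positions=4, statuses=("current", "never"),
           family=False, seed=0):
    rng = np.random.default_rng(seed)
    sheet = pd.DataFrame(
        {
            "cohort": "T",
            "smoking_status": rng.choice(statuses, size=n),
            "sex": rng.choice(sexes, size=n),
            "age": rng.normal(50, 5, n),
            "bmi": rng.normal(26, 4, n),
            "monocyte": rng.uniform(0.05, 0.15, n),
            "granulocyte": rng.uniform(0.5, 0.7, n),
            "nk": rng.uniform(0.02, 0.08, n),
            "cd8_naive": rng.uniform(0.02, 0.08, n),
            "chip_id": rng.choice([f"c{k}" for k in range(chips)], size=n),
            "chip_position": rng.choice([f"P{k}" for k in range(positions)], size=n),
            "family_id": [f"f{i // 2}" for i in range(n)] if family else "",
            "zygosity": "none",
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )
    return sheet


class TestBuildDesign:
    def test_single_sex_cohort_has_no_sex_column(self):
        des = build_design(_sheet(60, sexes=("F",)), "current_vs_never")
        assert "sex_M" not in des.columns
        assert any("sex" in w for w in des.warnings)

    def test_reference_coded_chip_and_position(self):
        des = build_design(_sheet(64, chips=2, positions=4), "current_vs_never")
        chip_cols = [c for c in des.columns if c.startswith("chip_id=")]
        pos_cols = [c for c in des.columns if c.startswith("chip_position=")]
        assert len(chip_cols) == 1 and len(pos_cols) == 3

    def test_constant_smoking_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            build_design(_sheet(30, statuses=("never",)), "current_vs_never")

    def test_contrast_subsets_samples(self):
        sheet = _sheet(90, statuses=("current", "former", "never"))
        des = build_design(sheet, "former_vs_never")
        kept = sheet.loc[des.sample_ids, "smoking_status"]
        assert set(kept.unique()) == {"former", "never"}

    def test_age_included_on_request(self):
        assert "age" in build_design(_sheet(40), "current_vs_never",
                                     include_age=True).columns


class TestFitProbeOls:
    def test_perfect_fit(self):
        des = build_design(_sheet(50, chips=1, positions=1), "current_vs_never")
        y = des.X[:, des.smoking_idx].astype(float)
        est, se, p, n = fit_probe_ols(y, des)
        assert est == pytest.approx(1.0, abs=1e-10)
        assert p < 1e-10

    def test_two_group_case_equals_t_test(self, rng):
        """No covariates: estimate is the mean difference, p the pooled t-test p."""
        sheet = _sheet(80, sexes=("F",), chips=1, positions=1)
        des = build_design(sheet, "current_vs_never")
        keep = [i for i, c in enumerate(des.columns) if c in ("intercept", "smoking")]
        des.X, des.columns = des.X[:, keep], ["intercept", "smoking"]
        des.smoking_idx = 1
        y = rng.standard_normal(des.n)
        g = des.X[:, 1] == 1
        est, se, p, n = fit_probe_ols(y, des)
        t, p_t = stats.ttest_ind(y[g], y[~g])
        assert est == pytest.approx(y[g].mean() - y[~g].mean(), abs=1e-12)
        assert p == pytest.approx(p_t, abs=1e-12)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        des = build_design(_sheet(100), "current_vs_never")
        y = rng.standard_normal(des.n)
        est, se, p, n = fit_probe_ols(y, des)
        fit = sm.OLS(y, des.X).fit()
        assert est == pytest.approx(fit.params[des.smoking_idx], abs=1e-10)
        assert se == pytest.approx(fit.bse[des.smoking_idx], abs=1e-10)
        assert p == pytest.approx(fit.pvalues[des.smoking_idx], abs=1e-10)

    def test_null_p_values_uniform(self):
        """1000 independent null responses: ~5% fall below 0.05."""
        from ewaskit.ewas import _ols_many

        rng = np.random.default_rng(42)
        des = build_design(_sheet(100), "current_vs_never")
        Y = rng.standard_normal((1000, des.n))
        _, _, pvals, _ = _ols_many(Y, des)
        assert abs(np.mean(pvals < 0.05) - 0.05) < 0.02

    def test_collinear_covariate_dropped_smoking_kept(self):
        des = build_design(_sheet(60), "current_vs_never")
        des.X = np.column_stack([des.X, des.X[:, 0] * 2.0])  # duplicate intercept
        des.columns = des.columns + ["dup"]
        y = np.random.default_rng(0).standard_normal(des.n)
        est, se, p, n = fit_probe_ols(y, des)
        assert np.isfinite(est) and se > 0

    def test_missing_values_dropped(self, rng):
        des = build_design(_sheet(90), "current_vs_never")
        y = rng.standard_normal(des.n)
        y[:5] = np.nan
        est, se, p, n = fit_probe_ols(y, des)
        assert n == des.n - 5


class TestFitProbeLmm:
    def _family_design(self, n=200, seed=1):
        sheet = _sheet(n, family=True, seed=seed)
        return build_design(sheet, "current_vs_never")

    def test_matches_mixedlm(self, rng):
        """Cross-check against the statsmodels REML implementation."""
        import statsmodels.api as sm

        des = self._family_design(240, seed=2)
        fam = np.asarray(des.groups)
        fam_eff = rng.standard_normal(fam.max() + 1) * 0.7
        y = fam_eff[fam] + rng.standard_normal(des.n)
        est, se, p, n, info = fit_probe_lmm(y, des)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, des.X, groups=fam).fit(reml=True)
        assert est == pytest.approx(fit.params[des.smoking_idx], abs=1e-6)
        assert se == pytest.approx(fit.bse[des.smoking_idx], rel=0.02)
        assert info["sigma_g2"] == pytest.approx(
            float(np.asarray(fit.cov_re)[0, 0]), rel=0.02
        )

    def test_zero_group_variance_matches_ols(self):
        """Anti-correlated pairs push the group variance to the boundary."""
        rng = np.random.default_rng(3)
        des = self._family_design(120, seed=3)
        v = rng.standard_normal(des.n // 2)
        y = np.empty(des.n)
        y[0::2], y[1::2] = v, -v  # within-pair anticorrelation
        est, se, p, n, info = fit_probe_lmm(y, des)
        est0, se0, p0, _ = fit_probe_ols(y, des)
        assert info["sigma_g2"] == 0.0
        assert est == pytest.approx(est0, abs=1e-6)
        assert se == pytest.approx(se0, abs=1e-6)
        assert p == pytest.approx(p0, abs=1e-6)

    def test_singleton_groups_equal_ols(self, rng):
        sheet = _sheet(80, family=False, seed=5)
        sheet["family_id"] = [f"f{i}" for i in range(80)]  # all singletons
        des = build_design(sheet, "current_vs_never")
        y = rng.standard_normal(des.n)
        est, se, p, n, info = fit_probe_lmm(y, des)
        est0, se0, p0, _ = fit_probe_ols(y, des)
        assert (est, se) == pytest.approx((est0, se0), abs=1e-10)
        assert info["fallback"] == "ols"

    def test_family_correlation_inflates_se_vs_ols(self):
        """ICC 0.6 across 200 families with family-constant smoking: the
        mixed SE exceeds the naive OLS SE (no within-pair contrasts exist
        to offset the clustering penalty)."""
        rng = np.random.default_rng(6)
        sheet = _sheet(400, family=True, seed=6)
        fam_ids = sheet["family_id"].to_numpy()
        first_status = sheet.groupby("family_id")["smoking_status"].first()
        sheet["smoking_status"] = first_status.loc[fam_ids].to_numpy()
        des = build_design(sheet, "current_vs_never")
        fam = np.asarray(des.groups)
        icc = 0.6
        fam_eff = rng.standard_normal(fam.max() + 1) * np.sqrt(icc)
        y = fam_eff[fam] + rng.standard_normal(des.n) * np.sqrt(1 - icc)
        _, se_lmm, _, _, info = fit_probe_lmm(y, des)
        _, se_ols, _, _ = fit_probe_ols(y, des)
        assert info["sigma_g2"] > 0
        assert se_lmm > se_ols

    def test_satterthwaite_df_within_bounds(self, rng):
        des = self._family_design(200, seed=7)
        fam = np.asarray(des.groups)
        y = rng.standard_normal(fam.max() + 1)[fam] * 0.8 + rng.standard_normal(des.n)
        _, _, _, _, info = fit_probe_lmm(y, des)
        assert 1 <= info["df"] <= des.n


class TestRunCohortEwas:
    def test_spiked_effect_recovered_on_raw_scale(self, study):
        truth = study["truth"]
        strong = truth.spiked[
            (truth.spiked["true_effect"].abs() > 0.1) & ~truth.spiked["heterogeneous"]
        ]
        res = study["cohort_results"][3]  # largest smoker count cohort
        for pid, row in strong.iterrows():
            est = res.table.at[pid, "estimate_raw"]
            se = res.table.at[pid, "se_raw"]
            assert abs(est - row["true_effect"]) < 4 * se

    def test_cohort_lambda_near_one_on_null_probes(self, null_run):
        from ewaskit.meta import genomic_lambda

        lam = genomic_lambda(null_run["cohort_results"][0].table["p"].dropna())
        assert 0.9 < lam < 1.1

    def test_no_normalize_equals_raw(self, tiny_dataset):
        res = run_cohort_ewas(tiny_dataset["datasets"][0], "current_vs_never",
                              normalize=False)
        assert np.allclose(res.table["estimate"], res.table["estimate_raw"])

    def test_sign_consistency_normalized_vs_raw(self, study):
        """Rank-INT is monotone: clearly significant probes agree in sign."""
        for res in study["cohort_results"]:
            t = res.table.dropna()
            strong = t[np.abs(t["estimate"] / t["se"]) > 2]
            assert (np.sign(strong["estimate"]) == np.sign(strong["estimate_raw"])).all()

    def test_permuted_labels_destroy_association(self, study):
        """Max |z| over spiked probes falls below the Bonferroni bound."""
        cfg = study["config"]
        truth = study["truth"]
        ds = study["datasets"][3].subset_probes(truth.spiked.index)
        z_bound = stats.norm.isf(0.05 / cfg.n_probes / 2)
        rng = np.random.default_rng(13)
        ok = 0
        for rep in range(10):
            perm = ds.samples.copy()
            perm["smoking_status"] = rng.permutation(
                perm["smoking_status"].to_numpy()
            )
            from ewaskit.datatypes import MethylationDataset

            pds = MethylationDataset(ds.betas, perm, ds.manifest, ds.name)
            res = run_cohort_ewas(pds, "current_vs_never")
            zmax = np.abs(res.table["estimate"] / res.table["se"]).max()
            ok += zmax < z_bound
        assert ok >= 9

    def test_missing_betas_handled(self):
        cfg = two_cohort_config(n_probes=40, n_spiked=0, missing_rate=0.03,
                                seed=15, cohort_sizes=(120, 120))
        ds, _ = generate_cohorts(cfg, generate_manifest(40, seed=15))
        res = run_cohort_ewas(ds[0], "current_vs_never")
        assert res.table["p"].notna().all()
        assert (res.table["n"] < ds[0].n_samples).any()
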