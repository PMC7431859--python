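import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from immunoselect import glmm
from immunoselect.phbr import PHBRMatrix
from immunoselect.simulate import SelectionTruth, simulate_mutations

from conftest import make_genotype


def tiny_matrix(n_pat=40, n_mut=12, seed=0, theta=0.0, beta2=0.0, intercept=-1.0):
    """A small scored study with scores drawn directly (no peptide scoring)."""
    rng = np.random.default_rng(seed)
    pids = [f"P{i:03d}" for i in range(n_pat)]
    mids = [f"M{j:02d}" for j in range(n_mut)]
    phbr_i = pd.DataFrame(rng.lognormal(0.5, 1.0, (n_pat, n_mut)), index=pids, columns=mids)
    phbr_ii = pd.DataFrame(rng.lognormal(1.5, 1.0, (n_pat, n_mut)), index=pids, columns=mids)
    phbr_i.index.name = phbr_ii.index.name = "patient_id"
    cohort = pd.DataFrame({
        "patient_id": pids,
        "sex": rng.choice(["male", "female"], size=n_pat),
        "age_years": rng.normal(60, 12, n_pat).round(1),
        "tumor_type": "SYN",
    })
    truth = SelectionTruth(beta2=beta2, theta_eta=theta, intercept=intercept)
    occ = simulate_mutations(cohort, phbr_i, phbr_ii, truth, "sex", seed=seed + 1)
    expressed = occ  # treat everything observed as expressed for these fixtures
    return PHBRMatrix(phbr_i, phbr_ii, occ, expressed), cohort, truth


class TestBuildDesign:
    def test_hand_built_toy_design(self):
        """3 patients x 2 mutations: rows equal a hand-computed table."""
        pids, mids = ["P1", "P2", "P3"], ["M1", "M2"]
        phbr_i = pd.DataFrame([[1.0, 2.0], [4.0, 8.0], [16.0, 32.0]], index=pids, columns=mids)
        phbr_ii = pd.DataFrame([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]], index=pids, columns=mids)
        occ = pd.DataFrame([[1, 1], [1, 1], [0, 1]], index=pids, columns=mids)
        exp = pd.DataFrame([[1, 1], [1, 1], [0, 1]], index=pids, columns=mids)
        cohort = pd.DataFrame({"patient_id": pids, "sex": ["male", "female", "male"],
                               "age_years": [50.0, 60.0, 70.0], "tumor_type": "T"})
        matrix = PHBRMatrix(phbr_i, phbr_ii, occ, exp)
        design = glmm.build_design(matrix, cohort, glmm.ModelSpec(equation=1))
        assert len(design) == 6
        # centered log PHBR-I: log values minus their grand mean
        logs = np.log(phbr_i.to_numpy())
        np.testing.assert_allclose(design["phbr_i"].to_numpy(),
                                   (logs - logs.mean()).ravel())
        np.testing.assert_allclose(design["sex"].to_numpy(),
                                   np.repeat([0, 1, 0] - np.mean([0, 1, 0]), 2))
        np.testing.assert_allclose(design["y"].to_numpy(), [1, 1, 1, 1, 0, 1])

    def test_mutation_expressed_once_dropped(self):
        pids = ["P1", "P2", "P3"]
        mids = ["M1", "M2"]
        ones = pd.DataFrame(1.0, index=pids, columns=mids)
        occ = pd.DataFrame([[1, 1], [1, 0], [0, 1]], index=pids, columns=mids)
        exp = pd.DataFrame([[1, 0], [1, 0], [0, 1]], index=pids, columns=mids)
        cohort = pd.DataFrame({"patient_id": pids, "sex": ["male", "female", "male"],
                               "age_years": [50.0, 60.0, 70.0], "tumor_type": "T"})
        matrix = PHBRMatrix(ones, ones, occ, exp)
        design = glmm.build_design(matrix, cohort, glmm.ModelSpec(equation=1))
        # M2 has expressed occurrence count 1 -> dropped; P3 then has no
        # observed expressed driver among retained mutations
        assert set(design["mutation_id"]) == {"M1"}

    def test_single_sex_cohort_flags_sex_terms(self):
        matrix, cohort, _ = tiny_matrix(seed=3, intercept=-0.5)
        cohort["sex"] = "female"
        design = glmm.build_design(matrix, cohort, glmm.ModelSpec(equation=1))
        assert np.all(design["sex"] == 0.0)
        fit = glmm.fit_mixed_logit(design, glmm.ModelSpec(equation=1))
        assert set(fit.dropped_terms) == {"sex", "phbr_i:sex", "phbr_ii:sex"}
        assert not fit.identifiable
        # the age model is unaffected
        fit2 = glmm.fit_mixed_logit(design, glmm.ModelSpec(equation=2))
        assert fit2.identifiable


class TestFitMixedLogit:
    def test_theta_zero_data_matches_plain_logistic_oracle(self):
        """With no random-effect variance the fit reproduces ordinary logistic."""
        matrix, cohort, _ = tiny_matrix(n_pat=150, n_mut=20, seed=7,
                                        theta=0.0, beta2=0.4, intercept=-1.0)
        spec = glmm.ModelSpec(equation=1)
        design = glmm.build_design(matrix, cohort, spec)
        fit = glmm.fit_mixed_logit(design, spec)
        X, kept, _ = glmm._design_matrix(design, spec.terms)
        oracle = sm.Logit(design["y"], sm.add_constant(X)).fit(disp=0)
        assert fit.theta_eta < 0.15
        np.testing.assert_allclose(fit.estimates, oracle.params, atol=2e-2)
        # within 2 SE, per coefficient
        assert np.all(np.abs(fit.estimates - oracle.params.to_numpy())
                      < 2 * oracle.bse.to_numpy())

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_lme4_glmer_on_small_study(self, tmp_path):
        """Independent cross-check: lme4's adaptive-quadrature GLMM."""
        matrix, cohort, _ = tiny_matrix(n_pat=60, n_mut=15, seed=11,
                                        theta=0.5, beta2=0.5, intercept=-1.0)
        spec = glmm.ModelSpec(equation=1)
        design = glmm.build_design(matrix, cohort, spec)
        fit = glmm.fit_mixed_logit(design, spec)
        d = design.copy()
        d["x1s"] = d["phbr_i"] * d["sex"]
        d["x2s"] = d["phbr_ii"] * d["sex"]
        d.to_csv(tmp_path / "design.tsv", sep="\t", index=False)
        script = f"""
        suppressMessages(library(lme4))
        d <- read.delim("{tmp_path / 'design.tsv'}")
        f <- glmer(y ~ phbr_i + phbr_ii + sex + x1s + x2s + (1|patient_id),
                   data=d, family=binomial, nAGQ=25)
        co <- summary(f)$coefficients
        cat(co[,1], sqrt(unlist(VarCorr(f))), sep="\\n")
        """
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                             timeout=300)
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        r_coefs, r_theta = np.array(vals[:-1]), vals[-1]
        np.testing.assert_allclose(fit.estimates, r_coefs, atol=5e-3)
        assert fit.theta_eta == pytest.approx(r_theta, abs=5e-3)

    def test_loglik_trace_monotone_nondecreasing(self):
        matrix, cohort, _ = tiny_matrix(n_pat=80, n_mut=15, seed=13,
                                        theta=0.4, beta2=0.3, intercept=-1.0)
        spec = glmm.ModelSpec(equation=1)
        fit = glmm.fit_mixed_logit(glmm.build_design(matrix, cohort, spec), spec)
        trace = fit.loglik_trace
        # L-BFGS-B accepted iterates improve; line-search probes may not.
        # The running maximum must end at the reported optimum.
        assert np.max(trace) == pytest.approx(fit.loglik, abs=1e-8)
        assert trace[-1] >= trace[0]

    def test_sex_recoding_equivariance(self):
        """Recoding sex 0/1 -> 1/0 flips main and interaction signs only."""
        matrix, cohort, _ = tiny_matrix(n_pat=100, n_mut=15, seed=17,
                                        theta=0.3, beta2=0.4, intercept=-1.0)
        spec = glmm.ModelSpec(equation=1)
        fit = glmm.fit_mixed_logit(glmm.build_design(matrix, cohort, spec), spec)
        flipped = cohort.copy()
        flipped["sex"] = cohort["sex"].map({"male": "female", "female": "male"})
        fit2 = glmm.fit_mixed_logit(glmm.build_design(matrix, flipped, spec), spec)
        assert fit2.coef("sex") == pytest.approx(-fit.coef("sex"), abs=1e-4)
        assert fit2.coef("phbr_ii:sex") == pytest.approx(-fit.coef("phbr_ii:sex"), abs=1e-4)
        assert fit2.coef("phbr_ii") == pytest.approx(fit.coef("phbr_ii"), abs=1e-4)
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-6)

    def test_constant_response_rejected(self):
        matrix, cohort, _ = tiny_matrix(seed=19, intercept=8.0)  # all y = 1
        spec = glmm.ModelSpec(equation=1)
        design = glmm.build_design(matrix, cohort, spec)
        if design["y"].min() == design["y"].max():
            with pytest.raises(ValueError, match="constant"):
                glmm.fit_mixed_logit(design, spec)


class TestQuartileOddsRatio:
    def test_closed_form_ln2_unit_gap(self):
        """beta = ln 2 with unit interquartile gap gives OR = 2 exactly."""
        design = pd.DataFrame({"phbr_ii": np.concatenate([np.zeros(2), np.ones(2)])})
        fit = _stub_fit(beta=np.log(2.0), se=0.1)
        orr, (lo, hi) = glmm.quartile_odds_ratio(fit, "phbr_ii", design)
        assert orr == pytest.approx(2.0)
        assert lo < orr < hi

    def test_zero_coefficient_gives_or_one(self):
        design = pd.DataFrame({"phbr_ii": [0.0, 0.0, 1.0, 1.0]})
        fit = _stub_fit(beta=0.0, se=0.1)
        orr, (lo, hi) = glmm.quartile_odds_ratio(fit, "phbr_ii", design)
        assert orr == pytest.approx(1.0)
        assert lo <= 1.0 <= hi

    def test_degenerate_quartiles_flagged(self):
        design = pd.DataFrame({"phbr_ii": [1.0, 1.0, 1.0, 1.0]})
        fit = _stub_fit(beta=1.0, se=0.1)
        assert glmm.quartile_odds_ratio(fit, "phbr_ii", design) == (1.0, (1.0, 1.0))

    def test_matches_predicted_odds_oracle_on_real_fit(self, scored_study):
        """OR equals odds(q75)/odds(q25) from the fitted linear predictor."""
        spec = glmm.ModelSpec(equation=1)
        design = glmm.build_design(scored_study["matrix"], scored_study["cohort"], spec)
        fit = glmm.fit_mixed_logit(design, spec)
        for score in ("phbr_i", "phbr_ii"):
            orr, _ = glmm.quartile_odds_ratio(fit, score, design)
            q25, q75 = np.percentile(design[score], [25, 75])
            b0, b = fit.coef("intercept"), fit.coef(score)
            odds = lambda x: np.exp(b0 + b * x)  # other covariates at 0
            assert orr == pytest.approx(odds(q75) / odds(q25), rel=1e-10)


def _stub_fit(beta: float, se: float) -> glmm.ModelFit:
    return glmm.ModelFit(
        equation=1, terms=("phbr_ii",), estimates=np.array([0.0, beta]),
        std_errors=np.array([0.1, se]), covariance=np.eye(2) * se**2,
        wald_z=np.array([0.0, 1.0]), wald_p=np.array([1.0, 0.5]),
        theta_eta=0.0, theta_eta_se=float("nan"), loglik=0.0, converged=True,
        n_patients=4, n_mutations=1, n_cells=4,
    )


class TestFitAllModels:
    def test_four_equations_fit_and_tidy_table(self, scored_study):
        fits, table = glmm.fit_all_models(scored_study["matrix"], scored_study["cohort"])
        assert set(fits) == {1, 2, 3, 4}
        ok = {eq for eq, f in fits.items() if not isinstance(f, Exception)}
        assert ok == {1, 2, 3, 4}
        assert {"model", "term", "estimate", "se", "z", "p", "theta_eta"} <= set(table.columns)
        for eq in ok:
            terms = set(table.loc[table["model"] == eq, "term"])
            assert terms == {"intercept", *glmm.EQUATION_TERMS[eq]}

    def test_failures_isolated_per_model(self):
        matrix, cohort, _ = tiny_matrix(seed=23, intercept=-1.0)
        cohort_bad = cohort.copy()
        cohort_bad["age_years"] = "not-a-number"
        fits, table = glmm.fit_all_models(matrix, cohort_bad, equations=(1, 2))
        assert isinstance(fits[2], Exception)
        assert isinstance(fits[1], Exception)  # age is parsed in build_design for all eqs
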