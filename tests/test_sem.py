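"""Covariance-structure engine: model building, implied covariance, ML
discrepancy, fitting and fit indices."""

import numpy as np
import pandas as pd
import pytest

from fadspath import sem, synthetic
from fadspath.sem import ModelNotRecursiveError, PathModelSpec, SpecError

from conftest import random_recursive_model


class TestBuildModel:
    def test_core_model_parses_with_six_edges(self):
        spec = sem.build_model({
            "variables": ["SNP", "ARA", "BMI", "SBP"],
            "edges": [["SNP", "ARA"], ["SNP", "BMI"], ["ARA", "BMI"],
                      ["SNP", "SBP"], ["ARA", "SBP"], ["BMI", "SBP"]],
        })
        assert len(spec.edges) == 6
        assert spec.exogenous == ("SNP",)
        assert spec.endogenous == ("ARA", "BMI", "SBP")

    def test_shipped_spec_files_load(self):
        from importlib import resources

        for mid in ("1a", "2a", "3a", "4a", "1b", "2b", "3b", "4b"):
            ref = resources.files("fadspath") / "specs" / f"model_{mid}.yaml"
            spec = sem.build_model(str(ref))
            assert len(spec.edges) == 6 and len(spec.variables) == 4

    def test_single_edge_parameter_count(self):
        spec = sem.build_model({"variables": ["X", "Y"], "edges": [["X", "Y"]]})
        assert spec.n_free == 3  # 1 structural + 2 variances
        assert spec.degrees_of_freedom() == 0

    def test_cycle_rejected(self):
        with pytest.raises(ModelNotRecursiveError):
            sem.build_model({"variables": ["X", "Y"],
                             "edges": [["X", "Y"], ["Y", "X"]]})

    def test_duplicate_slot_rejected(self):
        with pytest.raises(SpecError):
            PathModelSpec(variables=("X", "Y"), edges=(("X", "Y"), ("X", "Y")))

    def test_categorical_expansion_reference_coding(self):
        spec = sem.build_model({
            "variables": ["country", "isced", "BMI"],
            "edges": [["country", "BMI"], ["isced", "BMI"]],
            "categorical": {
                "country": ["EE", "DE", "HU", "IT", "ES", "SE"],
                "isced": ["low", "medium", "high"],
            },
        })
        country_vars = [v for v in spec.variables if v.startswith("country_")]
        isced_vars = [v for v in spec.variables if v.startswith("isced_")]
        assert len(country_vars) == 5 and len(isced_vars) == 2
        assert len(spec.edges) == 7
        assert "country_EE" not in spec.variables  # first level is reference


class TestImpliedCovariance:
    def test_no_edges_returns_s(self):
        spec = PathModelSpec(variables=("X", "Y"), edges=(("X", "Y"),))
        # b=0: Sigma should equal diag of variances
        sigma = sem.implied_covariance(spec, [0.0, 2.0, 3.0])
        assert np.allclose(sigma, np.diag([2.0, 3.0]))

    def test_single_edge_closed_form(self):
        spec = PathModelSpec(variables=("X", "Y"), edges=(("X", "Y"),))
        b = 0.7
        sigma = sem.implied_covariance(spec, [b, 1.0, 1.0])
        assert sigma[0, 0] == pytest.approx(1.0)
        assert sigma[0, 1] == pytest.approx(b)
        assert sigma[1, 1] == pytest.approx(1.0 + b**2)

    def test_matches_simulation_for_random_recursive_model(self):
        """Sigma(theta) equals the covariance of draws from the structural
        equations themselves (independent brute-force simulation)."""
        rng = np.random.default_rng(30)
        spec, paths, _ = random_recursive_model(rng, n_vars=5)
        ne = len(spec.edges)
        theta = np.zeros(spec.n_free)
        resid_sd = {}
        n = 1_000_000
        draws = {}
        # simulate the system directly, tracking residual SDs that give
        # unit variance per node (same convention the theta encodes)
        import networkx as nx

        g = spec.graph()
        for v in nx.topological_sort(g):
            parents = list(g.predecessors(v))
            if not parents:
                draws[v] = rng.standard_normal(n)
                resid_sd[v] = 1.0
                continue
            lin = sum(paths[(q, v)] * draws[q] for q in parents)
            sys_var = float(np.var(lin))
            rv = max(1.0 - sys_var, 0.05)
            draws[v] = lin + rng.standard_normal(n) * np.sqrt(rv)
            resid_sd[v] = rv
        for k, e in enumerate(spec.edges):
            theta[k] = paths[e]
        for i, v in enumerate(spec.variables):
            theta[ne + i] = resid_sd[v]
        sigma = sem.implied_covariance(spec, theta)
        X = np.column_stack([draws[v] for v in spec.variables])
        s_emp = np.cov(X, rowvar=False)
        assert np.abs(sigma - s_emp).max() < 3 * 2.0 / np.sqrt(n) + 0.005

    def test_wrong_theta_length_rejected(self):
        spec = PathModelSpec(variables=("X", "Y"), edges=(("X", "Y"),))
        with pytest.raises(ValueError):
            sem.implied_covariance(spec, [1.0])


class TestMLDiscrepancy:
    def test_zero_iff_equal(self):
        s = np.array([[2.0, 0.5], [0.5, 1.0]])
        assert sem.ml_discrepancy(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_case(self):
        assert sem.ml_discrepancy(np.array([[2.0]]), np.array([[1.0]])) == pytest.approx(
            np.log(2) + 0.5 - 1.0, abs=1e-12
        )

    def test_nonnegative_on_random_pd_pairs(self):
        rng = np.random.default_rng(32)
        for _ in range(300):
            p = rng.integers(1, 5)
            a = rng.standard_normal((p, p + 2))
            b = rng.standard_normal((p, p + 2))
            assert sem.ml_discrepancy(a @ a.T, b @ b.T) >= -1e-10

    def test_non_pd_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            sem.ml_discrepancy(np.array([[1.0, 2.0], [2.0, 1.0]]), np.eye(2))


class TestFit:
    def test_saturated_model_fits_exactly(self, ara_cohort_small):
        cohort, _ = ara_cohort_small
        spec = sem.build_model({
            "variables": ["SNP", "ARA", "BMI", "SBP"],
            "edges": [["SNP", "ARA"], ["SNP", "BMI"], ["ARA", "BMI"],
                      ["SNP", "SBP"], ["ARA", "SBP"], ["BMI", "SBP"]],
        })
        fitted = sem.fit(spec, cohort)
        assert fitted.converged
        assert fitted.f_min == pytest.approx(0.0, abs=1e-10)
        assert fitted.df == 0

    def test_ols_oracle_equivalence(self):
        """For any recursive model with uncorrelated residuals the ML
        estimates equal per-equation OLS."""
        rng = np.random.default_rng(33)
        for trial in range(20):
            spec, paths, marginals = random_recursive_model(rng)
            config = synthetic.SyntheticConfig(
                n_subjects=400, maf=0.3, std_paths=paths,
                marginals=marginals, seed=1000 + trial,
            )
            cohort, _ = synthetic.generate_cohort(config)
            fitted = sem.fit(spec, cohort)
            X = cohort[list(spec.variables)].to_numpy()
            s = np.cov(X, rowvar=False, ddof=1)
            idx = {v: i for i, v in enumerate(spec.variables)}
            for v in spec.endogenous:
                parents = [a for a, b in spec.edges if b == v]
                ii = [idx[q] for q in parents]
                beta = np.linalg.solve(s[np.ix_(ii, ii)], s[ii, idx[v]])
                for q, b_ols in zip(parents, beta):
                    assert fitted.coefficient(q, v) == pytest.approx(b_ols, abs=1e-6)

    def test_standardized_solution_scale_invariant(self, ara_cohort_small):
        cohort, _ = ara_cohort_small
        spec = sem.build_model({
            "variables": ["SNP", "ARA", "BMI", "SBP"],
            "edges": [["SNP", "ARA"], ["ARA", "BMI"], ["BMI", "SBP"]],
        })
        f1 = sem.fit(spec, cohort)
        rescaled = cohort.copy()
        rescaled["ARA"] = rescaled["ARA"] * 100 - 7.0
        rescaled["SBP"] = rescaled["SBP"] / 3.0 + 1.0
        f2 = sem.fit(spec, rescaled)
        for e in spec.edges:
            assert f1.std_solution[e] == pytest.approx(f2.std_solution[e], abs=1e-7)
        assert f1.f_min == pytest.approx(f2.f_min, abs=1e-10)

    def test_f_min_invariant_to_variable_order(self, ara_cohort_small):
        cohort, _ = ara_cohort_small
        edges = (("SNP", "ARA"), ("ARA", "BMI"), ("BMI", "SBP"))
        f1 = sem.fit(PathModelSpec(variables=("SNP", "ARA", "BMI", "SBP"), edges=edges),
                     cohort)
        f2 = sem.fit(PathModelSpec(variables=("SBP", "BMI", "SNP", "ARA"), edges=edges),
                     cohort)
        assert f1.f_min == pytest.approx(f2.f_min, abs=1e-9)

    def test_parameter_recovery_large_n(self):
        config = synthetic.default_config("2a", n_subjects=100_000, seed=40)
        cohort, ledger = synthetic.generate_cohort(config)
        spec = sem.build_model({
            "variables": ["SNP", "ARA", "BMI", "SBP"],
            "edges": [["SNP", "ARA"], ["SNP", "BMI"], ["ARA", "BMI"],
                      ["SNP", "SBP"], ["ARA", "SBP"], ["BMI", "SBP"]],
        })
        fitted = sem.fit(spec, cohort)
        for edge, truth in ledger.direct.items():
            assert fitted.std_solution[edge] == pytest.approx(truth, abs=0.02)

    def test_too_few_subjects_rejected(self, ara_cohort_small):
        cohort, _ = ara_cohort_small
        spec = sem.build_model({"variables": ["SNP", "ARA", "BMI", "SBP"],
                                "edges": [["SNP", "ARA"]]})
        with pytest.raises(ValueError, match="not greater"):
            sem.fit(spec, cohort.head(4))

    def test_missing_values_rejected(self, ara_cohort_small):
        cohort, _ = ara_cohort_small
        bad = cohort.head(100).copy()
        bad.loc[bad.index[0], "ARA"] = np.nan
        spec = sem.build_model({"variables": ["SNP", "ARA"], "edges": [["SNP", "ARA"]]})
        with pytest.raises(ValueError, match="missing"):
            sem.fit(spec, bad)


class TestFitIndices:
    def test_saturated_model_indices(self, ara_cohort_small):
        cohort, _ = ara_cohort_small
        spec = sem.build_model({
            "variables": ["SNP", "ARA", "BMI", "SBP"],
            "edges": [["SNP", "ARA"], ["SNP", "BMI"], ["ARA", "BMI"],
                      ["SNP", "SBP"], ["ARA", "SBP"], ["BMI", "SBP"]],
        })
        fi = sem.fit_indices(sem.fit(spec, cohort))
        assert fi.saturated
        assert fi.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fi.cfi == 1.0 and fi.rmsea == 0.0

    def test_independence_model_has_cfi_zero(self, ara_cohort_small):
        cohort, _ = ara_cohort_small
        variables = ("SNP", "ARA", "BMI", "SBP")
        spec = PathModelSpec(
            variables=variables, edges=(),
            fixed_zero=tuple(
                (a, b) for i, a in enumerate(variables) for b in variables[i + 1:]
            ),
        )
        fitted = sem.fit(spec, cohort)
        fi = sem.fit_indices(fitted)
        assert fi.df == fi.baseline_df
        assert fi.chi2 == pytest.approx(fi.baseline_chi2, rel=1e-6)
        assert fi.cfi == pytest.approx(0.0, abs=1e-9)

    def test_rmsea_zero_when_chi2_below_df(self, chain_fit):
        fitted, _ = chain_fit
        fi = sem.fit_indices(fitted)
        assert fi.df == 3
        if fi.chi2 <= fi.df:
            assert fi.rmsea == 0.0
        else:
            assert fi.rmsea > 0.0
        # well-specified model at n=10000 should pass all published cutoffs
        assert fi.all_pass
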