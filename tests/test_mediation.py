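"""Path enumeration, effect decomposition, indirect-effect inference and
Benjamini-Hochberg FDR control."""

import itertools

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from fadspath import mediation, published, sem
from fadspath.sem import PathModelSpec

CORE = {
    ("SNP", "FA"), ("SNP", "BMI"), ("FA", "BMI"),
    ("SNP", "BP"), ("FA", "BP"), ("BMI", "BP"),
}


def dfs_paths(edges, source, target):
    """Brute-force recursive enumeration oracle."""
    out = []

    def walk(node, acc):
        if node == target:
            out.append(tuple(acc))
            return
        for s, t in edges:
            if s == node:
                walk(t, acc + [t])

    walk(source, [source])
    return sorted(out)


class TestEnumeratePaths:
    def test_core_model_snp_to_bp(self):
        paths = mediation.enumerate_paths({e: 1.0 for e in CORE}, "SNP", "BP")
        assert sorted(paths) == sorted([
            ("SNP", "BP"),
            ("SNP", "FA", "BP"),
            ("SNP", "BMI", "BP"),
            ("SNP", "FA", "BMI", "BP"),
        ])

    def test_disconnected_pair_empty(self):
        g = {("A", "B"): 1.0, ("C", "D"): 1.0}
        assert mediation.enumerate_paths(g, "A", "D") == []

    def test_unknown_variable_raises(self):
        with pytest.raises(KeyError):
            mediation.enumerate_paths({("A", "B"): 1.0}, "A", "Z")

    def test_matches_dfs_oracle_on_random_dags(self):
        import networkx as nx

        rng = np.random.default_rng(50)
        for _ in range(200):
            n = rng.integers(3, 9)
            nodes = [f"v{i}" for i in range(n)]
            edges = [
                (nodes[i], nodes[j])
                for i, j in itertools.combinations(range(n), 2)
                if rng.random() < 0.4
            ]
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            got = sorted(mediation.enumerate_paths(g, nodes[0], nodes[-1]))
            want = dfs_paths(edges, nodes[0], nodes[-1])
            assert got == want


class TestDecompose:
    @pytest.mark.parametrize("model", sorted(published.PUBLISHED_INDIRECT))
    def test_published_indirect_cells_reproduce(self, model):
        """Every printed indirect cell equals the sum of products of that
        model's printed direct effects, to the 3-dp printing precision."""
        coefs = published.MODEL_DIRECT_EFFECTS[model]
        for (source, target), printed in published.PUBLISHED_INDIRECT[model].items():
            dec = mediation.decompose(coefs, source, target)
            assert round(dec.total_indirect, 3) == pytest.approx(printed, abs=1e-9)

    def test_published_total_effect(self):
        dec = mediation.decompose(published.MODEL_DIRECT_EFFECTS["2a"], "SNP", "SBP")
        assert dec.direct == 0.077
        assert round(dec.total, 3) == published.TOTAL_EFFECT_SNP_SBP_ARA

    def test_single_edge_total_equals_direct(self):
        dec = mediation.decompose({("X", "Y"): 0.4}, "X", "Y")
        assert dec.total_indirect == 0.0
        assert dec.total == dec.direct == 0.4

    def test_total_identity_machine_exact(self):
        rng = np.random.default_rng(51)
        nodes = ["a", "b", "c", "d", "e"]
        coefs = {
            (nodes[i], nodes[j]): float(rng.normal())
            for i, j in itertools.combinations(range(5), 2)
        }
        for s, t in itertools.combinations(nodes, 2):
            dec = mediation.decompose(coefs, s, t)
            assert dec.total == dec.direct + dec.total_indirect  # exact float identity
            for chain, prod in dec.paths:
                expect = np.prod([coefs[e] for e in zip(chain[:-1], chain[1:])])
                assert prod == pytest.approx(expect, rel=1e-12)

    def test_missing_edge_coefficient_raises(self):
        spec = PathModelSpec(variables=("X", "M", "Y"),
                             edges=(("X", "M"), ("M", "Y"), ("X", "Y")))
        coefs = {("X", "M"): 0.5, ("X", "Y"): 0.1}  # no value for M->Y
        with pytest.raises(KeyError, match="M->Y"):
            mediation.decompose(coefs, "X", "Y", graph=spec.graph())


class TestIndirectSE:
    def test_sobel_closed_form(self, chain_fit):
        """With independent a and b the delta variance of a*b reduces to
        a^2 se_b^2 + b^2 se_a^2; with the fitted parameter covariance the
        general delta formula adds the cross term."""
        fitted, _ = chain_fit
        res = mediation.indirect_se(
            fitted, "SNP", "BMI", which="total_indirect",
            method="delta", standardized=False,
        )
        ia = fitted.spec.edges.index(("SNP", "ARA"))
        ib = fitted.spec.edges.index(("ARA", "BMI"))
        a, b = fitted.theta[ia], fitted.theta[ib]
        va, vb = fitted.vcov[ia, ia], fitted.vcov[ib, ib]
        cab = fitted.vcov[ia, ib]
        want = a**2 * vb + b**2 * va + 2 * a * b * cab
        assert res["se"] ** 2 == pytest.approx(want, rel=1e-4)
        assert res["estimate"] == pytest.approx(a * b, rel=1e-10)

    def test_null_path_gives_large_p(self):
        # generating SNP->ARA = 0: the indirect SNP->BMI effect is null
        from fadspath import synthetic

        paths = {("SNP", "ARA"): 0.0, ("ARA", "BMI"): 0.3}
        config = synthetic.SyntheticConfig(
            n_subjects=5000, maf=0.29, std_paths=paths, seed=52
        )
        cohort, _ = synthetic.generate_cohort(config)
        spec = PathModelSpec(variables=("SNP", "ARA", "BMI"),
                             edges=(("SNP", "ARA"), ("ARA", "BMI")))
        fitted = sem.fit(spec, cohort)
        res = mediation.indirect_se(fitted, "SNP", "BMI")
        assert res["p"] > 0.05

    def test_small_bootstrap_refused(self, chain_fit):
        fitted, cohort = chain_fit
        with pytest.raises(ValueError, match="100"):
            mediation.indirect_se(fitted, "SNP", "SBP", method="bootstrap",
                                  data=cohort, n_boot=50)

    def test_delta_and_bootstrap_agree(self, chain_fit):
        """Method agreement at n=10000: delta and bootstrap SEs for the
        three-edge indirect effect within 15%."""
        fitted, cohort = chain_fit
        delta = mediation.indirect_se(fitted, "SNP", "SBP")
        boot = mediation.indirect_se(
            fitted, "SNP", "SBP", method="bootstrap",
            data=cohort, n_boot=2000, seed=53,
        )
        assert boot["se"] == pytest.approx(delta["se"], rel=0.15)
        assert boot["estimate"] == pytest.approx(delta["estimate"], rel=1e-9)


class TestBHFDR:
    def test_hand_worked_step_up(self):
        res = mediation.bh_fdr([0.001, 0.01, 0.02, 0.9], q=0.05)
        assert res.rejected == {"0", "1", "2"}
        assert res.alpha_adj == 0.02  # 0.02 <= 3*0.05/4 = 0.0375

    def test_nothing_rejected(self):
        res = mediation.bh_fdr({"a": 1.0, "b": 1.0})
        assert res.rejected == frozenset() and res.alpha_adj == 0.0

    def test_single_test_reduces_to_alpha(self):
        assert mediation.bh_fdr([0.04]).rejected == {"0"}
        assert mediation.bh_fdr([0.06]).rejected == frozenset()

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            mediation.bh_fdr([])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            mediation.bh_fdr([0.5, 1.2])

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(54)
        for _ in range(200):
            m = rng.integers(1, 30)
            pvals = rng.random(m) ** rng.uniform(0.5, 3)
            res = mediation.bh_fdr(pvals, q=0.05)
            reject_sm, *_ = multipletests(pvals, alpha=0.05, method="fdr_bh")
            mine = np.array([str(i) in res.rejected for i in range(m)])
            assert (mine == reject_sm).all()

    def test_rejection_set_is_step_up_prefix(self):
        rng = np.random.default_rng(55)
        pvals = rng.random(20)
        res = mediation.bh_fdr(pvals)
        rejected_p = sorted(p for lab, p in zip(res.labels, res.pvalues)
                            if lab in res.rejected)
        kept_p = [p for lab, p in zip(res.labels, res.pvalues)
                  if lab not in res.rejected]
        if rejected_p and kept_p:
            assert max(rejected_p) <= min(kept_p)
        assert res.alpha_adj <= res.q or res.alpha_adj == 0.0
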