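import numpy as np
import pandas as pd
import pytest

import domblup as db
from domblup.coding import GenotypeMatrix
from domblup.reml import ModelSpec, VarianceComponents


def _codings(seed=0, n=50, k=200):
    cfg = db.SimConfig(n_animals=n, n_snps=k, n_sd_offspring=0, n_smgs_groups=0,
                       seed=seed)
    pop = db.simulate_population(cfg)
    cs = db.compute_codings(pop.genotypes, db.estimate_allele_frequencies(pop.genotypes))
    return pop, cs


VC = VarianceComponents(0.3, 0.1, {"C": 0.6})


class TestBuildMme:
    def test_ma_system_has_no_dominance_block(self):
        pop, cs = _codings(n=20, k=15)
        mme = db.build_mme(ModelSpec("MA"), cs, VC, pop.phenotypes)
        assert mme.size == 1 + 15
        assert not mme.has_dominance

    def test_toy_system_matches_hand_algebra(self):
        # two animals, one SNP with codes (0, 2); frequencies fixed at p = 0.5
        g = GenotypeMatrix(ids=["a", "b"], codes=np.array([[0], [2]]))
        cs = db.compute_codings(g, db.AlleleFrequencies([0.5]))
        y = np.array([1.0, 3.0])
        vc = VarianceComponents(0.5, 0.25, {"C": 1.0})
        mme = db.build_mme(ModelSpec("MAD"), cs, vc, y)
        # T = [1 | z | h] with z = (-1, 1), h = (-0.5, -0.5)
        T = np.array([[1.0, -1.0, -0.5], [1.0, 1.0, -0.5]])
        lhs = T.T @ T  # residual variance 1
        lhs[1, 1] += cs.s_a / 0.5  # lambda_a = s_a * sigma2_e / sigma2_a = 1
        lhs[2, 2] += cs.s_h / 0.25  # lambda_d = 1
        rhs = T.T @ y
        assert mme.lhs == pytest.approx(lhs, abs=1e-12)
        assert mme.rhs == pytest.approx(rhs, abs=1e-12)

    def test_lambda_invariance_under_common_scaling(self):
        pop, cs = _codings(n=30, k=20)
        vc2 = VarianceComponents(0.6, 0.2, {"C": 1.2})
        e1 = db.solve_direct(db.build_mme(ModelSpec("MAD"), cs, VC, pop.phenotypes))
        e2 = db.solve_direct(db.build_mme(ModelSpec("MAD"), cs, vc2, pop.phenotypes))
        assert e1.additive == pytest.approx(e2.additive, rel=1e-10)
        assert e1.dominance == pytest.approx(e2.dominance, rel=1e-10)

    def test_zero_additive_variance_rejected(self):
        pop, cs = _codings(n=10, k=5)
        with pytest.raises(ValueError, match="sigma2_a"):
            db.build_mme(ModelSpec("MA"), cs, VarianceComponents(0.0, 0, {"C": 1}),
                         pop.phenotypes)


class TestSolvers:
    def test_zero_rhs_gives_zero_effects(self):
        pop, cs = _codings(n=20, k=10)
        mme = db.build_mme(ModelSpec("MAD"), cs, VC, np.zeros(20))
        eff = db.solve_direct(mme)
        assert np.all(eff.additive == 0) and np.all(eff.dominance == 0)

    def test_direct_matches_explicit_inverse(self):
        pop, cs = _codings(n=15, k=8)
        mme = db.build_mme(ModelSpec("MAD"), cs, VC, pop.phenotypes)
        eff = db.solve_direct(mme)
        x = np.linalg.inv(mme.lhs) @ mme.rhs
        stacked = np.concatenate(
            [list(eff.intercepts.values()), eff.additive, eff.dominance]
        )
        assert stacked == pytest.approx(x, abs=1e-12)

    def test_snp_blup_equals_gblup_predictions(self):
        """Duality: animal predictions from the marker system equal GBLUP
        from the matched G / D1 system with the same variance ratios."""
        pop, cs = _codings(seed=3, n=50, k=200)
        y = pop.phenotypes
        n = len(y)
        for model, dom_attr, s_w in (("MA", None, None), ("MAD", "H", cs.s_h),
                                     ("MAD2", "M", cs.s_m)):
            spec = ModelSpec(model)
            mme = db.build_mme(spec, cs, VC, y)
            pred = db.predict_genetic_values(cs, db.solve_direct(mme))
            G = cs.Z @ cs.Z.T / cs.s_a
            V = VC.sigma2_a * G + VC.sigma2_e * np.eye(n)
            if dom_attr:
                W = getattr(cs, dom_attr)
                Dm = W @ W.T / s_w
                V = V + VC.sigma2_d * Dm
            X = np.ones((n, 1))
            Vinv = np.linalg.inv(V)
            b = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
            r = Vinv @ (y - X @ b)
            ua = VC.sigma2_a * G @ r
            assert pred.bv == pytest.approx(ua, abs=1e-6)
            if dom_attr:
                ud = VC.sigma2_d * Dm @ r
                assert pred.dominance_value == pytest.approx(ud, abs=1e-6)

    def test_jacobi_diagonal_system_one_iteration(self):
        mme = db.MMESystem(
            lhs=np.diag([2.0, 4.0]),
            rhs=np.array([2.0, 8.0]),
            k=2, n_intercepts=0, has_dominance=False, intercept_labels=[],
            lambda_a=1.0, lambda_d=None, spec=ModelSpec("MA"),
        )
        eff = db.solve_jacobi(mme, relaxation_1=1.0, relaxation_2=0.0)
        assert eff.additive == pytest.approx([1.0, 2.0])
        assert eff.iterations == 1

    def test_jacobi_agrees_with_direct(self):
        pop, cs = _codings(seed=4, n=60, k=100)
        mme = db.build_mme(ModelSpec("MAD"), cs, VC, pop.phenotypes)
        direct = db.solve_direct(mme)
        jac = db.solve_jacobi(mme)
        scale = np.max(np.abs(direct.additive))
        assert np.max(np.abs(jac.additive - direct.additive)) < 1e-8 * scale
        assert np.max(np.abs(jac.dominance - direct.dominance)) < 1e-8

    def test_zero_relaxation_never_moves(self):
        pop, cs = _codings(n=10, k=5)
        mme = db.build_mme(ModelSpec("MA"), cs, VC, pop.phenotypes)
        with pytest.raises(RuntimeError, match="did not converge"):
            db.solve_jacobi(mme, relaxation_1=0.0, relaxation_2=0.0, max_iter=50)

    def test_shrinkage_monotonicity(self):
        """Increasing lambda_a (smaller sigma2_a) strictly shrinks ||a_hat||."""
        pop, cs = _codings(n=40, k=30)
        norms = []
        for s2a in (1.0, 0.3, 0.1, 0.03):
            vc = VarianceComponents(s2a, 0.0, {"C": 0.6})
            eff = db.solve_direct(db.build_mme(ModelSpec("MA"), cs, vc, pop.phenotypes))
            norms.append(np.linalg.norm(eff.additive))
        assert np.all(np.diff(norms) < 0)


class TestPredictions:
    def test_zero_effects_zero_predictions(self):
        pop, cs = _codings(n=10, k=5)
        eff = db.SNPEffects({"mu": 0.0}, np.zeros(5), np.zeros(5), ModelSpec("MAD"))
        pred = db.predict_genetic_values(cs, eff)
        assert np.all(pred.total == 0)

    def test_single_snp_breeding_value(self):
        g = GenotypeMatrix(ids=["a"], codes=np.array([[2]]))
        cs = db.compute_codings(g, db.AlleleFrequencies([0.25]))
        eff = db.SNPEffects({"mu": 0.0}, np.array([1.0]), None, ModelSpec("MA"))
        pred = db.predict_genetic_values(cs, eff)
        assert pred.bv[0] == pytest.approx(1.5)  # z = 2 - 2*0.25
        assert pred.total == pytest.approx(pred.bv)  # MA: total equals bv


class TestRanking:
    snp_map = pd.DataFrame(
        {
            "snp_id": ["s1", "s2", "s3"],
            "chromosome": [14, 2, 14],
            "position": [100, 50, 30],
        }
    )

    def _effects(self, add, dom):
        return db.SNPEffects({"mu": 0.0}, np.array(add), np.array(dom), ModelSpec("MAD"))

    def test_sorted_by_absolute_dominance(self):
        eff = self._effects([0.0, 0.0, 0.0], [3.0, -1.0, 2.0])
        out = db.rank_snp_effects(eff, self.snp_map, by="dominance", top=3)
        assert list(out["snp_id"]) == ["s1", "s3", "s2"]
        assert list(out["rank_dominance"]) == [1, 2, 3]

    def test_other_scale_rank_reported(self):
        eff = self._effects([0.5, 2.0, 1.0], [3.0, 1.0, 2.0])
        out = db.rank_snp_effects(eff, self.snp_map, by="dominance", top=3)
        # dominance order is s1, s3, s2; their additive ranks are 3, 2, 1
        assert list(out["snp_id"]) == ["s1", "s3", "s2"]
        assert list(out["rank_additive"]) == [3, 2, 1]

    def test_chromosome_exclusion(self):
        eff = self._effects([1.0, 0.5, 2.0], [3.0, 1.0, 2.0])
        out = db.rank_snp_effects(eff, self.snp_map, by="additive", top=3,
                                  exclude_chromosomes=(14,))
        assert set(out["chromosome"]) == {2}

    def test_ties_broken_by_position(self):
        eff = self._effects([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        out = db.rank_snp_effects(eff, self.snp_map, by="additive", top=3)
        assert list(out["snp_id"]) == ["s2", "s3", "s1"]  # (chr, pos) order

    def test_top_truncated_with_warning(self):
        eff = self._effects([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="truncating"):
            out = db.rank_snp_effects(eff, self.snp_map, by="additive", top=10)
        assert len(out) == 3
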