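import numpy as np
import pandas as pd
import pytest

from hybridgp.bayes import (
    MCMCSettings,
    ModelSpec,
    RandomTerm,
    build_design,
    fit_multitrait_gibbs,
    fit_single_trait,
)
from hybridgp.markers import KernelMatrix


def _kernel(n, seed=0, ids=None):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, max(n, 4)))
    return KernelMatrix(ids=ids or [f"o{j}" for j in range(n)], values=x @ x.T / x.shape[1])


class TestBuildDesign:
    def _data(self):
        phenos = pd.DataFrame(
            {
                "entry_id": ["h1", "h2", "h3", "h1", "h2", "h3"],
                "role": "hybrid",
                "year": [1, 1, 1, 2, 2, 2],
                "GY": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            }
        )
        ped = pd.DataFrame(
            {"hybrid": ["h1", "h2", "h3"], "male": ["m1", "m1", "m2"], "female": ["f1", "f2", "f1"]}
        )
        return phenos, ped

    def test_incidence_shapes_and_row_sums(self):
        phenos, ped = self._data()
        d = build_design(phenos, ped, ["GY"])
        assert d["Z_E"].values.shape == (6, 2)
        for key in ("Z_E", "Z_M", "Z_F", "Z_H"):
            assert np.array_equal(d[key].values.sum(axis=1), np.ones(6))

    def test_hybrid_observed_in_one_year_has_one_row(self):
        phenos, ped = self._data()
        phenos = phenos[~((phenos["entry_id"] == "h1") & (phenos["year"] == 2))]
        d = build_design(phenos, ped, ["GY"])
        assert sum(i.startswith("h1|") for i in d["obs_ids"]) == 1

    def test_masked_cell_count_matches_missing(self):
        phenos, ped = self._data()
        phenos.loc[phenos.index[2], "GY"] = np.nan
        d = build_design(phenos, ped, ["GY"])
        assert (~d["mask"]).sum() == 1

    def test_unknown_hybrid_errors(self):
        phenos, ped = self._data()
        with pytest.raises(KeyError, match="h3"):
            build_design(phenos, ped.iloc[:2], ["GY"])


class TestSamplerCore:
    def test_null_data_predicts_null(self, short_mcmc):
        n = 30
        y = np.zeros((n, 2))
        mask = np.ones((n, 2), bool)
        mask[:5] = False
        spec = ModelSpec(traits=["a", "b"], terms=[RandomTerm("g", _kernel(n))], mcmc=short_mcmc)
        ps = fit_multitrait_gibbs(spec, y, mask=mask)
        preds = ps.yhat[~mask]
        mcse = ps.yhat_mcse[~mask]
        assert np.all(np.abs(preds) <= 3 * np.maximum(mcse, 0.05))

    def test_single_trait_wrapper_matches_multitrait(self):
        n = 25
        rng = np.random.default_rng(0)
        y = rng.standard_normal(n)
        k = _kernel(n, seed=2)
        mc = MCMCSettings(iterations=500, burn_in=200, thin=2, seed=4)
        s1 = ModelSpec(traits=["t"], terms=[RandomTerm("g", k)], mcmc=mc)
        s2 = ModelSpec(traits=["t"], terms=[RandomTerm("g", k)], mcmc=mc)
        a = fit_single_trait(s1, y)
        b = fit_multitrait_gibbs(s2, y[:, None])
        assert np.allclose(a.yhat, b.yhat)  # identical seed -> identical draws

    def test_gblup_closed_form_oracle(self):
        """Fixed variances: posterior mean effect is K (K + lambda I)^-1 (y - ybar)."""
        rng = np.random.default_rng(7)
        n = 60
        k = _kernel(n, seed=7)
        g = np.linalg.cholesky(k.values + 1e-8 * np.eye(n)) @ rng.standard_normal(n)
        y = 2.0 + g + 0.7 * rng.standard_normal(n)
        lam = 0.49
        oracle = k.values @ np.linalg.solve(k.values + lam * np.eye(n), y - y.mean())
        spec = ModelSpec(
            traits=["t"],
            terms=[RandomTerm("g", k, fixed_cov=1.0)],
            fixed_residual=np.array([[lam]]),
            mcmc=MCMCSettings(iterations=6000, burn_in=1000, thin=1, seed=3),
        )
        ps = fit_single_trait(spec, y)
        assert np.corrcoef(ps.effect_means["g"][:, 0], oracle)[0, 1] > 0.999

    def test_high_heritability_recovers_signal(self):
        rng = np.random.default_rng(12)
        n = 50
        k = _kernel(n, seed=12)
        g = np.linalg.cholesky(k.values + 1e-8 * np.eye(n)) @ rng.standard_normal(n)
        y = g + 0.01 * rng.standard_normal(n)
        spec = ModelSpec(
            traits=["t"],
            terms=[RandomTerm("g", k)],
            mcmc=MCMCSettings(iterations=1500, burn_in=500, thin=2, seed=5),
        )
        ps = fit_single_trait(spec, y)
        assert np.corrcoef(ps.yhat[:, 0], y)[0, 1] > 0.99

    def test_prior_only_run_predicts_prior_mean(self, short_mcmc):
        n = 20
        y = np.full((n, 1), np.nan)
        spec = ModelSpec(traits=["t"], terms=[RandomTerm("g", _kernel(n))], mcmc=short_mcmc)
        ps = fit_single_trait(spec, y, mask=np.zeros((n, 1), bool))
        assert np.all(np.abs(ps.yhat) < 3 * np.maximum(ps.yhat_mcse, 0.1))

    def test_vanishing_variances_collapse_to_intercept(self):
        rng = np.random.default_rng(3)
        n = 40
        y = 5.0 + rng.standard_normal(n)
        spec = ModelSpec(
            traits=["t"],
            terms=[RandomTerm("g", _kernel(n, seed=3), fixed_cov=1e-12)],
            mcmc=MCMCSettings(iterations=500, burn_in=200, thin=2, seed=1),
        )
        ps = fit_single_trait(spec, y)
        assert np.allclose(ps.yhat[:, 0], y.mean(), atol=1e-3)

    def test_shrinkage_for_duplicate_hybrid(self):
        """A masked copy of an observed record predicts between it and the mean."""
        rng = np.random.default_rng(21)
        n = 30
        k = _kernel(n, seed=21).values
        # make the last row an exact duplicate (same kernel profile) of row 0
        k[-1, :] = k[0, :]
        k[:, -1] = k[:, 0]
        k[-1, -1] = k[0, 0]
        km = KernelMatrix(ids=[f"o{j}" for j in range(n)], values=k)
        g = np.linalg.cholesky(k + 1e-6 * np.eye(n)) @ rng.standard_normal(n)
        y = g + 0.3 * rng.standard_normal(n)
        y[-1] = y[0]
        mask = np.ones((n, 1), bool)
        mask[-1] = False
        spec = ModelSpec(
            traits=["t"],
            terms=[RandomTerm("g", km)],
            mcmc=MCMCSettings(iterations=2000, burn_in=600, thin=2, seed=9),
        )
        ps = fit_single_trait(spec, y, mask=mask)
        pred = ps.yhat[-1, 0]
        lo, hi = sorted([y[:-1].mean(), y[0]])
        assert lo - 0.15 <= pred <= hi + 0.15

    def test_deterministic_reproducibility(self, short_mcmc):
        n = 20
        rng = np.random.default_rng(2)
        y = rng.standard_normal((n, 2))
        mask = np.ones((n, 2), bool)
        mask[3:6] = False

        def run():
            spec = ModelSpec(
                traits=["a", "b"],
                terms=[RandomTerm("g", _kernel(n, seed=6)), RandomTerm("e2", _kernel(n, seed=8), cov="isotropic")],
                mcmc=short_mcmc,
            )
            return fit_multitrait_gibbs(spec, y, mask=mask)

        a, b = run(), run()
        assert np.array_equal(a.yhat, b.yhat)
        assert np.array_equal(a.sigma_draws["g"], b.sigma_draws["g"])

    def test_sigma_draws_are_spd(self, short_mcmc):
        n = 24
        rng = np.random.default_rng(14)
        y = rng.standard_normal((n, 3))
        spec = ModelSpec(traits=["a", "b", "c"], terms=[RandomTerm("g", _kernel(n, seed=1))], mcmc=short_mcmc)
        ps = fit_multitrait_gibbs(spec, y)
        for draws in (ps.sigma_draws["g"], ps.residual_draws):
            for s in draws:
                assert np.allclose(s, s.T)
                assert np.linalg.eigvalsh(s)[0] > 0

    def test_row_permutation_invariance_up_to_mc_error(self):
        rng = np.random.default_rng(31)
        n = 40
        k = _kernel(n, seed=31)
        y = (np.linalg.cholesky(k.values + 1e-8 * np.eye(n)) @ rng.standard_normal(n)
             + 0.5 * rng.standard_normal(n))
        perm = rng.permutation(n)
        mc = MCMCSettings(iterations=4000, burn_in=1000, thin=2, seed=11)
        ps1 = fit_single_trait(ModelSpec(traits=["t"], terms=[RandomTerm("g", k)], mcmc=mc), y)
        kp = KernelMatrix(ids=[k.ids[i] for i in perm], values=k.values[np.ix_(perm, perm)])
        ps2 = fit_single_trait(ModelSpec(traits=["t"], terms=[RandomTerm("g", kp)], mcmc=mc), y[perm])
        assert np.allclose(ps1.yhat[perm, 0], ps2.yhat[:, 0], atol=0.1)

    def test_predict_masked_table(self, short_mcmc):
        n = 15
        y = np.random.default_rng(0).standard_normal((n, 1))
        mask = np.ones((n, 1), bool)
        mask[[2, 7]] = False
        spec = ModelSpec(traits=["t"], terms=[RandomTerm("g", _kernel(n))], mcmc=short_mcmc)
        ps = fit_single_trait(spec, y, mask=mask, obs_ids=[f"obs{j}" for j in range(n)])
        tab = ps.predict_masked()
        assert set(tab["observation"]) == {"obs2", "obs7"}
        assert np.isfinite(tab["prediction"]).all()
        full = fit_single_trait(
            ModelSpec(traits=["t"], terms=[RandomTerm("g", _kernel(n))], mcmc=short_mcmc), y
        )
        assert full.predict_masked().empty
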