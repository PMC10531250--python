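"""Parental-information covariates for hybrid prediction.

Two strategies turn per-parent information into hybrid-level covariates,
two columns per trait:

* ``Pmean`` uses parental phenotypes directly:
  X_a = (P_M + P_F) / 2 (additive part) and X_d = |P_M - P_F| / 2
  (dominance part).
* ``BV`` first estimates each parent's breeding value from the
  single-trait model P = 1 mu + g + e with g ~ N(0, sigma_g^2 G), then
  plugs the posterior-mean g values into the same two formulas.

Both are symmetric in the two parents.  Parents phenotyped in several
years are averaged across years first.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .bayes import MCMCSettings, ModelSpec, RandomTerm, fit_single_trait
from .markers import KernelMatrix

logger = logging.getLogger("hybridgp")

STRATEGIES = ("NO_Cov", "Pmean", "BV")


def _parent_means(parents: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Across-year mean phenotype per parent (index entry_id, one col per trait)."""
    return parents.groupby("entry_id")[traits].mean()


def _pair_covariates(
    values: pd.DataFrame,
    ped: pd.DataFrame,
    traits: list[str],
    impute_missing: bool,
) -> pd.DataFrame:
    missing = (set(ped["male"]) | set(ped["female"])) - set(values.index)
    if missing:
        if not impute_missing:
            affected = ped[ped["male"].isin(missing) | ped["female"].isin(missing)]
            raise KeyError(
                "no parental values for parents of hybrids "
                f"{sorted(affected['hybrid'])[:5]} (parents {sorted(missing)[:5]}); "
                "pass impute_missing=True to fall back on the parent mean"
            )
        fill = values.mean(axis=0)
        values = pd.concat([values, pd.DataFrame({t: fill[t] for t in traits}, index=sorted(missing))])
    pm = values.loc[ped["male"], traits].to_numpy(float)
    pf = values.loc[ped["female"], traits].to_numpy(float)
    out = {}
    for j, t in enumerate(traits):
        out[f"{t}_a"] = (pm[:, j] + pf[:, j]) / 2.0
        out[f"{t}_d"] = np.abs(pm[:, j] - pf[:, j]) / 2.0
    return pd.DataFrame(out, index=list(ped["hybrid"]))


def pmean_covariates(
    parents: pd.DataFrame,
    ped: pd.DataFrame,
    traits: list[str],
    impute_missing: bool = False,
) -> pd.DataFrame:
    """Additive/dominance covariates from parental phenotypes (Pmean strategy)."""
    return _pair_covariates(_parent_means(parents, traits), ped, traits, impute_missing)


def estimate_breeding_values(
    parents: pd.DataFrame,
    g_parents: KernelMatrix,
    trait: str,
    mcmc: MCMCSettings | None = None,
) -> pd.Series:
    """Posterior-mean breeding values from P = 1 mu + g + e, g ~ N(0, sigma_g^2 G).

    Phenotypes are averaged across years per parent; the variance
    components get the sampler's default weakly-informative priors.
    """
    means = _parent_means(parents, [trait])
    ids = [i for i in g_parents.ids if i in means.index]
    if not ids:
        raise ValueError("kernel covers none of the phenotyped parents")
    pos = {i: j for j, i in enumerate(g_parents.ids)}
    sel = [pos[i] for i in ids]
    k = KernelMatrix(ids=ids, values=g_parents.values[np.ix_(sel, sel)], kind=g_parents.kind)
    if k.min_eigenvalue() < -1e-8:
        raise np.linalg.LinAlgError("parent kernel is not PSD; run ensure_psd first")
    spec = ModelSpec(
        traits=[trait],
        terms=[RandomTerm(name="g", kernel=k)],
        mcmc=mcmc or MCMCSettings(iterations=3000, burn_in=1000, thin=2),
    )
    y = means.loc[ids, trait].to_numpy(float)
    ps = fit_single_trait(spec, y, obs_ids=ids)
    bv = ps.effect_means["g"][:, 0]
    return pd.Series(bv, index=ids, name=trait)


def bv_covariates(
    bvs: pd.DataFrame,
    ped: pd.DataFrame,
    traits: list[str],
    impute_missing: bool = False,
) -> pd.DataFrame:
    """Additive/dominance covariates from parental breeding values (BV strategy).

    ``bvs`` is indexed by parent id with one column per trait (as returned
    by stacking :func:`estimate_breeding_values` outputs).
    """
    return _pair_covariates(bvs[traits], ped, traits, impute_missing)


def assemble_covariate_matrix(x: pd.DataFrame, standardize: bool = True) -> pd.DataFrame:
    """Optionally centre/scale covariate columns; constant columns are dropped."""
    if not standardize:
        return x.copy()
    sd = x.std(ddof=0)
    keep = sd > 0
    if (~keep).any():
        logger.warning("dropping constant covariate column(s): %s", list(x.columns[~keep]))
    x = x.loc[:, keep]
    return (x - x.mean()) / x.std(ddof=0)
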