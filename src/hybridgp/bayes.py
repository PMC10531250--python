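"""Gibbs sampler for the multi-trait kernel mixed model.

The response is an n x T matrix Y (observations x traits) modelled as a
sum of kernel-structured random effects plus optional fixed-scale
covariates and a matrix-variate residual:

    Y = sum_k  a_k  +  X B  +  E,      a_k ~ MN(0, K_k, Sigma_k),
    E ~ MN(0, I_n, R),

where each K_k is an observation-level PSD kernel (year blocks, GCA
expansions Z G Z', the SCA Hadamard kernel, or within-year interaction
kernels) and Sigma_k is a T x T trait covariance (or sigma^2 I for the
year term).  All full conditionals are conjugate: effects are sampled
row-wise in the eigenbasis of their kernel, trait covariances from
inverse-Wishart conditionals, the year variance from a scaled inverse
chi-square, and unobserved response cells by data augmentation from the
conditional normal of the current fit.  Per-trait intercepts are handled
by centring Y on its observed cells and restoring the means at
prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .markers import KernelMatrix

logger = logging.getLogger("hybridgp")

#: relative eigenvalue cutoff when truncating kernel eigendecompositions
EIG_REL_TOL = 1e-10


@dataclass
class MCMCSettings:
    """Chain length controls.  Defaults suit production runs; tests use less."""

    iterations: int = 10_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class RandomTerm:
    """One kernel-structured random effect of the model.

    ``cov="full"`` gives the effect a T x T inverse-Wishart trait
    covariance; ``cov="isotropic"`` uses sigma^2 I_T with a scaled
    inverse chi-square prior (the year-effect structure).  Setting
    ``fixed_cov`` freezes the (co)variance at that value (degenerate
    prior), which is how closed-form oracle comparisons are run.
    """

    name: str
    kernel: KernelMatrix
    cov: str = "full"
    fixed_cov: np.ndarray | float | None = None
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Truncated eigendecomposition (U_r, d_r), cached on the term."""
        if self._eig is None:
            d, u = np.linalg.eigh(self.kernel.values)
            if d[0] < -1e-8:
                raise np.linalg.LinAlgError(
                    f"kernel for term {self.name!r} is not PSD (min eig {d[0]:.3e})"
                )
            keep = d > EIG_REL_TOL * max(d[-1], 0.0)
            self._eig = (u[:, keep], np.maximum(d[keep], 0.0))
        return self._eig


@dataclass
class ModelSpec:
    """Everything the sampler needs except the response itself."""

    traits: list[str]
    terms: list[RandomTerm]
    covariates: np.ndarray | None = None
    covariate_names: list[str] | None = None
    beta_prior_var: float = 1e4
    fixed_residual: np.ndarray | None = None
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)


@dataclass
class PosteriorSummary:
    """Posterior means, retained covariance draws, and masked-cell predictions."""

    traits: list[str]
    trait_means: np.ndarray                     # per-trait centring constants
    yhat: np.ndarray                            # n x T posterior-mean fit, trait units
    yhat_mcse: np.ndarray                       # n x T Monte-Carlo standard errors
    mask: np.ndarray                            # True where the response was observed
    effect_means: dict[str, np.ndarray]         # term -> n x T posterior-mean contribution
    sigma_means: dict[str, np.ndarray]          # term -> T x T (isotropic: sigma^2 I)
    sigma_draws: dict[str, np.ndarray]          # term -> draws x T x T
    residual_mean: np.ndarray
    residual_draws: np.ndarray
    beta_mean: np.ndarray | None = None
    obs_ids: list[str] | None = None

    def predict_masked(self) -> pd.DataFrame:
        """Posterior-mean predictions for every unobserved (obs, trait) cell."""
        rows = []
        ids = self.obs_ids or [str(i) for i in range(self.yhat.shape[0])]
        for i, t in zip(*np.where(~self.mask)):
            rows.append(
                {
                    "observation": ids[i],
                    "trait": self.traits[t],
                    "prediction": self.yhat[i, t],
                    "mcse": self.yhat_mcse[i, t],
                }
            )
        return pd.DataFrame(rows, columns=["observation", "trait", "prediction", "mcse"])

    def genetic_correlation(self, term: str = "gM") -> np.ndarray:
        """Correlation matrix implied by the posterior-mean trait covariance."""
        s = self.sigma_means[term]
        d = np.sqrt(np.diag(s))
        return s / np.outer(d, d)


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

def _sample_rows(
    rng: np.random.Generator,
    etil: np.ndarray,
    d: np.ndarray,
    sigma_inv: np.ndarray,
    r_inv: np.ndarray,
) -> np.ndarray:
    """Sample the eigenbasis rows of one effect from their full conditional.

    Row i has prior N(0, d_i Sigma) and likelihood etil_i ~ N(row_i, R);
    rows are conditionally independent, so the whole block is drawn with
    batched T x T linear algebra.
    """
    prec = sigma_inv[None, :, :] / d[:, None, None] + r_inv[None, :, :]
    cov = np.linalg.inv(prec)
    mean = np.einsum("rij,rj->ri", cov, etil @ r_inv)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal(mean.shape)
    return mean + np.einsum("rij,rj->ri", chol, z)


def _draw_missing(
    rng: np.random.Generator,
    yc: np.ndarray,
    mu: np.ndarray,
    mask: np.ndarray,
    r_mat: np.ndarray,
) -> None:
    """Data augmentation: refresh unobserved cells in place, grouped by pattern."""
    miss_rows = np.flatnonzero(~mask.all(axis=1))
    if miss_rows.size == 0:
        return
    patterns: dict[bytes, list[int]] = {}
    for i in miss_rows:
        patterns.setdefault(mask[i].tobytes(), []).append(i)
    for key, rows in patterns.items():
        obs = np.frombuffer(key, dtype=bool)
        mis = ~obs
        rows = np.asarray(rows)
        if obs.any():
            roo = r_mat[np.ix_(obs, obs)]
            rmo = r_mat[np.ix_(mis, obs)]
            a = np.linalg.solve(roo, rmo.T).T
            cond_cov = r_mat[np.ix_(mis, mis)] - a @ rmo.T
            resid_o = yc[np.ix_(rows, np.flatnonzero(obs))] - mu[np.ix_(rows, np.flatnonzero(obs))]
            cond_mean = mu[np.ix_(rows, np.flatnonzero(mis))] + resid_o @ a.T
        else:
            cond_cov = r_mat
            cond_mean = mu[rows]
        # guard tiny asymmetries before the Cholesky
        cond_cov = 0.5 * (cond_cov + cond_cov.T)
        chol = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(cond_cov.shape[0]))
        z = rng.standard_normal(cond_mean.shape)
        yc[np.ix_(rows, np.flatnonzero(mis))] = cond_mean + z @ chol.T


def _as_cov(x, t: int) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    if arr.shape == (1, 1) and t > 1:
        return float(arr) * np.eye(t)
    if arr.shape != (t, t):
        raise ValueError(f"covariance shape {arr.shape} incompatible with {t} traits")
    return arr


def fit_multitrait_gibbs(
    spec: ModelSpec,
    y: np.ndarray,
    mask: np.ndarray | None = None,
    obs_ids: list[str] | None = None,
) -> PosteriorSummary:
    """Run the Gibbs sampler and summarise retained draws.

    ``y`` is n x T in trait units; unobserved cells are marked by
    ``mask=False`` (or NaN in ``y``).  The update order is fixed —
    covariate coefficients, each random effect in the order listed, each
    trait covariance, the residual covariance, then the augmented cells —
    so identical seeds and inputs reproduce the draw sequence exactly.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, t = y.shape
    if len(spec.traits) != t:
        raise ValueError("trait list does not match response columns")
    if mask is None:
        mask = np.isfinite(y)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != y.shape:
        raise ValueError("mask shape mismatch")
    rng = np.random.default_rng(spec.mcmc.seed)

    # centre per trait on observed cells; initialise augmented cells at 0.
    # A trait with no observed cells (prior-only run) centres at 0 with a
    # unit prior variance budget.
    has_obs = mask.any(axis=0)
    trait_means = np.array([y[mask[:, j], j].mean() if has_obs[j] else 0.0 for j in range(t)])
    yc = np.where(mask, y - trait_means[None, :], 0.0)

    # weakly-informative priors: each model term (and the residual) gets an
    # equal prior share of the observed per-trait phenotypic variance
    var_y = np.array(
        [max(yc[mask[:, j], j].var(), 1e-12) if has_obs[j] else 1.0 for j in range(t)]
    )
    n_parts = len(spec.terms) + 1
    share = var_y / n_parts
    df0_full = t + 2
    s0_full = np.diag(share)  # E[Sigma] = S0 at df0 = T + 2
    df0_iso = 5.0
    s0_iso = float(share.mean()) * (df0_iso - 2.0) / df0_iso

    x = spec.covariates
    if x is not None:
        x = np.asarray(x, dtype=float)
        if x.shape[0] != n:
            raise ValueError("covariate rows do not match observations")
    q = 0 if x is None else x.shape[1]

    # per-term state
    eigs = [term.eigensystem() for term in spec.terms]
    alphas = [np.zeros((d.size, t)) for _, d in eigs]
    contribs = [np.zeros((n, t)) for _ in spec.terms]
    sigmas: list[np.ndarray] = []
    for term in spec.terms:
        if term.fixed_cov is not None:
            sigmas.append(_as_cov(term.fixed_cov, t))
        elif term.cov == "isotropic":
            sigmas.append(s0_iso * df0_iso / (df0_iso - 2.0) * np.eye(t))
        else:
            sigmas.append(s0_full.copy())
    r_mat = _as_cov(spec.fixed_residual, t) if spec.fixed_residual is not None else np.diag(share)
    beta = np.zeros((q, t)) if q else None
    mu_total = np.zeros((n, t))

    if x is not None:
        xtx = x.T @ x
    mc = spec.mcmc
    keep = [it for it in range(mc.iterations) if it >= mc.burn_in and (it - mc.burn_in) % mc.thin == 0]
    n_keep = len(keep)
    keep_set = set(keep)

    yhat_sum = np.zeros((n, t))
    yhat_sq = np.zeros((n, t))
    effect_sums = {term.name: np.zeros((n, t)) for term in spec.terms}
    sigma_draws = {term.name: np.zeros((n_keep, t, t)) for term in spec.terms}
    resid_draws = np.zeros((n_keep, t, t))
    beta_sum = np.zeros((q, t)) if q else None
    kept = 0

    for it in range(mc.iterations):
        r_inv = np.linalg.inv(r_mat)

        # (i) covariate coefficient matrix B: vec(B) | rest is Gaussian
        if q:
            resid = yc - (mu_total - x @ beta)
            prec = np.kron(r_inv, xtx) + np.eye(q * t) / spec.beta_prior_var
            rhs = (x.T @ resid @ r_inv).T.reshape(-1)  # vec in trait-major order
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs)
            draw = mean + np.linalg.solve(chol.T, rng.standard_normal(q * t))
            new_beta = draw.reshape(t, q).T
            mu_total += x @ (new_beta - beta)
            beta = new_beta

        # (ii) each kernel-structured effect, rows independent in the eigenbasis
        for k_idx, term in enumerate(spec.terms):
            u, d = eigs[k_idx]
            resid = yc - (mu_total - contribs[k_idx])
            etil = u.T @ resid
            sigma_inv = np.linalg.inv(sigmas[k_idx])
            alpha = _sample_rows(rng, etil, d, sigma_inv, r_inv)
            new_contrib = u @ alpha
            mu_total += new_contrib - contribs[k_idx]
            contribs[k_idx] = new_contrib
            alphas[k_idx] = alpha

        # (iii) trait covariances
        for k_idx, term in enumerate(spec.terms):
            if term.fixed_cov is not None:
                continue
            alpha = alphas[k_idx]
            d = eigs[k_idx][1]
            r_rank = d.size
            if term.cov == "isotropic":
                ss = float(np.sum(alpha * alpha / d[:, None]))
                df_post = df0_iso + r_rank * t
                scale_sum = df0_iso * s0_iso + ss
                sigmas[k_idx] = (scale_sum / rng.chisquare(df_post)) * np.eye(t)
            else:
                ss = alpha.T @ (alpha / d[:, None])
                sigmas[k_idx] = np.atleast_2d(
                    stats.invwishart.rvs(df=df0_full + r_rank, scale=s0_full + ss, random_state=rng)
                )

        # (iv) residual covariance
        if spec.fixed_residual is None:
            e_mat = yc - mu_total
            r_mat = np.atleast_2d(
                stats.invwishart.rvs(df=df0_full + n, scale=s0_full + e_mat.T @ e_mat, random_state=rng)
            )

        # (v) data augmentation for unobserved cells
        _draw_missing(rng, yc, mu_total, mask, r_mat)

        if not np.isfinite(mu_total).all():
            raise FloatingPointError(f"divergent draw at iteration {it}")

        if it in keep_set:
            yhat_sum += mu_total
            yhat_sq += mu_total**2
            for term, contrib in zip(spec.terms, contribs):
                effect_sums[term.name] += contrib
            for term, sig in zip(spec.terms, sigmas):
                sigma_draws[term.name][kept] = sig
            resid_draws[kept] = r_mat
            if q:
                beta_sum += beta
            kept += 1

    yhat_mean = yhat_sum / n_keep
    yhat_var = np.maximum(yhat_sq / n_keep - yhat_mean**2, 0.0)
    return PosteriorSummary(
        traits=list(spec.traits),
        trait_means=trait_means,
        yhat=yhat_mean + trait_means[None, :],
        yhat_mcse=np.sqrt(yhat_var / n_keep),
        mask=mask,
        effect_means={k: v / n_keep for k, v in effect_sums.items()},
        sigma_means={k: v.mean(axis=0) for k, v in sigma_draws.items()},
        sigma_draws=sigma_draws,
        residual_mean=resid_draws.mean(axis=0),
        residual_draws=resid_draws,
        beta_mean=None if beta_sum is None else beta_sum / n_keep,
        obs_ids=obs_ids,
    )


def fit_single_trait(
    spec: ModelSpec,
    y: np.ndarray,
    mask: np.ndarray | None = None,
    obs_ids: list[str] | None = None,
) -> PosteriorSummary:
    """Single-trait special case (T = 1); covariances collapse to scalars."""
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    if len(spec.traits) != 1:
        raise ValueError("single-trait fit needs exactly one trait")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool).reshape(-1, 1)
    return fit_multitrait_gibbs(spec, y, mask=mask, obs_ids=obs_ids)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(phenos: pd.DataFrame, ped: pd.DataFrame, traits: list[str]):
    """Observation-level design from hybrid phenotypes and the pedigree.

    ``phenos`` needs columns entry_id, role, year plus one column per
    trait (hybrid rows only are used); ``ped`` maps hybrid -> male,
    female.  Returns the observation table (one row per hybrid x year),
    incidence matrices over years/males/females/hybrids, the response
    matrix and its observed-cell mask.
    """
    from .kernels import IncidenceMatrix

    hy = phenos[phenos["role"] == "hybrid"].copy()
    missing_ped = set(hy["entry_id"]) - set(ped["hybrid"])
    if missing_ped:
        raise KeyError(f"hybrids absent from pedigree: {sorted(missing_ped)[:5]}")
    parent_of = ped.set_index("hybrid")
    hy = hy.sort_values(["year", "entry_id"]).reset_index(drop=True)
    obs_ids = [f"{h}|{int(yr)}" for h, yr in zip(hy["entry_id"], hy["year"])]
    years = [str(int(v)) for v in hy["year"]]
    males = [str(parent_of.loc[h, "male"]) for h in hy["entry_id"]]
    females = [str(parent_of.loc[h, "female"]) for h in hy["entry_id"]]
    hybrids = [str(h) for h in hy["entry_id"]]

    z_e = IncidenceMatrix.from_levels(obs_ids, years)
    z_m = IncidenceMatrix.from_levels(obs_ids, males)
    z_f = IncidenceMatrix.from_levels(obs_ids, females)
    z_h = IncidenceMatrix.from_levels(obs_ids, hybrids)
    y = hy[traits].to_numpy(float)
    mask = np.isfinite(y)
    return {
        "obs": hy,
        "obs_ids": obs_ids,
        "Z_E": z_e,
        "Z_M": z_m,
        "Z_F": z_f,
        "Z_H": z_h,
        "Y": y,
        "mask": mask,
    }
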