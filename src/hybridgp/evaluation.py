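"""Cross-validation and the strategy x kernel x trait x year results grid.

The CV scheme is "untested lines in tested years": hybrids are
partitioned into k near-equal folds and all records of a test hybrid are
masked in every year, so every year stays represented in training while
the test hybrids are entirely unseen.  Prediction error is summarised as
NRMSE = RMSE / mean(observed) per trait within each year, averaged over
folds; "Global" is the unweighted mean of the per-year values.  Methods
are compared by the relative efficiency RE = NRMSE_x / NRMSE_ref and the
companion percentage gain (NRMSE_ref / NRMSE_x - 1) * 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import MCMCSettings, ModelSpec, RandomTerm, build_design, fit_multitrait_gibbs
from .covariates import (
    STRATEGIES,
    assemble_covariate_matrix,
    bv_covariates,
    estimate_breeding_values,
    pmean_covariates,
)
from .kernels import (
    KernelSpec,
    ensure_psd,
    expand_kernel,
    hybrid_kernel,
    interaction_kernel,
    build_kernel,
)
from .markers import MarkerMatrix, concat_individuals, genomic_relationship, qc_pipeline

logger = logging.getLogger("hybridgp")


# ---------------------------------------------------------------------------
# folds and metrics
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """Seeded partition of hybrids into k near-equal folds."""

    fold_of: dict[str, int]
    k: int
    seed: int

    def test_hybrids(self, fold: int) -> set[str]:
        return {h for h, f in self.fold_of.items() if f == fold}


def make_cv_folds(hybrids: list[str], k: int = 7, seed: int = 0) -> CVPlan:
    """Uniform random partition; all year-records of a hybrid share its fold."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(hybrids) < k:
        raise ValueError("need at least k hybrids")
    if len(set(hybrids)) != len(hybrids):
        raise ValueError("duplicate hybrid ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(hybrids))
    fold_of = {}
    for pos, idx in enumerate(order):
        fold_of[hybrids[idx]] = pos % k + 1
    return CVPlan(fold_of=fold_of, k=k, seed=seed)


def nrmse(observed, predicted, normalizer: str = "mean") -> float:
    """Root-mean-square error normalised by a scale of the observed values."""
    o = np.asarray(observed, float)
    p = np.asarray(predicted, float)
    if o.shape != p.shape or o.size == 0:
        raise ValueError("observed and predicted must be equal-length and non-empty")
    rmse = float(np.sqrt(np.mean((o - p) ** 2)))
    if normalizer == "mean":
        m = float(np.mean(o))
        if m == 0.0:
            raise ZeroDivisionError(
                "mean of observed values is zero; use normalizer='sd' or 'range'"
            )
        return rmse / m
    if normalizer == "sd":
        return rmse / float(np.std(o))
    if normalizer == "range":
        return rmse / float(np.ptp(o))
    raise ValueError(f"unknown normalizer {normalizer!r}")


def relative_efficiency(nrmse_x: float, nrmse_ref: float) -> float:
    """RE = NRMSE_x / NRMSE_ref; values below 1 favour method x."""
    if nrmse_x <= 0 or nrmse_ref <= 0:
        raise ValueError("NRMSE values must be positive")
    return nrmse_x / nrmse_ref


def percentage_gain(nrmse_x: float, nrmse_ref: float) -> float:
    """Percentage improvement of x over ref: (NRMSE_ref / NRMSE_x - 1) * 100."""
    return (nrmse_ref / nrmse_x - 1.0) * 100.0


# ---------------------------------------------------------------------------
# dataset preparation
# ---------------------------------------------------------------------------

@dataclass
class PreparedData:
    """QC'd markers, design matrices and covariates, ready for model fits."""

    traits: list[str]
    design: dict
    male_w: MarkerMatrix
    female_w: MarkerMatrix
    ped: pd.DataFrame
    parents_pheno: pd.DataFrame
    g_parents: "object"          # linear kernel over all parents, for BV fits
    covariates: dict = field(default_factory=dict)  # strategy -> obs-level DataFrame


def prepare_inputs(
    males: MarkerMatrix,
    females: MarkerMatrix,
    ped: pd.DataFrame,
    phenos: pd.DataFrame,
    traits: list[str],
    max_missing_frac: float = 0.15,
    min_maf: float = 0.05,
    bv_mcmc: MCMCSettings | None = None,
) -> PreparedData:
    """Run marker QC, build the design, and compute both covariate sets.

    Breeding values for the BV strategy come from single-trait fits on the
    across-year parent means with the linear genomic relationship matrix
    over all parents; parents are never part of the hybrid CV masking, so
    these are computed once per dataset.
    """
    male_w = qc_pipeline(males, max_missing_frac, min_maf)
    female_w = qc_pipeline(females, max_missing_frac, min_maf)
    design = build_design(phenos, ped, traits)
    parents_pheno = phenos[phenos["role"].isin(["male", "female"])]

    joint = qc_pipeline(concat_individuals(males, females), max_missing_frac, min_maf)
    g_parents = ensure_psd(genomic_relationship(joint))

    x_pmean = pmean_covariates(parents_pheno, ped, traits)
    bv_cols = {}
    for t in traits:
        bv_cols[t] = estimate_breeding_values(
            parents_pheno, g_parents, t, mcmc=bv_mcmc or MCMCSettings(iterations=2000, burn_in=800, thin=2)
        )
    x_bv = bv_covariates(pd.DataFrame(bv_cols), ped, traits)

    obs_hybrids = list(design["obs"]["entry_id"].astype(str))
    covariates = {
        "NO_Cov": None,
        "Pmean": assemble_covariate_matrix(x_pmean).loc[obs_hybrids],
        "BV": assemble_covariate_matrix(x_bv).loc[obs_hybrids],
    }
    return PreparedData(
        traits=list(traits),
        design=design,
        male_w=male_w,
        female_w=female_w,
        ped=ped,
        parents_pheno=parents_pheno,
        g_parents=g_parents,
        covariates=covariates,
    )


def build_model_terms(prep: PreparedData, spec: KernelSpec) -> list[RandomTerm]:
    """The seven random terms of the hybrid model for one kernel choice.

    The kernel choice applies to the parental similarity matrices G_M and
    G_F and propagates into the SCA and interaction kernels; "linear"
    reproduces GBLUP.
    """
    d = prep.design
    g_m = ensure_psd(build_kernel(prep.male_w, spec))
    g_f = ensure_psd(build_kernel(prep.female_w, spec))
    hyb_ids = list(dict.fromkeys(d["Z_H"].cols))
    ped_idx = prep.ped.set_index("hybrid")
    from .kernels import IncidenceMatrix

    z_m_h = IncidenceMatrix.from_levels(hyb_ids, [str(ped_idx.loc[h, "male"]) for h in hyb_ids], g_m.ids)
    z_f_h = IncidenceMatrix.from_levels(hyb_ids, [str(ped_idx.loc[h, "female"]) for h in hyb_ids], g_f.ids)
    h_kernel = hybrid_kernel(z_m_h, g_m, z_f_h, g_f)

    k_e = expand_kernel(d["Z_E"], _identity_kernel(d["Z_E"].cols))
    k_m = expand_kernel(d["Z_M"], g_m)
    k_f = expand_kernel(d["Z_F"], g_f)
    k_h = expand_kernel(d["Z_H"], h_kernel)
    terms = [
        RandomTerm(name="E", kernel=k_e, cov="isotropic"),
        RandomTerm(name="gM", kernel=k_m),
        RandomTerm(name="gF", kernel=k_f),
        RandomTerm(name="h", kernel=k_h),
        RandomTerm(name="uM", kernel=interaction_kernel(k_m, d["Z_E"])),
        RandomTerm(name="uF", kernel=interaction_kernel(k_f, d["Z_E"])),
        RandomTerm(name="uH", kernel=interaction_kernel(k_h, d["Z_E"])),
    ]
    for term in terms:
        term.eigensystem()  # decompose once; reused across folds and strategies
    return terms


def _identity_kernel(ids):
    from .markers import KernelMatrix

    return KernelMatrix(ids=list(ids), values=np.eye(len(ids)), kind="linear")


# ---------------------------------------------------------------------------
# the grid
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    """Per-fold NRMSE values, the aggregated grid, and raw predictions."""

    per_fold: pd.DataFrame
    grid: pd.DataFrame
    predictions: pd.DataFrame
    failures: list = field(default_factory=list)


def run_strategy_grid(
    prep: PreparedData,
    cv: CVPlan,
    strategies: list[str] = list(STRATEGIES),
    kernels: list[KernelSpec] | None = None,
    mcmc: MCMCSettings | None = None,
    normalizer: str = "mean",
) -> EvalResult:
    """Fit every (strategy, kernel) cell of the grid under the shared CV plan.

    For each fold all responses of the fold's hybrids are masked in every
    year; a leakage assertion verifies that no test-hybrid value is
    observed by the training fit.  Fold failures are recorded and the run
    continues.
    """
    kernels = kernels or [KernelSpec("linear")]
    mcmc = mcmc or MCMCSettings()
    d = prep.design
    y = d["Y"]
    base_mask = d["mask"]
    obs_hybrids = np.array(d["obs"]["entry_id"].astype(str))
    obs_years = np.array([int(v) for v in d["obs"]["year"]])
    unknown = set(obs_hybrids) - set(cv.fold_of)
    if unknown:
        raise KeyError(f"observations for hybrids outside the CV plan: {sorted(unknown)[:5]}")

    per_fold_rows = []
    pred_rows = []
    failures = []
    for spec in kernels:
        terms = build_model_terms(prep, spec)
        for strategy in strategies:
            x = prep.covariates.get(strategy)
            x_mat = None if x is None else x.to_numpy(float)
            for fold in range(1, cv.k + 1):
                test = cv.test_hybrids(fold)
                test_rows = np.isin(obs_hybrids, list(test))
                mask = base_mask.copy()
                mask[test_rows, :] = False
                # leakage guard: the training fit must see nothing from any
                # test hybrid, in any year, for any trait
                assert not mask[test_rows].any(), "test-hybrid responses leaked into training"
                model = ModelSpec(
                    traits=prep.traits,
                    terms=terms,
                    covariates=x_mat,
                    mcmc=MCMCSettings(
                        iterations=mcmc.iterations,
                        burn_in=mcmc.burn_in,
                        thin=mcmc.thin,
                        seed=mcmc.seed + fold,
                    ),
                )
                try:
                    ps = fit_multitrait_gibbs(model, y, mask=mask, obs_ids=d["obs_ids"])
                except Exception as e:  # pragma: no cover - defensive path
                    logger.error("fold %d failed for %s/%s: %s", fold, strategy, spec.name, e)
                    failures.append({"strategy": strategy, "kernel": spec.name, "fold": fold, "error": str(e)})
                    continue
                for j, trait in enumerate(prep.traits):
                    for yr in np.unique(obs_years):
                        sel = test_rows & (obs_years == yr) & base_mask[:, j]
                        if not sel.any():
                            continue
                        val = nrmse(y[sel, j], ps.yhat[sel, j], normalizer=normalizer)
                        per_fold_rows.append(
                            {
                                "strategy": strategy,
                                "kernel": spec.name,
                                "trait": trait,
                                "year": int(yr),
                                "fold": fold,
                                "nrmse": val,
                                "n_test": int(sel.sum()),
                            }
                        )
                    sel = test_rows & base_mask[:, j]
                    for i in np.flatnonzero(sel):
                        pred_rows.append(
                            {
                                "strategy": strategy,
                                "kernel": spec.name,
                                "trait": trait,
                                "year": int(obs_years[i]),
                                "fold": fold,
                                "observation": d["obs_ids"][i],
                                "observed": y[i, j],
                                "predicted": ps.yhat[i, j],
                            }
                        )

    per_fold = pd.DataFrame(per_fold_rows)
    if per_fold.empty:
        logger.warning("strategy grid produced no results")
        return EvalResult(per_fold=per_fold, grid=pd.DataFrame(), predictions=pd.DataFrame(pred_rows), failures=failures)
    grid = (
        per_fold.groupby(["strategy", "kernel", "trait", "year"], as_index=False)["nrmse"]
        .mean()
        .assign(year=lambda f: f["year"].astype(str))
    )
    glob = (
        grid.groupby(["strategy", "kernel", "trait"], as_index=False)["nrmse"]
        .mean()
        .assign(year="Global")
    )
    grid = pd.concat([grid, glob], ignore_index=True)
    return EvalResult(per_fold=per_fold, grid=grid, predictions=pd.DataFrame(pred_rows), failures=failures)


def gain_table(grid: pd.DataFrame, reference: str = "NO_Cov") -> pd.DataFrame:
    """RE and % gain of each strategy against the reference, per grid cell."""
    ref = grid[grid["strategy"] == reference].set_index(["kernel", "trait", "year"])["nrmse"]
    rows = []
    for _, r in grid.iterrows():
        if r["strategy"] == reference:
            continue
        key = (r["kernel"], r["trait"], r["year"])
        if key not in ref.index:
            continue
        rows.append(
            {
                "strategy": r["strategy"],
                "kernel": r["kernel"],
                "trait": r["trait"],
                "year": r["year"],
                "nrmse": r["nrmse"],
                "nrmse_ref": ref[key],
                "RE": relative_efficiency(r["nrmse"], ref[key]),
                "gain_pct": percentage_gain(r["nrmse"], ref[key]),
            }
        )
    return pd.DataFrame(rows)


def predictive_correlation(predictions: pd.DataFrame, truth: pd.DataFrame | None = None) -> pd.DataFrame:
    """Within-year Pearson correlation of predictions, averaged over years.

    Correlates predictions with the observed values, or with true genetic
    values when generator truth (observation x trait) is supplied.
    """
    df = predictions.copy()
    if truth is not None:
        long_truth = truth.stack().rename("target").reset_index()
        long_truth.columns = ["observation", "trait", "target"]
        df = df.merge(long_truth, on=["observation", "trait"])
    else:
        df["target"] = df["observed"]
    rows = []
    for (strategy, kernel, trait), sub in df.groupby(["strategy", "kernel", "trait"]):
        cors = [
            np.corrcoef(s["predicted"], s["target"])[0, 1]
            for _, s in sub.groupby("year")
            if len(s) > 2 and s["target"].std() > 0
        ]
        rows.append(
            {
                "strategy": strategy,
                "kernel": kernel,
                "trait": trait,
                "correlation": float(np.mean(cors)) if cors else np.nan,
            }
        )
    return pd.DataFrame(rows)


def aggregate_and_report(res: EvalResult, out_dir, reference: str = "NO_Cov") -> dict:
    """Write per-trait NRMSE tables, gain tables, and bar plots."""
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    if res.grid.empty:
        logger.warning("empty results grid; nothing to report")
        return written
    res.per_fold.to_csv(out / "nrmse_per_fold.csv", index=False)
    written["per_fold"] = out / "nrmse_per_fold.csv"
    for trait, sub in res.grid.groupby("trait"):
        table = sub.pivot_table(index=["kernel", "year"], columns="strategy", values="nrmse").round(3)
        path = out / f"nrmse_{trait}.csv"
        table.to_csv(path)
        written[f"nrmse_{trait}"] = path
    gains = gain_table(res.grid, reference=reference)
    if not gains.empty:
        gains.to_csv(out / "gains_vs_reference.csv", index=False)
        written["gains"] = out / "gains_vs_reference.csv"
    across = (
        res.grid[res.grid["year"] == "Global"]
        .groupby(["strategy", "kernel"], as_index=False)["nrmse"]
        .mean()
        .rename(columns={"nrmse": "nrmse_across_traits"})
    )
    across.to_csv(out / "nrmse_across_traits.csv", index=False)
    written["across_traits"] = out / "nrmse_across_traits.csv"

    for trait, sub in res.grid.groupby("trait"):
        fig, ax = plt.subplots(figsize=(7, 4))
        piv = sub.pivot_table(index="year", columns="strategy", values="nrmse", aggfunc="mean")
        piv.plot.bar(ax=ax, rot=0)
        ax.set_ylabel("NRMSE")
        ax.set_title(f"{trait}: prediction error by year and strategy")
        fig.tight_layout()
        path = out / f"nrmse_{trait}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written[f"plot_{trait}"] = path
    return written
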