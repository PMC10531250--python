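"""Synthetic hybrid-trial generator.

Emits datasets with the statistical structure the multi-trait kernel
model assumes: inbred male and female parents genotyped on a shared SNP
panel, an incomplete factorial of crosses evaluated over several years
with partial overlap of hybrid sets between consecutive years, and
three correlated traits (GY in t/ha, DTF and DTH in days) whose
phenotypes are sums of year effects, male/female GCA drawn on the
genomic relationship matrices, SCA drawn on the Hadamard cross kernel,
within-year interaction effects, an optional parental-covariate signal,
and a matrix-variate residual.  Parent phenotypes are their own GCA
values plus noise, so parental-information strategies are informative.

The default scenario (12 males x 120 females x 3 crosses = 360 hybrids,
500 markers, 3 years, 30% carry-over between years) is small enough for
minute-scale cross-validation while keeping the incomplete-factorial
shape of a real hybrid wheat programme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import pmean_covariates
from .kernels import IncidenceMatrix, expand_kernel, hybrid_kernel, interaction_kernel
from .markers import KernelMatrix, MarkerMatrix, genomic_relationship, qc_pipeline

DEFAULT_TRAITS = ("GY", "DTF", "DTH")
#: trait correlation shared by all genetic terms (GY-DTF, GY-DTH, DTF-DTH)
DEFAULT_TRAIT_CORR = np.array(
    [
        [1.00, 0.40, 0.40],
        [0.40, 1.00, 0.85],
        [0.40, 0.85, 1.00],
    ]
)
DEFAULT_TRAIT_SD = np.array([0.6, 4.0, 4.0])      # t/ha, days, days
DEFAULT_TRAIT_MEAN = np.array([6.0, 80.0, 75.0])  # t/ha, days, days

#: per-trait phenotypic-variance shares of each model term; GCA-heavy with
#: broad-sense within-year heritability 0.25+0.25+0.10 = 0.60
DEFAULT_VARIANCE_SHARES = {
    "gM": 0.25,
    "gF": 0.25,
    "h": 0.10,
    "uM": 0.05,
    "uF": 0.05,
    "uH": 0.05,
    "resid": 0.25,
}


@dataclass
class SimConfig:
    """Generator settings; defaults define the standard study conditions."""

    n_males: int = 12
    n_females: int = 120
    crosses_per_female: int = 3
    n_markers: int = 500
    n_years: int = 3
    maf_range: tuple[float, float] = (0.1, 0.5)
    missing_frac: float = 0.02
    traits: tuple[str, ...] = DEFAULT_TRAITS
    trait_corr: np.ndarray = field(default_factory=lambda: DEFAULT_TRAIT_CORR.copy())
    trait_sd: np.ndarray = field(default_factory=lambda: DEFAULT_TRAIT_SD.copy())
    trait_mean: np.ndarray = field(default_factory=lambda: DEFAULT_TRAIT_MEAN.copy())
    variance_shares: dict = field(default_factory=lambda: dict(DEFAULT_VARIANCE_SHARES))
    sigma_e_year: float = 1.0          # SD of year effects, shared across traits
    parent_h2: float = 0.7             # heritability of across-year parent means
    parental_signal: bool = False      # add X_AC beta_AC to hybrid responses
    beta_additive: float = 0.5         # own-trait coefficient on X_a
    beta_dominance: float = 2.0        # own-trait coefficient on X_d
    overlap: float = 0.3               # fraction of a year's hybrids carried to the next
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.crosses_per_female <= self.n_males:
            raise ValueError("crosses_per_female must be in [1, n_males]")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must be in [0, 1]")
        self.trait_corr = np.asarray(self.trait_corr, float)
        if np.linalg.eigvalsh(self.trait_corr)[0] <= 0:
            raise ValueError("trait correlation matrix must be SPD")

    def term_cov(self, term: str) -> np.ndarray:
        """Trait covariance for one model term, in squared trait units."""
        s = np.sqrt(self.variance_shares[term]) * np.asarray(self.trait_sd, float)
        return self.trait_corr * np.outer(s, s)

    @property
    def n_traits(self) -> int:
        return len(self.traits)


@dataclass
class SimTruth:
    """Generator ground truth kept for parameter-recovery checks."""

    g_male: pd.DataFrame
    g_female: pd.DataFrame
    sca: pd.DataFrame
    beta_year: pd.DataFrame
    genetic_value: pd.DataFrame   # per observation: GCA + SCA + interactions
    trait_corr: np.ndarray
    seed: int


@dataclass
class SimData:
    """Full synthetic dataset in the formats the pipeline consumes."""

    config: SimConfig
    males: MarkerMatrix
    females: MarkerMatrix
    hybrids: MarkerMatrix
    ped: pd.DataFrame
    phenos: pd.DataFrame
    truth: SimTruth


def _chol_psd(k: np.ndarray) -> np.ndarray:
    return np.linalg.cholesky(k + 1e-8 * np.trace(k) / k.shape[0] * np.eye(k.shape[0]))


def _matrix_normal(rng: np.random.Generator, row_chol: np.ndarray, col_cov: np.ndarray) -> np.ndarray:
    z = rng.standard_normal((row_chol.shape[0], col_cov.shape[0]))
    if not np.any(col_cov):  # zero variance budget: degenerate at 0
        return np.zeros_like(z)
    return row_chol @ z @ np.linalg.cholesky(col_cov).T


def simulate_parents(cfg: SimConfig, rng: np.random.Generator) -> tuple[MarkerMatrix, MarkerMatrix]:
    """Inbred parents coded 0/2 from per-marker Bernoulli allele frequencies."""
    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_markers)

    def _one(prefix: str, n: int) -> MarkerMatrix:
        dos = 2.0 * (rng.random((n, cfg.n_markers)) < freqs[None, :])
        mask = rng.random((n, cfg.n_markers)) < cfg.missing_frac
        return MarkerMatrix(
            ids=[f"{prefix}{i + 1}" for i in range(n)],
            dosages=np.where(mask, 0.0, dos),
            missing_mask=mask,
            snp_names=[f"snp{j}" for j in range(cfg.n_markers)],
            state="raw",
        )

    return _one("M", cfg.n_males), _one("F", cfg.n_females)


def simulate_crosses(
    cfg: SimConfig,
    males: MarkerMatrix,
    females: MarkerMatrix,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, MarkerMatrix, dict[int, list[str]]]:
    """Incomplete factorial: each female crossed to ``crosses_per_female`` males.

    Also assigns hybrids to years: each hybrid debuts in one year and a
    fraction ``overlap`` of a year's set is carried into the next, so
    consecutive years share hybrids while every hybrid is tested at
    least once.  Hybrid dosages are the parental means (F1 of inbreds).
    """
    rows = []
    for f in females.ids:
        mates = rng.choice(cfg.n_males, size=cfg.crosses_per_female, replace=False)
        for mi in mates:
            m = males.ids[mi]
            rows.append({"hybrid": f"{m}x{f}", "male": m, "female": f})
    ped = pd.DataFrame(rows)

    m_idx = {m: i for i, m in enumerate(males.ids)}
    f_idx = {f: i for i, f in enumerate(females.ids)}
    male_imp = qc_dosages(males)
    female_imp = qc_dosages(females)
    dos = 0.5 * (
        male_imp[[m_idx[m] for m in ped["male"]], :]
        + female_imp[[f_idx[f] for f in ped["female"]], :]
    )
    hybrids = MarkerMatrix(
        ids=list(ped["hybrid"]),
        dosages=dos,
        missing_mask=np.zeros_like(dos, dtype=bool),
        snp_names=list(males.snp_names),
        state="imputed",
    )

    # year membership: debut groups + carry-over between consecutive years
    order = rng.permutation(len(ped))
    debut_groups = np.array_split(order, cfg.n_years)
    year_sets: dict[int, list[str]] = {}
    prev: list[str] = []
    for y in range(1, cfg.n_years + 1):
        members = [ped["hybrid"].iloc[i] for i in debut_groups[y - 1]]
        if prev and cfg.overlap > 0:
            n_carry = int(round(cfg.overlap * len(prev)))
            carried = list(rng.choice(prev, size=n_carry, replace=False)) if n_carry else []
            members = sorted(set(members) | set(carried))
        year_sets[y] = sorted(members)
        prev = year_sets[y]
    return ped, hybrids, year_sets


def qc_dosages(m: MarkerMatrix) -> np.ndarray:
    """Mean-imputed dosages without dropping columns (keeps panels aligned)."""
    n_obs = (~m.missing_mask).sum(axis=0)
    col_mean = np.where(m.missing_mask, 0.0, m.dosages).sum(axis=0) / np.maximum(n_obs, 1)
    return np.where(m.missing_mask, col_mean[None, :], m.dosages)


def simulate_trial(
    cfg: SimConfig,
    ped: pd.DataFrame,
    males: MarkerMatrix,
    females: MarkerMatrix,
    year_sets: dict[int, list[str]],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw phenotypes from the generative model and return them with truth."""
    traits = list(cfg.traits)
    t = cfg.n_traits
    g_m = genomic_relationship(qc_pipeline(males, max_missing_frac=1.0, min_maf=0.0))
    g_f = genomic_relationship(qc_pipeline(females, max_missing_frac=1.0, min_maf=0.0))

    # level effects
    gm = _matrix_normal(rng, _chol_psd(g_m.values), cfg.term_cov("gM"))
    gf = _matrix_normal(rng, _chol_psd(g_f.values), cfg.term_cov("gF"))
    hyb_ids = list(ped["hybrid"])
    z_m_h = IncidenceMatrix.from_levels(hyb_ids, list(ped["male"]), g_m.ids)
    z_f_h = IncidenceMatrix.from_levels(hyb_ids, list(ped["female"]), g_f.ids)
    h_kernel = hybrid_kernel(z_m_h, g_m, z_f_h, g_f)
    sca = _matrix_normal(rng, _chol_psd(h_kernel.values), cfg.term_cov("h"))
    beta_year = cfg.sigma_e_year * rng.standard_normal((cfg.n_years, t))

    # observation table
    obs = []
    for y in range(1, cfg.n_years + 1):
        for hid in year_sets[y]:
            obs.append((hid, y))
    obs_ids = [f"{h}|{y}" for h, y in obs]
    n = len(obs)
    parent_of = ped.set_index("hybrid")
    z_e = IncidenceMatrix.from_levels(obs_ids, [str(y) for _, y in obs])
    z_m = IncidenceMatrix.from_levels(obs_ids, [str(parent_of.loc[h, "male"]) for h, _ in obs], g_m.ids)
    z_f = IncidenceMatrix.from_levels(obs_ids, [str(parent_of.loc[h, "female"]) for h, _ in obs], g_f.ids)
    z_h = IncidenceMatrix.from_levels(obs_ids, [h for h, _ in obs], hyb_ids)

    k_m_obs = expand_kernel(z_m, g_m)
    k_f_obs = expand_kernel(z_f, g_f)
    k_h_obs = expand_kernel(z_h, h_kernel)
    u_m = _matrix_normal(rng, _chol_psd(interaction_kernel(k_m_obs, z_e).values), cfg.term_cov("uM"))
    u_f = _matrix_normal(rng, _chol_psd(interaction_kernel(k_f_obs, z_e).values), cfg.term_cov("uF"))
    u_h = _matrix_normal(rng, _chol_psd(interaction_kernel(k_h_obs, z_e).values), cfg.term_cov("uH"))

    gca_obs = z_m.values @ gm + z_f.values @ gf
    sca_obs = z_h.values @ sca
    genetic = gca_obs + sca_obs + u_m + u_f + u_h
    year_obs = z_e.values @ beta_year
    resid = _matrix_normal(rng, np.eye(n), cfg.term_cov("resid"))
    y_mat = cfg.trait_mean[None, :] + year_obs + genetic + resid

    # parent phenotypes: own GCA + noise, emitted per year, calibrated so the
    # across-year parent mean has heritability parent_h2
    h2 = cfg.parent_h2
    gca_sd = np.sqrt(np.array([cfg.term_cov("gM")[j, j] for j in range(t)]))
    mean_noise_sd = gca_sd * np.sqrt((1.0 - h2) / h2)
    year_noise_sd = mean_noise_sd * np.sqrt(cfg.n_years)
    parent_rows = []
    for role, ids, g in (("male", males.ids, gm), ("female", females.ids, gf)):
        base = cfg.trait_mean[None, :] + g
        for y in range(1, cfg.n_years + 1):
            noise = rng.standard_normal((len(ids), t)) * year_noise_sd[None, :]
            vals = base + beta_year[y - 1][None, :] + noise
            for i, pid in enumerate(ids):
                parent_rows.append({"entry_id": pid, "role": role, "year": y, **dict(zip(traits, vals[i]))})
    parents_df = pd.DataFrame(parent_rows)

    # optional parental-covariate signal, dominance-weighted: the additive
    # mid-parent value is largely captured by the GCA kernels, so the part a
    # covariate-free model cannot reach enters mainly through |P_M - P_F|/2
    if cfg.parental_signal:
        x_ac = pmean_covariates(parents_df, ped, traits)
        beta = np.zeros((2 * t, t))
        for j, tr in enumerate(traits):
            beta[list(x_ac.columns).index(f"{tr}_a"), j] = cfg.beta_additive
            beta[list(x_ac.columns).index(f"{tr}_d"), j] = cfg.beta_dominance
        x_obs = x_ac.loc[[h for h, _ in obs]].to_numpy(float)
        x_obs = x_obs - x_obs.mean(axis=0, keepdims=True)
        y_mat = y_mat + x_obs @ beta

    hybrid_rows = []
    for (hid, yr), vals in zip(obs, y_mat):
        hybrid_rows.append({"entry_id": hid, "role": "hybrid", "year": yr, **dict(zip(traits, vals))})
    phenos = pd.concat([pd.DataFrame(hybrid_rows), parents_df], ignore_index=True)

    truth = SimTruth(
        g_male=pd.DataFrame(gm, index=g_m.ids, columns=traits),
        g_female=pd.DataFrame(gf, index=g_f.ids, columns=traits),
        sca=pd.DataFrame(sca, index=hyb_ids, columns=traits),
        beta_year=pd.DataFrame(beta_year, index=[str(y) for y in range(1, cfg.n_years + 1)], columns=traits),
        genetic_value=pd.DataFrame(genetic, index=obs_ids, columns=traits),
        trait_corr=cfg.trait_corr.copy(),
        seed=cfg.seed,
    )
    return phenos, truth


def simulate_dataset(cfg: SimConfig | None = None) -> SimData:
    """End-to-end generation from a config; fully reproducible from cfg.seed."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    males, females = simulate_parents(cfg, rng)
    ped, hybrids, year_sets = simulate_crosses(cfg, males, females, rng)
    phenos, truth = simulate_trial(cfg, ped, males, females, year_sets, rng)
    return SimData(
        config=cfg,
        males=males,
        females=females,
        hybrids=hybrids,
        ped=ped,
        phenos=phenos,
        truth=truth,
    )


def write_dataset(data: SimData, out_dir) -> None:
    """Emit the CSV formats the pipeline consumes, plus ground truth."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, m in (("markers_male", data.males), ("markers_female", data.females)):
        df = pd.DataFrame(np.where(m.missing_mask, np.nan, m.dosages), index=m.ids, columns=m.snp_names)
        df.to_csv(out / f"{name}.csv")
    data.ped.to_csv(out / "pedigree.csv", index=False)
    data.phenos.to_csv(out / "phenotypes.csv", index=False)
    data.truth.genetic_value.to_csv(out / "sim_truth.csv")
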