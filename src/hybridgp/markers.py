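"""Marker quality control and genomic relationship matrices.

Dosage matrices (individuals x SNPs, coded 0/1/2 counts of the counted
allele) pass through the standard pre-modelling pipeline: drop SNPs with
too many missing calls, mean-impute the remainder, drop low-MAF SNPs,
centre/scale each column, and form the VanRaden genomic relationship
matrix G = W W' / p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("hybridgp")

#: tolerance for symmetry / PSD checks on kernel matrices
PSD_TOL = 1e-8


class EmptyPanelError(ValueError):
    """All SNP columns were removed by a filtering step."""


@dataclass
class MarkerMatrix:
    """Individuals x SNPs dosage matrix with an explicit missing mask.

    ``state`` tracks pipeline position: ``raw`` (may contain missing),
    ``imputed`` (no missing, still on the 0..2 dosage scale) or
    ``standardized`` (columns centred, unit population SD).
    """

    ids: list[str]
    dosages: np.ndarray
    missing_mask: np.ndarray
    snp_names: list[str] = field(default_factory=list)
    state: str = "raw"

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.dosages.shape != self.missing_mask.shape:
            raise ValueError("dosages and missing_mask shapes differ")
        if len(self.ids) != self.dosages.shape[0]:
            raise ValueError("number of ids does not match dosage rows")
        if not self.snp_names:
            self.snp_names = [f"snp{j}" for j in range(self.dosages.shape[1])]
        if self.state != "standardized":
            vals = self.dosages[~self.missing_mask]
            if vals.size and not np.all(np.isin(vals, (0.0, 1.0, 2.0)) | ~np.isfinite(vals)):
                # continuous values are only legal after imputation
                if self.state == "raw":
                    raise ValueError("raw dosages must be in {0,1,2}")
        if self.state == "imputed" and self.missing_mask.any():
            raise ValueError("imputed matrix cannot carry missing cells")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]


@dataclass
class KernelMatrix:
    """Symmetric similarity matrix over a set of identified levels."""

    ids: list[str]
    values: np.ndarray
    kind: str = "linear"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kernel must be square")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ids do not match kernel dimension")
        asym = np.max(np.abs(self.values - self.values.T)) if self.values.size else 0.0
        if asym > 1e-10:
            raise ValueError(f"kernel not symmetric (max asymmetry {asym:.2e})")
        # enforce exact symmetry downstream of floating point noise
        self.values = 0.5 * (self.values + self.values.T)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_marker_csv(path, transposed: bool = False) -> MarkerMatrix:
    """Read a dosage CSV (header = SNP names, first column = individual id).

    Empty cells or NA tokens are treated as missing.  ``transposed=True``
    accepts the SNPs-in-rows layout.
    """
    df = pd.read_csv(path, index_col=0)
    if transposed:
        df = df.T
    vals = df.to_numpy(dtype=float)
    mask = ~np.isfinite(vals)
    vals = np.where(mask, 0.0, vals)
    return MarkerMatrix(
        ids=[str(i) for i in df.index],
        dosages=vals,
        missing_mask=mask,
        snp_names=[str(c) for c in df.columns],
        state="raw",
    )


def write_kernel_csv(k: KernelMatrix, path) -> None:
    k.to_frame().to_csv(path)


def read_kernel_csv(path, kind: str = "linear") -> KernelMatrix:
    df = pd.read_csv(path, index_col=0)
    return KernelMatrix(ids=[str(i) for i in df.index], values=df.to_numpy(float), kind=kind)


# ---------------------------------------------------------------------------
# QC pipeline
# ---------------------------------------------------------------------------

def filter_missingness(m: MarkerMatrix, max_missing_frac: float = 0.15) -> MarkerMatrix:
    """Retain SNPs whose missing fraction is strictly below the threshold."""
    if m.state != "raw":
        raise ValueError("missingness filter applies to raw dosages")
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = m.missing_mask.mean(axis=0)
    keep = frac < max_missing_frac
    if not keep.any():
        raise EmptyPanelError("missingness filter removed every SNP")
    return replace(
        m,
        dosages=m.dosages[:, keep].copy(),
        missing_mask=m.missing_mask[:, keep].copy(),
        snp_names=[s for s, k in zip(m.snp_names, keep) if k],
    )


def impute_naive(m: MarkerMatrix) -> MarkerMatrix:
    """Replace each missing call with the column mean of observed dosages.

    The column mean equals twice the observed allele frequency, i.e. the
    naive expectation under Hardy-Weinberg-free bookkeeping.
    """
    if m.state != "raw":
        raise ValueError("imputation applies to raw dosages")
    n_obs = (~m.missing_mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = [m.snp_names[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"SNPs with no observed calls cannot be imputed: {bad[:5]}")
    sums = np.where(m.missing_mask, 0.0, m.dosages).sum(axis=0)
    col_mean = sums / n_obs
    out = np.where(m.missing_mask, col_mean[None, :], m.dosages)
    return replace(
        m,
        dosages=out,
        missing_mask=np.zeros_like(m.missing_mask),
        state="imputed",
    )


def filter_maf(m: MarkerMatrix, min_maf: float = 0.05) -> MarkerMatrix:
    """Drop SNPs with minor allele frequency strictly below ``min_maf``."""
    if m.state != "imputed":
        raise ValueError("MAF filter applies to imputed dosages")
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    f = m.dosages.mean(axis=0) / 2.0
    maf = np.minimum(f, 1.0 - f)
    keep = maf >= min_maf
    if not keep.any():
        logger.warning("MAF filter removed every SNP")
    return replace(
        m,
        dosages=m.dosages[:, keep].copy(),
        missing_mask=m.missing_mask[:, keep].copy(),
        snp_names=[s for s, k in zip(m.snp_names, keep) if k],
    )


def standardize(m: MarkerMatrix) -> MarkerMatrix:
    """Centre each SNP column and scale to unit population SD (divisor n).

    Monomorphic columns carry no information and are dropped with a logged
    count.  Population-SD scaling makes mean(diag(G)) exactly 1.
    """
    if m.state != "imputed":
        raise ValueError("standardization applies to imputed dosages")
    mean = m.dosages.mean(axis=0)
    sd = m.dosages.std(axis=0)  # population SD
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropping %d zero-variance SNP column(s)", dropped)
    w = (m.dosages[:, keep] - mean[keep]) / sd[keep]
    return replace(
        m,
        dosages=w,
        missing_mask=np.zeros_like(w, dtype=bool),
        snp_names=[s for s, k in zip(m.snp_names, keep) if k],
        state="standardized",
    )


def qc_pipeline(
    m: MarkerMatrix,
    max_missing_frac: float = 0.15,
    min_maf: float = 0.05,
) -> MarkerMatrix:
    """missingness filter -> naive imputation -> MAF filter -> standardize."""
    return standardize(filter_maf(impute_naive(filter_missingness(m, max_missing_frac)), min_maf))


def genomic_relationship(w: MarkerMatrix) -> KernelMatrix:
    """VanRaden genomic relationship matrix G = W W' / p."""
    if w.state != "standardized":
        raise ValueError("G requires standardized markers")
    if w.p < 1:
        raise ValueError("no markers left to build G")
    g = w.dosages @ w.dosages.T / w.p
    return KernelMatrix(ids=list(w.ids), values=g, kind="linear")


def concat_individuals(a: MarkerMatrix, b: MarkerMatrix) -> MarkerMatrix:
    """Stack two raw marker matrices sharing a SNP panel (e.g. males+females)."""
    if a.snp_names != b.snp_names:
        raise ValueError("marker panels differ; cannot concatenate")
    if a.state != b.state:
        raise ValueError("states differ; cannot concatenate")
    return MarkerMatrix(
        ids=list(a.ids) + list(b.ids),
        dosages=np.vstack([a.dosages, b.dosages]),
        missing_mask=np.vstack([a.missing_mask, b.missing_mask]),
        snp_names=list(a.snp_names),
        state=a.state,
    )
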