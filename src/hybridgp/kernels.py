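"""Candidate kernels and Hadamard-product kernel composition.

Six parental similarity kernels are supported: the linear VanRaden G
(GBLUP), the Gaussian kernel on mean-scaled squared Euclidean distances,
and the arc-cosine (deep neural network) kernel with 1-4 hidden layers.
Observation-level kernels are then composed by incidence-matrix expansion
(Z K Z') and Hadamard products: the cross-specific SCA kernel
H = (Z_M G_M Z_M') (.) (Z_F G_F Z_F') and the within-year interaction
kernels V = (Z K Z') (.) (Z_E Z_E').
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .markers import KernelMatrix, MarkerMatrix

logger = logging.getLogger("hybridgp")

KERNEL_NAMES = ("linear", "GK", "AC_1", "AC_2", "AC_3", "AC_4")


@dataclass
class KernelSpec:
    """Which parental kernel to build and its hyperparameters."""

    name: str = "linear"
    gamma: float = 1.0      # GK bandwidth, on the mean-scaled d^2 axis
    layers: int = 1         # arc-cosine depth
    degree: int = 1         # arc-cosine activation degree (1 = ramp)

    def __post_init__(self) -> None:
        if self.name not in KERNEL_NAMES:
            raise ValueError(f"unknown kernel {self.name!r}; choose from {KERNEL_NAMES}")
        if self.name.startswith("AC_"):
            self.layers = int(self.name.split("_")[1])
        if self.name == "GK" and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not 1 <= self.layers <= 4:
            raise ValueError("arc-cosine layers must be in 1..4")


@dataclass
class IncidenceMatrix:
    """0/1 matrix mapping observation rows to factor levels (one 1 per row)."""

    rows: list[str]
    cols: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError("incidence shape mismatch")
        if not np.array_equal(self.values.sum(axis=1), np.ones(len(self.rows))):
            raise ValueError("every observation must map to exactly one level")

    @classmethod
    def from_levels(cls, rows: list[str], level_of: list[str], levels: list[str] | None = None) -> "IncidenceMatrix":
        if levels is None:
            levels = sorted(set(level_of))
        idx = {l: j for j, l in enumerate(levels)}
        z = np.zeros((len(rows), len(levels)))
        for i, l in enumerate(level_of):
            z[i, idx[l]] = 1.0
        return cls(rows=list(rows), cols=list(levels), values=z)

    @property
    def level_index(self) -> np.ndarray:
        """Per-row integer index of the assigned level."""
        return self.values.argmax(axis=1)


# ---------------------------------------------------------------------------
# parental kernels
# ---------------------------------------------------------------------------

def gaussian_kernel(w: MarkerMatrix, gamma: float = 1.0) -> KernelMatrix:
    """Gaussian (RBF) kernel exp(-gamma d^2 / mean(d^2)) on marker rows.

    Squared distances are scaled by their off-diagonal mean so that gamma
    is a unit-free bandwidth; the diagonal is exactly 1.
    """
    if w.state != "standardized":
        raise ValueError("GK requires standardized markers")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x = w.dosages
    n = x.shape[0]
    if n == 1:
        return KernelMatrix(ids=list(w.ids), values=np.ones((1, 1)), kind="GK")
    sq = np.sum(x * x, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (x @ x.T), 0.0)
    np.fill_diagonal(d2, 0.0)
    off = d2[~np.eye(n, dtype=bool)]
    scale = off.mean()
    if scale == 0.0:
        logger.warning("all marker rows identical; Gaussian kernel collapses to ones")
        return KernelMatrix(ids=list(w.ids), values=np.ones((n, n)), kind="GK")
    k = np.exp(-gamma * d2 / scale)
    np.fill_diagonal(k, 1.0)
    return KernelMatrix(ids=list(w.ids), values=k, kind="GK")


def _j1(theta: np.ndarray) -> np.ndarray:
    return np.sin(theta) + (np.pi - theta) * np.cos(theta)


def _jn(theta: np.ndarray, degree: int) -> np.ndarray:
    """Angular factor J_n(theta) of the degree-n arc-cosine kernel (n<=2)."""
    if degree == 0:
        return np.pi - theta
    if degree == 1:
        return _j1(theta)
    if degree == 2:
        return 3.0 * np.sin(theta) * np.cos(theta) + (np.pi - theta) * (1.0 + 2.0 * np.cos(theta) ** 2)
    raise ValueError("arc-cosine degree supported for n in {0, 1, 2}")


def arc_cosine_scalar(x: np.ndarray, y: np.ndarray, degree: int = 1) -> float:
    """Closed-form single-pair arc-cosine kernel (one layer), for cross-checks."""
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm vector")
    c = np.clip(x @ y / (nx * ny), -1.0, 1.0)
    theta = math.acos(c)
    return (1.0 / math.pi) * (nx * ny) ** degree * float(_jn(np.asarray(theta), degree))


def arc_cosine_kernel(w: MarkerMatrix, layers: int = 1, degree: int = 1) -> KernelMatrix:
    """Arc-cosine kernel of Cho & Saul with ``layers`` hidden layers.

    The base layer applies the degree-n closed form
    k(x,y) = (1/pi) ||x||^n ||y||^n J_n(theta); deeper layers repeat
    k^(l+1)(x,y) = (1/pi) [k^(l)(x,x) k^(l)(y,y)]^(n/2) J_n(theta^(l))
    on the normalised layer-l kernel.  The result is rescaled to mean
    diagonal 1 so its variance prior is comparable with the other kernels.
    """
    if w.state != "standardized":
        raise ValueError("AC kernel requires standardized markers")
    if layers < 1:
        raise ValueError("layers must be >= 1")
    x = w.dosages
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        bad = [w.ids[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero-norm marker rows for individuals {bad[:5]}")
    gram = x @ x.T
    cos = np.clip(gram / np.outer(norms, norms), -1.0, 1.0)
    theta = np.arccos(cos)
    k = (1.0 / np.pi) * np.outer(norms, norms) ** degree * _jn(theta, degree)
    for _ in range(layers - 1):
        d = np.sqrt(np.maximum(np.diag(k), 0.0))
        denom = np.outer(d, d)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(denom > 0, k / denom, 0.0)
        theta = np.arccos(np.clip(cos, -1.0, 1.0))
        k = (1.0 / np.pi) * denom**degree * _jn(theta, degree)
    md = np.diag(k).mean()
    if md > 0:
        k = k / md
    k = 0.5 * (k + k.T)
    return KernelMatrix(ids=list(w.ids), values=k, kind=f"AC_{layers}")


def build_kernel(w: MarkerMatrix, spec: KernelSpec) -> KernelMatrix:
    """Dispatch the six-kernel grid on standardized markers."""
    from .markers import genomic_relationship

    if spec.name == "linear":
        return genomic_relationship(w)
    if spec.name == "GK":
        return gaussian_kernel(w, gamma=spec.gamma)
    return arc_cosine_kernel(w, layers=spec.layers, degree=spec.degree)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def expand_kernel(z: IncidenceMatrix, k: KernelMatrix) -> KernelMatrix:
    """Observation-level expansion Z K Z': entry (o,o') = k[level(o), level(o')]."""
    pos = {l: j for j, l in enumerate(k.ids)}
    try:
        col_map = np.array([pos[l] for l in z.cols])
    except KeyError as e:
        raise KeyError(f"incidence level {e} not present in kernel ids") from e
    lev = col_map[z.level_index]
    vals = k.values[np.ix_(lev, lev)]
    return KernelMatrix(ids=list(z.rows), values=vals, kind=k.kind)


def hybrid_kernel(
    z_m: IncidenceMatrix,
    g_m: KernelMatrix,
    z_f: IncidenceMatrix,
    g_f: KernelMatrix,
) -> KernelMatrix:
    """SCA kernel of crosses: H = (Z_M G_M Z_M') (.) (Z_F G_F Z_F').

    Both incidence matrices must be indexed by the same hybrid list; H is
    PSD by the Schur product theorem.
    """
    if z_m.rows != z_f.rows:
        raise ValueError("male and female incidence matrices index different hybrids")
    km = expand_kernel(z_m, g_m).values
    kf = expand_kernel(z_f, g_f).values
    return KernelMatrix(ids=list(z_m.rows), values=km * kf, kind="hadamard")


def interaction_kernel(expanded: KernelMatrix, z_e: IncidenceMatrix) -> KernelMatrix:
    """Within-year interaction kernel V = expanded (.) (Z_E Z_E')."""
    if len(expanded.ids) != len(z_e.rows):
        raise ValueError("observation-level kernel and year incidence differ in length")
    same_year = (z_e.level_index[:, None] == z_e.level_index[None, :]).astype(float)
    return KernelMatrix(ids=list(expanded.ids), values=expanded.values * same_year, kind="hadamard")


def ensure_psd(k: KernelMatrix, jitter: float = 1e-8, max_escalations: int = 6) -> KernelMatrix:
    """Add escalating diagonal jitter until the minimum eigenvalue >= -1e-8."""
    vals = k.values
    lam = float(np.linalg.eigvalsh(vals)[0])
    if lam >= -1e-8:
        return k
    added = 0.0
    # start at the eigenvalue deficit so one step normally suffices
    step = max(jitter, -lam)
    for _ in range(max_escalations):
        added += step
        lam = float(np.linalg.eigvalsh(vals + added * np.eye(vals.shape[0]))[0])
        if lam >= -1e-8:
            logger.info("added diagonal jitter %.3e to kernel %s", added, k.kind)
            return KernelMatrix(ids=list(k.ids), values=vals + added * np.eye(vals.shape[0]), kind=k.kind)
        step *= 10.0
    raise np.linalg.LinAlgError(f"kernel remains indefinite after jitter {added:.3e}")
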