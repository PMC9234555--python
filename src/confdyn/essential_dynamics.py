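"""Essential dynamics: Cartesian covariance analysis of Cα motions.

The covariance matrix Cov_ij = <(r_i − <r_i>)(r_j − <r_j>)> is built over
the 3N Cartesian coordinates of the selected atoms (denominator n_frames,
ensemble-average convention) after a two-pass least-squares fit to the
trajectory mean.  Its eigenvectors are the principal components (PCs);
eigenvalues (Å²) give the amplitude of each collective mode.

Sampling quality of a PC is screened by its cosine content — the overlap
of the projection with the first half-period cosine.  Projections that
look like a half cosine are indistinguishable from random diffusion, so
only PCs with cosine content at or below a threshold (default 0.1) are
trusted for landscape construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_core import Trajectory, batched_superpose

__all__ = [
    "CovarianceModel",
    "ProjectionSeries",
    "build_covariance",
    "variance_fraction",
    "project",
    "cosine_content",
    "select_pcs",
    "porcupine_vectors",
]


@dataclass
class CovarianceModel:
    """Mean structure, 3N×3N covariance and its eigendecomposition."""

    mean_structure: np.ndarray   # (n, 3) Å
    covariance: np.ndarray       # (3N, 3N) Å²
    eigenvalues: np.ndarray      # descending, Å²
    eigenvectors: np.ndarray     # columns, orthonormal, (3N, 3N)
    n_frames: int
    resids: np.ndarray | None = None
    fit_reference: np.ndarray | None = None  # structure frames were fitted to

    @property
    def n_atoms(self) -> int:
        return self.mean_structure.shape[0]

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size

    def mode(self, component: int) -> np.ndarray:
        """Eigenvector of a 1-based PC index."""
        if not 1 <= component <= self.n_modes:
            raise ValueError(f"component must be in 1..{self.n_modes}")
        return self.eigenvectors[:, component - 1]


@dataclass
class ProjectionSeries:
    """Scalar projection of each frame onto one PC (Å)."""

    times: np.ndarray
    values: np.ndarray
    component: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)

    @property
    def variance(self) -> float:
        return float(self.values.var())


def _fitted_coords(
    traj: Trajectory, selection: str, fit: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Select atoms and two-pass fit frames to the mean structure.

    Returns (coords, atom indices, fit reference).  The fit reference is
    the structure the final pass aligned to; reusing it keeps projections
    of the same trajectory numerically consistent with the covariance.
    """
    idx = traj.topology.select(selection)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    X = traj.coords[:, idx, :]
    ref = None
    if fit:
        ref = X.mean(axis=0)
        X = batched_superpose(X, ref)      # pass 1: fit to raw mean
        ref = X.mean(axis=0)
        X = batched_superpose(X, ref)      # pass 2: fit to refined mean
    return X, idx, ref


def build_covariance(
    traj: Trajectory,
    selection: str = "name CA",
    fit: bool = True,
) -> CovarianceModel:
    """Covariance matrix of the fitted coordinates and its eigenpairs.

    Eigenvalues are sorted descending (ties keep the lower original
    index first); eigenvectors are returned as orthonormal columns.
    """
    if traj.n_frames < 2:
        raise ValueError("covariance needs at least 2 frames")
    X, idx, ref = _fitted_coords(traj, selection, fit)
    F, n, _ = X.shape
    flat = X.reshape(F, 3 * n)
    mean = flat.mean(axis=0)
    dev = flat - mean
    cov = dev.T @ dev / F
    evals, evecs = np.linalg.eigh(cov)
    order = np.arange(evals.size)[::-1]  # eigh is ascending; stable reverse
    evals = evals[order]
    evecs = evecs[:, order]
    return CovarianceModel(
        mean_structure=mean.reshape(n, 3),
        covariance=cov,
        eigenvalues=evals,
        eigenvectors=evecs,
        n_frames=F,
        resids=traj.topology.resids[idx],
        fit_reference=ref,
    )


def variance_fraction(model: CovarianceModel, k: int) -> float:
    """Fraction of total fluctuation captured by the top ``k`` PCs."""
    if not 1 <= k <= model.n_modes:
        raise ValueError(f"k must be in 1..{model.n_modes}")
    lam = np.clip(model.eigenvalues, 0.0, None)
    total = lam.sum()
    if total == 0:
        return 0.0
    return float(lam[:k].sum() / total)


def project(
    traj: Trajectory,
    model: CovarianceModel,
    component: int,
    selection: str = "name CA",
    fit: bool = True,
) -> ProjectionSeries:
    """Project mean-free fitted coordinates onto a PC (1-based index).

    Frames are superposed onto the model's own fit reference so that, for
    the trajectory the model was built from, the projection variance onto
    PC k reproduces the k-th eigenvalue.
    """
    idx = traj.topology.select(selection)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    X = traj.coords[:, idx, :]
    if fit:
        target = (
            model.fit_reference
            if model.fit_reference is not None
            else model.mean_structure
        )
        X = batched_superpose(X, target)
    F = X.shape[0]
    dev = X.reshape(F, -1) - model.mean_structure.reshape(-1)
    vals = dev @ model.mode(component)
    return ProjectionSeries(traj.times, vals, component)


def cosine_content(projection) -> float:
    """Overlap of a projection with the first half-period cosine, in [0, 1].

    c = (2/T)·(∫ p(t)·cos(πt/T) dt)² / ∫ p(t)² dt, evaluated by the
    midpoint rule on the sampled series.  Values near 1 indicate
    random-diffusion-like (unconverged) sampling along the mode.
    """
    p = np.asarray(getattr(projection, "values", projection), float)
    if p.size < 4:
        raise ValueError("projection too short for cosine content")
    denom = float(p @ p)
    if denom == 0:
        raise ValueError("cosine content undefined for an all-zero projection")
    n = p.size
    t = (np.arange(n) + 0.5) / n
    num = float(p @ np.cos(np.pi * t))
    return min(1.0, (2.0 / n) * num * num / denom)


def select_pcs(
    model: CovarianceModel,
    projections,
    threshold: float = 0.1,
) -> list[int]:
    """PC indices (1-based) whose cosine content is at or below threshold.

    ``projections`` is an ordered sequence of ProjectionSeries (or raw
    arrays) for PC1, PC2, ...; the passing indices are returned in order
    so the first two can serve as landscape coordinates.
    """
    passing: list[int] = []
    for i, proj in enumerate(projections, start=1):
        comp = getattr(proj, "component", i)
        if cosine_content(proj) <= threshold:
            passing.append(comp)
    if not passing:
        raise ValueError(
            "no principal component has cosine content <= "
            f"{threshold}; sampling along all screened modes resembles "
            "random diffusion — extend the trajectory"
        )
    return passing


def porcupine_vectors(
    model: CovarianceModel,
    component: int,
    scale: float = 1.0,
    cap: float = 15.0,
) -> np.ndarray:
    """Per-atom displacement arrows for one PC (for porcupine plots).

    The eigenvector is reshaped to (n, 3) and rescaled so the arrow norms
    sum to ``scale``; individual arrow magnitudes are then capped at
    ``cap`` Å (display cutoff).
    """
    v = model.mode(component).reshape(-1, 3).copy()
    norms = np.linalg.norm(v, axis=1)
    total = norms.sum()
    if total > 0:
        v *= scale / total
        norms = np.linalg.norm(v, axis=1)
    over = norms > cap
    if np.any(over):
        v[over] *= (cap / norms[over])[:, None]
    return v
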