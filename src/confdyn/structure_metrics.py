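"""RMSD / Rg / RMSF time series, probability distributions and mode detection.

Conventions follow the GROMACS analysis tools: RMSD is computed after an
optional least-squares fit to the reference frame, Rg is mass-weighted by
default, and RMSF is taken about the time-average structure obtained by a
two-round iterative fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .trajectory_core import (
    Trajectory,
    batched_fitted_rmsd,
    batched_superpose,
)

__all__ = [
    "MetricSeries",
    "Distribution",
    "rmsd_series",
    "rg_series",
    "rmsf_per_residue",
    "distribution",
]


@dataclass
class MetricSeries:
    """A scalar structural metric per frame (Å vs ps)."""

    times: np.ndarray
    values: np.ndarray
    metric_name: str
    selection: str = "all"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, self.metric_name: self.values})

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class Distribution:
    """Normalized histogram of a metric with detected modes."""

    bin_centers: np.ndarray
    bin_edges: np.ndarray
    probability: np.ndarray            # density: sums to 1 when × bin width
    peaks: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center": self.bin_centers, "probability": self.probability}
        )


def _resolve_reference(traj: Trajectory, reference_frame, selection: str):
    idx = traj.topology.select(selection)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    if np.isscalar(reference_frame):
        ref = traj.coords[int(reference_frame)][idx]
    else:
        ref = np.asarray(reference_frame, dtype=float)
        if ref.ndim != 2:
            raise ValueError("reference must be a frame index or (n, 3) array")
        if ref.shape[0] == traj.n_atoms:
            ref = ref[idx]
        elif ref.shape[0] != idx.size:
            raise ValueError(
                f"reference has {ref.shape[0]} atoms, selection has {idx.size}"
            )
    return idx, ref


def rmsd_series(
    traj: Trajectory,
    reference_frame=0,
    selection: str = "all",
    fit: bool = True,
    weights: np.ndarray | None = None,
) -> MetricSeries:
    """RMSD (Å) of each frame to a reference structure.

    With ``fit`` the minimum RMSD over rigid transforms is reported
    (gmx rms behaviour); without it, the raw coordinate deviation.
    """
    idx, ref = _resolve_reference(traj, reference_frame, selection)
    X = traj.coords[:, idx, :]
    if fit:
        vals = batched_fitted_rmsd(X, ref, weights=weights)
    else:
        w = np.ones(len(ref)) if weights is None else np.asarray(weights, float)
        d = X - ref[None]
        vals = np.sqrt(
            np.einsum("fni,fni,n->f", d, d, w) / w.sum()
        )
    return MetricSeries(traj.times, vals, "rmsd", selection)


def rg_series(
    traj: Trajectory,
    selection: str = "all",
    mass_weighted: bool = True,
) -> MetricSeries:
    """Radius of gyration (Å) per frame: Rg² = Σ w_k |r_k − r̄|² / Σ w_k."""
    idx = traj.topology.select(selection)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    X = traj.coords[:, idx, :]
    w = traj.topology.masses[idx] if mass_weighted else np.ones(idx.size)
    wsum = w.sum()
    com = np.einsum("fni,n->fi", X, w) / wsum
    d = X - com[:, None, :]
    rg2 = np.einsum("fni,fni,n->f", d, d, w) / wsum
    return MetricSeries(traj.times, np.sqrt(rg2), "rg", selection)


def rmsf_per_residue(
    traj: Trajectory,
    selection: str = "name CA",
    fit: bool = True,
    fit_rounds: int = 2,
) -> pd.Series:
    """RMSF (Å) per residue about the iteratively fitted average structure.

    RMSF_i = sqrt(<|r_i − <r_i>|²>).  Residues contributing several selected
    atoms are reduced by the root of the mean square fluctuation.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = traj.topology.select(selection)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    X = traj.coords[:, idx, :]
    if fit:
        ref = X.mean(axis=0)
        for _ in range(max(1, fit_rounds)):
            X = batched_superpose(X, ref)
            ref = X.mean(axis=0)
    mean = X.mean(axis=0)
    msf = np.einsum("fni,fni->n", X - mean, X - mean) / traj.n_frames
    resids = traj.topology.resids[idx]
    per_res = pd.Series(msf).groupby(resids).mean()
    out = np.sqrt(per_res)
    out.index.name = "resid"
    out.name = "rmsf"
    return out


def distribution(
    series,
    n_bins: int = 100,
    prominence_frac: float = 0.05,
) -> Distribution:
    """Normalized histogram with local-maximum (mode) detection.

    Peaks are local maxima of the density whose prominence is at least
    ``prominence_frac`` of the maximum density; this reproduces the
    one-peak / two-peak dichotomy robustly on unimodal vs bimodal data.
    """
    values = series.values if isinstance(series, MetricSeries) else np.asarray(series, float)
    if values.size == 0:
        raise ValueError("empty series")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        edges = np.array([vmin - 0.5, vmin + 0.5])
        centers = np.array([vmin])
        prob = np.array([1.0])  # density over unit-width bin
        return Distribution(centers, edges, prob, peaks=[(vmin, 1.0)])
    if values.size < n_bins:
        raise ValueError("series shorter than the number of bins")
    prob, edges = np.histogram(values, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    thr = prominence_frac * prob.max()
    pk, _ = find_peaks(prob, prominence=thr)
    idx = set(int(i) for i in pk)
    # boundary bins cannot be interior peaks; count one as a mode when it
    # tops its neighbour and the density drops by the prominence threshold
    # before any higher bin (a flat histogram therefore yields no modes)
    for i, inner in ((0, prob[1:]), (n_bins - 1, prob[:-1][::-1])):
        if prob[i] > inner[0]:
            higher = np.flatnonzero(inner > prob[i])
            descent = inner[: higher[0] + 1] if higher.size else inner
            if prob[i] - descent.min() >= thr:
                idx.add(i)
    peaks = [(float(centers[i]), float(prob[i])) for i in sorted(idx)]
    return Distribution(centers, edges, prob, peaks=peaks)
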