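"""Two-dimensional free-energy landscapes over collective-variable pairs.

G(bin) = −ln(P_bin / P_max) in units of kT, referenced to the most
populated bin (G = 0).  Basins are grown from local minima by a
lowest-G-first flood fill, and each basin can report the trajectory frame
nearest its minimum in z-scored CV space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FreeEnergySurface",
    "Basin",
    "build_fel",
    "find_basins",
    "representative_frame",
]


@dataclass
class FreeEnergySurface:
    """Binned 2-D free-energy surface in kT with frame-to-bin assignment."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    G: np.ndarray                 # (nx, ny), kT; NaN on empty bins
    mask: np.ndarray              # (nx, ny) bool, True where empty
    temperature: float            # K (bookkeeping; G itself is in kT)
    cv_x: np.ndarray              # per-frame CV values
    cv_y: np.ndarray
    frame_bins: np.ndarray        # (n_frames, 2) bin indices
    x_name: str = "cv_x"
    y_name: str = "cv_y"

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def filled(self, pad: float = 1.0) -> np.ndarray:
        """G with empty bins set to (max populated G + pad) for display."""
        out = self.G.copy()
        top = np.nanmax(self.G)
        out[self.mask] = top + pad
        return out

    def to_frame(self) -> pd.DataFrame:
        xc, yc = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        return pd.DataFrame(
            {
                self.x_name: xc.ravel(),
                self.y_name: yc.ravel(),
                "G_kT": self.filled().ravel(),
                "populated": (~self.mask).ravel().astype(int),
            }
        )


@dataclass
class Basin:
    """A connected low-G region with its minimum and member bins."""

    label: int
    bins: set = field(default_factory=set)      # {(i, j)}
    min_G: float = np.inf
    min_bin: tuple[int, int] = (-1, -1)
    center: tuple[float, float] = (np.nan, np.nan)  # CV units of min bin


def build_fel(
    cv_x,
    cv_y,
    n_bins: int = 32,
    temperature_K: float = 300.0,
    names: tuple[str, str] = ("cv_x", "cv_y"),
) -> FreeEnergySurface:
    """Free-energy surface from two equal-length CV series.

    Bins with zero population are masked (infinite free energy).  A
    degenerate input in which every sample falls in one bin yields a
    single populated bin at G = 0 with a warning.
    """
    x = np.asarray(getattr(cv_x, "values", cv_x), float)
    y = np.asarray(getattr(cv_y, "values", cv_y), float)
    if x.shape != y.shape:
        raise ValueError("CV series must have equal length")
    if x.size < 100:
        raise ValueError("need at least 100 samples for a landscape")
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=n_bins)
    if counts.max() == counts.sum():
        warnings.warn("all samples fall in a single bin; degenerate surface")
    mask = counts == 0
    with np.errstate(divide="ignore"):
        G = -np.log(counts / counts.max())
    G[mask] = np.nan
    ix = np.clip(np.searchsorted(x_edges, x, side="right") - 1, 0, n_bins - 1)
    iy = np.clip(np.searchsorted(y_edges, y, side="right") - 1, 0, n_bins - 1)
    return FreeEnergySurface(
        x_edges=x_edges,
        y_edges=y_edges,
        G=G,
        mask=mask,
        temperature=temperature_K,
        cv_x=x,
        cv_y=y,
        frame_bins=np.stack([ix, iy], axis=1),
        x_name=names[0],
        y_name=names[1],
    )


def find_basins(
    fes: FreeEnergySurface,
    max_G: float = 3.0,
    min_separation_bins: int = 2,
) -> list[Basin]:
    """Identify free-energy basins below ``max_G`` (kT).

    Populated bins with G ≤ max_G are visited lowest-G first.  A bin with
    no previously assigned neighbour seeds a new basin (a local minimum);
    otherwise it joins the neighbouring basin whose minimum is lowest.
    Minima closer than ``min_separation_bins`` (Chebyshev distance) are
    merged into the deeper basin.  Basins are returned sorted by depth.
    """
    from scipy import ndimage

    G = fes.G
    below = ~fes.mask & (G <= max_G)
    if not below.any():
        return []
    labelled, n_comp = ndimage.label(below, structure=np.ones((3, 3), dtype=int))
    xs, ys = fes.x_centers, fes.y_centers
    basins: list[Basin] = []
    for comp in range(1, n_comp + 1):
        member = labelled == comp
        masked = np.where(member, G, np.inf)
        i, j = np.unravel_index(np.argmin(masked), G.shape)
        basins.append(
            Basin(
                label=comp - 1,
                bins={(int(a), int(b)) for a, b in np.argwhere(member)},
                min_G=float(G[i, j]),
                min_bin=(int(i), int(j)),
                center=(float(xs[i]), float(ys[j])),
            )
        )
    # merge separate components whose minima are almost coincident
    basins.sort(key=lambda b: b.min_G)
    merged: list[Basin] = []
    for b in basins:
        host = next(
            (
                m for m in merged
                if max(
                    abs(m.min_bin[0] - b.min_bin[0]),
                    abs(m.min_bin[1] - b.min_bin[1]),
                ) < min_separation_bins
            ),
            None,
        )
        if host is None:
            merged.append(b)
        else:
            host.bins |= b.bins
    for new_label, b in enumerate(merged):
        b.label = new_label
    return merged


def representative_frame(
    fes: FreeEnergySurface,
    basin: Basin,
    traj=None,
    out_pdb=None,
) -> int:
    """Frame index whose CV pair best represents the basin minimum.

    Nearest frame to the basin's minimum-bin center, measured in z-scored
    CV space (the two CVs usually have different dynamic ranges); ties go
    to the earliest frame.  If a trajectory and output path are given the
    frame is written as a PDB.
    """
    bins = basin.bins
    if not bins:
        raise ValueError("basin contains no bins")
    member = np.array(
        [tuple(fb) in bins for fb in map(tuple, fes.frame_bins)], dtype=bool
    )
    if not member.any():
        raise ValueError("basin contains no trajectory frames")
    sx = fes.cv_x.std() or 1.0
    sy = fes.cv_y.std() or 1.0
    cx, cy = basin.center
    d2 = ((fes.cv_x - cx) / sx) ** 2 + ((fes.cv_y - cy) / sy) ** 2
    d2 = np.where(member, d2, np.inf)
    idx = int(np.argmin(d2))  # argmin returns the first (earliest) minimum
    if traj is not None and out_pdb is not None:
        traj.write_pdb(out_pdb, frames=[idx])
    return idx
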