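"""Geometric hydrogen-bond and salt-bridge analysis.

H-bonds use the gmx hbond criteria: donor–acceptor distance d ≤ 3.5 Å and
hydrogen–donor–acceptor angle ≤ 30°.  Salt bridges are tracked by the
minimum distance between basic side-chain nitrogens (NZ/NH1/NH2/NE, ...)
and acidic or phosphate oxygens (OD*/OE*/O1P/O2P/O3P/OP*/OG).  Hydrogens
are attached to donors by proximity (≤ 1.25 Å in-frame), so topologies
without explicit bonds work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from ._atoms import ACIDIC_OXYGENS, BASIC_NITROGENS
from .trajectory_core import Topology, Trajectory

__all__ = [
    "HBondCriteria",
    "ContactSeries",
    "detect_hbonds_frame",
    "hbond_occupancy",
    "hbond_count_series",
    "saltbridge_series",
    "moving_average",
    "trace_correlation",
]

_DH_BOND_CUTOFF = 1.25  # Å; hydrogen considered attached to its donor


@dataclass
class HBondCriteria:
    """Geometric H-bond definition (distance in Å, angle in degrees)."""

    max_da_distance: float = 3.5
    max_angle: float = 30.0

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be positive")
        if not 0 < self.max_angle < 90:
            raise ValueError("max_angle must be in (0, 90) degrees")


@dataclass
class ContactSeries:
    """Per-frame minimum contact distance plus a formed/broken flag."""

    partner: str
    times: np.ndarray
    distances: np.ndarray   # Å, per-frame minimum over the atom-pair set
    formed: np.ndarray      # bool per frame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.distances = np.asarray(self.distances, float)
        self.formed = np.asarray(self.formed, bool)

    @property
    def occupancy(self) -> float:
        """Fraction of frames in which the contact is formed."""
        return float(self.formed.mean())

    @property
    def mean_distance(self) -> float:
        return float(self.distances.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ps": self.times,
                "distance_A": self.distances,
                "formed": self.formed.astype(int),
            }
        )


def _donor_hydrogens(frame: np.ndarray, topology: Topology, donors: np.ndarray):
    """Map donor index -> attached hydrogen indices (proximity-based)."""
    h_idx = np.flatnonzero(topology.is_hydrogen)
    out: dict[int, np.ndarray] = {}
    if h_idx.size == 0:
        return out
    for d in donors:
        dist = np.linalg.norm(frame[h_idx] - frame[d], axis=1)
        near = h_idx[dist <= _DH_BOND_CUTOFF]
        if near.size:
            out[int(d)] = near
    return out


def detect_hbonds_frame(
    frame: np.ndarray,
    topology: Topology,
    criteria: HBondCriteria | None = None,
    donors_sel: np.ndarray | None = None,
    acceptors_sel: np.ndarray | None = None,
) -> list[tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triples satisfying the criteria.

    A triple qualifies iff the D–A distance is within ``max_da_distance``
    and the H–D–A angle (at the donor) is within ``max_angle``.  Donors
    lacking an attached hydrogen are skipped with a warning.
    """
    criteria = criteria or HBondCriteria()
    frame = np.asarray(frame, float)
    donors = (
        np.flatnonzero(topology.is_donor)
        if donors_sel is None
        else np.asarray(donors_sel, int)
    )
    acceptors = (
        np.flatnonzero(topology.is_acceptor)
        if acceptors_sel is None
        else np.asarray(acceptors_sel, int)
    )
    dh = _donor_hydrogens(frame, topology, donors)
    missing = [d for d in donors if int(d) not in dh]
    if missing:
        warnings.warn(
            f"{len(missing)} donor atom(s) have no attached hydrogen; skipped",
            stacklevel=2,
        )
    found: list[tuple[int, int, int]] = []
    cos_max = np.cos(np.deg2rad(criteria.max_angle))
    for d, hydrogens in dh.items():
        da = frame[acceptors] - frame[d]
        dist = np.linalg.norm(da, axis=1)
        ok = (dist <= criteria.max_da_distance) & (dist > 1e-9) & (acceptors != d)
        for a, v_da, r_da in zip(acceptors[ok], da[ok], dist[ok]):
            for h in hydrogens:
                v_dh = frame[h] - frame[d]
                r_dh = np.linalg.norm(v_dh)
                if r_dh < 1e-9 or a == h:
                    continue
                cos_ang = float(v_dh @ v_da) / (r_dh * r_da)
                if cos_ang >= cos_max - 1e-12:
                    found.append((int(d), int(h), int(a)))
    return found


def _residue_roles(topology: Topology, resid: int):
    atoms = topology.residues_of(resid)
    if atoms.size == 0:
        raise ValueError(f"residue {resid} not found in topology")
    donors = atoms[topology.is_donor[atoms]]
    acceptors = atoms[topology.is_acceptor[atoms]]
    return atoms, donors, acceptors


def hbond_occupancy(
    traj: Trajectory,
    resA: int,
    resB: int,
    criteria: HBondCriteria | None = None,
) -> ContactSeries:
    """H-bond occupancy between two residues (either donation direction).

    A frame counts as bonded if at least one qualifying triple exists with
    the donor in one residue and the acceptor in the other.  The distance
    trace is the per-frame minimum donor–acceptor distance.
    """
    criteria = criteria or HBondCriteria()
    topo = traj.topology
    _, donA, accA = _residue_roles(topo, resA)
    _, donB, accB = _residue_roles(topo, resB)
    formed = np.zeros(traj.n_frames, bool)
    dists = np.full(traj.n_frames, np.inf)
    pairs = [(donA, accB), (donB, accA)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for f in range(traj.n_frames):
            frame = traj.coords[f]
            best = np.inf
            hit = False
            for donors, acceptors in pairs:
                if donors.size == 0 or acceptors.size == 0:
                    continue
                d = np.linalg.norm(
                    frame[donors][:, None, :] - frame[acceptors][None, :, :], axis=2
                )
                best = min(best, float(d.min()))
                if not hit:
                    triples = detect_hbonds_frame(
                        frame, topo, criteria, donors_sel=donors, acceptors_sel=acceptors
                    )
                    hit = len(triples) > 0
            formed[f] = hit
            dists[f] = best
    return ContactSeries(f"hbond {resA}-{resB}", traj.times, dists, formed)


def hbond_count_series(
    traj: Trajectory,
    groupA_sel: str,
    groupB_sel: str,
    criteria: HBondCriteria | None = None,
) -> np.ndarray:
    """Per-frame count of distinct H-bond triples between two atom groups."""
    criteria = criteria or HBondCriteria()
    topo = traj.topology
    idxA = topo.select(groupA_sel)
    idxB = topo.select(groupB_sel)
    donA = idxA[topo.is_donor[idxA]]
    accA = idxA[topo.is_acceptor[idxA]]
    donB = idxB[topo.is_donor[idxB]]
    accB = idxB[topo.is_acceptor[idxB]]
    counts = np.zeros(traj.n_frames, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for f in range(traj.n_frames):
            frame = traj.coords[f]
            seen: set[tuple[int, int, int]] = set()
            for donors, acceptors in ((donA, accB), (donB, accA)):
                if donors.size and acceptors.size:
                    seen.update(
                        detect_hbonds_frame(
                            frame, topo, criteria,
                            donors_sel=donors, acceptors_sel=acceptors,
                        )
                    )
            counts[f] = len(seen)
    return counts


def saltbridge_series(
    traj: Trajectory,
    basic_res: int,
    acidic_res: int,
    cutoff: float = 4.0,
) -> ContactSeries:
    """Minimum N–O distance trace between a basic and an acidic residue.

    The order of the two residue arguments does not matter; the basic
    partner is recognised by its side-chain nitrogens and the acidic (or
    phospho) partner by its anionic oxygens.  A frame is "formed" when the
    minimum N–O distance is within ``cutoff`` (default 4.0 Å).
    """
    topo = traj.topology

    def atoms_of_class(resid: int, names: frozenset) -> np.ndarray:
        atoms = topo.residues_of(resid)
        if atoms.size == 0:
            raise ValueError(f"residue {resid} not found in topology")
        return atoms[[str(topo.names[a]) in names for a in atoms]]

    n1, o1 = atoms_of_class(basic_res, BASIC_NITROGENS), atoms_of_class(
        acidic_res, ACIDIC_OXYGENS
    )
    n2, o2 = atoms_of_class(acidic_res, BASIC_NITROGENS), atoms_of_class(
        basic_res, ACIDIC_OXYGENS
    )
    # accept arguments in either order
    if n1.size and o1.size:
        nitro, oxy = n1, o1
    elif n2.size and o2.size:
        nitro, oxy = n2, o2
    else:
        def inventory(resid: int) -> str:
            atoms = topo.residues_of(resid)
            return ", ".join(str(topo.names[a]) for a in atoms)

        raise ValueError(
            "salt-bridge residues lack the required atom classes: "
            f"residue {basic_res} has [{inventory(basic_res)}]; "
            f"residue {acidic_res} has [{inventory(acidic_res)}]. "
            f"Need basic N of {sorted(BASIC_NITROGENS)} on one side and "
            f"acidic O of {sorted(ACIDIC_OXYGENS)} on the other."
        )
    d = np.linalg.norm(
        traj.coords[:, nitro, None, :] - traj.coords[:, None, oxy, :], axis=3
    )
    mind = d.reshape(traj.n_frames, -1).min(axis=1)
    return ContactSeries(
        f"saltbridge {basic_res}-{acidic_res}", traj.times, mind, mind <= cutoff
    )


def moving_average(series: np.ndarray, bin_size: int) -> np.ndarray:
    """Centered moving average with windows shrunk at the edges.

    Length is preserved; ``bin_size=1`` is the identity.
    """
    x = np.asarray(getattr(series, "values", series), float)
    n = x.size
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if bin_size > n:
        raise ValueError(f"bin_size {bin_size} exceeds series length {n}")
    if bin_size == 1:
        return x.copy()
    csum = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    lo = np.maximum(0, i - (bin_size - 1) // 2)
    hi = np.minimum(n, i + bin_size // 2 + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def trace_correlation(seriesA, seriesB) -> float:
    """Pearson correlation between two equal-length distance traces."""
    a = np.asarray(getattr(seriesA, "distances", seriesA), float)
    b = np.asarray(getattr(seriesB, "distances", seriesB), float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("traces must have equal length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant trace")
    return float(pearsonr(a, b).statistic)
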