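"""Internal frame model: topology, trajectory, selections and superposition.

Coordinates are stored in Å and times in ps throughout.  File reading is
delegated to MDAnalysis (which converts nm-based formats such as GRO/XTC
to Å on read); writing of representative frames uses a plain multi-model
PDB writer so that round-trips stay within format precision (1e-3 Å).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._atoms import (
    ACCEPTOR_NAMES,
    DONOR_NAMES,
    element_from_name,
    mass_from_element,
)

__all__ = [
    "Topology",
    "Trajectory",
    "DomainMap",
    "read_system",
    "kabsch_rotation",
    "kabsch_superpose",
    "batched_fitted_rmsd",
    "write_pdb",
]


# --------------------------------------------------------------------------
# Topology
# --------------------------------------------------------------------------

@dataclass
class Topology:
    """Per-atom annotation: names, residues, masses and H-bond roles.

    Atom ids are contiguous 0-based indices; residue ids follow the source
    file (1-based, never renumbered) so that residue-level results can be
    cited against the crystal-structure numbering.
    """

    names: np.ndarray          # (n,) str
    resids: np.ndarray         # (n,) int, as in source file
    resnames: np.ndarray       # (n,) str
    masses: np.ndarray         # (n,) float, amu
    elements: np.ndarray       # (n,) str

    def __post_init__(self) -> None:
        n = len(self.names)
        for arr_name in ("resids", "resnames", "masses", "elements"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"topology field {arr_name!r} length mismatch")
        self.names = np.asarray(self.names, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.elements = np.asarray(self.elements, dtype=object)
        if np.any(self.masses <= 0):
            raise ValueError("all atom masses must be positive")

    @classmethod
    def from_names(
        cls,
        names: Sequence[str],
        resids: Sequence[int],
        resnames: Sequence[str],
        masses: Sequence[float] | None = None,
    ) -> "Topology":
        elements = np.array([element_from_name(n) for n in names], dtype=object)
        if masses is None:
            masses = np.array([mass_from_element(e) for e in elements])
        return cls(
            names=np.asarray(names, dtype=object),
            resids=np.asarray(resids, dtype=int),
            resnames=np.asarray(resnames, dtype=object),
            masses=np.asarray(masses, dtype=float),
            elements=elements,
        )

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def atom_ids(self) -> np.ndarray:
        return np.arange(self.n_atoms)

    @property
    def is_hydrogen(self) -> np.ndarray:
        return np.array([e == "H" for e in self.elements], dtype=bool)

    @property
    def is_donor(self) -> np.ndarray:
        return np.array([n in DONOR_NAMES for n in self.names], dtype=bool)

    @property
    def is_acceptor(self) -> np.ndarray:
        return np.array([n in ACCEPTOR_NAMES for n in self.names], dtype=bool)

    # -- selection mini-language ------------------------------------------

    def select(self, expression: str) -> np.ndarray:
        """Evaluate a selection expression; returns sorted atom indices.

        Grammar: clauses joined by ``and``; each clause is one of
        ``all``, ``name A B ...``, ``resname X Y ...``,
        ``resid 10-87 120 200-210``.
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        expr = expression.strip()
        if not expr:
            raise ValueError("empty selection expression")
        for clause in re.split(r"\s+and\s+", expr):
            tokens = clause.split()
            kw = tokens[0].lower()
            args = tokens[1:]
            if kw == "all":
                continue
            if not args:
                raise ValueError(f"selection clause {clause!r} has no arguments")
            if kw == "name":
                wanted = set(args)
                mask &= np.array([n in wanted for n in self.names], dtype=bool)
            elif kw == "resname":
                wanted = set(args)
                mask &= np.array([r in wanted for r in self.resnames], dtype=bool)
            elif kw == "resid":
                sub = np.zeros(self.n_atoms, dtype=bool)
                for a in args:
                    if "-" in a[1:]:
                        lo_s, hi_s = a[:1] + a[1:].split("-", 1)[0], a[1:].split("-", 1)[1]
                        lo, hi = int(lo_s), int(hi_s)
                    else:
                        lo = hi = int(a)
                    sub |= (self.resids >= lo) & (self.resids <= hi)
                mask &= sub
            else:
                raise ValueError(f"unknown selection keyword {kw!r}")
        return np.flatnonzero(mask)

    def subset(self, indices: np.ndarray) -> "Topology":
        idx = np.asarray(indices, dtype=int)
        return Topology(
            names=self.names[idx],
            resids=self.resids[idx],
            resnames=self.resnames[idx],
            masses=self.masses[idx],
            elements=self.elements[idx],
        )

    def residues_of(self, resid: int) -> np.ndarray:
        """Atom indices belonging to a residue id."""
        return np.flatnonzero(self.resids == resid)


# --------------------------------------------------------------------------
# Trajectory
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Ordered frames of coordinates (Å) with times (ps) and a topology."""

    topology: Topology
    coords: np.ndarray           # (n_frames, n_atoms, 3) Å
    times: np.ndarray            # (n_frames,) ps, strictly increasing
    box: np.ndarray | None = None  # optional 3 lengths, Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length must equal frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_subset(self, indices: np.ndarray) -> "Trajectory":
        idx = np.asarray(indices, dtype=int)
        return Trajectory(
            topology=self.topology.subset(idx),
            coords=self.coords[:, idx, :],
            times=self.times.copy(),
            box=None if self.box is None else self.box.copy(),
        )

    def select(self, expression: str) -> "Trajectory":
        idx = self.topology.select(expression)
        if idx.size == 0:
            raise ValueError(f"selection {expression!r} matches no atoms")
        return self.atom_subset(idx)

    def write_pdb(self, path: str | Path, frames: Iterable[int] | None = None) -> None:
        write_pdb(path, self.topology, self.coords, frames=frames)


# --------------------------------------------------------------------------
# Domain map
# --------------------------------------------------------------------------

#: Default pol-β domain decomposition: the 8 kD lyase domain plus the
#: DNA-binding (thumb), catalytic (palm) and nascent-base-pair (fingers)
#: sub-domains of the 31 kD polymerase domain.
DEFAULT_DOMAINS: Mapping[str, tuple[int, int]] = {
    "Lyase": (10, 87),
    "D": (90, 150),
    "C": (151, 260),
    "N": (261, 335),
}


@dataclass
class DomainMap:
    """Named, non-overlapping inclusive residue ranges."""

    ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_DOMAINS)
    )

    def __post_init__(self) -> None:
        spans = sorted(self.ranges.values())
        for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
            if a_hi < a_lo or b_hi < b_lo:
                raise ValueError("domain range must be lo <= hi")
            if b_lo <= a_hi:
                raise ValueError("domain ranges must not overlap")

    def domain_of(self, resid: int) -> str | None:
        for name, (lo, hi) in self.ranges.items():
            if lo <= resid <= hi:
                return name
        return None

    def selection(self, name: str) -> str:
        lo, hi = self.ranges[name]
        return f"resid {lo}-{hi}"

    def names(self) -> list[str]:
        return list(self.ranges)


# --------------------------------------------------------------------------
# Reading
# --------------------------------------------------------------------------

def read_system(
    topology_path: str | Path,
    trajectory_path: str | Path | None = None,
    selection: str = "all",
    stride: int = 1,
) -> Trajectory:
    """Read a topology (PDB/GRO) plus trajectory (XTC/TRR/DCD/PDB) from disk.

    MDAnalysis handles format dispatch and unit conversion to Å.  ``stride``
    subsamples frames on read.  Raises on atom-count mismatches between
    topology and trajectory, and on selections matching no atoms.
    """
    import MDAnalysis as mda

    topology_path = str(topology_path)
    try:
        if trajectory_path is None:
            u = mda.Universe(topology_path)
        else:
            u = mda.Universe(topology_path, str(trajectory_path))
    except (ValueError, IOError) as exc:
        raise ValueError(
            f"failed to read system ({topology_path}, {trajectory_path}): {exc}"
        ) from exc

    atoms = u.atoms
    names = [a.name for a in atoms]
    resids = [int(a.resid) for a in atoms]
    resnames = [a.resname for a in atoms]
    try:
        masses = np.asarray(atoms.masses, dtype=float)
        if np.any(masses <= 0):
            raise ValueError
    except Exception:
        masses = None
    topo = Topology.from_names(names, resids, resnames, masses=masses)

    idx = topo.select(selection)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")

    frames = []
    times = []
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message=".*no dt information.*")
        for i, ts in enumerate(u.trajectory):
            if i % stride:
                continue
            frames.append(np.array(ts.positions[idx], dtype=float))
            times.append(float(ts.time))
    coords = np.stack(frames)
    times = np.asarray(times, dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        # formats without time stamps: fall back to frame index in ps
        times = np.arange(len(frames), dtype=float)

    box = None
    if u.dimensions is not None and np.all(np.asarray(u.dimensions[:3]) > 0):
        box = np.asarray(u.dimensions[:3], dtype=float)

    return Trajectory(topology=topo.subset(idx), coords=coords, times=times, box=box)


# --------------------------------------------------------------------------
# Superposition
# --------------------------------------------------------------------------

def _validate_superpose_inputs(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    ref_centered = reference - np.average(reference, axis=0, weights=w)
    if np.linalg.matrix_rank(ref_centered, tol=1e-9) < 2:
        raise ValueError("reference geometry is degenerate (collinear or a point)")
    return mobile, reference, w


def kabsch_rotation(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation R and centroids aligning mobile onto reference.

    Returns ``(R, mobile_centroid, reference_centroid)`` with
    ``fitted = (mobile - mc) @ R.T + rc`` and ``det(R) = +1``.
    """
    mobile, reference, w = _validate_superpose_inputs(mobile, reference, weights)
    wsum = w.sum()
    mc = (w[:, None] * mobile).sum(axis=0) / wsum
    rc = (w[:, None] * reference).sum(axis=0) / wsum
    P = mobile - mc
    Q = reference - rc
    H = (w[:, None] * P).T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, mc, rc


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares superpose ``mobile`` onto ``reference``.

    Returns the fitted coordinates and the minimum weighted RMSD (Å) over
    all rigid transforms (proper rotations only).
    """
    R, mc, rc = kabsch_rotation(mobile, reference, weights)
    fitted = (np.asarray(mobile, dtype=float) - mc) @ R.T + rc
    w = np.ones(len(fitted)) if weights is None else np.asarray(weights, float)
    diff = fitted - np.asarray(reference, dtype=float)
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum() / w.sum()))
    return fitted, rmsd


def batched_fitted_rmsd(
    coords: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Minimum RMSD of every frame to ``reference`` (vectorized Kabsch).

    Uses the singular-value identity
    ``rmsd² = (E0 − 2·Σ σ_k·s_k) / W`` with the smallest singular value
    sign-flipped for improper optima, avoiding per-frame Python loops.
    """
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    n = reference.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    rc = (w[:, None] * reference).sum(axis=0) / wsum
    Q = reference - rc
    mc = (w[None, :, None] * coords).sum(axis=1) / wsum
    P = coords - mc[:, None, :]
    # weighted cross-covariance per frame: (F, 3, 3)
    H = np.einsum("fni,n,nj->fij", P, w, Q)
    sv = np.linalg.svd(H, compute_uv=False)
    det = np.linalg.det(H)
    # flip smallest singular value where the optimum needs a reflection
    sgn = np.where(det < 0, -1.0, 1.0)
    tr = sv[:, 0] + sv[:, 1] + sgn * sv[:, 2]
    e0 = (
        np.einsum("fni,fni,n->f", P, P, w)
        + np.einsum("ni,ni,n->", Q, Q, w)
    )
    msd = np.maximum(e0 - 2.0 * tr, 0.0)
    # e0 − 2·tr cancels catastrophically for near-identical structures;
    # anything below the float cancellation floor is an exact zero
    msd[msd < 1e-12 * e0] = 0.0
    return np.sqrt(msd / wsum)


def batched_superpose(
    coords: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Superpose every frame onto ``reference``; returns fitted coordinates."""
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    n = reference.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    rc = (w[:, None] * reference).sum(axis=0) / wsum
    Q = reference - rc
    mc = (w[None, :, None] * coords).sum(axis=1) / wsum
    P = coords - mc[:, None, :]
    H = np.einsum("fni,n,nj->fij", P, w, Q)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("fij,fjk->fik", np.transpose(Vt, (0, 2, 1)),
                                  np.transpose(U, (0, 2, 1))))
    D = np.repeat(np.eye(3)[None, :, :], len(coords), axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("fij,fjk,fkl->fil", np.transpose(Vt, (0, 2, 1)), D,
                  np.transpose(U, (0, 2, 1)))
    return np.einsum("fni,fji->fnj", P, R) + rc


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------

def write_pdb(
    path: str | Path,
    topology: Topology,
    coords: np.ndarray,
    frames: Iterable[int] | None = None,
) -> None:
    """Write frames as a multi-model PDB (fixed columns, 1e-3 Å precision)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    frame_ids = list(frames) if frames is not None else list(range(coords.shape[0]))
    with open(path, "w") as fh:
        for m, fi in enumerate(frame_ids, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for k in range(topology.n_atoms):
                name = str(topology.names[k])
                # PDB column rules: 4-char names start at col 13, shorter at 14
                name_field = name if len(name) >= 4 else f" {name:<3s}"
                x, y, z = coords[fi, k]
                fh.write(
                    f"ATOM  {k + 1:5d} {name_field:<4s} "
                    f"{str(topology.resnames[k])[:4]:<4s}A"
                    f"{int(topology.resids[k]):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {str(topology.elements[k]):>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
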