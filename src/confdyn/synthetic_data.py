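"""Synthetic trajectories with planted statistical structure.

These generators stand in for long explicit-solvent MD trajectories when
exercising the analysis stack.  They plant *known* structure — block
covariance between residue groups, two-state conformational hopping with
known occupancies and separations, exact H-bond/salt-bridge geometry,
drifting low-frequency modes — so every analysis result can be compared
with the value that was planted.

All generators are pure functions of their spec plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory_core import Topology, Trajectory, kabsch_superpose

__all__ = [
    "GaussianTrajectorySpec",
    "TwoStateSpec",
    "AtomisticFixtureSpec",
    "helix_structure",
    "ca_topology",
    "generate_gaussian_trajectory",
    "generate_two_state",
    "generate_cv_clusters",
    "build_interaction_fixture",
    "drifting_mode_series",
]

TIME_STEP_PS = 2.0  # sampling interval of the emulated trajectories


def helix_structure(
    n_residues: int,
    rise: float = 1.5,
    twist_deg: float = 100.0,
    radius: float = 2.3,
) -> np.ndarray:
    """Coarse helical Cα curve (rise 1.5 Å, ~100° twist per residue).

    The exact geometry is cosmetic; it only needs to be non-degenerate so
    least-squares superposition is well conditioned.
    """
    k = np.arange(n_residues)
    phi = np.deg2rad(twist_deg) * k
    return np.stack(
        [radius * np.cos(phi), radius * np.sin(phi), rise * k], axis=1
    )


def ca_topology(n_residues: int, resname: str = "ALA") -> Topology:
    """One Cα pseudo-atom per residue, resids 1..n."""
    return Topology.from_names(
        names=["CA"] * n_residues,
        resids=list(range(1, n_residues + 1)),
        resnames=[resname] * n_residues,
    )


# --------------------------------------------------------------------------
# Gaussian block-covariance trajectories
# --------------------------------------------------------------------------

@dataclass
class GaussianTrajectorySpec:
    """Stationary Gaussian fluctuations with block-correlated residues.

    ``blocks`` lists inclusive 1-based residue ranges; within a block the
    displacement vectors of any two residues correlate with ``rho``
    (identically on each Cartesian component, so the planted DCCM entry
    is exactly rho); between blocks the correlation is zero.  ``sigma``
    is the per-coordinate fluctuation in Å.
    """

    n_residues: int
    blocks: list[tuple[int, int]] = field(default_factory=list)
    rho: float = 0.8
    sigma: float = 1.0
    n_frames: int = 10_000
    seed: int = 0

    def residue_correlation(self) -> np.ndarray:
        """Planted residue-level correlation matrix R (DCCM target)."""
        R = np.eye(self.n_residues)
        for lo, hi in self.blocks:
            if not (1 <= lo <= hi <= self.n_residues):
                raise ValueError(f"block ({lo}, {hi}) out of range")
            sl = slice(lo - 1, hi)
            R[sl, sl] = self.rho
        np.fill_diagonal(R, 1.0)
        return R

    def covariance(self) -> np.ndarray:
        """Planted 3N×3N covariance: kron(R, I₃)·σ² (validated PSD)."""
        R = self.residue_correlation()
        evals = np.linalg.eigvalsh(R)
        if evals.min() < -1e-10:
            raise ValueError("planted correlation matrix is not PSD")
        return np.kron(R, np.eye(3)) * self.sigma**2


def generate_gaussian_trajectory(spec: GaussianTrajectorySpec) -> Trajectory:
    """Sample frames around a helical mean with the planted covariance."""
    rng = np.random.default_rng(spec.seed)
    mean = helix_structure(spec.n_residues)
    cov = spec.covariance()
    # small jitter keeps Cholesky stable when rho is exactly 1
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
    Z = rng.standard_normal((spec.n_frames, cov.shape[0]))
    disp = Z @ L.T
    coords = mean[None] + disp.reshape(spec.n_frames, spec.n_residues, 3)
    times = np.arange(spec.n_frames) * TIME_STEP_PS
    return Trajectory(ca_topology(spec.n_residues), coords, times)


# --------------------------------------------------------------------------
# Two-state hopping trajectories
# --------------------------------------------------------------------------

@dataclass
class TwoStateSpec:
    """Markovian hopping between two reference conformations.

    State B is state A plus ``separation`` Å (fitted RMSD) along a fixed
    displacement field orthogonal to A's rigid-body modes.  Occupancies
    set the stationary distribution; ``transition_rate`` scales the
    per-frame switching probabilities (detailed balance is preserved, so
    the planted occupancies hold for any rate in (0, 1]).
    """

    n_residues: int = 40
    separation: float = 7.0        # planted fitted RMSD(A, B), Å
    occupancies: tuple[float, float] = (0.5, 0.5)
    transition_rate: float = 0.05
    sigma: float = 0.25            # per-coordinate thermal noise, Å
    n_frames: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        pa, pb = self.occupancies
        if not np.isclose(pa + pb, 1.0) or pa <= 0 or pb <= 0:
            raise ValueError("occupancies must be positive and sum to 1")
        if not 0 < self.transition_rate <= 1:
            raise ValueError("transition_rate must be in (0, 1]")

    # -- planted geometry ---------------------------------------------------

    def state_structures(self) -> tuple[np.ndarray, np.ndarray]:
        """Reference structures (A, B); deterministic in the spec only."""
        A = helix_structure(self.n_residues)
        field_rng = np.random.default_rng(2_000_000_000 + self.n_residues)
        u = field_rng.standard_normal((self.n_residues, 3))
        # remove rigid-body content: translations and infinitesimal rotations
        centered = A - A.mean(axis=0)
        rigid = []
        for k in range(3):
            e = np.zeros(3)
            e[k] = 1.0
            rigid.append(np.tile(e, (self.n_residues, 1)).ravel())
            rigid.append(np.cross(centered, e).ravel())
        Q, _ = np.linalg.qr(np.stack(rigid, axis=1))
        flat = u.ravel()
        flat -= Q @ (Q.T @ flat)
        u = flat.reshape(self.n_residues, 3)
        u /= np.sqrt((u**2).sum() / self.n_residues)  # unit RMS per residue
        B = A + self.separation * u
        return A, B

    def planted_rmsd_ab(self) -> float:
        """Exact fitted RMSD between the two reference structures."""
        A, B = self.state_structures()
        _, rmsd = kabsch_superpose(B, A)
        return rmsd

    def expected_cv_centers(self) -> tuple[float, float]:
        """Planted centers of the RMSD-to-A distribution for states A and B.

        Thermal noise of σ per coordinate inflates the RMSD of a state
        about its reference to sqrt(d² + 3σ²).
        """
        d_ab = self.planted_rmsd_ab()
        noise = 3.0 * self.sigma**2
        return float(np.sqrt(noise)), float(np.sqrt(d_ab**2 + noise))


def generate_two_state(spec: TwoStateSpec) -> tuple[Trajectory, np.ndarray]:
    """Trajectory plus true per-frame state labels (0 = A, 1 = B)."""
    rng = np.random.default_rng(spec.seed)
    A, B = spec.state_structures()
    refs = np.stack([A, B])
    pa, pb = spec.occupancies
    # detailed balance: pa·p(A→B) = pb·p(B→A)
    p_ab = spec.transition_rate * pb
    p_ba = spec.transition_rate * pa
    labels = np.empty(spec.n_frames, dtype=int)
    state = int(rng.random() < pb)  # start from the stationary distribution
    for f in range(spec.n_frames):
        labels[f] = state
        p_switch = p_ab if state == 0 else p_ba
        if rng.random() < p_switch:
            state = 1 - state
    noise = rng.standard_normal((spec.n_frames, spec.n_residues, 3)) * spec.sigma
    coords = refs[labels] + noise
    times = np.arange(spec.n_frames) * TIME_STEP_PS
    return Trajectory(ca_topology(spec.n_residues), coords, times), labels


def generate_cv_clusters(
    centers: np.ndarray,
    sigmas: np.ndarray,
    weights: np.ndarray,
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample 2-D collective-variable points from a Gaussian mixture.

    Returns (x, y) series; basin free-energy differences on the resulting
    landscape are −ln(w_i/w_j) in kT by construction.
    """
    centers = np.atleast_2d(np.asarray(centers, float))
    sigmas = np.atleast_1d(np.asarray(sigmas, float))
    weights = np.asarray(weights, float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(weights), size=n, p=weights)
    pts = centers[comp] + rng.standard_normal((n, 2)) * sigmas[comp][:, None]
    return pts[:, 0], pts[:, 1]


# --------------------------------------------------------------------------
# Atomistic interaction fixtures
# --------------------------------------------------------------------------

@dataclass
class AtomisticFixtureSpec:
    """Small donor/acceptor or cation/anion fixture with exact geometry.

    ``kind`` is ``"hbond"`` (Ser OG–HG donating to Glu OE1) or
    ``"saltbridge"`` (Arg NH1 vs phospho-Ser O1P/O2P/O3P).  ``distances``
    gives the per-frame heavy-atom distance (Å); ``angles`` the per-frame
    H–D–A angle in degrees (H-bond fixtures only).  ``phospho_dialect``
    selects the phosphate-oxygen naming convention.
    """

    kind: str = "hbond"
    distances: np.ndarray = field(default_factory=lambda: np.full(10, 3.0))
    angles: np.ndarray | None = None
    phospho_dialect: str = "O1P"   # or "OP1"
    dh_bond_length: float = 1.0

    def __post_init__(self) -> None:
        self.distances = np.atleast_1d(np.asarray(self.distances, float))
        if self.kind not in {"hbond", "saltbridge"}:
            raise ValueError("kind must be 'hbond' or 'saltbridge'")
        if np.any(self.distances <= 0):
            raise ValueError("distances must be positive")
        if self.kind == "hbond":
            if self.angles is None:
                self.angles = np.zeros_like(self.distances)
            self.angles = np.atleast_1d(np.asarray(self.angles, float))
            if self.angles.shape != self.distances.shape:
                raise ValueError("angles and distances must have equal length")
            if np.any((self.angles < 0) | (self.angles >= 180)):
                raise ValueError("angles must lie in [0, 180) degrees")
            # hydrogen may not be pushed into the acceptor
            h_a = np.sqrt(
                self.distances**2
                + self.dh_bond_length**2
                - 2 * self.distances * self.dh_bond_length
                * np.cos(np.deg2rad(self.angles))
            )
            if np.any(h_a < 0.4):
                raise ValueError(
                    "requested geometry places the hydrogen inside the "
                    "acceptor (unsatisfiable distance/angle combination)"
                )
        if self.phospho_dialect not in {"O1P", "OP1"}:
            raise ValueError("phospho_dialect must be 'O1P' or 'OP1'")


def build_interaction_fixture(spec: AtomisticFixtureSpec) -> Trajectory:
    """Trajectory realizing the requested distances/angles exactly.

    The donor (or cation nitrogen) sits at the origin with the acceptor
    (or anion oxygen) along +x at the requested distance; the donor
    hydrogen lies in the xy-plane at the requested H–D–A angle.  Spectator
    atoms are placed far enough away not to satisfy any criterion.
    """
    n_frames = spec.distances.size
    times = np.arange(n_frames) * TIME_STEP_PS
    far = np.array([50.0, 50.0, 50.0])
    if spec.kind == "hbond":
        # residue 44 SER (donor OG + HG1 + CA), residue 335 GLU (OE1 + CA)
        topo = Topology.from_names(
            names=["CA", "OG", "HG1", "CA", "OE1"],
            resids=[44, 44, 44, 335, 335],
            resnames=["SER", "SER", "SER", "GLU", "GLU"],
        )
        coords = np.zeros((n_frames, 5, 3))
        ang = np.deg2rad(spec.angles)
        for f in range(n_frames):
            d = spec.distances[f]
            coords[f, 0] = far                      # donor-side CA, spectator
            coords[f, 1] = (0.0, 0.0, 0.0)          # OG donor
            coords[f, 2] = (
                spec.dh_bond_length * np.cos(ang[f]),
                spec.dh_bond_length * np.sin(ang[f]),
                0.0,
            )                                        # HG1
            coords[f, 3] = far + (5.0, 0.0, 0.0)    # acceptor-side CA
            coords[f, 4] = (d, 0.0, 0.0)            # OE1 acceptor
        return Trajectory(topo, coords, times)

    # salt bridge: ARG 40 vs phospho-SER 44
    op = spec.phospho_dialect
    o_names = {"O1P": ["O1P", "O2P", "O3P"], "OP1": ["OP1", "OP2", "OP3"]}[op]
    topo = Topology.from_names(
        names=["CA", "NH1", "NH2", "CA", *o_names],
        resids=[40, 40, 40, 44, 44, 44, 44],
        resnames=["ARG", "ARG", "ARG", "SEP", "SEP", "SEP", "SEP"],
    )
    coords = np.zeros((n_frames, 7, 3))
    for f in range(n_frames):
        d = spec.distances[f]
        coords[f, 0] = far                          # Arg CA
        coords[f, 1] = (0.0, 0.0, 0.0)              # NH1 — closest nitrogen
        coords[f, 2] = (0.0, 20.0, 0.0)             # NH2, remote
        coords[f, 3] = far + (5.0, 0.0, 0.0)        # Sep CA
        coords[f, 4] = (d, 0.0, 0.0)                # closest phosphate O
        coords[f, 5] = (d + 15.0, 0.0, 0.0)
        coords[f, 6] = (d + 15.0, 5.0, 0.0)
    return Trajectory(topo, coords, times)


# --------------------------------------------------------------------------
# Drifting low-frequency modes
# --------------------------------------------------------------------------

def drifting_mode_series(
    amplitude: float,
    period_fraction: float,
    noise: float,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """amplitude·cos(π·t·period_fraction) + Gaussian noise on t ∈ (0, 1).

    With ``period_fraction=1`` and no noise this is exactly the first
    half-period cosine (cosine content 1); with zero amplitude it is pure
    noise (cosine content typically below 0.1).
    """
    rng = np.random.default_rng(seed)
    t = (np.arange(n) + 0.5) / n
    return amplitude * np.cos(np.pi * t * period_fraction) + rng.normal(
        0.0, noise, n
    )
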