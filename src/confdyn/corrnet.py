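"""Dynamic cross-correlation and correlation-weighted residue networks.

The DCCM entry for residues i, j is
``C(i,j) = <Δr_i·Δr_j> / (<Δr_i²>^{1/2} <Δr_j²>^{1/2})`` over Cα
displacement vectors about their time means: +1 for fully correlated
motion, −1 for anti-correlated, 0 for uncorrelated (or perpendicular,
same-phase) motion.

Residue networks put a node on each Cα and an edge between residues whose
correlation magnitude passes a threshold (optionally AND-filtered by a
Cα–Cα contact cutoff on a reference frame); edge weights are
ω = −ln|C|, so strong correlation means short network distance.  Degree,
closeness and betweenness centralities are computed on this graph, with
betweenness normalized by 2/(N(N−1)) over all node pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .essential_dynamics import CovarianceModel
from .trajectory_core import Trajectory, batched_superpose

__all__ = [
    "DCCMatrix",
    "ResidueNetwork",
    "CentralityProfile",
    "compute_dccm",
    "dccm_from_covariance",
    "build_network",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "centrality_profile",
    "centrality_difference",
    "select_central_residues",
    "centrality_pearson",
]


@dataclass
class DCCMatrix:
    """Symmetric per-residue-pair correlation matrix, entries in [−1, 1]."""

    values: np.ndarray       # (n, n)
    resids: np.ndarray       # (n,)
    undefined: np.ndarray | None = None  # residues with zero fluctuation

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.resids = np.asarray(self.resids, int)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or self.resids.size != n:
            raise ValueError("DCCM must be square with one resid per row")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.resids, columns=self.resids)


@dataclass
class ResidueNetwork:
    """Correlation-weighted residue graph (ω = −ln|C| on included edges)."""

    graph: nx.Graph
    cmin: float
    contact_cutoff: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"i": i, "j": j, "C": d["corr"], "omega": d["weight"]}
            for i, j, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["i", "j", "C", "omega"])


@dataclass
class CentralityProfile:
    """Per-residue degree, closeness and betweenness centralities."""

    resids: np.ndarray
    degree: np.ndarray       # integer edge counts
    closeness: np.ndarray
    betweenness: np.ndarray  # normalized by 2/(N(N−1))
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "resid": self.resids,
                "C_d": self.degree,
                "C_c": self.closeness,
                "C_B": self.betweenness,
            }
        )


# --------------------------------------------------------------------------
# DCCM
# --------------------------------------------------------------------------

def compute_dccm(
    traj: Trajectory,
    selection: str = "name CA",
    fit: bool = True,
) -> DCCMatrix:
    """Cross-correlation matrix of atomic displacements about their means.

    Frames are superposed with the same two-pass mean fit used for the
    covariance analysis, so rigid-body motion does not masquerade as
    correlation.  Residues with zero fluctuation get off-diagonal entries
    of 0 (diagonal 1) and are flagged in ``undefined``.
    """
    if traj.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    idx = traj.topology.select(selection)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    X = traj.coords[:, idx, :]
    if fit:
        ref = X.mean(axis=0)
        X = batched_superpose(X, ref)
        ref = X.mean(axis=0)
        X = batched_superpose(X, ref)
    D = X - X.mean(axis=0)
    inner = np.einsum("fia,fja->ij", D, D) / traj.n_frames
    var = np.diag(inner).copy()
    zero = var <= 0
    denom = np.sqrt(np.where(zero, 1.0, var))
    C = inner / denom[:, None] / denom[None, :]
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    return DCCMatrix(
        values=C,
        resids=traj.topology.resids[idx],
        undefined=np.flatnonzero(zero) if zero.any() else None,
    )


def dccm_from_covariance(model: CovarianceModel) -> DCCMatrix:
    """DCCM from the 3×3 blocks of an existing covariance model.

    C(i,j) = trace(block_ij) / sqrt(trace(block_ii)·trace(block_jj)).
    Consistent with :func:`compute_dccm` on identically fitted data.
    """
    n = model.n_atoms
    blocks = model.covariance.reshape(n, 3, n, 3)
    inner = np.einsum("iaja->ij", blocks)
    var = np.diag(inner).copy()
    zero = var <= 0
    denom = np.sqrt(np.where(zero, 1.0, var))
    C = inner / denom[:, None] / denom[None, :]
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    resids = model.resids if model.resids is not None else np.arange(1, n + 1)
    return DCCMatrix(values=C, resids=np.asarray(resids, int),
                     undefined=np.flatnonzero(zero) if zero.any() else None)


# --------------------------------------------------------------------------
# Network construction and centralities
# --------------------------------------------------------------------------

def build_network(
    dccm: DCCMatrix,
    cmin: float = 0.3,
    contact_cutoff: float | None = None,
    reference_coords: np.ndarray | None = None,
) -> ResidueNetwork:
    """Correlation-weighted residue graph.

    Edge (i, j) is included iff |C_ij| ≥ cmin (and, when a contact filter
    is configured, the reference Cα–Cα distance is within the cutoff).
    Edge weight is ω = −ln|C_ij| ≥ 0; |C| = 0 pairs are never edges
    (infinite weight).
    """
    if contact_cutoff is not None and reference_coords is None:
        raise ValueError("contact filtering requires reference coordinates")
    n = dccm.n_residues
    g = nx.Graph()
    g.add_nodes_from(int(r) for r in dccm.resids)
    absC = np.abs(dccm.values)
    if reference_coords is not None:
        ref = np.asarray(reference_coords, float)
        if ref.shape != (n, 3):
            raise ValueError("reference coordinates must be (n_residues, 3)")
        dist = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=2)
    for i in range(n):
        for j in range(i + 1, n):
            c = absC[i, j]
            if c < cmin or c <= 0.0:
                continue
            if contact_cutoff is not None and dist[i, j] > contact_cutoff:
                continue
            omega = -np.log(min(c, 1.0))
            g.add_edge(
                int(dccm.resids[i]),
                int(dccm.resids[j]),
                weight=float(max(omega, 0.0)),
                corr=float(dccm.values[i, j]),
            )
    return ResidueNetwork(graph=g, cmin=cmin, contact_cutoff=contact_cutoff)


def degree_centrality(net: ResidueNetwork) -> pd.Series:
    """Number of incident edges per residue (binary adjacency degree)."""
    g = net.graph
    s = pd.Series({n: int(d) for n, d in g.degree()}).sort_index()
    s.index.name = "resid"
    s.name = "C_d"
    return s


def closeness_centrality(net: ResidueNetwork) -> pd.Series:
    """Closeness (N−1)/Σ_j d(i,j) with Dijkstra distances on ω.

    On a disconnected graph the sum runs over the reachable nodes only
    (with their count replacing N); isolated nodes get 0.
    """
    g = net.graph
    out = {}
    for node in g.nodes:
        lengths = nx.single_source_dijkstra_path_length(g, node, weight="weight")
        lengths.pop(node, None)
        total = sum(lengths.values())
        out[node] = (len(lengths) / total) if total > 0 else 0.0
    s = pd.Series(out).sort_index()
    s.index.name = "resid"
    s.name = "C_c"
    return s


def betweenness_centrality(net: ResidueNetwork) -> pd.Series:
    """Betweenness C_B(i) = [2/(N(N−1))] Σ_{a<b} τ_i^{ab}/N_ab.

    All weighted shortest paths are counted (tie multiplicity included);
    endpoints are excluded from their own pair terms and disconnected
    pairs contribute nothing.
    """
    g = net.graph
    n = g.number_of_nodes()
    raw = nx.betweenness_centrality(g, normalized=False, weight="weight")
    scale = 2.0 / (n * (n - 1)) if n > 1 else 0.0
    s = pd.Series({k: v * scale for k, v in raw.items()}).sort_index()
    s.index.name = "resid"
    s.name = "C_B"
    return s


def centrality_profile(net: ResidueNetwork, **params) -> CentralityProfile:
    """All three centralities on a common residue index."""
    cd = degree_centrality(net)
    cc = closeness_centrality(net)
    cb = betweenness_centrality(net)
    resids = cd.index.to_numpy()
    return CentralityProfile(
        resids=resids,
        degree=cd.to_numpy(),
        closeness=cc.reindex(resids).to_numpy(),
        betweenness=cb.reindex(resids).to_numpy(),
        params={"cmin": net.cmin, "contact_cutoff": net.contact_cutoff, **params},
    )


def centrality_difference(
    profileA: CentralityProfile,
    profileB: CentralityProfile,
    threshold: float = 0.12,
    measure: str = "betweenness",
) -> tuple[pd.Series, np.ndarray]:
    """Per-residue centrality difference A − B plus the |Δ| ≥ threshold set."""
    if not np.array_equal(profileA.resids, profileB.resids):
        raise ValueError("profiles cover different residue sets")
    a = getattr(profileA, measure)
    b = getattr(profileB, measure)
    delta = pd.Series(a - b, index=profileA.resids, name=f"delta_{measure}")
    delta.index.name = "resid"
    selected = delta.index[np.abs(delta.to_numpy()) >= threshold].to_numpy()
    return delta, selected


def select_central_residues(
    profile: CentralityProfile,
    threshold: float = 0.15,
    measure: str = "betweenness",
) -> np.ndarray:
    """Residues whose centrality meets an absolute threshold."""
    vals = getattr(profile, measure)
    return profile.resids[vals >= threshold]


def centrality_pearson(profile: CentralityProfile) -> pd.DataFrame:
    """Pairwise Pearson r between the degree/closeness/betweenness profiles."""
    df = pd.DataFrame(
        {
            "C_d": profile.degree.astype(float),
            "C_c": profile.closeness,
            "C_B": profile.betweenness,
        }
    )
    return df.corr(method="pearson")
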