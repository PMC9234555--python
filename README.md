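# confdyn

Conformational-dynamics analysis of protein MD trajectories, built for
questions like the one posed by phosphorylation of DNA polymerase β:
does a modification split the ensemble into distinct conformational
states, which domains move together, which hydrogen bonds and salt
bridges rearrange, and through which residues does correlated motion
flow.

The package covers the full post-simulation pipeline:

- **Structural metrics** — RMSD, radius of gyration and per-residue RMSF
  time series with density-normalised distributions and mode detection.
- **Interactions** — geometric hydrogen-bond occupancy (d ≤ 3.5 Å,
  H–D–A angle ≤ 30°) and minimum N–O salt-bridge distance traces, with
  moving-average smoothing and trace cross-correlation.
- **Essential dynamics** — the 3N×3N Cartesian covariance
  `Cov_ij = ⟨(r_i − ⟨r_i⟩)(r_j − ⟨r_j⟩)⟩` on fitted Cα coordinates, its
  eigenmodes, per-mode variance fractions, cosine-content convergence
  screening, and porcupine vector export.
- **Free-energy landscapes** — `G = −kT ln(P/P_max)` over any CV pair
  ((RMSD, Rg) or (PC1, PC2)), with basin extraction and
  representative-frame selection.
- **Correlation networks** — the dynamic cross-correlation matrix
  `C(i,j) = ⟨Δr_i·Δr_j⟩ / (⟨Δr_i²⟩⟨Δr_j²⟩)^{1/2}`, a residue graph with
  edge weights `ω = −ln|C_ij|`, and degree / closeness / betweenness
  centralities (`C_B(i) = [2/(N(N−1))] Σ_{a<b} τ_i^{ab}/N_ab`) with
  between-condition difference maps.
- **Synthetic generators** — trajectories with planted block
  covariance, two-state hopping with known occupancies and separations,
  exact-geometry H-bond/salt-bridge fixtures and drifting modes, used
  to validate every stage against known ground truth.

File I/O (PDB/GRO topologies; XTC/TRR/DCD/multi-model-PDB trajectories)
goes through MDAnalysis; graphs through networkx. See
[docs/methods.md](docs/methods.md) for models, conventions and
numerical choices.

## Worked example

Generate a two-state hopping trajectory (30 Cα residues, 7 Å planted
state separation) and run the core analyses:

```python
import numpy as np
from confdyn.synthetic_data import TwoStateSpec, generate_two_state
from confdyn.structure_metrics import rmsd_series, distribution
from confdyn.landscape import build_fel, find_basins
from confdyn.corrnet import compute_dccm, build_network, centrality_profile

spec = TwoStateSpec(n_residues=30, separation=7.0, n_frames=5000, seed=42)
traj, labels = generate_two_state(spec)
A, B = spec.state_structures()

rmsd = rmsd_series(traj, A, fit=True)
dist = distribution(rmsd, n_bins=60)
print("mean RMSD: %.2f A" % rmsd.mean)
print("modes:", ", ".join("%.2f A" % p[0] for p in dist.peaks))

fes = build_fel(rmsd, rmsd_series(traj, B, fit=True), n_bins=24,
                names=("rmsd_A", "rmsd_B"))
for b in find_basins(fes, max_G=2.0):
    print("basin %d: center=(%.2f, %.2f) A, G=%.2f kT" % (b.label, *b.center, b.min_G))

profile = centrality_profile(build_network(compute_dccm(traj), cmin=0.3))
for i in np.argsort(profile.betweenness)[-3:][::-1]:
    print("residue %d: C_B=%.3f" % (profile.resids[i], profile.betweenness[i]))
```

Output:

```
mean RMSD: 3.14 A
modes: 0.37 A, 6.98 A
basin 0: center=(0.46, 7.02) A, G=-0.00 kT
basin 1: center=(7.01, 0.42) A, G=0.35 kT
residue 4: C_B=0.193
residue 15: C_B=0.179
residue 1: C_B=0.149
```

The RMSD distribution is bimodal at the two planted state positions
(the generator's analytic centres are 0.43 Å and 7.01 Å), the
free-energy landscape over the two RMSD coordinates resolves exactly
two basins at those centres, and the basin free-energy gap (0.35 kT)
reflects the 41%/59% state occupancies (−ln(0.41/0.59) ≈ 0.36 kT).  The
betweenness profile ranks the residues that carry the most shortest-path
traffic in the correlation network.

The same analyses are available from the shell:

```sh
confdyn synth twostate --out traj.pdb --n-residues 30 --n-frames 500 --seed 42
confdyn rmsd --top traj.pdb --traj traj.pdb --select "name CA" --out rmsd.csv
confdyn fel  --top traj.pdb --traj traj.pdb --select "name CA" --n-bins 24
confdyn centrality --top traj.pdb --traj traj.pdb --select "name CA" --cmin 0.3
confdyn run --config config.yaml   # full two-condition comparison
```

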