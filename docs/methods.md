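# Methods

`confdyn` analyses protein conformational dynamics from MD trajectories.
It targets the kind of question asked of systems such as DNA polymerase β
under post-translational modification: has the ensemble split into
distinct conformational states, which domains move together, which
contacts break or form, and through which residues does correlated
motion flow.  This note records the models, conventions and numerical
choices behind each stage, and what the synthetic validation inputs do
and do not establish.

## Frame model and superposition

Coordinates are stored in Å, times in ps.  Residue numbering follows the
source file and is never renumbered, so results can be cited against
crystal-structure numbering (e.g. S44, E335 in the 2FMS-derived pol β
systems).  The default domain map is the pol β decomposition — lyase
10–87, DNA-binding (D) 90–150, catalytic (C) 151–260, nascent-base-pair
(N) 261–335 — and is fully overridable.

Least-squares superposition is weighted Kabsch (SVD of the weighted
cross-covariance with a reflection guard, so the rotation is always
proper).  Weights default to uniform: analyses here run on Cα atoms,
where mass weighting is a no-op; it remains available.  Batched RMSD
uses the singular-value identity `rmsd² = (E0 − 2Σσ_k s_k)/W`; because
that expression cancels catastrophically for near-identical structures,
mean-square deviations below 1e−12 of E0 are clamped to exactly zero
(this truncates only RMSDs below ~1e−6 Å relative scale).

Trajectory reading is delegated to MDAnalysis (PDB/GRO topologies;
XTC/TRR/DCD/multi-model-PDB coordinates; nm-based formats converted to Å
on read), with an optional frame stride for desk-scale subsampling of
densely written trajectories (e.g. 2 ps output intervals).  The
selection mini-language (`name`, `resid`, `resname`, `and`) is evaluated
on the internal topology, so atom classification never depends on the
reader.

## Structural metrics

- RMSD: per-frame minimum over rigid transforms against a chosen
  reference (fit on by default), or the raw deviation with fit off.
- Rg: `Rg² = Σ w_k |r_k − r̄|² / Σ w_k`, mass-weighted by default (the
  gyrate convention); an unweighted option suits Cα-only work.
- RMSF: fluctuation about the time-average structure after a two-round
  iterative fit (fit to the raw mean, re-average, fit again), the usual
  trajectory-tool convention.
- Distributions: density-normalised histograms (default 100 bins).
  Modes are local maxima with prominence at least 5% of the maximum
  density, judged against the histogram itself; a boundary bin counts
  as a mode when it tops its neighbour and the density falls by the
  threshold before any higher bin.  This reproduces the
  one-peak/two-peak dichotomy between a unimodal and a state-hopping
  ensemble while reporting zero modes for a flat density.

## Interactions

Hydrogen bonds use the geometric criterion: donor–acceptor distance
≤ 3.5 Å and hydrogen–donor–acceptor angle ≤ 30°.  Donor, acceptor and
hydrogen roles come from atom-name tables (standard PDB/CHARMM dialects,
including O1P/O2P/O3P and OP1/OP2/OP3 phosphoserine spellings), and
hydrogens attach to donors by proximity (≤ 1.25 Å in-frame), so
topologies without bond records work; a donor with no attached hydrogen
is skipped with a warning.  Occupancy between two residues counts a
frame when at least one qualifying triple exists in either donation
direction, using all donors/acceptors of both residues.

Salt bridges track the per-frame minimum distance between basic
side-chain nitrogens (NZ, NH1/NH2/NE, His ring nitrogens) and
acidic/phosphate oxygens (OD*/OE*, phosphate O's, terminal
carboxylates).  "Formed" defaults to ≤ 4.0 Å minimum N–O distance — a
conventional cutoff, configurable, since distance traces rather than a
formation cutoff are usually what gets reported.  Distance traces can be
smoothed with a centred moving average (edge windows shrink; length
preserved; the conventional display smoothing is a 500-frame window) and
compared by Pearson correlation, which is how coupled contact
rearrangements (one bridge forming as another breaks) are quantified.

## Essential dynamics

The covariance matrix `Cov_ij = <(r_i − <r_i>)(r_j − <r_j>)>` is built
over the 3N Cartesian coordinates of the selected atoms, unit-weighted
(Cα analyses; no mass weighting) with denominator n_frames — the
ensemble-average definition, not the n−1 sample estimator.  Frames are
fitted to the mean structure with the two-pass scheme above; the final
fit reference is stored on the model so that projecting the same
trajectory reproduces the eigenvalues exactly (and new trajectories are
projected in the model's own frame).  Eigenpairs come from `eigh`,
sorted descending with ties keeping the lower original index.

Cosine content of a projection is the half-cosine overlap

    c = (2/T)·(∫ p(t) cos(πt/T) dt)² / ∫ p(t)² dt,

evaluated with the midpoint rule on the sampled series.  A projection
resembling the first half-period cosine is indistinguishable from random
diffusion, so components are screened at c ≤ 0.1 (default) before being
used as landscape coordinates; if no screened mode passes, the error
says to extend the sampling rather than silently using an unconverged
mode.  Porcupine vectors reshape an eigenvector to per-residue arrows,
rescaled so arrow norms sum to a chosen length, with individual arrows
capped (default 15 Å) for display.

## Free-energy landscapes

For any two collective variables (RMSD/Rg or PC1/PC2), the surface is
`G = −ln(P/P_max)` in kT over a 2-D histogram (default 32×32 bins,
T = 300 K recorded for unit conversion), referenced to the most
populated bin; empty bins are masked as infinitely high and displayed at
max-populated-G + 1 kT when a filled grid is required.  Basins are
8-connected components of the populated region with G at or below a
cutoff (default 3 kT); separate components whose minima nearly coincide
(closer than `min_separation_bins`, Chebyshev) merge into the deeper
one.  A basin's representative frame is the frame nearest the minimum
bin's centre in z-scored CV space (the CVs typically have very different
dynamic ranges); exact ties resolve to the earliest frame.

## Correlation networks

The DCCM is `C(i,j) = <Δr_i·Δr_j> / (<Δr_i²><Δr_j²>)^{1/2}` on Cα
displacement vectors about their time means, after the same two-pass
superposition as the covariance fit (so rigid-body drift does not appear
as correlation).  Zero-fluctuation residues get off-diagonal entries of
0 and are flagged.  An equivalent path builds the DCCM from the 3×3
blocks of an existing covariance model.

The residue network has one node per Cα and an edge wherever
`|C_ij| ≥ cmin` (default 0.3), optionally AND-filtered by a Cα–Cα
contact cutoff (default 10 Å when enabled) on a reference frame; with no
sparsification the binary degree would be uninformative on an
effectively complete graph.  Edge weights are `ω = −ln|C|`; the
logarithm base is a pure rescaling that leaves shortest-path *structure*
unchanged, and the natural log is used throughout — stated prominently
because ω values themselves are base-dependent.

Centralities follow the per-measure conventions: degree is the binary
edge count; closeness is `(N−1)/Σ_j d(i,j)` with Dijkstra distances on ω
(on disconnected graphs the sum and count run over reachable nodes only;
isolated nodes get 0); betweenness counts all weighted shortest paths
with tie multiplicity (Brandes accumulation) and normalises by
`2/(N(N−1))` — over all node pairs, not the (N−1)(N−2)/2 non-endpoint
pairs, so the values match the convention used in correlation-network
analyses of allosteric signalling.  Comparative analysis selects
residues by absolute centrality (default C_B ≥ 0.15) and by
between-condition difference (default |ΔC_B| ≥ 0.12), and reports
Pearson correlations among the three measures.  A start/stop time window
restricts all network stages to the equilibrated part of a trajectory.

## Synthetic validation inputs

The generators plant known statistical structure so that every analysis
can be checked against the planted value:

- **Block-covariance Gaussian trajectories**: fluctuations around a
  coarse helical mean (rise 1.5 Å, 100° twist — non-degenerate for
  fitting; otherwise cosmetic) with covariance `kron(R, I₃)·σ²`, where R
  has within-block correlation ρ and zero between blocks.  The planted
  DCCM entry is then exactly ρ.  Default σ = 1 Å, ρ = 0.8, 10k frames.
  Because these frames share a fixed external frame, planted-value
  recovery is measured with superposition off; fitting would remove the
  rigid-body component of a planted block mode.
- **Two-state hopping**: a stationary, detailed-balanced Markov chain
  between two reference structures separated by a displacement field
  orthogonal to the rigid-body modes, scaled to a target fitted RMSD
  (default 7 Å, the scale of a domain-rearrangement transition), with
  per-coordinate noise σ = 0.25 Å.  The generator exposes its own
  analytic CV centres — `sqrt(3σ²)` and `sqrt(d_AB² + 3σ²)` on the
  RMSD-to-reference axes — fixed by the spec alone, against which basin
  centres are validated.
- **CV-space Gaussian mixtures**: free-energy calibration, where the
  basin gap must equal −ln(w₁/w₂) kT by construction.
- **Atomistic fixtures**: donor–H–acceptor triads and Arg/phospho-Ser
  ion pairs realising requested distances and angles exactly (to 1e−6),
  in both phosphate naming dialects; unsatisfiable geometry (hydrogen
  forced into the acceptor) is rejected.
- **Drifting modes**: half-cosine plus noise series for cosine-content
  calibration.

All generators are pure functions of spec + seed.  What they do *not*
emulate: anharmonic single-state dynamics, gradual (non-instantaneous)
state transitions, solvent/ion degrees of freedom, and realistic
force-field energetics.  Passing tests therefore establish the
correctness of the estimators and their conventions, not the
convergence behaviour of real MD ensembles — on real data, sampling
quality must still be judged with the cosine-content screen and window
sensitivity.

## Problem sizes and tolerances

Validation runs use 5–30 residues and 2k–50k frames: large enough for
the sampling laws being tested (e.g. ±0.05 on a correlation at 10k
frames, ±0.1 kT on a basin gap at 50k samples), small enough to run
comfortably on a single workstation core.  Exact identities (DCCM
limits, oracle agreement, spectral identities) are asserted at 1e−10 or
relative 1e−8; statistical recoveries at the 2-standard-error scale of
their planted conditions.  Stochastic checks aggregate over ≥ 10 seeds
rather than asserting single draws.

## Known limitations

- Donor/acceptor classification is name-table-based; exotic residues or
  nonstandard naming need table extensions, not bond perception.
- No periodic-boundary handling: trajectories are assumed whole-molecule
  processed, as is standard before this kind of analysis.
- Closeness on disconnected graphs uses the reachable-set convention;
  comparing closeness across conditions with different connectivity
  should be done with that in mind.
- Basin extraction is histogram-based; basins separated by a populated
  saddle below the G cutoff merge into one component.
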