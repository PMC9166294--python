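# Methods

## Contact graph

Each amino-acid residue contributes one node holding all of its heavy
atoms; each selected ligand molecule (cholesterol in the motivating SMO
application) is a single *interactor* node.  Hydrogens belong to no
node; waters and monoatomic ions are never nodes, and unselected hetero
molecules (including glycans) are excluded — the network is residues
plus named ligands only.

The distance between two nodes in a frame is the **minimum heavy-atom
distance** over all atom pairs, not a centroid distance: contact
semantics must see side-chain contacts, and an interactor as large as a
sterol would otherwise never register contacts at a 4.5 Å midpoint.
The per-frame contact score is a Gaussian-smoothed step

    s(d) = ½ · erfc((d − c) / (σ√2)),

exactly ½ at the cutoff `c` and point-symmetric about `(c, ½)`.  The
defaults `c = 4.5 Å` and `σ = 1.38 Å` are the values used for
heavy-atom contact definitions in allosteric-pathway analyses of SMO.
Smoothing is applied per frame and then time-averaged (not applied to a
time-averaged distance), so an edge weight is a smoothed contact
*frequency* in [0, 1]; weights below `prune_below = 1e-4` are stored as
exact zeros.  Edge weights are contact frequencies only; no
dynamical-coupling or correlation factor multiplies them.  Sequence-
adjacent residues keep their edges — backbone pathways (e.g. flow along
a helix extension) are physically meaningful routes.  Periodic-boundary
imaging is deliberately out of scope: input trajectories must already be
whole-molecule imaged.

Internally every length is Å; configuration values may carry `nm`/`A`
suffixes and are converted on load (with a decimal shift, so `0.138 nm`
and `1.38` are bit-identical).

## Current flow

The graph is a resistor network with edge conductances `w_ij`.  One unit
of current is injected equally across the source nodes (+1/|S| each) and
extracted equally across the sinks (−1/|T| each) — an equal-split
convention rather than a zero-resistance supernode, which keeps
per-source potentials meaningful; the difference between the two
conventions is a documented modelling choice, not an approximation.
Potentials solve `L v = b` by direct sparse factorization of the
Laplacian restricted to the connected component containing the
terminals, with the gauge fixed by grounding the lexicographically first
sink (determinism).  The solve is rejected if the residual ‖Lv − b‖∞
exceeds 1e-9, and a dense Moore–Penrose pseudoinverse solver is retained
in the test suite as an independent oracle (agreement to 1e-8 on
hundreds of random graphs).

Node throughflow uses the current-flow-betweenness convention
`F_k = ½ Σ_j |i_kj|` for interior nodes; source/sink nodes report their
net injected/extracted magnitude.  Flows are per unit injected current —
the natural normalization when comparing ligand-occupancy states; no
claim is made that absolute values match any particular published axis
scaling.  Effective resistance is the mean source potential minus the
mean sink potential per unit current; it obeys the series/harmonic
closed forms and Rayleigh monotonicity, both enforced by tests.

State comparison reports per-node mean, SEM (sd/√n over replicates,
reported as *missing* for n = 1, never 0) and delta versus a reference
condition (the ligand-free condition when present, else the
alphabetically first).  Interactor nodes absent from a condition are
reported as missing, not as zero flow.

## Observables

* **RMSF** — frames are superposed on an iterated mean structure (two
  passes: mean of the raw frames, then mean of the first-pass-aligned
  frames) using all residue-node anchors (Cα), then
  `RMSF_i = √⟨‖r_i − ⟨r_i⟩‖²⟩`.  Aligning on the whole protein rather
  than the analyzed subset reports domain fluctuations relative to the
  receptor as a whole.
* **Distance series** — per-frame Cα–Cα distances (superposition is
  irrelevant for pairwise distances); histograms use 0.5 Å bins anchored
  at 0 and density normalization so replicate overlays are comparable.
* **Hydrogen bonds** — a frame counts when the donor–acceptor heavy-atom
  distance is ≤ 3.0 Å; the D–H···A ≥ 150° criterion applies only when
  the topology actually contains donor hydrogens (attachment = same
  residue, ≤ 1.25 Å in the first frame), since the distance cutoff is
  the primary criterion and many analysis topologies are heavy-atom
  only.
* **Ligand stability** — each frame is superposed on frame 0 via the
  protein selection; the ligand's heavy-atom center-of-geometry
  displacement and its RMSD versus frame 0 are reported without further
  fitting, so in-place reorientation shows up in RMSD but not in COM
  displacement.
* Residue-numbering differences between constructs (e.g. human V329 vs
  mouse V333) are handled by per-chain integer offsets in the
  configuration, never hardcoded.

## Synthetic ground truth

The generators emit real `StructureModel`/`TrajectoryEnsemble` objects
(and multi-model PDB + YAML sidecars through their `write()` method), so
the full pipeline is exercised through its public interfaces.

* **Elastic network** — Kirchhoff matrix Γ with unit springs within
  10 Å; frames are reference coordinates plus per-axis Gaussian
  displacements with covariance `(kT/γ)·Γ⁺`, so
  `RMSF_i = √(3·(kT/γ)·Γ⁺_ii)` exactly in expectation.  `kT/γ = 1 Å²`
  by default, giving sub-Å fluctuations typical of a folded protein.
* **Bottleneck system** — source/sink patches (atoms 4 Å apart) joined
  only by a bridge chain at 5 Å steps; the direct source–sink distance
  is ≥ 10 Å, where the smoothed contact falls below the prune threshold,
  so every bridge node must carry the full unit current.  Background
  nodes hang off the source patch as a dead-end chain placed diagonally
  away from the pathway so they pick up no shunt current.  The generator
  re-derives the contact graph of its own noiseless geometry and refuses
  to emit a system with a source–sink bypass.
* **Two-route system** — route edge weights are set by inverting s(d)
  for target weights `g` and `r·g`, so with equal edge counts the
  current split is exactly `1/(1+r)` vs `r/(1+r)`.  Routes run on lanes
  ±5 Å apart; route nodes are three-atom residues because node *extent*
  is what keeps non-adjacent pairs beyond contact range while adjacent
  gaps set the weight — the one place the synthetic systems deviate from
  single-atom pseudo-residues (interactor beads are three-atom rigid
  groups throughout, so min-distance and centroid conventions are both
  exercised).
* **Occupancy series** — a 5-node backbone chain with ligand site A
  bridging the central segment in parallel with the backbone and site B
  bridging a weakly coupled side region.  Construction guarantees the
  two qualitative orderings used as ground truth: flow(A) > flow(B) when
  both are bound, and flow(A | both) < flow(A | A-only).
* Contact persistence < 1 is realized by displacing bridge nodes 25 Å
  out of plane in a Bernoulli-selected fraction of frames; positional
  jitter (SD 0.2 Å) keeps persistent/absent weights near 1/0 with
  controlled intermediate values.
* Every generator is a pure function of spec + seed; per-replicate seeds
  derive from a base seed plus the replicate index so replicate SEMs are
  reproducible.

What the synthetic systems do **not** emulate: real lipid bilayers,
force-field energetics, anisotropic or correlated side-chain dynamics,
or the sheer size of a receptor simulation.  Passing the recovery tests
shows the *machinery* (partitioning, contact averaging, flow algebra,
RMSF estimation) is correct, not that any particular biological
conclusion follows from a given trajectory.

## Problem sizes and numerical choices

The test suite and the acceptance script run on deliberately small
systems — 5–12-node random graphs (200 of them for the oracle
comparison), ~10–20-node synthetic trajectories with 6–20 frames, and
5 000-frame elastic-network samples — sizes at which the dense
pseudoinverse oracle is exact and the whole validation completes in
seconds.  Solver residual tolerance is 1e-9; oracle agreement 1e-8;
closed-form fixtures 1e-10.  B-factor output rounds half away from zero
to two decimals, with min–max scaling onto [0, 99.99] for values that
do not fit the fixed-width field.  Frame averaging sorts per-frame
contact terms before summation (exact frame-permutation invariance) up
to ~1 GiB of scratch, beyond which a compensated streaming sum is used.

## Known limitations

* The structure worked example on the deposited active-state SMO
  structure (PDB 6O3C, two bound cholesterols ~45 Å apart) requires
  downloading that entry; the corresponding test fails without network
  access rather than skipping.
* Mutual-information/generalized-correlation edge weighting, shortest-
  path or max-flow pathway definitions, and statistical tests beyond
  mean/SEM/delta are out of scope.
* mmCIF writing, connectivity perception and protonation assignment are
  not provided; multi-model PDB is the native trajectory format and
  XTC/DCD support relies on MDAnalysis.
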