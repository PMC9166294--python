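# aflow — current-flow allostery analysis of MD contact networks

`aflow` quantifies allosteric communication in membrane-protein
simulations by treating the time-averaged heavy-atom contact map of a
trajectory as a resistor network and measuring how much of a unit current
injected at a set of *source* residues and extracted at a set of *sink*
residues passes through every node.  It was built around a concrete use
case in Hedgehog signalling: the Smoothened (SMO) receptor binds
cholesterol at two sites roughly 45 Å apart — a shallow groove in the
extracellular cysteine-rich domain (CRD) and a pocket in the
seven-helix transmembrane domain (TMD) — and communication between the
sterol pocket and the intracellular "ionic lock" on helices α6/α7 is what
couples sterol binding to receptor activation.  Bound lipids and ligands
participate in that communication, so each selected ligand molecule
(e.g. one cholesterol) becomes its own network node, an *interactor*
node, alongside the per-residue nodes.

## Model

* **Nodes.** One node per amino-acid residue (all its heavy atoms); one
  node per selected ligand/lipid molecule.  Waters and ions are never
  nodes.
* **Edges.** For every node pair the minimum heavy-atom distance
  `d_ij(t)` in each frame is smoothed through a Gaussian step,
  `s(d) = ½·erfc((d − c)/(σ√2))` with defaults `c = 4.5 Å` and
  `σ = 1.38 Å`, and averaged over frames:
  `w_ij = ⟨s(d_ij(t))⟩_t ∈ [0, 1]`.
* **Flow.** Edge weights are conductances.  With `+1/|S|` current
  injected at each source and `−1/|T|` extracted at each sink, node
  potentials solve the graph-Laplacian system `L v = b`; the information
  flow through an interior node is `F_k = ½ Σ_j |w_kj (v_k − v_j)|`
  (current-flow betweenness).  All flows are per unit injected current,
  so they compare directly across ligand-occupancy states; replicate
  simulations are aggregated as mean ± SEM.
* **Observables.** Per-residue RMSF after two-pass iterated-mean Kabsch
  superposition, inter-residue Cα distance series/histograms (the
  α2–α6 opening metric of GPCR activation), hydrogen-bond occupancy
  (3 Å donor–acceptor cutoff, D–H···A ≥ 150° when hydrogens exist), and
  bound-ligand drift (COM displacement and RMSD in the protein frame).

## Worked example

Every analysis stage can be exercised on built-in synthetic systems with
known ground truth.  The four-condition ligand-occupancy series mimics a
receptor simulated with no sterol, a sterol at site A (on the
source→sink pathway), a sterol at site B (bridging a side region), or
both:

```python
from aflow.contacts import build_contact_graph
from aflow.flow import FlowNetwork, compute_information_flow
from aflow.synthetic import generate_state_series

for state, sy in generate_state_series(seed=0).items():
    graph = build_contact_graph(sy.trajectory, sy.node_map)
    flow = compute_information_flow(FlowNetwork(graph, sy.sources, sy.sinks))
    sterols = {lab: flow.throughflow[lab]
               for lab, kind in flow.node_kinds.items() if kind == "interactor"}
    print(f"{state:>7s}  R_eff = {flow.effective_resistance:5.2f}  "
          + "  ".join(f"{lab}: {v:.3f}" for lab, v in sterols.items()))
```

prints

```
   none  R_eff = 11.10
 A_only  R_eff =  7.65  L:CLR101: 0.593
 B_only  R_eff = 10.49  L:CLR102: 0.125
   both  R_eff =  7.76  L:CLR101: 0.565  L:CLR102: 0.055
```

Reading the numbers: the on-path sterol (site A) carries ~0.59 of the
unit source→sink current and lowers the effective source–sink resistance
from 11.1 to 7.7; the peripheral sterol (site B) carries far less; and
occupying both sites *reduces* the flow through site A (0.593 → 0.565)
because site B opens a parallel route — the same qualitative signature
seen for the CRD- and TMD-bound cholesterols in SMO.

Real trajectories run through the CLI:

```sh
aflow run -c config.yaml          # full pipeline: graphs, flow, RMSF, H-bonds …
aflow synth --kind bottleneck -o fixtures/   # ground-truth synthetic systems
aflow flow --graph edges.csv --sources A:ASP99 --sinks A:ARG455
```

The YAML config names conditions (topology + trajectory files +
replicate ids), source/sink residues (e.g. the CRD-pocket set D99, L112,
W113, Y134, I160, V161, I500 and the ionic-lock set R455, F459, W539 for
mouse SMO), interactor selectors (`residue_name: CLR`), contact
parameters (unit suffixes allowed: `cutoff: "0.45 nm"`), per-chain
numbering offsets, and distance/H-bond pairs.  Outputs are CSV tables
plus a JSON manifest with checksums; reruns are byte-identical.

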