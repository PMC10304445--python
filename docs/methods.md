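# Methods

## Model

The quantum model is an equivariant quantum graph circuit: one qubit per
node of the (heavy-atom) molecular graph, a node-permutation-equivariant
parameterized circuit, and a permutation-invariant measurement. The circuit
is built from *equivariantly diagonalizable unitaries* (EDUs),

    EDU = (V† ⊗ V†) D (V ⊗ V),

with a node-local unitary `V` and a diagonal two-qubit unitary `D`. We take
`D = RZZ(d)` (symmetric under qubit exchange, matching undirected bonds) and
`V` either an arbitrary ZYZ single-qubit unitary `U3(a,b,c) = RZ(a) RY(b)
RZ(c)` (*default* variant, 3 angles) or a bare `RY` (*simple*, 1 angle). All
rotations follow the convention `RP(θ) = exp(−iθP/2)` for a Pauli word `P`.

Parameter sharing is what makes the circuit a *graph* network:

* node-layer angles are shared by all atom qubits within a layer (a master
  qubit, if present, has its own per-layer angles);
* EDU node-local angles `V` are indexed by **bond type only** and shared
  across layers;
* the diagonal angle `d_l` is indexed by **layer only** and shared across
  bond types.

EDUs with different parameters do not commute in general, so applying them
bond-by-bond in arbitrary order would break permutation equivariance. EDUs
that share both `V` and `D` *do* commute (their product is jointly
diagonalized by `V ⊗ V`), therefore the link layer applies all bonds of one
type as a block, in the fixed total order single → aromatic → double →
triple → master. Within a block the bonds are applied in ascending
(min, max)-lexicographic order; this is pure presentation (commutation
makes any order equivalent to 1e-10 or better) but fixes bit-reproducible
output. The master block runs last: the ordering must be total and the
master link is an artificial feature, so it is appended after the chemical
bond types.

The readout runs over **all** qubits including the master qubit: the master
node is a node of the augmented graph as the circuit sees it, and excluding
it would make the readout depend on node identity, which the invariant
measurement deliberately avoids.

Output bound: every expectation lies in [−1, 1], so |prediction| ≤ |r0| +
|r1| (+ |r2| for the global readout). The readout coefficients are the
model's only way to reach target magnitudes outside that band.

## Encodings

Fixed schemes map atom features to the `(RY, RZ)` encoding angles:

| scheme | RY | RZ |
|---|---|---|
| `an` | tetrahedron polar angle | tetrahedron azimuth |
| `an_nh` | `(2z−7)π/4` | `2π·nh/5` |
| `an_arom_hyb` | `(2z−7)π/4` | `(−1)^a (2h−1) π/6`, `h ∈ {1,2,3}` |

For `an`, the four element states sit at the vertices of a tetrahedron
inscribed in the Bloch sphere (C at the pole; N, O, F at polar angle
`arccos(−1/3)` and azimuths 0, ±2π/3), the maximally spread configuration
of four single-qubit states: all pairwise Bloch-vector inner products equal
−1/3. Reading the RY angle as the polar and the RZ angle as the azimuthal
Bloch angle is exact for the `RY`-then-`RZ` preparation from |0⟩.

The hybrid encoding replaces the fixed table by a trainable network
(one-hot features → hidden 4, ReLU → 2 outputs, `2π·sigmoid`), shared by all
nodes so equivariance is preserved. Input widths are 9 (`an_nh` features:
4 elements + 5 hydrogen counts) and 8 (`an_arom_hyb`: 4 elements + 1
aromatic flag + 3 hybridizations), giving 50 and 46 parameters
(`4d + 4 + 8 + 2`). Aromaticity enters as a single binary entry, not a
width-2 one-hot — this is what makes the 8-input width (and the
46-parameter count) come out.

The master qubit is prepared in the fixed, non-trainable |+⟩ state
(`RY(π/2)`), which is distinct from every fixed atom state; a trainable
master state would blur the parameter-count comparisons between variants.

## Gradients

Every circuit gate is `exp(−iθP/2)` with `P² = I`, so the parameter-shift
rule is exact: `∂f/∂θ = [f(θ+π/2) − f(θ−π/2)]/2` per gate occurrence. A
shared scalar (e.g. a bond-type angle appearing in `V` and, negated, in
`V†`, on both qubits of every bond of that type) accumulates the
coefficient-weighted sum over its occurrences. The implementation caches
prefix states so each shifted evaluation resumes at the shifted gate rather
than re-running the whole circuit. Readout coefficients are linear and get
analytic gradients; hybrid encoding angles get parameter-shift derivatives
that are then backpropagated analytically through the small encoding
network. Classical models use hand-written reverse mode (including
subgradient routing through the max aggregation). All routes are tested
against central finite differences (step 1e-6, relative tolerance 1e-5);
coordinates where both values are below 1e-6 are compared absolutely at
1e-8, since central differences cannot resolve a relative error there.

## Structural accounting

`count_single_qubit_gate_layers` uses a fixed convention: each encoding
application contributes 2 layers (RY, RZ, never merged into neighbouring
blocks); a node layer contributes 3 (default) or 1 (simple); each EDU block
contributes twice the gate count of `V`; adjacent RZ layers of consecutive
default-EDU blocks merge into one. Under this convention a 3-layer
re-uploading model has exactly 6 more single-qubit gate layers than the
3-layer baseline, independent of how many bond types are present. The
default-vs-simple difference depends on the exact gate content chosen for
`V` and is reported by the counter but not treated as a cross-checkable
constant.

`schedule_link_layer` computes, per bond-type block, an exact minimum
proper edge coloring by backtracking (molecular blocks have at most ~12
edges, and only chromatic index Δ or Δ+1 is possible by Vizing's theorem);
rounds within a block can run in parallel on hardware, and executing the
rounds sequentially reproduces the sequential link layer exactly.

## Classical baselines

Matched for fairness rather than performance: 3 message-passing layers on
2-dimensional node features (the same two encoding angles the quantum model
consumes), mean readout, scalar linear head (2 weights + bias — the mean
readout is a 2-vector and a minimal scalarization is needed).

* GGNN-type layer: `x_i' = Φ x_i + aggr_j NN(e_ij) x_j` with a bond-type
  edge network (one-hot(4) → hidden 2, ReLU → 4, reshaped 2×2). No
  nonlinearity between GGNN layers; ReLU only after GCN layers. The empty
  neighborhood contributes the zero vector for every aggregation, keeping
  the layer total on isolated nodes.
* GCN layer: `x' = relu(D̃^{−1/2}(A+I)D̃^{−1/2} x Wᵀ)` with bond-order
  adjacency weights {single 1, aromatic 1.5, double 2, triple 3} — the
  standard propagation rule with self-loops, with bond features entering as
  adjacency entries.

Master nodes are a quantum-side preprocessing device and are rejected by
the classical models.

## Synthetic data

`generate_molecules` emulates the QM9 regime: 1–9 heavy atoms drawn from
{C, N, O, F} with carbon-dominated weights (0.68/0.14/0.14/0.04), a random
spanning tree of single bonds, optional benzene-like aromatic 6-rings
(probability 0.3 when ≥ 6 atoms), and stochastic single→double (0.25) /
single→triple (0.05) upgrades wherever a simplified valence budget (C 4,
N 3, O 2, F 1; aromatic bonds cost 1.5) allows. Hydrogens fill the leftover
budget (clipped to 0–4); hybridization is assigned sp/sp2/sp3 from the
highest incident bond order. This produces statistically plausible,
connected, valence-consistent graphs; it does **not** attempt kekulization,
ring strain, stereochemistry, or the true QM9 size distribution, so passing
tests demonstrate correctness of the machinery on realistic graph
*structure*, not chemical accuracy on real molecules.

Labels come from a frozen *teacher* model — a random draw of a small
EDU-QGC (angles uniform in (−π, π); readout offset in (0.2, 0.3) Ha and
slopes in (−0.15, 0.15), so targets land in a realistic HOMO-LUMO-gap
range) — plus optional Gaussian noise. Teacher labelling makes parameter
recovery a well-posed training benchmark with a known attainable optimum.

## Training protocol

Adam (lr 0.01, β₁ 0.9, β₂ 0.999, ε 1e-8), batch size 128 (the last partial
minibatch is used, not dropped), 150 epochs with validation every 10 epochs
in full runs; the weights at the lowest validation loss are kept. Quantum
angles and readout coefficients are initialized to exactly 1; classical and
encoding-network weights use seeded Glorot draws, with 3 restarts for
classical models. Epoch shuffling is seeded from the run seed, so runs are
bit-reproducible. Validation happens at epochs 10, 20, …; epoch 0 is not
validated (the all-ones initialization is deterministic and uninformative),
and the final epoch is always validated.

The desk-scale experiments in the tests and the acceptance script use
reduced problem sizes chosen to keep exact simulation pleasant on a laptop
CPU: 64 noiseless teacher-labelled molecules for 50 epochs for the recovery
benchmark, and a 160/40/40 split for 30 epochs for the end-to-end
quantum-vs-classical comparison. These sizes are the package's reference
configurations for synthetic data; full QM9-scale runs (10,000 training
molecules, 150 epochs) use the same code paths but require the external
dataset.

## Numerical choices and limitations

* Dense statevector simulation only, up to 12 qubits; double precision;
  global phase never compared.
* Tolerances: norm preservation 1e-10, unitarity/algebraic identities
  1e-12, permutation invariance 1e-9 (accumulated float noise over
  hundreds of gates), within-block order independence 1e-10.
* Degenerate inputs: single-node graphs have empty link layers; empty bond
  blocks are skipped; the max aggregation is subdifferentiable at ties
  (random continuous features make ties measure-zero).
* The generator retries internally until a valence-consistent connected
  graph is sampled, so requested counts are always delivered; extremely
  constrained settings (e.g. `max_atoms=1`) simply produce bondless graphs.
* No shot sampling or hardware noise is modelled anywhere; results are
  ideal-simulation results by construction.
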