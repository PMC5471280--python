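# Methods

`conforma` asks a structural question — is an unexpected crystallographic
position of a nuclear-receptor helix 12 (H12) a genuine stable state, or a
crystal-packing accident? — with two kinds of evidence: geometric metrics
between deposited conformers, and free-energy landscapes over
RMSD-to-reference collective variables estimated with the adaptive biasing
force (ABF) method. The atomistic molecular dynamics that would normally
feed the second half is replaced by an analytic toy system whose answer is
known exactly, so every stage of the estimator chain can be validated
end to end.

## Conformer metrics

**Superposition.** All comparisons rest on least-squares rigid fits
restricted to proper rotations (SVD/quaternion solution via
`scipy.spatial.transform.Rotation.align_vectors`); reflections are never
allowed, so a chiral set and its mirror image retain a nonzero residual.

**Region RMSD.** The displacement of H12 between two conformers is the RMSD
of its backbone (default N, CA, C, O; Cα-only available) *after* fitting the
two models on a core that excludes the mobile region (by default the Cα of
the ligand-binding domain outside residues 469–501). Fitting on the moving
region itself would absorb the displacement being measured. Models are
paired on (residue number, atom name), chain-agnostically, so differing
chain labels and differently resolved residue subsets are handled; residues
missing from one model are dropped from the comparison and counted.

**Helix displacement angle.** Each helix gets an axis — the first principal
direction of its Cα cloud, sign-fixed to point N→C — and the angle between
the (core-superposed) axes is reported in [0, 180]°. The principal-axis
definition carries a small intrinsic tilt for short helices (≈2° at 3
turns, decaying with length); the angle between two *similar-length* helices
is insensitive to it. Agreement with a rotated copy of the same helix is
within 1°.

**Charge clamp.** Distance from the clamp lysine NZ to the midpoint of the
clamp glutamate OE1/OE2 — the midpoint makes the metric invariant to the
arbitrary OE1/OE2 naming choice. An intact clamp grips both ends of a bound
coactivator helix; a displaced H12 pulls the glutamate away.

**Contacts and hydrogen bonds.** Hydrophobic contacts are residue pairs with
minimal heavy-atom distance ≤ 4.5 Å (a common convention; configurable).
Hydrogen bonds use a pure heavy-atom donor–acceptor distance criterion
(default ≤ 3.5 Å) with a built-in role table for protein side chains and a
permissive N/O rule for ligands; crystal structures carry no hydrogens, so
no angle term is applied. Both criteria are geometric screens, not energy
models.

**Landscape projection.** A conformation's coordinates on the free-energy
map are its Cα RMSDs (residues 469–501) to the canonical and to the
alternative reference structure, each computed after a core fit. By
construction the two references project to (d, 0) and (0, d), where d is
their mutual CV-region RMSD, and every conformation satisfies
|RMSD_C − RMSD_A| ≤ d.

**Trajectory mobility.** The RMSD distribution of a region over a
trajectory is taken against the converged fit-average structure (alternate
superpose-all-frames / re-average until the mean moves < 1e-6 Å, max 100
iterations). Narrow, low-mean distributions indicate a rigid region.

## The toy system

The generator stands in for ~100 ns MD replicas of a liganded LBD in two
histidine protonation states. It emulates their statistical structure:
diffusive CV dynamics at 298 K on a two-basin surface whose global minimum
switches with protonation state.

Surfaces place two minima in the (RMSD_C, RMSD_A) plane and connect them
with a C² piecewise-quintic profile along the joining line: every knot is a
stationary point with prescribed curvature, so minima energies and the
saddle height are **exact by construction**, which is what makes the preset
usable as an oracle. A harmonic term (k_perp, default 2 kcal/mol/Å²)
confines motion transverse to the line to a thermal band ≈ 2 Å wide,
emulating the geometric constraint that RMSD-pair coordinates of one
deforming region occupy a narrow curved band.

Preset parameters (kcal/mol, Å):

| preset | global min | local min | gap Δ | saddle |
|---|---|---|---|---|
| `state_e` (neutral His) | (8.75, 4.25) | (3.50, 8.00) | 5 | 9 |
| `state_plus` (charged His) | (3.50, 8.00) | (9.75, 3.50) | 1 | 7 |

`state_e` puts the global minimum in the alternative-conformer corner
(high RMSD_C, low RMSD_A); `state_plus` swaps it to the canonical corner
with a lower barrier and a shallow alternative basin — the qualitative
protonation-state story, at the reported landscape scale.

Dynamics are overdamped Euler–Maruyama:
x ← x + (−∇U + F_ext)·dt/γ + √(2 k_B T dt/γ)·ξ, with γ = 1 defining reduced
time, T = 298 K, k_B = 0.0019872041 kcal/mol/K, and dt = 0.02 — the largest
step stable against the stiffest curvature in the presets (κ·dt ≤ 0.2).
The "instantaneous force" recorded for ABF is the systematic force −∇U
only; excluding the thermal noise makes the bin-conditioned expectation of
the recorded force exactly −dA/dξ, giving a noise-free oracle for the
estimator chain. Equilibrium is verified against the Boltzmann distribution
by quadrature (occupancy ratios and a χ² histogram test), not assumed.

What the toy does **not** emulate: the Jacobian/curvature corrections of
true RMSD collective variables (toy CVs are Cartesian), force-field noise
in the instantaneous force, CV-orthogonal slow degrees of freedom, and
replica-to-replica structural drift. A green full-chain test therefore
establishes the correctness of the estimator pipeline, not of any
atomistic result.

## ABF estimator

Instantaneous CV forces are accrued in 0.1 × 0.1 Å bins over a 1–10 Å
domain per axis; the bias applied back to the dynamics is
−min(1, n/N) × (running bin mean force), with N = 4000 samples before full
application (linear ramp below, suppressing the noisy early estimate, and
the conventional reading of "full application after N samples"). The bin
mean includes the current sample and the bias is applied before the step;
half-open binning [edge, edge+width). Harmonic boundary restraints
(k = 10 kcal/mol/Å²) confine the walker to the domain; out-of-domain steps
are never accrued. Empty bins have *no* mean force — they are masked, not
zero — and runs are bit-reproducible given a seed.

## Landscape assembly

**Merging.** Replicas of one system are pooled by summing counts and force
sums; the pooled mean force is then the sample-count-weighted average of
per-replica means — the consistent estimator for independent samples of the
same conditional expectation. A simple per-replica average would weight a
10-sample replica equally with a 10⁶-sample one.

**Integration.** The free-energy gradient of a sampled bin is −(mean
force). The surface solves the discrete gradient equations in least
squares: one equation per adjacent sampled-bin pair — axis neighbors and,
in 2D, both diagonals, so the equation graph is connected exactly where the
8-neighbor sampled mask is — with the edge gradient taken as the mean of
the two bins' values, solved via sparse normal equations with one anchor
per connected component. Least squares is path-independent and
noise-robust; a BFS spanning-tree line integration is provided as a
cross-check mode. Unsampled bins are never interpolated. Disconnected
sampled components are integrated separately and flagged: their values
share no common reference.

**Basins.** Steepest-descent assignment of every sampled bin to a local
minimum over 8-neighbors, then iterative merging of any basin whose escape
barrier (lowest saddle to a neighbor) is shallower than `min_depth` into
the neighbor across that saddle. The pipeline default `min_depth` = 1
kcal/mol (≈ 1.7 k_BT) removes sampling-noise corrugation while preserving
every basin of physical interest (the shallowest reported feature is ≈ 4
kcal/mol deep). The end-to-end pipeline analyses the dominant connected
component: stray once-visited bins form their own components, each
trivially anchored at G = 0, and carry no information.

**Paths and barriers.** The minimum free-energy path between two basin
minima is the *minimax* (widest) path over 8-connected sampled bins — the
path minimizing the highest G crossed, which is exactly the quantity whose
peak defines the barrier — with ties broken by minimal summed G, then
lexicographic bin order, making the output deterministic. Arc length
accumulates Euclidean steps between bin centers and normalizes to a [0, 1]
generalized reaction coordinate. The barrier is max(G) − G(start); a
basin's relative depth along a path is max(G) − G(basin minimum). The
minimax value is verified against an independent oracle: exhaustive
enumeration of bottleneck levels with union-find connectivity of each
≤-level set.

## Scale of the full-chain validation

Fourteen replicas of 10⁶ steps each per system, half started in each
basin. The step count is set by physics, not convenience: with 0.1 Å bins
and N = 4000, ABF must accumulate roughly N × (basin area / bin area)
samples before a walker can leave a basin, and at dt = 0.02 the shallower
side of each preset (4 and 6 kcal/mol escape depths) traverses reliably at
10⁶ steps — which is what connects the two basins in the merged map. Both
systems run in ≈ 2 minutes on one CPU. Recovery quality at this scale:
surface RMS error ≈ 0.005 kcal/mol on bins with ≥ 4000 pooled samples,
barriers within 0.02 kcal/mol of the construction.

## Numerical choices and edge cases

- Altloc resolution: highest occupancy, ties to the alphabetically first id;
  only MODEL 1 of multi-model files; ranges match empty insertion codes.
- Selections exclude hydrogens and waters; the estradiol ligand is the
  HETATM residue EST.
- Empty selections and empty pairings raise, rather than returning vacuous
  0-atom RMSDs.
- Histogramming a (near-)constant RMSD trajectory pads a degenerate range
  instead of failing.
- Grid serialization writes floats with `repr` (shortest round-trip
  representation), so TSV round trips are bit-exact.
- Fixed 6-significant-digit formatting in all other text outputs keeps
  diff-based reproducibility checks stable.

## Known limitations

- Cross-subtype comparisons (ERα vs ERβ numbering) are out of scope; the
  pairing is by residue number within one numbering scheme.
- The helix axis definition is a package choice (principal component); the
  displacement-angle tolerance is correspondingly wide (±10°).
- No error bars on G (no block averaging), no string-method path
  refinement, no temperature reweighting.
- The ABF sampler biases toy Cartesian CVs only; projecting forces onto
  RMSD CVs of an atomistic trajectory is not implemented.
- Acceptance checks against the deposited crystal structures (5TOA, 3OLL,
  3OLS, 1QKM) require those PDB files in `data/pdb/`; they are not
  redistributed with the package.
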