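# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `trajnet`. Units are nm, kJ/mol, amu, e and ps
throughout (the Gromacs convention); PDB I/O converts Å ↔ nm at the
boundary.

## Superposition and fluctuation metrics

Rigid-body superposition uses the Kabsch SVD construction with the
reflection branch corrected, so the returned rotation is always proper
(det = +1). Configurations with fewer than 3 atoms, or with rank < 2 after
centring (collinear/coincident), are rejected rather than silently
returning one of the degenerate optima.

RMSD(t) fits every frame to a reference frame (default: the first) on the
analysis selection and reports the post-fit RMSD over that selection.
RMSF is computed about the *window-mean* structure: frames in the window
are fitted to their own mean, iterated (fit → recompute mean → refit)
until the mean is a fixed point of the procedure (tolerance 1e-12 nm,
typically a handful of iterations). The fixed-point iteration matters: at
convergence the fit reference and the ensemble mean coincide, which makes
downstream identities exact (see covariance below). Fitting to the first
frame instead is available via the `fit_to_mean` internals but is not the
default. RMSF is aggregated per residue by default (root-mean-square over
the residue's selected atoms); per-atom profiles are available.

Note a caveat of least-squares fitting on noisy data: the fitted rigid
motion is itself estimated from the fluctuations, so fitting
redistributes O(1/N) of the variance between atoms. With hundreds of
selected atoms this is a percent-level effect; tests that assert
amplitude recovery therefore use ≥200 atoms.

Rg and centre-of-mass distances are mass weighted by default (unweighted
modes via flags); masses come from a standard atomic-mass table keyed by
element, and unknown elements are an error rather than a guess.

SASA is Shrake–Rupley: `n_points` (default 960) golden-spiral points per
atom at radius r_vdw + probe (Bondi radii, probe 0.14 nm); a point is
exposed iff outside every *other selected* atom's expanded sphere. The
point count favours accuracy over speed; the quadrature error on an
isolated sphere at 960 points is well under 1%.

## Hydrogen bonds

A bond is declared when d(donor, acceptor) ≤ 0.35 nm **and** the
hydrogen–donor–acceptor angle is ≤ 30°. Both conventions are stated
explicitly because the field also uses donor–hydrogen–acceptor ≥ 150°:
here the angle is at the *donor*, and the distance is donor-to-acceptor,
matching the common MD-analysis tooling convention. Donors are N/O atoms
with a hydrogen within 0.12 nm in the first frame (covalent-bond
heuristic, assigned once); hydrogens on carbon are never donors;
acceptors are all N and O atoms. Topologies without hydrogens yield an
empty donor set with a warning rather than a silent heavy-atom fallback.

## Interaction energies

Cross-group energies sum f·q_iq_j/r (f = 138.935458 kJ·mol⁻¹·nm·e⁻²) and
4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] over cross pairs only; σ_ij/ε_ij combine by
Lorentz–Berthelot (default) or geometric rules. Electrostatics are plainly
truncated (optional cutoff; default none): mesh-Ewald long-range sums are
not decomposable per atom-group, so no reaction-field or lattice
correction is attempted, and absolute magnitudes are not comparable with
lattice-summed simulation energies. Window statistics use block averaging
with 5 equal blocks; the reported error is sd(block means)/√5. Per-residue
rows use the same pair lists, so the residue decomposition sums to the
group total exactly.

## Essential dynamics

The covariance C = ⟨(x−⟨x⟩)(x−⟨x⟩)ᵀ⟩ is accumulated over frames fitted to
the ensemble mean (the same fixed-point iteration as RMSF), with plain 1/F
normalisation and no mass weighting (a flagged option). Because the fit
reference equals the mean at convergence, two identities hold to machine
precision and are asserted in tests: projecting the mean structure gives
zero scores, and the variance of the PC-i scores over the training window
equals eigenvalue i. Multiple runs are pooled by concatenating their
window frames before the common fit. Eigenvalues below ~1e-18 nm² of total
trace are treated as numerically zero (a constant ensemble).

The free-energy landscape over two PCs is ΔG = −k_B·T·ln(P/P_max) on an
n_bins×n_bins histogram (default 32, range padded 5%, default 300 K,
k_B = 0.0083144621 kJ/mol/K, so k_B·T = 2.494 kJ/mol at 300 K).
Unoccupied bins are +∞ in memory and rendered in CSV as (max finite ΔG
+ 1) with an explicit `occupied` column. The representative frame is the
one whose scores fall nearest the centre of the most populated bin, ties
to the lowest frame index.

Subspace similarity uses two standard measures on the first k eigenpairs
(default k = 10): RMSIP = √((1/k)Σ_ij (v_i·w_j)²), and the Hess normalized
covariance overlap on the rank-k reconstructions,
1 − √(tr(Ã + B̃ − 2(Ã^{1/2}B̃Ã^{1/2})^{1/2}) / (trÃ + trB̃)). The trace of
the matrix square root is evaluated through the singular values of
Λ_a^{1/2}V_aᵀV_bΛ_b^{1/2} (k×k), which is exact and avoids forming 3N×3N
square roots; a dense `scipy.linalg.sqrtm` evaluation serves as the
independent oracle in tests. For nearly identical models the normalized
difference under the square root is a catastrophic cancellation; values
below 1e-12 are floored to zero so self-overlap is exactly 1 instead of
1 − √ε.

Porcupine extremes are mean ± scale·√λ·v (default first 3 modes),
writable as B-factor-annotated PDB pairs.

## Residue interaction network

Nodes are residues; an edge joins residues whose closest non-hydrogen
atoms are within 0.7 nm in the chosen frame (sequence neighbours included
like any pair). The graph is built on a single representative frame from
the FEL workflow; a frame-averaged consensus mode is deliberately out of
the default path. Edge weights count hydrogen bonds between the residues.

Betweenness is Brandes' algorithm with the normalization
2/((N−2)(N−1)) applied to the unordered-pair sum, so a path midpoint and
a star centre both score exactly 1. Two shortest-path semantics exist:

* `unweighted` (default): hop counts (BFS). The hydrogen-bond weights do
  not affect paths.
* `hbond_weighted`: Dijkstra with edge length 1/(1 + hbond_weight), i.e.
  more hydrogen bonds make an edge effectively shorter. This is an
  interpretation — the field convention for how bond counts should enter
  shortest paths is not settled — and is therefore opt-in.

Weighted path lengths are compared with a 1e-12 tolerance so that
genuinely equal path sums (e.g. 3 × 1/3 vs 1) are recognised as ties
despite floating-point rounding; the implementation is validated against
an exact rational-arithmetic path enumerator. Disconnected pairs
contribute no paths; the normalization always uses the global node count.
Centrality selection uses C_B ≥ 0.1; differential analysis flags
|ΔC_B| ≥ 0.05 per shared residue and intersects flagged sets across
multiple alternates.

## Synthetic data

The generators produce every input the pipeline consumes, with planted
ground truth:

* **Toy complexes** — two arc-shaped protein chains (idealised 5-atom
  residues: N, H, CA, C, O) emulating a horseshoe-fold dimer, plus an
  optional two-strand ladder ligand with nucleic-style backbone atoms
  (P, O5′, C5′, C4′, C3′, O3′). Hydrogen bonds are planted at named
  interaction sites (N-terminal, C-terminal, dimer interface) with ideal
  geometry (d = 0.30 nm, angle 0°); construction verifies that *only* the
  planted cross-group bonds satisfy the criteria (all other cross
  donor–acceptor pairs > 0.4 nm) and rejects infeasible plantings.
* **Gaussian trajectories** — x_t = ref + Σ_m a_{t,m} v_m + ε_t with
  orthonormal planted modes, per-mode variances, and isotropic noise;
  modes are drawn orthogonal to the rigid-body subspace so superposition
  fitting cannot absorb them. Deterministic per seed.
* **Graph fixtures** — path/star/cycle/complete/two-cluster-bridge graphs
  with analytic centralities, and random connected graphs (spanning tree
  + extras) with random bond weights.
* **Parameter fixtures** — null (all-zero), unit-charge and bounded
  random schemes (q ∈ [−1,1] e, σ ∈ [0.25,0.4] nm, ε ∈ [0.1,1] kJ/mol).

What the generator does *not* emulate: real force-field sampling,
secondary structure, smooth (spatially correlated) collective modes, and
physically consistent σ/ε–geometry combinations. Two practical
consequences, visible in the synthetic-study outputs: planted modes are
spatially white, so their variance perturbs local bond geometry more than
an equally large real collective motion would — the study generator
therefore defaults to mode variances (0.09, 0.03, 0.01) nm² + 0.003 nm
noise, keeping per-atom fluctuations near 0.02 nm as in a converged
stable complex — and the random parameter fixture is a numerical stress
fixture, not a force field, so reported synthetic interaction energies
can be large and positive where planted contacts clash with sampled σ.
Passing tests demonstrate correctness of the operators against exact
oracles, not physical realism of the synthetic ensembles. The
planted-mode *recovery* experiment uses the larger (0.9, 0.3, 0.1) nm²
spectrum at 5000 frames, where sampling error (≈√(2/F) ≈ 2%) sits
comfortably inside the 5% recovery tolerance.

## Pipeline

The driver reads a YAML config (labelled complexes, ≥1 run each,
selection expressions, window length in ns — default 60 ns, taken as
frames with time > t_end − window including the final frame), computes
per-run metrics, pools runs for essential dynamics (as in the
concatenated-runs protocol), builds the network on the representative
frame, and emits cross-complex overlap/RMSIP and differential-centrality
tables against a designated reference complex. SASA is evaluated on a
frame stride (default 10) — the area series varies slowly and the
quadrature is the most expensive per-frame operation. Reruns with the
same config and seed reproduce all CSVs bit-identically; the run log
records package version, config hash and seed. Multi-character chain ids,
overlapping groups, missing parameter coverage and degenerate geometry
all fail loudly with the offending stage and complex named.

Residue numbering is preserved as authored; an optional chain-offset
remap (`Topology.renumber_chain`) supports continuous renumbering of a
second protomer, off by default.

## Known limitations

* Coordinates are assumed whole/unwrapped: no periodic-boundary
  minimum-image handling anywhere.
* No binary trajectory formats (XTC/TRR/DCD) or mmCIF; multi-model PDB is
  the interchange format.
* Truncated electrostatics only (see above); no bonded terms, solvation
  or entropy estimates.
* Hydrogen-bond definitions are geometric only; no salt-bridge or
  π-interaction detection.
* The SASA dot density differs from other tools' defaults, so absolute
  areas agree with analytic spheres, not bit-for-bit with any particular
  program.
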