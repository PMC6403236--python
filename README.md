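# trajnet

Post-simulation analysis of biomolecular MD trajectories, built around the
workflow used to compare wild-type and mutant receptor–ligand complexes
(e.g. a Toll-like receptor ectodomain dimer bound to a duplex RNA): after
the simulations are done, what changed — in stability, contacts,
energetics, collective motion and residue communication?

`trajnet` implements that entire post-processing layer as a tested,
reusable library plus CLI:

* **Stability / geometry** — backbone RMSD(t) and per-residue RMSF via
  Kabsch least-squares superposition, radius of gyration, Shrake–Rupley
  solvent-accessible surface area, centre-of-mass and minimum inter-group
  distances.
* **Hydrogen bonds** — geometric detection with the standard criteria
  d(D,A) ≤ 0.35 nm and ∠H–D–A ≤ 30°, and per-frame inter-group counting.
* **Interaction energies** — pairwise nonbonded decomposition
  E = Σ f·q_iq_j/r_ij + Σ 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] over cross pairs,
  with per-residue decomposition and block-averaged errors.
* **Essential dynamics** — the 3N×3N coordinate covariance
  C = ⟨(x−⟨x⟩)(x−⟨x⟩)ᵀ⟩ and its eigensystem, PC projections, free-energy
  landscapes ΔG = −k_BT·ln(P/P_max), representative structures, the Hess
  normalized covariance overlap, RMSIP, and porcupine vectors.
* **Residue networks** — residue interaction network (contact ≤ 0.7 nm
  between non-hydrogen atoms, edges weighted by hydrogen-bond counts) and
  Brandes betweenness centrality
  C_B(v) = 2/((N−2)(N−1)) Σ_{s<t} σ_st(v)/σ_st, with C_B ≥ 0.1 selection
  and wild-type-vs-mutant differential analysis (|ΔC_B| ≥ 0.05).
* **Synthetic data** — generators for toy horseshoe complexes with planted
  hydrogen bonds, planted-mode Gaussian trajectories, known-centrality
  graphs and nonbonded parameter fixtures, so every stage is testable
  against exact ground truth without external data.
* **Pipeline** — a config-driven driver reproducing the full study layout
  (labelled complexes × multiple runs × last-N-ns windows) with a CSV/PDB
  report tree and bit-reproducible reruns.

Internal units are Gromacs-style throughout: nm, kJ/mol, amu, e, ps.

## Worked example

Generate a synthetic two-complex study (wild-type vs "mutant" with a
shifted contact pattern; 3 runs × 500 frames each) and run the whole
pipeline:

```bash
trajnet simulate --out study --labels wt,mutant --n-runs 3 --n-frames 500 --seed 1
trajnet pipeline --config study/config.yaml --out report
```

or from Python:

```python
from trajnet import PipelineConfig, run_pipeline
from trajnet.pipeline import generate_synthetic_study

cfg = PipelineConfig.from_yaml(
    generate_synthetic_study("study", labels=("wt", "mutant"),
                             n_runs=3, n_frames=500, seed=1))
run_pipeline(cfg, "report")
```

The report tree contains, per complex: `run*/rmsd.csv`, `run*/rmsf.csv`,
`run*/rg.csv`, `run*/sasa.csv`, `run*/hbond_*.csv`, `run*/mindist.csv`,
`run*/comdist.csv`, `run*/energy_*.csv`, an `energy_table.csv` across
runs, pooled `pca/` outputs (eigenvalues, projections, FEL grid,
representative structure) and `network/` outputs (edge list, centrality
table, B-factor-annotated PDB); plus cross-complex `cross/overlap.csv`,
`cross/rmsip.csv` and differential-centrality tables.

From the seed-1 study above, the wild-type complex reports a mean of
4.90 hydrogen bonds between chain A and the ligand over the last-window
frames (4.89 for chain B) against 5 planted bonds per chain, a dimer
hydrogen-bond mean of 0.99 against 1 planted, and 37 of 72 residues with
C_B ≥ 0.1 in the representative-frame network; the wt-vs-mutant
differential flags 5 residues at |ΔC_B| ≥ 0.05. The planted-mode recovery
experiment (three orthogonal modes of 0.9/0.3/0.1 nm², 5000 frames)
recovers the eigenvalues within 2.1% with RMSIP 0.99999 between planted
and recovered subspaces — the numbers printed by
`scripts/acceptance.py` below.

## Documentation

See `docs/methods.md` for the underlying models, conventions (fitting
references, hydrogen-bond angle definition, weighted-path semantics,
error estimation), numerical choices and known limitations.
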