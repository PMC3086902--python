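# szaggr — steric-zipper peptide aggregation analysis

`szaggr` analyzes multi-chain molecular-dynamics trajectories of short
amyloidogenic "steric zipper" peptides (hexapeptides such as VQIVYK from
tau, or VEALYL from the insulin B chain) as they spontaneously aggregate
into β-sheet oligomers. It is written for structural bioinformaticians who
have trajectories of ~10 peptide chains in a periodic box and want a
quantitative, reproducible account of *how* the oligomers form and *what*
they look like.

The package covers the full analysis chain:

- **Hierarchical aggregate classification.** Two chains join a *general*
  aggregate when any heavy-atom pair is within 0.45 nm (minimum image);
  a *β-sheet* aggregate additionally requires two consecutive inter-chain
  β-bridges under the Kabsch–Sander rules, so the β-partition always
  refines the general one.
- **Association/dissociation kinetics.** Aggregates are traced by their
  chain-ID sets; states shorter-lived than 10 ps are filtered out, and all
  growth is bookkept as bimolecular reactions A_i + A_j → A_{i+j}, split
  into polymerization (min(i,j)=1) and condensation (min(i,j)≥2). Rate
  constants k = n/T_obs convert to barriers via ΔG = k_B·T·ln(ν/k) with an
  attempt frequency ν = 1 ps⁻¹.
- **Conformational order metrics.** Nematic order parameter P2 (largest
  eigenvalue of the ordering tensor Q = ⟨3/2 ẑᵢẑᵢᵀ − 1/2 I⟩ over the
  strand axes ẑᵢ = CA2→CA5), chain extension, hydrophobic solvent-
  accessible surface (Shrake–Rupley, Bondi radii), strand polarity and
  registry, residue contact maps, and Rg–RMSD conformational landscapes.
- **Hydrogen-bond energetics.** DSSP-style backbone H-bond detection
  (E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, accepted
  below −0.5), plus the Espinosa distance-based energy
  E = −25300·exp(−3.6·d_HO[Å]) kJ/mol decomposed into backbone,
  side-chain–side-chain and mixed contributions per complex.
- **Dimer-decomposition conformational mapping.** Oligomers are decomposed
  into their unique contact-neighbor chain pairs; dimeric substructures are
  iteratively relabeled against a converging average reference, superposed
  (Kabsch), mapped by coordinate PCA, and clustered by k-means
  (Hartigan–Wong refinement over global-k-means seeds, cluster count by
  the Krzanowski–Lai criterion). Dimers cut from trimers/tetramers/decamers
  are assigned to the dimer-derived clusters, giving one shared shape space
  for all oligomer orders.
- **Transition networks.** Tracked dimers yield cluster-to-cluster
  transition counts with formation/disassembly boundary flows, exported as
  GraphML with net/total edge attributes and normalized node sizes.
- **Synthetic data with ground truth.** A seeded generator emits ideal-
  geometry hexapeptide trajectories (multi-model PDB) whose partitions,
  event logs, strand alignments and cluster labels are known exactly, so
  every stage is testable without MD data.

## Worked example

```python
from szaggr import aggregates, kinetics, synthetic_data
from szaggr.conf_metrics import chain_z_vectors, nematic_p2

cfg = synthetic_data.SimConfig(n_frames=2000, seed=42)   # 10 chains, 5 ns
traj, truth = synthetic_data.simulate_aggregation(cfg)
parts = [aggregates.general_aggregates(
             aggregates.heavy_atom_contacts(traj.frame(f)))
         for f in range(traj.n_frames)]
filtered = kinetics.stable_partition_stream(parts, traj.dt, cfg.min_lifetime)
log = kinetics.detect_events(filtered, traj.times)
summary = kinetics.classify_reactions(log, n_max=cfg.n_chains)
print(f"{len(log)} events ({summary['polymerization']} polymerization, "
      f"{summary['condensation']} condensation)")
print(f"final aggregate sizes: {sorted(len(a) for a in parts[-1])}")
p2 = nematic_p2(chain_z_vectors(traj.frame(traj.n_frames - 1))).P2
print(f"final-frame nematic order P2 = {p2:.2f}")
```

prints

```
47 events (12 polymerization, 15 condensation)
final aggregate sizes: [1, 2, 7]
final-frame nematic order P2 = 0.71
```

47 stability-filtered events occurred, of which 27 were associations
(12 consuming monomers, 15 fusing multimers) and 20 dissociations; after
5 ns the ten chains sit in a 7-mer, a dimer and a free monomer, and the
system's strand axes are substantially aligned (P2 = 0.71; 1 would be a
perfect nematic arrangement). The detected event log equals the
generator's scripted ground truth exactly.

The same stages are available from the shell:

```bash
szaggr --seed 42 --out run synth --n-frames 2000
szaggr --out run kinetics run/trajectory.pdb
szaggr --out run map      run/trajectory.pdb     # PCA + clustering
szaggr --out run network  run/trajectory.pdb     # GraphML networks
```

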