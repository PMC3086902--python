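# Methods

This note documents the models, conventions and numerical choices behind
`szaggr`, in the order the pipeline applies them.

## Units and data model

All quantities are nm / ps / kJ/mol internally (kcal/mol only where the
DSSP hydrogen-bond energy is conventionally quoted). PDB coordinates in
Ångström are converted on read and write; the round trip is exact to the
format's 0.001 Å precision. Chains are identified by PDB chain ID, frames
are 0-based internally and 1-based in emitted tables. Coordinates are kept
wrapped-as-given; every distance computation applies the cubic minimum-
image convention, so a chain shifted by a full box vector yields identical
contacts. Multi-model PDB is the supported trajectory dialect (one MODEL
per frame); sequences and atom rosters are recovered from the records
themselves, so no sidecar topology file is required. GRO/XTC input is not
implemented.

## Aggregate classification

A general aggregate is a connected component of the chain contact graph:
an edge exists when any heavy-atom pair of two chains is within 0.45 nm.
Contacts are found with a periodic k-d tree and are verified in tests
against an all-pairs minimum-image scan. A β-sheet aggregate is a
connected component of the β-edge graph, where a β-edge requires residues
i and i+1 of one chain both bridge-partnered to the same other chain.
Because β-edges presuppose heavy-atom proximity, the β-partition refines
the general partition in every frame; the code asserts this.

"Sheet size" statistics count ladder-connected strands (components of the
β-edge graph). Two sheets stacked face-to-face share no backbone hydrogen
bonds and therefore count as two sheets, which matches the intuition that
a β-sandwich has two layers.

## Secondary structure and hydrogen bonds

Backbone hydrogen bonds use the Kabsch–Sander electrostatic model,
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with r in Å,
accepted below −0.5 kcal/mol; any distance under 0.05 nm rejects the pair
as a clash. Missing amide hydrogens (united-atom input) are reconstructed
0.1 nm from N along the preceding C=O direction; the N-terminal residue
gets none. Bridge rules follow Kabsch–Sander with the acceptor-first bond
convention (Hb(i,j) = C=O of i accepting N-H of j): parallel bridges via
[Hb(i−1,j) ∧ Hb(j,i+1)] or [Hb(j−1,i) ∧ Hb(i,j+1)], antiparallel via
[Hb(i,j) ∧ Hb(j,i)] or [Hb(i−1,j+1) ∧ Hb(j−1,i+1)]. Ladders are maximal
runs of consecutive bridges; residues in ladders of length ≥ 2 are E,
isolated bridges B, bend S where the CA(i−2)→CA(i) / CA(i)→CA(i+2) angle
exceeds 70° (residues 3..L−2), else coil, with precedence E > B > S > C.
Helix and turn states are deliberately omitted: hexapeptide aggregates
populate E/B/S/C almost exclusively, and a residue matching a helix
pattern would be reported as coil. Intra-chain bridges require a sequence
separation of at least three residues.

Espinosa hydrogen-bond energies use E = −25300·exp(−3.6·d_HO[Å]) kJ/mol
after a geometric screen (donor–acceptor distance < 0.35 nm; donor–H–
acceptor angle > 120° where an H exists). For donors without an explicit
hydrogen (united-atom side chains, the N-terminal ammonium) d_HO is taken
as d(D,A) − 0.1 nm along the donor→acceptor line — a deterministic,
unbiased proxy. The donor/acceptor roster ships as a YAML file covering
all twenty residue types, with a pH switch that makes carboxylates
additionally donate below pH 4 (protonated glutamate/C-terminus). The
decomposition reports inter-chain backbone (bb), side-chain–side-chain
and mixed (mc_sc) sums separately; the total additionally includes
intra-chain bonds, so |hbE_tot| ≥ |hbE_bb + hbE_scsc + hbE_mcsc|. This is
one consistent reading of a decomposition whose published breakdown does
not close; the remainder is attributed to intra-chain terms.

## Kinetics

Aggregate identity across frames is the chain-ID set (chain IDs are stable
in MD; no spatial tracking is needed). The stability filter recognizes an
aggregate only if the identical chain set persists for
ceil(min_lifetime/dt) consecutive frames (default 10 ps at dt = 2.5 ps,
i.e. 4 frames), recognition applying from the first frame of the
qualifying run; chains of unrecognized states remain in their last
recognized grouping. Event detection compares consecutive filtered
partitions: a two-way merge is one association, a two-way split one
dissociation; k-way changes are decomposed into k−1 bimolecular steps,
largest partners first, flagged as simultaneous (dissociations mirror the
association decomposition in reverse so that replaying the log is exact);
chain exchanges decompose into a dissociation followed by an association
at the same timestamp. Replaying the event log from the initial partition
reproduces the final filtered partition exactly, and on generator output
the detected log equals the scripted ground truth event for event.

Rates and barriers: k = n/T_obs, ΔG = k_B·T·ln(ν/k) with
k_B = 0.0083145 kJ/(mol·K), defaults ν = 10¹² s⁻¹ and T = 310 K. With
zero observed transitions only a lower bound on ΔG exists and the
estimate is flagged instead of returning a number.

## Conformational metrics

The strand axis ẑᵢ links the CA atoms of residues 2 and 5. P2 is the
largest eigenvalue of Q = (1/N)Σ(3/2 ẑᵢẑᵢᵀ − 1/2 I) — the ordering-tensor
convention of standard MD analysis tools; it is invariant under global
rotation and under sign flips of any ẑᵢ. SASA uses Shrake–Rupley with a
0.14 nm probe, 960 Fibonacci sphere points (≤ 0.01 % error against the
closed form on a single sphere) and Bondi radii; hydrophobic surface sums
carbon and sulfur atoms (the amide hydrogens present in the data are
polar and excluded). Rg is mass-weighted over heavy atoms. Strand polarity
is the majority bridge polarity (ties broken by sign(ẑ_a·ẑ_b)); registry
offset is the median of (j−i) for parallel and (i+j−(L+1)) for
antiparallel bridges, zero meaning in-register. Rg–RMSD landscapes are 2D
histograms normalized so the modal bin equals one, with raw counts
retained. Per-size averages exclude aggregate orders with less than 50 ns
cumulative occurrence (configurable).

## Dimer decomposition, relabeling, PCA, clustering

Aggregates of selected orders are decomposed into one dimer record per
unique contact-neighbor chain pair ([ij] ≡ [ji]). Records carry main-chain
(N, CA, C, O) coordinates for fitting plus heavy-atom coordinates for Rg
and contact maps. Relabeling superposes both slot assignments of each
record onto a reference (Kabsch, proper rotations only) and keeps the
lower-RMSD one; the mean of the superposed ensemble becomes the next
reference, iterating until the labeling repeats (error after 50
iterations). The initial reference is an ideal-geometry in-register dimer;
a user-supplied reference (e.g. crystal coordinates) can be passed
instead. The procedure is idempotent and invariant under permuting the
stored chain order of any record.

PCA re-superposes all records onto their ensemble average and
diagonalizes the coordinate covariance; projections on all eigenvectors
are stored, the first three being the mapping axes. Clustering operates on
the superposed coordinate vectors, where Euclidean distance is
√N_atoms × RMSD in the common frame — an approximation to pairwise-optimal
RMSD that keeps k-means in a vector space (a config switch clusters in the
3-EV projection space instead). Seeding is incremental (fast) global
k-means: the k-cluster seed is the (k−1)-solution plus the candidate point
with the largest guaranteed error reduction; each seed set is refined by
Hartigan–Wong point transfers (objective provably non-increasing). The
cluster count maximizes the Krzanowski–Lai score
KL(k) = |DIFF(k)|/|DIFF(k+1)|, DIFF(k) = (k−1)^{2/p}W_{k−1} − k^{2/p}W_k,
over k = 2..10 (one extra W evaluation at the top; KL is undefined at
k = 1). Representatives are the member structures closest to each
centroid. Records from higher oligomers are relabeled against the
converged dimer reference and assigned to the nearest center without
updating the model; ties go to the lower cluster index. Cluster fractions
are record-weighted (a frame contributing several dimers counts each).

Clusters are named A/P/I/E by the mean dimer arrangement of their
members: mean(ẑ₁·ẑ₂) < −0.5 → A (antiparallel), > 0.5 → P (parallel),
mean minimal inter-chain distance > 0.6 nm → E (encounter complex), else
I (intermediate/irregular), numbered by descending occupancy.

## Transition networks

A dimer track is a maximal run of consecutive frames in which the same
unordered chain pair is a contact pair inside an aggregate of one order
stratum; a single missing frame breaks the track, and an order change
(e.g. trimer → tetramer) ends the track in one stratum and starts one in
the other — operationalizing formation and disassembly flows. Transitions
are counted between consecutive frames with different cluster labels;
track starts and ends add entry/exit counts, so per node
entries + inbound = exits + outbound holds exactly. Networks keep one
directed edge per cluster pair in the surplus direction (net = |c(a→b) −
c(b→a)|) with the raw total retained as an attribute; node and edge sizes
are normalized by each network's own maxima. Export is GraphML; a
round-trip reader is provided. Node occupancy counts records, not frames.

## Synthetic-data generator

The generator is a ground-truth harness, not a physical simulator:
geometric realizability takes precedence over dynamical realism. Chains
are ideal hexapeptides (backbone N, H, CA, C, O plus a CB pseudo side
chain) built by natural-extension-reference-frame placement with ideal
bond geometry and strand dihedrals φ = −139.0°, ψ = +132.6°, tuned once so
the extended strand has the builder-contract rise of 3.47 Å/residue
(CA1–CA6 = 1.735 nm). Dimer references place the partner strand at 0.48 nm
spacing with the requested polarity (antiparallel = 180° rotation about
the H-bond axis; odd registry shifts additionally flip the pleat phase,
since the H-bond pattern has a two-residue period) and then refine the
rigid placement by a deterministic Nelder–Mead pass that maximizes
clamped Kabsch–Sander bond energy under a clash penalty — both polarities
therefore genuinely hydrogen-bond under the DSSP rules (four in-register
bridges each).

Aggregation trajectories evolve a cluster-level stochastic process:
at each step unlocked aggregate pairs merge with probability p_assoc
(bimolecular only; several disjoint merges may share a timestep) and
aggregates split into two contiguous sub-stacks with probability
p_dissoc × size. Every event locks its chains for the 10 ps stability
window and no event is scheduled closer than that window to the end of
the trajectory, so the scripted log is exactly what the stability filter
plus event detection recover. Members of an aggregate are stacked at
0.48 nm with per-chain orientation signs (a new junction pair is parallel
with probability p_parallel, default 0.3 to reflect the predominantly
antiparallel pairing of these systems); Gaussian positional noise
(σ = 0.015 nm) keeps intra-aggregate neighbor distances ≤ 0.40 nm while
aggregates are placed with bounding-sphere separation margins ≥ 0.5 nm
under periodic minimum image — the 0.45 nm contact rule is therefore
unambiguous, and the emitted per-frame partition is recovered exactly.
Free monomers random-walk with periodic wrapping and collision avoidance.
Defaults mirror the reference study conditions at desk scale: 10 chains in
a 10 nm box (16.6 mM), dt = 2.5 ps, 2000 frames (5 ns), generated in
under a second.

What the generator does **not** emulate: internal chain flexibility
(strands stay near-ideal), realistic diffusion and encounter kinetics,
side-chain chemistry beyond a CB pseudo-atom, solvent, and any
force-field energetics. Passing tests therefore demonstrate that the
analysis operators are correct and self-consistent on geometrically
unambiguous input — not that the biological conclusions of any particular
MD study are reproduced at desk scale.

The labeled dimer ensemble (`make_dimer_ensemble`) perturbs four template
poses — antiparallel in-register, parallel in-register, a crossed
in-contact intermediate, and a crossed encounter complex 0.8 nm apart —
with Gaussian noise (default σ = 0.01 nm, template separations ≥ 10σ,
warned otherwise). The Markov label generator emits seeded chain
realizations for transition-network recovery tests.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: 300–2000 frames of
10 chains, 800-record cluster ensembles, 10⁵-step Markov chains — chosen
so the whole suite completes in well under a minute of CPU per stage
while leaving the statistical checks (3σ binomial bounds, ≥ 99 % purity)
meaningful. All stochastic inputs flow from explicit integer seeds through
`numpy.random.Generator`; identical seeds give bitwise-identical
coordinates and ground truth.

## Known limitations

- Hydrogen-bond analysis covers backbone and rostered side-chain sites
  only; solvent-mediated bonds are out of scope.
- The Espinosa parameterization is the standard distance-only form;
  published decompositions using a different parameterization will differ
  by a smooth monotone rescaling.
- Clustering distance is common-frame RMSD, not pairwise-optimal RMSD;
  for tight ensembles the two agree closely, for very heterogeneous
  ensembles the common-frame approximation can split elongated clusters.
- DimerRecord tracking assumes chain IDs are unique and stable across the
  trajectory (true for MD; not for ensembles of independent models).
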