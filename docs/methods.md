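# Methods

`aaadyn` implements two analyses for PLP-dependent aromatic amino acid
decarboxylases (AAADs) and their O2-dependent relatives: (1) 3D oxygen
free-energy mapping of trajectories by implicit ligand sampling with pathway
and barrier extraction, and (2) quantification of catalytic-loop
conformational dynamics (opening angle, contact distance, helicity,
correlation times, PCA, RMSD clustering). This note records the models, the
parameters that matter, the numerical choices, and the limits of what the
synthetic-data tests demonstrate.

## Implicit ligand sampling (ILS)

A weakly interacting gas molecule can be treated as a test particle: the
per-voxel free energy of placing the probe at position **r**, relative to
vacuum, is the Widom estimate

    G(r) = -kB T ln [ (1/(N C)) Σ_m Σ_k exp(-ΔE_mk(r) / kB T) ]

over N trajectory frames and C probe orientations, where ΔE_mk is the
interaction energy of inserting the probe into frame m with orientation k.
Orientational degrees of freedom are averaged out, so G depends on position
only. In bulk solvent G equals the probe's solvation free energy, and
subtracting that bulk value converts in-protein values into transfer costs
from solution.

Model and defaults:

* **Probe.** Rigid homonuclear diatomic O2: two identical LJ sites at
  ±0.605 Å (bond 1.21 Å), each with Rmin/2 = 1.7 Å, ε = 0.12 kcal/mol, no
  charges (O2 is apolar; electrostatics excluded). The σ = 1.7 Å literature
  value is read as CHARMM Rmin/2 by default; a 12-6 σ reading is available
  via `ProbeModel.o2(sigma_convention="lj")` since the convention is
  genuinely ambiguous in print.
* **Orientations.** Deterministic spherical-Fibonacci axes on one
  hemisphere (C2 symmetry of the diatomic halves the sphere); the default
  C = 21 matches common ILS practice. The quadrature second moment
  converges to the uniform-hemisphere value.
* **Energetics.** CHARMM combination rules (Rmin additive, ε geometric),
  minimum-image convention, pairwise truncation at the cutoff with no shift
  or tail correction. Default cutoff 10 Å, reduced to the minimum-image
  bound L/2 in small boxes.
* **Cap and occlusion.** Insertions with ΔE above 87 kB T (the weight
  underflow threshold) contribute zero weight; voxels where every sample is
  capped are flagged occluded and displayed at +30 kcal/mol, the flag being
  authoritative. Weights lie in [e^-87, ~e^30], well inside float64 range,
  so plain summation of capped Boltzmann weights is exact to machine
  precision and no log-sum-exp rearrangement is needed.
* **Grid.** Default spacing 1 Å at 300 K; voxel centers at
  `origin + spacing·(i,j,k)`.
* **Kernels.** Numba-compiled direct pair loops (no cell list): for the
  system sizes analysed here — hundreds to a few thousand atoms per frame —
  a cell list gains nothing, and the straight loop is the reference the
  vectorised single-insertion path is tested against (agreement to 1e-10).

**Bulk reference.** Bulk voxels lie farther than 12 Å (default; the value
is this package's operationalization of "far from the solute", beyond a
typical nonbonded cutoff) from every non-solvent atom in every frame. The
region is pooled as one Widom volume: mean_G = -kT ln⟨exp(-G/kT)⟩ over
qualifying voxels, occluded voxels included at zero weight — excluding them
would bias the volume average toward open structure. The quoted sd is the
spread of the pooled estimate over 5 contiguous voxel sub-blocks.

**Pathways and barriers.** The migration barrier between an active-site
voxel and the map boundary is the minimax (bottleneck) path cost: an exact
widest-path best-first search on the 26-connected voxel lattice
(26-connectivity avoids axis artifacts at 1 Å spacing), ties broken by
shorter path then lexicographic voxel order; occluded voxels are
impassable. Barriers are reported both vacuum-referenced and relative to
the bulk mean. Entrance pathways at an isovalue are the 26-connected
boundary patches ("exits") of the sub-isovalue component containing the
site voxel — two channels bored from one cavity are one connected component
with two exits, and the exit count is the pathway count. Lining residues
are those with any heavy atom within 4.5 Å (default) of any path voxel
center in at least half the frames, ranked by minimum distance.

## Loop conformational dynamics

**Alignment.** Each frame is rotated into the principal-axes frame of a
selection (the dimer Cα set in the intended use), longest gyration axis
along +z, centroid at the origin. All three axes are fixed — signs by the
selection's third central moment along each axis, falling back on
frame-to-frame continuity when the skewness vanishes — so aligned
coordinates are independent of the input rigid-body pose (tested to
1e-6 Å under random rigid motions). Fixing only the long axis would leave
the azimuth free and make any angle against z ill-defined.

**Opening angle θ.** At the anchor residue's Cα (Leu342 by default), the
angle between the vector to the tip residue's Cα (Tyr348) and the vector to
(0, 0, z_ref), where z_ref is the z component of the loop-Cα centroid
(residues 342–361) of a designated closed-reference structure processed
through the same alignment. Cα atoms are used because the defining residues
are named without atoms in the source convention; the reference center is
computed once from the closed structure and reused for all frames.

**Contact distance d.** Minimum over all cross-group atom pairs (Tyr348 vs
His203 atoms in the intended use), plain Euclidean — intra-protein, so no
periodic imaging.

**Helicity.** Kabsch–Sander backbone H-bond energy
E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with an H-bond
below −0.5 kcal/mol; amide H rebuilt at 1.01 Å opposite the C(i−1)/Cα
bisector when absent. A p-turn at i is an H-bond N-H(i+p)→C=O(i); two
consecutive turns make a minimal helix, marking residues i..i+p−1 (p = 4
for α, 3 for 3-10). The fraction of range residues assigned either class is
the helical content. Only helix classes are assigned; and because the
energy uses distances only, a mirror image scores identically — adequate
for helical content, not a chirality-aware DSSP.

**Correlation time.** Integrated autocorrelation with initial-positive
truncation: τ = dt·(1/2 + Σ ρ_k), summed to the lag before the first
negative ρ_k (including the first negative term is a defensible variant;
excluding it is the standard initial-positive-sequence rule adopted here).
On an exact exponential ACF the estimator is accurate to quadrature error
(<2% for τ ≥ 10·dt); on finite series its sampling error is roughly
√(4τ/n), so recovery tests use n = 2000·τ frames.

**PCA and free-energy surfaces.** Frames are least-squares fit (Kabsch)
onto the first frame using a fit selection — by default the analysis
selection; for enzymes, the protein-core (non-loop) Cα so that loop motion
is measured in the enzyme frame. The 3n×3n covariance of loop Cα
coordinates is eigendecomposed; projections are centered coordinates times
eigenvectors. Pooled ("combined trajectory") analyses compute one
covariance over all runs so projections are mutually comparable. The 2D
surface over (PC1, PC2) is F = -kT ln(p/p_max); empty bins carry NaN
sentinels rather than fake barriers. Note that the rigid-body fit removes
six degrees of freedom and couples modes through the noisy reference, so
idealized spectra (pure rank-1 motion, isotropic noise) are only recovered
exactly with the fit disabled (`fit=False`).

**GROMOS clustering.** Pairwise Cα RMSD after Kabsch fitting; greedily, the
unassigned frame with the most unassigned neighbors within the cutoff
(default 6.2 Å for the enzyme loop) seeds a cluster, it and its neighbors
are removed, and the process repeats; ties break on the lowest frame
index. Populations are non-increasing by construction.

## Group statistics

Barrier samples (one per replica × monomer) are compared with a two-sample
t-test — Welch's unequal-variance form by default, pooled-variance by flag
— and summarized per (group, form) with absolute and bulk-relative means,
standard deviations (all reported errors are sds), and a one-sample t-test
of the relative barrier against zero. Independent errors combine by
root-sum-of-squares; a literal "square root of the sum of the errors" is
exposed as an alternative flag because that phrasing is ambiguous in the
field's usage.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of their spec (seed included).

* **Rigid-water box** (default 216 molecules, 18.65 Å cube at 0.997 g/cm³,
  300 K): three-site rigid water with TIP3P geometry/charges and CHARMM
  O-site LJ, sampled by Metropolis MC with rigid translations, rotations,
  and a 10% fraction of molecule-teleport moves (symmetric uniform
  reinsertion proposals) that decorrelate cavity structure far faster than
  diffusion; move sizes adapt toward ~40% acceptance during equilibration
  (3000 sweeps) and freeze for production. Electrostatics use a
  molecule-based 9 Å cutoff (the minimum-image bound for this box) with a
  reaction-field correction (ε_RF = 78.5); O-O dispersion is truncated
  unshifted. Frames are written every 100 sweeps; the default production
  (50 000 sweeps) yields 500 frames. Mean energy (≈ −9.5 kcal/mol per
  molecule) and the O-O RDF (first peak 2.75 Å, g ≈ 2.7) match the
  expected bulk structure.

  *Caveat on the O2 solvation number.* With this box the probe's LJ
  interactions are necessarily truncated at 9 Å (no tail correction), and
  electrostatics are reaction-field rather than Ewald. Converged runs give
  an O2 solvation free energy of ≈ 2.3–2.4 kcal/mol, roughly 0.2–0.35
  above values computed with 12 Å-range force-switched LJ and PME in large
  boxes (≈ 2.0): the missing attractive tail alone accounts for
  ≈ +0.18 kcal/mol, and the absent H-site LJ attraction of CHARMM-variant
  water for part of the rest. The number is reproducible and internally
  consistent; it is systematically offset from the large-box reference
  setup, which is the expected behaviour of a truncated, reaction-field
  model, not a sampling artifact (teleport-move decorrelation and pooled
  full-box estimation were verified against longer reference runs).

* **LJ fluid**: single-site Metropolis MC; the substrate for exact
  ILS/Widom cross-checks and ideal-gas (ε = 0) uniformity tests.

* **Cavity/channel walls**: static pseudo-atoms on concentric spherical
  shells (spacing below the probe contact distance, hence watertight) with
  an optional cylindrical channel bored to the box face; shell sites carry
  SPH pseudo-residues (24-site patches), channel rings CHW residues, so
  lining analysis can name what it finds. Analytic expectations: G ≈ 0 at
  the cavity center (walls beyond cutoff), occluded walls, a channel
  bottleneck < 1 kcal/mol when the radius exceeds probe contact + 1 Å, and
  a disconnected map when the channel is sealed.

* **Loop trajectories**: frames = A + s_t (B − A) + Gaussian noise
  (0.3 Å/atom default), with s_t an exact AR(1) discretization of an
  Ornstein-Uhlenbeck process (known relaxation time, default stationary sd
  0.2 around mean 0.5) reflected into [0, 1]; ground truth records s_t,
  τ_true and basin labels (s ≷ 1/2). The default endpoints are a 20-atom
  Cα arc whose distal half swings 90° about a hinge atom — a genuine
  conformational change that survives least-squares superposition, unlike
  a whole-body rotation. A single stationary reflected-OU run is unimodal
  by construction; two-basin tests therefore pool runs dwelling near
  opposite endpoints (means 0.15 and 0.85), mirroring the combined
  open-start/closed-start trajectory design used for real enzymes.

* **Ideal backbone builder**: N/Cα/C/O from ideal bond geometry at given
  (φ, ψ) via natural extension of reference frames; (−57°, −47°) gives an
  α-helix with ≈1.5 Å rise per residue, (180°, 180°) an extended chain.

What passing synthetic tests do **not** show: force-field realism for
proteins, convergence of μs-scale loop sampling, PME-quality solvation
numbers, or pathway counts on real enzyme maps (isovalue choices there are
judgment calls; the flood-fill formalization here is one fixed convention).

## Problem sizes

Defaults are sized for a single CPU: water solvation uses 500 frames × 7
orientations over the full 18.65 Å box at 1 Å spacing (a few minutes);
channel analyses use 1–2 Å grids over ≤ 40 Å boxes; clustering examples use
hundreds of frames (pairwise RMSD is O(n²)). All are package choices and
scale up linearly through the same interfaces.

## Known limitations

* Orthorhombic boxes only; triclinic cells must be pre-wrapped.
* The probe is a rigid, apolar, ≤2-site LJ molecule; no charges or
  flexibility.
* Helicity assignment is distance-only (mirror-blind) and limited to α and
  3-10 classes.
* The opening-angle convention (Cα anchors, closed-reference z-projection,
  skewness-fixed principal axes) is one concrete realization of a verbally
  specified definition; absolute angles on other conventions may differ by
  a few degrees.
* Minimum distances ignore periodicity (intra-protein use).
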