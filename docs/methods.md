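# Methods

This note records the models behind each analysis, the parameter defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions a user should know before trusting
a number.

## Contact networks

A structure is mapped to an unweighted, undirected graph on residue
α-carbons.  An edge joins residues *i*, *j* when

    4 Å ≤ |Cα_i − Cα_j| ≤ 8 Å   (both bounds inclusive)

and the pair is not sequence-adjacent.  The lower bound plus the explicit
|i−j| ≥ 2 rule removes covalent neighbours even in strained conformations
where consecutive Cα atoms drift past 4 Å; the upper bound restricts edges
to van-der-Waals packing range.  Sequence adjacency is evaluated *within a
chain*: the sequential node index runs across chains, but the last residue
of one chain and the first of the next are not covalently linked and may
form an edge.  Every protein residue must carry exactly one Cα; HETATM
records (waters, ions, glycans) are parsed but excluded from residue
accounting and hence from networks.

Descriptors per network:

| descriptor | definition | units |
|---|---|---|
| adeg | mean node degree = 2·E/N | contacts/residue |
| asp  | mean shortest-path length over reachable unordered pairs | steps |
| E    | graph energy Σ\|λ_i\| of the adjacency matrix | — |
| dG_solv | Σ Δσ(class)·ASA over heavy atoms | kcal/mol |

On a disconnected graph, asp pools path lengths within components and the
bundle carries `connected=False`; this keeps the descriptor finite for
time-series correlation instead of returning infinity.

dG_solv uses the Eisenberg–McLachlan atomic solvation parameters
(cal·mol⁻¹·Å⁻²): C +16, neutral N/O −6, carboxylate O⁻ −24, charged N⁺
(Lys NZ, Arg NE/NH) −50, S +21, all overridable via `SolvationParams`.
These are the standard published values; they are defaults, not a claim
that any particular study used exactly them, so absolute dG_solv values
should be compared only within one parameter set.

## Equilibration by descriptor correlation

A trajectory window sampled around a relative conformational minimum
should show descriptors that fluctuate without trend.  For each
descriptor the Pearson correlation against time (and against every other
descriptor) is computed with a two-sided p-value from the t-distribution
with n−2 degrees of freedom; a descriptor is called **drifting** when
p < α (default α = 0.05, configurable).  A constant descriptor has no
defined correlation and is reported as stationary (no evidence of drift)
with a `constant` flag.

Caveat, stated in every report: frames are treated as independent.  At
10 ps spacing this is conventional, but autocorrelated series inflate the
test — for an AR(1) process with φ = 0.5 the variance of the time
correlation grows by ≈ (1+φ)/(1−φ) = 3 and the false-drift rate rises
from 5% to ≈ 26%.  The test suite pins exactly this behaviour; treat the
verdicts as a screen to be read next to the raw r and p values, not as a
hypothesis test with guaranteed level on correlated data.

## Spectral partitioning and whiskers

Modules are found by spectral clustering: build the symmetric normalised
Laplacian L = I − D^(−1/2) A D^(−1/2) (zero-degree nodes keep a zero
inverse-root), embed the nodes in the k eigenvectors of smallest
eigenvalue, row-normalise, and run k-means with 25 restarts from a fixed
seed.  The result is deterministic given (network, k, seed).  k is
user-supplied — typical choices are 2 for a single two-domain protein and
4 for an antibody-fragment/dimer complex — and an eigengap report is
logged to guide the choice; no automatic model selection is attempted.
Graphs with more connected components than k are rejected with guidance,
since no k-partition can respect the component structure.

The exact embedding used by the original module-decomposition literature
is not uniquely pinned down; the normalised-Laplacian choice here is a
config default of this package, validated on planted-partition and
disjoint-clique benchmarks (exact recovery), not a fidelity claim to any
specific prior implementation.

A **whisker** is a node whose cluster label differs from both of its
sequence neighbours (chain ends and chain breaks compare against the
single within-chain neighbour).  Whiskers mark residues pulled into a
foreign module by a long-range contact; a partition whose labels form
contiguous sequence blocks has none.  The partition map is the n×k 0/1
occupancy grid (one cell per node row) used for the colour-map rendering.

## Trajectory geometry

*Superposition.*  Kabsch via SVD with the determinant correction, so only
proper rotations are returned; at least three non-collinear reference
points are required.  Weights are optional and normalised internally.

*RMSD.*  Each frame is fit to the reference over a fit selection and
measured over a calc selection (defaults equal).  Split RMSD fits each
binding partner to its own reference independently, which removes
inter-partner motion — the whole-complex RMSD is therefore *not* the sum
of the split series, and the gap between them is itself informative.
Units are Å internally; nm reporting is a display toggle (×0.1).

*RMSF.*  Fluctuations are measured about the time-average structure after
two superposition passes (fit to reference, average, refit to the
average) — the common trajectory-tool convention.  Per-residue values are
taken at each residue's Cα.  Note the rigid-body fit absorbs six degrees
of freedom: for iid displacement noise the measured RMSF underestimates
σ√3 by ≈ √(1 − 6/3N), which is why the closed-form check uses 60 residues
(bias < 2%).  `fit=False` gives the unfitted estimator.

*PCA.*  Frames are superposed on the reference over the selection
(Cα-only and mass-unweighted by default), flattened to 3N-vectors and
mean-centred; eigenvalues/eigenvectors come from the SVD of the centred
frame matrix, so the variance fractions always sum to 1 over the full
spectrum.  Projections are reported for the leading components.  As a
surrogate for eigenvector animations, `extreme_projection_frames` emits
the two frames at the projection extremes as a 2-model PDB.

*Cosine content.*  For a projection p(t) on a window of length T,

    c_i = (2/T) · (∫₀ᵀ cos(iπt/T) p(t) dt)² / ∫₀ᵀ p(t)² dt

evaluated by trapezoid quadrature on the sampled, mean-centred series
(order i for the i-th component).  Analytic anchors: c₁ = 1 for a half
cosine, c₁ = 96/π⁴ ≈ 0.9855 for pure linear drift.  Components with
c ≥ 0.5 are flagged as diffusion-like (poorly sampled); the comparison is
strict — a value of exactly 0.5 is reported as borderline rather than
failed, and the flag is advisory output, never a hard error.

## Interface statistics

*Contacts* are counted between two disjoint atom groups per frame: the
number of atom pairs within the cutoff (default 3.5 Å, inclusive),
reported as mean ± sd over frames.  Pair counting (mindist semantics) is
the default because trajectory means of pair counts are the quantity that
legitimately comes out non-integer; a residue-pair mode is available when
a per-residue interface census is wanted.

*Hydrogen bonds.*  A donor–acceptor pair (N/O with a covalently bound H,
identified by a ≤ 1.25 Å X–H distance in the reference frame) is bonded
in a frame when the heavy-atom distance is ≤ 3.5 Å and the D–H···A
deviation from linearity is ≤ 30°.  Occupancy is the bonded fraction of
frames; bonds at occupancy ≥ 0.5 count as high-frequency.  All three
thresholds are configurable, and a heavy-atom mode (distance only) exists
for hydrogen-free models — the two modes bracket the conventions used by
the common H-bond tools, whose exact thresholds differ between programs.

## SASA, apolar term and the energy ledger

SASA is Shrake–Rupley: each atom's sphere is expanded by the probe radius
(1.4 Å, water) and sampled with golden-spiral points (default 960, which
keeps the lone-sphere quadrature error well under 1%); the accessible
area is the unoccluded fraction × 4π(r+probe)².  Radii are Bondi van der
Waals values; unknown elements raise rather than guess.  The apolar
solvation term is G_apolar = γ·SASA with γ = 0.022 kJ·mol⁻¹·Å⁻², the
standard surface-tension coefficient of MM-PBSA practice.  Complex SASA
is never larger than the sum of its separated parts, so ΔG_apolar of
binding is ≤ 0 whenever the interface buries surface.

The binding ledger combines per-term tables for complex, receptor and
ligand: Δterm = complex − receptor − ligand, total = Σ Δterm.  The polar
(Poisson–Boltzmann) and vacuum force-field terms are **ingest-only**: they
arrive in a TSV produced by an external engine, are tagged with their
provenance, and are never recomputed here — this package is the ledger,
not a PB solver.  No entropic term exists anywhere in the bookkeeping,
which is why the total is labelled ΔE_binding rather than ΔG_binding.
Per-residue decomposition energies are written into the PDB b-factor
column (`%6.2f`; values outside [−999.99, 9999.99] are rejected, and the
overflow of wide values into neighbouring blank columns is parsed back
tolerantly), so stabilising residues render blue-to-red in any viewer.

## Synthetic fixtures: what they emulate

`make_backbone` builds poly-alanine chains with full N/CA/C/O/CB heavy
atoms: an ideal α-helix (rise 1.5 Å, 100°/residue, radius 2.3 Å — giving
the canonical 3.8 Å Cα spacing and a contact signature of edges only at
2 ≤ |i−j| ≤ 4), an extended strand, a persistent-random-walk coil, and a
two-domain fixture (two helical bundles, bounding boxes 15 Å apart, one
midway linker residue) that stands in for a two-module complex.
`make_ensemble` adds motion: `static`, `harmonic` (one fixed random unit
mode driven through three sine periods — a single collective degree of
freedom, so PC1 captures ~all variance with low cosine content),
`diffusive` (cumulative Gaussian steps — the poorly-sampled random-walk
regime, high cosine content), and `gaussian` (iid isotropic displacement,
whose RMSF has the closed form σ√3).  `planted_partition_graph` is a
two-parameter stochastic block model with stored true labels.

These fixtures make every ground truth analytic, which is exactly what
they are for — and exactly their limit.  They have no side chains beyond
Cβ, no secondary-structure transitions, no solvent, no force field, and
their motions are statistically stationary by construction.  Passing
tests therefore demonstrate that the estimators are correct, not that any
particular biological trajectory is equilibrated or any binding energy is
accurate.

Default fixture sizes in tests and in `scripts/acceptance.py` (20–60
residues, 100–2000 frames, planted blocks of 20) are chosen so every
closed form is sharp (e.g. the RMSF fit-bias bound above) while the whole
verification run completes in seconds; the statistical calibrations use
500 replicates (type-I rate) and 200 replicates (AR(1) inflation), enough
for ±2% and ±8% binomial resolution respectively.

## Numerical conventions and edge cases

- Coordinates are Å everywhere internally; times are ps.
- PDB parsing is fixed-column v3.3; altLoc alternatives collapse to the
  highest-occupancy record, ties to altLoc `A`; missing element columns
  are inferred from the first alphabetic character of the atom name.
  Residue identity is the file's own (chain, res_seq, i_code) — author
  numbering is never rewritten; a sequential 0-based node index is
  derived for network work.
- Degenerate inputs raise typed errors rather than returning NaN:
  < 3 or collinear points for superposition, < 2 frames for RMSF/PCA,
  < 4 samples or an all-zero series for cosine content, edgeless graphs
  for asp/clustering, k outside [2, n] for partitioning.
- k-means determinism comes from the seeded 25-restart run; empty
  clusters (possible in principle) are flagged on the Partition rather
  than silently renumbered.
- All generators take explicit seeds; identical seeds give bit-identical
  output.

## Known limitations

- The polar solvation and vacuum MM terms are never computed; without an
  external PB engine the ledger can only combine what it is given.
- No periodic-boundary unwrapping: trajectories must be whole-molecule
  imaged before export to multi-model PDB.
- The drift test has nominal level only for uncorrelated frames (see the
  caveat above).
- Whisker detection is purely label-based; it does not verify that the
  responsible long-range contact exists in the frame being rendered.
- mmCIF, compressed transport and PDB REMARK semantics are out of scope;
  input is plain single/multi-model PDB text and TSV tables.
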