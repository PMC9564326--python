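# Methods

This note documents the models, numerical choices and limitations behind
each analysis stage. Units throughout: Å, kcal/mol, cal/(mol·K) for raw
entropies, ns, amu, elementary charges.

## Structural data model and I/O

Topologies hold an ordered atom list, named integer index groups (e.g.
`receptor`, `ligand`, `ring_atoms`, `receptor_ca`, per-moiety sugar groups)
and optional bonds. Atom indices are 0-based internally; PDB I/O uses the
format's 1-based serials. Waters and monoatomic ions are flagged by
residue-name whitelists (`HOH/WAT/...`, `CA/NA/CL/...`), configurable
because PDB dialects vary; the ambiguous case of a Ca²⁺ HETATM named `CA`
is resolved by the residue name, never the atom name. Multi-model PDB
reference structures (NMR ensembles) yield their first model. ATOM/HETATM
records are parsed with the fixed-column layout so that malformed input can
be reported with its line number; binary DCD trajectories go through
MDAnalysis. Force-field parameters (charge, LJ r_min/2 and well depth,
mass, intrinsic GB radius and screening factor per (residue, atom) key,
plus the global dielectrics) arrive as a YAML table; unset globals default
to ε_int = 3.0, ε_solv = 78.5, T = 300 K, probe 1.4 Å, γ = 0.0072
kcal/(mol·Å²), Coulomb constant 332.0636 kcal·Å/(mol·e²).

## Pose analysis

All RMSDs build on a weighted Kabsch fit (SVD with a determinant guard so
the rotation is always proper). The *positional* RMSD convention: each
frame is fitted to the reference on a fit selection (receptor Cα by
default) and the RMSD is measured over a measure selection (ligand ring
atoms) **without refitting**, so the series reports where the ligand sits
in the binding site, not its internal shape. The pairwise (2D) RMSD matrix
samples frames evenly (default every 0.1 ns) from all replicate runs
pooled, and accepts the same fit/measure separation; with the default
self-fit it measures internal shape instead. Pose clustering is
average-linkage agglomerative on the matrix, cut at an RMSD cutoff
(default 1.5 Å) — deterministic, standard for 2D-RMSD maps, and needs no
seed; the published analyses name poses but state no algorithm, so the
cutoff is exposed and the default was fixed before any comparison. Poses
are numbered by descending population; each pose's medoid minimises the
summed RMSD to its cluster; representative-structure extraction returns
the frame closest to the mean fitted shape over all runs, ties broken by
(run_id, time) for reproducibility.

## Glycan conformation

Glycosidic torsions follow the carbohydrate convention
φ = C2-C1-Ox-Cx, ψ = C1-Ox-Cx-C(x−1), switching to φ = C3-C2-Ox-Cx,
ψ = C2-Ox-Cx-C(x−1) when the donor is a sialic acid. Dihedrals are signed
with the standard right-handed convention (checked against MDAnalysis);
they are invariant under full reversal of the atom quadruple and flip sign
under reflection. Linkages are located from topology bonds when present,
otherwise from anomeric-carbon-to-oxygen distances (< 1.8 Å) in a supplied
frame.

CHI strain curves are one-dimensional relative energies on a periodic
angle grid, shipped as CSV data rather than hard-coded polynomials so the
parameterisation is replaceable; curves are normalised to min = 0 on load
and evaluated by periodic linear interpolation (exact at nodes, no
overshoot). The total CHI series sums the φ and ψ contributions of all
non-excluded linkages with no cross terms (the curves are 1-D). Two
linkage-specific rules: Neu5Acα2-3Gal is excluded from the total, and
Fucα1-3GlcNAc is evaluated on the mirror image of the curves, implemented
as (φ, ψ) → (−φ, −ψ) — negating both torsions is the enantiomeric relation
between α-L-fucose and the β-D template sugars the curves describe.

Ring puckering uses the Cremer–Pople coordinates (Q, θ, φ_ring) of the six
ring atoms ordered O5,C1..C5. Chairs are labelled ⁴C₁ for θ ≤ 45° and ¹C₄
for θ ≥ 135° (a symmetric partition of θ-space); near-planar rings
(Q < 0.1 Å) are labelled `other` with a warning rather than an error.

## Interactions

Hydrogen bonds are geometric: donor–acceptor heavy-atom distance ≤ 3.5 Å
and D-H···A angle ≥ 135° (both configurable; common MD-analysis
convention — the published tables state no criteria, so the defaults are
surfaced in every report). Donors are polar heavy atoms with a bonded
hydrogen; a distance-only mode (default cutoff 3.0 Å) serves hydrogen-free
topologies and Ca²⁺ coordination, which has no hydrogen geometry.
Occupancy is the fraction of frames satisfying the criteria, reported per
run and pooled (frame-weighted); "stable" means pooled occupancy ≥ 0.5 by
default — an explicit operationalisation of a qualitative notion, and
deliberately configurable.

Water densities are voxel counts of water oxygens on a cubic grid (default
cell 0.5 Å) averaged over frames; local maxima must beat all 26 neighbours
and a density floor (default 0.25 mean occupancy, suppressing bulk noise
at this cell size). Note that a site lying exactly on a voxel boundary
splits its counts across neighbouring cells; callers probing a known site
should centre the grid on it (the pipeline offsets the region by half a
cell). Bridge detection takes a candidate site (normally a density
maximum): per frame, the nearest water oxygen within one cell occupies the
site and its distances to the ion and to the nearest target atom are
recorded; a run exhibits the bridge when both per-run mean distances fall
inside the acceptance windows, and the report also states whether all runs
agree. An unoccupied site is a no-bridge result, not an error.

## MM-GBSA energetics

Single-trajectory scheme: ΔG = G(complex) − G(receptor) − G(ligand) per
snapshot with all species' coordinates from the complex frame, so bonded
terms cancel and are never computed. No nonbonded cutoff is applied —
rescoring conventionally uses all pairs, and the cutoffs used by MD
engines during sampling are irrelevant here. 1–4 scaling factors affect
only intramolecular pairs, which cancel in this scheme. Components:

* electrostatics k·q_iq_j/(ε_int·r) over cross pairs;
* 12-6 Lennard-Jones with Lorentz–Berthelot combination;
* GB-OBC polar solvation: effective Born radii from the pairwise
  descreening integral with the OBC tanh rescaling (model-I constants
  α = 0.8, β = 0, γ = 2.909125, radius offset 0.09 Å; screening factors
  are per-atom data, default 0.8), energy from the canonical smooth form
  f_GB = √(r² + R_iR_j·e^(−r²/4R_iR_j)) with prefactor
  −½(1/ε_int − 1/ε_solv); no salt term;
* nonpolar term γ·SASA by Shrake–Rupley sphere sampling (960 golden-spiral
  points per atom, probe 1.4 Å), chosen for implementation clarity over
  the LCPO approximation. The fixed point lattice makes SASA invariant
  under rigid motion only to within its angular resolution (~0.01 Å²/atom
  in practice); the other components are exactly invariant.

Snapshots are sampled evenly per run (`n_snapshots` is per run, capped at
the frame count by the pipeline); the headline value is the cross-run mean
± sample SD of per-run means, matching the replicate design.

**Per-moiety decomposition.** Each receptor–ligand cross pair (elec and
vdW) is attributed fully to the ligand-side group — no half shares,
because the reported tables attribute energy to ligand moieties only. GB
and SASA are decomposed per atom (half of each GB cross term to each
partner, self terms to their own atom; per-atom area changes × γ), and
each receptor atom's share is assigned to the group of its nearest ligand
atom in that frame. This proximity rule is the design choice that makes
the table exact: group energies sum to the interaction total to machine
precision, which is asserted in every pipeline run.

**Mutant construction.** Alanine truncation deletes side-chain atoms
beyond Cβ in topology and all frames, renames the residue ALA (switching
parameter lookup to alanine templates) and leaves backbone/Cβ coordinates
bit-identical; glycine targets are rejected. Residue deletion (e.g.
defucosylation) removes the residue everywhere and, when a bond crossed
from a removed carbon to a retained glycosidic oxygen, restores the free
hydroxyl by adding a hydrogen 0.96 Å along the former C–O direction —
matching the chemistry of the truncated free ligand.

## Entropy

**Quasiharmonic (−TΔS_RTV).** Frames are superposed on the selection's
mean structure (two-pass fit); the mass-weighted Cartesian covariance is
diagonalised; each eigenvalue λ gives a mode with x = ħ/√(k_BTλ) and the
*quantum* harmonic-oscillator entropy (the classical formula diverges for
stiff modes and is not used). With superposition the six smallest
eigenvalues — the external rotations/translations the fit removed — are
dropped; without superposition (e.g. on the harmonic-bath oracle, which
has no net rigid motion) all 3N modes are kept. Because QH entropy grows
with sampling time, it is evaluated on nested cumulative windows whose
endpoints are evenly spaced in 1/t (default 10 windows from T_total/10 to
T_total) and extrapolated by OLS in 1/t; the intercept is the
infinite-sampling estimate. −TΔS_RTV is assembled per run as
−T(S_complex − S_receptor − S_ligand) and averaged across runs. The atom
selection behind each species' entropy is explicit (the pipeline uses all
solute atoms); the free-ligand ensemble for the torsional term is a
required input, not guessed — without it the pipeline reports the term as
unavailable rather than silently zero.

**Karplus–Kushick (−TΔS_q^C).** Each torsion is unwrapped about its
circular mean (the estimator assumes unimodality; a circular SD above
120° triggers a warning), the covariance is taken in radians, and
S = (k_B/2) ln[(2πe)ⁿ det Σ]. A torsion with (near-)zero variance is
rejected by name rather than silently producing −∞.

## Reporting and statistics

ΔG_binding = ΔG_MM/GBSA + (−TΔS); run-to-run SDs combine in quadrature.
Percent contributions are 100·group/total rounded half-away-from-zero to
integers, with values rounding below 1% rendered "<1%". Complexes are
compared with a pooled-variance two-sample t test on per-run values
(df = n_A + n_B − 2, two-tailed; Welch available behind a flag), including
a summary-statistics entry mode for comparisons against published means ±
SDs. An instability gate withholds energy and entropy stages when the
ligand's positional RMSD exceeds a threshold (default 8 Å) in any run —
binding energies of unbound complexes are not meaningful numbers.

## Synthetic data: what it does and does not emulate

The generators exist to give every estimator an exact oracle:

* the harmonic bath draws independent Gaussian coordinates, so the
  mass-weighted covariance (hence the QH entropy) is known in closed form;
* torsion ensembles are multivariate Gaussians wrapped to (−180°, 180°],
  the exact KK reference;
* the toy complex is a tetrasaccharide-like ligand (Neu5Ac-Gal-GlcNAc
  core, branch fucose, 6′-sulfate), a three-residue receptor carrying a
  serine hydrogen-bond donor and an arginine salt bridge to the sulfate, a
  Ca²⁺ ion, and optionally a bridging water placed at stated
  Ca²⁺–O(water) and O(water)–O(sulfate) distances. Modes: `stable`
  (Gaussian jitter about the bound pose, defaults 0.2 Å ligand / 0.05 Å
  receptor), `multi-pose` (block-wise contiguous dwells at rigid pose
  offsets — mimicking MD autocorrelation rather than i.i.d. labels — with
  dwell fractions summing to 1), `diffusing` (linear escape to 14 Å by the
  final frame). Hydrogen bonds are planted with an exact on-fraction over
  randomly chosen frames.

Noise is Gaussian, not Boltzmann-from-force-field: that is what makes the
entropy and covariance oracles exact. Consequently passing tests establish
the *estimators'* correctness, not force-field realism; the toy complex
has no solvent box, no PME artifacts, unphysical bond geometry between
sugar rings, and charges chosen to plant a single dominant salt bridge.
Default test problem sizes (3 runs × 60–100 frames, ~67 atoms, 5·10⁴
frames for the QH oracle, 10⁵ samples for KK) were chosen as the smallest
sizes at which the closed-form recoveries are comfortably inside their
tolerances.

## Known limitations

* No Poisson–Boltzmann solver, normal-mode entropy, three-trajectory
  MM-GBSA, or mutual-information entropy expansions.
* GB radii sets and CHI curve parameterisations are data inputs; the
  package ships no claim about which variant reproduces any particular
  published table.
* The SASA decomposition's nearest-ligand-atom attribution of
  receptor-side burial is a convention (exact by construction, physically
  proximate, but not unique).
* Hydrogen-bond criteria and the "stable" occupancy threshold are
  conventions; different choices change which pairs a table lists.
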