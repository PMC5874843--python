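# Methods

This note records the models, conventions and numerical choices behind
`gelforge`, in the order the pipeline runs them, together with what the
synthetic-data generators do and do not emulate.

## Molecular data model and builders

The universal container is `Molecule`: parallel arrays of element symbols,
Cartesian coordinates (Å), partial charges (e), van der Waals radii (Å,
Bondi defaults) and role tags, plus an explicit bond list. Atomic weights
are the 2021 IUPAC abridged values and can be overridden per call; with
them, the guest drug formula C21H26O5 evaluates to 358.434 g/mol exactly.
A pseudo-element `X` (unit weight) serves as the generic Lennard-Jones site
of the synthetic toy systems.

PVA chains are built as idealized extended zig-zags from standard bond
lengths (C–C 1.54, C–O 1.43, C–H 1.09, O–H 0.96 Å) and tetrahedral angles,
H-capped, with atactic hydroxyl placement drawn from the chain seed. No
quantum-chemical geometry optimization is performed anywhere; idealized
geometry plus local steric relaxation is sufficient for every geometric and
energetic operation the package defines. Tacticity and end-group treatment
are free choices (atactic, H-capped) since nothing downstream depends on
them.

### Packing

`random_pack` places rigid chains by rejection sampling with a fixed
per-chain attempt budget (default 10,000): a random orientation, a
translation uniform over the in-box positions, and acceptance iff the
nearest atom-atom distance to everything already placed is at least the
minimum separation (KD-tree query). Isotropic orientations of ~88 Å rigid
rods jam well below the density the default configuration requires (random
sequential adsorption of the equivalent ~10 Å-pitch disks saturates near 50
rods per cross-section while 56 are needed), so packing escalates through
three whole-pack stages, each deterministic in the seed: (1) uniform SO(3)
orientations; (2) orientations concentrated within 3° of the longest box
axis; (3) candidate positions drawn from a shuffled transverse lattice with
pitch `min_separation + chain cross-diameter`, random spin and axial
offset. Every accepted placement satisfies the separation postcondition
regardless of stage — the stages change proposal distributions, never the
contract. The real study packed *flexible* chains, which bend to fit; the
orientation bias is this package's substitute for that flexibility.

### Crosslinking

The cyclic-iteration scheme draws uniformly over the *currently eligible*
set of hydroxyl pairs — unused sites, different chains, inter-oxygen
distance ≤ 10 Å — enumerated each round with a KD-tree. Because the
eligible set is enumerated exhaustively, a stall is detected exactly: if
the set empties before the stoichiometric target
`round(monomers · sa_parts / pva_parts)` (392 for 1960 monomers at 10:2),
the builder raises a structured shortfall error carrying the partial model
and the achieved count rather than silently truncating. Each accepted pair
loses its hydroxyl hydrogens (ester formation), gains a succinate diester
fragment (–CO–CH2–CH2–CO–, C4H4O2) spanning the two oxygens, and the
surroundings within 6 Å are relaxed. Bridges may not join two sites on one
chain, even at long contour distance.

Mass bookkeeping is exact by construction: the model's molar mass equals
the sum of its pristine fragments minus one water (18.015 g/mol) per ester
bond formed — two per bridge, two per cyclodextrin graft (see below) — and
is property-tested against independent formula arithmetic.

### Local relaxation

`local_relax` is plain steepest descent with backtracking on the bundled
non-bonded energy (bonded and 1-3 pairs excluded) plus harmonic restraints
holding bonds (k = 300 kcal mol⁻¹ Å⁻²) and angles (k = 50 kcal mol⁻¹
rad⁻²) at their values at entry. Steps are accepted only if the energy does
not increase; termination at `max_steps` (default 200; the builder uses 25
per bridge) or gradient infinity-norm < 10⁻³ kcal mol⁻¹ Å⁻¹. The restraint
constants are package conventions: the relaxation exists to relieve steric
clashes around new bridges, not to find force-field minima.

### Cyclodextrin grafting

The grafting chemistry follows the synthesis picture: a succinate, ester-
bound to a chain hydroxyl at one end, esterifies a primary-face hydroxyl of
γ-cyclodextrin at the other. Each graft therefore consumes one free chain
hydroxyl site, adds one pendant succinate plus one cyclodextrin, and costs
two waters. The builder's bridging succinates are all doubly esterified to
chains, so grafts are anchored on *pendant* succinates created at graft
time; the SA census of a model is `crosslinks + grafts`. Capacity errors
name the number of grafts actually placeable (free, clash-clear sites).

The packaged γ-cyclodextrin model is a deliberately coarse stand-in,
labeled as such: exact composition ((C6H10O5)8 = C48H80O40, 1297.13 g/mol)
and correct torus topology — glycosidic oxygens on a ring of radius
6·cos(π/8) ≈ 5.54 Å, secondary hydroxyls on the wider (−z) face, primary
hydroxyls on the narrower (+z) face — but schematic intra-unit geometry.
The cavity frame derived from it (glycosidic-oxygen centroid, smallest
principal axis oriented secondary→primary, mean in-plane rim radius) is
exact for this construction.

## Energy model and screening

The energy interface maps molecules at fixed geometry to a total energy in
kcal/mol, with E(∅) = 0 and rigid-motion invariance. The bundled
implementation sums Lennard-Jones 12-6 and Coulomb terms over all
non-bonded atom pairs, Lorentz–Berthelot mixing, k_e = 332.0636
kcal Å mol⁻¹ e⁻², configurable relative permittivity, and a 0.5 Å distance
clamp below which the pair energy is frozen at its clamp value so that
overlapping random poses stay finite. Because intramolecular exclusions
depend only on each molecule's own topology, they cancel exactly in the
supermolecular difference, and ΔE from three total-energy evaluations
equals the direct inter-fragment pair sum for rigid fragments — an identity
the suite checks to 10⁻⁹ kcal/mol on clash-free poses. (On poses inside the
clamp the identity still holds algebraically, but at energies of order 10⁸
kcal/mol double precision cannot resolve 10⁻⁹ absolute; the tests therefore
sample shells where no pair reaches the clamp.)

Orientation sampling uses normalized-Gaussian quaternions (uniform on
SO(3)) and shell translations uniform by volume, centroid-to-centroid,
defaulting to [0, host radius + guest radius + 5 Å]. A useful check worth
recording: the expected trace of a uniformly random rotation matrix is 0
(angle density (1−cos θ)/π gives E[cos θ] = −1/2), which the sampler
reproduces within Monte-Carlo error.

Ensemble statistics are the mean ΔE, its standard error (sample SD/√n), and
the lowest-k subset sorted ascending with ties broken by pose index.
Inclusion classification projects the guest into the cavity frame: "none"
if no atom falls inside the cylinder of rim radius and ±4 Å axial extent
(a declared convention — the quantitative inclusion criterion is this
package's, not inferred from any published rule); otherwise A or B
according to which end-marker centroid sits deeper along the
secondary→primary axis.

## Frame observables

* **RGYR** — mass-weighted, about the mass-weighted centroid.
* **SASA** — Shrake–Rupley with a deterministic Fibonacci spiral (default
  960 points, probe 1.4 Å) so results are bit-reproducible; validated
  against the analytic sphere (0.5%) and a 10⁶-point Monte-Carlo oracle on
  overlapping pairs (1%).
* **Waters in gel** — water oxygens within 3.0 Å of any gel atom, plus
  those inside the gel envelope: the 2 Å-cell grid cells not reachable from
  the box boundary by 6-connected flood fill through gel-free cells. Cells
  are blocked by atom *spheres* (center ± vdW radius), not centers, so the
  envelope does not leak through a thin gel wall depending on how the grid
  happens to align. Oxygen positions, not whole molecules, are the counting
  convention.
* **Guest capture** — a guest counts as captured when any atom is within
  4.5 Å of any gel atom; over a trajectory, an optional persistence
  parameter (default 1) requires the contact to hold for that many
  consecutive frames.
* **Hydrogen bonds** — geometric criterion D···A ≤ 3.5 Å and ∠D–H···A ≥
  150°, donor and acceptor in different components; both cutoffs
  configurable since this is a convention, not a measurement.

Frames are treated as whole molecules in free space: no periodic imaging is
applied, and inputs must be pre-imaged. Series evaluation is per-frame in
frame order; block averages use contiguous equal blocks with the remainder
folded into the last block.

## Release statistics

Factor coding is the exact min-max transform `2(x−min)/(max−min) − 1` with
an explicit inverse and no extrapolation; the packaged 20-run design's
printed coded columns agree with the transform to 10⁻⁴ and are validated on
load. Effect screening is OLS on the coded regressors with intercept;
the standardized effect is |coefficient/SE| against the two-sided critical
t at 95% and residual degrees of freedom. Reduced fits refit exactly the
included terms; R² is reported in percent, with the constant-response case
defined as 0. The swelling index divides by the *swollen* mass, as the
source arithmetic does (not the more common xerogel denominator). Drug
content is the positive gravimetric difference loaded − unloaded; the
operand order is chosen to give positive content. Cumulative release
applies the aliquot-replacement mass balance by default
(`c_i·V + Σ_{j<i} c_j·v_j`), which is monotone non-decreasing; the
uncorrected variant (`c_i·V`) is exposed and may decrease. Release over
102% sets a warning flag rather than raising. Profile summaries interpolate
the burst at the window edge (default 2 h) and fit the zero-order slope by
OLS over the late window.

### The published release regression

The packaged 20-run table (γ-CD proportion × release time, with its printed
coded levels) does **not** reproduce the published reduced regression
69.95 + 30.66·A + 5.53·A·B (R² = 64.77%): OLS on the table gives
69.00 + 33.76·A + 3.37·A·B with R² = 78.05% for the reduced {A, A·B} model
and 68.91 + 33.84·A − 0.53·B + 3.31·A·B (R² = 78.07%) for the full
{A, B, A·B} model. No standard variant tried (printed vs recomputed codes,
cell means, corner subsets, natural units, log-time coding, quadratic
terms) yields the published coefficients, and the published R² is *lower*
than any fit achievable from the printed rows — so the published equation
cannot derive from this table by ordinary least squares. Relatedly, on this
table the A·B interaction is not significant at 95% (|t| ≈ 0.71), although
the published account treats it as significant. `eq_comparison()` therefore
computes and reports the reduced fit, the full fit and the published
coefficients side by side; the package asserts its own fits against an
independent normal-equations oracle and records the published values for
comparison only. The design is non-orthogonal (unequal replication across
cells), which is also why reduced and full coefficients differ.

## Synthetic data: what passing tests show

The generators emulate *structure*, not thermodynamics: a ring of LJ sites
with an attractive cavity stands in for a cyclodextrin; a hollow gel shell
with waters sealed inside fixes the interior-water count by construction; a
rod with end markers gives unambiguous inclusion labels; factorial tables
are drawn from the stated linear model with Gaussian noise on the exact
replicate layout of the packaged design (2/2/6/6/2/2); release curves join
a saturating burst continuously to a linear phase through the exact burst
value at the window edge. Every generator is seeded, emits machine-readable
ground truth, and re-verifies category assignments by brute-force distance
checks after jitter (up to 100 retries, then an error).

Passing tests on these fixtures demonstrate that the *operations* are
correct — counters return constructed truths, estimators recover known
coefficients, screened minima agree with exhaustive search — and nothing
more: they say nothing about force-field realism, water structure, or the
magnitudes a 100 ns molecular-dynamics simulation would produce (RGYR,
SASA, capture counts of the real hydrogels are out of scope by design).

## Problem sizes

The default test run uses scaled-down study conditions chosen once: 8-9
chain matrices (~50-90 monomers) for builder properties over 20+ seeds,
20,000-pose screens with 100-pose minima against a 10⁶-point grid oracle,
50 seeded single-frame fixtures for the counters, and 200 replicates for
noisy parameter recovery. The full-scale 56 × 35 reference build (392 bridges) runs
once in the acceptance suite in about 2.5 minutes on one CPU; `analysis/`
scripts accept `--full` where the full-scale variant is meaningful.

## Known limitations

* The energy model is a generic pair potential; absolute interaction
  energies are not comparable to quantum-chemical values and are not meant
  to be.
* The cyclodextrin and guest structures are labeled coarse stand-ins; only
  composition, topology and two-endedness are meaningful.
* The packer's lattice stage is near-deterministic in its positions (spin,
  stagger and jitter remain random); at the default density this is the
  price of rigid-chain feasibility.
* Crosslinking can stall below target on sparse configurations; the
  shortfall is a structured error by contract, and the seeded property
  suite treats a verified shortfall as a legitimate outcome.
* No periodic boundary handling anywhere; all geometry is free-space.
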