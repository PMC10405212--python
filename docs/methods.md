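# Methods

vesiflow re-implements, as a tested desk-scale pipeline, the computational
chain behind an all-atom study of a charged glycolipid (lipid-A-like)
vesicle: a minimal hybrid particle-field (hPF) energy/force engine, the
coarse-grained-to-atomistic back-mapping procedure, and the analysis layer
for vesicle morphology, head-group interactions and water permeation.  The
original system — 644 doubly charged lipids (440 outer / 204 inner leaflet),
divalent counterions, ~210k waters, hundreds of ns of all-atom MD — is not
deposited anywhere, so every stage here runs on synthetic vesicles with
exact ground truth.  What passing tests demonstrate is therefore the
*correctness of the estimators and the engine*, not a reproduction of the
original trajectory's observables.

## Units

nm, ns, elementary charge e, kelvin.  Energies are in k_B T (reduced); the
Bjerrum length l_B (default 0.7 nm, water at room temperature) carries the
electrostatic scale.  Diffusion coefficients are quoted in 1e-5 cm^2/s,
which equals nm^2/ns exactly.

## Hybrid particle-field engine (`vesiflow.hpf`)

Particles interact through an external potential that depends on
mesh-interpolated densities rather than through pair forces.  For bead type
K at lattice point l,

    V_K(l) = k_B T [ sum_K' chi_KK' phi_K'(l) + (1/kappa)(sum_K' phi_K'(l) - 1) ],

with phi the number density normalized so the bulk reference is 1 (the
normalization is a declared convention; the reference density defaults to
the system mean and can be fixed explicitly), chi the symmetric
Flory-Huggins-style interaction matrix (k_B T) and kappa the
compressibility.  Density and charge assignment use the cloud-in-cell
(trilinear) kernel, which conserves mass/charge exactly per type.

Forces come in two discretizations, both exposed:

* `mesh` (default for analysis): central-difference gradient of V on the
  lattice, interpolated back with the same CIC weights.  By the antisymmetry
  of the difference operator this conserves total momentum exactly.
* `kernel` (default in the NVE integrator): the exact gradient of the
  discrete energy functional, F_i = -sum_l V(l) grad w_l(r_i).  This makes
  the propagated system Hamiltonian up to the C0 kinks of the trilinear
  weights, and gives the observed energy drift of ~0.2-0.5% of the mean
  kinetic energy over 1e4 leapfrog steps at dt = 1e-3 (reduced units),
  decreasing when dt is halved.

### Lattice electrostatics

The Coulomb potential is split Ewald-style with parameter alpha (default:
Gaussian screening width of two lattice spacings, i.e. alpha = 1/(2 h)).
The long-range part solves Poisson's equation in reciprocal space for the
Gaussian-filtered mesh charge density via forward/inverse FFT,
psi_hat = 4 pi l_B exp(-k^2/4 alpha^2) Q_hat / k^2, with the k=0 mode zeroed
(tinfoil boundary; non-neutral input is equivalent to a uniform background
and warns).  The short-range complement is the pairwise erfc sum over
minimum-image neighbors.

Energies are evaluated in k-space from the window-deconvolved structure
factor.  A CIC-assigned point charge interacts spuriously with its own mesh
images; this artifact is removed analytically per particle (the
single-particle window power spectrum is separable over axes and depends
only on the fractional cell offset), after which the standard continuum
Gaussian self-energy is subtracted.  With a 32^3 mesh on a 10 nm box this
puts the +/- pair energy within ~0.4% of an independent, well-converged
pairwise Ewald reference (`vesiflow.reference`) and keeps the total
alpha-invariant to ~0.3% over a 2x alpha range.

The mean-field short-range electrostatic option follows the lattice
Flory-Huggins route: chi_e = z [u_qn - (u_qq + u_nn)/2] with z = 6 for the
3D cubic lattice and the contact Coulomb energy l_B q^2 / sigma as the
default charge-charge site energy.  The exact pairwise prefactors are model
input (the source text for them is incomplete), so the whole combination
rule sits behind a swappable formula hook, and the resulting density-field
potential psi_short = chi_e sigma^3 (G_sigma * Q) is a declared, documented
form: local, symmetric, monotonically decaying from isolated charges.

## Back-mapping (`vesiflow.backmap`)

Atomistic molecules are rebuilt from CG configurations by library search
plus rigid superposition.  Each bead's back-mapping site is the centroid of
its member heavy atoms (~4 per bead).  For every trial conformer the
optimal proper rotation/translation is found by the Kabsch algorithm (SVD
of the cross-covariance; mirror solutions rejected by a determinant flip),
and the trial is accepted when the maximum per-site distance after the fit
is below the tolerance (default 0.2 nm).  "Maximum per-site deviation" is
our reading of the acceptance statistic; a whole-molecule RMSD criterion is
available behind a flag.  The search order is sequential first-pass by
default with an exhaustive best-of-all mode, since the original procedure
does not state which was used.  Degenerate (collinear) site sets are
rejected with a named error; the synthetic conformer template is a gentle
helix so its sites are never collinear.  CG water and ion beads are not
back-mapped geometrically — solvent is re-inserted by the builder, matching
the original workflow's re-solvation with printed counts.

## Synthetic vesicles (`vesiflow.synthetic`)

The generator is the source of ground truth for every analysis stage, with
the study composition as its defaults: 440/204 lipids at -2 e on the head
bead, +2 e counterions split per leaflet (204 cavity / 440 exterior —
automatically, since one divalent ion neutralizes one lipid), waters in the
cavity and bulk (full-scale counts 5707 / 204592; the desk-scale fixtures
use 57 / 2046, a 100x reduction).  Lipids sit on deterministic Fibonacci
lattices (no rejection sampling; a packing error triggers when the
requested count would fall below the minimum spacing).  A lipid is a
simplified template — one charged head bead and a linear tail of chain
sites — sufficient to exercise every estimator; lipid-A chemistry is not
reproduced.

Trajectories superpose: region-wise Brownian solvent (cavity/bulk D
defaulting to the study's 2.4 / 3.5 1e-5 cm^2/s magnitudes) with reflective
region boundaries; scripted crossing events as piecewise-linear radial
paths with small lateral jitter (default 0.05 nm, small against the
membrane thickness) occupying the membrane for exactly [entry, exit)
frames; breathing or volume-preserving ellipsoidal deformation; and a
chain tilt at fixed polar angle with random azimuth realizing a prescribed
S_CD through P2(cos tilt) = -2 S_CD (attainable range [-0.5, 0.25]).  Bulk
waters are additionally mirrored at the box walls so wrapped and unwrapped
geometry coincide and no spurious periodic-image membrane entries occur.
What the generator does *not* emulate: lipid-solvent coupling, realistic
membrane fluctuation spectra, equilibrium thermodynamics of any kind.

Free (unconfined) Brownian fixtures are provided separately for diffusion
calibration, because region-confined solvent saturates its MSD at the
region size.

## Morphology (`vesiflow.morphology`)

The external surface-fitting tool used by the original analysis publishes
no estimator formulas, so each observable is a declared estimator isolated
behind a named function:

* Surface fit: the leaflet head-group radii are kernel-averaged
  (great-circle Gaussian, width adapting to grid and point spacing) onto a
  theta/phi grid; normals come from the analytic gradient of r(theta,phi);
  polar quadrature uses cell-exact integrals of sin(theta), so a perfect
  sphere gives area, volume, curvature order parameter and roundness
  exactly (to machine precision) at any resolution.  Coverage gaps beyond
  ~3 kernel widths raise.
* Curvature order parameter: area-weighted <P2(cos angle(normal, radial))>;
  1 for a sphere, -0.5 for tangential normals.
* A_L: leaflet area / lipid count.  D_HH: per-node radial gap between the
  two head-group surfaces (radial rather than along local normals — the
  original does not state which), solid-angle weighted.
* S_CD: with united-atom chains the C-H order parameter is computed via the
  axial-symmetry identity S_CD = -1/2 P2(cos theta_axis), theta_axis
  between the local chain axis (C_{n-1} -> C_{n+1}) and the surface normal
  at the lipid's angular position (planar fallback: z).  All-trans along
  the normal gives exactly -0.5; values are bounded in [-0.5, 0.25].
* Roundness: sphericity psi = pi^(1/3) (6V)^(2/3) / A.
* Windowed statistics: non-overlapping left-aligned windows (default 25 ns)
  reporting min/max/mean; a trailing partial window is flagged.

Leaflet assignment is radial (head inside/outside the two-shell midsurface,
cross-checked against head-to-tail orientation; the radial indicator wins
conflicts at reduced confidence), with a planar z-side fallback for flat
bilayers.

## Interactions (`vesiflow.interactions`)

RDFs use periodic KD-tree pair counting normalized by ideal-gas shell
counts; CN = 4 pi rho int g r^2 dr with the integration interval closed
exactly at the cutoff, which is either explicit or the first minimum of the
Savitzky-Golay-smoothed g(r) after a peak above 1.2 (the printed CN table
gives no cutoffs, so auto-detection is a declared stand-in).  Hydrogen
bonds follow the geometric criterion D...A <= 0.35 nm and X-D...A <= 30
degrees with X the atom bonded to the donor (here the hydrogen); an
alternative linearity-at-H convention sits behind a flag since tools
differ.  Water region labels (cavity/membrane/bulk) come from the fitted
surfaces, with a fixed-radius fallback for rigid fixtures.

## Permeation (`vesiflow.permeation`)

Crossing detection is a pure function of the per-frame region labels: an
event opens on entry into the membrane and closes at the next non-membrane
label; bulk->cavity is inward, cavity->bulk outward, same-side returns are
reflected (tracked separately because fast reversible penetration is a
distinct regime); events open at either trajectory boundary are censored —
reported but excluded from residence statistics.  Residence classes use the
two observed regimes: fast < 1 ns, confined > 270 ns.  Crossing histograms
bin entry times into 10 ns bars.  Diffusion uses the Einstein relation on
FFT-computed MSDs with a lag-window fit (default 10-50% of the span,
config-exposed; the calibration analyses use 2-30%, where every lag
averages many origins) weighted by 1/lag to de-emphasize the poorly
averaged long lags; block averaging over molecules gives the uncertainty;
wrapped input (jumps > box/2) is rejected.

## Problem sizes and numerical choices

Desk-scale defaults keep the full test suite under ~1 minute and the
acceptance script under ~1 minute on one CPU: 50/24-lipid vesicles, 32^3
electrostatic meshes, 1e4-step NVE and Brownian runs, 400-molecule
diffusion fixtures, 5000-conformer libraries only where the library size
itself is checked.  Tolerances asserted in tests reflect measured
convergence headroom, not tuned limits: pair-energy 1%, alpha-invariance
0.5%, NVE drift 1% of mean KE, surface analytics 1-2%, D recovery 5%.

## Known limitations

* The chi parameter tables of the original CG lipid model live in
  supporting material that is not reproduced; the engine takes chi as
  input and ships only toy matrices.
* The hPF NVE integrator is a validation tool, not a production MD engine:
  no thermostats, no pressure coupling, no bonded terms.
* Synthetic trajectories are kinematic constructions; their "observables"
  are inputs, which is precisely what makes them usable as ground truth.
* The roundness/curvature estimators are consistent with the external
  tool's published purpose but not asserted to be numerically identical to
  it.
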