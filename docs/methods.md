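# Methods

This note documents the models, numerical choices and known limitations of
`condensax`. Units are Angstrom (A) for lengths, 1/A for momentum transfer q,
and arbitrary units for intensities; a single global scale factor absorbs the
electron-density contrast.

## Scattering model

**Gaussian blobs.** The coarse mass distribution inside a droplet is
represented by N Gaussian blobs of common width sigma (default 40 A) inside a
bounding sphere (default diameter 10,000 A). Both the real-space density and
its Fourier transform are Gaussians, so the form amplitude is
`f(q) = exp(-q^2 sigma^2 / 2)`, normalised to 1 at q = 0. Blobs carry unit
weight; only the window function modulates them.

**Window function.** To suppress the form factor of the bounding sphere
itself, every copy's amplitude is multiplied by a Gaussian window
`w(r) = exp(-|r - r_cm|^2 / (2 sigma_w^2))` centred on the centre of mass of
the model (sigma_w = 3000 A for the blob stage, 1500 A for the spherocylinder
stage). The window sets the q resolution of a fit to `2 pi / sigma_w`; the
fitter refuses windows that start below this limit, with 5% slack so the
conventional rounded value 0.002 1/A is admitted for sigma_w = 3000 A
(2 pi / 3000 = 0.00209).

During a greedy fit the window centre is frozen at the centre of mass of the
initial configuration: the per-move incremental amplitude update is exact
only for a fixed window, and single-particle moves shift the centre of mass
by O(step/N). The standalone `ensemble_intensity` recomputes the
instantaneous centre of mass on every call.

**Spherocylinders.** One protein dimer is approximated by 1-3 linked capped
cylinders of radius 12 A (model 1: 300 A; model 2: 155 + 135 A; model 3:
155 + 76 + 50 A). The amplitude of a segment is computed by decomposing it
into thin disks perpendicular to the axis: each disk of radius r contributes
its exact transverse factor `2 J1(q_perp r) / (q_perp r)` and an axial phase;
the uniform core is summed in closed form (a geometric series of slice
phases) and the caps by explicit slices. This decomposition converges to the
exact volume integral as the spacing shrinks; the default spacing R/2 keeps
the amplitude within ~0.1% over the fit window (q <= 0.03 1/A) and a finer
spacing (R/8) reaches ~1% out to qR = 3, verified against a three-dimensional
indicator-grid integration in the tests. A Gaussian-bead decomposition was
considered and rejected: a Gaussian cross-section deviates from the disk
factor by >40% at qR = 3.

Chains are linked cap-to-cap ("rolling" the cap of the new segment on the
previous one); the coherent chain amplitude is the sum of segment amplitudes
minus one sphere amplitude per joint, so the two overlapping joint
hemispheres are counted once. A fully stretched chain (bend angle 180 deg)
is then exactly equivalent to a single spherocylinder of the summed length,
which the tests assert. Bend angles use the convention 180 deg = stretched
out, 0 deg = folded back.

**Orientation averaging.** Measured droplet curves average over very many
droplets, so the model intensity is averaged over M random directions of the
momentum-transfer vector (default M = 300). The direction set is drawn once
per fit from the fit seed and reused for every chi^2 evaluation: greedy
acceptance needs a deterministic objective, and re-sampling would inject
noise into accept/reject decisions. The exact orientation average (the Debye
sum over point scatterers) serves as the independent oracle; the
Monte-Carlo average converges to it with RMS error ~ 1/sqrt(M).

## Reverse-Monte-Carlo fitting

The objective is `chi^2 = sum_i [(c I_mod(q_i) - I_exp(q_i)) / sigma_i]^2`
with the scale c minimised in closed form per evaluation and unit weights
when no uncertainties are present. Moves are:

* blob stage: random single-blob translations (Gaussian step, default 50 A);
* spherocylinder stage: whole-chain translations, whole-chain rotations
  about the reference point, and (for segmented models) rigid pivots of the
  sub-chain on one side of a joint (Gaussian angle, default 0.3 rad).

A move is accepted only if chi^2 strictly decreases, the chain reference
point stays inside the container and, when clash checking is on, no new
core-core overlap closer than R_a + R_b appears. Consecutive segments of one
chain share a joint cap by construction and are exempt; non-consecutive
segments (folded model 3) are checked. Acceptance is strictly greedy; an
optional Metropolis temperature exists but is off by default. The move
budget is fixed (`max_moves`) with an optional stall criterion; the original
stopping rule of this class of fits is not standardised, and a fixed budget
keeps runs deterministic. Amplitudes are maintained incrementally (one
complex array over directions x q), so a move costs O(M Nq) regardless of
ensemble size; clash queries use a uniform cell list over chain reference
points.

**Staged refinement.** Copies of model 1 are seeded from the blob fit:
reference points are sampled from the window-weighted Gaussian mixture of
the fitted blobs (the jitter widens progressively when a saturated region
rejects placements, so dense regions overflow into their surroundings rather
than stalling), orientations are uniform, and placements are retried until
clash-free. Model 2 is initialised by superimposing its 155 A segment on one
end of each model-1 rod and appending the second segment clash-free at a
random orientation; model 3 grows from model 2 analogously. When no random
orientation is admissible the stretched-out configuration is used - it
occupies a subset of the parent's own clash-free footprint - and, for deeply
folded parents, all appended segments are redrawn at random as a last
resort. Refinement then relaxes these initialisations.

## Structure metrics

* **g(r)**: pair counts per shell divided by the mean counts of (default 10)
  uniform placements of the same number of points in the same container.
  This Monte-Carlo normalisation handles the finite spherical volume without
  analytic shell-intersection formulas. Chain centres are volume-weighted
  centroids. The bin width is a free parameter (default 25-50 A in the CLI).
* **Nematic order**: in cubic boxes (default 400 A, grid centred on the
  container) holding at least 30 particles, `S = (3/2) e_max` of
  `T = <u u^T> - I/3`. S is invariant under global rotations and
  per-particle sign flips; boxes below the cutoff are omitted because the
  eigenvalue estimate is badly biased at small counts (isotropic axes give
  S ~ sqrt(5/N)). Edge-truncated boxes are retained if they meet the count.
  For segmented chains the per-segment axes are used by default.
* **Fractal dimension**: minus the slope of log I vs log q over a window
  (default 0.002-0.02 1/A). When the single-particle form amplitude is
  known (e.g. the blob width used to render a synthetic structure) it is
  divided out first, so the regression runs on the structure factor S(q);
  a mass fractal has S(q) ~ q^-d. Without this division the Gaussian blob
  factor exp(-q^2 sigma^2) steepens the apparent slope by ~0.2 over the
  default window at sigma = 40 A.
* **Guinier radius**: slope of ln I vs q^2 over the points with
  q Rg <= 1.3 (found by fixed-point iteration). For strongly elongated
  particles the Guinier regime ends earlier; the tests use q Rg <= 1.0 for
  the rod models, where the estimate is within 3% of the direct mass
  integral.

## Synthetic data

The generators are pure functions of their parameters and a seed.

* **Fractal structure**: a 3-D random walk with fixed step length (default
  200 A, comparable to the rod length and the nearest-neighbour distance of
  the fitted structures). An ideal chain has mass-fractal dimension exactly
  2, matching the measured q^-2 decay; confinement to a container redraws
  steps that would exit. Aggregation-type generators (DLA etc.) would give
  other dimensions and are out of scope.
* **Droplet profile**: windowed, orientation-averaged intensity of Gaussian
  blobs on the structure, with multiplicative Gaussian noise (default 2%
  relative - typical of well-exposed reduced SAXS curves) and uncertainties
  set to the noise level.
* **Dilute form factor**: exact Debye sum over a Gaussian-bead rendering of
  a stretched chain (bead sigma = r/2 matches the transverse second moment;
  the approximation error is O((qR)^4), negligible for q <= 0.05 1/A).
* **Crosslink tables**: link populations with per-condition detection
  probabilities, score distributions, and programmed abundances over four
  conditions (dilute, phase-separated, supernatant, pellet) x 3 replicates.
  The default population includes pellet-only crosslinks, coiled-coil
  selflinks enriched on condensation, monolinks depleted there,
  sub-threshold decoys and sporadic single-replicate species. Targeted
  transition areas carry 5% lognormal noise (typical of parallel-reaction-
  monitoring quantification), split over 5 heavy + 5 light transitions,
  with a householder (non-crosslinked reference) peptide per replicate.

What the generators do *not* emulate: instrument smearing, buffer-subtraction
artefacts, inter-droplet scattering, polydispersity, peptide-level
identification errors, retention-time drift, or missing transitions. Passing
tests therefore demonstrate the correctness of the algorithms under the
stated statistical assumptions, not performance on raw beamline or
mass-spectrometer output.

## XL-MS analysis rules

DSS identifications are kept when ld.Score > 20 (strict) in the observation
itself and the same unique peptide passes in >= 2 of 3 replicates of the
condition (the stricter of the two possible readings: every contributing
observation must pass the score threshold). PDH identifications require
ld.Score > 25, deltaS > 0.9 and FDR < 0.05 conjunctively, with no replicate
requirement. Peptide uniqueness is the order-normalised residue pair plus
link type plus reagent. Abundance is the sum of 10 transition areas divided
by the householder area per replicate; a peptide missing in a replicate is
excluded from that condition's mean rather than imputed. Differential
analysis uses log2(mean_A/mean_B) with a two-sided pooled-variance Student
t-test (Welch optional); identical groups report p = 1. Enrichment flags
log2FC > 1 strictly. No multiple-testing correction is applied by default
(Benjamini-Hochberg is available behind a flag). The zerolink category is
carried through classification but not quantified.

Domain intervals on the 440-residue reference sequence: CAP-Gly 1-80, L1
81-188, coiled coil 189-389 (segments A 189-297, B 302-357, C 363-389),
C-terminal 390-440 (L2 390-419, zinc finger 420-431, tail 432-440).

## Problem sizes and benchmarks

The production-scale fits of droplet data use 4,000 blobs and
50,000-100,000 model copies. The package's self-contained benchmarks run at
desk scale: fractal-dimension recovery uses 2,000-blob random walks (5
seeds), and the droplet benchmark fits 5,000 model-1 copies in a 6,000 A
container (500 blobs, 5,000 blob moves, 4,000 refinement moves, 96
orientation directions, 3 seeds). At 5,000 copies the mean box occupancy is
~10x lower than at 50,000, so only the densest protein-rich boxes reach the
30-particle cutoff of the nematic analysis; the maximum S over qualifying
boxes remains well below 0.4, and the box-occupancy variance exceeds the
uniform-placement null by a large margin, reproducing the isotropy and
heterogeneity conclusions at reduced scale.

## Known limitations

* The spherocylinder form factor drops faster than a real protein's at
  q > 0.15 1/A; conclusions below ~50 A length scales are outside the
  model's validity, as for any rigid homogeneous-density approximation.
* The greedy fit finds *a* structure consistent with the data, not a unique
  one; different seeds give statistically equivalent but distinct
  configurations.
* Structure-file output in PDB format writes coordinates in nanometres
  (fixed PDB columns cannot hold 10^4 A); the CSV XYZ table is the lossless
  interchange format.
* `chi2_trace` records the objective at the initial state and after each
  accepted move; rejected proposals are counted but not traced.
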