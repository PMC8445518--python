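# Methods

## Timing model

A coincidence timing category is a zero-mean two-component Gaussian
mixture over the measured time difference Δt (ps):

    p(Δt) = α N(Δt; 0, σ_F) + (1 − α) N(Δt; 0, σ_S),   FWHM = 2√(2 ln 2) σ.

The packaged bank holds 25 categories (fast FWHM 179.8–263.8 ps, slow
FWHM 660.3–897.3 ps, abundance 0.385–0.594), the pairings of five
rise-time classes per detector of a BGO–Cherenkov detector pair. The
"abundance ratio" column is interpreted as the **mixing weight of the
fast component** — the probability that a coincidence of that category
drew its spread from the narrow Gaussian — which is how the value
enters both the simulator's component selection and the reconstruction
weight. Values near 0.5 and the role the parameter plays in the TOF
weight formula support this reading over a literal fast:slow quotient.

Both components are centered. Physically the fast and slow populations
have slightly different trigger delays; the study deliberately removes
that shift (it would otherwise need a time-walk correction), so no mean
offset is modeled anywhere.

### Fitting

`fit_two_gaussian_mixture` is plain EM with both means pinned to zero,
so the free parameters are (σ_F, σ_S, α). Initialization is a
moment split: σ ∈ {0.5, 2} × sample SD, α = 0.5. Iteration stops when
the total log-likelihood improves by less than 1e-8 per event, or at
500 iterations; the log-likelihood is nondecreasing by construction and
the component with the smaller fitted sigma is reported as "fast". If a
component's responsibility mass vanishes the fit collapses to a single
Gaussian (degenerate but valid). All-equal samples are rejected.

At 10⁶ draws per category, sample-and-refit recovers every component
sigma to within ~2 ps and the abundance to within ~0.003 — this is the
fidelity level quoted for the simulation chain, and the package's
acceptance checks re-measure it.

## Scanner and simulation

The scanner is an idealized cylinder: `n_crystals_per_ring` crystals
uniformly spaced in azimuth (no blocks or gaps), `n_rings` rings of
pitch equal to the crystal size, radius measured to the crystal front
face. Detection assigns a photon to the crystal whose angular/axial bin
contains the ray's intersection with that front-face cylinder; there is
no depth-of-interaction or penetration model, because the timing
kernels already embody the detector physics. Two geometries are
pre-built: the desk default (1 ring × 360 crystals of 4 mm pitch, radius
424 mm — the circumference equivalent of the full-scale ring) and the
full-scale 666 × 48 layout, which is reachable through configuration
but not used by the tests.

The simulator is statistical, not photon transport:

1. decay count ~ Poisson(total activity × duration); decay positions
   sampled per voxel activity, uniform within the voxel;
2. an isotropic back-to-back photon pair is traced to the detector
   cylinder; the coincidence is kept iff both photons land within the
   axial extent and the crystal pair passes the minimum sector
   difference (the full-scale rule of 83 sectors of 666 is scaled to
   the configured ring: 45 of 360 by default);
3. optional attenuation: the pair survives with probability
   exp(−∫μ dl) along the whole LOR (exact for collinear true pairs);
   off by default;
4. the timing spread is added **once per pair** to the geometric time
   difference — equivalent in distribution to spreading both singles —
   and the applied kernel id and fast/slow component are stored in the
   event record.

Only true coincidences exist. No scatter, randoms, energy model, dead
time, pile-up, positron range, acollinearity, or multiple coincidences:
the reconstruction study this toolkit supports uses trues only, and the
timing kernels are the object under study.

Sign convention (also written into every list-mode header):
`delta_t_ps = t_a − t_b` with detector a < b by flattened index; a
positive Δt displaces the annihilation toward crystal b by c·Δt/2.

For thin-ring geometries almost all isotropic directions miss the ring
axially. `simulate_acquisition` therefore draws the direction
z-cosines only inside a conservative geometric band outside of which no
photon can reach the axial extent, and accounts for the out-of-band
decays by exact binomial thinning. This is importance sampling with a
provably zero-acceptance complement — it changes run time (~60×), not
the sampled distribution; the API-level `sample_emissions` /
`emit_and_detect` keep the naive semantics and the tests compare the
two.

## Reconstruction

List-mode MLEM, one full pass per iteration (no subsets — robust,
guaranteed-monotone convergence is worth more here than speed), no
post-filtering. The system element for event i and voxel j factors as
`p_ij · K_ij`:

- `p_ij` — intersection length of the LOR with voxel j, by incremental
  Siddon traversal;
- `K_ij` — the event kernel's CDF mass on the TOF bin containing the
  measured Δt, centered on the voxel's projection v′ onto the LOR time
  axis. TOF bins are 1 ps wide by default, so one CDF difference per
  (event, voxel) suffices.

Because Σ_t K = 1 (telescoping CDF differences), the sensitivity image
is TOF-free: s_j = Σ over admissible crystal pairs of a_ij p_ij, with
a_ij the attenuation survival factor when attenuation is on. A
per-event attenuation factor would cancel inside the MLEM ratio, so
attenuation enters the update only through s_j. The initial image is 1
on the sensitivity support and 0 outside; voxels with s_j = 0 stay 0.

Numerical choices:

- TOF weights are truncated for voxels farther than 6 slow-component
  sigmas from the measured Δt (discarded mass < 2e-9 — visible only
  below the monotonicity tolerances used in the tests);
- events whose forward projection is zero are skipped and counted;
- after every update Σ_j λ_j s_j equals the used-event count to < 1e-6
  relative, and the list-mode Poisson log-likelihood is nondecreasing —
  both are asserted per iteration in the tests, for all five weighting
  modes;
- Siddon tie-breaking on rays that run exactly along voxel boundary
  planes (e.g. the horizontal LOR of an even grid) is one-sided; the
  sensitivity image is exactly mirror-symmetric except on those
  gridline rows. Related: with length-weighted LOR sums the sensitivity
  of this 2D ring peaks near the FOV edge, not at the center (the
  center is within ~80% of the maximum).

Calibration scales the image so the mean over a background mask equals
the known background concentration; the study applies the final
iteration's scale factor to all of that run's snapshots (CRC/BV/CNR are
scale-invariant; only the bias analysis needs absolute units).

## Phantom, ROIs, metrics

The NEMA-IQ layout: six spheres (inner diameters 10, 13, 17, 22, 28,
37 mm) on a 114.4-mm pitch circle in the central transaxial plane of a
warm cylindrical body; the four smallest hot at 4:1 against an
11.38 kBq/cc background, the two largest water-filled and cold; every
sphere surrounded by a cold 1-mm wall (a chosen value — only inner
diameters are standardized); everything attenuates like water at
511 keV (0.0096 /mm). The body is a cylinder of radius 110 mm so the
layout fits the desk grid; `scale` shrinks sphere diameters *and* the
pitch circle together (walls stay 1 mm), and construction fails if
spheres would touch. Voxel membership is by center-point test
everywhere (rasterization and ROIs share the convention). No lung
insert, no bed.

Per sphere: a circular ROI of the sphere's inner diameter on the
central slice, a half-diameter ROI for the bias analysis, and 60
equally sized background ROIs. The standard spreads the 60 over five
slices; on a single-slice grid all 60 sit on the central slice at 12
angular positions × 5 concentric rings, placed deterministically from
the analytic layout (never estimated from the image), each ≥ 15 mm
from the phantom edge and clear of every sphere + wall. Same-size
background ROIs may therefore overlap one another, which correlates
the background samples and makes the desk-scale BV an optimistic noise
surrogate — fine for model *comparisons*, not for absolute NEMA
numbers.

Metrics: hot CRC = 100 (μ_H/μ_B − 1)/(ratio − 1); cold
CRC = 100 (1 − μ_C/μ_B); BV = 100 · SD(background ROI means)/mean
(N−1 denominator); CNR = (μ_H − μ_B)/√(σ_H² + σ_B²) with σ_B the
average within-ROI SD over the background ROIs. Bias uses the
half-diameter ROIs across noise realizations against the expected
concentration; it is reported as a percentage for hot spheres and as an
absolute offset for cold spheres (whose expected value is zero). CNR
on a noiseless image is reported as NaN rather than infinity.

## Study design and problem sizes

The study matrix pairs simulation timing models with reconstruction
kernels (mch, ch-mix, ch-dcmp, gauss, notof, mch-low; see the module
docstring of `tofmix.experiments`). ch-mix and ch-dcmp reconstruct the
same dataset, so their only difference is the weight function. The
mch-low subset is count-matched to the single-Gaussian dataset by
seeded uniform thinning. The BGO detector's higher stopping power is
emulated purely as a 1.52× acquisition-duration factor for the
mixture datasets — a count ratio, not a physics model.

Desk-scale defaults, chosen so a full study runs in minutes on one
core: one ring of 360 crystals, 128 × 128 × 1 grid of 2 × 2 × 4 mm³
voxels, 20-s acquisitions (a few 10⁵ trues per realization), five noise
realizations, 40 MLEM iterations with markers at 1–5, 10, 20, 40. The
kernel-fidelity validation uses 10⁶ draws per category. The acceptance
tests run a trimmed version (10-s acquisitions, three realizations) of
the directional comparisons.

## What the generator does and does not emulate

Passing tests show that the *mixture-kernel machinery* behaves
correctly — weights normalize, MLEM is monotone and count-conserving,
decomposed reconstruction consumes exactly the stored components, the
qualitative orderings (single-kernel models converge faster; more
counts beat narrower kernels on CNR) emerge at desk scale. They do not
validate photon physics (no scatter/randoms/energy model), absolute
full-scale quantities (coincidence counts, printed CNR percentages,
3D axial effects), or detector-material differences beyond the count
ratio. The full-scale geometry and grid are configurable for anyone
wanting to spend the compute.

## Known limitations

- 2D single-ring mode is the tested scale; 3D multi-ring paths share
  the same code but only smoke-level coverage.
- The sensitivity pair loop is exhaustive; for the full 666 × 48
  geometry it is the dominant cost and would need symmetry folding.
- EM fitting assumes exactly two zero-mean components; it will not
  flag model misfit (e.g. heavy tails) beyond a poor likelihood.
- Background ROI overlap (single-slice collapse) biases BV low at desk
  scale, as noted above.
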