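# Methods

This note documents the models behind `radiocell`: what each stage
assumes, which parameters matter, the accuracy that can be expected, and
the design choices made where the problem was genuinely open.

## Nuclear data

Half-lives, mean emission energies, yields, beta endpoints and branching
fractions are embedded as versioned constants taken from a standard
evaluated compilation (ICRP-107-like values).  The two supported parents
are Lu-177 (T½ = 6.647 d, pure beta/gamma, decaying to stable Hf-177)
and Ac-225 (T½ = 9.92 d), whose cascade

    Ac-225 → Fr-221 (4.8 min) → At-217 (32 ms) → Bi-213 (45.6 min)
           → 97.8% Po-213 (4.2 µs) | 2.2% Tl-209 (2.16 min)
           → Pb-209 (3.28 h) → Bi-209

carries exactly four alpha transitions per parent decay when weighted
over branches, totalling ≈ 27.5 MeV of alpha energy.  Beta branches are
represented by (endpoint, mean, yield) groups; when transport needs the
full energy distribution, energies are sampled from the allowed spectrum
shape with a non-relativistic Fermi (Coulomb) factor for the daughter's
atomic number, which reproduces tabulated mean beta energies to within a
few percent.  Conversion and Auger electrons are lumped into a small
number of monoenergetic lines; their exact partition is unimportant at
cellular scale but their summed energy matters for the medium dose
(Lu-177 total electron energy per decay ≈ 0.148 MeV).

Activities follow the closed-form Bateman solution, extended to branched
chains by summing classic linear-chain terms over all decay paths.  The
solution is validated against a stiff (Radau) ODE integration of the
full rate matrix to a relative tolerance of 1e-6 — a non-trivial check
because the cascade spans twelve orders of magnitude in half-life.
Daughters are assumed to decay where the parent decays (no recoil
relocation, no daughter diffusion); all chain members are treated at
transient equilibrium with the parent, which the Fr-221 ingrowth time
justifies (98% of equilibrium ≈ 27 min, comfortably inside the 30-min
waiting rule applied before any measurement).

## Cell geometry

Two geometric phases mirror the clonogenic protocol:

* **floating** (3 h incubation in suspension): concentric spheres —
  nucleus radius `R_N`, cell radius `R_C`, and a 7.5-nm membrane shell
  on the cell surface where the membrane-bound ligand sits;
* **attached** (7 d colony growth): concentric ellipsoids — nuclear
  semi-axes (a, b, c) with the maximum thickness h = 2c restricted to
  3, 4 or 5 µm by size class, and a cytoplasm ellipsoid that preserves
  the nuclear a/b ratio and reproduces the floating cell volume.

The default dimensions are assumptions, not measurements: floating
`R_C` ∈ {7, 8.7, 10} µm and `R_N` ∈ {3, 4, 5} µm for the
minimum/average/maximum classes.  The average cell radius is chosen so
that 100,000 cells in 1 mL occupy 0.027% of the volume, the occupancy
used by the cross-dose lattice; nuclear in-plane semi-axes follow from
the equivalent-sphere relation a²c = R_N³ with a = b.  The default
attached cell is a flat pancake: the cytoplasm extends 0.5 µm above the
nuclear pole and the in-plane semi-axes are scaled up to conserve
volume, which is what spread adherent cells look like and what makes
the membrane-source dose exceed the cytoplasm-source dose in that
phase.  Every dimension is overridable through the geometry API.

Cell radii can also be estimated from brightfield images: a Canny edge
map feeds a circular Hough transform over a configured radius search
range; accumulator peaks are kept above a relative threshold with
non-maximum suppression at 1.2× radius separation.  On synthetic fields
of 100 non-overlapping cells the detector recovers every cell with a
radius error below one pixel.  Pixel size is an explicit parameter —
no image metadata is parsed.

## S-value engine

The engine estimates `S(nucleus ← source)` in Gy/(Bq·s) at chain
equilibrium by Monte Carlo:

* **Alpha particles** travel along straight chords and deposit energy by
  residual-range differencing on an embedded water stopping-power table
  (continuous slowing down; no straggling, no delta rays).  Straight
  chords are accurate for alphas at cellular distances; the table
  reproduces accepted ranges to ~10% (≈ 46 µm at 5.79 MeV, ≈ 81 µm at
  8.38 MeV).
* **Electrons** at self-dose distances use the same chord scheme with a
  detour correction: multiple scattering makes the true track longer
  than the net displacement, so penetration is `0.7 × CSDA range` and
  the energy-loss rate per unit displacement is `S/0.7`.  This keeps the
  model energy-conserving while concentrating deposition the way
  measured kernels do.  At cross-dose distances (tens to hundreds of
  µm) the chord picture fails, and a scaled point kernel is used
  instead: `e(r) = E·F(r/r0)/(4πr²r0)` with r0 the CSDA range and F a
  normalized shape with a broad maximum near r/r0 ≈ 0.4, matching
  published water kernels.
* **Photons** are excluded throughout: they overwhelmingly escape the
  1-mL medium and contribute negligibly to the nucleus at cellular
  scale.

Variance reduction: emission directions are importance-sampled inside
the cone subtending the nucleus (weighted by solid-angle fraction), so
every history can score.  The MC error is estimated from 20 batch means;
runs are bit-reproducible for a fixed seed.  Default histories are 10⁶
per line for the electron-dominated nuclide and 10⁵ for the alpha
cascade.

The **medium S value** is analytic: all charged-particle energy emitted
by activity homogeneously mixed through 1 mL is absorbed locally, so
S = E_charged/m.  This reproduces the full-transport references
(2.30e-11 and 4.57e-9 Gy/(Bq·s)) within 4%.

The **cross-dose S value** places N cells (16 at the default occupancy)
uniformly in a 500-µm cube with non-overlap, gives every cell 1 Bq, and
scores the dose rate to each cell's nucleus from all the others,
averaging over cells and placements — the quantity a multicellular
cluster code reports.  Averaging over *all* cells (not just a central
one) matters: edge cells see fewer neighbours, and the cell-averaged
value is what matches the published magnitude.  The engine lands within
~20% of the full-transport 1.13e-6 Gy/(Bq·s) for Lu-177; the Ac-225
cross dose comes out below 1% of its self dose, justifying its neglect
in dose accumulation.

Accuracy bands: a 1-D quadrature oracle (surface alpha source on a
large sphere) confirms the chord machinery to ~1%.  Against the bundled
full-transport self S values the engine agrees within roughly ±30% for
the floating geometry and within a factor ~2.5 for the attached one.
Two effects dominate the spread: the detour-corrected chord model is a
deliberate simplification of electron transport, and the true cell
dimensions behind the reference values are not published — the defaults
above are assumptions.  Dose accumulation therefore accepts an external
S-value table, and the bundled reference table is the default for
absolute dose work.

## Kinetics and dose accumulation

Bound activity per cell is `added activity × uptake/100 / 10⁵` with the
uptake expressed in %AA/100,000 cells — by construction independent of
the actual cell number.  The dosimetry default (1.865%) is the mean of
the 1-h and 3-h uptake plateau; both radioligands share it, their
uptake being experimentally indistinguishable.  Bound activity splits
membrane : internal = 0.76 (membrane fraction 0.432).

Clearance is a mono-exponential to a plateau,
`r(t) = p + (1-p)·exp(-ln2·t/T_bio)`, fitted by bounded least squares;
defaults p = 0.41, T_bio = 2.3 h.  The plateau is extrapolated
unchanged across the full 7-day window, beyond the last measured point
at 120 h — the operative assumption of the cumulated-dose calculation.
Time-integrated activity has the closed form
`A0·[p/λp·(1-e^{-λp·T}) + (1-p)/(λp+λb)·(1-e^{-(λp+λb)·T})]`,
validated against adaptive quadrature to 1e-8.

Per phase, dose = TIA × S with the appropriate geometry: incubation
uses floating S values, constant bound activity (instant uptake, no
clearance while the radioactive medium is present) and adds the medium
term (100% of added activity, 1 mL) plus, for the beta emitter only,
the lattice cross term; colony growth uses attached S values with
clearance applied, and no medium or cross terms.  The geometry switch
is instantaneous at the end of incubation.  Everything is exactly
linear in concentration and in uptake, which fixes the structure of the
dose table: concentration ratios propagate exactly (0.5/0.1 → 5.000)
and size-class columns are proportional.

Absolute dose normalization is a known soft spot: with the reference
S values and the kinetics above, the 7-day average-size doses come out
~30% below the published table (2.07 vs 2.96 Gy at 0.4 MBq/mL for the
beta emitter; 1.06 vs 0.83 Gy at 0.37 kBq/mL for the alpha emitter —
within a factor 1.5 both ways).  The published normalization of uptake
to cell number in the treatment tubes is under-specified, so the
pipeline treats absolute parity as a plausibility check and asserts
exactness only for ratios and linearity.  The medium contribution comes
out at 2–5% of the cumulated dose, the few-percent scale reported.

## Dose response and RBE

Survival fractions are treated-to-untreated ratios of mean colony
counts, with Poisson standard deviations propagated through the ratio
(`sd = SF·√(1/mean_t + 1/mean_u)`); complete kill yields SF = 0 with a
one-sided upper bound and is excluded from log fits.  The model is
log-linear through the origin, `ln SF = -αD` (SF(0) = 1 by
normalization); an optional quadratic term exists but is off by
default since a single slope describes both radioligands.  Fits are
weighted by inverse ln-variance.

The reported α uncertainty has two components added in quadrature: the
WLS error scaled by √(reduced χ²), and the between-experiment standard
error of per-experiment slopes.  The second term exists because points
within an experiment share that experiment's untreated control — their
errors are correlated, and pooled residual scatter alone understates
the slope uncertainty.  With both components, the 2-SE interval covers
the generating slope in ≈ 93–95% of simulated assays.

RBE = α_test/α_ref with first-order uncorrelated-ratio error
propagation, validated against an explicit Monte Carlo ratio
distribution to 5%.

## Foci counting

The counting pipeline mirrors a standard ImageJ macro: maximum z
projection; nucleus segmentation by global Otsu threshold, hole
filling, minimum-area filter (500 px) and watershed splitting of
touching nuclei on the distance transform; then per nucleus an
adaptive threshold mean + k·SD (k = 2 by default — the constant is a
free choice, exposed in the API) of the damage signal inside the ROI,
with connected components of at least 4 px counted as foci.  Because
the threshold is ROI-relative, counts are invariant under affine
intensity rescaling.

## Synthetic data

The generators encode the assay designs: clonogenic counts are Poisson
around `450 × PE × exp(-αD)` (plating efficiency 0.5 — not published,
chosen to give realistic untreated counts of ≈ 225) over 3 experiments
× 3 replicate wells, with a lognormal experiment/condition factor
(σ = 0.06 on the ln scale).  That dispersion was calibrated once so
that simulated fit uncertainties land within a factor two of the
published slope errors (0.01 and 0.06 Gy⁻¹) and then frozen; it also
puts simulated R² at ≈ 0.96–0.98, the published regime.  Excretion
series use the measured grid {0, 4, 24, 48, 120} h, 2 experiments ×
triplicate, 3% multiplicative noise; displacement curves span
10⁻¹³–10⁻⁶ M with 5% noise; uptake data emulate gamma-counter lysate
and standard counts.

Foci images place elliptical nuclei (non-overlapping) with
negative-binomial focus counts matched to the published over-dispersed
mean ± SD (18.1 ± 7.4) and Gaussian foci of σ = 1.2 px at SNR 8.  Foci
are placed with a minimum mutual separation of 5 px: a "focus" in the
scored assay is by definition an optically resolvable object, so
ground truth counts resolvable foci; if a crowded nucleus cannot fit
its drawn count the placed number is recorded as truth.  Brightfield
fields are dark disks on a bright background with ground-truth radii.

What the generators do **not** emulate: optics (no PSF, no z-dependent
blur, no vignetting), clustered or nested damage foci, chromatic or
registration offsets between channels, cell-cycle or spatial
heterogeneity in uptake, and receptor-level binding kinetics.  Passing
tests therefore demonstrate that the analysis recovers parameters under
the model's own statistical assumptions — not that those assumptions
capture every property of real microscopy or counting data.

## Numerical choices

* Energy grids for range integration: 800-point geometric grids;
  log-log-free linear interpolation on dense grids (monotone by
  construction).
* Bateman terms require pairwise-distinct decay constants, which holds
  for both embedded chains; atom counts are clipped at zero to absorb
  1e-16-scale cancellation, and daughters are exactly zero at t = 0.
* Clearance and IC50 fits use bounded Levenberg–Marquardt/trust-region
  least squares; a flat retention series is returned flagged
  `degenerate` (half-life unidentifiable) rather than fitted; a flat
  displacement curve or an IC50 outside the tested span is returned
  flagged rather than raised.
* The IC50 hill slope is free by default (option to fix at 1);
  displacement signals are normalized to the mean signal at the lowest
  competitor concentration.
* Hough detection ties break by accumulator value; detections closer
  than 1.2× the minimum search radius are suppressed.
* All Monte Carlo and generator randomness flows through
  `numpy.random.default_rng(seed)`; no global state.

## Known limitations

* The transport engine is desk-scale by design: no electron
  condensed-history simulation, no alpha straggling or delta rays, no
  photon transport, no DNA-scale track structure.  Where absolute
  S-value parity matters, use the bundled full-transport table.
* Geant4-style production cuts and step limits have no analogue in a
  kernel engine and are not emulated.
* The true min/average/max cell dimensions behind the reference
  S values are unpublished; the default geometry is a documented
  assumption, and attached-cell S values are the most sensitive to it.
* Dose "to the DNA" is implemented as dose to the nucleus volume.
* Cell proliferation during colony growth, bystander effects, and
  microdosimetric (stochastic energy deposition) treatment are out of
  scope.
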