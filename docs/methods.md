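# Methods

This note documents the models, conventions and numerical choices behind
`ecdkit`, and what the synthetic-data tests do and do not establish about
real measurements.

## Spectral model

A calculated ECD spectrum is a sum of Gaussian bands centred at the
excitation wavelengths, each weighted by its rotational strength:

    S(λ) = Σ_i R_i · exp(−((λ − λ_i)/σ)²),   σ = HWHM / √(ln 2)

so that S(λ_i ± HWHM) is exactly half the single-band maximum.  Two
conventions deserve emphasis:

* **Wavelength-domain broadening.**  Band shapes are applied on the
  wavelength axis, not the energy (wavenumber) axis.  For the 185–320 nm
  window and a 10-nm HWHM the difference is a mild asymmetric distortion;
  because the fitting objective is scale- and shape-based (below), and the
  same convention is applied to every conformer, this is a documented
  convention rather than a physical claim.
* **Unit prefactor.**  No dipole/velocity-gauge intensity calibration is
  attempted; broadened spectra carry an `arbitrary` unit tag.  The fit is
  invariant under a global rescaling of the library, so absolute Δε
  calibration of calculated spectra is unnecessary.

Defaults: HWHM 10 nm; grid 185–320 nm in 0.5-nm steps, matching the range
accessible in aqueous solution (water absorbs below 185 nm) and
oversampling the band width by a factor of 20.

Peak picking reports signed bands — positive local maxima and negative
local minima above a prominence threshold — in descending wavelength, the
customary reading order of CD band tables.  Extrema whose sign contradicts
their curvature (e.g. a negative-valued local maximum between two deeper
minima) are shoulders, not bands, and are not reported.

## Measurement preprocessing

Final experimental spectra are the pointwise mean of replicate scans (five
by default in the generators) with the solvent blank subtracted.  No
smoothing or filtering is implemented anywhere.  Raw ellipticity converts
to molar CD by Δε = θ_mdeg / (32980·c·l) with c in mol/L and l in cm; the
constant 32980 = 100 · 3298 mdeg·L·mol⁻¹·cm⁻¹ per Δε unit.  Conversion is
opt-in: because the fit is scale-invariant, fits on raw instrument units
give identical subsets and relative abundances.

## Population fit

Given conformer records (id, relative energy, transitions), the fit:

1. broadens every conformer on the fitting grid;
2. enumerates all subsets of size 1..`max_subset_size` (default 3; at 20
   conformers that is 1350 subsets);
3. for each subset solves the non-negative least-squares problem
   min_{w≥0} ‖S_A w − t‖², adding the constraint Σw = `weight_sum_cap`
   when the unconstrained optimum exceeds the cap;
4. scores each subset by the cosine similarity between S_A w and t and
   returns the best, breaking ties toward the smaller subset and then the
   lower summed relative energy.

The NNLS solution is the Euclidean projection of the target onto the
convex polyhedral cone spanned by the subset's spectra; by Moreau's
characterization the projection direction also maximizes the cosine over
the cone, so step 3 and step 4 are mutually consistent.  Each projection
is computed exactly by support enumeration on the subset's Gram matrix
(2^k − 1 candidate supports for subset size k, each a ≤k×k solve, with
Karush–Kuhn–Tucker feasibility checks); the test suite cross-checks this
against `scipy.optimize.nnls` on random problems.

**Scale conventions.**  Cosine similarity, subset choice and abundance
*ratios* are invariant under positive rescaling of the target.  The
absolute abundances are the projection coefficients on the target's own
intensity scale: they are meaningful as populations when target and
library are on comparable intensity scales (as with synthetic mixtures, or
Δε-calibrated data on both sides), and they need not sum to 1 — real shape
fits typically assign ~97–98 % and leave the remainder to unassigned minor
conformers.  The cap Σw ≤ 1 (rather than Σw = 1) preserves exactly this
behaviour.

**Weight cap choice.**  `weight_sum_cap` defaults to 1.0.  The equality-
constrained fallback uses the same support-enumeration machinery with a
Lagrange multiplier row, so the cap never changes the subset ranking (the
cosine is scale-invariant along the projection ray).

**Optional wavelength shift.**  A uniform shift of all calculated
transitions before broadening (off by default) can compensate a systematic
excitation-energy bias of the electronic-structure method.  It is a single
global parameter, never fitted automatically.

**Degenerate targets.**  A target that anti-correlates with every library
spectrum projects to the cone apex everywhere; the fit then reports the
single least-bad conformer with zero weight, its (negative) cosine, and
`poor_fit: true`, rather than failing silently.  `poor_fit` is also set
whenever the best similarity falls below 0.9.

**Boltzmann weights** (R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹, default
298.15 K) are provided as an energy-based prior for reporting only; the
spectral fit never uses them.

## Torsion analysis

Dihedrals follow the IUPAC sign convention,
atan2((n₁×n₂)·b̂₂, n₁·n₂) with n₁ = b₁×b₂, n₂ = b₂×b₃, wrapped to
(−180°, 180°].  Collinear consecutive bonds raise an error (the angle is
undefined).  Backbone angles are φ_k = C(k−1)–N(k)–Cα(k)–C(k) and
ψ_k = N(k)–Cα(k)–C(k)–N(k+1).

**Table convention.**  Torsion tables are numbered from a declared start
terminus (default the N-terminus); row k holds (φ, ψ) of residue k+1.  For
C-terminally amidated peptides the amide nitrogen serves as N(k+1) of the
last residue, so an amidated pentapeptide yields exactly four full rows.
Without the amide the final ψ is undefined and that row is dropped.  φ of
residue 1 is undefined for a free amine terminus and never reported.

Backbone maps come from PDB N/CA/C atom names, or must be given explicitly
for XYZ input: element lists alone cannot identify a backbone without bond
perception, which is out of scope.  Angles are reported to 0.1°, the
customary precision of conformer tables.

The helix score is the RMS circular distance of all (φ, ψ) pairs from the
canonical α-helix point (−57°, −47°).  It is a coarse summary: for the
five GHRP-5 reference conformers it confirms that none is close to
canonical helical geometry (all deviations exceed 60° RMS), but it does
not rank "helix-likeness" among strongly non-helical structures — visual
and hydrogen-bond criteria used in structural discussions weigh the
angles differently.  Pairwise mean circular distance between torsion
tables is the sharper tool and cleanly identifies the structurally paired
conformers (aq-I/mic-II and mic-I/mic-III).

## Peptide masses

Average (not monoisotopic) residue masses; the free-peptide mass is the
residue sum plus one water (18.02 g/mol), with −0.98 g/mol for C-terminal
amidation (OH → NH₂).  The monomer table covers the 20 standard residues
plus Aib (85.11) and 2-Nal (197.23).  D/L flags are parsed and preserved
but never affect mass.  Validation covers GHRP-3/4/5/6 and ipamorelin
(canonical composition Aib-His-2Nal-Phe-Lys-NH₂, matching 711.9 g/mol);
the GHRP-1 and GHRP-2 rows of the usual reference table are internally
inconsistent with their own sequences by one alanine residue
(≈71.1 g/mol) and are excluded rather than silently "corrected".

## Synthetic-data generators

All generators are pure functions of (parameters, seed), using numpy's
PCG64 generator.

* **Transition libraries** stand in for per-conformer TD-DFT output: by
  default 20 conformers × 8 transitions, wavelengths uniform on
  190–310 nm, rotational strengths N(0, 10), relative energies uniform on
  [0, 3] kcal/mol (the energy window within which low-energy conformers of
  a flexible pentapeptide are typically considered).
* **Mixture spectra** combine the first k conformers with prescribed
  abundances, plus a half-sine baseline drift (the simplest smooth
  confounder for baseline-subtraction tests) and white Gaussian noise
  scaled as a fraction of the clean peak amplitude; 1 % is the default
  test condition, representative of a well-averaged far-UV CD measurement.
  Synthetic mixtures assign a total abundance of 0.98, mimicking the
  ~97–98 % totals that shape fits of real ensembles report.
* **Backbones** are built by natural-extension (NeRF) placement with
  standard peptide internal coordinates (N–Cα 1.458 Å, Cα–C 1.525 Å,
  C–N 1.329 Å; N–Cα–C 111.0°, Cα–C–N 117.2°, C–N–Cα 121.7°; ω = 180°).
  The first residue's ψ (default 140°) orients the first peptide unit but
  never enters the reported table.  These geometries are self-consistent
  for torsion round trips, not physically refined structures: no side
  chains, no hydrogens, idealized bond geometry.

**What passing tests show — and do not.**  Recovery of 65/25/8 %
abundances from synthetic mixtures establishes that the estimator is
correct and stable under the stated noise; it does not establish that
real fitted abundances are accurate, since those inherit the errors of
the conformational search, the electronic-structure method and implicit
solvation.  Likewise the torsion validation uses backbones *reconstructed*
from reference torsion tables — it verifies the geometry chain
(build → file round trip → extraction) to 0.1°, not the provenance of the
reference geometries themselves.

## Numerical choices

* Duplicate wavelengths in spectrum files are rejected, not averaged:
  silent averaging hides acquisition errors.
* Resampling is linear interpolation and refuses to extrapolate.
* Cosine values are clipped to [−1, 1] against rounding excursions;
  similarity ties in subset selection are resolved at 10⁻¹² resolution.
* Gram-matrix support solves fall back across supports on singular
  systems (exactly collinear library spectra), so duplicated conformers
  degrade gracefully to the lower-energy copy.
* Angle wrapping maps −180° to +180°, keeping the half-open interval
  (−180°, 180°] everywhere.

## Problem sizes

Default test and reproduction workloads: 200-trial recovery studies on
20-conformer libraries (≈1350 subset solves per fit) and 200-trial
replicate-averaging studies, chosen to bound the Monte-Carlo standard
error of a ≥95 % success criterion near 1.5 % while keeping a full run in
tens of seconds on one CPU.

## Known limitations

* No conformational search, no TD-DFT, no vibronic structure or solvent
  shifts: transition tables are consumed, never produced.
* No absolute intensity scale for calculated spectra.
* Minimal PDB support (first model, ATOM/HETATM coordinates, names,
  residue numbers); no CONECT, insertion codes or altlocs.
* No DSSP-style secondary-structure assignment or side-chain analysis.
* The fit's exhaustive enumeration is exponential in `max_subset_size`;
  it is intended for the "few dominant conformers out of ~20" regime, not
  for ensemble-weight estimation over hundreds of conformers.
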