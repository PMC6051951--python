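# Methods

## Scanner forward model and the synthetic phantom

The phantom module emulates the measurement situation the package analyses:
two PET systems imaging the same activity distribution. Ground truth is a
piecewise-constant field on a fine grid (default 1.0 mm isotropic, finer
than any modelled scanner grid so resampling is well posed): spherical
lesions, voxel-center-in-sphere membership, on a uniform background. Partial
volume is deliberately *not* modelled in the truth — finite resolution is
the scanner's job, and the crisp rule makes the truth brute-force checkable.

Each virtual scanner observes the truth as

```
observed = pgc · resample( blur(truth, FWHM), scanner grid ) + ε,
ε ~ N(0, (noise_coeff · √max(value,0))²)  per voxel, independent
```

* `FWHM` — the reconstructed PET resolution, modelled as an isotropic
  Gaussian PSF (6.3–7.0 mm for the clinical systems emulated).
* `pgc` ∈ (0, 1] — the fraction of the true AC the system images. ¹²⁴I emits
  a 605-keV prompt gamma in ~12 % of decays; the resulting spurious
  coincidences bias the imaged AC *down*, by 20 % (factor 0.8) on an older
  PET/CT without PGC correction and by 10 % (0.9) on current systems even
  with it.
* `noise_coeff` — one dial for the signal-to-noise difference caused by
  differing emission times; the √intensity form mimics the Poisson-like
  scaling of reconstructed PET noise. Defaults 0.15 (reference, 3.5 min/bed)
  and 0.10 (test, 8 min/bed): at a typical 100 kBq/mL lesion these give
  ~1.5 %/1 % voxel noise, rising steeply for the sub-kBq/mL lesions that the
  low-AC exclusion is there to catch.

Default lesion population: 40 non-overlapping spheres, diameters uniform
5–20 mm (a choice — no published size distribution exists for this setting),
ACs log-uniform over 0.2–800 kBq/mL (the three-decade range seen clinically),
trachea-surface distances uniform 0–30 mm so both proximity classes are
populated. Lesions keep a 25 mm margin to the grid border so the PSF never
interacts with the edge.

What the generator does *not* emulate: attenuation-map segmentation errors
(the clinical mechanism that would make trachea-adjacent lesions behave
differently), OSEM convergence/iteration effects, scatter, anatomical
background structure, and magnetic-field positron-range effects. Passing
tests therefore demonstrate that the *analysis chain* is correct and
self-consistent, not that any particular scanner pair agrees clinically.

## Harmonization

Three stages, in this order:

1. **Resolution matching.** Modelling each system's PSF as Gaussian,
   resolutions compose in quadrature, so the filter that brings a native
   resolution f to the common target F is a Gaussian of FWHM √(F² − f²).
   Target default 7.0 mm — the coarsest of the emulated systems; matching by
   smoothing can only go up, and the code refuses to "sharpen by smoothing".
2. **Grid matching.** Trilinear resampling onto a common grid (default
   2.1 × 2.1 × 2.4 mm³), evaluated at target voxel-center world coordinates;
   queries outside the source extent clamp to the edge value.
3. **PGC scaling.** Division by the scanner's recovery factor. Since imaged
   = factor · true, correction must divide; scaling commutes with the two
   linear stages (tested), so its position is immaterial.

Smoothing on the native grid (before resampling) preserves the finer
information; the whole chain is linear in the voxel values.

**Numerical choice — Fourier-domain smoothing with edge-replication
padding.** The matched filters can be small relative to the voxel size
(e.g. 1.66 mm FWHM on a 1.45 mm grid, σ ≈ 0.49 voxels). A sampled spatial
Gaussian kernel aliases badly at such σ, and the error is large enough to
break the quadrature equivalence between two harmonization paths by more
than a percent of lesion AC. Smoothing therefore multiplies the DFT by the
exact Gaussian transfer function (`scipy.ndimage.fourier_gaussian`), which
makes the semigroup identity (f₁ then f₂ ≡ √(f₁²+f₂²)) hold to numerical
precision at any σ. The volume is padded by 6σ before the FFT; padding
replicates the edge value rather than zero-filling, because the band-limited
kernel has oscillating tails and would ring off the artificial step that a
zero pad creates at the border of a uniform field (~10⁻³ relative). With
edge replication a uniform field is exactly invariant, and for interior
lesions (the documented assumption) the two pad choices agree to rounding.

## Quantification

* **max-AC**: hottest voxel whose center lies within 10 mm (default) of the
  lesion seed. The radius confines the search to the intended lesion — an
  unconstrained argmax would jump to a hotter neighbour; ties break by
  distance to seed, then lexicographic index, so results are deterministic.
* **avg-AC**: unweighted mean over voxels whose centers lie within a 7-mm
  sphere centered *at each volume's own max position* (the two modalities may
  use slightly different centers). 7 mm equals the harmonized resolution.
  Voxel-center membership, no partial-volume weighting: verifiable by
  exhaustive enumeration.
* **Percentage difference**: 100·(test − ref)/ref, undefined (error) for a
  non-positive reference.
* **Proximity**: adjacent ⇔ trachea-surface distance ≤ 5 mm (boundary
  inclusive, as the clinical rule is stated).
* **Low-AC exclusion**: records with reference avg-AC ≤ 1 kBq/mL are flagged
  (never dropped); at such levels a fixed absolute noise floor produces
  percentage deviations of tens of percent. The flag keys on the *reference*
  (CT-based) *avg*-AC — the stated rule ("approximately 1 kBq/mL") does not
  specify modality or AC type, so the choice is documented here; summaries
  are reported both with and without flagged lesions.

## Agreement statistics

Descriptive statistics use the n−1 SD; Lin's CCC uses n-denominator moments
(the original definition) — the conventions differ in the third decimal and
are deliberately not mixed. The CCC confidence interval is the Fisher-z
interval with Lin's asymptotic variance of the transformed estimate,
back-transformed by tanh; a bootstrap is not used. McBride bands: > 0.99
almost perfect, 0.95–0.99 substantial, 0.90–0.95 moderate, < 0.90 poor (the
lower two bands follow the criteria's standard form). The Mann-Whitney U
test is exact (full enumeration) when the smaller group has ≤ 8 values and
no ties, else the normal approximation with midrank-tie and continuity
corrections; significance at p < 0.05. Acceptance verdict: |mean| ≤ 10 %
and SD ≤ 25 %, boundaries inclusive.

The pipeline evaluates the four correction modes (`none`, `pgc`,
`harmonization`, `pgc_harmonization`) from one pair of simulated scans, so
all modes share identical noise realizations and differ only in the applied
corrections. Per-stage seeds are spawned from the study seed and recorded in
the report; a rerun with the same config is bit-identical.

## Two-point ¹³¹I TIAC uncertainty

The dosimetric chain: measured ¹²⁴I ACs a₂₄, a₁₂₀ →
λ_eff = ln(a₂₄/a₁₂₀)/96 h → projection to ¹³¹I by swapping physical decay
while keeping biology, λ₁₃₁ = λ_eff − λ_phys(¹²⁴I) + λ_phys(¹³¹I)
(half-lives 100.22 h and 192.6 h) → TIAC contribution
∫ B·exp(−λ₁₃₁(t−24)) dt over [24, 120] h, closed form
B·(1−e^(−λ₁₃₁Δt))/λ₁₃₁ with the analytic limit B·Δt used below
|λ₁₃₁Δt| < 10⁻¹². A negative λ₁₃₁ (late uptake) is physically meaningful and
propagates through the same expression. The amplitude convention
(re-projection of the 24-h AC through the decay swap) scales only the
absolute TIAC; every relative quantity is invariant to it, which is tested.

Monte Carlo: both ACs receive independent Gaussian noise of equal relative
SD (a first-order model of the measurement chain); draws producing a
non-positive AC are redrawn (a truncated normal — a log of a non-positive
ratio is undefined) and the redraw count is reported. The headline quantity
is the percentage SD of the simulated TIACs *about the reference TIAC* (the
RMS of the percentage differences); the SD about the sample mean is reported
alongside and differs by < 0.1 pp at the noise levels of interest. The
effective-half-life sweep default is 24–96 h in 24-h steps, bracketing
thyroid-remnant and metastasis kinetics. With two equal independent relative
errors whose log-sensitivities sum to 1, first-order propagation bounds the
ratio TIAC-SD / AC-SD to [1/√2, 1]; the simulation agrees with the
first-order value to within Monte-Carlo error at small noise and sits
slightly above it at 25 % noise (log-normal curvature).

Out of scope by design: absorbed-dose computation itself (S-values, lesion
mass), multi-point fitting protocols, and emission-time/noise equalization
between systems.

## Problem sizes

The shipped defaults are sized for a desk run: 100 000 Monte-Carlo draws per
sweep cell (Monte-Carlo SE of the reported SD ≈ 0.04 pp), a 150×150×130 mm
truth grid at 1 mm with 40 lesions for the default study (≈ 4 s), and
smaller grids in unit tests. All are parameters, not constants.
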