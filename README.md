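# petharm

Quantitative cross-scanner comparison of ¹²⁴I PET activity concentrations,
and the dosimetric consequences of their uncertainty.

## The problem

Pre-therapy lesion dosimetry in differentiated thyroid cancer measures ¹²⁴I
activity concentrations (ACs, kBq/mL) in neck lesions by PET at two time
points, fits a mono-exponential clearance curve, projects it to the
therapeutic nuclide ¹³¹I, and integrates it into a time-integrated activity
coefficient (TIAC) that drives the absorbed-dose estimate. When the two time
points come from *different* PET systems (e.g. a PET/CT and a PET/MR), the
raw ACs are not directly comparable: the systems differ in reconstructed
resolution, voxel grid, and in how much of the true AC they recover in the
presence of ¹²⁴I prompt-gamma coincidences (PGC). `petharm` implements the
full comparison chain:

* **harmonize** — match resolutions with an additional Gaussian filter of
  FWHM √(f_target² − f_native²) (Gaussian PSF quadrature), resample to a
  common voxel grid by trilinear interpolation, and divide by the scanner's
  PGC recovery factor (0.8 ⇒ a 20 % underestimation of the imaged AC);
* **quantify** — per lesion, the maximum AC (hottest voxel near a seed) and
  the average AC within a 7-mm spherical VOI centered on that voxel, paired
  across scanners as percentage differences 100·(test − ref)/ref;
* **agreement** — mean/median/SD/range of the differences, Lin's concordance
  correlation coefficient ρ_c = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²) with a 95 %
  CI and McBride strength class, a Mann-Whitney U comparison of
  trachea-adjacent (≤ 5 mm) vs distant lesions, and the acceptance rule
  |mean| ≤ 10 % (accuracy) and SD ≤ 25 % (precision);
* **tiacsim** — Monte-Carlo propagation of AC noise through the two-point
  fit, the λ_bio-preserving ¹²⁴I→¹³¹I projection
  λ_eff(131) = λ_eff(124) − λ_phys(124) + λ_phys(131), and the 24–120 h TIAC
  integral;
* **phantom** — a synthetic dual-scanner phantom generator (spherical lesions
  on a fine ground-truth grid, observed through Gaussian-PSF scanners with
  PGC loss and √intensity noise) that makes the whole chain testable without
  patient data;
* **pipeline** — one-config orchestration producing the four correction-mode
  summaries (`none`, `pgc`, `harmonization`, `pgc_harmonization`).

## Worked example

Run the default synthetic study — a Biograph-Duo-like reference PET/CT
(PGC recovery 0.8, 6.6 mm FWHM) versus an mMR-like test PET/MR (0.9,
6.3 mm FWHM) observing 40 shared lesions of 0.2–800 kBq/mL:

```
$ petharm run --out study_out --seed 1
avg-AC (corrected, n=33): mean -0.4% (median +0.8%) SD 5.4% -> accepted
full report in study_out/summary.json
```

33 of 40 lesions survive the low-AC exclusion (reference avg-AC > 1 kBq/mL;
very low ACs give unstable percentage differences). After both corrections
the mean avg-AC difference is −0.4 % with SD 5.4 %, inside the ±10 %/±25 %
acceptance bounds. `summary.json` holds all four correction modes; in the
same run the uncorrected comparison (`none`) shows a mean bias of +15.6 %
(the test scanner recovers 0.9 of the true AC vs 0.8, and its sharper PSF
reads small lesions higher), failing the accuracy bound — harmonization and
PGC scaling together remove it.

The TIAC uncertainty sweep:

```
$ petharm tiacsim --rel-sd 0.15,0.25 --t-eff-h 24,48,72,96 --n 100000 --seed 1 --out fig4.csv
```

gives, per (effective ¹²⁴I half-life, AC noise) cell, the percentage SD of
the projected ¹³¹I TIAC: at 15 % AC noise the TIAC SD is 10.7–11.3 %, at
25 % it is 18.0–19.1 % — i.e. a two-point protocol keeps the dose-relevant
TIAC uncertainty below ±20 % as long as each AC is measured to ±25 %.

Library use mirrors the CLI:

```python
from petharm import TiacSimConfig, simulate_tiac_uncertainty
res = simulate_tiac_uncertainty(TiacSimConfig(t_eff_124=24.0, rel_sd_ac=0.25, seed=1))
print(res.rel_sd_tiac)   # ~19.1 (%)
```

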