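# Methods

This note documents the models, conventions and defaults behind
`fibropet`, and what the synthetic phantom does and does not emulate.

## Image data model and conventions

Volumes are axis-aligned 3D scalar grids (`VolumeGrid`): CT in Hounsfield
units (valid range [-1024, 3071]), PET as activity concentration in
kBq/mL *as measured* — files are never decay pre-corrected, so the decay
correction step stays explicit and testable. World coordinates are RAS
millimetres; voxel indices are 0-based; `world = origin + index·spacing`
addresses voxel centres. PET frame intervals are half-open
`[start, start+duration)` in minutes post-injection (p.i.).

Masks and images must share one grid: PET/CT from a combined scanner are
hardware co-registered, so no image registration is implemented — a
congruence check with a clear error replaces it. CT-derived masks are
carried onto the PET grid by nearest-neighbour resampling of voxel
centres. On disk, volumes are NIfTI-1 (float32, lossless for float32
data) with a sidecar JSON carrying modality, units, frame timing and
full-precision geometry (the NIfTI affine itself is float32); masks are
uint8 NIfTI. DICOM ingestion, registration and reconstruction are out of
scope.

## CT quantification

The lung ROI is partitioned by pure density thresholding:

* aerated: `[-800, -100)` HU
* dense (non-aerated): `[-100, 300]` HU
* excluded: everything else in the ROI (air < -800, bone/metal > 300)

The two conventional bands share the -100 HU boundary without an owner;
the half-open-below rule assigns -100 HU to the dense band, keeping the
partition disjoint and total. Thresholds are configurable
(`DensityThresholds`). No morphological smoothing is applied.

Mean lung density (MLD) is the arithmetic mean HU over the **full** lung
ROI including out-of-band voxels; the fibrosis fraction is
`dense / (aerated + dense)`, i.e. the dense share of in-band tissue.
Out-of-band voxels count toward MLD but never toward compartment uptake.

## PET quantification

`%ID/g = 100 · c_corr / (A_inj · ρ)` with `c_corr` the ROI mean
concentration decay-corrected to **injection time** using the frame
mid-time as both time coordinate and correction point
(`correction factor = 2^(t_mid / T½)`, Ga-68 T½ = 67.71 min, a physical
constant). Correction to scan start is available by passing elapsed times
accordingly; injection-time reference is the default. Tissue density
defaults to ρ = 1.0 g/mL; an HU-derived alternative
(ρ = 1 + HU/1000, clamped at 0.05 g/mL) is provided
(`ct_quant.hu_tissue_density`) for lung-realistic masses.

Static uptake over the 15–75 min window is the frame-duration-weighted
mean of per-frame %ID/g over frames whose mid-time lies in the window; an
endpoint mode (last in-window frame) exists. Dynamic series yield one TAC
point per frame at the frame mid-time. `tac_divergence` returns the
earliest mid-time from which one curve exceeds another by more than a
tolerance (default 0.5 %ID/g) at every later point.

Degenerate inputs are explicit: an empty dense compartment reports `None`
("no fibrotic tissue"), never 0 ("no signal"); empty masks raise.

## The digital thorax phantom

Geometry: a soft-tissue cylinder (body) containing two ellipsoidal lungs,
rendered on a 64×64×48 CT grid at 0.4 mm and a 32×32×24 PET grid at
0.8 mm by default (the scanner's true voxel sizes are not public; these
are phantom parameters, not claims). The PET grid tiles the CT grid, so
PET rendering block-averages CT-grid fields — a crude partial-volume
surrogate; no PSF, scatter or attenuation modelling is attempted.

CT appearance: per-voxel HU draws from N(-650, 80) in aerated lung,
N(60, 60) in consolidation, N(40, 20) in the body shell, -1000 in air
(`ct_noise=False` uses the class means). Consolidations are spheres
stamped at random lung sites, coarse first and progressively finer, until
the lesion fraction of the lung reaches the target (always within ±0.02,
typically within a few 10⁻⁴). The ground-truth collagen burden is
proportional to the lesion HU excess above -100 HU, normalised to mean
1.0 — so "uptake tracks collagen content" is true by construction and
recoverable by the independent CT segmentation.

Lung kinetics (decay-free concentration, kBq/mL):

```
C(t) = A_inj · [ A·e^(-αt) + f_block·B_max·b·(1 - e^(-βt)) + c0 ]
```

| parameter | meaning | default | rationale |
|---|---|---|---|
| A | perfusion amplitude | 120 kBq/mL/MBq | early lung %ID/g of a few percent, typical of an IV peptide bolus |
| α | washout rate | 0.25 /min | control curve falls to ~5% of its initial value by 12 min p.i. |
| B_max | binding amplitude | 80 kBq/mL/MBq per unit burden | fibrotic plateau ~2–3 %ID/g at realistic burden |
| β | binding rate | 0.15 /min | plateau established within the 15–75 min window, still slightly rising |
| c0 | baseline offset | 0 | keeps the two-term form exact by default |
| f_block | residual specific binding | 1.0 (0.1 under blocking) | ×100 cold-peptide excess modelled as 90% suppression; no quantitative displacement value exists to calibrate against |
| blood fraction | body-shell curve scale | 0.4·A | renal-route peptide: blood pool below lung perfusion peak |

Measured concentration is `C(t)·2^(-t/T½)`; each PET frame holds the
analytic frame average of the measured curve per voxel (the specific term
uses the voxel's block-averaged burden). Poisson noise (default on)
samples expected counts `conc · voxel volume · sensitivity · duration`
with sensitivity 0.05 cps/Bq — a small-animal-PET-like count level where
late control frames become count-starved, as in practice.

This simple two-term form reproduces the qualitative TAC shapes (early
perfusion peak, control washout to baseline, fibrotic plateau/slight
rise); it is **not** a compartmental model and is not fitted. One known
departure from real curves: because specific binding accumulates from
t = 0, the fibrotic and control curves separate from the first frames,
earlier than the ~12 min at which real curves (initially matched in
perfusion) become distinguishable.

## Study designs

The default longitudinal design has five arms — NaCl, BLM, BLM+nintedanib,
BLM+tofacitinib, BLM+blocking — imaged at D0/D8/D15/D22 with six 10-min
frames covering 15–75 min p.i., n = 4 per arm (the scale of real such
experiments). Fibrosis-fraction trajectories:

| arm | D0 | D8 | D15 | D22 |
|---|---|---|---|---|
| NaCl | 0 | 0 | 0 | 0 |
| BLM | 0 | 0.15 | 0.25 | 0.35 |
| BLM+nintedanib | 0 | 0.15 | 0.10 | 0.08 |
| BLM+tofacitinib | 0 | 0.15 | 0.13 | 0.08 |
| BLM+blocking | 0 | 0.15 | 0.25 | 0.35 |

Treated arms share the BLM D8 state (treatment starts at D8) and regress
below it by D22 — the "dramatic decrease / prevented progression"
behaviour. Each subject draws one lognormal severity multiplier (median 1,
σ = 0.25) applied to its whole trajectory, so severity is a stable animal
trait; this makes the predictive correlations hold by construction:
within-arm D8 burden and D8→D22 progression are both proportional to the
multiplier (positively for BLM, negatively for treated arms). The
blocking arm keeps the BLM trajectory on CT and suppresses PET binding.
A dynamic "pilot" design (control vs established fibrosis at a D21
analogue, 2-min frames 2→75 min) serves the TAC analyses.

Simulation is bit-reproducible: all randomness derives from the single
design seed via per-subject/timepoint seed sequences.

## Biodistribution emulation

Organ tables are %ID/g for lungs, blood, bladder+urine, liver, spleen,
heart, muscle and kidneys, plus a urinary excreted %ID. Kidneys are the
hottest organ by construction (renal elimination route). The lung value
follows the subject's ground-truth window-averaged kinetic curve — the
noise-free limit of the imaging-derived uptake — so in vivo and ex vivo
lung measures agree up to noise. Fibrotic burden scales blood and heart
up (×(1 + 1.5·burden)) and the excreted fraction down
(60%·(1 − 0.5·burden)); lognormal noise (σ = 0.1) perturbs organs.
Nominal mouse organ masses make %ID and %ID/g interconvertible and allow
a mass-balance guard (organs + excreted ≤ 100 %ID). "Elimination" here
*means* urinary excreted %ID at sacrifice — a declared operational
definition, since no standard one exists for this readout.

## Statistics

* Summaries: median ± IQR with linear-interpolation (type-7) quartiles.
* Mann-Whitney U (mid-ranks): exact two-sided p by full enumeration of
  all labelings when the combined n ≤ 14 and the data are tie-free
  (counting labelings whose U deviates from the null mean at least as
  much as observed); otherwise a tie-corrected normal approximation
  without continuity correction.
* Kruskal-Wallis H with tie correction; p from χ²(k−1); optional exact
  enumeration for total n ≤ 8. All-tied input yields H = 0, p = 1.
* Post-hoc: Dunn's z on pooled mid-ranks with tie correction, p-values
  multiplied by k(k−1)/2 and clipped at 1 (the standard rank-based
  pairwise follow-up where only "Bonferroni post-hoc" is conventionally
  specified).
* Correlation: Spearman by default (the surrounding framework is
  nonparametric throughout); exact permutation p for n ≤ 8, else the
  t-approximation with n−2 df. Constant input returns an undefined (NaN)
  correlation rather than a value.
* Significance stars: * p<0.05, ** p<0.01, *** p<0.001.
* Group contrasts are unpaired throughout; longitudinal structure enters
  only through within-subject Δ metrics
  (Δ = metric(D22) − metric(D8) for uptake and MLD).

The enumeration cut-offs (14 / 8 / 8) keep exact tests at desk-scale
runtime; all exact routines are verified against independent brute-force
enumerations in the test suite, and the approximations against scipy.

## Problem sizes used in tests

Unit tests run on a 32×32×24 CT / 16×16×12 PET thorax; end-to-end checks
use the default 64×64×48 grid. The study-level direction checks simulate
the five-arm design at n = 8 per arm over 20 independent seeds — n = 8
gives the rank tests enough resolution for the configured effect sizes
while keeping a 20-replicate sweep at desk scale. The TAC landmark script
simulates 20 subjects per arm on the 2-min dynamic schedule.

## Known limitations

* No realistic anatomy (airway tree, heart, diaphragm motion), no PSF,
  scatter, attenuation or reconstruction modelling; partial-volume
  effects exist only via block averaging.
* The kinetic model is phenomenological; rate constants are not tissue
  parameters and must not be interpreted physiologically.
* TAC divergence occurs earlier than in perfusion-matched real curves
  (see above).
* Passing simulation-based tests demonstrates internal consistency of
  the pipeline under the phantom's assumptions — not performance on real
  scanner data, where ROI drawing, registration residuals and
  reconstruction artefacts dominate.
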