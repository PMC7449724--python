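# Methods

`thztdd` implements the analysis chain of a reflection-mode terahertz
pulsed-imaging experiment that quantifies transdermal drug delivery (TDD)
into skin, together with a forward simulator that makes every stage testable
without instrument data.

## Measurement model

The sample (skin) is pressed against a z-cut quartz imaging window.  A
broadband single-cycle THz pulse hits the window at oblique incidence and
the detector records two echoes: the air–quartz reflection (the *baseline*)
and the quartz–sample reflection.  With the baseline subtracted from both
the sample trace and an air-reference trace, the frequency-domain ratio

    M(f) = FFT(E_sample − E_baseline) / FFT(E_air − E_baseline)
         = r_qs(f) / r_qa

equals the ratio of the quartz–sample to quartz–air s-polarized Fresnel
amplitudes.  The emitter spectrum, quartz transmission, propagation through
the window (and therefore the window thickness) cancel identically in M —
this self-referencing is what makes the imaging quantitative, and it is
verified to 1e-10 in the tests.

Writing q_m = ñ_m cos θ_m for the "normal index" of medium m, with the
internal angles fixed by Snell's law ñ_a sin θ_a = ñ_q sin θ_q = ñ_s sin θ_s:

    r_qs = (q_q − q_s) / (q_q + q_s),     r_qa = (q_q − q_a) / (q_q + q_a)

Inversion to the sample's complex refractive index ñ_s = n + ik is closed
form per frequency:

    r_qs = M · r_qa
    X    = q_q (1 − r_qs) / (1 + r_qs)          (= ñ_s cos θ_s)
    ñ_s  = sqrt(X² + (ñ_a sin θ_a)²),  branch with Re(ñ_s) > 0

and the absorption coefficient is α = 4π f k / c (reported in cm⁻¹).  An
independent numerical root-solve of the un-rearranged equation agrees with
the closed form to 1e-15 in the test suite; the noiseless simulate→invert
round trip recovers ñ_s to machine precision (bound asserted: 1e-6).

### Sign and transform conventions

Permittivity is ε = ε′ + iε″ with ε″ ≥ 0 for passive media, so
ñ = sqrt(ε) = n + ik has k ≥ 0.  Spectra use the e^{+iωt} kernel (the
conjugate of numpy's FFT), which makes the one-way window propagation
factor exp(+i 2π f ñ_q d cos θ_q / c) both delay and attenuate the echo.
All forward simulation and inversion go through the `field_fft`/`field_ifft`
pair so the convention cannot drift.

## Dielectric models

The library ships literature-informed Debye parameterizations in
`src/thztdd/data/media.yaml` — simulator choices, not measured data:

| medium     | model                 | rationale |
|------------|-----------------------|-----------|
| water      | double Debye (ε_s 78.36, ε₂ 4.93, ε_∞ 3.48, τ₁ 8.24 ps, τ₂ 0.18 ps) | standard room-temperature parameterization |
| glycerol   | double Debye (τ₁ 0.9 ns, fast process 2 ps) | main relaxation fully relaxed on 0.1–2 THz ⇒ low, weakly lossy ε — the contrast mechanism |
| ethanol    | double Debye | stands in for the 10% aspirin/ethanol additive as one polar component |
| background | flat ε = 3.0 | dry protein/lipid matrix of skin |

Mixtures use Landau–Lifshitz–Looyenga (LLL) cube-root mixing,
ε_eff = (Σᵢ fᵢ εᵢ^{1/3})³, the standard rule for water-rich biological
tissue; it is pluggable (a linear rule ships for sensitivity checks).
Principal-branch cube roots are continuous because every component lies in
the closed upper half plane.  The 50% w/v glycerol/water solvent is 0.40
glycerol by volume (ρ_glycerol = 1.26 g/ml); the drug solution is 0.54
water / 0.36 glycerol / 0.10 ethanol.

Skin before treatment is 30% background + 70% water.  Delivered drug
solution displaces water volume-for-volume: a drug volume fraction φ gives
composition (0.30, 0.70 − φ, φ), valid for φ ≤ 0.70.  |M| at 0.3 THz is
strictly decreasing in φ (tested on a dense grid), which is what links image
darkening to delivered dose.

## Synthetic experiment

The generator emulates the study design: five groups — Control (no drug),
NT (topical drop), PT (soaked pad), NN (nanoneedle patch + pad), MN
(microneedle patch + pad) — with 10 replicates each, every replicate imaged
before and after treatment as a 40×40 raster covering 2×2 cm at 0.5 mm
pitch.  ("0.5 mm² per pixel" is read as 0.5 mm pitch; the alternative
0.5 mm²-area reading would give ≈0.71 mm pitch and a 28×28 grid.)

Key defaults, all configurable on `ExperimentDesign` / `Geometry`:

| parameter | default | why |
|-----------|---------|-----|
| incidence angle θ_a | 30° | typical reflection-imaging geometry; all math handles arbitrary oblique incidence |
| polarization | s | the measured ratio has the (ñ cos θ) s-pol form |
| quartz index | 2.11 + 0.0005i | z-cut quartz, ordinary ray, THz literature value |
| window thickness | 2 mm | cancels in M; sets only the echo delay |
| acquisition | 512 samples at 0.1 ps | 51.2 ps window, 5 THz Nyquist, 0.0195 THz resolution |
| pulse | derivative-of-Gaussian, width 0.3 ps | spectral peak ≈ 0.53 THz, energy across 0.1–2 THz |
| trace noise sd | 5e-4 × pulse peak | peak SNR 2000, mid-range for commercial TDS imagers |
| composition jitter | sd 0.01 on the background fraction | piece-to-piece biological variation; shared by the before/after pair |
| peak drug fraction | NN 0.45 > PT 0.25 > MN 0.20 > NT 0.15 > Control 0 | orders delivery efficacy: needle-pretreated pad ≫ pad ≫ patch-only/drop |
| spot profile | raised cosine, radius 5 mm (PT: uniform 5 mm disk) | pad wets its full footprint; drop/needle fields taper |

Recorded traces are composite (baseline echo + sample echo) plus a
separately emitted baseline trace; a rectangular time gate is available for
gating experiments.  All randomness flows from the single design seed
through per-replicate `SeedSequence` children, so a run is reproducible
trace-for-trace.

What the generator does **not** emulate: multiple Fabry–Pérot echoes in the
window, window-thickness nonuniformity, focused-beam corrections, scanner
jitter, occlusion-induced hydration drift between the before and after
scans, skin-surface topography, and any spectral fingerprint of the drug
itself.  Passing tests therefore demonstrate correctness of the processing
and statistics pipeline under the stated model — not that a real instrument
will achieve these error levels.

## Imaging and normalization

Each pixel is reduced to |M| at the band bin nearest 0.3 THz (nearest-bin
sampling, no interpolation; 0.293 THz at the default resolution).  The
after-treatment field is normalized by the mean pre-treatment |M| over the
central 5×5 block:

    |M|_norm = (|M|_after − mean_ROI |M|_before) / mean_ROI |M|_before

The ROI anchors at floor((dim−5)/2) per axis — rows/cols 17–21 on the
default grid; the drug spot is centered on the image midpoint so the block
is symmetric about it to within half a pixel.  The same fixed block
summarizes the after image (the spot is centered by construction).  The
normalization is scale-free: any common gain drift cancels.  Under the
default conditions the per-replicate ROI means land near −0.23 (NN) to
−0.08 (NT) with Control ≈ 0 — the same order of magnitude as reflection
images of glycerol-treated skin.

## Statistics

Per-group normality is screened with Shapiro–Wilk (Royston approximation,
3 ≤ n ≤ 50, via scipy); a failed screen is reported as a warning and the
parametric battery proceeds.  One-way ANOVA is computed from the standard
sums-of-squares decomposition.  Pairwise comparisons use Tukey–Kramer: pair
(i, j) is significant iff |mean_i − mean_j| > q_{α,k,df} ·
sqrt(MS_w/2 · (1/n_i + 1/n_j)); for the balanced design the common minimal
significant difference is MSD = q · sqrt(MS_w/n).  The studentized-range
critical value comes from numerical integration of the range distribution
(scipy's `studentized_range`, cached per (α, k, df)); the test suite
cross-checks it against a 2-million-draw Monte-Carlo quantile and the
q = √2·t two-group identity.  Comparison intervals are drawn with
half-width MSD/2, so non-overlapping bars coincide exactly with Tukey
significance.  Calibration under the null (5×10 design, 2000 replications)
gives an ANOVA type-I rate of 0.05 ± 0.01 and Tukey family-wise error ≤ 0.06.

## Numerical choices and degenerate inputs

- Square-root branch in the inversion: principal root, negated if
  Re < 0; bins where 1 + r_qs underflows (|·| < 1e-12) are masked NaN and
  flagged in the `valid` mask rather than propagated.
- Reference bins below 1e-8 of the in-band peak amplitude are masked in the
  ratio (division would only amplify noise).
- Valid band 0.2–1.5 THz by default; reflection data above ~1.5 THz are
  unreliable in practice (air-gap sensitivity grows with frequency).
- No taper by default (simulated traces decay naturally inside the window);
  a Tukey taper is available for gated composite traces.
- Noise-robustness regression (frozen from calibration of this chain): the
  median recovered n at 0.3 THz over 100 noise draws stays within 1% of
  truth at 0.1% trace noise and within 5% at 1% noise — the amplitude-ratio
  bias grows quadratically with noise.
- Fast-path DFT in imaging: the per-pixel chain needs only one frequency
  bin, so the raster transform is a single kernel contraction rather than a
  full FFT per pixel; it is identical to the FFT route to machine precision.

## Problem sizes

Defaults are sized so a full run is interactive: one experiment (100 rasters
of 1600 pixels × 512 samples) simulates and reduces in ~5 s; the statistical
calibration uses 2000 null replications and 2 × 10⁶ Monte-Carlo draws; the
20-seed qualitative reproduction in the test suite is the slowest single
item at ~2 minutes.

## Known limitations

- The dielectric parameters are literature-informed simulator defaults, not
  fits to any measured spectrum; absolute |M| levels shift with them (the
  normalized contrast is much less sensitive).
- Effective-medium mixing is a modeling choice; LLL and linear mixing
  differ by a few percent in |M| at high drug fractions.
- The drug's own absorption fingerprint is not modeled, so the simulator
  cannot probe spectroscopic drug identification, only hydration-contrast
  quantification.
- `load_figshare_export` adapts only the package's own raster layout;
  arbitrary deposited archives must be converted first.
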