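# Methods

This note documents the models implemented in `vwisim`, their assumptions,
the parameters that matter, and the deliberate design choices made where the
underlying protocol leaves details open.

## Extended phase graph engine (`vwisim.epg`)

Magnetization under a multi-pulse refocusing train is tracked as
configuration states (F₊ₖ, F₋ₖ, Zₖ) over integer dephasing orders k ≥ 0,
with F₋ₖ storing conj(F(−k)). An RF pulse of flip α about an axis at
azimuth φ mixes the three families order-by-order with the standard 3×3
rotation; a crusher interval shifts transverse orders by one (one shift per
half echo spacing, so spin echoes form at order zero midway between
pulses); relaxation scales transverse states by exp(−t/T2) and longitudinal
ones by exp(−t/T1), with M0 regrowth entering Z₀ only.

Assumptions and conventions:

* **Hard pulses** — relaxation during RF is neglected (pulses are ~ms
  against T2 of tens of ms).
* **CPMG phase convention** — excitation and refocusing axes 90° apart, so
  echo amplitudes are real and non-negative; this makes the constant- vs
  variable-flip comparison well posed.
* **Capacity is explicit** — the state allocates 2·(n_pulses + 2) orders;
  a shift that would push amplitude past the last order raises an error
  unless truncation is explicitly enabled. Nothing is dropped silently.
* **Start-up (SPSS) ramp** — the pseudo-steady state is approached with a
  linear ramp from the asymptotic first-pulse prescription 90° + α/2 down
  to the target flip over the start-up echoes (4 by default, excluded from
  the acquisition window). The ramp is a swappable policy function; any
  schedule ending at α works, the ramp only damps the transient.

The engine is validated against an independent isochromat Bloch simulator
(`vwisim.bloch`): N equally spaced isochromats make the ensemble average of
exp(ikθ) vanish exactly for 0 < |k| < N, so EPG and the oracle agree to
machine precision whenever N exceeds the highest populated order. The test
suite requires < 10⁻³ relative echo error on random trains at N = 4000 and
exact CPMG/Hahn closed forms.

## Sequence signal models (`vwisim.sequences`)

**Flow-sensitized dephasing.** A first gradient moment M1 gives a moving
spin the phase γ·M1·v (γ = 2.675×10⁸ rad s⁻¹ T⁻¹; M1 in mT·ms²/m is
10⁻⁹ T·s²/m). Intravoxel velocities are modeled uniform on
[v(1−δ), v(1+δ)], giving the attenuation |sin(Δφ/2)/(Δφ/2)| with
Δφ = 2γ·M1·v·δ. A coherent per-voxel phase does not attenuate a magnitude
image, so δ = 0 means no suppression regardless of velocity. δ defaults to
0.9 in the recirculating CCA/bulb and 0.4 in the more uniform distal
ICA/MCA — this single parameter carries the segment-dependent flow
uniformity contrast.

**iMSDE preparation (MERGE).** Attenuation = exp(−T_prep/T2) × flow factor.
T_prep is minimized under a 20 mT/m amplitude cap and a 100 mT/m/ms slew
(slew is not protocol-specified; it shifts only the duration scale, never
the monotonicity): for back-to-back opposite trapezoids of amplitude G,
ramp r = G/S and flat top f, |M1| = G(f+r)(f+2r), solved for f in closed
form, with triangular lobes below the cap. The internal RF structure of the
preparation is abstracted into a fixed 5 ms overhead. With centric
ordering, the k-space-center signal is PD·sin α·Mz at the first readout,
with Mz evolved by the standard spoiled recursion from the post-prep state.

**VISTA.** Echo amplitudes come from the EPG engine with either the
constant reduced-flip (RFA) schedule or a variable-flip (VFA) comparison
arm. The VFA policy is constant-target: the first acquired echo sets the
target and each later flip is solved so its echo equals it. Because the
echo is *not* monotone in the flip (stimulated pathways recall stored Z),
the solver scans a coarse flip grid and refines around the smallest
feasible flip; when no flip reaches the target the schedule follows the
maximum achievable echo. With a small first flip (12° default) the plateau
is sustainable through the center echo, reproducing both observations about
the two schemes: VFA's center-echo (SNR-bearing) amplitude exceeds RFA's,
while RFA's late-train (edge-sharpness-bearing) amplitudes exceed VFA's.
Flowing blood is additionally dephased by readout-direction FSD gradients;
their moment is not protocol-specified and defaults to 300 mT·ms²/m, enough
to crush arterial blood while leaving static tissue untouched. The k-space
center sits at acquired echo ⌈N/2⌉ under linear ordering (config-exposed);
`equivalent_te = −T2·ln(S_center/S₀)` is exposed as a diagnostic only.

**SNAP.** One inversion-recovery cycle is: inversion (efficiency η, default
1) → free recovery to TI → SPGR readout block (98 pulses × TR 10 ms at 11°)
→ free recovery to IRTR (1987 ms). Every stage is affine in Mz, so the
periodic steady state is the fixed point b/(1−a) of the composed affine
map, computed exactly; a 50-cycle brute iteration is kept as the test
oracle. The low-flip reference segment is modeled at the end of the cycle
where Mz has recovered toward +M0 — the IRTR cannot contain TI plus two
full readout trains, which matches the interleaved-reference design of
phase-sensitive IR sequences. TI is not protocol-specified; the default is
**800 ms**, chosen once so that in steady state the wall is clearly
positive (+0.30), freshly inverted inflowing blood clearly negative
(−0.24), and CSF near zero, and so that the measured wall/lumen SNR ratio
of the phantom lands in the range reported for patient cohorts. (A naive
single-shot calculation suggests ~500 ms, but the readout perturbation
raises the steady-state null point; 500 ms would null the wall.) Inflowing
blood is tracked by transit time from the inversion-coverage edge: blood
within coverage that spans ≥ 2 IRTR cycles relaxes between inversions and
is measurably less suppressed (the distal-decay mechanism); with selective
inversion, blood from outside the slab arrives at +M0 — the bright inflow
artifact. Phase-sensitive reconstruction is Re[IR·conj(ref)/|ref|]; where
the reference vanishes, the IR real part's sign is kept and the voxel is
flagged.

Blood relaxation defaults to T1/T2 = 1660/150 ms (literature-typical 3 T
values; overridable), the wall to 1114/55 ms.

## Protocol optimization (`vwisim.optimize`)

SNR efficiency of a (flip, ETL) cell is S_center · (ETL·esp/TR), TR fixed
at 2500 ms, wall relaxation. One EPG run per flip serves all ETLs (echo
amplitudes are causal in train length). The default grid is flips 10–90°
step 1°, ETL 30–200 step 5. The per-ETL optimal flip (the ridge) is
extracted as the efficiency-weighted centroid of the plateau within 0.2% of
the column maximum rather than a literal argmax: the objective is flat over
~10° around its optimum with a sub-0.1% ripple left by the finite start-up
transient, across which an argmax hops discontinuously; the centroid is a
ripple-robust estimator of the same optimum and makes the ridge reflect the
physical flip–ETL tradeoff. The grid argmax cell is still reported.

The M1 sweep acquires the phantom at each moment in {500, 1000, 1500}
mT·ms²/m and applies the selection rule: maximize wall SNR subject to the
slow (CSF-like) compartment retaining ≤ 30% of its unencoded signal. The
threshold is a design choice (the original selection was by visual
inspection); under the default CSF motion model (mean 0.015 m/s, full
spread) the residuals are ≈ 0.45/0.19/0.04, so the rule selects 1000.

## Digital phantom (`vwisim.phantom`)

The phantom emulates the *statistical structure* of a patient cohort, not
anatomy: two tubes (lumen radius 3.0 → 1.4 mm, wall 1.0 → 0.5 mm, both
config-exposed inventions) run foot-to-head through CCA → bulb → ICA C2 →
ICA C5 → MCA M1 with gentle bowing and an MCA bend, a CSF sheath on the
intracranial segments, muscle/white-matter backgrounds, and a coil-gain
field summing exponential falloffs (scale 80 mm) from a neck and a head
source so that the gain dips at C2–C5, the segments farthest from both
coils. Partial-volume fractions come from 4× supersampling restricted to
interface voxels (interior voxels are exact); fractions sum to 1 and
recover analytic cross-section areas to < 2%. Coordinates are RAS mm,
0-based voxel indices, NIfTI output with correct spacing.

Acquisition: ideal voxel signal = Σ_label fraction × per-tissue sequence
signal (flow-aware for lumen and CSF) × gain. Lumen voxels carry a
Poiseuille-like profile (velocity 2v(1−ρ²) at normalized radius ρ): the
slow near-wall layer is incompletely dephased, which is what produces the
small positive lumen residual that real measurements show. Complex Gaussian
noise with local SD σ₀/gain/√averages is added in quadrature; magnitude
images therefore carry Rician noise (background exactly Rayleigh) and the
noise level varies spatially, which is why σ_n is measured locally
downstream. SNAP simulates the IR/reference complex pair (with a smooth
shared background phase) and reconstructs the corrected-real image.

**Noise calibration.** The per-sequence noise floor σ₀ is fixed by a
deterministic calibration that pushes one *noiseless* acquisition through
the actual ROI pipeline (so partial-volume dilution of the wall midpath is
accounted for) and measures the resampler's noise-SD shrink factor on a
fixed-seed white-noise volume; σ₀ is then the value that maps the measured
wall signal onto the anchor pooled wall SNR per sequence (19.07 / 20.64 /
10.96 for MERGE / VISTA / SNAP — the published patient-cohort values, used
as generator calibration anchors). Everything else — lumen residuals,
location profiles, CNR tables, between-sequence ordering — is emergent.

Cohorts jitter radii and wall thickness (lognormal, 10%) and a global
per-subject SNR factor (mean-one lognormal, 30%, emulating coil loading);
subjects may be marked occluded at one location with probability 0.08
(≈ 2 of 25 expected) and are then excluded from quantitative analysis, as
in the reference study. Per-subject seeds derive deterministically from the
master seed.

What the phantom deliberately does **not** model: realistic anatomy, motion
artifacts, off-resonance/susceptibility at the skull base, fat, k-space
point-spread effects, parallel imaging. Passing tests demonstrate that the
measurement and statistics chain recovers known ground truth under
realistic noise and partial volume — not that the sequence models predict
absolute patient SNR. In particular the absolute lumen residuals of the
magnitude sequences are approximate (they depend on boundary-layer flow
details); their orderings and the wall-versus-lumen separation are the
validated quantities.

## Quantification (`vwisim.quantify`)

Cross-sections are reformatted by trilinear resampling onto planes normal
to the centerline tangent (central difference), 0.4 mm in-plane, with
0.5 mm through-plane averaging (5 sub-planes). An axis-aligned tube
reproduces native slices exactly; a 45°-oblique tube recovers the analytic
lumen area to < 3% where the native slice would see a ~41% elongated
ellipse.

ROIs derive from ground-truth labels — the stand-in for manual drawing:
wall signal is the mean over the *middle path* of the wall ring
(skeletonization of the wall mask, avoiding partial-volume boundary
pixels); lumen signal the mean over the lumen mask eroded one pixel
(sign-flipped for SNAP so the reported S_l is positive); σ_n the SD within
a 20 mm² disc placed in the adjacent reference tissue (muscle for
extracranial, white matter for intracranial locations), searched over
eight angular positions for ≥ 95% label purity. SNR_w = S_w/σ_n,
SNR_l = S_l/σ_n, CNR = SNR_w − SNR_l (magnitude) or SNR_w + SNR_l (SNAP).
**Rician bias is deliberately not corrected** — raw means are divided by
the reference SD, so SNR values inherit the same bias the measurement
convention carries on real magnitude images. Empty ROIs mark the
measurement missing and exclude the subject-location downstream.

## Statistics (`vwisim.stats`)

The wall-versus-lumen comparison is a two-sided Wilcoxon signed-rank test:
zero differences dropped, mid-ranks for ties, exact null distribution for
n ≤ 25 computed by convolution over the doubled mid-ranks (identical to
enumerating all 2ⁿ sign assignments; the literal enumeration is the test
oracle for n ≤ 12), normal approximation with tie and continuity correction
beyond. The headline test pools per-subject averages over the five
locations (sides averaged first; a flag switches to treating sides as
independent pairs); per-location tests are also emitted. No
multiple-testing correction is applied, matching the reference analysis;
the report notes it. Significance is declared at p < 0.05.

`run_all` chains cohort generation → three acquisitions per subject →
quantification → statistics, writing tidy CSVs, a Markdown report and a
provenance record (seed, versions, configuration); identical seeds give
byte-identical tables.

## Problem sizes

The default scene is the full 250 mm foot-head coverage with the LR extent
cropped to the 64 mm band containing both vessels (the full 160 mm FOV
builds too, and is exercised in tests); cohort runs use 18–25 subjects.
These sizes keep a full cohort study at a few minutes on one CPU while
leaving every mechanism (five locations, bilateral vessels, gain trough,
occlusion exclusions) in play.

## Known limitations

* The SNAP cycle tracks Mz only between discrete events; within-readout
  transverse dynamics and k-space weighting of the 98-echo block are
  reduced to the Mz at the block start.
* The VISTA blood model composes EPG amplitudes with an FSD dephasing
  factor; washout of excited spins during the 470 ms train is not
  explicitly modeled, so magnitude-sequence lumen residuals are
  approximate.
* The equivalent-TE diagnostic (−T2·ln S_center ≈ 131 ms for the default
  train) is a single-tissue summary; a contrast-matched calibration across
  tissues would give somewhat different values (the protocol's annotated
  86 ms is treated as a consistency check within a factor of two, not a
  target).
* Wilcoxon exactness is capped at n = 25 pairs before switching to the
  corrected normal approximation.
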