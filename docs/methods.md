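# Methods

## Model

The measured activity concentration in a tissue voxel or VOI is modelled
as a two-tissue compartment system driven by the metabolite-corrected
parent-plasma concentration Cp:

    dC1/dt = K1·Cp − (k2 + k3)·C1 + k4·C2
    dC2/dt = k3·C1 − k4·C2
    C(t)   = C1(t) + C2(t) + vB·Cwb(t)

with K1 [mL·cm⁻³·min⁻¹] the plasma-to-tissue transport rate, k2, k3, k4
[min⁻¹] the exchange rates, and vB the fractional blood volume carrying
whole-blood activity Cwb. Irreversible trapping corresponds to k4 = 0,
with the macro-parameter Ki = K1·k3/(k2+k3) (net influx rate, also the
asymptotic Patlak slope). The blood-volume term is *additive*
(C = C1 + C2 + vB·Cwb rather than (1−vB)(C1+C2) + vB·Cwb); both
conventions appear in the kinetic-modelling literature, and the additive
form is the one under which the Patlak slope of the simulated signal
equals Ki without a (1−vB) scale factor, keeping the TAC-level and
graphical analyses mutually consistent. All activities are
decay-corrected to injection time, as clinical reconstructions produce;
no decay term appears anywhere.

### Forward evaluation

The tissue response is the bi-exponential convolution
C1+C2 = K1·(B1·e^(−α1 t) + B2·e^(−α2 t)) ⊛ Cp with
α1,2 = (s ∓ √(s² − 4·k2·k4))/2, s = k2+k3+k4. Cp is sampled onto a
piecewise-uniform grid (0.25 s steps to 6 min, 1 s after) and treated as
piecewise linear; the convolution with each exponential is then exact per
segment and accumulated with a first-order recurrence (`scipy.signal.lfilter`),
with series expansions of the segment integrals below α·Δt = 10⁻⁴ to
avoid cancellation. When the eigenvalues collide (disc < 10⁻⁹, e.g.
k3 = 0 with k2 = k4) the analytic limit E(α) + (k3+k4−α)·F(α) is used,
where F is the t·e^(−αt) convolution, rather than failing or perturbing.
Frame averages are composite-Simpson integrals over the grid. Against an
independent stiff-ODE oracle (Radau, rtol 1e−10) the frame averages agree
to better than 0.01%.

### Fitting

Bounded nonlinear least squares (`scipy.optimize.least_squares`, trf)
minimises Σ wᵢ(yᵢ−ŷᵢ)²; weights default to uniform, with
duration-proportional weights available. Five starts: one default
initialisation (K1=0.1, k2=0.1, k3=0.05, k4=0.01, vB=0.05) plus four
seeded log-uniform draws within bounds (K1, k2, k3 ∈ [0,2], k4 ∈ [0,1],
vB ∈ [0,0.5]); ties are broken by lowest RSS then lowest K1, so fits are
deterministic given the seed. vB is a fitted parameter, so the
irreversible model has 4 free parameters and the reversible 5. Standard
errors come from the Gauss–Newton covariance. The model comparison uses
AIC = n·ln(RSS/n) + 2p — the usual least-squares form in kinetic
modelling, without small-sample correction — and
ΔAIC = AIC(rev) − AIC(irr): positive values prefer the irreversible
model, |ΔAIC| > 2 is read as decisive. Because the models are nested,
ΔAIC ≤ +2 always (equality when the fitted k4 sits on the zero bound), so
*preference* is keyed to the sign of ΔAIC and the >2 rule flags
decisiveness; for reversibly-generated data ΔAIC < −2 is the expected
decisive outcome.

### Patlak analysis

x(t) = ∫₀ᵗCp/Cp(t), y(t) = C(t)/Cp(t), evaluated at frame mid-times (the
mid-time, not the frame-integral, formulation — adequate for 5-min
frames); the running integral of Cp is exact under piecewise-linear
interpolation. The default fit window is t\* = 40 min to 70 min, the last
six whole-body passes of the first scan session; ordinary least squares
gives Ki (slope), V (intercept) and r². The vB·Cwb contribution is not
subtracted before the fit (image-space practice); it lands mostly in V
and contributes a slow positive drift ≈ vB·d(1/(R·pf))/dx to the slope,
< 1% of a lesion-scale Ki. Voxels whose points cannot be fitted
(non-finite values, < 2 usable frames) are NaN, never zero, so downstream
statistics can exclude them explicitly. The parametric-image routine runs
the identical per-voxel code path as the TAC-level fit, so the two are
bitwise equal.

## Blood input

The IDIF is the per-frame mean over a descending-aorta VOI. Venous
samples at 2, 5, 10, 20, 40, 60 and 120 min provide (i) the
plasma-to-whole-blood ratio, estimated as the mean of the per-sample
ratios and treated as constant in time (measured fluctuation around 1.50
is minimal), and (ii) parent fractions, fitted by the sigmoid

    pf(t) = (1 − b)/(1 + (t/t50)^n) + b,

which satisfies pf(0) = 1 exactly, is monotone non-increasing, and has
three parameters — exactly enough to interpolate the three measured
anchors (90% at 2 min, 40% at 20 min, 20% at 120 min); calibration solves
the 3×3 system by bounded least squares to ≤ 1e−6. The continuous input
is the piecewise-linear interpolation of the IDIF with (0, 0) prepended
and constant extrapolation past the last frame; venous ≈ arterial
equivalence is assumed after ~2 min and no dispersion or partial-volume
correction is applied, so a PSF-blurred aorta gives a known
underestimate of the early peak (and hence an overestimate of Ki
downstream — flagged, not corrected).

## Synthetic data generator

The generator emulates the structure of a D-WB FES study; its defaults
*are* the study conditions the tests run under.

* **Schedule** — 12×10 s + 4×60 s (0–6 min, chosen to resolve the bolus
  peak; per-frame timing of the early series is a design choice), 7×2 min,
  10×5 min (session one ends at exactly 70 min so the 40–70 Patlak and
  60–70 SUV windows align with frame boundaries), a 10 min intermission,
  then 8×5 min to 120 min. 41 frames, 110 min scanned.
* **Blood** — whole-blood bolus = smooth quadratic-exponential rise
  (t½ ≈ 0.35 min) × tri-exponential decay; defaults peak ≈ 20 kBq/mL near
  0.7 min and decay to ≈ 2 kBq/mL at 1 h, the scale expected for a
  200 MBq injection in a 70 kg adult. Plasma-to-whole-blood ratio 1.50,
  constant. Venous samples receive 3% multiplicative Gaussian noise on
  activities and additive SD 0.02 on parent fractions, clipped to [0,1].
* **Phantom** — 64×64×48 grid of 4 mm voxels: a soft-tissue body
  ellipsoid, two bone regions, a ~1.4 L liver ellipsoid and a
  descending-aorta cylinder (pure blood, vB = 1, the IDIF source), plus
  eight spherical lesions of 8–25 mm with irreversible kinetics. Liver K1
  is calibrated at build time so the *voxelised* liver mask holds exactly
  30% of the injected dose in the frame covering 30 min. Lesion kinetics
  are chosen so the noiseless lesion SUVmean values span ≈ 1.8–7 g/mL
  with median ≈ 3.8. Background soft tissue equilibrates within a few
  minutes (k2+k3 ≈ 0.25 min⁻¹) and carries mild irreversible trapping
  (Ki ≈ 0.006), mirroring real muscle/glandular tissue, which levels off
  early and is best described by an irreversible model; a background that
  has not equilibrated by 40 min would have an artefactually null or
  negative Patlak slope and make background Ki meaningless.
* **Noise** — zero-mean Gaussian per frame with
  SD = α·√(activity/duration), the standard TAC-level approximation of
  reconstructed PET noise (projection-domain Poisson simulation is out of
  scope). α = 0.1 for VOI-level TACs (≈ 1–2% on organ curves) and
  α = 1.0 per voxel (≈ 10–15%), with an optional isotropic Gaussian PSF
  (default FWHM 6 mm) applied before noise. Every stochastic operation
  takes an explicit seed; there is no hidden global state.

What the generator does *not* emulate: continuous-bed-motion geometry
(passes are whole-volume frames), attenuation/scatter, motion, anatomical
texture, and correlated reconstruction noise. Passing tests therefore
demonstrate the correctness and statistical behaviour of the analysis
chain under its stated assumptions, not clinical performance on real
images.

## Visibility analysis

SUV = C[kBq/mL] · weight[kg] / dose[MBq] (the two factors of 1000 cancel,
so no explicit conversion appears), duration-weighted over the 60–70 min
window, which must tile exactly with frames. Lesions are screened on
their full VOI by SUVmax ≥ 1.5 (inclusive); included lesions get a 50%
isocontour VOI: the 26-connected component holding the hottest seed voxel
(ties broken by lowest linear index) among voxels ≥ half that maximum,
searched within the seed bounding box padded by one voxel (a wider search
floods through noisy low-contrast backgrounds). Backgrounds default to a
3-voxel dilation shell around the lesion, clipped to the host organs.
CNR uses the population SD of the background (a convention that must be
fixed explicitly; sample SD would differ negligibly at these region
sizes). The Ki-image analysis reuses the SUV-derived VOIs, as lesions
are identified on SUV images. Image types are compared per lesion by
paired t-tests on log-transformed TBR/CNR; the reported "median ratio" is
the geometric mean exp(mean log-difference) — what the log-paired recipe
actually yields — with its t-based 95% CI.

## Numerical and scale choices

* Patlak images loop a shared line-fit kernel per voxel; the full default
  phantom (197k voxels) takes a few seconds.
* Simulation studies in the tests use 100 replicates (recovery bias,
  model selection) and the default phantom for visibility; these sizes
  give stable medians and proportions while keeping the whole suite at
  a few minutes.
* r² is defined as 1 on a zero-residual, zero-spread fit; on a
  numerically constant ordinate it is not meaningful and downstream code
  relies on slope/intercept only.
* The intermission (70–80 min) is simply absent from the schedule; fits
  and Patlak use only the frames that exist.

## Known limitations

* Indirect (image-space) Patlak only; direct reconstruction from raw data
  is out of scope, and no claim is made that the two agree quantitatively.
* No partial-volume correction anywhere; with the PSF enabled, IDIF peak
  and small-lesion uptake are biased low by construction.
* The AIC variant, weighting scheme and the decision to fit vB are
  explicit configuration; other choices shift ΔAIC values (not the
  qualitative behaviour under the defaults).
* At zero noise, model comparison through an interpolated IDIF measures
  interpolation mismatch rather than kinetics; the reversible model can
  absorb some of it. Comparisons are meaningful at realistic noise.
* Liver lesions are deliberately absent from the default phantom:
  spill-in from the hot liver makes their kinetics unreliable, and
  detectability claims there are not a goal.
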