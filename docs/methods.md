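# Methods

`navclust` implements three quantitative pipelines used to characterize the
nanoscale organization and gating of the cardiac sodium channel Nav1.5 in a
heterologous (HEK293F-type) expression system, together with seeded
synthetic-data generators that produce all three input kinds with known
ground truth. This note records the models, the defaults and why they were
chosen, the numerical choices, and what the synthetic data do and do not
establish about real recordings and images.

## Gating model

Whole-cell Na⁺ conductance follows the Hodgkin–Huxley m³h formulation. After
a voltage step at t = 0,

    G(t) = Ḡ · [m∞ − (m∞ − m₀) e^(−t/τm)]³ · [h∞ − (h∞ − h₀) e^(−t/τh)] + offset

with dimensionless activation (m) and inactivation (h) gates, time constants
τm, τh (ms), maximal conductance Ḡ (nS) and a residual leak-conductance
`offset`. Steady-state gate occupancies are two-state Boltzmann curves

    activation:    G/Gmax = 1 / (1 + exp((V½ − V)/k))
    inactivation:  G/Gmax = 1 / (1 + exp((V − V½)/k))

with the slope factor k stored positive and the direction carried by an
explicit sense flag (published tables are inconsistent about the sign of
inactivation k; the flag removes the ambiguity). Chord conductance is
G = I/(V − E_Na); recovery from inactivation is mono-exponential,
I_P2/I_P1 = 1 − exp(−t/τ) with half-time t½ = τ·ln 2 (an identity the code
maintains exactly); current decay is fit by y = −A₁e^(−t/τ₁) − A₂e^(−t/τ₂)
with τ₁ < τ₂ by relabeling. The slope factor maps to an effective gating
charge through k = RT/zF; RT/F is evaluated at 295.15 K (room-temperature
recording) unless overridden. The Nernst slope is exposed as a parameter
(default 58 mV/decade, the textbook room-temperature monovalent value)
rather than computed from an assumed temperature, because the usual
experimental practice quotes the 58 mV rule.

## Voltage protocols

All simulations and fits use the standard protocols: holding −120 mV;
activation, 50 ms steps from −90 to +35 mV in 5 mV increments (26 sweeps);
steady-state inactivation, 100 ms conditioning pre-pulses from −140 to
−50 mV followed by a 50 ms test pulse to −40 mV (19 sweeps); recovery, paired
−40 mV pulses with the interval incremented by 3 ms up to 72 ms (24
intervals). Sampling is 0.05 ms (20 kHz), a deliberate down-sampling of
typical acquisition rates that leaves all fitted quantities unchanged.

## Ephys generator: internal consistency choices

Three consistency properties cannot all hold simultaneously for a literal
m³h forward model, because inactivation proceeds during activation: the
measured peak conductance is below the full-activation value Ḡ·m∞³ by a
"shape factor" that depends on τm/τh. The generator makes the following
choices, each of which is load-bearing for the tests:

* Gate endpoints use the same convention the analysis later applies:
  m = (activation Boltzmann)^(1/3), h = inactivation Boltzmann. Noise-free
  τ fits with endpoints fixed this way invert the generator exactly
  (machine precision).
* The default τ curves are bell-shaped (qualitatively matching measured
  Nav1.5 kinetics: τm peaked mid-protocol at 0.2–1 ms, τh at 1–5 ms) and
  mutually proportional (τh = 5·τm). Proportionality keeps the peak-transient
  shape factor voltage-independent, so it cancels when the peak-conductance
  curve is normalized and the measured activation curve reproduces the
  Boltzmann exactly. With independently-shaped τ curves the measured
  activation curve is distorted by the voltage dependence of the shape
  factor — a real property of the peak-based method, but one that would make
  "generate at V½ = x, recover x" impossible. Users who want that distortion
  can pass any τ curves they like.
* Inactivation families start the test-pulse activation gate from its
  holding-potential value for every pre-pulse, so the test-pulse peak scales
  with availability h alone (the quantity the protocol reads out). Recovery
  families scale the P1 response by 1 − exp(−Δt/τrec), making the ratio
  identity exact by construction.
* `gmax_for_peak_density(target, cfg)` solves the (linear-in-gmax) analytic
  noise-free peak for a requested current density in pA/pF, which is how a
  condition with a stated peak density is configured.

Default condition parameters: Ḡ = 100 nS, E_Na = 19.58 mV, activation
(−42.62, 7.28) mV, inactivation (−96.14, 7.17) mV, C_m = 10.4 pF, additive
Gaussian current noise 20 pA. These are the values around which all
parameter-recovery experiments are run.

## Ephys fitting pipeline

Peaks are the largest-magnitude extremum per sweep, searched from 0.3 ms
after the step (capacitive-transient guard; leak subtraction and
series-resistance compensation are acquisition-side and out of scope).
Two robustness measures matter at realistic noise:

* For protocols whose sweeps share identical kinetics (availability,
  recovery; approximately, activation) a short boxcar (0.5–1 ms) precedes
  the extremum search. Without it, the |extremum| of pure noise puts a ~3σ
  floor under fully-inactivated sweeps, which inflates the fitted
  inactivation slope by ≈1 mV at 20 pA noise. The boxcar attenuation is
  common to all sweeps of a protocol and cancels in normalization.
* Activation conductance points within 10 mV of the fitted reversal are
  excluded: the chord conductance divides by the driving force and amplifies
  noise without bound there. (The singular point V = E_Na itself is guarded
  everywhere.)

Reversal is the linear interpolation of the I/V zero crossing on the limb
depolarized of the peak inward current. Boltzmann fits are trust-region
least squares with V½ initialized at the half-maximum crossing, k = 8 mV,
and k bounded to (0.5, 30) mV; flat input raises a degenerate-fit error
rather than returning an unbounded slope. τ fits hold the endpoints fixed
(cube-root convention above) with τ ∈ (0.05, 100) ms and a free offset; the
op holds Ḡ fixed by default. The per-cell orchestrator `analyze_condition`
frees the conductance scale in its τ fits because the only Ḡ it has is the
*measured peak* conductance, which understates the full-activation scale by
the shape factor (~4× at the default kinetics) and, if held fixed, forces
the optimizer to distort τm and τh by ~2× to compensate. Double-exponential
decay fits seed the slow component from a log-linear tail regression and
report small-sample AIC against a single-exponential fit of the same
segment. Condition comparisons use unpaired t tests.

## Localization microscopy

The movie localizer estimates per-frame background (median) and noise
(1.4826·MAD), takes 3×3 local maxima at least `snr_min` (default 6) noise
SDs above background as candidates, discards every candidate that shares a
`peak_mask` (default 9 px) window with another (multi-emitter rejection),
and fits an isotropic 2D Gaussian for sub-pixel position. Precision is
approximated as σ/√photons. Camera pixel pitch defaults to 100 nm. Drift is
estimated by sub-pixel phase cross-correlation of temporally binned 2D
localization histograms (20 nm bins) against the first bin, interpolated
linearly to per-frame shifts; the correction is therefore relative to the
first bin's mean position, and a static offset equal to the drift
accumulated within the first bin is not observable.

Cluster detection is density-reachability clustering (DBSCAN, defaults
eps = 20 nm, min_pts = 3) as a documented substitute for a Bayesian cluster
engine that is cited but not defined by the source analysis; it reports the
same per-cluster outputs (centroid, radius, occupancy). Cluster radius is
the RMS member-to-centroid distance, which for a planted Gaussian cluster
equals the generator's radius parameter. `percent_clustered` counts blinks,
not molecules; with multi-blink photophysics (default geometric, mean 3
blinks/molecule) monomer blink stacks are themselves dense and the blink
percentage saturates well above the molecular fraction — the blink
overcounting problem that molecular-counting corrections exist for and that
this package deliberately does not attempt. Recovery of a planted molecular
clustered fraction is therefore demonstrated at one blink per molecule.

Nearest-neighbor distances come from a k-d tree (exactly equal to the O(n²)
scan, by test), histogrammed at 2 nm; cluster radii at 5 nm; densities
normalized to unit area. The two-sample KS statistic is the sup-norm ECDF
difference over the merged sample; the p value is asymptotic via the
Kolmogorov distribution at √n_eff·D, n_eff = n_a·n_b/(n_a+n_b), with the
Stephens finite-sample correction (null p values are uniform by test); a
permutation p value is available. ROI rectangles are half-open in nm;
neighbors may lie outside an ROI: distances are computed on the full field
and reported points restricted to the ROI.

## PLA quantification

Channels are Gaussian-blurred (σ in voxels: DAPI 0.5, GFP 0.25) and
binarized with the triangle threshold, implemented explicitly: the
histogram peak is joined to the far end of the longer tail and the
threshold sits at the bin of maximal perpendicular distance to that chord
(cross-checked against the scikit-image implementation). Puncta candidates
are voxels equal to their 3×3×1 (x, y, z) maximum filter; a candidate is
kept when the (1,3,3)-median-filtered volume exceeds the local background —
the median over a (3,9,9) neighborhood — by at least the noise tolerance
(default 15, interpreted on an 8-bit scale). The median prefilter is what
makes the rule robust on Poisson backgrounds: single-voxel shot-noise spikes
vanish under it while multi-voxel puncta survive, and unlike a
surround-maximum rule it does not suppress adjacent dot pairs.

The signed Euclidean distance transform is measured to the set of boundary
voxels of the mask (mask voxels with a background neighbor): boundary
voxels are at distance 0, the sign is negative inside nuclei, and
anisotropic voxel sizes are respected. Cells are connected components of
the GFP mask of at least 200 voxels (smaller specks are noise); touching
cells are not split. Dots are assigned to the component containing them or
to the nearest component within 3 voxels, so membrane-proximal dots sitting
on the segmentation boundary still count. Dot intensity is the
background-subtracted sum within a 3-voxel-radius sphere. The
membrane-proximity readout is the fraction of in-cell dots within the
membrane margin (2 voxels) of the filled GFP mask boundary (filling removes
the nucleus hole, which is not membrane).

The stack generator renders ellipsoidal nuclei, cytoplasmic GFP shells and
Gaussian puncta (amplitude 100 over Poisson background 10, i.e. ≈31× the
background noise SD) on an 8-bit scale, placing 70% of dots within 2 voxels
of the cell boundary by the same Euclidean-distance metric the readout
uses, and separates cells by a 6-voxel buffer so segmented GFP volumes do
not touch.

## What the synthetic data do not show

The generators emulate protocol structure, noise statistics and geometry,
not biology: currents have exactly m³h kinetics (no gating-mode shifts, no
rundown, no series-resistance error), blinking is Bernoulli with no
photophysical correlations or duty-cycle structure, PSFs are isotropic
Gaussians without aberrations, and cells are ellipsoids. Passing
parameter-recovery tests therefore shows that the estimators are correct
and unbiased under their stated model, not that the model captures every
systematic error of real acquisitions. Frame counts, laser duty cycles and
ROI sizes are free parameters, not literature values.

## Problem sizes

The test suite and the acceptance script run at desk scale: 100-seed
repetitions for the Boltzmann and τ recovery experiments, ~10⁴ points per
condition for the nearest-neighbor/KS comparison, 8–20 cells per simulated
stack or condition, and 12×160×160 to 12×340×340-voxel stacks. All were
chosen so a full run completes in a few minutes on one core while keeping
median recovery errors well inside the stated tolerances.
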