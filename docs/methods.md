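# Methods

This note records the models, conventions and numerical choices behind
`deepmeg`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Forward model: spherical conductor

Magnetometer lead fields use the closed-form solution for a current
dipole in a homogeneous conducting sphere. The analytic sphere replaces
realistic (BEM/FEM) head models deliberately: it has the same algebraic
structure for every scan the package performs (a 3-column gain block per
grid point) while providing exact invariants for testing — a radial
dipole moment is externally silent, the field is linear in the moment,
and the radially-projected field equals the bare Biot–Savart field of the
primary current (volume currents contribute no radial component). These
identities are asserted to near machine precision in the test suite.
Defaults: sphere radius 0.09 m centred at the origin; helmet of radially
oriented magnetometers on a Fibonacci-lattice spherical cap of half-angle
2.0 rad at radius 0.105 m. Because the radial gain column is null, every
3-column block has effective rank 2; all fits use an eigendecomposition
pseudo-inverse with relative cutoff 1e-10, and grid points whose rank
falls below 2 are flagged.

Units are fixed throughout: meters for geometry, A·m for dipole moments,
femtotesla for fields, µV for SEEG.

## Synthetic sessions

The generator emulates the statistical structure that the analysis
relies on, with known ground truth:

- **Sources.** Interictal spikes from structure-labelled dipoles
  (hippocampus at 3.2 cm from the centre, thalamus at 2.4 cm, lateral
  temporal neocortex at 6.9 cm in the presets), tangentially oriented by
  default. The spike template is a biphasic sharp transient (σ = 15 ms)
  followed by a slow wave, normalised to +1 at its global extremum — the
  sample a reviewer would mark. Over 90% of its spectral energy lies
  below 60 Hz.
- **Events.** Spikes arrive at 30/min (exponential intervals with a
  0.8 s refractory gap) over a default 120 s session, i.e. roughly 60
  events — inside the tens-to-low-hundreds range of marked spikes per
  session the analysis is designed for. Each event draws one co-activation
  subset (all members fire at zero lag) and an independent lognormal
  amplitude factor (σ = 0.3); this across-trial amplitude co-fluctuation
  is what the ITCOR stage detects.
- **Amplitude regime.** Deep sources default to 20 nA·m. The ongoing
  background — 20 superficial tangential dipoles oscillating at 10 Hz
  under slow (< 0.5 Hz) amplitude envelopes — is scaled so its RMS at the
  deep source's best sensor is 3× the deep source's peak deflection
  there, plus 15 fT white and 15 fT 1/f sensor noise. This reproduces the
  regime of interest: the deep signal is present at the sensors but
  hidden under concurrent activity (concurrent SNR well below the 10 dB
  visibility threshold), yet separable by ICA.
- **SEEG.** Bipolar channels are modelled as direct noisy reads of their
  structure's source (300 µV spike peak, 30 µV 1/f + 10 µV white noise;
  cross-structure leakage configurable, default 0, since a bipolar
  montage suppresses volume conduction). The synthetic implantation
  places one electrode per source structure (deepest three contacts
  gray with the structure's label, middle contacts white, outer contacts
  gray "other") plus filler electrodes, giving ~40–130 bipolar channels
  depending on configuration.
- **Clocks.** The SEEG time base is offset (0.5–1.5 s) and drifted
  (±20 ppm) relative to MEG; shared triggers with 3.0–3.5 s jittered
  spacing are emitted in both bases. `align_clocks` recovers the affine
  map by least squares to machine precision on these noiseless triggers;
  markers are emitted in the SEEG clock and mapped to MEG time through
  the fitted model, exactly as real co-registration would.

What the generator does **not** emulate: realistic cortical geometry and
orientation dispersion, physiological artifacts (cardiac, ocular,
muscle), non-stationary background spectra, propagation delays within
networks, or SEEG contact localization error. Passing tests therefore
demonstrate the correctness and calibration of the machinery under the
stated statistical structure, not clinical performance on patient data.

## Preprocessing and ICA

Conditioning is a zero-phase FIR band-pass (1–170 Hz, Hamming firwin,
transition ≈ 1 Hz, applied by centred FFT convolution so the symmetric
taps introduce no delay; taps are mean-corrected to place an exact null
at DC) followed by polyphase resampling to 512 Hz. The two analysis
bands, 2–60 Hz and 12–60 Hz, use the same construction. Epochs are the
closed window [−0.3, +0.3] s around each marker — 2·⌊0.3·fs⌋+1 = 307
samples at 512 Hz, odd so the marker falls on the centre sample
(nearest-sample mapping; markers are instantaneous and sub-sample timing
is not used downstream).

The decomposition is negentropy-based fixed-point ICA (FastICA, logcosh
contrast, symmetric decorrelation, tolerance 2e-5) after PCA whitening to
exactly 20 dimensions. Symmetric rather than deflationary updates were
chosen for convergence robustness at 20 components; the variant is
recorded in run provenance. ICA's indeterminacies are absorbed by
convention: unit-norm topographies with the maximal-|weight| sensor
positive, variance carried by the time course, components ordered by
decreasing time-course power. Channels that are flat or exceed 20× their
own robust scale (1.4826·MAD) are dropped before the fit.

## Coupling statistics

Temporal correlations are pooled per decomposition (all component ×
channel pairs), Fisher-transformed, and thresholded at lfdr ≤ 0.2,
two-sided (SEEG polarity is montage-dependent). The local FDR uses an
empirical null: the histogram (up to 120 bins, proportionally fewer for
small pools) is smoothed by Poisson regression on a Legendre polynomial
basis with the **degree chosen by BIC over 2..7** — a pure-null histogram
retains its Gaussian (quadratic log-density) shape, so a lone extreme
order statistic cannot carve its own bump into the density estimate and
flag itself, while genuine signal mass earns the additional degrees. The
null parameters (μ₀, σ₀, π₀) come from central matching: a weighted
quadratic fit to the smoothed log density over the central 50% of the
data. Truncated maximum likelihood on the central values was implemented
first and abandoned: its likelihood is nearly flat in σ at realistic
pooling sizes (hundreds of values) and the estimates ran to bounds.
Measured behaviour of the final estimator: 0 discoveries on 10⁴ standard
normal draws across seeds; ≥ 99% power on a 5% N(6,1) mixture with ≤ 0.3%
null flags; a single z = 10 outlier among 10³ nulls is flagged.

ITCOR correlates component and channel amplitudes across trials at each
peri-spike time point, pooling (channel × time) values per component.
Because tens of trials give the Fisher transform visibly
heavier-than-Gaussian tails, the trial-dimension statistic is mapped
through its exact null instead — t = r·√((n−2)/(1−r²)) ~ t₍n−2₎, then the
probit of its CDF — so the pooled values are exactly standard normal
under independence and the empirical-null machinery stays calibrated at
any trial count (false-selection rate measured ≈ 3% of runs against the
5% design target; ~60% before the correction). η per the printed
transform is still recorded in the results table.

Selection requires: at least one lFDR-significant temporal channel, a
significant ITCOR time within ±50 ms of the anchor on such a channel
(the operational form of "the correlated activity corresponds to the
same period"), and averaged-waveform peak alignment within 10 ms (the
zero-lag check; the component's best channel is its highest-|r| doubly
significant channel). The three-stage battery replaces multi-reviewer
visual screening; provenance records it as automated screening.

## Localization

The single-dipole scan fits the 3-column gain at every grid point by
least squares; GOF = 1 − RSS/TSS. The confidence region keeps all points
with GOF ≥ max GOF − (1 − max GOF) — implemented with "≥" and the argmax
always included, since a strict ">" would exclude the point estimate
itself whenever max GOF = 1. Validity requires max GOF > 0.75. The
two-dipole scan enumerates grid-point pairs (6-column joint fits, grids
capped at 600 points for pair enumeration), retains pairs in the top 5%
of F = ((RSS₁ − RSS₂)/3)/(RSS₂/(n_sensors − 6)) — RSS₁ being the better
member's single fit — that also satisfy the confidence-interval
condition with validity GOF > 0.8, and accumulates a per-point score map.
Pairs whose midpoint out-fits both members are flagged as potential ghost
sources but not auto-excluded. Default grid spacing is 7.5 mm (10 mm in
the desk-scale studies); the scan region stays within 90% of the sphere
radius.

Verdicts use a synthetic spherical atlas (deep ball ≤ 4.5 cm = "mesial",
shell ≥ 5.5 cm = "lateral") and count the correlated structure as inside
the confidence region when it lies within one grid spacing of a member
point. Contingency rates are column-normalised (per localized class) and
displayed truncated, not rounded, to two decimals.

## Visibility

Background SNR is 20·log₁₀ of the averaged peak (±50 ms window, endpoints
inclusive at sample resolution) over the standard deviation of the same
averaged trace across the concatenated baseline segments
[−0.3, −0.05] ∪ [0.05, 0.3] s. Using the SD of the *averaged* baseline —
rather than the mean of per-trial SDs — is deliberate: it is the choice
under which averaging n events raises the SNR of an event-locked signal
by ~10·log₁₀(n), the behaviour the visibility-curve analysis depends on.
Concurrent SNR divides the same peak by the peak of the averaged residual
(sum of all other components) on the same sensor and window. Visibility
is SNR ≥ 10 dB (an amplitude ratio of ≈ 3); the bootstrap draws event
subsets without replacement (50 draws per count, counts in steps of 5)
and reports the smallest count at which ≥ 75% of draws are visible, or a
"not visible" sentinel. Note the max-over-window statistic is positively
biased at low SNR (the maximum of ~51 baseline-level samples), which is
inherent to the definition; tests account for it.

## Validation studies and problem sizes

The seeded studies run the full pipeline at desk scale: 64–96 sensor
helmets, 80–120 s sessions (≈ 40–60 spikes), 6–8 electrode montages,
10 mm scan grids. The localization-recovery study uses the triggered
12–60 Hz combination: the 2–60 Hz band retains the strong 10 Hz
background whose finite-sample covariance with a weak component's time
course contaminates mixing-column topographies (the time course is
recovered at r ≈ 0.9 while the topography degrades — a known property of
covariance-based mixing estimates), whereas the 12–60 Hz band excludes
the rhythm entirely and yields near-perfect topographies. Running two
bands exists in the design precisely because low frequencies can dominate
transient analysis. Measured at 50 scenarios: 98% of valid maps localize
within 1.5 grid spacings of the true source (median error ≈ 6 mm);
confidence-interval coverage 100% at 10% topography noise; 100 source-free
sessions select nothing; and in the 2–60 Hz mesial run the deep component
is concurrent-invisible (≈ 1 dB) but background-visible (≈ 18 dB) after
separation.

## Known limitations

- The sphere forward model cannot represent orientation-dependent
  sensitivity of realistic cortex; radial sources are exactly silent
  rather than merely attenuated.
- Continuous-mode ICA on short synthetic sessions sees fewer effective
  samples per source than a 10–30 min clinical recording; its selection
  power is correspondingly lower than triggered mode.
- lFDR calibration assumes the pooled set is dominated by null pairs;
  montages where most channels genuinely couple to sources would violate
  the central-Gaussian assumption.
- The ITCOR exact-null mapping assumes across-trial independence under
  the null; slow drifts spanning many inter-spike intervals could
  violate it.
- Two-dipole scans are enumerated, limiting pair grids to coarse
  spacings; no gradiometer support (magnetometers only, which are the
  more depth-sensitive sensor type).
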