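# Methods

This note documents the models, estimators and numerical choices behind
`axonatp`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the procedures were genuinely open.

## 1. TCSPC decay model and the moment lifetime

The recorded per-pixel histogram i(t_k) is modelled as the convolution of
a sum of m exponential decays (amplitudes A_j, lifetimes tau_j) with the
instrument response function h(t).  The average lifetime

    tau_bar = sum_j A_j tau_j / sum_j A_j

is estimated without fitting, from the moment identity

    tau_bar = F1/F0 - H1/H0,

with F0 = sum_k i(t_k), F1 = sum_k t_k i(t_k) over the
(background-corrected) decay and H0, H1 the same moments of the IRF.

Numerical conventions:

* **Bin-centre times.** t_k is the centre of bin k.  The centre
  convention minimises the first-moment discretization bias: for an
  exponential binned at width D the bin-centre mean is
  D/(e^(D/tau) - 1) + D/2 = tau (1 - D^2/(12 tau^2) + ...), i.e. the
  27 ps nominal bin contributes < 1e-4 ns of bias at nanosecond
  lifetimes.
* **Background.** A constant per-bin background can be subtracted before
  the F-moments; `background="auto"` estimates it from the bins preceding
  the decay rise (below 5% of the maximum).  The default is 0 — whether
  the original acquisition software subtracted background is unknown, so
  the estimator is explicit and configurable rather than silent.
* **Finite window.** Moments are computed over the recorded window only,
  with no tail extrapolation.  The estimator is unbiased only when the
  window is long compared to the lifetimes; at an 80 MHz repetition rate
  (12.5 ns period) a ~1.5 ns decay loses a small tail fraction and
  wrapped photons further compress the estimate by a few percent.  This
  bias is monotone in tau, so genotype *orderings* and anchor-based
  normalizations are preserved; tests that need unbiased absolute values
  use a 100 ns window at a lower repetition rate.

## 2. Phasor analysis

The phasor transform maps a histogram to
(g, s) = (<cos>, <sin>) at the repetition frequency, phase-corrected by
the mean IRF arrival time delta_IRF = H1/H0.  The correction is
implemented exactly as a time shift — not as complex division by the IRF
phasor; a full-deconvolution variant was deliberately left out of scope
because the shift form is what the moment estimator pairs with.

For an ideal mono-exponential decay, with x = 2 pi f_r tau:
g = 1/(1+x^2), s = x/(1+x^2).  These satisfy the exact identity
(g - 1/2)^2 + s^2 = 1/4: the mono-exponential locus is the universal
semicircle centred at (0.5, 0).  Note the constant 0.25 conventionally
quoted for this semicircle is the *squared* distance from the centre
(the Euclidean radius is 0.5 — the tau = 0 point (1, 0) is 0.5 from the
centre).  `semicircle_distance` therefore returns the squared form by
default and the Euclidean distance with `squared=False`.  s is maximal
(0.5) at tau = 1/(2 pi f_r) — about 1.99 ns at 80 MHz, conveniently near
CFP-donor lifetimes — and g decreases strictly with tau, so a shift
toward lower g reads as a lifetime increase (less ATP).

## 3. Multi-exponential fitting

`fit_multiexp` fits the discrete convolution of an m-component
exponential mixture (m = 1..3) with the normalised IRF histogram by
least squares, with Poisson-appropriate weights (residuals divided by
sqrt(max(counts, 1)), which reduces to plain least squares at high
counts).  The exponential kernel entry k integrates the exact density
over [(k-1/2)D, (k+1/2)D] so that discrete-convolution index arithmetic
stays aligned with the bin-centre time convention.  Start values come
from the moment estimate (lifetimes spread geometrically around tau_bar,
equal fractions); amplitude fractions are parameterised by softmax logits
and lifetimes by logs, keeping the parameters unconstrained.
Non-convergence is reported via `FitResult.success` and the optimizer
message — never silently.  Only the amplitude-weighted mean lifetime is
reliably identifiable when the model order exceeds the true one.

## 4. Axon-level variability statistics

Per-pixel lifetime maps mask out pixels below a minimum photon count
(default 100; at N photons the estimator SD is ~tau/sqrt(N)).  Within-axon
CV is SD/mean of the valid pixels of one axon; across-axon CV is the CV
of the per-axon means (two-stage).  Throughout, sample (n-1) standard
deviations are used — the natural choice at 8-10 axons per nerve.  Axons
with fewer than `min_pixels` valid pixels (default 50) are excluded with
a logged warning; invalid pixels are excluded, never imputed.  Group
comparisons wrap the standard tests (pooled-variance t, Welch, one-way
ANOVA + Tukey HSD, Kruskal-Wallis + Dunn's rank z tests; Dunn's test is
implemented directly from the rank-sum statistic with tie correction).

## 5. Ratio normalization and kinetics

The F/C ratio is normalized affinely so that the baseline-epoch mean maps
to 1 and the MB+GD anchor to 0.  Open parameters and the choices made:

* **MB+GD anchor window**: mean of the final 2 min of the MB+GD epoch
  ("end of experiment" without a stated window).
* **Baseline anchor**: mean over the entire annotated baseline epoch
  (nominally the initial 15 min).
* **Slope window**: 5 samples (~52 s at the 10.4 s frame interval) for
  all sliding-window linear regressions; trailing windows, uniform
  sampling assumed.  Echoed into every report manifest.
* **Onset threshold**: k = 3 times the SD of the baseline-epoch windowed
  slopes.  The onset criterion is applied to the *slope* by default; a
  value-threshold variant is available via `mode="value"` since the
  original wording is ambiguous between the two.  A not-detected onset
  returns nan rather than raising.
* **Rates**: the reported decay/recovery rate is the windowed slope of
  maximal magnitude within the queried epoch, sign retained.  On an
  exponential with time constant tau the trailing-window estimate at the
  steepest point is biased low by roughly a factor W/(2 tau) (W = window
  span); with W = 52 s and GD time constants of several hundred seconds
  this is < 10%.
* **Ramp levels**: per-frequency means over the final 15 s of each 30 s
  stimulation step.

CAP-area series are normalized with the same two-point convention
(baseline-only scaling when no MB+GD epoch exists).  The CAP integration
window runs from the first post-blanking threshold crossing (fallback
0.2 ms) to the first trough after the second peak (fallback window
0.2-1.7 ms, logged); the first 0.15 ms are blanked for the stimulus
artifact; the baseline voltage is the mean of the 0.5 ms before the
stimulus; areas integrate the signed excursion above baseline (a
rectified variant is available, since signed-vs-rectified is not
specified by convention).  Peak detection uses a prominence of 5 x the
pre-stimulus noise SD with a small absolute floor for noiseless traces.

## 6. ATP-lifetime calibration

Patch-clamp calibration data (lifetime vs dialysed ATP at
0, 1, 2, 4, 6, 10, 24 mM) are fitted with a Hill-form saturating curve
tau(c) = tau_max - (tau_max - tau_min) c^n/(K^n + c^n).  No functional
form is canonical for this sensor; Hill is the standard choice for
binding-protein biosensors and inverts in closed form.  The inverse is
only defined strictly inside (tau_min, tau_max) — out-of-range lifetimes
raise rather than extrapolate — and emits a `TransferabilityWarning`
unless the caller asserts the same cellular context: absolute lifetimes
differ between calibration cells and tissue, so no absolute axonal ATP
concentration is ever claimed.  Since no replicate-level calibration
values are published as text, the module ships with synthetic defaults
only.

## 7. The synthetic-data generator

The generator emulates the four input families at the study's stated
acquisition conditions: 80 MHz repetition rate, 27 ps TCSPC bins, a
Gaussian IRF (shape unstated in the original setup; Gaussian is
conventional and analytically tractable), 0.192 um pixels, the 10.4 s
confocal frame interval, 20 kHz CAP sampling, the
1/4/7/15/25/50/75/100 Hz x 30 s ramp, and the 15/30/45 min
baseline/GD/reperfusion protocol with a terminal MB+GD period.

* **Decays**: photons drawn per component (probability A_j/sum A),
  exponential arrival, additive IRF jitter, optional wrap modulo the
  recorded window (default on at 80 MHz: the window is the floor-multiple
  of the bin width inside the laser period, and wrapping modulo the
  window keeps photon conservation exact).  A noiseless expectation mode
  returns exact expected counts via the same integrated kernel as the
  fitter.
* **Scenes**: axons are parallel stripes (stand-ins for manual
  segmentation masks); per-axon means drawn with the across-axon SD,
  pixels with the within-axon SD, per-pixel photon numbers Poisson.
* **Ratio traces**: a piecewise latent trajectory (baseline plateau at 1;
  exponential decay during GD and stimulation steps; a hold-then-
  exponential recovery after reperfusion; linear collapse to exactly 0
  during MB+GD, which makes the zero anchor exact) is mapped affinely to
  a raw ratio and realised as FRET = ratio x CFP with constant CFP —
  absolute channel intensities are unconstrained in this design because
  only the ratio matters.  Channel noise is additive Gaussian; the
  default fraction (0.003 of the channel level, ~1% of the normalized
  trace) matches the smoothness of ensemble-averaged ratio recordings.
  YFP is constant up to noise, with an optional drift flag for QC tests.
* **CAP waveforms**: two positive Gaussian lobes, a small negative lobe
  marking the end-of-second-peak trough, a biphasic stimulus artifact
  inside the blanking interval, closed-form (erf) areas for oracles.
  Excitability sweeps scale the amplitude by a Hill recruitment curve of
  stimulus intensity.

Genotype scenario defaults mirror the qualitative two-group contrast the
experiments address — control vs null-like: mean lifetime 1.45 vs 1.55 ns,
within-axon SD 0.058 vs 0.093 ns, across-axon SD 0.044 vs 0.078 ns;
GD decay time constants 400 vs 600 s, recovery onset delays 180 vs 60 s,
recovery plateaus 0.607 vs 0.82 of baseline.  The lifetime means, CVs and
time constants are *assumptions chosen to produce a realistic contrast of
the right sign and rough magnitude*, not reproductions of published
per-group values (which are not printed as text); the recovery plateaus
are the one pair taken directly from the reported percentages, used as
scenario parameters.

What the generator does **not** emulate: optics (no PSF, no confocal
sectioning), photobleaching, detector dead time or afterpulsing, pH or
autofluorescence contamination (the emulated noise is purely statistical),
axon morphology beyond stripes, or any selection effects of manual
segmentation.  Passing tests therefore demonstrate that the *estimators
and statistics* behave correctly under the assumed data model — not that
the model captures every property of real tissue recordings.

## 8. Problem sizes and reproducibility

All randomness flows through one explicitly passed numpy Generator;
identical seeds give identical datasets and byte-identical report tables.
Recovery and ordering checks run on deliberately scaled-down scenes
(axon segments of ~21-42 pixels, 400-800 photons per pixel, 8 nerves per
group, 20 seeded ensembles) — sizes chosen so the whole suite documents
the statistical behaviour at desk scale while the estimators themselves
are size-agnostic.  The CLI writes a run manifest (config snapshot, seed,
package version, every analysis parameter, output checksums) so that any
reported number can be traced to its inputs.

## 9. Known limitations

* The moment estimator inherits the wrap/truncation bias at 80 MHz
  described above; absolute lifetimes from short-period acquisitions are
  a few percent low, consistently across groups.
* `fit_multiexp` fits one pixel/ROI at a time; there is no global
  multi-pixel fitting, no anisotropy and no FRET-efficiency model beyond
  the donor-lifetime readout.
* Axon segmentation is an input (the original masks were manual); no
  automatic segmentation is attempted.
* Whether "binned 4 times" in the original acquisition refers to temporal
  or spatial binning is ambiguous; the simulator exposes bin width and
  scene geometry independently so either reading can be configured, and
  neither is asserted as the original intent.
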