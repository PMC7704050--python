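# axonatp

Analysis pipeline for measuring axonal ATP in electrically active,
ex vivo nerve preparations (e.g. mouse optic nerve) that combine three
readouts of the same tissue:

* **two-photon FLIM/TCSPC** of the donor fluorophore of a genetically
  encoded FRET ATP sensor (ATeam family) — ATP binding raises FRET and
  *shortens* the donor lifetime, so a longer lifetime means less ATP;
* **confocal ratiometric imaging** of the same sensor — the FRET/CFP
  intensity ratio (F/C) tracks relative ATP over hour-long perfusion
  protocols (baseline, stimulation ramps, glucose deprivation,
  reperfusion, terminal mitochondrial blockade);
* **compound action potential (CAP) electrophysiology** — nerve function
  quantified as the area under the stimulus-evoked waveform.

The package is aimed at labs doing white-matter energy-metabolism
experiments who need the downstream numerics to be reproducible and
testable without access to a rig: a synthetic-data module generates every
input family from a seed, with known ground truth.

## The core quantities

**Moment lifetime.** The recorded TCSPC histogram is the convolution of a
sum of exponential decays with the instrument response function (IRF)
h(t).  The intensity-weighted average lifetime is estimated fit-free from
histogram moments:

    tau_bar = F1/F0 - H1/H0

where F0, F1 are the 0th/1st moments of the decay and H0, H1 those of the
IRF (H1/H0 = delta_IRF, the mean IRF arrival time).

**Phasor analysis.** Each decay maps to one point

    g = sum_k i(t_k) cos[2 pi f_r (t_k - delta_IRF)] / sum_k i(t_k)
    s = sum_k i(t_k) sin[2 pi f_r (t_k - delta_IRF)] / sum_k i(t_k)

at the laser repetition frequency f_r.  An ideal mono-exponential decay
with lifetime tau sits at g = 1/(1+(2 pi f_r tau)^2),
s = 2 pi f_r tau/(1+(2 pi f_r tau)^2), on the universal semicircle
(g-1/2)^2 + s^2 = 1/4; mixtures fall inside it.  Lifetime increases move
points counter-clockwise (toward lower g).

**Variability statistics.** From a pixel-wise lifetime map and an axon
label mask: the within-axon CV (SD/mean of the pixels of one axon) and
the across-axon CV (CV of the per-axon mean lifetimes of one nerve) — the
two-stage procedure.

**Ratio and CAP kinetics.** F/C traces are normalized to two anchors:
baseline mean = 1 and the terminal plateau under mitochondrial blockade +
glucose deprivation (MB+GD, full ATP depletion) = 0.  Kinetic parameters
are read off with sliding-window linear regression: maximal decay/recovery
rate, onset delay of recovery (first slope crossing of k x baseline-SD),
recovery amplitude, and per-frequency levels over the last 15 s of each
stimulation step.  CAP areas use a data-driven window from the response
onset (~0.2 ms post-stimulus) to the trough ending the second peak.

## Worked example

```python
import numpy as np
from axonatp import (SimConfig, GenotypeModel, gen_flim_scene,
                     pixel_lifetime_map, AxonSegmentation, nerve_summary)

cfg = SimConfig(seed=1, photons_per_pixel=800)        # 80 MHz, 27 ps bins
geno = GenotypeModel(mean_lifetime=1.45, within_axon_sd=0.058,
                     across_axon_sd=0.044, n_axons=8, axon_length_um=8.0)
scene = gen_flim_scene(geno, cfg)
lt = pixel_lifetime_map(scene.counts_image(), cfg.bin_times, scene.irf,
                        min_photons=100)
summ = nerve_summary(lt, AxonSegmentation(scene.labels), min_pixels=20)
print(f"whole-nerve tau_bar = {summ.whole_nerve_tau:.3f} ns")
print(f"mean within-axon CV = {summ.within_cv.mean():.4f}")
print(f"across-axon CV      = {summ.across_cv:.4f}")
```

prints (seed 1):

```
whole-nerve tau_bar = 1.442 ns
mean within-axon CV = 0.0516
across-axon CV      = 0.0254
```

The whole-nerve mean sits slightly below the configured 1.45 ns because
photons arriving later than the 12.5 ns laser period wrap around at
80 MHz, mildly compressing the moment estimate (a shared, order-preserving
bias; see `docs/methods.md`).  The within-axon CV (0.052) combines the
configured biological spread (0.04) with photon-limited estimator noise;
the across-axon CV reflects the draw of 8 axon means at SD 0.044.

The same library drives a CLI:

```bash
axonatp simulate --seed 1 --out dataset/
axonatp analyze dataset/
axonatp phasor-plot dataset/
```

which writes per-axon and per-nerve CSV tables, kinetics summaries,
excitability curves, group tests, a phasor figure, and a manifest echoing
every parameter that affects a reported number.

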