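# gbpct — self-supervised denoising for grating-based phase-contrast CT

Grating-based phase-contrast CT (gbPC-CT) adds a Talbot–Lau
interferometer to a conventional CT and measures, besides the usual
attenuation, the refraction of X-rays in the sample — the differential
phase, proportional to the transverse derivative of the projected
refractive-index decrement δ (and thus to electron density).  The phase
signal offers superior soft-tissue contrast, but integrating it during
reconstruction concentrates noise power at *low* spatial frequencies,
where smoothing filters are useless and where noise interferes most with
anatomy.  At clinical doses this low-frequency noise is the main obstacle
to medical use of gbPC-CT.

`gbpct` is an analysis pipeline that studies this problem end to end on
simulated data, with Noise2Inverse (N2I) — a self-supervised CNN denoiser
that needs nothing but the one noisy scan it is applied to — as the
centrepiece:

* **Simulation** — soft-tissue phantoms (water bath, tissue classes, thin
  fiber probes) and phase-stepping acquisitions with a sinusoidal
  stepping curve per pixel, configurable fringe visibility, and Poisson
  photon noise.
* **Signal retrieval** — closed-form sinusoid fits giving transmission
  `T = a_s/a_r` and differential phase `φ = φ_s − φ_r`, including the
  patchwise (PPR) variant that pools neighborhoods to trade resolution
  for noise.
* **Reconstruction** — filtered back projection with a Ram-Lak filter
  (attenuation coefficient) or a Hilbert filter that integrates the
  differential phase (electron density), with exact angle-subset
  handling.
* **Noise2Inverse** — interleaved sinogram splitting, X:1 training of a
  small dilated CNN (numpy, hand-written backprop), reference-guided
  model selection, split-averaged inference.  For a frozen network,
  self-supervised loss = ground-truth loss + noise variance; splitting
  by projection angles makes the subset noise independent, which is what
  lets a network train against noisy targets as if they were clean.
* **Evaluation** — PSNR (peak = sup-norm of the reference), canonical
  SSIM, Canny-based edge-preservation ratios EPRa = |R∩D|/|R| and
  EPRr = |R∩D|/|D|, aggregated per slice stack as mean ± std; radially
  averaged noise-power spectra P(k) of empty-beam reconstructions.

The two scripted studies mirror the questions the pipeline exists to
answer: how many sinogram splits should N2I use per signal type, and how
does N2I compare against FBP, PPR and Gaussian blurring — including why
blur cleans the attenuation image but leaves the electron density noisy
(the NPS tells the story).

## Worked example

```python
import numpy as np
from gbpct import (AcquisitionGeometry, make_phantom, simulate_stepping,
                   retrieve, reconstruct_attenuation)
from gbpct.phantom import make_phantom_stack
from gbpct import n2i
from gbpct.iqa import psnr

# an 8-slice marbled-tissue phantom in a water bath, double-sampled scan
phantom = make_phantom_stack(8, (64, 64), seed=7)
geometry = AcquisitionGeometry(n_angles=200, seed=3)   # low-dose preset
scan = simulate_stepping(phantom, geometry, noise=True)
sino = retrieve(scan)

noisy = reconstruct_attenuation(sino).data
splits = n2i.make_split_set(sino, 4, "attenuation")
run = n2i.train_and_select(n2i.make_training_pairs(splits), splits,
                           phantom.mu, seed=11)
denoised = n2i.denoise(run, splits).data

print(f"noisy FBP : {psnr(noisy, phantom.mu):5.2f} dB")
print(f"N2I (K=4) : {psnr(denoised, phantom.mu):5.2f} dB")
```

Output (about three minutes on one CPU):

```
noisy FBP : 16.39 dB
N2I (K=4) : 20.45 dB
```

The denoiser, trained only on the noisy scan itself, gains ~4 dB over
the filtered back projection; PSNR is measured against the known phantom.

The numbered drivers under `analysis/` run the full studies and write
their tables under `results/`:

```bash
python analysis/01_split_count_study.py      # N2I with 2 vs 4 splits, both signals
python analysis/02_denoiser_comparison.py    # FBP / PPR / blur / N2I + NPS analysis
python analysis/03_noise_power_spectra.py    # ramp vs Hilbert noise, blur effect
```

The same functionality is exposed as a CLI (`gbpct simulate|retrieve|
reconstruct|denoise|iqa|nps|experiment ...`) for running stages on files.

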