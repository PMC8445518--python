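# tofmix

Statistical TOF-PET simulation and list-mode reconstruction with
**Gaussian-mixture coincidence timing kernels**.

BGO crystals read out with fast SiPM electronics detect a handful of
prompt Cherenkov photons on top of the ordinary scintillation light.
Because the Cherenkov yield fluctuates event by event, such a detector
pair has no single coincidence timing resolution: events fall into
timing categories, and the time-difference distribution of each
category is well described by a **zero-mean two-component Gaussian
mixture** — a narrow "fast" component (Cherenkov-rich events) and a wide
"slow" component — mixed with an abundance weight α:

    p(Δt) = α · N(Δt; 0, σ_F) + (1 − α) · N(Δt; 0, σ_S)

`tofmix` is a desk-scale toolkit for studying what this does to image
reconstruction. It provides:

- a packaged bank of 25 such timing categories (fast/slow FWHM and
  abundance per category) plus sampling, density/CDF evaluation, and
  zero-mean EM refitting of mixtures;
- a statistical Monte Carlo simulator: decays sampled from a voxelized
  phantom, back-to-back photons traced to an idealized crystal
  cylinder, and the timing spread applied **per coincidence pair** (the
  kernel category and the fast/slow component actually used are stored
  in each list-mode record);
- list-mode TOF-MLEM reconstruction whose per-voxel TOF weight is the
  CDF difference of the event's kernel across a 1-ps TOF bin,

      K = (1−α)[cdf_S(k_{t+1}−v′) − cdf_S(k_t−v′)] + α[cdf_F(k_{t+1}−v′) − cdf_F(k_t−v′)]

  with modes for per-event mixture kernels, one fixed mixture kernel,
  the *decomposed* variant (the exact Gaussian component recorded for
  each event), a plain single Gaussian (LYSO-like, 213 ps), and non-TOF;
- the NEMA image-quality phantom and metric suite (CRC, background
  variability, CNR, half-diameter bias) used to compare the models.

It is written for researchers in tomographic reconstruction who want a
small, fully inspectable sandbox for multi-kernel TOF weighting rather
than a clinical-scale engine: the default geometry is a single detector
ring of 360 crystals and a 128 × 128 grid of 2-mm voxels, so a full
simulate–reconstruct–analyze study runs in minutes on one core.

## Worked example

Sample one million coincidence time differences from timing category 13
of the packaged bank and refit the zero-mean mixture by EM:

```python
import numpy as np
import tofmix as tm

bank = tm.load_bgo_cherenkov_bank()
k13 = bank.get(13)                      # FWHM 213.8 / 781.1 ps, alpha 0.427
dt, is_fast = tm.sample_delta_t(k13, 1_000_000, np.random.default_rng(1))
fit = tm.fit_two_gaussian_mixture(dt)
print(fit.kernel.fast.fwhm_ps, fit.kernel.slow.fwhm_ps, fit.kernel.alpha_fast)
```

prints

```
213.87669913129886 781.1671422426193 0.4276115444351736
```

i.e. the fitted fast FWHM (213.88 ps), slow FWHM (781.17 ps) and fast
abundance (0.4276) recover the category's input parameters (213.8,
781.1, 0.427) to a fraction of a picosecond — the sample-and-refit
fidelity the simulator is built on. The overall mixture has
`tm.mixture_fwhm(k13) ≈ 265.1` ps, between its two components.

A full desk-scale study (simulate five noise realizations of the NEMA
phantom per timing model, reconstruct all model pairs, tabulate CRC/BV/
CNR at the marker iterations) runs from the shell:

```bash
tofmix study --duration 20 --realizations 5 --seed 0 --out study_out/
tofmix simulate --timing mch --duration 20 --seed 1 --out run.lm
tofmix reconstruct --listmode run.lm --model mch --iters 40 --out recon_out/
```

Typical desk-scale behavior mirrors the full-scale findings
qualitatively: the single-Gaussian model converges in fewer iterations
than the mixture-kernel models at matched counts, while the
mixture-bank dataset acquired at a 1.52× count level reaches a higher
contrast-to-noise ratio at iteration 40.

## Layout

| module | contents |
| --- | --- |
| `tofmix.kernels` | mixture timing kernels: bank I/O, pdf/cdf, sampling, EM fit, fidelity validation |
| `tofmix.geometry` | ring scanner, voxel grid, shape phantoms, NEMA-IQ generator |
| `tofmix.simulate` | decay sampling, photon-pair detection, pair-level timing spread, acquisition driver |
| `tofmix.listmode` | versioned list-mode file format (text / flat binary) |
| `tofmix.recon` | Siddon projector, TOF weights, sensitivity image, list-mode MLEM, calibration |
| `tofmix.metrics` | NEMA ROIs, CRC, background variability, CNR, bias across realizations |
| `tofmix.experiments` | kernel-fidelity study and the NEMA study matrix |
| `tofmix.cli` | `tofmix simulate / reconstruct / analyze / fidelity / study` |

See `docs/methods.md` for the model assumptions, parameter defaults,
and numerical choices.
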