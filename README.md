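# mdrc

Analysis pipeline for **massively multidimensional diffusion–relaxation
correlation MRI** (MMD-MRI): tensor-valued, frequency-dependent diffusion
encoding correlated with R1 and R2 relaxation, inverted per voxel into
nonparametric distributions of microscopic tissue components, and summarized
into reproducibility-ready scalar maps.

The package is aimed at preclinical/ex vivo micro-imaging studies (e.g.
fixed mouse brain at high field) where modulated gradient waveforms probe
centroid frequencies ωcent/2π of tens to hundreds of Hz, and where
scan–rescan reproducibility of the derived metrics must be quantified before
group comparisons are meaningful.

## Model

The signal of a voxel for an acquisition with tensor-valued encoding
spectrum b(ω), repetition time τR (saturation–recovery) and echo time τE is
a sum of mono-exponential components *i*:

```
S(b(ω), τR, τE) = Σᵢ wᵢ · exp(−∫ b(ω) : Dᵢ(ω) dω) · (1 − e^(−τR·R1ᵢ)) · e^(−τE·R2ᵢ)
```

Each component carries an axisymmetric diffusion tensor spectrum with
Lorentzian dispersion between the long-time diffusivities D∥, D⊥ and the
restriction-free isotropic value D₀, with transition frequencies Γ∥, Γ⊥:

```
D∥(ω) = D₀ − (D₀ − D∥)/(1 + ω²/Γ∥²)        (radial analogously)
Diso(ω) = (D∥(ω) + 2·D⊥(ω))/3
DΔ(ω)  = (D∥(ω) − D⊥(ω))/(3·Diso(ω))
```

The inverse problem is solved by **Monte Carlo inversion**: random candidate
components inside hard limits (5·10⁻¹² < D < 5·10⁻⁹ m²/s, 0.1 < Γ < 10⁵ s⁻¹,
0.1 < R1 < 4 s⁻¹, 4 < R2 < 100 s⁻¹), nonnegative least-squares weights,
iterative mutation/refit refinement, and bootstrap resampling of the
acquisition for per-voxel solution ensembles. Distributions reduce to:

* moments E[x], V[x], C[x,y] for x, y ∈ {Diso, DΔ², R1, R2};
* signal fractions of three (Diso, DΔ²) bins — anisotropic-slow (WM-like),
  isotropic-slow (GM-like), fast (fluid);
* per-Hz frequency-dependence rates, e.g.
  Δω/2π E[Diso] = (E[Diso](ωmax) − E[Diso](ωmin)) / ((ωmax−ωmin)/2π),
  with (ωmin, ωmax) the 10th/90th b-value-weighted percentiles of the
  protocol's centroid frequencies;
* FA / direction-encoded color summaries of the mean tensor.

Scan–rescan agreement is quantified with Lin's concordance correlation
coefficient, Bland–Altman analysis with sample-quantile limits of agreement,
per-sample Pearson correlations (shift-invariant, isolating "method-specific"
reproducibility from e.g. fixation drift), and the within-subject coefficient
of variation CVws = √(MSws)/|μ̄|.

## Worked example

Invert a noiseless two-component voxel (70 % white-matter-like + 30 %
fluid) probed by the default 355-image protocol:

```python
import numpy as np
from mdrc import (DiffusionComponent, VoxelDistribution, make_default_protocol,
                  delta_spectra, protocol_frequency_band, signal_matrix,
                  invert_voxel, weighted_moments, bin_fractions,
                  delta_omega_metric)

protocol = make_default_protocol()
spectra = delta_spectra(protocol)
omega_min, omega_max = protocol_frequency_band(protocol)

wm = DiffusionComponent(d0=1.2e-9, d_par=7e-10, d_perp=9e-11,
                        gamma_par=2*np.pi*1000, gamma_perp=2*np.pi*1000,
                        theta=np.pi/2, r1=1.0, r2=40.0, w=0.7)
csf = DiffusionComponent(d0=2.1e-9, d_par=2e-9, d_perp=2e-9,
                         gamma_par=2*np.pi*10, gamma_perp=2*np.pi*10,
                         r1=0.35, r2=8.0, w=0.3)
truth = VoxelDistribution.from_components([wm, csf])
signals = signal_matrix(truth, protocol, spectra) @ truth.w

fit = invert_voxel(signals, protocol, spectra, rng=np.random.default_rng(0))
f1, f2, f3 = bin_fractions(fit.distribution, omega_min)
print(f"bin fractions f1={f1:.2f} f2={f2:.2f} f3={f3:.2f}")
print(f"E[Diso] = {weighted_moments(fit.distribution,'diso',omega_min).e_x:.2e}")
```

prints

```
bin fractions f1=0.71 f2=0.00 f3=0.29
E[Diso] = 8.02e-10
```

i.e. the anisotropic-slow and fast pools are recovered at their true signal
fractions (0.70/0.30) and the distribution mean isotropic diffusivity is
within 4 % of the ground truth (8.34·10⁻¹⁰ m²/s).

A full synthetic scan–rescan study (phantom → simulation → inversion → ROI
metrics → reproducibility report) is one call:

```python
from mdrc import run_scan_rescan_experiment
out = run_scan_rescan_experiment(seed=1)
print(out["report"]["E_r1"]["bland_altman"]["bias_detected"])   # True: R1 drift
print(out["report"]["E_ddelta2"]["ccc"])                        # ~0.98
```

There is also a thin CLI: `mdrc protocol`, `mdrc simulate`, `mdrc invert`,
`mdrc repro` (see `mdrc --help`).

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline quantities from
scratch — the partial-volume worked example (expected absolute scan–rescan
differences of the mixture mean and variance) and a compact end-to-end
scan–rescan study with its CCC/CVws/Bland–Altman report — and writes the
target JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
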