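# Methods

This note documents the model, the numerical choices, and the synthetic
world the package is tested against — including what a green test does and
does not establish.

## Signal model

A voxel is a discrete distribution of non-exchanging, axially symmetric
components. Component *i* is parameterized by
(D₀, D∥, D⊥, Γ∥, Γ⊥, θ, φ, R1, R2, w):

* **Diffusion.** The tensor spectrum D(ω) rises from the long-time values
  D∥, D⊥ to the restriction-free isotropic value D₀ along Lorentzians with
  transition frequencies Γ∥, Γ⊥ (angular, rad/s). This captures restricted
  diffusion: the larger the confining structure, the lower the frequency at
  which the apparent diffusivity recovers toward the free value.
* **Relaxation.** Longitudinal weighting uses the saturation-recovery form
  (1 − e^(−τR·R1)); τR is the time from saturation to the next excitation.
  Transverse weighting is e^(−τE·R2).
* **Encoding.** Each acquisition carries a tensor-valued encoding spectral
  density b(ω); the attenuation exponent is ∫b(ω):D(ω)dω. Spectra are stored
  one-sided (ω ≥ 0) with the negative half folded in — lossless because
  D(ω) is even — as nodes (ω_k, quadrature weight, 3×3 tensor density), so a
  single-node "delta spectrum" at ωcent makes the integral closed-form.
  Frequencies are angular internally; everything user-facing is ω/2π in Hz.

For the axisymmetric contraction the integrand reduces to
b:D = D⊥(ω)·tr b + (D∥(ω) − D⊥(ω))·uᵀb u, which makes the signal kernel for
hundreds of components a couple of `einsum`s.

### Waveforms

Encoding waveforms are a documented stand-in, not vendor pulse shapes: per
axis, the dephasing vector follows a Hann-windowed oscillation
q(t) ∝ sin²(πτ/T)·cos(2πmτ/T) with m ∈ {0, 1, 2} full oscillations
("modulation order"), so order controls the spectral main-lobe frequency.
The three axes are multiplexed into disjoint time slots; cross-axis moments
vanish exactly, and equal axis weights give a spherical b-tensor. Only the
spectral support matters downstream; slew-rate and hardware constraints are
out of scope. The discrete Fourier pipeline satisfies Parseval exactly
(tested to 1e-6 relative against the time-domain b, limited only by the
cumulative-trapezoid q(t)).

### Protocols

`make_default_protocol()` spans the study ranges: b 0–8·10⁹ s/m²,
τE 9.4–49.4 ms, τR 0.8–3.5 s, ωcent 36.6–247 Hz over modulation orders
0–2, b-tensor shapes linear/spherical/planar, golden-spiral orientations,
and a b=0 relaxation block crossing τE × τR (355 images).
`make_desk_protocol()` (205 images) keeps the same coverage with fewer
orientations; its b=0 block is deliberately dense (7×7) because R1
conditioning collapses with fewer τR samples (per-voxel E[R1] noise at
SNR 50 roughly triples with a 4×4 block).

The frequency pair (ωmin, ωmax) used by all Δω/2π metrics defaults to the
10th/90th percentiles of the protocol's b-value-weighted ωcent distribution
(36.6 and 247 Hz for both default protocols); weighting by b discounts
low-b images that carry little diffusion contrast. The probe frequency for
non-Δω maps and for bin assignment defaults to ωmin and is recorded in
output metadata.

## Monte Carlo inversion

Per voxel: draw `n_candidates` random components inside the hard limits
(log-uniform diffusivities/transition frequencies, uniform-on-sphere
orientations, uniform relaxation rates; D∥, D⊥ ≤ D₀ enforced by making D₀
the largest of three draws), fit weights by NNLS, keep the nonzero-weight
survivors, then for `n_refine` rounds propose `n_children` mutated copies
per survivor (log-space perturbation with a geometrically shrinking step,
tangential orientation jitter) plus `n_fresh` fresh random components, and
refit the joint basis. Parents stay in the basis, so the NNLS residual is
non-increasing by construction. Finally the solution is pruned to
`max_components` and refit.

Defaults: `n_candidates=500, n_refine=40, n_children=5, n_fresh=60,
max_components=10` (~0.3–0.5 s/voxel on one core for a 355-image protocol).
The counts are not physics; they trade accuracy for time and are all
config-exposed. Two defaults deserve justification:

* **max_components = 10.** With ~350 measurements at SNR 50, 20-component
  solutions chase noise; the component cloud spreads log-normally around the
  truth and its *linear*-space mean E[Diso] inherits an upward bias of
  ~10 %. Capping at 10 (with refit) halves that bias in the recovery
  experiment without hurting noiseless multi-component fits, whose true
  complexity here is ≤ 4 components.
* **Fresh-candidate injection.** Pure mutate-and-refit stalls in local
  optima for anisotropic voxels (the orientation/anisotropy trade-off);
  injected random components restore ergodicity cheaply.

Bootstrap ensembles refit on full-size resamples (with replacement) of the
protocol rows; `n_bootstrap=64` by default. All randomness descends from one
seed with per-voxel substreams derived by counter, so voxel order and
subsetting never change results.

### Rician noise handling

Magnitude MRI noise is Rician. At high b the noise floor σ√(π/2) reads as
unattenuated signal and creates spurious fast components that inflate
E[Diso] by tens of percent at SNR 50. The pipeline therefore applies the
first-order correction Ŝ = sign(M²−2σ²)·√|M²−2σ²| before inversion (σ from
the measured b=0 reference image and the nominal SNR). The signed square
root keeps the corrected noise symmetric around S ≈ 0, which matters for
least squares. A real preprocessing chain would use PCA denoising to the
same effect; that is out of scope here.

## Consolidation and projections

Bootstrap ensembles are consolidated by pooling components across solutions
and k-means clustering with the **L1 metric** (centroids are coordinate-wise
medians, i.e. k-medians — implemented in `KMediansL1`, since scikit-learn's
KMeans is L2-only). Features: Diso(ω) and DΔ²(ω) at (ωmin, ωmax), the
principal axis encoded as (sinθcosφ, sinθsinφ, |cosθ|) to avoid angular
wrap-around (a deliberate transformation of the raw angles), R1, R2 — each
normalized by its maximal absolute value. The cluster count defaults to the
median number of nonzero-weight components across bootstrap solutions. Each
cluster collapses to one component by per-parameter medians with the median
weight (no renormalization; normalization happens at projection time only).

2D projections deposit consolidated weights on 64×64 meshes in the
Diso–DΔ², Diso–R1 and Diso–R2 planes (Diso log-scaled over the inversion
limits; the other axes linear over theirs; out-of-range components are
clipped to edge cells and counted in a log message). ROI-level distributions
follow the exact order: per-scan ROI sum → per-scan normalization →
across-scan mean.

## Scalar maps and bins

Bins partition the (Diso, DΔ²) plane with the decision order: Diso > 10⁻⁹
m²/s → bin 3 (fast/fluid); else DΔ² > 0.25 → bin 1 (anisotropic-slow/WM);
else bin 2 (isotropic-slow/GM). Applying the Diso test first makes the
three predicates a true partition; boundary values (a measure-zero set)
fall to the later branch. Bin membership is evaluated at ωmin by default
(the evaluation frequency is not physically canonical and is config-exposed
and recorded in metadata).

E/V/C are weight-normalized population moments (weights are signal
fractions, not counts — no small-sample correction). Bin-resolved means use
membership frozen at the bin frequency, so Σ_b f_b·E[x|b] = E[x] holds as
an exact algebraic identity. DEC summaries: per bootstrap solution the FA
and principal eigenvector of the weight-mean tensor D̄(ω); the reported FA
is the sample median and the eigenvector is taken from the solution whose
FA is closest to that median (a median of eigenvectors is otherwise
ill-defined); RGB = |v|·FA is antipodally symmetric.

## Reproducibility statistics

* **CCC** uses population (1/n) variances; degenerate inputs are defined
  explicitly (both constant and equal → 1; constant with unequal means → 0).
  Strength-of-agreement labels: > 0.99 almost perfect, 0.95–0.99
  substantial, 0.90–0.95 moderate, else poor.
* **Bland–Altman** limits of agreement are empirical sample quantiles of
  d = rescan − scan with linear interpolation (the classical estimator,
  fixed and documented) at coverage 0.95; bias is flagged iff 0 lies outside
  [LOA_low, LOA_high]. With small n this is a conservative detector: the
  2.5 % quantile of a few dozen differences is essentially their minimum.
* **Per-sample Pearson** across ROIs is shift-invariant, so sample-specific
  drift does not lower it — it isolates method noise from sample-state bias.
  Samples with constant values are excluded with a warning.
* **CVws** uses the two-replicate within-subject mean square
  MSws = Σd²/(2n); the convention is config-visible since only the ratio
  √MSws/|μ̄| is canonical.
* **Mixture moments** for partial-volume reasoning:
  E(f) = (1−f)μ₁ + fμ₂ and V(f) = (1−f)v₁ + fv₂ + f(1−f)(μ₁−μ₂)², with the
  variance maximum at f\* = 1/2 + (v₂−v₁)/(2(μ₁−μ₂)²). For populations
  (10, 10) and (30, 50) s⁻¹/s⁻² this gives f\* = 0.55 and V(f\*) = 131 s⁻².
  With the mixing fraction re-drawn uniformly per scan, the expected
  absolute scan–rescan differences are E|ΔE| = |μ₁−μ₂|/3 = 20/3 ≈ 6.7 s⁻¹
  (closed form) and E|ΔV| = 35.2 s⁻² (2-D quadrature). The mixing-fraction
  distribution is an assumption; uniform is the default and the only one
  with these closed forms.

## Synthetic world

The phantom emulates the statistical structure of an ex vivo mouse-brain
study, not its anatomy: a 16×16×6 grid with six slab ROIs — a thick and a
deliberately 1-voxel-thin WM-like tract (the thin tract is partial-volume
dominated by construction), three GM-like regions, one fluid region.
Recipes: WM D∥/D⊥ = 7/0.9·10⁻¹⁰ m²/s with restriction transition near
1 kHz (band-flat but strongly anisotropic, DΔ² ≈ 0.47), GM Diso ≈ 3–4·10⁻¹⁰
m²/s with in-band dispersion (Γ/2π = 60–90 Hz, the cerebellum-like region
strongest), fluid Diso ≈ 2·10⁻⁹ m²/s. R1 0.35–1.1 s⁻¹ (ex vivo fixed tissue
at high field, matched to the τR range), R2 8–45 s⁻¹. Per-voxel lognormal
jitter 3 %, per-sample jitter 4 %, boundary voxels mixed 50/50 with the
neighboring recipe, Rician noise at SNR 50 relative to the b=0/shortest-τE/
longest-τR image, and a rescan R1 drift of +0.025 s⁻¹ per month over a
4-month gap (+0.1 s⁻¹ total) emulating progressive fixation.

What green tests establish: the estimator recovers the stated world's
distributions, bins, frequency-dependence rates and drift dissociation at
desk scale (hundreds of voxels, one core). What they do not establish:
behavior under real-scanner artifacts (EPI distortion, Gibbs ringing,
misregistration), anatomically realistic geometry, exchange between
compartments, non-Lorentzian dispersion, or full-study scale.

## Scale choices

The real study inverted ~130,000 voxels in 40 h on 48 cores (~53
core-seconds/voxel). Desk scale targets ≤ a few hundred voxels: the
end-to-end scan–rescan experiment defaults to 8 samples × 2 scans × 6 ROIs
× 4 voxels with a lighter inversion configuration (300 candidates, 24
rounds) and no bootstrap for E[x] recovery, finishing in ~2 min; the
acceptance script further reduces to 3 samples × 3 voxels. The bootstrap
ensemble path is exercised on single voxels and small replicate counts in
the tests.

## Known limitations

* E[Diso] retains a residual upward bias of ~5–8 % at SNR 50 even after the
  Rician correction and the sparser component cap; it vanishes with noise.
* Anisotropy near the DΔ² = 0.25 bin boundary is the least identifiable
  quantity: near-zero-residual solutions can trade bin-1 against bin-2
  weight by ~0.1 in noiseless two-component voxels with reduced protocols.
* R1 above ~1.5 s⁻¹ is poorly conditioned given τR ≤ 3.5 s; the relaxation
  block density dominates E[R1] precision.
* The k-medians cluster count heuristic (median component count) can merge
  genuinely distinct but close components when bootstrap solutions disagree
  on complexity.
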