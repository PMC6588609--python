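# Methods

This note documents the model, the discrete conventions, the synthetic
systems and the numerical choices behind `mdetune`, in the spirit of a
package's own methods documentation.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Signal model and assumptions

A compartment's diffusion is summarised by its diffusion spectrum — the
frequency representation of the velocity autocorrelation —
**D**(ω) = **R** diag(λ₁, λ₂, λ₃)(ω) **R**⁻¹, with principal spectra λᵢ(ω)
and an orientation **R**.  Under the Gaussian approximation of the cumulant
expansion (spin-phase distribution Gaussian per compartment, hence
mono-exponential compartment attenuation in b), the attenuation under an
effective gradient waveform g(t) is

    E = exp(−β),   β = (1/2π) ∫ Fᵀ(ω) D(ω) F(−ω) dω,

where F(ω) is the spectrum of the dephasing vector F(t) = γ∫₀ᵗ g dt′ and
γ = 2.6752218744·10⁸ rad s⁻¹ T⁻¹ (proton).  The b-tensor is
**b** = ∫ F(t)⊗F(t) dt; its trace (the b-value) equals the integrated
encoding power by Parseval's theorem.  ADC = β/b.  Mixtures attenuate as
fraction-weighted sums of compartment signals (no exchange); relaxation is
ignored.

Assumptions and their scope: the Gaussian approximation is accurate at low
to moderate diffusion weighting; its breakdown is quantified by the Monte
Carlo engine (the acceptance suite bounds the deviation of a single
cylinder's E(b) from mono-exponential decay by 1% of the unweighted signal
up to b = 4800 s/mm² under the isotropic encoding).  All compartments are
impermeable; membranes are perfectly reflecting.

## Discrete waveform convention

Gradient samples are held piecewise-constant over each dt, as a gradient
DAC plays them.  Consequently F(t) is the exact cumulative sum (piecewise
linear between nodes), the refocusing (echo) condition Σg·dt = 0 is exact,
and the b-tensor is evaluated with the exact piecewise-linear segment
integral — the textbook pulsed-gradient closed form
b = γ²g²δ²(Δ−δ/3) is reproduced to machine precision when δ and Δ are
grid-aligned.  The detuned derivation differences the node values of
|F(t)| directly on the sampled grid (no smoothing; |F| is non-smooth at
zero crossings), which makes the detuned b-value equal to the parent
trace(b) up to round-off rather than merely to a finite-difference
tolerance.

Spectra are computed by resampling F(t) to a 1 µs step (linear
interpolation of the piecewise-linear dephasing, hence exact at shared
nodes), zero-padding to 2²¹ points (≈0.5 Hz spacing) and scaling the FFT by
dt so it approximates the continuous transform.  With the one-sided (rfft)
grid and Hermitian weights (2 everywhere except DC and Nyquist) the
discrete Parseval identity is exact, which fixes every constant in the β
integral; β is computed by a midpoint sum truncated where the cumulative
encoding power reaches 1−10⁻⁹ of b (neglected contribution ≤ 10⁻⁹·b·max D).

## The isotropic fixture and spectral tuning

The shipped isotropic encoding (`mdetune/data/qmas_balanced_tau23ms.txt`,
frozen parameters in `waveform.FIXTURE_PARAMS`) is generated by
`generate_balanced_iso`: a magic-angle cone sweep

    q(t) = q₀ a(t) [sin ζ cos ψ, sin ζ sin ψ, cos ζ],  ζ = arccos(1/√3),

with envelope a(t) = sin²(πt/τ), τ = 23 ms, 1150 samples (dt = 20 µs), and
a **constant** spinning rate ψ = 2πn t/τ with n = 4 revolutions.  Because
a²(t) = sin⁴ has Fourier support only on harmonics 0, 1, 2 of 1/τ, any
integer n ≥ 3 makes the continuum b-tensor exactly isotropic.  The cone
axis is then rotated onto the body diagonal (1,1,1)/√3, which distributes
the envelope band (≲90 Hz, 1/3 of the power) and the narrow rotation band
(n/τ ≈ 174 Hz, 2/3 of the power) equally over the three laboratory axes:
the per-axis encoding power spectra agree in all their band weights and
differ only through small interference terms.  Residual discretisation
anisotropy is removed by a near-identity linear map
L = √(tr M/3)·M^(−1/2) applied to F(t) (M = ∫FFᵀdt), making the discrete
b-tensor isotropic to machine precision while preserving refocusing.

This per-axis balance is what makes the √3-scaled x-channel
(`derive_tuned`) spectrally *tuned*: the acceptance suite verifies that
tuned and isotropic encodings measure the same ADC on spheres of
R ∈ {1, 2.5, 5} µm to within 2% (measured ≈0.1%).  The textbook cone with
its axis on z (`generate_qmas`, azimuthal rule ψ′ ∝ a² or constant) is also
provided; it is isotropic in b-tensor but spectrally anisotropic (the
z-axis power is the envelope spectrum near DC) and is therefore not used
for the fixture.  Any externally designed waveform can be dropped in
through the text-file interface (whitespace/comma-delimited, `#` header
with dt).

The balanced construction trades amplitude efficiency for spectral
balance: at b = 1000 s/mm² the fixture peaks at 923 mT/m.  The package
models effective waveforms whose amplitudes are rescaled per b-step, so
generators enforce a hardware cap only when one is passed
(`QmasParams.max_gradient`); `Waveform.exceeds_cap` reports against the
500 mT/m default.

## Restricted diffusion spectra

For reflecting planar (plates at ±R), cylindrical and spherical
geometries,

    λ(ω) = Σₖ Bₖ aₖ ω² / (aₖ² + ω²),   aₖ = αₖ² D₀ / R²,

with αₖ the roots of J₁′ (cylinder), j₁′ (sphere) or (2k−1)π/2 (plane) and
weights Bₖ = 2(R²/αₖ²)/(αₖ²−1), 2(R²/αₖ²)/(αₖ²−2) and 32R²/((2k−1)⁴π⁴)
respectively.  λ(0) = 0, λ is monotone in |ω|, and results depend on
(R, D₀, ω) only through ωR²/D₀ — equivalently, signal curves depend on the
relative encoding time √(D₀τ)/R, which the acceptance suite verifies to
10⁻³ across matched parameter pairs.

Roots are found by a sign-change scan plus Brent refinement to ~10⁻¹²; the
first roots (1.8412, 2.0816) are cross-checked in the tests against an
independent bracketed-bisection oracle.  The weight sums obey exact
closed-form sum rules (Σ Bₖaₖ = D₀), but partial sums converge only like
1/K (0.99595 at K = 50); the default table therefore appends one tail mode
at the asymptotic root continuation (α_K + π) carrying the exact residual
weight.  This restores λ(∞) = D₀ while leaving the spectrum below the
first omitted rate (≫ any encoding frequency used here) unchanged to
O(1/α⁴); in-band correctness is validated independently against the Monte
Carlo engine.  `tail=False` recovers the plain truncation.  Cylinders are
transverse-restricted on the first two principal axes with a flat axial
D₀; planes are restricted on the third axis.

## Monte Carlo engine

Random walks with per-axis Gaussian steps of variance 2D₀·dt (consistent
with the free propagator at the step duration), initial positions uniform
in the restriction (rejection from the bounding box), and barriers
enforced by step rejection: a particle whose step endpoint would exit
stays in place for that step.  Rejection biases the near-wall density when
steps are large, so configurations with RMS step > R/2 are refused; the
default is 5000 time steps (the reference configuration also uses 10⁵
particles; routine tests use 10⁴ or fewer).  The phase is
φ = γ Σₜ g(t)·r̄(t)·dt with r̄ the step midpoint (removes the O(dt)
quadrature bias), and E = ⟨cos φ⟩; the residual |⟨sin φ⟩| (zero in
expectation for these symmetric substrates) is reported as a sanity
metric.  Orientations rotate the gradient into the substrate frame
(equivalent to rotating the substrate's symmetry axis relative to the
gradient frame).

Because amplitude only scales φ linearly, one trajectory pass yields E for
every (waveform, orientation, b) simultaneously; ADC is extracted from the
two lowest b-values (0 and 100 s/mm² by default).  Determinism holds for
fixed (seed, n_particles, n_steps) via one PCG64 stream per run; changing
the particle count reshuffles draws.

## Powder statistics

Orientation sets default to the spherical Fibonacci lattice; frames attach
in-plane axes spun by a deterministic golden-angle-like sequence so the
full frame set approximates a uniform sample of SO(3), not only of
directions (directional second moments match sphere integrals to ~10⁻³ at
n = 1000).  Powder averaging is the arithmetic mean of E over
orientations.  ⟨ADC⟩ and V_D use the population variance (the orientation
set is the design, not a sample).  The second-cumulant powder form is
E = exp(−⟨ADC⟩b + V_D b²/2); the third-order fit is
S = S₀·exp(−c₁b + c₂b²/2 − c₃b³/6) with S₀ free, by nonlinear least
squares initialised from a log-domain cubic — the sign convention is fixed
here (positive c₁, positive-curvature c₂) and round-trip tested.

## Synthetic phantoms and what they do (not) emulate

All systems use D₀ = 10⁻⁹ m²/s unless noted, mixed at the signal level
(valid because powder averaging is linear in compartment signals).

* **yeast**: 0.5 sphere R = 2.5 µm + 0.5 free — packed-cell suspension
  with intracellular restriction and extracellular hindered water.
* **microfibers**: 0.5 cylinder R = 5 µm (fiber lumen) + 0.4 cylinder
  R = 1 µm (micron-scale interstitial channels of a packed bundle) +
  0.1 free.  A packed fiber phantom is not only its lumina: the liquid in
  the interstitial voids is strongly anisotropic and restricted at the
  micron scale, and at τ = 23 ms a lone R = 5 µm cylinder is nearly
  transversely free in the tuned band (λ_t ≈ 0.8 D₀), so the interstitial
  compartment carries most of the anisotropy contrast.
* **liquid_crystal**: cylinders R = 2 nm, uniformly dispersed — reversed
  hexagonal phase water channels; transverse diffusion is invisible below
  kHz frequencies, giving apparently 1D, time-independent diffusion.
* **polymer**: three free pools (0.55/0.30/0.15 at 1.2, 0.35,
  0.08·10⁻⁹ m²/s) — multi-Gaussian, isotropic, time-independent.
* **pbs**: single free pool at 2.0·10⁻⁹ m²/s.
* **wm / gm / cerebellum**: illustrative mixtures of thin cylinders
  (axons/dendrites), anisotropic or isotropic Gaussian pools
  (extracellular space) and spheres (cell bodies); fractions are
  documented defaults chosen to express the qualitative regional ordering
  (white matter: maximal anisotropy; cerebellum: both contrasts; gray
  matter: anisotropy with weak size effects), not fits to any measured
  tissue curve.

The generator emulates noiseless Gaussian-compartment signals plus
optional Rician magnitude noise (σ = 1/SNR).  It does **not** emulate
exchange between compartments, relaxation weighting, polydisperse size
distributions, acquisition artefacts, or the higher-cumulant (non-Gaussian
phase) content of real signals — so passing phantom tests demonstrates the
encoding logic and the pipeline, not biological fidelity.  The contrast
thresholds used in qualitative checks ("overlap" max|ΔE| ≤ 0.01,
"diverge" ≥ 0.03 of the unweighted signal) are package conventions,
configurable in the tests' constants.

Volumes are rendered per labelled region with frames per (encoding, b,
orientation) and a TSV sidecar; voxel-wise maps powder-average per
(encoding, b), normalise by the fitted S₀ (measured b = 0 frame optional),
subtract at b*, and smooth with a Gaussian kernel specified as FWHM in
millimetres (σ = FWHM/√(8 ln 2)), with the kernel renormalised at the
volume edge.

## Problem sizes and determinism

Analytic powder averages use 15 orientations (protocol default) or 250 for
the reference-system recipe; dense moment checks use 1000.  Monte Carlo
stages use 5000 steps with 10⁵ particles for the Gaussian-approximation
bound and 10⁴ particles (60 orientations) for the cross-engine comparison;
the deviation measure for the bound is expressed in percent of the
unweighted signal, since a relative measure at the highest b is dominated
by counting noise even at 10⁵ particles.  Noisy parameter-recovery is
evaluated on powder-averaged curves (means of 15 orientation measurements
at SNR 50), averaged over 8 replicates in the acceptance script so the
reported error is stable across seeds.  All stochastic stages take a
single integer seed; per-stage seeds are derived from it.

## Known limitations

* The optimized constrained q-MAS waveform of the experimental literature
  is not reproduced; the balanced fixture is the package's own design with
  the same defining properties (isotropic b-tensor, near-identical
  per-axis spectra, smooth envelope).  Numeric waveforms can be imported.
* Gaussian-compartment composition ignores exchange and intra-compartment
  kurtosis; the Monte Carlo engine quantifies the latter for single
  compartments only.
* The rejection walk slightly depletes near-wall density at finite step
  size; the RMS-step guard and the 5000-step default keep this below the
  cross-engine tolerance, it is not extrapolated to zero step.
* Substrates are monodisperse; polydispersity, permeability, and composite
  intra/extra-cellular geometries are out of scope (mixtures are composed
  at the signal level instead).
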