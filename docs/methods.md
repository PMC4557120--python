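# Methods

This note documents the models implemented in photokin, the estimator
design decisions, the synthetic-data generator that stands in for the
original measurements, and the limitations of both.

## Global lifetime analysis (DADS)

The data matrix ΔA(tᵢ, λⱼ) is modelled as F·B. Basis columns:

- **Exponential decays** exp(−(t−t₀)/τ) convolved with a normalized Gaussian
  IRF of given FWHM, evaluated in the exponentially-modified-Gaussian closed
  form `0.5·erfcx((σ/τ − u)/√2)·exp(−u²/2)` with u = (t−t₀)/σ. `erfcx`
  keeps the expression stable at any σ/τ; far past the pulse, where `erfcx`
  of a large negative argument would overflow, the column switches to its
  asymptote, the pure exponential (relative switch error < 1e-170).
- **A step** (Gaussian CDF at t₀): a photoproduct formed within the window
  that does not decay inside it.
- **A flat offset** over all delays, pre-t₀ rows included: the baseline left
  by intermediates that outlive the excitation repetition period. A single
  "constant" cannot play both roles — the step is zero before t₀, the
  baseline is not — which is why the basis carries them as separate columns.

For fixed nonlinear parameters, B is solved by orthogonal decomposition
(LAPACK `gelsd`); χ² is the squared Frobenius residual. The lifetimes (and
optionally t₀ and IRF width) are then optimized by Levenberg–Marquardt on
the projected residual (variable projection), log-parameterized to enforce
positivity. Five deterministically jittered starts (fixed internal seed, so
fits are reproducible) guard against local minima; ties break toward the
smallest first lifetime. The covariance of the nonlinear parameters comes
from the Gauss–Newton approximation at the optimum.

Unweighted least squares is used throughout: the synthetic noise is
homoscedastic by construction, and no per-pixel error model is available
for the kind of data emulated.

Precision limit worth knowing: in the ultrafast window the radical branch
carries only β ≈ 2% of the signal, so at 0.5% rms noise and ~100 delay
points the Cramér–Rao bound on its lifetime is ≈ 7% — recoveries scatter by
about that much, and no estimator can do better under these conditions.

## SVD rank analysis and rotation

Rank estimation counts leading components that pass two criteria: singular
value at least `sv_ratio_threshold` (default 5) times the noise floor
(median of the trailing half of the singular values), and lag-1
autocorrelation of both singular vectors at least `autocorr_threshold`
(default 0.8) — smoothness separates signal from white noise. The
autocorrelation gate is skipped for vectors shorter than 8 points, where a
lag-1 statistic is meaningless; an absolute guard (10⁻¹⁰ of the leading
singular value) rejects the numerically-zero components of exact low-rank
matrices, whose noise floor vanishes. Counting stops at the first failure;
ties exclude the component.

Rotation into physical quantities uses an invertible model matrix X built
from spectroscopic constraints: C = U W X⁻¹ and S = X Vᵀ, which preserves
C·S = A^(K) for every invertible X. Condition numbers above 10¹² are
rejected.

## Photoconversion decomposition and the residual ground state

Constraints: the first spectrum of a stepwise-illumination series is the
dark-state spectrum; the final spectrum is the light-state spectrum
contaminated by a residual dark fraction ε.

A point the implementation surfaced: ε cannot be read off the spectra
alone. The contaminated endmember (final − ε·GS)/(1−ε) is an affine
combination of the two pure spectra for *every* ε, so any candidate
reproduces the series with mole fractions summing exactly to 1 — a row-sum
criterion is flat in ε and its minimizer is noise. What does identify ε is
the conversion *kinetics*: under constant light dose per step the dark
fraction decays geometrically, but the observed series saturates at the
photostationary residual. Decomposing against the raw final spectrum, the
dark-state profile is y_s = (1+q)rˢ − q before the plateau (q = ε/(1−ε))
and exactly 0 on it; a geometric decay with free offset fitted to the
pre-plateau points extrapolates to −q, and ε = gap/(1+gap) where gap is the
plateau-to-asymptote distance. On synthetic series with 0.2% noise this
recovers a 2% residual to ±0.3 points; it is exact noise-free.

The estimator assumes per-step conversion is first-order in the remaining
dark population (constant dose per step). Strongly varying illumination
doses would bias it.

## Binding isotherms

`binding_fraction` evaluates the physical root of the 1:1 equilibrium in
the cancellation-free form 2·A0·B0/(s + √(s² − 4·A0·B0)), s = A0+B0+K_D;
mass balance holds to 1e-9 against a bisection oracle.

`fit_kd` has two routes. With known free and bound endmember spectra (for a
chromoprotein the fully-bound spectrum is the independently measured
holo-protein dark state), each titration spectrum is projected onto the
bound-minus-free difference spectrum, giving absolute bound fractions, and
K_D is the single Levenberg–Marquardt parameter (log-transformed). Without
references, both spectra are eliminated by variable projection for each
trial K_D; this stays exact on noise-free data, but in the weak-binding
regime (A0_max ≪ K_D, e.g. 27 μM vs 250 μM) the spectral amplitude and K_D
are nearly degenerate — only the isotherm's curvature separates them — and
the reported standard error honestly exceeds 100%. The known-reference
route is the reliable one there and is what the analysis scripts use.

## Target models, SAS and branching

A kinetic scheme is a branched first-order network (no cycles, no
reversible steps) entered by the photoexcited species. Concentrations come
from the eigen-decomposition of the generator matrix; genuinely defective
rate matrices (coinciding rates along one chain, needing t·e^(−kt) terms)
are handled by a small multiplicative rate perturbation with a warning,
while the legitimate shared zero eigenvalue of multiple sinks is left
alone. An independent ODE-integrator oracle agrees to 1e-8.

The model matrix maps each species' kinetics onto the fit's basis functions
(eigenrates must match basis lifetimes within 1%; a non-decaying population
maps onto the step column). Species named as the ground state are excluded
from the matrix: difference data are blind to recovered ground state. The
projection S_diff = (Xᵀ)⁻¹·B copies χ² from the fit unchanged — by
construction, since C·S = F·B — so model comparison is purely about
physicality: non-negative concentrations (exact for valid schemes) and
non-negative absolute SAS, gs + S_diff/excited_fraction. The per-species
negativity score is normalized by each species' own spectral scale because
minor-branch SAS amplitudes scale inversely with the branch fraction and so
does their noise.

Branching ratios are recovered from the same non-negativity principle the
endmember constraints use ("wavelengths where the intermediate does not
absorb"): within one branch, every descendant's difference spectrum scales
as 1/fraction, so the smallest fraction keeping its SAS non-negative over
the strong ground-state support (gs ≥ 30% of its peak) is the estimate.
Two measures temper the extreme-value bias of maximizing a noisy ratio: a
5-point moving average over wavelength, and taking the mean of the top 5
ratio values (the touch-zero region of banded spectra spans several bins).
The direct ground-state channel takes the remainder, closing α+β+γ to 1.
This recovers γ = 8.4% to within ±0.3 points at 0.5% noise. The estimate is
a lower-bound-type estimator: it is exact only if each intermediate truly
has a zero-extinction region overlapping the ground-state band, which holds
for the cobalamin-like band library and is an assumption for real spectra.

## Pre-excitation baseline simulator

Two-state sample, df_E/dt = g(t)·f_G − k·f_E with a Gaussian pulse train
g(t). Between pulses the decay propagates analytically (exactly); across
each pulse the scalar linear ODE is integrated at rtol 1e-11. The default
pulse amplitude deposits ≈ 10% of the remaining ground state per pulse; all
reported baseline properties are amplitude-independent ratios. ΔA uses
Beer–Lambert with unit extinction coefficients and pathlength on a pure
absorption and a pure bleach channel, in two referencing views: *absolute*
(pre-first-pulse transmission), in which the surviving population decays as
e^(−kΔt) between pulses, and *per-cycle*, referenced to the pump-blocked
shot half a period after the preceding pulse, which reproduces the inverted
pre-pulse signal of long-lived species. Over an acquisition window short
against 1/k (k·window < 0.01 enforced) the surviving signal is constant to
first order — the constant component the global fits require.

`long_lived_constant_check` correlates the sign-flipped fitted baseline
with the negated pre-t₀ row mean; because the offset column is estimated
largely *from* the pre-t₀ rows, pure noise would correlate spuriously, so
the baseline must first exceed twice the fit's residual noise to be deemed
significant.

## Synthetic data: what it emulates, and what it does not

The generator produces three transient windows from sub-schemes of the full
photocycle (rates k_D = 0.471×10¹², k_HomoC = 0.012×10¹², k_CT =
0.044×10¹², k_RPR = 1.26×10⁹, k_HeteroC = 10⁸, k_R = 1.79×10⁶, k_AF = 10²,
k_Diss = 1.71, k_Diss′ = 0.06 s⁻¹):

- **fs–ns**: 20 linear pre-t₀ points (−1.5 to −0.2 ps) plus 100 log-spaced
  delays to 3 ns, 170 fs IRF, species A (excited state), B (radical pair),
  C (charge-transfer intermediate, static within the window — heterolysis
  at 0.1/ns happens beyond it and is carried by the non-decaying
  component), plus a flat inverted baseline (5% of peak) with the spectrum
  of the >1 ms intermediate;
- **ns–μs**: 150 log-spaced points, 2 ns–5 μs, rearrangement D*→D;
- **ms–s**: 4,800 points at 12.5 ms (the stated 55 s window and the stated
  4,800-point count are mutually inconsistent by 9%; the point count is
  kept), two dissociation steps ending in the light state.

Spectra are sums of Gaussian bands in wavelength (default FWHM ~20–60 nm)
at the published peak positions — dark state 510/540 nm plus a UV band,
light state 478/509/333/358 nm, cob(II)alamin-, MLCT- and
cob(III)alamin-like intermediates. Band amplitudes and the per-species
shapes beyond peak positions are the package's own choices. Because
absolute extinction scales of the intermediates are not published, each
transient matrix is normalized to unit peak |ΔA|, so `noise_rms` in OD is
also the relative noise level; ground-truth records carry the scale, the
scaled ground-state spectrum and the excited fraction (default 0.10).
Noise is homoscedastic Gaussian, seeded; identical specs give bit-identical
matrices.

Consequences for interpretation: passing recovery tests shows the
estimators are correct and precise *under this statistical model* —
separable bilinear data, Gaussian bands, homoscedastic noise, a single t₀,
no chirp. Real streak and pump–probe data add heteroscedastic noise,
wavelength-dependent IRF/dispersion, and scattering artifacts that the
generator does not emulate, so real-data accuracy is expected to be worse
than the synthetic figures.

## Numerical choices and degenerate inputs

- Times are stored in seconds everywhere; display units are cosmetic.
- Masked streak pixels (non-positive numerator or denominator of the
  ΔA log-ratio) become NaN sentinels, counted and reported; an all-masked
  frame is an error. The two dark frames are averaged before subtraction.
- Logarithmic binning spans the first positive time to the last; empty bins
  are dropped (the 4,800-point series yields ~320 populated bins for
  n_out = 500); rows at t ≤ 0 are discarded.
- t=0 alignment interpolates linearly onto the first trace's grid;
  trigger offsets larger than a trace's span are rejected.
- Basis condition numbers above 300 warn (near-degenerate lifetimes),
  above 10¹² error out listing the collinear columns.
- Lifetimes below a tenth of the local time resolution warn as
  unresolvable.

## Known limitations

- No reversible kinetics, second-order steps, or temperature dependence in
  the target models; no anisotropy or multi-pulse excitation in the fits.
- No spectral chirp or dispersion correction; one t₀ per dataset.
- The branching estimator needs a zero-extinction window for each
  intermediate inside the ground-state band.
- The reference-free K_D route is honest but weakly determined whenever the
  titration cannot approach saturation.
- The ultrafast middle lifetime is intrinsically at ~7% precision at the
  default conditions (see above); conclusions hinging on finer differences
  need more delay points or lower noise.
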