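# Methods

This note records the models implemented in `lovspec`, the defaults and
their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Steady-state photoreduction kinetics

The two-state conversion FMNox → FMNH• under continuous illumination is
modelled with first-order kinetics: the converted fraction is
x(t) = 1 − exp(−t/τ). The probe trace at 615 nm is fit with
A(t) = offset + A₁·exp(−t/τ); for a rise A₁ is negative. The literature
form of this expression is sometimes printed with a positive exponent,
which diverges; the saturating form implemented here is the only one
consistent with a bounded rise and is the standard convention.

Fitting is multi-start: τ starts are log-spaced over [Δt, 10·t_max]
(12 starts), the two linear parameters are solved exactly at each start,
and the best candidate is polished with Levenberg–Marquardt on
(offset, A₁, log τ). Standard errors come from the covariance of the
converged Jacobian. If the fitted |A₁| is below 10⁻⁶ of the data range the
trace carries no lifetime information and the fit is returned flagged
`degenerate` rather than reporting an arbitrary τ.

Yields are defined operationally: ΔA at the probe wavelength between t = 0
and the last recorded time at or below the illumination window (default
150 s), normalised to the initial absorbance at the normalisation
wavelength (default 450 nm, the oxidised-flavin band) to cancel
concentration differences. Probe extraction uses the nearest grid
wavelength without interpolation, matching discrete spectrophotometer
acquisition. pH series are re-expressed as percent of the maximum entry.

## SVD component counting

The SVD is taken on the raw, uncentered matrix: the scientific question is
how many absolute species spectra contribute, not how many variance
directions exist. The significance rule is a concrete criterion chosen for
this package (the qualitative outcome "two components" does not by itself
define one): a component is significant if its singular value exceeds 5×
the noise floor — the median of the trailing half of the singular-value
spectrum, floored at numerical-rank resolution — AND its right (time)
singular vector has lag-1 autocorrelation above 0.5. Random noise vectors
decorrelate at lag 1; genuine concentration profiles are smooth. Components
are counted from the top until the first failure, since a physical rank is
a prefix property.

## Global lifetime analysis

The forward model is a sum of exponential decays shared across wavelengths,
convolved with a Gaussian instrument response centred at t₀. The
convolution has the closed form

    c(t) = ½·exp(k²σ²/2 − k(t−t₀))·erfc((kσ − (t−t₀)/σ)/√2),

evaluated through the scaled complementary error function where the
exponent would overflow (the identity c = ½·erfcx(x)·exp(−(t−t₀)²/2σ²)
holds for x > 0). k = 0 encodes the non-decaying component exactly — not a
large lifetime — which keeps the kernel a smoothed step and the component
count honest. The optional D₀ spectrum is attached to the unit-area IRF
shape itself (δ ⊗ Gaussian), treated as an instrument-response-shaped
nuisance spectrum.

Fitting uses variable projection: amplitudes (the DADS) are conditionally
linear, so at each trial of the nonlinear parameters they are solved by
linear least squares against the kernel matrix, and only the lifetimes
(optionally t₀ and σ) are iterated. Multi-start uses 8 log-spaced
lifetimes spanning the time window, with a geometric spread when several
finite lifetimes are fit; ties are broken toward the smaller lifetime.
If two finite lifetimes converge within 10⁻⁶ relative the model is
over-parametrised and the fit is re-run with one fewer component, with a
warning. Lifetimes are reported ascending, ∞ last, DADS reordered to
match; the sign convention is negative = ground-state bleach, positive =
induced absorption.

The IRF σ defaults to 0.17 µs, i.e. a FWHM of ≈400 ns — a typical
single-pixel streak-camera resolution on a 200 µs window. Both t₀ and σ
are fixed by default and fittable on request; on synthetic data fixing
them at the generator's values isolates lifetime/DADS recovery from IRF
calibration.

## Spectral unmixing and the detection limit

DADS decomposition interpolates references onto the target grid, checks
for rank deficiency (naming the most collinear pair), and solves ordinary
or nonnegative least squares. Truncated-SVD denoising is provided for
noisy reference spectra.

The detection-limit calculation formalises "would we have seen an
intermediate?": in a consecutive first-order scheme A → B → C the peak of
B relative to C(∞) is x^(1/(1−x)) with x = k_form/k_decay. Given a
detection threshold θ the ratio is solved by bisection on (0, 1) to 10⁻¹⁰
and converted into the lifetime bound x·τ_form. The peak fraction
saturates at 1/e as x → 1, so thresholds ≥ 1/e drive the bound to its
upper limit τ_form. At θ = 0.10 the ratio is 0.137 and a 28.0 µs formation
lifetime bounds the intermediate below 3.8 µs.

## EPR

Nutation spectra are magnitude FFTs of mean-subtracted, Hamming-windowed,
4×-zero-padded traces; peaks are local maxima above 20% of the global
maximum, refined by parabolic interpolation. Assignment compares
α = ν_peak/(ω₁/2π) to the allowed values {1, √2} within 10% relative; when
ω₁ is unknown the lowest peak anchors α = 1. Peaks matching no allowed α
are flagged, not errors.

Powder patterns use first-order (high-field) resonance expressions, which
is adequate while D ≪ B₀ (4 mT against ~340 mT at X band; the error is of
order (D/B₀)² ~ 10⁻⁴). Orientation averaging uses a deterministic
golden-spiral grid (default 2000 points) for bit-reproducibility; the
integrated intensity is stable to 0.1% between 2000 and 8000 orientations.
The "3 mT Gaussian line width" convention is interpreted as FWHM; both
absorption and first-derivative (field-modulation) representations are
supported, and the half-field ΔMs = 2 transition is excluded. The doublet
species is a single Gaussian — hyperfine structure is out of scope. The
powder fit parametrises rhombicity as |E|/|D| ∈ [0, ⅓] so the physical
bound is enforced by box constraints; |D| well below the line width is an
intrinsically flat direction and is only determined to a fraction of the
width.

Fields are millitesla throughout; conversion to tesla happens only inside
the point-dipole relation r = (2.79/D[T])^⅓ Å, which assumes g = g_e for
both spins and a point dipole — neglecting spin delocalisation makes the
result the shortest possible distance.

## Structure distances

"Edge-to-edge" is the minimum heavy-atom pair distance between two atom
selections. Published distance tables rarely state their convention; the
default sets here are the 14 isoalloxazine ring atoms of FMN, the phenol
ring carbons plus OH for Tyr, and the 9 indole ring atoms for Trp, all
configurable. Hydrogens are excluded by default (X-ray structures lack
them); disordered atoms keep altloc A. Reproducing published values for a
specific crystal structure requires that structure's PDB file and may
differ by tenths of an Å if the original atom-set convention differed.

## Synthetic data: what it emulates, and what not

Species spectra are sums of Gaussian bands at the positions characteristic
of each species (FMNox 450 nm; FMNH• 576/615 nm plus a minor 385 nm band;
Trp• broad 440–580 nm; TyrO• narrow 400 nm with a 380 nm shoulder; triplet
above 650 nm plus 360–410 nm). They are parametrised shapes, not digitised
spectra, so every ground truth is analytically exact and recovery tests
have unambiguous targets. Band amplitudes are on the scale of a ~0.5 OD
protein sample.

Noise is additive i.i.d. Gaussian in OD — the simplest model adequate for
recovery testing. Real data differ in ways the generator deliberately does
not model: wavelength-correlated baseline drift, photodamage and
reoxidation during acquisition, shot-noise heteroscedasticity, streak-image
readout artifacts (generation starts at the ΔA(t,λ) level the model
describes, not at raw camera frames), hyperfine structure in the EPR
doublet, and any illumination-dose dependence of the kinetics. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated noise model, not robustness to every instrumental pathology.

All generators take explicit integer seeds; equal seeds give bit-identical
arrays. Default study conditions mirror the measurement protocols the
analyses target: 5 s spectra over 150 s for photoreduction (τ = 25.7 s
ground truth), a 200 µs window with 512 time points and ≈400 ns IRF FWHM
for transient absorption (28.0 µs + non-decaying ground truth), 2 ns steps
to 1400 ns for nutation, and a 320–372 mT field sweep for the cw EPR
pattern (|D| = 4 mT, |E| = 0, 3 mT width). Recovery criteria at these
conditions: mean τ within 2% over 50 replicates at 1%-of-rise noise;
lifetime within 3% and DADS cosine similarity above 0.999 per seed at 0.5%
noise; |D| within 0.2 mT at 2% noise.

## Known limitations

* First-order powder patterns exclude g-anisotropy, hyperfine coupling and
  the half-field transition.
* Target (species-associated) kinetic schemes with branching are not
  implemented; the analysis stops at DADS.
* The detection-limit scheme assumes strictly consecutive first-order
  steps with no back-reaction.
* mmCIF structures are not parsed; PDB only.
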