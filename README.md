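# lovspec

Analysis toolkit for flavin photochemistry in cysteine-less LOV
photoreceptor proteins.

Wild-type LOV (light-oxygen-voltage) domains respond to blue light by
forming a covalent flavin–cysteine adduct. When the reactive cysteine is
absent, an alternative photochemistry takes over: the excited flavin triplet
state abstracts an electron from a nearby aromatic residue, producing a
radical pair of the neutral flavin semiquinone FMNH• and a tryptophanyl or
tyrosyl radical. `lovspec` implements the computational chain used to
characterise this process across three kinds of measurement, plus a
synthetic-data generator that provides exact ground truth for every stage.

## What it computes

**Steady-state photoreduction** (`lovspec.steady_state`). The FMNox → FMNH•
conversion is tracked by the absorbance rise at 615 nm and fit with the
saturating single-exponential

    A₆₁₅(t) = offset + A₁·exp(−t/τ_Sq),   A₁ < 0 for a rise.

Yields are ΔA₆₁₅ after a fixed illumination window, normalised to A₄₅₀(0);
an SVD component counter verifies that exactly two species contribute.

**Global lifetime analysis of transient absorption** (`lovspec.ta`). A 2-D
difference-absorption matrix is fit to

    ΔA(t, λ) = (D₀(λ)·δ(t) + Σⱼ Dⱼ(λ)·exp(−kⱼt)) ⊗ g_app(t − t₀),

with a Gaussian apparatus function and closed-form exp ⊗ Gaussian kernels,
by variable projection (the decay-associated difference spectra Dⱼ are
conditionally linear). A non-decaying component is encoded exactly as
k = 0. DADS can be unmixed into reference spectra (ordinary or nonnegative
least squares), and the module evaluates the consecutive-kinetics detection
limit: the peak concentration of the intermediate in A → B → C relative to
the final product is x^(1/(1−x)) with x = k_form/k_decay, so a detection
threshold translates into a maximum lifetime of an unseen intermediate.

**EPR analysis** (`lovspec.epr`). Spin-echo nutation traces are
Fourier-analysed; peaks are assigned through ν_nut = α·ω₁/2π with
α = √(S(S+1) − m_s(m_s+1)) (α = 1 for a doublet, √2 for the triplet
0 ↔ ±1 transitions). Triplet powder patterns are simulated to first order,
B_res = B₀ ± ½[D(3cos²θ − 1) + 3E·sin²θ·cos2φ], orientation-averaged on a
deterministic golden-spiral grid with Gaussian broadening, and fit for
(|D|, |E|, width, center). The point-dipole relation D = 2.79/r³ T·Å³
(g = g_e for both spins) converts |D| into a lower bound on the interspin
distance.

**Structure distances** (`lovspec.structure`). Edge-to-edge (minimum
heavy-atom) distances between the FMN isoalloxazine ring and aromatic
side-chain ring systems, from PDB coordinates.

## Worked example

The numbered drivers under `analysis/` run the whole chain on synthetic
data; each prints what it found and writes tables under `results/`:

```bash
python analysis/01_simulate_datasets.py
python analysis/02_photoreduction_kinetics.py
python analysis/03_global_lifetime_analysis.py
python analysis/04_epr_analysis.py
python analysis/05_structure_distances.py
```

Output of the kinetics, lifetime and EPR stages:

```
615 nm rise: tau = 25.65 ± 0.004 s (ground truth 25.7 s)
photoreduction yield metric ΔA615/A450(0) = 0.5222
SVD: 2 significant components (top singular values [12.619, 5.38, 0.064, 0.062])

GLA: DADS1 decays with tau = 27.99 µs (ground truth 28.0 µs); DADS2 non-decaying
DADS2 unmixing coefficients: {'FMNH-FMNox': 1.0001, 'TrpRad': -0.0001}
radical-anion detection limit: rate ratio 0.137 → lifetime bound 3.8 µs

nutation_center: peaks [10.0, 14.16] MHz → ['doublet S=1/2', 'triplet S=1']
  frequency ratio at center: 1.42 (√2 ≈ 1.41)
powder fit: |D| = 4.00 mT, |E| = 0.00 mT, width = 2.85 mT (truth 4 / 0 / 3)
point-dipole distance from |D|: r = 8.86 Å (prints as 9 ± 1 Å)
```

The recovered τ of 25.65 s and 27.99 µs match the simulation ground truths
within the noise; the nutation peaks at 10 and 14.16 MHz are the doublet and
triplet signatures at ω₁/2π = 10 MHz; |D| = 4 mT corresponds to a shortest
possible electron–electron distance of ≈9 Å.

The same operations are scriptable through the `lovspec` CLI
(`lovspec simulate …`, `lovspec fit …`, `lovspec rank`, `lovspec unmix`,
`lovspec detection-limit`, `lovspec nutation`, `lovspec distance`), each
emitting a JSON report that embeds the package version, seed and config
hash.

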