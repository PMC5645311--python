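"""Ground-truth synthetic data for every analysis stage.

The generators produce exactly the data the analysis modules consume:
steady-state photoreduction spectral series (two-state FMNox → FMNH• with
single-exponential kinetics), microsecond transient-absorption matrices from
the DADS ⊗ Gaussian-IRF forward model, damped spin-nutation traces, and cw
EPR line shapes (doublet + triplet powder pattern).

Species spectra are sums of Gaussian bands placed at the positions
characteristic of the flavin photocycle — oxidised FMN at 450 nm, the neutral
semiquinone radical FMNH• at 576/615 nm with a minor 385 nm band, the neutral
tryptophanyl radical broad between 440 and 580 nm, the tyrosyl radical as a
narrow 400 nm band with a 380 nm shoulder, and the flavin triplet above
650 nm plus a 360–410 nm band. They are parametrised shapes, not digitised
literature spectra, so every ground truth is analytically exact.

All stochastic output is controlled by an explicit integer seed; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lovspec.errors import ValidationError
from lovspec.io import SpeciesBasis, Spectrum, SpectralMatrix, TimeTrace
from lovspec.epr import ZeroFieldSplitting, nutation_alpha, simulate_triplet_powder
from lovspec.ta import convolved_exponential, gaussian_irf_kernel


@dataclass(frozen=True)
class BandShape:
    """A Gaussian absorption band: center (nm), σ width (nm), amplitude (OD)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValidationError(f"band width must be positive, got {self.width}")
        if not np.isfinite(self.amplitude):
            raise ValidationError("band amplitude must be finite")

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        d = (grid - self.center) / self.width
        return self.amplitude * np.exp(-0.5 * d * d)


#: default band parametrisation per species (centers/widths in nm)
DEFAULT_BANDS: dict[str, tuple[BandShape, ...]] = {
    "FMNox": (
        BandShape(450.0, 25.0, 1.00),
        BandShape(368.0, 16.0, 0.75),
    ),
    "FMNHrad": (
        BandShape(576.0, 15.0, 0.50),
        BandShape(615.0, 10.0, 0.50),
        BandShape(500.0, 40.0, 0.25),
        BandShape(385.0, 14.0, 0.35),
    ),
    "TrpRad": (
        BandShape(510.0, 45.0, 0.30),
    ),
    "TyrORad": (
        BandShape(400.0, 7.0, 0.40),
        BandShape(380.0, 6.0, 0.16),
    ),
    "Triplet": (
        BandShape(660.0, 12.0, 0.25),
        BandShape(700.0, 14.0, 0.18),
        BandShape(385.0, 18.0, 0.30),
        BandShape(500.0, 60.0, 0.12),
    ),
}


@dataclass
class SimulationConfig:
    """Bundle of generator parameters; the seed fixes all stochastic output."""

    seed: int = 0
    noise_sigma: float = 0.0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


def make_flavin_basis(grid, overrides: dict | None = None) -> SpeciesBasis:
    """Reference spectra of the flavin photocycle species on ``grid`` (nm).

    ``overrides`` maps species names to band tuples (replacing the default
    parametrisation) and may add user-defined species.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValidationError("wavelength grid must be 1-D and strictly ascending")
    bands = dict(DEFAULT_BANDS)
    if overrides:
        for name, shapes in overrides.items():
            bands[name] = tuple(
                s if isinstance(s, BandShape) else BandShape(*s) for s in shapes
            )
    basis = SpeciesBasis()
    for name, shapes in bands.items():
        values = np.zeros_like(grid)
        for band in shapes:
            values = values + band.evaluate(grid)
        basis.add(name, Spectrum(grid, values, label=name))
    return basis


def simulate_photoreduction_series(
    basis: SpeciesBasis,
    tau: float,
    t_grid,
    a450_initial: float = 0.5,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SpectralMatrix:
    """Two-state FMNox → FMNH• steady-state spectral series (time unit s).

    A(λ, t) = s·[(1 − x(t))·FMNox(λ) + x(t)·FMNH•(λ)], x(t) = 1 − exp(−t/τ),
    with the scale s chosen so A(450 nm, t=0) = ``a450_initial``; i.i.d.
    Gaussian noise of σ = ``noise_sigma`` (OD) is added when requested.
    """
    if tau <= 0:
        raise ValidationError(f"tau must be positive, got {tau}")
    if noise_sigma < 0:
        raise ValidationError(f"noise_sigma must be >= 0, got {noise_sigma}")
    t = np.asarray(t_grid, dtype=float)
    ox = basis["FMNox"]
    sq = basis["FMNHrad"]
    a450 = float(np.interp(450.0, ox.wavelengths, ox.values))
    if a450 <= 0:
        raise ValidationError("FMNox reference has no absorbance at 450 nm")
    scale = a450_initial / a450
    x = 1.0 - np.exp(-t / tau)
    clean = scale * (
        np.outer(ox.values, 1.0 - x) + np.outer(sq.values, x)
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, noise_sigma, size=clean.shape)
    return SpectralMatrix(
        ox.wavelengths, t, clean, "s", label="photoreduction series"
    )


def simulate_ta_matrix(
    dads: list[Spectrum],
    lifetimes,
    t_grid,
    t0: float = 0.0,
    irf_sigma: float = 0.17,
    d0: Spectrum | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SpectralMatrix:
    """Transient-absorption matrix from the DADS ⊗ Gaussian-IRF forward model.

    ``lifetimes`` are µs; ``inf`` encodes a non-decaying component (rate 0).
    The exp ⊗ Gaussian kernels are evaluated in closed form, so the noiseless
    output equals the analytic model to machine precision.
    """
    lifetimes = list(np.atleast_1d(np.asarray(lifetimes, dtype=float)))
    if len(dads) != len(lifetimes):
        raise ValidationError(
            f"{len(dads)} DADS but {len(lifetimes)} lifetimes"
        )
    for tau in lifetimes:
        if not np.isinf(tau) and tau <= 0:
            raise ValidationError(f"lifetime must be positive or inf, got {tau}")
    if irf_sigma <= 0:
        raise ValidationError(f"irf_sigma must be positive, got {irf_sigma}")
    if noise_sigma < 0:
        raise ValidationError(f"noise_sigma must be >= 0, got {noise_sigma}")
    t = np.asarray(t_grid, dtype=float)
    grid = dads[0].wavelengths
    for d in dads[1:]:
        if not np.array_equal(d.wavelengths, grid):
            raise ValidationError("all DADS must share one wavelength grid")
    matrix = np.zeros((grid.size, t.size))
    for spec, tau in zip(dads, lifetimes):
        k = 0.0 if np.isinf(tau) else 1.0 / tau
        matrix += np.outer(spec.values, convolved_exponential(k, t0, irf_sigma, t))
    if d0 is not None:
        if not np.array_equal(d0.wavelengths, grid):
            raise ValidationError("D0 must share the DADS wavelength grid")
        matrix += np.outer(d0.values, gaussian_irf_kernel(t, t0, irf_sigma))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        matrix = matrix + rng.normal(0.0, noise_sigma, size=matrix.shape)
    return SpectralMatrix(grid, t, matrix, "us", label="TA matrix")


def simulate_nutation_trace(
    omega1_over_2pi: float,
    species,
    tp_grid,
    damping: float = 600.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> TimeTrace:
    """Damped echo-nutation oscillations vs preparation-pulse length (ns).

    ``species`` is a list of ``(S, ms, weight)``: each contributes
    weight·cos(2π·α·ν1·t_p)·exp(−t_p/damping) with α from the nutation
    relation. ``omega1_over_2pi`` is ν1 in MHz, ``tp_grid`` in ns; noise is
    relative to the total weight.
    """
    if omega1_over_2pi <= 0:
        raise ValidationError("omega1_over_2pi must be positive")
    if damping <= 0:
        raise ValidationError("damping must be positive")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    t = np.asarray(tp_grid, dtype=float)
    signal = np.zeros_like(t)
    total_weight = 0.0
    for S, ms, weight in species:
        alpha = nutation_alpha(S, ms)  # raises on unknown (S, ms)
        nu_mhz = alpha * omega1_over_2pi
        signal += weight * np.cos(2.0 * np.pi * nu_mhz * 1e-3 * t) * np.exp(
            -t / damping
        )
        total_weight += abs(weight)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        scale = total_weight if total_weight > 0 else 1.0
        signal = signal + rng.normal(0.0, noise_sigma * scale, size=signal.shape)
    return TimeTrace(t, signal, "ns", label="nutation")


def simulate_cw_epr(
    field_grid,
    doublet: tuple[float, float, float] | None = None,
    triplet: tuple[ZeroFieldSplitting, float] | None = None,
    derivative: bool = False,
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_orientations: int = 2000,
) -> Spectrum:
    """cw EPR line shape: Gaussian doublet plus triplet powder pattern.

    ``doublet`` is (center mT, FWHM mT, weight); ``triplet`` is
    (:class:`~lovspec.epr.ZeroFieldSplitting`, weight). Weights scale
    integrated absorption intensity. ``derivative`` returns the
    field-modulation (first-derivative) representation; relative Gaussian
    noise is added last.
    """
    grid = np.asarray(field_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValidationError("field grid must be 1-D and strictly ascending")
    w_doublet = doublet[2] if doublet is not None else 0.0
    w_triplet = triplet[1] if triplet is not None else 0.0
    if w_doublet == 0 and w_triplet == 0:
        raise ValidationError("at least one of doublet/triplet must have weight > 0")
    values = np.zeros_like(grid)
    if doublet is not None and w_doublet != 0:
        center, fwhm, weight = doublet
        if fwhm <= 0:
            raise ValidationError("doublet width must be positive")
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        d = (grid - center) / sigma
        gauss = np.exp(-0.5 * d * d) / (sigma * np.sqrt(2.0 * np.pi))  # unit area
        values = values + weight * (-d / sigma * gauss if derivative else gauss)
    if triplet is not None and w_triplet != 0:
        zfs, weight = triplet
        powder = simulate_triplet_powder(
            zfs, grid, derivative=derivative, n_orientations=n_orientations
        )
        values = values + weight * powder.values
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        scale = float(np.max(np.abs(values))) or 1.0
        values = values + rng.normal(0.0, noise_sigma * scale, size=values.shape)
    return Spectrum(grid, values, label="cw EPR", axis_label="B_mT")
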