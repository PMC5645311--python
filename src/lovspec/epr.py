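"""Pulsed and cw EPR analysis: nutation spectra, zero-field splitting,
powder patterns, and point-dipole spin–spin distances.

Spin-state assignment rests on the nutation relation

    ν_nut = α · ω1 / 2π,   α = √(S(S+1) − m_s(m_s + 1)),

so a doublet (S = ½) nutates at α = 1 and the ms = 0 ↔ ±1 transitions of a
triplet (S = 1) at α = √2 — a frequency ratio of √2 ≈ 1.4 at equal microwave
field strength.

In the point-dipole approximation with both g-values taken as the
free-electron value, the triplet fine-structure parameter D maps onto the
interspin distance r through D = 2.79 / r³ T·Å³. Because neither the real
spectral shapes nor the spin-density delocalisation enter, the resulting r
is the shortest possible distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from lovspec.errors import FitError, ValidationError
from lovspec.io import Spectrum, TimeTrace

#: point-dipole fine-structure constant for g = g_e, in T·Å³
POINT_DIPOLE_CONSTANT = 2.79

SQRT2 = math.sqrt(2.0)

#: allowed single-quantum transitions and their nutation factors
ALLOWED_TRANSITIONS: dict[tuple[float, float], float] = {
    (0.5, -0.5): 1.0,  # S = ½, ms = −½ ↔ +½
    (1.0, 0.0): SQRT2,  # S = 1, ms = 0 ↔ +1
    (1.0, -1.0): SQRT2,  # S = 1, ms = −1 ↔ 0
}


def nutation_alpha(S: float, ms: float) -> float:
    """Nutation factor α = √(S(S+1) − ms(ms+1)) for the transition
    ms ↔ ms+1. ``ms`` is the lower level of the transition."""
    if S <= 0 or (2 * S) != int(round(2 * S)):
        raise ValidationError(f"S must be a positive half-integer, got {S}")
    if abs(ms) > S or ms + 1 > S + 1e-12:
        raise ValidationError(f"invalid transition ms={ms} ↔ {ms + 1} for S={S}")
    val = S * (S + 1) - ms * (ms + 1)
    if val <= 0:
        raise ValidationError(f"forbidden transition (S={S}, ms={ms})")
    return math.sqrt(val)


def distance_from_D(absD_mT: float) -> float:
    """Point-dipole interspin distance r (Å) from |D| (mT): r = (2.79/D[T])^⅓.

    Assumes g = g_e for both spins; the estimate is a lower bound on the true
    distance because spin delocalisation is neglected.
    """
    if absD_mT <= 0:
        raise ValidationError(f"|D| must be positive, got {absD_mT}")
    return (POINT_DIPOLE_CONSTANT / (absD_mT * 1e-3)) ** (1.0 / 3.0)


def D_from_distance(r_angstrom: float) -> float:
    """Inverse of :func:`distance_from_D`: |D| (mT) = 2.79/r³ T·Å³."""
    if r_angstrom <= 0:
        raise ValidationError(f"distance must be positive, got {r_angstrom}")
    return POINT_DIPOLE_CONSTANT / r_angstrom**3 * 1e3


@dataclass
class ZeroFieldSplitting:
    """Triplet fine-structure parameters on a magnetic-field axis (mT).

    ``gaussian_width`` is the FWHM of the inhomogeneous Gaussian line applied
    to every orientation. ``distance`` is the point-dipole interspin distance
    derived from |D|.
    """

    absD: float
    absE: float = 0.0
    gaussian_width: float = 3.0
    center_field: float = 0.0

    def __post_init__(self):
        if self.absD < 0:
            raise ValidationError(f"|D| must be >= 0, got {self.absD}")
        if not 0 <= self.absE <= self.absD / 3 + 1e-12:
            raise ValidationError(
                f"|E| must satisfy 0 <= |E| <= |D|/3, got |E|={self.absE}, |D|={self.absD}"
            )
        if self.gaussian_width <= 0:
            raise ValidationError(f"width must be positive, got {self.gaussian_width}")

    @property
    def distance(self) -> float:
        return distance_from_D(self.absD)


# ---------------------------------------------------------------------------
# nutation analysis


@dataclass
class FrequencyPeak:
    frequency: float  # MHz
    amplitude: float


@dataclass
class NutationResult:
    """Assignment of nutation-spectrum peaks to spin manifolds."""

    peaks: list[FrequencyPeak]
    alphas: list[float]
    assignments: list[tuple[float, float] | None]  # (S, ms) or unassigned
    omega1_over_2pi: float | None

    def spin_states(self) -> list[float | None]:
        return [a[0] if a is not None else None for a in self.assignments]


@dataclass
class NutationSpectrum:
    frequencies: np.ndarray  # MHz
    amplitudes: np.ndarray
    peaks: list[FrequencyPeak]


def nutation_spectrum(
    trace: TimeTrace, peak_threshold: float = 0.2, pad_factor: int = 4
) -> NutationSpectrum:
    """Magnitude Fourier spectrum of a nutation time trace.

    The trace (echo amplitude vs preparation-pulse length, ns) is
    mean-subtracted, Hamming-windowed and zero-padded 4×; peaks are local
    maxima above ``peak_threshold`` of the global maximum, refined by
    parabolic interpolation. Frequencies are MHz.
    """
    if trace.unit != "ns":
        raise ValidationError(f"nutation traces must be in ns, got {trace.unit!r}")
    if len(trace) < 16:
        raise ValidationError(f"need >= 16 points, got {len(trace)}")
    dt = np.diff(trace.times)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
        raise ValidationError("nutation trace must be uniformly sampled")
    dt_ns = float(dt[0])

    y = trace.values - trace.values.mean()
    y = y * np.hamming(y.size)
    n_fft = pad_factor * y.size
    amp = np.abs(np.fft.rfft(y, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=dt_ns) * 1e3  # 1/ns → MHz

    peaks: list[FrequencyPeak] = []
    if amp.max() > 0:
        floor = peak_threshold * amp.max()
        for i in range(1, amp.size - 1):
            if amp[i] >= floor and amp[i] > amp[i - 1] and amp[i] >= amp[i + 1]:
                # parabolic refinement through the three points around the max
                denom = amp[i - 1] - 2 * amp[i] + amp[i + 1]
                delta = 0.5 * (amp[i - 1] - amp[i + 1]) / denom if denom != 0 else 0.0
                f = freqs[i] + delta * (freqs[1] - freqs[0])
                a = amp[i] - 0.25 * (amp[i - 1] - amp[i + 1]) * delta
                peaks.append(FrequencyPeak(float(f), float(a)))
    peaks.sort(key=lambda p: p.frequency)
    return NutationSpectrum(freqs, amp, peaks)


def assign_transitions(
    peaks, omega1_over_2pi: float | None = None, tolerance: float = 0.10
) -> NutationResult:
    """Assign nutation peaks to (S, ms) transitions via their α factors.

    With the microwave field strength ω1/2π known, α = ν_peak/(ω1/2π); when
    unknown, the lowest peak is taken as the α = 1 doublet reference and the
    others assigned by frequency ratio. Peaks matching no allowed α within
    ``tolerance`` (relative) are flagged unassigned.
    """
    freqs = [p.frequency if isinstance(p, FrequencyPeak) else float(p) for p in peaks]
    if not freqs:
        raise ValidationError("no peaks to assign")
    if any(f <= 0 for f in freqs):
        raise ValidationError("peak frequencies must be positive")
    ref = omega1_over_2pi if omega1_over_2pi is not None else min(freqs)
    alphas = [f / ref for f in freqs]
    assignments: list[tuple[float, float] | None] = []
    for alpha in alphas:
        best, best_err = None, tolerance
        for (S, ms), a in ALLOWED_TRANSITIONS.items():
            err = abs(alpha - a) / a
            if err <= best_err:
                # prefer the canonical ms=0 label for the triplet
                if best is None or err < best_err:
                    best, best_err = (S, ms), err
        assignments.append(best)
    peak_objs = [
        p if isinstance(p, FrequencyPeak) else FrequencyPeak(float(p), math.nan)
        for p in peaks
    ]
    return NutationResult(peak_objs, alphas, assignments, omega1_over_2pi)


# ---------------------------------------------------------------------------
# triplet powder pattern


def _golden_spiral(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic quasi-uniform orientations: returns (cosθ, φ)."""
    i = np.arange(n)
    cos_theta = (2 * i + 1.0) / n - 1.0
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    return cos_theta, phi


def triplet_resonance_fields(
    zfs: ZeroFieldSplitting, n_orientations: int = 2000
) -> np.ndarray:
    """First-order ΔMs = ±1 resonance-field offsets for a quasi-uniform
    orientation grid; shape (2·n_orientations,), in mT relative to center.

    B_res(θ, φ) = B0 ± ½·[D(3cos²θ − 1) + 3E sin²θ cos2φ]
    """
    cos_t, phi = _golden_spiral(n_orientations)
    sin2 = 1.0 - cos_t**2
    shift = 0.5 * (
        zfs.absD * (3.0 * cos_t**2 - 1.0) + 3.0 * zfs.absE * sin2 * np.cos(2 * phi)
    )
    return np.concatenate([shift, -shift])


def simulate_triplet_powder(
    zfs: ZeroFieldSplitting,
    field_grid,
    derivative: bool = False,
    n_orientations: int = 2000,
) -> Spectrum:
    """Orientation-averaged triplet EPR line shape on a field grid (mT).

    Uses first-order (high-field) resonance expressions — adequate while
    D ≪ the X-band resonance field — with every orientation contributing a
    Gaussian of FWHM ``zfs.gaussian_width``. The absorption spectrum is
    normalised to unit integrated intensity; ``derivative`` returns its first
    derivative (cw field-modulation convention).
    """
    grid = np.asarray(field_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ValidationError("field grid must be 1-D and strictly increasing")
    span_needed = zfs.absD + 3.0 * zfs.gaussian_width
    if (
        grid[0] > zfs.center_field - span_needed
        or grid[-1] < zfs.center_field + span_needed
    ):
        raise ValidationError(
            f"field grid must span center ± {span_needed:.2f} mT "
            f"(center {zfs.center_field} mT)"
        )
    sigma = zfs.gaussian_width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    b_res = zfs.center_field + triplet_resonance_fields(zfs, n_orientations)

    d = (grid[None, :] - b_res[:, None]) / sigma
    gauss = np.exp(-0.5 * d * d)
    absorption = gauss.sum(axis=0)
    norm = np.trapezoid(absorption, grid)
    if norm <= 0:
        raise ValidationError("powder pattern has zero intensity on this grid")
    if derivative:
        deriv = (-d / sigma * gauss).sum(axis=0) / norm
        values = deriv
    else:
        values = absorption / norm
    return Spectrum(grid, values, label="triplet powder", axis_label="B_mT")


@dataclass
class PowderFitReport:
    zfs: ZeroFieldSplitting
    amplitude: float
    rms: float
    n_starts: int
    success: bool


def fit_powder_pattern(
    spectrum: Spectrum,
    init: ZeroFieldSplitting,
    derivative: bool = False,
    n_orientations: int = 2000,
    d_start_factors=(0.5, 1.0, 2.0),
) -> PowderFitReport:
    """Least-squares fit of the triplet powder model to a field-swept spectrum.

    Free parameters: |D|, |E| (as the rhombicity fraction |E|/|D| ∈ [0, ⅓]),
    Gaussian FWHM, center field and an overall amplitude; multi-start on |D|.
    """
    grid = spectrum.wavelengths
    y = spectrum.values

    def model(params):
        absD, e_frac, width, center, amplitude = params
        zfs = ZeroFieldSplitting(absD, e_frac * absD, width, center)
        sim = simulate_triplet_powder(
            zfs, grid, derivative=derivative, n_orientations=n_orientations
        )
        return amplitude * sim.values

    def residual(params):
        return model(params) - y

    span = float(grid[-1] - grid[0])
    scale = float(np.max(np.abs(y))) or 1.0
    best = None
    lb = [1e-6, 0.0, 1e-3, grid[0], 0.0]
    ub = [span, 1.0 / 3.0, span, grid[-1], np.inf]
    for factor in d_start_factors:
        d0 = min(max(init.absD * factor, 2e-6), span * 0.9)
        p0 = [
            d0,
            min(init.absE / init.absD, 1.0 / 3.0) if init.absD > 0 else 0.0,
            init.gaussian_width,
            init.center_field,
            scale,
        ]
        p0 = np.clip(p0, lb, ub)
        try:
            fit = optimize.least_squares(
                residual, p0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12, x_scale="jac"
            )
        except Exception:
            continue
        if best is None or fit.cost < best.cost:
            best = fit
    if best is None or not best.success:
        raise FitError("powder-pattern fit failed to converge from all starts")
    absD, e_frac, width, center, amplitude = best.x
    resid = residual(best.x)
    return PowderFitReport(
        zfs=ZeroFieldSplitting(float(absD), float(e_frac * absD), float(width), float(center)),
        amplitude=float(amplitude),
        rms=float(np.sqrt(np.mean(resid**2))),
        n_starts=len(d_start_factors),
        success=True,
    )


def decompose_cw_series(
    spectra: list[Spectrum], doublet_ref: Spectrum, triplet_ref: Spectrum
) -> np.ndarray:
    """Nonnegative doublet/triplet fractions for an annealing series.

    Each spectrum is fit as a nonnegative linear combination of the two
    references (shared field grid); returns an (n, 2) array of
    (doublet, triplet) coefficients in reference units.
    """
    if not spectra:
        raise ValidationError("empty spectrum list")
    grid = doublet_ref.wavelengths
    if not np.array_equal(triplet_ref.wavelengths, grid):
        raise ValidationError("references must share one field grid")
    A = np.column_stack([doublet_ref.values, triplet_ref.values])
    if np.linalg.matrix_rank(A) < 2:
        raise ValidationError("doublet and triplet references are collinear")
    out = np.empty((len(spectra), 2))
    for i, spec in enumerate(spectra):
        if not np.array_equal(spec.wavelengths, grid):
            raise ValidationError(f"spectrum {i} is not on the reference field grid")
        out[i], _ = optimize.nnls(A, spec.values)
    return out
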