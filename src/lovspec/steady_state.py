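"""Steady-state photoreduction analysis: single-exponential kinetics,
yields, pH profiles and SVD component counting.

The photoreduction of oxidised FMN to the neutral semiquinone radical FMNH•
is tracked by the absorbance rise at 615 nm. The time course is fit with the
saturating single-exponential form

    A(t) = offset + A1 · exp(−t/τ)

(A1 < 0 for a rise); the photoreduction yield is the 615 nm rise after a
fixed illumination window, normalised to the initial 450 nm absorbance of the
oxidised flavin to cancel concentration differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from lovspec.errors import FitError, SpectralRangeError, ValidationError
from lovspec.io import SpectralMatrix, TimeTrace


def extract_trace(matrix: SpectralMatrix, wavelength: float) -> TimeTrace:
    """Time trace at the grid wavelength nearest the request (no interpolation,
    matching discrete spectrophotometer acquisition). The chosen wavelength is
    recorded in the trace label."""
    wl = matrix.wavelengths
    if not wl[0] <= wavelength <= wl[-1]:
        raise SpectralRangeError(
            f"{wavelength} nm outside data range [{wl[0]}, {wl[-1]}] nm"
        )
    idx = int(np.argmin(np.abs(wl - wavelength)))
    return TimeTrace(
        matrix.times,
        matrix.values[idx, :],
        matrix.time_unit,
        label=f"{wl[idx]:g} nm",
    )


@dataclass
class KineticFit:
    """Single-exponential fit A(t) = offset + A1·exp(−t/τ)."""

    tau: float
    amplitude: float  # A1, signed: negative for a rise
    offset: float
    stderr: dict[str, float]
    rms: float
    unit: str
    degenerate: bool = False  # |A1| below the resolvable threshold

    @property
    def initial_value(self) -> float:
        """A(t=0) = offset + A1."""
        return self.offset + self.amplitude


def _monoexp(t, offset, a1, tau):
    return offset + a1 * np.exp(-t / tau)


def fit_monoexponential(trace: TimeTrace, n_starts: int = 12) -> KineticFit:
    """Least-squares single-exponential fit with multi-start over τ.

    τ starts are log-spaced over [Δt, 10·t_max]; for each start the two linear
    parameters are solved exactly and the best candidate is polished by
    nonlinear least squares. Standard errors come from the covariance of the
    converged fit. If the fitted |A1| is below 1e-6 of the data range the fit
    is flagged degenerate (a constant trace carries no lifetime information).
    """
    if len(trace) < 4:
        raise ValidationError(f"need >= 4 points, got {len(trace)}")
    t = trace.times - trace.times[0]
    y = trace.values
    data_range = float(np.ptp(y))

    dt = float(np.min(np.diff(t)))
    t_max = float(t[-1])
    tau_grid = np.geomspace(max(dt, 1e-12 * t_max if t_max else 1e-12), 10 * t_max, n_starts)

    best = None  # (rss, tau, offset, a1)
    for tau in tau_grid:
        basis = np.column_stack([np.ones_like(t), np.exp(-t / tau)])
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
        rss = float(np.sum((basis @ coef - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, tau, coef[0], coef[1])

    def residual(params):
        offset, a1, log_tau = params
        return _monoexp(t, offset, a1, math.exp(log_tau)) - y

    p0 = np.array([best[2], best[3], math.log(best[1])])
    fit = optimize.least_squares(residual, p0, method="lm", xtol=1e-15, ftol=1e-15)
    if not fit.success:
        raise FitError(
            "single-exponential fit did not converge",
            {"best_start_tau": best[1], "rss": best[0]},
        )
    offset, a1, log_tau = fit.x
    tau = math.exp(log_tau)
    resid = fit.fun
    rms = float(np.sqrt(np.mean(resid**2)))

    degenerate = data_range == 0 or abs(a1) < 1e-6 * data_range

    # covariance of (offset, a1, tau) from the converged Jacobian
    stderr = {"offset": math.nan, "amplitude": math.nan, "tau": math.nan}
    dof = len(t) - 3
    if dof > 0 and not degenerate:
        J = fit.jac.copy()
        J[:, 2] *= tau  # d/d(log τ) → d/dτ
        try:
            cov = np.linalg.inv(J.T @ J) * (resid @ resid) / dof
            err = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            stderr = {
                "offset": float(err[0]),
                "amplitude": float(err[1]),
                "tau": float(err[2]),
            }
        except np.linalg.LinAlgError:
            pass

    return KineticFit(
        tau=tau,
        amplitude=float(a1),
        offset=float(offset),
        stderr=stderr,
        rms=rms,
        unit=trace.unit,
        degenerate=degenerate,
    )


@dataclass
class YieldResult:
    """Photoreduction yield: probe-wavelength rise over the illumination
    window, normalised to the initial norm-wavelength absorbance."""

    delta_a_probe: float
    a_norm_initial: float
    yield_metric: float
    probe_nm: float
    norm_nm: float
    t_window: float
    relative_yield: float | None = None


def photoreduction_yield(
    matrix: SpectralMatrix,
    window: float = 150.0,
    probe: float = 615.0,
    norm: float = 450.0,
) -> YieldResult:
    """yield = [A(probe, t_w) − A(probe, 0)] / A(norm, 0), with t_w the last
    recorded time ≤ ``window`` (times in the matrix unit, s for steady state)."""
    t = matrix.times
    if window > t[-1]:
        raise ValidationError(
            f"window {window} exceeds the last time point {t[-1]}"
        )
    i_window = int(np.searchsorted(t, window, side="right") - 1)
    if i_window < 0:
        raise ValidationError(f"no time point at or before {window}")
    probe_trace = extract_trace(matrix, probe)
    norm_trace = extract_trace(matrix, norm)
    a_norm0 = float(norm_trace.values[0])
    if a_norm0 <= 0:
        raise ValidationError(
            f"initial absorbance at {norm} nm must be positive, got {a_norm0}"
        )
    delta = float(probe_trace.values[i_window] - probe_trace.values[0])
    return YieldResult(
        delta_a_probe=delta,
        a_norm_initial=a_norm0,
        yield_metric=delta / a_norm0,
        probe_nm=probe,
        norm_nm=norm,
        t_window=float(t[i_window]),
    )


def relative_yield(variant: YieldResult, reference: YieldResult) -> float:
    """Variant yield as a percentage of the reference yield."""
    if reference.yield_metric <= 0:
        raise ValidationError("reference yield must be positive")
    return 100.0 * variant.yield_metric / reference.yield_metric


def ph_profile(results: list[tuple[float, YieldResult]]) -> pd.DataFrame:
    """Express yields across a pH series as percent of the maximum.

    Returns a DataFrame (pH, yield_metric, percent_of_max) sorted by pH; the
    maximum entry reads 100%.
    """
    if not results:
        raise ValidationError("empty pH series")
    ph = [p for p, _ in results]
    metrics = [r.yield_metric for _, r in results]
    if any(m < 0 for m in metrics):
        raise ValidationError("yields must be >= 0")
    peak = max(metrics)
    if peak == 0:
        raise ValidationError("all yields are zero; no maximum to normalise to")
    df = pd.DataFrame(
        {
            "pH": ph,
            "yield_metric": metrics,
            "percent_of_max": [100.0 * m / peak for m in metrics],
        }
    ).sort_values("pH", ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# SVD component counting


@dataclass
class RankReport:
    """Significant-component count from the SVD of a spectral series."""

    singular_values: np.ndarray  # descending
    noise_floor: float
    n_significant: int
    left_autocorr: np.ndarray  # lag-1, per component (spectral vectors)
    right_autocorr: np.ndarray  # lag-1, per component (time vectors)
    noise_factor: float
    autocorr_threshold: float


def _lag1_autocorr(v: np.ndarray) -> float:
    denom = float(v @ v)
    if denom == 0:
        return 0.0
    return float(v[:-1] @ v[1:]) / denom


def svd_rank(
    matrix: SpectralMatrix,
    noise_factor: float = 5.0,
    autocorr_threshold: float = 0.5,
) -> RankReport:
    """Count the spectrally significant components of a series.

    The SVD is taken on the raw (uncentered) matrix, since the question is
    how many absolute component spectra contribute, not how many variance
    directions. The noise floor is the median of the trailing half of the
    singular values (floored at numerical rank resolution); a component is
    significant when its singular value exceeds ``noise_factor`` × floor AND
    its right (time-domain) singular vector has lag-1 autocorrelation above
    ``autocorr_threshold`` — random noise vectors decorrelate at lag 1, real
    concentration profiles do not. Components are counted from the top until
    the first insignificant one.
    """
    n_rows, n_cols = matrix.shape
    if n_cols < 3:
        raise ValidationError(f"need >= 3 time columns, got {n_cols}")
    U, s, Vt = np.linalg.svd(matrix.values, full_matrices=False)
    m = s.size
    trailing = s[m // 2 :]
    eps_floor = s[0] * max(n_rows, n_cols) * np.finfo(float).eps
    floor = max(float(np.median(trailing)), eps_floor)

    left_ac = np.array([_lag1_autocorr(U[:, i]) for i in range(m)])
    right_ac = np.array([_lag1_autocorr(Vt[i, :]) for i in range(m)])

    n_significant = 0
    for i in range(m):
        if s[i] > noise_factor * floor and right_ac[i] > autocorr_threshold:
            n_significant += 1
        else:
            break
    return RankReport(
        singular_values=s,
        noise_floor=floor,
        n_significant=n_significant,
        left_autocorr=left_ac,
        right_autocorr=right_ac,
        noise_factor=noise_factor,
        autocorr_threshold=autocorr_threshold,
    )
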