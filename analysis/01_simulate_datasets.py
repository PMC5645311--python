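#!/usr/bin/env python
"""Generate the synthetic datasets consumed by the downstream analyses.

Produces, under results/data/:
  * photoreduction.csv — steady-state FMNox → FMNH• series (τ = 25.7 s,
    5 s increments over 150 s, noise σ = 1% of the 615 nm rise)
  * ta_matrix.csv — two-component transient-absorption matrix
    (28.0 µs triplet decay + non-decaying radical pair, IRF σ = 0.4 µs,
    0.5% noise, 200 µs window)
  * nutation_center.csv / nutation_lowfield.csv — echo-nutation traces at
    the spectrum center (doublet + triplet) and at the low-field edge
    (triplet only)
  * cw_epr.csv — doublet + triplet cw EPR spectrum (|D| = 4 mT, |E| = 0,
    3 mT Gaussian width)
"""

import sys
from pathlib import Path

import numpy as np

from lovspec import epr, io, synth

SEED = 20260919
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    grid = np.arange(300.0, 701.0, 1.0)
    basis = synth.make_flavin_basis(grid)

    # --- steady-state photoreduction series
    t = np.arange(0.0, 151.0, 5.0)
    clean = synth.simulate_photoreduction_series(basis, 25.7, t)
    rise = abs(clean.values[np.argmin(np.abs(grid - 615.0)), -1]
               - clean.values[np.argmin(np.abs(grid - 615.0)), 0])
    series = synth.simulate_photoreduction_series(
        basis, 25.7, t, noise_sigma=0.01 * rise, seed=SEED
    )
    io.write_spectral_matrix(series, OUT / "photoreduction.csv")

    # --- transient absorption
    ta_grid = np.linspace(340.0, 680.0, 100)
    ta_basis = synth.make_flavin_basis(ta_grid)
    dads1 = ta_basis["Triplet"].with_values(
        ta_basis["Triplet"].values - ta_basis["FMNox"].values, "DADS1"
    )
    dads2 = ta_basis["FMNHrad"].with_values(
        ta_basis["FMNHrad"].values - ta_basis["FMNox"].values, "DADS2"
    )
    scale = max(np.max(np.abs(dads1.values)), np.max(np.abs(dads2.values)))
    matrix = synth.simulate_ta_matrix(
        [dads1, dads2], [28.0, np.inf], np.linspace(0.0, 200.0, 512),
        t0=2.0, irf_sigma=0.4, noise_sigma=0.005 * scale, seed=SEED + 1,
    )
    io.write_spectral_matrix(matrix, OUT / "ta_matrix.csv")

    # --- nutation traces (2 ns steps to 1400 ns, as in a typical X-band setup)
    tp = np.arange(2.0, 1402.0, 2.0)
    center = synth.simulate_nutation_trace(
        10.0, [(0.5, -0.5, 1.0), (1.0, 0.0, 0.7)], tp,
        damping=600.0, noise_sigma=0.02, seed=SEED + 2,
    )
    io.write_trace(center, OUT / "nutation_center.csv")
    lowfield = synth.simulate_nutation_trace(
        10.0, [(1.0, 0.0, 1.0)], tp, damping=600.0, noise_sigma=0.02,
        seed=SEED + 3,
    )
    io.write_trace(lowfield, OUT / "nutation_lowfield.csv")

    # --- cw EPR spectrum
    b_grid = np.arange(320.0, 372.1, 0.1)
    zfs = epr.ZeroFieldSplitting(4.0, 0.0, 3.0, 346.0)
    cw = synth.simulate_cw_epr(
        b_grid, doublet=(346.0, 1.5, 0.5), triplet=(zfs, 1.0),
        noise_sigma=0.01, seed=SEED + 4,
    )
    io.write_spectrum(cw, OUT / "cw_epr.csv")

    print(f"wrote 5 synthetic datasets to {OUT}")


if __name__ == "__main__":
    sys.exit(main())
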