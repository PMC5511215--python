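"""z-scan FCS: autocorrelation fitting, the diffusion-law parabola, t-tests.

A membrane positioned at offset z from the beam waist is illuminated with an
effective area w(z)^2 = w0^2 [1 + (lambda z / (pi w0^2 n))^2]; the dwell
time of a freely diffusing probe therefore follows the diffusion-law
parabola

    tau_diff(z) = (w0^2 / 4D) * [1 + (lambda (z - z0) / (pi w0^2 n))^2]

whose minimum locates the true waist position z0 and whose curvature
calibrates the beam waist w0, giving a diffusion coefficient D free of
focal-position bias.  Per-curve autocorrelations follow the standard 2D
free-diffusion model G(lag) = (1/N) (1 + lag/tau_diff)^-1 (triplet term
omitted by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

__all__ = [
    "FcsCurve",
    "ZScanSeries",
    "ZScanFitResult",
    "acf_2d",
    "fit_acf",
    "diffusion_law_tau",
    "zscan_diffusion_fit",
    "compare_diffusion",
]


@dataclass
class FcsCurve:
    """One autocorrelation curve: lag times (s), G values, z offset (nm)."""

    lags: np.ndarray
    g: np.ndarray
    z_offset: float = 0.0
    duration: float = 60.0

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lag times must be strictly increasing")


@dataclass
class ZScanSeries:
    """Per-z fitted dwell times and particle numbers plus beam parameters."""

    z: np.ndarray  # nm, relative to the nominal waist
    tau_diff: np.ndarray  # s
    n_particles: np.ndarray
    wavelength: float = 470.0  # nm
    refractive_index: float = 1.33

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.tau_diff = np.asarray(self.tau_diff, dtype=float)
        self.n_particles = np.asarray(self.n_particles, dtype=float)
        if len(self.z) < 5:
            raise ValueError("a z-scan needs at least 5 positions")
        if np.any(self.tau_diff <= 0):
            raise ValueError("dwell times must be positive")


@dataclass
class ZScanFitResult:
    diffusion_coefficient: float  # um^2/s
    waist: float  # nm
    z0: float  # nm
    stderr: dict[str, float] = field(default_factory=dict)
    chi2_red: float = float("nan")
    extrapolated: bool = False


def acf_2d(lag, n_particles: float, tau_diff: float):
    """2D free-diffusion autocorrelation G = (1/N) (1 + lag/tau)^-1."""
    if n_particles <= 0 or tau_diff <= 0:
        raise ValueError("N and tau_diff must be positive")
    lag = np.asarray(lag, dtype=float)
    g = (1.0 / n_particles) / (1.0 + lag / tau_diff)
    return g if g.ndim else float(g)


def fit_acf(curve: FcsCurve, weights: np.ndarray | None = None) -> tuple[float, float]:
    """Fit (N, tau_diff) of the 2D model to one autocorrelation curve."""
    g0 = max(curve.g[0], 1e-6)
    half = g0 / 2
    i_half = int(np.argmin(np.abs(curve.g - half)))
    params = lmfit.Parameters()
    params.add("n_particles", value=1.0 / g0, min=1e-6)
    params.add("tau_diff", value=max(curve.lags[i_half], curve.lags[0]), min=1e-9)

    def residual(p):
        r = curve.g - acf_2d(curve.lags, p["n_particles"].value, p["tau_diff"].value)
        return r * weights if weights is not None else r

    out = lmfit.minimize(residual, params)
    return float(out.params["n_particles"].value), float(out.params["tau_diff"].value)


def diffusion_law_tau(z, d_um2_s: float, waist_nm: float, z0_nm: float,
                      wavelength_nm: float = 470.0, refractive_index: float = 1.33):
    """tau_diff(z) in seconds for membrane offset z (nm) from the waist."""
    z = np.asarray(z, dtype=float)
    beam = wavelength_nm * (z - z0_nm) / (np.pi * waist_nm**2 * refractive_index)
    tau0 = (waist_nm**2 * 1e-6) / (4.0 * d_um2_s)  # nm^2 -> um^2
    tau = tau0 * (1.0 + beam**2)
    return tau if tau.ndim else float(tau)


def zscan_diffusion_fit(series: ZScanSeries,
                        weights: np.ndarray | None = None) -> ZScanFitResult:
    """Fit the diffusion-law parabola to a z-scan dwell-time series.

    Initial values come from a quadratic fit of tau(z); the refined fit is
    weighted least squares.  If the fitted minimum z0 falls outside the
    scanned range the result is flagged as an extrapolation.
    """
    z, tau = series.z, series.tau_diff
    lam, n_ref = series.wavelength, series.refractive_index
    # closed-form initialisation from tau ~ A + B (z - z0)^2
    c2, c1, c0 = np.polyfit(z, tau, 2)
    if c2 > 0:
        z0_init = -c1 / (2 * c2)
        a_init = max(c0 - c2 * z0_init**2, 1e-9)
        w0_init = (a_init * lam**2 / (np.pi**2 * n_ref**2 * max(c2, 1e-30))) ** 0.25
        d_init = w0_init**2 * 1e-6 / (4 * a_init)
    else:
        z0_init, w0_init = float(z[np.argmin(tau)]), 250.0
        d_init = w0_init**2 * 1e-6 / (4 * tau.min())

    params = lmfit.Parameters()
    params.add("d", value=max(d_init, 1e-4), min=1e-6)
    params.add("w0", value=min(max(w0_init, 50.0), 2000.0), min=10.0)
    params.add("z0", value=z0_init)

    def residual(p):
        model = diffusion_law_tau(z, p["d"].value, p["w0"].value, p["z0"].value, lam, n_ref)
        r = tau - model
        return r * weights if weights is not None else r

    out = lmfit.minimize(residual, params)
    stderr = {
        k: float(out.params[k].stderr) if out.params[k].stderr else float("nan")
        for k in ("d", "w0", "z0")
    }
    z0 = float(out.params["z0"].value)
    return ZScanFitResult(
        diffusion_coefficient=float(out.params["d"].value),
        waist=float(out.params["w0"].value),
        z0=z0,
        stderr=stderr,
        chi2_red=float(out.redchi),
        extrapolated=not (z.min() <= z0 <= z.max()),
    )


def compare_diffusion(
    group_a, group_b, alpha: float = 0.1
) -> tuple[float, bool]:
    """Two-sample unequal-variance t-test on diffusion coefficients.

    Returns (p_value, significant) with significance declared at p < alpha
    (default 0.1).  Requires at least 3 values per group; two groups with
    zero variance each are rejected as untestable.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    if a.std() == 0 and b.std() == 0:
        raise ValueError("both groups have zero variance; t-test undefined")
    t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(p), bool(p < alpha)
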