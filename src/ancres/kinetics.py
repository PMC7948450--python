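"""Flavoenzyme kinetics fitting.

Steady-state Michaelis-Menten fits with censored K_M reporting, conversion of
NAD(P)H absorbance slopes to observed rates, catalytic efficiencies at the
precision kinetics tables print, and stopped-flow half-reaction analysis:
single-exponential traces give k_obs, and the hyperbolic saturation of k_obs
with coenzyme concentration gives the limiting reduction rate k_red and the
dissociation constant K_d.

All fits are unweighted nonlinear least squares (scipy ``curve_fit``) with
data-driven initial guesses: k_cat from the largest observed rate, K_M from
the concentration nearest half-saturation, k_obs from the half-amplitude
time.  When the fitted K_M falls below the lowest assayed substrate
concentration the point estimate is unstable and only the bound
"< c_min" is reported, with the numeric estimate retained for inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class RateDataset:
    """Steady-state observations: substrate concentration (µM) vs rate (s⁻¹)."""

    conc_uM: np.ndarray
    rate_per_s: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self):
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        self.rate_per_s = np.asarray(self.rate_per_s, dtype=float)
        if self.conc_uM.shape != self.rate_per_s.shape:
            raise ValueError("concentration and rate arrays differ in shape")
        if np.any(self.conc_uM < 0):
            raise ValueError("negative substrate concentration")
        if not np.all(np.isfinite(self.rate_per_s)):
            raise ValueError("non-finite rate observations")

    @classmethod
    def read_csv(cls, path) -> "RateDataset":
        df = pd.read_csv(path)
        rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
        return cls(df["conc_uM"].to_numpy(), df["rate_per_s"].to_numpy(), rep)


@dataclass
class MMFit:
    k_cat: float               # s^-1
    K_M: float                 # µM (point estimate, even when censored)
    k_cat_se: float
    K_M_se: float
    censored: bool
    K_M_report: str            # "13" or "<2.5"


@dataclass
class TraceFit:
    k_obs: float               # s^-1
    amplitude: float
    offset: float
    k_obs_se: float
    wavelength_nm: int | None = None
    degenerate: bool = False


@dataclass
class SaturationFit:
    k_red: float               # s^-1
    K_d: float                 # µM
    k_red_se: float
    K_d_se: float


def rate_from_absorbance(slope_per_min: float, enzyme_uM: float,
                         epsilon_mM_cm: float = 6.22,
                         path_cm: float = 1.0) -> float:
    """Observed rate (s⁻¹ per enzyme) from an A340 slope (ΔA/min).

    Beer-Lambert: slope / (ε·l) gives mM NAD(P)H consumed per minute; divide
    by the enzyme concentration and convert to per second.  Defaults use the
    NADPH extinction coefficient 6.22 mM⁻¹cm⁻¹ in a 1-cm cuvette.
    """
    if enzyme_uM <= 0:
        raise ValueError("enzyme concentration must be positive")
    if epsilon_mM_cm <= 0 or path_cm <= 0:
        raise ValueError("extinction coefficient and path length must be positive")
    uM_per_min = slope_per_min / (epsilon_mM_cm * path_cm) * 1000.0
    return uM_per_min / enzyme_uM / 60.0


def michaelis_menten(s, vmax, km):
    return vmax * s / (km + s)


def _mm_initial_guess(conc, rate):
    vmax0 = float(rate.max())
    if vmax0 <= 0:
        vmax0 = 1.0
    half = vmax0 / 2.0
    km0 = float(conc[np.argmin(np.abs(rate - half))])
    if km0 <= 0:
        km0 = float(np.median(conc[conc > 0])) if np.any(conc > 0) else 1.0
    return vmax0, km0


def _fit_hyperbola(conc, rate):
    p0 = _mm_initial_guess(conc, rate)
    popt, pcov = curve_fit(michaelis_menten, conc, rate, p0=p0, maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    return popt, perr


def fit_michaelis_menten(data: RateDataset) -> MMFit:
    """Unweighted least-squares Michaelis-Menten fit with K_M censoring.

    When the fitted K_M lies below the lowest assayed concentration it is
    reported as a bound ("< c_min") and flagged ``censored``.
    """
    conc, rate = data.conc_uM, data.rate_per_s
    if len(np.unique(conc)) < 3:
        raise ValueError("need at least 3 distinct substrate concentrations")
    (k_cat, K_M), (k_cat_se, K_M_se) = _fit_hyperbola(conc, rate)
    if k_cat <= 0 or K_M <= 0:
        raise RuntimeError(
            f"non-physical Michaelis-Menten fit: k_cat={k_cat:.4g}, "
            f"K_M={K_M:.4g}")
    c_min = float(conc[conc > 0].min())
    censored = bool(K_M < c_min)
    report = f"<{c_min:g}" if censored else f"{K_M:g}"
    return MMFit(k_cat=float(k_cat), K_M=float(K_M),
                 k_cat_se=float(k_cat_se), K_M_se=float(K_M_se),
                 censored=censored, K_M_report=report)


def round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def catalytic_efficiency(k_cat: float, K_M_uM: float,
                         censored: bool = False) -> tuple[float, str]:
    """k_cat/K_M in s⁻¹M⁻¹, rounded to two significant figures.

    Returns ``(value, label)``; a censored K_M (upper bound) makes the
    efficiency a lower bound, labelled with ">".
    """
    if K_M_uM <= 0:
        raise ValueError("K_M must be positive")
    eff = round_sig(k_cat / (K_M_uM * 1e-6), 2)
    label = f">{eff:g}" if censored else f"{eff:g}"
    return eff, label


def fit_exponential(time_s, absorbance, wavelength_nm: int | None = None,
                    ) -> TraceFit:
    """Single-exponential fit A(t) = amplitude·exp(-k_obs·t) + offset.

    Handles both falling (flavin reduction at 448 nm) and rising
    (reoxidation) traces; a flat trace is flagged degenerate.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(absorbance, dtype=float)
    if t.shape != y.shape or t.size < 10:
        raise ValueError("need >= 10 (time, absorbance) points")
    span = float(y.max() - y.min())
    if span < 1e-12 * max(1.0, abs(float(y.mean()))):
        return TraceFit(k_obs=0.0, amplitude=0.0, offset=float(y.mean()),
                        k_obs_se=float("nan"), wavelength_nm=wavelength_nm,
                        degenerate=True)
    amp0 = y[0] - y[-1]
    off0 = y[-1]
    # half-amplitude crossing time gives the initial rate guess
    half = off0 + amp0 / 2.0
    crossing = np.nonzero((y - half) * np.sign(amp0) <= 0)[0]
    t_half = t[crossing[0]] if crossing.size and t[crossing[0]] > 0 else (
        t[-1] / 2.0 or 1.0)
    k0 = math.log(2.0) / t_half

    def model(tt, amp, k, off):
        return amp * np.exp(-k * tt) + off

    popt, pcov = curve_fit(model, t, y, p0=(amp0, k0, off0), maxfev=20000)
    amp, k_obs, off = popt
    if k_obs <= 0:
        raise RuntimeError(f"non-positive fitted k_obs ({k_obs:.4g})")
    dt = float(np.median(np.diff(t)))
    if k_obs > math.pi / dt:
        raise RuntimeError(
            f"fitted k_obs {k_obs:.4g} s^-1 exceeds the sampling limit; "
            "the trace is undersampled")
    k_se = float(np.sqrt(pcov[1, 1]))
    return TraceFit(k_obs=float(k_obs), amplitude=float(amp),
                    offset=float(off), k_obs_se=k_se,
                    wavelength_nm=wavelength_nm)


def fit_saturation(conc_uM, k_obs_per_s) -> SaturationFit:
    """Hyperbolic fit k_obs = k_red·[C]/(K_d + [C]) of stopped-flow rates."""
    conc = np.asarray(conc_uM, dtype=float)
    kobs = np.asarray(k_obs_per_s, dtype=float)
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    (k_red, K_d), (k_red_se, K_d_se) = _fit_hyperbola(conc, kobs)
    if k_red <= 0 or K_d <= 0:
        raise RuntimeError(
            f"non-physical saturation fit: k_red={k_red:.4g}, K_d={K_d:.4g}")
    return SaturationFit(k_red=float(k_red), K_d=float(K_d),
                         k_red_se=float(k_red_se), K_d_se=float(K_d_se))
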