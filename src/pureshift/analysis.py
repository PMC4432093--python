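"""Spectrum quantification and homodecoupling sensitivity theory.

Covers peak picking with parabolic interpolation, signal-to-noise,
decoupling-sideband quantification at multiples of sw_ps, the multiplet
collapse gain, the J*T2 resolvability criterion for the gain from
homodecoupling, the time-shared duty-cycle penalty, and the residual-water
figure of merit for CTP gradient selection.

Sensitivity theory
------------------
Collapsing a fully resolved multiplet of intensities (a_1..a_m) into a
singlet of equal total integral raises the tallest line by
100*(sum a / max a - 1) percent: +100 % for 1:1 doublets and 1:2:1
triplets.  For Lorentzian lines of width 1/(pi T2) the gain for a doublet
with splitting J is (height of the equal-integral singlet)/(maximum of the
doublet) - 1; while the doublet is unresolved (pi J T2 < 1/sqrt(3)) its
maximum sits at the centre and the gain is exactly (pi J T2)^2, which is
~10 % at J*T2 = 0.1 — the regime where homodecoupling stops paying.
Time-shared decoupling that samples a fraction f of each dwell loses
100*(1-sqrt(f)) percent of S/N (6.7 % at f = 0.87).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .processing import Spectrum1D


@dataclass
class PeakReport:
    position_hz: float
    position_ppm: float
    height: float
    fwhm_hz: float | None = None
    integral: float | None = None
    flags: dict = field(default_factory=dict)


def peak_pick(spectrum: Spectrum1D, threshold: float, min_separation_hz: float = 0.0,
              use: str = "real") -> list[PeakReport]:
    """Local maxima above ``threshold`` with 3-point parabolic interpolation.

    Peaks closer than ``min_separation_hz`` to a taller peak are dropped;
    the list is ordered by position.
    """
    y = np.real(spectrum.data) if use == "real" else np.abs(spectrum.data)
    if y.size < 3:
        raise ValueError("spectrum too short to pick")
    hz = spectrum.hz
    cand = []
    for i in range(1, y.size - 1):
        if y[i] >= threshold and y[i] >= y[i - 1] and y[i] > y[i + 1]:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            d = 0.0 if denom == 0 else 0.5 * (y[i - 1] - y[i + 1]) / denom
            pos = hz[i] + d * (hz[1] - hz[0])
            h = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * d
            cand.append((h, pos, i))
    cand.sort(reverse=True)
    kept: list[tuple[float, float, int]] = []
    for h, pos, i in cand:
        if all(abs(pos - p) >= min_separation_hz for _, p, _ in kept):
            kept.append((h, pos, i))
    out = []
    for h, pos, i in sorted(kept, key=lambda t: t[1]):
        out.append(PeakReport(
            position_hz=float(pos),
            position_ppm=float(spectrum.carrier_ppm + pos / spectrum.base_freq),
            height=float(h),
            fwhm_hz=_fwhm_at(y, hz, i),
        ))
    return out


def _fwhm_at(y: np.ndarray, hz: np.ndarray, i: int) -> float | None:
    half = y[i] / 2.0
    lo = i
    while lo > 0 and y[lo] > half:
        lo -= 1
    hi = i
    while hi < y.size - 1 and y[hi] > half:
        hi += 1
    if y[lo] > half or y[hi] > half:
        return None
    f_lo = hz[lo] + (half - y[lo]) / (y[lo + 1] - y[lo] + 1e-300) * (hz[1] - hz[0])
    f_hi = hz[hi - 1] + (y[hi - 1] - half) / (y[hi - 1] - y[hi] + 1e-300) * (hz[1] - hz[0])
    return float(f_hi - f_lo)


def peak_pick_2d(data: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    """Local maxima of a real 2D matrix above threshold: (i1, i2, height)."""
    out = []
    for i in range(1, data.shape[0] - 1):
        for j in range(1, data.shape[1] - 1):
            v = data[i, j]
            if v >= threshold and v >= data[i - 1:i + 2, j - 1:j + 2].max():
                out.append((i, j, float(v)))
    return out


def snr(spectrum: Spectrum1D, peak_region_hz: tuple[float, float],
        noise_region_hz: tuple[float, float], use: str = "real") -> float:
    """Max height in the peak region over the RMS of the noise region."""
    y = np.real(spectrum.data) if use == "real" else np.abs(spectrum.data)
    hz = spectrum.hz
    pk = (hz >= peak_region_hz[0]) & (hz <= peak_region_hz[1])
    nz = (hz >= noise_region_hz[0]) & (hz <= noise_region_hz[1])
    if not pk.any() or not nz.any():
        raise ValueError("empty peak or noise region")
    if (pk & nz).any():
        raise ValueError("peak and noise regions must be disjoint")
    noise = y[nz] - y[nz].mean()
    rms = np.sqrt(np.mean(noise ** 2))
    return float(y[pk].max() / rms)


def sideband_scan(spectrum: Spectrum1D, parent_hz: float, sw_ps: float,
                  k_max: int = 3) -> dict[int, float]:
    """Relative magnitude at parent +/- k*sw_ps, read at the nearest digital
    point and normalised by the parent magnitude (no interpolation)."""
    if sw_ps <= 0:
        raise ValueError("sw_ps must be > 0")
    mag = np.abs(spectrum.data)
    hz = spectrum.hz
    parent = mag[spectrum.index_of_hz(parent_hz)]
    out = {}
    for k in range(1, k_max + 1):
        for sgn in (-1, 1):
            pos = parent_hz + sgn * k * sw_ps
            if pos < hz[0] or pos > hz[-1]:
                raise ValueError(f"sideband position {pos:.1f} Hz outside spectrum")
            out[sgn * k] = float(mag[spectrum.index_of_hz(pos)] / parent)
    return out


# ---------------------------------------------------------------------------
# sensitivity theory


def max_multiplet_gain(pattern) -> float:
    """Zero-linewidth peak-height gain (%) from collapsing a multiplet."""
    a = np.asarray(pattern, dtype=float)
    if a.size == 0 or np.any(a <= 0):
        raise ValueError("pattern must be non-empty positive intensities")
    return float(100.0 * (a.sum() / a.max() - 1.0))


def _lorentzian(nu, T2):
    h = 1.0 / (2 * np.pi * T2)  # HWHM of exp(-t/T2)
    return (1.0 / np.pi) * h / (nu ** 2 + h ** 2)


def decoupling_gain(J: float, T2: float, element_loss_fraction: float = 0.0,
                    method: str = "numeric") -> float:
    """Peak-height gain (%) of a decoupled singlet over the parent doublet.

    Both lines are Lorentzians of width 1/(pi T2); the singlet carries the
    full integral (scaled by 1 - element_loss_fraction), the doublet has
    half-integral components at +/- J/2.  ``closed_form`` is exact while
    the doublet maximum is at its centre (pi J T2 <= 1/sqrt(3)):
    gain = (1-loss)(1 + (pi J T2)^2) - 1.
    """
    if J < 0 or T2 <= 0:
        raise ValueError("need J >= 0 and T2 > 0")
    if J == 0.0:
        return float(100.0 * ((1.0 - element_loss_fraction) - 1.0))
    if method == "closed_form":
        return float(100.0 * ((1.0 - element_loss_fraction) * (1 + (np.pi * J * T2) ** 2) - 1.0))
    singlet = (1.0 - element_loss_fraction) * _lorentzian(0.0, T2)

    def neg_doublet(nu):
        return -0.5 * (_lorentzian(nu - J / 2, T2) + _lorentzian(nu + J / 2, T2))

    res = minimize_scalar(neg_doublet, bounds=(0.0, J), method="bounded",
                          options={"xatol": 1e-12 * max(J, 1.0)})
    doublet_max = -res.fun
    return float(100.0 * (singlet / doublet_max - 1.0))


def duty_cycle_penalty(sampling_fraction: float) -> float:
    """S/N loss (%) when only a fraction of each dwell samples the signal."""
    if not 0.0 < sampling_fraction <= 1.0:
        raise ValueError("sampling_fraction must be in (0, 1]")
    return float(100.0 * (1.0 - np.sqrt(sampling_fraction)))


# ---------------------------------------------------------------------------
# water residual


def water_residual(spectrum: Spectrum1D, water_offset_hz: float,
                   window_hz: float = 50.0) -> float:
    """Integral of |S(nu)| within +/-window of the water offset."""
    hz = spectrum.hz
    sel = (hz >= water_offset_hz - window_hz) & (hz <= water_offset_hz + window_hz)
    return float(np.abs(spectrum.data[sel]).sum() * (hz[1] - hz[0]))


def water_residual_study(scheme: str = "none", n_t1: int = 1,
                         element_kind: str = "bashd", n_chunks: int = 8,
                         total_points: int = 1024, sw: float = 5000.0,
                         water_offset_hz: float = -1775.0,
                         tau_rd: float = 5e-3, M0: float = 100.0,
                         n_slices: int = 257, tip_deg: float = 2.0,
                         zero_fill: int = 16384) -> np.ndarray:
    """Residual water amplitude vs t1 index for a suppression scheme.

    Classical water-only simulation of the real-time pure shift acquisition
    loop at the reference acquisition scale (~200 ms in 8 chunks): the hard
    echo-A 180s invert water at every element, radiation damping (tau_rd)
    regrows coherent transverse water while water is inverted, and —
    depending on ``scheme`` (``none``, ``z``, or ``xy``) — the CTP gradient
    pairs (signs alternating between elements) dephase the uninverted
    water each chunk, preventing the build-up.  ``tip_deg`` is the small
    coherent water tip left over from the preceding HSQC (pulse
    imperfections); it seeds the radiation-damping instability.  Each t1
    increment is prepared identically, so the residual is flat in t1; the
    scheme-on/off ratio is the figure of merit.
    """
    from .elements import AcquisitionPlan, ElementSpec, CtpGradients, realtime_acquisition
    from .engine import WaterModel, water_response
    from .processing import Fid, zero_fill_and_ft

    if scheme not in ("none", "z", "xy"):
        raise ValueError(f"unknown scheme {scheme!r}")
    kind = element_kind if scheme == "none" else "g" + element_kind
    axis = "z" if scheme != "xy" else "x"
    spec = ElementSpec(kind=kind, ctp=CtpGradients(axis=axis))
    if "bashd" in kind:
        spec.shape_duration = 2.44e-3
        spec.resolved_shape()
    plan = AcquisitionPlan(sw=sw, total_points=total_points, n_chunks=n_chunks,
                           element=spec)
    events = realtime_acquisition(plan)
    water = WaterModel(offset_hz=water_offset_hz, M0=M0, tau_rd=tau_rd,
                       n_slices=n_slices, max_step=5e-6)
    out = np.empty(n_t1)
    for k in range(n_t1):
        sig = water_response(water, events, tip_deg=tip_deg)
        fid = Fid(sig, dwell=1.0 / sw)
        spec1 = zero_fill_and_ft(fid, zero_fill)
        out[k] = water_residual(spec1, water_offset_hz)
    return out
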