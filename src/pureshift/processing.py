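"""Chunk assembly, apodization, Fourier transformation and referencing.

Conventions (fixed, documented):

* a signal exp(+i 2 pi nu t) appears at +nu on the Hz axis (axis stored
  ascending; ppm presentation runs high-to-low as usual);
* the first point of each FID is scaled by 0.5 before FT so that baselines
  of truncated Lorentzians stay flat (standard practice; disable with
  ``first_point_scale=1.0``);
* 2D quadrature: States hypercomplex from cos/sin records, or Rance-Kay
  sum/difference combination of echo/antiecho records into the same form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .engine import ChunkedFID


@dataclass
class Fid:
    """A 1D complex free-induction decay with axis calibration."""

    samples: np.ndarray
    dwell: float
    carrier_ppm: float = 8.25
    base_freq: float = 500.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.size == 0:
            raise ValueError("empty FID")

    @property
    def sw(self) -> float:
        return 1.0 / self.dwell

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dwell


@dataclass
class Spectrum1D:
    data: np.ndarray
    axis_hz: np.ndarray            # ascending offsets from the carrier
    carrier_ppm: float
    base_freq: float
    ref_offset_hz: float = 0.0     # internal-referencing correction

    @property
    def hz(self) -> np.ndarray:
        return self.axis_hz + self.ref_offset_hz

    @property
    def ppm(self) -> np.ndarray:
        return self.carrier_ppm + self.hz / self.base_freq

    def index_of_hz(self, hz: float) -> int:
        return int(np.argmin(np.abs(self.hz - hz)))

    @property
    def digital_resolution(self) -> float:
        return float(self.axis_hz[1] - self.axis_hz[0])


@dataclass
class Spectrum2D:
    data: np.ndarray                     # (n1, n2) real 2D spectrum
    axis1_hz: np.ndarray                 # indirect (15N)
    axis2_hz: np.ndarray                 # direct (1H)
    carrier_ppm: dict = field(default_factory=dict)
    base_freq: dict = field(default_factory=dict)
    history: list = field(default_factory=list)

    def index_of(self, hz1: float, hz2: float) -> tuple[int, int]:
        return (int(np.argmin(np.abs(self.axis1_hz - hz1))),
                int(np.argmin(np.abs(self.axis2_hz - hz2))))


# ---------------------------------------------------------------------------
# chunk assembly


def concatenate_chunks(cfid: ChunkedFID, droppoints: int = 0,
                       carrier_ppm: float | None = None,
                       base_freq: float | None = None) -> Fid:
    """Join chunks in order, dropping ``droppoints`` leading samples each."""
    if droppoints >= cfid.chunk_points:
        raise ValueError("droppoints must be smaller than chunk_points")
    parts = [np.asarray(c)[droppoints:] for c in cfid.chunks]
    meta = cfid.meta or {}
    return Fid(np.concatenate(parts), cfid.dwell,
               carrier_ppm=carrier_ppm if carrier_ppm is not None else meta.get("carrier_ppm", 8.25),
               base_freq=base_freq if base_freq is not None else meta.get("base_freq", 500.0))


def split_fid(fid: Fid, n_chunks: int) -> ChunkedFID:
    """Inverse of concatenate_chunks (droppoints=0) for any divisor chunking."""
    if fid.samples.size % n_chunks:
        raise ValueError("FID length not divisible by n_chunks")
    cp = fid.samples.size // n_chunks
    chunks = [fid.samples[i * cp:(i + 1) * cp] for i in range(n_chunks)]
    return ChunkedFID(chunks=chunks, dwell=fid.dwell, chunk_points=cp,
                      meta={"carrier_ppm": fid.carrier_ppm, "base_freq": fid.base_freq})


def assemble_interferogram(records: list[ChunkedFID], droppoints: int = 0) -> Fid:
    """Build the composite FID from interferogram records.

    Record k (acquired after k pure shift evolution periods of 1/sw_ps)
    contributes its k-th chunk; identical to real-time concatenation for an
    ideal element without relaxation.
    """
    if not records:
        raise ValueError("no records")
    cp, dw = records[0].chunk_points, records[0].dwell
    parts = []
    for k, rec in enumerate(records):
        if rec is None:
            raise ValueError(f"missing interferogram record {k}")
        if rec.chunk_points != cp or rec.dwell != dw:
            raise ValueError("inconsistent interferogram increments")
        if k >= rec.n_chunks:
            raise ValueError(f"record {k} has no chunk {k}")
        parts.append(np.asarray(rec.chunks[k])[droppoints:])
    meta = records[0].meta or {}
    return Fid(np.concatenate(parts), dw,
               carrier_ppm=meta.get("carrier_ppm", 8.25),
               base_freq=meta.get("base_freq", 500.0))


# ---------------------------------------------------------------------------
# apodization


def gaussian_window(t: np.ndarray, gf1: float) -> np.ndarray:
    """exp(-t^2/gf1^2): unity at t=0, e^-1 at t=gf1."""
    if gf1 <= 0:
        raise ValueError("gf1 must be > 0")
    return np.exp(-(t / gf1) ** 2)


def sine_squared_window(n: int, shift_deg: float = 90.0) -> np.ndarray:
    """sin^2 window; 90 degree shift gives the cosine-squared half-bell."""
    phi = np.deg2rad(shift_deg)
    x = np.arange(n) / max(n - 1, 1)
    return np.sin(phi + (np.pi - phi) * x) ** 2


def apodize(fid: Fid, window: str = "none", gf1: float = 0.085,
            shift_deg: float = 90.0) -> Fid:
    if window == "none":
        return replace(fid, samples=fid.samples.copy())
    if window == "gaussian":
        w = gaussian_window(fid.times(), gf1)
    elif window == "sine_squared":
        w = sine_squared_window(fid.samples.size, shift_deg)
    else:
        raise ValueError(f"unknown window {window!r}")
    return replace(fid, samples=fid.samples * w)


# ---------------------------------------------------------------------------
# Fourier transformation


def zero_fill_and_ft(fid: Fid, target_points: int | None = None,
                     first_point_scale: float = 0.5) -> Spectrum1D:
    """Zero-fill to ``target_points`` (>= length) and FFT.

    Parseval (sum |fid|^2 = mean |spec|^2) holds exactly when
    ``first_point_scale`` is 1 and no zero-filling is applied.
    """
    x = fid.samples.copy()
    if target_points is None:
        target_points = x.size
    if target_points < x.size:
        raise ValueError("target_points must be >= FID length")
    x[0] = x[0] * first_point_scale
    spec = np.fft.fftshift(np.fft.fft(x, n=target_points))
    axis = np.fft.fftshift(np.fft.fftfreq(target_points, d=fid.dwell))
    return Spectrum1D(spec, axis, fid.carrier_ppm, fid.base_freq)


def reference_shift(spectrum, delta_hz: float):
    """Internal referencing: shift the axis calibration, data untouched."""
    out = replace(spectrum, data=spectrum.data)
    out.ref_offset_hz = spectrum.ref_offset_hz + delta_hz
    return out


def ft_2d(hsqc_result: dict, zf2: int = 4096, zf1: int = 256,
          window2: str = "none", window1: str = "gaussian", gf1: float = 0.085,
          first_point_scale: float = 0.5, droppoints: int = 0) -> Spectrum2D:
    """Transform an hsqc_sequence result into a pure-phase 2D spectrum.

    cos/sin records are combined States-Haberkorn style; echo/antiecho
    records are first converted by the Rance-Kay sum/difference
    (cos = (E+A)/2, sin = (E-A)/2i), yielding absorption peaks at
    (+nu_N, +nu_H) without quadrature images.
    """
    recs = hsqc_result["records"]
    if hsqc_result.get("echo_antiecho"):
        if "echo" not in recs or "anti" not in recs:
            raise ValueError("echo/antiecho processing needs both records")
        pairs = [("echo", "anti")]
        conv = True
    else:
        pairs = [("cos", "sin")]
        conv = False
    cos_name, sin_name = pairs[0]
    n1 = len(recs[cos_name])
    carrier = hsqc_result["carrier_ppm"]
    base = hsqc_result["base_freq"]
    rows_cos, rows_sin = [], []
    ax2 = None
    for k in range(n1):
        fc = concatenate_chunks(recs[cos_name][k], droppoints,
                                carrier_ppm=carrier["H1"], base_freq=base["H1"])
        fs = concatenate_chunks(recs[sin_name][k], droppoints,
                                carrier_ppm=carrier["H1"], base_freq=base["H1"])
        c, s = fc.samples, fs.samples
        if conv:
            c, s = (c + s) / 2.0, (c - s) / 2.0j
        fc = replace(fc, samples=c)
        fs = replace(fs, samples=s)
        fc = apodize(fc, window2, gf1=gf1)
        fs = apodize(fs, window2, gf1=gf1)
        sc = zero_fill_and_ft(fc, zf2, first_point_scale)
        ss = zero_fill_and_ft(fs, zf2, first_point_scale)
        ax2 = sc.axis_hz
        rows_cos.append(np.real(sc.data))
        rows_sin.append(np.real(ss.data))
    inter = np.asarray(rows_cos) + 1j * np.asarray(rows_sin)   # (n1, zf2)
    dw1 = 1.0 / hsqc_result["sw1"]
    t1 = np.arange(n1) * dw1
    if window1 == "gaussian":
        inter = inter * gaussian_window(t1, gf1)[:, None]
    elif window1 == "sine_squared":
        inter = inter * sine_squared_window(n1)[:, None]
    inter[0] *= first_point_scale
    spec2 = np.fft.fftshift(np.fft.fft(inter, n=zf1, axis=0), axes=0)
    ax1 = np.fft.fftshift(np.fft.fftfreq(zf1, d=dw1))
    return Spectrum2D(np.real(spec2), ax1, ax2, carrier_ppm=carrier, base_freq=base,
                      history=[f"zf {zf1}x{zf2}", f"win1 {window1}", f"win2 {window2}"])
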