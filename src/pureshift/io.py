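"""File formats: JCAMP-DX 1D FIDs, 2D spectra (.npy + JSON sidecar),
two-column shape files, run configs and provenance records.

The JCAMP-DX writer emits an NTUPLES "NMR FID" block with two AFFN data
pages (real, imaginary) at full float64 precision, which the bundled
reader round-trips losslessly; parse errors report the offending line.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import yaml

from .processing import Fid, Spectrum2D
from .shapes import PulseShape

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# JCAMP-DX (1D complex FID)


def write_jcamp(fid: Fid, path, title: str = "pureshift FID") -> None:
    lines = [
        "##TITLE= " + title,
        "##JCAMP-DX= 5.00",
        "##DATA TYPE= NMR FID",
        "##DATA CLASS= NTUPLES",
        "##ORIGIN= pureshift",
        "##OWNER= ",
        f"##.DWELL TIME= {float(fid.dwell)!r}",
        f"##.CARRIER PPM= {float(fid.carrier_ppm)!r}",
        f"##.BASE FREQ MHZ= {float(fid.base_freq)!r}",
        "##NTUPLES= NMR FID",
        f"##VAR_DIM= {fid.samples.size}, {fid.samples.size}",
    ]
    for page, comp in (("R", np.real(fid.samples)), ("I", np.imag(fid.samples))):
        lines.append(f"##PAGE= N={page}")
        lines.append("##DATA TABLE= (X++(Y..Y)), XYDATA")
        for k, v in enumerate(comp):
            lines.append(f"{k} {float(v)!r}")
    lines.append("##END NTUPLES= NMR FID")
    lines.append("##END=")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


class JcampParseError(ValueError):
    def __init__(self, msg, lineno):
        super().__init__(f"line {lineno}: {msg}")
        self.lineno = lineno


def read_jcamp(path) -> Fid:
    dwell = carrier = base = None
    n_expected = None
    pages: dict[str, list[float]] = {}
    current: list[float] | None = None
    ended = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key, val = key.strip(), val.strip()
                if key == ".DWELL TIME":
                    dwell = float(val)
                elif key == ".CARRIER PPM":
                    carrier = float(val)
                elif key == ".BASE FREQ MHZ":
                    base = float(val)
                elif key == "VAR_DIM":
                    n_expected = int(val.split(",")[0])
                elif key == "PAGE":
                    name = val.split("=")[-1].strip()
                    current = pages.setdefault(name, [])
                elif key == "END":
                    ended = True
                continue
            if current is None:
                raise JcampParseError("data before any ##PAGE", lineno)
            parts = line.split()
            if len(parts) != 2:
                raise JcampParseError(f"expected 'index value', got {line!r}", lineno)
            try:
                current.append(float(parts[1]))
            except ValueError:
                raise JcampParseError(f"bad number {parts[1]!r}", lineno) from None
    if not ended:
        raise JcampParseError("missing ##END= (truncated file)", lineno)
    if dwell is None or "R" not in pages or "I" not in pages:
        raise JcampParseError("incomplete JCAMP-DX FID", lineno)
    re_, im_ = np.asarray(pages["R"]), np.asarray(pages["I"])
    if n_expected is not None and (re_.size != n_expected or im_.size != n_expected):
        raise JcampParseError("data table length does not match VAR_DIM", lineno)
    return Fid(re_ + 1j * im_, dwell, carrier_ppm=carrier if carrier is not None else 8.25,
               base_freq=base if base is not None else 500.0)


# ---------------------------------------------------------------------------
# 2D spectrum: binary matrix + JSON metadata sidecar


def write_spectrum2d(spec: Spectrum2D, path_base: str) -> None:
    np.save(path_base + ".npy", spec.data)
    meta = {
        "axis1_hz": [float(spec.axis1_hz[0]), float(spec.axis1_hz[-1]), int(spec.axis1_hz.size)],
        "axis2_hz": [float(spec.axis2_hz[0]), float(spec.axis2_hz[-1]), int(spec.axis2_hz.size)],
        "carrier_ppm": spec.carrier_ppm,
        "base_freq": spec.base_freq,
        "history": spec.history,
    }
    with open(path_base + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_spectrum2d(path_base: str) -> Spectrum2D:
    data = np.load(path_base + ".npy")
    with open(path_base + ".json") as fh:
        meta = json.load(fh)
    a1 = np.linspace(*meta["axis1_hz"][:2], meta["axis1_hz"][2])
    a2 = np.linspace(*meta["axis2_hz"][:2], meta["axis2_hz"][2])
    return Spectrum2D(data, a1, a2, carrier_ppm=meta["carrier_ppm"],
                      base_freq=meta["base_freq"], history=meta["history"])


# ---------------------------------------------------------------------------
# shapes: two-column text


def write_shape(shape: PulseShape, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pureshift shape: {shape.name}\n# amplitude phase_deg\n")
        for a, p in zip(shape.amplitude, shape.phase_deg):
            fh.write(f"{float(a)!r} {float(p)!r}\n")


def read_shape(path, name: str | None = None) -> PulseShape:
    amps, phases = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'amplitude phase'")
            amps.append(float(parts[0]))
            phases.append(float(parts[1]))
    return PulseShape(np.asarray(amps), np.asarray(phases), name=name or "imported")


# ---------------------------------------------------------------------------
# run configuration + provenance


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance(cfg: dict, seed: int | None) -> dict:
    return {"config_hash": config_hash(cfg), "seed": seed, "version": __version__}


def write_report(rows: list[dict], path, sep: str = "\t") -> None:
    """Delimited-text report table."""
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
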