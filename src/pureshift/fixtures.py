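"""Synthetic amide spin systems emulating representative protein samples.

Each residue is a three-spin fragment: the observed amide proton H_N
(active), its one-bond 15N partner, and one passive Halpha coupled to H_N
by a vicinal 3J_HH.  Styles set the proton T2 the samples showed
(denatured N-PGK ~60 ms with narrow amide dispersion, folded ubiquitin
~35 ms, PAF ~55 ms).  Generation is fully deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spin_core import Spin, SpinSystem

STYLES = {
    "denatured_npgk": {"T2": 0.060, "h_range": (7.8, 8.7)},
    "ubiquitin_like": {"T2": 0.035, "h_range": (6.8, 9.6)},
    "paf_like": {"T2": 0.055, "h_range": (6.9, 9.4)},
    "minimal_pair": {"T2": 0.060, "h_range": (8.24, 8.24)},
}

DEFAULT_BASE_FREQ = {"H1": 500.0, "N15": 50.68}
DEFAULT_CARRIER = {"H1": 8.25, "N15": 117.0}


@dataclass
class FixtureSpec:
    style: str = "denatured_npgk"
    n_residues: int = 1
    h_range: tuple | None = None          # amide 1H ppm range
    n_range: tuple = (105.0, 125.0)       # 15N ppm range
    ha_range: tuple = (3.9, 4.7)          # Halpha ppm range
    jhh_range: tuple = (4.0, 9.0)         # 3J(HN-Halpha), Hz
    jnh_range: tuple = (89.0, 95.0)       # |1J_NH|, Hz
    T2: float | None = None               # proton T2 override, s
    T2_n: float = 0.15                    # 15N T2, s
    seed: int = 0
    base_freq: dict = field(default_factory=lambda: dict(DEFAULT_BASE_FREQ))
    carrier_ppm: dict = field(default_factory=lambda: dict(DEFAULT_CARRIER))

    def __post_init__(self):
        if self.style not in STYLES:
            raise ValueError(f"unknown fixture style {self.style!r}")


def minimal_pair(J_nh: float = 90.0, J_hh: float = 8.0, T2: float = 0.060,
                 h_ppm: float = 8.24, n_ppm: float = 117.0, ha_ppm: float = 4.3,
                 base_freq: dict | None = None,
                 carrier_ppm: dict | None = None) -> SpinSystem:
    """One HN-N-Halpha fragment with J_NH = 90 Hz by default."""
    spins = [
        Spin("HN", "H1", h_ppm, T2=T2, role="active"),
        Spin("N", "N15", n_ppm, T2=0.15),
        Spin("HA", "H1", ha_ppm, T2=T2, role="passive"),
    ]
    J = np.zeros((3, 3))
    J[0, 1] = J[1, 0] = J_nh
    J[0, 2] = J[2, 0] = J_hh
    return SpinSystem(spins, J,
                      base_freq=dict(base_freq or DEFAULT_BASE_FREQ),
                      carrier_ppm=dict(carrier_ppm or DEFAULT_CARRIER))


def generate_fixture(spec: FixtureSpec) -> list[SpinSystem]:
    """Deterministic residue list (same seed -> identical systems)."""
    style = STYLES[spec.style]
    if spec.style == "minimal_pair":
        return [minimal_pair(T2=spec.T2 or style["T2"],
                             base_freq=spec.base_freq, carrier_ppm=spec.carrier_ppm)]
    rng = np.random.default_rng(spec.seed)
    t2 = spec.T2 if spec.T2 is not None else style["T2"]
    h_lo, h_hi = spec.h_range or style["h_range"]
    systems = []
    for r in range(spec.n_residues):
        h = rng.uniform(h_lo, h_hi)
        n = rng.uniform(*spec.n_range)
        ha = rng.uniform(*spec.ha_range)
        jhh = rng.uniform(*spec.jhh_range)
        jnh = rng.uniform(*spec.jnh_range)
        spins = [
            Spin(f"HN{r}", "H1", float(h), T2=t2, role="active"),
            Spin(f"N{r}", "N15", float(n), T2=spec.T2_n),
            Spin(f"HA{r}", "H1", float(ha), T2=t2, role="passive"),
        ]
        J = np.zeros((3, 3))
        J[0, 1] = J[1, 0] = float(jnh)
        J[0, 2] = J[2, 0] = float(jhh)
        systems.append(SpinSystem(spins, J, base_freq=dict(spec.base_freq),
                                  carrier_ppm=dict(spec.carrier_ppm)))
    return systems
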