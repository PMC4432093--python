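"""Spin systems, product-operator algebra and free-evolution Hamiltonians.

The simulator works in the Zeeman product basis of up to six spins-1/2
(matrix dimension <= 64), in a doubly rotating frame: each isotope has its
own transmitter (carrier) and offsets are measured from it.  Sign
convention: a spin at *higher* ppm than the carrier has a *positive*
offset in Hz and its transverse magnetisation precesses as exp(+i 2 pi nu t)
in the detected signal.

A 90x pulse rotates z-magnetisation onto -y (right-handed rotation about x
generated by exp(-i theta Ix)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import yaml

MAX_SPINS = 6

#: gyromagnetic ratios, rad s^-1 G^-1 (1H CODATA; 15N scaled by -0.10137)
GAMMA = {"H1": 26752.218744, "N15": 26752.218744 * -0.10137}

#: relative equilibrium polarisation (gamma ratio to 1H)
POLARIZATION = {"H1": 1.0, "N15": -0.10137}

_SIGMA = {
    "x": np.array([[0.0, 0.5], [0.5, 0.0]], dtype=complex),
    "y": np.array([[0.0, -0.5j], [0.5j, 0.0]], dtype=complex),
    "z": np.array([[0.5, 0.0], [0.0, -0.5]], dtype=complex),
    "+": np.array([[0.0, 1.0], [0.0, 0.0]], dtype=complex),
    "-": np.array([[0.0, 0.0], [1.0, 0.0]], dtype=complex),
}


@dataclass(frozen=True)
class Spin:
    """A single spin-1/2.

    Parameters
    ----------
    label : str
        Unique identifier within the system (e.g. ``"HN"``).
    isotope : {"H1", "N15"}
    shift_ppm : float
        Chemical shift in ppm.
    T2 : float
        Transverse relaxation time in seconds (> 0).
    T1 : float, optional
        Longitudinal relaxation time in seconds; if omitted the populations
        of this spin are frozen (phenomenological model).
    role : {"active", "passive", "water"}
        ``active`` marks an observed, 15N-bound amide proton; ``passive``
        spins are those whose couplings to active spins are suppressed by
        the pure shift element; ``water`` is only meaningful on 1H.
    """

    label: str
    isotope: str
    shift_ppm: float
    T2: float
    T1: float | None = None
    role: str = "passive"

    def __post_init__(self):
        if self.isotope not in GAMMA:
            raise ValueError(f"unknown isotope {self.isotope!r}")
        if self.T2 <= 0:
            raise ValueError("T2 must be > 0")
        if self.T1 is not None and self.T1 <= 0:
            raise ValueError("T1 must be > 0 when given")
        if self.role not in ("active", "passive", "water"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "water" and self.isotope != "H1":
            raise ValueError("role='water' is only permitted on 1H spins")


def ppm_to_offset_hz(shift_ppm: float, carrier_ppm: float, base_freq_MHz: float) -> float:
    """Rotating-frame offset in Hz: (shift - carrier) * base frequency.

    Higher ppm than the carrier gives a positive offset.
    """
    if base_freq_MHz <= 0:
        raise ValueError("base_freq_MHz must be > 0")
    return (shift_ppm - carrier_ppm) * base_freq_MHz


@dataclass
class SpinSystem:
    """A molecule-level spin model: spins, scalar couplings and frame.

    ``J`` is a symmetric (n, n) matrix of scalar couplings in Hz with zero
    diagonal.  ``base_freq`` maps isotope -> Larmor frequency in MHz and
    ``carrier_ppm`` maps isotope -> transmitter offset in ppm.
    """

    spins: list[Spin]
    J: np.ndarray
    base_freq: dict[str, float] = field(default_factory=lambda: {"H1": 500.0, "N15": 50.68})
    carrier_ppm: dict[str, float] = field(default_factory=lambda: {"H1": 8.25, "N15": 117.0})
    allow_weak_nh: bool = False  # permit active H without a one-bond N partner

    def __post_init__(self):
        self.J = np.asarray(self.J, dtype=float)
        n = len(self.spins)
        if n == 0 or n > MAX_SPINS:
            raise ValueError(f"spin count must be 1..{MAX_SPINS}, got {n}")
        if self.J.shape != (n, n):
            raise ValueError("J matrix shape must match spin count")
        if not np.allclose(self.J, self.J.T, atol=1e-12):
            raise ValueError("J must be symmetric")
        if np.any(np.abs(np.diag(self.J)) > 1e-12):
            raise ValueError("J diagonal must be zero")
        labels = [s.label for s in self.spins]
        if len(set(labels)) != n:
            raise ValueError("spin labels must be unique")
        if not self.allow_weak_nh:
            for i, s in enumerate(self.spins):
                if s.role != "active":
                    continue
                partners = [
                    j for j, t in enumerate(self.spins)
                    if t.isotope == "N15" and 80.0 <= abs(self.J[i, j]) <= 105.0
                ]
                if len(partners) != 1:
                    raise ValueError(
                        f"active spin {s.label!r} needs exactly one 15N partner "
                        "with |J| in [80, 105] Hz (set allow_weak_nh to override)"
                    )

    # -- bookkeeping ---------------------------------------------------
    @property
    def n_spins(self) -> int:
        return len(self.spins)

    @property
    def dim(self) -> int:
        return 2 ** self.n_spins

    def index(self, label: str) -> int:
        for i, s in enumerate(self.spins):
            if s.label == label:
                return i
        raise KeyError(f"no spin labelled {label!r}")

    def offsets_hz(self) -> np.ndarray:
        """Rotating-frame offset of every spin (Hz), in spin order."""
        return np.array(
            [
                ppm_to_offset_hz(s.shift_ppm, self.carrier_ppm[s.isotope], self.base_freq[s.isotope])
                for s in self.spins
            ]
        )

    def isotope_indices(self, isotope: str) -> list[int]:
        return [i for i, s in enumerate(self.spins) if s.isotope == isotope]

    def active_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.spins) if s.role == "active"]

    def passive_proton_indices(self) -> list[int]:
        return [
            i for i, s in enumerate(self.spins)
            if s.isotope == "H1" and s.role in ("passive", "water")
        ]

    # -- operators -----------------------------------------------------
    def operator(self, label: str, axis: str) -> np.ndarray:
        """Single-spin operator I_axis embedded in the full product space."""
        return single_spin_operator(self, label, axis)

    def total_operator(self, axis: str, indices: Iterable[int]) -> np.ndarray:
        out = np.zeros((self.dim, self.dim), dtype=complex)
        for i in indices:
            out += _embed(_SIGMA[axis], i, self.n_spins)
        return out

    def set_heteronuclear_decoupling(self, on: bool = True) -> "SpinSystem":
        """Return a view with all 1H-15N couplings zeroed (ideal decoupling).

        Intended for acquisition windows; homonuclear couplings untouched.
        """
        if not on:
            return self
        J = self.J.copy()
        for i, si in enumerate(self.spins):
            for j, sj in enumerate(self.spins):
                if {si.isotope, sj.isotope} == {"H1", "N15"}:
                    J[i, j] = 0.0
        return replace(self, J=J, allow_weak_nh=True)

    def zero_homonuclear_j(self) -> "SpinSystem":
        """Oracle view with every active-passive 1H-1H coupling removed."""
        J = self.J.copy()
        act = set(self.active_indices())
        for i, si in enumerate(self.spins):
            for j, sj in enumerate(self.spins):
                if si.isotope == "H1" and sj.isotope == "H1" and (i in act) != (j in act):
                    J[i, j] = 0.0
        return replace(self, J=J, allow_weak_nh=True)


def _embed(op2: np.ndarray, pos: int, n: int) -> np.ndarray:
    mat = np.array([[1.0]], dtype=complex)
    for k in range(n):
        mat = np.kron(mat, op2 if k == pos else np.eye(2, dtype=complex))
    return mat


def single_spin_operator(system: SpinSystem, label: str, axis: str) -> np.ndarray:
    if axis not in _SIGMA:
        raise ValueError(f"unknown axis {axis!r}")
    return _embed(_SIGMA[axis], system.index(label), system.n_spins)


def free_hamiltonian(system: SpinSystem, coupling_mode: str = "heteronuclear_secular") -> np.ndarray:
    """Free-evolution Hamiltonian (rad/s) in the rotating frame.

    coupling_mode:
      * ``"full"``  - isotropic 2 pi J I_i.I_j for every coupled pair;
      * ``"weak"``  - secular 2 pi J I_iz I_jz for every pair;
      * ``"heteronuclear_secular"`` (default) - isotropic for same-isotope
        pairs, secular for heteronuclear pairs (exact in the doubly
        rotating frame).
    """
    if coupling_mode not in ("full", "weak", "heteronuclear_secular"):
        raise ValueError(f"unknown coupling_mode {coupling_mode!r}")
    n, d = system.n_spins, system.dim
    H = np.zeros((d, d), dtype=complex)
    offs = system.offsets_hz()
    for i in range(n):
        H += 2 * np.pi * offs[i] * _embed(_SIGMA["z"], i, n)
    for i in range(n):
        for j in range(i + 1, n):
            Jij = system.J[i, j]
            if Jij == 0.0:
                continue
            same = system.spins[i].isotope == system.spins[j].isotope
            weak = coupling_mode == "weak" or (coupling_mode == "heteronuclear_secular" and not same)
            zz = _embed(_SIGMA["z"], i, n) @ _embed(_SIGMA["z"], j, n)
            if weak:
                C = zz
            else:
                C = zz.copy()
                for ax in ("x", "y"):
                    C += _embed(_SIGMA[ax], i, n) @ _embed(_SIGMA[ax], j, n)
            H += 2 * np.pi * Jij * C
    return H


def equilibrium_state(system: SpinSystem) -> np.ndarray:
    """Thermal state Id/d + sum_i p_i I_iz (deviation scaled to unit 1H)."""
    d = system.dim
    rho = np.eye(d, dtype=complex) / d
    for i, s in enumerate(system.spins):
        rho += POLARIZATION[s.isotope] * _embed(_SIGMA["z"], i, system.n_spins)
    return rho


# -- config round-trip -------------------------------------------------

def system_to_dict(system: SpinSystem) -> dict:
    spins = []
    for s in system.spins:
        rec = {"label": s.label, "isotope": s.isotope, "shift_ppm": float(s.shift_ppm),
               "T2": float(s.T2), "role": s.role}
        if s.T1 is not None:
            rec["T1"] = float(s.T1)
        spins.append(rec)
    couplings = []
    for i in range(system.n_spins):
        for j in range(i + 1, system.n_spins):
            if system.J[i, j] != 0.0:
                couplings.append([system.spins[i].label, system.spins[j].label,
                                  float(system.J[i, j])])
    return {
        "spins": spins,
        "couplings": couplings,
        "base_freq": {k: float(v) for k, v in system.base_freq.items()},
        "carrier_ppm": {k: float(v) for k, v in system.carrier_ppm.items()},
    }


def system_from_dict(data: dict) -> SpinSystem:
    spins = [Spin(**rec) for rec in data["spins"]]
    n = len(spins)
    J = np.zeros((n, n))
    labels = {s.label: i for i, s in enumerate(spins)}
    for a, b, j in data.get("couplings", []):
        J[labels[a], labels[b]] = J[labels[b], labels[a]] = float(j)
    return SpinSystem(spins=spins, J=J,
                      base_freq=dict(data["base_freq"]),
                      carrier_ppm=dict(data["carrier_ppm"]))


def save_system(system: SpinSystem, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(system_to_dict(system), fh, sort_keys=False)


def load_system(path) -> SpinSystem:
    with open(path) as fh:
        return system_from_dict(yaml.safe_load(fh))
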