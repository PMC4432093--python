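"""Density-matrix propagation through event sequences.

The engine executes flat lists of :class:`Event` objects (delays, hard and
shaped pulses, gradients, purges, windowed acquisition) on an ensemble of
spatial slices, with phenomenological relaxation, phase cycling and an
optional classical water magnetisation with radiation damping.

Relaxation model
----------------
Every off-diagonal element rho_ab decays at rate sum over spins whose
Zeeman state differs between a and b of 1/T2_i (so a single-quantum
coherence of spin i decays at 1/T2_i and a double-quantum coherence at the
sum of both rates).  Populations relax toward thermal equilibrium at 1/T1_i
when T1 is given, via the Walsh (product-of-2Iz) decomposition of the
diagonal; spins without T1 have frozen longitudinal order.

Gradients
---------
A gradient of amplitude g (G/cm) for tau seconds gives slice k the phase
gamma_i * g * z_k * tau on each spin-i coherence (applied as a diagonal
conjugation, so z-magnetisation is untouched); free evolution and
relaxation run concurrently.  Slice positions are midpoints of n equal
segments spanning the sample length, symmetric about the coil centre, and
the detected signal is the unweighted slice average.

Receiver
--------
The detected signal is the slice-averaged <I+> of the observed channel,
normalised so one fully polarised spin gives unit amplitude; water adds
its slice-averaged transverse magnetisation times ``water.scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .shapes import PulseShape
from .spin_core import (
    GAMMA,
    SpinSystem,
    equilibrium_state,
    free_hamiltonian,
)

# ---------------------------------------------------------------------------
# events


@dataclass
class Event:
    """One step of a pulse sequence.

    kind: delay | hard_pulse | shaped_pulse | gradient | acquire | purge |
    ideal_flip (instantaneous perfect inversion of passive protons).
    """

    kind: str
    duration: float = 0.0
    channel: str = "H1"
    flip_deg: float = 0.0
    phase_deg: float = 0.0
    phase_table: str | None = None       # name of a phase table to add per step
    receiver_table: str | None = None    # only meaningful on acquire events
    shape: PulseShape | None = None
    peak_b1_hz: float = 0.0
    offset_hz: float = 0.0
    amplitude: float = 0.0               # gradient, G/cm
    axis: str = "z"
    n_points: int = 0
    dwell: float = 0.0
    decouple: bool = True                # heteronuclear decoupling during acquire
    j_free: bool = False                 # oracle: suppress active-passive J_HH
    tags: tuple = ()

    def __post_init__(self):
        if self.duration < 0:
            raise ValueError("durations must be >= 0")
        if self.kind == "acquire" and self.n_points >= 1 and self.dwell <= 0:
            raise ValueError("acquire dwell must be > 0")


def delay(duration: float, **kw) -> Event:
    return Event("delay", duration=duration, **kw)


def hard_pulse(channel: str, flip_deg: float, phase_deg: float = 0.0, **kw) -> Event:
    return Event("hard_pulse", channel=channel, flip_deg=flip_deg, phase_deg=phase_deg, **kw)


def shaped_pulse(channel: str, shape: PulseShape, duration: float, peak_b1_hz: float,
                 offset_hz: float = 0.0, phase_deg: float = 0.0, **kw) -> Event:
    if shape.n_samples < 32:
        raise ValueError("shape needs >= 32 samples")
    if duration <= 0:
        raise ValueError("shaped pulse needs a positive duration")
    return Event("shaped_pulse", channel=channel, shape=shape, duration=duration,
                 peak_b1_hz=peak_b1_hz, offset_hz=offset_hz, phase_deg=phase_deg, **kw)


def gradient(amplitude: float, duration: float, axis: str = "z", **kw) -> Event:
    return Event("gradient", amplitude=amplitude, duration=duration, axis=axis, **kw)


def acquire(n_points: int, dwell: float, channel: str = "H1", **kw) -> Event:
    if n_points < 1:
        raise ValueError("acquire needs n_points >= 1")
    return Event("acquire", n_points=n_points, dwell=dwell, channel=channel, **kw)


# Element phase cycle (phase added to the tagged refocusing pulses).  A
# phase-inversion cycle {0, 180} leaves the ideal p -> -p pathway invariant
# for *any* number of element firings per transient (a 90-degree step would
# multiply the active coherence by -1 per element, which cannot be undone
# by a per-transient receiver sign in real-time acquisition), while
# non-inverted pathways from pulse imperfections change sign and cancel.
# The 4-step version inverts the echo-A and discriminating 180s independently.
EXORCYCLE_PHASES = {1: [0.0], 2: [0.0, 180.0], 4: [0.0, 180.0, 0.0, 180.0]}
EXORCYCLE_PHASES_B = {1: [0.0], 2: [0.0, 0.0], 4: [0.0, 0.0, 180.0, 180.0]}
EXORCYCLE_RECEIVER = {1: [1.0], 2: [1.0, 1.0], 4: [1.0, 1.0, 1.0, 1.0]}


# ---------------------------------------------------------------------------
# spatial ensemble / water


@dataclass
class EnsembleConfig:
    """Spatial grid for gradient simulation (slices symmetric about z=0)."""

    n_slices: int = 64
    length_cm: float = 1.6
    axes: tuple = ("x", "y", "z")
    stabilization_delay: float = 200e-6

    def __post_init__(self):
        if self.n_slices < 1:
            raise ValueError("n_slices >= 1")

    def positions(self) -> np.ndarray:
        n, L = self.n_slices, self.length_cm
        return (np.arange(n) + 0.5) / n * L - L / 2.0


class WaterModel:
    """Classical water magnetisation on its own (fine) slice grid.

    One-way coupled: water contributes to the receiver but never enters the
    quantum solute state.  Radiation damping rotates each slice's vector
    about the *coil-mean* transverse magnetisation with rate
    |<M_perp>|/(tau_rd M0); relaxation toward +z equilibrium and offset
    precession complete the Bloch equations, integrated with fixed-step RK4
    (step <= ``max_step``).
    """

    def __init__(self, offset_hz: float = 0.0, M0: float = 100.0, T1: float = 3.0,
                 T2: float = 0.5, tau_rd: float = 5e-3, n_slices: int = 513,
                 length_cm: float = 1.6, scale: float = 1.0, max_step: float = 10e-6):
        if tau_rd <= 0:
            raise ValueError("tau_rd must be > 0")
        self.offset_hz = offset_hz
        self.M0 = M0
        self.T1, self.T2 = T1, T2
        self.tau_rd = tau_rd
        self.n_slices = n_slices
        self.length_cm = length_cm
        self.scale = scale
        self.max_step = max_step
        self.z = (np.arange(n_slices) + 0.5) / n_slices * length_cm - length_cm / 2.0
        self.M = np.zeros((n_slices, 3))
        self.M[:, 2] = M0

    def reset(self, tip_deg: float = 0.0, tip_phase_deg: float = 0.0) -> None:
        """Return to equilibrium, optionally tipped by ``tip_deg`` about y."""
        self.M[:] = 0.0
        self.M[:, 2] = self.M0
        if tip_deg:
            self.rotate(tip_deg, tip_phase_deg)

    # -- elementary operations -----------------------------------------
    def rotate(self, flip_deg: float, phase_deg: float = 0.0) -> None:
        th = np.deg2rad(flip_deg)
        ph = np.deg2rad(phase_deg)
        ax = np.array([np.cos(ph), np.sin(ph), 0.0])
        K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        self.M = self.M @ R.T

    def gradient_phase(self, amplitude: float, duration: float) -> None:
        phi = GAMMA["H1"] * amplitude * duration * self.z
        c, s = np.cos(phi), np.sin(phi)
        mx, my = self.M[:, 0].copy(), self.M[:, 1].copy()
        self.M[:, 0] = c * mx - s * my
        self.M[:, 1] = s * mx + c * my

    def evolve(self, duration: float) -> None:
        if duration <= 0:
            return
        n_steps = max(1, int(np.ceil(duration / self.max_step)))
        h = duration / n_steps
        w = 2 * np.pi * self.offset_hz
        inv_t2, inv_t1 = 1.0 / self.T2, 1.0 / self.T1
        M0 = self.M0

        def deriv(M):
            mean_t = M[:, :2].mean(axis=0)
            # RD torque omega = (<My>, -<Mx>, 0)/(tau_rd M0): damps
            # transverse magnetisation when Mz > 0, regrows it from an
            # inverted state (dMz/dt = +|M_perp|^2/(tau_rd M0))
            ox = mean_t[1] / (self.tau_rd * M0)
            oy = -mean_t[0] / (self.tau_rd * M0)
            dM = np.empty_like(M)
            dM[:, 0] = -w * M[:, 1] + oy * M[:, 2] - inv_t2 * M[:, 0]
            dM[:, 1] = w * M[:, 0] - ox * M[:, 2] - inv_t2 * M[:, 1]
            dM[:, 2] = ox * M[:, 1] - oy * M[:, 0] + inv_t1 * (M0 - M[:, 2])
            return dM

        M = self.M
        for _ in range(n_steps):
            k1 = deriv(M)
            k2 = deriv(M + 0.5 * h * k1)
            k3 = deriv(M + 0.5 * h * k2)
            k4 = deriv(M + h * k3)
            M = M + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(M)):
            raise FloatingPointError("water integration produced non-finite values")
        self.M = M

    def purge(self) -> None:
        self.M[:, :2] = 0.0

    def transverse(self) -> complex:
        m = self.M.mean(axis=0)
        return complex(m[0], m[1])


# ---------------------------------------------------------------------------
# chunked FID container


@dataclass
class ChunkedFID:
    """Per-chunk complex records of a real-time pure shift acquisition."""

    chunks: list
    dwell: float
    chunk_points: int
    receiver_phase_deg: float = 0.0
    scale: float = 1.0
    noise_seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        lens = {len(c) for c in self.chunks}
        if len(lens) > 1:
            raise ValueError("all chunks must have equal length")

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)

    @property
    def sw_ps(self) -> float:
        return 1.0 / (self.chunk_points * self.dwell)

    def stream(self) -> np.ndarray:
        return np.concatenate([np.asarray(c) for c in self.chunks])


def chop_stream(samples: np.ndarray, chunk_points: int, dwell: float, **meta) -> ChunkedFID:
    if samples.size % chunk_points:
        raise ValueError("stream length not divisible by chunk_points")
    chunks = [samples[i:i + chunk_points] for i in range(0, samples.size, chunk_points)]
    return ChunkedFID(chunks=chunks, dwell=dwell, chunk_points=chunk_points, **meta)


# ---------------------------------------------------------------------------
# simulator


class Simulator:
    """Propagates a spin system (plus optional water) through event lists."""

    def __init__(self, system: SpinSystem, ensemble: EnsembleConfig | None = None,
                 water: WaterModel | None = None,
                 coupling_mode: str = "heteronuclear_secular",
                 relaxation: bool = True):
        self.system = system
        self.ensemble = ensemble or EnsembleConfig(n_slices=1)
        self.water = water
        self.coupling_mode = coupling_mode
        self.relaxation = relaxation
        n, d = system.n_spins, system.dim
        self._H_free = free_hamiltonian(system, coupling_mode)
        self._H_acq = free_hamiltonian(system.set_heteronuclear_decoupling(True), coupling_mode)
        self._H_acq_jfree = free_hamiltonian(
            system.set_heteronuclear_decoupling(True).zero_homonuclear_j(), coupling_mode)
        # spin bit tables: bit[i, a] = 1 if spin i is beta in basis state a
        bits = np.zeros((n, d), dtype=int)
        for a in range(d):
            for i in range(n):
                bits[i, a] = (a >> (n - 1 - i)) & 1
        self._bits = bits
        m = 0.5 - bits  # magnetic quantum number per spin/state
        # relaxation rate matrix for off-diagonal decay
        r2 = np.array([1.0 / s.T2 for s in system.spins])
        flip = (bits[:, :, None] != bits[:, None, :])
        self._gamma2 = np.einsum("i,iab->ab", r2, flip)
        # gradient phase weights: w[a] = sum_i gamma_i m_i(a)
        gam = np.array([GAMMA[s.isotope] for s in system.spins])
        self._grad_w = gam @ m
        # Walsh T1 machinery
        self._r1 = np.array([0.0 if s.T1 is None else 1.0 / s.T1 for s in system.spins])
        if np.any(self._r1 > 0):
            chi = np.ones((d, d))
            for S in range(d):
                for a in range(d):
                    for i in range(n):
                        if (S >> (n - 1 - i)) & 1 and bits[i, a]:
                            chi[S, a] *= -1.0
            self._chi = chi
            self._t1_rates = np.array([
                sum(self._r1[i] for i in range(n) if (S >> (n - 1 - i)) & 1)
                for S in range(d)
            ])
            self._eq_diag = np.real(np.diag(equilibrium_state(system)))
            self._c_eq = chi @ self._eq_diag / d
        else:
            self._chi = None
        self._prop_cache: dict = {}
        self._rot_cache: dict = {}
        self._shape_cache: dict = {}
        self._ops_cache: dict = {}

    # -- operator helpers ----------------------------------------------
    def _total_op(self, axis: str, isotope: str) -> np.ndarray:
        key = (axis, isotope)
        if key not in self._ops_cache:
            idx = self.system.isotope_indices(isotope)
            self._ops_cache[key] = self.system.total_operator(axis, idx)
        return self._ops_cache[key]

    def _detect_op(self, channel: str) -> np.ndarray:
        key = ("detect", channel)
        if key not in self._ops_cache:
            self._ops_cache[key] = (self._total_op("x", channel)
                                    + 1j * self._total_op("y", channel))
        return self._ops_cache[key]

    def initial_state(self) -> np.ndarray:
        """Equilibrium ensemble state, shape (n_slices, d, d)."""
        rho = equilibrium_state(self.system)
        return np.repeat(rho[None, :, :], self.ensemble.n_slices, axis=0)

    def state_from_operator(self, op: np.ndarray) -> np.ndarray:
        rho = np.eye(self.system.dim, dtype=complex) / self.system.dim + op
        return np.repeat(rho[None, :, :], self.ensemble.n_slices, axis=0)

    # -- propagation primitives ----------------------------------------
    def _unitary(self, H: np.ndarray, duration: float, key) -> np.ndarray:
        ck = (key, round(duration, 15))
        U = self._prop_cache.get(ck)
        if U is None:
            w, V = np.linalg.eigh(H)
            U = (V * np.exp(-1j * w * duration)) @ V.conj().T
            self._prop_cache[ck] = U
        return U

    def _relax(self, rho: np.ndarray, duration: float) -> np.ndarray:
        if not self.relaxation or duration <= 0:
            return rho
        decay = np.exp(-self._gamma2 * duration)
        np.fill_diagonal(decay, 1.0)
        rho = rho * decay[None, :, :]
        if self._chi is not None:
            d = self.system.dim
            diag = np.real(np.einsum("sii->si", rho))
            c = diag @ self._chi.T / d
            c = self._c_eq[None, :] + (c - self._c_eq[None, :]) * np.exp(-self._t1_rates * duration)[None, :]
            new_diag = c @ self._chi
            s_idx = np.arange(rho.shape[0])[:, None]
            i_idx = np.arange(d)[None, :]
            rho[s_idx, i_idx, i_idx] = new_diag
        return rho

    def propagate(self, rho: np.ndarray, H: np.ndarray, duration: float,
                  key="free") -> np.ndarray:
        if duration < 0:
            raise ValueError("duration must be >= 0")
        if duration == 0:
            return rho
        if np.max(np.abs(H - H.conj().T)) > 1e-9 * max(1.0, np.max(np.abs(H))):
            raise ValueError("Hamiltonian must be Hermitian")
        U = self._unitary(H, duration, key)
        rho = np.einsum("ij,sjk,lk->sil", U, rho, U.conj())
        return self._relax(rho, duration)

    def apply_hard_pulse(self, rho: np.ndarray, channel: str, flip_deg: float,
                         phase_deg: float) -> np.ndarray:
        key = (channel, round(flip_deg, 9), round(phase_deg % 360.0, 9))
        U = self._rot_cache.get(key)
        if U is None:
            th = np.deg2rad(flip_deg)
            ph = np.deg2rad(phase_deg)
            G = np.cos(ph) * self._total_op("x", channel) + np.sin(ph) * self._total_op("y", channel)
            w, V = np.linalg.eigh(G)
            U = (V * np.exp(-1j * th * w)) @ V.conj().T
            self._rot_cache[key] = U
        return np.einsum("ij,sjk,lk->sil", U, rho, U.conj())

    def _shaped_unitary(self, ev: Event) -> np.ndarray:
        key = (id(ev.shape), round(ev.duration, 15), round(ev.peak_b1_hz, 9),
               round(ev.offset_hz, 9), round(ev.phase_deg % 360.0, 9), ev.channel)
        U = self._shape_cache.get(key)
        if U is not None:
            return U
        shape = ev.shape
        dt = ev.duration / shape.n_samples
        Fx = self._total_op("x", ev.channel)
        Fy = self._total_op("y", ev.channel)
        U = np.eye(self.system.dim, dtype=complex)
        t = 0.5 * dt
        for a, ph in zip(shape.amplitude, shape.phase_deg):
            # phase-coherent offset: frequency-modulated phase ramp, no frame jump
            phi = np.deg2rad(ph + ev.phase_deg + 360.0 * ev.offset_hz * t)
            w1 = 2 * np.pi * ev.peak_b1_hz * a
            Hk = self._H_free + w1 * (np.cos(phi) * Fx + np.sin(phi) * Fy)
            w, V = np.linalg.eigh(Hk)
            U = ((V * np.exp(-1j * w * dt)) @ V.conj().T) @ U
            t += dt
        self._shape_cache[key] = U
        return U

    def apply_shaped_pulse(self, rho: np.ndarray, ev: Event) -> np.ndarray:
        U = self._shaped_unitary(ev)
        rho = np.einsum("ij,sjk,lk->sil", U, rho, U.conj())
        return self._relax(rho, ev.duration)

    def apply_gradient(self, rho: np.ndarray, amplitude: float, duration: float,
                       axis: str = "z") -> np.ndarray:
        if axis not in self.ensemble.axes:
            raise ValueError(f"gradient axis {axis!r} not available in this ensemble")
        if amplitude != 0.0:
            if rho.shape[0] != self.ensemble.n_slices:
                raise ValueError("ensemble state required for gradients")
            z = self.ensemble.positions()
            phases = np.exp(-1j * np.outer(z * amplitude * duration, self._grad_w))
            rho = phases[:, :, None] * rho * phases.conj()[:, None, :]
        if duration > 0:
            rho = self.propagate(rho, self._H_free, duration, key="free")
        return rho

    def apply_ideal_flip(self, rho: np.ndarray) -> np.ndarray:
        """Instantaneous perfect 180x on every passive proton (incl. water role)."""
        key = ("ideal_flip",)
        U = self._rot_cache.get(key)
        if U is None:
            idx = self.system.passive_proton_indices()
            G = self.system.total_operator("x", idx)
            w, V = np.linalg.eigh(G)
            U = (V * np.exp(-1j * np.pi * w)) @ V.conj().T
            self._rot_cache[key] = U
        return np.einsum("ij,sjk,lk->sil", U, rho, U.conj())

    def purge(self, rho: np.ndarray) -> np.ndarray:
        """Ideal homospoil: zero every off-diagonal element."""
        out = np.zeros_like(rho)
        idx = np.arange(self.system.dim)
        out[:, idx, idx] = rho[:, idx, idx]
        return out

    # -- acquisition ----------------------------------------------------
    def acquire_chunk(self, rho: np.ndarray, n_points: int, dwell: float,
                      channel: str = "H1", decouple: bool = True, j_free: bool = False,
                      noise_sigma: float = 0.0, rng: np.random.Generator | None = None,
                      with_water: bool = True):
        """Sample <I+> at dwell intervals; returns (samples, rho)."""
        H = self._H_acq_jfree if j_free else (self._H_acq if decouple else self._H_free)
        key = "acq_jfree" if j_free else ("acq_dec" if decouple else "acq_coup")
        D = self._detect_op(channel)
        scale = 4.0 / self.system.dim
        out = np.empty(n_points, dtype=complex)
        for k in range(n_points):
            s = np.einsum("sij,ji->", rho, D) / rho.shape[0] * scale
            if self.water is not None and with_water and channel == "H1":
                s = s + self.water.scale * self.water.transverse()
            out[k] = s
            if k < n_points - 1:
                rho = self.propagate(rho, H, dwell, key=key)
                if self.water is not None and with_water:
                    self.water.evolve(dwell)
        # advance through the final dwell so chunks abut seamlessly
        rho = self.propagate(rho, H, dwell, key=key)
        if self.water is not None and with_water:
            self.water.evolve(dwell)
        if noise_sigma > 0.0:
            if rng is None:
                raise ValueError("noise requested without rng")
            out = out + noise_sigma * (rng.standard_normal(n_points)
                                       + 1j * rng.standard_normal(n_points))
        return out, rho

    # -- sequence execution ---------------------------------------------
    def run_events(self, events: Sequence[Event], rho: np.ndarray,
                   phase_tables: dict | None = None, step: int = 0,
                   noise_sigma: float = 0.0, rng=None):
        """Single phase-cycle step; returns (samples, rho)."""
        tables = phase_tables or {}
        samples = []
        for ev in events:
            extra = 0.0
            if ev.phase_table:
                tab = tables[ev.phase_table]
                extra = tab[step % len(tab)]
            if ev.kind == "delay":
                rho = self.propagate(rho, self._H_free, ev.duration, key="free")
                if self.water is not None:
                    self.water.evolve(ev.duration)
            elif ev.kind == "hard_pulse":
                rho = self.apply_hard_pulse(rho, ev.channel, ev.flip_deg,
                                            ev.phase_deg + extra)
                if self.water is not None and ev.channel == "H1":
                    self.water.rotate(ev.flip_deg, ev.phase_deg + extra)
            elif ev.kind == "shaped_pulse":
                ev2 = ev
                if extra != 0.0:
                    ev2 = Event(**{**ev.__dict__, "phase_deg": ev.phase_deg + extra})
                rho = self.apply_shaped_pulse(rho, ev2)
                # water is far outside the amide band; selective pulses are
                # modelled as transparent to water (documented)
            elif ev.kind == "gradient":
                rho = self.apply_gradient(rho, ev.amplitude, ev.duration, ev.axis)
                if self.water is not None:
                    self.water.gradient_phase(ev.amplitude, ev.duration)
                    self.water.evolve(ev.duration)
            elif ev.kind == "purge":
                rho = self.purge(rho)
                if self.water is not None:
                    self.water.purge()
            elif ev.kind == "ideal_flip":
                rho = self.apply_ideal_flip(rho)
                if self.water is not None:
                    self.water.rotate(180.0, 0.0)
            elif ev.kind == "acquire":
                sig, rho = self.acquire_chunk(
                    rho, ev.n_points, ev.dwell, channel=ev.channel,
                    decouple=ev.decouple, j_free=ev.j_free,
                    noise_sigma=noise_sigma, rng=rng)
                samples.append(sig)
            else:
                raise ValueError(f"unknown event kind {ev.kind!r}")
        sig = np.concatenate(samples) if samples else np.empty(0, dtype=complex)
        return sig, rho

    def run_sequence(self, events: Sequence[Event], rho0: np.ndarray | None = None,
                     phase_tables: dict | None = None,
                     receiver_table: Sequence[float] | None = None,
                     n_steps: int = 1, noise_sigma: float = 0.0,
                     seed: int | None = None,
                     water_reset: dict | None = None) -> np.ndarray:
        """Execute ``events`` for each phase-cycle step and average.

        Deterministic given ``seed``; the receiver table multiplies each
        step's signal (defaults to all +1).
        """
        for ev in events:
            if ev.phase_table and (not phase_tables or ev.phase_table not in phase_tables):
                raise ValueError(f"unresolved phase table {ev.phase_table!r}")
        rng = np.random.default_rng(seed) if seed is not None else None
        if noise_sigma > 0 and rng is None:
            raise ValueError("noise requires a seed")
        rec = receiver_table or [1.0] * n_steps
        total = None
        for step in range(n_steps):
            rho = (rho0 if rho0 is not None else self.initial_state()).copy()
            if self.water is not None:
                self.water.reset(**(water_reset or {}))
            sig, _ = self.run_events(events, rho, phase_tables, step,
                                     noise_sigma=noise_sigma, rng=rng)
            sig = sig * rec[step % len(rec)]
            total = sig if total is None else total + sig
        return total / n_steps

    def sequence_propagator(self, events: Sequence[Event],
                            phase_tables: dict | None = None, step: int = 0) -> np.ndarray:
        """Net unitary of an event list (no relaxation, no gradients/acquire)."""
        U = np.eye(self.system.dim, dtype=complex)
        tables = phase_tables or {}
        for ev in events:
            extra = 0.0
            if ev.phase_table and ev.phase_table in tables:
                tab = tables[ev.phase_table]
                extra = tab[step % len(tab)]
            if ev.kind in ("delay", "gradient"):
                if ev.duration > 0:
                    U = self._unitary(self._H_free, ev.duration, "free") @ U
            elif ev.kind == "hard_pulse":
                ident = np.eye(self.system.dim, dtype=complex)
                rho = self.apply_hard_pulse(ident[None], ev.channel, ev.flip_deg,
                                            ev.phase_deg + extra)
                # recover the unitary from its action: U = R @ I => use cache
                key = (ev.channel, round(ev.flip_deg, 9),
                       round((ev.phase_deg + extra) % 360.0, 9))
                U = self._rot_cache[key] @ U
            elif ev.kind == "shaped_pulse":
                ev2 = ev
                if extra != 0.0:
                    ev2 = Event(**{**ev.__dict__, "phase_deg": ev.phase_deg + extra})
                U = self._shaped_unitary(ev2) @ U
            elif ev.kind == "ideal_flip":
                self.apply_ideal_flip(np.eye(self.system.dim, dtype=complex)[None])
                U = self._rot_cache[("ideal_flip",)] @ U
            else:
                raise ValueError(f"{ev.kind} has no unitary representation")
        return U


def propagator_fidelity(U: np.ndarray, U_ideal: np.ndarray) -> float:
    """|tr(U_ideal^dag U)| / d — 1 when equal up to a global phase."""
    d = U.shape[0]
    return float(abs(np.trace(U_ideal.conj().T @ U)) / d)


def water_response(water: WaterModel, events: Sequence[Event],
                   tip_deg: float = 0.0) -> np.ndarray:
    """Classical water-only signal through an event list (solute ignored)."""
    water.reset(tip_deg=tip_deg)
    out = []
    for ev in events:
        if ev.kind == "delay":
            water.evolve(ev.duration)
        elif ev.kind == "hard_pulse":
            if ev.channel == "H1":
                water.rotate(ev.flip_deg, ev.phase_deg)
        elif ev.kind == "shaped_pulse":
            pass  # band-selective, transparent to water
        elif ev.kind == "gradient":
            water.gradient_phase(ev.amplitude, ev.duration)
            water.evolve(ev.duration)
        elif ev.kind == "purge":
            water.purge()
        elif ev.kind == "ideal_flip":
            water.rotate(180.0, 0.0)
        elif ev.kind == "acquire":
            sig = np.empty(ev.n_points, dtype=complex)
            for k in range(ev.n_points):
                sig[k] = water.scale * water.transverse()
                water.evolve(ev.dwell)
            out.append(sig)
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return np.concatenate(out) if out else np.empty(0, dtype=complex)
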