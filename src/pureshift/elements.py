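"""J-refocusing elements, the real-time acquisition loop and HSQC skeletons.

The pure shift elements are double spin echoes: a hard-180 echo (echo A)
that inverts *every* proton, followed by a discriminating echo (echo B)
that re-inverts only the observed (active) amide protons — the BIRD
sandwich for broadband discrimination by the one-bond 15N coupling, or a
band-selective reBURP 180 for BASHD.  The net element propagator is then
the identity on active protons (with zero net shift evolution) and a 180
degree rotation on passive protons, which reverses homonuclear J_HH
evolution from chunk to chunk.

The BIRD core lasts 2*Delta = 1/1J_NH (11.1 ms at 90 Hz) independent of
field strength; the BASHD selective pulse spans the amide band and scales
inversely with field, so BASHD elements are shorter on protein samples.

Phase cycling: the standard gHSQC cycle is Phi1 = {x, y}, Phi2 = {y, -x},
Phi3 = {-x, -y}, extended to 32 steps when pure shift elements are added;
here the elements carry a 2-step (optionally 4-step) EXORCYCLE on the hard
echo-A 180 (two steps is the recommended minimum in practice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine as eng
from .engine import (EXORCYCLE_PHASES, EXORCYCLE_RECEIVER, ChunkedFID, Event,
                     Simulator, acquire, chop_stream, delay,
                     gradient, hard_pulse, shaped_pulse)
from .shapes import PulseShape, calibrate_b1, reburp_shape
from .spin_core import SpinSystem


@dataclass
class CtpGradients:
    """Matched CTP gradient pairs wrapped around the two echoes."""

    g1: float = 16.6          # G/cm, around the hard echo-A 180
    g2: float = 13.6          # G/cm, around the discriminating echo B
    duration: float = 0.5e-3  # s
    axis: str = "z"


@dataclass
class ElementSpec:
    """Parameters of one J-refocusing element."""

    kind: str = "bird"                      # bird | bashd | gbird | gbashd | ideal
    J_NH_nominal: float = 90.0              # Hz
    shape: PulseShape | None = None         # BASHD selective pulse
    shape_duration: float = 2.44e-3         # s
    shape_bandwidth: float = 2000.0         # Hz (informational)
    shape_peak_b1: float | None = None      # Hz; calibrated if omitted
    ctp: CtpGradients = field(default_factory=CtpGradients)
    delta1: float = 20e-6                   # amplifier/receiver blanking
    delta2: float = 50e-6                   # transmitter power switching
    delta3: float = 208e-6                  # 2nd 15N-180 time correction
    stabilization: float = 200e-6           # gradient recovery
    exorcycle_steps: int = 2

    def __post_init__(self):
        if self.kind not in ("bird", "bashd", "gbird", "gbashd", "ideal"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.exorcycle_steps not in (1, 2, 4):
            raise ValueError("exorcycle_steps must be 1, 2 or 4")

    def resolved_shape(self) -> tuple[PulseShape, float]:
        shape = self.shape or reburp_shape(256)
        b1 = self.shape_peak_b1
        if b1 is None:
            b1 = calibrate_b1(shape, self.shape_duration)
            self.shape_peak_b1 = b1
        if self.shape is None:
            self.shape = shape
        return shape, b1


def element_duration(events: list[Event]) -> float:
    """Total element duration: the exact sum of its event durations."""
    return float(sum(ev.duration for ev in events))


def contract_fidelity(sim: Simulator, events: list[Event],
                      phase_tables: dict | None = None,
                      n_phi: int = 721) -> float:
    """Fidelity of an element's net propagator to its decoupling contract.

    Contract: identity (zero net shift evolution) on active protons, a 180
    rotation on passive protons, identity on 15N.  The azimuth of the
    passive 180 is immaterial for homodecoupling (it still maps z to -z
    while passive spins are longitudinal), so the fidelity is maximised
    over a common passive azimuth.
    """
    system = sim.system
    U = sim.sequence_propagator(events, phase_tables=phase_tables)
    idx = system.passive_proton_indices()
    best = 0.0
    for phi in np.linspace(0.0, 360.0, n_phi):
        ph = np.deg2rad(phi)
        G = (np.cos(ph) * system.total_operator("x", idx)
             + np.sin(ph) * system.total_operator("y", idx))
        w, V = np.linalg.eigh(G)
        U_ideal = (V * np.exp(-1j * np.pi * w)) @ V.conj().T
        f = eng.propagator_fidelity(U, U_ideal)
        if f > best:
            best = f
    return best


def bird_element(spec: ElementSpec) -> list[Event]:
    """BIRD-based double spin echo (echo A + BIRD core + trailing 15N 180).

    With perfect pulses at J = J_NH_nominal the net propagator is, up to a
    global phase, the identity on 15N-bound protons (zero net shift
    evolution) and a 180 rotation on remote protons; the BIRD core lasts
    2*Delta = 1/J.  Delay padding keeps the signed shift evolution of
    active protons exactly balanced (the delta3 "time correction" of the
    second nitrogen 180).
    """
    if spec.kind not in ("bird", "gbird"):
        raise ValueError("bird_element needs kind bird or gbird")
    if spec.J_NH_nominal <= 0:
        raise ValueError("J_NH_nominal must be > 0")
    Delta = 1.0 / (2.0 * spec.J_NH_nominal)
    tau = spec.delta2
    # The right echo-A half (tau + delta1 + delta3 - delta2) balances both
    # the chemical-shift and the J_NH signed evolution of the active proton
    # over the whole element (the delta3 "time correction"): with the
    # trailing 15N 180 adjacent to the core, net shift and net J_NH phase
    # are exactly zero at J = J_NH_nominal.
    ev = [
        delay(spec.delta1, tags=("echoA",)),
        delay(tau, tags=("echoA",)),
        hard_pulse("H1", 180.0, 0.0, phase_table="exo", tags=("echoA", "echoA_180")),
        delay(tau + spec.delta1 + spec.delta3 - spec.delta2, tags=("echoA",)),
        delay(spec.delta2, tags=("gapAB",)),
        # BIRD core phases chosen so the core acts as 180x on the 15N-bound
        # proton (composing with echo A to the identity) and as the identity
        # (global phase) on remote protons
        hard_pulse("H1", 90.0, 270.0, tags=("core", "core_start")),
        delay(Delta, tags=("core",)),
        hard_pulse("H1", 180.0, 90.0, phase_table="exo2", tags=("core",)),
        hard_pulse("N15", 180.0, 0.0, tags=("core",)),
        delay(Delta, tags=("core",)),
        hard_pulse("H1", 90.0, 270.0, tags=("core", "core_end")),
        hard_pulse("N15", 180.0, 90.0, tags=("n_restore",)),
        delay(spec.delta3, tags=("tail",)),
    ]
    return ev


def bashd_element(spec: ElementSpec) -> list[Event]:
    """Band-selective double spin echo: hard-180 echo + reBURP echo.

    Net propagator: identity (shift-refocused) on in-band protons, 180 on
    out-of-band protons.  A passive proton *inside* the band is re-inverted
    too, so its couplings to in-band amides are not decoupled (recoupling).
    """
    if spec.kind not in ("bashd", "gbashd"):
        raise ValueError("bashd_element needs kind bashd or gbashd")
    shape, b1 = spec.resolved_shape()
    tau = spec.delta2
    ev = [
        delay(spec.delta1, tags=("echoA",)),
        delay(tau, tags=("echoA",)),
        hard_pulse("H1", 180.0, 0.0, phase_table="exo", tags=("echoA", "echoA_180")),
        delay(tau + spec.delta1, tags=("echoA",)),
        delay(spec.delta2, tags=("gapAB",)),
        shaped_pulse("H1", shape, spec.shape_duration, b1, offset_hz=0.0,
                     phase_deg=0.0, phase_table="exo2", tags=("core", "selective")),
        delay(spec.delta2, tags=("tail",)),
    ]
    return ev


def ideal_element() -> list[Event]:
    """Oracle element: instantaneous perfect inversion of passive protons."""
    return [Event("ideal_flip", tags=("core",))]


def build_element(spec: ElementSpec, grad_sign: float = 1.0) -> list[Event]:
    if spec.kind in ("bird", "gbird"):
        ev = bird_element(spec)
    elif spec.kind in ("bashd", "gbashd"):
        ev = bashd_element(spec)
    else:
        return ideal_element()
    if spec.kind in ("gbird", "gbashd"):
        ev = ctp_wrap(ev, spec, grad_sign=grad_sign)
    return ev


def ctp_wrap(events: list[Event], spec: ElementSpec, grad_sign: float = 1.0) -> list[Event]:
    """Insert matched CTP gradient pairs around echo A and echo B.

    Both echoes invert the observed coherence, so same-sign pairs (g, g)
    refocus it exactly (loss-free with perfect pulses) while transverse
    magnetisation that is *not* inverted by the discriminating echo —
    notably water — is dephased by the g2 pair.  ``grad_sign`` flips the
    polarity of the whole wrap; alternating it between successive elements
    makes the cumulative water-dephasing moment grow monotonically, so
    transverse water created in one chunk can never be gradient-echoed
    back into coherence by a later element.
    """
    ctp = spec.ctp
    if ctp is None or (ctp.g1 == 0 and ctp.g2 == 0):
        raise ValueError("CTP wrap requested without gradients defined")
    stab = spec.stabilization

    def pair(g):
        return (gradient(grad_sign * g, ctp.duration, ctp.axis, tags=("ctp",)),
                delay(stab, tags=("ctp_stab",)))

    # The closing g2 goes after the trailing 15N 180 when one exists (BIRD):
    # both g2 periods then sit in regions of opposite J_NH evolution sign,
    # keeping the element's net shift AND J_NH phase balanced.
    has_n_restore = any("n_restore" in ev.tags for ev in events)
    out: list[Event] = []
    for ev in events:
        if "echoA_180" in ev.tags:
            g, s = pair(ctp.g1)
            out.extend([g, s, ev])
            g2_, s2_ = pair(ctp.g1)
            out.extend([g2_, s2_])
        elif "core_start" in ev.tags or "selective" in ev.tags:
            g, s = pair(ctp.g2)
            out.extend([g, s, ev])
            if "selective" in ev.tags:
                g2_, s2_ = pair(ctp.g2)
                out.extend([g2_, s2_])
        elif "core_end" in ev.tags and not has_n_restore:
            out.append(ev)
            g, s = pair(ctp.g2)
            out.extend([g, s])
        elif "n_restore" in ev.tags:
            out.append(ev)
            g, s = pair(ctp.g2)
            out.extend([g, s])
        else:
            out.append(ev)
    return out


# ---------------------------------------------------------------------------
# acquisition plans


@dataclass
class AcquisitionPlan:
    """Chunked direct-dimension acquisition parameters."""

    sw: float = 5000.0            # Hz
    total_points: int = 1024      # complex points over the whole FID
    n_chunks: int = 4
    droppoints: int = 0
    element: ElementSpec = field(default_factory=ElementSpec)

    def __post_init__(self):
        if self.total_points % self.n_chunks:
            raise ValueError(
                "sw_ps must be an integer submultiple of sw: total_points "
                f"{self.total_points} not divisible by n_chunks {self.n_chunks}")
        if self.n_chunks > 1 and self.chunk_points % 2:
            raise ValueError("chunk_points must be even (half-chunk edges)")

    @property
    def dwell(self) -> float:
        return 1.0 / self.sw

    @property
    def chunk_points(self) -> int:
        return self.total_points // self.n_chunks

    @property
    def chunk_duration(self) -> float:
        return self.chunk_points * self.dwell

    @property
    def sw_ps(self) -> float:
        return 1.0 / self.chunk_duration

    @property
    def total_duration(self) -> float:
        return self.total_points * self.dwell


def realtime_acquisition(plan: AcquisitionPlan) -> list[Event]:
    """Real-time pure shift loop: acquisition chunks with elements between.

    Uses the midpoint-refocused arrangement (half chunk, then
    [element, full chunk] x (n-1), element, half chunk): each data chunk of
    duration 1/sw_ps is then centred between element firings, the net J_HH
    phase vanishes at every chunk centre, and decoupling sidebands appear
    at multiples of sw_ps.  One chunk degenerates to plain acquisition.
    """
    el = plan.element
    jf = el.kind == "ideal"
    dw = plan.dwell
    if plan.n_chunks == 1:
        return [acquire(plan.total_points, dw, "H1", j_free=jf, tags=("chunk",))]
    half = plan.chunk_points // 2
    ev: list[Event] = [acquire(half, dw, "H1", j_free=jf, tags=("chunk",))]
    for k in range(plan.n_chunks - 1):
        ev.extend(build_element(el, grad_sign=(-1.0) ** k))
        ev.append(acquire(plan.chunk_points, dw, "H1", j_free=jf, tags=("chunk",)))
    ev.extend(build_element(el, grad_sign=(-1.0) ** (plan.n_chunks - 1)))
    ev.append(acquire(half, dw, "H1", j_free=jf, tags=("chunk",)))
    return ev


def element_phase_tables(spec: ElementSpec) -> tuple[dict, list, int]:
    steps = spec.exorcycle_steps
    tables = {"exo": EXORCYCLE_PHASES[steps],
              "exo2": eng.EXORCYCLE_PHASES_B[steps]}
    return (tables, EXORCYCLE_RECEIVER[steps], steps)


def run_pure_shift_1d(system: SpinSystem, plan: AcquisitionPlan,
                      sim: Simulator | None = None,
                      initial: np.ndarray | None = None,
                      excite: str = "active",
                      noise_sigma: float = 0.0, seed: int | None = None) -> ChunkedFID:
    """One real-time pure shift FID.

    ``excite="active"`` (default) starts from in-phase x-coherence on the
    active amide protons only, as the HSQC transfer delivers it (passive
    protons longitudinal); ``excite="all"`` is a plain 90-acquire in which
    passive-proton coherence is chopped by the elements (artifact comb).
    """
    sim = sim or Simulator(system)
    tables, rec, steps = element_phase_tables(plan.element)
    if initial is not None:
        rho0 = initial
        events = realtime_acquisition(plan)
    elif excite == "active":
        d = system.dim
        op = np.zeros((d, d), dtype=complex)
        for i in system.active_indices():
            op += system.operator(system.spins[i].label, "x")
        rho0 = sim.state_from_operator(op)
        events = realtime_acquisition(plan)
    elif excite == "all":
        rho0 = None
        events = [hard_pulse("H1", 90.0, 90.0)] + realtime_acquisition(plan)
    else:
        raise ValueError(f"unknown excite mode {excite!r}")
    stream = sim.run_sequence(events, rho0=rho0, phase_tables=tables,
                              receiver_table=rec, n_steps=steps,
                              noise_sigma=noise_sigma, seed=seed)
    return chop_stream(stream, plan.chunk_points, plan.dwell,
                       noise_seed=seed,
                       meta={"sw": plan.sw, "n_chunks": plan.n_chunks,
                             "element": plan.element.kind,
                             "carrier_ppm": system.carrier_ppm["H1"],
                             "base_freq": system.base_freq["H1"]})


# ---------------------------------------------------------------------------
# HSQC skeletons


@dataclass
class HsqcPlan:
    """Indirect-dimension (15N) parameters of the 2D experiment."""

    variant: str = "edited_gHSQC"     # edited_gHSQC | gHSQC_SE | ideal_start
    n_increments: int = 64
    sw1: float = 1500.0               # Hz
    relaxation_delay: float = 1.0     # s (bookkeeping only in ideal_start)
    echo_antiecho: bool = False
    mode: str = "ideal_start"         # ideal_start | explicit

    @property
    def dwell1(self) -> float:
        return 1.0 / self.sw1


def _n_partner_offsets(system: SpinSystem) -> dict[int, float]:
    """Map active-proton index -> offset (Hz) of its one-bond 15N partner."""
    out = {}
    for i in system.active_indices():
        js = [(abs(system.J[i, j]), j) for j, s in enumerate(system.spins)
              if s.isotope == "N15" and system.J[i, j] != 0.0]
        if not js:
            raise ValueError("active proton without 15N partner")
        _, j = max(js)
        out[i] = system.offsets_hz()[j]
    return out


def hsqc_sequence(system: SpinSystem, hsqc: HsqcPlan, acq: AcquisitionPlan,
                  sim: Simulator | None = None) -> dict:
    """Run the 2D experiment; returns {'records': {...}, metadata}.

    ideal_start mode prepares in-phase active-1H coherence amplitude
    modulated by cos/sin(Omega_N t1) (or the echo/antiecho pair when
    ``echo_antiecho``), then runs the real-time acquisition loop.  explicit
    mode runs INEPT (delays 1/(4 J_NH)) - t1 with a 1H 180 at its midpoint -
    back-INEPT, with a two-step isotope-filter cycle on the first 15N 90.
    Both place the 2D peak at (nu_N, nu_H).
    """
    sim = sim or Simulator(system)
    tables, rec, steps = element_phase_tables(acq.element)
    acq_events = realtime_acquisition(acq)
    noffs = _n_partner_offsets(system)
    d = system.dim
    records: dict[str, list] = {}
    names = ("echo", "anti") if hsqc.echo_antiecho else ("cos", "sin")
    for name in names:
        records[name] = []
    for k in range(hsqc.n_increments):
        t1 = k * hsqc.dwell1
        if hsqc.mode == "ideal_start":
            for name in names:
                op = np.zeros((d, d), dtype=complex)
                for i, nu in noffs.items():
                    c, s = np.cos(2 * np.pi * nu * t1), np.sin(2 * np.pi * nu * t1)
                    lab = system.spins[i].label
                    Ix = system.operator(lab, "x")
                    Iy = system.operator(lab, "y")
                    if name == "cos":
                        op += c * Ix
                    elif name == "sin":
                        op += s * Ix
                    elif name == "echo":
                        op += c * Ix + s * Iy
                    else:  # anti
                        op += c * Ix - s * Iy
                rho0 = sim.state_from_operator(op)
                stream = sim.run_sequence(acq_events, rho0=rho0, phase_tables=tables,
                                          receiver_table=rec, n_steps=steps)
                records[name].append(chop_stream(stream, acq.chunk_points, acq.dwell))
        elif hsqc.mode == "explicit":
            J = acq.element.J_NH_nominal
            tau = 1.0 / (4.0 * J)
            for name in names:
                # 270 (not 90) on the first 15N 90 gives the +Omega_N sense
                # matching the ideal_start convention
                phN = 0.0 if name == "cos" else 270.0
                total = None
                for flt in range(2):  # isotope filter: N-90 x / -x, receiver +/-
                    pre = [
                        hard_pulse("H1", 90.0, 0.0),
                        delay(tau),
                        hard_pulse("H1", 180.0, 0.0), hard_pulse("N15", 180.0, 0.0),
                        delay(tau),
                        hard_pulse("H1", 90.0, 90.0),
                        hard_pulse("N15", 90.0, phN + 180.0 * flt),
                        delay(t1 / 2), hard_pulse("H1", 180.0, 0.0), delay(t1 / 2),
                        hard_pulse("N15", 90.0, 0.0),
                        hard_pulse("H1", 90.0, 0.0),
                        delay(tau),
                        hard_pulse("H1", 180.0, 0.0), hard_pulse("N15", 180.0, 0.0),
                        delay(tau),
                    ]
                    stream = sim.run_sequence(pre + acq_events, phase_tables=tables,
                                              receiver_table=rec, n_steps=steps)
                    stream = stream * (1.0 if flt == 0 else -1.0)
                    total = stream if total is None else total + stream
                records[name].append(chop_stream(total / 2.0, acq.chunk_points, acq.dwell))
        else:
            raise ValueError(f"unknown hsqc mode {hsqc.mode!r}")
    return {
        "records": records,
        "sw": acq.sw,
        "sw1": hsqc.sw1,
        "carrier_ppm": dict(system.carrier_ppm),
        "base_freq": dict(system.base_freq),
        "echo_antiecho": hsqc.echo_antiecho,
    }
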