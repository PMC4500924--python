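"""Double-cable myelinated axon model (MRG-style) with extracellular drive.

Morphology follows the McIntyre-Richardson-Grill mammalian fiber: a
repeating unit of node - MYSA - FLUT - 6 x STIN - FLUT - MYSA between
nodes of Ranvier, with per-diameter geometry from the published table
(linearly interpolated between entries; a prior-work small-fiber entry
extends the table down to 2 um).  Nodes carry fast Na+, persistent Na+,
slow K+ and leak channels; paranodes (MYSA/FLUT) carry a slow K+ current
plus leak; internodes are passive.  Myelin is a passive sheath whose
conductance and capacitance scale inversely with the lamella count.

Stimulation couples through the extracellular potential at each
compartment (the outer node of the double cable), supplied per unit
stimulus current from a volume-conductor solution and scaled by the pulse
waveform; the model is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._cable_core import run_cable, steady_gates

__all__ = [
    "MRG_GEOMETRY_TABLE",
    "mrg_geometry",
    "AxonMorphology",
    "MembraneParams",
    "StimProtocol",
    "CableTrace",
    "build_morphology",
    "closest_arc_to_point",
    "simulate",
    "detect_spikes",
    "is_activated",
    "find_threshold",
    "NOT_ACTIVATED",
]

#: Sentinel threshold for fibers not activated up to the amplitude cap.
NOT_ACTIVATED = float("nan")

# Per-diameter geometry: fiberD -> (axonD, nodeD, paraD1, paraD2,
# internode pitch deltax, FLUT length, myelin lamellae).  Lengths in um.
# 5.7-16.0 are the published MRG table; 2.0 is the small-fiber convention
# used by prior brainstem modelling work.
MRG_GEOMETRY_TABLE: dict[float, tuple] = {
    2.0: (1.6, 1.4, 1.4, 1.6, 200.0, 10.0, 30),
    5.7: (3.4, 1.9, 1.9, 3.4, 500.0, 35.0, 80),
    7.3: (4.6, 2.4, 2.4, 4.6, 750.0, 38.0, 100),
    8.7: (5.8, 2.8, 2.8, 5.8, 1000.0, 40.0, 110),
    10.0: (6.9, 3.3, 3.3, 6.9, 1150.0, 46.0, 120),
    11.5: (8.1, 3.7, 3.7, 8.1, 1250.0, 50.0, 130),
    12.8: (9.2, 4.2, 4.2, 9.2, 1350.0, 54.0, 135),
    14.0: (10.4, 4.7, 4.7, 10.4, 1400.0, 56.0, 140),
    15.0: (11.5, 5.0, 5.0, 11.5, 1450.0, 58.0, 145),
    16.0: (12.7, 5.5, 5.5, 12.7, 1500.0, 60.0, 150),
}

NODE_LENGTH_UM = 1.0
MYSA_LENGTH_UM = 3.0
# periaxonal space widths (um): node/MYSA tight, FLUT/STIN wider
SPACE_NODE_UM = 0.002
SPACE_MYSA_UM = 0.002
SPACE_FLUT_UM = 0.004
SPACE_STIN_UM = 0.004

NODE, MYSA, FLUT, STIN = 0, 1, 2, 3


def mrg_geometry(diameter_um: float) -> dict:
    """Geometric parameters for a fiber diameter in [2, 16] um.

    Tabulated diameters return the table entry exactly; intermediate
    diameters interpolate each parameter linearly in fiber diameter.
    """
    keys = np.array(sorted(MRG_GEOMETRY_TABLE))
    if not (keys[0] <= diameter_um <= keys[-1]):
        raise ValueError(f"fiber diameter {diameter_um} um outside [2, 16]")
    cols = np.array([MRG_GEOMETRY_TABLE[k] for k in keys], dtype=float)
    vals = [float(np.interp(diameter_um, keys, cols[:, j])) for j in range(7)]
    axonD, nodeD, paraD1, paraD2, deltax, flut_len, nl = vals
    stin_len = (deltax - NODE_LENGTH_UM - 2 * MYSA_LENGTH_UM - 2 * flut_len) / 6.0
    return {
        "fiberD": diameter_um,
        "axonD": axonD,
        "nodeD": nodeD,
        "paraD1": paraD1,
        "paraD2": paraD2,
        "deltax": deltax,
        "flut_length": flut_len,
        "stin_length": stin_len,
        "nl": nl,
    }


@dataclass
class AxonMorphology:
    """Compartmentalized fiber placed along a 3D trajectory."""

    diameter_um: float
    ctype: np.ndarray        # (ncomp,) compartment type codes
    lengths_um: np.ndarray   # (ncomp,)
    diams_um: np.ndarray     # (ncomp,) axolemma diameter
    positions_mm: np.ndarray  # (ncomp, 3) compartment centers
    nl: float                # myelin lamellae per internodal compartment

    @property
    def n_compartments(self) -> int:
        return len(self.ctype)

    @property
    def node_indices(self) -> np.ndarray:
        return np.nonzero(self.ctype == NODE)[0]

    @property
    def n_nodes(self) -> int:
        return int((self.ctype == NODE).sum())


@dataclass
class MembraneParams:
    """Channel densities (S/cm^2), passive properties, and temperature.

    The leak reversal is solved per compartment type so that ``v_rest`` is
    an exact equilibrium of the dynamics with gates at steady state.
    """

    gnaf: float = 3.0
    gnap: float = 0.01
    gks: float = 0.08
    gleak_node: float = 0.007
    gpas_mysa: float = 0.001
    gpas_flut: float = 0.0001
    gpas_stin: float = 0.0001
    gks_para: float = 2e-4     # paranodal slow K+ (MYSA + FLUT)
    e_na: float = 50.0
    e_k: float = -90.0
    cm: float = 2.0            # uF/cm^2 axolemma
    rho_axial: float = 70.0    # Ohm*cm axoplasm (and periaxonal space)
    g_myelin: float = 0.001    # S/cm^2 per myelin membrane
    c_myelin: float = 0.1      # uF/cm^2 per myelin membrane
    v_rest: float = -80.0
    celsius: float = 36.0

    def __post_init__(self) -> None:
        for name in (
            "gnaf", "gnap", "gks", "gleak_node", "gpas_mysa", "gpas_flut",
            "gpas_stin", "gks_para", "g_myelin",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be non-negative")
        if self.rho_axial <= 0 or self.cm <= 0 or self.c_myelin <= 0:
            raise ValueError("passive cable properties must be positive")

    @property
    def q10(self) -> tuple[float, float, float]:
        return (
            2.2 ** ((self.celsius - 20.0) / 10.0),
            2.9 ** ((self.celsius - 20.0) / 10.0),
            3.0 ** ((self.celsius - 36.0) / 10.0),
        )


@dataclass
class StimProtocol:
    """Rectangular pulse-train stimulus and the activation criterion.

    Cathodic monophasic pulses: the injected current is ``-amplitude_ma``
    at the active contact.  Activation requires a propagated action
    potential with latency in the closed window ``latency_window_ms`` after
    a pulse onset, for at least ``min_responding`` of ``n_pulses`` pulses.
    """

    pulse_width_us: float = 90.0
    rate_hz: float = 20.0
    n_pulses: int = 10
    amplitude_ma: float = 1.0
    polarity: str = "cathodic"
    latency_window_ms: tuple[float, float] = (1.0, 3.0)
    min_responding: int = 8
    onset_ms: float = 1.0  # quiet settling time before the first pulse

    def __post_init__(self) -> None:
        if self.pulse_width_us * 1e-3 >= 1000.0 / self.rate_hz:
            raise ValueError("pulse width must be shorter than the period")
        if self.amplitude_ma <= 0:
            raise ValueError("amplitude must be positive (sign via polarity)")
        if self.polarity not in ("cathodic", "anodic"):
            raise ValueError("polarity must be 'cathodic' or 'anodic'")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.rate_hz

    def pulse_onsets_ms(self, n_pulses: int | None = None) -> np.ndarray:
        n = self.n_pulses if n_pulses is None else n_pulses
        return self.onset_ms + self.period_ms * np.arange(n)

    @property
    def sign(self) -> float:
        return -1.0 if self.polarity == "cathodic" else 1.0


@dataclass
class CableTrace:
    """Membrane-potential traces at the nodes of Ranvier."""

    times_ms: np.ndarray      # (n_steps + 1,)
    vm_mV: np.ndarray         # (n_steps + 1, n_recorded)
    record_comp: np.ndarray   # recorded compartment indices
    morphology: AxonMorphology


# ---------------------------------------------------------------------------
# Morphology construction
# ---------------------------------------------------------------------------


def _arc_lengths(traj: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(traj, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def closest_arc_to_point(trajectory: np.ndarray, point: np.ndarray) -> float:
    """Arc length (mm) at which a polyline passes closest to a point."""
    traj = np.asarray(trajectory, dtype=float)
    arcs = _arc_lengths(traj)
    a, b = traj[:-1], traj[1:]
    ab = b - a
    ab2 = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(((point - a) * ab).sum(axis=1) / ab2, 0.0, 1.0)
    closest = a + t[:, None] * ab
    d = np.linalg.norm(closest - point, axis=1)
    k = int(np.argmin(d))
    return float(arcs[k] + t[k] * np.sqrt(ab2[k]))


def build_morphology(
    diameter_um: float,
    trajectory: np.ndarray,
    n_nodes: int = 21,
    center_arc_mm: float | None = None,
) -> AxonMorphology:
    """Place an n-node fiber along a trajectory by arc length.

    Compartment centers are positioned on the polyline; the fiber is
    centered at ``center_arc_mm`` (default: trajectory midpoint; callers
    typically pass the arc of closest approach to the lead).  Raises if the
    trajectory is shorter than the fiber span.
    """
    if n_nodes < 21:
        raise ValueError("at least 21 nodes of Ranvier are required")
    traj = np.asarray(trajectory, dtype=float)
    geom = mrg_geometry(diameter_um)

    unit_types = [NODE, MYSA, FLUT] + [STIN] * 6 + [FLUT, MYSA]
    unit_lengths = (
        [NODE_LENGTH_UM, MYSA_LENGTH_UM, geom["flut_length"]]
        + [geom["stin_length"]] * 6
        + [geom["flut_length"], MYSA_LENGTH_UM]
    )
    types: list[int] = []
    lengths: list[float] = []
    for _ in range(n_nodes - 1):
        types.extend(unit_types)
        lengths.extend(unit_lengths)
    types.append(NODE)
    lengths.append(NODE_LENGTH_UM)
    ctype = np.array(types, dtype=np.uint8)
    lengths_um = np.array(lengths)
    diam_by_type = {
        NODE: geom["nodeD"],
        MYSA: geom["paraD1"],
        FLUT: geom["paraD2"],
        STIN: geom["axonD"],
    }
    diams_um = np.array([diam_by_type[t] for t in types])

    span_mm = lengths_um.sum() / 1000.0
    arcs = _arc_lengths(traj)
    total = arcs[-1]
    if center_arc_mm is None:
        center_arc_mm = total / 2.0
    start = center_arc_mm - span_mm / 2.0
    if start < -1e-9 or start + span_mm > total + 1e-9:
        raise ValueError(
            f"trajectory ({total:.1f} mm) too short for a {span_mm:.1f} mm "
            f"fiber centered at arc {center_arc_mm:.1f} mm"
        )
    centers_mm = start + (np.cumsum(lengths_um) - lengths_um / 2.0) / 1000.0
    positions = np.stack(
        [np.interp(centers_mm, arcs, traj[:, k]) for k in range(3)], axis=1
    )
    return AxonMorphology(
        diameter_um=diameter_um,
        ctype=ctype,
        lengths_um=lengths_um,
        diams_um=diams_um,
        positions_mm=positions,
        nl=geom["nl"],
    )


# ---------------------------------------------------------------------------
# Electrical system assembly
# ---------------------------------------------------------------------------


def _resting_reversals(params: MembraneParams) -> tuple[float, float, float]:
    """Leak reversals (node, paranode) making v_rest an exact fixed point."""
    q1, q2, q3 = params.q10
    m, h, p, s = steady_gates(params.v_rest, q1, q2, q3)
    v = params.v_rest
    i_chan = (
        params.gnaf * m**3 * h * (v - params.e_na)
        + params.gnap * p**3 * (v - params.e_na)
        + params.gks * s * (v - params.e_k)
    )
    e_node = v + i_chan / params.gleak_node
    i_para_mysa = params.gks_para * s * (v - params.e_k)
    e_mysa = v + i_para_mysa / params.gpas_mysa
    e_flut = v + i_para_mysa / params.gpas_flut
    return e_node, e_mysa, e_flut


def build_system(morph: AxonMorphology, params: MembraneParams) -> dict:
    """Per-compartment electrical arrays for the integration kernel."""
    n = morph.n_compartments
    d_cm = morph.diams_um * 1e-4
    L_cm = morph.lengths_um * 1e-4
    area_cm2 = np.pi * d_cm * L_cm                     # axolemma area
    fiber_area_cm2 = np.pi * (morph.diameter_um * 1e-4) * L_cm  # myelin area

    is_node = morph.ctype == NODE
    is_mysa = morph.ctype == MYSA
    is_flut = morph.ctype == FLUT
    is_stin = morph.ctype == STIN

    C = params.cm * area_cm2 * 1.0  # uF
    e_node, e_mysa, e_flut = _resting_reversals(params)

    gpas = np.zeros(n)
    Epas = np.full(n, params.v_rest)
    gpas[is_node] = params.gleak_node * area_cm2[is_node]
    Epas[is_node] = e_node
    gpas[is_mysa] = params.gpas_mysa * area_cm2[is_mysa]
    Epas[is_mysa] = e_mysa
    gpas[is_flut] = params.gpas_flut * area_cm2[is_flut]
    Epas[is_flut] = e_flut
    gpas[is_stin] = params.gpas_stin * area_cm2[is_stin]
    gpas *= 1e3  # S -> mS

    gnaf = np.zeros(n)
    gnap = np.zeros(n)
    gks = np.zeros(n)
    gnaf[is_node] = params.gnaf * area_cm2[is_node] * 1e3
    gnap[is_node] = params.gnap * area_cm2[is_node] * 1e3
    gks[is_node] = params.gks * area_cm2[is_node] * 1e3
    para = is_mysa | is_flut
    gks[para] = params.gks_para * area_cm2[para] * 1e3

    # myelin sheath: 2*nl membranes in series; nodes get a shorting sheath
    n_mem = 2.0 * morph.nl
    Gmy = params.g_myelin / n_mem * fiber_area_cm2 * 1e3
    Cmy = params.c_myelin / n_mem * fiber_area_cm2
    Gmy[is_node] = 1e4 * area_cm2[is_node] * 1e3  # ~short: Vp pinned to Ve
    Cmy[is_node] = 0.0

    # intracellular axial conductance (mS) between adjacent compartments
    r_half = (
        params.rho_axial * (L_cm / 2.0) / (np.pi * d_cm**2 / 4.0)
    )  # Ohm per half-compartment
    ga = 1.0 / (r_half[:-1] + r_half[1:]) * 1e3

    # periaxonal axial conductance through the thin annular space
    space_um = np.empty(n)
    space_um[is_node] = SPACE_NODE_UM
    space_um[is_mysa] = SPACE_MYSA_UM
    space_um[is_flut] = SPACE_FLUT_UM
    space_um[is_stin] = SPACE_STIN_UM
    w_cm = space_um * 1e-4
    a_peri = np.pi * ((d_cm / 2 + w_cm) ** 2 - (d_cm / 2) ** 2)
    rp_half = params.rho_axial * (L_cm / 2.0) / a_peri
    gperi = 1.0 / (rp_half[:-1] + rp_half[1:]) * 1e3

    q1, q2, q3 = params.q10
    return {
        "ctype": morph.ctype,
        "C": C,
        "Cmy": Cmy,
        "Gmy": Gmy,
        "gpas": gpas,
        "Epas": Epas,
        "gnaf": gnaf,
        "gnap": gnap,
        "gks": gks,
        "e_na": params.e_na,
        "e_k": params.e_k,
        "ga": ga,
        "gp": gperi,
        "v_rest": params.v_rest,
        "q10_1": q1,
        "q10_2": q2,
        "q10_3": q3,
    }


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def build_time_grid(
    pulse_onsets_ms: np.ndarray,
    pulse_width_ms: float,
    duration_ms: float,
    dt_fine_ms: float = 0.005,
    dt_mid_ms: float = 0.025,
    dt_coarse_ms: float = 0.1,
    fine_after_ms: float = 1.0,
    mid_after_ms: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise time grid graded around the stimulus pulses.

    Three tiers: fine steps during each pulse and for ``fine_after_ms``
    beyond it (spike initiation), mid steps until ``mid_after_ms`` past the
    onset (response window and repolarization), coarse steps through the
    inter-pulse relaxation.  Returns (times at step endpoints, per-step
    dt), with times[0] = 0.
    """
    times = [0.0]
    t = 0.0
    onsets = np.asarray(pulse_onsets_ms, dtype=float)
    while t < duration_ms - 1e-12:
        if np.any(
            (t >= onsets - dt_fine_ms) & (t < onsets + pulse_width_ms + fine_after_ms)
        ):
            dt = dt_fine_ms
        elif np.any((t >= onsets - dt_fine_ms) & (t < onsets + mid_after_ms)):
            dt = dt_mid_ms
        else:
            dt = dt_coarse_ms
        # do not step over an upcoming onset
        future = onsets[onsets > t + 1e-12]
        if future.size and t + dt > future[0]:
            dt = future[0] - t
        dt = min(dt, duration_ms - t)
        t += dt
        times.append(t)
    times = np.asarray(times)
    return times, np.diff(times)


def _pulse_wave(times: np.ndarray, onsets: np.ndarray, width_ms: float) -> np.ndarray:
    """Unit-amplitude rectangular train sampled at step endpoints."""
    w = np.zeros_like(times)
    for t0 in onsets:
        w[(times > t0 + 1e-12) & (times <= t0 + width_ms + 1e-12)] = 1.0
    return w


def simulate(
    morph: AxonMorphology,
    params: MembraneParams | None = None,
    ve_unit_V_per_mA: np.ndarray | None = None,
    protocol: StimProtocol | None = None,
    n_pulses: int | None = None,
    duration_ms: float | None = None,
    dt_fine_ms: float = 0.005,
    dt_mid_ms: float = 0.025,
    dt_coarse_ms: float = 0.1,
    iinj_nA: float = 0.0,
    iinj_comp: int = 0,
    iinj_window_ms: tuple[float, float] = (1.0, 1.1),
    system: dict | None = None,
) -> CableTrace:
    """Integrate the double-cable model and record nodal membrane potential.

    Extracellular drive: ``Ve(t) = sign * amplitude * ve_unit * pulse(t)``
    where ``ve_unit`` is the volume-conductor potential per +1 mA at each
    compartment.  An optional intracellular current step (``iinj_nA`` into
    compartment ``iinj_comp``) supports propagation tests.
    """
    if params is None:
        params = MembraneParams()
    if dt_fine_ms > 0.010 + 1e-12:
        raise ValueError("dt must be <= 10 us")
    if protocol is None:
        protocol = StimProtocol(amplitude_ma=1.0)
        amp = 0.0
    else:
        amp = protocol.amplitude_ma
    onsets = protocol.pulse_onsets_ms(n_pulses)
    if duration_ms is None:
        duration_ms = onsets[-1] + max(5.0, protocol.latency_window_ms[1] + 2.0)
    times, dts = build_time_grid(
        onsets,
        protocol.pulse_width_us * 1e-3,
        duration_ms,
        dt_fine_ms,
        dt_mid_ms,
        dt_coarse_ms,
    )
    wave = _pulse_wave(times, onsets, protocol.pulse_width_us * 1e-3)
    wave *= protocol.sign * amp

    n = morph.n_compartments
    if ve_unit_V_per_mA is None:
        ve_mV = np.zeros(n)
    else:
        ve_mV = np.asarray(ve_unit_V_per_mA, dtype=float) * 1000.0
        if ve_mV.shape != (n,):
            raise ValueError("ve_unit must have one value per compartment")

    iinj = np.zeros_like(times)
    if iinj_nA != 0.0:
        lo, hi = iinj_window_ms
        iinj[(times > lo) & (times <= hi)] = iinj_nA * 1e-3  # uA

    sys_ = system if system is not None else build_system(morph, params)
    record_idx = morph.node_indices.astype(np.int64)
    rec = run_cable(
        dts,
        wave,
        ve_mV,
        iinj,
        int(iinj_comp),
        sys_["ctype"],
        sys_["C"],
        sys_["Cmy"],
        sys_["Gmy"],
        sys_["gpas"],
        sys_["Epas"],
        sys_["gnaf"],
        sys_["gnap"],
        sys_["gks"],
        sys_["e_na"],
        sys_["e_k"],
        sys_["ga"],
        sys_["gp"],
        sys_["v_rest"],
        sys_["q10_1"],
        sys_["q10_2"],
        sys_["q10_3"],
        record_idx,
    )
    if rec.shape[0] != len(times):
        raise FloatingPointError(
            f"cable integration diverged at step {rec.shape[0]} "
            f"(t = {times[min(rec.shape[0], len(times) - 1)]:.4f} ms)"
        )
    return CableTrace(times_ms=times, vm_mV=rec, record_comp=record_idx, morphology=morph)


# ---------------------------------------------------------------------------
# Spike detection and the activation criterion
# ---------------------------------------------------------------------------


def detect_spikes(
    trace_mV: np.ndarray,
    times_ms: np.ndarray,
    threshold_mV: float = -20.0,
    refractory_ms: float = 1.0,
) -> np.ndarray:
    """Spike times: upward crossings of the threshold, merged within 1 ms."""
    v = np.asarray(trace_mV, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("trace contains non-finite values")
    up = np.nonzero((v[:-1] < threshold_mV) & (v[1:] >= threshold_mV))[0]
    if up.size == 0:
        return np.empty(0)
    # linear interpolation of the crossing time
    t0, t1 = times_ms[up], times_ms[up + 1]
    v0, v1 = v[up], v[up + 1]
    tc = t0 + (threshold_mV - v0) / (v1 - v0) * (t1 - t0)
    merged = [tc[0]]
    for t in tc[1:]:
        if t - merged[-1] >= refractory_ms:
            merged.append(t)
    return np.asarray(merged)


def is_activated(spike_times_ms: np.ndarray, protocol: StimProtocol) -> bool:
    """Pulse-train activation: latency-windowed response to >= 8 of 10 pulses."""
    spikes = np.asarray(spike_times_ms, dtype=float)
    lo, hi = protocol.latency_window_ms
    onsets = protocol.pulse_onsets_ms()
    responding = sum(
        bool(np.any((spikes >= t0 + lo) & (spikes <= t0 + hi))) for t0 in onsets
    )
    needed = protocol.min_responding
    if protocol.n_pulses != 10:
        needed = int(np.ceil(protocol.min_responding / 10.0 * protocol.n_pulses))
    return responding >= needed


def _recording_node(morph: AxonMorphology, ve_mV: np.ndarray | None) -> int:
    """Index (into the node list) >= 5 internodes from the stimulus focus."""
    nodes = morph.node_indices
    if ve_mV is None or not np.any(ve_mV):
        focus = len(nodes) // 2
    else:
        focus = int(np.argmax(np.abs(ve_mV[nodes])))
    cand = len(nodes) - 1 if focus < len(nodes) / 2 else 0
    if abs(cand - focus) < 5:
        raise ValueError("no node >= 5 internodes from the stimulus focus")
    return cand


def _single_pulse_response(
    morph, params, ve_unit, protocol, dt_fine_ms, system
) -> bool:
    trace = simulate(
        morph,
        params,
        ve_unit,
        protocol,
        n_pulses=1,
        dt_fine_ms=dt_fine_ms,
        system=system,
    )
    ve = None if ve_unit is None else np.asarray(ve_unit) * 1000.0
    j = _recording_node(morph, ve)
    spikes = detect_spikes(trace.vm_mV[:, j], trace.times_ms)
    lo, hi = protocol.latency_window_ms
    t0 = protocol.onset_ms
    return bool(np.any((spikes >= t0 + lo) & (spikes <= t0 + hi)))


def _train_response(
    morph, params, ve_unit, protocol, dt_fine_ms, system
) -> bool:
    trace = simulate(
        morph,
        params,
        ve_unit,
        protocol,
        dt_fine_ms=dt_fine_ms,
        system=system,
    )
    ve = None if ve_unit is None else np.asarray(ve_unit) * 1000.0
    j = _recording_node(morph, ve)
    spikes = detect_spikes(trace.vm_mV[:, j], trace.times_ms)
    return is_activated(spikes, protocol)


def find_threshold(
    morph: AxonMorphology,
    ve_unit_V_per_mA: np.ndarray,
    protocol: StimProtocol | None = None,
    amp_grid: np.ndarray | None = None,
    params: MembraneParams | None = None,
    refine_ma: float | None = None,
    mode: str = "fast",
    confirm_train: bool = True,
    dt_fine_ms: float = 0.005,
) -> float:
    """Lowest amplitude on the grid that activates the fiber (mA).

    Mirrors the behavioural ramp: amplitudes from 0.1 to 3.5 mA in 0.1 mA
    steps by default.  ``mode='fast'`` evaluates a single pulse per
    amplitude (the model is deterministic and pulses at 20 Hz are
    effectively independent) and, when ``confirm_train`` is set, verifies
    the full 8-of-10 train criterion at the found threshold and one step
    below, adjusting if they disagree.  ``mode='train'`` runs the full
    train at every probed amplitude.  Returns NaN if the fiber is not
    activated at the amplitude cap.  ``refine_ma`` bisects between the
    bracketing grid points down to the given amplitude resolution.
    """
    if protocol is None:
        protocol = StimProtocol()
    if amp_grid is None:
        amp_grid = np.round(np.arange(0.1, 3.5 + 1e-9, 0.1), 10)
    amp_grid = np.asarray(amp_grid, dtype=float)
    if amp_grid.ndim != 1 or np.any(np.diff(amp_grid) <= 0):
        raise ValueError("amplitude grid must be strictly ascending")
    if params is None:
        params = MembraneParams()
    system = build_system(morph, params)

    if mode == "fast":
        probe = lambda a: _single_pulse_response(  # noqa: E731
            morph, params, ve_unit_V_per_mA,
            replace(protocol, amplitude_ma=a),
            dt_fine_ms, system,
        )
    elif mode == "train":
        probe = lambda a: _train_response(  # noqa: E731
            morph, params, ve_unit_V_per_mA,
            replace(protocol, amplitude_ma=a),
            dt_fine_ms, system,
        )
    else:
        raise ValueError("mode must be 'fast' or 'train'")

    if not probe(amp_grid[-1]):
        # High-amplitude conduction block can hide a low activation window;
        # spot-check a low amplitude before declaring the fiber inactive.
        low_i = max(0, len(amp_grid) // 8)
        if not probe(amp_grid[low_i]):
            return NOT_ACTIVATED
        warnings.warn(
            "activation non-monotone (conduction block below the amplitude "
            "cap); scanning upward from the lowest grid point",
            stacklevel=2,
        )
        for i, a in enumerate(amp_grid):
            if probe(a):
                hi_i, lo_i = i, (i - 1 if i > 0 else None)
                break
        threshold = float(amp_grid[hi_i])
        if refine_ma is not None and lo_i is not None:
            lo_a, hi_a = float(amp_grid[lo_i]), threshold
            while hi_a - lo_a > refine_ma:
                mid = 0.5 * (lo_a + hi_a)
                if probe(mid):
                    hi_a = mid
                else:
                    lo_a = mid
            threshold = hi_a
        return threshold
    if probe(amp_grid[0]):
        lo_i, hi_i = None, 0
    else:
        lo_i, hi_i = 0, len(amp_grid) - 1
        while hi_i - lo_i > 1:
            mid = (lo_i + hi_i) // 2
            if probe(amp_grid[mid]):
                hi_i = mid
            else:
                lo_i = mid
        # spot-check the monotonicity assumption one step above the bracket
        if hi_i + 1 < len(amp_grid) and not probe(amp_grid[hi_i + 1]):
            warnings.warn(
                "non-monotone activation bracket; falling back to full scan",
                stacklevel=2,
            )
            for i, a in enumerate(amp_grid):
                if probe(a):
                    hi_i = i
                    lo_i = i - 1 if i > 0 else None
                    break

    threshold = float(amp_grid[hi_i])

    if mode == "fast" and confirm_train:
        train = lambda a: _train_response(  # noqa: E731
            morph, params, ve_unit_V_per_mA,
            replace(protocol, amplitude_ma=a),
            dt_fine_ms, system,
        )
        i = hi_i
        if not train(amp_grid[i]):
            while i + 1 < len(amp_grid) and not train(amp_grid[i + 1]):
                i += 1
            i += 1
            if i >= len(amp_grid):
                return NOT_ACTIVATED
        else:
            while i > 0 and train(amp_grid[i - 1]):
                i -= 1
        threshold = float(amp_grid[i])
        hi_i, lo_i = i, (i - 1 if i > 0 else None)

    if refine_ma is not None and lo_i is not None:
        lo_a, hi_a = float(amp_grid[lo_i]), threshold
        while hi_a - lo_a > refine_ma:
            mid = 0.5 * (lo_a + hi_a)
            if probe(mid):
                hi_a = mid
            else:
                lo_a = mid
        threshold = hi_a
    return threshold
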