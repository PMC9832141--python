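"""Passive multi-compartment cable simulator.

A desk-scale validator for generated ensembles: one compartment per SWC
section, leak + capacitance per membrane area, axial coupling along the
tree, two-state kinetic synaptic conductances, backward-Euler integration
with a direct sparse solve.  It reproduces the cable-theory properties a
passive dendrite must show — distance-dependent attenuation of somatic
PSPs, driving-force dependence of amplitude, superposition of subthreshold
responses — without requiring NEURON.  It makes no attempt at active
conductances or spikes.

Internal units follow NEURON's convention: mV, ms, nA, uS, nF; geometry in
um, specific properties in per-cm^2 units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .morphology import Compartment, Morphology, SegmentRef
from .codegen import EPSILON_LENGTH_UM, _geometries

__all__ = [
    "PassiveParams",
    "SynapticEvent",
    "CurrentStep",
    "CableSystem",
    "syn_conductance",
    "exp2_peak_time",
    "build_cable",
    "simulate",
]


@dataclass(frozen=True)
class PassiveParams:
    """Specific passive membrane properties.

    Defaults are conventional textbook values for a passive pyramidal-cell
    membrane; all are exposed, none is sacred.
    """

    cm: float = 1.0  # membrane capacitance, uF/cm^2
    rm: float = 20000.0  # specific membrane resistance, Ohm*cm^2
    ra: float = 150.0  # axial resistivity, Ohm*cm
    e_leak: float = -65.0  # leak reversal, mV
    v_rest: float = -65.0  # resting / initial potential, mV

    def __post_init__(self) -> None:
        if min(self.cm, self.rm, self.ra) <= 0:
            raise ValueError("cm, rm, ra must all be positive")


@dataclass(frozen=True)
class SynapticEvent:
    """One two-state kinetic synapse activation on a compartment."""

    compartment: int  # index into the cable system
    onset: float  # ms
    gmax: float  # peak conductance, uS
    tau1: float  # rise, ms
    tau2: float  # decay, ms
    reversal: float  # mV

    def __post_init__(self) -> None:
        if not (0 < self.tau1 < self.tau2):
            raise ValueError(f"need 0 < tau1 < tau2, got {self.tau1}, {self.tau2}")
        if self.gmax < 0:
            raise ValueError("gmax must be >= 0")


@dataclass(frozen=True)
class CurrentStep:
    compartment: int
    onset: float  # ms
    duration: float  # ms
    amplitude: float  # nA


def exp2_peak_time(tau1: float, tau2: float) -> float:
    """Time-to-peak of the difference of exponentials (ms after onset)."""
    return tau1 * tau2 / (tau2 - tau1) * math.log(tau2 / tau1)


def syn_conductance(e: SynapticEvent, t) -> np.ndarray | float:
    """Conductance (uS) of the event at time(s) t (ms).

    g(t) = gmax * f * (exp(-(t-onset)/tau2) - exp(-(t-onset)/tau1)) for
    t >= onset, 0 before; f normalizes the peak to gmax, so the drawn
    weight IS the peak conductance (matching NEURON's Exp2Syn convention).
    """
    tp = exp2_peak_time(e.tau1, e.tau2)
    f = 1.0 / (math.exp(-tp / e.tau2) - math.exp(-tp / e.tau1))
    tt = np.asarray(t, dtype=float) - e.onset
    g = np.where(
        tt >= 0,
        e.gmax * f * (np.exp(-np.clip(tt, 0, None) / e.tau2)
                      - np.exp(-np.clip(tt, 0, None) / e.tau1)),
        0.0,
    )
    return g if g.ndim else float(g)


@dataclass
class CableSystem:
    """Discretized passive cell: one compartment per SWC section."""

    n: int
    capacitance: np.ndarray  # nF per compartment
    g_leak: np.ndarray  # uS per compartment
    e_leak: float
    v_rest: float
    g_axial: sp.csc_matrix  # Laplacian of axial couplings, uS
    comp_of_id: dict[int, int]  # SWC point id -> compartment index
    lengths: np.ndarray = field(repr=False, default=None)  # um
    diameters: np.ndarray = field(repr=False, default=None)  # um

    def index_of(self, ref: SegmentRef, m: Morphology) -> int:
        pid = m.sections[Compartment(ref.compartment)][ref.index]
        return self.comp_of_id[pid]


def axial_resistance_megaohm(ra: float, length_um: float, diam_um: float) -> float:
    """Axial resistance r = 4*Ra*L/(pi*d^2) of a cylinder, in MOhm."""
    L_cm = length_um * 1e-4
    d_cm = diam_um * 1e-4
    return 4.0 * ra * L_cm / (math.pi * d_cm**2) * 1e-6


def build_cable(m: Morphology, p: PassiveParams, use_3d: bool = False) -> CableSystem:
    """One compartment per section; leak and capacitance from cylinder area,
    axial coupling to the parent from the child section's own geometry."""
    geoms = _geometries(m, use_3d)
    ids = [pt.id for pt in m.points if pt.compartment is not None]
    comp_of_id = {pid: i for i, pid in enumerate(ids)}
    n = len(ids)
    cap = np.zeros(n)
    g_leak = np.zeros(n)
    lengths = np.zeros(n)
    diams = np.zeros(n)
    rows, cols, vals = [], [], []
    for pid in ids:
        i = comp_of_id[pid]
        g = geoms[pid]
        L = max(g.length, EPSILON_LENGTH_UM)
        area_cm2 = math.pi * (g.diameter * 1e-4) * (L * 1e-4)
        cap[i] = p.cm * area_cm2 * 1e3  # uF -> nF
        g_leak[i] = area_cm2 / p.rm * 1e6  # S -> uS
        lengths[i] = L
        diams[i] = g.diameter
        pt = m.point(pid)
        if pt.parent_id != -1 and pt.parent_id in comp_of_id:
            j = comp_of_id[pt.parent_id]
            g_ax = 1.0 / axial_resistance_megaohm(p.ra, L, g.diameter)  # uS
            rows += [i, j, i, j]
            cols += [i, j, j, i]
            vals += [g_ax, g_ax, -g_ax, -g_ax]
    g_axial = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return CableSystem(
        n=n,
        capacitance=cap,
        g_leak=g_leak,
        e_leak=p.e_leak,
        v_rest=p.v_rest,
        g_axial=g_axial,
        comp_of_id=comp_of_id,
        lengths=lengths,
        diameters=diams,
    )


def simulate(
    system: CableSystem,
    events: list,
    dt: float,
    T: float,
):
    """Backward-Euler integration of the passive tree.

    Returns ``(times, V)`` with ``times`` of length round(T/dt)+1 and ``V``
    of shape (len(times), n) in mV.  ``events`` may mix
    :class:`SynapticEvent` and :class:`CurrentStep`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(T / dt))
    times = np.arange(n_steps + 1) * dt
    syn = [e for e in events if isinstance(e, SynapticEvent)]
    steps = [e for e in events if isinstance(e, CurrentStep)]
    # Precompute synaptic conductance waveforms at the implicit time points.
    g_syn = np.zeros((n_steps + 1, system.n))
    ge_syn = np.zeros((n_steps + 1, system.n))
    for ev in syn:
        g = syn_conductance(ev, times)
        g_syn[:, ev.compartment] += g
        ge_syn[:, ev.compartment] += g * ev.reversal
    i_inj = np.zeros((n_steps + 1, system.n))
    for ev in steps:
        mask = (times >= ev.onset) & (times < ev.onset + ev.duration)
        i_inj[mask, ev.compartment] += ev.amplitude
    c_dt = system.capacitance / dt  # nF/ms = uS
    base = (
        sp.diags(c_dt + system.g_leak) + system.g_axial
    ).tocsc()
    # Integrate the deviation u = V - e_leak so that the resting state is an
    # exact fixed point of the scheme, not just a numerical one.
    u = np.empty((n_steps + 1, system.n))
    u[0] = system.v_rest - system.e_leak
    any_syn = bool(syn)
    solve_base = spla.factorized(base)
    for k in range(1, n_steps + 1):
        rhs = c_dt * u[k - 1] + (ge_syn[k] - g_syn[k] * system.e_leak) + i_inj[k]
        if any_syn and g_syn[k].any():
            A = base + sp.diags(g_syn[k])
            u_new = spla.spsolve(A.tocsc(), rhs)
        else:
            u_new = solve_base(rhs)
        if not np.all(np.isfinite(u_new)):
            raise FloatingPointError(f"non-finite state at t = {k * dt} ms")
        u[k] = u_new
    return times, u + system.e_leak
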