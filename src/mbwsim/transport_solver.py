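"""Tracer transport on the airway network and its time integration.

Each airway unit is a well-mixed, time-varying volume (an RC-network
capacitor in the electrical picture).  Links carry two transport paths:

* diffusion — a Fick conductance ``1/R_D`` acting on the mole-fraction
  difference across the link, active in both directions at all times;
* convection — an explicit upwind flux switched by the breathing phase:
  during inspiration a unit receives ``Q_hat * chi_parent`` from its
  parent and loses ``Q_hat_child * chi_self`` to each child, during
  expiration the directions (and donor concentrations) reverse.

The inlet node prescribes the inhaled mole fraction (pure tracer during
inspiration, none during expiration) behind a practically infinite
series resistance, so the stepwise inlet concentration cannot produce
spurious diffusive jumps at the mouth.

The balance ``d(V*chi)/dt = in - out`` is integrated in the expanded form
``V dchi/dt = in - out - chi dV/dt`` with a fixed-step explicit scheme;
only alveolated units change volume (linearly within each half-breath).
The default integrator is Heun's method (explicit trapezoid): the fastest
compartments have RC time constants of ~20 ms, and second order is needed
for the mouth trace to be converged to ~1e-4 at practical step sizes.  A
plain explicit-Euler backend is available for cross-checks.  Steps always
land exactly on the rectangular-flow switch times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import reference
from .model_builder import (
    BreathingPattern,
    LungModel,
    alveolar_peak_flows,
    compute_flows,
    diffusive_resistances,
)

__all__ = [
    "Gas",
    "HE_N2",
    "TransportSystem",
    "SimulationResult",
    "assemble",
    "simulate",
    "export_netlist",
]

#: Bound tolerance: mole fractions outside [-EPS, 1+EPS] abort the run.
CHI_EPS = 1e-6


@dataclass(frozen=True)
class Gas:
    """Binary gas pair: tracer washed in against a resident carrier."""

    name: str
    D: float  # binary molecular diffusion coefficient, cm^2/s

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("diffusion coefficient must be positive")


#: Helium tracer in nitrogen carrier.
HE_N2 = Gas("He-N2", reference.D_HE_N2)


class TransportSystem:
    """RC-network form of a lung model for one gas and breathing pattern.

    Holds per-unit arrays (parent index, link conductance, peak link flow,
    peak alveolar flow, end-expiratory volume) plus the dense phase
    matrices of the linear right-hand side.
    """

    def __init__(
        self,
        parent: np.ndarray,
        g_link: np.ndarray,
        q_hat: np.ndarray,
        q_alv: np.ndarray,
        V_base: np.ndarray,
        pattern: BreathingPattern,
        gas: Gas,
        model: LungModel | None = None,
        labels: Sequence[str] | None = None,
    ):
        n = len(parent)
        if not (len(g_link) == len(q_hat) == len(q_alv) == len(V_base) == n):
            raise ValueError("array lengths disagree")
        if (V_base <= 0).any():
            raise ValueError("volumes must be positive")
        if (g_link < 0).any():
            raise ValueError("conductances must be non-negative")
        roots = (parent < 0).sum()
        if roots != 1:
            raise ValueError("exactly one unit must connect to the inlet")
        self.parent = parent.astype(int)
        self.g_link = g_link.astype(float)
        self.q_hat = q_hat.astype(float)
        self.q_alv = q_alv.astype(float)
        self.V_base = V_base.astype(float)
        self.pattern = pattern
        self.gas = gas
        self.model = model
        self.labels = list(labels) if labels is not None else [f"AU{i}" for i in range(n)]
        self.root = int(np.argmin(parent))
        self._build_matrices()

    @property
    def n(self) -> int:
        return len(self.parent)

    def _build_matrices(self) -> None:
        n = self.n
        Mi = np.zeros((n, n))
        Me = np.zeros((n, n))
        bi = np.zeros(n)
        for i in range(n):
            p = self.parent[i]
            g = self.g_link[i]
            q = self.q_hat[i]
            if p >= 0:
                for M in (Mi, Me):
                    M[i, i] -= g
                    M[i, p] += g
                    M[p, p] -= g
                    M[p, i] += g
                Mi[i, p] += q
                Mi[p, p] -= q
                Me[i, i] -= q
                Me[p, i] += q
            else:  # inlet boundary: chi_inlet = 1 (insp) / 0 (exp)
                Mi[i, i] -= g
                Me[i, i] -= g
                bi[i] = g * 1.0 + q * 1.0
                Me[i, i] -= q
        self._M_insp, self._M_exp, self._b_insp = Mi, Me, bi

    @classmethod
    def from_arrays(
        cls,
        parent: Sequence[int],
        g_link: Sequence[float],
        q_hat: Sequence[float],
        q_alv: Sequence[float],
        V_base: Sequence[float],
        pattern: BreathingPattern | None = None,
        gas: Gas = HE_N2,
    ) -> "TransportSystem":
        """Hand-built system, e.g. small closed sub-networks for analysis."""
        return cls(
            np.asarray(parent, dtype=int),
            np.asarray(g_link, dtype=float),
            np.asarray(q_hat, dtype=float),
            np.asarray(q_alv, dtype=float),
            np.asarray(V_base, dtype=float),
            pattern or BreathingPattern(),
            gas,
        )

    def min_time_constant(self) -> float:
        """Smallest finite RC time constant, min over tau_D and tau_c."""
        with np.errstate(divide="ignore"):
            tau_d = np.where(self.g_link > 0, self.V_base / np.maximum(self.g_link, 1e-300), np.inf)
            tau_c = np.where(self.q_hat > 0, self.V_base / np.maximum(self.q_hat, 1e-300), np.inf)
        return float(min(tau_d.min(), tau_c.min()))


def assemble(
    model: LungModel,
    gas: Gas = HE_N2,
    pattern: BreathingPattern | None = None,
) -> TransportSystem:
    """Wire a lung model into its transport system for one gas."""
    pattern = pattern or BreathingPattern()
    q_hat = compute_flows(model, pattern)
    r_d = diffusive_resistances(model, gas.D)
    for u in model.units:
        if u.parent >= 0 and u.index not in model.units[u.parent].children:
            raise ValueError(f"unit {u.label} is not wired to its parent")
    return TransportSystem(
        parent=model.parent,
        g_link=1.0 / r_d,
        q_hat=q_hat,
        q_alv=alveolar_peak_flows(model, q_hat),
        V_base=model.volumes,
        pattern=pattern,
        gas=gas,
        model=model,
        labels=[u.label for u in model.units],
    )


@dataclass
class SimulationResult:
    """Time-resolved tracer state of a washout run.

    ``chi_he_mouth`` is sampled every solver step at the first TU unit
    (the upwind donor during expiration, i.e. the gas that physically
    leaves the model).  Full-state snapshots are kept on a coarser grid;
    volumes are reconstructed analytically from the triangular-wave
    inflation profile rather than stored.
    """

    t_mouth: np.ndarray
    chi_he_mouth: np.ndarray
    t_snap: np.ndarray
    chi_he_snap: np.ndarray  # (n_snap, n_units)
    system: TransportSystem
    dt: float
    scheme: str
    mass_residuals: np.ndarray  # per breath, relative

    @property
    def pattern(self) -> BreathingPattern:
        return self.system.pattern

    @property
    def chi_n2_mouth(self) -> np.ndarray:
        return 1.0 - self.chi_he_mouth

    def inflation(self, t: np.ndarray | float) -> np.ndarray:
        """Triangular inflation profile w(t): 0 at breath start, T/2 at peak."""
        tm = np.mod(np.asarray(t, dtype=float), self.pattern.T)
        return np.where(tm < self.pattern.T / 2, tm, self.pattern.T - tm)

    def volumes_at(self, t: float) -> np.ndarray:
        """Per-unit volumes at time t (cm^3)."""
        return self.system.V_base + self.system.q_alv * self.inflation(t)

    def chi_at(self, t: float) -> np.ndarray:
        """Full mole-fraction state at time t, linearly interpolated."""
        if t < self.t_snap[0] or t > self.t_snap[-1]:
            raise ValueError(f"t={t} outside snapshot range")
        k = int(np.searchsorted(self.t_snap, t, side="right")) - 1
        k = min(k, len(self.t_snap) - 2)
        w = (t - self.t_snap[k]) / (self.t_snap[k + 1] - self.t_snap[k])
        return (1 - w) * self.chi_he_snap[k] + w * self.chi_he_snap[k + 1]

    def n_breaths(self) -> int:
        return int(np.floor((self.t_mouth[-1] + 1e-12) / self.pattern.T))

    # -- writers ----------------------------------------------------------
    def mouth_trace_to_csv(self, path: str | Path, every: int = 1) -> None:
        t = self.t_mouth[::every]
        he = self.chi_he_mouth[::every]
        phase = np.where(np.mod(t, self.pattern.T) < self.pattern.T / 2, "insp", "exp")
        pd.DataFrame(
            {"time_s": t, "chi_he": he, "chi_n2": 1 - he, "flow_direction": phase}
        ).to_csv(path, index=False)

    def state_to_csv(self, path: str | Path, every: int = 1) -> None:
        """Long-format state table (time, au, chi_he, volume)."""
        frames = []
        for k in range(0, len(self.t_snap), every):
            t = self.t_snap[k]
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": t,
                        "au": self.system.labels,
                        "chi_he": self.chi_he_snap[k],
                        "volume_cm3": self.volumes_at(t),
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


class InstabilityError(RuntimeError):
    """Raised when a mole fraction leaves [0, 1] beyond tolerance."""


def simulate(
    system: TransportSystem,
    duration: float | None = None,
    dt: float = 5e-4,
    snapshot_interval: float = 0.02,
    chi0: np.ndarray | None = None,
    scheme: str = "heun",
    check_every: int = 50,
) -> SimulationResult:
    """Integrate the washout over ``duration`` seconds of breathing.

    The initial state is resident carrier everywhere (``chi = 0``) unless
    ``chi0`` is given.  ``dt`` must divide the half-period so phase
    switches land exactly on step boundaries, and must satisfy the RC
    stability bound ``dt < 0.5 * min(tau)``.  ``scheme`` is ``"heun"``
    (default, second order) or ``"euler"``.  The run aborts with
    :class:`InstabilityError` if any mole fraction leaves ``[0, 1]`` by
    more than ``1e-6`` (the state is never clamped: clamping would
    silently destroy tracer mass).
    """
    pattern = system.pattern
    if duration is None:
        duration = pattern.duration
    if scheme not in ("heun", "euler"):
        raise ValueError(f"unknown scheme {scheme!r}")
    heun = scheme == "heun"
    half = pattern.T / 2.0
    steps_half = round(half / dt)
    if abs(steps_half * dt - half) > 1e-9 * half or steps_half < 1:
        raise ValueError(f"dt={dt} must divide the half-period {half}")
    tau_min = system.min_time_constant()
    if np.isfinite(tau_min) and dt >= 0.5 * tau_min:
        raise ValueError(
            f"dt={dt} violates the stability bound 0.5*min(tau)={0.5 * tau_min:.3e}"
        )
    n_steps = round(duration / dt)
    snap_every = max(1, round(snapshot_interval / dt))

    n = system.n
    chi = np.zeros(n) if chi0 is None else np.asarray(chi0, dtype=float).copy()
    V = system.V_base.copy()
    q_alv = system.q_alv
    root = system.root
    g_root = system.g_link[root]
    q_root = system.q_hat[root]

    mouth = np.empty(n_steps)
    n_snaps = n_steps // snap_every + 1
    snaps = np.empty((n_snaps, n))
    t_snap = np.empty(n_snaps)
    snaps[0] = chi
    t_snap[0] = 0.0

    tracer0 = float(V @ chi)
    boundary = 0.0  # net tracer volume received through the inlet
    residuals = []
    lo, hi = -CHI_EPS, 1.0 + CHI_EPS

    def inlet_flux(c_root: float, inspiring: bool) -> float:
        if inspiring:
            return q_root * 1.0 + g_root * (1.0 - c_root)
        return -(q_root + g_root) * c_root

    k = 0
    isnap = 1
    while k < n_steps:
        phase = (k // steps_half) % 2  # 0 inspiration, 1 expiration
        if phase == 0:
            M, b, sg = system._M_insp, system._b_insp, 1.0
        else:
            M, b, sg = system._M_exp, 0.0, -1.0
        V_start = V.copy()
        block = min(steps_half, n_steps - k)
        for s in range(block):
            V1 = V_start + sg * q_alv * ((s + 1) * dt)
            f0 = (M @ chi + b - chi * (sg * q_alv)) / V
            if heun:
                pred = chi + dt * f0
                f1 = (M @ pred + b - pred * (sg * q_alv)) / V1
                boundary += 0.5 * dt * (
                    inlet_flux(chi[root], phase == 0)
                    + inlet_flux(pred[root], phase == 0)
                )
                chi = chi + 0.5 * dt * (f0 + f1)
            else:
                boundary += dt * inlet_flux(chi[root], phase == 0)
                chi = chi + dt * f0
            V = V1
            mouth[k] = chi[root]
            k += 1
            if k % snap_every == 0:
                snaps[isnap] = chi
                t_snap[isnap] = k * dt
                isnap += 1
            if k % check_every == 0 or s == block - 1:
                cmin, cmax = chi.min(), chi.max()
                if cmin < lo or cmax > hi:
                    raise InstabilityError(
                        f"chi left [0,1] at t={k * dt:.4f}s "
                        f"(min={cmin:.3e}, max={cmax:.3e}); reduce dt"
                    )
        if phase == 1 and k % (2 * steps_half) == 0:
            tracer = float(V @ chi)
            expected = tracer0 + boundary
            scale = max(abs(tracer), abs(boundary), 1e-12)
            residuals.append((tracer - expected) / scale)

    return SimulationResult(
        t_mouth=(np.arange(n_steps) + 1) * dt,
        chi_he_mouth=mouth,
        t_snap=t_snap[:isnap],
        chi_he_snap=snaps[:isnap],
        system=system,
        dt=dt,
        scheme=scheme,
        mass_residuals=np.array(residuals),
    )


def export_netlist(system: TransportSystem, title: str = "mbwsim lung model") -> str:
    """Emit a SPICE-dialect netlist of the RC network.

    One capacitor per unit (value: end-expiratory volume), one resistor
    per diffusive link (the inlet link carries the blocking value), and
    five switched voltage-controlled current sources per unit — three for
    the incoming convective flows (from the parent during inspiration,
    from each child during expiration) and two for the outgoing ones.
    Node names carry the unit labels; ``PHI`` is the breathing-phase
    control node (1 during inspiration, 0 during expiration).
    """
    lines = [f"* {title}", f"* gas {system.gas.name}, D={system.gas.D} cm2/s"]
    lines.append("* node INLET driven 1 (inspiration) / 0 (expiration); PHI phase control")
    lines.append("VIN INLET 0 PULSE(1 0 {half} 0 0 {half} {T})".format(
        half=system.pattern.T / 2, T=system.pattern.T))
    for i, lab in enumerate(system.labels):
        lines.append(f"C_{lab} {lab} 0 {system.V_base[i]:.6g}")
    for i, lab in enumerate(system.labels):
        p = system.parent[i]
        pname = system.labels[p] if p >= 0 else "INLET"
        if system.g_link[i] > 0:
            lines.append(f"R_{lab} {pname} {lab} {1.0 / system.g_link[i]:.6g}")
        q = system.q_hat[i]
        # Four switched sources per link; summed per unit this realises the
        # three incoming and two outgoing convective terms of a bifurcation
        # (parent inflow + two child backflows in; parent-ward + child-ward
        # outflows out).  Capacitors are understood as time-varying with the
        # alveolar inflation.
        lines.append(f"GIN_{lab} 0 {lab} VALUE={{V(PHI)*{q:.6g}*V({pname})}}")
        lines.append(f"GFW_{lab} {pname} 0 VALUE={{V(PHI)*{q:.6g}*V({pname})}}")
        lines.append(f"GBK_{lab} 0 {pname} VALUE={{(1-V(PHI))*{q:.6g}*V({lab})}}")
        lines.append(f"GOUT_{lab} {lab} 0 VALUE={{(1-V(PHI))*{q:.6g}*V({lab})}}")
    lines.append(".end")
    return "\n".join(lines) + "\n"
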