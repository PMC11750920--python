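"""Construction of the 251-unit airway network and its derived quantities.

The network has two parts.  The trachea unit (TU) lumps generations 0-3
into a straight tube discretised into 10 identical serial airway units
(AUs); fewer units produce visible numerical smearing of the expirogram
front.  The segment unit (SU) covers generations 4-23, organised into 6
areas; area ``a`` holds ``2**a`` parallel elements, each a serial chain of
AUs, and each SU AU lumps all ``2**(z-a)`` anatomically identical Weibel
airways of its generation within one element.

Asymmetry is introduced by volume factors attached to the elements of one
area and inherited down the subtree: volumes, alveoli and (peak) flows
scale by the accumulated factor ``f_tot``, lengths and diameters by
``f_tot**(1/3)``, cross-sections by ``f_tot**(2/3)``.  Sibling factors sum
to 2, so the total lung volume is invariant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import reference
from .morphometry import WeibelTable, alveolar_diameter, alveolar_volume, scale_to_volume, weibel_table

__all__ = [
    "AreaLayout",
    "AirwayUnit",
    "AsymmetrySpec",
    "BreathingPattern",
    "LungModel",
    "LUPartition",
    "build_symmetric",
    "apply_asymmetry",
    "compute_flows",
    "diffusive_resistances",
    "peclet",
    "transition_generation",
    "time_constants",
    "partition_lung_units",
    "default_model",
    "reference_report",
]


@dataclass(frozen=True)
class AreaLayout:
    """AUs per element for each SU area; area ``a`` has ``2**a`` elements."""

    m_au: tuple[int, ...] = reference.M_AU
    n_tu_units: int = reference.N_TU_UNITS

    def __post_init__(self) -> None:
        if len(self.m_au) != 6 or any(m < 1 for m in self.m_au):
            raise ValueError("layout needs 6 areas with >= 1 AU each")
        if sum(self.m_au) != 20:
            raise ValueError("areas must cover the 20 SU generations (z = 4..23)")

    @property
    def n_areas(self) -> int:
        return len(self.m_au)

    def phi(self, a: int, z_prime: int) -> int:
        """Global airway generation of AU position ``z'`` within area ``a``."""
        if not 0 <= a < self.n_areas or not 0 <= z_prime < self.m_au[a]:
            raise ValueError(f"no AU at (a={a}, z'={z_prime})")
        return z_prime + 4 + sum(self.m_au[:a])

    @property
    def n_units(self) -> int:
        return self.n_tu_units + sum(2**a * m for a, m in enumerate(self.m_au))


@dataclass
class AirwayUnit:
    """One well-mixed compartment of the network.

    Geometric values are per element (SU) or per serial slice (TU);
    ``R_D_parent`` and ``Q_hat_in`` are filled by
    :func:`diffusive_resistances` and :func:`compute_flows`.
    """

    index: int
    label: str
    a: int | None  # None for TU units
    e: int | None
    z_prime: int | None
    z: int | None  # global generation; None for TU units (they lump 0-3)
    l: float  # cm
    A: float  # cm^2, aggregate per element
    V_airway: float  # cm^3
    V_alv: float  # cm^3 at end expiration
    m_alv: float  # alveoli represented
    f_tot: float  # product of inherited asymmetry factors
    x: float  # cumulative axial position, cm
    parent: int  # index; -1 for the mouth-side root
    children: list[int] = field(default_factory=list)
    R_D_parent: float | None = None  # s/cm^3
    Q_hat_in: float | None = None  # cm^3/s

    @property
    def V_base(self) -> float:
        """End-expiratory volume (cm^3)."""
        return self.V_airway + self.V_alv

    @property
    def d(self) -> float:
        """Effective per-element diameter (cm), from the aggregate section."""
        return math.sqrt(4.0 * self.A / math.pi)

    @property
    def is_tu(self) -> bool:
        return self.a is None


@dataclass(frozen=True)
class AsymmetrySpec:
    """Even/odd volume factors applied to the elements of one area.

    Even elements of ``area`` get ``f_c``, odd elements ``2 - f_c``; the
    factors are inherited by every daughter area, all other factors are 1.
    """

    area: int
    f_c: float

    def __post_init__(self) -> None:
        if not 1 <= self.area <= 5:
            raise ValueError("asymmetry area must be in 1..5")
        if not 0.0 < self.f_c < 2.0:
            raise ValueError("f_c must lie strictly inside (0, 2)")

    def factor(self, a: int, e: int) -> float:
        if a != self.area:
            return 1.0
        return self.f_c if e % 2 == 0 else 2.0 - self.f_c

    def f_tot(self, a: int, e: int) -> float:
        """Accumulated factor of element (a, e): own times all ancestors'."""
        out = 1.0
        for i in range(a + 1):
            out *= self.factor(a - i, e >> i)
        return out


@dataclass(frozen=True)
class BreathingPattern:
    """Rectangular breathing: first half-period inspiration, then expiration."""

    T: float = reference.BREATH_PERIOD_S  # s
    Q_hat_TU: float = reference.Q_HAT_TU  # cm^3/s
    duration: float = 200.0  # s

    def __post_init__(self) -> None:
        if self.T <= 0 or self.Q_hat_TU < 0 or self.duration <= 0:
            raise ValueError("pattern parameters must be positive")

    @property
    def tidal_volume(self) -> float:
        """Inhaled volume per breath (cm^3); 500 ml at the defaults."""
        return self.Q_hat_TU * self.T / 2.0


class LungModel:
    """The wired network of airway units plus its construction metadata."""

    def __init__(
        self,
        units: Sequence[AirwayUnit],
        layout: AreaLayout,
        d_alv: float,
        s: float,
        asymmetry: AsymmetrySpec | None = None,
    ):
        self.units = list(units)
        self.layout = layout
        self.d_alv = d_alv
        self.s = s
        self.asymmetry = asymmetry
        self._index = {
            (u.a, u.e, u.z_prime): u.index for u in self.units if not u.is_tu
        }

    def __len__(self) -> int:
        return len(self.units)

    def su_unit(self, a: int, e: int, z_prime: int) -> AirwayUnit:
        return self.units[self._index[(a, e, z_prime)]]

    # -- vector views ------------------------------------------------------
    def _vec(self, attr: str) -> np.ndarray:
        return np.array([getattr(u, attr) for u in self.units], dtype=float)

    @property
    def parent(self) -> np.ndarray:
        return np.array([u.parent for u in self.units], dtype=int)

    @property
    def lengths(self) -> np.ndarray:
        return self._vec("l")

    @property
    def areas(self) -> np.ndarray:
        return self._vec("A")

    @property
    def volumes(self) -> np.ndarray:
        return self._vec("V_base")

    @property
    def alveoli(self) -> np.ndarray:
        return self._vec("m_alv")

    @property
    def f_tot(self) -> np.ndarray:
        return self._vec("f_tot")

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())

    @property
    def dead_space_volume(self) -> float:
        """Volume of all non-alveolated units (TU plus SU areas 0-3)."""
        return float(sum(u.V_base for u in self.units if u.m_alv == 0))

    def to_json(self, path: str | Path) -> None:
        records = []
        for u in self.units:
            records.append(
                {
                    "index": u.index,
                    "label": u.label,
                    "a": u.a,
                    "e": u.e,
                    "z_prime": u.z_prime,
                    "z": u.z,
                    "l_cm": u.l,
                    "A_cm2": u.A,
                    "V_base_cm3": u.V_base,
                    "m_alv": u.m_alv,
                    "f_tot": u.f_tot,
                    "x_cm": u.x,
                    "parent": u.parent,
                    "children": u.children,
                    "R_D_parent_s_cm3": u.R_D_parent,
                    "Q_hat_in_cm3_s": u.Q_hat_in,
                }
            )
        meta = {
            "n_units": len(self.units),
            "d_alv_cm": self.d_alv,
            "scaling_factor": self.s,
            "asymmetry": None
            if self.asymmetry is None
            else {"area": self.asymmetry.area, "f_c": self.asymmetry.f_c},
        }
        Path(path).write_text(json.dumps({"meta": meta, "units": records}, indent=1))


@dataclass(frozen=True)
class LUPartition:
    """Lung-unit partition used for the inter-unit concentration analysis.

    LU0 is the shared region above the asymmetry area (TU plus all areas
    ``< a*``); LU1/LU2 are the subtrees rooted at the even/odd elements of
    the asymmetry area.
    """

    area: int
    labels: np.ndarray  # 0, 1 or 2 per AU
    V_LU0: float  # cm^3
    dt_LU0: float  # s


# ---------------------------------------------------------------------------
# construction


def build_symmetric(
    scaled: WeibelTable,
    layout: AreaLayout | None = None,
    d_alv: float | None = None,
) -> LungModel:
    """Build the symmetric network from an already-scaled generation table.

    TU units take one tenth of the aggregate generation 0-3 volume and path
    length; each SU AU aggregates the ``2**(z-a)`` airways of its
    generation that belong to one element.  Alveolar volumes use spheres of
    diameter ``d_alv`` (defaults to the 3000-ml value).
    """
    layout = layout or AreaLayout()
    if d_alv is None:
        d_alv = alveolar_diameter(reference.LUNG_VOLUME_ML)
    have = set(scaled.z.tolist())
    if not set(range(24)) <= have:
        raise ValueError("scaled table must cover generations 0..23")

    v_alv_sphere = alveolar_volume(d_alv)
    g = {int(gen.z): gen for gen in scaled}

    tu_volume = sum(2**z * math.pi / 4.0 * g[z].d_cm**2 * g[z].l_cm for z in range(4))
    tu_path = sum(g[z].l_cm for z in range(4))
    n_tu = layout.n_tu_units
    l_tu = tu_path / n_tu
    v_tu = tu_volume / n_tu
    a_tu = v_tu / l_tu

    units: list[AirwayUnit] = []
    for i in range(n_tu):
        units.append(
            AirwayUnit(
                index=i,
                label=f"TU-{i}",
                a=None,
                e=None,
                z_prime=None,
                z=None,
                l=l_tu,
                A=a_tu,
                V_airway=v_tu,
                V_alv=0.0,
                m_alv=0.0,
                f_tot=1.0,
                x=i * l_tu,
                parent=i - 1,
            )
        )

    index: dict[tuple[int, int, int], int] = {}
    for a in range(layout.n_areas):
        for e in range(2**a):
            for zp in range(layout.m_au[a]):
                z = layout.phi(a, zp)
                gen = g[z]
                n_air = 2.0 ** (z - a)
                area = n_air * math.pi / 4.0 * gen.d_cm**2
                v_air = area * gen.l_cm
                m_alv = n_air * gen.m_alv_air
                if zp > 0:
                    parent = index[(a, e, zp - 1)]
                elif a == 0:
                    parent = n_tu - 1
                else:
                    parent = index[(a - 1, e // 2, layout.m_au[a - 1] - 1)]
                idx = len(units)
                index[(a, e, zp)] = idx
                pu = units[parent]
                units.append(
                    AirwayUnit(
                        index=idx,
                        label=f"SU-({a},{e},{zp})",
                        a=a,
                        e=e,
                        z_prime=zp,
                        z=z,
                        l=gen.l_cm,
                        A=area,
                        V_airway=v_air,
                        V_alv=m_alv * v_alv_sphere,
                        m_alv=m_alv,
                        f_tot=1.0,
                        x=pu.x + 0.5 * (pu.l + gen.l_cm),
                        parent=parent,
                    )
                )

    for u in units:
        if u.parent >= 0:
            units[u.parent].children.append(u.index)
    return LungModel(units, layout, d_alv=d_alv, s=reference.SCALING_FACTOR)


def apply_asymmetry(model: LungModel, spec: AsymmetrySpec) -> LungModel:
    """Return a new model with inherited volume factors applied.

    Volumes, alveoli (and therefore peak flows) scale by ``f_tot``;
    lengths by ``f_tot**(1/3)`` and cross-sections by ``f_tot**(2/3)``, so
    ``V = A*l`` stays consistent.  The total volume is preserved exactly
    because sibling factors sum to 2.
    """
    units = []
    for u in model.units:
        if u.is_tu or u.a < spec.area:
            units.append(replace(u, children=list(u.children), R_D_parent=None, Q_hat_in=None))
            continue
        f = spec.f_tot(u.a, u.e)
        c = f ** (1.0 / 3.0)
        units.append(
            replace(
                u,
                l=u.l * c,
                A=u.A * c**2,
                V_airway=u.V_airway * f,
                V_alv=u.V_alv * f,
                m_alv=u.m_alv * f,
                f_tot=f,
                children=list(u.children),
                R_D_parent=None,
                Q_hat_in=None,
            )
        )
    # x positions follow the stretched lengths
    for u in units:
        if u.parent >= 0:
            u.x = units[u.parent].x + 0.5 * (units[u.parent].l + u.l)
    return LungModel(units, model.layout, model.d_alv, model.s, asymmetry=spec)


# ---------------------------------------------------------------------------
# derived per-unit quantities


def compute_flows(model: LungModel, pattern: BreathingPattern) -> np.ndarray:
    """Peak convective inflow magnitude of every AU (cm^3/s).

    The tracheal flow is generated entirely by alveolar volume change, with
    every alveolus contributing the same flow; hence the inflow of an AU is
    the sum of the alveolar peak flows of its own and all downstream AUs.
    Results are stored on the units and returned indexed by AU.
    """
    m_alv = model.alveoli
    total = m_alv.sum()
    if total <= 0:
        raise ValueError("model has no alveoli; flows are undefined")
    q_alv = pattern.Q_hat_TU / total
    parent = model.parent
    q_hat = m_alv * q_alv
    for i in range(len(q_hat) - 1, 0, -1):
        q_hat[parent[i]] += q_hat[i]
    for u, q in zip(model.units, q_hat):
        u.Q_hat_in = float(q)
    return q_hat


def alveolar_peak_flows(model: LungModel, flows: np.ndarray) -> np.ndarray:
    """Peak alveolar flow of each AU: own inflow minus children's inflows."""
    q_alv = flows.copy()
    parent = model.parent
    for i in range(len(flows) - 1, 0, -1):
        q_alv[parent[i]] -= flows[i]
    return np.maximum(q_alv, 0.0)


def _parent_halfspan(model: LungModel) -> np.ndarray:
    """Link length 0.5*(l_N + l_M) per AU; l_M := l_N at the mouth root."""
    l = model.lengths
    parent = model.parent
    l_par = np.where(parent >= 0, l[np.maximum(parent, 0)], l)
    return 0.5 * (l + l_par)


def diffusive_resistances(model: LungModel, D: float = reference.D_HE_N2) -> np.ndarray:
    """Diffusional resistance of every AU's parent link (s/cm^3).

    ``R_D = 0.5*(l_N + l_M) / (D * A_N)`` with the child's own per-element
    cross-section; the model-inlet link of the first TU unit is overridden
    with the blocking value so the stepwise inlet concentration cannot leak
    in by diffusion.
    """
    if D <= 0:
        raise ValueError("diffusion coefficient must be positive")
    r = _parent_halfspan(model) / (D * model.areas)
    r[0] = reference.BLOCKING_RESISTANCE
    for u, v in zip(model.units, r):
        u.R_D_parent = float(v)
    return r


def peclet(model: LungModel, flows: np.ndarray, D: float = reference.D_HE_N2) -> np.ndarray:
    """Entrance Peclet number per AU: peak inflow times link length over D*A."""
    return flows * _parent_halfspan(model) / (D * model.areas)


def transition_generation(model: LungModel, pe: np.ndarray) -> int | None:
    """First generation along the root-to-tip path with entrance Pe < 1.

    Marks the convection-to-diffusion transition; returns ``None`` when Pe
    never drops below 1 (pure-convection limit).
    """
    for u in model.units:
        if not u.is_tu and u.e == 0 and pe[u.index] < 1.0:
            return u.z
    return None


def time_constants(
    model: LungModel, flows: np.ndarray, D: float = reference.D_HE_N2
) -> tuple[np.ndarray, np.ndarray]:
    """Diffusive and convective RC time constants per AU (at end expiration).

    ``tau_D = R_D * V`` and ``tau_c = V / Q``; units with zero flow get
    ``tau_c = inf``.  Under asymmetry ``tau_c`` is invariant (volume and
    flow are factorised identically) while ``tau_D`` picks up a factor
    ``f_tot**(2/3)`` plus a mixed-length correction across factor
    boundaries.
    """
    r_d = diffusive_resistances(model, D)
    v = model.volumes
    with np.errstate(divide="ignore"):
        tau_c = np.where(flows > 0, v / np.where(flows > 0, flows, 1.0), np.inf)
    return r_d * v, tau_c


def partition_lung_units(
    model: LungModel, area: int, pattern: BreathingPattern | None = None
) -> LUPartition:
    """Label every AU as LU0 (shared), LU1 (even subtrees) or LU2 (odd)."""
    if not 1 <= area <= 5:
        raise ValueError("partition area must be in 1..5")
    pattern = pattern or BreathingPattern()
    labels = np.zeros(len(model.units), dtype=int)
    for u in model.units:
        if u.is_tu or u.a < area:
            continue
        ancestor = u.e >> (u.a - area)
        labels[u.index] = 1 if ancestor % 2 == 0 else 2
    v_lu0 = float(model.volumes[labels == 0].sum())
    return LUPartition(area, labels, v_lu0, v_lu0 / pattern.Q_hat_TU)


# ---------------------------------------------------------------------------
# convenience pipeline and regression report


def default_model(
    asymmetry: AsymmetrySpec | None = None,
    pattern: BreathingPattern | None = None,
    D: float = reference.D_HE_N2,
) -> LungModel:
    """Scaled 3000-ml model with flows and resistances filled in."""
    pattern = pattern or BreathingPattern()
    result, scaled = scale_to_volume(weibel_table())
    model = build_symmetric(scaled, d_alv=result.d_alv)
    if asymmetry is not None:
        model = apply_asymmetry(model, asymmetry)
    compute_flows(model, pattern)
    diffusive_resistances(model, D)
    return model


def reference_report(
    model: LungModel | None = None,
    D: float = reference.D_HE_N2,
    pattern: BreathingPattern | None = None,
) -> pd.DataFrame:
    """Recompute the published per-element table and compare row by row.

    Returns one row per TU/SU generation with computed and printed ``l``,
    ``x``, ``A``, ``Qhat``, ``Pe`` and ``R_D`` plus a pass flag.  The
    tolerance is 1 % relative or half the printed decimal resolution,
    whichever is larger (printed values carry only 3-4 significant digits).
    """
    pattern = pattern or BreathingPattern()
    if model is None:
        model = default_model(pattern=pattern, D=D)
    flows = np.array([u.Q_hat_in for u in model.units])
    pe = peclet(model, flows, D)
    r_d = diffusive_resistances(model, D)

    def ok(computed: float, printed: float, resolution: float) -> bool:
        return abs(computed - printed) <= max(0.01 * abs(printed), 0.5 * resolution)

    rows = []
    tu = model.units[1]  # interior TU unit (index 0 carries the blocking link)
    rows.append(
        {
            "label": "TU",
            "z": "0-3",
            "l_cm": tu.l,
            "x_cm": model.units[0].x,
            "A_cm2": tu.A,
            "qhat_cm3_s": tu.Q_hat_in,
            "peclet": pe[tu.index],
            "R_D_s_cm3": r_d[tu.index],
            "peclet_printed": reference.TU_PECLET,
            "R_D_printed": reference.TU_R_D,
            "peclet_ok": ok(pe[tu.index], reference.TU_PECLET, 1e-3),
            "R_D_ok": ok(r_d[tu.index], reference.TU_R_D, 1e-2),
        }
    )
    for ref in reference.SU_ROWS:
        zp = ref.z - 4 - sum(model.layout.m_au[: ref.area])
        u = model.su_unit(ref.area, 0, zp)
        i = u.index
        pe_res = 1e-3  # Pe column printed with 3 decimals
        rd_res = 10.0 ** (math.floor(math.log10(ref.R_D_s_cm3)) - 2)  # 3 sig. digits
        rows.append(
            {
                "label": u.label,
                "z": ref.z,
                "l_cm": u.l,
                "x_cm": u.x,
                "A_cm2": u.A,
                "qhat_cm3_s": u.Q_hat_in,
                "peclet": pe[i],
                "R_D_s_cm3": r_d[i],
                "peclet_printed": ref.peclet,
                "R_D_printed": ref.R_D_s_cm3,
                "peclet_ok": ok(pe[i], ref.peclet, 1e-3),
                "R_D_ok": ok(r_d[i], ref.R_D_s_cm3, rd_res),
            }
        )
    return pd.DataFrame(rows)
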