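"""Weibel generation table and volume scaling to the resting lung.

The raw table refers to Weibel's 4800-ml reference lung.  Mapping it to the
3000-ml respiratory resting position proceeds in three steps: (1) evaluate
the mean alveolar diameter at the target volume, (2) compute the unscaled
model volume (cylindrical airways plus spherical alveoli) and its excess
over the target, (3) shrink diameters and lengths of generations 4-23 by a
single linear factor ``s`` chosen so the excess vanishes.  Generations 0-3
(trachea to segment bronchi) are deliberately left untouched so that
segment-level heterogeneity studies keep a fixed proximal geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference

__all__ = [
    "WeibelGeneration",
    "WeibelTable",
    "ScalingResult",
    "weibel_table",
    "alveolar_diameter",
    "alveolar_volume",
    "unscaled_total_volume",
    "scaling_factor",
    "scaled_table",
    "scale_to_volume",
]

_COLUMNS = ["z", "d_cm", "l_cm", "m_alv_air"]


@dataclass(frozen=True)
class WeibelGeneration:
    """One airway generation: 2**z anatomically identical airways."""

    z: int
    d_cm: float
    l_cm: float
    m_alv_air: float  # alveoli per airway; 0 in the conducting zone

    def __post_init__(self) -> None:
        if self.d_cm <= 0 or self.l_cm <= 0:
            raise ValueError(f"generation {self.z}: d and l must be positive")
        if self.m_alv_air < 0:
            raise ValueError(f"generation {self.z}: m_alv_air must be >= 0")


class WeibelTable:
    """Per-generation morphometry for generations 0-23.

    Thin wrapper around a :class:`pandas.DataFrame` with columns
    ``z, d_cm, l_cm, m_alv_air``; rows are unique and sorted by ``z``.
    """

    def __init__(self, df: pd.DataFrame):
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        df = df[_COLUMNS].sort_values("z").reset_index(drop=True)
        if df["z"].duplicated().any():
            raise ValueError("duplicate generation indices")
        if (df["d_cm"] <= 0).any() or (df["l_cm"] <= 0).any():
            raise ValueError("diameters and lengths must be positive")
        if (df["m_alv_air"] < 0).any():
            raise ValueError("alveoli counts must be non-negative")
        if (df.loc[df["z"] <= 16, "m_alv_air"] != 0).any():
            raise ValueError("generations z <= 16 are conducting (m_alv_air = 0)")
        self._df = df

    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self):
        for row in self._df.itertuples(index=False):
            yield WeibelGeneration(int(row.z), row.d_cm, row.l_cm, row.m_alv_air)

    def generation(self, z: int) -> WeibelGeneration:
        row = self._df[self._df["z"] == z]
        if row.empty:
            raise KeyError(f"no generation {z}")
        r = row.iloc[0]
        return WeibelGeneration(int(r.z), r.d_cm, r.l_cm, r.m_alv_air)

    @property
    def z(self) -> np.ndarray:
        return self._df["z"].to_numpy(dtype=int)

    @property
    def d(self) -> np.ndarray:
        return self._df["d_cm"].to_numpy()

    @property
    def l(self) -> np.ndarray:
        return self._df["l_cm"].to_numpy()

    @property
    def m_alv_air(self) -> np.ndarray:
        return self._df["m_alv_air"].to_numpy()

    # -- CSV round trip so alternate morphometries can be supplied --------
    def to_csv(self, path: str | Path) -> None:
        self._df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "WeibelTable":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class ScalingResult:
    """Outcome of scaling the reference lung to a target volume.

    Attributes
    ----------
    V_L : target lung volume (ml)
    d_alv : mean alveolar diameter at ``V_L`` (cm)
    V_LW : unscaled model volume (ml)
    deficit : ``V_LW - V_L`` (ml)
    s : linear scaling factor applied to d and l of generations 4-23
    """

    V_L: float
    d_alv: float
    V_LW: float
    deficit: float
    s: float


def alveolar_diameter(V_L: float) -> float:
    """Mean alveolar diameter (cm) at total lung volume ``V_L`` (ml).

    Empirical law ``d_alv = 1.54e-3 * V_L**(1/3)``; at 3000 ml this gives
    222 um.
    """
    if V_L <= 0:
        raise ValueError("lung volume must be positive")
    return reference.ALVEOLAR_DIAMETER_PREFACTOR * V_L ** (1.0 / 3.0)


def alveolar_volume(d_alv: float) -> float:
    """Volume (ml) of one spherical alveolus of diameter ``d_alv`` (cm)."""
    return math.pi / 6.0 * d_alv**3


def _airway_volumes(table: WeibelTable) -> np.ndarray:
    """Aggregate cylindrical airway volume per generation, 2**z airways."""
    return 2.0 ** table.z * math.pi / 4.0 * table.d**2 * table.l


def unscaled_total_volume(table: WeibelTable, d_alv: float) -> float:
    """Total model volume (ml): cylinders plus ``m_alv_air`` spheres per airway."""
    alv = 2.0 ** table.z * table.m_alv_air * alveolar_volume(d_alv)
    return float((_airway_volumes(table) + alv).sum())


def scaling_factor(table: WeibelTable, deficit: float) -> float:
    """Linear factor ``s`` removing ``deficit`` ml of distal airway volume.

    ``s = (1 - deficit / sum_{z=4..23} 2**z * (pi/4) d**2 l)**(1/3)``;
    only generations 4-23 enter the sum because proximal generations are
    never rescaled and alveolar volumes are kept fixed.
    """
    distal = float(_airway_volumes(table)[table.z >= 4].sum())
    if deficit >= distal:
        raise ValueError(
            f"deficit {deficit} ml not removable from {distal:.1f} ml of distal airways"
        )
    return (1.0 - deficit / distal) ** (1.0 / 3.0)


def scaled_table(table: WeibelTable, s: float) -> WeibelTable:
    """Multiply d and l of generations 4-23 by ``s``; 0-3 and alveoli untouched."""
    if s <= 0:
        raise ValueError("scaling factor must be positive")
    df = table.df
    distal = df["z"] >= 4
    df.loc[distal, ["d_cm", "l_cm"]] *= s
    return WeibelTable(df)


def scale_to_volume(
    table: WeibelTable, V_L: float = reference.LUNG_VOLUME_ML
) -> tuple[ScalingResult, WeibelTable]:
    """Scale ``table`` so the total model volume equals ``V_L`` ml."""
    d_alv = alveolar_diameter(V_L)
    V_LW = unscaled_total_volume(table, d_alv)
    deficit = V_LW - V_L
    if deficit <= 0:
        result = ScalingResult(V_L, d_alv, V_LW, deficit, 1.0)
        return result, table
    s = scaling_factor(table, deficit)
    return ScalingResult(V_L, d_alv, V_LW, deficit, s), scaled_table(table, s)


def weibel_table(total_alveoli: float | None = None) -> WeibelTable:
    """The embedded raw generation table (4800-ml reference geometry).

    Generations 0-3 carry the classic Weibel model-A values; diameters and
    lengths of generations 4-23 are obtained from the per-element reference
    geometry divided by the published scaling factor 0.917 (they agree with
    the classic Weibel column to ~2 %).  Alveoli are apportioned over
    generations 17-23 with the flow-fraction distribution of
    :func:`mbwsim.reference.alveolar_flow_fractions`; by default the total
    count is calibrated so the model scaled to 3000 ml closes exactly,
    which yields ~298 million alveoli and per-airway counts
    (5.1, 8.0, 12.0, 20.0, 20.0, 20.0, 17.0) for z = 17..23.
    """
    s = reference.SCALING_FACTOR
    rows = []
    for z, (d, l) in enumerate(reference.WEIBEL_G0_G3):
        rows.append((z, d, l, 0.0))
    for r in reference.SU_ROWS:
        n_air = 2.0 ** (r.z - r.area)
        d_scaled = math.sqrt(4.0 * r.A_cm2 / (math.pi * n_air))
        rows.append((r.z, d_scaled / s, r.l_cm / s, 0.0))
    df = pd.DataFrame(rows, columns=_COLUMNS)

    if total_alveoli is None:
        total_alveoli = _calibrated_alveolar_count()
    fractions = reference.alveolar_flow_fractions()
    for z, frac in fractions.items():
        df.loc[df["z"] == z, "m_alv_air"] = frac * total_alveoli / 2.0**z
    return WeibelTable(df)


def _calibrated_alveolar_count() -> float:
    """Total alveoli such that the scaled model volume is exactly 3000 ml."""
    v_tu = sum(
        2.0**z * math.pi / 4.0 * d**2 * l
        for z, (d, l) in enumerate(reference.WEIBEL_G0_G3)
    )
    v_su = sum(r.A_cm2 * r.l_cm * 2.0**r.area for r in reference.SU_ROWS)
    airway_scaled = v_tu + v_su
    v_alv = alveolar_volume(alveolar_diameter(reference.LUNG_VOLUME_ML))
    return (reference.LUNG_VOLUME_ML - airway_scaled) / v_alv
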