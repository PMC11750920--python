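"""Per-breath washout statistics: expirograms, phase-3 slopes, unit differences.

Each expiration is split into phase I (pure dead-space gas), phase II
(the mixing front) and phase III (alveolar gas), with the phase-III onset
set by the dead-space transit time ``V_Dead / Q``.  The phase-3 slope
``S3(n)`` is the least-squares trend of the expired nitrogen fraction
over the last 25 % of the exhaled tidal volume, by convention per litre
of expired volume.  The normalised slope divides by the breath's
time-averaged expired N2 fraction.  For asymmetric models the
volume-weighted mean N2 fractions of the two sibling lung units are
evaluated at the times ``t_n = 3.5 s - dt_LU0 + (n-1)*T`` at which their
diffusive interaction shapes the recorded phase III, and the ratio
``f_S3(n) = S3(n) / delta_chi(n)`` quantifies the proportionality
between slope and inter-unit concentration difference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model_builder import BreathingPattern, LUPartition
from .transport_solver import SimulationResult

__all__ = [
    "WashoutCurve",
    "S3Record",
    "extract_breaths",
    "phase3_slope",
    "normalized_s3",
    "lu_concentration_difference",
    "f_s3",
    "s3_peak_breath",
    "breath_metrics",
    "scenario_summary",
]

#: Below this magnitude S3 or delta-chi ratios are flagged unreliable.
NUMERIC_FLOOR = 1e-6

#: Fraction of the expired tidal volume over which S3 is regressed.
PHASE3_WINDOW = 0.25


@dataclass
class WashoutCurve:
    """Expiratory N2 record of one breath."""

    n: int  # breath index, 1-based
    t: np.ndarray  # s since expiration onset
    v_exp: np.ndarray  # ml expired since onset
    chi_n2: np.ndarray
    dt_dead: float  # s, exact dead-space transit time V_Dead/Q
    tidal_volume: float  # ml

    @property
    def dt_dead_rounded(self) -> float:
        """Transit time at one decimal, as conventionally reported (0.6 s)."""
        return round(self.dt_dead, 1)

    @property
    def phase3_mask(self) -> np.ndarray:
        """Samples after the dead-space transit time."""
        return self.t >= self.dt_dead

    @property
    def phase1_end(self) -> float:
        """End of phase I: expired N2 first exceeds 2 % of the end-tidal value."""
        thresh = 0.02 * self.chi_n2[-1]
        above = np.nonzero(self.chi_n2 > thresh)[0]
        return float(self.t[above[0]]) if len(above) else float(self.t[-1])

    @property
    def mean_chi_n2(self) -> float:
        """Time-averaged expired N2 fraction over the whole expiration."""
        return float(self.chi_n2.mean())


@dataclass
class S3Record:
    """Phase-3 metrics of one breath of one scenario."""

    n: int
    t_n: float  # s
    S3: float  # 1/L
    S3_norm: float  # 1/L
    mean_chi_n2: float
    delta_chi_n2: float | None = None
    f_S3: float | None = None
    reliable: bool = True


def extract_breaths(
    result: SimulationResult,
    pattern: BreathingPattern | None = None,
    dead_space: float | None = None,
) -> list[WashoutCurve]:
    """Split the mouth trace into per-breath expiratory curves.

    Incomplete trailing breaths are dropped with a warning.  The
    dead-space volume defaults to the attached model's; it only sets the
    phase-III flag, not the samples.
    """
    pattern = pattern or result.pattern
    if dead_space is None:
        if result.system.model is None:
            raise ValueError("no model attached; pass dead_space explicitly")
        dead_space = result.system.model.dead_space_volume
    dt_dead = dead_space / pattern.Q_hat_TU

    T, half = pattern.T, pattern.T / 2.0
    t = result.t_mouth
    n_full = int(np.floor((t[-1] + 1e-9) / T))
    if t[-1] % T > 1e-9 and t[-1] / T - n_full > 1e-9:
        warnings.warn(f"dropping truncated final breath after {n_full} full breaths")
    curves = []
    for n in range(1, n_full + 1):
        onset = (n - 1) * T + half
        sel = (t > onset + 1e-12) & (t <= n * T + 1e-12)
        te = t[sel] - onset
        curves.append(
            WashoutCurve(
                n=n,
                t=te,
                v_exp=pattern.Q_hat_TU * te,
                chi_n2=1.0 - result.chi_he_mouth[sel],
                dt_dead=dt_dead,
                tidal_volume=pattern.tidal_volume,
            )
        )
    return curves


def phase3_slope(curve: WashoutCurve, per: str = "volume") -> float:
    """Least-squares phase-3 slope over the last 25 % of expired volume.

    ``per="volume"`` (default) regresses the N2 fraction against expired
    volume in litres (units 1/L); ``per="time"`` returns the equivalent
    slope per second (the two differ by the constant expiratory flow).
    """
    window = curve.v_exp >= (1.0 - PHASE3_WINDOW) * curve.tidal_volume
    if window.sum() < 2:
        raise ValueError(f"breath {curve.n}: no samples in the phase-3 window")
    v_l = curve.v_exp[window] / 1000.0
    slope = float(np.polyfit(v_l, curve.chi_n2[window], 1)[0])
    if per == "time":
        return slope * curve.tidal_volume / 1000.0 / curve.t[-1]
    if per != "volume":
        raise ValueError("per must be 'volume' or 'time'")
    return slope


def normalized_s3(curve: WashoutCurve, s3: float | None = None) -> float:
    """S3 divided by the breath's time-averaged expired N2 fraction."""
    mean = curve.mean_chi_n2
    if mean <= 0:
        raise ValueError(f"breath {curve.n}: zero mean concentration")
    if s3 is None:
        s3 = phase3_slope(curve)
    return s3 / mean


def lu_concentration_difference(
    result: SimulationResult,
    partition: LUPartition,
    pattern: BreathingPattern | None = None,
    n_breaths: int | None = None,
) -> pd.DataFrame:
    """Volume-weighted mean N2 difference between LU1 and LU2 at t_n.

    ``t_n = 3.5 - dt_LU0 + (n-1)*T`` uses the exact transit time through
    the shared region LU0; breaths whose t_n falls outside the simulated
    range are truncated.  Returns columns ``n, t_n, chi_lu1, chi_lu2,
    delta_chi_n2``.
    """
    pattern = pattern or result.pattern
    if len(partition.labels) != result.system.n:
        raise ValueError("partition does not match the simulated model")
    if n_breaths is None:
        n_breaths = result.n_breaths()
    lu1 = partition.labels == 1
    lu2 = partition.labels == 2
    rows = []
    for n in range(1, n_breaths + 1):
        t_n = 3.5 - partition.dt_LU0 + (n - 1) * pattern.T
        if t_n < result.t_snap[0] or t_n > result.t_snap[-1]:
            continue
        chi_n2 = 1.0 - result.chi_at(t_n)
        v = result.volumes_at(t_n)
        m1 = float((chi_n2[lu1] * v[lu1]).sum() / v[lu1].sum())
        m2 = float((chi_n2[lu2] * v[lu2]).sum() / v[lu2].sum())
        rows.append({"n": n, "t_n": t_n, "chi_lu1": m1, "chi_lu2": m2,
                     "delta_chi_n2": m1 - m2})
    return pd.DataFrame(rows)


def f_s3(
    s3: np.ndarray, delta_chi: np.ndarray, floor: float = NUMERIC_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise ratio S3(n) / delta_chi(n) with reliability flags.

    Entries where either series sits below the numeric floor are returned
    as NaN and flagged unreliable rather than raising: near-zero slopes
    make the ratio ill-conditioned (0/0 for a symmetric model).
    """
    s3 = np.asarray(s3, dtype=float)
    delta_chi = np.asarray(delta_chi, dtype=float)
    if s3.shape != delta_chi.shape:
        raise ValueError("series must be aligned on the breath index")
    reliable = (np.abs(s3) >= floor) & (np.abs(delta_chi) >= floor)
    out = np.full_like(s3, np.nan)
    np.divide(s3, delta_chi, out=out, where=reliable)
    return out, reliable


def s3_peak_breath(s3: np.ndarray) -> int:
    """1-based breath index of the S3 maximum; ties break to the earlier breath."""
    s3 = np.asarray(s3, dtype=float)
    if len(s3) == 0:
        raise ValueError("empty series")
    return int(np.argmax(s3)) + 1


def breath_metrics(
    result: SimulationResult,
    partition: LUPartition | None = None,
    pattern: BreathingPattern | None = None,
    max_reliable_n: int = 20,
) -> pd.DataFrame:
    """Per-breath metrics table: S3, normalised S3, delta-chi, f_S3.

    With no partition (symmetric scenario) the inter-unit columns are NaN.
    ``f_S3`` is additionally flagged unreliable beyond ``max_reliable_n``
    breaths, where both numerator and denominator are tiny.
    """
    pattern = pattern or result.pattern
    curves = extract_breaths(result, pattern)
    s3 = np.array([phase3_slope(c) for c in curves])
    s3n = np.array([normalized_s3(c, v) for c, v in zip(curves, s3)])
    mean_chi = np.array([c.mean_chi_n2 for c in curves])
    n = np.arange(1, len(curves) + 1)

    if partition is not None:
        dchi_df = lu_concentration_difference(result, partition, pattern, len(curves))
        dchi = np.full(len(curves), np.nan)
        t_n = np.full(len(curves), np.nan)
        dchi[dchi_df["n"].to_numpy() - 1] = dchi_df["delta_chi_n2"].to_numpy()
        t_n[dchi_df["n"].to_numpy() - 1] = dchi_df["t_n"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ratio, reliable = f_s3(s3, np.nan_to_num(dchi))
        reliable &= ~np.isnan(dchi)
    else:
        dchi = np.full(len(curves), np.nan)
        t_n = 3.5 + (n - 1) * pattern.T - curves[0].dt_dead
        ratio = np.full(len(curves), np.nan)
        reliable = np.zeros(len(curves), dtype=bool)
    reliable &= n <= max_reliable_n

    return pd.DataFrame(
        {
            "n": n,
            "t_n": t_n,
            "S3_per_L": s3,
            "S3_norm_per_L": s3n,
            "mean_chi_n2": mean_chi,
            "delta_chi_n2": dchi,
            "f_S3": ratio,
            "reliable": reliable,
        }
    )


def scenario_summary(metrics: pd.DataFrame) -> dict:
    """Headline numbers of one scenario: peak breath/slope, plateau estimate."""
    s3 = metrics["S3_per_L"].to_numpy()
    peak = s3_peak_breath(s3)
    rel = metrics[metrics["reliable"]]
    plateau = float(rel["S3_norm_per_L"].tail(5).mean()) if len(rel) else float("nan")
    f_vals = rel["f_S3"].to_numpy()
    return {
        "n_breaths": int(len(metrics)),
        "peak_breath": peak,
        "peak_S3_per_L": float(s3[peak - 1]),
        "S3_norm_plateau_per_L": plateau,
        "f_S3_mean": float(np.nanmean(f_vals)) if len(f_vals) else float("nan"),
        "end_tidal_chi_n2_final": float(metrics["mean_chi_n2"].iloc[-1]),
    }


def metrics_to_csv(metrics: pd.DataFrame, path: str | Path) -> None:
    metrics.to_csv(path, index=False)


def summary_to_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=1))
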