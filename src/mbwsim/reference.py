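"""Published per-element reference geometry of the 251-unit lung model.

The model lumps Weibel's symmetric airway tree (Weibel ER, *Morphometry of
the Human Lung*, Springer 1963, model "A") into a trachea unit (TU,
generations 0-3, discretised into 10 serial airway units) and a segment
unit (SU, generations 4-23) organised into 6 areas of 2**a parallel
elements.  The table below lists, per SU generation, the per-element AU
length ``l_N`` (cm), the cumulative axial position ``x`` (cm), the
per-element aggregate cross-section ``A_N`` (cm^2), the peak convective
inflow ``Qhat_N_in`` (cm^3/s) for a 250 ml/s rectangular tracheal flow,
and the entrance Peclet number and diffusional link resistance
``R_D = 0.5*(l_N + l_M)/(D*A_N)`` for the He-N2 pair (D = 0.6 cm^2/s).

These printed values are the numerical anchor of the whole package: the
raw generation table in :mod:`mbwsim.morphometry` is derived from them
(lengths and diameters divided by the linear scaling factor s = 0.917) and
every rebuilt model is regression-checked against them.
"""

from __future__ import annotations

from typing import NamedTuple


class ReferenceRow(NamedTuple):
    """One printed SU row of the reference table (per-element values)."""

    area: int
    z: int
    l_cm: float
    x_cm: float
    A_cm2: float
    qhat_cm3_s: float
    peclet: float
    R_D_s_cm3: float


#: Linear scaling factor mapping the 4800-ml Weibel reference lung onto the
#: 3000-ml resting lung (applied to d and l of generations 4-23 only).
SCALING_FACTOR = 0.917

#: Binary molecular diffusion coefficient of the He-N2 pair (cm^2/s).
D_HE_N2 = 0.6

#: Target resting (end-expiratory) lung volume in ml.
LUNG_VOLUME_ML = 3000.0

#: Peak rectangular tracheal flow magnitude (cm^3/s) and breath period (s).
Q_HAT_TU = 250.0
BREATH_PERIOD_S = 4.0

#: AUs per element for areas 0..5; area a holds 2**a parallel elements.
M_AU = (1, 10, 1, 1, 1, 6)

#: Number of serial AUs the trachea unit is discretised into.
N_TU_UNITS = 10

#: Trachea-unit AU geometry: length (cm) and aggregate cross-section (cm^2)
#: of each of the 10 identical serial AUs (generations 0-3 lumped).
TU_L_CM = 1.945
TU_A_CM2 = 2.43525

#: Printed TU diagnostics: entrance Peclet number, internal link resistance
#: (s/cm^3) and the blocking resistance of the model-inlet link.
TU_PECLET = 332.780
TU_R_D = 1.33
BLOCKING_RESISTANCE = 1e100

#: Printed per-element SU rows, generations 4-23.
SU_ROWS: tuple[ReferenceRow, ...] = (
    ReferenceRow(0, 4, 1.161, 19.06, 2.094, 250.000, 309.074, 1.24e0),
    ReferenceRow(1, 5, 0.980, 20.13, 1.304, 125.000, 171.045, 1.37e0),
    ReferenceRow(1, 6, 0.827, 21.03, 1.665, 125.000, 112.990, 9.04e-1),
    ReferenceRow(1, 7, 0.697, 21.79, 2.181, 125.000, 72.800, 5.82e-1),
    ReferenceRow(1, 8, 0.588, 22.43, 2.928, 125.000, 45.749, 3.66e-1),
    ReferenceRow(1, 9, 0.496, 22.98, 4.030, 125.000, 28.041, 2.24e-1),
    ReferenceRow(1, 10, 0.419, 23.43, 5.687, 125.000, 16.763, 1.34e-1),
    ReferenceRow(1, 11, 0.353, 23.82, 8.229, 125.000, 9.774, 7.82e-2),
    ReferenceRow(1, 12, 0.298, 24.15, 12.207, 125.000, 5.559, 4.45e-2),
    ReferenceRow(1, 13, 0.251, 24.42, 18.567, 125.000, 3.083, 2.47e-2),
    ReferenceRow(1, 14, 0.212, 24.65, 28.953, 125.000, 1.668, 1.33e-2),
    ReferenceRow(2, 15, 0.179, 24.85, 23.145, 62.500, 0.880, 1.41e-2),
    ReferenceRow(3, 16, 0.151, 25.01, 18.970, 31.250, 0.453, 1.45e-2),
    ReferenceRow(4, 17, 0.127, 25.15, 15.941, 15.625, 0.227, 1.46e-2),
    ReferenceRow(5, 18, 0.107, 25.27, 13.735, 7.795, 0.111, 1.43e-2),
    ReferenceRow(5, 19, 0.091, 25.37, 24.265, 7.740, 0.053, 6.81e-3),
    ReferenceRow(5, 20, 0.077, 25.45, 43.952, 7.576, 0.024, 3.17e-3),
    ReferenceRow(5, 21, 0.065, 25.52, 81.624, 7.027, 0.010, 1.44e-3),
    ReferenceRow(5, 22, 0.054, 25.58, 155.416, 5.929, 0.004, 6.38e-4),
    ReferenceRow(5, 23, 0.046, 25.63, 303.400, 3.733, 0.001, 2.76e-4),
)

#: Classic Weibel model-A conducting airways, generations 0-3 (trachea, main
#: bronchi, lobar bronchi, segment bronchi) at the 4800-ml reference volume:
#: (diameter cm, length cm).  These generations are never rescaled.
WEIBEL_G0_G3 = (
    (1.80, 12.0),
    (1.22, 4.76),
    (0.83, 1.90),
    (0.56, 0.76),
)

#: Empirical prefactor of the mean alveolar diameter law
#: d_alv = 1.54e-3 * V_L**(1/3) (V_L in ml, d_alv in cm); Weibel 1963, p. 66.
ALVEOLAR_DIAMETER_PREFACTOR = 1.54e-3


def alveolar_flow_fractions() -> dict[int, float]:
    """Per-generation fractions of the total alveolar volume flow.

    Back-solved from the decrements of the printed per-element Qhat column:
    within the respiratory zone the convective inflow of an element drops
    from one generation to the next exactly by the alveolar flow of the AU
    in between, and it halves at each area boundary.  The area-4 AU
    (generation 17) contributes ``15.625 - 2*7.795`` per element.  The
    fractions sum to 1 by construction.
    """
    per_elem_17 = 15.625 - 2 * 7.795
    q5 = [r.qhat_cm3_s for r in SU_ROWS if r.area == 5]
    flows = {17: 16 * per_elem_17}
    for i, z in enumerate(range(18, 24)):
        nxt = q5[i + 1] if i + 1 < len(q5) else 0.0
        flows[z] = 32 * (q5[i] - nxt)
    total = sum(flows.values())
    return {z: q / total for z, q in flows.items()}
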