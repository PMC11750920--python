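# Methods

## Model overview

`mbwsim` represents the lung as a tree of 251 well-mixed compartments
("airway units", AUs) and simulates inert-gas washout as one-dimensional
convection–diffusion on that tree.  The design goal is the *mechanistic*
reproduction of diffusion–convection-interaction-dependent inhomogeneity
(DCDI): concentration differences that arise where convective and diffusive
transport are comparable (entrance Péclet number near 1), and that express
themselves as sloping alveolar plateaus in the expirogram.  Lung mechanics
is deliberately absent — flows are prescribed rectangular functions with
homogeneous specific ventilation — so convection-dependent inhomogeneity
(CDI) is excluded by construction and any phase-3 slope the model produces
is attributable to diffusive interaction alone.

## Geometry and scaling

The base morphometry is Weibel's symmetric model "A" (Weibel 1963): 24
generations, 2^z identical airways per generation, alveoli on generations
17–23.  Measured at a 4800-ml lung, the table is rescaled to the 3000-ml
resting position in three steps:

1. alveolar diameter from the empirical law `d_alv = 1.54e-3·V_L^(1/3)`
   (cm, volumes in ml) → 222 µm at 3000 ml;
2. unscaled model volume = cylinders + `m_alv_air` spheres per airway
   → 3368 ml, i.e. 368 ml of excess;
3. a single linear factor `s = 0.917` on diameters and lengths of
   generations 4–23 (cube-root of the required distal airway-volume
   reduction).  Generations 0–3 stay fixed so future segment-level studies
   keep a common proximal geometry; alveolar volumes are never rescaled.

Two embedded-data decisions matter here:

* **Generation table provenance.**  The classic Weibel column reproduces
  the model's published per-element geometry only to ~2 %.  The package
  therefore derives the raw diameters and lengths of generations 4–23 from
  the published per-element table (lengths and aggregate cross-sections
  divided by `s`), keeping the classic values for generations 0–3 (their
  aggregates agree to 0.2 %).  This makes every rebuilt per-element value
  consistent with the printed reference to print precision.
* **Alveolar distribution.**  Per-generation alveoli counts are
  back-solved from the decrements of the published peak-flow column (flow
  is generated exclusively by alveolar inflation, so each element's inflow
  drops by exactly its alveolar flow), and the total count is calibrated so
  the scaled model closes at 3000.0 ml — giving 298 million alveoli and
  per-airway counts (5.1, 8.0, 12.0, 20.0, 20.0, 20.0, 17.0) for
  z = 17…23, in near-exact agreement with Weibel's own distribution.  The
  calibration is a surrogate for an unpublished table, but it is the unique
  distribution consistent with the printed flows.

## Network construction

The trachea unit (generations 0–3) is a straight tube cut into 10 identical
serial AUs (length 1.94 cm, cross-section 2.43 cm² each); a coarser cut
visibly smears the expirogram front.  The segment unit (generations 4–23)
is divided into 6 areas; area `a` holds 2^a parallel elements, each a
serial chain of AUs, one per generation, following the layout
{1, 10, 1, 1, 1, 6} so that area 1 spans the convection-dominated zone
(z = 5–14), areas 2–4 the transition (z = 15–17) and area 5 the respiratory
zone (z = 18–23).  Each SU AU aggregates the 2^(z−a) identical Weibel
airways of its generation belonging to one element; per-element aggregate
cross-sections and volumes are the canonical stored quantities, matching
the published table.  Axial positions accumulate midpoint-to-midpoint
(`x_N = x_M + ½(l_M + l_N)`), which reproduces the published axis column to
the printed digit; the TU AUs sit at entrance positions `i·1.945` cm.  The
positions are used for reporting only.

## Asymmetry transform

A volume asymmetry at area `a*` assigns factor `f_c` to even elements and
`2 − f_c` to odd ones, inherited multiplicatively by all daughter areas;
the accumulated factor of an element is
`f_tot(a, e) = Π_{i=0..a} f(a−i, e div 2^i)`.  Volumes, alveoli counts and
(consequently) peak flows scale by `f_tot`; lengths and diameters by
`f_tot^(1/3)`; cross-sections by `f_tot^(2/3)`.  Because sibling factors
sum to 2, the total volume is invariant, and because volume and flow are
factorised identically, convective RC time constants `τ_c = V/Q` are
unchanged while diffusive ones `τ_D = R_D·V` scale by `f_tot^(2/3)` (with a
mixed-length correction across the factor boundary).  This asymmetric
sensitivity of `τ_D` is the mechanism behind all asymmetric results: the
smaller sibling equilibrates faster with fresh gas, a nitrogen difference
builds between the siblings, and their diffusive exchange ("Pendelluft"
across the bifurcation) during expiration tilts the plateau.

## Transport and integration

Per AU the tracer balance is `d(Vχ)/dt = V̇_in − V̇_out` with upwind
convective fluxes (the donor is the upstream compartment of the current
phase) and Fick conductances `D·A_N/½(l_N+l_M)` on every link.  The link
convention — each non-root AU owns one parent-link resistance using its own
per-element cross-section — is the one that reproduces the published
resistance column exactly.  In the electrical analogy the mole fraction is
a node voltage, the AU volume a (time-varying) capacitance, diffusion a
resistor and each convective term a switched voltage-controlled current
source; `export_netlist` emits this circuit as SPICE-dialect text.

Boundary and initial conditions: the lung starts as pure nitrogen; the
inlet node is held at χ_He = 1 during inspiration and 0 during expiration;
the inlet diffusional resistance is the blocking value 1e100 s/cm³, so the
stepwise inlet concentration cannot jump into the washout signal by
diffusion.  The washout signal is the mole fraction of the first TU unit —
the upwind donor during expiration, i.e. the gas that physically leaves.
Only alveolated AUs change volume; within each half-breath the volumes vary
linearly and are computed analytically.

**Integrator.**  The balance is integrated in the expanded form
`V dχ/dt = in − out − χ dV/dt` with a fixed-step explicit scheme whose
steps land exactly on the flow-switch times.  The default is Heun's method
(explicit trapezoid) at `dt = 0.5 ms`: the stiffest compartments — the
trachea units during breathing — have `τ_c ≈ 19 ms`, and a first-order
step leaves an O(dt/τ) imprint of several 1e-3 on the mouth trace, while
Heun at 0.5 ms is converged to ~3e-5 (sup-norm change under step halving).
A plain explicit-Euler backend is retained for cross-checks.  A start-up
check enforces `dt < ½·min(τ_D, τ_c)`; because summed conductances at a
node can be stricter than any single link, the state is additionally
monitored and the run aborts (never clamps — clamping would silently
destroy tracer mass) if any mole fraction leaves [0, 1] by more than 1e-6.
Closed systems conserve total tracer volume to machine precision (the flux
matrices have zero column sums); with breathing on, the discrete
mass-balance residual against the integrated boundary flux is O(dt) and is
logged per breath (≲ 1e-4 relative at the default step).

## Washout statistics

Expirograms are cut at the half-period boundaries; expired volume is
`Q̂·t` since expiration onset.  Phase III is flagged from the exact
dead-space transit time `Δt_Dead = V_Dead/Q̂ = 0.578 s` (reported rounded
to 0.6 s by convention).  S₃(n) is the ordinary least-squares slope of
expired χ_N₂ against expired volume over the last 25 % of the tidal volume
(units 1/L; a per-time variant differs by the constant flow).  All solver
samples inside the window are used without resampling.  The normalised
slope divides by the time-averaged expired χ_N₂ of the same breath.
Inter-unit differences use the partition LU0 (trachea unit plus all areas
above the asymmetry), LU1 and LU2 (subtrees of the even/odd elements);
volume-weighted mean nitrogen fractions are evaluated at
`t_n = 3.5 s − Δt_LU0 + (n−1)·T` with the exact `Δt_LU0 = V_LU0/Q̂`, by
linear interpolation on the 20-ms snapshot grid.  The ratio
`f_S3(n) = S₃(n)/Δχ̄_N₂(t_n)` is flagged unreliable when either series is
below 1e-6 or beyond breath 20, where both are tiny and the ratio is
ill-conditioned.

## Defaults

| parameter | value | meaning |
|---|---|---|
| `V_L` | 3000 ml | resting lung volume (scaling target) |
| `D` | 0.6 cm²/s | He–N₂ binary diffusion coefficient |
| `T` | 4 s | breath period (15 min⁻¹), square-wave flow |
| `Q̂` | 250 ml/s | peak tracheal flow → 500-ml tidal volume |
| duration | 200 s | 50 breaths |
| `dt` | 0.5 ms | Heun step; must divide T/2 |
| snapshots | 20 ms | full-state sampling for the unit means |
| `f_c` grid | 1.25, 1.5, 1.75 | study factors (1.0 = symmetric) |

## What the simulations do and do not show

The study conditions are idealised on purpose: pure tracer inhalation,
perfectly rectangular flows, identical specific ventilation everywhere, a
single symmetric bifurcating tree with one localised asymmetry.  Passing
results therefore demonstrate that *diffusive sibling interaction alone*
generates the characteristic S₃(n) phenomenology (null in the symmetric
and area-1 cases, rise-peak-decay elsewhere, peak shifting to breath 1
toward the periphery, S₃ ∝ Δχ̄_N₂); they do not predict clinical MBW
indices, which also carry CDI, irregular breathing, Taylor dispersion
(excluded here; the diffusion coefficient is a plain scalar a user may
replace by an effective dispersion coefficient) and gas exchange.

## Known limitations and numerical caveats

* **Compartmental smearing.**  Well-mixed compartments smear sharp fronts:
  in the convection-only limit (D → 0) the expirogram reflects the axial
  compartment profile instead of the plug-flow step, and in the default
  configuration the phase-II front extends somewhat past the nominal
  dead-space transit time.  The alveolar plateau is flat (spread < 1e-3)
  over the slope-measurement window, not over the entire phase-III span.
* **Null level.**  The symmetric model's S₃ is not exactly zero but
  ~5e-5 L⁻¹ — the smearing floor; asymmetric signals of interest are two
  to three orders larger.
* The first evaluation of `f_S3` (breath 1) deviates a few percent from
  the series mean (start-up transient); the series coefficient of
  variation stays below 2 % for all studied scenarios.
* Alveoli counts per generation are a flow-consistent surrogate, not a
  measured table; alternate morphometries can be supplied as CSV.
* No LCI or S_cond/S_acin decomposition; no plotting beyond the CSV/JSON
  artifacts.
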