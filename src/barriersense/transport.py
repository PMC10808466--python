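"""Lumped-parameter transport model of the filtration chip.

The chip's two channels (capillary above, filtrate below) are separated by a
thin porous membrane. This module predicts tracer movement across that
membrane from first principles:

* wall shear stress in a shallow rectangular channel (parallel-plate
  approximation, cgs units): tau = 6*Q*mu / (w*h^2);
* the pressure differential driving filtration, as the sum of a Bernoulli
  hydrostatic term 0.1*(rho*g*h - rho*v^2/2) (barye -> Pa) and a van 't Hoff
  osmotic term M*R*T (atm -> Pa);
* Darcy flux per unit membrane area j = (kappa / (mu*h_m)) * dP in um/s;
* the steady-state filtrate concentration obtained by scaling the mass flux
  by the membrane exposure time Vc/Q and the filtrate volume Vf; and
* the first-order transient approach to a new equilibrium,
  c_f(t) = a + b*(1 - exp(-t/tau)), with a literature time constant of 120 s.

Unit regimes are mixed deliberately (cgs for shear/hydrostatics, SI for
Darcy/osmotic); every function documents its unit contract and the
conversions live in :mod:`barriersense.units`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, InvalidMeasurementError
from .units import (
    ATM_TO_PA,
    BARYE_TO_PA,
    CM2_TO_UM2,
    GAS_CONSTANT_ATM_L,
    GRAVITY_CM_S2,
    POISE_TO_PA_S,
    UM3_TO_ML,
    molarity_mol_per_l,
)

#: default time constant of the filtrate compartment, seconds
DEFAULT_TAU_S = 120.0


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChipGeometry:
    """Channel and membrane dimensions and volumes governing transport.

    Three distinct heights appear in the model and are kept as separate
    fields: the flow channel height (shear stress), the membrane thickness
    (Darcy), and the capillary fluid column height (hydrostatics).
    """

    channel_width_w_cm: float
    channel_height_h_cm: float
    capillary_height_cm: float
    membrane_thickness_um: float
    exposed_area_A_cm2: float
    capillary_volume_Vc_ml: float
    filtrate_volume_Vf_ml: float

    def __post_init__(self):
        for name, value in vars(self).items():
            if not value > 0:
                raise InvalidInputError(f"geometry field {name} must be positive, got {value}")


@dataclass(frozen=True)
class FluidProperties:
    """Perfusate properties; defaults are water at 37 degC."""

    viscosity_mu_poise: float = 0.006913
    density_rho_g_cm3: float = 0.9933
    temperature_T_K: float = 310.15
    gravity_g_cm_s2: float = GRAVITY_CM_S2
    gas_constant_R_atm_l: float = GAS_CONSTANT_ATM_L

    def __post_init__(self):
        for name in ("viscosity_mu_poise", "density_rho_g_cm3", "temperature_T_K"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"fluid field {name} must be positive")

    @property
    def viscosity_mu_pas(self) -> float:
        """Viscosity in Pa·s, derived as 0.1 x poise (consistent by construction)."""
        return self.viscosity_mu_poise * POISE_TO_PA_S


@dataclass(frozen=True)
class Tracer:
    """A dye-conjugated target molecule tracked on one LED channel."""

    name: str
    molecular_weight: float          # g/mol (conjugate MW is a config choice)
    permeability_kappa_um2: float    # membrane permeability, um^2
    dye_channel: str = "cyan"

    def __post_init__(self):
        if not self.molecular_weight > 0:
            raise InvalidInputError("tracer molecular weight must be positive")
        if not self.permeability_kappa_um2 > 0:
            raise InvalidInputError("tracer permeability must be positive")


@dataclass(frozen=True)
class OperatingPoint:
    """Flow and loading conditions of one experimental segment."""

    flowrate_Q_ml_s: float
    capillary_concentration_C0: float  # mg/mL

    def __post_init__(self):
        if self.flowrate_Q_ml_s < 0:
            raise InvalidInputError("flowrate must be non-negative")
        if self.capillary_concentration_C0 < 0:
            raise InvalidInputError("capillary concentration must be non-negative")

    def linear_velocity_cm_s(self, geom: ChipGeometry) -> float:
        """Mean linear velocity v = Q / (w*h) in cm/s."""
        return self.flowrate_Q_ml_s / (geom.channel_width_w_cm * geom.channel_height_h_cm)


@dataclass(frozen=True)
class TransportPrediction:
    """All intermediate and final quantities of the steady-state chain."""

    flux_per_area_j_um_s: float
    pressure_dP_pa: float
    hydrostatic_pa: float
    osmotic_pa: float
    total_flux_J_ml_s: float
    mass_flux_mg_s: float
    exposure_time_s: float
    filtrate_eq_concentration: float   # mg/mL
    transient_a: float                 # mg/mL, starting equilibrium
    transient_b: float                 # mg/mL, step amplitude (a+b is final)
    time_constant_tau_s: float = DEFAULT_TAU_S

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def shear_stress(Q_ml_s: float, mu_poise: float, w_cm: float, h_cm: float) -> float:
    """Wall shear stress tau = 6*Q*mu/(w*h^2) in dynes/cm^2 (cgs throughout)."""
    if not (w_cm > 0 and h_cm > 0 and mu_poise > 0):
        raise InvalidInputError("channel width, height and viscosity must be positive")
    if Q_ml_s < 0:
        raise InvalidInputError("flowrate must be non-negative")
    return 6.0 * Q_ml_s * mu_poise / (w_cm * h_cm**2)


def hydrostatic_pressure(
    rho_g_cm3: float, g_cm_s2: float, h_cap_cm: float, v_cm_s: float
) -> float:
    """Bernoulli hydrostatic pressure 0.1*(rho*g*h - rho*v^2/2) in Pa.

    The inputs are cgs, so the parenthesis is in barye; the 0.1 converts to
    Pa. May be negative at high linear velocity; reported as-is.
    """
    if rho_g_cm3 < 0 or g_cm_s2 < 0 or h_cap_cm < 0:
        raise InvalidInputError("density, gravity and height must be non-negative")
    return BARYE_TO_PA * (rho_g_cm3 * g_cm_s2 * h_cap_cm - 0.5 * rho_g_cm3 * v_cm_s**2)


def osmotic_pressure(
    M_mol_l: float, T_K: float, R_atm_l: float = GAS_CONSTANT_ATM_L
) -> float:
    """Van 't Hoff osmotic pressure M*R*T, computed in atm and returned in Pa."""
    if M_mol_l < 0:
        raise InvalidInputError("molarity must be non-negative")
    if not T_K > 0:
        raise InvalidInputError("temperature must be positive")
    return M_mol_l * R_atm_l * T_K * ATM_TO_PA


def pressure_differential(hydrostatic_pa: float, osmotic_pa: float) -> float:
    """Total pressure differential across the membrane: the two terms summed."""
    return hydrostatic_pa + osmotic_pa


def darcy_flux_per_area(
    kappa_um2: float, mu_pas: float, h_m_um: float, dP_pa: float
) -> float:
    """Darcy flux per unit area j = (kappa/(mu*h_m))*dP.

    Unit contract: um^2 / (Pa·s · um) · Pa = um/s.
    """
    if not (kappa_um2 > 0 and mu_pas > 0 and h_m_um > 0):
        raise InvalidInputError("permeability, viscosity and thickness must be positive")
    return kappa_um2 / (mu_pas * h_m_um) * dP_pa


def total_flux(j_um_s: float, A_cm2: float) -> float:
    """Volumetric flux J through the exposed membrane area, in mL/s.

    The area is converted to um^2 (x1e8) so j*A is um^3/s, then scaled by
    1e-12 mL/um^3 — net J = j * A * 1e-4.
    """
    if not A_cm2 > 0:
        raise InvalidInputError("exposed area must be positive")
    return j_um_s * (A_cm2 * CM2_TO_UM2) * UM3_TO_ML


def mass_flux(J_ml_s: float, C0_mg_ml: float) -> float:
    """Tracer mass flux across the membrane, J*C0 in mg/s."""
    if J_ml_s < 0 or C0_mg_ml < 0:
        raise InvalidInputError("flux and concentration must be non-negative")
    return J_ml_s * C0_mg_ml


def exposure_time(Vc_ml: float, Q_ml_s: float) -> float:
    """Seconds a fluid element is exposed to the membrane: Vc/Q."""
    if not Vc_ml > 0:
        raise InvalidInputError("capillary volume must be positive")
    if not Q_ml_s > 0:
        raise ZeroDivisionError(
            "zero flowrate: static (no-flow) regime has no finite exposure time"
        )
    return Vc_ml / Q_ml_s


# ---------------------------------------------------------------------------
# composed predictions
# ---------------------------------------------------------------------------


def _pressure_terms(
    geom: ChipGeometry, fluid: FluidProperties, mw: float, op: OperatingPoint
) -> tuple[float, float, float]:
    v = op.linear_velocity_cm_s(geom)
    p_hs = hydrostatic_pressure(
        fluid.density_rho_g_cm3, fluid.gravity_g_cm_s2, geom.capillary_height_cm, v
    )
    M = molarity_mol_per_l(op.capillary_concentration_C0, mw)
    p_osm = osmotic_pressure(M, fluid.temperature_T_K, fluid.gas_constant_R_atm_l)
    return p_hs, p_osm, pressure_differential(p_hs, p_osm)


def steady_state_filtrate_concentration(
    geom: ChipGeometry,
    fluid: FluidProperties,
    tracer: Tracer | None,
    op: OperatingPoint,
    kappa_um2: float | None = None,
    molecular_weight: float | None = None,
) -> float:
    """Predicted equilibrium filtrate concentration, mg/mL.

    Composes the full chain: pressures -> Darcy flux -> volumetric flux ->
    mass flux -> exposure time -> dilution into the filtrate volume, i.e.
    cf = J*C0*(Vc/Q)/Vf. Monotone increasing (super-linear) in C0 because
    the osmotic pressure itself grows with C0. An impermeable membrane
    (kappa = 0, passed explicitly) yields exactly 0.
    """
    kappa = tracer.permeability_kappa_um2 if kappa_um2 is None else kappa_um2
    mw = tracer.molecular_weight if molecular_weight is None else molecular_weight
    if kappa == 0:
        return 0.0
    _, _, dP = _pressure_terms(geom, fluid, mw, op)
    j = darcy_flux_per_area(kappa, fluid.viscosity_mu_pas, geom.membrane_thickness_um, dP)
    J = total_flux(j, geom.exposed_area_A_cm2)
    m = mass_flux(J, op.capillary_concentration_C0)
    t_exp = exposure_time(geom.capillary_volume_Vc_ml, op.flowrate_Q_ml_s)
    return m * t_exp / geom.filtrate_volume_Vf_ml


def predict_transport(
    geom: ChipGeometry,
    fluid: FluidProperties,
    tracer: Tracer,
    op: OperatingPoint,
    starting_filtrate: float = 0.0,
    tau_s: float = DEFAULT_TAU_S,
) -> TransportPrediction:
    """Full steady-state + transient prediction for one operating point."""
    p_hs, p_osm, dP = _pressure_terms(geom, fluid, tracer.molecular_weight, op)
    j = darcy_flux_per_area(
        tracer.permeability_kappa_um2, fluid.viscosity_mu_pas, geom.membrane_thickness_um, dP
    )
    J = total_flux(j, geom.exposed_area_A_cm2)
    m = mass_flux(J, op.capillary_concentration_C0)
    t_exp = exposure_time(geom.capillary_volume_Vc_ml, op.flowrate_Q_ml_s)
    cf_eq = m * t_exp / geom.filtrate_volume_Vf_ml
    return TransportPrediction(
        flux_per_area_j_um_s=j,
        pressure_dP_pa=dP,
        hydrostatic_pa=p_hs,
        osmotic_pa=p_osm,
        total_flux_J_ml_s=J,
        mass_flux_mg_s=m,
        exposure_time_s=t_exp,
        filtrate_eq_concentration=cf_eq,
        transient_a=starting_filtrate,
        transient_b=cf_eq - starting_filtrate,
        time_constant_tau_s=tau_s,
    )


def estimate_permeability(
    measured_cf_mg_ml: float,
    geom: ChipGeometry,
    fluid: FluidProperties,
    tracer_mw: float,
    op: OperatingPoint,
    perfusion_time_s: float | None = None,
) -> float:
    """Membrane permeability kappa (um^2) from an observed filtrate concentration.

    Inverts the steady-state chain: the filtrate accumulated over the
    perfusion is cf = (kappa/(mu*h_m))*dP * A * 1e-4 * C0 * t / Vf, linear in
    kappa. When ``perfusion_time_s`` is omitted the membrane exposure time
    Vc/Q is used, making this the exact inverse of
    :func:`steady_state_filtrate_concentration`; the paper-style estimation
    protocol (e.g. a 30-minute perfusion) passes its duration explicitly.
    """
    if measured_cf_mg_ml < 0:
        raise InvalidMeasurementError(
            f"measured filtrate concentration must be non-negative, got {measured_cf_mg_ml}"
        )
    if measured_cf_mg_ml == 0:
        return 0.0  # boundary: impermeable-membrane solution
    if not op.capillary_concentration_C0 > 0:
        raise InvalidInputError("permeability estimation needs C0 > 0")
    t = exposure_time(geom.capillary_volume_Vc_ml, op.flowrate_Q_ml_s) \
        if perfusion_time_s is None else float(perfusion_time_s)
    if not t > 0:
        raise InvalidInputError("perfusion time must be positive")
    _, _, dP = _pressure_terms(geom, fluid, tracer_mw, op)
    if not dP > 0:
        raise InvalidMeasurementError(
            f"non-positive pressure differential ({dP} Pa) cannot drive filtration"
        )
    per_kappa = (
        1.0 / (fluid.viscosity_mu_pas * geom.membrane_thickness_um)
        * dP
        * geom.exposed_area_A_cm2 * CM2_TO_UM2 * UM3_TO_ML
        * op.capillary_concentration_C0
        * t
        / geom.filtrate_volume_Vf_ml
    )
    kappa = measured_cf_mg_ml / per_kappa
    if not kappa > 0:
        raise InvalidMeasurementError(f"measurement implies kappa = {kappa} <= 0")
    return kappa


def transient_response(a: float, b: float, tau_s: float, t_s) -> float:
    """First-order filtrate transient c_f(t) = a + b*(1 - exp(-t/tau)).

    ``a`` is the starting equilibrium concentration, ``a + b`` the final
    equilibrium, ``tau`` the compartment time constant (default 120 s in the
    callers). Accepts scalar or array ``t_s``.
    """
    if not tau_s > 0:
        raise InvalidInputError("time constant must be positive")
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("time must be non-negative")
    out = a + b * (1.0 - np.exp(-t / tau_s))
    return float(out) if out.ndim == 0 else out


def predict_equilibrium_diffusion_vs_flowrate(
    flowrates_ml_s: Sequence[float],
    geom: ChipGeometry,
    fluid: FluidProperties,
    tracer: Tracer,
    C0_mg_ml: float,
) -> list[tuple[float, float]]:
    """(Q, equilibrium diffusion %) pairs across flowrates.

    In the cell-free model the steady-state prediction scales as Vc/(Q*Vf)
    while the pressure differential barely depends on Q, so the diffusion
    percentage is strictly decreasing in flowrate.
    """
    qs = [float(q) for q in flowrates_ml_s]
    if any(q <= 0 for q in qs):
        raise InvalidInputError("flowrates must be positive")
    if len(set(qs)) != len(qs):
        raise InvalidInputError("flowrates must be distinct")
    out = []
    for q in qs:
        op = OperatingPoint(flowrate_Q_ml_s=q, capillary_concentration_C0=C0_mg_ml)
        cf = steady_state_filtrate_concentration(geom, fluid, tracer, op)
        out.append((q, 100.0 * cf / C0_mg_ml))
    return out
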