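"""Transport properties built on the equilibrium populations.

Molecules are treated as random walkers whose step size and hop
frequency depend on the bond state they are in: a molecule escapes a
deep well rarely (the frequency is the Boltzmann factor of its mean bond
energy) and moves by a distance set by the geometry of that state.  The
total diffusion coefficient is the population-weighted average of the
per-state coefficients ``D_i = lambda_i**2 * nu_i``.  Viscosity follows
by inverting the Stokes-Einstein relation, the speed of sound from the
equilibrium response functions, the thermal conductivity from a
two-dimensional analogue of Bridgman's equation, and the thermal
diffusivity as conductivity over (density times heat capacity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .equilibrium import (
    EquilibriumProperties,
    NonPhysicalStateError,
    mean_spring_energy,
    thermo_derivatives,
)
from .model_core import BOND_STATES, ModelParameters, ThermoState

__all__ = [
    "DynamicProperties",
    "step_length",
    "mean_bond_energy",
    "step_frequency",
    "diffusion",
    "average_diameter",
    "viscosity",
    "speed_of_sound",
    "thermal_conductivity",
    "thermal_diffusivity",
    "dynamic_properties",
]


@dataclass(frozen=True)
class DynamicProperties:
    """Transport properties at one state point (reduced units)."""

    t_star: float
    p_star: float
    d_total: float
    d_by_state: dict[str, float]
    lambda_by_state: dict[str, float]
    nu_by_state: dict[str, float]
    e_mean_by_state: dict[str, float]
    eta: float
    d_avg: float
    c_s: float
    kappa_th: float
    a_th: float


def _check_label(state_label: str) -> None:
    if state_label not in BOND_STATES:
        raise ValueError(f"unknown bond state {state_label!r}; expected one of {BOND_STATES}")


def step_length(state_label: str, state: ThermoState, params: ModelParameters) -> float:
    """Random-walk step size of a molecule in the given bond state.

    Hydrogen-bonded and cage molecules hop by the hydrogen-bond
    separation, Lennard-Jones molecules by the contact distance, and free
    molecules by the mean intermolecular distance in 2D, ``sqrt(v_0)``.
    """
    _check_label(state_label)
    if state_label in ("HB", "c"):
        return params.r_hb
    if state_label == "LJ":
        return params.sigma_lj
    return math.sqrt(params.v_0)


def mean_bond_energy(state_label: str, state: ThermoState, params: ModelParameters) -> float:
    """Thermal-average bond energy <E_i> of a molecule in the given state.

    For the hydrogen bond this is the Boltzmann-weighted average of the
    harmonic well over the bonding window; the cage adds the
    cooperativity bonus per molecule on top.  The Lennard-Jones and
    noninteracting states have orientation-independent energies.
    """
    _check_label(state_label)
    if state_label == "LJ":
        return -params.eps_lj
    if state_label == "0":
        return 0.0
    e_hb = -(params.eps_hb + params.eps_lj) + mean_spring_energy(state, params)
    if state_label == "c":
        return e_hb - params.eps_c
    return e_hb


def step_frequency(state_label: str, state: ThermoState, params: ModelParameters) -> float:
    """Hop frequency ``nu_i = C * exp(beta * <E_i>)``.

    With ``<E_i> <= 0``, deeper wells hop exponentially less often; the
    free state hops at the bare attempt frequency ``C``.
    """
    e_mean = mean_bond_energy(state_label, state, params)
    return params.c_freq * math.exp(state.beta * e_mean)


def diffusion(
    state: ThermoState,
    params: ModelParameters,
    eq: EquilibriumProperties,
) -> tuple[float, dict[str, float]]:
    """Total diffusion coefficient and the per-state coefficients.

    ``D_i = lambda_i**2 * nu_i`` and ``D = sum_i f_i * D_i``; the 2D
    random-walk numeric prefactor is absorbed into ``c_freq``.
    """
    d_by_state = {
        lbl: step_length(lbl, state, params) ** 2 * step_frequency(lbl, state, params)
        for lbl in BOND_STATES
    }
    pops = dict(zip(BOND_STATES, eq.populations))
    d_total = sum(pops[lbl] * d_by_state[lbl] for lbl in BOND_STATES)
    return d_total, d_by_state


def average_diameter(eq: EquilibriumProperties, params: ModelParameters) -> float:
    """Population-averaged molecular diameter.

    Molecules in the HB, LJ and free states have diameter ``r_hb``; a
    molecule in a hexagonal cage drags the whole cage, of diameter
    ``2 r_hb``.
    """
    return (eq.f_hb + eq.f_lj + eq.f_0) * params.r_hb + eq.f_c * 2.0 * params.r_hb


def viscosity(state: ThermoState, params: ModelParameters, d_total: float, d_avg: float) -> float:
    """Dynamic viscosity by Stokes-Einstein inversion,
    ``eta = T* / (c_se * D * d)``."""
    if d_total <= 0.0 or d_avg <= 0.0:
        raise NonPhysicalStateError("viscosity is singular: zero diffusion or diameter")
    return state.t_star / (params.c_se * d_total * d_avg)


def speed_of_sound(state: ThermoState, params: ModelParameters, eq: EquilibriumProperties) -> float:
    """Adiabatic speed of sound, ``c_s = sqrt(cp / (cv * rho * kappa_T))``
    (gamma-corrected isothermal compressibility; unit molecular mass)."""
    if eq.kappa_t <= 0.0 or eq.cv <= 0.0 or eq.rho <= 0.0:
        raise NonPhysicalStateError("speed of sound undefined: non-physical response functions")
    return math.sqrt(eq.cp / (eq.cv * eq.rho * eq.kappa_t))


def thermal_conductivity(
    state: ThermoState,
    params: ModelParameters,
    eq: EquilibriumProperties,
    c_s: float,
    *,
    prefactor: float = 2.0,
    exponent: float = 0.5,
) -> float:
    """Thermal conductivity from a 2D analogue of Bridgman's equation,
    ``kappa = 2 * rho**(1/2) * c_s`` (k_B = 1).

    In two dimensions the molecular spacing is ``rho**(-1/2)`` and energy
    is carried along 2 spatial directions, hence the exponent 1/2 and
    prefactor 2 (both overridable).
    """
    return prefactor * eq.rho ** exponent * c_s


def thermal_diffusivity(kappa_th: float, eq: EquilibriumProperties) -> float:
    """Thermal diffusivity ``a = kappa / (rho * c_p)``."""
    if eq.cp <= 0.0:
        raise NonPhysicalStateError("thermal diffusivity undefined: cp <= 0")
    return kappa_th / (eq.rho * eq.cp)


def dynamic_properties(
    state: ThermoState,
    params: ModelParameters,
    eq: EquilibriumProperties | None = None,
) -> DynamicProperties:
    """All transport properties at one state point.

    Computes the equilibrium properties first if not supplied.
    """
    if eq is None:
        eq = thermo_derivatives(state, params)
    d_total, d_by_state = diffusion(state, params, eq)
    lam = {lbl: step_length(lbl, state, params) for lbl in BOND_STATES}
    nu = {lbl: step_frequency(lbl, state, params) for lbl in BOND_STATES}
    e_mean = {lbl: mean_bond_energy(lbl, state, params) for lbl in BOND_STATES}
    d_avg = average_diameter(eq, params)
    eta = viscosity(state, params, d_total, d_avg)
    c_s = speed_of_sound(state, params, eq)
    kappa_th = thermal_conductivity(state, params, eq, c_s)
    a_th = thermal_diffusivity(kappa_th, eq)
    return DynamicProperties(
        t_star=state.t_star, p_star=state.p_star,
        d_total=d_total, d_by_state=d_by_state,
        lambda_by_state=lam, nu_by_state=nu, e_mean_by_state=e_mean,
        eta=eta, d_avg=d_avg, c_s=c_s, kappa_th=kappa_th, a_th=a_th,
    )
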