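"""Equilibrium theory: statistical weights, hexagon partition function,
state populations and thermodynamic functions.

The bookkeeping unit is one bond on the hexagonal lattice (a molecule and
its clockwise neighbour).  Each of the six bonds of a hexagon is hydrogen
bonded (HB), a Lennard-Jones contact (LJ) or noninteracting (0), with
isothermal-isobaric statistical weights ``Delta_i`` that fold the bond
energy, the orientational freedom (for HB) and the ``p*v`` volume cost
into one Boltzmann factor.  The configuration in which all six bonds are
hydrogen bonds is promoted to a cooperative hexagonal cage: it uses the
open cage volume ``v_c`` instead of ``v_hb`` and earns an extra
stabilisation ``delta = exp(-beta*eps_c)`` per molecule.  The hexagon
partition function is therefore

    Psi = (Delta_HB + Delta_LJ + Delta_0)**6 - Delta_HB**6 + (delta*Delta_c)**6

and the system partition function is ``Q = Psi**(N/6)`` (six bonds per
hexagon; the 1/6 corrects for the three interaction sites per molecule
and double counting of bonds), giving the Gibbs energy per molecule
``g = -(T*/6) ln Psi``.  Populations are exact logarithmic derivatives of
``Psi`` and sum to one by Euler homogeneity of degree six.  All weight
arithmetic is done in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import erf, logsumexp

from .model_core import ModelParameters, ThermoState

__all__ = [
    "StateWeights",
    "EquilibriumProperties",
    "NonPhysicalStateError",
    "hb_angular_integral",
    "mean_spring_energy",
    "state_weights",
    "hexagon_partition",
    "populations",
    "gibbs_per_molecule",
    "log_psi",
    "dlogpsi_dp_analytic",
    "dlogpsi_dt_analytic",
    "volume_analytic",
    "entropy_analytic",
    "thermo_derivatives",
]


class NonPhysicalStateError(ValueError):
    """Raised when a state point yields a non-physical result
    (non-finite weights, v <= 0 or kappa_t <= 0)."""


@dataclass(frozen=True)
class StateWeights:
    """Isothermal-isobaric statistical weights of the four bond states,
    stored as natural logarithms, plus the cage cooperativity factor."""

    log_hb: float
    log_lj: float
    log_0: float
    log_c: float
    log_coop: float

    @property
    def delta_hb(self) -> float:
        return math.exp(self.log_hb)

    @property
    def delta_lj(self) -> float:
        return math.exp(self.log_lj)

    @property
    def delta_0(self) -> float:
        return math.exp(self.log_0)

    @property
    def delta_c(self) -> float:
        return math.exp(self.log_c)

    @property
    def delta_coop(self) -> float:
        return math.exp(self.log_coop)


@dataclass(frozen=True)
class EquilibriumProperties:
    """Populations and thermodynamic functions at one state point
    (all per molecule, reduced units)."""

    t_star: float
    p_star: float
    f_hb: float
    f_lj: float
    f_0: float
    f_c: float
    g: float
    v: float
    h: float
    s: float
    rho: float
    kappa_t: float
    alpha_p: float
    cp: float
    cv: float

    @property
    def populations(self) -> tuple[float, float, float, float]:
        return (self.f_hb, self.f_lj, self.f_0, self.f_c)


# ---------------------------------------------------------------------------
# Angular factor of the hydrogen-bond well
# ---------------------------------------------------------------------------

def hb_angular_integral(state: ThermoState, params: ModelParameters) -> float:
    """Normalised orientational factor of the hydrogen-bond well,

        (1 / (2*theta_max)) * int_{-theta_max}^{theta_max}
            exp(-beta * k_s * theta**2) dtheta,

    i.e. the fraction of orientational phase space that survives the
    angular spring penalty (the well depth is factored out separately).
    Evaluated in closed form through the error function; always in (0, 1].
    """
    a = state.beta * params.k_s
    if a == 0.0:
        return 1.0
    u = params.theta_max * math.sqrt(a)
    # int exp(-a t^2) over the window = sqrt(pi/a) * erf(u)
    return math.sqrt(math.pi / a) * float(erf(u)) / (2.0 * params.theta_max)


def mean_spring_energy(state: ThermoState, params: ModelParameters) -> float:
    """Thermal average of the angular spring energy ``k_s*theta**2`` over
    the bonding window, ``-d ln I / d beta`` for the integral above.

    Tends to ``T*/2`` (equipartition) when the well is much narrower than
    the window and to ``k_s*theta_max**2/3`` (uniform average) when the
    spring is negligible.
    """
    a = state.beta * params.k_s
    if a == 0.0:
        return 0.0
    u = params.theta_max * math.sqrt(a)
    bracket = 1.0 - 2.0 * u * math.exp(-u * u) / (math.sqrt(math.pi) * float(erf(u)))
    return 0.5 * state.t_star * bracket


# ---------------------------------------------------------------------------
# Statistical weights and the hexagon partition function
# ---------------------------------------------------------------------------

def _log_weights(t_star: float, p_star: float, params: ModelParameters) -> StateWeights:
    """Log statistical weights at a raw (t, p) pair.

    Internal: does not validate the sign of ``p_star`` so finite-difference
    stencils may straddle p = 0.
    """
    beta = 1.0 / t_star
    state = ThermoState(t_star=t_star, p_star=max(p_star, 0.0))
    log_ang = math.log(hb_angular_integral(state, params))
    log_hb = beta * (params.eps_hb + params.eps_lj) + log_ang - beta * p_star * params.v_hb
    log_lj = beta * params.eps_lj - beta * p_star * params.v_lj
    log_0 = -beta * p_star * params.v_0
    # expressed relative to log_hb so that v_c == v_hb gives bitwise equality
    log_c = log_hb - beta * p_star * (params.v_c - params.v_hb)
    log_coop = -beta * params.eps_c
    w = StateWeights(log_hb=log_hb, log_lj=log_lj, log_0=log_0, log_c=log_c, log_coop=log_coop)
    if not all(map(math.isfinite, (log_hb, log_lj, log_0, log_c, log_coop))):
        raise NonPhysicalStateError(f"non-finite statistical weight at T*={t_star}, p*={p_star}")
    return w


def state_weights(state: ThermoState, params: ModelParameters) -> StateWeights:
    """Isothermal-isobaric statistical weights at a state point.

    ``Delta_HB = exp(beta*(eps_hb+eps_lj)) * I_ang * exp(-beta*p*v_hb)``,
    ``Delta_LJ = exp(beta*eps_lj) * exp(-beta*p*v_lj)``,
    ``Delta_0 = exp(-beta*p*v_0)``; ``Delta_c`` equals ``Delta_HB`` with
    ``v_c`` in place of ``v_hb``; ``delta_coop = exp(-beta*eps_c)``.
    """
    return _log_weights(state.t_star, state.p_star, params)


def _log_psi_from_weights(w: StateWeights) -> float:
    """ln Psi for one hexagon, computed stably in log space."""
    log_sum = float(logsumexp([w.log_hb, w.log_lj, w.log_0]))
    a = 6.0 * log_sum                 # (Delta_HB + Delta_LJ + Delta_0)^6
    b = 6.0 * w.log_hb                # all-HB term, removed
    c = 6.0 * (w.log_coop + w.log_c)  # cooperative cage channel
    m = max(a, c)
    val = math.exp(a - m) - math.exp(b - m) + math.exp(c - m)
    if not val > 0.0:
        raise NonPhysicalStateError("hexagon partition function is not positive")
    return m + math.log(val)


def log_psi(t_star: float, p_star: float, params: ModelParameters) -> float:
    """ln Psi at a raw (T*, p*) pair (p may be slightly negative inside
    finite-difference stencils)."""
    return _log_psi_from_weights(_log_weights(t_star, p_star, params))


def hexagon_partition(state: ThermoState, params: ModelParameters) -> float:
    """Return ln Psi, the log of the hexagon partition function

        Psi = (Delta_HB + Delta_LJ + Delta_0)**6 - Delta_HB**6
              + (delta * Delta_c)**6.

    Bonds around the hexagon are independent except that the all-HB
    configuration is replaced by the cooperative cage channel.
    """
    return _log_psi_from_weights(state_weights(state, params))


def _populations_from_weights(w: StateWeights) -> tuple[float, float, float, float]:
    log_sum = float(logsumexp([w.log_hb, w.log_lj, w.log_0]))
    lp = _log_psi_from_weights(w)
    c = 6.0 * (w.log_coop + w.log_c)
    f_hb = math.exp(5.0 * log_sum + w.log_hb - lp) - math.exp(6.0 * w.log_hb - lp)
    f_lj = math.exp(5.0 * log_sum + w.log_lj - lp)
    f_0 = math.exp(5.0 * log_sum + w.log_0 - lp)
    f_c = math.exp(c - lp)
    return (max(f_hb, 0.0), f_lj, f_0, f_c)


def populations(state: ThermoState, params: ModelParameters) -> tuple[float, float, float, float]:
    """Populations (f_HB, f_LJ, f_0, f_c) of the four bond states.

    Each population is the exact logarithmic derivative
    ``f_i = (1/6) d ln Psi / d ln Delta_i`` (with ``Delta_c`` carrying the
    cooperativity factor), so normalisation follows structurally from the
    degree-6 Euler homogeneity of Psi.
    """
    return _populations_from_weights(state_weights(state, params))


def gibbs_per_molecule(state: ThermoState, params: ModelParameters) -> float:
    """Gibbs free energy per molecule, g = -(T*/6) ln Psi
    (from Q = Psi**(N/6))."""
    return -(state.t_star / 6.0) * hexagon_partition(state, params)


# ---------------------------------------------------------------------------
# Analytic first derivatives (used as cross-checks and for the second
# derivatives' inner evaluations)
# ---------------------------------------------------------------------------

def _volume_raw(t_star: float, p_star: float, params: ModelParameters) -> float:
    f_hb, f_lj, f_0, f_c = _populations_from_weights(_log_weights(t_star, p_star, params))
    return f_hb * params.v_hb + f_lj * params.v_lj + f_0 * params.v_0 + f_c * params.v_c


def _entropy_raw(t_star: float, p_star: float, params: ModelParameters) -> float:
    beta = 1.0 / t_star
    f_hb, f_lj, f_0, f_c = _populations_from_weights(_log_weights(t_star, p_star, params))
    e_spring = mean_spring_energy(ThermoState(t_star=t_star), params)
    # d ln Delta_i / d beta
    d_hb = (params.eps_hb + params.eps_lj) - e_spring - p_star * params.v_hb
    d_lj = params.eps_lj - p_star * params.v_lj
    d_0 = -p_star * params.v_0
    d_c = (params.eps_hb + params.eps_lj) - e_spring - p_star * params.v_c - params.eps_c
    dlnpsi_dbeta = 6.0 * (f_hb * d_hb + f_lj * d_lj + f_0 * d_0 + f_c * d_c)
    lp = log_psi(t_star, p_star, params)
    # s = -dg/dT = lnPsi/6 + (T/6) dlnPsi/dT, with dlnPsi/dT = -beta^2 dlnPsi/dbeta
    return lp / 6.0 - (beta / 6.0) * dlnpsi_dbeta


def dlogpsi_dp_analytic(state: ThermoState, params: ModelParameters) -> float:
    """Exact d ln Psi / d p* = -6 beta sum_i f_i v_i."""
    return -6.0 * state.beta * _volume_raw(state.t_star, state.p_star, params)


def dlogpsi_dt_analytic(state: ThermoState, params: ModelParameters) -> float:
    """Exact d ln Psi / d T* via the chain rule through beta.

    Each weight's log depends linearly on beta except for the angular
    factor, whose beta-derivative is minus the mean spring energy.
    """
    t = state.t_star
    lp = log_psi(t, state.p_star, params)
    s = _entropy_raw(t, state.p_star, params)
    # invert s = lnPsi/6 + (T/6) dlnPsi/dT
    return (6.0 * s - lp) / t


def volume_analytic(state: ThermoState, params: ModelParameters) -> float:
    """Volume per molecule from the analytic pressure derivative:
    the population-weighted mixture of the per-state volumes."""
    return _volume_raw(state.t_star, state.p_star, params)


def entropy_analytic(state: ThermoState, params: ModelParameters) -> float:
    """Entropy per molecule from the analytic temperature derivative,
    s = -dg/dT."""
    return _entropy_raw(state.t_star, state.p_star, params)


# ---------------------------------------------------------------------------
# Finite differences
# ---------------------------------------------------------------------------

def _d1(f, x: float, scale: float = 1e-4) -> float:
    """First derivative: 5-point central stencil with one Richardson level."""
    h = scale * max(1.0, abs(x))

    def stencil(h):
        return (-f(x + 2 * h) + 8 * f(x + h) - 8 * f(x - h) + f(x - 2 * h)) / (12 * h)

    d_h, d_h2 = stencil(h), stencil(h / 2)
    return (16.0 * d_h2 - d_h) / 15.0


def thermo_derivatives(state: ThermoState, params: ModelParameters) -> EquilibriumProperties:
    """All equilibrium properties at one state point.

    First derivatives of g are taken by 5-point central differences with
    one level of Richardson extrapolation (relative step 1e-4); the
    response functions kappa_T, alpha_p and c_p are central differences of
    the exact analytic first derivatives, which keeps second-derivative
    noise negligible.  c_v follows from the thermodynamic identity
    ``c_p - c_v = T v alpha_p**2 / kappa_T``.
    """
    t, p = state.t_star, state.p_star
    lp = log_psi(t, p, params)
    g = -(t / 6.0) * lp

    v = _d1(lambda pp: -(t / 6.0) * log_psi(t, pp, params), p)
    s = _d1(lambda tt: (tt / 6.0) * log_psi(tt, p, params), t)
    h = g + t * s
    if not (v > 0.0 and math.isfinite(v)):
        raise NonPhysicalStateError(f"non-physical volume v={v} at T*={t}, p*={p}")

    dv_dp = _d1(lambda pp: _volume_raw(t, pp, params), p, scale=1e-3)
    dv_dt = _d1(lambda tt: _volume_raw(tt, p, params), t, scale=1e-3)
    ds_dt = _d1(lambda tt: _entropy_raw(tt, p, params), t, scale=1e-3)

    kappa_t = -dv_dp / v
    alpha_p = dv_dt / v
    cp = t * ds_dt
    if not (kappa_t > 0.0 and math.isfinite(kappa_t)):
        raise NonPhysicalStateError(f"non-physical compressibility kappa_t={kappa_t} at T*={t}, p*={p}")
    cv = cp - t * v * alpha_p ** 2 / kappa_t

    f_hb, f_lj, f_0, f_c = populations(state, params)
    return EquilibriumProperties(
        t_star=t, p_star=p,
        f_hb=f_hb, f_lj=f_lj, f_0=f_0, f_c=f_c,
        g=g, v=v, h=h, s=s, rho=1.0 / v,
        kappa_t=kappa_t, alpha_p=alpha_p, cp=cp, cv=cv,
    )
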