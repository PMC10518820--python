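"""Brute-force validators for the analytic theory.

These routines recompute the angular integrals and the hexagon
populations by direct numerical summation — composite trapezoid rules
and enumeration over a discretized configuration space — independently
of the closed-form expressions, so the two routes can be compared at
arbitrary state points.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable

import numpy as np

from .equilibrium import populations as analytic_populations
from .model_core import ModelParameters, ThermoState

__all__ = [
    "DiscretizedHexagon",
    "quadrature_oracle",
    "enumerate_populations",
    "uniform_populations_exact",
    "validation_report",
]

#: Hard cap on angular nodes: (n_theta + 2)**6 configurations stays below
#: ~1.5e8 weight products.
MAX_N_THETA = 21

#: Cap on the configuration count for the explicit product enumeration.
MAX_FULL_CONFIGS = 2_000_000

#: Fixed seed for the pseudo-random validation state points.
VALIDATION_SEED = 1234


@dataclass(frozen=True)
class DiscretizedHexagon:
    """A hexagon with the HB orientation discretized on an angular grid.

    Each of the six bonds is one of ``n_theta`` HB angular nodes, an LJ
    contact, or noninteracting — ``(n_theta + 2)**6`` configurations —
    plus the cooperative cage channel.
    """

    n_theta: int
    bond_states: tuple[str, ...]
    weight: float

    def __post_init__(self) -> None:
        if self.n_theta < 3 or self.n_theta % 2 == 0:
            raise ValueError("n_theta must be odd and >= 3 (theta = 0 must be a node)")
        if len(self.bond_states) != 6:
            raise ValueError("a hexagon has exactly six bonds")


def quadrature_oracle(f: Callable[[float], float], a: float, b: float, n: int) -> float:
    """Composite trapezoid estimate of ``int_a^b f`` on ``n`` uniform nodes."""
    if n < 1000:
        raise ValueError("oracle quadrature requires n >= 1000 nodes")
    x = np.linspace(a, b, n)
    y = np.array([f(t) for t in x], dtype=float)
    return float(np.trapezoid(y, x))


def _node_weights(state: ThermoState, params: ModelParameters, n_theta: int,
                  volume: float) -> np.ndarray:
    """Per-node statistical weights of the HB (or cage) bond on a uniform
    angular grid with trapezoid quadrature weights, normalised by the
    window width.  Their sum converges to the corresponding Delta."""
    beta = state.beta
    theta = np.linspace(-params.theta_max, params.theta_max, n_theta)
    h = theta[1] - theta[0]
    trap = np.full(n_theta, h)
    trap[0] = trap[-1] = h / 2.0
    boltz = np.exp(beta * (params.eps_hb + params.eps_lj) - beta * params.k_s * theta ** 2)
    return boltz * trap / (2.0 * params.theta_max) * math.exp(-beta * state.p_star * volume)


def enumerate_populations(
    state: ThermoState,
    params: ModelParameters,
    n_theta: int = 15,
    *,
    full: bool = False,
) -> tuple[float, float, float, float]:
    """Populations by direct summation over discretized hexagon
    configurations.

    Each bond is one of ``n_theta`` HB angular nodes, LJ, or 0; the
    all-HB configurations are replaced by the cooperative cage channel
    (cage nodes with volume ``v_c``, one cooperativity factor per
    molecule).  A population is the weighted mean fraction of bonds in
    that state.  By default the six-bond sum is collapsed by per-bond
    factorization (exact here because bonds are independent and the cage
    correction factorizes); ``full=True`` retains the explicit product
    enumeration over all configurations as a slow cross-check.

    Converges to the analytic populations as ``n_theta`` grows.
    """
    if n_theta < 3 or n_theta % 2 == 0:
        raise ValueError("n_theta must be odd and >= 3")
    if n_theta > MAX_N_THETA:
        raise ValueError(f"n_theta > {MAX_N_THETA} refused: enumeration too large")

    beta = state.beta
    w_hb = _node_weights(state, params, n_theta, params.v_hb)
    w_cage = _node_weights(state, params, n_theta, params.v_c)
    w_lj = math.exp(beta * params.eps_lj - beta * state.p_star * params.v_lj)
    w_0 = math.exp(-beta * state.p_star * params.v_0)
    delta_coop = math.exp(-beta * params.eps_c)
    cage_bond = delta_coop * float(w_cage.sum())
    cage_total = cage_bond ** 6  # all six bonds caged; factorizes exactly

    if full:
        return _enumerate_full(w_hb, w_lj, w_0, cage_total)

    s_hb = float(w_hb.sum())
    s = s_hb + w_lj + w_0
    psi = s ** 6 - s_hb ** 6 + cage_total
    # mean fraction of bonds per state: 6 * (per-bond weight) * s^5 by
    # exchange symmetry, minus the excluded all-HB configurations
    f_hb = (6.0 * s_hb * s ** 5 - 6.0 * s_hb ** 6) / (6.0 * psi)
    f_lj = 6.0 * w_lj * s ** 5 / (6.0 * psi)
    f_0 = 6.0 * w_0 * s ** 5 / (6.0 * psi)
    f_c = 6.0 * cage_total / (6.0 * psi)
    return (f_hb, f_lj, f_0, f_c)


def _enumerate_full(
    w_hb: np.ndarray, w_lj: float, w_0: float, cage_total: float
) -> tuple[float, float, float, float]:
    """Explicit loop over every (n_theta + 2)**6 bond configuration."""
    n_theta = len(w_hb)
    m = n_theta + 2
    if m ** 6 > MAX_FULL_CONFIGS:
        raise ValueError(
            f"full enumeration refused: {m ** 6} configurations exceeds "
            f"{MAX_FULL_CONFIGS}; use the factorized path"
        )
    bond_w = np.concatenate([w_hb, [w_lj, w_0]])
    psi = cage_total
    n_hb_sum = n_lj_sum = n_0_sum = 0.0
    for cfg in itertools.product(range(m), repeat=6):
        n_hb = sum(1 for i in cfg if i < n_theta)
        if n_hb == 6:
            continue  # replaced by the cage channel
        w = 1.0
        for i in cfg:
            w *= bond_w[i]
        n_lj = sum(1 for i in cfg if i == n_theta)
        psi += w
        n_hb_sum += n_hb * w
        n_lj_sum += n_lj * w
        n_0_sum += (6 - n_hb - n_lj) * w
    return (
        n_hb_sum / (6.0 * psi),
        n_lj_sum / (6.0 * psi),
        n_0_sum / (6.0 * psi),
        cage_total / psi,
    )


def uniform_populations_exact() -> tuple[Fraction, Fraction, Fraction, Fraction]:
    """Populations in the uniform-weight limit (all energies zero, no
    volume cost, no cooperativity penalty) by exact rational enumeration.

    Every bond has three equally weighted states; the all-HB hexagon is
    replaced by a single cage configuration of the same weight.
    """
    one = Fraction(1)
    psi = Fraction(0)
    n_hb_sum = n_lj_sum = n_0_sum = Fraction(0)
    for cfg in itertools.product(range(3), repeat=6):
        n_hb = cfg.count(0)
        if n_hb == 6:
            continue
        psi += one
        n_hb_sum += n_hb
        n_lj_sum += cfg.count(1)
        n_0_sum += cfg.count(2)
    psi += one  # the cage channel, weight 1
    return (
        n_hb_sum / (6 * psi),
        n_lj_sum / (6 * psi),
        n_0_sum / (6 * psi),
        one / psi,
    )


def validation_state_points(
    n_points: int = 12,
    seed: int = VALIDATION_SEED,
    t_range: tuple[float, float] = (0.15, 0.35),
    p_range: tuple[float, float] = (0.0, 1.0),
) -> list[ThermoState]:
    """Pseudo-random state points (fixed, documented seed) used by the
    analytic-vs-oracle comparison."""
    rng = np.random.default_rng(seed)
    t = rng.uniform(*t_range, size=n_points)
    p = rng.uniform(*p_range, size=n_points)
    return [ThermoState(t_star=float(ti), p_star=float(pi)) for ti, pi in zip(t, p)]


def validation_report(
    params: ModelParameters | None = None,
    n_points: int = 12,
    n_theta: int = 15,
    seed: int = VALIDATION_SEED,
    tol: float = 1e-3,
) -> list[dict]:
    """Compare analytic populations with the enumeration oracle at
    pseudo-random state points.

    Returns one record per state point with the analytic and oracle
    populations, the maximum absolute error, and a pass flag at ``tol``.
    """
    params = params or ModelParameters()
    rows = []
    for st in validation_state_points(n_points=n_points, seed=seed):
        ana = analytic_populations(st, params)
        orc = enumerate_populations(st, params, n_theta=n_theta)
        err = max(abs(a - o) for a, o in zip(ana, orc))
        rows.append({
            "t_star": st.t_star,
            "p_star": st.p_star,
            "analytic": ana,
            "oracle": orc,
            "abs_error": err,
            "pass": err < tol,
        })
    return rows
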