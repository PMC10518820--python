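"""Core definitions for the 2D Mercedes-Benz-style water model.

Each water molecule is a Lennard-Jones disk with three hydrogen-bonding
arms at 120 degrees.  A molecule and its clockwise neighbour on the
underlying hexagonal lattice can be in one of four bond states:

* ``HB``  -- a hydrogen bond, orientation-dependent;
* ``LJ``  -- a bare van der Waals (Lennard-Jones) contact;
* ``0``   -- no interaction;
* ``c``   -- part of a fully hydrogen-bonded, cooperative hexagonal cage.

All quantities are in reduced units: energies in units of the optimal
hydrogen-bond strength ``eps_hb``, lengths in units of the hydrogen-bond
separation ``r_hb``, with the Boltzmann constant equal to one, so that
``T* = k_B T / |eps_hb|`` and ``p* = p r_hb^2 / |eps_hb|``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Union

__all__ = [
    "ModelParameters",
    "ThermoState",
    "BOND_STATES",
    "energy_hb",
    "energy_lj",
    "energy_open",
]

#: Labels of the four bond states, in canonical order.
BOND_STATES = ("HB", "LJ", "0", "c")


@dataclass(frozen=True)
class ModelParameters:
    """Interaction constants, per-state volumes and unit-fixing prefactors.

    Attributes
    ----------
    eps_hb : float
        Depth of the hydrogen-bond well at perfect alignment (reduced; >= 0
        as stored, the sign is applied inside the energy functions).
    r_hb : float
        Hydrogen-bond separation; also the molecular diameter of the
        non-cage states.
    eps_lj : float
        Lennard-Jones contact depth.
    sigma_lj : float
        Lennard-Jones contact distance.
    k_s : float
        Angular spring constant weakening a hydrogen bond as the arm
        rotates away from its neighbour (energy per squared radian).
    eps_c : float
        Cooperativity bonus per molecule, granted only when six molecules
        close a full hexagonal cage.
    v_hb, v_lj, v_0, v_c : float
        Area per molecule in the hydrogen-bonded, Lennard-Jones,
        noninteracting and cage states.  The defaults order them as
        ``v_lj < v_hb < v_c < v_0``: the Lennard-Jones contact is
        tightest, the liquid hydrogen-bond network is denser than the
        open ice-like cage (``v_c >= v_hb`` is enforced), and unbound
        molecules sit at the largest, gas-like spacing.
    theta_max : float
        Half-width of the angular window within which an arm can still
        form a hydrogen bond.
    c_freq : float
        Unit-fixing prefactor of the hop frequency (sets the time scale).
    c_se : float
        Dimensionless Stokes-Einstein constant relating viscosity to
        diffusivity and molecular diameter.
    """

    eps_hb: float = 1.0
    r_hb: float = 1.0
    eps_lj: float = 0.1
    sigma_lj: float = 0.7
    k_s: float = 10.0
    eps_c: float = 0.03
    v_hb: float = 0.8
    v_lj: float = 0.49
    v_0: float = 1.3
    v_c: float = 1.2
    theta_max: float = math.pi / 3
    c_freq: float = 1.0
    c_se: float = 3 * math.pi

    def __post_init__(self) -> None:
        for name in ("eps_hb", "eps_lj", "k_s", "eps_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (signs are applied in the energy functions)")
        for name in ("r_hb", "sigma_lj", "v_hb", "v_lj", "v_0", "v_c", "c_freq", "c_se"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.v_c < self.v_hb:
            raise ValueError("v_c must be >= v_hb (the cage is the open, ice-like structure)")
        if not (0.0 < self.theta_max <= math.pi / 3):
            raise ValueError("theta_max must lie in (0, pi/3]")

    # -- config round-trip ------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ModelParameters":
        """Load parameters from a flat JSON key/value file; missing keys
        keep their defaults."""
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, dict):
            raise ValueError("parameter config must be a flat JSON object")
        return cls.from_dict(data)

    def evolve(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class ThermoState:
    """A thermodynamic state point in reduced units.

    ``t_star`` is the reduced temperature ``k_B T / |eps_hb|`` and
    ``p_star`` the reduced pressure ``p r_hb^2 / |eps_hb|``; ``beta`` is
    the inverse reduced temperature.
    """

    t_star: float
    p_star: float = 0.0
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.t_star > 0 and math.isfinite(self.t_star)):
            raise ValueError("t_star must be positive and finite")
        if self.p_star < 0:
            raise ValueError("p_star must be >= 0")
        object.__setattr__(self, "beta", 1.0 / self.t_star)


def energy_hb(theta: float, params: ModelParameters) -> float:
    """Pair energy of the hydrogen-bonded state at arm misalignment ``theta``.

    A harmonic well on top of the Lennard-Jones contact,

        E_HB(theta) = -(eps_hb + eps_lj) + k_s * theta**2,

    minimised at perfect alignment (theta = 0).  ``theta`` must lie within
    the bonding window ``|theta| <= theta_max``; outside it no hydrogen
    bond exists and this energy is undefined.
    """
    if abs(theta) > params.theta_max:
        raise ValueError(
            f"|theta| = {abs(theta):g} exceeds the bonding window theta_max = {params.theta_max:g}"
        )
    return -(params.eps_hb + params.eps_lj) + params.k_s * theta * theta


def energy_lj(params: ModelParameters) -> float:
    """Pair energy of the bare Lennard-Jones contact (orientation-independent)."""
    return -params.eps_lj


def energy_open() -> float:
    """Pair energy of the noninteracting state: exactly zero."""
    return 0.0
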