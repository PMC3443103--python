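"""Shear-to-force mapping for a sphere tethered near a wall in laminar flow.

A sedimented microsphere of radius a (default 2.25 um) hovering ~25 nm above
the chamber floor translates at a peak velocity u_p ~ 0.54 a G, where G is
the wall shear rate.  When a molecular tether of length L arrests the sphere,
the flow exerts a drag force F and a torque Gamma; mechanical equilibrium
about the contact point puts the bond under tension

    T = (F + Gamma / a) * sqrt(a / (2 L)).

Near-wall corrections to the free-space Stokes drag and torque are the
contact-limit constants 1.7005 (force) and 0.9440 (torque), giving
F = 6 pi mu a^2 * 1.7005 * G and Gamma = 4 pi mu a^3 * 0.9440 * G.  With the
default geometry these yield tension coefficients of 0.904 pN per s^-1 for a
68-nm tether and 0.855 pN per s^-1 for a 76-nm tether.

The module also provides the freely-jointed-chain (FJC) estimates used as
controls: the entropic stiffness s = 3 kT / (4 l^2) of a chain of rigid
links of length l, and the mean thermal force <F> = sqrt(2 s kT / pi) that
Brownian motion of the bead exerts through such a tether.

Units: lengths in nm, forces in pN, shear rates in s^-1, viscosity in Pa s.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

__all__ = [
    "BOLTZMANN",
    "ChamberGeometry",
    "TetherModel",
    "MONOMER_TETHER",
    "DIMER_TETHER",
    "peak_velocity",
    "drag_force",
    "tension_coefficient",
    "tension",
    "fjc_stiffness",
    "thermal_force",
]

BOLTZMANN = 1.380649e-23  # J/K

_NM = 1e-9
_N_TO_PN = 1e12


@dataclass(frozen=True)
class ChamberGeometry:
    """Flow-chamber bead and fluid parameters (defaults: the 4.5-um bead)."""

    bead_radius: float = 2250.0  # nm
    viscosity: float = 1.0e-3  # Pa s
    drag_coefficient: float = 1.7005  # near-wall force correction
    torque_coefficient: float = 0.9440  # near-wall torque correction
    velocity_coefficient: float = 0.54  # u_p = coeff * a * G

    def __post_init__(self) -> None:
        for name in (
            "bead_radius",
            "viscosity",
            "drag_coefficient",
            "torque_coefficient",
            "velocity_coefficient",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TetherModel:
    """Molecular tether between bead and surface.

    ``length`` (nm) is the lever arm L entering the tension formula;
    ``n_links`` and ``link_length`` (nm) parameterize the freely-jointed
    chain used for the stiffness / thermal-force controls.
    """

    length: float = 76.0  # nm
    n_links: int = 4
    link_length: float = 15.0  # nm

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError("length must be positive")
        if not self.link_length > 0:
            raise ValueError("link_length must be positive")


#: Antibody + monomeric ICAM-1 chain (L = 68 nm).
MONOMER_TETHER = TetherModel(length=68.0)
#: Antibody + Fc(ICAM-1)2 chain (L = 76 nm).
DIMER_TETHER = TetherModel(length=76.0)


def peak_velocity(geom: ChamberGeometry, shear_rate: float) -> float:
    """Peak translational velocity u_p = 0.54 a G of a free sphere, in um/s."""
    if shear_rate < 0:
        raise ValueError("shear_rate must be non-negative")
    radius_um = geom.bead_radius * 1e-3
    return geom.velocity_coefficient * radius_um * shear_rate


def drag_force(geom: ChamberGeometry, shear_rate: float) -> float:
    """Near-wall Stokes drag F = 6 pi mu a^2 f* G on a held sphere, in pN."""
    if shear_rate < 0:
        raise ValueError("shear_rate must be non-negative")
    a = geom.bead_radius * _NM
    force_n = 6.0 * math.pi * geom.viscosity * a**2 * geom.drag_coefficient * shear_rate
    return force_n * _N_TO_PN


def tension_coefficient(geom: ChamberGeometry, tether: TetherModel) -> float:
    """Bond tension per unit shear rate, (F + Gamma/a) sqrt(a/2L) / G, in pN s.

    The torque contributes Gamma/a = 4 pi mu a^2 t* G; the lever factor
    sqrt(a / 2L) converts sphere loading into tension along the tether.
    """
    a = geom.bead_radius * _NM
    drag_plus_torque = (
        6.0 * math.pi * geom.viscosity * a**2 * geom.drag_coefficient
        + 4.0 * math.pi * geom.viscosity * a**2 * geom.torque_coefficient
    )
    lever = math.sqrt(geom.bead_radius / (2.0 * tether.length))
    return drag_plus_torque * lever * _N_TO_PN


def tension(geom: ChamberGeometry, tether: TetherModel, shear_rate: float) -> float:
    """Bond tension T (pN) at wall shear rate G (s^-1)."""
    if shear_rate < 0:
        raise ValueError("shear_rate must be non-negative")
    return tension_coefficient(geom, tether) * shear_rate


def fjc_stiffness(tether: TetherModel, temperature: float = 298.0) -> float:
    """Entropic stiffness s = 3 kT / (4 l^2) of the FJC tether, in N/m."""
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    link_m = tether.link_length * _NM
    return 3.0 * BOLTZMANN * temperature / (4.0 * link_m**2)


def thermal_force(stiffness: float, temperature: float = 298.0) -> float:
    """Mean Brownian force <F> = sqrt(2 s kT / pi) on the tether, in pN."""
    if stiffness < 0:
        raise ValueError("stiffness must be non-negative")
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    force_n = math.sqrt(2.0 * stiffness * BOLTZMANN * temperature / math.pi)
    return force_n * _N_TO_PN
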