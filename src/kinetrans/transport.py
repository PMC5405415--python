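"""Ligand-independent transport and orientation constants.

The diffusion step of the three-step scheme is a well-mixed rate constant
whose value follows from the assay geometry, not from the ligand:

* in 2D (membrane-to-membrane) the encounter on-rate follows the
  diffusion-limited 2D capture law with its characteristic logarithmic
  dependence on the ratio of the inter-receptor distance ``b`` to the
  encounter radius ``a``::

      d+ = 2 pi D N_A / ln(b/a)      [um^2 mol^-1 s^-1]

* in an SPR flow cell the analyte is delivered by laminar flow; the
  transport coefficient follows the classical cube-root (Leveque) law::

      k_m = 1.282 (v D^2 / (h L))^(1/3)      [um s^-1]

  converted to a volumetric on-rate ``d+ = k_m A_c N_A 1e-15`` (M^-1 s^-1)
  using the encounter cross-section ``A_c = pi a^2`` per binding site.

Both expressions are pinned by golden regression values; nothing in this
module accepts a binding constant, so every output is ligand independent
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import N_AVOGADRO, Dimension

__all__ = [
    "GeometryParams",
    "diffusion_on_rate_2d",
    "spr_transport_rate",
    "rotational_equilibrium_default",
    "RotationalConstantUnset",
    "E2D_DEFAULT",
]

#: default 2D rotational equilibrium constant E^2D (dimensionless).
E2D_DEFAULT = 0.04

#: Leveque cube-root coefficient for flow-cell mass transport.
_LEVEQUE_COEF = 1.282


@dataclass(frozen=True)
class GeometryParams:
    """Assay geometry entering the transport constants.

    Parameters
    ----------
    D
        Diffusion coefficient, um^2 s^-1 (membrane diffusion in 2D,
        analyte diffusion in the SPR flow cell).
    b
        Mean inter-receptor distance on the membrane, um.
    a
        Encounter radius (order of a receptor diameter), um.
    v
        Flow velocity in the SPR cell, um s^-1.
    h, L_cell
        Flow-cell height and inlet-to-sampling distance, um.
    """

    D: float = 0.1
    b: float = 0.1
    a: float = 0.005
    v: float = 1.0e4
    h: float = 50.0
    L_cell: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("D", "b", "a", "v", "h", "L_cell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"geometry parameter {name} must be > 0")
        if self.b <= self.a:
            raise ValueError("mean inter-receptor distance b must exceed encounter radius a")

    @property
    def A_c(self) -> float:
        """Contact (encounter) area pi a^2, um^2."""
        return np.pi * self.a**2


def diffusion_on_rate_2d(geom: GeometryParams) -> float:
    """2D diffusion-limited encounter on-rate d+ in um^2 mol^-1 s^-1.

    Linear in D and divergent as b -> a+ (encounter becomes immediate).
    """
    return 2.0 * np.pi * geom.D * N_AVOGADRO / np.log(geom.b / geom.a)


def spr_transport_rate(geom: GeometryParams) -> float:
    """SPR flow-cell transport on-rate d+ in M^-1 s^-1.

    Cube-root Leveque transport coefficient (increasing in flow velocity
    and diffusivity, decreasing in cell height and sampling distance)
    converted to volumetric units through the encounter cross-section:
    1 um^3 = 1e-15 L.
    """
    k_m = _LEVEQUE_COEF * (geom.v * geom.D**2 / (geom.h * geom.L_cell)) ** (1.0 / 3.0)
    return k_m * geom.A_c * N_AVOGADRO * 1e-15


class RotationalConstantUnset(ValueError):
    """Raised when a rotational equilibrium constant has no configured value."""


def rotational_equilibrium_default(
    dimension: Dimension, override: float | None = None
) -> float:
    """Default rotational equilibrium constant E for a given dimensionality.

    2D has the literature value ``E^2D ~ 0.04``; no 3D default is printed
    anywhere, so the 3D value must be user supplied or estimated from
    matched FRET assays (see
    :func:`kinetrans.inference.estimate_rotational_constants`) -- it is
    never silently defaulted.
    """
    if override is not None:
        if override <= 0:
            raise ValueError("rotational equilibrium constant must be > 0")
        return override
    if dimension == "2D":
        return E2D_DEFAULT
    raise RotationalConstantUnset(
        "E^3D has no default; supply it explicitly or estimate it from "
        "matched 2D/3D FRET assays"
    )
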