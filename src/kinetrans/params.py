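"""Fundamental kinetic constants and species states for three-step receptor-ligand binding.

The binding of a membrane receptor (e.g. a TCR) to its ligand (e.g. a pMHC)
is resolved into three reversible steps::

    R + L  <-- d+/d- -->  RL*  <-- e+/e- -->  RL  <-- k+/k- -->  C

where ``RL*`` is the encounter complex (within reaction distance, arbitrary
mutual orientation), ``RL`` the oriented complex, and ``C`` the chemically
bound complex.  Translational diffusion (``d+``, ``d-``) and rotational
diffusion (``e+``, ``e-``) are ligand independent but depend on the
dimensionality of the experiment; the binding constants (``k+``, ``k-``)
are ligand specific and dimension independent.

Units
-----
3D concentrations are molar (M) and ``d+`` has units M^-1 s^-1; 2D
concentrations are mol um^-2 and ``d+`` has units um^2 mol^-1 s^-1.  All
first-order rates are s^-1.  The step affinities are ``K_D = d+/d-``
(M^-1 or um^2 mol^-1), ``E = e+/e-`` (dimensionless) and ``K_A = k+/k-``
(dimensionless).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np

Dimension = Literal["2D", "3D"]

_RATE_NAMES = ("d_plus", "d_minus", "e_plus", "e_minus", "k_plus", "k_minus")

#: Avogadro constant, mol^-1.
N_AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class FundamentalConstants:
    """The six step-level rate constants of the three-step binding scheme.

    Parameters
    ----------
    dimension
        ``"2D"`` (both molecules membrane anchored) or ``"3D"`` (at least
        one in solution).  Determines the units of ``d_plus``.
    d_plus, d_minus
        Translational diffusion on/off rate constants.
    e_plus, e_minus
        Rotational (orientation) on/off rate constants, s^-1.
    k_plus, k_minus
        Chemical binding on/off rate constants, s^-1.
    """

    dimension: Dimension
    d_plus: float
    d_minus: float
    e_plus: float
    e_minus: float
    k_plus: float
    k_minus: float

    def __post_init__(self) -> None:
        if self.dimension not in ("2D", "3D"):
            raise ValueError(f"dimension must be '2D' or '3D', got {self.dimension!r}")
        for name in _RATE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {v}")

    # -- derived affinities -------------------------------------------------
    @property
    def K_D(self) -> float:
        """Diffusion-step affinity d+/d- (M^-1 in 3D, um^2 mol^-1 in 2D)."""
        return self.d_plus / self.d_minus

    @property
    def E(self) -> float:
        """Rotational equilibrium constant e+/e- (dimensionless)."""
        return self.e_plus / self.e_minus

    @property
    def K_A(self) -> float:
        """Intrinsic binding affinity k+/k- (dimensionless)."""
        return self.k_plus / self.k_minus

    def scaled(self, factor: float, steps: Iterable[str] = ("d", "e", "k")) -> "FundamentalConstants":
        """Return a copy with the on AND off rates of the given steps scaled.

        Scaling a step's pair leaves its affinity unchanged; scaling all
        three steps uniformly leaves the equilibrium state unchanged and
        only speeds up the kinetics.
        """
        updates = {}
        for s in steps:
            if s not in ("d", "e", "k"):
                raise ValueError(f"unknown step {s!r}; expected 'd', 'e' or 'k'")
            updates[f"{s}_plus"] = getattr(self, f"{s}_plus") * factor
            updates[f"{s}_minus"] = getattr(self, f"{s}_minus") * factor
        return replace(self, **updates)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _RATE_NAMES}


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations of the five species at one instant.

    Units are M in 3D and mol um^-2 in 2D, matching the
    :class:`FundamentalConstants` they are propagated with.
    """

    R: float
    L: float
    RL_star: float
    RL: float
    C: float
    time: float = 0.0

    def __post_init__(self) -> None:
        for name in ("R", "L", "RL_star", "RL", "C"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"concentration {name} must be finite and >= 0, got {v}")

    @property
    def R_total(self) -> float:
        """Conserved receptor total R + RL* + RL + C."""
        return self.R + self.RL_star + self.RL + self.C

    @property
    def L_total(self) -> float:
        """Conserved ligand total L + RL* + RL + C."""
        return self.L + self.RL_star + self.RL + self.C

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.L, self.RL_star, self.RL, self.C])


SPECIES = ("R", "L", "RL_star", "RL", "C")


@dataclass
class Trajectory:
    """Deterministic trajectory of the five-species model.

    ``y`` has shape (n_times, 5) with columns ordered as :data:`SPECIES`.
    """

    times: np.ndarray
    y: np.ndarray
    params: FundamentalConstants = field(repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (self.times.size, 5):
            raise ValueError("y must have shape (len(times), 5)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def species(self, name: str) -> np.ndarray:
        return self.y[:, SPECIES.index(name)]

    def state(self, i: int) -> SpeciesState:
        r, l, rls, rl, c = np.clip(self.y[i], 0.0, None)
        return SpeciesState(R=r, L=l, RL_star=rls, RL=rl, C=c, time=float(self.times[i]))

    @property
    def R_total(self) -> np.ndarray:
        return self.y[:, [0, 2, 3, 4]].sum(axis=1)

    @property
    def L_total(self) -> np.ndarray:
        return self.y[:, [1, 2, 3, 4]].sum(axis=1)

    def to_frame(self):
        """Return the trajectory as a pandas DataFrame (time + 5 species)."""
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, **{n: self.y[:, i] for i, n in enumerate(SPECIES)}}
        )


def molecules_per_um2(conc_mol_per_um2: float) -> float:
    """Convert a 2D concentration from mol um^-2 to molecules um^-2."""
    return conc_mol_per_um2 * N_AVOGADRO


def mol_per_um2(density_molecules_per_um2: float) -> float:
    """Convert a 2D density from molecules um^-2 to mol um^-2."""
    return density_molecules_per_um2 / N_AVOGADRO
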