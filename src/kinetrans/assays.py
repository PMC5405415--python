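"""Synthetic generators for the four assay classes (TF, AF, SPR, FRET).

Every generator is a pure function of its parameters and a seed, and its
noiseless output equals the corresponding deterministic solution of the
full or effective model -- the oracle identity the test suite leans on.

Noise models: none for bond lifetimes (the exponential law is the signal),
binomial for adhesion frequencies, additive Gaussian for sensorgrams and
FRET traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .params import FundamentalConstants, SpeciesState, N_AVOGADRO
from .effective import (
    EffectiveConstants,
    EffectiveModelKind,
    project,
    reduce_to_effective,
)

__all__ = [
    "LifetimeSample",
    "AdhesionCurve",
    "Sensorgram",
    "FretTrace",
    "Ligand",
    "LigandPanel",
    "sample_tf_lifetimes",
    "synthesize_af_curve",
    "synthesize_sensorgram",
    "sensorgram_signal",
    "synthesize_fret_trace",
    "make_ligand_panel",
    "APL_NAMES",
]

#: canonical altered-peptide-ligand names for default synthetic panels,
#: ordered from most to least potent.
APL_NAMES = ("OVA", "A2", "E1", "V-OVA", "G4", "R4")


# ---------------------------------------------------------------------------
# thermal fluctuation: bond lifetimes
# ---------------------------------------------------------------------------


@dataclass
class LifetimeSample:
    """Bond durations observed in a thermal-fluctuation experiment."""

    durations: np.ndarray
    k_off_eff: float
    seed: int

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if self.durations.size == 0:
            raise ValueError("empty lifetime sample")
        if np.any(self.durations <= 0):
            raise ValueError("bond durations must be > 0")


def sample_tf_lifetimes(k_off_eff: float, n: int, seed: int) -> LifetimeSample:
    """Draw n i.i.d. exponential bond lifetimes with rate ``k_off_eff``.

    Under the PBA description of the thermal-fluctuation assay the
    measured dissociation rate is the fundamental ``k-`` itself.
    """
    if k_off_eff <= 0:
        raise ValueError("k_off_eff must be > 0")
    if n < 1:
        raise ValueError("need at least one lifetime")
    rng = np.random.default_rng(seed)
    return LifetimeSample(
        durations=rng.exponential(1.0 / k_off_eff, size=n), k_off_eff=k_off_eff, seed=seed
    )


# ---------------------------------------------------------------------------
# adhesion frequency
# ---------------------------------------------------------------------------


@dataclass
class AdhesionCurve:
    """Adhesion frequency vs contact time from repeated touch cycles."""

    contact_times: np.ndarray
    frequencies: np.ndarray
    cycles: int
    m_r: float  #: receptor surface density, molecules um^-2
    m_l: float  #: ligand surface density, molecules um^-2
    A_c: float  #: contact area, um^2
    seed: int
    k_on_eff: float = np.nan  #: generating SS on-rate, um^2 mol^-1 s^-1
    k_off_eff: float = np.nan

    def __post_init__(self) -> None:
        self.contact_times = np.asarray(self.contact_times, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any((self.frequencies < 0) | (self.frequencies > 1)):
            raise ValueError("adhesion frequencies must lie in [0, 1]")

    @property
    def mean_bonds_infinity(self) -> float:
        """Expected steady-state bond number <n> in the contact."""
        if self.k_off_eff == 0:
            return np.inf
        return self.bond_formation_rate / self.k_off_eff

    @property
    def bond_formation_rate(self) -> float:
        """Immigration rate of new bonds, s^-1."""
        return self.k_on_eff * self.m_r * self.m_l * self.A_c / N_AVOGADRO


def _as_ss_constants(model) -> tuple[float, float]:
    if isinstance(model, FundamentalConstants):
        eff = reduce_to_effective(model, EffectiveModelKind("SS", model.dimension))
        return eff.k_on, eff.k_off
    if isinstance(model, EffectiveConstants):
        return model.k_on, model.k_off
    raise TypeError("expected FundamentalConstants or EffectiveConstants")


def synthesize_af_curve(
    model,
    m_r: float,
    m_l: float,
    A_c: float,
    contact_times,
    cycles: int,
    seed: int,
    method: str = "poisson",
) -> AdhesionCurve:
    """Simulate an adhesion-frequency curve under the single-step model.

    Bonds in the contact form a linear immigration-death process:
    formation at constant rate ``nu = k_on m_r m_l A_c / N_A`` and
    independent dissociation at ``k_off`` per bond (receptor/ligand
    depletion in the contact is negligible at realistic densities).  The
    bond count at contact end is then exactly Poisson with mean
    ``(nu/k_off)(1 - exp(-k_off t))``; an adhesion event is >= 1 bond.

    ``method="poisson"`` samples that exact law directly (default);
    ``method="ssa"`` runs the event-driven simulation of the same process
    and serves as the mechanistic cross-check.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if m_r <= 0 or m_l <= 0 or A_c <= 0:
        raise ValueError("densities and contact area must be > 0")
    k_on, k_off = _as_ss_constants(model)
    contact_times = np.asarray(contact_times, dtype=float)
    nu = k_on * m_r * m_l * A_c / N_AVOGADRO
    rng = np.random.default_rng(seed)

    if method == "poisson":
        mu = np.where(
            k_off > 0, nu / max(k_off, 1e-300) * -np.expm1(-k_off * contact_times),
            nu * contact_times,
        )
        adhesions = rng.binomial(cycles, -np.expm1(-mu))
        freqs = adhesions / cycles
    elif method == "ssa":
        freqs = np.empty_like(contact_times)
        for i, T in enumerate(contact_times):
            stuck = 0
            for _ in range(cycles):
                t, n = 0.0, 0
                while True:
                    rate = nu + n * k_off
                    if rate <= 0:
                        break
                    t += rng.exponential(1.0 / rate)
                    if t > T:
                        break
                    if rng.random() * rate < nu:
                        n += 1
                    else:
                        n -= 1
                stuck += n >= 1
            freqs[i] = stuck / cycles
    else:
        raise ValueError(f"unknown method {method!r}")
    return AdhesionCurve(
        contact_times=contact_times,
        frequencies=freqs,
        cycles=cycles,
        m_r=m_r,
        m_l=m_l,
        A_c=A_c,
        seed=seed,
        k_on_eff=k_on,
        k_off_eff=k_off,
    )


# ---------------------------------------------------------------------------
# surface plasmon resonance
# ---------------------------------------------------------------------------


@dataclass
class Sensorgram:
    """Two-phase SPR sensorgram (association then dissociation)."""

    times: np.ndarray
    signal: np.ndarray
    concentration: float  #: analyte concentration during association, M
    t_assoc_end: float
    R_max: float
    noise_sd: float
    seed: int
    k_on_eff: float = np.nan  #: generating SS 3D on-rate, M^-1 s^-1
    k_off_eff: float = np.nan


def sensorgram_signal(
    times: np.ndarray,
    k_on: float,
    k_off: float,
    R_max: float,
    concentration: float,
    t_assoc_end: float,
) -> np.ndarray:
    """Noiseless 1:1 interaction signal for a two-phase injection.

    Association relaxes towards the Langmuir plateau
    ``R_max K_a c / (1 + K_a c)`` at observed rate ``k_on c + k_off``;
    dissociation decays exponentially at ``k_off``.
    """
    times = np.asarray(times, dtype=float)
    kobs = k_on * concentration + k_off
    if kobs > 0:
        R_eq = R_max * k_on * concentration / kobs
        assoc = R_eq * -np.expm1(-kobs * np.minimum(times, t_assoc_end))
        R_end = R_eq * -np.expm1(-kobs * t_assoc_end)
    else:
        assoc = np.zeros_like(times)
        R_end = 0.0
    return np.where(
        times <= t_assoc_end,
        assoc,
        R_end * np.exp(-k_off * np.maximum(times - t_assoc_end, 0.0)),
    )


def synthesize_sensorgram(
    eff: EffectiveConstants,
    concentration: float,
    t_assoc_end: float,
    t_total: float,
    n_points: int,
    R_max: float,
    noise_sd: float,
    seed: int,
) -> Sensorgram:
    """Generate a sensorgram from SS (3D) effective constants.

    Additive Gaussian noise of standard deviation ``noise_sd`` (response
    units) on top of the closed-form two-phase signal.
    """
    if concentration < 0:
        raise ValueError("analyte concentration must be >= 0")
    if not 0 < t_assoc_end < t_total:
        raise ValueError("schedule must have association then dissociation")
    times = np.linspace(0.0, t_total, n_points)
    clean = sensorgram_signal(times, eff.k_on, eff.k_off, R_max, concentration, t_assoc_end)
    rng = np.random.default_rng(seed)
    signal = clean + rng.normal(0.0, noise_sd, size=times.size) if noise_sd > 0 else clean
    return Sensorgram(
        times=times,
        signal=signal,
        concentration=concentration,
        t_assoc_end=t_assoc_end,
        R_max=R_max,
        noise_sd=noise_sd,
        seed=seed,
        k_on_eff=eff.k_on,
        k_off_eff=eff.k_off,
    )


# ---------------------------------------------------------------------------
# FRET traces
# ---------------------------------------------------------------------------


@dataclass
class FretTrace:
    """Donor/acceptor channel time courses from a 2D FRET experiment.

    The donor channel tracks the <L> meta-state (free or encounter-stage
    ligand), the acceptor channel the <C> meta-state (oriented or bound).
    """

    times: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    gain_donor: float
    gain_acceptor: float
    noise_sd: float
    seed: int


def synthesize_fret_trace(
    params: FundamentalConstants,
    initial: SpeciesState,
    times,
    gain_donor: float = 1.0,
    gain_acceptor: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FretTrace:
    """Generate FRET channels from a full-model trajectory projection."""
    if params.dimension != "2D":
        raise ValueError("single-molecule FRET traces are a 2D assay")
    from .core import simulate

    times = np.asarray(times, dtype=float)
    grouped = project(simulate(params, initial, times), EffectiveModelKind("FRET", "2D"))
    donor = gain_donor * grouped["L_meta"]
    acceptor = gain_acceptor * grouped["C_meta"]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        donor = donor + rng.normal(0.0, noise_sd, size=times.size)
        acceptor = acceptor + rng.normal(0.0, noise_sd, size=times.size)
    return FretTrace(
        times=times,
        donor=donor,
        acceptor=acceptor,
        gain_donor=gain_donor,
        gain_acceptor=gain_acceptor,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ligand panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ligand:
    name: str
    k_plus: float
    k_minus: float
    potency: float  #: 1/EC50 proxy

    @property
    def K_A(self) -> float:
        return self.k_plus / self.k_minus


@dataclass
class LigandPanel:
    """Named ligands with binding constants and a potency proxy."""

    ligands: list[Ligand] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ligands) < 2:
            raise ValueError("a panel needs at least 2 ligands for trend fitting")

    def __len__(self) -> int:
        return len(self.ligands)

    def __iter__(self):
        return iter(self.ligands)

    def k_plus(self) -> np.ndarray:
        return np.array([lg.k_plus for lg in self.ligands])

    def k_minus(self) -> np.ndarray:
        return np.array([lg.k_minus for lg in self.ligands])

    def K_A(self) -> np.ndarray:
        return np.array([lg.K_A for lg in self.ligands])

    def potency(self) -> np.ndarray:
        return np.array([lg.potency for lg in self.ligands])

    def constants(self, shared: Mapping | None = None, **transport) -> list[FundamentalConstants]:
        """Per-ligand FundamentalConstants sharing the given ligand-independent rates.

        ``transport`` must supply dimension, d_plus, d_minus, e_plus, e_minus.
        """
        if shared:
            transport = {**shared, **transport}
        return [
            FundamentalConstants(k_plus=lg.k_plus, k_minus=lg.k_minus, **transport)
            for lg in self.ligands
        ]


def make_ligand_panel(
    n: int = 6,
    fold_k_plus: float = 1e3,
    fold_k_minus: float = 10.0,
    k_plus_max: float = 1.0,
    k_minus_max: float = 0.5,
    potency_scale: float = 1.0,
    coupling: str = "affinity",
    jitter: float = 0.0,
    seed: int = 0,
    names: tuple[str, ...] | None = None,
) -> LigandPanel:
    """Build a synthetic ligand panel with prescribed log fold-ranges.

    ``k+`` and ``k-`` are log-spaced over ``fold_k_plus`` (default 10^3)
    and ``fold_k_minus`` (default 10), both increasing with potency; the
    implied ``K_A`` fold-range is their ratio.  The potency proxy 1/EC50
    is coupled to ``K_A`` (default) or to ``k+``.  With ``jitter > 0`` a
    lognormal perturbation of that log-sd is applied to interior ligands
    only, so the requested fold-ranges stay exact.
    """
    if n < 2:
        raise ValueError("panel size must be >= 2")
    if fold_k_plus <= 0 or fold_k_minus <= 0 or k_plus_max <= 0 or k_minus_max <= 0:
        raise ValueError("fold ranges and maxima must be > 0")
    frac = np.linspace(0.0, 1.0, n)
    kp = k_plus_max * fold_k_plus ** (frac - 1.0)
    km = k_minus_max * fold_k_minus ** (frac - 1.0)
    if jitter > 0 and n > 2:
        rng = np.random.default_rng(seed)
        kp[1:-1] *= np.exp(rng.normal(0.0, jitter, size=n - 2))
        km[1:-1] *= np.exp(rng.normal(0.0, jitter, size=n - 2))
        order = np.argsort(kp)
        kp, km = kp[order], km[order]
    K_A = kp / km
    if coupling == "affinity":
        pot = potency_scale * K_A
    elif coupling == "on-rate":
        pot = potency_scale * kp
    else:
        raise ValueError(f"unknown coupling rule {coupling!r}")
    if names is None:
        names = (
            tuple(reversed(APL_NAMES)) if n == len(APL_NAMES)
            else tuple(f"L{i+1}" for i in range(n))
        )
    if len(names) != n:
        raise ValueError("need one name per ligand")
    return LigandPanel(
        ligands=[Ligand(names[i], kp[i], km[i], pot[i]) for i in range(n)]
    )
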