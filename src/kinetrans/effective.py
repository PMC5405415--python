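"""Effective (assay-level) models and their mapping to fundamental constants.

Experimental assays cannot resolve all five species of the full scheme
``R + L <=> RL* <=> RL <=> C``; each assay class observes *grouped*
variables and therefore reports *effective* on/off rate constants.  Four
effective models cover the standard assay classes:

PBA (pre-binding model A; thermal-fluctuation assay)
    Encounter and orientation are lumped into one pre-binding species
    ``<RL> = RL* + RL`` (rotation internally equilibrated).  The reported
    binding step obeys::

        k_on = k+ E/(1+E),   k_off = k-,   K_a = K_A E/(1+E)

PBB (pre-binding model B; thermal fluctuation, bulk/3D FRET, SMFM)
    Multiple binding/unbinding events occur before de-orientation: the
    binding step is internally equilibrated and ``<C> = RL + C``::

        k_on = e+,   k_off = e-/(1+K_A),   K_a = E (K_A + 1)

FRET (single-molecule 2D FRET)
    Donor/acceptor signals resolve only the meta-states
    ``<R> = R + RL*``, ``<L> = L + RL*``, ``<C> = RL + C``; diffusion and
    binding are fast relative to the observable orientation transition::

        k_on = K_D e+,   k_off = e-/(1+K_A),   K_a = K_D E (K_A + 1)

SS (single-step; adhesion-frequency and SPR assays)
    Only bound (C) vs unbound is resolved; both pre-binding steps are
    fast.  With ``D = d- e- + d- k+ + e+ k+``::

        k_on = d+ e+ k+ / D,   k_off = d- e- k- / D,   K_a = K_D E K_A

The SS on-rate interpolates between the reaction-limited bound
``K_D E k+`` (small k+) and the transport-limited bound ``d+ e+/(d- + e+)``
(large k+).  Each closed form is verified against the full model by the
numerical reduction oracle :func:`validate_reduction`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .params import FundamentalConstants, Trajectory, SpeciesState, Dimension

__all__ = [
    "EffectiveModelKind",
    "EffectiveConstants",
    "reduce_to_effective",
    "ss_on_rate_bounds",
    "ss_reaction_limited",
    "ss_transport_limited",
    "invert_effective",
    "InvertedConstants",
    "UNDETERMINED",
    "project_state",
    "project",
    "GroupedTrajectory",
    "simulate_effective",
    "validate_reduction",
    "ReductionReport",
    "FAST_STEPS",
    "GROUPED_SPECIES",
]

_TAGS = ("PBA", "PBB", "FRET", "SS")

#: which of the three steps are treated as fast (internally equilibrated)
#: by each effective model; the complementary steps carry the observable
#: dynamics.  ``d`` = translational diffusion, ``e`` = rotation, ``k`` =
#: chemical binding.
FAST_STEPS: dict[str, tuple[str, ...]] = {
    "PBA": ("e",),
    "PBB": ("k",),
    "FRET": ("d", "k"),
    "SS": ("d", "e"),
}

#: grouped observable names per model, in simulation order.
GROUPED_SPECIES: dict[str, tuple[str, ...]] = {
    "PBA": ("R", "L", "RL_grouped", "C"),
    "PBB": ("R", "L", "RL_star", "C_grouped"),
    "FRET": ("R_meta", "L_meta", "C_meta"),
    "SS": ("R_unbound", "L_unbound", "C"),
}


@dataclass(frozen=True)
class EffectiveModelKind:
    """One of the four effective models, tagged with its dimensionality.

    ``FRET`` in 3D denotes bulk FRET, whose constants coincide with the
    PBB rows (only the meta-state ``<C> = RL + C`` is unresolved).
    """

    tag: str
    dimension: Dimension = "2D"

    def __post_init__(self) -> None:
        if self.tag not in _TAGS:
            raise ValueError(f"tag must be one of {_TAGS}, got {self.tag!r}")
        if self.dimension not in ("2D", "3D"):
            raise ValueError(f"dimension must be '2D' or '3D', got {self.dimension!r}")

    @property
    def bimolecular(self) -> bool:
        """Whether the effective on-step is bimolecular (carries K_D units)."""
        tag = "PBB" if self.tag == "FRET" and self.dimension == "3D" else self.tag
        return tag in ("FRET", "SS")


@dataclass(frozen=True)
class EffectiveConstants:
    """Effective on/off constants reported by one assay class.

    ``k_on`` is s^-1 for PBA and PBB (the pre-binding step is explicit in
    those reduced schemes, with constants ``pre_on``/``pre_off``) and
    carries the units of ``d+`` for FRET and SS.  ``K_a = k_on/k_off``
    always.
    """

    kind: EffectiveModelKind
    k_on: float
    k_off: float
    pre_on: float | None = None
    pre_off: float | None = None

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @property
    def K_a(self) -> float:
        """Effective affinity k_on/k_off."""
        return self.k_on / self.k_off


def _resolved_tag(kind: EffectiveModelKind) -> str:
    # bulk (3D) FRET carries the PBB constants and grouping
    if kind.tag == "FRET" and kind.dimension == "3D":
        return "PBB"
    return kind.tag


def reduce_to_effective(
    params: FundamentalConstants, kind: EffectiveModelKind
) -> EffectiveConstants:
    """Map fundamental constants to the effective constants of one model.

    The dimension of ``kind`` must match that of ``params``.
    """
    if kind.dimension != params.dimension:
        raise ValueError(
            f"kind dimension {kind.dimension} does not match params dimension "
            f"{params.dimension}"
        )
    tag = _resolved_tag(kind)
    dp, dm = params.d_plus, params.d_minus
    ep, em = params.e_plus, params.e_minus
    kp, km = params.k_plus, params.k_minus

    if tag == "PBA":
        E = ep / em if em > 0 else np.inf
        frac = E / (1.0 + E) if np.isfinite(E) else 1.0
        return EffectiveConstants(
            kind=kind, k_on=kp * frac, k_off=km,
            pre_on=dp, pre_off=dm / (1.0 + E) if np.isfinite(E) else 0.0,
        )
    if tag == "PBB":
        K_A = kp / km if km > 0 else np.inf
        k_off = em / (1.0 + K_A) if np.isfinite(K_A) else 0.0
        return EffectiveConstants(kind=kind, k_on=ep, k_off=k_off, pre_on=dp, pre_off=dm)
    if tag == "FRET":
        K_D = dp / dm if dm > 0 else np.inf
        if not np.isfinite(K_D):
            raise ValueError("FRET reduction requires d_minus > 0")
        K_A = kp / km if km > 0 else np.inf
        k_off = em / (1.0 + K_A) if np.isfinite(K_A) else 0.0
        return EffectiveConstants(kind=kind, k_on=K_D * ep, k_off=k_off)
    # SS
    denom = dm * em + dm * kp + ep * kp
    if denom == 0.0:
        return EffectiveConstants(kind=kind, k_on=0.0, k_off=0.0)
    return EffectiveConstants(
        kind=kind, k_on=dp * ep * kp / denom, k_off=dm * em * km / denom
    )


def ss_on_rate_bounds(params: FundamentalConstants) -> tuple[float, float]:
    """(reaction-limited, transport-limited) asymptotes of the SS on-rate.

    The exact on-rate combines them harmonically,
    ``1/k_on = 1/(K_D E k+) + (d- + e+)/(d+ e+)``, so it approaches
    ``K_D E k+`` when binding is slow and ``d+ e+/(d- + e+)`` when
    transport is slow, and never exceeds either.
    """
    reaction = params.K_D * params.E * params.k_plus
    transport = params.d_plus * params.e_plus / (params.d_minus + params.e_plus)
    return reaction, transport


def ss_reaction_limited(params: FundamentalConstants) -> EffectiveConstants:
    """Asymptotic SS constants when binding is rate limiting (k+ << d-e-/(d-+e+)).

    This is the regime of the adhesion-frequency assay established by the
    TF/AF off-rate equality: ``k_on = K_D E k+``, ``k_off = k-``,
    ``K_a = K_D E K_A``; the log decomposition behind the 2D trend lines.
    """
    kind = EffectiveModelKind("SS", params.dimension)
    return EffectiveConstants(
        kind=kind,
        k_on=params.K_D * params.E * params.k_plus,
        k_off=params.k_minus,
    )


def ss_transport_limited(params: FundamentalConstants) -> EffectiveConstants:
    """Asymptotic SS constants when transport is rate limiting (e+k+ >> d-(e-+k+)).

    This is the SPR flow-cell regime: ``k_on = d+`` (ligand independent),
    ``k_off = d-/(E K_A)``, ``K_a = K_D E K_A``; the log decomposition
    behind the 3D trend lines.
    """
    kind = EffectiveModelKind("SS", params.dimension)
    return EffectiveConstants(
        kind=kind,
        k_on=params.d_plus,
        k_off=params.d_minus / (params.E * params.K_A),
    )


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------

#: sentinel for a fundamental constant an assay cannot determine.
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class InvertedConstants:
    """Partial fundamental constants recovered from effective ones.

    ``values`` holds every constant (or derived affinity such as ``K_A``)
    the assay determines given the supplied ligand-independent constants;
    ``undetermined`` names the ones it provably cannot.  Nothing is ever
    guessed.
    """

    values: dict[str, float] = field(default_factory=dict)
    undetermined: tuple[str, ...] = ()

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def is_determined(self, key: str) -> bool:
        return key in self.values


def invert_effective(
    eff: EffectiveConstants, known: Mapping[str, float]
) -> InvertedConstants:
    """Recover the ligand-dependent fundamental constants from effective ones.

    Parameters
    ----------
    known
        Ligand-independent constants available to the inversion, e.g.
        ``{"d_plus": ..., "d_minus": ..., "e_plus": ..., "e_minus": ...}``.
        Different models need different subsets.

    Notes
    -----
    Which constants are recoverable is the central observability result:
    PBA determines (k+, k-); PBB determines e+ and, given e-, the affinity
    K_A but not k+ or k- individually; FRET 2D likewise (its on-rate is
    ligand independent, so k+ is undetermined); SS determines (k+, k-)
    when its on-rate is below the transport limit.
    """
    tag = _resolved_tag(eff.kind)
    vals: dict[str, float] = {}
    undet: list[str] = []
    if tag == "PBA":
        if "e_plus" in known and "e_minus" in known:
            E = known["e_plus"] / known["e_minus"]
        elif "E" in known:
            E = known["E"]
        else:
            raise ValueError("PBA inversion requires the rotational constant E (or e_plus/e_minus)")
        vals["k_minus"] = eff.k_off
        vals["k_plus"] = eff.k_on * (1.0 + E) / E
        undet += ["d_plus", "d_minus"]
    elif tag == "PBB":
        vals["e_plus"] = eff.k_on
        if "e_minus" in known:
            K_A = known["e_minus"] / eff.k_off - 1.0
            if K_A < 0:
                raise ValueError("PBB inversion infeasible: k_off exceeds e_minus")
            vals["K_A"] = K_A
        else:
            undet.append("K_A")
        undet += ["k_plus", "k_minus", "d_plus", "d_minus"]
    elif tag == "FRET":
        if "d_plus" in known and "d_minus" in known:
            K_D = known["d_plus"] / known["d_minus"]
        elif "K_D" in known:
            K_D = known["K_D"]
        else:
            K_D = None
        if K_D is not None:
            vals["e_plus"] = eff.k_on / K_D
        else:
            undet.append("e_plus")
        if "e_minus" in known:
            K_A = known["e_minus"] / eff.k_off - 1.0
            if K_A < 0:
                raise ValueError("FRET inversion infeasible: k_off exceeds e_minus")
            vals["K_A"] = K_A
        else:
            undet.append("K_A")
        # the FRET on-rate is ligand independent: no route to k+ or k-.
        undet += ["k_plus", "k_minus"]
    else:  # SS
        for need in ("d_plus", "d_minus", "e_plus", "e_minus"):
            if need not in known:
                raise ValueError(f"SS inversion requires {need}")
        dp, dm = known["d_plus"], known["d_minus"]
        ep, em = known["e_plus"], known["e_minus"]
        margin = dp * ep - eff.k_on * (dm + ep)
        if margin <= 0:
            raise ValueError(
                "SS inversion infeasible: effective on-rate at or above the "
                "transport limit d+e+/(d-+e+)"
            )
        kp = eff.k_on * dm * em / margin
        denom = dm * em + (dm + ep) * kp
        km = eff.k_off * denom / (dm * em)
        vals["k_plus"] = kp
        vals["k_minus"] = km
    return InvertedConstants(values=vals, undetermined=tuple(undet))


# ---------------------------------------------------------------------------
# projection and reduced simulation
# ---------------------------------------------------------------------------


def project_state(state: SpeciesState, kind: EffectiveModelKind) -> dict[str, float]:
    """Project one five-species state onto the grouped observables of a model."""
    tag = _resolved_tag(kind)
    if tag == "PBA":
        return {
            "R": state.R,
            "L": state.L,
            "RL_grouped": state.RL_star + state.RL,
            "C": state.C,
        }
    if tag == "PBB":
        return {
            "R": state.R,
            "L": state.L,
            "RL_star": state.RL_star,
            "C_grouped": state.RL + state.C,
        }
    if tag == "FRET":
        return {
            "R_meta": state.R + state.RL_star,
            "L_meta": state.L + state.RL_star,
            "C_meta": state.RL + state.C,
        }
    # SS: bound is C only; everything not bound counts as free partner
    return {
        "R_unbound": state.R + state.RL_star + state.RL,
        "L_unbound": state.L + state.RL_star + state.RL,
        "C": state.C,
    }


@dataclass
class GroupedTrajectory:
    """Trajectory in the grouped coordinates of one effective model."""

    kind: EffectiveModelKind
    times: np.ndarray
    columns: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.columns[name]

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(self.columns)

    def receptor_total(self) -> np.ndarray:
        """Grouped receptor mass (equals R_total of the full model)."""
        names = self.species_names
        if "R_meta" in names:
            return self.columns["R_meta"] + self.columns["C_meta"]
        if "R_unbound" in names:
            return self.columns["R_unbound"] + self.columns["C"]
        bound = "C_grouped" if "C_grouped" in names else "C"
        mid = "RL_grouped" if "RL_grouped" in names else "RL_star"
        return self.columns["R"] + self.columns[mid] + self.columns[bound]


def project(traj: Trajectory, kind: EffectiveModelKind) -> GroupedTrajectory:
    """Project a full-model trajectory onto a model's grouped observables."""
    tag = _resolved_tag(kind)
    R, L = traj.species("R"), traj.species("L")
    RLs, RL, C = traj.species("RL_star"), traj.species("RL"), traj.species("C")
    if tag == "PBA":
        cols = {"R": R, "L": L, "RL_grouped": RLs + RL, "C": C}
    elif tag == "PBB":
        cols = {"R": R, "L": L, "RL_star": RLs, "C_grouped": RL + C}
    elif tag == "FRET":
        cols = {"R_meta": R + RLs, "L_meta": L + RLs, "C_meta": RL + C}
    else:
        cols = {"R_unbound": R + RLs + RL, "L_unbound": L + RLs + RL, "C": C}
    return GroupedTrajectory(kind=kind, times=traj.times.copy(), columns=cols)


def simulate_effective(
    eff: EffectiveConstants,
    initial: Mapping[str, float],
    times: np.ndarray,
    rtol: float = 1e-10,
) -> GroupedTrajectory:
    """Integrate the reduced ODE system of an effective model.

    ``initial`` maps the model's grouped species names (see
    :data:`GROUPED_SPECIES`) to non-negative initial values.
    """
    tag = _resolved_tag(eff.kind)
    names = GROUPED_SPECIES[tag]
    y0 = np.array([float(initial[n]) for n in names])
    if np.any(y0 < 0):
        raise ValueError("initial grouped concentrations must be >= 0")
    times = np.asarray(times, dtype=float)
    kon, koff = eff.k_on, eff.k_off

    if tag in ("FRET", "SS"):

        def rhs(t, y):
            net = kon * y[0] * y[1] - koff * y[2]
            return [-net, -net, net]

    elif tag == "PBA":
        if eff.pre_on is None or eff.pre_off is None:
            raise ValueError("PBA simulation needs pre_on/pre_off (use reduce_to_effective)")
        pon, poff = eff.pre_on, eff.pre_off

        def rhs(t, y):
            pre_net = pon * y[0] * y[1] - poff * y[2]
            bind_net = kon * y[2] - koff * y[3]
            return [-pre_net, -pre_net, pre_net - bind_net, bind_net]

    else:  # PBB
        if eff.pre_on is None or eff.pre_off is None:
            raise ValueError("PBB simulation needs pre_on/pre_off (use reduce_to_effective)")
        pon, poff = eff.pre_on, eff.pre_off

        def rhs(t, y):
            pre_net = pon * y[0] * y[1] - poff * y[2]
            grp_net = kon * y[2] - koff * y[3]
            return [-pre_net, -pre_net, pre_net - grp_net, grp_net]

    scale = max(float(np.sum(y0)), 1e-300)
    sol = solve_ivp(
        rhs, (times[0], times[-1]), y0, t_eval=times, method="LSODA",
        rtol=rtol, atol=1e-12 * scale,
    )
    if not sol.success:
        raise RuntimeError(f"effective-model integration failed: {sol.message}")
    cols = {n: sol.y[i] for i, n in enumerate(names)}
    return GroupedTrajectory(kind=eff.kind, times=sol.t, columns=cols)


# ---------------------------------------------------------------------------
# numerical reduction oracle
# ---------------------------------------------------------------------------


@dataclass
class ReductionReport:
    """Outcome of comparing an effective model against the projected full model."""

    kind: EffectiveModelKind
    separation: float
    effective: EffectiveConstants
    max_relative_deviation: float
    per_species: dict[str, float]


def validate_reduction(
    params: FundamentalConstants,
    kind: EffectiveModelKind,
    separation: float,
    R_total: float = 1.0,
    L_total: float = 1.0,
    n_times: int = 300,
    t_max: float | None = None,
) -> ReductionReport:
    """Numerically verify one closed-form reduction.

    The model's fast steps (see :data:`FAST_STEPS`) are scaled
    ``separation``-fold faster (on and off together, leaving their
    affinities fixed), the full model is integrated from the all-free
    state and projected, and the effective model is run from the projected
    initial state with :func:`reduce_to_effective` constants.  The report
    carries the maximum relative deviation over grouped species; it
    shrinks as the separation grows (for SS and FRET down to the floor set
    by the equilibrium occupancy of the hidden intermediates).
    """
    if separation < 10:
        raise ValueError("separation factor must be >= 10")
    from .core import simulate  # local import to avoid cycles

    tag = _resolved_tag(kind)
    fast = FAST_STEPS[tag]
    slow = tuple(step for step in ("d", "e", "k") if step not in fast)
    # normalise so the realised timescale ratio is exactly `separation`:
    # relaxation rates are set by the off-rates, so match their geometric
    # means before applying the factor.
    fast_scale = np.exp(np.mean([np.log(getattr(params, f"{s}_minus")) for s in fast]))
    slow_scale = np.exp(np.mean([np.log(getattr(params, f"{s}_minus")) for s in slow]))
    params_s = params.scaled(separation * slow_scale / fast_scale, fast)
    eff = reduce_to_effective(params_s, kind)

    if t_max is None:
        # cover the slowest observable relaxation: the effective exchange
        # step and, for PBA/PBB, the explicit pre-binding step.
        load = R_total + L_total
        rates = [eff.k_off + (eff.k_on * load if eff.kind.bimolecular else eff.k_on)]
        if eff.pre_on is not None and eff.pre_off is not None:
            rates.append(eff.pre_off + eff.pre_on * load)
        slow = min(r for r in rates if r > 0) if any(r > 0 for r in rates) else 0.0
        t_max = 5.0 / slow if slow > 0 else 1.0
    times = np.linspace(t_max / n_times, t_max, n_times)

    initial = SpeciesState(R=R_total, L=L_total, RL_star=0.0, RL=0.0, C=0.0)
    full = simulate(params_s, initial, times)
    proj = project(full, kind)
    init_grouped = project_state(initial, kind)
    red = simulate_effective(eff, init_grouped, times)

    scale_all = max(R_total, L_total)
    per: dict[str, float] = {}
    for name in proj.species_names:
        ref = proj[name]
        amp = np.max(np.abs(ref))
        if amp <= 1e-12 * scale_all:
            per[name] = 0.0 if np.max(np.abs(red[name])) <= 1e-12 * scale_all else np.inf
            continue
        per[name] = float(np.max(np.abs(ref - red[name])) / amp)
    return ReductionReport(
        kind=kind,
        separation=separation,
        effective=eff,
        max_relative_deviation=max(per.values()),
        per_species=per,
    )
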