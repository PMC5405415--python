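"""Fitting effective constants from readouts and the five case analyses.

The case analyses turn the pairwise assay comparisons into executable
checks:

1. TF vs AF: the observed equality of the two off-rates selects the PBA
   description of the thermal-fluctuation assay (requires k+ << e-) and
   rejects PBB (whose equality would force a ligand-dependent e-).
2. AF vs SPR: log decompositions of the single-step constants.  In 2D
   (reaction limited) the effective trend lines have the slopes of the
   fundamental ones, with the k- line unshifted and the k+/K_A lines
   shifted by log(K_D E).  In 3D (transport limited) the on-rate is
   ligand independent and log k_off = -log K_a + const.
3/4. 2D FRET vs SPR and vs AF: FRET on-rates are ligand independent,
   FRET off-rates go as e-/(1+K_A), and the FRET/AF affinity ratio is
   (K_A + 1)/K_A per ligand.
5. 2D vs 3D FRET: matched FRET and AF affinities determine E^2D (valid
   for K_A << 1), and the FRET off-rate ratio propagates it to E^3D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize

from .assays import AdhesionCurve, LifetimeSample, LigandPanel, Sensorgram, sensorgram_signal
from .effective import (
    EffectiveConstants,
    EffectiveModelKind,
    reduce_to_effective,
    ss_reaction_limited,
    ss_transport_limited,
)
from .params import FundamentalConstants, N_AVOGADRO

__all__ = [
    "FitResult",
    "TrendLine",
    "CaseVerdict",
    "fit_lifetimes",
    "fit_sensorgram",
    "fit_adhesion_curve",
    "fit_trend",
    "case1_tf_model_selection",
    "case2_trend_lines",
    "case3_case4_fret_predictions",
    "estimate_rotational_constants",
    "RotationalEstimate",
]


@dataclass
class FitResult:
    """Estimates with uncertainties and honest diagnostics."""

    values: dict[str, float]
    stderr: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    residual_norm: float = 0.0
    flags: tuple[str, ...] = ()

    def __getitem__(self, key: str) -> float:
        return self.values[key]


# ---------------------------------------------------------------------------
# per-assay estimators
# ---------------------------------------------------------------------------


def fit_lifetimes(sample: LifetimeSample) -> FitResult:
    """Maximum-likelihood exponential rate for TF bond lifetimes.

    The MLE is the inverse sample mean; its standard error is
    ``k_off/sqrt(n)``.  A single observation is allowed but the SE is
    flagged unreliable.
    """
    d = sample.durations
    if np.any(d <= 0):
        raise ValueError("bond durations must be > 0")
    n = d.size
    k_off = 1.0 / d.mean()
    flags = () if n >= 2 else ("se-unreliable-single-observation",)
    return FitResult(
        values={"k_off": k_off},
        stderr={"k_off": k_off / np.sqrt(n)},
        residual_norm=0.0,
        flags=flags,
    )


def fit_sensorgram(sg: Sensorgram, fit_R_max: bool = True) -> FitResult:
    """Nonlinear least squares of the two-phase 1:1 model.

    Initial values come from the dissociation-phase log slope and the
    association plateau; convergence is reported honestly and a flat
    signal is flagged degenerate rather than fitted.
    """
    t, y, c, ta = sg.times, sg.signal, sg.concentration, sg.t_assoc_end
    if not (np.any(t <= ta) and np.any(t > ta)):
        raise ValueError("sensorgram must contain both phases")
    amp = float(np.max(np.abs(y)))
    if amp <= max(5.0 * sg.noise_sd / np.sqrt(max(t.size, 1)), 1e-300) or c == 0:
        return FitResult(
            values={"k_on": 0.0, "k_off": 0.0, "R_max": sg.R_max},
            converged=False,
            residual_norm=float(np.linalg.norm(y)),
            flags=("degenerate-flat-signal",),
        )

    # dissociation tail -> k_off guess
    mask = (t > ta) & (y > 0.05 * amp)
    if mask.sum() >= 3:
        slope = np.polyfit(t[mask], np.log(y[mask]), 1)[0]
        k_off0 = max(-slope, 1e-6)
    else:
        k_off0 = 1.0 / (t[-1] - ta)
    R_end0 = float(np.interp(ta, t, y))
    R_max0 = sg.R_max if not fit_R_max else max(R_end0 * 1.5, amp)
    k_on0 = max(k_off0 * R_end0 / (c * max(R_max0 - R_end0, 0.05 * R_max0)), 1e-12)

    def residuals(x):
        k_on, k_off, R_max = np.exp(x) if fit_R_max else (*np.exp(x), sg.R_max)
        return sensorgram_signal(t, k_on, k_off, R_max, c, ta) - y

    x0 = np.log([k_on0, k_off0, R_max0]) if fit_R_max else np.log([k_on0, k_off0])
    res = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    est = np.exp(res.x)
    values = {"k_on": est[0], "k_off": est[1], "R_max": est[2] if fit_R_max else sg.R_max}
    # covariance of log-parameters from J^T J
    stderr: dict[str, float] = {}
    try:
        dof = max(t.size - res.x.size, 1)
        s2 = 2 * res.cost / dof
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        names = ["k_on", "k_off"] + (["R_max"] if fit_R_max else [])
        for i, name in enumerate(names):
            stderr[name] = values[name] * np.sqrt(cov[i, i])
    except np.linalg.LinAlgError:
        stderr = {}
    return FitResult(
        values=values,
        stderr=stderr,
        converged=bool(res.success),
        residual_norm=float(np.linalg.norm(res.fun)),
        flags=() if res.success else ("nonconvergent",),
    )


def fit_adhesion_curve(curve: AdhesionCurve) -> FitResult:
    """Binomial maximum likelihood for the single-step adhesion model.

    The adhesion probability is ``p(t) = 1 - exp(-n_inf (1 - e^(-k_off t)))``
    with ``n_inf = m_r m_l A_c K_a / N_A``; the fit returns ``n_inf``,
    ``k_off`` and the implied 2D effective affinity ``K_a``.
    """
    t = curve.contact_times
    if t.size < 3:
        raise ValueError("need at least 3 contact-time points")
    k = np.round(curve.frequencies * curve.cycles).astype(int)
    m = curve.cycles
    if np.all(k == 0) or np.all(k == m):
        return FitResult(
            values={"n_inf": np.nan, "k_off": np.nan, "K_a": np.nan},
            converged=False,
            flags=("non-identifiable-saturated-frequencies",),
        )

    def nll(x):
        n_inf, k_off = np.exp(x)
        p = -np.expm1(-n_inf * -np.expm1(-k_off * t))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -(k * np.log(p) + (m - k) * np.log1p(-p)).sum()

    # moment-style start: plateau level and half-rise time
    f_inf0 = max(float(curve.frequencies.max()), 1.0 / m)
    n0 = max(-np.log1p(-min(f_inf0, 1 - 1e-9)), 1e-3)
    k0 = 1.0 / max(t[np.searchsorted(curve.frequencies, f_inf0 / 2.0) if curve.frequencies[0] < f_inf0 / 2 else 0], t[0])
    best = None
    for start in ([np.log(n0), np.log(k0)], [np.log(n0), 0.0], [0.0, 0.0]):
        r = minimize(nll, start, method="Nelder-Mead",
                     options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 4000})
        if best is None or r.fun < best.fun:
            best = r
    n_inf, k_off = np.exp(best.x)
    K_a = n_inf * N_AVOGADRO / (curve.m_r * curve.m_l * curve.A_c)
    stderr: dict[str, float] = {}
    try:
        h = 1e-4
        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                e_i, e_j = np.eye(2)[i] * h, np.eye(2)[j] * h
                H[i, j] = (
                    nll(best.x + e_i + e_j) - nll(best.x + e_i - e_j)
                    - nll(best.x - e_i + e_j) + nll(best.x - e_i - e_j)
                ) / (4 * h * h)
        cov = np.linalg.inv(H)
        if np.all(np.diag(cov) > 0):
            stderr = {"n_inf": n_inf * np.sqrt(cov[0, 0]), "k_off": k_off * np.sqrt(cov[1, 1])}
    except np.linalg.LinAlgError:
        pass
    return FitResult(
        values={"n_inf": n_inf, "k_off": k_off, "K_a": K_a},
        stderr=stderr,
        converged=bool(best.success),
        residual_norm=float(best.fun),
        flags=() if best.success else ("nonconvergent",),
    )


# ---------------------------------------------------------------------------
# trend lines
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrendLine:
    """OLS line of log10(constant) against log10(potency).

    In the conventional potency-vs-constant scatter this vertical offset
    is a shift of the trend line along the constant axis; two lines with
    equal slope are compared through :meth:`offset_from`.
    """

    constant: str
    assay: str
    slope: float
    intercept: float
    n: int

    def offset_from(self, other: "TrendLine") -> float:
        """Intercept difference (decades) relative to another line."""
        return self.intercept - other.intercept


def fit_trend(potency: np.ndarray, constant: np.ndarray, name: str, assay: str) -> TrendLine:
    """Least-squares log-log trend of a kinetic constant against potency."""
    potency = np.asarray(potency, float)
    constant = np.asarray(constant, float)
    if potency.size < 2:
        raise ValueError("trend fitting needs >= 2 ligands")
    x = np.log10(potency)
    y = np.log10(constant)
    if np.ptp(x) == 0:
        raise ValueError("degenerate panel: potency has zero spread")
    slope, intercept = np.polyfit(x, y, 1)
    return TrendLine(constant=name, assay=assay, slope=float(slope),
                     intercept=float(intercept), n=potency.size)


# ---------------------------------------------------------------------------
# case analyses
# ---------------------------------------------------------------------------


@dataclass
class CaseVerdict:
    """Outcome of one pairwise assay comparison."""

    case_id: int
    conditions: dict[str, bool]
    quantities: dict[str, float]
    conclusion: str


def case1_tf_model_selection(
    panel_constants: list[FundamentalConstants],
    threshold: float = 1e-2,
    pbb_consistency_tol: float = 1e-2,
) -> CaseVerdict:
    """Select PBA vs PBB for the thermal-fluctuation assay.

    PBA reproduces the observed TF/AF off-rate equality iff the binding
    on-rate is much slower than the pre-binding relaxation
    (``k+ (d- + e+) / (d- e-) <= threshold``, which reduces to
    ``k+ << e-`` when rotation is slower than diffusional separation).
    PBB would require ``e- = k_off_AF (1 + K_A)`` -- a different e- for
    every ligand; it is rejected when the required values spread by more
    than ``pbb_consistency_tol`` (relative) across the panel.
    """
    ratios, kp_over_em, required_em = [], [], []
    for p in panel_constants:
        ratios.append(p.k_plus * (p.d_minus + p.e_plus) / (p.d_minus * p.e_minus))
        kp_over_em.append(p.k_plus / p.e_minus)
        k_off_af = reduce_to_effective(p, EffectiveModelKind("SS", p.dimension)).k_off
        required_em.append(k_off_af * (1.0 + p.K_A))
    ratios = np.array(ratios)
    required_em = np.array(required_em)
    pba_ok = bool(np.max(ratios) <= threshold)
    spread = float(np.max(required_em) / np.min(required_em) - 1.0)
    pbb_ok = spread <= pbb_consistency_tol
    if pba_ok and not pbb_ok:
        conclusion = "the TF assay is appropriately described by the PBA model"
    elif pba_ok:
        conclusion = "PBA admissible; PBB not excluded on this panel"
    else:
        conclusion = "PBA timescale condition violated on this panel"
    return CaseVerdict(
        case_id=1,
        conditions={
            "pba_kplus_much_less_than_rotational_off": pba_ok,
            "pbb_ligand_independent_e_minus_possible": pbb_ok,
        },
        quantities={
            "max_kplus_over_prebinding_relaxation": float(np.max(ratios)),
            "max_kplus_over_e_minus": float(np.max(kp_over_em)),
            "pbb_required_e_minus_relative_spread": spread,
            "threshold": threshold,
        },
        conclusion=conclusion,
    )


def case2_trend_lines(
    panel: LigandPanel,
    assay: str,
    transport: dict[str, float],
) -> list[TrendLine]:
    """Trend lines of effective and fundamental constants against potency.

    ``assay`` is ``"AF"`` (2D, reaction-limited single-step decomposition:
    k_on = K_D E k+, k_off = k-, K_a = K_D E K_A) or ``"SPR"`` (3D,
    transport-limited decomposition: k_on = d+, k_off = d-/(E K_A),
    K_a = K_D E K_A).  ``transport`` supplies the shared ligand-independent
    constants (dimension, d_plus, d_minus, e_plus, e_minus).
    """
    if assay not in ("AF", "SPR"):
        raise ValueError("assay must be 'AF' or 'SPR'")
    constants = panel.constants(transport)
    limit = ss_reaction_limited if assay == "AF" else ss_transport_limited
    eff = [limit(p) for p in constants]
    pot = panel.potency()
    lines = [
        fit_trend(pot, np.array([e.k_on for e in eff]), "k_on_eff", assay),
        fit_trend(pot, np.array([e.k_off for e in eff]), "k_off_eff", assay),
        fit_trend(pot, np.array([e.K_a for e in eff]), "K_a_eff", assay),
        fit_trend(pot, panel.k_plus(), "k_plus", assay),
        fit_trend(pot, panel.k_minus(), "k_minus", assay),
        fit_trend(pot, panel.K_A(), "K_A", assay),
    ]
    return lines


def case3_case4_fret_predictions(
    panel: LigandPanel,
    transport: dict[str, float],
) -> tuple[list[TrendLine], CaseVerdict]:
    """FRET 2D vs AF/SPR structure: ligand (in)dependence and affinity ratios.

    Checks that the 2D FRET on-rate is ligand independent, the AF
    off-rate tracks k- while the FRET off-rate is inversely related to
    K_A, and the per-ligand FRET/AF affinity ratio equals (K_A + 1)/K_A.
    """
    constants = panel.constants(transport)
    fret = [reduce_to_effective(p, EffectiveModelKind("FRET", p.dimension)) for p in constants]
    af = [ss_reaction_limited(p) for p in constants]
    pot = panel.potency()
    K_A = panel.K_A()
    fret_kon = np.array([e.k_on for e in fret])
    fret_koff = np.array([e.k_off for e in fret])
    af_koff = np.array([e.k_off for e in af])
    ratio = np.array([f.K_a / a.K_a for f, a in zip(fret, af)])
    expected_ratio = (K_A + 1.0) / K_A

    lines = [
        fit_trend(pot, fret_koff, "k_off_eff", "FRET2D"),
        fit_trend(pot, np.array([e.K_a for e in fret]), "K_a_eff", "FRET2D"),
        fit_trend(pot, af_koff, "k_off_eff", "AF"),
        fit_trend(pot, np.array([e.K_a for e in af]), "K_a_eff", "AF"),
    ]
    kon_spread = float(np.ptp(fret_kon) / np.mean(fret_kon))
    ratio_err = float(np.max(np.abs(ratio / expected_ratio - 1.0)))
    koff_anticorr = bool(fit_trend(K_A, fret_koff, "k_off_vs_K_A", "FRET2D").slope < 0)
    verdict = CaseVerdict(
        case_id=3,
        conditions={
            "fret_on_rate_ligand_independent": kon_spread <= 1e-10,
            "af_off_rate_equals_k_minus": bool(
                np.allclose(af_koff, panel.k_minus(), rtol=1e-12)
            ),
            "fret_off_rate_decreases_with_K_A": koff_anticorr,
            "affinity_ratio_is_KA_plus_1_over_KA": ratio_err <= 1e-10,
        },
        quantities={
            "fret_on_rate_relative_spread": kon_spread,
            "max_affinity_ratio_relative_error": ratio_err,
        },
        conclusion=(
            "2D FRET on-rates are ligand independent and its off-rates scale "
            "as e-/(1+K_A); AF and FRET off-rates disagree whenever K_A "
            "varies, and their affinities differ by (K_A+1)/K_A"
        ),
    )
    return lines, verdict


# ---------------------------------------------------------------------------
# rotational constants (case 5)
# ---------------------------------------------------------------------------


@dataclass
class RotationalEstimate:
    """Rotational equilibrium constants recovered from matched assays."""

    E_2d: float | None
    E_3d: float | None
    valid: bool
    per_ligand_K_A: np.ndarray
    per_ligand_E_2d: np.ndarray
    flags: tuple[str, ...] = ()


def estimate_rotational_constants(
    fret2d: list[EffectiveConstants],
    af: list[EffectiveConstants],
    K_D_2d: float,
    fret3d: list[EffectiveConstants] | None = None,
) -> RotationalEstimate:
    """Recover E^2D (and optionally E^3D) from matched ligand panels.

    For each ligand the FRET 2D and AF affinities are
    ``K_D E (K_A + 1)`` and ``K_D E K_A``, so their difference isolates
    ``E^2D = (K_a_FRET - K_a_AF)/K_D`` and their ratio fixes ``K_A``.
    The estimate is declared invalid when any implied ``K_A >= 1`` (the
    two affinities then nearly coincide and the subtraction is
    ill-conditioned).  With a matched bulk-FRET (3D) panel the off-rate
    ratio ``e-^3D/e-^2D = k_off^3D/k_off^2D`` and the bulk on-rate
    ``e+^3D`` propagate to ``E^3D``.
    """
    if len(fret2d) != len(af):
        raise ValueError("FRET 2D and AF panels must cover the same ligands")
    if len(fret2d) == 0:
        raise ValueError("empty panels")
    k_fret = np.array([e.K_a for e in fret2d])
    k_af = np.array([e.K_a for e in af])
    diff = k_fret - k_af
    if np.any(diff <= 0):
        raise ValueError("FRET affinity must exceed the AF affinity per ligand")
    e2d_per = diff / K_D_2d
    K_A_per = k_af / diff
    flags: list[str] = []
    valid = bool(np.all(K_A_per < 1.0))
    if not valid:
        flags.append("invalid-K_A-not-small")
    if len(fret2d) == 1:
        flags.append("single-ligand-no-cross-consistency-check")
    else:
        spread = float(np.ptp(e2d_per) / np.mean(e2d_per))
        if spread > 1e-6:
            flags.append("cross-ligand-inconsistency")
    E_2d = float(np.mean(e2d_per))

    E_3d: float | None = None
    if fret3d is not None:
        if len(fret3d) != len(fret2d):
            raise ValueError("bulk FRET panel must cover the same ligands")
        e_plus_2d = np.array([e.k_on for e in fret2d]) / K_D_2d
        e_minus_2d = e_plus_2d / E_2d
        ratio = np.array([f3.k_off for f3 in fret3d]) / np.array(
            [f2.k_off for f2 in fret2d]
        )
        e_minus_3d = e_minus_2d * ratio
        e_plus_3d = np.array([f3.k_on for f3 in fret3d])
        E_3d = float(np.mean(e_plus_3d / e_minus_3d))
    else:
        flags.append("E3D-undetermined-no-bulk-fret")
    return RotationalEstimate(
        E_2d=E_2d,
        E_3d=E_3d,
        valid=valid,
        per_ligand_K_A=K_A_per,
        per_ligand_E_2d=e2d_per,
        flags=tuple(flags),
    )
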