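"""Exact stochastic counterpart of the five-species binding model.

A Gillespie direct-method simulator for the reaction scheme
``R + L <=> RL* <=> RL <=> C`` in terms of molecule counts.  The
bimolecular encounter propensity is ``d+ * nR * nL / omega`` where
``omega`` is the system size (reaction volume x Avogadro in 3D, contact
area x Avogadro in 2D), so that counts/omega reproduces the deterministic
concentration units and the mean over replicates converges to the ODE
solution.

Single-molecule assay synthesis (bond lifetimes, adhesion tests) is built
on this engine or on exact distributional shortcuts verified against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import FundamentalConstants

__all__ = ["StochasticResult", "stochastic_simulate", "counts_at"]

#: reaction index -> count increments (R, L, RL*, RL, C)
_STOICH = np.array(
    [
        [-1, -1, +1, 0, 0],  # R + L -> RL*
        [+1, +1, -1, 0, 0],  # RL* -> R + L
        [0, 0, -1, +1, 0],  # RL* -> RL
        [0, 0, +1, -1, 0],  # RL -> RL*
        [0, 0, 0, -1, +1],  # RL -> C
        [0, 0, 0, +1, -1],  # C -> RL
    ],
    dtype=np.int64,
)


@dataclass
class StochasticResult:
    """Event list of one stochastic realisation.

    ``event_times`` and ``event_kinds`` are parallel arrays; kind ``i``
    indexes the reaction rows of the scheme (0: encounter, 1: separation,
    2: orientation, 3: de-orientation, 4: binding, 5: unbinding).
    """

    event_times: np.ndarray
    event_kinds: np.ndarray
    initial_counts: np.ndarray
    t_max: float
    omega: float
    seed: int

    def __len__(self) -> int:
        return self.event_times.size


def stochastic_simulate(
    params: FundamentalConstants,
    initial_counts,
    omega: float,
    t_max: float,
    seed: int,
) -> StochasticResult:
    """Run one exact realisation up to ``t_max``.

    Parameters
    ----------
    initial_counts
        Length-5 integer counts (R, L, RL*, RL, C).
    omega
        System size converting counts to concentration (counts / omega);
        must be > 0 whenever the bimolecular step can fire.
    seed
        Required; the same seed reproduces the event list exactly.
    """
    n = np.asarray(initial_counts, dtype=np.int64)
    if n.shape != (5,) or np.any(n < 0):
        raise ValueError("initial_counts must be 5 non-negative integers")
    if omega <= 0 and params.d_plus > 0 and n[0] > 0 and n[1] > 0:
        raise ValueError("omega must be > 0 when the bimolecular step is active")

    rng = np.random.default_rng(seed)
    dp, dm = params.d_plus, params.d_minus
    ep, em = params.e_plus, params.e_minus
    kp, km = params.k_plus, params.k_minus
    inv_omega = 1.0 / omega if omega > 0 else 0.0

    t = 0.0
    nR, nL, nRLs, nRL, nC = (int(x) for x in n)
    times: list[float] = []
    kinds: list[int] = []
    a = np.empty(6)
    while True:
        a[0] = dp * nR * nL * inv_omega
        a[1] = dm * nRLs
        a[2] = ep * nRLs
        a[3] = em * nRL
        a[4] = kp * nRL
        a[5] = km * nC
        a_tot = a.sum()
        if a_tot <= 0.0:
            break
        t += rng.exponential(1.0 / a_tot)
        if t > t_max:
            break
        r = rng.random() * a_tot
        k = 0
        acc = a[0]
        while acc < r and k < 5:
            k += 1
            acc += a[k]
        if k == 0:
            nR -= 1; nL -= 1; nRLs += 1
        elif k == 1:
            nR += 1; nL += 1; nRLs -= 1
        elif k == 2:
            nRLs -= 1; nRL += 1
        elif k == 3:
            nRLs += 1; nRL -= 1
        elif k == 4:
            nRL -= 1; nC += 1
        else:
            nRL += 1; nC -= 1
        times.append(t)
        kinds.append(k)
    return StochasticResult(
        event_times=np.array(times),
        event_kinds=np.array(kinds, dtype=np.int64),
        initial_counts=n,
        t_max=t_max,
        omega=omega,
        seed=seed,
    )


def counts_at(result: StochasticResult, times) -> np.ndarray:
    """Reconstruct species counts at the requested times.

    Returns an array of shape (len(times), 5).  Times beyond ``t_max``
    are rejected.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times > result.t_max) or np.any(times < 0):
        raise ValueError("requested times outside [0, t_max]")
    if len(result) == 0:
        return np.tile(result.initial_counts, (times.size, 1))
    deltas = _STOICH[result.event_kinds]
    cum = np.concatenate(
        [result.initial_counts[None, :], result.initial_counts + np.cumsum(deltas, axis=0)]
    )
    idx = np.searchsorted(result.event_times, times, side="right")
    return cum[idx]
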