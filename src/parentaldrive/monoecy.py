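"""Closed-form recursions and analytics for the monoecious partial-selfing model.

A monoecious population of self- and cross-compatible hermaphrodites selfs
with fixed probability S and mates at random with probability 1 - S. Each
allele at a biallelic locus may carry a parental-effect toxin-antidote
element with killing penetrance k1 (allele M1) or k2 (allele M2). Under
monoecy, maternal-effect (*Medea*) and paternal-effect (*peel*) elements
yield identical recursions, so all results here depend only on the effective
penetrances.

The genotype-frequency recursion, its (p, Y) change of variables, the
internal allele-frequency equilibrium and equilibrium heterozygosity, and the
critical selfing rate / critical penetrance ratio for invasion are all
implemented in closed form; every one of them is validated elsewhere against
the brute-force mating-table oracle.

Allele-frequency functions accept numpy arrays and broadcast, which the
threshold grid searches rely on.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np

from .mating_engine import (
    DegeneratePopulationError,
    DriveParams,
    MonoeciousState,
)

__all__ = [
    "step",
    "step_pY",
    "mean_fitness",
    "implicit_equilibrium_residual",
    "internal_equilibrium_p",
    "equilibrium_Y",
    "equilibrium_Y_fixed_point",
    "critical_selfing",
    "critical_ratio",
    "delta_p",
    "neutral_fixation_index",
]


def step(state: MonoeciousState, params: DriveParams) -> MonoeciousState:
    """One generation of the genotype-frequency recursion.

    The M1M1 class in the next generation collects unkilled M1M1 progeny of
    selfed heterozygotes and of every outcross that can yield M1M1 (and
    symmetrically for M2M2); heterozygous progeny are never killed because
    they carry both antidotes.
    """
    X, Y, Z = state.X, state.Y, state.Z
    k1, k2, S = params.k1_eff, params.k2_eff, params.S
    o = 1.0 - S
    Xn = S * (X + Y * (1 - k2) / 4) + o * (X**2 + X * Y * (1 - k2 / 2) + Y**2 * (1 - k2) / 4)
    Yn = S * Y / 2 + o * (2 * X * Z + Y * (1 - Y / 2))
    Zn = S * (Z + Y * (1 - k1) / 4) + o * (Z**2 + Y * Z * (1 - k1 / 2) + Y**2 * (1 - k1) / 4)
    wbar = Xn + Yn + Zn
    if wbar <= 0.0:
        raise DegeneratePopulationError(f"mean fitness {wbar} <= 0 under {params}")
    return MonoeciousState(X=Xn / wbar, Y=Yn / wbar, Z=Zn / wbar).renormalized()


def mean_fitness(p, Y, params: DriveParams):
    """Population mean fitness w-bar as a function of p and Y.

    w-bar = 1 - (Y/2) [k1 (S/2 + (1-S) q) + k2 (S/2 + (1-S) p)]: each toxin
    removes the unprotected homozygous progeny of heterozygous toxin-source
    parents, weighted by how often those parents self versus meet the
    susceptible homozygote in an outcross.
    """
    k1, k2, S = params.k1_eff, params.k2_eff, params.S
    q = 1.0 - np.asarray(p, dtype=float)
    return 1.0 - (np.asarray(Y, dtype=float) / 2.0) * (
        k1 * (S / 2 + (1 - S) * q) + k2 * (S / 2 + (1 - S) * np.asarray(p))
    )


def step_pY(p, Y, params: DriveParams):
    """One generation in (allele frequency, heterozygosity) coordinates.

    Returns ``(p', Y', wbar)``. Identical dynamics to :func:`step` under the
    mapping p = X + Y/2. Accepts scalars or arrays (broadcast together).
    """
    p = np.asarray(p, dtype=float)
    Y = np.asarray(Y, dtype=float)
    k2, S = params.k2_eff, params.S
    q = 1.0 - p
    wbar = mean_fitness(p, Y, params)
    if np.any(wbar <= 0.0):
        raise DegeneratePopulationError(f"mean fitness <= 0 under {params}")
    pn = (p - (Y * k2 / 2.0) * (S / 2 + (1 - S) * p)) / wbar
    Yn = (S * Y / 2.0 + (1 - S) * 2.0 * p * q) / wbar
    if pn.ndim == 0:
        return float(pn), float(Yn), float(wbar)
    return pn, Yn, wbar


def delta_p(p: float, Y: float, params: DriveParams) -> float:
    """Per-generation change in M1 frequency, p' - p.

    Defined operationally from :func:`step_pY`. For equal penetrances and
    0 < S < 1 the sign exhibits positive frequency dependence: negative below
    p = 0.5, zero at 0.5, positive above (whenever Y > 0).
    """
    pn, _, _ = step_pY(p, Y, params)
    return pn - p


def implicit_equilibrium_residual(p, S: float, r: float):
    """Residual of the implicit internal-equilibrium condition.

    p [1 + r (S/2 + q - Sq) / (S/2 + p - Sp)] - 1 = 0 at an internal
    equilibrium. The equilibrium is independent of heterozygosity Y and
    depends on the penetrances only through their ratio r = k1/k2.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    A = S / 2 + q - S * q
    B = S / 2 + p - S * p
    return p * (1.0 + r * A / B) - 1.0


def internal_equilibrium_p(S: float, r: float) -> Optional[float]:
    """Unstable internal allele-frequency equilibrium p-hat, or None.

    Solves the quadratic form of the implicit equilibrium condition,
    (1-S)(1-r) p^2 + [S(1+r)/2 + (r-1)(1-S)] p - S/2 = 0, and returns the
    root in (0, 1). Limits are taken analytically: r = 1 gives 0.5 for any S
    (at S = 0 every frequency is neutral and 0.5 is the limiting threshold);
    S = 1 gives 1/(1+r); S = 0 with r != 1 has no internal equilibrium (the
    more penetrant element always sweeps) and returns None.
    """
    if r <= 0.0:
        raise ValueError(f"penetrance ratio r must be > 0, got {r}")
    if not 0.0 <= S <= 1.0:
        raise ValueError(f"S must be in [0, 1], got {S}")
    if r == 1.0:
        return 0.5
    if S == 0.0:
        return None
    if S == 1.0:
        return 1.0 / (1.0 + r)
    a = (1 - S) * (1 - r)
    b = S * (1 + r) / 2 + (r - 1) * (1 - S)
    c = -S / 2
    disc = b * b - 4 * a * c
    if disc < 0.0:
        return None
    # numerically stable quadratic roots (avoids cancellation as S -> 1)
    qq = -0.5 * (b + math.copysign(math.sqrt(disc), b))
    roots = [qq / a, c / qq]
    interior = [x for x in roots if 0.0 < x < 1.0]
    if not interior:
        return None
    phat = interior[0]
    # The returned root must zero the implicit condition; anything else is a bug.
    assert abs(float(implicit_equilibrium_residual(phat, S, r))) < 1e-10
    return phat


def equilibrium_Y(p: float, params: DriveParams) -> float:
    """Equilibrium heterozygosity Y-hat at a held allele frequency p.

    Y-hat = [1 - S/2 - sqrt(S^2/4 + (1-S) + (S-1) 4 p q K)] / K with
    K = k1 (S/2 + q - Sq) + k2 (S/2 + p - Sp). This is the stable fixed
    point of the heterozygosity recursion Y' (p pinned); at p = 0.5 with
    k1 = k2 = k it reduces to K = k. S = 1 gives Y-hat = 0 exactly.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    k1, k2, S = params.k1_eff, params.k2_eff, params.S
    q = 1.0 - p
    K = k1 * (S / 2 + q - S * q) + k2 * (S / 2 + p - S * p)
    if K <= 0.0:
        raise ValueError(f"K = {K} <= 0: no toxin acts, heterozygosity is neutral")
    disc = S * S / 4 + (1 - S) + (S - 1) * 4 * p * q * K
    if disc < 0.0:
        raise ValueError(
            f"negative discriminant {disc} for p={p}, k1={k1}, k2={k2}, S={S}"
        )
    return (1 - S / 2 - math.sqrt(disc)) / K


def equilibrium_Y_fixed_point(
    p: float,
    params: DriveParams,
    tol: float = 1e-10,
    max_iter: int = 10**6,
    damping: float = 0.5,
) -> float:
    """Equilibrium heterozygosity by damped fixed-point iteration at pinned p.

    Independent dynamical confirmation of :func:`equilibrium_Y`: iterates
    Y <- (1-d) Y + d [S Y/2 + (1-S) 2 p q] / wbar(Y) until successive values
    differ by less than ``tol``.
    """
    q = 1.0 - p
    S = params.S
    Y = 2.0 * p * q  # Hardy-Weinberg start
    for _ in range(max_iter):
        Yn = (S * Y / 2.0 + (1 - S) * 2.0 * p * q) / float(mean_fitness(p, Y, params))
        Yn = (1.0 - damping) * Y + damping * Yn
        if abs(Yn - Y) < tol:
            return Yn
        Y = Yn
    raise RuntimeError(f"fixed-point iteration did not converge within {max_iter}")


def critical_selfing(p: float, r: float) -> Optional[float]:
    """Critical selfing rate S_C above which an invader at frequency p fails.

    S_C = 2p(1-p)(1-r) / (2 p^2 r - 2 p^2 - p r + 3 p - 1). An invading
    element with penetrance ratio r relative to the resident is eliminated
    whenever S exceeds S_C. Equal penetrances (r = 1) give S_C = 0. Returns
    None when the expression has no finite value in [0, 1] (no selfing rate
    separates invasion from elimination at this frequency).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if r <= 0.0:
        raise ValueError(f"r must be > 0, got {r}")
    if r == 1.0:
        return 0.0
    den = 2 * p * p * r - 2 * p * p - p * r + 3 * p - 1
    if den == 0.0:
        return None
    sc = 2 * p * (1 - p) * (1 - r) / den
    if not 0.0 <= sc <= 1.0:
        return None
    return sc


def critical_ratio(p: float, S: float) -> float:
    """Critical penetrance ratio r_C an invader at frequency p must exceed.

    r_C = [S + 2p(1-p)(1-S) - Sp] / [2p(1-p)(1-S) + Sp]. Under obligate
    outcrossing (S = 0) r_C = 1: the stronger element always sweeps. As
    S -> 1 or p -> 0 the threshold diverges; S = 1 and (p = 0, S > 0) return
    +inf.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"p must be in [0, 1), got {p}")
    if not 0.0 <= S <= 1.0:
        raise ValueError(f"S must be in [0, 1], got {S}")
    if S == 1.0:
        return math.inf
    if p == 0.0:
        return math.inf if S > 0.0 else 1.0
    num = S + 2 * p * (1 - p) * (1 - S) - S * p
    den = 2 * p * (1 - p) * (1 - S) + S * p
    return num / den


def neutral_fixation_index(S: float) -> float:
    """Equilibrium fixation index of a neutral locus under partial selfing.

    F-hat_0 = S / (2 - S); the extended Hardy-Weinberg heterozygosity is
    2 p q (1 - F-hat_0).
    """
    if not 0.0 <= S <= 1.0:
        raise ValueError(f"S must be in [0, 1], got {S}")
    return S / (2.0 - S)
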