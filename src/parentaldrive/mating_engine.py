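"""First-principles enumeration of matings, segregation, and toxin-mediated killing.

Parental-effect toxin-antidote elements (*Medea*: maternal-effect, *peel*:
paternal-effect) act through a parent's genotype: a parent heterozygous or
homozygous for a driving allele loads every gamete/egg with a toxin, and only
zygotes that inherit at least one copy of that allele (and hence its zygotic
antidote) escape. This module enumerates every mating type in a partially
selfing population, applies Mendelian segregation and toxin survival factors,
and steps genotype frequencies one generation forward by brute force. It is
the generative source of the closed-form recursions implemented in
:mod:`parentaldrive.monoecy` and :mod:`parentaldrive.androdioecy`, and serves
as the independent oracle those closed forms are tested against.

Genotypes are encoded as counts of the M1 allele: 2 (M1M1), 1 (M1M2),
0 (M2M2). All logic is count-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "MATERNAL",
    "PATERNAL",
    "NONE",
    "DriveParams",
    "MonoeciousState",
    "CrossOutcome",
    "DegeneratePopulationError",
    "zygote_survival",
    "build_mating_table",
    "oracle_step",
    "transmission_tensor",
    "survival_tensor",
]

MATERNAL = "maternal"
PATERNAL = "paternal"
NONE = "none"

_ELEMENT_TYPES = (MATERNAL, PATERNAL, NONE)

#: Simplex sum must stay within this of 1 after a step before renormalizing.
RENORM_TOL = 1e-12
#: Hard failure: a simplex this far off 1 indicates a bug, not float drift.
RENORM_HARD_TOL = 1e-9


class DegeneratePopulationError(RuntimeError):
    """Raised when mean fitness is zero: every zygote in the population dies.

    Requires fully penetrant toxins and a population composed exclusively of
    affected matings; it signals a biologically impossible parameterization
    rather than a numerical problem.
    """


@dataclass(frozen=True)
class DriveParams:
    """Parameters of a biallelic parental-effect toxin-antidote locus.

    Attributes
    ----------
    k1, k2:
        Killing penetrance of the toxin carried by allele M1 / M2, in [0, 1]:
        the probability that a zygote lacking the allele dies when the
        toxin-source parent carries it.
    type1, type2:
        Which parent delivers each allele's toxin: ``"maternal"`` (*Medea*,
        egg parent), ``"paternal"`` (*peel*, sperm parent), or ``"none"``
        (no toxin; the corresponding penetrance is treated as 0).
    S:
        Selfing rate: fixed fraction of broods produced by self-fertilization.
    b:
        Outcross-to-self hermaphrodite-brood ratio (androdioecy only):
        hermaphrodite offspring per outcross brood relative to a selfed
        brood. b = 1/2 encodes the two-fold cost of males.
    """

    k1: float = 0.0
    k2: float = 0.0
    type1: str = MATERNAL
    type2: str = MATERNAL
    S: float = 0.0
    b: float = 1.0

    def __post_init__(self) -> None:
        for name, k in (("k1", self.k1), ("k2", self.k2)):
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {k}")
        if not 0.0 <= self.S <= 1.0:
            raise ValueError(f"S must be in [0, 1], got {self.S}")
        if not self.b > 0.0:
            raise ValueError(f"b must be > 0, got {self.b}")
        for name, t in (("type1", self.type1), ("type2", self.type2)):
            if t not in _ELEMENT_TYPES:
                raise ValueError(f"{name} must be one of {_ELEMENT_TYPES}, got {t!r}")

    @property
    def k1_eff(self) -> float:
        """Penetrance of M1's toxin; 0 when M1 carries no element."""
        return 0.0 if self.type1 == NONE else self.k1

    @property
    def k2_eff(self) -> float:
        """Penetrance of M2's toxin; 0 when M2 carries no element."""
        return 0.0 if self.type2 == NONE else self.k2

    @property
    def r(self) -> float:
        """Penetrance ratio r = k1/k2 (invader relative to resident)."""
        return self.k1_eff / self.k2_eff

    def with_(self, **kwargs) -> "DriveParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MonoeciousState:
    """Genotype frequencies (X, Y, Z) of (M1M1, M1M2, M2M2) on the 2-simplex."""

    X: float
    Y: float
    Z: float

    def __post_init__(self) -> None:
        total = self.X + self.Y + self.Z
        if abs(total - 1.0) > RENORM_HARD_TOL:
            raise ValueError(f"genotype frequencies sum to {total}, not 1")
        if min(self.X, self.Y, self.Z) < -RENORM_HARD_TOL:
            raise ValueError(f"negative genotype frequency in {self}")

    @classmethod
    def from_vector(cls, v) -> "MonoeciousState":
        """Build from frequencies indexed by M1-allele count (0, 1, 2)."""
        v = np.asarray(v, dtype=float)
        return cls(X=float(v[2]), Y=float(v[1]), Z=float(v[0]))

    @classmethod
    def from_pY(cls, p: float, Y: float) -> "MonoeciousState":
        """Build from allele frequency p and heterozygosity Y.

        Requires Y <= 2*min(p, 1-p) so that both homozygote frequencies are
        non-negative.
        """
        X = p - Y / 2.0
        Z = (1.0 - p) - Y / 2.0
        if min(X, Z) < -RENORM_HARD_TOL:
            raise ValueError(f"(p={p}, Y={Y}) lies outside the genotype simplex")
        return cls(X=max(X, 0.0), Y=Y, Z=max(Z, 0.0))

    def to_vector(self) -> np.ndarray:
        """Frequencies indexed by M1-allele count (0, 1, 2) = (Z, Y, X)."""
        return np.array([self.Z, self.Y, self.X], dtype=float)

    @property
    def p(self) -> float:
        """Frequency of the M1 allele, p = X + Y/2."""
        return self.X + self.Y / 2.0

    @property
    def q(self) -> float:
        """Frequency of the M2 allele."""
        return 1.0 - self.p

    def renormalized(self) -> "MonoeciousState":
        v = np.clip(self.to_vector(), 0.0, None)
        total = v.sum()
        if abs(total - 1.0) > RENORM_HARD_TOL:
            raise ValueError(f"simplex drift {abs(total - 1.0):.3e} exceeds hard limit")
        return MonoeciousState.from_vector(v / total)


@dataclass
class CrossOutcome:
    """One row of the mating table.

    ``survivors`` maps zygote genotype (M1 count) to Mendelian fraction x
    toxin survival; its values are <= the Mendelian fractions, with equality
    iff no toxin applies to that zygote class.
    """

    egg_genotype: int
    sperm_genotype: int
    selfing: bool
    frequency: float
    survivors: Dict[int, float] = field(default_factory=dict)

    @property
    def total_surviving(self) -> float:
        return self.frequency * sum(self.survivors.values())


def transmission_tensor() -> np.ndarray:
    """Mendelian segregation probabilities T[egg, sperm, zygote].

    Indices are M1-allele counts (0..2). T[e, s, z] is the probability that
    an egg parent with e copies and a sperm parent with s copies produce a
    zygote with z copies.
    """
    T = np.zeros((3, 3, 3))
    for e in range(3):
        for s in range(3):
            pe = e / 2.0  # P(egg gamete carries M1)
            ps = s / 2.0
            T[e, s, 0] = (1 - pe) * (1 - ps)
            T[e, s, 1] = pe * (1 - ps) + (1 - pe) * ps
            T[e, s, 2] = pe * ps
    return T


def survival_tensor(params: DriveParams) -> np.ndarray:
    """Zygote survival probabilities W[egg_parent, sperm_parent, zygote].

    For each allele i the toxin-source parent (egg parent for maternal
    elements, sperm parent for paternal ones) poisons the brood whenever it
    carries at least one copy of Mi; zygotes with zero copies of Mi lack the
    antidote and die with probability ki. Two simultaneously active toxins
    act independently, so their survival factors multiply. Under selfing the
    egg and sperm parent are the same individual, so callers simply pass the
    hermaphrodite's genotype in both slots.
    """
    W = np.ones((3, 3, 3))
    specs = [
        # (penetrance, source, carrier test on M1-count, zygote-lacks test)
        (params.k1_eff, params.type1, lambda c: c >= 1, lambda z: z == 0),
        (params.k2_eff, params.type2, lambda c: 2 - c >= 1, lambda z: z == 2),
    ]
    for k, source, carries, lacks in specs:
        if k == 0.0 or source == NONE:
            continue
        for e in range(3):
            for s in range(3):
                toxin_parent = e if source == MATERNAL else s
                if not carries(toxin_parent):
                    continue
                for z in range(3):
                    if lacks(z):
                        W[e, s, z] *= 1.0 - k
    return W


def zygote_survival(
    egg_parent: int, sperm_parent: int, zygote: int, params: DriveParams
) -> float:
    """Survival probability of one zygote class from one mating type.

    Genotypes are M1-allele counts in {0, 1, 2}. Raises ``ValueError`` for a
    zygote that Mendelian segregation of the two parents cannot produce.
    """
    for name, g in (("egg_parent", egg_parent), ("sperm_parent", sperm_parent),
                    ("zygote", zygote)):
        if g not in (0, 1, 2):
            raise ValueError(f"{name} must be an M1-allele count in {{0,1,2}}, got {g}")
    if transmission_tensor()[egg_parent, sperm_parent, zygote] == 0.0:
        raise ValueError(
            f"zygote {zygote} cannot arise from parents ({egg_parent}, {sperm_parent})"
        )
    return float(survival_tensor(params)[egg_parent, sperm_parent, zygote])


def build_mating_table(
    state: MonoeciousState, params: DriveParams
) -> List[CrossOutcome]:
    """Enumerate the 3 selfing and 9 outcross mating types of one generation.

    Selfing rows have frequency S * (parental genotype frequency); outcross
    rows have frequency (1 - S) * (egg freq) * (sperm freq), with both
    parents drawn from the same hermaphrodite pool. The sum of all surviving
    weights over the table is the population mean fitness.
    """
    T = transmission_tensor()
    W = survival_tensor(params)
    v = state.to_vector()
    rows: List[CrossOutcome] = []
    for g in range(3):
        surv = {z: float(T[g, g, z] * W[g, g, z]) for z in range(3) if T[g, g, z] > 0}
        rows.append(CrossOutcome(g, g, True, params.S * v[g], surv))
    for e in range(3):
        for s in range(3):
            surv = {
                z: float(T[e, s, z] * W[e, s, z]) for z in range(3) if T[e, s, z] > 0
            }
            rows.append(CrossOutcome(e, s, False, (1.0 - params.S) * v[e] * v[s], surv))
    return rows


def oracle_step(state: MonoeciousState, params: DriveParams) -> MonoeciousState:
    """One generation of the monoecious model by brute-force enumeration.

    Sums surviving-progeny weights over the full mating table and normalizes
    by mean fitness. Must agree with the closed-form recursions in
    :mod:`parentaldrive.monoecy` to machine precision.
    """
    offspring = np.zeros(3)
    for row in build_mating_table(state, params):
        for z, w in row.survivors.items():
            offspring[z] += row.frequency * w
    wbar = offspring.sum()
    if wbar <= 0.0:
        raise DegeneratePopulationError(
            f"mean fitness is {wbar}; every zygote dies under {params}"
        )
    return MonoeciousState.from_vector(offspring / wbar).renormalized()
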