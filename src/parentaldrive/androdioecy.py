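"""Sex-structured recursions for the *Caenorhabditis* androdioecious mating system.

Hermaphrodites (XX) self with probability S or mate with males with
probability 1 - S; hermaphrodites cannot mate with one another. Self broods
are entirely hermaphrodite; outcross broods are half male (X0), half
hermaphrodite, and each half is scaled by the outcross-brood parameter b
relative to a selfed brood (b = 1/2 is the two-fold cost of males; males
from X nondisjunction in selfers are ignored). Because males arise only
from outcrossing, male heterozygosity exceeds hermaphrodite heterozygosity
under partial selfing, which is why paternal-effect (*peel*) elements and
maternal-effect (*Medea*) elements no longer behave identically here.

The one-generation step is generated from the same mating-engine tensors
that power the monoecious oracle, extended with sex labels and brood
weights: *Medea* toxins key to the egg parent (always a hermaphrodite),
*peel* toxins to the sperm parent (the male in an outcross, the selfing
hermaphrodite itself in a self). The module also implements the numerical
invasion-threshold estimator: scan a grid of starting frequencies, iterate
for a fixed horizon, and locate the boundary between starting points that
decline and ones that advance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence

import numpy as np

from .mating_engine import (
    DegeneratePopulationError,
    DriveParams,
    MATERNAL,
    MonoeciousState,
    PATERNAL,
    RENORM_HARD_TOL,
    survival_tensor,
    transmission_tensor,
)

__all__ = [
    "AndrodioeciousState",
    "ELEMENT_CONFIGS",
    "step_andro",
    "population_allele_frequency",
    "numerical_threshold",
    "equilibrium_male_ratio",
]

logger = logging.getLogger(__name__)

#: element_config -> (type1, type2): invader allele M1 listed first.
ELEMENT_CONFIGS: Dict[str, tuple] = {
    "medea-medea": (MATERNAL, MATERNAL),
    "peel-peel": (PATERNAL, PATERNAL),
    "peel-vs-medea": (PATERNAL, MATERNAL),  # peel invader, Medea resident
    "medea-vs-peel": (MATERNAL, PATERNAL),  # Medea invader, peel resident
}


def equilibrium_male_ratio(S: float, b: float) -> float:
    """Male:hermaphrodite census ratio in the absence of killing.

    Each hermaphrodite contributes S + (1-S) b hermaphrodite offspring and
    (1-S) b male offspring, so the ratio is (1-S) b / (S + (1-S) b).
    """
    return (1 - S) * b / (S + (1 - S) * b)


@dataclass(frozen=True)
class AndrodioeciousState:
    """Sex-specific genotype frequencies plus the male:hermaphrodite ratio.

    (Xh, Yh, Zh) and (Xm, Ym, Zm) are the (M1M1, M1M2, M2M2) frequencies
    within hermaphrodites and males respectively; each triple sums to 1.
    ``m_ratio`` is the male-to-hermaphrodite census ratio, needed only for
    the sex-weighted population allele frequency.
    """

    Xh: float
    Yh: float
    Zh: float
    Xm: float
    Ym: float
    Zm: float
    m_ratio: float = 0.0

    def __post_init__(self) -> None:
        for label, total in (("hermaphrodite", self.Xh + self.Yh + self.Zh),
                             ("male", self.Xm + self.Ym + self.Zm)):
            if abs(total - 1.0) > RENORM_HARD_TOL:
                raise ValueError(f"{label} frequencies sum to {total}, not 1")
        if self.m_ratio < 0.0:
            raise ValueError(f"m_ratio must be >= 0, got {self.m_ratio}")

    @classmethod
    def from_monoecious(
        cls, state: MonoeciousState, m_ratio: float = 0.0
    ) -> "AndrodioeciousState":
        """Identical genotype frequencies in both sexes."""
        return cls(state.X, state.Y, state.Z, state.X, state.Y, state.Z, m_ratio)

    @classmethod
    def homozygote_mixture(
        cls, p: float, params: Optional[DriveParams] = None
    ) -> "AndrodioeciousState":
        """Pure-homozygote start: X = p, Y = 0, Z = 1 - p, identical in both
        sexes (the migration scenario: mixing two populations each fixed for
        one allele). The initial male ratio defaults to the no-killing
        equilibrium for the given parameters, 0 if none are given."""
        m = equilibrium_male_ratio(params.S, params.b) if params is not None else 0.0
        return cls(p, 0.0, 1.0 - p, p, 0.0, 1.0 - p, m)

    def herm_vector(self) -> np.ndarray:
        return np.array([self.Zh, self.Yh, self.Xh], dtype=float)

    def male_vector(self) -> np.ndarray:
        return np.array([self.Zm, self.Ym, self.Xm], dtype=float)

    @property
    def ph(self) -> float:
        return self.Xh + self.Yh / 2.0

    @property
    def pm(self) -> float:
        return self.Xm + self.Ym / 2.0


def population_allele_frequency(state: AndrodioeciousState) -> float:
    """Sex-weighted average allele frequency.

    Weights are proportional to each sex's census contribution: 1 for
    hermaphrodites, m_ratio for males; equals ph when m_ratio = 0.
    """
    m = state.m_ratio
    return (state.ph + m * state.pm) / (1.0 + m)


def _brood_tensors(params: DriveParams):
    """(selfing, outcross) progeny tensors: Mendelian fraction x survival.

    ``TWs[g, z]``: selfing hermaphrodite of genotype g -> surviving zygote z
    (egg and sperm parent are the same individual, so paternal toxins key to
    the hermaphrodite itself). ``TWx[g, g', z]``: hermaphrodite egg parent g
    crossed to male sperm parent g'.
    """
    T = transmission_tensor()
    W = survival_tensor(params)
    TWx = T * W
    TWs = np.array([TWx[g, g, :] for g in range(3)])
    return TWs, TWx


def _step_arrays(H: np.ndarray, M: np.ndarray, params: DriveParams):
    """Vectorized one-generation step on batches of states.

    H, M: arrays of shape (..., 3) of hermaphrodite / male genotype
    frequencies indexed by M1-allele count. Returns (H', M', wh, wm) where
    wh and wm are the per-hermaphrodite surviving brood weights of the
    hermaphrodite and male offspring pools.
    """
    TWs, TWx = _brood_tensors(params)
    S, b = params.S, params.b
    selfed = np.einsum("...g,gz->...z", H, TWs)
    crossed = np.einsum("...g,...h,ghz->...z", H, M, TWx)
    herm_raw = S * selfed + (1 - S) * b * crossed
    male_raw = (1 - S) * b * crossed
    wh = herm_raw.sum(axis=-1)
    wm = male_raw.sum(axis=-1)
    if np.any(wh <= 0.0):
        raise DegeneratePopulationError(
            f"hermaphrodite pool extinguished (mean brood weight <= 0) under {params}"
        )
    Hn = herm_raw / wh[..., None]
    # With S = 1 (or a fully killed outcross pool) there are no males; carry
    # the old male frequencies, which get zero weight everywhere they matter.
    safe = np.where(wm[..., None] > 0.0, wm[..., None], 1.0)
    Mn = np.where(wm[..., None] > 0.0, male_raw / safe, M)
    return Hn, Mn, wh, wm


def step_andro(state: AndrodioeciousState, params: DriveParams) -> AndrodioeciousState:
    """One generation of the androdioecious recursions.

    Hermaphrodite pool: selfed broods (weight S) plus the hermaphrodite half
    of outcross broods (weight (1-S) b); male pool: the male half of outcross
    broods only. Sperm-parent genotypes in outcrosses are drawn from the male
    genotype distribution. The census ratio is updated from the relative
    surviving weights of the two pools.
    """
    H, M = state.herm_vector(), state.male_vector()
    Hn, Mn, wh, wm = _step_arrays(H, M, params)
    Hn = np.clip(Hn, 0.0, None)
    Hn /= Hn.sum()
    Mn = np.clip(Mn, 0.0, None)
    Mn /= Mn.sum()
    return AndrodioeciousState(
        Xh=float(Hn[2]), Yh=float(Hn[1]), Zh=float(Hn[0]),
        Xm=float(Mn[2]), Ym=float(Mn[1]), Zm=float(Mn[0]),
        m_ratio=float(wm / wh) if wm > 0 else 0.0,
    )


def _batch_population_p(H: np.ndarray, M: np.ndarray, m_ratio: np.ndarray):
    counts = np.array([0.0, 0.5, 1.0])
    ph = H @ counts
    pm = M @ counts
    return (ph + m_ratio * pm) / (1.0 + m_ratio)


def numerical_threshold(
    params: DriveParams,
    element_config: str = "medea-medea",
    S_grid: Optional[Sequence[float]] = None,
    freq_grid: Optional[Sequence[float]] = None,
    horizon: int = 100,
    model: str = "androdioecy",
) -> Dict[float, float]:
    """Invasion-threshold frequencies by grid search over starting frequency.

    For each selfing rate S on the grid, start pure-homozygote populations
    (identical in both sexes) at every frequency on ``freq_grid``, iterate
    ``horizon`` generations, and classify each start by whether the allele
    frequency ended higher or lower than it began. The returned boundary for
    each S is the lowest starting frequency that advances (the first sign
    change along the grid); NaN if no starting frequency advances. Defaults:
    frequencies 0.001..0.999 step 0.001, selfing rates 0..0.99 step 0.01,
    horizon 100 generations.

    ``model="monoecy"`` runs the same scan on the monoecious closed-form
    recursion (used to validate the scan against the analytic equilibrium);
    ``element_config`` selects maternal/paternal identity of the invader
    (allele M1) and resident (M2).

    A non-monotone classification along the frequency grid is logged and the
    first sign change is still returned.
    """
    from . import monoecy  # local import to avoid cycle

    if element_config not in ELEMENT_CONFIGS:
        raise ValueError(
            f"element_config must be one of {sorted(ELEMENT_CONFIGS)}, got {element_config!r}"
        )
    type1, type2 = ELEMENT_CONFIGS[element_config]
    if S_grid is None:
        S_grid = np.round(np.arange(0.0, 0.991, 0.01), 10)
    if freq_grid is None:
        freq_grid = np.round(np.arange(0.001, 0.9991, 0.001), 10)
    freq_grid = np.asarray(freq_grid, dtype=float)

    thresholds: Dict[float, float] = {}
    for S in S_grid:
        pars = replace(params, S=float(S), type1=type1, type2=type2)
        p0 = freq_grid
        if model == "monoecy":
            p, Y = p0.copy(), np.zeros_like(p0)
            for _ in range(horizon):
                p, Y, _ = monoecy.step_pY(p, Y, pars)
            final = p
        elif model == "androdioecy":
            v = np.stack([1.0 - p0, np.zeros_like(p0), p0], axis=-1)
            H, M = v.copy(), v.copy()
            m = np.full(p0.shape, equilibrium_male_ratio(pars.S, pars.b))
            for _ in range(horizon):
                H, M, wh, wm = _step_arrays(H, M, pars)
                m = np.where(wm > 0, wm / wh, 0.0)
            final = _batch_population_p(H, M, m)
        else:
            raise ValueError(f"model must be 'monoecy' or 'androdioecy', got {model!r}")

        advances = final > p0
        idx = np.flatnonzero(advances)
        if idx.size == 0:
            thresholds[float(S)] = float("nan")
            continue
        if not np.all(advances[idx[0]:]):
            logger.warning(
                "non-monotone invasion classification at S=%.3f (%s, %s); "
                "returning first sign change",
                S, element_config, model,
            )
        thresholds[float(S)] = float(p0[idx[0]])
    return thresholds
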