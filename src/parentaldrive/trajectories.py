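"""Iteration driver, trajectory export, and De Finetti (ternary) coordinates.

Everything in the deterministic core is seedless: identical inputs produce
bit-identical trajectories, and the exported tables are diff-able (TSV with
a commented parameter-echo header plus a JSON metadata sidecar).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .mating_engine import DriveParams, MonoeciousState
from . import monoecy
from .androdioecy import (
    AndrodioeciousState,
    numerical_threshold,
    population_allele_frequency,
    step_andro,
)

__all__ = [
    "Trajectory",
    "iterate",
    "ternary_coordinates",
    "hardy_weinberg_curve",
    "neutral_selfing_curve",
    "vector_field",
    "threshold_curves",
    "write_trajectory",
    "read_trajectory",
]

#: |p - 0| or |p - 1| below this counts as fixation.
FIXATION_TOL = 1e-9
#: Cap on open-ended runs.
MAX_GENERATIONS = 10**6

_SQRT3_2 = math.sqrt(3.0) / 2.0


@dataclass
class Trajectory:
    """Ordered per-generation records of a deterministic recursion run.

    ``table`` has one row per generation; ``wbar`` columns hold the mean
    fitness of the step that produced each row (NaN for generation 0).
    ``terminal`` is "fixed_M1", "fixed_M2", or "interior" at tolerance 1e-9.
    """

    model: str
    params: DriveParams
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def terminal(self) -> str:
        p = float(self.table["p"].iloc[-1])
        if p >= 1.0 - FIXATION_TOL:
            return "fixed_M1"
        if p <= FIXATION_TOL:
            return "fixed_M2"
        return "interior"

    @property
    def generations(self) -> int:
        return len(self.table) - 1


def iterate(
    model: str,
    initial_state: Union[MonoeciousState, AndrodioeciousState],
    params: DriveParams,
    generations: int,
    stop_tol: Optional[float] = None,
) -> Trajectory:
    """Iterate the chosen model's one-generation step.

    ``stop_tol`` enables early stopping once the largest per-generation
    change in any recorded state variable falls below it. ``generations``
    must be >= 1 and at most 10^6.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if generations > MAX_GENERATIONS:
        raise ValueError(f"generations capped at {MAX_GENERATIONS}")

    rows: List[dict] = []
    if model == "monoecy":
        if not isinstance(initial_state, MonoeciousState):
            raise TypeError("monoecy model requires a MonoeciousState")
        state = initial_state
        rows.append(_mono_row(0, state, math.nan))
        for g in range(1, generations + 1):
            nxt = monoecy.step(state, params)
            wbar = float(monoecy.mean_fitness(state.p, state.Y, params))
            rows.append(_mono_row(g, nxt, wbar))
            if stop_tol is not None and _max_change(rows[-2], rows[-1]) < stop_tol:
                state = nxt
                break
            state = nxt
    elif model == "androdioecy":
        if not isinstance(initial_state, AndrodioeciousState):
            raise TypeError("androdioecy model requires an AndrodioeciousState")
        astate = initial_state
        rows.append(_andro_row(0, astate))
        for g in range(1, generations + 1):
            nxt = step_andro(astate, params)
            rows.append(_andro_row(g, nxt))
            if stop_tol is not None and _max_change(rows[-2], rows[-1]) < stop_tol:
                astate = nxt
                break
            astate = nxt
    else:
        raise ValueError(f"model must be 'monoecy' or 'androdioecy', got {model!r}")

    table = pd.DataFrame(rows)
    meta = {"model": model, "params": asdict(params),
            "generations_requested": generations, "stop_tol": stop_tol,
            "deterministic": True}
    return Trajectory(model=model, params=params, table=table, metadata=meta)


def _mono_row(gen: int, s: MonoeciousState, wbar: float) -> dict:
    return {"generation": gen, "X": s.X, "Y": s.Y, "Z": s.Z, "p": s.p, "wbar": wbar}


def _andro_row(gen: int, s: AndrodioeciousState) -> dict:
    return {
        "generation": gen, "Xh": s.Xh, "Yh": s.Yh, "Zh": s.Zh,
        "Xm": s.Xm, "Ym": s.Ym, "Zm": s.Zm, "m_ratio": s.m_ratio,
        "ph": s.ph, "pm": s.pm, "p": population_allele_frequency(s),
    }


def _max_change(a: dict, b: dict) -> float:
    return max(
        abs(b[k] - a[k]) for k in a
        if k not in ("generation", "wbar") and not math.isnan(a[k])
    )


# ---------------------------------------------------------------------------
# De Finetti / ternary coordinates


def ternary_coordinates(states) -> np.ndarray:
    """Barycentric -> planar mapping of genotype frequencies.

    Accepts an iterable of ``MonoeciousState`` or an (n, 3) array of
    (X, Y, Z) rows. Corners: M2M2 at (0, 0), M1M1 at (1, 0), M1M2 at the
    apex (1/2, sqrt(3)/2). The x coordinate of a point is then exactly the
    M1 allele frequency p = X + Y/2.
    """
    arr = np.asarray(
        [[s.X, s.Y, s.Z] if isinstance(s, MonoeciousState) else list(s) for s in states],
        dtype=float,
    )
    x = arr[:, 0] + arr[:, 1] / 2.0
    y = arr[:, 1] * _SQRT3_2
    return np.column_stack([x, y])


def hardy_weinberg_curve(n: int = 201) -> np.ndarray:
    """Planar coordinates of the Hardy-Weinberg parabola Y = 2pq."""
    p = np.linspace(0.0, 1.0, n)
    q = 1.0 - p
    return ternary_coordinates(np.column_stack([p * p, 2 * p * q, q * q]))


def neutral_selfing_curve(S: float, n: int = 201) -> np.ndarray:
    """Extended Hardy-Weinberg curve under neutral partial selfing.

    Y = 2pq (1 - F-hat_0) with F-hat_0 = S/(2-S).
    """
    F0 = monoecy.neutral_fixation_index(S)
    p = np.linspace(0.0, 1.0, n)
    q = 1.0 - p
    Y = 2 * p * q * (1.0 - F0)
    return ternary_coordinates(np.column_stack([p - Y / 2, Y, q - Y / 2]))


def vector_field(params: DriveParams, spacing: float = 0.05) -> pd.DataFrame:
    """One-generation displacement field over the genotype simplex.

    Returns a table with the ternary coordinates of each valid grid state
    and of its image one generation later (realizes the De Finetti flow
    portraits of genotype-frequency space).
    """
    pts = []
    n = int(round(1.0 / spacing))
    for i in range(n + 1):
        for j in range(n + 1 - i):
            X, Y = i * spacing, j * spacing
            Z = 1.0 - X - Y
            if Z < -1e-12:
                continue
            state = MonoeciousState(X, Y, max(Z, 0.0))
            nxt = monoecy.step(state, params)
            (x0, y0), = ternary_coordinates([state])
            (x1, y1), = ternary_coordinates([nxt])
            pts.append({"X": X, "Y": Y, "Z": max(Z, 0.0),
                        "x": x0, "y": y0, "dx": x1 - x0, "dy": y1 - y0})
    return pd.DataFrame(pts)


# ---------------------------------------------------------------------------
# Threshold curves


def threshold_curves(
    mode: str,
    S_grid: Sequence[float],
    r_values: Optional[Sequence[float]] = None,
    k_pairs: Optional[Sequence[tuple]] = None,
    element_config: str = "medea-medea",
    b: float = 1.0,
    freq_grid: Optional[Sequence[float]] = None,
    horizon: int = 100,
) -> pd.DataFrame:
    """Invasion-threshold frequencies over an (S, penetrance) grid.

    ``mode="monoecy"`` evaluates the analytic internal equilibrium, which
    depends on the penetrances only through their ratio r (rows may be given
    either as ``r_values`` or explicit ``k_pairs``). ``mode="androdioecy"``
    runs the numerical grid estimator, where the absolute penetrances matter.
    """
    rows = []
    if k_pairs is not None:
        pairs = [(float(k1), float(k2)) for k1, k2 in k_pairs]
    elif r_values is not None:
        pairs = [(min(1.0, float(r)), min(1.0, float(r)) / float(r)) for r in r_values]
    else:
        raise ValueError("provide r_values or k_pairs")

    if mode == "monoecy":
        for k1, k2 in pairs:
            r = k1 / k2
            for S in S_grid:
                rows.append({"mode": mode, "S": float(S), "k1": k1, "k2": k2,
                             "r": r, "p_hat": monoecy.internal_equilibrium_p(float(S), r)})
    elif mode == "androdioecy":
        for k1, k2 in pairs:
            params = DriveParams(k1=k1, k2=k2, b=b)
            th = numerical_threshold(
                params, element_config=element_config, S_grid=S_grid,
                freq_grid=freq_grid, horizon=horizon,
            )
            for S, phat in th.items():
                rows.append({"mode": mode, "S": S, "k1": k1, "k2": k2,
                             "r": k1 / k2, "p_hat": phat})
    else:
        raise ValueError(f"mode must be 'monoecy' or 'androdioecy', got {mode!r}")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write a trajectory as TSV with a commented parameter header.

    A JSON sidecar (``<path>.json``) carries the full metadata. Writing and
    re-reading a trajectory is lossless (values are serialized with repr
    round-trip precision).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# parentaldrive trajectory, model={traj.model}\n")
        for key, val in asdict(traj.params).items():
            fh.write(f"# {key} = {val}\n")
        fh.write(f"# terminal = {traj.terminal}\n")
        traj.table.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({**traj.metadata, "terminal": traj.terminal}, fh, indent=2)
    return path


def read_trajectory(path) -> Trajectory:
    """Re-read a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar) as fh:
        meta = json.load(fh)
    table = pd.read_csv(path, sep="\t", comment="#")
    params = DriveParams(**meta["params"])
    return Trajectory(model=meta["model"], params=params, table=table, metadata=meta)
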