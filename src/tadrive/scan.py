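"""Numerical fate classification, threshold grid scans, and phase-portrait coordinates.

The deterministic maps are bistable under partial selfing: an invading
allele either sweeps or is eliminated depending on whether its starting
frequency is above or below the separatrix. This module locates that
separatrix numerically by iterating the recursions from a grid of
starting frequencies and classifying each fate, mirroring the scan used
for the sex-structured cases where no closed form exists (starting
frequencies 0.001 to 0.999 in steps of 0.001, fate read off after 100
generations, selfing rates 0 to 0.99 in steps of 0.01).

Grid cells are independent; internally whole columns of starting
frequencies are advanced simultaneously with numpy kernels that replicate
the scalar step maps exactly (equivalence is enforced by the test suite),
so results are identical to serial evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .androdioecy import AndroParams, SexState, population_mean_p, step_androdioecious
from .model import Element, GenotypeState, ModelParams, step_monoecious

_EQ_TOL = 1e-12


@dataclass(frozen=True)
class FateResult:
    """Outcome of iterating from one starting state.

    ``fate`` is "fix", "loss", or "undecided"; ``p_final`` the allele
    frequency when iteration stopped; ``generations_run`` the number of
    steps taken.
    """

    fate: str
    p_final: float
    generations_run: int


@dataclass
class ThresholdGrid:
    """Estimated invasion-threshold frequency per selfing rate.

    ``thresholds[i]`` is the midpoint between the largest starting
    frequency classified as loss and the smallest classified as fix at
    ``S_values[i]`` (NaN when the fate never flips in range, e.g. S = 0
    with r != 1 where the invader always fixes). ``brackets`` holds the
    flanking (largest-loss, smallest-fix) pair, and ``flags`` any cell
    diagnostics ("no_flip", "non_monotone", "degenerate").
    """

    S_values: np.ndarray
    p_values: np.ndarray
    thresholds: np.ndarray
    brackets: List[Tuple[float, float]]
    comparator: str
    flags: List[Optional[str]] = field(default_factory=list)


def _p_of(state: Union[GenotypeState, SexState]) -> float:
    if isinstance(state, SexState):
        return population_mean_p(state, "equal")
    return state.p


def classify_fate(
    state0: Union[GenotypeState, SexState],
    params: Union[ModelParams, AndroParams],
    model: str = "monoecious",
    comparator: str = "after_n",
    n_generations: int = 100,
    epsilon: float = 1e-6,
) -> FateResult:
    """Classify the fate of the M1 allele from a starting state.

    ``after_n`` (default): fix iff the allele frequency after
    ``n_generations`` exceeds the starting frequency, loss iff below,
    undecided if unchanged within 1e-12. ``absorbing``: iterate until the
    frequency leaves (epsilon, 1 - epsilon) or the generation cap is hit.
    For the androdioecious model, frequency means the equal-weight sex
    average.
    """
    if model == "monoecious":
        step = lambda s: step_monoecious(s, params).state
    elif model == "androdioecious":
        step = lambda s: step_androdioecious(s, params).state
    else:
        raise ValueError(f"unknown model: {model!r}")
    if comparator not in ("after_n", "absorbing"):
        raise ValueError(f"unknown comparator: {comparator!r}")

    p0 = _p_of(state0)
    state = state0
    if comparator == "after_n":
        for _ in range(n_generations):
            state = step(state)
        p_final = _p_of(state)
        if p_final > p0 + _EQ_TOL:
            fate = "fix"
        elif p_final < p0 - _EQ_TOL:
            fate = "loss"
        else:
            fate = "undecided"
        return FateResult(fate, p_final, n_generations)

    p_final = p0
    for t in range(n_generations):
        if p_final < epsilon:
            return FateResult("loss", p_final, t)
        if p_final > 1.0 - epsilon:
            return FateResult("fix", p_final, t)
        state = step(state)
        p_final = _p_of(state)
    if p_final < epsilon:
        fate = "loss"
    elif p_final > 1.0 - epsilon:
        fate = "fix"
    else:
        fate = "undecided"
    return FateResult(fate, p_final, n_generations)


# ---------------------------------------------------------------------------
# vectorized trajectory kernels (batched over starting frequencies)
# ---------------------------------------------------------------------------


def _batch_final_p_mono(
    p0: np.ndarray, Y0: np.ndarray, params: ModelParams, n_generations: int
) -> np.ndarray:
    """Iterate the compact monoecious (p, Y) map over a batch of starts."""
    p = np.array(p0, dtype=float)
    Y = np.array(Y0, dtype=float)
    S = params.S
    k1, k2 = params.effective_k
    for _ in range(n_generations):
        q = 1.0 - p
        A_p = S / 2.0 + p * (1.0 - S)
        A_q = S / 2.0 + q * (1.0 - S)
        wbar = 1.0 - (Y / 2.0) * (k1 * A_q + k2 * A_p)
        p_next = (p - (Y / 2.0) * k2 * A_p) / wbar
        Y = (S * Y / 2.0 + (1.0 - S) * 2.0 * p * q) / wbar
        p = p_next
    return p


def _batch_final_p_andro(
    p0: np.ndarray, params: AndroParams, n_generations: int
) -> np.ndarray:
    """Iterate the sex-structured map from all-homozygote symmetric starts.

    State per batch element is (ph, Yh, pm, Ym); killing exposure follows
    the element types exactly as in the scalar step. Returns the
    equal-weight mean allele frequency after ``n_generations``.
    """
    ph = np.array(p0, dtype=float)
    pm = ph.copy()
    Yh = np.zeros_like(ph)
    Ym = np.zeros_like(ph)
    S, b, k1, k2 = params.S, params.b, params.k1, params.k2
    e1, e2 = params.element1, params.element2
    k1_self = k1 if e1 != Element.NONE else 0.0
    k2_self = k2 if e2 != Element.NONE else 0.0
    for _ in range(n_generations):
        qh, qm = 1.0 - ph, 1.0 - pm
        egg_p = ph - (Yh / 2.0) * k2 if e2 == Element.MEDEA else ph
        sperm_p = pm - (Ym / 2.0) * k2 if e2 == Element.PEEL else pm
        egg_q = qh - (Yh / 2.0) * k1 if e1 == Element.MEDEA else qh
        sperm_q = qm - (Ym / 2.0) * k1 if e1 == Element.PEEL else qm
        c11 = egg_p * sperm_p
        c12 = ph * qm + qh * pm
        c22 = egg_q * sperm_q
        Xh = ph - Yh / 2.0
        Zh = qh - Yh / 2.0
        s11 = Xh + Yh * (1.0 - k2_self) / 4.0
        s12 = Yh / 2.0
        s22 = Zh + Yh * (1.0 - k1_self) / 4.0
        h11 = S * s11 + b * (1.0 - S) * c11
        h12 = S * s12 + b * (1.0 - S) * c12
        h22 = S * s22 + b * (1.0 - S) * c22
        w_h = h11 + h12 + h22
        ph = (h11 + h12 / 2.0) / w_h
        Yh = h12 / w_h
        if S < 1.0:
            w_m = c11 + c12 + c22
            pm = (c11 + c12 / 2.0) / w_m
            Ym = c12 / w_m
    return (ph + pm) / 2.0


def _fates_along_p(
    p_grid: np.ndarray,
    params: Union[ModelParams, AndroParams],
    model: str,
    n_generations: int,
) -> np.ndarray:
    """Fate code per starting frequency: -1 loss, +1 fix, 0 undecided."""
    if model == "monoecious":
        p_final = _batch_final_p_mono(
            p_grid, np.zeros_like(p_grid), params, n_generations
        )
    elif model == "androdioecious":
        p_final = _batch_final_p_andro(p_grid, params, n_generations)
    else:
        raise ValueError(f"unknown model: {model!r}")
    codes = np.zeros(len(p_grid), dtype=int)
    codes[p_final > p_grid + _EQ_TOL] = 1
    codes[p_final < p_grid - _EQ_TOL] = -1
    return codes


def threshold_scan(
    params: Union[ModelParams, AndroParams],
    model: str = "monoecious",
    S_grid: Optional[Sequence[float]] = None,
    p_grid: Optional[Sequence[float]] = None,
    n_generations: int = 100,
) -> ThresholdGrid:
    """Estimate the invasion-threshold frequency across selfing rates.

    For each selfing rate S, the recursions are iterated from
    all-homozygote starts (X = p0, Y = 0, Z = 1 - p0; both sexes
    identical under androdioecy) for every starting frequency p0 in
    ``p_grid``, and the threshold is the midpoint between the largest p0
    classified as loss and the smallest classified as fix. Defaults
    follow the reference scan: p0 from 0.001 to 0.999 step 0.001, S from
    0 to 0.99 step 0.01, fate read after 100 generations.
    """
    if S_grid is None:
        S_grid = np.arange(0.0, 0.991, 0.01)
    if p_grid is None:
        p_grid = np.arange(0.001, 0.9995, 0.001)
    S_values = np.asarray(S_grid, dtype=float)
    p_values = np.asarray(p_grid, dtype=float)
    if np.any(np.diff(S_values) < 0) or np.any(np.diff(p_values) < 0):
        raise ValueError("S_grid and p_grid must be sorted ascending")

    thresholds = np.full(len(S_values), np.nan)
    brackets: List[Tuple[float, float]] = []
    flags: List[Optional[str]] = []
    for i, S in enumerate(S_values):
        cell_params = _with_S(params, float(S))
        if S >= 1.0:
            # complete selfing from Y = 0: every p is an equilibrium
            brackets.append((np.nan, np.nan))
            flags.append("degenerate")
            continue
        codes = _fates_along_p(p_values, cell_params, model, n_generations)
        loss_idx = np.flatnonzero(codes == -1)
        fix_idx = np.flatnonzero(codes == 1)
        if len(loss_idx) == 0 or len(fix_idx) == 0:
            brackets.append((np.nan, np.nan))
            flags.append("no_flip")
            continue
        lo = p_values[loss_idx[-1]]
        hi = p_values[fix_idx[0]]
        # a clean separatrix: all losses below all fixes
        monotone = loss_idx[-1] < fix_idx[0] and np.all(np.diff(codes) >= 0)
        thresholds[i] = (lo + hi) / 2.0
        brackets.append((float(lo), float(hi)))
        flags.append(None if monotone else "non_monotone")
    return ThresholdGrid(S_values, p_values, thresholds, brackets, "after_n", flags)


def _with_S(params: Union[ModelParams, AndroParams], S: float):
    if isinstance(params, AndroParams):
        return AndroParams(S, params.k1, params.k2, params.element1, params.element2, params.b)
    return ModelParams(S, params.k1, params.k2, params.element1, params.element2)


def refine_threshold(
    params: ModelParams,
    S: float,
    lo: float,
    hi: float,
    n_generations: int = 100,
    tol: float = 1e-6,
) -> float:
    """Bisect the monoecious fate boundary to ``tol`` inside a bracket."""
    cell_params = _with_S(params, S)

    def fate_sign(p0: float) -> int:
        codes = _fates_along_p(np.array([p0]), cell_params, "monoecious", n_generations)
        return int(codes[0])

    f_lo, f_hi = fate_sign(lo), fate_sign(hi)
    if f_lo >= 0 or f_hi <= 0:
        raise ValueError("bracket does not straddle the fate boundary")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fate_sign(mid) <= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def vector_field(
    params: ModelParams, model: str = "monoecious", grid_resolution: int = 20
) -> List[Tuple[float, float, float, float, float, float]]:
    """One-step displacement at each point of a genotype-simplex grid.

    Returns ``(X, Y, Z, dX, dY, dZ)`` at every grid point X = i/n,
    Y = j/n, Z = 1 - X - Y; the displacement components sum to zero.
    """
    if grid_resolution < 2:
        raise ValueError("grid_resolution must be >= 2")
    if model != "monoecious":
        raise ValueError("vector fields are defined on the monoecious simplex")
    n = grid_resolution
    out = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            X, Y = i / n, j / n
            Z = 1.0 - X - Y
            state = GenotypeState(X, Y, max(Z, 0.0))
            nxt = step_monoecious(state, params).state
            out.append((X, Y, Z, nxt.X - X, nxt.Y - Y, nxt.Z - Z))
    return out


def ternary_coords(state: Union[GenotypeState, Tuple[float, float, float]]) -> Tuple[float, float]:
    """Planar embedding of a genotype simplex point in the unit triangle.

    Corners: M1M1 at (0, 0), M2M2 at (1, 0), heterozygote at the apex
    (1/2, sqrt(3)/2): ``x = Z + Y/2``, ``y = (sqrt(3)/2) Y``.
    """
    if isinstance(state, GenotypeState):
        X, Y, Z = state.as_tuple()
    else:
        X, Y, Z = state
    return (Z + Y / 2.0, (np.sqrt(3.0) / 2.0) * Y)
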