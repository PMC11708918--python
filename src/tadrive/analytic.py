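"""Closed-form equilibria and invasion thresholds for the monoecious model.

Setting ``p' = p`` in the compact recursion gives the implicit internal
equilibrium condition

    p * r * (S/2 + q(1-S)) = q * (S/2 + p(1-S)),        r = k1/k2,

which depends only on the selfing rate ``S`` and the penetrance ratio
``r`` — not on heterozygosity or on the penetrance magnitudes. The
explicit root in (0, 1),

    p_hat = [S(r-3) + 2 - 2r + sqrt((S-2)^2 (1+r^2) + 2r (S^2+4S-4))]
            / [4 (r-1) (S-1)],

has removable singularities at r = 1 (p_hat = 1/2 by symmetry) and S = 1
(p_hat = 1/(1+r)). The internal equilibrium is always unstable: the system
is bistable and p_hat is the invasion threshold. Every closed-form value
is verified against the implicit condition and falls back to bracketed
root-finding when the residual is too large.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

_RESIDUAL_TOL = 1e-10


def eq_residual(p: float, S: float, r: float) -> float:
    """Residual of the implicit internal-equilibrium condition at ``p``.

    Zero iff ``p`` is an internal equilibrium for selfing rate ``S`` and
    penetrance ratio ``r``. Written in polynomial form so it is finite on
    the closed interval [0, 1].
    """
    q = 1.0 - p
    A_p = S / 2.0 + p * (1.0 - S)
    A_q = S / 2.0 + q * (1.0 - S)
    return p * r * A_q - q * A_p


@dataclass(frozen=True)
class EquilibriumPoint:
    """Internal (unstable) equilibrium of the monoecious model.

    ``K = k1 (S/2 + q(1-S)) + k2 (S/2 + p(1-S))`` is the composite
    selection intensity at the equilibrium; mean fitness there is
    ``1 - (Y_hat/2) K``.
    """

    p_hat: float
    Y_hat: float
    K: float
    residual: float
    stability: str = "unstable"


def _bisect_equilibrium(S: float, r: float) -> Optional[float]:
    """Bracketed root of the implicit condition on (0, 1), if any."""
    f = lambda p: eq_residual(p, S, r)
    eps = 1e-12
    lo, hi = eps, 1.0 - eps
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0.0:
        return None
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0.0:
            return mid
        if flo * fm < 0.0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def internal_equilibrium_p(S: float, r: float) -> Optional[float]:
    """Internal equilibrium allele frequency p_hat, or None if there is none.

    Parameters
    ----------
    S
        Selfing rate in [0, 1].
    r
        Penetrance ratio k1/k2 (> 0).

    Returns
    -------
    The unique root of the implicit equilibrium condition in (0, 1), or
    ``None`` when no interior equilibrium exists (obligate outcrossing
    with r != 1, where the stronger allele simply sweeps; S = 0 with
    r = 1 is degenerate — every p is neutral — and also returns None).
    """
    if not (0.0 <= S <= 1.0):
        raise ValueError(f"S must lie in [0, 1]; got {S!r}")
    if r <= 0.0:
        raise ValueError(f"penetrance ratio r must be > 0; got {r!r}")
    if S == 0.0:
        return None
    if r == 1.0:
        # equally penetrant antagonists: symmetric threshold
        return 0.5
    if S == 1.0:
        # limit of the explicit root: p r/2 = q/2
        p_hat = 1.0 / (1.0 + r)
    else:
        disc = (S - 2.0) ** 2 * (1.0 + r * r) + 2.0 * r * (S * S + 4.0 * S - 4.0)
        if disc < 0.0:
            p_hat = math.nan
        else:
            p_hat = (S * (r - 3.0) + 2.0 - 2.0 * r + math.sqrt(disc)) / (
                4.0 * (r - 1.0) * (S - 1.0)
            )
    # the implicit condition is ground truth; fall back to bisection if the
    # printed radical misbehaves numerically
    if not (
        0.0 < p_hat < 1.0 and abs(eq_residual(p_hat, S, r)) < _RESIDUAL_TOL
    ):
        p_hat_bis = _bisect_equilibrium(S, r)
        if p_hat_bis is None or not (0.0 < p_hat_bis < 1.0):
            return None
        p_hat = p_hat_bis
    return p_hat


def selection_intensity(S: float, k1: float, k2: float, p: float) -> float:
    """Composite selection intensity K at allele frequency p."""
    q = 1.0 - p
    return k1 * (S / 2.0 + q * (1.0 - S)) + k2 * (S / 2.0 + p * (1.0 - S))


def equilibrium_heterozygosity(S: float, k1: float, k2: float, p_hat: float) -> float:
    """Equilibrium heterozygosity Y_hat at a fixed allele frequency.

    Solves the fixed point of the heterozygosity recursion at ``p_hat``:
    ``(K/2) Y^2 - (1 - S/2) Y + 2 (1-S) p q = 0`` with K the composite
    selection intensity. Both quadratic roots are computed and the one
    giving a feasible genotype simplex (Y in [0,1], X = p - Y/2 >= 0,
    Z = q - Y/2 >= 0) is returned — this is always the smaller root.
    """
    if not (0.0 < p_hat < 1.0):
        raise ValueError(f"p_hat must lie in (0, 1); got {p_hat!r}")
    if k1 + k2 <= 0.0:
        raise ValueError("equilibrium heterozygosity requires k1 + k2 > 0")
    q_hat = 1.0 - p_hat
    K = selection_intensity(S, k1, k2, p_hat)
    c = 2.0 * (1.0 - S) * p_hat * q_hat
    b = 1.0 - S / 2.0
    if K == 0.0:
        return c / b
    disc = b * b - 2.0 * K * c
    assert disc >= -1e-15, "heterozygosity quadratic has no real root"
    disc = max(disc, 0.0)
    roots = sorted(((b - math.sqrt(disc)) / K, (b + math.sqrt(disc)) / K))
    feasible = [
        Y
        for Y in roots
        if -1e-12 <= Y <= 1.0 + 1e-12
        and p_hat - Y / 2.0 >= -1e-9
        and q_hat - Y / 2.0 >= -1e-9
    ]
    assert feasible, "no feasible heterozygosity root"
    return min(max(feasible[0], 0.0), 1.0)


def equilibrium(S: float, k1: float, k2: float) -> Optional[EquilibriumPoint]:
    """Full internal equilibrium (p_hat, Y_hat, K) or None if none exists."""
    if k2 <= 0.0:
        raise ValueError("equilibrium requires k2 > 0 (penetrance ratio undefined)")
    r = k1 / k2
    p_hat = internal_equilibrium_p(S, r)
    if p_hat is None:
        return None
    Y_hat = equilibrium_heterozygosity(S, k1, k2, p_hat)
    K = selection_intensity(S, k1, k2, p_hat)
    return EquilibriumPoint(p_hat, Y_hat, K, eq_residual(p_hat, S, r))


def critical_selfing(p: float, r: float) -> float:
    """Critical selfing rate S_C for an invader at frequency ``p``.

    ``S_C = 2 p (1-p) (1-r) / (2 p^2 r - 2 p^2 - p r + 3 p - 1)``.
    For selfing rates above S_C the invader (penetrance ratio r > 1
    relative to the resident) is eliminated; below it, it fixes. The raw
    formula value is returned even when it falls outside [0, 1], in which
    case no selfing rate in range is critical (e.g. a majority invader
    always fixes); callers report that explicitly rather than clamping.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"invader frequency p must lie in (0, 1); got {p!r}")
    if r <= 0.0:
        raise ValueError(f"penetrance ratio r must be > 0; got {r!r}")
    if r == 1.0:
        # numerator vanishes identically: any selfing blocks nothing
        return 0.0
    denom = 2.0 * p * p * r - 2.0 * p * p - p * r + 3.0 * p - 1.0
    if denom == 0.0:
        raise ZeroDivisionError(
            f"critical-selfing denominator vanishes at p={p!r}, r={r!r}"
        )
    return 2.0 * p * (1.0 - p) * (1.0 - r) / denom


def critical_ratio(p: float, S: float) -> float:
    """Critical penetrance ratio r_C for an invader at frequency ``p``.

    ``r_C = [S + 2 p (1-p) (1-S) - S p] / [2 p (1-p) (1-S) + S p]``.
    The invader sweeps iff its penetrance ratio exceeds r_C. At S = 0 this
    is 1 for every p: under obligate outcrossing any stronger element
    invades.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"invader frequency p must lie in (0, 1); got {p!r}")
    if not (0.0 <= S <= 1.0):
        raise ValueError(f"S must lie in [0, 1]; got {S!r}")
    denom = 2.0 * p * (1.0 - p) * (1.0 - S) + S * p
    if denom == 0.0:
        raise ZeroDivisionError(f"critical-ratio denominator vanishes at p={p!r}")
    return (S + 2.0 * p * (1.0 - p) * (1.0 - S) - S * p) / denom
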