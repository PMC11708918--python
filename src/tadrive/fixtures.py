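"""Seeded random fixtures: valid genotype states and parameter draws.

Used by the property-test suites (oracle equivalence of the compact
recursions against the mating-table enumeration) and by the ``fixtures``
CLI subcommand. Genotype states are drawn uniformly on the simplex
(Dirichlet(1,1,1)); parameters uniformly on their declared ranges.
Identical seeds give identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .androdioecy import AndroParams, SexState
from .model import Element, GenotypeState, ModelParams

_ELEMENT_CHOICES = (Element.MEDEA, Element.PEEL, Element.NONE)


@dataclass(frozen=True)
class FixtureSpec:
    """How many random (state, params) pairs to draw and from where."""

    n_states: int
    seed: int
    S_range: Tuple[float, float] = (0.0, 1.0)
    k_range: Tuple[float, float] = (0.0, 1.0)
    b_range: Tuple[float, float] = (0.5, 2.0)
    random_elements: bool = True

    def __post_init__(self) -> None:
        if self.n_states < 0:
            raise ValueError("n_states must be >= 0")
        for name in ("S_range", "k_range", "b_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be (lo, hi) with lo <= hi")


def _draw_elements(rng: np.random.Generator, spec: FixtureSpec) -> Tuple[Element, Element]:
    if spec.random_elements:
        i, j = rng.integers(0, len(_ELEMENT_CHOICES), size=2)
        return (_ELEMENT_CHOICES[i], _ELEMENT_CHOICES[j])
    return (Element.MEDEA, Element.MEDEA)


def generate_fixtures(spec: FixtureSpec) -> List[Tuple[GenotypeState, ModelParams]]:
    """Random monoecious (state, params) pairs, reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    out: List[Tuple[GenotypeState, ModelParams]] = []
    for _ in range(spec.n_states):
        X, Y, Z = rng.dirichlet([1.0, 1.0, 1.0])
        S = rng.uniform(*spec.S_range)
        k1, k2 = rng.uniform(*spec.k_range, size=2)
        e1, e2 = _draw_elements(rng, spec)
        out.append((GenotypeState(X, Y, Z), ModelParams(S, k1, k2, e1, e2)))
    return out


def generate_sex_fixtures(spec: FixtureSpec) -> List[Tuple[SexState, AndroParams]]:
    """Random androdioecious (state, params) pairs, reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    out: List[Tuple[SexState, AndroParams]] = []
    for _ in range(spec.n_states):
        Xh, Yh, Zh = rng.dirichlet([1.0, 1.0, 1.0])
        Xm, Ym, Zm = rng.dirichlet([1.0, 1.0, 1.0])
        S = rng.uniform(*spec.S_range)
        k1, k2 = rng.uniform(*spec.k_range, size=2)
        b = rng.uniform(*spec.b_range)
        e1, e2 = _draw_elements(rng, spec)
        out.append(
            (SexState(Xh, Yh, Zh, Xm, Ym, Zm), AndroParams(S, k1, k2, e1, e2, b))
        )
    return out
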