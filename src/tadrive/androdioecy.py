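"""Sex-structured drive dynamics for the *Caenorhabditis* mating system.

Androdioecy here means: hermaphrodites self (probability ``S``) to produce
only hermaphrodites, or mate with males (probability ``1 - S``) to produce
a 50:50 mix of hermaphrodites and males. Males arise exclusively from
outcrossing, so male heterozygosity ``Ym`` exceeds hermaphrodite
heterozygosity ``Yh`` under partial selfing — which is why paternal-effect
(*peel*) elements, whose killing is keyed to the sperm parent, experience
more selection than maternal-effect (*Medea*) elements under this mating
system.

The cost-of-males parameter ``b`` is the ratio of hermaphrodite offspring
from an outcross to hermaphrodite offspring from a self-fertilization
(b = 1/2 is the classical two-fold cost of males, b = 1 means outcrossing
is free). ``b`` weights only the outcross contribution to the
hermaphrodite pool; male genotype frequencies depend only on the outcross
classes and are normalized separately, so they are b-independent.

Toxin exposure per mating class follows one rule for every element
combination: a Medea-type allele's toxin is present when the EGG parent is
heterozygous; a peel-type allele's toxin when the SPERM parent is (under
selfing the two coincide). Mixed Medea-vs-peel antagonism therefore needs
no hand-written cases.

As in the monoecious module, a 12-row mating-table enumeration
(:func:`build_androdioecious_mating_table` + :func:`step_andro_from_table`)
serves as the oracle for the compact recursion
(:func:`step_androdioecious`); the two agree to 1e-12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, List, Sequence, Tuple, Union

from .model import (
    Element,
    ExtinctionError,
    GenotypeState,
    _check_unit,
    _normalize_simplex,
    GENOTYPES,
    progeny_weights,
)


@dataclass(frozen=True)
class SexState:
    """Sex-specific genotype frequencies: hermaphrodites and males.

    ``(Xh, Yh, Zh)`` and ``(Xm, Ym, Zm)`` each form a simplex. Derived
    allele frequencies are ``ph = Xh + Yh/2`` and ``pm = Xm + Ym/2``.
    """

    Xh: float
    Yh: float
    Zh: float
    Xm: float
    Ym: float
    Zm: float

    def __post_init__(self) -> None:
        for name in ("Xh", "Yh", "Zh", "Xm", "Ym", "Zm"):
            _check_unit(name, getattr(self, name))
        for label, total in (
            ("hermaphrodite", self.Xh + self.Yh + self.Zh),
            ("male", self.Xm + self.Ym + self.Zm),
        ):
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{label} genotype frequencies must sum to 1; got {total!r}"
                )

    @property
    def hermaphrodites(self) -> GenotypeState:
        return GenotypeState(self.Xh, self.Yh, self.Zh)

    @property
    def males(self) -> GenotypeState:
        return GenotypeState(self.Xm, self.Ym, self.Zm)

    @property
    def ph(self) -> float:
        return self.Xh + self.Yh / 2.0

    @property
    def pm(self) -> float:
        return self.Xm + self.Ym / 2.0

    @classmethod
    def symmetric(cls, state: GenotypeState) -> "SexState":
        """Both sexes at the same genotype frequencies."""
        X, Y, Z = state.as_tuple()
        return cls(X, Y, Z, X, Y, Z)


@dataclass(frozen=True)
class AndroParams:
    """Parameters of the androdioecious model.

    Same drive parameters as the monoecious model plus ``b``, the ratio
    of hermaphrodite offspring per outcross to hermaphrodite offspring
    per selfing (biologically plausible range roughly 0.5 to 2; from
    *C. elegans* brood data b is close to 1).
    """

    S: float
    k1: float
    k2: float
    element1: Element = Element.MEDEA
    element2: Element = Element.MEDEA
    b: float = 1.0

    def __post_init__(self) -> None:
        _check_unit("S", self.S)
        _check_unit("k1", self.k1)
        _check_unit("k2", self.k2)
        object.__setattr__(self, "element1", Element(self.element1))
        object.__setattr__(self, "element2", Element(self.element2))
        if self.b <= 0.0:
            raise ValueError(f"cost-of-males parameter b must be > 0; got {self.b!r}")


@dataclass(frozen=True)
class SexStepResult:
    """Next-generation sex-specific state and pool normalizers.

    ``w_h`` is the hermaphrodite-pool normalizer (selfed broods weight 1,
    outcross broods weight b); ``w_m`` the male-pool normalizer (outcross
    broods only). At S = 1 the male pool receives no input: the male state
    is carried forward unchanged and ``w_m`` is NaN.
    """

    state: SexState
    w_h: float
    w_m: float


@dataclass(frozen=True)
class AndroMatingRow:
    """One androdioecious mating class.

    ``herm_factor`` and ``male_factor`` scale this row's surviving
    progeny into the hermaphrodite and male pools respectively: selfing
    rows contribute only hermaphrodites (factor 1); outcross rows
    contribute ``b`` per unit to the hermaphrodite pool and 1 to the male
    pool.
    """

    egg_parent: str
    sperm_parent: str
    kind: str  # "self" or "cross"
    frequency: float
    weights: Tuple[float, float, float]
    herm_factor: float
    male_factor: float


@dataclass(frozen=True)
class AndroMatingTable:
    rows: Tuple[AndroMatingRow, ...]

    def __iter__(self) -> Iterator[AndroMatingRow]:
        return iter(self.rows)

    def pool_totals(self) -> Tuple[Tuple[float, ...], Tuple[float, ...]]:
        """Unnormalized (hermaphrodite, male) progeny totals per genotype."""
        herm = [0.0, 0.0, 0.0]
        male = [0.0, 0.0, 0.0]
        for row in self.rows:
            for g in range(3):
                herm[g] += row.frequency * row.herm_factor * row.weights[g]
                male[g] += row.frequency * row.male_factor * row.weights[g]
        return tuple(herm), tuple(male)


def build_androdioecious_mating_table(
    state: SexState, params: AndroParams
) -> AndroMatingTable:
    """Enumerate the 3 selfing + 9 outcross mating classes.

    The egg parent is always a hermaphrodite. Selfing classes occur with
    frequency ``S * (Xh, Yh, Zh)``; outcross classes pair a hermaphrodite
    egg parent with a male sperm parent drawn by male genotype frequency,
    ``(1 - S) * f_h * f_m``. Killing weights come from the shared
    per-mating exposure rule (Medea: egg parent; peel: sperm parent).
    """
    fh = dict(zip(GENOTYPES, (state.Xh, state.Yh, state.Zh)))
    fm = dict(zip(GENOTYPES, (state.Xm, state.Ym, state.Zm)))
    rows: List[AndroMatingRow] = []
    for g in GENOTYPES:
        rows.append(
            AndroMatingRow(
                g, g, "self", params.S * fh[g], progeny_weights(g, g, params), 1.0, 0.0
            )
        )
    for ge in GENOTYPES:
        for gs in GENOTYPES:
            rows.append(
                AndroMatingRow(
                    ge,
                    gs,
                    "cross",
                    (1.0 - params.S) * fh[ge] * fm[gs],
                    progeny_weights(ge, gs, params),
                    params.b,
                    1.0,
                )
            )
    return AndroMatingTable(tuple(rows))


def _next_state_from_totals(
    herm: Sequence[float], male: Sequence[float], state: SexState
) -> Tuple[SexState, float, float]:
    w_h = sum(herm)
    if w_h <= 0.0:
        raise ExtinctionError("hermaphrodite pool empty (all progeny killed)")
    Xh, Yh, Zh = _normalize_simplex([t / w_h for t in herm], "androdioecy herm pool")
    w_m = sum(male)
    if w_m > 0.0:
        Xm, Ym, Zm = _normalize_simplex([t / w_m for t in male], "androdioecy male pool")
    else:
        # no outcrossing: males are absent, carry state forward
        Xm, Ym, Zm = state.Xm, state.Ym, state.Zm
        w_m = math.nan
    return SexState(Xh, Yh, Zh, Xm, Ym, Zm), w_h, w_m


def step_andro_from_table(
    table: AndroMatingTable, state: SexState, params: AndroParams
) -> SexStepResult:
    """Advance one generation by summing the mating table (oracle path)."""
    herm, male = table.pool_totals()
    if params.S < 1.0 and sum(male) <= 0.0:
        raise ExtinctionError("male pool empty under outcrossing (all progeny killed)")
    next_state, w_h, w_m = _next_state_from_totals(herm, male, state)
    return SexStepResult(next_state, w_h, w_m)


def _cross_pool(state: SexState, params: AndroParams) -> Tuple[float, float, float]:
    """Surviving outcross progeny per genotype, per unit outcross brood.

    Egg gametes come from hermaphrodites, sperm gametes from males.
    Killing factorizes by parent: for allele 2 (kills M1M1 with k2), a
    Medea element discounts the heterozygous egg-parent gamete stream
    (``ph - (Yh/2) k2``) while a peel discounts the male stream
    (``pm - (Ym/2) k2``); symmetrically for allele 1 against M2M2.
    Heterozygous progeny are never killed.
    """
    ph, pm = state.ph, state.pm
    qh, qm = 1.0 - ph, 1.0 - pm
    Yh, Ym = state.Yh, state.Ym

    # M1 gamete streams surviving the allele-2 toxin
    egg_p = ph - (Yh / 2.0) * params.k2 if params.element2 == Element.MEDEA else ph
    sperm_p = pm - (Ym / 2.0) * params.k2 if params.element2 == Element.PEEL else pm
    # M2 gamete streams surviving the allele-1 toxin
    egg_q = qh - (Yh / 2.0) * params.k1 if params.element1 == Element.MEDEA else qh
    sperm_q = qm - (Ym / 2.0) * params.k1 if params.element1 == Element.PEEL else qm

    c11 = egg_p * sperm_p
    c12 = ph * qm + qh * pm
    c22 = egg_q * sperm_q
    return c11, c12, c22


def _self_pool(state: SexState, params: AndroParams) -> Tuple[float, float, float]:
    """Surviving selfed progeny per genotype, per unit selfed brood.

    The selfing hermaphrodite is both egg and sperm parent, so any
    element type (Medea or peel) with a heterozygous selfer exposes the
    opposite-homozygote progeny class.
    """
    k1 = params.k1 if params.element1 != Element.NONE else 0.0
    k2 = params.k2 if params.element2 != Element.NONE else 0.0
    s11 = state.Xh + state.Yh * (1.0 - k2) / 4.0
    s12 = state.Yh / 2.0
    s22 = state.Zh + state.Yh * (1.0 - k1) / 4.0
    return s11, s12, s22


def step_androdioecious(state: SexState, params: AndroParams) -> SexStepResult:
    """Advance one generation via the compact sex-structured recursion.

    Hermaphrodite pool: ``S * self + b (1-S) * cross``, normalized by
    ``w_h``. Male pool: ``(1-S) * cross`` alone, normalized by ``w_m``
    (hence b-independent). Agrees with the mating-table oracle to 1e-12.
    """
    S, b = params.S, params.b
    self_tot = _self_pool(state, params)
    cross_tot = _cross_pool(state, params)
    herm = [S * s + b * (1.0 - S) * c for s, c in zip(self_tot, cross_tot)]
    male = [(1.0 - S) * c for c in cross_tot]
    if S < 1.0 and sum(male) <= 0.0:
        raise ExtinctionError("male pool empty under outcrossing (all progeny killed)")
    next_state, w_h, w_m = _next_state_from_totals(herm, male, state)
    return SexStepResult(next_state, w_h, w_m)


def population_mean_p(
    state: SexState, weights: Union[str, Tuple[float, float]] = "equal"
) -> float:
    """Sex-weighted population mean allele frequency.

    ``weights`` is ``"hermaphrodite_only"``, ``"equal"``, or a custom
    ``(w_h, w_m)`` pair (normalized internally). The equal rule is the
    package default for reported population frequencies.
    """
    if weights == "hermaphrodite_only":
        wh, wm = 1.0, 0.0
    elif weights == "equal":
        wh, wm = 0.5, 0.5
    elif isinstance(weights, tuple) and len(weights) == 2:
        wh, wm = weights
        if wh < 0 or wm < 0 or wh + wm <= 0:
            raise ValueError("custom sex weights must be non-negative, not both zero")
    else:
        raise ValueError(f"unknown sex-weighting rule: {weights!r}")
    total = wh + wm
    return (wh * state.ph + wm * state.pm) / total


def iterate_androdioecious(
    state0: SexState, params: AndroParams, n_generations: int
) -> List[Tuple[int, SexState, float, float]]:
    """Iterate the sex-structured map, recording every generation.

    Returns ``(t, state_t, w_h, w_m)`` for t = 0 .. n_generations, where
    the normalizers are those of the step producing generation t+1 (NaN
    in the final row, where no step is taken).
    """
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    out: List[Tuple[int, SexState, float, float]] = []
    state = state0
    for t in range(n_generations):
        result = step_androdioecious(state, params)
        out.append((t, state, result.w_h, result.w_m))
        state = result.state
    out.append((n_generations, state, math.nan, math.nan))
    return out
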