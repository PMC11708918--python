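"""Monoecious toxin-antidote drive model: state, parameters, one-generation map.

The population is an infinite monoecious partial selfer. Each generation a
hermaphrodite selfs with probability ``S`` and outcrosses at random with
probability ``1 - S``. At one biallelic locus, allele ``M1`` may kill
``M2M2`` homozygous progeny of a heterozygous parent with penetrance ``k1``
(and ``M2`` kills ``M1M1`` with penetrance ``k2``). For a *Medea* element
the toxin-bearing parent is the egg parent; for a *peel* element it is the
sperm parent. Under monoecy the two element types (and any mix) yield
identical recursions because cross frequencies are symmetric in the two
parental roles.

Two independent routes compute the next generation:

* :func:`build_mating_table` / :func:`step_from_table` — brute-force
  enumeration of the 3 selfing and 9 outcross mating classes with
  Mendelian segregation and per-class killing (the oracle);
* :func:`step_monoecious` — the compact recursion in allele frequency
  ``p`` and heterozygosity ``Y``.

They agree to 1e-12 on every valid input; the test suite enforces this.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, List, Sequence, Tuple

logger = logging.getLogger(__name__)

#: tolerance for the genotype-frequency simplex constraint
SIMPLEX_TOL = 1e-12
#: renormalization corrections larger than this are logged
RENORM_WARN = 1e-9

GENOTYPES = ("M1M1", "M1M2", "M2M2")

#: probability that a gamete from each genotype carries M1
_M1_GAMETE = {"M1M1": 1.0, "M1M2": 0.5, "M2M2": 0.0}


class Element(str, Enum):
    """Type of toxin-antidote activity carried by an allele.

    ``MEDEA``: maternal-effect — toxin deposited in eggs by a heterozygous
    egg parent. ``PEEL``: paternal-effect — toxin delivered by sperm of a
    heterozygous sperm parent. ``NONE``: the allele carries no element (its
    penetrance is ignored).
    """

    MEDEA = "medea"
    PEEL = "peel"
    NONE = "none"


class ExtinctionError(RuntimeError):
    """Raised when killing removes every progeny class (mean fitness 0)."""


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1]; got {value!r}")


@dataclass(frozen=True)
class GenotypeState:
    """Genotype frequencies (X, Y, Z) of (M1M1, M1M2, M2M2); sum to 1."""

    X: float
    Y: float
    Z: float

    def __post_init__(self) -> None:
        for name in ("X", "Y", "Z"):
            _check_unit(name, getattr(self, name))
        total = self.X + self.Y + self.Z
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype frequencies must sum to 1; got {total!r}")

    @property
    def p(self) -> float:
        """Frequency of the M1 allele, X + Y/2."""
        return self.X + self.Y / 2.0

    @property
    def q(self) -> float:
        """Frequency of the M2 allele, 1 - p."""
        return 1.0 - self.p

    @classmethod
    def from_pY(cls, p: float, Y: float) -> "GenotypeState":
        """Build a state from allele frequency and heterozygosity.

        Requires ``Y/2 <= min(p, 1-p)`` so that both homozygote
        frequencies are non-negative.
        """
        _check_unit("p", p)
        _check_unit("Y", Y)
        X = p - Y / 2.0
        Z = 1.0 - p - Y / 2.0
        if X < -SIMPLEX_TOL or Z < -SIMPLEX_TOL:
            raise ValueError(f"(p={p}, Y={Y}) implies negative homozygote frequency")
        return cls(max(X, 0.0), Y, max(Z, 0.0))

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.X, self.Y, self.Z)


@dataclass(frozen=True)
class ModelParams:
    """Mating-system and drive parameters for the monoecious model.

    Parameters
    ----------
    S
        Selfing rate: fixed fraction of broods produced by selfing.
    k1, k2
        Killing penetrances of M1 (against M2M2 progeny) and of M2
        (against M1M1 progeny).
    element1, element2
        Element type of each allele. Monoecious dynamics are identical
        for every combination; the distinction matters only for the
        androdioecious model.
    """

    S: float
    k1: float
    k2: float
    element1: Element = Element.MEDEA
    element2: Element = Element.MEDEA

    def __post_init__(self) -> None:
        _check_unit("S", self.S)
        _check_unit("k1", self.k1)
        _check_unit("k2", self.k2)
        object.__setattr__(self, "element1", Element(self.element1))
        object.__setattr__(self, "element2", Element(self.element2))
        if (self.element1, self.element2) != (Element.MEDEA, Element.MEDEA):
            logger.debug(
                "element types (%s, %s) noted; monoecious Medea and peel "
                "elements behave identically in this model",
                self.element1.value,
                self.element2.value,
            )

    @property
    def r(self) -> float:
        """Penetrance ratio k1/k2 (defined only for k2 > 0)."""
        if self.k2 <= 0.0:
            raise ValueError("penetrance ratio r = k1/k2 requires k2 > 0")
        return self.k1 / self.k2

    @property
    def effective_k(self) -> Tuple[float, float]:
        """Penetrances with inert (element = none) alleles zeroed.

        The Medea/peel distinction itself does not matter under monoecy,
        but an allele carrying no element kills nothing regardless of
        its nominal penetrance.
        """
        k1 = self.k1 if self.element1 != Element.NONE else 0.0
        k2 = self.k2 if self.element2 != Element.NONE else 0.0
        return k1, k2


@dataclass(frozen=True)
class StepResult:
    """Next-generation state and the mean fitness of the parental pool."""

    state: GenotypeState
    mean_fitness: float


@dataclass(frozen=True)
class MatingRow:
    """One mating class: parents, frequency, surviving-progeny weights.

    ``weights`` are per-genotype (M1M1, M1M2, M2M2) products of the
    Mendelian share and the survival fraction after killing.
    """

    egg_parent: str
    sperm_parent: str
    kind: str  # "self" or "cross"
    frequency: float
    weights: Tuple[float, float, float]


@dataclass(frozen=True)
class MatingTable:
    """The 3 selfing + 9 outcross rows for one parental generation."""

    rows: Tuple[MatingRow, ...]

    def __iter__(self) -> Iterator[MatingRow]:
        return iter(self.rows)

    def progeny_totals(self) -> Tuple[float, float, float]:
        """Unnormalized surviving-progeny totals per genotype."""
        totals = [0.0, 0.0, 0.0]
        for row in self.rows:
            for g in range(3):
                totals[g] += row.frequency * row.weights[g]
        return tuple(totals)  # type: ignore[return-value]


def progeny_weights(
    egg_parent: str, sperm_parent: str, params: "ModelParams | object"
) -> Tuple[float, float, float]:
    """Surviving-progeny weights for a single mating.

    Mendelian segregation from the two parental genotypes, then killing:
    M1M1 progeny die with penetrance ``k2`` when the allele-2 element is
    active in this mating (egg parent heterozygous for a Medea, sperm
    parent heterozygous for a peel); M2M2 progeny die with ``k1``
    symmetrically. Heterozygous progeny carry both antidotes and are
    never killed. Under selfing egg and sperm parent coincide, so Medea
    and peel exposure rules agree there.

    ``params`` needs attributes k1, k2, element1, element2 (shared with
    the androdioecious parameter object).
    """
    a_e = _M1_GAMETE[egg_parent]
    a_s = _M1_GAMETE[sperm_parent]
    share11 = a_e * a_s
    share12 = a_e * (1.0 - a_s) + (1.0 - a_e) * a_s
    share22 = (1.0 - a_e) * (1.0 - a_s)

    egg_het = egg_parent == "M1M2"
    sperm_het = sperm_parent == "M1M2"

    def exposed(element: Element) -> bool:
        if element == Element.MEDEA:
            return egg_het
        if element == Element.PEEL:
            return sperm_het
        return False

    surv11 = 1.0 - params.k2 if exposed(params.element2) else 1.0
    surv22 = 1.0 - params.k1 if exposed(params.element1) else 1.0
    return (share11 * surv11, share12, share22 * surv22)


def build_mating_table(state: GenotypeState, params: ModelParams) -> MatingTable:
    """Enumerate the 12 mating classes of a monoecious partial selfer.

    Selfing rows occur with frequency ``S * (X, Y, Z)``; outcross rows
    with ``(1 - S) * f_egg * f_sperm`` for every ordered parental pair.
    """
    freqs = dict(zip(GENOTYPES, state.as_tuple()))
    rows: List[MatingRow] = []
    for g in GENOTYPES:
        rows.append(
            MatingRow(g, g, "self", params.S * freqs[g], progeny_weights(g, g, params))
        )
    for ge in GENOTYPES:
        for gs in GENOTYPES:
            rows.append(
                MatingRow(
                    ge,
                    gs,
                    "cross",
                    (1.0 - params.S) * freqs[ge] * freqs[gs],
                    progeny_weights(ge, gs, params),
                )
            )
    return MatingTable(tuple(rows))


def _normalize_simplex(values: Sequence[float], context: str) -> Tuple[float, ...]:
    """Clamp tiny negatives and renormalize; log unusually large drift."""
    clamped = [0.0 if -SIMPLEX_TOL < v < 0.0 else v for v in values]
    total = sum(clamped)
    if abs(total - 1.0) > RENORM_WARN:
        logger.warning("simplex drift %.3e in %s", total - 1.0, context)
    return tuple(v / total for v in clamped)


def step_from_table(table: MatingTable) -> StepResult:
    """Advance one generation by summing the mating table (oracle path).

    Next-generation genotype frequencies are the per-genotype column sums
    (frequency x weight) normalized by the grand total, which is the mean
    fitness.

    Raises
    ------
    ExtinctionError
        If the grand total is zero (killing removed all progeny).
    """
    totals = table.progeny_totals()
    wbar = sum(totals)
    if wbar <= 0.0:
        raise ExtinctionError("all progeny classes were killed (mean fitness 0)")
    X, Y, Z = _normalize_simplex([t / wbar for t in totals], "step_from_table")
    return StepResult(GenotypeState(X, Y, Z), wbar)


def mean_fitness(state: GenotypeState, params: ModelParams) -> float:
    """Mean fitness of the progeny pool produced by ``state``.

    ``wbar = 1 - (Y/2) * (k1*(S/2 + q(1-S)) + k2*(S/2 + p(1-S)))``:
    killing only removes homozygous progeny of heterozygous parents.
    """
    p, q, Y, S = state.p, state.q, state.Y, params.S
    k1, k2 = params.effective_k
    A_p = S / 2.0 + p * (1.0 - S)
    A_q = S / 2.0 + q * (1.0 - S)
    return 1.0 - (Y / 2.0) * (k1 * A_q + k2 * A_p)


def step_monoecious(state: GenotypeState, params: ModelParams) -> StepResult:
    """Advance one generation via the compact (p, Y) recursion.

    ``p' = (p - (Y/2) k2 (S/2 + p(1-S))) / wbar`` and
    ``Y' = (S Y / 2 + (1-S) 2 p q) / wbar``, mapped back to genotype
    frequencies as ``X' = p' - Y'/2``, ``Z' = 1 - X' - Y'``.
    """
    p, q, Y, S = state.p, state.q, state.Y, params.S
    _, k2 = params.effective_k
    A_p = S / 2.0 + p * (1.0 - S)
    wbar = mean_fitness(state, params)
    if wbar <= 0.0:
        raise ExtinctionError("all progeny classes were killed (mean fitness 0)")
    p_next = (p - (Y / 2.0) * k2 * A_p) / wbar
    Y_next = (S * Y / 2.0 + (1.0 - S) * 2.0 * p * q) / wbar
    X_next = p_next - Y_next / 2.0
    Z_next = 1.0 - p_next - Y_next / 2.0
    X_next, Y_next, Z_next = _normalize_simplex(
        [X_next, Y_next, Z_next], "step_monoecious"
    )
    return StepResult(GenotypeState(X_next, Y_next, Z_next), wbar)


def allele_frequency(state: GenotypeState) -> float:
    """Frequency of the M1 allele, p = X + Y/2."""
    return state.p


def iterate_trajectory(
    state0: GenotypeState, params: ModelParams, n_generations: int
) -> List[Tuple[int, GenotypeState, float]]:
    """Iterate the one-generation map, recording every generation.

    Returns ``(t, state_t, wbar_t)`` for t = 0 .. n_generations, where
    ``wbar_t`` is the mean fitness of the progeny pool produced by
    generation t (:func:`mean_fitness` evaluated at ``state_t``).
    """
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    out: List[Tuple[int, GenotypeState, float]] = []
    state = state0
    for t in range(n_generations + 1):
        out.append((t, state, mean_fitness(state, params)))
        if t < n_generations:
            state = step_monoecious(state, params).state
    return out
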