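"""Monoecious recursion: mating-table oracle, compact step, invariants."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from tadrive.model import (
    Element,
    GenotypeState,
    ModelParams,
    allele_frequency,
    build_mating_table,
    iterate_trajectory,
    mean_fitness,
    step_from_table,
    step_monoecious,
)

TOL = 1e-12


def row(table, egg, sperm, kind):
    matches = [
        r for r in table if (r.egg_parent, r.sperm_parent, r.kind) == (egg, sperm, kind)
    ]
    assert len(matches) == 1
    return matches[0]


class TestMatingTable:
    def test_pure_heterozygote_full_selfing(self):
        """Selfing a heterozygote with full penetrance: only the Y/2 class survives."""
        table = build_mating_table(GenotypeState(0, 1, 0), ModelParams(1, 1, 1))
        nonzero = [r for r in table if r.frequency > 0]
        assert len(nonzero) == 1
        (r,) = nonzero
        assert (r.egg_parent, r.sperm_parent, r.kind) == ("M1M2", "M1M2", "self")
        assert r.frequency == 1.0
        assert r.weights == (0.0, 0.5, 0.0)

    def test_fixed_population_rows(self):
        """A population fixed for M1M1 only ever selfs or crosses with itself."""
        table = build_mating_table(GenotypeState(1, 0, 0), ModelParams(0.3, 0.7, 0.2))
        nonzero = [r for r in table if r.frequency > 0]
        assert {(r.egg_parent, r.sperm_parent) for r in nonzero} == {("M1M1", "M1M1")}
        for r in nonzero:
            assert r.weights == (1.0, 0.0, 0.0)

    def test_printed_table_weights(self):
        """Direct substitution of the printed frequencies and killing weights."""
        state = GenotypeState(0.25, 0.5, 0.25)
        table = build_mating_table(state, ModelParams(0.6, 0.9, 0.5))
        r = row(table, "M1M2", "M2M2", "cross")
        assert r.frequency == pytest.approx(0.4 * 0.5 * 0.25, abs=TOL)
        assert r.weights[2] == pytest.approx((1 - 0.9) / 2, abs=TOL)
        # heterozygote progeny are never reduced by killing
        r_self = row(table, "M1M2", "M1M2", "self")
        assert r_self.weights == ((1 - 0.5) / 4, 0.5, (1 - 0.9) / 4)

    def test_frequency_partition(self, mono_fixtures):
        """Selfing rows sum to S and outcross rows to 1 - S."""
        for state, params in mono_fixtures[:50]:
            table = build_mating_table(state, params)
            self_sum = sum(r.frequency for r in table if r.kind == "self")
            cross_sum = sum(r.frequency for r in table if r.kind == "cross")
            assert self_sum == pytest.approx(params.S, abs=1e-9)
            assert cross_sum == pytest.approx(1 - params.S, abs=1e-9)


class TestStepFromTable:
    def test_heterozygote_selfing_survivors(self):
        """Fully penetrant antagonists: only heterozygous selfed progeny survive."""
        table = build_mating_table(GenotypeState(0, 1, 0), ModelParams(1, 1, 1))
        result = step_from_table(table)
        assert result.state.as_tuple() == (0.0, 1.0, 0.0)
        assert result.mean_fitness == pytest.approx(0.5, abs=TOL)

    def test_fixed_population_is_neutral(self):
        table = build_mating_table(GenotypeState(1, 0, 0), ModelParams(0.5, 1, 1))
        result = step_from_table(table)
        assert result.state.as_tuple() == (1.0, 0.0, 0.0)
        assert result.mean_fitness == pytest.approx(1.0, abs=TOL)

    def test_symmetric_outcross_enumeration(self):
        """Full 9-row outcross sum at symmetric start with k1 = k2 = 1."""
        table = build_mating_table(GenotypeState(0.25, 0.5, 0.25), ModelParams(0, 1, 1))
        result = step_from_table(table)
        assert result.state.p == pytest.approx(0.5, abs=TOL)
        assert result.state.Y == pytest.approx(2 / 3, abs=TOL)
        assert result.mean_fitness == pytest.approx(0.75, abs=TOL)


class TestStepMonoecious:
    def test_single_element_full_selfing(self):
        """One fully penetrant element, complete selfing, symmetric start."""
        result = step_monoecious(GenotypeState(0.25, 0.5, 0.25), ModelParams(1, 1, 0))
        assert result.state.p == pytest.approx(4 / 7, abs=TOL)
        assert result.state.Y == pytest.approx(2 / 7, abs=TOL)
        assert result.mean_fitness == pytest.approx(0.875, abs=TOL)

    def test_outcrossing_equal_penetrance_conserves_p(self):
        """Random mating with equal penetrances changes no allele frequency."""
        for k in (0.2, 0.7, 1.0):
            result = step_monoecious(
                GenotypeState(0.25, 0.5, 0.25), ModelParams(0, k, k)
            )
            assert result.state.p == pytest.approx(0.5, abs=TOL)

    def test_no_selection_identity(self, mono_fixtures):
        for state, _ in mono_fixtures[:20]:
            params = ModelParams(0.4, 0, 0)
            result = step_monoecious(state, params)
            assert result.state.p == pytest.approx(state.p, abs=TOL)
            assert result.mean_fitness == pytest.approx(1.0, abs=TOL)

    def test_oracle_equivalence(self, mono_fixtures):
        """Compact (p, Y) recursion == mating-table enumeration, componentwise."""
        for state, params in mono_fixtures:
            compact = step_monoecious(state, params)
            oracle = step_from_table(build_mating_table(state, params))
            assert compact.state.X == pytest.approx(oracle.state.X, abs=TOL)
            assert compact.state.Y == pytest.approx(oracle.state.Y, abs=TOL)
            assert compact.state.Z == pytest.approx(oracle.state.Z, abs=TOL)
            assert compact.mean_fitness == pytest.approx(oracle.mean_fitness, abs=TOL)

    def test_simplex_conservation(self, mono_fixtures):
        for state, params in mono_fixtures[:200]:
            nxt = step_monoecious(state, params).state
            assert nxt.X + nxt.Y + nxt.Z == pytest.approx(1.0, abs=TOL)

    @pytest.mark.parametrize("p_fixed", [0.0, 1.0])
    def test_boundary_fixed_points(self, p_fixed):
        state = GenotypeState.from_pY(p_fixed, 0.0)
        for S in (0.0, 0.5, 1.0):
            nxt = step_monoecious(state, ModelParams(S, 0.9, 0.4)).state
            assert nxt.p == pytest.approx(p_fixed, abs=TOL)
            assert nxt.Y == pytest.approx(0.0, abs=TOL)

    def test_frozen_selfer(self):
        """S = 1 without heterozygotes: every allele frequency is an equilibrium."""
        for p in (0.1, 0.37, 0.9):
            state = GenotypeState.from_pY(p, 0.0)
            nxt = step_monoecious(state, ModelParams(1, 1, 1)).state
            assert nxt.as_tuple() == pytest.approx(state.as_tuple(), abs=TOL)

    def test_heterozygote_restoration(self):
        """Any outcrossing rebuilds heterozygotes from a homozygote-only state."""
        for p, S in [(0.2, 0.0), (0.5, 0.6), (0.9, 0.99)]:
            state = GenotypeState.from_pY(p, 0.0)
            params = ModelParams(S, 0.8, 0.3)
            result = step_monoecious(state, params)
            expected = (1 - S) * 2 * p * (1 - p) / result.mean_fitness
            assert result.state.Y == pytest.approx(expected, abs=TOL)
            assert result.state.Y > 0

    @given(
        p=st.floats(0.01, 0.99),
        Y=st.floats(0.0, 1.0),
        S=st.floats(0.0, 1.0),
        k1=st.floats(0.0, 1.0),
        k2=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_step_preserves_simplex_property(self, p, Y, S, k1, k2):
        Y = min(Y, 2 * min(p, 1 - p))
        state = GenotypeState.from_pY(p, Y)
        nxt = step_monoecious(state, ModelParams(S, k1, k2)).state
        assert nxt.X + nxt.Y + nxt.Z == pytest.approx(1.0, abs=TOL)
        assert -TOL <= nxt.p <= 1 + TOL


class TestDiscussionLimits:
    """Closed-form allele-frequency increments for a single element (k2 = 0)."""

    def test_selfing_limit(self):
        for p, Y, k1 in [(0.3, 0.4, 1.0), (0.7, 0.2, 0.5), (0.1, 0.15, 0.9)]:
            state = GenotypeState.from_pY(p, Y)
            dp = step_monoecious(state, ModelParams(1, k1, 0)).state.p - p
            expected = (p * Y * k1 / 4) / (1 - Y * k1 / 4)
            assert dp == pytest.approx(expected, abs=TOL)

    def test_outcrossing_limit(self):
        for p, Y, k1 in [(0.3, 0.4, 1.0), (0.7, 0.2, 0.5), (0.1, 0.15, 0.9)]:
            q = 1 - p
            state = GenotypeState.from_pY(p, Y)
            dp = step_monoecious(state, ModelParams(0, k1, 0)).state.p - p
            expected = (p * q * Y * k1 / 2) / (1 - q * Y * k1 / 2)
            assert dp == pytest.approx(expected, abs=TOL)


class TestSignLaw:
    def test_direction_of_change_is_y_independent(self):
        """sign(dp) follows p k1 (S/2 + q(1-S)) - q k2 (S/2 + p(1-S)) for any Y > 0."""
        for S in (0.2, 0.6, 0.95):
            for k1, k2 in [(0.9, 0.5), (0.3, 0.8), (1.0, 1.0)]:
                for p in (0.1, 0.3, 0.5, 0.8):
                    q = 1 - p
                    predicted = p * k1 * (S / 2 + q * (1 - S)) - q * k2 * (
                        S / 2 + p * (1 - S)
                    )
                    for Y in (0.05, 0.2, 2 * min(p, q)):
                        state = GenotypeState.from_pY(p, Y)
                        dp = step_monoecious(state, ModelParams(S, k1, k2)).state.p - p
                        if abs(predicted) > 1e-12:
                            assert math.copysign(1, dp) == math.copysign(1, predicted)
                        else:
                            assert abs(dp) < 1e-9


class TestTrajectory:
    def test_constant_at_fixation(self):
        traj = iterate_trajectory(GenotypeState(1, 0, 0), ModelParams(0.5, 0.9, 0.5), 100)
        assert len(traj) == 101
        assert all(s.p == 1.0 for _, s, _ in traj)

    def test_bistable_fates_around_critical_selfing(self):
        """p0 = 0.2 invader sweeps under low selfing, is lost under high selfing."""
        start = GenotypeState.from_pY(0.2, 0.0)
        low = iterate_trajectory(start, ModelParams(0.0, 0.9, 0.5), 2000)[-1][1].p
        high = iterate_trajectory(start, ModelParams(0.6, 0.9, 0.5), 2000)[-1][1].p
        # approach to fixation is only algebraic under pure outcrossing
        # (selection pressure vanishes quadratically at the boundary)
        assert low > 0.99
        assert high < 1e-3

    def test_records_parental_mean_fitness(self):
        start = GenotypeState.from_pY(0.3, 0.2)
        params = ModelParams(0.4, 0.8, 0.6)
        traj = iterate_trajectory(start, params, 5)
        for _, state, wbar in traj:
            assert wbar == pytest.approx(mean_fitness(state, params), abs=TOL)


def test_allele_frequency_examples():
    assert allele_frequency(GenotypeState(0.25, 0.5, 0.25)) == 0.5
    assert allele_frequency(GenotypeState(1, 0, 0)) == 1.0
    assert allele_frequency(GenotypeState(0.1, 0.36, 0.54)) == pytest.approx(0.28)


def test_inert_allele_kills_nothing():
    """element = none zeroes that allele's penetrance in both code paths."""
    state = GenotypeState(0.2, 0.5, 0.3)
    params = ModelParams(0.5, 0.9, 0.7, Element.NONE, Element.MEDEA)
    inert = step_monoecious(state, params)
    explicit = step_monoecious(state, ModelParams(0.5, 0.0, 0.7))
    assert inert.state.as_tuple() == pytest.approx(explicit.state.as_tuple(), abs=TOL)


def test_invalid_states_and_params_rejected():
    with pytest.raises(ValueError):
        GenotypeState(0.5, 0.6, 0.4)
    with pytest.raises(ValueError):
        GenotypeState.from_pY(0.1, 0.9)
    with pytest.raises(ValueError):
        ModelParams(1.2, 0.5, 0.5)
    with pytest.raises(ValueError):
        ModelParams(0.5, -0.1, 0.5)
    with pytest.raises(ValueError):
        ModelParams(0.5, 0.5, 0.0).r
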