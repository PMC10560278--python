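"""Posterior updates, identification thresholds, and action selection."""

import numpy as np
import pytest

from bcinav.actions import Identify, Move
from bcinav.bayes import (
    BayesStrategy,
    PosteriorField,
    StringencyConfig,
    bayes_update_movement,
    bayes_update_ti,
    counterfactual_classes,
    counterfactual_state,
    decide_identification,
    next_action_bayes,
)
from bcinav.feedback import KindError, LikelihoodMatrix, Observation
from bcinav.gridworld import (
    EpisodeState,
    Grid,
    MovementClass,
    MovementEvent,
    Position,
    manhattan_distance,
    true_movement_class,
)


def _move_1d(frm, to):
    # 1-based display locations on the 9x1 grid
    return MovementEvent(Position(frm - 1, 0), Position(to - 1, 0))


class TestCounterfactualState:
    """Anchors: the 1-D move from location 5 to 6 under each hypothesis."""

    @pytest.mark.parametrize(
        "hyp, expected",
        [(1, MovementClass.FA), (2, MovementClass.FA), (3, MovementClass.FA),
         (4, MovementClass.FA), (5, MovementClass.SO), (6, MovementClass.TR),
         (7, MovementClass.TT), (8, MovementClass.TT), (9, MovementClass.TT)],
    )
    def test_move_5_to_6(self, hyp, expected):
        ev = _move_1d(5, 6)
        assert counterfactual_state(ev, Position(hyp - 1, 0)) == expected

    def test_vectorised_matches_scalar(self, rng):
        grid = Grid(5, 4)
        for _ in range(50):
            cells = grid.all_positions()
            origin = cells[rng.integers(len(cells))]
            from bcinav.gridworld import neighbours

            dest = neighbours(grid, origin)[0]
            ev = MovementEvent(origin, dest)
            vec = counterfactual_classes(grid, ev)
            for cell in cells:
                assert vec[grid.cell_index(cell)] == int(counterfactual_state(ev, cell))


def _oracle_movement_update(grid, prior, ev, obs_index, A, divide_marginal=True):
    """Independent cell-by-cell evaluation of the posterior update."""
    marginal = A[obs_index, :].sum() / A.sum() if divide_marginal else 1.0
    unnorm = np.empty(grid.n_cells)
    for idx, cell in enumerate(grid.all_positions()):
        state = int(true_movement_class(ev, cell))
        unnorm[idx] = A[obs_index, state] * prior[idx] / marginal
    return unnorm / unnorm.sum()


def _random_instance(rng):
    grid = Grid(int(rng.integers(2, 7)), int(rng.integers(1, 7)))
    from bcinav.gridworld import neighbours

    cells = grid.all_positions()
    origin = cells[int(rng.integers(len(cells)))]
    nb = neighbours(grid, origin)
    dest = nb[int(rng.integers(len(nb)))]
    A = rng.dirichlet(np.ones(4), size=4).T + 1e-3
    A = A / A.sum(axis=0)
    prior = rng.dirichlet(np.ones(grid.n_cells))
    obs = int(rng.integers(4))
    return grid, prior, MovementEvent(origin, dest), obs, A


def test_movement_update_matches_brute_force_oracle():
    """1,000 random small instances agree with explicit per-cell evaluation
    to 1e-12, and the posterior stays normalised."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        grid, prior, ev, obs, A = _random_instance(rng)
        p = PosteriorField(grid, prior.copy())
        got = bayes_update_movement(
            p, ev, Observation(obs, "movement"), LikelihoodMatrix(A, "movement")
        )
        expected = _oracle_movement_update(grid, prior, ev, obs, A)
        assert np.allclose(got.probabilities, expected, atol=1e-12, rtol=0)
        assert abs(got.probabilities.sum() - 1.0) < 1e-9


def test_marginal_divisor_cancels():
    """Dividing by P(O) or not yields the same normalised posterior."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        grid, prior, ev, obs, A = _random_instance(rng)
        with_div = _oracle_movement_update(grid, prior, ev, obs, A, divide_marginal=True)
        without = _oracle_movement_update(grid, prior, ev, obs, A, divide_marginal=False)
        assert np.allclose(with_div, without, atol=1e-12)


class TestMovementUpdateLimits:
    def test_uniform_likelihood_leaves_posterior_unchanged(self, small_grid, rng):
        p = PosteriorField.uniform(small_grid)
        A = LikelihoodMatrix(np.full((4, 4), 0.25), "movement")
        got = bayes_update_movement(p, _move_1d(5, 6), Observation(0, "movement"), A)
        assert np.allclose(got.probabilities, p.probabilities)

    def test_identity_likelihood_tr_collapses_posterior(self, small_grid):
        p = PosteriorField.uniform(small_grid)
        A = LikelihoodMatrix.identity("movement")
        got = bayes_update_movement(
            p, _move_1d(5, 6), Observation(int(MovementClass.TR), "movement"), A
        )
        expected = np.zeros(9)
        expected[5] = 1.0
        assert np.allclose(got.probabilities, expected)

    def test_kind_mismatch(self, small_grid):
        p = PosteriorField.uniform(small_grid)
        with pytest.raises(KindError):
            bayes_update_movement(
                p, _move_1d(5, 6), Observation(0, "ti"), LikelihoodMatrix.identity("movement")
            )


class TestTIUpdate:
    def test_identity_fti_zeroes_identified_cell(self, small_grid):
        p = PosteriorField.uniform(small_grid)
        got = bayes_update_ti(
            p, Position(3, 0), Observation(1, "ti"), LikelihoodMatrix.identity("ti")
        )
        assert got.probabilities[3] == 0.0
        assert np.allclose(got.probabilities.sum(), 1.0)
        assert np.allclose(got.probabilities[np.arange(9) != 3], 1 / 8)

    def test_uniform_ti_matrix_no_change(self, small_grid):
        p = PosteriorField.uniform(small_grid)
        A = LikelihoodMatrix(np.full((2, 2), 0.5), "ti")
        got = bayes_update_ti(p, Position(3, 0), Observation(1, "ti"), A)
        assert np.allclose(got.probabilities, p.probabilities)

    def test_diag_08_hand_value(self, small_grid):
        """FTI at cell c with a 0.8-diagonal matrix: c's posterior becomes
        0.2 / (0.2 + 8*0.8) from a uniform 9-cell prior."""
        p = PosteriorField.uniform(small_grid)
        A = LikelihoodMatrix(np.array([[0.8, 0.2], [0.2, 0.8]]), "ti")
        got = bayes_update_ti(p, Position(3, 0), Observation(1, "ti"), A)
        assert got.probabilities[3] == pytest.approx(0.2 / (0.2 + 8 * 0.8), abs=1e-12)

    def test_rejects_movement_matrix(self, small_grid):
        p = PosteriorField.uniform(small_grid)
        with pytest.raises(KindError):
            bayes_update_ti(
                p, Position(0, 0), Observation(1, "ti"), LikelihoodMatrix.identity("movement")
            )


def _field_with_mass_at(grid, cell, mass):
    probs = np.full(grid.n_cells, (1 - mass) / (grid.n_cells - 1))
    probs[grid.cell_index(cell)] = mass
    return PosteriorField(grid, probs)


class TestDecideIdentification:
    TR = Observation(int(MovementClass.TR), "movement")
    TT = Observation(int(MovementClass.TT), "movement")

    @pytest.mark.parametrize(
        "stringency, obs, p_c, expected",
        [
            (0.1, "TR", 0.15, True),    # > 10% chance with a TR output
            (0.1, "TT", 0.70, True),    # > twice as likely as all others (2/3)
            (0.1, "TT", 0.60, False),
            (0.9, "TR", 0.50, False),
            (0.9, "TT", 0.905, False),  # 0.905 < 1.0/1.1
            (0.9, "TR", 0.905, True),
        ],
    )
    def test_threshold_anchors(self, small_grid, stringency, obs, p_c, expected):
        cur = Position(4, 0)
        field = _field_with_mass_at(small_grid, cur, p_c)
        cfg = StringencyConfig(stringency)
        got = decide_identification(field, cur, getattr(self, obs), cfg)
        assert got is expected

    def test_upper_threshold_formula(self):
        for s in np.arange(0.1, 0.95, 0.1):
            cfg = StringencyConfig(round(s, 1))
            assert cfg.upper_threshold == pytest.approx((s + 0.1) / (s + 0.2))
            assert cfg.lower_threshold < cfg.upper_threshold

    def test_monotone_in_stringency(self, small_grid, rng):
        """Raising stringency never turns a no-identify into an identify."""
        cur = Position(4, 0)
        for _ in range(50):
            p_c = float(rng.uniform(0, 1))
            obs = [self.TR, self.TT][int(rng.integers(2))]
            field = _field_with_mass_at(small_grid, cur, p_c)
            decisions = [
                decide_identification(field, cur, obs, StringencyConfig(round(s, 1)))
                for s in np.arange(0.1, 0.95, 0.1)
            ]
            # True may only turn to False as stringency rises
            assert all(a or not b for a, b in zip(decisions, decisions[1:]))

    def test_binary_variant_ignores_tr_shortcut(self, small_grid):
        cur = Position(4, 0)
        field = _field_with_mass_at(small_grid, cur, 0.5)
        obs = Observation(0, "movement_binary")  # "correct"
        assert not decide_identification(field, cur, obs, StringencyConfig(0.1), binary=True)
        field = _field_with_mass_at(small_grid, cur, 0.7)
        assert decide_identification(field, cur, obs, StringencyConfig(0.1), binary=True)

    def test_rejects_ti_observation(self, small_grid):
        field = PosteriorField.uniform(small_grid)
        with pytest.raises(KindError):
            decide_identification(
                field, Position(0, 0), Observation(0, "ti"), StringencyConfig(0.1)
            )


class TestNextAction:
    def _state(self, grid, robot):
        return EpisodeState(grid=grid, target=Position(0, 0), robot=robot,
                            initial_distance=2)

    def test_step_toward_peaked_posterior(self, rng):
        grid = Grid(10, 10)
        field = _field_with_mass_at(grid, Position(9, 9), 0.999999)
        s = self._state(grid, Position(0, 0))
        act = next_action_bayes(field, s, None, StringencyConfig(0.1), rng)
        assert isinstance(act, Move)
        assert manhattan_distance(act.destination, Position(9, 9)) == 17

    def test_tied_posterior_uniform_step(self, small_grid):
        field = PosteriorField.uniform(small_grid)
        s = self._state(small_grid, Position(4, 0))
        seen = set()
        for seed in range(100):
            act = next_action_bayes(
                field, s, None, StringencyConfig(0.9), np.random.default_rng(seed)
            )
            seen.add(act.destination)
        assert seen == {Position(3, 0), Position(5, 0)}

    def test_peak_at_current_below_threshold_moves_to_runner_up(self, small_grid, rng):
        probs = np.full(9, 0.3 / 7)
        probs[4] = 0.4   # current cell, below the s=0.9 thresholds
        probs[8] = 0.3   # runner-up
        field = PosteriorField(small_grid, probs)
        s = self._state(small_grid, Position(4, 0))
        obs = Observation(int(MovementClass.TT), "movement")
        act = next_action_bayes(field, s, obs, StringencyConfig(0.9), rng)
        assert act == Move(Position(5, 0))  # first step toward cell 9

    def test_identification_fires(self, small_grid, rng):
        field = _field_with_mass_at(small_grid, Position(4, 0), 0.95)
        s = self._state(small_grid, Position(4, 0))
        obs = Observation(int(MovementClass.TR), "movement")
        act = next_action_bayes(field, s, obs, StringencyConfig(0.5), rng)
        assert act == Identify(Position(4, 0))


class TestBayesStrategy:
    def test_posterior_normalised_through_episode(self, small_grid, rng):
        strat = BayesStrategy(
            LikelihoodMatrix.uniform_diagonal("movement", 0.7),
            LikelihoodMatrix.uniform_diagonal("ti", 0.8),
            stringency=0.5,
        )
        state = EpisodeState(grid=small_grid, target=Position(8, 0),
                             robot=Position(0, 0), initial_distance=8)
        strat.reset(state, rng)
        pos = state.robot
        for _ in range(30):
            dest = Position(min(pos.row + 1, 8), 0) if pos.row < 8 else Position(7, 0)
            ev = MovementEvent(pos, dest)
            obs = Observation(int(rng.integers(4)), "movement")
            state.robot = dest
            strat.observe_movement(ev, obs, state)
            strat.posterior.check_normalised()
            pos = dest

    def test_fti_deselection_forces_movement_next(self, small_grid, rng):
        strat = BayesStrategy(
            LikelihoodMatrix.uniform_diagonal("movement", 0.7),
            LikelihoodMatrix.uniform_diagonal("ti", 0.8),
            stringency=0.1,
        )
        state = EpisodeState(grid=small_grid, target=Position(8, 0),
                             robot=Position(4, 0), initial_distance=4)
        strat.reset(state, rng)
        # pile evidence on the current cell, then deselect it
        strat.observe_movement(
            MovementEvent(Position(3, 0), Position(4, 0)),
            Observation(int(MovementClass.TR), "movement"),
            state,
        )
        strat.observe_ti_false(Position(4, 0), state)
        act = strat.next_action(state, rng)
        assert isinstance(act, Move)

    def test_custom_initial_posterior(self, small_grid, rng):
        prior = np.zeros(9)
        prior[8] = 1.0
        strat = BayesStrategy(
            LikelihoodMatrix.identity("movement"),
            LikelihoodMatrix.identity("ti"),
            initial_posterior=prior,
        )
        state = EpisodeState(grid=small_grid, target=Position(8, 0),
                             robot=Position(0, 0), initial_distance=8)
        strat.reset(state, rng)
        assert strat.posterior.probabilities[8] == 1.0
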