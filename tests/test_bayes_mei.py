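"""Tests for posterior updating, entropy, and MEI level selection."""

import numpy as np
import pytest

from clsmei import (
    Catalog,
    PosteriorState,
    SelectionConstraints,
    entropy,
    expected_posterior_entropy,
    init_posterior,
    predictive_response_dist,
    select_mei_level,
    update_posterior,
)
from clsmei.bayes_mei import LikelihoodTable
from conftest import random_valid_mcpf, uniform_mcpf


def brute_force_expected_entropy(state, catalog, level, table):
    """Independent double loop over the 11 responses: weight each posterior's
    entropy by its predictive probability (the update's normalizing mass)."""
    total = 0.0
    for cu in range(0, 55, 5):
        lik = table.floored(level)[:, cu // 5]
        mass = float((state.probs * lik).sum())
        post = update_posterior(state, catalog, (level, cu), table)
        total += mass * entropy(post)
    return total


def brute_force_mei(state, catalog, constraints, table):
    cands = constraints.candidate_levels()
    values = [brute_force_expected_entropy(state, catalog, lv, table) for lv in cands]
    best = min(values)
    for lv, v in zip(cands, values):
        if v <= best + 1e-12:
            return float(lv)
    raise AssertionError


def random_catalog(rng, n):
    return Catalog(tuple(random_valid_mcpf(rng, f"e{i}") for i in range(n)))


class TestInitAndEntropy:
    def test_uniform_prior_and_log2_entropy(self, mid_catalog):
        state = init_posterior(mid_catalog)
        np.testing.assert_allclose(state.probs, 1 / len(mid_catalog))
        assert entropy(state) == pytest.approx(np.log2(len(mid_catalog)), abs=1e-12)

    def test_two_entries_one_bit(self, two_entry_catalog):
        state = init_posterior(two_entry_catalog)
        assert entropy(state) == pytest.approx(1.0, abs=1e-12)

    def test_hand_entropy(self):
        assert entropy(PosteriorState(np.array([0.5, 0.25, 0.25]))) == pytest.approx(1.5)

    def test_point_mass_zero_bits(self):
        assert entropy(PosteriorState(np.array([0.0, 1.0, 0.0]))) == 0.0

    def test_invalid_posterior_rejected(self):
        with pytest.raises(ValueError):
            PosteriorState(np.array([0.6, 0.6]))


class TestUpdate:
    def test_matches_manual_normalization(self, small_catalog):
        table = LikelihoodTable(small_catalog)
        state = init_posterior(small_catalog)
        lik = table.floored(60.0)[:, 25 // 5]
        expected = state.probs * lik / (state.probs * lik).sum()
        got = update_posterior(state, small_catalog, (60.0, 25), table)
        np.testing.assert_allclose(got.probs, expected, atol=1e-12)
        assert got.n_trials_absorbed == 1
        assert state.n_trials_absorbed == 0  # input unmodified

    def test_uninformative_trial_leaves_posterior(self):
        # identical entries: every response is equally likely under each
        a = uniform_mcpf("a")
        b = uniform_mcpf("b")
        cat = Catalog((a, b))
        state = init_posterior(cat)
        new = update_posterior(state, cat, (55.0, 20))
        np.testing.assert_allclose(new.probs, state.probs, atol=1e-12)

    def test_order_invariance(self, small_catalog):
        trials = [(30.0, 10), (70.0, 35), (50.0, 20)]
        table = LikelihoodTable(small_catalog)

        def run(seq):
            s = init_posterior(small_catalog)
            for t in seq:
                s = update_posterior(s, small_catalog, t, table)
            return s.probs

        np.testing.assert_allclose(run(trials), run(trials[::-1]), atol=1e-12)
        # and equals one-shot joint-likelihood normalization
        joint = np.ones(len(small_catalog))
        for lv, cu in trials:
            joint *= table.floored(lv)[:, cu // 5]
        np.testing.assert_allclose(run(trials), joint / joint.sum(), atol=1e-12)

    def test_off_scale_response_rejected(self, small_catalog):
        with pytest.raises(ValueError):
            update_posterior(init_posterior(small_catalog), small_catalog, (60.0, 27))


class TestPredictive:
    def test_point_mass_gives_entry_probs(self, two_entry_catalog):
        state = PosteriorState(np.array([1.0, 0.0]))
        table = LikelihoodTable(two_entry_catalog)
        got = predictive_response_dist(state, two_entry_catalog, 55.0, table)
        np.testing.assert_allclose(got, table.raw(55.0)[0], atol=1e-9)

    def test_uniform_mixture_is_mean(self, two_entry_catalog):
        state = init_posterior(two_entry_catalog)
        table = LikelihoodTable(two_entry_catalog)
        got = predictive_response_dist(state, two_entry_catalog, 80.0, table)
        np.testing.assert_allclose(got, table.raw(80.0).mean(axis=0), atol=1e-9)

    def test_weighted_three_entry_sum(self):
        rng = np.random.default_rng(1)
        cat = random_catalog(rng, 3)
        w = np.array([0.5, 0.3, 0.2])
        state = PosteriorState(w)
        table = LikelihoodTable(cat)
        got = predictive_response_dist(state, cat, 65.0, table)
        np.testing.assert_allclose(got, w @ table.raw(65.0), atol=1e-9)


class TestExpectedEntropy:
    def test_point_mass_is_zero(self, two_entry_catalog):
        state = PosteriorState(np.array([0.0, 1.0]))
        for lv in (20.0, 60.0, 100.0):
            assert expected_posterior_entropy(state, two_entry_catalog, lv) == pytest.approx(0.0, abs=1e-12)

    def test_uninformative_level_keeps_entropy(self):
        cat = Catalog((uniform_mcpf("a"), uniform_mcpf("b")))
        state = init_posterior(cat)
        got = expected_posterior_entropy(state, cat, 55.0)
        assert got == pytest.approx(entropy(state), abs=1e-9)

    def test_matches_brute_force(self, two_entry_catalog):
        state = init_posterior(two_entry_catalog)
        table = LikelihoodTable(two_entry_catalog)
        for lv in np.arange(0, 115, 5.0):
            got = expected_posterior_entropy(state, two_entry_catalog, lv, table)
            want = brute_force_expected_entropy(state, two_entry_catalog, lv, table)
            assert got == pytest.approx(want, abs=1e-10)

    def test_information_never_hurts(self):
        rng = np.random.default_rng(5)
        for i in range(20):
            cat = random_catalog(rng, int(rng.integers(2, 8)))
            table = LikelihoodTable(cat)
            p = rng.dirichlet(np.ones(len(cat)))
            state = PosteriorState(p)
            h = entropy(state)
            for lv in rng.choice(np.arange(0, 115, 5.0), size=5):
                assert expected_posterior_entropy(state, cat, lv, table) <= h + 1e-12


class TestSelection:
    def test_point_mass_tie_breaks_lowest(self, two_entry_catalog):
        state = PosteriorState(np.array([1.0, 0.0]))
        c = SelectionConstraints(lower_limit=20.0, upper_limit=90.0)
        assert select_mei_level(state, two_entry_catalog, c) == 20.0

    def test_max_transition_filters_candidates(self, two_entry_catalog):
        c = SelectionConstraints(previous_level=100.0, max_transition=45.0)
        cands = c.candidate_levels()
        assert cands.min() == 55.0
        assert 100.0 not in cands  # no consecutive repeat

    def test_discriminative_region_selected(self, two_entry_catalog):
        # the entries differ only above 60 dB, so MEI must probe there
        state = init_posterior(two_entry_catalog)
        c = SelectionConstraints(lower_limit=0.0, upper_limit=110.0)
        lv = select_mei_level(state, two_entry_catalog, c)
        assert lv >= 60.0

    def test_empty_candidate_set_fails(self, two_entry_catalog):
        state = init_posterior(two_entry_catalog)
        c = SelectionConstraints(
            lower_limit=50.0, upper_limit=50.0, previous_level=50.0
        )
        with pytest.raises(ValueError):
            select_mei_level(state, two_entry_catalog, c)

    def test_oracle_equivalence_random_catalogs(self):
        rng = np.random.default_rng(99)
        for i in range(25):
            cat = random_catalog(rng, int(rng.integers(2, 11)))
            table = LikelihoodTable(cat)
            p = rng.dirichlet(np.ones(len(cat)))
            state = PosteriorState(p)
            prev = float(rng.choice(np.arange(0, 115, 5.0)))
            c = SelectionConstraints(previous_level=prev)
            got = select_mei_level(state, cat, c, table)
            want = brute_force_mei(state, cat, c, table)
            assert got == want
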