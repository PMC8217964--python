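"""Ballot aggregation, SMART batch ranking and swing-weight derivation."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oppmcda import (
    Ballot,
    ElicitationError,
    QuestionType,
    TieError,
    VoteSet,
    aggregate_categorical,
    aggregate_numeric,
    default_efor_registry,
    derive_weights,
    run_workshop,
    smart_rank,
)
from oppmcda.elicitation import BallotValidationError

from conftest import PILOT_INCREMENTS, PILOT_WEIGHTS_PCT


def make_votes(ballots, registry):
    return VoteSet(ballots=tuple(ballots), registry=registry)


CAT = {"q": QuestionType.CATEGORICAL}
NUM = {"q": QuestionType.NUMERIC}


class TestCategorical:
    def test_pilot_inclusion_split_keeps_all_nine(self):
        # 21 voters realising the reported 57/19/24 percent split
        ballots = (
            [Ballot(f"v{i}", "q", "keep_9") for i in range(12)]
            + [Ballot(f"w{i}", "q", "keep_8") for i in range(4)]
            + [Ballot(f"x{i}", "q", "keep_7") for i in range(5)]
        )
        res = aggregate_categorical(make_votes(ballots, CAT), "q")
        assert res.winner == "keep_9"
        assert res.shares["keep_9"] == pytest.approx(12 / 21)
        assert math.fsum(res.shares.values()) == pytest.approx(1.0)

    def test_singleton_winner_has_full_share(self):
        res = aggregate_categorical(make_votes([Ballot("v", "q", "A")], CAT), "q")
        assert res.winner == "A" and res.shares == {"A": 1.0}

    def test_exact_tie_is_explicit(self):
        ballots = [Ballot(f"v{i}", "q", "A" if i < 5 else "B") for i in range(10)]
        res = aggregate_categorical(make_votes(ballots, CAT), "q")
        assert res.winner is None and res.tied == ("A", "B")

    @pytest.mark.parametrize(
        "policy, expected", [("fewest", "A"), ("most", "B")]
    )
    def test_explicit_tie_break_policies(self, policy, expected):
        ballots = [Ballot("v1", "q", "A"), Ballot("v2", "q", "B")]
        res = aggregate_categorical(make_votes(ballots, CAT), "q", tie_break=policy)
        assert res.winner == expected and res.is_tie

    def test_rerun_policy_raises(self):
        ballots = [Ballot("v1", "q", "A"), Ballot("v2", "q", "B")]
        with pytest.raises(TieError) as exc:
            aggregate_categorical(make_votes(ballots, CAT), "q", tie_break="rerun")
        assert exc.value.options == ("A", "B")

    def test_zero_ballots_is_an_error(self):
        with pytest.raises(ElicitationError):
            aggregate_categorical(make_votes([], CAT), "q")

    def test_invariant_under_ballot_reordering(self):
        ballots = [Ballot(f"v{i}", "q", opt) for i, opt in enumerate("ABABB")]
        a = aggregate_categorical(make_votes(ballots, CAT), "q")
        b = aggregate_categorical(make_votes(ballots[::-1], CAT), "q")
        assert (a.winner, a.shares) == (b.winner, b.shares)


class TestNumeric:
    @pytest.mark.parametrize(
        "responses, expected",
        [((200, 208), 204.0), ((42.5,), 42.5), ((10, 20, 30, 40), 25.0)],
    )
    def test_mean(self, responses, expected):
        ballots = [Ballot(f"v{i}", "q", float(r)) for i, r in enumerate(responses)]
        assert aggregate_numeric(make_votes(ballots, NUM), "q") == pytest.approx(expected)

    def test_zero_ballots_is_an_error(self):
        with pytest.raises(ElicitationError):
            aggregate_numeric(make_votes([], NUM), "q")

    def test_non_numeric_response_rejected_at_construction(self):
        with pytest.raises(BallotValidationError):
            make_votes([Ballot("v", "q", "lots")], NUM)

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=20), st.randoms(use_true_random=False))
    def test_permutation_invariance(self, values, rnd):
        ballots = [Ballot(f"v{i}", "q", v) for i, v in enumerate(values)]
        shuffled = list(ballots)
        rnd.shuffle(shuffled)
        assert aggregate_numeric(make_votes(ballots, NUM), "q") == aggregate_numeric(
            make_votes(shuffled, NUM), "q"
        )


def brute_force_batch_order(ballots_by_voter, pool):
    """Independent oracle: mean within-batch position, id tie-break."""
    positions = {}
    for order in ballots_by_voter:
        for pos, cid in enumerate(order, start=1):
            positions.setdefault(cid, []).append(pos)
    return sorted(positions, key=lambda c: (sum(positions[c]) / len(positions[c]), c))


class TestSmartRank:
    REG = {"b1": QuestionType.RANKING_BATCH, "b2": QuestionType.RANKING_BATCH}

    def _cs(self, ids):
        from oppmcda import Criterion, CriterionSet

        return CriterionSet(criteria=tuple(Criterion(id=i, name=i) for i in ids))

    def test_unanimity_returns_the_common_order(self):
        cs = self._cs("abcd")
        ballots = [
            Ballot(v, "b1", ("c", "a")) for v in ("v1", "v2")
        ] + [Ballot(v, "b2", ("d", "b")) for v in ("v1", "v2")]
        got = smart_rank(make_votes(ballots, self.REG), ["b1", "b2"], cs)
        assert got == ("c", "a", "d", "b")

    def test_two_voter_tie_resolved_lexicographically(self):
        # mean positions: A=1.5, B=1.5, C=3 -> tie {A,B} broken by id
        cs = self._cs(["A", "B", "C"])
        reg = {"b1": QuestionType.RANKING_BATCH}
        ballots = [Ballot("v1", "b1", ("A", "B", "C")), Ballot("v2", "b1", ("B", "A", "C"))]
        got = smart_rank(make_votes(ballots, reg), ["b1"], cs)
        assert got == ("A", "B", "C")

    def test_id_outside_pool_names_voter_and_id(self):
        cs = self._cs("abcd")
        ballots = [
            Ballot("v1", "b1", ("a", "b")),
            Ballot("v1", "b2", ("a", "c")),  # 'a' already placed by batch 1
        ]
        with pytest.raises(BallotValidationError) as exc:
            smart_rank(make_votes(ballots, self.REG), ["b1", "b2"], cs)
        assert "v1" in str(exc.value) and "'a'" in str(exc.value)

    def test_agrees_with_brute_force_over_small_panels(self):
        # exhaustive-ish sweep: <=4 criteria, <=5 voters, single batch ranking all
        reg = {"b1": QuestionType.RANKING_BATCH}
        for n_crit in (2, 3, 4):
            ids = [chr(ord("a") + i) for i in range(n_crit)]
            cs = self._cs(ids)
            perms = list(itertools.permutations(ids))
            for n_voters in (1, 2, 3, 5):
                for trial in range(20):
                    # deterministic pseudo-random voter profiles
                    profile = [perms[(trial * 7 + v * 13) % len(perms)] for v in range(n_voters)]
                    ballots = [Ballot(f"v{v}", "b1", p) for v, p in enumerate(profile)]
                    got = smart_rank(make_votes(ballots, reg), ["b1"], cs)
                    assert list(got) == brute_force_batch_order(profile, ids)


class TestDeriveWeights:
    def test_pilot_increments_reproduce_published_weights(self, registry):
        scheme = derive_weights(registry.ids, PILOT_INCREMENTS)
        assert scheme.display_percents() == PILOT_WEIGHTS_PCT
        assert math.fsum(scheme.display_percents()) == pytest.approx(100.0, abs=1e-9)

    def test_all_zero_increments_give_equal_weights(self):
        scheme = derive_weights([f"c{i}" for i in range(9)], [0.0] * 8)
        assert all(w == pytest.approx(1 / 9) for w in scheme.weights)

    def test_single_unit_increment_closed_form(self):
        # top raw weight 2, eight raws of 1 -> 20% then 10% each
        scheme = derive_weights([f"c{i}" for i in range(9)], [1.0] + [0.0] * 7)
        assert scheme.raw == (2.0,) + (1.0,) * 8
        assert scheme.weights[0] == pytest.approx(0.2)
        assert all(w == pytest.approx(0.1) for w in scheme.weights[1:])

    def test_negative_increment_rejected(self):
        with pytest.raises(ElicitationError):
            derive_weights(["a", "b"], [-0.1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ElicitationError):
            derive_weights(["a", "b", "c"], [0.1])

    # zero or clearly-representable increments: below ~1e-16 the chain factor
    # 1 + delta rounds to 1 and strict monotonicity cannot hold in floats
    @given(
        st.lists(
            st.one_of(st.just(0.0), st.floats(1e-6, 5.0)), min_size=1, max_size=11
        ).map(tuple)
    )
    @settings(max_examples=200, deadline=None)
    def test_normalization_and_monotonicity(self, incr):
        ids = [f"c{i}" for i in range(len(incr) + 1)]
        scheme = derive_weights(ids, incr)
        assert math.fsum(scheme.weights) == pytest.approx(1.0, abs=1e-12)
        for i, d in enumerate(incr):
            if d > 0:
                assert scheme.weights[i] > scheme.weights[i + 1]
            else:
                assert scheme.weights[i] == scheme.weights[i + 1]

    @given(st.lists(st.floats(0.0, 5.0), min_size=1, max_size=11), st.floats(0.1, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_of_normalization(self, incr, k):
        # scaling all raw weights by k > 0 leaves normalized weights unchanged
        ids = [f"c{i}" for i in range(len(incr) + 1)]
        scheme = derive_weights(ids, incr)
        scaled = [k * r for r in scheme.raw]
        total = math.fsum(scaled)
        renorm = [s / total for s in scaled]
        assert all(a == pytest.approx(b, rel=1e-12) for a, b in zip(renorm, scheme.weights))


class TestRunWorkshop:
    def test_pilot_votes_reproduce_the_published_scheme(self, registry, pilot_votes):
        res = run_workshop(pilot_votes, registry)
        assert res.kept == registry
        assert res.price_rule.threshold == pytest.approx(2.04)
        assert res.scheme.ranked_ids == registry.ids
        assert res.scheme.display_percents() == PILOT_WEIGHTS_PCT
        assert any("inclusion" in line for line in res.report)

    def test_empty_vote_set_names_first_missing_question(self, registry):
        from oppmcda import standard_question_registry

        empty = VoteSet(ballots=(), registry=standard_question_registry())
        with pytest.raises(ElicitationError) as exc:
            run_workshop(empty, registry)
        assert "criteria_inclusion" in str(exc.value)
        assert exc.value.stage == "inclusion"

    def test_stage_name_attached_to_downstream_failures(self, registry, pilot_votes):
        # drop one increment question entirely
        ballots = tuple(b for b in pilot_votes.ballots if b.question_id != "increment_8")
        votes = VoteSet(ballots=ballots, registry=pilot_votes.registry)
        with pytest.raises(ElicitationError) as exc:
            run_workshop(votes, registry)
        assert exc.value.stage == "increment_8"
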