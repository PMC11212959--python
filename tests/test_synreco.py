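import numpy as np
import pytest

from parsability.synreco import (
    IllegalOrderError,
    IncompleteTrialError,
    MalformedLogError,
    NotCheckableError,
    ParticipantLog,
    RatingRecord,
    SynRecoTrial,
    TrialCompleteError,
    include_participant,
    include_rater,
    read_logs,
    reconstruction_grammaticality,
    run_trial,
    verbatim_accuracy,
    write_logs,
)


def make_trial(tokens, **kw):
    return SynRecoTrial(item_id="i0", condition="Intact", full_sequence=list(tokens), **kw)


class TestStateMachine:
    def test_reveal_appends_to_last_submitted_order(self):
        t = make_trial(["this", "a", "is"])
        t.reveal_next().reveal_next()
        t.apply_reorder(["this", "a"])
        t.reveal_next()
        assert t.current_words == ["this", "a", "is"]

    def test_fresh_trial_first_reveal(self):
        t = make_trial(["this", "a", "is"])
        t.reveal_next()
        assert t.current_words == ["this"]

    def test_reveal_past_end_raises(self):
        t = make_trial(["a", "b"])
        t.reveal_next().reveal_next()
        with pytest.raises(TrialCompleteError):
            t.reveal_next()

    def test_reorder_to_grammatical_string(self):
        t = make_trial(["this", "a", "is"])
        for _ in range(3):
            t.reveal_next()
        t.apply_reorder(["this", "is", "a"])
        assert t.current_words == ["this", "is", "a"]
        assert t.submissions == [(3, [0, 2, 1])]

    def test_identity_reorder_recorded(self):
        t = make_trial(["a", "b"])
        t.reveal_next().reveal_next()
        t.apply_reorder(["a", "b"])
        assert t.submissions == [(2, [0, 1])]

    def test_unrevealed_word_rejected(self):
        t = make_trial(["this", "a", "is"])
        t.reveal_next().reveal_next()
        with pytest.raises(IllegalOrderError):
            t.apply_reorder(["this", "is"])

    def test_duplicate_words_tracked_by_reveal_index(self):
        t = make_trial(["the", "cat", "the", "dog"])
        for _ in range(4):
            t.reveal_next()
        t.apply_reorder(["the", "the", "cat", "dog"])
        assert sorted(t.current_order) == [0, 1, 2, 3]
        assert t.current_words == ["the", "the", "cat", "dog"]

    def test_display_multiset_invariant_under_random_actions(self):
        """Fuzz: any legal reveal/reorder sequence keeps the display equal
        (as a multiset) to the revealed stimulus tokens."""
        rng = np.random.default_rng(11)
        tokens = ["a", "b", "a", "c", "b", "d"]
        for _ in range(40):
            t = make_trial(tokens)
            while not t.is_complete:
                t.reveal_next()
                if rng.random() < 0.7:
                    perm = rng.permutation(len(t.current_order))
                    t.apply_reorder([t.current_words[i] for i in perm])
                assert sorted(t.current_words) == sorted(tokens[: t.n_revealed])


class TestCheckOrder:
    def test_allowed_and_disallowed_orders(self):
        allowed = {3: {("this", "is", "a")}, 2: {("this", "a"), ("a", "this")}}
        t = make_trial(["this", "a", "is"], allowed_orders=allowed)
        t.reveal_next().reveal_next()
        t.apply_reorder(["a", "this"])
        assert t.check_order() is True
        t.reveal_next()
        t.apply_reorder(["is", "this", "a"])
        assert t.check_order() is False
        t.apply_reorder(["this", "is", "a"])
        assert t.check_order() is True

    def test_multiple_permissible_orders_both_accepted(self):
        allowed = {3: {("books", "and", "pencils"), ("pencils", "and", "books")}}
        for order in (["books", "and", "pencils"], ["pencils", "and", "books"]):
            t = make_trial(["books", "and", "pencils"], allowed_orders=allowed)
            for _ in range(3):
                t.reveal_next()
            t.apply_reorder(order)
            assert t.check_order() is True

    def test_missing_allowed_orders_not_checkable(self):
        t = make_trial(["a", "b"])
        t.reveal_next()
        with pytest.raises(NotCheckableError):
            t.check_order()


class TestInclusionFilter:
    @pytest.mark.parametrize(
        "attention,fillers,expected",
        [
            (5, 8, True),
            (4, 6, True),   # boundary: "at least"
            (3, 12, False),
            (7, 5, False),
            (4, 5, False),
        ],
    )
    def test_thresholds(self, attention, fillers, expected):
        p = ParticipantLog(
            participant_id="p",
            attention_results=[True] * attention + [False] * (7 - attention),
            filler_results=[True] * fillers + [False] * (12 - fillers),
        )
        assert include_participant(p) is expected

    def test_monotone_adding_a_pass_never_excludes(self):
        for att in range(8):
            for fil in range(13):
                p = ParticipantLog(
                    "p",
                    attention_results=[True] * att + [False] * (7 - att),
                    filler_results=[True] * fil + [False] * (12 - fil),
                )
                if include_participant(p):
                    for i in range(7):
                        q = ParticipantLog(
                            "p",
                            attention_results=[
                                True if j == i else v
                                for j, v in enumerate(p.attention_results)
                            ],
                            filler_results=list(p.filler_results),
                        )
                        assert include_participant(q)

    def test_malformed_log_rejected(self):
        p = ParticipantLog("p", attention_results=[True] * 3, filler_results=[True] * 12)
        with pytest.raises(MalformedLogError):
            include_participant(p)


class TestVerbatimAccuracy:
    def test_untouched_intact_orders_score_one(self):
        originals = {"i0": ["a", "b", "c"]}
        t = run_trial(["a", "b", "c"], "i0", "Intact", policy=lambda tr: None)
        assert verbatim_accuracy([t], originals) == {"Intact": 1.0}

    def test_incomplete_trial_rejected(self):
        t = make_trial(["a", "b"])
        t.reveal_next()
        with pytest.raises(IncompleteTrialError):
            verbatim_accuracy([t], {"i0": ["a", "b"]})

    def test_mixed_outcomes_averaged_per_condition(self):
        originals = {"i0": ["a", "b"], "i1": ["c", "d"]}
        good = run_trial(["a", "b"], "i0", "Scrambled1", policy=lambda tr: None)
        bad = run_trial(["d", "c"], "i1", "Scrambled1", policy=lambda tr: None)
        assert verbatim_accuracy([good, bad], originals) == {"Scrambled1": 0.5}


class TestReconstructionGrammaticality:
    class ConstantScorer:
        def __init__(self):
            self.seen = []

        def score(self, tokens, sentence_id=""):
            from parsability.surprisal_scoring import mean_surprisal

            self.seen.append(list(tokens))
            # surprisal proxy: number of adjacent out-of-alphabet-order pairs
            v = sum(1 for a, b in zip(tokens, tokens[1:]) if a > b)
            return mean_surprisal([v] * len(tokens), sentence_id)

    def test_noop_participants_equal_stimulus_baseline(self):
        t = run_trial(["b", "a"], "i0", "Scrambled1", policy=lambda tr: None)
        res = reconstruction_grammaticality([t], self.ConstantScorer())
        assert res["Scrambled1"]["reconstruction"] == res["Scrambled1"]["stimulus_baseline"]

    def test_perfect_reconstruction_beats_baseline(self):
        t = run_trial(["b", "a"], "i0", "Scrambled1",
                      policy=lambda tr: sorted(tr.current_words))
        res = reconstruction_grammaticality([t], self.ConstantScorer())
        assert res["Scrambled1"]["reconstruction"] < res["Scrambled1"]["stimulus_baseline"]


class TestRaterQc:
    def _record(self, gram_sent=4, gram_wl=2, extra=()):
        ratings = [("Intact", gram_sent, 5), ("WordList", gram_wl, 1),
                   ("Intact", 3, 2), ("WordList", 1, 4)]
        ratings += list(extra)
        return RatingRecord("r0", ratings)

    def test_good_rater_included(self):
        assert include_rater(self._record()) is True

    def test_never_using_top_rating_excludes(self):
        r = RatingRecord("r0", [("Intact", 4, 3), ("WordList", 1, 2),
                                ("Intact", 3, 2), ("WordList", 2, 1)])
        assert include_rater(r) is False

    def test_low_sentence_grammaticality_excludes(self):
        r = RatingRecord("r0", [("Intact", 2, 5), ("WordList", 1, 3),
                                ("Intact", 3, 2), ("WordList", 4, 1)])
        # Intact mean = 2.5 < 3
        assert include_rater(r) is False

    def test_invalid_rating_values_rejected(self):
        with pytest.raises(ValueError):
            RatingRecord("r0", [("Intact", 6, 3)])

    def test_missing_condition_malformed(self):
        r = RatingRecord("r0", [("Intact", 5, 1), ("Intact", 1, 2),
                                ("Intact", 3, 4), ("Intact", 2, 3)])
        with pytest.raises(MalformedLogError):
            include_rater(r)


class TestLogRoundtrip:
    def test_jsonl_write_read_preserves_finals_and_bookkeeping(self, tmp_path):
        t1 = run_trial(["b", "a", "c"], "i0", "Scrambled1",
                       policy=lambda tr: sorted(tr.current_words))
        t2 = run_trial(["c", "b", "a"], "i1", "Backward", policy=lambda tr: None)
        log = ParticipantLog("p0", trials=[t1, t2],
                             attention_results=[True] * 7,
                             filler_results=[True] * 6 + [False] * 6)
        p = tmp_path / "logs.jsonl"
        write_logs([log], p)
        back = read_logs(p)
        assert len(back) == 1
        assert [t.final_words for t in back[0].trials] == [t1.final_words, t2.final_words]
        assert back[0].attention_results == log.attention_results
        assert back[0].filler_results == log.filler_results
        assert include_participant(back[0]) == include_participant(log)
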