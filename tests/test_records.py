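"""Event-log analysis: validation, dynamic tournament, episodes, abstraction chain."""

import io
import itertools

import numpy as np
import pytest

from peckorder import (
    EmptyRecordError,
    GeneratorConfig,
    InteractionEvent,
    InteractionRecord,
    RecordValidationError,
    TriadConfiguration,
    UndefinedRateError,
    attack_matrix,
    current_tournament,
    dominance_relations,
    episode_summary,
    episodes,
    estimate_rates,
    generate_record,
    is_linear,
    linearity_timeline,
    rank_order,
    read_events,
)
from peckorder.records import LINEAR, NONLINEAR, UNDEFINED


def _tsv(rows):
    return io.StringIO("time_s\tactor\trecipient\n" + "".join(rows))


class TestReadEvents:
    def test_well_formed(self):
        rec = read_events(_tsv(["0.0\tA\tB\n", "1.0\tB\tC\n", "2.0\tC\tA\n"]))
        assert len(rec.events) == 3
        assert rec.roster == ("A", "B", "C")

    def test_extra_columns_ignored(self):
        src = io.StringIO("time_s\tactor\trecipient\tnote\n1.0\tA\tB\tpeck\n")
        rec = read_events(src)
        assert rec.events[0].actor == "A"

    def test_self_attack_names_line(self):
        with pytest.raises(RecordValidationError, match="line 3"):
            read_events(_tsv(["0.0\tA\tB\n", "10.0\tA\tA\n"]))

    def test_decreasing_time_names_line(self):
        with pytest.raises(RecordValidationError, match="line 3"):
            read_events(_tsv(["5.0\tA\tB\n", "4.0\tB\tA\n"]))

    def test_empty_file_flagged(self):
        with pytest.raises(EmptyRecordError):
            read_events(_tsv([]))

    def test_missing_column(self):
        with pytest.raises(RecordValidationError, match="missing column"):
            read_events(io.StringIO("time_s\tactor\n1.0\tA\n"))

    def test_equal_timestamps_keep_file_order(self):
        rec = read_events(_tsv(["1.0\tA\tB\n", "1.0\tB\tA\n"]))
        pt = current_tournament(rec)
        assert pt.directions[("A", "B")] == ("B", "A")  # later row wins


class TestCurrentTournament:
    def test_most_recent_attack_wins(self):
        rec = read_events(_tsv(["0.0\tA\tB\n", "1.0\tB\tA\n"]))
        pt = current_tournament(rec)
        assert pt.directions[("A", "B")] == ("B", "A")

    def test_upto_zero_is_empty(self, toy_record):
        pt = current_tournament(toy_record, 0)
        assert pt.directions == {} and not pt.is_complete

    def test_fill_in_completes(self):
        rows = [f"{i}.0\t{a}\t{b}\n" for i, (a, b) in
                enumerate(itertools.combinations("ABCD", 2))]
        rec = read_events(_tsv(rows))
        pt = current_tournament(rec)
        assert pt.is_complete
        assert is_linear(pt.to_tournament())  # A>all, B>C,D, C>D is linear

    def test_incomplete_cannot_convert(self, toy_record):
        with pytest.raises(ValueError, match="incomplete"):
            current_tournament(toy_record, 2).to_tournament()

    def test_upto_out_of_range(self, toy_record):
        with pytest.raises(ValueError):
            current_tournament(toy_record, 9)


class TestEpisodes:
    def test_hand_trace(self, toy_record):
        eps = episodes(toy_record)
        assert len(eps) == 2
        first, second = eps
        assert first.configuration is TriadConfiguration.TRANSITIVE
        assert not first.censored
        assert first.start_event_index == 2 and first.end_event_index == 3
        assert first.duration_interactions == 1
        assert first.duration_s == pytest.approx(120.0)
        assert second.configuration is TriadConfiguration.INTRANSITIVE
        assert second.censored and second.end_event_index is None

    def test_repeat_attacks_extend_episodes(self):
        rec = InteractionRecord(
            ("A", "B", "C"),
            (
                InteractionEvent(0.0, "A", "B"),
                InteractionEvent(10.0, "B", "C"),
                InteractionEvent(20.0, "A", "C"),
                InteractionEvent(60.0, "A", "C"),  # repeat: does not end the spell
                InteractionEvent(140.0, "C", "A"),
            ),
        )
        first = episodes(rec)[0]
        assert first.duration_interactions == 2
        assert first.duration_s == pytest.approx(120.0)

    def test_never_interacting_pair_yields_no_episodes(self):
        rec = read_events(_tsv(["0.0\tA\tB\n", "1.0\tB\tC\n", "2.0\tA\tB\n"]))
        assert episodes(rec) == []

    def test_small_roster_empty(self):
        rec = read_events(_tsv(["0.0\tA\tB\n"]))
        assert episodes(rec) == []

    def test_triad_internal_duration_option(self):
        # D-A event between completion and reversal counts for 'group' only
        rec = InteractionRecord(
            ("A", "B", "C", "D"),
            (
                InteractionEvent(0.0, "A", "B"),
                InteractionEvent(1.0, "B", "C"),
                InteractionEvent(2.0, "A", "C"),
                InteractionEvent(3.0, "D", "A"),
                InteractionEvent(4.0, "C", "A"),
            ),
        )
        by_group = [e for e in episodes(rec, "group") if e.triad == ("A", "B", "C")][0]
        by_triad = [e for e in episodes(rec, "triad") if e.triad == ("A", "B", "C")][0]
        assert by_group.duration_interactions == 2
        assert by_triad.duration_interactions == 1

    def test_episode_tiling_on_synthetic_record(self):
        """Closed episodes plus the censored tail partition each triad's range."""
        rec = generate_record(GeneratorConfig(n=4, alpha=0.7, beta=0.3, n_events=400, seed=9))
        by_triad = {}
        for e in episodes(rec):
            by_triad.setdefault(e.triad, []).append(e)
        last = len(rec.events) - 1
        for tri, eps in by_triad.items():
            eps.sort(key=lambda e: e.start_event_index)
            for prev, nxt in zip(eps, eps[1:]):
                assert prev.end_event_index == nxt.start_event_index
            assert eps[-1].censored
            spans = sum(e.duration_interactions for e in eps)
            assert spans == last - eps[0].start_event_index


class TestEpisodeSummary:
    def test_toy_summary(self, toy_record):
        summ = episode_summary(episodes(toy_record))
        tr = summ.by_configuration.loc["transitive"]
        assert tr["n_closed"] == 1
        assert tr["mean_interactions"] == pytest.approx(1.0)
        assert tr["mean_seconds"] == pytest.approx(120.0)
        it = summ.by_configuration.loc["intransitive"]
        assert it["n_closed"] == 0 and it["n_censored"] == 1
        assert summ.n_triads_ever_intransitive == 1

    def test_empty_input_all_zero(self):
        summ = episode_summary([])
        assert (summ.by_configuration[["n_closed", "n_censored"]].to_numpy() == 0).all()
        assert summ.n_triads == 0

    def test_rule2_regime_orders_mean_durations(self):
        """With beta << alpha, intransitive spells are much shorter than transitive."""
        rec = generate_record(
            GeneratorConfig(n=3, alpha=0.9, beta=0.05, n_events=8000, seed=4)
        )
        summ = episode_summary(episodes(rec))
        by = summ.by_configuration
        assert by.loc["intransitive", "n_closed"] > 10
        assert (
            by.loc["intransitive", "mean_interactions"]
            < by.loc["transitive", "mean_interactions"]
        )
        assert summ.duration_ratio_interactions > 1


class TestLinearityTimeline:
    def test_linear_fill_in_no_switches(self):
        rows = [f"{i}.0\t{a}\t{b}\n" for i, (a, b) in
                enumerate(itertools.combinations("ABCD", 2))]
        statuses, switches = linearity_timeline(read_events(_tsv(rows)))
        assert statuses[-1] == LINEAR and switches == 0
        assert all(s == UNDEFINED for s in statuses[:-1])

    def test_counterattack_and_revert_count_two_switches(self):
        rows = [f"{i}.0\t{a}\t{b}\n" for i, (a, b) in
                enumerate(itertools.combinations("ABCD", 2))]
        rows += ["10.0\tC\tA\n", "11.0\tA\tC\n"]
        statuses, switches = linearity_timeline(read_events(_tsv(rows)))
        assert statuses[-2:] == [NONLINEAR, LINEAR]
        assert switches == 2

    def test_uninteracted_pair_stays_undefined(self):
        rec = read_events(_tsv(["0.0\tA\tB\n", "1.0\tB\tC\n", "2.0\tB\tA\n"]))
        statuses, switches = linearity_timeline(rec)
        assert all(s == UNDEFINED for s in statuses) and switches == 0

    def test_timeline_matches_tournament_oracle(self):
        """Incremental status equals is_linear on the rebuilt tournament, per event."""
        rec = generate_record(GeneratorConfig(n=4, alpha=0.6, beta=0.4, n_events=300, seed=13))
        statuses, _ = linearity_timeline(rec)
        for k in (6, 50, 150, 299):
            pt = current_tournament(rec, k + 1)
            if pt.is_complete:
                expected = LINEAR if is_linear(pt.to_tournament()) else NONLINEAR
            else:
                expected = UNDEFINED
            assert statuses[k] == expected


class TestAttackMatrix:
    def test_counts_and_half_open_boundary(self, toy_record):
        m = attack_matrix(toy_record, (0.0, 140.0))
        assert m.counts.loc["A", "B"] == 1
        assert m.counts.loc["C", "A"] == 0  # event at exactly end_s excluded
        assert m.total == 3
        full = attack_matrix(toy_record)
        assert full.total == 4
        assert (np.diag(full.counts.to_numpy()) == 0).all()

    def test_disjoint_windows_sum_to_full(self, toy_record):
        a = attack_matrix(toy_record, (0.0, 15.0)).counts
        b = attack_matrix(toy_record, (15.0, 1000.0)).counts
        full = attack_matrix(toy_record, (0.0, 1000.0)).counts
        assert ((a + b) == full).all().all()

    def test_empty_window_all_zero(self, toy_record):
        assert attack_matrix(toy_record, (500.0, 600.0)).total == 0

    def test_inverted_window_rejected(self, toy_record):
        with pytest.raises(ValueError, match="inverted"):
            attack_matrix(toy_record, (10.0, 5.0))


class TestDominance:
    def _matrix(self, rows):
        rec = read_events(_tsv(rows))
        return attack_matrix(rec)

    def test_one_sided_attacks_dominate(self):
        m = self._matrix([f"{i}.0\tA\tB\n" for i in range(5)] + ["9.0\tB\tC\n"])
        rel, undet = dominance_relations(m)
        assert ("A", "B") in rel and ("B", "C") in rel
        assert ("A", "C") in undet  # 0-0 pair undetermined

    def test_equal_counts_undetermined(self):
        m = self._matrix(["0.0\tA\tB\n", "1.0\tB\tA\n", "2.0\tA\tB\n", "3.0\tB\tA\n"])
        rel, undet = dominance_relations(m)
        assert rel == set() and ("A", "B") in undet

    def test_threshold_policy(self):
        m = self._matrix(["0.0\tA\tB\n", "1.0\tA\tB\n", "2.0\tB\tA\n"])
        rel_default, _ = dominance_relations(m)
        assert ("A", "B") in rel_default  # 2/3 majority
        rel_strict, undet_strict = dominance_relations(m, threshold=0.8)
        assert rel_strict == set() and ("A", "B") in undet_strict

    def test_rank_order_linear_example(self):
        relations = {("A", "B"), ("A", "C"), ("A", "D"),
                     ("B", "C"), ("B", "D"), ("C", "D")}
        ranks = rank_order(relations, "ABCD")
        assert ranks.order == ("A", "B", "C", "D")
        assert [ranks.scores[r] for r in ranks.order] == [3, 2, 1, 0]
        assert ranks.is_linear and ranks.complete

    def test_rank_order_cycle_not_linear(self):
        ranks = rank_order({("A", "B"), ("B", "C"), ("C", "A")}, "ABC")
        assert set(ranks.scores.values()) == {1}
        assert ranks.complete and not ranks.is_linear

    def test_incomplete_relations_flagged(self):
        ranks = rank_order({("A", "B")}, "ABC")
        assert not ranks.complete and not ranks.is_linear


class TestPlot:
    def test_music_notation_smoke(self, toy_record, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        from peckorder import plot_record

        ax = plot_record(toy_record)
        labels = [t.get_text() for t in ax.texts if t.get_text()]
        assert sorted(labels) == ["A", "B", "C"]
        ax.figure.savefig(tmp_path / "record.svg")


class TestSessions:
    def test_split_sessions_half_open_windows(self, toy_record):
        from peckorder import split_sessions

        rec = InteractionRecord(toy_record.roster, toy_record.events,
                                sessions=((0.0, 20.0), (20.0, 200.0)))
        day1, day2 = split_sessions(rec)
        assert len(day1.events) == 2 and len(day2.events) == 2
        assert episodes(day1) == []  # triad never completes within day 1

    def test_record_without_sessions_returned_whole(self, toy_record):
        from peckorder import split_sessions

        assert split_sessions(toy_record) == [toy_record]


class TestRateEstimation:
    def test_recovers_generator_rates(self):
        cfg = GeneratorConfig(n=3, alpha=0.5, beta=0.05, n_events=10_000, seed=17)
        est = estimate_rates(generate_record(cfg))
        assert est.alpha_ci[0] <= 0.5 <= est.alpha_ci[1]
        assert est.beta_ci[0] <= 0.05 <= est.beta_ci[1]
        assert est.beta_hat < est.alpha_hat

    def test_no_intransitive_episode_flags_alpha(self):
        # transitive fill-in, then a reversal that keeps the triad transitive
        rec = read_events(_tsv([
            "0.0\tA\tB\n", "1.0\tB\tC\n", "2.0\tA\tC\n", "3.0\tB\tA\n",
        ]))
        est = estimate_rates(rec)
        assert not est.alpha_defined and np.isnan(est.alpha_hat)
        assert est.beta_hat == 0.0

    def test_no_closed_episode_is_an_error(self, toy_record):
        rec = InteractionRecord(toy_record.roster, toy_record.events[:3])
        with pytest.raises(UndefinedRateError):
            estimate_rates(rec)
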