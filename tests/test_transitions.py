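"""Region classification and the indirect-invasion accounting."""

import numpy as np
import pytest

from rpdsim import (
    canonical_key,
    classify_state,
    compare_performers,
    compress_to_regions,
    count_exit_paths,
    make_fixture_log,
    make_named_strategy,
    nash_occupancy,
    parse_key,
)

# A phenotype that defects on-path but rewards cooperation: neutral against
# the defector, exploitable door-opener for cooperators.
TRIGGER = "D,1,0;C,1,1"


@pytest.fixture(scope="module")
def keys():
    return {
        name: canonical_key(make_named_strategy(name))
        for name in ("ALLC", "ALLD", "TFT", "GRIM", "STFT", "CTFT")
    }


class TestClassifyState:
    def test_worked_two_strategy_mixture(self):
        label = classify_state({"A": 0.65, "B": 0.30, "C": 0.05}, threshold=0.9)
        assert label.kind == "mix2"
        assert label.strategies == ("A", "B")

    def test_monoculture_is_pure(self):
        label = classify_state({"A": 1.0}, threshold=0.9)
        assert label.kind == "pure" and label.strategies == ("A",)

    def test_four_even_strategies_are_other_interior(self):
        freqs = {k: 0.25 for k in "ABCD"}
        label = classify_state(freqs, threshold=0.9)
        assert label.kind == "other_interior" and label.strategies == ()

    def test_threshold_must_leave_room_for_noise_and_mixtures(self):
        for bad in (0.5, 0.3, 1.0, 1.2):
            with pytest.raises(ValueError):
                classify_state({"A": 1.0}, threshold=bad)

    def test_classification_is_scale_free(self, rng):
        # Multiplying every count by a constant leaves the label unchanged.
        for _ in range(50):
            counts = rng.integers(1, 100, size=5)
            freqs = {f"S{i}": c / counts.sum() for i, c in enumerate(counts)}
            scaled = {
                f"S{i}": 7 * c / (7 * counts.sum()) for i, c in enumerate(counts)
            }
            assert classify_state(freqs, 0.9) == classify_state(scaled, 0.9)

    def test_frequency_ties_break_by_key_order(self):
        label = classify_state({"B": 0.5, "A": 0.5}, threshold=0.9)
        assert label.strategies == ("A", "B")


class TestCompressToRegions:
    def test_constant_log_is_a_single_span(self, keys):
        log = make_fixture_log([({keys["ALLD"]: 1.0}, 120)])
        spans = compress_to_regions(log, 0.9)
        assert len(spans) == 1
        assert spans[0].label.kind == "pure"
        assert (spans[0].start, spans[0].stop) == (0, 120)

    def test_scripted_three_region_trajectory(self, keys):
        a, b = keys["ALLD"], keys["STFT"]
        log = make_fixture_log(
            [({a: 1.0}, 100), ({a: 0.5, b: 0.5}, 50), ({b: 1.0}, 100)]
        )
        spans = compress_to_regions(log, 0.9)
        assert [s.label.kind for s in spans] == ["pure", "mix2", "pure"]
        assert [s.length for s in spans] == [100, 50, 100]

    def test_spans_tile_the_run(self, keys, rng):
        names = list(keys.values())
        script = []
        for _ in range(30):
            weights = rng.dirichlet(np.ones(3))
            counts = (weights * 100).astype(int)
            counts[0] += 100 - counts.sum()
            chosen = rng.choice(len(names), size=3, replace=False)
            freqs = {
                names[c]: n / 100 for c, n in zip(chosen, counts) if n > 0
            }
            script.append((freqs, int(rng.integers(1, 10))))
        log = make_fixture_log(script)
        spans = compress_to_regions(log, 0.9)
        assert sum(s.length for s in spans) == log.n_generations
        for prev, nxt in zip(spans, spans[1:]):
            assert prev.stop == nxt.start
            assert prev.label != nxt.label


class TestComparePerformers:
    def test_allc_is_a_neutral_mutant_of_tft(self, named, game):
        assert compare_performers(named["ALLC"], named["TFT"], game) == "equal"

    def test_alld_performs_worse_against_tft(self, named, game):
        assert compare_performers(named["ALLD"], named["TFT"], game) == "worse"

    def test_alld_performs_better_against_allc(self, named, game):
        assert compare_performers(named["ALLD"], named["ALLC"], game) == "better"

    def test_ctft_invades_suspicious_tft(self, named, game):
        assert compare_performers(named["CTFT"], named["STFT"], game) == "better"

    def test_second_order_comparison_breaks_payoff_ties(self, named, game):
        # The trigger phenotype earns the defector payoff against ALLD on
        # both sides, but cooperators prosper against it, so a cooperative
        # entrant is better against the trigger while worse against ALLD.
        trigger = parse_key(TRIGGER)
        assert compare_performers(trigger, named["ALLD"], game) == "equal"
        assert compare_performers(named["ALLC"], trigger, game) == "better"
        assert compare_performers(named["ALLC"], named["ALLD"], game) == "worse"

    def test_mixtures_extend_the_payoff_functional_linearly(self, named, game):
        mix = [(named["TFT"], 0.5), (named["ALLC"], 0.5)]
        # U(ALLD, mix) = (1.75 + 4)/2 = 2.875 < U(mix, mix) = 3.
        assert compare_performers(named["ALLD"], mix, game) == "worse"

    def test_float_mode_agrees_with_exact_mode(self, named, game):
        pairs = [("ALLC", "TFT"), ("ALLD", "TFT"), ("ALLD", "ALLC"), ("CTFT", "STFT")]
        for q, p in pairs:
            assert compare_performers(
                named[q], named[p], game, exact=False
            ) == compare_performers(named[q], named[p], game, exact=True)


class TestCountExitPaths:
    def test_cooperation_to_defection_chain_counts_once(self, keys, game):
        # TFT -> TFT+ALLC -> ALLC+TFT -> ALLC -> ALLC+ALLD: the classic
        # neutral stepping stone out of cooperation.
        tft, allc, alld = keys["TFT"], keys["ALLC"], keys["ALLD"]
        log = make_fixture_log(
            [
                ({tft: 1.0}, 50),
                ({tft: 0.6, allc: 0.4}, 20),
                ({allc: 0.6, tft: 0.4}, 20),
                ({allc: 1.0}, 50),
                ({allc: 0.8, alld: 0.2}, 10),
            ]
        )
        tally = count_exit_paths(compress_to_regions(log, 0.9), game)
        assert tally.indirect_invasions == 1
        assert tally.other_paths == 0 and tally.unclassified == 0
        record = tally.records[0]
        assert record.equilibrium == tft
        assert record.chain == (allc, alld)

    def test_defection_to_cooperation_chain_counts_once(self, keys, game):
        alld, stft, ctft = keys["ALLD"], keys["STFT"], keys["CTFT"]
        log = make_fixture_log(
            [
                ({alld: 1.0}, 50),
                ({alld: 0.6, stft: 0.4}, 20),
                ({stft: 0.6, alld: 0.4}, 20),
                ({stft: 1.0}, 50),
                ({stft: 0.8, ctft: 0.2}, 10),
            ]
        )
        tally = count_exit_paths(compress_to_regions(log, 0.9), game)
        assert (tally.indirect_invasions, tally.other_paths) == (1, 0)

    def test_direct_entry_of_a_worse_performer_is_another_path(self, keys, game):
        alld, allc = keys["ALLD"], keys["ALLC"]
        log = make_fixture_log([({alld: 1.0}, 50), ({alld: 0.8, allc: 0.2}, 10)])
        tally = count_exit_paths(compress_to_regions(log, 0.9), game)
        assert (tally.indirect_invasions, tally.other_paths) == (0, 1)

    def test_evaporated_neutral_excursions_are_not_exits(self, keys, game):
        alld = keys["ALLD"]
        log = make_fixture_log(
            [
                ({alld: 1.0}, 50),
                ({alld: 0.8, TRIGGER: 0.2}, 5),
                ({alld: 1.0}, 50),
                ({alld: 0.8, TRIGGER: 0.2}, 5),
                ({alld: 1.0}, 50),
            ]
        )
        tally = count_exit_paths(compress_to_regions(log, 0.9), game)
        assert tally.total == 0

    def test_residents_reentering_the_label_do_not_reset_the_chain(self, keys, game):
        # ALLD drops below the threshold and comes back while the trigger
        # phenotype holds the door open; the cooperator that then enters
        # invades via the trigger, so this is one indirect invasion.
        alld, allc = keys["ALLD"], keys["ALLC"]
        log = make_fixture_log(
            [
                ({alld: 1.0}, 50),
                ({alld: 0.7, TRIGGER: 0.3}, 10),
                ({TRIGGER: 0.95, alld: 0.05}, 10),
                ({TRIGGER: 0.7, alld: 0.3}, 10),
                ({TRIGGER: 0.6, alld: 0.25, allc: 0.15}, 10),
            ]
        )
        tally = count_exit_paths(compress_to_regions(log, 0.9), game)
        assert (tally.indirect_invasions, tally.other_paths) == (1, 0)
        assert tally.records[0].chain == (TRIGGER, allc)

    def test_threshold_flicker_of_one_mutant_counts_once(self, keys, game):
        # A disadvantaged mutant hovering around 10% flickers the label
        # between pure and mix2; that is one invasion event, not four.
        alld, allc, stft = keys["ALLD"], keys["ALLC"], keys["STFT"]
        flicker = []
        for _ in range(4):
            flicker.append(({alld: 1.0}, 5))
            flicker.append(({alld: 0.85, allc: 0.15}, 3))
        log = make_fixture_log(flicker)
        tally = count_exit_paths(compress_to_regions(log, 0.9), game)
        assert (tally.indirect_invasions, tally.other_paths) == (0, 1)
        # A different resolving mutant within the same episode still counts.
        log2 = make_fixture_log(
            [
                ({alld: 1.0}, 5),
                ({alld: 0.85, allc: 0.15}, 3),
                ({alld: 1.0}, 5),
                ({alld: 0.85, keys["TFT"]: 0.15}, 3),
            ]
        )
        tally2 = count_exit_paths(compress_to_regions(log2, 0.9), game)
        assert tally2.other_paths == 2

    def test_interior_interruptions_are_tallied_as_unclassified(self, keys, game):
        alld, stft, tft, allc = keys["ALLD"], keys["STFT"], keys["TFT"], keys["ALLC"]
        log = make_fixture_log(
            [
                ({alld: 1.0}, 50),
                ({alld: 0.7, TRIGGER: 0.3}, 10),
                ({alld: 0.25, TRIGGER: 0.25, tft: 0.25, allc: 0.25}, 10),
                ({stft: 1.0}, 50),
            ]
        )
        tally = count_exit_paths(compress_to_regions(log, 0.9), game)
        assert tally.unclassified == 1
        assert tally.indirect_invasions == 0 and tally.other_paths == 0

    def test_tally_conservation(self, keys, game):
        alld, allc, tft, stft, ctft = (
            keys["ALLD"],
            keys["ALLC"],
            keys["TFT"],
            keys["STFT"],
            keys["CTFT"],
        )
        log = make_fixture_log(
            [
                ({alld: 1.0}, 30),
                ({alld: 0.8, allc: 0.2}, 5),  # other path (direct worse entry)
                ({alld: 1.0}, 30),
                ({alld: 0.6, stft: 0.4}, 5),
                ({stft: 1.0}, 30),
                ({stft: 0.8, ctft: 0.2}, 5),  # indirect invasion resolves
                ({alld: 1.0}, 30),  # defection re-established (non-neutral entry)
                ({alld: 0.25, tft: 0.25, allc: 0.25, stft: 0.25}, 5),  # unclassified
                ({tft: 1.0}, 30),
            ]
        )
        tally = count_exit_paths(compress_to_regions(log, 0.9), game)
        assert tally.total == len(tally.records)
        assert (
            tally.indirect_invasions + tally.other_paths + tally.unclassified
            == tally.total
        )
        assert tally.total == 3

    def test_records_replay_consistently(self, keys, game):
        alld, stft, ctft = keys["ALLD"], keys["STFT"], keys["CTFT"]
        log = make_fixture_log(
            [
                ({alld: 1.0}, 50),
                ({alld: 0.6, stft: 0.4}, 20),
                ({stft: 1.0}, 50),
                ({stft: 0.8, ctft: 0.2}, 10),
            ]
        )
        tally = count_exit_paths(compress_to_regions(log, 0.9), game)
        for record in tally.records:
            sequence = [record.equilibrium, *record.chain]
            verdicts = [
                compare_performers(parse_key(q), parse_key(p), game)
                for p, q in zip(sequence, sequence[1:])
            ]
            assert all(v == "equal" for v in verdicts[:-1])
            if record.classification == "indirect_invasion":
                assert verdicts[-1] == "better"
            elif record.classification == "other_path":
                assert verdicts[-1] == "worse"


class TestNashOccupancy:
    def test_defector_monoculture_is_always_in_equilibrium(self, keys, game):
        log = make_fixture_log([({keys["ALLD"]: 1.0}, 40)])
        assert nash_occupancy(compress_to_regions(log, 0.9), game) == 1.0

    def test_cooperator_monoculture_never_is(self, keys, game):
        log = make_fixture_log([({keys["ALLC"]: 1.0}, 40)])
        assert nash_occupancy(compress_to_regions(log, 0.9), game) == 0.0

    def test_interior_time_only_lowers_the_bound(self, keys, game):
        four = {keys[n]: 0.25 for n in ("ALLC", "ALLD", "TFT", "STFT")}
        log = make_fixture_log([({keys["TFT"]: 1.0}, 50), (four, 50)])
        assert nash_occupancy(compress_to_regions(log, 0.9), game) == 0.5
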