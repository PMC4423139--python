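"""Repeat decomposition: examples, independent oracles, invariants."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from cysrep.repeats import (
    CORE,
    CoreMatch,
    DEFAULT_INVENTORY,
    alternation_stats,
    classify_tail,
    decompose,
    find_cores,
    segment_units,
)
from cysrep.simulate import MAIN_UNITS, RepeatPlan, generate_edcrp_like

# ---------------------------------------------------------------------------
# independent oracles


def oracle_find_cores(seq, core=CORE, max_mm=1, prefix=2):
    """Brute-force greedy scan: test every window, take non-overlapping."""
    out, i = [], 0
    while i + len(core) <= len(seq):
        w = seq[i : i + len(core)]
        if w[:prefix] == core[:prefix]:
            mm = sum(1 for a, b in zip(w[prefix:], core[prefix:]) if a != b or a == "X")
            if mm <= max_mm:
                out.append((i, mm))
                i += len(core)
                continue
        i += 1
    return out


def oracle_max_units(seq, max_mm=1, max_tail=4):
    """Exhaustive DP: maximum number of non-overlapping valid units."""
    n = len(seq)
    best = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        best[i] = best[i + 1]
        if i + 6 <= n and oracle_find_cores(seq[i : i + 6], max_mm=max_mm):
            for length in range(6, 6 + max_tail + 1):
                if i + length <= n:
                    best[i] = max(best[i], 1 + best[i + length])
    return best[0]


def oracle_alternation(labels):
    """Exhaustive substring scan for the longest two-label alternating run."""
    n = len(labels)
    best = None
    for s in range(n):
        for e in range(s + 2, n + 1):
            sub = labels[s:e]
            if len(set(sub)) == 2 and all(x != y for x, y in zip(sub, sub[1:])):
                if best is None or e - s > best[1]:
                    best = (s, e - s)
    if best is None:
        return None, min(1, n), 0
    return best[0], best[1], best[1] // 2


# ---------------------------------------------------------------------------
# find_cores


class TestFindCores:
    def test_two_exact_cores(self):
        matches = find_cores("CCDPCQKPCCDPCQQSV", max_mismatch=0)
        assert [(m.start, m.mismatches) for m in matches] == [(0, 0), (8, 0)]

    def test_one_substitution_outside_anchor(self):
        matches = find_cores("CCDPCEKP", max_mismatch=1)
        assert [(m.start, m.mismatches) for m in matches] == [(0, 1)]

    def test_cc_anchor_is_exact(self):
        assert find_cores("CADPCQ", max_mismatch=2) == []

    def test_x_counts_as_mismatch(self):
        assert find_cores("CCXPCQ", max_mismatch=0) == []
        assert [m.mismatches for m in find_cores("CCXPCQ", max_mismatch=1)] == [1]

    @pytest.mark.parametrize("seed", range(100))
    def test_equals_bruteforce_on_random_sequences(self, seed, random_crich_seq):
        seq = random_crich_seq(seed, 200)
        got = [(m.start, m.mismatches) for m in find_cores(seq)]
        assert got == oracle_find_cores(seq)

    @pytest.mark.parametrize("seed", range(50))
    def test_monotone_in_max_mismatch(self, seed, random_crich_seq):
        seq = random_crich_seq(seed + 1000, 150)
        counts = [len(find_cores(seq, max_mismatch=m)) for m in (0, 1, 2, 3)]
        assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# classify_tail


@pytest.mark.parametrize(
    "tail,label",
    [
        ("KP", "KP"),
        ("KTV", "K(T/S)V"),
        ("KSV", "K(T/S)V"),
        ("T", "(T/S)"),
        ("S", "(T/S)"),
        ("QSV", "QS(V)"),
        ("QS", "QS(V)"),
        ("", "CORE_ONLY"),
        ("QW", "OTHER"),
        ("KPV", "OTHER"),
    ],
)
def test_classify_tail_default_inventory(tail, label):
    assert classify_tail(tail) == label


def test_classify_tail_too_long_errors():
    with pytest.raises(ValueError, match="longer"):
        classify_tail("KTVKP")


# ---------------------------------------------------------------------------
# segment_units / decompose


class TestSegmentation:
    def test_two_printed_units(self):
        seq = "CCDPCQKPCCDPCQQSV"
        arch = decompose(seq)
        assert [(u.start, u.end, u.tail) for u in arch.units] == [
            (0, 8, "KP"),
            (8, 17, "QSV"),
        ]
        assert arch.nterm == "" and arch.cterm == ""

    def test_nterm_and_short_tails(self):
        arch = decompose("MWYCCDPCQTCCDPCQS")
        assert arch.nterm == "MWY"
        assert [u.tail for u in arch.units] == ["T", "S"]
        assert arch.cterm == ""

    def test_four_printed_main_units(self):
        arch = decompose("".join(u for _, u in MAIN_UNITS))
        assert arch.n_repeats == 4
        assert len(set(arch.labels)) == 4
        assert sorted(u.length for u in arch.units) == [7, 8, 9, 9]

    def test_no_cores_means_all_nterm(self):
        arch = decompose("MWAAAGHHW")
        assert arch.nterm == "MWAAAGHHW"
        assert arch.n_repeats == 0 and arch.cterm == ""

    def test_wide_gap_becomes_linker(self):
        # gap of 14 > core+max_tail: unit truncated at 10, surplus is a linker
        seq = "CCDPCQKPAAAAAA" + "CCDPCQT"
        arch = decompose(seq)
        assert arch.units[0].tail == "KPAA"
        assert [(iv, s) for iv, s in arch.linkers] == [((10, 14), "AAAA")]
        assert arch.reconstruct() == seq

    def test_last_unit_rule_leaves_unmatched_to_cterm(self):
        # residues after the final core match no inventory tail
        seq = "CCDPCQWWGG"
        arch = decompose(seq)
        assert arch.units[0].tail == "" and arch.units[0].type_label == "CORE_ONLY"
        assert arch.cterm == "WWGG"

    def test_overlapping_cores_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            segment_units("CCDPCQKPCCDPCQ", [CoreMatch(0, 0), CoreMatch(3, 0)])

    @pytest.mark.parametrize("seed", range(50))
    def test_unit_count_equals_exhaustive_dp(self, seed, random_crich_seq):
        seq = random_crich_seq(seed + 5000, random.Random(seed).randint(12, 60))
        arch = decompose(seq)
        assert arch.n_repeats == oracle_max_units(seq)
        assert arch.reconstruct() == seq

    @given(st.text(alphabet="CDPQKSTVX", min_size=1, max_size=120))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_reconstruction_invariant(self, seq):
        arch = decompose(seq)
        assert arch.reconstruct() == seq
        assert all(6 <= u.length <= 10 for u in arch.units)

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_zero_noise_synthetic_recovered_exactly(self, seed):
        plan = RepeatPlan.random_mix(list(MAIN_UNITS), n_units=12)
        rec, truth = generate_edcrp_like(seed=seed, plan=plan)
        arch = decompose(rec.seq)
        tru = truth.true_architecture
        assert arch.nterm == tru.nterm and arch.cterm == tru.cterm
        assert [(u.start, u.end, u.type_label) for u in arch.units] == [
            (u.start, u.end, u.type_label) for u in tru.units
        ]
        assert arch.type_counts == tru.type_counts


# ---------------------------------------------------------------------------
# alternation


class TestAlternation:
    def test_perfect_alternation(self):
        s = alternation_stats(list("ABABAB"))
        assert s.pair_labels == ("A", "B")
        assert (s.run_length, s.n_pairs, s.run_start_unit) == (6, 3, 0)

    def test_constant_labels_degenerate(self):
        s = alternation_stats(list("AAA"))
        assert s.pair_labels is None and s.n_pairs == 0 and s.run_length == 1

    def test_three_distinct_labels_break_run(self):
        s = alternation_stats(list("ABCBCB"))
        assert s.pair_labels == ("B", "C") and s.run_length == 5

    def test_empty_and_singleton(self):
        assert alternation_stats([]).n_pairs == 0
        assert alternation_stats(["A"]).pair_labels is None

    def test_tie_broken_by_earliest_start(self):
        s = alternation_stats(list("ABAXCDCY"))
        assert s.run_start_unit == 0 and s.run_length == 3

    @pytest.mark.parametrize("seed", range(200))
    def test_equals_exhaustive_substring_oracle(self, seed):
        r = random.Random(seed)
        labels = [r.choice("ABC") for _ in range(r.randint(0, 12))]
        s = alternation_stats(labels)
        start, length, pairs = oracle_alternation(labels)
        assert s.run_length == length and s.n_pairs == pairs
        if start is not None:
            assert s.run_start_unit == start


# ---------------------------------------------------------------------------
# architecture serialization


def test_architecture_json_and_table(toy_records):
    arch = decompose(toy_records[0])
    d = arch.to_dict()
    assert d["n_repeats"] == 2 and d["record_id"] == "a"
    assert [u["type_label"] for u in d["units"]] == ["KP", "QS(V)"]
    table = arch.units_table()
    assert list(table["length"]) == [8, 9]
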