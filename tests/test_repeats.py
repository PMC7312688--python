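"""Repeat census: SSR, tandem and dispersed detectors against planted truth
and brute-force oracles."""

import numpy as np
import pytest

from mitokit.genome_io import CircularSequence, FeatureInterval, revcomp
from mitokit.repeats import (
    DISPERSED_BINS,
    DispersedRepeat,
    bin_dispersed,
    classify_location,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    summarize_ssrs,
)
from mitokit.synthetic import _base_probs, _scrubbed


def _background(seed, n, gc=0.45):
    return _scrubbed(np.random.default_rng(seed), n, _base_probs(gc))


def brute_force_ssrs(s: str, thresholds=(8, 4, 4, 3, 3, 3)):
    """Exhaustive sliding-window oracle: maximal perfect runs per motif size."""
    found = set()
    n = len(s)
    for p in range(1, 7):
        i = 0
        while i + p <= n:
            j = i + p
            while j < n and s[j] == s[j - p]:
                j += 1
            count = (j - i) // p
            if count >= thresholds[p - 1]:
                motif = s[i : i + p]
                minimal = all(motif != motif[:q] * (p // q) for q in range(1, p) if p % q == 0)
                if minimal:
                    found.add((i + 1, i + count * p, p))
                i = j - p + 1
            else:
                i += 1
    return found


def test_ssr_threshold_boundary():
    bg = _background(2, 400)
    for run, expect in ((7, 0), (8, 1)):
        seq = CircularSequence(bg[:200] + "G" * run + bg[200:], "s", is_circular=False)
        records = find_ssrs(seq)
        assert len(records) == expect
        if expect:
            assert records[0].motif == "G" and records[0].repeat_count == 8


def test_ssr_matches_sliding_window_oracle():
    rng = np.random.default_rng(7)
    s = "".join("ACGT"[i] for i in rng.integers(0, 4, 30_000))
    seq = CircularSequence(s, "s", is_circular=False)
    got = {(r.interval.start, r.interval.end, len(r.motif)) for r in find_ssrs(seq)}
    assert got == brute_force_ssrs(s)


def test_planted_ssrs_recovered_exactly(record, truth):
    detected = find_ssrs(record.sequence)
    got = {(r.interval.start, r.interval.end, r.motif_class) for r in detected}
    want = {
        (int(r.start), int(r.end), r.motif_class)
        for r in truth["ssrs"].itertuples(index=False)
    }
    assert got == want  # 100% precision and recall


def test_ssr_records_tile_their_sequence(record):
    for r in find_ssrs(record.sequence):
        spanned = record.sequence.fetch(r.interval.start, r.interval.end)
        assert spanned == r.motif * r.repeat_count


def test_ssr_rotation_invariance(record):
    base = find_ssrs(record.sequence)
    rotated = find_ssrs(record.sequence.rotate(12_345))
    key = lambda recs: sorted((r.motif_class, r.repeat_count) for r in recs)
    assert key(base) == key(rotated)


def test_summarize_ssrs_proportions():
    bg = _background(3, 3000)
    seq = CircularSequence(bg[:1000] + "A" * 8 + bg[1000:2000] + "AT" * 4 + bg[2000:],
                           "s", is_circular=False)
    records = find_ssrs(seq)
    summary = summarize_ssrs(records)
    assert summary.ssr_class_counts["mono"] == 1
    assert summary.ssr_class_counts["di"] == 1
    assert summary.ssr_class_proportions["mono"] == 50.0
    single = summarize_ssrs(records[:1])
    assert single.ssr_class_proportions[records[0].motif_class] == 100.0


def test_summarize_empty_is_all_zero():
    summary = summarize_ssrs([])
    assert sum(summary.ssr_class_counts.values()) == 0
    assert all(v == 0.0 for v in summary.ssr_class_proportions.values())


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------

def brute_force_tandems(s: str, min_unit=7, max_unit=100):
    """Exhaustive start/period scan for maximal arrays of >= 2 copies."""
    out = set()
    n = len(s)
    for p in range(min_unit, max_unit + 1):
        for i in range(n - 2 * p + 1):
            if s[i : i + p] == s[i + p : i + 2 * p]:
                j = i + 2 * p
                while j < n and s[j] == s[j - p]:
                    j += 1
                # maximality on the left
                if i > 0 and s[i - 1] == s[i - 1 + p]:
                    continue
                arr = s[i:j]
                # smallest-period convention
                periods = [q for q in range(1, p) if all(arr[k] == arr[k + q] for k in range(len(arr) - q))]
                if periods:
                    continue
                out.add((i + 1, j))
    return out


def test_tandem_planted_unit_recovered():
    bg = _background(4, 5000)
    unit = "AGAGCAGGTCGGTCTAGGTAGTTGAAA"
    seq = CircularSequence(bg[:2500] + unit * 2 + bg[2500:], "s")
    found = find_tandem_repeats(seq)
    assert len(found) == 1
    t = found[0]
    assert (t.unit_length, t.copy_number) == (27, 2.0)
    assert t.unit == unit


def test_tandem_null_background():
    seq = CircularSequence(_background(3, 5000), "s")
    assert find_tandem_repeats(seq) == []


def test_tandem_partial_copy_and_smallest_period():
    bg = _background(5, 4000)
    unit = "GATTCCGGAATACGGCAT"  # 18 bp
    array = unit * 3 + unit[:5]
    seq = CircularSequence(bg[:2000] + array + bg[2000:], "s", is_circular=False)
    found = find_tandem_repeats(seq)
    assert len(found) == 1
    t = found[0]
    assert t.unit_length == 18
    assert t.copy_number == pytest.approx(len(array) / 18, abs=0.01)
    assert brute_force_tandems(bg[:2000] + array + bg[2000:]) == {
        (t.interval.start, t.interval.end)
    }


def test_tandem_matches_exhaustive_oracle_on_random_sequence():
    rng = np.random.default_rng(12)
    s = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
    seq = CircularSequence(s, "s", is_circular=False)
    got = {(t.interval.start, t.interval.end) for t in find_tandem_repeats(seq, max_unit=100)}
    assert got == brute_force_tandems(s)


def test_planted_tandems_recovered(record, truth):
    found = find_tandem_repeats(record.sequence)
    got = {(t.interval.start, t.interval.end) for t in found}
    want = {(int(r.start), int(r.end)) for r in truth["tandems"].itertuples(index=False)}
    assert got == want


# ---------------------------------------------------------------------------
# location classification
# ---------------------------------------------------------------------------

def test_classify_location(record, truth):
    g = record.gene("rrnL").exons[0]
    assert classify_location(FeatureInterval(g.start + 5, g.start + 25), record) == "rrnL"
    s0 = truth["ssrs"].iloc[0]
    label = classify_location(FeatureInterval(int(s0.start), int(s0.end)), record)
    assert label.startswith("IGS(")


def test_classify_location_wraps_origin(record):
    n = len(record.sequence)
    label = classify_location(FeatureInterval(n - 3, 4, wraps_origin=True), record)
    assert label  # resolves with wraparound instead of raising


# ---------------------------------------------------------------------------
# dispersed repeats
# ---------------------------------------------------------------------------

def test_dispersed_null_random_sequence():
    seq = CircularSequence(_background(11, 20_000), "s")
    assert find_dispersed_repeats(seq) == []


def test_dispersed_planted_inverted_block():
    bg = _background(8, 20_000)
    block = bg[1000:1500]  # 500 bp
    seq = CircularSequence(bg[:10_000] + revcomp(block) + bg[10_000:], "s")
    found = find_dispersed_repeats(seq)
    assert len(found) == 1
    rep = found[0]
    assert rep.orientation == "inverted"
    assert rep.identity == 100.0
    assert (rep.interval_a.start, rep.interval_a.end) == (1001, 1500)
    assert (rep.interval_b.start, rep.interval_b.end) == (10_001, 10_500)


def test_dispersed_planted_set_recovered(record, truth):
    found = find_dispersed_repeats(record.sequence)
    got = {
        (r.interval_a.start, r.interval_a.end, r.interval_b.start, r.interval_b.end, r.orientation)
        for r in found
    }
    want = {
        (int(r.a_start), int(r.a_end), int(r.b_start), int(r.b_end), r.orientation)
        for r in truth["dispersed"].itertuples(index=False)
    }
    assert got == want


def test_dispersed_large_repeats_fall_in_top_bin(record, truth):
    found = find_dispersed_repeats(record.sequence)
    summary = bin_dispersed(found, len(record.sequence))
    over_1kb = truth["dispersed"][truth["dispersed"].length >= 1000]
    assert summary.dispersed_bin_counts[">=1000"] == len(over_1kb)


def test_bin_boundaries():
    def rep(length):
        return DispersedRepeat(
            FeatureInterval(1, length), FeatureInterval(5000, 5000 + length - 1),
            length, "direct", 100.0, footprint_bp=2 * length,
        )

    summary = bin_dispersed([rep(30), rep(49), rep(50), rep(1000)], 100_000)
    assert summary.dispersed_bin_counts["30-49"] == 2
    assert summary.dispersed_bin_counts["50-69"] == 1
    assert summary.dispersed_bin_counts[">=1000"] == 1
    assert sum(summary.dispersed_bin_counts.values()) == 4


def test_bin_empty():
    summary = bin_dispersed([], 100_000)
    assert sum(summary.dispersed_bin_counts.values()) == 0
    assert summary.dispersed_genome_fraction_pct == 0.0
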