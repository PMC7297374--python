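"""Unit and property tests for the per-read tail caller.

Each operation is checked against an independent brute-force oracle:
exhaustive window scans for the anchors, full segment enumeration for the
refinement, sliding-mean scans for the quality filter, and plain Hamming
arithmetic for the adaptor probe.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pafinder.params import ParameterSet, DEFAULT_PARAMS
from pafinder.tailcall import (
    trim_read, find_preliminary_region, refine_region,
    apply_quality_bleed_filter, detect_adaptor, call_read,
)

from conftest import make_read

ADAPTOR5 = "TTTAACGCGAATTAATTCTG"


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_prelim(bases, params=DEFAULT_PARAMS):
    """Exhaustive window scan for the preliminary region."""
    w5, w3 = params.anchor5_len, params.anchor3_len
    b5, b3 = params.anchor5_max_mm, params.anchor3_max_mm
    starts = [i for i in range(len(bases) - w5 + 1)
              if sum(c != "A" for c in bases[i:i + w5]) <= b5]
    ends = [i + w3 for i in range(len(bases) - w3 + 1)
            if sum(c != "A" for c in bases[i:i + w3]) <= b3]
    if not starts or not ends or max(ends) <= min(starts):
        return None, "no_prelim"
    s, e = min(starts), max(ends)
    if e - s < params.min_prelim_len:
        return None, "prelim_too_short"
    return (s, e), "none"


def oracle_refine(bases, prelim, params=DEFAULT_PARAMS):
    """Enumerate every subinterval of prelim that could be a tail: starts
    and ends on 'A', contains no non-A run >= nonA_split_run, contains
    >= min_pure_A_run consecutive As, length >= min_prelim_len.  Pick the
    longest, ties 5'-most."""
    ps, pe = prelim
    best = None
    for i in range(ps, pe):
        if bases[i] != "A":
            continue
        run_non_a = 0
        best_a_run = 0
        cur_a_run = 0
        for j in range(i, pe):
            if bases[j] == "A":
                cur_a_run += 1
                run_non_a = 0
                best_a_run = max(best_a_run, cur_a_run)
            else:
                run_non_a += 1
                cur_a_run = 0
            if run_non_a >= params.nonA_split_run:
                break
            if bases[j] != "A":
                continue
            length = j + 1 - i
            if (best_a_run >= params.min_pure_A_run
                    and length >= params.min_prelim_len
                    and (best is None or length > best[1] - best[0])):
                best = (i, j + 1)
    if best is None:
        return None, "no_pure_run"
    return best, "none"


def oracle_qc(tail, quals, params):
    s, e = tail
    w = params.qc_window
    for i in range(s, e - w + 1):
        if np.mean(quals[i:i + w]) < params.qc_mean_threshold:
            return (s, i), True
    return tail, False


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# trim_read
# ---------------------------------------------------------------------------

class TestTrim:
    def test_trailing_g_run_removed(self):
        read = make_read("ACGT" * 10 + "CCCCCCCCCC" + "G" * 30)
        out = trim_read(read, None)
        assert out.bases == "ACGT" * 10 + "CCCCCCCCCC"
        assert len(out.quals) == 50

    def test_g_run_and_everything_after_removed(self):
        read = make_read("ACGTACGTAC" + "G" * 12 + "TTTT")
        assert trim_read(read, None).bases == "ACGTACGTAC"

    def test_short_g_run_kept(self):
        read = make_read("ACGTACGT" + "G" * 9 + "ACGT")
        assert trim_read(read, None).bases == read.bases

    def test_exact_adaptor5_with_template_switch_gs(self):
        body = "CCTTCCTTCCTTCCTT"
        read = make_read("GGGGGG" + ADAPTOR5 + body)
        assert trim_read(read, ADAPTOR5).bases == body

    def test_fuzzy_adaptor5_within_error_rate(self):
        mutated = "A" + ADAPTOR5[1:-1] + "C"  # 2 mismatches, 20% of 20 = 4 allowed
        body = "CCTTCCTTCCTT"
        read = make_read(mutated + body)
        assert trim_read(read, ADAPTOR5).bases == body

    def test_non_matching_adaptor5_left_alone(self):
        read = make_read("CCCCCCCCCCCCCCCCCCCCCCCC")
        assert trim_read(read, ADAPTOR5).bases == read.bases


# ---------------------------------------------------------------------------
# find_preliminary_region
# ---------------------------------------------------------------------------

class TestPreliminary:
    def test_region_between_anchors(self):
        bases = "C" * 25 + "A" * 30 + "CGTCGTCGTCGT"
        interval, reason = find_preliminary_region(bases)
        assert reason == "none"
        # 1-mismatch windows pull each edge one base outward; refinement
        # strips those flanking non-A bases later
        assert interval == oracle_prelim(bases)[0]
        s, e = interval
        assert s == 24 and e == 56

    def test_no_a_content(self):
        assert find_preliminary_region("C" * 50) == (None, "no_prelim")

    def test_prelim_too_short(self):
        # a broken 8-A block: fuzzy anchors frame only 9 nt, below the
        # 10-nt minimum
        bases = "CCCC" + "AAAACAAAA" + "CCCC"
        assert find_preliminary_region(bases) == (None, "prelim_too_short")

    def test_nine_a_read_discarded(self):
        # 9 As: the fuzzy anchors frame an 11-nt preliminary region (one
        # flanking base each side), so the read survives the length check
        # but dies at the pure-run requirement — discarded either way
        call = call_read(make_read("C" * 25 + "A" * 9 + "C" * 20))
        assert not call.retained
        assert call.discard_reason == "no_pure_run"

    def test_search_start_shifts_5prime_anchor(self):
        bases = "A" * 20 + "C" * 20 + "A" * 20
        full, _ = find_preliminary_region(bases)
        shifted, _ = find_preliminary_region(bases, search_start=25)
        assert full[0] < 25 <= shifted[0]

    @given(st.text(alphabet="AC", min_size=0, max_size=40))
    @settings(max_examples=300, deadline=None)
    def test_matches_exhaustive_window_oracle(self, bases):
        assert find_preliminary_region(bases) == oracle_prelim(bases)

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=60))
    @settings(max_examples=300, deadline=None)
    def test_matches_oracle_full_alphabet(self, bases):
        assert find_preliminary_region(bases) == oracle_prelim(bases)


# ---------------------------------------------------------------------------
# refine_region
# ---------------------------------------------------------------------------

class TestRefine:
    def test_pure_tail_unchanged(self):
        bases = "A" * 15
        assert refine_region(bases, (0, 15)) == ((0, 15), "none")

    def test_longest_segment_wins(self):
        bases = "A" * 12 + "C" * 5 + "A" * 30
        assert refine_region(bases, (0, len(bases)))[0] == (17, 47)

    def test_tie_goes_5prime(self):
        bases = "A" * 12 + "C" * 5 + "A" * 12
        assert refine_region(bases, (0, len(bases)))[0] == (0, 12)

    def test_no_pure_run_discarded(self):
        # 18 bases, no 10 consecutive As anywhere
        bases = "AAAACAAAACAAAACAAA"
        assert refine_region(bases, (0, len(bases))) == (None, "no_pure_run")

    def test_interior_short_non_a_runs_kept(self):
        bases = "A" * 10 + "CCCC" + "A" * 10
        assert refine_region(bases, (0, len(bases)))[0] == (0, 24)

    def test_edges_stripped_to_a(self):
        bases = "C" + "A" * 12 + "C"
        assert refine_region(bases, (0, 14))[0] == (1, 13)

    @given(st.text(alphabet="AC", min_size=0, max_size=30))
    @settings(max_examples=500, deadline=None)
    def test_matches_enumeration_oracle(self, bases):
        prelim = (0, len(bases))
        got = refine_region(bases, prelim)
        assert got == oracle_refine(bases, prelim)


# ---------------------------------------------------------------------------
# apply_quality_bleed_filter
# ---------------------------------------------------------------------------

QC_ON = DEFAULT_PARAMS.replace(qc_filter_enabled=True)


class TestQualityFilter:
    def test_noop_when_disabled(self):
        quals = np.full(60, 10)
        assert apply_quality_bleed_filter((0, 60), quals) == ((0, 60), False, "none")

    def test_high_quality_untouched(self):
        quals = np.full(60, 37)
        tail, truncated, _ = apply_quality_bleed_filter(
            (0, 60), quals, QC_ON, bases="A" * 60)
        assert tail == (0, 60) and not truncated

    def test_truncates_at_quality_collapse(self):
        quals = np.concatenate([np.full(50, 37), np.full(30, 10)])
        tail, truncated, reason = apply_quality_bleed_filter(
            (0, 80), quals, QC_ON, bases="A" * 80)
        # first sub-threshold window straddles the junction: (37,10,10)/3 < 25
        assert tail == (0, 49) and truncated and reason == "none"

    def test_mean_exactly_threshold_not_truncated(self):
        quals = np.array([25, 25, 25] + [37] * 10)
        tail, truncated, _ = apply_quality_bleed_filter(
            (0, 13), quals, QC_ON, bases="A" * 13)
        assert tail == (0, 13) and not truncated

    def test_discards_when_truncated_below_minimum(self):
        quals = np.concatenate([np.full(5, 37), np.full(25, 10)])
        tail, truncated, reason = apply_quality_bleed_filter(
            (0, 30), quals, QC_ON, bases="A" * 30)
        assert tail is None and truncated and reason == "no_pure_run"

    @given(st.lists(st.integers(0, 45), min_size=12, max_size=60))
    @settings(max_examples=300, deadline=None)
    def test_matches_sliding_mean_oracle_and_is_monotone_idempotent(self, qlist):
        quals = np.array(qlist)
        tail = (0, len(quals))
        bases = "A" * len(quals)
        got, truncated, reason = apply_quality_bleed_filter(
            tail, quals, QC_ON, bases=bases)
        want, want_trunc = oracle_qc(tail, quals, QC_ON)
        assert truncated == want_trunc
        if got is not None:
            assert got == want
            # never lengthens
            assert got[1] <= tail[1] and got[0] == tail[0]
            # idempotent
            again = apply_quality_bleed_filter(got, quals, QC_ON, bases=bases)
            assert again == (got, False, "none")
        else:
            # discarded: the oracle's truncation was below the minimum
            assert want_trunc and (
                want[1] - want[0] < QC_ON.min_pure_A_run
            )


# ---------------------------------------------------------------------------
# detect_adaptor
# ---------------------------------------------------------------------------

ADAPTOR3 = "CGTTGCTGGCGTTCGTTCGGCTTGTTGGTG"  # A-free, 30 nt


def mutate(seq, positions, base="T"):
    out = list(seq)
    for p in positions:
        out[p] = base if out[p] != base else "C"
    return "".join(out)


class TestDetectAdaptor:
    def test_exact_adaptor_found_at_low_rate(self):
        bases = "A" * 40 + ADAPTOR3
        assert detect_adaptor(bases, 40, ADAPTOR3, error_rate=0.1)

    def test_three_substitutions_rate_dependent(self):
        probe = mutate(ADAPTOR3[:20], [2, 7, 13]) + ADAPTOR3[20:]
        bases = "A" * 40 + probe
        assert hamming(probe[:20], ADAPTOR3[:20]) == 3
        assert not detect_adaptor(bases, 40, ADAPTOR3, error_rate=0.1)  # allows 2
        assert detect_adaptor(bases, 40, ADAPTOR3, error_rate=0.2)      # allows 4

    def test_tail_to_read_end_never_found(self):
        bases = "A" * 150
        assert not detect_adaptor(bases, 150, ADAPTOR3, error_rate=0.35)
        assert not detect_adaptor(bases, 140, ADAPTOR3, error_rate=0.35)

    def test_offset_window_tolerates_spurious_as(self):
        bases = "A" * 40 + "AAA" + ADAPTOR3  # 3 bled As past the called end
        assert detect_adaptor(bases, 40, ADAPTOR3, error_rate=0.1)
        assert not detect_adaptor(bases, 40, ADAPTOR3, error_rate=0.1, max_offset=2)

    def test_short_adaptor_rejected(self):
        with pytest.raises(ValueError, match="probe"):
            detect_adaptor("A" * 50, 10, "CGTCGT")

    @given(st.text(alphabet="ACGT", min_size=0, max_size=80),
           st.integers(0, 60))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_error_rate(self, bases, tail_end):
        rates = (0.1, 0.2, 0.25, 0.3, 0.35)
        hits = [detect_adaptor(bases, tail_end, ADAPTOR3, error_rate=r)
                for r in rates]
        assert hits == sorted(hits)


# ---------------------------------------------------------------------------
# call_read composition
# ---------------------------------------------------------------------------

class TestCallRead:
    def test_end_to_end_clean_read(self):
        anchor = "CGTCGTGGCTTGCGTTCGTTCGTCG"  # 25 nt, A-free
        read = make_read(anchor + "A" * 40 + ADAPTOR3[:20])
        call = call_read(read, adaptor3=ADAPTOR3)
        assert call.retained
        assert call.tail_len == 40
        assert call.tail == (25, 65)
        assert call.adaptor_found
        # the fuzzy 5' window absorbs the anchor's last base into the
        # preliminary region; the mapped anchor is everything upstream
        assert call.anchor_seq == anchor[:24]

    def test_all_g_read_discarded(self):
        call = call_read(make_read("G" * 80))
        assert call.discard_reason == "no_prelim"

    def test_short_anchor_flagged_for_mapping(self):
        anchor = "CGTCGTGGCTTGCGT"  # 15 nt < 20
        call = call_read(make_read(anchor + "A" * 40))
        assert call.retained and call.tail_len == 40
        assert call.anchor_len == 14  # last anchor base absorbed by the fuzzy window
        assert call.anchor_len < DEFAULT_PARAMS.min_anchor_map_len

    def test_qc_filter_composes(self):
        anchor = "CGTCGTGGCTTGCGTTCGTTCGTCG"
        bases = anchor + "A" * 46 + ADAPTOR3[:20]
        quals = np.concatenate([
            np.full(25, 37), np.full(40, 37), np.full(6, 10), np.full(20, 10),
        ])
        from pafinder.io_formats import SequencingRead

        read = SequencingRead("r", bases, quals)
        call = call_read(read, adaptor3=ADAPTOR3, params=QC_ON)
        assert call.qc_truncated
        # 40 high-quality As; the first offending window starts one base
        # earlier (mean(37,10,10) < 25), so 39 survive
        assert call.tail_len == 39

    def test_retained_call_invariants_on_random_reads(self, rng):
        params = DEFAULT_PARAMS
        for _ in range(200):
            n = int(rng.integers(20, 120))
            bases = "".join(rng.choice(list("ACGT"), size=n,
                                       p=[0.45, 0.2, 0.15, 0.2]))
            call = call_read(make_read(bases))
            if not call.retained:
                continue
            ps, pe = call.prelim
            ts, te = call.tail
            assert 0 <= ps <= ts < te <= pe <= n
            assert call.tail_len == te - ts <= n
            tail = bases[ts:te]
            assert tail[0] == "A" and tail[-1] == "A"
            assert "A" * params.min_pure_A_run in tail
            import re

            assert not re.search("[^A]{%d,}" % params.nonA_split_run, tail)


class TestParameterSet:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet(anchor5_max_mm=9)
        with pytest.raises(ValueError):
            ParameterSet(min_prelim_len=3)
        with pytest.raises(ValueError):
            ParameterSet(adaptor_error_rate=1.5)

    def test_rate_based_anchor_budgets(self):
        params = ParameterSet(use_anchor_error_rates=True)
        # floor(0.1 * 9) = 0 and floor(0.2 * 6) = 1
        assert params.effective_anchor5_max_mm == 0
        assert params.effective_anchor3_max_mm == 1

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ParameterSet.from_dict({"bogus": 1})

    def test_fingerprint_stable_and_sensitive(self):
        assert ParameterSet().fingerprint() == ParameterSet().fingerprint()
        assert (ParameterSet().fingerprint()
                != ParameterSet(qc_filter_enabled=True).fingerprint())
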