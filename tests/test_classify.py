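"""Modal-length instability calls and overall MSI status."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msiamp import (ClassifyConfig, LengthDistribution, LocusStatus,
                    OverallStatus, call_locus, default_panel, modal_length,
                    overall_status)
from msiamp.classify import (ComparatorSource, LocusCall, calls_from_flags)


def _dist(counts, locus="BAT26"):
    return LengthDistribution(locus_name=locus, counts=counts)


class TestModalLength:
    def test_strict_argmax(self):
        assert modal_length(_dist({116: 5000, 115: 900, 114: 300})) == 116
        assert modal_length(_dist({113: 4000, 116: 3999})) == 113

    def test_tie_breaks_toward_comparator(self):
        assert modal_length(_dist({113: 10, 116: 10}),
                            comparator_mode=116) == 116
        assert modal_length(_dist({113: 10, 116: 10}),
                            comparator_mode=112) == 113

    def test_tie_breaks_toward_shorter_without_comparator(self):
        assert modal_length(_dist({113: 10, 116: 10})) == 113

    def test_empty_distribution_errors(self):
        with pytest.raises(ValueError, match="empty"):
            modal_length(_dist({}))

    def test_matches_bruteforce_argmax(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            lengths = rng.choice(np.arange(100, 130), size=8,
                                 replace=False)
            counts = {int(L): int(c) for L, c in
                      zip(lengths, rng.integers(1, 500, size=8))}
            best = None
            for L, c in counts.items():  # exhaustive max scan oracle
                if best is None or c > counts[best] or \
                        (c == counts[best] and L < best):
                    best = L
            assert modal_length(_dist(counts)) == best


@pytest.fixture(scope="module")
def bat26():
    return default_panel()["BAT26"]


@pytest.fixture(scope="module")
def d18s55():
    return default_panel()["D18S55"]


class TestCallLocus:
    def _deep(self, mode, locus="BAT26"):
        return _dist({mode: 4000, mode - 1: 300}, locus)

    def test_three_bp_deletion_unstable(self, bat26):
        call = call_locus(self._deep(113), self._deep(116), bat26)
        assert call.delta_bp == 3
        assert call.status is LocusStatus.UNSTABLE
        assert call.comparator_source is ComparatorSource.MATCHED_NORMAL

    def test_equal_modes_stable(self, bat26):
        call = call_locus(self._deep(116), self._deep(116), bat26)
        assert call.delta_bp == 0
        assert call.status is LocusStatus.STABLE

    @pytest.mark.parametrize("delta,expected", [
        (0, LocusStatus.STABLE), (1, LocusStatus.STABLE),
        (2, LocusStatus.UNSTABLE), (3, LocusStatus.UNSTABLE),
    ])
    def test_mononucleotide_cutoff_inclusive(self, bat26, delta, expected):
        call = call_locus(self._deep(116 - delta), self._deep(116), bat26)
        assert call.status is expected

    @pytest.mark.parametrize("delta,expected", [
        (2, LocusStatus.STABLE), (3, LocusStatus.STABLE),
        (4, LocusStatus.UNSTABLE), (6, LocusStatus.UNSTABLE),
    ])
    def test_dinucleotide_cutoff_inclusive(self, d18s55, delta, expected):
        tum = self._deep(147 - delta, "D18S55")
        call = call_locus(tum, self._deep(147, "D18S55"), d18s55)
        assert call.status is expected

    def test_insertion_deletion_symmetry(self, bat26):
        up = call_locus(self._deep(119), self._deep(116), bat26)
        down = call_locus(self._deep(113), self._deep(116), bat26)
        assert up.delta_bp == down.delta_bp == 3
        assert up.status is down.status is LocusStatus.UNSTABLE

    def test_shallow_tumour_is_no_call(self, bat26):
        call = call_locus(_dist({113: 50}), self._deep(116), bat26)
        assert call.status is LocusStatus.NO_CALL

    def test_shallow_normal_is_no_call(self, bat26):
        call = call_locus(self._deep(113), _dist({116: 10}), bat26)
        assert call.status is LocusStatus.NO_CALL

    def test_integer_comparator_is_panel_reference(self, bat26):
        call = call_locus(self._deep(118), 121, bat26)
        assert call.comparator_source is ComparatorSource.PANEL_REFERENCE
        assert call.delta_bp == 3
        assert call.status is LocusStatus.UNSTABLE

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.dictionaries(st.integers(100, 140), st.integers(100, 5000),
                           min_size=1, max_size=10))
    def test_tumour_equals_normal_always_stable(self, bat26, counts):
        """Paired mode with identical tumour and normal distributions can
        never call instability, whatever the histogram looks like."""
        call = call_locus(_dist(counts), _dist(counts), bat26)
        assert call.status in (LocusStatus.STABLE, LocusStatus.NO_CALL)
        if call.status is LocusStatus.STABLE:
            assert call.delta_bp == 0


def _status_of(flags):
    return overall_status(calls_from_flags(flags)).overall


class TestOverallStatus:
    def test_published_row_patterns(self):
        # four unstable of five -> MSI-H; single unstable -> MSI-L
        assert _status_of([1, 1, 1, 1, 0]) is OverallStatus.MSI_H
        assert _status_of([0, 0, 0, 0, 1]) is OverallStatus.MSI_L
        assert _status_of([0, 0, 0, 0, 0]) is OverallStatus.MSS

    def test_no_informative_calls_indeterminate(self):
        calls = [LocusCall("L1", LocusStatus.NO_CALL)]
        assert overall_status(calls).overall is OverallStatus.INDETERMINATE
        assert overall_status([]).overall is OverallStatus.INDETERMINATE

    def test_no_call_loci_excluded_from_denominator(self):
        calls = [LocusCall("L1", LocusStatus.UNSTABLE),
                 LocusCall("L2", LocusStatus.NO_CALL),
                 LocusCall("L3", LocusStatus.STABLE)]
        result = overall_status(calls)
        assert result.n_informative == 2
        assert result.n_unstable == 1
        assert result.overall is OverallStatus.MSI_L

    def test_all_32_call_vectors_match_bruteforce_rule(self):
        """Exhaustive check of the combination rule over every possible
        five-locus stable/unstable vector."""
        for flags in product([False, True], repeat=5):
            n = sum(flags)  # independent brute-force count
            expected = (OverallStatus.MSI_H if n >= 2
                        else OverallStatus.MSI_L if n == 1
                        else OverallStatus.MSS)
            assert _status_of(list(flags)) is expected

    def test_adding_unstable_never_demotes(self):
        rank = {OverallStatus.MSS: 0, OverallStatus.MSI_L: 1,
                OverallStatus.MSI_H: 2}
        for flags in product([False, True], repeat=4):
            before = _status_of(list(flags))
            after = _status_of(list(flags) + [True])
            assert rank[after] >= rank[before]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ClassifyConfig(mono_cutoff_bp=0)
        with pytest.raises(ValueError):
            ClassifyConfig(min_reads_per_locus=-1)
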