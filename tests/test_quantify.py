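"""Counting statistics: labelled-event percentages, concentrations, ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caspore.quantify import (
    EventCounts,
    barcode_library_size,
    binding_efficiency,
    control_efficiency,
    counts_from_decoded,
    normalized_binding_ratio,
    pct_dcas9_events,
    population_sd,
    position_binding_fraction,
    relative_concentration,
    summarize,
    wilson_interval,
)

import pandas as pd


def two_barcode_counts(n1d, n1n, n2d, n2n):
    return EventCounts(barcode_counts={"11111": (n1d, n1n), "11001": (n2d, n2n)})


class TestPctDcas9Events:
    def test_printed_pair(self):
        pct = pct_dcas9_events(two_barcode_counts(947, 0, 53, 0))
        assert pct["11111"] == pytest.approx(94.7)
        assert pct["11001"] == pytest.approx(5.3)

    def test_zero_labelled_for_one_barcode(self):
        pct = pct_dcas9_events(two_barcode_counts(0, 5, 10, 3))
        assert pct["11111"] == 0.0
        assert pct["11001"] == 100.0

    def test_equal_counts_split_evenly(self):
        counts = EventCounts(
            barcode_counts={f"{i:05b}": (1, 0) for i in range(4)}
        )
        pct = pct_dcas9_events(counts)
        assert all(v == pytest.approx(25.0) for v in pct.values())

    def test_no_labelled_events_is_an_error(self):
        with pytest.raises(ValueError):
            pct_dcas9_events(two_barcode_counts(0, 5, 0, 3))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 10_000), st.integers(0, 10_000)),
            min_size=2,
            max_size=6,
        ).filter(lambda xs: sum(x[0] for x in xs) > 0)
    )
    def test_percentages_sum_to_one_hundred(self, tallies):
        counts = EventCounts(
            barcode_counts={f"b{i}": t for i, t in enumerate(tallies)}
        )
        assert sum(pct_dcas9_events(counts).values()) == pytest.approx(100.0)


class TestRelativeConcentration:
    def test_equal_counts_split_evenly_in_both_modes(self):
        counts = two_barcode_counts(30, 70, 30, 70)
        for mode in ("printed", "efficiency_corrected"):
            rel = relative_concentration(counts, mode=mode)
            assert rel["11111"] == pytest.approx(0.5)

    def test_one_to_three_mixture_corrected_recovers_input_fraction(self):
        # exact expected counts at mixture 1:3, equal efficiency p=0.4
        counts = two_barcode_counts(120, 180, 40, 60)  # 11111 is the 75% species
        rel = relative_concentration(counts, mode="efficiency_corrected")
        assert rel["11111"] == pytest.approx(0.75)
        assert rel["11001"] == pytest.approx(0.25)

    def test_one_to_three_mixture_printed_form_squares_the_fraction(self):
        counts = two_barcode_counts(120, 180, 40, 60)
        rel = relative_concentration(counts, mode="printed")
        assert rel["11111"] == pytest.approx(0.9)
        assert rel["11001"] == pytest.approx(0.1)

    def test_normalization_sums_to_one(self):
        counts = two_barcode_counts(17, 55, 41, 13)
        for mode in ("printed", "efficiency_corrected"):
            assert sum(relative_concentration(counts, mode=mode).values()) == (
                pytest.approx(1.0)
            )

    def test_zero_efficiency_barcode_is_an_error_in_corrected_mode(self):
        with pytest.raises(ValueError, match="efficiency"):
            relative_concentration(two_barcode_counts(0, 10, 5, 5))

    def test_printed_mode_requires_two_barcodes(self):
        counts = EventCounts(barcode_counts={"11111": (5, 5)})
        with pytest.raises(ValueError):
            relative_concentration(counts, mode="printed")


class TestPositionStatistics:
    COUNTS = EventCounts(
        position_counts={1: (10, 10), 2: (0, 50), 3: (337, 663)},
        barcode_counts={"11010": (300, 100)},
    )

    @pytest.mark.parametrize("pos,expected", [(1, 0.5), (2, 0.0), (3, 0.337)])
    def test_position_binding_fraction(self, pos, expected):
        assert position_binding_fraction(self.COUNTS, pos) == pytest.approx(expected)

    def test_zero_total_at_position_is_an_error(self):
        counts = EventCounts(position_counts={1: (0, 0)})
        with pytest.raises(ValueError):
            position_binding_fraction(counts, 1)

    @pytest.mark.parametrize(
        "fracs,expected",
        [
            ((0.337, 0.337, 0.337), 0.337),
            ((0.0, 0.0, 0.0), 0.0),
            ((0.3, 0.33, 0.38), 0.33666666666),
        ],
    )
    def test_control_efficiency_is_the_mean(self, fracs, expected):
        assert control_efficiency(fracs) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "xp,xc,expected", [(0.337, 0.337, 1.0), (0.0, 0.337, 0.0), (0.1685, 0.337, 0.5)]
    )
    def test_normalized_binding_ratio(self, xp, xc, expected):
        assert normalized_binding_ratio(xp, xc) == pytest.approx(expected)

    def test_ratio_requires_positive_control(self):
        with pytest.raises(ValueError):
            normalized_binding_ratio(0.3, 0.0)

    def test_ratio_may_exceed_one(self):
        assert normalized_binding_ratio(0.5, 0.337) > 1.0


class TestBindingEfficiency:
    @pytest.mark.parametrize(
        "nd,nn,expected", [(10, 0, 100.0), (0, 10, 0.0), (337, 663, 33.7)]
    )
    def test_examples(self, nd, nn, expected):
        assert binding_efficiency(nd, nn) == pytest.approx(expected)

    def test_zero_events_is_an_error(self):
        with pytest.raises(ValueError):
            binding_efficiency(0, 0)


class TestPopulationSd:
    @pytest.mark.parametrize(
        "values,expected",
        [((1, 1, 1), 0.0), ((0, 2), 1.0), ((2, 4, 4, 4, 5, 5, 7, 9), 2.0)],
    )
    def test_uses_population_divisor(self, values, expected):
        assert population_sd(values) == pytest.approx(expected)


class TestLibrarySize:
    @pytest.mark.parametrize("bits,expected", [(5, 32), (1, 2)])
    def test_small_libraries(self, bits, expected):
        assert barcode_library_size(bits) == expected

    def test_dense_barcode_library_is_exact_and_huge(self):
        size = barcode_library_size(56)
        assert size == 72_057_594_037_927_936
        assert size > 10**16
        assert isinstance(size, int)


class TestScaleInvariance:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.tuples(
            st.integers(1, 500), st.integers(0, 500),
            st.integers(1, 500), st.integers(0, 500),
        ),
        st.integers(2, 9),
    )
    def test_all_fractions_unchanged_under_count_scaling(self, tallies, factor):
        a = two_barcode_counts(*tallies)
        b = two_barcode_counts(*(factor * t for t in tallies))
        assert pct_dcas9_events(a) == pytest.approx(pct_dcas9_events(b))
        for mode in ("printed", "efficiency_corrected"):
            assert relative_concentration(a, mode=mode) == pytest.approx(
                relative_concentration(b, mode=mode)
            )


def test_wilson_interval_brackets_the_fraction():
    lo, hi = wilson_interval(337, 1000)
    assert lo < 0.337 < hi
    assert hi - lo < 0.07


def test_counts_from_decoded_table():
    decoded = pd.DataFrame(
        {
            "barcode": ["11111", "11111", "11001", "unclassified", "11010"],
            "bound_flags": ["1", "0", "1", "", "101"],
        }
    )
    counts = counts_from_decoded(decoded)
    assert counts.barcode_counts["11111"] == (1, 1)
    assert counts.barcode_counts["11001"] == (1, 0)
    assert counts.barcode_counts["11010"] == (1, 0)
    assert "unclassified" not in counts.barcode_counts
    # positional tallies: single-site rows contribute to position 1 only
    assert counts.position_counts[1] == (3, 1)
    assert counts.position_counts[2] == (0, 1)
    assert counts.position_counts[3] == (1, 0)


def test_summarize_assembles_consistent_result():
    counts = two_barcode_counts(120, 180, 40, 60)
    result = summarize(counts)
    assert result.pct_dcas9["11111"] == pytest.approx(75.0)
    assert result.rel_concentration_corrected["11111"] == pytest.approx(0.75)
    assert result.rel_concentration_printed["11111"] == pytest.approx(0.9)
    assert result.binding_efficiency_pct["11111"] == pytest.approx(40.0)
    d = result.to_dict()
    assert d["counts"]["barcodes"]["11001"]["n_dcas9"] == 40
    frame = result.to_frame()
    assert set(frame["barcode"]) == {"11111", "11001"}
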