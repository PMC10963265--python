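"""Spike calling, barcode matching, orientation handling, bound-state calls."""

import numpy as np
import pytest

from caspore import BindingModelParams, SimConfig
from caspore.barcode_decode import (
    PeakParams,
    SpikeCall,
    assign_barcode,
    call_dcas9,
    decode_event,
    detect_spikes,
)
from caspore.event_detect import TranslocationEvent, estimate_dsdna_level, find_events
from caspore.guide_model import ConfigurationError, matched_probe
from caspore.pipeline import RunConfig, decode_events, detect_and_filter
from caspore.trace_sim import simulate_trace, single_site_design

from conftest import match_events_to_truth

SLOTS = tuple(np.linspace(0.2, 0.8, 5))


def event_with_spikes(spike_fracs, n=500, ds=120.0, extra=120.0, width=40, noise=2.0):
    depth = np.full(n, ds)
    for f, e in spike_fracs:
        c = int(round(f * n))
        depth[max(c - width // 2, 0): c - width // 2 + width] += e
    rng = np.random.default_rng(0)
    return TranslocationEvent(
        start=0, end=n, baseline_level=10_000.0,
        samples=-(depth + rng.normal(0, noise, n)),
        noise_pA=noise, sampling_rate=250_000.0,
    )


class TestDetectSpikes:
    def test_five_injected_spikes_found_at_positions(self):
        ev = event_with_spikes([(f, 120.0) for f in SLOTS])
        calls = detect_spikes(ev, dsdna_level=120.0)
        assert len(calls) == 5
        for call, frac in zip(calls, SLOTS):
            assert abs(call.position - frac) < 0.08  # within one spike width

    def test_low_prominence_spike_not_called(self):
        params = PeakParams(height=10.0, prominence=40.0)
        ev = event_with_spikes([(0.3, 25.0), (0.7, 120.0)])
        calls = detect_spikes(ev, params, dsdna_level=120.0)
        assert len(calls) == 1
        assert abs(calls[0].position - 0.7) < 0.08

    def test_close_pair_keeps_the_deeper_spike(self):
        # two spikes inside one min-distance window: deeper one wins
        ev = event_with_spikes([(0.40, 60.0), (0.44, 180.0)], width=8)
        params = PeakParams(height=40.0, prominence=30.0, min_distance=0.1)
        calls = detect_spikes(ev, params, dsdna_level=120.0)
        assert len(calls) == 1
        assert abs(calls[0].position - 0.44) < 0.03

    def test_flat_event_yields_no_calls(self):
        ev = event_with_spikes([])
        assert detect_spikes(ev, dsdna_level=120.0) == []


def spikes_at(*fracs):
    return [SpikeCall(position=f, depth=120.0) for f in fracs]


class TestAssignBarcode:
    def test_palindromic_code_assigned_with_ambiguous_orientation(self):
        occ = spikes_at(*SLOTS)  # occupancy 11111
        code, orient = assign_barcode(occ, SLOTS, {"11111", "11001"})
        assert (code, orient) == ("11111", "ambiguous")

    def test_reversed_occupancy_matches_with_reverse_orientation(self):
        # occupancy 10011 is the mirror of 11001
        occ = spikes_at(SLOTS[0], SLOTS[3], SLOTS[4])
        code, orient = assign_barcode(occ, SLOTS, {"11001"})
        assert (code, orient) == ("11001", "reverse")

    def test_unmatched_occupancy_is_unclassified(self):
        occ = spikes_at(SLOTS[0], SLOTS[2], SLOTS[4])  # 10101
        code, orient = assign_barcode(occ, SLOTS, {"11111", "11001"})
        assert (code, orient) == ("unclassified", "ambiguous")

    def test_two_codes_matching_both_orientations_is_not_unique(self):
        # occupancy 10011 matches 10011 forward and 11001 reversed
        occ = spikes_at(SLOTS[0], SLOTS[3], SLOTS[4])
        code, orient = assign_barcode(occ, SLOTS, {"10011", "11001"})
        assert (code, orient) == ("unclassified", "ambiguous")

    def test_overlapping_slot_windows_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_barcode(spikes_at(0.5), SLOTS, {"11111"}, slot_tolerance=0.6)

    def test_empty_library_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_barcode([], SLOTS, set())


class TestCallDcas9:
    SITES = (0.08,)

    def test_spike_at_window_centre_is_bound(self):
        flags, off = call_dcas9(spikes_at(0.08, *SLOTS), SLOTS, self.SITES, "forward")
        assert flags == (True,)
        assert off == 0

    def test_no_extra_spikes_means_unbound(self):
        flags, off = call_dcas9(spikes_at(*SLOTS), SLOTS, self.SITES, "forward")
        assert flags == (False,)
        assert off == 0

    def test_reverse_orientation_mirrors_windows(self):
        flags, off = call_dcas9(spikes_at(0.92), SLOTS, self.SITES, "reverse")
        assert flags == (True,)

    def test_three_site_scenarios(self):
        sites = (0.04, 0.10, 0.90)
        # no non-barcode spikes: nothing bound
        flags, _ = call_dcas9(spikes_at(*SLOTS), SLOTS, sites, "forward")
        assert flags == (False, False, False)
        # spikes in two of three windows: exactly those two bound
        flags, _ = call_dcas9(
            spikes_at(0.04, 0.90, *SLOTS), SLOTS, sites, "forward"
        )
        assert flags == (True, False, True)

    def test_off_window_spike_counted_as_artifact(self):
        flags, off = call_dcas9(spikes_at(0.99), SLOTS, self.SITES, "forward")
        assert flags == (False,)
        assert off == 1

    def test_spike_consumed_by_slot_cannot_mark_a_site(self):
        # one spike at the slot centre: it is a barcode spike, not a binding
        flags, off = call_dcas9(spikes_at(SLOTS[0]), SLOTS, (SLOTS[0] - 0.07,), "forward")
        assert flags == (False,)
        assert off == 0


class TestEndToEndDecoding:
    def run_mixture(self, n_events, seed, p=0.5, knot_rate=0.045):
        d1 = single_site_design("m11111", "11111", weight=1.0)
        d2 = single_site_design("m11001", "11001", weight=1.0)
        probe = matched_probe("p", d1.overhang_sites[0][1])
        cfg = RunConfig(
            designs=[d1, d2],
            probes={"m11111": probe, "m11001": probe},
            sim=SimConfig(seed=seed, knot_rate=knot_rate),
            binding=BindingModelParams(baseline_efficiency=p),
            n_events=n_events,
        )
        trace, truths = simulate_trace(
            cfg.designs_with_probes(), n_events, cfg.sim, binding_params=cfg.binding
        )
        events, _ = detect_and_filter(trace, cfg.detector)
        decoded = decode_events(events, cfg)
        pairs = match_events_to_truth(events, truths)
        truth_by_interval = {(ev.start, ev.end): t for ev, t in pairs}
        return cfg, events, decoded, truth_by_interval

    def test_orientation_invariance_under_time_reversal(self):
        cfg, events, decoded, _ = self.run_mixture(60, seed=41)
        overhangs = {d.barcode: [p for p, _ in d.overhang_sites] for d in cfg.designs}
        ds = estimate_dsdna_level(events)
        n_checked = 0
        for ev, (_, row) in zip(events, decoded.iterrows()):
            fwd = decode_event(
                ev, cfg.slot_positions, cfg.barcode_library, overhangs,
                params=cfg.peaks, dsdna_level=ds,
            )
            rev = decode_event(
                ev.time_reversed(), cfg.slot_positions, cfg.barcode_library,
                overhangs, params=cfg.peaks, dsdna_level=ds,
            )
            assert fwd.barcode == rev.barcode
            if fwd.classified:
                assert fwd.bound_flags == rev.bound_flags
                n_checked += 1
        assert n_checked >= 10

    def test_per_site_accuracy_against_truth(self):
        _, events, decoded, truth_by_interval = self.run_mixture(
            1000, seed=43, p=0.5, knot_rate=0.0
        )
        correct = total = 0
        for ev, (_, row) in zip(events, decoded.iterrows()):
            truth = truth_by_interval.get((ev.start, ev.end))
            if truth is None or row["barcode"] == "unclassified":
                continue
            called = tuple(c == "1" for c in row["bound_flags"])
            total += 1
            correct += called == truth.bound_flags
        assert total >= 250
        assert correct / total >= 0.99

    def test_barcode_confusion_is_diagonal_dominant(self):
        _, events, decoded, truth_by_interval = self.run_mixture(
            800, seed=47, p=0.5, knot_rate=0.0
        )
        design_to_code = {"m11111": "11111", "m11001": "11001"}
        wrong = total = 0
        for ev, (_, row) in zip(events, decoded.iterrows()):
            truth = truth_by_interval.get((ev.start, ev.end))
            if truth is None or row["barcode"] == "unclassified":
                continue
            total += 1
            wrong += row["barcode"] != design_to_code[truth.design]
        assert total >= 200
        assert wrong / total <= 0.01
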