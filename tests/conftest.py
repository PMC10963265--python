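"""Shared fixtures: canned designs, probes and truth-matching helpers."""

import bisect

import numpy as np
import pytest

from caspore import BindingModelParams, SimConfig, matched_probe
from caspore.trace_sim import single_site_design


@pytest.fixture
def design_pair():
    """Equimolar 11111/11001 single-overhang carriers sharing one target."""
    d1 = single_site_design("m11111", "11111", weight=1.0)
    d2 = single_site_design("m11001", "11001", weight=1.0)
    return d1, d2


@pytest.fixture
def probe(design_pair):
    return matched_probe("matched", design_pair[0].overhang_sites[0][1])


@pytest.fixture
def quiet_sim():
    """Simulator config with the stochastic artifact channels switched off."""
    return SimConfig(seed=42, folded_fraction=0.0, knot_rate=0.0)


def binding(p: float) -> BindingModelParams:
    return BindingModelParams(baseline_efficiency=p)


def match_events_to_truth(events, truths, min_overlap=0.5):
    """Pair detected events with ground-truth records by interval overlap."""
    starts = [t.start for t in truths]
    pairs = []
    for ev in events:
        i = bisect.bisect_right(starts, ev.start + 5) - 1
        if i < 0:
            continue
        t = truths[i]
        overlap = min(ev.end, t.end) - max(ev.start, t.start)
        if overlap > min_overlap * (t.end - t.start):
            pairs.append((ev, t))
    return pairs


def binomial_3se(p: float, n: int) -> float:
    return 3.0 * np.sqrt(max(p * (1.0 - p), 1e-12) / n)
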