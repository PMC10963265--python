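"""Synthetic nanopore traces of barcoded DNA carriers with dCas9 probes.

The generator emulates the assay's measurement phenomenology: a positive
open-pore current with Gaussian noise; per-molecule square-pulse blockades
while a DNA carrier transits the pore; five equally spaced dumbbell-hairpin
barcode groups, each present ("1") or absent ("0"), appearing as short
deeper spikes; sequence-programmable overhang sites that produce a spike
only when a dCas9 RNP is bound (an unbound 50-bp overhang is below the
detection limit); bidirectional translocation (the spike pattern mirrors
for reverse events); partially folded carriers (~70 % of events) whose
blockade doubles over a leading or trailing stretch; and occasional knot
artifacts - spurious spikes inside an unbound overhang's window that mimic
a bound protein (~4.5 % of unbound sites).  Binding itself is drawn from
the sequence-level model in :mod:`caspore.guide_model`.

Every stochastic choice flows from one :class:`numpy.random.Generator`, so
a seed fully determines the trace and its ground-truth log.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .event_detect import CurrentTrace
from .guide_model import (
    BindingModelParams,
    GuideProbe,
    TargetSite,
    binding_probability,
    matched_probe,
    mismatch_profile,
)

__all__ = [
    "SimConfig",
    "NanostructureDesign",
    "GroundTruthRecord",
    "simulate_event",
    "simulate_trace",
    "single_site_design",
    "three_site_design",
    "truth_to_dataframe",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class SimConfig:
    """Trace-simulator parameters.

    Defaults mirror the measurement conditions the generator emulates:
    250 kHz sampling with a 50 kHz low-pass, ~10 nA open-pore current with
    6 pA noise, a 120 pA dsDNA blockade with 120 pA extra spike depth,
    ~2 ms dwells, 70 % folded events and a 4.5 % per-unbound-site knot
    artifact rate.  Amplitude and dwell values are phenomenological
    placeholders on the correct scales, not fitted constants.
    """

    sampling_rate: float = 250_000.0
    baseline_current: float = 10_000.0
    noise_sd: float = 6.0
    dsdna_blockade: float = 120.0
    spike_extra_blockade: float = 120.0
    spike_width_samples: int = 40
    dwell_mean: float = 2e-3
    dwell_sigma: float = 0.2  # lognormal shape parameter of the dwell draw
    event_rate: float = 100.0
    min_gap_samples: int = 1000
    folded_fraction: float = 0.7
    knot_rate: float = 0.045
    lowpass_cutoff: float = 50_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.baseline_current <= 0:
            raise ValueError("sampling_rate and baseline_current must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dwell_mean <= 0:
            raise ValueError("dwell_mean must be positive")
        for name in ("folded_fraction", "knot_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.event_rate <= 0:
            raise ValueError("event_rate must be positive")
        if self.spike_width_samples < 2:
            raise ValueError("spike_width_samples must be >= 2")


@dataclass(frozen=True)
class NanostructureDesign:
    """A barcoded DNA carrier: bit pattern, slot layout, overhang sites.

    Positions are fractions of the carrier length in (0, 1).  Barcode slots
    default to a layout symmetric about the carrier midpoint so that the
    slot windows map onto themselves under direction reversal; overhang
    sites may sit anywhere clear of the slot windows.
    """

    name: str
    barcode: str
    overhang_sites: Tuple[Tuple[float, TargetSite], ...] = ()
    barcode_slot_positions: Optional[Tuple[float, ...]] = None
    concentration_weight: float = 1.0
    #: half-width of each overhang's decoding window as a fraction of the
    #: event; None derives it from the barcode slot spacing
    overhang_window: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.barcode or set(self.barcode) - {"0", "1"}:
            raise ValueError("barcode must be a non-empty string over {0,1}")
        if self.barcode_slot_positions is None:
            slots = tuple(np.linspace(0.2, 0.8, len(self.barcode)))
            object.__setattr__(self, "barcode_slot_positions", slots)
        else:
            object.__setattr__(
                self, "barcode_slot_positions", tuple(self.barcode_slot_positions)
            )
        if len(self.barcode_slot_positions) != len(self.barcode):
            raise ValueError("barcode length must equal the number of slot positions")
        object.__setattr__(self, "overhang_sites", tuple(self.overhang_sites))
        positions = list(self.barcode_slot_positions) + [
            p for p, _ in self.overhang_sites
        ]
        if any(not 0.0 < p < 1.0 for p in positions):
            raise ValueError("all fractional positions must lie in (0, 1)")
        slots = self.barcode_slot_positions
        if any(b <= a for a, b in zip(slots, slots[1:])):
            raise ValueError("slot positions must be strictly increasing")
        site_pos = [p for p, _ in self.overhang_sites]
        if any(b <= a for a, b in zip(site_pos, site_pos[1:])):
            raise ValueError("overhang positions must be strictly increasing")
        if self.concentration_weight < 0:
            raise ValueError("concentration_weight must be >= 0")
        if self.overhang_window is not None and not 0.0 < self.overhang_window < 0.5:
            raise ValueError("overhang_window must lie in (0, 0.5)")

    @property
    def slot_spacing(self) -> float:
        slots = self.barcode_slot_positions
        if len(slots) < 2:
            return 0.5
        return min(b - a for a, b in zip(slots, slots[1:]))

    def window_tolerance(self, slot_tolerance: float = 0.4) -> float:
        """Half-width of barcode slot windows as a fraction of the event."""
        return slot_tolerance * self.slot_spacing

    def overhang_tolerance(self, slot_tolerance: float = 0.4) -> float:
        """Half-width of overhang windows; defaults to the slot window width."""
        if self.overhang_window is not None:
            return self.overhang_window
        return self.window_tolerance(slot_tolerance)

    def overhang_windows(self, slot_tolerance: float = 0.4) -> List[Tuple[float, float]]:
        hw = self.overhang_tolerance(slot_tolerance)
        return [(p, hw) for p, _ in self.overhang_sites]

    def all_window_centers(self) -> List[float]:
        return sorted(
            list(self.barcode_slot_positions) + [p for p, _ in self.overhang_sites]
        )


@dataclass(frozen=True)
class GroundTruthRecord:
    """Per-event ground truth written alongside each simulated trace."""

    index: int
    design: str
    direction: str  # "forward" | "reverse"
    folded: bool
    bound_flags: Tuple[bool, ...]
    knot_fractions: Tuple[float, ...]  # forward-frame fractional positions
    start: int
    end: int
    degenerate: bool = False


def _lowpass(depth: np.ndarray, config: SimConfig) -> np.ndarray:
    """Zero-phase first-order smoothing of pulse edges.

    Forward-backward application keeps the clean profile exactly symmetric
    under time reversal, which the decoder's orientation handling relies on.
    """
    alpha = 1.0 - math.exp(-2.0 * math.pi * config.lowpass_cutoff / config.sampling_rate)
    pad = 8
    padded = np.concatenate((np.zeros(pad), depth, np.zeros(pad)))
    smoothed = signal.filtfilt([alpha], [1.0, alpha - 1.0], padded, padlen=0)
    return smoothed[pad:-pad]


def simulate_event(
    design: NanostructureDesign,
    bound_flags: Sequence[bool],
    direction: str,
    folded: bool,
    config: SimConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, GroundTruthRecord]:
    """Simulate one translocation event; returns absolute current samples.

    The event is a square-pulse blockade of lognormal dwell; every "1"
    barcode slot and every bound overhang adds a spike of extra depth at its
    fractional position; each unbound overhang receives a spurious knot
    spike with probability ``config.knot_rate``, placed uniformly inside
    that site's decoding window; folded events double the base blockade
    over a random leading or trailing 25-45 % stretch.  The whole clean
    profile is mirrored for reverse translocations, low-pass smoothed, and
    Gaussian noise added.  An event too short to resolve adjacent spike
    windows is flagged degenerate in the truth record.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    bound_flags = tuple(bool(b) for b in bound_flags)
    if len(bound_flags) != len(design.overhang_sites):
        raise ValueError("bound_flags length must match the number of overhang sites")

    mu = math.log(config.dwell_mean) - 0.5 * config.dwell_sigma**2
    dwell = rng.lognormal(mean=mu, sigma=config.dwell_sigma)
    n = max(int(round(dwell * config.sampling_rate)), 16)

    centers = design.all_window_centers()
    min_gap = min(
        (b - a for a, b in zip(centers, centers[1:])), default=1.0
    )
    degenerate = n * min_gap < 1.2 * config.spike_width_samples

    spike_fracs = [
        pos
        for pos, bit in zip(design.barcode_slot_positions, design.barcode)
        if bit == "1"
    ]
    spike_fracs += [
        pos for (pos, _), bound in zip(design.overhang_sites, bound_flags) if bound
    ]
    # Knot artifacts mimic a bound protein, so they are placed tightly around
    # the expected spike location (well inside the decoding window and clear
    # of the neighbouring barcode slot's spike).
    tol = design.overhang_tolerance()
    knots = []
    for (pos, _), bound in zip(design.overhang_sites, bound_flags):
        if not bound and rng.random() < config.knot_rate:
            knots.append(pos + rng.uniform(-0.25, 0.25) * tol)
    if folded:
        fold_fraction = rng.uniform(0.25, 0.45)
        fold_leading = rng.random() < 0.5
    # noise drawn last so the clean profile is a pure function of the draws
    depth = np.full(n, config.dsdna_blockade)
    w = config.spike_width_samples
    for f in spike_fracs + knots:
        c = int(round(f * n))
        depth[max(c - w // 2, 0): min(c - w // 2 + w, n)] += config.spike_extra_blockade
    if folded:
        k = int(round(fold_fraction * n))
        if fold_leading:
            depth[:k] += config.dsdna_blockade
        else:
            depth[n - k:] += config.dsdna_blockade
    if direction == "reverse":
        depth = depth[::-1].copy()
    clean = config.baseline_current - _lowpass(depth, config)
    samples = clean + rng.normal(0.0, config.noise_sd, size=n)

    record = GroundTruthRecord(
        index=-1,
        design=design.name,
        direction=direction,
        folded=folded,
        bound_flags=bound_flags,
        knot_fractions=tuple(knots),
        start=0,
        end=n,
        degenerate=degenerate,
    )
    return samples, record


def simulate_trace(
    designs_with_probes: Sequence[Tuple[NanostructureDesign, Optional[GuideProbe]]],
    n_events: int,
    config: SimConfig,
    binding_params: Optional[BindingModelParams] = None,
) -> Tuple[CurrentTrace, List[GroundTruthRecord]]:
    """Simulate a full trace of ``n_events`` translocations plus baseline gaps.

    Designs are drawn multinomially by ``concentration_weight``; for each
    event every overhang site's bound flag is Bernoulli with the probe's
    sequence-model binding probability at that site (zero when no probe is
    paired with the design); direction is Bernoulli(0.5) and fold state
    Bernoulli(``folded_fraction``).  Identical seeds give identical output.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if not designs_with_probes:
        raise ValueError("at least one design is required")
    if binding_params is None:
        binding_params = BindingModelParams()
    designs = [d for d, _ in designs_with_probes]
    weights = np.array([d.concentration_weight for d in designs], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("concentration weights must not all be zero")
    probs = weights / weights.sum()

    site_p: List[List[float]] = []
    for design, probe in designs_with_probes:
        ps = []
        for _, site in design.overhang_sites:
            if probe is None:
                ps.append(0.0)
            else:
                ps.append(
                    binding_probability(mismatch_profile(probe, site), site, binding_params)
                )
        site_p.append(ps)

    rng = np.random.default_rng(config.seed)
    gap_scale = max(
        config.sampling_rate / config.event_rate
        - config.dwell_mean * config.sampling_rate
        - config.min_gap_samples,
        10.0,
    )

    def gap_segment() -> np.ndarray:
        g = config.min_gap_samples + int(rng.exponential(gap_scale))
        return config.baseline_current + rng.normal(0.0, config.noise_sd, size=g)

    segments = [gap_segment()]
    pos = segments[0].size
    truths: List[GroundTruthRecord] = []
    for i in range(n_events):
        di = int(rng.choice(len(designs), p=probs))
        design = designs[di]
        bound = [rng.random() < p for p in site_p[di]]
        direction = "forward" if rng.random() < 0.5 else "reverse"
        folded = rng.random() < config.folded_fraction
        ev_samples, rec = simulate_event(design, bound, direction, folded, config, rng)
        truths.append(
            GroundTruthRecord(
                index=i,
                design=rec.design,
                direction=rec.direction,
                folded=rec.folded,
                bound_flags=rec.bound_flags,
                knot_fractions=rec.knot_fractions,
                start=pos,
                end=pos + ev_samples.size,
                degenerate=rec.degenerate,
            )
        )
        segments.append(ev_samples)
        pos += ev_samples.size
        segments.append(gap_segment())
        pos += segments[-1].size

    trace = CurrentTrace(
        samples=np.concatenate(segments),
        sampling_rate=config.sampling_rate,
        source=f"simulated(seed={config.seed})",
    )
    return trace, truths


# ---------------------------------------------------------------------------
# Canned designs
# ---------------------------------------------------------------------------

#: Arbitrary but fixed 20-nt protospacer used by the canned designs.
DEFAULT_PROTOSPACER = "GCTATCGGTACCAGGCTTCA"
DEFAULT_PAM = "TGG"


def single_site_design(
    name: str,
    barcode: str,
    protospacer: str = DEFAULT_PROTOSPACER,
    pam: str = DEFAULT_PAM,
    site_position: float = 0.08,
    weight: float = 1.0,
) -> NanostructureDesign:
    """A carrier with one overhang site clear of the barcode region."""
    return NanostructureDesign(
        name=name,
        barcode=barcode,
        overhang_sites=((site_position, TargetSite(protospacer, pam)),),
        concentration_weight=weight,
    )


def three_site_design(
    name: str,
    barcode: str,
    sites: Sequence[TargetSite],
    site_positions: Sequence[float] = (0.04, 0.10, 0.90),
    overhang_window: float = 0.025,
    weight: float = 1.0,
) -> NanostructureDesign:
    """A carrier with three overhang sites, as used for positional mismatch scans.

    The default site positions need ~1000-sample events to resolve; pair
    this design with a config whose ``dwell_mean`` is at least 4 ms.  The
    barcode should be non-palindromic so orientation (and hence position
    attribution) is unambiguous; overhang windows are narrower than the
    barcode slot windows because two sites share the PAM-proximal flank.
    """
    if len(sites) != 3:
        raise ValueError("three_site_design requires exactly 3 target sites")
    return NanostructureDesign(
        name=name,
        barcode=barcode,
        overhang_sites=tuple(zip(site_positions, sites)),
        overhang_window=overhang_window,
        concentration_weight=weight,
    )


def matched_single_site_pair(
    barcode_a: str = "11111", barcode_b: str = "11001"
) -> Tuple[NanostructureDesign, NanostructureDesign, GuideProbe]:
    """Two equimolar single-site carriers plus the probe matching both sites."""
    a = single_site_design(barcode_a, barcode_a)
    b = single_site_design(barcode_b, barcode_b)
    probe = matched_probe("matched", a.overhang_sites[0][1])
    return a, b, probe


# ---------------------------------------------------------------------------
# Ground-truth log IO
# ---------------------------------------------------------------------------

def truth_to_dataframe(truths: Sequence[GroundTruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index": [t.index for t in truths],
            "design": [t.design for t in truths],
            "direction": [t.direction for t in truths],
            "folded": [t.folded for t in truths],
            "degenerate": [t.degenerate for t in truths],
            "bound_flags": ["".join("1" if b else "0" for b in t.bound_flags) for t in truths],
            "knot_fractions": [
                ";".join(f"{f:.6f}" for f in t.knot_fractions) for t in truths
            ],
            "start": [t.start for t in truths],
            "end": [t.end for t in truths],
        }
    )


def write_truth(prefix, truths: Sequence[GroundTruthRecord]) -> None:
    """Write the truth log as CSV and JSON next to the trace container."""
    df = truth_to_dataframe(truths)
    df.to_csv(f"{prefix}.csv", index=False)
    with open(f"{prefix}.json", "w") as fh:
        json.dump(df.to_dict(orient="records"), fh, indent=1)


def read_truth(csv_path) -> List[GroundTruthRecord]:
    df = pd.read_csv(csv_path, keep_default_na=False, dtype={"bound_flags": str})
    records = []
    for row in df.to_dict(orient="records"):
        knots = tuple(
            float(x) for x in str(row["knot_fractions"]).split(";") if x not in ("", "nan")
        )
        records.append(
            GroundTruthRecord(
                index=int(row["index"]),
                design=str(row["design"]),
                direction=str(row["direction"]),
                folded=str(row["folded"]).lower() == "true",
                bound_flags=tuple(c == "1" for c in str(row["bound_flags"])),
                knot_fractions=knots,
                start=int(row["start"]),
                end=int(row["end"]),
                degenerate=str(row["degenerate"]).lower() == "true",
            )
        )
    return records
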