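"""Spike calling, barcode assignment and dCas9 bound-state calls.

An unfolded translocation event carries a pattern of short deep spikes on
top of the dsDNA blockade: up to five barcode spikes at fixed fractional
slots ("1" bits) plus one spike per overhang site where a dCas9 RNP is
bound.  Translocation can be in either direction, so the observed pattern
may be the mirror image of the designed one; the decoder resolves
orientation by matching the slot-occupancy vector against the declared
barcode library in both directions.  Spikes that fall in no window are
counted as off-window artifacts.

All positions here are fractions of the event duration in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .event_detect import TranslocationEvent
from .guide_model import ConfigurationError

__all__ = [
    "PeakParams",
    "SpikeCall",
    "DecodedEvent",
    "detect_spikes",
    "assign_barcode",
    "call_dcas9",
    "decode_event",
]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class PeakParams:
    """Spike-finder parameters: threshold, height, distance, prominence.

    ``height`` and ``prominence`` are in pA on the extra-blockade profile
    (depth beyond the dsDNA level); ``min_distance`` is a fraction of the
    event duration; ``threshold`` is the minimum sample-to-neighbour drop
    (rarely needed, default 0).
    """

    threshold: float = 0.0
    height: float = 60.0
    min_distance: float = 0.05
    prominence: float = 40.0
    smooth_samples: int = 7

    def __post_init__(self) -> None:
        for name in ("threshold", "height", "min_distance", "prominence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SpikeCall:
    """One called spike: fractional position within the event, extra depth (pA)."""

    position: float
    depth: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.position <= 1.0:
            raise ValueError("spike position must lie in [0, 1]")


@dataclass(frozen=True)
class DecodedEvent:
    """Decoder output for one event.

    ``bound_flags`` is None when the barcode is unclassified (such events
    are excluded from all downstream counts).
    """

    barcode: str
    orientation: str  # "forward" | "reverse" | "ambiguous"
    bound_flags: Optional[Tuple[bool, ...]]
    off_window_count: int = 0

    @property
    def classified(self) -> bool:
        return self.barcode != UNCLASSIFIED

    @property
    def any_bound(self) -> bool:
        return bool(self.bound_flags) and any(self.bound_flags)


def detect_spikes(
    event: TranslocationEvent,
    params: Optional[PeakParams] = None,
    dsdna_level: Optional[float] = None,
) -> List[SpikeCall]:
    """Call spikes on an unfolded event's extra-blockade profile.

    Local maxima of depth beyond the dsDNA level satisfying the height,
    prominence and minimum-distance constraints; when two candidates
    violate the distance constraint the deeper one wins (tie: earlier
    position), which is the priority rule of topographic peak picking.
    """
    if params is None:
        params = PeakParams()
    depth = event.depth_profile()
    if dsdna_level is None:
        dsdna_level = float(np.median(depth))
    extra = depth - dsdna_level
    if params.smooth_samples > 1:
        extra = ndimage.uniform_filter1d(extra, size=params.smooth_samples)
    n = extra.size
    distance = max(1, int(round(params.min_distance * n)))
    idx, props = find_peaks(
        extra,
        height=params.height,
        prominence=params.prominence,
        distance=distance,
        threshold=params.threshold if params.threshold > 0 else None,
    )
    return [
        SpikeCall(position=i / n, depth=float(extra[i])) for i in sorted(idx)
    ]


def _occupancy(
    positions: Sequence[float],
    slot_positions: Sequence[float],
    tol: float,
) -> str:
    bits = []
    for center in slot_positions:
        bits.append("1" if any(abs(p - center) <= tol for p in positions) else "0")
    return "".join(bits)


def _slot_tol(slot_positions: Sequence[float], slot_tolerance: float) -> float:
    if slot_tolerance >= 0.5:
        raise ConfigurationError(
            "slot_tolerance must be < 0.5: slot windows would overlap"
        )
    if len(slot_positions) < 2:
        return slot_tolerance * 0.5
    spacing = min(b - a for a, b in zip(slot_positions, list(slot_positions)[1:]))
    if spacing <= 0:
        raise ConfigurationError("slot positions must be strictly increasing")
    return slot_tolerance * spacing


def assign_barcode(
    spikes: Sequence[SpikeCall],
    slot_positions: Sequence[float],
    library: Set[str],
    slot_tolerance: float = 0.4,
) -> Tuple[str, str]:
    """Binarize slot occupancy and match it against the barcode library.

    The occupancy vector is compared with every library code in forward
    and reversed orientation.  A unique match fixes (code, orientation); a
    palindromic code matches both ways and yields orientation "ambiguous";
    matches to two different codes, or no match, yield ("unclassified",
    "ambiguous").  Matching is exact: the assay always measures declared
    mixtures.
    """
    if not library:
        raise ConfigurationError("barcode library must not be empty")
    tol = _slot_tol(slot_positions, slot_tolerance)
    occ = _occupancy([s.position for s in spikes], slot_positions, tol)
    forward = sorted(c for c in library if c == occ)
    reverse = sorted(c for c in library if c[::-1] == occ)
    matched = sorted(set(forward) | set(reverse))
    if len(matched) != 1:
        return UNCLASSIFIED, "ambiguous"
    code = matched[0]
    if forward and reverse:
        return code, "ambiguous"
    return code, "forward" if forward else "reverse"


def call_dcas9(
    spikes: Sequence[SpikeCall],
    slot_positions: Sequence[float],
    overhang_windows: Sequence,
    orientation: str,
    slot_tolerance: float = 0.4,
) -> Tuple[Tuple[bool, ...], int]:
    """Per-overhang bound calls plus the off-window artifact count.

    ``overhang_windows`` items are either bare centres (the slot window
    half-width applies) or ``(centre, half_width)`` pairs.  Each spike is
    assigned to at most one window - the nearest centre among barcode slots
    and overhang windows in the oriented frame, ties going to the barcode
    slot - so a spike consumed by a slot can never also mark a site as
    bound.  A site is bound iff at least one unconsumed spike falls inside
    its window (windows mirror under reverse orientation).  For palindromic
    barcodes the orientation is ambiguous; the frame with the fewer
    off-window spikes is used (tie: forward).
    """
    tol = _slot_tol(slot_positions, slot_tolerance)
    sites = [
        (w[0], w[1]) if isinstance(w, (tuple, list)) else (float(w), tol)
        for w in overhang_windows
    ]

    def evaluate(reverse: bool) -> Tuple[Tuple[bool, ...], int]:
        positions = [1.0 - s.position if reverse else s.position for s in spikes]
        centers = [(c, tol, "slot", None) for c in slot_positions] + [
            (c, hw, "site", i) for i, (c, hw) in enumerate(sites)
        ]
        bound = [False] * len(sites)
        off = 0
        for p in positions:
            best = None
            for c, hw, kind, site_idx in centers:
                d = abs(p - c)
                if d > hw:
                    continue
                key = (d, 0 if kind == "slot" else 1)
                if best is None or key < best[0]:
                    best = (key, kind, site_idx)
            if best is None:
                off += 1
            elif best[1] == "site":
                bound[best[2]] = True
        return tuple(bound), off

    if orientation == "forward":
        return evaluate(False)
    if orientation == "reverse":
        return evaluate(True)
    fwd, rev = evaluate(False), evaluate(True)
    return fwd if fwd[1] <= rev[1] else rev


def decode_event(
    event: TranslocationEvent,
    slot_positions: Sequence[float],
    library: Set[str],
    overhang_windows_by_barcode: Dict[str, Sequence],
    params: Optional[PeakParams] = None,
    dsdna_level: Optional[float] = None,
    slot_tolerance: float = 0.4,
) -> DecodedEvent:
    """Full per-event decoding: spikes -> barcode -> bound-state calls."""
    spikes = detect_spikes(event, params=params, dsdna_level=dsdna_level)
    barcode, orientation = assign_barcode(spikes, slot_positions, library, slot_tolerance)
    if barcode == UNCLASSIFIED:
        return DecodedEvent(
            barcode=UNCLASSIFIED,
            orientation=orientation,
            bound_flags=None,
            off_window_count=0,
        )
    windows = overhang_windows_by_barcode.get(barcode, ())
    flags, off = call_dcas9(spikes, slot_positions, windows, orientation, slot_tolerance)
    return DecodedEvent(
        barcode=barcode,
        orientation=orientation,
        bound_flags=flags,
        off_window_count=off,
    )
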