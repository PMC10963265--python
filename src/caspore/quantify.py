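"""Counting statistics for the barcoded dCas9 nanopore assay.

Every quantity reported by the assay reduces to counts of decoded,
unfolded events: N_{b, dCas9} (events with barcode b and at least one
bound-overhang call) and N_{b, No dCas9} (barcode b, no bound call), or
their per-overhang-position analogues for the three-site mismatch-scan
carrier.  This module implements those statistics:

* specificity: the percentage of dCas9-labelled events carrying each
  barcode (the labelled-event percentage),
* relative concentration: the normalized bound percentage of each
  nanostructure in a two-species mixture, in two documented variants,
* position-wise binding fractions, the control efficiency (their mean for
  the matched-target carrier), and the normalized binding ratio of a
  mismatched position relative to that control,
* binding efficiency, the population standard deviation used across
  repeated measurements, and the barcode library size 2**n_bits.

Wilson 95 % confidence intervals are attached to fractions as supporting
output; replicate spread across pores is summarized with the population
(divisor N) standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "EventCounts",
    "QuantResult",
    "pct_dcas9_events",
    "relative_concentration",
    "position_binding_fraction",
    "control_efficiency",
    "normalized_binding_ratio",
    "binding_efficiency",
    "population_sd",
    "barcode_library_size",
    "wilson_interval",
    "counts_from_decoded",
    "summarize",
]


def _check_count(value: int, what: str) -> int:
    iv = int(value)
    if iv != value or iv < 0:
        raise ValueError(f"{what} must be a non-negative integer, got {value!r}")
    return iv


@dataclass
class EventCounts:
    """Tallies of decoded events.

    ``barcode_counts`` maps barcode -> (n_dcas9, n_no_dcas9); for
    positional designs ``position_counts`` maps overhang position index
    (1-based) -> (n_dcas9, n_no_dcas9).
    """

    barcode_counts: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    position_counts: Dict[int, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for b, (nd, nn) in self.barcode_counts.items():
            self.barcode_counts[b] = (
                _check_count(nd, f"N_{b}_dCas9"),
                _check_count(nn, f"N_{b}_NodCas9"),
            )
        for i, (nd, nn) in self.position_counts.items():
            self.position_counts[i] = (
                _check_count(nd, f"N_dCas9_pos_{i}"),
                _check_count(nn, f"N_NodCas9_pos_{i}"),
            )

    def total_events(self, barcode: str) -> int:
        nd, nn = self.barcode_counts[barcode]
        return nd + nn


def pct_dcas9_events(counts: EventCounts) -> Dict[str, float]:
    """Percentage of dCas9-labelled events carrying each barcode.

    %_b = N_{b, dCas9} / sum_b' N_{b', dCas9} * 100; the values sum to 100.
    Defined for any number of barcodes (the two-barcode case is the assay's
    published form).
    """
    labelled = {b: nd for b, (nd, _) in counts.barcode_counts.items()}
    denom = sum(labelled.values())
    if denom == 0:
        raise ValueError("no dCas9-labelled events: percentages undefined")
    return {b: 100.0 * nd / denom for b, nd in labelled.items()}


def relative_concentration(
    counts: EventCounts, mode: str = "efficiency_corrected"
) -> Dict[str, float]:
    """Normalized bound fraction per nanostructure in a two-species mixture.

    ``printed`` evaluates the published form literally: for each barcode,
    X = (labelled fraction of that barcode) * (total events with that
    barcode), then X is normalized over the two species.  Because both
    factors scale with the mixture fraction, this weights each species by
    roughly the square of its abundance (a 1:3 mixture at equal binding
    efficiency yields 10 %:90 %, not 25 %:75 %).

    ``efficiency_corrected`` (default) divides each labelled count by the
    per-barcode efficiency estimate p_b = N_{b,dCas9} / (N_{b,dCas9} +
    N_{b,No dCas9}), which reduces X to the total event count of that
    barcode; under equal efficiencies it recovers the input mixture
    fraction.  Both modes normalize to sum to 1.
    """
    barcodes = list(counts.barcode_counts)
    if mode not in ("printed", "efficiency_corrected"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "printed" and len(barcodes) != 2:
        raise ValueError("printed mode is defined for exactly two barcodes")
    labelled_total = sum(nd for nd, _ in counts.barcode_counts.values())
    if labelled_total == 0:
        raise ValueError("no dCas9-labelled events")
    x: Dict[str, float] = {}
    for b, (nd, nn) in counts.barcode_counts.items():
        if mode == "printed":
            x[b] = (nd / labelled_total) * (nd + nn)
        else:
            if nd == 0:
                raise ValueError(
                    f"barcode {b}: estimated binding efficiency is zero; "
                    "efficiency-corrected concentration undefined"
                )
            p_hat = nd / (nd + nn)
            x[b] = nd / p_hat  # == nd + nn
    total = sum(x.values())
    return {b: v / total for b, v in x.items()}


def position_binding_fraction(counts: EventCounts, position: int) -> float:
    """X_position = N_dCas9 at that overhang / all events scored there."""
    nd, nn = counts.position_counts[position]
    if nd + nn == 0:
        raise ValueError(f"no events scored at position {position}")
    return nd / (nd + nn)


def control_efficiency(control_position_fractions: Sequence[float]) -> float:
    """Mean binding fraction across the control carrier's overhang positions.

    The matched-target carrier presents the same target at three positions;
    their average is the control efficiency every mismatched position is
    normalized against.
    """
    fractions = list(control_position_fractions)
    if not fractions:
        raise ValueError("control fractions must not be empty")
    return float(np.mean(fractions))


def normalized_binding_ratio(x_position: float, x_control: float) -> float:
    """Position binding fraction divided by the matched-target control.

    A probe binding a mismatched position as well as its perfect target has
    ratio 1.0; the ratio may exceed 1.
    """
    if x_control <= 0:
        raise ValueError("control binding fraction must be positive")
    ratio = x_position / x_control
    if ratio < 0:
        raise ValueError("binding fractions must be non-negative")
    return ratio


def binding_efficiency(n_dcas9: int, n_no_dcas9: int) -> float:
    """Percentage of carrier events whose overhang shows a dCas9 spike."""
    nd = _check_count(n_dcas9, "N_dCas9")
    nn = _check_count(n_no_dcas9, "N_NodCas9")
    if nd + nn == 0:
        raise ValueError("binding efficiency undefined for zero events")
    return 100.0 * nd / (nd + nn)


def population_sd(values: Iterable[float]) -> float:
    """Population standard deviation, sqrt(sum((x - mean)^2) / N)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("population SD undefined for zero values")
    return float(np.std(arr, ddof=0))


def barcode_library_size(n_bits: int) -> int:
    """Number of distinct codes for an n-bit barcode, 2**n exactly."""
    n = int(n_bits)
    if n != n_bits or n < 0:
        raise ValueError("n_bits must be a non-negative integer")
    return 1 << n


def wilson_interval(successes: int, total: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Wilson score confidence interval for a binomial fraction."""
    if total <= 0:
        raise ValueError("total must be positive")
    lo, hi = proportion_confint(successes, total, alpha=alpha, method="wilson")
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Assembly from decoded events
# ---------------------------------------------------------------------------

def counts_from_decoded(decoded: pd.DataFrame) -> EventCounts:
    """Tally an :class:`EventCounts` from a decoded-event table.

    Expects the flat CSV schema written by the pipeline: columns
    ``barcode`` and ``bound_flags`` (string of 0/1 per overhang site,
    empty for siteless designs).  Unclassified events are excluded.
    Position counts are tallied per overhang index across all classified
    events that scored that position.
    """
    barcode_counts: Dict[str, List[int]] = {}
    position_counts: Dict[int, List[int]] = {}
    classified = decoded[decoded["barcode"] != "unclassified"]
    for row in classified.to_dict(orient="records"):
        flags = str(row.get("bound_flags", "") or "")
        bound_any = "1" in flags
        tally = barcode_counts.setdefault(str(row["barcode"]), [0, 0])
        tally[0 if bound_any else 1] += 1
        for i, ch in enumerate(flags, start=1):
            ptally = position_counts.setdefault(i, [0, 0])
            ptally[0 if ch == "1" else 1] += 1
    return EventCounts(
        barcode_counts={b: (nd, nn) for b, (nd, nn) in barcode_counts.items()},
        position_counts={i: (nd, nn) for i, (nd, nn) in position_counts.items()},
    )


@dataclass
class QuantResult:
    """All derived statistics for one decoded-event table."""

    counts: EventCounts
    pct_dcas9: Dict[str, float]
    binding_efficiency_pct: Dict[str, float]
    rel_concentration_corrected: Optional[Dict[str, float]]
    rel_concentration_printed: Optional[Dict[str, float]]
    position_fractions: Dict[int, float]
    normalized_ratios: Optional[Dict[int, float]]
    wilson_ci: Dict[str, Tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "counts": {
                "barcodes": {
                    b: {"n_dcas9": nd, "n_no_dcas9": nn}
                    for b, (nd, nn) in self.counts.barcode_counts.items()
                },
                "positions": {
                    str(i): {"n_dcas9": nd, "n_no_dcas9": nn}
                    for i, (nd, nn) in self.counts.position_counts.items()
                },
            },
            "pct_dcas9": self.pct_dcas9,
            "binding_efficiency_pct": self.binding_efficiency_pct,
            "rel_concentration_corrected": self.rel_concentration_corrected,
            "rel_concentration_printed": self.rel_concentration_printed,
            "position_fractions": {str(i): v for i, v in self.position_fractions.items()},
            "normalized_ratios": (
                None
                if self.normalized_ratios is None
                else {str(i): v for i, v in self.normalized_ratios.items()}
            ),
            "wilson_ci": {b: list(ci) for b, ci in self.wilson_ci.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, (nd, nn) in self.counts.barcode_counts.items():
            rows.append(
                {
                    "barcode": b,
                    "n_dcas9": nd,
                    "n_no_dcas9": nn,
                    "pct_dcas9": self.pct_dcas9.get(b),
                    "binding_efficiency_pct": self.binding_efficiency_pct.get(b),
                    "rel_conc_corrected": (self.rel_concentration_corrected or {}).get(b),
                    "rel_conc_printed": (self.rel_concentration_printed or {}).get(b),
                    "wilson_lo": self.wilson_ci[b][0],
                    "wilson_hi": self.wilson_ci[b][1],
                }
            )
        return pd.DataFrame(rows)


def summarize(
    counts: EventCounts,
    control_fraction: Optional[float] = None,
) -> QuantResult:
    """Compute every statistic the counts support; skip the rest gracefully."""
    try:
        pct = pct_dcas9_events(counts)
    except ValueError:
        pct = {}
    eff = {
        b: binding_efficiency(nd, nn) for b, (nd, nn) in counts.barcode_counts.items()
    }
    try:
        corrected = relative_concentration(counts, mode="efficiency_corrected")
    except ValueError:
        corrected = None
    try:
        printed = relative_concentration(counts, mode="printed")
    except ValueError:
        printed = None
    positions = {
        i: position_binding_fraction(counts, i) for i in sorted(counts.position_counts)
    }
    ratios = None
    if control_fraction is not None and control_fraction > 0:
        ratios = {
            i: normalized_binding_ratio(f, control_fraction)
            for i, f in positions.items()
        }
    ci = {
        b: wilson_interval(nd, nd + nn) if nd + nn else (0.0, 1.0)
        for b, (nd, nn) in counts.barcode_counts.items()
    }
    return QuantResult(
        counts=counts,
        pct_dcas9=pct,
        binding_efficiency_pct=eff,
        rel_concentration_corrected=corrected,
        rel_concentration_printed=printed,
        position_fractions=positions,
        normalized_ratios=ratios,
        wilson_ci=ci,
    )
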