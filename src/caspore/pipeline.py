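"""Pipeline orchestration: simulate -> detect -> decode -> quantify.

The stage order mirrors the assay's analysis chain: a translocation finder
segments the raw trace into events; events failing the 15 pA noise filter
or classified folded are discarded; the remaining events are decoded into
(barcode, orientation, per-overhang bound flags); and the decoded table is
reduced to the assay's counting statistics.  A run directory receives the
trace container, ground-truth log, event container, decoded CSV, the
quantification JSON/CSV, a log, and a provenance manifest (config hash +
seed), each written atomically.  Identical config + seed give identical
results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .barcode_decode import DecodedEvent, PeakParams, decode_event
from .event_detect import (
    CurrentTrace,
    TranslocationEvent,
    classify_fold_state,
    estimate_dsdna_level,
    filter_noisy_events,
    find_events,
    write_events_h5,
    write_trace_h5,
)
from .guide_model import (
    BindingModelParams,
    ConfigurationError,
    GuideProbe,
    TargetSite,
)
from .quantify import QuantResult, counts_from_decoded, summarize
from .trace_sim import (
    GroundTruthRecord,
    NanostructureDesign,
    SimConfig,
    simulate_trace,
    write_truth,
)

logger = logging.getLogger("caspore")

__all__ = [
    "DetectorParams",
    "RunConfig",
    "run_pipeline",
    "run_arrays",
    "detect_and_filter",
    "decode_events",
]


@dataclass(frozen=True)
class DetectorParams:
    """Event-finder and quality-filter parameters."""

    threshold_sigma: float = 5.0
    min_duration: float = 2e-4
    max_noise_pA: float = 15.0
    folded_level_factor: float = 1.5
    fold_min_fraction: float = 0.2
    opening_samples: int = 61

    def __post_init__(self) -> None:
        if self.threshold_sigma <= 0 or self.min_duration <= 0:
            raise ValueError("threshold_sigma and min_duration must be positive")
        if self.max_noise_pA <= 0:
            raise ValueError("max_noise_pA must be positive")


def _strict_kwargs(cls, d: dict, what: str) -> dict:
    allowed = {f.name for f in fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ConfigurationError(f"unknown {what} keys: {sorted(unknown)}")
    return d


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    designs: List[NanostructureDesign]
    probes: Dict[str, Optional[GuideProbe]] = field(default_factory=dict)
    sim: SimConfig = field(default_factory=SimConfig)
    detector: DetectorParams = field(default_factory=DetectorParams)
    peaks: PeakParams = field(default_factory=PeakParams)
    binding: BindingModelParams = field(default_factory=BindingModelParams)
    library: Optional[List[str]] = None
    slot_tolerance: float = 0.4
    quantify_mode: str = "efficiency_corrected"
    n_events: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.designs:
            raise ConfigurationError("at least one design is required")
        if self.quantify_mode not in ("printed", "efficiency_corrected"):
            raise ConfigurationError(f"unknown quantify_mode {self.quantify_mode!r}")
        if self.n_events < 0:
            raise ConfigurationError("n_events must be >= 0")
        names = [d.name for d in self.designs]
        if len(set(names)) != len(names):
            raise ConfigurationError("design names must be unique")
        barcodes = [d.barcode for d in self.designs]
        if len(set(barcodes)) != len(barcodes):
            raise ConfigurationError("design barcodes must be unique")
        layouts = {d.barcode_slot_positions for d in self.designs}
        if len(layouts) != 1:
            raise ConfigurationError("all designs must share one slot layout")
        for probe_name in self.probes:
            if probe_name not in names:
                raise ConfigurationError(f"probe mapped to unknown design {probe_name!r}")
        # window geometry: slot and overhang windows must not overlap
        for d in self.designs:
            slot_hw = d.window_tolerance(self.slot_tolerance)
            site_hw = d.overhang_tolerance(self.slot_tolerance)
            windows = sorted(
                [(c, slot_hw) for c in d.barcode_slot_positions]
                + [(p, site_hw) for p, _ in d.overhang_sites]
            )
            for (a, ha), (b, hb) in zip(windows, windows[1:]):
                if b - a < ha + hb:
                    raise ConfigurationError(
                        f"design {d.name!r}: windows at {a:.3f} and {b:.3f} overlap "
                        f"(half-widths {ha:.3f}/{hb:.3f} too large)"
                    )

    @property
    def slot_positions(self) -> Tuple[float, ...]:
        return self.designs[0].barcode_slot_positions

    @property
    def barcode_library(self) -> set:
        if self.library is not None:
            return set(self.library)
        return {d.barcode for d in self.designs}

    def designs_with_probes(self):
        return [(d, self.probes.get(d.name)) for d in self.designs]

    def canonical_dict(self) -> dict:
        def convert(obj):
            if isinstance(obj, (NanostructureDesign, SimConfig, DetectorParams,
                                PeakParams, GuideProbe, TargetSite)):
                return {k: convert(v) for k, v in asdict(obj).items()}
            if isinstance(obj, BindingModelParams):
                d = asdict(obj)
                d["per_position_ratio"] = {
                    f"{p}:{int(w)}": r for (p, w), r in obj.per_position_ratio.items()
                }
                return d
            if isinstance(obj, dict):
                return {str(k): convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "designs": [convert(d) for d in self.designs],
            "probes": {k: convert(v) for k, v in self.probes.items()},
            "sim": convert(self.sim),
            "detector": convert(self.detector),
            "peaks": convert(self.peaks),
            "binding": convert(self.binding),
            "library": sorted(self.barcode_library),
            "slot_tolerance": self.slot_tolerance,
            "quantify_mode": self.quantify_mode,
            "n_events": self.n_events,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    # -- construction from YAML -------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        unknown = set(raw) - {
            "designs", "probes", "sim", "detector", "peaks", "binding",
            "library", "slot_tolerance", "quantify_mode", "n_events", "seed",
        }
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")

        probes_raw = raw.get("probes", [])
        probes_by_name = {}
        for p in probes_raw:
            p = _strict_kwargs(GuideProbe, dict(p), "probe")
            probe = GuideProbe(**p)
            probes_by_name[probe.name] = probe

        designs: List[NanostructureDesign] = []
        probe_map: Dict[str, Optional[GuideProbe]] = {}
        for d in raw.get("designs", []):
            d = dict(d)
            probe_name = d.pop("probe", None)
            overhangs = []
            for site in d.pop("overhangs", []):
                site = dict(site)
                pos = site.pop("position")
                site = _strict_kwargs(TargetSite, site, "overhang site")
                overhangs.append((float(pos), TargetSite(**site)))
            d = _strict_kwargs(NanostructureDesign, d, "design")
            d["overhang_sites"] = tuple(overhangs)
            design = NanostructureDesign(**d)
            designs.append(design)
            if probe_name is not None:
                if probe_name not in probes_by_name:
                    raise ConfigurationError(f"unknown probe name {probe_name!r}")
                probe_map[design.name] = probes_by_name[probe_name]

        sim = SimConfig(**_strict_kwargs(SimConfig, dict(raw.get("sim", {})), "sim"))
        detector = DetectorParams(
            **_strict_kwargs(DetectorParams, dict(raw.get("detector", {})), "detector")
        )
        peak_raw = dict(raw.get("peaks", {}))
        peaks = PeakParams(**_strict_kwargs(PeakParams, peak_raw, "peaks"))
        binding = (
            BindingModelParams.from_dict(raw["binding"])
            if "binding" in raw
            else BindingModelParams()
        )
        cfg = cls(
            designs=designs,
            probes=probe_map,
            sim=sim,
            detector=detector,
            peaks=peaks,
            binding=binding,
            library=raw.get("library"),
            slot_tolerance=float(raw.get("slot_tolerance", 0.4)),
            quantify_mode=raw.get("quantify_mode", "efficiency_corrected"),
            n_events=int(raw.get("n_events", 100)),
            seed=int(raw.get("seed", 0)),
        )
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(raw)

    def with_overrides(
        self,
        seed: Optional[int] = None,
        n_events: Optional[int] = None,
        quantify_mode: Optional[str] = None,
    ) -> "RunConfig":
        cfg = self
        if seed is not None:
            cfg = replace(cfg, sim=replace(cfg.sim, seed=seed), seed=seed)
        if n_events is not None:
            cfg = replace(cfg, n_events=n_events)
        if quantify_mode is not None:
            cfg = replace(cfg, quantify_mode=quantify_mode)
        return cfg


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def detect_and_filter(
    trace: CurrentTrace, detector: DetectorParams
) -> Tuple[List[TranslocationEvent], Dict[str, int]]:
    """Find events and apply the noise and fold filters.

    Returns the unfolded, low-noise events (fold_state set) plus a tally of
    the discard pathways.
    """
    events = find_events(
        trace,
        threshold_sigma=detector.threshold_sigma,
        min_duration=detector.min_duration,
    )
    kept, noisy = filter_noisy_events(events, max_noise_pA=detector.max_noise_pA)
    tally = {"detected": len(events), "noisy_discarded": len(noisy)}
    if not kept:
        tally.update(folded_discarded=0, unfolded=0)
        return [], tally
    ds_level = estimate_dsdna_level(kept)
    unfolded = []
    n_folded = 0
    for ev in kept:
        state = classify_fold_state(
            ev,
            dsdna_level=ds_level,
            folded_level_factor=detector.folded_level_factor,
            min_fraction=detector.fold_min_fraction,
            opening_samples=detector.opening_samples,
        )
        ev = replace(ev, fold_state=state)
        if state == "folded":
            n_folded += 1
        else:
            unfolded.append(ev)
    tally.update(folded_discarded=n_folded, unfolded=len(unfolded))
    return unfolded, tally


def decode_events(
    events: Sequence[TranslocationEvent], config: RunConfig
) -> pd.DataFrame:
    """Decode unfolded events into the flat per-event table."""
    overhangs_by_barcode = {
        d.barcode: d.overhang_windows(config.slot_tolerance) for d in config.designs
    }
    ds_level = estimate_dsdna_level(events) if events else None
    rows = []
    for i, ev in enumerate(events):
        dec = decode_event(
            ev,
            slot_positions=config.slot_positions,
            library=config.barcode_library,
            overhang_windows_by_barcode=overhangs_by_barcode,
            params=config.peaks,
            dsdna_level=ds_level,
            slot_tolerance=config.slot_tolerance,
        )
        rows.append(
            {
                "event_id": i,
                "start": ev.start,
                "end": ev.end,
                "noise_pA": ev.noise_pA,
                "barcode": dec.barcode,
                "orientation": dec.orientation,
                "bound_flags": (
                    "".join("1" if b else "0" for b in dec.bound_flags)
                    if dec.bound_flags is not None
                    else ""
                ),
                "off_window_count": dec.off_window_count,
            }
        )
    columns = [
        "event_id", "start", "end", "noise_pA", "barcode", "orientation",
        "bound_flags", "off_window_count",
    ]
    return pd.DataFrame(rows, columns=columns)


def run_arrays(config: RunConfig):
    """End-to-end run without file IO.

    Returns a dict with the trace, ground truth, filtered events, decoded
    table, counts, quantification result and stage tallies.
    """
    trace, truths = simulate_trace(
        config.designs_with_probes(),
        config.n_events,
        config.sim,
        binding_params=config.binding,
    )
    events, tally = detect_and_filter(trace, config.detector)
    decoded = decode_events(events, config)
    counts = counts_from_decoded(decoded)
    quant = summarize(counts)
    n_classified = int((decoded["barcode"] != "unclassified").sum()) if len(decoded) else 0
    tally["classified"] = n_classified
    tally["unclassified"] = len(decoded) - n_classified
    return {
        "trace": trace,
        "truths": truths,
        "events": events,
        "decoded": decoded,
        "counts": counts,
        "quant": quant,
        "tally": tally,
    }


def _atomic_write(path: Path, writer) -> None:
    tmp_fd, tmp_name = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    os.close(tmp_fd)
    try:
        writer(tmp_name)
        os.replace(tmp_name, path)
    except BaseException:
        if os.path.exists(tmp_name):
            os.unlink(tmp_name)
        raise


def run_pipeline(config: RunConfig, out_dir) -> Dict:
    """Run every stage and write all artifacts into ``out_dir``.

    Any stage failure aborts with the stage name; artifacts already written
    remain in place.  Returns the run summary (event yields + paths).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "simulate"
    try:
        logger.info("stage=simulate n_events=%d seed=%d", config.n_events, config.seed)
        trace, truths = simulate_trace(
            config.designs_with_probes(),
            config.n_events,
            config.sim,
            binding_params=config.binding,
        )
        _atomic_write(out / "trace.h5", lambda p: write_trace_h5(p, trace, config.seed))
        write_truth(out / "truth", truths)

        stage = "detect"
        events, tally = detect_and_filter(trace, config.detector)
        logger.info(
            "stage=detect detected=%d noisy_discarded=%d folded_discarded=%d unfolded=%d",
            tally["detected"], tally["noisy_discarded"],
            tally["folded_discarded"], tally["unfolded"],
        )
        _atomic_write(out / "events.h5", lambda p: write_events_h5(p, events))

        stage = "decode"
        decoded = decode_events(events, config)
        n_classified = int((decoded["barcode"] != "unclassified").sum()) if len(decoded) else 0
        tally["classified"] = n_classified
        tally["unclassified"] = len(decoded) - n_classified
        logger.info(
            "stage=decode classified=%d unclassified=%d",
            n_classified, tally["unclassified"],
        )
        _atomic_write(out / "decoded.csv", lambda p: decoded.to_csv(p, index=False))

        stage = "quantify"
        counts = counts_from_decoded(decoded)
        quant = summarize(counts)
        _atomic_write(out / "quant.json", lambda p: quant.to_json(p))
        _atomic_write(
            out / "quant.csv", lambda p: quant.to_frame().to_csv(p, index=False)
        )

        manifest = {
            "package": "caspore",
            "version": __version__,
            "seed": config.seed,
            "config_sha256": config.config_hash(),
            "n_events": config.n_events,
            "yields": tally,
        }
        _atomic_write(
            out / "manifest.json",
            lambda p: Path(p).write_text(json.dumps(manifest, indent=1)),
        )
        logger.info("run complete: %s", json.dumps(tally))
        return {"out_dir": str(out), "yields": tally, "quant": quant, "manifest": manifest}
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
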