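# Methods

This note documents the models, conventions and numerical choices behind
`caspore`, in the spirit of a simulator/analysis package's model
documentation: what is being emulated, which knobs matter, and what passing
tests do and do not demonstrate about real recordings.

## Guide–target binding model

dCas9 RNP engagement is modelled at the sequence level only. A target is a
20-bp protospacer plus a 3-nt PAM; engagement requires the PAM to match
N-G-G (a non-PAM target binds with `no_pam_probability`, default 0). The
spacer–protospacer comparison uses PAM-proximal numbering: position 1 is
the base adjacent to the PAM, increasing distally; a position matches when
the spacer base equals the transcript equivalent of the protospacer base
(A–A, C–C, G–G, U–T). Mismatches are classified as wobble when the
(guide base, opposing DNA base) pair is one of rG-dT, rU-dG, rA-dC, rC-dA —
four of the sixteen ordered RNA–DNA pairs. Wobble classification is
position-independent; position dependence lives entirely in the multiplier
table.

Binding probability is multiplicative:

    p = baseline_efficiency × Π ratio(position, wobble?)   (clamped to [0,1])

with `baseline_efficiency = 0.337` by default, the binding efficiency of a
perfectly matched probe under the high-salt measurement buffer used for
multi-overhang carriers. The per-position ratios ship in
`caspore/data/binding_defaults.yaml` as **illustrative band values** — seed
(positions 1–12) non-wobble 0.1, seed wobble 0.6, distal 0.9 — expressing
the qualitative ordering (seed mismatches largely abolish binding, wobble
pairs are better tolerated, distal mismatches mild). They are deliberately
not presented as measured constants: mismatch tolerance is guide-intrinsic
and varies strongly between probes, which is precisely what the assay
exists to measure. A mismatch whose position/wobble key has no table entry
is a configuration error, never a silent default. The seed boundary
defaults to 12 (the upper end of the 8–12 nt seed description) and is
configurable. PAM scanning reports every NGG offset on the given strand,
5′→3′, overlapping matches included; reverse-complement scanning is the
caller's responsibility because overhang constructs are short, oriented
sequences.

An open convention: whether a "wobble" mispair is defined against the
strand the guide pairs with or the displaced strand is ambiguous in common
usage; this package adopts guide-base-versus-paired-DNA-base and applies it
consistently.

## Trace simulator

The generator reproduces the *phenomenology* of the measurement, not its
electrokinetics. Defaults (all in `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| `sampling_rate` | 250 kHz | recording bandwidth |
| `lowpass_cutoff` | 50 kHz | zero-phase first-order edge smoothing |
| `baseline_current` | 10 000 pA | open-pore level |
| `noise_sd` | 6 pA | Gaussian, white, added after smoothing |
| `dsdna_blockade` | 120 pA | square-pulse depth of the bare carrier |
| `spike_extra_blockade` | 120 pA | additional depth of a spike |
| `spike_width_samples` | 40 (~160 µs) | chosen so 5 slots resolve in a default dwell |
| `dwell_mean`, `dwell_sigma` | 2 ms, 0.2 | lognormal dwell (no distribution is prescribed by the assay; lognormal is the conventional heavy-tailed choice) |
| `event_rate` | 100 /s | sets exponential baseline gaps between events |
| `folded_fraction` | 0.7 | fraction of partially folded carriers |
| `knot_rate` | 0.045 | per-unbound-overhang spurious-spike probability |

Amplitudes and dwell are placeholders on the right scales — the published
traces are graphical only — and every downstream statistic is count-based,
so their exact values are immaterial as long as SNR is realistic
(120 pA / 6 pA here). Blockades are negative deflections from a positive
baseline, the usual convention for LiCl solid-state recordings; the
analysis is magnitude-only so polarity is cosmetic.

Geometry: barcode slots default to five positions symmetric about the
carrier midpoint (0.2 … 0.8), so the slot window set maps onto itself under
direction reversal — this is what lets a single occupancy vector be matched
forward and reversed. Overhang sites sit outside the slot region (default
single-site design: fraction 0.08). The three-site positional-scan carrier
places sites at 0.04/0.10/0.90 with narrower windows (half-width 0.025) and
needs ~4 ms dwells to resolve the two PAM-side sites; it should carry a
non-palindromic barcode so orientation, and hence position attribution, is
unambiguous.

Per event: the design is drawn multinomially by concentration weight; each
overhang's bound flag is Bernoulli with the sequence-model probability of
its paired probe (0 with no probe); direction is Bernoulli(½); folded
events double the base blockade over a uniform 25–45 % leading or trailing
stretch. Unbound overhangs contribute **no** deflection (a bare 50-bp
overhang is below the detection limit); with probability `knot_rate` they
instead receive a knot spike, placed tightly around the expected spike
position (uniform within ±¼ of the decoding-window half-width) because the
artifact's defining property is that it is indistinguishable from a bound
protein. Reverse events are generated by mirroring the whole clean profile,
and the low-pass emulation is applied forward–backward (zero phase), so
mirror symmetry is exact before noise. Events too short to resolve adjacent
windows are flagged `degenerate` in the ground-truth log. All randomness
flows from one `numpy` Generator seeded from the config: identical seeds
give byte-identical traces.

What the simulator does **not** emulate: capture-rate and pore-size
physics, salt-dependent binding efficiency, baseline drift or 1/f noise,
multi-level fold geometries, real Bessel-filter phase response, and
instrument artifacts beyond the knot channel. Passing tests therefore
demonstrate correctness of the *analysis chain* under the stated signal
model, not robustness to every failure mode of a physical pore.

## Event detection and quality filters

Baseline: the open-pore level is fitted by iterated median/MAD on samples
within 4σ of the current level, starting from the 75th percentile (the
baseline is the top level; blockades only deepen). The method assumes
translocations are sparse: if the fitted mode holds less than half the
trace, or a non-trivial mass of samples lies *above* it, the baseline is
declared not estimable. A trace consisting of one constant level is
indistinguishable from pure baseline and is reported as such — a
documented limitation, irrelevant for traces with gaps between events.

Events are maximal runs deflecting more than `threshold_sigma` (default 5)
baseline SDs below the level, extended outward to the 1σ re-crossing,
merged if they touch, and kept above `min_duration` (default 200 µs).
Intervals are half-open `[start, end)` in 0-based sample indices
everywhere. 5σ with boundary refinement is standard resistive-pulse
practice; no specific threshold is prescribed by the assay description.

Noise filter: events with within-event noise above 15 pA are discarded
before decoding. "Noise" is implemented as a robust scale of the
first-difference of the depth profile (1.4826·median|Δ|/√2), which is
consistent for the per-sample SD of white noise while being insensitive to
the event's internal level structure. A residual-about-fitted-levels
definition was considered and rejected: spikes and folds sit 120 pA off any
two-level fit and would dominate the residual, so heavily folded events
would be discarded as "noisy" rather than classified folded, corrupting
the yield accounting. On synthetic data the noise is white by
construction; on filtered real data this estimator reads the
high-frequency noise floor.

Fold classifier (replacing manual by-eye curation with a deterministic
rule): an event is folded when more than `min_fraction` (0.2) of its
*opened* depth profile exceeds `folded_level_factor` (1.5) × the dsDNA
level. The grey morphological opening (running min then max over
`opening_samples` = 61) removes any excursion narrower than the window —
spikes, however densely packed — while leaving sustained fold plateaus
(≥ 125 samples at default geometry) at full width. A plain
fraction-of-deep-samples rule fails here: a fully barcoded unfolded event
has ~48 % of its samples at spike depth and would always be misclassified.
A median filter also fails, because windows spanning *two* adjacent barcode
spikes see a deep majority and hallucinate a plateau; the opening's
running-minimum is immune to spike spacing. The dsDNA level itself is
calibrated from the events as the median across events of the per-event
25th-percentile depth — a lower quantile, because in a folded fully
barcoded event the doubled-plus-spike samples can be the majority, which
breaks a median-of-medians.

## Decoding

Spike calling runs `scipy.signal.find_peaks` (height 60 pA, prominence
40 pA, minimum distance 5 % of the event, after a 7-sample moving average)
on the extra-blockade profile (depth beyond the dsDNA level); within a
violating pair the deeper peak wins, which is `find_peaks`' own priority
rule. Slot occupancy uses fixed fractional windows, slot centre ± 40 % of
the inter-slot spacing; fractional-position normalization over the full
event is the adopted convention for locating the barcode region in events
of variable dwell. The occupancy vector is matched *exactly* against the
declared barcode library, forward and reversed — the assay always measures
known mixtures, so fuzzy matching is out of scope. A palindromic code
yields orientation "ambiguous"; occupancies matching different codes in
the two orientations, or no code, are "unclassified" and excluded from all
counts (mirroring the exclusion of unclear events from analysis).

Bound-state calling assigns each spike to at most one window — nearest
centre among slots and overhang windows in the oriented frame, ties to the
slot — so a barcode spike can never double as a binding call. A site is
bound iff an unconsumed spike lands in its window; windows mirror under
reverse orientation, and for ambiguous orientation the frame with fewer
off-window spikes is used (tie: forward). Off-window spikes are counted as
artifact indicators per event.

## Quantification

All statistics are implemented exactly as printed, on counts of classified
unfolded events, plus Wilson 95 % intervals as supporting output. One
genuine discrepancy is documented rather than resolved: the literal
relative-concentration formulas multiply the labelled *fraction* of a
barcode by the *total* event count of that same barcode, weighting each
species by roughly the square of its abundance — a 25:75 mixture at equal
efficiencies evaluates to 10:90, while the accompanying text describes
recovering "close to 25 % / 75 %", which is the labelled-event fraction.
Both computations are provided: `printed` (the literal form) and
`efficiency_corrected` (default; divides the labelled count by the
per-barcode efficiency estimate, reducing to the total event count of the
species, which recovers the input fraction under equal efficiencies).
Neither guesses intent; the labelled-event *percentage* (the specificity
statistic) is what the mixture-recovery targets report. The no-PAM-control
false-positive fraction is interpreted per-structure (bound events of that
structure over all its events), matching the knot-rate recovery property.

Multi-barcode generalizations (denominator = all labelled events) are
provided; the published forms are the two-barcode special case. The
barcode library size is computed in exact integer arithmetic (2^56 must
not round through a float).

## Problem sizes and determinism

The acceptance script simulates 5000 events per scenario (two scenarios),
matching the scale at which the headline percentages were defined; the
statistical property tests use 2000 events per condition, and
detection-accuracy tests 500–1000. At the default event rate this is ~15 M
samples per 5000-event trace, a few seconds end to end. Every stochastic
test is seeded; the acceptance script derives independent sub-seeds from
its `--seed` via `numpy.random.SeedSequence`. Tolerances on stochastic
checks are 3 binomial standard errors computed from the realized count of
classified (or labelled) events — the quantity's actual sampling unit —
never from the raw event count.

## Known limitations

- The binding model is probabilistic per event with no kinetics: no
  dwell-time dependence, no salt or temperature dependence, no
  cleavage-versus-binding distinction.
- The fold classifier assumes folds double the blockade; exotic fold
  geometries (multiple overlaps, mid-event folds shorter than the opening
  window) are out of scope.
- Degenerate (too-short) events are flagged in truth logs but still
  decoded if they pass the filters; at default geometry they are rare
  (<1 %).
- TDMS import is an optional hook requiring the `nptdms` package; the
  native containers are HDF5/CSV/JSON.
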