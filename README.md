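# caspore

Simulation and analysis of barcoded DNA-carrier nanopore assays for dCas9
binding: single-nucleotide specificity, relative target concentration, and
position-resolved mismatch tolerance of CRISPR guide probes.

## The assay

A long DNA carrier translocating a solid-state nanopore produces a transient
ionic-current blockade. The carrier is patterned with five equally spaced
dumbbell-hairpin groups, each present ("1") or absent ("0"), which appear as
short deep spikes riding on the dsDNA blockade — a 5-bit barcode (2^5 = 32
codes) identifying the nanostructure. The carrier also presents short dsDNA
overhangs bearing a 20-bp protospacer next to an NGG PAM. A catalytically
dead Cas9 ribonucleoprotein (dCas9 RNP) programmed with a matching crRNA
binds the overhang; only a *bound* overhang is heavy enough to produce a
spike, so the presence of a spike at the expected position reads out binding
at the single-molecule level. Translocations occur in either direction
(mirrored spike patterns), ~70 % of carriers translocate partially folded
(excluded from decoding), and occasional DNA knots produce spurious spikes
that mimic a bound protein (the assay's false-positive channel).

Counting decoded events gives the assay's statistics. With
N<sub>b,dCas9</sub> the number of events with barcode *b* and a dCas9 spike:

- **Specificity** — labelled-event percentage per barcode:
  %dCas9<sub>b</sub> = N<sub>b,dCas9</sub> / Σ<sub>b′</sub> N<sub>b′,dCas9</sub> × 100.
- **Relative concentration** — normalized bound fraction per species,
  X / (X + Y), where X multiplies the labelled fraction by the total event
  count of that barcode (the literal published form, `printed` mode) or
  divides the labelled count by the per-barcode efficiency estimate
  (`efficiency_corrected` mode, the default — under equal efficiencies it
  returns the input mixture fraction; see `docs/methods.md`).
- **Binding efficiency** — N<sub>dCas9</sub> / (N<sub>dCas9</sub> +
  N<sub>No dCas9</sub>) × 100 per overhang.
- **Normalized binding ratio** — X<sub>position i</sub> / X<sub>control</sub>,
  the position binding fraction over the matched-target control efficiency
  (a matched probe binding at the control efficiency has ratio 1.0).
- Replicate spread uses the population SD, √(Σ(x − x̄)² / N).

The package implements the whole chain: a sequence-level guide–target
binding model (PAM scan, per-position mismatch profile, wobble
classification, configurable multiplicative binding probabilities), a
seeded trace simulator with ground-truth logs, a translocation-event finder
with the 15 pA noise filter and an automated fold classifier, a barcode /
bound-state decoder with orientation handling, and the counting statistics
above.

## Worked example

Two equimolar carriers (barcodes 11111 and 11001) present targets differing
by a single base; one probe matches the 11111 target (binding probability
0.80), the mismatched carrier sees no true binding, and knots fire at 4.5 %
per unbound overhang:

```python
from caspore import BindingModelParams, SimConfig, matched_probe
from caspore.pipeline import RunConfig, run_arrays
from caspore.trace_sim import single_site_design

d1 = single_site_design("matched", "11111", weight=1.0)
d2 = single_site_design("mismatched", "11001", weight=1.0)
probe = matched_probe("probe", d1.overhang_sites[0][1])
cfg = RunConfig(
    designs=[d1, d2],
    probes={"matched": probe},
    sim=SimConfig(seed=1, knot_rate=0.045),
    binding=BindingModelParams(baseline_efficiency=0.8),
    n_events=1000,
)
res = run_arrays(cfg)
print("yields:", res["tally"])
q = res["quant"]
for b, v in sorted(q.pct_dcas9.items()):
    print(f"% dCas9 events [{b}]: {v:.1f}")
for b, v in sorted(q.binding_efficiency_pct.items()):
    print(f"binding efficiency [{b}]: {v:.1f}%")
```

prints

```
yields: {'detected': 1000, 'noisy_discarded': 0, 'folded_discarded': 700, 'unfolded': 300, 'classified': 298, 'unclassified': 2}
% dCas9 events [11001]: 5.4
% dCas9 events [11111]: 94.6
binding efficiency [11001]: 3.4%
binding efficiency [11111]: 85.5%
```

Of 1000 simulated translocations, 700 folded carriers are excluded and 298
of the 300 unfolded events decode to a clean barcode. 94.6 % of
dCas9-labelled events carry the matched barcode — single-base specificity —
while the 5.4 % / 3.4 % on the mismatched carrier is the knot-artifact
false-positive floor, not true binding. The matched carrier's measured
binding efficiency (85.5 %) is the configured 80 % plus the same artifact
channel acting on its unbound fraction.

The same pipeline is available from the shell:

```
caspore run --config config.yaml --out runs/demo --seed 1
caspore simulate | detect | decode | quantify   # individual stages
```

(see `tests/test_pipeline.py::config_dict` for the YAML schema).

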