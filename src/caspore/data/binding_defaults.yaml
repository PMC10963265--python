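# Default binding-model parameters for dCas9 probe simulations.
#
# baseline_efficiency is the binding efficiency of a perfectly matched
# probe under high-salt nanopore measurement conditions (0.337).  The
# band_ratios are ILLUSTRATIVE placeholders expressing the qualitative
# seed/distal and wobble/non-wobble ordering of mismatch tolerance; they
# are user configuration, not measured constants, because mismatch
# tolerance is guide-intrinsic and varies between probes.
baseline_efficiency: 0.337
no_pam_probability: 0.0
seed_boundary: 12
band_ratios:
  seed:
    non_wobble: 0.1
    wobble: 0.6
  distal:
    non_wobble: 0.9
    wobble: 0.9
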