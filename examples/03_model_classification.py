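"""Detecting an injected folding-strength signal and classifying it.

Injects the canonical profile shape into a synthetic genome purely by
rearranging synonymous codons — weaker folding at both CDS ends,
stronger folding mid-CDS — then recomputes ΔLFE and evaluates the
formal Model 1 / Model 2 element rules.
"""

from codonfold import classify_model1, classify_model2, species_mean_dlfe
from codonfold.synthetic_data import (BiasRegion, SimulationConfig,
                                      generate_genome, inject_folding_bias)

cfg = SimulationConfig(n_cds=30, cds_length=450, target_gc=0.5, seed=5)
genome = generate_genome(cfg, "biased_species", seed=5)
genome = inject_folding_bias(genome, [
    BiasRegion("start", 0, 50, "weaker", 250),
    BiasRegion("start", 110, 340, "stronger", 600),
    BiasRegion("end", 0, 50, "weaker", 250),
], seed=6)

res_start = species_mean_dlfe(genome, n_randomizations=10, anchor="start",
                              seed=7)
res_end = species_mean_dlfe(genome, n_randomizations=10, anchor="end", seed=7)

for name, cls in (("Model 1 (positive ends)",
                   classify_model1(res_start, res_end)),
                  ("Model 2 (weak ends)",
                   classify_model2(res_start, res_end))):
    print(name)
    for element, ok in cls.elements.items():
        print(f"  {element:12s} {'PASS' if ok else 'fail'}")
    print(f"  peak position i* = {cls.peak_position} nt\n")

print("Element E (= A and C and D) passing means the species conforms to")
print("the model: ends folding weaker than expected, mid-CDS stronger —")
print("detected from codon arrangement alone, since the injection changed")
print("no codon frequencies, GC or protein.")
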