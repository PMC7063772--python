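"""Codon-usage bias, the weak-profile rule, and non-linear dependence.

Computes ENc and composition-corrected ENc' on generated genomes,
then runs the four-trait weak-ΔLFE classifier and the maximal
information coefficient on a trait-linked profile cohort.
"""

import numpy as np

from codonfold import (enc, enc_prime, gc_content, mic_statistic,
                       weak_dlfe_classifier)
from codonfold.synthetic_data import (SimulationConfig, generate_genome,
                                      simulate_profile_cohort)

for cub, label in ((0.0, "uniform synonymous usage"),
                   (0.8, "strong codon-usage bias")):
    cfg = SimulationConfig(n_cds=50, cds_length=300, target_gc=0.5,
                           cub_strength=cub, seed=5)
    g = generate_genome(cfg, "sp", seed=5)
    print(f"{label:28s} GC {gc_content(g):5.1f}%  "
          f"ENc {enc(g):5.2f}  ENc' {enc_prime(g):5.2f}")

tree, traits, mat_start, _ = simulate_profile_cohort(n_species=60, seed=8)
out = weak_dlfe_classifier(mat_start, traits)
print(f"\nweak-profile classifier on {len(out.table)} species: "
      f"precision {out.precision:.2f}, recall {out.recall:.2f}")
print("(rule: endosymbiont, or GC < 38%, or ENc' > 56.5, or T_opt > 58 °C;"
      "\n label: std of the 31-position ΔLFE vector < 0.14)")

# a relation MIC sees but linear R² does not: mid-CDS ΔLFE diverging
# into strong-positive and strong-negative branches at high GC
rng = np.random.default_rng(9)
gc = rng.uniform(40, 70, 200)
sign = np.where(rng.random(200) < 0.5, 1.0, -1.0)
dlfe_mid = sign * 0.02 * (gc - 40) + rng.normal(0, 0.03, 200)
r2 = np.corrcoef(gc, dlfe_mid)[0, 1] ** 2
print(f"\ndiverging-branch relation: linear R² = {r2:.3f}, "
      f"MIC = {mic_statistic(gc, dlfe_mid):.2f}")
print("MIC detects strong statistical dependence where regression sees none.")
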