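"""Species-mean ΔLFE profile under the CDS-wide null model.

Generates a small codon-sampled genome, compares each native CDS
against 20 synonymous permutations of itself, and prints the mean
ΔLFE and Wilcoxon p per window position.  Without injected bias the
profile hovers around zero: the native codon arrangement folds no
differently than random synonymous arrangements.
"""

from codonfold import species_mean_dlfe
from codonfold.synthetic_data import SimulationConfig, generate_genome

cfg = SimulationConfig(n_cds=40, cds_length=300, target_gc=0.5, seed=1)
genome = generate_genome(cfg, "demo_species", seed=1)

res = species_mean_dlfe(genome, null_model="cds_wide", n_randomizations=20,
                        anchor="start", seed=2)
table = res.to_frame().dropna()
print(table.to_string(index=False, float_format=lambda v: f"{v:8.4f}"))

n_sig = int((table.p_value < 0.05).sum())
print(f"\nmean ΔLFE hovers near 0; {n_sig}/{len(table)} positions reach "
      "nominal p < 0.05.")
print("Note: the canonical test pools all 20 replicate differences per CDS,")
print("which are dependent, so a few nominally significant positions are")
print("expected even without any signal; type-I calibration is exact with")
print("n_randomizations=1 (or aggregate='per_cds').")
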