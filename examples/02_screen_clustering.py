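"""Cluster an all-by-all fitness screen into fitness classes.

Simulates the 8x8 screen of reconstructed genotypes (64 wells, well-level
noise calibrated so null competitions have SD 0.0017), fits every well,
assembles the genotype x genotype selection-coefficient matrix, and
clusters it with pairwise-complete Euclidean distance and average linkage.
Three fitness plateaus emerge: wild-type-like, mildly deleterious
(mad3-null-like, s ~ -0.015) and strongly deleterious (bub1-null-like,
censored at s < -0.3).
"""

from dupfit import SimCompetitionConfig, calibrated_bio_sd, cluster_fitness_classes
from dupfit import presets, simulate
from dupfit.pipeline import fit_screen, s_matrix

genos = presets.reconstructed_genotypes()
design = simulate.ScreenDesign.all_by_all([g.label for g in genos])
counts = simulate.simulate_screen(
    design,
    presets.class_assignment(genos),
    SimCompetitionConfig(bio_sd=calibrated_bio_sd(), seed=1),
)
estimates = fit_screen(counts)
print(estimates["status"].value_counts().to_dict())

matrix = s_matrix(estimates)
result = cluster_fitness_classes(matrix, wildtype=presets.EXTANT_LABEL)
print(f"{result.n_classes} fitness classes")
for cl, mean in result.class_mean_s.items():
    members = sorted(result.labels.index[result.labels == cl])
    print(f"  class {cl}: mean s vs wild-type = {mean:+.4f}  {members}")
# censored wells enter the matrix at the -0.3 bound, so the strongly
# deleterious class reports a mean of about -0.3
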