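"""Enumerate neutral evolutionary paths across the genotype landscape.

Builds the single-mutational-step graph over the reconstructed genotypes
(duplication, single element losses, gene losses; reversions excluded),
classifies every edge from fluorophore-swapped replicate contrasts of a
simulated screen, then asks: can the extant-like paralog pair be reached
from the single-copy ancestor without crossing a detectable fitness
defect, and is it an absorbing state?
"""

from dupfit import SimCompetitionConfig, calibrated_bio_sd
from dupfit import presets, simulate
from dupfit.landscape import build_landscape, classify_edges, find_neutral_paths, is_absorbing
from dupfit.pipeline import estimates_map, fit_screen

genos = presets.reconstructed_genotypes()
counts = simulate.simulate_screen(
    simulate.ScreenDesign.all_by_all([g.label for g in genos]),
    presets.class_assignment(genos),
    SimCompetitionConfig(bio_sd=calibrated_bio_sd(), seed=2),
)
scape = build_landscape(genos)
classify_edges(scape, estimates_map(fit_screen(counts)), reference=presets.EXTANT_LABEL)

print(scape.edges_frame().to_string(index=False))

paths = find_neutral_paths(scape, presets.SOURCE_LABEL, presets.EXTANT_LABEL)
for p in paths:
    print(" -> ".join(p.nodes))
    print(f"   events: {p.events} ({p.degenerations} degenerations)")
print("extant pair absorbing:", is_absorbing(scape, presets.EXTANT_LABEL))
# a neutral path with >= 3 degenerations plus an absorbing end state is the
# duplication-degeneration-complementation signature: no step needs to be
# adaptive, and the end state cannot be left without a fitness cost
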