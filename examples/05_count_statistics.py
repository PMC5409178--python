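"""Exact statistics for colony sectoring and localization scoring.

Runs the hypergeometric-enumeration Fisher test on the reference
chromosome-loss counts (sectored vs white colonies per genotype), then
bootstrap confidence intervals and Holm-corrected pairwise tests on
synthetic localization scores.
"""

from dupfit.stats import (
    LocalizationCounts,
    SectoringTable,
    bootstrap_fraction_ci,
    pairwise_fisher_corrected,
    sectoring_summary,
)

tables = [
    SectoringTable("WT", 3, 131),
    SectoringTable("bub1_delta", 29, 65),
    SectoringTable("mad3_delta", 5, 177),
    SectoringTable("scp_rescue", 3, 207),
]
summary = sectoring_summary(tables, reference="WT")
print(summary.to_string(index=False))
# only the strain lacking the kinase-carrying gene is starred (p < 0.001):
# the single-copy rescue is indistinguishable from wild type

strains = [
    LocalizationCounts("Bub1-GFP", nucleus_only=8, puncta_only=70, both=22, discarded=26),
    LocalizationCounts("Mad3-GFP", nucleus_only=88, puncta_only=2, both=10, discarded=7),
    LocalizationCounts("SCP-GFP", nucleus_only=45, puncta_only=5, both=50, discarded=11),
]
for s in strains:
    for cat in ("nucleus", "puncta"):
        frac, (lo, hi) = bootstrap_fraction_ci(s, cat, n_boot=2000, seed=0)
        print(f"{s.strain:9s} {cat:7s} fraction {frac:.2f}  95% CI [{lo:.2f}, {hi:.2f}]")

print(pairwise_fisher_corrected(strains, "puncta").to_string(index=False))
# cells scored "both" count toward the nucleus AND the puncta fractions
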