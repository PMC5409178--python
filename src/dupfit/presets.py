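"""Reconstructed spindle-checkpoint genotype set and its synthetic truth.

The genotype compositions here are a *reconstruction* consistent with the
reported schematic of assayed evolutionary intermediates, not a curated
table: the single-copy protein (SCP) carries every functional element; the
duplication copies it to the MAD3 locus under the MAD3 promoter; stepwise
element losses then partition the elements into an extant-like Bub1 allele
(no first KEN box, no first ABBA motif) and an extant-like Mad3 allele (no
kinase domain, no Mad1-binding region); gene losses from the extant-like
pair give the bub1-null-like and mad3-null-like exits.

The synthetic fitness truth used by the generator encodes the two pathway
functions the assay is sensitive to: kinase-dependent function requires a
KINASE domain at some locus; APC-inhibitor function requires a first KEN
box at some locus. Losing the former is strongly deleterious
(bub1-null-like, s = -0.35, beyond the -0.3 censoring bound), losing the
latter mildly deleterious (mad3-null-like, s = -0.015); genotypes keeping
both are wild-type-like (s = 0).
"""

from __future__ import annotations

from typing import Mapping

from .landscape import ELEMENT_UNIVERSE, AlleleSpec, GenotypeSpec

__all__ = [
    "CLASS_FITNESS",
    "scp_allele",
    "reconstructed_genotypes",
    "true_fitness_class",
    "class_assignment",
    "SOURCE_LABEL",
    "EXTANT_LABEL",
]

CLASS_FITNESS: Mapping[str, float] = {
    "wt_like": 0.0,
    "mad3_like": -0.015,
    "bub1_like": -0.35,
}

SOURCE_LABEL = "SCP"
EXTANT_LABEL = "extant_pair"

BUB1_LIKE_ELEMENTS = ELEMENT_UNIVERSE - {"KEN1", "ABBA1"}
MAD3_LIKE_ELEMENTS = ELEMENT_UNIVERSE - {"KINASE", "MAD1B"}


def scp_allele(promoter: str = "BUB1pr", minus: set[str] | frozenset[str] = frozenset()) -> AlleleSpec:
    """An SCP-derived allele missing the given elements."""
    return AlleleSpec(ELEMENT_UNIVERSE - set(minus), promoter, "SCP")


def reconstructed_genotypes() -> list[GenotypeSpec]:
    """Eight genotypes spanning the reconstructed landscape (see module
    docstring): the single-copy ancestor proxy, the fresh duplicate, three
    stepwise degeneration intermediates, the extant-like pair, and the two
    single-gene exits from it."""
    bub1_like = scp_allele("BUB1pr", {"KEN1", "ABBA1"})
    mad3_like = scp_allele("MAD3pr", {"KINASE", "MAD1B"})
    return [
        GenotypeSpec(SOURCE_LABEL, locus_bub1=scp_allele()),
        GenotypeSpec("SCPx2", locus_bub1=scp_allele(), locus_mad3=scp_allele("MAD3pr")),
        GenotypeSpec(
            "dKEN1",
            locus_bub1=scp_allele("BUB1pr", {"KEN1"}),
            locus_mad3=scp_allele("MAD3pr"),
        ),
        GenotypeSpec(
            "dKEN1_dABBA1",
            locus_bub1=bub1_like,
            locus_mad3=scp_allele("MAD3pr"),
        ),
        GenotypeSpec(
            "dKEN1_dABBA1_dKIN",
            locus_bub1=bub1_like,
            locus_mad3=scp_allele("MAD3pr", {"KINASE"}),
        ),
        GenotypeSpec(EXTANT_LABEL, locus_bub1=bub1_like, locus_mad3=mad3_like),
        GenotypeSpec("mad3_locus_only", locus_mad3=mad3_like),
        GenotypeSpec("bub1_locus_only", locus_bub1=bub1_like),
    ]


def true_fitness_class(genotype: GenotypeSpec) -> str:
    """Synthetic ground-truth class from the two pathway functions."""
    elements = genotype.all_elements()
    if "KINASE" not in elements:
        return "bub1_like"
    if "KEN1" not in elements:
        return "mad3_like"
    return "wt_like"


def class_assignment(
    genotypes: list[GenotypeSpec] | None = None,
) -> dict[str, float]:
    """Per-genotype true selection coefficient relative to wild type."""
    genotypes = genotypes if genotypes is not None else reconstructed_genotypes()
    return {g.label: CLASS_FITNESS[true_fitness_class(g)] for g in genotypes}
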