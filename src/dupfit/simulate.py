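"""Synthetic inputs with the statistical structure the analyses assume.

Everything downstream consumes is generated here: binomially sampled
competition count tables on logistic frequency trajectories, full all-by-all
screen matrices with well-level biological noise, protein alignments evolved
down a tree with conserved regions whose rate relaxes inside a flagged
clade, and per-colony sectoring counts. All generators are deterministic
given their seed.

Defaults follow the assay design they emulate: 50,000 cells counted at
generations 20 and 40; an 8x8 all-by-all screen (64 wells) with 16
contamination-control wells and fluorophore-swapped diagonal; biological
replicate noise modelled as a single Gaussian perturbation of s per well,
calibrated so a simulated null screen's fitted-s SD is 0.0017. Drift and
within-assay mutation are deliberately not simulated (the assay spans ~40
generations, far shorter than Ne).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import phylo
from .fitness import CompetitionCounts, logistic_trajectory

__all__ = [
    "SimCompetitionConfig",
    "ScreenDesign",
    "SimAlignmentConfig",
    "simulate_competition",
    "simulate_screen",
    "simulate_alignment",
    "simulate_sectoring",
    "calibrated_bio_sd",
    "NULL_SD",
]

#: fitted-s standard deviation of the null (self-vs-self) competitions that
#: the well-level noise is calibrated against
NULL_SD = 0.0017


def calibrated_bio_sd(
    target_sd: float = NULL_SD,
    n_cells: int = 50_000,
    R0: float = 0.5,
    timepoints: Sequence[float] = (20.0, 40.0),
) -> float:
    """Well-level noise SD such that fitted null-screen SD ~= ``target_sd``.

    The fitted estimator's variance is the binomial sampling variance plus
    the well-level variance, so bio_sd^2 = target^2 - sampling variance,
    with the sampling term taken from the delta method at s = 0:
    sum_t 1/(n R(1-R)) / (t2-t1)^2.
    """
    t1, t2 = timepoints
    samp_var = (2.0 / (n_cells * R0 * (1 - R0))) / (t2 - t1) ** 2
    if samp_var >= target_sd**2:
        raise ValueError("sampling noise alone exceeds the target SD")
    return math.sqrt(target_sd**2 - samp_var)


@dataclass(frozen=True)
class SimCompetitionConfig:
    """Parameters of one simulated competition well."""

    true_s: float = 0.0
    R0: float = 0.5
    n_cells: int = 50_000
    timepoints: tuple[float, ...] = (20.0, 40.0)
    bio_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.R0 < 1.0:
            raise ValueError("R0 must lie strictly in (0, 1)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        tp = tuple(float(t) for t in self.timepoints)
        if any(t < 0 for t in tp) or list(tp) != sorted(set(tp)):
            raise ValueError("timepoints must be non-negative and strictly increasing")
        if self.bio_sd < 0:
            raise ValueError("bio_sd must be non-negative")
        object.__setattr__(self, "timepoints", tp)


def simulate_competition(
    config: SimCompetitionConfig, well_id: str = "sim"
) -> CompetitionCounts:
    """Simulate one well: binomial counts on a logistic trajectory.

    A single Gaussian perturbation epsilon ~ N(0, bio_sd) is added to
    true_s for the whole well (biological, not per-timepoint, noise), then
    r_t ~ Binomial(n_cells, R(t)) independently at each timepoint.
    """
    rng = np.random.default_rng(config.seed)
    s_eff = config.true_s + (rng.normal(0.0, config.bio_sd) if config.bio_sd > 0 else 0.0)
    t = np.asarray(config.timepoints)
    p = logistic_trajectory(config.R0, s_eff, t)
    red = rng.binomial(config.n_cells, p)
    return CompetitionCounts(
        well_id=well_id,
        timepoints=config.timepoints,
        red=tuple(int(r) for r in red),
        green=tuple(int(config.n_cells - r) for r in red),
    )


@dataclass(frozen=True)
class ScreenDesign:
    """All-by-all competition design: every green genotype against every
    red genotype, with the diagonal pairing fluorophore-swapped copies of
    the same genotype as negative controls."""

    green_genotypes: tuple[str, ...]
    red_genotypes: tuple[str, ...]
    controls: int = 16

    def __post_init__(self) -> None:
        for side in (self.green_genotypes, self.red_genotypes):
            if len(set(side)) != len(side):
                raise ValueError("duplicate genotype labels")
        if self.controls < 0:
            raise ValueError("controls must be non-negative")

    @classmethod
    def all_by_all(cls, labels: Sequence[str], controls: int = 16) -> "ScreenDesign":
        labels = tuple(labels)
        return cls(labels, labels, controls)

    @property
    def wells(self) -> list[tuple[str, str]]:
        """Full cross product of (green, red) genotype labels."""
        return list(itertools.product(self.green_genotypes, self.red_genotypes))


def simulate_screen(
    design: ScreenDesign,
    class_assignment: Mapping[str, float],
    config: SimCompetitionConfig,
    missing_wells: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Simulate every well of a screen as a long count table.

    Fitness composes additively on the s scale: the true selection
    coefficient of a well (red strain relative to green) is
    s_red - s_green from the per-genotype assignment, perturbed by one
    N(0, bio_sd) draw per well. Wells listed in ``missing_wells`` are
    omitted (competitions not performed). Columns follow the interchange
    schema: well_id, green_genotype, red_genotype, generation, red_count,
    green_count, total_count.
    """
    unknown = (set(design.green_genotypes) | set(design.red_genotypes)) - set(
        class_assignment
    )
    if unknown:
        raise KeyError(f"no fitness assigned for genotypes: {sorted(unknown)}")
    missing = set(missing_wells)
    rng = np.random.default_rng(config.seed)
    rows = []
    for i, (green, red) in enumerate(design.wells):
        s_true = class_assignment[red] - class_assignment[green]
        s_eff = s_true + (rng.normal(0.0, config.bio_sd) if config.bio_sd > 0 else 0.0)
        if (green, red) in missing:
            continue
        well_id = f"w{i:03d}_{green}_vs_{red}"
        p = logistic_trajectory(config.R0, s_eff, np.asarray(config.timepoints))
        reds = rng.binomial(config.n_cells, p)
        for t, r in zip(config.timepoints, reds):
            rows.append(
                {
                    "well_id": well_id,
                    "green_genotype": green,
                    "red_genotype": red,
                    "generation": t,
                    "red_count": int(r),
                    "green_count": int(config.n_cells - r),
                    "total_count": int(config.n_cells),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimAlignmentConfig:
    """Generative model of an alignment with conserved-rate regions.

    ``regions`` are (start, end, rho) with 0 < rho < 1 slowing every branch
    inside the column interval; ``shifted_regions`` maps a region index to
    a flagged-clade label whose branches revert to the background rate 1.0
    for those columns (the relaxation signature the scanner must detect).
    """

    tree: "dendropy.Tree | str"
    length: int
    regions: tuple[tuple[int, int, float], ...] = ()
    shifted_regions: Mapping[int, str] = field(default_factory=dict)
    exchangeability: np.ndarray | None = None
    frequencies: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")
        regs = tuple((int(a), int(b), float(r)) for a, b, r in self.regions)
        last = 0
        for a, b, r in sorted(regs):
            if not 0 <= a < b <= self.length:
                raise ValueError(f"region ({a}, {b}) outside [0, {self.length})")
            if a < last:
                raise ValueError("regions must not overlap")
            if not 0 < r < 1:
                raise ValueError("conserved-rate multiplier must lie in (0, 1)")
            last = b
        for idx in self.shifted_regions:
            if not 0 <= idx < len(regs):
                raise ValueError(f"shifted region index {idx} out of range")
        object.__setattr__(self, "regions", regs)

    def model(self) -> phylo.PhyloModel:
        tree = self.tree
        if isinstance(tree, str):
            tree = phylo.read_tree(tree, from_string=True)
        kwargs = {}
        if self.exchangeability is not None:
            kwargs["exchangeability"] = self.exchangeability
        if self.frequencies is not None:
            kwargs["frequencies"] = self.frequencies
        return phylo.PhyloModel(tree, **kwargs)


def simulate_alignment(config: SimAlignmentConfig) -> dict[str, str]:
    """Evolve a protein alignment down the tree under the region rates.

    The root sequence is drawn from the stationary frequencies; each column
    then evolves along every branch with length scaled by its region's
    multiplier, except that columns of a shifted region use the background
    rate on branches inside the named flagged clade. Returns one (gapless)
    sequence per leaf, deterministic given the seed.
    """
    model = config.model()
    cache = model._tree_cache()
    if len(cache.leaf_names) < 2:
        raise ValueError("tree must have at least 2 leaves")
    for idx, clade in config.shifted_regions.items():
        if clade not in cache.clades:
            raise ValueError(f"tree has no flagged clade labelled {clade!r}")

    # per-column rate class: 0 = background, i+1 = region i
    col_region = np.zeros(config.length, dtype=int)
    for i, (a, b, _r) in enumerate(config.regions):
        col_region[a:b] = i + 1

    rng = np.random.default_rng(config.seed)
    seqs: dict[int, np.ndarray] = {}
    root_state = rng.choice(20, size=config.length, p=model.frequencies)
    seqs[cache.root_index] = root_state

    # walk edges parent->child in reverse postorder (parents first)
    for edge_idx in reversed(range(len(cache.edges))):
        child, parent, blen = cache.edges[edge_idx]
        parent_state = seqs[parent]
        child_state = np.empty_like(parent_state)
        # effective multiplier per column on this edge
        mult = np.ones(config.length)
        for i, (a, b, r) in enumerate(config.regions):
            in_shifted_clade = (
                i in config.shifted_regions
                and cache.clades[config.shifted_regions[i]][edge_idx]
            )
            mult[a:b] = 1.0 if in_shifted_clade else r
        for m in np.unique(mult):
            cols = np.nonzero(mult == m)[0]
            p = model.transition_matrix(blen * m)
            cum = np.cumsum(p, axis=1)
            u = rng.random(cols.size)
            child_state[cols] = (cum[parent_state[cols]] > u[:, None]).argmax(axis=1)
        seqs[child] = child_state

    aa = np.array(list(phylo.AMINO_ACIDS))
    return {
        name: "".join(aa[seqs[i]]) for i, name in enumerate(cache.leaf_names)
    }


def simulate_sectoring(
    loss_prob: float, n_colonies: int, seed: int = 0
) -> tuple[int, int]:
    """(sectored, white) colony counts: sectored ~ Binomial(n, loss_prob)."""
    if not 0.0 <= loss_prob <= 1.0:
        raise ValueError("loss_prob must lie in [0, 1]")
    if n_colonies < 0:
        raise ValueError("n_colonies must be non-negative")
    rng = np.random.default_rng(seed)
    sectored = int(rng.binomial(n_colonies, loss_prob))
    return sectored, n_colonies - sectored
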