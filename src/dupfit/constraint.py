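"""Conserved-region detection and relaxed-constraint tests in paralogs.

The scan has three stages. First, conserved regions are decoded from the
pre-duplication sub-alignment with the two-state rate HMM (posterior
threshold 0.5, minimum run length 3 columns). Second, each region's column
interval is mapped into the coordinates of the full alignment that also
contains the post-duplication paralogs, using the shared (pre-duplication)
rows to translate columns; a region whose columns are entirely gapped in
one paralog clade is flagged unalignable there. Third, each mapped region x
paralog clade is tested for a change in evolutionary rate: a single rate
rho shared by all branches (one parameter) against separate rates inside
and outside the flagged clade (two parameters), with 2*delta-lnL referred
to chi-square with one degree of freedom. Relaxation means the fitted
post-duplication rate exceeds the rate elsewhere. Benjamini-Hochberg
adjustment is applied across all region x clade tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from . import phylo
from .hmm import RateHMM, _golden_max, column_log_emissions, posterior_decode, fit_hmm

__all__ = [
    "ConstraintRegion",
    "MappedRegion",
    "ConstraintTest",
    "DecodeResult",
    "decode_regions",
    "map_regions",
    "lrt_constraint_change",
    "scan_protein",
]

RHO_MAX = 10.0
RHO_MIN = 1e-4


@dataclass(frozen=True)
class ConstraintRegion:
    """A conserved alignment segment, 0-based half-open columns."""

    start: int
    end: int
    mean_posterior: float
    rho_hat: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")
        if not 0.5 <= self.mean_posterior <= 1.0:
            raise ValueError("mean conserved posterior must be in [0.5, 1]")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MappedRegion:
    """A region translated to full-alignment coordinates.

    ``unalignable`` lists paralog clades whose sequences are entirely
    gapped across the mapped interval.
    """

    source: ConstraintRegion
    start: int
    end: int
    unalignable: tuple[str, ...] = ()


@dataclass(frozen=True)
class ConstraintTest:
    """One-rate vs two-rate LRT for one region and one paralog clade."""

    region: MappedRegion
    paralog_clade: str
    lnL_one_rate: float
    lnL_two_rate: float
    lrt: float
    p: float
    rho_shared: float
    rho_pre: float
    rho_post: float
    direction: str  # "relaxed" | "constrained"
    q: float | None = None
    at_bound: bool = False

    def __post_init__(self) -> None:
        if self.lrt < -1e-6:
            raise ValueError("LRT statistic below numerical floor")


@dataclass(frozen=True)
class DecodeResult:
    regions: tuple[ConstraintRegion, ...]
    log_likelihood: float
    posterior: np.ndarray
    hmm: RateHMM


def decode_regions(
    alignment: Mapping[str, str],
    model: phylo.PhyloModel,
    hmm: RateHMM | None = None,
    min_len: int = 3,
    seed: int = 0,
) -> DecodeResult:
    """Posterior-decode conserved regions on a (pre-duplication) alignment.

    When ``hmm`` is None its parameters are fitted by EM with restarts.
    Maximal runs of columns with conserved posterior > 0.5 and length >=
    ``min_len`` become regions; each region's rho_hat is the single-rate
    fit over its columns.
    """
    data = phylo.encode_alignment(alignment, model.leaf_names)
    if data.shape[1] == 0:
        raise ValueError("empty alignment")
    if hmm is None:
        hmm = fit_hmm(data, model, seed=seed)
    log_em = column_log_emissions(data, model, hmm)
    gamma, loglik, _ = posterior_decode(log_em, hmm)
    conserved = gamma[:, 0] > 0.5

    regions: list[ConstraintRegion] = []
    start = None
    for i, flag in enumerate(list(conserved) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                cols = data[:, start:i]

                def region_ll(r: float) -> float:
                    return float(np.sum(phylo.alignment_log_likelihoods(cols, model, r)))

                rho = _golden_max(region_ll, RHO_MIN, RHO_MAX, tol=1e-4)
                regions.append(
                    ConstraintRegion(
                        start, i, float(gamma[start:i, 0].mean()), rho_hat=rho
                    )
                )
            start = None
    return DecodeResult(tuple(regions), loglik, gamma, hmm)


def _residue_positions(seq: str) -> list[int]:
    return [i for i, ch in enumerate(seq) if ch not in "-.?"]


def build_column_map(
    pre_alignment: Mapping[str, str], full_alignment: Mapping[str, str]
) -> dict[int, int]:
    """Map pre-alignment columns to full-alignment columns via shared rows.

    Shared rows must have identical ungapped content in both alignments;
    each pre column with at least one shared residue maps to the full
    column holding that residue, and all shared rows must agree.
    """
    shared = [k for k in pre_alignment if k in full_alignment]
    if not shared:
        raise ValueError("no shared rows between the two alignments")
    colmap: dict[int, int] = {}
    for name in shared:
        pre_pos = _residue_positions(pre_alignment[name])
        full_pos = _residue_positions(full_alignment[name])
        if len(pre_pos) != len(full_pos):
            raise ValueError(f"shared row {name!r} differs between alignments")
        pre_res = [pre_alignment[name][i] for i in pre_pos]
        full_res = [full_alignment[name][i] for i in full_pos]
        if [c.upper() for c in pre_res] != [c.upper() for c in full_res]:
            raise ValueError(f"shared row {name!r} differs between alignments")
        for pc, fc in zip(pre_pos, full_pos):
            if colmap.setdefault(pc, fc) != fc:
                raise ValueError(
                    f"inconsistent column correspondence at pre column {pc}"
                )
    return colmap


def map_regions(
    regions: Sequence[ConstraintRegion],
    pre_alignment: Mapping[str, str],
    full_alignment: Mapping[str, str],
    paralog_rows: Mapping[str, Sequence[str]] | None = None,
) -> list[MappedRegion]:
    """Translate regions into full-alignment coordinates.

    ``paralog_rows`` maps a paralog-clade name to the full-alignment row
    names of that clade; a region all-gap across a clade's rows is flagged
    unalignable for it.
    """
    colmap = build_column_map(pre_alignment, full_alignment)
    out: list[MappedRegion] = []
    for reg in regions:
        cols = [colmap[c] for c in range(reg.start, reg.end) if c in colmap]
        if not cols:
            raise ValueError(f"region {reg.start}:{reg.end} has no mappable column")
        start, end = min(cols), max(cols) + 1
        flagged: list[str] = []
        for clade, rows in (paralog_rows or {}).items():
            present = [r for r in rows if r in full_alignment]
            if present and all(
                set(full_alignment[r][start:end]) <= set("-.?") for r in present
            ):
                flagged.append(clade)
        out.append(MappedRegion(reg, start, end, tuple(flagged)))
    return out


def lrt_constraint_change(
    region: MappedRegion | ConstraintRegion,
    full_alignment: Mapping[str, str] | np.ndarray,
    model: phylo.PhyloModel,
    clade: str | None = None,
    tol: float = 1e-6,
) -> ConstraintTest:
    """One-rate vs two-rate likelihood-ratio test over a region's columns.

    The null fits a single rate multiplier rho on every branch; the
    alternative fits one rate on branches inside the flagged clade
    (including its stem) and one on all other branches, by golden-section
    per coordinate. lnL_two >= lnL_one is guaranteed by starting the
    two-rate fit at the one-rate optimum. An optimizer pinned at the upper
    rate bound is flagged.
    """
    if isinstance(region, ConstraintRegion):
        region = MappedRegion(region, region.start, region.end)
    if isinstance(full_alignment, np.ndarray):
        data = full_alignment
    else:
        data = phylo.encode_alignment(full_alignment, model.leaf_names)
    if region.end > data.shape[1]:
        raise ValueError("region extends past the alignment")
    cols = data[:, region.start : region.end]
    mask = model.clade_edge_mask(clade)
    clade_name = clade if clade is not None else model.clade_names()[0]

    def ll_one(r: float) -> float:
        return float(np.sum(phylo.alignment_log_likelihoods(cols, model, r)))

    def ll_two(r_out: float, r_in: float) -> float:
        rates = np.where(mask, r_in, r_out)
        return float(np.sum(phylo.alignment_log_likelihoods(cols, model, rates)))

    rho_shared = _golden_max(ll_one, RHO_MIN, RHO_MAX, tol=tol)
    l1 = ll_one(rho_shared)

    r_out, r_in = rho_shared, rho_shared
    prev = ll_two(r_out, r_in)
    for _ in range(25):
        r_out = _golden_max(lambda r: ll_two(r, r_in), RHO_MIN, RHO_MAX, tol=tol)
        r_in = _golden_max(lambda r: ll_two(r_out, r), RHO_MIN, RHO_MAX, tol=tol)
        cur = ll_two(r_out, r_in)
        if cur - prev < 1e-8:
            prev = cur
            break
        prev = cur
    l2 = max(prev, l1)  # nested models; guard against coordinate-descent jitter
    lrt = max(0.0, 2.0 * (l2 - l1))
    p = float(sp_stats.chi2.sf(lrt, df=1))
    at_bound = any(
        abs(r - RHO_MAX) < 10 * tol for r in (rho_shared, r_out, r_in)
    )
    return ConstraintTest(
        region=region,
        paralog_clade=clade_name,
        lnL_one_rate=l1,
        lnL_two_rate=l2,
        lrt=lrt,
        p=p,
        rho_shared=rho_shared,
        rho_pre=r_out,
        rho_post=r_in,
        direction="relaxed" if r_in > r_out else "constrained",
        at_bound=at_bound,
    )


@dataclass(frozen=True)
class ScanResult:
    tests: tuple[ConstraintTest, ...]
    regions: tuple[MappedRegion, ...]
    decode: DecodeResult

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "start": t.region.start,
                "end": t.region.end,
                "paralog_clade": t.paralog_clade,
                "lnL_one_rate": t.lnL_one_rate,
                "lnL_two_rate": t.lnL_two_rate,
                "lrt": t.lrt,
                "p": t.p,
                "q": t.q,
                "rho_pre": t.rho_pre,
                "rho_post": t.rho_post,
                "direction": t.direction,
                "relaxed": (t.q is not None and t.q < 0.05 and t.direction == "relaxed"),
            }
            for t in self.tests
        ]
        return pd.DataFrame(rows)

    def complementary_summary(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per region: which clades show significant relaxation.

        ``complementary`` is True when exactly one paralog clade relaxed —
        the partitioning pattern expected under subfunctionalization;
        ``lost_in_both`` when every clade relaxed.
        """
        df = self.to_frame()
        if df.empty:
            return pd.DataFrame(
                columns=["start", "end", "relaxed_clades", "complementary", "lost_in_both"]
            )
        out = []
        n_clades = df["paralog_clade"].nunique()
        for (start, end), grp in df.groupby(["start", "end"], sort=True):
            relaxed = sorted(grp.loc[grp["relaxed"], "paralog_clade"])
            out.append(
                {
                    "start": start,
                    "end": end,
                    "relaxed_clades": ",".join(relaxed),
                    "complementary": len(relaxed) == 1,
                    "lost_in_both": 0 < n_clades == len(relaxed),
                }
            )
        return pd.DataFrame(out)


def scan_protein(
    pre_alignment: Mapping[str, str],
    full_alignment: Mapping[str, str],
    model: phylo.PhyloModel,
    hmm: RateHMM | None = None,
    min_len: int = 3,
    seed: int = 0,
) -> ScanResult:
    """decode -> map -> LRT for every region x paralog clade, with BH
    adjustment across all tests.

    The pre-duplication model reuses the full model's substitution process
    on the tree pruned to the pre-alignment's taxa. Regions unalignable in
    a clade are skipped for that clade (they cannot be rate-tested).
    """
    pre_taxa = [n for n in model.leaf_names if n in pre_alignment]
    if len(pre_taxa) < 2:
        raise ValueError("need >= 2 pre-duplication sequences present on the tree")
    pre_tree = model.tree.extract_tree_with_taxa_labels(pre_taxa)
    pre_model = phylo.PhyloModel(
        pre_tree, model.exchangeability, model.frequencies, model.clade_label
    )
    decode = decode_regions(pre_alignment, pre_model, hmm=hmm, min_len=min_len, seed=seed)

    clades = model.clade_names()
    paralog_rows = {c: model.clade_leaves(c) for c in clades}
    mapped = map_regions(decode.regions, pre_alignment, full_alignment, paralog_rows)

    data = phylo.encode_alignment(full_alignment, model.leaf_names)
    tests: list[ConstraintTest] = []
    for reg in mapped:
        for clade in clades:
            if clade in reg.unalignable:
                continue
            tests.append(lrt_constraint_change(reg, data, model, clade))
    if tests:
        _, qvals, _, _ = multipletests([t.p for t in tests], method="fdr_bh")
        tests = [replace(t, q=float(q)) for t, q in zip(tests, qvals)]
    return ScanResult(tuple(tests), tuple(mapped), decode)
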