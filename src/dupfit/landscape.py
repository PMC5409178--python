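"""Genotype landscapes for duplication-degeneration-complementation analysis.

A genotype is the presence/absence of named functional elements (KEN boxes,
TPR, ABBA motifs, GLEBS, the Mad1-binding region, the kinase domain) at two
loci. Nodes that differ by exactly one evolutionary event — a duplication
filling the empty locus, the loss of a single element, or the loss of a
whole gene — are joined by a directed parent->child edge. Reversions are
excluded (no edge re-creates an element, and losing a still-identical
duplicate, which would undo the duplication, is likewise excluded), so the
landscape is a DAG. Edges carry replicate fitness contrasts and effect
calls; path enumeration then asks whether the extant paralog pair is
reachable from the single-copy ancestor through steps without a detectable
fitness defect, and whether it is an absorbing state (every allowed exit
deleterious).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .fitness import AssayConfig, SelectionEstimate, call_effect

__all__ = [
    "ELEMENT_UNIVERSE",
    "AlleleSpec",
    "GenotypeSpec",
    "FitnessLandscape",
    "build_landscape",
    "classify_step",
    "cluster_fitness_classes",
    "ClusterResult",
    "classify_edges",
    "find_neutral_paths",
    "Path",
    "is_absorbing",
]

ELEMENT_UNIVERSE = frozenset(
    {"KEN1", "KEN2", "TPR", "ABBA1", "ABBA2", "GLEBS", "MAD1B", "KINASE"}
)
PROMOTERS = ("BUB1pr", "MAD3pr")
PROVENANCES = ("SCP", "extant_Bub1", "extant_Mad3")
LOCUS_PROMOTER = {"bub1": "BUB1pr", "mad3": "MAD3pr"}


@dataclass(frozen=True)
class AlleleSpec:
    """One allele: its functional elements, promoter and provenance."""

    elements: frozenset[str]
    promoter: str = "BUB1pr"
    provenance: str = "SCP"

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", frozenset(self.elements))
        unknown = self.elements - ELEMENT_UNIVERSE
        if unknown:
            raise ValueError(f"unknown elements: {sorted(unknown)}")
        if self.promoter not in PROMOTERS:
            raise ValueError(f"promoter must be one of {PROMOTERS}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")
        # extant alleles must match the known paralog element layout
        if self.provenance == "extant_Bub1" and (
            "KEN1" in self.elements or "KINASE" not in self.elements
        ):
            raise ValueError("extant Bub1 lacks KEN1 and carries the kinase domain")
        if self.provenance == "extant_Mad3" and (
            not {"KEN1", "KEN2"} <= self.elements or "KINASE" in self.elements
        ):
            raise ValueError("extant Mad3 carries both KEN boxes and no kinase")

    def drop(self, element: str) -> "AlleleSpec":
        if element not in self.elements:
            raise ValueError(f"{element} not present")
        return AlleleSpec(self.elements - {element}, self.promoter, self.provenance)


@dataclass(frozen=True)
class GenotypeSpec:
    """Alleles at the BUB1 and MAD3 loci (either may be absent)."""

    label: str
    locus_bub1: AlleleSpec | None = None
    locus_mad3: AlleleSpec | None = None

    @property
    def loci(self) -> dict[str, AlleleSpec | None]:
        return {"bub1": self.locus_bub1, "mad3": self.locus_mad3}

    @property
    def viable_loci(self) -> int:
        return sum(a is not None for a in self.loci.values())

    def all_elements(self) -> frozenset[str]:
        out: set[str] = set()
        for a in self.loci.values():
            if a is not None:
                out |= a.elements
        return frozenset(out)

    def element_count(self) -> int:
        return sum(len(a.elements) for a in self.loci.values() if a is not None)


def classify_step(parent: GenotypeSpec, child: GenotypeSpec) -> str | None:
    """Event type if ``child`` is exactly one step from ``parent``.

    Returns "duplication", "element_loss" or "gene_loss", or None when the
    pair is not a single step. A gene loss that reconstitutes the
    pre-duplication genotype (losing a copy identical to the remaining
    allele's elements) is a reversion of the duplication and returns None.
    """
    pl, cl = parent.loci, child.loci

    # duplication: empty locus filled with a copy of the occupied allele,
    # under the target locus promoter
    for locus in ("bub1", "mad3"):
        other = "mad3" if locus == "bub1" else "bub1"
        if (
            pl[locus] is None
            and cl[locus] is not None
            and pl[other] is not None
            and cl[other] == pl[other]
            and cl[locus].elements == pl[other].elements
            and cl[locus].promoter == LOCUS_PROMOTER[locus]
        ):
            return "duplication"

    # gene loss: one locus emptied, the other untouched
    for locus in ("bub1", "mad3"):
        other = "mad3" if locus == "bub1" else "bub1"
        if pl[locus] is not None and cl[locus] is None and cl[other] == pl[other]:
            if (
                pl[other] is not None
                and pl[locus].elements == pl[other].elements
            ):
                return None  # undoing the duplication: a reversion
            return "gene_loss"

    # element loss: same occupancy, one allele loses exactly one element
    diffs = []
    for locus in ("bub1", "mad3"):
        if (pl[locus] is None) != (cl[locus] is None):
            return None
        if pl[locus] != cl[locus]:
            diffs.append(locus)
    if len(diffs) == 1:
        pa, ca = pl[diffs[0]], cl[diffs[0]]
        if (
            pa.promoter == ca.promoter
            and pa.provenance == ca.provenance
            and ca.elements < pa.elements
            and len(pa.elements - ca.elements) == 1
        ):
            return "element_loss"
    return None


@dataclass
class FitnessLandscape:
    """Directed single-step genotype graph (a networkx DiGraph underneath).

    Node attributes: ``genotype`` (GenotypeSpec), optional ``fitness_class``
    and ``mean_s``. Edge attributes: ``event``, and after classification
    ``call`` plus the replicate contrasts ``s_reps``.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def genotypes(self) -> dict[str, GenotypeSpec]:
        return {n: d["genotype"] for n, d in self.graph.nodes(data=True)}

    def edges_frame(self) -> pd.DataFrame:
        rows = []
        for u, v, d in self.graph.edges(data=True):
            reps = d.get("s_reps") or ()
            rows.append(
                {
                    "parent": u,
                    "child": v,
                    "event": d["event"],
                    "s_rep1": reps[0].s if len(reps) > 0 else np.nan,
                    "s_rep2": reps[1].s if len(reps) > 1 else np.nan,
                    "call": d.get("call", "unknown"),
                }
            )
        return pd.DataFrame(rows, columns=["parent", "child", "event", "s_rep1", "s_rep2", "call"])

    def to_dot(self) -> str:
        color = {
            "deleterious": "red",
            "beneficial": "green",
            "no_detectable_effect": "black",
            "inconsistent": "orange",
            "unknown": "grey",
        }
        lines = ["digraph landscape {"]
        for n in self.graph.nodes:
            lines.append(f'  "{n}";')
        for u, v, d in self.graph.edges(data=True):
            c = color.get(d.get("call", "unknown"), "grey")
            lines.append(f'  "{u}" -> "{v}" [color={c}, label="{d["event"]}"];')
        lines.append("}")
        return "\n".join(lines)


def build_landscape(genotypes: Sequence[GenotypeSpec]) -> FitnessLandscape:
    """Pairwise single-step comparison of every ordered genotype pair."""
    labels = [g.label for g in genotypes]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate genotype labels")
    g = nx.DiGraph()
    for geno in genotypes:
        g.add_node(geno.label, genotype=geno)
    for parent in genotypes:
        for child in genotypes:
            if parent.label == child.label:
                continue
            event = classify_step(parent, child)
            if event is not None:
                g.add_edge(parent.label, child.label, event=event)
    return FitnessLandscape(g)


@dataclass(frozen=True)
class ClusterResult:
    labels: "pd.Series"
    n_classes: int
    class_mean_s: "pd.Series | None"
    linkage: np.ndarray
    cut_height: float


def _pairwise_complete_distances(values: np.ndarray) -> np.ndarray:
    """Condensed Euclidean distances over shared-observed entries, rescaled
    by sqrt(p / p_observed) to stay comparable across missingness patterns."""
    n, p = values.shape
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~np.isnan(values[i]) & ~np.isnan(values[j])
            m = int(mask.sum())
            if m == 0:
                raise ValueError(
                    f"rows {i} and {j} share no observed entries; cannot cluster"
                )
            diff = values[i, mask] - values[j, mask]
            out.append(float(np.sqrt(np.sum(diff**2) * p / m)))
    return np.asarray(out)


def cluster_fitness_classes(
    s_matrix: pd.DataFrame,
    wildtype: str | None = None,
    max_k: int = 6,
    sep_factor: float = 3.0,
) -> ClusterResult:
    """Agglomerative (average-linkage) clustering of the screen's s matrix.

    Rows are genotypes; entries the selection coefficient of the row
    genotype relative to the column genotype (NaN = competition not
    performed; censored values must already carry the -0.3 bound). The flat
    partition counts as class-separating every merge whose height stands
    clear of the bulk of merge heights (> ``sep_factor`` x their median),
    i.e. all the large jumps in the dendrogram, not only the single largest
    gap — fitness plateaus at very different depths (say -0.015 and -0.3)
    otherwise collapse into the nearer one. The class count is capped at
    ``max_k``. Rows are ordered lexicographically before linkage so
    equal-distance ties break deterministically and the partition is
    invariant to input order.
    """
    if s_matrix.isna().all(axis=1).any():
        bad = s_matrix.index[s_matrix.isna().all(axis=1)][0]
        raise ValueError(f"genotype {bad!r} has no observed competition")
    order = sorted(s_matrix.index)
    mat = s_matrix.loc[order]
    values = mat.to_numpy(dtype=float)
    n = values.shape[0]
    if n < 2:
        labels = pd.Series(np.ones(n, dtype=int), index=mat.index)
        return ClusterResult(labels, n, None, np.empty((0, 4)), 0.0)
    dist = _pairwise_complete_distances(values)
    link = hierarchy.linkage(dist, method="average")
    heights = np.sort(link[:, 2])
    m = len(heights)

    # separating merges: heights well above the bulk (median) of all merges
    threshold = max(sep_factor * float(np.median(heights)), 1e-12)
    n_sep = int(np.sum(heights > threshold))
    n_sep = min(n_sep, max_k - 1)
    if n_sep == 0:
        cut = float(heights[-1]) + 1.0
    else:
        lo = float(heights[m - n_sep - 1]) if m - n_sep - 1 >= 0 else 0.0
        cut = 0.5 * (lo + float(heights[m - n_sep]))
    flat = hierarchy.fcluster(link, t=cut, criterion="distance")
    labels = pd.Series(flat, index=mat.index, name="fitness_class")

    class_means = None
    if wildtype is not None:
        if wildtype not in s_matrix.columns:
            raise KeyError(f"wild-type column {wildtype!r} not in matrix")
        wt_col = mat[wildtype]
        class_means = wt_col.groupby(labels).mean()
        class_means.name = "mean_s_vs_wildtype"
    return ClusterResult(labels, int(labels.nunique()), class_means, link, float(cut))


def _oriented(reps: Iterable[SelectionEstimate], flip: bool) -> list[SelectionEstimate]:
    out = []
    for e in reps:
        if flip:
            e = SelectionEstimate(
                e.well_id, -e.s, R0_hat=e.R0_hat, status=e.status, se=e.se,
                converged=e.converged, message=e.message,
            )
        out.append(e)
    return out


def _lookup_contrast(
    estimates: Mapping[tuple[str, str], Sequence[SelectionEstimate]],
    focal: str,
    reference: str,
) -> list[SelectionEstimate] | None:
    """Replicates of focal-vs-reference, using the swapped orientation
    (sign-flipped) when only that was measured."""
    if (focal, reference) in estimates:
        return _oriented(estimates[(focal, reference)], flip=False)
    if (reference, focal) in estimates:
        return _oriented(estimates[(reference, focal)], flip=True)
    return None


def _compose(
    child_wt: Sequence[SelectionEstimate], parent_wt: Sequence[SelectionEstimate]
) -> list[SelectionEstimate] | None:
    """s_child,parent = s_child,WT - s_parent,WT, replicate by replicate."""
    out = []
    for c, p in zip(child_wt, parent_wt):
        if c.status == "censored_low" and p.status == "censored_low":
            return None  # both off-scale: contrast not estimable
        if c.status == "censored_low":
            out.append(SelectionEstimate("composed", c.s, status="censored_low"))
        elif p.status == "censored_low":
            out.append(SelectionEstimate("composed", -p.s, status="censored_low"))
        else:
            out.append(SelectionEstimate("composed", c.s - p.s))
    return out


def classify_edges(
    landscape: FitnessLandscape,
    estimates: Mapping[tuple[str, str], Sequence[SelectionEstimate]],
    config: AssayConfig | None = None,
    reference: str | None = None,
) -> FitnessLandscape:
    """Attach replicate contrasts and effect calls to every edge.

    ``estimates`` maps (focal, reference) genotype pairs to >= 2 replicate
    estimates of s_focal - s_reference (fluorophore-swapped measurements
    already oriented; the swapped key is used with a sign flip if needed).
    When no direct competition exists for an edge, the contrast is composed
    through the ``reference`` genotype: s_child,parent = s_child,ref -
    s_parent,ref. An edge with no estimable contrast is labelled
    ``unknown``, never silently neutral.
    """
    config = config or AssayConfig()
    for u, v, d in landscape.graph.edges(data=True):
        reps = _lookup_contrast(estimates, v, u)
        if reps is None and reference is not None:
            child_wt = _lookup_contrast(estimates, v, reference)
            parent_wt = _lookup_contrast(estimates, u, reference)
            if child_wt and parent_wt:
                reps = _compose(child_wt, parent_wt)
        if reps is None or len(reps) < 2:
            d["call"] = "unknown"
            d["s_reps"] = tuple(reps or ())
        else:
            d["call"] = call_effect(reps, config)
            d["s_reps"] = tuple(reps)
    return landscape


@dataclass(frozen=True)
class Path:
    """A directed path with its event sequence.

    ``degenerations`` counts element-loss events; ``indeterminate`` is True
    when any traversed edge lacked a classified effect call.
    """

    nodes: tuple[str, ...]
    events: tuple[str, ...]
    degenerations: int
    indeterminate: bool = False


def find_neutral_paths(
    landscape: FitnessLandscape, source: str | GenotypeSpec, target: str | GenotypeSpec
) -> list[Path]:
    """All directed paths from source to target with no deleterious edge.

    Exhaustive depth-first enumeration (the landscape is a DAG). Edges
    called deleterious are never traversed; edges with an unknown call are
    traversed but mark the path indeterminate.
    """
    src = source.label if isinstance(source, GenotypeSpec) else source
    tgt = target.label if isinstance(target, GenotypeSpec) else target
    g = landscape.graph
    for node in (src, tgt):
        if node not in g:
            raise KeyError(f"genotype {node!r} not in landscape")

    paths: list[Path] = []

    def dfs(node: str, nodes: list[str], events: list[str], indet: bool) -> None:
        if node == tgt:
            paths.append(
                Path(
                    tuple(nodes),
                    tuple(events),
                    sum(e == "element_loss" for e in events),
                    indet,
                )
            )
            # target may still have onward edges, but paths are simple and
            # the graph acyclic: stop here
            return
        for _, child, d in g.out_edges(node, data=True):
            call = d.get("call", "unknown")
            if call == "deleterious":
                continue
            dfs(child, nodes + [child], events + [d["event"]], indet or call == "unknown")

    dfs(src, [src], [], False)
    return paths


def is_absorbing(landscape: FitnessLandscape, node: str | GenotypeSpec) -> bool:
    """True iff every outgoing edge is deleterious.

    A node without outgoing edges is vacuously absorbing (documented
    convention). Any unclassified outgoing edge raises: absorption cannot
    be decided without calls.
    """
    n = node.label if isinstance(node, GenotypeSpec) else node
    calls = [d.get("call", "unknown") for _, _, d in landscape.graph.out_edges(n, data=True)]
    if any(c == "unknown" for c in calls):
        raise ValueError(f"node {n!r} has unclassified outgoing edges")
    return all(c == "deleterious" for c in calls)
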