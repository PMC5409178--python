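"""Reversible amino-acid substitution models and pruning likelihoods.

A :class:`PhyloModel` couples a rooted tree (dendropy) with a general
time-reversible rate matrix built from a symmetric exchangeability structure
S and stationary frequencies pi: q_ij = s_ij pi_j (i != j), diagonal set so
rows sum to zero, and the whole matrix scaled to one expected substitution
per site per unit branch length. Transition matrices come from the
symmetrized eigendecomposition (exact, no Pade), so likelihood evaluations
at many rate multipliers are cheap.

Column likelihoods are computed by Felsenstein pruning, vectorized over
alignment columns, with gaps treated as missing data (partial vector of
ones). The per-branch rate multiplier hook is what the rate HMM and the
relaxed-constraint likelihood-ratio test build on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "PhyloModel",
    "equal_exchangeabilities",
    "load_paml_matrix",
    "read_tree",
    "column_likelihood",
    "alignment_log_likelihoods",
]

# PAML residue order
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_MISSING = set("-.?X*")

DUP_LABEL = "DUP"


def equal_exchangeabilities() -> np.ndarray:
    """Equal-rates (Poisson-type) exchangeability structure."""
    s = np.ones((20, 20))
    np.fill_diagonal(s, 0.0)
    return s


def load_paml_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML-dialect rate file: 19 lower-triangle rows of
    exchangeabilities followed by one line of 20 stationary frequencies.

    Blank lines and ``#`` comments are ignored; the 190 exchangeabilities
    may be wrapped arbitrarily across lines.
    """
    tokens: list[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            tokens.extend(float(x) for x in line.split())
    if len(tokens) < 190 + 20:
        raise ValueError("expected 190 exchangeabilities plus 20 frequencies")
    tri, freqs = tokens[:190], np.asarray(tokens[190:210])
    s = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = tri[k]
            k += 1
    if not math.isclose(freqs.sum(), 1.0, rel_tol=0, abs_tol=1e-3):
        raise ValueError("frequencies must sum to 1")
    return s, freqs / freqs.sum()


def read_tree(source: str | Path, *, from_string: bool = False) -> dendropy.Tree:
    """Read a rooted newick tree; internal node labels are preserved so the
    post-duplication clade marker (label ``DUP``) survives parsing."""
    kwargs = dict(
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if from_string:
        return dendropy.Tree.get(data=str(source), **kwargs)
    return dendropy.Tree.get(path=str(source), **kwargs)


@dataclass
class PhyloModel:
    """Tree + reversible substitution model (+ optional duplication flag).

    ``exchangeability`` is the symmetric S; ``frequencies`` the stationary
    distribution; ``clade_label`` the internal-node label marking
    post-duplication clades (default ``"DUP"``).
    """

    tree: dendropy.Tree
    exchangeability: np.ndarray = field(default_factory=equal_exchangeabilities)
    frequencies: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))
    clade_label: str = DUP_LABEL

    def __post_init__(self) -> None:
        self.exchangeability = np.asarray(self.exchangeability, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.exchangeability.shape != (20, 20):
            raise ValueError("exchangeability must be 20x20")
        if not np.allclose(self.exchangeability, self.exchangeability.T):
            raise ValueError("exchangeability must be symmetric")
        if not math.isclose(self.frequencies.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("frequencies must sum to 1")
        if any(
            (e.length or 0.0) < 0 for e in self.tree.preorder_edge_iter()
        ):
            raise ValueError("branch lengths must be non-negative")
        self._decomp: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
        self._cache: _TreeCache | None = None

    # -- rate matrix ---------------------------------------------------
    @property
    def rate_matrix(self) -> np.ndarray:
        """Normalized GTR rate matrix Q (rows sum to 0, mean rate 1)."""
        q = self.exchangeability * self.frequencies[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(self.frequencies, np.diag(q)))
        return q / mu

    def _eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self._decomp is None:
            pi = self.frequencies
            d = np.sqrt(pi)
            b = (d[:, None] * self.rate_matrix) / d[None, :]
            lam, u = np.linalg.eigh(0.5 * (b + b.T))
            left = u.T * d[None, :]          # U^T D^{1/2}
            right = (1.0 / d)[:, None] * u   # D^{-1/2} U
            self._decomp = (lam, right, left)
        return self._decomp

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); exact via the symmetric eigendecomposition."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        lam, right, left = self._eigen()
        p = (right * np.exp(lam * t)[None, :]) @ left
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)

    # -- tree bookkeeping ----------------------------------------------
    def _tree_cache(self) -> "_TreeCache":
        if self._cache is None:
            self._cache = _TreeCache(self.tree, self.clade_label)
        return self._cache

    @property
    def leaf_names(self) -> list[str]:
        return self._tree_cache().leaf_names

    @property
    def n_edges(self) -> int:
        return len(self._tree_cache().edges)

    def clade_names(self) -> list[str]:
        """Labels of flagged post-duplication clades (one per DUP node)."""
        return list(self._tree_cache().clades)

    def clade_edge_mask(self, clade: str | None = None) -> np.ndarray:
        """Boolean mask over edges inside (incl. the stem of) a flagged clade."""
        cache = self._tree_cache()
        if clade is None:
            if len(cache.clades) != 1:
                raise ValueError(
                    f"tree has {len(cache.clades)} flagged clades; name one of "
                    f"{list(cache.clades)}"
                )
            clade = next(iter(cache.clades))
        return cache.clades[clade]

    def clade_leaves(self, clade: str) -> list[str]:
        cache = self._tree_cache()
        mask = cache.clades[clade]
        names = set()
        for i, (child, _parent, _b) in enumerate(cache.edges):
            if mask[i] and child < len(cache.leaf_names):
                names.add(cache.leaf_names[child])
        return sorted(names)


class _TreeCache:
    """Postorder edge arrays for vectorized pruning."""

    def __init__(self, tree: dendropy.Tree, clade_label: str) -> None:
        leaves = [lf for lf in tree.leaf_node_iter()]
        self.leaf_names = [lf.taxon.label for lf in leaves]
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ValueError("duplicate leaf labels")
        index: dict[int, int] = {}
        for i, lf in enumerate(leaves):
            index[id(lf)] = i
        nxt = len(leaves)
        for nd in tree.postorder_node_iter():
            if id(nd) not in index:
                index[id(nd)] = nxt
                nxt += 1
        self.n_nodes = nxt
        self.root_index = index[id(tree.seed_node)]
        # edges in postorder: (child_idx, parent_idx, length)
        self.edges: list[tuple[int, int, float]] = []
        for nd in tree.postorder_node_iter():
            if nd.parent_node is not None:
                self.edges.append(
                    (index[id(nd)], index[id(nd.parent_node)], float(nd.edge.length or 0.0))
                )
        # flagged clades: label DUP (or DUP-suffixed to disambiguate several)
        self.clades: dict[str, np.ndarray] = {}
        for nd in tree.preorder_node_iter():
            label = getattr(nd, "label", None)
            if nd.is_leaf() or not label:
                continue
            if label == clade_label or label.startswith(clade_label + "_") or (
                clade_label == DUP_LABEL and label.startswith(DUP_LABEL)
            ):
                members = {id(x) for x in nd.preorder_iter()}
                # mark edges whose child node lies inside the clade (incl. stem)
                mask = np.zeros(len(self.edges), dtype=bool)
                for i, nd2 in enumerate(
                    n for n in tree.postorder_node_iter() if n.parent_node is not None
                ):
                    if id(nd2) in members:
                        mask[i] = True
                self.clades[label] = mask


def encode_alignment(
    alignment: Mapping[str, str], leaf_names: Sequence[str]
) -> np.ndarray:
    """Rows ordered by ``leaf_names``; -1 encodes gap/missing."""
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")
    missing = [n for n in leaf_names if n not in alignment]
    if missing:
        raise ValueError(f"alignment lacks sequences for leaves: {missing}")
    n_cols = lengths.pop()
    out = np.empty((len(leaf_names), n_cols), dtype=np.int8)
    for i, name in enumerate(leaf_names):
        for j, ch in enumerate(alignment[name].upper()):
            if ch in _MISSING:
                out[i, j] = -1
            elif ch in _AA_INDEX:
                out[i, j] = _AA_INDEX[ch]
            else:
                raise ValueError(f"unknown residue {ch!r} in sequence {name!r}")
    return out


def alignment_log_likelihoods(
    alignment: Mapping[str, str] | np.ndarray,
    model: PhyloModel,
    rate: float | np.ndarray = 1.0,
) -> np.ndarray:
    """Per-column pruning log-likelihoods.

    ``rate`` is a scalar multiplier applied to every branch, or an array of
    per-edge multipliers in the model's postorder edge order (the hook used
    by the two-rate constraint test).
    """
    cache = model._tree_cache()
    if isinstance(alignment, np.ndarray):
        data = alignment
    else:
        data = encode_alignment(alignment, cache.leaf_names)
    n_leaves = len(cache.leaf_names)
    n_cols = data.shape[1]
    rates = np.broadcast_to(np.asarray(rate, dtype=float), (len(cache.edges),))
    if np.any(rates <= 0):
        raise ValueError("rate multipliers must be positive")

    partial = np.ones((cache.n_nodes, n_cols, 20))
    for i in range(n_leaves):
        col = data[i]
        obs = col >= 0
        partial[i, obs, :] = 0.0
        partial[i, obs, col[obs]] = 1.0

    log_scale = np.zeros(n_cols)
    for (child, parent, blen), rho in zip(cache.edges, rates):
        p = model.transition_matrix(blen * rho)
        partial[parent] *= partial[child] @ p.T
        mx = partial[parent].max(axis=1)
        mx[mx == 0] = 1.0  # impossible column; log(0) surfaces at the root
        partial[parent] /= mx[:, None]
        log_scale += np.log(mx)

    site = partial[cache.root_index] @ model.frequencies
    with np.errstate(divide="ignore"):
        return np.log(site) + log_scale


def column_likelihood(
    column: Mapping[str, str] | str | Sequence[str],
    model: PhyloModel,
    rate: float = 1.0,
) -> float:
    """Log-likelihood of a single alignment column at a given rate multiplier.

    ``column`` maps leaf name to a one-letter residue (or gap); a bare
    string/sequence is taken in the model's leaf order.
    """
    names = model.leaf_names
    if isinstance(column, Mapping):
        aln = {k: str(v) for k, v in column.items()}
    else:
        if len(column) != len(names):
            raise ValueError("column length must match number of leaves")
        aln = {n: c for n, c in zip(names, column)}
    return float(alignment_log_likelihoods(aln, model, rate)[0])
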