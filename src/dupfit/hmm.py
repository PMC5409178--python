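"""Two-state rate HMM over alignment columns.

State 0 ("conserved") multiplies every branch length by rho_c < 1; state 1
("background") leaves them untouched. Emissions are phylogenetic column
log-likelihoods, so this is a phylo-HMM in the usual sense: the hidden chain
runs along alignment columns and captures the spatial clustering of
constrained sites. Forward-backward is implemented both in scaled space and
in log space (the two must agree, and tests enforce it); Baum-Welch with
random restarts fits the transition matrix and the conserved-rate multiplier
when they are not supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import logsumexp

from . import phylo

__all__ = ["RateHMM", "forward_loglik", "posterior_decode", "fit_hmm"]

CONSERVED, BACKGROUND = 0, 1


@dataclass
class RateHMM:
    """Two-state (conserved/background) rate HMM.

    ``transitions[i, j]`` is P(state j at column c+1 | state i at column c);
    rows must sum to one. ``initial`` defaults to the chain's stationary
    distribution.
    """

    rho_conserved: float = 0.2
    transitions: np.ndarray = field(
        default_factory=lambda: np.array([[0.95, 0.05], [0.05, 0.95]])
    )
    initial: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.transitions.shape != (2, 2) or np.any(self.transitions < 0):
            raise ValueError("transitions must be a non-negative 2x2 matrix")
        if not np.allclose(self.transitions.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if not 0 < self.rho_conserved < 1:
            raise ValueError("rho_conserved must lie in (0, 1)")
        if self.initial is None:
            self.initial = self.stationary()
        self.initial = np.asarray(self.initial, dtype=float)
        if not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")

    def stationary(self) -> np.ndarray:
        a = self.transitions
        denom = a[0, 1] + a[1, 0]
        if denom == 0:
            return np.array([0.5, 0.5])
        return np.array([a[1, 0] / denom, a[0, 1] / denom])


def column_log_emissions(
    alignment: Mapping[str, str] | np.ndarray,
    model: phylo.PhyloModel,
    hmm: RateHMM,
) -> np.ndarray:
    """(n_cols, 2) log-emission matrix: conserved rate rho_c vs background 1."""
    le_c = phylo.alignment_log_likelihoods(alignment, model, hmm.rho_conserved)
    le_b = phylo.alignment_log_likelihoods(alignment, model, 1.0)
    return np.column_stack([le_c, le_b])


def forward_loglik(
    log_emissions: np.ndarray, hmm: RateHMM, method: str = "scaled"
) -> float:
    """Total forward log-likelihood of the column sequence.

    ``method="scaled"`` uses the classical per-column normalization;
    ``method="log"`` runs the recursion with logsumexp. Both are exact and
    must agree to high precision.
    """
    le = np.asarray(log_emissions, dtype=float)
    if le.ndim != 2 or le.shape[1] != 2 or le.shape[0] == 0:
        raise ValueError("log_emissions must be (n_cols, 2) with n_cols >= 1")
    if method == "scaled":
        # subtract the per-column max once so exp() stays in range
        shift = le.max(axis=1)
        e = np.exp(le - shift[:, None])
        alpha = hmm.initial * e[0]
        ll = shift[0]
        c = alpha.sum()
        alpha /= c
        ll += np.log(c)
        for t in range(1, le.shape[0]):
            alpha = (alpha @ hmm.transitions) * e[t]
            c = alpha.sum()
            alpha /= c
            ll += np.log(c) + shift[t]
        return float(ll)
    if method == "log":
        log_a = np.log(hmm.transitions)
        la = np.log(hmm.initial) + le[0]
        for t in range(1, le.shape[0]):
            la = logsumexp(la[:, None] + log_a, axis=0) + le[t]
        return float(logsumexp(la))
    raise ValueError(f"unknown method {method!r}")


def posterior_decode(
    log_emissions: np.ndarray, hmm: RateHMM
) -> tuple[np.ndarray, float, np.ndarray]:
    """Forward-backward: per-column state posteriors.

    Returns ``(gamma, loglik, xi_sum)`` where ``gamma[t, k]`` is
    P(state k | data), and ``xi_sum[i, j]`` the expected number of i->j
    transitions (used by Baum-Welch).
    """
    le = np.asarray(log_emissions, dtype=float)
    n = le.shape[0]
    shift = le.max(axis=1)
    e = np.exp(le - shift[:, None])
    a = hmm.transitions

    alpha = np.empty((n, 2))
    c = np.empty(n)
    alpha[0] = hmm.initial * e[0]
    c[0] = alpha[0].sum()
    alpha[0] /= c[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ a) * e[t]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]

    beta = np.empty((n, 2))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (a @ (e[t + 1] * beta[t + 1])) / c[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi_sum = np.zeros((2, 2))
    for t in range(n - 1):
        xi = (alpha[t][:, None] * a) * (e[t + 1] * beta[t + 1])[None, :] / c[t + 1]
        xi_sum += xi
    loglik = float(np.sum(np.log(c)) + np.sum(shift))
    return gamma, loglik, xi_sum


def fit_hmm(
    alignment: Mapping[str, str] | np.ndarray,
    model: phylo.PhyloModel,
    n_restarts: int = 10,
    init_rho: float = 0.2,
    init_self: float = 0.95,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-6,
    rho_bounds: tuple[float, float] = (1e-3, 0.999),
) -> RateHMM:
    """Baum-Welch fit of (rho_c, transitions) with jittered random restarts.

    The background emission vector is fixed (rate 1); each M-step updates
    the transition matrix in closed form and refits rho_c by golden-section
    maximization of the posterior-weighted conserved emission term. The
    restart with the best final likelihood wins.
    """
    cache_leafs = model.leaf_names
    if not isinstance(alignment, np.ndarray):
        alignment = phylo.encode_alignment(alignment, cache_leafs)
    le_b = phylo.alignment_log_likelihoods(alignment, model, 1.0)

    def emission_at(rho: float) -> np.ndarray:
        le_c = phylo.alignment_log_likelihoods(alignment, model, rho)
        return np.column_stack([le_c, le_b])

    rng = np.random.default_rng(seed)
    best: tuple[float, RateHMM] | None = None
    for restart in range(n_restarts):
        if restart == 0:
            rho = init_rho
            self_p = init_self
        else:
            rho = float(np.clip(init_rho * np.exp(rng.normal(0, 0.7)), *rho_bounds))
            self_p = float(rng.uniform(0.7, 0.995))
        hmm = RateHMM(rho, np.array([[self_p, 1 - self_p], [1 - self_p, self_p]]))
        prev = -np.inf
        for _ in range(max_iter):
            le = emission_at(hmm.rho_conserved)
            gamma, ll, xi = posterior_decode(le, hmm)
            if abs(ll - prev) < tol:
                prev = ll
                break
            prev = ll
            trans = xi / np.clip(xi.sum(axis=1, keepdims=True), 1e-300, None)
            trans = np.clip(trans, 1e-6, None)
            trans /= trans.sum(axis=1, keepdims=True)
            w = gamma[:, CONSERVED]

            def expected_ll(r: float) -> float:
                return float(
                    np.dot(w, phylo.alignment_log_likelihoods(alignment, model, r))
                )

            rho_new = _golden_max(expected_ll, *rho_bounds, tol=1e-4)
            try:
                hmm = RateHMM(rho_new, trans, initial=hmm.stationary())
            except ValueError:
                break
        if best is None or prev > best[0]:
            best = (prev, hmm)
    assert best is not None
    return best[1]


def _golden_max(f, lo: float, hi: float, tol: float = 1e-6) -> float:
    """Golden-section maximization of a unimodal scalar function."""
    invphi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1, f2 = f(x1), f(x2)
    while b - a > tol:
        if f1 >= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - invphi * (b - a)
            f1 = f(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + invphi * (b - a)
            f2 = f(x2)
    return 0.5 * (a + b)
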