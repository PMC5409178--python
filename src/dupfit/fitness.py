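"""Selection-coefficient inference from competitive flow-cytometry counts.

Two fluorescently labelled strains (red and green) are grown in co-culture
under serial dilution. Under deterministic logistic competition the red
frequency R obeys dR/dt = s R G with G = 1 - R, whose solution is linear on
the log-odds scale:

    logit R(t) = logit R(0) + s t

so the selection coefficient *s* is the per-generation change in log-odds of
sampling a red cell. Counts at each assayed generation are modelled as
binomial draws from R(t), giving the likelihood

    L = prod_t C(n_t, r_t) R(t)^{r_t} (1 - R(t))^{n_t - r_t}

which is exactly a binomial logistic regression of the red fraction on
generation number. This module provides the trajectory, the likelihood, the
closed-form two-timepoint estimator, the general Newton/IRLS MLE, the
censoring rules for undetectable competitors, assay-resolution summaries,
replicate-consistent effect calls, and the effective-population-size
arithmetic of the serial-dilution design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

__all__ = [
    "CompetitionCounts",
    "SelectionEstimate",
    "ResolutionSummary",
    "AssayConfig",
    "logistic_trajectory",
    "log_likelihood",
    "estimate_s_closed_form",
    "estimate_s_mle",
    "censor_competition",
    "detection_limit",
    "estimate_resolution",
    "call_effect",
    "estimate_ne",
]

Status = Literal["measured", "censored_low", "equally_lethal"]


@dataclass(frozen=True)
class CompetitionCounts:
    """Red/green cell counts for one competition well.

    ``timepoints`` are generation numbers; ``red`` and ``green`` are the
    cells of each colour counted at the matching generation.
    """

    well_id: str
    timepoints: tuple[float, ...]
    red: tuple[int, ...]
    green: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.timepoints) == len(self.red) == len(self.green)):
            raise ValueError("timepoints, red and green must have equal length")
        if any(t < 0 for t in self.timepoints):
            raise ValueError("generations must be non-negative")
        if list(self.timepoints) != sorted(self.timepoints):
            raise ValueError("timepoints must be increasing")
        if any(r < 0 or int(r) != r for r in self.red) or any(
            g < 0 or int(g) != g for g in self.green
        ):
            raise ValueError("counts must be non-negative integers")

    @property
    def totals(self) -> tuple[int, ...]:
        return tuple(r + g for r, g in zip(self.red, self.green))


@dataclass(frozen=True)
class SelectionEstimate:
    """A fitted (or censored) selection coefficient for one well.

    ``status`` is ``measured`` for a numeric fit, ``censored_low`` when one
    competitor fell below countable abundance (s reported at the +/-0.3
    bound, sign against the depleted channel), or ``equally_lethal`` when
    both strains collapsed (reported s = 0).
    """

    well_id: str
    s: float
    R0_hat: float | None = None
    status: Status = "measured"
    se: float | None = None
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.status == "measured" and not math.isfinite(self.s):
            raise ValueError("measured estimates must be finite")
        if self.status == "censored_low" and abs(self.s) != CENSOR_BOUND:
            raise ValueError(f"censored estimates carry the bound {CENSOR_BOUND}")


CENSOR_BOUND = 0.3


@dataclass(frozen=True)
class ResolutionSummary:
    """Null-competition summary: resolution = 1.96 x SD of the null estimates."""

    mean_s: float
    sd_s: float
    resolution: float
    call_threshold: float = 0.005
    n: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(self.resolution, 1.96 * self.sd_s, rel_tol=0, abs_tol=1e-15):
            raise ValueError("resolution must equal 1.96 * sd_s")
        if self.call_threshold < self.resolution:
            raise ValueError("call_threshold must be >= resolution")


@dataclass(frozen=True)
class AssayConfig:
    """Censoring floors and design constants of the competition assay."""

    min_channel_count: int = 50
    min_total_count: int = 50
    max_magnitude: float = CENSOR_BOUND
    detect_denominator: int = 50_000
    Ne: float = 3.44e5  # informational
    dilution_factor: int = 1024
    call_threshold: float = 0.005

    def __post_init__(self) -> None:
        for name in ("min_channel_count", "min_total_count", "max_magnitude",
                     "detect_denominator", "dilution_factor", "call_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def logistic_trajectory(R0: float, s: float, t: float | np.ndarray) -> float | np.ndarray:
    """Expected red frequency R(t) = R0 e^{st} / ((1-R0) + R0 e^{st}).

    Evaluated in log-odds space: logit R(t) = logit R0 + s t, which is safe
    for strongly deleterious s where the naive form underflows.
    """
    if not 0.0 < R0 < 1.0:
        raise ValueError("R0 must lie strictly inside (0, 1)")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = expit(logit(R0) + s * t)
    return float(out) if out.ndim == 0 else out


def log_likelihood(counts: CompetitionCounts, R0: float, s: float) -> float:
    """Binomial log-likelihood of the counts under the logistic trajectory.

    Includes the combinatorial constants (scipy's binomial log-pmf), so the
    value is the full log of the product likelihood.
    """
    t = np.asarray(counts.timepoints, dtype=float)
    r = np.asarray(counts.red)
    n = np.asarray(counts.totals)
    p = logistic_trajectory(R0, s, t)
    return float(np.sum(stats.binom.logpmf(r, n, p)))


def _check_positive_counts(counts: CompetitionCounts) -> None:
    if any(r == 0 for r in counts.red) or any(g == 0 for g in counts.green):
        raise ValueError(
            "zero count in a channel: apply censoring (censor_competition) first"
        )


def estimate_s_closed_form(counts: CompetitionCounts) -> SelectionEstimate:
    """Two-timepoint estimator s = [log(r2/g2) - log(r1/g1)] / (t2 - t1).

    This is the exact MLE for two timepoints. R0_hat is back-extrapolated
    from the fitted log-odds line to t = 0; the standard error is the
    delta-method value sqrt(1/r1 + 1/g1 + 1/r2 + 1/g2) / (t2 - t1).
    """
    if len(counts.timepoints) != 2:
        raise ValueError("closed form requires exactly two timepoints")
    _check_positive_counts(counts)
    (t1, t2) = counts.timepoints
    (r1, r2), (g1, g2) = counts.red, counts.green
    lo1 = math.log(r1 / g1)
    lo2 = math.log(r2 / g2)
    s = (lo2 - lo1) / (t2 - t1)
    R0 = expit(lo1 - s * t1)
    se = math.sqrt(1 / r1 + 1 / g1 + 1 / r2 + 1 / g2) / (t2 - t1)
    return SelectionEstimate(counts.well_id, s, R0_hat=float(R0), se=se)


def estimate_s_mle(
    counts: CompetitionCounts,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> SelectionEstimate:
    """Joint MLE of (R0, s) by Newton's method on the binomial likelihood.

    The model is a logistic regression of red counts on generation with
    intercept logit R0 and slope s; Newton's method with the exact Fisher
    information is iterated until the log-likelihood changes by less than
    ``tol`` or ``max_iter`` is reached. Non-convergence is flagged on the
    returned estimate, never silently ignored.
    """
    if len(counts.timepoints) < 2:
        raise ValueError("need at least two timepoints")
    _check_positive_counts(counts)
    t = np.asarray(counts.timepoints, dtype=float)
    r = np.asarray(counts.red, dtype=float)
    n = np.asarray(counts.totals, dtype=float)
    X = np.column_stack([np.ones_like(t), t])

    # start from the log-odds least-squares line (exact at T=2)
    emp = np.log(r / (n - r))
    beta = np.linalg.lstsq(X, emp, rcond=None)[0]

    def lnl(b: np.ndarray) -> float:
        p = expit(X @ b)
        return float(np.sum(stats.binom.logpmf(r, n, p)))

    prev = lnl(beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = n * p * (1 - p)
        grad = X.T @ (r - n * p)
        info = X.T @ (w[:, None] * X)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # halve the step until the likelihood does not decrease
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            cur = lnl(cand)
            if cur >= prev - 1e-12:
                break
            lam /= 2
        beta = beta + lam * step
        cur = lnl(beta)
        if abs(cur - prev) < tol:
            converged = True
            prev = cur
            break
        prev = cur

    eta = X @ beta
    p = expit(eta)
    w = n * p * (1 - p)
    info = X.T @ (w[:, None] * X)
    try:
        se = float(np.sqrt(np.linalg.inv(info)[1, 1]))
    except np.linalg.LinAlgError:
        se = float("nan")
    return SelectionEstimate(
        counts.well_id,
        float(beta[1]),
        R0_hat=float(expit(beta[0])),
        se=se,
        converged=converged,
        message="" if converged else "Newton iteration did not converge",
    )


def censor_competition(
    counts: CompetitionCounts, config: AssayConfig | None = None
) -> SelectionEstimate | CompetitionCounts:
    """Apply the count-floor censoring rules, in order of precedence.

    1. If the total count at any timepoint is below ``min_total_count``,
       both strains collapsed: report s = 0, status ``equally_lethal``.
    2. Else if either channel is below ``min_channel_count`` at any
       timepoint, the estimate is unreliable: report the censoring bound
       (s = -0.3 when red is depleted, +0.3 when green is), status
       ``censored_low``.
    3. Otherwise pass the counts through for estimation.
    """
    config = config or AssayConfig()
    if any(tot < config.min_total_count for tot in counts.totals):
        return SelectionEstimate(counts.well_id, 0.0, status="equally_lethal")
    red_dep = any(r < config.min_channel_count for r in counts.red)
    green_dep = any(g < config.min_channel_count for g in counts.green)
    if red_dep or green_dep:
        sign = -1.0 if red_dep else 1.0
        return SelectionEstimate(
            counts.well_id, sign * config.max_magnitude, status="censored_low"
        )
    return counts


def fit_well(
    counts: CompetitionCounts, config: AssayConfig | None = None
) -> SelectionEstimate:
    """Censor then estimate: the per-well entry point used by the pipeline."""
    out = censor_competition(counts, config)
    if isinstance(out, SelectionEstimate):
        return out
    if len(out.timepoints) == 2:
        return estimate_s_closed_form(out)
    return estimate_s_mle(out)


def detection_limit(
    config: AssayConfig | None = None,
    R0: float = 0.5,
    t_final: float = 40.0,
    tol: float = 1e-6,
) -> float:
    """Selection coefficient at which the expected minority frequency hits
    1/detect_denominator at ``t_final`` generations, found by bisection.

    Bracket: [logit(1/D) - logit(R0)] / t_final is the analytic root; the
    bisection is run on logistic_trajectory to the requested |ds| < tol and
    the two must agree (the closed form serves as the bracket midpoint).
    """
    config = config or AssayConfig()
    if not 0 < R0 < 1:
        raise ValueError("R0 must be in (0,1)")
    if t_final <= 0:
        raise ValueError("t_final must be positive")
    target = 1.0 / config.detect_denominator
    if target >= 1:
        raise ValueError("detect_denominator must exceed 1")

    def f(s: float) -> float:
        return logistic_trajectory(R0, s, t_final) - target

    lo, hi = -10.0, 10.0
    if f(lo) * f(hi) > 0:
        raise ValueError("no root in bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def estimate_resolution(
    null_estimates: Iterable[float], call_threshold: float = 0.005
) -> ResolutionSummary:
    """Mean, sample SD (n-1 denominator) and 1.96*SD of null-competition s."""
    vals = np.asarray(list(null_estimates), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two null estimates")
    sd = float(np.std(vals, ddof=1))
    return ResolutionSummary(
        mean_s=float(np.mean(vals)),
        sd_s=sd,
        resolution=1.96 * sd,
        call_threshold=max(call_threshold, 1.96 * sd),
        n=int(vals.size),
    )


EffectCall = Literal["deleterious", "beneficial", "no_detectable_effect", "inconsistent"]


def call_effect(
    replicates: Sequence[SelectionEstimate],
    config: AssayConfig | None = None,
) -> EffectCall:
    """Consistent-replicate effect call for one genotype contrast.

    Replicates must already be oriented to the same contrast (the
    fluorophore-swapped replicate sign-flipped by the caller). Deleterious
    iff every replicate is at or below -threshold, beneficial iff every one
    is at or above +threshold; sign disagreement with at least one replicate
    past the threshold is inconsistent; anything else is no detectable
    effect. A censored replicate forces the call in its direction.
    """
    config = config or AssayConfig()
    if len(replicates) < 2:
        raise ValueError("replication is mandatory: need >= 2 replicate estimates")
    thr = config.call_threshold
    if any(e.status == "censored_low" and e.s < 0 for e in replicates):
        return "deleterious"
    if any(e.status == "censored_low" and e.s > 0 for e in replicates):
        return "beneficial"
    svals = [e.s for e in replicates]
    if all(s <= -thr for s in svals):
        return "deleterious"
    if all(s >= thr for s in svals):
        return "beneficial"
    if max(svals) > 0 > min(svals) and max(abs(s) for s in svals) >= thr:
        return "inconsistent"
    return "no_detectable_effect"


def estimate_ne(
    saturation_density: float = 2e8,
    culture_volume: float = 0.32,
    dilution_factor: float = 1024,
    generations_per_cycle: float | None = None,
) -> float:
    """Harmonic-mean effective population size over one dilution cycle.

    With bottleneck N_b = density * volume / dilution and g = log2(dilution)
    doublings per cycle, the census sizes are N_b * 2^i for i = 0..g-1 and

        Ne = g / sum_i 1 / (N_b 2^i).

    If the dilution factor is not a power of two, g = log2(dilution) is used
    with a warning (the schedule is then only approximately geometric).
    """
    if min(saturation_density, culture_volume, dilution_factor) <= 0:
        raise ValueError("inputs must be positive")
    g = generations_per_cycle
    if g is None:
        g = math.log2(dilution_factor)
        if abs(g - round(g)) > 1e-9:
            import warnings

            warnings.warn(
                "dilution factor is not a power of 2; using g = log2(dilution)",
                stacklevel=2,
            )
        else:
            g = round(g)
    n_b = saturation_density * culture_volume / dilution_factor
    denom = sum(1.0 / (n_b * 2**i) for i in range(int(math.ceil(g))))
    return g / denom
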