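"""K* scores: provable bounds on the binding-constant estimate, ranking, Δb.

The K* score of a sequence s is the ratio of state partition functions

    K*(s) = Z_C(s) / (Z_P(s) · Z_L(s)),

an ensemble-based estimate of the association constant K_a.  Each state's Z
comes with provable lower/upper bounds, which combine into bounds on
log10 K*:

    lower = z_lower(C) / (z_upper(P) · z_upper(L)),
    upper = z_upper(C) / (z_lower(P) · z_lower(L)).

The *point score* reported alongside the bounds is the classical K* score
z_lower(C)/(z_lower(P)·z_lower(L)) — the ratio of the accumulated per-state
lower bounds, which is how ε-approximate scores are conventionally quoted.

Δb is the retrospective change-in-binding statistic: the log10 of a
variant's percent change in K* relative to wild type, normalized so the
wild type sits at 0:

    Δb = log10(100 · K*_v / K*_WT) − 2 = log10(K*_v / K*_WT).

Positive Δb predicts improved binding, negative predicts decreased binding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .confspace import (
    DesignProblem,
    ROLES,
    Sequence,
    ValidationError,
    project_sequence,
)
from .partition import (
    DEFAULT_GUARD_LIMIT,
    LOG10E,
    PartitionFunctionResult,
    approx_partition_eps,
    ewakstar_partition,
    exact_partition,
)

__all__ = [
    "KStarScore",
    "DeltaB",
    "kstar_score",
    "rank_sequences",
    "delta_b",
    "PfuncCache",
]

METHODS = ("exact", "eps", "window")

#: Cache type for unbound-state partition functions: many design sequences
#: share an unbound projection, so its Z need only be computed once.
PfuncCache = dict


@dataclass(frozen=True)
class KStarScore:
    """Bounds and point estimate on log10 K* for one sequence."""

    sequence: Sequence
    method: str
    log10_lower: float
    log10_upper: float
    log10_score: float
    pfuncs: Mapping[str, PartitionFunctionResult]

    def __post_init__(self) -> None:
        if self.log10_lower > self.log10_upper + 1e-9:
            raise ValueError("log10_lower exceeds log10_upper")

    def to_dict(self) -> dict:
        return {
            "sequence": str(self.sequence),
            "method": self.method,
            "log10_lower": round(self.log10_lower, 4),
            "log10_upper": round(self.log10_upper, 4),
            "log10_score": round(self.log10_score, 4),
            "n_minimized": {
                role: self.pfuncs[role].n_minimized for role in ROLES
            },
        }


@dataclass(frozen=True)
class DeltaB:
    """Predicted change in binding of a variant relative to wild type."""

    variant: Sequence
    delta_b: float


def _estimate(
    state,
    sequence: Sequence,
    method: str,
    rt: float,
    epsilon: float | None,
    w_conf: float | None,
    guard_limit: int,
) -> PartitionFunctionResult:
    if method == "exact":
        return exact_partition(state, sequence, rt, guard_limit=guard_limit)
    if method == "eps":
        if epsilon is None:
            raise ValueError("method 'eps' requires epsilon")
        return approx_partition_eps(state, sequence, epsilon, rt)
    if method == "window":
        if w_conf is None:
            raise ValueError("method 'window' requires w_conf")
        return ewakstar_partition(state, sequence, w_conf, rt)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def kstar_score(
    problem: DesignProblem,
    sequence: Sequence,
    method: str = "exact",
    epsilon: float | None = None,
    w_conf: float | None = None,
    rt: float | None = None,
    guard_limit: int = DEFAULT_GUARD_LIMIT,
    cache: PfuncCache | None = None,
) -> KStarScore:
    """Compute K* bounds for one complex sequence.

    The three state partition functions are evaluated on the sequence's
    projections with the same estimator.  ``cache`` (an ordinary dict) reuses
    unbound-state results across sequences sharing a projection.
    """
    if rt is None:
        rt = problem.constants.RT
    problem.complex.validate_sequence(sequence)
    pfuncs: dict[str, PartitionFunctionResult] = {}
    for role in ROLES:
        proj = project_sequence(problem, sequence, role)
        key = (role, proj, method, epsilon, w_conf, rt)
        if cache is not None and role != "complex" and key in cache:
            pfuncs[role] = cache[key]
            continue
        res = _estimate(
            problem.states[role], proj, method, rt, epsilon, w_conf, guard_limit
        )
        if cache is not None and role != "complex":
            cache[key] = res
        pfuncs[role] = res
    c, p, l = pfuncs["complex"], pfuncs["protein"], pfuncs["ligand"]
    lower = c.log_z_lower - p.log_z_upper - l.log_z_upper
    upper = c.log_z_upper - p.log_z_lower - l.log_z_lower
    score = c.log_z_lower - p.log_z_lower - l.log_z_lower
    return KStarScore(
        sequence=sequence,
        method=method,
        log10_lower=lower * LOG10E,
        log10_upper=upper * LOG10E,
        log10_score=score * LOG10E,
        pfuncs=pfuncs,
    )


def rank_sequences(
    problem: DesignProblem,
    candidates: Iterable[Sequence],
    top_m: int | None = None,
    method: str = "exact",
    epsilon: float | None = None,
    w_conf: float | None = None,
    rt: float | None = None,
    guard_limit: int = DEFAULT_GUARD_LIMIT,
) -> list[KStarScore]:
    """Score all candidates and return the top ``top_m`` in decreasing K*.

    Ordering contract: sequences are sorted by descending log10 lower bound
    (ties broken deterministically on the sequence itself), which reproduces
    the exact descending-K* order whenever the returned bound intervals are
    pairwise disjoint.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValidationError("rank_sequences: empty candidate set")
    cache: PfuncCache = {}
    scores = [
        kstar_score(
            problem,
            seq,
            method=method,
            epsilon=epsilon,
            w_conf=w_conf,
            rt=rt,
            guard_limit=guard_limit,
            cache=cache,
        )
        for seq in candidates
    ]
    scores.sort(key=lambda s: (-s.log10_lower, s.sequence.assignment))
    if top_m is not None:
        scores = scores[: max(0, top_m)]
    return scores


def delta_b(variant_score: KStarScore, wildtype_score: KStarScore) -> DeltaB:
    """Δb = log10(100·K*_v/K*_WT) − 2, evaluated on the point scores.

    The percent-change and the −2 normalization cancel to a log-ratio, so
    the wild type itself scores exactly 0 under any estimator applied
    consistently to both arguments.
    """
    wt = wildtype_score.log10_score
    if not math.isfinite(wt):
        raise ValidationError("wild-type K* score is zero or undefined")
    v = variant_score.log10_score
    return DeltaB(variant=variant_score.sequence, delta_b=v - wt)
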