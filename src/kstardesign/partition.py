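"""Partition-function estimators over rotamer ensembles.

The partition function of a sequence s in state x is the Boltzmann-weighted
sum Z_x(s) = Σ_{d ∈ Q(s)} exp(−E_x(d)/RT) over its conformations, with
E_x(d) the minimized energy.  Three estimators are provided:

* :func:`exact_partition` — exhausts the space (oracle; guarded).
* :func:`approx_partition_eps` — the ε-approximation: enumerate
  conformations by lower bound, minimize each, and stop once the provable
  remainder (remaining count × the Boltzmann weight of the next lower bound)
  is at most an ε fraction of the total upper bound.  Guarantees
  z_lower ≥ (1−ε)·Z.
* :func:`ewakstar_partition` — the energy-window estimator: stop once the
  next lower bound exceeds the best minimized energy seen so far plus the
  window w_conf.  Guarantees the retained ensemble contains every
  conformation whose minimized energy is within w_conf of the GMEC's
  (because lower bounds never exceed minimized energies).

All accumulation is in the natural-log domain (numpy.logaddexp), so Z values
spanning hundreds of orders of magnitude neither overflow nor underflow.
Every enumerated conformation is minimized; the two counts coincide by
policy, which keeps the bounds conservative and the bookkeeping simple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .confspace import DesignProblemError, Sequence, State, conf_count

__all__ = [
    "GuardLimitError",
    "PartitionFunctionResult",
    "exact_partition",
    "approx_partition_eps",
    "ewakstar_partition",
    "LOG10E",
]

LOG10E = math.log10(math.e)

#: Default refusal threshold for exhaustive evaluation.
DEFAULT_GUARD_LIMIT = 1_000_000


class GuardLimitError(DesignProblemError):
    """Exhaustive evaluation refused: the conformation space is too large."""


@dataclass(frozen=True)
class PartitionFunctionResult:
    """Provable bounds on Z in the natural-log domain, with provenance.

    ``log_z_lower``/``log_z_upper`` bracket ln Z; ``halting_reason`` is one
    of ``exhausted`` (bounds coincide at the exact value), ``epsilon_met``
    or ``window_exceeded``.  ``ensemble`` optionally retains the minimized
    conformations that make up the lower bound.
    """

    log_z_lower: float
    log_z_upper: float
    n_enumerated: int
    n_minimized: int
    halting_reason: str
    ensemble: tuple[tuple[tuple[tuple[str, str], ...], float], ...] | None = None

    def __post_init__(self) -> None:
        if self.log_z_lower > self.log_z_upper + 1e-9:
            raise ValueError("z_lower exceeds z_upper")

    @property
    def log10_z_lower(self) -> float:
        return self.log_z_lower * LOG10E

    @property
    def log10_z_upper(self) -> float:
        return self.log_z_upper * LOG10E

    def to_dict(self) -> dict:
        return {
            "log_z_lower": self.log_z_lower,
            "log_z_upper": self.log_z_upper,
            "log10_z_lower": self.log10_z_lower,
            "log10_z_upper": self.log10_z_upper,
            "n_enumerated": self.n_enumerated,
            "n_minimized": self.n_minimized,
            "halting_reason": self.halting_reason,
        }


def _log_count(n: int) -> float:
    return math.log(n) if n > 0 else -math.inf


def _run(
    state: State,
    sequence: Sequence,
    rt: float,
    should_halt,
    keep_ensemble: bool,
) -> tuple[float, float, int, str, list]:
    """Shared enumerate-minimize-accumulate loop.

    ``should_halt(log_q, n_done, next_lb, e_min)`` is consulted after each
    minimization, with ``next_lb`` the lower bound of the next queued
    conformation.  Returns (log_q, log_remainder, n, reason, ensemble).
    """
    if rt <= 0:
        raise ValueError("RT must be > 0")
    from .astar import enumerate_conformations

    total = conf_count(state, sequence)
    stream = enumerate_conformations(state, sequence)
    log_q = -math.inf
    e_min = math.inf
    n = 0
    ensemble: list = []
    nxt = next(stream, None)
    while nxt is not None:
        conf, lb = nxt
        e = state.minimizer.energy(state.role, conf, lb)
        log_q = float(np.logaddexp(log_q, -e / rt))
        e_min = min(e_min, e)
        n += 1
        if keep_ensemble:
            ensemble.append((conf, e))
        nxt = next(stream, None)
        if nxt is None:
            return log_q, -math.inf, n, "exhausted", ensemble
        next_lb = nxt[1]
        reason = should_halt(log_q, n, next_lb, e_min)
        if reason is not None:
            log_rem = _log_count(total - n) - next_lb / rt
            return log_q, log_rem, n, reason, ensemble
    # empty conformation space cannot occur (rotamer lists are non-empty),
    # but an exhausted stream with zero yields would land here
    return log_q, -math.inf, n, "exhausted", ensemble


def _result(
    log_q: float, log_rem: float, n: int, reason: str, ensemble: list, keep: bool
) -> PartitionFunctionResult:
    return PartitionFunctionResult(
        log_z_lower=log_q,
        log_z_upper=float(np.logaddexp(log_q, log_rem)),
        n_enumerated=n,
        n_minimized=n,
        halting_reason=reason,
        ensemble=tuple(ensemble) if keep else None,
    )


def exact_partition(
    state: State,
    sequence: Sequence,
    rt: float,
    guard_limit: int = DEFAULT_GUARD_LIMIT,
    keep_ensemble: bool = False,
) -> PartitionFunctionResult:
    """Exact Z by exhaustive minimization of every conformation.

    Refuses (``GuardLimitError``) when the space exceeds ``guard_limit``
    conformations; this estimator is the oracle for small spaces, not a
    production path.
    """
    total = conf_count(state, sequence)
    if total > guard_limit:
        raise GuardLimitError(
            f"state {state.role}, sequence {sequence}: {total} conformations "
            f"exceed the guard limit of {guard_limit}"
        )
    log_q, log_rem, n, reason, ens = _run(
        state, sequence, rt, lambda *a: None, keep_ensemble
    )
    return _result(log_q, log_rem, n, reason, ens, keep_ensemble)


def approx_partition_eps(
    state: State,
    sequence: Sequence,
    epsilon: float,
    rt: float,
    keep_ensemble: bool = False,
) -> PartitionFunctionResult:
    """ε-approximate Z: provably z_lower ≥ (1−ε)·Z and z_lower ≤ Z ≤ z_upper.

    Halts once remainder/(q_sum + remainder) ≤ ε, where the remainder bounds
    the unenumerated mass by (remaining count)·exp(−next lb/RT).  ε = 0
    exhausts the space.
    """
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must be in [0, 1)")
    total = conf_count(state, sequence)

    def halt(log_q: float, n: int, next_lb: float, e_min: float):
        if epsilon == 0.0:
            return None
        log_rem = _log_count(total - n) - next_lb / rt
        frac = math.exp(log_rem - float(np.logaddexp(log_q, log_rem)))
        return "epsilon_met" if frac <= epsilon else None

    log_q, log_rem, n, reason, ens = _run(state, sequence, rt, halt, keep_ensemble)
    return _result(log_q, log_rem, n, reason, ens, keep_ensemble)


def ewakstar_partition(
    state: State,
    sequence: Sequence,
    w_conf: float,
    rt: float,
    keep_ensemble: bool = False,
) -> PartitionFunctionResult:
    """Energy-window Z: minimize conformations until the next lower bound
    exceeds (best minimized energy so far) + w_conf.

    Because each conformation's lower bound never exceeds its minimized
    energy, and the best-so-far minimized energy never exceeds the true
    GMEC energy plus anything, the retained ensemble provably contains every
    conformation with minimized energy ≤ GMEC + w_conf.  All minimized
    conformations contribute to z_lower (a strictly tighter valid lower
    bound than the in-window subset alone).
    """
    if w_conf < 0:
        raise ValueError("w_conf must be >= 0")

    def halt(log_q: float, n: int, next_lb: float, e_min: float):
        return "window_exceeded" if next_lb > e_min + w_conf else None

    log_q, log_rem, n, reason, ens = _run(state, sequence, rt, halt, keep_ensemble)
    return _result(log_q, log_rem, n, reason, ens, keep_ensemble)
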