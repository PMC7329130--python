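"""FRIES: provable sequence-space pruning around the wild type.

For each state independently, sequences are enumerated in order of their
optimal lower-bound energy E_v^⊖ until the wild type appears; the minimized
energy E_WT of the wild type's first conformation (by lower bound) anchors
an energy window, and enumeration continues while E_v^⊖ ≤ E_WT + w — every
sequence never enumerated is provably outside the window.  Each enumerated
sequence then faces a partition-function magnitude test built from two
provable bounds:

    q_v^⊕  = |Q(v)| · exp(−E_v^⊖ / RT)      (upper bound on Z_v)
    q_WT^⊖ = exp(−E_WT / RT)                (lower bound on Z_WT)

and is pruned when its upper bound is provably more than m orders of
magnitude below the wild type's lower bound.  A design sequence survives the
whole problem only if its projection survives in the protein, the ligand and
the complex state.

The magnitude criterion is configurable: the default direction prunes v iff
ln q_v^⊕ < ln q_WT^⊖ − m·ln(base), i.e. keeps a sequence unless it is
provably worse (less stable) than wild type by more than m orders — the
intent of removing markedly destabilized sequences.  The literal inequality
ln q_v^⊕ ≤ ln q_WT^⊖ + m as a keep rule (which would instead prune
sequences more stable than wild type) is available behind
``eq6_as_printed`` for fidelity experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence as TSequence

from .astar import enumerate_conformations, enumerate_sequences
from .confspace import (
    DesignProblem,
    ROLES,
    Sequence,
    State,
    ValidationError,
    conf_count,
    project_sequence,
)

__all__ = [
    "FriesParams",
    "FriesSequenceRecord",
    "FriesStateReport",
    "fries_prune_state",
    "fries_prune_problem",
]


@dataclass(frozen=True)
class FriesParams:
    """Pruning thresholds.

    w: sequence energy window above E_WT, kcal/mol.
    m: allowance in orders of magnitude for the partition-function test.
    m_log_base: base of those "orders" (10 per common usage; e is the
        literal unit of the natural-log inequality).
    eq6_as_printed: apply the magnitude inequality in its literal printed
        direction instead of the default stability-protective direction.
    """

    w: float
    m: float
    m_log_base: float = 10.0
    eq6_as_printed: bool = False

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("w must be >= 0")
        if self.m < 0:
            raise ValueError("m must be >= 0")
        if self.m_log_base not in (10.0, math.e):
            raise ValueError("m_log_base must be 10 or e")


@dataclass(frozen=True)
class FriesSequenceRecord:
    """Per-sequence diagnostics for one enumerated sequence in one state."""

    sequence: Sequence
    ev_lower: float  # E_v^⊖
    log_qv_upper: float  # ln q_v^⊕
    decision: str  # kept | pruned_magnitude


@dataclass
class FriesStateReport:
    survivors: set[Sequence]
    e_wt: float
    n_sequences_total: int
    n_enumerated: int
    n_pruned_window: int
    n_pruned_magnitude: int
    records: list[FriesSequenceRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "e_wt": self.e_wt if not math.isnan(self.e_wt) else None,
            "n_sequences_total": self.n_sequences_total,
            "n_enumerated": self.n_enumerated,
            "n_pruned_window": self.n_pruned_window,
            "n_pruned_magnitude": self.n_pruned_magnitude,
            "n_survivors": len(self.survivors),
            "survivors": sorted(str(s) for s in self.survivors),
        }


def _space_size(state: State, space: Mapping[int, TSequence[str]] | None) -> int:
    n = 1
    for pos in state.mutable_positions:
        if space is not None and pos.index in space:
            n *= len(space[pos.index])
        else:
            n *= len(pos.allowed_types)
    return n


def fries_prune_state(
    state: State,
    wild_type: Sequence,
    params: FriesParams,
    rt: float,
    space: Mapping[int, TSequence[str]] | None = None,
) -> FriesStateReport:
    """Prune one state's sequence space around its wild-type projection.

    Sequences enumerated before the wild type satisfy the window criterion
    automatically (their E_v^⊖ is below the wild type's, which is below
    E_WT).  The wild type itself always survives.  A state with no mutable
    positions keeps its single empty sequence and prunes nothing.
    """
    state.validate_sequence(wild_type)
    total = _space_size(state, space)
    if not state.mutable_positions:
        return FriesStateReport(
            survivors={Sequence()},
            e_wt=math.nan,
            n_sequences_total=1,
            n_enumerated=1,
            n_pruned_window=0,
            n_pruned_magnitude=0,
            records=[],
        )

    stream = enumerate_sequences(state, space)
    enumerated: list[tuple[Sequence, float]] = []
    for seq, ev in stream:
        enumerated.append((seq, ev))
        if seq == wild_type:
            break
    else:
        raise ValidationError(
            f"state {state.role}: wild type {wild_type} not in the sequence space"
        )

    # Window anchor: minimized energy of the wild type's first conformation
    # by lower bound (conservative: not necessarily its GMEC).
    conf, lb = next(enumerate_conformations(state, wild_type))
    e_wt = state.minimizer.energy(state.role, conf, lb)

    for seq, ev in stream:
        if ev > e_wt + params.w:
            break
        enumerated.append((seq, ev))

    log_q_wt = -e_wt / rt
    slack = params.m * math.log(params.m_log_base)
    survivors: set[Sequence] = set()
    records: list[FriesSequenceRecord] = []
    n_mag = 0
    for seq, ev in enumerated:
        log_q_up = math.log(conf_count(state, seq)) - ev / rt
        if seq == wild_type:
            keep = True
        elif params.eq6_as_printed:
            keep = log_q_up <= log_q_wt + slack
        else:
            keep = log_q_up >= log_q_wt - slack
        if keep:
            survivors.add(seq)
        else:
            n_mag += 1
        records.append(
            FriesSequenceRecord(
                sequence=seq,
                ev_lower=ev,
                log_qv_upper=log_q_up,
                decision="kept" if keep else "pruned_magnitude",
            )
        )
    return FriesStateReport(
        survivors=survivors,
        e_wt=e_wt,
        n_sequences_total=total,
        n_enumerated=len(enumerated),
        n_pruned_window=total - len(enumerated),
        n_pruned_magnitude=n_mag,
        records=records,
    )


def fries_prune_problem(
    problem: DesignProblem,
    params: FriesParams,
    rt: float | None = None,
) -> tuple[set[Sequence], dict[str, FriesStateReport]]:
    """Prune the three states independently and intersect.

    Returns the surviving complex sequences (those whose projections survive
    in every state) plus the per-state reports.
    """
    if rt is None:
        rt = problem.constants.RT
    reports: dict[str, FriesStateReport] = {}
    for role in ROLES:
        wt_proj = project_sequence(problem, problem.wild_type_sequence, role)
        reports[role] = fries_prune_state(problem.states[role], wt_proj, params, rt)
    survivors = {
        seq
        for seq in reports["complex"].survivors
        if project_sequence(problem, seq, "protein") in reports["protein"].survivors
        and project_sequence(problem, seq, "ligand") in reports["ligand"].survivors
    }
    return survivors, reports
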