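"""Brute-force oracles, independent of the package's A*/estimator paths.

Everything here enumerates exhaustively with itertools and evaluates
energies by direct matrix summation, so it can check gap-freeness, ordering,
partition-function bounds and pruning decisions on small spaces.
"""

from __future__ import annotations

import itertools
import math

from kstardesign.confspace import (
    DesignProblem,
    ROLES,
    Sequence,
    State,
    project_sequence,
)


def conf_options(state: State, sequence: Sequence):
    """Per-position (type, rotamer) options of a sequence, lexicographic."""
    opts = []
    for pos in state.positions:
        rtype = state.assigned_type(pos, sequence)
        opts.append([(rtype.name, r) for r in rtype.rotamers])
    return opts


def brute_conformations(state: State, sequence: Sequence):
    """All (conformation, lower-bound energy), in lexicographic option order."""
    em = state.ematrix
    out = []
    for conf in itertools.product(*conf_options(state, sequence)):
        e = em.const
        for i, (ti, ri) in enumerate(conf):
            e += em.single(i, ti, ri)
            for j in range(i + 1, len(conf)):
                tj, rj = conf[j]
                e += em.pair(i, ti, ri, j, tj, rj)
        out.append((conf, e))
    return out


def brute_minimized(state: State, sequence: Sequence):
    """All (conformation, minimized energy)."""
    return [
        (conf, state.minimizer.energy(state.role, conf, lb))
        for conf, lb in brute_conformations(state, sequence)
    ]


def brute_ev_lower(state: State, sequence: Sequence) -> float:
    """E_v^⊖: minimum lower-bound energy over the sequence's conformations."""
    return min(lb for _, lb in brute_conformations(state, sequence))


def brute_e_wt_anchor(state: State, wild_type: Sequence) -> float:
    """Minimized energy of the wild type's first conformation by lower bound
    (ties broken lexicographically, matching the enumeration contract)."""
    confs = brute_conformations(state, wild_type)
    conf, lb = min(confs, key=lambda item: item[1])  # stable: first minimal
    return state.minimizer.energy(state.role, conf, lb)


def brute_log_z(state: State, sequence: Sequence, rt: float) -> float:
    """ln Z over minimized energies, exhaustively (log-domain, shift trick)."""
    energies = [e for _, e in brute_minimized(state, sequence)]
    m = min(energies)
    return -m / rt + math.log(math.fsum(math.exp(-(e - m) / rt) for e in energies))


def brute_gmec_energy(state: State, sequence: Sequence) -> float:
    """True GMEC minimized energy of a sequence."""
    return min(e for _, e in brute_minimized(state, sequence))


def all_state_sequences(state: State):
    """Every sequence of a state's full mutable space."""
    mut = state.mutable_positions
    if not mut:
        return [Sequence()]
    choice_sets = [[t.name for t in pos.allowed_types] for pos in mut]
    return [
        Sequence.from_dict({pos.index: name for pos, name in zip(mut, combo)})
        for combo in itertools.product(*choice_sets)
    ]


def brute_fries_state(state: State, wild_type: Sequence, w, m, rt,
                      m_log_base=10.0, eq6_as_printed=False):
    """Survivor set from exact E_v^⊖ and |Q(v)| for every sequence."""
    from kstardesign.confspace import conf_count

    e_wt = brute_e_wt_anchor(state, wild_type)
    log_q_wt = -e_wt / rt
    slack = m * math.log(m_log_base)
    survivors = set()
    for seq in all_state_sequences(state):
        ev = brute_ev_lower(state, seq)
        if ev > e_wt + w:
            continue
        log_q_up = math.log(conf_count(state, seq)) - ev / rt
        if seq == wild_type:
            survivors.add(seq)
        elif eq6_as_printed:
            if log_q_up <= log_q_wt + slack:
                survivors.add(seq)
        elif log_q_up >= log_q_wt - slack:
            survivors.add(seq)
    return survivors


def brute_fries_problem(problem: DesignProblem, w, m, rt=None, **kw):
    if rt is None:
        rt = problem.constants.RT
    per_state = {}
    for role in ROLES:
        wt = project_sequence(problem, problem.wild_type_sequence, role)
        state = problem.states[role]
        if not state.mutable_positions:
            per_state[role] = {Sequence()}
        else:
            per_state[role] = brute_fries_state(state, wt, w, m, rt, **kw)
    return {
        seq
        for seq in per_state["complex"]
        if project_sequence(problem, seq, "protein") in per_state["protein"]
        and project_sequence(problem, seq, "ligand") in per_state["ligand"]
    }


def brute_log10_kstar(problem: DesignProblem, sequence: Sequence, rt=None) -> float:
    """Exact log10 K* from exhaustive per-state partition functions."""
    if rt is None:
        rt = problem.constants.RT
    logs = {
        role: brute_log_z(
            problem.states[role], project_sequence(problem, sequence, role), rt
        )
        for role in ROLES
    }
    return (logs["complex"] - logs["protein"] - logs["ligand"]) / math.log(10)
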