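"""Gap-free best-first (A*) enumeration over rotamer conformation spaces.

Two enumerations, both lazy streams in non-decreasing order of the pairwise
lower-bound energy:

* :func:`enumerate_conformations` — all conformations of one sequence within
  a state, each with its exact lower-bound energy.
* :func:`enumerate_sequences` — all sequences of a state's mutable space,
  each with its exact optimal lower bound E_v^⊖ = min over the sequence's
  conformations of the lower-bound energy (the score a sequence pruning step
  needs).  Sequences come off a multi-sequence tree ordered by an admissible
  bound; a popped full sequence is refined to exactness by descending its
  single-sequence conformation tree to the first leaf and re-queued, so the
  emitted order is provably correct.

Both trees expand positions in static index order, with an admissible
heuristic of the classic pairwise form: for each unassigned position, the
best option's singles energy plus its interactions with the assigned prefix
plus, for each later unassigned position, the best pair energy available
there.  Ties break lexicographically on (type index, rotamer index), so
streams are fully deterministic.
"""

from __future__ import annotations

import heapq
from typing import Iterator, Mapping, Sequence as TSequence

from .confspace import (
    Sequence,
    State,
    ValidationError,
)

__all__ = ["enumerate_conformations", "enumerate_sequences"]

Conformation = tuple[tuple[str, str], ...]


def _conf_options(state: State, sequence: Sequence) -> list[list[tuple[str, str]]]:
    """Per-position (type, rotamer) options for one sequence: the assigned
    type's rotamers, in rotamer order."""
    state.validate_sequence(sequence)
    opts = []
    for pos in state.positions:
        rtype = state.assigned_type(pos, sequence)
        opts.append([(rtype.name, rot) for rot in rtype.rotamers])
    return opts


class _ConfTree:
    """A* tree over the conformations of one sequence in one state."""

    def __init__(self, state: State, sequence: Sequence):
        self.state = state
        opts = _conf_options(state, sequence)
        self.opts = opts
        n = len(opts)
        em = state.ematrix
        self.n = n
        self.singles = [
            [em.single(j, t, r) for (t, r) in opts[j]] for j in range(n)
        ]
        # pair[(i, j)][oi][oj], i < j
        self.pair: dict[tuple[int, int], list[list[float]]] = {}
        for i in range(n):
            for j in range(i + 1, n):
                self.pair[(i, j)] = [
                    [
                        em.pair(i, ti, ri, j, tj, rj)
                        for (tj, rj) in opts[j]
                    ]
                    for (ti, ri) in opts[i]
                ]
        # M[j][o] = singles + best possible pair with every later position:
        # a completion bound that only depends on j being in the unassigned
        # suffix (valid because expansion is in static index order).
        self.M = [
            [
                self.singles[j][o]
                + sum(min(self.pair[(j, k)][o]) for k in range(j + 1, n))
                for o in range(len(opts[j]))
            ]
            for j in range(n)
        ]

    def stream(self) -> Iterator[tuple[Conformation, float]]:
        n = self.n
        if n == 0:
            yield (), self.state.ematrix.const
            return
        # Node: (f, choices, depth, g, C) with C[j][o] = sum of pair energies
        # between option o at unassigned position j and the assigned prefix.
        root_c = [[0.0] * len(self.opts[j]) for j in range(n)]
        root_h = sum(min(m) for m in self.M)
        const = self.state.ematrix.const
        heap = [(const + root_h, (), 0, const, root_c)]
        while heap:
            f, choices, depth, g, c = heapq.heappop(heap)
            if depth == n:
                conf = tuple(self.opts[j][o] for j, o in enumerate(choices))
                yield conf, g
                continue
            for o in range(len(self.opts[depth])):
                child_g = g + self.singles[depth][o] + c[depth][o]
                child_c = c[:depth + 1]  # slots < depth+1 never read again
                h = 0.0
                for j in range(depth + 1, n):
                    pj = self.pair[(depth, j)][o]
                    cj = c[j]
                    row = [cj[p] + pj[p] for p in range(len(cj))]
                    child_c.append(row)
                    mj = self.M[j]
                    h += min(mj[p] + row[p] for p in range(len(row)))
                heapq.heappush(
                    heap, (child_g + h, choices + (o,), depth + 1, child_g, child_c)
                )


def enumerate_conformations(
    state: State, sequence: Sequence
) -> Iterator[tuple[Conformation, float]]:
    """Yield every conformation of ``sequence`` exactly once, as
    (conformation, lower-bound energy), in non-decreasing energy order.

    The stream is lazy: abandoning it early costs nothing beyond the nodes
    already expanded.
    """
    return _ConfTree(state, sequence).stream()


# ---------------------------------------------------------------------------
# Sequence enumeration (multi-sequence tree)
# ---------------------------------------------------------------------------


def _normalize_space(
    state: State, space: Mapping[int, TSequence[str]] | None
) -> list[tuple[int, list[str]]]:
    """Allowed type names per mutable position, in position order."""
    mut = state.mutable_positions
    out = []
    for pos in mut:
        if space is not None and pos.index in space:
            names = list(space[pos.index])
            if not names:
                raise ValidationError(
                    f"state {state.role}: empty type set at position {pos.index}"
                )
            for name in names:
                pos.type_named(name)  # raises if not allowed
        else:
            names = [t.name for t in pos.allowed_types]
        out.append((pos.index, names))
    if space is not None:
        unknown = set(space) - {p.index for p in mut}
        if unknown:
            raise ValidationError(
                f"state {state.role}: sequence space restricts non-mutable "
                f"positions {sorted(unknown)}"
            )
    return out


class _SeqTree:
    """A* multi-sequence tree: types assigned to mutable positions in order;
    the node score is an admissible lower bound on E_v^⊖ over completions."""

    def __init__(self, state: State, space: Mapping[int, TSequence[str]] | None):
        self.state = state
        self.mut = _normalize_space(state, space)
        em = state.ematrix
        n = len(state.positions)
        # Full option lists (union over allowed types) per position, tagged
        # with the owning type's index within that position's allowed set.
        self.opts: list[list[tuple[int, str, str]]] = []
        for pos in state.positions:
            restricted = dict(self.mut).get(pos.index)
            row = []
            for ti, t in enumerate(pos.allowed_types):
                if pos.mutable and restricted is not None and t.name not in restricted:
                    continue
                for rot in t.rotamers:
                    row.append((ti, t.name, rot))
            self.opts.append(row)
        self.singles = [
            [em.single(j, t, r) for (_, t, r) in self.opts[j]] for j in range(n)
        ]
        self.n = n
        # minpair[(j,k)][o][tk] = best pair energy between option o at j and
        # any rotamer of type-name tk at k (j < k).
        self.minpair: dict[tuple[int, int], list[dict[str, float]]] = {}
        for j in range(n):
            for k in range(j + 1, n):
                table = []
                for (_, tj, rj) in self.opts[j]:
                    best: dict[str, float] = {}
                    for (_, tk, rk) in self.opts[k]:
                        e = em.pair(j, tj, rj, k, tk, rk)
                        if tk not in best or e < best[tk]:
                            best[tk] = e
                    table.append(best)
                self.minpair[(j, k)] = table

    def _bound(self, assigned: dict[int, str]) -> float:
        """Admissible lower bound on min conformation energy over all
        sequences completing the partial type assignment."""
        n = self.n
        em = self.state.ematrix
        # allowed type names per position under the partial assignment
        allowed: list[set[str] | None] = []
        for pos in self.state.positions:
            if pos.index in assigned:
                allowed.append({assigned[pos.index]})
            elif pos.mutable:
                allowed.append(set(dict(self.mut)[pos.index]))
            else:
                allowed.append(None)  # single type, no restriction needed
        total = em.const
        for j in range(n):
            best_j = None
            for o, (_, tj, _) in enumerate(self.opts[j]):
                if allowed[j] is not None and tj not in allowed[j]:
                    continue
                val = self.singles[j][o]
                for k in range(j + 1, n):
                    row = self.minpair[(j, k)][o]
                    if allowed[k] is None:
                        val += min(row.values())
                    else:
                        val += min(row[t] for t in allowed[k] if t in row)
                if best_j is None or val < best_j:
                    best_j = val
            total += best_j
        return total

    def stream(self) -> Iterator[tuple[Sequence, float]]:
        mut = self.mut
        n_mut = len(mut)
        type_index = [
            {name: i for i, name in enumerate(names)} for _, names in mut
        ]
        # Node: (score, type-choice tuple, 0 exact / 1 bound)
        root = (self._bound({}), (), 1)
        heap = [root]
        while heap:
            score, choices, is_bound = heapq.heappop(heap)
            depth = len(choices)
            if depth == n_mut:
                seq = Sequence.from_dict(
                    {mut[j][0]: mut[j][1][choices[j]] for j in range(n_mut)}
                )
                if not is_bound:
                    yield seq, score
                    continue
                # Refine to the exact E_v^⊖: first leaf of the sequence's
                # conformation tree, then re-queue (exact >= the bound, so
                # order remains provably non-decreasing).
                _, exact = next(enumerate_conformations(self.state, seq))
                heapq.heappush(heap, (exact, choices, 0))
                continue
            pos_idx, names = mut[depth]
            for name in names:
                child = dict(
                    (mut[j][0], mut[j][1][choices[j]]) for j in range(depth)
                )
                child[pos_idx] = name
                heapq.heappush(
                    heap,
                    (self._bound(child), choices + (type_index[depth][name],), 1),
                )


def enumerate_sequences(
    state: State, space: Mapping[int, TSequence[str]] | None = None
) -> Iterator[tuple[Sequence, float]]:
    """Yield every sequence of the (optionally restricted) mutable space
    exactly once, as (sequence, E_v^⊖), in non-decreasing E_v^⊖.

    E_v^⊖ is exact: the minimum lower-bound energy over the sequence's
    conformations.  ``space`` optionally restricts the allowed type names per
    mutable position index; omitted positions keep their full allowed set.
    A state with no mutable positions yields the single empty sequence.
    """
    return _SeqTree(state, space).stream()
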