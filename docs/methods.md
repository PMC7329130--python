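# Methods

## Model

A design problem consists of three states (unbound protein, unbound ligand,
complex) over discrete conformation spaces: each position carries an
ordered set of residue types, each type an ordered set of rotamers. The
energy of a full conformation decomposes pairwise,

    E_lb(d) = const + Σ_i singles(i, t_i, r_i) + Σ_{i<j} pairs(i, t_i, r_i, j, t_j, r_j),

in kcal/mol, and this value is a *lower bound* on the conformation's
minimized energy E(d). Continuous minimization itself is out of scope; its
contract is carried by a deterministic minimized-energy model with
E(d) ≥ E_lb(d) for every conformation. Two kinds are provided: `identity`
(E = E_lb, used by the hand-checkable fixtures) and `seeded-offset`
(E = E_lb + δ, δ ∈ [0, delta_max] a stable hash of seed, state role and
assignment — reproducible and independent of enumeration order). Every
provable statement in the package (bounds, window completeness, pruning
guarantees) relies only on E ≥ E_lb and determinism, so it holds for any
conforming energy model.

Thermodynamics enter through Z_x(s) = Σ_d exp(−E_x(d)/RT). Default
constants are R = 1.98720×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 298.15 K
(RT ≈ 0.5925 kcal/mol); RT is configurable everywhere, and the toy
fixtures set RT = 1 so every number can be checked by hand.

Flexible-but-not-mutable shell residues are positions with one allowed type
and several rotamers — one mechanism covers both mutable and flexible
positions. Conformation counts |Q(v)| are exact arbitrary-precision
integers (products over positions never overflow). Mutability requires
allowed types to be listed explicitly in the problem file; nothing is
inferred from an amino-acid alphabet, so any counting convention (with or
without proline, synthetic labels, …) is expressible.

## Enumeration

Both enumerations are lazy best-first searches with an admissible pairwise
completion bound; positions expand in static index order and ties break
lexicographically on (type index, rotamer index), so streams are fully
deterministic.

* Conformations of one sequence stream in non-decreasing E_lb; admissibility
  of the heuristic guarantees gap-freeness and ordering (leaf g-values never
  undercut any popped leaf).
* Sequences stream in non-decreasing E_v^⊖ = min_d E_lb(d), the optimal
  lower bound of each sequence. A popped full sequence's bound is refined to
  the exact E_v^⊖ by descending its conformation tree to the first leaf and
  re-queueing; since the exact value can only be larger than the bound, the
  emitted order is correct. Dynamic expansion ordering was deliberately not
  used: determinism of equal-score emission is part of the tested contract.

## Partition-function estimators

All accumulation is in the natural-log domain (`numpy.logaddexp`), so Z
values spanning hundreds of orders of magnitude neither overflow nor
underflow; remainder terms use `math.log` on exact integer counts.

* `exact_partition` exhausts the space (refusing above a configurable guard
  limit, default 10⁶ conformations) — the oracle path.
* `approx_partition_eps` enumerates by lower bound, minimizes every
  enumerated conformation, and after each minimization bounds the missing
  mass by (remaining count)·exp(−next lb/RT); it halts when that remainder
  is at most an ε fraction of q_sum + remainder, giving
  z_lower = q_sum ≥ (1−ε)·Z and z_upper = q_sum + remainder ≥ Z. ε is the
  relative-gap form of the accuracy parameter. ε = 0 exhausts the space.
* `ewakstar_partition` halts once the next lower bound exceeds
  E_min + w_conf, with E_min the best minimized energy seen so far. Because
  lb(d) ≤ E(d) for every conformation and E_min ≥ E_GMEC, the retained
  ensemble provably contains every conformation with
  E(d) ≤ E_GMEC + w_conf. z_lower sums *all* minimized conformations, not
  only the in-window subset — a strictly tighter valid lower bound that
  preserves the superset guarantee.

Enumerated and minimized conformation counts coincide by policy (every
enumerated conformation is minimized); the result records both fields so
downstream cost comparisons stay meaningful.

## FRIES pruning

Per state: enumerate sequences by E_v^⊖ until the wild type appears
(everything emitted earlier automatically satisfies the window criterion);
anchor E_WT at the minimized energy of the wild type's *first* conformation
by lower bound — not its GMEC, which makes the window slightly conservative
since E_WT ≥ E_GMEC,WT; continue while E_v^⊖ ≤ E_WT + w. Sequences never
enumerated are window-pruned without being touched. Each enumerated
sequence then faces the magnitude test built from
q_v^⊕ = |Q(v)|·exp(−E_v^⊖/RT) (an upper bound on Z_v) and
q_WT^⊖ = exp(−E_WT/RT) (a lower bound on Z_WT).

The magnitude inequality's direction is genuinely ambiguous in its usual
statement: read literally as a keep rule, ln q_v^⊕ ≤ ln q_WT^⊖ + m would
prune sequences *more* stable than the wild type and, with small m, could
prune the wild type itself — the opposite of the filter's purpose of
removing markedly destabilized sequences. The default therefore prunes v
iff ln q_v^⊕ < ln q_WT^⊖ − m·ln(10): keep unless *provably* more than m
orders of magnitude worse. Under this direction the wild type always
survives (q_WT^⊕ ≥ q_WT^⊖ identically); it is also kept unconditionally as
a safeguard. The literal direction remains available
(`eq6_as_printed=True`) for fidelity experiments, and m's units are
configurable between log10 ("orders of magnitude", the default) and
natural-log.

The magnitude filter applies only to window-surviving sequences, matching
the two-stage sequencing of the procedure. The three per-state survivor
sets intersect through the complex→unbound position map; a state with no
mutable positions contributes the full (single, empty-projection) space and
prunes nothing.

## K* scores, ranking, Δb

Per-state bounds combine into bounds on log10 K*: lower =
z_lower(C)/(z_upper(P)·z_upper(L)), upper = z_upper(C)/(z_lower(P)·z_lower(L)).
The *point score* is the classical K* score
z_lower(C)/(z_lower(P)·z_lower(L)) — the ratio of accumulated per-state
lower bounds, which is how ε-approximate scores are conventionally
reported; it always lies inside the bound interval. Unbound-state results
are cached across sequences sharing a projection.

Ranking computes all candidate scores and sorts by descending lower bound
(deterministic tie-break on the sequence). When two returned intervals are
disjoint this provably reproduces the exact descending-K* order; when they
overlap the data cannot distinguish the pair and the lower bound decides.
A lazy refine-on-pop queue was considered and rejected: the contract is the
ordering property, candidate sets here are FRIES survivor sets (tens of
sequences), and a single code path removes a class of dual-path
inconsistencies.

Δb = log10(100·K*_v/K*_WT) − 2 = log10(K*_v/K*_WT), evaluated on the point
scores. "Percent change" is the ratio form 100·K*_v/K*_WT (the stated
wild-type-at-0 normalization forces this reading; the difference form would
shift every value). Positive Δb predicts improved binding.

## Synthetic generator

The generator emulates the *statistics* of structure-derived energy
matrices: singles ~ N(0, σ_single²), intra-partner pairs ~ N(0, σ_pair²),
complex = disjoint sum of the unbound matrices plus interface pairs
~ N(0, σ_pair²) each independently replaced by a clash penalty e_clash with
probability p_clash, and a seeded-offset minimizer. Normals rather than
uniforms: mass concentrates near zero with occasional large terms, as in
force-field matrices. The defaults are the benchmark profile — 4 positions
per partner, 2 mutable (one per partner, round-robin) with 5 types each,
2–5 rotamers per type, σ_single = 3.0, σ_pair = 1.5, p_clash = 0.05,
e_clash = 50, delta_max = 0.3 kcal/mol — chosen so Boltzmann mass
concentrates near the GMEC as in real rotameric landscapes while every
state stays exhaustible by a brute-force oracle. The generator emits the
same JSON schema `load_problem` consumes; there is no privileged in-memory
path.

What it does **not** emulate: real rotamer-library geometry, correlated
energies between neighbouring positions, backbone flexibility, solvation,
or the heavy-tailed minimization gaps of real continuous minimizers
(offsets here are bounded by delta_max). Passing tests therefore establish
the *algorithmic guarantees* — bounds, completeness, ordering, pruning
soundness — under any conforming energy model, but say nothing about
biophysical accuracy on real structures.

## Suite and benchmark sizes

Oracle-checked suites use a small profile (2 positions per partner, 3 types
per mutable position, 2–3 rotamers) so exhaustive enumeration stays cheap:
~540 sequences across 60 seeded problems for the estimator contracts,
200 seeded problems for the pruning guarantee, 50 for the ranking contract.
The estimator-accuracy benchmark uses the full default profile on 200
seeded problems: FRIES at w = 4 kcal/mol, m = 2, then per-survivor log10 K*
with the window estimator (w_conf ∈ {1, 3, 5}) against ε = 0.68 and
ε = 0.10 references, reporting the maximum absolute difference. These sizes
are the package's reference configuration; all are plain parameters.

## Numerical choices and degenerate inputs

Halting checks run after each minimization using the next queued lower
bound; an exhausted queue sets the remainder to zero, and an exhausted
estimator's bounds coincide at the exact Z. Energies are compared exactly
as floats (no tolerance inside the algorithms; tests use 1e-9 slack for
accumulated sums). Empty rotamer lists, unassigned mutable positions,
missing singles entries, a wild type outside the space, and guard-limit
violations all raise typed errors eagerly. Missing pair entries default to
0 under a schema flag (`default_missing_pairs_to_zero`, default true).
Pair energies are stored once per unordered pair (lower index first) and
queried symmetrically.

## Limitations

No DEE-style pruning, no continuous minimization, no structure I/O, no
parallel expansion, and the sequence ranking is exhaustive over its
candidate set (sublinear multi-sequence search over huge sequence spaces is
out of scope). The energy-window and ε estimators are compared empirically
by the benchmark; no analytic equivalence between w_conf and ε is asserted.
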