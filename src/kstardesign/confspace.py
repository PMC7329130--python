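"""Data model and I/O for multi-state protein-design problems.

A design problem consists of three *states* — the unbound protein, the
unbound ligand, and the protein-ligand complex — sharing one sequence space
over mutable positions.  Each state carries a discrete conformation space
(positions x residue types x rotamers), a pairwise-decomposable energy
matrix that yields a provable lower bound on any conformation's energy, and
a deterministic minimized-energy model that stands in for continuous
all-atom minimization: it maps a conformation to an energy that is never
below the pairwise lower bound.

Energies are in kcal/mol throughout.  Conformation counts are exact Python
integers (real design spaces reach ~1e12 conformations; products must never
overflow).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "DesignProblemError",
    "SchemaError",
    "ValidationError",
    "ResidueType",
    "DesignPosition",
    "EnergyMatrix",
    "MinimizedEnergyModel",
    "Constants",
    "Sequence",
    "State",
    "DesignProblem",
    "ROLES",
    "load_problem",
    "loads_problem",
    "save_problem",
    "dumps_problem",
    "project_sequence",
    "conf_count",
    "lower_bound_energy",
    "ematrix_to_tsv",
]

ROLES = ("protein", "ligand", "complex")

#: Gas constant in kcal·mol⁻¹·K⁻¹ and physiological-ish temperature in K.
#: RT ≈ 0.5925 kcal/mol at these defaults.
DEFAULT_R = 1.98720e-3
DEFAULT_T = 298.15


class DesignProblemError(Exception):
    """Base class for problems with a design problem."""


class SchemaError(DesignProblemError):
    """The input file does not conform to the design-problem JSON schema."""


class ValidationError(DesignProblemError):
    """A structurally well-formed problem violates a model invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidueType:
    """A residue type and its discrete rotamer set (side-chain conformers)."""

    name: str
    rotamers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rotamers:
            raise ValidationError(f"residue type {self.name!r}: empty rotamer list")
        if len(set(self.rotamers)) != len(self.rotamers):
            raise ValidationError(f"residue type {self.name!r}: duplicate rotamer ids")


@dataclass(frozen=True)
class DesignPosition:
    """One residue position of a state.

    A position is *mutable* when more than one residue type is allowed (or it
    is explicitly declared mutable).  A flexible-but-not-mutable shell
    residue is encoded as a position with a single allowed type and multiple
    rotamers.
    """

    index: int
    label: str
    allowed_types: tuple[ResidueType, ...]
    wild_type: str
    mutable: bool = None  # type: ignore[assignment]  # derived when omitted

    def __post_init__(self) -> None:
        if not self.allowed_types:
            raise ValidationError(f"position {self.label!r}: no allowed types")
        names = [t.name for t in self.allowed_types]
        if len(set(names)) != len(names):
            raise ValidationError(f"position {self.label!r}: duplicate type names")
        if self.wild_type not in names:
            raise ValidationError(
                f"position {self.label!r}: wild type {self.wild_type!r} "
                f"not among allowed types {names}"
            )
        if self.mutable is None:
            object.__setattr__(self, "mutable", len(self.allowed_types) > 1)
        elif not self.mutable and len(self.allowed_types) > 1:
            raise ValidationError(
                f"position {self.label!r}: declared immutable but has "
                f"{len(self.allowed_types)} allowed types"
            )

    def type_named(self, name: str) -> ResidueType:
        for t in self.allowed_types:
            if t.name == name:
                return t
        raise ValidationError(
            f"position {self.label!r}: type {name!r} not allowed"
        )


@dataclass
class EnergyMatrix:
    """Pairwise-decomposable energies: constant + singles + pairs (kcal/mol).

    ``pairs`` is stored once per unordered pair with the lower position index
    first; queries with swapped arguments are mapped transparently.  Missing
    pair entries default to 0 when ``default_missing_pairs_to_zero`` is set
    (the usual sparse convention), otherwise every cross-position combination
    must be listed explicitly.
    """

    const: float = 0.0
    singles: dict[tuple[int, str, str], float] = field(default_factory=dict)
    pairs: dict[
        tuple[tuple[int, str, str], tuple[int, str, str]], float
    ] = field(default_factory=dict)
    default_missing_pairs_to_zero: bool = True

    def set_single(self, pos: int, type_name: str, rot: str, energy: float) -> None:
        self.singles[(pos, type_name, rot)] = float(energy)

    def set_pair(
        self,
        pos1: int,
        type1: str,
        rot1: str,
        pos2: int,
        type2: str,
        rot2: str,
        energy: float,
    ) -> None:
        if pos1 == pos2:
            raise ValidationError("pair energy within a single position")
        a, b = (pos1, type1, rot1), (pos2, type2, rot2)
        if pos2 < pos1:
            a, b = b, a
        self.pairs[(a, b)] = float(energy)

    def single(self, pos: int, type_name: str, rot: str) -> float:
        try:
            return self.singles[(pos, type_name, rot)]
        except KeyError:
            raise ValidationError(
                f"missing singles entry for (pos {pos}, {type_name}, {rot})"
            ) from None

    def pair(
        self,
        pos1: int,
        type1: str,
        rot1: str,
        pos2: int,
        type2: str,
        rot2: str,
    ) -> float:
        a, b = (pos1, type1, rot1), (pos2, type2, rot2)
        if pos2 < pos1:
            a, b = b, a
        val = self.pairs.get((a, b))
        if val is None:
            if self.default_missing_pairs_to_zero:
                return 0.0
            raise ValidationError(f"missing pairs entry for {a} x {b}")
        return val


@dataclass(frozen=True)
class MinimizedEnergyModel:
    """Deterministic conformation -> minimized energy model.

    Houses the contract of continuous minimization without its physics: the
    minimized energy E(d) of a conformation d always satisfies
    E(d) >= lower_bound_energy(d), and the same conformation always maps to
    the same energy.

    kind "identity" returns the lower bound itself; kind "seeded-offset"
    adds a deterministic pseudo-random offset in [0, delta_max], computed
    from a stable hash of (seed, state role, assignment) so it is
    independent of enumeration order.
    """

    kind: str = "identity"
    delta_max: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "seeded-offset"):
            raise ValidationError(f"unknown minimizer kind {self.kind!r}")
        if self.delta_max < 0:
            raise ValidationError("minimizer delta_max must be >= 0")

    def energy(
        self,
        role: str,
        conformation: tuple[tuple[str, str], ...],
        lower_bound: float,
    ) -> float:
        if self.kind == "identity" or self.delta_max == 0.0:
            return lower_bound
        key = f"{self.seed}|{role}|{conformation!r}".encode()
        digest = hashlib.sha256(key).digest()
        u = int.from_bytes(digest[:8], "big") / 2.0**64
        return lower_bound + self.delta_max * u


@dataclass(frozen=True)
class Constants:
    """Thermodynamic constants. RT = R*T sets the Boltzmann energy scale."""

    R: float = DEFAULT_R
    T: float = DEFAULT_T

    @property
    def RT(self) -> float:
        rt = self.R * self.T
        if rt <= 0:
            raise ValidationError("RT must be > 0")
        return rt


@dataclass(frozen=True, order=True)
class Sequence:
    """An assignment of one residue-type name per (mutable) position.

    Stored as a position-sorted tuple of (position index, type name) pairs so
    sequences are hashable, orderable and canonical.  The empty sequence is
    the valid projection onto a state with no mutable positions.
    """

    assignment: tuple[tuple[int, str], ...] = ()

    @classmethod
    def from_dict(cls, d: Mapping[int, str]) -> "Sequence":
        return cls(tuple(sorted((int(k), str(v)) for k, v in d.items())))

    def as_dict(self) -> dict[int, str]:
        return dict(self.assignment)

    def get(self, pos: int) -> str | None:
        return self.as_dict().get(pos)

    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.assignment)

    def __len__(self) -> int:
        return len(self.assignment)

    def __str__(self) -> str:
        if not self.assignment:
            return "(empty)"
        return " ".join(f"{p}:{t}" for p, t in self.assignment)


@dataclass
class State:
    """One thermodynamic state: positions, energy matrix, minimizer."""

    role: str
    positions: list[DesignPosition]
    ematrix: EnergyMatrix
    minimizer: MinimizedEnergyModel = field(default_factory=MinimizedEnergyModel)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown state role {self.role!r}")
        for i, pos in enumerate(self.positions):
            if pos.index != i:
                raise ValidationError(
                    f"state {self.role}: position indices must be contiguous "
                    f"from 0 (found {pos.index} at slot {i})"
                )

    @property
    def mutable_positions(self) -> list[DesignPosition]:
        return [p for p in self.positions if p.mutable]

    def wild_type_sequence(self) -> Sequence:
        return Sequence.from_dict(
            {p.index: p.wild_type for p in self.mutable_positions}
        )

    def assigned_type(self, pos: DesignPosition, sequence: Sequence) -> ResidueType:
        """Residue type at ``pos`` under ``sequence`` (single type if immutable)."""
        name = sequence.get(pos.index)
        if name is None:
            if pos.mutable:
                raise ValidationError(
                    f"state {self.role}: sequence does not assign mutable "
                    f"position {pos.index}"
                )
            return pos.allowed_types[0]
        return pos.type_named(name)

    def validate_sequence(self, sequence: Sequence) -> None:
        known = {p.index for p in self.positions}
        for pos_idx, _ in sequence.assignment:
            if pos_idx not in known:
                raise ValidationError(
                    f"state {self.role}: sequence assigns unknown position {pos_idx}"
                )
        for pos in self.positions:
            self.assigned_type(pos, sequence)  # raises on any violation


@dataclass
class DesignProblem:
    """Three states plus the correspondence map between complex and unbound positions.

    ``position_map`` sends every complex position index to a
    (role, position index) pair in exactly one unbound state; mutable complex
    positions must map to mutable unbound positions so a complex sequence
    projects consistently onto all three states.
    """

    states: dict[str, State]
    position_map: dict[int, tuple[str, int]]
    wild_type_sequence: Sequence
    constants: Constants = field(default_factory=Constants)

    def __post_init__(self) -> None:
        for role in ROLES:
            if role not in self.states:
                raise ValidationError(f"missing state {role!r}")
            if self.states[role].role != role:
                raise ValidationError(
                    f"state stored under {role!r} has role "
                    f"{self.states[role].role!r}"
                )
        self._validate_position_map()
        self._validate_wild_type()

    def _validate_position_map(self) -> None:
        cplx = self.states["complex"]
        mapped_targets: set[tuple[str, int]] = set()
        for pos in cplx.positions:
            if pos.index not in self.position_map:
                raise ValidationError(
                    f"complex position {pos.index} missing from position_map"
                )
            role, idx = self.position_map[pos.index]
            if role not in ("protein", "ligand"):
                raise ValidationError(
                    f"position_map[{pos.index}] targets invalid state {role!r}"
                )
            target_state = self.states[role]
            if not 0 <= idx < len(target_state.positions):
                raise ValidationError(
                    f"position_map[{pos.index}] targets missing position "
                    f"{idx} of state {role}"
                )
            if (role, idx) in mapped_targets:
                raise ValidationError(
                    f"position_map maps two complex positions onto {role}:{idx}"
                )
            mapped_targets.add((role, idx))
            target = target_state.positions[idx]
            if pos.mutable and not target.mutable:
                raise ValidationError(
                    f"mutable complex position {pos.index} maps to immutable "
                    f"{role} position {idx}"
                )
        for extra in set(self.position_map) - {p.index for p in cplx.positions}:
            raise ValidationError(
                f"position_map entry {extra} is not a complex position"
            )

    def _validate_wild_type(self) -> None:
        cplx = self.states["complex"]
        expected = {p.index for p in cplx.mutable_positions}
        got = set(self.wild_type_sequence.positions())
        if expected != got:
            raise ValidationError(
                f"wild-type sequence assigns positions {sorted(got)}, "
                f"expected mutable complex positions {sorted(expected)}"
            )
        for role in ROLES:
            proj = project_sequence(self, self.wild_type_sequence, role)
            self.states[role].validate_sequence(proj)

    @property
    def complex(self) -> State:
        return self.states["complex"]

    @property
    def protein(self) -> State:
        return self.states["protein"]

    @property
    def ligand(self) -> State:
        return self.states["ligand"]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def project_sequence(problem: DesignProblem, sequence: Sequence, role: str) -> Sequence:
    """Restrict a complex sequence to the positions mapped into one state.

    The complex projection is the identity.  Unbound projections rename
    complex position indices to the target state's indices; positions mapped
    into the other partner are dropped.  The empty projection is valid (a
    state with no mutable positions).
    """
    if role not in ROLES:
        raise ValidationError(f"unknown state role {role!r}")
    if role == "complex":
        return sequence
    out: dict[int, str] = {}
    for pos_idx, type_name in sequence.assignment:
        try:
            target_role, target_idx = problem.position_map[pos_idx]
        except KeyError:
            raise ValidationError(
                f"sequence position {pos_idx} has no position_map entry"
            ) from None
        if target_role == role:
            out[target_idx] = type_name
    return Sequence.from_dict(out)


def conf_count(state: State, sequence: Sequence) -> int:
    """|Q(v)|: exact number of conformations of a sequence in a state.

    Product over positions of the rotamer count of the assigned type; exact
    arbitrary-precision integer.
    """
    state.validate_sequence(sequence)
    n = 1
    for pos in state.positions:
        n *= len(state.assigned_type(pos, sequence).rotamers)
    return n


def lower_bound_energy(
    state: State, conformation: tuple[tuple[str, str], ...]
) -> float:
    """Pairwise lower-bound energy of a full conformation: const + Σ singles + Σ pairs."""
    if len(conformation) != len(state.positions):
        raise ValidationError(
            f"state {state.role}: conformation assigns {len(conformation)} "
            f"positions, expected {len(state.positions)}"
        )
    em = state.ematrix
    total = em.const
    for pos, (tname, rot) in zip(state.positions, conformation):
        rtype = pos.type_named(tname)
        if rot not in rtype.rotamers:
            raise ValidationError(
                f"state {state.role}: rotamer {rot!r} not in type {tname!r} "
                f"at position {pos.index}"
            )
        total += em.single(pos.index, tname, rot)
    n = len(conformation)
    for i in range(n):
        ti, ri = conformation[i]
        for j in range(i + 1, n):
            tj, rj = conformation[j]
            total += em.pair(i, ti, ri, j, tj, rj)
    return total


def sequence_space_size(state: State) -> int:
    """Number of sequences in the state's full mutable space (exact integer)."""
    n = 1
    for pos in state.mutable_positions:
        n *= len(pos.allowed_types)
    return n


# ---------------------------------------------------------------------------
# JSON schema I/O
# ---------------------------------------------------------------------------


def _state_to_obj(state: State) -> dict:
    return {
        "positions": [
            {
                "label": p.label,
                "types": [
                    {"name": t.name, "rotamers": list(t.rotamers)}
                    for t in p.allowed_types
                ],
                "wild_type": p.wild_type,
                "mutable": p.mutable,
            }
            for p in state.positions
        ],
        "ematrix": {
            "const": state.ematrix.const,
            "singles": [
                [pos, t, r, e]
                for (pos, t, r), e in sorted(state.ematrix.singles.items())
            ],
            "pairs": [
                [a[0], a[1], a[2], b[0], b[1], b[2], e]
                for (a, b), e in sorted(state.ematrix.pairs.items())
            ],
            "default_missing_pairs_to_zero": state.ematrix.default_missing_pairs_to_zero,
        },
        "minimizer": {
            "kind": state.minimizer.kind,
            "delta_max": state.minimizer.delta_max,
            "seed": state.minimizer.seed,
        },
    }


def _require(obj: Mapping, key: str, context: str):
    if key not in obj:
        raise SchemaError(f"{context}: missing field {key!r}")
    return obj[key]


def _state_from_obj(role: str, obj: Mapping) -> State:
    ctx = f"states.{role}"
    if not isinstance(obj, Mapping):
        raise SchemaError(f"{ctx}: expected an object")
    positions = []
    for i, pobj in enumerate(_require(obj, "positions", ctx)):
        pctx = f"{ctx}.positions[{i}]"
        types = tuple(
            ResidueType(
                name=str(_require(tobj, "name", pctx)),
                rotamers=tuple(str(r) for r in _require(tobj, "rotamers", pctx)),
            )
            for tobj in _require(pobj, "types", pctx)
        )
        positions.append(
            DesignPosition(
                index=i,
                label=str(pobj.get("label", f"pos{i}")),
                allowed_types=types,
                wild_type=str(_require(pobj, "wild_type", pctx)),
                mutable=pobj.get("mutable"),
            )
        )
    eobj = _require(obj, "ematrix", ctx)
    em = EnergyMatrix(
        const=float(eobj.get("const", 0.0)),
        default_missing_pairs_to_zero=bool(
            eobj.get("default_missing_pairs_to_zero", True)
        ),
    )
    for row in _require(eobj, "singles", f"{ctx}.ematrix"):
        if len(row) != 4:
            raise SchemaError(f"{ctx}.ematrix.singles: row {row!r} is not [pos,type,rot,E]")
        em.set_single(int(row[0]), str(row[1]), str(row[2]), float(row[3]))
    for row in eobj.get("pairs", []):
        if len(row) != 7:
            raise SchemaError(
                f"{ctx}.ematrix.pairs: row {row!r} is not [pos1,type1,rot1,pos2,type2,rot2,E]"
            )
        em.set_pair(
            int(row[0]), str(row[1]), str(row[2]),
            int(row[3]), str(row[4]), str(row[5]),
            float(row[6]),
        )
    mobj = obj.get("minimizer", {})
    minimizer = MinimizedEnergyModel(
        kind=str(mobj.get("kind", "identity")),
        delta_max=float(mobj.get("delta_max", 0.0)),
        seed=int(mobj.get("seed", 0)),
    )
    state = State(role=role, positions=positions, ematrix=em, minimizer=minimizer)
    _validate_ematrix_coverage(state)
    return state


def _validate_ematrix_coverage(state: State) -> None:
    """Eagerly check every (position, type, rotamer) has a singles entry
    (and every cross-position combination a pairs entry when defaults are off)."""
    em = state.ematrix
    entries = []
    for pos in state.positions:
        for t in pos.allowed_types:
            for r in t.rotamers:
                em.single(pos.index, t.name, r)  # raises if missing
                entries.append((pos.index, t.name, r))
    for (p, t, r) in em.singles:
        if (p, t, r) not in set(entries):
            raise ValidationError(
                f"state {state.role}: singles entry ({p},{t},{r}) refers to "
                "an unknown position/type/rotamer"
            )
    if not em.default_missing_pairs_to_zero:
        for i, a in enumerate(entries):
            for b in entries[i + 1:]:
                if a[0] != b[0]:
                    em.pair(a[0], a[1], a[2], b[0], b[1], b[2])


def dumps_problem(problem: DesignProblem) -> str:
    obj = {
        "constants": {"R": problem.constants.R, "T": problem.constants.T},
        "states": {role: _state_to_obj(problem.states[role]) for role in ROLES},
        "position_map": {
            str(k): [v[0], v[1]] for k, v in sorted(problem.position_map.items())
        },
        "wild_type": {str(p): t for p, t in problem.wild_type_sequence.assignment},
    }
    return json.dumps(obj, indent=1, sort_keys=True)


def save_problem(problem: DesignProblem, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_problem(problem))
        fh.write("\n")


def loads_problem(text: str) -> DesignProblem:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(obj, Mapping):
        raise SchemaError("top level: expected an object")
    cobj = obj.get("constants", {})
    constants = Constants(
        R=float(cobj.get("R", DEFAULT_R)), T=float(cobj.get("T", DEFAULT_T))
    )
    sobj = _require(obj, "states", "top level")
    states = {role: _state_from_obj(role, _require(sobj, role, "states")) for role in ROLES}
    pmap_obj = _require(obj, "position_map", "top level")
    position_map = {}
    for k, v in pmap_obj.items():
        if not (isinstance(v, (list, tuple)) and len(v) == 2):
            raise SchemaError(f"position_map[{k}]: expected [state, index]")
        position_map[int(k)] = (str(v[0]), int(v[1]))
    wt_obj = _require(obj, "wild_type", "top level")
    wild_type = Sequence.from_dict({int(k): str(v) for k, v in wt_obj.items()})
    return DesignProblem(
        states=states,
        position_map=position_map,
        wild_type_sequence=wild_type,
        constants=constants,
    )


def load_problem(path) -> DesignProblem:
    """Load and eagerly validate a design problem from its JSON file."""
    with open(path) as fh:
        return loads_problem(fh.read())


def ematrix_to_tsv(state: State) -> str:
    """Inspection-friendly TSV dump of a state's energy matrix."""
    lines = ["kind\tpos1\ttype1\trot1\tpos2\ttype2\trot2\tenergy"]
    lines.append(f"const\t\t\t\t\t\t\t{state.ematrix.const!r}")
    for (pos, t, r), e in sorted(state.ematrix.singles.items()):
        lines.append(f"single\t{pos}\t{t}\t{r}\t\t\t\t{e!r}")
    for (a, b), e in sorted(state.ematrix.pairs.items()):
        lines.append(
            f"pair\t{a[0]}\t{a[1]}\t{a[2]}\t{b[0]}\t{b[1]}\t{b[2]}\t{e!r}"
        )
    return "\n".join(lines) + "\n"
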