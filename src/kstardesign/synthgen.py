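"""Seeded generator of three-state design problems, plus hand-checkable toys.

The generator emulates the statistics of structure-derived pairwise energy
matrices without any structural input: singles and pair energies are drawn
from zero-centred normals (heavier mass near zero with occasional large
terms, as in force-field matrices), cross-partner interface pairs are
occasionally replaced by a large steric-clash penalty, and a deterministic
seeded offset in [0, delta_max] stands in for the gap between a
conformation's pairwise lower bound and its continuously minimized energy.
The complex energy matrix is the disjoint sum of the two unbound matrices
plus the interface terms, so unbound and bound landscapes are thermodynamically
consistent.

Default parameters are the benchmark profile used throughout: 4 positions
per partner, 2 mutable (one per partner) with 5 residue types each, 2–5
rotamers per type, sigma_single = 3.0 and sigma_pair = 1.5 kcal/mol,
p_clash = 0.05 with e_clash = 50 kcal/mol, delta_max = 0.3 kcal/mol —
chosen so Boltzmann mass concentrates near the GMEC as in real rotameric
landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .confspace import (
    Constants,
    DesignPosition,
    DesignProblem,
    EnergyMatrix,
    MinimizedEnergyModel,
    ResidueType,
    Sequence,
    State,
    ValidationError,
)

__all__ = [
    "GeneratorParams",
    "generate_problem",
    "toy1_state",
    "toy2_problem",
    "toy_fixtures",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic landscape (energies in kcal/mol)."""

    n_protein_pos: int = 4
    n_ligand_pos: int = 4
    n_mutable: int = 2  # assigned round-robin: protein, ligand, protein, ...
    types_per_mutable: int = 5
    rotamers_min: int = 2
    rotamers_max: int = 5
    sigma_single: float = 3.0
    sigma_pair: float = 1.5
    p_clash: float = 0.05
    e_clash: float = 50.0
    delta_max: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_protein_pos < 1 or self.n_ligand_pos < 1:
            raise ValidationError("each partner needs at least one position")
        if not 1 <= self.rotamers_min <= self.rotamers_max:
            raise ValidationError("need 1 <= rotamers_min <= rotamers_max")
        if self.n_mutable < 0 or self.types_per_mutable < 1:
            raise ValidationError("invalid mutable-position parameters")
        if min(self.sigma_single, self.sigma_pair, self.e_clash) < 0:
            raise ValidationError("energy scales must be >= 0")
        if not 0.0 <= self.p_clash <= 1.0:
            raise ValidationError("p_clash must be in [0, 1]")
        if self.delta_max < 0:
            raise ValidationError("delta_max must be >= 0")

    def mutable_slots(self) -> list[tuple[str, int]]:
        """(partner role, partner position index) for each mutable position,
        alternating protein/ligand starting with the protein."""
        slots: list[tuple[str, int]] = []
        counts = {"protein": 0, "ligand": 0}
        caps = {"protein": self.n_protein_pos, "ligand": self.n_ligand_pos}
        order = ["protein", "ligand"]
        i = 0
        while len(slots) < self.n_mutable:
            role = order[i % 2]
            if counts[role] < caps[role]:
                slots.append((role, counts[role]))
                counts[role] += 1
            elif counts[order[(i + 1) % 2]] >= caps[order[(i + 1) % 2]]:
                raise ValidationError(
                    "n_mutable exceeds the total number of positions"
                )
            i += 1
        return slots


def _partner_positions(
    role: str,
    n_pos: int,
    mutable_idx: set[int],
    params: GeneratorParams,
    rng: np.random.Generator,
) -> list[DesignPosition]:
    positions = []
    for i in range(n_pos):
        if i in mutable_idx:
            types = tuple(
                ResidueType(
                    name=f"T{t}",
                    rotamers=tuple(
                        f"r{k}"
                        for k in range(
                            int(
                                rng.integers(
                                    params.rotamers_min, params.rotamers_max + 1
                                )
                            )
                        )
                    ),
                )
                for t in range(params.types_per_mutable)
            )
            wt = "T0"
        else:
            types = (
                ResidueType(
                    name="WT",
                    rotamers=tuple(
                        f"r{k}"
                        for k in range(
                            int(
                                rng.integers(
                                    params.rotamers_min, params.rotamers_max + 1
                                )
                            )
                        )
                    ),
                ),
            )
            wt = "WT"
        positions.append(
            DesignPosition(
                index=i, label=f"{role}{i}", allowed_types=types, wild_type=wt
            )
        )
    return positions


def _options(pos: DesignPosition) -> list[tuple[str, str]]:
    return [(t.name, r) for t in pos.allowed_types for r in t.rotamers]


def _partner_ematrix(
    positions: list[DesignPosition],
    params: GeneratorParams,
    rng: np.random.Generator,
) -> EnergyMatrix:
    em = EnergyMatrix()
    for pos in positions:
        for t, r in _options(pos):
            em.set_single(pos.index, t, r, rng.normal(0.0, params.sigma_single))
    for i, pi in enumerate(positions):
        for pj in positions[i + 1:]:
            for ti, ri in _options(pi):
                for tj, rj in _options(pj):
                    em.set_pair(
                        pi.index, ti, ri, pj.index, tj, rj,
                        rng.normal(0.0, params.sigma_pair),
                    )
    return em


def generate_problem(params: GeneratorParams) -> DesignProblem:
    """Build a seeded three-state problem; same params -> identical problem.

    Unbound matrices get normal singles/intra pairs; the complex matrix is
    their disjoint sum plus interface pairs, each independently replaced by
    the clash penalty with probability p_clash.
    """
    rng = np.random.default_rng(params.seed)
    slots = params.mutable_slots()
    mut = {"protein": {i for r, i in slots if r == "protein"},
           "ligand": {i for r, i in slots if r == "ligand"}}

    prot_pos = _partner_positions(
        "protein", params.n_protein_pos, mut["protein"], params, rng
    )
    lig_pos = _partner_positions(
        "ligand", params.n_ligand_pos, mut["ligand"], params, rng
    )
    prot_em = _partner_ematrix(prot_pos, params, rng)
    lig_em = _partner_ematrix(lig_pos, params, rng)

    # Complex: protein positions first, ligand positions shifted after them.
    shift = params.n_protein_pos
    cplx_pos = [
        DesignPosition(
            index=p.index, label=p.label, allowed_types=p.allowed_types,
            wild_type=p.wild_type,
        )
        for p in prot_pos
    ] + [
        DesignPosition(
            index=p.index + shift, label=p.label, allowed_types=p.allowed_types,
            wild_type=p.wild_type,
        )
        for p in lig_pos
    ]
    cplx_em = EnergyMatrix(const=prot_em.const + lig_em.const)
    for (pos, t, r), e in prot_em.singles.items():
        cplx_em.set_single(pos, t, r, e)
    for (pos, t, r), e in lig_em.singles.items():
        cplx_em.set_single(pos + shift, t, r, e)
    for (a, b), e in prot_em.pairs.items():
        cplx_em.set_pair(a[0], a[1], a[2], b[0], b[1], b[2], e)
    for (a, b), e in lig_em.pairs.items():
        cplx_em.set_pair(a[0] + shift, a[1], a[2], b[0] + shift, b[1], b[2], e)
    for pi in prot_pos:
        for pj in lig_pos:
            for ti, ri in _options(pi):
                for tj, rj in _options(pj):
                    e = rng.normal(0.0, params.sigma_pair)
                    if rng.random() < params.p_clash:
                        e = params.e_clash
                    cplx_em.set_pair(
                        pi.index, ti, ri, pj.index + shift, tj, rj, e
                    )

    minimizer_kind = "seeded-offset" if params.delta_max > 0 else "identity"
    states = {
        role: State(
            role=role,
            positions=pos_list,
            ematrix=em,
            minimizer=MinimizedEnergyModel(
                kind=minimizer_kind, delta_max=params.delta_max, seed=params.seed
            ),
        )
        for role, pos_list, em in (
            ("protein", prot_pos, prot_em),
            ("ligand", lig_pos, lig_em),
            ("complex", cplx_pos, cplx_em),
        )
    }
    position_map = {i: ("protein", i) for i in range(params.n_protein_pos)}
    position_map.update(
        {i + shift: ("ligand", i) for i in range(params.n_ligand_pos)}
    )
    wild_type = Sequence.from_dict(
        {p.index: "T0" for p in cplx_pos if p.mutable}
    )
    return DesignProblem(
        states=states,
        position_map=position_map,
        wild_type_sequence=wild_type,
        constants=Constants(),
    )


# ---------------------------------------------------------------------------
# Hand-checkable fixtures
# ---------------------------------------------------------------------------


def toy1_state() -> State:
    """Two-position toy state (the complex state of the toy problem).

    p0 is mutable with types X (rotamers x1, x2) and Y (rotamer y1); p1 is a
    flexible shell position with the single type Z (rotamers z1, z2).  The
    only non-zero pair term couples x2 with z1.  Sequence X has conformation
    energies {0, 2, 2, 3}; sequence Y has {5, 7}.
    """
    em = EnergyMatrix()
    em.set_single(0, "X", "x1", 0.0)
    em.set_single(0, "X", "x2", 1.0)
    em.set_single(0, "Y", "y1", 5.0)
    em.set_single(1, "Z", "z1", 0.0)
    em.set_single(1, "Z", "z2", 2.0)
    em.set_pair(0, "X", "x2", 1, "Z", "z1", 1.0)
    return State(
        role="complex",
        positions=[
            DesignPosition(
                index=0,
                label="p0",
                allowed_types=(
                    ResidueType("X", ("x1", "x2")),
                    ResidueType("Y", ("y1",)),
                ),
                wild_type="X",
            ),
            DesignPosition(
                index=1,
                label="p1",
                allowed_types=(ResidueType("Z", ("z1", "z2")),),
                wild_type="Z",
            ),
        ],
        ematrix=em,
        minimizer=MinimizedEnergyModel(kind="identity"),
    )


def toy2_problem() -> DesignProblem:
    """Three-state toy: protein = {p0}, ligand = {p1}, complex = the toy
    state, with the pair terms acting as interface energies.  Constants are
    R = T = 1 so RT = 1 and the arithmetic is hand-checkable."""
    prot_em = EnergyMatrix()
    prot_em.set_single(0, "X", "x1", 0.0)
    prot_em.set_single(0, "X", "x2", 1.0)
    prot_em.set_single(0, "Y", "y1", 5.0)
    protein = State(
        role="protein",
        positions=[
            DesignPosition(
                index=0,
                label="p0",
                allowed_types=(
                    ResidueType("X", ("x1", "x2")),
                    ResidueType("Y", ("y1",)),
                ),
                wild_type="X",
            )
        ],
        ematrix=prot_em,
        minimizer=MinimizedEnergyModel(kind="identity"),
    )
    lig_em = EnergyMatrix()
    lig_em.set_single(0, "Z", "z1", 0.0)
    lig_em.set_single(0, "Z", "z2", 2.0)
    ligand = State(
        role="ligand",
        positions=[
            DesignPosition(
                index=0,
                label="p1",
                allowed_types=(ResidueType("Z", ("z1", "z2")),),
                wild_type="Z",
            )
        ],
        ematrix=lig_em,
        minimizer=MinimizedEnergyModel(kind="identity"),
    )
    return DesignProblem(
        states={"protein": protein, "ligand": ligand, "complex": toy1_state()},
        position_map={0: ("protein", 0), 1: ("ligand", 0)},
        wild_type_sequence=Sequence.from_dict({0: "X"}),
        constants=Constants(R=1.0, T=1.0),
    )


def toy_fixtures() -> dict:
    """Both toys: TOY1 as a bare State, TOY2 as the full three-state problem
    whose complex state is TOY1."""
    return {"TOY1": toy1_state(), "TOY2": toy2_problem()}
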