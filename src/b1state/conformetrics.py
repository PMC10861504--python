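"""Geometric observables for conformational-state comparison.

Three scalar observables recur in comparisons of receptor activation
states and are implemented here with full provenance:

* the TM6 kink angle — the planar angle at three C-alpha atoms
  (conventionally 6.33b-6.47b-6.59b, the vertex at the PxxG proline),
  quantifying how sharply TM6 bends upon Gs coupling;
* per-position C-alpha displacements between two superposed states
  (e.g. the outward shift of the cytoplasmic end of TM6);
* extracellular-loop occupancy of the orthosteric pocket — how many
  loop heavy atoms of a ligand-free model fall inside the volume that
  the peptide agonist occupies in a peptide-bound reference.

The kink is deliberately the literal three-point angle, not a
helix-axis fit: that is how the quantity is defined in the comparisons
this package reproduces, and it is invariant under rigid motion of the
model.  An axis-based estimator would smooth over exactly the local
bend being measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import MissingAtomError, RoleAssignmentError
from .numbering import NumberingTable
from .structure_io import StructureModel
from .superpose import Scope, superpose_models


def _ca_position(model: StructureModel, table: NumberingTable, position: str | int) -> np.ndarray:
    chain = model.receptor_chain
    number = table.resolve(position) if isinstance(position, str) else int(position)
    res = chain.residue(number)
    if res is None or res.ca is None:
        label = position if isinstance(position, str) else f"residue {number}"
        raise MissingAtomError(
            f"{model.label}: C-alpha of {label} (author {number}) absent"
        )
    return res.ca.position


@dataclass
class KinkMeasurement:
    structure_label: str
    generic_triple: tuple[str, str, str]
    author_residues: tuple[int, int, int]
    angle_deg: float

    def __post_init__(self) -> None:
        if not 0.0 < self.angle_deg <= 180.0:
            raise ValueError(f"kink angle {self.angle_deg} outside (0, 180]")


@dataclass
class DisplacementMeasurement:
    labels: tuple[str, str]
    position: str
    scope_name: str
    distance: float
    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.distance < 0:
            raise ValueError("distance must be non-negative")
        if not np.isclose(self.distance, np.linalg.norm(self.vector), atol=1e-9):
            raise ValueError("distance inconsistent with displacement vector norm")


@dataclass
class PocketOverlap:
    loop_description: str
    peptide_chains: list[str]
    cutoff: float
    count: int
    total_loop_atoms: int
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.count <= self.total_loop_atoms:
            raise ValueError("overlap count outside [0, loop atom total]")


def angle_at_vertex(p1: np.ndarray, pv: np.ndarray, p3: np.ndarray) -> float:
    """Planar angle (degrees) at ``pv`` formed by ``p1`` and ``p3``."""
    v1 = np.asarray(p1, float) - np.asarray(pv, float)
    v2 = np.asarray(p3, float) - np.asarray(pv, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate kink: coincident C-alpha atoms")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def kink_angle(
    model: StructureModel,
    table: NumberingTable,
    g1: str = "6.33b",
    g_vertex: str = "6.47b",
    g3: str = "6.59b",
) -> KinkMeasurement:
    """Three-point C-alpha kink angle at ``g_vertex``."""
    p1 = _ca_position(model, table, g1)
    pv = _ca_position(model, table, g_vertex)
    p3 = _ca_position(model, table, g3)
    return KinkMeasurement(
        structure_label=model.label,
        generic_triple=(g1, g_vertex, g3),
        author_residues=(table.resolve(g1), table.resolve(g_vertex), table.resolve(g3)),
        angle_deg=angle_at_vertex(p1, pv, p3),
    )


def paired_displacement(
    model_a: StructureModel,
    model_b: StructureModel,
    table_a: NumberingTable,
    position: str,
    scope: Scope | None = None,
    table_b: NumberingTable | None = None,
) -> DisplacementMeasurement:
    """C-alpha displacement of ``position`` after superposing a onto b."""
    scope = scope or Scope()
    moved, _ = superpose_models(model_a, model_b, scope, table_a, table_b)
    pa = _ca_position(moved, table_a, position)
    pb = _ca_position(model_b, table_b or table_a, position)
    vec = pb - pa
    return DisplacementMeasurement(
        labels=(model_a.label, model_b.label),
        position=position,
        scope_name=scope.name,
        distance=float(np.linalg.norm(vec)),
        vector=vec,
    )


def cross_structure_distance(
    model_a: StructureModel,
    model_b: StructureModel,
    table_a: NumberingTable,
    residue_a: str | int,
    residue_b: str | int,
    scope: Scope | None = None,
    table_b: NumberingTable | None = None,
) -> float:
    """C-alpha--C-alpha distance between (possibly different) residues of
    two structures after position-matched superposition."""
    scope = scope or Scope()
    moved, _ = superpose_models(model_a, model_b, scope, table_a, table_b)
    pa = _ca_position(moved, table_a, residue_a)
    pb = _ca_position(model_b, table_b or table_a, residue_b)
    return float(np.linalg.norm(pa - pb))


def pocket_overlap(
    model_apo: StructureModel,
    model_holo: StructureModel,
    table_apo: NumberingTable,
    loop_residues: list[int] | str,
    peptide_role: str = "peptide",
    cutoff: float = 4.5,
    scope: Scope | None = None,
    table_holo: NumberingTable | None = None,
) -> PocketOverlap:
    """Count apo-loop heavy atoms inside the holo peptide's site.

    The apo model is first superposed onto the holo model over the TMD
    C-alphas; a loop heavy atom counts as overlapping when it lies
    within ``cutoff`` of any peptide heavy atom.
    """
    peptide_chains = model_holo.chains_by_role(peptide_role)
    if not peptide_chains:
        raise RoleAssignmentError(
            f"{model_holo.label}: no chain with role {peptide_role!r}"
        )
    scope = scope or Scope()
    moved, _ = superpose_models(model_apo, model_holo, scope, table_apo, table_holo)

    if isinstance(loop_residues, str):
        numbers = table_apo.segment_residues(loop_residues)
        loop_desc = loop_residues
    else:
        numbers = list(loop_residues)
        loop_desc = f"residues {numbers[0]}-{numbers[-1]}" if numbers else "residues []"
    chain = moved.receptor_chain
    loop_atoms = []
    for n in numbers:
        res = chain.residue(n)
        if res is None:
            continue
        for atom in res.heavy_atoms():
            loop_atoms.append((f"{n}:{atom.name}", atom.position))

    pep_atoms = []
    for pc in peptide_chains:
        for res in pc.residues:
            for atom in res.heavy_atoms():
                pep_atoms.append((f"{pc.chain_id}/{res.author_number}:{atom.name}", atom.position))

    pairs: list[tuple[str, str]] = []
    count = 0
    if loop_atoms and pep_atoms:
        tree = cKDTree(np.array([p for _, p in pep_atoms]))
        loop_pos = np.array([p for _, p in loop_atoms])
        neighbor_lists = tree.query_ball_point(loop_pos, r=cutoff)
        for (lname, _), idx in zip(loop_atoms, neighbor_lists):
            if idx:
                count += 1
                for j in sorted(idx):
                    pairs.append((lname, pep_atoms[j][0]))
    return PocketOverlap(
        loop_description=loop_desc,
        peptide_chains=[c.chain_id for c in peptide_chains],
        cutoff=cutoff,
        count=count,
        total_loop_atoms=len(loop_atoms),
        pairs=pairs,
    )
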