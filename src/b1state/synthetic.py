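"""Idealized coordinate fixtures with planted ground truth.

Every analysis stage in this package (kink angles, superposed
displacements, contact networks, interfaces, pocket occupancy, state
calls) is testable offline against fixtures whose answers are known by
construction:

* TM helices are ideal alpha-helical C-alpha traces (1.5 A rise,
  100 deg/residue, 2.3 A radius) arranged as a 7-helix bundle on a
  10 A circle, numbered with the real receptor numbering tables so the
  shipped generic-position maps apply unchanged;
* kink angles are planted exactly: the extracellular part of TM6 is
  rotated about the vertex C-alpha onto a cone whose half-angle is the
  target three-point angle, with the free cone azimuth solved (1-D
  deterministic root-find) to satisfy a tip-displacement or
  cross-receptor separation target at the same time;
* rigid segment displacements are planted exactly by whole-segment
  translation; a superposition over the untouched helices is then the
  identity and the measured shift equals the planted magnitude;
* contacts are planted by placing one polar and/or one apolar
  pseudo-side-chain atom per residue (named as standard atoms of
  standard residues, so the criteria code paths run unmodified) at the
  target pair distance; "broken" networks place the atoms pointing away
  from the bundle and the generator verifies the separation margin.

Side chains are not physically realistic (a single pseudo-atom each)
and loops are interpolated arcs; the fixtures exercise geometry and
contact logic, not stereochemistry.

``paper_emulation_set`` builds an inactive / ligand-free-Gs-coupled
(transitional) / peptide-bound trio for each of the three receptors
with the printed magnitudes of the study conditions planted (TM6 kink
angles, cytoplasmic TM6 shifts, extracellular TM movements,
cross-receptor ECL3 tip separations, network integrity per state,
interface strength ordering, pocket occupancy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .errors import B1StateError
from .numbering import NumberingTable, load_attested_pairs, load_tables
from .networks import load_motifs, MotifDefinition
from .structure_io import Atom, Chain, Residue, StructureModel

RISE = 1.5  # A per residue along the helix axis
TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # A, C-alpha cylinder radius
BUNDLE_RADIUS = 10.0  # A, helix axes from the bundle axis

# one polar and one apolar pseudo-side-chain atom name per residue type;
# residues without a polar side chain fall back to the backbone carbonyl O
POLAR_ATOM = {
    "ASP": "OD1", "GLU": "OE1", "ARG": "NH1", "LYS": "NZ", "HIS": "NE2",
    "ASN": "ND2", "GLN": "NE2", "THR": "OG1", "SER": "OG", "TYR": "OH",
    "TRP": "NE1", "MET": "SD", "CYS": "SG",
}
HYDRO_ATOM = {
    "LEU": "CD1", "VAL": "CG1", "ILE": "CD1", "PHE": "CZ", "TRP": "CZ2",
    "MET": "CE", "TYR": "CE1", "ALA": "CB",
}
_POLAR_FALLBACK = "O"
_HYDRO_FALLBACK = "CB"

POLAR_PLANT_DISTANCE = 2.9
HYDRO_PLANT_DISTANCE = 4.0
BROKEN_DISTANCE = 7.0
_CLEARANCE = 4.6  # above every contact cutoff

# Printed study-condition magnitudes planted into the emulation set.
PLANTED = {
    "GLP1R": {
        "kink_free": 98.0, "kink_bound": 112.0,
        "tm6_cyto_shift": 11.9, "cyto_pos": "6.37b",
        "tm6_tip_pos": "6.59b",
        "ec_moves_bound": {"TM1": ("1.33b", 6.5), "TM6": ("6.59b", 4.8), "TM7": ("7.33b", 6.2)},
    },
    "GCGR": {
        "kink_free": 120.0, "kink_bound": 120.0,
        "tm6_cyto_shift": 14.1, "cyto_pos": "6.37b",
        "tm6_tip_pos": "6.57b",
        "ec_moves_bound": {"TM1": ("1.34b", 4.8), "TM6": ("6.57b", 9.1), "TM7": ("7.33b", 5.3)},
    },
    "GIPR": {
        "kink_free": 148.0, "kink_bound": 113.0,
        "tm6_cyto_shift": 10.9, "cyto_pos": "6.37b",
        "tm6_tip_pos": "6.55b",
        "tm6_cyto_free_vs_bound": 4.5,
        "ec_moves_bound": {"TM1": ("1.30b", 10.1), "TM6": ("6.55b", 10.9), "TM7": ("7.33b", 8.1)},
    },
}
# ligand-free trio: 6.59b tip separation from the GLP1R tip
CROSS_TIP_SEPARATION = {"GCGR": 10.0, "GIPR": 21.0}
RMSD_AGOPAM = 0.53  # near-identity of the ligand-free and ago-PAM-bound receptor

_HELIX_AZIMUTH = {f"TM{k}": 2.0 * np.pi * (k - 1) / 7.0 for k in range(1, 8)}
# helices whose residue index increases toward the extracellular side
_INDEX_UP = {"TM2", "TM4", "TM6"}

GALPHA_NAMES = {376: "PHE", 380: "ARG", 385: "TYR", 388: "LEU",
                391: "TYR", 392: "GLU", 393: "LEU", 394: "LEU"}
PEPTIDE_SEQ = ("HIS", "SER", "GLN", "GLY", "THR", "PHE", "THR", "SER", "ASP", "TYR")


# ---------------------------------------------------------------------------
# Truth container


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside generated fixtures."""

    kink_angles: dict[str, float] = field(default_factory=dict)
    displacements: list[dict] = field(default_factory=list)
    cross_distances: list[dict] = field(default_factory=list)
    contacts: list[dict] = field(default_factory=list)
    network_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    overlaps: dict[str, int] = field(default_factory=dict)
    state_labels: dict[str, str] = field(default_factory=dict)
    chain_roles: dict[str, str] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def _clean(obj):
            if isinstance(obj, dict):
                return {str(k): _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        payload = {
            "kink_angles": self.kink_angles,
            "displacements": self.displacements,
            "cross_distances": self.cross_distances,
            "contacts": self.contacts,
            "network_fractions": self.network_fractions,
            "overlaps": self.overlaps,
            "state_labels": self.state_labels,
            "chain_roles": self.chain_roles,
            "extras": self.extras,
        }
        return json.dumps(_clean(payload), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Ideal helices (generic op, also used directly in tests)


@dataclass
class HelixSpec:
    n_residues: int
    rise: float = RISE
    twist_deg: float = TWIST
    radius: float = HELIX_RADIUS
    kink: tuple[int, float] | None = None  # (0-based pivot index, angle deg)
    probe_offset: int = 7
    noise_sigma: float = 0.0
    start_number: int = 1
    chain_id: str = "A"
    residue_name: str = "ALA"

    def __post_init__(self) -> None:
        if self.n_residues < 8:
            raise ValueError("helix needs >= 8 residues")
        if self.kink is not None:
            pivot, angle = self.kink
            if not 0.0 < angle < 180.0:
                raise ValueError("bend angle must lie in (0, 180)")
            if not self.probe_offset <= pivot <= self.n_residues - 1 - self.probe_offset:
                raise ValueError("kink pivot too close to the helix end for the probe offset")


def _ideal_trace(n: int, rise: float, twist_deg: float, radius: float) -> np.ndarray:
    i = np.arange(n, dtype=float)
    t = np.radians(twist_deg) * i
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), rise * i])


def _angle(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _plant_threepoint_angle(coords: np.ndarray, pivot: int, offset: int, target_deg: float) -> np.ndarray:
    """Rotate coords beyond ``pivot`` so the angle at C-alpha triple
    (pivot-offset, pivot, pivot+offset) equals ``target_deg`` exactly."""
    out = coords.copy()
    p1, pv, p3 = out[pivot - offset], out[pivot], out[pivot + offset]
    v1, v2 = p1 - pv, p3 - pv
    axis = np.cross(v1, v2)
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise B1StateError("cannot plant a bend on collinear probe atoms")
    axis /= norm
    current = _angle(v1, v2)
    rot = Rotation.from_rotvec(np.radians(target_deg - current) * axis)
    out[pivot + 1:] = rot.apply(out[pivot + 1:] - pv) + pv
    return out


def make_helix(spec: HelixSpec, seed: int = 0) -> Chain:
    """Ideal alpha-helical C-alpha trace, optional planted bend and noise."""
    coords = _ideal_trace(spec.n_residues, spec.rise, spec.twist_deg, spec.radius)
    if spec.kink is not None:
        pivot, angle = spec.kink
        coords = _plant_threepoint_angle(coords, pivot, spec.probe_offset, angle)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
    residues = [
        Residue(
            chain_id=spec.chain_id,
            author_number=spec.start_number + i,
            name=spec.residue_name,
            atoms=[Atom(name="CA", position=coords[i])],
        )
        for i in range(spec.n_residues)
    ]
    return Chain(chain_id=spec.chain_id, residues=residues)


# ---------------------------------------------------------------------------
# Receptor bundles


def _segment_cents(table: NumberingTable, segment: str) -> list[int]:
    anchor = table.anchors[segment]
    return [anchor.anchor_cents + (n - anchor.anchor_author)
            for n in range(anchor.start_author, anchor.end_author + 1)]


def _tm_ca(segment: str, cents: int) -> np.ndarray:
    """Deterministic C-alpha position for a TM generic position (base frame)."""
    az = _HELIX_AZIMUTH[segment]
    center = np.array([BUNDLE_RADIUS * np.cos(az), BUNDLE_RADIUS * np.sin(az), 0.0])
    c50 = (int(segment[2])) * 100 + 50
    steps = cents - c50
    z = RISE * (steps if segment in _INDEX_UP else -steps)
    phase = np.radians(TWIST) * steps + 3.0 * az
    offset = np.array([HELIX_RADIUS * np.cos(phase), HELIX_RADIUS * np.sin(phase), z])
    return center + offset


def _radial(point: np.ndarray) -> np.ndarray:
    xy = np.array([point[0], point[1], 0.0])
    n = np.linalg.norm(xy)
    return xy / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])


def _residue_names(receptor_id: str, table: NumberingTable,
                   motifs: dict[str, MotifDefinition]) -> dict[int, str]:
    names: dict[int, str] = {}
    for motif in motifs.values():
        if motif.receptors and receptor_id not in motif.receptors:
            continue
        for member in motif.members:
            if member.kind == "partner":
                continue
            try:
                number = (member.author_number if member.kind == "loop"
                          else table.resolve(member.raw))
            except B1StateError:
                continue
            allowed = motif.allowed.get(member.raw)
            if allowed:
                names.setdefault(number, allowed[0])
    for pair in load_attested_pairs():
        if pair.receptor_id == receptor_id:
            names[pair.author_number] = pair.residue_name
    return names


def _base_receptor_chain(receptor_id: str, table: NumberingTable,
                         motifs: dict[str, MotifDefinition]) -> Chain:
    names = _residue_names(receptor_id, table, motifs)
    residues: list[Residue] = []
    for segment in ("TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7"):
        anchor = table.anchors[segment]
        for n in range(anchor.start_author, anchor.end_author + 1):
            cents = anchor.anchor_cents + (n - anchor.anchor_author)
            residues.append(Residue(
                chain_id="R", author_number=n, name=names.get(n, "ALA"),
                atoms=[Atom(name="CA", position=_tm_ca(segment, cents))],
            ))
    # H8: straight arm leaving the TM7 base, tilted off the membrane normal
    h8 = table.anchors["H8"]
    tm7 = table.anchors["TM7"]
    tm7_base = _tm_ca("TM7", tm7.anchor_cents + (tm7.end_author - tm7.anchor_author))
    direction = Rotation.from_rotvec(np.array([0.0, 0.0, 0.4])).apply(_radial(tm7_base))
    for n in range(h8.start_author, h8.end_author + 1):
        step = n - h8.start_author
        pos = tm7_base + direction * (3.8 * (step + 1)) + np.array([0.0, 0.0, -1.5])
        residues.append(Residue(chain_id="R", author_number=n, name=names.get(n, "ALA"),
                                atoms=[Atom(name="CA", position=pos)]))
    # loops: interpolated arcs between flanking segment ends, bulged outward
    flank = {
        "ICL1": ("TM1", "TM2"), "ECL1": ("TM2", "TM3"), "ICL2": ("TM3", "TM4"),
        "ECL2": ("TM4", "TM5"), "ICL3": ("TM5", "TM6"), "ECL3": ("TM6", "TM7"),
    }
    by_number = {r.author_number: r for r in residues}
    for loop, (lo, hi) in table.loops.items():
        seg_a, seg_b = flank[loop]
        end_a = by_number.get(table.anchors[seg_a].end_author)
        end_b = by_number.get(table.anchors[seg_b].start_author)
        if end_a is None or end_b is None:
            continue
        pa, pb = end_a.atoms[0].position, end_b.atoms[0].position
        count = hi - lo + 1
        for k, n in enumerate(range(lo, hi + 1)):
            f = (k + 1) / (count + 1)
            pos = (1 - f) * pa + f * pb
            bulge = np.sin(np.pi * f)
            pos = pos + 3.0 * bulge * _radial(pos) + np.array(
                [0.0, 0.0, 2.0 * bulge * np.sign(pa[2] + pb[2] + 1e-9)])
            residues.append(Residue(chain_id="R", author_number=n, name=names.get(n, "GLY"),
                                    atoms=[Atom(name="CA", position=pos)]))
    return Chain(chain_id="R", residues=residues)


def _galpha_chain(z_top: float = -12.0) -> Chain:
    """Single helix standing in for the Gs alpha5 helix (authors 375-394)."""
    n = 20
    coords = _ideal_trace(n, RISE, TWIST, HELIX_RADIUS)
    coords = coords - coords[-1] + np.array([0.0, 0.0, z_top])
    residues = [
        Residue(chain_id="A", author_number=375 + i, name=GALPHA_NAMES.get(375 + i, "ALA"),
                atoms=[Atom(name="CA", position=coords[i])])
        for i in range(n)
    ]
    return Chain(chain_id="A", residues=residues)


def _peptide_coords() -> list[np.ndarray]:
    return [np.array([2.0 * np.cos(np.radians(TWIST) * i),
                      2.0 * np.sin(np.radians(TWIST) * i),
                      6.0 + 1.4 * i]) for i in range(10)]


def _peptide_chain() -> Chain:
    residues = []
    for i, pos in enumerate(_peptide_coords()):
        cb = pos + 1.5 * _radial(pos)
        residues.append(Residue(chain_id="P", author_number=i + 1, name=PEPTIDE_SEQ[i],
                                atoms=[Atom(name="CA", position=pos), Atom(name="CB", position=cb)]))
    return Chain(chain_id="P", residues=residues)


# ---------------------------------------------------------------------------
# Geometry edits


def _chain_index(chain: Chain) -> dict[int, Residue]:
    return {r.author_number: r for r in chain.residues}


def _translate(chain: Chain, numbers: list[int], vector: np.ndarray) -> None:
    idx = _chain_index(chain)
    for n in numbers:
        res = idx.get(n)
        if res is None:
            continue
        for atom in res.atoms:
            atom.position = atom.position + vector


def _rotate_about(chain: Chain, numbers: list[int], rot: Rotation, center: np.ndarray) -> None:
    idx = _chain_index(chain)
    for n in numbers:
        res = idx.get(n)
        if res is None:
            continue
        for atom in res.atoms:
            atom.position = rot.apply(atom.position - center) + center


def _minimal_rotation(v_from: np.ndarray, v_to: np.ndarray) -> Rotation:
    a = v_from / np.linalg.norm(v_from)
    b = v_to / np.linalg.norm(v_to)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    c = float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return Rotation.identity()
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.cross(a, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(a, np.array([0.0, 1.0, 0.0]))
        return Rotation.from_rotvec(np.pi * perp / np.linalg.norm(perp))
    return Rotation.from_rotvec(np.arctan2(s, c) * axis / s)


def _plant_tm6_kink(
    chain: Chain,
    table: NumberingTable,
    angle_deg: float,
    tip_position: str | None = None,
    tip_reference: np.ndarray | None = None,
    tip_target: float | None = None,
) -> float:
    """Rotate the extracellular part of TM6 about the 6.47b vertex.

    The three-point angle 6.33b-6.47b-6.59b is planted exactly for any
    cone azimuth psi; when a tip constraint is given, psi is solved so
    that the C-alpha at ``tip_position`` lands at ``tip_target`` A from
    ``tip_reference``.  Returns the achieved tip distance (or 0.0).
    """
    idx = _chain_index(chain)
    p33 = idx[table.resolve("6.33b")].atoms[0].position
    pv = idx[table.resolve("6.47b")].atoms[0].position
    p59 = idx[table.resolve("6.59b")].atoms[0].position
    v1, v2 = p33 - pv, p59 - pv
    L = np.linalg.norm(v2)
    v1_hat = v1 / np.linalg.norm(v1)
    e1 = v2 - np.dot(v2, v1_hat) * v1_hat
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v1_hat, e1)
    theta = np.radians(angle_deg)

    def w_of(psi: float) -> np.ndarray:
        return L * (np.cos(theta) * v1_hat + np.sin(theta) * (np.cos(psi) * e1 + np.sin(psi) * e2))

    anchor6 = table.anchors["TM6"]
    vertex_author = table.resolve("6.47b")
    ec_numbers = [n for n in range(vertex_author + 1, anchor6.end_author + 1)]

    def tip_after(psi: float) -> np.ndarray:
        rot = _minimal_rotation(v2, w_of(psi))
        p_tip = idx[table.resolve(tip_position)].atoms[0].position
        return rot.apply(p_tip - pv) + pv

    psi_star = 0.0
    achieved = 0.0
    if tip_position is not None and tip_reference is not None and tip_target is not None:
        def f(psi: float) -> float:
            return float(np.linalg.norm(tip_after(psi) - tip_reference)) - tip_target

        grid = np.linspace(0.0, 2.0 * np.pi, 721)
        vals = np.array([f(p) for p in grid])
        bracket = None
        for i in range(len(grid) - 1):
            if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
                bracket = (grid[i], grid[i + 1])
                break
        if bracket is not None:
            psi_star = brentq(f, *bracket, xtol=1e-12)
        else:  # infeasible target: take the closest achievable azimuth
            psi_star = float(grid[int(np.argmin(np.abs(vals)))])
        achieved = f(psi_star) + tip_target
    rot = _minimal_rotation(v2, w_of(psi_star))
    _rotate_about(chain, ec_numbers, rot, pv)
    return achieved


# ---------------------------------------------------------------------------
# Contact planting


def _side_atom_name(res: Residue, kind: str) -> str:
    if kind == "polar":
        return POLAR_ATOM.get(res.name, _POLAR_FALLBACK)
    return HYDRO_ATOM.get(res.name, _HYDRO_FALLBACK)


def _get_or_none(res: Residue, name: str) -> Atom | None:
    return res.atom(name)


def _plant_pairs(
    pairs: list[tuple[Residue, Residue, str]],
    distances: dict[str, float] | None = None,
) -> list[dict]:
    """Place pseudo-side-chain atoms so each (a, b, kind) pair sits at the
    planting distance for its kind.  Greedy: an already placed atom anchors
    its partners; contradictory constraints raise."""
    distances = distances or {"polar": POLAR_PLANT_DISTANCE, "hydrophobic": HYDRO_PLANT_DISTANCE}
    planted = []
    for res_a, res_b, kind in pairs:
        d = distances[kind]
        name_a = _side_atom_name(res_a, kind)
        name_b = _side_atom_name(res_b, kind)
        ca_a = res_a.atoms[0].position
        ca_b = res_b.atoms[0].position
        atom_a = _get_or_none(res_a, name_a)
        atom_b = _get_or_none(res_b, name_b)
        if atom_a is None and atom_b is None:
            u = ca_b - ca_a
            u = u / np.linalg.norm(u)
            mid = 0.5 * (ca_a + ca_b)
            atom_a = Atom(name=name_a, position=mid - 0.5 * d * u)
            atom_b = Atom(name=name_b, position=mid + 0.5 * d * u)
            res_a.atoms.append(atom_a)
            res_b.atoms.append(atom_b)
        elif atom_a is not None and atom_b is None:
            u = ca_b - atom_a.position
            u = u / np.linalg.norm(u)
            atom_b = Atom(name=name_b, position=atom_a.position + d * u)
            res_b.atoms.append(atom_b)
        elif atom_b is not None and atom_a is None:
            u = ca_a - atom_b.position
            u = u / np.linalg.norm(u)
            atom_a = Atom(name=name_a, position=atom_b.position + d * u)
            res_a.atoms.append(atom_a)
        else:
            actual = np.linalg.norm(atom_a.position - atom_b.position)
            if not np.isclose(actual, d, atol=1e-6):
                raise B1StateError(
                    f"contact planting conflict: {res_a.name}{res_a.author_number}-"
                    f"{res_b.name}{res_b.author_number} already at {actual:.2f} A, want {d}"
                )
        planted.append({
            "residue_a": f"{res_a.chain_id}/{res_a.name}{res_a.author_number}",
            "residue_b": f"{res_b.chain_id}/{res_b.name}{res_b.author_number}",
            "kind": kind,
            "distance": d,
        })
    return planted


def _plant_broken(pairs: list[tuple[Residue, Residue, str]]) -> None:
    """Give every member its pseudo-atom pointing away from the bundle and
    verify each expected pair clears every contact cutoff."""
    for res_a, res_b, kind in pairs:
        for res in (res_a, res_b):
            name = _side_atom_name(res, kind)
            if res.atom(name) is None:
                ca = res.atoms[0].position
                res.atoms.append(Atom(name=name, position=ca + 1.6 * _radial(ca)))
    for res_a, res_b, kind in pairs:
        a = res_a.atom(_side_atom_name(res_a, kind))
        b = res_b.atom(_side_atom_name(res_b, kind))
        d = float(np.linalg.norm(a.position - b.position))
        if d < _CLEARANCE:
            raise B1StateError(
                f"broken-pair placement too close ({d:.2f} A) for "
                f"{res_a.author_number}-{res_b.author_number}"
            )


def _motif_pairs_resolved(
    model: StructureModel, table: NumberingTable, motif: MotifDefinition
) -> list[tuple[Residue, Residue, str]]:
    out = []
    idx_by_chain = {c.chain_id: _chain_index(c) for c in model.chains}
    receptor = model.receptor_chain
    for mem_a, mem_b, kind in motif.pairs:
        def _res(member):
            if member.kind == "partner":
                chains = model.chains_by_role(member.partner_role)
                if not chains:
                    raise B1StateError(f"fixture lacks a {member.partner_role} chain")
                return idx_by_chain[chains[0].chain_id][member.author_number]
            number = member.author_number if member.kind == "loop" else table.resolve(member.raw)
            return idx_by_chain[receptor.chain_id][number]

        out.append((_res(mem_a), _res(mem_b), kind))
    return out


# ---------------------------------------------------------------------------
# Spec-level generator operations


@dataclass
class BundleSpec:
    receptor_id: str = "GLP1R"
    noise_sigma: float = 0.0
    with_galpha: bool = False


@dataclass
class DisplacementOp:
    segment: str  # TM1..TM7
    part: str = "whole"  # whole | ec | ic
    magnitude: float = 5.0
    direction: str = "out"  # out | in  (radial w.r.t. the bundle axis)


def _segment_part_numbers(table: NumberingTable, segment: str, part: str) -> list[int]:
    anchor = table.anchors[segment]
    numbers = list(range(anchor.start_author, anchor.end_author + 1))
    if part == "whole":
        return numbers
    c50 = int(segment[2]) * 100 + 50
    out = []
    for n in numbers:
        cents = anchor.anchor_cents + (n - anchor.anchor_author)
        steps = cents - c50
        z = RISE * (steps if segment in _INDEX_UP else -steps)
        if (part == "ec" and z > 2.0) or (part == "ic" and z < -2.0):
            out.append(n)
    return out


def make_bundle(spec: BundleSpec, seed: int = 0) -> StructureModel:
    """Plain 7TM+H8 bundle (no planted contacts), optional partner helix."""
    tables = load_tables()
    motifs = load_motifs()
    table = tables[spec.receptor_id]
    receptor = _base_receptor_chain(spec.receptor_id, table, motifs)
    receptor.entity_role = "receptor"
    chains = [receptor]
    if spec.with_galpha:
        galpha = _galpha_chain()
        galpha.entity_role = "Galpha"
        chains.append(galpha)
    model = StructureModel(label=f"{spec.receptor_id.lower()}_bundle", chains=chains)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        for _, _, atom in model.iter_atoms():
            atom.position = atom.position + rng.normal(0.0, spec.noise_sigma, 3)
    return model


def make_state_pair(
    spec: BundleSpec, plan: list[DisplacementOp], seed: int = 0
) -> tuple[StructureModel, StructureModel, SyntheticTruth]:
    """Paired fixtures differing by rigid whole/half-segment translations.

    Truth records, per op, every generic position carried by the moved
    residues together with the planted magnitude; a superposition over
    the untouched helices recovers each magnitude exactly (up to noise).
    """
    table = load_tables()[spec.receptor_id]
    model_a = make_bundle(BundleSpec(spec.receptor_id, 0.0, spec.with_galpha), seed)
    model_b = model_a.copy()
    model_a.label = f"{spec.receptor_id.lower()}_state_a"
    model_b.label = f"{spec.receptor_id.lower()}_state_b"
    truth = SyntheticTruth(state_labels={model_a.label: "base", model_b.label: "displaced"},
                           chain_roles={c.chain_id: c.entity_role for c in model_a.chains})
    moved_segments = set()
    for op in plan:
        if op.segment not in _HELIX_AZIMUTH:
            raise B1StateError(f"displacement plan references unknown helix {op.segment!r}")
        numbers = _segment_part_numbers(table, op.segment, op.part)
        az = _HELIX_AZIMUTH[op.segment]
        r_hat = np.array([np.cos(az), np.sin(az), 0.0])
        vec = op.magnitude * (r_hat if op.direction == "out" else -r_hat)
        _translate(model_b.receptor_chain, numbers, vec)
        moved_segments.add(op.segment)
        anchor = table.anchors[op.segment]
        for n in numbers:
            cents = anchor.anchor_cents + (n - anchor.anchor_author)
            truth.displacements.append({
                "position": f"{cents // 100}.{cents % 100:02d}b",
                "author_number": n,
                "distance": op.magnitude,
                "scope_segments": sorted(set(_HELIX_AZIMUTH) - moved_segments),
            })
    frozen = sorted(set(_HELIX_AZIMUTH) - moved_segments)
    for row in truth.displacements:
        row["scope_segments"] = frozen
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed + 1)
        for model in (model_a, model_b):
            for _, _, atom in model.iter_atoms():
                atom.position = atom.position + rng.normal(0.0, spec.noise_sigma, 3)
    return model_a, model_b, truth


def make_network_fixture(
    motif: MotifDefinition,
    intact: bool,
    seed: int = 0,
    receptor_id: str = "GLP1R",
    drop_pairs: tuple[int, ...] = (),
) -> tuple[StructureModel, SyntheticTruth]:
    """Bundle with one motif planted intact (pairs at planting distance)
    or broken (pairs beyond every cutoff).  ``drop_pairs`` removes
    expected pairs from the planted set (they stay expected, so the
    truth fraction drops accordingly)."""
    needs_partner = any(m.kind == "partner" for m in motif.members)
    model = make_bundle(BundleSpec(receptor_id, 0.0, with_galpha=needs_partner), seed)
    model.label = f"{receptor_id.lower()}_{motif.name}_{'intact' if intact else 'broken'}"
    table = load_tables()[receptor_id]
    resolved = _motif_pairs_resolved(model, table, motif)
    if intact:
        kept = [p for i, p in enumerate(resolved) if i not in drop_pairs]
        dropped = [p for i, p in enumerate(resolved) if i in drop_pairs]
        planted = _plant_pairs(kept)
        if dropped:
            _plant_broken(dropped)
        fraction = len(kept) / len(resolved)
    else:
        _plant_broken(resolved)
        planted = []
        fraction = 0.0
    truth = SyntheticTruth(
        contacts=planted,
        network_fractions={model.label: {motif.name: fraction}},
        chain_roles={c.chain_id: c.entity_role for c in model.chains},
    )
    return model, truth


def make_interface_fixture(
    receptor_id: str = "GLP1R", n_contacts: int = 4, seed: int = 0
) -> tuple[StructureModel, SyntheticTruth]:
    """Two-chain fixture with exactly ``n_contacts`` planted receptor-Galpha
    contacts and verified clearance everywhere else."""
    candidates = [
        (391, "2.46b", "polar"),
        (392, "7.61b", "polar"),
        (393, "3.54b", "hydrophobic"),
        (388, "5.61b", "hydrophobic"),
        (380, "3.58b", "polar"),
        (394, "6.43b", "hydrophobic"),
    ]
    if not 1 <= n_contacts <= len(candidates):
        raise B1StateError(f"n_contacts must be in [1, {len(candidates)}]")
    model = make_bundle(BundleSpec(receptor_id, 0.0, with_galpha=True), seed)
    model.label = f"{receptor_id.lower()}_interface_{n_contacts}"
    table = load_tables()[receptor_id]
    receptor = model.receptor_chain
    galpha = model.chains_by_role("Galpha")[0]
    ridx, gidx = _chain_index(receptor), _chain_index(galpha)
    pairs = [
        (gidx[ga], ridx[table.resolve(pos)], kind)
        for ga, pos, kind in candidates[:n_contacts]
    ]
    planted = _plant_pairs(pairs)
    _verify_interface_clearance(model, expected=n_contacts)
    truth = SyntheticTruth(
        contacts=planted,
        extras={"interface_contacts": n_contacts},
        chain_roles={c.chain_id: c.entity_role for c in model.chains},
    )
    return model, truth


def _verify_interface_clearance(model: StructureModel, expected: int) -> None:
    """Plain-distance audit that exactly ``expected`` contact-capable
    receptor/partner atom pairs (polar-polar or sidechain-C-C) fall within
    the widest contact cutoff."""
    from scipy.spatial.distance import cdist

    receptor = model.receptor_chain
    partners = [c for c in model.chains if c.entity_role in ("Galpha", "Gbeta", "Ggamma")]

    def _split(chains):
        polar, carbon = [], []
        for c in chains:
            for r in c.residues:
                for a in r.atoms:
                    if a.name == "CA":
                        continue
                    (polar if a.element in ("N", "O", "S") else carbon).append(a.position)
        return np.array(polar).reshape(-1, 3), np.array(carbon).reshape(-1, 3)

    rp, rc = _split([receptor])
    pp, pc = _split(partners)
    if len(rp) + len(rc) == 0 or len(pp) + len(pc) == 0:
        raise B1StateError("clearance audit found no pseudo-side-chain atoms")
    n_close = 0
    if len(rp) and len(pp):
        n_close += int((cdist(rp, pp) <= _CLEARANCE).sum())
    if len(rc) and len(pc):
        n_close += int((cdist(rc, pc) <= _CLEARANCE).sum())
    if n_close != expected:
        raise B1StateError(
            f"interface fixture has {n_close} contact-capable close pairs, expected {expected}"
        )


# ---------------------------------------------------------------------------
# Paper-emulation trios


def _state_interface_pairs(state: str) -> list[tuple[int, str, str]]:
    base = [(391, "2.46b", "polar"), (393, "3.54b", "hydrophobic"), (394, "6.43b", "hydrophobic")]
    if state != "bound":
        return base
    return base + [
        (392, "7.61b", "polar"),
        (392, "8.49b", "polar"),
        (394, "6.37b", "polar"),
        (380, "3.58b", "polar"),
        (385, "ICL3", "polar"),
        (388, "5.61b", "hydrophobic"),
    ]


def make_state_trio(
    receptor_id: str, seed: int = 0, noise_sigma: float = 0.0
) -> tuple[dict[str, StructureModel], SyntheticTruth]:
    """Inactive / ligand-free-Gs (transitional) / peptide-bound trio with the
    printed study magnitudes planted (see PLANTED)."""
    return _emulation_models([receptor_id], seed, noise_sigma)


def _emulation_models(
    receptor_ids: list[str], seed: int = 0, noise_sigma: float = 0.0
) -> tuple[dict[str, StructureModel], SyntheticTruth]:
    tables = load_tables()
    motifs = load_motifs()
    truth = SyntheticTruth()
    models: dict[str, StructureModel] = {}
    glp1r_free_tip: np.ndarray | None = None

    order = [r for r in ("GLP1R", "GCGR", "GIPR") if r in receptor_ids]
    for receptor_id in order:
        table = tables[receptor_id]
        planted = PLANTED[receptor_id]
        prefix = receptor_id.lower()
        az6 = _HELIX_AZIMUTH["TM6"]
        r6_out = np.array([np.cos(az6), np.sin(az6), 0.0])
        tm6_all = _segment_part_numbers(table, "TM6", "whole")

        # ---- inactive ----------------------------------------------------
        inactive = make_bundle(BundleSpec(receptor_id), seed)
        inactive.label = f"{prefix}_inactive"
        _plant_pairs(_motif_pairs_resolved(inactive, table, motifs["HETY"]))
        _plant_pairs(_motif_pairs_resolved(inactive, table, motifs["cytoplasmic"]))
        _plant_broken(_motif_pairs_resolved(inactive, table, motifs["central"]))
        _plant_broken(_motif_pairs_resolved(inactive, table, motifs["PxxG"]))
        models[inactive.label] = inactive
        truth.state_labels[inactive.label] = "inactive"
        truth.network_fractions[inactive.label] = {"HETY": 1.0, "cytoplasmic": 1.0,
                                                   "central": 0.0, "PxxG": 0.0}

        # ---- ligand-free Gs-coupled (transitional) -----------------------
        free = make_bundle(BundleSpec(receptor_id, with_galpha=True), seed)
        free.label = f"{prefix}_ligand_free"
        chain = free.receptor_chain
        _translate(chain, tm6_all, planted["tm6_cyto_shift"] * r6_out)
        if receptor_id == "GLP1R":
            _plant_tm6_kink(chain, table, planted["kink_free"])
            glp1r_free_tip = _chain_index(chain)[table.resolve("6.59b")].atoms[0].position.copy()
        elif glp1r_free_tip is not None:
            achieved = _plant_tm6_kink(
                chain, table, planted["kink_free"],
                tip_position="6.59b", tip_reference=glp1r_free_tip,
                tip_target=CROSS_TIP_SEPARATION[receptor_id],
            )
            truth.cross_distances.append({
                "pair": ["glp1r_ligand_free", free.label],
                "positions": ["6.59b", "6.59b"],
                "distance": achieved,
                "scope_segments": ["TM1", "TM2", "TM3", "TM4", "TM5", "TM7"],
            })
        else:
            _plant_tm6_kink(chain, table, planted["kink_free"])
        truth.kink_angles[free.label] = planted["kink_free"]
        truth.displacements.append({
            "pair": [inactive.label, free.label], "position": planted["cyto_pos"],
            "distance": planted["tm6_cyto_shift"],
            "scope_segments": ["TM1", "TM2", "TM3", "TM4", "TM5", "TM7"],
        })
        # pocket-occupying loop conformations (receptor-specific)
        pep_template = _peptide_coords()
        pocket_loops = {"GCGR": ("ECL2", range(291, 297)), "GIPR": ("ECL3", range(362, 367))}
        if receptor_id in pocket_loops:
            _, residues_in = pocket_loops[receptor_id]
            idx = _chain_index(chain)
            for k, n in enumerate(residues_in):
                idx[n].atoms[0].position = pep_template[k] + np.array([0.9, 0.0, 0.3])
        if receptor_id == "GLP1R":
            _plant_pairs(_motif_pairs_resolved(free, table, motifs["central"]))
            _plant_pairs(_motif_pairs_resolved(free, table, motifs["PxxG"]))
            truth.network_fractions.setdefault(free.label, {}).update(central=1.0, PxxG=1.0)
        elif receptor_id == "GCGR":
            _plant_pairs(_motif_pairs_resolved(free, table, motifs["PxxG"]))
            _plant_pairs(_motif_pairs_resolved(free, table, motifs["fw_switch"]))
            _plant_broken(_motif_pairs_resolved(free, table, motifs["central"]))
            truth.network_fractions.setdefault(free.label, {}).update(
                central=0.0, PxxG=1.0, fw_switch=1.0)
        else:
            _plant_broken(_motif_pairs_resolved(free, table, motifs["central"]))
            _plant_broken(_motif_pairs_resolved(free, table, motifs["PxxG"]))
            truth.network_fractions.setdefault(free.label, {}).update(central=0.0, PxxG=0.0)
        _plant_interface(free, table, "ligand_free")
        _plant_broken(_motif_pairs_resolved(free, table, motifs["HETY"]))
        _plant_broken(_motif_pairs_resolved(free, table, motifs["cytoplasmic"]))
        truth.network_fractions.setdefault(free.label, {}).update(HETY=0.0, cytoplasmic=0.0)
        models[free.label] = free
        truth.state_labels[free.label] = "transitional"

        # ---- peptide-bound ----------------------------------------------
        bound = make_bundle(BundleSpec(receptor_id, with_galpha=True), seed)
        bound.label = f"{prefix}_bound"
        chain = bound.receptor_chain
        _translate(chain, tm6_all, planted["tm6_cyto_shift"] * r6_out)
        if "tm6_cyto_free_vs_bound" in planted:
            _translate(chain, tm6_all, -planted["tm6_cyto_free_vs_bound"] * r6_out)
            truth.displacements.append({
                "pair": [free.label, bound.label], "position": planted["cyto_pos"],
                "distance": planted["tm6_cyto_free_vs_bound"],
                "scope_segments": ["TM2", "TM3", "TM4", "TM5"],
            })
        tm6_pos, tm6_move = planted["ec_moves_bound"]["TM6"]
        free_ref = _chain_index(free.receptor_chain)[table.resolve(tm6_pos)].atoms[0].position
        achieved = _plant_tm6_kink(
            chain, table, planted["kink_bound"],
            tip_position=tm6_pos, tip_reference=free_ref, tip_target=tm6_move,
        )
        truth.kink_angles[bound.label] = planted["kink_bound"]
        truth.displacements.append({
            "pair": [free.label, bound.label], "position": tm6_pos, "distance": achieved,
            "scope_segments": ["TM2", "TM3", "TM4", "TM5"],
        })
        for seg in ("TM1", "TM7"):
            pos, move = planted["ec_moves_bound"][seg]
            numbers = _segment_part_numbers(table, seg, "ec")
            az = _HELIX_AZIMUTH[seg]
            inward = -np.array([np.cos(az), np.sin(az), 0.0])
            _translate(chain, numbers, move * inward)
            truth.displacements.append({
                "pair": [free.label, bound.label], "position": pos, "distance": move,
                "scope_segments": ["TM2", "TM3", "TM4", "TM5"],
            })
        pep = _peptide_chain()
        pep.entity_role = "peptide"
        bound.chains.append(pep)
        # relay + compact central layer + PxxG characterize the active state
        _plant_pairs(_motif_pairs_resolved(bound, table, motifs["transmission_relay"]))
        _plant_pairs(_motif_pairs_resolved(bound, table, motifs["central"]))
        _plant_pairs(_motif_pairs_resolved(bound, table, motifs["PxxG"]))
        if receptor_id == "GIPR":
            _plant_pairs(_motif_pairs_resolved(bound, table, motifs["tm5_ecl3_seal"]))
        _plant_interface(bound, table, "bound")
        _plant_peptide_anchors(bound, table)
        _plant_broken(_motif_pairs_resolved(bound, table, motifs["HETY"]))
        _plant_broken(_motif_pairs_resolved(bound, table, motifs["cytoplasmic"]))
        truth.network_fractions[bound.label] = {"HETY": 0.0, "cytoplasmic": 0.0,
                                                "central": 1.0, "PxxG": 1.0,
                                                "transmission_relay": 1.0}
        models[bound.label] = bound
        truth.state_labels[bound.label] = "active_like"

        # pocket-overlap ground truth: ligand-free loop atoms near the bound
        # peptide (frames coincide over TM2-TM5 by construction)
        pep_atoms = np.array([a.position for r in pep.residues for a in r.atoms])
        for loop in ("ECL2", "ECL3"):
            lo, hi = table.loops[loop]
            idx = _chain_index(free.receptor_chain)
            loop_atoms = [a.position for n in range(lo, hi + 1) if n in idx
                          for a in idx[n].atoms]
            from scipy.spatial.distance import cdist

            close = int((cdist(np.array(loop_atoms), pep_atoms).min(axis=1) <= 4.5).sum())
            truth.overlaps[f"{free.label}:{loop}"] = close

        for model in (inactive, free, bound):
            truth.chain_roles.update({c.chain_id: c.entity_role for c in model.chains})

    # correlated-noise twin for the near-identity RMSD comparison
    if "GLP1R" in order:
        rng = np.random.default_rng(seed + 977)
        agopam = models["glp1r_ligand_free"].copy()
        agopam.label = "glp1r_agopam"
        sigma = RMSD_AGOPAM / np.sqrt(3.0)
        for _, _, atom in agopam.iter_atoms():
            atom.position = atom.position + rng.normal(0.0, sigma, 3)
        models[agopam.label] = agopam
        truth.extras["rmsd_glp1r_ligand_free_vs_agopam"] = RMSD_AGOPAM
        truth.state_labels[agopam.label] = "transitional"

    if noise_sigma > 0:
        rng = np.random.default_rng(seed + 1)
        for model in models.values():
            for _, _, atom in model.iter_atoms():
                atom.position = atom.position + rng.normal(0.0, noise_sigma, 3)
    return models, truth


def _plant_interface(model: StructureModel, table: NumberingTable, state: str) -> None:
    receptor = model.receptor_chain
    galpha = model.chains_by_role("Galpha")[0]
    ridx, gidx = _chain_index(receptor), _chain_index(galpha)
    pairs = []
    for ga, pos, kind in _state_interface_pairs(state):
        if pos.startswith("ICL"):
            lo, hi = table.loops[pos]
            number = (lo + hi) // 2
        else:
            number = table.resolve(pos)
        pairs.append((gidx[ga], ridx[number], kind))
    _plant_pairs(pairs)


def _plant_peptide_anchors(model: StructureModel, table: NumberingTable) -> None:
    """Polar anchors tying the peptide into the pocket rim (7.35b and ECL3)."""
    receptor = model.receptor_chain
    pep = model.chains_by_role("peptide")[0]
    ridx, pidx = _chain_index(receptor), _chain_index(pep)
    lo, hi = table.loops["ECL3"]
    pairs = [
        (pidx[9], ridx[table.resolve("7.35b")], "polar"),
        (pidx[5], ridx[(lo + hi) // 2], "polar"),
    ]
    _plant_pairs(pairs)


def paper_emulation_set(
    seed: int = 0, noise_sigma: float = 0.0
) -> tuple[dict[str, StructureModel], SyntheticTruth]:
    """All three receptor trios plus the noisy near-identical twin."""
    return _emulation_models(["GLP1R", "GCGR", "GIPR"], seed, noise_sigma)


def write_fixture_set(
    out_dir: str | Path,
    seed: int = 0,
    receptor_ids: list[str] | None = None,
    noise_sigma: float = 0.0,
) -> dict:
    """Write the emulation fixtures as PDB files plus a JSON truth file.

    Deterministic filenames and byte-identical re-runs for a fixed seed.
    Returns a manifest {label: filename}.
    """
    from .structure_io import write_pdb

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if receptor_ids is not None and len(receptor_ids) == 0:
        (out_dir / "truth.json").write_text(SyntheticTruth().to_json() + "\n")
        return {}
    models, truth = _emulation_models(
        receptor_ids or ["GLP1R", "GCGR", "GIPR"], seed, noise_sigma
    )
    manifest = {}
    for label in sorted(models):
        filename = f"{label}.pdb"
        write_pdb(models[label], out_dir / filename)
        manifest[label] = filename
    (out_dir / "truth.json").write_text(truth.to_json() + "\n")
    return manifest
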