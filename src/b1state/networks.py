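"""Contacts, conserved-network integrity and interface comparison.

Contact criteria are purely geometric and hydrogen-free (deposited
cryo-EM models carry no hydrogens): a hydrogen bond is an N/O/S
heavy-atom pair within ``hbond_max``; a salt bridge pairs a Lys/Arg/His
side-chain nitrogen with an Asp/Glu side-chain oxygen within
``salt_bridge_max``; a hydrophobic contact pairs two side-chain carbons
within ``hydrophobic_max``.  Absolute contact counts are therefore
criteria-dependent; every report echoes the cutoffs used, and
comparative statements (peptide-bound > ligand-free) are the robust
output.

Named conserved networks (HETY, the cytoplasmic and central polar
networks, PxxG, the transmission relay, ...) ship in a structured
catalog; ``network_status`` evaluates the expected pairwise contacts of
a motif and declares it intact when at least ``threshold`` of them are
present (default 0.5 — network "breakup" is a qualitative notion, so
the raw fraction is always reported alongside the flag).

Buried interface area uses a deterministic Shrake-Rupley numerical SASA
(Fibonacci sphere, 960 points by default, probe 1.4 A) with the fixed
radii table C 1.70, N 1.55, O 1.52, S 1.80 A:
buried = (SASA_a + SASA_b - SASA_ab) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .errors import MotifResolutionError, RoleAssignmentError
from .numbering import NumberingTable
from .structure_io import Atom, Chain, Residue, StructureModel

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
_DEFAULT_RADIUS = 1.70
_BACKBONE = {"N", "CA", "C", "O", "OXT"}
_BASIC_SIDE_N = {
    ("LYS", "NZ"),
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"),
}
_ACIDIC_SIDE_O = {
    ("ASP", "OD1"), ("ASP", "OD2"),
    ("GLU", "OE1"), ("GLU", "OE2"),
}

AtomRef = tuple[Chain, Residue, Atom]


@dataclass
class ContactCriteria:
    hbond_max: float = 3.5
    salt_bridge_max: float = 4.0
    hydrophobic_max: float = 4.5
    min_seq_separation: int = 4

    def __post_init__(self) -> None:
        if min(self.hbond_max, self.salt_bridge_max, self.hydrophobic_max) <= 0:
            raise ValueError("contact cutoffs must be positive")

    def as_dict(self) -> dict:
        return {
            "hbond_max": self.hbond_max,
            "salt_bridge_max": self.salt_bridge_max,
            "hydrophobic_max": self.hydrophobic_max,
            "min_seq_separation": self.min_seq_separation,
        }


@dataclass(frozen=True)
class ContactRecord:
    chain_a: str
    residue_a: int
    resname_a: str
    atom_a: str
    chain_b: str
    residue_b: int
    resname_b: str
    atom_b: str
    contact_type: str  # hbond | salt_bridge | hydrophobic
    distance: float

    def residue_pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.chain_a, self.residue_a), (self.chain_b, self.residue_b))


def _is_polar(atom: Atom) -> bool:
    return atom.element in ("N", "O", "S")


def _is_sidechain_carbon(atom: Atom) -> bool:
    return atom.element == "C" and atom.name not in _BACKBONE


def _classify(res_a: Residue, atom_a: Atom, res_b: Residue, atom_b: Atom,
              d: float, criteria: ContactCriteria) -> str | None:
    key_a = (res_a.name, atom_a.name)
    key_b = (res_b.name, atom_b.name)
    salt = (
        d <= criteria.salt_bridge_max
        and ((key_a in _BASIC_SIDE_N and key_b in _ACIDIC_SIDE_O)
             or (key_b in _BASIC_SIDE_N and key_a in _ACIDIC_SIDE_O))
    )
    if salt:
        return "salt_bridge"
    if d <= criteria.hbond_max and _is_polar(atom_a) and _is_polar(atom_b):
        return "hbond"
    if d <= criteria.hydrophobic_max and _is_sidechain_carbon(atom_a) and _is_sidechain_carbon(atom_b):
        return "hydrophobic"
    return None


def find_contacts(
    model: StructureModel,
    criteria: ContactCriteria,
    group_a: list[AtomRef],
    group_b: list[AtomRef],
) -> list[ContactRecord]:
    """All contacts between two disjoint atom groups, deterministically ordered.

    Symmetric in group order: each record is canonicalised so that the
    lexicographically smaller (chain, residue, atom) side comes first.
    """
    if not group_a or not group_b:
        return []
    pa = np.array([a.position for _, _, a in group_a])
    pb = np.array([a.position for _, _, a in group_b])
    rmax = max(criteria.hbond_max, criteria.salt_bridge_max, criteria.hydrophobic_max)
    tree = cKDTree(pb)
    neighbor_lists = tree.query_ball_point(pa, r=rmax)

    records: set[ContactRecord] = set()
    for i, idx in enumerate(neighbor_lists):
        ca, ra, aa = group_a[i]
        for j in idx:
            cb, rb, ab = group_b[j]
            if ca.chain_id == cb.chain_id:
                if ra.key == rb.key:
                    continue
                if abs(ra.author_number - rb.author_number) < criteria.min_seq_separation:
                    continue
            d = float(np.linalg.norm(aa.position - ab.position))
            kind = _classify(ra, aa, rb, ab, d, criteria)
            if kind is None:
                continue
            side_a = (ca.chain_id, ra.author_number, ra.name, aa.name)
            side_b = (cb.chain_id, rb.author_number, rb.name, ab.name)
            if side_b < side_a:
                side_a, side_b = side_b, side_a
            records.add(ContactRecord(*side_a, *side_b, contact_type=kind, distance=round(d, 6)))
    return sorted(
        records,
        key=lambda r: (r.chain_a, r.residue_a, r.atom_a, r.chain_b, r.residue_b, r.atom_b, r.contact_type),
    )


# ---------------------------------------------------------------------------
# Motifs


@dataclass(frozen=True)
class MotifMember:
    """A motif member: generic position, loop residue or partner residue."""

    raw: str

    @property
    def kind(self) -> str:
        if ":" not in self.raw:
            return "generic"
        prefix = self.raw.split(":", 1)[0]
        return "loop" if prefix.startswith(("ECL", "ICL")) else "partner"

    @property
    def partner_role(self) -> str:
        return self.raw.split(":", 1)[0]

    @property
    def author_number(self) -> int:
        return int(self.raw.split(":", 1)[1])

    def __str__(self) -> str:
        return self.raw


@dataclass
class MotifDefinition:
    name: str
    members: list[MotifMember]
    pairs: list[tuple[MotifMember, MotifMember, str]]
    allowed: dict[str, list[str]] = field(default_factory=dict)
    description: str = ""
    receptors: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"motif {self.name}: needs >= 2 members")
        member_set = {m.raw for m in self.members}
        for a, b, kind in self.pairs:
            if a.raw not in member_set or b.raw not in member_set:
                raise ValueError(f"motif {self.name}: pair ({a}, {b}) not drawn from members")
            if kind not in ("polar", "hydrophobic"):
                raise ValueError(f"motif {self.name}: unknown pair kind {kind!r}")


from functools import lru_cache


@lru_cache(maxsize=1)
def _motif_text() -> str:
    return resources.files("b1state.data").joinpath("motifs.yaml").read_text()


def load_motifs() -> dict[str, MotifDefinition]:
    raw = yaml.safe_load(_motif_text())
    out: dict[str, MotifDefinition] = {}
    for name, entry in raw["motifs"].items():
        members = [MotifMember(m) for m in entry["members"]]
        pairs = [(MotifMember(a), MotifMember(b), kind) for a, b, kind in entry["pairs"]]
        out[name] = MotifDefinition(
            name=name,
            members=members,
            pairs=pairs,
            allowed={k: list(v) for k, v in entry.get("allowed", {}).items()},
            description=entry.get("description", "").strip(),
            receptors=entry.get("receptors"),
        )
    return out


@dataclass
class NetworkStatus:
    motif_name: str
    structure_label: str
    fraction: float
    intact: bool
    threshold: float
    evidence: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_present = sum(1 for e in self.evidence if e["present"])
        if self.evidence and not np.isclose(self.fraction, n_present / len(self.evidence)):
            raise ValueError("fraction inconsistent with evidence list")


def _resolve_member(
    model: StructureModel, table: NumberingTable, member: MotifMember
) -> tuple[Chain, Residue]:
    if member.kind == "partner":
        chains = model.chains_by_role(member.partner_role)
        if not chains:
            raise MotifResolutionError(
                f"{model.label}: no chain with role {member.partner_role!r} for member {member}"
            )
        chain = chains[0]
        number = member.author_number
    else:
        chain = model.receptor_chain
        number = member.author_number if member.kind == "loop" else table.resolve(member.raw)
    res = chain.residue(number)
    if res is None:
        raise MotifResolutionError(
            f"{model.label}: motif member {member} -> residue {number} absent from chain "
            f"{chain.chain_id}"
        )
    return chain, res


def network_status(
    model: StructureModel,
    table: NumberingTable,
    motif: MotifDefinition,
    criteria: ContactCriteria | None = None,
    threshold: float = 0.5,
) -> NetworkStatus:
    """Evaluate a motif's expected pairwise contacts on one model."""
    criteria = criteria or ContactCriteria()
    evidence = []
    for mem_a, mem_b, kind in motif.pairs:
        chain_a, res_a = _resolve_member(model, table, mem_a)
        chain_b, res_b = _resolve_member(model, table, mem_b)
        group_a = [(chain_a, res_a, atom) for atom in res_a.heavy_atoms()]
        group_b = [(chain_b, res_b, atom) for atom in res_b.heavy_atoms()]
        contacts = find_contacts(model, criteria, group_a, group_b)
        if kind == "polar":
            hits = [c for c in contacts if c.contact_type in ("hbond", "salt_bridge")]
        else:
            hits = [c for c in contacts if c.contact_type == "hydrophobic"]
        evidence.append(
            {
                "pair": (str(mem_a), str(mem_b)),
                "kind": kind,
                "present": bool(hits),
                "min_distance": min((c.distance for c in hits), default=None),
            }
        )
    fraction = sum(e["present"] for e in evidence) / len(evidence) if evidence else 0.0
    return NetworkStatus(
        motif_name=motif.name,
        structure_label=model.label,
        fraction=fraction,
        intact=fraction >= threshold,
        threshold=threshold,
        evidence=evidence,
    )


# ---------------------------------------------------------------------------
# SASA / interface


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2)."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("SASA of zero atoms is undefined")
    unit = fibonacci_sphere(sphere_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    rmax = float(expanded.max())
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        ri = expanded[i]
        pts = coords[i] + ri * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], r=ri + rmax) if j != i]
        if neighbors:
            nb = np.array(neighbors)
            # keep only spheres that actually overlap atom i's expanded sphere
            dists = np.linalg.norm(coords[nb] - coords[i], axis=1)
            nb = nb[dists < ri + expanded[nb]]
            accessible = np.ones(sphere_points, dtype=bool)
            for j in nb:
                accessible &= (
                    np.linalg.norm(pts - coords[j], axis=1) >= expanded[j]
                )
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ri * ri * frac
    return areas


def _radii_for(atoms: list[AtomRef]) -> np.ndarray:
    return np.array([VDW_RADII.get(a.element, _DEFAULT_RADIUS) for _, _, a in atoms])


def buried_area(
    model: StructureModel,
    group_a: list[AtomRef],
    group_b: list[AtomRef],
    probe: float = 1.4,
    sphere_points: int = 960,
) -> float:
    """Interface area buried between two atom groups:
    (SASA_a + SASA_b - SASA_ab) / 2, in A^2."""
    if not group_a or not group_b:
        raise ValueError("buried_area requires two non-empty groups")
    ca = np.array([a.position for _, _, a in group_a])
    cb = np.array([a.position for _, _, a in group_b])
    ra = _radii_for(group_a)
    rb = _radii_for(group_b)
    sasa_a = shrake_rupley(ca, ra, probe, sphere_points).sum()
    sasa_b = shrake_rupley(cb, rb, probe, sphere_points).sum()
    sasa_ab = shrake_rupley(
        np.vstack([ca, cb]), np.concatenate([ra, rb]), probe, sphere_points
    ).sum()
    return max(0.0, float((sasa_a + sasa_b - sasa_ab) / 2.0))


@dataclass
class InterfaceSummary:
    structure_label: str
    receptor_chain: str
    partner_chains: list[str]
    contacts: list[ContactRecord]
    buried_area: float
    per_segment: dict[str, int] = field(default_factory=dict)
    criteria: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.buried_area < 0:
            raise ValueError("buried area must be non-negative")

    @property
    def contact_count(self) -> int:
        return len(self.contacts)


def interface_summary(
    model: StructureModel,
    criteria: ContactCriteria | None = None,
    table: NumberingTable | None = None,
    partner_roles: tuple[str, ...] = ("Galpha", "Gbeta", "Ggamma"),
    sphere_points: int = 960,
) -> InterfaceSummary:
    """Receptor vs G-protein contacts, buried area and per-segment counts."""
    criteria = criteria or ContactCriteria()
    receptor = model.receptor_chain
    partners = [c for role in partner_roles for c in model.chains_by_role(role)]
    if not partners:
        raise RoleAssignmentError(
            f"{model.label}: no partner chains with roles {partner_roles}"
        )
    group_r = [(receptor, r, a) for r in receptor.residues for a in r.heavy_atoms()]
    group_p = [(c, r, a) for c in partners for r in c.residues for a in r.heavy_atoms()]
    contacts = find_contacts(model, criteria, group_r, group_p)
    area = buried_area(model, group_r, group_p, sphere_points=sphere_points)

    per_segment: dict[str, int] = {}
    for rec in contacts:
        # receptor side is whichever chain id matches
        num = rec.residue_a if rec.chain_a == receptor.chain_id else rec.residue_b
        if table is not None:
            try:
                seg = table.label(num)
                if seg not in ("ICL1", "ECL1", "ICL2", "ECL2", "ICL3", "ECL3"):
                    seg = seg.split(".")[0]
                    seg = {"1": "TM1", "2": "TM2", "3": "TM3", "4": "TM4",
                           "5": "TM5", "6": "TM6", "7": "TM7", "8": "H8"}[seg]
            except Exception:
                seg = "other"
        else:
            seg = "receptor"
        per_segment[seg] = per_segment.get(seg, 0) + 1
    return InterfaceSummary(
        structure_label=model.label,
        receptor_chain=receptor.chain_id,
        partner_chains=[c.chain_id for c in partners],
        contacts=contacts,
        buried_area=area,
        per_segment=dict(sorted(per_segment.items())),
        criteria=criteria.as_dict(),
    )
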