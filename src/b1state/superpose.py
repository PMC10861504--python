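"""Optimal rigid superposition (Kabsch) and RMSD.

``kabsch`` computes the proper rotation + translation minimising the
RMSD of one point set onto another (SVD solution with the reflection
branch corrected to det(R) = +1).  ``superpose_models`` lifts this to
structure models with a named atom scope; correspondences are built by
generic position (for cross-receptor comparisons) or author number (for
same-receptor pairs), and the matched residue list is recorded so every
reported RMSD is auditable.

The default scope for displacement measurements is all matched
transmembrane-segment C-alpha atoms ("TMD Ca"): receptors are aligned
on the helical bundle before any per-position shift is read off.  No
outlier trimming is performed; a single well-defined number is
preferred over an iteratively edited one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CorrespondenceError, DegenerateGeometryError
from .numbering import NumberingTable, SEGMENTS
from .structure_io import StructureModel

_TM_SEGMENTS = tuple(s for s in SEGMENTS if s.startswith("TM"))


@dataclass
class RigidTransform:
    """x -> R x + t with R a proper rotation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation has determinant != +1 (reflection)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(rotation=Rinv, translation=-Rinv @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(rotation=np.eye(3), translation=np.zeros(3))

    def matrix3x4(self) -> list[list[float]]:
        return np.hstack([self.rotation, self.translation[:, None]]).tolist()


def rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Root-mean-square deviation between paired coordinates (no fitting)."""
    P = np.asarray(P, dtype=float).reshape(-1, 3)
    Q = np.asarray(Q, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise ValueError(f"point count mismatch: {P.shape[0]} vs {Q.shape[0]}")
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


def kabsch(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping point set P onto Q."""
    P = np.asarray(P, dtype=float).reshape(-1, 3)
    Q = np.asarray(Q, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise ValueError(f"point count mismatch: {P.shape[0]} vs {Q.shape[0]}")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    if S[0] <= 0 or S[1] / S[0] < 1e-10:
        raise DegenerateGeometryError("point set is (near-)collinear; rotation underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(rotation=R, translation=cq - R @ cp)


@dataclass
class Scope:
    """Named atom scope for a superposition.

    ``segments`` defaults to the seven TM helices; ``match_by`` is
    "generic" (cross-receptor, position-matched) or "author"
    (same-receptor numbering).
    """

    name: str = "TMD Ca"
    segments: Sequence[str] | None = None
    match_by: str = "generic"
    atom_name: str = "CA"

    def segment_list(self) -> tuple[str, ...]:
        return tuple(self.segments) if self.segments is not None else _TM_SEGMENTS


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    atom_count: int
    scope_name: str
    matched: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        if self.atom_count < 3:
            raise ValueError("superposition needs >= 3 atoms")


def matched_coordinates(
    mobile: StructureModel,
    reference: StructureModel,
    scope: Scope,
    table_mobile: NumberingTable,
    table_reference: NumberingTable | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Paired (mobile, reference) coordinates for the scope.

    Only positions present in both receptor chains (and carrying the
    scope atom) are used; each matched position is recorded by its
    generic label.
    """
    table_reference = table_reference or table_mobile
    cm = mobile.receptor_chain
    cr = reference.receptor_chain
    P, Q, labels = [], [], []
    for segment in scope.segment_list():
        if scope.match_by == "generic":
            nums_m = table_mobile.segment_residues(segment)
            nums_r = table_reference.segment_residues(segment)
            anchor_m = table_mobile.anchors[segment]
            anchor_r = table_reference.anchors[segment]
            cents_m = {anchor_m.anchor_cents + (n - anchor_m.anchor_author): n for n in nums_m}
            cents_r = {anchor_r.anchor_cents + (n - anchor_r.anchor_author): n for n in nums_r}
            shared = sorted(set(cents_m) & set(cents_r))
            pairs = [(cents_m[c], cents_r[c], c) for c in shared]
        else:
            nums = sorted(set(table_mobile.segment_residues(segment))
                          & set(table_reference.segment_residues(segment)))
            anchor = table_mobile.anchors[segment]
            pairs = [(n, n, anchor.anchor_cents + (n - anchor.anchor_author)) for n in nums]
        for num_m, num_r, cents in pairs:
            res_m = cm.residue(num_m)
            res_r = cr.residue(num_r)
            if res_m is None or res_r is None:
                continue
            am = res_m.atom(scope.atom_name)
            ar = res_r.atom(scope.atom_name)
            if am is None or ar is None:
                continue
            P.append(am.position)
            Q.append(ar.position)
            labels.append(f"{segment}:{cents / 100:.2f}b")
    return (
        np.array(P, dtype=float).reshape(-1, 3),
        np.array(Q, dtype=float).reshape(-1, 3),
        labels,
    )


def superpose_models(
    mobile: StructureModel,
    reference: StructureModel,
    scope: Scope,
    table_mobile: NumberingTable,
    table_reference: NumberingTable | None = None,
) -> tuple[StructureModel, SuperpositionResult]:
    """Superpose ``mobile`` onto ``reference`` over the scope's C-alphas."""
    P, Q, labels = matched_coordinates(mobile, reference, scope, table_mobile, table_reference)
    if len(P) < 3:
        raise CorrespondenceError(
            f"{mobile.label} vs {reference.label}: only {len(P)} matched atoms in scope "
            f"{scope.name!r}"
        )
    transform = kabsch(P, Q)
    moved = mobile.transformed(transform.rotation, transform.translation)
    result = SuperpositionResult(
        transform=transform,
        rmsd=rmsd(transform.apply(P), Q),
        atom_count=len(P),
        scope_name=scope.name,
        matched=labels,
    )
    return moved, result
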