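"""Pipeline orchestration: run a configured comparison and call states.

A :class:`ComparisonSpec` names the structures (coordinate files or
in-memory models, each with a receptor id, a biological role tag and
optional chain-role hints) and the measurement plan: TM6 kink triples,
per-position displacements with their superposition scope, cross-
structure distances, conserved-network evaluations, receptor-G-protein
interface summaries, pocket-overlap queries and state calls.  The
output is a bundle of tidy tables, one row per measurement, each row
carrying its full provenance (structures, positions, resolved author
residues, scope, criteria) so every number is auditable; per-row
failures are recorded instead of aborting the run, and repeated runs on
identical inputs produce byte-identical files.

The conformational-state caller reduces the measurements to a rule
table over the two base-locking polar networks:

* HETY and cytoplasmic networks intact            -> inactive
* both broken, G-alpha engaged, no peptide bound  -> transitional
* both broken, G-alpha engaged, peptide bound     -> active_like
* anything else                                   -> indeterminate

The TM6 kink is reported as evidence but is deliberately not a
classification feature: ligand-free kink angles are receptor-specific
(GIPR's moderate ~148 deg vs GLP-1R's sharp ~98 deg), so no single
angle threshold separates the states across receptors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__ as _version
from .errors import B1StateError, SpecValidationError
from .conformetrics import cross_structure_distance, kink_angle, paired_displacement, pocket_overlap
from .networks import (
    ContactCriteria,
    MotifDefinition,
    find_contacts,
    interface_summary,
    load_motifs,
    network_status,
)
from .numbering import NumberingTable, load_tables
from .structure_io import StructureModel, assign_roles, read_structure
from .superpose import Scope

STATE_ROLES = ("inactive", "ligand_free_Gs", "peptide_bound_Gs", "intermediate")


@dataclass
class StructureEntry:
    label: str
    receptor_id: str
    role: str = "intermediate"
    path: str | None = None
    model: StructureModel | None = None
    receptor_chain_hint: str | None = None
    chain_roles: dict[str, str] = field(default_factory=dict)

    def load(self) -> StructureModel:
        if self.model is None:
            model = read_structure(self.path)
            model.label = self.label
            self.model = assign_roles(
                model, receptor_hint=self.receptor_chain_hint, role_hints=self.chain_roles
            )
        return self.model


@dataclass
class ComparisonSpec:
    structures: list[StructureEntry]
    kinks: list[dict] = field(default_factory=list)
    displacements: list[dict] = field(default_factory=list)
    distances: list[dict] = field(default_factory=list)
    networks: list[dict] = field(default_factory=list)
    interfaces: list[str] = field(default_factory=list)
    overlaps: list[dict] = field(default_factory=list)
    classify: list[str] = field(default_factory=list)
    criteria: ContactCriteria = field(default_factory=ContactCriteria)
    network_threshold: float = 0.5

    def validate(self) -> None:
        labels = [s.label for s in self.structures]
        if len(labels) != len(set(labels)):
            raise SpecValidationError("structure labels must be unique")
        known = set(labels)

        def _check(label: str, where: str) -> None:
            if label not in known:
                raise SpecValidationError(f"{where}: unknown structure label {label!r}")

        for row in self.kinks:
            _check(row["structure"], "kinks")
        for row in self.displacements:
            _check(row["mobile"], "displacements")
            _check(row["reference"], "displacements")
        for row in self.distances:
            _check(row["mobile"], "distances")
            _check(row["reference"], "distances")
        for row in self.networks:
            _check(row["structure"], "networks")
        for label in self.interfaces:
            _check(label, "interfaces")
        for row in self.overlaps:
            _check(row["apo"], "overlaps")
            _check(row["holo"], "overlaps")
        for label in self.classify:
            _check(label, "classify")

    def entry(self, label: str) -> StructureEntry:
        for s in self.structures:
            if s.label == label:
                return s
        raise SpecValidationError(f"unknown structure label {label!r}")

    @staticmethod
    def from_yaml(path: str | Path) -> "ComparisonSpec":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        structures = []
        for s in raw.get("structures", []):
            p = s.get("path")
            if p is not None and not Path(p).is_absolute():
                p = str((path.parent / p).resolve())
            structures.append(
                StructureEntry(
                    label=s["label"],
                    receptor_id=s["receptor"],
                    role=s.get("role", "intermediate"),
                    path=p,
                    receptor_chain_hint=s.get("receptor_chain"),
                    chain_roles=dict(s.get("chain_roles", {})),
                )
            )
        plan = raw.get("measurements", {})
        criteria = ContactCriteria(**raw.get("criteria", {}))
        return ComparisonSpec(
            structures=structures,
            kinks=list(plan.get("kinks", [])),
            displacements=list(plan.get("displacements", [])),
            distances=list(plan.get("distances", [])),
            networks=list(plan.get("networks", [])),
            interfaces=list(plan.get("interfaces", [])),
            overlaps=list(plan.get("overlaps", [])),
            classify=list(plan.get("classify", [])),
            criteria=criteria,
            network_threshold=float(raw.get("network_threshold", 0.5)),
        )


# ---------------------------------------------------------------------------
# State calling


@dataclass
class StateCall:
    structure_label: str
    call: str  # inactive | transitional | active_like | indeterminate
    evidence: dict = field(default_factory=dict)


def classify_state(
    model: StructureModel,
    table: NumberingTable,
    criteria: ContactCriteria | None = None,
    motifs: dict[str, MotifDefinition] | None = None,
    threshold: float = 0.5,
) -> StateCall:
    """Call inactive / transitional / active_like from network integrity,
    G-alpha engagement and peptide engagement."""
    criteria = criteria or ContactCriteria()
    motifs = motifs or load_motifs()
    hety = network_status(model, table, motifs["HETY"], criteria, threshold)
    cyto = network_status(model, table, motifs["cytoplasmic"], criteria, threshold)

    def _chain_atoms(chain):
        return [(chain, r, a) for r in chain.residues for a in r.heavy_atoms()]

    receptor_atoms = _chain_atoms(model.receptor_chain)
    galpha_engaged = False
    for chain in model.chains_by_role("Galpha"):
        if find_contacts(model, criteria, receptor_atoms, _chain_atoms(chain)):
            galpha_engaged = True
            break
    peptide_engaged = False
    for chain in model.chains_by_role("peptide"):
        if find_contacts(model, criteria, receptor_atoms, _chain_atoms(chain)):
            peptide_engaged = True
            break

    if hety.intact and cyto.intact:
        call = "inactive"
    elif not hety.intact and not cyto.intact and galpha_engaged:
        call = "active_like" if peptide_engaged else "transitional"
    else:
        call = "indeterminate"
    return StateCall(
        structure_label=model.label,
        call=call,
        evidence={
            "HETY_fraction": hety.fraction,
            "HETY_intact": hety.intact,
            "cytoplasmic_fraction": cyto.fraction,
            "cytoplasmic_intact": cyto.intact,
            "galpha_engaged": galpha_engaged,
            "peptide_engaged": peptide_engaged,
        },
    )


# ---------------------------------------------------------------------------
# Running the plan


def _scope_from(row: dict) -> Scope:
    segments = row.get("scope")
    if segments in (None, "TMD"):
        return Scope()
    return Scope(name="+".join(segments), segments=list(segments))


@dataclass
class ReportBundle:
    tables: dict[str, pd.DataFrame]
    log: str

    def write(self, out_dir: str | Path) -> list[Path]:
        """TSV + JSON per table plus the run log; deterministic bytes."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name in sorted(self.tables):
            df = self.tables[name]
            tsv = out_dir / f"{name}.tsv"
            df.to_csv(tsv, sep="\t", index=False, float_format="%.4f", lineterminator="\n")
            js = out_dir / f"{name}.json"
            payload = json.loads(df.to_json(orient="records", double_precision=4))
            js.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
            written.extend([tsv, js])
        log_path = out_dir / "run_log.txt"
        log_path.write_text(self.log)
        written.append(log_path)
        return written


def run_comparison(spec: ComparisonSpec, tables: dict[str, NumberingTable] | None = None) -> ReportBundle:
    """Execute the full measurement plan; failures are per-row, not fatal."""
    spec.validate()
    tables = tables or load_tables()
    motifs = load_motifs()
    crit = spec.criteria

    def _table(entry: StructureEntry) -> NumberingTable:
        if entry.receptor_id not in tables:
            raise SpecValidationError(f"no numbering table for receptor {entry.receptor_id!r}")
        return tables[entry.receptor_id]

    kink_rows, disp_rows, dist_rows = [], [], []
    net_rows, iface_rows, overlap_rows, state_rows = [], [], [], []
    errors: list[str] = []

    for row in spec.kinks:
        entry = spec.entry(row["structure"])
        triple = row.get("triple", ["6.33b", "6.47b", "6.59b"])
        out = {"structure": entry.label, "receptor": entry.receptor_id, "state_role": entry.role,
               "g1": triple[0], "g_vertex": triple[1], "g3": triple[2]}
        try:
            m = kink_angle(entry.load(), _table(entry), *triple)
            out.update(residues="-".join(map(str, m.author_residues)),
                       angle_deg=m.angle_deg, error="")
        except B1StateError as exc:
            out.update(residues="", angle_deg=float("nan"), error=str(exc))
            errors.append(f"kink {entry.label}: {exc}")
        kink_rows.append(out)

    for row in spec.displacements:
        mobile, reference = spec.entry(row["mobile"]), spec.entry(row["reference"])
        scope = _scope_from(row)
        out = {"mobile": mobile.label, "reference": reference.label,
               "position": row["position"], "scope": scope.name}
        try:
            m = paired_displacement(
                mobile.load(), reference.load(), _table(mobile), row["position"],
                scope=scope, table_b=_table(reference),
            )
            out.update(distance_A=m.distance, error="")
        except B1StateError as exc:
            out.update(distance_A=float("nan"), error=str(exc))
            errors.append(f"displacement {mobile.label}->{reference.label}: {exc}")
        disp_rows.append(out)

    for row in spec.distances:
        mobile, reference = spec.entry(row["mobile"]), spec.entry(row["reference"])
        scope = _scope_from(row)
        out = {"mobile": mobile.label, "reference": reference.label,
               "residue_mobile": str(row["residue_mobile"]),
               "residue_reference": str(row["residue_reference"]), "scope": scope.name}
        try:
            d = cross_structure_distance(
                mobile.load(), reference.load(), _table(mobile),
                row["residue_mobile"], row["residue_reference"],
                scope=scope, table_b=_table(reference),
            )
            out.update(distance_A=d, error="")
        except B1StateError as exc:
            out.update(distance_A=float("nan"), error=str(exc))
            errors.append(f"distance {mobile.label}->{reference.label}: {exc}")
        dist_rows.append(out)

    for row in spec.networks:
        entry = spec.entry(row["structure"])
        for motif_name in row.get("motifs", ["HETY", "cytoplasmic"]):
            motif = motifs[motif_name]
            out = {"structure": entry.label, "receptor": entry.receptor_id,
                   "state_role": entry.role, "motif": motif_name,
                   "threshold": spec.network_threshold, "criteria": json.dumps(crit.as_dict())}
            if motif.receptors and entry.receptor_id not in motif.receptors:
                continue
            try:
                status = network_status(entry.load(), _table(entry), motif, crit,
                                        spec.network_threshold)
                out.update(fraction=status.fraction, intact=status.intact, error="")
            except B1StateError as exc:
                out.update(fraction=float("nan"), intact=False, error=str(exc))
                errors.append(f"network {entry.label}/{motif_name}: {exc}")
            net_rows.append(out)

    for label in spec.interfaces:
        entry = spec.entry(label)
        out = {"structure": label, "receptor": entry.receptor_id, "state_role": entry.role,
               "criteria": json.dumps(crit.as_dict())}
        try:
            summary = interface_summary(entry.load(), crit, _table(entry))
            out.update(
                contact_count=summary.contact_count,
                hbonds=sum(1 for c in summary.contacts if c.contact_type == "hbond"),
                salt_bridges=sum(1 for c in summary.contacts if c.contact_type == "salt_bridge"),
                hydrophobic=sum(1 for c in summary.contacts if c.contact_type == "hydrophobic"),
                buried_area_A2=summary.buried_area,
                per_segment=json.dumps(summary.per_segment, sort_keys=True),
                error="",
            )
        except B1StateError as exc:
            out.update(contact_count=-1, buried_area_A2=float("nan"), error=str(exc))
            errors.append(f"interface {label}: {exc}")
        iface_rows.append(out)

    for row in spec.overlaps:
        apo, holo = spec.entry(row["apo"]), spec.entry(row["holo"])
        scope = _scope_from(row)
        cutoff = float(row.get("cutoff", 4.5))
        loop = row["loop"]
        out = {"apo": apo.label, "holo": holo.label, "loop": str(loop),
               "cutoff_A": cutoff, "scope": scope.name}
        try:
            res = pocket_overlap(
                apo.load(), holo.load(), _table(apo), loop,
                cutoff=cutoff, scope=scope, table_holo=_table(holo),
            )
            out.update(overlap_atoms=res.count, loop_atoms=res.total_loop_atoms, error="")
        except B1StateError as exc:
            out.update(overlap_atoms=-1, loop_atoms=-1, error=str(exc))
            errors.append(f"overlap {apo.label}->{holo.label}: {exc}")
        overlap_rows.append(out)

    for label in spec.classify:
        entry = spec.entry(label)
        out = {"structure": label, "receptor": entry.receptor_id, "state_role": entry.role}
        try:
            call = classify_state(entry.load(), _table(entry), crit, motifs,
                                  spec.network_threshold)
            out.update(call=call.call, error="", **{k: v for k, v in call.evidence.items()})
        except B1StateError as exc:
            out.update(call="error", error=str(exc))
            errors.append(f"classify {label}: {exc}")
        state_rows.append(out)

    tables_out = {
        "kinks": pd.DataFrame(kink_rows),
        "displacements": pd.DataFrame(disp_rows),
        "distances": pd.DataFrame(dist_rows),
        "networks": pd.DataFrame(net_rows),
        "interfaces": pd.DataFrame(iface_rows),
        "overlaps": pd.DataFrame(overlap_rows),
        "states": pd.DataFrame(state_rows),
    }
    log_lines = [
        f"b1state {_version}",
        f"criteria: {json.dumps(crit.as_dict(), sort_keys=True)}",
        f"network_threshold: {spec.network_threshold}",
        f"structures: {', '.join(s.label for s in spec.structures)}",
        f"rows: " + ", ".join(f"{k}={len(v)}" for k, v in sorted(tables_out.items())),
    ]
    if errors:
        log_lines.append("row errors:")
        log_lines.extend(f"  {e}" for e in errors)
    return ReportBundle(tables=tables_out, log="\n".join(log_lines) + "\n")
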