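"""Class-B ("Wootten") generic residue numbering.

Positions are written ``x.yyb`` where ``x`` is the helix (1-7, or 8 for
the amphipathic helix H8) and consecutive residues differ by 0.01.
Within a segment the map to deposited author numbers is exactly linear,
so a single attested anchor pair per (receptor, segment) determines the
whole segment:

    author_number = anchor_author + 100 * (index - anchor_index)

The shipped tables for GLP1R, GCGR and GIPR are seeded from residue <->
position pairs printed in the structural literature on these receptors;
``validate_table`` re-checks every attested pair against the linear
model and reports (without resolving) the inconsistencies.  Position
8.47b aliases 7.61b: the TM7-H8 junction asparagine is labelled either
way depending on the numbering convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import NoAnchorError, RangeError, UnmappedError

SEGMENTS = ("TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7", "H8")
LOOPS = ("ICL1", "ECL1", "ICL2", "ECL2", "ICL3", "ECL3")

_POSITION_RE = re.compile(r"^([1-8])\.(\d{2})b$")

# index bounds in hundredths, keyed by helix number; the upper TM bound
# admits 2.71b-class positions attested at helix ends
_TM_BOUNDS = (20, 75)
_H8_BOUNDS = (40, 70)


@dataclass(frozen=True)
class GenericPosition:
    """A generic position such as 6.37b, stored as integer hundredths."""

    segment: str
    cents: int  # e.g. 637 for 6.37b

    @property
    def helix(self) -> int:
        return 8 if self.segment == "H8" else int(self.segment[2])

    @property
    def index(self) -> float:
        return self.cents / 100.0

    def __str__(self) -> str:
        return f"{self.cents // 100}.{self.cents % 100:02d}b"

    @staticmethod
    def parse(text: str) -> "GenericPosition":
        m = _POSITION_RE.match(text.strip())
        if not m:
            raise ValueError(f"not a generic position: {text!r}")
        helix, frac = int(m.group(1)), int(m.group(2))
        lo, hi = _H8_BOUNDS if helix == 8 else _TM_BOUNDS
        if not lo <= frac <= hi:
            raise ValueError(f"{text!r}: fractional index .{frac:02d} outside [.{lo}, .{hi}]")
        segment = "H8" if helix == 8 else f"TM{helix}"
        return GenericPosition(segment=segment, cents=helix * 100 + frac)


@dataclass(frozen=True)
class SegmentAnchor:
    receptor_id: str
    segment: str
    anchor_cents: int
    anchor_author: int
    start_author: int
    end_author: int

    def __post_init__(self) -> None:
        if not self.start_author <= self.anchor_author <= self.end_author:
            raise ValueError(
                f"{self.receptor_id} {self.segment}: anchor {self.anchor_author} "
                f"outside [{self.start_author}, {self.end_author}]"
            )


@dataclass
class NumberingTable:
    receptor_id: str
    anchors: dict[str, SegmentAnchor]
    loops: dict[str, tuple[int, int]] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)

    # -- forward -----------------------------------------------------------
    def resolve(self, position: str | GenericPosition) -> int:
        """Map a generic position to the deposited author residue number."""
        if isinstance(position, str):
            position = GenericPosition.parse(self.aliases.get(position.strip(), position))
        elif str(position) in self.aliases:
            position = GenericPosition.parse(self.aliases[str(position)])
        anchor = self.anchors.get(position.segment)
        if anchor is None:
            raise NoAnchorError(f"{self.receptor_id}: segment {position.segment} not anchored")
        number = anchor.anchor_author + (position.cents - anchor.anchor_cents)
        if not anchor.start_author <= number <= anchor.end_author:
            raise RangeError(
                f"{self.receptor_id}: {position} -> {number} outside "
                f"{position.segment} range [{anchor.start_author}, {anchor.end_author}]"
            )
        return number

    # -- inverse -----------------------------------------------------------
    def label(self, author_number: int) -> str:
        """Map an author number back to a generic position or loop label."""
        for loop, (lo, hi) in self.loops.items():
            if lo <= author_number <= hi:
                return loop
        for segment in SEGMENTS:
            anchor = self.anchors.get(segment)
            if anchor and anchor.start_author <= author_number <= anchor.end_author:
                cents = anchor.anchor_cents + (author_number - anchor.anchor_author)
                return str(GenericPosition(segment=segment, cents=cents))
        raise UnmappedError(
            f"{self.receptor_id}: residue {author_number} outside all known segments/loops"
        )

    def segment_residues(self, segment: str) -> list[int]:
        """All author numbers of a TM segment or loop, in order."""
        if segment in self.loops:
            lo, hi = self.loops[segment]
            return list(range(lo, hi + 1))
        anchor = self.anchors.get(segment)
        if anchor is None:
            raise NoAnchorError(f"{self.receptor_id}: segment {segment} not anchored")
        return list(range(anchor.start_author, anchor.end_author + 1))


# ---------------------------------------------------------------------------
# Shipped data

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class AttestedPair:
    receptor_id: str
    residue_letter: str
    author_number: int
    generic: str  # "6.37b" or a loop name
    source: str

    @property
    def residue_name(self) -> str:
        return _ONE_TO_THREE[self.residue_letter]


from functools import lru_cache


@lru_cache(maxsize=1)
def _load_text() -> str:
    return resources.files("b1state.data").joinpath("numbering.yaml").read_text()


def _load_raw() -> dict:
    return yaml.safe_load(_load_text())


def load_tables() -> dict[str, NumberingTable]:
    """Load the shipped numbering tables for GLP1R, GCGR and GIPR."""
    raw = _load_raw()
    aliases = dict(raw.get("aliases", {}))
    tables: dict[str, NumberingTable] = {}
    for rid, entry in raw["receptors"].items():
        anchors = {}
        for seg, a in entry["segments"].items():
            anchors[seg] = SegmentAnchor(
                receptor_id=rid,
                segment=seg,
                anchor_cents=round(float(a["anchor_index"]) * 100),
                anchor_author=int(a["anchor_author"]),
                start_author=int(a["start"]),
                end_author=int(a["end"]),
            )
        loops = {name: (int(lo), int(hi)) for name, (lo, hi) in entry.get("loops", {}).items()}
        tables[rid] = NumberingTable(receptor_id=rid, anchors=anchors, loops=loops, aliases=aliases)
    return tables


def load_attested_pairs() -> list[AttestedPair]:
    raw = _load_raw()
    out = []
    for p in raw["attested_pairs"]:
        residue = p["residue"]
        out.append(
            AttestedPair(
                receptor_id=p["receptor"],
                residue_letter=residue[0],
                author_number=int(residue[1:]),
                generic=p["generic"],
                source=p["source"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Validation


def validate_table(
    table: NumberingTable, attested_pairs: list[AttestedPair]
) -> list[dict]:
    """Classify each attested pair as consistent/inconsistent with the table.

    Loop attestations check range membership; segment attestations check
    the linear model.  Report-only: nothing is resolved silently.
    """
    report = []
    for pair in attested_pairs:
        if pair.receptor_id != table.receptor_id:
            continue
        entry = {
            "receptor": pair.receptor_id,
            "residue": f"{pair.residue_letter}{pair.author_number}",
            "generic": pair.generic,
            "source": pair.source,
        }
        if pair.generic in LOOPS:
            lo_hi = table.loops.get(pair.generic)
            ok = lo_hi is not None and lo_hi[0] <= pair.author_number <= lo_hi[1]
            entry.update(expected=None, consistent=bool(ok))
        else:
            try:
                expected = table.resolve(pair.generic)
            except (NoAnchorError, RangeError) as exc:
                entry.update(expected=None, consistent=False, error=str(exc))
                report.append(entry)
                continue
            entry.update(expected=expected, consistent=expected == pair.author_number)
        report.append(entry)
    return report
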