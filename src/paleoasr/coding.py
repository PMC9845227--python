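"""Discrete character coding of uncinate-process evidence.

The character has three unordered states:

* 0 — uncinate process absent
* 1 — cartilaginous (or calcified) uncinate process
* 2 — ossified uncinate process

Evidence per taxon is a count of examined dorsal / posterior-cervical
vertebral ribs, how many bear an uncinate scar (the osteological
correlate of an unossified process), and the best-preserved process
class.  Two coding approaches are supported:

* preferred — present (state from the evidence) if at least one
  specimen shows a scar or a preserved process; otherwise uncertain
  ``{0,1,2}``.
* alternate — as preferred, but taxa with no positive evidence and at
  least ``min_ribs`` examined ribs are coded absent ``{0}``.

An expert override (e.g. for the outgroup) always wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

ALL_STATES = frozenset({0, 1, 2})
PROCESS_CLASSES = ("none", "cartilaginous", "calcified", "ossified")
_PROCESS_RANK = {c: i for i, c in enumerate(PROCESS_CLASSES)}

#: evidence class → character state; ``None`` means "no positive evidence".
DEFAULT_STATE_MAPPING = {
    "ossified": 2,
    "calcified": 1,
    "cartilaginous": 1,
    "none": None,
    "scar": 1,
}


class CodingError(ValueError):
    pass


@dataclass(frozen=True)
class SpecimenEvidence:
    """Osteological evidence for one taxon (possibly aggregated specimens)."""

    taxon: str
    n_ribs_examined: int
    n_ribs_with_scar: int
    preserved_process: str = "none"
    override_state: Optional[frozenset[int]] = None

    def __post_init__(self):
        if not 0 <= self.n_ribs_with_scar <= self.n_ribs_examined:
            raise CodingError(
                f"{self.taxon}: scar count {self.n_ribs_with_scar} outside "
                f"[0, {self.n_ribs_examined}]"
            )
        if self.preserved_process not in PROCESS_CLASSES:
            raise CodingError(
                f"{self.taxon}: unknown process class {self.preserved_process!r}"
            )
        if self.override_state is not None:
            ov = frozenset(self.override_state)
            if not ov or not ov <= ALL_STATES:
                raise CodingError(f"{self.taxon}: bad override state {ov}")
            object.__setattr__(self, "override_state", ov)


@dataclass
class CharacterCoding:
    """Per-taxon state sets; the full set {0,1,2} means '?' (uncertain)."""

    states: dict[str, frozenset[int]]
    approach: str = "preferred"

    def __post_init__(self):
        for taxon, s in self.states.items():
            if not s or not s <= ALL_STATES:
                raise CodingError(f"{taxon}: invalid state set {s}")

    def __getitem__(self, taxon: str) -> frozenset[int]:
        return self.states[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.states

    def taxa(self) -> list[str]:
        return list(self.states)

    def is_uncertain(self, taxon: str) -> bool:
        return self.states[taxon] == ALL_STATES

    def n_present(self) -> int:
        """Taxa positively coded as bearing a process (state set ⊆ {1,2})."""
        return sum(1 for s in self.states.values() if s <= {1, 2})

    def n_absent(self) -> int:
        return sum(1 for s in self.states.values() if s == {0})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"taxon": list(self.states), "states": [format_states(s) for s in self.states.values()]}
        )


def format_states(states: frozenset[int]) -> str:
    if states == ALL_STATES:
        return "?"
    return "/".join(str(s) for s in sorted(states))


def parse_states(text: str) -> frozenset[int]:
    text = text.strip()
    if text in ("?", ""):
        return ALL_STATES
    try:
        return frozenset(int(tok) for tok in text.split("/"))
    except ValueError as exc:
        raise CodingError(f"cannot parse state set {text!r}") from exc


def aggregate_evidence(rows: Iterable[SpecimenEvidence]) -> list[SpecimenEvidence]:
    """Merge multiple rows per taxon: counts summed, strongest process kept."""
    merged: dict[str, SpecimenEvidence] = {}
    for row in rows:
        prev = merged.get(row.taxon)
        if prev is None:
            merged[row.taxon] = row
            continue
        if prev.override_state is not None and row.override_state is not None \
                and prev.override_state != row.override_state:
            raise CodingError(f"{row.taxon}: conflicting override states")
        merged[row.taxon] = SpecimenEvidence(
            taxon=row.taxon,
            n_ribs_examined=prev.n_ribs_examined + row.n_ribs_examined,
            n_ribs_with_scar=prev.n_ribs_with_scar + row.n_ribs_with_scar,
            preserved_process=max(
                prev.preserved_process, row.preserved_process, key=_PROCESS_RANK.get
            ),
            override_state=prev.override_state or row.override_state,
        )
    return list(merged.values())


def evidence_state(
    ev: SpecimenEvidence,
    mapping: Optional[dict[str, Optional[int]]] = None,
) -> Optional[int]:
    """State supported by positive evidence, or None when there is none.

    A preserved process outranks scars; under the default mapping an
    ossified process gives state 2 and scars or a cartilaginous /
    calcified process give state 1.
    """
    mapping = DEFAULT_STATE_MAPPING if mapping is None else mapping
    if ev.preserved_process not in PROCESS_CLASSES:
        raise CodingError(f"unknown process class {ev.preserved_process!r}")
    state = mapping.get(ev.preserved_process)
    if state is not None:
        return state
    if ev.n_ribs_with_scar >= 1:
        return mapping.get("scar", 1)
    return None


def code_preferred(
    table: Iterable[SpecimenEvidence],
    mapping: Optional[dict[str, Optional[int]]] = None,
) -> CharacterCoding:
    """Preferred approach: positive evidence → that state, else uncertain."""
    rows = aggregate_evidence(table)
    if not rows:
        raise CodingError("empty evidence table")
    states: dict[str, frozenset[int]] = {}
    for ev in rows:
        if ev.override_state is not None:
            states[ev.taxon] = ev.override_state
            continue
        s = evidence_state(ev, mapping)
        states[ev.taxon] = frozenset({s}) if s is not None else ALL_STATES
    return CharacterCoding(states, approach="preferred")


def code_alternate(
    table: Iterable[SpecimenEvidence],
    min_ribs: int = 5,
    mapping: Optional[dict[str, Optional[int]]] = None,
) -> CharacterCoding:
    """Alternate approach: well-sampled scar-free taxa are coded absent.

    Identical to :func:`code_preferred` except that a taxon with no
    positive evidence whose examined rib count is at least ``min_ribs``
    is coded ``{0}``.
    """
    if min_ribs < 1:
        raise CodingError("min_ribs must be >= 1")
    rows = aggregate_evidence(table)
    if not rows:
        raise CodingError("empty evidence table")
    states: dict[str, frozenset[int]] = {}
    for ev in rows:
        if ev.override_state is not None:
            states[ev.taxon] = ev.override_state
            continue
        s = evidence_state(ev, mapping)
        if s is not None:
            states[ev.taxon] = frozenset({s})
        elif ev.n_ribs_examined >= min_ribs:
            states[ev.taxon] = frozenset({0})
        else:
            states[ev.taxon] = ALL_STATES
    return CharacterCoding(states, approach="alternate")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_evidence(path) -> list[SpecimenEvidence]:
    """Read a delimited evidence table.

    Columns: taxon, n_ribs_examined, n_ribs_with_scar, preserved_process,
    override_state (blank for none; e.g. "0" or "1/2").
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"taxon", "n_ribs_examined", "n_ribs_with_scar", "preserved_process"}
    if not required.issubset(df.columns):
        raise CodingError(
            f"evidence table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    rows = []
    for rec in df.to_dict("records"):
        override = rec.get("override_state", "").strip()
        rows.append(
            SpecimenEvidence(
                taxon=rec["taxon"].strip(),
                n_ribs_examined=int(rec["n_ribs_examined"]),
                n_ribs_with_scar=int(rec["n_ribs_with_scar"]),
                preserved_process=(rec["preserved_process"].strip() or "none"),
                override_state=parse_states(override) if override else None,
            )
        )
    return rows


def write_evidence(rows: Iterable[SpecimenEvidence], path) -> None:
    df = pd.DataFrame(
        [
            (
                r.taxon,
                r.n_ribs_examined,
                r.n_ribs_with_scar,
                r.preserved_process,
                format_states(r.override_state) if r.override_state else "",
            )
            for r in rows
        ],
        columns=[
            "taxon",
            "n_ribs_examined",
            "n_ribs_with_scar",
            "preserved_process",
            "override_state",
        ],
    )
    df.to_csv(path, sep="\t", index=False)


def write_coding(coding: CharacterCoding, path) -> None:
    coding.to_frame().to_csv(path, sep="\t", index=False)


def read_coding(path, approach: str = "preferred") -> CharacterCoding:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    states = {rec["taxon"].strip(): parse_states(rec["states"]) for rec in df.to_dict("records")}
    return CharacterCoding(states, approach=approach)


def to_nexus(coding: CharacterCoding) -> str:
    """Render the coding as a one-character NEXUS matrix ({} for ambiguity)."""

    def cell(states: frozenset[int]) -> str:
        if states == ALL_STATES:
            return "?"
        if len(states) == 1:
            return str(next(iter(states)))
        return "{" + "".join(str(s) for s in sorted(states)) + "}"

    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={len(coding.states)} NCHAR=1;",
        '  FORMAT DATATYPE=STANDARD SYMBOLS="012" MISSING=?;',
        "  MATRIX",
    ]
    width = max(len(t) for t in coding.states) + 2
    for taxon, states in coding.states.items():
        safe = taxon.replace(" ", "_")
        lines.append(f"    {safe:<{width}}{cell(states)}")
    lines += ["  ;", "END;"]
    return "\n".join(lines) + "\n"
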