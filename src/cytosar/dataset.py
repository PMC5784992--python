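"""Training-set construction from a ChEMBL-style activity table.

The curation pipeline turns raw assay rows into per-cell-line
active/explicit-inactive compound sets:

1. each record is classified against the activity thresholds —
   IC50/IG50 strictly below 10,000 nM or percent inhibition strictly
   above 50% means *active*; censored relations that cannot decide the
   threshold are *indeterminate* and excluded;
2. records are grouped by (compound, cell line); pairs classified both
   active and inactive by different assays are excluded outright;
3. cell lines on the misidentification exclusion list are dropped, as
   are cell lines with fewer than ``min_active`` actives or
   ``min_inactive`` explicitly tested inactives.

For model fitting a compound not labelled active for a cell line is
treated as inactive for it (the global-inactive convention); the
eligibility filter, by contrast, counts only explicit tested-inactive
records, otherwise it would be vacuous.
"""

from __future__ import annotations

import enum
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from cytosar.errors import EmptyTrainingSetError, SchemaError, UnknownUnitError
from cytosar.mna import DescriptorSet

log = logging.getLogger(__name__)

ACTIVITY_THRESHOLD_NM = 10_000.0
INHIBITION_THRESHOLD_PCT = 50.0

_UNIT_TO_NM = {
    "M": 1e9,
    "mM": 1e6,
    "uM": 1e3,
    "µM": 1e3,
    "μM": 1e3,
    "nM": 1.0,
    "pM": 1e-3,
}

CONCENTRATION_ENDPOINTS = ("IC50", "IG50", "GI50")
VALID_RELATIONS = ("=", "<", ">", "<=", ">=")

ACTIVITY_COLUMNS = (
    "compound_id",
    "cell_line",
    "endpoint",
    "value",
    "unit",
    "relation",
)


class Label(enum.Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    cell_line: str
    endpoint: str  # IC50 | IG50/GI50 | INHIBITION
    value: float
    unit: str
    relation: str = "="
    structure: str = ""


@dataclass(frozen=True)
class CellLineLabel:
    """Metadata for one cell line (short name is the unique key)."""

    short_name: str
    full_name: str = ""
    tissue: str = ""
    kind: str = "tumour"  # tumour | normal
    tumour_type: str = ""


@dataclass
class ActivityTable:
    records: list[ActivityRecord]
    skipped: int = 0


@dataclass
class TrainingSet:
    """Descriptor corpus plus per-cell-line label assignments.

    ``descriptors`` holds every retained compound; ``actives`` and
    ``explicit_inactives`` are disjoint per cell line. ``provenance``
    is a deterministic log of exclusion counts by reason.
    """

    descriptors: dict[str, DescriptorSet]
    actives: dict[str, frozenset[str]]
    explicit_inactives: dict[str, frozenset[str]]
    cell_lines: dict[str, CellLineLabel]
    provenance: dict = field(default_factory=dict)

    @property
    def compounds(self) -> list[str]:
        return sorted(self.descriptors)

    @property
    def n_compounds(self) -> int:
        return len(self.descriptors)

    def is_active(self, compound_id: str, cell_line: str) -> bool:
        return compound_id in self.actives[cell_line]

    def subset(self, compound_ids: Iterable[str]) -> "TrainingSet":
        """Restrict the corpus to the given compounds (for CV refits)."""
        keep = set(compound_ids)
        return TrainingSet(
            descriptors={c: d for c, d in self.descriptors.items() if c in keep},
            actives={a: frozenset(s & keep) for a, s in self.actives.items()},
            explicit_inactives={
                a: frozenset(s & keep)
                for a, s in self.explicit_inactives.items()
            },
            cell_lines=self.cell_lines,
            provenance={"subset_of": self.provenance.get("n_compounds", None)},
        )


def normalize_concentration(value: float, unit: str) -> float:
    """Convert a molar-family concentration to nM (exact powers of ten)."""
    unit = unit.strip()
    if unit not in _UNIT_TO_NM:
        raise UnknownUnitError(f"UNKNOWN_UNIT: {unit!r}")
    return float(value) * _UNIT_TO_NM[unit]


def classify_record(record: ActivityRecord) -> Label:
    """Classify one assay record as active / inactive / indeterminate.

    Concentration endpoints: active iff the true value is strictly
    below 10,000 nM. Percent inhibition: active iff strictly above
    50%. Relations other than ``=`` bound the true value on one side;
    when the bound cannot decide the threshold the record is
    indeterminate and takes no part in labelling.
    """
    rel = record.relation.strip()
    if rel not in VALID_RELATIONS:
        raise ValueError(f"unknown relation {rel!r}")
    endpoint = record.endpoint.strip().upper()
    if endpoint in CONCENTRATION_ENDPOINTS:
        nm = normalize_concentration(record.value, record.unit)
        t = ACTIVITY_THRESHOLD_NM
        if rel == "=":
            return Label.ACTIVE if nm < t else Label.INACTIVE
        if rel == "<":  # true < nm
            return Label.ACTIVE if nm <= t else Label.INDETERMINATE
        if rel == "<=":  # true <= nm
            return Label.ACTIVE if nm < t else Label.INDETERMINATE
        if rel == ">":  # true > nm
            return Label.INACTIVE if nm >= t else Label.INDETERMINATE
        # ">=": true >= nm; active needs true < t
        return Label.INACTIVE if nm >= t else Label.INDETERMINATE
    if endpoint == "INHIBITION":
        if record.unit.strip() not in ("%", "percent"):
            raise UnknownUnitError(
                f"UNKNOWN_UNIT: inhibition must be in %, got {record.unit!r}"
            )
        v = float(record.value)
        t = INHIBITION_THRESHOLD_PCT
        if rel == "=":
            return Label.ACTIVE if v > t else Label.INACTIVE
        if rel == ">":  # true > v
            return Label.ACTIVE if v >= t else Label.INDETERMINATE
        if rel == ">=":  # true >= v
            return Label.ACTIVE if v > t else Label.INDETERMINATE
        if rel == "<":  # true < v
            return Label.INACTIVE if v <= t else Label.INDETERMINATE
        # "<=": true <= v
        return Label.INACTIVE if v <= t else Label.INDETERMINATE
    raise ValueError(f"unknown endpoint {record.endpoint!r}")


def resolve_pair(labels: Iterable[Label]) -> Label | None:
    """Resolve one (compound, cell line) pair's classified records.

    Any active + any inactive -> conflict, excluded (None). All
    indeterminate -> excluded. Indeterminates never vote.
    """
    votes = {l for l in labels if l is not Label.INDETERMINATE}
    if not votes:
        return None
    if votes == {Label.ACTIVE}:
        return Label.ACTIVE
    if votes == {Label.INACTIVE}:
        return Label.INACTIVE
    return None  # conflict


def resolve_conflicts(
    classified: Iterable[tuple[str, str, Label]],
) -> tuple[dict[tuple[str, str], Label], dict[str, int]]:
    """Group classified records by (compound, cell line) and resolve.

    Returns the per-pair labels and exclusion counts by reason
    (``conflict`` or ``all_indeterminate``).
    """
    grouped: dict[tuple[str, str], list[Label]] = defaultdict(list)
    for compound, cell_line, label in classified:
        grouped[(compound, cell_line)].append(label)
    resolved: dict[tuple[str, str], Label] = {}
    excluded = {"conflict": 0, "all_indeterminate": 0}
    for pair in sorted(grouped):
        label = resolve_pair(grouped[pair])
        if label is None:
            votes = {l for l in grouped[pair] if l is not Label.INDETERMINATE}
            excluded["conflict" if votes else "all_indeterminate"] += 1
        else:
            resolved[pair] = label
    return resolved, excluded


def build_training_set(
    records: Sequence[ActivityRecord],
    descriptor_sets: Mapping[str, DescriptorSet],
    cell_lines: Mapping[str, CellLineLabel] | Sequence[CellLineLabel],
    exclusion_list: Iterable[str] = (),
    min_active: int = 3,
    min_inactive: int = 10,
) -> TrainingSet:
    """Run the full curation pipeline; see module docstring.

    ``descriptor_sets`` maps compound id to its descriptor set; records
    for compounds without one (failed validation upstream) are dropped.
    Raises :class:`EmptyTrainingSetError` if no cell line survives.
    """
    if not isinstance(cell_lines, Mapping):
        cell_lines = {c.short_name: c for c in cell_lines}
    excluded_lines = set(exclusion_list)

    classified: list[tuple[str, str, Label]] = []
    rejects = {"no_structure": 0, "bad_record": 0}
    for rec in records:
        if rec.compound_id not in descriptor_sets:
            rejects["no_structure"] += 1
            continue
        try:
            label = classify_record(rec)
        except (UnknownUnitError, ValueError) as exc:
            rejects["bad_record"] += 1
            log.warning("rejected record %s/%s: %s", rec.compound_id, rec.cell_line, exc)
            continue
        classified.append((rec.compound_id, rec.cell_line, label))

    resolved, pair_exclusions = resolve_conflicts(classified)

    per_line_active: dict[str, set[str]] = defaultdict(set)
    per_line_inactive: dict[str, set[str]] = defaultdict(set)
    for (compound, line), label in resolved.items():
        (per_line_active if label is Label.ACTIVE else per_line_inactive)[
            line
        ].add(compound)

    line_drops: dict[str, str] = {}
    retained: list[str] = []
    for line in sorted(set(per_line_active) | set(per_line_inactive)):
        if line in excluded_lines:
            line_drops[line] = "EXCLUDED_CELL_LINE"
        elif len(per_line_active[line]) < min_active:
            line_drops[line] = "TOO_FEW_ACTIVES"
        elif len(per_line_inactive[line]) < min_inactive:
            line_drops[line] = "TOO_FEW_INACTIVES"
        else:
            retained.append(line)

    if not retained:
        raise EmptyTrainingSetError(
            "EMPTY_TRAINING_SET: no cell line survived the eligibility filters"
        )

    corpus: set[str] = set()
    for line in retained:
        corpus |= per_line_active[line] | per_line_inactive[line]

    provenance = {
        "n_records": len(records),
        "records_rejected": dict(sorted(rejects.items())),
        "pairs_excluded": dict(sorted(pair_exclusions.items())),
        "cell_lines_dropped": dict(sorted(line_drops.items())),
        "cell_lines_retained": sorted(retained),
        "n_compounds": len(corpus),
    }
    return TrainingSet(
        descriptors={c: descriptor_sets[c] for c in sorted(corpus)},
        actives={l: frozenset(per_line_active[l]) for l in retained},
        explicit_inactives={
            l: frozenset(per_line_inactive[l]) for l in retained
        },
        cell_lines={
            l: cell_lines.get(l, CellLineLabel(short_name=l)) for l in retained
        },
        provenance=provenance,
    )


def read_activity_table(path: str | Path) -> ActivityTable:
    """Read the documented activity CSV schema.

    Mandatory columns: compound_id, cell_line, endpoint, value, unit,
    relation (``structure`` is optional). Rows with missing values are
    skipped and counted, not fatal; a missing column is a schema error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"activity table missing columns: {missing}")
    records: list[ActivityRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        try:
            value = float(getattr(row, "value"))
        except (TypeError, ValueError):
            skipped += 1
            continue
        if not getattr(row, "compound_id") or not getattr(row, "cell_line"):
            skipped += 1
            continue
        records.append(
            ActivityRecord(
                compound_id=getattr(row, "compound_id"),
                cell_line=getattr(row, "cell_line"),
                endpoint=getattr(row, "endpoint"),
                value=value,
                unit=getattr(row, "unit"),
                relation=getattr(row, "relation") or "=",
                structure=getattr(row, "structure", ""),
            )
        )
    if skipped:
        log.warning("skipped %d malformed rows in %s", skipped, path)
    return ActivityTable(records=records, skipped=skipped)


def read_cell_line_table(path: str | Path) -> dict[str, CellLineLabel]:
    """Read cell-line metadata CSV (short_name, full_name, tissue, kind, tumour_type)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "short_name" not in df.columns:
        raise SchemaError("cell-line table missing 'short_name' column")
    out: dict[str, CellLineLabel] = {}
    for row in df.to_dict("records"):
        label = CellLineLabel(
            short_name=row["short_name"],
            full_name=row.get("full_name", ""),
            tissue=row.get("tissue", ""),
            kind=row.get("kind", "tumour") or "tumour",
            tumour_type=row.get("tumour_type", ""),
        )
        out[label.short_name] = label
    return out


def read_exclusion_list(path: str | Path) -> set[str]:
    """Plain-text exclusion list: one cell-line id per line, # comments."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out
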