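"""Synthetic molecule libraries and activity panels with known truth.

This generator stands in for a mined bioactivity extract so the whole
pipeline is testable offline. Molecules are assembled from a curated
fragment grammar (aromatic/aliphatic ring scaffolds with substituent
slots); every emitted structure passes the six admissibility criteria
by construction. The activity panel designates *signal* cell lines —
a compound carrying the line's marker substructure is active with
probability ``p_hit``, else with background rate ``p_bg`` — and
*noise* cell lines that are active at ``p_bg`` regardless, plus a
label-flip rate ``epsilon``. Actives receive IC50 values drawn
log-uniformly in [10, 9999] nM and inactives in [10001, 1e6] nM, so
every value sits strictly off the 10,000 nM decision boundary.

Defaults (500 compounds, 3 signal + 2 noise lines, p_hit=0.9,
p_bg=0.05, epsilon=0.02, ~30% marker prevalence, seed 42) define the
standard recovery benchmark: model selection at AUC > 0.8 should keep
exactly the signal lines.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from cytosar.dataset import CellLineLabel
from cytosar.mna import descriptor_set
from cytosar.structures import Molecule, parse_structure, to_rdkit, validate_structure, write_sdf

#: Ring scaffolds with python-format substituent slots.
_TEMPLATES = [
    "c1ccc({0})cc1",
    "c1cc({0})ccc1{1}",
    "c1cc({0})cc({1})c1",
    "c1c({0})cc({1})cc1{2}",
    "c1ccc({0})nc1",
    "c1cc({0})cnc1{1}",
    "c1cnc({0})cn1",
    "c1cc({0})c({1})cc1",
    "C1CCC({0})CC1",
    "C1CC({0})CC({1})C1",
    "C1CCN({0})CC1",
    "C1CCOC1{0}",
    "c1coc({0})c1",
    "c1csc({0})c1",
    "c1cc({0})[nH]c1",
    "c1ccc2cc({0})ccc2c1",
    "c1ccc2c(c1)cc({0})o2",
    "CC({0})CC({1})C",
    "C({0})CC({1})CC{2}",
    "CCCC{0}",
    "CC(C)CC({0}){1}",
]

#: Background substituents; deliberately free of the default markers.
_SUBSTITUENTS = [
    "C", "CC", "CCC", "CCCC", "C(C)C", "C(C)(C)C", "O", "OC", "OCC",
    "OC(C)C", "N", "NC", "NCC", "N(C)C", "F", "Cl", "Br", "I", "C#N",
    "C=C", "C=CC", "CO", "CCO", "CN", "C(=O)C", "C(=O)CC", "C(=O)N",
    "C(=O)NC", "S", "SC", "CSC", "C#CC",
]

#: Default marker substructures for signal cell lines (substituent-form
#: SMILES that double as substructure queries).
DEFAULT_FRAGMENTS = ("C(=O)O", "S(=O)(=O)N", "C(F)(F)F")

_TISSUES = ["liver", "lung", "skin", "blood", "kidney", "breast", "colon"]


@dataclass(frozen=True)
class PanelSpec:
    """Study conditions for one synthetic panel."""

    n_compounds: int = 500
    n_signal_celllines: int = 3
    n_noise_celllines: int = 2
    fragments: tuple[str, ...] = DEFAULT_FRAGMENTS
    p_hit: float = 0.9
    p_bg: float = 0.05
    epsilon: float = 0.02
    seed: int = 42
    p_fragment: float = 0.3  # marker prevalence in the library
    min_active_warning: int = 3
    include_conflicts: bool = False
    conflict_rate: float = 0.05
    extra_endpoints: bool = False

    def __post_init__(self):
        for p in (self.p_hit, self.p_bg, self.epsilon, self.p_fragment):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def generate_library(
    n: int,
    seed: int,
    fragments: tuple[str, ...] = DEFAULT_FRAGMENTS,
    p_fragment: float = 0.3,
    path: str | Path | None = None,
) -> list[Molecule]:
    """Generate ``n`` valid molecules from the fragment grammar.

    Each marker fragment is injected independently with probability
    ``p_fragment`` (capped by the chosen scaffold's slot count), so
    markers appear in roughly 30% of the library by default.
    Deterministic per seed; optionally also written as SDF.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    molecules: list[Molecule] = []
    seen: set[str] = set()
    attempts = 0
    while len(molecules) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError(
                "fragment grammar exhausted before reaching the requested "
                "library size; lower n"
            )
        # marker inclusion is drawn once per molecule, then assembly
        # retries until a novel structure is found: duplicate rejection
        # must not bias marker prevalence away from its nominal rate
        forced = [f for f in fragments if rng.random() < p_fragment]
        canonical = None
        for _ in range(100):
            smiles = _assemble(rng, list(forced))
            cand = Chem.CanonSmiles(smiles)
            if cand not in seen:
                canonical = cand
                break
        if canonical is None:
            continue  # this marker combination is exhausted
        identifier = f"CPD{len(molecules):05d}"
        mol = parse_structure(smiles, "smiles", identifier=identifier)
        if not validate_structure(mol).passed:
            continue  # grammar occasionally yields a <3-carbon chain
        seen.add(canonical)
        molecules.append(mol)
    if path is not None:
        write_sdf(((m, {"smiles": m.identifier}) for m in molecules), path)
    return molecules


def _assemble(rng, forced: list[str]) -> str:
    rng.shuffle(forced)
    max_slots = max(t.count("{") for t in _TEMPLATES)
    forced = forced[:max_slots]
    # pick a scaffold with enough slots so injected markers are never
    # silently dropped (keeps marker prevalence at its nominal rate)
    eligible = [t for t in _TEMPLATES if t.count("{") >= len(forced)]
    template = eligible[int(rng.integers(len(eligible)))]
    n_slots = template.count("{")
    fillers = list(forced)
    while len(fillers) < n_slots:
        fillers.append(_SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))])
    rng.shuffle(fillers)
    return template.format(*fillers)


def has_fragment(mol: Molecule, fragment_smarts: str) -> bool:
    """Substructure test on the rebuilt hydrogen-complete graph."""
    query = Chem.MolFromSmarts(fragment_smarts)
    if query is None:
        raise ValueError(f"bad fragment SMARTS: {fragment_smarts!r}")
    return to_rdkit(mol).HasSubstructMatch(query)


@dataclass
class PanelData:
    """In-memory panel: activity rows, cell-line metadata, ground truth."""

    activity: pd.DataFrame
    cell_lines: pd.DataFrame
    truth: dict
    library: list[Molecule] = field(default_factory=list)


def generate_panel(
    library: list[Molecule],
    spec: PanelSpec,
    outdir: str | Path | None = None,
) -> PanelData:
    """Simulate the activity table for a library under a panel spec.

    Emits one record per (compound, cell line) pair — every compound
    is explicitly tested on every line — plus metadata and a truth
    file recording each line's type and marker. With ``outdir`` the
    three artifacts are written as activity.csv, cell_lines.csv and
    truth.json (and the library as library.sdf).
    """
    rng = np.random.default_rng(spec.seed)
    lines = _make_cell_lines(spec)
    presence = {
        frag: np.array([has_fragment(m, frag) for m in library])
        for frag in spec.fragments
    }

    rows: list[dict] = []
    active_counts: dict[str, int] = {}
    for name, meta, line_type, frag in lines:
        if line_type == "signal":
            p = np.where(presence[frag], spec.p_hit, spec.p_bg)
        else:
            p = np.full(len(library), spec.p_bg)
        active = rng.random(len(library)) < p
        flip = rng.random(len(library)) < spec.epsilon
        active = active ^ flip
        active_counts[name] = int(active.sum())
        for mol, is_act in zip(library, active):
            rows.append(_record(rng, mol, name, bool(is_act), spec))
            if spec.include_conflicts and rng.random() < spec.conflict_rate:
                rows.append(_record(rng, mol, name, not is_act, spec))

    activity = pd.DataFrame(rows)
    cell_df = pd.DataFrame(
        [
            {
                "short_name": meta.short_name,
                "full_name": meta.full_name,
                "tissue": meta.tissue,
                "kind": meta.kind,
                "tumour_type": meta.tumour_type,
            }
            for _, meta, _, _ in lines
        ]
    )
    warnings = [
        f"cell line {name}: only {count} active records, below "
        f"{spec.min_active_warning}"
        for name, count in active_counts.items()
        if count < spec.min_active_warning
    ]
    truth = {
        "spec": {k: list(v) if isinstance(v, tuple) else v
                 for k, v in asdict(spec).items()},
        "cell_lines": {
            name: {"type": line_type, "fragment": frag, "kind": meta.kind}
            for name, meta, line_type, frag in lines
        },
        "active_counts": active_counts,
        "warnings": warnings,
    }
    panel = PanelData(activity=activity, cell_lines=cell_df, truth=truth,
                      library=list(library))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        activity.to_csv(outdir / "activity.csv", index=False)
        cell_df.to_csv(outdir / "cell_lines.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
        write_sdf(((m, {}) for m in library), outdir / "library.sdf")
    return panel


def _make_cell_lines(spec: PanelSpec):
    lines = []
    for i in range(spec.n_signal_celllines):
        name = f"SIG-{i + 1}"
        kind = "tumour" if i % 2 == 0 else "normal"
        meta = CellLineLabel(
            short_name=name,
            full_name=f"synthetic signal line {i + 1}",
            tissue=_TISSUES[i % len(_TISSUES)],
            kind=kind,
            tumour_type="synthetic carcinoma" if kind == "tumour" else "",
        )
        frag = spec.fragments[i % len(spec.fragments)]
        lines.append((name, meta, "signal", frag))
    for i in range(spec.n_noise_celllines):
        name = f"RND-{i + 1}"
        kind = "tumour" if i % 2 == 0 else "normal"
        meta = CellLineLabel(
            short_name=name,
            full_name=f"synthetic noise line {i + 1}",
            tissue=_TISSUES[(i + spec.n_signal_celllines) % len(_TISSUES)],
            kind=kind,
            tumour_type="synthetic carcinoma" if kind == "tumour" else "",
        )
        lines.append((name, meta, "noise", None))
    return lines


def _record(rng, mol: Molecule, cell_line: str, active: bool, spec: PanelSpec) -> dict:
    # log-uniform IC50 strictly off the 10,000 nM boundary
    if active:
        lo, hi = 10.0, 9999.0
    else:
        lo, hi = 10001.0, 1e6
    value_nm = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    endpoint = "IC50"
    if spec.extra_endpoints:
        draw = rng.random()
        if draw < 0.2:
            endpoint = "IG50"
        elif draw < 0.3:
            pct = rng.uniform(50.5, 100.0) if active else rng.uniform(0.0, 49.5)
            return {
                "compound_id": mol.identifier,
                "cell_line": cell_line,
                "endpoint": "INHIBITION",
                "value": round(float(pct), 3),
                "unit": "%",
                "relation": "=",
                "structure": "",
            }
    if rng.random() < 0.2:
        value, unit = value_nm / 1e3, "uM"
    else:
        value, unit = value_nm, "nM"
    return {
        "compound_id": mol.identifier,
        "cell_line": cell_line,
        "endpoint": endpoint,
        "value": float(value),
        "unit": unit,
        "relation": "=",
        "structure": "",
    }


def default_panel(seed: int = 42, outdir: str | Path | None = None) -> PanelData:
    """The standard recovery benchmark at its stated study conditions."""
    spec = PanelSpec(seed=seed)
    library = generate_library(
        spec.n_compounds, seed, fragments=spec.fragments,
        p_fragment=spec.p_fragment,
    )
    return generate_panel(library, spec, outdir=outdir)


def panel_training_set(panel: PanelData, min_active: int = 3, min_inactive: int = 10):
    """Descriptorize the library and run the curation pipeline."""
    from cytosar.dataset import ActivityRecord, build_training_set

    descriptor_sets = {m.identifier: descriptor_set(m) for m in panel.library}
    records = [
        ActivityRecord(
            compound_id=r["compound_id"],
            cell_line=r["cell_line"],
            endpoint=r["endpoint"],
            value=float(r["value"]),
            unit=r["unit"],
            relation=r["relation"],
        )
        for r in panel.activity.to_dict("records")
    ]
    cell_lines = {
        row["short_name"]: CellLineLabel(**row)
        for row in panel.cell_lines.to_dict("records")
    }
    return build_training_set(
        records, descriptor_sets, cell_lines,
        min_active=min_active, min_inactive=min_inactive,
    )
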