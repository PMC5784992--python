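"""Profile rendering and model-summary tables.

Two user-facing artifacts live here: the per-query cytotoxicity
profile (tumour and normal tables of cell line, Pa, Pi sorted by
Pa-Pi) and the model summary that aggregates per-cell-line
cross-validated AUCs into per-organ rows plus grand means, mirroring
the layout of published validation tables. Display values (Pa, Pi,
mean AUCs) are rounded to 3 decimals; model files keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from cytosar.dataset import CellLineLabel
from cytosar.engine import ActivityModel, Prediction
from cytosar.structures import Molecule, write_sdf

PROFILE_COLUMNS = [
    "kind", "cell_line", "full_name", "tissue", "tumour_type", "pa", "pi",
]

CV_TABLE_COLUMNS = [
    "cell_line", "type", "tissue", "n_active", "auc_loo", "auc_kfold",
]


@dataclass
class ProfileReport:
    """Ranked (cell line, Pa, Pi) rows split into tumour and normal tables."""

    tumour: pd.DataFrame
    normal: pd.DataFrame
    structure_id: str = ""
    model_version: str = ""

    @classmethod
    def from_predictions(
        cls,
        predictions: list[Prediction],
        cell_lines: dict[str, CellLineLabel],
        structure_id: str = "",
        model_version: str = "",
    ) -> "ProfileReport":
        rows = []
        for p in predictions:  # already sorted by Pa-Pi desc, name asc
            meta = cell_lines.get(p.cell_line, CellLineLabel(p.cell_line))
            rows.append(
                {
                    "kind": meta.kind,
                    "cell_line": meta.short_name,
                    "full_name": meta.full_name,
                    "tissue": meta.tissue,
                    "tumour_type": meta.tumour_type,
                    "pa": round(p.pa, 3),
                    "pi": round(p.pi, 3),
                }
            )
        df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
        return cls(
            tumour=df[df["kind"] == "tumour"].reset_index(drop=True),
            normal=df[df["kind"] == "normal"].reset_index(drop=True),
            structure_id=structure_id,
            model_version=model_version,
        )

    def to_csv(self, path: str | Path) -> None:
        pd.concat([self.tumour, self.normal], ignore_index=True).to_csv(
            path, index=False
        )

    def to_sdf(self, molecule: Molecule, path: str | Path) -> None:
        """One SDF record: the query with both tables as properties."""
        props = {
            "structure_id": self.structure_id or molecule.identifier,
            "model_version": self.model_version,
            "tumour_profile": _profile_text(self.tumour),
            "normal_profile": _profile_text(self.normal),
        }
        write_sdf([(molecule, props)], path)


def _profile_text(df: pd.DataFrame) -> str:
    lines = ["cell_line\tPa\tPi"]
    for row in df.itertuples(index=False):
        lines.append(f"{row.cell_line}\t{row.pa:.3f}\t{row.pi:.3f}")
    return "\n".join(lines)


def read_profile_csv(path: str | Path) -> ProfileReport:
    df = pd.read_csv(path, dtype={"pa": float, "pi": float}, keep_default_na=False)
    return ProfileReport(
        tumour=df[df["kind"] == "tumour"].reset_index(drop=True),
        normal=df[df["kind"] == "normal"].reset_index(drop=True),
    )


def render_profile(
    predictions: list[Prediction], model: ActivityModel, structure_id: str = ""
) -> ProfileReport:
    return ProfileReport.from_predictions(
        predictions, model.cell_lines, structure_id=structure_id
    )


@dataclass
class ModelSummary:
    """Per-line table with mean row, per-organ aggregation, grand means."""

    per_line: pd.DataFrame
    per_organ: pd.DataFrame
    grand_means: dict = field(default_factory=dict)


def summarize_models(cv_table: pd.DataFrame) -> ModelSummary:
    """Aggregate a per-cell-line CV table.

    ``cv_table`` needs columns cell_line, tissue, n_active, auc_loo,
    auc_kfold (extra columns pass through). Per-organ rows report the
    cell-line count, total actives and arithmetic-mean AUCs; grand
    means are the plain arithmetic means over cell lines. All means
    are rounded to 3 decimals.
    """
    if cv_table.empty:
        raise ValueError("cv_table is empty")
    required = {"cell_line", "tissue", "n_active", "auc_loo", "auc_kfold"}
    missing = required - set(cv_table.columns)
    if missing:
        raise ValueError(f"cv_table missing columns: {sorted(missing)}")

    grand = {
        "auc_loo": round(float(cv_table["auc_loo"].mean()), 3),
        "auc_kfold": round(float(cv_table["auc_kfold"].mean()), 3),
        "n_cell_lines": int(len(cv_table)),
        "n_active_total": int(cv_table["n_active"].sum()),
    }

    per_line = cv_table.copy().reset_index(drop=True)
    mean_row = {c: "" for c in per_line.columns}
    mean_row.update(
        {"cell_line": "Mean", "auc_loo": grand["auc_loo"],
         "auc_kfold": grand["auc_kfold"]}
    )
    per_line = pd.concat(
        [per_line, pd.DataFrame([mean_row])], ignore_index=True
    )

    per_organ = (
        cv_table.groupby("tissue", sort=True)
        .agg(
            n_cell_lines=("cell_line", "size"),
            n_active=("n_active", "sum"),
            auc_loo=("auc_loo", "mean"),
            auc_kfold=("auc_kfold", "mean"),
        )
        .round({"auc_loo": 3, "auc_kfold": 3})
        .reset_index()
    )
    return ModelSummary(per_line=per_line, per_organ=per_organ, grand_means=grand)


def cv_results_table(
    loo_results: dict, kfold_results: dict, cell_lines: dict[str, CellLineLabel]
) -> pd.DataFrame:
    """Join LOO and k-fold results into the standard CV CSV layout."""
    rows = []
    for line in sorted(loo_results):
        meta = cell_lines.get(line, CellLineLabel(line))
        kf = kfold_results.get(line)
        rows.append(
            {
                "cell_line": line,
                "type": meta.kind,
                "tissue": meta.tissue,
                "n_active": loo_results[line].n_active,
                "auc_loo": loo_results[line].auc,
                "auc_kfold": kf.auc if kf is not None else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=CV_TABLE_COLUMNS)


def load_reference_normal_panel() -> pd.DataFrame:
    """Published cross-validated accuracies for 27 normal human cell lines.

    Transcribed reference table (cell line, type, tissue, number of
    training actives, LOO and 20-fold AUC) used to exercise the
    summary aggregation against its printed grand means.
    """
    with resources.files("cytosar.data").joinpath(
        "normal_cell_line_auc.csv"
    ).open() as fh:
        return pd.read_csv(fh)
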