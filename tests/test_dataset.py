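"""Activity classification thresholds, conflict handling, set curation."""

import pytest

from cytosar.dataset import (
    ActivityRecord,
    CellLineLabel,
    Label,
    build_training_set,
    classify_record,
    normalize_concentration,
    read_activity_table,
    resolve_conflicts,
    resolve_pair,
)
from cytosar.errors import EmptyTrainingSetError, SchemaError, UnknownUnitError
from cytosar.mna import descriptor_set
from cytosar.structures import parse_structure


def _rec(value, unit="nM", endpoint="IC50", relation="=", compound="c1", line="L1"):
    return ActivityRecord(
        compound_id=compound,
        cell_line=line,
        endpoint=endpoint,
        value=value,
        unit=unit,
        relation=relation,
    )


class TestUnits:
    @pytest.mark.parametrize(
        "value,unit,expected",
        [
            (10, "µM", 10_000.0),
            (10, "uM", 10_000.0),
            (1, "nM", 1.0),
            (2, "mM", 2e6),
            (1, "M", 1e9),
            (500, "pM", 0.5),
        ],
    )
    def test_power_of_ten_conversion(self, value, unit, expected):
        assert normalize_concentration(value, unit) == expected

    def test_unknown_unit_rejected(self):
        with pytest.raises(UnknownUnitError, match="UNKNOWN_UNIT"):
            normalize_concentration(5, "parrots")


class TestClassify:
    @pytest.mark.parametrize(
        "value,unit,endpoint,relation,expected",
        [
            (9999, "nM", "IC50", "=", Label.ACTIVE),
            (10_000, "nM", "IC50", "=", Label.INACTIVE),  # strict boundary
            (9.999, "uM", "IG50", "=", Label.ACTIVE),
            (10, "uM", "IG50", "=", Label.INACTIVE),
            (50, "%", "INHIBITION", "=", Label.INACTIVE),  # strict boundary
            (50.1, "%", "INHIBITION", "=", Label.ACTIVE),
            # censored relations: decided only when the bound decides
            (5000, "nM", "IC50", "<", Label.ACTIVE),
            (10_000, "nM", "IC50", "<", Label.ACTIVE),
            (20_000, "nM", "IC50", "<", Label.INDETERMINATE),
            (5000, "nM", "IC50", ">", Label.INDETERMINATE),
            (10_000, "nM", "IC50", ">", Label.INACTIVE),
            (20_000, "nM", "IC50", ">=", Label.INACTIVE),
            (9999, "nM", "IC50", "<=", Label.ACTIVE),
            (10_000, "nM", "IC50", "<=", Label.INDETERMINATE),
            (60, "%", "INHIBITION", ">", Label.ACTIVE),
            (50, "%", "INHIBITION", ">", Label.ACTIVE),
            (40, "%", "INHIBITION", ">", Label.INDETERMINATE),
            (50, "%", "INHIBITION", "<", Label.INACTIVE),
            (60, "%", "INHIBITION", "<", Label.INDETERMINATE),
            (50, "%", "INHIBITION", ">=", Label.INDETERMINATE),
        ],
    )
    def test_threshold_rules(self, value, unit, endpoint, relation, expected):
        rec = _rec(value, unit, endpoint, relation)
        assert classify_record(rec) is expected

    def test_inhibition_requires_percent(self):
        with pytest.raises(UnknownUnitError):
            classify_record(_rec(60, "nM", "INHIBITION"))


class TestConflicts:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            ([Label.ACTIVE, Label.INACTIVE], None),
            ([Label.ACTIVE, Label.ACTIVE, Label.INDETERMINATE], Label.ACTIVE),
            ([Label.INACTIVE], Label.INACTIVE),
            ([Label.INDETERMINATE], None),
        ],
    )
    def test_pair_resolution(self, labels, expected):
        assert resolve_pair(labels) is expected

    def test_grouping_and_reason_counts(self):
        classified = [
            ("c1", "L1", Label.ACTIVE),
            ("c1", "L1", Label.INACTIVE),
            ("c2", "L1", Label.ACTIVE),
            ("c3", "L1", Label.INDETERMINATE),
        ]
        resolved, excluded = resolve_conflicts(classified)
        assert resolved == {("c2", "L1"): Label.ACTIVE}
        assert excluded == {"conflict": 1, "all_indeterminate": 1}


def _descriptors(n):
    """n distinct single-compound descriptor sets from simple alkanols."""
    out = {}
    for i in range(n):
        smiles = "C" * (i + 3) + "O"
        mol = parse_structure(smiles, identifier=f"c{i}")
        out[f"c{i}"] = descriptor_set(mol)
    return out


class TestBuildTrainingSet:
    def _records(self, line, n_active, n_inactive, start=0):
        recs = []
        for i in range(start, start + n_active):
            recs.append(_rec(100, compound=f"c{i}", line=line))
        for i in range(start + n_active, start + n_active + n_inactive):
            recs.append(_rec(50_000, compound=f"c{i}", line=line))
        return recs

    def test_retention_filter(self):
        descs = _descriptors(15)
        records = self._records("KEEP", 3, 10) + self._records("DROP", 2, 13)
        cells = [CellLineLabel("KEEP"), CellLineLabel("DROP")]
        ts = build_training_set(records, descs, cells)
        assert set(ts.actives) == {"KEEP"}
        assert ts.provenance["cell_lines_dropped"] == {"DROP": "TOO_FEW_ACTIVES"}

    def test_exclusion_list(self):
        descs = _descriptors(13)
        records = self._records("BAD", 3, 10)
        with pytest.raises(EmptyTrainingSetError):
            build_training_set(records, descs, [CellLineLabel("BAD")], ["BAD"])

    def test_active_inactive_disjoint_and_conserved(self):
        descs = _descriptors(14)
        records = self._records("L", 4, 10)
        # add a conflicting pair for c0
        records.append(_rec(99_000, compound="c0", line="L"))
        ts = build_training_set(records, descs, [CellLineLabel("L")])
        assert not (ts.actives["L"] & ts.explicit_inactives["L"])
        assert "c0" not in ts.actives["L"]
        assert ts.provenance["pairs_excluded"]["conflict"] == 1

    def test_min_active_monotonicity(self):
        descs = _descriptors(20)
        records = self._records("A", 3, 10) + self._records("B", 5, 12)
        cells = [CellLineLabel("A"), CellLineLabel("B")]
        retained = []
        for min_active in (3, 4, 6):
            try:
                ts = build_training_set(records, descs, cells, min_active=min_active)
                retained.append(set(ts.actives))
            except EmptyTrainingSetError:
                retained.append(set())
        assert retained[0] >= retained[1] >= retained[2]

    def test_provenance_deterministic(self):
        descs = _descriptors(14)
        records = self._records("L", 4, 10)
        a = build_training_set(records, descs, [CellLineLabel("L")]).provenance
        b = build_training_set(records, descs, [CellLineLabel("L")]).provenance
        assert a == b


class TestActivityTableIO:
    HEADER = "compound_id,cell_line,endpoint,value,unit,relation,structure\n"

    def test_reads_rows(self, tmp_path):
        rows = [
            f"c{i},L1,IC50,{100 * (i + 1)},nM,=," for i in range(5)
        ]
        path = tmp_path / "a.csv"
        path.write_text(self.HEADER + "\n".join(rows) + "\n")
        table = read_activity_table(path)
        assert len(table.records) == 5
        assert table.skipped == 0

    def test_empty_value_skipped(self, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text(self.HEADER + "c1,L1,IC50,,nM,=,\nc2,L1,IC50,5,nM,=,\n")
        table = read_activity_table(path)
        assert len(table.records) == 1
        assert table.skipped == 1

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text("compound_id,endpoint,value,unit,relation\nc1,IC50,5,nM,=\n")
        with pytest.raises(SchemaError, match="cell_line"):
            read_activity_table(path)
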