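"""Scoring, analytic leave-one-out, calibration, prediction, persistence."""

import math

import numpy as np
import pytest

from cytosar.dataset import CellLineLabel, TrainingSet
from cytosar.engine import (
    ActivityModel,
    Calibration,
    DescriptorStatistics,
    calibrate,
    fit,
    fit_model,
    loo_scores,
    predict_profile,
    raw_score,
)
from cytosar.errors import ModelError, OutOfDomainError
from cytosar.fixtures import generate_library
from cytosar.mna import DescriptorSet, descriptor_set


def oracle_score(query, line, stats, c=1.0, exclude=None):
    """Independent brute-force scorer: explicit loop, no shared code."""
    n = stats.n_compounds
    n_a = stats.active_totals[line]
    excl = set()
    excl_act = False
    if exclude is not None:
        excl, excl_act = set(exclude[0]), exclude[1]
        n = n - 1
        if excl_act:
            n_a = n_a - 1
    p0 = n_a / n
    angles = []
    for d in query:
        nd = stats.descriptor_counts.get(d, 0)
        nad = stats.active_descriptor_counts[line].get(d, 0)
        if d in excl:
            nd = nd - 1
            if excl_act:
                nad = nad - 1
        if nd <= 0:
            continue
        p = (nad + c * p0) / (nd + c)
        angles.append(math.asin(2 * p - 1))
    if not angles:
        return None
    return math.sin(sum(angles) / len(angles))


def random_stats(rng, n_desc=30, n=50):
    """Random but consistent sufficient statistics for one cell line."""
    descs = [f"d{i}" for i in range(n_desc)]
    n_a = int(rng.integers(1, n))
    counts = {}
    active_counts = {}
    for d in descs:
        nd = int(rng.integers(1, n + 1))
        counts[d] = nd
        active_counts[d] = int(rng.integers(0, min(nd, n_a) + 1))
    return DescriptorStatistics(
        n_compounds=n,
        descriptor_counts=counts,
        active_totals={"L": n_a},
        active_descriptor_counts={"L": active_counts},
    )


def toy_training_set(n_compounds, n_active, seed, line="L"):
    lib = generate_library(n_compounds, seed=seed)
    descs = {m.identifier: descriptor_set(m) for m in lib}
    rng = np.random.default_rng(seed)
    ids = sorted(descs)
    actives = frozenset(rng.choice(ids, n_active, replace=False))
    return TrainingSet(
        descriptors=descs,
        actives={line: actives},
        explicit_inactives={line: frozenset(set(ids) - actives)},
        cell_lines={line: CellLineLabel(line)},
    )


class TestFit:
    def test_counts(self):
        d1 = DescriptorSet(frozenset({"a", "b"}), "c1")
        d2 = DescriptorSet(frozenset({"b", "c"}), "c2")
        ts = TrainingSet(
            descriptors={"c1": d1, "c2": d2},
            actives={"L": frozenset({"c1"})},
            explicit_inactives={"L": frozenset({"c2"})},
            cell_lines={"L": CellLineLabel("L")},
        )
        stats = fit(ts)
        assert stats.descriptor_counts == {"a": 1, "b": 2, "c": 1}
        assert stats.active_descriptor_counts["L"] == {"a": 1, "b": 1}
        assert stats.active_totals["L"] == 1

    def test_total_increments_conserved(self):
        ts = toy_training_set(20, 5, seed=1)
        stats = fit(ts)
        assert sum(stats.descriptor_counts.values()) == sum(
            len(ds) for ds in ts.descriptors.values()
        )

    def test_empty_refused(self):
        ts = TrainingSet({}, {}, {}, {})
        with pytest.raises(ModelError):
            fit(ts)


class TestRawScore:
    def test_prior_probability_gives_zero(self):
        stats = DescriptorStatistics(
            n_compounds=20,
            descriptor_counts={"d": 10},
            active_totals={"L": 10},
            active_descriptor_counts={"L": {"d": 5}},
        )
        # P(a|d) = (5 + 0.5)/11 = 0.5 = P0 -> B = 0
        assert raw_score({"d"}, "L", stats, c=1.0) == pytest.approx(0.0)

    def test_single_descriptor_closed_form(self):
        stats = DescriptorStatistics(
            n_compounds=20,
            descriptor_counts={"d": 9},
            active_totals={"L": 10},
            active_descriptor_counts={"L": {"d": 9}},
        )
        # P = (9 + 1*0.5)/(9 + 1) = 0.95; single term -> B = 2P - 1
        assert raw_score({"d"}, "L", stats) == pytest.approx(0.9, abs=1e-12)

    def test_matches_independent_oracle_1000_cases(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            stats = random_stats(rng)
            m = int(rng.integers(1, 15))
            query = {f"d{i}" for i in rng.integers(0, 40, size=m)}
            expected = oracle_score(query, "L", stats)
            if expected is None:
                with pytest.raises(OutOfDomainError):
                    raw_score(query, "L", stats)
            else:
                assert raw_score(query, "L", stats) == pytest.approx(
                    expected, abs=1e-12
                )

    def test_unknown_only_query_refused(self):
        stats = random_stats(np.random.default_rng(0))
        with pytest.raises(OutOfDomainError):
            raw_score({"unseen"}, "L", stats)

    def test_smoothing_keeps_score_strictly_inside_unit_interval(self):
        stats = DescriptorStatistics(
            n_compounds=10,
            descriptor_counts={"d": 5},
            active_totals={"L": 5},
            active_descriptor_counts={"L": {"d": 5}},
        )
        b = raw_score({"d"}, "L", stats, c=0.5)
        assert -1.0 < b < 1.0


class TestLOO:
    @pytest.mark.parametrize("n,na,seed", [(20, 5, 3), (50, 12, 9)])
    def test_analytic_equals_refit_exhaustively(self, n, na, seed):
        ts = toy_training_set(n, na, seed=seed)
        stats = fit(ts)
        analytic = loo_scores(ts, stats, "L")
        all_ids = set(ts.compounds)
        for cid in ts.compounds:
            reduced = fit(ts.subset(all_ids - {cid}))
            expected = oracle_score(
                ts.descriptors[cid].descriptors, "L", reduced
            )
            if expected is None:
                assert analytic[cid] is None
            else:
                assert analytic[cid] == pytest.approx(expected, abs=1e-12)

    def test_duplicate_compounds_same_score(self):
        ds = DescriptorSet(frozenset({"a", "b"}), "")
        other = DescriptorSet(frozenset({"a", "c"}), "")
        ts = TrainingSet(
            descriptors={"c1": ds, "c2": ds, "c3": other, "c4": other},
            actives={"L": frozenset({"c1", "c2"})},
            explicit_inactives={"L": frozenset({"c3", "c4"})},
            cell_lines={"L": CellLineLabel("L")},
        )
        scores = loo_scores(ts, fit(ts), "L")
        assert scores["c1"] == scores["c2"]

    def test_unique_descriptor_compound_out_of_domain(self):
        lone = DescriptorSet(frozenset({"only_mine"}), "")
        shared = DescriptorSet(frozenset({"a", "b"}), "")
        ts = TrainingSet(
            descriptors={"c1": lone, "c2": shared, "c3": shared},
            actives={"L": frozenset({"c1", "c2"})},
            explicit_inactives={"L": frozenset({"c3"})},
            cell_lines={"L": CellLineLabel("L")},
        )
        scores = loo_scores(ts, fit(ts), "L")
        assert scores["c1"] is None
        cal = calibrate(scores, {"c1", "c2"}, {"c3"})
        assert cal.n_dropped == 1
        assert len(cal.active_scores) == 1


class TestCalibration:
    def test_cdf_boundaries(self):
        cal = Calibration([0.1, 0.2, 0.3], [-0.2, -0.1])
        assert cal.pa(1.0) == 1.0
        assert cal.pa(0.0) == 0.0
        assert cal.pi(-1.0) == 1.0
        assert cal.pi(0.5) == 0.0

    def test_median_active_score_gives_half(self):
        cal = Calibration([0.1, 0.2, 0.3, 0.4, 0.5], [0.0])
        assert cal.pa(0.3) == pytest.approx(3 / 5)
        assert cal.pa(0.29) == pytest.approx(2 / 5)

    def test_monotonicity(self):
        rng = np.random.default_rng(5)
        cal = Calibration(
            list(rng.normal(size=30)), list(rng.normal(size=50))
        )
        grid = np.linspace(-3, 3, 101)
        pas = [cal.pa(b) for b in grid]
        pis = [cal.pi(b) for b in grid]
        assert all(a <= b + 1e-12 for a, b in zip(pas, pas[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(pis, pis[1:]))
        assert all(0 <= v <= 1 for v in pas + pis)

    def test_degenerate_class_refused(self):
        with pytest.raises(ModelError):
            Calibration([], [0.1])

    def test_training_active_retention_rates(self, standard_training_set):
        """Thresholding Pa at t discards ~t of the training actives."""
        model = fit_model(standard_training_set)
        for line, cal in model.calibrations.items():
            pas = [cal.pa(b) for b in cal.active_scores]
            n_a = len(cal.active_scores)
            for threshold, expected_kept in [(0.5, 0.5), (0.7, 0.3)]:
                kept = sum(1 for p in pas if p > threshold) / n_a
                assert kept == pytest.approx(expected_kept, abs=1.5 / n_a + 0.02)


class TestPredict:
    def test_identical_lines_identical_rows(self):
        ts = toy_training_set(30, 8, seed=4)
        twin = TrainingSet(
            descriptors=ts.descriptors,
            actives={"L1": ts.actives["L"], "L2": ts.actives["L"]},
            explicit_inactives={
                "L1": ts.explicit_inactives["L"],
                "L2": ts.explicit_inactives["L"],
            },
            cell_lines={"L1": CellLineLabel("L1"), "L2": CellLineLabel("L2")},
        )
        model = fit_model(twin)
        preds = predict_profile(ts.descriptors[ts.compounds[0]], model)
        assert len(preds) == 2
        assert preds[0].pa == preds[1].pa and preds[0].pi == preds[1].pi
        # tie broken by name
        assert [p.cell_line for p in preds] == ["L1", "L2"]

    def test_out_of_vocabulary_refusal(self):
        ts = toy_training_set(30, 8, seed=4)
        model = fit_model(ts)
        with pytest.raises(OutOfDomainError):
            predict_profile({"nonexistent"}, model)

    def test_sorted_by_pa_minus_pi(self, standard_training_set):
        model = fit_model(standard_training_set)
        query = standard_training_set.descriptors[
            standard_training_set.compounds[0]
        ]
        preds = predict_profile(query, model)
        gaps = [p.pa - p.pi for p in preds]
        assert gaps == sorted(gaps, reverse=True)
        assert all(0 <= p.pa <= 1 and 0 <= p.pi <= 1 for p in preds)


class TestPersistence:
    def test_save_load_identical_predictions(self, tmp_path):
        ts = toy_training_set(40, 10, seed=6)
        model = fit_model(ts)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = ActivityModel.load(path)
        for cid in ts.compounds[:10]:
            a = predict_profile(ts.descriptors[cid], model)
            b = predict_profile(ts.descriptors[cid], loaded)
            assert a == b

    def test_wrong_schema_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"schema_version": 99}')
        with pytest.raises(ModelError):
            ActivityModel.load(path)
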