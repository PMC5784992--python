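"""Naive-Bayes scoring over MNA descriptors with Pa/Pi calibration.

The model for one cell line *a* is built from binary descriptor
incidence counts over the training corpus of *N* compounds:

* ``N_d``  — compounds whose descriptor set contains *d*;
* ``N_a``  — compounds active for *a* (global-inactive convention:
  every other corpus compound counts as inactive for *a*);
* ``N_ad`` — active compounds containing *d*.

With smoothing constant ``c > 0`` the per-descriptor conditional is
shrunk toward the prior ``P0 = N_a / N``::

    P(a|d) = (N_ad + c * P0) / (N_d + c)

and the raw score of a query with known descriptors d1..dm is the
bounded arcsine mean::

    B = sin( (1/m) * sum_i arcsin(2 * P(a|d_i) - 1) )

Averaging keeps molecule size from inflating the score and smoothing
keeps every term strictly inside (-pi/2, pi/2), so B lies in (-1, 1).
A plain mean-log-odds scorer is available behind ``scorer="logodds"``
for comparison; calibration and validation are scorer-agnostic.

Pa and Pi are read off the leave-one-out score distributions of the
training actives and inactives: Pa(B) is the fraction of active LOO
scores at or below B (the probability that raising the decision
threshold to B would discard a true active — a type-1 error rate), and
Pi(B) the fraction of inactive LOO scores at or above B. Leave-one-out
is computed analytically by decrementing the counts of the held-out
compound, which is exactly equivalent to refitting without it.
"""

from __future__ import annotations

import json
import logging
import math
from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from cytosar.dataset import CellLineLabel, TrainingSet
from cytosar.errors import ModelError, OutOfDomainError
from cytosar.mna import DescriptorSet

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1
SCORERS = ("arcsin", "logodds")


@dataclass
class DescriptorStatistics:
    """Sufficient statistics of the corpus: all exact integer counts."""

    n_compounds: int
    descriptor_counts: dict[str, int]
    active_totals: dict[str, int]
    active_descriptor_counts: dict[str, dict[str, int]]

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.active_totals)


@dataclass(frozen=True)
class Prediction:
    cell_line: str
    b: float
    pa: float
    pi: float
    known_fraction: float


def fit(training_set: TrainingSet) -> DescriptorStatistics:
    """Count descriptor incidences over the corpus and the active sets."""
    if training_set.n_compounds == 0:
        raise ModelError("cannot fit an empty training set")
    descriptor_counts: Counter[str] = Counter()
    for ds in training_set.descriptors.values():
        descriptor_counts.update(ds.descriptors)
    active_totals: dict[str, int] = {}
    active_descriptor_counts: dict[str, dict[str, int]] = {}
    for line, actives in training_set.actives.items():
        active_totals[line] = len(actives)
        counts: Counter[str] = Counter()
        for cid in actives:
            counts.update(training_set.descriptors[cid].descriptors)
        active_descriptor_counts[line] = dict(counts)
    return DescriptorStatistics(
        n_compounds=training_set.n_compounds,
        descriptor_counts=dict(descriptor_counts),
        active_totals=active_totals,
        active_descriptor_counts=active_descriptor_counts,
    )


def _as_descriptor_iter(descriptors) -> Iterable[str]:
    if isinstance(descriptors, DescriptorSet):
        return descriptors.descriptors
    return descriptors


def raw_score(
    descriptors,
    cell_line: str,
    stats: DescriptorStatistics,
    c: float = 1.0,
    exclude: tuple[Iterable[str], bool] | None = None,
    scorer: str = "arcsin",
) -> float:
    """Raw score B of a descriptor set for one cell line.

    ``exclude`` removes one training compound's contributions (its
    descriptor set and whether it is active for this cell line) before
    scoring — the analytic leave-one-out device. Unknown descriptors
    (corpus count zero after exclusion) are skipped; if none are known
    the query is outside the applicability domain.
    """
    if scorer not in SCORERS:
        raise ValueError(f"unknown scorer {scorer!r}")
    if c <= 0:
        raise ValueError("smoothing constant c must be > 0")
    query = set(_as_descriptor_iter(descriptors))
    n = stats.n_compounds
    n_a = stats.active_totals[cell_line]
    n_ad = stats.active_descriptor_counts[cell_line]
    excl_descs: set[str] = set()
    excl_active = False
    if exclude is not None:
        excl_iter, excl_active = exclude
        excl_descs = set(_as_descriptor_iter(excl_iter))
        n -= 1
        if excl_active:
            n_a -= 1
    if n <= 0:
        raise ModelError("no compounds left after exclusion")
    p0 = n_a / n
    terms = []
    for d in sorted(query):
        nd = stats.descriptor_counts.get(d, 0)
        nad = n_ad.get(d, 0)
        if d in excl_descs:
            nd -= 1
            if excl_active:
                nad -= 1
        if nd <= 0:
            continue  # unknown to the (reduced) corpus
        p = (nad + c * p0) / (nd + c)
        terms.append(p)
    if not terms:
        raise OutOfDomainError(
            f"OUT_OF_DOMAIN: no query descriptor known to the model "
            f"for cell line {cell_line!r}"
        )
    if scorer == "arcsin":
        mean = sum(math.asin(2.0 * p - 1.0) for p in terms) / len(terms)
        return math.sin(mean)
    # mean log-odds; unbounded, used only for comparison
    return sum(math.log(p / (1.0 - p)) for p in terms) / len(terms)


def known_fraction(descriptors, stats: DescriptorStatistics) -> float:
    """Fraction of the query's descriptors present in the vocabulary."""
    query = set(_as_descriptor_iter(descriptors))
    if not query:
        return 0.0
    known = sum(1 for d in query if stats.descriptor_counts.get(d, 0) > 0)
    return known / len(query)


def loo_scores(
    training_set: TrainingSet,
    stats: DescriptorStatistics,
    cell_line: str,
    c: float = 1.0,
    scorer: str = "arcsin",
) -> dict[str, float | None]:
    """Leave-one-out score of every corpus compound for one cell line.

    Each compound is scored with its own contributions removed from
    the counts; the result equals scoring against a model refit
    without it. Compounds whose every descriptor is unique to
    themselves become out-of-domain under self-exclusion and are
    recorded as ``None`` (dropped from calibration and CV, counted in
    the model report).
    """
    out: dict[str, float | None] = {}
    actives = training_set.actives[cell_line]
    for cid in training_set.compounds:
        ds = training_set.descriptors[cid]
        try:
            out[cid] = raw_score(
                ds, cell_line, stats, c=c,
                exclude=(ds, cid in actives), scorer=scorer,
            )
        except OutOfDomainError:
            out[cid] = None
    return out


@dataclass
class Calibration:
    """Empirical LOO score distributions for one cell line.

    ``active_scores`` / ``inactive_scores`` are ascending; Pa/Pi are
    step functions on them. ``interpolate=True`` switches to linear
    interpolation between steps.
    """

    active_scores: list[float]
    inactive_scores: list[float]
    n_dropped: int = 0
    interpolate: bool = False

    def __post_init__(self):
        self.active_scores = sorted(self.active_scores)
        self.inactive_scores = sorted(self.inactive_scores)
        if not self.active_scores or not self.inactive_scores:
            raise ModelError(
                "calibration needs at least one active and one inactive LOO score"
            )

    def pa(self, b: float) -> float:
        """Fraction of training actives with LOO score <= b."""
        scores = self.active_scores
        if not self.interpolate:
            return bisect_right(scores, b) / len(scores)
        return _interp_cdf(scores, b)

    def pi(self, b: float) -> float:
        """Fraction of training inactives with LOO score >= b."""
        scores = self.inactive_scores
        if not self.interpolate:
            return (len(scores) - bisect_left(scores, b)) / len(scores)
        return 1.0 - _interp_cdf(scores, b, strict=True)


def _interp_cdf(scores: list[float], b: float, strict: bool = False) -> float:
    n = len(scores)
    if b < scores[0]:
        return 0.0
    if b > scores[-1]:
        return 1.0
    idx = bisect_left(scores, b) if strict else bisect_right(scores, b)
    idx = min(max(idx, 1), n - 1)
    lo, hi = scores[idx - 1], scores[idx]
    frac = 0.0 if hi == lo else (b - lo) / (hi - lo)
    return ((idx - 1) + frac + 1) / (n + 1)


def calibrate(
    scores: Mapping[str, float | None],
    active_ids: Iterable[str],
    inactive_ids: Iterable[str],
    interpolate: bool = False,
) -> Calibration:
    """Build the Pa/Pi calibration curves from LOO scores and labels."""
    active_ids = set(active_ids)
    inactive_ids = set(inactive_ids)
    act = [s for cid, s in scores.items() if cid in active_ids and s is not None]
    inact = [s for cid, s in scores.items() if cid in inactive_ids and s is not None]
    dropped = sum(1 for s in scores.values() if s is None)
    return Calibration(
        active_scores=act,
        inactive_scores=inact,
        n_dropped=dropped,
        interpolate=interpolate,
    )


@dataclass
class ActivityModel:
    """A fitted, calibrated multi-cell-line cytotoxicity model."""

    stats: DescriptorStatistics
    c: float
    scorer: str
    calibrations: dict[str, Calibration]
    cell_lines: dict[str, CellLineLabel]
    report: dict = field(default_factory=dict)

    @property
    def retained_cell_lines(self) -> list[str]:
        return sorted(self.calibrations)

    def predict(self, descriptors) -> list[Prediction]:
        return predict_profile(descriptors, self)

    # -- persistence ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize to a single JSON file; reload is bit-exact."""
        payload = {
            "schema_version": SCHEMA_VERSION,
            "c": self.c,
            "scorer": self.scorer,
            "n_compounds": self.stats.n_compounds,
            "descriptor_counts": self.stats.descriptor_counts,
            "active_totals": self.stats.active_totals,
            "active_descriptor_counts": self.stats.active_descriptor_counts,
            "calibrations": {
                line: {
                    "active_scores": cal.active_scores,
                    "inactive_scores": cal.inactive_scores,
                    "n_dropped": cal.n_dropped,
                    "interpolate": cal.interpolate,
                }
                for line, cal in self.calibrations.items()
            },
            "cell_lines": {
                line: {
                    "short_name": m.short_name,
                    "full_name": m.full_name,
                    "tissue": m.tissue,
                    "kind": m.kind,
                    "tumour_type": m.tumour_type,
                }
                for line, m in self.cell_lines.items()
            },
            "report": self.report,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ActivityModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ModelError(
                f"unsupported model schema version: {payload.get('schema_version')}"
            )
        stats = DescriptorStatistics(
            n_compounds=payload["n_compounds"],
            descriptor_counts=payload["descriptor_counts"],
            active_totals=payload["active_totals"],
            active_descriptor_counts=payload["active_descriptor_counts"],
        )
        calibrations = {
            line: Calibration(
                active_scores=d["active_scores"],
                inactive_scores=d["inactive_scores"],
                n_dropped=d["n_dropped"],
                interpolate=d["interpolate"],
            )
            for line, d in payload["calibrations"].items()
        }
        cell_lines = {
            line: CellLineLabel(**d) for line, d in payload["cell_lines"].items()
        }
        return cls(
            stats=stats,
            c=payload["c"],
            scorer=payload["scorer"],
            calibrations=calibrations,
            cell_lines=cell_lines,
            report=payload.get("report", {}),
        )


def fit_model(
    training_set: TrainingSet,
    c: float = 1.0,
    scorer: str = "arcsin",
    tested_only: bool = False,
    interpolate: bool = False,
    cell_lines: Iterable[str] | None = None,
) -> ActivityModel:
    """Fit counts, run LOO, calibrate every (or the given) cell line(s).

    ``tested_only`` restricts the calibration inactives to explicitly
    tested inactive compounds instead of the global-inactive pool.
    """
    stats = fit(training_set)
    lines = sorted(cell_lines) if cell_lines is not None else sorted(
        training_set.actives
    )
    calibrations: dict[str, Calibration] = {}
    dropped: dict[str, int] = {}
    for line in lines:
        scores = loo_scores(training_set, stats, line, c=c, scorer=scorer)
        actives = training_set.actives[line]
        if tested_only:
            inactives = set(training_set.explicit_inactives[line])
        else:
            inactives = set(training_set.compounds) - set(actives)
        cal = calibrate(scores, actives, inactives, interpolate=interpolate)
        calibrations[line] = cal
        dropped[line] = cal.n_dropped
    return ActivityModel(
        stats=stats,
        c=c,
        scorer=scorer,
        calibrations=calibrations,
        cell_lines=dict(training_set.cell_lines),
        report={
            "loo_out_of_domain": dropped,
            "tested_only": tested_only,
            "n_compounds": training_set.n_compounds,
        },
    )


def predict_profile(descriptors, model: ActivityModel) -> list[Prediction]:
    """Score a query against every calibrated cell line; rank by Pa-Pi.

    Cell lines for which the query is out of domain are omitted with a
    warning; if every cell line is out of domain the whole prediction
    is refused. Ties in Pa-Pi are broken by cell-line short name so
    repeated runs render identically.
    """
    frac = known_fraction(descriptors, model.stats)
    rows: list[Prediction] = []
    for line in model.retained_cell_lines:
        try:
            b = raw_score(
                descriptors, line, model.stats, c=model.c, scorer=model.scorer
            )
        except OutOfDomainError:
            log.warning("query out of domain for cell line %s; omitted", line)
            continue
        cal = model.calibrations[line]
        rows.append(
            Prediction(
                cell_line=line,
                b=b,
                pa=cal.pa(b),
                pi=cal.pi(b),
                known_fraction=frac,
            )
        )
    if not rows:
        raise OutOfDomainError(
            "OUT_OF_DOMAIN: query shares no descriptor with the model vocabulary"
        )
    rows.sort(key=lambda p: (-(p.pa - p.pi), p.cell_line))
    return rows
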