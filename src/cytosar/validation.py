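"""Cross-validated ROC-AUC estimation and AUC-threshold model selection.

AUC is the Mann-Whitney estimator — the probability that a randomly
chosen active outscores a randomly chosen inactive, ties counted half —
computed from midranks. Leave-one-out CV uses the engine's analytic
self-exclusion; k-fold CV partitions the corpus once (all cell lines
share the folds) with compounds dealt round-robin within activity-
signature groups so each cell line's actives spread evenly over folds.
Models are retained only when their LOO AUC strictly exceeds the
selection threshold (default 0.8).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from cytosar.dataset import TrainingSet
from cytosar.engine import fit, loo_scores, raw_score
from cytosar.errors import OutOfDomainError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVResult:
    cell_line: str
    method: str  # "LOO" or "KFOLD(k,seed)"
    auc: float  # NaN when degenerate
    n_active: int
    n_inactive: int
    n_dropped: int

    @property
    def degenerate(self) -> bool:
        return math.isnan(self.auc)


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Mann-Whitney AUC: [#(pos>neg) + 0.5*#ties] / (n_pos*n_neg)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs at least one score of each class")
    ranks = rankdata(scores)  # midranks handle ties exactly
    rank_sum_pos = float(ranks[labels].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _labelled_scores(
    training_set: TrainingSet,
    cell_line: str,
    scores: Mapping[str, float | None],
    tested_only: bool,
) -> tuple[list[float], list[bool], int]:
    actives = training_set.actives[cell_line]
    if tested_only:
        pool = set(actives) | set(training_set.explicit_inactives[cell_line])
    else:
        pool = set(training_set.compounds)
    xs: list[float] = []
    ys: list[bool] = []
    dropped = 0
    for cid in sorted(pool):
        s = scores.get(cid)
        if s is None:
            dropped += 1
            continue
        xs.append(s)
        ys.append(cid in actives)
    return xs, ys, dropped


def _cv_result(
    cell_line: str, method: str, xs: list[float], ys: list[bool], dropped: int
) -> CVResult:
    n_active = sum(ys)
    n_inactive = len(ys) - n_active
    if n_active == 0 or n_inactive == 0:
        log.warning(
            "degenerate class for %s after drops (%d active / %d inactive)",
            cell_line, n_active, n_inactive,
        )
        auc = float("nan")
    else:
        auc = roc_auc(xs, ys)
    return CVResult(
        cell_line=cell_line,
        method=method,
        auc=auc,
        n_active=n_active,
        n_inactive=n_inactive,
        n_dropped=dropped,
    )


def loo_cv(
    training_set: TrainingSet,
    c: float = 1.0,
    scorer: str = "arcsin",
    tested_only: bool = False,
) -> dict[str, CVResult]:
    """Leave-one-out AUC per cell line from analytic self-exclusion scores."""
    stats = fit(training_set)
    out: dict[str, CVResult] = {}
    for line in sorted(training_set.actives):
        scores = loo_scores(training_set, stats, line, c=c, scorer=scorer)
        xs, ys, dropped = _labelled_scores(training_set, line, scores, tested_only)
        out[line] = _cv_result(line, "LOO", xs, ys, dropped)
    return out


def make_folds(training_set: TrainingSet, k: int, seed: int) -> list[list[str]]:
    """One shared fold partition for all cell lines.

    Compounds are grouped by their activity signature (the set of cell
    lines they are active for), shuffled within groups, and dealt
    round-robin to the k folds — an approximate per-cell-line
    stratification on the active label with a single corpus partition.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    compounds = training_set.compounds
    if k > len(compounds):
        log.warning("k=%d exceeds corpus size %d; reducing", k, len(compounds))
        k = len(compounds)
    signature = {
        cid: tuple(
            sorted(l for l, s in training_set.actives.items() if cid in s)
        )
        for cid in compounds
    }
    rng = np.random.default_rng(seed)
    ordered: list[str] = []
    for sig in sorted(set(signature.values())):
        group = [cid for cid in compounds if signature[cid] == sig]
        rng.shuffle(group)
        ordered.extend(group)
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, cid in enumerate(ordered):
        folds[i % k].append(cid)
    return folds


def kfold_cv(
    training_set: TrainingSet,
    k: int = 20,
    seed: int = 0,
    c: float = 1.0,
    scorer: str = "arcsin",
    tested_only: bool = False,
) -> dict[str, CVResult]:
    """k-fold AUC per cell line; every compound scored exactly once.

    Each fold's compounds are scored against counts fitted on the
    remaining folds; per-cell-line scores are pooled over folds before
    the AUC. The partition is reproducible from the seed.
    """
    folds = make_folds(training_set, k, seed)
    k = len(folds)
    method = f"KFOLD({k},{seed})"
    scores: dict[str, dict[str, float | None]] = {
        line: {} for line in training_set.actives
    }
    all_ids = set(training_set.compounds)
    for fold in folds:
        reduced = training_set.subset(all_ids - set(fold))
        stats = fit(reduced)
        for cid in fold:
            ds = training_set.descriptors[cid]
            for line in training_set.actives:
                try:
                    scores[line][cid] = raw_score(
                        ds, line, stats, c=c, scorer=scorer
                    )
                except OutOfDomainError:
                    scores[line][cid] = None
    out: dict[str, CVResult] = {}
    for line in sorted(training_set.actives):
        xs, ys, dropped = _labelled_scores(
            training_set, line, scores[line], tested_only
        )
        out[line] = _cv_result(line, method, xs, ys, dropped)
    return out


def select_models(
    cv_results: Mapping[str, CVResult], threshold: float = 0.8
) -> tuple[set[str], dict[str, str]]:
    """Retain cell lines whose AUC strictly exceeds the threshold.

    Returns (retained set, dropped reasons). A line at exactly the
    threshold is dropped; degenerate (NaN) results are dropped too.
    """
    retained: set[str] = set()
    dropped: dict[str, str] = {}
    for line, res in sorted(cv_results.items()):
        if res.degenerate:
            dropped[line] = "DEGENERATE_CLASS"
        elif res.auc > threshold:
            retained.add(line)
        else:
            dropped[line] = f"AUC_{res.auc:.3f}_NOT_ABOVE_{threshold}"
    return retained, dropped
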