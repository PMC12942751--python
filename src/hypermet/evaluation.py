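"""Metrics, cross-validation, confidence intervals, and the ratio sweep.

Point metrics (ACC, SEN, SPE, PRE, MCC) are computed from integer
confusion counts; any zero denominator yields 0 with the metric listed in
an ``undefined`` flag set so reports stay machine-readable.  AUC is the
trapezoidal ROC area (identical to the Mann-Whitney concordance
probability with half credit for ties) and AUPRC uses the average-
precision convention, both delegated to scikit-learn.  Fold means are
reported with the sample SD (k-1 denominator; a flag switches to the
population SD) and the 95% CI half-width 1.96 * SD / sqrt(k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .association import (
    LabeledPairSet,
    build_pair_features,
    predict_pairs,
    train_classifier,
)
from .hgnn import EmbeddingSet

METRIC_NAMES = ("ACC", "SEN", "SPE", "PRE", "MCC", "AUC", "AUPRC")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    values: dict[str, float]
    undefined: set[str] = field(default_factory=set)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_dict(self) -> dict:
        return {"values": dict(self.values), "undefined": sorted(self.undefined)}


@dataclass
class CvReport:
    folds: list[MetricReport]
    mean: dict[str, float]
    sd: dict[str, float]
    ci95: dict[str, float]
    k: int
    seed: int
    sd_convention: str = "sample"

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "sd_convention": self.sd_convention,
            "auprc_convention": "average_precision",
            "folds": [f.as_dict() for f in self.folds],
            "mean": self.mean,
            "sd": self.sd,
            "ci95_halfwidth": self.ci95,
        }


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between labels and predictions")
    for arr, name in ((y_true, "labels"), (y_pred, "predictions")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def point_metrics(c: ConfusionCounts) -> MetricReport:
    """ACC/SEN/SPE/PRE/MCC from counts; zero denominators -> 0 + flag."""
    if c.total == 0:
        raise ValueError("no evaluated pairs")
    values: dict[str, float] = {}
    undefined: set[str] = set()

    def ratio(name: str, num: int, den: int) -> None:
        if den == 0:
            values[name] = 0.0
            undefined.add(name)
        else:
            values[name] = num / den

    ratio("ACC", c.tp + c.tn, c.total)
    ratio("SEN", c.tp, c.tp + c.fn)
    ratio("SPE", c.tn, c.tn + c.fp)
    ratio("PRE", c.tp, c.tp + c.fp)
    denom2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom2 == 0:
        values["MCC"] = 0.0
        undefined.add("MCC")
    else:
        values["MCC"] = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom2)
    return MetricReport(values, undefined)


def auc_roc(y_true, scores) -> float:
    """Trapezoidal ROC area == Mann-Whitney concordance with tie half-credit."""
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


def auprc(y_true, scores) -> float:
    """Average precision (precision summed over positive-retrieval steps)."""
    y_true = np.asarray(y_true, dtype=int)
    if y_true.sum() == 0:
        raise ValueError("AUPRC requires at least one positive")
    return float(average_precision_score(y_true, np.asarray(scores, dtype=float)))


def kfold_split(labels, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Stratified-by-label partition into k folds (index arrays), seeded."""
    labels = np.asarray(labels, dtype=int)
    if labels.size < k:
        raise ValueError(f"{labels.size} pairs cannot be split into {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(labels.size), labels)]


def ci95_halfwidth(sd: float, k: int) -> float:
    """95% CI half-width 1.96 * SD / sqrt(k)."""
    if sd < 0 or k < 1:
        raise ValueError("sd must be >= 0 and k >= 1")
    return 1.96 * sd / math.sqrt(k)


def score_metrics(y_true, scores, threshold: float = 0.5) -> MetricReport:
    """All seven metrics from raw scores at the given decision threshold."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    report = point_metrics(confusion(y_true, (scores >= threshold).astype(int)))
    report.values["AUC"] = auc_roc(y_true, scores)
    report.values["AUPRC"] = auprc(y_true, scores)
    return report


def _aggregate(folds: list[MetricReport], k: int, seed: int,
               sd_convention: str) -> CvReport:
    ddof = 1 if sd_convention == "sample" else 0
    mean, sd, ci = {}, {}, {}
    for name in METRIC_NAMES:
        vals = np.array([f[name] for f in folds])
        mean[name] = float(vals.mean())
        sd[name] = float(vals.std(ddof=ddof))
        ci[name] = ci95_halfwidth(sd[name], k)
    return CvReport(folds, mean, sd, ci, k=k, seed=seed, sd_convention=sd_convention)


def cross_validate(
    pairs: LabeledPairSet,
    disease_emb: EmbeddingSet,
    metabolite_emb: EmbeddingSet,
    classifier_params: dict | None = None,
    k: int = 5,
    seed: int = 0,
    sd_convention: str = "sample",
) -> CvReport:
    """Stratified k-fold CV of the boosted pair classifier.

    Each fold trains on the other k-1 folds and reports all seven metrics
    on the held-out fold.
    """
    if sd_convention not in ("sample", "population"):
        raise ValueError("sd_convention must be 'sample' or 'population'")
    feats = build_pair_features(pairs, disease_emb, metabolite_emb)
    x, y = feats.values, pairs.labels
    fold_reports = []
    for test_idx in kfold_split(y, k=k, seed=seed):
        mask = np.zeros(len(y), dtype=bool)
        mask[test_idx] = True
        model = train_classifier(x[~mask], y[~mask], classifier_params, seed=seed)
        scores, _ = predict_pairs(model, x[mask])
        fold_reports.append(score_metrics(y[mask], scores))
    return _aggregate(fold_reports, k, seed, sd_convention)


def ratio_sweep(
    positives,
    catalog,
    disease_emb: EmbeddingSet,
    metabolite_emb: EmbeddingSet,
    ratios=range(1, 11),
    indirect=None,
    classifier_params: dict | None = None,
    k: int = 5,
    seed: int = 0,
) -> dict[int, CvReport]:
    """One fresh negative sample + k-fold CV per requested ratio.

    Feasibility at the largest ratio is established up front so an
    infeasible request fails before any work, naming the maximum feasible
    ratio.
    """
    from .association import sample_negatives

    ratios = sorted(set(int(r) for r in ratios))
    n_pos = len(set(positives))
    n_dis = len(catalog.ids_of_type("disease"))
    n_met = len(catalog.ids_of_type("metabolite"))
    indirect_extra = len({(d, m) for (m, d) in (indirect or set())} - set(positives))
    pool = n_dis * n_met - n_pos - indirect_extra
    max_feasible = pool // n_pos if n_pos else 0
    bad = [r for r in ratios if r > max_feasible]
    if bad:
        raise ValueError(
            f"ratios {bad} infeasible: pool of {pool} negatives supports "
            f"at most ratio 1:{max_feasible}"
        )
    out: dict[int, CvReport] = {}
    for r in ratios:
        sampled = sample_negatives(positives, catalog, ratio=r,
                                   indirect=indirect, seed=seed + r)
        out[r] = cross_validate(sampled, disease_emb, metabolite_emb,
                                classifier_params, k=k, seed=seed)
    return out
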