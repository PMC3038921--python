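"""Evaluation harness: LOOCV, independent tests, metrics, multi-run
averaging over resampled negative sets, and the reliability-index sweep.

Accuracy is reported per class as sensitivity TP/(TP+FN) and positive
predictive value TP/(TP+FP), plus the overall accuracy (fraction of
proteins predicted into their annotated class).  Leave-one-out
cross-validation retrains the model for every held-out protein and, to
avoid information leakage, removes the held-out protein from every evidence
source before featurizing: from its training partners' interactor sets,
from the GO class counts, and from the co-expression reference group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .classifier import (
    DEFAULT_ALPHA,
    DEFAULT_PRIORS,
    ClassifierModel,
    Prediction,
    classify,
    train_model,
)
from .features import BinningConfig, CohortFeaturizer
from .io import sample_non_nucleolar
from .types import (
    CLASS_ORDER,
    AnnotationBundle,
    LabelledCorpus,
    NucleolarClass,
    ProteinRecord,
)

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "class_metrics",
    "loocv",
    "fit",
    "evaluate_independent",
    "multirun_evaluate",
    "reliability_sweep",
]

DEFAULT_RI_THRESHOLDS = (1.0, 2.0, 5.0, 10.0, 25.0, 50.0, 100.0, 150.0)


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows are true classes, columns predicted classes, both
    in canonical class order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(CLASS_ORDER)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be >= 0")

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[Tuple[NucleolarClass, NucleolarClass]]
    ) -> "ConfusionMatrix":
        idx = {c: i for i, c in enumerate(CLASS_ORDER)}
        counts = np.zeros((len(CLASS_ORDER), len(CLASS_ORDER)), dtype=int)
        for truth, pred in pairs:
            counts[idx[truth], idx[pred]] += 1
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvaluationReport:
    """Per-class sensitivity/PPV, overall accuracy, coverage, and optional
    across-run standard deviations.

    Metrics with a zero denominator are NaN (undefined), never 0 — an
    absent class must not silently deflate averages.
    """

    sensitivity: Dict[NucleolarClass, float]
    ppv: Dict[NucleolarClass, float]
    accuracy: float
    n_evaluated: int
    coverage: float = 1.0
    sensitivity_sd: Dict[NucleolarClass, float] = field(default_factory=dict)
    ppv_sd: Dict[NucleolarClass, float] = field(default_factory=dict)
    accuracy_sd: float = 0.0
    n_runs: int = 1


def class_metrics(confusion: ConfusionMatrix, coverage: float = 1.0) -> EvaluationReport:
    """One-vs-rest sensitivity and PPV per class plus overall accuracy."""
    if confusion.total < 1:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    c = confusion.counts
    sens, ppv = {}, {}
    for i, cls in enumerate(CLASS_ORDER):
        tp = c[i, i]
        fn = c[i, :].sum() - tp
        fp = c[:, i].sum() - tp
        sens[cls] = float(tp / (tp + fn)) if (tp + fn) > 0 else math.nan
        ppv[cls] = float(tp / (tp + fp)) if (tp + fp) > 0 else math.nan
    return EvaluationReport(
        sensitivity=sens,
        ppv=ppv,
        accuracy=float(np.trace(c) / confusion.total),
        n_evaluated=confusion.total,
        coverage=coverage,
    )


def fit(
    corpus: LabelledCorpus,
    bundle: AnnotationBundle,
    config: Optional[BinningConfig] = None,
    priors: Optional[Mapping[NucleolarClass, float]] = None,
    alpha: float = DEFAULT_ALPHA,
    featurizer: Optional[CohortFeaturizer] = None,
) -> ClassifierModel:
    """Featurize a labelled corpus (each protein held out of its own
    evidence) and train a model on it."""
    fz = featurizer or CohortFeaturizer(corpus.proteins, bundle, config)
    labels = corpus.labels
    vectors = fz.vectors(labels, targets=list(labels))
    return train_model(labels, vectors, priors=priors, alpha=alpha, binning=fz.config)


def loocv(
    corpus: LabelledCorpus,
    bundle: AnnotationBundle,
    config: Optional[BinningConfig] = None,
    priors: Optional[Mapping[NucleolarClass, float]] = None,
    alpha: float = DEFAULT_ALPHA,
) -> Tuple[List[Prediction], EvaluationReport]:
    """Leave-one-out cross-validation with full holdout of the test
    protein.

    For every protein: the remaining corpus is featurized with the held-out
    id excluded from all interactor sets, GO class counts and co-expression
    references; a model is retrained on it; the held-out protein is then
    featurized and classified under the same exclusions.
    """
    labels = corpus.labels
    if len(labels) < 2 or len(set(labels.values())) < 2:
        raise ValueError("LOOCV needs >= 2 proteins spanning >= 2 classes")
    fz = CohortFeaturizer(corpus.proteins, bundle, config)
    predictions: List[Prediction] = []
    for held_out in sorted(labels):
        rest = {pid: cls for pid, cls in labels.items() if pid != held_out}
        vectors = fz.vectors(rest, exclude_id=held_out)
        model = train_model(
            rest,
            vectors,
            priors=priors,
            alpha=alpha,
            binning=fz.config,
        )
        predictions.append(classify(model, vectors[held_out], protein_id=held_out))
    confusion = ConfusionMatrix.from_pairs(
        [(labels[p.id], p.label) for p in predictions]
    )
    return predictions, class_metrics(confusion)


def evaluate_independent(
    model: ClassifierModel,
    test: LabelledCorpus,
    bundle: AnnotationBundle,
    config: Optional[BinningConfig] = None,
) -> Tuple[List[Prediction], EvaluationReport]:
    """Score a held-out test corpus against a trained model.

    Any overlap between the test ids and the model's training manifest is
    an error (leakage guard).
    """
    if len(test) == 0:
        raise ValueError("test corpus is empty")
    overlap = set(test.ids) & set(model.training_ids)
    if overlap:
        raise ValueError(
            f"test corpus overlaps the training manifest: {sorted(overlap)[:5]}"
        )
    fz = CohortFeaturizer(test.proteins, bundle, config or model.binning)
    vectors = fz.vectors(model.training_manifest, targets=test.ids)
    predictions = [
        classify(model, vectors[pid], protein_id=pid) for pid in test.ids
    ]
    truths = test.labels
    confusion = ConfusionMatrix.from_pairs(
        [(truths[p.id], p.label) for p in predictions]
    )
    return predictions, class_metrics(confusion)


def _aggregate(reports: Sequence[EvaluationReport]) -> EvaluationReport:
    def mean_sd(values: List[float]) -> Tuple[float, float]:
        arr = np.array(values, dtype=float)
        if np.all(np.isnan(arr)):
            return math.nan, math.nan
        mean = float(np.nanmean(arr))
        sd = float(np.nanstd(arr, ddof=1)) if len(arr) > 1 else 0.0
        return mean, sd

    sens, sens_sd, ppv, ppv_sd = {}, {}, {}, {}
    for cls in CLASS_ORDER:
        sens[cls], sens_sd[cls] = mean_sd([r.sensitivity[cls] for r in reports])
        ppv[cls], ppv_sd[cls] = mean_sd([r.ppv[cls] for r in reports])
    acc, acc_sd = mean_sd([r.accuracy for r in reports])
    cov, _ = mean_sd([r.coverage for r in reports])
    return EvaluationReport(
        sensitivity=sens,
        ppv=ppv,
        accuracy=acc,
        n_evaluated=int(np.mean([r.n_evaluated for r in reports])),
        coverage=cov,
        sensitivity_sd=sens_sd,
        ppv_sd=ppv_sd,
        accuracy_sd=acc_sd,
        n_runs=len(reports),
    )


def multirun_evaluate(
    nucleolar_corpus: LabelledCorpus,
    negative_pool: Sequence[ProteinRecord],
    bundle: AnnotationBundle,
    n_negative: int,
    n_runs: int = 10,
    mode: str = "loocv",
    seeds: Optional[Sequence[int]] = None,
    config: Optional[BinningConfig] = None,
    priors: Optional[Mapping[NucleolarClass, float]] = None,
    alpha: float = DEFAULT_ALPHA,
    test_corpus: Optional[LabelledCorpus] = None,
) -> EvaluationReport:
    """Average an evaluation over runs that share the nucleolar training
    groups but resample the non-nucleolar set.

    Each run draws ``n_negative`` fresh negatives from ``negative_pool``
    (excluding nucleolar-labelled ids) with its own seed, then runs either
    LOOCV or — with ``mode="independent"`` and a ``test_corpus`` — an
    independent test.  The report carries per-metric mean and across-run
    standard deviation (n-1 denominator; 0 for a single run).
    """
    if mode not in ("loocv", "independent"):
        raise ValueError(f"unknown mode: {mode!r}")
    if mode == "independent" and test_corpus is None:
        raise ValueError("mode='independent' requires a test_corpus")
    if seeds is None:
        seeds = list(range(1, n_runs + 1))
    if len(seeds) != n_runs:
        raise ValueError("need one seed per run")
    nucleolar_ids = set(nucleolar_corpus.ids)
    reports = []
    for s in seeds:
        negatives = sample_non_nucleolar(
            list(negative_pool), nucleolar_ids, n_negative, seed=s
        )
        corpus = nucleolar_corpus.merge(negatives, provenance=f"run(seed={s})")
        if mode == "loocv":
            _, report = loocv(corpus, bundle, config, priors, alpha)
        else:
            model = fit(corpus, bundle, config, priors, alpha)
            _, report = evaluate_independent(model, test_corpus, bundle, config)
        reports.append(report)
    return _aggregate(reports)


def reliability_sweep(
    predictions: Sequence[Prediction],
    truths: Mapping[str, NucleolarClass],
    thresholds: Sequence[float] = DEFAULT_RI_THRESHOLDS,
) -> List[Tuple[float, float, Optional[EvaluationReport]]]:
    """Accuracy/coverage as the minimum reliability index rises.

    At threshold t only predictions with RI >= t are scored; coverage is
    the retained fraction and is non-increasing in t.  Returns a list of
    (threshold, coverage, report) with report ``None`` when nothing
    survives.
    """
    missing = [p.id for p in predictions if p.id not in truths]
    if missing:
        raise ValueError(f"predictions without truth labels: {missing[:5]}")
    if not predictions:
        raise ValueError("no predictions to sweep")
    out = []
    for t in thresholds:
        retained = [p for p in predictions if p.reliability_index >= t]
        coverage = len(retained) / len(predictions)
        if retained:
            confusion = ConfusionMatrix.from_pairs(
                [(truths[p.id], p.label) for p in retained]
            )
            report = class_metrics(confusion, coverage=coverage)
        else:
            report = None
        out.append((float(t), coverage, report))
    return out
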