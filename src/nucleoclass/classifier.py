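"""Semi-naive Bayes training, scoring, and the reliability index.

Training counts, per feature channel and bin, how many proteins of each
class fall in the bin; a pseudocount keeps every entry strictly positive.
Each bin column is normalised by the total count in the bin regardless of
class, giving per-bin class proportions.  A protein's per-class score is
the class prior multiplied by its bin entries across the channels it has;
the predicted label is the highest-scoring class and the reliability index
is the ratio of the top score to the runner-up.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Mapping, Optional

import numpy as np

from .features import CHANNELS, MISSING, BinningConfig, FeatureVector
from .types import CLASS_ORDER, LabelledCorpus, NucleolarClass

__all__ = [
    "DEFAULT_PRIORS",
    "DEFAULT_ALPHA",
    "ConditionalProbabilityTable",
    "ClassifierModel",
    "Prediction",
    "train_model",
    "score",
    "classify",
    "save_model",
    "load_model",
]

#: class priors, chosen in the original study to minimise the average class
#: error under leave-one-out cross-validation
DEFAULT_PRIORS: Dict[NucleolarClass, float] = {
    NucleolarClass.ENRICHED: 0.20,
    NucleolarClass.NUCLEOPLASMIC: 0.15,
    NucleolarClass.CYTOPLASMIC: 0.15,
    NucleolarClass.NON_NUCLEOLAR: 0.50,
}

DEFAULT_ALPHA = 0.1


@dataclass
class ConditionalProbabilityTable:
    """Per-bin class proportions for one feature channel.

    ``table`` has shape (n_bins, 4); every row (bin) sums to 1 and all
    entries are strictly positive thanks to the pseudocount.
    """

    feature: str
    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim != 2 or self.table.shape[1] != len(CLASS_ORDER):
            raise ValueError(
                f"{self.feature}: table must be (n_bins, {len(CLASS_ORDER)})"
            )
        if not np.all(self.table > 0):
            raise ValueError(f"{self.feature}: all entries must be > 0")
        sums = self.table.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"{self.feature}: bin rows must sum to 1, got {sums}")

    @property
    def n_bins(self) -> int:
        return self.table.shape[0]


@dataclass
class ClassifierModel:
    """A trained model: priors, pseudocount, per-channel tables, binning."""

    priors: Dict[NucleolarClass, float]
    alpha: float
    tables: Dict[str, ConditionalProbabilityTable]
    binning: BinningConfig
    training_manifest: Dict[str, NucleolarClass] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("pseudocount alpha must be > 0")
        if set(self.priors) != set(CLASS_ORDER):
            raise ValueError("priors must cover exactly the four classes")
        vals = np.array([self.priors[c] for c in CLASS_ORDER])
        if not np.all(vals > 0):
            raise ValueError("priors must be strictly positive")
        if not math.isclose(vals.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"priors must sum to 1, got {vals.sum()}")

    @property
    def training_ids(self) -> FrozenSet[str]:
        return frozenset(self.training_manifest)


@dataclass(frozen=True)
class Prediction:
    """Classifier output for one protein."""

    id: str
    scores: Dict[NucleolarClass, float]
    label: NucleolarClass
    reliability_index: float
    channels_used: FrozenSet[str]


def train_model(
    corpus: LabelledCorpus | Mapping[str, NucleolarClass],
    vectors: Mapping[str, FeatureVector],
    priors: Optional[Mapping[NucleolarClass, float]] = None,
    alpha: float = DEFAULT_ALPHA,
    binning: Optional[BinningConfig] = None,
) -> ClassifierModel:
    """Train from labelled feature vectors.

    For channel f, bin b, class c the table entry is
    ``(n_fbc + alpha) / sum_c'(n_fbc' + alpha)`` where n counts training
    proteins of class c whose channel-f bin is b; MISSING channels are not
    counted.  A bin that no protein occupies therefore gets the uniform
    0.25 vector.
    """
    labels = corpus.labels if isinstance(corpus, LabelledCorpus) else dict(corpus)
    if not labels:
        raise ValueError("training corpus is empty")
    if alpha <= 0:
        raise ValueError("pseudocount alpha must be > 0")
    missing_vectors = set(labels) - set(vectors)
    if missing_vectors:
        raise ValueError(
            f"no feature vector for labelled proteins: {sorted(missing_vectors)[:5]}"
        )
    config = binning or BinningConfig()
    n_bins = config.n_bins()
    class_idx = {c: i for i, c in enumerate(CLASS_ORDER)}

    counts = {ch: np.zeros((n_bins[ch], len(CLASS_ORDER))) for ch in CHANNELS}
    for pid in sorted(labels):
        vec = vectors[pid]
        ci = class_idx[labels[pid]]
        for ch, b in vec.channels().items():
            if b is MISSING:
                continue
            if not 0 <= b < n_bins[ch]:
                raise ValueError(
                    f"protein {pid}: channel {ch} bin {b} out of range "
                    f"[0, {n_bins[ch]})"
                )
            counts[ch][b, ci] += 1

    tables = {}
    for ch, cnt in counts.items():
        numer = cnt + alpha
        tables[ch] = ConditionalProbabilityTable(
            ch, numer / numer.sum(axis=1, keepdims=True)
        )
    return ClassifierModel(
        priors=dict(priors) if priors is not None else dict(DEFAULT_PRIORS),
        alpha=alpha,
        tables=tables,
        binning=config,
        training_manifest=dict(labels),
    )


def _log_scores(model: ClassifierModel, vector: FeatureVector):
    log_s = np.log([model.priors[c] for c in CLASS_ORDER])
    used = []
    for ch, b in vector.channels().items():
        if b is MISSING:
            continue
        table = model.tables[ch]
        if not 0 <= b < table.n_bins:
            raise ValueError(
                f"channel {ch}: bin {b} out of range [0, {table.n_bins})"
            )
        log_s = log_s + np.log(table.table[b])
        used.append(ch)
    return log_s, frozenset(used)


def score(model: ClassifierModel, vector: FeatureVector) -> Dict[NucleolarClass, float]:
    """Per-class score: prior x product of bin entries over present
    channels.  Computed in log space; strictly positive."""
    log_s, _ = _log_scores(model, vector)
    return {c: float(np.exp(log_s[i])) for i, c in enumerate(CLASS_ORDER)}


def classify(
    model: ClassifierModel, vector: FeatureVector, protein_id: str = ""
) -> Prediction:
    """Label a protein with its highest-scoring class (precedence order
    breaks exact ties) and attach the reliability index, the ratio of the
    top score to the second score (1.0 under an exact tie)."""
    log_s, used = _log_scores(model, vector)
    order = np.argsort(log_s, kind="stable")[::-1]
    # stable descending sort then precedence: among equal scores pick the
    # earliest class in the fixed order
    top_value = log_s[order[0]]
    top_idx = min(i for i in range(len(log_s)) if log_s[i] == top_value)
    second_value = max(log_s[i] for i in range(len(log_s)) if i != top_idx)
    ri = float(np.exp(top_value - second_value))
    return Prediction(
        id=protein_id,
        scores={c: float(np.exp(log_s[i])) for i, c in enumerate(CLASS_ORDER)},
        label=CLASS_ORDER[top_idx],
        reliability_index=ri,
        channels_used=used,
    )


def save_model(model: ClassifierModel, path) -> None:
    """Serialise to diffable JSON."""
    payload = {
        "format": "nucleoclass-model",
        "version": 1,
        "priors": {c.name: model.priors[c] for c in CLASS_ORDER},
        "alpha": model.alpha,
        "binning": model.binning.to_dict(),
        "tables": {
            ch: cpt.table.tolist() for ch, cpt in sorted(model.tables.items())
        },
        "training_manifest": {
            pid: cls.name for pid, cls in sorted(model.training_manifest.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path) -> ClassifierModel:
    """Load and re-validate a saved model (invariant violations are load
    errors)."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "nucleoclass-model":
        raise ValueError(f"{path}: not a nucleoclass model file")
    priors = {NucleolarClass[k]: float(v) for k, v in payload["priors"].items()}
    tables = {
        ch: ConditionalProbabilityTable(ch, np.asarray(tab, dtype=float))
        for ch, tab in payload["tables"].items()
    }
    return ClassifierModel(
        priors=priors,
        alpha=float(payload["alpha"]),
        tables=tables,
        binning=BinningConfig.from_dict(payload["binning"]),
        training_manifest={
            pid: NucleolarClass[c]
            for pid, c in payload.get("training_manifest", {}).items()
        },
    )
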