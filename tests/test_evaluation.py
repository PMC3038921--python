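"""Metrics, LOOCV holdout semantics, independent tests, multi-run
averaging, and the reliability sweep."""

import math

import numpy as np
import pytest

from nucleoclass.classifier import Prediction
from nucleoclass.evaluation import (
    ConfusionMatrix,
    class_metrics,
    evaluate_independent,
    fit,
    loocv,
    multirun_evaluate,
    reliability_sweep,
)
from nucleoclass.features import BinningConfig, CohortFeaturizer
from nucleoclass.types import (
    CLASS_ORDER,
    AnnotationBundle,
    LabelledCorpus,
    ProteinRecord,
)

from _oracles import one_vs_rest_metrics

E, NP, NC, NN = CLASS_ORDER


def make_corpus(spec):
    """spec: list of (id, sequence, class)."""
    return LabelledCorpus([(ProteinRecord(i, s), c) for i, s, c in spec])


class TestClassMetrics:
    def test_sensitivity_and_ppv_formulas(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 18  # TP for ENRICHED
        counts[0, 3] = 7   # FN (missed into NON_NUCLEOLAR)
        counts[1, 0] = 2   # FP into ENRICHED
        counts[1, 1] = 10
        report = class_metrics(ConfusionMatrix(counts))
        assert report.sensitivity[E] == pytest.approx(18 / 25)
        assert report.ppv[E] == pytest.approx(0.9)

    def test_diagonal_matrix_is_perfect(self):
        report = class_metrics(ConfusionMatrix(np.diag([5, 4, 3, 8])))
        assert report.accuracy == 1.0
        for cls in CLASS_ORDER:
            assert report.sensitivity[cls] == 1.0
            assert report.ppv[cls] == 1.0

    def test_zero_denominator_is_nan_not_zero(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[3, 3] = 10  # only NON_NUCLEOLAR present
        report = class_metrics(ConfusionMatrix(counts))
        assert math.isnan(report.sensitivity[E])
        assert math.isnan(report.ppv[E])

    def test_matches_one_vs_rest_oracle_on_random_matrices(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            counts = rng.integers(0, 20, size=(4, 4))
            if counts.sum() == 0:
                counts[0, 0] = 1
            report = class_metrics(ConfusionMatrix(counts))
            sens, ppv, acc = one_vs_rest_metrics(counts.tolist())
            for i, cls in enumerate(CLASS_ORDER):
                for got, want in ((report.sensitivity[cls], sens[i]),
                                  (report.ppv[cls], ppv[i])):
                    if math.isnan(want):
                        assert math.isnan(got)
                    else:
                        assert got == pytest.approx(want, abs=1e-12)
            assert report.accuracy == pytest.approx(acc, abs=1e-12)


def separable_fixture():
    """A tiny corpus where the GO channel alone separates all classes.

    Classes are balanced and sequences identical, so every other channel
    is class-uninformative and the GO channel decides."""
    terms = {E: "GO:1", NP: "GO:2", NC: "GO:3", NN: "GO:4"}
    spec, go = [], {}
    for ci, cls in enumerate(CLASS_ORDER):
        for k in range(4):
            pid = f"{cls.name[:2]}{k}"
            spec.append((pid, "ACDEFGHIKLMNPQRSTVWY", cls))
            go[pid] = frozenset({terms[cls]})
    corpus = make_corpus(spec)
    bundle = AnnotationBundle(go_terms=go)
    return corpus, bundle


class TestLoocv:
    def test_separable_corpus_reaches_full_accuracy(self):
        corpus, bundle = separable_fixture()
        predictions, report = loocv(corpus, bundle)
        assert report.accuracy == 1.0
        assert len(predictions) == len(corpus)

    def test_degenerate_corpus_rejected(self):
        corpus = make_corpus([("a", "ACDE", E), ("b", "MKLV", E)])
        with pytest.raises(ValueError, match="2 classes"):
            loocv(corpus, AnnotationBundle())

    def test_predictions_independent_of_corpus_order(self):
        corpus, bundle = separable_fixture()
        rev = LabelledCorpus(list(reversed(corpus.records)))
        p1, _ = loocv(corpus, bundle)
        p2, _ = loocv(rev, bundle)
        by_id_1 = {p.id: (p.label, p.reliability_index) for p in p1}
        by_id_2 = {p.id: (p.label, p.reliability_index) for p in p2}
        assert by_id_1 == by_id_2

    def test_held_out_protein_removed_from_training_npi(self):
        """Featurizing training protein B while A is held out must drop A
        from B's interactor set: B's proximity then comes from C alone."""
        corpus = make_corpus(
            [("A", "ACDE", E), ("B", "MKLV", NP), ("C", "GHIW", NN), ("D", "PQRS", NN)]
        )
        bundle = AnnotationBundle(
            interactions=AnnotationBundle.adjacency_from_edges(
                [("A", "B"), ("B", "C")]
            ),
            localisations={
                "A": frozenset({"nucleolus"}),   # distance 0.0
                "C": frozenset({"cytosol"}),     # distance 3.0
            },
        )
        config = BinningConfig(npi_thresholds=(0.4, 0.8, 1.6, 2.4))
        fz = CohortFeaturizer(corpus.proteins, bundle, config)
        labels = corpus.labels
        rest = {pid: cls for pid, cls in labels.items() if pid != "A"}

        with_a = fz.vectors(labels)["B"]      # NP = mean(0.0, 3.0) = 1.5 -> bin 2
        without_a = fz.vectors(rest, exclude_id="A")["B"]  # NP = 3.0 -> bin 4
        assert with_a.npi == 2
        assert without_a.npi == 4


class TestEvaluateIndependent:
    def test_overlap_with_training_manifest_rejected(self):
        corpus, bundle = separable_fixture()
        model = fit(corpus, bundle)
        with pytest.raises(ValueError, match="overlaps"):
            evaluate_independent(model, corpus, bundle)

    def test_empty_test_set_rejected(self):
        corpus, bundle = separable_fixture()
        model = fit(corpus, bundle)
        with pytest.raises(ValueError, match="empty"):
            evaluate_independent(model, LabelledCorpus([]), bundle)

    def test_separable_test_set_classified_perfectly(self):
        corpus, bundle = separable_fixture()
        # held-out twins: same GO structure, new ids
        spec, go = [], dict(bundle.go_terms)
        for cls, term in ((E, "GO:1"), (NP, "GO:2"), (NC, "GO:3"), (NN, "GO:4")):
            for k in range(2):
                pid = f"test_{cls.name[:2]}{k}"
                spec.append((pid, "ACDEFGHIKLMNPQRSTVWY", cls))
                go[pid] = frozenset({term})
        test = make_corpus(spec)
        test_bundle = AnnotationBundle(go_terms=go)
        model = fit(corpus, bundle)
        _, report = evaluate_independent(model, test, test_bundle)
        assert report.accuracy == 1.0


class TestMultirun:
    @pytest.fixture()
    def small_cohort(self, cohort_factory):
        """A full cohort whose labelled groups are subset per test."""
        return cohort_factory("high", 7)

    def _split(self, cohort):
        records, bundle, corpus = cohort
        nucleolar = corpus.subset(
            [pid for pid, c in corpus.labels.items() if c is not NN]
        )
        pool = [r for r, c in corpus.records if c is NN]
        return nucleolar, pool, bundle

    def test_reproducible_mean_and_sd(self, small_cohort):
        nucleolar, pool, bundle = self._split(small_cohort)
        nucleolar = nucleolar.subset(nucleolar.ids[:18])
        kwargs = dict(
            n_negative=30, n_runs=3, mode="loocv", seeds=[1, 2, 3]
        )
        r1 = multirun_evaluate(nucleolar, pool, bundle, **kwargs)
        r2 = multirun_evaluate(nucleolar, pool, bundle, **kwargs)
        assert r1.accuracy == r2.accuracy
        assert r1.accuracy_sd == r2.accuracy_sd
        assert r1.n_runs == 3

    def test_exhausted_pool_forces_identical_runs(self, small_cohort):
        nucleolar, pool, bundle = self._split(small_cohort)
        nucleolar = nucleolar.subset(nucleolar.ids[:12])
        pool = pool[:20]
        report = multirun_evaluate(
            nucleolar, pool, bundle, n_negative=20, n_runs=3, seeds=[1, 2, 3]
        )
        assert report.accuracy_sd == 0.0

    def test_single_run_has_zero_sd(self, small_cohort):
        nucleolar, pool, bundle = self._split(small_cohort)
        nucleolar = nucleolar.subset(nucleolar.ids[:12])
        report = multirun_evaluate(
            nucleolar, pool, bundle, n_negative=15, n_runs=1, seeds=[4]
        )
        assert report.accuracy_sd == 0.0
        assert report.n_runs == 1


class TestReliabilitySweep:
    def _predictions(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        predictions, truths = [], {}
        for i in range(n):
            truth = CLASS_ORDER[rng.integers(4)]
            correct = rng.random() < 0.7
            label = truth if correct else CLASS_ORDER[rng.integers(4)]
            ri = float(np.exp(rng.uniform(0, 6)))
            predictions.append(
                Prediction(f"p{i}", {c: 1.0 for c in CLASS_ORDER}, label, ri, frozenset())
            )
            truths[f"p{i}"] = truth
        return predictions, truths

    def test_threshold_one_keeps_everything(self):
        predictions, truths = self._predictions()
        sweep = reliability_sweep(predictions, truths, [1.0])
        assert sweep[0][1] == 1.0

    def test_coverage_non_increasing(self):
        predictions, truths = self._predictions()
        sweep = reliability_sweep(predictions, truths)
        coverages = [cov for _, cov, _ in sweep]
        assert all(a >= b for a, b in zip(coverages, coverages[1:]))

    def test_missing_truth_rejected(self):
        predictions, truths = self._predictions()
        del truths["p0"]
        with pytest.raises(ValueError, match="p0"):
            reliability_sweep(predictions, truths)
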