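"""Train the naive Bayes model and classify proteins.

Each protein's per-class score is the class prior multiplied by the
per-bin class proportions of its eight feature channels; the reliability
index (RI) is the ratio of the best score to the runner-up — a large RI
means a clear-cut call.
"""

import tempfile
from pathlib import Path

from nucleoclass import CohortFeaturizer, classify, load_cohort_dir
from nucleoclass.evaluation import fit
from nucleoclass.simulate import default_spec, generate_cohort
from nucleoclass.types import CLASS_ORDER

with tempfile.TemporaryDirectory() as tmp:
    out = generate_cohort(default_spec("high", seed=42), Path(tmp) / "cohort")
    records, bundle, corpus = load_cohort_dir(out)

    model = fit(corpus, bundle)
    fz = CohortFeaturizer(records, bundle, model.binning)
    vectors = fz.vectors(model.training_manifest)

    print("id        true-class                predicted                 RI")
    for pid in ["ENR0001", "NPL0001", "NCY0001", "NON0001"]:
        pred = classify(model, vectors[pid], protein_id=pid)
        truth = corpus.labels[pid].value
        print(f"{pid}  {truth:25s} {pred.label.value:25s} {pred.reliability_index:8.1f}")

# Training proteins scored against a model trained on themselves are
# optimistic; see 03_cross_validation.py for honest accuracy estimates.
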