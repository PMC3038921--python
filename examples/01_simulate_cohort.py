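"""Generate a synthetic study cohort and inspect what it contains.

The generator emits every input the classifier consumes — sequences,
targeting-predictor outputs, GO annotations, tissue expression, an
interaction network, localisation annotations, SILAC ratios, orthology —
with class-conditional structure, so the whole pipeline runs without any
external downloads.
"""

import tempfile
from collections import Counter
from pathlib import Path

from nucleoclass import load_cohort_dir
from nucleoclass.simulate import default_spec, generate_cohort

with tempfile.TemporaryDirectory() as tmp:
    out = generate_cohort(default_spec("high", seed=42), Path(tmp) / "cohort")
    records, bundle, corpus = load_cohort_dir(out)

    print(f"proteins: {len(records)}")
    print("class sizes:", dict(Counter(c.value for c in corpus.labels.values())))
    print(f"expression profiles over {len(bundle.tissues)} tissues:",
          len(bundle.expression))
    n_edges = sum(len(v) for v in bundle.interactions.values()) // 2
    print(f"interaction edges: {n_edges}")
    print(f"SILAC-measured proteins: {len(bundle.silac)}")

# The four class sizes (30/22/24/200) are the study's training-set sizes;
# annotations are deliberately incomplete (some proteins lack expression or
# localisation data) so missing-channel handling is exercised.
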