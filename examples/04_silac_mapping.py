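"""Map dual SILAC abundance ratios onto the four classes and check
agreement with the classifier.

Each SILAC-measured protein carries a nucleolar/cytoplasmic and a
nucleoplasmic/cytoplasmic abundance ratio.  Class regions (rectangles in
log2 ratio space) are calibrated from a small set of proteins with both a
literature label and ratios; proteins outside every region are
"undefined".  Calibration proteins are excluded from agreement scoring.
"""

import tempfile
from pathlib import Path

import numpy as np

from nucleoclass import load_cohort_dir, loocv
from nucleoclass.silac import agreement_report, calibrate_regions, classify_silac
from nucleoclass.simulate import default_spec, generate_cohort
from nucleoclass.types import CLASS_ORDER

with tempfile.TemporaryDirectory() as tmp:
    out = generate_cohort(default_spec("high", seed=42), Path(tmp) / "cohort")
    records, bundle, corpus = load_cohort_dir(out)

    # small calibration overlap: 4 labelled proteins with ratios per class
    calibration, seen = [], {cls: 0 for cls in CLASS_ORDER}
    for pid, cls in corpus.labels.items():
        if pid in bundle.silac and seen[cls] < 4:
            calibration.append((pid, bundle.silac[pid], cls))
            seen[cls] += 1
    regions = calibrate_regions(calibration, margin=0.5)
    for cls, rect in regions.regions.items():
        print(f"{cls.value:25s} log2 nuc/cyto [{rect.x_lo:6.2f},{rect.x_hi:6.2f}] "
              f"log2 nucpl/cyto [{rect.y_lo:6.2f},{rect.y_hi:6.2f}]")

    groups = {pid: classify_silac(r, regions) for pid, r in bundle.silac.items()}
    predictions, _ = loocv(corpus, bundle)
    confusion, disagreements, n_undef = agreement_report(
        predictions, groups, excluded_ids=regions.calibration_ids
    )
    agreement = np.trace(confusion.counts) / confusion.total
    print(f"\nagreement with classifier: {agreement:.3f} on {confusion.total} proteins")
    print(f"undefined-ratio proteins: {n_undef}; disagreements: {len(disagreements)}")

# Disagreements between ratio-based grouping and the classifier flag
# proteins worth a closer look (conditional or cyclic nucleolar residents).
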