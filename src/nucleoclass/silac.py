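"""Mapping dual SILAC abundance ratios onto nucleolar-association classes.

Quantitative spatial proteomics assigns each protein two abundance ratios:
nucleolar/cytoplasmic and nucleoplasmic/cytoplasmic.  In (log2, log2) space
each class occupies an axis-aligned rectangle; proteins outside every
rectangle are UNDEFINED (their ratios are unlike those of the calibration
proteins).  Region boundaries are calibrated from proteins carrying both a
literature class label and SILAC ratios; calibration proteins are flagged
so downstream agreement scoring can exclude them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Sequence, Set, Tuple, Union

import numpy as np
import yaml

from .classifier import Prediction
from .evaluation import ConfusionMatrix
from .types import CLASS_ORDER, NucleolarClass, SilacRatios

__all__ = [
    "UNDEFINED",
    "Rectangle",
    "SilacRegionConfig",
    "classify_silac",
    "calibrate_regions",
    "agreement_report",
]

#: group label for proteins whose ratios fall outside every class region
UNDEFINED = "undefined"


@dataclass(frozen=True)
class Rectangle:
    """Closed axis-aligned rectangle in (log2 nuc/cyto, log2 nucpl/cyto)
    space; infinite bounds allowed."""

    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float

    def __post_init__(self) -> None:
        if self.x_lo > self.x_hi or self.y_lo > self.y_hi:
            raise ValueError(f"degenerate rectangle bounds: {self}")

    def contains(self, x: float, y: float) -> bool:
        return self.x_lo <= x <= self.x_hi and self.y_lo <= y <= self.y_hi

    def intersects(self, other: "Rectangle") -> bool:
        return (
            max(self.x_lo, other.x_lo) <= min(self.x_hi, other.x_hi)
            and max(self.y_lo, other.y_lo) <= min(self.y_hi, other.y_hi)
        )


@dataclass
class SilacRegionConfig:
    """One rectangle per class; rectangles must be pairwise disjoint."""

    regions: Dict[NucleolarClass, Rectangle]
    calibration_ids: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        classes = list(self.regions)
        for i, a in enumerate(classes):
            for b in classes[i + 1 :]:
                if self.regions[a].intersects(self.regions[b]):
                    raise ValueError(
                        f"overlapping SILAC regions: {a.name} and {b.name}"
                    )

    def to_dict(self) -> dict:
        return {
            "regions": {
                cls.name: [r.x_lo, r.x_hi, r.y_lo, r.y_hi]
                for cls, r in self.regions.items()
            },
            "calibration_ids": sorted(self.calibration_ids),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SilacRegionConfig":
        return cls(
            regions={
                NucleolarClass[name]: Rectangle(*bounds)
                for name, bounds in d["regions"].items()
            },
            calibration_ids=frozenset(d.get("calibration_ids", ())),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SilacRegionConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def classify_silac(
    ratios: SilacRatios, regions: SilacRegionConfig
) -> Union[NucleolarClass, str]:
    """Group of the rectangle containing the protein's log2 ratios, or
    UNDEFINED.  Boundary points belong to the rectangle (closed bounds)."""
    x = math.log2(ratios.nuc_cyto)
    y = math.log2(ratios.nucpl_cyto)
    for cls in CLASS_ORDER:
        region = regions.regions.get(cls)
        if region is not None and region.contains(x, y):
            return cls
    return UNDEFINED


def calibrate_regions(
    overlap: Sequence[Tuple[str, SilacRatios, NucleolarClass]],
    margin: float = 0.5,
) -> SilacRegionConfig:
    """Derive class rectangles from labelled calibration points.

    Each class gets the axis-aligned bounding box of its points in log2
    space, expanded by ``margin``; overlapping boxes are shrunk to the
    midline of their overlap along the axis where the overlap is smallest.
    If the shrinking pushes a calibration point out of its class box the
    classes are inseparable by axis-aligned rectangles and calibration
    fails.
    """
    points: Dict[NucleolarClass, List[Tuple[float, float]]] = {}
    ids: Set[str] = set()
    for pid, ratios, cls in overlap:
        points.setdefault(cls, []).append(
            (math.log2(ratios.nuc_cyto), math.log2(ratios.nucpl_cyto))
        )
        ids.add(pid)
    missing = [c.name for c in CLASS_ORDER if c not in points]
    if missing:
        raise ValueError(f"no calibration points for classes: {missing}")

    boxes: Dict[NucleolarClass, List[float]] = {}
    for cls, pts in points.items():
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        boxes[cls] = [
            min(xs) - margin,
            max(xs) + margin,
            min(ys) - margin,
            max(ys) + margin,
        ]

    classes = [c for c in CLASS_ORDER if c in boxes]
    for _ in range(32):  # overlap resolution converges quickly; bound it
        overlapping = None
        for i, a in enumerate(classes):
            for b in classes[i + 1 :]:
                ra, rb = boxes[a], boxes[b]
                ox = min(ra[1], rb[1]) - max(ra[0], rb[0])
                oy = min(ra[3], rb[3]) - max(ra[2], rb[2])
                if ox >= 0 and oy >= 0:
                    overlapping = (a, b, ox, oy)
                    break
            if overlapping:
                break
        if overlapping is None:
            break
        a, b, ox, oy = overlapping
        ra, rb = boxes[a], boxes[b]
        if ox <= oy:  # shrink along x
            mid = (max(ra[0], rb[0]) + min(ra[1], rb[1])) / 2.0
            lower, upper = (ra, rb) if (ra[0] + ra[1]) <= (rb[0] + rb[1]) else (rb, ra)
            lower[1] = min(lower[1], mid)
            upper[0] = max(upper[0], float(np.nextafter(mid, np.inf)))
        else:  # shrink along y
            mid = (max(ra[2], rb[2]) + min(ra[3], rb[3])) / 2.0
            lower, upper = (ra, rb) if (ra[2] + ra[3]) <= (rb[2] + rb[3]) else (rb, ra)
            lower[3] = min(lower[3], mid)
            upper[2] = max(upper[2], float(np.nextafter(mid, np.inf)))
    else:
        raise ValueError("SILAC region overlap resolution did not converge")

    rects = {cls: Rectangle(*boxes[cls]) for cls in classes}
    for cls, pts in points.items():
        for x, y in pts:
            if not rects[cls].contains(x, y):
                raise ValueError(
                    f"calibration classes are not separable by axis-aligned "
                    f"rectangles: a {cls.name} point at ({x:.3g}, {y:.3g}) "
                    f"falls outside its calibrated region"
                )
    return SilacRegionConfig(regions=rects, calibration_ids=frozenset(ids))


def agreement_report(
    predictions: Sequence[Prediction],
    silac_groups: Mapping[str, Union[NucleolarClass, str]],
    excluded_ids: Set[str] = frozenset(),
) -> Tuple[ConfusionMatrix, List[Tuple[str, Union[NucleolarClass, str], NucleolarClass]], int]:
    """Compare classifier predictions with SILAC-derived groups.

    Proteins in ``excluded_ids`` (trained on, or used for threshold
    calibration) and UNDEFINED-group proteins are omitted from the matrix;
    the UNDEFINED count is returned as a side tally.  Rows of the matrix
    are SILAC groups (taken as truth), columns the predicted classes.
    The disagreement list carries (id, silac group, predicted class) for
    every retained protein where the two differ.
    """
    pairs = []
    disagreements = []
    n_undefined = 0
    for pred in predictions:
        if pred.id in excluded_ids or pred.id not in silac_groups:
            continue
        group = silac_groups[pred.id]
        if group == UNDEFINED:
            n_undefined += 1
            continue
        pairs.append((group, pred.label))
        if group is not pred.label:
            disagreements.append((pred.id, group, pred.label))
    return ConfusionMatrix.from_pairs(pairs), disagreements, n_undefined
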