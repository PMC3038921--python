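"""Core domain types for nucleolar-association classification.

The classifier assigns every human protein to one of four dynamic-localisation
classes: nucleolar-enriched (predominantly nucleolar in all conditions),
nucleolar-nucleoplasmic (shuttles between nucleolus and other nuclear
regions), nucleolar-cytoplasmic (shuttles between nucleolus and cytoplasm),
and non-nucleolar (never localises to the nucleolus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

__all__ = [
    "NucleolarClass",
    "CLASS_ORDER",
    "NUCLEOLAR_CLASSES",
    "ProteinRecord",
    "LabelledCorpus",
    "TargetingRecord",
    "SilacRatios",
    "LocalisationDistanceMap",
    "AnnotationBundle",
]

#: residues accepted in a protein sequence: the 20 standard amino acids plus
#: ambiguous / non-standard letters that occur in real sequence databases.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_RESIDUES = STANDARD_RESIDUES | frozenset("XUB")


class NucleolarClass(Enum):
    """The four nucleolar-association classes.

    Declaration order is the fixed precedence order used for deterministic
    tie-breaking (ENRICHED wins ties over NUCLEOPLASMIC, and so on).
    """

    ENRICHED = "nucleolar-enriched"
    NUCLEOPLASMIC = "nucleolar-nucleoplasmic"
    CYTOPLASMIC = "nucleolar-cytoplasmic"
    NON_NUCLEOLAR = "non-nucleolar"

    @classmethod
    def from_label(cls, text: str) -> "NucleolarClass":
        """Parse a class label from either the enum name or the file label."""
        t = text.strip()
        for member in cls:
            if t == member.name or t.lower() == member.value:
                return member
        raise ValueError(f"unknown nucleolar class label: {text!r}")

    def __lt__(self, other: "NucleolarClass") -> bool:
        order = list(type(self))
        return order.index(self) < order.index(other)


CLASS_ORDER: Tuple[NucleolarClass, ...] = tuple(NucleolarClass)
#: the three classes that associate with the nucleolus (GOscore classes)
NUCLEOLAR_CLASSES: Tuple[NucleolarClass, ...] = CLASS_ORDER[:3]
CLASS_INDEX: Dict[NucleolarClass, int] = {c: i for i, c in enumerate(CLASS_ORDER)}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein: opaque identifier plus upper-case amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id}: sequence must be non-empty")
        seq = self.sequence.upper()
        bad = set(seq) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.id}: invalid residues {sorted(bad)} in sequence"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabelledCorpus:
    """A set of proteins with class labels (training or test material)."""

    records: List[Tuple[ProteinRecord, NucleolarClass]]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for rec, label in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate protein id in corpus: {rec.id}")
            seen.add(rec.id)
            if not isinstance(label, NucleolarClass):
                raise ValueError(f"invalid class label for {rec.id}: {label!r}")

    @property
    def ids(self) -> List[str]:
        return [rec.id for rec, _ in self.records]

    @property
    def labels(self) -> Dict[str, NucleolarClass]:
        return {rec.id: label for rec, label in self.records}

    @property
    def proteins(self) -> List[ProteinRecord]:
        return [rec for rec, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, ids, provenance: Optional[str] = None) -> "LabelledCorpus":
        keep = set(ids)
        return LabelledCorpus(
            [(r, c) for r, c in self.records if r.id in keep],
            provenance if provenance is not None else self.provenance,
        )

    def merge(self, other: "LabelledCorpus", provenance: str = "") -> "LabelledCorpus":
        return LabelledCorpus(self.records + other.records, provenance)


@dataclass(frozen=True)
class TargetingRecord:
    """Upstream targeting-predictor outputs for one protein.

    ``signal_peptide`` and ``tmd_count`` come from a signal-peptide/TMD
    predictor (Phobius), ``mito_peptide`` from a mitochondrial-transit
    predictor (TargetP), and ``nols_max`` is the maximum nucleolar
    localisation signal score from NoD (``None`` when the predictor reported
    nothing).
    """

    signal_peptide: bool = False
    tmd_count: int = 0
    mito_peptide: bool = False
    nols_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tmd_count < 0:
            raise ValueError("tmd_count must be >= 0")
        if self.nols_max is not None and not 0.0 <= self.nols_max <= 1.0:
            raise ValueError(f"nols_max must be in [0,1], got {self.nols_max}")


@dataclass(frozen=True)
class SilacRatios:
    """Dual SILAC spatial abundance ratios for one protein."""

    nuc_cyto: float
    nucpl_cyto: float

    def __post_init__(self) -> None:
        if self.nuc_cyto <= 0 or self.nucpl_cyto <= 0:
            raise ValueError("SILAC ratios must be strictly positive")


# default compartment vocabulary: each annotation label maps to one of four
# cellular region groups, each of which carries a nucleolar proximity
# distance.  The distance expresses how far an annotated region is from the
# nucleolus (0 = the nucleolus itself).
DEFAULT_GROUP_DISTANCES: Dict[str, float] = {
    "nucleolus": 0.0,
    "nuclear_other": 1.2,
    "cytoplasmic": 3.0,
    "nuclear_generic": 0.8,
}

DEFAULT_VOCABULARY: Dict[str, str] = {
    "nucleolus": "nucleolus",
    "nucleoplasm": "nuclear_other",
    "nuclear_speckles": "nuclear_other",
    "speckles": "nuclear_other",
    "nuclear_pore": "nuclear_other",
    "nuclear_envelope": "nuclear_other",
    "cytosol": "cytoplasmic",
    "cytoplasm": "cytoplasmic",
    "mitochondrion": "cytoplasmic",
    "golgi": "cytoplasmic",
    "endoplasmic_reticulum": "cytoplasmic",
    "lysosome": "cytoplasmic",
    "peroxisome": "cytoplasmic",
    "endosome": "cytoplasmic",
    "plasma_membrane": "cytoplasmic",
    "extracellular": "cytoplasmic",
    "secreted": "cytoplasmic",
    "nuclear": "nuclear_generic",
}


@dataclass
class LocalisationDistanceMap:
    """Maps compartment annotation labels to nucleolar proximity distances.

    Labels are first resolved to one of four region groups (nucleolus /
    other nuclear sub-compartments / cytoplasmic-or-beyond / bare "nuclear"),
    which carry distances 0.0 / 1.2 / 3.0 / 0.8 by default.  Both tables are
    editable, so site-specific vocabularies can be plugged in.
    """

    group_distances: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_DISTANCES)
    )
    vocabulary: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_VOCABULARY)
    )

    def __post_init__(self) -> None:
        for group, d in self.group_distances.items():
            if d < 0:
                raise ValueError(f"distance for group {group!r} must be >= 0")
        for label, group in self.vocabulary.items():
            if group not in self.group_distances:
                raise ValueError(
                    f"label {label!r} maps to unknown group {group!r}"
                )

    def knows(self, label: str) -> bool:
        return label.strip().lower() in self.vocabulary

    def distance(self, label: str) -> float:
        key = label.strip().lower()
        if key not in self.vocabulary:
            raise KeyError(f"unknown compartment label: {label!r}")
        return self.group_distances[self.vocabulary[key]]


@dataclass
class AnnotationBundle:
    """All per-protein annotations the feature channels consume.

    Every field is keyed by protein id; a protein absent from a table simply
    has that annotation missing.  ``expression`` vectors share the single
    ``tissues`` ordering.  ``interactions`` is stored as an undirected
    adjacency map.
    """

    targeting: Dict[str, TargetingRecord] = field(default_factory=dict)
    go_terms: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    expression: Dict[str, np.ndarray] = field(default_factory=dict)
    tissues: Tuple[str, ...] = ()
    interactions: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    localisations: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    silac: Dict[str, SilacRatios] = field(default_factory=dict)
    orthology: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    distance_map: LocalisationDistanceMap = field(
        default_factory=LocalisationDistanceMap
    )

    def __post_init__(self) -> None:
        n = len(self.tissues)
        for pid, vec in self.expression.items():
            if n and len(vec) != n:
                raise ValueError(
                    f"expression vector for {pid} has length {len(vec)}, "
                    f"expected {n} tissues"
                )
        for pid, labels in self.localisations.items():
            for lab in labels:
                if not self.distance_map.knows(lab):
                    raise ValueError(
                        f"protein {pid}: unknown compartment label {lab!r}"
                    )

    def neighbors(self, pid: str) -> FrozenSet[str]:
        return self.interactions.get(pid, frozenset())

    @staticmethod
    def adjacency_from_edges(edges) -> Dict[str, FrozenSet[str]]:
        """Build an undirected adjacency map from (a, b) edge pairs."""
        adj: Dict[str, set] = {}
        for a, b in edges:
            if a == b:
                continue  # self-loops carry no proximity information
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return {k: frozenset(v) for k, v in adj.items()}
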