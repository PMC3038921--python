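"""The five feature channels and their discretization.

Each protein is summarised by eight discrete channels feeding the
classifier:

* ``aa_S``/``aa_L``/``aa_I``/``aa_K`` — binned frequencies of serine,
  leucine, isoleucine and lysine (the residues whose frequencies differ
  between nucleolar-association classes);
* ``targeting`` — a 9-state combination of targeting-motif scores
  (signal peptide / TMD, mitochondrial transit peptide, nucleolar
  localisation signal);
* ``coexpr`` — binned mean Pearson correlation of the protein's tissue
  expression profile with the nucleolar-cytoplasmic training group;
* ``go`` — which nucleolar class (if any) dominates the protein's GO-term
  enrichment ratio (the GOscore g_c), 4 states;
* ``npi`` — binned nucleolar proximity of interactors: the mean, over
  interaction partners, of the mean nucleolar distance of each partner's
  annotated compartments.

A channel whose inputs are unavailable is MISSING (``None``) and is simply
skipped at training and scoring time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import yaml

from .types import (
    NUCLEOLAR_CLASSES,
    AnnotationBundle,
    LocalisationDistanceMap,
    NucleolarClass,
    ProteinRecord,
    TargetingRecord,
)

logger = logging.getLogger("nucleoclass")

__all__ = [
    "MISSING",
    "TargetingScores",
    "GoScoreVector",
    "BinningConfig",
    "FeatureVector",
    "aa_frequencies",
    "discretize",
    "equal_frequency_thresholds",
    "targeting_scores",
    "targeting_bin",
    "coexpression_score",
    "go_scores",
    "go_bin",
    "interactor_np",
    "npi_score",
    "extract_features",
    "CohortFeaturizer",
]

MISSING = None

TRACKED_RESIDUES = ("S", "L", "I", "K")

#: feature channel names in canonical order
CHANNELS = ("aa_S", "aa_L", "aa_I", "aa_K", "targeting", "coexpr", "go", "npi")


@dataclass(frozen=True)
class TargetingScores:
    """Targeting-motif scores derived from upstream predictor outputs.

    s_M: mitochondrial transit peptide predicted (0/1).
    s_S: signal peptide or >= 1 transmembrane domain predicted (0/1).
    s_N: nucleolar localisation signal strength (0/1/2).
    s_C: combined cytoplasmic-export score (0/1/2), fully determined by
         s_S and s_M.
    """

    s_M: int
    s_S: int
    s_N: int
    s_C: int

    def __post_init__(self) -> None:
        if self.s_M not in (0, 1) or self.s_S not in (0, 1):
            raise ValueError("s_M and s_S must be 0/1")
        if self.s_N not in (0, 1, 2) or self.s_C not in (0, 1, 2):
            raise ValueError("s_N and s_C must be 0/1/2")
        expected = 2 if self.s_S == 1 else (1 if self.s_M == 1 else 0)
        if self.s_C != expected:
            raise ValueError(
                f"s_C={self.s_C} inconsistent with s_S={self.s_S}, s_M={self.s_M}"
            )


@dataclass(frozen=True)
class GoScoreVector:
    """Per-class GOscores g_c, plus the number of usable annotating terms.

    ``g`` is ``None`` when the protein has no usable terms (n_terms = 0);
    the score is then undefined and the GO channel falls in the
    below-threshold bin.
    """

    g: Optional[Dict[NucleolarClass, float]]
    n_terms: int


# Default bin thresholds.  The exact empirical thresholds behind the
# published bins are not available, so the packaged defaults were frozen
# once by equal-frequency binning of the synthetic reference cohort
# (preset "high", seed 42); override any of them via BinningConfig.
DEFAULT_AA_THRESHOLDS: Dict[str, Tuple[float, ...]] = {
    "S": (0.0667870, 0.0774487, 0.0861423, 0.0984743),
    "L": (0.0747126, 0.0914634, 0.1005291, 0.1111111),
    "I": (0.0322581, 0.0420650, 0.0491368, 0.0568720),
    "K": (0.0500577, 0.0579251, 0.0684094),
}
DEFAULT_COEXPR_THRESHOLDS: Tuple[float, ...] = (-0.0304151, 0.0228660, 0.0742543)
DEFAULT_NPI_THRESHOLDS: Tuple[float, ...] = (0.4, 0.8, 1.6, 2.4)


def _validate_increasing(name: str, thresholds: Sequence[float]) -> None:
    arr = list(thresholds)
    if any(b <= a for a, b in zip(arr, arr[1:])):
        raise ValueError(f"{name}: thresholds must be strictly increasing: {arr}")


@dataclass
class BinningConfig:
    """Discretization thresholds for all continuous channels.

    Bins are half-open intervals ``[t_i, t_{i+1})``; values at or above the
    last threshold fall in the last bin.  ``n`` thresholds give ``n + 1``
    bins.  GO uses a single score threshold (default 0.003) below which a
    protein is considered unannotated with respect to the nucleolar classes.
    """

    aa_thresholds: Dict[str, Tuple[float, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_AA_THRESHOLDS.items()}
    )
    coexpr_thresholds: Tuple[float, ...] = DEFAULT_COEXPR_THRESHOLDS
    npi_thresholds: Tuple[float, ...] = DEFAULT_NPI_THRESHOLDS
    go_threshold: float = 0.003

    def __post_init__(self) -> None:
        missing = set(TRACKED_RESIDUES) - set(self.aa_thresholds)
        if missing:
            raise ValueError(f"aa_thresholds missing residues: {sorted(missing)}")
        for aa, thr in self.aa_thresholds.items():
            _validate_increasing(f"aa_thresholds[{aa}]", thr)
        _validate_increasing("coexpr_thresholds", self.coexpr_thresholds)
        _validate_increasing("npi_thresholds", self.npi_thresholds)
        if self.go_threshold <= 0:
            raise ValueError("go_threshold must be positive")

    def n_bins(self) -> Dict[str, int]:
        """Bin count per channel (targeting is the fixed 3x3 grid; GO the
        fixed 4 states)."""
        out = {f"aa_{aa}": len(self.aa_thresholds[aa]) + 1 for aa in TRACKED_RESIDUES}
        out["targeting"] = 9
        out["coexpr"] = len(self.coexpr_thresholds) + 1
        out["go"] = 4
        out["npi"] = len(self.npi_thresholds) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "aa_thresholds": {k: list(v) for k, v in self.aa_thresholds.items()},
            "coexpr_thresholds": list(self.coexpr_thresholds),
            "npi_thresholds": list(self.npi_thresholds),
            "go_threshold": self.go_threshold,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BinningConfig":
        return cls(
            aa_thresholds={k: tuple(v) for k, v in d["aa_thresholds"].items()},
            coexpr_thresholds=tuple(d["coexpr_thresholds"]),
            npi_thresholds=tuple(d["npi_thresholds"]),
            go_threshold=float(d["go_threshold"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "BinningConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class FeatureVector:
    """Per-channel bin assignments for one protein.

    Sequence-derived channels (the four amino-acid bins and the targeting
    bin) are always present; ``coexpr`` and ``npi`` may be MISSING when the
    protein lacks an expression profile or localisation-annotated
    interactors.  The GO channel is never MISSING: the no-usable-terms case
    maps to the below-threshold bin (3).
    """

    aa_S: int
    aa_L: int
    aa_I: int
    aa_K: int
    targeting: int
    coexpr: Optional[int]
    go: int
    npi: Optional[int]

    def __post_init__(self) -> None:
        if not 0 <= self.targeting <= 8:
            raise ValueError(f"targeting bin out of range: {self.targeting}")

    def channels(self) -> Dict[str, Optional[int]]:
        return {name: getattr(self, name) for name in CHANNELS}


def aa_frequencies(sequence: str) -> Dict[str, float]:
    """Frequencies of the four tracked residues (count / sequence length)."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    n = len(seq)
    return {aa: seq.count(aa) / n for aa in TRACKED_RESIDUES}


def discretize(value: float, thresholds: Sequence[float]) -> int:
    """Map a value to a bin index against ordered thresholds.

    Bins are half-open ``[t_i, t_{i+1})``; ties at a threshold resolve
    upward, and values >= the last threshold land in the last bin.
    """
    _validate_increasing("thresholds", thresholds)
    return int(np.searchsorted(np.asarray(thresholds, dtype=float), value, side="right"))


def equal_frequency_thresholds(values: Sequence[float], n_bins: int) -> List[float]:
    """Quantile thresholds giving ~equal-occupancy bins on ``values``.

    Thresholds sit at the k/n_bins quantiles, so on the calibration data
    itself each bin holds within ~20% of |values|/n_bins members.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    arr = np.asarray(values, dtype=float)
    if len(np.unique(arr)) < n_bins:
        raise ValueError(
            f"need at least {n_bins} distinct values, got {len(np.unique(arr))}"
        )
    qs = [k / n_bins for k in range(1, n_bins)]
    thresholds = np.quantile(arr, qs).tolist()
    _validate_increasing("equal-frequency thresholds", thresholds)
    return thresholds


def targeting_scores(
    signal_peptide: bool,
    tmd_count: int,
    mito_peptide: bool,
    nols_max: Optional[float],
) -> TargetingScores:
    """Combine upstream targeting-predictor outputs into the four scores."""
    if tmd_count < 0:
        raise ValueError("tmd_count must be >= 0")
    if nols_max is not None and not 0.0 <= nols_max <= 1.0:
        raise ValueError(f"nols_max must be in [0,1], got {nols_max}")
    s_S = 1 if (signal_peptide or tmd_count >= 1) else 0
    s_M = 1 if mito_peptide else 0
    if nols_max is None or nols_max < 0.8:
        s_N = 0
    elif nols_max < 0.9:
        s_N = 1
    else:
        s_N = 2
    s_C = 2 if s_S == 1 else (1 if s_M == 1 else 0)
    return TargetingScores(s_M=s_M, s_S=s_S, s_N=s_N, s_C=s_C)


def targeting_bin(scores: TargetingScores) -> int:
    """Bijection from the 3x3 (s_C, s_N) grid onto bins 0..8."""
    return 3 * scores.s_C + scores.s_N


def coexpression_score(
    query_profile: np.ndarray,
    reference_profiles: Sequence[np.ndarray],
) -> Optional[float]:
    """Mean Pearson correlation between a query expression profile and a
    reference group; ``None`` when undefined (flat query, no usable refs)."""
    q = np.asarray(query_profile, dtype=float)
    if len(reference_profiles) == 0:
        return None
    if q.size < 3:
        raise ValueError("profiles must have length >= 3")
    if q.std() == 0:
        return None
    rs = []
    for ref in reference_profiles:
        r = np.asarray(ref, dtype=float)
        if r.size != q.size:
            raise ValueError(
                f"profile length mismatch: {r.size} vs {q.size}"
            )
        if r.std() == 0:
            continue  # flat reference carries no correlation signal
        rs.append(float(np.corrcoef(q, r)[0, 1]))
    if not rs:
        return None
    return float(np.mean(rs))


def go_scores(
    terms: Iterable[str],
    class_term_counts: Mapping[NucleolarClass, Mapping[str, int]],
    proteome_term_counts: Mapping[str, int],
) -> GoScoreVector:
    """GOscore g_c = mean over the protein's terms of n_ct / n_t.

    n_ct is the number of class-c proteins annotated with term t and n_t
    the number of proteome proteins annotated with t.  Terms absent from
    the proteome table are dropped (with a log warning).
    """
    usable = []
    for t in set(terms):
        if proteome_term_counts.get(t, 0) >= 1:
            usable.append(t)
        else:
            logger.warning("GO term %s absent from proteome counts; dropped", t)
    if not usable:
        return GoScoreVector(g=None, n_terms=0)
    g = {}
    for cls, counts in class_term_counts.items():
        g[cls] = sum(counts.get(t, 0) / proteome_term_counts[t] for t in usable) / len(
            usable
        )
    return GoScoreVector(g=g, n_terms=len(usable))


def go_bin(scores: GoScoreVector, go_threshold: float = 0.003) -> int:
    """4-state GO channel: the index of the dominant nucleolar class, or 3
    when the score is undefined or all GOscores fall below the threshold."""
    if scores.g is None:
        return 3
    values = [scores.g.get(c, 0.0) for c in NUCLEOLAR_CLASSES]
    best = max(values)
    if best < go_threshold:
        return 3
    return values.index(best)  # first max = class-precedence tie-break


def interactor_np(
    localisations: Iterable[str],
    distances: Optional[LocalisationDistanceMap] = None,
) -> float:
    """Nucleolar proximity of one interactor: mean distance over its
    annotated compartments."""
    dmap = distances or LocalisationDistanceMap()
    labels = list(localisations)
    if not labels:
        raise ValueError("interactor has no localisation annotations")
    return float(np.mean([dmap.distance(lab) for lab in labels]))


def npi_score(
    protein_id: str,
    interactions: Mapping[str, FrozenSet[str]],
    localisations: Mapping[str, Iterable[str]],
    excluded_ids: Set[str] = frozenset(),
    distances: Optional[LocalisationDistanceMap] = None,
) -> Optional[float]:
    """Nucleolar proximity of interactors: mean NP over the protein's
    partners; ``None`` when no partner has localisation annotations."""
    partners = set(interactions.get(protein_id, frozenset()))
    partners.discard(protein_id)
    partners -= set(excluded_ids)
    usable = [p for p in partners if localisations.get(p)]
    if not usable:
        return None
    return float(
        np.mean([interactor_np(localisations[p], distances) for p in sorted(usable)])
    )


def extract_features(
    protein: ProteinRecord,
    bundle: AnnotationBundle,
    config: BinningConfig,
    class_term_counts: Mapping[NucleolarClass, Mapping[str, int]],
    proteome_term_counts: Mapping[str, int],
    reference_profiles: Sequence[np.ndarray],
    excluded_ids: Set[str] = frozenset(),
) -> FeatureVector:
    """Compose all channel computations into one FeatureVector."""
    freqs = aa_frequencies(protein.sequence)
    aa_bins = {
        aa: discretize(freqs[aa], config.aa_thresholds[aa]) for aa in TRACKED_RESIDUES
    }
    trec = bundle.targeting.get(protein.id, TargetingRecord())
    tbin = targeting_bin(
        targeting_scores(
            trec.signal_peptide, trec.tmd_count, trec.mito_peptide, trec.nols_max
        )
    )
    coexpr_bin: Optional[int] = MISSING
    if protein.id in bundle.expression:
        score = coexpression_score(bundle.expression[protein.id], reference_profiles)
        if score is not None:
            coexpr_bin = discretize(score, config.coexpr_thresholds)
    gvec = go_scores(
        bundle.go_terms.get(protein.id, frozenset()),
        class_term_counts,
        proteome_term_counts,
    )
    gbin = go_bin(gvec, config.go_threshold)
    npi = npi_score(
        protein.id,
        bundle.interactions,
        bundle.localisations,
        excluded_ids,
        bundle.distance_map,
    )
    nbin = discretize(npi, config.npi_thresholds) if npi is not None else MISSING
    return FeatureVector(
        aa_S=aa_bins["S"],
        aa_L=aa_bins["L"],
        aa_I=aa_bins["I"],
        aa_K=aa_bins["K"],
        targeting=tbin,
        coexpr=coexpr_bin,
        go=gbin,
        npi=nbin,
    )


class CohortFeaturizer:
    """Featurizes a cohort efficiently, with per-protein holdout support.

    Sequence-derived channels and the pairwise expression-correlation matrix
    are precomputed once.  ``vectors`` then produces feature vectors for any
    target set under a given training manifest, excluding a held-out protein
    (and always the target itself) from the GO class counts, the
    co-expression reference group, and every interactor set — so a protein
    never contributes evidence about itself.
    """

    def __init__(
        self,
        records: Sequence[ProteinRecord],
        bundle: AnnotationBundle,
        config: Optional[BinningConfig] = None,
    ) -> None:
        self.records = list(records)
        self.by_id = {r.id: r for r in self.records}
        self.bundle = bundle
        self.config = config or BinningConfig()

        # static sequence channels
        self._aa_bins: Dict[str, Dict[str, int]] = {}
        self._targeting_bin: Dict[str, int] = {}
        for rec in self.records:
            freqs = aa_frequencies(rec.sequence)
            self._aa_bins[rec.id] = {
                aa: discretize(freqs[aa], self.config.aa_thresholds[aa])
                for aa in TRACKED_RESIDUES
            }
            trec = bundle.targeting.get(rec.id, TargetingRecord())
            self._targeting_bin[rec.id] = targeting_bin(
                targeting_scores(
                    trec.signal_peptide,
                    trec.tmd_count,
                    trec.mito_peptide,
                    trec.nols_max,
                )
            )

        # expression correlation matrix over every protein in the bundle
        # with a non-flat profile (reference groups may lie outside the
        # featurized record set, e.g. training proteins during an
        # independent test)
        expressed = sorted(
            pid
            for pid in bundle.expression
            if np.asarray(bundle.expression[pid]).std() > 0
        )
        self._expr_row = {pid: i for i, pid in enumerate(expressed)}
        if expressed:
            X = np.vstack([bundle.expression[pid] for pid in expressed])
            self._corr = np.corrcoef(X)
        else:
            self._corr = np.zeros((0, 0))

        # proteome-wide GO term counts (distinct proteins per term)
        self.proteome_term_counts: Dict[str, int] = {}
        for pid, terms in bundle.go_terms.items():
            for t in terms:
                self.proteome_term_counts[t] = self.proteome_term_counts.get(t, 0) + 1

        # per-interactor nucleolar proximity cache
        self._np_cache: Dict[str, float] = {}

    def _np(self, pid: str) -> Optional[float]:
        if pid not in self._np_cache:
            labels = self.bundle.localisations.get(pid)
            if not labels:
                return None
            self._np_cache[pid] = interactor_np(labels, self.bundle.distance_map)
        return self._np_cache[pid]

    def _class_term_counts(
        self, train_labels: Mapping[str, NucleolarClass]
    ) -> Dict[NucleolarClass, Dict[str, int]]:
        counts: Dict[NucleolarClass, Dict[str, int]] = {
            c: {} for c in NUCLEOLAR_CLASSES
        }
        for pid, cls in train_labels.items():
            if cls not in counts:
                continue
            for t in self.bundle.go_terms.get(pid, frozenset()):
                counts[cls][t] = counts[cls].get(t, 0) + 1
        return counts

    def _coexpr(
        self, pid: str, ref_ids: Sequence[str], holdout: Set[str]
    ) -> Optional[float]:
        if pid not in self._expr_row:
            return None
        rows = [
            self._expr_row[r]
            for r in ref_ids
            if r in self._expr_row and r != pid and r not in holdout
        ]
        if not rows:
            return None
        return float(self._corr[self._expr_row[pid], rows].mean())

    def _go(
        self,
        pid: str,
        base_counts: Mapping[NucleolarClass, Mapping[str, int]],
        train_labels: Mapping[str, NucleolarClass],
        holdout: Set[str],
    ) -> GoScoreVector:
        terms = [
            t
            for t in self.bundle.go_terms.get(pid, frozenset())
            if self.proteome_term_counts.get(t, 0) >= 1
        ]
        if not terms:
            return GoScoreVector(g=None, n_terms=0)
        # remove held-out proteins' contributions from the class counts
        holdout_terms = {
            h: (train_labels[h], self.bundle.go_terms.get(h, frozenset()))
            for h in holdout
            if h in train_labels
        }
        g = {}
        for cls in NUCLEOLAR_CLASSES:
            total = 0.0
            for t in terms:
                n_ct = base_counts[cls].get(t, 0)
                for h, (hcls, hterms) in holdout_terms.items():
                    if hcls is cls and t in hterms:
                        n_ct -= 1
                total += n_ct / self.proteome_term_counts[t]
            g[cls] = total / len(terms)
        return GoScoreVector(g=g, n_terms=len(terms))

    def vectors(
        self,
        train_labels: Mapping[str, NucleolarClass],
        exclude_id: Optional[str] = None,
        targets: Optional[Sequence[str]] = None,
    ) -> Dict[str, FeatureVector]:
        """Feature vectors for ``targets`` (default: all cohort proteins).

        ``exclude_id`` names a held-out protein removed from every evidence
        source; each target protein is additionally held out of its own
        evidence.
        """
        target_ids = list(targets) if targets is not None else [
            r.id for r in self.records
        ]
        base_counts = self._class_term_counts(train_labels)
        ref_ids = sorted(
            pid
            for pid, cls in train_labels.items()
            if cls is NucleolarClass.CYTOPLASMIC and pid != exclude_id
        )
        out: Dict[str, FeatureVector] = {}
        for pid in target_ids:
            holdout = {pid}
            if exclude_id is not None:
                holdout.add(exclude_id)
            coexpr = self._coexpr(pid, ref_ids, holdout)
            coexpr_bin = (
                discretize(coexpr, self.config.coexpr_thresholds)
                if coexpr is not None
                else MISSING
            )
            gbin = go_bin(
                self._go(pid, base_counts, train_labels, holdout),
                self.config.go_threshold,
            )
            partners = set(self.bundle.neighbors(pid)) - holdout
            nps = [
                self._np(q) for q in sorted(partners) if self._np(q) is not None
            ]
            nbin = (
                discretize(float(np.mean(nps)), self.config.npi_thresholds)
                if nps
                else MISSING
            )
            aa = self._aa_bins[pid]
            out[pid] = FeatureVector(
                aa_S=aa["S"],
                aa_L=aa["L"],
                aa_I=aa["I"],
                aa_K=aa["K"],
                targeting=self._targeting_bin[pid],
                coexpr=coexpr_bin,
                go=gbin,
                npi=nbin,
            )
        return out
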