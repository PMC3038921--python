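"""Synthetic cohort generation with class-conditional structure.

Generates everything a cohort directory needs — sequences, targeting
predictor outputs, GO annotations, tissue expression, an interaction
network, localisation annotations, SILAC ratios, orthology and labels — so
the full pipeline can run without external downloads.  Class-conditional
contrasts (amino-acid composition biases, targeting-motif rates, GO term
pools, expression templates, network assortativity, compartment
annotations, SILAC ratio clusters) mirror the signals the real feature
channels exploit; a ``separation`` preset scales every between-class
contrast so both easy and hard recovery regimes are available.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .types import CLASS_ORDER, DEFAULT_VOCABULARY, NucleolarClass

__all__ = ["CohortSpec", "default_spec", "generate_cohort", "SEPARATION_PRESETS"]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# baseline amino-acid composition (roughly vertebrate-like; sums to 1)
BASE_COMPOSITION = {
    "A": 0.070, "C": 0.020, "D": 0.050, "E": 0.068, "F": 0.039,
    "G": 0.066, "H": 0.026, "I": 0.047, "K": 0.058, "L": 0.099,
    "M": 0.022, "N": 0.036, "P": 0.061, "Q": 0.047, "R": 0.055,
    "S": 0.081, "T": 0.053, "V": 0.065, "W": 0.012, "Y": 0.025,
}

# full-strength composition contrasts: the nucleolar-enriched class is
# lysine/serine-rich, the nucleoplasmic class serine-rich, the
# nucleolar-cytoplasmic class leucine/isoleucine-rich
COMPOSITION_DELTAS = {
    NucleolarClass.ENRICHED: {"K": 0.070, "S": 0.020, "L": -0.040, "I": -0.020},
    NucleolarClass.NUCLEOPLASMIC: {"S": 0.080, "K": 0.010, "L": -0.035, "I": -0.025},
    NucleolarClass.CYTOPLASMIC: {"I": 0.050, "L": 0.040, "S": -0.030, "K": -0.020},
    NucleolarClass.NON_NUCLEOLAR: {},
}

ORGANISMS = (
    "pan_troglodytes",
    "mus_musculus",
    "rattus_norvegicus",
    "danio_rerio",
    "drosophila_melanogaster",
    "caenorhabditis_elegans",
    "saccharomyces_cerevisiae",
    "giardia_lamblia",
)

# per-class orthologue probabilities: nucleolar groups conserved deep into
# eukaryotes, the non-nucleolar group decaying fast with distance
ORTHOLOGY_PROBS = {
    NucleolarClass.ENRICHED: (0.95, 0.92, 0.90, 0.78, 0.72, 0.65, 0.60, 0.35),
    NucleolarClass.NUCLEOPLASMIC: (0.90, 0.85, 0.81, 0.62, 0.55, 0.45, 0.32, 0.20),
    NucleolarClass.CYTOPLASMIC: (0.93, 0.90, 0.88, 0.72, 0.69, 0.62, 0.55, 0.42),
    NucleolarClass.NON_NUCLEOLAR: (0.82, 0.78, 0.75, 0.55, 0.30, 0.25, 0.15, 0.08),
}

LOC_DISTRIBUTIONS = {
    NucleolarClass.ENRICHED: {"nucleolus": 0.75, "nuclear": 0.15, "nucleoplasm": 0.10},
    NucleolarClass.NUCLEOPLASMIC: {
        "nucleoplasm": 0.45, "nucleolus": 0.25, "nuclear": 0.20, "speckles": 0.10,
    },
    # the nucleolar-cytoplasmic group is dominated by ribosomal-like
    # proteins annotated both in the nucleolus (assembly) and the cytosol
    NucleolarClass.CYTOPLASMIC: {
        "nucleolus": 0.40, "cytosol": 0.40, "cytoplasm": 0.10, "nuclear": 0.10,
    },
    NucleolarClass.NON_NUCLEOLAR: {
        "cytosol": 0.30, "plasma_membrane": 0.15, "extracellular": 0.10,
        "mitochondrion": 0.10, "nuclear": 0.20, "golgi": 0.15,
    },
}

# SILAC cluster centres in (log2 nuc/cyto, log2 nucpl/cyto); at full
# separation every pair of classes is separated on at least one axis
SILAC_LOG2_MEANS = {
    NucleolarClass.ENRICHED: (3.0, 0.8),
    NucleolarClass.NUCLEOPLASMIC: (1.2, 3.2),
    NucleolarClass.CYTOPLASMIC: (1.4, -1.6),
    NucleolarClass.NON_NUCLEOLAR: (-2.4, -0.2),
}

NOLS_BETAS = {
    NucleolarClass.ENRICHED: (9.0, 1.5),
    NucleolarClass.NUCLEOPLASMIC: (5.0, 3.0),
    NucleolarClass.CYTOPLASMIC: (2.0, 6.0),
    NucleolarClass.NON_NUCLEOLAR: (0.8, 10.0),
}

SIGNAL_RATES = {
    NucleolarClass.ENRICHED: 0.01,
    NucleolarClass.NUCLEOPLASMIC: 0.01,
    NucleolarClass.CYTOPLASMIC: 0.01,  # ribosomal-like: no secretory signals
    NucleolarClass.NON_NUCLEOLAR: 0.25,
}
TMD_LAMBDAS = {
    NucleolarClass.ENRICHED: 0.05,
    NucleolarClass.NUCLEOPLASMIC: 0.05,
    NucleolarClass.CYTOPLASMIC: 0.05,
    NucleolarClass.NON_NUCLEOLAR: 0.70,
}
MITO_RATES = {
    NucleolarClass.ENRICHED: 0.02,
    NucleolarClass.NUCLEOPLASMIC: 0.02,
    NucleolarClass.CYTOPLASMIC: 0.02,
    NucleolarClass.NON_NUCLEOLAR: 0.12,
}

#: how each preset scales between-class contrasts
SEPARATION_PRESETS = {"high": 1.0, "medium": 0.85, "low": 0.55}

CLASS_PREFIX = {
    NucleolarClass.ENRICHED: "ENR",
    NucleolarClass.NUCLEOPLASMIC: "NPL",
    NucleolarClass.CYTOPLASMIC: "NCY",
    NucleolarClass.NON_NUCLEOLAR: "NON",
}


def _interp(value: float, toward: float, weight: float) -> float:
    """Pull a class-specific parameter toward the pooled value as the
    separation weight drops below 1."""
    return toward + weight * (value - toward)


@dataclass
class CohortSpec:
    """Fully resolved generation parameters for one synthetic cohort.

    Build one with :func:`default_spec`; every between-class contrast has
    already been scaled by the chosen separation preset.
    """

    class_sizes: Dict[NucleolarClass, int]
    aa_composition: Dict[NucleolarClass, Dict[str, float]]
    length_range: Tuple[int, int]
    signal_rates: Dict[NucleolarClass, float]
    tmd_lambdas: Dict[NucleolarClass, float]
    mito_rates: Dict[NucleolarClass, float]
    nols_betas: Dict[NucleolarClass, Tuple[float, float]]
    go_pool_size: int
    go_shared_pool_size: int
    go_terms_per_protein: Tuple[int, int]
    go_shared_fraction: float
    n_tissues: int
    expr_signal: float
    expr_noise_sd: float
    expr_missing_rate: float
    ppi_within: float
    ppi_between: float
    loc_distributions: Dict[NucleolarClass, Dict[str, float]]
    loc_corruption_rate: float
    loc_missing_rate: float
    silac_log2_means: Dict[NucleolarClass, Tuple[float, float]]
    silac_log2_sd: float
    silac_missing_rate: float
    orthology_probs: Dict[NucleolarClass, Tuple[float, ...]]
    organisms: Tuple[str, ...]
    separation: str
    seed: int

    def __post_init__(self) -> None:
        for cls, size in self.class_sizes.items():
            if size < 2:
                raise ValueError(f"class size for {cls.name} must be >= 2")
        for cls, comp in self.aa_composition.items():
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"composition for {cls.name} sums to {total}, expected 1"
                )
            if any(v < 0 for v in comp.values()):
                raise ValueError(f"negative composition entry for {cls.name}")
        for name, value in [
            ("go_shared_fraction", self.go_shared_fraction),
            ("expr_missing_rate", self.expr_missing_rate),
            ("ppi_within", self.ppi_within),
            ("ppi_between", self.ppi_between),
            ("loc_corruption_rate", self.loc_corruption_rate),
            ("loc_missing_rate", self.loc_missing_rate),
            ("silac_missing_rate", self.silac_missing_rate),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        for cls, probs in self.orthology_probs.items():
            if any(not 0 <= p <= 1 for p in probs):
                raise ValueError(f"orthology probabilities for {cls.name} not in [0,1]")


def default_spec(separation: str = "high", seed: int = 42) -> CohortSpec:
    """The packaged study conditions at a given separation preset.

    Class sizes default to 30/22/24/200 (enriched / nucleoplasmic /
    cytoplasmic / non-nucleolar).  ``separation`` in {high, medium, low}
    scales every between-class contrast.
    """
    if separation not in SEPARATION_PRESETS:
        raise ValueError(
            f"unknown separation preset {separation!r}; "
            f"choose from {sorted(SEPARATION_PRESETS)}"
        )
    w = SEPARATION_PRESETS[separation]

    compositions = {}
    for cls in CLASS_ORDER:
        comp = dict(BASE_COMPOSITION)
        for aa, delta in COMPOSITION_DELTAS[cls].items():
            comp[aa] = max(comp[aa] + w * delta, 0.001)
        total = sum(comp.values())
        compositions[cls] = {aa: v / total for aa, v in comp.items()}

    pooled_signal = float(np.mean(list(SIGNAL_RATES.values())))
    pooled_tmd = float(np.mean(list(TMD_LAMBDAS.values())))
    pooled_mito = float(np.mean(list(MITO_RATES.values())))
    pooled_beta = tuple(np.mean(list(NOLS_BETAS.values()), axis=0))

    return CohortSpec(
        class_sizes={
            NucleolarClass.ENRICHED: 30,
            NucleolarClass.NUCLEOPLASMIC: 22,
            NucleolarClass.CYTOPLASMIC: 24,
            NucleolarClass.NON_NUCLEOLAR: 200,
        },
        aa_composition=compositions,
        length_range=(200, 800),
        signal_rates={
            c: _interp(SIGNAL_RATES[c], pooled_signal, w) for c in CLASS_ORDER
        },
        tmd_lambdas={c: _interp(TMD_LAMBDAS[c], pooled_tmd, w) for c in CLASS_ORDER},
        mito_rates={c: _interp(MITO_RATES[c], pooled_mito, w) for c in CLASS_ORDER},
        nols_betas={
            c: (
                _interp(NOLS_BETAS[c][0], pooled_beta[0], w),
                _interp(NOLS_BETAS[c][1], pooled_beta[1], w),
            )
            for c in CLASS_ORDER
        },
        go_pool_size=12,
        go_shared_pool_size=20,
        go_terms_per_protein=(3, 7),
        # at full separation the class pools are fully disjoint (no shared
        # draws); lower presets mix in a class-blind shared pool
        go_shared_fraction=_interp(0.0, 0.9, w),
        n_tissues=79,
        expr_signal=w,
        expr_noise_sd=0.8,
        expr_missing_rate=0.08,
        ppi_within=_interp(0.25, 0.05, w),
        ppi_between=_interp(0.002, 0.05, w),
        loc_distributions={c: dict(LOC_DISTRIBUTIONS[c]) for c in CLASS_ORDER},
        loc_corruption_rate=_interp(0.10, 0.50, w),
        loc_missing_rate=0.05,
        silac_log2_means={
            c: (w * SILAC_LOG2_MEANS[c][0], w * SILAC_LOG2_MEANS[c][1])
            for c in CLASS_ORDER
        },
        silac_log2_sd=0.4,
        silac_missing_rate=0.15,
        orthology_probs={c: tuple(ORTHOLOGY_PROBS[c]) for c in CLASS_ORDER},
        organisms=ORGANISMS,
        separation=separation,
        seed=seed,
    )


def _protein_ids(spec: CohortSpec) -> Dict[NucleolarClass, List[str]]:
    return {
        cls: [f"{CLASS_PREFIX[cls]}{i + 1:04d}" for i in range(spec.class_sizes[cls])]
        for cls in CLASS_ORDER
    }


def generate_cohort(spec: CohortSpec, out_dir) -> Path:
    """Write a complete cohort directory; identical spec + seed gives
    byte-identical files."""
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ids_by_class = _protein_ids(spec)
    all_ids = [pid for cls in CLASS_ORDER for pid in ids_by_class[cls]]
    label_of = {
        pid: cls for cls in CLASS_ORDER for pid in ids_by_class[cls]
    }

    # --- sequences -------------------------------------------------------
    aa_list = list(AA20)
    with open(out / "sequences.fasta", "w") as fh:
        for cls in CLASS_ORDER:
            probs = np.array([spec.aa_composition[cls][aa] for aa in aa_list])
            probs = probs / probs.sum()
            for pid in ids_by_class[cls]:
                length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
                seq = "".join(rng.choice(aa_list, size=length, p=probs))
                fh.write(f">{pid}\n")
                for i in range(0, length, 60):
                    fh.write(seq[i : i + 60] + "\n")

    # --- labels ----------------------------------------------------------
    with open(out / "labels.tsv", "w") as fh:
        fh.write("id\tclass\n")
        for pid in all_ids:
            fh.write(f"{pid}\t{label_of[pid].value}\n")

    # --- targeting predictor outputs ------------------------------------
    with open(out / "targeting.tsv", "w") as fh:
        fh.write("id\tsignal_peptide\ttmd_count\tmito_peptide\tnols_max\n")
        for cls in CLASS_ORDER:
            a, b = spec.nols_betas[cls]
            for pid in ids_by_class[cls]:
                sp = int(rng.random() < spec.signal_rates[cls])
                tmd = int(rng.poisson(spec.tmd_lambdas[cls]))
                mito = int(rng.random() < spec.mito_rates[cls])
                nols = float(rng.beta(a, b))
                fh.write(f"{pid}\t{sp}\t{tmd}\t{mito}\t{nols:.4f}\n")

    # --- GO annotations --------------------------------------------------
    pools = {
        cls: [f"GO:{7000000 + 100 * ci + k:07d}" for k in range(spec.go_pool_size)]
        for ci, cls in enumerate(CLASS_ORDER)
    }
    shared = [f"GO:{7990000 + k:07d}" for k in range(spec.go_shared_pool_size)]
    with open(out / "go.tsv", "w") as fh:
        fh.write("id\tterm_id\n")
        for cls in CLASS_ORDER:
            for pid in ids_by_class[cls]:
                lo, hi = spec.go_terms_per_protein
                n_terms = int(rng.integers(lo, hi + 1))
                terms = set()
                while len(terms) < n_terms:
                    if rng.random() < spec.go_shared_fraction:
                        terms.add(shared[int(rng.integers(len(shared)))])
                    else:
                        pool = pools[cls]
                        terms.add(pool[int(rng.integers(len(pool)))])
                for t in sorted(terms):
                    fh.write(f"{pid}\t{t}\n")

    # --- expression ------------------------------------------------------
    templates = {
        cls: rng.normal(0.0, 1.0, spec.n_tissues) for cls in CLASS_ORDER
    }
    global_template = rng.normal(0.0, 1.0, spec.n_tissues)
    with open(out / "expression.tsv", "w") as fh:
        fh.write("id\t" + "\t".join(f"tissue{t + 1:02d}" for t in range(spec.n_tissues)) + "\n")
        for cls in CLASS_ORDER:
            for pid in ids_by_class[cls]:
                if rng.random() < spec.expr_missing_rate:
                    continue
                profile = (
                    spec.expr_signal * templates[cls]
                    + (1.0 - spec.expr_signal) * global_template
                    + rng.normal(0.0, spec.expr_noise_sd, spec.n_tissues)
                )
                fh.write(pid + "\t" + "\t".join(f"{v:.6f}" for v in profile) + "\n")

    # --- protein-protein interactions ------------------------------------
    with open(out / "ppi.tsv", "w") as fh:
        fh.write("id_a\tid_b\n")
        for i, a in enumerate(all_ids):
            for b in all_ids[i + 1 :]:
                p = (
                    spec.ppi_within
                    if label_of[a] is label_of[b]
                    else spec.ppi_between
                )
                if rng.random() < p:
                    fh.write(f"{a}\t{b}\n")

    # --- localisation annotations ----------------------------------------
    vocab = sorted(DEFAULT_VOCABULARY)
    with open(out / "localisation.tsv", "w") as fh:
        fh.write("id\tcompartment_label\n")
        for cls in CLASS_ORDER:
            dist = spec.loc_distributions[cls]
            labels = sorted(dist)
            probs = np.array([dist[k] for k in labels])
            probs = probs / probs.sum()
            for pid in ids_by_class[cls]:
                if rng.random() < spec.loc_missing_rate:
                    continue
                n_labels = min(1 + int(rng.poisson(0.8)), 3)
                drawn = set()
                for _ in range(n_labels):
                    lab = labels[int(rng.choice(len(labels), p=probs))]
                    if rng.random() < spec.loc_corruption_rate:
                        lab = vocab[int(rng.integers(len(vocab)))]
                    drawn.add(lab)
                for lab in sorted(drawn):
                    fh.write(f"{pid}\t{lab}\n")

    # --- SILAC ratios -----------------------------------------------------
    with open(out / "silac.tsv", "w") as fh:
        fh.write("id\tnuc_cyto_ratio\tnucpl_cyto_ratio\n")
        for cls in CLASS_ORDER:
            mx, my = spec.silac_log2_means[cls]
            sd = spec.silac_log2_sd
            for pid in ids_by_class[cls]:
                if rng.random() < spec.silac_missing_rate:
                    continue
                # clip at 2 SD: keeps class clusters compact so ratio-space
                # regions remain separable at full contrast
                lx = float(np.clip(rng.normal(mx, sd), mx - 2 * sd, mx + 2 * sd))
                ly = float(np.clip(rng.normal(my, sd), my - 2 * sd, my + 2 * sd))
                fh.write(f"{pid}\t{2.0 ** lx:.6f}\t{2.0 ** ly:.6f}\n")

    # --- orthology --------------------------------------------------------
    with open(out / "orthology.tsv", "w") as fh:
        fh.write("id\torganism\n")
        for cls in CLASS_ORDER:
            probs = spec.orthology_probs[cls]
            for pid in ids_by_class[cls]:
                for org, p in zip(spec.organisms, probs):
                    if rng.random() < p:
                        fh.write(f"{pid}\t{org}\n")

    return out


def cohort_checksum(cohort_dir) -> str:
    """SHA-256 over all cohort files (sorted); convenient for determinism
    checks."""
    h = hashlib.sha256()
    for path in sorted(Path(cohort_dir).glob("*")):
        h.update(path.name.encode())
        h.update(path.read_bytes())
    return h.hexdigest()
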