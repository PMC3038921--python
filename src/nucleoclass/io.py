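"""Readers and writers for cohort files, plus negative-set sampling.

All tabular inputs are tab-separated files with a header row; lines starting
with ``#`` are comments.  Sequences arrive as FASTA.  GO annotations may
alternatively arrive as GAF 2.x.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    AnnotationBundle,
    LabelledCorpus,
    LocalisationDistanceMap,
    NucleolarClass,
    ProteinRecord,
    SilacRatios,
    TargetingRecord,
)

logger = logging.getLogger("nucleoclass")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_targeting",
    "read_go",
    "read_expression",
    "read_ppi",
    "read_localisation",
    "read_labels",
    "read_silac",
    "read_orthology",
    "load_cohort",
    "sample_non_nucleolar",
    "COHORT_FILENAMES",
]

#: canonical file names inside a cohort directory
COHORT_FILENAMES = {
    "fasta": "sequences.fasta",
    "targeting": "targeting.tsv",
    "go": "go.tsv",
    "expression": "expression.tsv",
    "ppi": "ppi.tsv",
    "localisation": "localisation.tsv",
    "labels": "labels.tsv",
    "silac": "silac.tsv",
    "orthology": "orthology.tsv",
}


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_fasta(path) -> List[ProteinRecord]:
    """Read protein records; duplicate ids are a hard error."""
    records: List[ProteinRecord] = []
    seen: Set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise ValueError(f"{path}: FASTA record with empty header")
        if entry.id in seen:
            raise ValueError(f"{path}: duplicate protein id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(entry.id, str(entry.seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _as_bool(x: str, path, col: str) -> bool:
    if x in ("0", "1"):
        return x == "1"
    raise ValueError(f"{path}: column {col} must be 0/1, got {x!r}")


def read_targeting(path) -> Dict[str, TargetingRecord]:
    df = _read_tsv(path)
    out = {}
    for row in df.itertuples(index=False):
        nols = None if pd.isna(row.nols_max) or row.nols_max == "NA" else float(row.nols_max)
        out[row.id] = TargetingRecord(
            signal_peptide=_as_bool(row.signal_peptide, path, "signal_peptide"),
            tmd_count=int(row.tmd_count),
            mito_peptide=_as_bool(row.mito_peptide, path, "mito_peptide"),
            nols_max=nols,
        )
    return out


def _is_gaf(path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.startswith("!gaf-version") or line.startswith("!")
    return False


def read_go(path) -> Dict[str, FrozenSet[str]]:
    """Read GO annotations from a two-column TSV (id, term_id) or GAF 2.x.

    GAF rows use column 2 (DB object id) and column 5 (GO id); qualifier
    ``NOT`` rows are dropped.
    """
    terms: Dict[str, Set[str]] = {}
    if _is_gaf(path):
        with open(path) as fh:
            for line in fh:
                if line.startswith("!") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 5:
                    raise ValueError(f"{path}: malformed GAF line: {line!r}")
                if "NOT" in cols[3].split("|"):
                    continue
                terms.setdefault(cols[1], set()).add(cols[4])
    else:
        df = _read_tsv(path)
        for row in df.itertuples(index=False):
            terms.setdefault(row.id, set()).add(row.term_id)
    return {k: frozenset(v) for k, v in terms.items()}


def read_expression(path) -> Tuple[Dict[str, np.ndarray], Tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    tissues = tuple(df.columns[1:])
    profiles = {
        str(row[0]): np.asarray(row[1:], dtype=float)
        for row in df.itertuples(index=False)
    }
    return profiles, tissues


def read_ppi(path) -> Dict[str, FrozenSet[str]]:
    df = _read_tsv(path)
    return AnnotationBundle.adjacency_from_edges(
        (row.id_a, row.id_b) for row in df.itertuples(index=False)
    )


def read_localisation(
    path, distance_map: Optional[LocalisationDistanceMap] = None
) -> Dict[str, FrozenSet[str]]:
    dmap = distance_map or LocalisationDistanceMap()
    df = _read_tsv(path)
    out: Dict[str, Set[str]] = {}
    for row in df.itertuples(index=False):
        label = row.compartment_label.strip().lower()
        if not dmap.knows(label):
            raise ValueError(
                f"{path}: unknown compartment label {label!r} for {row.id}"
            )
        out.setdefault(row.id, set()).add(label)
    return {k: frozenset(v) for k, v in out.items()}


def read_labels(path, provenance: str = "") -> Dict[str, NucleolarClass]:
    df = _read_tsv(path)
    out: Dict[str, NucleolarClass] = {}
    for pid, label in zip(df["id"], df["class"]):
        if pid in out:
            raise ValueError(f"{path}: duplicate labelled id {pid!r}")
        out[pid] = NucleolarClass.from_label(label)
    return out


def read_silac(path) -> Dict[str, SilacRatios]:
    df = _read_tsv(path)
    return {
        row.id: SilacRatios(float(row.nuc_cyto_ratio), float(row.nucpl_cyto_ratio))
        for row in df.itertuples(index=False)
    }


def read_orthology(path) -> Dict[str, FrozenSet[str]]:
    df = _read_tsv(path)
    out: Dict[str, Set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.id, set()).add(row.organism)
    return {k: frozenset(v) for k, v in out.items()}


def load_cohort(
    fasta_path,
    annotation_paths: Union[Mapping[str, Union[str, Path]], str, Path, None] = None,
    labels_path=None,
    distance_map: Optional[LocalisationDistanceMap] = None,
    provenance: str = "",
) -> Tuple[List[ProteinRecord], AnnotationBundle, Optional[LabelledCorpus]]:
    """Load a full cohort: sequences, annotations, and optional labels.

    ``annotation_paths`` may be a mapping from annotation kind
    (``targeting``, ``go``, ``expression``, ``ppi``, ``localisation``,
    ``silac``, ``orthology``) to a file path, or a directory containing the
    canonical file names (see :data:`COHORT_FILENAMES`).  Annotations for
    proteins absent from the FASTA are retained but logged.
    """
    records = read_fasta(fasta_path)
    known = {r.id for r in records}
    dmap = distance_map or LocalisationDistanceMap()

    paths: Dict[str, Path] = {}
    if annotation_paths is None:
        pass
    elif isinstance(annotation_paths, (str, Path)):
        d = Path(annotation_paths)
        for kind, name in COHORT_FILENAMES.items():
            if kind in ("fasta", "labels"):
                continue
            p = d / name
            if p.exists():
                paths[kind] = p
    else:
        paths = {k: Path(v) for k, v in annotation_paths.items()}
        unknown_kinds = set(paths) - (set(COHORT_FILENAMES) - {"fasta", "labels"})
        if unknown_kinds:
            raise ValueError(f"unknown annotation kinds: {sorted(unknown_kinds)}")

    bundle_kwargs: Dict[str, object] = {"distance_map": dmap}
    if "targeting" in paths:
        bundle_kwargs["targeting"] = read_targeting(paths["targeting"])
    if "go" in paths:
        bundle_kwargs["go_terms"] = read_go(paths["go"])
    if "expression" in paths:
        profiles, tissues = read_expression(paths["expression"])
        bundle_kwargs["expression"] = profiles
        bundle_kwargs["tissues"] = tissues
    if "ppi" in paths:
        bundle_kwargs["interactions"] = read_ppi(paths["ppi"])
    if "localisation" in paths:
        bundle_kwargs["localisations"] = read_localisation(paths["localisation"], dmap)
    if "silac" in paths:
        bundle_kwargs["silac"] = read_silac(paths["silac"])
    if "orthology" in paths:
        bundle_kwargs["orthology"] = read_orthology(paths["orthology"])

    bundle = AnnotationBundle(**bundle_kwargs)

    for kind in ("targeting", "go_terms", "expression", "localisations", "silac", "orthology"):
        table = getattr(bundle, kind)
        strays = set(table) - known
        if strays:
            logger.warning(
                "%d %s annotations refer to proteins absent from the FASTA "
                "(e.g. %s); they are retained.",
                len(strays), kind, sorted(strays)[0],
            )

    corpus = None
    if labels_path is not None:
        labels = read_labels(labels_path)
        missing = set(labels) - known
        if missing:
            raise ValueError(
                f"labelled proteins absent from FASTA: {sorted(missing)[:5]}"
            )
        by_id = {r.id: r for r in records}
        corpus = LabelledCorpus(
            [(by_id[pid], cls) for pid, cls in labels.items()], provenance
        )
    return records, bundle, corpus


def load_cohort_dir(cohort_dir, distance_map=None, provenance: str = ""):
    """Convenience wrapper: load a cohort from a directory written by
    :func:`nucleoclass.simulate.generate_cohort`."""
    d = Path(cohort_dir)
    labels = d / COHORT_FILENAMES["labels"]
    return load_cohort(
        d / COHORT_FILENAMES["fasta"],
        d,
        labels_path=labels if labels.exists() else None,
        distance_map=distance_map,
        provenance=provenance,
    )


def sample_non_nucleolar(
    pool: List[ProteinRecord],
    nucleolar_annotated: Set[str],
    n: int,
    seed: int,
) -> LabelledCorpus:
    """Randomly draw ``n`` proteins not annotated as nucleolar.

    The draw is seeded and platform-stable; output preserves pool order.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    eligible = [r for r in pool if r.id not in nucleolar_annotated]
    if len(eligible) < n:
        raise ValueError(
            f"cannot sample {n} non-nucleolar proteins: only "
            f"{len(eligible)} available after excluding nucleolar-annotated"
        )
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(eligible), size=n, replace=False).tolist())
    return LabelledCorpus(
        [(eligible[i], NucleolarClass.NON_NUCLEOLAR) for i in idx],
        provenance=f"sampled-non-nucleolar(seed={seed})",
    )
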